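import random

import numpy as np
import pytest

from wincorr.correct import (AnchoredConsensus, correct_read, make_aligner,
                             realign_consensus, resolve_overlap,
                             run_correction, run_polishing)
from wincorr.edit import edit_distance
from wincorr.io_seq import (SeqRecord, SequenceStore, read_fasta, write_fasta,
                            write_paf)
from wincorr.kmers import kmer_codes
from wincorr.piles import Window, build_piles
from wincorr.synthetic import (evaluate_correction, random_genome,
                               simulate_reads, truth_overlaps)


@pytest.fixture
def aligner(params):
    return make_aligner(params)


class TestRealignConsensus:
    def test_identity(self, params, aligner):
        tmpl = random_genome(2000, 0.5, 1)
        w = Window(500, 1000)
        ac = realign_consensus(tmpl, tmpl[500:1000], w, params, aligner, {})
        assert ac is not None
        assert (ac.tb, ac.te) == (500, 1000)
        assert (ac.qb, ac.qe) == (0, 500)
        assert len(ac.blocks) == 1

    def test_insertion_keeps_interval(self, params, aligner):
        tmpl = random_genome(2000, 0.5, 2)
        w = Window(500, 1000)
        cons = tmpl[500:750] + "A" + tmpl[750:1000]
        ac = realign_consensus(tmpl, cons, w, params, aligner, {})
        assert ac is not None
        assert (ac.tb, ac.te) == (500, 1000)
        assert ac.qe - ac.qb == 501
        assert len(ac.blocks) == 2  # one insertion op splits the blocks

    def test_shuffled_consensus_discarded(self, params, aligner):
        rng = random.Random(3)
        tmpl = random_genome(2000, 0.5, 3)
        shuffled = list(tmpl[500:1000])
        rng.shuffle(shuffled)
        ac = realign_consensus(tmpl, "".join(shuffled), Window(500, 1000),
                               params, aligner, {})
        assert ac is None

    def test_empty_consensus(self, params, aligner):
        tmpl = random_genome(2000, 0.5, 4)
        assert realign_consensus(tmpl, "", Window(0, 500), params, aligner,
                                 {}) is None


def _anchored(window, consensus, tb, te, counts):
    return AnchoredConsensus(
        window=window, consensus=consensus, tb=tb, te=te,
        qb=0, qe=len(consensus),
        blocks=[(tb, te, 0, len(consensus))], kmer_counts=counts,
    )


class TestResolveOverlap:
    def test_tie_keeps_right(self, params):
        seq = random_genome(500, 0.5, 5)
        counts = {int(c): params.kmer_solidity
                  for c in kmer_codes(seq, params.k)}
        left = _anchored(Window(0, 500), seq, 0, 500, counts)
        right = _anchored(Window(450, 950), seq, 450, 950, counts)
        resolve_overlap(left, right, params)
        assert left.te == 450       # left trimmed: right wins ties
        assert right.tb == 450

    def test_more_solid_kmers_wins(self, params):
        seq = random_genome(500, 0.5, 6)
        solid = {int(c): params.kmer_solidity
                 for c in kmer_codes(seq, params.k)}
        left = _anchored(Window(0, 500), seq, 0, 500, solid)
        right = _anchored(Window(450, 950), seq, 450, 950, {})
        resolve_overlap(left, right, params)
        assert left.te == 500       # left untouched
        assert right.tb == 500      # right trimmed past the overlap

    def test_zero_overlap_unchanged(self, params):
        a = _anchored(Window(0, 500), "A" * 500, 0, 500, {})
        b = _anchored(Window(450, 950), "A" * 500, 500, 1000, {})
        resolve_overlap(a, b, params)
        assert (a.tb, a.te, b.tb, b.te) == (0, 500, 500, 1000)


def _sim_files(tmp_path, genome_len, coverage, error_rate, seed,
               mean_length=2000):
    genome = random_genome(genome_len, 0.5, seed)
    reads, truths = simulate_reads(genome, coverage, mean_length=mean_length,
                                   error_rate=error_rate, seed=seed)
    paf = truth_overlaps(truths, {r.id: len(r.seq) for r in reads})
    rp, pp = tmp_path / "reads.fa", tmp_path / "ovl.paf"
    write_fasta(reads, rp)
    write_paf(paf, pp)
    return genome, reads, truths, rp, pp


class TestCorrectRead:
    def test_error_free_fixpoint(self, tmp_path, params):
        genome, reads, truths, rp, pp = _sim_files(tmp_path, 6000, 15, 0.0, 7)
        out = tmp_path / "corr.fa"
        run_correction(rp, pp, out, params)
        corrected = read_fasta(out)
        assert [r.id for r in corrected] == [r.id for r in reads]
        upper_seen = False
        for orig, corr in zip(reads, corrected):
            assert corr.seq.upper() == orig.seq
            upper_seen |= any(c.isupper() for c in corr.seq)
        assert upper_seen

    def test_no_pile_fully_lowercase(self, params):
        store = SequenceStore()
        rec = SeqRecord("r", random_genome(2000, 0.5, 8))
        store.add("r", rec.seq)
        corrected, stats = correct_read(rec, None, store, params)
        assert corrected.seq == rec.seq.lower()
        assert stats.windows == 0

    def test_noisy_read_tenfold_improvement(self, tmp_path, params):
        genome, reads, truths, rp, pp = _sim_files(tmp_path, 9000, 45, 0.12, 9)
        store = SequenceStore.from_records(reads)
        from wincorr.io_seq import parse_paf
        piles = build_piles(parse_paf(pp), params, store=store)
        # pick a mid-genome read with decent coverage
        target = max(reads, key=lambda r: len(piles.get(r.id).tuples)
                     if r.id in piles else 0)
        truth = next(t for t in truths if t.id == target.id)
        corrected, stats = correct_read(target, piles[target.id], store,
                                        params)
        true_seq = truth.true_sequence(genome)
        before = edit_distance(target.seq, true_seq)
        after = edit_distance(corrected.seq.upper(), true_seq)
        assert stats.processed > 0
        assert after * 10 <= before

    def test_lowercase_spans_are_input_substrings_in_order(self, tmp_path,
                                                           params):
        genome, reads, truths, rp, pp = _sim_files(tmp_path, 6000, 20, 0.12, 10)
        out = tmp_path / "corr.fa"
        run_correction(rp, pp, out, params)
        import re
        for orig, corr in zip(reads, read_fasta_cased(out)):
            pos = 0
            for run in re.findall(r"[acgt]+", corr.seq):
                found = orig.seq.find(run.upper(), pos)
                assert found >= 0
                pos = found + len(run)


def read_fasta_cased(path):
    """Case-preserving FASTA reader for checking the output mask."""
    records = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append(SeqRecord(name, "".join(chunks)))
                name, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append(SeqRecord(name, "".join(chunks)))
    return records


class TestRunCorrection:
    def test_empty_paf_returns_lowercase_input(self, tmp_path, params):
        reads = [SeqRecord("a", random_genome(1500, 0.5, 11)),
                 SeqRecord("b", random_genome(1200, 0.5, 12))]
        rp, pp, out = tmp_path / "r.fa", tmp_path / "o.paf", tmp_path / "c.fa"
        write_fasta(reads, rp)
        pp.write_text("")
        run_correction(rp, pp, out, params)
        got = read_fasta_cased(out)
        assert [(r.id, r.seq) for r in got] == [
            (r.id, r.seq.lower()) for r in reads
        ]

    def test_worker_count_does_not_change_output(self, tmp_path, params):
        genome, reads, truths, rp, pp = _sim_files(tmp_path, 5000, 15, 0.10, 13)
        out1, out4 = tmp_path / "c1.fa", tmp_path / "c4.fa"
        run_correction(rp, pp, out1, params, threads=1)
        run_correction(rp, pp, out4, params, threads=4)
        assert out1.read_bytes() == out4.read_bytes()

    def test_improves_error_rate(self, tmp_path, params):
        genome, reads, truths, rp, pp = _sim_files(tmp_path, 8000, 30, 0.12, 14)
        out = tmp_path / "c.fa"
        run_correction(rp, pp, out, params)
        report = evaluate_correction(reads, read_fasta(out), truths, genome)
        assert report.error_rate_after < report.error_rate_before / 5


class TestRunPolishing:
    def test_perfect_inputs_identity(self, tmp_path, params):
        genome = random_genome(4000, 0.5, 15)
        contig = SeqRecord("ctg", genome)
        reads, truths = simulate_reads(genome, 25, error_rate=0.0, seed=15)
        paf = []
        for t in truths:
            from wincorr.io_seq import OverlapRecord
            paf.append(OverlapRecord(
                t.id, t.length, 0, t.length, t.strand, "ctg", len(genome),
                t.start, t.end, t.length, t.length, 255))
        cp, rp, pp = tmp_path / "ctg.fa", tmp_path / "r.fa", tmp_path / "o.paf"
        write_fasta([contig], cp)
        write_fasta(reads, rp)
        write_paf(paf, pp)
        out = tmp_path / "p.fa"
        run_polishing(cp, rp, pp, out, params)
        (got,) = read_fasta(out)
        assert got.seq == genome

    def test_contig_shorter_than_window_unchanged(self, tmp_path, params):
        genome = random_genome(4000, 0.5, 16)
        short = SeqRecord("short", genome[:400])  # < window length 500
        reads, truths = simulate_reads(genome, 20, error_rate=0.0, seed=16)
        from wincorr.io_seq import OverlapRecord
        paf = [OverlapRecord(t.id, t.length, 0, min(400, t.length), t.strand,
                             "short", 400, 0, 400, 300, 400, 255)
               for t in truths if t.start == 0]
        cp, rp, pp = tmp_path / "c.fa", tmp_path / "r.fa", tmp_path / "o.paf"
        write_fasta([short], cp)
        write_fasta(reads, rp)
        write_paf(paf, pp)
        out = tmp_path / "p.fa"
        run_polishing(cp, rp, pp, out, params)
        (got,) = read_fasta_cased(out)
        assert got.seq == short.seq.lower()

    def test_zero_mapped_reads_returns_contig(self, tmp_path, params):
        contig = SeqRecord("ctg", random_genome(2000, 0.5, 17))
        reads = [SeqRecord("r0", random_genome(1000, 0.5, 18))]
        cp, rp, pp = tmp_path / "c.fa", tmp_path / "r.fa", tmp_path / "o.paf"
        write_fasta([contig], cp)
        write_fasta(reads, rp)
        pp.write_text("")
        out = tmp_path / "p.fa"
        run_polishing(cp, rp, pp, out, params)
        (got,) = read_fasta_cased(out)
        assert got.seq == contig.seq.lower()
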