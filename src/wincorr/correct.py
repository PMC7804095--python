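"""Per-read correction orchestration and assembly-polishing mode.

For each template (read, or contig in polishing mode): extract coverage
windows from its alignment pile, compute each window's segmented POA
consensus, polish it on a local de Bruijn graph, realign it to the
template around its source window, resolve overlaps between consecutive
consensi by solid k-mer counts, and splice the winning factors back into
the read.  Corrected bases are reported in uppercase, untouched bases in
lowercase.
"""

from __future__ import annotations

import logging
import multiprocessing as mp
from dataclasses import dataclass, field

from Bio import Align

from .dbg_polish import build_local_dbg, polish_consensus
from .kmers import kmer_codes
from .io_seq import SeqRecord, SequenceStore, parse_paf, read_fasta, write_fasta
from .params import Params
from .piles import (AlignmentPile, Window, build_piles, extract_windows,
                    support_array, window_sequences)
from .segmentation import full_msa_consensus, segmented_consensus

log = logging.getLogger(__name__)


@dataclass
class CorrectedRead:
    id: str
    seq: str                 # uppercase = corrected, lowercase = untouched


@dataclass
class AnchoredConsensus:
    window: Window
    consensus: str
    tb: int                  # aligned interval on the full template
    te: int
    qb: int                  # aligned interval on the consensus
    qe: int
    blocks: list[tuple[int, int, int, int]]   # (t0, t1, q0, q1) aligned runs
    kmer_counts: dict[str, int]


@dataclass
class ReadStats:
    windows: int = 0
    processed: int = 0
    skipped_anchors: int = 0
    skipped_realign: int = 0

    def add(self, other: "ReadStats") -> None:
        self.windows += other.windows
        self.processed += other.processed
        self.skipped_anchors += other.skipped_anchors
        self.skipped_realign += other.skipped_realign


def make_aligner(params: Params) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_score
    aligner.extend_gap_score = params.gap_score
    return aligner


def realign_consensus(
    template: str, consensus: str, window: Window, params: Params,
    aligner: Align.PairwiseAligner, kmer_counts: dict[str, int],
) -> AnchoredConsensus | None:
    """Locally align the consensus to the template around its window.

    The slice is the window extended by the inter-window overlap O on both
    sides.  A consensus is discarded (window left uncorrected) when its
    alignment score falls below ``realign_min_identity`` times the perfect
    all-match score: unlike a matches-over-length ratio, the score charges
    the gaps a chimeric sequence needs to fake matches.
    """
    if not consensus:
        return None
    lo = max(0, window.wb - params.window_overlap)
    hi = min(len(template), window.we + params.window_overlap)
    alignments = aligner.align(template[lo:hi], consensus)
    floor = params.realign_min_identity * params.match_score * len(consensus)
    if alignments.score < max(floor, 1):
        return None
    aln = alignments[0]
    tblocks, qblocks = aln.aligned
    blocks = [
        (int(t0) + lo, int(t1) + lo, int(q0), int(q1))
        for (t0, t1), (q0, q1) in zip(tblocks, qblocks)
    ]
    return AnchoredConsensus(
        window=window, consensus=consensus,
        tb=blocks[0][0], te=blocks[-1][1],
        qb=blocks[0][2], qe=blocks[-1][3],
        blocks=blocks, kmer_counts=kmer_counts,
    )


def _map_template_pos(blocks, tpos: int) -> int:
    """Consensus coordinate of the first aligned base at or after tpos."""
    for t0, t1, q0, q1 in blocks:
        if tpos <= t0:
            return q0
        if tpos < t1:
            return q0 + (tpos - t0)
    return blocks[-1][3]


def _solid_count(seq: str, counts: dict[int, int], k: int, solidity: int) -> int:
    n = 0
    for code in kmer_codes(seq, k).tolist():
        if counts.get(code, 0) >= solidity:
            n += 1
    return n


def resolve_overlap(
    left: AnchoredConsensus, right: AnchoredConsensus, params: Params
) -> None:
    """Assign the overlapping template span wholly to one consensus.

    The winner is the consensus whose overlapping factor holds more solid
    k-mers, solidity judged against each consensus's own source-window
    frequency table; ties go to the right (i+1-th) consensus.  The loser
    is trimmed in place.
    """
    s = right.tb
    e = min(left.te, right.te)
    if e <= s:
        return
    k = params.k
    lq0 = _map_template_pos(left.blocks, s)
    left_sub = left.consensus[lq0:left.qe]
    rq1 = _map_template_pos(right.blocks, e)
    right_sub = right.consensus[right.qb:rq1]
    n_left = _solid_count(left_sub, left.kmer_counts, k, params.kmer_solidity)
    n_right = _solid_count(right_sub, right.kmer_counts, k, params.kmer_solidity)
    if n_left > n_right:
        right.tb = e
        right.qb = _map_template_pos(right.blocks, e)
    else:
        left.te = s
        left.qe = _map_template_pos(left.blocks, s)


def correct_read(
    record: SeqRecord, pile: AlignmentPile | None, store: SequenceStore,
    params: Params, aligner: Align.PairwiseAligner | None = None,
) -> tuple[CorrectedRead, ReadStats]:
    """Correct one template read from its alignment pile."""
    stats = ReadStats()
    template = record.seq.upper()
    if pile is None or not pile.tuples:
        return CorrectedRead(record.id, template.lower()), stats
    if aligner is None:
        aligner = make_aligner(params)
    support = support_array(pile, len(template))
    windows = extract_windows(support, params)
    stats.windows = len(windows)
    anchored: list[AnchoredConsensus] = []
    for window in windows:
        ws = window_sequences(pile, window, store, params)
        seqs = [ws.template_seq] + ws.members
        if params.segmentation:
            consensus = segmented_consensus(seqs, params)
        else:
            consensus = full_msa_consensus(seqs, params) or None
        if consensus is None:
            stats.skipped_anchors += 1
            continue
        dbg = build_local_dbg(seqs, params.k, params.kmer_solidity)
        consensus = polish_consensus(consensus, seqs, params, dbg=dbg)
        ac = realign_consensus(
            template, consensus, window, params, aligner, dbg.counts
        )
        if ac is None:
            stats.skipped_realign += 1
            continue
        anchored.append(ac)
        stats.processed += 1
    anchored.sort(key=lambda a: (a.tb, a.te))
    for i in range(len(anchored) - 1):
        resolve_overlap(anchored[i], anchored[i + 1], params)
    parts: list[str] = []
    pos = 0
    for ac in anchored:
        if ac.te <= ac.tb or ac.qe <= ac.qb or ac.tb < pos:
            continue
        parts.append(template[pos:ac.tb].lower())
        parts.append(ac.consensus[ac.qb:ac.qe].upper())
        pos = ac.te
    parts.append(template[pos:].lower())
    return CorrectedRead(record.id, "".join(parts)), stats


# -- parallel driver -----------------------------------------------------

_WORKER: dict = {}


def _init_worker(store, piles, params):
    _WORKER["store"] = store
    _WORKER["piles"] = piles
    _WORKER["params"] = params
    _WORKER["aligner"] = make_aligner(params)


def _work(record: SeqRecord):
    pile = _WORKER["piles"].get(record.id)
    corrected, stats = correct_read(
        record, pile, _WORKER["store"], _WORKER["params"], _WORKER["aligner"]
    )
    return corrected, stats


def _run(
    templates: list[SeqRecord],
    store: SequenceStore,
    piles: dict[str, AlignmentPile],
    params: Params,
    out_path,
    threads: int = 1,
) -> ReadStats:
    """Correct every template in input order; output is byte-identical for
    any worker count (ordered result collection)."""
    total = ReadStats()
    out_records: list[SeqRecord] = []
    if threads <= 1:
        _init_worker(store, piles, params)
        results = map(_work, templates)
    else:
        pool = mp.Pool(
            threads, initializer=_init_worker, initargs=(store, piles, params)
        )
        chunk = max(1, len(templates) // (threads * 4))
        results = pool.imap(_work, templates, chunksize=chunk)
    for corrected, stats in results:
        out_records.append(SeqRecord(corrected.id, corrected.seq))
        total.add(stats)
    if threads > 1:
        pool.close()
        pool.join()
    write_fasta(out_records, out_path)
    return total


def run_correction(
    reads_path, paf_path, out_path, params: Params, threads: int = 1
) -> ReadStats:
    """Self-correction: every read is a template; reads appear exactly once
    in the output, in input order."""
    records = read_fasta(reads_path)
    store = SequenceStore.from_records(records)
    piles = build_piles(parse_paf(paf_path), params, store=store)
    stats = _run(records, store, piles, params, out_path, threads)
    log.info(
        "corrected %d reads: %d windows (%d processed, %d skipped for "
        "anchors, %d skipped at realignment)",
        len(records), stats.windows, stats.processed,
        stats.skipped_anchors, stats.skipped_realign,
    )
    return stats


def run_polishing(
    contigs_path, reads_path, paf_path, out_path, params: Params,
    threads: int = 1,
) -> ReadStats:
    """Assembly polishing: same engine with contigs as the only templates
    (reads never become templates; no reciprocal piles)."""
    contigs = read_fasta(contigs_path)
    reads = read_fasta(reads_path)
    store = SequenceStore.from_records(list(contigs) + list(reads))
    contig_ids = {c.id for c in contigs}
    piles = build_piles(
        parse_paf(paf_path), params, store=store, templates=contig_ids
    )
    stats = _run(contigs, store, piles, params, out_path, threads)
    log.info(
        "polished %d contigs: %d windows (%d processed)",
        len(contigs), stats.windows, stats.processed,
    )
    return stats
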