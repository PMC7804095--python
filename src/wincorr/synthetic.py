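"""Seeded synthetic data and a base-level correction evaluator.

The read simulator is a deliberately simplified stand-in for an
indel-dominant long-read simulator: per-base error events are drawn
i.i.d. with the requested total rate and split between insertions,
deletions and substitutions according to the mix proportions (defaults
0.145 : 0.06 : 0.02, i.e. the classic PacBio-like profile at 12% total).
Ground-truth genome intervals are recorded per read, true overlaps are
derived from interval intersections, and the evaluator measures recall,
precision and pre/post error rates against the per-read truth by exact
edit-distance alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edit import edit_ops
from .io_seq import OverlapRecord, SeqRecord, reverse_complement

DEFAULT_ERROR_MIX = (0.145, 0.06, 0.02)   # insertion : deletion : substitution

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReadTruth:
    id: str
    start: int          # genome interval [start, end)
    end: int
    strand: str         # '+' or '-'
    n_ins: int = 0      # introduced error events by type
    n_del: int = 0
    n_sub: int = 0

    @property
    def n_errors(self) -> int:
        return self.n_ins + self.n_del + self.n_sub

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def error_fraction(self) -> float:
        return self.n_errors / self.length if self.length else 0.0

    def true_sequence(self, genome: str) -> str:
        seq = genome[self.start:self.end]
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass
class EvalReport:
    reads: int
    bases_in: int
    bases_out: int
    error_rate_before: float      # percent
    error_rate_after: float       # percent
    recall: float                 # percent of erroneous bases repaired
    precision: float              # percent of modified bases that are correct

    def as_dict(self) -> dict:
        return {
            "reads": self.reads,
            "bases_in": self.bases_in,
            "bases_out": self.bases_out,
            "error_rate_before_pct": self.error_rate_before,
            "error_rate_after_pct": self.error_rate_after,
            "recall_pct": self.recall,
            "precision_pct": self.precision,
        }


def random_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """i.i.d. random genome with the requested GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return bytes(_BASES[codes]).decode("ascii")


def _mutate(true_seq: str, error_rate: float, mix,
            rng) -> tuple[str, tuple[int, int, int]]:
    """Apply i.i.d. per-base error events; returns the mutated sequence and
    the (insertions, deletions, substitutions) event counts."""
    n = len(true_seq)
    if error_rate <= 0:
        return true_seq, (0, 0, 0)
    mix = np.asarray(mix, dtype=float)
    mix = mix / mix.sum()
    raw = np.frombuffer(true_seq.encode("ascii"), dtype=np.uint8)
    hit = rng.random(n) < error_rate
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return true_seq, (0, 0, 0)
    kinds = rng.choice(3, size=idx.size, p=mix)          # 0 ins, 1 del, 2 sub
    rand_bases = _BASES[rng.integers(0, 4, size=idx.size)]
    sub_shift = rng.integers(1, 4, size=idx.size)
    parts: list[bytes] = []
    pos = 0
    code_of = {65: 0, 67: 1, 71: 2, 84: 3}
    for i, k, rb, sh in zip(idx.tolist(), kinds.tolist(),
                            rand_bases.tolist(), sub_shift.tolist()):
        parts.append(raw[pos:i].tobytes())
        if k == 0:      # insertion after the current base
            parts.append(raw[i:i + 1].tobytes())
            parts.append(bytes([rb]))
        elif k == 1:    # deletion
            pass
        else:           # substitution with a different base
            c = (code_of[raw[i]] + sh) % 4
            parts.append(bytes([int(_BASES[c])]))
        pos = i + 1
    parts.append(raw[pos:].tobytes())
    counts = (
        int((kinds == 0).sum()), int((kinds == 1).sum()),
        int((kinds == 2).sum()),
    )
    return b"".join(parts).decode("ascii"), counts


def corrupt_sequence(
    seq: str,
    error_rate: float,
    seed: int = 0,
    error_mix=DEFAULT_ERROR_MIX,
) -> tuple[str, np.ndarray]:
    """Mutated copy of ``seq`` plus a coordinate map.

    The returned array has length len(seq) + 1 and maps every original
    position (and the end sentinel) to its position in the mutated
    sequence — the exact projection needed to build ground-truth overlap
    records against the corrupted copy (e.g. a contig with injected
    errors).
    """
    rng = np.random.default_rng(seed)
    n = len(seq)
    mix = np.asarray(error_mix, dtype=float)
    mix = mix / mix.sum()
    hit = rng.random(n) < error_rate
    idx = np.nonzero(hit)[0]
    kinds = rng.choice(3, size=idx.size, p=mix)       # 0 ins, 1 del, 2 sub
    rand_bases = _BASES[rng.integers(0, 4, size=idx.size)]
    sub_shift = rng.integers(1, 4, size=idx.size)
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code_of = {65: 0, 67: 1, 71: 2, 84: 3}
    delta = np.zeros(n + 1, dtype=np.int64)           # length change AFTER pos
    parts: list[bytes] = []
    pos = 0
    for i, k, rb, sh in zip(idx.tolist(), kinds.tolist(),
                            rand_bases.tolist(), sub_shift.tolist()):
        parts.append(raw[pos:i].tobytes())
        if k == 0:
            parts.append(raw[i:i + 1].tobytes())
            parts.append(bytes([rb]))
            delta[i + 1] += 1
        elif k == 1:
            delta[i + 1] -= 1
        else:
            c = (code_of[raw[i]] + sh) % 4
            parts.append(bytes([int(_BASES[c])]))
        pos = i + 1
    parts.append(raw[pos:].tobytes())
    mutated = b"".join(parts).decode("ascii")
    pos_map = np.arange(n + 1, dtype=np.int64) + np.cumsum(delta)
    return mutated, pos_map


def simulate_reads(
    genome: str,
    coverage: float,
    mean_length: int = 3000,
    error_rate: float = 0.12,
    error_mix=DEFAULT_ERROR_MIX,
    seed: int = 0,
    min_length: int = 1000,
) -> tuple[list[SeqRecord], list[ReadTruth]]:
    """Noisy reads with per-read ground truth.

    Start positions are uniform, lengths log-normal truncated to
    [min_length, len(genome)], strands equiprobable, and errors drawn per
    base by the mix proportions on the read-oriented true sequence.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    glen = len(genome)
    if glen < min_length:
        raise ValueError(
            f"genome ({glen} bp) shorter than minimum read length {min_length}"
        )
    rng = np.random.default_rng(seed)
    sigma = 0.35
    mu = np.log(mean_length) - sigma * sigma / 2.0
    target = coverage * glen
    reads: list[SeqRecord] = []
    truths: list[ReadTruth] = []
    total = 0
    i = 0
    while total < target:
        length = int(rng.lognormal(mu, sigma))
        length = max(min_length, min(glen, length))
        start = int(rng.integers(0, glen - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        truth_seq = genome[start:start + length]
        if strand == "-":
            truth_seq = reverse_complement(truth_seq)
        seq, (ni, nd, ns) = _mutate(truth_seq, error_rate, error_mix, rng)
        name = f"read{i:06d}"
        reads.append(SeqRecord(name, seq))
        truths.append(ReadTruth(name, start, start + length, strand,
                                ni, nd, ns))
        total += length
        i += 1
    return reads, truths


def truth_overlaps(
    truths: list[ReadTruth],
    read_lengths: dict[str, int],
    min_overlap: int = 500,
) -> list[OverlapRecord]:
    """PAF records for every read pair whose genome intervals intersect by
    at least ``min_overlap`` bases, projected into read coordinates.

    The identity field is approximated as (1 - e1)(1 - e2) from the
    per-read error fractions; it is only used for N-best pile ranking.
    """
    order = sorted(range(len(truths)), key=lambda i: truths[i].start)
    records: list[OverlapRecord] = []

    def project(t: ReadTruth, os: int, oe: int, lr: int) -> tuple[int, int]:
        span = t.end - t.start
        fb = (os - t.start) / span
        fe = (oe - t.start) / span
        if t.strand == "+":
            b, e = round(fb * lr), round(fe * lr)
        else:
            b, e = round((1 - fe) * lr), round((1 - fb) * lr)
        b = max(0, min(lr - 1, b))
        e = max(b + 1, min(lr, e))
        return b, e

    for oi, i in enumerate(order):
        ti = truths[i]
        for j in order[oi + 1:]:
            tj = truths[j]
            if tj.start >= ti.end - min_overlap + 1:
                break
            os_, oe = max(ti.start, tj.start), min(ti.end, tj.end)
            if oe - os_ < min_overlap:
                continue
            li = read_lengths[ti.id]
            lj = read_lengths[tj.id]
            qb, qe = project(ti, os_, oe, li)
            tb, te = project(tj, os_, oe, lj)
            strand = "+" if ti.strand == tj.strand else "-"
            ident = (1 - ti.error_fraction) * (1 - tj.error_fraction)
            blocklen = oe - os_
            records.append(OverlapRecord(
                qname=ti.id, qlen=li, qstart=qb, qend=qe, strand=strand,
                tname=tj.id, tlen=lj, tstart=tb, tend=te,
                nmatch=max(1, round(ident * blocklen)), blocklen=blocklen,
                mapq=255,
            ))
    return records


def write_truth_table(truths: list[ReadTruth], path) -> None:
    with open(path, "w") as fh:
        for t in truths:
            fh.write(f"{t.id}\t{t.start}\t{t.end}\t{t.strand}"
                     f"\t{t.n_ins}\t{t.n_del}\t{t.n_sub}\n")


def read_truth_table(path) -> list[ReadTruth]:
    truths = []
    with open(path) as fh:
        for line in fh:
            name, start, end, strand, ni, nd, ns = line.rstrip("\n").split("\t")
            truths.append(ReadTruth(name, int(start), int(end), strand,
                                    int(ni), int(nd), int(ns)))
    return truths


def _error_positions(truth_seq: str, read_seq: str) -> tuple[int, set]:
    dist, pos, kind = edit_ops(truth_seq, read_seq)
    marks = set()
    for p, k in zip(pos.tolist(), kind.tolist()):
        # insertions sit between truth bases; offset them off the integer grid
        marks.add(p + 0.5 if k == 3 else p)
    return dist, marks


def evaluate_correction(
    originals: list[SeqRecord],
    corrected: list[SeqRecord],
    truths: list[ReadTruth],
    genome: str,
) -> EvalReport:
    """Base-level recall / precision / error rates against per-read truth.

    Recall is the fraction of originally erroneous base positions no
    longer erroneous after correction; precision the fraction of changed
    positions that became correct; error rates are edit distance over
    truth length, expressed in percent.
    """
    truth_by_id = {t.id: t for t in truths}
    corr_by_id = {r.id: r for r in corrected}
    pre_edits = post_edits = truth_total = 0
    repaired = broken = err_before = 0
    bases_in = bases_out = 0
    n = 0
    for orig in originals:
        truth = truth_by_id.get(orig.id)
        if truth is None:
            raise KeyError(f"read id {orig.id!r} missing from truth table")
        corr = corr_by_id.get(orig.id)
        if corr is None:
            raise KeyError(f"read id {orig.id!r} missing from corrected reads")
        truth_seq = truth.true_sequence(genome)
        d_pre, e_pre = _error_positions(truth_seq, orig.seq.upper())
        d_post, e_post = _error_positions(truth_seq, corr.seq.upper())
        pre_edits += d_pre
        post_edits += d_post
        truth_total += len(truth_seq)
        err_before += len(e_pre)
        repaired += len(e_pre - e_post)
        broken += len(e_post - e_pre)
        bases_in += len(orig.seq)
        bases_out += len(corr.seq)
        n += 1
    modified = repaired + broken
    return EvalReport(
        reads=n,
        bases_in=bases_in,
        bases_out=bases_out,
        error_rate_before=100.0 * pre_edits / truth_total if truth_total else 0.0,
        error_rate_after=100.0 * post_edits / truth_total if truth_total else 0.0,
        recall=100.0 * repaired / err_before if err_before else 0.0,
        precision=100.0 * repaired / modified if modified else 100.0,
    )
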