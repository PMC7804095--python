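"""Anchor-chain segmentation of window MSAs.

Shared, non-repeated k-mers act as anchors pinning collinear segments of
the window's sequences.  A longest chain of mutually order-consistent
anchors (adjacent pairs co-occurring in >= T sequences) splits one large
MSA into many small, cheap ones whose consensi are concatenated back
together around the anchors.  Only sequences containing both bordering
anchors take part in a segment's MSA, which excludes spurious sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import anchor_compat_kernel
from .kmers import decode_kmer, kmer_codes
from .msa_poa import poa_consensus
from .params import Params


@dataclass
class AnchorCandidate:
    """A k-mer occurring exactly once in every sequence that contains it."""

    kmer: str
    positions: dict[int, int]    # sequence index -> start of the occurrence


@dataclass
class AnchorChain:
    anchors: list[AnchorCandidate]
    pair_support: list[int]      # co-occurrence count of each adjacent pair

    def __len__(self) -> int:
        return len(self.anchors)


def _candidate_matrix(
    seqs: list[str], k: int, min_sequences: int
) -> tuple[np.ndarray, np.ndarray]:
    """(codes, P): anchor k-mer codes and their position matrix
    (candidate x sequence, -1 when absent), sorted by template position,
    then by mean position for candidates absent from the template."""
    n_seqs = len(seqs)
    code_arrs, seq_arrs, pos_arrs, banned = [], [], [], []
    for i, seq in enumerate(seqs):
        codes = kmer_codes(seq, k)
        if codes.size == 0:
            continue
        uniq, first, counts = np.unique(
            codes, return_index=True, return_counts=True
        )
        banned.append(uniq[counts > 1])
        once = counts == 1
        code_arrs.append(uniq[once])
        pos_arrs.append(first[once])
        seq_arrs.append(np.full(int(once.sum()), i, dtype=np.int64))
    empty = np.empty(0, np.int64), np.empty((0, n_seqs), np.int64)
    if not code_arrs:
        return empty
    codes = np.concatenate(code_arrs)
    seq_idx = np.concatenate(seq_arrs)
    pos = np.concatenate(pos_arrs)
    order = np.argsort(codes, kind="stable")
    codes, seq_idx, pos = codes[order], seq_idx[order], pos[order]
    uniq, starts, counts = np.unique(codes, return_index=True,
                                     return_counts=True)
    bad = np.unique(np.concatenate(banned)) if banned else np.empty(0, np.int64)
    keep = (counts >= min_sequences) & ~np.isin(uniq, bad)
    if not keep.any():
        return empty
    member_keep = np.repeat(keep, counts)
    rows = np.repeat(np.arange(int(keep.sum())), counts[keep])
    P = np.full((int(keep.sum()), n_seqs), -1, dtype=np.int64)
    P[rows, seq_idx[member_keep]] = pos[member_keep]
    cand_codes = uniq[keep]
    # sort: candidates on the template first by template position, the rest
    # by mean position
    present = P >= 0
    mean_pos = np.where(present, P, 0).sum(axis=1) / present.sum(axis=1)
    on_template = P[:, 0] >= 0
    primary = np.where(on_template, 0, 1)
    secondary = np.where(on_template, P[:, 0].astype(float), mean_pos)
    order = np.lexsort((np.arange(P.shape[0]), secondary, primary))
    return cand_codes[order], P[order]


def _to_candidates(cand_codes: np.ndarray, P: np.ndarray,
                   k: int) -> list[AnchorCandidate]:
    out = []
    for code, row in zip(cand_codes.tolist(), P):
        idx = np.nonzero(row >= 0)[0]
        out.append(AnchorCandidate(
            decode_kmer(code, k),
            dict(zip(idx.tolist(), row[idx].tolist())),
        ))
    return out


def select_anchor_candidates(
    seqs: list[str], k: int, min_sequences: int
) -> list[AnchorCandidate]:
    """k-mers unique within each containing sequence, present in enough
    sequences, sorted by template position (mean position when absent
    from the template)."""
    cand_codes, P = _candidate_matrix(seqs, k, min_sequences)
    return _to_candidates(cand_codes, P, k)


def _position_matrix(
    candidates: list[AnchorCandidate], n_seqs: int
) -> np.ndarray:
    P = np.full((len(candidates), n_seqs), -1, dtype=np.int64)
    for i, cand in enumerate(candidates):
        for s, p in cand.positions.items():
            P[i, s] = p
    return P


def chain_is_valid(
    chain: list[int], P: np.ndarray, k: int, min_support: int
) -> bool:
    """Recheck both chain conditions on explicit candidate indices."""
    present = P >= 0
    for a in range(len(chain)):
        for b in range(a + 1, len(chain)):
            i, j = chain[a], chain[b]
            both = present[i] & present[j]
            if np.any(P[j, both] < P[i, both] + k):
                return False
            if b == a + 1 and int(both.sum()) < min_support:
                return False
    return True


def _chain_search(P: np.ndarray, k: int, min_support: int,
                  max_expansions: int) -> tuple[list[int], np.ndarray]:
    """Longest all-pairs-valid chain over position-sorted candidates.

    Depth-first search with a cardinality bound, seeded with a greedy
    left-to-right chain so that pruning bites immediately; exact whenever
    the expansion budget is not exhausted (it never is on collinear
    inputs).  Extension checks the running AND of the order rows of the
    whole chain, so every returned chain is valid for all pairs, not just
    adjacent ones.  Ties resolve to the leftmost chain by exploration
    order.
    """
    n = P.shape[0]
    if n == 0:
        return [], np.zeros((0, 0), np.int32)
    order_ok, co = anchor_compat_kernel(
        np.ascontiguousarray(P, dtype=np.int32), k
    )
    adj_ok = order_ok & (co >= min_support)

    greedy: list[int] = []
    gcompat = np.ones(n, dtype=bool)
    for j in range(n):
        if gcompat[j] and (not greedy or adj_ok[greedy[-1], j]):
            greedy.append(j)
            gcompat &= order_ok[j]
    best = list(greedy)

    chain: list[int] = []
    compat: list[np.ndarray] = [np.ones(n, dtype=bool)]
    expansions = 0

    def search(idx: int) -> None:
        nonlocal expansions, best
        if len(chain) + (n - idx) <= len(best):
            return
        if idx == n or expansions > max_expansions:
            return
        expansions += 1
        j = idx
        if compat[-1][j] and (not chain or adj_ok[chain[-1], j]):
            chain.append(j)
            compat.append(compat[-1] & order_ok[j])
            if len(chain) > len(best):
                best = list(chain)
            search(idx + 1)
            chain.pop()
            compat.pop()
        search(idx + 1)

    search(0)
    return best, co


def longest_anchor_chain(
    candidates: list[AnchorCandidate],
    n_seqs: int,
    k: int,
    min_support: int,
    max_expansions: int = 50000,
) -> AnchorChain:
    """Longest chain of order-consistent anchors (see ``_chain_search``)."""
    if not candidates:
        return AnchorChain([], [])
    P = _position_matrix(candidates, n_seqs)
    best, co = _chain_search(P, k, min_support, max_expansions)
    anchors = [candidates[i] for i in best]
    support = [int(co[best[i], best[i + 1]]) for i in range(len(best) - 1)]
    return AnchorChain(anchors, support)


def _piece_consensus(seqs: list[str], params: Params) -> str:
    return poa_consensus(
        seqs, params.match_score, params.mismatch_score, params.gap_score
    )


def segmented_consensus(seqs: list[str], params: Params) -> str | None:
    """Window consensus assembled from per-segment MSAs, or None (skip)
    when fewer than ``min_anchors`` chain anchors are found.

    Reconstruction: consensus(prefix) + a1 + consensus(]a1,a2[) + a2 +
    ... + an + consensus(suffix), each local MSA running only on the
    sequences that contain the bordering anchors (the window template,
    sequence 0, leads whenever it participates).
    """
    k = params.k
    cand_codes, P = _candidate_matrix(seqs, k, params.anchor_support)
    best, _co = _chain_search(P, k, params.anchor_support,
                              params.chain_max_expansions)
    if len(best) < params.min_anchors:
        return None
    parts: list[str] = []

    def piece(rows: list[tuple[int, str]]) -> str:
        rows.sort(key=lambda p: p[0])
        return _piece_consensus([s for _, s in rows], params)

    first = best[0]
    pres = np.nonzero(P[first] >= 0)[0]
    parts.append(piece([(int(s), seqs[s][:P[first, s]]) for s in pres]))
    parts.append(decode_kmer(int(cand_codes[first]), k))
    for left, right in zip(best, best[1:]):
        both = np.nonzero((P[left] >= 0) & (P[right] >= 0))[0]
        parts.append(piece([
            (int(s), seqs[s][P[left, s] + k: P[right, s]]) for s in both
        ]))
        parts.append(decode_kmer(int(cand_codes[right]), k))
    last = best[-1]
    pres = np.nonzero(P[last] >= 0)[0]
    parts.append(piece([(int(s), seqs[s][P[last, s] + k:]) for s in pres]))
    return "".join(parts)


def full_msa_consensus(seqs: list[str], params: Params) -> str:
    """Single whole-window MSA (segmentation disabled)."""
    return poa_consensus(
        seqs, params.match_score, params.mismatch_score, params.gap_score
    )
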