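"""Local de Bruijn graph polishing of window consensi.

A small-k de Bruijn graph over the window's sequences separates solid
k-mers (frequency >= the solidity threshold) from weak ones.  Runs of
weak k-mers on the consensus, flanked by sketches of solid k-mers, are
re-spelled by paths linking a left-flank anchor to a right-flank anchor;
weak extremities are re-spelled by greedily following highest-weight
edges outward from the innermost solid anchor.

k-mers are handled as 2-bit integer codes throughout (see ``kmers``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmers import decode_kmer, kmer_codes
from .params import Params


@dataclass
class LocalDBG:
    k: int
    counts: dict[int, int]             # k-mer code -> frequency
    solid: set[int]
    solid_sorted: np.ndarray
    succ: dict[int, dict[int, int]]    # weights = (k+1)-mer counts
    pred: dict[int, dict[int, int]]

    def is_solid(self, kmer: str) -> bool:
        codes = kmer_codes(kmer, self.k)
        return codes.size == 1 and int(codes[0]) in self.solid

    def solid_kmers(self) -> set[str]:
        return {decode_kmer(c, self.k) for c in self.solid}


@dataclass
class WeakRegion:
    ws: int                      # first weak k-mer position on the consensus
    we: int                      # last weak k-mer position (inclusive)
    left_anchors: list[int] = field(default_factory=list)   # nearest first
    right_anchors: list[int] = field(default_factory=list)  # nearest first
    kind: str = "internal"       # internal | left | right | isolated


def build_local_dbg(seqs: list[str], k: int, solidity: int) -> LocalDBG:
    """Graph over the solid k-mers of the window's sequences (template
    included); edge weights count the supporting (k+1)-mers."""
    karrs = [kmer_codes(s, k) for s in seqs]
    karrs = [a for a in karrs if a.size]
    if not karrs:
        return LocalDBG(k, {}, set(), np.empty(0, np.int64), {}, {})
    uniq, cnt = np.unique(np.concatenate(karrs), return_counts=True)
    counts = dict(zip(uniq.tolist(), cnt.tolist()))
    solid_sorted = uniq[cnt >= solidity]
    solid = set(solid_sorted.tolist())
    succ: dict[int, dict[int, int]] = {}
    pred: dict[int, dict[int, int]] = {}
    k1arrs = [kmer_codes(s, k + 1) for s in seqs]
    k1arrs = [a for a in k1arrs if a.size]
    if k1arrs:
        u1, c1 = np.unique(np.concatenate(k1arrs), return_counts=True)
        mask = np.int64(4) ** k - 1
        pre = u1 >> 2
        suf = u1 & mask
        ok = np.isin(pre, solid_sorted) & np.isin(suf, solid_sorted)
        for a, b, w in zip(pre[ok].tolist(), suf[ok].tolist(),
                           c1[ok].tolist()):
            succ.setdefault(a, {})[b] = w
            pred.setdefault(b, {})[a] = w
    return LocalDBG(k, counts, solid, solid_sorted, succ, pred)


def find_weak_regions(consensus: str, dbg: LocalDBG, n: int) -> list[WeakRegion]:
    """Maximal runs of weak consensus k-mers with up to n solid flanking
    anchor positions on each side; a missing flank flags an extremity."""
    k = dbg.k
    codes = kmer_codes(consensus, k)
    m = codes.size
    if m == 0:
        return []
    weak = ~np.isin(codes, dbg.solid_sorted)
    regions: list[WeakRegion] = []
    i = 0
    while i < m:
        if not weak[i]:
            i += 1
            continue
        j = i
        while j < m and weak[j]:
            j += 1
        region = WeakRegion(i, j - 1)
        p = i - 1
        while p >= 0 and not weak[p] and len(region.left_anchors) < n:
            region.left_anchors.append(p)
            p -= 1
        p = j
        while p < m and not weak[p] and len(region.right_anchors) < n:
            region.right_anchors.append(p)
            p += 1
        if not region.left_anchors and not region.right_anchors:
            region.kind = "isolated"
        elif not region.left_anchors:
            region.kind = "left"
        elif not region.right_anchors:
            region.kind = "right"
        regions.append(region)
        i = j
    return regions


def _dfs_path(dbg: LocalDBG, source: int, target: int, max_edges: int,
              budget: int) -> list[int] | None:
    """Depth-first search with backtracking from source to target,
    following heavier edges first; at most ``budget`` node expansions."""
    if source not in dbg.solid or target not in dbg.solid:
        return None
    path = [source]
    expanded = 0

    def rec(node: int, depth: int) -> bool:
        nonlocal expanded
        if depth >= max_edges or expanded >= budget:
            return False
        expanded += 1
        succs = dbg.succ.get(node)
        if not succs:
            return False
        for nxt in sorted(succs, key=lambda x: (-succs[x], x)):
            if nxt == target:
                path.append(nxt)
                return True
            path.append(nxt)
            if rec(nxt, depth + 1):
                return True
            path.pop()
        return False

    if rec(source, 0):
        return path
    return None


def repair_internal(consensus: str, dbg: LocalDBG, region: WeakRegion,
                    params: Params,
                    codes: np.ndarray | None = None
                    ) -> tuple[int, int, str] | None:
    """Try to link left-flank to right-flank anchors through the graph.

    Anchor pairs are tried nearest-to-the-region first; on success returns
    (start, end, replacement) on consensus coordinates, on failure None
    (the region is left unpolished).
    """
    k = dbg.k
    if codes is None:
        codes = kmer_codes(consensus, k)
    region_len = region.we - region.ws + k
    pairs = sorted(
        ((pl, pr) for pl in region.left_anchors for pr in region.right_anchors),
        key=lambda p: (region.ws - p[0]) + (p[1] - region.we),
    )
    for pl, pr in pairs:
        source = int(codes[pl])
        target = int(codes[pr])
        max_edges = (pr - pl) + max(10, region_len // 2) + k
        found = _dfs_path(dbg, source, target, max_edges,
                          params.dbg_max_expansions)
        if found is not None:
            spelled = decode_kmer(found[0], k) + "".join(
                "ACGT"[node & 3] for node in found[1:]
            )
            return pl, pr + k, spelled
    return None


def repair_extremity(consensus: str, dbg: LocalDBG, region: WeakRegion,
                     params: Params,
                     codes: np.ndarray | None = None
                     ) -> tuple[int, int, str] | None:
    """Greedy highest-weight walk outward from the innermost solid anchor,
    truncated at the length of the region to polish or at a dead end."""
    k = dbg.k
    if codes is None:
        codes = kmer_codes(consensus, k)
    high_shift = 2 * (k - 1)
    if region.kind == "left":
        p = region.right_anchors[0]
        target_len = p
        cur = int(codes[p])
        out: list[str] = []
        while len(out) < target_len:
            preds = dbg.pred.get(cur)
            if not preds:
                break
            cur = min(preds, key=lambda x: (-preds[x], x))
            out.append("ACGT"[cur >> high_shift])
        if not out:
            return None
        return 0, p, "".join(reversed(out))
    if region.kind == "right":
        p = region.left_anchors[0]
        target_len = len(consensus) - (p + k)
        cur = int(codes[p])
        out = []
        while len(out) < target_len:
            succs = dbg.succ.get(cur)
            if not succs:
                break
            cur = min(succs, key=lambda x: (-succs[x], x))
            out.append("ACGT"[cur & 3])
        if not out:
            return None
        return p + k, len(consensus), "".join(out)
    return None


def polish_consensus(consensus: str, seqs: list[str], params: Params,
                     dbg: LocalDBG | None = None) -> str:
    """Repair every weak region of the consensus, left to right; bases not
    covered by a successful repair are preserved verbatim."""
    k = params.k
    if len(consensus) < k:
        return consensus
    if dbg is None:
        dbg = build_local_dbg(seqs, k, params.kmer_solidity)
    if not dbg.solid:
        return consensus
    regions = find_weak_regions(consensus, dbg, params.flank_solid)
    if not regions:
        return consensus
    codes = kmer_codes(consensus, k)
    edits: list[tuple[int, int, str]] = []
    for region in regions:
        if region.kind == "internal":
            edit = repair_internal(consensus, dbg, region, params, codes)
        elif region.kind in ("left", "right"):
            edit = repair_extremity(consensus, dbg, region, params, codes)
        else:
            edit = None
        if edit is not None:
            edits.append(edit)
    if not edits:
        return consensus
    parts: list[str] = []
    pos = 0
    for start, end, repl in edits:
        if start < pos:
            continue  # overlapping repair spans: keep the earlier one
        parts.append(consensus[pos:start])
        parts.append(repl)
        pos = end
    parts.append(consensus[pos:])
    return "".join(parts)
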