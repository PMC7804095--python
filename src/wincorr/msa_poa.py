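"""Partial-order-graph multiple sequence alignment and majority consensus.

The running MSA is a DAG with one base per node.  It is initialized with
the window's template, then iteratively enriched: each further sequence is
locally aligned to the graph (generalized Smith-Waterman, see
``_kernels.poa_align_kernel``) and merged in, fusing matching nodes,
attaching mismatching bases as aligned-to alternatives of the same MSA
column and appending insertions as fresh nodes.  Flattening the graph by
aligned-to equivalence classes yields the MSA matrix from which consensus
is called by per-column majority vote with template tie-breaking.
"""

from __future__ import annotations

import numpy as np

from ._kernels import poa_align_kernel, topo_csr_kernel

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_LUT = np.zeros(256, dtype=np.int8)
for _b, _c in _CODE.items():
    _LUT[ord(_b)] = _c
_BASE = "ACGT"
GAP = "-"


def encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class POAGraph:
    """DAG storage for a running multiple sequence alignment."""

    def __init__(self) -> None:
        self.labels: list[int] = []
        self.preds: list[list[int]] = []
        self.succ_w: list[dict[int, int]] = []
        self.class_of: list[int] = []
        self.classes: dict[int, list[int]] = {}
        self.traces: list[list[int]] = []
        self._next_class = 0
        # flat edge arrays mirroring succ_w, for the compiled topo/CSR pass
        self._eu: list[int] = []
        self._ev: list[int] = []

    # -- construction -----------------------------------------------------

    def _new_node(self, label: int, cls: int | None = None) -> int:
        v = len(self.labels)
        self.labels.append(label)
        self.preds.append([])
        self.succ_w.append({})
        if cls is None:
            cls = self._next_class
            self._next_class += 1
            self.classes[cls] = []
        self.class_of.append(cls)
        self.classes[cls].append(v)
        return v

    def _add_edge(self, u: int, v: int) -> None:
        w = self.succ_w[u]
        if v in w:
            w[v] += 1
        else:
            w[v] = 1
            self.preds[v].append(u)
            self._eu.append(u)
            self._ev.append(v)

    @property
    def n_sequences(self) -> int:
        return len(self.traces)

    def _flatten(self):
        n = len(self.labels)
        eu = np.asarray(self._eu, dtype=np.int32)
        ev = np.asarray(self._ev, dtype=np.int32)
        placed, topo, indptr, pred_idx = topo_csr_kernel(n, eu, ev)
        if int(placed) != n:
            raise RuntimeError("POA graph contains a cycle")
        return np.asarray(self.labels, dtype=np.int8), topo, indptr, pred_idx

    def topo_order(self) -> list[int]:
        return self._flatten()[1].tolist()

    # -- alignment --------------------------------------------------------

    def align(self, seq: str, match: int = 2, mismatch: int = -3,
              gap: int = -2):
        """Local alignment of ``seq`` to the graph; returns (score, ops)."""
        labels, topo, indptr, flat = self._flatten()
        query = encode(seq)
        score, ops_n, ops_q = poa_align_kernel(
            labels, topo, indptr, flat, query,
            np.int32(match), np.int32(mismatch), np.int32(gap),
        )
        return int(score), list(zip(ops_n.tolist(), ops_q.tolist()))

    def add_alignment(self, seq: str, ops) -> None:
        """Merge an aligned sequence into the graph (one trace per call)."""
        query = encode(seq)
        consumed = [j for _, j in ops if j >= 0]
        jstart = consumed[0] if consumed else len(seq)
        jend = consumed[-1] if consumed else len(seq) - 1
        full_ops = (
            [(-1, j) for j in range(jstart)]
            + list(ops)
            + [(-1, j) for j in range(jend + 1, len(seq))]
        )
        prev = None
        trace: list[int] = []
        for v, j in full_ops:
            if j < 0:
                continue  # graph node skipped by this sequence
            base = int(query[j])
            if v >= 0 and self.labels[v] == base:
                node = v
            elif v >= 0:
                node = -1
                for cand in self.classes[self.class_of[v]]:
                    if self.labels[cand] == base:
                        node = cand
                        break
                if node < 0:
                    node = self._new_node(base, self.class_of[v])
            else:
                node = self._new_node(base)
            if prev is not None and prev != node:
                self._add_edge(prev, node)
            prev = node
            trace.append(node)
        self.traces.append(trace)

    # -- flattening -------------------------------------------------------

    def msa_matrix(self) -> list[str]:
        """Rows of the MSA (row 0 = template); gap symbol '-'.

        Columns are aligned-to equivalence classes ordered topologically;
        in the rare case a trace visits two nodes of one class, the later
        node is split into a fresh column so that removing gaps from any
        row always reproduces its sequence exactly.
        """
        for _ in range(len(self.labels) + 1):
            order = self.topo_order()
            rank = {v: r for r, v in enumerate(order)}
            cls_rank = {
                c: min(rank[v] for v in nodes)
                for c, nodes in self.classes.items()
                if nodes
            }
            cols = sorted(cls_rank, key=lambda c: cls_rank[c])
            col_of = {c: i for i, c in enumerate(cols)}
            conflicts: list[int] = []
            for trace in self.traces:
                last = -1
                for v in trace:
                    c = col_of[self.class_of[v]]
                    if c <= last:
                        conflicts.append(v)
                    else:
                        last = c
            if not conflicts:
                rows = []
                for trace in self.traces:
                    row = [GAP] * len(cols)
                    for v in trace:
                        row[col_of[self.class_of[v]]] = _BASE[self.labels[v]]
                    rows.append("".join(row))
                return rows
            for v in set(conflicts):
                if len(self.classes[self.class_of[v]]) == 1:
                    continue
                old = self.class_of[v]
                self.classes[old].remove(v)
                cls = self._next_class
                self._next_class += 1
                self.classes[cls] = [v]
                self.class_of[v] = cls
        raise RuntimeError("could not linearize MSA columns")


def init_graph(template: str) -> POAGraph:
    """Linear chain of template bases; every edge starts with weight 1."""
    if not template:
        raise ValueError("template sequence must be non-empty")
    g = POAGraph()
    prev = None
    trace = []
    for base in template:
        v = g._new_node(_CODE.get(base, 0))
        if prev is not None:
            g._add_edge(prev, v)
        prev = v
        trace.append(v)
    g.traces.append(trace)
    return g


def align_to_graph(graph: POAGraph, seq: str, match: int = 2,
                   mismatch: int = -3, gap: int = -2):
    return graph.align(seq, match, mismatch, gap)


def add_alignment(graph: POAGraph, seq: str, ops) -> None:
    graph.add_alignment(seq, ops)


def consensus_from_matrix(rows: list[str], weights: list[int] | None = None) -> str:
    """Per-column majority vote; ties resolve to the template symbol when it
    participates, otherwise to the lexicographically smallest base; a
    winning gap emits nothing.  Optional per-row weights stand in for
    duplicated rows."""
    if not rows:
        raise ValueError("empty MSA matrix")
    if weights is None:
        weights = [1] * len(rows)
    ncols = len(rows[0])
    if ncols == 0:
        return ""
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(rows), ncols)
    w = np.asarray(weights, dtype=np.int64)[:, None]
    syms = np.frombuffer(b"-ACGT", dtype=np.uint8)
    counts = np.empty((5, ncols), dtype=np.int64)
    for s in range(5):
        counts[s] = ((arr == syms[s]) * w).sum(axis=0)
    top = counts.max(axis=0)
    n_winners = (counts == top).sum(axis=0)
    first_win = np.argmax(counts == top, axis=0)
    # index of the template symbol in '-ACGT'
    tmpl_idx = np.zeros(ncols, dtype=np.int64)
    for s in range(1, 5):
        tmpl_idx[arr[0] == syms[s]] = s
    tmpl_wins = counts[tmpl_idx, np.arange(ncols)] == top
    base_hits = counts[1:] == top
    has_base_win = base_hits.any(axis=0)
    first_base_win = np.argmax(base_hits, axis=0) + 1
    choice = np.where(
        n_winners == 1, first_win,
        np.where(tmpl_wins, tmpl_idx,
                 np.where(has_base_win, first_base_win, 0)),
    )
    keep = choice != 0
    return bytes(syms[choice[keep]]).decode("ascii")


def poa_consensus(seqs: list[str], match: int = 2, mismatch: int = -3,
                  gap: int = -2) -> str:
    """Consensus of a set of sequences; seqs[0] acts as the template."""
    seqs = [s for s in seqs]
    if not seqs:
        return ""
    first = seqs[0]
    if all(s == first for s in seqs):
        return first
    nonempty = [s for s in seqs if s]
    # empty rows would be all-gap in the matrix; give them their vote here
    if 2 * len(nonempty) <= len(seqs):
        return ""
    if not first:
        return poa_consensus(nonempty, match, mismatch, gap)
    # adding a duplicate sequence never changes the graph topology, so
    # identical rows are collapsed into one weighted row
    weights: dict[str, int] = {first: 1}
    order = [first]
    for seq in seqs[1:]:
        if not seq:
            continue
        if seq in weights:
            weights[seq] += 1
        else:
            weights[seq] = 1
            order.append(seq)
    # with an absolute-majority string no column can out-vote it, and with
    # two variants every column goes to the heavier one (template on ties)
    total = sum(weights.values())
    heaviest = max(order, key=lambda s: weights[s])
    if 2 * weights[heaviest] > total:
        return heaviest
    if len(order) == 2:
        return order[0] if weights[order[0]] >= weights[order[1]] else order[1]
    graph = init_graph(first)
    for seq in order[1:]:
        _, ops = graph.align(seq, match, mismatch, gap)
        graph.add_alignment(seq, ops)
    return consensus_from_matrix(graph.msa_matrix(),
                                 [weights[s] for s in order])
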