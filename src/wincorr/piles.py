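"""Alignment piles, per-base support and window extraction.

An alignment pile collects, for one template read A, the tuples
(A, R, Ab, Ae, Rb, Re, S) describing every retained overlap of A.  Windows
are fixed-length intervals of A whose every base is supported by at least
``min_support`` pile reads; consecutive windows overlap by
``window_overlap`` bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io_seq import OverlapRecord, SequenceStore
from .params import Params


@dataclass(frozen=True)
class AlignmentTuple:
    template: str       # A
    read: str           # R
    ab: int
    ae: int
    rb: int
    re: int
    reverse: bool       # S: True when R aligns reverse-complement to A
    identity: float


@dataclass
class AlignmentPile:
    template: str
    tuples: list[AlignmentTuple]


@dataclass(frozen=True)
class Window:
    """Half-open interval [wb, we) on the template; we - wb == window_length."""

    wb: int
    we: int


@dataclass
class WindowSequences:
    window: Window
    template_seq: str            # A[wb:we)
    members: list[str]           # projected pile subsequences, forward strand


def _sort_key(t: AlignmentTuple):
    # identity desc, longer template span first, then read id for determinism
    return (-t.identity, -(t.ae - t.ab), t.read, t.ab, t.rb)


def build_piles(
    overlaps: Iterable[OverlapRecord],
    params: Params,
    store: SequenceStore | None = None,
    templates: set[str] | None = None,
) -> dict[str, AlignmentPile]:
    """Group overlap records into per-template piles, capped at the N best.

    Every PAF line contributes a tuple to the pile of its query and a
    mirrored tuple to the pile of its target.  When ``templates`` is given
    (assembly-polishing mode), piles are only built for those ids and no
    mirrored read piles are created.  Self-overlaps are dropped: a read
    must not vote for itself.
    """
    piles: dict[str, list[AlignmentTuple]] = {}
    for rec in overlaps:
        if rec.qname == rec.tname:
            continue
        if store is not None:
            for name in (rec.qname, rec.tname):
                if name not in store:
                    raise KeyError(f"overlap references unknown read id {name!r}")
        reverse = rec.strand == "-"
        ident = rec.identity
        if templates is None or rec.qname in templates:
            piles.setdefault(rec.qname, []).append(AlignmentTuple(
                rec.qname, rec.tname, rec.qstart, rec.qend,
                rec.tstart, rec.tend, reverse, ident,
            ))
        if templates is None or rec.tname in templates:
            piles.setdefault(rec.tname, []).append(AlignmentTuple(
                rec.tname, rec.qname, rec.tstart, rec.tend,
                rec.qstart, rec.qend, reverse, ident,
            ))
    out: dict[str, AlignmentPile] = {}
    for name, tuples in piles.items():
        tuples.sort(key=_sort_key)
        out[name] = AlignmentPile(name, tuples[: params.max_overlaps])
    return out


def support_array(pile: AlignmentPile, template_length: int) -> np.ndarray:
    """Per-base count of pile tuples covering each template position."""
    delta = np.zeros(template_length + 1, dtype=np.int32)
    for t in pile.tuples:
        delta[t.ab] += 1
        delta[t.ae] -= 1
    return np.cumsum(delta[:-1]).astype(np.int32)


def extract_windows(support: np.ndarray, params: Params) -> list[Window]:
    """Fixed-length windows over maximal runs of support >= min_support.

    Within a run, windows start at the run start and advance by stride
    L - O; if the last stride overshoots the run, a final window is
    right-aligned to end exactly at the run end.
    """
    L, O, C = params.window_length, params.window_overlap, params.min_support
    ok = support >= C
    windows: list[Window] = []
    n = len(ok)
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        run_len = j - i
        if run_len >= L:
            stride = L - O
            start = i
            while start + L <= j:
                windows.append(Window(start, start + L))
                start += stride
            if windows[-1].we < j:
                windows.append(Window(j - L, j))
        i = j
    return windows


def project_interval(
    t: AlignmentTuple, tb: int, te: int
) -> tuple[int, int]:
    """Map template interval [tb, te) into read coordinates.

    Linear interpolation between the overlap endpoint pairs; with S=1 the
    template interval lands on the reverse strand of R, so the returned
    forward-strand read interval is mirrored.
    """
    span_a = t.ae - t.ab
    span_r = t.re - t.rb
    fb = (tb - t.ab) / span_a
    fe = (te - t.ab) / span_a
    if not t.reverse:
        rb = t.rb + round(fb * span_r)
        re = t.rb + round(fe * span_r)
    else:
        rb = t.rb + round((1.0 - fe) * span_r)
        re = t.rb + round((1.0 - fb) * span_r)
    return rb, re


def window_sequences(
    pile: AlignmentPile, window: Window, store: SequenceStore,
    params: Params,
) -> WindowSequences:
    """Template factor plus projected member subsequences for one window.

    Members are clipped to the window, projected through the overlap
    endpoints and oriented to the template's forward strand; projections
    shorter than k bases are dropped.
    """
    template_seq = store.get(pile.template, window.wb, window.we)
    members: list[str] = []
    for t in pile.tuples:
        tb = max(t.ab, window.wb)
        te = min(t.ae, window.we)
        if te <= tb:
            continue
        rb, re = project_interval(t, tb, te)
        rb = max(t.rb, rb)
        re = min(t.re, re)
        if re - rb < params.k:
            continue
        members.append(store.get(t.read, rb, re, reverse=t.reverse))
    return WindowSequences(window, template_seq, members)
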