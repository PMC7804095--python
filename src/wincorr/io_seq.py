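"""FASTA / PAF input-output and a compact random-access sequence store.

All coordinates handled here are 0-based, half-open, matching PAF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

log = logging.getLogger(__name__)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    id: str
    seq: str


@dataclass(frozen=True)
class OverlapRecord:
    """One PAF line (12 mandatory columns)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    blocklen: int
    mapq: int

    @property
    def identity(self) -> float:
        return self.nmatch / self.blocklen

    def to_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.qname, self.qlen, self.qstart, self.qend, self.strand,
                self.tname, self.tlen, self.tstart, self.tend,
                self.nmatch, self.blocklen, self.mapq,
            )
        )


def read_fasta(path) -> list[SeqRecord]:
    """Parse a (possibly multi-line) FASTA file.

    Sequences are uppercased; duplicate ids and empty sequences raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[SeqRecord] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {name!r}")
        if name in seen:
            raise ValueError(f"duplicate record id {name!r}")
        seen.add(name)
        records.append(SeqRecord(name, seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ValueError("FASTA header with empty id")
                chunks = []
            else:
                if name is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line.strip())
    flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 80) -> None:
    """Write FASTA, preserving the case of each base byte-for-byte."""
    if width < 1:
        raise ValueError("width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def parse_paf(path) -> Iterator[OverlapRecord]:
    """Stream PAF records; extra tag columns beyond the 12th are ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            strand = cols[4]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                rec = OverlapRecord(
                    qname=cols[0], qlen=int(cols[1]),
                    qstart=int(cols[2]), qend=int(cols[3]),
                    strand=strand,
                    tname=cols[5], tlen=int(cols[6]),
                    tstart=int(cols[7]), tend=int(cols[8]),
                    nmatch=int(cols[9]), blocklen=int(cols[10]),
                    mapq=int(cols[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            yield rec


def write_paf(records: Iterable[OverlapRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


class SequenceStore:
    """Random-access store keeping every base in 2 bits.

    Non-ACGT input letters are normalized to 'A' (the 4-symbol encoding
    admits nothing else); the number of replaced bases is logged.
    """

    def __init__(self) -> None:
        self._packed: dict[str, np.ndarray] = {}
        self._length: dict[str, int] = {}
        self.total_bases = 0
        self.replaced_bases = 0

    def __contains__(self, name: str) -> bool:
        return name in self._length

    def __len__(self) -> int:
        return len(self._length)

    def add(self, name: str, seq: str) -> None:
        if name in self._length:
            raise ValueError(f"duplicate sequence id {name!r}")
        raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        codes = _CODE[raw]
        bad = codes == 255
        nbad = int(bad.sum())
        if nbad:
            self.replaced_bases += nbad
            codes = np.where(bad, np.uint8(0), codes)
        n = codes.size
        # 4 bases per byte, base i in bits (2*(i%4), 2*(i%4)+1) of byte i//4
        pad = (-n) % 4
        if pad:
            codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
        quads = codes.reshape(-1, 4)
        packed = (
            quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4)
            | (quads[:, 3] << 6)
        ).astype(np.uint8)
        self._packed[name] = packed
        self._length[name] = n
        self.total_bases += n

    @classmethod
    def from_records(cls, records: Iterable[SeqRecord]) -> "SequenceStore":
        store = cls()
        for rec in records:
            store.add(rec.id, rec.seq)
        if store.replaced_bases:
            log.info("normalized %d non-ACGT bases to 'A'", store.replaced_bases)
        return store

    def length(self, name: str) -> int:
        try:
            return self._length[name]
        except KeyError:
            raise KeyError(f"unknown sequence id {name!r}") from None

    def _codes(self, name: str, b: int, e: int) -> np.ndarray:
        n = self.length(name)
        if not 0 <= b <= e <= n:
            raise IndexError(f"slice [{b},{e}) out of range for {name!r} (len {n})")
        if b == e:
            return np.empty(0, dtype=np.uint8)
        packed = self._packed[name]
        lo, hi = b // 4, (e + 3) // 4
        chunk = packed[lo:hi]
        quads = np.empty((chunk.size, 4), dtype=np.uint8)
        quads[:, 0] = chunk & 3
        quads[:, 1] = (chunk >> 2) & 3
        quads[:, 2] = (chunk >> 4) & 3
        quads[:, 3] = (chunk >> 6) & 3
        flat = quads.reshape(-1)
        return flat[b - 4 * lo: e - 4 * lo]

    def get(self, name: str, b: int | None = None, e: int | None = None,
            reverse: bool = False) -> str:
        """Substring [b, e) of the stored sequence, or its reverse complement."""
        if b is None:
            b = 0
        if e is None:
            e = self.length(name)
        codes = self._codes(name, b, e)
        if reverse:
            codes = (3 - codes)[::-1]
        return bytes(_BASE[codes]).decode("ascii")
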