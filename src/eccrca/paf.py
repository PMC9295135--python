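"""PAF alignment records and the base-level ``cs`` difference string.

PAF (pairwise alignment format) is the line-oriented output of minimap2:
twelve mandatory tab-separated columns followed by SAM-style typed tags.
All coordinates are 0-based, half-open.  When the aligner is run with
``-c --cs``, each record carries a short-form ``cs`` tag encoding the
alignment at base resolution (``:n`` match run, ``*rq`` substitution,
``+seq`` insertion, ``-seq`` deletion); this is what downstream variant
pileups consume.  Long-form cs and CIGAR-only records parse fine but are
treated as carrying no variant information.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "PafRecord",
    "CsOp",
    "PafError",
    "parse_paf",
    "parse_cs",
    "write_paf",
    "cs_spans",
]


class PafError(ValueError):
    """Malformed PAF line or cs string."""


_CS_TOKEN = re.compile(r":(\d+)|\*([a-zA-Z])([a-zA-Z])|\+([a-zA-Z]+)|-([a-zA-Z]+)|=([A-Za-z]+)")


@dataclass(frozen=True)
class CsOp:
    """One operation of a cs difference string.

    ``match_run`` consumes ``length`` bases of both sequences;
    ``substitution`` consumes one base of each (``ref_bases``/``query_bases``
    hold the single bases); ``insertion`` consumes query only; ``deletion``
    consumes reference only.
    """

    kind: str  # match_run | substitution | insertion | deletion
    length: int
    ref_bases: str = ""
    query_bases: str = ""

    @property
    def ref_span(self) -> int:
        return self.length if self.kind in ("match_run", "substitution", "deletion") else 0

    @property
    def query_span(self) -> int:
        return self.length if self.kind in ("match_run", "substitution", "insertion") else 0


@dataclass
class PafRecord:
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
    alnlen: int
    mapq: int
    tags: tuple[str, ...] = field(default_factory=tuple)

    def tag(self, name: str) -> str | None:
        """Value of optional tag ``name`` (text after the type code), or None."""
        prefix = name + ":"
        for t in self.tags:
            if t.startswith(prefix):
                return t.split(":", 2)[2]
        return None

    @property
    def cs(self) -> str | None:
        return self.tag("cs")

    @property
    def has_short_cs(self) -> bool:
        """True when the record carries a short-form cs usable for pileups."""
        cs = self.cs
        return cs is not None and not cs.startswith("=") and cs != ""

    def validate(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise PafError(
                f"invalid query interval qstart={self.qstart} qend={self.qend} qlen={self.qlen}"
            )
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise PafError(
                f"invalid target interval tstart={self.tstart} tend={self.tend} tlen={self.tlen}"
            )
        if self.strand not in ("+", "-"):
            raise PafError(f"invalid strand {self.strand!r}")
        if self.nmatch > self.alnlen:
            raise PafError(f"nmatch {self.nmatch} exceeds alnlen {self.alnlen}")


def parse_cs(cs: str) -> list[CsOp]:
    """Parse a short-form cs string into its ordered operations."""
    ops: list[CsOp] = []
    pos = 0
    n = len(cs)
    while pos < n:
        m = _CS_TOKEN.match(cs, pos)
        if m is None:
            raise PafError(f"unknown cs operator {cs[pos]!r} at offset {pos}")
        if m.group(1) is not None:
            ops.append(CsOp("match_run", int(m.group(1))))
        elif m.group(2) is not None:
            ops.append(CsOp("substitution", 1, m.group(2).lower(), m.group(3).lower()))
        elif m.group(4) is not None:
            seq = m.group(4).lower()
            ops.append(CsOp("insertion", len(seq), "", seq))
        elif m.group(5) is not None:
            seq = m.group(5).lower()
            ops.append(CsOp("deletion", len(seq), seq, ""))
        else:  # long-form =ACGT match: accepted, represented as a match run
            seq = m.group(6)
            ops.append(CsOp("match_run", len(seq)))
        pos = m.end()
    return ops


def cs_spans(ops: Iterable[CsOp]) -> tuple[int, int]:
    """(reference span, query span) implied by a cs op list."""
    ref = qry = 0
    for op in ops:
        ref += op.ref_span
        qry += op.query_span
    return ref, qry


def _parse_line(line: str, lineno: int) -> PafRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise PafError(f"line {lineno}: expected >=12 tab-separated columns, got {len(cols)}")
    try:
        rec = PafRecord(
            qname=cols[0],
            qlen=int(cols[1]),
            qstart=int(cols[2]),
            qend=int(cols[3]),
            strand=cols[4],
            tname=cols[5],
            tlen=int(cols[6]),
            tstart=int(cols[7]),
            tend=int(cols[8]),
            nmatch=int(cols[9]),
            alnlen=int(cols[10]),
            mapq=int(cols[11]),
            tags=tuple(cols[12:]),
        )
    except ValueError as exc:
        raise PafError(f"line {lineno}: non-integer coordinate field ({exc})") from None
    if rec.strand not in ("+", "-"):
        raise PafError(f"line {lineno}: strand must be '+' or '-', got {rec.strand!r}")
    return rec


def parse_paf(stream: Iterable[str] | str) -> list[PafRecord]:
    """Parse PAF text (a string or an iterable of lines) into records.

    Records are returned in input order; unknown optional tags are preserved
    verbatim so that :func:`write_paf` round-trips losslessly.
    """
    if isinstance(stream, str):
        lines: Iterator[str] = iter(stream.splitlines())
    else:
        lines = iter(stream)
    records: list[PafRecord] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        records.append(_parse_line(line, lineno))
    return records


def write_paf(records: Iterable[PafRecord]) -> str:
    """Serialize records to PAF text; inverse of :func:`parse_paf`."""
    out: list[str] = []
    for rec in records:
        rec.validate()
        cols = [
            rec.qname,
            str(rec.qlen),
            str(rec.qstart),
            str(rec.qend),
            rec.strand,
            rec.tname,
            str(rec.tlen),
            str(rec.tstart),
            str(rec.tend),
            str(rec.nmatch),
            str(rec.alnlen),
            str(rec.mapq),
            *rec.tags,
        ]
        out.append("\t".join(cols))
    return "".join(line + "\n" for line in out)
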