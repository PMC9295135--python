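"""Per-circle variant calling and full-length consensus sequences.

Sub-reads stacked on one fragment of a circle form a natural mini-pileup:
every pass re-sequences the same template molecule, so a true template
variant (relative to the reference genome) recurs in every pass while a
sequencing error appears in one.  Variants are called per reference
position from the cs difference strings, requiring a minimum depth of 4
covering sub-reads and a minimum allele frequency of 0.75, and the circle's
consensus is the reference sequence of its fragment cycle with those
variants incorporated — not a read-space assembly.

The consensus string starts at the voted start of the canonical first
fragment (the lexicographically smallest rotation of the fragment tuple
sequence) and follows the circle in the orientation in which it was read,
so that two reads of the same molecule in the same orientation yield
byte-identical sequences.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from eccrca.caller import CircleCall, FragmentLocus, SubRead

__all__ = [
    "ConsensusParams",
    "Variant",
    "FragmentPileup",
    "pileup",
    "call_variants",
    "build_consensus",
    "circle_variants",
    "reverse_complement",
]

_REF = "."  # sentinel allele for "matches the reference"
_DEL = "-"

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusParams:
    """Variant-calling thresholds.

    min_depth: minimum covering sub-reads at a position.
    min_af: minimum alternate allele frequency.
    snv_only: ignore insertions/deletions when building the consensus.
    max_ins_len: insertions longer than this (bp) are treated as unaligned
        junction sequence and dropped.
    boundary_margin: variants within this many bases of a voted fragment
        boundary are suppressed (alignment-end jitter piles up artifactual
        mismatches there).
    """

    min_depth: int = 4
    min_af: float = 0.75
    snv_only: bool = False
    max_ins_len: int = 50
    boundary_margin: int = 20

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0 < self.min_af <= 1):
            raise ValueError("min_af must be in (0, 1]")


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 0-based reference position (anchor position for insertions)
    kind: str  # snv | ins | del
    ref: str
    alt: str
    depth: int
    alt_count: int

    @property
    def af(self) -> float:
        return self.alt_count / self.depth


@dataclass
class FragmentPileup:
    """Allele counts over one fragment's reference interval.

    ``base_counts[pos]`` counts the sentinel ``.`` (reference), an alternate
    base, or ``-`` (deleted) for each covering sub-read; deletions cover,
    insertions anchor to the preceding reference position and are tallied
    separately in ``ins_counts``.
    """

    fragment: FragmentLocus
    base_counts: dict[int, Counter] = field(default_factory=lambda: defaultdict(Counter))
    ins_counts: dict[int, Counter] = field(default_factory=lambda: defaultdict(Counter))
    ref_bases: dict[int, str] = field(default_factory=dict)  # known from cs ops

    def depth(self, pos: int) -> int:
        return sum(self.base_counts[pos].values())


def pileup(fragment: FragmentLocus, subreads: Sequence[SubRead]) -> FragmentPileup | None:
    """Stack the cs ops of the fragment's sub-reads over its interval.

    Returns None when no sub-read carries cs ops (the fragment is then
    reference-only in the consensus).
    """
    with_cs = [s for s in subreads if s.cs_ops]
    if not with_cs:
        return None
    pile = FragmentPileup(fragment)
    lo, hi = fragment.start, fragment.end
    for sub in with_cs:
        tpos = sub.tstart
        for op in sub.cs_ops:
            if op.kind == "match_run":
                for p in range(max(tpos, lo), min(tpos + op.length, hi)):
                    pile.base_counts[p][_REF] += 1
                tpos += op.length
            elif op.kind == "substitution":
                if lo <= tpos < hi:
                    pile.base_counts[tpos][op.query_bases.upper()] += 1
                    pile.ref_bases[tpos] = op.ref_bases.upper()
                tpos += 1
            elif op.kind == "deletion":
                for i, base in enumerate(op.ref_bases):
                    p = tpos + i
                    if lo <= p < hi:
                        pile.base_counts[p][_DEL] += 1
                        pile.ref_bases[p] = base.upper()
                tpos += op.length
            elif op.kind == "insertion":
                anchor = tpos - 1
                if lo <= anchor < hi:
                    pile.ins_counts[anchor][op.query_bases.upper()] += 1
    return pile


def call_variants(
    pile: FragmentPileup, params: ConsensusParams | None = None
) -> list[Variant]:
    """Emit at most one variant per reference position.

    A variant requires depth >= min_depth and alternate frequency >= min_af;
    among competing alternates the highest count wins, ties going to the
    lexicographically smaller allele.  Positions within ``boundary_margin``
    of a voted boundary are skipped, as are over-long insertions.
    """
    params = params or ConsensusParams()
    frag = pile.fragment
    lo = frag.start + params.boundary_margin
    hi = frag.end - params.boundary_margin
    variants: list[Variant] = []
    for pos in sorted(pile.base_counts):
        if not (lo <= pos < hi):
            continue
        counts = pile.base_counts[pos]
        depth = sum(counts.values())
        if depth < params.min_depth:
            continue
        alts = [(n, allele) for allele, n in counts.items() if allele != _REF]
        if not alts:
            continue
        alts.sort(key=lambda t: (-t[0], t[1]))
        alt_count, allele = alts[0]
        if alt_count / depth < params.min_af:
            continue
        ref = pile.ref_bases.get(pos, "N")
        if allele == _DEL:
            if params.snv_only:
                continue
            variants.append(Variant(frag.chrom, pos, "del", ref, _DEL, depth, alt_count))
        else:
            variants.append(Variant(frag.chrom, pos, "snv", ref, allele, depth, alt_count))
    if not params.snv_only:
        for pos in sorted(pile.ins_counts):
            if not (lo <= pos < hi):
                continue
            depth = pile.depth(pos)
            if depth < params.min_depth:
                continue
            seqs = sorted(pile.ins_counts[pos].items(), key=lambda t: (-t[1], t[0]))
            seq, n = seqs[0]
            if len(seq) > params.max_ins_len:
                continue
            if n / depth < params.min_af:
                continue
            ref = pile.ref_bases.get(pos, "N")
            variants.append(Variant(frag.chrom, pos, "ins", ref, seq, depth, n))
    variants.sort(key=lambda v: (v.pos, v.kind))
    return variants


def circle_variants(
    circle: CircleCall, params: ConsensusParams | None = None
) -> list[list[Variant]]:
    """Variants per fragment of an accepted circle (empty list when no cs)."""
    params = params or ConsensusParams()
    out: list[list[Variant]] = []
    for frag, members in zip(circle.fragments, circle.members):
        pile = pileup(frag, members)
        out.append(call_variants(pile, params) if pile is not None else [])
    return out


def _apply_variants(seq: str, frag: FragmentLocus, variants: Sequence[Variant]) -> str:
    """Apply variants (reference coordinates) to the plus-strand substring."""
    chars = list(seq)
    inserts: dict[int, str] = {}
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        i = v.pos - frag.start
        if not (0 <= i < len(chars)):
            continue
        if v.kind == "snv":
            chars[i] = v.alt
        elif v.kind == "del":
            chars[i] = ""
        elif v.kind == "ins":
            inserts[i] = v.alt
    for i in sorted(inserts, reverse=True):
        chars[i] = chars[i] + inserts[i]
    return "".join(chars)


def _canonical_rotation(fragments: Sequence[FragmentLocus]) -> int:
    """Index of the rotation whose fragment tuple sequence is smallest."""
    tuples = [(f.chrom, f.start, f.end, f.strand) for f in fragments]
    k = len(tuples)
    best, best_i = None, 0
    for i in range(k):
        rot = tuple(tuples[i:] + tuples[:i])
        if best is None or rot < best:
            best, best_i = rot, i
    return best_i


def build_consensus(
    circle: CircleCall,
    reference: Mapping[str, str],
    variants: Sequence[Sequence[Variant]] | None = None,
) -> str:
    """Full-length circle sequence from the reference with variants applied.

    ``reference`` maps chromosome name to sequence (a dict or a
    ``pyfaidx.Fasta``).  Fragments are taken in cycle order starting at the
    canonical rotation; minus-strand fragments contribute their reverse
    complement.  Variants (one list per fragment, reference coordinates)
    are applied on the plus strand before orientation.
    """
    if variants is None:
        variants = [[] for _ in circle.fragments]
    rot = _canonical_rotation(circle.fragments)
    k = len(circle.fragments)
    parts: list[str] = []
    for off in range(k):
        i = (rot + off) % k
        frag = circle.fragments[i]
        if frag.chrom not in reference:
            raise KeyError(f"fragment chromosome {frag.chrom!r} absent from reference")
        chrom_seq = reference[frag.chrom]
        if frag.end > len(chrom_seq):
            raise ValueError(
                f"fragment {frag} exceeds chromosome bounds ({len(chrom_seq)} bp)"
            )
        seq = str(chrom_seq[frag.start : frag.end]).upper()
        seq = _apply_variants(seq, frag, variants[i])
        if frag.strand == "-":
            seq = reverse_complement(seq)
        parts.append(seq)
    return "".join(parts)
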