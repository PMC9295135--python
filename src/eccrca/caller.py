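"""Reconstruct eccDNA circles from the sub-read alignments of RCA long reads.

Each RCA long read is a tandem concatemer of one circular template.  After
alignment its sub-reads (one PAF record each) visit the template's genomic
fragments periodically.  The caller, per read:

1. drops sub-reads below a mapping-quality floor (default 30);
2. greedily clusters sub-reads into genomic loci, allowing a bounded
   start/end offset (default 20 bp) between a sub-read and the cluster's
   first-seen representative;
3. checks that the cluster-label sequence along the read is the periodic
   extension of a fragment cycle (any starting rotation — RCA phase is
   random); discordant order, location or strand rejects the whole read;
4. counts passes per fragment; a circle needs >=2 full passes (the minimum
   over fragments of full sub-read counts) to be kept;
5. votes each fragment boundary as the mode of member sub-read starts/ends,
   then refines boundaries by threading: the median unaligned query gap at
   each fragment junction is pushed into the upstream fragment's 3' end so
   that successive sub-reads abut in the query.

A read whose first/last sub-read is a truncated partial pass (the
concatemer starts or stops mid-fragment) is tolerated: the partial
alignment attaches to its locus cluster, votes only for the boundary it
fully reaches, and does not count as a full pass.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from eccrca.paf import CsOp, PafRecord, parse_cs

__all__ = [
    "CallerParams",
    "FragmentLocus",
    "SubRead",
    "LocusCluster",
    "CircleCall",
    "filter_subreads",
    "cluster_loci",
    "check_concordance",
    "count_passes",
    "vote_boundaries",
    "thread_refine",
    "call_circles",
    "REJECTION_REASONS",
]

REJECTION_REASONS = (
    "single_hit",
    "low_mapq",
    "discordant_order",
    "discordant_strand",
    "discordant_location",
    "insufficient_passes",
)


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the circle caller.

    min_mapq: sub-reads below this mapping quality are discarded.
    max_offset: maximum start/end offset (bp) for two sub-reads to count as
        the same genomic locus.
    min_full_passes: minimum full passes for a confident circle.
    max_query_overlap: query-space overlap (bp) between successive sub-reads
        absorbed by threading; larger overlaps flag the junction.
    max_junction_gap: unaligned query bases (bp) at a junction absorbed by
        threading; larger gaps flag the junction.
    """

    min_mapq: int = 30
    max_offset: int = 20
    min_full_passes: int = 2
    max_query_overlap: int = 20
    max_junction_gap: int = 50

    def __post_init__(self) -> None:
        if self.min_full_passes < 1:
            raise ValueError("min_full_passes must be >= 1")
        for name in ("min_mapq", "max_offset", "max_query_overlap", "max_junction_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True, order=True)
class FragmentLocus:
    """One genomic fragment of a circle; 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def from_string(cls, text: str) -> "FragmentLocus":
        chrom, span, strand = text.rsplit(":", 2)
        start, end = span.split("-")
        return cls(chrom, int(start), int(end), strand)


@dataclass
class SubRead:
    """One kept alignment of an RCA read, ranked by query start."""

    read_id: str
    qstart: int
    qend: int
    chrom: str
    tstart: int
    tend: int
    strand: str
    mapq: int
    rank: int = -1
    cs_ops: list[CsOp] | None = None
    partial: bool = False  # truncated flanking pass
    votes_start: bool = True
    votes_end: bool = True

    @classmethod
    def from_paf(cls, rec: PafRecord) -> "SubRead":
        ops = parse_cs(rec.cs) if rec.has_short_cs else None
        return cls(
            read_id=rec.qname,
            qstart=rec.qstart,
            qend=rec.qend,
            chrom=rec.tname,
            tstart=rec.tstart,
            tend=rec.tend,
            strand=rec.strand,
            mapq=rec.mapq,
            cs_ops=ops,
        )


@dataclass
class LocusCluster:
    """Sub-reads mapping to the same genomic locus within the offset bound.

    The representative interval is the first (full) member's; membership of
    later sub-reads is tested against it, never re-centred.
    """

    cluster_id: int
    chrom: str
    strand: str
    rep_start: int
    rep_end: int
    members: list[SubRead] = field(default_factory=list)


@dataclass
class JunctionDiagnostic:
    junction: int  # index into the fragment cycle (after fragment i)
    query_gap: int  # median qstart_next - qend_prev before adjustment
    adjustment: int  # bases pushed into the upstream fragment's 3' end
    flagged: bool


@dataclass
class CircleCall:
    """Result of decomposing one RCA read; accepted or rejected."""

    read_id: str
    status: str  # accepted | rejected
    reason: str | None = None
    fragments: list[FragmentLocus] = field(default_factory=list)
    pass_counts: list[int] = field(default_factory=list)
    full_passes: int = 0
    junctions: list[JunctionDiagnostic] = field(default_factory=list)
    # per-fragment member sub-reads, kept for variant pileups (not serialized)
    members: list[list[SubRead]] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def circle_length(self) -> int:
        return sum(f.length for f in self.fragments)


def filter_subreads(
    records: Iterable[PafRecord], params: CallerParams
) -> dict[str, list[SubRead]]:
    """Group alignments by read, drop low-MQ ones, sort by qstart, rank.

    Reads whose alignments are all below the MQ floor still appear in the
    result with an empty list, so the caller can report them as rejected.
    """
    groups: dict[str, list[SubRead]] = {}
    for rec in records:
        groups.setdefault(rec.qname, [])
        if rec.mapq >= params.min_mapq:
            groups[rec.qname].append(SubRead.from_paf(rec))
    for subs in groups.values():
        subs.sort(key=lambda s: (s.qstart, s.qend))
        for rank, s in enumerate(subs):
            s.rank = rank
    return groups


def _full_match(cluster: LocusCluster, sub: SubRead, max_offset: int) -> bool:
    return (
        sub.chrom == cluster.chrom
        and sub.strand == cluster.strand
        and abs(sub.tstart - cluster.rep_start) <= max_offset
        and abs(sub.tend - cluster.rep_end) <= max_offset
    )


def _partial_match(cluster: LocusCluster, sub: SubRead, max_offset: int) -> str | None:
    """Classify a flanking sub-read as a truncated partial pass of a cluster.

    The sub-read must lie within the representative interval (plus offset),
    match exactly one boundary within the offset, and be truncated on the
    other side by more than twice the offset — so boundary jitter alone,
    which moves both ends by at most the offset, can never masquerade as a
    partial pass.  Returns 'start', 'end' (the matched boundary) or None.
    """
    if sub.chrom != cluster.chrom or sub.strand != cluster.strand:
        return None
    if sub.tstart < cluster.rep_start - max_offset or sub.tend > cluster.rep_end + max_offset:
        return None
    if abs(sub.tstart - cluster.rep_start) <= max_offset and sub.tend < cluster.rep_end - 2 * max_offset:
        return "start"
    if abs(sub.tend - cluster.rep_end) <= max_offset and sub.tstart > cluster.rep_start + 2 * max_offset:
        return "end"
    return None


def cluster_loci(
    subreads: Sequence[SubRead], params: CallerParams
) -> tuple[list[LocusCluster], list[int]]:
    """Greedy order-deterministic clustering of one read's sub-reads.

    Walking in rank order, a sub-read joins the first existing cluster with
    the same chromosome and strand whose representative start and end are
    each within ``max_offset``; otherwise it seeds a new cluster and becomes
    its representative.  The first and last sub-read of the read may instead
    attach as truncated partial passes (see :func:`_partial_match`); a
    flanking sub-read that seeded its own singleton cluster is re-attached
    in a second pass when a later full cluster contains it.

    Returns the clusters and the per-rank cluster labels (cluster ids
    renumbered by first appearance along the read).
    """
    clusters: list[LocusCluster] = []
    labels: list[int] = []
    last = len(subreads) - 1
    for sub in subreads:
        placed = False
        for cl in clusters:
            if _full_match(cl, sub, params.max_offset):
                sub.partial = False
                sub.votes_start = sub.votes_end = True
                cl.members.append(sub)
                labels.append(cl.cluster_id)
                placed = True
                break
        if not placed and sub.rank in (0, last):
            for cl in clusters:
                side = _partial_match(cl, sub, params.max_offset)
                if side is not None:
                    sub.partial = True
                    sub.votes_start = side == "start"
                    sub.votes_end = side == "end"
                    cl.members.append(sub)
                    labels.append(cl.cluster_id)
                    placed = True
                    break
        if not placed:
            cl = LocusCluster(
                cluster_id=len(clusters),
                chrom=sub.chrom,
                strand=sub.strand,
                rep_start=sub.tstart,
                rep_end=sub.tend,
                members=[sub],
            )
            sub.partial = False
            sub.votes_start = sub.votes_end = True
            clusters.append(cl)
            labels.append(cl.cluster_id)

    # Second pass: a flanking sub-read that arrived before its full-length
    # cluster existed (e.g. a truncated first pass) sits in a singleton
    # cluster; fold it into the matching later cluster as a partial member.
    for idx in (0, last):
        if last < 1:
            break
        lab = labels[idx]
        cl = clusters[lab]
        if len(cl.members) != 1 or cl.members[0].rank != idx:
            continue
        sub = cl.members[0]
        for other in clusters:
            if other.cluster_id == lab:
                continue
            side = _partial_match(other, sub, params.max_offset)
            if side is not None:
                sub.partial = True
                sub.votes_start = side == "start"
                sub.votes_end = side == "end"
                other.members.append(sub)
                cl.members.clear()
                labels[idx] = other.cluster_id
                break

    # Drop emptied clusters and renumber labels by first appearance.
    kept = [cl for cl in clusters if cl.members]
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
    for cl in kept:
        cl.cluster_id = remap[cl.cluster_id]
    kept.sort(key=lambda cl: cl.cluster_id)
    labels = [remap[lab] for lab in labels]
    # Keep members in rank order after re-attachment.
    for cl in kept:
        cl.members.sort(key=lambda s: s.rank)
    return kept, labels


def check_concordance(
    labels: Sequence[int], clusters: Sequence[LocusCluster], params: CallerParams
) -> tuple[list[int] | None, str | None]:
    """Verify the label sequence is the periodic extension of one cycle.

    The candidate cycle is the distinct labels in order of first appearance;
    acceptance requires ``labels[i] == cycle[i % k]`` for every position.
    Because labels are numbered by first appearance, the random RCA start
    phase costs nothing — any rotation of the true cycle presents as the
    identity rotation.  On a mismatch the observed cluster is compared with
    the expected one: same location on the opposite strand is classified as
    ``discordant_strand``, anything else as ``discordant_order``.
    """
    cycle: list[int] = []
    for lab in labels:
        if lab not in cycle:
            cycle.append(lab)
    k = len(cycle)
    # the same locus on both strands within one read is a strand conflict
    # even when the label sequence happens to be periodic
    for ia in range(k):
        for ib in range(ia + 1, k):
            a, b = clusters[cycle[ia]], clusters[cycle[ib]]
            if (
                a.chrom == b.chrom
                and a.strand != b.strand
                and abs(a.rep_start - b.rep_start) <= params.max_offset
                and abs(a.rep_end - b.rep_end) <= params.max_offset
            ):
                return None, "discordant_strand"
    for i, lab in enumerate(labels):
        want = cycle[i % k]
        if lab != want:
            exp, obs = clusters[want], clusters[lab]
            if (
                obs.chrom == exp.chrom
                and obs.strand != exp.strand
                and abs(obs.rep_start - exp.rep_start) <= params.max_offset
                and abs(obs.rep_end - exp.rep_end) <= params.max_offset
            ):
                return None, "discordant_strand"
            return None, "discordant_order"
    return cycle, None


def count_passes(
    labels: Sequence[int], subreads: Sequence[SubRead], cycle: Sequence[int]
) -> tuple[list[int], int]:
    """Per-fragment full-pass counts and the circle's full-pass number.

    A fragment's count is the number of concordant *full* (non-partial)
    sub-reads on its locus; the circle's full passes is the minimum over
    fragments, which guarantees every base of the circle was sequenced at
    least that many times.
    """
    counts = Counter(
        lab for lab, sub in zip(labels, subreads) if not sub.partial
    )
    per_fragment = [counts.get(lab, 0) for lab in cycle]
    return per_fragment, min(per_fragment) if per_fragment else 0


def _mode_with_tiebreak(values: Sequence[int]) -> int:
    """Mode; ties resolved by the (lower) median of the tied values."""
    counts = Counter(values)
    top = max(counts.values())
    tied = sorted(v for v, c in counts.items() if c == top)
    return tied[(len(tied) - 1) // 2]


def vote_boundaries(cluster: LocusCluster) -> tuple[int, int]:
    """Fragment boundaries as independent modes of member starts and ends.

    Partial flanking members vote only for the boundary they fully reach.
    """
    starts = [s.tstart for s in cluster.members if s.votes_start]
    ends = [s.tend for s in cluster.members if s.votes_end]
    start = _mode_with_tiebreak(starts) if starts else cluster.rep_start
    end = _mode_with_tiebreak(ends) if ends else cluster.rep_end
    return start, end


def _lower_median(values: Sequence[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def thread_refine(
    fragments: list[FragmentLocus],
    labels: Sequence[int],
    subreads: Sequence[SubRead],
    cycle: Sequence[int],
    params: CallerParams,
) -> tuple[list[FragmentLocus] | None, list[JunctionDiagnostic]]:
    """Thread sub-reads through junctions to close query gaps/overlaps.

    For junction j (after cycle position j), the median unaligned query gap
    over all rank-adjacent sub-read pairs spanning it is assigned entirely
    to the upstream fragment's 3' boundary in its strand orientation: a
    positive gap extends it, a small negative overlap trims it.  Gaps or
    overlaps beyond tolerance leave the fragment untouched and flag the
    junction.  Returns None (rejection ``discordant_location``) if an
    adjustment would invert a fragment.
    """
    k = len(cycle)
    pos_in_cycle = {lab: i for i, lab in enumerate(cycle)}
    gaps: dict[int, list[int]] = {j: [] for j in range(k)}
    for a, b in zip(range(len(subreads) - 1), range(1, len(subreads))):
        j = pos_in_cycle[labels[a]]
        gaps[j].append(subreads[b].qstart - subreads[a].qend)

    adjusted = list(fragments)
    diagnostics: list[JunctionDiagnostic] = []
    for j in range(k):
        if not gaps[j]:
            continue
        delta = _lower_median(gaps[j])
        apply_delta = 0
        flagged = False
        if 0 < delta <= params.max_junction_gap:
            apply_delta = delta
        elif -params.max_query_overlap <= delta < 0:
            apply_delta = delta
        elif delta != 0:
            flagged = True
        if apply_delta:
            frag = adjusted[j]
            if frag.strand == "+":
                new = (frag.start, frag.end + apply_delta)
            else:  # 3' end of a minus-strand fragment is its genomic start
                new = (frag.start - apply_delta, frag.end)
            if new[0] >= new[1]:
                return None, diagnostics
            adjusted[j] = replace(frag, start=new[0], end=new[1])
        diagnostics.append(
            JunctionDiagnostic(junction=j, query_gap=delta, adjustment=apply_delta, flagged=flagged)
        )
    return adjusted, diagnostics


def call_circles(
    records: Iterable[PafRecord] | str, params: CallerParams | None = None
) -> list[CircleCall]:
    """Run the full per-read calling pipeline on PAF records.

    ``records`` may be parsed records or raw PAF text.  Returns one
    :class:`CircleCall` per read (accepted circles and rejected reads with
    their reason), in input read order.
    """
    from eccrca.paf import parse_paf

    if isinstance(records, str):
        records = parse_paf(records)
    params = params or CallerParams()
    calls: list[CircleCall] = []
    for read_id, subreads in filter_subreads(records, params).items():
        calls.append(_call_one(read_id, subreads, params))
    return calls


def _call_one(read_id: str, subreads: list[SubRead], params: CallerParams) -> CircleCall:
    if not subreads:
        return CircleCall(read_id, "rejected", "low_mapq")
    if len(subreads) == 1:
        return CircleCall(read_id, "rejected", "single_hit")
    clusters, labels = cluster_loci(subreads, params)
    cycle, reason = check_concordance(labels, clusters, params)
    if cycle is None:
        return CircleCall(read_id, "rejected", reason)
    pass_counts, full_passes = count_passes(labels, subreads, cycle)
    if full_passes < params.min_full_passes:
        return CircleCall(read_id, "rejected", "insufficient_passes", full_passes=full_passes)
    voted: list[FragmentLocus] = []
    for lab in cycle:
        cl = clusters[lab]
        start, end = vote_boundaries(cl)
        if start >= end:
            return CircleCall(read_id, "rejected", "discordant_location")
        voted.append(FragmentLocus(cl.chrom, start, end, cl.strand))
    refined, junctions = thread_refine(voted, labels, subreads, cycle, params)
    if refined is None:
        return CircleCall(read_id, "rejected", "discordant_location")
    return CircleCall(
        read_id=read_id,
        status="accepted",
        fragments=refined,
        pass_counts=pass_counts,
        full_passes=full_passes,
        junctions=junctions,
        members=[list(clusters[lab].members) for lab in cycle],
    )
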