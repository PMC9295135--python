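"""Catalog of unique eccDNAs: deduplication, coverage and summary statistics.

Accepted circles from many reads are collapsed into unique molecules by a
canonical key invariant to the read's starting phase (cycle rotation) and
sequencing orientation (reverse traversal with strands flipped).  The
number of distinct reads behind one key is the molecule's event count.
Fragment-level deduplication (exact chromosome/start/end, strand ignored)
feeds a per-base genome coverage track, per-chromosome density, and the
size-periodicity statistic that exposes the nucleosomal ladder in circle
lengths.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from eccrca.caller import CircleCall, FragmentLocus

__all__ = [
    "UniqueEccDNA",
    "canonicalize",
    "deduplicate_circles",
    "deduplicate_fragments",
    "event_count_distribution",
    "CoverageTrack",
    "compute_coverage",
    "coverage_bedgraph",
    "size_interval_statistic",
    "fragment_count_histogram",
    "interchromosomal_pairs",
    "chromosome_density",
]

FragmentKey = tuple[str, int, int, str]


@dataclass
class UniqueEccDNA:
    """One deduplicated circular molecule."""

    key: tuple[FragmentKey, ...]
    fragments: list[FragmentLocus]
    event_count: int

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def circle_length(self) -> int:
        return sum(f.length for f in self.fragments)

    @property
    def continuity(self) -> str:
        # single-fragment circles arise from one continuous genomic locus
        return "continuous" if self.n_fragments == 1 else "non_continuous"


def _flip(t: FragmentKey) -> FragmentKey:
    chrom, start, end, strand = t
    return (chrom, start, end, "-" if strand == "+" else "+")


def canonicalize(fragments: Sequence[FragmentLocus]) -> tuple[FragmentKey, ...]:
    """Rotation- and orientation-invariant identity key of a circle.

    Among all rotations of the fragment cycle and all rotations of the
    reverse traversal (fragment order reversed, strands flipped — the same
    molecule read the other way around), the lexicographically smallest
    tuple sequence is the key.
    """
    fwd = [(f.chrom, f.start, f.end, f.strand) for f in fragments]
    rev = [_flip(t) for t in reversed(fwd)]
    k = len(fwd)
    best: tuple[FragmentKey, ...] | None = None
    for seq in (fwd, rev):
        for i in range(k):
            rot = tuple(seq[i:] + seq[:i])
            if best is None or rot < best:
                best = rot
    assert best is not None
    return best


def deduplicate_circles(circles: Iterable[CircleCall]) -> list[UniqueEccDNA]:
    """Collapse accepted circles into unique molecules with event counts.

    The event count is the number of distinct supporting reads; identity is
    the full ordered (canonicalized) fragment tuple, so circles joining the
    same fragments in different cyclic orders stay distinct molecules.
    """
    by_key: dict[tuple[FragmentKey, ...], UniqueEccDNA] = {}
    reads_seen: dict[tuple[FragmentKey, ...], set[str]] = defaultdict(set)
    for circle in circles:
        if not circle.accepted:
            continue
        key = canonicalize(circle.fragments)
        if key not in by_key:
            by_key[key] = UniqueEccDNA(
                key=key,
                fragments=[FragmentLocus(*t) for t in key],
                event_count=0,
            )
        reads_seen[key].add(circle.read_id)
    for key, uniq in by_key.items():
        uniq.event_count = len(reads_seen[key])
    return list(by_key.values())


def deduplicate_fragments(
    circles: Iterable[CircleCall | UniqueEccDNA],
) -> list[tuple[str, int, int]]:
    """Unique fragments by exact (chromosome, start, end); strand ignored.

    Fragments with identical coordinates are amplification duplicates of
    the same genomic piece and contribute to coverage once.
    """
    seen: dict[tuple[str, int, int], None] = {}
    for circle in circles:
        if isinstance(circle, CircleCall) and not circle.accepted:
            continue
        for f in circle.fragments:
            seen.setdefault((f.chrom, f.start, f.end))
    return list(seen)


def event_count_distribution(
    uniques: Sequence[UniqueEccDNA],
) -> dict[str, float] | None:
    """Fractions of unique eccDNAs by supporting-read count: 1, 2, 3, >3."""
    if not uniques:
        return None
    n = len(uniques)
    bins = Counter()
    for u in uniques:
        if u.event_count <= 3:
            bins[str(u.event_count)] += 1
        else:
            bins[">3"] += 1
    return {k: bins.get(k, 0) / n for k in ("1", "2", "3", ">3")}


@dataclass
class CoverageTrack:
    """Per-base unique-fragment coverage, one integer array per chromosome."""

    arrays: dict[str, np.ndarray]

    def total_mass(self) -> int:
        return int(sum(a.sum() for a in self.arrays.values()))

    def density(self) -> dict[str, float]:
        return {c: float(a.sum()) / len(a) for c, a in self.arrays.items() if len(a)}


def compute_coverage(
    fragments: Iterable[tuple[str, int, int]], chrom_sizes: Mapping[str, int]
) -> CoverageTrack:
    """Per-base counts of unique fragments over the genome."""
    deltas = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_sizes.items()}
    for chrom, start, end in fragments:
        if chrom not in deltas:
            raise KeyError(f"fragment chromosome {chrom!r} not in chrom sizes")
        if end > chrom_sizes[chrom]:
            raise ValueError(
                f"fragment {chrom}:{start}-{end} beyond chromosome end {chrom_sizes[chrom]}"
            )
        deltas[chrom][start] += 1
        deltas[chrom][end] -= 1
    return CoverageTrack({c: np.cumsum(d[:-1]) for c, d in deltas.items()})


def coverage_bedgraph(track: CoverageTrack) -> str:
    """Sorted, run-merged bedGraph text of the non-zero coverage runs."""
    lines: list[str] = []
    for chrom in sorted(track.arrays):
        arr = track.arrays[chrom]
        if not len(arr):
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(arr)]))
        for s, e in zip(starts, ends):
            v = int(arr[s])
            if v:
                lines.append(f"{chrom}\t{s}\t{e}\t{v}")
    return "".join(line + "\n" for line in lines)


def size_interval_statistic(
    lengths: Sequence[int],
    max_length: int = 3000,
    window: int = 11,
    prominence_frac: float = 0.05,
    min_peak_distance: int = 50,
) -> tuple[float | None, list[int]]:
    """Estimate the periodic spacing (bp) of the circle-size distribution.

    Circle lengths inherit the nucleosomal ladder of apoptotic DNA
    fragments, producing evenly spaced peaks in the size histogram.  The
    histogram (1 bp bins over [0, max_length]) is smoothed with a centred
    moving average and local maxima with prominence >= ``prominence_frac``
    of the global maximum and pairwise separation >= ``min_peak_distance``
    (well below one nucleosome repeat, so genuine rungs are never merged
    but noisy plateau tops do not double-count) are located; the statistic
    is the mean spacing of successive peaks.  Returns (None, peaks) when
    fewer than two peaks exist.
    """
    hist = np.zeros(max_length + 1)
    for length in lengths:
        if 0 <= length <= max_length:
            hist[length] += 1
    kernel = np.ones(window) / window
    smooth = np.convolve(hist, kernel, mode="same")
    peaks, _ = find_peaks(
        smooth, prominence=prominence_frac * smooth.max(), distance=min_peak_distance
    )
    peaks = [int(p) for p in peaks]
    if len(peaks) < 2:
        return None, peaks
    spacings = np.diff(peaks)
    return float(np.mean(spacings)), peaks


def fragment_count_histogram(
    uniques: Sequence[UniqueEccDNA], max_fragments: int | None = None
) -> dict[str, object]:
    """Unique-eccDNA counts by fragment number, plus continuity totals."""
    counts = Counter(u.n_fragments for u in uniques)
    top = max_fragments or (max(counts) if counts else 1)
    histogram = [counts.get(k, 0) for k in range(1, top + 1)]
    continuous = counts.get(1, 0)
    return {
        "histogram": histogram,
        "continuous": continuous,
        "non_continuous": len(uniques) - continuous,
    }


def interchromosomal_pairs(
    uniques: Sequence[UniqueEccDNA],
) -> dict[tuple[str, str], int]:
    """Unordered chromosome pair tallies of two-fragment circles."""
    pairs: Counter = Counter()
    for u in uniques:
        if u.n_fragments != 2:
            continue
        a, b = u.fragments[0].chrom, u.fragments[1].chrom
        pairs[tuple(sorted((a, b)))] += 1
    return dict(pairs)


def chromosome_density(
    track: CoverageTrack, x_name: str = "chrX"
) -> dict[str, object]:
    """Per-chromosome covered-base density and the X/autosome ratio.

    Density is covered-base mass divided by chromosome length; the ratio is
    the X density over the mean autosomal density (chromosomes named like
    ``chr<number>``), reflecting genomic copy number in a male diploid
    genome (one X, two of each autosome).
    """
    density = track.density()
    autosomes = [
        d for c, d in density.items() if c.startswith("chr") and c[3:].isdigit()
    ]
    ratio = None
    if x_name in density and autosomes and np.mean(autosomes) > 0:
        ratio = float(density[x_name] / np.mean(autosomes))
    return {"density": density, "x_autosome_ratio": ratio}
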