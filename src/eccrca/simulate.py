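"""Ground-truthed simulation of eccDNA RCA concatemer sequencing.

The generator emulates the data this pipeline consumes: a reference
genome, a catalog of circular templates (1-7 genomic fragments, either
strand, possibly inter-chromosomal), and for each template one or more RCA
long reads — tandem copies of the circle starting at a random phase —
emitted either as FASTQ (with Nanopore-like substitution/indel errors, for
the external-aligner path) or directly as PAF records with cs tags
(bypassing the aligner, with controlled boundary clipping standing in for
alignment-end jitter).

Default parameters follow the biology the catalog statistics expect:
circle lengths sit on a 188 bp nucleosomal lattice with Gaussian
dispersion, most circles are single-fragment, most are supported by a
single read, and the X chromosome is sampled at half the autosomal rate
(one X versus two of each autosome in a male diploid genome).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from eccrca.caller import FragmentLocus
from eccrca.consensus import reverse_complement
from eccrca.paf import PafRecord

__all__ = [
    "SimParams",
    "SimTruth",
    "ReadTruth",
    "SimResult",
    "generate_reference",
    "sample_circles",
    "simulate_read",
    "emit_direct_paf",
    "simulate_dataset",
    "write_outputs",
]

_BASES = np.array(list("ACGT"))

# single-event fraction e^-0.117 ~= 0.89: most unique circles are seen once
_DEFAULT_FRAGMENT_PROBS = {1: 0.85, 2: 0.10, 3: 0.03, 4: 0.012, 5: 0.005, 6: 0.002, 7: 0.001}


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions.

    Genome: ``n_autosomes`` autosomes plus chrX, each of the given length,
    uniform base composition at the given GC.
    Circles: fragment count ~ ``fragment_count_probs``; total length =
    ``period``*m + Normal(0, ``sigma``) with the nucleosome multiplicity m
    geometric(``mult_p``) truncated at ``mult_max`` (median ~5 nucleosomes,
    ~1 kb); fragments each >= ``min_fragment_len``, placed uniformly with
    chromosomes weighted by length times rate (X at ``x_rate``).
    Reads: reads per circle = 1 + Poisson(``reread_poisson``); passes per
    read = ``pass_min`` + Poisson(``pass_extra_poisson``), capped at
    ``pass_max`` when set; with
    ``partial_passes`` the concatemer starts at a random offset inside its
    first fragment, so the flanking sub-reads are truncated partial passes.
    Errors: per-base substitution/insertion/deletion rates apply to FASTQ
    reads; direct PAF records carry substitution errors only (indel errors
    are an alignment artifact the cs bookkeeping would have to re-absorb).
    ``snv_rate`` plants true template variants relative to the reference,
    shared by every pass of a circle.  ``jitter`` clips up to that many
    bases off each alignment end in direct-PAF mode.
    """

    seed: int = 0
    n_autosomes: int = 4
    autosome_length: int = 400_000
    x_length: int = 400_000
    gc: float = 0.5
    n_circles: int = 200
    fragment_count_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRAGMENT_PROBS)
    )
    period: int = 188
    sigma: float = 15.0
    mult_p: float = 0.13
    mult_max: int = 16
    min_fragment_len: int = 50
    minus_strand_prob: float = 0.5
    x_rate: float = 0.5
    reread_poisson: float = 0.117
    pass_min: int = 2
    pass_extra_poisson: float = 1.7
    pass_max: int | None = None
    partial_passes: bool = True
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    snv_rate: float = 0.0
    jitter: int = 0
    mapq: int = 60


@dataclass
class ReadTruth:
    read_id: str
    circle_id: str
    rotation: int  # index of the first fragment in the read's traversal
    offset: int  # bases into that fragment where the concatemer starts
    pass_count: int


@dataclass
class SimTruth:
    circle_id: str
    fragments: list[FragmentLocus]
    variants: list[tuple[str, int, str, str]]  # chrom, pos, ref, alt
    template: str  # circle sequence in cycle orientation, variants applied
    reads: list[ReadTruth] = field(default_factory=list)

    @property
    def circle_length(self) -> int:
        return sum(f.length for f in self.fragments)


@dataclass
class SimResult:
    params: SimParams
    reference: dict[str, str]
    chrom_sizes: dict[str, int]
    truths: list[SimTruth]
    paf_records: list[PafRecord]
    reads: list[tuple[str, str]]  # (read id, sequence)


def generate_reference(
    params: SimParams, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, int]]:
    """Random reference genome: chr1..chrN autosomes plus chrX."""
    p_gc = params.gc / 2
    p_at = (1 - params.gc) / 2
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    names = [f"chr{i}" for i in range(1, params.n_autosomes + 1)] + ["chrX"]
    lengths = [params.autosome_length] * params.n_autosomes + [params.x_length]
    ref = {
        name: "".join(rng.choice(_BASES, size=n, p=probs))
        for name, n in zip(names, lengths)
    }
    return ref, {name: len(seq) for name, seq in ref.items()}


def _draw_categorical(rng: np.random.Generator, probs: Mapping[int, float]) -> int:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=p / p.sum()))


def _draw_length(params: SimParams, rng: np.random.Generator, k: int) -> int:
    geom = rng.geometric(params.mult_p)
    m = int(min(geom, params.mult_max))
    length = int(round(params.period * m + rng.normal(0, params.sigma)))
    return max(length, k * params.min_fragment_len)


def _partition(total: int, k: int, min_len: int, rng: np.random.Generator) -> list[int]:
    extra = rng.multinomial(total - k * min_len, np.full(k, 1.0 / k))
    return [min_len + int(e) for e in extra]


def _template_fragment(
    ref: Mapping[str, str], frag: FragmentLocus, variants: dict[int, tuple[str, str]]
) -> str:
    seq = list(ref[frag.chrom][frag.start : frag.end].upper())
    for pos, (_ref_base, alt) in variants.items():
        seq[pos - frag.start] = alt
    out = "".join(seq)
    return reverse_complement(out) if frag.strand == "-" else out


def sample_circles(
    params: SimParams,
    reference: Mapping[str, str],
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> list[SimTruth]:
    """Draw ``n_circles`` ground-truth circular templates."""
    names = sorted(chrom_sizes)
    weights = np.array(
        [
            chrom_sizes[c] * (params.x_rate if c == "chrX" else 1.0)
            for c in names
        ],
        dtype=float,
    )
    weights /= weights.sum()
    truths: list[SimTruth] = []
    for idx in range(params.n_circles):
        k = _draw_categorical(rng, params.fragment_count_probs)
        total = _draw_length(params, rng, k)
        lengths = _partition(total, k, params.min_fragment_len, rng)
        fragments: list[FragmentLocus] = []
        variants: list[tuple[str, int, str, str]] = []
        frag_vars: list[dict[int, tuple[str, str]]] = []
        for flen in lengths:
            for _attempt in range(100):
                chrom = names[int(rng.choice(len(names), p=weights))]
                if chrom_sizes[chrom] > flen:
                    break
            else:
                raise RuntimeError(f"cannot place fragment of {flen} bp")
            start = int(rng.integers(0, chrom_sizes[chrom] - flen))
            strand = "-" if rng.random() < params.minus_strand_prob else "+"
            frag = FragmentLocus(chrom, start, start + flen, strand)
            fv: dict[int, tuple[str, str]] = {}
            if params.snv_rate > 0:
                n_var = rng.binomial(flen, params.snv_rate)
                for pos in sorted(rng.choice(flen, size=n_var, replace=False)):
                    gpos = start + int(pos)
                    ref_base = reference[chrom][gpos].upper()
                    alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                    fv[gpos] = (ref_base, alt)
                    variants.append((chrom, gpos, ref_base, alt))
            fragments.append(frag)
            frag_vars.append(fv)
        template = "".join(
            _template_fragment(reference, f, fv) for f, fv in zip(fragments, frag_vars)
        )
        truths.append(
            SimTruth(
                circle_id=f"circle{idx:05d}",
                fragments=fragments,
                variants=variants,
                template=template,
            )
        )
    return truths


def _read_plan(
    truth: SimTruth, params: SimParams, rng: np.random.Generator, read_no: int
) -> ReadTruth:
    rotation = int(rng.integers(0, len(truth.fragments)))
    offset = 0
    if params.partial_passes:
        offset = int(rng.integers(0, truth.fragments[rotation].length))
    pass_count = params.pass_min + int(rng.poisson(params.pass_extra_poisson))
    if params.pass_max is not None:
        pass_count = min(pass_count, params.pass_max)
    return ReadTruth(
        read_id=f"{truth.circle_id}_r{read_no}",
        circle_id=truth.circle_id,
        rotation=rotation,
        offset=offset,
        pass_count=pass_count,
    )


def _segments(truth: SimTruth, plan: ReadTruth) -> list[tuple[int, int, int]]:
    """Tile the read with (fragment index, local start, local end) segments.

    Local coordinates run 0..fragment length in the fragment's traversal
    orientation (5' of the read).  The walk starts ``offset`` bases into
    fragment ``rotation`` and covers exactly pass_count circle lengths, so
    a non-zero offset produces truncated flanking segments.
    """
    k = len(truth.fragments)
    remaining = plan.pass_count * truth.circle_length
    segs: list[tuple[int, int, int]] = []
    fi, off = plan.rotation, plan.offset
    while remaining > 0:
        flen = truth.fragments[fi].length
        take = min(flen - off, remaining)
        segs.append((fi, off, off + take))
        remaining -= take
        fi, off = (fi + 1) % k, 0
    return segs


def _local_to_genomic(frag: FragmentLocus, a: int, b: int) -> tuple[int, int]:
    """Map a traversal-local interval [a, b) to genomic coordinates."""
    if frag.strand == "+":
        return frag.start + a, frag.start + b
    return frag.end - b, frag.end - a


def _template_offsets(truth: SimTruth) -> list[int]:
    offs = [0]
    for f in truth.fragments[:-1]:
        offs.append(offs[-1] + f.length)
    return offs


def simulate_read(
    truth: SimTruth, plan: ReadTruth, params: SimParams, rng: np.random.Generator
) -> str:
    """Concatemer read sequence with iid substitution/indel errors."""
    offs = _template_offsets(truth)
    clean = "".join(
        truth.template[offs[fi] + a : offs[fi] + b] for fi, a, b in _segments(truth, plan)
    )
    if params.sub_rate == params.ins_rate == params.del_rate == 0:
        return clean
    out: list[str] = []
    for base in clean:
        if rng.random() < params.del_rate:
            continue
        if rng.random() < params.sub_rate:
            base = str(rng.choice([b for b in "ACGT" if b != base]))
        out.append(base)
        if rng.random() < params.ins_rate:
            out.append(str(rng.choice(_BASES)))
    return "".join(out)


def _build_cs(
    reference: Mapping[str, str],
    chrom: str,
    tstart: int,
    tend: int,
    variant_map: Mapping[int, tuple[str, str]],
    error_positions: Mapping[int, str],
) -> tuple[str, int]:
    """Short-form cs over [tstart, tend); returns (cs, number of matches)."""
    if not error_positions and not any(tstart <= p < tend for p in variant_map):
        return f":{tend - tstart}", tend - tstart
    parts: list[str] = []
    run = 0
    matches = 0
    ref_seq = reference[chrom]
    for p in range(tstart, tend):
        alt = None
        if p in error_positions:
            alt = error_positions[p]
        elif p in variant_map:
            alt = variant_map[p][1]
        if alt is None:
            run += 1
            matches += 1
        else:
            if run:
                parts.append(f":{run}")
                run = 0
            parts.append(f"*{ref_seq[p].lower()}{alt.lower()}")
    if run:
        parts.append(f":{run}")
    return "".join(parts), matches


def emit_direct_paf(
    truths: Sequence[SimTruth],
    reference: Mapping[str, str],
    chrom_sizes: Mapping[str, int],
    params: SimParams,
    rng: np.random.Generator,
) -> list[PafRecord]:
    """PAF records as a well-behaved aligner would produce them.

    One record per traversed fragment segment; query intervals tile the
    read, target intervals equal truth minus independent uniform end clips
    of at most ``jitter`` bases (the clipped bases become unaligned query,
    which the caller's threading step re-absorbs), cs tags consistent with
    the planted template variants plus per-record substitution errors.
    """
    records: list[PafRecord] = []
    for truth in truths:
        var_by_frag: list[dict[int, tuple[str, str]]] = []
        for frag in truth.fragments:
            var_by_frag.append(
                {
                    pos: (ref_b, alt)
                    for chrom, pos, ref_b, alt in truth.variants
                    if chrom == frag.chrom and frag.start <= pos < frag.end
                }
            )
        for plan in truth.reads:
            segs = _segments(truth, plan)
            qlen = plan.pass_count * truth.circle_length
            qpos = 0
            for fi, a, b in segs:
                frag = truth.fragments[fi]
                seg_len = b - a
                glo, ghi = _local_to_genomic(frag, a, b)
                clip_lo = clip_hi = 0
                if params.jitter > 0 and seg_len > 2 * params.jitter + 1:
                    clip_lo = int(rng.integers(0, params.jitter + 1))
                    clip_hi = int(rng.integers(0, params.jitter + 1))
                tstart, tend = glo + clip_lo, ghi - clip_hi
                # read-left clip is the genomic-start clip on '+', genomic-end on '-'
                left, right = (clip_lo, clip_hi) if frag.strand == "+" else (clip_hi, clip_lo)
                qstart, qend = qpos + left, qpos + seg_len - right
                errors: dict[int, str] = {}
                if params.sub_rate > 0:
                    n_err = rng.binomial(tend - tstart, params.sub_rate)
                    for off in rng.choice(tend - tstart, size=n_err, replace=False):
                        p = tstart + int(off)
                        cur = var_by_frag[fi].get(p, (None, None))[1] or reference[
                            frag.chrom
                        ][p].upper()
                        errors[p] = str(rng.choice([x for x in "ACGT" if x != cur]))
                cs, matches = _build_cs(
                    reference, frag.chrom, tstart, tend, var_by_frag[fi], errors
                )
                records.append(
                    PafRecord(
                        qname=plan.read_id,
                        qlen=qlen,
                        qstart=qstart,
                        qend=qend,
                        strand=frag.strand,
                        tname=frag.chrom,
                        tlen=chrom_sizes[frag.chrom],
                        tstart=tstart,
                        tend=tend,
                        nmatch=matches,
                        alnlen=tend - tstart,
                        mapq=params.mapq,
                        tags=("tp:A:P", f"cs:Z:{cs}"),
                    )
                )
                qpos += seg_len
    return records


def simulate_dataset(params: SimParams, with_reads: bool = False) -> SimResult:
    """Full simulation: reference, circles, read plans, PAF (and FASTQ)."""
    rng = np.random.default_rng(params.seed)
    reference, chrom_sizes = generate_reference(params, rng)
    truths = sample_circles(params, reference, chrom_sizes, rng)
    for truth in truths:
        n_reads = 1 + int(rng.poisson(params.reread_poisson))
        truth.reads = [
            _read_plan(truth, params, rng, i) for i in range(n_reads)
        ]
    paf_records = emit_direct_paf(truths, reference, chrom_sizes, params, rng)
    reads: list[tuple[str, str]] = []
    if with_reads:
        for truth in truths:
            for plan in truth.reads:
                reads.append((plan.read_id, simulate_read(truth, plan, params, rng)))
    return SimResult(params, reference, chrom_sizes, truths, paf_records, reads)


def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, chrom.sizes, FASTQ, PAF, truth TSVs and a manifest."""
    from eccrca.paf import write_paf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["reference"] = outdir / "reference.fa"
    with open(paths["reference"], "w") as fh:
        for name in sorted(result.reference):
            fh.write(f">{name}\n")
            seq = result.reference[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    paths["chrom_sizes"] = outdir / "reference.chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for name in sorted(result.chrom_sizes):
            fh.write(f"{name}\t{result.chrom_sizes[name]}\n")

    paths["paf"] = outdir / "alignments.paf"
    paths["paf"].write_text(write_paf(result.paf_records))

    paths["fastq"] = outdir / "reads.fastq"
    with open(paths["fastq"], "w") as fh:
        for read_id, seq in result.reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    paths["truth_circles"] = outdir / "truth_circles.tsv"
    with open(paths["truth_circles"], "w") as fh:
        fh.write("circle_id\tn_fragments\tcircle_length\tfragments\tvariants\n")
        for t in result.truths:
            frags = ";".join(str(f) for f in t.fragments)
            vars_ = ";".join(f"{c}:{p}:{r}>{a}" for c, p, r, a in t.variants)
            fh.write(
                f"{t.circle_id}\t{len(t.fragments)}\t{t.circle_length}\t{frags}\t{vars_}\n"
            )

    paths["truth_reads"] = outdir / "truth_reads.tsv"
    with open(paths["truth_reads"], "w") as fh:
        fh.write("read_id\tcircle_id\trotation\toffset\tpass_count\n")
        for t in result.truths:
            for r in t.reads:
                fh.write(
                    f"{r.read_id}\t{r.circle_id}\t{r.rotation}\t{r.offset}\t{r.pass_count}\n"
                )

    paths["manifest"] = outdir / "manifest.json"
    params_dict = asdict(result.params)
    params_dict["fragment_count_probs"] = {
        str(k): v for k, v in result.params.fragment_count_probs.items()
    }
    paths["manifest"].write_text(json.dumps(params_dict, indent=2) + "\n")
    return paths
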