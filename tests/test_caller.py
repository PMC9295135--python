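"""Circle-calling pipeline: filtering, clustering, concordance, voting,
threading.  Each combinatorial operation is checked against an independent
brute-force oracle on small instances."""

import itertools

import numpy as np
import pytest

from eccrca.caller import (
    CallerParams,
    CircleCall,
    FragmentLocus,
    SubRead,
    call_circles,
    check_concordance,
    cluster_loci,
    count_passes,
    filter_subreads,
    thread_refine,
    vote_boundaries,
    _mode_with_tiebreak,
)
from eccrca.catalog import canonicalize
from eccrca.paf import PafRecord


def make_record(qname, qstart, qend, tname, tstart, tend, strand="+", mapq=60):
    return PafRecord(
        qname, 100_000, qstart, qend, strand, tname, 1_000_000, tstart, tend,
        tend - tstart, tend - tstart, mapq,
    )


def make_sub(rank, qstart, qend, chrom, tstart, tend, strand="+"):
    return SubRead("r", qstart, qend, chrom, tstart, tend, strand, 60, rank=rank)


# ---------------------------------------------------------------- filtering

def test_mapq_threshold_is_sharp(params):
    recs = [
        make_record("r", 0, 500, "chr1", 1000, 1500, mapq=29),
        make_record("r", 500, 1000, "chr1", 1000, 1500, mapq=30),
    ]
    subs = filter_subreads(recs, params)["r"]
    assert [s.mapq for s in subs] == [30]


def test_filter_matches_brute_force_count(rng, params):
    mapqs = rng.integers(0, 61, size=200)
    recs = [
        make_record(f"r{i % 7}", 0, 500, "chr1", 1000, 1500, mapq=int(q))
        for i, q in enumerate(mapqs)
    ]
    kept = sum(len(v) for v in filter_subreads(recs, params).values())
    assert kept == int(np.sum(mapqs >= 30))


def test_subreads_sorted_and_ranked(params):
    recs = [
        make_record("r", 900, 1400, "chr1", 1000, 1500),
        make_record("r", 0, 500, "chr1", 1000, 1500),
        make_record("r", 450, 950, "chr1", 1000, 1500),
    ]
    subs = filter_subreads(recs, params)["r"]
    assert [s.qstart for s in subs] == [0, 450, 900]
    assert [s.rank for s in subs] == [0, 1, 2]


# --------------------------------------------------------------- clustering

def test_offset_20_joins_21_splits(params):
    a = make_sub(0, 0, 900, "chr1", 1000, 1900)
    b = make_sub(1, 900, 1820, "chr1", 1020, 1920)
    clusters, labels = cluster_loci([a, b], params)
    assert labels == [0, 0] and len(clusters) == 1

    b21 = make_sub(1, 900, 1821, "chr1", 1021, 1920)
    clusters, labels = cluster_loci([a, b21], params)
    assert labels == [0, 1] and len(clusters) == 2


def test_identical_coordinates_one_cluster(params):
    subs = [make_sub(i, i * 500, i * 500 + 500, "chr2", 5000, 5500) for i in range(5)]
    clusters, labels = cluster_loci(subs, params)
    assert labels == [0] * 5
    assert len(clusters[0].members) == 5


def _oracle_cluster(subs, max_offset):
    """Independent representative-based greedy clustering over plain tuples."""
    reps = []  # (chrom, strand, start, end)
    labels = []
    for chrom, start, end, strand in subs:
        for i, (rc, rs, rstart, rend) in enumerate(reps):
            if (
                chrom == rc and strand == rs
                and abs(start - rstart) <= max_offset
                and abs(end - rend) <= max_offset
            ):
                labels.append(i)
                break
        else:
            labels.append(len(reps))
            reps.append((chrom, strand, start, end))
    return labels


@pytest.mark.parametrize("jitter", [0, 5, 10, 20])
def test_clustering_matches_oracle_under_jitter(jitter, rng, params):
    for _ in range(200):
        n_loci = int(rng.integers(1, 4))
        loci = [
            ("chr1", int(rng.integers(0, 100_000)) * 10, "+")
            for _ in range(n_loci)
        ]
        n = int(rng.integers(2, 9))
        subs, tuples = [], []
        for rank in range(n):
            chrom, base, strand = loci[int(rng.integers(0, n_loci))]
            s = base + int(rng.integers(-jitter, jitter + 1))
            e = base + 1000 + int(rng.integers(-jitter, jitter + 1))
            # ranks 1..n: no sub-read is flagged as a flanking partial,
            # so the core representative rule is what gets exercised
            subs.append(make_sub(rank + 1, 0, 0, chrom, s, e, strand))
            tuples.append((chrom, s, e, strand))
        _, labels = cluster_loci(subs, params)
        assert labels == _oracle_cluster(tuples, params.max_offset)


# -------------------------------------------------------------- concordance

def _clusters_for_labels(labels):
    """Distinct well-separated loci so only order can be discordant."""
    k = max(labels) + 1
    return [
        type("C", (), dict(cluster_id=i, chrom="chr1", strand="+",
                           rep_start=i * 10_000, rep_end=i * 10_000 + 1000))()
        for i in range(k)
    ]


def _oracle_periodic(labels):
    """A label sequence is concordant iff it is the periodic extension of
    its first-appearance cycle (brute force, by definition)."""
    cycle = list(dict.fromkeys(labels))
    k = len(cycle)
    return all(lab == cycle[i % k] for i, lab in enumerate(labels))


def _normalize(seq):
    remap = {}
    for x in seq:
        remap.setdefault(x, len(remap))
    return [remap[x] for x in seq]


def test_concordance_examples(params):
    for labels, expect in [
        ((0, 1, 2, 0, 1, 2, 0), [0, 1, 2]),
        ((0, 0, 0), [0]),
        ((0, 1, 0, 1, 0), [0, 1]),
    ]:
        cycle, reason = check_concordance(labels, _clusters_for_labels(labels), params)
        assert cycle == expect and reason is None

    cycle, reason = check_concordance((0, 1, 0, 2), _clusters_for_labels((0, 1, 0, 2)), params)
    assert cycle is None and reason == "discordant_order"


def test_concordance_matches_oracle_exhaustively(params):
    """All first-appearance-normalized label sequences of length <= 8 over
    <= 3 symbols agree with the brute-force periodicity oracle."""
    seen = set()
    for length in range(2, 9):
        for raw in itertools.product(range(3), repeat=length):
            labels = tuple(_normalize(raw))
            if labels in seen:
                continue
            seen.add(labels)
            cycle, reason = check_concordance(
                labels, _clusters_for_labels(labels), params
            )
            assert (cycle is not None) == _oracle_periodic(labels), labels


def test_opposite_strand_same_locus_is_discordant_strand(params):
    clusters = _clusters_for_labels((0, 1))
    clusters[1].rep_start = clusters[0].rep_start
    clusters[1].rep_end = clusters[0].rep_end
    clusters[1].strand = "-"
    cycle, reason = check_concordance((0, 1, 0), clusters, params)
    assert cycle is None and reason == "discordant_strand"


# ------------------------------------------------------------ pass counting

def test_pass_counts_example():
    labels = [0, 1, 0, 1, 0]
    subs = [make_sub(i, 0, 0, "chr1", 0, 100) for i in range(5)]
    counts, full = count_passes(labels, subs, [0, 1])
    assert counts == [3, 2] and full == 2


def test_partial_members_do_not_count_as_passes():
    labels = [0, 0, 0]
    subs = [make_sub(i, 0, 0, "chr1", 0, 100) for i in range(3)]
    subs[0].partial = True
    counts, full = count_passes(labels, subs, [0])
    assert counts == [2] and full == 2


def test_pass_counts_match_symbol_count_oracle(rng):
    for _ in range(100):
        k = int(rng.integers(1, 4))
        reps = int(rng.integers(1, 6))
        labels = list(range(k)) * reps + list(range(int(rng.integers(0, k))))
        subs = [make_sub(i, 0, 0, "chr1", 0, 100) for i in range(len(labels))]
        counts, full = count_passes(labels, subs, list(range(k)))
        assert counts == [labels.count(c) for c in range(k)]
        assert full == min(labels.count(c) for c in range(k))


# ----------------------------------------------------------------- voting

def _oracle_mode(values):
    best = None
    top = max(values.count(v) for v in values)
    tied = sorted({v for v in values if values.count(v) == top})
    mid = tied[(len(tied) - 1) // 2]
    return mid


def test_vote_majority_example():
    cl = cluster_of([(1000, 1900), (1000, 1912), (1012, 1900)])
    assert vote_boundaries(cl) == (1000, 1900)


def cluster_of(coords):
    from eccrca.caller import LocusCluster

    members = [make_sub(i, 0, 0, "chr1", s, e) for i, (s, e) in enumerate(coords)]
    return LocusCluster(0, "chr1", "+", coords[0][0], coords[0][1], members)


def test_vote_single_member_is_itself():
    assert vote_boundaries(cluster_of([(123, 456)])) == (123, 456)


def test_vote_matches_exhaustive_mode_oracle(rng):
    for _ in range(1000):
        n = int(rng.integers(1, 10))
        starts = [int(v) for v in rng.integers(0, 5, size=n)]
        ends = [int(v) + 100 for v in rng.integers(0, 5, size=n)]
        cl = cluster_of(list(zip(starts, ends)))
        assert vote_boundaries(cl) == (_oracle_mode(starts), _oracle_mode(ends))
        assert _mode_with_tiebreak(starts) == _oracle_mode(starts)


def test_partial_member_votes_one_boundary_only():
    cl = cluster_of([(1000, 2000), (1000, 2000)])
    partial = make_sub(2, 0, 0, "chr1", 1500, 2000)
    partial.partial = True
    partial.votes_start = False
    partial.votes_end = True
    cl.members.append(partial)
    assert vote_boundaries(cl) == (1000, 2000)


# --------------------------------------------------------------- threading

def abutting_subreads(circle_len, passes):
    subs = []
    for i in range(passes):
        subs.append(make_sub(i, i * circle_len, (i + 1) * circle_len, "chr1", 5000, 5000 + circle_len))
    return subs


def test_threading_fixed_point_when_query_abuts(params):
    subs = abutting_subreads(800, 3)
    frags = [FragmentLocus("chr1", 5000, 5800, "+")]
    refined, diags = thread_refine(frags, [0, 0, 0], subs, [0], params)
    assert refined == frags
    assert all(d.query_gap == 0 for d in diags)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_threading_recovers_junction_clip(strand, params):
    # every alignment lost 7 query bases at its right end: gaps of 7
    subs = []
    for i in range(3):
        subs.append(make_sub(i, i * 800, (i + 1) * 800 - 7, "chr1", 5000, 5793, strand))
    frags = [FragmentLocus("chr1", 5000, 5793, strand)]
    refined, diags = thread_refine(frags, [0, 0, 0], subs, [0], params)
    if strand == "+":
        assert refined == [FragmentLocus("chr1", 5000, 5800, "+")]
    else:  # 3' of a minus-strand fragment is its genomic start
        assert refined == [FragmentLocus("chr1", 4993, 5793, "-")]
    assert diags[0].query_gap == 7 and diags[0].adjustment == 7


def test_threading_trims_small_overlap(params):
    subs = []
    for i in range(3):
        subs.append(make_sub(i, max(0, i * 800 - 5), (i + 1) * 800, "chr1", 5000, 5805))
    frags = [FragmentLocus("chr1", 5000, 5805, "+")]
    refined, diags = thread_refine(frags, [0, 0, 0], subs, [0], params)
    assert refined == [FragmentLocus("chr1", 5000, 5800, "+")]


def test_threading_flags_oversized_gap(params):
    subs = []
    for i in range(3):
        subs.append(make_sub(i, i * 900, i * 900 + 800, "chr1", 5000, 5800))
    frags = [FragmentLocus("chr1", 5000, 5800, "+")]
    refined, diags = thread_refine(frags, [0, 0, 0], subs, [0], params)
    assert refined == frags  # untouched
    assert diags[0].flagged and diags[0].query_gap == 100


# ------------------------------------------------------------- end-to-end

def test_zero_noise_batch_recovers_all_truths(clean_sim):
    calls = call_circles(clean_sim.paf_records)
    truth = {t.circle_id: t for t in clean_sim.truths}
    assert all(c.accepted for c in calls)
    assert len(calls) == len(clean_sim.truths)
    for c in calls:
        t = truth[c.read_id.rsplit("_r", 1)[0]]
        assert canonicalize(c.fragments) == canonicalize(t.fragments)


def test_single_pass_reads_rejected_insufficient(clean_sim, params):
    # keep only the first pass's records of each read
    per_read_first = {}
    for rec in clean_sim.paf_records:
        per_read_first.setdefault(rec.qname, []).append(rec)
    truths = {t.circle_id: t for t in clean_sim.truths}
    records = []
    for qname, recs in per_read_first.items():
        k = len(truths[qname.rsplit("_r", 1)[0]].fragments)
        records.extend(recs[:k])
    calls = call_circles(records, params)
    assert all(not c.accepted for c in calls)
    assert {c.reason for c in calls} <= {"insufficient_passes", "single_hit"}


def test_middle_subread_on_opposite_strand_rejected(params):
    recs = []
    for i in range(4):
        strand = "-" if i == 1 else "+"
        recs.append(make_record("r", i * 800, (i + 1) * 800, "chr1", 5000, 5800, strand=strand))
    (call,) = call_circles(recs, params)
    assert call.reason == "discordant_strand"


def test_all_low_mapq_reported_as_low_mapq(params):
    recs = [make_record("r", i * 800, (i + 1) * 800, "chr1", 5000, 5800, mapq=20) for i in range(3)]
    (call,) = call_circles(recs, params)
    assert call.reason == "low_mapq"


def test_single_alignment_rejected_uncertain(params):
    (call,) = call_circles([make_record("r", 0, 800, "chr1", 5000, 5800)], params)
    assert call.reason == "single_hit"


def test_acceptance_monotone_in_min_passes(clean_sim):
    strict = {c.read_id for c in call_circles(clean_sim.paf_records, CallerParams(min_full_passes=3)) if c.accepted}
    loose = {c.read_id for c in call_circles(clean_sim.paf_records, CallerParams(min_full_passes=2)) if c.accepted}
    assert strict <= loose


def test_determinism_identical_output(clean_sim):
    a = call_circles(clean_sim.paf_records)
    b = call_circles(clean_sim.paf_records)
    assert [(c.read_id, c.status, c.fragments, c.pass_counts) for c in a] == [
        (c.read_id, c.status, c.fragments, c.pass_counts) for c in b
    ]


def test_conservation_passes_times_length_equals_query_span(clean_sim):
    spans = {}
    for rec in clean_sim.paf_records:
        lo, hi = spans.get(rec.qname, (10**12, 0))
        spans[rec.qname] = (min(lo, rec.qstart), max(hi, rec.qend))
    for c in call_circles(clean_sim.paf_records):
        lo, hi = spans[c.read_id]
        # whole passes at zero error: aligned span == passes x circle length
        assert c.full_passes * c.circle_length == hi - lo
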