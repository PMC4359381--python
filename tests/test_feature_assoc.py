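"""Promoter windows, location classes, profiles and promoter statistics."""

import numpy as np
import pytest

from melscan import (
    Feature,
    FeatureSet,
    GenomeIndex,
    MEL,
    MutationCatalog,
    PromoterParams,
    aggregate_interval_scores,
    biallelic_mel_stats,
    chromosome_load_correlation,
    classify_catalog,
    classify_location,
    define_promoters,
    density_profile,
    distance_to_anchor,
    group_compare,
    promoter_mutation_frequency,
)
from conftest import make_catalog, make_record


def _features(*feats):
    return FeatureSet(list(feats))


# ---------------------------------------------------------------------------
# promoter windows


def test_promoter_plus_strand_mrna():
    fs = _features(Feature("g", "chr1", 1000, 2000, "+", "mRNA"))
    [w] = define_promoters(fs)
    assert (w.start, w.end) == (500, 1050)


def test_promoter_minus_strand_mirrored():
    fs = _features(Feature("g", "chr1", 500, 1000, "-", "mRNA"))
    [w] = define_promoters(fs)
    # TSS = 1000 on the minus strand: upstream extends to larger coordinates
    assert (w.start, w.end) == (950, 1500)


def test_promoter_trna_centred_window():
    fs = _features(Feature("t", "chr1", 2001, 2072, "+", "tRNA"))
    [w] = define_promoters(fs)
    assert (w.start, w.end) == (1761, 2310)
    assert w.width == 550


def test_promoter_truncated_at_chromosome_start():
    fs = _features(Feature("g", "chr1", 100, 900, "+", "mRNA"))
    [w] = define_promoters(fs, chrom_lengths={"chr1": 5000})
    assert w.start == 1 and w.truncated


def test_polycistronic_snorna_single_promoter():
    fs = _features(
        Feature("s1", "chr1", 5000, 5100, "+", "snoRNA", cluster_id="cl1"),
        Feature("s2", "chr1", 5200, 5300, "+", "snoRNA", cluster_id="cl1"),
    )
    windows = define_promoters(fs)
    assert len(windows) == 1
    # anchored at the cluster's 5'-most TSS
    assert (windows[0].start, windows[0].end) == (4500, 5050)


def test_intronic_snorna_inherits_host_promoter():
    fs = _features(
        Feature("host", "chr1", 1000, 4000, "+", "mRNA"),
        Feature("sno", "chr1", 2000, 2100, "+", "snoRNA", host_feature_id="host"),
    )
    windows = {w.feature_id: w for w in define_promoters(fs)}
    assert (windows["sno"].start, windows["sno"].end) == (
        windows["host"].start,
        windows["host"].end,
    )


# ---------------------------------------------------------------------------
# classification


def _annotated():
    return _features(
        Feature("g1", "chr1", 1000, 2000, "+", "mRNA"),
        Feature("a1", "chr1", 600, 700, "+", "ARS"),
    )


def test_classify_priority_promoter_over_others():
    fs = _annotated()
    promoters = define_promoters(fs)
    # 650 lies in both the ARS and g1's promoter window [500, 1050]
    assert classify_location("chr1", 650, fs, promoters) == "promoter"
    assert classify_location("chr1", 1500, fs, promoters) == "gene_body"
    assert classify_location("chr1", 5000, fs, promoters) == "intergenic"
    assert classify_location("chr2", 10, fs, promoters) == "intergenic"


def test_classification_partitions_catalog():
    fs = _annotated()
    promoters = define_promoters(fs)
    entries = [("c1", "chr1", p, "C") for p in (650, 1500, 5000, 900, 1)]
    entries.append(("c2", "chr2", 3, "G"))
    cat = make_catalog(entries)
    counts = classify_catalog(cat, fs, promoters)
    assert counts.sum() == cat.total_mutations


# ---------------------------------------------------------------------------
# anchor distances and profiles


def test_distance_examples():
    fs = _features(Feature("g", "chr1", 1000, 2000, "+", "mRNA"))
    assert distance_to_anchor("chr1", 979, fs, "TSS") == -21
    assert distance_to_anchor("chr1", 1000, fs, "TSS") == 0
    neg = _features(Feature("g", "chr1", 200, 1000, "-", "mRNA"))
    assert distance_to_anchor("chr1", 1021, neg, "TSS") == -21


def test_distance_requires_anchor():
    fs = _features(Feature("g", "chr1", 1000, 2000, "+", "mRNA"))
    with pytest.raises(ValueError):
        distance_to_anchor("chr1", 500, fs, "TATA")


def test_density_profile_sum_identity():
    fs = _features(Feature("g", "chr1", 1000, 2000, "+", "mRNA"))
    in_range = [960, 990, 1005, 1400]
    out_range = [3000, 4000, 5000, 6000, 7000, 8000]
    cat = make_catalog([("c1", "chr1", p, "C") for p in in_range + out_range])
    prof = density_profile(cat, fs, "TSS", range_bp=500)
    assert prof.total_mutations_in_range == 4
    assert prof.density.sum() == pytest.approx(0.4)
    assert (prof.density >= 0).all()


def test_density_profile_single_offset():
    fs = _features(Feature("g", "chr1", 1000, 2000, "+", "mRNA"))
    cat = make_catalog([("c%d" % i, "chr1", 1000, "C") for i in range(5)])
    prof = density_profile(cat, fs, "TSS", range_bp=100)
    nz = np.flatnonzero(prof.density)
    assert nz.tolist() == [100]  # offset 0 sits mid-array
    assert prof.offsets[nz[0]] == 0


# ---------------------------------------------------------------------------
# promoter mutation frequency


def _promoter_set():
    fs = _features(
        Feature("g1", "chr1", 2000, 4000, "+", "mRNA"),
        Feature("g2", "chr1", 8000, 10_000, "+", "mRNA"),
    )
    return define_promoters(fs)


def test_downsampling_degenerate_target_equals_size():
    promoters = _promoter_set()
    cat = make_catalog(
        [("c1", "chr1", 1600, "C"), ("c1", "chr1", 1700, "C"), ("c1", "chr1", 7600, "C")]
    )
    table = promoter_mutation_frequency(
        [cat], promoters, downsample_target=3, n_bootstraps=10, seed=0
    )
    assert table.table["toy"].loc["g1"] == pytest.approx(2.0)
    assert table.table["toy"].loc["g2"] == pytest.approx(1.0)


def test_downsampling_half_matches_hypergeometric(rng):
    promoters = _promoter_set()
    n_total = 400
    in_g1 = 60
    positions = [1550 + i for i in range(in_g1)]  # inside g1's window [1500, 2050]
    positions += [20_000 + 7 * i for i in range(n_total - in_g1)]
    cat = make_catalog([("c%d" % (i % 8), "chr1", p, "C") for i, p in enumerate(positions)])
    B = 1000
    table = promoter_mutation_frequency(
        [cat], promoters, downsample_target=n_total // 2, n_bootstraps=B, seed=4
    )
    mean = table.table["toy"].loc["g1"]
    # hypergeometric: E = K/2, Var = K * (1/2) * (1/2) * (n - n/2) / (n - 1)
    var = in_g1 * 0.25 * (n_total - n_total // 2) / (n_total - 1)
    se = np.sqrt(var / B)
    assert abs(mean - in_g1 / 2) < 3 * se
    assert table.table["toy"].loc["g2"] == 0.0


def test_downsampling_rejects_small_catalog():
    promoters = _promoter_set()
    cat = make_catalog([("c1", "chr1", 1600, "C")])
    with pytest.raises(ValueError, match="smaller than"):
        promoter_mutation_frequency([cat], promoters, downsample_target=5)


# ---------------------------------------------------------------------------
# rank statistics


def test_group_compare_identical_groups():
    _, p = group_compare([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_group_compare_extreme_separation_exact():
    # n = m = 3, most extreme ranking: exact two-sided p = 2/20
    _, p = group_compare([1, 2, 3], [10, 11, 12])
    assert p == pytest.approx(0.1)


def test_group_compare_empty_group_rejected():
    with pytest.raises(ValueError):
        group_compare([], [1.0])


def test_aggregate_interval_scores():
    positions = np.arange(1, 1001)
    scores = np.ones(1000)
    sums = aggregate_interval_scores(positions, scores, [(100, 649), (600, 700)])
    assert sums.tolist() == [550.0, 101.0]
    empty = aggregate_interval_scores(np.array([]), np.array([]), [(1, 10)])
    assert empty.tolist() == [0.0]


# ---------------------------------------------------------------------------
# chromosome load correlation


def test_load_correlation_perfect_monotone():
    lengths = {"c1": 100, "c2": 200, "c3": 300, "c4": 400}
    g = GenomeIndex({c: "A" * n for c, n in lengths.items()})
    entries = []
    for i, chrom in enumerate(lengths, start=1):
        for j in range(i):
            entries.append(("clone", chrom, j + 1, "C"))
    cat = make_catalog(entries)
    out = chromosome_load_correlation(cat, g)
    assert out["C"][0] == pytest.approx(1.0)
    assert np.isnan(out["G"][0])  # no G mutations: constant zero counts


def test_load_correlation_hand_ranks():
    # counts (2,1,3,5,4) against lengths (100..500): rho = 1 - 6*4/120 = 0.8
    lengths = {f"c{i}": 100 * i for i in range(1, 6)}
    g = GenomeIndex({c: "A" * n for c, n in lengths.items()})
    per_chrom = {"c1": 2, "c2": 1, "c3": 3, "c4": 5, "c5": 4}
    entries = []
    for chrom, k in per_chrom.items():
        for j in range(k):
            entries.append(("clone", chrom, j + 1, "C"))
    cat = make_catalog(entries)
    assert chromosome_load_correlation(cat, g)["C"][0] == pytest.approx(0.8)


def test_load_correlation_needs_three_chromosomes():
    g = GenomeIndex({"c1": "A" * 10, "c2": "A" * 20})
    with pytest.raises(ValueError, match="3 chromosomes"):
        chromosome_load_correlation(make_catalog([("c", "c1", 1, "A")]), g)


# ---------------------------------------------------------------------------
# biallelic statistics


def _mel(chrom, start, end):
    return MEL(
        chrom=chrom, start=start, end=end, per_base_counts={},
        mutation_total=6, transformant_count=4, clone_ids=frozenset("abcd"),
        n_at_c=3, n_at_g=3,
    )


def test_biallelic_hom_in_mel_fraction():
    mels = [_mel("chr1", 100, 200)]
    cat = MutationCatalog("t")
    for i in range(8):  # hom mutations inside the MEL
        cat.add(make_record(f"g{i}", "chr1", 110 + i, allele_frequency=0.95))
    for i in range(2):  # hom mutations outside
        cat.add(make_record(f"g{i}", "chr1", 5000 + i, allele_frequency=0.95))
    stats = biallelic_mel_stats(cat, mels)
    assert stats.n_hom == 10
    assert stats.hom_in_mel_fraction == pytest.approx(0.8)


def test_biallelic_per_genome_rules():
    mels = [_mel("chr1", 100, 200)]
    cat = MutationCatalog("t")
    # genome A: one hom inside -> biallelic
    cat.add(make_record("A", "chr1", 150, allele_frequency=1.0))
    # genome B: two het inside the same MEL -> biallelic under the pair proxy
    cat.add(make_record("B", "chr1", 140, allele_frequency=0.5))
    cat.add(make_record("B", "chr1", 160, allele_frequency=0.5))
    # genome C: a single het inside -> not biallelic
    cat.add(make_record("C", "chr1", 170, allele_frequency=0.5))
    stats = biallelic_mel_stats(cat, mels)
    assert stats.per_genome_biallelic_fraction == pytest.approx(2 / 3)
    strict = biallelic_mel_stats(cat, mels, het_pair_counts=False)
    assert strict.per_genome_biallelic_fraction == pytest.approx(1 / 3)
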