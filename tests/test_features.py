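"""Feature extraction: weighted order statistics, MAF density peaks,
chr21 positional bins and the 186-feature contract."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import leukotype as lk
from leukotype import features as feat


def _dosage(chrom_values, rng=None, weights=None):
    """Dosage table from {chrom: list of log2fc}; positions sequential."""
    rows = []
    i = 0
    for chrom, vals in chrom_values.items():
        for v in vals:
            i += 1
            rows.append(dict(gene_id=f"G{i}", chrom=str(chrom),
                             start=1000 * i, log2fc=v,
                             weight=1.0 if weights is None else weights[i - 1]))
    return pd.DataFrame(rows)


def _maf(chrom_values):
    rows = []
    i = 0
    for chrom, vals in chrom_values.items():
        for v in vals:
            i += 1
            rows.append(dict(chrom=str(chrom), pos=100 * i, depth=100, maf=v))
    return pd.DataFrame(rows)


def _neutral_tables(rng):
    """Diploid-looking dosage/MAF across all 23 chromosomes."""
    dosage = _dosage({c: rng.normal(0, 0.1, 10) for c in feat.CHROMOSOMES})
    maf = _maf({c: np.minimum(f := rng.binomial(100, 0.5, 10) / 100, 1 - f)
                for c in feat.CHROMOSOMES})
    return dosage, maf


# --------------------------------------------------------------------------
# weighted order statistics
# --------------------------------------------------------------------------
def test_weighted_median_reduces_to_unweighted():
    assert feat.weighted_median([-1, 0, 5], [1, 1, 1]) == 0


def brute_force_weighted_percentile(values, weights, q):
    order = np.argsort(values, kind="stable")
    values, weights = np.asarray(values)[order], np.asarray(weights)[order]
    cum = 0.0
    for v, w in zip(values, weights):
        cum += w
        if cum >= q * weights.sum():
            return v
    return values[-1]


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(-10, 10), st.floats(0.01, 5)),
                min_size=1, max_size=20),
       st.sampled_from([0.05, 0.25, 0.5, 0.75, 0.95]))
def test_weighted_percentile_matches_cumulative_scan(pairs, q):
    values = [p[0] for p in pairs]
    weights = [p[1] for p in pairs]
    assert feat.weighted_percentile(values, weights, q) == pytest.approx(
        brute_force_weighted_percentile(values, weights, q))


# --------------------------------------------------------------------------
# log2FC computation
# --------------------------------------------------------------------------
def _counts_and_reference(rng, factor=None, double_gene=None):
    n = 40 * len(feat.CHROMOSOMES)
    genes = [f"G{i}" for i in range(n)]
    chroms = np.repeat(list(feat.CHROMOSOMES), 40)
    ref = rng.integers(50, 500, n).astype(float)
    counts = ref.copy()
    if factor is not None:
        counts = counts * factor
    if double_gene is not None:
        counts[double_gene] *= 2
    counts_table = pd.DataFrame({"gene_id": genes, "chrom": chroms,
                                 "start": np.arange(1, n + 1) * 1000,
                                 "count": counts})
    reference = pd.DataFrame({"gene_id": genes, "expr": ref})
    return counts_table, reference


def test_log2fc_identity_is_zero():
    counts, ref = _counts_and_reference(np.random.default_rng(0))
    out = feat.compute_log2fc(counts, ref)
    assert np.allclose(out["log2fc"], 0.0, atol=1e-12)
    assert np.allclose(out["weight"], np.log1p(ref["expr"]))


def test_log2fc_global_scaling_cancels():
    counts, ref = _counts_and_reference(np.random.default_rng(1), factor=1.5)
    out = feat.compute_log2fc(counts, ref)
    assert np.allclose(out["log2fc"], 0.0, atol=1e-12)


def test_log2fc_single_doubled_gene():
    counts, ref = _counts_and_reference(np.random.default_rng(2),
                                        double_gene=0)
    out = feat.compute_log2fc(counts, ref)
    # library-size shift from one gene among ~920 is negligible
    assert out["log2fc"].iloc[0] == pytest.approx(1.0, abs=0.01)
    assert np.abs(out["log2fc"].iloc[1:]).max() < 0.01


def test_log2fc_too_few_chromosomes_errors():
    counts, ref = _counts_and_reference(np.random.default_rng(3))
    counts = counts[counts["chrom"] == "1"]
    with pytest.raises(feat.FeatureError, match="chromosomes"):
        feat.compute_log2fc(counts, ref)


# --------------------------------------------------------------------------
# MAF density peaks
# --------------------------------------------------------------------------
def test_kde_peak_matches_grid_argmax_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        f = rng.choice([0.02, 1 / 3, 0.5])
        raw = rng.binomial(100, f, 40) / 100
        folded = np.minimum(raw, 1 - raw)
        primary, secondary = feat.maf_peaks(folded)
        grid, dens = feat.maf_density(folded)
        assert primary == pytest.approx(grid[int(np.argmax(dens))])
        assert 0 <= secondary <= 0.5


def test_maf_peaks_bimodal_secondary():
    rng = np.random.default_rng(1)
    raw = np.concatenate([rng.binomial(200, 0.5, 60) / 200,
                          rng.binomial(200, 0.02, 40) / 200])
    folded = np.minimum(raw, 1 - raw)
    primary, secondary = feat.maf_peaks(folded)
    assert abs(primary - 0.5) < 0.05
    assert abs(secondary - 0.0) < 0.05
    assert abs(primary - secondary) >= feat.SECONDARY_PEAK_MIN_DISTANCE


def test_maf_peaks_unimodal_secondary_equals_primary():
    rng = np.random.default_rng(2)
    raw = rng.binomial(200, 0.5, 100) / 200
    primary, secondary = feat.maf_peaks(np.minimum(raw, 1 - raw))
    assert primary == secondary


# --------------------------------------------------------------------------
# chromosome metrics
# --------------------------------------------------------------------------
def test_chromosome_metrics_diploid_and_trisomy():
    rng = np.random.default_rng(0)
    log2fc_di = rng.normal(0.0, 0.25, 500)
    log2fc_tri = rng.normal(np.log2(1.5), 0.25, 500)
    raw_di = rng.binomial(100, 0.5, 200) / 100
    raw_tri = rng.binomial(100, rng.choice([1 / 3, 2 / 3], 200), 200) / 100
    dosage = _dosage({"1": log2fc_di, "2": log2fc_tri})
    maf = _maf({"1": np.minimum(raw_di, 1 - raw_di),
                "2": np.minimum(raw_tri, 1 - raw_tri)})
    m1 = feat.chromosome_metrics(dosage, maf, "1")
    assert abs(m1["log2fc_wmedian"]) < 0.05
    assert abs(m1["maf_peak_primary"] - 0.5) < 0.05
    assert m1["het_fraction"] > 0.7
    m2 = feat.chromosome_metrics(dosage, maf, "2")
    assert abs(m2["log2fc_wmedian"] - 0.585) < 0.07
    assert abs(m2["maf_peak_primary"] - 1 / 3) < 0.05


def test_chromosome_metrics_weighted_median_uses_weights():
    dosage = _dosage({"1": [0.0, 0.0, 1.0, 1.0, 1.0]},
                     weights=[10.0, 10.0, 0.1, 0.1, 0.1])
    maf = _maf({"1": [0.5] * 5})
    m = feat.chromosome_metrics(dosage, maf, "1")
    assert m["log2fc_wmedian"] == 0.0


def test_sparse_chromosome_imputed_neutral():
    dosage = _dosage({"1": [1.5, 1.5]})  # below the 5-gene minimum
    maf = _maf({"1": [0.1, 0.1]})
    m = feat.chromosome_metrics(dosage, maf, "1")
    assert m["log2fc_wmedian"] == 0.0
    assert m["maf_peak_primary"] == 0.5
    assert m["het_fraction"] == 1.0


# --------------------------------------------------------------------------
# chr21 positional features
# --------------------------------------------------------------------------
def test_chr21_bins_diploid_near_zero():
    rng = np.random.default_rng(0)
    starts = rng.integers(feat.IAMP21_REGION_START, feat.IAMP21_REGION_END,
                          500)
    dosage = pd.DataFrame({"gene_id": [f"G{i}" for i in range(500)],
                           "chrom": "21", "start": starts,
                           "log2fc": rng.normal(0, 0.2, 500), "weight": 1.0})
    bins = feat.chr21_positional_features(dosage)
    assert len(bins) == 24
    assert np.abs(bins).max() < 0.15


def test_chr21_bins_amplified_region():
    rng = np.random.default_rng(1)
    starts = rng.integers(feat.IAMP21_REGION_START, feat.IAMP21_REGION_END,
                          1000)
    dosage = pd.DataFrame({"gene_id": [f"G{i}" for i in range(1000)],
                           "chrom": "21", "start": starts,
                           "log2fc": rng.normal(np.log2(2.5), 0.2, 1000),
                           "weight": 1.0})
    bins = feat.chr21_positional_features(dosage)
    assert np.abs(bins - np.log2(2.5)).max() < 0.15  # ~1.32 each


def test_chr21_bin_boundaries_are_the_printed_interval():
    width = (feat.IAMP21_REGION_END - feat.IAMP21_REGION_START) / 24
    rows = [dict(gene_id="A", chrom="21", start=feat.IAMP21_REGION_START,
                 log2fc=2.0, weight=1.0),
            dict(gene_id="B", chrom="21", start=feat.IAMP21_REGION_END,
                 log2fc=3.0, weight=1.0),
            dict(gene_id="C", chrom="21", start=feat.IAMP21_REGION_START - 1,
                 log2fc=9.0, weight=1.0),
            dict(gene_id="D", chrom="21", start=feat.IAMP21_REGION_END + 1,
                 log2fc=9.0, weight=1.0)]
    # pad so the chromosome median (bin fallback) is 0
    rows += [dict(gene_id=f"P{i}", chrom="21",
                  start=feat.IAMP21_REGION_START + int((i + 0.5) * width),
                  log2fc=0.0, weight=1.0) for i in range(24)]
    bins = feat.chr21_positional_features(pd.DataFrame(rows))
    assert bins[0] == pytest.approx(1.0)   # mean(2.0, pad 0.0): start included
    assert bins[-1] == pytest.approx(1.5)  # mean(3.0, pad 0.0): end included
    assert np.abs(bins[1:-1]).max() == 0.0  # out-of-region genes never counted


# --------------------------------------------------------------------------
# full vector contract
# --------------------------------------------------------------------------
def test_feature_vector_contract():
    rng = np.random.default_rng(0)
    dosage, maf = _neutral_tables(rng)
    vec = feat.extract_features(dosage, maf)
    assert len(vec) == 186
    assert list(vec.index) == list(feat.FEATURE_NAMES)
    assert sum("chr21_region" in n for n in vec.index) == 24
    assert np.isfinite(vec.to_numpy()).all()


def test_feature_vector_deterministic_and_order_invariant():
    rng = np.random.default_rng(1)
    dosage, maf = _neutral_tables(rng)
    vec1 = feat.extract_features(dosage, maf)
    vec2 = feat.extract_features(dosage, maf)
    pd.testing.assert_series_equal(vec1, vec2)
    shuffled = feat.extract_features(
        dosage.sample(frac=1, random_state=2).reset_index(drop=True),
        maf.sample(frac=1, random_state=3).reset_index(drop=True))
    pd.testing.assert_series_equal(vec1, shuffled)


def test_region_features_shift_exactly_with_dosage():
    rng = np.random.default_rng(2)
    starts = rng.integers(feat.IAMP21_REGION_START, feat.IAMP21_REGION_END,
                          300)
    dosage = pd.DataFrame({"gene_id": [f"G{i}" for i in range(300)],
                           "chrom": "21", "start": starts,
                           "log2fc": rng.normal(0, 0.2, 300), "weight": 1.0})
    before = feat.chr21_positional_features(dosage)
    shifted = dosage.assign(log2fc=dosage["log2fc"] + 0.7)
    after = feat.chr21_positional_features(shifted)
    assert np.allclose(after - before, 0.7)


def test_missing_columns_raise():
    with pytest.raises(feat.FeatureError, match="lacks columns"):
        feat.extract_features(pd.DataFrame({"chrom": []}),
                              pd.DataFrame({"chrom": [], "pos": [],
                                            "depth": [], "maf": []}))
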