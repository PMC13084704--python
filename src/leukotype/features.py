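"""Chromosome-level dosage/MAF feature extraction for virtual karyotyping.

One RNA-seq sample is summarized as a fixed, ordered vector of 186 features:

* 23 chromosomes (1-22, X) x 7 metrics = 161 — expression-weighted median
  log2 fold-change versus a diploid reference, weighted 5th/95th percentile
  range boundaries, the primary and secondary folded-MAF density peak
  positions, the MAF density height at 0.5, and the heterozygous fraction
  (share of SNVs with folded MAF in [0.4, 0.5]);
* 24 positional dosage features — mean log2FC in 24 equal-width bins across
  the iAMP21 diagnostic region chr21:25,772,460-39,428,528;
* 1 genome-wide weighted median log2FC.

Folded MAF ``min(f, 1-f)`` lives in [0, 0.5]: balanced disomy peaks at 0.5,
trisomy at 1/3, loss of heterozygosity near 0 — which is what separates a
whole-genome-doubled ("masked") near-haploid genome, dosage-identical to a
diploid one, from true disomy.

MAF density peaks are located on a fixed 256-point grid by a Gaussian kernel
density estimate with bandwidth 0.03 and boundary reflection at 0 and 0.5;
the secondary peak is the next-highest local maximum at distance >= 0.08
from the primary (equal to the primary if unimodal).  Chromosomes with fewer
than 5 genes or SNVs are imputed with diploid-neutral values (median 0,
peaks 0.5, het fraction 1), deliberately biasing sparse samples toward the
majority non-aneuploid class.
"""
from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

#: iAMP21 diagnostic region (1-based inclusive, GRCh38)
IAMP21_REGION_START = 25_772_460
IAMP21_REGION_END = 39_428_528
N_REGION_BINS = 24

KDE_BANDWIDTH = 0.03
KDE_GRID_SIZE = 256
SECONDARY_PEAK_MIN_DISTANCE = 0.08
HET_MAF_WINDOW = (0.4, 0.5)
MIN_GENES_PER_CHROM = 5
MIN_SNVS_PER_CHROM = 5

_CHROM_METRIC_SUFFIXES = ("log2fc_wmedian", "log2fc_p05", "log2fc_p95",
                          "maf_peak_primary", "maf_peak_secondary",
                          "maf_density_at_half", "het_fraction")

#: density at 0.5 of a degenerate folded-MAF sample entirely at 0.5
#: (point mass plus its boundary reflection) — the neutral imputation value
NEUTRAL_DENSITY_AT_HALF = float(2.0 / (KDE_BANDWIDTH * np.sqrt(2 * np.pi)))


def _build_feature_names() -> tuple[str, ...]:
    names: list[str] = []
    for chrom in CHROMOSOMES:
        names += [f"chr{chrom}_{s}" for s in _CHROM_METRIC_SUFFIXES]
    names += [f"chr21_region_bin{i:02d}_mean_log2fc"
              for i in range(1, N_REGION_BINS + 1)]
    names.append("genome_log2fc_wmedian")
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _build_feature_names()
assert len(FEATURE_NAMES) == 186

#: features derived from the MAF table (ablating these leaves dosage only)
MAF_FEATURE_NAMES: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES
    if any(n.endswith(s) for s in ("maf_peak_primary", "maf_peak_secondary",
                                   "maf_density_at_half", "het_fraction")))

FEATURE_MANIFEST_HASH = hashlib.sha256(
    "\n".join(FEATURE_NAMES).encode()).hexdigest()


class FeatureError(ValueError):
    """Inputs unusable for feature extraction."""


# --------------------------------------------------------------------------
# weighted order statistics
# --------------------------------------------------------------------------
def weighted_median(values, weights) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half."""
    return weighted_percentile(values, weights, 0.5)


def weighted_percentile(values, weights, q: float) -> float:
    """Weighted q-percentile via the cumulative-weight definition.

    Returns the smallest value v such that the total weight of observations
    <= v reaches q times the total weight.  Zero total weight falls back to
    the unweighted percentile.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise FeatureError("weighted percentile of empty input")
    if (weights < 0).any():
        raise FeatureError("negative weights")
    if weights.sum() == 0:
        weights = np.ones_like(values)
    order = np.argsort(values, kind="stable")
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights)
    idx = int(np.searchsorted(cum, q * cum[-1], side="left"))
    return float(values[min(idx, values.size - 1)])


# --------------------------------------------------------------------------
# folded-MAF density
# --------------------------------------------------------------------------
def maf_density(folded_maf: np.ndarray,
                grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-bandwidth Gaussian KDE of folded MAF on [0, 0.5].

    Mass is reflected at both boundaries (x -> -x and x -> 1 - x) so that
    densities at 0 (LOH) and 0.5 (balanced disomy) are not artificially
    depressed.  Returns (grid, density).
    """
    x = np.asarray(folded_maf, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, 0.5, KDE_GRID_SIZE)
    aug = np.concatenate([x, -x, 1.0 - x])
    z = (grid[:, None] - aug[None, :]) / KDE_BANDWIDTH
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (
        x.size * KDE_BANDWIDTH * np.sqrt(2 * np.pi))
    return grid, dens


def maf_peaks(folded_maf: np.ndarray) -> tuple[float, float]:
    """Primary and secondary folded-MAF density peak positions.

    The primary peak is the global argmax over the density grid; the
    secondary is the highest other local maximum at distance >=
    ``SECONDARY_PEAK_MIN_DISTANCE`` from the primary, or the primary again
    if the density is unimodal.  Grid endpoints count as local maxima.
    """
    grid, dens = maf_density(folded_maf)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    is_max = np.zeros_like(dens, dtype=bool)
    is_max[1:-1] = interior
    is_max[0] = dens[0] >= dens[1]
    is_max[-1] = dens[-1] >= dens[-2]
    peaks = np.flatnonzero(is_max)
    order = peaks[np.argsort(dens[peaks], kind="stable")[::-1]]
    primary = float(grid[order[0]])
    for idx in order[1:]:
        if abs(float(grid[idx]) - primary) >= SECONDARY_PEAK_MIN_DISTANCE:
            return primary, float(grid[idx])
    return primary, primary


# --------------------------------------------------------------------------
# per-chromosome metrics
# --------------------------------------------------------------------------
def chromosome_metrics(dosage: pd.DataFrame, maf: pd.DataFrame,
                       chrom: str) -> dict[str, float]:
    """The 7 named metrics for one chromosome; sparse inputs are imputed."""
    chrom = str(chrom)
    genes = dosage[dosage["chrom"].astype(str) == chrom]
    snvs = maf[maf["chrom"].astype(str) == chrom]
    out: dict[str, float] = {}
    if len(genes) >= MIN_GENES_PER_CHROM:
        vals = genes["log2fc"].to_numpy(float)
        w = genes["weight"].to_numpy(float)
        out["log2fc_wmedian"] = weighted_median(vals, w)
        out["log2fc_p05"] = weighted_percentile(vals, w, 0.05)
        out["log2fc_p95"] = weighted_percentile(vals, w, 0.95)
    else:
        logger.warning("chr%s: %d genes, imputing neutral dosage metrics",
                       chrom, len(genes))
        out["log2fc_wmedian"] = out["log2fc_p05"] = out["log2fc_p95"] = 0.0
    if len(snvs) >= MIN_SNVS_PER_CHROM:
        folded = np.minimum(snvs["maf"].to_numpy(float),
                            1.0 - snvs["maf"].to_numpy(float))
        primary, secondary = maf_peaks(folded)
        out["maf_peak_primary"] = primary
        out["maf_peak_secondary"] = secondary
        _, dens_half = maf_density(folded, grid=np.array([0.5]))
        out["maf_density_at_half"] = float(dens_half[0])
        lo, hi = HET_MAF_WINDOW
        out["het_fraction"] = float(((folded >= lo) & (folded <= hi)).mean())
    else:
        logger.warning("chr%s: %d SNVs, imputing neutral MAF metrics",
                       chrom, len(snvs))
        out["maf_peak_primary"] = out["maf_peak_secondary"] = 0.5
        out["maf_density_at_half"] = NEUTRAL_DENSITY_AT_HALF
        out["het_fraction"] = 1.0
    return out


def chr21_positional_features(dosage: pd.DataFrame) -> np.ndarray:
    """Mean log2FC in 24 equal-width bins across the iAMP21 region.

    Bin edges span chr21:25,772,460-39,428,528 (1-based inclusive); a gene
    belongs to the bin containing its start.  Empty bins are imputed with
    the chromosome-21 weighted median (0 if chr21 is absent).
    """
    genes = dosage[dosage["chrom"].astype(str) == "21"]
    if len(genes):
        fallback = weighted_median(genes["log2fc"].to_numpy(float),
                                   genes["weight"].to_numpy(float))
    else:
        fallback = 0.0
    edges = np.linspace(IAMP21_REGION_START, IAMP21_REGION_END,
                        N_REGION_BINS + 1)
    starts = genes["start"].to_numpy(float)
    log2fc = genes["log2fc"].to_numpy(float)
    out = np.empty(N_REGION_BINS)
    for i in range(N_REGION_BINS):
        if i < N_REGION_BINS - 1:
            mask = (starts >= edges[i]) & (starts < edges[i + 1])
        else:  # last bin closes the interval
            mask = (starts >= edges[i]) & (starts <= edges[i + 1])
        out[i] = log2fc[mask].mean() if mask.any() else fallback
    return out


def extract_features(dosage: pd.DataFrame, maf: pd.DataFrame) -> pd.Series:
    """The full 186-feature vector for one sample (pure and deterministic)."""
    for df, cols, what in ((dosage, ("gene_id", "chrom", "start", "log2fc",
                                     "weight"), "dosage"),
                           (maf, ("chrom", "pos", "depth", "maf"), "MAF")):
        if missing := set(cols) - set(df.columns):
            raise FeatureError(f"{what} table lacks columns {sorted(missing)}")
    values: list[float] = []
    for chrom in CHROMOSOMES:
        metrics = chromosome_metrics(dosage, maf, chrom)
        values += [metrics[s] for s in _CHROM_METRIC_SUFFIXES]
    values += list(chr21_positional_features(dosage))
    values.append(weighted_median(dosage["log2fc"].to_numpy(float),
                                  dosage["weight"].to_numpy(float)))
    vec = pd.Series(values, index=list(FEATURE_NAMES), dtype=float)
    if not np.isfinite(vec.to_numpy()).all():
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise FeatureError(f"non-finite features: {bad}")
    return vec


def compute_log2fc(counts_table: pd.DataFrame,
                   reference_profile: pd.DataFrame) -> pd.DataFrame:
    """Per-gene dosage log2FC from raw counts and a diploid reference profile.

    Convenience path when upstream CNV-caller output is unavailable: the
    sample is library-size normalized so its total matches the reference
    total, then log2fc = log2(normalized count / reference value) and
    weight = log1p(reference value).  Genes absent from the reference (or
    with non-positive reference values) are dropped.
    """
    counts = counts_table.copy()
    counts["chrom"] = counts["chrom"].astype(str)
    ref = reference_profile.set_index("gene_id")["expr"]
    ref = ref[ref > 0]
    counts = counts[counts["gene_id"].isin(ref.index)]
    if counts.empty:
        raise FeatureError("no genes shared with the reference profile")
    scale = float(ref.loc[counts["gene_id"]].sum()) / max(
        float(counts["count"].sum()), 1.0)
    norm = counts["count"].to_numpy(float) * scale
    refv = ref.loc[counts["gene_id"]].to_numpy(float)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(np.maximum(norm, 1e-9) / refv)
    out = pd.DataFrame({"gene_id": counts["gene_id"].to_numpy(),
                        "chrom": counts["chrom"].to_numpy(),
                        "start": counts["start"].to_numpy(int),
                        "log2fc": log2fc,
                        "weight": np.log1p(refv)})
    if out["chrom"].nunique() < len(CHROMOSOMES):
        raise FeatureError(
            f"only {out['chrom'].nunique()} chromosomes represented after "
            f"filtering (need {len(CHROMOSOMES)})")
    return out
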