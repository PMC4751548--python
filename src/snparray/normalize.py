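"""Thresholded quantile normalization (tQN) and BAF/LRR computation.

Infinium arrays report two fluorescence channels per SNP, x for the A allele
and y for the B allele.  After the vendor's affine normalization the data lie
roughly in the unit quadrant with R = x + y near 1.  Two derived tracks are
the standard input to contamination and copy-number analyses:

* **BAF** (B-allele frequency): the angular coordinate
  theta = (2/pi) * arctan(y/x), rescaled piecewise-linearly so that the
  genotype cluster centroids of a reference panel map to exactly 0, 0.5 and 1.
* **LRR** (log-R ratio): log2 of the observed total intensity R over the
  reference intensity R0 expected at the observed theta, interpolated between
  the reference centroids.

For an uncontaminated euploid sample the expected LRR is 0 and the expected
BAF at heterozygous markers is 0.5.

tQN quantile-normalizes the x channel against the y channel *within* each
array to remove dye bias, but caps each normalized value at a multiplicative
threshold (default 1.5) times its raw value so that extreme markers are not
dragged across the plane.  An optional between-array quantile normalization
may precede it.  Reference cluster centroids are estimated after pushing the
reference intensities through the identical normalization chain, so test and
reference samples are always on the same scale.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import (MISSING, GenotypeSet, SNPArrayError, DimensionError)

logger = logging.getLogger(__name__)

#: default multiplicative cap on the within-array quantile normalization
DEFAULT_THRESHOLD = 1.5
#: smallest reference-sample count for a genotype cluster to be trusted
DEFAULT_MIN_CLUSTER_SIZE = 3

CLUSTER_COLUMNS = [
    "theta_AA", "theta_AB", "theta_BB",
    "r_AA", "r_AB", "r_BB",
    "n_AA", "n_AB", "n_BB",
    "imputed_AA", "imputed_AB", "imputed_BB",
]


# ---------------------------------------------------------------------------
# quantile normalization primitives
# ---------------------------------------------------------------------------

def _qn_map(values: np.ndarray, target_sorted: np.ndarray) -> np.ndarray:
    """Map ``values`` onto the sorted target distribution by rank, averaging
    the target over tied ranks."""
    ranks = rankdata(values, method="average")  # 1..n, halves on ties
    return np.interp(ranks, np.arange(1, len(target_sorted) + 1), target_sorted)


def quantile_normalize_between(matrix: np.ndarray) -> np.ndarray:
    """Between-array quantile normalization of one intensity channel.

    Columns are arrays.  Every column is replaced so its sorted values equal
    the mean of the per-rank values across columns; ties map to the average of
    the tied target values.  A single column is returned unchanged (with a
    warning): there is nothing to normalize against.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise DimensionError("expected a 2-D matrix of columns to normalize")
    if matrix.shape[1] < 2:
        warnings.warn("between-array normalization needs >= 2 arrays; returning input")
        return matrix.copy()
    target = np.sort(matrix, axis=0).mean(axis=1)
    out = np.empty_like(matrix)
    for j in range(matrix.shape[1]):
        out[:, j] = _qn_map(matrix[:, j], target)
    return out


def tqn_within(x_col: np.ndarray, y_col: np.ndarray,
               threshold: float = DEFAULT_THRESHOLD):
    """Thresholded within-array quantile normalization of x against y.

    Both channels are mapped by rank onto the mean of the two sorted channels,
    then each normalized value is capped at ``threshold`` times its raw value.
    Exact zeros pass through unchanged.  Returns ``(x_norm, y_norm)``.
    """
    x_col = np.asarray(x_col, dtype=float)
    y_col = np.asarray(y_col, dtype=float)
    if x_col.shape != y_col.shape:
        raise DimensionError("x and y channels differ in length")
    if np.nanmin(x_col, initial=0.0) < 0 or np.nanmin(y_col, initial=0.0) < 0:
        raise SNPArrayError("negative intensities")
    if threshold <= 1:
        raise SNPArrayError(f"threshold must exceed 1, got {threshold}")
    target = 0.5 * (np.sort(x_col) + np.sort(y_col))
    x_norm = np.minimum(_qn_map(x_col, target), threshold * x_col)
    y_norm = np.minimum(_qn_map(y_col, target), threshold * y_col)
    x_norm[x_col == 0] = 0.0
    y_norm[y_col == 0] = 0.0
    return x_norm, y_norm


# ---------------------------------------------------------------------------
# polar coordinates
# ---------------------------------------------------------------------------

def theta_r(x, y):
    """Polar intensity coordinates: theta = (2/pi)*arctan(y/x), R = x + y.

    Uses the two-argument arctangent so x = 0 maps to theta = 1 exactly.
    theta is undefined (NaN) where both channels are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(invalid="ignore"):
        # divide by pi/2 rather than multiply by 2/pi: arctan2 results at the
        # axes and the diagonal then map to exactly 0, 0.5 and 1
        theta = np.arctan2(y, x) / (np.pi / 2.0)
    theta = np.where((x == 0) & (y == 0), np.nan, theta)
    return theta, x + y


def xy_from_theta_r(theta, R):
    """Invert :func:`theta_r`: channel intensities whose polar coordinates are
    exactly (theta, R).  Used by the intensity simulator."""
    theta = np.asarray(theta, dtype=float)
    R = np.asarray(R, dtype=float)
    ang = theta * (np.pi / 2.0)
    c, s = np.cos(ang), np.sin(ang)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = R * c / (c + s)
    # pin the exact anchors: the diagonal and the two axes must round-trip
    # through theta_r bit-exactly
    x = np.where(theta == 0.5, 0.5 * R, x)
    x = np.where(theta == 0.0, R, x)
    x = np.where(theta == 1.0, 0.0, x)
    y = R - x  # guarantees x + y == R to the last bit
    return x, y


# ---------------------------------------------------------------------------
# reference clusters
# ---------------------------------------------------------------------------

def _apply_chain(gset: GenotypeSet, threshold: float, prenormalize: bool):
    """The tQN intensity chain shared by cluster estimation and tqn()."""
    x = np.array(gset.x, dtype=float)
    y = np.array(gset.y, dtype=float)
    if prenormalize and gset.n_samples >= 2:
        x = quantile_normalize_between(x)
        y = quantile_normalize_between(y)
    for j in range(gset.n_samples):
        x[:, j], y[:, j] = tqn_within(x[:, j], y[:, j], threshold)
    return theta_r(x, y) + (x, y)


def estimate_clusters(
    reference: GenotypeSet,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    threshold: float = DEFAULT_THRESHOLD,
    prenormalize: bool = False,
    provenance: str = "reference",
) -> pd.DataFrame:
    """Estimate per-marker genotype-conditional (theta, R) centroids from a
    reference panel.

    The reference intensities are first pushed through the same normalization
    chain applied by :func:`tqn` (so centroids live on the normalized scale);
    the centroid of each genotype class is the median theta and median R of
    the reference samples carrying that call.  Classes backed by fewer than
    ``min_cluster_size`` samples are imputed and flagged:

    * missing heterozygote: theta midpoint of the flanking homozygotes, R
      their mean;
    * one missing homozygote: mirror of the other about theta = 0.5, same R;
    * both homozygotes missing: placed symmetrically about the heterozygote.

    Markers with no usable class at all, or whose centroids are not monotone
    in theta, are excluded (all-NaN rows) and later receive missing BAF/LRR.

    On the sex chromosomes the centroids are estimated from the appropriate
    diploid/hemizygous subset when sex metadata is available: X from female
    reference samples, Y from males.  This keeps X centroids on the diploid
    intensity scale so that hemizygous male samples show their reduced-R
    signature instead of dragging the reference level down.
    """
    if reference.x is None or reference.y is None:
        raise SNPArrayError("reference set has no x/y intensities")
    theta, R, _, _ = _apply_chain(reference, threshold, prenormalize)

    sex = reference.samples["sex"].to_numpy()
    females = sex == "female"
    males = sex == "male"
    chrom = reference.markers["chrom"].str.upper().to_numpy()

    col_ok = np.ones((reference.n_markers, reference.n_samples), dtype=bool)
    if females.any():
        col_ok[np.ix_(chrom == "X", ~females)] = False
    if males.any():
        col_ok[np.ix_(chrom == "Y", ~males)] = False

    stats = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN medians
        for g, label in ((0, "AA"), (1, "AB"), (2, "BB")):
            mask = (reference.calls == g) & col_ok
            t = np.where(mask, theta, np.nan)
            r = np.where(mask, R, np.nan)
            stats[f"theta_{label}"] = np.nanmedian(t, axis=1)
            stats[f"r_{label}"] = np.nanmedian(r, axis=1)
            stats[f"n_{label}"] = mask.sum(axis=1)

    tab = pd.DataFrame(stats, index=reference.marker_names)
    for label in ("AA", "AB", "BB"):
        thin = tab[f"n_{label}"] < min_cluster_size
        tab.loc[thin, [f"theta_{label}", f"r_{label}"]] = np.nan
        tab[f"imputed_{label}"] = thin

    _impute_clusters(tab)
    _drop_nonmonotone(tab)
    tab = tab[CLUSTER_COLUMNS]
    tab.attrs["provenance"] = provenance
    tab.attrs["threshold"] = threshold
    tab.attrs["min_cluster_size"] = min_cluster_size
    return tab


def _impute_clusters(tab: pd.DataFrame) -> None:
    tAA, tAB, tBB = (tab["theta_AA"], tab["theta_AB"], tab["theta_BB"])
    rAA, rAB, rBB = (tab["r_AA"], tab["r_AB"], tab["r_BB"])

    # one missing homozygote: mirror the other about theta = 0.5
    aa_gap = tAA.isna() & tBB.notna()
    tab.loc[aa_gap, "theta_AA"] = 1.0 - tBB[aa_gap]
    tab.loc[aa_gap, "r_AA"] = rBB[aa_gap]
    bb_gap = tBB.isna() & tab["theta_AA"].notna() & ~aa_gap
    tab.loc[bb_gap, "theta_BB"] = 1.0 - tab.loc[bb_gap, "theta_AA"]
    tab.loc[bb_gap, "r_BB"] = tab.loc[bb_gap, "r_AA"]

    # both homozygotes missing: symmetric about the observed heterozygote
    only_het = tab["theta_AA"].isna() & tab["theta_BB"].isna() & tAB.notna()
    tab.loc[only_het, "theta_AA"] = 0.5 * tAB[only_het]
    tab.loc[only_het, "theta_BB"] = 0.5 * (1.0 + tAB[only_het])
    tab.loc[only_het, "r_AA"] = rAB[only_het]
    tab.loc[only_het, "r_BB"] = rAB[only_het]

    # missing heterozygote: midpoint of the flanking homozygotes
    het_gap = tab["theta_AB"].isna() & tab["theta_AA"].notna() & tab["theta_BB"].notna()
    tab.loc[het_gap, "theta_AB"] = 0.5 * (tab.loc[het_gap, "theta_AA"]
                                          + tab.loc[het_gap, "theta_BB"])
    tab.loc[het_gap, "r_AB"] = 0.5 * (tab.loc[het_gap, "r_AA"]
                                      + tab.loc[het_gap, "r_BB"])


def _drop_nonmonotone(tab: pd.DataFrame) -> None:
    bad = ((tab["theta_AA"] > tab["theta_AB"]) | (tab["theta_AB"] > tab["theta_BB"]))
    bad = bad.fillna(False)
    if bad.any():
        logger.warning("%d markers with non-monotone cluster centroids excluded",
                       int(bad.sum()))
        tab.loc[bad, ["theta_AA", "theta_AB", "theta_BB",
                      "r_AA", "r_AB", "r_BB"]] = np.nan


# ---------------------------------------------------------------------------
# BAF / LRR
# ---------------------------------------------------------------------------

def baf_from_theta(theta, theta_AA, theta_AB, theta_BB):
    """Piecewise-linear BAF anchored at the cluster centroids.

    theta <= theta_AA maps to 0, theta >= theta_BB maps to 1 and theta_AB maps
    to exactly 0.5, with linear interpolation between anchors.  Degenerate
    clusters (coincident anchors) yield NaN for interior thetas.  Arguments
    broadcast, so per-marker anchors may be column vectors against a
    markers x samples theta matrix.
    """
    theta = np.asarray(theta, dtype=float)
    theta_AA = np.asarray(theta_AA, dtype=float)
    theta_AB = np.asarray(theta_AB, dtype=float)
    theta_BB = np.asarray(theta_BB, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lower = 0.5 * (theta - theta_AA) / (theta_AB - theta_AA)
        upper = 0.5 + 0.5 * (theta - theta_AB) / (theta_BB - theta_AB)
        baf = np.where(theta < theta_AB, lower, upper)
        baf = np.where(theta <= theta_AA, 0.0, baf)
        baf = np.where(theta >= theta_BB, 1.0, baf)
        baf = np.where(theta == theta_AB, 0.5, baf)
        # coincident anchors leave the interior interpolation undefined
        degenerate = (theta_AA == theta_AB) | (theta_AB == theta_BB)
        interior = (theta > theta_AA) & (theta < theta_BB)
        baf = np.where(degenerate & interior, np.nan, baf)
    baf = np.where(np.isnan(theta) | np.isnan(theta_AA) | np.isnan(theta_AB)
                   | np.isnan(theta_BB), np.nan, baf)
    return baf


def lrr_from_r(theta, R, theta_AA, theta_AB, theta_BB, r_AA, r_AB, r_BB):
    """log2 ratio of observed total intensity to the reference level R0.

    R0 is the linear interpolation of (theta_g, r_g) over the three genotype
    centroids at the observed theta, clamped to the outer centroids beyond
    them (no extrapolation).  Missing where R <= 0 or R0 <= 0.
    """
    theta = np.asarray(theta, dtype=float)
    R = np.asarray(R, dtype=float)
    args = [np.asarray(a, dtype=float)
            for a in (theta_AA, theta_AB, theta_BB, r_AA, r_AB, r_BB)]
    theta_AA, theta_AB, theta_BB, r_AA, r_AB, r_BB = args
    with np.errstate(invalid="ignore", divide="ignore"):
        low = r_AA + (r_AB - r_AA) * (theta - theta_AA) / (theta_AB - theta_AA)
        high = r_AB + (r_BB - r_AB) * (theta - theta_AB) / (theta_BB - theta_AB)
        r0 = np.where(theta < theta_AB, low, high)
        r0 = np.where(theta <= theta_AA, r_AA, r0)
        r0 = np.where(theta >= theta_BB, r_BB, r0)
        r0 = np.where(theta == theta_AB, r_AB, r0)
        lrr = np.log2(R / r0)
    lrr = np.where((R <= 0) | (r0 <= 0) | np.isnan(theta) | np.isnan(r0),
                   np.nan, lrr)
    return lrr


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def tqn(
    gset: GenotypeSet,
    cluster_table: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    prenormalize: bool = False,
) -> GenotypeSet:
    """Run the full tQN pipeline and attach BAF/LRR tracks.

    Optional between-array quantile normalization per channel, then per-sample
    thresholded within-array normalization, polar transformation, and BAF/LRR
    against ``cluster_table``.  Markers absent from the cluster table (or with
    excluded centroids) get missing BAF/LRR.  Returns a new GenotypeSet with
    normalized x/y and the ``normalized`` flag set.
    """
    if gset.x is None or gset.y is None:
        raise SNPArrayError("tQN requires x/y intensities")
    theta, R, x, y = _apply_chain(gset, threshold, prenormalize)

    clusters = cluster_table.reindex(gset.marker_names)
    col = lambda name: clusters[name].to_numpy()[:, None]
    baf = baf_from_theta(theta, col("theta_AA"), col("theta_AB"), col("theta_BB"))
    lrr = lrr_from_r(theta, R,
                     col("theta_AA"), col("theta_AB"), col("theta_BB"),
                     col("r_AA"), col("r_AB"), col("r_BB"))
    out = gset.copy()
    out.x, out.y, out.baf, out.lrr = x, y, np.clip(baf, 0.0, 1.0), lrr
    out.normalized = True
    return out


def normalized_tracks(gset: GenotypeSet) -> pd.DataFrame:
    """Long-format (marker, chrom, pos, sample, baf, lrr) table of the
    normalized tracks, the layout downstream CNV callers consume."""
    if gset.baf is None or gset.lrr is None:
        raise SNPArrayError("no normalized tracks present; run tqn() first")
    m, s = gset.shape
    return pd.DataFrame({
        "marker": np.repeat(gset.marker_names.to_numpy(), s),
        "chrom": np.repeat(gset.markers["chrom"].to_numpy(), s),
        "pos": np.repeat(gset.markers["pos"].to_numpy(), s),
        "sample": np.tile(gset.sample_ids.to_numpy(), m),
        "baf": gset.baf.ravel(),
        "lrr": gset.lrr.ravel(),
    })
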