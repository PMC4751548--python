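"""Per-sample quality control: call-distribution and intensity summaries,
sex inference from the sex chromosomes, and threshold-based flagging.

Failed arrays show aberrant intensity distributions and/or an excess of
missing and heterozygous calls, so those are the statistics summarized here.
Heterozygosity and missingness thresholds apply to raw per-array counts
(rates are reported alongside).  Sex is inferred from X-chromosome
heterozygosity (males are hemizygous, so their X het rate is near zero) and,
when intensities are present, from median total intensity over Y probes
(females have only background signal there).  Discordance between inferred
and recorded sex is a classic flag for sample swaps and contamination.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .core import (MISSING, PSEUDOAUTOSOMAL, GenotypeSet, SNPArrayError,
                   genotype_counts)

logger = logging.getLogger(__name__)

#: X het rate below this is called male (hemizygous X)
DEFAULT_X_HET_THRESHOLD = 0.1
#: median Y-probe intensity above this indicates a Y chromosome; midway
#: between background (~0.1) and hemizygous male signal (~0.5)
DEFAULT_Y_INTENSITY_THRESHOLD = 0.3


def sample_qc(
    gset: GenotypeSet,
    x_het_threshold: float = DEFAULT_X_HET_THRESHOLD,
    y_intensity_threshold: float = DEFAULT_Y_INTENSITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample QC statistics.

    Returns one row per sample: genotype-class counts and call rate; median
    and IQR of total intensity R = x + y (only when intensities are present);
    X heterozygosity and median Y intensity; inferred sex and concordance
    with the sample table; and a flag column initialized to "pass" (see
    :func:`flag_samples`).
    """
    counts = genotype_counts(gset, axis="sample")
    n_m = gset.n_markers
    qc = pd.DataFrame(index=gset.sample_ids)
    qc["n_missing"] = counts["n_missing"]
    qc["n_het"] = counts["n_het"]
    qc["n_hom"] = counts["n_refhom"] + counts["n_althom"]
    qc["call_rate"] = 1.0 - counts["n_missing"] / n_m if n_m else np.nan

    if gset.x is not None and gset.y is not None:
        R = gset.x + gset.y
        qc["intensity_median"] = np.nanmedian(R, axis=0)
        q75, q25 = np.nanpercentile(R, [75, 25], axis=0)
        qc["intensity_iqr"] = q75 - q25

    sex = infer_sex(gset, x_het_threshold, y_intensity_threshold)
    qc = qc.join(sex)
    qc["flag"] = "pass"
    return qc


def infer_sex(
    gset: GenotypeSet,
    x_het_threshold: float = DEFAULT_X_HET_THRESHOLD,
    y_intensity_threshold: float = DEFAULT_Y_INTENSITY_THRESHOLD,
) -> pd.DataFrame:
    """Infer each sample's sex from sex-chromosome calls and intensities.

    male iff X het rate < ``x_het_threshold`` and, when Y intensity evidence
    exists, it exceeds ``y_intensity_threshold``; female iff X het rate is at
    or above the threshold and Y evidence is absent or low; otherwise (the
    two lines of evidence conflict) unknown.  Pseudoautosomal ("XY") markers
    are excluded from the X het rate.  Returns columns x_het_rate,
    y_intensity, inferred_sex, sex_concordant.
    """
    chrom = gset.markers["chrom"].str.upper()
    x_mask = (chrom == "X").to_numpy() & ~(chrom == PSEUDOAUTOSOMAL).to_numpy()
    y_mask = (chrom == "Y").to_numpy()
    n = gset.n_samples
    out = pd.DataFrame(index=gset.sample_ids)

    if not x_mask.any():
        warnings.warn("no X-chromosome markers: sex cannot be inferred")
        out["x_het_rate"] = np.nan
        out["y_intensity"] = np.nan
        out["inferred_sex"] = "unknown"
        out["sex_concordant"] = "unknown"
        return out

    xc = gset.calls[x_mask]
    non_missing = (xc != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore"):
        x_het = np.where(non_missing > 0,
                         (xc == 1).sum(axis=0) / np.maximum(non_missing, 1),
                         np.nan)
    out["x_het_rate"] = x_het

    y_int = np.full(n, np.nan)
    if y_mask.any() and gset.x is not None and gset.y is not None:
        R = gset.x[y_mask] + gset.y[y_mask]
        y_int = np.nanmedian(R, axis=0)
    out["y_intensity"] = y_int

    inferred = np.full(n, "unknown", dtype=object)
    has_y = ~np.isnan(y_int)
    y_high = has_y & (y_int > y_intensity_threshold)
    male_x = ~np.isnan(x_het) & (x_het < x_het_threshold)
    female_x = ~np.isnan(x_het) & (x_het >= x_het_threshold)
    inferred[male_x & (~has_y | y_high)] = "male"
    inferred[female_x & (~has_y | ~y_high)] = "female"
    out["inferred_sex"] = inferred

    recorded = gset.samples["sex"].to_numpy()
    concordant = np.full(n, "unknown", dtype=object)
    known = (recorded != "unknown") & (inferred != "unknown")
    concordant[known] = np.where(recorded[known] == inferred[known], "yes", "no")
    out["sex_concordant"] = concordant
    return out


def flag_samples(
    qc_table: pd.DataFrame,
    thresholds: dict,
    gset: Optional[GenotypeSet] = None,
    group_by: Optional[str] = None,
) -> pd.DataFrame:
    """Apply pass/fail thresholds to a QC table, optionally per subgroup.

    ``thresholds`` maps threshold names to limits: ``max_missing``,
    ``max_het`` (counts), ``min_intensity`` / ``max_intensity`` (median R
    bounds).  With ``group_by`` (a sample-table column in ``gset``),
    ``thresholds`` instead maps group labels to such dicts; samples in
    unmentioned groups are not tested, and a threshold dict naming an unknown
    group is an error.  A sample fails iff any applicable threshold is
    violated.  Flags are written to the returned copy of the QC table and,
    when ``gset`` is given, back into its sample table (column qc_flag).

    Relaxing any threshold can only turn fails into passes (monotonicity).
    """
    qc = qc_table.copy()
    if group_by is None:
        groups = {None: qc.index}
        thresholds = {None: thresholds}
    else:
        if gset is None:
            raise SNPArrayError("group_by requires the GenotypeSet for metadata")
        labels = gset.samples[group_by].reindex(qc.index)
        known = set(labels.dropna().astype(str))
        unknown = set(map(str, thresholds)) - known
        if unknown:
            raise SNPArrayError(f"thresholds name unknown groups: {sorted(unknown)}")
        groups = {g: qc.index[(labels.astype(str) == str(g)).to_numpy()]
                  for g in thresholds}

    fail = pd.Series(False, index=qc.index)
    checks = {
        "max_missing": ("n_missing", "gt"),
        "max_het": ("n_het", "gt"),
        "min_intensity": ("intensity_median", "lt"),
        "max_intensity": ("intensity_median", "gt"),
    }
    for g, limits in thresholds.items():
        idx = groups[g]
        for name, limit in limits.items():
            if name not in checks:
                raise SNPArrayError(f"unknown threshold {name!r}")
            col, op = checks[name]
            if col not in qc.columns:
                raise SNPArrayError(f"QC table lacks column {col!r} for {name!r}")
            vals = qc.loc[idx, col]
            viol = vals > limit if op == "gt" else vals < limit
            fail.loc[idx] |= viol.fillna(False)

    qc["flag"] = np.where(fail, "fail", "pass")
    if gset is not None:
        gset.samples.loc[qc.index, "qc_flag"] = qc["flag"]
    return qc


def qc_summary_data(gset: GenotypeSet, n_bins: int = 50):
    """Plot-ready data behind the QC summary figure.

    Returns ``(call_dist, density)``: per-sample genotype-class counts
    ordered by n_missing (descending, worst first) with the current qc_flag
    attached, and — when intensities are present — a bins x samples histogram
    of total intensity R whose mass sums to n_markers * n_samples (DataFrame
    with the bin mid-points as index; None otherwise).
    """
    call_dist = genotype_counts(gset, axis="sample")
    call_dist["qc_flag"] = gset.samples["qc_flag"]
    call_dist = call_dist.sort_values("n_missing", ascending=False)

    density = None
    if gset.x is not None and gset.y is not None:
        R = gset.x + gset.y
        finite = R[np.isfinite(R)]
        lo, hi = (float(finite.min()), float(finite.max())) if finite.size else (0, 1)
        edges = np.linspace(lo, hi + 1e-9, n_bins + 1)
        hist = np.stack([np.histogram(np.nan_to_num(R[:, j], nan=lo),
                                      bins=edges)[0]
                         for j in range(gset.n_samples)], axis=1)
        density = pd.DataFrame(hist, index=0.5 * (edges[:-1] + edges[1:]),
                               columns=gset.sample_ids)
    return call_dist, density
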