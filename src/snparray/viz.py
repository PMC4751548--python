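"""Plot-ready data for the package's standard figures.

Every function here returns deterministic tabular data (cluster plots,
genotype dotplots, BAF/LRR tracks with a running-median smoother, and one- /
two-locus mosaic plots of genotype frequency against phenotype); rendering is
a thin optional layer so the scientific content stays testable.  The display
convention for dotplots flips the internal B-allele dosage to counts of the
reference (A) allele.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeSet, SNPArrayError, subset

DEFAULT_SMOOTH_WINDOW = 31


def cluster_plot_data(gset: GenotypeSet, marker: str) -> pd.DataFrame:
    """Per-sample (x, y, call, qc_flag) records for one marker's cluster plot."""
    if gset.x is None or gset.y is None:
        raise SNPArrayError("cluster plots require x/y intensities")
    if marker not in gset.marker_names:
        raise SNPArrayError(f"unknown marker {marker!r}")
    i = gset.marker_names.get_loc(marker)
    return pd.DataFrame({
        "sample": gset.sample_ids,
        "x": gset.x[i],
        "y": gset.y[i],
        "call": gset.calls[i],
        "qc_flag": gset.samples["qc_flag"].to_numpy(),
    })


def dotplot_data(gset: GenotypeSet, region: Tuple[str, int, int]) -> pd.DataFrame:
    """Long-format grid for a genotype dotplot over a genomic region.

    Markers get constant integer spacing (index 1..k) alongside their true
    Mbp positions for the physical-position guide lines.  ``dosage_ref`` is
    the displayed count of the reference (A) allele, 2 - B-dosage; missing
    calls are NaN (blank cells).  An empty region yields an empty frame.
    """
    sub = subset(gset, markers=region)
    rows = []
    for idx in range(sub.n_markers):
        d = sub.calls[idx].astype(float)
        d[d == MISSING] = np.nan
        rows.append(pd.DataFrame({
            "marker": sub.marker_names[idx],
            "marker_index": idx + 1,
            "pos_Mbp": sub.markers["pos"].iat[idx] / 1e6,
            "sample": sub.sample_ids,
            "dosage_ref": 2.0 - d,
        }))
    if not rows:
        return pd.DataFrame(columns=["marker", "marker_index", "pos_Mbp",
                                     "sample", "dosage_ref"])
    return pd.concat(rows, ignore_index=True)


def running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running median; edge windows shrink, NaNs are skipped.
    ``window`` must be odd."""
    if window < 1 or window % 2 == 0:
        raise SNPArrayError(f"smooth window must be odd and positive, got {window}")
    half = window // 2
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    for i in range(values.size):
        seg = values[max(0, i - half):i + half + 1]
        seg = seg[~np.isnan(seg)]
        if seg.size:
            out[i] = np.median(seg)
    return out


def baf_lrr_track(gset: GenotypeSet, sample: str,
                  smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> pd.DataFrame:
    """Per-marker (chrom, pos, baf, lrr) for one sample with running-median
    smoother columns (baf_smooth, lrr_smooth), smoothed within chromosomes."""
    if gset.baf is None or gset.lrr is None:
        raise SNPArrayError(f"sample {sample!r} has no normalized tracks; "
                            "run tqn() first")
    if sample not in gset.sample_ids:
        raise SNPArrayError(f"unknown sample {sample!r}")
    j = gset.sample_ids.get_loc(sample)
    track = pd.DataFrame({
        "marker": gset.marker_names,
        "chrom": gset.markers["chrom"].to_numpy(),
        "pos": gset.markers["pos"].to_numpy(),
        "baf": gset.baf[:, j],
        "lrr": gset.lrr[:, j],
    })
    for col in ("baf", "lrr"):
        track[f"{col}_smooth"] = np.concatenate([
            running_median(grp[col].to_numpy(), smooth_window)
            for _, grp in track.groupby("chrom", sort=False)])
    return track


def mosaic_data(gset: GenotypeSet, markers: Sequence[str],
                phenotype: Optional[Union[str, Sequence]] = "phenotype"):
    """Blocks for a one- or two-locus mosaic plot.

    One marker: per-genotype ``width`` = frequency among non-missing calls.
    Two markers: per genotype pair, ``area`` = joint frequency.  ``fill`` is
    the phenotype mean over the block's samples for numeric phenotypes, or
    per-level proportions for categorical ones.  Missing genotypes are
    excluded and counted in the frame's ``attrs["n_excluded"]``.
    """
    if not 1 <= len(markers) <= 2:
        raise SNPArrayError("mosaic plots use one or two markers")
    phen = (gset.samples[phenotype] if isinstance(phenotype, str)
            else pd.Series(np.asarray(phenotype), index=gset.sample_ids))
    if phen.isna().all():
        raise SNPArrayError("phenotype is entirely missing")
    numeric = pd.api.types.is_numeric_dtype(phen)

    genos = []
    for m in markers:
        if m not in gset.marker_names:
            raise SNPArrayError(f"unknown marker {m!r}")
        genos.append(gset.calls[gset.marker_names.get_loc(m)])
    ok = np.all([g != MISSING for g in genos], axis=0)
    if not ok.any():
        raise SNPArrayError("all genotypes missing at the requested markers")

    df = pd.DataFrame({f"g{i}": g[ok] for i, g in enumerate(genos)})
    df["phen"] = phen.to_numpy()[ok]
    keys = [f"g{i}" for i in range(len(markers))]
    grouped = df.groupby(keys)
    out = grouped.size().rename("count").reset_index()
    weight_col = "width" if len(markers) == 1 else "area"
    out[weight_col] = out["count"] / out["count"].sum()
    if numeric:
        out["fill"] = grouped["phen"].mean().to_numpy()
    else:
        levels = pd.unique(df["phen"].dropna())
        props = (df.groupby(keys)["phen"]
                 .value_counts(normalize=True).unstack(fill_value=0.0))
        for lv in levels:
            out[f"prop_{lv}"] = props[lv].to_numpy()
    out.attrs["n_excluded"] = int((~ok).sum())
    return out


def render_figure(data: pd.DataFrame, kind: str, path) -> None:
    """Minimal optional rendering of any of the data frames above to a file.

    Carries no contract beyond writing a figure; requires matplotlib.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    if kind == "cluster":
        for call, grp in data.groupby("call"):
            ax.scatter(grp["x"], grp["y"], s=12, label=f"call {call}")
        ax.set_xlabel("x intensity"); ax.set_ylabel("y intensity"); ax.legend()
    elif kind == "baflrr":
        ax.plot(data["pos"] / 1e6, data["baf"], ".", ms=2)
        ax.plot(data["pos"] / 1e6, data["baf_smooth"], "r-", lw=1)
        ax.set_ylabel("BAF"); ax.set_xlabel("position (Mbp)")
    else:
        data.plot(ax=ax)
    fig.savefig(path, dpi=100)
    plt.close(fig)
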