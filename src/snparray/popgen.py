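"""Population-genetic summaries: allele frequencies, identity-by-state
distance, hierarchical clustering order, PCA of the genotype matrix, and
Mendelian-inconsistency checks for pedigree validation.

IBS sharing between two individuals at one biallelic marker is the fraction
of their four allele comparisons that match, which for B-allele dosages
d_i, d_j reduces to (2 - |d_i - d_j|) / 2; genetic distance is one minus the
sharing proportion averaged over jointly called markers.  Hierarchically
clustering that distance matrix puts closely related samples adjacent, the
ordering used by kinship heatmaps; PCA of the (mean-imputed, centered)
genotype matrix exposes the same population structure as point clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import MISSING, GenotypeSet, SNPArrayError

logger = logging.getLogger(__name__)


def allele_freqs(gset: GenotypeSet) -> pd.DataFrame:
    """Per-marker B-allele frequency, heterozygote rate and missing rate.

    freq = (sum of B dosages) / (2 * number of non-missing calls); markers
    with no calls get NaN.
    """
    calls = gset.calls
    non_missing = (calls != MISSING).sum(axis=1)
    b_sum = np.where(calls == MISSING, 0, calls).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(non_missing > 0, b_sum / (2.0 * non_missing), np.nan)
        het = np.where(non_missing > 0,
                       (calls == 1).sum(axis=1) / np.maximum(non_missing, 1),
                       np.nan)
    n = gset.n_samples
    return pd.DataFrame({
        "freq_B": freq,
        "het_rate": het,
        "missing_rate": (calls == MISSING).sum(axis=1) / n if n else np.nan,
    }, index=gset.marker_names)


@dataclass
class DistanceMatrix:
    """Pairwise IBS distances with per-pair joint coverage.

    values: n x n symmetric matrix, zero diagonal, entries NaN where the
    jointly non-missing marker count falls below the min_overlap used.
    """
    values: np.ndarray
    ids: pd.Index
    n_shared: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def ibs_distance(gset: GenotypeSet, min_overlap: int = 1) -> DistanceMatrix:
    """IBS distance matrix: 1 - mean allele-sharing over jointly called markers.

    Pairs sharing fewer than ``min_overlap`` markers get a missing entry.
    """
    if gset.n_samples < 2:
        raise SNPArrayError("need at least two samples for pairwise distances")
    calls = gset.calls.astype(np.int16)
    present = calls != MISSING
    n = gset.n_samples
    dist = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = present[:, i, None] & present[:, i:]
        diff = np.abs(calls[:, i, None] - calls[:, i:])
        diff = np.where(both, diff, 0)
        cnt = both.sum(axis=0)
        with np.errstate(invalid="ignore"):
            d = np.where(cnt > 0, diff.sum(axis=0) / (2.0 * cnt), np.nan)
        dist[i, i:] = d
        dist[i:, i] = d
        shared[i, i:] = cnt
        shared[i:, i] = cnt
    np.fill_diagonal(dist, 0.0)
    dist[shared < min_overlap] = np.nan
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(values=dist, ids=gset.sample_ids, n_shared=shared)


def ibs_sharing(gset: GenotypeSet, min_overlap: int = 1) -> DistanceMatrix:
    """Complementary view: proportion of alleles shared identical by state."""
    d = ibs_distance(gset, min_overlap)
    return DistanceMatrix(values=1.0 - d.values, ids=d.ids, n_shared=d.n_shared)


def hclust_order(dist: DistanceMatrix, method: str = "average"):
    """Agglomerative clustering of a complete distance matrix.

    Returns ``(leaf_order, linkage)``: sample ids in heatmap display order and
    the scipy linkage (merge history).  Missing entries are an error — relax
    min_overlap or drop sparse samples first.
    """
    vals = dist.values
    if np.isnan(vals).any():
        raise SNPArrayError(
            "distance matrix has missing entries; relax min_overlap")
    Z = hierarchy.linkage(squareform(vals, checks=False), method=method)
    order = hierarchy.leaves_list(Z)
    return dist.ids[order], Z


def pca_genotypes(gset: GenotypeSet, k: int = 2, scale: bool = False):
    """Project samples onto the top ``k`` principal components of the
    genotype matrix.

    Missing calls are mean-imputed per marker and markers are centered;
    with ``scale`` each marker is additionally divided by its binomial
    dosage standard deviation sqrt(2 p (1 - p)).  Returns
    ``(projections, var_explained)``: a samples x k DataFrame and the
    fraction of total variance per component (non-increasing, summing to at
    most 1).  The sign of each component is fixed by making its
    largest-magnitude marker loading positive.
    """
    n_m, n_s = gset.shape
    if not 1 <= k <= min(n_m, n_s):
        raise SNPArrayError(f"k={k} out of range for a {n_m} x {n_s} matrix")
    X = gset.calls.astype(float)
    X[gset.calls == MISSING] = np.nan
    means = np.nanmean(X, axis=1, keepdims=True)
    means = np.nan_to_num(means, nan=0.0)  # all-missing markers contribute 0
    X = np.where(np.isnan(X), means, X) - means
    if scale:
        p = np.clip(means / 2.0, 1e-6, 1 - 1e-6)
        X /= np.sqrt(2.0 * p * (1.0 - p))
    total_var = float((X ** 2).sum())
    if total_var == 0:
        raise SNPArrayError("genotype matrix has zero variance")
    # SVD of markers x samples: right singular vectors are sample coordinates
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    proj = (Vt.T * S) * flip
    var_explained = S ** 2 / total_var
    cols = [f"PC{i + 1}" for i in range(k)]
    return (pd.DataFrame(proj[:, :k], index=gset.sample_ids, columns=cols),
            var_explained[:k])


# ---------------------------------------------------------------------------
# Mendelian checks
# ---------------------------------------------------------------------------

def _gametes(dosage: int):
    return {0: (0,), 1: (0, 1), 2: (1,)}[dosage]


def _trio_consistent(kid: int, dad: int, mom: int) -> bool:
    """Autosomal rule: offspring dosage must be producible as one paternal
    plus one maternal gamete; an unknown (missing) parent contributes any
    allele."""
    dads = _gametes(dad) if dad != MISSING else (0, 1)
    moms = _gametes(mom) if mom != MISSING else (0, 1)
    return any(a + b == kid for a in dads for b in moms)


def _build_tables():
    trio = np.zeros((3, 4, 4), dtype=bool)  # kid x (dad+1 offset) x (mom+1)
    for kid in range(3):
        for dad in (MISSING, 0, 1, 2):
            for mom in (MISSING, 0, 1, 2):
                trio[kid, dad + 1, mom + 1] = _trio_consistent(kid, dad, mom)
    return trio


_TRIO_OK = _build_tables()


def mendel_check(gset: GenotypeSet,
                 trios: Optional[Sequence[Tuple[str, str, str]]] = None
                 ) -> pd.DataFrame:
    """Count Mendelian inconsistencies per (offspring, father, mother) trio.

    Trios default to the sample table's father/mother fields (offspring with
    at least one named, present parent).  A marker is tested when the
    offspring and at least one parent are called; it is inconsistent iff the
    offspring dosage is impossible under biallelic inheritance given the
    called parents (single-parent duos use the weaker shared-allele rule).
    On the X chromosome male offspring are hemizygous: their call (0 or 2)
    must match a maternal allele, the father is ignored, and a heterozygous
    male X call is itself inconsistent.  Y and pseudoautosomal markers are
    not tested.  Returns n_tested / n_inconsistent / inconsistency_rate per
    trio; trios referencing absent samples are skipped with a warning.
    """
    samples = gset.samples
    if trios is None:
        trios = []
        for kid, row in samples.iterrows():
            father = row["father"] if row["father"] != "0" else None
            mother = row["mother"] if row["mother"] != "0" else None
            if father or mother:
                trios.append((kid, father or "0", mother or "0"))
    ids = gset.sample_ids
    chrom = gset.markers["chrom"].str.upper().to_numpy()
    is_x = chrom == "X"
    testable = ~np.isin(chrom, ("Y", "XY", "M", "MT"))

    rows = []
    for kid, dad, mom in trios:
        if kid not in ids or (dad != "0" and dad not in ids) \
                or (mom != "0" and mom not in ids):
            logger.warning("trio (%s, %s, %s) references absent samples; skipped",
                           kid, dad, mom)
            continue
        kcal = gset.calls[:, ids.get_loc(kid)].astype(int)
        dcal = (gset.calls[:, ids.get_loc(dad)].astype(int)
                if dad != "0" else np.full_like(kcal, MISSING))
        mcal = (gset.calls[:, ids.get_loc(mom)].astype(int)
                if mom != "0" else np.full_like(kcal, MISSING))
        kid_male = samples.loc[kid, "sex"] == "male"

        tested = testable & (kcal != MISSING) \
            & ((dcal != MISSING) | (mcal != MISSING))
        ok = np.ones_like(tested)
        auto = tested & ~is_x
        ok[auto] = _TRIO_OK[kcal[auto], dcal[auto] + 1, mcal[auto] + 1]
        xm = tested & is_x
        if xm.any():
            if kid_male:
                # hemizygous offspring: call must be 0/2 and match a maternal
                # allele; the father contributes no X to sons
                tested[xm] = mcal[xm] != MISSING
                ok[xm] = np.array(
                    [m == MISSING or (k != 1 and (k // 2) in _gametes(m))
                     for k, m in zip(kcal[xm], mcal[xm])])
            else:
                # female offspring: the hemizygous father passes his one
                # allele; a heterozygous paternal X call is uninformative
                dx = dcal[xm].copy()
                dx[dx == 1] = MISSING
                ok[xm] = _TRIO_OK[kcal[xm], dx + 1, mcal[xm] + 1]
                tested[xm] = (dx != MISSING) | (mcal[xm] != MISSING)
        n_tested = int(tested.sum())
        n_bad = int((tested & ~ok).sum())
        rows.append(dict(offspring=kid, father=dad, mother=mom,
                         n_tested=n_tested, n_inconsistent=n_bad,
                         inconsistency_rate=(n_bad / n_tested
                                             if n_tested else np.nan)))
    return pd.DataFrame(rows, columns=["offspring", "father", "mother",
                                       "n_tested", "n_inconsistent",
                                       "inconsistency_rate"])
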