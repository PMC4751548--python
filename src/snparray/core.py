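"""Core container for SNP genotyping-array datasets.

The central object is :class:`GenotypeSet`, modeled on a PLINK fileset: a
markers x samples matrix of biallelic genotype calls stored in parallel with a
marker map and a sample (pedigree) table, plus optional two-channel
hybridization intensities and derived B-allele-frequency / log-R-ratio tracks.
All matrices share one marker ordering (sorted by chromosome then position)
and one sample ordering, so the object is self-describing and safe to subset.

Genotype calls are coded as the dosage of the Illumina "B" allele:
0 = AA, 1 = AB, 2 = BB, with ``MISSING`` (-1) as a dedicated no-call
sentinel.  This orientation matches the B-allele frequency axis used by the
normalization module; display-level flips to reference-allele counts live in
:mod:`snparray.viz`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing (no-call) genotype; distinct from dosage 0
MISSING: int = -1

VALID_CALLS = frozenset({MISSING, 0, 1, 2})

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: placeholder for an unknown A/B allele nucleotide
UNKNOWN_ALLELE = "N"

#: chromosome labels that are not autosomes
SEX_CHROMS = ("X", "Y")
#: pseudoautosomal label: diploid in both sexes, excluded from X heterozygosity
PSEUDOAUTOSOMAL = "XY"
NON_AUTOSOMES = frozenset({"X", "Y", "XY", "M", "MT"})

MARKER_COLUMNS = ("chrom", "pos", "cM", "allele_A", "allele_B")
SAMPLE_COLUMNS = ("family", "father", "mother", "sex", "phenotype", "batch", "qc_flag")

SEXES = ("unknown", "male", "female")


class SNPArrayError(ValueError):
    """Base class for all errors raised by this package."""


class DimensionError(SNPArrayError):
    """Matrices and metadata tables disagree in shape or ordering."""


class FormatError(SNPArrayError):
    """A file does not conform to its declared format."""


def chrom_sort_key(chrom: str):
    """Sort key placing numeric chromosomes first (numerically), then X, Y,
    the pseudoautosomal region, mitochondria, then anything else by name."""
    c = str(chrom)
    try:
        return (0, int(c), "")
    except ValueError:
        special = {"X": 0, "Y": 1, "XY": 2, "M": 3, "MT": 3}
        return (1, special.get(c.upper(), 9), c)


def _normalize_sex(value) -> str:
    mapping = {
        "male": "male", "m": "male", "1": "male", 1: "male",
        "female": "female", "f": "female", "2": "female", 2: "female",
        "unknown": "unknown", "u": "unknown", "0": "unknown", 0: "unknown",
    }
    if pd.isna(value):
        return "unknown"
    key = value.lower() if isinstance(value, str) else value
    try:
        return mapping[key]
    except (KeyError, TypeError):
        raise SNPArrayError(f"unrecognized sex value: {value!r}") from None


def prepare_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Coerce a marker map to the canonical column set, indexed by marker name.

    Accepts a ``name`` column or a pre-set index.  Missing ``cM`` becomes NaN;
    missing alleles become :data:`UNKNOWN_ALLELE`.
    """
    m = markers.copy()
    if "name" in m.columns:
        m = m.set_index("name")
    m.index = m.index.astype(str)
    m.index.name = "name"
    if m.index.has_duplicates:
        dups = m.index[m.index.duplicated()].unique().tolist()
        raise SNPArrayError(f"duplicate marker names: {dups[:5]}")
    if "chrom" not in m.columns or "pos" not in m.columns:
        raise SNPArrayError("marker map requires 'chrom' and 'pos' columns")
    m["chrom"] = m["chrom"].astype(str)
    m["pos"] = m["pos"].astype(np.int64)
    if "cM" not in m.columns:
        m["cM"] = np.nan
    m["cM"] = m["cM"].astype(float)
    for col in ("allele_A", "allele_B"):
        if col not in m.columns:
            m[col] = UNKNOWN_ALLELE
        m[col] = m[col].fillna(UNKNOWN_ALLELE).astype(str).str.upper()
        bad = ~m[col].isin(NUCLEOTIDES | {UNKNOWN_ALLELE, "0", "-"})
        if bad.any():
            raise SNPArrayError(f"illegal {col} values: {m.loc[bad, col].unique()[:5]}")
        m.loc[m[col].isin(("0", "-")), col] = UNKNOWN_ALLELE
    known = (m["allele_A"] != UNKNOWN_ALLELE) & (m["allele_B"] != UNKNOWN_ALLELE)
    clash = known & (m["allele_A"] == m["allele_B"])
    if clash.any():
        raise SNPArrayError(
            f"allele_A == allele_B at markers: {m.index[clash][:5].tolist()}")
    extra = [c for c in m.columns if c not in MARKER_COLUMNS]
    return m[list(MARKER_COLUMNS) + extra]


def prepare_samples(samples: Union[pd.DataFrame, Sequence[str]]) -> pd.DataFrame:
    """Coerce sample metadata to the canonical column set, indexed by sample id.

    A bare sequence of ids is accepted and filled with defaults (family = id,
    unknown parents/sex, no phenotype).
    """
    if not isinstance(samples, pd.DataFrame):
        samples = pd.DataFrame(index=pd.Index([str(s) for s in samples], name="id"))
    s = samples.copy()
    if "id" in s.columns:
        s = s.set_index("id")
    s.index = s.index.astype(str)
    s.index.name = "id"
    if s.index.has_duplicates:
        dups = s.index[s.index.duplicated()].unique().tolist()
        raise SNPArrayError(f"duplicate sample ids: {dups[:5]}")
    if "family" not in s.columns:
        s["family"] = s.index
    s["family"] = s["family"].fillna(pd.Series(s.index, index=s.index)).astype(str)
    for col in ("father", "mother"):
        if col not in s.columns:
            s[col] = "0"
        s[col] = s[col].fillna("0").astype(str)
    if "sex" not in s.columns:
        s["sex"] = "unknown"
    s["sex"] = s["sex"].map(_normalize_sex)
    if "phenotype" not in s.columns:
        s["phenotype"] = np.nan
    if "batch" not in s.columns:
        s["batch"] = pd.NA
    if "qc_flag" not in s.columns:
        s["qc_flag"] = "unset"
    extra = [c for c in s.columns if c not in SAMPLE_COLUMNS]
    return s[list(SAMPLE_COLUMNS) + extra]


@dataclass
class GenotypeSet:
    """A self-contained genotyping dataset.

    Attributes
    ----------
    calls : (n_markers, n_samples) int8 array of B-allele dosages, -1 missing.
    markers : DataFrame indexed by marker name with columns chrom, pos, cM,
        allele_A, allele_B; always sorted by (chrom, pos).
    samples : DataFrame indexed by sample id with pedigree/QC columns.
    x, y : optional non-negative intensity matrices (same shape as calls).
    baf, lrr : optional normalized tracks (same shape as calls).
    normalized : True once thresholded quantile normalization has been applied.
    """

    calls: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame
    x: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    baf: Optional[np.ndarray] = None
    lrr: Optional[np.ndarray] = None
    normalized: bool = False

    # -- basic introspection -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_names(self) -> pd.Index:
        return self.markers.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    @property
    def shape(self):
        return self.calls.shape

    def matrices(self):
        """Names of the matrix attributes that are present."""
        return [n for n in ("calls", "x", "y", "baf", "lrr")
                if getattr(self, n) is not None]

    # -- chromosome masks ----------------------------------------------------
    def autosome_mask(self) -> np.ndarray:
        return ~self.markers["chrom"].str.upper().isin(NON_AUTOSOMES).to_numpy()

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.markers["chrom"].str.upper() == chrom.upper()).to_numpy()

    def copy(self) -> "GenotypeSet":
        return GenotypeSet(
            calls=self.calls.copy(),
            markers=self.markers.copy(),
            samples=self.samples.copy(),
            x=None if self.x is None else self.x.copy(),
            y=None if self.y is None else self.y.copy(),
            baf=None if self.baf is None else self.baf.copy(),
            lrr=None if self.lrr is None else self.lrr.copy(),
            normalized=self.normalized,
        )

    def equals(self, other: "GenotypeSet") -> bool:
        if self.shape != other.shape or self.matrices() != other.matrices():
            return False
        if not np.array_equal(self.calls, other.calls):
            return False
        for name in ("x", "y", "baf", "lrr"):
            a, b = getattr(self, name), getattr(other, name)
            if a is not None and not np.allclose(a, b, equal_nan=True):
                return False
        return (self.markers.index.equals(other.markers.index)
                and self.samples.index.equals(other.samples.index))


def make_genotype_set(
    calls,
    markers: pd.DataFrame,
    samples: Union[pd.DataFrame, Sequence[str]],
    x=None,
    y=None,
    baf=None,
    lrr=None,
    normalized: bool = False,
) -> GenotypeSet:
    """Validate and assemble a :class:`GenotypeSet`.

    Markers are re-sorted to (chromosome, position) order and every matrix is
    permuted consistently, so construction is idempotent on its own output.

    Raises
    ------
    DimensionError
        if any matrix disagrees with the metadata tables in shape.
    SNPArrayError
        for duplicate ids or illegal call codes.
    """
    calls = np.asarray(calls)
    if calls.ndim != 2:
        raise DimensionError(f"calls must be 2-D, got shape {calls.shape}")
    bad = ~np.isin(calls, list(VALID_CALLS))
    if bad.any():
        raise SNPArrayError(
            f"illegal call codes: {np.unique(calls[bad])[:5]} "
            f"(expected {sorted(VALID_CALLS)})")
    calls = calls.astype(np.int8)

    markers = prepare_markers(markers)
    samples = prepare_samples(samples)
    n_m, n_s = calls.shape
    if len(markers) != n_m:
        raise DimensionError(
            f"calls has {n_m} rows but marker map has {len(markers)} markers")
    if len(samples) != n_s:
        raise DimensionError(
            f"calls has {n_s} columns but sample table has {len(samples)} samples")

    def _check_matrix(mat, name, non_negative=False, unit=False):
        if mat is None:
            return None
        mat = np.asarray(mat, dtype=float)
        if mat.shape != calls.shape:
            raise DimensionError(
                f"{name} shape {mat.shape} != calls shape {calls.shape}")
        if non_negative and np.nanmin(mat, initial=0.0) < 0:
            raise SNPArrayError(f"{name} contains negative intensities")
        if unit and mat.size:
            finite = mat[np.isfinite(mat)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise SNPArrayError(f"{name} values must lie in [0, 1]")
        return mat

    x = _check_matrix(x, "x", non_negative=True)
    y = _check_matrix(y, "y", non_negative=True)
    baf = _check_matrix(baf, "baf", unit=True)
    lrr = _check_matrix(lrr, "lrr")

    order = sorted(
        range(n_m),
        key=lambda i: (chrom_sort_key(markers["chrom"].iat[i]), markers["pos"].iat[i]),
    )
    if order != list(range(n_m)):
        perm = np.asarray(order)
        markers = markers.iloc[perm]
        calls = calls[perm]
        x = None if x is None else x[perm]
        y = None if y is None else y[perm]
        baf = None if baf is None else baf[perm]
        lrr = None if lrr is None else lrr[perm]

    _check_cm_monotone(markers)
    return GenotypeSet(calls=calls, markers=markers, samples=samples,
                       x=x, y=y, baf=baf, lrr=lrr, normalized=normalized)


def _check_cm_monotone(markers: pd.DataFrame) -> None:
    for chrom, grp in markers.groupby("chrom", sort=False):
        cm = grp["cM"].to_numpy()
        cm = cm[~np.isnan(cm)]
        if cm.size > 1 and np.any(np.diff(cm) < 0):
            raise SNPArrayError(f"cM positions decrease along chromosome {chrom}")


def _resolve_selector(selector, index: pd.Index, markers: Optional[pd.DataFrame]):
    """Turn an id list / boolean mask / genomic region into a boolean mask over
    ``index``, preserving the dataset's own ordering."""
    if selector is None:
        return np.ones(len(index), dtype=bool)
    if isinstance(selector, tuple) and len(selector) == 3 and markers is not None:
        chrom, start, end = selector
        return ((markers["chrom"] == str(chrom))
                & (markers["pos"] >= int(start))
                & (markers["pos"] <= int(end))).to_numpy()
    selector = np.asarray(selector)
    if selector.dtype == bool:
        if selector.size != len(index):
            raise DimensionError(
                f"boolean selector of length {selector.size} for axis of {len(index)}")
        return selector
    ids = pd.Index([str(s) for s in selector])
    unknown = ids.difference(index)
    if len(unknown):
        raise SNPArrayError(f"unknown ids in selector: {unknown[:5].tolist()}")
    return index.isin(ids)


def subset(gset: GenotypeSet, markers=None, samples=None) -> GenotypeSet:
    """Subset markers and/or samples, keeping all matrices consistent.

    Selectors may be id lists, boolean masks, or (for markers) a genomic
    region tuple ``(chrom, start, end)`` with 1-based closed bounds.  Relative
    order is always the dataset's own order; an empty selection is valid.
    """
    mmask = _resolve_selector(markers, gset.markers.index, gset.markers)
    smask = _resolve_selector(samples, gset.samples.index, None)
    take = lambda mat: None if mat is None else mat[np.ix_(mmask.nonzero()[0],
                                                           smask.nonzero()[0])]
    return GenotypeSet(
        calls=take(gset.calls),
        markers=gset.markers.loc[mmask].copy(),
        samples=gset.samples.loc[smask].copy(),
        x=take(gset.x), y=take(gset.y), baf=take(gset.baf), lrr=take(gset.lrr),
        normalized=gset.normalized,
    )


def genotype_counts(gset: GenotypeSet, axis: str = "sample") -> pd.DataFrame:
    """Tabulate genotype classes per sample (axis="sample") or per marker.

    Returns a DataFrame with columns n_refhom (dosage 0), n_het, n_althom
    (dosage 2) and n_missing; the four counts sum to the extent of the other
    axis.
    """
    if axis not in ("sample", "marker"):
        raise SNPArrayError(f"axis must be 'sample' or 'marker', got {axis!r}")
    ax = 0 if axis == "sample" else 1
    counts = {
        "n_refhom": (gset.calls == 0).sum(axis=ax),
        "n_het": (gset.calls == 1).sum(axis=ax),
        "n_althom": (gset.calls == 2).sum(axis=ax),
        "n_missing": (gset.calls == MISSING).sum(axis=ax),
    }
    index = gset.sample_ids if axis == "sample" else gset.marker_names
    return pd.DataFrame(counts, index=index)
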