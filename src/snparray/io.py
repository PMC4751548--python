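"""Readers and writers: BeadStudio FinalReport input; PLINK, R/qtl and HGDP
export.

The PLINK binary writer is bit-exact against the published .bed layout:
magic bytes 0x6C 0x1B, mode byte 0x01 (SNP-major), then one row of
2-bit codes per marker with samples packed four per byte, least-significant
pair first.  Note the allele orientation: **A1 is the Illumina B allele** and
A2 the A allele, so that PLINK's count-of-A1 dosage equals this package's
internal B-allele dosage.  PLINK users accustomed to A1 = minor allele should
re-reference with ``plink --a2-allele`` if that convention matters downstream.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import (COMPLEMENT, MISSING, UNKNOWN_ALLELE, FormatError,
                   GenotypeSet, SNPArrayError, make_genotype_set,
                   prepare_markers)

logger = logging.getLogger(__name__)

BED_MAGIC = bytes([0x6C, 0x1B])
BED_SNP_MAJOR = bytes([0x01])

#: 2-bit PLINK code per B-allele dosage (index -1 = missing handled separately)
_PLINK_CODE_BY_DOSAGE = {0: 0b11, 1: 0b10, 2: 0b00, MISSING: 0b01}
_DOSAGE_BY_PLINK_CODE = {v: k for k, v in _PLINK_CODE_BY_DOSAGE.items()}

_SEX_TO_PLINK = {"male": 1, "female": 2, "unknown": 0}
_PLINK_TO_SEX = {1: "male", 2: "female", 0: "unknown"}


@dataclass
class FinalReportDialect:
    """Formatting conventions of a GenomeStudio/BeadStudio FinalReport export.

    allele_coding: "AB" for A/B calls, "top" for forward-strand nucleotides.
    """
    allele_coding: str = "AB"
    missing_token: str = "-"
    delimiter: str = "\t"
    has_header_block: bool = True

    def __post_init__(self):
        if not self.missing_token:
            raise SNPArrayError("missing_token must be non-empty")
        if self.allele_coding not in ("AB", "top"):
            raise SNPArrayError(f"unknown allele coding {self.allele_coding!r}")


# ---------------------------------------------------------------------------
# FinalReport reading
# ---------------------------------------------------------------------------

def _open_finalreport(path, member: Optional[str]):
    path = Path(path)
    if zipfile.is_zipfile(path):
        zf = zipfile.ZipFile(path)
        names = zf.namelist()
        if member is None:
            if len(names) > 1:
                raise FormatError(
                    f"archive has {len(names)} members; specify one of {names}")
            member = names[0]
        return _io.TextIOWrapper(zf.open(member), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _find_column(columns, exact=(), prefixes=()):
    low = {c.lower().strip(): c for c in columns}
    for name in exact:
        if name in low:
            return low[name]
    for c in columns:
        if any(c.lower().strip().startswith(p) for p in prefixes):
            return c
    return None


def read_beadstudio(
    path,
    manifest: pd.DataFrame,
    dialect: Optional[FinalReportDialect] = None,
    allow_ragged: bool = False,
    member: Optional[str] = None,
) -> GenotypeSet:
    """Parse a (possibly ZIP-compressed) FinalReport into a GenotypeSet.

    The file is long-format: one row per (sample, SNP) with call and x/y
    intensity columns, optionally preceded by a ``[Header]`` block terminated
    by a ``[Data]`` line.  Column names are matched case-insensitively
    ("SNP Name", "Sample ID", columns starting with "Allele1"/"Allele2", and
    "X"/"Y", with "X Raw"/"Y Raw" accepted as a fallback).

    Calls are translated to B-allele dosage through the ``manifest``: A/B
    coding directly; nucleotide coding matched against allele_A/allele_B with
    a reverse-strand (complement) fallback.  Markers absent from the manifest
    are dropped with a logged count.  Samples covering only part of the
    marker set raise an error unless ``allow_ragged``, in which case the gaps
    become missing calls.
    """
    if dialect is None:
        dialect = FinalReportDialect()
    manifest = prepare_markers(manifest)

    with _open_finalreport(path, member) as fh:
        first = fh.readline()
        if dialect.has_header_block and first.strip().startswith("["):
            seen_data = first.strip().lower() == "[data]"
            while not seen_data:
                line = fh.readline()
                if not line:
                    raise FormatError("no [Data] section found in FinalReport")
                seen_data = line.strip().lower() == "[data]"
            df = pd.read_csv(fh, sep=dialect.delimiter, dtype=str)
        else:
            body = first + fh.read()
            df = pd.read_csv(_io.StringIO(body), sep=dialect.delimiter, dtype=str)

    snp_col = _find_column(df.columns, exact=("snp name",))
    samp_col = _find_column(df.columns, exact=("sample id",))
    a1_col = _find_column(df.columns, prefixes=("allele1",))
    a2_col = _find_column(df.columns, prefixes=("allele2",))
    x_col = _find_column(df.columns, exact=("x",)) or _find_column(
        df.columns, exact=("x raw",))
    y_col = _find_column(df.columns, exact=("y",)) or _find_column(
        df.columns, exact=("y raw",))
    needed = {"SNP Name": snp_col, "Sample ID": samp_col,
              "Allele1": a1_col, "Allele2": a2_col}
    missing_cols = [k for k, v in needed.items() if v is None]
    if missing_cols:
        raise FormatError(f"FinalReport lacks required columns: {missing_cols}")

    in_manifest = df[snp_col].isin(manifest.index)
    n_dropped = df.loc[~in_manifest, snp_col].nunique()
    if n_dropped:
        logger.info("dropping %d markers absent from the manifest", n_dropped)
        df = df.loc[in_manifest]
    if df.empty:
        raise FormatError("no FinalReport rows match the manifest")

    a1 = df[a1_col].str.strip().to_numpy()
    a2 = df[a2_col].str.strip().to_numpy()
    miss = (a1 == dialect.missing_token) | (a2 == dialect.missing_token)
    if dialect.allele_coding == "AB":
        dosage = (a1 == "B").astype(np.int8) + (a2 == "B").astype(np.int8)
        unresolved = ~miss & ~(np.isin(a1, ("A", "B")) & np.isin(a2, ("A", "B")))
    else:
        alle_A = manifest["allele_A"].reindex(df[snp_col]).to_numpy()
        alle_B = manifest["allele_B"].reindex(df[snp_col]).to_numpy()
        dosage, unresolved = _nucleotide_dosage(a1, a2, alle_A, alle_B)
    if unresolved.any():
        n = int((unresolved & ~miss).sum())
        if n:
            warnings.warn(f"{n} calls could not be matched to manifest alleles; "
                          "set to missing")
    dosage = np.where(miss | unresolved, MISSING, dosage).astype(np.int8)

    samples = pd.unique(df[samp_col])
    long = pd.DataFrame({"snp": df[snp_col].to_numpy(),
                         "sample": df[samp_col].to_numpy(),
                         "dosage": dosage})
    counts = long.groupby("sample", sort=False).size()
    n_markers_present = long["snp"].nunique()
    if counts.nunique() > 1 or counts.iloc[0] != n_markers_present:
        if not allow_ragged:
            raise FormatError(
                "samples cover unequal marker sets; pass allow_ragged=True "
                "to fill the gaps with missing calls")
    marker_order = manifest.index[manifest.index.isin(long["snp"])]

    def _pivot(values, fill):
        wide = long.assign(v=values).pivot_table(
            index="snp", columns="sample", values="v", aggfunc="first")
        return wide.reindex(index=marker_order, columns=samples).fillna(fill)

    calls = _pivot(long["dosage"].astype(float), float(MISSING)).to_numpy()
    x_mat = y_mat = None
    if x_col is not None and y_col is not None:
        x_mat = _pivot(pd.to_numeric(df[x_col], errors="coerce").to_numpy(),
                       np.nan).to_numpy()
        y_mat = _pivot(pd.to_numeric(df[y_col], errors="coerce").to_numpy(),
                       np.nan).to_numpy()
    return make_genotype_set(calls.astype(np.int8),
                             manifest.loc[marker_order].reset_index(),
                             list(samples), x=x_mat, y=y_mat)


def _nucleotide_dosage(a1, a2, allele_A, allele_B):
    """B-allele dosage from nucleotide calls, with complement fallback.

    Each observed allele is matched against the manifest A/B nucleotides; if
    either allele of a call fails to match directly, both are complemented
    (reverse-strand report) and re-matched.  Calls failing both ways are
    flagged unresolved.
    """
    def match(tokens):
        is_b = tokens == allele_B
        ok = (tokens == allele_A) | is_b
        return is_b.astype(np.int8), ok

    comp = np.vectorize(lambda t: COMPLEMENT.get(t, "?"))
    b1, ok1 = match(a1)
    b2, ok2 = match(a2)
    direct_ok = ok1 & ok2
    cb1, cok1 = match(comp(a1))
    cb2, cok2 = match(comp(a2))
    comp_ok = cok1 & cok2
    dosage = np.where(direct_ok, b1 + b2, np.where(comp_ok, cb1 + cb2, 0))
    return dosage.astype(np.int8), ~(direct_ok | comp_ok)


# ---------------------------------------------------------------------------
# PLINK binary
# ---------------------------------------------------------------------------

def write_plink(gset: GenotypeSet, prefix) -> None:
    """Write ``prefix``.bed/.bim/.fam in PLINK 1 binary (SNP-major) format.

    A1 is the Illumina B allele and A2 the A allele (see module docstring);
    markers with unknown alleles are exported as "0 0" with a warning.
    """
    prefix = Path(prefix)
    m = gset.markers
    unknown = (m["allele_A"] == UNKNOWN_ALLELE) | (m["allele_B"] == UNKNOWN_ALLELE)
    if unknown.any():
        warnings.warn(f"{int(unknown.sum())} markers have unknown alleles; "
                      "exported as '0 0'")
    bim = pd.DataFrame({
        "chrom": m["chrom"],
        "name": m.index,
        "cM": m["cM"].fillna(0.0),
        "pos": m["pos"],
        "A1": m["allele_B"].where(m["allele_B"] != UNKNOWN_ALLELE, "0"),
        "A2": m["allele_A"].where(m["allele_A"] != UNKNOWN_ALLELE, "0"),
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    s = gset.samples
    fam = pd.DataFrame({
        "family": s["family"],
        "id": s.index,
        "father": s["father"],
        "mother": s["mother"],
        "sex": s["sex"].map(_SEX_TO_PLINK),
        "phenotype": [int(v) if float(v).is_integer() else v
                      for v in pd.to_numeric(s["phenotype"],
                                             errors="coerce").fillna(-9)],
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    codes = np.empty(gset.shape, dtype=np.uint8)
    for dosage, code in _PLINK_CODE_BY_DOSAGE.items():
        codes[gset.calls == dosage] = code
    n_s = gset.n_samples
    pad = (-n_s) % 4
    if pad:
        # padding positions carry code 0 ("hom A1"); PLINK readers ignore them
        codes = np.concatenate(
            [codes, np.zeros((gset.n_markers, pad), dtype=np.uint8)], axis=1)
    codes = codes.reshape(gset.n_markers, -1, 4)
    packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
              | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(BED_MAGIC + BED_SNP_MAJOR)
        fh.write(packed.tobytes())


def read_plink(prefix) -> GenotypeSet:
    """Read a PLINK 1 .bed/.bim/.fam fileset; inverse of :func:`write_plink`."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "name", "cM", "pos", "A1", "A2"],
                      dtype={"chrom": str, "name": str, "A1": str, "A2": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["family", "id", "father", "mother", "sex",
                             "phenotype"],
                      dtype={"family": str, "id": str, "father": str,
                             "mother": str})
    markers = pd.DataFrame({
        "name": bim["name"],
        "chrom": bim["chrom"],
        "pos": bim["pos"],
        "cM": bim["cM"].where(bim["cM"] != 0, np.nan),
        "allele_A": bim["A2"].replace("0", UNKNOWN_ALLELE),
        "allele_B": bim["A1"].replace("0", UNKNOWN_ALLELE),
    })
    samples = fam.copy()
    samples["sex"] = fam["sex"].map(_PLINK_TO_SEX).fillna("unknown")
    samples.loc[samples["phenotype"] == -9, "phenotype"] = np.nan

    n_m, n_s = len(bim), len(fam)
    row_bytes = (n_s + 3) // 4
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != BED_MAGIC:
        raise FormatError("bad .bed magic bytes")
    if raw[2:3] != BED_SNP_MAJOR:
        raise FormatError("only SNP-major .bed files are supported")
    expected = 3 + n_m * row_bytes
    if len(raw) != expected:
        raise FormatError(f".bed length {len(raw)} != expected {expected}")
    packed = np.frombuffer(raw[3:], dtype=np.uint8).reshape(n_m, row_bytes)
    codes = np.empty((n_m, row_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (packed >> (2 * k)) & 0b11
    codes = codes[:, :n_s]
    calls = np.empty((n_m, n_s), dtype=np.int8)
    for code, dosage in _DOSAGE_BY_PLINK_CODE.items():
        calls[codes == code] = dosage
    return make_genotype_set(calls, markers, samples)


# ---------------------------------------------------------------------------
# R/qtl and HGDP export
# ---------------------------------------------------------------------------

_RQTL_TOKEN = {0: "A", 1: "H", 2: "B", MISSING: "-"}


def write_rqtl_csv(gset: GenotypeSet, path, founders=None) -> None:
    """Write the single-file R/qtl cross layout.

    Row 1: "id" then marker names; row 2: chromosomes; row 3: genetic
    positions (cM, falling back to Mbp when absent, with a warning); then one
    genotype row per sample with tokens A/H/B/-.  If ``founders`` is a pair of
    sample ids the markers are first recoded against those parental lines.
    """
    if founders is not None:
        from .merge import recode_by_parents
        gset, _ = recode_by_parents(gset, *founders)
    cm = gset.markers["cM"]
    if cm.isna().any():
        warnings.warn("markers lack cM positions; using Mbp (pos/1e6) instead")
        cm = cm.fillna(gset.markers["pos"] / 1e6)
    with open(path, "wt", encoding="utf-8") as fh:
        names = gset.marker_names.tolist()
        fh.write(",".join(["id"] + names) + "\n")
        fh.write(",".join([""] + gset.markers["chrom"].tolist()) + "\n")
        fh.write(",".join([""] + [f"{v:g}" for v in cm]) + "\n")
        for j, sid in enumerate(gset.sample_ids):
            tokens = [_RQTL_TOKEN[int(c)] for c in gset.calls[:, j]]
            fh.write(",".join([sid] + tokens) + "\n")


def write_hgdp(gset: GenotypeSet, path) -> None:
    """Write an HGDP-style tab-delimited genotype matrix.

    First row: "marker" then sample ids; then one row per marker with
    two-letter nucleotide genotypes ("AG") or "--" for missing.  Markers with
    unknown alleles are skipped with a warning.
    """
    m = gset.markers
    known = ((m["allele_A"] != UNKNOWN_ALLELE)
             & (m["allele_B"] != UNKNOWN_ALLELE)).to_numpy()
    if not known.all():
        warnings.warn(f"{int((~known).sum())} markers with unknown alleles skipped")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(["marker"] + gset.sample_ids.tolist()) + "\n")
        for i in np.nonzero(known)[0]:
            a, b = m["allele_A"].iat[i], m["allele_B"].iat[i]
            geno = {0: a + a, 1: a + b, 2: b + b, MISSING: "--"}
            row = [geno[int(c)] for c in gset.calls[i]]
            fh.write("\t".join([str(m.index[i])] + row) + "\n")
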