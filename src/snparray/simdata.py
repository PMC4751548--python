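"""Synthetic genotyping-array data with known ground truth.

The generator emulates the features of a real Infinium dataset that the rest
of the package consumes: biallelic genotypes with population structure,
genotype-conditional two-channel intensity clusters obeying the R = x + y ~ 1
coordinate model, sex chromosomes (hemizygous male X at half intensity, Y
probes with female background signal), trios with optional planted Mendelian
errors, sample contamination as intensity mixtures, and a FinalReport writer
so the BeadStudio parser can be exercised round-trip.

Population structure is modeled as independent logit-normal drift of each
population's allele frequencies away from a shared ancestral frequency —
enough to produce realistic kinship-block and PCA-cluster structure without a
coalescent.  Linkage disequilibrium is deliberately absent; see the methods
note for what this does and does not let tests demonstrate.

All draws are made with ``numpy.random.default_rng`` seeded from
``SimConfig.seed`` plus a stream label, so marker-level quantities (positions,
allele frequencies) are shared between cohorts generated from the same config
(e.g. a reference panel and a test cohort) while their samples are
independent, and every output is bit-reproducible.
"""

from __future__ import annotations

import zipfile
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeSet, SNPArrayError, make_genotype_set, subset
from .io import FinalReportDialect
from .normalize import xy_from_theta_r

_NUCS = np.array(list("ACGT"))

#: number of autosomes over which markers are spread (mouse-style karyotype)
N_AUTOSOMES = 19


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a small multi-population array experiment: three
    populations of ten samples on a 2,000-marker array whose canonical
    genotype clusters sit at theta 0.05 / 0.5 / 0.95 with total intensity 1,
    observed with Gaussian noise (sigma 0.03) and 1% missing calls.
    ``divergence`` scales the logit-normal between-population drift of allele
    frequencies (0 = panmixia).  ``sex_fractions`` is (male, female).
    ``contamination`` lists (sample_id, fraction) intensity mixtures.
    """
    n_pops: int = 3
    n_per_pop: Union[int, Sequence[int]] = 10
    n_markers: int = 2000
    divergence: float = 0.3
    cluster_theta: Tuple[float, float, float] = (0.05, 0.5, 0.95)
    cluster_r: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sigma: float = 0.03
    missing_rate: float = 0.01
    sex_fractions: Tuple[float, float] = (0.5, 0.5)
    x_fraction: float = 0.05
    y_fraction: float = 0.01
    contamination: Optional[Sequence[Tuple[str, float]]] = None
    seed: int = 0

    def __post_init__(self):
        for name in ("divergence", "noise_sigma", "missing_rate",
                     "x_fraction", "y_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SNPArrayError(f"{name} must lie in [0, 1], got {v}")
        if self.n_pops < 1 or self.n_markers < 1:
            raise SNPArrayError("need at least one population and one marker")

    def per_pop(self) -> np.ndarray:
        if np.isscalar(self.n_per_pop):
            return np.full(self.n_pops, int(self.n_per_pop))
        sizes = np.asarray(self.n_per_pop, dtype=int)
        if sizes.size != self.n_pops:
            raise SNPArrayError("n_per_pop length must equal n_pops")
        return sizes


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, zlib.crc32(stream.encode()) & 0x7FFFFFFF])


# ---------------------------------------------------------------------------
# markers and allele frequencies (shared across cohorts for one config)
# ---------------------------------------------------------------------------

def _simulate_markers(config: SimConfig) -> pd.DataFrame:
    rng = _rng(config, "markers")
    n = config.n_markers
    n_y = int(round(config.y_fraction * n))
    n_x = int(round(config.x_fraction * n))
    n_auto = n - n_x - n_y
    chroms = np.concatenate([
        np.repeat([str(c + 1) for c in range(N_AUTOSOMES)],
                  np.diff(np.linspace(0, n_auto, N_AUTOSOMES + 1).astype(int))),
        np.repeat("X", n_x), np.repeat("Y", n_y),
    ])
    pos = np.empty(n, dtype=np.int64)
    for c in pd.unique(chroms):
        idx = np.nonzero(chroms == c)[0]
        pos[idx] = np.sort(rng.integers(1, 190_000_000, size=idx.size))
    a_idx = rng.integers(0, 4, size=n)
    b_idx = (a_idx + rng.integers(1, 4, size=n)) % 4
    return pd.DataFrame({
        "name": [f"snp{i:05d}" for i in range(n)],
        "chrom": chroms,
        "pos": pos,
        "cM": pos / 2e6,  # ~0.5 cM/Mb genetic map
        "allele_A": _NUCS[a_idx],
        "allele_B": _NUCS[b_idx],
    })


def _population_freqs(config: SimConfig) -> np.ndarray:
    """(n_markers, n_pops) B-allele frequencies: ancestral Uniform(0.05, 0.95)
    perturbed per population by logit-normal drift with sd = 2 * divergence."""
    rng = _rng(config, "freqs")
    p_anc = rng.uniform(0.05, 0.95, size=config.n_markers)
    logit = np.log(p_anc / (1 - p_anc))[:, None]
    drift = rng.normal(0.0, 2.0 * config.divergence,
                       size=(config.n_markers, config.n_pops))
    return 1.0 / (1.0 + np.exp(-(logit + drift)))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    config: SimConfig,
    cohort: str = "main",
    n_per_pop: Optional[Union[int, Sequence[int]]] = None,
):
    """Simulate a genotype cohort; returns ``(GenotypeSet, pop_labels)``.

    Autosomal genotypes are Binomial(2, p_pop); X-chromosome genotypes are
    drawn haploid for males (coded 0/2) and diploid for females; Y probes are
    haploid for males and missing for females.  Different ``cohort`` labels
    under one config share markers and allele frequencies but have independent
    samples — use this to draw a reference panel alongside a test cohort.
    """
    markers = _simulate_markers(config)
    freqs = _population_freqs(config)
    sizes = (config.per_pop() if n_per_pop is None
             else SimConfig(**{**config.__dict__, "n_per_pop": n_per_pop}).per_pop())
    rng = _rng(config, f"samples/{cohort}")

    pop_labels = np.repeat(np.arange(config.n_pops), sizes)
    n_samples = pop_labels.size
    sex = rng.choice(["male", "female"], size=n_samples,
                     p=np.asarray(config.sex_fractions)
                     / sum(config.sex_fractions))
    chrom = markers["chrom"].to_numpy()
    is_x, is_y = chrom == "X", chrom == "Y"

    p = freqs[:, pop_labels]  # markers x samples
    calls = rng.binomial(2, p).astype(np.int8)
    male = sex == "male"
    if is_x.any() and male.any():
        hap = rng.binomial(1, p[np.ix_(is_x, male)]).astype(np.int8) * 2
        calls[np.ix_(is_x, male)] = hap
    if is_y.any():
        calls[np.ix_(is_y, ~male)] = MISSING
        if male.any():
            hap = rng.binomial(1, p[np.ix_(is_y, male)]).astype(np.int8) * 2
            calls[np.ix_(is_y, male)] = hap
    if config.missing_rate > 0:
        drop = rng.random(calls.shape) < config.missing_rate
        calls[drop] = MISSING

    ids = [f"{cohort}_p{p_}_{i:03d}" for i, p_ in enumerate(pop_labels)]
    samples = pd.DataFrame({"id": ids, "sex": sex,
                            "population": [f"pop{p_}" for p_ in pop_labels]})
    gset = make_genotype_set(calls, markers, samples)
    order = gset.samples.index.get_indexer(pd.Index(ids))
    # construction sorts markers only; sample order is unchanged
    assert (order == np.arange(n_samples)).all()
    return gset, np.asarray([f"pop{p_}" for p_ in pop_labels])


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

#: Y-probe background total intensity in samples lacking a Y chromosome
FEMALE_Y_BACKGROUND = 0.1
#: hemizygous loci hybridize one chromosome's worth of DNA
HEMIZYGOUS_R_SCALE = 0.5


def simulate_intensities(gset: GenotypeSet, config: SimConfig,
                         cohort: str = "main") -> GenotypeSet:
    """Attach x/y intensities drawn from the genotype-conditional cluster model.

    Each call receives polar coordinates (theta, R) normally perturbed about
    its genotype's centroid (theta truncated to [0, 1]) and is mapped back to
    channel intensities exactly, so with zero noise ``theta_r`` recovers the
    centroid and R precisely.  Male X and male Y probes use the homozygote
    clusters with R scaled by 0.5; Y probes in females emit uniform-theta
    background at R ~ 0.1.  Missing calls emit mid-polar background.
    Contamination entries replace a sample's intensities with a
    (1 - f) : f mixture with a randomly chosen donor sample.
    """
    rng = _rng(config, f"intensity/{cohort}")
    m, n = gset.shape
    theta_c = np.asarray(config.cluster_theta, dtype=float)
    r_c = np.asarray(config.cluster_r, dtype=float)

    calls = gset.calls
    obs = np.where(calls == MISSING, 1, calls)
    theta = theta_c[obs].astype(float)
    R = r_c[obs].astype(float)
    theta[calls == MISSING] = rng.uniform(0.0, 1.0, size=int((calls == MISSING).sum()))

    male = (gset.samples["sex"] == "male").to_numpy()
    is_x = gset.chrom_mask("X")
    is_y = gset.chrom_mask("Y")
    hemi = np.zeros((m, n), dtype=bool)
    hemi[np.ix_(is_x, male)] = True
    hemi[np.ix_(is_y, male)] = True
    R[hemi] *= HEMIZYGOUS_R_SCALE
    no_y = np.zeros((m, n), dtype=bool)
    no_y[np.ix_(is_y, ~male)] = True
    R[no_y] = FEMALE_Y_BACKGROUND
    theta[no_y] = rng.uniform(0.0, 1.0, size=int(no_y.sum()))

    if config.noise_sigma > 0:
        theta = np.clip(theta + rng.normal(0, config.noise_sigma, size=(m, n)),
                        0.0, 1.0)
        R = np.maximum(R + rng.normal(0, config.noise_sigma, size=(m, n)), 1e-6)

    x, y = xy_from_theta_r(theta, R)
    if config.contamination:
        ids = gset.sample_ids
        for entry in config.contamination:
            if len(entry) == 3:  # explicit donor
                sid, donor_id, frac = entry
                donor = ids.get_loc(str(donor_id))
            else:
                (sid, frac), donor = entry, None
            j = ids.get_loc(str(sid))
            if donor is None:
                donor = rng.choice([k for k in range(n) if k != j])
            x[:, j] = (1 - frac) * x[:, j] + frac * x[:, donor]
            y[:, j] = (1 - frac) * y[:, j] + frac * y[:, donor]
    out = gset.copy()
    out.x, out.y = x, y
    return out


# ---------------------------------------------------------------------------
# trios
# ---------------------------------------------------------------------------

def simulate_trios(config: SimConfig, n_trios: int = 10,
                   planted_errors: int = 0, cohort: str = "trios"):
    """Simulate parent-offspring trios; returns ``(GenotypeSet, truth)``.

    Parents are drawn from population 0's allele frequencies; each offspring
    inherits one allele per parent per marker (maternal-only on the male X).
    ``planted_errors`` offspring calls at autosomal markers are overwritten
    with a different dosage to create known Mendelian inconsistencies; the
    ``truth`` frame records (sample, marker, original, planted).
    """
    markers = _simulate_markers(config)
    p = _population_freqs(config)[:, 0]
    rng = _rng(config, f"samples/{cohort}")
    m = config.n_markers
    chrom = markers["chrom"].to_numpy()
    is_x, is_y = chrom == "X", chrom == "Y"
    is_auto = ~(is_x | is_y)

    cols, rows_meta = [], []
    for t in range(n_trios):
        dad = rng.binomial(2, p).astype(np.int8)
        mom = rng.binomial(2, p).astype(np.int8)
        dad[is_x] = rng.binomial(1, p[is_x]).astype(np.int8) * 2
        dad[is_y] = rng.binomial(1, p[is_y]).astype(np.int8) * 2
        mom[is_y] = MISSING
        kid_sex = "male" if rng.random() < config.sex_fractions[0] / sum(
            config.sex_fractions) else "female"
        pat = rng.binomial(1, dad / 2.0).astype(np.int8)
        mat = rng.binomial(1, mom.clip(0) / 2.0).astype(np.int8)
        kid = (pat + mat).astype(np.int8)
        if kid_sex == "male":
            kid[is_x] = mat[is_x] * 2
            kid[is_y] = dad[is_y]
        else:
            kid[is_x] = (dad[is_x] // 2 + mat[is_x]).astype(np.int8)
            kid[is_y] = MISSING
        fid, mid, kid_id = f"fa{t:02d}", f"mo{t:02d}", f"kid{t:02d}"
        cols += [dad, mom, kid]
        rows_meta += [
            dict(id=fid, family=f"trio{t:02d}", sex="male"),
            dict(id=mid, family=f"trio{t:02d}", sex="female"),
            dict(id=kid_id, family=f"trio{t:02d}", sex=kid_sex,
                 father=fid, mother=mid),
        ]
    calls = np.stack(cols, axis=1)
    if config.missing_rate > 0:
        drop = rng.random(calls.shape) < config.missing_rate
        calls[drop] = MISSING

    samples = pd.DataFrame(rows_meta)
    truth = []
    if planted_errors:
        kid_cols = np.arange(2, calls.shape[1], 3)
        eligible = np.array([(i, j) for j in kid_cols
                             for i in np.nonzero(is_auto)[0]
                             if calls[i, j] != MISSING])
        pick = eligible[rng.choice(len(eligible), size=planted_errors,
                                   replace=False)]
        for i, j in pick:
            old = int(calls[i, j])
            new = int(rng.choice([g for g in (0, 1, 2) if g != old]))
            calls[i, j] = new
            truth.append(dict(sample=samples["id"].iat[j],
                              marker=markers["name"].iat[i],
                              original=old, planted=new))
    gset = make_genotype_set(calls, markers, samples)
    return gset, pd.DataFrame(truth, columns=["sample", "marker",
                                              "original", "planted"])


# ---------------------------------------------------------------------------
# FinalReport fixture writer
# ---------------------------------------------------------------------------

def write_finalreport(gset: GenotypeSet, path,
                      dialect: Optional[FinalReportDialect] = None,
                      zip_compress: bool = False) -> None:
    """Write a syntactically valid FinalReport for ``gset`` (sample-major,
    header block, 6-decimal intensities), optionally wrapped in a ZIP."""
    if gset.x is None or gset.y is None:
        raise SNPArrayError("FinalReport output requires x/y intensities")
    if dialect is None:
        dialect = FinalReportDialect()
    d = dialect.delimiter
    miss = dialect.missing_token
    lines = []
    if dialect.has_header_block:
        lines += ["[Header]",
                  f"GSGT Version{d}synthetic",
                  f"Num Used SNPs{d}{gset.n_markers}",
                  f"Num SNPs{d}{gset.n_markers}",
                  f"Num Samples{d}{gset.n_samples}",
                  f"Total Samples{d}{gset.n_samples}",
                  "[Data]"]
    coding = "AB" if dialect.allele_coding == "AB" else "Top"
    lines.append(d.join(["SNP Name", "Sample ID",
                         f"Allele1 - {coding}", f"Allele2 - {coding}",
                         "X", "Y"]))
    names = gset.marker_names.to_numpy()
    if dialect.allele_coding == "AB":
        tok = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"),
               MISSING: (miss, miss)}
        tokens = [tok] * gset.n_markers
    else:
        tokens = []
        for i in range(gset.n_markers):
            a = gset.markers["allele_A"].iat[i]
            b = gset.markers["allele_B"].iat[i]
            tokens.append({0: (a, a), 1: (a, b), 2: (b, b),
                           MISSING: (miss, miss)})
    for j, sid in enumerate(gset.sample_ids):
        for i in range(gset.n_markers):
            a1, a2 = tokens[i][int(gset.calls[i, j])]
            lines.append(d.join([names[i], sid, a1, a2,
                                 f"{gset.x[i, j]:.6f}", f"{gset.y[i, j]:.6f}"]))
    text = "\n".join(lines) + "\n"
    path = Path(path)
    if zip_compress or path.suffix == ".zip":
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr(path.stem + ".txt", text)
    else:
        path.write_text(text, encoding="utf-8")
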