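# Methods

This note documents the models and numerical choices behind `snparray`: what
each stage computes, the assumptions it makes, and what the synthetic-data
generator does and does not emulate.

## Data model

A dataset is a markers × samples matrix of biallelic genotype calls stored
alongside a marker map and a sample (pedigree) table, with optional
two-channel hybridization intensities and derived BAF/LRR tracks — the same
decomposition as a PLINK fileset. Calls are coded as the dosage of the
Illumina **B** allele (0 = AA, 1 = AB, 2 = BB, −1 = no-call). B-dosage was
chosen over reference-allele counts so the call code is oriented the same way
as the B-allele frequency axis; display-level flips to reference-allele
counts live in `viz.dotplot_data`. Positions are 1-based and genomic region
queries are closed intervals, matching array-manifest conventions. Markers
are always kept sorted by (chromosome, position) — numeric chromosomes first,
then X, Y, the XY pseudoautosomal label, and mitochondria — and every matrix
is permuted in lockstep, so construction is idempotent and subsetting can
never desynchronize the metadata from the matrices.

The container is agnostic about whether stored intensities are raw or have
been through the vendor's affine normalization; the `normalized` flag records
only whether tQN has been applied.

## Intensity coordinates

Each SNP's two channels (x for allele A, y for allele B) are summarized in
polar coordinates: theta = (2/π)·arctan2(y, x) ∈ [0, 1] and total intensity
R = x + y. The two-argument arctangent maps x = 0 to theta = 1 exactly, and
theta is computed by dividing by π/2 (rather than multiplying by 2/π) so that
the axes and the diagonal land on 0, 0.5 and 1 bit-exactly. In a clean
diploid sample AA/AB/BB clusters sit near theta ≈ 0, 0.5, 1 with R ≈ 1.

## Thresholded quantile normalization (tQN)

Residual dye bias between the two Infinium color channels is removed by
quantile-normalizing the x channel against the y channel **within** each
array: the target distribution is the mean of the two sorted channels and
each channel is mapped through it by rank (ties mapped to the average of the
tied target values). Because unrestricted QN can drag outlying probes across
the plane and destroy copy-number signal, each normalized value is capped at
`threshold` × its raw value (multiplicative cap, default 1.5, matching the
method's reference implementation; exact zeros pass through unchanged). An
optional between-array quantile normalization per channel can precede the
within-array step; it is **off by default**.

Known limitation: within-array QN of one channel against the other assumes
the two channels are compositionally exchangeable. At desk scale
(~2,000 markers) a sample's genotype composition (its overall B-allele load)
skews the two channel distributions and induces a per-array theta offset of
order ±0.02 after normalization; the offset is zero-mean across arrays and
shrinks roughly with marker count, so it is negligible at real array sizes
(tens of thousands of markers). Consequently the calibration guarantees below
are stated as expectations over a cohort, not per-array bounds.

## Reference clusters, BAF and LRR

Genotype-conditional cluster centroids (theta_g, r_g) per marker are
estimated from a reference panel as the **median** theta and R of reference
samples carrying each call — medians rather than means for robustness to
miscalls. The reference intensities are first pushed through the *identical*
normalization chain used for test samples, so centroids and observations
share one scale. Classes backed by fewer than `min_cluster_size` (default 3)
reference samples are imputed and flagged: a missing heterozygote centroid is
the midpoint of the flanking homozygotes (R their mean); a missing homozygote
mirrors the other about theta = 0.5 with the same R; when only the
heterozygote is observed the homozygotes are placed symmetrically about it.
Markers with no usable class, or whose centroids are not monotone in theta,
are excluded and yield missing BAF/LRR.

On the sex chromosomes, centroids are estimated from the subset of reference
samples that is diploid there when sex metadata is available (X from females,
Y from males). This keeps the X reference level on the diploid scale, so a
hemizygous male X shows its expected depressed LRR instead of dragging the
reference level down toward itself.

**BAF** is the piecewise-linear rescaling of theta anchored at the centroids:
0 at/below theta_AA, exactly 0.5 at theta_AB, 1 at/above theta_BB, linear
between. Coincident anchors (a degenerate marker) make the interior
interpolation undefined; those thetas get missing BAF rather than an
arbitrary value. **LRR** is log2(R / R0), where R0 is the linear
interpolation of (theta_g, r_g) at the observed theta, clamped to the outer
centroids beyond them — no extrapolation, which would otherwise produce
negative or exploding reference levels near the axes. LRR is missing
wherever R ≤ 0 or R0 ≤ 0.

For an uncontaminated euploid sample the expected LRR is 0 and the expected
BAF at heterozygous calls is 0.5; a hemizygous male X shows no BAF near 0.5
and depressed LRR. These are the calibration properties the acceptance
script measures.

## Quality control

Per-sample statistics: genotype-class counts, call rate, median and IQR of
R. Thresholds for flagging apply to raw per-array counts of missing and
heterozygous calls (an array hybridization failure inflates the counts
directly; rates are reported alongside), with optional subgroup-specific
thresholds; flagging is monotone in the thresholds. Sex is inferred from the
X heterozygosity rate (males, hemizygous, sit near 0; default threshold 0.1)
and, when available, the median R over Y probes (default threshold 0.3,
midway between the ~0.1 female background and the ~0.5 hemizygous male signal
of the intensity model). Conflicting lines of evidence yield "unknown"
rather than a guess. Pseudoautosomal ("XY") markers are excluded from X
heterozygosity. Both thresholds are configurable and echoed into outputs.

## Population-genetic summaries

IBS sharing at one marker is the matched fraction of the four allele
comparisons, (2 − |d_i − d_j|)/2 for dosages d; distance is 1 − mean sharing
over jointly called markers, with pairs below `min_overlap` masked. The
distance matrix is clustered with average-linkage agglomerative clustering
(configurable; the linkage choice was open and average is the common default
for kinship heatmaps). PCA mean-imputes missing calls per marker, centers,
optionally scales by the binomial dosage SD √(2p(1−p)) (both modes provided;
unscaled is the default), and takes an SVD; each component's sign is fixed by
making its largest-magnitude marker loading positive, so results are
reproducible and invariant (up to that convention) to marker order.

Mendelian checks enumerate gametes: a tested marker (offspring called, at
least one parent called) is inconsistent iff no paternal × maternal gamete
combination yields the offspring dosage; single-parent duos use the weaker
shared-allele rule; on the X, male offspring must match a maternal allele
(heterozygous male X calls are themselves inconsistent) and female offspring
receive the hemizygous father's single allele, with a heterozygous paternal
X call treated as uninformative. Y and pseudoautosomal markers are not
tested.

## Merging and parental recoding

Datasets are joined on marker name (then verified against chromosome and
position — name-only joins are fragile, position-only joins break on
multi-mapping manifests). The second dataset's allele encoding is reconciled
marker-by-marker: identical → keep; swapped A/B labels → flip dosages
d → 2 − d; complementary (reverse-strand) → complement then reconcile.
Strand-ambiguous SNPs (A/T, C/G) are kept when the encodings already agree
and dropped on any conflict, since complementation is indistinguishable from
a swap there. The merge keeps the intersection of markers; more than 50%
dropped is treated as an error. Recoding against parental lines keeps only
markers where the two parents are opposite homozygotes and re-expresses
dosage as the count of parent-B alleles.

## Haplotype-mosaic HMM

The hidden state is the reference haplotype being copied (haploid) or the
unordered haplotype pair (diploid, H(H+1)/2 states). Between markers
d centimorgans apart each chromosome of ancestry keeps its haplotype with
probability exp(−jump_rate·d); otherwise the new haplotype is uniform over
the whole panel (the standard copying-model form — it gives the identity at
d = 0, the uniform distribution as d → ∞, and composes exactly across merged
intervals, so dropping an uninformative marker never changes the decode).
Diploid transitions factor as two independent haploid chromosomes mapped
onto unordered pairs. Emissions flip each allele independently with
probability ε ∈ (0, 0.5); missing observations emit probability 1 for every
state. Decoding (Viterbi, ties toward the lowest-index state) and posteriors
(forward–backward) are computed in log space throughout — ample at the
tens-of-thousands-of-markers scale this package targets, with no need for
scaling tricks. Observations are genotype dosages, not intensities.

## Synthetic data

The generator emulates the features the pipeline consumes, with known ground
truth and bit-reproducibility under a seed:

* **Markers**: spread over 19 autosomes plus X (5%) and Y (1%) by default,
  uniform positions, a ~0.5 cM/Mb genetic map, random distinct A/B
  nucleotides.
* **Genotypes**: ancestral B-allele frequencies Uniform(0.05, 0.95);
  population structure as independent logit-normal drift per population with
  SD = 2·divergence (default divergence 0.3) — sufficient to produce the
  kinship-block and PCA-cluster structure of real multi-population cohorts
  without coalescent machinery. Genotypes are Binomial(2, p); male X and Y
  are haploid (coded 0/2), female Y is missing. Default 3 populations × 10
  samples, 2,000 markers, 1% missing calls, balanced sexes.
* **Intensities**: polar coordinates drawn Normal around canonical centroids
  (theta 0.05/0.5/0.95, R 1.0, noise sigma 0.03) and inverted to channels
  exactly, so x + y equals the drawn R to the last bit and zero noise
  round-trips the centroids exactly. Hemizygous loci scale R by 0.5; female
  Y probes emit uniform-theta background at R ≈ 0.1. Contamination mixes two
  samples' channel intensities at a stated fraction (donor explicit or
  random).
* **Trios**: parents drawn from population frequencies, offspring inheriting
  one gamete per parent (maternal-only on the male X), with an optional
  number of planted genotype errors at known markers for validating the
  Mendelian checks.
* **FinalReport writer**: a syntactically valid header + `[Data]` long-format
  file (optionally ZIP-wrapped) that round-trips exactly on calls and to six
  decimals on intensities.

Different cohort labels under one configuration (e.g. a test cohort and a
reference panel) share markers and allele frequencies but draw independent
samples, each from its own seeded stream.

**What the generator does not emulate** — and hence what passing tests do not
demonstrate about real data: linkage disequilibrium (markers are
independent), batch effects and plate structure, the vendor's affine
normalization artifacts, marker-specific failure modes (paralogy, null
alleles), and realistic pedigree structure beyond independent trios.
Genotype calls are inputs to the simulation, not re-called from intensities,
so call/intensity discordance only arises where the tests plant it.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to exercise every
code path while staying far from numerical degeneracy: calibration cohorts of
20 samples (plus 50 reference samples) × 2,000 markers; structure cohorts of
28 samples in 3 populations; HMM panels of 4 haplotypes × 500 markers, with
brute-force oracles at ≤ 8 markers × ≤ 3 haplotypes. The implementation
itself is vectorized and comfortably handles the tens-of-thousands-of-markers
× hundreds-of-samples datasets it is designed for.
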