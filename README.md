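# snparray

Quality control, normalization and exploratory genetic analysis for Illumina
Infinium-style SNP genotyping arrays — a Python library plus a `snparray`
command-line tool for the "medium-sized" datasets (tens of thousands of
markers, hundreds of samples) common in experimental and population genetics.

Infinium arrays report, for every SNP and sample, a discrete genotype call
and two fluorescence intensities (x for the A allele, y for the B allele).
Most downstream genetics tooling consumes only the calls; the intensities,
however, carry the signal needed to catch failed arrays, contaminated or
swapped samples, and copy-number anomalies. `snparray` keeps calls,
intensities, marker map and pedigree together in one container and provides:

* **Parsing** of BeadStudio/GenomeStudio FinalReport exports (plain or
  ZIP-compressed, A/B or nucleotide allele coding, dialect-tolerant column
  matching), and bit-exact **PLINK .bed/.bim/.fam** read/write plus R/qtl
  and HGDP export.
* **Sample QC**: call-rate / heterozygosity / intensity summaries,
  threshold-based flagging (global or per subgroup), and sex inference from
  X heterozygosity and Y intensity with concordance checks against recorded
  sex.
* **Normalization**: thresholded quantile normalization (tQN) of the two
  channels within each array, then **BAF** and **LRR** against genotype
  cluster centroids estimated from reference samples. In polar coordinates
  theta = (2/π)·arctan2(y, x), R = x + y:

      BAF  = piecewise-linear(theta; theta_AA -> 0, theta_AB -> 0.5, theta_BB -> 1)
      LRR  = log2( R / R0(theta) )

  with R0 interpolated between the reference centroids. For a clean euploid
  sample E[LRR] = 0 and E[BAF | het] = 0.5; a hemizygous male X shows no BAF
  near 0.5 and depressed LRR.
* **Genetics tools**: allele frequencies, IBS distance / kinship with
  hierarchical-clustering order for heatmaps, genotype PCA, Mendelian
  -inconsistency checks for trios, dataset merging with allele-encoding and
  strand-swap reconciliation, parental-line recoding, and a reference-panel
  haplotype-mosaic HMM (Viterbi + posteriors) over a genetic map.
* **A synthetic-data generator** (`snparray.simdata`) producing genotypes,
  cluster-model intensities, trios, contamination and FinalReport fixtures
  with known ground truth, so the entire pipeline is testable offline.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a 3-population cohort, run QC, convert to PLINK and inspect
structure — entirely from the command line:

```sh
$ snparray simulate --pops 3 --per-pop 10 --markers 2000 --seed 17 --out demo
wrote demo_finalreport.txt (2000 markers x 30 samples)

$ snparray qc --beadstudio demo_finalreport.txt --manifest demo_manifest.tsv \
      --max-missing 100 --out qc.tsv
0 of 30 samples flagged

$ snparray convert --beadstudio demo_finalreport.txt \
      --manifest demo_manifest.tsv --to plink --out demo
converted 2000 markers x 30 samples

$ snparray pca --plink demo -k 2 --out pcs.tsv
top 2 PCs explain 14.6% of variance
```

`qc.tsv` holds one row per sample (counts, call rate, intensity median/IQR,
X-het rate, Y intensity, inferred sex, concordance, pass/fail flag); with
these thresholds no simulated array fails. The two leading PCs carry 14.6%
of the genotype variance (7.6% + 7.0%) — two components standing far above
the rest is the classic signature of three well-separated populations, and
plotting `pcs.tsv` shows the 30 samples in three tight clusters matching
`demo_truth.tsv`.

The same steps in Python:

```python
import snparray as sp

cfg = sp.SimConfig(n_pops=3, n_per_pop=10, n_markers=2000, seed=17)
gset, pops = sp.simulate_genotypes(cfg)
gset = sp.simulate_intensities(gset, cfg)

clusters = sp.estimate_clusters(gset)          # or a separate reference panel
norm = sp.tqn(gset, clusters, threshold=1.5)   # adds .baf / .lrr tracks
qc = sp.sample_qc(norm)
proj, var_explained = sp.pca_genotypes(gset, k=2)
```

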