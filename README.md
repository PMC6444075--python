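# copulamri

Copula-based interdependence analysis of paired quantitative MRI maps, for
unsupervised subtyping of glioblastoma (or any tumor cohort with two
co-registered parametric maps).

Diffusion MRI's apparent diffusion coefficient (ADC) probes tumor
microstructure; perfusion MRI's relative cerebral blood volume (rCBV) probes
vascularity. Each map alone is an established biomarker, but *how the two
co-vary voxel-by-voxel inside a tumor* — whether cellularity and vascularity
are coupled or decoupled — is information neither map carries alone.
`copulamri` quantifies exactly that interdependence and uses it to stratify
patients.

## Method

For each patient, the paired within-tumor voxel values
(x&#8321;,y&#8321;),…,(x&#8345;,y&#8345;) of the NAWM-normalized ADC and rCBV
maps are mapped to pseudo-observations by the **empirical copula transform**

  u&#8342; = rank(x&#8342;)/(n+1),  v&#8342; = rank(y&#8342;)/(n+1),

which discards both marginal distributions (and with them scanner- and
sequence-dependent scaling: any strictly increasing distortion of either map
leaves the result bit-identical) and keeps only the dependence structure.
The pairs (u&#8342;,v&#8342;) are binned on an equal-width 10 × 10 grid over
the unit square, giving a **joint-distribution matrix** p(i,j): near-uniform
when ADC and rCBV are independent, concentrated on the main diagonal when
they are strongly coupled.

Nine second-order (Haralick-style) statistics summarize each patient's
matrix — Energy, Contrast, Entropy, Homogeneity, Correlation, SumAverage,
Variance, Dissimilarity, AutoCorrelation (formulas in
[docs/methods.md](docs/methods.md)). The cohort's patients × 9 feature table
is z-scored and clustered by agglomerative hierarchical clustering with
**complete linkage**; the cluster count is chosen by **majority vote among a
battery of classical cluster-validity indices** over k = 2…10. Cluster
stability is assessed by leave-one-out consensus: the consensus matrix
M(i,j) is the fraction of leave-one-out repetitions in which patients i and
j co-cluster. Subtypes are then compared on any per-patient quantity
(Kruskal-Wallis with Benjamini-Hochberg FDR control) and on survival
(Kaplan-Meier, log-rank, and univariate/multivariate Cox
proportional-hazards models with the subtypes encoded as indicators against
the intermediate-interdependence subtype).

A synthetic-cohort generator (Gaussian copula with tunable correlation ρ,
realistic NAWM-normalized marginals, exponential subgroup-linked survival)
makes the whole pipeline testable without patient data.

## Worked example

Library use — one strongly coupled patient (ρ = 0.9, 4,000 voxels):

```python
from copulamri import SubgroupSpec, sample_patient, patient_matrix, second_order_features

spec = SubgroupSpec("demo", dependence_rho=0.9, n_patients=1, voxels_per_patient=4000)
sample = sample_patient(spec, seed=42)
m = patient_matrix(sample, bins=10)          # 10x10 joint-distribution matrix
fv = second_order_features(m)
print(f"energy={fv.energy:.4f} contrast={fv.contrast:.3f} "
      f"entropy={fv.entropy:.3f} correlation={fv.correlation:.3f}")
```

```
energy=0.0271 contrast=1.927 entropy=5.562 correlation=0.883
```

High matrix correlation and low contrast/entropy are the signature of a
diagonalized joint distribution — tightly coupled diffusion and perfusion.
An independent patient (ρ ≈ 0) instead approaches the uniform matrix
(energy 0.01, entropy log₂100 ≈ 6.64, correlation 0).

Command line — simulate a 30-patient, three-subgroup cohort as NIfTI images
and run the full pipeline:

```bash
copulamri simulate --out-dir demo --seed 5 --n-patients 30 --voxels 1000
copulamri run-all --manifest demo/manifest.csv --clinical demo/clinical.csv --out-dir demo/out
```

```
k=3, cluster sizes {1: 10, 2: 13, 3: 7}, consensus means {1: 1.0, 2: 1.0, 3: 1.0}
```

The validity-index vote recovers the three generating subgroups
(10/13/7 ≈ the 35/42/23% cohort proportions), and every subtype is
perfectly stable under leave-one-out re-clustering. `demo/out/` holds
`features.csv`, `labels.csv`, `consensus.csv`, `votes.csv`,
`group_stats.csv`, `cox_os.csv`, `cox_pfs.csv` and `run_meta.json` (the
config echo that makes the run bit-reproducible). The staged subcommands
`transform`, `features`, `cluster`, `consensus` and `survival` expose the
same pipeline one CSV-to-CSV step at a time; for real cohorts, point
`--manifest` at a CSV listing each patient's ADC/rCBV/tumor-mask/NAWM-mask
NIfTI paths.

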