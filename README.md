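# icaclust

Clustering of short gene-expression time series (GETS) by a two-step method:
**independent component analysis** followed by **Ward hierarchical clustering
with Mojena's stopping rule**.

## The problem

RNA-seq time-course experiments measure read counts for thousands of genes at
a handful of time points (often 3–5). Grouping genes by temporal expression
pattern is the standard way to summarise such data, but the usual tools fit it
poorly: counts are not Gaussian, the series are too short for model-based
(likelihood) clustering, and k-means or plain hierarchical clustering treat
the time points as independent variables, ignoring the serial dependence
between adjacent measurements — and k-means additionally requires the number
of clusters up front.

The two-step method implemented here addresses all three issues:

1. **Decomposition.** The genes × time matrix *Y* (m genes, N time points;
   each row the mean expression of one gene over time) is modelled as a linear
   mixture of statistically independent components, *Y = A·S*. The mixing
   matrix is estimated as *A ≈ K·R* — PCA whitening *K* followed by an
   orthogonal rotation *R* chosen by FastICA's symmetric fixed-point iteration
   (logcosh contrast). Because the series are short, all N components are kept
   (k = N), so no information is discarded. Each gene receives a k-vector of
   component scores; these scores — not the raw time columns — are the
   clustering features, which is how the temporal dependence enters the
   clustering. ICA makes no distributional assumption, so count data are fine.
   Pairwise independence of the recovered components can be verified with
   Hoeffding's nonparametric D test (permutation p-values).

2. **Clustering.** The score vectors are agglomerated by Ward's
   minimum-variance method: at each stage the pair of clusters A, B minimising
   the within-group sum-of-squares increment
   *I*<sub>AB</sub> = n<sub>A</sub>n<sub>B</sub>/(n<sub>A</sub>+n<sub>B</sub>) · ‖ȳ<sub>A</sub> − ȳ<sub>B</sub>‖²
   is merged. The number of clusters is chosen automatically by **Mojena's
   rule**: with fusion heights α₁ ≤ … ≤ α<sub>m−1</sub>, the first stage *j*
   with α<sub>j</sub> > ᾱ + c·S<sub>α</sub> selects k = m − j + 1 clusters
   (default c = 3.50).

The package also ships a **simulator** for temporally autocorrelated Poisson
counts (Gaussian copula with AR(1) correlation, per-cluster rate profiles and
per-gene rate jitter) and an **evaluation harness** that scores clusterings by
the correct classification rate (CCR: fraction of genes in their true cluster
after optimal one-to-one label matching) and benchmarks the method against
k-means.

## Worked example

```python
from icaclust import SimulationConfig, simulate_dataset, ICAClust, ccr

cfg = SimulationConfig(seed=1)             # 458 genes, 6 clusters, 4 times
data = simulate_dataset(cfg, replicate=0)  # genes x time count DataFrame

model = ICAClust(c=3.00, random_state=1).fit(data.counts)
print("selected clusters:", model.n_clusters_)
print("Mojena threshold: %.1f" % model.mojena_.threshold)
print("CCR vs simulation truth: %.1f%%" % ccr(data.true_labels, model.labels_).percent)
```

prints

```
selected clusters: 6
Mojena threshold: 100.5
CCR vs simulation truth: 99.6%
```

The simulated dataset has six groups of genes with distinct 4-point temporal
profiles; Mojena's rule recovers the six groups without being told the number,
and 99.6 % of the 458 genes land in their true cluster after optimal label
matching. `model.decomposition_` holds the component scores, temporal mixing
matrix, whitening and rotation matrices; `model.dendrogram_` the Ward merge
history.

The same pipeline runs from the shell on real tables:

```bash
icaclust run --input counts.tsv --sample-sheet sheet.csv \
    --conditions piau,commercial --c 3.5 --seed 0 --out results/
icaclust simulate --replicates 10 --seed 1 --out sim/
icaclust compare --k-grid 2:7 --c-grid 2.25:3.75:0.25 --seed 1 --out cmp/
icaclust evaluate --truth sim/truth_rep00.tsv --predicted results/clusters.tsv
```

`run` accepts either a pre-averaged genes × time series matrix, or a count
matrix plus a sample sheet (replicates are averaged per time point, and with
`--conditions a,b` the per-gene log2(a/b) fold-change series is clustered).

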