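# echemfp

Electrochemical-fingerprint chemotaxonomy: from differential-pulse
voltammograms (DPV) of plant extracts to a phenetic dendrogram.

Plants' electroactive compounds (flavonoids, phenolic acids, ascorbate,
…) are under genetic control, so the DPV trace of a leaf extract — its
*electrochemical fingerprint* — carries a chemical signature of
relatedness: closely related species show similar fingerprints, distant
ones differ.  Recording each specimen under two conditions (water
extract in pH 7.0 phosphate buffer; ethanol extract in pH 4.5 acetate
buffer) widens the set of compounds seen.  `echemfp` implements the full
analysis chain used in this kind of study, for researchers who want to
evaluate or reuse it with controlled, simulated data:

1. **Simulation** — a known phylogeny (Yule ingroup + distant outgroup),
   compound concentrations evolving by geometric Brownian motion along
   its branches, and DPV traces rendered as Gaussian oxidation peaks
   over 0–1.3 V with replicate amplitude jitter and noise;
2. **Preprocessing** — resampling to a canonical 326-point grid,
   per-curve min–max normalization, replicate averaging;
3. **Pattern recognition** — the potential axis is deleted and the two
   condition traces are fused into a scatter on [0, 1]², summarized as a
   kernel-density map and a binned heatmap with "hot area" counting;
4. **Chemometrics** — a taxa × 652 feature matrix (the two concatenated
   traces) and PCA with explained-variance reporting;
5. **Phylogram** — Euclidean distances, UPGMA dendrogram with Newick
   export, clade labels at a chosen k, and recovery metrics (cophenetic
   correlation, adjusted Rand index) against the simulated ground truth.

## Worked example

```sh
echemfp run-all --out results/demo --seed 0
```

prints

```
echemfp: simulating world (seed=0)
echemfp: preprocessing: normalization=minmax, grid=326 points
echemfp: fusion: bins=25, density grid=50, bandwidth=scott, hot quantile=0.75
echemfp: PCA: 3 components explain 73.5% of variance
echemfp: clustering: metric=euclidean, linkage=average, k=5
36 taxa, 216 traces; 73.5% variance in 3 components; cophenetic r = 0.9555
```

The default world has 31 ingroup and 5 outgroup taxa, each measured
under 2 conditions with 3 replicates (216 traces).  The three leading
principal components of the 36 × 652 fingerprint matrix carry 73.5 % of
the variance (44.7 + 19.7 + 9.0; see `explained_variance.csv`), i.e.
the fingerprints are low-dimensional enough to summarize but not
trivial.  The cophenetic correlation of 0.956 says the UPGMA dendrogram
(`dendrogram.nwk`) represents the pairwise fingerprint distances
faithfully.  `report.json` additionally records that cutting the
dendrogram into two groups exactly separates the 5 outgroup taxa from
the 31 ingroup taxa (`ari_outgroup_k2 = 1.0`) and that the planted
clades of the true tree are recovered with adjusted Rand index 0.85
(`ari_true_clades`).  Per-species hot-area counts — the number of
connected high-density regions in each fused fingerprint, a compact
species-discriminating feature — are in `hot_areas.csv`.

The same stages are available individually (`simulate`, `preprocess`,
`fuse`, `pca`, `cluster`, `evaluate`), all driven by a YAML config, and
as library functions:

```python
from echemfp import (SimulationConfig, generate_dataset, build_fingerprints,
                     build_feature_matrix, distance_matrix, upgma, to_newick)

world = generate_dataset(SimulationConfig(seed=0))
X = build_feature_matrix(build_fingerprints(world.panel))
print(to_newick(upgma(distance_matrix(X)))[:80], "...")
```

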