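# Methods

`echemfp` implements an electrochemical-fingerprint chemotaxonomy
pipeline: differential-pulse voltammograms (DPV) of plant extracts,
recorded under two extraction/electrolyte conditions, are normalized,
fused into pattern-recognition representations, and clustered into a
phenetic dendrogram whose clades are read as a phylogenetic hypothesis.
Because no public voltammogram panel of this kind exists, the package
ships a first-class synthetic-data generator whose ground truth (a tree,
compound concentrations) makes every downstream stage testable.

## The generative model

**Phylogeny.** A rooted binary ultrametric tree: a pure-birth (Yule)
ingroup crown and a pure-birth outgroup crown joined at the root.  The
two root-child stems have unscaled length 0.3 and are multiplied by
`outgroup_branch_scale` (default 5), so every outgroup–ingroup path is
longer than any within-group path.  The outgroup crown is scaled to 0.2
of the ingroup crown's depth: the outgroup stands for a coherent set of
taxa sharing derived chemistry, mirroring the empirical observation that
out-taxa cluster together.  (With equal crown depths, five outgroup taxa
are as internally diverse as a 31-taxon ingroup and fragment under
average-linkage clustering rather than forming a clade.)  The whole tree
is rescaled to unit depth.

**Chemistry.** Each of `n_compounds` (default 150) electroactive
compounds evolves independently by geometric Brownian motion: the
log-concentration diffuses with variance `sigma^2 × branch length`
(`sigma` = 0.5 per unit tree depth), so concentrations stay positive and
closely related species have similar compound profiles — the premise
that makes chemotaxonomy work.  Root log-concentrations are drawn from
N(0, 0.25).

**Electrochemistry.** A compound contributes a Gaussian oxidation peak:

    current(E) = a · Σ_c conc_c · eff_c(cond) · exp(−(E − μ_c(cond))² / 2w_c²)
                 + baseline(E) + ε(E)

Three compounds sit near 0.4 V (the ascorbate/luteolin region of leaf
extracts); the rest are uniform on 0.55–1.1 V where phenolics oxidize.
Peaks under the pH 4.5 acetate condition are shifted +0.06 V relative to
pH 7.0 phosphate (proton-coupled oxidations shift anodically at lower
pH).  Per-condition extraction efficiencies `eff_c` ~ Beta(2, 2) model
which compounds each solvent/electrolyte combination can see; a
compound may be invisible under one condition.  The per-replicate
amplitude `a` is lognormal with coefficient of variation
`replicate_amplitude_cv` (default 0.08) — replicates vary in peak
*intensity*, never in peak *potential*, matching how repeat DPV
recordings behave (electrode-area differences rescale the whole
curve).  `ε` is iid Gaussian (`noise_sd`, default 0.01) and the baseline
is a smooth monotone quadratic reaching `baseline_amplitude` (default
0.1) at the anodic end of the 0–1.3 V window.

**Peak widths are deliberately narrow** (sd 4–7 mV, versus the tens of
mV of a broad experimental DPV envelope).  The Gaussian peak basis is
band-limited: roughly `window / width` bands are spectrally resolvable,
and that number caps the effective character count the trace can carry.
With realistic broad peaks only ~15 effective characters survive per
condition, which is too few for Brownian distances to concentrate — no
clustering method could then recover the tree reliably.  Narrow peaks
let each compound remain resolvable, which is what makes the premise
"fingerprints are phylogenetically informative" true inside the model.
The same reasoning sets the compound panel at 150: with only ~a dozen
compounds, even the noise-free log-concentration matrix (the most any
method could use) fails to recover planted structure, because
Brownian *sampling* variance across so few characters swamps the
patristic signal.  Passing tests on this generator therefore show that
the pipeline recovers structure when the chemistry carries enough
information; they do not show that any particular real assay carries
that much.

**Randomness.** All stages draw from named substreams of a single root
seed (tree, compound panel, traits, one stream per trace keyed by
taxon × condition × replicate), so changing one stage's parameters
never perturbs another stage's draws.

## Planted clades

`true_clades` cuts the realized tree at the midpoint of the largest
internal-node-free height interval within 5–95 % of the crown depth:
clades are the groups separated by the longest pause in diversification
— the most salient structure a reader would mark on a dendrogram.  The
clade count is therefore seed-dependent (typically 3–7 at the default
design).

Exact recovery of this partition by the fingerprint dendrogram is *not*
guaranteed even without measurement noise: the fingerprints realize one
Brownian sample per lineage, and the trace representation (band-limited
peak basis, exponentiation of the log-scale walk, per-curve min–max
normalization) each shave fidelity.  At the default design the recovery
ARI is typically 0.6–0.9.  Measurement noise in the range 0–0.1 barely
moves it: after 3-replicate averaging, iid noise adds a nearly constant
offset to all 652-dimensional squared distances (relative fluctuation
~1/√652), a monotone transform that average-linkage clustering is
largely insensitive to.

## Pipeline stages and defaults

* **Grid** 0–1.3 V, step 0.004 V (326 points); traces are linearly
  interpolated onto it, never extrapolated.
* **Normalization** per-curve min–max to [0, 1] (area normalization
  available).  Pipeline order is fixed: resample → normalize each
  replicate → pointwise mean → re-normalize; the maximum pointwise
  replicate standard deviation is retained as a QC statistic.
* **Fusion** pairs the two condition traces pointwise, discarding the
  potential axis.  Density maps use a Gaussian product kernel with
  per-axis Scott bandwidth (σ_j n^(−1/6)), evaluated at the cell
  centers of a 50×50 grid and renormalized to integrate to exactly 1,
  so the normalization invariant is machine-testable.  Heatmaps are
  25×25 histograms with the top/right boundary closed.  Hot areas are
  8-connected components of cells strictly above the 0.75 quantile of
  the nonzero cells.  Note that the hot-area *count* is not monotone in
  the threshold: raising the threshold can split one area in two
  (any dumbbell-shaped region is a counterexample); counts only become
  monotone in the near-empty regime of isolated hot cells.
* **Features** concatenate the two normalized condition traces
  (36 × 652 at the default design); a pointwise-overlay mode exists.
  Columns are not re-standardized: they already share the [0, 1] scale,
  and standardizing hundreds of correlated columns would inflate noise
  in flat trace regions.
* **PCA** by SVD of the column-centered matrix; component signs fixed
  so the largest-magnitude loading entry is positive, making results
  platform-stable.
* **Clustering** Euclidean distances on the feature rows (correlation
  distance available), UPGMA (average linkage; single/complete
  available) with merge height = distance/2 and deterministic
  smallest-index tie-breaking.  The dendrogram is ultrametric and
  exports to Newick with branch length = parent height − child height.
  Cluster count k is never auto-selected; a silhouette table is written
  to inform the choice.  Cophenetic correlation and adjusted Rand
  index quantify dendrogram fidelity and partition recovery.

## Degenerate inputs and numerical choices

Constant traces cannot be min–max normalized and raise a degenerate-
input error (this includes the pointwise mean of mirror-image
replicates).  Correlation distance rejects constant rows; cophenetic
correlation rejects constant distance matrices; density maps reject
fully coincident point sets (zero bandwidth).  Distance symmetry is
enforced to 1e-12; density normalization to 1e-6; the UPGMA argmin is
taken in row-major order so ties resolve to the smallest (i, j) pair.

## Problem sizes

Tests and the acceptance script run the full default design (36 taxa,
216 traces, 652 features) — the study scale this package emulates —
plus 10-seed suites for the recovery properties; unit tests use a 7-taxon
world.  A full pipeline run takes a few seconds on one core.

## Known limitations

* The generator idealizes DPV physics: no scan-rate or kinetics
  modeling, Gaussian peaks narrower than experimental envelopes, no
  correlated (pink/drift) noise, no electrode fouling.
* Brownian evolution cannot produce the qualitative presence/absence
  contrasts between distant families that real secondary metabolism
  shows; the outgroup's separation is purely quantitative.
* Min–max normalization discards all absolute-amplitude information;
  two extracts differing only by a global concentration factor are
  indistinguishable by design.
* UPGMA assumes a constant divergence rate (ultrametricity); it is a
  phenetic method, and the dendrogram is a similarity summary, not a
  model-based phylogeny estimate.
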