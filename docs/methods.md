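# Methods

## The measurement model

An internal-reference isobaric design labels one common region (default
`BA46`) in every multiplexed batch. For each batch run, reporter
intensities are divided by the reference channel per protein, giving
ratios that are comparable across batches; a zero or missing reference
intensity invalidates the whole protein row for that run. Technical
replicate ratios are averaged on the **linear** scale before the log2
transform (`avg_scale="log"` switches to averaging log-ratios; the two
differ by a small Jensen bias of ~½·σ²·ln 2, about 0.01 log2 units at the
default noise). A protein enters the merged matrix only if quantified in
both replicates of every batch — a strict complete-case rule, which is the
conservative reading of replicate-level missing-value exclusion.

Normalization is an alternating median polish: column medians then row
medians are subtracted until the largest absolute row/column median is
≤ 1e-9 (at most 100 sweeps). A single column-then-row pass does not leave
both medians at zero, so iteration is required for the postcondition to be
testable. The reference-region column is identically log2(1) = 0 before
normalization by construction — a structural fact the synthetic truth must
respect (see below).

The inter-region variability filter keeps proteins whose log2 range across
regions is ≥ 1 (max/min fold change ≥ 2). The linear-difference reading of
"difference between maximum and minimum ratios" is rejected as
scale-dependent. The Q3 + 1.5·IQR whisker of all within-protein pairwise
log2 differences is reported as a diagnostic only; the filter itself uses
the fold-change rule.

## Synthetic world

The generator's defaults state the emulated design: 29 regions, 4 batches
of 7 regions + the shared reference, 2 technical replicates, 2000
proteins, 6 region clusters, a planted log2 effect of 1.5 for signature
proteins, additive Gaussian log2 noise of sd 0.25 per measurement
(multiplicative lognormal on intensities), and 5 % dropout.

Choices the design left open, fixed once:

* **Dropout is protein-level per run**, not per channel: a protein
  identified in a run has values in all reporter channels, so isobaric
  missingness operates at the identification level. (Per-channel dropout
  at 5 % combined with the complete-case merge rule would discard ~96 % of
  proteins — clearly not the intended world.) At 5 % per run,
  0.95⁸ ≈ 66 % of proteins survive the merge.
* **The cluster containing the reference region carries no planted
  signatures.** Ratios of the reference to itself are identically 1, so no
  elevation is observable in its column; this cluster is identified by the
  *absence* of elevation, mirroring a heterogeneous/background cluster
  containing the reference area. Cluster-signature fractions
  (10 % of proteins, split over the five signature-bearing clusters) and
  BA-signature fraction (3 %, one or two target regions each) mirror the
  proportions reported for real cortical data (474/4308 and 134/4308).
* **Noise scale**: the only published anchor is a median replicate CV of
  ~6 % per batch; log2 noise of 0.09 reproduces that (CV ≈ |ε₁−ε₂|/√2 for
  lognormal noise), and the default 0.25 is deliberately harder, the same
  order of magnitude but stressing the recovery margin rather than fitting
  the CV.
* **Coupled transcriptome**: counts are gamma-Poisson (dispersion 0.002)
  around means `base · 2^(m + ε)`, ε ~ N(0, 0.1 log2), base median ≈ 700
  counts — deep enough that counting noise (~0.08 log2) does not dominate
  the planted fold changes. Per planted gene one QC-passing region pair
  realizes its concordance category: *agree* copies the protein profile,
  *partially agree* scales it to a 3.2 log2 fold change (same sign,
  magnitudes differing by > 1 log2 unit with margin against noise),
  *disagree* negates it, the *only* and *no change* categories use flat
  profiles with a +2 log2 mRNA elevation where needed. 8 of 29 samples
  fail QC by default (one metric each), matching the reported pass rate.

What a green recovery test does **not** establish: the planted clusters
are symmetric and equally sized, noise is homoscedastic and uncorrelated
across proteins, missingness is MCAR, and there is no ratio compression or
batch interaction — all of which real isobaric data violate to some
degree. Recovery on this world validates the machinery, not field
performance.

## Consensus clustering and k selection

Per k, regions are subsampled at 80 % (features at 100 %) 1000 times
(tests and the acceptance script use 200 — the consensus estimates are
identical within Monte Carlo error at a fifth of the runtime), clustered
by Euclidean k-means (k-means++, 10 restarts), and the consensus matrix is
co-clustering counts over co-sampling counts. The per-k partition is
average-linkage hierarchical clustering of 1 − consensus. k is chosen as
the smallest k whose successor's relative CDF-area gain falls below 0.05,
requiring a positive mean silhouette; the full diagnostics are always
reported and the choice can be overridden.

Two caveats, both verified empirically:

* The area under the consensus CDF equals 1 − mean(consensus); a perfectly
  crisp consensus matrix has area equal to the fraction of zero pairs, so
  the *relative* area gain when a genuine split is added scales with the
  fraction of pairs it touches. With only two true clusters, any third
  cluster touches ~¼–½ of all pairs and the gain never drops below 0.05 —
  automatic selection cannot return k = 2 on clean two-cluster data. With
  six clusters of ~5 regions, an over-split touches ~2 % of pairs and the
  gain collapses (Δ(7) ≈ 0.015), which is why the rule works at atlas
  scale.
* On the default world, Δ(6) sits at ≈ 0.045–0.052 across atlas
  realizations, straddling the 0.05 threshold: automatic selection returns
  6 at some seeds and 5 at others, although the k = 6 partition matches
  the planted labels with ARI 1.0 throughout. The recovery tests fix the
  realization (atlas seed 1), where k = 6 is selected.

## ISA biclustering

Standard up-restricted ISA: from sparse random region seeds (2 regions
each), alternate protein scores = column-standardized matrix × region
scores and region scores = row-standardized matrixᵀ × protein scores,
keeping scores above mean + t·sd of the current score vector (row
thresholds {1.0, 1.5, 2.0, 2.5, 3.0} × column thresholds {1.0, 1.5, 2.0},
200 seeds, each seed run at every grid point). Convergence requires the
protein-score correlation with the previous iteration to reach 0.99 twice
in a row (≤ 100 iterations); non-convergent runs are dropped with a log
entry. Scores are rescaled to max = 1; near-duplicates (region Jaccard
≥ 0.8 and protein-score correlation ≥ 0.9) merge, keeping the module
reached by most seeds as the robust representative.

A module yields cluster signatures iff its regions all lie inside one
cluster and cover ≥ 80 % of it ("no regions outside" is the binding
clause); member proteins with score ≥ 0.7 are pooled per cluster. The
coverage fraction is computed over the cluster's regions, not the
module's — with the no-outside-regions clause the two readings coincide
except for modules strictly inside a cluster, where the cluster-relative
reading is the stricter one.

## BA-level signatures and the cutoff

Within-protein pairwise log2 differences across region pairs are
approximately normal on normalized data; the cutoff is their
mean + 3·SD rounded to the nearest 0.5 (reproducing the 0.00/0.35 → 1.05
→ 1 derivation deterministically). A protein is a signature of its
qualifying regions (excess over its own median ≥ cutoff) iff it qualifies
in one or two regions; proteins elevated in more regions are excluded
entirely rather than redistributed. Note the final call is *not* monotone
in the cutoff even though the qualifying relation is: a three-region
protein excluded at cutoff 1.0 can drop to two qualifying regions at a
stricter cutoff and become callable.

Enrichment is the one-sided hypergeometric over-representation tail by
default; the two-sided option doubles the smaller tail (capped at 1), as
the construction behind a "two-sided hypergeometric test" is otherwise
underdetermined.

## Transcriptome and concordance conventions

* QC thresholds are inclusive (RIN ≥ 6, 28S/18S ≥ 0.7, mapping ≥ 0.4);
  missing metrics fail with reason "missing".
* Median-of-ratios reference genes are those with nonzero counts in every
  sample; size factors are identified only up to the global
  geometric-mean scale, so scale-equivariance holds for size-factor
  ratios.
* Detection keeps genes with count > 1 (strict) in ≥ ⌈50 %⌉ of samples.
* Region profiles average log2(normalized + 1) over a region's passing
  samples.
* Concordance requires both |log2FC| > 1 for the agree/partially
  agree/disagree categories — a change passing the threshold in one
  modality only is routed to the corresponding "only" category regardless
  of direction; this is the unique exhaustive six-way partition. "Same
  magnitude" is the symmetric reading |ΔP − ΔM| ≤ 1 log2 unit. Fold
  changes exactly at the threshold are "no change" (FC ≤ 2). Both
  matrices are zero-mean normalized per gene over the shared regions;
  pair fold changes are themselves shift-invariant, so this affects
  reporting only.

## Numerical conventions

* Tie-break in abundance tiering: descending iBAQ, then protein id; a
  protein straddling a cumulative break belongs to the upper tier.
* Silhouette uses the 0-by-convention for singleton clusters and for
  identical points (0/0 → 0).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give bit-identical synthetic
  fixtures and reports for deterministic stages.

## Known limitations

* No ratio compression, peptide-level modelling, or protein inference —
  the generator and pipeline start at protein-level reporter intensities.
* Module acceptance assumes a hard partition of regions; fuzzy or
  overlapping region clusters are out of scope.
* The download-gated checks against the study's deposited supplementary
  tables (variable-protein and signature counts on real data) are not
  runnable offline and are not part of the test suite.
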