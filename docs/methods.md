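# Methods

## Problem

A signed gene regulatory network (GRN) encodes a qualitative prediction: if
a transcription factor (TF) is upregulated, its activated targets should go
up and its repressed targets down. This package measures how well a signed,
directed GRN explains a compendium of expression contrasts, using a
conservative sign-consistency model, two empirical null models, and
TF–target correlation summaries split by regulatory role. Because the
analysis needs data whose true regulatory structure is known, it ships a
synthetic-world generator that plays the role of an experimental network
plus a public expression compendium plus a kinetic simulator.

## Contrasts and labels

Expression is pooled from several datasets (emulating mixed microarray and
RNA-seq studies). Two normalization stages are implemented:

- **Quantile normalization**, per dataset: each dataset's samples are forced
  onto a common value distribution (the row-wise mean of the column-sorted
  matrix); ties receive the mean of the reference values across the tied
  rank block. Intended for raw-scale data.
- **Per-gene, per-dataset z-scoring** (sample sd, n−1 denominator; constant
  rows map to 0): removes per-dataset gene-level location and scale so
  heterogeneous platforms can be pooled.

A contrast is Δ = mean(case) − mean(reference) within one dataset, so +1
reads "up in the case condition"; the convention is configurable and every
downstream count is invariant to a global sign flip. One global threshold
*t* is calibrated as the (1−f)-quantile of the pooled |Δ| multiset (linear
interpolation), targeting a deregulated fraction f (default 0.5; 1/3 and
2/3 are the conventional alternates). Labels are sign(Δ) where |Δ| > t
(strict), else 0. The achieved fraction is reported because discrete Δ
multisets cannot always hit f exactly.

On simulator output the pipeline applies z-scoring only. Z-scoring is a
positive per-row rescaling within each dataset and therefore preserves
contrast signs exactly, which keeps the noiseless ground-truth recovery
property exact; quantile normalization forces all samples of a dataset onto
one value multiset and would distort cross-sample differences that the
simulator defines on an already comparable scale. QN remains available (and
tested) for data arriving on raw platform scales.

## Conservative sign consistency

For edge u →(s) v and one contrast, with labels ℓ(u), ℓ(v) ∈ {−1, 0, +1}:

- **inconsistent** iff ℓ(u) ≠ 0, ℓ(v) ≠ 0 and ℓ(v) ≠ s·ℓ(u);
- **consistent** iff ℓ(u) ≠ 0, ℓ(v) ≠ 0 and ℓ(v) = s·ℓ(u);
- **indeterminate** otherwise — an "unchanged" label never counts against
  the network (the conservative choice; per sign, exactly 2 of the 9 label
  combinations are inconsistent).

Each edge is assessed independently across all contrasts (no AND/OR logic
for multi-regulator targets; the single-regulator split isolates the
unambiguous cases). Aggregates: the **global** load (total inconsistent
(edge, contrast) cases), per-edge counts (nIncons) and their mean
**mEdge** = Σ nIncons / nPairs, per-contrast counts, and the
activation/repression splits. Edges with a missing expression row are
excluded from nPairs (not silently counted consistent) and reported, as are
unmeasured genes. Self-loops participate; duplicate edges with one sign are
deduplicated; dual-sign pairs abort by default or are quarantined and
reported under a permissive flag, since the sign model is undefined for
them. With an operon map, each member gene inherits the operon's edges and
is assessed per-gene (the least lossy reading of per-operon regulation).

## Null models

- **Profile shuffle**: permute the assignment of expression rows to gene
  ids; topology untouched. Implemented as a permutation of label-matrix
  rows with the threshold held fixed — exactly equivalent to permuting
  contrast rows and relabeling, because labeling is entrywise with one
  global t. Per-iteration recalibration is available behind a flag but off
  by default (one fixed t is what a single-compendium analysis uses).
- **Degree-preserving rewiring**: accepted double-edge swaps
  (a→x, b→y) ⇒ (a→y, b→x), rejecting duplicates and (by default) new
  self-loops; 10×|E| accepted swaps per draw, with an attempt cap so
  degenerate topologies (e.g. a single-TF star, where only no-op swaps
  exist) terminate. Signs stay attached to the regulator's edge slot, so
  each TF's activation/repression out-profile — not just the degree
  sequences and the global sign multiset — is preserved; this is the
  stricter reading of "keep the node degrees".

Each null repeats its perturbation nIteration times (default 200), records
the global load per iteration, and reports **mGlobal** (exact mean) plus
the mid-rank percentile of the observed load. All per-iteration draws come
from independently spawned child streams of one master seed
(`numpy.random.SeedSequence`), so results are bit-reproducible.

## Correlation by role

For every known TF–target pair, the Pearson (or Spearman, via per-row rank
transform) correlation of the two profiles across all samples of the
z-scored compendium; **mc** = Σ cPairs / nPairs per category
(all possible TF × gene pairs excluding self-pairs, known pairs,
activation, repression, and the single-regulator restrictions). Pairs with
a constant or absent profile are skipped and counted; an empty category
reports mc as undefined rather than 0.

## Mann–Whitney U

Per-contrast inconsistency loads and deregulated-gene counts are compared
between perturbed and unperturbed contrasts with a two-sided Mann–Whitney
U. Midranks handle ties. For combined n ≤ 16 the p-value is exact: all
C(n₁+n₂, n₁) assignments of the pooled (mid)ranks are enumerated and
arrangements with |U − n₁n₂/2| at least the observed deviation counted.
Above 16, a normal approximation with tie-corrected variance and a 0.5
continuity correction is used (the two branches agree to < 0.05 around the
cutoff). The test is implemented here because the exact-with-ties branch is
pinned by contract; scipy's asymptotic implementation serves as an
independent cross-check in the tests.

## Synthetic worlds

The generator emulates a bacterial GRN study: a signed directed acyclic
network, steady-state log-scale expression propagated through it, and a
multi-dataset compendium of wild-type references and perturbation cases.

**Network.** TFs get an implicit order; each non-first TF is regulated by
one earlier TF with probability 0.4; each target draws its regulator count
(mean `mean_in_degree`) and regulators uniformly among TFs. With
`mean_in_degree = 1` (the default) the network is a forest: every gene has
at most one regulator. A template network can be supplied instead, in which
case its topology is copied verbatim (degree profile preserved exactly) and
only signs and weights are redrawn. Signs are +1 with probability
`activation_fraction` (default 0.5); weights are positive,
U(0.5, 1.5); basal levels U(−1, 1).

**Expression.** Per sample, in topological order:
x_v = b_v + Σ_u s(u→v)·w(u→v)·x_u + ε, ε ~ N(0, σ), σ = 0.3 z-units by
default, so noise propagates downstream. Cyclic networks are rejected
unless damped fixed-point iteration is not required — acyclic generation is
the supported regime. Condition semantics: knockout clamps the affected
gene at −2 (z-units, exact, overriding its equation), overexpression at
+2, stress shifts the basal level of up to 3 root regulators by ±1.5, and
wild-type is unclamped. Clamp magnitudes comfortably exceed calibrated
thresholds. A per-(dataset, gene) N(0, 0.5) offset added after propagation
emulates platform/batch effects; it cancels inside every within-dataset
contrast and is removed by z-scoring. Each of 3 datasets contains one
wild-type reference group, its share of case groups, and 2 extra wild-type
groups, 3 replicates each (72 samples, 21 contrasts in the default world);
each non-reference group forms one contrast against its dataset's
reference, flagged perturbed unless it is wild-type.

**Ground truth** is the noiseless, offset-free solve of the same system:
label sign = sign(Δ) where |Δ| > 10⁻⁹. With σ = 0 and any t below the
smallest nonzero |Δ|, the pipeline reproduces these labels exactly.

**Why the positive control is a forest.** Sign consistency is a per-edge
property, but expression responds to whole paths: with multiple regulators,
interfering paths of opposite sign can contradict an individual edge even
in a noiseless linear system. A world guaranteed to satisfy "σ = 0 ⇒ zero
inconsistency at every t > 0" therefore needs unambiguous regulation, which
is exactly in-degree ≤ 1. Multi-regulator generation is supported
(`mean_in_degree > 1`) and exhibits precisely that residual inconsistency.
For the same reason, stress shifts only root regulators (a shift landing
mid-path would be a genuine ground-truth contradiction of the incoming
edge), and double knockouts pick two regulators with no directed path
between them.

**Controls.** `decouple` regenerates expression with all weights zero, so
the network has no influence; the perturbation targets are redrawn
uniformly over all genes, because leaving them on the original TFs would
keep the strongly-labeled rows preferentially on high-out-degree nodes — a
residual network–expression association the negative control exists to
remove. `contrast_rich_world` provides 30 perturbed and 30 unperturbed
contrasts, with perturbation conditions carrying 2× measurement noise
(a perturbation drags along physiological responses beyond the regulatory
cascade), for the perturbed-vs-unperturbed comparison.

## What the synthetic worlds do and do not show

The simulator preserves the properties the analysis consumes — sign-faithful
propagation, calibrated label fractions, dataset structure, noise — but is
linear and Gaussian: no saturation, no mRNA kinetics or delays, no
condition-specific rewiring, and far smaller than a real compendium
(dozens of genes and contrasts rather than thousands of edge–contrast
cases). Passing tests demonstrate that the pipeline's statistics behave
correctly and directionally as designed on data with known truth; they say
nothing about whether any real organism's GRN is consistent with its
expression data.

## Numerical choices

- Quantile-normalization ties: mean of the reference values over the tied
  rank block (cumulative-sum implementation, O(n log n) per column).
- z-score: sample sd (n−1); constant rows → 0; datasets with one sample are
  an error rather than a silent pass-through.
- Threshold: `numpy.quantile` linear interpolation; boundary |Δ| = t labels
  0 (strict inequality), stated explicitly so tests are exact.
- Rewiring attempt cap: max(100, 50 × n_swaps) proposals.
- Percentile of an observed load in a null: mid-rank
  (below + ½·equal) / n × 100, robust to the heavy ties of small discrete
  loads.
- Correlations are clipped to [−1, 1] against floating-point overshoot;
  Spearman is Pearson on per-row midranks.
- The shuffled-profile correlation collapse is measured as the mean mc over
  repeated permutation draws: a single draw of ~25 pairs can land pairs on
  genuinely co-regulated genes and carries sampling noise of order 0.05–0.1.
- All randomness flows from one master seed through named
  `SeedSequence` substreams; derived seeds stay below 2³¹.

## Known limitations

- The rewiring null preserves per-TF sign out-profiles; a looser null
  (global sign reshuffle) is configurable in principle but not exposed on
  the CLI.
- Damped fixed-point simulation for cyclic networks is not implemented;
  generation is acyclic by construction and cyclic inputs are rejected.
- Operon expansion assumes the operon map covers target genes only;
  regulator-side operons are not expanded.
- The exact Mann–Whitney branch enumerates C(n₁+n₂, n₁) arrangements and is
  deliberately capped at combined n = 16.
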