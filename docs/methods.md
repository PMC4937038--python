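# Methods

## Scope and data model

`metaboselect` operates on a corrected, aligned samples×features intensity
table (one row per subject, one column per m/z feature, binary class label).
Raw spectra, retention times, peak picking and batch/drift correction are
upstream of this package and out of scope. All operations treat the table as
the unit of exchange (`FeatureTable`): unique sample and feature ids, finite
intensities, labels in {+1, −1}.

## Synthetic data generator

The generator exists so that every downstream stage can be exercised and
validated without access to a real cohort, which in this field is typically
not shareable.

**Model.** Intensities are log-normal: a latent n×p standard-normal matrix Z
is scaled to `base_log_mean + base_log_sd · Z` and exponentiated. MS
intensities are positive and right-skewed, and defining effects and
correlations on the log scale keeps both interpretable. Correlated ion
blocks (a parent ion with its fragments/adducts) use one shared latent
factor per block with loading √r, giving equicorrelation ≈ r within the
block. Informative features receive a class-conditional mean shift of
`effect_size` log-scale standard deviations, assigned one per cluster first
and then to singletons, so that planted signal co-occurs with correlation
structure the way fragment groups do in real data.

**The `gazel_like` preset** emulates a 111-subject (55/56), 1195-feature
serum cohort. Its calibration targets are the cohort's published correlation
summaries: ≈2.4% of unordered feature pairs with |r| > 0.5 and ≈576 features
with at least one |r| > 0.8 partner. One correlation tier cannot produce
both numbers, so the preset uses two: 144 tight blocks of 4 features at
r = 0.9 (the |r| > 0.8 partners: 576 features) and 10 loose blocks of 57 at
r = 0.6 (the bulk of the |r| > 0.5 pairs), with 49 independent leftovers.
At n = 111 the sample correlation of a 0.6-population pair exceeds 0.5
about 95% of the time and essentially never exceeds 0.8, which lands the
pair share at ≈2.2% — inside the ±0.01 calibration band.

Defaults of 10 informative features at effect size 1.0 are the conditions
used by the recovery checks; the real cohort's true effect sizes are
unknown, so the planted effect is a study condition, not an estimate.

**Known mismatch.** The cohort reports 107 features with ANOVA p < 0.1, of
which 52 survive BH correction. No generator with valid (marginally
uniform) null p-values can match both: with ≈50 strongly informative
features, the *expected* null exceedance alone is ≈0.1 × 1145 ≈ 114 > 107 −
52. The cohort's p-value distribution was evidently slightly conservative.
The generator therefore treats the correlation summaries as calibration
targets and simply reports its own ANOVA counts (≈130 below 0.1 with the
10-feature default; ≈10 BH-significant), which `summarize_structure`
computes for any table.

**What the generator does not emulate:** heteroscedastic noise, batch and
drift artifacts, missing values, non-Gaussian log-intensity tails, and
biologically structured (pathway-level) correlation. Passing recovery tests
therefore demonstrate the workflow's mechanics under a favourable, clean
signal model, not expected performance on real cohorts.

## Filters

The correlation filter reproduces the pairwise-scan heuristic of the
standard redundancy-removal routine: while any retained pair exceeds the
threshold in |r|, the worst pair is located and the member with the larger
mean absolute correlation to all remaining features is dropped (ties by
lexicographic feature id). Exhaustive maximum-subset selection is
NP-hard and intractable at p ≈ 1200; the greedy rule is validated against
exhaustive search on 5-feature instances. The postcondition — no retained
pair above the threshold — holds by construction of the loop.

Mutual information between features uses the Gaussian closed form
MI = −½·ln(1−r²) in nats: deterministic, parameter-free, and the natural
continuous-data estimator when a correlation matrix is already the object
of interest. Each feature's score is its row mean over the MI matrix
(diagonal excluded); features below 0.02 nats are kept as approximately
independent. Binning estimators were deliberately excluded.

## Ranking routes

*ANOVA*: per-feature one-way two-group F-test (identical to the squared
pooled-t), ascending p, BH adjustment attached; its top set is everything
below the 0.1 entry p-value rather than a fixed n.

*Forests* are built tree-by-tree over explicit bootstrap draws
(`sklearn` decision trees, mtry = 2·⌈√p⌉ capped at p — double the
conventional default, kept deliberately). Out-of-bag error is the
misclassification of majority votes over trees not containing a sample;
samples never out-of-bag (possible at very small ensembles) are excluded
from the denominator and counted in the log. Replicated training keeps the
forest with the smallest OOB error. MdGini is the mean unnormalized
Gini-impurity decrease per feature. MdAcc permutation importance draws one
permutation per feature and scores the accuracy drop on each tree's own OOB
samples, averaged over trees — the single-permutation variant used by
mainstream forest implementations, chosen over per-tree re-permutation for
tractability at p ≈ 1200 on one CPU.

*SVM routes* use a linear kernel at C = 1 (no tuning) on unit-variance
scaled data; scaling is applied before SVM only, since trees and F-tests
are scale-invariant (a `center` flag covers conventional autoscaling).
SVM-RFE-W ranks by |w| from a single fit. RFE variants halve the feature
set each round (⌈p/2⌉ kept; a drop-one schedule is available), ordering
eliminations by the inner model's importance; subset quality per round is
pooled leave-one-out accuracy or Cohen's kappa. Because elimination order
is importance-driven, the Acc and Kappa variants of one RFE pass share an
ordering; the metric selects the best subset size and, across replicates,
the best replicate — which is where the two variants can diverge.

RF-RFE supports `cv="loocv"` (n model fits per round) and `cv="oob"` (one
forest per round supplies both the quality estimate and the elimination
importances). The scaled-down study conditions used in the acceptance
checks run RF-RFE with `cv="oob"`, 200-tree forests, and 1–2 replicates;
at these settings a full ten-route pass on a 111×1195 table takes well
under a minute of the workflow's ≈45 s total.

Seeding: a master seed fans out through `SeedSequence([master, index])`, so
each replicate is reproducible in isolation and all routes are bit-stable
for a fixed seed.

## Stability consensus and the concept lattice

Top sets (200 for filtered routes, 178 for unfiltered, ANOVA's p < 0.1 set
— both cutoffs kept as plain workflow constants) form a formal context:
objects are the union of selected features, attributes the ten techniques.
The stability degree is a row sum; the consensus keeps degree ≥ 6,
balancing complementarity of methods against subset size. Features selected
by no technique never enter the context.

All formal concepts are enumerated with NextClosure over attribute sets
(lectic-order closure enumeration) — canonical, provably complete, and
trivial at 10 attributes (complexity O(#concepts·|O|·|A|²)). The cover
relation is the transitive reduction of extent containment; lattice height
is the longest bottom-to-top chain. Correctness is established by
exhaustive closure enumeration over all attribute subsets on random
contexts up to 20×15. Contexts are exchanged in the Burmeister `.cxt`
dialect and lattices as GraphML digraphs, replacing interactive lattice
GUIs with file-based export.

## Prediction

All three routes run on the consensus subset. Evaluation metrics derive
from confusion counts; any zero denominator yields an explicit `None`
rather than a silent zero, and misclassification ≡ 1 − accuracy.

*Nested forests*: a forest on the full consensus supplies the MdAcc
ranking (the resolution chosen for the ambiguity between ranking-stage
LOOCV and evaluation-stage splits: rank on full data, evaluate on splits);
nested subsets (48→40→30→20→10→5 by default) are each evaluated over
repeated stratified 75/25 splits ("on average 75%" read as a fixed
stratified draw), pooling confusion counts across splits and averaging the
evaluation forests' OOB errors.

*Backwards elimination* (varSelRF-style): drop the least-important 20% per
refit (importance recomputed each round), track OOB error, return the
smallest variable set attaining the minimum (0-s.e. rule; a 1-s.e. option
exists), and intersect across replicates for the stable set. An empty
intersection is a legitimate outcome (logged, not raised).

*Logistic pipeline*: the four stages run exactly in order — univariable
entry at p < 0.25; collinearity pruning to max |r| ≤ 0.5 using the same
worst-pair/mean-|r| rule as the correlation filter; reduction to a
10-feature shortlist dropping the smallest |point-biserial correlation with
outcome| first and breaking ties by the larger univariable p (the two
criteria ordered lexicographically, since no weighting is given); and
bidirectional stepwise AIC starting from the full shortlist model.
Complete separation — routine at n ≈ 100 with strong features — is handled
by refitting with a small L2 penalty (λ = 10⁻⁴) via IRLS so coefficients
and Wald p-values stay finite; affected features are flagged in the trace,
never dropped silently.

LOOCV probabilities (for ROC construction) refit the model on n−1 samples
per fold; multivariate ROC always uses these out-of-fold probabilities,
never resubstitution scores.

## Interpretation

AUC is the Mann–Whitney statistic with half-credit ties, its CI the DeLong
placement-value estimator (chosen over bootstrap for determinism; a
stratified-bootstrap alternative is provided), and the operating point
maximizes Youden's J. Degenerate score vectors are flagged, not errored.

Discretization is equal-width over each feature's observed range with the
outer intervals unbounded (equal-frequency behind a flag); association
rules come from a level-wise Apriori with exact supports/confidences,
single-item consequents, and a strictly positive support threshold as a
combinatorial guard. The support threshold and the choice of scaled
intensities for discretization are configuration parameters (scaled,
centered intensities are the default, matching interval labels of
magnitude ≈ 1).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the cohort-scale recovery at
111×1195 with 200-tree forests, 2 replicate forests per importance route,
OOB-scored RF-RFE, and 10 stratified evaluation splits, over 10 (suite) or
6 (script) synthetic cohorts; oracle checks use 100 random contexts /
instances each. These sizes are the package's chosen desk-scale operating
point; the library defaults (2000 trees, 50 replicates, 100 replications,
LOOCV) remain the reference conditions.

## Known limitations

- The greedy correlation filter is not guaranteed optimal beyond the
  instances where it is validated against exhaustive search.
- The single-permutation MdAcc estimator is noisier than per-tree
  re-permutation at very small ensembles.
- Stepwise AIC and the shortlist stage inherit the instability of greedy
  selection; the trace records every elimination so runs can be audited.
- The ridge fallback's Wald p-values under separation are
  penalization-dependent; they are used only for ordering and entry
  decisions, not reported as inferential p-values.
- Apriori here is for small item universes (a handful of features × 4
  bins); it is not an optimized frequent-itemset miner.
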