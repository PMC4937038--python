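# metaboselect

Stability-consensus feature selection and predictive modelling for
case-control untargeted metabolomics.

## The problem

Untargeted LC-MS metabolomics yields on the order of a thousand m/z features
per serum sample, heavily inter-correlated (a metabolite appears as a parent
ion plus fragments and adducts) and measured on barely a hundred subjects.
When the goal is an *early predictive* biomarker — discriminating subjects
who will develop disease years later from matched controls — the class
effects are subtle, no single ranking method is reliable, and a model built
on all features overfits. `metaboselect` implements a complete discovery
workflow for this setting, aimed at analysts who need a short (1–10 feature)
predictive signature from a samples×features intensity table with a binary
class label (`1` = case, `−1` = control):

1. **Filters** — remove redundant features by greedy Pearson-correlation
   elimination (default threshold |r| > 0.95) or dependent features by
   average Gaussian mutual information, MI(i,j) = −½·ln(1−r²ᵢⱼ), with an
   average-MI cut of 0.02 nats.
2. **Ten ranking routes** — random-forest importances (mean decrease in OOB
   accuracy, MdAcc, and mean decrease in Gini, MdGini; 2000 trees,
   mtry = 2·⌈√p⌉, best of 50 replicate forests by OOB error), linear-SVM
   hyperplane weights (SVM-RFE-W), and recursive feature elimination with
   forest or SVM inner models scored by leave-one-out accuracy or Cohen's
   kappa — applied to the raw table and to the correlation- and MI-filtered
   tables — plus per-feature one-way ANOVA with Benjamini–Hochberg
   correction.
3. **Stability consensus** — the routes' top sets (top 200 filtered, top 178
   unfiltered, ANOVA p < 0.1) form a features×techniques formal context;
   each feature's *stability degree* is the number of techniques selecting
   it, and features with degree ≥ 6 form the consensus. The full concept
   lattice of the context is enumerated with NextClosure and exported as
   `.cxt`/GraphML for inspection.
4. **Prediction** — three routes on the consensus subset: a forest evaluated
   on nested top-k subsets over repeated stratified 75/25 splits; a
   varSelRF-style backwards elimination keeping the variable set at minimum
   OOB error, replicated to a stable intersection; and a four-stage logistic
   selection (univariable entry p < 0.25 → collinearity pruning to
   max |r| ≤ 0.5 → 10-feature shortlist by outcome correlation →
   bidirectional stepwise AIC).
5. **Interpretation** — ROC/AUC with DeLong confidence intervals from
   leave-one-out probabilities, Welch t-tests, a signed Pearson correlation
   network, and Apriori association rules on equal-width discretized
   intensities.

Because cohorts of this kind are rarely shareable, the package includes a
first-class synthetic generator (`synthdata`) that emulates the reference
cohort's structure — 55 cases / 56 controls, 1195 log-normal features,
correlated ion blocks giving ≈2.4% of feature pairs |r| > 0.5 and ≈576
features with an |r| > 0.8 partner, and planted subtle class effects — so
every stage is testable end to end.

## Worked example

```python
import metaboselect as ms

spec = ms.gazel_like(seed=0)              # 111×1195, 10 planted features
table = ms.generate_dataset(spec)

summary = ms.summarize_structure(table)
print(f"{100 * summary.frac_pairs_above_05:.1f}% of pairs |r|>0.5,",
      f"{summary.n_features_with_partner_above_08} features with an |r|>0.8 partner")

run = ms.run_ten_routes(table, n_trees=200, replicates=2, seed=0)
print(f"consensus (degree >= 6): {len(run.consensus)} features")

reports = ms.rf_predict_nested(table, run.consensus,
                               subset_sizes=[48, 20, 10, 5],
                               replications=10, n_trees=200, seed=0)
for r in reports:
    print(f"{r.model_id}: misclassification {100 * r.misclassification:.1f}%,"
          f" OOB error {r.oob_error:.3f}")
full = ms.rf_predict_nested(table, table.feature_ids, subset_sizes=[1195],
                            replications=10, n_trees=200, seed=0)
print(f"full-table: misclassification {100 * full[0].misclassification:.1f}%")
```

Output (seed 0):

```
2.2% of pairs |r|>0.5, 576 features with an |r|>0.8 partner
consensus (degree >= 6): 67 features
48-Rf-acc: misclassification 6.4%, OOB error 0.122
20-Rf-acc: misclassification 9.3%, OOB error 0.111
10-Rf-acc: misclassification 18.9%, OOB error 0.133
5-Rf-acc: misclassification 12.1%, OOB error 0.154
full-table: misclassification 27.1%
```

The structure summary shows the generator reproducing the cohort's
correlation profile; the consensus concentrates the ten planted features
(plus correlated passengers); and the evaluation shows why selection
matters here — the consensus-subset forests misclassify a quarter as often
as the forest trained on all 1195 features, with small subsets staying
competitive.

A thin CLI mirrors the stages: `metaboselect synth|filter|rank|stability|
predict|interpret --help`.

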