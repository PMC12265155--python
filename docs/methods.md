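# Methods

## Problem and data model

The package treats drug withdrawal — removal from the market by a
regulatory agency after unanticipated toxicity — as a binary label and
predicts it from four complementary projections of a drug corpus. The
corpus is three tables: a drug table (label, free-text withdrawal reasons,
ATC codes, ChEMBL-style chemical descriptors, SMILES or a precomputed
fingerprint), an activity table of (drug, protein, IC50 nM) triples, and a
protein table of raw structural feature counts with sequence length.
Investigational (clinical-trial) drugs carry no training label and are
used only for screening.

## Feature views

**Fingerprint.** Morgan circular fingerprints, radius 2, folded to 512
bits. Synthetic drugs carry bit vectors directly, so the chemistry backend
(RDKit) is optional; real SMILES are encoded deterministically and a parse
failure is a hard error naming the drug.

**Chem.** Numeric descriptors pass through unchanged; acid/base/neutral/
zwitterion, prodrug, route-of-administration and ro3 flags become 0/1
columns; chirality is one-hot over {achiral, racemic, single_stereoisomer}.
Missing numeric values are imputed with the **training-split median**,
computed once when the view layout is fitted and reused for all held-out
drugs — median because it is robust and leak-free; no rule for missing
values is inherent to the data.

**Target.** Binary incidence: a drug "targets" a protein when at least one
IC50 record exists for the pair. An optional potency cutoff (nM) is
available but off by default, since the evidence threshold is a judgement
call we did not want baked in. Duplicate records collapse idempotently.

**Target feature.** Raw structural counts are divided by sequence length
(per-residue rates), then weighted by interaction potency as
F = f · (max(sIC50) − pIC50 + 1) / max(sIC50). The weight uses the pair's
*minimum* IC50 (strongest evidence) and the protein's IC50 maximum over
the **training corpus only**, so held-out drugs never influence the
normalization; a held-out pair weaker than the training maximum is clamped
to it. The formula is strictly decreasing in pIC50, reduces to F = f for a
single-IC50 protein at 1 nM, and to f/max(sIC50) for the weakest binder.
An alternate reading without the denominator, F = f · (max − p + 1), is
available via `denominator=False`; the default was chosen because it uses
every quantity the weighting names and keeps the weight on the scale of f.
Columns are (protein, feature) pairs by default, preserving both
protein-level and feature-level attribution; a pooled per-feature variant
(summed over proteins) is available via `pooled=True`.

All four layouts are fitted by `ViewBuilder` on the training segment and
projected onto any drug list, which is what makes the leakage audits in
the test suite possible.

## Splitting, normalization, the ensemble

Per seed: the majority class is undersampled to the minority count, then
each class is partitioned 80/10/10 into train/test1/test2 (sizes rounded
as round(0.1·m) per test segment). Features are min-max normalized with
train statistics; constant train columns map to 0 (not NaN) and held-out
values extrapolate beyond [0, 1] unclipped, since clipping would discard
the information that a value is out of the training range.

Base classifiers come from a fixed registry (all scikit-learn):

| view | family | key hyperparameters |
|---|---|---|
| fingerprint | random forest | entropy, depth 64, log2 features, min leaf 2, min split 5, 188 trees |
| chem | extra trees stacked with a decision tree | ET: bootstrap, gini, 0.65 features, min leaf 7, 100 trees; DT: gini, depth 5, min leaf 18, min split 3 |
| target | RBF sampler + gradient boosting | γ = 0.05; lr 0.1, depth 9, 0.65 features, min leaf 14, min split 15, 100 estimators, subsample 0.5 |
| target_feature | multilayer perceptron | identity activation, one hidden layer of width 150, SGD solver |
| meta | K nearest neighbours | 57 neighbours, distance weights |

"One hidden layer of width 150" is the reading consistent with a search
space over layer *sizes*; a depth-150 identity MLP would collapse to a
linear model anyway. The chem stacker's decision tree sees the extra-trees
class probabilities **plus** the raw feature vector (`passthrough`);
internal 5-fold cross-fitting generates the stacking features. The MLP
runs up to 500 SGD iterations; non-convergence within that budget is
tolerated silently because the classifier is already adequate at that
point on these inputs.

The meta-classifier trains on the four base withdrawal probabilities over
train + test1 (the bases having seen only train) and is evaluated on
test2; this reuse of the bases' own training rows in the meta pool is
deliberate fidelity to the protocol, and the per-drug base probabilities
are exposed so an out-of-fold variant can be built if hygiene is preferred
over fidelity. A drug missing from a view contributes the uninformative
0.5. The averaging baseline is the unweighted mean of the four
probabilities. Decision threshold is 0.5 with ties classified withdrawn
(screening favours sensitivity). The KNN neighbour count is clamped to the
meta-pool size for tiny corpora; the registry value stays 57.

Metrics (accuracy, F1, precision, recall, MCC, AUROC) are computed with
scikit-learn; MCC is defined as 0 when a confusion-matrix marginal is
empty and precision/recall use the 0-convention under zero division. The
test suite checks all six against an independent confusion-matrix /
rank-statistic oracle.

## Feature selection

Three selectors per balanced 80% resample (seeds 0–9): RFECV (step 1,
5-fold stratified CV, random forest of 100 trees — the forest size is our
choice; only the model family is prescribed), variance threshold at 0, and
top ⌈25%⌉ by the chi-squared score. The resample is min-max scaled within
itself so chi-squared's nonnegativity precondition holds. Per-method score
= 10 × selections/repeats; combined = unweighted mean of the three
("combined with equal weights" read as a mean — a sum rescaled by 3 is the
same ranking). Ties at the chi-squared cutoff break lexicographically for
determinism. Note the chi-squared scorer is the feature-count statistic
(observed class sums vs prior-expected), not the full 2×2 Pearson
statistic; for a symmetric binary split it is half the classical value.

Class contrasts report log2(withdrawn summary / not-withdrawn summary),
with means for continuous features and class-normalized frequencies for
flags; significance is Welch's t for continuous and Fisher exact for
flags at α = 0.05 (the threshold is prescribed, the tests are our choice
of the standard pair). A nonpositive class summary yields an undefined
(NaN) ratio rather than ±inf.

## ATC enrichment and reasons

Level-1 group = uppercase first letter of the ATC code; drugs without a
code are omitted, drugs with codes in several groups count once per group.
Each observed group gets a two-sided Fisher exact test of the 2×2
(withdrawn/not × in/out) table. The p-value follows the conventional
definition — sum of fixed-margin hypergeometric probabilities of tables no
more probable than the observed — computed in exact integer arithmetic
over the common denominator C(n, a+c), so no floating-point tie ambiguity
arises; the test suite checks it exhaustively against a rational-
arithmetic enumeration for all tables with total ≤ 24 and against
scipy.stats.fisher_exact. The Bonferroni divisor defaults to 14 (the full
WHO level-1 standard), giving 0.05/14 ≈ 0.0036; pass the observed-group
count to correct over those instead. The reason curation table ships as
editable CSV data (`watchtox/data/reason_map.csv`) with case-folded exact
matching; unmapped strings pass through tagged "uncurated".

## Synthetic corpora

The generator emulates the three tables with a signal planted in exactly
four ways: additive shifts on chosen descriptors, elevated activity
probability against designated toxic proteins, fingerprint bits biased
toward the withdrawn class, and class-dependent ATC letter frequencies.
Toxic proteins also share elevated helix fraction (0.45–0.65 vs 0.15–0.35)
and contact rate (3.5–4.5 vs 1.5–2.5 per residue) so structural-feature
selection has something to find. Background descriptor distributions sit
at plausible small-molecule scales (MW ≈ N(380, 110), alogp ≈ N(2.5, 1.5),
counts Poisson, QED uniform) to keep min-max normalization nondegenerate.
IC50s are lognormal in nM (ln-scale μ = 4, σ = 1.5; median ≈ 55 nM), which
matches typical bioactivity spreads and exercises the potency weighting's
max() nontrivially. One root seed splits into fixed per-view substreams,
so adding a view never perturbs another and generation is a pure function
of the config. Investigational drugs are drawn from a 50/50 mixture of the
two class distributions by default; each one's source class is recorded on
the bundle (it is a sampling outcome, not a config property).

The shipped **strong-signal condition** is 600 drugs (withdrawn fraction
0.5 — a balanced corpus keeps the balanced-split machinery nondegenerate
at this scale), 40 proteins of which 6 toxic with hit probabilities
(0.8, 0.1) vs background 0.15, alogp +1.5, 8 signal bits at flip
probability 0.15, and N-group ATC enrichment (0.45 vs 0.18). The
**null condition** is 400 drugs with every effect zeroed and equal
probabilities, making the classes exchangeable by construction; any
classifier's expected accuracy is 0.5 there, which calibrates the whole
pipeline against self-deception. What passing on these corpora does *not*
show: real descriptor correlations (features are independent given the
class), chemically valid structures (fingerprints are synthetic bits),
assay noise structure, or the 120:1511 class imbalance of a real
withdrawal corpus — the balanced-resampling machinery handles imbalance,
but the shipped conditions do not stress it.

## Screening

Ten independently trained ensembles (one per protocol seed, each with its
own balanced resample and split — matching a protocol described as
training on ten different balanced random subsets) each cast a hard label
per candidate; votes use hard labels rather than summed probabilities,
reproducing the integer 0–10 scale. Candidates never enter training
corpora or normalization; each model projects them through its own fitted
view layout. Flagging defaults to unanimity (10/10), configurable.

## Problem sizes and numerical choices

The test suite and the acceptance script run the strong-signal condition
(600 drugs × 10 seeds), the null condition (400 × 10), and chem-view
consensus selection (10 resamples × 3 selectors); together about five
minutes on one CPU, RFECV dominating. Ties: probability 0.5 → withdrawn;
chi-squared cutoff ties → lexicographic; equal screening votes → drug_id
order. Degenerate inputs: single-class training labels, empty prediction
sets, all-zero Fisher tables and nonpositive IC50 maxima are hard errors;
constant train columns normalize to 0; empty activity sets yield all-zero
matrices.

## Known limitations

Real-data rankings (which proteins, which descriptors) depend on the
specific corpus snapshot and are not reproduced by synthetic corpora; the
meta-training pool deliberately reuses base-training rows (see above), so
absolute ensemble metrics on small corpora are optimistic relative to an
out-of-fold stacking design; only IC50 evidence is consumed (no Ki/EC50);
structures are parse-or-reject with no standardization or tautomer
handling; and the ChEMBL download adapter is intentionally out of the
tested path — file-based corpora are the supported interface.
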