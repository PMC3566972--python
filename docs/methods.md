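# Methods

This note documents the models and procedures implemented in
`hexamyloid`, the parameters that matter, the numerical conventions, and
what the synthetic benchmarks do and do not establish.

## Energy-threshold labeling

A hexapeptide is the atomic unit of classification: a 6-residue window
over the 20-letter amino-acid alphabet. Ingestion sanitizes sequences
(uppercase; every cysteine replaced by serine, since cysteines would
form disulfide bridges between the tightly packed zipper chains), cuts
long proteins into non-overlapping chunks of at most 80 residues, and
slides a 6-residue window one position at a time. Windows containing a
symbol outside the 20-letter alphabet (X, B, Z, U, O, J, stops, gaps)
are dropped rather than imputed: the model space is the standard
alphabet, and imputation would fabricate sequence. Windows are not
recovered across the 80-residue chunk boundary; chunking exists only to
serve upstream redundancy reduction, and `chunk=False` disables it.

The label derives from the minimal threading energy: amyloidogenic iff
E_min ≤ −23 kcal/mol. The boundary is inclusive ("not greater than"),
so −23.0 exactly is positive. Lowering the threshold can only shrink
the positive set (monotonicity, property-tested).

Two energy sources for the same peptides are compared by
(a) classification overlap — the fraction of shared peptides labeled
identically after thresholding both columns, with breakdowns among the
first source's positives and negatives — and (b) the mean and
q-th percentile (nearest-rank convention on sorted values, q = 90 by
default) of the absolute energy difference.

## Simplified steric-zipper geometry

The template set models the cross-β zipper core as two identical
five-strand β-sheets of threaded hexapeptide copies. From a scaffold
pose, the second sheet is rigidly translated on a grid: 0–8 Å along the
chain direction and 6–11 Å of sheet separation, both in 1 Å steps —
9 × 6 = 54 poses. The third rigid-body direction of the full-profile
method (2,511 templates) is deliberately not sampled; the 46-fold
reduction is the point of the simplification.

The geometric frame is recomputed from coordinates, never assumed:
the chain axis is the mean Cα(i)→Cα(i+1) direction of sheet 1, the
inter-strand axis the mean direction between consecutive strand
centroids, and the sheet normal their cross product, oriented from
sheet 1 toward sheet 2. Sheet separation is the centroid gap projected
on that normal. Because the translation applied for a template is
exactly `shift·axis + (separation − native)·normal`, the recomputed
separation of every template equals its configured value to machine
precision, and all intra-sheet distances are preserved (both asserted
to 1e-9 Å in tests).

No canonical scaffold structure is bundled; the shipped
`synthetic_ideal_scaffold()` builds an idealized parallel in-register
sheet (3.5 Å rise per residue, 4.8 Å strand spacing, 8.0 Å nominal
sheet offset, alternating pleat) purely so the geometry can be exercised
and tested offline. Any user PDB with two annotated sheets is accepted
via `read_scaffold_pdb`. Energy computation is an adapter contract —
`(peptide, template) -> 10 per-chain energies in kcal/mol` — intended to
wrap an external design/energy program; the bundled
`HydropathySurrogateAdapter` is an affine function of summed
Kyte–Doolittle hydropathy with separation and shift penalties, useful
for testing the minimum-selection machinery and nothing else.

## Alternating decision tree

The ADTree is the interpretable centerpiece. Base conditions are the
120 equality tests `AAj = X`. Instances carry weights, initially 1.
The root prediction value is a₀ = ½·ln((W₊+ε)/(W₋+ε)); each boosting
round scans every existing prediction node's path predicate c₁ against
every base condition c₂ and adds, at the minimizer of

    Z(c₁, c₂) = 2·(√(W₊(c₁∧c₂)·W₋(c₁∧c₂)) + √(W₊(c₁∧¬c₂)·W₋(c₁∧¬c₂))) + W(¬c₁),

a splitter whose true/false prediction values are the smoothed
half-log-odds on the corresponding weight subsets, then multiplies the
weights of affected instances by exp(−y·value). Scoring sums every
prediction value on satisfied paths; the sign is the class, and
1/(1+exp(−2F)) is exposed as a calibrated ranking probability (the
standard logistic map of a boosting margin).

Numerical conventions:

* **Smoothing** ε = 1.0 added inside every half-log-odds ratio keeps
  values finite on pure nodes. The constant used by other ADTree
  implementations is not standardized, so printed rule values are
  comparable in shape and sign but not bit-for-bit.
* **Search** is exhaustive over all (prediction node × 120 conditions),
  not a path-limited heuristic, so training needs no random seed.
* **Tie-break**: candidates within a relative 1e-9 of the minimal Z are
  treated as tied (guarding against last-ulp summation-order noise) and
  resolved by lowest position, then alphabetical residue, then earliest
  created prediction node. Training is therefore fully deterministic,
  and the tie rule is replicated by the pure-Python reference trainer
  used as the test oracle.
* With equal-ε smoothing the added value is a shrunk version of the
  unsmoothed loss minimizer on the same side of zero, so the total
  exponential loss Σ exp(−yF) is non-increasing across iterations for
  any ε ≥ 0 (property-tested).

Typical operating points: 50 iterations for an interpretable rule list,
250 for the strongest classifier. Rules export in the notation
`n: AAj | X a | !X b`, ordered by boosting iteration (significance).

## Baseline classifiers

**Naive Bayes** treats the six positions as independent categorical
attributes: P(r|p,c) = (count+α)/(n_c+20α) with α = 1 (the smoothing
convention is this package's choice), priors from class counts,
posteriors accumulated in log space. It is cross-checked in tests
against an independent categorical implementation.

**MLP**: 120 one-hot inputs → 60 logistic hidden units → 1 logistic
output; per-instance stochastic gradient descent with momentum on
squared error, learning rate 0.1, momentum 0.2, 500 epochs, seeded
uniform [−0.5, 0.5] initialization, order reshuffled each epoch from
the same generator. A single output unit predicting the positive-class
probability is used (some toolkits use two complementary output units);
the ranking, and hence AUC, is equivalent. Gradients are verified
against central finite differences; training is bit-reproducible given
the seed.

## Evaluation and statistical comparison

TPR = TP/(TP+FN), TNR = TN/(TN+FP), Acc = (TP+TN)/total, with the
amyloidogenic class positive; a class absent from the truth makes the
corresponding rate NaN with a warning. ROC curves are built from
descending-score thresholds with tied scores grouped into a single
point; the trapezoid area then equals the Mann–Whitney probability
estimate with ties counted one half (asserted exactly in tests), so
AUC(s) + AUC(−s) = 1 and AUC is invariant under strictly monotone score
transforms.

The comparison protocol runs k = 10 resamples of an unstratified
random 66/34 train/test split (stratification available as an option),
trains every method on identical splits, and records test AUC. Per-run
differences between two methods are tested with the corrected resampled
t-test, t = d̄ / √((1/k + n_test/n_train)·s²_d) with k−1 degrees of
freedom: the (1/k + n₂/n₁) factor inflates the variance to compensate
for the dependence induced by overlapping training sets, and the
statistic reduces to the classical paired t when the ratio is zero.
Zero variance is a draw when the mean difference is also zero, and is
reported as p = 0 with a degeneracy flag otherwise. Pairwise outcomes at
α = 0.05 (two-sided, no multiple-comparison correction — the table
reports raw pairwise results) aggregate into wins/draws/losses per
method. All split seeds default to 0..k−1 and are recorded in the
result.

## Synthetic data generation

The sequence generator draws a label from a class prior (default 0.184,
the positive fraction typical of energy-threshold-labeled hexapeptide
corpora), then each residue independently from the class's 6×20
position frequency matrix. The default background is an overall protein
composition with cysteine's mass folded into serine, matching sanitized
sequence space; `with_signal(position, residue, weight)` plants a
discriminating motif. Because positions are independent, the
Bayes-optimal ranking score is the summed per-position log-likelihood
ratio, and its two class distributions are enumerated exactly by
convolution (scores merged at 1e-9 resolution; ±∞ handled as extreme
ranks), yielding an exact optimal-AUC ceiling that Monte-Carlo sampling
reproduces within 0.005 in tests. The enumeration is exact for the
structured configurations used here; adversarial dense PFMs could make
the convolved support large.

The energy-table generator draws base energies from Normal(−20, 3)
kcal/mol and adds a signed between-source difference calibrated so that
E|Δ| equals the configured target (default 1.0 kcal/mol). The default
shape is Laplace; note that |Laplace| has a 90th-percentile-to-mean
ratio of ln 10 ≈ 2.3 and a Gaussian difference ≈ 2.06, whereas paired
threading pipelines have been observed with ratios as low as 1.4
(sub-Gaussian tails) — the shape is selectable where that matters.

What the generators deliberately do not emulate: correlation between
adjacent windows of the same protein, position-dependent background
composition, redundancy structure, or any physical relation between a
sequence and its energy. Passing the recovery benchmarks therefore
shows that the learners extract position-specific statistical signal at
realistic sizes and class imbalance — not that they would reach the
same accuracy on experimentally labeled peptides.

## Problem sizes and benchmark conditions

The acceptance script mirrors the scale of an energy-labeled hexapeptide
corpus: 4481 training and 1586 test peptides, a 2702-record paired
energy table, 100 replicate trainings for planted-condition recovery,
and a 10-run resampled comparison on 1200 peptides (MLP at 60 epochs
there, to keep the 30 trainings proportionate). Its benchmark generator
plants a multi-position motif (I at 4, V at 3, F at 5, L at 2, S at 1
in positives; P enriched at 4 in negatives) whose enumerated
Bayes-optimal AUC is ≈ 0.93, emulating the strongly separable regime
that energy-labeled hexapeptide data exhibits; the classifiers' reported
AUCs are meaningful relative to that computed ceiling.

## Known limitations

* The energy adapter for a real design program is specified but not
  bundled; labels from the surrogate are non-physical.
* The idealized scaffold has textbook geometry, not refined fibril
  coordinates; template poses are translations only (no rotational
  scan), by design.
* ADTree rule values depend on the smoothing constant; comparisons with
  other implementations should be structural (which conditions, what
  sign and order), not numeric.
* The corrected resampled t-test is a heuristic variance correction; it
  is conservative and can declare draws between genuinely different but
  closely matched methods.
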