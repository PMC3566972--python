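# hexamyloid

Amyloids are proteins that aggregate into highly ordered cross-β fibrils;
short *hot-spot* segments — well represented by hexapeptides — can drive
this transformation when exposed. The physicochemical route to predicting
a hexapeptide's amyloidogenicity threads it onto steric-zipper backbone
templates (two facing, interdigitated β-sheets) and thresholds its
minimal computed energy, which is accurate but expensive. `hexamyloid`
implements a fast alternative stack for structural bioinformaticians:

* **Simplified zipper geometry** — enumerates 54 rigid-body templates of
  two five-strand β-sheets (shifts of 0–8 Å along the chains ×
  separations of 6–11 Å across the sheets, 1 Å steps), threads a query
  hexapeptide onto all ten chains, and labels it *amyloidogenic* iff the
  minimal per-chain energy E_min ≤ −23 kcal/mol. Energy computation is an
  adapter contract for an external design program; a clearly labeled
  non-physical surrogate ships for testing.
* **Sequence-only classifiers**, trained on energy-labeled 6-residue
  sequences, that replace threading entirely:
  * an **alternating decision tree** (ADTree) written from scratch — a
    boosted ensemble of position–residue tests `AAj = X` whose score is
    the sum of prediction values over all satisfied paths,
    F(x) = v₀ + Σₜ vₜ(x); each boosting round adds the splitter
    minimizing Z(c₁,c₂) = 2(√(W₊W₋)|c₁∧c₂ + √(W₊W₋)|c₁∧¬c₂) + W(¬c₁),
    giving a directly interpretable rule list;
  * **categorical Naive Bayes** with per-position conditionals and
    Laplace smoothing;
  * a **multilayer perceptron** (120 one-hot inputs → 60 logistic hidden
    units → 1 output, per-instance SGD with momentum on squared error).
* **Evaluation statistics** — TPR/TNR/accuracy, ROC curves with tie
  grouping whose trapezoid area equals the Mann–Whitney statistic
  (ties ½), the 10-run 66/34 resampling protocol, the corrected resampled
  t-test t = d̄ / √((1/k + n₂/n₁)·s²_d), and wins/draws/losses tables.
* **Synthetic data generators** — position-frequency-matrix sequence
  sampling with plantable motif signals and an *exact* enumerated
  Bayes-optimal AUC oracle, plus paired energy tables with a controlled
  between-source difference distribution.

## Worked example

```python
from hexamyloid import planted_motif_config, sample_peptides, train_adtree

config = planted_motif_config(n=4000, seed=0, position=4, residue="I", weight=0.9)
data = sample_peptides(config)
model = train_adtree(data, iterations=10)
print(model.format_rules())
```

```
root -0.729
1: AA4 | I 1.356 | !I -1.059
2: AA3 | N -1.508 | !N 0.017
...
```

The root value −0.729 is the half-log-odds of the 754:3246 class
imbalance. Rule 1 recovers the planted motif: isoleucine at position 4
adds +1.356 to the score (its absence −1.059); the sign of the summed
score is the class call, so

```python
model.predict_score("NNQINY")   # +0.635 -> amyloidogenic
model.predict_score("NNQQNY")   # -1.705 -> non-amyloidogenic
```

The `examples/` directory holds one short script per capability
(window extraction, energy labeling and source agreement, rule reading,
the resampled classifier comparison, template enumeration + threading);
each prints its numbers with a line on what they mean. A thin CLI wraps
the same operations (`hexamyloid extract | label | train | predict |
eval | compare | simulate | templates`).

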