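# bmsf — Binary Matrix Shuffling Filter for neuronal morphology classification

`bmsf` implements a wrapper feature-selection method — the **Binary Matrix
Shuffling Filter (BMSF)** — together with the full experimental apparatus
needed to use and evaluate it on neuronal morphometry data: an SWC
reconstruction parser with an L-measure-style metric catalog, the
SVC-with-RBF classification protocol, an SVM-RFE baseline, a replicated
stratified evaluation harness (accuracy / MCC / recall), a one-vs-rest
hierarchy over imbalanced neuron types, and a synthetic-data module so
everything runs end to end without any download.

It is aimed at neuroinformatics practitioners who classify digital neuron
reconstructions (e.g. from NeuroMorpho.org) by morphometric features and
want a parsimonious, interpretable feature subset rather than opaque
principal components.

## The method

Given a labeled feature table with m candidate features, one BMSF round:

1. draws a random **balanced inclusion matrix** B ∈ {0,1}^(k×m) (default
   k = 50): each column is an independent permutation of k/2 ones and k/2
   zeros, so every feature appears in exactly half the combinations;
2. scores each row i by the ten-fold cross-validated accuracy a_i of a
   support vector classifier (RBF kernel, C = 2^c, γ = 2^g tuned on the
   base-2 grid c ∈ [−5, 15], g ∈ [3, −15]) trained on the features with
   B_ij = 1, with the fold assignment held fixed across rows;
3. fits a surrogate regression f̂ (support vector regression, RBF) with
   the inclusion vectors as predictors and the accuracies a as response;
4. for each feature j forms two forced test sets — B with column j set to
   all ones (predictions Z₁) and to all zeros (Z₀) — and computes the
   margin mean(Z₁) − mean(Z₀);
5. keeps the features with positive margin and repeats with fresh seeds
   until a round deletes nothing.

Because each feature is judged inside random combinations of the others,
interactions count, and redundant features (whose forced inclusion buys
nothing the rest of the set does not already provide) are eliminated.
The result is ranked by final-round margin.

## Worked example

```bash
# a 586-neuron table mirroring the 7-type corpus imbalance (~81%
# pyramidal ... 0.3% Purkinje), 43 catalog-named features, 5 of them
# informative, 5 redundant, the rest noise:
bmsf simulate table --n 586 --seed 7 --out table.csv --truth truth.json

# BMSF selection:
bmsf select bmsf --table table.csv --k 50 --folds 10 --seed 7 --out sel.json
```

which prints (output of the commands above):

```
wrote 586 x 43 table to table.csv
selected 6 features (converged): N_s, NW, RP, Bar, Pc, HT
```

Six of 43 features survive, ranked by final-round margin: three of the
planted informative features (`N_s`, `NW`, `HT`), two redundant copies
(`RP` copies `N_s`, `Bar` copies `NW`) and one noise column.  The two
missed informative features mark the two rarest classes — 7 and 3
neurons out of 586 — whose contribution to overall accuracy is below
the selector's resolution at this imbalance; different seeds return
different but comparably predictive lists, which is expected behavior
for a wrapper selector on imbalanced data.  Then:

```bash
bmsf evaluate --table table.csv --selector bmsf --classifier svc_rbf \
     --reps 5 --seed 7 --out eval.json
```

writes a report with the replicated independent-test summary in
`mean ± SD` percent form (`accuracy_formatted`), per-class recalls, and
the features each replication selected, with a CSV mirror in `eval.csv`.
`bmsf hierarchy --table table.csv --out hier.json` runs the one-vs-rest
cascade (largest class vs the smaller ones, then the next, ...) and
records each level's accuracy/MCC/recall and private feature subset.

The same machinery is importable as a library
(`bmsf.selection.bmsf_select`, `bmsf.evaluation.replicate_experiment`,
...), and `bmsf features --swc-dir D --labels labels.csv --out table.csv`
computes the morphometric table from SWC reconstructions directly.

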