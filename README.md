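# toxprofile

Bioassay response profiling for animal acute toxicity.

High-throughput screening (HTS) repositories hold millions of qualitative
bioassay outcomes — *active*, *inactive*, *inconclusive* — for compounds that
also have in vivo endpoints such as rat oral LD50. `toxprofile` mines these
data to answer two questions a computational toxicologist asks of such a
collection:

1. **Which assays track the animal endpoint?** Each assay column is treated
   as a predictor of the binary toxicity label and ranked by relevance.
2. **Which compounds should be prioritized for animal testing?** Compounds
   are scored by a consensus over their responses in the selected assay
   panel.

The package is a library first (import `toxprofile`), with a thin
`toxprofile` command-line wrapper and a planted-signal simulator so the whole
workflow is testable without any database download.

## The model

**Response matrix.** Outcomes are encoded in a sparse compound × assay matrix
*M* with *M<sub>ij</sub>* ∈ {1, −1, 0} (active / inactive /
untested-or-inconclusive). Assays with fewer than 6 active responses are
dropped as uninformative (tunable). Compounds with −log₁₀ LD50 (mol/kg) > 3.00
are *toxic*, < 2.00 *nontoxic*, and the band in between is *marginal* and
excluded from assay evaluation.

**Assay relevance.** For assay vector *A<sub>i</sub>* against endpoint vector
*T* (compounds untested in the assay or without a binary label are excluded):

- sensitivity = TP / (TP + FN), specificity = TN / (TN + FP)
- CCR = (sensitivity + specificity) / 2 — the correct classification rate,
  robust to the active-poor imbalance of HTS columns
- L = sensitivity / FPR, FPR = FP / (FP + TN) — the likelihood-of-correlation
  parameter. L up-weights the true positive rate and collapses as false
  positives accumulate, encoding the asymmetry that an active response is
  evidence of toxicity while an inactive response is only weak evidence of
  safety
- Pearson χ² on the 2×2 table, reported for comparison

Panel selection is two-stage: assays with CCR > 0.6 become candidates, and
the top 50% of candidates ranked by L form the panel (both cutoffs tunable).

**Compound scoring.** Each panel cell contributes a normalized response

- active: R = A<sub>t</sub> / (A<sub>i</sub> · A<sub>j</sub>)
- inactive: R = −I<sub>t</sub> / (I<sub>i</sub> · I<sub>j</sub>)
- untested/inconclusive: R = 0

where A<sub>t</sub>, A<sub>i</sub>, A<sub>j</sub> are the total, per-assay and
per-compound active counts of the panel submatrix (I the inactive analogues).
R is the reciprocal of the cell's expected count under row/column
independence, so responses in promiscuous assays or broadly active compounds
are down-weighted. The **S score** of compound *j* is the sum of R over the
panel; S > 0 predicts toxic. A compound is scored only if it is *eligible*:
≥ 3 active panel responses, or (when its endpoint is known) a reported
response in more than half the panel.

## Worked example

```python
from toxprofile import (SyntheticSpec, simulate, filter_low_info_assays,
                        score_assays, rank_and_select, prioritize)

matrix, truth = simulate(SyntheticSpec(seed=7))   # 1,000 x 100 screen, 10 planted assays
filtered, _ = filter_low_info_assays(matrix)
selection = rank_and_select(score_assays(filtered, truth.labels))
ranking = prioritize(matrix, selection.panel_assays, labels=truth.labels)
print(ranking.head(3))
```

Running `python examples/prioritize_compounds.py` (the same computation)
prints:

```
Selected panel: ['A089', 'A041', 'A070', 'A012', 'A040']

255 of 1000 compounds are eligible
Top of the prioritization (S > 0 predicts toxic):
compound_id  s_score  n_active  n_inactive  n_reported  eligible  predicted_toxic label
      C0012    5.155         3           0           3      True             True toxic
      C0157    5.155         3           0           3      True             True toxic
...
Among the 138 compounds with S > 0, 98.6% are truly toxic (base rate among eligible: 61.6%)
```

Every assay in the selected panel is one of the planted toxicity-correlated
assays, and the S > 0 rule concentrates true toxicants far beyond the 61.6%
base rate of the eligible set — the behavior the consensus score is designed
for. The other scripts in `examples/` walk through matrix construction,
assay ranking and the file-based pipeline.

The same stages are available from the shell:

```sh
toxprofile simulate --seed 42 -o sim/
toxprofile rank-assays --matrix sim/matrix.tsv --labels sim/labels.tsv \
    -o relevance.tsv --panel-out panel.txt
toxprofile score-compounds --matrix sim/matrix.tsv --panel panel.txt \
    --labels sim/labels.tsv -o scores.tsv
```

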