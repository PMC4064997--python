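# Methods

## Problem setting

Public HTS repositories classify each tested (compound, assay) pair as
active, inactive or inconclusive; most pairs are untested. For a compound
collection with measured rat oral LD50, the package asks which assays'
active calls co-occur with in vivo toxicity, and then uses the selected
assays as a read-across panel to rank further compounds. The unit of
analysis is the response matrix M (rows compounds, columns assays, entries
1/−1/0), plus a per-compound endpoint vector T.

## Endpoint discretization

−log₁₀ LD50 in mol/kg is discretized with strict inequalities: > 3.00 toxic,
< 2.00 nontoxic, the closed band [2.00, 3.00] marginal. Boundary values fall
in the marginal band because both outer rules are strict. Marginal compounds
are removed before assay evaluation (they carry no binary signal) but are
reported untouched otherwise; `drop_marginal` preserves the toxic and
nontoxic counts exactly.

## Matrix construction

Long-format outcome records are rolled up per (compound, assay) with an
any-active-wins rule (active > inactive > no-call). This mirrors how several
substance-level deposits collapse onto one compound: a single confirmed
active is treated as evidence of activity regardless of other deposits.
Assays with fewer than `min_actives = 6` active responses among the target
compounds are removed; the cutoff is a pragmatic noise floor, not a fitted
quantity, and is exposed everywhere as a parameter.

## Assay relevance statistics

With compounds untested in the assay (entry 0) and compounds lacking a
binary label excluded, the 2×2 confusion table (TP: active & toxic, TN:
inactive & nontoxic, FP: active & nontoxic, FN: inactive & toxic) yields:

- **CCR** = (sensitivity + specificity) / 2. If the tested set contains no
  toxic or no nontoxic compounds, one rate is undefined and the assay is
  flagged unscorable (NaN) rather than imputed — the alternative of
  substituting 0 or 1 would systematically favor tiny, lopsided assays.
- **L** = sensitivity / FPR, the positive likelihood ratio. This is the
  package's reading of the likelihood-of-correlation parameter: it is the
  standard named statistic for "how much more likely is an active call in a
  toxic compound than a nontoxic one", it gives the true positive rate a
  multiplicative weight, and it decreases strictly and steeply as FP grows.
  Edge conventions: FP = 0 with sensitivity > 0 gives +inf (best possible;
  sorts ahead of any finite L, ties broken by assay id); TP = FP = 0 gives
  0 (no actives, no evidence); an empty toxic or nontoxic side gives NaN
  (unscorable). With TN = 0 the false positive rate is saturated at 1 and L
  degenerates to the sensitivity, so the strict-decrease law is guaranteed
  on the domain TP ≥ 1, TN ≥ 1 — the domain the property tests sweep.
- **χ²** is the Pearson statistic without continuity correction (a Yates
  flag is exposed); zero margins give NaN. It is computed through
  scipy and cross-checked in the tests against a from-scratch Σ(O−E)²/E.

## Panel selection

Candidates are assays with CCR strictly greater than the cutoff (default
0.6). Candidates are ordered by L descending with assay-id ascending as the
deterministic tie-break, and the panel is the first
floor(top_fraction × n_candidates) of them (default 0.5; 95 candidates give
a 47-assay panel). CCR alone over-selects assays with a handful of lucky
calls; L alone over-selects high-TPR assays with almost no active coverage;
the two-stage rule uses CCR as a sanity floor and L as the ranking. An
optional `min_l` floor further restricts the panel for users who prefer an
absolute threshold over a fraction.

## S score

Panel statistics (A_t, A_i, A_j and inactive analogues I_t, I_i, I_j) are
counted by default on the panel submatrix (`stats_scope="panel"`), keeping
the score self-contained in the assays actually used for ranking;
`stats_scope="full"` is available to normalize against the whole matrix.
The per-cell contribution R = M_ij · A_t/(A_i·A_j) (actives) or
M_ij · I_t/(I_i·I_j) (inactives) is the inverse of the cell's expected count
under independence of its row and column totals, i.e. a lift: an active
call in an assay that fires rarely, from a compound that is rarely active,
is up-weighted. Since a nonzero cell contributes to its own marginals the
denominators are always positive; this is asserted, not guarded. Zero
entries contribute exactly 0.0 (no floating-point residue), so a fully
untested compound scores exactly 0 and sits on the classification boundary,
which is deliberately *not* classified toxic (strict S > 0 rule).

Eligibility guards against over-interpreting sparse profiles: a compound is
scored if it has ≥ 3 active panel responses, or — when its endpoint is known
— a reported response in more than half the panel. "More than half" is
implemented as strictly more than round-half-up(fraction × panel size),
which yields 25 of 47. Compounds without an endpoint (the new-compound
screening use case) qualify only through the actives clause: for them an
abundance of inactive calls is not evidence about the endpoint.

## Synthetic data generator

`SyntheticSpec` plants a known subset of relevant assays whose active rate
is `relevant_sensitivity` in toxic and `relevant_fp_rate` in nontoxic
compounds; all other assays fire at `irrelevant_active_rate` regardless of
the label. Each cell is independently untested with probability
1 − `tested_fraction` and inconclusive with `inconclusive_fraction` given
tested. Defaults (1,000 compounds, 100 assays, 10 relevant, sensitivity
0.9, FP rate 0.02, base rate 0.05, half of cells tested, 5% inconclusive,
40% toxic prevalence) describe a strong-signal, sparse, active-poor screen
of desk scale. Continuous LD50 endpoints are drawn uniformly inside each
class band so the label derivation path is exercised too.

What the generator does **not** emulate: assay–assay correlation (real
tumor-line panels are highly collinear), compound-driven missingness
(untested cells are not random in practice), dose–response semantics, and
assay metadata. Passing recovery tests therefore demonstrate that the
statistics and selection logic do what they claim under known signal — not
that a particular public screen will yield a panel of any given quality.

The end-to-end check (`recovery_experiment`) reports *panel precision* —
the planted share of the selected panel — as the headline recovery metric,
with recall alongside. Precision is the right headline because its chance
level is simply n_relevant/n_assays under a signal-free generator, whereas
recall is mechanically capped by the panel size (half the candidate set)
whenever the candidates are dominated by the planted assays themselves.
The matched null control uses 100 compounds so that sampling noise in CCR
produces non-empty chance panels to measure; at 1,000 compounds the null
candidate set is empty and the control degenerates. Selection bias makes
the null's toxic/nontoxic S separation slightly positive (panels are chosen
for chance correlation on the same data), so the overlap check compares the
between-class gap to the within-class spread instead of expecting zero.

## Determinism and numerics

All simulation randomness flows through `numpy.random.default_rng` seeded
from the spec; replicate r of an experiment uses seed + r. Ranking and
prioritization tie-breaks are lexicographic on ids, so every output is a
pure function of inputs and parameters; the pipeline writes a manifest
(parameters, input SHA-256 digests, package version) and re-runs are
byte-identical. Counts are exact integers; the only floating-point
operations are the final rate divisions and R sums, so golden values are
asserted at 1e-12 and oracle comparisons at 1e-9.

## Known limitations

- The matrix is stored densely (int8); fine to ~10⁷ cells, not for
  repository-scale mining.
- L is undefined on assays whose tested compounds are all toxic or all
  nontoxic; such assays are excluded rather than rescued, which can discard
  a genuinely informative assay with pathological coverage.
- No multiple-testing control is applied to χ² (it is a descriptive
  comparison column, not a selection criterion).
- Compound identifiers are opaque strings; resolving vendor identifiers to
  a common registry is out of scope and must happen upstream.
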