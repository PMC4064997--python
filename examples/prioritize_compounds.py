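"""Score compounds with the consensus S score and prioritize them.

Uses a simulated screen: selects the assay panel, computes each
compound's S score (the sum of lift-normalized responses R over the
panel), applies the eligibility criteria (>= 3 actives, or a reported
response in more than half the panel) and ranks the eligible compounds.
"""
from toxprofile import (
    SyntheticSpec,
    filter_low_info_assays,
    prioritize,
    rank_and_select,
    score_assays,
    simulate,
)

spec = SyntheticSpec(seed=7)
matrix, truth = simulate(spec)
filtered, _ = filter_low_info_assays(matrix)
selection = rank_and_select(score_assays(filtered, truth.labels))
panel = selection.panel_assays
print(f"Selected panel: {panel}\n")

ranking = prioritize(matrix, panel, labels=truth.labels)
print(f"{len(ranking)} of {len(matrix.compound_ids)} compounds are eligible")
print("Top of the prioritization (S > 0 predicts toxic):")
print(ranking.head(8).to_string(index=False, float_format=lambda v: f"{v:.3f}"))

positive = ranking[ranking.predicted_toxic]
frac = (positive.label == "toxic").mean()
print(f"\nAmong the {len(positive)} compounds with S > 0, "
      f"{frac:.1%} are truly toxic "
      f"(base rate among eligible: {(ranking.label == 'toxic').mean():.1%})")
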