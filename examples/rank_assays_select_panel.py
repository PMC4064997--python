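"""Rank assays by relevance to the animal endpoint and select a panel.

Simulates a screen with 10 planted toxicity-correlated assays among 100,
filters out low-information assays, scores every remaining assay against
the endpoint (confusion counts, CCR, L, chi-square) and runs the
two-stage selection: CCR > 0.6 candidates, top 50% by L.
"""
from toxprofile import (
    SyntheticSpec,
    filter_low_info_assays,
    rank_and_select,
    relevance_table,
    score_assays,
    simulate,
)

spec = SyntheticSpec(seed=42)  # 1,000 compounds x 100 assays, 10 relevant
matrix, truth = simulate(spec)
matrix, removed = filter_low_info_assays(matrix, min_actives=6)
print(f"{len(removed)} low-information assays removed, {len(matrix.assay_ids)} ranked")

relevances = score_assays(matrix, truth.labels)
selection = rank_and_select(relevances, ccr_cutoff=0.6, top_fraction=0.5)
print(f"{len(selection.candidate_assays)} candidates with CCR > 0.6, "
      f"panel of {len(selection.panel_assays)} (min L in panel: "
      f"{selection.min_l_in_panel:.1f})\n")

table = relevance_table(relevances)
print("Top of the relevance ranking (L = sensitivity / false-positive rate;")
print("high L means actives concentrate in toxic compounds):")
print(table.head(8).to_string(index=False, float_format=lambda v: f"{v:.3f}"))

planted = set(truth.relevant_assay_ids)
hits = [a for a in selection.panel_assays if a in planted]
print(f"\nPlanted relevant assays recovered in the panel: {len(hits)}"
      f"/{len(selection.panel_assays)} panel slots are planted signal")
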