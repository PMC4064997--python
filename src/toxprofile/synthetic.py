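"""Planted-signal synthetic screening data.

Generates sparse compound × assay response matrices with a known subset of
toxicity-correlated ("relevant") assays, so every stage of the profiling
workflow — low-information filtering, relevance ranking, panel selection
and S scoring — can be exercised end to end with ground truth in hand.

Cells are independent: each is untested with probability
1 - tested_fraction, inconclusive with probability inconclusive_fraction
given tested (both encoded 0), and otherwise active with a rate that
depends on whether the assay is relevant and the compound toxic:

=================  =============  ====================
assay              toxic          nontoxic
=================  =============  ====================
relevant           sensitivity    false-positive rate
irrelevant         base rate      base rate
=================  =============  ====================

Cell-level independence is a deliberate simplification: real HTS panels
(e.g. 60 tumor-line growth screens) have strongly correlated columns.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import assay_relevance, compound_scoring
from .datamodel import ResponseMatrix, ToxicityLabels, filter_low_info_assays

__all__ = ["SyntheticSpec", "SyntheticTruth", "RecoverySummary", "simulate", "recovery_experiment"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for a planted-signal screening matrix.

    Defaults describe a desk-scale screen: 1,000 compounds against 100
    assays of which 10 genuinely track the endpoint with high sensitivity
    (0.9) and a low false-positive rate (0.02), against a 5% nonspecific
    active rate, half of all cells tested, and a 40% toxic prevalence.
    """

    n_compounds: int = 1000
    n_assays: int = 100
    toxic_fraction: float = 0.4
    n_relevant_assays: int = 10
    relevant_sensitivity: float = 0.9   # P(active | toxic, tested)
    relevant_fp_rate: float = 0.02      # P(active | nontoxic, tested)
    irrelevant_active_rate: float = 0.05
    tested_fraction: float = 0.5        # per-cell P(tested)
    inconclusive_fraction: float = 0.05  # P(inconclusive | tested)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_assays < 1:
            raise ValueError("n_compounds and n_assays must be >= 1")
        if not 0 <= self.n_relevant_assays <= self.n_assays:
            raise ValueError("n_relevant_assays must be in [0, n_assays]")
        if not 0.0 < self.toxic_fraction < 1.0:
            raise ValueError("toxic_fraction must be in (0, 1)")
        for name in ("relevant_sensitivity", "relevant_fp_rate", "irrelevant_active_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.tested_fraction <= 1.0:
            raise ValueError("tested_fraction must be in (0, 1]")
        if not 0.0 <= self.inconclusive_fraction < 1.0:
            raise ValueError("inconclusive_fraction must be in [0, 1)")

    @property
    def has_planted_signal(self) -> bool:
        return self.relevant_sensitivity > self.relevant_fp_rate


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated screen."""

    labels: ToxicityLabels
    relevant_assay_ids: list[str]
    diagnostics: dict = field(default_factory=dict)


def simulate(spec: SyntheticSpec) -> tuple[ResponseMatrix, SyntheticTruth]:
    """Draw one matrix + label set from the spec; reproducible given seed."""
    rng = np.random.default_rng(spec.seed)
    width_c = max(4, len(str(spec.n_compounds)))
    width_a = max(3, len(str(spec.n_assays)))
    compound_ids = [f"C{i:0{width_c}d}" for i in range(1, spec.n_compounds + 1)]
    assay_ids = [f"A{i:0{width_a}d}" for i in range(1, spec.n_assays + 1)]

    toxic = rng.random(spec.n_compounds) < spec.toxic_fraction
    # continuous endpoint consistent with the class thresholds (strictly
    # above 3.00 toxic, strictly below 2.00 nontoxic)
    ld50 = np.where(
        toxic,
        rng.uniform(3.0 + 1e-6, 6.0, spec.n_compounds),
        rng.uniform(0.0, 2.0 - 1e-6, spec.n_compounds),
    )
    labels = ToxicityLabels.from_ld50(pd.Series(ld50, index=compound_ids))

    relevant_idx = rng.choice(spec.n_assays, size=spec.n_relevant_assays, replace=False)
    relevant_mask = np.zeros(spec.n_assays, dtype=bool)
    relevant_mask[relevant_idx] = True
    relevant_ids = [assay_ids[i] for i in sorted(relevant_idx)]

    shape = (spec.n_compounds, spec.n_assays)
    tested = rng.random(shape) < spec.tested_fraction
    inconclusive = tested & (rng.random(shape) < spec.inconclusive_fraction)
    conclusive = tested & ~inconclusive

    # active rate per cell: relevant columns condition on the compound label
    p_active = np.full(shape, spec.irrelevant_active_rate)
    rel_rates = np.where(toxic, spec.relevant_sensitivity, spec.relevant_fp_rate)
    p_active[:, relevant_mask] = rel_rates[:, None]

    active = conclusive & (rng.random(shape) < p_active)
    values = np.zeros(shape, dtype=np.int8)
    values[conclusive] = -1
    values[active] = 1

    matrix = ResponseMatrix(
        pd.DataFrame(values, index=pd.Index(compound_ids, dtype=str),
                     columns=pd.Index(assay_ids, dtype=str))
    )
    truth = SyntheticTruth(
        labels=labels,
        relevant_assay_ids=relevant_ids,
        diagnostics={
            "n_untested": int((~tested).sum()),
            "n_inconclusive": int(inconclusive.sum()),
            "n_active": int(active.sum()),
            "n_inactive": int((values == -1).sum()),
        },
    )
    return matrix, truth


@dataclass
class RecoverySummary:
    """Per-replicate and aggregate recovery metrics of an end-to-end run.

    The headline *recovery* is panel precision — the fraction of the
    selected panel made up of planted relevant assays — whose chance level
    under a signal-free generator is n_relevant / n_assays.  Recall (the
    fraction of planted assays recovered) is reported alongside; note that
    recall is capped by panel size over n_relevant whenever the candidate
    set is dominated by the planted assays themselves.
    """

    panel_precisions: list[float]        # planted share of the panel; NaN if empty
    relevant_recalls: list[float]        # planted assays found / n_relevant
    chance_levels: list[float]           # n_relevant / assays ranked, per rep
    s_separations: list[float]           # mean S toxic - mean S nontoxic
    s_positive_precisions: list[float]   # P(toxic | S>0, eligible); NaN if none
    toxic_base_rates: list[float]        # P(toxic | eligible)
    panel_sizes: list[int]
    n_relevant_in_panel: list[int]

    @property
    def recovery_fractions(self) -> list[float]:
        return self.panel_precisions

    @property
    def mean_recovery(self) -> float:
        return float(np.nanmean(self.panel_precisions))

    @property
    def pooled_precision(self) -> float:
        """Aggregate precision: planted slots over all panel slots, robust
        to the tiny/empty panels a signal-free generator produces."""
        total = sum(self.panel_sizes)
        return sum(self.n_relevant_in_panel) / total if total else float("nan")

    @property
    def mean_recall(self) -> float:
        return float(np.nanmean(self.relevant_recalls))

    @property
    def mean_chance(self) -> float:
        return float(np.nanmean(self.chance_levels))

    @property
    def mean_separation(self) -> float:
        return float(np.nanmean(self.s_separations))

    @property
    def sd_separation(self) -> float:
        vals = [v for v in self.s_separations if not np.isnan(v)]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def recovery_experiment(
    spec: SyntheticSpec,
    n_reps: int = 20,
    ccr_cutoff: float = 0.6,
    top_fraction: float = 0.5,
    min_actives: int = 6,
    compound_min_actives: int = 3,
    coverage_fraction: float = 0.5,
) -> RecoverySummary:
    """Run the full workflow on ``n_reps`` independent replicates.

    Each replicate reseeds the spec with ``spec.seed + rep``, simulates a
    matrix, applies the low-information assay filter, ranks and selects the
    panel, and computes S scores.  Reported per replicate: the planted
    share of the panel (precision) and its chance level, the recall of
    planted assays, the toxic-vs-nontoxic mean S separation, and the
    precision of the S>0 rule among eligible compounds.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    precisions, recalls, chance, seps, precs, bases, sizes, founds = (
        [], [], [], [], [], [], [], []
    )
    for rep in range(n_reps):
        m, truth = simulate(replace(spec, seed=spec.seed + rep))
        filtered, _ = filter_low_info_assays(m, min_actives=min_actives)
        relevances = assay_relevance.score_assays(filtered, truth.labels)
        sel = assay_relevance.rank_and_select(
            relevances, ccr_cutoff=ccr_cutoff, top_fraction=top_fraction
        )
        panel = sel.panel_assays
        n_rel = len(truth.relevant_assay_ids)
        found = len(set(panel) & set(truth.relevant_assay_ids))
        founds.append(found)
        precisions.append(found / len(panel) if panel else float("nan"))
        recalls.append(found / n_rel if n_rel else float("nan"))
        n_ranked = len(filtered.assay_ids)
        n_rel_ranked = len(set(filtered.assay_ids) & set(truth.relevant_assay_ids))
        chance.append(n_rel_ranked / n_ranked if n_ranked else float("nan"))
        sizes.append(len(panel))

        if panel:
            s = compound_scoring.s_scores(m, panel)
            t = truth.labels.sign_vector(m.compound_ids)
            seps.append(float(s[t == 1].mean() - s[t == -1].mean()))
            ranking = compound_scoring.prioritize(
                m, panel, labels=truth.labels,
                min_actives=compound_min_actives,
                coverage_fraction=coverage_fraction,
            )
            pos = ranking[ranking["predicted_toxic"]]
            precs.append(
                float((pos["label"] == "toxic").mean()) if len(pos) else float("nan")
            )
            bases.append(
                float((ranking["label"] == "toxic").mean()) if len(ranking) else float("nan")
            )
        else:
            seps.append(float("nan"))
            precs.append(float("nan"))
            bases.append(float("nan"))
    return RecoverySummary(
        panel_precisions=precisions,
        relevant_recalls=recalls,
        chance_levels=chance,
        s_separations=seps,
        s_positive_precisions=precs,
        toxic_base_rates=bases,
        panel_sizes=sizes,
        n_relevant_in_panel=founds,
    )
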