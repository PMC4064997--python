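"""Assay relevance scoring against a binary animal-toxicity endpoint.

Each assay column A_i of the response matrix is treated as a predictor of
the endpoint vector T (toxic = +1, nontoxic = -1).  Compounds that are
untested/inconclusive in the assay (entry 0) or marginal/unlabeled in T are
excluded; the remaining compounds form a 2×2 confusion table from which
three relevance statistics are computed:

* CCR — the correct classification rate, the mean of sensitivity
  TP/(TP+FN) and specificity TN/(TN+FP) (balanced accuracy, robust to the
  strong active/inactive imbalance of HTS data);
* L — the likelihood-of-correlation parameter, the positive likelihood
  ratio sensitivity / FPR where FPR = FP/(FP+TN).  L up-weights the true
  positive rate and collapses quickly as false positives accumulate, which
  encodes the systemic-toxicity asymmetry: an active response is evidence
  of toxicity, an inactive response is weak evidence of safety;
* chi² — the Pearson association statistic on the 2×2 table, reported for
  comparison with the L ranking.

Panel selection is two-stage: pre-select candidates with CCR strictly above
a cutoff (default 0.6), then keep the top fraction (default 50%) ranked by
L descending.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ResponseMatrix, ToxicityLabels

__all__ = [
    "ConfusionCounts",
    "AssayRelevance",
    "SelectionResult",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "ccr",
    "l_score",
    "chi2_association",
    "score_assays",
    "relevance_table",
    "rank_and_select",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 cross-tabulation of assay response vs animal endpoint.

    TP: active in assay and toxic; TN: inactive in assay and nontoxic;
    FP: active in assay but nontoxic; FN: inactive in assay but toxic.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(assay_column: pd.Series, labels: ToxicityLabels) -> ConfusionCounts:
    """Cross-tabulate one assay vector against the endpoint vector T.

    Compounds with a 0 entry (untested/inconclusive) or without a binary
    label (marginal or absent) contribute to no cell.
    """
    a = pd.Series(assay_column)
    t = labels.sign_vector(a.index)
    a_np = a.to_numpy()
    t_np = t.to_numpy()
    mask = (a_np != 0) & (t_np != 0)
    a_np, t_np = a_np[mask], t_np[mask]
    return ConfusionCounts(
        tp=int(((a_np == 1) & (t_np == 1)).sum()),
        fp=int(((a_np == 1) & (t_np == -1)).sum()),
        tn=int(((a_np == -1) & (t_np == -1)).sum()),
        fn=int(((a_np == -1) & (t_np == 1)).sum()),
    )


def sensitivity(counts: ConfusionCounts) -> float:
    """True positive rate TP/(TP+FN); NaN when no toxic compound was tested."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else math.nan


def specificity(counts: ConfusionCounts) -> float:
    """True negative rate TN/(TN+FP); NaN when no nontoxic compound was tested."""
    denom = counts.tn + counts.fp
    return counts.tn / denom if denom else math.nan


def ccr(counts: ConfusionCounts) -> float:
    """Correct classification rate: (sensitivity + specificity) / 2.

    Undefined (NaN) when either the toxic side (TP+FN) or the nontoxic side
    (TN+FP) is empty; such assays are flagged unscorable rather than given
    imputed rates.
    """
    se, sp = sensitivity(counts), specificity(counts)
    if math.isnan(se) or math.isnan(sp):
        return math.nan
    return (se + sp) / 2.0


def l_score(counts: ConfusionCounts) -> float:
    """Likelihood-of-correlation parameter L = sensitivity / FPR.

    L rises with the true positive rate and falls sharply as false
    positives accumulate.  Edge conventions: with no false positives and a
    positive TPR the evidence is unbounded (+inf, sorts first); with no
    actives at all (TP = FP = 0) there is no evidence (0.0); with an empty
    toxic or nontoxic side the statistic is undefined (NaN, unscorable).
    """
    pos = counts.tp + counts.fn
    neg = counts.fp + counts.tn
    if pos == 0 or neg == 0:
        return math.nan
    se = counts.tp / pos
    fpr = counts.fp / neg
    if fpr == 0.0:
        return math.inf if se > 0.0 else 0.0
    return se / fpr


def chi2_association(counts: ConfusionCounts, correction: bool = False) -> float:
    """Pearson chi-square statistic on the 2×2 table (no Yates correction
    by default).  NaN when any row or column margin is zero."""
    table = np.array([[counts.tp, counts.fn], [counts.fp, counts.tn]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return math.nan
    stat, _, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat)


@dataclass
class AssayRelevance:
    """Per-assay relevance record: confusion counts plus the derived
    statistics and, after selection, the panel rank."""

    assay_id: str
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    ccr: float
    l_score: float
    chi2: float
    candidate: bool = False
    panel: bool = False
    rank: int | None = None

    @property
    def scorable(self) -> bool:
        return not math.isnan(self.ccr)


def score_assays(
    m: ResponseMatrix,
    labels: ToxicityLabels,
    chi2_correction: bool = False,
) -> list[AssayRelevance]:
    """Score every assay column of the matrix against the endpoint."""
    out = []
    for aid in m.assay_ids:
        c = confusion_counts(m.column(aid), labels)
        out.append(
            AssayRelevance(
                assay_id=aid,
                counts=c,
                sensitivity=sensitivity(c),
                specificity=specificity(c),
                ccr=ccr(c),
                l_score=l_score(c),
                chi2=chi2_association(c, correction=chi2_correction),
            )
        )
    return out


@dataclass
class SelectionResult:
    """Outcome of the two-stage panel selection."""

    candidate_assays: list[str]
    panel_assays: list[str]  # ordered by l_score descending
    ccr_cutoff: float
    top_fraction: float
    min_l_in_panel: float = math.nan
    relevances: list[AssayRelevance] = field(default_factory=list)


def _sort_key(r: AssayRelevance) -> tuple[float, str]:
    # descending l_score (inf first), ties broken by assay_id ascending
    return (-r.l_score, r.assay_id)


def rank_and_select(
    relevances: list[AssayRelevance],
    ccr_cutoff: float = 0.6,
    top_fraction: float = 0.5,
    min_l: float | None = None,
) -> SelectionResult:
    """Two-stage selection: CCR strictly above ``ccr_cutoff`` pre-selects
    candidates; the top ``floor(top_fraction * n_candidates)`` of them by L
    (descending, ties by assay id) form the panel.  ``min_l`` optionally
    further restricts the panel to assays with L >= min_l.

    Mutates the relevance records in place (candidate/panel flags, rank of
    candidates in L order).
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    candidates = [r for r in relevances if r.scorable and r.ccr > ccr_cutoff]
    for r in relevances:
        r.candidate = False
        r.panel = False
        r.rank = None
    candidates.sort(key=_sort_key)
    for i, r in enumerate(candidates, start=1):
        r.candidate = True
        r.rank = i
    n_panel = math.floor(top_fraction * len(candidates))
    panel = candidates[:n_panel]
    if min_l is not None:
        panel = [r for r in panel if r.l_score >= min_l]
    for r in panel:
        r.panel = True
    if not candidates:
        logger.warning(
            "no assay passed CCR > %.3g; panel is empty", ccr_cutoff
        )
    return SelectionResult(
        candidate_assays=[r.assay_id for r in candidates],
        panel_assays=[r.assay_id for r in panel],
        ccr_cutoff=ccr_cutoff,
        top_fraction=top_fraction,
        min_l_in_panel=min((r.l_score for r in panel), default=math.nan),
        relevances=list(relevances),
    )


def relevance_table(relevances: list[AssayRelevance]) -> pd.DataFrame:
    """Flatten relevance records into the ranking TSV layout."""
    rows = [
        {
            "assay_id": r.assay_id,
            "tp": r.counts.tp,
            "fp": r.counts.fp,
            "tn": r.counts.tn,
            "fn": r.counts.fn,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "ccr": r.ccr,
            "l_score": r.l_score,
            "chi2": r.chi2,
            "candidate_flag": r.candidate,
            "panel_flag": r.panel,
            "rank": r.rank if r.rank is not None else "",
        }
        for r in relevances
    ]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["ccr", "l_score", "assay_id"], ascending=[False, False, True], na_position="last"
        ).reset_index(drop=True)
    return df
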