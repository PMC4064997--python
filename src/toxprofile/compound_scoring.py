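"""Consensus S-score compound prioritization over a selected assay panel.

Each cell of the panel submatrix contributes a normalized response value R:
for an active entry, R = A_t / (A_i · A_j) where A_t is the total number of
active responses in the submatrix, A_i the actives in that assay and A_j
the actives of that compound; for an inactive entry, R = -I_t / (I_i · I_j)
with the analogous inactive counts; untested/inconclusive cells contribute
exactly 0.  R is the reciprocal of the expected cell count under row/column
independence (a lift), so responses concentrated in promiscuous assays or
broadly active compounds are down-weighted.  The S score of a compound is
the sum of R over the panel; larger S means higher predicted acute-toxicity
potential, with S = 0 the classification boundary.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ResponseMatrix, ToxClass, ToxicityLabels

__all__ = [
    "PanelStats",
    "CompoundScore",
    "panel_stats",
    "response_value",
    "response_values",
    "s_score",
    "s_scores",
    "coverage_threshold",
    "eligibility",
    "classify_compound",
    "prioritize",
    "panel_profiles",
]

logger = logging.getLogger(__name__)


@dataclass
class PanelStats:
    """Active/inactive count summaries of a panel submatrix.

    Conservation holds by construction: sum(a_i) = sum(a_j) = a_t and
    sum(i_i) = sum(i_j) = i_t.
    """

    panel: list[str]
    a_t: int
    i_t: int
    a_i: pd.Series  # actives per assay
    i_i: pd.Series  # inactives per assay
    a_j: pd.Series  # actives per compound
    i_j: pd.Series  # inactives per compound


def panel_stats(m: ResponseMatrix, panel: Sequence[str]) -> PanelStats:
    """Count actives and inactives on the submatrix restricted to the panel."""
    missing = [a for a in panel if a not in m.data.columns]
    if missing:
        raise KeyError(f"panel assay not in matrix: {missing[0]!r}")
    sub = m.data[list(panel)]
    active = sub == 1
    inactive = sub == -1
    return PanelStats(
        panel=list(panel),
        a_t=int(active.to_numpy().sum()),
        i_t=int(inactive.to_numpy().sum()),
        a_i=active.sum(axis=0),
        i_i=inactive.sum(axis=0),
        a_j=active.sum(axis=1),
        i_j=inactive.sum(axis=1),
    )


def response_value(entry: int, stats: PanelStats, assay: str, compound: str) -> float:
    """Normalized response R for one cell.

    0 entries (untested or inconclusive) contribute exactly 0.  For nonzero
    entries the normalizing counts include the cell itself, so the
    denominators are necessarily positive; a zero denominator indicates the
    stats were computed on a different submatrix and is asserted against.
    """
    if entry == 0:
        return 0.0
    if entry == 1:
        a_i, a_j = int(stats.a_i[assay]), int(stats.a_j[compound])
        assert a_i > 0 and a_j > 0 and stats.a_t > 0, (
            "active entry with zero active counts: stats inconsistent with submatrix"
        )
        return stats.a_t / (a_i * a_j)
    if entry == -1:
        i_i, i_j = int(stats.i_i[assay]), int(stats.i_j[compound])
        assert i_i > 0 and i_j > 0 and stats.i_t > 0, (
            "inactive entry with zero inactive counts: stats inconsistent with submatrix"
        )
        return -stats.i_t / (i_i * i_j)
    raise ValueError(f"entry must be 1, -1 or 0, got {entry!r}")


def _stats_for_scope(
    m: ResponseMatrix, panel: Sequence[str], stats_scope: str
) -> PanelStats:
    if stats_scope == "panel":
        return panel_stats(m, panel)
    if stats_scope == "full":
        full = panel_stats(m, m.assay_ids)
        full.panel = list(panel)
        return full
    raise ValueError(f"stats_scope must be 'panel' or 'full', got {stats_scope!r}")


def response_values(
    m: ResponseMatrix,
    panel: Sequence[str],
    stats: PanelStats | None = None,
    stats_scope: str = "panel",
) -> pd.DataFrame:
    """R values for every (compound, panel assay) cell, vectorized."""
    if stats is None:
        stats = _stats_for_scope(m, panel, stats_scope)
    sub = m.data[list(panel)].to_numpy(dtype=np.int8)
    a_i = stats.a_i[list(panel)].to_numpy(dtype=float)
    i_i = stats.i_i[list(panel)].to_numpy(dtype=float)
    a_j = stats.a_j.reindex(m.compound_ids).to_numpy(dtype=float)
    i_j = stats.i_j.reindex(m.compound_ids).to_numpy(dtype=float)
    r = np.zeros(sub.shape, dtype=float)
    act = sub == 1
    inact = sub == -1
    with np.errstate(divide="ignore", invalid="ignore"):
        r_act = stats.a_t / np.outer(a_j, a_i)
        r_inact = -stats.i_t / np.outer(i_j, i_i)
    r[act] = r_act[act]
    r[inact] = r_inact[inact]
    assert np.isfinite(r).all(), "stats inconsistent with submatrix"
    return pd.DataFrame(r, index=m.data.index, columns=list(panel))


def s_scores(
    m: ResponseMatrix,
    panel: Sequence[str],
    stats: PanelStats | None = None,
    stats_scope: str = "panel",
) -> pd.Series:
    """S score for every compound: row sums of the R matrix."""
    return response_values(m, panel, stats=stats, stats_scope=stats_scope).sum(axis=1)


def s_score(
    m: ResponseMatrix,
    panel: Sequence[str],
    compound: str,
    stats: PanelStats | None = None,
    stats_scope: str = "panel",
) -> float:
    """S score of a single compound (sum of R over the panel assays)."""
    if compound not in m.data.index:
        raise KeyError(f"compound not in matrix: {compound!r}")
    return float(s_scores(m, panel, stats=stats, stats_scope=stats_scope)[compound])


def coverage_threshold(panel_size: int, coverage_fraction: float = 0.5) -> int:
    """Smallest reported-response count satisfying the coverage clause.

    "More than ``coverage_fraction`` of the panel", with the fractional
    panel share rounded half-up before the strict comparison: for a
    47-assay panel at 0.5 this gives 25.
    """
    if panel_size < 1:
        raise ValueError("panel_size must be >= 1")
    return int(math.floor(coverage_fraction * panel_size + 0.5)) + 1


def eligibility(
    n_active: int,
    n_reported: int,
    panel_size: int,
    min_actives: int = 3,
    coverage_fraction: float = 0.5,
    labeled: bool = True,
) -> bool:
    """A compound is classifiable from its profile if it has at least
    ``min_actives`` active panel responses, or (for compounds with a known
    endpoint) a reported response in more than ``coverage_fraction`` of the
    panel.  Unlabeled screening compounds qualify only via the actives
    clause."""
    if n_active >= min_actives:
        return True
    return labeled and n_reported >= coverage_threshold(panel_size, coverage_fraction)


def classify_compound(s: float, threshold: float = 0.0) -> bool:
    """Predicted toxic iff S is strictly above the threshold (default 0)."""
    return bool(s > threshold)


@dataclass
class CompoundScore:
    compound_id: str
    s_score: float
    n_active: int
    n_inactive: int
    n_reported: int
    eligible: bool
    predicted_toxic: bool
    label: str = "unknown"


def prioritize(
    m: ResponseMatrix,
    panel: Sequence[str],
    labels: ToxicityLabels | None = None,
    min_actives: int = 3,
    coverage_fraction: float = 0.5,
    s_threshold: float = 0.0,
    stats_scope: str = "panel",
) -> pd.DataFrame:
    """Rank eligible compounds by S score.

    Returns a DataFrame (one row per eligible compound, S descending, ties
    by compound id) with columns compound_id, s_score, n_active,
    n_inactive, n_reported, eligible, predicted_toxic, label.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    stats = _stats_for_scope(m, panel, stats_scope)
    sub = m.data[panel]
    n_active = (sub == 1).sum(axis=1)
    n_inactive = (sub == -1).sum(axis=1)
    scores = s_scores(m, panel, stats=stats)
    rows = []
    for cid in m.compound_ids:
        if labels is not None and cid in labels:
            label = labels.classes[cid]
            labeled = label in (ToxClass.TOXIC.value, ToxClass.NONTOXIC.value)
        else:
            label, labeled = "unknown", False
        na, ni = int(n_active[cid]), int(n_inactive[cid])
        elig = eligibility(
            na, na + ni, len(panel),
            min_actives=min_actives,
            coverage_fraction=coverage_fraction,
            labeled=labeled,
        )
        if not elig:
            continue
        s = float(scores[cid])
        rows.append(
            {
                "compound_id": cid,
                "s_score": s,
                "n_active": na,
                "n_inactive": ni,
                "n_reported": na + ni,
                "eligible": True,
                "predicted_toxic": classify_compound(s, threshold=s_threshold),
                "label": label,
            }
        )
    if not rows:
        logger.warning("no compound met the eligibility criteria; empty ranking")
        return pd.DataFrame(
            columns=[
                "compound_id", "s_score", "n_active", "n_inactive",
                "n_reported", "eligible", "predicted_toxic", "label",
            ]
        )
    df = pd.DataFrame(rows).sort_values(
        ["s_score", "compound_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return df


def panel_profiles(
    m: ResponseMatrix,
    panel: Sequence[str],
    compound_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """The 1/-1/0 panel profiles behind a prioritization, rows ordered as
    given (typically by descending S) — the data behind a response heatmap."""
    sub = m.data[list(panel)]
    if compound_order is not None:
        sub = sub.loc[list(compound_order)]
    return sub.copy()


def export_heatmap(profiles: pd.DataFrame, path, labels: ToxicityLabels | None = None):
    """Render 1/-1/0 panel profiles as a PNG heatmap (active red,
    inactive green, no data grey).  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    cmap = ListedColormap(["#7fbf7f", "#d9d9d9", "#d7191c"])  # -1, 0, 1
    norm = BoundaryNorm([-1.5, -0.5, 0.5, 1.5], cmap.N)
    height = max(2.0, 0.12 * len(profiles))
    width = max(3.0, 0.25 * len(profiles.columns))
    fig, ax = plt.subplots(figsize=(width, height))
    ax.imshow(profiles.to_numpy(), aspect="auto", cmap=cmap, norm=norm,
              interpolation="nearest")
    ax.set_xticks(range(len(profiles.columns)))
    ax.set_xticklabels(profiles.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(profiles)))
    ticklabels = list(profiles.index)
    if labels is not None:
        ticklabels = [
            f"{cid} [{labels.classes.get(cid, 'unknown')}]" for cid in ticklabels
        ]
    ax.set_yticklabels(ticklabels, fontsize=6)
    ax.set_xlabel("panel assay")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
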