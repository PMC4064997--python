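"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive element-by-element loops so they stay
independent of the vectorized implementation paths they check.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from toxprofile import ResponseMatrix, ToxClass, ToxicityLabels


# ---------------------------------------------------------------- oracles
def brute_confusion(assay_column: pd.Series, labels: ToxicityLabels) -> dict[str, int]:
    """Naive per-compound confusion recount."""
    counts = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for cid, entry in assay_column.items():
        if entry == 0 or cid not in labels:
            continue
        cls = labels.class_of(cid)
        if cls == ToxClass.MARGINAL:
            continue
        toxic = cls == ToxClass.TOXIC
        if entry == 1 and toxic:
            counts["tp"] += 1
        elif entry == 1 and not toxic:
            counts["fp"] += 1
        elif entry == -1 and not toxic:
            counts["tn"] += 1
        else:
            counts["fn"] += 1
    return counts


def brute_chi2(tp: int, fn: int, fp: int, tn: int) -> float:
    """Pearson statistic from first principles: sum (O-E)^2/E over the
    2x2 table with margins-derived expectations."""
    obs = [[tp, fn], [fp, tn]]
    n = tp + fn + fp + tn
    rows = [tp + fn, fp + tn]
    cols = [tp + fp, fn + tn]
    if n == 0 or 0 in rows or 0 in cols:
        return float("nan")
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (obs[i][j] - e) ** 2 / e
    return stat


def brute_panel_counts(m: ResponseMatrix, panel: list[str]) -> dict:
    """Naive recount of the six panel-stat quantities."""
    a_t = i_t = 0
    a_i = {a: 0 for a in panel}
    i_i = {a: 0 for a in panel}
    a_j = {c: 0 for c in m.compound_ids}
    i_j = {c: 0 for c in m.compound_ids}
    for c in m.compound_ids:
        for a in panel:
            v = m.entry(c, a)
            if v == 1:
                a_t += 1
                a_i[a] += 1
                a_j[c] += 1
            elif v == -1:
                i_t += 1
                i_i[a] += 1
                i_j[c] += 1
    return {"a_t": a_t, "i_t": i_t, "a_i": a_i, "i_i": i_i, "a_j": a_j, "i_j": i_j}


def random_matrix(rng: np.random.Generator, n_compounds: int, n_assays: int,
                  p=(0.5, 0.3, 0.2)) -> ResponseMatrix:
    """Random sparse matrix with P(0), P(-1), P(1) as given."""
    vals = rng.choice([0, -1, 1], size=(n_compounds, n_assays), p=list(p))
    return ResponseMatrix(pd.DataFrame(
        vals.astype(np.int8),
        index=[f"c{i}" for i in range(n_compounds)],
        columns=[f"a{j}" for j in range(n_assays)],
    ))


def random_labels(rng: np.random.Generator, compound_ids: list[str],
                  p_toxic=0.4, p_marginal=0.1) -> ToxicityLabels:
    classes = rng.choice(
        [ToxClass.TOXIC.value, ToxClass.MARGINAL.value, ToxClass.NONTOXIC.value],
        size=len(compound_ids),
        p=[p_toxic, p_marginal, 1 - p_toxic - p_marginal],
    )
    return ToxicityLabels(classes=pd.Series(classes, index=compound_ids))


# ---------------------------------------------------------------- fixtures
@pytest.fixture
def toy_matrix() -> ResponseMatrix:
    """3x3 matrix whose normalized response values are hand-evaluated in
    the compound-scoring golden tests."""
    return ResponseMatrix(pd.DataFrame(
        [[1, -1, 0],
         [0, 1, 1],
         [-1, 0, 1]],
        index=["c1", "c2", "c3"],
        columns=["a1", "a2", "a3"],
    ))


@pytest.fixture
def four_compound_labels() -> ToxicityLabels:
    return ToxicityLabels.from_classes(
        {"c1": "toxic", "c2": "toxic", "c3": "nontoxic", "c4": "nontoxic"}
    )
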