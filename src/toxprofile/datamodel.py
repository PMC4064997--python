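"""Core data types for bioassay response profiling.

The central object is the compound × assay *response matrix* M with entries
in {1, -1, 0}: 1 for an active outcome, -1 for inactive, 0 for untested or
inconclusive.  Animal acute-toxicity endpoints arrive as -log10(LD50) in
mol/kg and are discretized into toxic / marginal / nontoxic classes.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Outcome",
    "OutcomeRecord",
    "ToxClass",
    "ToxicityLabels",
    "ResponseMatrix",
    "build_matrix",
    "classify_ld50",
    "drop_marginal",
    "filter_low_info_assays",
    "TOXIC_THRESHOLD",
    "NONTOXIC_THRESHOLD",
]

#: -log10(LD50 mol/kg) strictly above this -> toxic
TOXIC_THRESHOLD = 3.00
#: -log10(LD50 mol/kg) strictly below this -> nontoxic
NONTOXIC_THRESHOLD = 2.00


class Outcome(str, enum.Enum):
    """A single bioassay outcome as classified by the depositing screen."""

    ACTIVE = "active"
    INACTIVE = "inactive"
    INCONCLUSIVE = "inconclusive"
    UNTESTED = "untested"

    @classmethod
    def from_string(cls, s: str) -> "Outcome":
        try:
            return cls(s.strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(
                f"unknown outcome {s!r}; expected one of: {valid}"
            ) from None

    @property
    def matrix_value(self) -> int:
        """Matrix encoding: active -> 1, inactive -> -1, otherwise 0."""
        if self is Outcome.ACTIVE:
            return 1
        if self is Outcome.INACTIVE:
            return -1
        return 0


@dataclass(frozen=True)
class OutcomeRecord:
    """One (compound, assay) outcome from a long-format table."""

    compound_id: str
    assay_id: str
    outcome: Outcome

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if not self.assay_id:
            raise ValueError("assay_id must be non-empty")
        if not isinstance(self.outcome, Outcome):
            raise TypeError("outcome must be an Outcome enum member")


class ToxClass(str, enum.Enum):
    TOXIC = "toxic"
    MARGINAL = "marginal"
    NONTOXIC = "nontoxic"


def classify_ld50(neg_log_ld50: float) -> ToxClass:
    """Discretize -log10(LD50 mol/kg) into an acute-toxicity class.

    Strictly above 3.00 is toxic, strictly below 2.00 is nontoxic and the
    closed band [2.00, 3.00] (boundaries included) is marginal.
    """
    x = float(neg_log_ld50)
    if not math.isfinite(x):
        raise ValueError(f"neg_log_ld50 must be finite, got {neg_log_ld50!r}")
    if x > TOXIC_THRESHOLD:
        return ToxClass.TOXIC
    if x < NONTOXIC_THRESHOLD:
        return ToxClass.NONTOXIC
    return ToxClass.MARGINAL


@dataclass
class ToxicityLabels:
    """Per-compound acute-toxicity endpoint.

    ``classes`` maps compound_id -> ToxClass value string; ``neg_log_ld50``
    optionally carries the underlying continuous endpoint, in which case the
    class of every compound with a value is derived from it.
    """

    classes: pd.Series
    neg_log_ld50: pd.Series | None = None

    def __post_init__(self) -> None:
        self.classes = pd.Series(self.classes, dtype="object")
        self.classes.index = self.classes.index.astype(str)
        if self.classes.index.has_duplicates:
            dups = self.classes.index[self.classes.index.duplicated()].tolist()
            raise ValueError(f"duplicate compound ids in labels: {dups[:5]}")
        bad = set(self.classes) - {c.value for c in ToxClass}
        if bad:
            raise ValueError(f"invalid toxicity classes: {sorted(bad)[:5]}")
        if self.neg_log_ld50 is not None:
            self.neg_log_ld50 = pd.Series(self.neg_log_ld50, dtype=float)
            self.neg_log_ld50.index = self.neg_log_ld50.index.astype(str)
            for cid, val in self.neg_log_ld50.items():
                derived = classify_ld50(val).value
                if cid in self.classes.index and self.classes[cid] != derived:
                    raise ValueError(
                        f"compound {cid}: class {self.classes[cid]!r} "
                        f"inconsistent with neg_log_ld50={val} ({derived!r})"
                    )

    @classmethod
    def from_ld50(cls, neg_log_ld50: pd.Series) -> "ToxicityLabels":
        s = pd.Series(neg_log_ld50, dtype=float)
        classes = s.map(lambda v: classify_ld50(v).value)
        return cls(classes=classes, neg_log_ld50=s)

    @classmethod
    def from_classes(cls, mapping: dict[str, ToxClass | str]) -> "ToxicityLabels":
        vals = {
            str(k): (v.value if isinstance(v, ToxClass) else str(v).lower())
            for k, v in mapping.items()
        }
        return cls(classes=pd.Series(vals, dtype="object"))

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.classes.index

    @property
    def compound_ids(self) -> list[str]:
        return self.classes.index.tolist()

    def class_of(self, compound_id: str) -> ToxClass:
        return ToxClass(self.classes[compound_id])

    def counts(self) -> dict[str, int]:
        c = self.classes.value_counts()
        return {t.value: int(c.get(t.value, 0)) for t in ToxClass}

    def sign_vector(self, compound_ids: Sequence[str]) -> pd.Series:
        """Endpoint vector T: toxic -> +1, nontoxic -> -1, marginal or
        unlabeled -> 0 (excluded from confusion counting)."""
        mapped = {ToxClass.TOXIC.value: 1, ToxClass.NONTOXIC.value: -1}
        t = self.classes.map(mapped).reindex(pd.Index(compound_ids, dtype=str))
        return t.fillna(0).astype(np.int8)


def drop_marginal(labels: ToxicityLabels) -> ToxicityLabels:
    """Remove marginal compounds, keeping toxic and nontoxic ones intact."""
    keep = labels.classes != ToxClass.MARGINAL.value
    ld50 = None
    if labels.neg_log_ld50 is not None:
        ld50 = labels.neg_log_ld50[
            labels.neg_log_ld50.index.isin(labels.classes.index[keep])
        ]
    return ToxicityLabels(classes=labels.classes[keep], neg_log_ld50=ld50)


@dataclass
class ResponseMatrix:
    """Sparse compound × assay response matrix M with entries in {1, -1, 0}.

    Stored densely as an int8 DataFrame (rows = compounds, columns = assays);
    an absent (compound, assay) pair is identically a 0 entry.  Desk-scale
    profiling matrices (thousands × hundreds) fit comfortably.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate compound ids in matrix rows")
        if df.columns.has_duplicates:
            raise ValueError("duplicate assay ids in matrix columns")
        vals = df.to_numpy()
        if vals.size and not np.isin(vals, (-1, 0, 1)).all():
            bad = vals[~np.isin(vals, (-1, 0, 1))]
            raise ValueError(f"matrix entries must be in {{1,-1,0}}; found {bad[:5]}")
        self.data = df.astype(np.int8)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    # -- basic accessors -------------------------------------------------
    @property
    def compound_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def assay_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def entry(self, compound_id: str, assay_id: str) -> int:
        return int(self.data.at[compound_id, assay_id])

    def column(self, assay_id: str) -> pd.Series:
        """Assay vector A_i over the matrix's compounds."""
        return self.data[assay_id]

    def actives_per_assay(self) -> pd.Series:
        return (self.data == 1).sum(axis=0)

    def inactives_per_assay(self) -> pd.Series:
        return (self.data == -1).sum(axis=0)

    def restrict_assays(self, assay_ids: Sequence[str]) -> "ResponseMatrix":
        missing = [a for a in assay_ids if a not in self.data.columns]
        if missing:
            raise KeyError(f"assays not in matrix: {missing[:5]}")
        return ResponseMatrix(self.data[list(assay_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResponseMatrix):
            return NotImplemented
        return self.data.equals(other.data)


def build_matrix(
    records: Iterable[OutcomeRecord],
    compounds_of_interest: Sequence[str] | None = None,
) -> ResponseMatrix:
    """Assemble the response matrix from long-format outcome records.

    Duplicate (compound, assay) records are rolled up conservatively:
    any ACTIVE wins (1), else any INACTIVE (-1), else 0 — mirroring how
    multiple substance-level screens collapse to one compound-level call.
    When ``compounds_of_interest`` is given, rows are restricted to (and
    ordered by) that list; compounds without records become all-zero rows.
    """
    cells: dict[tuple[str, str], int] = {}
    assay_order: list[str] = []
    compound_order: list[str] = []
    seen_assays: set[str] = set()
    seen_compounds: set[str] = set()
    for rec in records:
        if rec.assay_id not in seen_assays:
            seen_assays.add(rec.assay_id)
            assay_order.append(rec.assay_id)
        if rec.compound_id not in seen_compounds:
            seen_compounds.add(rec.compound_id)
            compound_order.append(rec.compound_id)
        key = (rec.compound_id, rec.assay_id)
        new = rec.outcome.matrix_value
        old = cells.get(key, 0)
        # any-active-wins, then any-inactive
        if old == 1 or new == 1:
            cells[key] = 1
        elif old == -1 or new == -1:
            cells[key] = -1
        else:
            cells[key] = 0

    if compounds_of_interest is not None:
        rows = [str(c) for c in compounds_of_interest]
        if len(set(rows)) != len(rows):
            raise ValueError("compounds_of_interest contains duplicates")
    else:
        rows = compound_order

    df = pd.DataFrame(
        np.zeros((len(rows), len(assay_order)), dtype=np.int8),
        index=pd.Index(rows, dtype=str),
        columns=pd.Index(assay_order, dtype=str),
    )
    row_set = set(rows)
    for (cid, aid), val in cells.items():
        if cid in row_set and val != 0:
            df.at[cid, aid] = val
    return ResponseMatrix(df)


def filter_low_info_assays(
    m: ResponseMatrix, min_actives: int = 6
) -> tuple[ResponseMatrix, list[str]]:
    """Drop assays with fewer than ``min_actives`` active responses.

    HTS columns with almost no actives carry little signal for endpoint
    correlation; the default cutoff of 6 is deliberately tunable.
    Returns the filtered matrix and the list of removed assay ids.
    """
    if min_actives < 1:
        raise ValueError("min_actives must be >= 1")
    actives = m.actives_per_assay()
    keep = actives[actives >= min_actives].index.tolist()
    removed = [a for a in m.assay_ids if a not in set(keep)]
    return ResponseMatrix(m.data[keep]), removed
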