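"""Data model and I/O for interval-coded dyadic behavior.

A dyadic interaction is coded in short fixed intervals (2 s by default).
For every interval the coder registers the presence (1) or absence (0) of
each behavior category; several categories may co-occur in one interval.
The default coding scheme is the MCAM (Middle Childhood Attachment
Micro-observation system): seven main categories — positive/negative
mother behavior (M+, M-), positive/negative child behavior (C+, C-), and
three task-related categories (MAlone, CAlone, Together) — where the four
attachment categories aggregate 16 coded subcategories by logical OR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CodingScheme",
    "BehaviorSeries",
    "SubcategorySeries",
    "AttachmentScores",
    "SCORE_RANGES",
    "mcam_scheme",
    "read_scheme",
    "read_behavior_table",
    "write_behavior_table",
    "read_subcategory_table",
    "aggregate_subcategories",
    "validate_series",
    "read_attachment_scores",
    "write_attachment_scores",
]

#: Instrument ranges of the dyad-level attachment covariates:
#: trust is a 4-point Likert scale (PIML trust subscale); avoidance and
#: anxiety are 7-point Likert scales (ECR-RC subscales).
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "trust": (1.0, 4.0),
    "avoidance": (1.0, 7.0),
    "anxiety": (1.0, 7.0),
}

_MCAM_CATEGORIES = ("M+", "M-", "C+", "C-", "MAlone", "CAlone", "Together")

_MCAM_SUBCATEGORIES = {
    # positive mother behavior
    "Attention": "M+",
    "Responsivity": "M+",
    "Positive affective communication": "M+",
    "Structuring (pos./neutral)": "M+",
    "Task related structuring": "M+",
    # negative mother behavior
    "Structuring (directive/neg.)": "M-",
    "Covert hostility": "M-",
    "Overt hostility": "M-",
    "Non-contingent reaction": "M-",
    # positive child behavior
    "Engagement": "C+",
    "Positive affect": "C+",
    "Involving mother (pos./neutral)": "C+",
    # negative child behavior
    "Involving mother (neg.)": "C-",
    "Controlling/maintaining": "C-",
    "Avoidant": "C-",
    "Resistant": "C-",
}


@dataclass(frozen=True)
class CodingScheme:
    """An ordered set of behavior categories plus a subcategory mapping.

    Categories are the units of analysis; subcategories are the units of
    coding. A category with no subcategories (e.g. the task categories of
    the MCAM) is coded directly under its own name.
    """

    categories: tuple[str, ...]
    subcategory_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("category identifiers must be unique")
        if not self.categories:
            raise ValueError("scheme must define at least one category")
        for sub, cat in self.subcategory_map.items():
            if cat not in self.categories:
                raise ValueError(f"subcategory {sub!r} maps to unknown category {cat!r}")
            if sub in self.categories:
                raise ValueError(f"subcategory {sub!r} collides with a category name")

    @property
    def subcategories(self) -> tuple[str, ...]:
        return tuple(self.subcategory_map)

    def subcategories_of(self, category: str) -> tuple[str, ...]:
        """Subcategories feeding *category* (empty for directly coded ones)."""
        return tuple(s for s, c in self.subcategory_map.items() if c == category)


def mcam_scheme() -> CodingScheme:
    """The default MCAM scheme: 7 main categories, 16 subcategories."""
    return CodingScheme(categories=_MCAM_CATEGORIES, subcategory_map=dict(_MCAM_SUBCATEGORIES))


def read_scheme(source) -> CodingScheme:
    """Read a scheme from a two-column CSV ``subcategory,category``.

    Category order is the order of first appearance. A row whose
    subcategory equals its category declares a directly coded category.
    """
    df = pd.read_csv(source, dtype=str)
    _require_columns(df, ("subcategory", "category"), "scheme file")
    categories: list[str] = []
    submap: dict[str, str] = {}
    for sub, cat in zip(df["subcategory"], df["category"]):
        if cat not in categories:
            categories.append(cat)
        if sub != cat:
            if sub in submap:
                raise ValueError(f"subcategory {sub!r} listed twice")
            submap[sub] = cat
    return CodingScheme(categories=tuple(categories), subcategory_map=submap)


class _IntervalMatrix:
    """Shared structure: a binary intervals x columns matrix for one dyad."""

    def __init__(self, dyad_id: str, values: pd.DataFrame, interval_length: float = 2.0):
        self.dyad_id = str(dyad_id)
        values = pd.DataFrame(values).copy()
        values.index = pd.RangeIndex(1, len(values) + 1, name="interval")
        values.columns = [str(c) for c in values.columns]
        self.values = values
        self.interval_length = float(interval_length)

    @property
    def n_intervals(self) -> int:
        return len(self.values)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{type(self).__name__}(dyad_id={self.dyad_id!r}, "
            f"T={self.n_intervals}, columns={list(self.values.columns)})"
        )


class BehaviorSeries(_IntervalMatrix):
    """One dyad's binary presence matrix, intervals (rows) x categories.

    Rows are 1-based contiguous interval indices; ``interval_length`` (in
    seconds) is carried as metadata only and never enters any statistic.
    """

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


class SubcategorySeries(_IntervalMatrix):
    """One dyad's binary presence matrix at the subcategory level."""

    @property
    def subcategories(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass
class AttachmentScores:
    """Dyad-level self-reported attachment covariates (missing allowed)."""

    dyad_id: str
    trust: float | None = None
    avoidance: float | None = None
    anxiety: float | None = None

    def get(self, scale: str) -> float | None:
        if scale not in SCORE_RANGES:
            raise ValueError(f"unknown attachment scale {scale!r}")
        return getattr(self, scale)

    def range_violations(self) -> list[str]:
        """Scores outside their instrument range (missing is not a violation)."""
        out = []
        for scale, (lo, hi) in SCORE_RANGES.items():
            v = getattr(self, scale)
            if v is not None and not (lo <= v <= hi):
                out.append(f"{scale}={v} outside [{lo}, {hi}]")
        return out


# ---------------------------------------------------------------------------
# behavior table I/O
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, needed: Sequence[str], what: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def _check_binary(values: pd.Series, what: str) -> pd.Series:
    numeric = pd.to_numeric(values, errors="coerce")
    bad = numeric.isna() | ~numeric.isin([0, 1])
    if bad.any():
        offending = values[bad].unique()[:5].tolist()
        raise ValueError(f"non-binary value(s) in {what}: {offending}")
    return numeric.astype(np.int8)


def _check_intervals(intervals: Iterable[int], dyad: str) -> int:
    seen = sorted(set(int(i) for i in intervals))
    T = seen[-1] if seen else 0
    expected = list(range(1, T + 1))
    if seen != expected:
        missing = sorted(set(expected) - set(seen))
        raise ValueError(
            f"dyad {dyad!r}: interval sequence has gaps or does not start at 1 "
            f"(missing {missing[:5]}{'...' if len(missing) > 5 else ''})"
        )
    return T


def read_behavior_table(
    source,
    scheme: CodingScheme | None = None,
    layout: str = "long",
    interval_length: float = 2.0,
) -> list[BehaviorSeries]:
    """Read interval-coded behavior from CSV into one series per dyad.

    Long layout has columns ``dyad_id,interval,category,value``; wide layout
    has ``dyad_id,interval`` plus one column per category. Interval indices
    must form a contiguous 1..T per dyad; values must be 0/1; unknown
    category labels are rejected against *scheme* (default: MCAM).
    """
    scheme = scheme or mcam_scheme()
    df = pd.read_csv(source)
    if layout == "long":
        _require_columns(df, ("dyad_id", "interval", "category", "value"), "long behavior table")
        unknown = sorted(set(df["category"].astype(str)) - set(scheme.categories))
        if unknown:
            raise ValueError(f"unknown category label(s): {unknown}")
        dup = df.duplicated(subset=["dyad_id", "interval", "category"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                f"duplicate row for (dyad_id={row['dyad_id']!r}, "
                f"interval={row['interval']}, category={row['category']!r})"
            )
        df = df.assign(value=_check_binary(df["value"], "behavior table"))
        out = []
        for dyad in df["dyad_id"].astype(str).unique():
            sub = df[df["dyad_id"].astype(str) == dyad]
            T = _check_intervals(sub["interval"], dyad)
            mat = sub.pivot(index="interval", columns="category", values="value")
            mat = mat.reindex(index=range(1, T + 1), columns=list(scheme.categories))
            mat = mat.fillna(0).astype(np.int8)
            out.append(BehaviorSeries(dyad, mat, interval_length))
        return out
    if layout == "wide":
        _require_columns(df, ("dyad_id", "interval"), "wide behavior table")
        value_cols = [c for c in df.columns if c not in ("dyad_id", "interval")]
        unknown = sorted(set(value_cols) - set(scheme.categories))
        if unknown:
            raise ValueError(f"unknown category column(s): {unknown}")
        if df.duplicated(subset=["dyad_id", "interval"]).any():
            raise ValueError("duplicate (dyad_id, interval) row in wide table")
        for c in value_cols:
            df[c] = _check_binary(df[c], f"column {c!r}")
        out = []
        for dyad in df["dyad_id"].astype(str).unique():
            sub = df[df["dyad_id"].astype(str) == dyad].set_index("interval")
            T = _check_intervals(sub.index, dyad)
            mat = sub[value_cols].reindex(range(1, T + 1))
            mat = mat.reindex(columns=list(scheme.categories)).fillna(0).astype(np.int8)
            out.append(BehaviorSeries(dyad, mat, interval_length))
        return out
    raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


def write_behavior_table(series: Sequence[BehaviorSeries], target, layout: str = "long") -> None:
    """Write series to CSV in the long or wide layout (round-trip safe)."""
    if layout == "long":
        frames = []
        for s in series:
            stacked = s.values.stack()
            frame = stacked.rename("value").reset_index()
            frame.columns = ["interval", "category", "value"]
            frame.insert(0, "dyad_id", s.dyad_id)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(target, index=False)
    elif layout == "wide":
        frames = []
        for s in series:
            frame = s.values.reset_index()
            frame.insert(0, "dyad_id", s.dyad_id)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(target, index=False)
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


def read_subcategory_table(source, scheme: CodingScheme | None = None,
                           interval_length: float = 2.0) -> list[SubcategorySeries]:
    """Read a long CSV ``dyad_id,interval,subcategory,value`` of subcategory codes."""
    scheme = scheme or mcam_scheme()
    df = pd.read_csv(source)
    _require_columns(df, ("dyad_id", "interval", "subcategory", "value"), "subcategory table")
    known = set(scheme.subcategory_map) | set(scheme.categories)
    unknown = sorted(set(df["subcategory"].astype(str)) - known)
    if unknown:
        raise ValueError(f"unknown subcategory label(s): {unknown}")
    if df.duplicated(subset=["dyad_id", "interval", "subcategory"]).any():
        raise ValueError("duplicate (dyad_id, interval, subcategory) row")
    df = df.assign(value=_check_binary(df["value"], "subcategory table"))
    out = []
    for dyad in df["dyad_id"].astype(str).unique():
        sub = df[df["dyad_id"].astype(str) == dyad]
        T = _check_intervals(sub["interval"], dyad)
        mat = sub.pivot(index="interval", columns="subcategory", values="value")
        mat = mat.reindex(index=range(1, T + 1)).fillna(0).astype(np.int8)
        out.append(SubcategorySeries(dyad, mat, interval_length))
    return out


# ---------------------------------------------------------------------------
# aggregation and validation
# ---------------------------------------------------------------------------

def aggregate_subcategories(sub: SubcategorySeries, scheme: CodingScheme | None = None) -> BehaviorSeries:
    """Collapse subcategory codes to main categories by logical OR.

    A main category is present in an interval iff at least one of its
    subcategories is present. A column named exactly like a category is
    treated as that category coded directly (the MCAM task categories).
    """
    scheme = scheme or mcam_scheme()
    for col in sub.values.columns:
        if col not in scheme.subcategory_map and col not in scheme.categories:
            raise ValueError(f"unmapped subcategory {col!r}")
    data = {}
    for cat in scheme.categories:
        sources = [c for c in sub.values.columns
                   if c == cat or scheme.subcategory_map.get(c) == cat]
        if sources:
            data[cat] = (sub.values[sources].to_numpy().max(axis=1)).astype(np.int8)
        else:
            data[cat] = np.zeros(sub.n_intervals, dtype=np.int8)
    mat = pd.DataFrame(data, index=sub.values.index, columns=list(scheme.categories))
    return BehaviorSeries(sub.dyad_id, mat, sub.interval_length)


def validate_series(series: BehaviorSeries) -> list[str]:
    """Report invariant violations; an empty list means the series is valid."""
    report: list[str] = []
    if series.values.shape[1] == 0:
        report.append(f"dyad {series.dyad_id!r}: empty category set")
    if series.n_intervals < 2:
        report.append(f"dyad {series.dyad_id!r}: too short for sequencing (T={series.n_intervals} < 2)")
    arr = series.values.to_numpy()
    if arr.size and not np.isin(arr, (0, 1)).all():
        bad = np.unique(arr[~np.isin(arr, (0, 1))])[:5]
        report.append(f"dyad {series.dyad_id!r}: non-binary cell value(s) {bad.tolist()}")
    return report


# ---------------------------------------------------------------------------
# attachment scores I/O
# ---------------------------------------------------------------------------

def read_attachment_scores(source) -> list[AttachmentScores]:
    """Read ``dyad_id,trust,avoidance,anxiety`` CSV; empty cells are missing.

    Out-of-range values are retained but flagged with a warning so the
    caller can decide (see :func:`dyadseq.inference.flag_outliers` for
    the sample-level screening step).
    """
    df = pd.read_csv(source)
    _require_columns(df, ("dyad_id", "trust", "avoidance", "anxiety"), "attachment scores table")
    if df["dyad_id"].duplicated().any():
        dup = df.loc[df["dyad_id"].duplicated(), "dyad_id"].iloc[0]
        raise ValueError(f"duplicate dyad_id {dup!r} in scores table")
    records = []
    for _, row in df.iterrows():
        rec = AttachmentScores(
            dyad_id=str(row["dyad_id"]),
            **{
                scale: (None if pd.isna(row[scale]) else float(row[scale]))
                for scale in SCORE_RANGES
            },
        )
        for violation in rec.range_violations():
            warnings.warn(f"dyad {rec.dyad_id!r}: {violation}", UserWarning, stacklevel=2)
        records.append(rec)
    return records


def write_attachment_scores(scores: Sequence[AttachmentScores], target) -> None:
    pd.DataFrame(
        [
            {"dyad_id": s.dyad_id, "trust": s.trust, "avoidance": s.avoidance, "anxiety": s.anxiety}
            for s in scores
        ]
    ).to_csv(target, index=False)
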