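"""Per-dyad relative frequencies and chance-corrected lag-1 sequencing.

The sequencing likelihood of an ordered pair of behaviors (first, second)
is a normalized Jaccard index over the T-1 lag-1 interval pairs (t, t+1):

    Jac_Obs  = n11 / (n11 + n10 + n01)
    Jac_Exp  = p1 * p2 / (1 - (1 - p1) * (1 - p2))
    Jac_Norm = (Jac_Obs - Jac_Exp) / (1 - Jac_Exp)

where n11 counts pairs with the first behavior at t and the second at t+1,
n10 pairs with only the first at t, n01 pairs with only the second at t+1,
and p1, p2 are the relative frequencies of the two behaviors. Jac_Norm = 0
means the sequence occurs exactly as often as expected by chance given the
behaviors' base rates; Jac_Norm = 1 means the two behaviors always follow
each other; negative values mean the sequence is avoided.

By default p1 is computed over intervals 1..T-1 and p2 over 2..T (the
lag-aligned windows), so observed and expected counts range over the same
set of interval pairs; pass ``p_window="full"`` for full-series
frequencies as a sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .behavior import BehaviorSeries

__all__ = [
    "LagContingency",
    "SequenceStat",
    "DyadProfile",
    "relative_frequency",
    "lag_contingency",
    "jaccard_observed",
    "jaccard_expected",
    "jaccard_normalized",
    "dyad_profile",
    "profiles_to_frame",
    "write_profiles",
]

PWindow = Literal["lagged", "full"]


@dataclass(frozen=True)
class LagContingency:
    """2x2 counts for an ordered behavior pair over the T-1 lag-1 pairs."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def pairs(self) -> int:
        """Total number of lag-1 interval pairs, i.e. T - 1."""
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class SequenceStat:
    """Sequencing statistics for one ordered pair; None encodes undefined."""

    first: str
    second: str
    p1: float
    p2: float
    jac_obs: float | None
    jac_exp: float | None
    jac_norm: float | None
    contingency: LagContingency

    @property
    def occurs(self) -> bool:
        """Whether the sequence is observed at least once (n11 > 0)."""
        return self.contingency.n11 > 0


@dataclass(frozen=True)
class DyadProfile:
    """All relative frequencies and all ordered-pair stats for one dyad."""

    dyad_id: str
    frequencies: dict[str, float]
    sequences: dict[tuple[str, str], SequenceStat]

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.frequencies)


def _column(series: BehaviorSeries, category: str) -> np.ndarray:
    if category not in series.values.columns:
        raise ValueError(f"unknown category {category!r} for dyad {series.dyad_id!r}")
    return series.values[category].to_numpy()


def relative_frequency(series: BehaviorSeries, category: str) -> float:
    """Proportion of intervals in which *category* is present (over all T)."""
    return float(_column(series, category).mean())


def lag_contingency(series: BehaviorSeries, first: str, second: str) -> LagContingency:
    """Count the lag-1 contingencies of *first* at t vs *second* at t+1.

    The pair may be an auto-loop (first == second), which measures
    behavioral persistence across consecutive intervals.
    """
    if series.n_intervals < 2:
        raise ValueError(f"dyad {series.dyad_id!r}: need T >= 2 for lag-1 sequencing")
    a = _column(series, first)[:-1].astype(bool)
    b = _column(series, second)[1:].astype(bool)
    return LagContingency(
        n11=int(np.sum(a & b)),
        n10=int(np.sum(a & ~b)),
        n01=int(np.sum(~a & b)),
        n00=int(np.sum(~a & ~b)),
    )


def jaccard_observed(c: LagContingency) -> float | None:
    """Observed Jaccard index n11/(n11+n10+n01); None when 0/0."""
    denom = c.n11 + c.n10 + c.n01
    if denom == 0:
        return None
    return c.n11 / denom


def jaccard_expected(p1: float, p2: float) -> float | None:
    """Chance-level Jaccard index for independent behaviors with rates p1, p2.

    Returns None (undefined) when both rates are zero.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError(f"rates must be in [0, 1], got p1={p1}, p2={p2}")
    if p1 == 0.0 and p2 == 0.0:
        return None
    return (p1 * p2) / (1.0 - (1.0 - p1) * (1.0 - p2))


def jaccard_normalized(
    series: BehaviorSeries, first: str, second: str, p_window: PWindow = "lagged"
) -> SequenceStat:
    """Chance-corrected sequencing likelihood for the ordered pair.

    Jac_Norm is undefined (None) whenever either behavior never occurs in
    its window (the chance correction is then meaningless), or when
    Jac_Exp = 1 (both behaviors always present; zero denominator).
    """
    cont = lag_contingency(series, first, second)
    if p_window == "lagged":
        p1 = float(_column(series, first)[:-1].mean())
        p2 = float(_column(series, second)[1:].mean())
    elif p_window == "full":
        p1 = relative_frequency(series, first)
        p2 = relative_frequency(series, second)
    else:
        raise ValueError(f"p_window must be 'lagged' or 'full', got {p_window!r}")
    obs = jaccard_observed(cont)
    exp = jaccard_expected(p1, p2)
    norm: float | None = None
    if obs is not None and exp is not None and p1 > 0.0 and p2 > 0.0 and exp < 1.0:
        norm = (obs - exp) / (1.0 - exp)
    return SequenceStat(first, second, p1, p2, obs, exp, norm, cont)


def dyad_profile(series: BehaviorSeries, p_window: PWindow = "lagged") -> DyadProfile:
    """All K relative frequencies and all K x K ordered-pair stats of a dyad.

    Frequencies are taken over the full T intervals; sequencing stats
    include auto-loops, so a 7-category scheme yields 49 entries.
    """
    if series.n_intervals < 2:
        raise ValueError(f"dyad {series.dyad_id!r}: need T >= 2 for a profile")
    cats = list(series.values.columns)
    freqs = {c: relative_frequency(series, c) for c in cats}
    seqs = {
        (f, s): jaccard_normalized(series, f, s, p_window=p_window)
        for f in cats
        for s in cats
    }
    return DyadProfile(series.dyad_id, freqs, seqs)


def profiles_to_frame(profiles: Sequence[DyadProfile]) -> pd.DataFrame:
    """Long-format export: dyad_id, measure_type, first, second, value.

    Frequency rows carry the category in ``first`` and an empty ``second``;
    undefined sequencing stats have an empty value.
    """
    rows = []
    for p in profiles:
        for cat, freq in p.frequencies.items():
            rows.append(
                {"dyad_id": p.dyad_id, "measure_type": "frequency",
                 "first": cat, "second": "", "value": freq}
            )
        for (f, s), stat in p.sequences.items():
            rows.append(
                {"dyad_id": p.dyad_id, "measure_type": "sequence",
                 "first": f, "second": s,
                 "value": np.nan if stat.jac_norm is None else stat.jac_norm}
            )
    return pd.DataFrame(rows, columns=["dyad_id", "measure_type", "first", "second", "value"])


def write_profiles(profiles: Sequence[DyadProfile], target) -> None:
    profiles_to_frame(profiles).to_csv(target, index=False)
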