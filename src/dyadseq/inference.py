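"""Across-dyad aggregation and inference.

Sequencing likelihoods are aggregated across dyads with three conventions:
(i) undefined per-dyad statistics are excluded, and the count of dyads for
which a statistic is defined is reported alongside; (ii) "dyads showing the
sequence" counts dyads where the ordered pair actually occurs at least once
(n11 > 0); (iii) the mean sequencing likelihood is tested against 0 with an
upper-tailed one-sample t-test. Covariate analyses use Spearman rank
correlations, with first-order partial Spearman correlations (Pearson's
partial-correlation formula applied to average ranks) to disentangle
overlapping covariates. Inter-rater reliability is a Cohen's kappa pooled
over all interval x category binary coding decisions, plus a correlation
of the per-dyad derived measures between coders.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import AttachmentScores, BehaviorSeries, SCORE_RANGES
from .metrics import DyadProfile

__all__ = [
    "SampleSummary",
    "CorrelationResult",
    "KappaResult",
    "upper_tailed_t",
    "prop_positive",
    "spearman",
    "partial_spearman",
    "zscore_vs_sample",
    "flag_outliers",
    "pooled_kappa",
    "coder_measure_agreement",
    "summarize_frequencies",
    "summarize_sequences",
    "summaries_to_frame",
    "correlate_with_scores",
    "correlations_to_frame",
    "compare_dyad_profile",
    "sequence_label",
]

COVARIATES = tuple(SCORE_RANGES)  # ("trust", "avoidance", "anxiety")

#: Which covariate each covariate is partialled against (the two overlapping
#: insecurity dimensions control for each other; trust is reported raw).
PARTIAL_CONTROLS = {"avoidance": "anxiety", "anxiety": "avoidance"}


def sequence_label(first: str, second: str) -> str:
    return f"{first} => {second}"


@dataclass(frozen=True)
class SampleSummary:
    """Across-dyad summary of one measure (a frequency or an ordered pair)."""

    measure: str
    kind: Literal["frequency", "sequence"]
    n_dyads_showing: int
    n_defined: int
    mean: float | None
    sd: float | None
    min: float | None
    max: float | None
    prop_positive: float | None
    t_stat: float | None
    p_value: float | None


@dataclass(frozen=True)
class CorrelationResult:
    measure: str
    covariate: str
    rho: float
    p_value: float
    n: int
    controlled_for: str | None = None

    def __post_init__(self) -> None:
        if self.controlled_for == self.covariate:
            raise ValueError("cannot control a covariate for itself")


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    p_observed: float
    p_expected: float
    n_decisions: int


# ---------------------------------------------------------------------------
# elementary inference operations
# ---------------------------------------------------------------------------

def _defined(values: Iterable[float | None]) -> np.ndarray:
    return np.array([v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))],
                    dtype=float)


def upper_tailed_t(values: Sequence[float]) -> tuple[float, float]:
    """One-sample t-test of the mean against 0, upper tail (H1: mean > 0)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values, got {arr.size}")
    if np.ptp(arr) == 0.0:
        raise ValueError("zero variance: t-statistic undefined")
    res = stats.ttest_1samp(arr, popmean=0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def prop_positive(values: Iterable[float | None]) -> float | None:
    """Share of strictly positive values among the defined ones."""
    arr = _defined(values)
    if arr.size == 0:
        return None
    return float(np.mean(arr > 0.0))


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    y = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired inputs must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman(x: Sequence[float], y: Sequence[float],
             measure: str = "x", covariate: str = "y") -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    xs, ys = _complete_pairs(x, y)
    if xs.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {xs.size}")
    if np.std(stats.rankdata(xs)) == 0.0 or np.std(stats.rankdata(ys)) == 0.0:
        raise ValueError("zero rank variance: correlation undefined")
    res = stats.spearmanr(xs, ys)
    return CorrelationResult(measure, covariate, float(res.statistic), float(res.pvalue), int(xs.size))


def _partial_from_pairwise(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation from the three pairwise coefficients."""
    # |r| within float error of 1 is degenerate just like exact 1
    if min(1.0 - r_xz**2, 1.0 - r_yz**2) <= 1e-12:
        raise ValueError("degenerate partial correlation: |r_xz| = 1 or |r_yz| = 1")
    return (r_xy - r_xz * r_yz) / math.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))


def partial_spearman(x: Sequence[float], y: Sequence[float], control: Sequence[float],
                     measure: str = "x", covariate: str = "y",
                     controlled_for: str = "z") -> CorrelationResult:
    """Partial Spearman: rank-transform all three, then first-order partial.

    p-value from the t approximation with n - 3 degrees of freedom.
    """
    x = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    y = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    z = np.asarray([np.nan if v is None else v for v in control], dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y and control must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[keep], y[keep], z[keep]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete triples, got {n}")
    rx, ry, rz = stats.rankdata(x), stats.rankdata(y), stats.rankdata(z)
    if min(np.std(rx), np.std(ry), np.std(rz)) == 0.0:
        raise ValueError("zero rank variance: partial correlation undefined")
    r_xy = float(np.corrcoef(rx, ry)[0, 1])
    r_xz = float(np.corrcoef(rx, rz)[0, 1])
    r_yz = float(np.corrcoef(ry, rz)[0, 1])
    r = _partial_from_pairwise(r_xy, r_xz, r_yz)
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationResult(measure, covariate, float(r), p, n, controlled_for)


def zscore_vs_sample(value: float, reference: Sequence[float]) -> float:
    """Standard score of *value* against a reference sample (sd with n-1)."""
    ref = np.asarray(reference, dtype=float)
    if ref.size < 2:
        raise ValueError(f"reference needs at least 2 values, got {ref.size}")
    sd = float(np.std(ref, ddof=1))
    if sd == 0.0:
        raise ValueError("zero reference standard deviation")
    return (float(value) - float(np.mean(ref))) / sd


def flag_outliers(
    scores: Sequence[AttachmentScores], scale: str = "trust", threshold: float = 3.0
) -> tuple[list[AttachmentScores], list[AttachmentScores]]:
    """Partition dyads into (retained, excluded) by leave-one-out |z| on *scale*.

    Each dyad's score is standardized against the remaining dyads; |z| >=
    threshold excludes it. A dyad with a missing score is retained (it cannot
    be screened). If the remaining dyads are constant, a differing held-out
    score counts as infinitely extreme and an equal one as z = 0, so a single
    gross outlier in an otherwise homogeneous sample is still caught.
    """
    if len(scores) < 3:
        raise ValueError(f"need at least 3 dyads, got {len(scores)}")
    values = [s.get(scale) for s in scores]
    retained, excluded = [], []
    for i, rec in enumerate(scores):
        v = values[i]
        if v is None:
            retained.append(rec)
            continue
        rest = [u for j, u in enumerate(values) if j != i and u is not None]
        if len(rest) < 2:
            raise ValueError("not enough defined reference scores for leave-one-out z")
        try:
            z = zscore_vs_sample(v, rest)
        except ValueError:  # constant reference
            z = 0.0 if v == rest[0] else math.inf
        (excluded if abs(z) >= threshold else retained).append(rec)
    return retained, excluded


# ---------------------------------------------------------------------------
# inter-rater reliability
# ---------------------------------------------------------------------------

def _paired_decisions(coder_a: Sequence[BehaviorSeries],
                      coder_b: Sequence[BehaviorSeries]) -> tuple[np.ndarray, np.ndarray]:
    by_id = {s.dyad_id: s for s in coder_b}
    if sorted(by_id) != sorted(s.dyad_id for s in coder_a):
        raise ValueError("coders must cover the same dyads")
    a_parts, b_parts = [], []
    for sa in coder_a:
        sb = by_id[sa.dyad_id]
        if sa.values.shape != sb.values.shape or list(sa.values.columns) != list(sb.values.columns):
            raise ValueError(f"dyad {sa.dyad_id!r}: shape or category mismatch between coders")
        a_parts.append(sa.values.to_numpy().ravel())
        b_parts.append(sb.values.to_numpy().ravel())
    return np.concatenate(a_parts), np.concatenate(b_parts)


def pooled_kappa(
    coder_a: Sequence[BehaviorSeries],
    coder_b: Sequence[BehaviorSeries],
    ci_method: Literal["asymptotic", "bootstrap"] = "asymptotic",
    n_boot: int = 2000,
    seed: int | None = None,
) -> KappaResult:
    """Cohen's kappa pooled over all interval x category binary decisions.

    All cells of both coders' matrices are flattened into one binary
    agreement table; kappa = (p_o - p_e) / (1 - p_e) with chance agreement
    p_e from the two coders' marginal presence rates. The 95% CI uses the
    large-sample standard error sqrt(p_o(1-p_o)/(n(1-p_e)^2)) by default,
    or a nonparametric bootstrap over decisions.
    """
    a, b = _paired_decisions(coder_a, coder_b)
    n = a.size
    if n == 0:
        raise ValueError("no coding decisions to compare")

    def _kappa(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
        p_o = float(np.mean(a == b))
        pa, pb = float(np.mean(a)), float(np.mean(b))
        p_e = pa * pb + (1.0 - pa) * (1.0 - pb)
        if p_e == 1.0:
            raise ValueError("degenerate marginals: chance agreement is 1")
        return (p_o - p_e) / (1.0 - p_e), p_o, p_e

    kappa, p_o, p_e = _kappa(a, b)
    if ci_method == "asymptotic":
        se = math.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
        lo, hi = kappa - 1.959963984540054 * se, kappa + 1.959963984540054 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                reps.append(_kappa(a[idx], b[idx])[0])
            except ValueError:
                continue
        lo, hi = (float(q) for q in np.percentile(reps, [2.5, 97.5]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return KappaResult(float(kappa), float(lo), float(hi), p_o, p_e, int(n))


def _profile_values(profiles: Sequence[DyadProfile], measure_class: str) -> dict:
    out = {}
    for p in profiles:
        if measure_class == "frequency":
            for cat, v in p.frequencies.items():
                out[(p.dyad_id, cat)] = v
        elif measure_class == "sequence":
            for pair, stat in p.sequences.items():
                out[(p.dyad_id, pair)] = stat.jac_norm
        else:
            raise ValueError(f"measure_class must be 'frequency' or 'sequence', got {measure_class!r}")
    return out


def coder_measure_agreement(
    profiles_a: Sequence[DyadProfile],
    profiles_b: Sequence[DyadProfile],
    measure_class: Literal["frequency", "sequence"] = "frequency",
    method: Literal["pearson", "spearman"] = "pearson",
) -> CorrelationResult:
    """Correlate the per-dyad derived measures of two coders.

    Pools every (dyad, measure) value of the chosen class that is defined
    for both coders into one paired vector and correlates it.
    """
    va = _profile_values(profiles_a, measure_class)
    vb = _profile_values(profiles_b, measure_class)
    keys = [k for k in va if k in vb and va[k] is not None and vb[k] is not None]
    if len(keys) < 3:
        raise ValueError(f"need at least 3 paired defined values, got {len(keys)}")
    x = np.array([va[k] for k in keys], dtype=float)
    y = np.array([vb[k] for k in keys], dtype=float)
    if method == "pearson":
        res = stats.pearsonr(x, y)
        return CorrelationResult(f"coder_agreement_{measure_class}", "coder_b",
                                 float(res.statistic), float(res.pvalue), len(keys))
    if method == "spearman":
        return spearman(x, y, measure=f"coder_agreement_{measure_class}", covariate="coder_b")
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# sample summaries (Table-3/4-style)
# ---------------------------------------------------------------------------

def _moments(arr: np.ndarray) -> tuple[float | None, float | None, float | None, float | None]:
    if arr.size == 0:
        return None, None, None, None
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return mean, sd, float(np.min(arr)), float(np.max(arr))


def summarize_frequencies(profiles: Sequence[DyadProfile]) -> list[SampleSummary]:
    """Across-dyad summary of each category's relative frequency.

    Frequencies are defined for every dyad; "showing" counts dyads with a
    nonzero frequency. No mean test is attached (frequencies are bounded
    positive, unlike the chance-centered sequencing stats).
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    out = []
    for cat in profiles[0].categories:
        vals = np.array([p.frequencies[cat] for p in profiles], dtype=float)
        mean, sd, vmin, vmax = _moments(vals)
        out.append(SampleSummary(
            measure=cat, kind="frequency",
            n_dyads_showing=int(np.sum(vals > 0)), n_defined=int(vals.size),
            mean=mean, sd=sd, min=vmin, max=vmax,
            prop_positive=prop_positive(vals), t_stat=None, p_value=None,
        ))
    return out


def summarize_sequences(profiles: Sequence[DyadProfile]) -> list[SampleSummary]:
    """Across-dyad summary of each ordered pair's sequencing likelihood.

    Undefined per-dyad stats are excluded from the mean, SD, range,
    proportion-positive and the upper-tailed t-test; ``n_dyads_showing``
    counts dyads in which the sequence actually occurs (n11 > 0).
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    out = []
    for pair in profiles[0].sequences:
        stats_ = [p.sequences[pair] for p in profiles]
        defined = _defined([s.jac_norm for s in stats_])
        mean, sd, vmin, vmax = _moments(defined)
        t_stat = p_value = None
        if defined.size >= 2 and np.std(defined, ddof=1) > 0.0:
            t_stat, p_value = upper_tailed_t(defined)
        out.append(SampleSummary(
            measure=sequence_label(*pair), kind="sequence",
            n_dyads_showing=sum(s.occurs for s in stats_), n_defined=int(defined.size),
            mean=mean, sd=sd, min=vmin, max=vmax,
            prop_positive=prop_positive([s.jac_norm for s in stats_]),
            t_stat=t_stat, p_value=p_value,
        ))
    return out


def summaries_to_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    """Tabular export mirroring the Dyads/PropDy>0/Mean/sig/SD/Min/Max layout."""
    return pd.DataFrame(
        [
            {
                "measure": s.measure, "kind": s.kind,
                "dyads": s.n_dyads_showing, "n_defined": s.n_defined,
                "prop_positive": s.prop_positive, "mean": s.mean,
                "t_stat": s.t_stat, "p_value": s.p_value,
                "sd": s.sd, "min": s.min, "max": s.max,
            }
            for s in summaries
        ]
    )


# ---------------------------------------------------------------------------
# covariate correlations (Table-5/6-style)
# ---------------------------------------------------------------------------

def correlate_with_scores(
    profiles: Sequence[DyadProfile],
    scores: Sequence[AttachmentScores],
    covariates: Sequence[str] = COVARIATES,
    partial_controls: dict[str, str] | None = None,
    min_pairs: int = 3,
) -> list[CorrelationResult]:
    """Spearman (and partial Spearman) correlations of every measure with
    every covariate.

    Measures with fewer than *min_pairs* complete pairs, or with no rank
    variance, are skipped with a warning. By default avoidance and anxiety
    are additionally partialled for each other; trust is reported raw.
    """
    if partial_controls is None:
        partial_controls = dict(PARTIAL_CONTROLS)
    by_id = {s.dyad_id: s for s in scores}
    matched = [p for p in profiles if p.dyad_id in by_id]
    if len(matched) < min_pairs:
        raise ValueError(f"need at least {min_pairs} dyads with scores, got {len(matched)}")

    measures: list[tuple[str, list[float | None]]] = []
    for cat in matched[0].categories:
        measures.append((cat, [p.frequencies[cat] for p in matched]))
    for pair in matched[0].sequences:
        measures.append((sequence_label(*pair), [p.sequences[pair].jac_norm for p in matched]))

    cov_values = {
        c: [by_id[p.dyad_id].get(c) for p in matched] for c in covariates
    }

    results: list[CorrelationResult] = []
    for label, values in measures:
        for cov in covariates:
            try:
                results.append(spearman(values, cov_values[cov], measure=label, covariate=cov))
            except ValueError as err:
                warnings.warn(f"skipping {label} ~ {cov}: {err}", UserWarning, stacklevel=2)
                continue
            control = partial_controls.get(cov)
            if control is not None:
                try:
                    results.append(
                        partial_spearman(values, cov_values[cov], cov_values[control],
                                         measure=label, covariate=cov, controlled_for=control)
                    )
                except ValueError as err:
                    warnings.warn(f"skipping partial {label} ~ {cov} | {control}: {err}",
                                  UserWarning, stacklevel=2)
    return results


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "measure": r.measure, "covariate": r.covariate,
                "controlled_for": r.controlled_for or "", "rho": r.rho,
                "p_value": r.p_value, "n": r.n,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# single-dyad comparison (low-trust-dyad-style z-score table)
# ---------------------------------------------------------------------------

def compare_dyad_profile(target: DyadProfile, reference: Sequence[DyadProfile]) -> pd.DataFrame:
    """z-scores of one dyad's measures against a reference sample.

    Measures that are undefined for the target dyad, or whose reference
    has fewer than 2 defined values or zero spread, get a NaN z (logged
    column ``note`` says why).
    """
    if len(reference) < 2:
        raise ValueError(f"reference sample needs at least 2 dyads, got {len(reference)}")
    rows = []

    def _row(measure: str, kind: str, value: float | None, ref_vals: list[float | None]) -> dict:
        ref = _defined(ref_vals)
        note, z = "", np.nan
        if value is None:
            note = "undefined for target dyad"
        elif ref.size < 2:
            note = "reference too small"
        elif np.std(ref, ddof=1) == 0.0:
            note = "zero reference sd"
        else:
            z = zscore_vs_sample(value, ref)
        return {
            "measure": measure, "kind": kind,
            "target_value": np.nan if value is None else value,
            "ref_mean": np.nan if ref.size == 0 else float(np.mean(ref)),
            "ref_sd": np.nan if ref.size < 2 else float(np.std(ref, ddof=1)),
            "n_ref": int(ref.size), "z": z, "note": note,
        }

    for cat in target.categories:
        rows.append(_row(cat, "frequency", target.frequencies[cat],
                         [p.frequencies.get(cat) for p in reference]))
    for pair, stat in target.sequences.items():
        rows.append(_row(sequence_label(*pair), "sequence", stat.jac_norm,
                         [p.sequences[pair].jac_norm if pair in p.sequences else None
                          for p in reference]))
    return pd.DataFrame(rows)
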