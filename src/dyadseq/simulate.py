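"""Synthetic dyads: coupled binary behavior streams with linked covariates.

Each dyad is a set of binary behavior streams over T intervals. Uncoupled
categories are independent Bernoulli draws at their base rate; a coupled
pair (first, second, q1, q0) makes the second category at interval t+1
Bernoulli(q1) when the first was present at t and Bernoulli(q0) otherwise —
a first-order Markov mechanism in the pair, the minimal structure that
produces nonzero chance-corrected sequencing. When several couplings target
the same category, the conditional success probabilities combine by
noisy-OR. Dyads are heterogeneous: each dyad's (q1, q0) are drawn around
the configured values, and dyad-level covariate scores are a linear
function of the dyad's realized coupling deviations plus truncated
Gaussian noise, so covariates genuinely correlate with sequencing strength.

Defaults emulate the published mother-child sample: 54 dyads, 90
two-second intervals, the seven MCAM categories at their observed mean
rates, persistent/cross-lagged couplings on the pairs reported as
significant, and covariate moments matching the questionnaire sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import AttachmentScores, BehaviorSeries, SCORE_RANGES

__all__ = [
    "Coupling",
    "CovariateLink",
    "GeneratorConfig",
    "SyntheticSample",
    "marginal_preserving_coupling",
    "default_config",
    "load_generator_config",
    "generate_dyad",
    "generate_sample",
]

#: Mean relative frequencies of the seven MCAM categories in the published
#: sample; used as default base rates.
MCAM_BASE_RATES: dict[str, float] = {
    "M+": 0.45, "M-": 0.02, "C+": 0.39, "C-": 0.05,
    "MAlone": 0.13, "CAlone": 0.47, "Together": 0.04,
}

#: Covariate moments of the questionnaire sample (mean, sd), used as
#: emulation targets for the synthetic scores.
COVARIATE_MOMENTS: dict[str, tuple[float, float]] = {
    "trust": (3.51, 0.32),
    "avoidance": (2.44, 0.84),
    "anxiety": (2.11, 0.79),
}


@dataclass(frozen=True)
class Coupling:
    """Lag-1 conditional for a stream pair: P(second at t+1 | first at t)."""

    first: str
    second: str
    q1: float  # conditional when first present at t
    q0: float  # conditional when first absent at t

    def __post_init__(self) -> None:
        for name in ("q1", "q0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def gap(self) -> float:
        return self.q1 - self.q0


@dataclass(frozen=True)
class CovariateLink:
    """Links a covariate to the realized coupling strength of one pair."""

    covariate: str
    pair: tuple[str, str]
    weight: float

    def __post_init__(self) -> None:
        if self.covariate not in SCORE_RANGES:
            raise ValueError(f"unknown covariate {self.covariate!r}")


def marginal_preserving_coupling(first: str, second: str,
                                 p_first: float, p_second: float, gap: float) -> Coupling:
    """A coupling with q1 - q0 = gap that keeps the second stream's marginal.

    Solves p_second = p_first*q1 + (1-p_first)*q0 with q1 = q0 + gap,
    clipping into [0, 1] when the exact solution leaves the unit interval.
    """
    q0 = float(np.clip(p_second - p_first * gap, 0.0, 1.0))
    q1 = float(np.clip(q0 + gap, 0.0, 1.0))
    return Coupling(first, second, q1, q0)


def _default_couplings() -> tuple[Coupling, ...]:
    r = MCAM_BASE_RATES
    spec = [  # (first, second, coupling gap)
        ("M+", "M+", 0.30), ("C+", "C+", 0.30),
        ("M+", "C+", 0.12), ("C+", "M+", 0.12),
        ("CAlone", "CAlone", 0.50), ("MAlone", "MAlone", 0.35),
        ("Together", "Together", 0.25),
        ("M-", "M-", 0.25), ("C-", "C-", 0.20), ("M-", "C-", 0.15),
    ]
    raw = [marginal_preserving_coupling(f, s, r[f], r[s], g) for f, s, g in spec]
    # targets with several incoming couplings combine by noisy-OR at
    # generation time; temper each conditional with a 1/m exponent so the
    # combined marginal stays near the configured base rate
    n_sources = {}
    for c in raw:
        n_sources[c.second] = n_sources.get(c.second, 0) + 1
    out = []
    for c in raw:
        m = n_sources[c.second]
        if m > 1:
            c = Coupling(c.first, c.second,
                         1.0 - (1.0 - c.q1) ** (1.0 / m),
                         1.0 - (1.0 - c.q0) ** (1.0 / m))
        out.append(c)
    return tuple(out)


def _default_links() -> tuple[CovariateLink, ...]:
    return (
        CovariateLink("trust", ("M-", "C-"), -1.0),
        CovariateLink("trust", ("C-", "C-"), -1.0),
        CovariateLink("avoidance", ("M+", "M+"), 1.0),
        CovariateLink("avoidance", ("M-", "C-"), 1.0),
        CovariateLink("anxiety", ("M-", "C-"), 1.0),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic dyad sample.

    ``coupling_sd`` is the between-dyad standard deviation of each
    conditional (q1, q0); ``link_strength`` is the population correlation
    between a covariate's signal (the weighted realized coupling
    deviations) and the covariate score before range truncation.
    """

    n_dyads: int = 54
    T: int = 90
    base_rates: Mapping[str, float] = field(default_factory=lambda: dict(MCAM_BASE_RATES))
    couplings: tuple[Coupling, ...] = field(default_factory=_default_couplings)
    covariate_links: tuple[CovariateLink, ...] = field(default_factory=_default_links)
    covariate_moments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(COVARIATE_MOMENTS))
    coupling_sd: float = 0.05
    link_strength: float = 0.6
    interval_length: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError(f"T must be >= 2, got {self.T}")
        if self.n_dyads < 1:
            raise ValueError(f"n_dyads must be >= 1, got {self.n_dyads}")
        for cat, p in self.base_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"base rate of {cat!r} must be in [0, 1], got {p}")
        seen = set()
        for c in self.couplings:
            if c.first not in self.base_rates or c.second not in self.base_rates:
                raise ValueError(f"coupling {c.first}->{c.second} names unknown categories")
            if (c.first, c.second) in seen:
                raise ValueError(f"duplicate coupling for pair {c.first}->{c.second}")
            seen.add((c.first, c.second))
        for link in self.covariate_links:
            if link.pair not in seen:
                raise ValueError(
                    f"covariate link on {link.pair} has no matching coupling")
        if not 0.0 <= self.coupling_sd:
            raise ValueError("coupling_sd must be non-negative")
        if not 0.0 <= self.link_strength <= 1.0:
            raise ValueError("link_strength must be in [0, 1]")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.base_rates)


@dataclass(frozen=True)
class SyntheticSample:
    """Generated series and scores, plus the truth needed to recompute them."""

    series: list[BehaviorSeries]
    scores: list[AttachmentScores]
    config: GeneratorConfig
    realized_couplings: dict[str, dict[tuple[str, str], Coupling]]


def _dyad_rng(config: GeneratorConfig, dyad_index: int) -> np.random.Generator:
    # substream deterministically derived from (seed, dyad_index)
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(dyad_index)]))


def _realize_couplings(config: GeneratorConfig,
                       rng: np.random.Generator) -> dict[tuple[str, str], Coupling]:
    out = {}
    for c in config.couplings:
        q1 = float(np.clip(c.q1 + rng.normal(0.0, config.coupling_sd), 0.0, 1.0))
        q0 = float(np.clip(c.q0 + rng.normal(0.0, config.coupling_sd), 0.0, 1.0))
        out[(c.first, c.second)] = Coupling(c.first, c.second, q1, q0)
    return out


def _simulate_streams(config: GeneratorConfig,
                      realized: Mapping[tuple[str, str], Coupling],
                      rng: np.random.Generator) -> np.ndarray:
    cats = config.categories
    idx = {c: k for k, c in enumerate(cats)}
    base = np.array([config.base_rates[c] for c in cats])
    targets: dict[int, list[Coupling]] = {}
    for c in realized.values():
        targets.setdefault(idx[c.second], []).append(c)
    values = np.zeros((config.T, len(cats)), dtype=np.int8)
    values[0] = rng.random(len(cats)) < base
    for t in range(1, config.T):
        prev = values[t - 1]
        p = base.copy()
        for k, sources in targets.items():
            # noisy-OR of the active conditionals
            miss = 1.0
            for c in sources:
                miss *= 1.0 - (c.q1 if prev[idx[c.first]] else c.q0)
            p[k] = 1.0 - miss
        values[t] = rng.random(len(cats)) < p
    return values


def _dyad_id(dyad_index: int) -> str:
    return f"d{dyad_index + 1:03d}"


def generate_dyad(config: GeneratorConfig, dyad_index: int) -> BehaviorSeries:
    """Generate one dyad's behavior series, reproducible from (seed, index)."""
    rng = _dyad_rng(config, dyad_index)
    realized = _realize_couplings(config, rng)
    values = _simulate_streams(config, realized, rng)
    mat = pd.DataFrame(values, columns=list(config.categories))
    return BehaviorSeries(_dyad_id(dyad_index), mat, config.interval_length)


def generate_sample(config: GeneratorConfig) -> SyntheticSample:
    """Generate a full sample: series, linked covariate scores, and truth.

    Covariate scores are mean + sd * (r * signal + sqrt(1-r^2) * noise),
    where the signal is the weight-combined standardized deviation of the
    dyad's realized coupling gaps from their configured values, r is
    ``link_strength``, and the result is truncated to the instrument range.
    """
    series: list[BehaviorSeries] = []
    realized_all: dict[str, dict[tuple[str, str], Coupling]] = {}
    configured = {(c.first, c.second): c for c in config.couplings}
    for i in range(config.n_dyads):
        rng = _dyad_rng(config, i)
        realized = _realize_couplings(config, rng)
        values = _simulate_streams(config, realized, rng)
        mat = pd.DataFrame(values, columns=list(config.categories))
        sid = _dyad_id(i)
        series.append(BehaviorSeries(sid, mat, config.interval_length))
        realized_all[sid] = realized

    # covariate stream separate from the dyad substreams (tag far above any
    # plausible dyad_index)
    cov_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2**24]))
    links_by_cov: dict[str, list[CovariateLink]] = {}
    for link in config.covariate_links:
        links_by_cov.setdefault(link.covariate, []).append(link)

    # sd of a realized gap deviation: both q1 and q0 jittered independently
    gap_sd = config.coupling_sd * np.sqrt(2.0) if config.coupling_sd > 0 else 1.0
    scores: list[AttachmentScores] = []
    for i in range(config.n_dyads):
        sid = _dyad_id(i)
        vals: dict[str, float] = {}
        for cov, (mean, sd) in config.covariate_moments.items():
            links = links_by_cov.get(cov, [])
            eps = cov_rng.normal()
            if links:
                signal = sum(
                    link.weight
                    * (realized_all[sid][link.pair].gap - configured[link.pair].gap)
                    / gap_sd
                    for link in links
                )
                norm = np.sqrt(sum(link.weight**2 for link in links))
                r = config.link_strength
                raw = mean + sd * (r * signal / norm + np.sqrt(1.0 - r**2) * eps)
            else:
                raw = mean + sd * eps
            lo, hi = SCORE_RANGES[cov]
            vals[cov] = float(np.clip(raw, lo, hi))
        scores.append(AttachmentScores(dyad_id=sid, **vals))
    return SyntheticSample(series, scores, config, realized_all)


def default_config(**overrides) -> GeneratorConfig:
    """The default mother-child-like sample config, with keyword overrides."""
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


def load_generator_config(source) -> GeneratorConfig:
    """Read a :class:`GeneratorConfig` from a flat TOML file.

    Recognized keys: scalars ``n_dyads, T, seed, coupling_sd,
    link_strength, interval_length``; a ``[base_rates]`` table; an array
    ``[[couplings]]`` of tables with ``first, second`` and either
    ``q1``/``q0`` or a single ``gap`` (expanded marginal-preservingly from
    the base rates); ``[[covariate_links]]`` with ``covariate, first,
    second, weight``; and ``[covariate_moments]`` mapping covariate to
    ``{mean, sd}``. Omitted keys keep their defaults.
    """
    import tomllib

    with open(source, "rb") as fh:
        data = tomllib.load(fh)
    kwargs: dict = {}
    for key in ("n_dyads", "T", "seed", "coupling_sd", "link_strength", "interval_length"):
        if key in data:
            kwargs[key] = data[key]
    base = dict(data.get("base_rates", MCAM_BASE_RATES))
    kwargs["base_rates"] = base
    if "couplings" in data:
        couplings = []
        for c in data["couplings"]:
            if "gap" in c:
                couplings.append(marginal_preserving_coupling(
                    c["first"], c["second"], base[c["first"]], base[c["second"]], c["gap"]))
            else:
                couplings.append(Coupling(c["first"], c["second"], c["q1"], c["q0"]))
        kwargs["couplings"] = tuple(couplings)
    if "covariate_links" in data:
        kwargs["covariate_links"] = tuple(
            CovariateLink(l["covariate"], (l["first"], l["second"]), l["weight"])
            for l in data["covariate_links"])
    elif "couplings" in data:
        kwargs["covariate_links"] = ()  # custom couplings void the default links
    if "covariate_moments" in data:
        kwargs["covariate_moments"] = {
            k: (v["mean"], v["sd"]) for k, v in data["covariate_moments"].items()}
    return GeneratorConfig(**kwargs)
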