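"""End-to-end analysis runs: profiles, summaries, correlations, networks.

A run either reads an interval-coded behavior table (plus optional
covariate scores) or generates a synthetic sample, then computes per-dyad
profiles, sample summaries, covariate correlations and network exports,
writing everything (including a run log with every convention used) into
an output directory. Outputs are deterministic: the same inputs and seed
produce byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from . import behavior, inference, metrics, network
from .behavior import AttachmentScores, BehaviorSeries, CodingScheme
from .simulate import GeneratorConfig, generate_sample

__all__ = ["RunConfig", "AnalysisBundle", "ConfigError", "run_analyze", "run_compare_dyad"]


class ConfigError(ValueError):
    """Invalid run configuration (as opposed to unreadable input data)."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run.

    Exactly one of ``behavior_path`` (a long/wide CSV) or ``generator``
    (a synthetic-sample config) must be set.
    """

    behavior_path: str | Path | None = None
    scores_path: str | Path | None = None
    scheme_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    layout: Literal["long", "wide"] = "long"
    alpha: float = 0.05
    outlier_scale: str = "trust"
    outlier_threshold: float = 3.0
    p_window: Literal["lagged", "full"] = "lagged"
    out_dir: str | Path | None = None
    formats: tuple[str, ...] = ("dot", "graphml")
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.behavior_path is None) == (self.generator is None):
            raise ConfigError("exactly one of behavior_path or generator must be set")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.p_window not in ("lagged", "full"):
            raise ConfigError(f"p_window must be 'lagged' or 'full', got {self.p_window!r}")
        for f in self.formats:
            if f not in ("dot", "graphml"):
                raise ConfigError(f"unknown network format {f!r}")


@dataclass
class AnalysisBundle:
    """In-memory results of a run (everything also written to out_dir)."""

    profiles: list[metrics.DyadProfile]
    freq_summaries: list[inference.SampleSummary]
    seq_summaries: list[inference.SampleSummary]
    correlations: list[inference.CorrelationResult]
    networks: dict[str, network.NetworkSpec]
    excluded_dyads: list[str]
    log: dict
    warnings: list[str] = field(default_factory=list)


def _load_inputs(config: RunConfig) -> tuple[list[BehaviorSeries], list[AttachmentScores] | None]:
    if config.generator is not None:
        sample = generate_sample(config.generator)
        return sample.series, sample.scores
    scheme: CodingScheme | None = None
    if config.scheme_path is not None:
        scheme = behavior.read_scheme(config.scheme_path)
    series = behavior.read_behavior_table(config.behavior_path, scheme=scheme, layout=config.layout)
    scores = None
    if config.scores_path is not None:
        scores = behavior.read_attachment_scores(config.scores_path)
    return series, scores


def run_analyze(config: RunConfig) -> AnalysisBundle:
    """Run the full pipeline and (if ``out_dir`` is set) write the bundle.

    Stages degrade gracefully: with fewer than 2 dyads the sample stages
    are skipped; without scores (or fewer than 3 scored dyads) the
    correlation stage is skipped with a logged warning.
    """
    series, scores = _load_inputs(config)
    notes: list[str] = []

    excluded: list[str] = []
    if scores is not None and len(scores) >= 3:
        retained, dropped = inference.flag_outliers(
            scores, scale=config.outlier_scale, threshold=config.outlier_threshold)
        excluded = [s.dyad_id for s in dropped]
        if excluded:
            notes.append(
                f"excluded {len(excluded)} outlier dyad(s) on {config.outlier_scale}: {excluded}")
            keep = set(s.dyad_id for s in retained)
            series = [s for s in series if s.dyad_id in keep]
            scores = retained

    profiles = [metrics.dyad_profile(s, p_window=config.p_window) for s in series]

    freq_summaries: list[inference.SampleSummary] = []
    seq_summaries: list[inference.SampleSummary] = []
    if len(profiles) >= 2:
        freq_summaries = inference.summarize_frequencies(profiles)
        seq_summaries = inference.summarize_sequences(profiles)
    else:
        notes.append("fewer than 2 dyads: sample summary stage skipped")

    correlations: list[inference.CorrelationResult] = []
    scored = 0 if scores is None else sum(
        1 for s in scores if s.dyad_id in {p.dyad_id for p in profiles})
    if scores is None:
        notes.append("no scores table: correlation stage skipped")
    elif scored < 3:
        notes.append(f"only {scored} dyads with scores: correlation stage skipped")
    elif profiles:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            correlations = inference.correlate_with_scores(profiles, scores)
        notes.extend(str(w.message) for w in caught)

    networks: dict[str, network.NetworkSpec] = {}
    if freq_summaries and seq_summaries:
        networks["sample"] = network.build_sample_network(
            freq_summaries, seq_summaries, alpha=config.alpha)
    if correlations:
        for cov in inference.COVARIATES:
            for controlled in (None, inference.PARTIAL_CONTROLS.get(cov)):
                seq_c = [r for r in correlations
                         if r.covariate == cov and r.controlled_for == controlled
                         and " => " in r.measure]
                freq_c = [r for r in correlations
                          if r.covariate == cov and r.controlled_for == controlled
                          and " => " not in r.measure]
                if not (seq_c or freq_c):
                    continue
                name = cov if controlled is None else f"{cov}_partial"
                networks[name] = network.build_correlation_network(
                    seq_c, freq_c, alpha=config.alpha)

    log = {
        "seed": config.seed,
        "alpha": config.alpha,
        "p_window": config.p_window,
        "lag": 1,
        "outlier_scale": config.outlier_scale,
        "outlier_threshold": config.outlier_threshold,
        "prop_positive_denominator": "dyads with defined statistic",
        "mean_test": "upper-tailed one-sample t vs 0, defined dyads only",
        "dyads_column": "dyads in which the sequence occurs (n11 > 0)",
        "excluded_dyads": excluded,
        "n_dyads_analyzed": len(profiles),
        "source": "generator" if config.generator is not None else str(config.behavior_path),
        "notes": notes,
    }

    bundle = AnalysisBundle(profiles, freq_summaries, seq_summaries, correlations,
                            networks, excluded, log, notes)
    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: AnalysisBundle, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics.write_profiles(bundle.profiles, out / "profiles.csv")
    if bundle.freq_summaries:
        inference.summaries_to_frame(bundle.freq_summaries).to_csv(
            out / "frequency_summary.csv", index=False)
    if bundle.seq_summaries:
        inference.summaries_to_frame(bundle.seq_summaries).to_csv(
            out / "sequence_summary.csv", index=False)
    if bundle.correlations:
        inference.correlations_to_frame(bundle.correlations).to_csv(
            out / "correlations.csv", index=False)
    for name, spec in bundle.networks.items():
        for fmt in config.formats:
            ext = "dot" if fmt == "dot" else "graphml"
            (out / f"network_{name}.{ext}").write_text(
                network.export_network(spec, format=fmt))
    (out / "run_log.json").write_text(json.dumps(bundle.log, indent=2, sort_keys=True) + "\n")


def run_compare_dyad(config: RunConfig, dyad_id: str) -> pd.DataFrame:
    """z-score one dyad's measures against the rest of the sample.

    Outlier screening is not applied here: the typical use is exactly to
    profile a dyad that was excluded from the sample analyses.
    """
    series, _ = _load_inputs(config)
    by_id = {s.dyad_id: s for s in series}
    if dyad_id not in by_id:
        raise ValueError(f"dyad {dyad_id!r} not present in the input")
    reference = [s for s in series if s.dyad_id != dyad_id]
    if len(reference) < 3:
        raise ValueError(f"reference sample needs at least 3 dyads, got {len(reference)}")
    target = metrics.dyad_profile(by_id[dyad_id], p_window=config.p_window)
    ref_profiles = [metrics.dyad_profile(s, p_window=config.p_window) for s in reference]
    table = inference.compare_dyad_profile(target, ref_profiles)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in dyad_id)
        table.to_csv(out / f"compare_{safe}.csv", index=False)
    return table
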