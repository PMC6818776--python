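"""Network depictions of dyadic behavior dynamics.

Two views are supported. The *sample network* shows the average dynamics of
a sample: each behavior category is a node sized by its mean relative
frequency (with a floor so labels stay readable), and each ordered pair
whose mean sequencing likelihood tests significant is a directed edge
weighted by the absolute mean, solid when the sequence occurs more often
than chance and dashed when less often; auto-loops are downscaled so
between-category edges stay visible. The *correlation network* shows how a
sample's dynamics covary with one dyad-level covariate: node size is the
absolute frequency-covariate correlation, edge weight the absolute
sequence-covariate correlation, and shading encodes the sign (grey
positive, black negative); only significant correlations are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx

from .inference import CorrelationResult, SampleSummary

__all__ = [
    "NodeSpec",
    "EdgeSpec",
    "NetworkSpec",
    "build_sample_network",
    "build_correlation_network",
    "export_network",
    "network_spec_from_graphml",
]


@dataclass(frozen=True)
class NodeSpec:
    category: str
    size: float
    border: str  # "grey" | "black"


@dataclass(frozen=True)
class EdgeSpec:
    first: str
    second: str
    weight: float  # absolute magnitude
    sign: int  # +1 / -1
    style: str  # "solid" | "dashed"
    significant: bool

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("edge weight is a magnitude and must be >= 0")
        if (self.style == "dashed") != (self.sign < 0):
            raise ValueError("dashed style must coincide with negative sign")


@dataclass(frozen=True)
class NetworkSpec:
    nodes: tuple[NodeSpec, ...]
    edges: tuple[EdgeSpec, ...]
    auto_loop_scale: float = 0.5
    min_node_size: float = 0.05
    node_order: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 < self.auto_loop_scale <= 1.0:
            raise ValueError("auto_loop_scale must be in (0, 1]")
        for n in self.nodes:
            if n.size < self.min_node_size:
                raise ValueError(f"node {n.category!r} below minimum size")


def _sign_style(value: float) -> tuple[int, str]:
    sign = -1 if value < 0 else 1
    return sign, ("dashed" if sign < 0 else "solid")


def build_sample_network(
    freq_summaries: Sequence[SampleSummary],
    seq_summaries: Sequence[SampleSummary],
    alpha: float = 0.05,
    min_node_size: float = 0.05,
    node_scale: float = 1.0,
    auto_loop_scale: float = 0.5,
) -> NetworkSpec:
    """Average-sample network: node size from mean frequency, edges from
    significant mean sequencing likelihoods (p < alpha, upper-tailed test
    for positive means; negative means are drawn dashed when their
    two-sided evidence 2*(1-p) < alpha... see note).

    Edges are drawn only for pairs whose t-test p-value is below *alpha*;
    the sign of the mean decides solid (positive) vs dashed (negative).
    For a negative mean the upper-tailed p is near 1, so the lower-tail
    evidence 1 - p is used against alpha, keeping the "less often than
    chance" sequences visible exactly when they are significantly negative.
    """
    freqs = [s for s in freq_summaries if s.kind == "frequency"]
    seqs = [s for s in seq_summaries if s.kind == "sequence"]
    n_cat = len(freqs)
    if n_cat == 0 or len(seqs) != n_cat * n_cat:
        raise ValueError(
            f"incomplete summaries: {n_cat} frequencies but {len(seqs)} sequences "
            f"(need all {n_cat * n_cat} ordered pairs)")
    order = tuple(s.measure for s in freqs)
    nodes = tuple(
        NodeSpec(s.measure, max(min_node_size, node_scale * (s.mean or 0.0)), "black")
        for s in freqs
    )
    edges = []
    for s in seqs:
        if s.mean is None or s.p_value is None:
            continue
        tail_p = s.p_value if s.mean >= 0 else 1.0 - s.p_value
        if tail_p >= alpha:
            continue
        first, second = s.measure.split(" => ")
        sign, style = _sign_style(s.mean)
        weight = abs(s.mean) * (auto_loop_scale if first == second else 1.0)
        edges.append(EdgeSpec(first, second, weight, sign, style, True))
    return NetworkSpec(nodes, tuple(edges), auto_loop_scale, min_node_size, order)


def build_correlation_network(
    seq_correlations: Sequence[CorrelationResult],
    freq_correlations: Sequence[CorrelationResult],
    alpha: float = 0.05,
    min_node_size: float = 0.05,
    auto_loop_scale: float = 0.5,
) -> NetworkSpec:
    """Correlation network for a single covariate (optionally partial).

    Node size = |rho| of the frequency-covariate correlation (floored);
    node border grey/black for positive/negative rho. Edges are drawn for
    sequence-covariate correlations with p < alpha, weighted by |rho|,
    grey-solid when positive and black-dashed when negative.
    """
    covs = {(r.covariate, r.controlled_for) for r in seq_correlations} | {
        (r.covariate, r.controlled_for) for r in freq_correlations
    }
    if len(covs) > 1:
        raise ValueError(f"mixed covariates in one network: {sorted(covs)}")
    order = tuple(r.measure for r in freq_correlations)
    nodes = tuple(
        NodeSpec(r.measure, max(min_node_size, abs(r.rho)),
                 "grey" if r.rho >= 0 else "black")
        for r in freq_correlations
    )
    edges = []
    for r in seq_correlations:
        if r.p_value >= alpha:
            continue
        first, second = r.measure.split(" => ")
        sign, style = _sign_style(r.rho)
        weight = abs(r.rho) * (auto_loop_scale if first == second else 1.0)
        edges.append(EdgeSpec(first, second, weight, sign, style, True))
    return NetworkSpec(nodes, tuple(edges), auto_loop_scale, min_node_size, order)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _saturation(weight: float, clip: float) -> float:
    return min(weight, clip) / clip if clip > 0 else 0.0


def export_network(spec: NetworkSpec, format: Literal["dot", "graphml"] = "dot",
                   weight_clip: float = 1.0) -> str:
    """Deterministic serialization of a network spec.

    DOT output carries visual attributes directly (node ``width``,
    edge ``penwidth``/``style`` and a greyscale color whose saturation is
    linear in |weight| clipped at *weight_clip*); GraphML carries the raw
    spec attributes and round-trips via :func:`network_spec_from_graphml`.
    """
    fmt = format.lower()
    if fmt == "dot":
        lines = ["digraph behavior {"]
        if spec.node_order:
            lines.append(f'  graph [node_order="{",".join(spec.node_order)}"];')
        lines.append(f"  graph [auto_loop_scale={spec.auto_loop_scale:g}, "
                     f"min_node_size={spec.min_node_size:g}];")
        for n in spec.nodes:
            shade = "gray50" if n.border == "grey" else "black"
            lines.append(
                f'  "{n.category}" [width={n.size:.6g}, fixedsize=true, '
                f"color={shade}];"
            )
        for e in spec.edges:
            sat = _saturation(e.weight, weight_clip)
            grey = int(round(90 - 90 * sat))  # 0 = black (full saturation)
            lines.append(
                f'  "{e.first}" -> "{e.second}" [penwidth={0.5 + 3.5 * sat:.6g}, '
                f'weight={e.weight:.6g}, sign={e.sign}, style={e.style}, '
                f'color=gray{grey}];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"
    if fmt == "graphml":
        g = nx.DiGraph()
        g.graph["auto_loop_scale"] = spec.auto_loop_scale
        g.graph["min_node_size"] = spec.min_node_size
        g.graph["node_order"] = ",".join(spec.node_order)
        for n in spec.nodes:
            g.add_node(n.category, size=n.size, border=n.border)
        for e in spec.edges:
            g.add_edge(e.first, e.second, weight=e.weight, sign=e.sign,
                       style=e.style, significant=e.significant)
        return "\n".join(nx.generate_graphml(g)) + "\n"
    raise ValueError(f"unknown format {format!r} (use 'dot' or 'graphml')")


def network_spec_from_graphml(text: str) -> NetworkSpec:
    """Rebuild a :class:`NetworkSpec` from GraphML text (round-trip)."""
    g = nx.parse_graphml(text)
    order = tuple(c for c in g.graph.get("node_order", "").split(",") if c)
    node_iter = order if order else list(g.nodes)
    nodes = tuple(
        NodeSpec(c, float(g.nodes[c]["size"]), str(g.nodes[c]["border"]))
        for c in node_iter
    )
    edges = tuple(
        EdgeSpec(u, v, float(d["weight"]), int(d["sign"]), str(d["style"]),
                 bool(d["significant"]))
        for u, v, d in g.edges(data=True)
    )
    return NetworkSpec(
        nodes, edges,
        auto_loop_scale=float(g.graph.get("auto_loop_scale", 0.5)),
        min_node_size=float(g.graph.get("min_node_size", 0.05)),
        node_order=order,
    )
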