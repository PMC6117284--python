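"""Synthetic watersheds with known ground truth.

Generates topologies, stratified source sample sets and mixture samples whose
data-generating process matches the fitted model (Gaussian source scatter,
convex tracer mixing, Gaussian residual noise), so posterior consistency is
testable end to end. ``true_composite`` chains the true per-node proportions
through the network exactly and is the oracle for the deconvolution.

Default scales mirror typical fingerprinting studies: a handful of tracers
(3-15), 10-30 composite samples per source group, and 3-9 mixture samples
per node. All randomness flows from one master seed through named substreams
(sources / mixtures / per node), so runs are reproducible and the source and
mixture noise are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_report import (
    DEFAULT_LEVEL,
    SourceGroup,
    SourceSet,
    TracerTable,
    WatershedGraph,
    write_mixture_table,
    write_network_config,
    write_source_table,
)
from .mixing_model import PosteriorDraws

__all__ = [
    "TruthSpec",
    "make_topology",
    "random_topology",
    "build_truth",
    "recovery_truth",
    "pooling_hurts_truth",
    "simulate_sources",
    "simulate_mixtures",
    "true_composite",
    "true_node_means",
    "point_mass_posteriors",
    "simulate_bundle",
]


@dataclass
class TruthSpec:
    """Ground truth for one synthetic watershed.

    ``proportions`` maps node -> level -> {immediate input name -> p} (inputs
    are the node's local groups and upstream nodes); ``signatures`` maps each
    local group to its true per-tracer mean, so stratified (per-sub-watershed
    shifted) signatures are encoded directly.
    """

    graph: WatershedGraph
    panel: list[str]
    proportions: dict[str, dict[str, dict[str, float]]]
    signatures: dict[str, np.ndarray]
    source_sd: float | dict[str, float] = 1.0
    tau: float | np.ndarray = 0.5
    n_source: int | dict[str, int] = 15
    n_mix: int | dict[str, int] = 6
    levels: list[str] = field(default_factory=lambda: [DEFAULT_LEVEL])
    seed: int = 0

    def __post_init__(self) -> None:
        j = len(self.panel)
        for g, sig in self.signatures.items():
            self.signatures[g] = np.broadcast_to(np.asarray(sig, float), (j,)).copy()
        self.tau = np.broadcast_to(np.asarray(self.tau, float), (j,)).copy()
        if (self.tau <= 0).any():
            raise ValueError("tau must be > 0")
        for node, by_level in self.proportions.items():
            for lev, p in by_level.items():
                vals = np.array(list(p.values()), float)
                if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"true proportions at {node!r}/{lev!r} are not a simplex"
                    )

    def sd_for(self, group: str) -> float:
        if isinstance(self.source_sd, dict):
            return float(self.source_sd.get(group, 1.0))
        return float(self.source_sd)

    def n_source_for(self, group: str) -> int:
        if isinstance(self.n_source, dict):
            return int(self.n_source.get(group, 15))
        return int(self.n_source)

    def n_mix_for(self, node: str) -> int:
        if isinstance(self.n_mix, dict):
            return int(self.n_mix.get(node, 6))
        return int(self.n_mix)


# ---------------------------------------------------------------------------
# topologies
# ---------------------------------------------------------------------------


def make_topology(kind: str) -> WatershedGraph:
    """Canonical experimental designs.

    ``simple``: one node fed by three local source classes. ``longitudinal``:
    a 4-node nested chain over classes A-D with not every class present in
    every sub-watershed. ``distributed``: three sub-watershed outlets feeding
    two main-channel confluence nodes (5 nodes, 4 edges).
    """
    if kind == "simple":
        return WatershedGraph(
            nodes=["M"],
            edges=[],
            local_sources={"M": {"S_A": "A", "S_B": "B", "S_C": "C"}},
            classes=["A", "B", "C"],
        )
    if kind == "longitudinal":
        return WatershedGraph(
            nodes=["M1", "M2", "M3", "M4"],
            edges=[("M1", "M2"), ("M2", "M3"), ("M3", "M4")],
            local_sources={
                "M1": {"S_A1": "A", "S_B1": "B", "S_C1": "C"},
                "M2": {"S_B2": "B", "S_C2": "C", "S_D2": "D"},
                "M3": {"S_A3": "A", "S_D3": "D"},
                "M4": {"S_C4": "C", "S_D4": "D"},
            },
            classes=["A", "B", "C", "D"],
        )
    if kind == "distributed":
        return WatershedGraph(
            nodes=["M1", "M2", "M3", "M4", "M5"],
            edges=[("M1", "M3"), ("M2", "M3"), ("M3", "M5"), ("M4", "M5")],
            local_sources={
                "M1": {"S_A1": "A", "S_B1": "B"},
                "M2": {"S_B2": "B", "S_C2": "C"},
                "M3": {"S_D3": "D"},
                "M4": {"S_C4": "C", "S_D4": "D"},
                "M5": {},
            },
            classes=["A", "B", "C", "D"],
        )
    raise ValueError(f"unknown topology kind {kind!r}")


def random_topology(rng: np.random.Generator, max_nodes: int = 5) -> WatershedGraph:
    """Random small DAG for property tests: edges flow low -> high index,
    headwaters always get local groups so every node has an input."""
    n = int(rng.integers(1, max_nodes + 1))
    nodes = [f"M{i + 1}" for i in range(n)]
    classes = ["A", "B", "C", "D"][: int(rng.integers(2, 5))]
    edges = []
    for j in range(1, n):
        ups = [i for i in range(j) if rng.random() < 0.5]
        if not ups and rng.random() < 0.5:
            ups = [j - 1]
        edges += [(nodes[i], nodes[j]) for i in ups]
    has_up = {v for _, v in edges}
    local: dict[str, dict[str, str]] = {}
    for i, node in enumerate(nodes):
        k = int(rng.integers(0 if node in has_up else 1, 4))
        chosen = list(rng.choice(classes, size=min(k, len(classes)), replace=False))
        if node not in has_up and not chosen:
            chosen = [classes[0]]
        local[node] = {f"S_{c}{i + 1}": c for c in chosen}
    return WatershedGraph(nodes, edges, local, classes)


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------


def _inputs(graph: WatershedGraph, node: str) -> list[str]:
    return graph.upstream(node) + list(graph.local_sources.get(node, {}))


def build_truth(
    graph: WatershedGraph,
    seed: int = 0,
    n_tracers: int = 8,
    source_sd: float = 1.0,
    tau: float = 0.5,
    n_source: int = 15,
    n_mix: int = 6,
    signature_spread: float = 6.0,
    subwatershed_shift: float = 0.0,
    levels: list[str] | None = None,
    proportions: dict | None = None,
) -> TruthSpec:
    """Random but reproducible truth over a given topology.

    Class signatures are drawn once per class; a nonzero
    ``subwatershed_shift`` adds an independent per-group offset, emulating
    the stratified case where the same land-use class carries different
    tracer values in different sub-watersheds.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    levels = levels or [DEFAULT_LEVEL]
    panel = [f"tr{j + 1}" for j in range(n_tracers)]
    class_base = {
        c: rng.normal(0.0, signature_spread, n_tracers) for c in graph.classes
    }
    signatures = {}
    for node in graph.nodes:
        for g, c in graph.local_sources.get(node, {}).items():
            shift = rng.normal(0.0, subwatershed_shift, n_tracers) if subwatershed_shift else 0.0
            signatures[g] = class_base[c] + shift
    if proportions is None:
        proportions = {}
        for node in graph.nodes:
            names = _inputs(graph, node)
            proportions[node] = {}
            for lev in levels:
                p = rng.dirichlet(np.full(len(names), 2.0))
                proportions[node][lev] = dict(zip(names, p.tolist()))
    return TruthSpec(
        graph=graph,
        panel=panel,
        proportions=proportions,
        signatures=signatures,
        source_sd=source_sd,
        tau=tau,
        n_source=n_source,
        n_mix=n_mix,
        levels=levels,
        seed=seed,
    )


def recovery_truth(seed: int = 0) -> TruthSpec:
    """Single-node recovery scenario: 3 sources, 8 tracers, well-separated
    signatures, 30 source samples per group, 10 mixture samples, and true
    proportions (0.6, 0.3, 0.1)."""
    graph = make_topology("simple")
    signatures = {
        "S_A": np.array([10.0, 0.0, 0.0, 5.0, -5.0, 3.0, 0.0, 2.0]),
        "S_B": np.array([0.0, 10.0, 0.0, -5.0, 5.0, 0.0, 3.0, -2.0]),
        "S_C": np.array([0.0, 0.0, 10.0, 0.0, 0.0, -3.0, -3.0, 0.0]),
    }
    return TruthSpec(
        graph=graph,
        panel=[f"tr{j + 1}" for j in range(8)],
        proportions={"M": {DEFAULT_LEVEL: {"S_A": 0.6, "S_B": 0.3, "S_C": 0.1}}},
        signatures=signatures,
        source_sd=1.0,
        tau=0.5,
        n_source=30,
        n_mix=10,
        seed=seed,
    )


def pooling_hurts_truth(seed: int = 0) -> TruthSpec:
    """Confluence scenario where pooling same-class sources across
    sub-watersheds destroys the signal: class A's signature is shifted in
    opposite directions in the two tributaries, so the watershed-pooled class
    A signature collapses toward the class B one while each stratified local
    group stays sharp. Truth at the confluence: A 0.62, B 0.38."""
    graph = WatershedGraph(
        nodes=["M1", "M2", "M3"],
        edges=[("M1", "M3"), ("M2", "M3")],
        local_sources={
            "M1": {"S_A1": "A", "S_B1": "B"},
            "M2": {"S_A2": "A", "S_B2": "B"},
            "M3": {},
        },
        classes=["A", "B"],
    )
    signatures = {
        "S_A1": np.array([6.0, 2.0, -2.0, 1.0]),
        "S_A2": np.array([-6.0, -2.0, 2.0, -1.0]),
        "S_B1": np.array([0.0, -4.0, 4.0, 3.0]),
        "S_B2": np.array([1.0, -5.0, 5.0, 2.0]),
    }
    proportions = {
        "M1": {DEFAULT_LEVEL: {"S_A1": 0.8, "S_B1": 0.2}},
        "M2": {DEFAULT_LEVEL: {"S_A2": 0.2, "S_B2": 0.8}},
        "M3": {DEFAULT_LEVEL: {"M1": 0.7, "M2": 0.3}},
    }
    return TruthSpec(
        graph=graph,
        panel=["tr1", "tr2", "tr3", "tr4"],
        proportions=proportions,
        signatures=signatures,
        source_sd=1.0,
        tau=0.5,
        n_source=15,
        n_mix=8,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _rng(truth: TruthSpec, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([truth.seed, *tags]))


def simulate_sources(truth: TruthSpec) -> dict[str, SourceSet]:
    """Draw raw source samples per local group: Normal(signature, sd)."""
    out: dict[str, SourceSet] = {}
    for ni, node in enumerate(truth.graph.nodes):
        groups: dict[str, SourceGroup] = {}
        for gi, (g, cls) in enumerate(truth.graph.local_sources.get(node, {}).items()):
            n = truth.n_source_for(g)
            if n < 2:
                raise ValueError(f"group {g!r}: need n >= 2 source samples")
            rng = _rng(truth, 1, ni, gi)
            samples = truth.signatures[g] + rng.normal(
                0.0, truth.sd_for(g), size=(n, len(truth.panel))
            )
            groups[g] = SourceGroup(g, raw=pd.DataFrame(samples, columns=truth.panel))
        if groups:
            out[node] = SourceSet(
                node, groups=groups, class_map=dict(truth.graph.local_sources[node])
            )
    return out


def true_node_means(truth: TruthSpec) -> dict[str, dict[str, np.ndarray]]:
    """Exact mixture mean per node and level, chained through upstream truth."""
    from .deconvolution import unmixing_order

    means: dict[str, dict[str, np.ndarray]] = {}
    for node in unmixing_order(truth.graph):
        means[node] = {}
        for lev in truth.levels:
            total = np.zeros(len(truth.panel))
            for name, q in truth.proportions[node][lev].items():
                if name in truth.signatures:
                    total += q * truth.signatures[name]
                else:
                    up_lev = lev if lev in means[name] else DEFAULT_LEVEL
                    total += q * means[name][up_lev]
            means[node][lev] = total
    return means


def simulate_mixtures(truth: TruthSpec) -> dict[str, TracerTable]:
    """Draw mixture samples: Y = true node mean + Normal(0, tau), per level."""
    means = true_node_means(truth)
    out: dict[str, TracerTable] = {}
    for ni, node in enumerate(truth.graph.nodes):
        rng = _rng(truth, 2, ni)
        rows, labels, idx = [], [], []
        for lev in truth.levels:
            n = truth.n_mix_for(node)
            rows.append(
                means[node][lev] + rng.normal(0.0, truth.tau, size=(n, len(truth.panel)))
            )
            labels += [lev] * n
            idx += [f"{node}_{lev}_{i}" for i in range(n)]
        data = pd.DataFrame(np.vstack(rows), columns=truth.panel, index=idx)
        out[node] = TracerTable(
            node, data=data, factor=pd.Series(labels, index=idx, name="factor")
        )
    return out


def true_composite(truth: TruthSpec) -> dict[str, dict[str, dict[str, float]]]:
    """Exact ultimate-class composite per node x level (the deconvolution oracle)."""
    from .deconvolution import unmixing_order

    comp: dict[str, dict[str, dict[str, float]]] = {}
    local_all = truth.graph.local_sources
    for node in unmixing_order(truth.graph):
        comp[node] = {}
        for lev in truth.levels:
            total = {c: 0.0 for c in truth.graph.classes}
            for name, q in truth.proportions[node][lev].items():
                if name in local_all.get(node, {}):
                    total[local_all[node][name]] += q
                else:
                    up_lev = lev if lev in comp[name] else DEFAULT_LEVEL
                    for c, v in comp[name][up_lev].items():
                        total[c] += q * v
            comp[node][lev] = total
    return comp


def point_mass_posteriors(
    truth: TruthSpec, n_draws: int = 100
) -> dict[str, PosteriorDraws]:
    """Degenerate per-node posteriors at the true proportions (for exact
    checks of the deconvolution recursion)."""
    return {
        node: PosteriorDraws.point_mass(node, truth.proportions[node], n_draws=n_draws)
        for node in truth.graph.nodes
    }


def simulate_bundle(truth: TruthSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the full input bundle (mixture/source CSVs, graph + truth YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    write_network_config(truth.graph, outdir / "network.yaml")
    paths["network"] = outdir / "network.yaml"
    for node, table in simulate_mixtures(truth).items():
        p = outdir / f"mixture_{node}.csv"
        write_mixture_table(table, p)
        paths[f"mixture_{node}"] = p
    for node, sset in simulate_sources(truth).items():
        p = outdir / f"sources_{node}.csv"
        write_source_table(sset, p)
        paths[f"sources_{node}"] = p
    truth_doc = {
        "panel": truth.panel,
        "levels": truth.levels,
        "tau": np.asarray(truth.tau).tolist(),
        "proportions": truth.proportions,
        "true_composite": true_composite(truth),
        "seed": truth.seed,
    }
    with open(outdir / "truth.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=False)
    paths["truth"] = outdir / "truth.yaml"
    return paths
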