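"""Tabular and configuration I/O plus apportionment report rendering.

Data conventions: CSV is comma-separated UTF-8 with a header row and decimal
points; watershed topology and run configuration are YAML (JSON, being a YAML
subset, also parses). Node areas are reporting metadata only and never enter
inference.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("riverunmix")

__all__ = [
    "FormatError",
    "TracerTable",
    "SourceGroup",
    "SourceSet",
    "ConcentrationTable",
    "WatershedGraph",
    "McmcSettings",
    "RunConfig",
    "load_mixture_table",
    "load_source_table",
    "load_concentration_table",
    "load_network_config",
    "load_run_config",
    "write_mixture_table",
    "write_source_table",
    "write_network_config",
    "render_apportionment_table",
    "area_share",
]


class FormatError(ValueError):
    """Raised when an input file violates the declared layout or invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

DEFAULT_LEVEL = "all"


@dataclass
class TracerTable:
    """Mixture samples at one network node: samples x tracer panel (+ factor).

    ``data`` is indexed by sample id with one column per tracer; ``factor``
    assigns each sample a level of the run's fixed factor (sediment type,
    season, ...), defaulting to a single level ``"all"``. Level order is
    first-appearance order and affects report row order only.
    """

    node_id: str
    data: pd.DataFrame
    factor: pd.Series
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1:
            raise FormatError(f"node {self.node_id!r}: tracer table has no samples")
        if not self.data.index.equals(self.factor.index):
            raise FormatError(f"node {self.node_id!r}: factor not aligned with samples")
        bad = self.data.columns[self.data.isna().any(axis=0)]
        if len(bad):
            raise FormatError(
                f"node {self.node_id!r}: missing values in tracer(s) {list(bad)}"
            )

    @property
    def panel(self) -> list[str]:
        return list(self.data.columns)

    @property
    def levels(self) -> list[str]:
        seen: list[str] = []
        for v in self.factor:
            if v not in seen:
                seen.append(v)
        return seen

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    def values_for(self, tracer: str) -> np.ndarray:
        return self.data[tracer].to_numpy(float)


@dataclass
class SourceGroup:
    """One stratified source group: raw samples, or mean/sd/n summaries.

    Exactly one of ``raw`` (samples x tracers) and ``summary`` (tracers x
    [mean, sd, n]) is set. ``moments()`` returns per-tracer (mean, sd, n)
    either way.
    """

    name: str
    raw: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.raw is None) == (self.summary is None):
            raise FormatError(f"group {self.name!r}: need exactly one of raw/summary")
        if self.raw is not None:
            if self.raw.shape[0] < 2:
                raise FormatError(
                    f"group {self.name!r}: {self.raw.shape[0]} sample(s); "
                    "need >= 2 for a defined SD"
                )
        else:
            s = self.summary
            missing = {"mean", "sd", "n"} - set(s.columns)
            if missing:
                raise FormatError(f"group {self.name!r}: summary lacks {sorted(missing)}")
            if (s["n"] < 2).any():
                bad = s.index[s["n"] < 2][0]
                raise FormatError(
                    f"group {self.name!r}, tracer {bad!r}: n < 2 (SD undefined)"
                )
            if (s["sd"] < 0).any():
                raise FormatError(f"group {self.name!r}: negative SD")

    @property
    def panel(self) -> list[str]:
        src = self.raw.columns if self.raw is not None else self.summary.index
        return list(src)

    @property
    def n_samples(self) -> int:
        if self.raw is not None:
            return int(self.raw.shape[0])
        return int(self.summary["n"].min())

    def moments(self) -> pd.DataFrame:
        """Per-tracer mean, sd (ddof=1) and n, as a tracers x [mean, sd, n] frame."""
        if self.summary is not None:
            return self.summary[["mean", "sd", "n"]].astype(float)
        return pd.DataFrame(
            {
                "mean": self.raw.mean(axis=0),
                "sd": self.raw.std(axis=0, ddof=1),
                "n": float(self.raw.shape[0]),
            }
        )


@dataclass
class SourceSet:
    """Stratified source groups at one node with a group -> ultimate-class map."""

    node_id: str
    groups: dict[str, SourceGroup]
    class_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        panels = {g: tuple(grp.panel) for g, grp in self.groups.items()}
        if len(set(panels.values())) > 1:
            raise FormatError(
                f"node {self.node_id!r}: tracer panels differ across groups: {panels}"
            )
        for g in self.groups:
            self.class_map.setdefault(g, g)

    @property
    def panel(self) -> list[str]:
        first = next(iter(self.groups.values()))
        return first.panel

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    def has_raw(self) -> bool:
        return all(g.raw is not None for g in self.groups.values())


@dataclass
class ConcentrationTable:
    """Per-source tracer concentrations (strictly positive, shared mass units)."""

    data: pd.DataFrame  # groups x tracers

    def __post_init__(self) -> None:
        if (self.data <= 0).any().any() or self.data.isna().any().any():
            raise FormatError("concentration table must be strictly positive")

    def matrix(self, groups: Sequence[str], panel: Sequence[str]) -> np.ndarray:
        missing = [g for g in groups if g not in self.data.index]
        if missing:
            raise FormatError(f"concentration table lacks group(s) {missing}")
        missing_t = [t for t in panel if t not in self.data.columns]
        if missing_t:
            raise FormatError(f"concentration table lacks tracer(s) {missing_t}")
        return self.data.loc[list(groups), list(panel)].to_numpy(float)


@dataclass
class WatershedGraph:
    """DAG of mixture nodes with upstream edges and per-node local source groups.

    ``local_sources`` maps node -> {group name -> ultimate class}; ``areas``
    holds optional contributing areas in km^2, used only for reporting.
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    local_sources: dict[str, dict[str, str]]
    classes: list[str]
    areas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise FormatError(f"edge ({u!r}, {v!r}) references undeclared node")
            g.add_edge(u, v)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise FormatError(f"watershed graph contains a cycle: {cycle}")
        for n in self.nodes:
            if not self.local_sources.get(n) and g.in_degree(n) == 0:
                raise FormatError(f"node {n!r} has no inputs (no local sources, no upstream edges)")
        for n, groups in self.local_sources.items():
            if n not in self.nodes:
                raise FormatError(f"local sources declared for unknown node {n!r}")
            for grp, cls in groups.items():
                if cls not in self.classes:
                    raise FormatError(
                        f"group {grp!r} at node {n!r} maps to undeclared class {cls!r}"
                    )
        self._nx = g

    def upstream(self, node: str) -> list[str]:
        return sorted(self._nx.predecessors(node))

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class McmcSettings:
    """Chain length, burn-in, thinning and chain count for one model fit."""

    chain_length: int = 1_000_000
    burn: int = 700_000
    thin: int = 300
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn < self.chain_length:
            raise ValueError("burn must be < chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.chain_length - self.burn) // self.thin

    @property
    def n_retained_total(self) -> int:
        return self.n_retained_per_chain * self.n_chains

    def doubled(self) -> "McmcSettings":
        """Retry profile after a failed convergence gate: double the chain."""
        return McmcSettings(
            chain_length=2 * self.chain_length,
            burn=2 * self.burn,
            thin=self.thin,
            n_chains=self.n_chains,
            seed=self.seed,
        )


#: MCMC profile used throughout the test suite; the class default mirrors the
#: field-scale runs (1e6 iterations, 7e5 burn, thin 300, 3 chains).
TEST_PROFILE = dict(chain_length=50_000, burn=25_000, thin=25, n_chains=3)


@dataclass
class RunConfig:
    """Top-level run options shared by the CLI and the library drivers."""

    mode: str = "deconv"  # deconv | pooled | single_node
    factor: str | None = None
    alpha: float | dict[str, float] = 1.0
    error_model: str = "residual_only"  # residual_only | process_only
    concentration: bool = False
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    seed: int = 0
    range_threshold: float = 0.5
    manual_exclude: list[str] = field(default_factory=list)
    manual_include: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in {"deconv", "pooled", "single_node"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.error_model not in {"residual_only", "process_only"}:
            raise ValueError(f"unknown error model {self.error_model!r}")
        vals = (
            [self.alpha] if np.isscalar(self.alpha) else list(self.alpha.values())
        )
        if any(a <= 0 for a in vals):
            raise ValueError("Dirichlet hyperparameters must be > 0")

    def alpha_for(self, groups: Sequence[str]) -> np.ndarray:
        if np.isscalar(self.alpha):
            return np.full(len(groups), float(self.alpha))
        return np.array([float(self.alpha.get(g, 1.0)) for g in groups])


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def load_mixture_table(
    path: str | Path,
    panel: Sequence[str],
    factor_name: str | None = None,
    node_id: str | None = None,
) -> TracerTable:
    """Read a mixture-sample CSV and validate it against the declared panel.

    Rows with any missing panel value are dropped with a warning naming them;
    an empty result is an error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: empty mixture table")
    missing = [c for c in panel if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing tracer column(s) {missing}")
    if factor_name is not None and factor_name not in df.columns:
        raise FormatError(f"{path}: missing factor column {factor_name!r}")

    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    else:
        df.index = [f"s{i}" for i in range(len(df))]
    data = df[list(panel)].apply(pd.to_numeric, errors="coerce")
    keep = data.notna().all(axis=1)
    if not keep.all():
        dropped = list(data.index[~keep])
        warnings.warn(f"{path}: dropped sample(s) with missing panel values: {dropped}")
        log.warning("%s: dropped samples %s", path, dropped)
    data = data[keep]
    if data.empty:
        raise FormatError(f"{path}: no complete samples after dropping missing values")
    if factor_name is None:
        factor = pd.Series(DEFAULT_LEVEL, index=data.index, name="factor")
    else:
        factor = df.loc[keep, factor_name].astype(str).rename("factor")
    return TracerTable(node_id or path.stem, data=data, factor=factor)


def load_source_table(
    path: str | Path,
    mode: str = "raw",
    class_map: Mapping[str, str] | None = None,
    node_id: str | None = None,
) -> SourceSet:
    """Read a source-group CSV in raw or summary layout.

    Raw layout: ``group`` column (+ optional ``sample_id``) and one column per
    tracer. Summary layout (long): ``group, tracer, mean, sd, n``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: empty source table")
    if "group" not in df.columns:
        raise FormatError(f"{path}: missing 'group' column")
    groups: dict[str, SourceGroup] = {}
    if mode == "raw":
        tracer_cols = [c for c in df.columns if c not in ("group", "sample_id")]
        if not tracer_cols:
            raise FormatError(f"{path}: no tracer columns")
        for gname, sub in df.groupby("group", sort=False):
            raw = sub[tracer_cols].apply(pd.to_numeric, errors="coerce")
            keep = raw.notna().all(axis=1)
            if not keep.all():
                warnings.warn(f"{path}: group {gname!r}: dropped incomplete sample(s)")
            raw = raw[keep].reset_index(drop=True)
            groups[str(gname)] = SourceGroup(str(gname), raw=raw)
    elif mode == "summary":
        need = {"tracer", "mean", "sd", "n"}
        if not need <= set(df.columns):
            raise FormatError(f"{path}: summary layout needs columns {sorted(need)}")
        for gname, sub in df.groupby("group", sort=False):
            summ = sub.set_index("tracer")[["mean", "sd", "n"]].astype(float)
            groups[str(gname)] = SourceGroup(str(gname), summary=summ)
    else:
        raise ValueError(f"unknown source table mode {mode!r}")
    return SourceSet(
        node_id or path.stem, groups=groups, class_map=dict(class_map or {})
    )


def load_concentration_table(path: str | Path) -> ConcentrationTable:
    df = pd.read_csv(path)
    if "group" not in df.columns:
        raise FormatError(f"{path}: missing 'group' column")
    df = df.set_index("group").apply(pd.to_numeric, errors="coerce")
    return ConcentrationTable(df)


def load_network_config(path: str | Path) -> WatershedGraph:
    """Read a watershed topology YAML/JSON file into a validated DAG."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return _graph_from_dict(cfg, origin=str(path))


def _graph_from_dict(cfg: Mapping, origin: str = "<config>") -> WatershedGraph:
    try:
        nodes_raw = cfg["nodes"]
        classes = [str(c) for c in cfg.get("classes", [])]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{origin}: malformed network config") from exc
    nodes, local_sources, areas = [], {}, {}
    for item in nodes_raw:
        if isinstance(item, str):
            item = {"id": item}
        nid = str(item["id"])
        nodes.append(nid)
        local_sources[nid] = {str(g): str(c) for g, c in (item.get("local_sources") or {}).items()}
        if "area_km2" in item:
            areas[nid] = float(item["area_km2"])
    edges = [(str(u), str(v)) for u, v in cfg.get("edges", [])]
    if not classes:
        classes = sorted({c for m in local_sources.values() for c in m.values()})
    return WatershedGraph(nodes, edges, local_sources, classes, areas)


def write_network_config(graph: WatershedGraph, path: str | Path) -> None:
    cfg = {
        "nodes": [
            {
                "id": n,
                **({"local_sources": graph.local_sources[n]} if graph.local_sources.get(n) else {}),
                **({"area_km2": graph.areas[n]} if n in graph.areas else {}),
            }
            for n in graph.nodes
        ],
        "edges": [list(e) for e in graph.edges],
        "classes": graph.classes,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_mixture_table(table: TracerTable, path: str | Path) -> None:
    out = table.data.copy()
    out.insert(0, "factor", table.factor)
    out.index.name = "sample_id"
    out.to_csv(path)


def write_source_table(src: SourceSet, path: str | Path) -> None:
    if src.has_raw():
        frames = []
        for gname, grp in src.groups.items():
            f = grp.raw.copy()
            f.insert(0, "group", gname)
            frames.append(f)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        rows = []
        for gname, grp in src.groups.items():
            m = grp.moments()
            for tracer, row in m.iterrows():
                rows.append(
                    dict(group=gname, tracer=tracer, mean=row["mean"], sd=row["sd"], n=row["n"])
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    mcmc = McmcSettings(**cfg.pop("mcmc", {}))
    return RunConfig(mcmc=mcmc, **cfg)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def render_apportionment_table(
    summary: pd.DataFrame,
    txt_path: str | Path | None = None,
    csv_path: str | Path | None = None,
) -> str:
    """Render a posterior summary as the conventional "mean ± SD" text table.

    ``summary`` needs columns node, level, source, mean, sd; values are
    formatted to two decimals. A machine-readable CSV twin is written whenever
    ``csv_path`` is given. Rendering is a pure function of the summary.
    """
    cols = ["node", "level", "source", "mean", "sd"]
    missing = [c for c in cols if c not in summary.columns]
    if missing:
        raise FormatError(f"summary lacks column(s) {missing}")
    buf = io.StringIO()
    buf.write(f"{'node':<10}{'source':<14}{'level':<10}{'proportion':<14}\n")
    for _, row in summary.iterrows():
        cell = f"{row['mean']:.2f} ± {row['sd']:.2f}"
        buf.write(f"{str(row['node']):<10}{str(row['source']):<14}{str(row['level']):<10}{cell:<14}\n")
    text = buf.getvalue()
    if txt_path is not None:
        Path(txt_path).write_text(text, encoding="utf-8")
    if csv_path is not None:
        summary.to_csv(csv_path, index=False)
    return text


def area_share(graph: WatershedGraph, node: str, outlet: str) -> float:
    """Contributing-area share of ``node`` within ``outlet``'s watershed, in %.

    Areas are the cumulative contributing areas recorded on the graph (km^2).
    """
    try:
        a, total = graph.areas[node], graph.areas[outlet]
    except KeyError as exc:
        raise FormatError(f"missing area for node {exc.args[0]!r}") from exc
    if total <= 0:
        raise FormatError("outlet area must be positive")
    return 100.0 * a / total
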