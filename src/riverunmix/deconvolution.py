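"""Network-wide orchestration: sequential node fits and deconvolution.

Nodes are fitted in topological (upstream-first) order, with each upstream
node's mixture samples acting as a pseudo-source to its downstream neighbour.
Deconvolution then re-expresses every node's posterior over its immediate
inputs as a posterior over the ultimate source classes by the recursion

    composite(node) = sum over immediate inputs i of q_i * composite(i)

applied draw-by-draw, where a local source group's composite is the indicator
of its ultimate class. Because independently fitted nodes have independent
posteriors, draws are paired index-wise after an independent seeded
permutation of each node's pooled retained draws, which propagates the full
posterior uncertainty through the network. The pooled baseline instead merges
same-class source groups across sub-watersheds and unmixes every node against
the merged classes in a single model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_report import (
    ConcentrationTable,
    DEFAULT_LEVEL,
    McmcSettings,
    RunConfig,
    SourceGroup,
    SourceSet,
    TracerTable,
    WatershedGraph,
)
from .mixing_model import ConvergenceReport, NodeModelSpec, PosteriorDraws, run_mcmc

__all__ = [
    "ConvergenceError",
    "NodePosteriors",
    "CompositeApportionment",
    "unmixing_order",
    "assemble_node_sources",
    "fit_network",
    "deconvolute",
    "pooled_fit",
    "summarize_composite",
]


class ConvergenceError(RuntimeError):
    """A node failed the Gelman-Rubin gate even after the automatic retry."""


@dataclass
class NodePosteriors:
    """Per-node posteriors over immediate inputs, with convergence reports."""

    posteriors: dict[str, PosteriorDraws]
    reports: dict[str, ConvergenceReport] = field(default_factory=dict)

    def __getitem__(self, node: str) -> PosteriorDraws:
        return self.posteriors[node]

    def __contains__(self, node: str) -> bool:
        return node in self.posteriors


@dataclass
class CompositeApportionment:
    """Deconvoluted draws: node -> level -> (n_draws, n_classes) array."""

    classes: list[str]
    draws: dict[str, dict[str, np.ndarray]]

    def mean(self, node: str, level: str, cls: str) -> float:
        return float(self.draws[node][level][:, self.classes.index(cls)].mean())

    def summary(self) -> pd.DataFrame:
        return summarize_composite(self)


def unmixing_order(graph: WatershedGraph) -> list[str]:
    """Topological node order (upstream before downstream), ties by label."""
    return list(nx.lexicographical_topological_sort(graph._nx))


def assemble_node_sources(
    graph: WatershedGraph,
    node: str,
    mixtures: dict[str, TracerTable],
    sources: dict[str, SourceSet],
    config: RunConfig | None = None,
    panel: list[str] | None = None,
    conc_table: ConcentrationTable | None = None,
) -> NodeModelSpec:
    """Build the node's model spec: upstream pseudo-sources + local groups.

    An upstream node contributes a pseudo-source whose moments are computed
    from its own mixture samples pooled across factor levels; it therefore
    needs at least 2 mixture samples for a defined SD.
    """
    config = config or RunConfig()
    table = mixtures[node]
    panel = panel or table.panel
    names: list[str] = []
    mean_rows, sd_rows, n_rows = [], [], []
    for up in graph.upstream(node):
        up_table = mixtures[up]
        if up_table.n_samples < 2:
            raise ValueError(
                f"upstream node {up!r} has {up_table.n_samples} mixture sample(s); "
                "need >= 2 for a pseudo-source SD"
            )
        sub = up_table.data[panel]
        names.append(up)
        mean_rows.append(sub.mean(axis=0).to_numpy())
        sd_rows.append(sub.std(axis=0, ddof=1).to_numpy())
        n_rows.append(np.full(len(panel), float(sub.shape[0])))
    local = sources.get(node)
    if local is not None:
        for g in local.group_names:
            mom = local.groups[g].moments().loc[panel]
            names.append(g)
            mean_rows.append(mom["mean"].to_numpy())
            sd_rows.append(mom["sd"].to_numpy())
            n_rows.append(mom["n"].to_numpy())
    conc = None
    if config.concentration:
        if conc_table is None:
            raise ValueError("concentration on but no concentration table given")
        conc = conc_table.matrix(names, panel)
    return NodeModelSpec(
        node_id=node,
        sources=names,
        panel=list(panel),
        mean=np.array(mean_rows),
        sd=np.array(sd_rows),
        n=np.array(n_rows),
        levels=table.levels,
        alpha=config.alpha_for(names),
        error_model=config.error_model,
        conc=conc,
    )


def _node_seed(master: int, idx: int) -> int:
    return int(
        np.random.SeedSequence([int(master) % (2**31 - 1), 7919, idx]).generate_state(1)[0]
        % (2**31 - 1)
    )


def fit_network(
    graph: WatershedGraph,
    mixtures: dict[str, TracerTable],
    sources: dict[str, SourceSet],
    config: RunConfig,
    conc_table: ConcentrationTable | None = None,
    panels: dict[str, list[str]] | None = None,
    force: bool = False,
) -> NodePosteriors:
    """Fit every node in upstream-first order with per-node derived seeds.

    A node failing the convergence gate is retried once with doubled chain
    length; a second failure raises unless ``force`` is set, in which case the
    flagged posterior is kept.
    """
    order = unmixing_order(graph)
    posts: dict[str, PosteriorDraws] = {}
    reports: dict[str, ConvergenceReport] = {}
    for idx, node in enumerate(order):
        spec = assemble_node_sources(
            graph,
            node,
            mixtures,
            sources,
            config,
            panel=(panels or {}).get(node),
            conc_table=conc_table,
        )
        settings = McmcSettings(
            chain_length=config.mcmc.chain_length,
            burn=config.mcmc.burn,
            thin=config.mcmc.thin,
            n_chains=config.mcmc.n_chains,
            seed=_node_seed(config.seed, idx),
        )
        post = run_mcmc(spec, mixtures[node], settings)
        if not post.convergence.passed:
            post = run_mcmc(spec, mixtures[node], settings.doubled())
        if not post.convergence.passed and not force:
            raise ConvergenceError(
                f"node {node!r} failed the R-hat gate after one doubled-chain retry "
                f"(fraction above {post.convergence.fraction_above:.2%})"
            )
        posts[node] = post
        reports[node] = post.convergence
    return NodePosteriors(posteriors=posts, reports=reports)


def _aligned_level(
    comp_levels: list[str], level: str, upstream: str, level_map: dict | None
) -> str:
    if level in comp_levels:
        return level
    if level_map and (upstream, level) in level_map:
        return level_map[(upstream, level)]
    if DEFAULT_LEVEL in comp_levels:
        return DEFAULT_LEVEL
    raise ValueError(
        f"cannot align level {level!r} with upstream node {upstream!r} "
        f"(its levels: {comp_levels}); provide a level map"
    )


def deconvolute(
    graph: WatershedGraph,
    node_posteriors: NodePosteriors | dict[str, PosteriorDraws],
    pairing_seed: int = 0,
    level_map: dict | None = None,
) -> CompositeApportionment:
    """Propagate node posteriors down the DAG into ultimate-class composites.

    Draw pairing: each node's pooled retained draws are independently
    permuted with a seed derived from ``pairing_seed``, truncated to the
    minimum draw count over nodes, and paired index-wise. Any pairing is
    valid because independently fitted node posteriors are independent; the
    permutation removes chain-order artifacts.
    """
    posts = (
        node_posteriors.posteriors
        if isinstance(node_posteriors, NodePosteriors)
        else node_posteriors
    )
    order = unmixing_order(graph)
    missing = [n for n in order if n not in posts]
    if missing:
        raise ValueError(f"no posterior for node(s) {missing}")
    classes = list(graph.classes)
    n_draws = min(posts[n].p_draws(posts[n].levels[0]).shape[0] for n in order)
    permuted: dict[str, dict[str, np.ndarray]] = {}
    for idx, node in enumerate(order):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(pairing_seed) % (2**31 - 1), 104729, idx])
        )
        post = posts[node]
        perm = rng.permutation(post.p_draws(post.levels[0]).shape[0])[:n_draws]
        permuted[node] = {lev: post.p_draws(lev)[perm] for lev in post.levels}

    comp: dict[str, dict[str, np.ndarray]] = {}
    for node in order:
        post = posts[node]
        inputs = post.sources
        local = graph.local_sources.get(node, {})
        comp[node] = {}
        for lev in post.levels:
            q = permuted[node][lev]  # (n_draws, K)
            total = np.zeros((n_draws, len(classes)))
            for ki, name in enumerate(inputs):
                if name in local:
                    ci = classes.index(local[name])
                    total[:, ci] += q[:, ki]
                elif name in comp:
                    up_lev = _aligned_level(list(comp[name]), lev, name, level_map)
                    total += q[:, ki : ki + 1] * comp[name][up_lev]
                else:
                    raise ValueError(
                        f"input {name!r} of node {node!r} is neither a local group "
                        "nor an already-deconvoluted upstream node"
                    )
            comp[node][lev] = total
    return CompositeApportionment(classes=classes, draws=comp)


def _pool_groups(
    graph: WatershedGraph, sources: dict[str, SourceSet], panel: list[str]
) -> dict[str, SourceGroup]:
    """Merge same-class groups across sub-watersheds into one group per class."""
    by_class: dict[str, list[SourceGroup]] = {c: [] for c in graph.classes}
    for node, sset in sources.items():
        for gname, grp in sset.groups.items():
            cls = graph.local_sources.get(node, {}).get(gname, sset.class_map.get(gname))
            if cls is None:
                raise ValueError(f"group {gname!r} at node {node!r} has no class")
            by_class.setdefault(cls, []).append(grp)
    pooled: dict[str, SourceGroup] = {}
    for cls, groups in by_class.items():
        if not groups:
            raise ValueError(f"ultimate class {cls!r} present in no sub-watershed")
        if all(g.raw is not None for g in groups):
            raw = pd.concat([g.raw[panel] for g in groups], ignore_index=True)
            pooled[cls] = SourceGroup(cls, raw=raw)
        else:
            # exact pooled moments: within-group + between-group sums of squares
            rows = []
            for tr in panel:
                ms = np.array([g.moments().loc[tr, "mean"] for g in groups])
                sds = np.array([g.moments().loc[tr, "sd"] for g in groups])
                ns = np.array([g.moments().loc[tr, "n"] for g in groups])
                n = ns.sum()
                m = float((ns * ms).sum() / n)
                ss = float(((ns - 1) * sds**2).sum() + (ns * (ms - m) ** 2).sum())
                rows.append(dict(tracer=tr, mean=m, sd=np.sqrt(ss / (n - 1)), n=n))
            pooled[cls] = SourceGroup(
                cls, summary=pd.DataFrame(rows).set_index("tracer")
            )
    return pooled


def pooled_fit(
    graph: WatershedGraph,
    mixtures: dict[str, TracerTable],
    sources: dict[str, SourceSet],
    config: RunConfig,
    conc_table: ConcentrationTable | None = None,
    panel: list[str] | None = None,
) -> PosteriorDraws:
    """Watershed-wide baseline: merge classes across sub-watersheds, then unmix
    all node mixtures against the merged classes in one model.

    With ``config.factor`` unset, the node label is used as the factor, so the
    fit still reports a proportion simplex per node (one level per node).
    """
    if not mixtures:
        raise ValueError("need at least one mixture node")
    order = [n for n in unmixing_order(graph) if n in mixtures]
    panel = panel or mixtures[order[0]].panel
    pooled_groups = _pool_groups(graph, sources, panel)
    class_order = [c for c in graph.classes if c in pooled_groups]
    frames, factors = [], []
    for node in order:
        t = mixtures[node]
        frames.append(t.data[panel])
        if config.factor is not None:
            factors.append(t.factor)
        else:
            factors.append(pd.Series(node, index=t.data.index))
    data = pd.concat(frames)
    data.index = [f"{n}:{i}" for n, f in zip(order, frames) for i in f.index]
    factor = pd.concat(factors)
    factor.index = data.index
    combined = TracerTable("pooled", data=data, factor=factor)

    mom = {c: pooled_groups[c].moments().loc[panel] for c in class_order}
    conc = None
    if config.concentration:
        if conc_table is None:
            raise ValueError("concentration on but no concentration table given")
        conc = conc_table.matrix(class_order, panel)
    spec = NodeModelSpec(
        node_id="pooled",
        sources=class_order,
        panel=list(panel),
        mean=np.array([mom[c]["mean"].to_numpy() for c in class_order]),
        sd=np.array([mom[c]["sd"].to_numpy() for c in class_order]),
        n=np.array([mom[c]["n"].to_numpy() for c in class_order]),
        levels=combined.levels,
        alpha=config.alpha_for(class_order),
        error_model=config.error_model,
        conc=conc,
    )
    settings = McmcSettings(
        chain_length=config.mcmc.chain_length,
        burn=config.mcmc.burn,
        thin=config.mcmc.thin,
        n_chains=config.mcmc.n_chains,
        seed=_node_seed(config.seed, 999),
    )
    post = run_mcmc(spec, combined, settings)
    if not post.convergence.passed:
        post = run_mcmc(spec, combined, settings.doubled())
    return post


def summarize_composite(comp: CompositeApportionment) -> pd.DataFrame:
    """Mean, SD and quantiles per node x level x ultimate class."""
    qs = [0.025, 0.25, 0.5, 0.75, 0.975]
    rows = []
    for node, by_level in comp.draws.items():
        for lev, arr in by_level.items():
            for ci, cls in enumerate(comp.classes):
                d = arr[:, ci]
                rows.append(
                    {
                        "node": node,
                        "level": lev,
                        "source": cls,
                        "mean": d.mean(),
                        "sd": d.std(ddof=1) if len(d) > 1 else 0.0,
                        **{f"q{100 * q:g}": np.quantile(d, q) for q in qs},
                    }
                )
    return pd.DataFrame(rows)
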