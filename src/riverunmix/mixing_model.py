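"""Per-node Bayesian mixing model.

The model treats each mixture sample at a node as a noisy, optionally
concentration-weighted, convex combination of its candidate sources'
tracer signatures:

    Y_ij ~ Normal( sum_k p'_kj(level(i)) * mu_kj ,  sd_j )

with p'_kj = p_k c_kj / sum_l p_l c_lj (concentration dependence), a
Dirichlet(alpha) prior on each factor level's proportion simplex, and either
a per-tracer residual scale tau_j ("residual only", the default) or a
source-variance-propagated scale ("process only") as sd_j. Source means and
SDs are uncertain: each MCMC iteration draws them from the closed-form
posterior given the source samples alone (noninformative p(mu, sigma^2)
proportional to 1/sigma^2). Convergence is gated on the Gelman-Rubin
potential scale reduction factor, rejecting a fit when more than 5% of
monitored variables exceed 1.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _sampler
from .io_report import (
    ConcentrationTable,
    McmcSettings,
    RunConfig,
    SourceSet,
    TracerTable,
    DEFAULT_LEVEL,
)

__all__ = [
    "NodeModelSpec",
    "PosteriorDraws",
    "ConvergenceReport",
    "source_param_draw",
    "apply_concentration",
    "mixture_mean",
    "log_posterior",
    "run_mcmc",
    "gelman_rubin",
    "check_convergence",
    "RHAT_THRESHOLD",
    "RHAT_MAX_FRACTION",
]

RHAT_THRESHOLD = 1.05
RHAT_MAX_FRACTION = 0.05


@dataclass
class NodeModelSpec:
    """Everything the sampler needs for one node, in array form.

    ``sources`` is the ordered list of immediate inputs (local stratified
    groups plus upstream-node pseudo-sources); ``mean``/``sd``/``n`` are
    (K, J) source moments over the tracer ``panel``. ``tau_fixed`` pins the
    residual scale instead of sampling it (useful for controlled analyses).
    """

    node_id: str
    sources: list[str]
    panel: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    levels: list[str] = field(default_factory=lambda: [DEFAULT_LEVEL])
    alpha: np.ndarray | None = None
    error_model: str = "residual_only"
    conc: np.ndarray | None = None
    draw_sources: bool = True
    tau_fixed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.atleast_2d(np.asarray(self.mean, float))
        self.sd = np.atleast_2d(np.asarray(self.sd, float))
        self.n = np.atleast_2d(np.asarray(self.n, float))
        k, j = self.mean.shape
        if len(self.sources) < 2:
            raise ValueError(f"node {self.node_id!r}: nothing to unmix with < 2 sources")
        if len(self.sources) != k or len(self.panel) != j:
            raise ValueError("source/tracer dimensions inconsistent")
        if self.sd.shape != (k, j) or self.n.shape != (k, j):
            raise ValueError("moment array shapes inconsistent")
        if (self.sd < 0).any():
            raise ValueError("negative source SD")
        if self.alpha is None:
            self.alpha = np.ones(k)
        self.alpha = np.asarray(self.alpha, float)
        if self.alpha.shape != (k,) or (self.alpha <= 0).any():
            raise ValueError("alpha must be positive, one per source")
        if self.error_model not in {"residual_only", "process_only"}:
            raise ValueError(f"unknown error model {self.error_model!r}")
        if self.error_model == "process_only" and not (self.sd > 0).any():
            raise ValueError("process_only error needs nonzero source SDs")
        if self.conc is not None:
            self.conc = np.asarray(self.conc, float)
            if self.conc.shape != (k, j):
                raise ValueError("concentration array shape mismatch")
            if (self.conc <= 0).any():
                raise ValueError("concentrations must be strictly positive")
        if self.tau_fixed is not None:
            self.tau_fixed = np.broadcast_to(
                np.asarray(self.tau_fixed, float), (j,)
            ).copy()
            if (self.tau_fixed <= 0).any():
                raise ValueError("fixed tau must be strictly positive")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @classmethod
    def from_source_set(
        cls,
        source_set: SourceSet,
        config: RunConfig | None = None,
        panel: list[str] | None = None,
        levels: list[str] | None = None,
        conc_table: ConcentrationTable | None = None,
        node_id: str | None = None,
    ) -> "NodeModelSpec":
        config = config or RunConfig()
        panel = panel or source_set.panel
        names = source_set.group_names
        mom = {g: source_set.groups[g].moments().loc[panel] for g in names}
        mean = np.array([mom[g]["mean"].to_numpy() for g in names])
        sd = np.array([mom[g]["sd"].to_numpy() for g in names])
        narr = np.array([mom[g]["n"].to_numpy() for g in names])
        conc = None
        if config.concentration:
            if conc_table is None:
                raise ValueError("concentration on but no concentration table given")
            conc = conc_table.matrix(names, panel)
        return cls(
            node_id=node_id or source_set.node_id,
            sources=names,
            panel=list(panel),
            mean=mean,
            sd=sd,
            n=narr,
            levels=levels or [DEFAULT_LEVEL],
            alpha=config.alpha_for(names),
            error_model=config.error_model,
            conc=conc,
        )


@dataclass
class ConvergenceReport:
    rhat: pd.Series  # indexed by parameter name
    fraction_above: float
    passed: bool


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: (chains, draws, params) with named parameters.

    Parameter layout per draw: the proportion simplex of every factor level
    (level-major, source-minor) followed by the per-tracer residual scales.
    """

    node_id: str
    sources: list[str]
    levels: list[str]
    panel: list[str]
    draws: np.ndarray  # (C, T, P)
    tau_sampled: bool = True
    convergence: ConvergenceReport | None = None

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_per_chain(self) -> int:
        return self.draws.shape[1]

    @property
    def param_names(self) -> list[str]:
        names = [
            f"p[{lev}][{src}]" for lev in self.levels for src in self.sources
        ]
        names += [f"tau[{tr}]" for tr in self.panel]
        return names

    def monitored(self) -> tuple[np.ndarray, list[str]]:
        """Draw block for R-hat: all proportions, plus taus when sampled."""
        k, n_lev = len(self.sources), len(self.levels)
        stop = n_lev * k + (len(self.panel) if self.tau_sampled else 0)
        return self.draws[:, :, :stop], self.param_names[:stop]

    def p_draws(self, level: str | None = None) -> np.ndarray:
        """Pooled (chains concatenated) proportion draws, (C*T, K)."""
        level = level if level is not None else self.levels[0]
        l = self.levels.index(level)
        k = len(self.sources)
        block = self.draws[:, :, l * k : (l + 1) * k]
        return block.reshape(-1, k)

    def tau_draws(self) -> np.ndarray:
        start = len(self.levels) * len(self.sources)
        return self.draws[:, :, start:].reshape(-1, len(self.panel))

    def summary(self) -> pd.DataFrame:
        qs = [0.025, 0.25, 0.5, 0.75, 0.975]
        rows = []
        for lev in self.levels:
            p = self.p_draws(lev)
            for ki, src in enumerate(self.sources):
                d = p[:, ki]
                rows.append(
                    {
                        "node": self.node_id,
                        "level": lev,
                        "source": src,
                        "mean": d.mean(),
                        "sd": d.std(ddof=1),
                        **{f"q{100 * q:g}": np.quantile(d, q) for q in qs},
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def point_mass(
        cls,
        node_id: str,
        proportions: dict[str, dict[str, float]],
        n_draws: int = 200,
        n_chains: int = 2,
    ) -> "PosteriorDraws":
        """Degenerate posterior with every draw at the given means.

        ``proportions`` maps level -> {source -> proportion}; used for worked
        examples and for turning printed summary tables back into draw sets.
        """
        levels = list(proportions)
        sources = list(next(iter(proportions.values())))
        vec = []
        for lev in levels:
            p = np.array([proportions[lev][s] for s in sources], float)
            vec.append(p / p.sum())
        flat = np.concatenate(vec)
        draws = np.tile(flat, (n_chains, n_draws, 1))
        return cls(
            node_id=node_id,
            sources=sources,
            levels=levels,
            panel=[],
            draws=draws,
            tau_sampled=False,
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def source_param_draw(
    mean: np.ndarray,
    sd: np.ndarray,
    n: float | np.ndarray,
    rng: np.random.Generator,
    plug_in: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mu, sigma) from the sources-only posterior for one group.

    Per tracer: sigma^2 ~ scaled-inverse-chi-square(n-1, s^2), then
    mu | sigma^2 ~ Normal(xbar, sigma^2/n) — the standard posterior under the
    noninformative prior p(mu, sigma^2) proportional to 1/sigma^2. Plug-in
    mode returns the empirical (xbar, s) unchanged. Tracers with s = 0 are
    degenerate and returned as (xbar, 0) in either mode.
    """
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    n = np.broadcast_to(np.asarray(n, float), mean.shape)
    if (n < 2).any():
        raise ValueError("source posterior needs n >= 2 per tracer")
    if (sd < 0).any():
        raise ValueError("negative source SD")
    if plug_in:
        return mean.copy(), sd.copy()
    chi = rng.chisquare(n - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.where(sd > 0, (n - 1.0) * sd**2 / chi, 0.0)
    mu = mean + rng.standard_normal(mean.shape) * np.sqrt(sigma2 / n)
    return mu, np.sqrt(sigma2)


def apply_concentration(p: np.ndarray, conc: np.ndarray) -> np.ndarray:
    """Concentration-weight a proportion vector: p'_kj = p_k c_kj / sum_l p_l c_lj."""
    p = np.asarray(p, float)
    conc = np.atleast_2d(np.asarray(conc, float))
    if (conc <= 0).any():
        raise ValueError("concentrations must be strictly positive")
    num = p[:, None] * conc
    return num / num.sum(axis=0, keepdims=True)


def mixture_mean(p_prime: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Predicted mixture mean per tracer: m_j = sum_k p'_kj mu_kj."""
    return np.einsum("kj,kj->j", np.asarray(p_prime, float), np.asarray(mu, float))


def log_posterior(
    p_levels: np.ndarray,
    tau: np.ndarray,
    spec: NodeModelSpec,
    y: np.ndarray,
    level_idx: np.ndarray,
    mu: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
    tau_upper: np.ndarray | None = None,
) -> float:
    """Log posterior density in natural (p, tau) coordinates.

    Sum over samples and tracers of the Normal log-likelihood, plus the
    Dirichlet(alpha) log prior per level and the uniform tau prior. The
    sampler itself works in ILR/log coordinates and adds the corresponding
    Jacobians; this function is the plain-density reference used for grid
    integration and direct checks.
    """
    p_levels = np.atleast_2d(np.asarray(p_levels, float))
    tau = np.broadcast_to(np.asarray(tau, float), (len(spec.panel),))
    y = np.atleast_2d(np.asarray(y, float))
    if not np.isfinite(y).all():
        raise ValueError("non-finite mixture data")
    mu = spec.mean if mu is None else mu
    sigma = spec.sd if sigma is None else sigma
    if np.any(np.abs(p_levels.sum(axis=1) - 1.0) > 1e-8) or (p_levels < 0).any():
        return -np.inf
    lp = 0.0
    conc = spec.conc if spec.conc is not None else np.ones_like(mu)
    m = np.empty((p_levels.shape[0], len(spec.panel)))
    v = np.empty_like(m)
    for l, p in enumerate(p_levels):
        with np.errstate(divide="ignore"):
            lp += float(np.sum((spec.alpha - 1.0) * np.log(p)))
        pp = apply_concentration(p, conc)
        m[l] = mixture_mean(pp, mu)
        v[l] = np.sum(pp**2 * sigma**2, axis=0)
    if spec.error_model == "residual_only":
        if (tau <= 0).any():
            return -np.inf
        if tau_upper is not None:
            if (tau > tau_upper).any():
                return -np.inf
            lp += float(np.sum(-np.log(tau_upper)))
        var = np.broadcast_to(tau**2, m.shape)
    else:
        var = v
        if (var[np.unique(level_idx)] <= 0).any():
            return -np.inf
    resid = y - m[level_idx]
    lp += float(
        np.sum(-0.5 * (np.log(2 * np.pi * var[level_idx])) - resid**2 / (2 * var[level_idx]))
    )
    return lp


# ---------------------------------------------------------------------------
# sampling and diagnostics
# ---------------------------------------------------------------------------


def _chain_seed(master: int, chain: int) -> int:
    ss = np.random.SeedSequence([int(master) % (2**31 - 1), chain])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_mcmc(
    spec: NodeModelSpec,
    data: TracerTable | None,
    settings: McmcSettings,
) -> PosteriorDraws:
    """Sample the node posterior; returns retained draws with a convergence report.

    With ``data=None`` the likelihood is absent and the sampler targets the
    Dirichlet prior (a prior-recovery mode used for validation). A fit that
    fails the Gelman-Rubin gate is returned flagged, never silently accepted.
    """
    k, j = spec.mean.shape
    if data is not None:
        levels = data.levels
        missing = [t for t in spec.panel if t not in data.panel]
        if missing:
            raise ValueError(f"mixture table lacks tracer(s) {missing}")
        y = data.data[spec.panel].to_numpy(float)
        if not np.isfinite(y).all():
            raise ValueError("non-finite mixture data")
        lev_idx = np.array([levels.index(v) for v in data.factor], np.int64)
    else:
        levels = list(spec.levels)
        y = np.empty((0, j))
        lev_idx = np.empty(0, np.int64)
    n_lev = len(levels)

    conc = spec.conc if spec.conc is not None else np.ones((k, j))
    residual = spec.error_model == "residual_only"
    tau_sample = residual and spec.tau_fixed is None
    if spec.tau_fixed is not None:
        logtau_init = np.log(spec.tau_fixed)
        tau_upper = np.full(j, np.inf)
    else:
        emp = y.std(axis=0, ddof=1) if y.shape[0] >= 2 else np.array([])
        scale = np.ones(j)
        if y.shape[0] >= 2:
            scale = np.where(emp > 0, emp, np.maximum(np.abs(y).mean(axis=0), 1.0))
        tau_upper = 10.0 * scale
        logtau_init = np.log(scale)
    basis = _sampler.ilr_basis(k)

    per_chain = settings.n_retained_per_chain
    draws = np.empty((settings.n_chains, per_chain, n_lev * k + j))
    for c in range(settings.n_chains):
        draws[c] = _sampler.run_chain(
            y,
            lev_idx,
            n_lev,
            spec.mean,
            spec.sd,
            spec.n,
            spec.draw_sources,
            conc,
            spec.alpha,
            residual,
            tau_sample,
            logtau_init,
            tau_upper,
            basis,
            settings.chain_length,
            settings.burn,
            settings.thin,
            _chain_seed(settings.seed, c),
        )
    post = PosteriorDraws(
        node_id=spec.node_id,
        sources=list(spec.sources),
        levels=levels,
        panel=list(spec.panel),
        draws=draws,
        tau_sampled=tau_sample,
    )
    block, names = post.monitored()
    rhat = gelman_rubin(block)
    passed, frac = check_convergence(rhat)
    post.convergence = ConvergenceReport(
        rhat=pd.Series(rhat, index=names), fraction_above=frac, passed=passed
    )
    return post


def gelman_rubin(draws_by_chain: np.ndarray) -> np.ndarray:
    """Classical potential scale reduction factor, per parameter.

    ``draws_by_chain`` is (chains, draws, params). R-hat =
    sqrt(((n-1)/n * W + B/n) / W) with B/n the variance of chain means and W
    the mean within-chain variance. Chains that agree exactly (B = 0) give
    the formula's floor sqrt((n-1)/n) <= 1.
    """
    x = np.asarray(draws_by_chain, float)
    if x.ndim == 2:
        x = x[:, :, None]
    c, n, _ = x.shape
    if c < 2:
        raise ValueError("Gelman-Rubin needs >= 2 chains")
    if n < 2:
        raise ValueError("Gelman-Rubin needs >= 2 draws per chain")
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    out = np.empty(x.shape[2])
    for i in range(x.shape[2]):
        if b_over_n[i] == 0.0:
            out[i] = np.sqrt((n - 1) / n)
        elif w[i] == 0.0:
            out[i] = np.inf
        else:
            out[i] = np.sqrt(var_plus[i] / w[i])
    return out


def check_convergence(
    rhat: np.ndarray,
    threshold: float = RHAT_THRESHOLD,
    max_fraction: float = RHAT_MAX_FRACTION,
) -> tuple[bool, float]:
    """Gate a fit on its R-hat values: fail iff the fraction above the
    threshold strictly exceeds ``max_fraction``. Returns (passed, fraction)."""
    rhat = np.asarray(rhat, float)
    if rhat.size == 0:
        raise ValueError("no monitored variables")
    frac = float(np.mean(rhat > threshold))
    return frac <= max_fraction, frac
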