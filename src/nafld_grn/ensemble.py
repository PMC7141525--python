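"""Random-circuit-perturbation ensembles.

For a given topology, kinetic parameters are sampled from broad,
biologically motivated ranges; each sampled model is integrated from many
random initial conditions and its distinct stable steady states are
collected.  The ensemble of models stands in for a heterogeneous cell
population sharing one regulatory wiring.

Sampling conventions (defaults of :class:`SamplingRanges`):

* production uniform on (1, 100) [1e6 molecules/hr]
* degradation uniform on (0.1, 1) [1/hr]
* fold change uniform on (1, 100) for activators; the reciprocal for
  inhibitors
* cooperativity integer-uniform on {1..6}
* thresholds by the half-functional rule: uniform on
  (0.02, 1.98) x median unregulated level, so that a regulator has roughly
  even odds of sitting above or below its threshold across the ensemble.

Each model draws its parameters and initial conditions from its own
counter-derived substream of the master seed, so ensembles are reproducible
and models are independent of ensemble size ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from nafld_grn import _kernels
from nafld_grn.network import (
    ACTIVATION,
    KineticModel,
    RegulatoryNetwork,
    ShiftedHillParams,
)

__all__ = [
    "SamplingRanges",
    "IntegrationSettings",
    "SteadyStateSet",
    "EnsembleResult",
    "median_unregulated",
    "sample_model",
    "find_steady_states",
    "run_ensemble",
]

FLAG_OK = ""
FLAG_NO_CONVERGENCE = "no_convergence"
FLAG_EXCEEDS_CAP = "exceeds_cap"


@dataclass(frozen=True)
class SamplingRanges:
    """Bounds and laws for random kinetic-parameter sampling."""

    production: tuple[float, float] = (1.0, 100.0)
    degradation: tuple[float, float] = (0.1, 1.0)
    fold_change: tuple[float, float] = (1.0, 100.0)
    cooperativity: tuple[int, int] = (1, 6)
    threshold_factor: tuple[float, float] = (0.02, 1.98)

    def __post_init__(self) -> None:
        for name in ("production", "degradation", "fold_change", "threshold_factor"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} bounds must satisfy lower < upper")
        lo, hi = self.cooperativity
        if int(lo) != lo or int(hi) != hi or not 1 <= lo <= hi:
            raise ValueError("cooperativity bounds must be integers with 1 <= lo <= hi")


def median_unregulated(ranges: SamplingRanges) -> float:
    """Median of the unregulated steady-state level g/k under the ranges.

    Base anchor of the half-functional threshold rule.
    """
    glo, ghi = ranges.production
    klo, khi = ranges.degradation

    def cdf(m: float) -> float:
        def inner(k: float) -> float:
            return min(max((m * k - glo) / (ghi - glo), 0.0), 1.0)

        val, _ = quad(inner, klo, khi, limit=200)
        return val / (khi - klo)

    return brentq(lambda m: cdf(m) - 0.5, glo / khi, ghi / klo, xtol=1e-10)


def half_functional_medians(
    network: RegulatoryNetwork,
    ranges: SamplingRanges,
    n_mc: int = 200_000,
    n_iter: int = 5,
    mc_seed: int = 2_718_281,
) -> dict[str, float]:
    """Per-gene median expression level under randomization, for thresholds.

    The half-functional rule requires each regulator to have roughly even
    odds of sitting above the threshold of the links it drives, so the
    threshold range for an edge is centered on the *regulated* median level
    of its source gene.  The medians are estimated by a self-consistent
    Monte Carlo: starting from unregulated g/k level samples, each gene's
    level distribution is repeatedly rebuilt as g/k times shifted-Hill
    factors whose regulator levels are drawn from the previous round's
    distributions and whose thresholds are centered on the previous
    medians.  The iteration settles within a few rounds.  The estimate is
    deterministic (fixed internal seed) so that a topology always maps to
    the same sampling distribution.
    """
    rng = np.random.default_rng(mc_seed)
    flo, fhi = ranges.threshold_factor
    levels = {
        n: rng.uniform(*ranges.production, n_mc)
        / rng.uniform(*ranges.degradation, n_mc)
        for n in network.nodes
    }
    for _ in range(n_iter):
        med = {n: float(np.median(levels[n])) for n in network.nodes}
        nxt = {}
        for node in network.nodes:
            gk = rng.uniform(*ranges.production, n_mc) / rng.uniform(
                *ranges.degradation, n_mc
            )
            prod = np.ones(n_mc)
            for e in network.incoming(node):
                u = rng.uniform(*ranges.fold_change, n_mc)
                lam = u if e.sign == ACTIVATION else 1.0 / u
                nn = rng.integers(
                    ranges.cooperativity[0], ranges.cooperativity[1] + 1, n_mc
                )
                b0 = rng.uniform(flo * med[e.source], fhi * med[e.source], n_mc)
                x = rng.permutation(levels[e.source])
                hm = 1.0 / (1.0 + (x / b0) ** nn)
                prod *= hm + lam * (1.0 - hm)
            nxt[node] = gk * prod
        levels = nxt
    return {n: float(np.median(levels[n])) for n in network.nodes}


@dataclass(frozen=True)
class IntegrationSettings:
    """Numerical settings for steady-state finding.

    Euler with a fixed step (chosen against the fastest sampled degradation
    rate) is the default; ``method='rk45'`` switches to adaptive Cash-Karp
    with the same probe-window convergence test.  A trajectory counts as
    converged when the relative change of every node over a probe window is
    below ``conv_tol``; non-converged runs are discarded.  Converged
    endpoints closer than ``merge_rtol`` (relative, log2 space, with an
    absolute floor ``merge_floor``) are merged to their centroid.
    """

    method: str = "euler"
    dt: float = 0.2
    t_max: float = 500.0
    check_every: int = 25
    conv_tol: float = 1e-5
    merge_rtol: float = 0.01
    merge_floor: float = 0.01
    max_states: int = 4
    max_keep: int = 32
    rk_rtol: float = 1e-8
    rk_atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.method not in ("euler", "rk45"):
            raise ValueError(f"unknown integration method {self.method!r}")

    @classmethod
    def fast(cls) -> "IntegrationSettings":
        """Coarser step for large variant screens (state counts agree with
        the default settings on all but ~0.3% of sampled models)."""
        return cls(dt=0.5, t_max=500.0, check_every=10, conv_tol=1e-5)


@dataclass(frozen=True)
class SteadyStateSet:
    """Distinct stable states of one model (levels stored in log2 scale)."""

    model_id: int
    states: np.ndarray  # (n_states_kept, N) log2 levels, by basin size desc
    basin_counts: np.ndarray  # initial conditions converged to each state
    n_converged: int
    uncapped_count: int
    flag: str = FLAG_OK

    @property
    def count(self) -> int:
        return self.states.shape[0]


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Per-model substream keys derived from the master seed by counter."""
    return np.random.SeedSequence(seed).generate_state(2 * n, dtype=np.uint64).reshape(n, 2)


def _edge_medians(network: RegulatoryNetwork, ranges: SamplingRanges) -> np.ndarray:
    """Per-edge source-gene medians anchoring the threshold ranges."""
    med = half_functional_medians(network, ranges)
    return np.array([med[e.source] for e in network.edges])


def _draw_params(
    network: RegulatoryNetwork,
    ranges: SamplingRanges,
    rng: np.random.Generator,
    edge_med: np.ndarray,
):
    N, E = network.n_nodes, network.n_edges
    g = rng.uniform(*ranges.production, N)
    k = rng.uniform(*ranges.degradation, N)
    u = rng.uniform(*ranges.fold_change, E)
    act = np.array([e.sign == ACTIVATION for e in network.edges])
    lam = np.where(act, u, 1.0 / u)
    nn = rng.integers(ranges.cooperativity[0], ranges.cooperativity[1] + 1, E)
    b0 = rng.uniform(
        ranges.threshold_factor[0] * edge_med, ranges.threshold_factor[1] * edge_med, E
    )
    return g, k, lam, nn.astype(np.int64), b0


def _draw_inits(
    network: RegulatoryNetwork, g, k, lam, rng: np.random.Generator, n_init: int
) -> np.ndarray:
    """Initial conditions log2-uniform over each node's attainable level range.

    Every fixed point satisfies ``X_i = (g_i / k_i) * prod_e H_e`` with each
    factor in [min(1, lam_e), max(1, lam_e)], so sampling between those
    extremes covers all attainable steady states.
    """
    _, tgt = network.edge_arrays()
    lo = g / k
    hi = g / k
    lo_f = np.minimum(1.0, lam)
    hi_f = np.maximum(1.0, lam)
    for e in range(network.n_edges):
        lo = lo.copy()
        hi = hi.copy()
        lo[tgt[e]] *= lo_f[e]
        hi[tgt[e]] *= hi_f[e]
    u = rng.uniform(np.log2(lo), np.log2(hi), size=(n_init, network.n_nodes))
    return 2.0 ** u


def sample_model(
    network: RegulatoryNetwork,
    ranges: SamplingRanges,
    rng: np.random.Generator,
    edge_med: np.ndarray | None = None,
) -> KineticModel:
    """Draw one random kinetic model for ``network`` from ``ranges``."""
    if edge_med is None:
        edge_med = _edge_medians(network, ranges)
    g, k, lam, nn, b0 = _draw_params(network, ranges, rng, edge_med)
    production = dict(zip(network.nodes, g))
    degradation = dict(zip(network.nodes, k))
    edge_params = {
        (e.source, e.target): ShiftedHillParams(b0[i], int(nn[i]), lam[i])
        for i, e in enumerate(network.edges)
    }
    return KineticModel(production, degradation, edge_params)


@dataclass
class EnsembleResult:
    """Steady-state sets over an ensemble of sampled models."""

    network: RegulatoryNetwork
    ranges: SamplingRanges
    settings: IntegrationSettings
    seed: int
    n_init: int
    # packed per-model parameters (node order / edge order of the network)
    G: np.ndarray
    K: np.ndarray
    LAM: np.ndarray
    NN: np.ndarray
    B0: np.ndarray
    # per-model outcomes
    counts: np.ndarray  # uncapped distinct-state counts
    n_converged: np.ndarray
    states: np.ndarray  # (n_models, max_keep, N) log2 levels
    basins: np.ndarray  # (n_models, max_keep)

    @property
    def n_models(self) -> int:
        return self.G.shape[0]

    @property
    def flags(self) -> np.ndarray:
        out = np.full(self.n_models, FLAG_OK, dtype=object)
        out[self.counts > self.settings.max_states] = FLAG_EXCEEDS_CAP
        out[self.n_converged == 0] = FLAG_NO_CONVERGENCE
        return out

    @property
    def retained(self) -> np.ndarray:
        """Models kept after capping: converged and within the state cap."""
        return (self.n_converged > 0) & (self.counts <= self.settings.max_states)

    def fraction_exceeding_cap(self) -> float:
        ok = self.n_converged > 0
        return float(np.mean(self.counts[ok] > self.settings.max_states))

    def state_set(self, i: int) -> SteadyStateSet:
        kept = min(self.counts[i], self.settings.max_keep)
        order = np.argsort(-self.basins[i, :kept], kind="stable")
        flag = self.flags[i]
        return SteadyStateSet(
            model_id=i,
            states=self.states[i, order],
            basin_counts=self.basins[i, order].astype(int),
            n_converged=int(self.n_converged[i]),
            uncapped_count=int(self.counts[i]),
            flag=str(flag),
        )

    def model_at(self, i: int) -> KineticModel:
        production = dict(zip(self.network.nodes, self.G[i]))
        degradation = dict(zip(self.network.nodes, self.K[i]))
        edge_params = {
            (e.source, e.target): ShiftedHillParams(
                self.B0[i, j], int(self.NN[i, j]), self.LAM[i, j]
            )
            for j, e in enumerate(self.network.edges)
        }
        return KineticModel(production, degradation, edge_params)

    def pooled_states(self) -> tuple[np.ndarray, np.ndarray]:
        """All states of retained models: (levels log2 (n, N), model index)."""
        levels, owner = [], []
        for i in np.flatnonzero(self.retained):
            c = int(self.counts[i])
            levels.append(self.states[i, :c])
            owner.append(np.full(c, i))
        if not levels:
            return np.empty((0, self.network.n_nodes)), np.empty(0, dtype=int)
        return np.vstack(levels), np.concatenate(owner)

    def stability_class_counts(self) -> pd.Series:
        """Retained-model tally by state count (1=mono, 2=bi, ...)."""
        c = self.counts[self.retained]
        return pd.Series(c).value_counts().sort_index()

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Wide per-(model, state) table; lossless round-trip."""
        net = self.network
        rows = []
        for i in range(self.n_models):
            base = {"model_id": i, "n_states": int(self.counts[i]),
                    "n_converged": int(self.n_converged[i])}
            for j, n in enumerate(net.nodes):
                base[f"g_{n}"] = self.G[i, j]
                base[f"k_{n}"] = self.K[i, j]
            for j, e in enumerate(net.edges):
                key = f"{e.source}.{e.target}"
                base[f"lam_{key}"] = self.LAM[i, j]
                base[f"n_{key}"] = int(self.NN[i, j])
                base[f"b0_{key}"] = self.B0[i, j]
            kept = min(int(self.counts[i]), self.settings.max_keep)
            if kept == 0:
                rows.append({**base, "state_index": -1, "basin_count": 0})
            for s in range(kept):
                row = {**base, "state_index": s, "basin_count": int(self.basins[i, s])}
                for j, n in enumerate(net.nodes):
                    row[f"l2_{n}"] = self.states[i, s, j]
                rows.append(row)
        df = pd.DataFrame(rows)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        network: RegulatoryNetwork,
        ranges: SamplingRanges | None = None,
        settings: IntegrationSettings | None = None,
        seed: int = -1,
        n_init: int = -1,
    ) -> "EnsembleResult":
        ranges = ranges or SamplingRanges()
        settings = settings or IntegrationSettings()
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        nm = int(df["model_id"].max()) + 1
        N, E = network.n_nodes, network.n_edges
        G = np.zeros((nm, N))
        K = np.zeros((nm, N))
        LAM = np.zeros((nm, E))
        NN = np.zeros((nm, E), dtype=np.int64)
        B0 = np.zeros((nm, E))
        counts = np.zeros(nm, dtype=np.int64)
        nconv = np.zeros(nm, dtype=np.int64)
        states = np.zeros((nm, settings.max_keep, N))
        basins = np.zeros((nm, settings.max_keep))
        first = ~df["model_id"].duplicated()
        sub = df[first]
        for j, n in enumerate(network.nodes):
            G[sub["model_id"], j] = sub[f"g_{n}"]
            K[sub["model_id"], j] = sub[f"k_{n}"]
        for j, e in enumerate(network.edges):
            key = f"{e.source}.{e.target}"
            LAM[sub["model_id"], j] = sub[f"lam_{key}"]
            NN[sub["model_id"], j] = sub[f"n_{key}"]
            B0[sub["model_id"], j] = sub[f"b0_{key}"]
        counts[sub["model_id"]] = sub["n_states"]
        nconv[sub["model_id"]] = sub["n_converged"]
        valid = df["state_index"] >= 0
        dv = df[valid]
        mi = dv["model_id"].to_numpy()
        si = dv["state_index"].to_numpy()
        basins[mi, si] = dv["basin_count"]
        for j, n in enumerate(network.nodes):
            states[mi, si, j] = dv[f"l2_{n}"]
        return cls(network, ranges, settings, seed, n_init,
                   G, K, LAM, NN, B0, counts, nconv, states, basins)


def _integrate_batch(network, G, K, LAM, NN, B0, X0, settings):
    src, tgt = network.edge_arrays()
    return _kernels.integrate_ensemble(
        G, K, LAM, NN, B0, src, tgt, X0,
        settings.dt, settings.t_max, settings.check_every, settings.conv_tol,
        settings.merge_rtol, settings.merge_floor, settings.max_keep,
        settings.method == "rk45", settings.rk_rtol, settings.rk_atol,
    )


def find_steady_states(
    network: RegulatoryNetwork,
    model: KineticModel,
    n_init: int = 100,
    seed: int = 0,
    settings: IntegrationSettings | None = None,
) -> SteadyStateSet:
    """Stable steady states of one model from ``n_init`` random starts."""
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    settings = settings or IntegrationSettings()
    model.validate_against(network)
    g, k, lam, nn, b0 = model.arrays(network)
    rng = np.random.default_rng(seed)
    X0 = _draw_inits(network, g, k, lam, rng, n_init)[None]
    counts, nconv, states, basins = _integrate_batch(
        network, g[None], k[None], lam[None], nn[None], b0[None], X0, settings
    )
    res = EnsembleResult(
        network, SamplingRanges(), settings, seed, n_init,
        g[None], k[None], lam[None], nn[None], b0[None],
        counts, nconv, states, basins,
    )
    return res.state_set(0)


def run_ensemble(
    network: RegulatoryNetwork,
    ranges: SamplingRanges | None = None,
    n_models: int = 10000,
    n_init: int = 100,
    seed: int = 0,
    settings: IntegrationSettings | None = None,
    chunk: int = 500,
) -> EnsembleResult:
    """Sample ``n_models`` kinetic models and find each one's stable states."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    ranges = ranges or SamplingRanges()
    settings = settings or IntegrationSettings()
    N, E = network.n_nodes, network.n_edges
    edge_med = _edge_medians(network, ranges)
    keys = _spawn_seeds(seed, n_models)

    G = np.empty((n_models, N))
    K = np.empty((n_models, N))
    LAM = np.empty((n_models, E))
    NN = np.empty((n_models, E), dtype=np.int64)
    B0 = np.empty((n_models, E))
    counts = np.empty(n_models, dtype=np.int64)
    nconv = np.empty(n_models, dtype=np.int64)
    states = np.empty((n_models, settings.max_keep, N))
    basins = np.empty((n_models, settings.max_keep))

    for lo in range(0, n_models, chunk):
        hi = min(lo + chunk, n_models)
        X0 = np.empty((hi - lo, n_init, N))
        for m in range(lo, hi):
            rng = np.random.Generator(np.random.PCG64(keys[m]))
            G[m], K[m], LAM[m], NN[m], B0[m] = _draw_params(network, ranges, rng, edge_med)
            X0[m - lo] = _draw_inits(network, G[m], K[m], LAM[m], rng, n_init)
        c, nc, st, ba = _integrate_batch(
            network, G[lo:hi], K[lo:hi], LAM[lo:hi], NN[lo:hi], B0[lo:hi], X0, settings
        )
        counts[lo:hi] = c
        nconv[lo:hi] = nc
        states[lo:hi] = st
        basins[lo:hi] = ba

    return EnsembleResult(
        network, ranges, settings, seed, n_init,
        G, K, LAM, NN, B0, counts, nconv, states, basins,
    )
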