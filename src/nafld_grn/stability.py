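"""Relative stability, bifurcation analysis and stochastic switching.

Three views of how robust each co-existing phenotype is:

* *relative stability* — within a multistable phase, the fraction of random
  initial conditions that converge to each member state;
* *bifurcation scan* — equilibria and their linear stability as the PPARG
  degradation rate (the parameter perturbed by Hsp90 upregulation in fatty
  liver) is swept, revealing the saddle-node folds that bound the
  hepatocyte/hybrid bistable window, with hysteresis under slow sweeps;
* *stochastic switching* — Euler-Maruyama integration of the kinetic model
  with additive Gaussian noise, reporting noise-driven transitions between
  attractors and residence times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from nafld_grn import _kernels
from nafld_grn.ensemble import (
    EnsembleResult,
    IntegrationSettings,
    _draw_inits,
)
from nafld_grn.network import (
    KineticModel,
    RegulatoryNetwork,
    build_jacobian,
    build_rhs,
)

__all__ = [
    "RelativeStability",
    "BifurcationBranch",
    "NoiseSpec",
    "Trajectory",
    "find_equilibria",
    "relative_stability",
    "bifurcation_scan",
    "hysteresis_sweep",
    "stochastic_simulate",
]


# ---------------------------------------------------------------------------
# Equilibria by multi-start root finding (the integration-free oracle)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Equilibrium:
    levels: np.ndarray
    stable: bool
    max_real_eigenvalue: float


def find_equilibria(
    network: RegulatoryNetwork,
    model: KineticModel,
    n_starts: int = 200,
    seed: int = 0,
    tol: float = 1e-9,
    merge_tol: float = 1e-6,
) -> list[Equilibrium]:
    """All equilibria of the assembled ODE system by multi-start Newton.

    Starts are log-uniform over each node's attainable level range plus the
    unregulated corners.  Residuals are judged relative to each node's rate
    scale (production + turnover), so the acceptance test is invariant to
    the wide spread of sampled rate magnitudes.  Stability comes from the
    eigenvalues of the analytic Jacobian (all real parts negative).  Roots
    closer than ``merge_tol`` (relative, log space) are deduplicated.
    """
    f = build_rhs(network, model)
    jac = build_jacobian(network, model)
    g, k, lam, _, _ = model.arrays(network)
    rng = np.random.default_rng(seed)
    starts = list(_draw_inits(network, g, k, lam, rng, n_starts))
    src, tgt = network.edge_arrays()
    lo = g / k
    hi = g / k
    for e in range(network.n_edges):
        lo[tgt[e]] *= min(1.0, lam[e])
        hi[tgt[e]] *= max(1.0, lam[e])
    starts += [lo, hi, g / k]
    found: list[np.ndarray] = []
    for x0 in starts:
        sol = root(f, x0, jac=jac, method="hybr")
        x = sol.x
        if not sol.success or np.any(x <= 0):
            continue
        if np.max(np.abs(f(x)) / (g + k * np.abs(x))) > tol:
            continue
        if any(
            np.all(np.abs(np.log(x) - np.log(y)) < merge_tol + merge_tol * np.abs(np.log(y)))
            for y in found
        ):
            continue
        found.append(x)
    out = []
    for x in found:
        ev = np.linalg.eigvals(jac(x))
        mre = float(np.max(ev.real))
        out.append(Equilibrium(x, mre < 0, mre))
    return sorted(out, key=lambda e: tuple(e.levels))


# ---------------------------------------------------------------------------
# Relative stability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelativeStability:
    """Convergence fractions to each member state of one phase."""

    phase: tuple[str, ...]
    model_ids: np.ndarray
    fractions: pd.DataFrame  # rows = models, columns = member labels

    def mean_fractions(self) -> pd.Series:
        return self.fractions.mean(axis=0)


def relative_stability(
    ensemble: EnsembleResult,
    phase_composition,
    phase: Sequence[str],
    n_init: int = 1000,
    seed: int = 0,
    max_models: int | None = None,
) -> RelativeStability:
    """Fraction of random initial conditions converging to each phase member.

    Models are those of the ensemble whose phase (over the phase gene pair)
    equals ``phase``; each is re-simulated from ``n_init`` fresh
    log2-uniform initial conditions, endpoints are matched to the model's
    known states by nearest log2 distance, and per-state fractions over the
    converged runs are returned (they sum to 1 per model).  Models whose
    recorded states do not carry distinct member labels are excluded.
    """
    phase = tuple(sorted(phase))
    ids = phase_composition.models_with_phase(phase)
    if max_models is not None and ids.size > max_models:
        ids = np.random.default_rng(seed).choice(ids, size=max_models, replace=False)
    settings = ensemble.settings
    src, tgt = ensemble.network.edge_arrays()
    rng = np.random.default_rng(seed)
    rows = []
    kept_ids = []
    pair_labels_of = {}
    for mid, lbl in zip(phase_composition.model_ids, phase_composition.pair_labels):
        pair_labels_of.setdefault(int(mid), []).append(lbl)
    for mid in ids:
        labels = pair_labels_of[int(mid)]
        if len(set(labels)) != len(labels):
            continue  # degenerate labeling; cannot attribute basins uniquely
        c = int(ensemble.counts[mid])
        known = ensemble.states[mid, :c]  # log2
        X0 = _draw_inits(
            ensemble.network,
            ensemble.G[mid],
            ensemble.K[mid],
            ensemble.LAM[mid],
            rng,
            n_init,
        )[None]
        counts, nconv, states, basins = _kernels.integrate_ensemble(
            ensemble.G[mid][None], ensemble.K[mid][None], ensemble.LAM[mid][None],
            ensemble.NN[mid][None], ensemble.B0[mid][None], src, tgt, X0,
            settings.dt, settings.t_max, settings.check_every, settings.conv_tol,
            settings.merge_rtol, settings.merge_floor, settings.max_keep,
            settings.method == "rk45", settings.rk_rtol, settings.rk_atol,
        )
        if nconv[0] == 0:
            continue
        per_state = np.zeros(c)
        kept = min(int(counts[0]), settings.max_keep)
        for s in range(kept):
            d = np.linalg.norm(states[0, s] - known, axis=1)
            per_state[np.argmin(d)] += basins[0, s]
        rows.append(per_state / per_state.sum())
        kept_ids.append(int(mid))
    if not rows:
        raise ValueError(f"no usable models exhibit phase {phase}")
    # order columns by the member labels
    frac = pd.DataFrame(
        [
            {lbl: r[j] for j, lbl in enumerate(pair_labels_of[mid][: len(r)])}
            for mid, r in zip(kept_ids, rows)
        ],
        index=kept_ids,
    )[list(phase)]
    return RelativeStability(phase, np.array(kept_ids), frac)


# ---------------------------------------------------------------------------
# Bifurcation scan over the PPARG degradation rate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BifurcationBranch:
    """Equilibria along the swept parameter, stitched into branches."""

    parameter: str
    table: pd.DataFrame  # columns: value, branch, stable, max_re, <node levels>

    def stable_count(self, value: float) -> int:
        sub = self.table[np.isclose(self.table["value"], value)]
        return int(sub["stable"].sum())

    def fold_intervals(self) -> list[tuple[float, float]]:
        """Parameter intervals bracketing a change in equilibrium count."""
        vals = np.sort(self.table["value"].unique())
        counts = [len(self.table[self.table["value"] == v]) for v in vals]
        out = []
        for i in range(len(vals) - 1):
            if counts[i] != counts[i + 1]:
                out.append((float(vals[i]), float(vals[i + 1])))
        return out


def bifurcation_scan(
    network: RegulatoryNetwork,
    model: KineticModel,
    sweep: np.ndarray,
    node: str = "PPARG",
    n_starts: int = 200,
    seed: int = 0,
    refine_folds: bool = True,
    refine_tol: float = 1e-4,
) -> BifurcationBranch:
    """Equilibria vs the degradation rate of ``node`` (default PPARG).

    At each grid value all equilibria are located by multi-start Newton and
    classified by Jacobian eigenvalues; branches are stitched between
    neighboring grid points by nearest log-distance continuation.  Fold
    (saddle-node) points, where the equilibrium count changes, are refined
    by bisection when ``refine_folds`` is set.
    """
    sweep = np.asarray(sweep, dtype=float)
    if np.any(sweep <= 0):
        raise ValueError("swept degradation rates must be positive")

    def equilibria_at(kv: float):
        return find_equilibria(
            network, model.with_rate(node, degradation=kv), n_starts=n_starts, seed=seed
        )

    rows = []
    prev: list[tuple[int, np.ndarray]] = []
    next_branch = 0
    grid = list(sweep)
    extra: list[float] = []
    if refine_folds:
        counts = {}
        for v in grid:
            counts[v] = len(equilibria_at(v))
        for a, b in zip(grid[:-1], grid[1:]):
            if counts[a] != counts[b]:
                lo, hi = a, b
                clo = counts[a]
                while hi - lo > refine_tol:
                    mid = 0.5 * (lo + hi)
                    if len(equilibria_at(mid)) == clo:
                        lo = mid
                    else:
                        hi = mid
                extra += [lo, hi]
    for v in sorted(set(grid + extra)):
        eqs = equilibria_at(v)
        assigned = []
        used = set()
        for eq in eqs:
            lx = np.log(eq.levels)
            best, bestd = None, np.inf
            for bid, ly in prev:
                if bid in used:
                    continue
                d = np.linalg.norm(lx - ly)
                if d < bestd:
                    best, bestd = bid, d
            if best is None:
                best = next_branch
                next_branch += 1
            used.add(best)
            assigned.append((best, eq))
        prev = [(bid, np.log(eq.levels)) for bid, eq in assigned]
        for bid, eq in assigned:
            row = {
                "value": v,
                "branch": bid,
                "stable": eq.stable,
                "max_re": eq.max_real_eigenvalue,
            }
            row.update({n: lv for n, lv in zip(network.nodes, eq.levels)})
            rows.append(row)
    return BifurcationBranch(f"degradation[{node}]", pd.DataFrame(rows))


def hysteresis_sweep(
    network: RegulatoryNetwork,
    model: KineticModel,
    sweep: np.ndarray,
    node: str = "PPARG",
    settings: IntegrationSettings | None = None,
) -> pd.DataFrame:
    """Quasi-static up- then down-sweep of the degradation rate of ``node``.

    The system is relaxed to steady state at each grid value starting from
    the previous endpoint; inside a bistable window the two sweep
    directions settle on different branches.
    """
    settings = settings or IntegrationSettings()
    sweep = np.asarray(sweep, dtype=float)
    rows = []
    for direction, grid in (("up", sweep), ("down", sweep[::-1])):
        m = model.with_rate(node, degradation=float(grid[0]))
        eqs = [e for e in find_equilibria(network, m) if e.stable]
        x = eqs[0].levels.copy()
        for v in grid:
            m = model.with_rate(node, degradation=float(v))
            x = _relax(network, m, x, settings)
            row = {"direction": direction, "value": float(v)}
            row.update({n: lv for n, lv in zip(network.nodes, x)})
            rows.append(row)
    return pd.DataFrame(rows)


def _relax(network, model, x0, settings: IntegrationSettings) -> np.ndarray:
    g, k, lam, nn, b0 = model.arrays(network)
    src, tgt = network.edge_arrays()
    n_steps = int(settings.t_max / settings.dt)
    xi = np.zeros((n_steps, network.n_nodes))
    traj = _kernels.em_trajectory(
        g, k, lam, nn, b0, src, tgt, np.asarray(x0, float), settings.dt,
        n_steps, np.zeros(network.n_nodes), xi, n_steps,
    )
    return traj[-1]


# ---------------------------------------------------------------------------
# Stochastic switching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Per-node additive noise amplitudes.

    The default mimics intrinsic fluctuations (0.1 on HNF4A, HNF1A and
    SREBF1) plus the extra extrinsic load of fatty-acid burden on PPARG
    (amplitude 15).
    """

    amplitudes: dict[str, float] = field(
        default_factory=lambda: {"HNF4A": 0.1, "HNF1A": 0.1, "PPARG": 15.0, "SREBF1": 0.1}
    )

    def __post_init__(self) -> None:
        for n, a in self.amplitudes.items():
            if a < 0:
                raise ValueError(f"noise amplitude of {n} must be >= 0")

    def array(self, nodes: Sequence[str]) -> np.ndarray:
        return np.array([self.amplitudes[n] for n in nodes])


@dataclass
class Trajectory:
    """Time series of node levels plus attractor occupancy."""

    nodes: tuple[str, ...]
    time: np.ndarray  # hours, strictly increasing
    levels: np.ndarray  # (n_samples, N), clipped nonnegative
    attractors: np.ndarray | None = None  # (n_attr, N) levels
    attractor_labels: tuple[str, ...] | None = None
    occupancy: np.ndarray | None = None  # per-sample attractor index

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels, columns=list(self.nodes))
        df.insert(0, "time", self.time)
        if self.occupancy is not None:
            df["state"] = [
                self.attractor_labels[i] if i >= 0 else ""
                for i in self.occupancy
            ]
        return df

    def switch_events(self) -> pd.DataFrame:
        """Transitions between attractors (after the dwell filter)."""
        if self.occupancy is None:
            raise ValueError("occupancy not assigned")
        occ = self.occupancy
        rows = []
        prev = occ[0]
        t_enter = self.time[0]
        for i in range(1, occ.size):
            if occ[i] != prev:
                rows.append(
                    {
                        "time": float(self.time[i]),
                        "from": self.attractor_labels[prev],
                        "to": self.attractor_labels[occ[i]],
                        "residence": float(self.time[i] - t_enter),
                    }
                )
                prev = occ[i]
                t_enter = self.time[i]
        return pd.DataFrame(rows)

    def residence_times(self) -> pd.Series:
        """Total simulated time spent in each attractor."""
        if self.occupancy is None:
            raise ValueError("occupancy not assigned")
        dt = np.diff(self.time, append=self.time[-1])
        out = {}
        for i, lbl in enumerate(self.attractor_labels):
            out[lbl] = float(dt[self.occupancy == i].sum())
        return pd.Series(out)


def _assign_occupancy(
    levels: np.ndarray, attractors: np.ndarray, dwell: int
) -> np.ndarray:
    """Nearest-attractor call in log space with a dwell debounce filter.

    A switch is accepted only after ``dwell`` consecutive samples nearest to
    the new attractor; shorter excursions are treated as noise flickers.
    """
    la = np.log2(np.maximum(attractors, 1e-12))
    lx = np.log2(np.maximum(levels, 1e-12))
    d = np.linalg.norm(lx[:, None, :] - la[None, :, :], axis=2)
    raw = np.argmin(d, axis=1)
    occ = np.empty_like(raw)
    current = raw[0]
    run = 0
    cand = current
    for i, r in enumerate(raw):
        if r == current:
            run = 0
            cand = current
        elif r == cand:
            run += 1
            if run >= dwell:
                current = cand
                run = 0
        else:
            cand = r
            run = 1
        occ[i] = current
    return occ


def stochastic_simulate(
    network: RegulatoryNetwork,
    model: KineticModel,
    noise: NoiseSpec | None = None,
    duration: float = 20000.0,
    dt: float = 0.01,
    seed: int = 0,
    save_every: int = 100,
    dwell: int = 5,
    attractors: np.ndarray | None = None,
    attractor_labels: Sequence[str] | None = None,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Euler-Maruyama simulation ``X += f(X) dt + amplitude * xi * sqrt(dt)``.

    Levels are clipped at zero after each step.  When deterministic
    attractors are supplied (or computable via :func:`find_equilibria`),
    each saved sample is assigned to the nearest attractor in log space
    with a ``dwell``-sample debounce, from which switch events and
    residence times derive.
    """
    noise = noise or NoiseSpec()
    model.validate_against(network)
    g, k, lam, nn, b0 = model.arrays(network)
    src, tgt = network.edge_arrays()
    amps = noise.array(network.nodes)
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    if attractors is None:
        eqs = [e for e in find_equilibria(network, model) if e.stable]
        attractors = np.array([e.levels for e in eqs])
    attractors = np.asarray(attractors, dtype=float)
    if x0 is None:
        x0 = attractors[0].copy()
    x0 = np.asarray(x0, dtype=float)
    # chunked noise generation keeps memory bounded on long runs
    chunk_steps = min(n_steps, 2_000_000)
    levels = [x0[None, :]]
    x = x0.copy()
    done = 0
    while done < n_steps:
        n = min(chunk_steps, n_steps - done)
        n -= n % save_every or 0
        if n <= 0:
            n = n_steps - done
        xi = rng.standard_normal((n, network.n_nodes))
        traj = _kernels.em_trajectory(
            g, k, lam, nn, b0, src, tgt, x, dt, n, amps, xi, save_every
        )
        if np.any(~np.isfinite(traj)):
            raise FloatingPointError("stochastic trajectory diverged")
        levels.append(traj[1:])
        x = traj[-1].copy()
        done += n
    levels = np.vstack(levels)
    time = np.arange(levels.shape[0]) * dt * save_every
    occ = None
    labels = tuple(attractor_labels) if attractor_labels is not None else tuple(
        f"A{i}" for i in range(attractors.shape[0])
    )
    if attractors.size:
        occ = _assign_occupancy(levels, attractors, dwell)
    return Trajectory(network.nodes, time, levels, attractors, labels, occ)
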