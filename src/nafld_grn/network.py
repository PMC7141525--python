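"""Signed regulatory topologies and shifted-Hill ODE assembly.

A :class:`RegulatoryNetwork` is a signed directed graph over named genes
(self-loops permitted).  A :class:`KineticModel` attaches a production and a
degradation rate to every node and a shifted-Hill triplet (threshold ``B0``,
cooperativity ``n``, fold change ``lam``) to every edge, which together
define a system of coupled ODEs

    dX_i/dt = g_i * prod_e H_s(X_source(e); B0_e, n_e, lam_e) - k_i * X_i

where the product runs over the edges targeting node *i* and ``H_s`` is the
shifted Hill function interpolating between basal production (factor 1, no
regulator) and fold-changed production (factor ``lam``, saturating
regulator).  Regulators combine multiplicatively on a single basal rate,
the standard random-circuit-perturbation convention.

Concentrations are expressed in units of 1e6 molecules and time in hours;
the bundled literature parameterization of the liver circuit uses the same
units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

ACTIVATION = "activation"
INHIBITION = "inhibition"

#: Node order of the bundled wild-type liver circuit.
WILDTYPE_NODES = ("HNF4A", "HNF1A", "PPARG", "SREBF1")


class NetworkStructureError(ValueError):
    """Topology/parameterization mismatch or malformed network."""


class InvalidParameterError(ValueError):
    """Kinetic parameter outside its admissible domain."""


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise NetworkStructureError(
                f"edge sign must be '{ACTIVATION}' or '{INHIBITION}', got {self.sign!r}"
            )

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Signed directed graph over named genes."""

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkStructureError("duplicate node names")
        declared = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in declared or e.target not in declared:
                raise NetworkStructureError(
                    f"edge {e.source}->{e.target} references undeclared node"
                )
            pair = (e.source, e.target)
            if pair in seen:
                raise NetworkStructureError(f"duplicate edge {e.source}->{e.target}")
            seen.add(pair)

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, name: str) -> int:
        return self.nodes.index(name)

    def incoming(self, node: str) -> list[Edge]:
        return [e for e in self.edges if e.target == node]

    def self_activation_nodes(self) -> tuple[str, ...]:
        return tuple(
            e.source for e in self.edges if e.is_self_loop and e.sign == ACTIVATION
        )

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(source_index, target_index) integer arrays in edge order."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        src = np.array([idx[e.source] for e in self.edges], dtype=np.int64)
        tgt = np.array([idx[e.target] for e in self.edges], dtype=np.int64)
        return src, tgt

    def with_signs(self, signs: Sequence[str]) -> "RegulatoryNetwork":
        """Same wiring, new edge signs (in edge order)."""
        if len(signs) != self.n_edges:
            raise NetworkStructureError("one sign per edge required")
        return RegulatoryNetwork(
            self.nodes,
            tuple(Edge(e.source, e.target, s) for e, s in zip(self.edges, signs)),
        )

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tsign\n")
            for e in self.edges:
                fh.write(f"{e.source}\t{e.target}\t{e.sign}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, nodes: Sequence[str] | None = None) -> "RegulatoryNetwork":
        edges = []
        order: list[str] = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["source", "target", "sign"]:
                raise NetworkStructureError(f"unexpected header {header!r}")
            for line in fh:
                if not line.strip():
                    continue
                s, t, sign = line.rstrip("\n").split("\t")
                edges.append(Edge(s, t, sign))
                for name in (s, t):
                    if name not in order:
                        order.append(name)
        return cls(tuple(nodes) if nodes is not None else tuple(order), tuple(edges))


@dataclass(frozen=True)
class ShiftedHillParams:
    """Threshold ``B0`` (1e6 molecules), cooperativity ``n``, fold change ``lam``.

    ``lam > 1`` for activators and ``lam < 1`` for inhibitors.
    """

    threshold: float
    cooperativity: int
    fold_change: float

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise InvalidParameterError(f"threshold must be > 0, got {self.threshold}")
        if int(self.cooperativity) != self.cooperativity or self.cooperativity < 1:
            raise InvalidParameterError(
                f"cooperativity must be a positive integer, got {self.cooperativity}"
            )
        if not self.fold_change > 0:
            raise InvalidParameterError(f"fold change must be > 0, got {self.fold_change}")

    def check_sign(self, sign: str) -> None:
        if sign == ACTIVATION and self.fold_change <= 1:
            raise InvalidParameterError(
                f"activating edge requires fold change > 1, got {self.fold_change}"
            )
        if sign == INHIBITION and self.fold_change >= 1:
            raise InvalidParameterError(
                f"inhibiting edge requires fold change < 1, got {self.fold_change}"
            )


def shifted_hill(B, params: ShiftedHillParams):
    """Shifted Hill regulation factor ``H-(B) + lam * H+(B)``.

    ``H-(B) = B0^n / (B0^n + B^n)`` and ``H+ = 1 - H-``.  The value lies
    between ``min(1, lam)`` and ``max(1, lam)``; at ``B = 0`` it is exactly 1
    (basal production) and it saturates at ``lam``.  Accepts scalar or array
    ``B >= 0``.
    """
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise InvalidParameterError("regulator level must be nonnegative")
    b0n = params.threshold ** params.cooperativity
    hminus = b0n / (b0n + B ** params.cooperativity)
    out = hminus + params.fold_change * (1.0 - hminus)
    return out if out.ndim else float(out)


def shifted_hill_derivative(B, params: ShiftedHillParams):
    """d H_s / dB, used in analytic Jacobians."""
    B = np.asarray(B, dtype=float)
    n = params.cooperativity
    b0n = params.threshold ** n
    bn = B ** n
    dhplus = np.where(B > 0, n * b0n * bn / (B * (b0n + bn) ** 2), 0.0 if n > 1 else 0.0)
    if n == 1:
        dhplus = b0n / (b0n + bn) ** 2
    out = (params.fold_change - 1.0) * dhplus
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class KineticModel:
    """One full parameterization of a network's ODE system."""

    production: Mapping[str, float]
    degradation: Mapping[str, float]
    edge_params: Mapping[tuple[str, str], ShiftedHillParams]

    def __post_init__(self) -> None:
        for name, g in self.production.items():
            if not g > 0:
                raise InvalidParameterError(f"production rate of {name} must be > 0")
        for name, k in self.degradation.items():
            if not k > 0:
                raise InvalidParameterError(f"degradation rate of {name} must be > 0")

    def validate_against(self, network: RegulatoryNetwork) -> None:
        missing = set(network.nodes) - set(self.production) | set(network.nodes) - set(
            self.degradation
        )
        if missing:
            raise NetworkStructureError(f"missing node rates for {sorted(missing)}")
        pairs = {(e.source, e.target) for e in network.edges}
        if pairs != set(self.edge_params):
            raise NetworkStructureError(
                "edge parameter set does not match network edges"
            )
        for e in network.edges:
            self.edge_params[(e.source, e.target)].check_sign(e.sign)

    def with_rate(self, node: str, *, degradation: float | None = None,
                  production: float | None = None) -> "KineticModel":
        """Copy with one node's rate(s) replaced (e.g. for bifurcation sweeps)."""
        prod = dict(self.production)
        degr = dict(self.degradation)
        if production is not None:
            prod[node] = production
        if degradation is not None:
            degr[node] = degradation
        return KineticModel(prod, degr, dict(self.edge_params))

    # -- packed arrays for fast kernels ---------------------------------
    def arrays(self, network: RegulatoryNetwork):
        """(g, k, lam, n, b0) arrays in node / edge order of ``network``."""
        g = np.array([self.production[n] for n in network.nodes])
        k = np.array([self.degradation[n] for n in network.nodes])
        lam = np.array(
            [self.edge_params[(e.source, e.target)].fold_change for e in network.edges]
        )
        nn = np.array(
            [self.edge_params[(e.source, e.target)].cooperativity for e in network.edges],
            dtype=np.int64,
        )
        b0 = np.array(
            [self.edge_params[(e.source, e.target)].threshold for e in network.edges]
        )
        return g, k, lam, nn, b0


def build_rhs(network: RegulatoryNetwork, model: KineticModel) -> Callable[[np.ndarray], np.ndarray]:
    """Derivative function ``x -> dx/dt`` of the assembled shifted-Hill system.

    Regulators combine as multiplicative shifted-Hill factors on a single
    basal production rate; a node with no regulators obeys
    ``dX/dt = g - k X``.
    """
    model.validate_against(network)
    g, k, lam, nn, b0 = model.arrays(network)
    src, tgt = network.edge_arrays()
    b0n = b0 ** nn

    def rhs(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        hminus = b0n / (b0n + x[src] ** nn)
        h = hminus + lam * (1.0 - hminus)
        p = np.ones_like(g)
        np.multiply.at(p, tgt, h)
        return g * p - k * x

    return rhs


def build_jacobian(network: RegulatoryNetwork, model: KineticModel) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic Jacobian of the assembled system (for stability analysis)."""
    model.validate_against(network)
    g, k, lam, nn, b0 = model.arrays(network)
    src, tgt = network.edge_arrays()
    b0n = b0 ** nn
    N = network.n_nodes
    E = network.n_edges

    def jac(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xs = x[src]
        xn = xs ** nn
        hminus = b0n / (b0n + xn)
        h = hminus + lam * (1.0 - hminus)
        p = np.ones(N)
        np.multiply.at(p, tgt, h)
        # d h_e / d x_source
        with np.errstate(divide="ignore", invalid="ignore"):
            dhplus = np.where(
                xs > 0, nn * b0n * xn / (xs * (b0n + xn) ** 2), 0.0
            )
        dhplus = np.where((nn == 1), b0n / (b0n + xn) ** 2, dhplus)
        dh = (lam - 1.0) * dhplus
        J = np.diag(-k)
        for e in range(E):
            J[tgt[e], src[e]] += g[tgt[e]] * (p[tgt[e]] / h[e]) * dh[e]
        return J

    return jac


def degradation_from_halflife(t_half: float) -> float:
    """First-order degradation rate (1/hr) from a protein half-life (hr)."""
    if not t_half > 0:
        raise InvalidParameterError(f"half-life must be > 0, got {t_half}")
    return math.log(2.0) / t_half


# ---------------------------------------------------------------------------
# Config I/O and the bundled literature circuit
# ---------------------------------------------------------------------------

def save_model_yaml(network: RegulatoryNetwork, model: KineticModel, path: str | Path) -> None:
    model.validate_against(network)
    doc = {
        "nodes": {
            n: {
                "production": float(model.production[n]),
                "degradation": float(model.degradation[n]),
            }
            for n in network.nodes
        },
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "fold_change": float(model.edge_params[(e.source, e.target)].fold_change),
                "cooperativity": int(model.edge_params[(e.source, e.target)].cooperativity),
                "threshold": float(model.edge_params[(e.source, e.target)].threshold),
            }
            for e in network.edges
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model_yaml(path: str | Path) -> KineticModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _model_from_doc(doc)


def _model_from_doc(doc: dict) -> KineticModel:
    production = {n: float(v["production"]) for n, v in doc["nodes"].items()}
    degradation = {n: float(v["degradation"]) for n, v in doc["nodes"].items()}
    edge_params = {
        (e["source"], e["target"]): ShiftedHillParams(
            threshold=float(e["threshold"]),
            cooperativity=int(e["cooperativity"]),
            fold_change=float(e["fold_change"]),
        )
        for e in doc["edges"]
    }
    return KineticModel(production, degradation, edge_params)


def wildtype_network() -> RegulatoryNetwork:
    """The bundled wild-type liver circuit: 10 edges (8 activating, 2 inhibiting)
    over HNF4A, HNF1A, PPARG, SREBF1."""
    ref = resources.files("nafld_grn.data").joinpath("wildtype_topology.tsv")
    with resources.as_file(ref) as p:
        return RegulatoryNetwork.from_tsv(p, nodes=WILDTYPE_NODES)


def literature_model() -> KineticModel:
    """Literature kinetic parameterization of the wild-type circuit.

    Production/degradation per node and the ten shifted-Hill triplets; the
    PPARG degradation rate of 0.08/hr corresponds to the bistable
    hepatocyte/hybrid regime used in the switching analyses.
    """
    ref = resources.files("nafld_grn.data").joinpath("literature_params.yaml")
    with resources.as_file(ref) as p:
        return load_model_yaml(p)
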