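"""Topology randomization and scoring.

Two families of variants of the wild-type circuit are enumerated:

* *sign shuffles* keep every (source, target) pair — hence all in/out
  degrees — and reassign which 2 of the 10 edges are inhibitory.  With 8
  activating and 2 inhibiting edges there are C(10, 2) = 45 assignments;
  excluding the wild type leaves 44 "hypothetical" networks.
* *self-loop mutants* delete any subset of the four self-activation loops
  (2^4 = 16 networks, from the full wild type down to the loop-less
  ``null``), leaving all other edges untouched.

Each variant's ensemble is scored by the Jensen-Shannon divergence of its
16-bin state-frequency distribution against the wild-type reference and by
its plasticity (fraction of models that are multistable).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from nafld_grn.ensemble import (
    EnsembleResult,
    IntegrationSettings,
    SamplingRanges,
    run_ensemble,
)
from nafld_grn.network import ACTIVATION, INHIBITION, RegulatoryNetwork
from nafld_grn.states import binarize, calls_to_labels, state_frequency_distribution

__all__ = [
    "NetworkVariant",
    "PlasticityScore",
    "enumerate_sign_shuffles",
    "enumerate_selfloop_mutants",
    "jsd",
    "js_distance",
    "plasticity",
    "ensemble_state_frequency",
    "score_variants",
    "SELF_LOOP_TOKENS",
]

#: Codename tokens of the four self-activation loops (wild-type order).
SELF_LOOP_TOKENS = {"HNF4A": "4a", "HNF1A": "1a", "PPARG": "g", "SREBF1": "f1"}

PROVENANCE_WILDTYPE = "wild-type"
PROVENANCE_SHUFFLE = "sign-shuffle"
PROVENANCE_SELFLOOP = "self-loop-mutant"


@dataclass(frozen=True)
class NetworkVariant:
    codename: str
    network: RegulatoryNetwork
    provenance: str


def enumerate_sign_shuffles(wildtype: RegulatoryNetwork) -> list[NetworkVariant]:
    """All degree-preserving sign reassignments of the wild-type edges.

    Every variant keeps the 10 (source, target) pairs and the global count
    of 8 activating / 2 inhibiting edges; exactly the wild type itself is
    excluded, leaving 44 variants.
    """
    n_inhib = sum(e.sign == INHIBITION for e in wildtype.edges)
    wt_signs = tuple(e.sign for e in wildtype.edges)
    out = []
    for inhib in combinations(range(wildtype.n_edges), n_inhib):
        signs = tuple(
            INHIBITION if i in inhib else ACTIVATION for i in range(wildtype.n_edges)
        )
        if signs == wt_signs:
            continue
        pairs = "+".join(
            f"{wildtype.edges[i].source}-{wildtype.edges[i].target}" for i in inhib
        )
        out.append(
            NetworkVariant(f"inh[{pairs}]", wildtype.with_signs(signs), PROVENANCE_SHUFFLE)
        )
    return out


def selfloop_codename(kept: Iterable[str]) -> str:
    kept = set(kept)
    tokens = [t for n, t in SELF_LOOP_TOKENS.items() if n in kept]
    return "_".join(tokens) if tokens else "null"


def enumerate_selfloop_mutants(wildtype: RegulatoryNetwork) -> list[NetworkVariant]:
    """All 2^L presence/absence combinations of the self-activation loops.

    Codenames follow the token convention (``4a_1a_g_f1`` = all four loops
    present, ``null`` = none); the full combination is the wild type itself.
    """
    loops = wildtype.self_activation_nodes()
    out = []
    for r in range(len(loops) + 1):
        for kept in combinations(loops, r):
            keep = set(kept)
            edges = tuple(
                e
                for e in wildtype.edges
                if not (e.is_self_loop and e.sign == ACTIVATION and e.source not in keep)
            )
            net = RegulatoryNetwork(wildtype.nodes, edges)
            prov = PROVENANCE_WILDTYPE if len(kept) == len(loops) else PROVENANCE_SELFLOOP
            out.append(NetworkVariant(selfloop_codename(keep), net, prov))
    return out


def jsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Jensen-Shannon divergence between two discrete distributions.

    ``JSD(P, Q) = D(P || M)/2 + D(Q || M)/2`` with ``M = (P + Q)/2`` and
    base-2 Kullback-Leibler divergences, so the value lies in [0, 1]: 0 for
    identical distributions, 1 for disjoint supports.  Zero-probability
    bins contribute nothing to their own KL terms.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("distributions must share a support")
    for name, X in (("P", P), ("Q", Q)):
        if np.any(X < 0) or not np.isclose(X.sum(), 1.0, atol=1e-8):
            raise ValueError(f"{name} must be a normalized distribution")
    M = 0.5 * (P + Q)

    def kl(A: np.ndarray) -> float:
        mask = A > 0
        return float(np.sum(A[mask] * np.log2(A[mask] / M[mask])))

    return 0.5 * kl(P) + 0.5 * kl(Q)


def js_distance(P: np.ndarray, Q: np.ndarray) -> float:
    """Jensen-Shannon distance: the square root of :func:`jsd`.

    Both the divergence and its square root are bounded by [0, 1]; the
    distance is the metric form and is the quantity usually quoted when
    distributions are compared as "distances".
    """
    return float(np.sqrt(jsd(P, Q)))


@dataclass(frozen=True)
class PlasticityScore:
    """Fraction of parameter sets yielding multistable solutions."""

    n_multi: int
    n_mono: int
    n_all: int

    @property
    def value(self) -> float:
        return self.n_multi / self.n_all

    def __float__(self) -> float:
        return self.value


def plasticity(ensemble: EnsembleResult) -> PlasticityScore:
    """Plasticity ``P = N(multi) / N(all)`` over retained models.

    Models flagged during steady-state finding (no convergence, or more
    distinct states than the cap) are excluded from both counts.
    """
    counts = ensemble.counts[ensemble.retained]
    if counts.size == 0:
        raise ValueError("ensemble has no retained models")
    n_multi = int(np.sum(counts > 1))
    return PlasticityScore(n_multi, int(counts.size) - n_multi, int(counts.size))


def ensemble_state_frequency(ensemble: EnsembleResult) -> pd.Series:
    """Binarize all four genes and tally the 16-bin state distribution."""
    levels, _ = ensemble.pooled_states()
    b = binarize(levels, ensemble.network.nodes)
    labels = calls_to_labels(b.calls)
    return state_frequency_distribution(labels, ensemble.network.n_nodes)


def score_variants(
    variants: Sequence[NetworkVariant],
    reference: pd.Series,
    ranges: SamplingRanges | None = None,
    n_models: int = 2000,
    n_init: int = 100,
    seed: int = 0,
    settings: IntegrationSettings | None = None,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Ensemble each variant and score it against the wild-type reference.

    All variants reuse the same sampling-range configuration and master
    seed, so differences in JSD and plasticity reflect topology only.
    Returns one row per variant (codename, provenance, jsd, plasticity,
    n_retained).
    """
    rows = []
    for v in variants:
        if progress is not None:
            progress(v.codename)
        ens = run_ensemble(
            v.network,
            ranges=ranges,
            n_models=n_models,
            n_init=n_init,
            seed=seed,
            settings=settings,
        )
        freq = ensemble_state_frequency(ens)
        p = plasticity(ens)
        rows.append(
            {
                "codename": v.codename,
                "provenance": v.provenance,
                "n_self_loops": len(v.network.self_activation_nodes()),
                "jsd": jsd(freq.to_numpy(), reference.to_numpy()),
                "js_distance": js_distance(freq.to_numpy(), reference.to_numpy()),
                "plasticity": p.value,
                "n_retained": p.n_all,
            }
        )
    return pd.DataFrame(rows)
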