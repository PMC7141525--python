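"""State classification: z-normalization, bimodality, H/L binarization,
phase composition and state-frequency distributions.

Pooled log2 steady-state levels of each gene across an ensemble are
z-normalized and, when bimodal by Sarle's coefficient, split at the interior
density minimum into a high (H) and a low (L) group.  A steady state then
maps to a label string over the ordered genes (16 possibilities for four
genes); the set of labels co-existing within one model is its *phase*
(e.g. ``{HL, LH}`` over the HNF4A/PPARG pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from nafld_grn.ensemble import EnsembleResult

__all__ = [
    "ZNormalization",
    "BimodalitySummary",
    "PhaseComposition",
    "BIMODALITY_CUTOFF",
    "z_normalize",
    "bimodality_coefficient",
    "binarize",
    "label_states",
    "state_frequency_distribution",
    "all_labels",
    "hierarchical_clusters",
]

#: Sarle's coefficient of the uniform distribution; larger values indicate
#: multimodality.
BIMODALITY_CUTOFF = 5.0 / 9.0


class DegenerateDistributionError(ValueError):
    """Pooled values carry no spread (or too few points) for the statistic."""


@dataclass(frozen=True)
class ZNormalization:
    """Population-convention z-scores of a pooled sample."""

    mean: float
    sd: float
    z: np.ndarray


def z_normalize(values: np.ndarray) -> ZNormalization:
    """z-scores ``(E_i - mean) / sd`` with the population sd (divide by n)."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    sd = float(values.std())  # population convention
    if values.size < 2 or sd == 0:
        raise DegenerateDistributionError(
            "need at least two distinct values to z-normalize"
        )
    return ZNormalization(mean, sd, (values - mean) / sd)


@dataclass(frozen=True)
class BimodalitySummary:
    n: int
    skewness: float
    excess_kurtosis: float
    coefficient: float

    @property
    def bimodal(self) -> bool:
        return self.coefficient > BIMODALITY_CUTOFF


def bimodality_coefficient(values: np.ndarray) -> BimodalitySummary:
    """Sarle's bimodality coefficient for finite samples.

    ``b = (g^2 + 1) / (k + 3 (n-1)^2 / ((n-2)(n-3)))`` with population
    (biased) skewness ``g`` and excess kurtosis ``k``.  ``b`` tends to 5/9
    for the uniform distribution, 1/3 for the normal, and 1 for a symmetric
    two-point mixture.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 4:
        raise DegenerateDistributionError("bimodality coefficient requires n >= 4")
    g = stats.skew(values, bias=True)
    k = stats.kurtosis(values, fisher=True, bias=True)
    b = (g**2 + 1.0) / (k + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    return BimodalitySummary(n, float(g), float(k), float(b))


def _kde_threshold(z: np.ndarray, grid_size: int = 512) -> float | None:
    """Interior density minimum between the two highest modes of a KDE.

    Scott's-rule Gaussian KDE; returns None when no interior minimum exists.
    Ties in the minimum are broken toward the midpoint of the two modes.
    """
    kde = stats.gaussian_kde(z)  # Scott's rule by default
    lo, hi = z.min(), z.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    interior = slice(1, -1)
    d = dens[interior]
    maxima = np.flatnonzero((d > dens[:-2]) & (d >= dens[2:])) + 1
    if maxima.size < 2:
        return None
    top2 = maxima[np.argsort(dens[maxima])][-2:]
    a, b = sorted(top2)
    seg = dens[a : b + 1]
    lows = np.flatnonzero(seg == seg.min())
    mid = (b - a) / 2
    pick = lows[np.argmin(np.abs(lows - mid))]
    return float(grid[a + pick])


@dataclass(frozen=True)
class BinarizationResult:
    nodes: tuple[str, ...]
    znorms: tuple[ZNormalization, ...]
    bimodality: tuple[BimodalitySummary, ...]
    thresholds: np.ndarray  # per node, in z units
    calls: np.ndarray  # (n_states, n_nodes) bool, True = H


def binarize(levels: np.ndarray, nodes: Sequence[str]) -> BinarizationResult:
    """Per-node H/L calls on pooled log2 levels (rows = states).

    Each node is z-normalized; if its pooled distribution is bimodal
    (Sarle's b > 5/9) the threshold sits at the interior KDE density
    minimum between the two dominant modes, otherwise (or when no interior
    minimum exists) it falls back to z = 0 with a warning.
    """
    levels = np.asarray(levels, dtype=float)
    znorms, summaries, thresholds = [], [], []
    for j, name in enumerate(nodes):
        zn = z_normalize(levels[:, j])
        bc = bimodality_coefficient(levels[:, j])
        thr = None
        if bc.bimodal:
            thr = _kde_threshold(zn.z)
        if thr is None:
            warnings.warn(
                f"node {name}: no bimodal interior minimum, falling back to z=0",
                stacklevel=2,
            )
            thr = 0.0
        znorms.append(zn)
        summaries.append(bc)
        thresholds.append(thr)
    thresholds = np.array(thresholds)
    z = np.column_stack([zn.z for zn in znorms])
    return BinarizationResult(
        tuple(nodes), tuple(znorms), tuple(summaries), thresholds, z > thresholds
    )


def all_labels(n_nodes: int) -> list[str]:
    """All H/L label strings over ``n_nodes`` genes, in lexicographic order."""
    return ["".join(p) for p in product("HL", repeat=n_nodes)]


def calls_to_labels(calls: np.ndarray, subset: Sequence[int] | None = None) -> np.ndarray:
    """Label strings from boolean H calls, optionally over a node subset."""
    calls = np.asarray(calls, dtype=bool)
    if subset is not None:
        calls = calls[:, list(subset)]
    lut = np.array(["L", "H"])
    return np.array(["".join(row) for row in lut[calls.astype(int)]])


@dataclass(frozen=True)
class PhaseComposition:
    """Per-model phase sets and ensemble-level tallies."""

    nodes: tuple[str, ...]
    model_ids: np.ndarray
    state_labels: np.ndarray  # full-width label per pooled state
    pair_labels: np.ndarray  # label over the phase gene pair
    phases: Mapping[int, frozenset]  # model id -> set of pair labels
    state_counts: Mapping[int, int]  # model id -> number of states
    frequency: pd.Series  # full-width 16-bin state-frequency distribution

    def phase_tally(self, n_states: int | None = None) -> pd.Series:
        """Counts of phases, optionally restricted to models with a given
        state count (1 = monostable, 2 = bistable, ...).

        When ``n_states`` is given, only models whose states carry distinct
        labels count: an n-stable phase is then one of the C(4, n) label
        combinations.  Models with label-degenerate states (two states
        differing only in the genes outside the phase pair) are left out.
        """
        items = [
            tuple(sorted(p))
            for mid, p in self.phases.items()
            if n_states is None
            or (self.state_counts[mid] == n_states and len(p) == n_states)
        ]
        return pd.Series(items).value_counts() if items else pd.Series(dtype=int)

    def models_with_phase(self, phase: Sequence[str], exact_count: bool = True) -> np.ndarray:
        """Model ids whose phase equals the given label set (as a set)."""
        target = frozenset(phase)
        return np.array(
            [
                mid
                for mid, p in self.phases.items()
                if p == target and (not exact_count or self.state_counts[mid] == len(target))
            ],
            dtype=int,
        )


def label_states(
    ensemble: EnsembleResult,
    binarization: BinarizationResult | None = None,
    phase_genes: tuple[str, str] = ("HNF4A", "PPARG"),
) -> PhaseComposition:
    """Label every retained steady state H/L and build phase tallies.

    The full-width labels feed the state-frequency distribution (16 bins
    for four genes, normalized to 1); the two-gene labels over
    ``phase_genes`` define the phases used in the relative-stability and
    phase-proportion analyses.
    """
    nodes = ensemble.network.nodes
    levels, owner = ensemble.pooled_states()
    if binarization is None:
        binarization = binarize(levels, nodes)
    labels = calls_to_labels(binarization.calls)
    pair_idx = [nodes.index(g) for g in phase_genes]
    pair_labels = calls_to_labels(binarization.calls, pair_idx)
    phases: dict[int, frozenset] = {}
    counts: dict[int, int] = {}
    for mid in np.unique(owner):
        mask = owner == mid
        phases[int(mid)] = frozenset(pair_labels[mask])
        counts[int(mid)] = int(mask.sum())
    freq = state_frequency_distribution(labels, len(nodes))
    return PhaseComposition(
        tuple(nodes), owner, labels, pair_labels, phases, counts, freq
    )


def state_frequency_distribution(labels: np.ndarray, n_nodes: int) -> pd.Series:
    """Frequency of each H/L state across all pooled steady states.

    Every steady state of every retained model contributes one count; the
    result is indexed by all ``2**n_nodes`` labels and sums to 1.
    """
    idx = all_labels(n_nodes)
    counts = pd.Series(labels).value_counts().reindex(idx, fill_value=0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no labeled states")
    return counts / total


def hierarchical_clusters(z_levels: np.ndarray, k: int = 4) -> np.ndarray:
    """Ward-linkage agglomerative clustering of z-scored levels into k groups.

    With k = 4 on a two-gene matrix the groups map onto the HH/HL/LH/LL
    quadrants by the signs of their centroids.
    """
    z_levels = np.asarray(z_levels, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > z_levels.shape[0]:
        raise ValueError("k exceeds the number of samples")
    if k == 1:
        return np.zeros(z_levels.shape[0], dtype=int)
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    return model.fit_predict(z_levels)


def cluster_quadrant_labels(z_levels: np.ndarray, assignments: np.ndarray) -> dict[int, str]:
    """Map cluster ids to H/L quadrant labels by centroid signs."""
    out = {}
    for c in np.unique(assignments):
        centroid = z_levels[assignments == c].mean(axis=0)
        out[int(c)] = "".join("H" if v > 0 else "L" for v in centroid)
    return out
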