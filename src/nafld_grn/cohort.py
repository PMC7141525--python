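"""Synthetic clinical cohorts and the associated validation statistics.

The model predicts a sign structure for gene-gene correlations (HNF4A
anti-correlated with PPARG, positively correlated with HNF1A, ...) and
group shifts between healthy and NASH livers (HNF4A down, PPARG up).  This
module generates log2-normalized expression matrices with a configurable
group design and inter-gene correlation structure — a synthetic stand-in
for public liver transcriptomics cohorts — and provides the two statistics
used to test the predictions: Spearman rank correlation and the two-tailed
Student's t-test.

Values are drawn per group from a multivariate normal in log2 space
(a Gaussian copula with normal margins), the simplest structure matching a
log2-normalized array with a target correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSpec",
    "ExpressionMatrix",
    "default_nafld_spec",
    "generate_cohort",
    "gene_correlation",
    "group_compare",
]

GENES = ("HNF4A", "HNF1A", "PPARG", "SREBF1")

#: Target inter-gene correlations mirroring the predicted sign structure.
DEFAULT_CORRELATION = pd.DataFrame(
    [
        [1.0, 0.5, -0.5, -0.4],
        [0.5, 1.0, -0.4, -0.3],
        [-0.5, -0.4, 1.0, 0.5],
        [-0.4, -0.3, 0.5, 1.0],
    ],
    index=list(GENES),
    columns=list(GENES),
)


class ConstantGeneError(ValueError):
    """A statistic is undefined because a gene carries no variance."""


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic two-group expression cohort.

    ``group_means``/``group_sds`` give per-group, per-gene log2 location and
    scale; ``correlation`` is the shared inter-gene correlation matrix
    (symmetric positive semi-definite, unit diagonal).
    """

    genes: tuple[str, ...]
    group_sizes: Mapping[str, int]
    group_means: Mapping[str, Mapping[str, float]]
    group_sds: Mapping[str, Mapping[str, float]]
    correlation: pd.DataFrame
    seed: int = 0

    def __post_init__(self) -> None:
        for grp, n in self.group_sizes.items():
            if n < 3:
                raise ValueError(f"group {grp!r} needs at least 3 samples, got {n}")
        for grp in self.group_sizes:
            for g in self.genes:
                if not self.group_sds[grp][g] > 0:
                    raise ValueError(f"sd of {g} in group {grp!r} must be > 0")
        C = self.correlation.loc[list(self.genes), list(self.genes)].to_numpy()
        if not np.allclose(C, C.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-10:
            raise ValueError(
                f"correlation matrix not positive semi-definite (eigenvalue {w.min():.3g})"
            )


def default_nafld_spec(
    n_healthy: int = 50, n_nash: int = 50, seed: int = 0
) -> CohortSpec:
    """Healthy-vs-NASH design with the predicted shifts and correlations.

    Relative to healthy livers, NASH samples shift by -1 log2 in HNF4A and
    HNF1A and +1 log2 in PPARG and SREBF1, with unit log2 spread per gene.
    """
    healthy = {"HNF4A": 8.0, "HNF1A": 7.0, "PPARG": 5.0, "SREBF1": 6.0}
    shift = {"HNF4A": -1.0, "HNF1A": -1.0, "PPARG": 1.0, "SREBF1": 1.0}
    nash = {g: healthy[g] + shift[g] for g in GENES}
    sds = {g: 1.0 for g in GENES}
    return CohortSpec(
        genes=GENES,
        group_sizes={"healthy": n_healthy, "NASH": n_nash},
        group_means={"healthy": healthy, "NASH": nash},
        group_sds={"healthy": dict(sds), "NASH": dict(sds)},
        correlation=DEFAULT_CORRELATION,
        seed=seed,
    )


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample group labels."""

    values: pd.DataFrame  # index = genes, columns = sample ids
    groups: pd.Series  # index = sample ids

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression values must be finite")
        if set(self.values.columns) != set(self.groups.index):
            raise ValueError("group labels must cover exactly the samples")

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path, labels_path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")
        self.groups.rename("group").to_csv(labels_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path, labels_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col="gene")
        groups = pd.read_csv(labels_path, sep="\t", index_col="sample")["group"]
        return cls(values, groups)


def generate_cohort(spec: CohortSpec) -> ExpressionMatrix:
    """Draw the cohort: per-group multivariate normal in log2 space."""
    rng = np.random.default_rng(spec.seed)
    C = spec.correlation.loc[list(spec.genes), list(spec.genes)].to_numpy()
    blocks, labels, ids = [], [], []
    for grp, n in spec.group_sizes.items():
        mu = np.array([spec.group_means[grp][g] for g in spec.genes])
        sd = np.array([spec.group_sds[grp][g] for g in spec.genes])
        cov = C * np.outer(sd, sd)
        X = rng.multivariate_normal(mu, cov, size=n, method="svd")
        blocks.append(X.T)
        labels += [grp] * n
        ids += [f"{grp}_{i}" for i in range(n)]
    values = pd.DataFrame(np.hstack(blocks), index=list(spec.genes), columns=ids)
    return ExpressionMatrix(values, pd.Series(labels, index=ids))


def gene_correlation(
    matrix: ExpressionMatrix, gene_a: str, gene_b: str
) -> tuple[float, float]:
    """Spearman rank correlation between two genes with two-sided p-value."""
    a = matrix.values.loc[gene_a].to_numpy()
    b = matrix.values.loc[gene_b].to_numpy()
    if a.size < 4:
        raise ValueError("need at least 4 samples for a rank correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantGeneError("correlation undefined for a constant gene")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def group_compare(
    matrix: ExpressionMatrix, gene: str, group_a: str, group_b: str
) -> tuple[float, float]:
    """Equal-variance Student's t-test on log2 values, two-tailed."""
    a = matrix.values.loc[gene, matrix.samples_in(group_a)].to_numpy()
    b = matrix.values.loc[gene, matrix.samples_in(group_b)].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ConstantGeneError("t statistic undefined with zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def ensemble_cohort(
    ensemble, n_samples: int = 200, seed: int = 0
) -> ExpressionMatrix:
    """Pseudo-cohort of steady states sampled from an ensemble.

    Each pseudo-sample is one steady state (log2 levels) of a retained
    model, linking the circuit's predicted correlation structure to the
    cohort statistics.
    """
    levels, _ = ensemble.pooled_states()
    rng = np.random.default_rng(seed)
    take = rng.choice(levels.shape[0], size=min(n_samples, levels.shape[0]), replace=False)
    ids = [f"model_state_{i}" for i in range(take.size)]
    values = pd.DataFrame(
        levels[take].T, index=list(ensemble.network.nodes), columns=ids
    )
    return ExpressionMatrix(values, pd.Series(["ensemble"] * take.size, index=ids))
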