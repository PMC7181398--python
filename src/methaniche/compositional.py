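"""Compositionality-robust correlation (SparCC) and clustering comparison.

Relative abundances are compositional: each sample sums to a constant, so
naive Pearson correlation between components is biased negative. SparCC
estimates the correlations of the underlying (basis) abundances from the
variances of pairwise log-ratios,

    t_ij = Var_samples( log x_i - log x_j )
         = w_i + w_j - 2 rho_ij sqrt(w_i w_j),

under a sparsity assumption (most true correlations near zero) that makes
the basis variances w identifiable through the linear system

    sum_{j != i} t_ij = (p - 2) w_i + sum_j w_j .

Strongly correlated pairs violate the sparsity assumption, so the strongest
pair is iteratively excluded from the system and the variances re-solved.

This module also provides partition-agreement metrics (adjusted Rand index,
best-match Jaccard) used to compare the Pearson-network clustering with the
SparCC-based one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AbundanceTable
from .network import ClusterAssignment, CorrelationMatrix

__all__ = [
    "SparccSettings",
    "NetworkComparison",
    "sparcc_correlation",
    "adjusted_rand_index",
    "compare_assignments",
]


@dataclass
class SparccSettings:
    """Tuning knobs for the basis-correlation estimator.

    ``pseudocount`` is added before taking logs (use ~0.5 on raw counts,
    ~1e-6 on percent tables). ``n_exclusion_iterations`` strong pairs with
    ``|rho| > exclusion_threshold`` are removed from the variance system,
    one per iteration.
    """

    pseudocount: float = 1e-6
    n_exclusion_iterations: int = 10
    exclusion_threshold: float = 0.1

    def __post_init__(self) -> None:
        if min(self.pseudocount, self.exclusion_threshold) <= 0:
            raise ValueError("pseudocount and exclusion_threshold must be positive")
        if self.n_exclusion_iterations < 0:
            raise ValueError("n_exclusion_iterations must be nonnegative")


def _variation_matrix(x: np.ndarray) -> np.ndarray:
    """t_ij = Var over samples of log(x_i) - log(x_j); x is features x samples."""
    logx = np.log(x)
    p = logx.shape[0]
    t = np.zeros((p, p))
    for i in range(p):
        d = logx[i] - logx
        t[i] = d.var(axis=1)
    return (t + t.T) / 2.0


def _solve_basis_variances(t: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    """Solve the sparsity-approximation system for basis variances.

    Each excluded pair (i, j) removes t_ij from both equations and reduces
    the coefficient pattern accordingly.
    """
    p = t.shape[0]
    m = np.ones((p, p)) + (p - 2) * np.eye(p)
    rhs = t.sum(axis=1)
    for i, j in excluded:
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        rhs[i] -= t[i, j]
        rhs[j] -= t[i, j]
    try:
        omega = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular basis-variance system") from e
    return omega


def _correlation_from(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    rho = (omega[:, None] + omega[None, :] - t) / (
        2.0 * np.sqrt(np.outer(omega, omega))
    )
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def sparcc_correlation(
    table: AbundanceTable,
    settings: SparccSettings | None = None,
    relaxed: bool = False,
) -> CorrelationMatrix:
    """Basis correlations from compositional data.

    Requires at least 4 features (the sparsity system is ill-posed below
    that); ``relaxed=True`` permits the exact 3-feature solve with the
    exclusion loop disabled. Scale-invariant: multiplying any sample column
    by a positive constant does not change the result.
    """
    settings = settings or SparccSettings()
    p, n = table.values.shape
    if relaxed:
        if p < 3:
            raise ValueError("need at least 3 features")
    elif p < 4:
        raise ValueError("need at least 4 features for basis estimation")
    if n < 3:
        raise ValueError("need at least 3 samples")

    # work on per-sample fractions: makes the estimate exactly invariant to
    # rescaling any sample's column (the pseudocount then acts on fractions)
    x = table.values.to_numpy(float)
    x = x / x.sum(axis=0, keepdims=True) + settings.pseudocount
    t = _variation_matrix(x)

    excluded: set[tuple[int, int]] = set()
    omega = _solve_basis_variances(t, excluded)
    n_rounds = 0 if relaxed else settings.n_exclusion_iterations
    for _ in range(n_rounds):
        rho = _correlation_from(t, np.maximum(omega, np.min(t[t > 0], initial=1.0) / 2))
        a = np.abs(rho)
        np.fill_diagonal(a, 0.0)
        for i, j in excluded:
            a[i, j] = a[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(a), a.shape)
        if a[i, j] <= settings.exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        omega = _solve_basis_variances(t, excluded)

    if (omega <= 0).any():
        floor = float(np.min(t[t > 0], initial=1.0) / 2.0)
        warnings.warn(
            f"{int((omega <= 0).sum())} nonpositive basis variances floored at {floor:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
        omega = np.maximum(omega, floor)

    rho = _correlation_from(t, omega)
    return CorrelationMatrix(table.feature_ids, (rho + rho.T) / 2.0, "sparcc")


# ---------------------------------------------------------------------------
# Partition comparison
# ---------------------------------------------------------------------------


def adjusted_rand_index(a: pd.Series, b: pd.Series) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    Computed from the contingency table N with the standard formula
    (sum of C(n_ij,2) terms, corrected by the product of marginal terms).
    """
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("partitions share no nodes")
    ai = pd.Categorical(a.loc[shared]).codes
    bi = pd.Categorical(b.loc[shared]).codes
    n = len(shared)
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1)

    def comb2(x: np.ndarray) -> float:
        return float((x * (x - 1) / 2).sum())

    sum_ij = comb2(table)
    sum_a = comb2(table.sum(axis=1))
    sum_b = comb2(table.sum(axis=0))
    total = n * (n - 1) / 2
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclass
class NetworkComparison:
    """Agreement between two cluster assignments on their shared nodes."""

    ari: float
    best_match: pd.DataFrame  # per cluster of `a`: best cluster of `b`, jaccard
    n_shared_nodes: int


def compare_assignments(a: ClusterAssignment, b: ClusterAssignment) -> NetworkComparison:
    """ARI plus best-match Jaccard per cluster of ``a`` against ``b``."""
    shared = a.labels.index.intersection(b.labels.index)
    if len(shared) == 0:
        raise ValueError("assignments share no nodes")
    la, lb = a.labels.loc[shared], b.labels.loc[shared]
    ari = adjusted_rand_index(la, lb)
    rows = []
    for ca in np.sort(la.unique()):
        set_a = set(la.index[la == ca])
        best_j, best_c = 0.0, None
        for cb in np.sort(lb.unique()):
            set_b = set(lb.index[lb == cb])
            j = len(set_a & set_b) / len(set_a | set_b)
            if j > best_j:
                best_j, best_c = j, int(cb)
        rows.append({"cluster_a": int(ca), "best_cluster_b": best_c, "jaccard": best_j})
    return NetworkComparison(
        ari=ari, best_match=pd.DataFrame(rows), n_shared_nodes=len(shared)
    )
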