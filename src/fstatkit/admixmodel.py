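"""qpWave-style rank tests, qpAdm-style admixture fits, Basal Eurasian alpha,
and the composed two-stage ancestry prediction.

The machinery rests on the f4 matrix ``X[i, j] = f4(L0, Li; R0, Rj)`` between
a set of "left" populations (target first) and "right" outgroups (base
first), computed on the intersection of sites usable in *all* left and right
populations, with a delete-one-block jackknife covariance ``Q`` of the
flattened matrix.

* **Rank test** (qpWave): the hypothesis that the left set relates to the
  right set through ``r+1`` independent ancestry streams means ``X`` has rank
  at most ``r``.  The test statistic is the minimum of
  ``vec(X - AB)' Q^{-1} vec(X - AB)`` over rank-``r`` factorizations,
  minimized by alternating generalized least squares, referred to a
  chi-square with ``(n_left - 1 - r)(n_right - 1 - r)`` degrees of freedom.
* **Admixture fit** (qpAdm): with left = (target, k sources), a model in
  which the target is a mixture of the sources forces rank ``k - 1``; the
  mixture weights are the left null vector of the fitted matrix normalized
  to sum to one, and the residual chi-square (dof ``n_right - k``) is the
  model-fit test.  Weight SEs come from re-estimating the weights on each
  delete-one-block replicate (full jackknife of the weight vector).
* **Basal Eurasian alpha**: a two-source fit of a target against a deeply
  branching African proxy and a non-basal Eurasian source, with outgroups
  confined to crown Eurasians, reads the proxy's weight as the basal
  proportion.
* **Composed prediction**: the product of an admixture proportion and the
  source's own alpha, with a first-order (delta-method) SE assuming the two
  estimates are independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .eigendata import GenotypeDataset, allele_frequencies
from .fstats import BlockAssignment, jackknife_covariance

RIDGE_FRACTION = 1e-5


class ConvergenceError(RuntimeError):
    pass


@dataclass
class F4Matrix:
    """f4 values between left/right population pairs with jackknife covariance."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    values: np.ndarray  # (n_left-1, n_right-1)
    covariance: np.ndarray  # (d, d) of row-major vec(values)
    block_sums: np.ndarray  # (g, n_left-1, n_right-1) per-block numerator sums
    block_counts: np.ndarray  # (g,) usable SNPs per block
    n_snps: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_blocks(self) -> int:
        return int((self.block_counts > 0).sum())

    def delete_one(self, j: int) -> np.ndarray:
        """f4 matrix recomputed with block ``j`` removed."""
        total = self.block_sums.sum(axis=0)
        n = self.block_counts.sum()
        return (total - self.block_sums[j]) / (n - self.block_counts[j])


def build_f4_matrix(
    dataset: GenotypeDataset,
    left: Sequence[str],
    right: Sequence[str],
    blocks: BlockAssignment,
) -> F4Matrix:
    """Compute the left-vs-right f4 matrix on the common usable SNP set.

    The SNP set is the intersection of sites with at least one observed
    allele in every left and right population (the classical qpAdm default),
    so every cell shares one site set and one jackknife weighting.
    """
    left = tuple(left)
    right = tuple(right)
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need at least two left and two right populations")
    overlap = set(left) & set(right)
    if overlap:
        raise ValueError(f"populations in both left and right sets: {sorted(overlap)}")

    table = allele_frequencies(dataset, list(left) + list(right))
    lcols = [table.column(p) for p in left]
    rcols = [table.column(p) for p in right]
    counts = table.allele_counts[:, lcols + rcols]
    usable = (counts > 0).all(axis=1)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("empty usable-SNP intersection across left + right populations")

    fl = table.frequencies[np.ix_(usable, lcols)]
    fr = table.frequencies[np.ix_(usable, rcols)]
    dl = fl[:, [0]] - fl[:, 1:]  # (n, m): L0 - Li
    dr = fr[:, [0]] - fr[:, 1:]  # (n, q): R0 - Rj
    idx = blocks.block_index[usable]
    g = blocks.n_blocks
    m, q = dl.shape[1], dr.shape[1]

    block_sums = np.zeros((g, m, q))
    for i in range(m):
        prod = dl[:, [i]] * dr  # (n, q)
        for j in range(q):
            block_sums[:, i, j] = np.bincount(idx, weights=prod[:, j], minlength=g)
    block_counts = np.bincount(idx, minlength=g).astype(float)

    total = block_sums.sum(axis=0)
    values = total / n_usable
    cov = jackknife_covariance(
        block_sums.reshape(g, m * q), block_counts, total.reshape(m * q), float(n_usable)
    )
    return F4Matrix(
        left=left,
        right=right,
        values=values,
        covariance=cov,
        block_sums=block_sums,
        block_counts=block_counts,
        n_snps=n_usable,
    )


# ---------------------------------------------------------------------------
# Rank test
# ---------------------------------------------------------------------------


@dataclass
class RankTestResult:
    rank: int
    chi2: float
    dof: int
    p_value: float
    n_iterations: int
    factors: tuple[np.ndarray, np.ndarray] | None  # (A, B) with X_hat = A @ B


def _regularized_inverse_factor(cov: np.ndarray) -> np.ndarray:
    """Lower-triangular W with W' W = Q^{-1}; adds a ridge if Q is singular."""
    q = np.asarray(cov, dtype=float)
    try:
        c = np.linalg.cholesky(q)
    except np.linalg.LinAlgError:
        ridge = RIDGE_FRACTION * float(np.mean(np.diag(q)))
        warnings.warn(
            f"jackknife covariance numerically singular; adding ridge {ridge:.3g}",
            RuntimeWarning,
            stacklevel=3,
        )
        c = np.linalg.cholesky(q + ridge * np.eye(q.shape[0]))
    # Q = C C'  =>  Q^{-1} = C'^{-1} C^{-1}; whitener W = C^{-1}
    return linalg.solve_triangular(c, np.eye(q.shape[0]), lower=True)


def _fit_rank(
    x: np.ndarray,
    whitener: np.ndarray,
    rank: int,
    tol: float = 1e-10,
    max_iter: int = 1000,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, np.ndarray, np.ndarray, int]:
    """Minimize ||W (vec(x) - vec(AB))||^2 over rank-``rank`` factorizations.

    Alternating GLS: A given B and B given A are each linear least-squares
    problems in the whitened metric.  Returns (chi2, A, B, iterations).
    """
    m, q = x.shape
    vec = x.reshape(-1)
    if rank == 0:
        r = whitener @ vec
        return float(r @ r), np.zeros((m, 0)), np.zeros((0, q)), 0

    if init is None:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        rs = np.sqrt(s[:rank])
        a = u[:, :rank] * rs
        b = (vt[:rank, :].T * rs).T
    else:
        a, b = init[0].copy(), init[1].copy()

    wx = whitener @ vec
    chi2_prev = np.inf
    for it in range(1, max_iter + 1):
        # solve for A with B fixed: vec(AB) = kron(I_m, B') vec(A) (row-major)
        da = whitener @ np.kron(np.eye(m), b.T)
        a = np.linalg.lstsq(da, wx, rcond=None)[0].reshape(m, rank)
        # solve for B with A fixed: vec(AB) = kron(A, I_q) vec(B)
        db = whitener @ np.kron(a, np.eye(q))
        bv = np.linalg.lstsq(db, wx, rcond=None)[0]
        b = bv.reshape(rank, q)
        resid = wx - whitener @ (a @ b).reshape(-1)
        chi2 = float(resid @ resid)
        if abs(chi2_prev - chi2) <= tol * (1.0 + chi2):
            return chi2, a, b, it
        chi2_prev = chi2
    raise ConvergenceError(
        f"alternating least squares did not converge in {max_iter} iterations "
        f"(last chi2 = {chi2:.6g}, change = {chi2_prev - chi2:.3g})"
    )


def qpwave_rank_test(f4m: F4Matrix, rank: int) -> RankTestResult:
    """Test whether the f4 matrix is consistent with the given rank.

    A rank of ``r`` corresponds to the left populations being related to the
    rights through ``r + 1`` independent ancestry streams.
    """
    m, q = f4m.shape
    if not 0 <= rank < min(m, q):
        raise ValueError(f"testable ranks are 0..{min(m, q) - 1}, got {rank}")
    w = _regularized_inverse_factor(f4m.covariance)
    chi2, a, b, it = _fit_rank(f4m.values, w, rank)
    dof = (m - rank) * (q - rank)
    return RankTestResult(
        rank=rank,
        chi2=chi2,
        dof=dof,
        p_value=float(stats.chi2.sf(chi2, dof)),
        n_iterations=it,
        factors=(a, b),
    )


# ---------------------------------------------------------------------------
# qpAdm
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureFit:
    target: str
    sources: tuple[str, ...]
    outgroups: tuple[str, ...]
    weights: np.ndarray
    weight_se: np.ndarray
    chi2: float
    dof: int
    p_value: float
    feasible: bool
    n_snps: int
    n_blocks: int
    rank_result: RankTestResult = field(repr=False, default=None)

    def weight_of(self, source: str) -> tuple[float, float]:
        i = self.sources.index(source)
        return float(self.weights[i]), float(self.weight_se[i])


def _weights_from_fit(x_hat: np.ndarray) -> np.ndarray:
    """Mixture weights from the left null vector of a rank-deficient f4 matrix.

    Rows of ``x_hat`` are f4(target, source_i; ...); a left null vector v with
    v' x_hat = 0 satisfies sum_i v_i f4(target, source_i; .) = 0, i.e. the
    target is the v-weighted mixture of the sources once v is scaled to sum 1.
    """
    k = x_hat.shape[0]
    if k == 1:
        return np.array([1.0])
    u, s, _ = np.linalg.svd(x_hat)
    v = u[:, -1]
    total = v.sum()
    if abs(total) < 1e-10 * np.abs(v).sum():
        raise ValueError("degenerate null space: weights are not identifiable")
    return v / total


def qpadm_fit(
    dataset: GenotypeDataset,
    target: str,
    sources: Sequence[str],
    outgroups: Sequence[str],
    blocks: BlockAssignment,
    f4m: F4Matrix | None = None,
) -> AdmixtureFit:
    """Estimate admixture proportions of ``target`` from ``sources``.

    ``f4m`` may carry a precomputed left = (target, *sources) vs outgroups
    matrix.  Infeasible fits (weights outside [0, 1]) are returned flagged,
    not suppressed.
    """
    sources = tuple(sources)
    outgroups = tuple(outgroups)
    k = len(sources)
    if k < 1:
        raise ValueError("need at least one source")
    if k >= len(outgroups):
        raise ValueError(
            f"insufficient outgroups: {k} sources need at least {k + 1} outgroups, "
            f"got {len(outgroups)}"
        )
    if f4m is None:
        f4m = build_f4_matrix(dataset, (target,) + sources, outgroups, blocks)
    elif f4m.left != (target,) + sources or f4m.right != outgroups:
        raise ValueError("precomputed f4 matrix does not match the requested model")

    rank = k - 1
    w = _regularized_inverse_factor(f4m.covariance)
    chi2, a, b, _ = _fit_rank(f4m.values, w, rank)
    weights = _weights_from_fit(a @ b if rank > 0 else np.zeros_like(f4m.values))
    m, q = f4m.shape
    dof = (m - rank) * (q - rank)  # = n_right - k

    # weight SEs: re-fit on each delete-one-block replicate, weighted jackknife
    g_idx = np.flatnonzero(f4m.block_counts > 0)
    g = len(g_idx)
    if g < 2:
        raise ValueError("weight jackknife requires >= 2 non-empty blocks")
    loo_weights = np.empty((g, k))
    for row, j in enumerate(g_idx):
        xj = f4m.delete_one(j)
        if rank == 0:
            loo_weights[row] = 1.0
        else:
            _, aj, bj, _ = _fit_rank(xj, w, rank, init=(a, b), max_iter=500)
            loo_weights[row] = _weights_from_fit(aj @ bj)
    mweights = f4m.block_counts[g_idx]
    n = mweights.sum()
    h = n / mweights
    theta = weights
    theta_dot = g * theta - ((1.0 - mweights / n)[:, None] * loo_weights).sum(axis=0)
    pseudo = h[:, None] * theta[None, :] - (h - 1.0)[:, None] * loo_weights
    var = ((pseudo - theta_dot[None, :]) ** 2 / (h - 1.0)[:, None]).sum(axis=0) / g
    weight_se = np.sqrt(np.maximum(var, 0.0))

    feasible = bool(np.all((weights >= 0.0) & (weights <= 1.0)))
    return AdmixtureFit(
        target=target,
        sources=sources,
        outgroups=outgroups,
        weights=weights,
        weight_se=weight_se,
        chi2=chi2,
        dof=dof,
        p_value=float(stats.chi2.sf(chi2, dof)),
        feasible=feasible,
        n_snps=f4m.n_snps,
        n_blocks=f4m.n_blocks,
    )


@dataclass
class NestedComparison:
    full: AdmixtureFit
    reduced: AdmixtureFit
    threshold: float
    reduced_rejected: bool  # reduced fails while full is acceptable
    preferred: str  # "reduced" (parsimony) or "full"


def nested_model_comparison(
    dataset: GenotypeDataset,
    target: str,
    full_sources: Sequence[str],
    reduced_sources: Sequence[str],
    outgroups: Sequence[str],
    blocks: BlockAssignment,
    threshold: float = 0.05,
) -> NestedComparison:
    """Fit nested admixture models and flag a significant loss of fit.

    The reduced model is preferred on parsimony grounds when both fits are
    acceptable; the full model is preferred when dropping sources makes the
    fit fail the threshold.
    """
    if not set(reduced_sources) < set(full_sources):
        raise ValueError("reduced_sources must be a proper subset of full_sources")
    full = qpadm_fit(dataset, target, full_sources, outgroups, blocks)
    reduced = qpadm_fit(dataset, target, reduced_sources, outgroups, blocks)
    reduced_rejected = reduced.p_value < threshold <= full.p_value
    preferred = "full" if reduced_rejected else "reduced"
    return NestedComparison(full, reduced, threshold, reduced_rejected, preferred)


# ---------------------------------------------------------------------------
# Basal Eurasian alpha and the composed prediction
# ---------------------------------------------------------------------------


@dataclass
class AlphaEstimate:
    population: str
    alpha: float
    se: float
    basal_proxy: str
    nonbasal_source: str
    outgroups: tuple[str, ...]
    fit: AdmixtureFit = field(repr=False, default=None)

    @property
    def within_unit_interval(self) -> bool:
        return 0.0 <= self.alpha <= 1.0


def basal_alpha(
    dataset: GenotypeDataset,
    target: str,
    nonbasal_source: str,
    basal_proxy: str,
    outgroups: Sequence[str],
    blocks: BlockAssignment,
) -> AlphaEstimate:
    """Basal Eurasian proportion of ``target`` via a deep-proxy two-way fit.

    The outgroup set must contain only populations without basal ancestry
    (eastern non-Africans and pre-expansion Eurasian genomes): the proxy's
    weight then reads as the basal proportion because the proxy and the true
    basal lineage are indistinguishable to those outgroups.
    """
    fit = qpadm_fit(dataset, target, (basal_proxy, nonbasal_source), outgroups, blocks)
    alpha, se = fit.weight_of(basal_proxy)
    est = AlphaEstimate(
        population=target,
        alpha=alpha,
        se=se,
        basal_proxy=basal_proxy,
        nonbasal_source=nonbasal_source,
        outgroups=tuple(outgroups),
        fit=fit,
    )
    return est


@dataclass(frozen=True)
class ComposedAlpha:
    estimate: float
    se: float

    def as_percent(self, decimals: int = 1) -> tuple[float, float]:
        return (
            round(100.0 * self.estimate, decimals),
            round(100.0 * self.se, decimals),
        )


def compose_alpha(
    proportion: float,
    proportion_se: float,
    alpha_source: float,
    alpha_source_se: float,
) -> ComposedAlpha:
    """Predicted alpha of a mixed population from one admixture leg.

    If a target owes a fraction ``p`` of its ancestry to a source whose own
    basal proportion is ``a``, unidirectional gene flow predicts the target's
    basal proportion ``p * a``.  The SE is first-order error propagation
    assuming the two estimates are independent:
    ``sqrt(p^2 sa^2 + a^2 sp^2)``.
    """
    if proportion_se < 0 or alpha_source_se < 0:
        raise ValueError("standard errors must be non-negative")
    est = proportion * alpha_source
    se = math.sqrt(
        (proportion * alpha_source_se) ** 2 + (alpha_source * proportion_se) ** 2
    )
    return ComposedAlpha(estimate=est, se=se)
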