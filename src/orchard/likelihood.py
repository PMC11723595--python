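"""Frequency estimation, constrained clonal-proportion fitting, tree scores.

A tree with genotype matrix B implies mutation frequencies F = B U, where
the clonal proportions U satisfy U >= 0 and per-sample column sums <= 1
(the leftover is the non-cancerous fraction).  Trees are scored with a
binomial read-count likelihood evaluated at a point estimate U* obtained
by projecting the observed frequencies onto the cone of tree-consistent
frequency matrices — a weighted, constrained least-squares problem solved
per sample.
"""

from __future__ import annotations

import math
from typing import Sequence

import numba
import numpy as np
from scipy.special import gammaln

from .io_formats import VafDataset
from .phylo_model import MutationTree, count_extensions, tree_to_genotype

LAMBDA_EPS = 1e-10  # clip for VAFs before taking logs


def estimate_frequencies(data: VafDataset) -> np.ndarray:
    """Observed mutation frequencies F_hat = clip(vaf / omega, 0, 1).

    Entries with no mapped reads are set to 0.  A variant read observed at
    a locus with omega = 0 is impossible and rejected.
    """
    N = data.total_reads
    if ((data.omega == 0) & (data.var_reads > 0)).any():
        raise ValueError("variant reads observed where variant read probability is 0")
    lam = data.vaf()
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(N > 0, lam / np.where(data.omega > 0, data.omega, 1.0), 0.0)
    return np.clip(F, 0.0, 1.0)


def compute_weights(data: VafDataset) -> np.ndarray:
    """Inverse-variance weights for the frequency-projection objective.

    By the delta method, Var(F_hat) = lam(1-lam) / (N omega^2) under
    binomial sampling, so W = omega^2 N / (lam~ (1 - lam~)) with a
    Jeffreys-style smoothed VAF lam~ = (b + 1/2)/(N + 1) that keeps the
    variance strictly positive at lam in {0, 1}.  W = 0 where N = 0.
    """
    N = data.total_reads
    lam_s = (data.var_reads + 0.5) / (N + 1.0)
    W = data.omega ** 2 * N / (lam_s * (1.0 - lam_s))
    return np.where(N > 0, W, 0.0)


def binom_logpmf(b: np.ndarray, N: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Elementwise log Binom(b | N, lam) with lam clipped to
    [LAMBDA_EPS, 1 - LAMBDA_EPS]; entries with N = 0 contribute 0."""
    b = np.asarray(b, dtype=np.float64)
    N = np.asarray(N, dtype=np.float64)
    lam = np.clip(np.asarray(lam, dtype=np.float64), LAMBDA_EPS, 1.0 - LAMBDA_EPS)
    a = N - b
    out = (
        gammaln(N + 1.0) - gammaln(b + 1.0) - gammaln(a + 1.0)
        + b * np.log(lam) + a * np.log1p(-lam)
    )
    return np.where(N > 0, out, 0.0)


def projection_objective(B: np.ndarray, U: np.ndarray, F_hat: np.ndarray,
                         W: np.ndarray) -> float:
    """Weighted squared error || W ⊙ (F_hat - B U) ||_F^2.

    (The weights multiply the residuals, matching the Frobenius form of the
    quadratic surrogate objective.)
    """
    R = W * (F_hat - B @ U)
    return float(np.sum(R * R))


@numba.njit(cache=True)
def _nnqp_cd(A, c, u, mu, max_sweeps, tol):
    """Cyclic coordinate descent for min 1/2 u'Au - (c - mu 1)'u s.t. u >= 0.

    Each coordinate update is the exact 1-d minimizer clipped at 0; the
    sweep stops when the largest coordinate move falls below ``tol``.
    """
    n = A.shape[0]
    for _ in range(max_sweeps):
        delta = 0.0
        for i in range(n):
            if A[i, i] <= 1e-300:
                new = 0.0  # coordinate absent from the objective
            else:
                r = c[i] - mu
                for j in range(n):
                    if j != i:
                        r -= A[i, j] * u[j]
                new = r / A[i, i]
                if new < 0.0:
                    new = 0.0
            d = new - u[i]
            if d < 0.0:
                d = -d
            if d > delta:
                delta = d
            u[i] = new
        if delta < tol:
            break
    return u


@numba.njit(cache=True)
def _solve_columns(B, F_hat, W, U):
    """Solve the per-sample QPs min ||w ⊙ (f - Bu)||^2, u >= 0, sum u <= 1.

    The simplex-cap constraint is enforced through its scalar dual mu >= 0
    (the KKT multiplier of 1'u <= 1): the inner nonnegative QP is solved by
    coordinate descent, and mu is found by bisection on the monotone map
    mu -> sum(u*(mu)).  U is updated in place (warm start on entry).
    """
    n, m = F_hat.shape
    for s in range(m):
        w2 = W[:, s] * W[:, s]
        A = np.empty((n, n))
        c = np.empty(n)
        for i in range(n):
            c[i] = 0.0
            for k in range(n):
                c[i] += B[k, i] * w2[k] * F_hat[k, s]
            for j in range(i, n):
                acc = 0.0
                for k in range(n):
                    acc += B[k, i] * w2[k] * B[k, j]
                A[i, j] = acc
                A[j, i] = acc
        u = U[:, s]
        for i in range(n):
            if u[i] < 0.0:
                u[i] = 0.0
        u = _nnqp_cd(A, c, u, 0.0, 4000, 1e-14)
        total = u.sum()
        if total > 1.0 + 1e-12:
            lo = 0.0
            hi = 1.0
            for _ in range(60):
                u = _nnqp_cd(A, c, u, hi, 4000, 1e-14)
                if u.sum() <= 1.0:
                    break
                lo = hi
                hi *= 4.0
            for _ in range(100):
                mid = 0.5 * (lo + hi)
                u = _nnqp_cd(A, c, u, mid, 1000, 1e-14)
                if u.sum() > 1.0:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < 1e-15:
                    break
            u = _nnqp_cd(A, c, u, hi, 4000, 1e-14)
        U[:, s] = u
    return U


def fit_clonal_proportions(
    B: np.ndarray,
    F_hat: np.ndarray,
    W: np.ndarray,
    warm_start: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize || W ⊙ (F_hat - B U) ||^2 s.t. U >= 0, column sums <= 1.

    The problem separates by sample into small convex QPs, solved exactly
    by coordinate descent on the nonnegativity cone with the sum
    constraint handled through its scalar dual multiplier (bisection).
    Warm starts from a related tree's U speed up repeated calls during the
    search.  Returns (U*, F* = B U*).
    """
    B = np.ascontiguousarray(B, dtype=np.float64)
    F_hat = np.ascontiguousarray(F_hat, dtype=np.float64)
    W = np.ascontiguousarray(W, dtype=np.float64)
    n, m = F_hat.shape
    if B.shape != (n, n) or W.shape != (n, m):
        raise ValueError("dimension mismatch between B, F_hat and W")
    U = np.zeros((n, m)) if warm_start is None else \
        np.ascontiguousarray(np.asarray(warm_start, dtype=np.float64).copy())
    if U.shape != (n, m):
        raise ValueError("warm start has wrong shape")
    U = _solve_columns(B, F_hat, W, U)
    return U, B @ U


def data_log_likelihood(
    data: VafDataset,
    B: np.ndarray,
    U: np.ndarray,
    rows: Sequence[int] | None = None,
) -> float:
    """Binomial log likelihood of the read counts under F = B U.

    ``rows`` selects the dataset rows (mutation indices) that the rows of
    ``B``/``U`` refer to, in order; defaults to all mutations in input
    order.  Samples are exchangeable: the result is a plain sum over
    samples and mutations.
    """
    F = np.asarray(B, dtype=np.float64) @ np.asarray(U, dtype=np.float64)
    if rows is None:
        rows = range(data.n_mutations)
    rows = list(rows)
    b = data.var_reads[rows]
    N = data.total_reads[rows]
    omega = data.omega[rows]
    return float(binom_logpmf(b, N, omega * F).sum())


def tree_log_score(
    tree: MutationTree,
    data: VafDataset,
    order_prefix: Sequence[int],
    F_hat: np.ndarray | None = None,
    W: np.ndarray | None = None,
    warm_start: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Unnormalized log score phi of a (partial) tree.

    phi = log P(D_placed | B, U*) + sum over insertion steps of -log(tau),
    where tau is the number of valid placements of the next mutation into
    the preceding partial tree (the uniform placement prior) and the
    likelihood covers only the placed mutations' data.  ``order_prefix``
    is the first ``l`` labels of the insertion order pi; the intermediate
    partial trees are the restrictions of ``tree`` to its prefixes.

    Returns ``(phi, U*)`` with U rows in ``order_prefix`` order.
    """
    labels = list(order_prefix)
    if set(labels) != set(tree.labels):
        raise ValueError("order_prefix must list exactly the tree's mutations")
    if F_hat is None:
        F_hat = estimate_frequencies(data)
    if W is None:
        W = compute_weights(data)

    prior = 0.0
    for ell in range(1, len(labels)):
        prior -= math.log(count_extensions(tree.restrict(labels[:ell])))

    rows = [lab - 1 for lab in labels]
    B = tree_to_genotype(tree, order=labels).astype(np.float64)
    U, _ = fit_clonal_proportions(B, F_hat[rows], W[rows], warm_start=warm_start)
    loglik = data_log_likelihood(data, B, U, rows=rows)
    return prior + loglik, U
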