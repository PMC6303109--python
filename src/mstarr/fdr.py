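"""False discovery rate control.

Storey q-values are the pipeline's FDR machinery for enhancer and
methylation-dependent enhancer calls; Benjamini-Hochberg step-up adjustment
is provided as a cross-check (with pi0 fixed at 1, the two coincide).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import InputError

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


@dataclass
class QValueResult:
    pvalues: np.ndarray
    qvalues: np.ndarray
    pi0: float
    lambda_grid: np.ndarray
    pi0_lambda: np.ndarray
    pi0_method: str = "smoother"


def _check_pvalues(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    return p


def _pi0_smoother(pi0_lambda: np.ndarray, grid: np.ndarray) -> float:
    # cubic least-squares smooth over the lambda grid, evaluated at max(lambda)
    coef = np.polynomial.polynomial.polyfit(grid, pi0_lambda, deg=3)
    return float(np.polynomial.polynomial.polyval(grid.max(), coef))


def _pi0_bootstrap(p: np.ndarray, grid: np.ndarray, n_boot: int = 100,
                   seed: int = 0) -> float:
    """Storey (2004) bootstrap pi0: pick lambda minimizing estimated MSE."""
    m = p.size
    pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in grid])
    min_pi0 = pi0_lambda.min()
    rng = np.random.default_rng(seed)
    mse = np.zeros(grid.size)
    for _ in range(n_boot):
        pb = p[rng.integers(0, m, size=m)]
        pi0_b = np.array([(pb > lam).mean() / (1.0 - lam) for lam in grid])
        mse += (pi0_b - min_pi0) ** 2
    return float(pi0_lambda[np.argmin(mse)])


def estimate_pi0(pvals, lambda_grid=None, method: str = "smoother") -> tuple[float, np.ndarray, str]:
    """Estimate the null proportion pi0 from a p-value distribution."""
    p = _check_pvalues(pvals)
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in grid])
    used = method
    if method == "smoother":
        pi0 = _pi0_smoother(pi0_lambda, grid)
        if not (0.0 < pi0 <= 1.0):
            pi0 = _pi0_bootstrap(p, grid)
            used = "bootstrap"
    elif method == "bootstrap":
        pi0 = _pi0_bootstrap(p, grid)
    else:
        raise InputError(f"unknown pi0 method: {method!r}")
    pi0 = min(pi0, 1.0)
    if pi0 <= 0.0:
        # degenerate distributions (e.g. all p tiny); smallest sensible value
        pi0 = max(float(pi0_lambda.min()), 1.0 / p.size)
        pi0 = min(pi0, 1.0)
        used = "floor"
    return pi0, pi0_lambda, used


def storey_qvalue(pvals, lambda_grid=None, pi0: float | None = None,
                  pi0_method: str = "smoother") -> QValueResult:
    """Storey q-values.

    pi0 is estimated as #{p > lambda} / (m (1 - lambda)) over the lambda
    grid, smoothed by a cubic fit evaluated at the largest lambda (bootstrap
    fallback if the smooth leaves (0, 1]). q(p_i) is pi0 times the
    cumulative minimum of m * p_(j) / j taken from the largest p downward.

    Passing ``pi0=1`` reproduces Benjamini-Hochberg adjusted p-values.
    """
    p = _check_pvalues(pvals)
    m = p.size
    if m < 2:
        raise InputError("need at least 2 p-values")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if pi0 is None:
        pi0_hat, pi0_lambda, used = estimate_pi0(p, grid, method=pi0_method)
    else:
        if not (0.0 < pi0 <= 1.0):
            raise InputError("pi0 must lie in (0, 1]")
        pi0_hat, used = float(pi0), "fixed"
        pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in grid])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(pi0_hat * q_sorted, 1.0)
    return QValueResult(pvalues=p, qvalues=q, pi0=pi0_hat, lambda_grid=grid,
                        pi0_lambda=pi0_lambda, pi0_method=used)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = _check_pvalues(pvals)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
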