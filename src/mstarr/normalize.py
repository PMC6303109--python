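"""Count normalization: log2-CPM with precision and sample quality weights.

Counts are transformed to log2 counts per million with a 0.5 offset. A
mean-variance trend is then fitted by locally weighted regression of the
square-root residual standard deviation on average log2-CPM, and each
observation receives an inverse predicted-variance precision weight at its
fitted value. Optionally, per-sample quality weights down-weight noisy
replicates; they are estimated by alternating between window-wise weighted
fits and per-sample residual variance factors, and are normalized to
geometric mean 1.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import ConfigurationError, CountMatrix, InputError, NormalizedMatrix


def log_cpm(counts, library_sizes) -> np.ndarray:
    """log2((count + 0.5) / (library_size + 1) * 1e6)."""
    c = np.asarray(counts, dtype=float)
    lib = np.asarray(library_sizes, dtype=float)
    if np.any(lib <= 0):
        raise InputError("library sizes must be positive")
    return np.log2((c + 0.5) / (lib + 1.0) * 1e6)


def design_matrix(samples: pd.DataFrame, interaction: bool = True) -> np.ndarray:
    """Default design: intercept, type, condition (and their interaction).

    Codings: type t = 0 for DNA, 1 for RNA; condition c = 0 for
    unmethylated, 1 for methylated.
    """
    t = (samples["type"].to_numpy() == "RNA").astype(float)
    c = (samples["condition"].to_numpy() == "methylated").astype(float)
    cols = [np.ones_like(t), t, c]
    if interaction:
        cols.append(t * c)
    return np.column_stack(cols)


def _rowwise_ols_residual_sd(values: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residual SD and fitted values from per-row OLS with a shared design."""
    n, p = X.shape
    if n - p < 2:
        raise ConfigurationError(
            f"need >= 2 residual degrees of freedom (n={n}, p={p})")
    pinv = np.linalg.pinv(X)          # p x n
    beta = values @ pinv.T            # W x p
    fitted = beta @ X.T               # W x n
    resid = values - fitted
    sd = np.sqrt((resid ** 2).sum(axis=1) / (n - p))
    return sd, fitted


def precision_weights(values: np.ndarray, X: np.ndarray, span: float = 0.5,
                      iterations: int = 4) -> tuple[np.ndarray, pd.DataFrame]:
    """Observation weights from the fitted mean-variance trend.

    The trend regresses sqrt(residual SD) on average log2-CPM via lowess
    (default span 0.5, 4 robustness iterations); the weight of each
    observation is the inverse fourth power of the trend value interpolated
    at that observation's fitted log2-CPM (i.e. inverse predicted variance).
    """
    values = np.asarray(values, dtype=float)
    sd, fitted = _rowwise_ols_residual_sd(values, X)
    sx = values.mean(axis=1)
    sy = np.sqrt(sd)
    smoothed = lowess(sy, sx, frac=span, it=iterations, return_sorted=True)
    tx, ty = smoothed[:, 0], smoothed[:, 1]
    # flat extrapolation outside the observed mean range
    pred = np.interp(fitted, tx, ty)
    pred = np.clip(pred, max(ty[ty > 0].min() if np.any(ty > 0) else 1e-4, 1e-4), None)
    weights = pred ** -4
    trend = pd.DataFrame({"avg_log_cpm": tx, "sqrt_resid_sd": ty})
    return weights, trend


def sample_quality_weights(values: np.ndarray, X: np.ndarray,
                           obs_weights: np.ndarray | None = None,
                           iterations: int = 2) -> np.ndarray:
    """Per-sample variance factors, returned as weights with geometric mean 1.

    Alternates (at most ``iterations`` times) between window-wise weighted
    least squares fits and estimation of per-sample residual variance
    factors; a sample whose residuals are systematically inflated receives a
    proportionally smaller weight.
    """
    values = np.asarray(values, dtype=float)
    W, n = values.shape
    if n < 3:
        raise ConfigurationError(f"quality weights need >= 3 samples, got {n}")
    p = X.shape[1]
    if obs_weights is None:
        obs_weights = np.ones_like(values)
    sw = np.ones(n)
    for _ in range(iterations):
        w = obs_weights * sw
        beta = _wls_beta(values, w, X)
        resid = values - beta @ X.T
        # weighted squared residuals standardized by each window's own scale
        num = obs_weights * resid ** 2
        sigma2 = (w * resid ** 2).sum(axis=1) / max(n - p, 1)
        sigma2 = np.where(sigma2 <= 0, np.nan, sigma2)
        z = num / sigma2[:, None]
        factors = np.nanmean(z, axis=0)
        factors = np.clip(factors, 1e-6, None)
        sw = 1.0 / factors
        sw = sw / np.exp(np.mean(np.log(sw)))
    return sw


def _wls_beta(values: np.ndarray, weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Batched weighted least squares coefficients (one weight row per window)."""
    A = np.einsum("wn,np,nq->wpq", weights, X, X)
    b = np.einsum("wn,np,wn->wp", weights, X, values)
    return np.linalg.solve(A, b[..., None])[..., 0]


def normalize_counts(counts: CountMatrix, design: np.ndarray | None = None,
                     span: float = 0.5, quality_weights: bool = True) -> NormalizedMatrix:
    """Full normalization: log2-CPM, precision weights, quality weights.

    RNA and DNA samples are normalized jointly in one matrix, as both enter
    the same per-window models downstream.
    """
    X = design_matrix(counts.samples) if design is None else design
    lib = counts.samples["lib_size"].to_numpy(dtype=float)
    vals = log_cpm(counts.counts.to_numpy(), lib[None, :])
    obs_w, trend = precision_weights(vals, X, span=span)
    if quality_weights:
        sw = sample_quality_weights(vals, X, obs_weights=obs_w)
    else:
        sw = np.ones(counts.n_samples)
    values = pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    obs = pd.DataFrame(obs_w, index=values.index, columns=values.columns)
    sweights = pd.Series(sw, index=values.columns, name="sample_weight")
    return NormalizedMatrix(values=values, obs_weights=obs, sample_weights=sweights,
                            trend=trend, samples=counts.samples)
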