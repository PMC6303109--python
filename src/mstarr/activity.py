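"""Per-window enhancer activity models.

Each analyzed window is tested with two weighted linear models on its
normalized abundances y_i:

* the nested model  y_i = mu + t_i b1 I[c_i=0] + t_i b2 I[c_i=1] + e_i,
  where t_i codes sample type (DNA input 0, mRNA 1) and c_i condition
  (unmethylated 0, methylated 1). b1 and b2 estimate the mRNA-over-DNA
  excess within the unmethylated and methylated condition respectively;
  positive values indicate regulatory (enhancer-like) activity.

* the interaction model  y_i = mu + t_i bt + c_i bc + t_i c_i btxc + e_i,
  whose interaction coefficient btxc measures methylation dependence: a
  negative btxc means the mRNA/DNA excess is larger when unmethylated.

A window is called an enhancer if b1 or b2 is positive with q-value below
the FDR threshold; among enhancers, a window is methylation-dependent (MD)
if the interaction q-value (computed over the enhancer subset only) passes
the same threshold, with direction given by the sign of btxc.

The public surface follows the Model/Results idiom: build an
:class:`ActivityModel` from a normalized matrix, ``fit()`` it, and read
estimates, p/q-values and calls off the returned :class:`ActivityResults`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigurationError, NormalizedMatrix
from .fdr import storey_qvalue, bh_adjust

UNMETH_HIGHER = "unmeth_higher"
METH_HIGHER = "meth_higher"
NONE = "none"

# reason codes for per-window NA results
OK = ""
RANK_DEFICIENT = "rank_deficient"
EXACT_FIT = "exact_fit"


def _type_condition_codes(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = (samples["type"].to_numpy() == "RNA").astype(float)
    c = (samples["condition"].to_numpy() == "methylated").astype(float)
    return t, c


def nested_design(samples: pd.DataFrame) -> np.ndarray:
    """Design [1, t*I(c=0), t*I(c=1)]."""
    t, c = _type_condition_codes(samples)
    return np.column_stack([np.ones_like(t), t * (1 - c), t * c])


def interaction_design(samples: pd.DataFrame) -> np.ndarray:
    """Design [1, t, c, t*c]."""
    t, c = _type_condition_codes(samples)
    return np.column_stack([np.ones_like(t), t, c, t * c])


def wls_fit(values: np.ndarray, weights: np.ndarray, X: np.ndarray):
    """Batched per-window weighted least squares with t-statistics.

    ``values`` and ``weights`` are (windows x samples); the design is
    shared. Returns (beta, se, pvals, sigma2, df). Windows whose weighted
    normal equations are singular get NaN rows; exact fits (zero residual
    variance) get NaN standard errors and p-values.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ConfigurationError(f"no residual degrees of freedom (n={n}, p={p})")
    A = np.einsum("wn,np,nq->wpq", weights, X, X)
    b = np.einsum("wn,np,wn->wp", weights, X, values)
    ok = np.abs(np.linalg.det(A)) > 1e-12 * np.abs(A).max(axis=(1, 2)) ** p
    beta = np.full(b.shape, np.nan)
    Ainv = np.full(A.shape, np.nan)
    if ok.any():
        Ainv[ok] = np.linalg.inv(A[ok])
        beta[ok] = np.einsum("wpq,wq->wp", Ainv[ok], b[ok])
    resid = values - np.einsum("wp,np->wn", beta, X)
    sigma2 = np.einsum("wn,wn->w", weights, resid ** 2) / df
    var_beta = sigma2[:, None] * np.einsum("wpp->wp", Ainv)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(var_beta)
        tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    exact = sigma2 <= 1e-12 * np.nanmax(np.abs(values), axis=1) ** 2
    pvals[exact] = np.nan
    se[exact] = np.nan
    return beta, se, pvals, sigma2, df


def fit_nested(values, weights, samples: pd.DataFrame) -> pd.DataFrame:
    """Nested model fits for one or many windows.

    Returns a DataFrame with mu, beta1, beta2, se1, se2, p1, p2,
    residual_variance, df and a reason code for degenerate windows.
    """
    X = nested_design(samples)
    beta, se, pvals, sigma2, df = wls_fit(values, weights, X)
    out = pd.DataFrame({
        "mu": beta[:, 0], "beta1": beta[:, 1], "beta2": beta[:, 2],
        "se1": se[:, 1], "se2": se[:, 2],
        "p1": pvals[:, 1], "p2": pvals[:, 2],
        "residual_variance": sigma2, "df": df,
    })
    out["reason"] = _reasons(beta[:, 0], sigma2, pvals[:, 1])
    return out


def fit_interaction(values, weights, samples: pd.DataFrame) -> pd.DataFrame:
    """Interaction model fits for one or many windows."""
    X = interaction_design(samples)
    for cell in ((0, 0), (0, 1), (1, 0), (1, 1)):
        t, c = _type_condition_codes(samples)
        if not np.any((t == cell[0]) & (c == cell[1])):
            raise ConfigurationError(
                f"empty design cell type={cell[0]} condition={cell[1]}")
    beta, se, pvals, sigma2, df = wls_fit(values, weights, X)
    out = pd.DataFrame({
        "mu_full": beta[:, 0], "beta_t": beta[:, 1], "beta_c": beta[:, 2],
        "beta_txc": beta[:, 3], "se_txc": se[:, 3], "p_txc": pvals[:, 3],
        "residual_variance_full": sigma2, "df_full": df,
    })
    out["reason_full"] = _reasons(beta[:, 0], sigma2, pvals[:, 3])
    return out


def _reasons(beta0, sigma2, p) -> np.ndarray:
    reason = np.full(beta0.shape, OK, dtype=object)
    reason[~np.isfinite(beta0)] = RANK_DEFICIENT
    reason[np.isfinite(beta0) & ~np.isfinite(p) & (sigma2 <= 1e-12)] = EXACT_FIT
    return reason


def call_enhancers(frame: pd.DataFrame, q_threshold: float = 0.10,
                   fdr_method: str = "storey",
                   alternative: str = "greater") -> pd.DataFrame:
    """Attach q1/q2 and the enhancer call to a nested-fit frame.

    is_enhancer = (beta1 > 0 and q1 < threshold) or (beta2 > 0 and
    q2 < threshold); q-values are computed across all tested windows.
    With ``alternative="greater"`` (default) the q-values come from
    upper-tail p-values, matching the directional call; "two-sided" uses
    the reported two-sided p-values directly.
    """
    out = frame.copy()
    for k in ("1", "2"):
        p = out[f"p{k}"].to_numpy(dtype=float)
        if alternative == "greater":
            # one-sided upper-tail p from the two-sided p and the sign
            sign_pos = out[f"beta{k}"].to_numpy() > 0
            p = np.where(sign_pos, p / 2.0, 1.0 - p / 2.0)
        elif alternative != "two-sided":
            raise ConfigurationError(f"unknown alternative {alternative!r}")
        out[f"q{k}"] = _adjust(p, fdr_method)
    out["is_enhancer"] = (
        ((out["beta1"] > 0) & (out["q1"] < q_threshold)) |
        ((out["beta2"] > 0) & (out["q2"] < q_threshold))
    ).fillna(False)
    return out


def call_md(frame: pd.DataFrame, q_threshold: float = 0.10,
            fdr_method: str = "storey") -> pd.DataFrame:
    """Attach q_txc (over the enhancer subset only) and the MD call.

    The MD test set is the enhancer set: q-values for the interaction term
    are computed only among windows already called enhancers. Direction is
    ``unmeth_higher`` for negative btxc (more active when unmethylated),
    ``meth_higher`` for positive.
    """
    out = frame.copy()
    out["q_txc"] = np.nan
    enh = out["is_enhancer"].to_numpy(dtype=bool) & np.isfinite(out["p_txc"].to_numpy(dtype=float))
    if enh.sum() >= 2:
        out.loc[enh, "q_txc"] = _adjust(out.loc[enh, "p_txc"].to_numpy(), fdr_method)
    out["is_md"] = (out["is_enhancer"] & (out["q_txc"] < q_threshold)).fillna(False)
    direction = np.where(out["beta_txc"] < 0, UNMETH_HIGHER,
                         np.where(out["beta_txc"] > 0, METH_HIGHER, NONE))
    out["md_direction"] = np.where(out["is_md"], direction, NONE)
    return out


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    q = np.full(p.shape, np.nan)
    fin = np.isfinite(p)
    if fin.sum() >= 2:
        if method == "storey":
            q[fin] = storey_qvalue(p[fin]).qvalues
        elif method == "bh":
            q[fin] = bh_adjust(p[fin])
        else:
            raise ConfigurationError(f"unknown fdr method {method!r}")
    return q


class ActivityModel:
    """Per-window activity model over a normalized count matrix.

    Parameters
    ----------
    normalized : NormalizedMatrix
        Joint RNA/DNA log2-CPM values with weights, as produced by
        :func:`mstarr.normalize.normalize_counts`.
    use_weights : bool
        If False, fit ordinary (unweighted) least squares for comparison.
    """

    def __init__(self, normalized: NormalizedMatrix, use_weights: bool = True):
        if normalized.samples is None:
            raise ConfigurationError("normalized matrix lacks sample metadata")
        self.normalized = normalized
        self.use_weights = use_weights

    @classmethod
    def from_counts(cls, counts, **norm_kwargs) -> "ActivityModel":
        from .normalize import normalize_counts
        return cls(normalize_counts(counts, **norm_kwargs))

    def fit(self, q_threshold: float = 0.10, fdr_method: str = "storey",
            alternative: str = "greater", center_interaction_null: bool = True,
            ) -> "ActivityResults":
        """Fit both models for every window and attach calls.

        ``alternative`` controls the enhancer q-values: "greater" (default)
        computes them from upper-tail p-values, matching the directional
        call rule (beta > 0 at FDR < threshold); "two-sided" uses the plain
        two-sided p-values. ``center_interaction_null`` subtracts the
        genome-wide median interaction estimate before testing — an
        empirical-null location correction for the composition shift that
        arises because active windows absorb a condition-dependent share of
        the mRNA library (almost all windows carry no interaction, so the
        median estimates the null offset).
        """
        values = self.normalized.values.to_numpy()
        if self.use_weights:
            weights = self.normalized.combined_weights.to_numpy()
        else:
            weights = np.ones_like(values)
        samples = self.normalized.samples
        nested = fit_nested(values, weights, samples)
        inter = fit_interaction(values, weights, samples)
        if center_interaction_null and len(inter) >= 50:
            offset = float(np.nanmedian(inter["beta_txc"]))
            inter["beta_txc"] = inter["beta_txc"] - offset
            with np.errstate(invalid="ignore", divide="ignore"):
                tstat = inter["beta_txc"] / inter["se_txc"]
                inter["p_txc"] = 2.0 * stats.t.sf(np.abs(tstat), inter["df_full"])
            inter.loc[~np.isfinite(inter["se_txc"]), "p_txc"] = np.nan
            inter.attrs["null_offset"] = offset
        frame = pd.concat([nested, inter], axis=1)
        frame.index = self.normalized.values.index
        frame = call_enhancers(frame, q_threshold, fdr_method,
                               alternative=alternative)
        frame = call_md(frame, q_threshold, fdr_method)
        return ActivityResults(frame, q_threshold=q_threshold)


@dataclass
class ActivityResults:
    """Per-window estimates, p/q-values and enhancer/MD calls."""

    frame: pd.DataFrame
    q_threshold: float = 0.10

    @property
    def n_windows(self) -> int:
        return len(self.frame)

    @property
    def n_enhancers(self) -> int:
        return int(self.frame["is_enhancer"].sum())

    @property
    def n_md(self) -> int:
        return int(self.frame["is_md"].sum())

    @property
    def direction_split(self) -> float:
        """Fraction of MD enhancers more active when unmethylated."""
        md = self.frame[self.frame["is_md"]]
        if len(md) == 0:
            return float("nan")
        return float((md["md_direction"] == UNMETH_HIGHER).mean())

    def summary(self) -> str:
        lines = [
            "Per-window activity model results",
            "=" * 40,
            f"windows tested        {self.n_windows:>10d}",
            f"enhancers (q<{self.q_threshold:.2f})    {self.n_enhancers:>10d}",
            f"MD enhancers          {self.n_md:>10d}",
        ]
        if self.n_md:
            lines.append(f"more active unmeth.   {self.direction_split:>10.1%}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cols = ["mu", "beta1", "beta2", "p1", "p2", "q1", "q2",
                "beta_t", "beta_c", "beta_txc", "p_txc", "q_txc",
                "residual_variance", "df", "is_enhancer", "is_md",
                "md_direction", "reason"]
        self.frame[cols].to_csv(path, sep="\t", index_label="window")
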