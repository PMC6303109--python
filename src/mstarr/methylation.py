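"""CpG methylation dynamics on the transfected plasmid pool.

Site-level methylation is estimated from bisulfite counts; conversion
efficiency comes from an unmethylated spike-in; post-transfection
convergence toward endogenous methylation is quantified by Spearman
correlation; TF-binding-site-specific methylation changes and their
family-level enrichment among the most dynamic TFs are computed
hypergeometrically; and interferon-alpha (IFNA) induced activity changes
are coupled to methylation loss via quantile-stratified correlations and a
logistic model of demethylation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import InputError
from .enrichment import family_hypergeometric


def methylation_level(meth, total, min_cov: int = 1):
    """meth/total where total >= min_cov, else NaN (absent marker)."""
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(meth > total):
        raise InputError("methylated count exceeds total count")
    if np.any(total < 0):
        raise InputError("negative total count")
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(total >= min_cov, meth / np.where(total == 0, np.nan, total), np.nan)
    return level if level.shape else float(level)


def conversion_efficiency(meth, total):
    """Bisulfite conversion efficiency from an unmethylated spike-in.

    efficiency = 1 - (sum methylated calls / sum total calls) over spike-in
    cytosines; NaN where a sample has zero spike-in coverage. Accepts
    site x sample arrays and returns one estimate per sample.
    """
    meth = np.atleast_2d(np.asarray(meth, dtype=float))
    total = np.atleast_2d(np.asarray(total, dtype=float))
    tot = total.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        eff = 1.0 - meth.sum(axis=0) / np.where(tot == 0, np.nan, tot)
    return eff


def convergence_correlation(post_levels: np.ndarray, endogenous: np.ndarray,
                            min_sites: int = 10) -> tuple[float, float]:
    """Spearman correlation of mean post-transfection level with endogenous.

    ``post_levels`` holds per-site mean levels (NaN where uncovered);
    jointly covered sites below ``min_sites`` raise an error.
    """
    post = np.asarray(post_levels, dtype=float)
    endo = np.asarray(endogenous, dtype=float)
    ok = np.isfinite(post) & np.isfinite(endo)
    if ok.sum() < min_sites:
        raise InputError(f"only {int(ok.sum())} jointly covered sites (< {min_sites})")
    rho, p = stats.spearmanr(post[ok], endo[ok])
    return float(rho), float(p)


def site_mean_levels(meth: np.ndarray, total: np.ndarray, sample_mask=None,
                     min_cov: int = 1) -> np.ndarray:
    """Per-site mean methylation across (a subset of) samples.

    A site's mean uses only samples covering it at >= min_cov; sites
    covered in no sample get NaN.
    """
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    if sample_mask is not None:
        meth = meth[:, sample_mask]
        total = total[:, sample_mask]
    covered = total >= min_cov
    with np.errstate(invalid="ignore", divide="ignore"):
        lev = np.where(covered, meth / np.where(total == 0, np.nan, total), np.nan)
        out = np.nanmean(np.where(covered, lev, np.nan), axis=1)
    return out


def tfbs_methylation_delta(initial_level: np.ndarray, post_level: np.ndarray,
                           tf_labels: np.ndarray, min_sites: int = 100) -> pd.Series:
    """Mean methylation change per TF over CpGs in its binding sites.

    delta = mean(post - initial) across covered CpGs; TFs with fewer than
    ``min_sites`` covered CpGs are omitted.
    """
    tf = np.asarray(tf_labels, dtype=object)
    if tf.size == 0:
        raise InputError("empty TFBS map")
    init = np.asarray(initial_level, dtype=float)
    post = np.asarray(post_level, dtype=float)
    ok = np.isfinite(init) & np.isfinite(post) & (tf != "")
    frame = pd.DataFrame({"tf": tf[ok], "delta": post[ok] - init[ok]})
    grouped = frame.groupby("tf")["delta"]
    counts = grouped.size()
    means = grouped.mean()
    keep = counts[counts >= min_sites].index
    return means.loc[keep].sort_index()


def top_k_family_enrichment(deltas: pd.Series, family_map: pd.Series,
                            k: int = 20, direction: str = "loss") -> pd.DataFrame:
    """Family enrichment among the top-k most dynamic TFs.

    Ranks TFs by methylation change (most negative first for ``loss``,
    most positive first for ``gain``; ties broken by TF name) and tests
    each family's representation in the top k against all analyzable TFs.
    """
    if k > len(deltas):
        raise InputError(f"k={k} exceeds {len(deltas)} analyzable TFs")
    ordered = deltas.sort_index()  # name order breaks ties deterministically
    ascending = direction == "loss"
    ranked = ordered.sort_values(ascending=ascending, kind="mergesort")
    top = set(ranked.index[:k])
    fams = family_map.reindex(deltas.index)
    rows = []
    for fam in sorted(fams.dropna().unique()):
        members = set(fams.index[fams == fam])
        k_fam = len(top & members)
        if k_fam == 0:
            rows.append({"family": fam, "k_in_top": 0, "family_size": len(members),
                         "fold": 0.0, "p": 1.0})
            continue
        fold, p = family_hypergeometric(k_fam, k, len(members), len(deltas))
        rows.append({"family": fam, "k_in_top": k_fam, "family_size": len(members),
                     "fold": fold, "p": p})
    return pd.DataFrame(rows).set_index("family")


def ifna_effect(values: pd.DataFrame, treatment: pd.Series) -> pd.Series:
    """Per-window mean difference in normalized counts, IFNA+ minus IFNA-.

    Windows missing in one treatment group (all-NaN there) are excluded.
    """
    plus_cols = treatment.index[treatment == "IFNA+"]
    minus_cols = treatment.index[treatment == "IFNA-"]
    if len(plus_cols) == 0 or len(minus_cols) == 0:
        raise InputError("both IFNA+ and IFNA- samples are required")
    plus = values[list(plus_cols)].mean(axis=1)
    minus = values[list(minus_cols)].mean(axis=1)
    out = plus - minus
    return out.dropna()


def ifna_methylation_coupling(effects: pd.Series, deltas: pd.Series,
                              n_quantiles: int = 15, min_pairs: int = 10) -> pd.DataFrame:
    """Spearman coupling of activity induction and methylation change.

    Pairs the two series on their index, then reports rho overall and
    within progressively restricted upper quantiles of the induction
    effect (cumulative upper tails: stratum q keeps the top (n-q+1)/n of
    effects). Strata with fewer than ``min_pairs`` pairs get NaN.
    """
    paired = pd.concat([effects.rename("effect"), deltas.rename("delta")],
                       axis=1).dropna()
    if len(paired) < min_pairs:
        raise InputError(f"only {len(paired)} pairs (< {min_pairs})")
    rows = []
    for qi in range(n_quantiles):
        cut = paired["effect"].quantile(qi / n_quantiles)
        sub = paired[paired["effect"] >= cut]
        if len(sub) < min_pairs:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(sub["effect"], sub["delta"])
        rows.append({"quantile": qi + 1, "threshold": cut, "n": len(sub),
                     "rho": rho, "p": p})
    return pd.DataFrame(rows).set_index("quantile")


def demethylation_logistic(effects: pd.Series, lost_flags: pd.Series):
    """Logistic model: probability of methylation loss vs. activity change.

    Fits lost ~ effect by maximum likelihood; returns (coefficient, Wald
    p, McFadden pseudo-R2, flag). Complete separation falls back to an
    L2-penalized fit and flags the result.
    """
    paired = pd.concat([effects.rename("effect"), lost_flags.rename("lost")],
                       axis=1).dropna()
    y = paired["lost"].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise InputError("both retained (0) and lost (1) outcomes are required")
    X = sm.add_constant(paired[["effect"]].to_numpy())
    flag = ""
    import warnings
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0)
        if not np.all(np.isfinite(fit.bse)):
            raise np.linalg.LinAlgError
        coef = float(fit.params[1])
        p = float(fit.pvalues[1])
        pseudo_r2 = float(fit.prsquared)
    except Exception:
        fit = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        coef = float(fit.params[1])
        p = np.nan
        ll = sm.Logit(y, X).loglike(fit.params)
        ll0 = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
        pseudo_r2 = float(1.0 - ll / ll0)
        flag = "penalized_fallback"
    return coef, p, pseudo_r2, flag
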