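"""In vivo validation: methylation-expression coupling and luciferase models.

Mirrors two validation arms. First, array-style paired methylation and
expression data across many individuals: probes are filtered on detection
p-value and on constitutive hypo/hypermethylation, CpG sites are paired to
their closest gene within 100 kb, each pair gets a simple linear model of
expression on methylation (M-values), and enrichment of significant pairs
in MD versus non-MD enhancers is tested by Fisher's exact test. Second, a
luciferase reporter validation: a linear mixed model predicting log2
normalized luciferase activity from fragment length and the reporter-assay
activity estimate, with a random intercept per assay batch.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .core import ConfigurationError, InputError
from .enrichment import fisher_exact_2sided
from .fdr import storey_qvalue


def filter_probes(detection_p: pd.Series, mean_level: pd.Series | None = None,
                  detection_threshold: float = 0.05,
                  level_bounds: tuple = (0.1, 0.9)) -> pd.DataFrame:
    """Probe-level filters: detection p-value and constitutive methylation.

    Returns a DataFrame with per-probe keep flags and the reason for
    removal; the mean-level bounds apply only when levels are supplied
    (methylation probes).
    """
    keep = detection_p <= detection_threshold
    reason = pd.Series("", index=detection_p.index, dtype=object)
    reason[~keep] = "detection_p"
    if mean_level is not None:
        lo, hi = level_bounds
        out_of_bounds = (mean_level < lo) | (mean_level > hi)
        reason[keep & out_of_bounds] = "constitutive_level"
        keep &= ~out_of_bounds
    return pd.DataFrame({"keep": keep, "reason": reason})


def pair_sites_to_genes(sites: pd.DataFrame, genes: pd.DataFrame,
                        max_dist: int = 100_000) -> pd.DataFrame:
    """Pair each CpG site with its closest gene, dropping distant sites.

    ``sites`` has columns chrom, pos; ``genes`` has chrom, start, end (the
    TSS-TES span), gene. Distance is 0 inside the span, else the distance
    to the nearer span boundary; sites farther than ``max_dist`` from every
    gene are dropped.
    """
    out = []
    for chrom, ss in sites.groupby("chrom", sort=False):
        gg = genes[genes["chrom"] == chrom]
        if len(gg) == 0:
            continue
        gs = gg["start"].to_numpy()
        ge = gg["end"].to_numpy()
        names = gg["gene"].to_numpy()
        for probe, pos in zip(ss.index, ss["pos"].to_numpy()):
            d = np.where((pos >= gs) & (pos < ge), 0,
                         np.minimum(np.abs(pos - gs), np.abs(pos - (ge - 1))))
            j = int(np.argmin(d))
            if d[j] <= max_dist:
                out.append({"probe": probe, "gene": names[j], "distance": int(d[j])})
    return pd.DataFrame(out, columns=["probe", "gene", "distance"]).set_index("probe")


def site_gene_models(methylation: pd.DataFrame, expression: pd.DataFrame,
                     fdr: float = 0.10) -> pd.DataFrame:
    """Per-pair linear model of expression on methylation across individuals.

    Rows of the two matrices are matched pairs (same index); columns are
    individuals. Returns slope, p, q and a significance flag per pair;
    zero-variance methylation gives an NA row with a reason code.
    """
    m = methylation.to_numpy(dtype=float)
    e = expression.loc[methylation.index].to_numpy(dtype=float)
    n = m.shape[1]
    if n < 3:
        raise InputError(f"need >= 3 individuals, got {n}")
    mc = m - m.mean(axis=1, keepdims=True)
    ec = e - e.mean(axis=1, keepdims=True)
    sxx = (mc ** 2).sum(axis=1)
    sxy = (mc * ec).sum(axis=1)
    zero_var = sxx <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = sxy / sxx
        resid = ec - slope[:, None] * mc
        sigma2 = (resid ** 2).sum(axis=1) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        tstat = slope / se
        p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    exact = (sigma2 <= 1e-14) & ~zero_var
    p[exact] = np.nan
    slope[zero_var] = np.nan
    p[zero_var] = np.nan
    out = pd.DataFrame({"slope": slope, "p": p}, index=methylation.index)
    out["reason"] = ""
    out.loc[zero_var, "reason"] = "zero_variance"
    out.loc[exact, "reason"] = "exact_fit"
    out["q"] = np.nan
    fin = np.isfinite(p)
    if fin.sum() >= 2:
        out.loc[fin, "q"] = storey_qvalue(p[fin]).qvalues
    out["significant"] = (out["q"] < fdr).fillna(False)
    return out


def md_enrichment(pair_results: pd.DataFrame, md_annotation: pd.Series,
                  subset: str = "all", slopes: pd.Series | None = None,
                  promoter: pd.Series | None = None):
    """Fisher enrichment of significant pairs in MD vs non-MD enhancers.

    ``subset`` restricts the tested pairs: "all"; "negative" (negative
    methylation-expression slopes only); "negative_promoter" additionally
    requires the promoter flag.
    """
    frame = pair_results.copy()
    frame["md"] = md_annotation.reindex(frame.index)
    frame = frame[frame["md"].isin(["MD", "non-MD"])]
    if subset in ("negative", "negative_promoter"):
        sl = frame["slope"] if slopes is None else slopes.reindex(frame.index)
        frame = frame[sl < 0]
    if subset == "negative_promoter":
        if promoter is None:
            raise InputError("promoter flags required for the promoter subset")
        frame = frame[promoter.reindex(frame.index).fillna(False)]
    md = frame["md"] == "MD"
    sig = frame["significant"].astype(bool)
    tab = [[int((md & sig).sum()), int((md & ~sig).sum())],
           [int((~md & sig).sum()), int((~md & ~sig).sum())]]
    return fisher_exact_2sided(tab)


def within_vs_across_correlation(methylation: pd.DataFrame,
                                 expression: pd.DataFrame):
    """Within-individual vs across-individual Spearman correlations.

    Within: for each individual (column), the correlation across pairs
    between methylation and expression. Across: for each pair (row), the
    correlation across individuals. With a single individual, the across
    vector is empty.
    """
    e = expression.loc[methylation.index]
    within = np.array([
        stats.spearmanr(methylation[c], e[c]).statistic
        for c in methylation.columns
    ])
    if methylation.shape[1] < 3:
        across = np.array([])
    else:
        m = methylation.to_numpy(dtype=float)
        ex = e.to_numpy(dtype=float)
        rm = stats.rankdata(m, axis=1)
        re_ = stats.rankdata(ex, axis=1)
        rm = rm - rm.mean(axis=1, keepdims=True)
        re_ = re_ - re_.mean(axis=1, keepdims=True)
        denom = np.sqrt((rm ** 2).sum(axis=1) * (re_ ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            across = (rm * re_).sum(axis=1) / denom
    return within, across


@dataclass
class LuciferaseFit:
    """Fixed effects, batch variance, and variance-explained summaries."""

    fixed_effects: pd.Series
    fixed_se: pd.Series
    batch_variance: float
    variance_explained_fixed: float    # squared corr of fixed-effect fit with y
    variance_explained_mstarr: float   # reporter-estimate term alone
    flag: str = ""


def luciferase_mixed_model(table: pd.DataFrame, response: str = "log2_activity",
                           estimate_col: str = "mstarr_estimate") -> LuciferaseFit:
    """Random-intercept mixed model for the luciferase validation.

    Fits ``response ~ length + estimate`` with a random intercept per
    assay batch by REML. Variance explained is reported both for the full
    fixed-effect prediction and for the reporter-assay estimate term
    alone (squared correlation with the response). A singular random
    effect falls back to batch-as-fixed-effect, flagged.
    """
    needed = {response, estimate_col, "length", "batch"}
    if not needed.issubset(table.columns):
        raise InputError(f"luciferase table must have columns {sorted(needed)}")
    formula = f"{response} ~ length + {estimate_col}"
    flag = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, table, groups=table["batch"]).fit(reml=True)
        batch_var = float(fit.cov_re.iloc[0, 0])
        params = fit.fe_params
        se = fit.bse_fe
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError
        fixed_pred = np.asarray(fit.model.exog @ params)
    except Exception:
        flag = "fixed_batch_fallback"
        ols = smf.ols(f"{formula} + C(batch)", table).fit()
        keep = [t for t in ols.params.index if not t.startswith("C(batch)")]
        params = ols.params[keep]
        se = ols.bse[keep]
        batch_var = float(np.var(
            [v for t, v in ols.params.items() if t.startswith("C(batch)")] + [0.0]))
        X = sm.add_constant(table[["length", estimate_col]])
        X = X[["const", "length", estimate_col]]
        fixed_pred = np.asarray(X @ params.values)
    y = table[response].to_numpy(dtype=float)
    r_fixed = np.corrcoef(fixed_pred, y)[0, 1] ** 2 if np.std(fixed_pred) > 0 else 0.0
    est_term = table[estimate_col].to_numpy(dtype=float)
    r_est = np.corrcoef(est_term, y)[0, 1] ** 2 if np.std(est_term) > 0 else 0.0
    return LuciferaseFit(fixed_effects=pd.Series(params),
                         fixed_se=pd.Series(se),
                         batch_variance=batch_var,
                         variance_explained_fixed=float(r_fixed),
                         variance_explained_mstarr=float(r_est),
                         flag=flag)
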