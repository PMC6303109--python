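"""Synthetic data generator with known ground truth.

Emulates the statistical structure of a methylation-sensitive reporter
assay experiment: negative-binomial DNA/RNA counts across replicates in an
unmethylated and a methylated condition, with per-window activity
multipliers (RNA over DNA) that encode enhancer and methylation-dependent
(MD) activity; feature tables for the MD classifier; bisulfite methylation
matrices with TF-binding-site-driven drift toward endogenous levels; paired
methylation/expression data across individuals; and a luciferase-style
validation table.

Defaults mirror the emulated study design: 6 replicates per condition (one
droppable), 200 bp windows, and an 86/14 split of MD enhancers that are
more active when unmethylated versus methylated. Every operation draws from
its own labelled pseudo-random stream derived from the master seed, so
adding one simulation never perturbs another's draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (DNA, METH, RNA, UNMETH, ConfigurationError, CountMatrix,
                   rng_for)


@dataclass
class SimConfig:
    """Configuration of the count-level simulation.

    ``dispersion`` is the negative-binomial size parameter (variance =
    mean + mean^2/dispersion); ``mean_depth`` is the expected reads per
    sample. ``cpg_density_model`` maps CpG counts to relative MD propensity:
    windows with more CpGs are more likely to be methylation-dependent, and
    CpG-free windows never are.
    """

    n_windows: int = 1000
    window_width: int = 200
    n_reps_per_condition: int = 6
    dropped_reps: list = field(default_factory=list)  # [(condition, replicate)]
    enhancer_fraction: float = 0.08
    md_fraction_of_enhancers: float = 0.15
    md_direction_split: float = 0.86
    activity_log2fc_range: tuple = (1.0, 4.0)
    md_log2fc_range: tuple = (1.0, 3.0)
    dispersion: float = 10.0
    mean_depth: float = 1e6
    cpg_density_model: dict = field(default_factory=lambda: {"mean_cpg": 4.0, "slope": 0.5})
    seed: int = 0

    def validate(self) -> None:
        for name in ("enhancer_fraction", "md_fraction_of_enhancers", "md_direction_split"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_windows < 1:
            raise ConfigurationError(f"n_windows must be >= 1, got {self.n_windows}")
        if self.window_width < 1:
            raise ConfigurationError(f"window_width must be >= 1, got {self.window_width}")
        if self.n_reps_per_condition < 1:
            raise ConfigurationError(
                f"n_reps_per_condition must be >= 1, got {self.n_reps_per_condition}")
        if self.mean_depth <= 0:
            raise ConfigurationError(f"mean_depth must be > 0, got {self.mean_depth}")
        if self.dispersion <= 0:
            raise ConfigurationError(f"dispersion must be > 0, got {self.dispersion}")
        for name in ("activity_log2fc_range", "md_log2fc_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} interval is empty: ({lo}, {hi})")
        for cond, rep in self.dropped_reps:
            if cond not in (UNMETH, METH):
                raise ConfigurationError(f"dropped_reps condition {cond!r} unknown")
            if not (1 <= rep <= self.n_reps_per_condition):
                raise ConfigurationError(f"dropped_reps replicate {rep} out of range")


@dataclass
class SimTruth:
    """Ground truth behind a simulated library.

    ``frame`` has one row per window with baseline_propensity (relative
    abundance in the plasmid pool), activity multipliers per condition
    (RNA-over-DNA fold change; 1 for non-enhancers), enhancer/MD flags,
    direction, and CpG count.
    """

    frame: pd.DataFrame

    @property
    def n_windows(self) -> int:
        return len(self.frame)

    @property
    def is_enhancer(self) -> np.ndarray:
        return self.frame["is_enhancer"].to_numpy(dtype=bool)

    @property
    def is_md(self) -> np.ndarray:
        return self.frame["is_md"].to_numpy(dtype=bool)


def simulate_library(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw per-window ground truth: propensities, multipliers, flags.

    Enhancer status is Bernoulli(enhancer_fraction) per window; among
    enhancers, MD status is assigned with probability proportional to
    1 - exp(-slope * cpg_count) (so CpG-free windows are never MD), scaled
    to hit md_fraction_of_enhancers in expectation; MD direction is
    Bernoulli(md_direction_split) toward more-active-when-unmethylated.
    """
    config.validate()
    rng = rng_for(config.seed, "library")
    n = config.n_windows
    windows = pd.DataFrame({
        "chrom": "chrSim",
        "start": np.arange(n) * config.window_width,
        "end": (np.arange(n) + 1) * config.window_width,
    })
    windows.index = pd.Index(
        [f"chrSim:{s}-{e}" for s, e in zip(windows.start, windows.end)], name="window")

    propensity = rng.dirichlet(np.full(n, 5.0))
    cpg = rng.poisson(config.cpg_density_model.get("mean_cpg", 4.0), size=n)
    is_enh = rng.random(n) < config.enhancer_fraction

    slope = config.cpg_density_model.get("slope", 0.5)
    md_weight = 1.0 - np.exp(-slope * cpg)
    is_md = np.zeros(n, dtype=bool)
    enh_idx = np.flatnonzero(is_enh)
    if enh_idx.size and config.md_fraction_of_enhancers > 0:
        w = md_weight[enh_idx]
        mean_w = w.mean() if w.mean() > 0 else 1.0
        p_md = np.clip(config.md_fraction_of_enhancers * w / mean_w, 0.0, 1.0)
        is_md[enh_idx] = rng.random(enh_idx.size) < p_md
    is_md &= cpg > 0  # CpG-free windows are forced non-MD

    lo, hi = config.activity_log2fc_range
    base_lfc = rng.uniform(lo, hi, size=n)
    mlo, mhi = config.md_log2fc_range
    md_lfc = rng.uniform(mlo, mhi, size=n)
    unmeth_higher = rng.random(n) < config.md_direction_split

    mult_u = np.ones(n)
    mult_m = np.ones(n)
    mult_u[is_enh] = 2.0 ** base_lfc[is_enh]
    mult_m[is_enh] = 2.0 ** base_lfc[is_enh]
    md = is_md
    down = md & unmeth_higher     # activity suppressed by methylation
    up = md & ~unmeth_higher
    mult_m[down] = mult_m[down] * 2.0 ** -md_lfc[down]
    mult_u[up] = mult_u[up] * 2.0 ** -md_lfc[up]

    frame = pd.DataFrame({
        "baseline_propensity": propensity,
        "activity_multiplier_unmeth": mult_u,
        "activity_multiplier_meth": mult_m,
        "is_enhancer": is_enh,
        "is_md": is_md,
        "md_unmeth_higher": np.where(is_md, unmeth_higher, False),
        "cpg_count": cpg,
    }, index=windows.index)
    return windows, SimTruth(frame)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with size ``dispersion``; Poisson in the limit."""
    mean = np.asarray(mean, dtype=float)
    if not np.isfinite(dispersion) or dispersion > 1e8:
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    """Sample metadata for the 2-condition, 2-type replicate design."""
    rows = []
    dropped = {(c, r) for c, r in config.dropped_reps}
    for cond in (UNMETH, METH):
        for rep in range(1, config.n_reps_per_condition + 1):
            if (cond, rep) in dropped:
                continue
            for typ in (DNA, RNA):
                name = f"{typ}_{'u' if cond == UNMETH else 'm'}{rep}"
                rows.append({"sample": name, "type": typ, "condition": cond,
                             "treatment": "none", "replicate": rep})
    return pd.DataFrame(rows).set_index("sample")


def simulate_counts(truth: SimTruth, config: SimConfig) -> CountMatrix:
    """Draw the window x sample count matrix given the truth layer.

    DNA counts ~ NB(depth * propensity, dispersion); RNA counts
    ~ NB(depth * propensity * multiplier(condition), dispersion). Dropped
    replicates are absent from the output. Methylation affects only the RNA
    rate; the plasmid DNA pool is methylation-independent.
    """
    config.validate()
    if truth.n_windows != config.n_windows:
        raise ConfigurationError("truth and config disagree on n_windows")
    rng = rng_for(config.seed, "counts")
    samples = sample_sheet(config)
    prop = truth.frame["baseline_propensity"].to_numpy()
    mult = {UNMETH: truth.frame["activity_multiplier_unmeth"].to_numpy(),
            METH: truth.frame["activity_multiplier_meth"].to_numpy()}
    cols = {}
    for name, meta in samples.iterrows():
        mean = config.mean_depth * prop
        if meta["type"] == RNA:
            mean = mean * mult[meta["condition"]]
        cols[name] = _nb_draw(rng, mean, config.dispersion)
    counts = pd.DataFrame(cols, index=truth.frame.index)
    return CountMatrix(counts, samples)


def simulate_features(truth: SimTruth, n_features: int = 117,
                      n_informative: int = 10, effect_size: float = 1.0,
                      missing_fraction: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Feature table for the MD classifier, with known informative columns.

    Informative features are shifted by ``effect_size`` standard deviations
    in MD windows; the rest are exchangeable noise. A ``missing_fraction``
    of entries is set missing at random. Labels ride along in an ``is_md``
    column mirroring the truth.
    """
    if n_informative > n_features:
        raise ConfigurationError(
            f"n_informative ({n_informative}) exceeds n_features ({n_features})")
    rng = rng_for(seed, "features")
    n = truth.n_windows
    X = rng.standard_normal((n, n_features))
    md = truth.is_md.astype(float)
    X[:, :n_informative] += effect_size * md[:, None]
    if missing_fraction > 0:
        mask = rng.random((n, n_features)) < missing_fraction
        X[mask] = np.nan
    cols = ([f"informative_{i+1}" for i in range(n_informative)] +
            [f"noise_{i+1}" for i in range(n_features - n_informative)])
    out = pd.DataFrame(X, index=truth.frame.index, columns=cols)
    out.insert(0, "is_md", truth.is_md)
    return out


@dataclass
class MethylationSimConfig:
    """Settings for the bisulfite methylation simulation.

    ``tfbs_rates`` maps TF name -> per-transfection drift rate toward the
    endogenous level for CpGs in that TF's binding sites; sites outside any
    TFBS drift at ``baseline_rate``. ``error_rate`` is the apparent
    methylation rate of truly unmethylated cytosines (failed bisulfite
    conversion), and ``n_spikein`` unmethylated spike-in sites are included
    for conversion-efficiency estimation.
    """

    sites_per_window: float = 2.0
    coverage: float = 50.0
    tfbs_rates: dict = field(default_factory=dict)
    baseline_rate: float = 0.05
    error_rate: float = 0.003
    n_spikein: int = 1000
    n_reps_per_condition: int = 2
    seed: int = 0


@dataclass
class MethylationSim:
    """Simulated methylation matrices: site table + count arrays."""

    sites: pd.DataFrame            # chrom, pos, window, tf, endogenous, is_spikein
    samples: pd.DataFrame          # condition per sample
    pre_level: np.ndarray          # sites x samples, assigned levels (0/1)
    meth: np.ndarray               # sites x samples observed methylated counts
    total: np.ndarray              # sites x samples total counts
    post_level_true: np.ndarray    # sites x samples latent post-transfection level


def simulate_methylation(truth: SimTruth, config: MethylationSimConfig) -> MethylationSim:
    """Simulate pre/post-transfection CpG methylation with TFBS drift.

    Pre-transfection levels are 0 (unmethylated condition) or 1
    (methylated, M.SssI-treated). Post-transfection, each site drifts
    toward its endogenous level: post = pre + rate * (endogenous - pre),
    with the rate set by TFBS membership. Observed methylated counts are
    binomial given the latent level, coverage, and the bisulfite error rate.
    """
    rng = rng_for(config.seed, "methylation")
    n_win = truth.n_windows
    n_sites = rng.poisson(config.sites_per_window, size=n_win)
    win_idx = np.repeat(np.arange(n_win), n_sites)
    n = win_idx.size
    tf_names = list(config.tfbs_rates)
    tf = np.full(n, "", dtype=object)
    if tf_names:
        assign = rng.integers(0, len(tf_names) + 1, size=n)  # equal share + none
        for k, name in enumerate(tf_names):
            tf[assign == k] = name
    endog = rng.beta(0.4, 0.4, size=n)  # bimodal endogenous landscape
    window_ids = truth.frame.index.to_numpy()
    sites = pd.DataFrame({
        "chrom": "chrSim",
        "pos": win_idx * 200 + rng.integers(0, 200, size=n),
        "window": window_ids[win_idx],
        "tf": tf,
        "endogenous": endog,
        "is_spikein": False,
    })
    if config.n_spikein:
        spike = pd.DataFrame({
            "chrom": "spikein",
            "pos": np.arange(config.n_spikein),
            "window": "",
            "tf": "",
            "endogenous": 0.0,
            "is_spikein": True,
        })
        sites = pd.concat([sites, spike], ignore_index=True)
    n_all = len(sites)

    rows = []
    for cond in (UNMETH, METH):
        for rep in range(1, config.n_reps_per_condition + 1):
            rows.append({"sample": f"bs_{'u' if cond == UNMETH else 'm'}{rep}",
                         "condition": cond})
    samples = pd.DataFrame(rows).set_index("sample")
    n_samp = len(samples)

    rate = np.full(n_all, config.baseline_rate)
    for name, r in config.tfbs_rates.items():
        rate[sites["tf"].to_numpy() == name] = r
    rate[sites["is_spikein"].to_numpy()] = 0.0

    pre = np.zeros((n_all, n_samp))
    meth_cond = (samples["condition"] == METH).to_numpy()
    pre[:, meth_cond] = 1.0
    pre[sites["is_spikein"].to_numpy(), :] = 0.0

    endog_col = sites["endogenous"].to_numpy()[:, None]
    post = pre + rate[:, None] * (endog_col - pre)
    obs_p = np.clip(post + (1.0 - post) * config.error_rate, 0.0, 1.0)
    total = rng.poisson(config.coverage, size=(n_all, n_samp))
    meth = rng.binomial(total, obs_p)
    return MethylationSim(sites=sites, samples=samples, pre_level=pre,
                          meth=meth, total=total, post_level_true=post)


def simulate_monocyte_pairs(n_individuals: int = 1202, n_pairs: int = 1000,
                            causal_fraction: float = 0.1, rho_causal: float = -0.5,
                            seed: int = 0):
    """Paired methylation (M-value) / expression data across individuals.

    For a causal pair, expression correlates with methylation at
    ``rho_causal`` across individuals; non-causal pairs are independent.
    Returns (methylation DataFrame [pairs x individuals], expression
    DataFrame, causal flags Series).
    """
    if n_individuals < 3:
        raise ConfigurationError(
            f"n_individuals must be >= 3, got {n_individuals}")
    if not (-1.0 < rho_causal < 1.0):
        raise ConfigurationError(f"|rho_causal| must be < 1, got {rho_causal}")
    if not (0.0 <= causal_fraction <= 1.0):
        raise ConfigurationError(
            f"causal_fraction must lie in [0,1], got {causal_fraction}")
    rng = rng_for(seed, "monocyte")
    causal = rng.random(n_pairs) < causal_fraction
    m = rng.standard_normal((n_pairs, n_individuals))       # M-values, ~logit scale
    noise = rng.standard_normal((n_pairs, n_individuals))
    rho = np.where(causal, rho_causal, 0.0)[:, None]
    expr = rho * m + np.sqrt(1.0 - rho ** 2) * noise
    idx = pd.Index([f"cg{i:06d}" for i in range(n_pairs)], name="probe")
    cols = [f"ind{j:04d}" for j in range(n_individuals)]
    meth = pd.DataFrame(m, index=idx, columns=cols)
    expression = pd.DataFrame(expr, index=idx, columns=cols)
    flags = pd.Series(causal, index=idx, name="causal")
    return meth, expression, flags


def simulate_luciferase(mstarr_estimates, n_constructs: int = 18,
                        reps_per_condition: int = 8, n_batches: int = 4,
                        slope: float = 0.8, intercept: float = 0.5,
                        length_coef: float = 0.002, batch_sd: float = 0.5,
                        noise_sd: float = 0.3, max_dropped: int = 2,
                        seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Luciferase-style validation table with a known linear structure.

    log2 normalized activity = intercept + slope * mstarr_estimate +
    length_coef * fragment_length + batch intercept + noise. One or two
    replicates per construct may be dropped (emulating discarded wells),
    leaving 6-8 replicates. Returns (long table, truth dict).
    """
    if n_constructs < 2:
        raise ConfigurationError(f"n_constructs must be >= 2, got {n_constructs}")
    rng = rng_for(seed, "luciferase")
    est = np.asarray(mstarr_estimates, dtype=float)
    if est.size < n_constructs:
        raise ConfigurationError(
            f"need >= {n_constructs} activity estimates, got {est.size}")
    est = est[:n_constructs]
    length = rng.integers(250, 351, size=n_constructs).astype(float)
    batch_effects = rng.normal(0.0, batch_sd, size=n_batches)
    rows = []
    for i in range(n_constructs):
        drop = rng.integers(0, max_dropped + 1)
        keep = reps_per_condition - drop
        for rep in range(1, keep + 1):
            batch = int(rng.integers(0, n_batches))
            y = (intercept + slope * est[i] + length_coef * length[i] +
                 batch_effects[batch] + rng.normal(0.0, noise_sd))
            rows.append({"construct": f"cons{i+1:02d}", "replicate": rep,
                         "batch": f"batch{batch+1}", "length": length[i],
                         "mstarr_estimate": est[i], "log2_activity": y})
    table = pd.DataFrame(rows)
    truth = {"intercept": intercept, "slope": slope, "length_coef": length_coef,
             "batch_sd": batch_sd, "noise_sd": noise_sd,
             "batch_effects": batch_effects}
    return table, truth
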