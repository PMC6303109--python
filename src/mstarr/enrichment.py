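"""Enrichment statistics: Fisher tests, chromatin states, TF families.

Covers the annotation-side statistics: two-sided Fisher's exact tests with
Haldane-corrected odds ratios and Woolf confidence intervals, assignment of
fragment extents to chromatin states by majority (>50%) overlap, selection
of significantly enriched TF-binding motifs, and hypergeometric enrichment
of TF families among significant motifs. Motif scanning itself is consumed
as a binary fragment x motif hit table produced by an external scanner.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import InputError
from .fdr import storey_qvalue


@dataclass
class FisherResult:
    odds_ratio: float
    log2_odds: float
    pvalue: float
    ci95: tuple
    corrected: bool = False  # Haldane-Anscombe 0.5 applied (a zero cell)


def fisher_exact_2sided(table) -> FisherResult:
    """Two-sided Fisher's exact test with a finite odds ratio.

    The p-value sums hypergeometric probabilities no larger than the
    observed table's. The sample odds ratio uses the Haldane-Anscombe 0.5
    correction when any cell is zero; the 95% CI is Woolf's (normal on the
    log odds) on the corrected table. A margin of zeros yields an
    undefined-result marker (NaN fields).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise InputError("need a 2x2 table of non-negative counts")
    if t.sum() < 1:
        raise InputError("table grand total must be >= 1")
    a, b, c, d = t.ravel()
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return FisherResult(np.nan, np.nan, np.nan, (np.nan, np.nan))
    _, p = stats.fisher_exact(t, alternative="two-sided")
    corrected = bool(np.any(t == 0))
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = np.exp(np.log(oratio) - 1.959963984540054 * se)
    hi = np.exp(np.log(oratio) + 1.959963984540054 * se)
    return FisherResult(odds_ratio=float(oratio), log2_odds=float(np.log2(oratio)),
                        pvalue=float(p), ci95=(float(lo), float(hi)),
                        corrected=corrected)


def assign_chromatin_state(extent_start: int, extent_end: int,
                           segments: pd.DataFrame) -> str | None:
    """State covering more than half of the extent, else None.

    ``segments`` has columns chrom(optional), start, end, state and must be
    non-overlapping; an exact 50/50 split assigns no state.
    """
    seg = segments.sort_values("start")
    s = seg["start"].to_numpy()
    e = seg["end"].to_numpy()
    if np.any(e[:-1] > s[1:]):
        raise InputError("chromatin-state segments overlap")
    length = extent_end - extent_start
    if length <= 0:
        raise InputError("empty extent")
    overlap = np.minimum(e, extent_end) - np.maximum(s, extent_start)
    overlap = np.clip(overlap, 0, None).astype(float)
    per_state = pd.Series(overlap).groupby(seg["state"].to_numpy()).sum()
    if per_state.empty:
        return None
    best = per_state.idxmax()
    if per_state[best] / length > 0.5:
        return str(best)
    return None


def state_enrichment(calls: pd.Series, states: pd.Series) -> pd.DataFrame:
    """Per-state Fisher enrichment of called windows versus the rest."""
    out = []
    called = calls.astype(bool)
    for state in sorted(x for x in states.dropna().unique()):
        in_state = states == state
        tab = [[int((called & in_state).sum()), int((called & ~in_state).sum())],
               [int((~called & in_state).sum()), int((~called & ~in_state).sum())]]
        r = fisher_exact_2sided(tab)
        out.append({"state": state, "odds_ratio": r.odds_ratio,
                    "log2_odds": r.log2_odds, "p": r.pvalue,
                    "ci_lo": r.ci95[0], "ci_hi": r.ci95[1]})
    return pd.DataFrame(out).set_index("state")


def motif_enrichment(hits_test: pd.DataFrame, hits_background: pd.DataFrame,
                     family_map: pd.Series | None = None) -> pd.DataFrame:
    """Per-motif enrichment of hit fractions, test set versus background.

    Both inputs are binary fragment x motif tables sharing columns. The
    enrichment p per motif is a Fisher exact test of hit counts; q-values
    are attached for downstream motif selection.
    """
    motifs = [c for c in hits_test.columns if c in hits_background.columns]
    n_t, n_b = len(hits_test), len(hits_background)
    rows = []
    for m in motifs:
        kt = int(hits_test[m].sum())
        kb = int(hits_background[m].sum())
        r = fisher_exact_2sided([[kt, n_t - kt], [kb, n_b - kb]])
        rows.append({"motif": m, "test_fraction": kt / n_t,
                     "background_fraction": kb / n_b,
                     "odds_ratio": r.odds_ratio, "p": r.pvalue})
    out = pd.DataFrame(rows).set_index("motif")
    fin = out["p"].notna()
    out["q"] = np.nan
    if fin.sum() >= 2:
        out.loc[fin, "q"] = storey_qvalue(out.loc[fin, "p"].to_numpy()).qvalues
    if family_map is not None:
        out["family"] = family_map.reindex(out.index)
    return out


def select_significant_motifs(records: pd.DataFrame, bg_floor: float = 0.10,
                              fdr: float = 0.01) -> list[str]:
    """Motifs on >``bg_floor`` of background fragments passing the FDR."""
    if len(records) == 0:
        return []
    keep = (records["background_fraction"] > bg_floor) & (records["q"] < fdr)
    return sorted(records.index[keep.fillna(False)])


def family_hypergeometric(k: int, n_sig: int, family_size: int,
                          n_total: int = 364) -> tuple[float, float]:
    """TF-family enrichment among significant motifs.

    fold = (k/n_sig) / (family_size/n_total); p = upper-tail hypergeometric
    P(X >= k) drawing n_sig motifs from n_total of which family_size belong
    to the family.
    """
    if not (0 <= k <= min(n_sig, family_size)) or family_size > n_total or n_sig > n_total:
        raise InputError("impossible hypergeometric counts")
    if n_sig == 0 or family_size == 0:
        raise InputError("n_sig and family_size must be positive")
    fold = (k / n_sig) / (family_size / n_total)
    p = float(stats.hypergeom.sf(k - 1, n_total, family_size, n_sig))
    return fold, min(p, 1.0)


def family_enrichment_table(significant: list[str], family_map: pd.Series,
                            n_total: int | None = None) -> pd.DataFrame:
    """Hypergeometric fold and p for every family with a significant motif."""
    n_total = len(family_map) if n_total is None else n_total
    sig_fams = family_map.reindex(significant).dropna()
    rows = []
    for fam, k in sig_fams.value_counts().items():
        size = int((family_map == fam).sum())
        fold, p = family_hypergeometric(int(k), len(significant), size, n_total)
        rows.append({"family": fam, "k": int(k), "family_size": size,
                     "fold": fold, "p": p})
    return pd.DataFrame(rows).set_index("family").sort_values("p")
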