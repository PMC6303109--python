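"""Genome windowing, fragment coverage counting, and analysis-set filters.

The genome is tiled into fixed-width non-overlapping windows (200 bp by
default). Fragment alignments (BED-like, 0-based half-open) are counted
against every window they overlap by at least 1 bp. Two filters define the
analysis set: a detection filter requiring nonzero RNA and DNA counts in at
least half the replicates of every condition, and a DNA-stability filter
removing windows whose between-replicate abundance differences are outliers
of the pooled difference distribution.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .core import DNA, RNA, ConfigurationError, CountMatrix, InputError, as_chrom_sizes


def make_windows(chrom_sizes, width: int = 200) -> pd.DataFrame:
    """Tile each chromosome into consecutive non-overlapping windows.

    The trailing partial window is retained, so window widths sum exactly to
    the chromosome length. Returns a DataFrame with columns
    ``chrom``, ``start``, ``end`` and an index of window ids
    ``"{chrom}:{start}-{end}"``.
    """
    sizes = as_chrom_sizes(chrom_sizes)
    if width < 1:
        raise InputError(f"window width must be >= 1, got {width}")
    rows = []
    for chrom, size in sizes.items():
        if size < 1:
            raise InputError(f"chromosome {chrom} has non-positive size {size}")
        starts = np.arange(0, size, width)
        ends = np.minimum(starts + width, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    out = pd.concat(rows, ignore_index=True)
    out.index = pd.Index(
        [f"{c}:{s}-{e}" for c, s, e in zip(out.chrom, out.start, out.end)],
        name="window",
    )
    return out


def _check_fragments(fragments: pd.DataFrame) -> pd.DataFrame:
    bad = fragments.index[fragments["start"].to_numpy() >= fragments["end"].to_numpy()]
    if len(bad):
        raise InputError(f"malformed interval (start >= end) at line {bad[0]}")
    return fragments


def count_overlaps(fragments: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Count, per window, the fragments overlapping it by >= 1 bp.

    A fragment increments every window it touches. Windows must be sorted,
    non-overlapping tiles per chromosome (as produced by
    :func:`make_windows`); fragments on chromosomes absent from the window
    set raise an error.
    """
    _check_fragments(fragments)
    counts = np.zeros(len(windows), dtype=np.int64)
    for chrom, frag in fragments.groupby("chrom", sort=False):
        idx = np.flatnonzero((windows["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise InputError(f"fragments on unknown chromosome {chrom!r}")
        w_start = windows["start"].to_numpy()[idx]
        w_end = windows["end"].to_numpy()[idx]
        fs = frag["start"].to_numpy()
        fe = frag["end"].to_numpy()
        # first window whose end > fragment start; last whose start < fragment end
        first = np.searchsorted(w_end, fs, side="right")
        last = np.searchsorted(w_start, fe, side="left") - 1
        valid = first <= last
        first, last = first[valid], last[valid]
        delta = np.zeros(idx.size + 1, dtype=np.int64)
        np.add.at(delta, first, 1)
        np.add.at(delta, last + 1, -1)
        counts[idx] += np.cumsum(delta[:-1])
    return counts


def fragment_extent(windows: pd.DataFrame, fragments: pd.DataFrame) -> pd.DataFrame:
    """Union span of the fragments overlapping each window.

    The extent runs from the most upstream start to the most downstream end
    among overlapping fragments. Windows without any overlapping fragment get
    NA extents (absent-extent marker) rather than raising.
    """
    _check_fragments(fragments)
    ext_start = np.full(len(windows), np.nan)
    ext_end = np.full(len(windows), np.nan)
    for chrom, frag in fragments.groupby("chrom", sort=False):
        idx = np.flatnonzero((windows["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            continue
        w_start = windows["start"].to_numpy()[idx]
        w_end = windows["end"].to_numpy()[idx]
        for fs, fe in zip(frag["start"].to_numpy(), frag["end"].to_numpy()):
            first = np.searchsorted(w_end, fs, side="right")
            last = np.searchsorted(w_start, fe, side="left") - 1
            if first > last:
                continue
            sl = idx[first:last + 1]
            ext_start[sl] = np.fmin(ext_start[sl], fs)
            ext_end[sl] = np.fmax(ext_end[sl], fe)
    out = windows[["chrom", "start", "end"]].copy()
    out["extent_start"] = ext_start
    out["extent_end"] = ext_end
    return out


def unique_fragment_count(fragments: pd.DataFrame) -> int:
    """Number of distinct (chrom, start, end) fragment triples."""
    if len(fragments) == 0:
        return 0
    return int(fragments.drop_duplicates(["chrom", "start", "end"]).shape[0])


def filter_detected(counts: CountMatrix, min_fraction: float = 0.5) -> np.ndarray:
    """Detection filter: keep windows observed in both data types.

    A window is kept iff, within every condition, its RNA count is nonzero
    in at least ceil(min_fraction * n_reps) replicates AND its DNA count is
    nonzero in at least that many replicates.
    """
    samples = counts.samples
    mask = np.ones(counts.n_windows, dtype=bool)
    conditions = samples["condition"].unique()
    for cond in conditions:
        for typ in (RNA, DNA):
            cols = samples.index[(samples["condition"] == cond) & (samples["type"] == typ)]
            if len(cols) == 0:
                raise ConfigurationError(
                    f"no samples with type={typ} in condition={cond}")
            need = int(np.ceil(min_fraction * len(cols)))
            nonzero = (counts.counts[list(cols)].to_numpy() > 0).sum(axis=1)
            mask &= nonzero >= need
    return mask


def filter_stable(dna_values: pd.DataFrame, central: float = 0.90,
                  max_outside: float = 0.25) -> np.ndarray:
    """DNA stability filter on normalized DNA abundances.

    All pairwise between-replicate differences (signed, fixed replicate
    order) are pooled across windows; the central ``central`` interval
    (e.g. [5th, 95th percentile]) of the pooled distribution is formed, and
    a window is removed iff more than ``max_outside`` of its pairs fall
    outside that interval.
    """
    vals = dna_values.to_numpy(dtype=float)
    n = vals.shape[1]
    if n < 2:
        raise ConfigurationError("filter_stable needs >= 2 DNA replicates")
    pairs = list(combinations(range(n), 2))
    diffs = np.stack([vals[:, i] - vals[:, j] for i, j in pairs], axis=1)
    alpha = (1.0 - central) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    outside = (diffs < lo) | (diffs > hi)
    frac_outside = outside.mean(axis=1)
    return frac_outside <= max_outside
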