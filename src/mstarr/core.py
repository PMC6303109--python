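"""Shared containers and small utilities.

The pipeline's central objects are a :class:`CountMatrix` (window x sample
integer counts plus per-sample metadata) and a :class:`NormalizedMatrix`
(log2-CPM values with observation and sample weights), which feed the
per-window activity models.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA = "DNA"
RNA = "RNA"
UNMETH = "unmethylated"
METH = "methylated"


class ConfigurationError(ValueError):
    """Raised when a configuration value is invalid; names the field."""


class InputError(ValueError):
    """Raised on malformed input data."""


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Pseudo-random stream derived from a master seed and a fixed label.

    Each module draws from its own labelled stream, so adding a stage never
    perturbs another stage's draws. The label is hashed (SHA-256) into the
    seed sequence, making the stream independent of call order.
    """
    digest = hashlib.sha256(label.encode()).digest()
    tag = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass
class CountMatrix:
    """Window x sample counts with sample metadata.

    ``counts`` is a DataFrame indexed by window id with one column per sample;
    ``samples`` is a DataFrame indexed by sample name with columns
    ``type`` (DNA/RNA), ``condition`` (unmethylated/methylated), ``treatment``,
    ``replicate`` and ``lib_size`` (column sum over all windows, computed
    before any filtering).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise InputError("count columns and sample metadata rows disagree")
        if "lib_size" not in self.samples.columns:
            self.samples = self.samples.copy()
            self.samples["lib_size"] = self.counts.sum(axis=0).to_numpy()

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_windows(self, mask) -> "CountMatrix":
        sub = self.counts.loc[mask] if getattr(mask, "dtype", None) == bool else self.counts.loc[mask]
        return CountMatrix(sub, self.samples.copy())

    def select_samples(self, index) -> "CountMatrix":
        return CountMatrix(self.counts[list(index)], self.samples.loc[list(index)].copy())


@dataclass
class NormalizedMatrix:
    """log2-CPM values with precision and sample quality weights.

    ``values`` holds the normalized abundances y_i consumed by the activity
    models; ``obs_weights`` the per-observation inverse-variance weights from
    the mean-variance trend; ``sample_weights`` the per-sample quality
    factors (geometric mean 1). ``trend`` is the fitted mean-variance curve
    as (average log2-CPM, sqrt residual SD) pairs.
    """

    values: pd.DataFrame
    obs_weights: pd.DataFrame
    sample_weights: pd.Series
    trend: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.obs_weights.shape:
            raise InputError("values and observation weights shapes differ")
        w = self.obs_weights.to_numpy()
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise InputError("observation weights must be finite and positive")
        s = self.sample_weights.to_numpy(dtype=float)
        if np.any(s <= 0):
            raise InputError("sample weights must be positive")

    @property
    def combined_weights(self) -> pd.DataFrame:
        """Observation weight x sample quality weight, elementwise."""
        return self.obs_weights * self.sample_weights


def as_chrom_sizes(obj) -> dict[str, int]:
    if isinstance(obj, dict):
        return {str(k): int(v) for k, v in obj.items()}
    if isinstance(obj, pd.Series):
        return {str(k): int(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {str(r[0]): int(r[1]) for r in obj.itertuples(index=False)}
    raise InputError("unsupported chrom sizes object")
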