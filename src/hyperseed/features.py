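"""Per-seed spectra, smoothing, band-ratio features, normalization and splits.

Feature engineering for the non-CNN models: each seed crop is summarized by
its masked mean spectrum, lightly smoothed with a Savitzky-Golay filter
(window 7, polyorder 3), optionally expanded with all pairwise band ratios
R_jk = X_j / X_k (j < k), and min-max normalized with statistics fitted on
the training partition only.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import kurtosis, skew

from .segmentation import SeedCrop

__all__ = [
    "SummaryStats",
    "SplitSpec",
    "mean_spectrum",
    "smooth",
    "band_ratios",
    "ratio_names",
    "band_names",
    "minmax_fit_apply",
    "protein_class",
    "summarize",
    "split",
    "CLASS_NAMES",
]

CLASS_NAMES = ("low", "medium", "high")
RATIO_EPS = 1e-8


def mean_spectrum(crop: SeedCrop) -> np.ndarray:
    """Per-band mean over the crop's seed pixels (nonzero-mask pixels only)."""
    mask = np.any(crop.patch != 0, axis=2)
    if not mask.any():
        raise ValueError("crop contains no seed pixels")
    return crop.patch[mask].mean(axis=0)


def smooth(spectrum: np.ndarray, window: int = 7, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing; preserves polynomials up to ``polyorder``."""
    spectrum = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not polyorder < window <= spectrum.size:
        raise ValueError(
            f"need polyorder < window <= len(spectrum); got "
            f"({polyorder}, {window}, {spectrum.size})"
        )
    return savgol_filter(spectrum, window, polyorder)


def band_ratios(spectrum: np.ndarray) -> np.ndarray:
    """All pairwise ratios R_jk = X_j / X_k for j < k, lexicographic order.

    Length C(C-1)/2 for C bands.  Denominators below 1e-8 in magnitude yield
    a 0 feature instead of an overflow, keeping the matrix shape stable.
    """
    x = np.asarray(spectrum, dtype=float)
    j, k = np.triu_indices(x.size, k=1)
    denom = x[k]
    safe = np.abs(denom) >= RATIO_EPS
    out = np.zeros(j.size)
    np.divide(x[j], denom, out=out, where=safe)
    return out


def ratio_names(wavelengths: np.ndarray) -> list[str]:
    wl = np.asarray(wavelengths)
    j, k = np.triu_indices(wl.size, k=1)
    return [f"ratio:{wl[a]:.0f}/{wl[b]:.0f}" for a, b in zip(j, k)]


def band_names(wavelengths: np.ndarray) -> list[str]:
    return [f"band:{w:.0f}" for w in np.asarray(wavelengths)]


def minmax_fit_apply(train: np.ndarray, *others: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-column (x - min) / (max - min) with min/max from ``train`` only.

    Constant training columns map to 0 everywhere; values outside the training
    range are not clipped (test values may fall below 0 or above 1).
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("training matrix is empty")
    lo = train.min(axis=0)
    span = train.max(axis=0) - lo
    constant = span == 0

    def _apply(mat: np.ndarray) -> np.ndarray:
        mat = np.asarray(mat, dtype=float)
        out = np.zeros_like(mat)
        np.divide(mat - lo, span, out=out, where=~constant)
        return out

    return tuple(_apply(m) for m in (train, *others))


def protein_class(p: float) -> str:
    """Three-class protein label: <10% low, 10-14% medium (inclusive), >14% high."""
    if p < 0:
        raise ValueError("protein percentage must be >= 0")
    if p < 10.0:
        return "low"
    if p <= 14.0:
        return "medium"
    return "high"


@dataclass(frozen=True)
class SummaryStats:
    """The eleven ground-truth summary statistics reported for protein."""

    mean: float
    median: float
    mode: float
    range: float
    variance: float
    sd: float
    iqr: float
    q1: float
    q3: float
    skewness: float
    kurtosis: float


def summarize(values: np.ndarray) -> SummaryStats:
    """Summary statistics of a protein-percentage vector.

    Quartiles use linear interpolation; the mode is the most frequent value
    after rounding to 0.01 (ties -> smallest); skewness/kurtosis are the
    moment (Fisher) estimators.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    rounded = np.round(v, 2)
    uniq, counts = np.unique(rounded, return_counts=True)
    mode = float(uniq[np.argmax(counts)])
    degenerate = np.ptp(v) == 0  # moment shape stats undefined; report 0
    return SummaryStats(
        mean=float(v.mean()),
        median=float(np.median(v)),
        mode=mode,
        range=float(v.max() - v.min()),
        variance=float(v.var(ddof=1)),
        sd=float(v.std(ddof=1)),
        iqr=float(q3 - q1),
        q1=float(q1),
        q3=float(q3),
        skewness=0.0 if degenerate else float(skew(v)),
        kurtosis=0.0 if degenerate else float(kurtosis(v)),
    )


def _round_half_up(x: float) -> int:
    return int(floor(x + 0.5))


@dataclass(frozen=True)
class SplitSpec:
    """Train/test/validation partition of seed indices."""

    n_total: int
    n_train: int
    n_test: int
    n_val: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    val_idx: np.ndarray


def split(n_total: int, rng_seed: int = 0) -> SplitSpec:
    """Partition ``n_total`` samples with a 3:1 train:test and 4:1 train:val ratio.

    n_test = round_half_up(n/4); n_val = round_half_up((n - n_test)/5);
    n_train is the remainder.  Half-up rounding is the only convention that
    reproduces both published count triples (5057 -> 3034/1264/759 and
    4746 -> 2847/1187/712).  Assignment is a seeded shuffle.
    """
    if n_total < 5:
        raise ValueError("need at least 5 samples to split")
    n_test = _round_half_up(n_total / 4)
    n_val = _round_half_up((n_total - n_test) / 5)
    n_train = n_total - n_test - n_val
    perm = np.random.default_rng(rng_seed).permutation(n_total)
    return SplitSpec(
        n_total=n_total,
        n_train=n_train,
        n_test=n_test,
        n_val=n_val,
        train_idx=perm[:n_train],
        test_idx=perm[n_train:n_train + n_test],
        val_idx=perm[n_train + n_test:],
    )
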