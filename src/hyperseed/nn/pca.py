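"""Pixel-space PCA reduction of the spectral dimension.

Each pixel's spectrum is one observation; projecting onto the top-K principal
components reduces a (H, W, C) cube to (H, W, K) while preserving the
spatial layout, which is what the 3-D convolutional input expects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["PCAReducer", "fit_pca", "apply_pca"]


@dataclass
class PCAReducer:
    """Top-K principal basis fitted on pixel spectra."""

    components: np.ndarray  # (K, C)
    mean: np.ndarray  # (C,)
    n_components: int
    explained_variance: np.ndarray  # fractions, non-increasing


def fit_pca(pixels: np.ndarray, k: int) -> PCAReducer:
    """Fit the reducer on an (observations, C) matrix of pixel spectra."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2:
        raise ValueError("pixels must be 2-D (observations, bands)")
    if k > pixels.shape[1]:
        raise ValueError(f"K={k} exceeds the {pixels.shape[1]} bands")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(pixels)
    return PCAReducer(
        components=pca.components_,
        mean=pca.mean_,
        n_components=k,
        explained_variance=pca.explained_variance_ratio_,
    )


def apply_pca(cube: np.ndarray, reducer: PCAReducer) -> np.ndarray:
    """Project the last (spectral) axis of a cube or batch onto the basis.

    Accepts (H, W, C) or (N, H, W, C); returns the same leading shape
    with C replaced by K.
    """
    cube = np.asarray(cube, dtype=float)
    if cube.shape[-1] != reducer.mean.size:
        raise ValueError("band count does not match the fitted basis")
    flat = cube.reshape(-1, cube.shape[-1])
    projected = (flat - reducer.mean) @ reducer.components.T
    return projected.reshape(*cube.shape[:-1], reducer.n_components)
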