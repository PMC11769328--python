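"""Feature-based protein regressors and permutation wavelength ranking.

Two regressor families are supported on the engineered spectra: a random
forest (bagged trees with random split candidates) and a kernel support
vector regressor with an epsilon-insensitive loss.  Wavelength relevance is
measured by permutation importance — the drop in held-out R^2 when one
feature column is shuffled — and the top-ranked bands seed the reduced
band + band-ratio dataset variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_permutation
from sklearn.svm import SVR

from .features import band_names, band_ratios, ratio_names

__all__ = [
    "DatasetVariant",
    "RegressorSpec",
    "build_variant",
    "train_regressor",
    "permutation_importance",
    "select_top_bands",
]

_VARIANT_DESCRIPTIONS = {
    1: "all spectral bands",
    2: "top 100 spectral bands + band ratios of top 100 bands",
    3: "all spectral bands + ratios of all bands",
}


@dataclass(frozen=True)
class DatasetVariant:
    """One of the three fixed feature-set compositions."""

    id: int

    def __post_init__(self) -> None:
        if self.id not in _VARIANT_DESCRIPTIONS:
            raise ValueError("variant id must be 1, 2 or 3")

    @property
    def description(self) -> str:
        return _VARIANT_DESCRIPTIONS[self.id]


@dataclass
class RegressorSpec:
    """Family + hyperparameters of a feature-based regressor.

    The published study names the model families but not their settings;
    the defaults here (500 trees / rbf SVR with C=10, epsilon=0.1) are
    ordinary field choices and fully exposed.
    """

    family: str = "tree-ensemble"
    hyperparameters: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("tree-ensemble", "kernel-svr"):
            raise ValueError("family must be 'tree-ensemble' or 'kernel-svr'")


def build_variant(
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    variant: DatasetVariant | int,
    importance: pd.DataFrame | None = None,
    top_k: int = 100,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the feature matrix for one dataset variant.

    ``spectra`` is (n_samples, n_bands) reflectance.  Variant 1 keeps the raw
    bands; variant 2 keeps the ``top_k`` most important bands plus all their
    pairwise ratios (requires an importance table); variant 3 keeps all bands
    plus all pairwise ratios.  Returns (matrix, column names).
    """
    if isinstance(variant, int):
        variant = DatasetVariant(variant)
    spectra = np.asarray(spectra, dtype=float)
    wavelengths = np.asarray(wavelengths)

    if variant.id == 1:
        return spectra.copy(), band_names(wavelengths)

    if variant.id == 2:
        if importance is None:
            raise ValueError("variant 2 requires a permutation-importance table")
        top_wl = select_top_bands(importance, k=top_k)
        idx = [int(np.argmin(np.abs(wavelengths - wl))) for wl in top_wl]
        sub = spectra[:, idx]
        sub_wl = wavelengths[idx]
        ratios = np.stack([band_ratios(row) for row in sub])
        cols = band_names(sub_wl) + ratio_names(sub_wl)
        return np.hstack([sub, ratios]), cols

    ratios = np.stack([band_ratios(row) for row in spectra])
    cols = band_names(wavelengths) + ratio_names(wavelengths)
    return np.hstack([spectra, ratios]), cols


def train_regressor(X: np.ndarray, y: np.ndarray, spec: RegressorSpec):
    """Fit the requested regressor; deterministic for a given ``rng_seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match len(y)")
    if spec.family == "tree-ensemble":
        params = {"n_estimators": 500, "max_depth": None, "n_jobs": 1}
        params.update(spec.hyperparameters)
        model = RandomForestRegressor(random_state=spec.rng_seed, **params)
    else:
        params = {"kernel": "rbf", "C": 10.0, "epsilon": 0.1}
        params.update(spec.hyperparameters)
        model = SVR(**params)
    model.fit(X, y)
    return model


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    n_repeats: int = 10,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance table: mean R^2 drop per shuffled column.

    Score the model on (X, y) — conventionally a held-out fold — then, per
    feature, average the score drop over ``n_repeats`` column shuffles.
    """
    result = _sk_permutation(model, np.asarray(X, dtype=float),
                             np.asarray(y, dtype=float),
                             scoring="r2", n_repeats=n_repeats,
                             random_state=rng_seed, n_jobs=1)
    table = pd.DataFrame({
        "feature_name": feature_names,
        "mean_drop": result.importances_mean,
        "sd": result.importances_std,
    })
    table["wavelength_nm"] = [
        float(name.split(":")[1]) if name.startswith("band:") else np.nan
        for name in feature_names
    ]
    return table


def select_top_bands(importance: pd.DataFrame, k: int = 100) -> np.ndarray:
    """The ``k`` most important band wavelengths, ties to the lower wavelength."""
    bands = importance.dropna(subset=["wavelength_nm"])
    if len(bands) < k:
        raise ValueError(f"only {len(bands)} band features, need {k}")
    ordered = bands.sort_values(["mean_drop", "wavelength_nm"],
                                ascending=[False, True], kind="mergesort")
    return ordered["wavelength_nm"].to_numpy()[:k]
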