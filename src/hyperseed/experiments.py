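"""End-to-end scaled-down studies on synthetic scenes.

These functions wire the pipeline stages together at desk scale (hundreds of
seeds, small patches) so that the qualitative behavior of the published
method — homography beating naive resampling, the segmentation chain
recovering every planted seed, feature models and the CNN recovering the
protein link — can be measured from scratch in minutes on one CPU.  They are
reused by the command-line runner, the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import features as feat
from . import metrics as met
from .coregister import TiePointSet, compare_methods, estimate_homography
from .feature_models import RegressorSpec, train_regressor
from .nn import ArchitectureSpec, TrainConfig, apply_pca, build_model, fit_pca
from .nn import predict as nn_predict
from .nn import train as nn_train
from .segmentation import segment_scene
from .synthetic import SceneSpec, generate_scene, simulate_crop_dataset

__all__ = [
    "coregistration_study",
    "segmentation_study",
    "feature_model_study",
    "cnn_regression_study",
    "cnn_classification_study",
]


def coregistration_study(rng_seed: int = 0, n_outliers: int = 3,
                         outlier_px: float = 60.0) -> dict:
    """Robust homography recovery and the resampling-vs-homography ordering.

    A synthetic scene provides 16 exact marker correspondences; 12 are used
    as tie points together with ``n_outliers`` grossly wrong pairs (> 50 px
    off), and RANSAC (7.0 px threshold) must recover the transform while
    excluding the outliers.  Error is measured on the four held-out markers.
    """
    rng = np.random.default_rng(rng_seed)
    spec = SceneSpec(marker_count=16, noise_sd=0.0, rng_seed=rng_seed)
    scene = generate_scene(spec)
    vnir_pts = scene.vnir_markers
    swir_pts = scene.swir_markers

    order = rng.permutation(len(vnir_pts))
    fit_idx, held_idx = order[:12], order[12:]
    src = vnir_pts[fit_idx]
    ref = swir_pts[fit_idx]
    # gross outliers: correct source points paired with far-off references
    out_src = vnir_pts[held_idx[:n_outliers]] + rng.uniform(5, 15, (n_outliers, 2))
    out_ref = (scene.truth_transform(out_src)
               + rng.uniform(outlier_px, 2 * outlier_px, (n_outliers, 2)))
    tiepoints = TiePointSet(np.vstack([src, out_src]), np.vstack([ref, out_ref]))

    h, report = estimate_homography(tiepoints, ransac_threshold=7.0,
                                    rng_seed=rng_seed)
    held_res = np.linalg.norm(h(vnir_pts[held_idx]) - swir_pts[held_idx], axis=1)
    comparison = compare_methods(scene, rng_seed=rng_seed)
    return {
        "holdout_rmse_px": float(np.sqrt(np.mean(held_res ** 2))),
        "inlier_count": report.inlier_count,
        "n_tiepoints": report.n_points,
        "resampling_rmse_px": comparison["resampling"].rmse,
        "homography_rmse_px": comparison["homography"].rmse,
    }


def segmentation_study(rng_seed: int = 0, noise_sd: float = 0.01) -> dict:
    """Segment a full 24-seed scene and score the mask against truth."""
    spec = SceneSpec(noise_sd=noise_sd, rng_seed=rng_seed)
    scene = generate_scene(spec)
    mask, table = segment_scene(scene.vnir)
    truth = scene.truth_mask.astype(bool)
    pred = mask.astype(bool)
    tp = np.sum(truth & pred)
    fp = np.sum(~truth & pred)
    fn = np.sum(truth & ~pred)
    f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
    return {
        "n_planted": len(scene.truth_components),
        "n_components": len(table),
        "pixel_f1": float(f1),
    }


def _crop_spectra(crops: np.ndarray) -> np.ndarray:
    """Masked mean spectrum per crop, Savitzky-Golay smoothed."""
    masks = np.any(crops != 0, axis=3)
    spectra = np.empty((len(crops), crops.shape[3]))
    for i in range(len(crops)):
        spectra[i] = crops[i][masks[i]].mean(axis=0)
    return np.stack([feat.smooth(s) for s in spectra])


def feature_model_study(n_seeds: int = 400, rng_seed: int = 0,
                        noise_sd: float = 0.01, n_trees: int = 500) -> dict:
    """Random-forest protein recovery from mean seed spectra.

    Crops come straight from the generative link; spectra are smoothed,
    min-max normalized on the training partition, and a random forest is
    scored on the held-out test partition.
    """
    crops, protein = simulate_crop_dataset(n_seeds, rng_seed=rng_seed,
                                           noise_sd=noise_sd)
    spectra = _crop_spectra(crops)
    del crops
    parts = feat.split(n_seeds, rng_seed=rng_seed)
    x_train, x_test = feat.minmax_fit_apply(spectra[parts.train_idx],
                                            spectra[parts.test_idx])
    model = train_regressor(
        x_train, protein[parts.train_idx],
        RegressorSpec("tree-ensemble", {"n_estimators": n_trees}, rng_seed),
    )
    scores = met.regression_metrics(protein[parts.test_idx], model.predict(x_test))
    return {"holdout_r2": scores.r2, "rmse_pct": scores.rmse,
            "n_train": parts.n_train, "n_test": parts.n_test}


def _pca_patches(crops: np.ndarray, k: int, rng_seed: int) -> np.ndarray:
    """Fit pixel-space PCA on a subsample of seed pixels, project all crops."""
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 31)))
    flat = crops.reshape(-1, crops.shape[3])
    seed_px = np.flatnonzero(np.any(flat != 0, axis=1))
    sample = rng.choice(seed_px, size=min(20000, len(seed_px)), replace=False)
    reducer = fit_pca(flat[sample], k)
    return apply_pca(crops, reducer)


def cnn_regression_study(n_seeds: int = 400, rng_seed: int = 0,
                         patch_size: int = 16, pca_k: int = 8,
                         epochs: int = 30, variant: str = "global_attention_se",
                         noise_sd: float = 0.01) -> dict:
    """Held-out R^2 of the attentive CNN on the synthetic protein link."""
    crops, protein = simulate_crop_dataset(n_seeds, rng_seed=rng_seed,
                                           patch_size=patch_size,
                                           noise_sd=noise_sd)
    patches = _pca_patches(crops, pca_k, rng_seed)
    del crops
    parts = feat.split(n_seeds, rng_seed=rng_seed)
    arch = ArchitectureSpec(variant=variant, kernel_set="compact",
                            task="regression")
    model = build_model(arch, input_depth=pca_k,
                        input_hw=(patch_size, patch_size), rng_seed=rng_seed)
    config = TrainConfig(epochs=epochs, loss="mse", rng_seed=rng_seed)
    history = nn_train(model, patches[parts.train_idx],
                       protein[parts.train_idx], config)
    preds = nn_predict(model, patches[parts.test_idx])
    scores = met.regression_metrics(protein[parts.test_idx], preds)
    return {"holdout_r2": scores.r2, "rmse_pct": scores.rmse,
            "final_loss": history[-1], "n_train": parts.n_train,
            "n_test": parts.n_test}


def cnn_classification_study(n_seeds: int = 400, rng_seed: int = 0,
                             patch_size: int = 16, pca_k: int = 8,
                             epochs: int = 30, variant: str = "base",
                             noise_sd: float = 0.01) -> dict:
    """Held-out accuracy on well-separated low/medium/high protein classes."""
    crops, protein = simulate_crop_dataset(
        n_seeds, rng_seed=rng_seed, patch_size=patch_size, noise_sd=noise_sd,
        class_centers=(8.5, 12.0, 17.0),
    )
    labels = np.array([feat.protein_class(p) for p in protein])
    class_idx = np.array([feat.CLASS_NAMES.index(c) for c in labels])
    patches = _pca_patches(crops, pca_k, rng_seed)
    del crops
    parts = feat.split(n_seeds, rng_seed=rng_seed)
    arch = ArchitectureSpec(variant=variant, kernel_set="compact",
                            task="classification")
    model = build_model(arch, input_depth=pca_k,
                        input_hw=(patch_size, patch_size), rng_seed=rng_seed)
    config = TrainConfig(epochs=epochs, loss="categorical_cross_entropy",
                         rng_seed=rng_seed)
    nn_train(model, patches[parts.train_idx], class_idx[parts.train_idx], config)
    probs = nn_predict(model, patches[parts.test_idx])
    preds = np.array([feat.CLASS_NAMES[i] for i in probs.argmax(axis=1)])
    scores = met.classification_metrics(labels[parts.test_idx], preds)
    return {"holdout_accuracy": scores.accuracy, "macro_f1": scores.f1,
            "n_train": parts.n_train, "n_test": parts.n_test}
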