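"""Synthetic VNIR/SWIR scene generator for the seed-protein pipeline.

The simulator emulates a bench-top push-broom scanning stage: a dark tray
carrying wheat kernels in a rows x cols grid, a 50% reflectance panel strip,
and high-contrast fiducial marker disks visible to both sensors.  The two
sensors image the same flat scene on different rasters related by a known
projective transform (anisotropic scale + translation), so every downstream
stage — calibration, co-registration, segmentation, feature models and the
CNN — can be exercised against exact ground truth.

The protein -> reflectance link is the simulator's generative model:

    reflectance(lambda, p) = base(lambda) * (1 - alpha * t) * (1 - d(p) * dips(lambda))

with t = (p - 7.69) / 11.96 the protein fraction of the observed range,
alpha the link strength (seed reflectance decreases monotonically with
protein at every band), and Gaussian moisture-absorption dips near 1450 nm
and 1950 nm whose depth d(p) = d0 * (1 - 0.5 t) shrinks with protein —
low-protein (higher-moisture) seeds show the deepest dips.  The link is
qualitative domain structure, not a fitted physical model; its parameters
are exposed on :class:`SceneSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .calibration import RadiometricResponse
from .coregister import HomographyTransform
from .envi import SpectralCube

__all__ = [
    "SceneSpec",
    "ScenePair",
    "CalibrationFixtures",
    "generate_scene",
    "generate_calibration_fixtures",
    "compose_raw",
    "seed_reflectance",
    "simulate_crop_dataset",
    "default_vnir_wavelengths",
    "default_swir_wavelengths",
    "default_stacked_wavelengths",
]

PROTEIN_MIN = 7.69
PROTEIN_MAX = 19.65
PROTEIN_RANGE = PROTEIN_MAX - PROTEIN_MIN

# smooth wheat-kernel-like base reflectance: dark in the blue, rising through
# the visible, flat in the NIR, gently declining through the SWIR with mild
# water features already present in the envelope
_BASE_POINTS = np.array([
    (400, 0.08), (460, 0.15), (520, 0.20), (600, 0.30), (700, 0.42),
    (800, 0.50), (900, 0.54), (1000, 0.55), (1300, 0.55), (1450, 0.50),
    (1700, 0.52), (1950, 0.45), (2200, 0.48), (2500, 0.42),
])
_BASE_CURVE = PchipInterpolator(_BASE_POINTS[:, 0], _BASE_POINTS[:, 1])

TRAY_REFLECTANCE = 0.06
PANEL_REFLECTANCE = 0.5
MARKER_REFLECTANCE = 0.9
MARKER_RADIUS_PX = 5.0


def default_vnir_wavelengths() -> np.ndarray:
    """300 bands, 400-1000 nm."""
    return np.linspace(400.0, 1000.0, 300)


def default_swir_wavelengths() -> np.ndarray:
    """362 bands, 960-2500 nm."""
    return np.linspace(960.0, 2500.0, 362)


def default_stacked_wavelengths() -> np.ndarray:
    """The 662-band VNIR-then-SWIR concatenation used by the stacked cube."""
    return np.concatenate([default_vnir_wavelengths(), default_swir_wavelengths()])


def seed_reflectance(
    wavelengths: np.ndarray,
    protein_pct: float,
    alpha: float = 0.35,
    dip_depth: float = 0.30,
    dip_protein_fade: float = 0.5,
) -> np.ndarray:
    """Evaluate the generative protein -> reflectance link at given bands.

    Strictly decreasing in ``protein_pct`` at every wavelength for the default
    parameters (the fade of the moisture dips with protein is kept weaker
    than the multiplicative darkening).
    """
    wl = np.asarray(wavelengths, dtype=float)
    t = (protein_pct - PROTEIN_MIN) / PROTEIN_RANGE
    base = _BASE_CURVE(wl)
    dips = (np.exp(-0.5 * ((wl - 1450.0) / 45.0) ** 2)
            + np.exp(-0.5 * ((wl - 1950.0) / 55.0) ** 2))
    depth = dip_depth * (1.0 - dip_protein_fade * t)
    return base * (1.0 - alpha * t) * (1.0 - depth * dips)


@dataclass
class SceneSpec:
    """Layout, spectral and noise parameters of one synthetic scene pair."""

    grid_rows: int = 6
    grid_cols: int = 4
    seed_axes: tuple[float, float] = (40.0, 20.0)  # (major, minor) px, VNIR frame
    protein_pct: Sequence[float] | None = None  # None -> even spread over full range
    marker_count: int = 12
    noise_sd: float = 0.0
    vnir_wavelengths: np.ndarray = field(default_factory=default_vnir_wavelengths)
    swir_wavelengths: np.ndarray = field(default_factory=default_swir_wavelengths)
    true_transform: HomographyTransform | None = None
    rng_seed: int = 0
    orientation: str = "ventral"
    orientation_contrast: float = 0.0  # fractional reflectance offset for dorsal
    cell_px: float = 56.0
    link_alpha: float = 0.35
    dip_depth: float = 0.30

    def __post_init__(self) -> None:
        if self.protein_pct is None:
            n = self.grid_rows * self.grid_cols
            self.protein_pct = list(np.linspace(PROTEIN_MIN, PROTEIN_MAX, n))
        self.protein_pct = [float(p) for p in self.protein_pct]
        capacity = self.grid_rows * self.grid_cols
        if len(self.protein_pct) > capacity:
            raise ValueError(
                f"{len(self.protein_pct)} seeds exceed grid capacity {capacity}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.marker_count < 4:
            raise ValueError("at least 4 fiducial markers are required")
        for wl in (self.vnir_wavelengths, self.swir_wavelengths):
            if len(wl) > 1 and not np.all(np.diff(wl) > 0):
                raise ValueError("wavelength lists must be strictly increasing")
        if self.true_transform is None:
            self.true_transform = HomographyTransform.scale_translate(
                0.5, 0.5, 3.0, 2.0
            )
        if self.orientation not in ("ventral", "dorsal"):
            raise ValueError("orientation must be 'ventral' or 'dorsal'")

    # ---- derived layout (VNIR frame, 0-based pixel-center coordinates) ----

    @property
    def margin_x(self) -> float:
        return 28.0

    @property
    def grid_top(self) -> float:
        return 60.0

    @property
    def vnir_dims(self) -> tuple[int, int]:
        h = int(self.grid_top + self.grid_rows * self.cell_px + 20)
        w = int(2 * self.margin_x + self.grid_cols * self.cell_px)
        return h, w

    @property
    def swir_dims(self) -> tuple[int, int]:
        h, w = self.vnir_dims
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
        mapped = self.true_transform(corners)
        return (int(np.ceil(mapped[:, 1].max())) + 4,
                int(np.ceil(mapped[:, 0].max())) + 4)

    @property
    def panel_rect(self) -> tuple[float, float, float, float]:
        """(y0, y1, x0, x1) of the 50% panel strip in the VNIR frame."""
        _, w = self.vnir_dims
        return (6.0, 38.0, 10.0, w - 10.0)

    def seed_centers(self) -> np.ndarray:
        """(n_seeds, 2) array of (x, y) centers, row-major over the grid."""
        centers = []
        for i in range(len(self.protein_pct)):
            r, c = divmod(i, self.grid_cols)
            centers.append((self.margin_x + (c + 0.5) * self.cell_px,
                            self.grid_top + (r + 0.5) * self.cell_px))
        return np.array(centers, dtype=float).reshape(-1, 2)

    def marker_centers(self) -> np.ndarray:
        """Fiducial disk centers on a half-cell lattice between the seeds.

        Candidate nodes sit every half cell; nodes coinciding with seed
        centers (both half-indices odd) are excluded, so markers never touch
        a seed for the default seed axes.
        """
        nodes = [
            (self.margin_x + c * self.cell_px / 2,
             self.grid_top + r * self.cell_px / 2)
            for r in range(2 * self.grid_rows + 1)
            for c in range(2 * self.grid_cols + 1)
            if not (r % 2 == 1 and c % 2 == 1)
        ]
        if self.marker_count > len(nodes):
            raise ValueError(
                f"cannot place {self.marker_count} markers on {len(nodes)} nodes"
            )
        idx = np.unique(np.round(
            np.linspace(0, len(nodes) - 1, self.marker_count)).astype(int))
        # linspace rounding can merge adjacent indices; backfill from unused nodes
        pool = [i for i in range(len(nodes)) if i not in set(idx)]
        take = list(idx) + pool[:self.marker_count - len(idx)]
        return np.array([nodes[i] for i in sorted(take)], dtype=float)

    def grid_label(self, seed_index: int) -> str:
        r, c = divmod(seed_index, self.grid_cols)
        return f"{chr(ord('A') + c)}{r + 1}"


@dataclass
class ScenePair:
    """A rendered VNIR/SWIR pair with full ground truth."""

    vnir: SpectralCube
    swir: SpectralCube
    truth_mask: np.ndarray
    truth_components: pd.DataFrame
    truth_transform: HomographyTransform
    protein_by_seed: dict[str, float]
    vnir_markers: np.ndarray
    swir_markers: np.ndarray
    panel_rect: tuple[float, float, float, float]
    spec: SceneSpec


def _render_labels(spec: SceneSpec, transform: HomographyTransform | None,
                   dims: tuple[int, int]) -> np.ndarray:
    """Integer label map: 0 tray, 1 panel, 2 marker, 3+i seed i.

    ``transform`` maps VNIR coordinates into the target frame; membership is
    evaluated by inverse-mapping each target pixel center into the VNIR frame,
    so both sensors see exactly the same scene geometry.
    """
    h, w = dims
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    if transform is not None:
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        src = transform.inverse()(pts)
        vx = src[:, 0].reshape(h, w)
        vy = src[:, 1].reshape(h, w)
    else:
        vx, vy = xs, ys

    labels = np.zeros(dims, dtype=np.int32)
    y0, y1, x0, x1 = spec.panel_rect
    labels[(vy >= y0) & (vy <= y1) & (vx >= x0) & (vx <= x1)] = 1
    for mx, my in spec.marker_centers():
        labels[(vx - mx) ** 2 + (vy - my) ** 2 <= MARKER_RADIUS_PX ** 2] = 2
    a = spec.seed_axes[1] / 2.0  # semi-axis along x (seeds lie long-side along scan)
    b = spec.seed_axes[0] / 2.0  # semi-axis along y
    for i, (cx, cy) in enumerate(spec.seed_centers()):
        inside = ((vx - cx) / a) ** 2 + ((vy - cy) / b) ** 2 <= 1.0
        labels[inside] = 3 + i
    return labels


def _spectra_table(spec: SceneSpec, wavelengths: np.ndarray) -> np.ndarray:
    """Row l of the table is the reflectance spectrum of label l."""
    n_seeds = len(spec.protein_pct)
    table = np.empty((3 + n_seeds, len(wavelengths)))
    table[0] = TRAY_REFLECTANCE
    table[1] = PANEL_REFLECTANCE
    table[2] = MARKER_REFLECTANCE
    orient_gain = 1.0
    if spec.orientation == "dorsal":
        orient_gain = 1.0 + spec.orientation_contrast
    for i, p in enumerate(spec.protein_pct):
        table[3 + i] = orient_gain * seed_reflectance(
            wavelengths, p, spec.link_alpha, spec.dip_depth
        )
    return table


def _components_from_mask(spec: SceneSpec, labels: np.ndarray) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(spec.protein_pct):
        region = labels == 3 + i
        area = int(region.sum())
        if area == 0:
            continue
        ys, xs = np.nonzero(region)
        rows.append({
            "component_id": i + 1,
            "area": area,
            "min_row": int(ys.min()), "min_col": int(xs.min()),
            "max_row": int(ys.max()), "max_col": int(xs.max()),
            "centroid_x": float(xs.mean()), "centroid_y": float(ys.mean()),
            "grid_label": spec.grid_label(i),
            "protein_pct": p,
        })
    return pd.DataFrame(rows, columns=[
        "component_id", "area", "min_row", "min_col", "max_row", "max_col",
        "centroid_x", "centroid_y", "grid_label", "protein_pct",
    ])


def generate_scene(spec: SceneSpec) -> ScenePair:
    """Render the VNIR/SWIR reflectance pair with full ground truth.

    Bit-reproducible for a given ``spec.rng_seed``; the two sensors use
    independent noise substreams derived from it.
    """
    ss = np.random.SeedSequence(spec.rng_seed)
    rng_vnir, rng_swir = (np.random.default_rng(s) for s in ss.spawn(2))

    vnir_labels = _render_labels(spec, None, spec.vnir_dims)
    swir_labels = _render_labels(spec, spec.true_transform, spec.swir_dims)

    vnir = _spectra_table(spec, spec.vnir_wavelengths)[vnir_labels]
    swir = _spectra_table(spec, spec.swir_wavelengths)[swir_labels]
    if spec.noise_sd > 0:
        vnir = vnir + rng_vnir.normal(0.0, spec.noise_sd, vnir.shape)
        swir = swir + rng_swir.normal(0.0, spec.noise_sd, swir.shape)
        vnir = np.clip(vnir, 0.0, None)
        swir = np.clip(swir, 0.0, None)

    truth_mask = (vnir_labels >= 3).astype(np.uint8)
    components = _components_from_mask(spec, vnir_labels)
    markers = spec.marker_centers()
    return ScenePair(
        vnir=SpectralCube(vnir.astype(np.float32), spec.vnir_wavelengths),
        swir=SpectralCube(swir.astype(np.float32), spec.swir_wavelengths),
        truth_mask=truth_mask,
        truth_components=components,
        truth_transform=spec.true_transform,
        protein_by_seed={spec.grid_label(i): p
                         for i, p in enumerate(spec.protein_pct)},
        vnir_markers=markers,
        swir_markers=spec.true_transform(markers) if len(markers) else markers,
        panel_rect=spec.panel_rect,
        spec=spec,
    )


@dataclass
class CalibrationFixtures:
    """Dark/bright frames plus the hidden truth needed for round-trip tests.

    ``l_ref`` is the panel's radiant exposure during the bright scan
    (panel radiance x integration time), the constant that makes the
    response -> radiance chain an exact inverse of :func:`compose_raw`.
    """

    dark_frame: SpectralCube
    bright_frame: SpectralCube
    panel_reflectance: float
    integration_time: float
    illumination: float
    true_response: np.ndarray

    @property
    def l_ref(self) -> float:
        return self.panel_reflectance * self.illumination * self.integration_time

    def response(self) -> RadiometricResponse:
        from .calibration import compute_response

        return compute_response(self.bright_frame, self.dark_frame, self.l_ref,
                                self.integration_time)


def generate_calibration_fixtures(
    spec: SceneSpec,
    true_radiance_scale: float,
    integration_time: float = 0.01,
    sensor: str = "vnir",
) -> CalibrationFixtures:
    """Dark and bright DN frames consistent with the calibration equations.

    The truth model is ``raw = dark + L * R * t_int`` with a per-pixel-per-band
    response R; the bright frame is a full-frame scan of the 50% panel under
    flat illumination ``true_radiance_scale``.
    """
    if true_radiance_scale <= 0:
        raise ValueError("true_radiance_scale must be > 0")
    dims = spec.vnir_dims if sensor == "vnir" else spec.swir_dims
    wl = spec.vnir_wavelengths if sensor == "vnir" else spec.swir_wavelengths
    shape = (*dims, len(wl))
    rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, 17)))
    response = rng.uniform(0.8, 1.2, shape)
    dark = rng.uniform(3.0, 8.0, shape)
    panel_radiance = PANEL_REFLECTANCE * true_radiance_scale
    bright = dark + panel_radiance * response * integration_time
    return CalibrationFixtures(
        dark_frame=SpectralCube(dark, wl, "dn"),
        bright_frame=SpectralCube(bright, wl, "dn"),
        panel_reflectance=PANEL_REFLECTANCE,
        integration_time=integration_time,
        illumination=true_radiance_scale,
        true_response=response,
    )


def compose_raw(radiance: SpectralCube, fixtures: CalibrationFixtures) -> SpectralCube:
    """Forward-simulate a raw DN scan from a known radiance cube."""
    raw = (fixtures.dark_frame.data
           + radiance.data * fixtures.true_response * fixtures.integration_time)
    return SpectralCube(raw, radiance.wavelengths, "dn", radiance.interleave)


def simulate_crop_dataset(
    n_seeds: int,
    rng_seed: int = 0,
    patch_size: int = 16,
    wavelengths: np.ndarray | None = None,
    noise_sd: float = 0.01,
    protein_pct: np.ndarray | None = None,
    class_centers: Sequence[float] | None = None,
    class_sd: float = 0.4,
    link_alpha: float = 0.35,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-seed crop patches straight from the generative link.

    A fast path for model experiments: each seed is a filled ellipse on a
    zeroed background inside a ``patch_size`` square, its spectrum drawn from
    :func:`seed_reflectance` plus i.i.d. Gaussian noise.  Protein values are
    uniform over the observed range unless given explicitly, or drawn from
    Gaussian clusters when ``class_centers`` is set (for classification
    experiments with separated low/medium/high groups).

    Returns ``(crops, protein)`` with crops of shape (n, ph, pw, bands),
    float32.
    """
    wl = default_stacked_wavelengths() if wavelengths is None else np.asarray(wavelengths)
    rng = np.random.default_rng(rng_seed)
    if protein_pct is not None:
        protein = np.asarray(protein_pct, dtype=float)
        if len(protein) != n_seeds:
            raise ValueError("protein_pct length must equal n_seeds")
    elif class_centers is not None:
        which = rng.integers(0, len(class_centers), n_seeds)
        protein = np.array(class_centers)[which] + rng.normal(0, class_sd, n_seeds)
        protein = np.clip(protein, PROTEIN_MIN, PROTEIN_MAX)
    else:
        protein = rng.uniform(PROTEIN_MIN, PROTEIN_MAX, n_seeds)

    ys, xs = np.mgrid[0:patch_size, 0:patch_size].astype(float)
    c = (patch_size - 1) / 2.0
    a, b = 0.30 * patch_size, 0.44 * patch_size  # semi-axes (x, y)
    mask = (((xs - c) / a) ** 2 + ((ys - c) / b) ** 2 <= 1.0)

    crops = np.zeros((n_seeds, patch_size, patch_size, len(wl)), dtype=np.float32)
    for i, p in enumerate(protein):
        spectrum = seed_reflectance(wl, p, alpha=link_alpha)
        patch = np.where(mask[:, :, None], spectrum[None, None, :], 0.0)
        if noise_sd > 0:
            noise = rng.normal(0.0, noise_sd, patch.shape)
            patch = np.where(mask[:, :, None], np.clip(patch + noise, 0, None), 0.0)
        crops[i] = patch.astype(np.float32)
    return crops, protein
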