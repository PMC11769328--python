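"""Radiometric calibration: raw digital numbers -> radiance -> reflectance.

The chain follows the standard bench-top push-broom procedure: subtract the
dark-current frame, derive a per-pixel-per-band radiometric response from a
bright scan of a reflectance panel of known output, divide by response and
integration time to obtain spectral radiance, and normalize by the panel
region to obtain reflectance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envi import SpectralCube

__all__ = [
    "RadiometricResponse",
    "subtract_background",
    "compute_response",
    "to_radiance",
    "to_reflectance",
]


@dataclass
class RadiometricResponse:
    """Per-pixel-per-band response R (DN per unit radiant exposure).

    ``invalid`` flags pixels whose bright-minus-dark signal was not positive;
    their response is unusable and radiance there is reported as 0.
    """

    response: np.ndarray
    integration_time: float
    panel_exposure: float
    invalid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.integration_time <= 0:
            raise ValueError("integration_time must be > 0")
        if self.invalid is None:
            self.invalid = np.zeros(self.response.shape, dtype=bool)


def subtract_background(raw: SpectralCube, dark: SpectralCube) -> SpectralCube:
    """Dark-current subtraction, S = S_raw - S_bg, clipped at zero.

    Negative excursions are dark-noise artifacts and are clipped rather than
    propagated.
    """
    if raw.shape != dark.shape:
        raise ValueError(f"shape mismatch: raw {raw.shape} vs dark {dark.shape}")
    signal = np.clip(raw.data.astype(float) - dark.data.astype(float), 0.0, None)
    return SpectralCube(signal, raw.wavelengths, "dn", raw.interleave)


def compute_response(
    bright: SpectralCube,
    dark: SpectralCube,
    l_ref: float,
    integration_time: float = 1.0,
) -> RadiometricResponse:
    """Radiometric response R = (S_bright - S_bg) / L_ref, elementwise.

    ``l_ref`` is the panel's known radiant exposure (radiance x integration
    time) during the bright scan.  Pixels with non-positive numerator are
    flagged invalid instead of producing nonsense responses.
    """
    if l_ref <= 0:
        raise ValueError("l_ref must be > 0")
    if bright.shape != dark.shape:
        raise ValueError("bright/dark shape mismatch")
    numerator = bright.data.astype(float) - dark.data.astype(float)
    invalid = numerator <= 0
    response = np.where(invalid, np.nan, numerator) / l_ref
    return RadiometricResponse(response, integration_time, l_ref, invalid)


def to_radiance(signal: SpectralCube, resp: RadiometricResponse) -> SpectralCube:
    """Convert a background-subtracted DN cube to spectral radiance.

    L = S / (R * t_int); invalid-response pixels map to 0.
    """
    if resp.integration_time <= 0:
        raise ValueError("integration_time must be > 0")
    if signal.shape != resp.response.shape:
        raise ValueError("signal/response shape mismatch")
    with np.errstate(invalid="ignore", divide="ignore"):
        radiance = signal.data / (resp.response * resp.integration_time)
    radiance = np.where(resp.invalid, 0.0, radiance)
    return SpectralCube(radiance, signal.wavelengths, "radiance", signal.interleave)


def to_reflectance(
    scene: SpectralCube,
    panel: SpectralCube | np.ndarray,
    panel_reflectance: float = 0.5,
) -> SpectralCube:
    """Panel-normalized reflectance.

    ``panel`` is a radiance cube (or array) covering the reflectance-panel
    region of interest; it is summarized per band by its spatial mean.  The
    scene is then scaled as ``scene / panel_mean * panel_reflectance``.
    """
    if not 0 < panel_reflectance <= 1:
        raise ValueError("panel_reflectance must be in (0, 1]")
    panel_data = panel.data if isinstance(panel, SpectralCube) else np.asarray(panel)
    if panel_data.ndim != 3 or panel_data.shape[2] != scene.n_bands:
        raise ValueError("panel region must be 3-D with the scene's band count")
    panel_mean = panel_data.reshape(-1, panel_data.shape[2]).mean(axis=0)
    if np.any(panel_mean <= 0):
        bad = np.flatnonzero(panel_mean <= 0)
        raise ValueError(f"panel radiance non-positive in bands {bad[:5].tolist()}")
    refl = scene.data / panel_mean * panel_reflectance
    return SpectralCube(refl, scene.wavelengths, "reflectance", scene.interleave)
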