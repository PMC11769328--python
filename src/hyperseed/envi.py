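"""ENVI-format hyperspectral cube I/O.

An ENVI dataset is a pair of files: an ASCII ``.hdr`` describing the raster
(samples = width, lines = height, bands, interleave, data type, wavelengths)
and a headerless raw binary holding the pixel values.  Cubes are kept in
memory as ``(lines, samples, bands)`` float arrays regardless of the
interleave they were stored with.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpectralCube", "read_envi", "write_envi", "band_at"]

# ENVI numeric "data type" codes -> numpy dtypes (subset used here)
_DTYPE_CODES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_CODE_FOR_DTYPE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}

_INTERLEAVES = ("bil", "bip", "bsq")


@dataclass
class SpectralCube:
    """A height x width x bands volume with per-band wavelengths in nm.

    ``units`` tags the physical meaning of the values: raw digital numbers
    (``dn``), spectral radiance (``radiance``) or reflectance fractions
    (``reflectance``).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    units: str = "reflectance"
    interleave: str = "bil"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (height, width, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"{self.data.shape[2]} bands but {self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube data must be finite")
        if self.interleave not in _INTERLEAVES:
            raise ValueError(f"interleave must be one of {_INTERLEAVES}")

    @classmethod
    def stacked(cls, data: np.ndarray, wavelengths: np.ndarray,
                units: str = "reflectance", interleave: str = "bil") -> "SpectralCube":
        """Build a cube whose wavelength list need not be monotone.

        Used for multi-sensor stacks where the sensors' ranges overlap, so the
        concatenated wavelength list is only piecewise increasing.
        """
        cube = cls.__new__(cls)
        cube.data = np.asarray(data)
        cube.wavelengths = np.asarray(wavelengths, dtype=float)
        cube.units = units
        cube.interleave = interleave
        if cube.data.ndim != 3 or cube.data.shape[2] != cube.wavelengths.size:
            raise ValueError("data/wavelength shape mismatch")
        return cube

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


def _parse_header(text: str) -> dict:
    """Parse an ENVI header into a {key: value} dict (values as strings or lists)."""
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic)")
    # join multi-line { ... } blocks
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            inner = value.strip("{}").strip()
            fields[key] = [v.strip() for v in inner.split(",") if v.strip()]
        else:
            fields[key] = value
    return fields


def read_envi(header_path: str | Path) -> SpectralCube:
    """Read an ENVI header/binary pair into a :class:`SpectralCube`.

    Raises if the wavelength block is missing, its length disagrees with the
    declared band count, or the binary size is inconsistent with the header.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = str(fields["interleave"]).lower()
    except KeyError as exc:
        raise ValueError(f"header missing required field: {exc}") from exc

    if "wavelength" not in fields:
        raise ValueError("header has no wavelength block")
    wavelengths = np.array([float(w) for w in fields["wavelength"]])
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but {wavelengths.size} wavelengths"
        )
    # headers written in micrometers: convert to nm
    if np.all(wavelengths < 10.0):
        wavelengths = wavelengths * 1000.0

    if dtype_code not in _DTYPE_CODES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_DTYPE_CODES[dtype_code])
    byte_order = int(fields.get("byte order", 0))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    bin_path = _binary_path_for(header_path)
    raw = np.fromfile(bin_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"binary holds {raw.size} values, header implies {expected}"
        )

    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    units = str(fields.get("units", "reflectance"))
    data = np.ascontiguousarray(data)
    if wavelengths.size > 1 and not np.all(np.diff(wavelengths) > 0):
        # multi-sensor stack: wavelength list is only piecewise increasing
        return SpectralCube.stacked(data, wavelengths, units, interleave)
    return SpectralCube(data, wavelengths, units, interleave)


def _binary_path_for(header_path: Path) -> Path:
    for candidate in (header_path.with_suffix(".img"), header_path.with_suffix(""),
                      header_path.with_suffix(".dat")):
        if candidate.exists() and candidate != header_path:
            return candidate
    raise FileNotFoundError(f"no binary companion found for {header_path}")


def write_envi(cube: SpectralCube, out_path: str | Path, dtype_code: int = 4) -> Path:
    """Write ``cube`` as an ENVI header (``.hdr``) + raw binary (``.img``) pair.

    Returns the header path.  Data are stored as 32-bit floats by default.
    """
    if cube.n_bands == 0 or cube.data.size == 0:
        raise ValueError("refusing to write an empty cube")
    out_path = Path(out_path)
    header_path = out_path if out_path.suffix == ".hdr" else out_path.with_suffix(".hdr")
    bin_path = header_path.with_suffix(".img")

    h, w, b = cube.shape
    dtype = np.dtype(_DTYPE_CODES[dtype_code]).newbyteorder("<")
    if cube.interleave == "bsq":
        arr = cube.data.transpose(2, 0, 1)
    elif cube.interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)
    else:  # bip
        arr = cube.data
    np.ascontiguousarray(arr, dtype=dtype).tofile(bin_path)

    wl = ", ".join(f"{x:.6f}" for x in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {hyperseed cube}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {dtype_code}\n"
        f"interleave = {cube.interleave}\n"
        "byte order = 0\n"
        f"units = {cube.units}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    return header_path


def band_at(cube: SpectralCube, wavelength_nm: float) -> int:
    """Index of the band whose wavelength is nearest ``wavelength_nm``.

    Ties break to the lower index.  Requests farther than one inter-band step
    outside the covered range are rejected.
    """
    wl = cube.wavelengths
    if wl.size == 0:
        raise ValueError("cube has no bands")
    step = float(np.max(np.diff(wl))) if wl.size > 1 else 0.0
    if wavelength_nm < wl[0] - step or wavelength_nm > wl[-1] + step:
        raise ValueError(
            f"{wavelength_nm} nm outside covered range "
            f"[{wl[0]:.1f}, {wl[-1]:.1f}] +/- {step:.1f} nm"
        )
    dist = np.abs(wl - wavelength_nm)
    return int(np.argmin(dist))  # argmin returns the first (lower) index on ties
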