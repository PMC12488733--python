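"""Hyperspectral cube I/O and white-reference correction.

A push-broom Vis-NIR imager produces a rows x cols x bands intensity volume
together with a measurement of a white reflectance-standard panel.  Dividing
the (dark-corrected) raw intensities by the (dark-corrected) panel intensities
converts counts to relative reflectance, removing lamp spectrum and detector
gain.  Cubes are stored band-last in memory; on disk the ENVI convention
(text header + flat binary, BIL/BIP/BSQ interleaves) is used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "HyperCube",
    "WhiteReference",
    "read_envi",
    "write_envi",
    "white_correct",
]

#: Default spectral axis of the instrument: 360 contiguous bands over
#: 395-1008 nm (band centers evenly spaced, endpoints included).
DEFAULT_RANGE_NM = (395.0, 1008.0)
DEFAULT_N_BANDS = 360


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", values)

    @property
    def count(self) -> int:
        return int(self.values.size)

    @classmethod
    def default(cls, n_bands: int = DEFAULT_N_BANDS,
                span_nm: tuple[float, float] = DEFAULT_RANGE_NM) -> "WavelengthGrid":
        """Evenly spaced band centers spanning ``span_nm`` inclusive."""
        lo, hi = span_nm
        return cls(np.linspace(lo, hi, n_bands))

    def nearest_band(self, wavelength_nm: float) -> int:
        """Index of the band center closest to ``wavelength_nm``.

        Raises ``ValueError`` for wavelengths outside the grid range.
        """
        lo, hi = self.values[0], self.values[-1]
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside grid range "
                f"[{lo}, {hi}] nm"
            )
        return int(np.argmin(np.abs(self.values - wavelength_nm)))


@dataclass
class HyperCube:
    """A rows x cols x bands volume with its wavelength axis.

    ``kind`` is ``"raw"`` for detector counts and ``"reflectance"`` after
    white-reference correction; reflectance values live in ``[0, 1 + headroom]``
    (specular highlights on glossy fruit may slightly exceed the white panel).
    """

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.grid.count:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but grid has "
                f"{self.grid.count}"
            )
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class WhiteReference:
    """Per-band mean intensity of the white panel, with optional dark current."""

    spectrum: np.ndarray
    dark: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if self.dark is None:
            self.dark = np.zeros_like(self.spectrum)
        else:
            self.dark = np.asarray(self.dark, dtype=float)
        if self.dark.shape != self.spectrum.shape:
            raise ValueError("dark spectrum must match white spectrum shape")
        if np.any(self.spectrum <= self.dark):
            bad = np.nonzero(self.spectrum <= self.dark)[0]
            raise ValueError(
                f"white spectrum not above dark at bands {bad.tolist()}"
            )


# --------------------------------------------------------------------------
# ENVI format
# --------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str) -> dict:
    """Parse ENVI key = value pairs, including {...} blocks spanning lines."""
    fields: dict[str, str] = {}
    # join {...} blocks onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path: str | Path) -> HyperCube:
    """Read an ENVI header/binary pair into a band-last ``HyperCube``.

    Supports BIL, BIP and BSQ interleaves and the common integer and float
    data types.  The wavelength list is required: without it, downstream
    band selection by nanometre is meaningless.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())

    try:
        samples = int(fields["samples"])   # columns
        lines = int(fields["lines"])       # rows
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header {header_path} missing field {exc}") from exc

    if "wavelength" not in fields:
        raise ValueError(f"ENVI header {header_path} has no wavelength field")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(w) for w in wl_text.split(",") if w.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"header lists {wavelengths.size} wavelengths but {bands} bands"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")

    byte_order = int(fields.get("byte order", 0))
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<" if byte_order == 0 else ">")

    data_path = _sibling_binary(header_path)
    raw = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"{data_path} holds {raw.size} values, header implies {expected}"
        )

    if interleave == "bsq":       # (bands, rows, cols)
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":     # (rows, bands, cols)
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:                         # bip: (rows, cols, bands)
        cube = raw.reshape(lines, samples, bands)

    return HyperCube(np.ascontiguousarray(cube), WavelengthGrid(wavelengths),
                     kind="raw")


def _sibling_binary(header_path: Path) -> Path:
    """Locate the binary partner of an ENVI .hdr file."""
    if header_path.suffix == ".hdr":
        for ext in ("", ".img", ".dat", ".raw", ".bsq", ".bil", ".bip"):
            candidate = header_path.with_suffix(ext)
            if candidate.exists() and candidate != header_path:
                return candidate
    raise FileNotFoundError(f"no binary file found next to {header_path}")


def write_envi(cube: HyperCube, header_path: str | Path,
               interleave: str = "bsq") -> Path:
    """Write a cube as an ENVI header + flat binary pair.

    Emits 32-bit little-endian float; returns the binary path.
    """
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")

    rows, cols, bands = cube.shape
    data = np.asarray(cube.data, dtype="<f4")
    if interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = data.transpose(0, 2, 1)
    else:
        flat = data

    binary_path = header_path.with_suffix(".img")
    np.ascontiguousarray(flat).tofile(binary_path)

    wl = ", ".join(f"{w:.6f}" for w in cube.grid.values)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(np.float32)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return binary_path


# --------------------------------------------------------------------------
# White-reference correction
# --------------------------------------------------------------------------

def white_correct(raw: HyperCube, ref: WhiteReference,
                  headroom: float = 0.1) -> HyperCube:
    """Convert raw counts to relative reflectance.

    reflectance[p, b] = (raw[p, b] - dark[b]) / (white[b] - dark[b]),
    clipped to ``[0, 1 + headroom]``.  The instrument's 30-min preheat keeps
    dark current small, so ``dark`` defaults to zero, but a measured dark
    frame can be supplied.
    """
    if raw.kind != "raw":
        raise ValueError("white_correct expects a raw cube")
    if ref.spectrum.size != raw.grid.count:
        raise ValueError(
            f"white reference has {ref.spectrum.size} bands, cube has "
            f"{raw.grid.count}"
        )
    denom = ref.spectrum - ref.dark
    zero = np.nonzero(denom == 0)[0]
    if zero.size:
        raise ValueError(f"zero white-minus-dark denominator at bands {zero.tolist()}")
    reflectance = (raw.data.astype(float) - ref.dark) / denom
    np.clip(reflectance, 0.0, 1.0 + headroom, out=reflectance)
    return HyperCube(reflectance, raw.grid, kind="reflectance")
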