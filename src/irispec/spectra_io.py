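"""Spectrum container, absorbance <-> extinction conversion, distortions, file I/O.

A single-element IR detector reports the apparent absorbance
``A = -log10(I/I0)``, which mixes true absorption with light scattered out of
the forward direction.  With ``G`` the detector reception area and ``g`` the
geometric cross section of the particle (``G >> g``), the extinction
efficiency follows from the apparent absorbance as

    Q_ext = (G/g) * (1 - 10^(-A))

and the two representations carry the same information.

Experimental spectra additionally suffer baseline shift, tilt, curvature and
scaling distortions.  These are modelled on the absorbance representation
(where they physically arise) as

    A_distorted(v) = s * A(v) + c0 + c1 * u + c2 * u^2

with ``u = (v - v_mid) / (v_max - v_min)`` a centred, range-normalized
wavenumber coordinate in [-0.5, 0.5] that keeps the coefficients O(1) and
mutually decorrelated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .dispersion import WavenumberGrid

__all__ = [
    "Spectrum",
    "ConversionParams",
    "DistortionParams",
    "absorbance_to_qext",
    "qext_to_absorbance",
    "apply_distortion",
    "remove_distortion",
    "read_spectrum",
    "write_spectrum",
    "read_index_table",
    "interpolate_index",
]

SpectrumKind = Literal["absorbance", "qext"]
_KINDS = ("absorbance", "qext")


@dataclass(frozen=True)
class Spectrum:
    """Values on a wavenumber grid, tagged as apparent absorbance or Q_ext.

    Absorbance values are allowed to dip negative: raw experimental baselines do.
    """

    grid: WavenumberGrid
    values: np.ndarray
    kind: SpectrumKind

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.values.shape:
            raise ValueError("values must match the grid shape")
        if not np.isfinite(vals).all():
            raise ValueError("spectrum values must be finite")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.grid)

    def with_values(self, values: np.ndarray, kind: SpectrumKind | None = None) -> "Spectrum":
        return Spectrum(grid=self.grid, values=values, kind=kind or self.kind)


@dataclass(frozen=True)
class ConversionParams:
    """G/g: detector reception area over particle geometric cross section (> 1)."""

    g_ratio: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.g_ratio) or self.g_ratio <= 1.0:
            raise ValueError(f"G/g must be > 1, got {self.g_ratio}")


@dataclass(frozen=True)
class DistortionParams:
    """Multiplicative scale plus quadratic additive baseline (absorbance units)."""

    scale: float = 1.0
    shift: float = 0.0
    tilt: float = 0.0
    curvature: float = 0.0

    def __post_init__(self) -> None:
        p = [self.scale, self.shift, self.tilt, self.curvature]
        if not np.isfinite(p).all():
            raise ValueError("distortion parameters must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    @property
    def is_identity(self) -> bool:
        return (
            self.scale == 1.0
            and self.shift == 0.0
            and self.tilt == 0.0
            and self.curvature == 0.0
        )

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "shift": self.shift,
            "tilt": self.tilt,
            "curvature": self.curvature,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistortionParams":
        return cls(**{k: float(v) for k, v in d.items()})


def absorbance_to_qext(spec: Spectrum, params: ConversionParams) -> Spectrum:
    """Q_ext = (G/g) (1 - 10^-A); saturates at G/g for opaque samples."""
    if spec.kind != "absorbance":
        raise ValueError(f"expected an absorbance spectrum, got kind={spec.kind!r}")
    q = params.g_ratio * (1.0 - np.power(10.0, -spec.values))
    return spec.with_values(q, kind="qext")


def qext_to_absorbance(spec: Spectrum, params: ConversionParams) -> Spectrum:
    """Inverse of :func:`absorbance_to_qext`; requires 0 <= Q_ext < G/g."""
    if spec.kind != "qext":
        raise ValueError(f"expected a qext spectrum, got kind={spec.kind!r}")
    ratio = spec.values / params.g_ratio
    if (ratio >= 1.0).any():
        raise ValueError(
            "Q_ext reaches G/g; the assumed reception-area ratio is too small "
            "for these data"
        )
    a = -np.log10(1.0 - ratio)
    return spec.with_values(a, kind="absorbance")


def _normalized_coordinate(grid: WavenumberGrid) -> np.ndarray:
    v = grid.values
    if v.size < 2:
        raise ValueError("distortion needs a grid of at least 2 points")
    lo, hi = v[0], v[-1]
    return (v - 0.5 * (lo + hi)) / (hi - lo)


def apply_distortion(spec: Spectrum, d: DistortionParams) -> Spectrum:
    """s*A + c0 + c1*u + c2*u^2 on the centred unit coordinate u in [-0.5, 0.5]."""
    if spec.kind != "absorbance":
        raise ValueError("distortions are defined on absorbance spectra")
    u = _normalized_coordinate(spec.grid)
    return spec.with_values(d.scale * spec.values + d.shift + d.tilt * u + d.curvature * u**2)


def remove_distortion(spec: Spectrum, d: DistortionParams) -> Spectrum:
    """Exact inverse of :func:`apply_distortion` (scale > 0 guarantees it exists)."""
    if spec.kind != "absorbance":
        raise ValueError("distortions are defined on absorbance spectra")
    u = _normalized_coordinate(spec.grid)
    return spec.with_values(
        (spec.values - d.shift - d.tilt * u - d.curvature * u**2) / d.scale
    )


# ---------------------------------------------------------------------------
# File I/O: two-column spectra, three-column refractive-index tables
# ---------------------------------------------------------------------------


def _parse_columns(path: Path, ncols: int) -> np.ndarray:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) != ncols:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncols} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    return np.asarray(rows, dtype=float)


def _sorted_by_wavenumber(data: np.ndarray, path: Path) -> np.ndarray:
    v = data[:, 0]
    if np.unique(v).size != v.size:
        raise ValueError(f"{path}: duplicate wavenumbers")
    if (np.diff(v) < 0).any():
        warnings.warn(
            f"{path}: wavenumbers not ascending; re-sorting", stacklevel=3
        )
        data = data[np.argsort(v)]
    return data


def read_spectrum(path, kind: SpectrumKind) -> Spectrum:
    """Read a two-column (wavenumber cm^-1, value) text file; '#' comments allowed."""
    path = Path(path)
    data = _sorted_by_wavenumber(_parse_columns(path, 2), path)
    return Spectrum(grid=WavenumberGrid(data[:, 0]), values=data[:, 1], kind=kind)


def write_spectrum(spec: Spectrum, path) -> None:
    """Write a spectrum losslessly (12 significant digits) with a unit header."""
    path = Path(path)
    label = "apparent_absorbance" if spec.kind == "absorbance" else "extinction_efficiency_Qext"
    header = f"wavenumber_cm-1 {label}"
    np.savetxt(
        path,
        np.column_stack([spec.grid.values, spec.values]),
        fmt="%.12g",
        header=header,
    )


def read_index_table(path) -> tuple[WavenumberGrid, np.ndarray]:
    """Read a three-column (wavenumber, n, k) reference refractive-index table."""
    path = Path(path)
    data = _sorted_by_wavenumber(_parse_columns(path, 3), path)
    if (data[:, 2] < 0).any():
        raise ValueError(f"{path}: negative k values (absorbing convention needs k >= 0)")
    return WavenumberGrid(data[:, 0]), data[:, 1] + 1j * data[:, 2]


def write_index_table(grid: WavenumberGrid, index: np.ndarray, path) -> None:
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([grid.values, index.real, index.imag]),
        fmt="%.12g",
        header="wavenumber_cm-1 n k",
    )


def interpolate_index(
    table: tuple[WavenumberGrid, np.ndarray], grid: WavenumberGrid
) -> np.ndarray:
    """Linearly interpolate a tabulated complex index onto ``grid`` (no extrapolation)."""
    tgrid, tindex = table
    lo, hi = tgrid.span
    glo, ghi = grid.span
    if glo < lo or ghi > hi:
        raise ValueError(
            f"requested grid [{glo}, {ghi}] cm^-1 extends beyond the table span "
            f"[{lo}, {hi}] cm^-1; refusing to extrapolate"
        )
    n = np.interp(grid.values, tgrid.values, tindex.real)
    k = np.interp(grid.values, tgrid.values, tindex.imag)
    return n + 1j * k
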