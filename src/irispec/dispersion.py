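"""Kramers-Kronig-consistent dispersion model built from anti-symmetrized Lorentzians.

The imaginary part of the refractive index of a voxel (a region of spatially
constant optical properties -- the whole sphere, or the core/shell of a layered
sphere) is modelled as a sum of Lorentzian absorption bands, each
anti-symmetrized by subtracting its mirror image at negative wavenumber::

    Im eta(v) = sum_m [ h_m / (1 + ((v - v_m)/G_m)^2)
                      - h_m / (1 + ((v + v_m)/G_m)^2) ]

Anti-symmetry (``Im eta(-v) = -Im eta(v)``) is what causality demands of any
physical refractive index, and it is exactly what makes the Hilbert-transform
partner of each band available in closed form.  The real part is therefore
computed analytically rather than by numerical Kramers-Kronig integration::

    Re eta(v) = n_inf - sum_m [ h_m u_m^- / (1 + (u_m^-)^2)
                              - h_m u_m^+ / (1 + (u_m^+)^2) ]

with ``u_m^- = (v - v_m)/G_m`` and ``u_m^+ = (v + v_m)/G_m``.  ``n_inf`` is the
real baseline index contributed by resonances outside the measured window
(e.g. electronic transitions in the visible/UV).

A numerical principal-value Hilbert transform (:func:`kk_numeric_transform`)
is provided as a brute-force cross-check of the closed form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LorentzianBand",
    "VoxelDispersion",
    "WavenumberGrid",
    "imag_index",
    "real_index",
    "complex_index",
    "kk_numeric_transform",
]


@dataclass(frozen=True)
class LorentzianBand:
    """One absorption band: center and half-width in cm^-1, dimensionless height.

    The height is the peak value contributed to the imaginary refractive index
    (up to the tiny negative-mirror correction).
    """

    center: float
    height: float
    width: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.center, self.height, self.width]).all():
            raise ValueError("band parameters must be finite")
        if self.center <= 0:
            raise ValueError(f"band center must be > 0 cm^-1, got {self.center}")
        if self.width <= 0:
            raise ValueError(f"band width must be > 0 cm^-1, got {self.width}")
        if self.height < 0:
            raise ValueError(f"band height must be >= 0, got {self.height}")


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumbers in cm^-1 (wavenumber = 1 / vacuum wavelength)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("grid must be a non-empty 1-D array")
        if not np.isfinite(v).all():
            raise ValueError("grid values must be finite")
        if (v <= 0).any():
            raise ValueError("wavenumbers must be positive")
        if (np.diff(v) <= 0).any():
            raise ValueError("wavenumbers must be strictly increasing")
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @classmethod
    def regular(cls, start: float, stop: float, spacing: float) -> "WavenumberGrid":
        n = int(round((stop - start) / spacing)) + 1
        return cls(start + spacing * np.arange(n))

    def __len__(self) -> int:
        return self.values.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


def _canonical_bands(bands: Iterable[LorentzianBand]) -> tuple[LorentzianBand, ...]:
    # sort by center; ties broken by height descending so band matching is stable
    return tuple(sorted(bands, key=lambda b: (b.center, -b.height)))


@dataclass(frozen=True)
class VoxelDispersion:
    """Complex refractive-index model of one voxel: M bands plus the baseline n_inf.

    ``n_infinity`` must be >= 1 (a passive dielectric); bands are stored in
    canonical order (ascending center).  An empty band set is permitted only
    through :meth:`_degenerate` for internal testing.
    """

    bands: tuple[LorentzianBand, ...]
    n_infinity: float = 1.5

    def __post_init__(self) -> None:
        bands = _canonical_bands(self.bands)
        if len(bands) < 1:
            raise ValueError("a dispersion model needs at least one band")
        if not np.isfinite(self.n_infinity) or self.n_infinity < 1.0:
            raise ValueError(f"n_infinity must be >= 1, got {self.n_infinity}")
        object.__setattr__(self, "bands", bands)

    @classmethod
    def _degenerate(cls, n_infinity: float = 1.5) -> "VoxelDispersion":
        """Band-free constant index; bypasses the M >= 1 check (tests only)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "bands", ())
        object.__setattr__(obj, "n_infinity", float(n_infinity))
        return obj

    @classmethod
    def from_arrays(
        cls,
        centers: Sequence[float],
        heights: Sequence[float],
        widths: Sequence[float],
        n_infinity: float = 1.5,
    ) -> "VoxelDispersion":
        bands = tuple(
            LorentzianBand(float(c), float(h), float(w))
            for c, h, w in zip(centers, heights, widths, strict=True)
        )
        return cls(bands=bands, n_infinity=n_infinity)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def band_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = np.array([b.center for b in self.bands])
        h = np.array([b.height for b in self.bands])
        w = np.array([b.width for b in self.bands])
        return c, h, w

    # -- evaluation -----------------------------------------------------

    def imag_index(self, grid: WavenumberGrid | np.ndarray) -> np.ndarray:
        return imag_index(self, grid)

    def real_index(self, grid: WavenumberGrid | np.ndarray) -> np.ndarray:
        return real_index(self, grid)

    def complex_index(self, grid: WavenumberGrid | np.ndarray) -> np.ndarray:
        return complex_index(self, grid)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "basis": "lorentzian",
            "n_infinity": float(self.n_infinity),
            "bands": [
                {"center_cm1": b.center, "height": b.height, "width_cm1": b.width}
                for b in self.bands
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelDispersion":
        basis = d.get("basis", "lorentzian")
        if basis != "lorentzian":
            raise ValueError(f"unsupported dispersion basis {basis!r}")
        bands = tuple(
            LorentzianBand(b["center_cm1"], b["height"], b["width_cm1"])
            for b in d["bands"]
        )
        return cls(bands=bands, n_infinity=float(d["n_infinity"]))


def _as_values(grid: WavenumberGrid | np.ndarray) -> np.ndarray:
    if isinstance(grid, WavenumberGrid):
        return grid.values
    v = np.asarray(grid, dtype=float)
    if v.size == 0:
        raise ValueError("empty evaluation grid")
    return v


def imag_index(model: VoxelDispersion, grid: WavenumberGrid | np.ndarray) -> np.ndarray:
    """Imaginary refractive index of ``model`` on ``grid`` (odd in the wavenumber)."""
    v = _as_values(grid)
    c, h, w = model.band_arrays()
    if c.size == 0:
        return np.zeros_like(v)
    um = (v[..., None] - c) / w
    up = (v[..., None] + c) / w
    return np.sum(h / (1.0 + um**2) - h / (1.0 + up**2), axis=-1)


def real_index(model: VoxelDispersion, grid: WavenumberGrid | np.ndarray) -> np.ndarray:
    """Real refractive index: n_inf plus the analytic Hilbert partner of each band."""
    v = _as_values(grid)
    c, h, w = model.band_arrays()
    if c.size == 0:
        return np.full_like(v, model.n_infinity, dtype=float)
    um = (v[..., None] - c) / w
    up = (v[..., None] + c) / w
    return model.n_infinity - np.sum(
        h * um / (1.0 + um**2) - h * up / (1.0 + up**2), axis=-1
    )


def complex_index(model: VoxelDispersion, grid: WavenumberGrid | np.ndarray) -> np.ndarray:
    """Complex refractive index ``n + i k`` with the absorbing k >= 0 convention."""
    return real_index(model, grid) + 1j * imag_index(model, grid)


def kk_numeric_transform(
    wide_grid: np.ndarray,
    imag_values: np.ndarray,
    eval_grid: np.ndarray,
) -> np.ndarray:
    """Brute-force principal-value Kramers-Kronig transform of a sampled Im eta.

    ``wide_grid`` must be a dense grid of positive wavenumbers wide enough that
    the integrand has decayed at its edges; the imaginary part is extended
    anti-symmetrically to negative wavenumbers and the principal-value integral

        Re eta(v) - n_inf = (1/pi) PV int Im eta(v') / (v' - v) dv'

    is evaluated by trapezoid quadrature with the singularity removed by the
    standard subtraction trick.  Serves as an independent oracle for
    :func:`real_index`; evaluation points are restricted to the inner half of
    the wide grid to keep edge-truncation error away.
    """
    vg = np.asarray(wide_grid, dtype=float)
    gi = np.asarray(imag_values, dtype=float)
    ve = np.atleast_1d(np.asarray(eval_grid, dtype=float))
    if vg.ndim != 1 or vg.size < 16 or (np.diff(vg) <= 0).any():
        raise ValueError("wide grid must be dense, 1-D and strictly increasing")
    if gi.shape != vg.shape:
        raise ValueError("imaginary values must match the wide grid")
    lo, hi = vg[0], vg[-1]
    # the integrand is extended anti-symmetrically to [-hi, hi], so the usable
    # region is the inner half of that extended span (and inside the data)
    if ((ve < lo) | (ve > 0.5 * hi)).any():
        raise ValueError(
            "evaluation points must lie in the inner 50% of the (extended) wide "
            "grid (edge truncation would corrupt the transform)"
        )

    # anti-symmetric extension onto [-hi, hi]
    full = np.concatenate([-vg[::-1], vg])
    gfull = np.concatenate([-gi[::-1], gi])

    out = np.empty_like(ve)
    for i, v in enumerate(ve):
        g_at_v = np.interp(v, full, gfull)
        diff = full - v
        integrand = np.empty_like(gfull)
        small = np.abs(diff) < 1e-12
        integrand[~small] = (gfull[~small] - g_at_v) / diff[~small]
        if small.any():
            # replace the singular sample by the local derivative
            j = np.flatnonzero(small)[0]
            jl, jr = max(j - 1, 0), min(j + 1, full.size - 1)
            integrand[small] = (gfull[jr] - gfull[jl]) / (full[jr] - full[jl])
        pv = np.trapezoid(integrand, full)
        pv += g_at_v * np.log(abs((full[-1] - v) / (v - full[0])))
        out[i] = pv / np.pi
    return out if np.ndim(eval_grid) else out[0]
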