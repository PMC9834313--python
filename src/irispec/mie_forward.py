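"""Lorenz-Mie extinction of homogeneous and two-layer (coated) spheres.

Efficiencies are computed from the partial-wave series

    Q_ext = (2/x^2) sum_n (2n+1) Re(a_n + b_n)
    Q_sca = (2/x^2) sum_n (2n+1) (|a_n|^2 + |b_n|^2)

with the series truncated at the Wiscombe order N = ceil(x + 4 x^(1/3) + 2).
The complex refractive index uses the ``m = n + ik``, ``k >= 0`` absorbing
convention (time dependence exp(-i w t)); the host medium is vacuum/air.

Numerics
--------
Homogeneous spheres use the logarithmic derivative ``D_n = psi_n'/psi_n`` of
the Riccati-Bessel function at the (complex) internal argument, computed by
downward recurrence seeded well above the truncation order -- the classic
stable formulation; the regular function psi follows from those ratios
(normalized to psi_0 = sin z) and the irregular chi by upward recurrence,
which is its stable direction.  The series itself runs in JIT-compiled
scalar kernels (:mod:`irispec._mie_kernels`) with per-point truncation.

Coated (two-layer) spheres solve the concentric-sphere boundary-value problem
(Aden-Kerker).  The shell radial functions mix the regular and irregular
Riccati-Bessel solutions; for absorbing media the irregular part grows
exponentially, so all shell quantities are assembled from logarithmic
derivatives and cross ratios of the form ``psi_n(z1)/psi_n(z2)`` and
``chi_n(z2)/chi_n(z1)`` whose exponential factors largely cancel
(ratio-stabilized, Toon-Ackerman style).  Coated efficiencies are referenced
to the OUTER geometric cross section.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._mie_kernels import coated_efficiencies, homogeneous_efficiencies
from .dispersion import VoxelDispersion, WavenumberGrid, complex_index

__all__ = [
    "SphereGeometry",
    "MieResult",
    "size_parameter",
    "truncation_order",
    "qext_homogeneous",
    "qext_coated",
    "qext_from_dispersion",
]

_CM_PER_UM = 1.0e-4


@dataclass(frozen=True)
class SphereGeometry:
    """Outer radius and optional core radius, both in micrometres.

    A bare sphere has one voxel (J = 1); a core turns the shell into a second
    voxel (J = 2), core listed first.
    """

    outer_radius: float
    core_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.outer_radius) or self.outer_radius <= 0:
            raise ValueError(f"outer radius must be > 0 um, got {self.outer_radius}")
        if self.core_radius is not None:
            if not np.isfinite(self.core_radius) or self.core_radius <= 0:
                raise ValueError(f"core radius must be > 0 um, got {self.core_radius}")
            if self.core_radius >= self.outer_radius:
                raise ValueError(
                    f"core radius {self.core_radius} um must be smaller than "
                    f"outer radius {self.outer_radius} um"
                )

    @property
    def J(self) -> int:
        return 1 if self.core_radius is None else 2

    @property
    def geometric_cross_section(self) -> float:
        """pi * outer_radius^2 in um^2."""
        return float(np.pi * self.outer_radius**2)


@dataclass(frozen=True)
class MieResult:
    """Per-wavenumber efficiencies plus the outer geometric cross section (um^2)."""

    q_ext: np.ndarray
    q_sca: np.ndarray
    q_abs: np.ndarray
    geometric_cross_section: float


def size_parameter(radius_um: float, wavenumber_cm1) -> np.ndarray | float:
    """Dimensionless size parameter x = 2 pi r / lambda = 2 pi r vtilde."""
    if np.any(np.asarray(radius_um) < 0):
        raise ValueError("radius must be non-negative")
    return 2.0 * np.pi * radius_um * _CM_PER_UM * np.asarray(wavenumber_cm1, dtype=float)


def truncation_order(x: float) -> int:
    """Wiscombe series length N = ceil(x + 4 x^(1/3) + 2), clamped to N >= 3."""
    if x <= 0:
        raise ValueError("size parameter must be positive")
    return max(3, int(np.ceil(x + 4.0 * np.cbrt(x) + 2.0)))


def _validate_index(m: np.ndarray, L: int, what: str) -> np.ndarray:
    m = np.asarray(m, dtype=complex)
    if m.shape == ():
        m = np.full(L, complex(m))
    if m.shape != (L,):
        raise ValueError(f"{what} must be scalar or match the grid length {L}")
    if not np.isfinite(m).all():
        raise ValueError(f"{what} contains non-finite values")
    if (m.imag < -1e-12).any():
        raise ValueError(
            f"{what} has a negative imaginary part; this module uses the "
            "m = n + ik, k >= 0 absorbing convention"
        )
    return m


def qext_homogeneous(
    index,
    radius_um: float,
    grid: WavenumberGrid,
) -> MieResult:
    """Efficiencies of a homogeneous sphere for a per-grid complex index."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    v = grid.values
    L = v.size
    m = _validate_index(index, L, "refractive index")
    x = size_parameter(radius_um, v)
    qext, qsca = homogeneous_efficiencies(np.ascontiguousarray(m),
                                          np.ascontiguousarray(x))
    g = float(np.pi * radius_um**2)
    return MieResult(q_ext=qext, q_sca=qsca, q_abs=qext - qsca, geometric_cross_section=g)


def qext_coated(
    core_index,
    shell_index,
    geometry: SphereGeometry,
    grid: WavenumberGrid,
) -> MieResult:
    """Efficiencies of a two-layer sphere, referenced to the outer cross section.

    Boundary conditions at the core surface fix, per order, the admixture of
    the irregular shell solution; TM (electric) modes require continuity of
    (1/m) psi'/psi, TE (magnetic) modes of m psi'/psi.  The resulting shell
    log-derivatives replace the homogeneous D_n at the outer surface.
    """
    if geometry.core_radius is None:
        raise ValueError("geometry has no core; use qext_homogeneous")
    v = grid.values
    L = v.size
    m1 = _validate_index(core_index, L, "core index")
    m2 = _validate_index(shell_index, L, "shell index")
    x = size_parameter(geometry.core_radius, v)   # core size parameter
    y = size_parameter(geometry.outer_radius, v)  # outer size parameter
    qext, qsca = coated_efficiencies(
        np.ascontiguousarray(m1), np.ascontiguousarray(m2),
        np.ascontiguousarray(x), np.ascontiguousarray(y))
    return MieResult(
        q_ext=qext,
        q_sca=qsca,
        q_abs=qext - qsca,
        geometric_cross_section=geometry.geometric_cross_section,
    )


def qext_from_dispersion(
    models: Sequence[VoxelDispersion] | VoxelDispersion,
    geometry: SphereGeometry,
    grid: WavenumberGrid,
):
    """Forward map: dispersion model(s) -> extinction-efficiency Spectrum.

    One model for a homogeneous sphere, (core, shell) for a two-layer sphere.
    This is the model spectrum the reconstruction engine fits to the data.
    """
    from .spectra_io import Spectrum  # local import avoids a cycle

    if isinstance(models, VoxelDispersion):
        models = (models,)
    models = tuple(models)
    if len(models) != geometry.J:
        raise ValueError(
            f"geometry has {geometry.J} voxel(s) but {len(models)} dispersion "
            "model(s) were supplied"
        )
    if geometry.J == 1:
        m = complex_index(models[0], grid)
        res = qext_homogeneous(m, geometry.outer_radius, grid)
    else:
        mc = complex_index(models[0], grid)
        ms = complex_index(models[1], grid)
        res = qext_coated(mc, ms, geometry, grid)
    return Spectrum(grid=grid, values=res.q_ext, kind="qext")
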