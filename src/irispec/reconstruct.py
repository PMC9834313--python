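"""Inverse-scattering engine: fit Kramers-Kronig-consistent Lorentzian dispersions
to a measured extinction (or apparent-absorbance) spectrum through the Mie
forward model.

The estimation problem is a bounded nonlinear least-squares fit of the target

    S = sum_l [ Q_ext_model(v_l) - Q_ext_given(v_l) ]^2

over, per voxel, M band centers/heights/widths plus the baseline index n_inf,
optionally the experimental distortion parameters (scale, shift, tilt,
curvature) and the sphere radii.  Band centers start equi-spaced across the
measured window (unbiased initialization: some start band is always near every
true band), heights and widths start at small random values, and the fit is
repeated from ``n_starts`` seeded starts, keeping the best objective.

Usage follows the model/results pattern::

    model = RefractiveIndexModel(spectrum, geometry, config)
    results = model.fit()
    results.summary()
    nk = results.complex_index(voxel=0, grid=grid)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

from .dispersion import VoxelDispersion, WavenumberGrid, LorentzianBand
from .mie_forward import SphereGeometry, qext_coated, qext_homogeneous
from .quality import ReconstructionScore, r_squared
from .spectra_io import (
    ConversionParams,
    DistortionParams,
    Spectrum,
    write_index_table,
    write_spectrum,
)

__all__ = [
    "FitConfig",
    "RefractiveIndexModel",
    "RefractiveIndexResults",
    "FitResult",
    "init_parameters",
    "objective_s",
    "equispaced_centers",
    "fit",
    "fit_layered",
]

_N_RADIUS_SCAN = 13  # coarse radius profile resolution per start


@dataclass(frozen=True)
class FitConfig:
    """Everything that controls a reconstruction fit.

    ``bands_per_voxel`` is M, one value per voxel (an int is broadcast).
    Bounds are box constraints handed to the trust-region solver; center
    bounds default to the measured wavenumber range.  Free radii start from
    the geometry the model was built with and default to +/-50% bounds
    around that start.
    """

    bands_per_voxel: int | tuple[int, ...] = 6
    height_bounds: tuple[float, float] = (0.0, 1.0)
    width_bounds: tuple[float, float] = (2.0, 400.0)
    center_bounds: Optional[tuple[float, float]] = None
    n_infinity_bounds: tuple[float, float] = (1.0, 2.0)
    init_height_range: tuple[float, float] = (0.001, 0.1)
    init_width_range: tuple[float, float] = (5.0, 50.0)
    n_infinity_init: float = 1.5
    fit_distortion: bool = False
    fit_outer_radius: bool = False
    fit_core_radius: bool = False
    outer_radius_bounds: Optional[tuple[float, float]] = None
    core_radius_bounds: Optional[tuple[float, float]] = None
    g_ratio: Optional[float] = None
    seed: int = 0
    n_starts: int = 3
    n_basin_hops: int = 4
    max_evaluations: int = 400
    step_tolerance: float = 1e-10
    residual_tolerance: float = 1e-10
    min_points_per_parameter: float = 10.0

    def __post_init__(self) -> None:
        m = self.bands_per_voxel
        if isinstance(m, int):
            if m < 1:
                raise ValueError("bands_per_voxel must be >= 1")
        else:
            object.__setattr__(self, "bands_per_voxel", tuple(int(v) for v in m))
            if any(v < 1 for v in self.bands_per_voxel):
                raise ValueError("bands_per_voxel entries must be >= 1")
        for name in ("height_bounds", "width_bounds", "n_infinity_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be well-ordered, got ({lo}, {hi})")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    def bands_for(self, voxel_count: int) -> tuple[int, ...]:
        m = self.bands_per_voxel
        if isinstance(m, int):
            return (m,) * voxel_count
        if len(m) != voxel_count:
            raise ValueError(
                f"bands_per_voxel has {len(m)} entries for {voxel_count} voxel(s)"
            )
        return m

    def to_dict(self) -> dict:
        d = {}
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            d[f] = list(v) if isinstance(v, tuple) else v
        return d


class _Packing:
    """Maps between the flat solver vector and structured fit parameters.

    Layout: per voxel [centers(M), heights(M), widths(M), n_inf], then the
    distortion block [scale, shift, tilt, curvature] if fitted, then the free
    radii (outer before core).
    """

    def __init__(self, bands: tuple[int, ...], fit_distortion: bool,
                 fit_outer: bool, fit_core: bool):
        self.bands = bands
        self.fit_distortion = fit_distortion
        self.fit_outer = fit_outer
        self.fit_core = fit_core
        self.voxel_offsets = []
        off = 0
        for m in bands:
            self.voxel_offsets.append(off)
            off += 3 * m + 1
        self.distortion_offset = off if fit_distortion else None
        off += 4 if fit_distortion else 0
        self.outer_offset = off if fit_outer else None
        off += 1 if fit_outer else 0
        self.core_offset = off if fit_core else None
        off += 1 if fit_core else 0
        self.size = off

    def voxel_params(self, theta: np.ndarray, j: int):
        m = self.bands[j]
        o = self.voxel_offsets[j]
        return (theta[o:o + m], theta[o + m:o + 2 * m],
                theta[o + 2 * m:o + 3 * m], theta[o + 3 * m])

    def distortion(self, theta: np.ndarray) -> Optional[DistortionParams]:
        if self.distortion_offset is None:
            return None
        o = self.distortion_offset
        return DistortionParams(scale=theta[o], shift=theta[o + 1],
                                tilt=theta[o + 2], curvature=theta[o + 3])

    def radii(self, theta: np.ndarray) -> tuple[Optional[float], Optional[float]]:
        outer = float(theta[self.outer_offset]) if self.outer_offset is not None else None
        core = float(theta[self.core_offset]) if self.core_offset is not None else None
        return outer, core


def equispaced_centers(grid: WavenumberGrid, m: int) -> np.ndarray:
    """M mid-bin centers: v_min + (i - 1/2) (v_max - v_min) / M, i = 1..M."""
    lo, hi = grid.span
    return lo + (np.arange(1, m + 1) - 0.5) * (hi - lo) / m


def init_parameters(
    config: FitConfig,
    grid: WavenumberGrid,
    voxel_count: int,
    rng: np.random.Generator | int = 0,
    geometry: Optional[SphereGeometry] = None,
) -> np.ndarray:
    """Initial solver vector: equi-spaced centers, random heights/widths.

    Heights and widths are drawn from the seeded generator (the unbiased,
    random-start initialization); n_inf starts at ``n_infinity_init``, the
    distortion at identity, and free radii at the geometry's current values.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    bands = config.bands_for(voxel_count)
    if max(bands) > len(grid) / 3:
        warnings.warn(
            f"M={max(bands)} bands on a {len(grid)}-point grid is heavily "
            "over-parameterized", stacklevel=2)
    packing = _Packing(bands, config.fit_distortion,
                       config.fit_outer_radius, config.fit_core_radius)
    theta = np.empty(packing.size)
    for j, m in enumerate(bands):
        o = packing.voxel_offsets[j]
        theta[o:o + m] = equispaced_centers(grid, m)
        theta[o + m:o + 2 * m] = rng.uniform(*config.init_height_range, size=m)
        theta[o + 2 * m:o + 3 * m] = rng.uniform(*config.init_width_range, size=m)
        theta[o + 3 * m] = config.n_infinity_init
    if packing.distortion_offset is not None:
        theta[packing.distortion_offset:packing.distortion_offset + 4] = (1.0, 0.0, 0.0, 0.0)
    if packing.outer_offset is not None:
        if geometry is None:
            raise ValueError("free outer radius needs a geometry for its start value")
        theta[packing.outer_offset] = geometry.outer_radius
    if packing.core_offset is not None:
        if geometry is None or geometry.core_radius is None:
            raise ValueError("free core radius needs a geometry with a core")
        theta[packing.core_offset] = geometry.core_radius
    return theta


def _complex_index_fast(centers, heights, widths, n_inf, v) -> np.ndarray:
    """Vectorized Lorentzian dispersion evaluation on raw parameter arrays."""
    um = (v[:, None] - centers) / widths
    up = (v[:, None] + centers) / widths
    lm = 1.0 / (1.0 + um * um)
    lp = 1.0 / (1.0 + up * up)
    k = np.sum(heights * (lm - lp), axis=1)
    n = n_inf - np.sum(heights * (um * lm - up * lp), axis=1)
    return n + 1j * k


@dataclass
class RefractiveIndexResults:
    """Estimates and diagnostics of one reconstruction fit.

    ``dispersions`` holds one recovered voxel model per voxel (core first for
    layered spheres); ``geometry`` includes any refined radii; ``objective``
    is the final sum-of-squares S of the best start.
    """

    model: "RefractiveIndexModel"
    dispersions: tuple[VoxelDispersion, ...]
    geometry: SphereGeometry
    distortion: Optional[DistortionParams]
    objective: float
    theta: np.ndarray
    converged: bool
    n_evaluations: int
    start_objectives: list[float]
    best_start: int
    scores: Optional[tuple[ReconstructionScore, ...]] = None

    def predict_qext(self, grid: Optional[WavenumberGrid] = None) -> Spectrum:
        """Model extinction-efficiency spectrum at the fitted parameters."""
        from .mie_forward import qext_from_dispersion

        grid = grid or self.model.spectrum.grid
        return qext_from_dispersion(self.dispersions, self.geometry, grid)

    def complex_index(self, voxel: int = 0,
                      grid: Optional[WavenumberGrid] = None) -> np.ndarray:
        grid = grid or self.model.spectrum.grid
        return self.dispersions[voxel].complex_index(grid)

    def score(self, references: Sequence[np.ndarray],
              grid: Optional[WavenumberGrid] = None) -> tuple[ReconstructionScore, ...]:
        """R^2 of each voxel's reconstruction against reference complex indexes."""
        grid = grid or self.model.spectrum.grid
        scores = tuple(
            r_squared(np.asarray(ref), d.complex_index(grid))
            for ref, d in zip(references, self.dispersions, strict=True)
        )
        self.scores = scores
        return scores

    def to_dict(self) -> dict:
        d = {
            "objective": float(self.objective),
            "converged": bool(self.converged),
            "n_evaluations": int(self.n_evaluations),
            "best_start": int(self.best_start),
            "start_objectives": [float(s) for s in self.start_objectives],
            "geometry": {
                "outer_radius_um": self.geometry.outer_radius,
                "core_radius_um": self.geometry.core_radius,
            },
            "distortion": self.distortion.to_dict() if self.distortion else None,
            "dispersions": [disp.to_dict() for disp in self.dispersions],
        }
        if self.scores is not None:
            d["scores"] = [s.to_dict() for s in self.scores]
        return d

    def save(self, directory) -> None:
        """Write result.yaml plus model Q_ext and reconstructed n,k curves."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "result.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        grid = self.model.spectrum.grid
        write_spectrum(self.predict_qext(grid), directory / "model_qext.csv")
        names = ("core", "shell") if len(self.dispersions) == 2 else ("sphere",)
        for name, disp in zip(names, self.dispersions):
            write_index_table(grid, disp.complex_index(grid),
                              directory / f"reconstructed_index_{name}.csv")

    def summary(self) -> str:
        """Human-readable fit report (also returned as a string)."""
        lines = ["Refractive-index reconstruction", "=" * 48]
        lines.append(f"objective S          {self.objective:.6e}")
        lines.append(f"converged            {self.converged}")
        lines.append(f"starts (best #{self.best_start})    "
                     + ", ".join(f"{s:.3e}" for s in self.start_objectives))
        lines.append(f"outer radius [um]    {self.geometry.outer_radius:.4f}")
        if self.geometry.core_radius is not None:
            lines.append(f"core radius [um]     {self.geometry.core_radius:.4f}")
        if self.distortion is not None:
            d = self.distortion
            lines.append(
                f"distortion           scale={d.scale:.4f} shift={d.shift:+.4f} "
                f"tilt={d.tilt:+.4f} curvature={d.curvature:+.4f}")
        names = ("core", "shell") if len(self.dispersions) == 2 else ("sphere",)
        for name, disp in zip(names, self.dispersions):
            lines.append(f"-- voxel: {name} (n_inf = {disp.n_infinity:.4f})")
            lines.append("   center[cm-1]   height     width[cm-1]")
            for b in disp.bands:
                lines.append(f"   {b.center:10.2f}   {b.height:8.5f}   {b.width:9.2f}")
        if self.scores is not None:
            for name, s in zip(names, self.scores):
                lines.append(
                    f"R^2 ({name})        real={s.r2_real:.4f} imag={s.r2_imag:.4f}")
        text = "\n".join(lines)
        return text


# Backwards-friendly alias: the result object IS the fit result
FitResult = RefractiveIndexResults


class RefractiveIndexModel:
    """Reconstruction model bound to one observed spectrum and sphere geometry.

    The comparison space follows the data: Q_ext spectra are fitted in Q_ext
    space; absorbance spectra are fitted in absorbance space, with the model
    Q_ext converted through the G/g relation and the (optionally fitted)
    distortion applied to the model absorbance, which is equivalent to
    unfolding the data.
    """

    def __init__(
        self,
        spectrum: Spectrum,
        geometry: SphereGeometry,
        config: Optional[FitConfig] = None,
    ) -> None:
        self.spectrum = spectrum
        self.geometry = geometry
        self.config = config or FitConfig()
        self.voxel_count = geometry.J
        self._bands = self.config.bands_for(self.voxel_count)
        self.packing = _Packing(
            self._bands,
            self.config.fit_distortion,
            self.config.fit_outer_radius,
            self.config.fit_core_radius,
        )
        if self.config.fit_core_radius and geometry.core_radius is None:
            raise ValueError("fit_core_radius requires a geometry with a core")
        if spectrum.kind == "absorbance":
            if self.config.g_ratio is None:
                raise ValueError(
                    "fitting an absorbance spectrum needs g_ratio (G/g) to relate "
                    "absorbance to extinction efficiency")
            self._conv = ConversionParams(self.config.g_ratio)
        else:
            self._conv = None
            if self.config.fit_distortion:
                raise ValueError(
                    "distortion parameters act on the absorbance representation; "
                    "provide the data as absorbance (with g_ratio) to fit them")
        n_pts, n_par = len(spectrum), self.packing.size
        guard = self.config.min_points_per_parameter
        if guard > 0 and n_pts < guard * n_par:
            raise ValueError(
                f"{n_pts} spectrum points for {n_par} parameters is below the "
                f"identifiability guard ({guard} points/parameter); set "
                "min_points_per_parameter=0 to override")
        self._lb, self._ub = self._bounds()
        self._warned_clamp = False
        if self.spectrum.kind == "absorbance":
            self._u = None  # built lazily by apply_distortion path

    # -- parameterization ----------------------------------------------

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        grid = self.spectrum.grid
        lo, hi = grid.span
        lb = np.empty(self.packing.size)
        ub = np.empty(self.packing.size)
        for j, m in enumerate(self._bands):
            o = self.packing.voxel_offsets[j]
            if cfg.center_bounds is not None:
                clo, chi = cfg.center_bounds
            else:
                # confine centers to the measured window: a band outside it is
                # seen only through its dispersive tail and becomes a nuisance
                # mode nearly degenerate with n_inf
                clo, chi = lo, hi
            lb[o:o + m], ub[o:o + m] = clo, chi
            lb[o + m:o + 2 * m], ub[o + m:o + 2 * m] = cfg.height_bounds
            lb[o + 2 * m:o + 3 * m], ub[o + 2 * m:o + 3 * m] = cfg.width_bounds
            lb[o + 3 * m], ub[o + 3 * m] = cfg.n_infinity_bounds
        if self.packing.distortion_offset is not None:
            o = self.packing.distortion_offset
            lb[o:o + 4] = (0.1, -2.0, -2.0, -2.0)
            ub[o:o + 4] = (10.0, 2.0, 2.0, 2.0)
        if self.packing.outer_offset is not None:
            b = cfg.outer_radius_bounds or (
                0.5 * self.geometry.outer_radius, 1.5 * self.geometry.outer_radius)
            lb[self.packing.outer_offset], ub[self.packing.outer_offset] = b
        if self.packing.core_offset is not None:
            b = cfg.core_radius_bounds or (
                0.5 * self.geometry.core_radius, 1.5 * self.geometry.core_radius)
            lb[self.packing.core_offset], ub[self.packing.core_offset] = b
        return lb, ub

    def init_parameters(self, rng: np.random.Generator | int = 0) -> np.ndarray:
        return init_parameters(self.config, self.spectrum.grid, self.voxel_count,
                               rng, geometry=self.geometry)

    def _clamp(self, theta: np.ndarray) -> np.ndarray:
        if ((theta < self._lb - 1e-9) | (theta > self._ub + 1e-9)).any():
            if not self._warned_clamp:
                warnings.warn("parameter vector outside bounds; clamping",
                              stacklevel=3)
                self._warned_clamp = True
        return np.clip(theta, self._lb, self._ub)

    def _geometry_at(self, theta: np.ndarray) -> SphereGeometry:
        outer, core = self.packing.radii(theta)
        if outer is None and core is None:
            return self.geometry
        new_outer = outer if outer is not None else self.geometry.outer_radius
        new_core = core if core is not None else self.geometry.core_radius
        return SphereGeometry(outer_radius=new_outer, core_radius=new_core)

    def _model_qext(self, theta: np.ndarray) -> np.ndarray:
        v = self.spectrum.grid.values
        geom = self._geometry_at(theta)
        indexes = []
        for j in range(self.voxel_count):
            c, h, w, n_inf = self.packing.voxel_params(theta, j)
            indexes.append(_complex_index_fast(c, h, w, n_inf, v))
        if self.voxel_count == 1:
            res = qext_homogeneous(indexes[0], geom.outer_radius, self.spectrum.grid)
        else:
            res = qext_coated(indexes[0], indexes[1], geom, self.spectrum.grid)
        return res.q_ext

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        """Per-point model-minus-data residuals in the comparison space."""
        theta = self._clamp(np.asarray(theta, dtype=float))
        q_model = self._model_qext(theta)
        if self.spectrum.kind == "qext":
            return q_model - self.spectrum.values
        # absorbance space: convert the model, distort the model, compare raw
        ratio = q_model / self._conv.g_ratio
        ratio = np.minimum(ratio, 1.0 - 1e-12)
        a_model = -np.log10(1.0 - ratio)
        d = self.packing.distortion(theta)
        if d is not None:
            v = self.spectrum.grid.values
            u = (v - 0.5 * (v[0] + v[-1])) / (v[-1] - v[0])
            a_model = d.scale * a_model + d.shift + d.tilt * u + d.curvature * u**2
        return a_model - self.spectrum.values

    def objective_s(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """The target function S (sum of squared residuals) and the residuals."""
        r = self.residuals(theta)
        return float(np.dot(r, r)), r

    # -- fitting ---------------------------------------------------------

    def _jitter(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Perturb a converged solution for a basin hop (bounded, seeded).

        Three proposal kinds target the known failure modes of band fitting:
        plain parameter jitter; splitting the strongest band in two while
        recycling the weakest (escapes merged close pairs + a band wasted on
        noise); and, for layered spheres, exchanging a band between core and
        shell (escapes wrong-voxel assignment).
        """
        out = theta.copy()
        lo, hi = self.spectrum.grid.span
        for j, m in enumerate(self._bands):
            o = self.packing.voxel_offsets[j]
            bin_width = (hi - lo) / m
            out[o:o + m] += rng.normal(0.0, 0.1 * bin_width, size=m)
            out[o + m:o + 2 * m] *= np.exp(rng.normal(0.0, 0.25, size=m))
            out[o + 2 * m:o + 3 * m] *= np.exp(rng.normal(0.0, 0.25, size=m))
            out[o + 3 * m] += rng.normal(0.0, 0.01)
        for off in (self.packing.outer_offset, self.packing.core_offset):
            if off is not None:
                out[off] *= 1.0 + rng.normal(0.0, 0.005)
        if rng.random() < 0.5:
            # split the strongest band (by integrated absorption h*width) of a
            # random voxel, recycling the weakest as its second half
            j = int(rng.integers(self.voxel_count))
            m = self._bands[j]
            if m >= 2:
                o = self.packing.voxel_offsets[j]
                c, h, w = out[o:o + m], out[o + m:o + 2 * m], out[o + 2 * m:o + 3 * m]
                strength = h * w
                i_s, i_w = int(np.argmax(strength)), int(np.argmin(strength))
                if i_s != i_w:
                    c0, h0, w0 = c[i_s], h[i_s], w[i_s]
                    c[i_s], c[i_w] = c0 - 0.7 * w0, c0 + 0.7 * w0
                    h[i_s] = h[i_w] = 0.6 * h0
                    w[i_s] = w[i_w] = 0.7 * w0
        if self.voxel_count == 2 and rng.random() < 0.5:
            o1, o2 = self.packing.voxel_offsets
            m1, m2 = self._bands
            i1, i2 = rng.integers(m1), rng.integers(m2)
            for k1, k2 in ((i1, i2), (m1 + i1, m2 + i2), (2 * m1 + i1, 2 * m2 + i2)):
                out[o1 + k1], out[o2 + k2] = out[o2 + k2], out[o1 + k1]
        return np.clip(out, self._lb, self._ub)

    def _profile_radius(self, theta0: np.ndarray, offset: int) -> np.ndarray:
        """Global search over one free radius by a coarse profile objective.

        S is violently multi-modal in a radius, and with the other radius
        parameters free the band parameters partially compensate for a wrong
        radius, so neither a plain 1-D sweep (bands still random, landscape
        flat) nor a local joint fit (locks onto the wrong fringe alignment)
        finds the right basin.  What does discriminate is the *profiled*
        objective: a short band fit at each frozen candidate radius -- near
        the true radius even a few solver iterations drop S well below what
        any wrong radius allows.  A fine profile around the coarse winner
        then hands a warm-started state to the deep solves.
        """
        frozen = np.ones(self.packing.size, dtype=bool)
        frozen[offset] = False
        budget = 15  # iterations; enough to separate basins, cheap enough to sweep

        def light(theta, radius):
            trial = theta.copy()
            trial[offset] = radius
            out, sol = self._solve(trial, frozen, max_nfev=budget)
            return out, float(2.0 * sol.cost)

        coarse = np.linspace(self._lb[offset], self._ub[offset], _N_RADIUS_SCAN)
        best_theta, best_s = None, np.inf
        for rc in coarse:
            th, s = light(theta0, rc)
            if s < best_s:
                best_theta, best_s = th, s
        step = coarse[1] - coarse[0]
        r0 = best_theta[offset]
        for rc in np.clip(r0 + step * np.array([-0.5, -0.25, 0.25, 0.5]),
                          self._lb[offset], self._ub[offset]):
            th, s = light(best_theta, rc)
            if s < best_s:
                best_theta, best_s = th, s
        return best_theta

    def _solve(self, theta0: np.ndarray, free: np.ndarray,
               max_nfev: Optional[int] = None):
        """One bounded trust-region solve over the masked parameter subset."""
        cfg = self.config
        theta_full = theta0.copy()

        def fun(sub):
            theta_full[free] = sub
            return self.residuals(theta_full)

        sol = least_squares(
            fun,
            theta0[free],
            bounds=(self._lb[free], self._ub[free]),
            method="trf",
            x_scale="jac",
            xtol=cfg.step_tolerance,
            ftol=cfg.residual_tolerance,
            gtol=1e-12,
            max_nfev=max_nfev or cfg.max_evaluations,
        )
        theta_full[free] = np.clip(sol.x, self._lb[free], self._ub[free])
        return theta_full, sol

    def fit(self) -> RefractiveIndexResults:
        """Multi-start bounded least squares; returns the best-objective result.

        Each start runs in stages when radii are free: a coarse 1-D scan per
        free radius (global), a band fit with the radii frozen (the scanned
        radius is typically within half a scan step of the optimum, and band
        estimation is far better conditioned at fixed geometry), then a joint
        refinement with everything released.
        """
        cfg = self.config
        children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_starts)
        best = None
        start_objectives: list[float] = []
        n_eval_total = 0
        radius_offsets = [o for o in (self.packing.outer_offset,
                                      self.packing.core_offset) if o is not None]
        all_free = np.ones(self.packing.size, dtype=bool)
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            theta0 = self.init_parameters(rng)
            if radius_offsets:
                for off in radius_offsets:
                    theta0 = self._profile_radius(theta0, off)
                frozen = all_free.copy()
                frozen[radius_offsets] = False
                theta0, sol0 = self._solve(theta0, frozen)
                n_eval_total += sol0.nfev
            theta_fit, sol = self._solve(theta0, all_free)
            n_eval_total += sol.nfev
            s = float(2.0 * sol.cost)  # cost = 0.5 sum r^2
            # seeded basin hops: jitter the converged solution and re-solve,
            # keeping improvements.  The objective is riddled with secondary
            # minima (a band locked onto the wrong spectral feature); a local
            # perturbation of band parameters escapes them far more cheaply
            # than an extra cold start.  Skipped once S is at the numerical
            # floor of the data.
            s_floor = 1e-12 * float(np.dot(self.spectrum.values, self.spectrum.values))
            for _ in range(cfg.n_basin_hops):
                if s <= s_floor:
                    break
                theta_try = self._jitter(theta_fit, rng)
                theta_new, sol_new = self._solve(theta_try, all_free)
                n_eval_total += sol_new.nfev
                s_new = float(2.0 * sol_new.cost)
                if s_new < s:
                    theta_fit, sol, s = theta_new, sol_new, s_new
            start_objectives.append(s)
            if best is None or s < best[0]:
                best = (s, sol, theta_fit, i)
        s_best, sol, theta_fit, i_best = best
        theta = np.clip(theta_fit, self._lb, self._ub)
        dispersions = []
        for j in range(self.voxel_count):
            c, h, w, n_inf = self.packing.voxel_params(theta, j)
            bands = tuple(LorentzianBand(float(ci), float(hi_), float(wi))
                          for ci, hi_, wi in zip(c, h, w))
            dispersions.append(VoxelDispersion(bands=bands, n_infinity=float(n_inf)))
        return RefractiveIndexResults(
            model=self,
            dispersions=tuple(dispersions),
            geometry=self._geometry_at(theta),
            distortion=self.packing.distortion(theta),
            objective=s_best,
            theta=theta,
            converged=bool(sol.status > 0),
            n_evaluations=n_eval_total,
            start_objectives=start_objectives,
            best_start=i_best,
        )


def objective_s(
    theta: np.ndarray,
    given: Spectrum,
    geometry: SphereGeometry,
    config: FitConfig,
) -> tuple[float, np.ndarray]:
    """Standalone evaluation of the target function S for a parameter vector."""
    return RefractiveIndexModel(given, geometry, config).objective_s(theta)


def fit(
    given: Spectrum,
    geometry: SphereGeometry,
    config: Optional[FitConfig] = None,
    reference: Optional[Sequence[np.ndarray]] = None,
) -> RefractiveIndexResults:
    """Reconstruct voxel dispersions from a spectrum; score if a reference is given."""
    model = RefractiveIndexModel(given, geometry, config)
    results = model.fit()
    if not results.converged:
        warnings.warn("no start converged; returning the best iterate", stacklevel=2)
    if reference is not None:
        results.score(reference)
    return results


def fit_layered(
    given: Spectrum,
    geometry: SphereGeometry,
    config: Optional[FitConfig] = None,
    reference: Optional[Sequence[np.ndarray]] = None,
) -> RefractiveIndexResults:
    """Joint two-voxel (core + shell) reconstruction through the coated-sphere model."""
    if geometry.J != 2:
        raise ValueError("fit_layered needs a geometry with a core (J = 2)")
    return fit(given, geometry, config, reference)
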