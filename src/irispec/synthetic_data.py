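"""Seeded synthetic ground truth: dispersions, forward spectra, noise, distortions.

The generator emulates the study conditions of the reconstruction problem:
smooth multi-band Lorentzian refractive indexes over the mid-IR window
(~500-4000 cm^-1), microspheres of ~10 um radius (optionally with a distinct
core), bounded multiplicative noise of up to ~10% on the extinction
efficiency, and additive-polynomial-plus-scaling distortions on the
absorbance representation.  Every artefact is reproducible bit-exactly from
its seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .dispersion import LorentzianBand, VoxelDispersion, WavenumberGrid
from .mie_forward import SphereGeometry, qext_from_dispersion
from .spectra_io import (
    ConversionParams,
    DistortionParams,
    Spectrum,
    absorbance_to_qext,
    apply_distortion,
    qext_to_absorbance,
    read_spectrum,
    write_spectrum,
)

__all__ = [
    "TruthBundle",
    "default_grid",
    "random_dispersion",
    "add_noise",
    "make_observation",
]

# mid-IR measurement window typical of single-cell FTIR/QCL instruments
DEFAULT_RANGE = (500.0, 4000.0)
DEFAULT_SPACING = 2.0
DEFAULT_RADIUS_UM = 10.0


def default_grid(spacing: float = DEFAULT_SPACING) -> WavenumberGrid:
    """The default 500-4000 cm^-1 synthetic measurement grid."""
    return WavenumberGrid.regular(DEFAULT_RANGE[0], DEFAULT_RANGE[1], spacing)


def random_dispersion(
    n_bands: int = 6,
    center_range: tuple[float, float] = (600.0, 3600.0),
    height_range: tuple[float, float] = (0.02, 0.3),
    width_range: tuple[float, float] = (10.0, 60.0),
    n_infinity: float = 1.5,
    seed: int | np.random.SeedSequence = 0,
) -> VoxelDispersion:
    """Draw a random but resolvable multi-band dispersion model.

    Band centers are rejection-sampled so that every pairwise gap is at least
    1.5x the mean drawn width, keeping bands spectrally resolvable the way
    distinct vibrational bands of a real polymer are.
    """
    for name, rng_ in (("center", center_range), ("height", height_range), ("width", width_range)):
        lo, hi = rng_
        if not (0 <= lo <= hi):
            raise ValueError(f"{name}_range must be ordered and non-negative, got {rng_}")
    rng = np.random.default_rng(seed)
    heights = rng.uniform(*height_range, size=n_bands)
    widths = rng.uniform(*width_range, size=n_bands)
    min_gap = 1.5 * float(widths.mean())
    for _ in range(10_000):
        centers = np.sort(rng.uniform(*center_range, size=n_bands))
        if n_bands == 1 or (np.diff(centers) >= min_gap).all():
            break
    else:
        raise RuntimeError(
            f"could not place {n_bands} bands with pairwise gaps >= {min_gap:.1f} "
            f"cm^-1 in {center_range}; use fewer bands or a wider range"
        )
    bands = tuple(
        LorentzianBand(float(c), float(h), float(w))
        for c, h, w in zip(centers, heights, widths)
    )
    return VoxelDispersion(bands=bands, n_infinity=n_infinity)


def add_noise(spec: Spectrum, fraction: float, seed: int | np.random.SeedSequence = 0) -> Spectrum:
    """Bounded multiplicative noise: each value times (1 + eps), eps ~ U(-f, +f)."""
    if not 0.0 <= fraction <= 0.5:
        raise ValueError(f"noise fraction must be in [0, 0.5], got {fraction}")
    if fraction == 0.0:
        return spec
    rng = np.random.default_rng(seed)
    eps = rng.uniform(-fraction, fraction, size=len(spec))
    return spec.with_values(spec.values * (1.0 + eps))


@dataclass(frozen=True)
class TruthBundle:
    """A complete simulated observation with its generating ground truth."""

    dispersions: tuple[VoxelDispersion, ...]
    geometry: SphereGeometry
    clean_qext: Spectrum
    observed: Spectrum
    noise_fraction: float
    distortion: Optional[DistortionParams]
    g_ratio: Optional[float]
    seed: int

    def save(self, directory) -> None:
        """Write truth.yaml, clean_qext.csv, observed.csv into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        truth = {
            "seed": self.seed,
            "noise_fraction": self.noise_fraction,
            "observed_kind": self.observed.kind,
            "geometry": {
                "outer_radius_um": self.geometry.outer_radius,
                "core_radius_um": self.geometry.core_radius,
            },
            "g_ratio": self.g_ratio,
            "distortion": self.distortion.to_dict() if self.distortion else None,
            "dispersions": [d.to_dict() for d in self.dispersions],
        }
        with open(directory / "truth.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(truth, fh, sort_keys=False)
        write_spectrum(self.clean_qext, directory / "clean_qext.csv")
        write_spectrum(self.observed, directory / "observed.csv")

    @classmethod
    def load(cls, directory) -> "TruthBundle":
        directory = Path(directory)
        with open(directory / "truth.yaml", "r", encoding="utf-8") as fh:
            truth = yaml.safe_load(fh)
        geom = SphereGeometry(
            outer_radius=truth["geometry"]["outer_radius_um"],
            core_radius=truth["geometry"]["core_radius_um"],
        )
        dist = truth.get("distortion")
        return cls(
            dispersions=tuple(VoxelDispersion.from_dict(d) for d in truth["dispersions"]),
            geometry=geom,
            clean_qext=read_spectrum(directory / "clean_qext.csv", kind="qext"),
            observed=read_spectrum(directory / "observed.csv", kind=truth["observed_kind"]),
            noise_fraction=float(truth["noise_fraction"]),
            distortion=DistortionParams.from_dict(dist) if dist else None,
            g_ratio=truth.get("g_ratio"),
            seed=int(truth["seed"]),
        )


def make_observation(
    dispersions: Sequence[VoxelDispersion] | VoxelDispersion,
    geometry: SphereGeometry,
    grid: Optional[WavenumberGrid] = None,
    noise_fraction: float = 0.0,
    distortion: Optional[DistortionParams] = None,
    g_ratio: Optional[float] = None,
    seed: int = 0,
) -> TruthBundle:
    """Compose the full forward pipeline: dispersion -> Mie -> (noise, distortion).

    Without a distortion the observation is the (noisy) Q_ext spectrum itself.
    With a distortion, the clean Q_ext is converted to apparent absorbance via
    the G/g relation (``g_ratio`` is then required), noise is applied, and the
    distortion acts on the absorbance representation, mirroring how real
    instruments corrupt spectra.
    """
    if isinstance(dispersions, VoxelDispersion):
        dispersions = (dispersions,)
    dispersions = tuple(dispersions)
    if grid is None:
        grid = default_grid()
    if distortion is not None and g_ratio is None:
        raise ValueError("a distortion requires g_ratio to form the absorbance spectrum")

    clean = qext_from_dispersion(dispersions, geometry, grid)
    noisy = add_noise(clean, noise_fraction, seed=seed)
    if distortion is None:
        observed = noisy
    else:
        absorb = qext_to_absorbance(noisy, ConversionParams(g_ratio))
        observed = apply_distortion(absorb, distortion)
    return TruthBundle(
        dispersions=dispersions,
        geometry=geometry,
        clean_qext=clean,
        observed=observed,
        noise_fraction=noise_fraction,
        distortion=distortion,
        g_ratio=g_ratio,
        seed=seed,
    )
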