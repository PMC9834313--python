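"""Coefficient-of-determination scoring of reconstructed refractive indexes.

Real and imaginary parts are scored separately:

    R^2 = 1 - S_res / S_tot,   S_res = sum (eta_k - eta~_k)^2,
                               S_tot = sum (eta_k - mean(eta))^2

where eta is the reference part and eta~ its reconstruction.  R^2 is not
clamped: a reconstruction worse than the reference's mean scores negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ReconstructionScore", "r_squared"]


@dataclass(frozen=True)
class ReconstructionScore:
    """Per-part R^2 plus the sums of squares they derive from."""

    r2_real: float
    r2_imag: float
    residual_sum_real: float
    residual_sum_imag: float
    total_sum_real: float
    total_sum_imag: float

    @property
    def minimum(self) -> float:
        return min(self.r2_real, self.r2_imag)

    def to_dict(self) -> dict:
        return {
            "r2_real": self.r2_real,
            "r2_imag": self.r2_imag,
            "residual_sum_real": self.residual_sum_real,
            "residual_sum_imag": self.residual_sum_imag,
            "total_sum_real": self.total_sum_real,
            "total_sum_imag": self.total_sum_imag,
        }


def _part_score(ref: np.ndarray, rec: np.ndarray, part: str) -> tuple[float, float, float]:
    s_res = float(np.sum((ref - rec) ** 2))
    s_tot = float(np.sum((ref - ref.mean()) ** 2))
    if s_tot <= 0.0:
        raise ValueError(
            f"reference {part} part is constant; R^2 is undefined (S_tot = 0)"
        )
    return 1.0 - s_res / s_tot, s_res, s_tot


def r_squared(reference: np.ndarray, reconstruction: np.ndarray) -> ReconstructionScore:
    """Score a reconstructed complex index against a reference on a shared grid."""
    ref = np.asarray(reference, dtype=complex)
    rec = np.asarray(reconstruction, dtype=complex)
    if ref.shape != rec.shape:
        raise ValueError("reference and reconstruction must share a grid")
    if ref.size < 3:
        raise ValueError("need at least 3 points to score a reconstruction")
    r2r, sres_r, stot_r = _part_score(ref.real, rec.real, "real")
    r2i, sres_i, stot_i = _part_score(ref.imag, rec.imag, "imaginary")
    return ReconstructionScore(
        r2_real=r2r,
        r2_imag=r2i,
        residual_sum_real=sres_r,
        residual_sum_imag=sres_i,
        total_sum_real=stot_r,
        total_sum_imag=stot_i,
    )
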