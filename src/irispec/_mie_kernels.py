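"""JIT-compiled scalar Mie series kernels.

The partial-wave series is evaluated point by point with per-wavenumber
truncation (Wiscombe order).  Scalar loops avoid the (order x wavenumber)
temporaries a vectorized formulation needs; inside a least-squares fit the
forward model is evaluated tens of thousands of times, so this is the hot
path of the whole package.

All recurrences match the formulation documented in :mod:`irispec.mie_forward`:
downward logarithmic-derivative recurrence for psi (seeded 15 orders above the
truncation order), upward recurrence for the irregular chi, and
ratio-stabilized shell algebra for the coated sphere.
"""

from __future__ import annotations

import cmath

import numpy as np
from numba import njit

_EXTRA_ORDERS = 15


@njit(cache=False, fastmath=True)
def _trunc(x: float) -> int:
    n = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    return n if n > 3 else 3


@njit(cache=False, fastmath=True)
def _d1_fill(z: complex, nmax: int, out: np.ndarray) -> None:
    """Downward recurrence for D_n = psi_n'/psi_n, n = 0..nmax.

    Seeded at max(nmax, |z|) + 15: the recurrence only converges onto the
    true ratio once the order exceeds |z|.
    """
    zinv = 1.0 / z
    nstart = int(abs(z))
    if nstart < nmax:
        nstart = nmax
    d = 0.0 + 0.0j
    for n in range(nstart + _EXTRA_ORDERS, 0, -1):
        noz = n * zinv
        d = noz - 1.0 / (d + noz)
        if n - 1 <= nmax:
            out[n - 1] = d


@njit(cache=False, fastmath=True)
def _psi_chi_fill(z: complex, nmax: int, d1: np.ndarray,
                  psi: np.ndarray, chi: np.ndarray) -> None:
    """psi from the D_n ratios, chi upward from cos z.

    The ratio chain psi_n = psi_{n-1} / (D_n + n/z) is anchored at psi_0 =
    sin z or psi_1 = sin z / z - cos z, whichever is larger: near real zeros
    of sin (size parameter at a multiple of pi) anchoring at psi_0 would
    poison every order with its relative error.
    """
    zinv = 1.0 / z
    sz = cmath.sin(z)
    cz = cmath.cos(z)
    psi1 = sz * zinv - cz
    if nmax >= 1 and abs(psi1) > abs(sz):
        psi[1] = psi1
        psi[0] = psi1 * (d1[1] + zinv)
        start = 2
    else:
        psi[0] = sz
        start = 1
    for n in range(start, nmax + 1):
        psi[n] = psi[n - 1] / (d1[n] + n * zinv)
    chi[0] = cz
    if nmax >= 1:
        chi[1] = cz * zinv + sz
    for n in range(1, nmax):
        chi[n + 1] = (2 * n + 1) * zinv * chi[n] - chi[n - 1]


@njit(cache=False, fastmath=True)
def homogeneous_efficiencies(m: np.ndarray, x: np.ndarray):
    """(Q_ext, Q_sca) of a homogeneous sphere per grid point."""
    L = m.shape[0]
    qe = np.empty(L)
    qs = np.empty(L)
    nglob = _trunc(float(np.max(x)))
    dmx = np.empty(nglob + 1, np.complex128)
    d1y = np.empty(nglob + 1, np.complex128)
    psi = np.empty(nglob + 1, np.complex128)
    chi = np.empty(nglob + 1, np.complex128)
    for l in range(L):
        xl = x[l]
        ml = m[l]
        nl = _trunc(xl)
        _d1_fill(ml * xl, nl, dmx)
        zy = complex(xl, 0.0)
        _d1_fill(zy, nl, d1y)
        _psi_chi_fill(zy, nl, d1y, psi, chi)
        se = 0.0
        ss = 0.0
        for n in range(1, nl + 1):
            nox = n / xl
            da = dmx[n] / ml + nox
            db = ml * dmx[n] + nox
            psin = psi[n].real
            psin1 = psi[n - 1].real
            xin = complex(psin, -chi[n].real)
            xin1 = complex(psin1, -chi[n - 1].real)
            a = (da * psin - psin1) / (da * xin - xin1)
            b = (db * psin - psin1) / (db * xin - xin1)
            se += (2 * n + 1) * (a.real + b.real)
            ss += (2 * n + 1) * (abs(a) ** 2 + abs(b) ** 2)
        qe[l] = 2.0 / (xl * xl) * se
        qs[l] = 2.0 / (xl * xl) * ss
    return qe, qs


@njit(cache=False, fastmath=True)
def coated_efficiencies(m1: np.ndarray, m2: np.ndarray,
                        x: np.ndarray, y: np.ndarray):
    """(Q_ext, Q_sca) of a two-layer sphere, outer-cross-section normalized.

    Per order the core boundary condition fixes the irregular-solution
    admixture via the stabilized product
    ``aq = (psi_n(m2 x) chi_n(m2 y)) / (psi_n(m2 y) chi_n(m2 x)) * ...``
    whose exponential shell factors cancel; the effective shell logarithmic
    derivatives then enter the standard outer-surface coefficient formulas.
    """
    L = m1.shape[0]
    qe = np.empty(L)
    qs = np.empty(L)
    nglob = _trunc(float(np.max(y)))
    d1x1 = np.empty(nglob + 1, np.complex128)
    d12x = np.empty(nglob + 1, np.complex128)
    d12y = np.empty(nglob + 1, np.complex128)
    d1y = np.empty(nglob + 1, np.complex128)
    psi2x = np.empty(nglob + 1, np.complex128)
    chi2x = np.empty(nglob + 1, np.complex128)
    psi2y = np.empty(nglob + 1, np.complex128)
    chi2y = np.empty(nglob + 1, np.complex128)
    psiy = np.empty(nglob + 1, np.complex128)
    chiy = np.empty(nglob + 1, np.complex128)
    for l in range(L):
        xl = x[l]
        yl = y[l]
        m1l = m1[l]
        m2l = m2[l]
        nl = _trunc(yl)
        z1x = m1l * xl
        z2x = m2l * xl
        z2y = m2l * yl
        z2xinv = 1.0 / z2x
        z2yinv = 1.0 / z2y
        zy = complex(yl, 0.0)
        _d1_fill(z1x, nl, d1x1)
        _d1_fill(z2x, nl, d12x)
        _d1_fill(z2y, nl, d12y)
        _d1_fill(zy, nl, d1y)
        _psi_chi_fill(z2x, nl, d12x, psi2x, chi2x)
        _psi_chi_fill(z2y, nl, d12y, psi2y, chi2y)
        _psi_chi_fill(zy, nl, d1y, psiy, chiy)
        se = 0.0
        ss = 0.0
        for n in range(1, nl + 1):
            g2x = chi2x[n - 1] / chi2x[n] - n * z2xinv
            g2y = chi2y[n - 1] / chi2y[n] - n * z2yinv
            cross = (psi2x[n] / psi2y[n]) * (chi2y[n] / chi2x[n])
            rtm = (m2l / m1l) * d1x1[n]
            rte = (m1l / m2l) * d1x1[n]
            aq = cross * (d12x[n] - rtm) / (g2x - rtm)
            bq = cross * (d12x[n] - rte) / (g2x - rte)
            dna = (d12y[n] - aq * g2y) / (1.0 - aq)
            dnb = (d12y[n] - bq * g2y) / (1.0 - bq)
            noy = n / yl
            da = dna / m2l + noy
            db = m2l * dnb + noy
            psin = psiy[n].real
            psin1 = psiy[n - 1].real
            xin = complex(psin, -chiy[n].real)
            xin1 = complex(psin1, -chiy[n - 1].real)
            a = (da * psin - psin1) / (da * xin - xin1)
            b = (db * psin - psin1) / (db * xin - xin1)
            se += (2 * n + 1) * (a.real + b.real)
            ss += (2 * n + 1) * (abs(a) ** 2 + abs(b) ** 2)
        qe[l] = 2.0 / (yl * yl) * se
        qs[l] = 2.0 / (yl * yl) * ss
    return qe, qs
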