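"""Buffered 14-7 van der Waals interactions with titration-state scaling.

The pair term is U_ij = f_i(l, z) f_j(l, z) * S(r) * U_14-7(r), where the
per-atom scale f follows the residue scaling table (protons of LYS/CYS
scale as lambda, ASP/GLU as lambda*f^m(zeta), HIS as
(1-lambda) f^m(zeta) + lambda; all other atoms are 1), S is a C^2
switching taper, and hydrogen interaction sites are displaced toward their
heavy atom by the AMOEBA reduction factor.

A soft-core variant is provided for completeness, but the extended-system
path defaults to the plain scaled form: a titrating proton is always
sterically protected by its heavy atom, so no soft core is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .system import PolarizableSystem, StateParams

# buffered 14-7 constants (Halgren buffering)
DELTA = 0.07
GAMMA = 0.12


def buffered_14_7(r, r_min, eps):
    """Energy and dE/dr of the buffered 14-7 potential.

    Minimum of exactly -eps at r = r_min.
    """
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise ValueError("buffered 14-7 undefined at r <= 0")
    rho = r / r_min
    t1 = ((1.0 + DELTA) / (rho + DELTA)) ** 7
    t2 = (1.0 + GAMMA) / (rho ** 7 + GAMMA)
    e = eps * t1 * (t2 - 2.0)
    dt1 = -7.0 * t1 / (rho + DELTA)
    dt2 = -t2 / (rho ** 7 + GAMMA) * 7.0 * rho ** 6
    de = eps * (dt1 * (t2 - 2.0) + t1 * dt2) / r_min
    return e, de


def softcore_14_7(rho, eps, lam_pair, alpha_sc: float = 0.7, n_sc: int = 2):
    """Soft-core buffered 14-7 in the normalized separation rho = r/r_min.

    t1 and t2 acquire an alpha (1 - lambda)^2 buffer in their denominators
    and the whole term is scaled by lambda^n; at lambda = 1 this is exactly
    the plain buffered 14-7, and at rho = 0 it stays finite for lambda < 1.
    """
    rho = np.asarray(rho, float)
    buf = alpha_sc * (1.0 - lam_pair) ** 2
    t1 = (1.0 + DELTA) ** 7 / (buf + (rho + DELTA) ** 7)
    t2 = (1.0 + GAMMA) / (buf + rho ** 7 + GAMMA)
    return lam_pair ** n_sc * eps * t1 * (t2 - 2.0)


def combine_rmin(ri: float, rj: float) -> float:
    """AMOEBA cubic-mean combining rule."""
    return (ri ** 3 + rj ** 3) / (ri ** 2 + rj ** 2)


def combine_eps(ei: float, ej: float) -> float:
    """HHG (harmonic-mean-of-geometric) combining rule."""
    if ei == 0.0 or ej == 0.0:
        return 0.0
    return 4.0 * ei * ej / (np.sqrt(ei) + np.sqrt(ej)) ** 2


def _switch(r, r_on, r_off):
    """C^2 taper: 1 below r_on, 0 above r_off, quintic smoothstep between."""
    r = np.asarray(r, float)
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    mid = (r > r_on) & (r < r_off)
    t = (r[mid] - r_on) / (r_off - r_on)
    s[mid] = 1.0 - t ** 3 * (10.0 - 15.0 * t + 6.0 * t * t)
    ds[mid] = -30.0 * t ** 2 * (1.0 - t) ** 2 / (r_off - r_on)
    s[r >= r_off] = 0.0
    return s, ds


@dataclass
class VdwConfig:
    cutoff: Optional[float] = None   # r_off; None = no cutoff (vacuum)
    taper_start: Optional[float] = None  # r_on; default 10/12 of cutoff
    use_softcore: bool = False


def vdw_energy_extended(system: PolarizableSystem, state: StateParams,
                        positions: np.ndarray,
                        config: VdwConfig = VdwConfig()):
    """Total scaled buffered 14-7 energy, Cartesian gradient, and the
    analytic derivatives with respect to every extended variable.

    Returns (U, dU_dX (n,3), dU_dext {k: value}).
    """
    n = system.n
    grad = np.zeros((n, 3))
    dext = {k: 0.0 for k in range(system.n_ext)}
    if n < 2:
        return 0.0, grad, dext

    # reduced interaction sites for hydrogens
    red = np.array([p.reduction for p in system.vdw_params])
    heavy = np.arange(n)
    for i, a in enumerate(system.atoms):
        if red[i] < 1.0 and a.bonded:
            heavy[i] = a.bonded[0]
    sites = positions[heavy] + red[:, None] * (positions - positions[heavy])

    cutoff = config.cutoff
    if cutoff is not None and system.cell is not None:
        cutoff = min(cutoff, 0.5 * system.cell.min_width())
    elif cutoff is None and system.cell is not None:
        cutoff = 0.5 * system.cell.min_width()

    ii, jj = np.triu_indices(n, k=1)
    dr = sites[ii] - sites[jj]
    if system.cell is not None:
        dr = system.cell.minimum_image(dr)
    r = np.linalg.norm(dr, axis=1)

    vsc = system.vscale[ii, jj]
    keep = vsc != 0.0
    if cutoff is not None:
        keep &= r < cutoff
    ii, jj, dr, r, vsc = ii[keep], jj[keep], dr[keep], r[keep], vsc[keep]

    rmin_i = np.array([p.r_min for p in system.vdw_params])
    eps_i = np.array([p.epsilon for p in system.vdw_params])
    rmin = (rmin_i[ii] ** 3 + rmin_i[jj] ** 3) / (rmin_i[ii] ** 2 + rmin_i[jj] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = 4.0 * eps_i[ii] * eps_i[jj] / \
            (np.sqrt(eps_i[ii]) + np.sqrt(eps_i[jj])) ** 2
    eps = np.nan_to_num(eps)

    e, de = buffered_14_7(r, rmin, eps)
    if cutoff is not None:
        r_on = config.taper_start if config.taper_start is not None \
            else cutoff * (10.0 / 12.0)
        s, ds = _switch(r, r_on, cutoff)
        de = de * s + e * ds
        e = e * s

    f = state.vdw_factor
    fij = f[ii] * f[jj] * vsc
    U = float(np.sum(fij * e))

    # Cartesian gradient through the reduced sites
    fr = (fij * de / r)[:, None] * dr
    np.add.at(grad, ii, fr)
    np.add.at(grad, jj, -fr)
    # chain rule of the reduced-site placement
    red_grad = np.zeros((n, 3))
    w = red[:, None]
    red_grad += grad * w
    hmask = red < 1.0
    if np.any(hmask):
        np.add.at(red_grad, heavy[hmask], grad[hmask] * (1.0 - red[hmask, None]))
        grad = red_grad
    # (when all reductions are 1 the two coincide)
    else:
        grad = red_grad

    for k, dfk in state.dvdw.items():
        dfij = (dfk[ii] * f[jj] + f[ii] * dfk[jj]) * vsc
        dext[k] = dext.get(k, 0.0) + float(np.sum(dfij * e))
    return U, grad, dext
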