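"""Ewald decomposition for point multipoles.

Everything is phrased through per-atom *potential stacks*: the electrostatic
potential and its Cartesian derivatives (up to third order) at each atom
site, produced by a given set of source moments.  Energies, fields, forces,
torques and titration-state derivatives are all contractions of moments
with these stacks:

    U        = (1/2) sum_i M_i . Phi_i            (permanent energy)
    dU/dl_k  =       sum_i Mdot_i . Phi_i         (state derivative)
    F_i      = - M_i . grad Phi_i                 (force)
    E_i      = - Phi^(1)_i                        (field, for induction)

The total stack is real-space (erfc kernel, with masking and optional Thole
damping folded in as short-range bare-kernel corrections) + reciprocal
(erf, all pairs including self) + an analytic self correction removing the
i-with-i reciprocal term.  Charged cells add a uniform-background term
-pi q_tot^2 / (2 beta^2 V).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import CrystalCell
from .tensors import (Moments, b_coulomb, b_erfc, potential_stack,
                      thole_lambdas)


@dataclass
class RealKernel:
    """Real-space interaction recipe for one mask flavour."""

    beta: Optional[float]          # None -> vacuum (bare Coulomb, no Ewald)
    cutoff: Optional[float]
    scale: np.ndarray              # (n, n) pair mask scale factors
    damped: bool = False           # Thole damping with frozen widths
    damping_alpha: Optional[np.ndarray] = None   # per-atom effective alpha
    thole_a: float = 0.39


def _pair_radials(r: np.ndarray, ii, jj, kernel: RealKernel) -> np.ndarray:
    """Effective B-sequence per pair combining Ewald, masks and damping.

    Ewald:  B = B_erfc + (s * lam - 1) B_bare
    vacuum: B = s * lam * B_bare
    with lam the per-rank Thole factors (1 when undamped; rank 0 never
    damped — damping only enters polarization interactions, rank >= 1).
    """
    s = kernel.scale[ii, jj]
    Bb = b_coulomb(r)
    nmax = Bb.shape[-1] - 1
    lam = np.ones_like(Bb)
    if kernel.damped:
        width = (kernel.damping_alpha[ii] * kernel.damping_alpha[jj]) ** (1.0 / 6.0)
        width = np.where((kernel.damping_alpha[ii] > 0)
                         & (kernel.damping_alpha[jj] > 0), width, 0.0)
        lth = thole_lambdas(r, width, kernel.thole_a)
        for k in range(1, nmax + 1):
            lam[:, k] = lth[:, k - 1]
    eff = s[:, None] * lam
    if kernel.beta is None:
        return eff * Bb
    return b_erfc(r, kernel.beta) + (eff - 1.0) * Bb


def real_space_stacks(system, positions: np.ndarray, src: Moments,
                      kernel: RealKernel, order: int) -> list[np.ndarray]:
    """Per-atom potential stacks from the real-space pair sum."""
    n = system.n
    stacks = [np.zeros((n,) + (3,) * m) for m in range(order + 1)]
    if n < 2:
        return stacks
    ii, jj, dr, r = system.pair_list(positions, kernel.cutoff)
    if len(ii) == 0:
        return stacks
    if np.any(r < 1e-6):
        raise ValueError("overlapping atoms in real-space electrostatics")
    B = _pair_radials(r, ii, jj, kernel)
    st_i = potential_stack(dr, B, src.take(jj), order)    # at i from j
    st_j = potential_stack(-dr, B, src.take(ii), order)   # at j from i
    for m in range(order + 1):
        np.add.at(stacks[m], ii, st_i[m])
        np.add.at(stacks[m], jj, st_j[m])
    return stacks


# ---------------------------------------------------------------------------
# Reciprocal space: direct structure-factor summation (exact oracle backend)

def kvectors(cell: CrystalCell, beta: float, tol: float = 1e-10):
    """Half-space reciprocal vectors within the Gaussian-decay cutoff."""
    kcut = 2.0 * beta * np.sqrt(np.log(1.0 / tol))
    rec = 2.0 * np.pi * cell.reciprocal       # rows
    mmax = [int(np.floor(kcut / np.linalg.norm(rec[i]))) + 1 for i in range(3)]
    ms = []
    for m1 in range(0, mmax[0] + 1):
        r2 = range(-mmax[1], mmax[1] + 1) if m1 > 0 else range(0, mmax[1] + 1)
        for m2 in r2:
            if m1 == 0 and m2 == 0:
                r3 = range(1, mmax[2] + 1)
            else:
                r3 = range(-mmax[2], mmax[2] + 1)
            for m3 in r3:
                ms.append((m1, m2, m3))
    ms = np.array(ms, float)
    k = ms @ rec
    k2 = np.einsum("ka,ka->k", k, k)
    keep = k2 <= kcut ** 2
    return k[keep], k2[keep]


class KsumRecip:
    """Direct Ewald k-space summation for multipole sources.

    Exact (to the Gaussian tail tolerance); serves both as a production
    backend for small cells and as the oracle the mesh PME is tested
    against.
    """

    def __init__(self, cell: CrystalCell, beta: float, tol: float = 1e-10):
        self.cell = cell
        self.beta = beta
        self.k, self.k2 = kvectors(cell, beta, tol)
        self.coeff = 4.0 * np.pi / cell.volume * \
            np.exp(-self.k2 / (4.0 * beta ** 2)) / self.k2

    def phases(self, positions: np.ndarray) -> np.ndarray:
        return np.exp(1j * positions @ self.k.T)   # (n, nk)

    def structure_factor(self, phases: np.ndarray, src: Moments) -> np.ndarray:
        """S(k) = sum_j Lambda_j(k) e^{i k.r_j}; Lambda = q + i k.d - k.m2.k"""
        lam = (src.m0[:, None]
               + 1j * (src.m1 @ self.k.T)
               - np.einsum("ka,jab,kb->jk", self.k, src.m2, self.k))
        return np.einsum("jk,jk->k", lam, phases)

    def stacks(self, positions: np.ndarray, src: Moments,
               order: int) -> list[np.ndarray]:
        """Per-site reciprocal potential stack (phi, grad phi, ...).

        Half-space symmetry: the full sum is 2 Re(half-space sum).
        """
        ph = self.phases(positions)
        S = self.structure_factor(ph, src)
        pw = np.conj(ph) * (self.coeff * S)[None, :]   # (n, nk)
        out = [2.0 * np.real(pw.sum(axis=1))]
        kp = None
        for m in range(1, order + 1):
            # outer product k^(x)m, shape (nk, 3, ..., 3)
            kp = self.k if kp is None else np.einsum("k...,ka->k...a",
                                                     kp, self.k)
            val = 2.0 * np.real(
                (-1j) ** m * np.tensordot(pw, kp, axes=([1], [0])))
            out.append(val)
        return out

    def energy(self, positions: np.ndarray, src: Moments) -> float:
        ph = self.phases(positions)
        S = self.structure_factor(ph, src)
        return float(np.sum(self.coeff * np.abs(S) ** 2))


# ---------------------------------------------------------------------------
# Self and neutrality corrections

def self_stacks(src: Moments, beta: float) -> list[np.ndarray]:
    """Analytic correction removing each atom's interaction with its own
    Gaussian-screened (erf) image in the reciprocal sum.

    From the small-r expansion erf(beta r)/r = c0 + c1 r^2 + c2 r^4 + ...,
    c0 = 2 beta / sqrt(pi), c1 = -2 beta^3 / (3 sqrt(pi)),
    c2 = beta^5 / (5 sqrt(pi)).
    """
    n = src.n
    c0 = 2.0 * beta / np.sqrt(np.pi)
    c1 = -2.0 * beta ** 3 / (3.0 * np.sqrt(np.pi))
    c2 = beta ** 5 / (5.0 * np.sqrt(np.pi))
    phi0 = -c0 * src.m0
    phi1 = 2.0 * c1 * src.m1
    eye = np.eye(3)
    phi2 = -2.0 * c1 * src.m0[:, None, None] * eye - 16.0 * c2 * src.m2
    d = src.m1
    phi3 = 8.0 * c2 * (np.einsum("ab,pc->pabc", eye, d)
                       + np.einsum("ac,pb->pabc", eye, d)
                       + np.einsum("bc,pa->pabc", eye, d))
    return [phi0, phi1, phi2, phi3][: 4]


def background_energy(q_total: float, beta: float, volume: float) -> float:
    """Uniform-background correction for a net-charged cell."""
    return -np.pi * q_total ** 2 / (2.0 * beta ** 2 * volume)


def background_derivative(q_total: float, dq_total: float, beta: float,
                          volume: float) -> float:
    return -np.pi * q_total * dq_total / (beta ** 2 * volume)
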