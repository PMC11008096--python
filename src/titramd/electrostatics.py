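"""Permanent multipole electrostatics: real-space Ewald + reciprocal sum +
self/neutrality corrections, with Cartesian forces (torques distributed to
frame atoms) and analytic titration/tautomer-state derivatives.

All quantities are assembled from per-atom potential stacks (see ewald.py);
energies are in kcal/mol after scaling by the Coulomb constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import COULOMB
from .ewald import (KsumRecip, RealKernel, background_derivative,
                    background_energy, real_space_stacks, self_stacks)
from .system import PolarizableSystem, StateParams
from .tensors import Moments, probe_energy, probe_force, probe_torque


@dataclass
class ElectrostaticsConfig:
    beta: Optional[float] = None        # None with no cell -> vacuum sum
    cutoff: Optional[float] = None
    recip: str = "ksum"                 # "ksum" | "pme"
    ktol: float = 1e-10                 # Gaussian-tail tolerance of the k-sum
    pme_grid: tuple[int, int, int] = (0, 0, 0)
    pme_order: int = 5
    neutralize: bool = True


class MultipoleElectrostatics:
    """Stateful evaluator bound to one system + configuration."""

    def __init__(self, system: PolarizableSystem,
                 config: ElectrostaticsConfig = ElectrostaticsConfig()):
        self.system = system
        self.config = config
        self.cell = system.cell
        if self.cell is not None:
            self.beta = config.beta if config.beta is not None \
                else self.cell.ewald_beta
            self.cutoff = config.cutoff if config.cutoff is not None \
                else self.cell.real_cutoff
            if self.cutoff > 0.5 * self.cell.min_width() + 1e-9:
                raise ValueError("Ewald real-space cutoff exceeds half cell width")
            if config.recip == "pme":
                from .pme import PmeRecip
                self.recip = PmeRecip(self.cell, self.beta,
                                      grid=config.pme_grid,
                                      order=config.pme_order)
            else:
                self.recip = KsumRecip(self.cell, self.beta, config.ktol)
        else:
            self.beta = None
            self.cutoff = None
            self.recip = None

    # -- stack assembly ----------------------------------------------------
    def total_stacks(self, positions: np.ndarray, src: Moments,
                     order: int, scale: np.ndarray,
                     damped: bool = False) -> list[np.ndarray]:
        """real + reciprocal + self potential stacks for given sources.

        Masking (and optional Thole damping) enter only through short-range
        bare-kernel corrections in the real-space part.
        """
        kernel = RealKernel(
            beta=self.beta, cutoff=self.cutoff, scale=scale, damped=damped,
            damping_alpha=self.system.damping_alpha,
            thole_a=self.system.thole_a)
        stacks = real_space_stacks(self.system, positions, src, kernel, order)
        if self.recip is not None:
            rec = self.recip.stacks(positions, src, order)
            slf = self_stacks(src, self.beta)
            for m in range(order + 1):
                stacks[m] = stacks[m] + rec[m] + slf[m]
        return stacks

    # -- permanent multipole energy ---------------------------------------
    def permanent(self, positions: np.ndarray, state: StateParams):
        """(U, dU_dX, dU_dext) of the permanent multipole electrostatics.

        Forces include the frame (torque) contributions; dU_dext covers the
        real, reciprocal, self and neutrality terms of every extended
        variable with nonzero moment derivatives.
        """
        M = state.moments
        stacks = self.total_stacks(positions, M, 3, self.system.mscale)
        U = 0.5 * float(np.sum(probe_energy(stacks, M)))
        grad = -probe_force(stacks, M)              # dU/dX (pair part)
        torque = probe_torque(stacks, M)
        # distribute_torques returns force increments (-dU/dX)
        grad = grad - self.system.distribute_torques(torque, positions)

        dext = {k: 0.0 for k in range(self.system.n_ext)}
        for k, Md in state.dmoments.items():
            dext[k] = float(np.sum(probe_energy(stacks, Md)))

        if self.cell is not None and self.config.neutralize:
            U += background_energy(state.q_total, self.beta, self.cell.volume)
            for k, dq in state.dq_total.items():
                dext[k] += background_derivative(
                    state.q_total, dq, self.beta, self.cell.volume)
        U *= COULOMB
        grad *= COULOMB
        dext = {k: v * COULOMB for k, v in dext.items()}
        return U, grad, dext

    def permanent_energy(self, positions: np.ndarray,
                         state: StateParams) -> float:
        M = state.moments
        stacks = self.total_stacks(positions, M, 2, self.system.mscale)
        U = 0.5 * float(np.sum(probe_energy(stacks, M)))
        if self.cell is not None and self.config.neutralize:
            U += background_energy(state.q_total, self.beta, self.cell.volume)
        return U * COULOMB


def real_space_softcore_pair(q1: float, q2: float, r: float, lam1: float,
                             lam2: float, alpha_sc: float = 0.7,
                             beta: Optional[float] = None):
    """Soft-core real-space charge pair: the separation r is buffered to
    f = r + alpha_sc (1 - lam1 lam2)^2, which stays positive as r -> 0 for
    decoupled pairs.  Returns (U, dU/dr, dU/dlam1) in kcal/mol units.

    This is the optional protection for titrating charge sites; the
    production path leaves it off (the proton's heavy atom already shields
    it), which removes the df/dlambda term from the state derivative.
    """
    f = r + alpha_sc * (1.0 - lam1 * lam2) ** 2
    if beta is None:
        g = 1.0 / f
        dg = -1.0 / f ** 2
    else:
        from scipy.special import erfc
        g = erfc(beta * f) / f
        dg = (-erfc(beta * f) / f ** 2
              - 2.0 * beta * np.exp(-(beta * f) ** 2) / (np.sqrt(np.pi) * f))
    df_dlam1 = -2.0 * alpha_sc * (1.0 - lam1 * lam2) * lam2
    U = COULOMB * q1 * q2 * g
    return U, COULOMB * q1 * q2 * dg, COULOMB * q1 * q2 * dg * df_dlam1
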