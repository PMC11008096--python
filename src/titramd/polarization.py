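"""Induced-dipole polarization: Thole-damped self-consistent field,
polarization energy, Cartesian gradient, and the extended-variable
derivative obtained from a single converged SCF.

The energy is U_pol = -1/2 mu . E_p, where mu solves

    (alpha^-1 - T) mu = E_d

with E_d the permanent field under group-based (direct) masking and E_p the
permanent field under bonded (energy) masking.  Because the two mask sets
differ, the gradient requires the adjoint dipole set nu solving the same
system with E_p as the right-hand side; mu and nu are converged together in
one conjugate-gradient loop, which is what "a single SCF per step" means
operationally.

The extended-variable derivative follows from U = -1/2 E_p^T A^-1 E_d with
A = alpha^-1 - T:

    dU/dl = -1/2 [ Edot_p . mu + nu . Edot_d ] - 1/2 sum_i alphadot_i F_d,i . F_p,i

where Edot are fields sourced by the moment derivatives Mdot, and
F_d = E_d + T mu, F_p = E_p + T nu are total fields (finite even where
alpha = 0).  The Thole damping width is frozen (fixed charge density), so T
itself carries no state dependence — this is what makes one SCF enough.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import COULOMB
from .electrostatics import MultipoleElectrostatics
from .system import PolarizableSystem, StateParams
from .tensors import Moments, probe_force, probe_torque


class SCFConvergenceError(RuntimeError):
    def __init__(self, residuals):
        super().__init__(f"induced-dipole SCF failed to converge; residual "
                         f"history {residuals[-5:]}")
        self.residuals = residuals


@dataclass
class SCFState:
    mu: np.ndarray          # induced dipoles (direct-mask solve), e*A
    nu: np.ndarray          # adjoint dipoles (energy-mask solve), e*A
    E_d: np.ndarray         # permanent field, group masking, e/A^2
    E_p: np.ndarray         # permanent field, bonded masking, e/A^2
    converged: bool
    iterations: int
    residual: float


@dataclass
class PolarizationConfig:
    scf_tol: float = 1e-6       # max induced-dipole change, e*A
    scf_max_iter: int = 200
    mode: str = "mutual"        # "mutual" | "direct"


class Polarization:
    def __init__(self, system: PolarizableSystem,
                 elec: MultipoleElectrostatics,
                 config: PolarizationConfig = PolarizationConfig()):
        self.system = system
        self.elec = elec
        self.config = config

    # -- fields ------------------------------------------------------------
    def permanent_fields(self, positions: np.ndarray, moments: Moments):
        """(E_d, E_p): permanent multipole fields at every site under the
        two masking conventions, Thole-damped, full Ewald when periodic."""
        st_d = self.elec.total_stacks(positions, moments, 1,
                                      self.system.dscale, damped=True)
        st_p = self.elec.total_stacks(positions, moments, 1,
                                      self.system.pscale, damped=True)
        return -st_d[1], -st_p[1]

    def dipole_field(self, positions: np.ndarray, mu: np.ndarray) -> np.ndarray:
        """Field of an induced-dipole set at every site (T mu)."""
        st = self.elec.total_stacks(positions, Moments.dipoles(mu), 1,
                                    self.system.uscale, damped=True)
        return -st[1]

    def field_operator(self, positions: np.ndarray) -> "DipoleFieldOperator":
        """Precomputed T-matrix application for repeated SCF iterations."""
        return DipoleFieldOperator(self, positions)

    # -- SCF ---------------------------------------------------------------
    def scf_solve(self, positions: np.ndarray, state: StateParams,
                  tolerance: Optional[float] = None) -> SCFState:
        """Converge mu and nu by preconditioned conjugate gradients."""
        alpha = state.alpha
        E_d, E_p = self.permanent_fields(positions, state.moments)
        tol = tolerance if tolerance is not None else self.config.scf_tol

        if self.config.mode == "direct" or not np.any(alpha > 0):
            mu = alpha[:, None] * E_d
            nu = alpha[:, None] * E_p
            return SCFState(mu, nu, E_d, E_p, True, 0, 0.0)

        op = self.field_operator(positions)
        mu, it1, r1 = self._cg(op, alpha, E_d, tol)
        nu, it2, r2 = self._cg(op, alpha, E_p, tol)
        return SCFState(mu, nu, E_d, E_p, True, max(it1, it2), max(r1, r2))

    def _cg(self, field_op, alpha, E, tol):
        """CG on (alpha^-1 - T) mu = E restricted to polarizable sites."""
        act = alpha > 0
        mu = alpha[:, None] * E          # direct-field start
        mu[~act] = 0.0

        def A_of(m):
            out = np.zeros_like(m)
            Tm = field_op(m)
            out[act] = m[act] / alpha[act, None] - Tm[act]
            return out

        r = E.copy()
        r[~act] = 0.0
        r = r - A_of(mu)
        z = alpha[:, None] * r
        res0 = float(np.max(np.abs(z))) if z.size else 0.0
        if res0 < tol:
            return mu, 0, res0
        p = z.copy()
        rz = float(np.sum(r * z))
        residuals = []
        for it in range(1, self.config.scf_max_iter + 1):
            Ap = A_of(p)
            denom = float(np.sum(p * Ap))
            if denom == 0.0:
                break
            a = rz / denom
            mu = mu + a * p
            r = r - a * Ap
            z = alpha[:, None] * r
            res = float(np.max(np.abs(z))) if z.size else 0.0
            residuals.append(res)
            if res < tol:
                return mu, it, res
            rz_new = float(np.sum(r * z))
            p = z + (rz_new / rz) * p
            rz = rz_new
        if residuals and residuals[-1] < tol:
            return mu, len(residuals), residuals[-1]
        raise SCFConvergenceError(residuals or [np.inf])

    # -- energy ------------------------------------------------------------
    def energy(self, scf: SCFState) -> float:
        """U_pol = -1/2 mu . E_p, kcal/mol."""
        if not scf.converged:
            raise SCFConvergenceError([scf.residual])
        return -0.5 * float(np.sum(scf.mu * scf.E_p)) * COULOMB

    # -- gradient ----------------------------------------------------------
    def gradient(self, positions: np.ndarray, state: StateParams,
                 scf: SCFState) -> np.ndarray:
        """Analytic dU_pol/dX including Thole-damped T-matrix derivatives
        and torque distribution onto multipole frame atoms."""
        M = state.moments
        Dmu = Moments.dipoles(scf.mu)
        Dnu = Moments.dipoles(scf.nu)
        grad = np.zeros_like(positions)
        torque = np.zeros((self.system.n, 3))

        terms = [(Dmu, M, self.system.pscale),
                 (Dnu, M, self.system.dscale)]
        if self.config.mode == "mutual":
            terms.append((Dnu, Dmu, self.system.uscale))
        for A, B, scale in terms:
            stB = self.elec.total_stacks(positions, B, 2, scale, damped=True)
            stA = self.elec.total_stacks(positions, A, 3, scale, damped=True)
            grad += 0.5 * (-probe_force(stB[:3], A))
            grad += 0.5 * (-probe_force(stA, B))
            if B is M:
                torque += 0.5 * probe_torque(stA, M)
        grad = grad - self.system.distribute_torques(torque, positions)
        return grad * COULOMB

    # -- extended-variable derivative (single SCF) --------------------------
    def state_derivative(self, positions: np.ndarray, state: StateParams,
                         scf: SCFState) -> dict[int, float]:
        """dU_pol/d(lambda_k or zeta_k) from the already-converged SCF.

        No re-solve happens here: the expression only contracts the fixed
        mu/nu with fields of the moment derivatives and with the total
        fields scaled by dalpha.
        """
        dext = {k: 0.0 for k in range(self.system.n_ext)}
        if not (state.dmoments or state.dalpha):
            return dext
        if self.config.mode == "mutual":
            op = self.field_operator(positions)
            F_d = scf.E_d + op(scf.mu)
            F_p = scf.E_p + op(scf.nu)
        else:
            F_d, F_p = scf.E_d, scf.E_p
        for k in range(self.system.n_ext):
            val = 0.0
            Md = state.dmoments.get(k)
            if Md is not None:
                std = self.elec.total_stacks(positions, Md, 1,
                                             self.system.dscale, damped=True)
                stp = self.elec.total_stacks(positions, Md, 1,
                                             self.system.pscale, damped=True)
                Edot_d, Edot_p = -std[1], -stp[1]
                val += -0.5 * (float(np.sum(Edot_p * scf.mu))
                               + float(np.sum(scf.nu * Edot_d)))
            da = state.dalpha.get(k)
            if da is not None:
                val += -0.5 * float(np.sum(da * np.sum(F_d * F_p, axis=1)))
            if val != 0.0:
                dext[k] = val * COULOMB
        return dext


class DipoleFieldOperator:
    """Cached application mu -> T mu at fixed geometry.

    Precomputes the real-space rank-2 tensors (u-scaled, Thole damped), the
    reciprocal phase factors, and the self-field coefficient, so each SCF
    iteration costs only contractions.
    """

    def __init__(self, pol: Polarization, positions: np.ndarray):
        from .ewald import KsumRecip, RealKernel, _pair_radials
        from .tensors import t_tensor
        system = pol.system
        elec = pol.elec
        kernel = RealKernel(beta=elec.beta, cutoff=elec.cutoff,
                            scale=system.uscale, damped=True,
                            damping_alpha=system.damping_alpha,
                            thole_a=system.thole_a)
        self.n = system.n
        ii, jj, dr, r = system.pair_list(positions, kernel.cutoff)
        self.ii, self.jj = ii, jj
        if len(ii):
            B = _pair_radials(r, ii, jj, kernel)
            self.T2 = t_tensor(2, dr, B)
        else:
            self.T2 = None
        self._recip = None
        self._pme = None
        if elec.recip is not None:
            if isinstance(elec.recip, KsumRecip):
                rec = elec.recip
                self._recip = (rec.phases(positions), rec.coeff, rec.k)
            else:
                self._pme = (elec.recip, positions)
            beta = elec.beta
            self.self_coeff = 4.0 * beta ** 3 / (3.0 * np.sqrt(np.pi))
        else:
            self.self_coeff = 0.0

    def __call__(self, mu: np.ndarray) -> np.ndarray:
        E = np.zeros((self.n, 3))
        if self.T2 is not None:
            Ei = np.einsum("pab,pb->pa", self.T2, mu[self.jj])
            Ej = np.einsum("pab,pb->pa", self.T2, mu[self.ii])
            np.add.at(E, self.ii, Ei)
            np.add.at(E, self.jj, Ej)
        if self._recip is not None:
            ph, coeff, k = self._recip
            A = mu @ k.T                                # (n, nk)
            S = 1j * np.einsum("jk,jk->k", ph, A.astype(complex))
            pw = np.conj(ph) * (coeff * S)[None, :]
            phi1 = 2.0 * np.real(-1j * (pw @ k))
            E += -phi1
        elif self._pme is not None:
            rec, positions = self._pme
            st = rec.stacks(positions, Moments.dipoles(mu), 1)
            E += -st[1]
        if self._recip is not None or self._pme is not None:
            E += self.self_coeff * mu
        return E
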