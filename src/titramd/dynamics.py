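"""The extended Hamiltonian and its Langevin propagation.

U(X, theta) = U_bonded(X) + U_nonbonded(X, lambda, zeta) + U_bias(lambda,
zeta), with lambda_k = sin^2(theta_k).  Bonded terms always use the
protonated-state parameters (a deprotonated site keeps its alchemically
decoupled proton bonded in place), so they contribute nothing to dU/dtheta.
The chain rule dU/dtheta_k = dU/dlambda_k * 2 sin(theta_k) cos(theta_k)
keeps every lambda in [0, 1] without reflecting walls.

Cartesian and theta degrees of freedom are propagated jointly by a BAOAB
Langevin splitting, thermostatted at the same bath temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .bias import BiasParams, bias_energy
from .constants import KB, KCAL_TO_AMU_A2_FS2
from .electrostatics import ElectrostaticsConfig, MultipoleElectrostatics
from .model import ExtendedState, TitrationRecord
from .polarization import Polarization, PolarizationConfig
from .system import PolarizableSystem
from .vdw import VdwConfig, vdw_energy_extended

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
           "S": 32.06, "P": 30.974, "NA": 22.99, "CL": 35.45}


def atom_mass(name: str) -> float:
    key = name.upper()
    return _MASSES.get(key[:2], _MASSES.get(key[:1], 16.0))


@dataclass
class EngineConfig:
    bias: BiasParams = field(default_factory=BiasParams)
    vdw: VdwConfig = field(default_factory=VdwConfig)
    elec: ElectrostaticsConfig = field(default_factory=ElectrostaticsConfig)
    pol: PolarizationConfig = field(default_factory=PolarizationConfig)
    include_bonded: bool = True
    include_vdw: bool = True
    include_elec: bool = True
    include_pol: bool = True
    bond_k: float = 350.0       # kcal/mol/A^2
    angle_k: float = 50.0       # kcal/mol/A^2 on the 1-3 distance


@dataclass
class EnergyReport:
    total: float
    grad_x: np.ndarray
    grad_ext: np.ndarray
    components: dict[str, float]
    scf_iterations: int = 0


class CpHMDEngine:
    """Extended-Hamiltonian evaluator for one system + configuration."""

    def __init__(self, system: PolarizableSystem,
                 config: EngineConfig = EngineConfig()):
        self.system = system
        self.config = config
        n = system.n
        self.elec = None
        self.pol = None
        if n > 0 and config.include_elec:
            self.elec = MultipoleElectrostatics(system, config.elec)
            if config.include_pol:
                self.pol = Polarization(system, self.elec, config.pol)
        self._bond_terms = self._build_bonded() if config.include_bonded else []

    def _build_bonded(self):
        """Harmonic bond + 1-3 distance terms anchored at the construction
        geometry (a deliberately simple bonded model for toy systems)."""
        terms = []
        pos = self.system.positions
        seen = set()
        for a in self.system.atoms:
            for j in a.bonded:
                key = (min(a.index, j), max(a.index, j))
                if key in seen:
                    continue
                seen.add(key)
                r0 = float(np.linalg.norm(pos[a.index] - pos[j]))
                terms.append((key[0], key[1], r0, self.config.bond_k))
        # 1-3 pseudo-angle terms
        for a in self.system.atoms:
            nb = sorted(a.bonded)
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    i, j = nb[x], nb[y]
                    key = (min(i, j), max(i, j))
                    if key in seen:
                        continue
                    seen.add(key)
                    r0 = float(np.linalg.norm(pos[i] - pos[j]))
                    terms.append((i, j, r0, self.config.angle_k))
        return terms

    def bonded(self, positions: np.ndarray):
        U = 0.0
        grad = np.zeros_like(positions)
        for i, j, r0, k in self._bond_terms:
            dr = positions[i] - positions[j]
            r = float(np.linalg.norm(dr))
            U += k * (r - r0) ** 2
            g = 2.0 * k * (r - r0) / r * dr
            grad[i] += g
            grad[j] -= g
        return U, grad

    # ------------------------------------------------------------------
    def energy(self, positions: np.ndarray, theta: np.ndarray,
               want_gradients: bool = True) -> EnergyReport:
        system = self.system
        ext = np.sin(theta) ** 2
        state = system.interpolate_state(positions, ext)
        U = 0.0
        grad = np.zeros_like(positions) if system.n else np.zeros((0, 3))
        dext = np.zeros(system.n_ext)
        comp: dict[str, float] = {}
        scf_iters = 0

        if self.config.include_bonded and system.n:
            ub, gb = self.bonded(positions)
            U += ub
            grad += gb
            comp["bonded"] = ub

        if self.config.include_vdw and system.n:
            uv, gv, dv = vdw_energy_extended(system, state, positions,
                                             self.config.vdw)
            U += uv
            grad += gv
            for k, v in dv.items():
                dext[k] += v
            comp["vdw"] = uv

        if self.elec is not None:
            if want_gradients:
                ue, ge, de = self.elec.permanent(positions, state)
                grad += ge
                for k, v in de.items():
                    dext[k] += v
            else:
                ue = self.elec.permanent_energy(positions, state)
            U += ue
            comp["permanent"] = ue
            if self.pol is not None:
                scf = self.pol.scf_solve(positions, state)
                scf_iters = scf.iterations
                up = self.pol.energy(scf)
                U += up
                if want_gradients:
                    grad += self.pol.gradient(positions, state, scf)
                    for k, v in self.pol.state_derivative(
                            positions, state, scf).items():
                        dext[k] += v
                comp["polarization"] = up

        ubias, dbias = bias_energy(system.sites, ext, self.config.bias)
        U += ubias
        dext[: len(dbias)] += dbias
        comp["bias"] = ubias

        # chain rule through lambda = sin^2(theta)
        grad_theta = dext * 2.0 * np.sin(theta) * np.cos(theta)
        return EnergyReport(U, grad, grad_theta, comp, scf_iters)


# ---------------------------------------------------------------------------
# Langevin propagation

@dataclass
class LangevinSpec:
    timestep: float = 1.0       # fs
    friction: float = 5.0       # ps^-1
    temperature: float = 298.0  # K
    seed: int = 1
    theta_mass: float = 5.0     # amu*A^2
    freeze_theta: bool = False  # fixed-lambda window sampling


class LangevinIntegrator:
    """Joint BAOAB propagation of Cartesian and theta degrees of freedom."""

    def __init__(self, engine: CpHMDEngine, state: ExtendedState,
                 spec: LangevinSpec):
        self.engine = engine
        self.state = state
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.masses = np.array([atom_mass(a.name)
                                for a in engine.system.atoms])
        self.report = engine.energy(state.X, state.theta)
        self.n_steps = 0

    def _kick(self, dt_half: float) -> None:
        st, rp = self.state, self.report
        if not np.all(np.isfinite(rp.grad_x)) or \
           not np.all(np.isfinite(rp.grad_ext)):
            raise RuntimeError(f"non-finite force at step {self.n_steps}")
        if self.masses.size:
            acc = -rp.grad_x * KCAL_TO_AMU_A2_FS2 / self.masses[:, None]
            st.V += dt_half * acc
        if not self.spec.freeze_theta:
            st.theta_velocity += dt_half * (-rp.grad_ext * KCAL_TO_AMU_A2_FS2
                                            / st.theta_mass)

    def _drift(self, dt_half: float) -> None:
        st = self.state
        st.X += dt_half * st.V
        if not self.spec.freeze_theta:
            st.theta += dt_half * st.theta_velocity

    def _ou(self, dt: float) -> None:
        gamma = self.spec.friction * 1e-3    # ps^-1 -> fs^-1
        if gamma <= 0.0:
            return
        st = self.state
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(1.0 - c1 * c1)
        kt = KB * self.spec.temperature * KCAL_TO_AMU_A2_FS2
        if self.masses.size:
            sig = np.sqrt(kt / self.masses)[:, None]
            st.V = c1 * st.V + c2 * sig * self.rng.standard_normal(st.V.shape)
        if not self.spec.freeze_theta:
            sig_t = np.sqrt(kt / st.theta_mass)
            st.theta_velocity = c1 * st.theta_velocity + \
                c2 * sig_t * self.rng.standard_normal(st.theta.shape)

    def step(self, n: int = 1) -> None:
        dt = self.spec.timestep
        for _ in range(n):
            self._kick(0.5 * dt)
            self._drift(0.5 * dt)
            self._ou(dt)
            self._drift(0.5 * dt)
            self.report = self.engine.energy(self.state.X, self.state.theta)
            self._kick(0.5 * dt)
            self.n_steps += 1

    def kinetic_energy(self) -> float:
        """Kinetic energy of Cartesian + theta degrees of freedom, kcal/mol."""
        st = self.state
        ke = 0.0
        if self.masses.size:
            ke += 0.5 * float(np.sum(self.masses[:, None] * st.V ** 2))
        ke += 0.5 * float(np.sum(st.theta_mass * st.theta_velocity ** 2))
        return ke / KCAL_TO_AMU_A2_FS2

    def kinetic_temperature(self) -> float:
        dof = self.state.V.size + self.state.theta.size
        return 2.0 * self.kinetic_energy() / (dof * KB)


@dataclass
class RunConfig:
    steps: int = 1000
    save_interval: int = 10
    langevin: LangevinSpec = field(default_factory=LangevinSpec)
    start_lambda: float = 0.5   # intermediate start facilitates relaxation
    start_zeta: float = 0.5


def initial_state(system: PolarizableSystem, run: RunConfig) -> ExtendedState:
    n_ext = system.n_ext
    theta = np.full(n_ext, float(ExtendedState.theta_of(run.start_lambda)))
    for s in system.sites:
        if s.zeta_index is not None:
            theta[s.zeta_index] = float(ExtendedState.theta_of(run.start_zeta))
    return ExtendedState(
        X=system.positions.copy(),
        V=np.zeros((system.n, 3)),
        theta=theta,
        theta_velocity=np.zeros(n_ext),
        theta_mass=np.full(n_ext, run.langevin.theta_mass),
    )


def run_cphmd(engine: CpHMDEngine, run: RunConfig,
              state: Optional[ExtendedState] = None,
              record: Optional[TitrationRecord] = None) -> TitrationRecord:
    """Propagate and record per-site (lambda, zeta) every save interval."""
    system = engine.system
    if state is None:
        state = initial_state(system, run)
    if record is None:
        record = TitrationRecord(pH=engine.config.bias.pH)
    integ = LangevinIntegrator(engine, state, run.langevin)

    def save(step):
        ext = state.lam
        lams = {s.lambda_index: float(ext[s.lambda_index])
                for s in system.sites}
        zetas = {s.lambda_index: float(ext[s.zeta_index])
                 for s in system.sites if s.zeta_index is not None}
        record.append(step, lams, zetas)

    save(0)
    done = 0
    while done < run.steps:
        todo = min(run.save_interval, run.steps - done)
        integ.step(todo)
        done += todo
        save(done)
    return record
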