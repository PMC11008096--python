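"""Bias terms, the extended Hamiltonian, and Langevin propagation."""

import numpy as np
import pytest

from titramd.bias import BiasParams, bias_energy
from titramd.constants import KB, LN10
from titramd.dynamics import (CpHMDEngine, EngineConfig, LangevinIntegrator,
                              LangevinSpec, RunConfig, initial_state,
                              run_cphmd)
from titramd.fixtures import analytic_site
from titramd.model import ExtendedState


def _bias_only_engine(pKa=7.0, pH=7.0, barrier=2.0, model_bias=None):
    system = analytic_site(pKa, model_bias)
    cfg = EngineConfig(bias=BiasParams(barrier=barrier, pH=pH),
                       include_bonded=False, include_vdw=False,
                       include_elec=False, include_pol=False)
    return CpHMDEngine(system, cfg)


class TestBiasEnergy:
    def test_ph_equal_pka_zeroes_ph_bias(self):
        system = analytic_site(7.0)
        for lam in (0.0, 0.3, 1.0):
            U, _ = bias_energy(system.sites, np.array([lam]),
                               BiasParams(barrier=0.0, pH=7.0))
            assert U == pytest.approx(0.0, abs=1e-14)

    def test_ph_bias_closed_form(self):
        """pKa - pH = 1 at 298 K and lambda = 0:
        U_pH = ln(10) k_B T ~ 1.3643 kcal/mol."""
        system = analytic_site(8.0)
        params = BiasParams(barrier=0.0, pH=7.0, temperature=298.0)
        U0, _ = bias_energy(system.sites, np.array([0.0]), params)
        assert U0 == pytest.approx(LN10 * KB * 298.0, rel=1e-12)
        assert U0 == pytest.approx(1.3636, abs=5e-4)
        U1, _ = bias_energy(system.sites, np.array([1.0]), params)
        assert U1 == 0.0

    def test_barrier_height(self):
        system = analytic_site(7.0)
        params = BiasParams(barrier=2.5, pH=7.0)
        Uh, _ = bias_energy(system.sites, np.array([0.5]), params)
        U0, _ = bias_energy(system.sites, np.array([0.0]), params)
        assert Uh - U0 == pytest.approx(2.5)

    def test_his_three_surface_blend(self, his_fixture):
        site = his_fixture.system.sites[0]
        site.model_bias = np.array([0.0, 1.0, -2.0])
        site.model_bias_zeta0 = np.array([0.0, 0.5])
        site.model_bias_tautomer = np.array([0.0, 0.3])
        params = BiasParams(barrier=0.0, pH=site.pKa_ref)
        ext = np.array([0.4, 0.6])
        U, dext = bias_energy([site], ext, params)
        h = 1e-7
        for k in (0, 1):
            e2 = ext.copy()
            e2[k] += h
            up, _ = bias_energy([site], e2, params)
            e2[k] -= 2 * h
            um, _ = bias_energy([site], e2, params)
            assert dext[k] == pytest.approx((up - um) / (2 * h), rel=1e-6)
        site.model_bias = np.zeros(5)
        site.model_bias_zeta0 = None
        site.model_bias_tautomer = None


def test_theta_zero_kills_theta_gradient():
    """d lambda/d theta = 0 at the end state regardless of dU/dlambda."""
    eng = _bias_only_engine(pKa=9.0, pH=4.0)
    rep = eng.energy(np.zeros((0, 3)), np.array([0.0]))
    assert rep.grad_ext[0] == 0.0


def test_total_energy_reduces_at_protonated_end(cys_fixture):
    """All lambda = 1, no barrier, pH = pKa: the extended energy equals the
    plain protonated-system energy plus U_mod(1)."""
    system = cys_fixture.system
    pka = system.sites[0].pKa_ref
    eng = CpHMDEngine(system, EngineConfig(
        bias=BiasParams(barrier=0.0, pH=pka)))
    theta = np.full(system.n_ext, np.pi / 2)   # lambda = 1
    rep = eng.energy(system.positions, theta)
    assert rep.components["bias"] == pytest.approx(0.0, abs=1e-12)


def test_master_theta_derivative_fd(dipeptide_fixture, rng):
    """dU/dtheta of the full extended Hamiltonian matches FD."""
    from titramd.polarization import PolarizationConfig
    eng = CpHMDEngine(dipeptide_fixture.system,
                      EngineConfig(pol=PolarizationConfig(scf_tol=1e-10)))
    theta = rng.uniform(0.3, 1.2, dipeptide_fixture.system.n_ext)
    pos = dipeptide_fixture.system.positions
    rep = eng.energy(pos, theta)
    h = 1e-5
    for k in range(len(theta)):
        tp = theta.copy()
        tp[k] += h
        tm = theta.copy()
        tm[k] -= h
        fd = (eng.energy(pos, tp, want_gradients=False).total
              - eng.energy(pos, tm, want_gradients=False).total) / (2 * h)
        assert rep.grad_ext[k] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestLangevin:
    def test_free_flight(self):
        """Zero force, zero friction: theta advances linearly."""
        eng = _bias_only_engine(barrier=0.0, pKa=7.0, pH=7.0)
        st = ExtendedState(np.zeros((0, 3)), np.zeros((0, 3)),
                           np.array([0.6]), np.array([0.01]),
                           np.array([5.0]))
        integ = LangevinIntegrator(eng, st, LangevinSpec(
            timestep=1.0, friction=0.0))
        integ.step(10)
        assert st.theta[0] == pytest.approx(0.6 + 0.01 * 10.0)

    def test_determinism(self):
        """Identical seeds produce bit-identical trajectories."""
        outs = []
        for _ in range(2):
            eng = _bias_only_engine(pKa=7.0, pH=6.0)
            rec = run_cphmd(eng, RunConfig(
                steps=200, save_interval=20,
                langevin=LangevinSpec(timestep=1.0, seed=42)))
            outs.append(rec.lam[0])
        assert outs[0] == outs[1]

    def test_zero_step_run_records_initial_state(self):
        eng = _bias_only_engine()
        rec = run_cphmd(eng, RunConfig(steps=0, save_interval=10))
        assert rec.n_samples == 1
        assert rec.lam[0] == [pytest.approx(0.5)]

    def test_lambda_stays_bounded_under_random_walk(self, rng):
        """sin^2 keeps lambda in [0, 1] for arbitrary theta excursions."""
        theta = np.cumsum(rng.normal(scale=10.0, size=1000))
        lam = np.sin(theta) ** 2
        assert np.all((lam >= 0.0) & (lam <= 1.0))

    def test_energy_conservation_velocity_verlet_limit(self, cys_fixture):
        """Friction 0 (thermostat off): total extended energy drift below
        1e-4 kcal/mol per step at a 0.5 fs timestep."""
        from titramd.polarization import PolarizationConfig
        system = cys_fixture.system
        eng = CpHMDEngine(system, EngineConfig(
            pol=PolarizationConfig(scf_tol=1e-10)))
        run = RunConfig(langevin=LangevinSpec(timestep=0.5, friction=0.0,
                                              seed=3))
        st = initial_state(system, run)
        rng = np.random.default_rng(5)
        st.V += rng.normal(scale=2e-3, size=st.V.shape)
        st.theta_velocity += rng.normal(scale=2e-3,
                                        size=st.theta_velocity.shape)
        integ = LangevinIntegrator(eng, st, run.langevin)
        e0 = integ.report.total + integ.kinetic_energy()
        nsteps = 100
        integ.step(nsteps)
        e1 = integ.report.total + integ.kinetic_energy()
        assert abs(e1 - e0) / nsteps < 1e-4

    def test_thermostat_temperature(self):
        """A harmonic degree of freedom thermalizes to the bath
        temperature within statistical error."""
        eng = _bias_only_engine(barrier=-0.0, pKa=7.0, pH=7.0)
        # quadratic well in theta via the barrier term at lambda ~ 0.5
        eng.config.bias.barrier = 2.0
        st = ExtendedState(np.zeros((0, 3)), np.zeros((0, 3)),
                           np.array([np.pi / 4]), np.array([0.0]),
                           np.array([5.0]))
        integ = LangevinIntegrator(eng, st, LangevinSpec(
            timestep=1.0, friction=10.0, temperature=298.0, seed=9))
        temps = []
        for _ in range(400):
            integ.step(25)
            temps.append(integ.kinetic_temperature())
        mean_T = np.mean(temps)
        # one DOF, 400 quasi-independent samples: sigma ~ T sqrt(2/N)
        assert abs(mean_T - 298.0) < 4.0 * 298.0 * np.sqrt(2.0 / 400)


@pytest.mark.parametrize("delta,deprotonated", [(-6.0, True), (6.0, False)])
def test_strong_acid_base_limits(delta, deprotonated):
    """pKa - pH = -6: the site deprotonates and stays below lambda = 0.1
    for the vast majority of post-burn-in samples; +6 mirrors it."""
    eng = _bias_only_engine(pKa=7.0 + delta, pH=7.0)
    rec = run_cphmd(eng, RunConfig(
        steps=20000, save_interval=20,
        langevin=LangevinSpec(timestep=1.5, friction=2.0, seed=17,
                              theta_mass=2.0)))
    lam = np.array(rec.lam[0][len(rec.lam[0]) // 5:])
    if deprotonated:
        assert np.mean(lam < 0.1) > 0.95
    else:
        assert np.mean(lam > 0.9) > 0.95


def test_flat_landscape_recovers_henderson_hasselbalch():
    """With U_mod = 0 and no nonbonded coupling, the sampled deprotonated
    fraction at pH = pKa - 0.5 matches 1/(1+10^0.5) within sampling error;
    this is the operational meaning of the bias flattening the surface."""
    from titramd.sampling import count_fractions
    eng = _bias_only_engine(pKa=7.0, pH=6.5)
    rec = run_cphmd(eng, RunConfig(
        steps=120000, save_interval=25,
        langevin=LangevinSpec(timestep=1.5, friction=2.0, seed=23,
                              theta_mass=2.0)))
    s, nd, npr, _ = count_fractions(rec)
    expect = 1.0 / (1.0 + 10.0 ** 0.5)
    n_kept = nd + npr
    sigma = np.sqrt(expect * (1 - expect) / n_kept)
    # autocorrelation inflates the error; allow a generous multiple
    assert abs(s - expect) < 10.0 * sigma + 0.02
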