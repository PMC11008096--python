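"""pH replica exchange, BAR, model-PMF fitting, fraction counting, and the
Hill-equation pKa fit."""

import numpy as np
import pytest

from titramd.bias import BiasParams
from titramd.constants import KB, LN10
from titramd.dynamics import CpHMDEngine, EngineConfig, LangevinSpec, \
    RunConfig, run_cphmd
from titramd.fixtures import analytic_site
from titramd.model import TitrationRecord
from titramd.sampling import (ReplicaLadder, bar_estimate, count_fractions,
                              exchange_criterion, fit_hill, fit_model_pmf,
                              hill_curve, run_phrex)


def _engines(pKa, phs, barrier=2.0):
    out = []
    for ph in phs:
        s = analytic_site(pKa)
        out.append(CpHMDEngine(s, EngineConfig(
            bias=BiasParams(barrier=barrier, pH=float(ph)),
            include_bonded=False, include_vdw=False, include_elec=False,
            include_pol=False)))
    return out


class TestExchangeCriterion:
    def test_identical_lambdas_always_accept(self):
        sites = analytic_site(7.0).sites
        lam = np.array([0.3])
        dE, p = exchange_criterion(lam, lam, sites, 6.0, 7.0, 298.0)
        assert dE == pytest.approx(0.0, abs=1e-14)
        assert p == 1.0

    def test_downhill_always_accepts(self):
        sites = analytic_site(7.0).sites
        dE, p = exchange_criterion(np.array([1.0]), np.array([0.0]),
                                   sites, 6.0, 7.0, 298.0)
        if dE < 0:
            assert p == 1.0

    def test_closed_form_single_site(self):
        """lambda_A = 0, lambda_B = 1, delta pH = 1:
        |dE| = ln(10) k_B T and p = min(1, e^-|dE|/kT) on the uphill side."""
        sites = analytic_site(7.0).sites
        T = 298.0
        kt = LN10 * KB * T
        dE, p = exchange_criterion(np.array([0.0]), np.array([1.0]),
                                   sites, 6.0, 7.0, T)
        assert abs(dE) == pytest.approx(kt, rel=1e-12)
        if dE > 0:
            assert p == pytest.approx(np.exp(-LN10), rel=1e-12)
        dE2, p2 = exchange_criterion(np.array([1.0]), np.array([0.0]),
                                     sites, 6.0, 7.0, T)
        assert dE2 == pytest.approx(-dE, rel=1e-12)
        assert (p == 1.0) != (p2 == 1.0)


def test_descending_ladder_rejected():
    with pytest.raises(ValueError, match="ascending"):
        ReplicaLadder(_engines(7.0, [7.5, 6.5]))


def test_same_ph_ladder_reproduces_single_run_exactly():
    """Two replicas at the same pH: every swap is accepted (dE = 0) yet is
    a no-op, so the first walker's trajectory is bit-identical to a plain
    single-pH run with the same seed."""
    engines = _engines(7.0, [6.8, 6.8])
    ladder = ReplicaLadder(engines, exchange_interval=200)
    spec = LangevinSpec(timestep=1.5, friction=2.0, seed=37, theta_mass=2.0)
    recs = run_phrex(ladder, 5000, RunConfig(save_interval=50,
                                             langevin=spec), seed=3)
    acc = sum(ladder.accepted.values())
    att = sum(ladder.attempts.values())
    assert acc == att and att > 0        # degenerate swaps always accepted
    single = run_cphmd(_engines(7.0, [6.8])[0], RunConfig(
        steps=5000, save_interval=50,
        langevin=LangevinSpec(timestep=1.5, friction=2.0, seed=37,
                              theta_mass=2.0)))
    assert recs[0].lam[0] == single.lam[0]


def test_phrex_default_interval_is_500():
    ladder = ReplicaLadder(_engines(7.0, [6.5, 7.5]))
    assert ladder.exchange_interval == 500


class TestBar:
    def test_identical_states(self):
        dg, err = bar_estimate(np.zeros(100), np.zeros(100), 298.0)
        assert dg == pytest.approx(0.0, abs=1e-10)

    def test_antisymmetry(self, rng):
        wf = rng.normal(1.5, 0.8, 400)
        wr = rng.normal(-0.7, 0.8, 400)
        dg1, _ = bar_estimate(wf, wr, 298.0)
        dg2, _ = bar_estimate(wr, wf, 298.0)
        assert dg1 == pytest.approx(-dg2, abs=1e-9)

    def test_empty_direction_rejected(self):
        with pytest.raises(ValueError):
            bar_estimate(np.array([]), np.ones(10), 298.0)

    def test_gaussian_work_oracle(self):
        """Crooks-consistent Gaussian work: w_F ~ N(dG + d, 2 d k_B T),
        w_R ~ N(-dG + d, 2 d k_B T). BAR recovers dG within 3 SE at
        n = 5000 per direction."""
        T = 298.0
        kt = KB * T
        dG_true = 1.0
        dissip = 1.0
        sigma2 = 2.0 * kt * dissip
        rng = np.random.default_rng(2024)
        wf = rng.normal(dG_true + dissip, np.sqrt(sigma2), 5000)
        wr = rng.normal(-dG_true + dissip, np.sqrt(sigma2), 5000)
        dg, err = bar_estimate(wf, wr, T)
        assert abs(dg - dG_true) < 3.0 * max(err, 1e-6)

    def test_poor_overlap_warns(self):
        with pytest.warns(UserWarning, match="overlap"):
            bar_estimate(np.full(50, 100.0), np.full(50, 100.0), 298.0)


class TestModelPmfFit:
    def test_zero_differences_zero_polynomial(self):
        lam = np.linspace(0, 1, 11)
        c = fit_model_pmf(lam, np.zeros(10))
        assert np.allclose(c, 0.0)

    def test_quartic_roundtrip(self):
        """A PMF generated from a known quartic is recovered exactly."""
        lam = np.linspace(0, 1, 11)
        true = np.array([0.0, 1.2, -3.4, 2.2, 0.7])
        G = np.polynomial.polynomial.polyval(lam, true)
        dgs = np.diff(G)
        c = fit_model_pmf(lam, dgs, degree=4)
        assert np.allclose(c, -true, atol=1e-6)

    def test_symmetric_constraint_forces_zero_endstate_gap(self, rng):
        lam = np.linspace(0, 1, 11)
        dgs = rng.normal(0.3, 0.2, 10)     # asymmetric noise
        c = fit_model_pmf(lam, dgs, degree=4, symmetric_endpoints=True)
        val = np.polynomial.polynomial.polyval
        assert val(1.0, -c) == pytest.approx(0.0, abs=1e-10)
        assert val(0.0, -c) == 0.0

    def test_degree_vs_windows_guard(self):
        with pytest.raises(ValueError):
            fit_model_pmf(np.linspace(0, 1, 4), np.zeros(3), degree=5)


class TestFractionCounting:
    def _rec(self, series):
        rec = TitrationRecord(pH=7.0)
        for i, v in enumerate(series):
            rec.append(i, {0: v}, {})
        return rec

    def test_one_each(self):
        s, nd, npr, disc = count_fractions(self._rec([0.05, 0.95]),
                                           burn_in=0.0)
        assert (s, nd, npr, disc) == (0.5, 1, 1, 0)

    def test_intermediate_discarded(self):
        s, nd, npr, disc = count_fractions(self._rec([0.05, 0.5, 0.95]),
                                           burn_in=0.0)
        assert (nd, npr, disc) == (1, 1, 1)
        assert s == 0.5

    def test_thresholds_inclusive(self):
        s, nd, npr, disc = count_fractions(self._rec([0.10, 0.90]),
                                           burn_in=0.0)
        assert (nd, npr, disc) == (1, 1, 0)

    def test_all_intermediate_is_error(self):
        with pytest.raises(ValueError, match="end state"):
            count_fractions(self._rec([0.5, 0.4, 0.6]), burn_in=0.0)

    def test_empty_record_is_error(self):
        with pytest.raises(ValueError):
            count_fractions(TitrationRecord(pH=7.0))


class TestHillFit:
    def test_noiseless_roundtrip(self):
        ph = np.arange(5.5, 8.6, 0.5)
        s = hill_curve(ph, 7.0, 1.0)
        fit = fit_hill(ph, s)
        assert fit.pKa == pytest.approx(7.0, abs=1e-6)
        assert fit.n == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("n", [0.6, 1.0, 1.7])
    def test_midpoint_is_half_for_any_coefficient(self, n):
        assert hill_curve(4.2, 4.2, n) == pytest.approx(0.5)

    def test_ph_shift_equivariance(self):
        """Shifting every pH by c shifts pKa by c and leaves n fixed."""
        rng = np.random.default_rng(8)
        ph = np.arange(3.0, 6.1, 0.5)
        s = hill_curve(ph, 4.4, 0.9) + rng.normal(0, 0.01, ph.size)
        f1 = fit_hill(ph, s)
        f2 = fit_hill(ph + 2.0, s)
        assert f2.pKa - f1.pKa == pytest.approx(2.0, abs=1e-8)
        assert f2.n == pytest.approx(f1.n, abs=1e-8)

    def test_binomial_noise_recovery(self):
        """n = 0.8, pKa = 4.2 with 2000 binomial draws per point is
        recovered within its 95% confidence interval."""
        rng = np.random.default_rng(77)
        ph = np.arange(2.7, 5.8, 0.5)
        true = hill_curve(ph, 4.2, 0.8)
        s = rng.binomial(2000, true) / 2000.0
        fit = fit_hill(ph, s)
        assert abs(fit.pKa - 4.2) < 2.0 * fit.pKa_stderr + 0.02
        assert abs(fit.n - 0.8) < 2.0 * fit.n_stderr + 0.02

    def test_no_transition_rejected(self):
        ph = np.array([1.0, 1.5, 2.0])
        with pytest.raises(ValueError, match="transition"):
            fit_hill(ph, np.array([0.99, 0.995, 0.999]))
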