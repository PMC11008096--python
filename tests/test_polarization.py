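"""Induced-dipole SCF, polarization energy/gradient, and the single-SCF
extended-variable derivative."""

import numpy as np
import pytest

from titramd.constants import COULOMB
from titramd.electrostatics import ElectrostaticsConfig, MultipoleElectrostatics
from titramd.io import ForceField
from titramd.model import Atom, MultipoleSet, PolarizeParams
from titramd.polarization import (Polarization, PolarizationConfig,
                                  SCFConvergenceError, SCFState)
from titramd.system import PolarizableSystem

TIGHT = PolarizationConfig(scf_tol=1e-12)


def _vacuum_system(positions, charges, alphas, groups=None):
    ff = ForceField()
    atoms, mp = [], []
    for i, (p, q, a) in enumerate(zip(positions, charges, alphas)):
        t = i + 1
        atoms.append(Atom(i, "X", t, p))
        mp.append(MultipoleSet(q, np.zeros(3), np.zeros((3, 3))))
        ff.polarize[t] = PolarizeParams(a, 0.39)
    s = PolarizableSystem(atoms, ff, None, multipoles=mp)
    if groups is not None:
        s.groups = np.asarray(groups)
        s.dscale = np.where(s.groups[:, None] == s.groups[None, :], 0.0, 1.0)
    return s


def _pol(system, **kw):
    elec = MultipoleElectrostatics(system, ElectrostaticsConfig())
    return Polarization(system, elec, PolarizationConfig(scf_tol=1e-12, **kw))


def test_single_site_in_coulomb_field():
    """mu = alpha E exactly; U = -1/2 alpha E^2."""
    s = _vacuum_system([[0, 0, 0], [3.0, 0, 0]], [0.8, 0.0], [0.0, 1.2])
    pol = _pol(s)
    st = s.interpolate_state(s.positions, np.zeros(0))
    scf = pol.scf_solve(s.positions, st)
    E = 0.8 / 9.0
    assert scf.mu[1] == pytest.approx([1.2 * E, 0, 0])
    assert pol.energy(scf) == pytest.approx(-0.5 * 1.2 * E ** 2 * COULOMB)


def test_coulomb_field_magnitude():
    """|E| = k q / r^2 in kcal/mol units after the Coulomb factor."""
    s = _vacuum_system([[0, 0, 0], [2.0, 0, 0]], [1.0, 0.0], [0.0, 1.0])
    pol = _pol(s)
    st = s.interpolate_state(s.positions, np.zeros(0))
    E_d, E_p = pol.permanent_fields(s.positions, st.moments)
    assert np.linalg.norm(E_d[1]) * COULOMB == pytest.approx(
        332.063713 * 1.0 / 4.0)


def test_same_group_atoms_do_not_polarize_each_other():
    s = _vacuum_system([[0, 0, 0], [3.0, 0, 0]], [0.8, 0.0], [0.0, 1.2],
                       groups=[7, 7])
    pol = _pol(s)
    st = s.interpolate_state(s.positions, np.zeros(0))
    E_d, E_p = pol.permanent_fields(s.positions, st.moments)
    assert np.allclose(E_d, 0.0)
    assert not np.allclose(E_p, 0.0)   # energy field uses bonded masks only


def test_zero_polarizability_gives_zero_dipoles_and_energy(rng):
    pos = rng.uniform(0, 6, (4, 3))
    s = _vacuum_system(pos, [0.3, -0.2, 0.4, -0.5], [0.0] * 4)
    pol = _pol(s)
    st = s.interpolate_state(s.positions, np.zeros(0))
    scf = pol.scf_solve(s.positions, st)
    assert np.allclose(scf.mu, 0.0)
    assert pol.energy(scf) == 0.0


def test_iterative_equals_dense_matrix_solve(rng):
    """CG result equals the direct solve of (alpha^-1 - T) mu = E_d."""
    pos = rng.uniform(0, 5, (6, 3))
    q = [0.3, -0.4, 0.5, -0.4, 0.2, -0.2]
    s = _vacuum_system(pos, q, [0.9, 1.1, 0.7, 1.3, 0.8, 1.0])
    pol = _pol(s)
    st = s.interpolate_state(s.positions, np.zeros(0))
    scf = pol.scf_solve(s.positions, st)
    n = 6
    A = np.zeros((3 * n, 3 * n))
    for j in range(n):
        for c in range(3):
            mu = np.zeros((n, 3))
            mu[j, c] = 1.0
            A[:, 3 * j + c] = -pol.dipole_field(pos, mu).ravel()
    alpha = np.array([0.9, 1.1, 0.7, 1.3, 0.8, 1.0])
    A += np.diag(np.repeat(1.0 / alpha, 3))
    mu_dense = np.linalg.solve(A, scf.E_d.ravel()).reshape(n, 3)
    assert np.max(np.abs(mu_dense - scf.mu)) < 1e-9
    # energy equals the half-contraction of the dense solution
    nu_dense = np.linalg.solve(A, scf.E_p.ravel()).reshape(n, 3)
    assert pol.energy(scf) == pytest.approx(
        -0.5 * float(np.sum(mu_dense * scf.E_p)) * COULOMB, rel=1e-9)


def test_unconverged_state_rejected():
    scf = SCFState(np.zeros((1, 3)), np.zeros((1, 3)), np.zeros((1, 3)),
                   np.zeros((1, 3)), False, 0, 1.0)
    s = _vacuum_system([[0, 0, 0]], [0.0], [1.0])
    with pytest.raises(SCFConvergenceError):
        _pol(s).energy(scf)


def test_quadrupole_field_matches_numeric_potential_gradient(rng):
    """Field of a pure quadrupole equals -grad of its potential."""
    from titramd.tensors import Moments, b_coulomb, potential_stack
    Q = rng.normal(size=(3, 3))
    Q = 0.5 * (Q + Q.T)
    Q -= np.eye(3) * np.trace(Q) / 3.0
    src = Moments(np.zeros(1), np.zeros((1, 3)), Q[None])
    probe = np.array([2.0, 1.0, -1.5])
    h = 1e-5
    field = -potential_stack(probe[None], b_coulomb(
        np.linalg.norm(probe)[None]), src, 1)[1][0]
    for c in range(3):
        p2 = probe.copy()
        p2[c] += h
        up = potential_stack(p2[None], b_coulomb(
            np.linalg.norm(p2)[None]), src, 0)[0][0]
        p2[c] -= 2 * h
        um = potential_stack(p2[None], b_coulomb(
            np.linalg.norm(p2)[None]), src, 0)[0][0]
        assert field[c] == pytest.approx(-(up - um) / (2 * h), rel=1e-7)


def test_thole_damping_keeps_contact_energy_finite():
    """Two polarizable sites approaching r -> 0 stay finite (undamped
    point dipoles would diverge)."""
    energies = []
    for r in (1.0, 0.3, 0.05, 0.005):
        s = _vacuum_system([[0, 0, 0], [r, 0, 0]], [0.5, -0.5], [1.0, 1.0])
        pol = _pol(s)
        st = s.interpolate_state(s.positions, np.zeros(0))
        scf = pol.scf_solve(s.positions, st)
        energies.append(pol.energy(scf))
    assert all(np.isfinite(energies))


def test_variational_bound_on_fixtures(cys_fixture, dipeptide_fixture):
    """U_pol <= 0 for induction by the permanent field."""
    for fx in (cys_fixture, dipeptide_fixture):
        system = fx.system
        elec = MultipoleElectrostatics(system, ElectrostaticsConfig())
        pol = Polarization(system, elec, TIGHT)
        ext = np.full(system.n_ext, 0.5)
        st = system.interpolate_state(system.positions, ext)
        scf = pol.scf_solve(system.positions, st)
        assert pol.energy(scf) <= 1e-10


def test_gradient_matches_fd_and_conserves_force(rng):
    pos = rng.uniform(0, 5, (3, 3))
    s = _vacuum_system(pos, [0.4, -0.6, 0.2], [0.9, 0.0, 1.1])
    pol = _pol(s)

    def U(p):
        st = s.interpolate_state(p, np.zeros(0))
        return pol.energy(pol.scf_solve(p, st))

    st = s.interpolate_state(pos, np.zeros(0))
    scf = pol.scf_solve(pos, st)
    g = pol.gradient(pos, st, scf)
    assert np.allclose(g.sum(axis=0), 0.0, atol=1e-8)
    h = 1e-5
    for i in range(3):
        for c in range(3):
            p2 = pos.copy()
            p2[i, c] += h
            up = U(p2)
            p2[i, c] -= 2 * h
            um = U(p2)
            assert g[i, c] == pytest.approx((up - um) / (2 * h),
                                            rel=1e-5, abs=1e-9)


class TestSingleScfDerivative:
    """The headline property: dU_pol/dlambda from ONE converged SCF equals
    the two-sided finite difference in which each side is re-solved."""

    @pytest.mark.parametrize("fixture_name",
                             ["cys_fixture", "his_fixture",
                              "dipeptide_fixture"])
    def test_matches_resolved_fd(self, fixture_name, request, rng):
        fx = request.getfixturevalue(fixture_name)
        system = fx.system
        elec = MultipoleElectrostatics(system,
                                       ElectrostaticsConfig(ktol=1e-10))
        pol = Polarization(system, elec, TIGHT)
        ext = rng.uniform(0.2, 0.8, system.n_ext)
        pos = system.positions

        def U(e):
            st = system.interpolate_state(pos, e)
            return pol.energy(pol.scf_solve(pos, st))

        st = system.interpolate_state(pos, ext)
        scf = pol.scf_solve(pos, st)
        dext = pol.state_derivative(pos, st, scf)
        h = 1e-4
        for k in range(system.n_ext):
            e2 = ext.copy()
            e2[k] += h
            up = U(e2)
            e2[k] -= 2 * h
            um = U(e2)
            fd = (up - um) / (2 * h)
            assert dext[k] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_no_titrating_sites_gives_zero(self, rng):
        pos = rng.uniform(0, 5, (3, 3))
        s = _vacuum_system(pos, [0.4, -0.6, 0.2], [0.9, 1.0, 1.1])
        pol = _pol(s)
        st = s.interpolate_state(pos, np.zeros(0))
        scf = pol.scf_solve(pos, st)
        assert pol.state_derivative(pos, st, scf) == {}
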