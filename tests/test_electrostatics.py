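"""Permanent multipole electrostatics: Coulomb/Madelung oracles, PME vs
direct k-sum, self and neutrality terms, forces and state derivatives."""

import numpy as np
import pytest

from titramd.constants import COULOMB
from titramd.electrostatics import real_space_softcore_pair
from titramd.ewald import KsumRecip, background_energy, self_stacks
from titramd.model import Atom, CrystalCell, Frame, MultipoleSet
from titramd.io import ForceField
from titramd.pme import PmeRecip
from titramd.system import PolarizableSystem
from titramd.tensors import Moments

from conftest import charge_system, electrostatics_for


def total_energy(system, **kw):
    es = electrostatics_for(system, **kw)
    st = system.interpolate_state(system.positions, np.zeros(system.n_ext))
    return es.permanent_energy(system.positions, st)


def test_neutral_pair_reaches_coulomb_limit():
    """+1/-1 at 3 A in a huge cell: the full Ewald total (real + recip +
    self + neutrality) reproduces Coulomb's law."""
    cell = CrystalCell(np.eye(3) * 150.0, ewald_beta=0.22, real_cutoff=20.0)
    s = charge_system([[0, 0, 0], [3.0, 0, 0]], [1.0, -1.0], cell)
    U = total_energy(s, ktol=1e-12)
    assert U == pytest.approx(-COULOMB / 3.0, rel=1e-4)


def test_madelung_constant_8_ion_lattice(ionic_fixture):
    system = ionic_fixture.system
    U = total_energy(system, ktol=1e-14)
    nearest = 2.5
    M = -(U / 4.0) * nearest / COULOMB
    assert M == pytest.approx(1.747565, abs=5e-5)


def test_beta_invariance(ionic_fixture, rng):
    """Total energy is invariant to the Ewald splitting parameter."""
    pos = ionic_fixture.system.positions
    vals = []
    for beta in (1.8, 2.2, 2.6):
        cell = CrystalCell(np.eye(3) * 5.0, ewald_beta=beta,
                           real_cutoff=2.4999)
        s = charge_system(pos, [(-1.0) ** i for i in
                                (0, 1, 1, 2, 1, 2, 2, 3)], cell)
        vals.append(total_energy(s, ktol=1e-14))
    assert np.allclose(vals, vals[0], rtol=1e-5)


def test_zero_moments_zero_energy_and_forces():
    cell = CrystalCell(np.eye(3) * 10.0, ewald_beta=0.8, real_cutoff=4.5)
    s = charge_system([[1, 1, 1], [5, 5, 5]], [0.0, 0.0], cell)
    es = electrostatics_for(s)
    st = s.interpolate_state(s.positions, np.zeros(0))
    U, g, _ = es.permanent(s.positions, st)
    assert U == 0.0
    assert np.allclose(g, 0.0)


def test_overlapping_atoms_rejected():
    cell = CrystalCell(np.eye(3) * 10.0, ewald_beta=0.8, real_cutoff=4.5)
    s = charge_system([[1, 1, 1], [1, 1, 1 + 1e-8]], [1.0, -1.0], cell)
    es = electrostatics_for(s)
    st = s.interpolate_state(s.positions, np.zeros(0))
    with pytest.raises(ValueError, match="overlap"):
        es.permanent_energy(s.positions, st)


def test_self_energy_single_charge_closed_form():
    """- beta / sqrt(pi) * k for a unit charge."""
    beta = 0.7
    src = Moments(np.array([1.0]), np.zeros((1, 3)), np.zeros((1, 3, 3)))
    st = self_stacks(src, beta)
    u_self = 0.5 * src.m0[0] * st[0][0] * COULOMB
    assert u_self == pytest.approx(-beta / np.sqrt(np.pi) * COULOMB)


def test_background_term_zero_for_neutral():
    assert background_energy(0.0, 0.7, 1000.0) == 0.0
    assert background_energy(2.0, 0.7, 1000.0) < 0.0


def test_background_lambda_derivative_matches_fd(cys_fixture):
    """The neutrality term's state derivative tracks dq_tot/dlambda."""
    system = cys_fixture.system
    # place the CYS fragment in a periodic cell so the background term acts
    atoms = system.atoms
    cell = CrystalCell(np.eye(3) * 12.0, ewald_beta=0.9, real_cutoff=5.0)
    psys = PolarizableSystem(atoms, system.ff, cell, sites=system.sites)
    es = electrostatics_for(psys, ktol=1e-10)
    ext = np.array([0.37])
    h = 1e-6

    def U(e):
        st = psys.interpolate_state(psys.positions, e)
        return es.permanent_energy(psys.positions, st)

    st = psys.interpolate_state(psys.positions, ext)
    _, _, dext = es.permanent(psys.positions, st)
    fd = (U(ext + h) - U(ext - h)) / (2 * h)
    assert dext[0] == pytest.approx(fd, rel=1e-6)


def test_lambda_derivative_equals_potential_times_charge():
    """For a site whose charge is q(lambda) = lambda q^P, dU/dlambda equals
    the electrostatic potential at the site times q^P."""
    cell = CrystalCell(np.eye(3) * 12.0, ewald_beta=0.9, real_cutoff=5.0)
    lam = 0.42
    qP = 0.8
    s = charge_system([[0, 0, 0], [3.0, 0, 0], [0, 3.5, 0]],
                      [lam * qP, -0.5, 0.6], cell)
    es = electrostatics_for(s, ktol=1e-12)
    st = s.interpolate_state(s.positions, np.zeros(0))
    stacks = es.total_stacks(s.positions, st.moments, 0, s.mscale)
    # potential at site 0 (includes its own self/background environment)
    phi0 = stacks[0][0]
    from titramd.ewald import background_energy

    def U_of(l):
        s2 = charge_system([[0, 0, 0], [3.0, 0, 0], [0, 3.5, 0]],
                           [l * qP, -0.5, 0.6], cell)
        return total_energy(s2, ktol=1e-12)

    h = 1e-6
    fd = (U_of(lam + h) - U_of(lam - h)) / (2 * h)
    # analytic: qP * (potential at site) + background derivative
    vol = cell.volume
    qtot = lam * qP - 0.5 + 0.6
    bg = -np.pi * qtot * qP / (0.9 ** 2 * vol)
    assert qP * phi0 * COULOMB + bg * COULOMB == pytest.approx(fd, rel=1e-5)


def _random_multipole_system(rng, n=12, box=10.0, beta=0.75, neutral=True):
    q = rng.normal(size=n) * 0.5
    if neutral:
        q -= q.mean()
    d = rng.normal(size=(n, 3)) * 0.2
    Q = rng.normal(size=(n, 3, 3)) * 0.1
    Q = 0.5 * (Q + np.swapaxes(Q, 1, 2))
    Q -= np.eye(3) * np.trace(Q, axis1=1, axis2=2)[:, None, None] / 3.0
    pos = rng.uniform(0, box, (n, 3))
    atoms = [Atom(i, "X", 1, pos[i]) for i in range(n)]
    mp = [MultipoleSet(q[i], d[i], Q[i], Frame.NONE) for i in range(n)]
    cell = CrystalCell(np.eye(3) * box, ewald_beta=beta,
                       real_cutoff=0.45 * box)
    return PolarizableSystem(atoms, ForceField(), cell, multipoles=mp), \
        Moments(q, d, Q)


def test_pme_equals_direct_ksum(rng):
    """Mesh PME total equals the explicit structure-factor summation."""
    system, src = _random_multipole_system(rng, n=12)
    ks = KsumRecip(system.cell, 0.75, tol=1e-14)
    pm = PmeRecip(system.cell, 0.75, order=10, spacing=0.25)
    Uk = ks.energy(system.positions, src)
    Up = pm.energy(system.positions, src)
    assert Up == pytest.approx(Uk, rel=1e-6)


def test_pme_grid_refinement_converges(rng):
    system, src = _random_multipole_system(rng, n=8)
    coarse = PmeRecip(system.cell, 0.75, order=6, spacing=0.8)
    fine = PmeRecip(system.cell, 0.75, order=8, spacing=0.3)
    ks = KsumRecip(system.cell, 0.75, tol=1e-14)
    Uk = ks.energy(system.positions, src)
    err_c = abs(coarse.energy(system.positions, src) - Uk)
    err_f = abs(fine.energy(system.positions, src) - Uk)
    assert err_f < err_c
    assert err_f / abs(Uk) < 1e-6


def test_pme_translation_invariance(rng):
    system, src = _random_multipole_system(rng, n=6)
    pm = PmeRecip(system.cell, 0.75, order=10, spacing=0.25)
    U1 = pm.energy(system.positions, src)
    U2 = pm.energy(system.positions + np.array([1.234, -0.77, 0.41]), src)
    assert U2 == pytest.approx(U1, abs=1e-8 + 1e-8 * abs(U1))


def test_spread_conserves_total_charge(rng):
    system, src = _random_multipole_system(rng, n=6, neutral=False)
    pm = PmeRecip(system.cell, 0.75, order=6, spacing=0.5)
    Q = pm.spread(system.positions, src)
    assert Q.sum() == pytest.approx(src.m0.sum(), abs=1e-8)


def test_forces_and_state_derivatives_match_fd(dipeptide_fixture, rng):
    """Analytic dU/dX (with torque distribution) and dU/dlambda of the full
    permanent electrostatics match central finite differences."""
    system = dipeptide_fixture.system
    es = electrostatics_for(system, ktol=1e-10)
    ext = rng.uniform(0.2, 0.8, system.n_ext)
    pos = system.positions + rng.normal(scale=0.04, size=(system.n, 3))
    st = system.interpolate_state(pos, ext)
    U, grad, dext = es.permanent(pos, st)
    assert np.allclose(grad.sum(axis=0), 0.0, atol=1e-8)
    h = 1e-5

    def U_of(p, e):
        s = system.interpolate_state(p, e)
        return es.permanent_energy(p, s)

    for i in rng.choice(system.n, 4, replace=False):
        for c in range(3):
            p2 = pos.copy()
            p2[i, c] += h
            up = U_of(p2, ext)
            p2[i, c] -= 2 * h
            um = U_of(p2, ext)
            assert grad[i, c] == pytest.approx((up - um) / (2 * h),
                                               rel=1e-5, abs=1e-6)
    for k in range(system.n_ext):
        e2 = ext.copy()
        e2[k] += h
        up = U_of(pos, e2)
        e2[k] -= 2 * h
        um = U_of(pos, e2)
        assert dext[k] == pytest.approx((up - um) / (2 * h),
                                        rel=1e-5, abs=1e-6)


def test_softcore_pair_finite_at_contact_and_fd():
    U0, _, _ = real_space_softcore_pair(0.4, 0.4, 0.0, 0.5, 0.5)
    assert np.isfinite(U0)
    h = 1e-6
    U, dUdr, dUdl = real_space_softcore_pair(0.4, 0.4, 2.0, 0.5, 0.7)
    Up = real_space_softcore_pair(0.4, 0.4, 2.0, 0.5 + h, 0.7)[0]
    Um = real_space_softcore_pair(0.4, 0.4, 2.0, 0.5 - h, 0.7)[0]
    assert dUdl == pytest.approx((Up - Um) / (2 * h), rel=1e-6)
    # lambda = 1 for both: reduces to the plain kernel, no soft buffer
    U1, _, dl = real_space_softcore_pair(0.4, 0.4, 2.0, 1.0, 1.0)
    assert U1 == pytest.approx(COULOMB * 0.16 / 2.0)
    assert dl == 0.0
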