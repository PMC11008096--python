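"""Deterministic generators for test systems.

Every fixture is a pure function of its `FixtureSpec`: toy diatomics,
small water boxes, minimal titratable model compounds (reduced analogues
of capped amino-acid model peptides), an 8-ion cubic lattice, and a small
hydrogen-bonded dipeptide-like P1 cell.  The embedded parameters are
fixture parameters chosen to be chemically plausible — documented subsets,
not a published force-field distribution.  The cysteine sulfur carries the
4.0 (thiolate) -> 2.8 (thiol) A^3 polarizability change that makes sulfur
the canonical test of interpolating between two nonzero polarizabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ForceField, read_parameters_string
from .model import (Atom, CrystalCell, Frame, MultipoleSet, PolarizeParams,
                    ResidueKind, VdwParams)
from .residues import REFERENCE_PKA, ResidueDefinition, build_titratable_sites
from .system import PolarizableSystem

FIXTURE_KINDS = ("diatomic-multipole", "water-box", "model-compound",
                 "ionic-lattice", "dipeptide-crystal-toy")


@dataclass
class FixtureSpec:
    kind: str
    n: int = 8                      # size parameter (waters, ions, ...)
    residue: str = "CYS"            # model-compound residue kind
    a: float = 5.0                  # ionic lattice constant
    seed: int = 1
    jitter: float = 0.0             # positional noise amplitude, A


@dataclass
class Fixture:
    name: str
    system: PolarizableSystem
    spec: FixtureSpec


def make_fixture(spec: FixtureSpec) -> Fixture:
    if spec.kind == "diatomic-multipole":
        return _diatomic(spec)
    if spec.kind == "water-box":
        return _water_box(spec)
    if spec.kind == "model-compound":
        return _model_compound(spec)
    if spec.kind == "ionic-lattice":
        return _ionic_lattice(spec)
    if spec.kind == "dipeptide-crystal-toy":
        return _dipeptide_crystal(spec)
    raise ValueError(f"unknown fixture kind '{spec.kind}'; "
                     f"choose from {FIXTURE_KINDS}")


# ---------------------------------------------------------------------------
# water

WATER_PARAMETERS = """
# fixture water parameters (AMOEBA-style frames and masking)
mpole-12-scale 0.0
mpole-13-scale 0.0
mpole-14-scale 0.4
mpole-15-scale 0.8
polar-12-scale 0.0
polar-13-scale 0.0
polar-14-scale 1.0
vdw-12-scale 0.0
vdw-13-scale 0.0
vdw-14-scale 1.0

vdw        1   3.405  0.1100
vdw        2   2.655  0.0135  0.910

multipole  1  bisector  2 2   -0.51966
          0.00000  0.00000  0.14279
          0.37928
          0.00000 -0.41809
          0.00000  0.00000  0.03881
multipole  2  zthenx  1 2    0.25983
         -0.03859  0.00000 -0.05818
         -0.03673
          0.00000 -0.10739
         -0.00203  0.00000  0.14412
polarize   1   0.837  0.390   2
polarize   2   0.496  0.390   1
"""


def water_forcefield() -> ForceField:
    return read_parameters_string(WATER_PARAMETERS)


def _water_geometry(center: np.ndarray, R: np.ndarray) -> np.ndarray:
    """O + 2 H, OH = 0.9572 A, HOH = 104.52 deg, oriented by R."""
    th = np.radians(104.52 / 2.0)
    base = np.array([
        [0.0, 0.0, 0.0],
        [0.9572 * np.sin(th), 0.0, 0.9572 * np.cos(th)],
        [-0.9572 * np.sin(th), 0.0, 0.9572 * np.cos(th)],
    ])
    return base @ R.T + center


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _water_box(spec: FixtureSpec) -> Fixture:
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    per_side = int(np.ceil(n ** (1.0 / 3.0)))
    spacing = 3.1
    box = max(per_side * spacing, 10.0)
    atoms: list[Atom] = []
    count = 0
    for i in range(per_side):
        for j in range(per_side):
            for k in range(per_side):
                if count >= n:
                    break
                c = (np.array([i, j, k]) + 0.5) * (box / per_side)
                c = c + rng.uniform(-spec.jitter, spec.jitter, 3) \
                    if spec.jitter else c
                pos = _water_geometry(c, _random_rotation(rng))
                o = len(atoms)
                atoms.append(Atom(o, "O", 1, pos[0], [o + 1, o + 2]))
                atoms.append(Atom(o + 1, "H", 2, pos[1], [o]))
                atoms.append(Atom(o + 2, "H", 2, pos[2], [o]))
                count += 1
    cell = CrystalCell(np.eye(3) * box, ewald_beta=0.9,
                       real_cutoff=min(4.9, 0.45 * box))
    system = PolarizableSystem(atoms, water_forcefield(), cell)
    return Fixture(f"water-box-{n}", system, spec)


# ---------------------------------------------------------------------------
# simple fixtures

def _diatomic(spec: FixtureSpec) -> Fixture:
    ff = ForceField()
    ff.vdw[1] = VdwParams(3.5, 0.1)
    ff.vdw[2] = VdwParams(3.2, 0.08)
    # unbonded pair: nothing is mask-scaled away
    atoms = [Atom(0, "A", 1, [0.0, 0.0, 0.0]),
             Atom(1, "B", 2, [0.0, 0.0, 2.9])]
    mp = [MultipoleSet(0.35, [0.0, 0.0, 0.12], np.diag([0.08, -0.03, -0.05]),
                       Frame.Z_ONLY, (1,)),
          MultipoleSet(-0.35, [0.0, 0.0, -0.10], np.diag([-0.04, -0.04, 0.08]),
                       Frame.Z_ONLY, (0,))]
    system = PolarizableSystem(atoms, ff, None, multipoles=mp)
    return Fixture("diatomic-multipole", system, spec)


def _ionic_lattice(spec: FixtureSpec) -> Fixture:
    """Rock-salt-like cube: 8 alternating unit charges on a cubic grid."""
    a = spec.a
    ff = ForceField()
    ff.vdw[10] = VdwParams(3.0, 0.1)
    ff.vdw[11] = VdwParams(3.0, 0.1)
    atoms, mp = [], []
    idx = 0
    for i in range(2):
        for j in range(2):
            for k in range(2):
                q = (-1.0) ** (i + j + k)
                t = 10 if q > 0 else 11
                atoms.append(Atom(idx, "NA" if q > 0 else "CL", t,
                                  np.array([i, j, k]) * (a / 2.0)))
                mp.append(MultipoleSet(q, np.zeros(3), np.zeros((3, 3))))
                idx += 1
    cell = CrystalCell(np.eye(3) * a, ewald_beta=2.2,
                       real_cutoff=0.4999 * a)
    system = PolarizableSystem(atoms, ff, cell, multipoles=mp)
    return Fixture("ionic-lattice", system, spec)


# ---------------------------------------------------------------------------
# titratable model compounds

def _mset(q, d=(0, 0, 0), Q=None, frame=Frame.NONE, fa=()):
    Q = np.zeros((3, 3)) if Q is None else np.diag(Q)
    return MultipoleSet(q, np.array(d, float), Q, frame, fa)


def _cys_fragment(off: int, origin: np.ndarray):
    """Reduced thiol model: cap carbon - sulfur - titrating hydrogen."""
    o = np.asarray(origin, float)
    atoms = [
        Atom(off + 0, "CB", 101, o + [0.0, 0.0, 0.0], [off + 1]),
        Atom(off + 1, "SG", 102, o + [1.82, 0.0, 0.0], [off + 0, off + 2]),
        Atom(off + 2, "HG", 103, o + [2.25, 1.27, 0.0], [off + 1]),
    ]
    zx = (Frame.Z_THEN_X, (off + 0, off + 2))
    zo = (Frame.Z_ONLY, (off + 1,))
    mp_P = {
        off + 0: _mset(0.12),
        off + 1: _mset(-0.32, (0, 0, 0.08), (0.05, -0.02, -0.03), *zx),
        off + 2: _mset(0.20, (0, 0, -0.03), (-0.01, -0.01, 0.02), *zo),
    }
    mp_U = {
        off + 0: _mset(-0.08),
        off + 1: _mset(-0.92, (0, 0, 0.15), (0.08, -0.04, -0.04), *zx),
        off + 2: _mset(0.0, (0, 0, 0.0), (0, 0, 0), *zo),
    }
    d = ResidueDefinition(
        residue_kind=ResidueKind.CYS,
        atoms=[off, off + 1, off + 2],
        titrating_hydrogens={off + 2: 0},
        endstate_multipoles={"P": mp_P, "U": mp_U},
        endstate_polarizabilities={
            "P": {off: 1.334, off + 1: 2.8, off + 2: 0.496},
            "U": {off: 1.334, off + 1: 4.0, off + 2: 0.0},
        },
        pKa_ref=REFERENCE_PKA[ResidueKind.CYS],
    )
    return atoms, d


def _lys_fragment(off: int, origin: np.ndarray):
    """Reduced amine model: cap carbon - nitrogen - three hydrogens."""
    o = np.asarray(origin, float)
    atoms = [
        Atom(off + 0, "CE", 111, o + [0.0, 0.0, 0.0], [off + 1]),
        Atom(off + 1, "NZ", 112, o + [1.50, 0.0, 0.0],
             [off + 0, off + 2, off + 3, off + 4]),
        Atom(off + 2, "HZ1", 113, o + [1.95, 0.55, 0.80], [off + 1]),
        Atom(off + 3, "HZ2", 113, o + [1.95, 0.25, -0.93], [off + 1]),
        Atom(off + 4, "HZ3", 113, o + [1.95, -0.90, 0.15], [off + 1]),
    ]
    zx = (Frame.Z_THEN_X, (off + 0, off + 3))
    zo = (Frame.Z_ONLY, (off + 1,))
    mp_P = {
        off + 0: _mset(0.19),
        off + 1: _mset(-0.15, (0, 0, 0.10), (0.04, 0.04, -0.08), *zx),
        off + 2: _mset(0.32, (0, 0, -0.05), (-0.02, -0.02, 0.04), *zo),
        off + 3: _mset(0.32, (0, 0, -0.05), (-0.02, -0.02, 0.04), *zo),
        off + 4: _mset(0.32, (0, 0, -0.05), (-0.02, -0.02, 0.04), *zo),
    }
    mp_U = {
        off + 0: _mset(0.05),
        off + 1: _mset(-0.69, (0, 0, 0.22), (0.08, 0.08, -0.16), *zx),
        off + 2: _mset(0.0, frame=zo[0], fa=zo[1]),
        off + 3: _mset(0.32, (0, 0, -0.06), (-0.02, -0.02, 0.04), *zo),
        off + 4: _mset(0.32, (0, 0, -0.06), (-0.02, -0.02, 0.04), *zo),
    }
    d = ResidueDefinition(
        residue_kind=ResidueKind.LYS,
        atoms=[off + i for i in range(5)],
        titrating_hydrogens={off + 2: 0},
        endstate_multipoles={"P": mp_P, "U": mp_U},
        endstate_polarizabilities={
            "P": {off: 1.334, off + 1: 1.073, off + 2: 0.496,
                  off + 3: 0.496, off + 4: 0.496},
            "U": {off: 1.334, off + 1: 1.073, off + 2: 0.0,
                  off + 3: 0.496, off + 4: 0.496},
        },
        pKa_ref=REFERENCE_PKA[ResidueKind.LYS],
    )
    return atoms, d


def _carboxylate_fragment(off: int, origin: np.ndarray,
                          kind: ResidueKind):
    """Reduced carboxylic acid: cap C - carboxyl C - two O, each with a
    (possibly dummy) proton.  Protonated tautomerism: P1 = proton on O1
    (zeta = 1), P2 = proton on O2."""
    o = np.asarray(origin, float)
    atoms = [
        Atom(off + 0, "CB", 121, o + [0.0, 0.0, 0.0], [off + 1]),
        Atom(off + 1, "CG", 122, o + [1.52, 0.0, 0.0],
             [off + 0, off + 2, off + 3]),
        Atom(off + 2, "OD1", 123, o + [2.17, 1.06, 0.0], [off + 1, off + 4]),
        Atom(off + 3, "OD2", 123, o + [2.17, -1.06, 0.0], [off + 1, off + 5]),
        Atom(off + 4, "HD1", 124, o + [3.13, 0.98, 0.0], [off + 2]),
        Atom(off + 5, "HD2", 124, o + [3.13, -0.98, 0.0], [off + 3]),
    ]
    zxO1 = (Frame.Z_THEN_X, (off + 1, off + 0))
    zxO2 = (Frame.Z_THEN_X, (off + 1, off + 0))
    zo1 = (Frame.Z_ONLY, (off + 2,))
    zo2 = (Frame.Z_ONLY, (off + 3,))

    def carboxyl(qcb, qcg, qo1, qo2, qh1, qh2, do1, do2):
        return {
            off + 0: _mset(qcb),
            off + 1: _mset(qcg, (0, 0, 0.05), (0.02, 0.02, -0.04),
                           Frame.Z_THEN_X, (off + 2, off + 3)),
            off + 2: _mset(qo1, (0, 0, do1), (0.06, -0.03, -0.03), *zxO1),
            off + 3: _mset(qo2, (0, 0, do2), (0.06, -0.03, -0.03), *zxO2),
            off + 4: _mset(qh1, (0, 0, -0.02) if qh1 else (0, 0, 0),
                           (-0.01, -0.01, 0.02) if qh1 else (0, 0, 0), *zo1),
            off + 5: _mset(qh2, (0, 0, -0.02) if qh2 else (0, 0, 0),
                           (-0.01, -0.01, 0.02) if qh2 else (0, 0, 0), *zo2),
        }

    mp_U = carboxyl(0.05, 0.65, -0.85, -0.85, 0.0, 0.0, 0.12, 0.12)
    mp_P1 = carboxyl(0.05, 0.60, -0.55, -0.50, 0.40, 0.0, 0.05, 0.10)
    mp_P2 = carboxyl(0.05, 0.60, -0.50, -0.55, 0.0, 0.40, 0.10, 0.05)
    alpha_U = {off: 1.334, off + 1: 1.334, off + 2: 0.837, off + 3: 0.837,
               off + 4: 0.0, off + 5: 0.0}
    alpha_P1 = {off: 1.334, off + 1: 1.334, off + 2: 0.832, off + 3: 0.914,
                off + 4: 0.457, off + 5: 0.0}
    alpha_P2 = {off: 1.334, off + 1: 1.334, off + 2: 0.914, off + 3: 0.832,
                off + 4: 0.0, off + 5: 0.457}
    d = ResidueDefinition(
        residue_kind=kind,
        atoms=[off + i for i in range(6)],
        titrating_hydrogens={off + 4: +1, off + 5: -1},
        endstate_multipoles={"U": mp_U, "P1": mp_P1, "P2": mp_P2},
        endstate_polarizabilities={"U": alpha_U, "P1": alpha_P1,
                                   "P2": alpha_P2},
        pKa_ref=REFERENCE_PKA[kind],
    )
    return atoms, d


def _his_fragment(off: int, origin: np.ndarray):
    """Reduced imidazole: cap C, ND1-H (HID side, -1), CE1, NE2-H
    (HIE side, +1).  Neutral tautomerism: U1 = HIE (zeta = 1), U2 = HID."""
    o = np.asarray(origin, float)
    atoms = [
        Atom(off + 0, "CB", 131, o + [0.0, 0.0, 0.0], [off + 1]),
        Atom(off + 1, "ND1", 132, o + [1.39, 0.0, 0.0],
             [off + 0, off + 2, off + 3]),
        Atom(off + 2, "HD1", 133, o + [1.85, -0.93, 0.0], [off + 1]),
        Atom(off + 3, "CE1", 134, o + [2.10, 1.16, 0.0], [off + 1, off + 4]),
        Atom(off + 4, "NE2", 135, o + [3.44, 1.02, 0.0], [off + 3, off + 5]),
        Atom(off + 5, "HE2", 136, o + [4.10, 1.78, 0.0], [off + 4]),
    ]
    zxN1 = (Frame.Z_THEN_X, (off + 3, off + 0))
    zxN2 = (Frame.Z_THEN_X, (off + 3, off + 5))
    zo1 = (Frame.Z_ONLY, (off + 1,))
    zo2 = (Frame.Z_ONLY, (off + 4,))

    def imid(qcb, qn1, qh1, qce, qn2, qh2):
        return {
            off + 0: _mset(qcb),
            off + 1: _mset(qn1, (0, 0, 0.09), (0.05, -0.02, -0.03), *zxN1),
            off + 2: _mset(qh1, (0, 0, -0.02) if qh1 else (0, 0, 0),
                           (-0.01, -0.01, 0.02) if qh1 else (0, 0, 0), *zo1),
            off + 3: _mset(qce, (0, 0, 0.03), (0.02, 0.01, -0.03),
                           Frame.BISECTOR, (off + 1, off + 4)),
            off + 4: _mset(qn2, (0, 0, 0.09), (0.05, -0.02, -0.03), *zxN2),
            off + 5: _mset(qh2, (0, 0, -0.02) if qh2 else (0, 0, 0),
                           (-0.01, -0.01, 0.02) if qh2 else (0, 0, 0), *zo2),
        }

    mp_P = imid(0.21, -0.15, 0.38, 0.20, -0.02, 0.38)      # HIP, +1
    mp_U1 = imid(0.10, -0.56, 0.0, 0.18, -0.08, 0.36)      # HIE
    mp_U2 = imid(0.10, -0.08, 0.36, 0.18, -0.56, 0.0)      # HID
    aN, aC, aH = 1.073, 1.334, 0.496

    def al(h1, h2):
        return {off: aC, off + 1: aN, off + 2: h1, off + 3: aC,
                off + 4: aN, off + 5: h2}

    d = ResidueDefinition(
        residue_kind=ResidueKind.HIS,
        atoms=[off + i for i in range(6)],
        titrating_hydrogens={off + 5: +1, off + 2: -1},
        endstate_multipoles={"P": mp_P, "U1": mp_U1, "U2": mp_U2},
        endstate_polarizabilities={"P": al(aH, aH), "U1": al(0.0, aH),
                                   "U2": al(aH, 0.0)},
        pKa_ref=REFERENCE_PKA[ResidueKind.HIS],
    )
    return atoms, d


_FRAGMENTS = {
    "CYS": _cys_fragment,
    "LYS": _lys_fragment,
    "ASP": lambda off, o: _carboxylate_fragment(off, o, ResidueKind.ASP),
    "GLU": lambda off, o: _carboxylate_fragment(off, o, ResidueKind.GLU),
    "HIS": _his_fragment,
}

_FRAGMENT_VDW = {
    101: VdwParams(3.82, 0.101), 102: VdwParams(4.005, 0.355),
    103: VdwParams(3.00, 0.0265, 0.98),
    111: VdwParams(3.82, 0.101), 112: VdwParams(3.71, 0.105),
    113: VdwParams(2.70, 0.020, 0.91),
    121: VdwParams(3.82, 0.101), 122: VdwParams(3.78, 0.106),
    123: VdwParams(3.51, 0.112), 124: VdwParams(2.65, 0.015, 0.91),
    131: VdwParams(3.82, 0.101), 132: VdwParams(3.71, 0.110),
    133: VdwParams(2.65, 0.015, 0.91), 134: VdwParams(3.80, 0.101),
    135: VdwParams(3.71, 0.110), 136: VdwParams(2.65, 0.015, 0.91),
}

# cap-carbon polarizabilities for atoms outside the interpolated site
_FRAGMENT_POLARIZE = {t: PolarizeParams(1.334, 0.39)
                      for t in (101, 111, 121, 131, 134)}
_FRAGMENT_POLARIZE.update({102: PolarizeParams(3.4, 0.39),
                           112: PolarizeParams(1.073, 0.39),
                           122: PolarizeParams(1.334, 0.39),
                           123: PolarizeParams(0.837, 0.39),
                           132: PolarizeParams(1.073, 0.39),
                           135: PolarizeParams(1.073, 0.39),
                           103: PolarizeParams(0.496, 0.39),
                           113: PolarizeParams(0.496, 0.39),
                           124: PolarizeParams(0.496, 0.39),
                           133: PolarizeParams(0.496, 0.39),
                           136: PolarizeParams(0.496, 0.39)})


def _fragment_ff(with_water: bool = False) -> ForceField:
    ff = water_forcefield() if with_water else ForceField()
    ff.vdw.update(_FRAGMENT_VDW)
    ff.polarize.update(_FRAGMENT_POLARIZE)
    ff.scales.update({"mpole-12-scale": 0.0, "mpole-13-scale": 0.0,
                      "mpole-14-scale": 0.4, "mpole-15-scale": 0.8,
                      "polar-12-scale": 0.0, "polar-13-scale": 0.0,
                      "polar-14-scale": 1.0,
                      "vdw-12-scale": 0.0, "vdw-13-scale": 0.0,
                      "vdw-14-scale": 1.0})
    # polarization groups: the titrating group is one unit, the cap carbon
    # its own, so the cap's permanent field induces dipoles on the site
    groups = {
        102: (103,), 103: (102,),
        112: (113,), 113: (112,),
        122: (123,), 123: (122, 124), 124: (123,),
        132: (133, 134), 133: (132,), 134: (132, 135),
        135: (134, 136), 136: (135,),
    }
    ff.polarize_group_types.update(groups)
    return ff


def _model_compound(spec: FixtureSpec) -> Fixture:
    """A titratable fragment plus two waters: the desk-scale analogue of a
    solvated capped model peptide.  The waters sit outside the fragment's
    bonded-mask range, so all nonbonded terms are exercised."""
    res = spec.residue.upper()
    if res not in _FRAGMENTS:
        raise ValueError(f"unknown model-compound residue '{spec.residue}'")
    atoms, rd = _FRAGMENTS[res](0, np.zeros(3))
    rng = np.random.default_rng(spec.seed)
    frag_pos = np.array([a.position for a in atoms])
    centroid = frag_pos.mean(axis=0)
    placed = []
    tries = 0
    while len(placed) < 2 and tries < 500:
        tries += 1
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        c = centroid + u * rng.uniform(4.2, 5.2)
        dmin = min(np.linalg.norm(frag_pos - c, axis=1).min(),
                   min((np.linalg.norm(p - c) for p in placed), default=99.0))
        if dmin > 3.0:
            placed.append(c)
    for c in placed:
        o = len(atoms)
        pos = _water_geometry(c, _random_rotation(rng))
        atoms.append(Atom(o, "O", 1, pos[0], [o + 1, o + 2]))
        atoms.append(Atom(o + 1, "H", 2, pos[1], [o]))
        atoms.append(Atom(o + 2, "H", 2, pos[2], [o]))
    ff = _fragment_ff(with_water=True)
    sites = build_titratable_sites(atoms, [rd])
    system = PolarizableSystem(atoms, ff, None, sites=sites)
    return Fixture(f"model-compound-{res}", system, spec)


def _site_placeholder_multipoles(atoms, sites):
    """Static multipoles for site atoms are never used (interpolation takes
    over), but the system needs a full list; supply zeros."""
    return [MultipoleSet(0.0, np.zeros(3), np.zeros((3, 3)))
            for _ in atoms]


def _dipeptide_crystal(spec: FixtureSpec) -> Fixture:
    """HIS-like imidazole hydrogen-bonded to a carboxylate in a small P1
    cell — a desk-scale analogue of a histidyl-aspartate crystal contact."""
    atoms_h, rd_h = _his_fragment(0, np.array([1.0, 1.2, 5.0]))
    # place the carboxylate so HE2...OD1 is a short polar contact
    atoms_a, rd_a = _carboxylate_fragment(6, np.array([8.3, 3.6, 5.0]),
                                          ResidueKind.ASP)
    # rotate the carboxylate to face the imidazole
    pivot = atoms_a[0].position.copy()
    Rz = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    for a in atoms_a:
        a.position = pivot + Rz @ (a.position - pivot)
    atoms = atoms_h + atoms_a
    ff = _fragment_ff()
    sites = build_titratable_sites(atoms, [rd_h, rd_a])
    mp = _site_placeholder_multipoles(atoms, sites)
    cell = CrystalCell(np.eye(3) * 11.5, ewald_beta=0.85, real_cutoff=5.1)
    system = PolarizableSystem(atoms, ff, cell, sites=sites, multipoles=mp)
    return Fixture("dipeptide-crystal-toy", system, spec)


def analytic_site(pKa_ref: float = 7.0,
                  model_bias: np.ndarray | None = None) -> PolarizableSystem:
    """An atom-free system with one two-state titratable site.

    With no atoms there is no nonbonded potential, and with U_mod = 0 the
    extended variable samples exactly the Henderson-Hasselbalch two-state
    free-energy surface set by the barrier and pH bias — the analytic
    reference for titration statistical mechanics.
    """
    from .model import TitratableSite
    site = TitratableSite(
        residue_kind=ResidueKind.LYS,
        lambda_index=0,
        zeta_index=None,
        atoms=[],
        titrating_hydrogens={},
        endstate_multipoles={"U": {}, "P": {}},
        endstate_polarizabilities={"U": {}, "P": {}},
        pKa_ref=pKa_ref,
        model_bias=(np.zeros(5) if model_bias is None
                    else np.asarray(model_bias, float)),
    )
    return PolarizableSystem([], ForceField(), None, sites=[site])


def standard_fixtures(seed: int = 1) -> list[Fixture]:
    """The gradient-oracle suite: every fixture kind plus all residues."""
    out = [
        make_fixture(FixtureSpec("diatomic-multipole", seed=seed)),
        make_fixture(FixtureSpec("water-box", n=4, seed=seed)),
        make_fixture(FixtureSpec("ionic-lattice", seed=seed)),
        make_fixture(FixtureSpec("dipeptide-crystal-toy", seed=seed)),
    ]
    for res in ("ASP", "GLU", "HIS", "LYS", "CYS"):
        out.append(make_fixture(FixtureSpec("model-compound", residue=res,
                                            seed=seed)))
    return out
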