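"""Domain data model: atoms, multipoles, force-field parameters, titratable
sites, periodic cells, and the extended (Cartesian + theta) dynamical state.

Conventions
-----------
* 0-based atom indices internally; file formats are 1-based.
* A titration variable ``lambda = sin^2(theta)`` is 1 for the protonated
  state and 0 for the deprotonated state.
* Tautomer variable ``zeta`` selects between two proton placements where a
  residue has them; the convention is ``zeta = 1`` selects the "1" side
  (histidine HE2 / carboxylate O1).
* Quadrupoles are stored as traceless symmetric Cartesian 3x3 matrices in
  e*A^2; the electrostatic energy operator is ``q + d.grad + (Q/3):gradgrad``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np


class Frame(Enum):
    """Local multipole frame conventions."""

    NONE = "none"
    Z_ONLY = "z-only"
    Z_THEN_X = "z-then-x"
    Z_BISECTOR = "z-then-bisector"
    BISECTOR = "bisector"
    TRISECTOR = "trisector"


@dataclass
class Atom:
    index: int
    name: str
    type_id: int
    position: np.ndarray
    bonded: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.index}: position must be a 3-vector")


@dataclass
class MultipoleSet:
    """Permanent multipole of one atom in its local frame.

    q in e, d in e*A, Q traceless symmetric in e*A^2.
    """

    q: float
    d: np.ndarray
    Q: np.ndarray
    frame: Frame = Frame.NONE
    frame_atoms: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float).reshape(3)
        Q = np.asarray(self.Q, dtype=float).reshape(3, 3)
        Q = 0.5 * (Q + Q.T)
        Q = Q - np.eye(3) * (np.trace(Q) / 3.0)  # enforce tracelessness
        self.Q = Q

    def as_vector(self) -> np.ndarray:
        """13-component vector (q, dx, dy, dz, Qxx..Qzz row-major)."""
        return np.concatenate(([self.q], self.d, self.Q.ravel()))

    @staticmethod
    def from_vector(v: np.ndarray, frame: Frame = Frame.NONE,
                    frame_atoms: tuple[int, ...] = ()) -> "MultipoleSet":
        v = np.asarray(v, dtype=float).reshape(13)
        return MultipoleSet(v[0], v[1:4], v[4:].reshape(3, 3), frame, frame_atoms)


@dataclass
class VdwParams:
    r_min: float            # minimum-energy separation, A
    epsilon: float          # well depth, kcal/mol
    reduction: float = 1.0  # hydrogen reduction factor in (0, 1]

    def __post_init__(self) -> None:
        if self.r_min <= 0:
            raise ValueError("vdw r_min must be positive")
        if self.epsilon < 0:
            raise ValueError("vdw epsilon must be non-negative")
        if not (0.0 < self.reduction <= 1.0):
            raise ValueError("vdw reduction factor must be in (0, 1]")


@dataclass
class PolarizeParams:
    alpha: float            # isotropic polarizability, A^3
    thole: float = 0.39     # Thole damping coefficient
    group: int = 0          # polarization-group id

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("polarizability must be non-negative")


class ResidueKind(Enum):
    ASP = "ASP"
    GLU = "GLU"
    HIS = "HIS"
    LYS = "LYS"
    CYS = "CYS"


#: residues whose tautomer variable exists (two proton placements)
TAUTOMERIC = {ResidueKind.ASP, ResidueKind.GLU, ResidueKind.HIS}


@dataclass
class TitratableSite:
    """One titrating residue: end-state parameters plus bias metadata.

    ``endstate_multipoles`` maps end-state label -> {atom index -> MultipoleSet}.
    End states are "U"/"P" for LYS and CYS, "U"/"P1"/"P2" for ASP and GLU
    (protonated tautomerism: the acidic proton may sit on either carboxylate
    oxygen), and "U1"/"U2"/"P" for HIS (neutral tautomerism between HIE =
    "U1", zeta = 1, and HID = "U2"; "P" is the doubly protonated HIP form).
    """

    residue_kind: ResidueKind
    lambda_index: int
    zeta_index: Optional[int]
    atoms: list[int]
    titrating_hydrogens: dict[int, int]  # atom index -> direction in {+1, -1, 0}
    endstate_multipoles: dict[str, dict[int, MultipoleSet]]
    endstate_polarizabilities: dict[str, dict[int, float]]
    pKa_ref: float
    model_bias: np.ndarray = field(default_factory=lambda: np.zeros(5))
    # HIS carries three PMFs: titration at zeta=1, at zeta=0, and tautomer
    model_bias_zeta0: Optional[np.ndarray] = None
    model_bias_tautomer: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        has_zeta = self.residue_kind in TAUTOMERIC
        if has_zeta and self.zeta_index is None:
            raise ValueError(f"{self.residue_kind.value} site requires a zeta index")
        if not has_zeta and self.zeta_index is not None:
            raise ValueError(
                f"{self.residue_kind.value} has no tautomer; zeta index not allowed")
        self._validate_frames()

    def _validate_frames(self) -> None:
        """All end states of an atom must share frame and frame atoms.

        Without a shared local frame the per-atom torque could not be
        accumulated once across end states.
        """
        states = list(self.endstate_multipoles)
        for i in self.atoms:
            defs = [self.endstate_multipoles[s][i] for s in states
                    if i in self.endstate_multipoles[s]]
            if not defs:
                continue
            f0, a0 = defs[0].frame, defs[0].frame_atoms
            for m in defs[1:]:
                if m.frame != f0 or m.frame_atoms != a0:
                    raise ValueError(
                        f"atom {i}: local-frame convention and frame atoms must be "
                        f"identical for all protonation end states "
                        f"(got {m.frame}/{m.frame_atoms} vs {f0}/{a0})")

    @property
    def expected_states(self) -> tuple[str, ...]:
        if self.residue_kind in (ResidueKind.LYS, ResidueKind.CYS):
            return ("U", "P")
        if self.residue_kind is ResidueKind.HIS:
            return ("U1", "U2", "P")
        return ("U", "P1", "P2")


@dataclass
class CrystalCell:
    """Triclinic periodic cell plus Ewald/PME controls.

    ``lattice`` rows are the cell vectors a, b, c (A).
    """

    lattice: np.ndarray
    ewald_beta: float = 0.545
    real_cutoff: float = 7.0
    grid: tuple[int, int, int] = (0, 0, 0)  # 0 -> choose from spacing
    spline_order: int = 5

    def __post_init__(self) -> None:
        L = np.asarray(self.lattice, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(L)) < 1e-10:
            raise ValueError("cell lattice is singular")
        self.lattice = L
        if self.real_cutoff > 0.5 * self.min_width() + 1e-9:
            raise ValueError(
                f"real-space cutoff {self.real_cutoff} A exceeds half the minimum "
                f"cell width {0.5 * self.min_width():.3f} A (minimum image unsafe)")

    @staticmethod
    def from_params(a: float, b: float, c: float,
                    alpha: float = 90.0, beta: float = 90.0, gamma: float = 90.0,
                    **kw) -> "CrystalCell":
        al, be, ga = np.radians([alpha, beta, gamma])
        va = np.array([a, 0.0, 0.0])
        vb = np.array([b * np.cos(ga), b * np.sin(ga), 0.0])
        cx = np.cos(be)
        cy = (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz = np.sqrt(max(1.0 - cx * cx - cy * cy, 0.0))
        vc = c * np.array([cx, cy, cz])
        return CrystalCell(np.array([va, vb, vc]), **kw)

    @property
    def volume(self) -> float:
        return abs(np.linalg.det(self.lattice))

    @property
    def reciprocal(self) -> np.ndarray:
        """Rows are reciprocal vectors (no 2*pi): recip @ lattice.T = I."""
        return np.linalg.inv(self.lattice).T

    def min_width(self) -> float:
        """Smallest perpendicular width of the cell (minimum-image bound)."""
        rec = self.reciprocal
        return float(min(1.0 / np.linalg.norm(rec[i]) for i in range(3)))

    def cell_params(self) -> tuple[float, float, float, float, float, float]:
        a, b, c = (np.linalg.norm(self.lattice[i]) for i in range(3))
        va, vb, vc = self.lattice
        al = np.degrees(np.arccos(np.dot(vb, vc) / (b * c)))
        be = np.degrees(np.arccos(np.dot(va, vc) / (a * c)))
        ga = np.degrees(np.arccos(np.dot(va, vb) / (a * b)))
        return float(a), float(b), float(c), float(al), float(be), float(ga)

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Wrap displacement vectors (..., 3) to the nearest image."""
        frac = dr @ self.reciprocal.T
        frac -= np.round(frac)
        return frac @ self.lattice


@dataclass
class ExtendedState:
    """Cartesian coordinates/velocities plus the extended theta vector.

    ``lambda_k = sin^2(theta_k)``, guaranteeing lambda in [0, 1] for any
    theta excursion without reflecting walls.
    """

    X: np.ndarray
    V: np.ndarray
    theta: np.ndarray
    theta_velocity: np.ndarray
    theta_mass: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float).reshape(-1, 3)
        self.V = np.asarray(self.V, float).reshape(self.X.shape)
        self.theta = np.atleast_1d(np.asarray(self.theta, float))
        self.theta_velocity = np.asarray(self.theta_velocity, float).reshape(
            self.theta.shape)
        self.theta_mass = np.asarray(self.theta_mass, float).reshape(self.theta.shape)

    @property
    def lam(self) -> np.ndarray:
        """sin^2(theta), the titration/tautomer values in [0, 1]."""
        return np.sin(self.theta) ** 2

    def dlam_dtheta(self) -> np.ndarray:
        return 2.0 * np.sin(self.theta) * np.cos(self.theta)

    @staticmethod
    def theta_of(lam: np.ndarray | float) -> np.ndarray:
        """Inverse mapping: a theta in [0, pi/2] with sin^2(theta) = lam."""
        return np.arcsin(np.sqrt(np.clip(lam, 0.0, 1.0)))

    def copy(self) -> "ExtendedState":
        return ExtendedState(self.X.copy(), self.V.copy(), self.theta.copy(),
                             self.theta_velocity.copy(), self.theta_mass.copy())


@dataclass
class TitrationRecord:
    """Per-site time series of (step, lambda, zeta) at one ensemble pH."""

    pH: float
    steps: list[int] = field(default_factory=list)
    lam: dict[int, list[float]] = field(default_factory=dict)   # site -> series
    zeta: dict[int, list[float]] = field(default_factory=dict)

    def append(self, step: int, lam_by_site: dict[int, float],
               zeta_by_site: dict[int, float]) -> None:
        for s, v in lam_by_site.items():
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError(f"lambda out of [0,1]: {v}")
        self.steps.append(step)
        for s, v in lam_by_site.items():
            self.lam.setdefault(s, []).append(float(v))
        for s, v in zeta_by_site.items():
            self.zeta.setdefault(s, []).append(float(v))

    @property
    def n_samples(self) -> int:
        return len(self.steps)
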