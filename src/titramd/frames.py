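"""Local multipole frames: rotation matrices, their analytic derivatives
with respect to frame-atom positions, and torque-to-force conversion.

The rotation matrix R has the global directions of the local x, y, z axes
as its columns, so a local moment maps to the global frame as d_g = R d_l
and Q_g = R Q_l R^T.  Because R depends on atom positions, moving a
frame-defining atom rotates the moment; the chain rule through dR/dx is
what turns electrostatic torques into forces on the frame atoms.
"""

from __future__ import annotations

import numpy as np

from .model import Frame, MultipoleSet
from .tensors import _EPSILON


class FrameError(ValueError):
    pass


class _Vec:
    """A 3-vector with jacobians w.r.t. a set of position slots."""

    __slots__ = ("v", "jac")

    def __init__(self, v, jac=None):
        self.v = np.asarray(v, float)
        self.jac = jac or {}   # slot -> (3,3), jac[a, c] = d v_a / d x_c

    def __add__(self, other):
        jac = {s: J.copy() for s, J in self.jac.items()}
        for s, J in other.jac.items():
            jac[s] = jac.get(s, 0.0) + J
        return _Vec(self.v + other.v, jac)

    def __sub__(self, other):
        jac = {s: J.copy() for s, J in self.jac.items()}
        for s, J in other.jac.items():
            jac[s] = jac.get(s, 0.0) - J
        return _Vec(self.v - other.v, jac)

    def scaled(self, c: float):
        return _Vec(self.v * c, {s: J * c for s, J in self.jac.items()})

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.v))

    def normalized(self):
        n = self.norm
        if n < 1e-10:
            raise FrameError("degenerate frame geometry: zero-length axis")
        u = self.v / n
        D = (np.eye(3) - np.outer(u, u)) / n
        return _Vec(u, {s: D @ J for s, J in self.jac.items()})

    def perp_to(self, z: "_Vec"):
        """Component perpendicular to the unit vector z (z assumed unit)."""
        dot = float(self.v @ z.v)
        val = self.v - dot * z.v
        jac = {}
        slots = set(self.jac) | set(z.jac)
        for s in slots:
            J = np.zeros((3, 3))
            if s in self.jac:
                Jv = self.jac[s]
                J += Jv - np.outer(z.v, z.v @ Jv)
            if s in z.jac:
                Jz = z.jac[s]
                J += -np.outer(z.v, self.v @ Jz) - dot * Jz
            jac[s] = J
        return _Vec(val, jac)

    def cross(self, other: "_Vec"):
        val = np.cross(self.v, other.v)
        jac = {}
        for s in set(self.jac) | set(other.jac):
            J = np.zeros((3, 3))
            if s in self.jac:
                J += np.einsum("abc,bk,c->ak", _EPSILON, self.jac[s], other.v)
            if s in other.jac:
                J += np.einsum("abc,b,ck->ak", _EPSILON, self.v, other.jac[s])
            jac[s] = J
        return _Vec(val, jac)


def _rel(positions: np.ndarray, owner: int, other: int) -> _Vec:
    v = positions[other] - positions[owner]
    return _Vec(v, {other: np.eye(3), owner: -np.eye(3)})


_FALLBACK_AXES = np.eye(3)


def frame_rotation(frame: Frame, owner: int, frame_atoms: tuple[int, ...],
                   positions: np.ndarray, derivatives: bool = False):
    """Rotation matrix (and optionally dR/dx per involved atom).

    Returns (R, dR) where dR maps atom index -> (3, 3, 3) array with
    dR[atom][a, b, c] = d R_{ab} / d x_c(atom).  dR is None when
    derivatives is False.
    """
    if frame is Frame.NONE:
        return np.eye(3), ({} if derivatives else None)

    try:
        if frame is Frame.Z_ONLY:
            z = _rel(positions, owner, frame_atoms[0]).normalized()
            # deterministic perpendicular reference: least-aligned lab axis
            k = int(np.argmin(np.abs(z.v)))
            ref = _Vec(_FALLBACK_AXES[k])
            x = ref.perp_to(z).normalized()
        elif frame is Frame.Z_THEN_X:
            z = _rel(positions, owner, frame_atoms[0]).normalized()
            x = _rel(positions, owner, frame_atoms[1]).perp_to(z).normalized()
        elif frame is Frame.BISECTOR:
            u1 = _rel(positions, owner, frame_atoms[0]).normalized()
            u2 = _rel(positions, owner, frame_atoms[1]).normalized()
            z = (u1 + u2).normalized()
            x = _rel(positions, owner, frame_atoms[0]).perp_to(z).normalized()
        elif frame is Frame.Z_BISECTOR:
            z = _rel(positions, owner, frame_atoms[0]).normalized()
            u1 = _rel(positions, owner, frame_atoms[1]).normalized()
            u2 = _rel(positions, owner, frame_atoms[2]).normalized()
            x = (u1 + u2).perp_to(z).normalized()
        elif frame is Frame.TRISECTOR:
            u1 = _rel(positions, owner, frame_atoms[0]).normalized()
            u2 = _rel(positions, owner, frame_atoms[1]).normalized()
            u3 = _rel(positions, owner, frame_atoms[2]).normalized()
            z = (u1 + u2 + u3).normalized()
            x = _rel(positions, owner, frame_atoms[0]).perp_to(z).normalized()
        else:  # pragma: no cover
            raise FrameError(f"unsupported frame {frame}")
    except FrameError as e:
        raise FrameError(f"atom {owner} frame {frame.value} with atoms "
                         f"{frame_atoms}: {e}") from None

    y = z.cross(x)
    R = np.column_stack([x.v, y.v, z.v])
    if not derivatives:
        return R, None
    slots = set(x.jac) | set(y.jac) | set(z.jac)
    dR = {}
    for s in slots:
        d = np.zeros((3, 3, 3))
        if s in x.jac:
            d[:, 0, :] = x.jac[s]
        if s in y.jac:
            d[:, 1, :] = y.jac[s]
        if s in z.jac:
            d[:, 2, :] = z.jac[s]
        dR[s] = d
    return R, dR


def rotate_moments(m: MultipoleSet, R: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """(q, d_global, Q_global) of a local multipole under R."""
    return m.q, R @ m.d, R @ m.Q @ R.T


def rotate_vector_set(q, d, Q, R):
    """Rotate raw component arrays (used for moment derivatives too)."""
    return q, R @ d, R @ Q @ R.T


def torque_frame_forces(torque: np.ndarray, frame: Frame, owner: int,
                        frame_atoms: tuple[int, ...],
                        positions: np.ndarray) -> dict[int, np.ndarray]:
    """Convert a torque on one multipole into forces on its frame atoms.

    The torque is tau = dU/d(eps) for an infinitesimal rotation eps of the
    global moments.  Any admissible variation of R under atomic motion is a
    rotation (R stays orthonormal), generated by
    eps(dx) = axial(dR R^T), so the force contribution on a frame atom is
    F_c = -tau . d eps / d x_c.  Returns atom -> force increment; the
    increments sum (with the pair forces) to a translation-invariant total.
    """
    if frame is Frame.NONE:
        return {}
    R, dR = frame_rotation(frame, owner, frame_atoms, positions,
                           derivatives=True)
    out = {}
    for s, d in dR.items():
        # W_c = dR/dx_c @ R^T  (antisymmetric); eps_e = -(1/2) eps_{eab} W_ab
        W = np.einsum("abc,db->adc", d, R)   # W[a, d, c] = dR_ab/dx_c R_db
        deps = -0.5 * np.einsum("eab,abc->ec", _EPSILON, W)
        out[s] = -(torque @ deps)
    return out
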