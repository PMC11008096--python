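"""System assembly: per-atom parameters, masking matrices, polarization
groups, and evaluation of the titration-state-dependent parameter set.

`PolarizableSystem` is the object the energy modules consume.  Its
`interpolate_state` method turns a vector of extended variables into
global-frame moments, their per-variable derivatives, polarizabilities and
van der Waals scale factors — everything downstream is a function of that
`StateParams` bundle plus positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .frames import frame_rotation, torque_frame_forces
from .interpolation import (effective_damping_alpha, interpolate_multipole,
                            interpolate_polarizability, vdw_scale)
from .io import ForceField
from .model import (Atom, CrystalCell, Frame, MultipoleSet, PolarizeParams,
                    TitratableSite, VdwParams)
from .tensors import Moments


# ---------------------------------------------------------------------------
# Frame-atom resolution against connectivity

def assign_multipoles(atoms: list[Atom], ff: ForceField) -> list[MultipoleSet]:
    """Resolve each atom's multipole block and frame atoms from connectivity."""
    out: list[MultipoleSet] = []
    for a in atoms:
        blocks = ff.multipoles.get(a.type_id)
        if not blocks:
            out.append(MultipoleSet(0.0, np.zeros(3), np.zeros((3, 3))))
            continue
        resolved = None
        for blk in blocks:
            fa = _match_frame_atoms(a, blk.frame, blk.frame_types, atoms)
            if fa is not None:
                m = blk.moments
                resolved = MultipoleSet(m.q, m.d.copy(), m.Q.copy(),
                                        blk.frame, fa)
                break
        if resolved is None:
            raise ValueError(
                f"atom {a.index} ({a.name}, type {a.type_id}): no multipole "
                f"frame definition matches its connectivity")
        out.append(resolved)
    return out


def _match_frame_atoms(a: Atom, frame: Frame, ftypes: tuple[int, ...],
                       atoms: list[Atom]) -> Optional[tuple[int, ...]]:
    if frame is Frame.NONE:
        return ()
    neigh = [atoms[j] for j in a.bonded]

    def pick(types: list[int], pool: list[Atom]) -> Optional[list[int]]:
        chosen: list[int] = []
        avail = list(pool)
        for t in types:
            hit = next((x for x in avail if x.type_id == t), None)
            if hit is None:
                return None
            chosen.append(hit.index)
            avail.remove(hit)
        return chosen

    if frame in (Frame.Z_ONLY,):
        got = pick(list(ftypes), neigh)
        return tuple(got) if got else None
    if frame is Frame.Z_THEN_X:
        zt, xt = ftypes
        for z in [x for x in neigh if x.type_id == zt]:
            # x-atom: another direct neighbor, else a neighbor of the z atom
            cands = [x for x in neigh if x.index != z.index] + \
                    [atoms[j] for j in z.bonded if j != a.index]
            hit = next((x for x in cands if x.type_id == xt), None)
            if hit is not None:
                return (z.index, hit.index)
        return None
    if frame is Frame.BISECTOR:
        got = pick(list(ftypes), neigh)
        return tuple(got) if got else None
    if frame in (Frame.Z_BISECTOR, Frame.TRISECTOR):
        got = pick(list(ftypes), neigh)
        return tuple(got) if got else None
    return None


# ---------------------------------------------------------------------------
# Bonded-path masks

def bonded_path_orders(atoms: list[Atom], max_order: int = 4) -> np.ndarray:
    """n x n matrix of bond-path separations (1 = bonded, ...), clipped at
    max_order + 1; diagonal 0."""
    n = len(atoms)
    sep = np.full((n, n), max_order + 1, dtype=np.int8)
    np.fill_diagonal(sep, 0)
    for a in atoms:
        frontier = {a.index}
        seen = {a.index}
        for depth in range(1, max_order + 1):
            nxt = set()
            for i in frontier:
                for j in atoms[i].bonded:
                    if j not in seen:
                        nxt.add(j)
                        seen.add(j)
                        sep[a.index, j] = min(sep[a.index, j], depth)
            frontier = nxt
    return sep


def polarization_groups(atoms: list[Atom], ff: ForceField) -> np.ndarray:
    """Group id per atom: connected components over bonds whose two atom
    types list each other in their polarize group definitions."""
    n = len(atoms)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in atoms:
        gts = ff.polarize_group_types.get(a.type_id, ())
        for j in a.bonded:
            if atoms[j].type_id in gts:
                ri, rj = find(a.index), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = [find(i) for i in range(n)]
    ids = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    return np.array([ids[r] for r in roots])


# ---------------------------------------------------------------------------
# State bundle

@dataclass
class StateParams:
    """Interpolated, global-frame parameters at one extended-variable state."""

    moments: Moments                       # global frame
    dmoments: dict[int, Moments]           # per extended variable k
    alpha: np.ndarray
    dalpha: dict[int, np.ndarray]
    vdw_factor: np.ndarray                 # per-atom f(lambda, zeta)
    dvdw: dict[int, np.ndarray]
    rotations: list[np.ndarray]
    q_total: float
    dq_total: dict[int, float]


class PolarizableSystem:
    def __init__(self, atoms: list[Atom], ff: ForceField,
                 cell: Optional[CrystalCell] = None,
                 sites: Optional[list[TitratableSite]] = None,
                 multipoles: Optional[list[MultipoleSet]] = None):
        self.atoms = atoms
        self.ff = ff
        self.cell = cell
        self.sites = sites or []
        self.n = len(atoms)
        self.static_multipoles = (multipoles if multipoles is not None
                                  else assign_multipoles(atoms, ff))

        self.vdw_params = [ff.vdw.get(a.type_id, VdwParams(1.0, 0.0))
                           for a in atoms]
        self.polarize_params = [ff.polarize.get(a.type_id,
                                                PolarizeParams(0.0, 0.39))
                                for a in atoms]

        # extended-variable bookkeeping
        self.n_ext = 0
        self._site_of_atom: dict[int, TitratableSite] = {}
        for s in self.sites:
            self.n_ext = max(self.n_ext, s.lambda_index + 1)
            if s.zeta_index is not None:
                self.n_ext = max(self.n_ext, s.zeta_index + 1)
            for i in s.atoms:
                self._site_of_atom[i] = s

        sep = bonded_path_orders(atoms)
        m12, m13, m14, m15 = ff.mpole_scales()
        v12, v13, v14 = ff.vdw_scales()
        p12, p13, p14 = ff.polar_scales()
        self.mscale = np.ones((self.n, self.n))
        self.vscale = np.ones((self.n, self.n))
        self.pscale = np.ones((self.n, self.n))
        for order, mv, vv, pv in ((1, m12, v12, p12), (2, m13, v13, p13),
                                  (3, m14, v14, p14), (4, m15, 1.0, 1.0)):
            mask = sep == order
            self.mscale[mask] = mv
            self.vscale[mask] = vv
            self.pscale[mask] = pv
        np.fill_diagonal(self.mscale, 0.0)
        np.fill_diagonal(self.vscale, 0.0)
        np.fill_diagonal(self.pscale, 0.0)

        groups = polarization_groups(atoms, ff)
        self.groups = groups
        self.dscale = np.where(groups[:, None] == groups[None, :], 0.0, 1.0)
        self.uscale = np.ones((self.n, self.n))
        np.fill_diagonal(self.uscale, 0.0)

        # frozen Thole damping widths (fixed charge-density approximation)
        eff = np.array([
            effective_damping_alpha(self._site_of_atom.get(i), i,
                                    self.polarize_params[i].alpha)
            for i in range(self.n)])
        self.damping_alpha = eff
        self.thole_a = min((p.thole for p in self.polarize_params
                            if p.alpha > 0), default=0.39)

        self.positions = np.array([a.position for a in atoms], float) \
            if self.n else np.zeros((0, 3))

    # -- state values ------------------------------------------------------
    def site_state(self, ext: np.ndarray, site: TitratableSite):
        lam = float(ext[site.lambda_index])
        zeta = (float(ext[site.zeta_index])
                if site.zeta_index is not None else None)
        return lam, zeta

    # -- interpolation -----------------------------------------------------
    def interpolate_state(self, positions: np.ndarray,
                          ext: np.ndarray) -> StateParams:
        n = self.n
        q = np.empty(n)
        d_loc = np.empty((n, 3))
        Q_loc = np.empty((n, 3, 3))
        alpha = np.empty(n)
        vf = np.ones(n)
        dM: dict[int, np.ndarray] = {}
        dA: dict[int, np.ndarray] = {}
        dV: dict[int, np.ndarray] = {}
        frames: list[tuple[Frame, tuple[int, ...]]] = []

        for i in range(n):
            site = self._site_of_atom.get(i)
            if site is None:
                m = self.static_multipoles[i]
                q[i], d_loc[i], Q_loc[i] = m.q, m.d, m.Q
                alpha[i] = self.polarize_params[i].alpha
                frames.append((m.frame, m.frame_atoms))
            else:
                lam, zeta = self.site_state(ext, site)
                M, Md, Mz = interpolate_multipole(site, i, lam, zeta)
                a, ad, az = interpolate_polarizability(site, i, lam, zeta)
                f, fd, fz = vdw_scale(site, i, lam, zeta)
                q[i], d_loc[i], Q_loc[i] = M[0], M[1:4], M[4:].reshape(3, 3)
                alpha[i] = a
                vf[i] = f
                ref = site.endstate_multipoles[site.expected_states[0]][i]
                frames.append((ref.frame, ref.frame_atoms))
                for k, Mk, ak, fk in ((site.lambda_index, Md, ad, fd),
                                      (site.zeta_index, Mz, az, fz)):
                    if k is None:
                        continue
                    dM.setdefault(k, np.zeros((n, 13)))[i] = Mk
                    dA.setdefault(k, np.zeros(n))[i] = ak
                    dV.setdefault(k, np.zeros(n))[i] = fk

        # rotate local moments (and their derivatives) to the global frame
        rotations = []
        d_glob = np.empty((n, 3))
        Q_glob = np.empty((n, 3, 3))
        for i in range(n):
            fr, fa = frames[i]
            R, _ = frame_rotation(fr, i, fa, positions)
            rotations.append(R)
            d_glob[i] = R @ d_loc[i]
            Q_glob[i] = R @ Q_loc[i] @ R.T

        dmom: dict[int, Moments] = {}
        for k, arr in dM.items():
            dq = arr[:, 0]
            dd = np.empty((n, 3))
            dQ = np.empty((n, 3, 3))
            for i in range(n):
                R = rotations[i]
                dd[i] = R @ arr[i, 1:4]
                dQ[i] = R @ arr[i, 4:].reshape(3, 3) @ R.T
            dmom[k] = Moments(dq, dd, dQ)

        self._frames = frames
        return StateParams(
            moments=Moments(q, d_glob, Q_glob),
            dmoments=dmom,
            alpha=alpha,
            dalpha=dA,
            vdw_factor=vf,
            dvdw=dV,
            rotations=rotations,
            q_total=float(q.sum()),
            dq_total={k: float(m.m0.sum()) for k, m in dmom.items()},
        )

    def distribute_torques(self, torques: np.ndarray,
                           positions: np.ndarray) -> np.ndarray:
        """Convert per-atom torques into frame-atom force increments.

        Total force and total torque about any origin are conserved.
        """
        forces = np.zeros_like(positions)
        for i in range(self.n):
            tau = torques[i]
            if not np.any(tau):
                continue
            fr, fa = self._frames[i]
            for a, f in torque_frame_forces(tau, fr, i, fa, positions).items():
                forces[a] += f
        return forces

    # -- geometry ----------------------------------------------------------
    def pair_list(self, positions: np.ndarray,
                  cutoff: Optional[float] = None):
        """All i<j pairs (minimum image when periodic), optionally cut off.

        Returns (ii, jj, dr, r) with dr = r_i - r_j wrapped to the nearest
        image.
        """
        n = self.n
        ii, jj = np.triu_indices(n, k=1)
        dr = positions[ii] - positions[jj]
        if self.cell is not None:
            dr = self.cell.minimum_image(dr)
        r = np.linalg.norm(dr, axis=1)
        if cutoff is not None:
            keep = r < cutoff
            ii, jj, dr, r = ii[keep], jj[keep], dr[keep], r[keep]
        return ii, jj, dr, r
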