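"""Smooth particle-mesh Ewald for point multipoles.

Charge, dipole and quadrupole sources are spread onto a regular grid with
cardinal B-splines (including the spline derivatives the dipole/quadrupole
sources require), convolved with the Ewald influence function via FFT, and
the resulting potential (with derivatives up to third order) is
interpolated back at every atom site.  The interface mirrors the direct
k-space summation backend (`KsumRecip`), which serves as its oracle.
"""

from __future__ import annotations

import numpy as np

from .model import CrystalCell
from .tensors import Moments


def bspline(order: int, u: np.ndarray) -> np.ndarray:
    """Cardinal B-spline M_order evaluated at u (support (0, order))."""
    if order == 1:
        return np.where((u >= 0) & (u < 1.0), 1.0, 0.0)
    lower = bspline(order - 1, u)
    shifted = bspline(order - 1, u - 1.0)
    return (u * lower + (order - u) * shifted) / (order - 1)


def bspline_derivs(order: int, u: np.ndarray, nderiv: int) -> list[np.ndarray]:
    """[M, M', M'', ...] via M_n^(k)(u) = sum_j (-1)^j C(k,j) M_{n-k}(u - j)."""
    from math import comb
    out = [bspline(order, u)]
    for k in range(1, nderiv + 1):
        acc = np.zeros_like(u)
        for j in range(k + 1):
            acc += (-1) ** j * comb(k, j) * bspline(order - k, u - j)
        out.append(acc)
    return out


class PmeRecip:
    """Reciprocal-space evaluator on a B-spline mesh."""

    def __init__(self, cell: CrystalCell, beta: float,
                 grid: tuple[int, int, int] = (0, 0, 0), order: int = 5,
                 spacing: float = 1.0):
        self.cell = cell
        self.beta = beta
        self.order = order
        dims = []
        for i in range(3):
            k = grid[i] if grid[i] else int(np.ceil(
                np.linalg.norm(cell.lattice[i]) / spacing))
            k = max(k, 2 * order)
            dims.append(_good_fft_size(k))
        self.dims = tuple(dims)
        self._influence = self._build_influence()

    def _build_influence(self) -> np.ndarray:
        K1, K2, K3 = self.dims
        V = self.cell.volume
        rec = self.cell.reciprocal  # rows, no 2*pi
        m1 = np.fft.fftfreq(K1, 1.0 / K1)
        m2 = np.fft.fftfreq(K2, 1.0 / K2)
        m3 = np.fft.fftfreq(K3, 1.0 / K3)
        M1, M2, M3 = np.meshgrid(m1, m2, m3, indexing="ij")
        mvec = (M1[..., None] * rec[0] + M2[..., None] * rec[1]
                + M3[..., None] * rec[2])
        msq = np.einsum("...a,...a->...", mvec, mvec)
        with np.errstate(divide="ignore", invalid="ignore"):
            C = np.exp(-np.pi ** 2 * msq / self.beta ** 2) / (np.pi * V * msq)
        C[0, 0, 0] = 0.0

        B = np.ones(self.dims)
        for axis, K in enumerate(self.dims):
            m = np.fft.fftfreq(K, 1.0 / K)
            k = np.arange(self.order - 1)
            Mn = bspline(self.order, k + 1.0)
            denom = Mn @ np.exp(2j * np.pi * np.outer(k, m) / K)
            mag = np.abs(denom) ** 2
            with np.errstate(divide="ignore"):
                bi = np.where(mag > 1e-10, 1.0 / np.where(mag > 1e-10, mag, 1.0),
                              0.0)
            shape = [1, 1, 1]
            shape[axis] = K
            B = B * bi.reshape(shape)
        return C * B

    # -- spreading ---------------------------------------------------------
    def _spline_tables(self, positions: np.ndarray, nderiv: int):
        """Per-atom spline weights and grid support indices.

        Returns (idx[3] lists of (n, order) int arrays,
                 w[3] lists of [(n, order)] arrays per derivative level),
        with derivatives already scaled by the grid factor K (derivative
        w.r.t. the fractional coordinate s, not the grid coordinate u).
        """
        frac = positions @ self.cell.reciprocal.T
        frac -= np.floor(frac)
        idx, wts = [], []
        for axis, K in enumerate(self.dims):
            u = frac[:, axis] * K
            base = np.floor(u).astype(int)
            offs = np.arange(self.order)
            grid_idx = (base[:, None] - offs[None, :]) % K
            uu = u[:, None] - (base[:, None] - offs[None, :])
            dv = bspline_derivs(self.order, uu, nderiv)
            dv = [d * K ** p for p, d in enumerate(dv)]
            idx.append(grid_idx)
            wts.append(dv)
        return idx, wts

    def _frac_moments(self, src: Moments):
        """Moments converted to fractional-derivative coefficients."""
        A = self.cell.reciprocal  # ds_u/dr_a = A[u, a]
        d_f = src.m1 @ A.T
        m2_f = np.einsum("ua,pab,vb->puv", A, src.m2, A)
        return src.m0, d_f, m2_f

    def spread(self, positions: np.ndarray, src: Moments) -> np.ndarray:
        """Populate the source grid Q with splined multipoles."""
        q, d_f, m2_f = self._frac_moments(src)
        idx, wts = self._spline_tables(positions, 2)
        Q = np.zeros(self.dims)
        n = len(q)
        for j in range(n):
            w = [[wts[ax][p][j] for p in range(3)] for ax in range(3)]
            # coefficient field: q W + d.grad_j W + m2 : grad_j grad_j W
            # (derivatives w.r.t. the atom position; the dipole density
            #  -d.grad_r delta flips sign through grad_r -> -grad_j)
            c = q[j] * _outer3(w[0][0], w[1][0], w[2][0])
            for u in range(3):
                c += d_f[j, u] * _outer3(*_pick(w, u, 1))
            for u in range(3):
                for v in range(3):
                    if u == v:
                        c += m2_f[j, u, u] * _outer3(*_pick(w, u, 2))
                    else:
                        c += m2_f[j, u, v] * _outer3(*_pick2(w, u, v))
            np.add.at(Q, np.ix_(idx[0][j], idx[1][j], idx[2][j]), c)
        return Q

    # -- evaluation --------------------------------------------------------
    def potential_grid(self, Q: np.ndarray) -> np.ndarray:
        return np.real(np.fft.ifftn(np.fft.fftn(Q) * self._influence)) \
            * np.prod(self.dims)

    def stacks(self, positions: np.ndarray, src: Moments,
               order: int) -> list[np.ndarray]:
        """Per-site reciprocal potential stack [phi, grad phi, ...]."""
        Q = self.spread(positions, src)
        phi = self.potential_grid(Q)
        idx, wts = self._spline_tables(positions, order)
        A = self.cell.reciprocal
        n = positions.shape[0]
        out = [np.zeros((n,) + (3,) * m) for m in range(order + 1)]
        for j in range(n):
            w = [[wts[ax][p][j] for p in range(order + 1)] for ax in range(3)]
            block = phi[np.ix_(idx[0][j], idx[1][j], idx[2][j])]
            for m in range(order + 1):
                for uidx in np.ndindex(*(3,) * m):
                    degs = [0, 0, 0]
                    for u in uidx:
                        degs[u] += 1
                    val = np.sum(block * _outer3(w[0][degs[0]], w[1][degs[1]],
                                                 w[2][degs[2]]))
                    # fractional -> Cartesian: multiply A factors
                    out[m][(j,) + uidx] += val
            # convert mixed fractional derivatives to Cartesian
        return self._to_cartesian(out, A)

    def _to_cartesian(self, stacks_frac, A):
        out = [stacks_frac[0]]
        for m in range(1, len(stacks_frac)):
            t = stacks_frac[m]
            for ax in range(m):
                t = np.tensordot(t, A, axes=([1], [0]))
            out.append(t)
        return out

    def energy(self, positions: np.ndarray, src: Moments) -> float:
        Q = self.spread(positions, src)
        phi = self.potential_grid(Q)
        return 0.5 * float(np.sum(Q * phi))


def _good_fft_size(k: int) -> int:
    while True:
        m = k
        for p in (2, 3, 5):
            while m % p == 0:
                m //= p
        if m == 1:
            return k
        k += 1


def _outer3(a, b, c):
    return a[:, None, None] * b[None, :, None] * c[None, None, :]


def _pick(w, u, deg):
    """Spline triples with derivative `deg` on axis u."""
    return tuple(w[ax][deg if ax == u else 0] for ax in range(3))


def _pick2(w, u, v):
    return tuple(w[ax][(1 if ax == u else 0) + (1 if ax == v else 0)]
                 for ax in range(3))
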