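"""Cartesian interaction tensors for point multipoles.

The pair interaction between two multipole sites is written with the
operator convention

    U_ij = L_i L_j g(r),   L_i = q_i + d_i . grad_i + (Q_i/3) : grad_i grad_i

with r = r_i - r_j, so grad_i = +grad_r and grad_j = -grad_r (each
derivative on the j side contributes a factor -1).

The rank-n tensor T^(n) = grad^n g(r) is generated once, symbolically, as a
sum of monomial terms  c * x^p y^q z^s * B_k(r)  where the radial sequence
obeys B_{k+1} = -(1/r) dB_k/dr.  Supplying different B sequences yields the
bare Coulomb, Ewald real-space (erfc), and Thole-damped kernels from the
same tensor expressions.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import combinations_with_replacement

import numpy as np
from scipy.special import erfc

MAX_RANK = 5

# ---------------------------------------------------------------------------
# Symbolic generation of T^(n) term lists

# term representation: {(px, py, pz, k): coeff}
_Term = dict


def _differentiate(terms: _Term, axis: int) -> _Term:
    out: _Term = defaultdict(float)
    for (px, py, pz, k), c in terms.items():
        p = [px, py, pz]
        # monomial derivative
        if p[axis] > 0:
            p2 = list(p)
            p2[axis] -= 1
            out[(p2[0], p2[1], p2[2], k)] += c * p[axis]
        # radial derivative: d/dx_a B_k = -x_a B_{k+1}
        p3 = list(p)
        p3[axis] += 1
        out[(p3[0], p3[1], p3[2], k + 1)] -= c
    return {key: v for key, v in out.items() if v != 0.0}


def _build_term_lists(max_rank: int):
    """term_lists[n] maps a sorted multi-index tuple -> term dict."""
    lists = [{(): {(0, 0, 0, 0): 1.0}}]
    for n in range(1, max_rank + 1):
        prev = lists[n - 1]
        cur = {}
        for idx in combinations_with_replacement(range(3), n):
            # differentiate the parent component (drop first axis)
            parent = idx[1:]
            cur[idx] = _differentiate(prev[parent], idx[0])
        lists.append(cur)
    return lists


_TERM_LISTS = _build_term_lists(MAX_RANK)


def t_tensor(rank: int, dr: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Evaluate T^(rank) for P displacement vectors.

    dr: (P, 3); B: (P, >= rank+1) radial sequence.  Returns (P, 3, ..., 3).
    """
    P = dr.shape[0]
    x, y, z = dr[:, 0], dr[:, 1], dr[:, 2]
    # monomial cache
    powcache: dict[tuple[int, int, int], np.ndarray] = {}

    def mono(px, py, pz):
        key = (px, py, pz)
        if key not in powcache:
            m = np.ones(P)
            if px:
                m = m * x ** px
            if py:
                m = m * y ** py
            if pz:
                m = m * z ** pz
            powcache[key] = m
        return powcache[key]

    out = np.zeros((P,) + (3,) * rank)
    for idx, terms in _TERM_LISTS[rank].items():
        val = np.zeros(P)
        for (px, py, pz, k), c in terms.items():
            val += c * mono(px, py, pz) * B[:, k]
        # scatter into all index permutations (tensor is fully symmetric)
        for perm in set(_permutations(idx)):
            out[(slice(None),) + perm] = val
    return out


def _permutations(idx: tuple[int, ...]):
    from itertools import permutations
    return permutations(idx)


# ---------------------------------------------------------------------------
# Radial sequences

def b_coulomb(r: np.ndarray, nmax: int = MAX_RANK) -> np.ndarray:
    """Bare 1/r sequence: B_k = (2k-1)!! / r^(2k+1)."""
    r = np.asarray(r, float)
    B = np.empty(r.shape + (nmax + 1,))
    B[..., 0] = 1.0 / r
    for k in range(nmax):
        B[..., k + 1] = (2 * k + 1) * B[..., k] / r ** 2
    return B


def b_erfc(r: np.ndarray, beta: float, nmax: int = MAX_RANK) -> np.ndarray:
    """Ewald real-space sequence: B_0 = erfc(beta r)/r."""
    r = np.asarray(r, float)
    B = np.empty(r.shape + (nmax + 1,))
    B[..., 0] = erfc(beta * r) / r
    expo = np.exp(-(beta * r) ** 2) / (beta * np.sqrt(np.pi))
    for k in range(nmax):
        B[..., k + 1] = ((2 * k + 1) * B[..., k]
                         + (2 * beta ** 2) ** (k + 1) * expo) / r ** 2
    return B


def thole_lambdas(r: np.ndarray, damp_width: np.ndarray | float,
                  a: float = 0.39) -> np.ndarray:
    """Thole damping factors (lambda_3, lambda_5, lambda_7, lambda_9, lambda_11).

    damp_width is (alpha_i * alpha_j)^(1/6); u = r / damp_width;
    the exponential charge-density model gives v = a u^3 and

        lambda_3  = 1 - E
        lambda_5  = 1 - (1 + v) E
        lambda_7  = 1 - (1 + v + 3v^2/5) E
        lambda_9  = 1 - (1 + v + 18v^2/35 + 9v^3/35) E
        lambda_11 = 1 - (1 + v + 53v^2/105 + 6v^3/35 + 3v^4/35) E

    with E = exp(-v).  Each successive factor follows from lambda_{2k+3} =
    lambda_{2k+1} - (r/(2k+1)) dlambda_{2k+1}/dr, which keeps the damped
    radial family consistent under differentiation (checked by the
    finite-difference tensor tests).
    """
    r = np.asarray(r, float)
    w = np.broadcast_to(np.asarray(damp_width, float), r.shape)
    out = np.ones(r.shape + (5,))
    ok = w > 0
    u = np.where(ok, r / np.where(ok, w, 1.0), 1e8)
    v = np.minimum(a * u ** 3, 50.0)   # exp(-50) below any tolerance
    E = np.exp(-v)
    v2, v3, v4 = v * v, v ** 3, v ** 4
    out[..., 0] = 1.0 - E
    out[..., 1] = 1.0 - (1.0 + v) * E
    out[..., 2] = 1.0 - (1.0 + v + 0.6 * v2) * E
    out[..., 3] = 1.0 - (1.0 + v + (18.0 / 35.0) * v2 + (9.0 / 35.0) * v3) * E
    # lambda_11 = lambda_9 - (r/9) dlambda_9/dr
    out[..., 4] = 1.0 - (1.0 + v + (53.0 / 105.0) * v2
                         + (6.0 / 35.0) * v3 + (3.0 / 35.0) * v4) * E
    return out


def b_damped_correction(r: np.ndarray, damp_width, a: float = 0.39,
                        nmax: int = MAX_RANK) -> np.ndarray:
    """(lambda_{2k+1} - 1) * B_k^bare for k = 1..nmax; k = 0 slot is zero.

    This is the short-range correction that converts an undamped kernel into
    a Thole-damped one; rank-0 (the potential) is never damped here because
    damping only enters polarization interactions, which start at rank 1.
    """
    lam = thole_lambdas(r, damp_width, a)
    Bb = b_coulomb(r, nmax)
    out = np.zeros_like(Bb)
    for k in range(1, nmax + 1):
        out[..., k] = (lam[..., k - 1] - 1.0) * Bb[..., k]
    return out


# ---------------------------------------------------------------------------
# Moment containers and contractions

class Moments:
    """Per-atom operator moments: m0 = q, m1 = d, m2 = Q/3 (traceless)."""

    __slots__ = ("m0", "m1", "m2")

    def __init__(self, q, d, Q):
        q = np.asarray(q, float)
        self.m0 = q
        self.m1 = np.asarray(d, float).reshape(q.shape + (3,))
        self.m2 = np.asarray(Q, float).reshape(q.shape + (3, 3)) / 3.0

    @staticmethod
    def zeros(n: int) -> "Moments":
        return Moments(np.zeros(n), np.zeros((n, 3)), np.zeros((n, 3, 3)))

    @staticmethod
    def dipoles(mu: np.ndarray) -> "Moments":
        n = mu.shape[0]
        return Moments(np.zeros(n), mu, np.zeros((n, 3, 3)))

    def take(self, idx) -> "Moments":
        m = Moments.__new__(Moments)
        m.m0 = self.m0[idx]
        m.m1 = self.m1[idx]
        m.m2 = self.m2[idx]
        return m

    @property
    def n(self) -> int:
        return self.m0.shape[0]

    def max_rank(self) -> int:
        if np.any(self.m2):
            return 2
        if np.any(self.m1):
            return 1
        return 0


def potential_stack(dr: np.ndarray, B: np.ndarray, src: Moments,
                    max_order: int) -> list[np.ndarray]:
    """Taylor stack of the potential at probe points due to sources.

    dr = r_probe - r_source, one source per row.  Returns
    [phi, grad phi, grad^2 phi, ...] up to max_order, each (P, 3, ...).

    phi^(m) = sum_nj (-1)^nj  T^(m+nj) . m_src^(nj)
    """
    src_rank = src.max_rank()
    tcache: dict[int, np.ndarray] = {}

    def T_of(rank: int) -> np.ndarray:
        if rank not in tcache:
            tcache[rank] = t_tensor(rank, dr, B)
        return tcache[rank]

    out = []
    for m in range(max_order + 1):
        acc = np.zeros((dr.shape[0],) + (3,) * m)
        for nj in range(src_rank + 1):
            T = T_of(m + nj)
            sign = -1.0 if nj % 2 else 1.0
            if nj == 0:
                acc += sign * T * src.m0.reshape((-1,) + (1,) * m)
            elif nj == 1:
                acc += sign * np.einsum("p...a,pa->p...", T, src.m1)
            else:
                acc += sign * np.einsum("p...ab,pab->p...", T, src.m2)
        out.append(acc)
    return out


def probe_energy(stack: list[np.ndarray], probe: Moments) -> np.ndarray:
    """Energy of probe moments in the potential stack: q phi + d.grad phi +
    (Q/3):grad grad phi, per pair."""
    u = stack[0] * probe.m0
    u = u + np.einsum("pa,pa->p", stack[1], probe.m1)
    u = u + np.einsum("pab,pab->p", stack[2], probe.m2)
    return u


def probe_force(stack: list[np.ndarray], probe: Moments) -> np.ndarray:
    """-dU/dr_probe; needs the stack up to order rank(probe)+1."""
    f = stack[1] * probe.m0[:, None]
    if len(stack) > 2 and np.any(probe.m1):
        f = f + np.einsum("pab,pb->pa", stack[2], probe.m1)
    if len(stack) > 3 and np.any(probe.m2):
        f = f + np.einsum("pabc,pbc->pa", stack[3], probe.m2)
    return -f


_EPSILON = np.zeros((3, 3, 3))
for _i, _j, _k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
    _EPSILON[_i, _j, _k] = 1.0
    _EPSILON[_k, _j, _i] = -1.0


def probe_torque(stack: list[np.ndarray], probe: Moments) -> np.ndarray:
    """dU/d(epsilon) for an infinitesimal rotation of the probe moments.

    With U = d.G1 + m2:G2 (G_m = phi^(m)), delta d = eps x d and
    delta m2 = [eps x] m2 + m2 [eps x]^T, giving

        tau_e = (d x G1)_e + 2 * eps_{aec} G2_{ab} m2_{cb}.
    """
    G1, G2 = stack[1], stack[2]
    tau = np.einsum("eab,pa,pb->pe", _EPSILON, probe.m1, G1)
    tau = tau + 2.0 * np.einsum("aec,pab,pcb->pe", _EPSILON, G2, probe.m2)
    return tau
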