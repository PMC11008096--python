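"""Interpolation of permanent multipoles and polarizabilities in the
titration (lambda) and tautomer (zeta) variables.

Mixing conventions per residue case (lambda = 1 is protonated; zeta = 1
selects the "1" side: histidine HE2/HIE, carboxylate O1):

* LYS, CYS (no tautomer):
    M(l)      = (1 - l) M^U + l M^P
* ASP, GLU (protonated tautomerism, proton on either oxygen):
    M(l, z)   = (1 - l) M^U + l [z M^P1 + (1 - z) M^P2]
* HIS (neutral tautomerism between HIE = U1 and HID = U2; P = HIP):
    M(l, z)   = l M^P + (1 - l) [z M^U1 + (1 - z) M^U2]

All derivatives are the exact linears of these forms.  Polarizabilities
follow the same mixing.  The Thole damping width, by contrast, is frozen
(fixed charge-density approximation): atoms interpolating between two
nonzero polarizabilities use the mean of their end-state values, titrating
hydrogens use their protonated-state value, and the width therefore has
zero derivative with respect to lambda and zeta.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .model import ResidueKind, TitratableSite


def _mix_coeffs(kind: ResidueKind, lam: float, zeta: Optional[float]):
    """Weights {state: (w, dw/dlam, dw/dzeta)} for the residue case."""
    if kind in (ResidueKind.LYS, ResidueKind.CYS):
        if zeta is not None:
            raise ValueError(f"{kind.value} has no tautomer variable")
        return {"U": (1.0 - lam, -1.0, 0.0), "P": (lam, 1.0, 0.0)}
    if zeta is None:
        raise ValueError(f"{kind.value} requires a tautomer value")
    if kind is ResidueKind.HIS:
        return {
            "P": (lam, 1.0, 0.0),
            "U1": ((1.0 - lam) * zeta, -zeta, 1.0 - lam),
            "U2": ((1.0 - lam) * (1.0 - zeta), -(1.0 - zeta), -(1.0 - lam)),
        }
    # ASP / GLU
    return {
        "U": (1.0 - lam, -1.0, 0.0),
        "P1": (lam * zeta, zeta, lam),
        "P2": (lam * (1.0 - zeta), 1.0 - zeta, -lam),
    }


def interpolate_multipole(site: TitratableSite, atom: int, lam: float,
                          zeta: Optional[float] = None):
    """Local-frame (M, dM/dlambda, dM/dzeta) 13-vectors for one atom."""
    coeffs = _mix_coeffs(site.residue_kind, lam, zeta)
    M = np.zeros(13)
    Md = np.zeros(13)
    Mz = np.zeros(13)
    for state, (w, wd, wz) in coeffs.items():
        v = site.endstate_multipoles[state][atom].as_vector()
        M += w * v
        Md += wd * v
        Mz += wz * v
    return M, Md, Mz


def interpolate_polarizability(site: TitratableSite, atom: int, lam: float,
                               zeta: Optional[float] = None):
    """(alpha, dalpha/dlambda, dalpha/dzeta) for one atom."""
    coeffs = _mix_coeffs(site.residue_kind, lam, zeta)
    a = ad = az = 0.0
    for state, (w, wd, wz) in coeffs.items():
        v = site.endstate_polarizabilities[state][atom]
        a += w * v
        ad += wd * v
        az += wz * v
    assert a >= -1e-12, "interpolated polarizability went negative"
    return max(a, 0.0), ad, az


def effective_damping_alpha(site: Optional[TitratableSite], atom: int,
                            static_alpha: float) -> float:
    """Fixed polarizability entering the Thole damping width.

    Non-titrating atoms keep their static value.  Atoms interpolating
    between nonzero end states (thiolate sulfur, carboxylate oxygens) use
    the mean of their end-state values; titrating hydrogens (zero at one
    end) use their largest end-state value, so damping behaves as in the
    protonated state whenever the hydrogen is present.  In all cases the
    width is state-independent: its lambda/zeta derivative is exactly zero.
    """
    if site is None or atom not in site.atoms:
        return static_alpha
    vals = [site.endstate_polarizabilities[s][atom]
            for s in site.endstate_polarizabilities
            if atom in site.endstate_polarizabilities[s]]
    if not vals or max(vals) == min(vals):
        return vals[0] if vals else static_alpha
    if min(vals) <= 0.0:
        return max(vals)           # titrating hydrogen
    return float(np.mean(vals))    # sulfur / carboxylate oxygen


def thole_effective_density(site_i: Optional[TitratableSite], atom_i: int,
                            alpha_i: float,
                            site_j: Optional[TitratableSite], atom_j: int,
                            alpha_j: float) -> float:
    """Frozen pair damping width (alpha_i^eff * alpha_j^eff)^(1/6)."""
    ai = effective_damping_alpha(site_i, atom_i, alpha_i)
    aj = effective_damping_alpha(site_j, atom_j, alpha_j)
    if ai <= 0.0 or aj <= 0.0:
        return 0.0  # undamped (bare) interaction
    return float((ai * aj) ** (1.0 / 6.0))


def vdw_scale(site: TitratableSite, atom: int, lam: float,
              zeta: Optional[float]):
    """Per-atom van der Waals scale factor f(lambda, zeta) and derivatives.

    Only titrating hydrogens scale; every other atom returns (1, 0, 0).
    The tautomer factor f^m(zeta) is zeta for direction +1 and 1 - zeta
    for direction -1.
    """
    direction = site.titrating_hydrogens.get(atom)
    if direction is None:
        return 1.0, 0.0, 0.0
    kind = site.residue_kind
    if kind in (ResidueKind.LYS, ResidueKind.CYS):
        return lam, 1.0, 0.0
    fm = zeta if direction > 0 else 1.0 - zeta
    dfm = 1.0 if direction > 0 else -1.0
    if kind is ResidueKind.HIS:
        # proton present in HIP (l=1) and in its own tautomer at l=0
        return (1.0 - lam) * fm + lam, 1.0 - fm, (1.0 - lam) * dfm
    # ASP / GLU: proton exists only when protonated, on the zeta-selected O
    return lam * fm, fm, lam * dfm
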