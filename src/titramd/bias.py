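"""Bias potentials on the extended titration/tautomer variables.

Three components per site:

* a barrier 4 beta_t l (1 - l) per variable, maximal (= beta_t) at the
  intermediate state l = 0.5 and zero at both end states — it suppresses
  unphysical fractional protonation and sets the transition kinetics;
* the model-compound bias U_mod, a fitted polynomial that cancels the
  model compound's titration PMF so that only the difference between the
  actual environment and the reference drives titration (HIS carries three
  surfaces: titration at each tautomer end plus a tautomer surface scaled
  by (1 - lambda); ASP/GLU carry a tautomer surface scaled by lambda);
* the pH bias ln(10) k_B T (pKa_ref - pH)(1 - lambda): the relative
  deprotonation free energy at the ensemble pH (lambda = 1 is protonated,
  so the term vanishes for the protonated state).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB, LN10
from .model import ResidueKind, TitratableSite


@dataclass
class BiasParams:
    barrier: float = 2.0        # beta_t, kcal/mol
    pH: float = 7.0
    temperature: float = 298.0  # K


def _poly(coeffs, x: float) -> tuple[float, float]:
    """(value, derivative) of an ascending-coefficient polynomial."""
    if coeffs is None:
        return 0.0, 0.0
    c = np.asarray(coeffs, float)
    p = np.polynomial.polynomial
    return float(p.polyval(x, c)), float(p.polyval(x, p.polyder(c)))


def ph_bias(site: TitratableSite, lam: float, params: BiasParams) -> float:
    return LN10 * KB * params.temperature * (site.pKa_ref - params.pH) \
        * (1.0 - lam)


def bias_energy(sites: list[TitratableSite], ext: np.ndarray,
                params: BiasParams):
    """(U_bias, dU/dext) over all sites."""
    U = 0.0
    dext = np.zeros(len(ext))
    bt = params.barrier
    kt = LN10 * KB * params.temperature
    for site in sites:
        li = site.lambda_index
        lam = float(ext[li])
        zi = site.zeta_index
        zeta = float(ext[zi]) if zi is not None else None

        # barrier
        U += 4.0 * bt * lam * (1.0 - lam)
        dext[li] += 4.0 * bt * (1.0 - 2.0 * lam)
        if zi is not None:
            U += 4.0 * bt * zeta * (1.0 - zeta)
            dext[zi] += 4.0 * bt * (1.0 - 2.0 * zeta)

        # model-compound bias
        if site.residue_kind is ResidueKind.HIS:
            v1, d1 = _poly(site.model_bias, lam)          # titration at zeta=1
            v0, d0 = _poly(site.model_bias_zeta0, lam)    # titration at zeta=0
            vt, dt = _poly(site.model_bias_tautomer, zeta)
            U += zeta * v1 + (1.0 - zeta) * v0 + (1.0 - lam) * vt
            dext[li] += zeta * d1 + (1.0 - zeta) * d0 - vt
            dext[zi] += v1 - v0 + (1.0 - lam) * dt
        else:
            v, d = _poly(site.model_bias, lam)
            U += v
            dext[li] += d
            if zi is not None:
                vt, dt = _poly(site.model_bias_tautomer, zeta)
                U += lam * vt
                dext[li] += vt
                dext[zi] += lam * dt

        # pH bias
        U += kt * (site.pKa_ref - params.pH) * (1.0 - lam)
        dext[li] += -kt * (site.pKa_ref - params.pH)
    return U, dext


def ph_bias_total(sites: list[TitratableSite], lam_values: np.ndarray,
                  pH: float, temperature: float) -> float:
    """U_pH of a lambda configuration at a given pH (used by pH-REX)."""
    kt = LN10 * KB * temperature
    return float(sum(kt * (s.pKa_ref - pH) * (1.0 - lam_values[s.lambda_index])
                     for s in sites))
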