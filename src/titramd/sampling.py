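"""Enhanced sampling and titration analysis: pH replica exchange,
Bennett-acceptance-ratio free energies, model-PMF fitting, end-state
fraction counting, and Hill-equation pKa estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq, curve_fit

from .bias import ph_bias_total
from .constants import KB
from .dynamics import (CpHMDEngine, LangevinIntegrator, RunConfig,
                       initial_state)
from .model import TitrationRecord, TitratableSite


# ---------------------------------------------------------------------------
# pH replica exchange

def exchange_criterion(lam_A: np.ndarray, lam_B: np.ndarray,
                       sites: list[TitratableSite],
                       pH_A: float, pH_B: float,
                       temperature: float) -> tuple[float, float]:
    """(Delta E, acceptance probability) for swapping the pH values of two
    replicas.

    Only the pH-bias term depends on pH, so the Metropolis energy is

        dE = [U_pH(l_A; pH_B) + U_pH(l_B; pH_A)]
           - [U_pH(l_A; pH_A) + U_pH(l_B; pH_B)]
    """
    dE = (ph_bias_total(sites, lam_A, pH_B, temperature)
          + ph_bias_total(sites, lam_B, pH_A, temperature)
          - ph_bias_total(sites, lam_A, pH_A, temperature)
          - ph_bias_total(sites, lam_B, pH_B, temperature))
    beta = 1.0 / (KB * temperature)
    p = min(1.0, float(np.exp(-beta * dE)))
    return dE, p


@dataclass
class ReplicaLadder:
    """Ascending pH values plus one engine per replica."""

    engines: list[CpHMDEngine]
    exchange_interval: int = 500
    attempts: dict[int, int] = field(default_factory=dict)
    accepted: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        phs = [e.config.bias.pH for e in self.engines]
        if any(b < a for a, b in zip(phs, phs[1:])):
            raise ValueError("replica pH values must be ascending")

    @property
    def pHs(self) -> list[float]:
        return [e.config.bias.pH for e in self.engines]


def run_phrex(ladder: ReplicaLadder, steps: int, run: RunConfig,
              seed: int = 1) -> list[TitrationRecord]:
    """pH replica exchange: neighbor swaps of pH every exchange interval,
    alternating even/odd pairs.  Records are tagged by pH (each record
    follows one pH value, not one walker), matching how titration curves
    are accumulated."""
    engines = ladder.engines
    n_rep = len(engines)
    if n_rep < 2:
        raise ValueError("replica exchange needs at least two replicas")
    rng = np.random.default_rng(seed)
    integrators = []
    for i, eng in enumerate(engines):
        st = initial_state(eng.system, run)
        spec = run.langevin
        spec_i = type(spec)(timestep=spec.timestep, friction=spec.friction,
                            temperature=spec.temperature,
                            seed=spec.seed + 7919 * i,
                            theta_mass=spec.theta_mass)
        integrators.append(LangevinIntegrator(eng, st, spec_i))
    # pH slots: records follow a pH value, not a walker; slot_of[i] is the
    # slot whose pH replica i currently simulates
    records = [TitrationRecord(pH=e.config.bias.pH) for e in engines]
    slot_of = list(range(n_rep))

    def save(step: int) -> None:
        for i, (eng, integ) in enumerate(zip(engines, integrators)):
            rec = records[slot_of[i]]
            ext = integ.state.lam
            sites = eng.system.sites
            lams = {s.lambda_index: float(ext[s.lambda_index]) for s in sites}
            zetas = {s.lambda_index: float(ext[s.zeta_index])
                     for s in sites if s.zeta_index is not None}
            rec.append(step, lams, zetas)

    interval = ladder.exchange_interval
    save_every = run.save_interval
    done = 0
    sweep = 0
    save(0)
    next_save = save_every
    while done < steps:
        block_end = min(done + interval, steps)
        while done < block_end:
            target = min(next_save, block_end)
            if target > done:
                for integ in integrators:
                    integ.step(target - done)
                done = target
            if done == next_save:
                save(done)
                next_save += save_every
        # alternating neighbor swaps of pH between simulations
        start = sweep % 2
        sweep += 1
        order = np.argsort([slot_of[i] for i in range(n_rep)])
        for a in range(start, n_rep - 1, 2):
            i, j = order[a], order[a + 1]
            ei, ej = engines[i], engines[j]
            T = ei.config.bias.temperature
            lam_i = integrators[i].state.lam
            lam_j = integrators[j].state.lam
            dE, p = exchange_criterion(lam_i, lam_j, ei.system.sites,
                                       ei.config.bias.pH, ej.config.bias.pH,
                                       T)
            ladder.attempts[a] = ladder.attempts.get(a, 0) + 1
            if rng.uniform() < p:
                ladder.accepted[a] = ladder.accepted.get(a, 0) + 1
                if ei.config.bias.pH == ej.config.bias.pH:
                    continue   # identical ensembles: the swap is a no-op
                ei.config.bias.pH, ej.config.bias.pH = \
                    ej.config.bias.pH, ei.config.bias.pH
                slot_of[i], slot_of[j] = slot_of[j], slot_of[i]
                # bias changed: refresh cached forces for both walkers
                for k in (i, j):
                    integrators[k].report = engines[k].energy(
                        integrators[k].state.X, integrators[k].state.theta)
    return records


# ---------------------------------------------------------------------------
# Bennett acceptance ratio

def bar_estimate(forward_work: np.ndarray, reverse_work: np.ndarray,
                 temperature: float) -> tuple[float, float]:
    """Self-consistent BAR estimate of Delta G (kcal/mol) and its standard
    error from forward (0->1) and reverse (1->0) work samples.

    Solves  sum_F f(beta(M + w_F - dG)) = sum_R f(beta(-M + w_R + dG))
    with f the Fermi function and M = ln(n_F/n_R)/beta, by bisection.
    """
    wf = np.asarray(forward_work, float)
    wr = np.asarray(reverse_work, float)
    if wf.size == 0 or wr.size == 0:
        raise ValueError("BAR requires work samples in both directions")
    beta = 1.0 / (KB * temperature)
    M = np.log(wf.size / wr.size) / beta

    def fermi(x):
        return 1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))

    def imbalance(dg):
        return (np.sum(fermi(beta * (M + wf - dg)))
                - np.sum(fermi(beta * (-M + wr + dg))))

    lo = min(wf.min(), -wr.max()) - 50.0 * KB * temperature
    hi = max(wf.max(), -wr.min()) + 50.0 * KB * temperature
    if imbalance(lo) * imbalance(hi) > 0:
        dg = 0.5 * (np.mean(wf) - np.mean(wr))
    else:
        dg = brentq(imbalance, lo, hi, xtol=1e-10)

    # asymptotic variance (Bennett)
    ff = fermi(beta * (M + wf - dg))
    fr = fermi(beta * (-M + wr + dg))
    nf, nr = wf.size, wr.size
    mean_sq = (np.sum(ff ** 2) + np.sum(fr ** 2)) / (nf + nr)
    mean = (np.sum(ff) + np.sum(fr)) / (nf + nr)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (mean_sq / mean ** 2 - 1.0) * (1.0 / nf + 1.0 / nr)
    err = float(np.sqrt(max(var, 0.0))) / beta
    overlap_warn = mean < 1e-6
    if overlap_warn:
        import warnings
        warnings.warn("BAR: negligible overlap between work distributions; "
                      "uncertainty is unreliable", stacklevel=2)
        err = max(err, abs(dg))
    return float(dg), err


# ---------------------------------------------------------------------------
# model PMF fit

def fit_model_pmf(window_lambdas: np.ndarray, window_dgs: np.ndarray,
                  degree: int = 4, symmetric_endpoints: bool = False
                  ) -> np.ndarray:
    """Fit the cumulative PMF G(lambda) to a polynomial and return the
    model-bias coefficients (ascending powers) that cancel it.

    G is anchored at G(0) = 0 (no constant term).  With
    ``symmetric_endpoints`` (carboxylate tautomer symmetry) the fit is
    constrained to G(1) = 0 as well.  The returned coefficients are the
    *negated* polynomial: adding U_mod to the Hamiltonian flattens the
    model compound's titration free-energy surface.
    """
    lam = np.asarray(window_lambdas, float)
    dgs = np.asarray(window_dgs, float)
    if lam.size < 3:
        raise ValueError("need at least 3 windows")
    if degree >= lam.size:
        raise ValueError("polynomial degree must be below the window count")
    # cumulative free energy at window midpoints/edges
    G = np.concatenate(([0.0], np.cumsum(dgs)))
    basis = np.vander(lam, degree + 1, increasing=True)[:, 1:]  # drop const
    if symmetric_endpoints:
        # substitute the last basis column to enforce G(1) = 0:
        # G = sum_k c_k (l^k - l^degree)  for k = 1..degree-1
        reduced = basis[:, :-1] - basis[:, [-1]]
        coef, *_ = np.linalg.lstsq(reduced, G, rcond=None)
        full = np.concatenate((coef, [-np.sum(coef)]))
    else:
        full, *_ = np.linalg.lstsq(basis, G, rcond=None)
    return -np.concatenate(([0.0], full))


# ---------------------------------------------------------------------------
# fraction counting and Hill fit

DEPROT_THRESHOLD = 0.10
PROT_THRESHOLD = 0.90


def count_fractions(record: TitrationRecord, site_id: Optional[int] = None,
                    burn_in: float = 0.1):
    """(S_deprot, n_deprot, n_prot, n_discarded) from a lambda series.

    lambda <= 0.10 counts as deprotonated, lambda >= 0.90 as protonated;
    intermediate samples are discarded.  The first ``burn_in`` fraction of
    the series is dropped before counting.
    """
    if record.n_samples == 0:
        raise ValueError("empty titration record")
    if site_id is None:
        site_id = sorted(record.lam)[0]
    series = np.asarray(record.lam[site_id], float)
    series = series[int(np.floor(burn_in * series.size)):]
    n_dep = int(np.sum(series <= DEPROT_THRESHOLD))
    n_pro = int(np.sum(series >= PROT_THRESHOLD))
    n_disc = series.size - n_dep - n_pro
    if n_dep + n_pro == 0:
        raise ValueError("no samples at either end state; fraction undefined")
    return n_dep / (n_dep + n_pro), n_dep, n_pro, n_disc


@dataclass
class HillFit:
    pKa: float
    n: float
    residuals: np.ndarray
    covariance: np.ndarray

    @property
    def pKa_stderr(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def n_stderr(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))


def hill_curve(pH, pKa, n):
    """Deprotonated fraction S = 1 / (1 + 10^(n (pKa - pH)))."""
    return 1.0 / (1.0 + 10.0 ** (n * (pKa - np.asarray(pH, float))))


def fit_hill(ph_values: np.ndarray, s_deprot: np.ndarray) -> HillFit:
    """Nonlinear least squares of the generalized titration curve."""
    ph = np.asarray(ph_values, float)
    s = np.asarray(s_deprot, float)
    if ph.size < 3:
        raise ValueError("need at least 3 pH points")
    if s.max() < 0.05 or s.min() > 0.95:
        raise ValueError("no titration transition in data; Hill fit is "
                         "degenerate")
    guess_pka = float(ph[np.argmin(np.abs(s - 0.5))])
    popt, pcov = curve_fit(hill_curve, ph, s, p0=[guess_pka, 1.0],
                           maxfev=10000)
    res = s - hill_curve(ph, *popt)
    if popt[1] <= 0:
        raise ValueError("Hill fit produced a non-positive coefficient")
    return HillFit(float(popt[0]), float(popt[1]), res, pcov)
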