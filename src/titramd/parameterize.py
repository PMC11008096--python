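"""Model-compound parameterization: fixed-lambda window sampling, BAR
free-energy differences between neighboring windows, and the polynomial
model-bias fit.

The titration PMF of a model compound is collected from evenly spaced
lambda windows (lambda fixed, conformations sampled by Langevin dynamics),
the free-energy difference between neighbors is estimated with the Bennett
acceptance ratio from forward and reverse energy gaps, and the cumulative
PMF is fit to a polynomial whose negation becomes U_mod — subtracting it
flattens the model's titration surface so that, in any other environment,
only the difference from the reference drives protonation.
"""

from __future__ import annotations

import numpy as np

from .dynamics import (CpHMDEngine, EngineConfig, LangevinIntegrator,
                       RunConfig, initial_state)
from .fixtures import Fixture
from .model import ExtendedState, ResidueKind
from .sampling import bar_estimate, fit_model_pmf


def titration_energy(engine: CpHMDEngine, positions: np.ndarray,
                     theta: np.ndarray) -> float:
    """The lambda-dependent part of the Hamiltonian (vdW + permanent +
    polarization); bonded terms are lambda-invariant and the bias is what
    is being parameterized, so both are excluded from the PMF work."""
    rep = engine.energy(positions, theta)
    return sum(rep.components.get(k, 0.0)
               for k in ("vdw", "permanent", "polarization"))


def window_sampling(engine: CpHMDEngine, window_lambdas: np.ndarray,
                    steps: int, run: RunConfig, sample_interval: int = 20,
                    equilibration: int = 200):
    """Sample each fixed-lambda window; return per-window forward and
    reverse energy gaps to the neighboring windows."""
    system = engine.system
    site = system.sites[0]
    thetas = ExtendedState.theta_of(window_lambdas)
    n_w = len(window_lambdas)
    fwd = [[] for _ in range(n_w)]   # U(l_{i+1}) - U(l_i) on window i
    rev = [[] for _ in range(n_w)]   # U(l_{i-1}) - U(l_i) on window i
    for w in range(n_w):
        st = initial_state(system, run)
        st.theta[site.lambda_index] = thetas[w]
        if site.zeta_index is not None:
            st.theta[site.zeta_index] = ExtendedState.theta_of(1.0)
        spec = run.langevin
        spec_w = type(spec)(timestep=spec.timestep, friction=spec.friction,
                            temperature=spec.temperature,
                            seed=spec.seed + 131 * w,
                            theta_mass=spec.theta_mass, freeze_theta=True)
        integ = LangevinIntegrator(engine, st, spec_w)
        integ.step(equilibration)
        done = 0
        while done < steps:
            integ.step(sample_interval)
            done += sample_interval
            u_here = titration_energy(engine, st.X, st.theta)
            th = st.theta.copy()
            if w + 1 < n_w:
                th[site.lambda_index] = thetas[w + 1]
                fwd[w].append(titration_energy(engine, st.X, th) - u_here)
            if w > 0:
                th[site.lambda_index] = thetas[w - 1]
                rev[w].append(titration_energy(engine, st.X, th) - u_here)
    return fwd, rev


def model_pmf_pipeline(fixture: Fixture, windows: int, steps: int,
                       run: RunConfig, degree: int = 4) -> dict:
    """Full window -> BAR -> polynomial pipeline for one model compound."""
    engine = CpHMDEngine(fixture.system, EngineConfig())
    lams = np.linspace(0.0, 1.0, windows)
    fwd, rev = window_sampling(engine, lams, steps, run)
    dgs, errs = [], []
    T = run.langevin.temperature
    for i in range(windows - 1):
        dg, err = bar_estimate(np.array(fwd[i]), np.array(rev[i + 1]), T)
        dgs.append(dg)
        errs.append(err)
    kind = fixture.system.sites[0].residue_kind
    symmetric = kind in (ResidueKind.ASP, ResidueKind.GLU)
    coeffs = fit_model_pmf(lams, np.array(dgs), degree=degree,
                           symmetric_endpoints=False)
    return {
        "residue": kind.value,
        "window_lambdas": [float(x) for x in lams],
        "dG": [float(x) for x in dgs],
        "dG_err": [float(x) for x in errs],
        "model_bias": [float(c) for c in coeffs],
        "tautomer_symmetric": symmetric,
    }
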