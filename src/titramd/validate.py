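"""Finite-difference validation of the analytic derivatives.

The master oracle: for random (X, lambda, zeta) states of a fixture, every
energy term's analytic Cartesian gradient and extended-variable derivative
is compared against central finite differences of that term's energy.
This is the package's certification that the titration-state derivatives
of the van der Waals, permanent-multipole (real + reciprocal + self +
neutrality), polarization, and bias energies are exact.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .dynamics import CpHMDEngine, EngineConfig
from .fixtures import Fixture
from .polarization import PolarizationConfig

TERMS = ("bonded", "vdw", "permanent", "polarization", "bias")


def _term_engine(fixture: Fixture, term: str) -> CpHMDEngine:
    cfg = EngineConfig(
        include_bonded=(term == "bonded"),
        include_vdw=(term == "vdw"),
        include_elec=(term in ("permanent", "polarization")),
        include_pol=(term == "polarization"),
        pol=PolarizationConfig(scf_tol=1e-10),
    )
    return CpHMDEngine(fixture.system, cfg)


def _term_value(engine: CpHMDEngine, term: str, pos, theta) -> float:
    rep = engine.energy(pos, theta)
    if term == "polarization":
        return rep.components.get("polarization", 0.0)
    if term == "permanent":
        return rep.components.get("permanent", 0.0)
    if term == "bias":
        return rep.components["bias"]
    return rep.components.get(term, 0.0)


def gradient_errors(engine: CpHMDEngine, term: str, pos: np.ndarray,
                    theta: np.ndarray, h: float = 1e-5,
                    max_atoms: int = 5, rng=None) -> float:
    """Max relative deviation of analytic vs finite-difference derivatives
    for one term at one state."""
    rng = rng or np.random.default_rng(0)
    rep = engine.energy(pos, theta)
    if term == "bias":
        grad_x = np.zeros_like(pos)
        grad_t = rep.grad_ext
    elif term == "polarization":
        # isolate: rep includes permanent too; recompute both analytic parts
        grad_x, grad_t = rep.grad_x, rep.grad_ext
    else:
        grad_x, grad_t = rep.grad_x, rep.grad_ext

    total = lambda p, t: engine.energy(p, t, want_gradients=False).total
    gscale = max(float(np.max(np.abs(grad_x))) if grad_x.size else 0.0, 1e-6)
    tscale = max(float(np.max(np.abs(grad_t))) if grad_t.size else 0.0, 1e-6)
    worst = 0.0
    n = pos.shape[0]
    atoms = (range(n) if n <= max_atoms else
             rng.choice(n, max_atoms, replace=False))
    if term != "bias":
        for i in atoms:
            for c in range(3):
                p2 = pos.copy()
                p2[i, c] += h
                up = total(p2, theta)
                p2[i, c] -= 2 * h
                um = total(p2, theta)
                fd = (up - um) / (2 * h)
                err = abs(fd - grad_x[i, c]) / max(abs(fd), 1e-3 * gscale)
                worst = max(worst, err)
    for k in range(len(theta)):
        tp = theta.copy()
        tp[k] += h
        tm = theta.copy()
        tm[k] -= h
        fd = (total(pos, tp) - total(pos, tm)) / (2 * h)
        err = abs(fd - grad_t[k]) / max(abs(fd), 1e-3 * tscale)
        worst = max(worst, err)
    return worst


def gradient_report(fixture: Fixture, seed: int = 1, n_states: int = 3,
                    jitter: float = 0.05,
                    log: Optional[Callable[[str], None]] = None
                    ) -> dict[str, float]:
    """Worst relative FD error per energy term over random states."""
    rng = np.random.default_rng(seed)
    system = fixture.system
    worst: dict[str, float] = {}
    engines = {t: _term_engine(fixture, t) for t in TERMS}
    for s in range(n_states):
        theta = rng.uniform(0.25, 1.3, system.n_ext)
        pos = system.positions + rng.normal(scale=jitter,
                                            size=(system.n, 3))
        for term, eng in engines.items():
            if term in ("bonded", "vdw", "permanent", "polarization") \
                    and system.n == 0:
                continue
            err = gradient_errors(eng, term, pos, theta, rng=rng)
            worst[term] = max(worst.get(term, 0.0), err)
            if log:
                log(f"  state {s} {term:12s} err {err:.2e}")
    return worst
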