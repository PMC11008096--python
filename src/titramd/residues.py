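"""Titratable-residue definitions and site construction.

A `ResidueDefinition` carries everything that distinguishes one protonation
end state from another for a group of atoms: per-atom multipole sets and
polarizabilities for each end state, the titrating hydrogens with their
tautomer direction tags, and the reference (model compound) pKa.
`build_titratable_sites` validates the definitions against the atom list
and allocates extended-variable indices.

Bonded terms are, by construction, those of the protonated state for every
site: a deprotonated site keeps its (alchemically decoupled) proton as a
bonded dummy, so the bonded potential never depends on lambda or zeta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (Atom, MultipoleSet, ResidueKind, TAUTOMERIC,
                    TitratableSite)

#: reference model-compound pKa values
REFERENCE_PKA = {
    ResidueKind.ASP: 3.94,
    ResidueKind.GLU: 4.25,
    ResidueKind.HIS: 6.50,
    ResidueKind.LYS: 10.40,
    ResidueKind.CYS: 8.55,
}


@dataclass
class ResidueDefinition:
    residue_kind: ResidueKind
    atoms: list[int]
    titrating_hydrogens: dict[int, int]
    endstate_multipoles: dict[str, dict[int, MultipoleSet]]
    endstate_polarizabilities: dict[str, dict[int, float]]
    pKa_ref: float
    model_bias: np.ndarray = field(default_factory=lambda: np.zeros(5))
    model_bias_zeta0: Optional[np.ndarray] = None
    model_bias_tautomer: Optional[np.ndarray] = None


def build_titratable_sites(atoms: list[Atom],
                           definitions: list[ResidueDefinition]
                           ) -> list[TitratableSite]:
    """Allocate extended-variable indices and validate each definition.

    HIS/ASP/GLU receive a tautomer (zeta) index; LYS/CYS do not.  End-state
    frame consistency is enforced by the TitratableSite constructor.
    """
    sites = []
    next_idx = 0
    n = len(atoms)
    for d in definitions:
        for i in d.atoms:
            if not (0 <= i < n):
                raise ValueError(f"residue references nonexistent atom {i}")
        lam_idx = next_idx
        next_idx += 1
        zeta_idx = None
        if d.residue_kind in TAUTOMERIC:
            zeta_idx = next_idx
            next_idx += 1
        site = TitratableSite(
            residue_kind=d.residue_kind,
            lambda_index=lam_idx,
            zeta_index=zeta_idx,
            atoms=list(d.atoms),
            titrating_hydrogens=dict(d.titrating_hydrogens),
            endstate_multipoles=d.endstate_multipoles,
            endstate_polarizabilities=d.endstate_polarizabilities,
            pKa_ref=d.pKa_ref,
            model_bias=np.asarray(d.model_bias, float),
            model_bias_zeta0=d.model_bias_zeta0,
            model_bias_tautomer=d.model_bias_tautomer,
        )
        missing = set(site.expected_states) - set(d.endstate_multipoles)
        if missing:
            raise ValueError(
                f"{d.residue_kind.value}: missing end states {sorted(missing)}")
        sites.append(site)
    return sites
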