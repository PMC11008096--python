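"""Readers and writers: Tinker-style XYZ coordinates, the force-field
parameter dialect, and lambda-trajectory CSV files.

Parameter dialect
-----------------
A simplified Tinker-PRM-like text format::

    mpole-14-scale 0.4            # masking-scale header lines
    vdw       13  3.780  0.1010   [reduction]
    multipole 13  zthenx 14 15    -0.51966
              0.14279 0.00000 0.10000
              0.37928
              0.00000 -0.41809
              0.00000  0.00000 0.03881
    polarize  13  0.837 0.390     14 15

Frame keywords: ``none``, ``zonly``, ``zthenx``, ``bisector``,
``zbisect`` (Z-then-bisector), ``trisector``.  Frame atoms are given as
atom *types* and resolved against connectivity when a system is built.
Dipoles are read in e*Bohr and quadrupoles in e*Bohr^2 (the published
AMOEBA convention) and converted to e*A / e*A^2 on load; quadrupoles are
made traceless on load.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .constants import BOHR
from .model import Atom, CrystalCell, Frame, MultipoleSet, PolarizeParams, \
    TitrationRecord, VdwParams


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tinker XYZ

def read_tinker_xyz(path) -> tuple[list[Atom], Optional[CrystalCell]]:
    """Read a Tinker XYZ file; returns atoms and the periodic cell if the
    optional box line (a b c alpha beta gamma) is present."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ParseError(f"{path}:1: first line must hold the atom count")

    start = 1
    cell = None
    if len(lines) > 1:
        toks = lines[1].split()
        if len(toks) == 6:
            try:
                a, b, c, al, be, ga = (float(t) for t in toks)
                cell = CrystalCell.from_params(a, b, c, al, be, ga,
                                               real_cutoff=0.0)
                cell.real_cutoff = 0.45 * cell.min_width()
                start = 2
            except ValueError:
                pass

    atoms: list[Atom] = []
    for ln in range(start, start + natoms):
        if ln >= len(lines):
            raise ParseError(f"{path}: expected {natoms} atoms, file truncated")
        toks = lines[ln].split()
        try:
            idx = int(toks[0]) - 1
            name = toks[1]
            pos = [float(toks[2]), float(toks[3]), float(toks[4])]
            type_id = int(toks[5])
            bonded = [int(t) - 1 for t in toks[6:]]
        except (IndexError, ValueError) as e:
            raise ParseError(f"{path}:{ln + 1}: malformed atom line ({e})")
        atoms.append(Atom(idx, name, type_id, np.array(pos), bonded))

    if [a.index for a in atoms] != list(range(natoms)):
        raise ParseError(f"{path}: atom indices must be 1..{natoms} in order")
    _check_bond_symmetry(atoms, str(path))
    return atoms, cell


def _check_bond_symmetry(atoms: list[Atom], label: str) -> None:
    n = len(atoms)
    for a in atoms:
        for j in a.bonded:
            if not (0 <= j < n):
                raise ParseError(f"{label}: atom {a.index + 1} bonded to "
                                 f"nonexistent atom {j + 1}")
            if a.index not in atoms[j].bonded:
                raise ParseError(
                    f"{label}: bond list asymmetric: {a.index + 1} lists "
                    f"{j + 1} but not vice versa")


def write_tinker_xyz(path, atoms: list[Atom],
                     cell: Optional[CrystalCell] = None,
                     title: str = "titramd") -> None:
    out: list[str] = [f"{len(atoms):6d}  {title}"]
    if cell is not None:
        p = cell.cell_params()
        out.append("  " + "  ".join(f"{v:12.8f}" for v in p))
    for a in atoms:
        bonds = "".join(f"{j + 1:6d}" for j in a.bonded)
        out.append(f"{a.index + 1:6d}  {a.name:<4s}"
                   f"{a.position[0]:14.8f}{a.position[1]:14.8f}"
                   f"{a.position[2]:14.8f}{a.type_id:6d}{bonds}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Parameter file

_FRAME_KEYWORDS = {
    "none": Frame.NONE,
    "zonly": Frame.Z_ONLY,
    "zthenx": Frame.Z_THEN_X,
    "bisector": Frame.BISECTOR,
    "zbisect": Frame.Z_BISECTOR,
    "trisector": Frame.TRISECTOR,
}

_FRAME_NATOMS = {
    Frame.NONE: 0, Frame.Z_ONLY: 1, Frame.Z_THEN_X: 2,
    Frame.BISECTOR: 2, Frame.Z_BISECTOR: 3, Frame.TRISECTOR: 3,
}


@dataclass
class MultipoleBlock:
    """A type-level multipole definition; frame atoms as atom types."""

    frame: Frame
    frame_types: tuple[int, ...]
    moments: MultipoleSet  # local frame, frame_atoms unresolved


@dataclass
class ForceField:
    multipoles: dict[int, list[MultipoleBlock]] = field(default_factory=dict)
    vdw: dict[int, VdwParams] = field(default_factory=dict)
    polarize: dict[int, PolarizeParams] = field(default_factory=dict)
    polarize_group_types: dict[int, tuple[int, ...]] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)

    def mpole_scales(self) -> tuple[float, float, float, float]:
        """(1-2, 1-3, 1-4, 1-5) permanent-multipole masking factors."""
        return (self.scales.get("mpole-12-scale", 0.0),
                self.scales.get("mpole-13-scale", 0.0),
                self.scales.get("mpole-14-scale", 0.4),
                self.scales.get("mpole-15-scale", 0.8))

    def vdw_scales(self) -> tuple[float, float, float]:
        return (self.scales.get("vdw-12-scale", 0.0),
                self.scales.get("vdw-13-scale", 0.0),
                self.scales.get("vdw-14-scale", 1.0))

    def polar_scales(self) -> tuple[float, float, float]:
        """p-scale (energy-field) bonded masks 1-2, 1-3, 1-4."""
        return (self.scales.get("polar-12-scale", 0.0),
                self.scales.get("polar-13-scale", 0.0),
                self.scales.get("polar-14-scale", 1.0))


def read_parameters(path_or_file) -> ForceField:
    if hasattr(path_or_file, "read"):
        lines = path_or_file.read().splitlines()
        label = "<stream>"
    else:
        lines = Path(path_or_file).read_text().splitlines()
        label = str(path_or_file)

    ff = ForceField()
    i = 0
    n = len(lines)

    def toks_of(line: str) -> list[str]:
        return line.split("#", 1)[0].split()

    while i < n:
        toks = toks_of(lines[i])
        if not toks:
            i += 1
            continue
        key = toks[0].lower()
        try:
            if key == "vdw":
                t = int(toks[1])
                red = float(toks[4]) if len(toks) > 4 else 1.0
                ff.vdw[t] = VdwParams(float(toks[2]), float(toks[3]), red)
            elif key == "polarize":
                t = int(toks[1])
                group = tuple(int(x) for x in toks[4:])
                ff.polarize[t] = PolarizeParams(float(toks[2]), float(toks[3]))
                ff.polarize_group_types[t] = group
            elif key == "multipole":
                t = int(toks[1])
                fkw = toks[2].lower()
                if fkw not in _FRAME_KEYWORDS:
                    raise ParseError(
                        f"{label}:{i + 1}: unknown multipole frame keyword "
                        f"'{toks[2]}'")
                frame = _FRAME_KEYWORDS[fkw]
                na = _FRAME_NATOMS[frame]
                ftypes = tuple(int(x) for x in toks[3:3 + na])
                if len(ftypes) != na:
                    raise ParseError(
                        f"{label}:{i + 1}: frame '{fkw}' needs {na} frame types")
                q = float(toks[3 + na])
                d = np.array([float(x) for x in toks_of(lines[i + 1])]) * BOHR
                qxx = float(toks_of(lines[i + 2])[0])
                qxy, qyy = (float(x) for x in toks_of(lines[i + 3]))
                qxz, qyz, qzz = (float(x) for x in toks_of(lines[i + 4]))
                Q = np.array([[qxx, qxy, qxz], [qxy, qyy, qyz],
                              [qxz, qyz, qzz]]) * BOHR ** 2
                ff.multipoles.setdefault(t, []).append(
                    MultipoleBlock(frame, ftypes, MultipoleSet(q, d, Q, frame)))
                i += 4
            elif key.endswith("-scale"):
                ff.scales[key] = float(toks[1])
            else:
                raise ParseError(f"{label}:{i + 1}: unknown record '{toks[0]}'")
        except ParseError:
            raise
        except (IndexError, ValueError) as e:
            raise ParseError(f"{label}:{i + 1}: malformed record ({e})")
        i += 1

    _validate_frame_types(ff, label)
    return ff


def read_parameters_string(text: str) -> ForceField:
    return read_parameters(_io.StringIO(text))


def _validate_frame_types(ff: ForceField, label: str) -> None:
    known = set(ff.multipoles) | set(ff.vdw) | set(ff.polarize)
    for t, blocks in ff.multipoles.items():
        for blk in blocks:
            for ft in blk.frame_types:
                if ft not in known:
                    raise ParseError(
                        f"{label}: multipole for type {t} references frame "
                        f"atom type {ft} which is defined nowhere in the file")


# ---------------------------------------------------------------------------
# Titration record CSV

def write_titration_records(path, records: list[TitrationRecord]) -> None:
    rows = []
    for rec in records:
        for si, series in rec.lam.items():
            zser = rec.zeta.get(si, [np.nan] * len(series))
            for step, lam, zeta in zip(rec.steps, series, zser):
                rows.append((step, si, lam, zeta, rec.pH))
    df = pd.DataFrame(rows, columns=["step", "site_id", "lambda", "zeta", "pH"])
    df.to_csv(path, index=False)


def read_titration_records(path) -> list[TitrationRecord]:
    df = pd.read_csv(path)
    records = []
    for pH, g in df.groupby("pH", sort=True):
        rec = TitrationRecord(pH=float(pH))
        steps = sorted(g["step"].unique())
        rec.steps = [int(s) for s in steps]
        for si, gs in g.groupby("site_id"):
            gs = gs.sort_values("step")
            rec.lam[int(si)] = gs["lambda"].tolist()
            z = gs["zeta"]
            if not z.isna().all():
                rec.zeta[int(si)] = z.tolist()
        records.append(rec)
    return records
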