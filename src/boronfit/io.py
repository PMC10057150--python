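"""File I/O: coordinate sets (XYZ/PDB/mol2), torsion definitions and energy
tables.

Multi-frame XYZ and (multi-MODEL) PDB carry coordinates only; the chemical
description (types, charges, bonds) travels in a mol2 file or in the minimal
topology text format of :mod:`boronfit.topology`. mol2 and PDB parsing is
delegated to MDAnalysis; user-facing index files are 1-based and converted on
read.
"""

from __future__ import annotations

import warnings

import numpy as np

from .conformers import TorsionDefinition
from .errors import FormatError
from .topology import Atom, Conformer, ConformerSet, Topology


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------


def read_xyz(path) -> tuple[list[str], ConformerSet]:
    """Read a (multi-frame) XYZ file; returns atom names and frames."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="XYZ")
        names = [str(n) for n in u.atoms.names]
        frames = ConformerSet(
            Conformer(u.atoms.positions.astype(float).copy()) for _ in u.trajectory
        )
    return names, frames


def write_xyz(path, names, conformers, comment: str = "") -> None:
    n = len(names)
    with open(path, "w") as fh:
        for m, frame in enumerate(conformers):
            fh.write(f"{n}\n{comment} frame {m}\n")
            for name, (x, y, z) in zip(names, frame.coords):
                fh.write(f"{name:<4s} {x:14.8f} {y:14.8f} {z:14.8f}\n")


# ---------------------------------------------------------------------------
# PDB / mol2 (MDAnalysis-backed)
# ---------------------------------------------------------------------------


def read_pdb(path) -> tuple[list[str], ConformerSet]:
    """Coordinates from ATOM/HETATM records; frames split on MODEL/END."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="PDB")
        names = [str(n) for n in u.atoms.names]
        frames = ConformerSet(
            Conformer(u.atoms.positions.astype(float).copy()) for _ in u.trajectory
        )
    return names, frames


def read_mol2(path) -> tuple[Topology, ConformerSet]:
    """Topology (names, types, charges, bonds) plus coordinates from a mol2
    file. The atom-type column is taken verbatim as the force-field label."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="MOL2")
        charges = (
            u.atoms.charges if hasattr(u.atoms, "charges") else np.zeros(len(u.atoms))
        )
        atoms = [
            Atom(str(n), str(t), float(q))
            for n, t, q in zip(u.atoms.names, u.atoms.types, charges)
        ]
        bonds = [(int(b[0]), int(b[1])) for b in u.bonds.indices]
        frames = ConformerSet(
            Conformer(u.atoms.positions.astype(float).copy()) for _ in u.trajectory
        )
    return Topology(atoms, bonds), frames


def write_mol2(path, top: Topology, conformer: Conformer, name: str = "MOL") -> None:
    lines = [
        "@<TRIPOS>MOLECULE",
        name,
        f"{top.n_atoms} {len(top.bonds)} 0 0 0",
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for i, (a, (x, y, z)) in enumerate(zip(top.atoms, conformer.coords), start=1):
        lines.append(
            f"{i:>4} {a.name:<4} {x:10.4f} {y:10.4f} {z:10.4f} "
            f"{a.type:<5} 1 {name} {a.charge:9.4f}"
        )
    lines.append("@<TRIPOS>BOND")
    for bi, (i, j) in enumerate(top.bonds, start=1):
        lines.append(f"{bi:>4} {i + 1:>4} {j + 1:>4} 1")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Small tables
# ---------------------------------------------------------------------------


def _records(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            yield lineno, line.replace(",", " ").split()


def read_torsion_defs(path) -> list[TorsionDefinition]:
    """Torsion definition file: ``label i j k l [atom-name string]`` per line,
    1-based indices."""
    defs = []
    for lineno, fields in _records(path):
        if len(fields) < 5:
            raise FormatError("need 'label i j k l'", path=path, line=lineno)
        try:
            idx = tuple(int(f) - 1 for f in fields[1:5])
        except ValueError as exc:
            raise FormatError(str(exc), path=path, line=lineno) from exc
        if any(i < 0 for i in idx):
            raise FormatError("indices are 1-based", path=path, line=lineno)
        defs.append(
            TorsionDefinition(fields[0], idx, " ".join(fields[5:]))
        )
    return defs


def read_delta_e(path) -> tuple[list[str], list[float]]:
    """Two-column relative-energy table: ``label  ΔE(kcal/mol)`` per line."""
    labels, values = [], []
    for lineno, fields in _records(path):
        if len(fields) != 2:
            raise FormatError("need 'label value'", path=path, line=lineno)
        try:
            values.append(float(fields[1]))
        except ValueError as exc:
            raise FormatError(str(exc), path=path, line=lineno) from exc
        labels.append(fields[0])
    return labels, values


def read_reference_table(path):
    """Reference-minima table: rows ``label ΔE percent τ…`` (one angle column
    per torsion). A comment header ``# label dE percent tau1 tau2 …`` names
    the torsion columns; otherwise they are called tau1, tau2, …"""
    from .analysis import ReferenceRow

    tau_names = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        cols = first[1:].split()
        if len(cols) > 3:
            tau_names = cols[3:]
    rows = []
    for lineno, fields in _records(path):
        if len(fields) < 4:
            raise FormatError("need 'label dE percent tau...'", path=path, line=lineno)
        try:
            de, pct = float(fields[1]), float(fields[2])
            taus = [float(f) for f in fields[3:]]
        except ValueError as exc:
            raise FormatError(str(exc), path=path, line=lineno) from exc
        names = tau_names or [f"tau{i + 1}" for i in range(len(taus))]
        if len(names) != len(taus):
            raise FormatError("torsion column count mismatch", path=path, line=lineno)
        rows.append(ReferenceRow(fields[0], de, pct, dict(zip(names, taus))))
    return rows
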