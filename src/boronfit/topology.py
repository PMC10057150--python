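"""Molecular topology, conformer containers, and bonded-term enumeration.

A :class:`Topology` is intentionally minimal: named atoms with force-field
atom-type labels and partial charges, plus an explicit bond list. Atom typing
is user-supplied (or comes from a fixture/mol2 file); no perception from
chemical structure is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoronfitError, FormatError
from .params import WILDCARD, AtomTypeKey, ParameterSet


@dataclass(frozen=True)
class Atom:
    name: str
    type: str  # force-field atom-type label, e.g. "oh"
    charge: float = 0.0  # e


@dataclass
class Topology:
    atoms: list[Atom]
    bonds: list[tuple[int, int]]  # 0-based index pairs

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        norm = []
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise BoronfitError(f"bond index out of range: ({i}, {j})")
            if i == j:
                raise BoronfitError(f"self-bond on atom {i}")
            pair = (min(i, j), max(i, j))
            if pair in seen:
                raise BoronfitError(f"duplicate bond {pair}")
            seen.add(pair)
            norm.append(pair)
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self) -> list[list[int]]:
        nb: list[list[int]] = [[] for _ in self.atoms]
        for i, j in self.bonds:
            nb[i].append(j)
            nb[j].append(i)
        return [sorted(x) for x in nb]

    def type_of(self, i: int) -> str:
        return self.atoms[i].type


@dataclass
class Conformer:
    coords: np.ndarray  # (N, 3) Å
    qm_energy: float | None = None  # kcal/mol

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise BoronfitError(f"coordinates must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise BoronfitError("non-finite coordinates")


class ConformerSet(list):
    """An ordered list of :class:`Conformer` frames sharing one atom order."""

    def __init__(self, frames=()):
        super().__init__(frames)
        if self:
            n = self[0].coords.shape[0]
            for m, f in enumerate(self):
                if f.coords.shape[0] != n:
                    raise BoronfitError(f"frame {m} has {f.coords.shape[0]} atoms, expected {n}")

    @property
    def qm_energies(self) -> np.ndarray | None:
        vals = [f.qm_energy for f in self]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)

    def coords_array(self) -> np.ndarray:
        return np.stack([f.coords for f in self])


@dataclass
class TermLists:
    """Enumerated bonded interactions of a topology (0-based index tuples)."""

    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    propers: list[tuple[int, int, int, int]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int]] = field(default_factory=list)


def _match_improper(types3, key_labels) -> bool:
    """Can the three outer labels of an improper key be assigned to the three
    neighbor types (order-free, wildcards allowed)?"""
    want = [key_labels[0], key_labels[1], key_labels[3]]

    def assign(remaining, pool):
        if not remaining:
            return True
        lab = remaining[0]
        for idx, t in enumerate(pool):
            if lab == WILDCARD or lab == t:
                if assign(remaining[1:], pool[:idx] + pool[idx + 1:]):
                    return True
        return False

    return assign(want, list(types3))


def enumerate_terms(top: Topology, pset: ParameterSet | None = None) -> TermLists:
    """List every bonded interaction of ``top``.

    Angles are all length-2 bond paths (counted once per (i,j,k)/(k,j,i)
    pair), propers all length-3 paths (once per orientation of the central
    bond). Impropers need a parameter set: one term is emitted for each
    improper key that matches an atom with exactly three neighbors (the
    central atom sits third in the key, AMBER-style); the outer atoms are
    assigned in the lowest-index order that matches the key.
    """
    nb = top.neighbors()
    terms = TermLists(bonds=list(top.bonds))
    for j in range(top.n_atoms):
        for a in range(len(nb[j])):
            for b in range(a + 1, len(nb[j])):
                terms.angles.append((nb[j][a], j, nb[j][b]))
    seen = set()
    for j, k in top.bonds:
        for orient in ((j, k), (k, j)):
            jj, kk = orient
            for i in nb[jj]:
                if i == kk:
                    continue
                for l in nb[kk]:
                    if l == jj or l == i:
                        continue
                    quad = (i, jj, kk, l)
                    if quad[::-1] in seen:
                        continue
                    seen.add(quad)
                    terms.propers.append(quad)
    if pset is not None and pset.impropers:
        for c in range(top.n_atoms):
            if len(nb[c]) != 3:
                continue
            ctype = top.type_of(c)
            for labels in pset.impropers:
                if labels[2] != ctype and labels[2] != WILDCARD:
                    continue
                if not _match_improper([top.type_of(x) for x in nb[c]], labels):
                    continue
                placed = _place_improper(nb[c], [top.type_of(x) for x in nb[c]], labels)
                if placed is not None:
                    i, j2, l = placed
                    terms.impropers.append((i, j2, c, l))
                    break  # one improper per center
    return terms


def _place_improper(idxs, types3, labels):
    """Deterministically assign the three neighbor atoms to key positions
    (1, 2, 4): try candidate atoms in index order at each position."""
    want = [labels[0], labels[1], labels[3]]
    order = sorted(range(3), key=lambda p: idxs[p])

    def rec(pos, used):
        if pos == 3:
            return []
        for p in order:
            if p in used:
                continue
            if want[pos] == WILDCARD or want[pos] == types3[p]:
                rest = rec(pos + 1, used | {p})
                if rest is not None:
                    return [idxs[p]] + rest
        return None

    return rec(0, set())


def proper_key(top: Topology, quad) -> AtomTypeKey:
    return AtomTypeKey(tuple(top.type_of(x) for x in quad))


# ---------------------------------------------------------------------------
# Minimal-topology text format
# ---------------------------------------------------------------------------
# One record per line; blank lines and '#' comments ignored. A 4-field line is
# an atom ("index name type charge", 1-based contiguous indices); a 2-field
# line is a bond ("i j", 1-based). Example:
#     1  B1   b    0.3000
#     2  O1   oh  -0.6000
#     1  2


def read_topology(path) -> Topology:
    atoms: list[tuple[int, Atom]] = []
    bonds: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            try:
                if len(fields) == 4:
                    idx = int(fields[0])
                    atoms.append((idx, Atom(fields[1], fields[2], float(fields[3]))))
                elif len(fields) == 2:
                    bonds.append((int(fields[0]) - 1, int(fields[1]) - 1))
                else:
                    raise ValueError(f"expected 2 or 4 fields, got {len(fields)}")
            except ValueError as exc:
                raise FormatError(str(exc), path=path, line=lineno) from exc
    atoms.sort(key=lambda t: t[0])
    if [i for i, _ in atoms] != list(range(1, len(atoms) + 1)):
        raise FormatError("atom indices must be contiguous from 1", path=path)
    return Topology([a for _, a in atoms], bonds)


def write_topology(top: Topology, path) -> None:
    lines = ["# minimal topology: atom lines 'index name type charge', bond lines 'i j' (1-based)"]
    for i, a in enumerate(top.atoms, start=1):
        lines.append(f"{i:>3}  {a.name:<4} {a.type:<3} {a.charge:9.4f}")
    for i, j in top.bonds:
        lines.append(f"{i + 1:>3} {j + 1:>3}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
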