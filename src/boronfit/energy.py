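"""AMBER-functional-form molecular-mechanics energy for a single molecule.

    E = Σ_bonds K_r (r − r_eq)²
      + Σ_angles K_θ (θ − θ_eq)²            (Δθ in radians)
      + Σ_torsions (V_n / divider) (1 + cos(n·φ − γ))
      + Σ_impropers (same cosine form)
      + Coulomb + 12-6 Lennard-Jones        (optional)

The cosine argument n·φ − γ is formed in degrees and converted to radians in
one step; n is used literally even when negative or non-integer. Nonbonded
interactions are gas-phase (no cutoff, no periodicity): 1-2 and 1-3 pairs are
excluded, 1-4 pairs scaled by 1/1.2 (electrostatics) and 1/2.0 (LJ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterGapError
from .params import AtomTypeKey, ParameterSet
from .topology import Conformer, TermLists, Topology, enumerate_terms
from . import geometry

COULOMB_CONSTANT = 332.0522173  # kcal Å / (mol e²)


@dataclass
class NonbondedParams:
    """Per-atom-type 12-6 LJ parameters plus the AMBER 1-4 scale factors.

    ``lj`` maps an atom-type label to (R*, ε): R* is the per-atom van der
    Waals radius in Å (pair minimum at R*_i + R*_j), ε the well depth in
    kcal/mol, combined by Lorentz–Berthelot rules.
    """

    lj: dict[str, tuple[float, float]] = field(default_factory=dict)
    scee: float = 1.2  # 1-4 electrostatic divisor
    scnb: float = 2.0  # 1-4 LJ divisor

    def __post_init__(self):
        for t, (rstar, eps) in self.lj.items():
            if rstar <= 0 or eps < 0:
                raise ValueError(f"invalid LJ parameters for type {t!r}")


def builtin_lj_params() -> NonbondedParams:
    """LJ table shipped with the package (GAFF-like values for the organic
    types; the boron radius/well depth is this package's own choice,
    documented in the methods note)."""
    from importlib.resources import files

    lj = {}
    path = files("boronfit").joinpath("data/lj_params.dat")
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        t, rstar, eps = line.split()
        lj[t] = (float(rstar), float(eps))
    return NonbondedParams(lj=lj)


@dataclass
class EnergyReport:
    """Total energy with a per-component and per-term breakdown (kcal/mol)."""

    total: float
    components: dict[str, float]
    term_energies: dict[str, list[tuple[tuple, float]]] = field(default_factory=dict)


def _torsion_energy(terms, phi_deg: float) -> float:
    e = 0.0
    for t in terms:
        e += (t.v_n / t.divider) * (1.0 + np.cos(np.radians(t.n * phi_deg - t.gamma)))
    return e


def bonded_energy(
    top: Topology,
    pset: ParameterSet,
    conformer: Conformer,
    terms: TermLists | None = None,
) -> EnergyReport:
    """Bond + angle + proper + improper energy with per-term breakdown.

    Raises :class:`ParameterGapError` listing every unresolvable key before
    any energy is reported.
    """
    if terms is None:
        terms = enumerate_terms(top, pset)
    coords = conformer.coords
    missing: list[tuple] = []
    per_term: dict[str, list] = {"bond": [], "angle": [], "proper": [], "improper": []}

    bond_params, angle_params, proper_params, improper_params = [], [], [], []
    for i, j in terms.bonds:
        p = pset.lookup_bond(AtomTypeKey((top.type_of(i), top.type_of(j))))
        if p is None:
            missing.append((top.type_of(i), top.type_of(j)))
        bond_params.append(p)
    for i, j, k in terms.angles:
        p = pset.lookup_angle(
            AtomTypeKey((top.type_of(i), top.type_of(j), top.type_of(k)))
        )
        if p is None:
            missing.append((top.type_of(i), top.type_of(j), top.type_of(k)))
        angle_params.append(p)
    for quad in terms.propers:
        tl = pset.lookup_dihedral(AtomTypeKey(tuple(top.type_of(x) for x in quad)))
        if not tl:
            missing.append(tuple(top.type_of(x) for x in quad))
        proper_params.append(tl)
    for quad in terms.impropers:
        tl = pset.lookup_improper(AtomTypeKey(tuple(top.type_of(x) for x in quad)))
        if not tl:
            # enumerate_terms only emits impropers that matched a key, but a
            # caller may pass hand-built TermLists
            key = AtomTypeKey(tuple(top.type_of(x) for x in quad))
            tl = _wildcard_improper(pset, top, quad)
            if not tl:
                missing.append(key.labels)
        improper_params.append(tl)
    if missing:
        # deduplicate preserving order
        uniq = list(dict.fromkeys(missing))
        raise ParameterGapError(uniq)

    e_bond = 0.0
    for (i, j), p in zip(terms.bonds, bond_params):
        r = geometry.measure_bond(coords, i, j)
        e = p.k_r * (r - p.r_eq) ** 2
        per_term["bond"].append(((i, j), e))
        e_bond += e
    e_angle = 0.0
    for (i, j, k), p in zip(terms.angles, angle_params):
        th = geometry.measure_angle(coords, i, j, k)
        e = p.k_theta * np.radians(th - p.theta_eq) ** 2
        per_term["angle"].append(((i, j, k), e))
        e_angle += e
    e_proper = 0.0
    for quad, tl in zip(terms.propers, proper_params):
        phi = geometry.measure_torsion(coords, *quad)
        e = _torsion_energy(tl, phi)
        per_term["proper"].append((quad, e))
        e_proper += e
    e_improper = 0.0
    for quad, tl in zip(terms.impropers, improper_params):
        phi = geometry.measure_torsion(coords, *quad)
        e = _torsion_energy(tl, phi)
        per_term["improper"].append((quad, e))
        e_improper += e

    components = {
        "bond": e_bond,
        "angle": e_angle,
        "proper": e_proper,
        "improper": e_improper,
    }
    return EnergyReport(sum(components.values()), components, per_term)


def _wildcard_improper(pset, top, quad):
    from .topology import _match_improper

    ctype = top.type_of(quad[2])
    outer = [top.type_of(quad[0]), top.type_of(quad[1]), top.type_of(quad[3])]
    for labels, tl in pset.impropers.items():
        if labels[2] in (ctype, "X") and _match_improper(outer, labels):
            return list(tl)
    return []


def pair_exclusions(top: Topology) -> tuple[set, set]:
    """(excluded 1-2/1-3 pairs, scaled 1-4 pairs), as frozensets of pairs.

    A pair whose shortest bond-path length is 3 but that is also connected by
    a shorter path (small rings) is treated by its shortest path, matching
    the usual exclusion-list construction.
    """
    nb = top.neighbors()
    n = top.n_atoms
    excluded, scaled = set(), set()
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        for d in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in nb[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if v <= s:
                continue
            if d in (1, 2):
                excluded.add((s, v))
            elif d == 3:
                scaled.add((s, v))
    return excluded, scaled


def nonbonded_energy(
    top: Topology, nb: NonbondedParams, conformer: Conformer
) -> EnergyReport:
    """Gas-phase Coulomb + 12-6 LJ over all non-excluded pairs."""
    missing = sorted(
        {a.type for a in top.atoms if a.type not in nb.lj}
    )
    if missing:
        raise ParameterGapError([(t,) for t in missing])
    coords = conformer.coords
    charges = np.array([a.charge for a in top.atoms])
    excluded, scaled = pair_exclusions(top)
    e_coul = e_lj = 0.0
    n = top.n_atoms
    for i in range(n):
        ri, ei = nb.lj[top.atoms[i].type]
        for j in range(i + 1, n):
            if (i, j) in excluded:
                continue
            r = float(np.linalg.norm(coords[j] - coords[i]))
            rj, ej = nb.lj[top.atoms[j].type]
            eps = np.sqrt(ei * ej)
            rmin = ri + rj
            x6 = (rmin / r) ** 6
            lj = eps * (x6 * x6 - 2.0 * x6)
            coul = COULOMB_CONSTANT * charges[i] * charges[j] / r
            if (i, j) in scaled:
                lj /= nb.scnb
                coul /= nb.scee
            e_lj += lj
            e_coul += coul
    comps = {"coulomb": e_coul, "lj": e_lj}
    return EnergyReport(e_coul + e_lj, comps)


def total_mm_energy(
    top: Topology,
    pset: ParameterSet,
    conformer: Conformer,
    nb: NonbondedParams | None = None,
    terms: TermLists | None = None,
) -> EnergyReport:
    """E_MM for one conformer: bonded terms plus, when ``nb`` is given, the
    gas-phase nonbonded terms. Without ``nb`` the energy is bonded-only,
    which is the appropriate mode when nonbonded settings are unknown."""
    rep = bonded_energy(top, pset, conformer, terms=terms)
    components = dict(rep.components)
    if nb is not None:
        nrep = nonbonded_energy(top, nb, conformer)
        components.update(nrep.components)
    return EnergyReport(sum(components.values()), components, rep.term_energies)
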