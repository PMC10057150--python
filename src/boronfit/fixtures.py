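"""Deterministic toy boronate fixtures.

Each fixture is a small (≤25-atom) tetrahedral boronate: a boron center
carrying the characteristic warhead substituents — hydroxyls (``oh``/``ho``),
an adduct oxygen that may link to a serine-side-chain stub
(``oh``–``2c``–``cx``) or to a methyl ester-like arm (``o``–``c3``), and a
phenyl, benzyl, α-aminobenzyl or (methylamino)methyl carbon substituent.
They are reduced analogs, not the full compounds the parameter library was
fitted on: they exist so that every bonded term that can occur in a small
fragment resolves against the built-in library plus the shipped GAFF-like
fallback subset, and so the fitting and analysis machinery can be exercised
end to end without external data.

Geometries are grown from the boron center by natural-extension placement at
the equilibrium bond lengths and angles of the parameter set, so bond strain
is zero by construction. Angle strain is zero only where the printed
equilibria are mutually consistent; at the benzylic ``c2`` center (109.5°,
120.97° and 123.3° equilibria sharing four substituents) and at ring ipso
carbons no strain-free embedding exists and a small residual remains.

:func:`library_key_audit` reports which fitted torsion keys are realized in
at least one fixture and which cannot occur in fragments this small.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .conformers import TorsionDefinition
from .energy import NonbondedParams, builtin_lj_params
from .geometry import nerf_place, rotation_about_axis
from .params import (
    AtomTypeKey,
    ParameterSet,
    builtin_boronate_params,
    gaff_fallback_params,
    merged,
)
from .topology import Atom, Conformer, Topology, enumerate_terms, proper_key

FIXTURE_KINDS = ("phenyl", "benzyl", "benzylamino", "methylamino")

# nominal per-type point charges for the toy fixtures (e); not RESP-derived
_CHARGES = {
    "b": 0.50, "o": -0.50, "oh": -0.60, "ho": 0.40, "c2": -0.10, "c3": -0.05,
    "ca": -0.10, "ha": 0.12, "h1": 0.06, "hc": 0.04, "n3": -0.70, "hn": 0.35,
    "2c": 0.10, "cx": -0.10,
}


class Fixture(NamedTuple):
    topology: Topology
    conformer: Conformer
    torsions: list[TorsionDefinition]


def fixture_params() -> ParameterSet:
    """Built-in boronate library overlaid on the shipped fallback subset."""
    return merged(builtin_boronate_params(), gaff_fallback_params())


class _Builder:
    """Grows a molecule atom by atom at equilibrium internal coordinates."""

    def __init__(self, pset: ParameterSet):
        self.pset = pset
        self.atoms: list[Atom] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[tuple[int, int]] = []

    def _r_eq(self, t1: str, t2: str) -> float:
        p = self.pset.lookup_bond(AtomTypeKey((t1, t2)))
        if p is None:
            raise KeyError(f"no bond parameter {t1}-{t2}")
        return p.r_eq

    def _theta_eq(self, t1: str, t2: str, t3: str) -> float:
        p = self.pset.lookup_angle(AtomTypeKey((t1, t2, t3)))
        if p is None:
            raise KeyError(f"no angle parameter {t1}-{t2}-{t3}")
        return p.theta_eq

    def add(self, name, type_, parent=None, ref2=None, ref3=None,
            r=None, theta=None, phi=0.0) -> int:
        """Place one atom. r defaults to the parent-bond r_eq, theta to the
        ref2-parent-new θ_eq; phi is the ref3-ref2-parent-new torsion."""
        idx = len(self.atoms)
        if parent is not None and r is None:
            r = self._r_eq(type_, self.atoms[parent].type)
        if ref2 is not None and theta is None:
            theta = self._theta_eq(self.atoms[ref2].type,
                                   self.atoms[parent].type, type_)
        if parent is None:
            pos = np.zeros(3)
        elif ref2 is None:
            pos = self.coords[parent] + np.array([r, 0.0, 0.0])
        elif ref3 is None:
            d = self.coords[ref2] - self.coords[parent]
            d /= np.linalg.norm(d)
            rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), theta)
            pos = self.coords[parent] + r * (rot @ d)
        else:
            pos = nerf_place(self.coords[ref3], self.coords[ref2],
                             self.coords[parent], r, theta, phi)
        self.atoms.append(Atom(name, type_, _CHARGES[type_]))
        self.coords.append(np.asarray(pos, dtype=float))
        if parent is not None:
            self.bonds.append((parent, idx))
        return idx

    def bond(self, i: int, j: int):
        self.bonds.append((min(i, j), max(i, j)))

    def add_phenyl(self, attach: int, ref2: int, ref3: int,
                   theta: float = 120.0, phi: float = 0.0) -> int:
        """Attach a benzene ring (6 ca + 5 ha) to ``attach``; returns the
        ipso index. The ipso substituent angle is split evenly (120°/120°)
        to minimize angle strain at the junction."""
        # ring tilt 150° (not 180°): keeps every torsion through the
        # attachment bond away from the ±180° seam, where terms with
        # non-integer periodicity are discontinuous
        c1 = self.add("C1", "ca", attach, ref2, ref3, theta=None, phi=phi)
        c2 = self.add("C2", "ca", c1, attach, ref2, theta=theta, phi=150.0)
        c3 = self.add("C3", "ca", c2, c1, attach, theta=120.0, phi=180.0)
        c4 = self.add("C4", "ca", c3, c2, c1, theta=120.0, phi=0.0)
        c5 = self.add("C5", "ca", c4, c3, c2, theta=120.0, phi=0.0)
        c6 = self.add("C6", "ca", c5, c4, c3, theta=120.0, phi=0.0)
        self.bond(c6, c1)
        for c, p, g in ((c2, c1, c3), (c3, c2, c4), (c4, c3, c5),
                        (c5, c4, c6), (c6, c5, c1)):
            self.add(f"H{c}", "ha", c, p, g, theta=120.0, phi=180.0)
        return c1

    def build(self) -> tuple[Topology, Conformer]:
        top = Topology(list(self.atoms), list(self.bonds))
        return top, Conformer(np.array(self.coords))


def _tetra(b: _Builder, center, first, second=None):
    """Helper phi values for the 3rd/4th substituents of a tetrahedral
    center are ±120°, which reproduces 109.47° sibling angles exactly."""


def _phenyl() -> Fixture:
    b = _Builder(fixture_params())
    B = b.add("B", "b")
    o1 = b.add("O1", "oh", B)                                  # serine-link O
    o2 = b.add("O2", "oh", B, o1)                              # hydroxyl
    o3 = b.add("O3", "oh", B, o1, o2, phi=120.0)               # hydroxyl
    c1 = b.add_phenyl(B, o1, o2, phi=-120.0)
    h2 = b.add("HO2", "ho", o2, B, o1, phi=180.0)
    h3 = b.add("HO3", "ho", o3, B, o1, phi=180.0)
    cb = b.add("CB", "2c", o1, B, o2, phi=75.0)  # off the ±180° seam
    for k, phi in (("HB1", 60.0), ("HB2", 180.0), ("HB3", -60.0)):
        b.add(k, "h1", cb, o1, B, phi=phi)
    top, conf = b.build()
    taus = [
        TorsionDefinition("tau1", (cb, o1, B, c1), "CB-O1-B-C1"),
        TorsionDefinition("tau2", (o1, B, c1, c1 + 1), "O1-B-C1-C2"),
        TorsionDefinition("tau3", (h2, o2, B, o1), "HO2-O2-B-O1"),
        TorsionDefinition("tau4", (h3, o3, B, o1), "HO3-O3-B-O1"),
    ]
    return Fixture(top, conf, taus)


def _benzyl() -> Fixture:
    b = _Builder(fixture_params())
    B = b.add("B", "b")
    o1 = b.add("O1", "oh", B)                                  # hydroxyl
    o2 = b.add("O2", "o", B, o1)                               # second OH arm
    o3 = b.add("O3", "o", B, o1, o2, phi=120.0)                # methoxy arm
    c7 = b.add("C7", "c2", B, o1, o2, phi=-120.0)              # benzylic C
    ho1 = b.add("HO1", "ho", o1, B, o2, phi=180.0)
    ho2 = b.add("HO2", "ho", o2, B, o1, phi=180.0)
    c8 = b.add("C8", "c3", o3, B, o1, phi=180.0)               # O-methyl
    for k, phi in (("H81", 60.0), ("H82", 180.0), ("H83", -60.0)):
        b.add(k, "h1", c8, o3, B, phi=phi)
    c1 = b.add_phenyl(c7, B, o1, phi=180.0)
    for k, phi in (("H71", 60.0), ("H72", -60.0)):
        b.add(k, "ha", c7, B, o1, phi=phi)
    top, conf = b.build()
    taus = [
        TorsionDefinition("tau1", (c8, o3, B, c7), "C8-O3-B-C7"),
        TorsionDefinition("tau2", (o1, B, c7, c1), "O1-B-C7-C1"),
        TorsionDefinition("tau3", (ho1, o1, B, o2), "HO1-O1-B-O2"),
        TorsionDefinition("tau4", (ho2, o2, B, o1), "HO2-O2-B-O1"),
    ]
    return Fixture(top, conf, taus)


def _benzylamino() -> Fixture:
    b = _Builder(fixture_params())
    B = b.add("B", "b")
    o1 = b.add("O1", "oh", B)
    o2 = b.add("O2", "oh", B, o1)
    o3 = b.add("O3", "oh", B, o1, o2, phi=120.0)
    c7 = b.add("C7", "c3", B, o1, o2, phi=-120.0)              # α carbon
    for o, ref in ((o1, o2), (o2, o1), (o3, o1)):
        b.add(f"HO{o}", "ho", o, B, ref, phi=180.0)
    n = b.add("N", "n3", c7, B, o1, phi=60.0)
    b.add("H7", "h1", c7, B, o1, phi=-60.0)
    c1 = b.add_phenyl(c7, B, o1, phi=180.0)
    b.add("HN1", "hn", n, c7, B, phi=60.0)
    b.add("HN2", "hn", n, c7, B, phi=180.0)
    top, conf = b.build()
    taus = [
        TorsionDefinition("tau1", (n, c7, B, o1), "N-C7-B-O1"),
        TorsionDefinition("tau2", (o1, B, c7, c1), "O1-B-C7-C1"),
        TorsionDefinition("tau3", (5, o1, B, o2), "HO1-O1-B-O2"),
        TorsionDefinition("tau4", (6, o2, B, o1), "HO2-O2-B-O1"),
    ]
    return Fixture(top, conf, taus)


def _methylamino() -> Fixture:
    b = _Builder(fixture_params())
    B = b.add("B", "b")
    o1 = b.add("O1", "oh", B)                                  # serine-link O
    o2 = b.add("O2", "oh", B, o1)
    o3 = b.add("O3", "oh", B, o1, o2, phi=120.0)
    c7 = b.add("C7", "c3", B, o1, o2, phi=-120.0)              # B-CH2
    ho2 = b.add("HO2", "ho", o2, B, o1, phi=180.0)
    ho3 = b.add("HO3", "ho", o3, B, o1, phi=180.0)
    # staggered groups are rotated 15° as a block (relative phis, hence
    # sibling angles, unchanged) so no torsion sits on the ±180° seam
    cb = b.add("CB", "2c", o1, B, o2, phi=75.0)
    b.add("HB1", "h1", cb, o1, B, phi=45.0)
    b.add("HB2", "h1", cb, o1, B, phi=-75.0)
    cx = b.add("CA", "cx", cb, o1, B, phi=165.0)
    for k, phi in (("HA1", 60.0), ("HA2", 180.0), ("HA3", -60.0)):
        b.add(k, "hc", cx, cb, o1, phi=phi)
    n = b.add("N", "n3", c7, B, o1, phi=165.0)
    b.add("H71", "h1", c7, B, o1, phi=45.0)
    b.add("H72", "h1", c7, B, o1, phi=-75.0)
    hn = b.add("HN", "hn", n, c7, B, phi=60.0)
    c9 = b.add("C9", "c3", n, c7, B, phi=180.0)
    for k, phi in (("H91", 60.0), ("H92", 180.0), ("H93", -60.0)):
        b.add(k, "hc", c9, n, c7, phi=phi)
    top, conf = b.build()
    taus = [
        TorsionDefinition("tau1", (cb, o1, B, c7), "CB-O1-B-C7"),
        TorsionDefinition("tau2", (o1, B, c7, n), "O1-B-C7-N"),
        TorsionDefinition("tau3", (ho2, o2, B, o1), "HO2-O2-B-O1"),
        TorsionDefinition("tau4", (ho3, o3, B, o1), "HO3-O3-B-O1"),
    ]
    return Fixture(top, conf, taus)


_BUILDERS = {
    "phenyl": _phenyl,
    "benzyl": _benzyl,
    "benzylamino": _benzylamino,
    "methylamino": _methylamino,
}


def toy_boronate_fixture(kind: str) -> Fixture:
    """Build the requested fixture: (Topology, Conformer, four τ definitions
    for the rotatable bonds at boron). Deterministic: identical output on
    every call."""
    if kind not in _BUILDERS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return _BUILDERS[kind]()


def fixture_nonbonded() -> NonbondedParams:
    return builtin_lj_params()


def library_key_audit() -> dict:
    """Which fitted proper-torsion keys of the built-in library occur in at
    least one fixture, and which cannot be realized in fragments this small.

    Returns ``{"realized": {key: [fixture kinds]}, "unrealized": [keys],
    "improper_realized": bool}``.
    """
    lib = builtin_boronate_params()
    pset = fixture_params()
    realized: dict[tuple, list[str]] = {ck: [] for ck in lib.propers}
    improper_hit = False
    for kind in FIXTURE_KINDS:
        fix = toy_boronate_fixture(kind)
        terms = enumerate_terms(fix.topology, pset)
        seen = {proper_key(fix.topology, q).canonical() for q in terms.propers}
        for ck in realized:
            if ck in seen:
                realized[ck].append(kind)
        for quad in terms.impropers:
            labels = tuple(fix.topology.type_of(x) for x in quad)
            if labels in lib.impropers:
                improper_hit = True
    return {
        "realized": {ck: kinds for ck, kinds in realized.items() if kinds},
        "unrealized": sorted(ck for ck, kinds in realized.items() if not kinds),
        "improper_realized": improper_hit,
    }
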