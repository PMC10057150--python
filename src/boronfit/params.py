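"""Force-field parameter model and the built-in boronate parameter library.

Parameters follow the additive AMBER functional form and its frcmod
conventions: bonds and angles are harmonic, torsions are cosine series
``(V_n / divider) * (1 + cos(n*phi - gamma))``, and impropers reuse the same
cosine form with the central (trigonal) atom third in the four-type key.

Units throughout: kcal/mol for energies and barrier heights, Å for lengths,
degrees for angles and phases; angle force constants are per radian² as is
conventional in AMBER parameter tables.

The built-in library covers tetrahedral boronate warheads — phenyl-, benzyl-,
benzylamino- and methylamino-boronates covalently adducted to a serine-like
oxygen — using GAFF/ff14SB atom-type labels (``b``, ``o``, ``oh``, ``ho``,
``c2``, ``c3``, ``ca``, ``ha``, ``h1``, ``n3``, ``2c``, ``cx``). Torsion
barriers were fitted against quantum single-point energies; several fitted
periodicities are non-integer or negative and are stored and evaluated
literally (see :mod:`boronfit.frcmod` for export dialects).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .errors import InvalidKeyError

WILDCARD = "X"
_LABEL_RE = re.compile(r"^[a-z0-9]{1,2}$")


def _check_labels(labels: tuple[str, ...]) -> tuple[str, ...]:
    if len(labels) not in (2, 3, 4):
        raise InvalidKeyError(f"atom-type key needs 2, 3 or 4 labels, got {labels!r}")
    for lab in labels:
        if lab != WILDCARD and not _LABEL_RE.match(lab):
            raise InvalidKeyError(f"bad atom-type label {lab!r} in {labels!r}")
    return labels


@dataclass(frozen=True)
class AtomTypeKey:
    """An ordered tuple of 2 (bond), 3 (angle) or 4 (dihedral) atom-type labels.

    Labels are lowercase alphanumeric, at most two characters, or the wildcard
    ``"X"`` (allowed only at the outer positions of a four-label key).
    """

    labels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "labels", _check_labels(tuple(self.labels)))

    @property
    def arity(self) -> int:
        return len(self.labels)

    def reversed(self) -> "AtomTypeKey":
        return AtomTypeKey(self.labels[::-1])

    def canonical(self) -> tuple[str, ...]:
        """Direction-independent dict key: the lexicographically smaller of
        the label tuple and its reverse."""
        return min(self.labels, self.labels[::-1])

    @property
    def is_wildcard(self) -> bool:
        return WILDCARD in self.labels

    def __str__(self) -> str:
        return "-".join(self.labels)


def key(*labels: str) -> AtomTypeKey:
    """Convenience constructor: ``key("oh", "b", "ca", "ca")``."""
    return AtomTypeKey(tuple(labels))


@dataclass(frozen=True)
class BondParam:
    key: AtomTypeKey
    k_r: float  # kcal/(mol Å²)
    r_eq: float  # Å

    def __post_init__(self):
        if self.key.arity != 2:
            raise InvalidKeyError(f"bond key must have 2 labels: {self.key}")
        if self.k_r <= 0 or self.r_eq <= 0:
            raise ValueError(f"bond parameters must be positive: {self}")


@dataclass(frozen=True)
class AngleParam:
    key: AtomTypeKey
    k_theta: float  # kcal/(mol rad²)
    theta_eq: float  # degrees

    def __post_init__(self):
        if self.key.arity != 3:
            raise InvalidKeyError(f"angle key must have 3 labels: {self.key}")
        if self.k_theta <= 0 or not (0.0 < self.theta_eq < 180.0):
            raise ValueError(f"invalid angle parameters: {self}")


@dataclass(frozen=True)
class DihedralTermParam:
    """One cosine term of a (possibly multi-term) torsion series.

    ``v_n`` may be negative and ``n`` may be negative or non-integer, exactly
    as obtained from the fit; both are used literally in the energy
    expression. Note cos(-n*phi - gamma) = cos(n*phi + gamma), so the sign of
    ``n`` is physically meaningful whenever gamma != 0 (mod 180).
    """

    key: AtomTypeKey
    divider: int  # frcmod IDIVF
    v_n: float  # kcal/mol
    gamma: float  # degrees
    n: float  # periodicity, real-valued
    is_improper: bool = False

    def __post_init__(self):
        if self.key.arity != 4:
            raise InvalidKeyError(f"dihedral key must have 4 labels: {self.key}")
        if self.divider < 1:
            raise ValueError(f"divider must be >= 1: {self}")

    def same_values(self, other: "DihedralTermParam") -> bool:
        return (
            self.divider == other.divider
            and self.v_n == other.v_n
            and self.gamma == other.gamma
            and self.n == other.n
            and self.is_improper == other.is_improper
        )


@dataclass
class ParameterSet:
    """Typed store of bond/angle/proper/improper parameters.

    Bond, angle and proper-torsion lookup is symmetric under key reversal;
    improper keys are directional (central atom third). A proper key may carry
    several additive cosine terms. Adding an entry identical to an existing
    one is a no-op; adding a different entry under an existing proper key
    appends an additive term.
    """

    bonds: dict[tuple, BondParam] = field(default_factory=dict)
    angles: dict[tuple, AngleParam] = field(default_factory=dict)
    propers: dict[tuple, list[DihedralTermParam]] = field(default_factory=dict)
    impropers: dict[tuple, list[DihedralTermParam]] = field(default_factory=dict)
    provenance: dict[tuple, str] = field(default_factory=dict)

    # -- population -------------------------------------------------------

    def add_bond(self, p: BondParam, note: str = ""):
        self.bonds[p.key.canonical()] = p
        if note:
            self.provenance[("bond",) + p.key.canonical()] = note

    def add_angle(self, p: AngleParam, note: str = ""):
        self.angles[p.key.canonical()] = p
        if note:
            self.provenance[("angle",) + p.key.canonical()] = note

    def add_dihedral(self, p: DihedralTermParam, note: str = ""):
        if p.is_improper:
            store, ck = self.impropers, p.key.labels
        else:
            store, ck = self.propers, p.key.canonical()
        terms = store.setdefault(ck, [])
        if not any(t.same_values(p) for t in terms):
            terms.append(p)
        if note:
            kind = "improper" if p.is_improper else "proper"
            self.provenance[(kind,) + ck] = note

    # -- lookup -----------------------------------------------------------

    def lookup_bond(self, k: AtomTypeKey) -> BondParam | None:
        return self.bonds.get(k.canonical())

    def lookup_angle(self, k: AtomTypeKey) -> AngleParam | None:
        return self.angles.get(k.canonical())

    def lookup_dihedral(self, k: AtomTypeKey) -> list[DihedralTermParam]:
        """Resolve a proper-torsion key: exact (either direction) first, then
        wildcard ``X-j-k-X`` entries on the central pair. Empty list if
        nothing matches; the caller decides the error policy."""
        if k.arity != 4:
            raise InvalidKeyError(f"dihedral lookup needs a 4-label key: {k}")
        hit = self.propers.get(k.canonical())
        if hit:
            return list(hit)
        mid = (k.labels[1], k.labels[2])
        for ck, terms in self.propers.items():
            if ck[0] == WILDCARD and ck[3] == WILDCARD:
                if (ck[1], ck[2]) in (mid, mid[::-1]):
                    return list(terms)
        return []

    def lookup_improper(self, k: AtomTypeKey) -> list[DihedralTermParam]:
        return list(self.impropers.get(k.labels, []))

    # -- whole-set operations ---------------------------------------------

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            bonds=dict(self.bonds),
            angles=dict(self.angles),
            propers={k: list(v) for k, v in self.propers.items()},
            impropers={k: list(v) for k, v in self.impropers.items()},
            provenance=dict(self.provenance),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return (
            self.bonds == other.bonds
            and self.angles == other.angles
            and self.propers == other.propers
            and self.impropers == other.impropers
        )

    def n_entries(self) -> tuple[int, int, int, int]:
        return (
            len(self.bonds),
            len(self.angles),
            sum(len(v) for v in self.propers.values()),
            sum(len(v) for v in self.impropers.values()),
        )


def merged(primary: ParameterSet, fallback: ParameterSet) -> ParameterSet:
    """Union of two sets; on key collision the primary entry wins outright
    (fallback terms for that key are dropped, they are alternatives, not
    additive refinements)."""
    out = fallback.copy()
    out.bonds.update(primary.bonds)
    out.angles.update(primary.angles)
    for ck, terms in primary.propers.items():
        out.propers[ck] = list(terms)
    for ck, terms in primary.impropers.items():
        out.impropers[ck] = list(terms)
    out.provenance.update(primary.provenance)
    return out


# ---------------------------------------------------------------------------
# Built-in boronate library
# ---------------------------------------------------------------------------

# Fitted torsion rows (type1-type2-type3-type4, divider, V_n, gamma, n), in
# table order. Two rows appear twice with identical values (collapsed on
# load); "oh-b-c3-h1" appears twice with different values and is kept as a
# two-term additive series.
_DIHEDRAL_ROWS = [
    ("oh-b-ca-ca", 1, 15.7206, 170.366, -1.001),
    ("b-c2-ca-ca", 1, 0.7000, 180.000, 2.000),
    ("b-o-c3-c3", 1, 3.4800, 106.880, 1.500),
    ("b-o-c3-h1", 1, 4.1053, 256.511, 2.000),
    ("o-b-o-ho", 1, 0.8361, 0.000, 3.000),
    ("o-b-c2-ha", 1, 2.5070, 172.978, 0.129),
    ("o-b-c2-ca", 1, 15.7206, 170.366, -1.000),
    ("o-b-o-c3", 1, 0.8347, 0.000, 3.000),
    ("ho-o-b-c2", 1, 2.0509, 112.044, 5.000),
    ("c2-b-o-c3", 1, 2.3740, 114.599, -0.197),
    ("cx-2c-oh-b", 1, 3.4800, 106.881, 1.500),
    ("ho-oh-b-o", 1, 0.8361, 0.000, 3.000),
    ("ho-oh-b-c2", 1, 2.0509, 112.044, 5.000),
    ("ho-oh-b-ca", 1, 2.0509, 112.044, 5.000),
    ("oh-b-o-ho", 1, 0.8361, 0.000, 3.000),
    ("oh-b-oh-ho", 1, 0.8361, 0.000, 3.000),
    ("oh-b-c2-ha", 1, 2.5070, 172.978, 0.129),
    ("oh-b-c3-h1", 1, 2.5070, 172.978, 0.129),
    ("oh-b-c2-ca", 1, 15.7206, 170.366, -1.000),
    ("oh-b-c3-ca", 1, 15.7205, 170.366, 0.000),
    ("h1-2c-oh-b", 1, 4.1053, 256.511, 2.000),
    ("2c-oh-b-o", 1, 2.3743, 114.599, -0.197),
    ("2c-oh-b-c2", 1, 2.3743, 114.599, -0.197),
    ("h1-2c-oh-b", 1, 4.1053, 256.511, 2.000),
    ("oh-b-c3-n3", 1, -2.2276, 0.000, 2.156),
    ("2c-oh-b-oh", 1, -44.4201, 0.000, 1.251),
    ("2c-oh-b-c3", 1, -12.2011, 0.000, 2.000),
    ("ho-oh-b-c3", 1, 8.0608, 0.000, -0.101),
    ("oh-b-c3-h1", 1, 0.5691, 0.000, 2.385),
    ("oh-b-ca-ca", 1, 15.7206, 170.366, -1.001),
    ("2c-oh-b-ca", 1, 2.3743, 114.599, -0.197),
]

_IMPROPER_ROWS = [
    ("b-ha-c2-ha", 1, 1.1000, 180.000, 2.000),
]

# Literature bond and angle parameters for the boron environment. Two source
# conventions are recorded in the provenance notes because the original
# compilation cites them under two different reference numberings.
_BOND_ROWS = [
    ("b-o", 450.00, 1.510, "literature set A"),
    ("oh-b", 450.00, 1.510, "literature set A"),
    ("b-c2", 340.00, 1.630, "literature"),
    ("b-ca", 340.00, 1.630, "literature"),
    ("b-c3", 326.80, 1.510, "literature"),
]

_ANGLE_ROWS = [
    ("ca-c2-ha", 47.90, 123.30, "literature"),
    ("b-o-ho", 35.00, 109.50, "literature set A"),
    ("ho-oh-b", 35.00, 109.50, "literature set A"),
    ("b-c2-ha", 50.00, 109.50, "literature set B"),
    ("b-c3-h1", 50.00, 109.50, "literature set B"),
    ("b-c3-hc", 50.00, 109.50, "literature set B"),
    ("b-c3-c3", 50.00, 109.50, "literature set B"),
    ("b-c3-n3", 50.00, 109.31, "literature set B"),
    ("b-c2-ca", 127.38, 120.97, "literature set B"),
    ("b-ca-ca", 127.38, 120.97, "literature set B"),
    ("b-o-c3", 90.00, 109.50, "literature set A"),
    ("o-b-o", 90.00, 109.50, "literature set A"),
    ("oh-b-o", 90.00, 109.50, "literature set A"),
    ("oh-b-oh", 90.00, 109.50, "literature set A"),
    ("oh-b-c2", 60.00, 109.50, "literature set A"),
    ("oh-b-ca", 60.00, 109.50, "literature set A"),
    ("oh-b-c3", 60.00, 109.50, "literature set A"),
    ("o-b-c2", 60.00, 109.50, "literature set A"),
    ("2c-oh-b", 60.00, 109.50, "literature set A"),
    ("b-c3-ca", 127.38, 111.90, "literature set B"),
]


def builtin_boronate_params() -> ParameterSet:
    """The complete built-in boronate library: 31 fitted proper-torsion rows
    (29 surviving after duplicate collapse, on 28 keys), one fitted improper,
    and the 5 bond / 20 angle literature values."""
    pset = ParameterSet()
    for name, kr, req, note in _BOND_ROWS:
        pset.add_bond(BondParam(key(*name.split("-")), kr, req), note=note)
    for name, kt, te, note in _ANGLE_ROWS:
        pset.add_angle(AngleParam(key(*name.split("-")), kt, te), note=note)
    for name, div, v, g, n in _DIHEDRAL_ROWS:
        pset.add_dihedral(
            DihedralTermParam(key(*name.split("-")), div, v, g, n),
            note="fitted torsion library",
        )
    for name, div, v, g, n in _IMPROPER_ROWS:
        pset.add_dihedral(
            DihedralTermParam(key(*name.split("-")), div, v, g, n, is_improper=True),
            note="fitted torsion library",
        )
    return pset


def gaff_fallback_params() -> ParameterSet:
    """Approximate GAFF/ff14SB-derived subset shipped with the package,
    covering the organic scaffold terms (ring, methyl, amine, serine stub)
    that the boron-specific library does not; includes the wildcard torsions
    used for bonds the fitted library leaves generic."""
    from importlib.resources import files

    from .frcmod import read_frcmod

    path = files("boronfit").joinpath("data/gaff_subset.frcmod")
    return read_frcmod(str(path))


def replace_term(
    pset: ParameterSet, k: AtomTypeKey, term_index: int, **changes
) -> ParameterSet:
    """Return a copy of ``pset`` with one proper term replaced
    (``v_n=…, gamma=…, n=…``)."""
    out = pset.copy()
    terms = list(out.propers[k.canonical()])
    terms[term_index] = replace(terms[term_index], **changes)
    out.propers[k.canonical()] = terms
    return out
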