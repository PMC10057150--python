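"""Structure-set generation and quality control.

Torsion scans rotate one side of a single (acyclic) bond rigidly, so every
internal coordinate not involving the scanned torsion is preserved exactly;
the scan therefore isolates the torsional degree of freedom the way a
quantum scan of the same angle would. The coverage check verifies that a
structure set samples the angular range of each torsion to be fitted, and the
synthetic-energy oracle produces QM-like target energies (a known
molecular-mechanics surface plus an arbitrary scale offset plus Gaussian
noise) for testing the fitting machinery without any quantum chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, NonRotatableError
from .energy import NonbondedParams, total_mm_energy
from .geometry import rotation_about_axis, measure_torsion
from .params import ParameterSet
from .topology import Conformer, ConformerSet, Topology, enumerate_terms


@dataclass(frozen=True)
class TorsionDefinition:
    """A named torsion: four 0-based atom indices plus a display string."""

    label: str
    indices: tuple[int, int, int, int]
    atom_names: str = ""

    def __post_init__(self):
        if len(set(self.indices)) != 4:
            raise ValueError(f"torsion {self.label!r} needs 4 distinct atoms")


@dataclass
class CoverageReport:
    """Fraction of 30° bins (12 over (−180°, 180°]) populated per torsion."""

    fractions: dict[str, float] = field(default_factory=dict)
    populated_bins: dict[str, int] = field(default_factory=dict)
    n_bins: int = 12

    @property
    def minimum(self) -> float:
        return min(self.fractions.values()) if self.fractions else 0.0

    @property
    def warn(self) -> bool:
        """True when any fitted torsion covers less than half the circle."""
        return self.minimum < 0.5


def _moving_side(top: Topology, j: int, k: int) -> list[int]:
    """Atoms on the k/l side after deleting bond j-k; error if j-k is in a
    ring (deleting it leaves the graph connected) or not a bond."""
    if (min(j, k), max(j, k)) not in set(top.bonds):
        raise NonRotatableError(f"{j}-{k} is not a bond")
    nb = top.neighbors()
    seen = {j, k}
    stack = [k]
    side = []
    while stack:
        u = stack.pop()
        side.append(u)
        for v in nb[u]:
            if v == j and u == k:
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if j in side or len(side) + _component_size(nb, j, exclude=(j, k)) != top.n_atoms:
        raise NonRotatableError(f"bond {j}-{k} lies in a ring")
    return side


def _component_size(nb, start, exclude):
    j, k = exclude
    seen = {start, k}
    stack = [start]
    count = 0
    while stack:
        u = stack.pop()
        count += 1
        for v in nb[u]:
            if u == j and v == k:
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return count


def scan_torsion(
    top: Topology,
    conformer: Conformer,
    torsion: TorsionDefinition,
    step: float = 10.0,
) -> ConformerSet:
    """Rigid-rotation torsion scan: 360/step frames, the first being the
    input geometry; frame m has the torsion rotated by +m·step degrees
    (right-handed rotation of the l-side about the j→k axis increases the
    measured angle)."""
    if step <= 0 or abs(360.0 / step - round(360.0 / step)) > 1e-9:
        raise ValueError(f"step must divide 360: {step}")
    i, j, k, l = torsion.indices
    side = _moving_side(top, j, k)
    if l not in side:
        raise NonRotatableError(f"atom {l} is not on the moving side of {j}-{k}")
    axis = conformer.coords[k] - conformer.coords[j]
    if np.linalg.norm(axis) < 1e-12:
        raise DegenerateGeometryError(f"zero-length scan axis {j}-{k}")
    origin = conformer.coords[j]
    n_frames = int(round(360.0 / step))
    frames = []
    for m in range(n_frames):
        rot = rotation_about_axis(axis, m * step)
        coords = conformer.coords.copy()
        coords[side] = (coords[side] - origin) @ rot.T + origin
        frames.append(Conformer(coords))
    return ConformerSet(frames)


def coverage_check(
    conformers: ConformerSet, torsions: list[TorsionDefinition]
) -> CoverageReport:
    """Deterministic 30°-bin occupancy audit of a structure set."""
    report = CoverageReport()
    edges = np.linspace(-180.0, 180.0, report.n_bins + 1)
    for t in torsions:
        angles = np.array(
            [measure_torsion(f.coords, *t.indices) for f in conformers]
        )
        # (−180, 180]: put the left edge into the last bin
        idx = np.clip(
            np.searchsorted(edges, angles, side="left") - 1, 0, report.n_bins - 1
        )
        idx[angles <= -180.0 + 1e-12] = report.n_bins - 1
        populated = len(set(idx.tolist()))
        report.populated_bins[t.label] = populated
        report.fractions[t.label] = populated / report.n_bins
    return report


def synthetic_qm_energies(
    top: Topology,
    pset_true: ParameterSet,
    conformers: ConformerSet,
    noise_sd: float = 0.0,
    offset: float = 0.0,
    seed: int = 0,
    nb: NonbondedParams | None = None,
) -> np.ndarray:
    """QM-like target energies from a known parameter set:
    E = E_MM(pset_true) + offset + N(0, noise_sd²), reproducible per seed.

    Fitting against these energies with the same topology must recover
    ``pset_true`` (noiseless case) with K = −offset."""
    terms = enumerate_terms(top, pset_true)
    e = np.array(
        [
            total_mm_energy(top, pset_true, f, nb=nb, terms=terms).total
            for f in conformers
        ]
    )
    rng = np.random.default_rng(seed)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    noise = rng.normal(0.0, noise_sd, size=e.shape) if noise_sd > 0 else 0.0
    return e + offset + noise


def attach_qm_energies(conformers: ConformerSet, energies) -> ConformerSet:
    """Return a new set with per-frame qm_energy values attached."""
    energies = np.asarray(energies, dtype=float)
    if len(energies) != len(conformers):
        from .errors import AlignmentError

        raise AlignmentError(
            f"{len(energies)} energies for {len(conformers)} conformers"
        )
    return ConformerSet(
        Conformer(f.coords.copy(), qm_energy=float(e))
        for f, e in zip(conformers, energies)
    )
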