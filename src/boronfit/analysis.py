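"""Validation analytics: equilibrium conformer populations and torsional
basin statistics.

Boltzmann populations convert relative conformer energies ΔE (kcal/mol) into
equilibrium percentages p_i = 100·exp(−ΔE_i/RT)/Σ_j exp(−ΔE_j/RT) at a given
temperature (default 298 K, R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹).

Basin extraction segments a torsion trajectory on the circle: a histogram at
``bin_width`` degrees is taken, maximal circular runs of contiguous non-empty
bins form candidate basins, and basins holding less than ``min_occupancy`` of
the frames are discarded (the conventional >10% population criterion). Each
basin is summarized by the circular mean of its member angles — the correct
average across the ±180° wrap — and its occupancy fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformers import TorsionDefinition
from .errors import EmptyInputError, SchemaMismatchError
from .geometry import measure_torsion, wrap_angle
from .topology import ConformerSet

GAS_CONSTANT_KCAL = 1.987204e-3  # kcal / (mol K)


@dataclass
class BoltzmannTable:
    labels: list[str]
    delta_e: np.ndarray  # kcal/mol, re-referenced so min == 0
    percent: np.ndarray  # equilibrium population, %
    temperature: float  # K

    def rows(self):
        return list(zip(self.labels, self.delta_e, self.percent))


def boltzmann_populations(
    delta_e, temperature: float = 298.0, labels=None
) -> BoltzmannTable:
    """Equilibrium percentages of conformers from relative energies.

    Energies are re-referenced to their minimum internally, so any common
    offset is irrelevant. Populations are strictly decreasing in ΔE.
    """
    de = np.asarray(delta_e, dtype=float)
    if de.size == 0:
        raise EmptyInputError("no conformer energies given")
    if not np.all(np.isfinite(de)):
        raise ValueError("non-finite energies")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    de = de - de.min()
    w = np.exp(-de / (GAS_CONSTANT_KCAL * temperature))
    pct = 100.0 * w / w.sum()
    if labels is None:
        labels = [f"conf{i + 1}" for i in range(de.size)]
    return BoltzmannTable(list(labels), de, pct, temperature)


@dataclass
class TorsionSeries:
    label: str
    angles: np.ndarray  # degrees, (−180, 180]
    times: np.ndarray | None = None

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size and (
            self.angles.min() <= -180.0 or self.angles.max() > 180.0
        ):
            self.angles = wrap_angle(self.angles)


def torsion_timeseries(
    frames: ConformerSet, torsions: list[TorsionDefinition]
) -> list[TorsionSeries]:
    """Per-frame torsion angles for each definition, in frame order."""
    out = []
    for t in torsions:
        angles = np.array([measure_torsion(f.coords, *t.indices) for f in frames])
        out.append(TorsionSeries(t.label, angles))
    return out


@dataclass
class Basin:
    center: float  # circular mean, degrees in (−180, 180]
    occupancy: float  # fraction of frames
    support: tuple[float, float]  # bin-edge interval (may wrap past 180)


@dataclass
class BasinSummary:
    label: str
    basins: list[Basin] = field(default_factory=list)

    @property
    def centers(self) -> list[float]:
        return [b.center for b in self.basins]


def circular_mean(angles_deg) -> float:
    """Direction of the mean unit vector, degrees in (−180, 180]."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    s, c = np.sin(a).mean(), np.cos(a).mean()
    if np.hypot(s, c) < 1e-12:
        raise EmptyInputError("circular mean undefined for balanced angles")
    return wrap_angle(np.degrees(np.arctan2(s, c)))


def circular_distance(a: float, b: float) -> float:
    """|a − b| on the circle, in [0, 180]."""
    return abs(float(wrap_angle(a - b)))


def detect_basins(
    series: TorsionSeries,
    bin_width: float = 10.0,
    min_occupancy: float = 0.10,
) -> BasinSummary:
    """Segment a torsion distribution into circular basins.

    Histogram at ``bin_width``; maximal circularly-contiguous runs of
    non-empty bins are basins, separated by empty bins; runs holding fewer
    than ``min_occupancy`` of the frames are dropped. Basin centers are
    circular means of the member angles. If no bin is empty the whole circle
    is one basin.
    """
    if series.angles.size == 0:
        raise EmptyInputError(f"empty torsion series {series.label!r}")
    nbins = int(round(360.0 / bin_width))
    if abs(nbins * bin_width - 360.0) > 1e-9 or nbins < 1:
        raise ValueError(f"bin width must divide 360: {bin_width}")
    edges = np.linspace(-180.0, 180.0, nbins + 1)
    # assign to bins over (−180, 180]
    idx = np.clip(np.searchsorted(edges, series.angles, side="left") - 1, 0, nbins - 1)
    idx[series.angles <= -180.0 + 1e-12] = nbins - 1
    counts = np.bincount(idx, minlength=nbins)
    occupied = counts > 0
    if occupied.all():
        members = np.ones(series.angles.size, dtype=bool)
        return BasinSummary(
            series.label,
            [Basin(circular_mean(series.angles), 1.0, (-180.0, 180.0))],
        )
    # rotate so the scan starts at an empty bin, then find runs
    start = int(np.argmin(occupied))  # first empty bin
    order = [(start + i) % nbins for i in range(nbins)]
    basins = []
    run: list[int] = []
    for b in order:
        if occupied[b]:
            run.append(b)
        elif run:
            basins.append(run)
            run = []
    if run:
        basins.append(run)
    n = series.angles.size
    out = []
    for run_bins in basins:
        member = np.isin(idx, run_bins)
        occ = member.sum() / n
        if occ < min_occupancy:
            continue
        lo = edges[run_bins[0]]
        hi = edges[run_bins[-1] + 1]
        out.append(Basin(circular_mean(series.angles[member]), float(occ), (lo, hi)))
    out.sort(key=lambda b: b.center)
    return BasinSummary(series.label, out)


@dataclass(frozen=True)
class ReferenceRow:
    """One reference conformer: label, ΔE (kcal/mol), population %, and the
    torsion angles of its optimized geometry."""

    label: str
    delta_e: float
    percent: float
    taus: dict  # torsion label -> degrees


@dataclass
class Correspondence:
    conformer: str
    torsion: str
    reference_angle: float
    nearest_center: float | None
    distance: float | None  # circular |Δ|, degrees
    matched: bool


def compare_to_reference(
    basins: dict[str, BasinSummary],
    reference: list[ReferenceRow],
    threshold: float = 30.0,
) -> list[Correspondence]:
    """Match each reference conformer's torsion angles to the nearest
    simulated basin center (minimal circular distance); a torsion is
    "matched" when that distance is at most ``threshold`` degrees."""
    report = []
    for row in reference:
        for tlabel, ref_angle in row.taus.items():
            if tlabel not in basins:
                raise SchemaMismatchError(
                    f"reference torsion {tlabel!r} has no basin summary"
                )
            centers = basins[tlabel].centers
            if not centers:
                report.append(
                    Correspondence(row.label, tlabel, ref_angle, None, None, False)
                )
                continue
            dists = [circular_distance(ref_angle, c) for c in centers]
            best = int(np.argmin(dists))
            report.append(
                Correspondence(
                    row.label,
                    tlabel,
                    ref_angle,
                    centers[best],
                    dists[best],
                    dists[best] <= threshold,
                )
            )
    return report
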