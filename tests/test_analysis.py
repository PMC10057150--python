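"""Boltzmann populations, circular statistics, basin extraction."""

import numpy as np
import pytest

import boronfit as bf
from boronfit.analysis import (
    Basin,
    BasinSummary,
    ReferenceRow,
    TorsionSeries,
    circular_distance,
    circular_mean,
)
from boronfit.errors import EmptyInputError, SchemaMismatchError


class TestBoltzmann:
    def test_published_five_conformer_column(self):
        table = bf.boltzmann_populations([0.00, 2.16, 2.97, 3.54, 4.10])
        assert [round(p, 1) for p in table.percent] == [96.5, 2.5, 0.6, 0.2, 0.1]

    def test_published_nine_conformer_leaders(self):
        de = [0.00, 0.18, 0.54, 0.91, 1.25, 1.34, 2.28, 2.32, 2.39]
        table = bf.boltzmann_populations(de)
        assert round(table.percent[0], 1) == 37.9
        assert round(table.percent[1], 1) == 28.0

    def test_single_conformer_is_100_percent(self):
        table = bf.boltzmann_populations([0.0])
        assert table.percent[0] == 100.0

    def test_percentages_sum_to_100_and_decrease(self, rng):
        de = np.sort(rng.uniform(0, 5, size=8))
        table = bf.boltzmann_populations(de)
        assert table.percent.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(table.percent) <= 0)
        assert table.delta_e.min() == 0.0

    def test_invariant_under_common_energy_shift(self):
        a = bf.boltzmann_populations([0.0, 1.0, 2.0])
        b = bf.boltzmann_populations([10.0, 11.0, 12.0])
        assert np.allclose(a.percent, b.percent)

    def test_temperature_limits(self):
        de = [0.0, 1.0, 2.0]
        hot = bf.boltzmann_populations(de, temperature=1e9)
        assert np.allclose(hot.percent, 100.0 / 3, atol=1e-3)
        cold = bf.boltzmann_populations(de, temperature=1e-3)
        assert cold.percent[0] == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            bf.boltzmann_populations([])


class TestCircular:
    def test_wraparound_mean(self):
        assert circular_mean([175.0, -175.0]) == pytest.approx(180.0)
        assert circular_mean([10.0, 20.0]) == pytest.approx(15.0)

    def test_matches_brute_force_cosine_objective(self, rng):
        """The circular mean is the direction maximizing the mean cosine
        alignment Σcos(θ−μ); check against a grid search of that objective."""
        for _ in range(5):
            angles = bf.wrap_angle(rng.normal(150.0, 25.0, size=40))
            got = circular_mean(angles)
            grid = np.arange(-180.0, 180.0, 0.01)
            score = np.cos(np.radians(angles[None, :] - grid[:, None])).sum(axis=1)
            best = grid[int(np.argmax(score))]
            assert circular_distance(got, best) < 0.02

    def test_near_frechet_mean_for_concentrated_samples(self, rng):
        """For a concentrated cluster the circular mean also minimizes the
        summed squared circular distance to within a fraction of a degree
        (the two notions coincide as the spread shrinks)."""
        angles = bf.wrap_angle(rng.normal(170.0, 8.0, size=60))
        got = circular_mean(angles)
        grid = np.arange(-180.0, 180.0, 0.01)
        cost = np.array([np.sum(bf.wrap_angle(angles - g) ** 2) for g in grid])
        best = grid[int(np.argmin(cost))]
        assert circular_distance(got, best) < 0.5

    def test_circular_distance_wraps(self):
        assert circular_distance(179.0, -179.0) == pytest.approx(2.0)
        assert circular_distance(-68.0, -65.0) == pytest.approx(3.0)


class TestTimeseries:
    def test_scan_yields_linear_wrapped_ramp(self, ma, ma_scan):
        (series,) = bf.torsion_timeseries(ma_scan, [ma.torsions[1]])
        d = np.diff(np.unwrap(np.radians(series.angles)))
        assert np.allclose(np.degrees(d), 10.0, atol=1e-9)
        assert series.angles.min() > -180.0 and series.angles.max() <= 180.0

    def test_single_frame(self, ma):
        frames = bf.ConformerSet([ma.conformer])
        out = bf.torsion_timeseries(frames, ma.torsions)
        assert all(len(s.angles) == 1 for s in out)

    def test_agrees_with_per_frame_loop(self, ma, ma_scan):
        series = bf.torsion_timeseries(ma_scan, ma.torsions)
        for s, tdef in zip(series, ma.torsions):
            manual = [bf.measure_torsion(f.coords, *tdef.indices) for f in ma_scan]
            assert np.allclose(s.angles, manual)


class TestBasins:
    def test_wraparound_cluster_becomes_one_basin(self):
        angles = np.concatenate([np.full(50, 175.0), np.full(50, -175.0)])
        summary = bf.detect_basins(TorsionSeries("tau", angles))
        assert len(summary.basins) == 1
        assert summary.basins[0].center == pytest.approx(180.0)
        assert summary.basins[0].occupancy == 1.0

    def test_two_von_mises_clusters(self):
        rng = np.random.default_rng(42)
        mus = np.radians([-60.0, 170.0])
        n = 5000
        samples = np.concatenate(
            [rng.vonmises(mu, 50.0, size=n // 2) for mu in mus]
        )
        summary = bf.detect_basins(TorsionSeries("tau", np.degrees(samples)))
        assert len(summary.basins) == 2
        centers = sorted(summary.centers, key=lambda c: circular_distance(c, -60))
        assert circular_distance(centers[0], -60.0) < 2.0
        assert circular_distance(centers[1], 170.0) < 2.0
        for b in summary.basins:
            assert abs(b.occupancy - 0.5) < 0.03

    def test_min_occupancy_filter_matches_brute_force(self, rng):
        angles = bf.wrap_angle(
            np.concatenate(
                [rng.normal(0.0, 5.0, size=92), rng.normal(120.0, 3.0, size=8)]
            )
        )
        summary = bf.detect_basins(TorsionSeries("tau", angles), min_occupancy=0.10)
        # the 8%-occupancy side cluster is discarded
        assert len(summary.basins) == 1
        assert circular_distance(summary.basins[0].center, 0.0) < 3.0

    def test_uniform_circle_is_single_full_basin(self, rng):
        angles = rng.uniform(-179.9, 180.0, size=3600)
        summary = bf.detect_basins(TorsionSeries("tau", angles))
        assert len(summary.basins) == 1
        assert summary.basins[0].occupancy == 1.0

    def test_occupancies_disjoint_and_bounded(self, rng):
        angles = bf.wrap_angle(
            np.concatenate(
                [rng.normal(mu, 8.0, size=300) for mu in (-120.0, 0.0, 120.0)]
            )
        )
        summary = bf.detect_basins(TorsionSeries("tau", angles))
        assert sum(b.occupancy for b in summary.basins) <= 1.0 + 1e-12
        assert len(summary.basins) == 3


class TestCorrespondence:
    def test_published_tau3_agreement(self):
        """A reference minimum at τ₃ = −68° against a simulated basin
        averaging −65° is matched at |Δ| = 3°."""
        basins = {"tau3": BasinSummary("tau3", [Basin(-65.0, 0.8, (-90.0, -40.0))])}
        rows = [ReferenceRow("1A", 0.0, 37.9, {"tau3": -68.0})]
        (c,) = bf.compare_to_reference(basins, rows)
        assert c.distance == pytest.approx(3.0)
        assert c.matched

    def test_wraparound_distance(self):
        basins = {"t": BasinSummary("t", [Basin(-179.0, 1.0, (-180.0, -170.0))])}
        (c,) = bf.compare_to_reference(basins, [ReferenceRow("r", 0, 100, {"t": 179.0})])
        assert c.distance == pytest.approx(2.0)
        assert c.matched

    def test_empty_basin_list_is_unmatched(self):
        basins = {"t": BasinSummary("t", [])}
        (c,) = bf.compare_to_reference(basins, [ReferenceRow("r", 0, 100, {"t": 10.0})])
        assert not c.matched and c.nearest_center is None

    def test_nearest_of_several_and_threshold(self):
        basins = {"t": BasinSummary("t", [Basin(-60.0, 0.5, (-80., -40.)),
                                          Basin(120.0, 0.5, (100., 140.))])}
        (c,) = bf.compare_to_reference(
            basins, [ReferenceRow("r", 0, 100, {"t": 100.0})], threshold=15.0
        )
        assert c.nearest_center == 120.0
        assert c.distance == pytest.approx(20.0)
        assert not c.matched

    def test_missing_torsion_label_raises(self):
        with pytest.raises(SchemaMismatchError):
            bf.compare_to_reference({}, [ReferenceRow("r", 0, 100, {"t": 0.0})])
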