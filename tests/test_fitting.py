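"""Offset profiling, objective/R², and torsion-parameter recovery."""

import numpy as np
import pytest

import boronfit as bf
from boronfit.errors import AlignmentError, EmptyInputError, FormatError
from boronfit.params import replace_term

KEY = bf.key("oh", "b", "c3", "n3")


@pytest.fixture(scope="module")
def noiseless_problem(ma, ma_scan, fullset):
    """Scan frames with synthetic QM energies from the true parameters, and a
    perturbed starting set for the oh-b-c3-n3 term."""
    e_qm = bf.synthetic_qm_energies(
        ma.topology, fullset, ma_scan, noise_sd=0.0, offset=7.3, seed=11
    )
    confs = bf.attach_qm_energies(ma_scan, e_qm)
    start = replace_term(fullset, KEY, 0, v_n=1.0, gamma=90.0, n=1.5)
    return confs, start


class TestQmEnergyFile:
    def test_hartree_conversion_to_relative_kcal(self, tmp_path):
        path = tmp_path / "qm.dat"
        path.write_text("-100.000000\n-99.999000\n")
        e = bf.read_qm_energy_file(path, units="hartree")
        rel = e - e.min()
        assert rel[0] == 0.0
        assert rel[1] == pytest.approx(0.627509474, abs=1e-9)

    def test_kcal_passthrough_and_comments(self, tmp_path):
        path = tmp_path / "qm.dat"
        path.write_text("# header\n\n1.5\n  2.5 # trailing\n")
        e = bf.read_qm_energy_file(path, units="kcal/mol")
        assert list(e) == [1.5, 2.5]

    def test_non_numeric_line_reports_position(self, tmp_path):
        path = tmp_path / "qm.dat"
        path.write_text("1.0\nspam\n")
        with pytest.raises(FormatError) as err:
            bf.read_qm_energy_file(path, units="kcal/mol")
        assert err.value.line == 2


class TestOffset:
    def test_hand_example(self):
        assert bf.optimal_offset([10, 11, 12], [1, 2, 3]) == pytest.approx(-9.0)
        assert bf.objective_value([10, 11, 12], [1, 2, 3], -9.0) == pytest.approx(0.0)

    def test_identical_energies_give_zero(self):
        assert bf.optimal_offset([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_beats_grid_search(self, rng):
        for _ in range(20):
            e_mm = rng.normal(size=30)
            e_qm = rng.normal(size=30)
            k_star = bf.optimal_offset(e_mm, e_qm)
            f_star = bf.objective_value(e_mm, e_qm, k_star)
            grid = np.linspace(k_star - 10, k_star + 10, 10_000)
            f_grid = ((e_mm - e_qm)[None, :] + grid[:, None]) ** 2
            assert f_star <= f_grid.sum(axis=1).min() + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            bf.optimal_offset([], [])


class TestObjectiveR2:
    def test_hand_sums(self):
        assert bf.objective_value([1.0, -1.0], [0.0, 0.0], 0.0) == pytest.approx(2.0)
        assert bf.r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0) == 1.0

    def test_constant_model_scores_zero(self):
        e_qm = np.array([1.0, 2.0, 3.0])
        e_mm = np.full(3, 5.0)
        K = bf.optimal_offset(e_mm, e_qm)  # brings the constant to mean(E_QM)
        assert bf.r_squared(e_mm, e_qm, K) == pytest.approx(0.0, abs=1e-14)

    def test_matches_independent_resummation(self, rng):
        e_mm = rng.normal(size=50)
        e_qm = rng.normal(size=50)
        K = 0.37
        f_loop = sum((m - q + K) ** 2 for m, q in zip(e_mm, e_qm))
        assert bf.objective_value(e_mm, e_qm, K) == pytest.approx(f_loop, rel=1e-12)
        ss_tot = sum((q - np.mean(e_qm)) ** 2 for q in e_qm)
        assert bf.r_squared(e_mm, e_qm, K) == pytest.approx(
            1 - f_loop / ss_tot, rel=1e-12
        )

    def test_zero_variance_target_rejected(self):
        with pytest.raises(EmptyInputError):
            bf.r_squared([1.0, 2.0], [3.0, 3.0], 0.0)

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            bf.objective_value([1.0], [1.0, 2.0], 0.0)


class TestRecovery:
    def test_noiseless_recovery_is_exact(self, ma, fullset, noiseless_problem):
        confs, start = noiseless_problem
        res = bf.fit_dihedrals(
            ma.topology, start, confs, bf.FitSpec(terms=[bf.FitTerm(KEY)], seed=0)
        )
        true = fullset.propers[KEY.canonical()][0]
        v, g, n = bf.canonical_term(res.terms[0].v_n, res.terms[0].gamma, res.terms[0].n)
        tv, tg, tn = bf.canonical_term(true.v_n, true.gamma, true.n)
        assert v == pytest.approx(tv, abs=1e-4)
        assert abs(bf.wrap_angle(g - tg)) < 0.1
        assert n == pytest.approx(tn, abs=1e-3)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.converged

    def test_profile_property_and_offset_optimality(self, ma, noiseless_problem):
        confs, start = noiseless_problem
        res = bf.fit_dihedrals(
            ma.topology, start, confs, bf.FitSpec(terms=[bf.FitTerm(KEY)], seed=1)
        )
        e_qm = confs.qm_energies
        e_mm = res.residuals - res.K + e_qm
        assert bf.optimal_offset(e_mm, e_qm) == pytest.approx(res.K, abs=1e-9)
        grid = np.linspace(res.K - 5, res.K + 5, 2000)
        f_grid = min(bf.objective_value(e_mm, e_qm, k) for k in grid)
        assert res.f <= f_grid + 1e-12

    def test_qm_shift_moves_K_only(self, ma, noiseless_problem):
        confs, start = noiseless_problem
        spec = bf.FitSpec(terms=[bf.FitTerm(KEY)], seed=2)
        res0 = bf.fit_dihedrals(ma.topology, start, confs, spec)
        shifted = bf.attach_qm_energies(confs, confs.qm_energies + 12.5)
        res1 = bf.fit_dihedrals(ma.topology, start, shifted, spec)
        # same model (up to the cosine symmetries), same objective value
        assert res1.f == pytest.approx(res0.f, abs=1e-8)
        for t0, t1 in zip(res0.terms, res1.terms):
            assert bf.canonical_term(t1.v_n, t1.gamma, t1.n) == pytest.approx(
                bf.canonical_term(t0.v_n, t0.gamma, t0.n), abs=1e-5
            )
        # for any fixed model, the optimal offset tracks the shift exactly
        e_qm = confs.qm_energies
        e_mm0 = res0.residuals - res0.K + e_qm
        assert bf.optimal_offset(e_mm0, e_qm + 12.5) == pytest.approx(
            res0.K + 12.5, abs=1e-9
        )

    def test_true_start_cannot_be_beaten(self, ma, fullset, noiseless_problem):
        confs, _ = noiseless_problem
        # starting at the generating parameters: f must be (numerically) zero
        res = bf.fit_dihedrals(
            ma.topology, fullset, confs,
            bf.FitSpec(terms=[bf.FitTerm(KEY)], multistart=1, seed=0),
        )
        assert res.f < 1e-16

    def test_objective_trace_is_monotone(self, ma, noiseless_problem):
        confs, start = noiseless_problem
        res = bf.fit_dihedrals(
            ma.topology, start, confs, bf.FitSpec(terms=[bf.FitTerm(KEY)], seed=3)
        )
        trace = res.diagnostics["trace_best_so_far"]
        assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))

    def test_noiseless_K_equals_offset_for_matching_representative(
        self, ma, fullset, ma_scan
    ):
        e_qm = bf.synthetic_qm_energies(
            ma.topology, fullset, ma_scan, noise_sd=0.0, offset=7.3, seed=11
        )
        confs = bf.attach_qm_energies(ma_scan, e_qm)
        res = bf.fit_dihedrals(
            ma.topology, fullset, confs,
            bf.FitSpec(terms=[bf.FitTerm(KEY)], multistart=1, seed=0),
        )
        assert res.K == pytest.approx(7.3, abs=1e-6)

    def test_zero_floating_parameters_rejected(self):
        with pytest.raises(ValueError):
            bf.FitSpec(terms=[])
        with pytest.raises(ValueError):
            bf.FitSpec(terms=[bf.FitTerm(KEY, vary=())])

    def test_underdetermined_set_rejected(self, ma, noiseless_problem):
        confs, start = noiseless_problem
        two = bf.ConformerSet(confs[:2])
        with pytest.raises(AlignmentError):
            bf.fit_dihedrals(
                ma.topology, start, two, bf.FitSpec(terms=[bf.FitTerm(KEY)])
            )

    def test_fix_n_mode_keeps_periodicity(self, ma, noiseless_problem):
        confs, start = noiseless_problem
        res = bf.fit_dihedrals(
            ma.topology, start, confs,
            bf.FitSpec(terms=[bf.FitTerm(KEY)], fit_n_continuous=False,
                       multistart=2, seed=0),
        )
        assert res.terms[0].n == 1.5  # unchanged from the starting set


def test_canonical_term_is_energy_invariant(rng):
    """The canonical representative reproduces the same torsion profile up
    to an additive constant."""
    phi = np.linspace(-180, 180, 73)
    for _ in range(50):
        v = rng.uniform(-10, 10)
        g = rng.uniform(-400, 400)
        n = rng.uniform(-6, 6)
        cv, cg, cn = bf.canonical_term(v, g, n)
        e0 = v * (1 + np.cos(np.radians(n * phi - g)))
        e1 = cv * (1 + np.cos(np.radians(cn * phi - cg)))
        d = e1 - e0
        assert cv >= 0 and cn >= 0 and 0 <= cg < 360
        assert np.ptp(d) < 1e-9  # constant shift only
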