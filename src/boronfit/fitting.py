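"""Least-squares fitting of torsion parameters to quantum single-point
energies.

The objective is

    f(K) = Σ_i ( E_MM,i − E_QM,i + K )²

over the N conformers of a structure set, where K is a molecule- and
set-dependent constant aligning the two energy scales. For any candidate
torsion parameters, the optimal K has the closed form

    K* = mean(E_QM − E_MM),

so K is profiled out analytically at every objective evaluation rather than
exposed to the optimizer; this removes one perfectly conditioned but
redundant dimension. The remaining nonlinear problem over the floating
(V_n, γ, n) values is solved with a bounded trust-region least-squares
optimizer, restarted from several random initial points.

Because the cosine model has exact symmetries — (v, γ, n) ≡ (v, −γ, −n), and
flipping the sign of v shifts the energy by a constant that K absorbs —
fitted terms are reported as found, and :func:`canonical_term` maps any term
to a canonical representative (v ≥ 0, n ≥ 0, γ ∈ [0, 360)) for comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    AlignmentError,
    EmptyInputError,
    FormatError,
    NonConvergenceWarning,
    RankDeficiencyWarning,
)
from .energy import NonbondedParams, total_mm_energy
from .params import AtomTypeKey, DihedralTermParam, ParameterSet, replace_term
from .topology import ConformerSet, Topology, enumerate_terms
from . import geometry

HARTREE_TO_KCAL = 627.509474


def read_qm_energy_file(path, units: str = "hartree") -> np.ndarray:
    """One energy per non-comment line, in structure order; returns kcal/mol.

    ``units`` is ``"hartree"`` (converted at 627.509474 kcal/mol) or
    ``"kcal/mol"`` (passthrough). Blank lines and ``#`` comments are skipped.
    """
    if units not in ("hartree", "kcal/mol"):
        raise ValueError(f"unknown energy units {units!r}")
    vals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                vals.append(float(line))
            except ValueError as exc:
                raise FormatError(
                    f"not a number: {line!r}", path=path, line=lineno
                ) from exc
    arr = np.array(vals, dtype=float)
    return arr * HARTREE_TO_KCAL if units == "hartree" else arr


def optimal_offset(e_mm, e_qm) -> float:
    """The unique K minimizing Σ(E_MM − E_QM + K)² for fixed E_MM."""
    e_mm = np.asarray(e_mm, dtype=float)
    e_qm = np.asarray(e_qm, dtype=float)
    if e_mm.size == 0 or e_qm.size == 0:
        raise EmptyInputError("offset needs at least one energy pair")
    if e_mm.shape != e_qm.shape:
        raise AlignmentError(f"length mismatch: {e_mm.shape} vs {e_qm.shape}")
    return float(np.mean(e_qm - e_mm))


def objective_value(e_mm, e_qm, K: float) -> float:
    e_mm = np.asarray(e_mm, dtype=float)
    e_qm = np.asarray(e_qm, dtype=float)
    if e_mm.shape != e_qm.shape:
        raise AlignmentError(f"length mismatch: {e_mm.shape} vs {e_qm.shape}")
    return float(np.sum((e_mm - e_qm + K) ** 2))


def r_squared(e_mm, e_qm, K: float) -> float:
    """Coefficient of determination of E_MM + K against E_QM."""
    e_mm = np.asarray(e_mm, dtype=float)
    e_qm = np.asarray(e_qm, dtype=float)
    if e_mm.shape != e_qm.shape:
        raise AlignmentError(f"length mismatch: {e_mm.shape} vs {e_qm.shape}")
    if e_qm.size < 2:
        raise EmptyInputError("R² needs at least two structures")
    ss_tot = float(np.sum((e_qm - e_qm.mean()) ** 2))
    if ss_tot == 0.0:
        raise EmptyInputError("R² undefined: target energies have zero variance")
    return 1.0 - objective_value(e_mm, e_qm, K) / ss_tot


def _wrap_360(gamma: float) -> float:
    g = gamma % 360.0
    return 0.0 if g >= 360.0 else g  # float modulo can round up to 360.0


def canonical_term(v: float, gamma: float, n: float) -> tuple[float, float, float]:
    """Map (v, γ, n) to the energy-equivalent representative with v ≥ 0,
    n ≥ 0 and γ ∈ [0, 360). (The v sign flip changes the energy only by a
    constant, which the offset K absorbs.)"""
    if n < 0:
        n, gamma = -n, -gamma
    if v < 0:
        v, gamma = -v, gamma + 180.0
    return v, _wrap_360(gamma), n


@dataclass
class FitTerm:
    """One torsion term to optimize: which key, which term of its series, and
    which of (v_n, gamma, n) float."""

    key: AtomTypeKey
    term_index: int = 0
    vary: tuple[str, ...] = ("v_n", "gamma", "n")

    def __post_init__(self):
        bad = set(self.vary) - {"v_n", "gamma", "n"}
        if bad:
            raise ValueError(f"unknown parameters {bad}")


@dataclass
class FitSpec:
    """Configuration of a torsion fit.

    Bounds default to |V_n| ≤ 50 kcal/mol and |n| ≤ 6; γ is unconstrained
    during optimization and wrapped to [0, 360) in the result. When
    ``fit_n_continuous`` is off, every n is held at its starting value.
    """

    terms: list[FitTerm]
    fit_n_continuous: bool = True
    v_bounds: tuple[float, float] = (-50.0, 50.0)
    n_bounds: tuple[float, float] = (-6.0, 6.0)
    multistart: int = 8
    seed: int = 0
    ftol: float = 1e-10

    def __post_init__(self):
        if not self.terms:
            raise ValueError("FitSpec needs at least one term")
        if not self.fit_n_continuous:
            self.terms = [
                FitTerm(t.key, t.term_index, tuple(p for p in t.vary if p != "n"))
                for t in self.terms
            ]
        if not any(t.vary for t in self.terms):
            raise ValueError("at least one parameter must float")
        for lo, hi in (self.v_bounds, self.n_bounds):
            if lo >= hi:
                raise ValueError("bounds must be ordered")


@dataclass
class FitResult:
    terms: list[DihedralTermParam]  # fitted values, γ wrapped to [0, 360)
    K: float  # kcal/mol
    f: float  # objective value, kcal²/mol²
    r2: float
    residuals: np.ndarray  # E_MM + K − E_QM per structure
    pset: ParameterSet  # input set with fitted terms substituted
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))


def _phi_matrix(top, conformers, quads):
    """Torsion angles (degrees): shape (n_frames, n_quads)."""
    out = np.empty((len(conformers), len(quads)))
    for m, frame in enumerate(conformers):
        for q, quad in enumerate(quads):
            out[m, q] = geometry.measure_torsion(frame.coords, *quad)
    return out


def fit_dihedrals(
    top: Topology,
    pset: ParameterSet,
    conformers: ConformerSet,
    spec: FitSpec,
    nb: NonbondedParams | None = None,
) -> FitResult:
    """Fit the floating torsion parameters of ``spec`` to the conformers'
    QM energies.

    Every conformer must carry a ``qm_energy``. The fitted keys must resolve
    to at least one enumerated torsion of the topology. Multistart: the
    current parameter values seed the first start; the remaining starts are
    drawn uniformly inside the bounds from ``spec.seed``. Ties within 1e-9
    relative objective are broken toward the smallest Σ|V_n| (parsimony).
    """
    e_qm = conformers.qm_energies
    if e_qm is None:
        raise AlignmentError("every conformer needs a qm_energy")
    n_struct = len(conformers)

    term_lists = enumerate_terms(top, pset)
    # map each fitted (key, term_index) to its torsion instances
    fit_quads: list[list[tuple]] = []
    start_terms: list[DihedralTermParam] = []
    fitted_ids = set()
    for ft in spec.terms:
        ck = ft.key.canonical()
        if ck not in pset.propers:
            raise AlignmentError(f"no parameter entry for fitted key {ft.key}")
        series = pset.propers[ck]
        if not (0 <= ft.term_index < len(series)):
            raise AlignmentError(
                f"term index {ft.term_index} out of range for {ft.key}"
            )
        quads = [
            quad
            for quad in term_lists.propers
            if AtomTypeKey(tuple(top.type_of(x) for x in quad)).canonical() == ck
        ]
        if not quads:
            raise AlignmentError(f"fitted key {ft.key} matches no torsion in topology")
        fit_quads.append(quads)
        start_terms.append(series[ft.term_index])
        fitted_ids.add((ck, ft.term_index))

    n_params = sum(len(ft.vary) for ft in spec.terms)
    if n_struct < n_params:
        raise AlignmentError(
            f"{n_struct} structures cannot determine {n_params} parameters"
        )

    # Base energy per frame: everything except the fitted terms. Evaluate the
    # full model once per frame with fitted terms' v_n zeroed.
    zeroed = pset
    for ft in spec.terms:
        zeroed = replace_term(zeroed, ft.key, ft.term_index, v_n=0.0)
    e_base = np.array(
        [
            total_mm_energy(top, zeroed, frame, nb=nb, terms=term_lists).total
            for frame in conformers
        ]
    )
    phis = [_phi_matrix(top, conformers, quads) for quads in fit_quads]
    dividers = [t.divider for t in start_terms]

    # Parameter handling: γ and n are the genuinely nonlinear parameters and
    # go to the optimizer; every floating v_n (and the offset K) is profiled
    # out by linear least squares at each evaluation — the model is linear in
    # the barrier heights, so their optimum given (γ, n) is exact.
    v_float = ["v_n" in ft.vary for ft in spec.terms]

    def unpack_nl(x):
        """Nonlinear vector -> per-term (gamma, n)."""
        vals = []
        pos = 0
        for ft, t0 in zip(spec.terms, start_terms):
            g, n = t0.gamma, t0.n
            if "gamma" in ft.vary:
                g = x[pos]; pos += 1
            if "n" in ft.vary:
                n = x[pos]; pos += 1
            vals.append((g, n))
        return vals

    def design(x):
        """Per-term basis functions g_t(frame) = (1/div)Σ_inst(1+cos(nφ−γ))."""
        cols = []
        for (g, n), phi, div in zip(unpack_nl(x), phis, dividers):
            cols.append(
                np.sum(1.0 + np.cos(np.radians(n * phi - g)), axis=1) / div
            )
        return cols

    def solve_linear(x):
        """Best (v per term, K) for fixed nonlinear parameters; fixed-v terms
        contribute at their stored barrier height."""
        cols = design(x)
        e_fixed = e_base.copy()
        free_cols = []
        for flt, col, t0 in zip(v_float, cols, start_terms):
            if flt:
                free_cols.append(col)
            else:
                e_fixed = e_fixed + t0.v_n * col
        target = e_qm - e_fixed
        if not free_cols:
            K = float(np.mean(target))
            return [], e_fixed + K, K
        A = np.column_stack(free_cols + [np.ones(n_struct)])
        sol, *_ = np.linalg.lstsq(A, target, rcond=None)
        vs = np.clip(sol[:-1], *spec.v_bounds)
        e_mm = e_fixed + np.column_stack(free_cols) @ vs
        K = float(np.mean(e_qm - e_mm))
        return list(vs), e_mm + K, K

    trace: list[float] = []

    def residuals_fn(x):
        _, e_model, _ = solve_linear(x)
        res = e_model - e_qm
        trace.append(float(np.dot(res, res)))
        return res

    lo, hi, x0 = [], [], []
    for ft, t0 in zip(spec.terms, start_terms):
        if "gamma" in ft.vary:
            lo.append(-np.inf); hi.append(np.inf)
            x0.append(t0.gamma)
        if "n" in ft.vary:
            lo.append(spec.n_bounds[0]); hi.append(spec.n_bounds[1])
            x0.append(np.clip(t0.n, *spec.n_bounds))

    rng = np.random.default_rng(spec.seed)
    starts = [np.array(x0)]
    for _ in range(max(0, spec.multistart - 1)):
        xs = []
        for ft in spec.terms:
            if "gamma" in ft.vary:
                xs.append(rng.uniform(0.0, 360.0))
            if "n" in ft.vary:
                xs.append(rng.uniform(*spec.n_bounds))
        starts.append(np.array(xs))

    results = []
    if len(x0) == 0:
        # purely linear problem: one exact solve
        vs, e_model, _ = solve_linear(np.empty(0))
        f_val = float(np.sum((e_model - e_qm) ** 2))
        trace.append(f_val)
        results.append((f_val, sum(abs(v) for v in vs), None))
    else:
        for xs in starts:
            sol = least_squares(
                residuals_fn, xs, bounds=(lo, hi), method="trf",
                ftol=spec.ftol, xtol=1e-12, gtol=1e-12,
            )
            f_val = float(2.0 * sol.cost)
            vs, _, _ = solve_linear(sol.x)
            vsum = sum(abs(v) for v in vs) + sum(
                abs(t0.v_n)
                for flt, t0 in zip(v_float, start_terms)
                if not flt
            )
            results.append((f_val, vsum, sol))
    f_best = min(r[0] for r in results)
    tol = 1e-9 * max(1.0, f_best)
    contenders = [r for r in results if r[0] <= f_best + tol]
    f_val, _, best = min(contenders, key=lambda r: r[1])
    x_best = best.x if best is not None else np.empty(0)

    if best is not None:
        jac_rank = np.linalg.matrix_rank(best.jac) if best.jac.size else 0
        if jac_rank < len(x_best):
            warnings.warn(
                f"fit is rank-deficient at the solution ({jac_rank}/{len(x_best)})",
                RankDeficiencyWarning,
                stacklevel=2,
            )
    n_free_v = sum(v_float)
    if n_free_v:
        A = np.column_stack(
            [c for c, flt in zip(design(x_best), v_float) if flt]
            + [np.ones(n_struct)]
        )
        if np.linalg.matrix_rank(A) < n_free_v + 1:
            warnings.warn(
                "barrier-height design is rank-deficient (indistinguishable terms)",
                RankDeficiencyWarning,
                stacklevel=2,
            )
    converged = bool(best is None or best.status > 0)
    if not converged:
        warnings.warn(
            "optimizer stopped before convergence; best-so-far returned",
            NonConvergenceWarning,
            stacklevel=2,
        )

    vs, e_model, K = solve_linear(x_best)
    e_mm = e_model - K
    fitted = []
    out_pset = pset
    vs_iter = iter(vs)
    for ft, t0, (g, n) in zip(spec.terms, start_terms, unpack_nl(x_best)):
        v = next(vs_iter) if "v_n" in ft.vary else t0.v_n
        g = _wrap_360(g)
        out_pset = replace_term(out_pset, ft.key, ft.term_index, v_n=v, gamma=g, n=n)
        fitted.append(DihedralTermParam(ft.key, t0.divider, float(v), g, n))
    return FitResult(
        terms=fitted,
        K=K,
        f=objective_value(e_mm, e_qm, K),
        r2=r_squared(e_mm, e_qm, K),
        residuals=e_mm + K - e_qm,
        pset=out_pset,
        diagnostics={
            "converged": converged,
            "status": int(best.status) if best is not None else 1,
            "n_starts": len(results),
            "seed": spec.seed,
            "start_objectives": [r[0] for r in results],
            "trace_best_so_far": list(np.minimum.accumulate(trace)),
            "n_structures": n_struct,
            "n_parameters": n_params,
        },
    )
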