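"""MM energy terms against hand-derived values, plus invariances."""

import numpy as np
import pytest

import boronfit as bf
from boronfit.energy import COULOMB_CONSTANT, NonbondedParams
from boronfit.errors import ParameterGapError
from boronfit.params import DihedralTermParam, ParameterSet
from boronfit.topology import Atom, Conformer, TermLists, Topology


def two_atoms(t1, t2, r, q1=0.0, q2=0.0):
    top = Topology([Atom("A", t1, q1), Atom("B", t2, q2)], [(0, 1)])
    conf = Conformer(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))
    return top, conf


def test_bond_term_hand_value(builtin):
    # B-O stretched by 0.10 Å: 450·0.10² = 4.500 kcal/mol
    top, conf = two_atoms("b", "o", 1.610)
    rep = bf.bonded_energy(top, builtin, conf)
    assert rep.components["bond"] == pytest.approx(4.500, abs=1e-12)


@pytest.mark.parametrize(
    "phi, expected",
    [(0.0, 1.6722), (60.0, 0.0), (120.0, 1.6722)],
)
def test_proper_torsion_closed_form(builtin, phi, expected):
    # o-b-o-ho: V=0.8361, γ=0, n=3 → E = 0.8361(1+cos 3φ)
    (term,) = builtin.lookup_dihedral(bf.key("o", "b", "o", "ho"))
    e = (term.v_n / term.divider) * (1 + np.cos(np.radians(term.n * phi - term.gamma)))
    assert e == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("phi, expected", [(0.0, 0.0), (180.0, 0.0), (90.0, 2.2)])
def test_improper_closed_form_via_energy(builtin, phi, expected):
    # planar-restraint improper b-ha-c2-ha: 1.1(1+cos(2φ−180))
    top = Topology(
        [Atom("B", "b", 0.0), Atom("H1", "ha", 0.0), Atom("C", "c2", 0.0),
         Atom("H2", "ha", 0.0)],
        [(2, 0), (2, 1), (2, 3)],
    )
    # place the improper quadruple at the requested angle
    from boronfit.geometry import nerf_place

    a = np.array([1.5, 0.0, 0.0])
    b_ = np.array([0.0, 1.0, 0.0])
    c = np.array([0.0, 0.0, 0.0])
    d = nerf_place(a, b_, c, 1.0, 120.0, phi)
    conf = Conformer(np.stack([a, b_, c, d]))
    pset = ParameterSet()
    pset.add_dihedral(
        DihedralTermParam(bf.key("b", "ha", "c2", "ha"), 1, 1.1, 180.0, 2.0,
                          is_improper=True)
    )
    terms = TermLists(impropers=[(0, 1, 2, 3)])
    rep = bf.bonded_energy(top, pset, conf, terms=terms)
    assert rep.components["improper"] == pytest.approx(expected, abs=1e-9)


def test_lj_well_minimum():
    nb = NonbondedParams(lj={"c3": (1.9, 0.10), "oh": (1.7, 0.20)})
    top, conf = two_atoms("c3", "oh", 1.9 + 1.7)
    top = Topology(top.atoms, [])  # not bonded: full nonbonded pair
    rep = bf.nonbonded_energy(top, nb, conf)
    assert rep.components["lj"] == pytest.approx(-np.sqrt(0.10 * 0.20), abs=1e-12)
    assert rep.components["coulomb"] == 0.0


def test_coulomb_constant_arithmetic():
    nb = NonbondedParams(lj={"c3": (1.9, 0.0)})
    top = Topology([Atom("A", "c3", 1.0), Atom("B", "c3", -1.0)], [])
    conf = Conformer(np.array([[0.0, 0.0, 0.0], [COULOMB_CONSTANT / 100.0, 0.0, 0.0]]))
    rep = bf.nonbonded_energy(top, nb, conf)
    assert rep.components["coulomb"] == pytest.approx(-100.0, abs=1e-9)


def test_exclusions_only_1_4_pair_contributes_scaled():
    nb = NonbondedParams(lj={"c3": (1.9, 0.10)})
    top = Topology(
        [Atom(f"C{i}", "c3", 0.5) for i in range(4)],
        [(0, 1), (1, 2), (2, 3)],
    )
    coords = np.array([[0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [3.0, 1.5, 0]], float)
    rep = bf.nonbonded_energy(top, nb, Conformer(coords))
    r14 = np.linalg.norm(coords[3] - coords[0])
    coul = COULOMB_CONSTANT * 0.25 / r14 / 1.2
    x6 = (3.8 / r14) ** 6
    lj = 0.10 * (x6 * x6 - 2 * x6) / 2.0
    assert rep.components["coulomb"] == pytest.approx(coul, rel=1e-12)
    assert rep.components["lj"] == pytest.approx(lj, rel=1e-12)


def test_total_is_sum_of_components(ma, fullset):
    nb = bf.builtin_lj_params()
    rep = bf.total_mm_energy(ma.topology, fullset, ma.conformer, nb=nb)
    assert rep.total == pytest.approx(sum(rep.components.values()), abs=0.0)
    bonded = bf.bonded_energy(ma.topology, fullset, ma.conformer)
    nbr = bf.nonbonded_energy(ma.topology, nb, ma.conformer)
    assert rep.total == pytest.approx(bonded.total + nbr.total, abs=1e-12)
    # per-term breakdown sums to the component values
    for comp, pairs in rep.term_energies.items():
        assert rep.components[comp] == pytest.approx(
            sum(e for _, e in pairs), abs=1e-12
        )


def test_rigid_motion_invariance(ma, fullset, rng):
    from scipy.spatial.transform import Rotation

    nb = bf.builtin_lj_params()
    e0 = bf.total_mm_energy(ma.topology, fullset, ma.conformer, nb=nb).total
    rot = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
    shift = rng.uniform(-20, 20, size=3)
    moved = Conformer(ma.conformer.coords @ rot.T + shift)
    e1 = bf.total_mm_energy(ma.topology, fullset, moved, nb=nb).total
    assert abs(e1 - e0) < 1e-9


def test_parameter_gap_lists_missing_keys(builtin):
    top = Topology([Atom("A", "zz", 0.0), Atom("B", "b", 0.0)], [(0, 1)])
    conf = Conformer(np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]))
    with pytest.raises(ParameterGapError) as err:
        bf.bonded_energy(top, builtin, conf)
    assert ("zz", "b") in err.value.missing_keys


def test_bonded_only_mode_omits_nonbonded_components(ma, fullset):
    rep = bf.total_mm_energy(ma.topology, fullset, ma.conformer)
    assert "coulomb" not in rep.components and "lj" not in rep.components
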