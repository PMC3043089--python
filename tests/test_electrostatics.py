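import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trpmhc.electrostatics import (
    ChargeScheme,
    ChargeSet,
    PointCharge,
    assign_formal_charges,
    electrostatic_distance,
    evaluate_potential_field,
    hodgkin_index,
    shell_grid,
    similarity_matrix,
)
from trpmhc.structures import Atom, Chain, ChainRole, ComplexStructure, Residue


def _residue(name, atoms, num=1):
    return Residue(name, (num, ""), tuple(Atom(n, n[0], xyz) for n, xyz in atoms))


def _unit(residues):
    return ComplexStructure(
        id="u", chains={"A": Chain("A", ChainRole.MHC_ALPHA, residues)}
    )


class TestAssignCharges:
    def test_neutral_chain_gives_empty_set(self):
        unit = _unit(
            [
                _residue("GLY", [("CA", (0, 0, 0))], 1),
                _residue("ALA", [("CA", (3, 0, 0)), ("CB", (4, 0, 0))], 2),
            ]
        )
        assert len(assign_formal_charges(unit)) == 0

    def test_acid_base_pair_nets_zero(self):
        unit = _unit(
            [
                _residue("ASP", [("CA", (0, 0, 0)), ("OD1", (1, 0, 0)), ("OD2", (1, 1, 0))], 1),
                _residue("LYS", [("CA", (5, 0, 0)), ("NZ", (7, 0, 0))], 2),
            ]
        )
        q = assign_formal_charges(unit)
        assert sorted(c.sign for c in q) == [-1, 1]
        assert q.net_charge == 0

    def test_anchor_centroids_match_hand_values(self):
        unit = _unit(
            [
                _residue("ARG", [("CA", (0, 0, 0)), ("CZ", (3, 3, 3))], 1),
                _residue("ARG", [("CA", (9, 0, 0)), ("CZ", (12, 0, 0))], 2),
                _residue("GLU", [("CA", (5, 5, 0)), ("OE1", (6, 6, 0)), ("OE2", (8, 6, 0))], 3),
            ]
        )
        q = assign_formal_charges(unit)
        assert q.net_charge == +1
        anchors = {c.seq_id[0]: c.anchor for c in q}
        assert anchors[1] == pytest.approx((3, 3, 3))
        assert anchors[3] == pytest.approx((7, 6, 0))  # carboxylate-oxygen centroid

    def test_missing_sidechain_falls_back(self):
        unit = _unit(
            [
                _residue("LYS", [("CA", (0, 0, 0)), ("CB", (1, 0, 0))], 1),
                _residue("ASP", [("CA", (5, 0, 0))], 2),
            ]
        )
        q = assign_formal_charges(unit)
        by_num = {c.seq_id[0]: c for c in q}
        assert by_num[1].anchor_source == "CB"
        assert by_num[2].anchor_source == "CA"
        assert q.n_fallback_anchors == 2

    def test_histidine_off_by_default(self):
        unit = _unit([_residue("HIS", [("CA", (0, 0, 0)), ("NE2", (1, 0, 0))], 1)])
        assert len(assign_formal_charges(unit)) == 0
        assert len(assign_formal_charges(unit, ChargeScheme(his_charged=True))) == 1


def _charge(sign, xyz):
    return PointCharge("A", (1, ""), "LYS" if sign > 0 else "ASP", sign, tuple(xyz))


class TestPotentialField:
    def test_single_charge_reference_value(self):
        q = ChargeSet([_charge(+1, (0, 0, 0))])
        f = evaluate_potential_field(q, np.array([[2.0, 0, 0]]), dielectric=1.0, kappa=0.0)
        assert f.values[0] == pytest.approx(0.5)

    def test_superposition_is_linear(self):
        pts = np.random.default_rng(1).normal(scale=8, size=(20, 3))
        q1 = ChargeSet([_charge(+1, (0, 0, 0))])
        q2 = ChargeSet([_charge(-1, (3, 1, 0))])
        both = ChargeSet(q1.charges + q2.charges)
        f1 = evaluate_potential_field(q1, pts).values
        f2 = evaluate_potential_field(q2, pts).values
        f12 = evaluate_potential_field(both, pts).values
        assert np.allclose(f12, f1 + f2, atol=1e-12)

    def test_sign_flip_negates_field(self):
        pts = np.random.default_rng(2).normal(scale=8, size=(10, 3))
        q = ChargeSet([_charge(+1, (0, 0, 0)), _charge(+1, (4, 0, 0))])
        neg = ChargeSet([_charge(-c.sign, c.anchor) for c in q])
        assert np.allclose(
            evaluate_potential_field(q, pts).values,
            -evaluate_potential_field(neg, pts).values,
        )

    def test_empty_set_gives_zero_field(self):
        f = evaluate_potential_field(ChargeSet(), np.zeros((5, 3)))
        assert np.all(f.values == 0.0)

    def test_matches_per_point_loop_oracle(self):
        rng = np.random.default_rng(3)
        charges = ChargeSet(
            [_charge(int(s), xyz) for s, xyz in zip(rng.choice([-1, 1], 40), rng.normal(scale=10, size=(40, 3)))]
        )
        pts = rng.normal(scale=12, size=(25, 3))
        dielectric, kappa = 80.0, 0.124
        f = evaluate_potential_field(charges, pts, dielectric, kappa).values
        for k, x in enumerate(pts):
            expected = 0.0
            for c in charges:
                r = max(np.linalg.norm(x - c.xyz), 0.1)
                expected += c.sign * np.exp(-kappa * r) / (dielectric * r)
            assert f[k] == pytest.approx(expected, abs=1e-9)


class TestHodgkinSimilarity:
    def test_identity(self):
        assert hodgkin_index([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)
        assert electrostatic_distance(1.0) == pytest.approx(0.0)

    def test_anti_identity(self):
        assert hodgkin_index([1.0, -2.0], [-1.0, 2.0]) == pytest.approx(-1.0)
        assert electrostatic_distance(-1.0) == pytest.approx(2.0)

    def test_worked_example(self):
        si = hodgkin_index([1.0, 0.0], [1.0, 1.0])
        assert si == pytest.approx(2 / 3)
        assert electrostatic_distance(si) == pytest.approx(np.sqrt(2 / 3))

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_scale_sensitivity(self, c):
        phi = np.array([0.3, -1.2, 0.7])
        assert hodgkin_index(phi, c * phi) == pytest.approx(2 * c / (1 + c**2))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-1.0, 1.0))
    def test_distance_monotone_and_bounded(self, si):
        d = electrostatic_distance(si)
        assert 0.0 <= d <= 2.0
        assert d <= electrostatic_distance(si - 0.1) + 1e-12


class TestSimilarityMatrix:
    def _fields(self):
        pts = shell_grid((-5, 5), (-5, 5), heights=(3, 4), spacing=2.0)
        qs = [
            ChargeSet([_charge(+1, (0, 0, 0))]),
            ChargeSet([_charge(-1, (0, 0, 0))]),
            ChargeSet([_charge(+1, (1, 0, 0))]),
        ]
        return [
            evaluate_potential_field(q, pts, complex_id=f"c{i}") for i, q in enumerate(qs)
        ]

    def test_structure_and_range(self):
        m = similarity_matrix(self._fields())
        assert np.allclose(m.si, m.si.T)
        assert np.allclose(np.diag(m.si), 1.0)
        assert np.all(m.si >= -1 - 1e-12) and np.all(m.si <= 1 + 1e-12)
        assert np.allclose(m.dist, np.sqrt(np.clip(2 - 2 * m.si, 0, None)))
        assert m.si[0, 1] == pytest.approx(-1.0)  # sign-flipped charge set

    def test_grid_mismatch_rejected(self):
        f = self._fields()
        other = evaluate_potential_field(
            ChargeSet([_charge(1, (0, 0, 0))]),
            np.zeros((3, 3)) + 1.0,
            complex_id="odd",
        )
        with pytest.raises(ValueError, match="shared point set"):
            similarity_matrix([f[0], other])

    def test_zero_field_flagged(self):
        pts = np.ones((4, 3))
        f0 = evaluate_potential_field(ChargeSet(), pts, complex_id="zero")
        f1 = evaluate_potential_field(ChargeSet([_charge(1, (0, 0, 0))]), pts, complex_id="one")
        m = similarity_matrix([f0, f1])
        assert ("zero", "one") in m.flagged
        assert np.isnan(m.si[0, 1])


class TestShellGrid:
    def test_counts_and_heights(self):
        g = shell_grid((-2, 2), (-1, 1), heights=(3.0, 5.0), spacing=1.0)
        assert g.shape == (5 * 3 * 3, 3)
        assert g[:, 2].min() == pytest.approx(3.0)
        assert g[:, 2].max() == pytest.approx(5.0)

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            shell_grid((-1, 1), (-1, 1), spacing=0.0)
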