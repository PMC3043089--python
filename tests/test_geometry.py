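import numpy as np
import pytest

from trpmhc.contacts import compute_contacts
from trpmhc.electrostatics import assign_formal_charges
from trpmhc.geometry import (
    DegenerateGeometryError,
    RingTooSmallError,
    ChargeRing,
    Plane3D,
    docking_angle,
    groove_plane,
    match_complementary_charges,
    peptide_axis,
)
from trpmhc.structures import Atom, Chain, ChainRole, ComplexStructure, Residue, truncate_complex
from trpmhc.synth import ToyComplexSpec, generate_toy_complex

from conftest import rigid_transform


def _ca_chain(points, role=ChainRole.PEPTIDE, chain_id="C"):
    residues = [
        Residue("GLY", (i + 1, ""), (Atom("CA", "C", tuple(p)),))
        for i, p in enumerate(points)
    ]
    return ComplexStructure(id="x", chains={chain_id: Chain(chain_id, role, residues)})


class TestPeptideAxis:
    def test_collinear_points(self):
        pts = [(i, 0.0, 0.0) for i in range(9)]
        axis = peptide_axis(_ca_chain(pts))
        assert np.allclose(axis.d, [1, 0, 0])

    def test_orientation_follows_chain_order(self):
        pts = [(8 - i, 0.0, 0.0) for i in range(9)]  # N-terminus at +x
        axis = peptide_axis(_ca_chain(pts))
        assert np.allclose(axis.d, [-1, 0, 0])

    def test_noisy_line_within_three_degrees(self):
        rng = np.random.default_rng(7)
        pts = np.column_stack(
            [np.arange(9) * 3.5, rng.normal(0, 0.2, 9), rng.normal(0, 0.2, 9)]
        )
        axis = peptide_axis(_ca_chain(pts))
        angle = np.degrees(np.arccos(abs(axis.d @ np.array([1.0, 0, 0]))))
        assert angle < 3.0

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            peptide_axis(_ca_chain([(0, 0, 0), (1, 0, 0)]))


class TestGroovePlane:
    def test_planar_input(self, toy_units):
        pmhc, tr = toy_units
        plane = groove_plane(pmhc, tr)
        assert abs(plane.n @ np.array([0, 0, 1.0])) > 0.999
        assert plane.n[2] > 0  # oriented toward the TR side (toys put TR at +z)

    def test_equivariant_under_rotation(self, toy_units):
        pmhc, tr = toy_units
        rot, t = rigid_transform(np.random.default_rng(5))
        moved_p = _transform_unit(pmhc, rot, t)
        moved_t = _transform_unit(tr, rot, t)
        n0 = groove_plane(pmhc, tr).n
        n1 = groove_plane(moved_p, moved_t).n
        assert np.allclose(rot @ n0, n1, atol=1e-9)

    def test_jittered_helices_within_three_degrees(self):
        rng = np.random.default_rng(9)
        xs = np.arange(-15, 16, 1.5)
        helix1 = np.column_stack([xs, np.full_like(xs, 9.0), rng.normal(0, 0.3, len(xs))])
        helix2 = np.column_stack([xs, np.full_like(xs, -9.0), rng.normal(0, 0.3, len(xs))])
        unit = _ca_chain(np.vstack([helix1, helix2]), role=ChainRole.MHC_ALPHA, chain_id="A")
        n = groove_plane(unit).n
        tilt = np.degrees(np.arccos(abs(n[2])))
        assert tilt < 3.0

    def test_collinear_input_rejected(self):
        unit = _ca_chain([(i, 0, 0) for i in range(12)], role=ChainRole.MHC_ALPHA, chain_id="A")
        with pytest.raises(DegenerateGeometryError):
            groove_plane(unit)


@pytest.fixture(scope="module")
def matched_ring():
    structure, truth = generate_toy_complex(
        ToyComplexSpec(theta_true=72.0, n_ring_pairs=8, seed=11)
    )
    pmhc, tr = truncate_complex(structure)
    cm = compute_contacts(pmhc, tr, 5.0)
    pq = assign_formal_charges(pmhc)
    tq = assign_formal_charges(tr)
    plane = groove_plane(pmhc, tr)
    ring = match_complementary_charges(pq, tq, cm, plane)
    return structure, pmhc, tr, ring, plane, truth


class TestChargeMatching:
    def test_planted_pairs_found_exactly(self, matched_ring):
        _, _, _, ring, _, truth = matched_ring
        assert ring.n_points == truth.n_ring_pairs  # distractors excluded

    def test_every_pair_is_complementary(self, matched_ring):
        _, _, _, ring, _, _ = matched_ring
        for mhc_c, tr_c in ring.matched_pairs:
            assert mhc_c.sign == -tr_c.sign

    def test_ring_order_matches_polar_sort(self, matched_ring):
        _, _, _, ring, _, _ = matched_ring
        centred = ring.ring_points - ring.ring_points.mean(axis=0)
        angles = np.arctan2(centred[:, 1], centred[:, 0])
        assert np.array_equal(np.argsort(-angles), np.arange(len(angles)))

    def test_same_sign_neighbours_rejected(self, matched_ring):
        _, pmhc, tr, _, plane, _ = matched_ring
        cm = compute_contacts(pmhc, tr, 5.0)
        pq = assign_formal_charges(pmhc)
        tq = assign_formal_charges(tr)
        # flip every TR charge: all pairs become same-sign, nothing matches
        for c in tq.charges[:]:
            object.__setattr__(c, "sign", -c.sign)
        with pytest.raises(RingTooSmallError):
            match_complementary_charges(pq, tq, cm, plane)

    def test_small_ring_rejected(self, matched_ring):
        _, pmhc, tr, _, plane, _ = matched_ring
        cm = compute_contacts(pmhc, tr, 5.0)
        pq = assign_formal_charges(pmhc)
        tq = assign_formal_charges(tr)
        pq.charges = pq.charges[:3]
        with pytest.raises(RingTooSmallError, match="at least 4"):
            match_complementary_charges(pq, tq, cm, plane)


def _synthetic_ring(angle_deg, n=8, a=10.0, b=5.0):
    t = 2 * np.pi * np.arange(n) / n + 0.3
    th = np.radians(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    pts = (rot @ np.vstack([a * np.cos(t), b * np.sin(t)])).T
    plane = Plane3D((0, 0, 0), (0, 0, 1))
    return ChargeRing(matched_pairs=[(None, None)] * n, ring_points=pts, plane=plane)


class TestDockingAngle:
    def _pep(self, plane):
        from trpmhc.geometry import Line3D

        e1, e2 = plane.basis()
        return Line3D((0, 0, 0), tuple(e1))

    def test_aligned_ring_reads_zero(self):
        ring = _synthetic_ring(0.0)
        res = docking_angle(ring, self._pep(ring.plane), ring.plane)
        assert res.theta == pytest.approx(0.0, abs=1e-9)

    def test_constructed_forty_degrees(self):
        ring = _synthetic_ring(40.0)
        res = docking_angle(ring, self._pep(ring.plane), ring.plane)
        assert res.theta == pytest.approx(40.0, abs=1e-9)

    def test_obtuse_angles_not_folded(self):
        ring = _synthetic_ring(112.0)
        res = docking_angle(ring, self._pep(ring.plane), ring.plane)
        assert res.theta == pytest.approx(112.0, abs=1e-9)

    def test_isotropic_ring_flagged(self):
        ring = _synthetic_ring(30.0, a=5.0, b=5.0)
        with pytest.warns(UserWarning, match="low-confidence"):
            res = docking_angle(ring, self._pep(ring.plane), ring.plane)
        assert res.low_confidence


def _transform_unit(c, rot, t):
    out = ComplexStructure(id=c.id, mhc_class=c.mhc_class)
    for cid, chain in c.chains.items():
        residues = [
            Residue(
                r.name,
                r.seq_id,
                tuple(
                    Atom(a.name, a.element, tuple(rot @ a.xyz + t), a.occupancy)
                    for a in r.atoms
                ),
            )
            for r in chain
        ]
        out.chains[cid] = Chain(cid, chain.role, residues)
    return out


def _measure_theta(structure):
    pmhc, tr = truncate_complex(structure)
    cm = compute_contacts(pmhc, tr, 5.0)
    pq = assign_formal_charges(pmhc)
    tq = assign_formal_charges(tr)
    plane = groove_plane(pmhc, tr)
    ring = match_complementary_charges(pq, tq, cm, plane)
    pep = peptide_axis(pmhc)
    return docking_angle(ring, pep, plane, complex_id=structure.id).theta


class TestThetaInvariance:
    def test_rigid_motion_leaves_theta_unchanged(self, toy_complex):
        structure, truth = toy_complex
        rot, t = rigid_transform(np.random.default_rng(12))
        moved = _transform_unit(structure, rot, t)
        assert _measure_theta(moved) == pytest.approx(_measure_theta(structure), abs=1e-6)

    def test_mirror_reflection_maps_theta_to_supplement(self, toy_complex):
        structure, truth = toy_complex
        mirror = np.diag([1.0, -1.0, 1.0])  # reflect across the peptide-normal plane
        reflected = _transform_unit(structure, mirror, np.zeros(3))
        theta = _measure_theta(structure)
        assert _measure_theta(reflected) == pytest.approx(180.0 - theta, abs=1e-6)


class TestThetaRecovery:
    @pytest.mark.parametrize("theta_true", [20.0, 45.0, 72.0, 87.0, 112.0])
    def test_landmark_angles_within_two_degrees(self, theta_true):
        structure, truth = generate_toy_complex(
            ToyComplexSpec(theta_true=theta_true, coordinate_noise=0.3, seed=21)
        )
        assert _measure_theta(structure) == pytest.approx(theta_true, abs=2.0)

    def test_noise_free_recovery_is_exact(self, toy_complex):
        structure, truth = toy_complex
        assert _measure_theta(structure) == pytest.approx(truth.theta_true, abs=0.1)
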