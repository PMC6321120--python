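import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import habitkit as hk
from habitkit.structure_io import bond_graph_for_unit, MolecularUnit
from habitkit.supramolecular_geometry import format_symmetry_code


def units_of(structure):
    return hk.identify_molecules(hk.expand_symmetry(structure), structure.cell)


def rings_of(structure):
    rings = []
    for i, u in enumerate(units_of(structure)):
        rings.extend(hk.perceive_rings(u, unit_index=i, start_id=len(rings) + 1))
    return rings


class TestHydrogenBonds:
    def test_linear_contact_detected_with_requested_geometry(self):
        s = hk.make_contact_pair("hbond", d_ha=1.8, angle=180.0)
        recs = [r for r in hk.detect_hbonds(s) if not r.intra]
        assert len(recs) == 1
        r = recs[0]
        assert r.d_ha == pytest.approx(1.8, abs=1e-6)
        assert r.angle_dha == pytest.approx(180.0, abs=1e-6)
        assert r.d_da == pytest.approx(r.d_dh + 1.8, abs=1e-6)  # collinear

    def test_published_geometry_recovered(self):
        # the archetypal O-H...O row: 0.84 / 1.97 / 2.7999 Å at 170°
        s = hk.make_contact_pair("hbond", d_dh=0.84, d_ha=1.97, angle=170.0)
        r = [x for x in hk.detect_hbonds(s) if not x.intra][0]
        assert r.d_dh == pytest.approx(0.84, abs=1e-6)
        assert r.d_ha == pytest.approx(1.97, abs=1e-6)
        assert r.angle_dha == pytest.approx(170.0, abs=1e-6)
        # law of cosines from the exact construction; the printed 2.7999 is
        # what those (rounded) distances and angle imply to ~1e-3
        expected_da = math.sqrt(0.84**2 + 1.97**2 - 2 * 0.84 * 1.97 * math.cos(math.radians(170)))
        assert r.d_da == pytest.approx(expected_da, abs=1e-9)
        assert r.d_da == pytest.approx(2.7999, abs=2e-3)
        assert r.symmetry_code == "x, y, z"

    def test_bent_contact_rejected(self):
        s = hk.make_contact_pair("hbond", d_ha=1.8, angle=90.0)
        assert [r for r in hk.detect_hbonds(s) if not r.intra] == []

    def test_criteria_are_configurable(self):
        s = hk.make_contact_pair("hbond", d_ha=1.8, angle=90.0)
        crit = hk.HBondCriteria(min_angle=80.0)
        assert [r for r in hk.detect_hbonds(s, crit) if not r.intra]

    def test_hydrogen_free_structure_rejected(self):
        s = hk.make_lj_crystal(4.0, element="C")
        with pytest.raises(ValueError, match="hydrogen"):
            hk.detect_hbonds(s)

    def test_records_invariant_under_symmetry_shift(self):
        """Shifting the whole asymmetric unit by a lattice vector changes nothing."""
        s = hk.make_contact_pair("hbond", d_ha=1.97, angle=170.0)
        shifted = hk.CrystalStructure(
            cell=s.cell, ops=s.ops,
            asym_atoms=[hk.AtomSite(a.label, a.element,
                                    tuple((np.array(a.frac) + 0.25) % 1.0), a.occupancy, a.charge)
                        for a in s.asym_atoms],
        )
        a = [(r.donor, r.acceptor, round(r.d_ha, 6), round(r.angle_dha, 4))
             for r in hk.detect_hbonds(s)]
        b = [(r.donor, r.acceptor, round(r.d_ha, 6), round(r.angle_dha, 4))
             for r in hk.detect_hbonds(shifted)]
        assert a == b


class TestRingPerception:
    def pentane_ring_unit(self):
        coords = hk.make_ring_fixture(5, q2=0.2, phi2=10.0)
        return MolecularUnit(indices=list(range(5)), labels=[f"C{i+1}" for i in range(5)],
                             elements=["C"] * 5, cart=coords, charges=np.zeros(5))

    def test_single_five_ring(self):
        rings = hk.perceive_rings(self.pentane_ring_unit())
        assert len(rings) == 1 and len(rings[0].atom_labels) == 5

    def test_fused_bicyclic_two_rings(self):
        # two hexagons sharing an edge (naphthalene-like skeleton)
        a = 1.40
        coords = []
        for i in range(6):
            ang = math.pi / 3 * i + math.pi / 6
            coords.append((a * math.cos(ang), a * math.sin(ang), 0.0))
        cx = 2 * a * math.cos(math.pi / 6)
        for i in range(6):
            ang = math.pi / 3 * i + math.pi / 6
            p = (cx + a * math.cos(ang), a * math.sin(ang), 0.0)
            if min(np.linalg.norm(np.array(p) - np.array(q)) for q in coords) > 0.1:
                coords.append(p)
        coords = np.array(coords)
        assert len(coords) == 10
        unit = MolecularUnit(indices=list(range(10)), labels=[f"C{i+1}" for i in range(10)],
                             elements=["C"] * 10, cart=coords, charges=np.zeros(10))
        rings = hk.perceive_rings(unit)
        assert len(rings) == 2
        assert sorted(len(r.atom_labels) for r in rings) == [6, 6]
        # oracle: exhaustive simple-cycle enumeration yields cyclomatic number 2
        g = bond_graph_for_unit(unit)
        assert g.number_of_edges() - g.number_of_nodes() + 1 == 2

    def test_centroid_is_unweighted_mean(self):
        ring = hk.perceive_rings(self.pentane_ring_unit())[0]
        assert np.allclose(ring.centroid, ring.coords.mean(axis=0))

    def test_planarity_rms_zero_for_flat_ring(self):
        coords = hk.make_ring_fixture(5, q2=0.0)
        unit = MolecularUnit(indices=list(range(5)), labels=[f"C{i+1}" for i in range(5)],
                             elements=["C"] * 5, cart=coords, charges=np.zeros(5))
        assert hk.perceive_rings(unit)[0].planarity_rms == pytest.approx(0.0, abs=1e-12)


class TestStacking:
    def test_coaxial_parallel_rings(self):
        s = hk.make_contact_pair("pi_pi", perp=3.5, offset=0.0)
        recs = hk.classify_stacking(rings_of(s))
        assert {r.klass for r in recs} == {"pi-pi"}
        r = recs[0]
        assert r.cg_distance == pytest.approx(3.5, abs=1e-9)
        assert r.dihedral == pytest.approx(0.0, abs=1e-9)
        assert r.slippage == pytest.approx(0.0, abs=1e-9)

    def test_offset_stack_pythagoras(self):
        s = hk.make_contact_pair("pi_pi", perp=3.2, offset=2.0)
        r = hk.classify_stacking(rings_of(s))[0]
        assert r.cg_distance == pytest.approx(math.hypot(3.2, 2.0), abs=1e-9)
        assert r.slippage == pytest.approx(2.0, abs=1e-9)

    def test_slippage_perpendicular_identity(self):
        s = hk.make_contact_pair("pi_pi", perp=3.1, offset=1.3)
        rings = rings_of(s)
        for r in hk.classify_stacking(rings):
            ring_i = next(x for x in rings if x.ring_id == r.ring_i)
            ring_j = next(x for x in rings if x.ring_id == r.ring_j)
            d_perp = abs(float((ring_j.centroid - ring_i.centroid) @ ring_i.normal))
            assert r.slippage**2 + d_perp**2 == pytest.approx(r.cg_distance**2, abs=1e-9)

    def test_t_shaped_classification(self):
        s = hk.make_contact_pair("t_shaped", cg=5.2016, dihedral=70.0)
        recs = hk.classify_stacking(rings_of(s))
        assert recs and all(r.klass == "t-shaped" for r in recs)
        assert recs[0].cg_distance == pytest.approx(5.2016, abs=1e-4)
        assert recs[0].dihedral == pytest.approx(70.0, abs=1e-6)
        assert recs[0].slippage is None

    def test_intermediate_angle_unclassified_without_slippage(self):
        s = hk.make_contact_pair("t_shaped", cg=5.0, dihedral=40.0)
        recs = hk.classify_stacking(rings_of(s))
        assert recs and all(r.klass == "unclassified" and r.slippage is None for r in recs)

    def test_beyond_cutoff_ignored(self):
        s = hk.make_contact_pair("pi_pi", perp=6.5, offset=0.0)
        assert hk.classify_stacking(rings_of(s)) == []

    def test_records_are_directional(self):
        # tilt ring 2 slightly: slippage along n_i differs from n_j
        s = hk.make_contact_pair("t_shaped", cg=4.5, dihedral=15.0)
        recs = hk.classify_stacking(rings_of(s))
        by_pair = {(r.ring_i, r.ring_j): r for r in recs}
        assert (1, 2) in by_pair and (2, 1) in by_pair
        assert by_pair[(1, 2)].slippage != pytest.approx(by_pair[(2, 1)].slippage, abs=1e-6)


class TestCremerPople:
    def test_planar_pentagon_unpuckered(self):
        res = hk.cremer_pople(hk.make_ring_fixture(5, q2=0.0))
        assert res.q2 == pytest.approx(0.0, abs=1e-12)
        assert res.conformer == "planar"

    def test_lifted_atom_against_direct_formula(self):
        """One apex displaced: oracle evaluates the textbook sums explicitly."""
        coords = hk.make_ring_fixture(5, q2=0.0)
        coords[0, 2] += 0.5
        res = hk.cremer_pople(coords)
        # oracle: independent evaluation from the mean-plane definition
        centered = coords - coords.mean(axis=0)
        j = np.arange(5)
        rp = (centered * np.sin(2 * np.pi * j / 5)[:, None]).sum(axis=0)
        rpp = (centered * np.cos(2 * np.pi * j / 5)[:, None]).sum(axis=0)
        n = np.cross(rp, rpp)
        n /= np.linalg.norm(n)
        z = centered @ n
        qc = math.sqrt(2 / 5) * float((z * np.cos(4 * np.pi * j / 5)).sum())
        qs = -math.sqrt(2 / 5) * float((z * np.sin(4 * np.pi * j / 5)).sum())
        assert res.q2 == pytest.approx(math.hypot(qc, qs), abs=1e-12)
        assert res.phi2 == pytest.approx(math.degrees(math.atan2(qs, qc)) % 360, abs=1e-9)
        assert abs(z.sum()) < 1e-12

    @pytest.mark.parametrize("q2,phi2", [(0.3831, 42.8048), (0.3838, 221.4092), (0.45, 108.0)])
    def test_inverse_construction_round_trip(self, q2, phi2):
        res = hk.cremer_pople(hk.make_ring_fixture(5, q2=q2, phi2=phi2))
        assert res.q2 == pytest.approx(q2, abs=1e-6)
        assert res.phi2 == pytest.approx(phi2, abs=1e-6)

    def test_envelope_label_for_reference_phase(self):
        res = hk.cremer_pople(hk.make_ring_fixture(5, q2=0.3831, phi2=42.8048))
        assert res.conformer.startswith("envelope")
        assert "atom 2" in res.conformer  # apex is the second ring atom

    @pytest.mark.parametrize("seed", range(12))
    def test_round_trip_robust_to_jitter(self, seed):
        coords = hk.make_ring_fixture(5, q2=0.3831, phi2=42.8048, jitter=0.01, seed=seed)
        res = hk.cremer_pople(coords)
        assert res.q2 == pytest.approx(0.3831, abs=0.02)

    def test_parseval_identity(self):
        coords = hk.make_ring_fixture(6, q2=0.25, phi2=77.0, q3=0.31)
        res = hk.cremer_pople(coords)
        assert sum(v**2 for v in res.q.values()) == pytest.approx(float((res.z**2).sum()), abs=1e-10)

    def test_cyclic_relabeling_preserves_amplitude_shifts_phase(self):
        coords = hk.make_ring_fixture(5, q2=0.31, phi2=50.0)
        base = hk.cremer_pople(coords)
        rolled = hk.cremer_pople(np.roll(coords, -1, axis=0))
        assert rolled.q2 == pytest.approx(base.q2, abs=1e-10)
        # starting one atom later advances the phase by 2·(360/5) = 144°
        assert (rolled.phi2 - base.phi2) % 360 == pytest.approx(144.0, abs=1e-6)

    def test_collinear_ring_rejected(self):
        pts = np.array([[i, 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError):
            hk.cremer_pople(pts)

    def test_infeasible_amplitude_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            hk.make_ring_fixture(5, q2=2.5)


class TestKabsch:
    def test_identical_sets_zero(self):
        a = np.random.default_rng(1).normal(size=(6, 3))
        assert hk.kabsch_rmsd(a, a).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(7, 3))
        rot = Rotation.from_euler("zyx", [0.4, -1.1, 2.2]).as_matrix()
        b = a @ rot.T + np.array([3.0, -1.0, 0.5])
        res = hk.kabsch_rmsd(a, b)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(5, 3))
        b = a + rng.normal(scale=0.1, size=(5, 3))
        assert hk.kabsch_rmsd(a, b).rmsd == pytest.approx(hk.kabsch_rmsd(b, a).rmsd, abs=1e-12)

    def test_against_rotation_grid_refinement(self):
        """Brute-force oracle: numerically minimize RMSD over Euler angles."""
        a = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]], float)
        b = a.copy()
        b[3] += 0.1
        res = hk.kabsch_rmsd(a, b)

        ca, cb = a - a.mean(0), b - b.mean(0)

        def cost(euler):
            r = Rotation.from_euler("zyx", euler).as_matrix()
            return np.sqrt(np.mean(np.sum((cb @ r.T - ca) ** 2, axis=1)))

        best = min(
            (minimize(cost, x0, method="Nelder-Mead",
                      options={"xatol": 1e-12, "fatol": 1e-14}).fun
             for x0 in itertools.product([0.0, 1.0, -1.0], repeat=3)),
        )
        assert res.rmsd == pytest.approx(best, abs=1e-7)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            hk.kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[i, 0, 0] for i in range(4)], float)
        with pytest.raises(ValueError, match="collinear"):
            hk.kabsch_rmsd(line, line)


def test_symmetry_code_formatting(c2c_ops):
    codes = {format_symmetry_code(op) for op in c2c_ops}
    assert "x, y, z" in codes
    assert "-x, -y, -z" in codes
    inv = [op for op in c2c_ops if op.rotation == ((-1, 0, 0), (0, -1, 0), (0, 0, -1))
           and op.translation == (0.0, 0.0, 0.0)][0]
    assert format_symmetry_code(inv, (1, 2, 1)) == "1-x, 2-y, 1-z"
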