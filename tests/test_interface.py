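"""Salt bridges, distance series, SASA."""

import numpy as np
import pytest

from allodyn import interface, synthetic as syn, trajio
from allodyn.exceptions import InputError, ParameterError, SelectionError

from tests.conftest import particle_topology, single_atom_topology


def _charged_chain_traj(n_frames=100, seed=0, charges=None):
    """Chain with CB pseudo-atoms; residues 2 (+1) and 7 (−1) by default."""
    import dataclasses

    top, ref = syn.make_chain_structure(10, 3.8)
    q = np.zeros(top.n_atoms)
    if charges is None:
        charges = {2: 1.0, 7: -1.0}
    for resid, charge in charges.items():
        sel = trajio.select(top, f"resid {resid} and name CB")
        q[sel.atom_indices[0]] = charge
    top = dataclasses.replace(top, charges=q)
    spec = syn.CovarianceSpec(10, sigma=0.3)
    traj = syn.sample_gaussian_trajectory(top, ref, spec, n_frames, seed)
    return top, traj


class TestSaltBridgePopulation:
    def test_planted_occupancy_exact(self):
        top, traj = _charged_chain_traj()
        planted = syn.plant_contact_pair(traj, 2, 7, 0.60, 3.0, 8.0, seed=1)
        rec = interface.salt_bridge_population(planted, 2, 7, cutoff=4.0)
        assert rec.population == pytest.approx(0.60, abs=1e-12)

    def test_always_apart_is_zero(self):
        top, traj = _charged_chain_traj()
        planted = syn.plant_contact_pair(traj, 2, 7, 0.0, 3.0, 8.0, seed=2)
        rec = interface.salt_bridge_population(planted, 2, 7, cutoff=4.0)
        assert rec.population == 0.0

    def test_classification_against_starting_frame(self):
        top, traj = _charged_chain_traj()
        planted = syn.plant_contact_pair(traj, 2, 7, 1.0, 3.0, 8.0, seed=3)
        rec = interface.salt_bridge_population(
            planted, 2, 7, cutoff=4.0, starting_frame=planted.coords[0]
        )
        assert rec.bridge_class == "initial"
        apart = syn.plant_contact_pair(traj, 2, 7, 0.0, 3.0, 8.0, seed=3)
        rec2 = interface.salt_bridge_population(
            planted, 2, 7, cutoff=4.0, starting_frame=apart.coords[0]
        )
        assert rec2.bridge_class == "newly_formed"

    def test_standard_residue_atom_groups(self):
        # LYS NZ vs GLU OE1/OE2 at 3.5 Å -> population 1
        top = trajio.Topology(
            atom_names=np.array(["CA", "NZ", "CA", "OE1", "OE2"], dtype=object),
            elements=np.array(["C", "N", "C", "O", "O"], dtype=object),
            resids=np.array([1, 1, 2, 2, 2]),
            resnames=np.array(["LYS", "LYS", "GLU", "GLU", "GLU"], dtype=object),
            chain_ids=np.array(["A"] * 5, dtype=object),
        )
        coords = np.array(
            [[0, 0, 0], [1, 0, 0], [10, 0, 0], [4.5, 0, 0], [9, 0, 0]], dtype=float
        )
        traj = trajio.Trajectory(coords[None], top)
        rec = interface.salt_bridge_population(traj, 1, 2, cutoff=4.0)
        assert rec.population == 1.0
        assert rec.basic_atoms == ("NZ",)
        assert set(rec.acidic_atoms) == {"OE1", "OE2"}

    def test_missing_atoms_without_override_is_error(self):
        top, ref = syn.make_chain_structure(4, 3.8, side_chains=False)
        traj = trajio.Trajectory(ref[None], top)
        with pytest.raises(ParameterError):
            interface.salt_bridge_population(traj, 1, 3)


class TestScanInterface:
    def test_single_planted_bridge_found_and_classed(self):
        top, traj = _charged_chain_traj()
        planted = syn.plant_contact_pair(traj, 2, 7, 0.8, 3.0, 8.0, seed=4)
        sel_a = trajio.select(top, "resid 1-5")
        sel_b = trajio.select(top, "resid 6-10")
        # force frame 0 into contact for a deterministic "initial" class
        records = interface.scan_interface_salt_bridges(
            planted, sel_a, sel_b, cutoff=4.0, min_population=0.5,
            starting_frame=syn.plant_contact_pair(traj, 2, 7, 1.0, 3.0, 8.0, seed=4).coords[0],
        )
        assert len(records) == 1
        assert records[0].population == pytest.approx(0.8, abs=1e-12)
        assert records[0].bridge_class == "initial"

    def test_high_threshold_empties_scan(self):
        top, traj = _charged_chain_traj()
        planted = syn.plant_contact_pair(traj, 2, 7, 0.8, 3.0, 8.0, seed=5)
        records = interface.scan_interface_salt_bridges(
            planted,
            trajio.select(top, "resid 1-5"),
            trajio.select(top, "resid 6-10"),
            min_population=0.9,
        )
        assert records == []

    def test_scan_equals_exhaustive_per_pair_calls(self):
        top, traj = _charged_chain_traj(charges={2: 1.0, 4: -1.0, 7: -1.0, 9: 1.0})
        planted = syn.plant_contact_pair(traj, 2, 7, 0.7, 3.0, 8.0, seed=6)
        sel_a = trajio.select(top, "resid 1-5")
        sel_b = trajio.select(top, "resid 6-10")
        records = interface.scan_interface_salt_bridges(planted, sel_a, sel_b)
        expected = {}
        for basic, acidic in [(2, 7), (9, 4)]:
            expected[(basic, acidic)] = interface.salt_bridge_population(
                planted, basic, acidic
            ).population
        got = {(r.basic_residue, r.acidic_residue): r.population for r in records}
        assert got == expected

    def test_overlapping_selections_rejected(self):
        top, traj = _charged_chain_traj()
        sel = trajio.select(top, "resid 1-6")
        with pytest.raises(InputError):
            interface.scan_interface_salt_bridges(traj, sel, trajio.select(top, "resid 5-10"))


class TestDistanceSeries:
    def test_constant_pair(self):
        top = particle_topology(2)
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = 5.0
        traj = trajio.Trajectory(coords, top)
        series = interface.distance_series(traj, np.array([0]), np.array([1]))
        np.testing.assert_allclose(series, 5.0)

    def test_min_bounded_by_mean_pairwise_distance(self):
        # the minimum pair distance is bounded by the average pair distance,
        # which itself bounds the centroid distance (Jensen); the centroid
        # distance can undercut the minimum when groups interleave, so only
        # these two inequalities are general
        rng = np.random.default_rng(0)
        top = particle_topology(8)
        coords = rng.normal(0, 5, size=(10, 8, 3))
        traj = trajio.Trajectory(coords, top)
        ga, gb = np.arange(4), np.arange(4, 8)
        dmin = interface.distance_series(traj, ga, gb, "min")
        dcen = interface.distance_series(traj, ga, gb, "centroid")
        for f in range(10):
            pair_mean = np.mean(
                [np.linalg.norm(coords[f, a] - coords[f, b]) for a in ga for b in gb]
            )
            assert dmin[f] <= pair_mean + 1e-12
            assert dcen[f] <= pair_mean + 1e-12

    def test_min_equals_centroid_for_single_atoms(self):
        rng = np.random.default_rng(8)
        top = particle_topology(2)
        coords = rng.normal(0, 5, size=(6, 2, 3))
        traj = trajio.Trajectory(coords, top)
        dmin = interface.distance_series(traj, np.array([0]), np.array([1]), "min")
        dcen = interface.distance_series(traj, np.array([0]), np.array([1]), "centroid")
        np.testing.assert_allclose(dmin, dcen, atol=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        top = particle_topology(6)
        coords = rng.normal(0, 5, size=(4, 6, 3))
        traj = trajio.Trajectory(coords, top)
        ga, gb = np.array([0, 1, 2]), np.array([3, 4, 5])
        series = interface.distance_series(traj, ga, gb, "min")
        for f in range(4):
            brute = min(
                np.linalg.norm(coords[f, a] - coords[f, b]) for a in ga for b in gb
            )
            assert abs(series[f] - brute) < 1e-12

    def test_empty_group_is_error(self):
        top = particle_topology(2)
        traj = trajio.Trajectory(np.zeros((1, 2, 3)), top)
        with pytest.raises(SelectionError):
            interface.distance_series(traj, np.array([], dtype=int), np.array([1]))


class TestComputeSasa:
    def test_isolated_sphere_analytic(self):
        top = single_atom_topology(radius=1.9)
        area = interface.compute_sasa(np.zeros((1, 3)), top, probe=1.4)
        analytic = 4 * np.pi * 3.3**2
        assert abs(area[0] - analytic) / analytic < 0.01

    def test_far_separated_atoms_additive(self):
        top = particle_topology(2, radius=1.9)
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        areas = interface.compute_sasa(coords, top)
        analytic = 4 * np.pi * 3.3**2
        np.testing.assert_allclose(areas, analytic, rtol=0.01)

    def test_caged_atom_fully_buried(self):
        # octahedral + cubic cage of large neighbors around a small atom
        cage = []
        for d in range(3):
            for s in (-1, 1):
                v = np.zeros(3)
                v[d] = 2.2 * s
                cage.append(v)
        for sx in (-1, 1):
            for sy in (-1, 1):
                for sz in (-1, 1):
                    cage.append(np.array([sx, sy, sz]) * 1.6)
        coords = np.vstack([np.zeros(3), cage])
        top = particle_topology(len(coords), radius=1.7)
        areas = interface.compute_sasa(coords, top)
        assert areas[0] == 0.0

    def test_quadrature_convergence(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(0, 2.5, size=(20, 3))
        top = particle_topology(20, radius=1.7)
        t1 = interface.compute_sasa(coords, top, n_sphere_points=480).sum()
        t2 = interface.compute_sasa(coords, top, n_sphere_points=960).sum()
        t3 = interface.compute_sasa(coords, top, n_sphere_points=1920).sum()
        assert abs(t1 - t2) / t2 < 0.02
        assert abs(t3 - t2) / t2 < 0.02

    def test_per_atom_bounded_by_isolated_value(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(0, 3, size=(12, 3))
        top = particle_topology(12, radius=1.7)
        areas = interface.compute_sasa(coords, top)
        assert np.all(areas <= 4 * np.pi * 3.1**2 + 1e-9)

    def test_matches_mdtraj_reference(self):
        """Independent Shrake-Rupley cross-check on a random cluster."""
        mdtraj = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(4)
        n = 10
        coords = rng.normal(0, 2.5, size=(n, 3))
        radius = 1.5
        top = particle_topology(n, radius=radius)
        mine = interface.compute_sasa(coords, top, n_sphere_points=1920)
        df = mdtraj.Topology()
        ch = df.add_chain()
        for i in range(n):
            res = df.add_residue("ALA", ch)
            df.add_atom(f"C{i}", mdtraj.element.carbon, res)
        t = mdtraj.Trajectory(coords[None] / 10.0, df)  # nm
        ref = mdtraj.shrake_rupley(
            t, probe_radius=0.14, n_sphere_points=1920,
            change_radii={"C": radius / 10.0},
        )[0] * 100.0  # nm² -> Å²
        np.testing.assert_allclose(mine, ref, rtol=0.03, atol=0.5)


class TestSiteSasa:
    def test_single_isolated_site_atom(self):
        top = particle_topology(2, radius=1.9)
        coords = np.array([[[0.0, 0, 0], [100.0, 0, 0]]])
        traj = trajio.Trajectory(coords, top)
        res = interface.site_sasa(traj, top, [1])
        assert res.mean == pytest.approx(4 * np.pi * 3.3**2, rel=0.01)

    def test_occlusion_monotone_in_neighbor_distance(self):
        top = particle_topology(3, radius=1.7)
        values = []
        for sep in (20.0, 10.0, 5.0, 3.0, 2.0):
            coords = np.array([[[0.0, 0, 0], [sep, 0, 0], [-sep, 0, 0]]])
            traj = trajio.Trajectory(coords, top)
            values.append(interface.site_sasa(traj, top, [1]).mean)
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
        assert values[-1] < values[0]

    def test_stride_on_static_trajectory(self):
        top = particle_topology(4, radius=1.7)
        rng = np.random.default_rng(5)
        frame = rng.normal(0, 3, size=(4, 3))
        traj = trajio.Trajectory(np.repeat(frame[None], 6, axis=0), top)
        m1 = interface.site_sasa(traj, top, [1, 2], stride=1).mean
        m2 = interface.site_sasa(traj, top, [1, 2], stride=2).mean
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_site_never_exceeds_total(self):
        top = particle_topology(6, radius=1.7)
        rng = np.random.default_rng(6)
        frame = rng.normal(0, 3, size=(6, 3))
        traj = trajio.Trajectory(frame[None], top)
        site = interface.site_sasa(traj, top, [1, 2]).mean
        total = interface.compute_sasa(frame, top).sum()
        assert site <= total + 1e-9

    def test_missing_residue_is_error(self):
        top = particle_topology(3)
        traj = trajio.Trajectory(np.zeros((1, 3, 3)) + np.arange(3)[None, :, None] * 5, top)
        with pytest.raises(SelectionError):
            interface.site_sasa(traj, top, [99])


class TestPercentChange:
    def test_identical_is_zero(self):
        assert interface.percent_change(100.0, 100.0) == 0.0

    def test_plus_23_percent(self):
        assert interface.percent_change(123.0, 100.0) == pytest.approx(23.0)

    def test_antisymmetry_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a, b = rng.uniform(10, 200, size=2)
            lhs = interface.percent_change(a, b)
            rhs = -interface.percent_change(b, a) * a / b
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_zero_reference_is_error(self):
        with pytest.raises(InputError):
            interface.percent_change(5.0, 0.0)
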