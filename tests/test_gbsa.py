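"""MM/GBSA: analytic limits, thermodynamic identities, decomposition."""

import dataclasses

import numpy as np
import pytest

from allodyn import gbsa, synthetic as syn, trajio
from allodyn.exceptions import CapabilityError, ClashError, InputError

from tests.conftest import particle_topology, single_atom_topology


class TestMMCrossEnergy:
    def test_coulomb_closed_form(self, toy_ion_pair):
        s = toy_ion_pair
        e_elec, _ = gbsa.mm_cross_energy(s.trajectory.coords[0], s.topology, [0], [1])
        assert e_elec == pytest.approx(-100.0, abs=1e-9)

    def test_lj_minimum_at_combined_rmin(self):
        top = particle_topology(2)
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])  # rmin_i/2 + rmin_j/2 = 4
        _, e_vdw = gbsa.mm_cross_energy(coords, top, [0], [1])
        assert e_vdw == pytest.approx(-0.1, abs=1e-12)

    def test_matches_generator_ground_truth(self):
        s = syn.make_toy_complex(
            4, 3, [0.5, -0.3, 0.8, 0.0, -0.5, 0.2, -0.7], gap=4.0, seed=3
        )
        e_elec, e_vdw = gbsa.mm_cross_energy(
            s.trajectory.coords[0], s.topology, np.arange(4), np.arange(4, 7)
        )
        assert e_elec == pytest.approx(s.ground_truth["coulomb_cross_energy"], abs=1e-9)
        assert e_vdw == pytest.approx(s.ground_truth["lj_cross_energy"], abs=1e-9)

    def test_clash_detected(self):
        top = particle_topology(2)
        coords = np.array([[0.0, 0, 0], [0.05, 0, 0]])
        with pytest.raises(ClashError):
            gbsa.mm_cross_energy(coords, top, [0], [1])


class TestGBPolar:
    def test_single_ion_born_formula(self):
        top = single_atom_topology(radius=1.7, charge=1.0)
        g = gbsa.gb_polar_energy(np.zeros((1, 3)), top, [0])
        analytic = -166.03185 * (1 - 1 / 78.5) / (1.7 - 0.09)
        assert abs(g - analytic) / abs(analytic) < 1e-6

    def test_far_separated_ions_additive(self):
        """At 500 Å the self (Born) energies decouple to 1e-4 kcal/mol.

        The pair energy also carries the physical solvent-screened Coulomb
        cross term −332.0637·(1/ε_in − 1/ε_out)·q₁q₂/r, which decays only as
        1/r; subtracting that closed form isolates the separability of the
        Born radii and self-energies.
        """
        r = 500.0
        top = particle_topology(2, charges=[1.0, -1.0], radius=1.7)
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        g_pair = gbsa.gb_polar_energy(coords, top, [0, 1])
        cross = -332.0637 * (1 - 1 / 78.5) * (1.0 * -1.0) / r
        g_each = gbsa.gb_polar_energy(np.zeros((1, 3)), single_atom_topology(1.7, 1.0), [0])
        assert abs((g_pair - cross) - 2 * g_each) < 1e-4

    def test_far_separated_neutral_partner_additive(self):
        # with q2 = 0 there is no cross term at all: strict additivity
        top = particle_topology(2, charges=[1.0, 0.0], radius=1.7)
        coords = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        g_pair = gbsa.gb_polar_energy(coords, top, [0, 1])
        g_ion = gbsa.gb_polar_energy(np.zeros((1, 3)), single_atom_topology(1.7, 1.0), [0])
        assert abs(g_pair - g_ion) < 1e-4

    def test_desolvation_monotone_on_approach(self):
        top = particle_topology(2, charges=[1.0, -1.0], radius=1.7)
        separations = np.linspace(12.0, 4.0, 9)
        values = []
        for r in separations:
            coords = np.array([[0.0, 0, 0], [r, 0, 0]])
            values.append(gbsa.gb_polar_energy(coords, top, [0, 1]))
        diffs = np.diff(values)
        assert np.all(diffs > 0), f"G_pol not monotone: {values}"

    def test_per_atom_sums_to_total(self):
        rng = np.random.default_rng(0)
        top = particle_topology(6, charges=rng.uniform(-1, 1, 6), radius=1.7)
        coords = rng.normal(0, 4, size=(6, 3))
        total, per_atom = gbsa.gb_polar_energy(coords, top, return_per_atom=True)
        assert per_atom.sum() == pytest.approx(total, abs=1e-10)


class TestNonpolar:
    def test_intercept(self):
        assert gbsa.nonpolar_solvation(0.0) == pytest.approx(0.92)

    def test_direct_formula(self):
        assert gbsa.nonpolar_solvation(1000.0) == pytest.approx(6.34)

    def test_affine_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a, b = rng.uniform(0, 5000, 2)
            lhs = gbsa.nonpolar_solvation(a) + gbsa.nonpolar_solvation(b)
            assert lhs - gbsa.nonpolar_solvation(a + b) == pytest.approx(0.92, abs=1e-12)

    def test_negative_sasa_rejected(self):
        with pytest.raises(InputError):
            gbsa.nonpolar_solvation(-1.0)


from hypothesis import given, settings  # noqa: E402
from hypothesis import strategies as st  # noqa: E402


class TestEnergyProperties:
    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.floats(0.0, 1e5, allow_nan=False),
        b=st.floats(0.0, 1e5, allow_nan=False),
    )
    def test_nonpolar_affine_identity(self, a, b):
        lhs = gbsa.nonpolar_solvation(a) + gbsa.nonpolar_solvation(b)
        assert lhs - gbsa.nonpolar_solvation(a + b) == pytest.approx(0.92, abs=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(nu=st.floats(5.0, 4000.0), factor=st.floats(1.01, 10.0))
    def test_entropy_decreases_with_frequency(self, nu, factor):
        s_low = gbsa.vibrational_entropy([nu], 310.0)
        s_high = gbsa.vibrational_entropy([nu * factor], 310.0)
        assert s_high < s_low
        assert s_low > 0


def _diatomic(k=100.0, masses=(12.011, 12.011), r0=3.8):
    top = particle_topology(2)
    top = dataclasses.replace(
        top, charges=np.zeros(2), lj_epsilon=np.zeros(2),
        masses=np.asarray(masses, float)
    )
    coords = np.array([[0.0, 0, 0], [r0, 0, 0]])
    model = gbsa.ToyEnergyModel(top, bonds=[(0, 1, k, r0)])
    return coords, model


class TestHarmonicEntropy:
    def test_matches_closed_form_oscillator(self):
        k, m = 100.0, 12.011
        coords, model = _diatomic(k, (m, m))
        result = gbsa.harmonic_entropy(coords, model, 310.0)
        mu = m / 2
        nu = np.sqrt(k / mu * 4.184e26) / (2 * np.pi * 2.99792458e10)
        x = 1.4387768775039337 * nu / 310.0
        R = 1.987204259e-3
        closed = R * (x / np.expm1(x) - np.log1p(-np.exp(-x)))
        assert len(result["frequencies_cm1"]) == 1
        assert result["frequencies_cm1"][0] == pytest.approx(nu, rel=1e-6)
        assert abs(result["entropy"] - closed) < 1e-8

    def test_translation_invariance(self):
        coords, model = _diatomic()
        s1 = gbsa.harmonic_entropy(coords, model, 310.0)["entropy"]
        s2 = gbsa.harmonic_entropy(coords + np.array([7.0, -3.0, 11.0]), model, 310.0)["entropy"]
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_stiffer_bond_lowers_entropy(self):
        c1, m1 = _diatomic(k=100.0)
        c2, m2 = _diatomic(k=200.0)
        r1 = gbsa.harmonic_entropy(c1, m1, 310.0)
        r2 = gbsa.harmonic_entropy(c2, m2, 310.0)
        assert r2["frequencies_cm1"][0] == pytest.approx(
            np.sqrt(2) * r1["frequencies_cm1"][0], rel=1e-8
        )
        assert r2["entropy"] < r1["entropy"]

    def test_minimization_reaches_stationary_point(self):
        coords, model = _diatomic(k=50.0, r0=3.0)
        stretched = coords.copy()
        stretched[1, 0] = 3.6
        result = gbsa.harmonic_entropy(stretched, model, 310.0)
        assert np.linalg.norm(model.gradient(result["minimized_coords"])) < 1e-6


class TestBindingFreeEnergy:
    def _rigid_ion_traj(self):
        s = syn.make_toy_complex(1, 1, [1.0, -1.0], gap=3.320637, seed=0, n_frames=10)
        return s

    def test_term_identity_per_snapshot(self):
        s = self._rigid_ion_traj()
        opts = gbsa.EnergyOptions(n_energy_snapshots=5, sasa_points=240)
        dec = gbsa.binding_free_energy(s.trajectory, s.topology, [0], [1], opts)
        per_snap = dec.delta_g_per_snapshot
        manual = (
            dec.terms["dE_inter"]
            + dec.terms["dE_elec"]
            + dec.terms["dE_vdW"]
            + dec.terms["dG_sol_elec"]
            + dec.terms["dG_sol_nonpolar"]
            + dec.minus_t_delta_s
        )
        np.testing.assert_allclose(per_snap, manual, atol=1e-9)
        assert dec.delta_g == pytest.approx(
            dec.delta_e_mm + dec.delta_g_sol + dec.minus_t_delta_s, abs=1e-9
        )

    def test_internal_term_exactly_zero(self):
        s = self._rigid_ion_traj()
        opts = gbsa.EnergyOptions(n_energy_snapshots=3, sasa_points=240)
        dec = gbsa.binding_free_energy(s.trajectory, s.topology, [0], [1], opts)
        assert np.all(dec.terms["dE_inter"] == 0.0)

    def test_rigid_frames_identical_and_match_closed_form(self):
        s = self._rigid_ion_traj()
        opts = gbsa.EnergyOptions(n_energy_snapshots=5, sasa_points=960)
        dec = gbsa.binding_free_energy(s.trajectory, s.topology, [0], [1], opts)
        for term in dec.terms.values():
            assert np.ptp(term) < 1e-9
        frame = s.trajectory.coords[0]
        e_elec, e_vdw = gbsa.mm_cross_energy(frame, s.topology, [0], [1])
        gp = (
            gbsa.gb_polar_energy(frame, s.topology, [0, 1], options=opts)
            - gbsa.gb_polar_energy(frame, s.topology, [0], options=opts)
            - gbsa.gb_polar_energy(frame, s.topology, [1], options=opts)
        )
        from allodyn.interface import compute_sasa

        sc = compute_sasa(frame, s.topology, None, 1.4, 960).sum()
        sa = compute_sasa(frame[:1], _sub_top(s.topology, [0]), None, 1.4, 960).sum()
        sb = compute_sasa(frame[1:], _sub_top(s.topology, [1]), None, 1.4, 960).sum()
        expected = e_elec + e_vdw + gp + (0.00542 * (sc - sa - sb) - 0.92)
        assert dec.delta_g == pytest.approx(expected, abs=1e-9)
        assert e_elec == pytest.approx(-100.0, abs=1e-9)

    def test_distant_neutral_complex_decouples(self):
        s = syn.make_toy_complex(2, 2, [0.0] * 4, gap=50.0, seed=2, n_frames=4)
        opts = gbsa.EnergyOptions(n_energy_snapshots=2, sasa_points=240)
        dec = gbsa.binding_free_energy(
            s.trajectory, s.topology, np.arange(2), np.arange(2, 4), opts
        )
        m = dec.term_means
        assert abs(m["dE_elec"]) < 1e-6
        assert abs(m["dG_sol_elec"]) < 1e-6
        assert dec.delta_g == pytest.approx(m["dE_vdW"] + m["dG_sol_nonpolar"], abs=1e-6)

    def test_part_swap_symmetry(self):
        s = syn.make_toy_complex(3, 2, [0.4, -0.2, 0.1, -0.6, 0.3], gap=4.5, seed=5, n_frames=6)
        opts = gbsa.EnergyOptions(n_energy_snapshots=3, sasa_points=240)
        a, b = np.arange(3), np.arange(3, 5)
        d1 = gbsa.binding_free_energy(s.trajectory, s.topology, a, b, opts)
        d2 = gbsa.binding_free_energy(s.trajectory, s.topology, b, a, opts)
        assert d1.delta_g == pytest.approx(d2.delta_g, abs=1e-12)

    def test_overlapping_parts_rejected(self):
        s = self._rigid_ion_traj()
        with pytest.raises(InputError):
            gbsa.binding_free_energy(s.trajectory, s.topology, [0], [0, 1])

    def test_entropy_needs_energy_model(self):
        s = self._rigid_ion_traj()
        opts = gbsa.EnergyOptions(entropy=True, n_energy_snapshots=2, n_entropy_snapshots=1)
        with pytest.raises(CapabilityError):
            gbsa.binding_free_energy(s.trajectory, s.topology, [0], [1], opts)


def _sub_top(top, idx):
    idx = np.asarray(idx)
    return dataclasses.replace(
        top,
        atom_names=top.atom_names[idx],
        elements=top.elements[idx],
        resids=top.resids[idx],
        resnames=top.resnames[idx],
        chain_ids=top.chain_ids[idx],
        charges=top.charges[idx],
        lj_rmin_half=top.lj_rmin_half[idx],
        lj_epsilon=top.lj_epsilon[idx],
        gb_radius=top.gb_radius[idx],
        masses=top.masses[idx],
    )


class TestPerResidueDecomposition:
    def test_charged_pair_splits_evenly(self):
        # residues 1 and 4 carry the only charges; electrostatics must land
        # half on each side of the closed-form -100 kcal/mol pair term
        s = syn.make_toy_complex(2, 2, [1.0, 0.0, 0.0, -1.0], gap=10.0, seed=1, n_frames=2)
        coords = s.trajectory.coords.copy()
        # place the charged pair at the -100 kcal/mol distance, far from others
        coords[:, 0] = [0.0, 0.0, 0.0]
        coords[:, 1] = [0.0, 200.0, 0.0]
        coords[:, 3] = [3.320637, 0.0, 0.0]
        coords[:, 2] = [3.320637, 200.0, 0.0]
        traj = trajio.Trajectory(coords, s.topology)
        opts = gbsa.EnergyOptions(n_energy_snapshots=2, sasa_points=240)
        elec, _ = gbsa._mm_pair_matrices(coords[0], s.topology, np.arange(2), np.arange(2, 4), 1.0)
        dec = gbsa.per_residue_decomposition(traj, s.topology, np.arange(2), np.arange(2, 4), opts)
        # isolate the electrostatic share: recompute with charges zeroed
        neutral = _sub_top(s.topology, np.arange(4))
        neutral = dataclasses.replace(neutral, charges=np.zeros(4))
        dec0 = gbsa.per_residue_decomposition(traj, neutral, np.arange(2), np.arange(2, 4), opts)
        elec_share = {r: dec.per_residue[r] - dec0.per_residue[r] for r in dec.per_residue}
        total_elec = sum(elec_share.values())
        assert total_elec == pytest.approx(elec.sum() + (
            dec.term_means["dG_sol_elec"] - dec0.term_means["dG_sol_elec"]), abs=1e-6)
        # gas-phase -100 splits -50/-50 between residues 1 and 4
        gas_share_1 = 0.5 * elec[0, :].sum()
        assert gas_share_1 == pytest.approx(-50.0, abs=1e-3)

    def test_conservation_sum_equals_total(self):
        s = syn.make_toy_complex(3, 3, [0.5, -0.2, 0.1, -0.4, 0.3, -0.3], gap=4.0,
                                 seed=7, n_frames=4)
        opts = gbsa.EnergyOptions(n_energy_snapshots=2, sasa_points=240)
        a, b = np.arange(3), np.arange(3, 6)
        dec = gbsa.per_residue_decomposition(s.trajectory, s.topology, a, b, opts)
        total_enthalpic = (
            dec.term_means["dE_elec"]
            + dec.term_means["dE_vdW"]
            + dec.term_means["dG_sol_elec"]
            + (dec.term_means["dG_sol_nonpolar"] + 0.92)  # beta reported separately
        )
        assert sum(dec.per_residue.values()) == pytest.approx(total_enthalpic, abs=1e-6)

    def test_significance_threshold_filter(self):
        values = {1: -5.6, 2: -0.4, 3: -2.9}
        significant = sorted(r for r, v in values.items() if v < -1.0)
        assert significant == [1, 3]
        # and the library applies the same rule
        s = syn.make_toy_complex(1, 1, [1.0, -1.0], gap=3.320637, seed=0, n_frames=2)
        opts = gbsa.EnergyOptions(n_energy_snapshots=1, sasa_points=240)
        dec = gbsa.per_residue_decomposition(s.trajectory, s.topology, [0], [1], opts)
        assert dec.significant == sorted(
            r for r, v in dec.per_residue.items() if v < -1.0
        )
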