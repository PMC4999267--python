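"""Force field, builders and synthetic trajectory generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import miningminima as mm


def fd_gradient(system, x, solvation=None, h=1e-6):
    g = np.zeros(x.size)
    flat = x.ravel()
    for a in range(x.size):
        xp = flat.copy(); xp[a] += h
        xm = flat.copy(); xm[a] -= h
        g[a] = (mm.potential_energy(system, xp.reshape(-1, 3), solvation)
                - mm.potential_energy(system, xm.reshape(-1, 3), solvation)) / (2 * h)
    return g.reshape(-1, 3)


class TestEnergyGradient:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_analytic_gradient_matches_finite_differences(self, seed):
        sys_ = mm.build_chain(3, lj_epsilon=0.1,
                              charges=[0.2, -0.1, 0.0, 0.1, -0.2, 0.0])
        rng = np.random.default_rng(seed)
        x = sys_.coords + 0.15 * rng.standard_normal(sys_.coords.shape)
        solv = mm.SolvationModel(kind="born", born_radii=np.full(6, 1.8))
        g = mm.gradient(sys_, x, solv)
        fd = fd_gradient(sys_, x, solv)
        assert np.max(np.abs(g - fd)) / np.max(np.abs(fd)) < 1e-6

    def test_compiled_kernel_matches_reference_numpy_path(self):
        sys_ = mm.build_chain(4, lj_epsilon=0.1,
                              charges=[0.3, -0.1, 0.0, 0.1, -0.2, 0.0, -0.1])
        rng = np.random.default_rng(3)
        x = sys_.coords + 0.1 * rng.standard_normal(sys_.coords.shape)
        fast = mm.energy_components(sys_, x)
        slow = mm.energy_components(sys_, x, compiled=False)
        for key in ("bond", "angle", "torsion", "vdw", "coul"):
            assert fast[key] == pytest.approx(slow[key], abs=1e-10)
        assert np.allclose(mm.gradient(sys_, x),
                           mm.gradient(sys_, x, compiled=False), atol=1e-10)

    def test_solvation_w_is_zero_for_kind_none(self):
        sys_ = mm.build_chain(1, charges=[0.5, -0.5, 0.0, 0.0])
        assert mm.VACUUM.energy(sys_, sys_.coords) == 0.0


class TestBuildChain:
    def test_three_fold_torsion_has_three_wells(self, chain1, chain1_search):
        pool, _ = chain1_search
        assert len(pool) == 3
        found = sorted(round(r.torsions_deg[0]) for r in pool)
        assert found == [-60, 60, 180]

    def test_27_wells_match_grid_enumeration(self, chain3_search, chain3_grid_oracle):
        pool, _ = chain3_search
        assert len(pool) == 27
        assert len(chain3_grid_oracle) == 27
        for r in chain3_grid_oracle:
            assert any(mm.circular_torsion_distance(r.torsions_deg, p.torsions_deg) < 15.0
                       for p in pool)

    def test_flat_torsion_profile_gives_single_well(self):
        flat = mm.build_chain(1, torsion_params=((0.0, 3, 0.0),))
        pool, _ = mm.run_search(flat)
        assert len(pool) == 1

    def test_nonpositive_force_constant_rejected(self):
        with pytest.raises(mm.ParameterError):
            mm.build_chain(1, bond_k=0.0)
        with pytest.raises(mm.ParameterError):
            mm.build_chain(1, angle_k=-5.0)
        with pytest.raises(mm.ParameterError):
            mm.build_chain(0)


class TestHostGuest:
    def test_host_minimization_keeps_frozen_atoms_bit_identical(self, host_guest):
        host, _, _ = host_guest
        x, _, ok = mm.minimize(host)
        assert ok
        assert np.array_equal(x[host.frozen], host.coords[host.frozen])

    def test_far_separated_neutralized_complex_has_no_interaction(self, host_guest):
        host, guest, _ = host_guest
        far = mm.concatenate_systems(host, guest,
                                     guest_coords=guest.coords + np.array([500.0, 0, 0]))
        far.charges[:] = 0.0
        far._compiled = None
        lig = np.zeros(far.n_atoms, dtype=bool)
        lig[host.n_atoms:] = True
        inter = mm.interaction_terms(far, far.coords, ~lig, lig)
        assert abs(inter["vdw"]) < 1e-6
        assert abs(inter["coul"]) < 1e-6

    def test_free_guest_has_folded_and_extended_families(self, host_guest, guest_search):
        _, guest, _ = host_guest
        pool, _ = guest_search
        d = mm.end_to_end_distances(guest, pool)
        # two well-separated end-to-end distance families
        assert d.min() < 4.5 < d.max()


class TestSyntheticTrajectories:
    def test_populations_recover_spec_weights(self, three_state_trajectory):
        spec, traj = three_state_trajectory
        ang = traj.series("chi")
        centers = np.array([-60.0, 60.0, -180.0])
        # assign each frame to the circularly nearest center
        d = np.abs(ang[:, None] - centers[None, :])
        d = np.minimum(d, 360.0 - d)
        counts = np.bincount(np.argmin(d, axis=1), minlength=3) / len(ang)
        assert np.max(np.abs(counts - np.array([0.5, 0.3, 0.2]))) < 0.02

    def test_wraparound_state_straddles_boundary(self):
        spec = mm.SyntheticTrajectorySpec(
            dihedrals={"d": [(175.0, 60.0, 1.0)]}, n_frames=1000, seed=5)
        a = mm.generate_dihedral_trajectory(spec).series("d")
        assert np.all((a >= -180.0) & (a < 180.0))
        assert np.any(a > 170.0) and np.any(a < -170.0)

    def test_zero_frames_is_an_empty_trajectory(self):
        spec = mm.SyntheticTrajectorySpec(
            dihedrals={"d": [(0.0, 10.0, 1.0)]}, n_frames=0, seed=0)
        traj = mm.generate_dihedral_trajectory(spec)
        assert traj.n_frames == 0

    def test_bad_weights_rejected(self):
        with pytest.raises(mm.ParameterError):
            mm.SyntheticTrajectorySpec(
                dihedrals={"d": [(0.0, 10.0, 0.7), (90.0, 10.0, 0.7)]}, n_frames=10)

    def test_generation_is_bit_reproducible(self):
        spec = mm.SyntheticTrajectorySpec(
            dihedrals={"d": [(-60.0, 20.0, 0.6), (60.0, 20.0, 0.4)]},
            n_frames=500, seed=11, correlation=0.3)
        a = mm.generate_dihedral_trajectory(spec).series("d")
        b = mm.generate_dihedral_trajectory(spec).series("d")
        assert np.array_equal(a, b)


class TestIO:
    def test_system_yaml_round_trip(self, tmp_path, host_guest):
        host, _, _ = host_guest
        p = tmp_path / "host.yaml"
        host.save(p)
        back = mm.ToyMolecularSystem.load(p)
        assert np.allclose(back.coords, host.coords)
        assert np.array_equal(back.frozen, host.frozen)
        assert back.bonds == host.bonds
        assert mm.potential_energy(back) == pytest.approx(mm.potential_energy(host))

    def test_multiframe_xyz_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        frames = rng.standard_normal((3, 4, 3))
        p = tmp_path / "t.xyz"
        mm.write_xyz(p, ["C", "O", "N", "S"], frames)
        els, back = mm.read_xyz(p)
        assert els == ["C", "O", "N", "S"]
        assert np.allclose(back, frames, atol=1e-7)

    @given(st.floats(min_value=-1e4, max_value=1e4))
    @settings(deadline=None, max_examples=50)
    def test_wrap_angle_stays_in_range(self, a):
        w = float(mm.wrap_angle_deg(a))
        assert -180.0 <= w < 180.0
        assert abs((w - a) % 360.0) < 1e-6 or abs((w - a) % 360.0 - 360.0) < 1e-6
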