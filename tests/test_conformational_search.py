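"""Minimization, distortion, deduplication and the iterated search."""

import numpy as np
import pytest

import miningminima as mm
from miningminima.conformational_search import make_conformer


class TestMinimize:
    def test_start_at_minimum_is_a_fixed_point(self, chain1, chain1_search):
        pool, _ = chain1_search
        x, e, ok = mm.minimize(chain1, pool[0].coords)
        assert ok
        assert np.array_equal(x, pool[0].coords)
        assert e == pytest.approx(pool[0].energy, abs=1e-12)

    def test_double_well_descends_to_the_nearer_well(self):
        # 2-fold torsion: wells at +-90, barrier at 0/180
        sys_ = mm.build_chain(1, torsion_params=((3.0, 2, 0.0),))
        state = mm.cartesian_to_bat(sys_, zmatrix=mm.reference_zmatrix(sys_))
        # dense scan oracle of the torsion profile
        phis = np.linspace(-np.pi, np.pi, 1441)
        ti = state.torsion_indices
        q0 = state.q

        def energy_at(phi):
            q = q0.copy()
            q[ti[0]] = phi
            return mm.potential_energy(sys_, mm.bat_to_cartesian(state.with_q(q)))

        scan = np.array([energy_at(p) for p in phis])
        wells_deg = sorted(round(np.rad2deg(phis[i])) for i in range(1, 1440)
                           if scan[i] < scan[i - 1] and scan[i] < scan[i + 1])
        assert wells_deg == [-90, 90]
        # start just on the +90 side of the barrier top at 0
        q = q0.copy()
        q[ti[0]] = np.deg2rad(12.0)
        x, e, ok = mm.minimize(sys_, mm.bat_to_cartesian(state.with_q(q)))
        assert ok
        final = mm.cartesian_to_bat(sys_, x, zmatrix=mm.reference_zmatrix(sys_))
        assert final.torsions_deg[0] == pytest.approx(90.0, abs=1.0)

    def test_harmonic_system_reaches_analytic_minimum(self):
        # bonds and angles only: the minimum energy is exactly zero
        sys_ = mm.build_chain(1, torsion_params=((0.0, 3, 0.0),))
        rng = np.random.default_rng(0)
        x0 = sys_.coords + 0.2 * rng.standard_normal(sys_.coords.shape)
        _, e, ok = mm.minimize(sys_, x0)
        assert ok
        assert e < 1e-8

    def test_energy_never_increases(self, chain3):
        rng = np.random.default_rng(1)
        for _ in range(3):
            x0 = chain3.coords + 0.3 * rng.standard_normal(chain3.coords.shape)
            e0 = mm.potential_energy(chain3, x0)
            _, e, _ = mm.minimize(chain3, x0)
            assert e <= e0 + 1e-9


class TestDistortAndDescend:
    def test_three_fold_parent_reaches_the_other_wells(self, chain1):
        cfg = mm.SearchConfig()
        parent = make_conformer(chain1, chain1.coords, config=cfg)
        kids = mm.distort_and_descend(chain1, parent, cfg)
        angles = {round(k.torsions_deg[0] / 10) * 10 for k in kids}
        # parent sits at 180; both other wells must appear among candidates
        assert {-60, 60} <= {a for a in angles}

    def test_zero_amplitude_reproduces_the_parent(self, chain1):
        cfg = mm.SearchConfig(amplitudes=(0.0,))
        parent = make_conformer(chain1, chain1.coords, config=cfg)
        kids = mm.distort_and_descend(chain1, parent, cfg)
        assert kids
        for k in kids:
            assert mm.circular_torsion_distance(k.torsions_deg, parent.torsions_deg) < 1e-6

    def test_host_stays_frozen_in_every_candidate(self, host_guest):
        _, _, comp = host_guest
        cfg = mm.SearchConfig(amplitudes=(np.deg2rad(60.0),))
        parent = make_conformer(comp, comp.coords, config=cfg)
        kids = mm.distort_and_descend(comp, parent, cfg)
        assert kids
        for k in kids:
            assert np.array_equal(k.coords[comp.frozen], comp.coords[comp.frozen])


class TestDeduplicate:
    def _rec(self, torsions, energy):
        return mm.ConformerRecord(torsions_deg=np.asarray(torsions, float),
                                  energy=energy)

    def test_nearly_identical_records_collapse(self):
        a = self._rec([10.0, 20.0, 30.0], 1.0)
        b = self._rec([10.01, 20.01, 30.01], 1.0 + 1e-6)
        out = mm.deduplicate([a, b], threshold_deg=5.0)
        assert len(out) == 1
        assert out[0].energy == 1.0   # lowest-energy representative kept

    def test_wrap_aware_distance_merges_across_180(self):
        a = self._rec([-179.0], 0.5)
        b = self._rec([179.0], 0.5)
        assert mm.circular_torsion_distance(a.torsions_deg, b.torsions_deg) == pytest.approx(2.0)
        assert len(mm.deduplicate([a, b], threshold_deg=5.0)) == 1

    def test_close_torsions_but_distinct_energies_survive(self):
        a = self._rec([10.0], 0.0)
        b = self._rec([11.0], 0.5)   # same well geometrically, different energy
        assert len(mm.deduplicate([a, b], threshold_deg=5.0)) == 2

    def test_27_distinct_minima_survive(self, chain3_search):
        pool, _ = chain3_search
        assert len(mm.deduplicate(pool, threshold_deg=15.0)) == 27

    def test_idempotence(self, chain3_search):
        pool, _ = chain3_search
        once = mm.deduplicate(pool)
        twice = mm.deduplicate(once)
        assert [r.energy for r in once] == [r.energy for r in twice]


class TestRunSearch:
    def test_finds_all_27_wells_with_nonincreasing_free_energy(self, chain3_search,
                                                               chain3_grid_oracle):
        pool, hist = chain3_search
        assert len(pool) == 27
        assert all(hist[i + 1] <= hist[i] + 1e-9 for i in range(len(hist) - 1))
        for r in chain3_grid_oracle:
            assert any(mm.circular_torsion_distance(r.torsions_deg, p.torsions_deg) < 15.0
                       for p in pool)

    def test_search_is_invariant_to_the_starting_well(self, chain3, chain3_search):
        pool, _ = chain3_search
        # start from a different well than the default anti chain
        start = next(r for r in pool
                     if mm.circular_torsion_distance(r.torsions_deg,
                                                     pool[0].torsions_deg) > 30)
        pool2, _ = mm.run_search(chain3, start_coords=start.coords)
        assert len(pool2) == 27
        set1 = sorted(tuple(np.round(r.torsions_deg / 15)) for r in pool)
        set2 = sorted(tuple(np.round(r.torsions_deg / 15)) for r in pool2)
        assert set1 == set2

    def test_single_well_converges_in_one_iteration(self):
        sys_ = mm.build_chain(1, torsion_params=((0.0, 3, 0.0),))
        pool, hist = mm.run_search(sys_)
        assert len(pool) == 1
        assert len(hist) == 2   # initial value + one confirming iteration

    def test_guest_pool_contains_folded_and_extended_families(self, host_guest,
                                                              guest_search):
        _, guest, _ = host_guest
        pool, hist = guest_search
        d = mm.end_to_end_distances(guest, pool)
        assert d.min() < 4.5 < d.max()
        assert all(hist[i + 1] <= hist[i] + 1e-9 for i in range(len(hist) - 1))
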