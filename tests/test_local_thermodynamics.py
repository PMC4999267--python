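"""Configuration integrals, free-energy accumulation, entropy split."""

import copy

import numpy as np
import pytest

import miningminima as mm
from miningminima.conformational_search import make_conformer
from conftest import torsional_quadrature_g


@pytest.fixture(scope="module")
def stiff_single_torsion():
    """1-fold cosine well with curvature above the soft-mode threshold."""
    sys_ = mm.build_chain(1, torsion_params=((5.0, 1, 0.0),))
    rec = make_conformer(sys_, sys_.coords)
    return sys_, rec


class TestLocalIntegral:
    def test_stiff_harmonic_well_is_the_gaussian_integral(self, stiff_single_torsion,
                                                          thermo_config):
        sys_, rec = stiff_single_torsion
        rec = copy.copy(rec)
        mm.local_integral(sys_, rec, thermo_config)
        rt = thermo_config.rt
        lam = rec.hessian.eigenvalues[0]
        assert lam >= thermo_config.soft_mode_threshold
        ba = rec.hessian.bond_angle_indices
        blk = rec.hessian.full[np.ix_(ba, ba)]
        expected = (0.5 * np.sum(np.log(2 * np.pi * rt / np.linalg.eigvalsh(blk)))
                    + 0.5 * np.log(2 * np.pi * rt / lam)
                    - rec.energy / rt)
        assert rec.log_z == pytest.approx(expected, abs=1e-9)

    def test_soft_anharmonic_well_matches_dense_quadrature(self, thermo_config):
        # a shallow 1-fold well below the threshold is handled by quadrature
        sys_ = mm.build_chain(1, torsion_params=((0.8, 1, 0.0),))
        rec = make_conformer(sys_, sys_.coords)
        assert rec.hessian.eigenvalues[0] < thermo_config.soft_mode_threshold
        mm.local_integral(sys_, rec, thermo_config)
        # independent dense-trapezoid oracle over the full period
        state = rec.hessian.state
        q0 = state.q
        ti = state.torsion_indices
        phis = np.linspace(-np.pi, np.pi, 4001)
        du = np.empty_like(phis)
        for i, p in enumerate(phis):
            q = q0.copy()
            q[ti[0]] = p
            du[i] = mm.potential_energy(sys_, mm.bat_to_cartesian(state.with_q(q))) - rec.energy
        z_oracle = np.trapezoid(np.exp(-du / thermo_config.rt), phis)
        ba = rec.hessian.bond_angle_indices
        blk = rec.hessian.full[np.ix_(ba, ba)]
        log_expected = (0.5 * np.sum(np.log(2 * np.pi * thermo_config.rt
                                            / np.linalg.eigvalsh(blk)))
                        + np.log(z_oracle) - rec.energy / thermo_config.rt)
        assert rec.log_z == pytest.approx(log_expected, abs=np.log(1.01))

    def test_symmetry_equivalent_wells_have_equal_integrals(self, chain1,
                                                            chain1_search,
                                                            thermo_config):
        pool, _ = chain1_search
        zs = []
        for rec in pool:
            r = copy.copy(rec)
            mm.local_integral(chain1, r, thermo_config)
            zs.append(r.log_z)
        assert np.ptp(zs) < 1e-9

    def test_saddle_point_rejected(self, chain1, thermo_config):
        # a record doctored to carry a negative torsional eigenvalue
        rec = make_conformer(chain1, chain1.coords)
        bad = copy.copy(rec)
        bad.hessian = copy.copy(rec.hessian)
        bad.hessian.eigenvalues = np.array([-1.0])
        with pytest.raises(mm.ThermoError):
            mm.local_integral(chain1, bad, thermo_config)


class TestAccumulation:
    def _harmonic_record(self, log_z, energy=0.0, mean_energy=None):
        return mm.ConformerRecord(energy=energy, log_z=log_z,
                                  mean_energy=energy if mean_energy is None else mean_energy)

    def test_two_identical_wells_shift_g_by_minus_rt_ln2(self, thermo_config):
        one = mm.accumulate_free_energy([self._harmonic_record(1.3)], thermo_config)
        two = mm.accumulate_free_energy([self._harmonic_record(1.3)] * 2, thermo_config)
        assert two.free_energy - one.free_energy == pytest.approx(
            -thermo_config.rt * np.log(2.0), abs=1e-12)

    def test_single_well_equipartition(self, stiff_single_torsion, thermo_config):
        sys_, rec = stiff_single_torsion
        rec = copy.copy(rec)
        mm.local_integral(sys_, rec, thermo_config)
        led = mm.accumulate_free_energy([rec], thermo_config)
        n_modes = rec.hessian.full.shape[0]
        assert led.mean_energy - rec.energy == pytest.approx(
            0.5 * thermo_config.rt * n_modes, rel=1e-9)

    def test_entropy_identity_holds_on_every_ledger(self, chain3_search, thermo_config):
        pool, _ = chain3_search
        led = mm.accumulate_free_energy(pool, thermo_config)
        assert led.free_energy - (led.mean_energy + led.minus_t_s_config) == pytest.approx(
            0.0, abs=1e-9)
        assert np.sum(led.weights) == pytest.approx(1.0, abs=1e-12)

    def test_appending_a_well_strictly_lowers_g(self, thermo_config):
        recs = [self._harmonic_record(0.0)]
        g = mm.accumulate_free_energy(recs, thermo_config).free_energy
        for log_z in (-5.0, -1.0, 2.0):
            recs.append(self._harmonic_record(log_z))
            g_new = mm.accumulate_free_energy(recs, thermo_config).free_energy
            assert g_new < g
            g = g_new

    def test_conformer_order_never_changes_the_result(self, chain3_search,
                                                      thermo_config):
        pool, _ = chain3_search
        led = mm.accumulate_free_energy(pool, thermo_config)
        rng = np.random.default_rng(0)
        perm = list(pool)
        rng.shuffle(perm)
        led2 = mm.accumulate_free_energy(perm, thermo_config)
        assert led2.free_energy == pytest.approx(led.free_energy, abs=1e-12)
        assert led2.mean_energy == pytest.approx(led.mean_energy, abs=1e-10)

    def test_empty_list_rejected(self, thermo_config):
        with pytest.raises(mm.ThermoError):
            mm.accumulate_free_energy([], thermo_config)


class TestOracleEquivalence:
    def test_one_torsion_g_matches_dense_quadrature(self, chain1, chain1_search,
                                                    thermo_config):
        pool, _ = chain1_search
        for rec in pool:
            if rec.log_z is None:
                mm.local_integral(chain1, rec, thermo_config)
        g = mm.accumulate_free_energy(pool, thermo_config).free_energy
        g_oracle = torsional_quadrature_g(chain1, pool, thermo_config)
        assert abs(g - g_oracle) < 0.1

    def test_two_torsion_g_matches_dense_quadrature(self, thermo_config):
        sys_ = mm.build_chain(2)
        pool, _ = mm.run_search(sys_)
        assert len(pool) == 9
        for rec in pool:
            if rec.log_z is None:
                mm.local_integral(sys_, rec, thermo_config)
        g = mm.accumulate_free_energy(pool, thermo_config).free_energy
        g_oracle = torsional_quadrature_g(sys_, pool, thermo_config)
        assert abs(g - g_oracle) < 0.1

    def test_low_temperature_limit_recovers_the_minimum_energy(self, chain1):
        cfg = mm.ThermoConfig(temperature=1.0)
        scfg = mm.SearchConfig(temperature=1.0)
        pool, _ = mm.run_search(chain1, config=scfg)
        for rec in pool:
            mm.local_integral(chain1, rec, cfg)
        led = mm.accumulate_free_energy(pool, cfg)
        assert abs(led.free_energy - pool[0].energy) < 0.05


class TestBinding:
    def _ledger(self, log_zs, config, energies=None):
        energies = energies if energies is not None else [0.0] * len(log_zs)
        recs = [mm.ConformerRecord(energy=e, log_z=lz, mean_energy=e)
                for lz, e in zip(log_zs, energies)]
        return mm.accumulate_free_energy(recs, config)

    def test_non_interacting_guest_in_standard_volume_binds_with_zero_dg(self,
                                                                         thermo_config):
        # complex = receptor x ligand x (free volume 1/C0' and full rotation);
        # Z_complex picks up exactly the 8 pi^2 / C0' the standard state removes
        rec = self._ledger([2.0], thermo_config)
        lig = self._ledger([-1.0], thermo_config)
        free_volume_log = thermo_config.external_log_factor
        comp = self._ledger([2.0 - 1.0 + free_volume_log], thermo_config)
        res = mm.binding_free_energy(comp, rec, lig)
        assert res.delta_g == pytest.approx(0.0, abs=1e-9)

    def test_algebraic_identity_for_degenerate_ledgers(self, thermo_config):
        a = self._ledger([1.0, 0.3], thermo_config)
        res = mm.binding_free_energy(a, a, a)
        assert res.delta_g == pytest.approx(-a.free_energy, abs=1e-12)
        assert res.delta_g == pytest.approx(
            res.delta_mean_energy + res.minus_t_delta_s, abs=1e-9)

    def test_mismatched_temperatures_rejected(self, thermo_config):
        other = mm.ThermoConfig(temperature=310.0)
        a = self._ledger([1.0], thermo_config)
        b = self._ledger([1.0], other)
        with pytest.raises(mm.ThermoError):
            mm.binding_free_energy(a, a, b)


class TestEntropySplit:
    def test_482_wells_cost_3_7_kcal_per_mol(self):
        assert round(mm.conformational_entropy_bound(482), 1) == 3.7

    def test_split_on_a_synthetic_ledger(self, thermo_config):
        recs = [mm.ConformerRecord(energy=0.0, log_z=0.0, mean_energy=0.5)
                for _ in range(4)]
        led = mm.accumulate_free_energy(recs, thermo_config)
        conf, vib = led_split = mm.entropy_split(led, n_bound_conformations=1)
        assert conf == pytest.approx(thermo_config.rt * np.log(4), abs=1e-12)
        assert conf + vib == pytest.approx(led.minus_t_s_config, abs=1e-12)

    def test_single_well_and_full_credit_give_zero(self, thermo_config):
        one = mm.accumulate_free_energy(
            [mm.ConformerRecord(energy=0.0, log_z=0.0, mean_energy=0.0)], thermo_config)
        assert mm.entropy_split(one, 1)[0] == 0.0
        three = mm.accumulate_free_energy(
            [mm.ConformerRecord(energy=0.0, log_z=0.0, mean_energy=0.0)] * 3,
            thermo_config)
        assert mm.entropy_split(three, 3)[0] == 0.0

    def test_invalid_counts_rejected(self, thermo_config):
        led = mm.accumulate_free_energy(
            [mm.ConformerRecord(energy=0.0, log_z=0.0, mean_energy=0.0)], thermo_config)
        with pytest.raises(mm.ThermoError):
            mm.entropy_split(led, 2)   # more bound poses than wells
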