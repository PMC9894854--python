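"""Synthetic-cycle generator: determinism, invariants, truth recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from salpflux import dilution as dil
from salpflux import grazing, thorium, trapflux
from salpflux.demography import BIN_EDGES
from salpflux.synthetic import (
    CycleScenario,
    GroundTruth,
    NoiseConfig,
    default_abundance_by_bin,
    generate_cycle,
    generate_gut_pigments,
    generate_salp_tows,
    generate_th_profiles,
    generate_trap_samples,
)


def cycles_equal(c1, c2) -> bool:
    if len(c1.tows) != len(c2.tows):
        return False
    for t1, t2 in zip(c1.tows, c2.tows):
        if t1.volume_filtered != t2.volume_filtered:
            return False
        if not t1.individuals.equals(t2.individuals):
            return False
    if not c1.gut_pigments.equals(c2.gut_pigments):
        return False
    for s1, s2 in zip(c1.traps, c2.traps):
        if s1.poc_mass != s2.poc_mass or not s1.pellets.equals(s2.pellets):
            return False
    for p1, p2 in zip(c1.th_profiles, c2.th_profiles):
        if not p1.samples.equals(p2.samples):
            return False
    for e1, e2 in zip(c1.dilution, c2.dilution):
        if e1.chl != e2.chl:
            return False
    return True


class TestDeterminism:
    def test_same_seed_reproduces_bundle(self):
        sc = CycleScenario()
        assert cycles_equal(generate_cycle(sc, 1), generate_cycle(sc, 1))

    def test_different_seed_changes_noise_not_truth(self):
        sc = CycleScenario()
        c1, c2 = generate_cycle(sc, 1), generate_cycle(sc, 2)
        assert not c1.gut_pigments.equals(c2.gut_pigments)
        assert c1.truth == c2.truth

    def test_written_tables_are_byte_identical(self, tmp_path):
        sc = CycleScenario()
        p1 = generate_cycle(sc, 3).write(tmp_path / "a")
        p2 = generate_cycle(sc, 3).write(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key


class TestScenarioValidation:
    def test_nonincreasing_trap_depths_rejected(self):
        with pytest.raises(ValueError, match="trap_depths"):
            CycleScenario(trap_depths=(70.0, 70.0, 300.0))

    def test_euphotic_depth_below_shallowest_trap_rejected(self):
        with pytest.raises(ValueError, match="euphotic_depth"):
            CycleScenario(euphotic_depth=120.0, trap_depths=(100.0, 300.0))

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration_days"):
            CycleScenario(duration_days=0.0)

    def test_negative_abundance_rejected(self):
        bad = default_abundance_by_bin()
        bad["oozooid"] = -bad["oozooid"]
        with pytest.raises(ValueError, match="abundance_by_bin"):
            GroundTruth(abundance_by_bin=bad)


class TestTows:
    def test_zero_abundance_gives_empty_tows_but_populated_traps(self):
        zero = {s: np.zeros(len(BIN_EDGES) - 1) for s in ("oozooid", "blastozooid")}
        sc = CycleScenario(true_params=GroundTruth(abundance_by_bin=zero))
        cycle = generate_cycle(sc, 1)
        assert all(len(t.individuals) == 0 for t in cycle.tows)
        assert all(s.poc_mass > 0 for s in cycle.traps)

    def test_day_and_night_tows_present_with_plausible_volumes(self):
        tows = generate_salp_tows(CycleScenario(), 1)
        assert any(t.is_night for t in tows) and any(not t.is_night for t in tows)
        assert all(150.0 <= t.volume_filtered <= 500.0 for t in tows)

    def test_poisson_mean_matches_areal_expectation(self):
        """Mean count over many tows approaches abundance·V/z."""
        truth = GroundTruth(
            abundance_by_bin={
                "oozooid": np.zeros(len(BIN_EDGES) - 1),
                "blastozooid": np.r_[np.zeros(5), 20.0, np.zeros(len(BIN_EDGES) - 7)],
            }
        )
        sc = CycleScenario(duration_days=75.0, true_params=truth,
                           trap_depths=(70.0, 100.0), tow_depth=200.0)
        counts, expected = [], []
        for tow in generate_salp_tows(sc, 5):
            counts.append(len(tow.individuals))
            expected.append(20.0 * tow.volume_filtered / 200.0)
        assert np.mean(counts) == pytest.approx(np.mean(expected), rel=0.05)

    def test_night_day_factor_shifts_counts(self):
        sc = CycleScenario(duration_days=40.0, night_day_factor=3.0)
        tows = generate_salp_tows(sc, 2)
        day = np.mean([len(t.individuals) / t.volume_filtered
                       for t in tows if not t.is_night])
        night = np.mean([len(t.individuals) / t.volume_filtered
                         for t in tows if t.is_night])
        assert night / day == pytest.approx(3.0, rel=0.2)


class TestGutPigments:
    def test_noiseless_points_sit_on_power_law(self, noiseless_cycle):
        gp = noiseless_cycle.gut_pigments
        truth = noiseless_cycle.truth
        np.testing.assert_allclose(
            gp["gpig"],
            truth.pigment_power_a * gp["length_oal"] ** truth.pigment_power_b,
        )

    def test_subsample_cap_per_stage_per_tow(self, noisy_cycle):
        sizes = noisy_cycle.gut_pigments.groupby(["tow_id", "stage"]).size()
        assert (sizes <= 10).all()

    def test_empty_population_gives_empty_records(self):
        zero = {s: np.zeros(len(BIN_EDGES) - 1) for s in ("oozooid", "blastozooid")}
        sc = CycleScenario(true_params=GroundTruth(abundance_by_bin=zero))
        assert len(generate_gut_pigments(sc, 1)) == 0


class TestThoriumProfiles:
    def test_zero_export_means_equilibrium_with_u238(self):
        sc = CycleScenario(true_params=GroundTruth(th_export_true=0.0),
                           noise=NoiseConfig.off())
        p1, _ = generate_th_profiles(sc, 1)
        a_u = thorium.u238_from_salinity(sc.salinity)
        np.testing.assert_allclose(p1.samples["a_th"], a_u)

    def test_identical_noiseless_profiles_make_nss_equal_ss(self, noiseless_cycle):
        p1, p2 = noiseless_cycle.th_profiles
        z_eu = noiseless_cycle.scenario.euphotic_depth
        assert thorium.nss_export(p1, p2, z_eu).flux == pytest.approx(
            thorium.ss_export(p1, z_eu).flux, rel=1e-9
        )

    def test_constructed_deficiency_recovers_truth(self, noiseless_cycle):
        p1, _ = noiseless_cycle.th_profiles
        sc = noiseless_cycle.scenario
        est = thorium.ss_export(p1, sc.euphotic_depth).flux
        assert est == pytest.approx(sc.true_params.th_export_true, rel=0.05)

    def test_salinity_in_oceanic_range(self, noisy_cycle):
        for p in noisy_cycle.th_profiles:
            sal = p.samples["salinity"]
            assert ((sal >= 34.0) & (sal <= 35.5)).all()


class TestTrapsAndDilution:
    def test_noiseless_flux_at_euphotic_depth_is_f0(self, noiseless_cycle):
        sc = noiseless_cycle.scenario
        top = [t for t in noiseless_cycle.traps if t.depth == sc.euphotic_depth][0]
        assert trapflux.poc_flux(top).value == pytest.approx(
            sc.true_params.f0_true, rel=1e-12
        )

    def test_noiseless_two_depth_slope_is_b_true(self, noiseless_cycle):
        sc = noiseless_cycle.scenario
        pts = [(t.depth, trapflux.poc_flux(t).value)
               for t in noiseless_cycle.traps[:2]]
        fit = trapflux.fit_attenuation(pts, sc.euphotic_depth)
        assert fit.b == pytest.approx(sc.true_params.b_true, abs=1e-12)

    def test_zero_grazing_equalises_bottle_rates(self):
        sc = CycleScenario(true_params=GroundTruth(g_true=0.0),
                           noise=NoiseConfig.off())
        for exp in generate_cycle(sc, 1).dilution:
            rates = dil.dilution_rates(exp)
            assert rates.g == pytest.approx(0.0, abs=1e-12)

    def test_all_generated_quantities_nonnegative(self, noisy_cycle):
        for t in noisy_cycle.traps:
            assert t.poc_mass >= 0
            assert (t.pellets[["length", "width"]].to_numpy() > 0).all()
        for p in noisy_cycle.th_profiles:
            assert (p.samples["a_th"] >= 0).all()
        for tow in noisy_cycle.tows:
            assert tow.volume_filtered > 0
        for e in noisy_cycle.dilution:
            for i, f in e.chl.values():
                assert i > 0 and f > 0


class TestRecovery:
    def test_noiseless_recovery_exact(self, noiseless_cycle):
        """With noise off every estimator returns its ground-truth value
        (the ²³⁴Th balance to discretization error)."""
        sc = noiseless_cycle.scenario
        truth = sc.true_params
        fit = grazing.fit_gut_pigment_power(noiseless_cycle.gut_pigments)
        assert fit.a == pytest.approx(truth.pigment_power_a, rel=1e-9)
        assert fit.b == pytest.approx(truth.pigment_power_b, rel=1e-9)
        pts = [(t.depth, trapflux.poc_flux(t).value) for t in noiseless_cycle.traps]
        att = trapflux.fit_attenuation(pts, sc.euphotic_depth)
        assert att.f0 == pytest.approx(truth.f0_true, rel=1e-9)
        assert att.b == pytest.approx(truth.b_true, abs=1e-9)
        for exp in noiseless_cycle.dilution:
            rates = dil.dilution_rates(exp)
            assert rates.mu_insitu == pytest.approx(truth.mu_true, rel=1e-9)
            assert rates.g == pytest.approx(truth.g_true, rel=1e-9)
        est = thorium.ss_export(noiseless_cycle.th_profiles[0],
                                sc.euphotic_depth).flux
        assert est == pytest.approx(truth.th_export_true, rel=0.05)

    def test_default_noise_median_errors_below_15pct(self):
        """Median absolute relative error of (a, b, F0, b_atten, μ, g)
        over 200 seeds stays below 15% under default noise."""
        sc = CycleScenario()
        truth = sc.true_params
        errs = {k: [] for k in ("a", "b", "f0", "b_att", "mu", "g")}
        for seed in range(200):
            cycle = generate_cycle(sc, seed)
            fit = grazing.fit_gut_pigment_power(cycle.gut_pigments)
            errs["a"].append(abs(fit.a / truth.pigment_power_a - 1))
            errs["b"].append(abs(fit.b / truth.pigment_power_b - 1))
            pts = [(t.depth, trapflux.poc_flux(t).value) for t in cycle.traps]
            att = trapflux.fit_attenuation(pts, sc.euphotic_depth)
            errs["f0"].append(abs(att.f0 / truth.f0_true - 1))
            errs["b_att"].append(abs(att.b / truth.b_true - 1))
            mu = np.mean([dil.dilution_rates(e).mu_insitu for e in cycle.dilution])
            g = np.mean([dil.dilution_rates(e).g for e in cycle.dilution])
            errs["mu"].append(abs(mu / truth.mu_true - 1))
            errs["g"].append(abs(g / truth.g_true - 1))
        for name, vals in errs.items():
            assert np.median(vals) < 0.15, name

    def test_attenuation_exponent_recovered_within_point_one(self):
        """Median |b̂ − b_true| < 0.1 under per-tube lognormal trap noise."""
        sc = CycleScenario()
        devs = []
        for seed in range(200):
            cycle = generate_cycle(sc, seed)
            pts = [(t.depth, trapflux.poc_flux(t).value) for t in cycle.traps]
            att = trapflux.fit_attenuation(pts, sc.euphotic_depth)
            devs.append(abs(att.b - sc.true_params.b_true))
        assert np.median(devs) < 0.1

    def test_grazing_bias_small_under_chl_noise(self):
        """Mean bias of g under 5% lognormal chl noise is below 0.02 d⁻¹
        (500 independent bottle draws)."""
        sc = CycleScenario()
        errors = []
        for seed in range(84):  # 84 cycles × 6 depths > 500 experiments
            cycle = generate_cycle(sc, seed)
            for e in cycle.dilution:
                errors.append(dil.dilution_rates(e).g - sc.true_params.g_true)
        assert abs(np.mean(errors)) < 0.02
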