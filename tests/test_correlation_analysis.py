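import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bruisemap.correlation_analysis import (
    AnalysisConfig,
    PairedProfiles,
    apply_yield_mask,
    correlate,
    pearson_r,
    register_profiles,
    summarize_by_height,
)
from bruisemap.damage_metrics import DamageProfile
from bruisemap.energy_reconstruction import EnergyProfile
from bruisemap.errors import (
    DegenerateSeriesError,
    ParameterError,
    RegistrationError,
    ValidationError,
)
from bruisemap.synthetic_data import (
    CoupledSampleTruth,
    SimulatorParams,
    make_coupled_sample,
)


class TestPearsonR:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            assert pearson_r(x, y) == pytest.approx(
                stats.pearsonr(x, y).statistic, abs=1e-12
            )

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(pearson_r(np.ones(5), np.arange(5.0)))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            pearson_r(np.arange(4.0), np.arange(5.0))

    def test_too_short(self):
        with pytest.raises(ValidationError):
            pearson_r(np.arange(2.0), np.arange(2.0))

    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-50, max_value=50),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        base = pearson_r(x, y)
        assert pearson_r(a * x + b, y) == pytest.approx(base, abs=1e-9)
        assert pearson_r(x, a * y + b) == pytest.approx(base, abs=1e-9)
        assert pearson_r(-x, y) == pytest.approx(-base, abs=1e-9)


def _energy(values, center, pitch=1.9):
    values = np.asarray(values, float)
    return EnergyProfile(
        positions_mm=np.arange(values.size) * pitch, energy_j=values, center_index=center
    )


def _damage(lateral, depth, defined=None, width=None):
    lateral = np.asarray(lateral, float)
    depth = np.asarray(depth, float)
    width = np.full_like(depth, 0.8) if width is None else np.asarray(width, float)
    defined = np.ones(lateral.size, bool) if defined is None else np.asarray(defined, bool)
    return DamageProfile(lateral_mm=lateral, depth_mm=depth, width_mm=width, defined=defined)


class TestRegisterProfiles:
    def test_identical_supports_positional_identity(self):
        e = _energy([0.1, 0.5, 1.0, 0.5, 0.1], center=2)
        d = _damage(np.arange(5) * 1.9, [1.0, 2.0, 3.0, 2.0, 1.0])
        paired = register_profiles(d, e, damage_center_mm=2 * 1.9)
        assert paired.n_points == 5
        np.testing.assert_allclose(paired.depth_mm, d.depth_mm)
        np.testing.assert_allclose(paired.energy_j, e.energy_j)

    def test_peak_align_recovers_shift(self):
        e = _energy([0.0, 0.1, 0.5, 1.0, 0.5, 0.1, 0.0], center=3)
        # damage peak sits 2 pitch units away from the lateral origin used
        # by the energy frame; peak_align must line the peaks up
        lateral = np.arange(7) * 1.9 + 2 * 1.9
        depth = np.array([0.1, 0.5, 1.2, 3.0, 1.2, 0.5, 0.1])
        d = _damage(lateral, depth)
        cfg = AnalysisConfig(registration="peak_align")
        paired = register_profiles(d, e, cfg)
        k = int(np.argmax(paired.energy_j))
        assert paired.depth_mm[k] == pytest.approx(3.0)
        assert pearson_r(paired.depth_mm, paired.energy_j) > 0.97

    def test_metadata_needs_center(self):
        e = _energy([0.1, 0.5, 1.0], center=1)
        d = _damage(np.arange(3) * 1.9, [1, 2, 3])
        with pytest.raises(ParameterError):
            register_profiles(d, e)

    def test_overlap_too_small(self):
        # centres aligned at opposite ends: only 2 pitch steps in common
        e = _energy([0.1, 0.5, 1.0, 0.5], center=0)
        d = _damage(np.arange(4) * 1.9, [1, 2, 3, 4])
        with pytest.raises(RegistrationError):
            register_profiles(d, e, damage_center_mm=3 * 1.9)

    def test_undefined_positions_as_zero_or_dropped(self):
        e = _energy([0.1, 0.5, 1.0, 0.5, 0.1], center=2)
        defined = [False, True, True, True, False]
        d = _damage(np.arange(5) * 1.9, [0.0, 2.0, 3.0, 2.0, 0.0], defined=defined)
        with_zeros = register_profiles(d, e, damage_center_mm=2 * 1.9)
        assert with_zeros.n_points == 5
        dropped = register_profiles(
            d, e, damage_center_mm=2 * 1.9, include_undefined_as_zero=False
        )
        assert dropped.n_points == 3

    def test_registered_offset_matches_generator(self, sim_h125):
        offset = 2 * 1.9
        sample = make_coupled_sample(
            SimulatorParams(drop_height_m=0.125),
            CoupledSampleTruth(seed=5, lateral_offset_mm=offset),
            sim=sim_h125,
        )
        paired = register_profiles(
            sample.damage_truth,
            sample.energy_profile_truth,
            damage_center_mm=sample.damage_center_mm,
            include_undefined_as_zero=False,
        )
        # the pairing must undo the lateral offset: peak energy pairs with peak depth
        assert int(np.argmax(paired.energy_j)) == int(np.argmax(paired.depth_mm))


def _paired(depth, width, energy):
    depth = np.asarray(depth, float)
    return PairedProfiles(
        depth_mm=depth,
        width_mm=np.asarray(width, float),
        energy_j=np.asarray(energy, float),
        offsets_mm=np.arange(depth.size) * 1.9,
    )


class TestYieldMask:
    def test_noop_when_disabled(self):
        paired = _paired([1, 2, 3], [1, 1, 1], [0.1, 0.2, 0.3])
        out, n = apply_yield_mask(paired, np.array([1.0, 2.0, 3.0]), AnalysisConfig())
        assert n == 0
        assert out is paired

    def test_all_above_yield_is_identity(self):
        paired = _paired([1, 2, 3], [1, 1, 1], [0.1, 0.2, 0.3])
        cfg = AnalysisConfig(mask_sub_yield=True)
        out, n = apply_yield_mask(paired, np.array([9.0, 10.0, 11.0]), cfg)
        assert n == 0
        np.testing.assert_allclose(out.depth_mm, paired.depth_mm)

    def test_counts(self):
        paired = _paired([1, 2, 3, 4, 5], np.ones(5), [0.1, 0.2, 0.3, 0.4, 0.5])
        cfg = AnalysisConfig(mask_sub_yield=True)  # yield force 8.75 N
        out, n = apply_yield_mask(paired, np.array([5.0, 9.0, 10.0, 3.0, 12.0]), cfg)
        assert out.n_points == 3
        assert n == 2
        np.testing.assert_allclose(out.depth_mm, [2, 3, 5])

    def test_all_masked_raises(self):
        paired = _paired([1, 2, 3], np.ones(3), [0.1, 0.2, 0.3])
        cfg = AnalysisConfig(mask_sub_yield=True)
        with pytest.raises(DegenerateSeriesError):
            apply_yield_mask(paired, np.array([1.0, 2.0, 3.0]), cfg)

    def test_misaligned_profile(self):
        paired = _paired([1, 2, 3], np.ones(3), [0.1, 0.2, 0.3])
        with pytest.raises(ValidationError):
            apply_yield_mask(paired, np.ones(4), AnalysisConfig())

    def test_masking_improves_r_on_average(self, sims_by_height):
        # Monte-Carlo: sub-yield sites carry depth zero and drag r down;
        # excluding them raises the mean correlation
        h = 0.05
        sim = sims_by_height[h]
        cfg0 = AnalysisConfig()
        no_mask, masked = [], []
        for seed in range(50):
            s = make_coupled_sample(
                SimulatorParams(drop_height_m=h),
                CoupledSampleTruth(seed=seed, sigma0_mm=0.05),
                sim=sim,
            )
            paired = register_profiles(
                s.damage_truth,
                s.energy_profile_truth,
                cfg0,
                damage_center_mm=s.damage_center_mm,
                include_undefined_as_zero=True,
            )
            no_mask.append(correlate(paired, h, cfg0).r_depth)
            cfg_m = AnalysisConfig(mask_sub_yield=True, yield_force_n=s.yield_force_n)
            steps = np.round(
                (paired.offsets_mm + s.energy_profile_truth.center_position_mm) / 1.9
            ).astype(int)
            out, _ = apply_yield_mask(
                paired, s.peak_force_profile[np.clip(steps, 0, 39)], cfg_m
            )
            masked.append(correlate(out, h, cfg_m).r_depth)
        assert np.mean(masked) >= np.mean(no_mask)


class TestCorrelateAndSummaries:
    def test_noise_free_sample_r_one(self, sim_h125):
        sample = make_coupled_sample(
            SimulatorParams(drop_height_m=0.125),
            CoupledSampleTruth(seed=9, sigma0_mm=0.0),
            sim=sim_h125,
        )
        paired = register_profiles(
            sample.damage_truth,
            sample.energy_profile_truth,
            damage_center_mm=sample.damage_center_mm,
            include_undefined_as_zero=False,
        )
        res = correlate(paired, 0.125)
        assert res.r_depth == pytest.approx(1.0, abs=1e-9)

    def test_spearman_option(self):
        paired = _paired([1, 2, 3, 4], np.ones(4), [1, 4, 9, 16])
        res = correlate(paired, 0.1, AnalysisConfig(method="spearman"))
        assert res.r_depth == pytest.approx(1.0)

    def test_width_independent_of_energy(self, sim_h125):
        rs = []
        for seed in range(50):
            s = make_coupled_sample(
                SimulatorParams(drop_height_m=0.125),
                CoupledSampleTruth(seed=seed),
                sim=sim_h125,
            )
            paired = register_profiles(
                s.damage_truth,
                s.energy_profile_truth,
                damage_center_mm=s.damage_center_mm,
                include_undefined_as_zero=False,
            )
            rs.append(correlate(paired, 0.125).r_width)
        assert abs(np.mean(rs)) < 0.25  # loose at 50 seeds; acceptance runs 200

    def test_summary_single_sample(self):
        res = correlate(_paired([1, 2, 3], np.ones(3), [1, 2, 3]), 0.1)
        s = summarize_by_height([res])
        assert s[0].r_depth_min == s[0].r_depth_max == s[0].r_depth_mean

    def test_summary_min_max_mean(self):
        results = [
            correlate(_paired([1, 2, 3], np.ones(3), e), 0.05)
            for e in ([1, 2, 2.2], [1, 2, 4], [1, 1.1, 3])
        ]
        # overwrite r values directly for the arithmetic check
        import dataclasses

        results = [
            dataclasses.replace(r, r_depth=v) for r, v in zip(results, [0.4, 0.6, 0.8])
        ]
        s = summarize_by_height(results)[0]
        assert s.r_depth_min == pytest.approx(0.4)
        assert s.r_depth_max == pytest.approx(0.8)
        assert s.r_depth_mean == pytest.approx(0.6)
        assert s.r_depth_min <= s.r_depth_mean <= s.r_depth_max

    def test_empty_results_rejected(self):
        with pytest.raises(ValidationError):
            summarize_by_height([])
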