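"""Study-design bookkeeping and statistical behavior of the generator."""

import numpy as np
import pytest
from scipy import stats

from teafuse.containers import SENSOR_KEYS
from teafuse.enose import steady_state_average
from teafuse.hsi import extract_roi_spectrum
from teafuse.simulate import (
    CubeSimConfig,
    EnoseSimConfig,
    TitrationMeasurement,
    VarietySpec,
    default_variety_table,
    draw_tp,
    simulate_cube,
    simulate_dataset,
    simulate_enose,
    titration_to_tp,
)

NOISELESS_ENOSE = EnoseSimConfig(
    trace_noise_sd=0.0, amplitude_noise_rel=0.0, variety_offset_rel=0.0
)


class TestVarietyTable:
    def test_total_sample_count(self):
        assert sum(v.n for v in default_variety_table()) == 110

    def test_pooled_weighted_mean(self):
        vs = default_variety_table()
        pooled = sum(v.n * v.tp_mean for v in vs) / sum(v.n for v in vs)
        assert pooled == pytest.approx(18.78, abs=0.005)

    def test_pooled_range_endpoints(self):
        vs = default_variety_table()
        assert min(v.tp_range[0] for v in vs) == 10.65
        assert max(v.tp_range[1] for v in vs) == 29.65

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            VarietySpec("x", "black", 10, 25.0, 1.0, (10.0, 20.0))
        with pytest.raises(ValueError):
            VarietySpec("x", "oolong", 10, 15.0, 1.0, (10.0, 20.0))


class TestDrawTp:
    def test_vanishing_sd_returns_mean(self, rng):
        spec = VarietySpec("x", "green", 5, 26.0, 1e-9, (25.0, 29.0))
        assert draw_tp(spec, rng) == pytest.approx(26.0, abs=1e-6)

    def test_matches_truncated_normal_mean(self, rng):
        # Monte-Carlo mean against the closed-form truncated-normal mean
        spec = next(
            v for v in default_variety_table() if v.name.startswith("Huangshan")
        )
        a = (spec.tp_range[0] - spec.tp_mean) / spec.tp_sd
        b = (spec.tp_range[1] - spec.tp_mean) / spec.tp_sd
        dist = stats.truncnorm(a, b, loc=spec.tp_mean, scale=spec.tp_sd)
        draws = np.array([draw_tp(spec, rng) for _ in range(10_000)])
        se = dist.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - dist.mean()) < 3 * se

    def test_draws_stay_in_range(self, rng):
        spec = next(
            v for v in default_variety_table() if v.name.startswith("Huangshan")
        )
        draws = np.array([draw_tp(spec, rng) for _ in range(2_000)])
        assert draws.min() >= 25.32 and draws.max() <= 29.41


class TestSimulateEnose:
    def test_plateau_ordering_w1w_largest(self, rng):
        rec = simulate_enose(20.0, "v", rng, config=NOISELESS_ENOSE)
        plateaus = rec.traces[-1] - 1.0
        j_w1w = SENSOR_KEYS.index("f6")  # W1W
        assert plateaus[j_w1w] == max(plateaus)
        assert plateaus[j_w1w] > plateaus[SENSOR_KEYS.index("f7")]  # > W2S

    def test_deviation_signs(self, rng):
        rec = simulate_enose(20.0, "v", rng, config=NOISELESS_ENOSE)
        dev = rec.traces[-1] - 1.0
        pos = [1, 5, 6, 7, 8]  # W5S, W1S, W1W, W2S, W2W
        neg = [0, 2, 4]  # W1C, W3C, W5C
        assert all(dev[j] > 0 for j in pos)
        assert all(dev[j] < 0 for j in neg)
        assert all(abs(dev[j]) < 0.1 for j in (3, 9))  # W6S, W3S near zero

    def test_rsav_within_2pct_of_plateau(self, rng):
        cfg = NOISELESS_ENOSE
        tp = 18.0
        rec = simulate_enose(tp, "v", rng, config=cfg)
        for j in range(10):
            a = cfg.base[j] + cfg.slope[j] * tp
            rsav = steady_state_average(rec.traces[:, j], t0=55)
            assert rsav == pytest.approx(1.0 + a, abs=0.02 * abs(a) + 1e-12)

    def test_deterministic_under_seed(self):
        r1 = simulate_enose(15.0, "v", np.random.default_rng(7))
        r2 = simulate_enose(15.0, "v", np.random.default_rng(7))
        np.testing.assert_array_equal(r1.traces, r2.traces)

    def test_rsav_monotone_in_tp_noise_free(self, rng):
        tps = np.linspace(12.0, 28.0, 8)
        rsav = [
            steady_state_average(
                simulate_enose(tp, "v", rng, config=NOISELESS_ENOSE).traces[:, 6]
            )
            for tp in tps
        ]
        assert np.all(np.diff(rsav) > 0)


class TestSimulateCube:
    QUIET = CubeSimConfig(depth_noise_rel=0.0, texture_noise_rel=0.0)

    def test_absorption_depth_increases_with_tp(self, rng):
        low = simulate_cube(11.0, "v", rng, self.QUIET, texture=False, noise=False)
        high = simulate_cube(29.0, "v", rng, self.QUIET, texture=False, noise=False)
        i1106 = low.band_index(1106.0)
        s_low = extract_roi_spectrum(low).reflectance[i1106]
        s_high = extract_roi_spectrum(high).reflectance[i1106]
        assert s_high < s_low

    def test_texture_and_noise_off_gives_flat_images(self, rng):
        cube = simulate_cube(20.0, "v", rng, texture=False, noise=False)
        roi = cube.data[7:57, 7:57, :]
        assert np.all(roi == roi[:1, :1, :])

    def test_fixed_seed_bit_identical(self):
        c1 = simulate_cube(20.0, "v", np.random.default_rng(3))
        c2 = simulate_cube(20.0, "v", np.random.default_rng(3))
        np.testing.assert_array_equal(c1.data, c2.data)

    def test_noise_inflated_outside_clean_range(self, rng):
        cfg = CubeSimConfig(depth_noise_rel=0.0, texture_noise_rel=0.0)
        cube = simulate_cube(20.0, "v", rng, cfg, texture=False)
        flat = simulate_cube(20.0, "v", rng, cfg, texture=False, noise=False)
        resid = cube.data.astype(float) - flat.data.astype(float)
        inside = (cube.wavelengths >= 944) & (cube.wavelengths <= 1688)
        sd_in = resid[:, :, inside].std()
        sd_out = resid[:, :, ~inside].std()
        assert sd_out > 3 * sd_in


class TestTitration:
    def test_blank_equals_sample_gives_zero(self):
        m = TitrationMeasurement(A=5.0, B=5.0, omega=2.0, m=1.0, V1=10.0, V2=10.0)
        assert titration_to_tp(m) == 0.0

    def test_linearity(self):
        base = TitrationMeasurement(A=12.0, B=2.0, omega=2.0, m=1.0, V1=10.0, V2=10.0)
        doubled_delta = TitrationMeasurement(A=22.0, B=2.0, omega=2.0, m=1.0, V1=10.0, V2=10.0)
        doubled_mass = TitrationMeasurement(A=12.0, B=2.0, omega=2.0, m=2.0, V1=10.0, V2=10.0)
        x = titration_to_tp(base)
        assert titration_to_tp(doubled_delta) == pytest.approx(2 * x)
        assert titration_to_tp(doubled_mass) == pytest.approx(x / 2)

    def test_hand_evaluated_case(self):
        m = TitrationMeasurement(A=12.0, B=2.0, omega=2.0, m=1.0, V1=10.0, V2=10.0)
        assert titration_to_tp(m) == pytest.approx(0.36604, abs=5e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            titration_to_tp(
                TitrationMeasurement(A=5.0, B=1.0, omega=2.0, m=0.0, V1=10.0, V2=10.0)
            )


class TestDataset:
    def test_same_seed_byte_identical(self):
        d1 = simulate_dataset(5)
        d2 = simulate_dataset(5)
        assert [s.tp_true for s in d1] == [s.tp_true for s in d2]
        for a, b in zip(d1[:3], d2[:3]):
            np.testing.assert_array_equal(a.enose.traces, b.enose.traces)
            np.testing.assert_array_equal(a.cube().data, b.cube().data)

    def test_per_variety_means_near_table(self, dataset110):
        specs = {v.name: v for v in default_variety_table()}
        by_var: dict[str, list[float]] = {}
        for s in dataset110:
            by_var.setdefault(s.variety, []).append(s.tp_true)
        for name, vals in by_var.items():
            spec = specs[name]
            se = spec.tp_sd / np.sqrt(len(vals))
            assert abs(np.mean(vals) - spec.tp_mean) < 4 * se, name

    def test_tp_within_variety_range(self, dataset110):
        specs = {v.name: v for v in default_variety_table()}
        for s in dataset110:
            low, high = specs[s.variety].tp_range
            assert low <= s.tp_true <= high
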