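"""Synthetic-screen generator: analytic curves, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rdeep.errors import ConfigError, InvalidParameterError
from rdeep.simulate import (
    FRACTIONS,
    GaussianPeak,
    NoiseModel,
    ShiftScenario,
    gaussian_curve,
    parse_peaks,
    simulate_screen,
)


class TestGaussianCurve:
    def test_peak_maximum_equals_amplitude(self):
        c = gaussian_curve([GaussianPeak(10.0, 12.0, 1.5)])
        assert c[11] == pytest.approx(10.0)  # fraction 12 is index 11
        assert c.argmax() == 11

    def test_empty_peak_list_is_zero(self):
        assert np.all(gaussian_curve([]) == 0)

    def test_two_equal_peaks_are_symmetric(self):
        c = gaussian_curve([GaussianPeak(5, 5, 1), GaussianPeak(5, 20, 1)])
        assert c[4] == pytest.approx(c[19])

    def test_nonpositive_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            gaussian_curve([(1.0, 5.0, 0.0)])

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0.1, 50),
        mu=st.floats(1, 25),
        sigma=st.floats(0.3, 6),
    )
    def test_curve_nonnegative_and_bounded_by_amplitude_sum(self, a, mu, sigma):
        c = gaussian_curve([GaussianPeak(a, mu, sigma)])
        assert np.all(c >= 0)
        assert c.max() <= a + 1e-9


class TestShiftScenario:
    def test_amplitude_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            ShiftScenario("none", [(0.5, 10, 1)], [(0.5, 10, 1)])

    def test_none_requires_identical_conditions(self):
        with pytest.raises(ConfigError):
            ShiftScenario("none", [(1.0, 10, 1)], [(1.0, 12, 1)])

    def test_precipitation_requires_peak_past_boundary(self):
        with pytest.raises(ConfigError):
            ShiftScenario("precipitation", [(1.0, 10, 1)], [(1.0, 20, 1)], 1.0)
        ShiftScenario("precipitation", [(1.0, 10, 1)], [(1.0, 24, 1)], 1.0)

    def test_peaks_for_carries_requested_total(self):
        scen = ShiftScenario("none", [(1.0, 12, 1.5)], [(1.0, 12, 1.5)])
        curve = gaussian_curve(scen.peaks_for("CTRL", 100.0))
        assert curve.sum() == pytest.approx(100.0)


class TestSimulateScreen:
    def test_grid_shape_and_columns(self):
        table, truth = simulate_screen(10, seed=1)
        assert len(table) == 10 * 2 * 3 * 25
        assert list(table.columns) == ["protein_id", "condition", "replicate", "fraction", "intensity"]
        assert len(truth) == 10
        assert (table["intensity"] >= 0).all()

    def test_seeded_reproducibility_is_bitwise(self):
        t1, g1 = simulate_screen(10, seed=1)
        t2, g2 = simulate_screen(10, seed=1)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_different_seeds_differ(self):
        t1, _ = simulate_screen(5, seed=1)
        t2, _ = simulate_screen(5, seed=2)
        assert not t1["intensity"].equals(t2["intensity"])

    def test_pure_none_mixture(self):
        _, truth = simulate_screen(20, scenario_mixture={"none": 1.0}, seed=3)
        assert (truth["kind"] == "none").all()
        assert (truth["shift_distance"] == 0).all()

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            simulate_screen(5, scenario_mixture={"none": 0.5}, seed=1)

    def test_seed_required(self):
        with pytest.raises(ConfigError):
            simulate_screen(5)

    def test_noiseless_run_reproduces_analytic_curve(self):
        table, truth = simulate_screen(
            5, scenario_mixture={"left_complete": 1.0}, noise=NoiseModel.noiseless(), seed=4
        )
        for _, row in truth.iterrows():
            peaks = parse_peaks(row["rnase_peaks"])
            sub = table[
                (table.protein_id == row.protein_id)
                & (table.condition == "RNASE")
                & (table.replicate == 1)
            ].sort_values("fraction")
            obs = sub["intensity"].to_numpy()
            scale = obs.sum()
            expected = np.zeros(25)
            for amp, pos, width in peaks:
                unit = GaussianPeak(1.0, pos, width)
                expected += gaussian_curve([GaussianPeak(amp * scale / unit.grid_area(), pos, width)])
            assert np.allclose(obs, expected, rtol=1e-9)
            # replicates identical without noise
            sub2 = table[
                (table.protein_id == row.protein_id)
                & (table.condition == "RNASE")
                & (table.replicate == 3)
            ].sort_values("fraction")
            assert np.array_equal(obs, sub2["intensity"].to_numpy())

    def test_replicate_mean_converges_to_clean_curve_as_noise_shrinks(self):
        devs = []
        for s in (0.3, 0.03):
            table, _ = simulate_screen(
                1,
                scenario_mixture={"none": 1.0},
                noise=NoiseModel(replicate_sigma_log=s, channel_bias_range=0.0),
                seed=5,
            )
            clean, _ = simulate_screen(
                1, scenario_mixture={"none": 1.0}, noise=NoiseModel.noiseless(), seed=5
            )
            m = table.groupby(["condition", "fraction"])["intensity"].mean()
            c = clean.groupby(["condition", "fraction"])["intensity"].mean()
            devs.append(float(np.abs(m / c - 1).max()))
        assert devs[1] < devs[0]

    def test_ground_truth_roundtrips_through_serialization(self):
        _, truth = simulate_screen(5, seed=6)
        for _, row in truth.iterrows():
            peaks = parse_peaks(row["control_peaks"])
            assert abs(sum(p[0] for p in peaks) - 1.0) < 1e-9


class TestNoiseModel:
    def test_negative_sigma_rejected(self):
        with pytest.raises(ConfigError):
            NoiseModel(replicate_sigma_log=-0.1)

    def test_nonpositive_bias_rejected(self):
        with pytest.raises(ConfigError):
            NoiseModel(channel_bias=np.zeros((25, 2, 3)))

    def test_multiplicative_noise_has_unit_mean(self):
        rng = np.random.default_rng(0)
        s = 0.15
        draws = np.exp(rng.normal(-0.5 * s * s, s, size=200_000))
        assert draws.mean() == pytest.approx(1.0, abs=5e-3)
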