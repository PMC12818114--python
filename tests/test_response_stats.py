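"""Characterization statistics: energy, reproducibility, sensitivity, batches."""

import numpy as np
import pytest

from protonfilm import (
    CalibrationModel,
    MeasurementGroup,
    NoiseSpec,
    batch_variation,
    energy_dependence,
    noise_to_signal,
    percent_difference,
    preset_truth,
    rational_response,
    reproducibility,
    resolvable,
    sensitivity_deviation,
    simulate_calibration_dataset,
)

def group(label, dose, *triplets):
    return MeasurementGroup(label=label, dose_gy=dose, netods=np.asarray(triplets))


@pytest.fixture(scope="module")
def b1_model():
    ds = simulate_calibration_dataset(preset_truth("B1"), noise=NoiseSpec.noiseless())
    return CalibrationModel.fit(ds)


class TestPercentDifference:
    def test_day_to_day_red_channel_at_10_gy(self):
        """The benchmark session pair 0.4426 vs 0.4403 differs by 0.52 %."""
        assert percent_difference(0.4426, 0.4403) == pytest.approx(0.52, abs=0.01)

    def test_identical_values(self):
        assert percent_difference(0.3, 0.3) == 0.0

    def test_symmetric_form(self):
        assert percent_difference(2.0, 1.0) == pytest.approx(66.67, abs=0.01)
        assert percent_difference(1.0, 2.0) == percent_difference(2.0, 1.0)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            percent_difference(0.0, 0.3)


class TestReproducibility:
    def test_identical_sessions(self):
        g = group("day1", 10.0, [0.44, 0.26, 0.11], [0.45, 0.27, 0.12])
        np.testing.assert_allclose(reproducibility(g, g), 0.0)

    def test_single_film_sessions_reduce_to_percent_difference(self):
        g1 = group("day1", 10.0, [0.4426, 0.26, 0.11])
        g2 = group("day2", 10.0, [0.4403, 0.26, 0.11])
        out = reproducibility(g1, g2)
        assert out[0] == pytest.approx(percent_difference(0.4426, 0.4403))
        assert out[1] == 0.0

    def test_dose_mismatch_rejected(self):
        g1 = group("day1", 5.0, [0.3, 0.2, 0.1])
        g2 = group("day2", 10.0, [0.3, 0.2, 0.1])
        with pytest.raises(ValueError, match="dose mismatch"):
            reproducibility(g1, g2)

    def test_two_simulated_sessions_agree_below_one_percent(self, b1_truth):
        """Five films per session at 0.3 % scanner noise keep the red-channel
        session means within 1 % in the large majority of seeds."""
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            means = []
            for session in range(2):
                noise = NoiseSpec(fractions=(0.003, 0.003, 0.003), seed=1000 * seed + session)
                ds = simulate_calibration_dataset(
                    b1_truth, dose_grid_gy=[10.0], replicates=5, noise=noise
                )
                means.append(ds.frame[ds.frame["channel"] == "red"]["netod"].mean())
            wins += percent_difference(*means) < 1.0
        assert wins >= 0.95 * n_seeds


class TestEnergyDependence:
    def test_equal_groups_give_zero(self):
        g = group("70", 5.0, [0.3, 0.2, 0.1])
        np.testing.assert_allclose(
            energy_dependence([g, group("150", 5.0, [0.3, 0.2, 0.1])]), 0.0
        )

    def test_reported_energy_means_oracle(self):
        """Red-channel means 0.30/0.32/0.33 across three energies: the max
        deviation from the grand mean 0.31667 is 0.01667 -> 5.263 %."""
        groups = [
            group(e, 5.0, [m, m, m])
            for e, m in (("70", 0.30), ("150", 0.32), ("225", 0.33))
        ]
        out = energy_dependence(groups)
        grand = np.mean([0.30, 0.32, 0.33])
        expected = 100 * max(abs(m - grand) for m in (0.30, 0.32, 0.33)) / grand
        assert expected == pytest.approx(5.263, abs=1e-3)
        np.testing.assert_allclose(out, expected)

    def test_two_group_closed_form(self):
        eps = 0.04
        x = 0.3
        out = energy_dependence(
            [group("a", 5.0, [x] * 3), group("b", 5.0, [x * (1 + eps)] * 3)]
        )
        np.testing.assert_allclose(out, 100 * eps / (2 + eps), rtol=1e-12)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="two"):
            energy_dependence([group("70", 5.0, [0.3, 0.2, 0.1])])

    def test_statistic_shrinks_with_group_size(self, b1_truth):
        """More films per group average the noise down: the statistic should
        roughly halve when the group size quadruples."""
        def stat(films, seed):
            rng = np.random.default_rng(seed)
            gs = []
            for e in ("70", "150", "225"):
                od = rational_response(5.0, 0.0740, 0.0842, 0.9684)
                vals = od * (1 + 0.01 * rng.standard_normal((films, 3)))
                gs.append(MeasurementGroup(label=e, dose_gy=5.0, netods=vals))
            return energy_dependence(gs)[0]

        small = np.mean([stat(2, s) for s in range(30)])
        large = np.mean([stat(32, s + 100) for s in range(30)])
        assert large < small / 2.5

    def test_scale_invariance(self):
        gs = [group("a", 5.0, [0.3, 0.2, 0.1]), group("b", 5.0, [0.31, 0.21, 0.11])]
        base = energy_dependence(gs)
        scaled = energy_dependence(
            [MeasurementGroup(g.label, g.dose_gy, g.netods * 7.3) for g in gs]
        )
        np.testing.assert_allclose(scaled, base, rtol=1e-12)


class TestSensitivity:
    def test_measured_equals_predicted(self, b1_model):
        pred = np.array([float(b1_model.channels[ch].predict(5.0))
                         for ch in ("red", "green", "blue")])
        np.testing.assert_allclose(sensitivity_deviation(pred, b1_model, 5.0), 0.0, atol=1e-9)

    def test_fixed_relative_offset(self, b1_model):
        pred = np.array([float(b1_model.channels[ch].predict(5.0))
                         for ch in ("red", "green", "blue")])
        out = sensitivity_deviation(pred * 1.015, b1_model, 5.0)
        np.testing.assert_allclose(out, 1.5, rtol=1e-9)

    def test_zero_dose_rejected(self, b1_model):
        with pytest.raises(ValueError, match="positive"):
            sensitivity_deviation(np.zeros(3), b1_model, 0.0)

    def test_plus_minus_5pct_dose_perturbations_within_3pct(self, b1_model, b1_truth):
        """Films irradiated at D*(1 +/- 0.05) with 1 % netOD noise read back
        within ~3 % of the nominal-dose prediction shifted by the true
        perturbation, i.e. measured-vs-predicted deviations stay moderate."""
        rng = np.random.default_rng(21)
        hits = 0
        trials = 50
        for _ in range(trials):
            delta = rng.choice([-0.05, 0.05])
            actual = 5.0 * (1 + delta)
            od = np.array([b1_truth.netod(actual, ch) for ch in ("red", "green", "blue")])
            od = od * (1 + 0.01 * rng.standard_normal(3))
            dev = sensitivity_deviation(od, b1_model, actual)
            hits += np.all(np.abs(dev) <= 3.0)
        assert hits >= 0.9 * trials


class TestResolvable:
    def test_equal_doses_not_resolvable(self, b1_model):
        assert not resolvable(5.0, 5.0, b1_model, 1e-4).any()

    def test_zero_sigma_always_resolvable(self, b1_model):
        assert resolvable(5.0, 5.05, b1_model, 0.0).all()

    def test_half_gray_five_percent_step_red_channel(self, b1_model):
        """0.5 vs 0.525 Gy: red-channel netOD separation ~1.7e-3 beats
        2*sqrt(2)*4e-4, so the doses are resolvable."""
        delta = rational_response(0.525, 0.0740, 0.0842, 0.9684) - rational_response(
            0.5, 0.0740, 0.0842, 0.9684
        )
        assert delta > 2 * np.sqrt(2) * 4e-4
        assert resolvable(0.5, 0.525, b1_model, 4e-4)[0]

    def test_monotone_in_dose_separation(self, b1_model):
        sigma = 4e-4
        flags = [resolvable(0.5, 0.5 + step, b1_model, sigma)[0]
                 for step in (0.005, 0.025, 0.1, 0.5)]
        # once resolvable, wider separations stay resolvable
        first_true = flags.index(True) if True in flags else len(flags)
        assert all(flags[first_true:])

    def test_negative_sigma_rejected(self, b1_model):
        with pytest.raises(ValueError, match="non-negative"):
            resolvable(0.5, 1.0, b1_model, -1e-4)


class TestBatchVariation:
    def test_equal_batches(self):
        g = group("B1", 10.0, [0.4, 0.25, 0.1])
        np.testing.assert_allclose(batch_variation(g, g), 0.0)

    def test_hand_computed_means(self):
        g1 = group("B1", 10.0, [0.40, 0.40, 0.40])
        g2 = group("B2", 10.0, [0.45, 0.45, 0.45])
        np.testing.assert_allclose(batch_variation(g1, g2), 100 * 0.05 / 0.425)
        assert batch_variation(g1, g2)[0] == pytest.approx(11.76, abs=0.01)

    def test_b1_vs_b2_model_difference_at_10_gy(self):
        """Noiseless pipeline: B1 vs B2 red forward models at 10 Gy differ by
        5.66 % (the measured batch spread of ~12 % includes lot chemistry the
        dose-response parameters alone do not capture)."""
        t1, t2 = preset_truth("B1"), preset_truth("B2")
        ds1 = simulate_calibration_dataset(t1, dose_grid_gy=[10.0], noise=NoiseSpec.noiseless())
        ds2 = simulate_calibration_dataset(t2, dose_grid_gy=[10.0], noise=NoiseSpec.noiseless())
        def grp(ds, label):
            f = ds.frame
            trip = [float(f[f["channel"] == ch]["netod"].iloc[0])
                    for ch in ("red", "green", "blue")]
            return group(label, 10.0, trip)
        out = batch_variation(grp(ds1, "B1"), grp(ds2, "B2"))
        assert out[0] == pytest.approx(5.66, abs=0.02)


class TestNoiseToSignal:
    def test_zero_noise_dataset(self, b1_truth):
        ds = simulate_calibration_dataset(b1_truth, noise=NoiseSpec.noiseless())
        np.testing.assert_allclose(noise_to_signal(ds), 0.0, atol=1e-8)

    def test_single_point_arithmetic(self):
        import pandas as pd

        df = pd.DataFrame([
            {"dose_gy": 5.0, "channel": ch, "netod": 0.4, "sigma": 0.01}
            for ch in ("red", "green", "blue")
        ])
        np.testing.assert_allclose(noise_to_signal(df), 2.5)

    def test_default_noise_orders_channels(self, b1_truth):
        """Scanner noise defaults must reproduce the red < green < blue
        noise-to-signal ordering."""
        ds = simulate_calibration_dataset(b1_truth, replicates=1, noise=NoiseSpec(seed=9))
        r, g, b = noise_to_signal(ds)
        assert r < g < b
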