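"""Synthetic ABR generator: determinism, fidelity, class structure."""

import dataclasses

import numpy as np
import pytest

from abrwave.core import WINDOW_START
from abrwave.labelgen import extract_window, window_index_of
from abrwave.simulator import (
    NoiseSpec,
    SimulatorConfig,
    WaveTemplate,
    add_interference_noise,
    default_templates,
    simulate_dataset,
    simulate_recording,
)


class TestSimulateRecording:
    def test_noiseless_annotations_are_local_maxima(self, clean_sweep, grid):
        rec, ann = clean_sweep
        window = extract_window(rec).values
        assert len(ann.waves) == 3
        for wave in ann.waves:
            idx = window_index_of(ann[wave], grid)
            lo, hi = max(idx - 20, 0), min(idx + 21, len(window))
            assert lo + int(np.argmax(window[lo:hi])) == idx

    def test_zero_amplitudes_give_flat_trace_empty_annotation(self, quiet_noise):
        templates = [
            dataclasses.replace(t, mean_amplitude=0.0, amplitude_sd=0.0)
            for t in default_templates()
        ]
        rec, ann = simulate_recording(
            templates, quiet_noise, "normal", np.random.default_rng(0)
        )
        assert (rec.potentials == 0).all()
        assert len(ann) == 0

    def test_mean_realized_wave_v_latency_matches_template(self):
        config = SimulatorConfig()
        target = next(t for t in config.templates if t.wave_id == "V")
        pairs = simulate_dataset(1000, 0.0, config, seed=11)
        lats = [ann["V"] for _, ann in pairs if "V" in ann]
        se = target.latency_sd / np.sqrt(len(lats))
        assert abs(np.mean(lats) - target.mean_latency) < 3 * se

    def test_annotations_snap_to_grid(self, grid):
        pairs = simulate_dataset(50, 0.5, seed=2)
        for _, ann in pairs:
            for wave in ann.waves:
                idx = grid.index_of(ann[wave])
                assert abs(float(grid.time(idx)) - ann[wave]) < grid.dt / 2

    def test_unordered_templates_rejected(self, quiet_noise):
        templates = [
            WaveTemplate("I", 3.0, 0.1, 0.3, 0.05, 0.25),
            WaveTemplate("III", 2.0, 0.1, 0.3, 0.05, 0.25),
        ]
        with pytest.raises(ValueError, match="increase"):
            simulate_recording(
                templates, quiet_noise, "normal", np.random.default_rng(0)
            )


class TestSimulateDataset:
    def test_same_seed_is_bit_identical(self):
        a = simulate_dataset(25, 0.5, seed=9)
        b = simulate_dataset(25, 0.5, seed=9)
        for (ra, aa), (rb, ab) in zip(a, b):
            np.testing.assert_array_equal(ra.potentials, rb.potentials)
            assert aa.latencies == ab.latencies

    def test_stratified_mix_is_exact(self):
        pairs = simulate_dataset(614, 433 / 614, seed=4, stratified=True)
        abnormal = sum(1 for rec, _ in pairs if rec.subject_class == "abnormal")
        assert abnormal == 433

    def test_unstratified_mix_within_binomial_noise(self):
        n, p = 614, 433 / 614
        pairs = simulate_dataset(n, p, seed=4)
        abnormal = sum(1 for rec, _ in pairs if rec.subject_class == "abnormal")
        assert abs(abnormal - n * p) < 4 * np.sqrt(n * p * (1 - p))

    def test_all_normal_default_config_annotates_all_waves(self):
        for _, ann in simulate_dataset(10, 0.0, seed=3):
            assert ann.waves == ("I", "III", "V")

    def test_abnormal_class_has_lower_wave_i_amplitude(self):
        """Monte-Carlo class separation on the noise-free wave-I peak."""
        config = SimulatorConfig(noise=NoiseSpec(0, 0, 1, 0, 0))
        heights = {"normal": [], "abnormal": []}
        for cls in heights:
            for _, seq in zip(range(150), np.random.SeedSequence(21).spawn(150)):
                rec, ann = simulate_recording(
                    list(config.templates),
                    config.noise,
                    cls,
                    np.random.default_rng(seq),
                    abnormal_effects=config.abnormal,
                )
                w = extract_window(rec).values
                heights[cls].append(w[: window_index_of(2.6)].max())
        assert np.mean(heights["abnormal"]) < np.mean(heights["normal"])


class TestAddInterferenceNoise:
    def test_all_zero_noise_is_identity(self, clean_sweep, quiet_noise):
        rec, _ = clean_sweep
        out = add_interference_noise(rec, quiet_noise)
        np.testing.assert_array_equal(out.potentials, rec.potentials)

    def test_original_untouched_and_reproducible(self, clean_sweep):
        rec, _ = clean_sweep
        before = rec.potentials.copy()
        spec = NoiseSpec(baseline_sd=0.05, rng_seed=77)
        a = add_interference_noise(rec, spec)
        b = add_interference_noise(rec, spec)
        np.testing.assert_array_equal(rec.potentials, before)
        np.testing.assert_array_equal(a.potentials, b.potentials)

    def test_broadband_component_sd_matches_spec(self, clean_sweep):
        rec, _ = clean_sweep
        sigma = 0.08
        diffs = []
        for seed in range(10):
            spec = NoiseSpec(
                baseline_sd=sigma, drift_amplitude=0.0, late_artifact_prob=0.0,
                rng_seed=seed,
            )
            diffs.append(add_interference_noise(rec, spec).potentials - rec.potentials)
        pooled = np.concatenate(diffs)  # 10,240 samples
        assert abs(pooled.std() - sigma) / sigma < 0.05

    def test_drift_only_is_pure_sinusoid(self, clean_sweep, grid):
        rec, _ = clean_sweep
        spec = NoiseSpec(
            baseline_sd=0.0, drift_amplitude=0.1, drift_period=15.0,
            late_artifact_prob=0.0, rng_seed=5,
        )
        delta = add_interference_noise(rec, spec).potentials - rec.potentials
        t = grid.times()
        # fit amplitude/phase at the configured period; residual must vanish
        design = np.column_stack(
            [np.sin(2 * np.pi * t / 15.0), np.cos(2 * np.pi * t / 15.0)]
        )
        coef, *_ = np.linalg.lstsq(design, delta, rcond=None)
        assert np.abs(delta - design @ coef).max() < 1e-10
        assert np.hypot(*coef) == pytest.approx(0.1, rel=1e-9)
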