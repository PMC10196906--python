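"""Synthetic generator: spectra, artifact injection, reviewers, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from dryeeg.labeling import Label, band_rms, fleiss_kappa
from dryeeg.preprocess import preprocess_pipeline
from dryeeg.synthdata import (
    ARTIFACT_TYPES,
    BackgroundParams,
    ReviewerParams,
    SynthConfig,
    expected_mask_fraction,
    generate_background,
    generate_dataset,
    generate_recording_background,
    inject_artifacts,
    simulate_reviewers,
)


class TestBackground:
    def test_spectral_slope_matches_config(self):
        """Welch log-log slope over 1-30 Hz within +/-0.3 of the configured
        1/f exponent (alpha band excluded from the fit)."""
        params = BackgroundParams()
        x = generate_background(120.0, 500.0, params, seed=5)
        f, pxx = sps.welch(x, fs=500.0, nperseg=4096)
        sel = (f >= 1) & (f <= 30) & ~((f > 7) & (f < 14))
        slope = np.polyfit(np.log(f[sel]), np.log(pxx[sel]), 1)[0]
        assert slope == pytest.approx(-params.beta, abs=0.3)

    def test_deterministic(self):
        a = generate_background(10.0, 500.0, seed=3)
        b = generate_background(10.0, 500.0, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_lf_boost_raises_low_band_power(self):
        on = BackgroundParams(lf_boost=1.6)
        off = dataclasses.replace(on, lf_boost=1.0)
        def lf_power(p):
            x = generate_background(60.0, 500.0, p, seed=9)
            f, pxx = sps.welch(x, fs=500.0, nperseg=2048)
            return pxx[(f >= 0.5) & (f <= 6.0)].sum()
        assert lf_power(on) > lf_power(off)

    def test_zero_mean_and_rms_scaling(self):
        x = generate_background(30.0, 500.0, BackgroundParams(rms_uv=15.0), seed=1)
        assert abs(x.mean()) < 1.0
        assert np.sqrt(np.mean(x**2)) == pytest.approx(15.0, rel=1e-6)


class TestInjectArtifacts:
    def test_zero_rates_is_noop(self):
        cfg = SynthConfig(artifact_rates={k: 0.0 for k in ARTIFACT_TYPES})
        rng = np.random.default_rng(0)
        bg = generate_recording_background(cfg, rng)
        out, truth = inject_artifacts(bg, cfg, rng)
        np.testing.assert_array_equal(out, bg)
        assert truth.events == []
        assert not any(m.any() for m in truth.masks.values())

    def test_blink_amplitude_above_background(self):
        rates = {k: 0.0 for k in ARTIFACT_TYPES}
        rates["blink"] = 6.0
        cfg = SynthConfig(duration_s=60.0, artifact_rates=rates)
        rng = np.random.default_rng(4)
        bg = generate_recording_background(cfg, rng)
        out, truth = inject_artifacts(bg, cfg, rng)
        blink_events = [e for e in truth.events if e.type == "blink"]
        assert blink_events
        ev = blink_events[0]
        e = ev.electrodes[0]
        i = list(truth.masks).index(e)
        i0, i1 = int(ev.start_s * 500), int(ev.end_s * 500)
        peak = np.abs(out[i, i0:i1] - bg[i, i0:i1]).max()
        assert peak >= 0.6 * 100.0  # weakest electrode scaling of min amplitude

    def test_pop_survives_preprocessing_as_clipped_plateau(self):
        from dryeeg.preprocess import DEFAULT_ELECTRODES, RawRecording

        rates = {k: 0.0 for k in ARTIFACT_TYPES}
        cfg = SynthConfig(duration_s=20.0, artifact_rates=rates)
        rng = np.random.default_rng(0)
        bg = generate_recording_background(cfg, rng)
        bg[0, 5000:7500] += 1500.0  # pop-sized step on FC3
        rec = RawRecording(signal=bg, rate=500.0,
                           channel_names=list(DEFAULT_ELECTRODES))
        prep = preprocess_pipeline(rec)
        assert prep.signal.max() == pytest.approx(800.0)
        assert np.all(np.abs(prep.signal) <= 800.0)

    def test_mask_fraction_matches_rate_duration_product(self):
        """Single-type mask coverage converges to rate x mean duration on a
        10-minute recording (within 10%)."""
        rates = {k: 0.0 for k in ARTIFACT_TYPES}
        rates["pop"] = 40.0  # single-electrode events; high count, low overlap
        durations = dict(SynthConfig().duration_ranges)
        durations["pop"] = (1.0, 1.0)
        cfg = SynthConfig(duration_s=600.0, artifact_rates=rates,
                          duration_ranges=durations)
        rng = np.random.default_rng(11)
        n = int(600 * 500)
        _, truth = inject_artifacts(np.zeros((8, n)), cfg, rng)
        expected = rates["pop"] / 60.0 * 1.0  # rate x mean duration (all electrodes)
        observed = np.mean([m.mean() for m in truth.masks.values()]) * 8
        assert observed == pytest.approx(expected, rel=0.10)
        assert expected_mask_fraction(cfg) == pytest.approx(expected)

    def test_mask_is_union_of_event_supports(self):
        cfg = SynthConfig(duration_s=30.0)
        rng = np.random.default_rng(2)
        bg = generate_recording_background(cfg, rng)
        _, truth = inject_artifacts(bg, cfg, rng)
        rebuilt = {e: np.zeros(truth.n_samples, dtype=bool) for e in truth.masks}
        for ev in truth.events:
            i0, i1 = int(round(ev.start_s * 500)), int(round(ev.end_s * 500))
            for e in ev.electrodes:
                rebuilt[e][i0:i1] = True
        for e in truth.masks:
            np.testing.assert_array_equal(truth.masks[e], rebuilt[e])


class TestReviewers:
    def _truth(self, seed=0, duration=120.0, rates=None):
        cfg = SynthConfig(duration_s=duration,
                          artifact_rates=rates or dict(SynthConfig().artifact_rates))
        rng = np.random.default_rng(seed)
        bg = generate_recording_background(cfg, rng)
        _, truth = inject_artifacts(bg, cfg, rng)
        return truth

    def test_noiseless_reviewers_reproduce_truth(self):
        truth = self._truth()
        params = ReviewerParams(n_reviewers=3, jitter_s=0.0, flip_prob=0.0,
                                hf_prob=0.0)
        tracks = simulate_reviewers(truth, ("FC3", "CP3"), 12000, 100.0,
                                    params, seed=1)
        mask = truth.channel_mask("FC3", "CP3", target_rate=100.0, n_target=12000)
        for t in tracks:
            np.testing.assert_array_equal(t.labels == Label.ARTIFACT, mask)
        assert fleiss_kappa(tracks, categories=(Label.CLEAN, Label.ARTIFACT)) \
            == pytest.approx(1.0)

    def test_coin_flip_reviewers_have_zero_kappa(self):
        """Per-sample flip probability 0.5 makes labels independent of the
        truth and of each other: kappa within +/-0.05 of 0."""
        truth = self._truth(duration=300.0)
        params = ReviewerParams(n_reviewers=3, jitter_s=0.0, flip_prob=0.5,
                                hf_prob=0.0)
        tracks = simulate_reviewers(truth, ("FC3", "CP3"), 30000, 100.0,
                                    params, seed=2)
        kappa = fleiss_kappa(tracks, categories=(Label.CLEAN, Label.ARTIFACT))
        assert abs(kappa) <= 0.05

    def test_moderate_noise_in_substantial_agreement_band(self):
        """Jitter 0.3 s + 2% flips lands in the substantial-agreement band
        (0.55-0.9) observed for trained human reviewers."""
        params = ReviewerParams(n_reviewers=3, jitter_s=0.3, flip_prob=0.02,
                                hf_prob=0.0)
        kappas = []
        for seed in (0, 1):
            truth = self._truth(seed=seed, duration=180.0)
            tracks = simulate_reviewers(truth, ("FC3", "CP3"), 18000, 100.0,
                                        params, seed=seed + 10)
            kappas.append(
                fleiss_kappa(tracks, categories=(Label.CLEAN, Label.ARTIFACT))
            )
        assert 0.55 <= np.mean(kappas) <= 0.9

    def test_jitter_bounded_by_margin(self):
        with pytest.raises(ValueError):
            ReviewerParams(jitter_s=0.6)

    def test_muscle_events_can_be_clean_hf(self):
        rates = {k: 0.0 for k in ARTIFACT_TYPES}
        rates["muscle"] = 6.0
        truth = self._truth(rates=rates)
        params = ReviewerParams(n_reviewers=3, jitter_s=0.0, flip_prob=0.0,
                                hf_prob=1.0)
        tracks = simulate_reviewers(truth, ("FT7", "TP7"), 12000, 100.0,
                                    params, seed=3)
        if truth.channel_events("FT7", "TP7"):
            assert any((t.labels == Label.CLEAN_HF).any() for t in tracks)


class TestDataset:
    def test_counting_and_determinism(self):
        cfg = SynthConfig(n_subjects=2, sessions_per_subject=1, duration_s=20.0,
                          seed=42)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        assert len(a) == 2
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.recording.signal, sb.recording.signal)
            assert sa.n_reviewers == sb.n_reviewers
            for ch in sa.tracks:
                for ta, tb in zip(sa.tracks[ch], sb.tracks[ch]):
                    np.testing.assert_array_equal(ta.labels, tb.labels)
        assert len(a[0].tracks) == 12  # default bipolar montage
        assert {s.n_reviewers for s in a} <= {3, 4}

    def test_clean_vs_muscle_band_rms_separation(self):
        """Premise for classification: muscle-artifact samples carry more
        25-35 Hz power than clean samples."""
        rates = {k: 0.0 for k in ARTIFACT_TYPES}
        rates["muscle"] = 5.0
        cfg = SynthConfig(n_subjects=1, duration_s=120.0, seed=7,
                          artifact_rates=rates)
        session = generate_dataset(cfg)[0]
        prep = preprocess_pipeline(session.recording)
        name = "FT7-TP7"
        ci = prep.channel_names.index(name)
        mask = session.truth.channel_mask("FT7", "TP7", target_rate=100.0,
                                          n_target=prep.n_samples)
        if mask.sum() < 100 or (~mask).sum() < 100:
            pytest.skip("no muscle events landed on this channel")
        rms = band_rms(prep.signal[ci], 100.0, 25, 35, 1.0)
        assert np.median(rms[mask]) > np.median(rms[~mask])
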