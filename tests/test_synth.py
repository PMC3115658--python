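"""Synthetic crackle waveforms and multichannel recordings."""

import numpy as np
import pytest

import cracklekit as ck
from cracklekit.synth import (GroundTruthAnnotation, SynthConfig,
                              half_period_schedule, render_crackle,
                              synthesize_crackle, synthesize_recording)

FS = 8000


class TestCrackleWaveform:
    def test_equal_half_periods_closed_form(self):
        # pitch = 2/(T1+T2+T3+T4); equal half-periods at 416.67 Hz -> 1.2 ms
        durations, _ = half_period_schedule(416.67, 4, 1.0, 1.0)
        assert np.allclose(durations, 1.2, atol=1e-3)

    def test_t2_over_t1_ratio(self):
        durations, _ = half_period_schedule(400.0, 6, 1.5, 0.7)
        assert durations[1] / durations[0] == pytest.approx(1.5)
        assert np.allclose(durations[1:], durations[1])
        assert 2000.0 / durations[:4].sum() == pytest.approx(400.0)

    def test_no_decay_amplitude_ratios(self):
        w = synthesize_crackle(416.67, 4, 1.0, 1.0, 1, FS)
        d = ck.decompose_half_periods(w, FS, detrend=False)
        assert d.A[1] / d.A[0] == pytest.approx(1.0, abs=0.02)
        assert d.A[2] / d.A[0] == pytest.approx(1.0, abs=0.02)

    def test_negative_polarity_peak_downward(self):
        w = synthesize_crackle(400.0, 5, 1.2, 0.8, -1, FS)
        assert w[np.argmax(np.abs(w))] < 0

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="sample_rate"):
            synthesize_crackle(416.67, 4, 1.0, 1.0, 1, 2000)

    def test_too_few_half_periods_rejected(self):
        with pytest.raises(ValueError):
            synthesize_crackle(416.67, 3, 1.0, 1.0, 1, FS)

    def test_render_deterministic(self):
        d, a = half_period_schedule(350.0, 6, 1.3, 0.7)
        w1 = render_crackle(d, a, 1, FS)
        w2 = render_crackle(d, a, 1, FS)
        assert np.array_equal(w1, w2)


class TestRecording:
    def test_deterministic_given_seed(self, geometry):
        prof = ck.builtin_profile("CHF")
        s1, a1 = synthesize_recording(prof, geometry, duration=6, n_breaths=3, seed=5)
        s2, a2 = synthesize_recording(prof, geometry, duration=6, n_breaths=3, seed=5)
        assert np.array_equal(s1, s2)
        assert len(a1.crackles) == len(a2.crackles)
        for c1, c2 in zip(a1.crackles, a2.crackles):
            assert c1.to_dict() == c2.to_dict()

    def test_duration_precondition(self, geometry):
        with pytest.raises(ValueError, match="2 s per breath"):
            synthesize_recording(ck.builtin_profile("IPF"), geometry,
                                 duration=5, n_breaths=3, seed=0)

    def test_needs_two_channels_per_side(self):
        geom = ck.ChannelGeometry(
            positions=np.array([[-5.0, -10, 10], [5.0, -10, 10], [8.0, -10, 4]]),
            side=("left", "right", "right"),
            quadrant=("bottom-left", "bottom-right", "bottom-right"))
        with pytest.raises(ValueError, match="CTC"):
            synthesize_recording(ck.builtin_profile("IPF"), geom,
                                 duration=6, n_breaths=3, seed=0)

    def test_breaths_alternate_with_known_boundaries(self, ipf_recording):
        _, ann = ipf_recording
        assert len(ann.breaths) == 3
        for b in ann.breaths:
            assert b.insp_start < b.insp_end < b.exp_end

    def test_zero_transmission_single_channel_families(self, geometry):
        prof = ck.builtin_profile("IPF").replace(transmission_level=0.0,
                                                 transmission_sd=1e-9)
        _, ann = synthesize_recording(prof, geometry, duration=6, n_breaths=3,
                                      seed=3)
        assert len(ann.crackles) > 0
        for c in ann.crackles:
            assert len(c.channels) == 1  # mother only, no audible children

    def test_focal_sources_within_one_quadrant_region(self, geometry):
        prof = ck.builtin_profile("PN")
        _, ann = synthesize_recording(prof, geometry, duration=6, n_breaths=3,
                                      seed=4)
        assert ann.focal_quadrant is not None
        vert, side = ann.focal_quadrant.split("-")
        for c in ann.crackles:
            x, _, z = c.source
            assert (x < 0) == (side == "left")
            assert (z < 14.0) == (vert == "bottom")

    def test_mother_amplitude_bounds_children(self, ipf_recording):
        _, ann = ipf_recording
        for c in ann.crackles:
            mother_amp = c.channels[c.mother_channel].amplitude
            for hit in c.channels.values():
                assert hit.amplitude <= mother_amp + 1e-9

    def test_inspiratory_rate_recovery(self, geometry):
        # over >= 200 breaths, mean generated inspiratory crackle count
        # within 3 SE of the profile rate
        prof = ck.builtin_profile("CHF")
        counts = []
        for seed in range(70):
            _, ann = synthesize_recording(prof, geometry, duration=6,
                                          n_breaths=3, seed=1000 + seed)
            for b in ann.breaths:
                counts.append(sum(1 for c in ann.crackles
                                  if c.breath_index == b.breath_index
                                  and c.phase == "inspiration"))
        counts = np.asarray(counts, dtype=float)
        assert counts.size >= 200
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - prof.insp_crackle_rate_mean) < 3 * se

    def test_true_pitch_recovers_profile_mean(self, geometry):
        # cohort-level Monte-Carlo check against the generator parameters
        prof = ck.builtin_profile("IPF")
        patient_means = []
        for seed in range(30):
            _, ann = synthesize_recording(prof, geometry, duration=6,
                                          n_breaths=3, seed=2000 + seed)
            insp = [c.pitch_hz for c in ann.crackles if c.phase == "inspiration"]
            if insp:
                patient_means.append(np.mean(insp))
        patient_means = np.asarray(patient_means)
        se = patient_means.std(ddof=1) / np.sqrt(patient_means.size)
        assert abs(patient_means.mean() - prof.pitch_mean) < 3 * se

    def test_annotation_jsonl_round_trip(self, tmp_path, ipf_recording):
        _, ann = ipf_recording
        path = tmp_path / "ann.jsonl"
        ann.to_json_lines(path)
        back = GroundTruthAnnotation.from_json_lines(path)
        assert back.sample_rate == ann.sample_rate
        assert len(back.crackles) == len(ann.crackles)
        assert back.crackles[0].to_dict() == ann.crackles[0].to_dict()
        assert back.breath_boundaries() == ann.breath_boundaries()
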