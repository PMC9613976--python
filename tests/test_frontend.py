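import numpy as np
import pytest

from speechdx import audio, frontend
from speechdx.exceptions import InsufficientDataError, ValidationError
from speechdx.frontend import (
    PitchTrack,
    Segmentation,
    phonation_features,
    prosody_stdf0,
    segment_speech,
    syllable_features,
    timing_features,
    track_pitch,
)

FS = 48000


def make_pitch(f0_values, voiced=None, step=0.01):
    f0 = np.asarray(f0_values, dtype=float)
    voiced = np.ones(len(f0), dtype=bool) if voiced is None else voiced
    times = np.arange(len(f0)) * step + step
    return PitchTrack(times=times, f0=f0, voiced=voiced, step=step)


def make_segmentation(labels, duration=2.0):
    n = len(labels)
    edges = np.linspace(0.0, duration * n, n + 1)
    return Segmentation(starts=edges[:-1], ends=edges[1:], labels=tuple(labels))


class TestPitchTracking:
    def test_recovers_constant_f0(self):
        for f0 in (90.0, 120.0, 220.0):
            x = audio.simulate_sustained_vowel(f0_hz=f0, duration_s=2.0)
            pitch = track_pitch(x, FS)
            assert pitch.voiced.mean() > 0.9
            med = np.median(pitch.voiced_f0)
            assert med == pytest.approx(f0, rel=0.01)

    def test_silence_is_unvoiced(self):
        x = audio.simulate_sustained_vowel(duration_s=1.0)
        padded = np.concatenate([np.zeros(FS), x, np.zeros(FS)])
        pitch = track_pitch(padded, FS)
        assert not pitch.voiced[: 80].any()
        assert not pitch.voiced[-80:].any()

    def test_rejects_bad_input(self):
        with pytest.raises(ValidationError):
            track_pitch(np.zeros((10, 2)), FS)
        with pytest.raises(ValidationError):
            track_pitch(np.zeros(1000), 8000)


class TestSegmentation:
    def test_counts_syllables_as_voiced_intervals(self):
        x = audio.simulate_syllable_train(n_syllables=10)
        pitch = track_pitch(x, FS)
        seg = segment_speech(x, FS, pitch)
        assert seg.of_label("voiced").sum() == 10

    def test_partitions_whole_recording(self):
        x = audio.simulate_syllable_train(n_syllables=8)
        pitch = track_pitch(x, FS)
        seg = segment_speech(x, FS, pitch)
        assert seg.starts[0] == 0.0
        assert seg.ends[-1] == pytest.approx(len(x) / FS, abs=0.02)
        assert np.allclose(seg.starts[1:], seg.ends[:-1])

    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            Segmentation(starts=np.array([0.0, 1.0]), ends=np.array([1.0, 0.5]),
                         labels=("voiced", "pause"))
        with pytest.raises(ValidationError):
            Segmentation(starts=np.array([0.0, 2.0]), ends=np.array([1.0, 3.0]),
                         labels=("voiced", "pause"))
        with pytest.raises(ValidationError):
            Segmentation(starts=np.array([0.0]), ends=np.array([1.0]),
                         labels=("chatter",))


class TestPhonation:
    def test_clean_vowel_near_zero_perturbations(self):
        x = audio.simulate_sustained_vowel(f0_hz=120.0, duration_s=4.0)
        feats = phonation_features(track_pitch(x, FS), x, FS)
        assert feats["stdF0_a"] < 0.05
        assert feats["jitter"] < 0.2
        assert feats["PSI"] == 0.0
        assert feats["stdPSD"] >= 0.0

    def test_clean_vowel_no_subharmonic_flags_across_f0(self):
        for f0 in (90.0, 150.0, 200.0):
            x = audio.simulate_sustained_vowel(f0_hz=f0, duration_s=3.0)
            feats = phonation_features(track_pitch(x, FS), x, FS)
            assert feats["PSI"] == 0.0

    def test_jitter_increases_with_planted_jitter(self):
        vals = []
        for j in (0.0, 1.0, 3.0):
            x = audio.simulate_sustained_vowel(jitter_pct=j, duration_s=4.0,
                                               seed=2)
            vals.append(phonation_features(track_pitch(x, FS), x, FS)["jitter"])
        assert vals[0] < vals[1] < vals[2]

    def test_too_short_phonation_rejected(self):
        x = audio.simulate_sustained_vowel(duration_s=1.0)
        with pytest.raises(InsufficientDataError, match="2 s"):
            phonation_features(track_pitch(x, FS), x, FS)

    def test_amplitude_invariance(self):
        x = audio.simulate_sustained_vowel(jitter_pct=1.0, f0_drift_st=0.3,
                                           duration_s=3.0, seed=5)
        pitch = track_pitch(x, FS)
        f1 = phonation_features(pitch, x, FS)
        f2 = phonation_features(track_pitch(3.7 * x, FS), 3.7 * x, FS)
        assert f1["stdF0_a"] == pytest.approx(f2["stdF0_a"], abs=1e-9)
        assert f1["jitter"] == pytest.approx(f2["jitter"], rel=1e-6)
        assert f1["PSI"] == f2["PSI"]
        assert f1["stdPSD"] == pytest.approx(f2["stdPSD"], abs=1e-9)


class TestTiming:
    def test_uniform_three_types_hand_case(self):
        # 30 intervals of 2 s each, 10 of each type, stationary pattern
        labels = ["voiced", "unvoiced", "pause"] * 10
        seg = make_segmentation(labels, duration=2.0)
        feats = timing_features(seg)
        assert feats["EST"] == pytest.approx(np.log2(3.0), abs=1e-12)
        assert feats["RST"] == pytest.approx(30.0)  # 30 intervals in 60 s
        assert abs(feats["AST"]) < 1e-9  # stationary pattern
        assert feats["GVI"] == 0.0  # pauses never flanked by voiced on both sides

    def test_gvi_counts_flanked_pauses(self):
        labels = ["voiced", "pause", "voiced", "pause", "voiced",
                  "unvoiced", "pause", "unvoiced", "voiced", "pause"]
        seg = make_segmentation(labels, duration=6.0)  # 60 s total
        feats = timing_features(seg)
        assert feats["GVI"] == pytest.approx(2.0)  # 2 flanked pauses per minute

    def test_ast_positive_when_intervals_accelerate(self):
        # short intervals late, long intervals early -> late RST > early RST
        durs = np.concatenate([np.full(10, 3.0), np.full(20, 1.0)])
        edges = np.concatenate([[0.0], np.cumsum(durs)])
        labels = tuple(["voiced", "pause"] * 15)
        seg = Segmentation(starts=edges[:-1], ends=edges[1:], labels=labels)
        assert timing_features(seg)["AST"] > 0

    def test_est_never_exceeds_log2_3(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = rng.dirichlet(np.ones(3))
            seg = audio.simulate_interval_sequence(
                dict(zip(("voiced", "unvoiced", "pause"), p)),
                total_s=30.0, seed=seed,
            )
            if len(seg) < 10:
                continue
            assert timing_features(seg)["EST"] <= np.log2(3.0) + 1e-12

    def test_too_few_intervals_rejected(self):
        with pytest.raises(InsufficientDataError, match=">= 10"):
            timing_features(make_segmentation(["voiced"] * 5))


class TestSyllables:
    def test_hand_case_from_manual_segmentation(self):
        # voiced 100 ms bursts at onsets 0, 0.2, 0.45, 0.6 s
        starts = np.array([0.0, 0.1, 0.2, 0.3, 0.45, 0.55, 0.6])
        ends = np.array([0.1, 0.2, 0.3, 0.45, 0.55, 0.6, 0.7])
        labels = ("voiced", "pause", "voiced", "pause", "voiced", "pause",
                  "voiced")
        seg = Segmentation(starts=starts, ends=ends, labels=labels)
        x = np.zeros(int(0.7 * FS))
        feats = syllable_features(x, FS, seg)
        assert feats["VD"] == pytest.approx(100.0)
        gaps = np.diff([0.0, 0.2, 0.45, 0.6])
        assert feats["DDKI"] == pytest.approx(np.std(gaps, ddof=1) * 1000.0)
        assert feats["DDKR"] == pytest.approx(1.0 / np.median(gaps))

    def test_recovers_planted_rate(self):
        x = audio.simulate_syllable_train(rate_per_s=1.0 / 0.150,
                                          n_syllables=20)
        pitch = track_pitch(x, FS)
        seg = segment_speech(x, FS, pitch)
        feats = syllable_features(x, FS, seg)
        assert feats["DDKR"] == pytest.approx(1.0 / 0.150, rel=0.05)
        assert feats["DDKI"] < 10.0  # regular train: little onset variability
        assert feats["NSR"] > 0

    def test_too_few_onsets_rejected(self):
        seg = make_segmentation(["voiced", "pause", "voiced", "pause"])
        with pytest.raises(InsufficientDataError, match=">= 3"):
            syllable_features(np.zeros(FS), FS, seg)


class TestProsody:
    def test_constant_f0_gives_zero(self):
        pitch = make_pitch(np.full(600, 120.0))
        assert prosody_stdf0(pitch) == 0.0

    def test_robust_to_octave_jumps(self):
        f0 = np.full(600, 120.0)
        f0[::20] = 240.0  # 5% octave errors, excluded by the 6 st gate
        assert prosody_stdf0(make_pitch(f0)) < 0.1

    def test_matches_mad_estimate(self, rng):
        st = rng.standard_normal(600) * 2.0
        f0 = 120.0 * 2.0 ** (st / 12.0)
        est = prosody_stdf0(make_pitch(f0))
        modal = 12.0 * np.log2(f0 / np.median(f0))
        modal = modal[np.abs(modal) <= 6.0]
        expected = 1.4826 * np.median(np.abs(modal - np.median(modal)))
        assert est == pytest.approx(expected, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError, match="5 s"):
            prosody_stdf0(make_pitch(np.full(100, 120.0)))
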