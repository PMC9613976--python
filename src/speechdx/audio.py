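"""Synthetic audio and symbolic fixtures with planted, known parameters.

These generators produce the controlled inputs the acoustic front-end is
validated against: a glottal-pulse-like sustained vowel with planted
jitter, pitch drift and a period-doubled (sub-harmonic) episode; a
syllable-repetition train with planted onset-interval statistics; and a
symbolic voiced/unvoiced/pause interval sequence with planted type
incidences.  They emulate the waveform properties the front-end
measures, not natural speech.
"""

from __future__ import annotations

import numpy as np
from scipy.io import wavfile
from scipy.ndimage import gaussian_filter1d

from .exceptions import ValidationError
from .frontend import Segmentation

DEFAULT_FS = 48000


def write_wav(path, waveform: np.ndarray, fs: int = DEFAULT_FS) -> None:
    """Write a mono float waveform as RIFF WAV, 16-bit PCM."""
    x = np.asarray(waveform, dtype=float)
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak * 0.9
    wavfile.write(path, int(fs), (x * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a RIFF WAV as mono float in [-1, 1]; stereo is downmixed."""
    fs, data = wavfile.read(path)
    x = np.asarray(data, dtype=float)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if data.dtype == np.int16:
        x = x / 32768.0
    elif data.dtype == np.int32:
        x = x / 2147483648.0
    return x, int(fs)


def _pulse(fs: float, width_s: float = 0.0015) -> np.ndarray:
    w = max(4, int(round(width_s * fs)))
    return np.hanning(w)


def simulate_sustained_vowel(
    f0_hz: float = 120.0,
    duration_s: float = 4.0,
    jitter_pct: float = 0.0,
    f0_drift_st: float = 0.0,
    subharmonic_fraction: float = 0.0,
    fs: int = DEFAULT_FS,
    seed: int = 0,
    subharmonic_depth: float = 0.15,
) -> np.ndarray:
    """Glottal-pulse train with planted jitter, drift and sub-harmonics.

    Cycle lengths carry iid relative perturbations scaled so that the
    local-jitter statistic (mean absolute consecutive-period difference
    over the mean period) equals ``jitter_pct`` in expectation.  A slow
    pitch drift with sample SD exactly ``f0_drift_st`` semitones is
    superimposed.  A contiguous, centred episode covering
    ``subharmonic_fraction`` of the duration alternates pulse amplitudes
    (period doubling).  For alternating amplitudes (1, d) the F0 peak
    retains a fraction 2d/(1+d^2) of the doubled-period ACF peak; with a
    40 ms frame holding only ~5 pulses, frame phase spreads the measured
    ratio by roughly +-0.15 around that value.  The default depth 0.15
    (ratio 0.29) keeps planted episodes inside the detection band
    [0.10, 0.55] across frame phases.
    """
    if not 60 <= f0_hz <= 400:
        raise ValidationError("f0_hz must be within 60-400 Hz")
    if fs < 16000:
        raise ValidationError("fs must be >= 16 kHz")
    if not 0.0 <= subharmonic_fraction <= 1.0:
        raise ValidationError("subharmonic_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    if f0_drift_st > 0:
        grid = np.arange(0, duration_s + 0.01, 0.01)
        drift = gaussian_filter1d(rng.standard_normal(len(grid)), sigma=30.0)
        drift = (drift - drift.mean()) / drift.std(ddof=1) * f0_drift_st
    else:
        grid = np.array([0.0, duration_s])
        drift = np.zeros(2)

    # sigma such that E|d_i - d_{i+1}| * 100 = jitter_pct for iid normal d
    sigma = (jitter_pct / 100.0) * np.sqrt(np.pi) / 2.0

    exact_grid = jitter_pct == 0 and f0_drift_st == 0
    base_period = round(fs / f0_hz) / fs if exact_grid else 1.0 / f0_hz

    times = []
    t = 0.0
    while t < duration_s:
        times.append(t)
        f0_t = f0_hz * 2.0 ** (np.interp(t, grid, drift) / 12.0)
        period = (1.0 / f0_t) if not exact_grid else base_period
        if sigma > 0:
            period *= 1.0 + sigma * rng.standard_normal()
        t += period
    times = np.asarray(times)

    sub_lo = duration_s * (0.5 - subharmonic_fraction / 2.0)
    sub_hi = duration_s * (0.5 + subharmonic_fraction / 2.0)

    pulse = _pulse(fs)
    n = int(round(duration_s * fs)) + len(pulse)
    x = np.zeros(n)
    for i, tc in enumerate(times):
        amp = 1.0
        if sub_lo <= tc < sub_hi and i % 2 == 1:
            amp = subharmonic_depth
        start = int(round(tc * fs))
        x[start : start + len(pulse)] += amp * pulse
    return x[: int(round(duration_s * fs))]


def simulate_syllable_train(
    rate_per_s: float = 1.0 / 0.150,
    onset_sd_ms: float = 0.0,
    n_syllables: int = 20,
    fs: int = DEFAULT_FS,
    seed: int = 0,
    f0_hz: float = 150.0,
    burst_s: float = 0.060,
) -> np.ndarray:
    """Voiced burst train with planted onset-to-onset interval statistics.

    Onset intervals are normal(1/rate, onset_sd) truncated positive.
    Each syllable is a short glottal-pulse burst with a raised-cosine
    energy envelope, separated by silence, so that voiced-interval
    detection recovers the onsets.
    """
    if n_syllables < 3:
        raise ValidationError("need at least 3 syllables")
    if rate_per_s <= 0:
        raise ValidationError("rate must be positive")
    rng = np.random.default_rng(seed)
    mean_gap = 1.0 / rate_per_s
    sd = onset_sd_ms / 1000.0
    gaps = np.full(n_syllables - 1, mean_gap)
    if sd > 0:
        for i in range(len(gaps)):
            g = -1.0
            while g <= burst_s / 2:  # keep bursts from fusing
                g = rng.normal(mean_gap, sd)
            gaps[i] = g
    onsets = np.concatenate([[0.05], 0.05 + np.cumsum(gaps)])

    pulse = _pulse(fs)
    period = int(round(fs / f0_hz))
    burst_len = int(round(burst_s * fs))
    envelope = np.hanning(burst_len)
    total = onsets[-1] + burst_s + 0.15
    x = np.zeros(int(round(total * fs)))
    for onset in onsets:
        start = int(round(onset * fs))
        burst = np.zeros(burst_len + len(pulse))
        for p0 in range(0, burst_len, period):
            burst[p0 : p0 + len(pulse)] += pulse
        x[start : start + burst_len] += burst[:burst_len] * envelope
    return x


def simulate_interval_sequence(
    type_probs: dict[str, float],
    duration_params: dict[str, tuple[float, float]] | None = None,
    total_s: float = 60.0,
    seed: int = 0,
) -> Segmentation:
    """Symbolic voiced/unvoiced/pause sequence with planted type incidences.

    Interval types are drawn iid from ``type_probs``; durations are
    lognormal with per-type (mu, sigma) parameters of the underlying
    normal (default mu = log 0.15 s, sigma = 0.3 for every type).  The
    sequence is truncated to end exactly at ``total_s``.
    """
    if total_s <= 0:
        raise ValidationError("total_s must be positive")
    labels = sorted(type_probs)
    bad = set(labels) - {"voiced", "unvoiced", "pause"}
    if bad:
        raise ValidationError(f"unknown interval types: {sorted(bad)}")
    probs = np.array([type_probs[lab] for lab in labels], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValidationError("type_probs must be a probability distribution")
    if duration_params is None:
        duration_params = {lab: (float(np.log(0.15)), 0.3) for lab in labels}

    rng = np.random.default_rng(seed)
    starts, ends, out_labels = [], [], []
    t = 0.0
    while t < total_s:
        lab = labels[rng.choice(len(labels), p=probs)]
        mu, sig = duration_params[lab]
        dur = float(rng.lognormal(mu, sig))
        end = min(t + dur, total_s)
        starts.append(t)
        ends.append(end)
        out_labels.append(lab)
        t = end
    return Segmentation(
        starts=np.array(starts), ends=np.array(ends), labels=tuple(out_labels)
    )
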