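"""Desk-scale acoustic feature extraction from mono WAV audio.

Implements the subset of the acoustic features that is fully specifiable
from the waveform alone: pitch variability (sustained and connected
speech), jitter, proportion of sub-harmonic intervals, band-power
variability, the interval-timing family (entropy, rate, acceleration of
speech timing, gaping in-between voiced intervals), net speech rate and
the diadochokinetic measures.  Consonant-level and respiration-derived
features (DUS, VOT, RFA, RLR, RSR, PIR) are *not* extracted here; they
enter the pipeline only through feature tables.

Analysis settings are conventional for dysarthria analysis: 40 ms
frames at a 10 ms step, F0 search range 60-400 Hz, minimum pause
duration 60 ms and minimum voiced duration 30 ms.  All features are
invariant to waveform amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as spsig

from .exceptions import InsufficientDataError, ValidationError

FRAME_S = 0.040
STEP_S = 0.010
F0_MIN = 60.0
F0_MAX = 400.0
VOICING_THRESHOLD = 0.30
MIN_PAUSE_S = 0.060
MIN_VOICED_S = 0.030
SILENCE_REL = 1e-2  # frame RMS below this fraction of the loudest frame = pause
SUBHARMONIC_RATIO = 0.45
SUBHARMONIC_MIN_F0_PEAK = 0.10  # the perceived-F0 peak must still exist

LABELS = ("voiced", "unvoiced", "pause")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PitchTrack:
    """Frame-wise F0 track: times (s), F0 (Hz, 0 where unvoiced), voicing."""

    times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray
    step: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("frame times must be strictly increasing")
        if np.any(self.f0[self.voiced] <= 0):
            raise ValidationError("voiced frames must carry positive F0")

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced]

    @property
    def voiced_duration(self) -> float:
        return float(self.voiced.sum() * self.step)


@dataclass(frozen=True)
class Segmentation:
    """Ordered voiced/unvoiced/pause intervals covering a recording."""

    starts: np.ndarray
    ends: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.starts) == len(self.ends) == len(self.labels)):
            raise ValidationError("segmentation arrays must have equal length")
        if len(self.starts) == 0:
            raise ValidationError("segmentation must contain at least one interval")
        if np.any(self.ends - self.starts <= 0):
            raise ValidationError("interval durations must be positive")
        if not np.allclose(self.starts[1:], self.ends[:-1]):
            raise ValidationError("intervals must be contiguous")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValidationError(f"unknown interval labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_duration(self) -> float:
        return float(self.ends[-1] - self.starts[0])

    def of_label(self, label: str) -> np.ndarray:
        return np.array([lab == label for lab in self.labels])


# ---------------------------------------------------------------------------
# framing helpers
# ---------------------------------------------------------------------------

def _frames(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Slice x into 40 ms frames at a 10 ms step; return (frames, centre times)."""
    flen = int(round(FRAME_S * fs))
    step = int(round(STEP_S * fs))
    if len(x) < flen:
        x = np.pad(x, (0, flen - len(x)))
    n = 1 + (len(x) - flen) // step
    idx = np.arange(flen)[None, :] + step * np.arange(n)[:, None]
    frames = x[idx]
    times = (np.arange(n) * step + flen / 2) / fs
    return frames, times


def _frame_acf(frames: np.ndarray) -> np.ndarray:
    """Biased normalised autocorrelation of mean-removed frames (per row)."""
    x = frames - frames.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * x.shape[1])))
    spec = np.fft.rfft(x, nfft, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : x.shape[1]]
    r0 = acf[:, 0].copy()
    r0[r0 <= 0] = np.inf  # silent frame: normalised ACF becomes 0
    return acf / r0[:, None]


def _parabolic(values: np.ndarray, i: int) -> float:
    """Sub-sample peak refinement via a three-point parabola."""
    if i <= 0 or i >= len(values) - 1:
        return float(i)
    a, b, c = values[i - 1], values[i], values[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(i)
    return i + 0.5 * (a - c) / denom


# ---------------------------------------------------------------------------
# pitch tracking and segmentation
# ---------------------------------------------------------------------------

def track_pitch(waveform: np.ndarray, fs: float) -> PitchTrack:
    """Autocorrelation F0 tracking on 40 ms frames at a 10 ms step.

    Search range 60-400 Hz; a frame is voiced when its normalised
    autocorrelation peak exceeds the periodicity-strength threshold and
    its energy is above the relative silence floor.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValidationError("waveform must be a non-empty 1-D array")
    if fs < 16000:
        raise ValidationError("sampling rate must be >= 16 kHz")
    frames, times = _frames(x, fs)
    acf = _frame_acf(frames)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    floor = SILENCE_REL * rms.max() if rms.max() > 0 else np.inf

    lag_min = int(np.floor(fs / F0_MAX))
    lag_max = min(int(np.ceil(fs / F0_MIN)), acf.shape[1] - 2)

    f0 = np.zeros(len(frames))
    voiced = np.zeros(len(frames), dtype=bool)
    for i in range(len(frames)):
        if rms[i] <= floor:
            continue
        window = acf[i, lag_min : lag_max + 1]
        j = int(np.argmax(window))
        strength = window[j]
        if strength < VOICING_THRESHOLD:
            continue
        lag = _parabolic(acf[i], lag_min + j)
        if lag <= 0:
            continue
        voiced[i] = True
        f0[i] = fs / lag
    return PitchTrack(times=times, f0=f0, voiced=voiced, step=STEP_S)


def segment_speech(waveform: np.ndarray, fs: float, pitch: PitchTrack) -> Segmentation:
    """Classify frames as voiced/unvoiced/pause and merge them into intervals.

    Voicing comes from the pitch track; remaining frames are unvoiced
    when their energy is above the relative noise floor and pauses
    otherwise.  Voiced runs shorter than 30 ms and pause runs shorter
    than 60 ms are absorbed into their longer neighbour.  The intervals
    partition [0, T] exactly.
    """
    x = np.asarray(waveform, dtype=float)
    frames, _ = _frames(x, fs)
    if len(frames) != len(pitch.voiced):
        raise ValidationError("pitch track does not match this waveform framing")
    rms = np.sqrt(np.mean(frames**2, axis=1))
    floor = SILENCE_REL * rms.max() if rms.max() > 0 else np.inf

    labels = np.where(pitch.voiced, 0, np.where(rms > floor, 1, 2))  # v/u/p

    def runs(lab: np.ndarray) -> list[list]:
        out = []
        start = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[start]:
                out.append([start, i, int(lab[start])])
                start = i
        return out

    min_frames = {0: int(round(MIN_VOICED_S / STEP_S)), 2: int(round(MIN_PAUSE_S / STEP_S))}
    r = runs(labels)
    changed = True
    while changed and len(r) > 1:
        changed = False
        lengths = [b - a for a, b, _ in r]
        order = np.argsort(lengths, kind="stable")
        for k in order:
            a, b, lab = r[k]
            need = min_frames.get(lab)
            if need is None or b - a >= need:
                continue
            left = r[k - 1] if k > 0 else None
            right = r[k + 1] if k < len(r) - 1 else None
            if left is None and right is None:
                continue
            if right is None or (left is not None and
                                 (left[1] - left[0]) >= (right[1] - right[0])):
                target = left
            else:
                target = right
            r[k][2] = target[2]
            merged = []
            for seg in r:
                if merged and merged[-1][2] == seg[2]:
                    merged[-1][1] = seg[1]
                else:
                    merged.append(seg)
            r = merged
            changed = True
            break

    total = len(x) / fs
    step = STEP_S
    starts = np.array([a * step for a, _, _ in r])
    ends = np.array([b * step for _, b, _ in r])
    ends[-1] = max(total, ends[-1])
    starts[0] = 0.0
    ends = np.minimum(ends, ends[-1])
    name = {0: "voiced", 1: "unvoiced", 2: "pause"}
    return Segmentation(
        starts=starts, ends=ends, labels=tuple(name[lab] for _, _, lab in r)
    )


# ---------------------------------------------------------------------------
# phonation features (sustained vowel)
# ---------------------------------------------------------------------------

def _cycle_peaks(x: np.ndarray, fs: float, f0_median: float) -> np.ndarray:
    """Glottal-pulse peak times (s) via relative-height peak picking."""
    height = 0.3 * np.percentile(np.abs(x), 95)
    distance = max(1, int(0.6 * fs / f0_median))
    peaks, _ = spsig.find_peaks(x, height=height, distance=distance)
    refined = np.array([_parabolic(x, p) for p in peaks])
    return refined / fs


def _semitones(f0: np.ndarray) -> np.ndarray:
    return 12.0 * np.log2(f0 / np.median(f0))


def _subharmonic_flags(frames: np.ndarray, acf: np.ndarray, fs: float,
                       voiced: np.ndarray) -> np.ndarray:
    """Flag voiced frames whose ACF shows a half-rate (period-doubled) peak.

    For a period-doubled frame the ACF peak at the doubled period carries
    the full signal power while the peak at the perceived-F0 lag is
    depressed: their difference equals the relative power of the
    alternating (half-rate) component.  A frame is flagged when that
    half-rate peak holds at least ``SUBHARMONIC_RATIO`` of the dominant
    peak while the F0 peak is still present (at least
    ``SUBHARMONIC_MIN_F0_PEAK`` of it) - i.e. the frame alternates rather
    than simply phonating an octave lower.

    The dominant lag is taken from the biased-ACF argmax over the F0
    search range (its triangular taper makes the shortest true period win
    on purely periodic frames); peak values are read from the
    bias-corrected ACF, where the peaks of a periodic signal are equal.
    """
    lag_min = int(np.floor(fs / F0_MAX))
    lag_max = min(int(np.ceil(fs / F0_MIN)), acf.shape[1] - 2)
    flen = acf.shape[1]
    unbias = 1.0 / (1.0 - np.arange(flen) / flen)

    def peak(row: np.ndarray, lag: int, halo: int = 3) -> float:
        lo = max(lag - halo, 0)
        return float(row[lo : lag + halo + 1].max())

    flags = np.zeros(len(frames), dtype=bool)
    for i in np.nonzero(voiced)[0]:
        dominant = lag_min + int(np.argmax(acf[i, lag_min : lag_max + 1]))
        row = acf[i] * unbias
        p_dom = peak(row, dominant)
        if p_dom <= 0:
            continue
        half = dominant // 2
        ratio = peak(row, half) / p_dom if half >= 4 else 0.0
        if ratio < SUBHARMONIC_MIN_F0_PEAK and 2 * dominant <= flen - 2:
            # dominant lag is the F0 itself; look for the doubled period
            p_two = peak(row, 2 * dominant)
            if p_two > p_dom:
                ratio = p_dom / p_two
        flags[i] = (
            SUBHARMONIC_MIN_F0_PEAK <= ratio <= 1.0 - SUBHARMONIC_RATIO
        )
    return flags


def phonation_features(pitch: PitchTrack, waveform: np.ndarray, fs: float) -> dict:
    """Sustained-phonation features: stdF0_a, jitter, PSI, stdPSD.

    * ``stdF0_a`` — SD of voiced F0 in semitones re the subject median.
    * ``jitter`` — mean absolute consecutive-period difference over the
      mean period, percent (local jitter), measured on glottal-cycle
      peaks.
    * ``PSI`` — percentage of voiced time in frames flagged as
      period-doubled (sub-harmonic).
    * ``stdPSD`` — mean over eight 1 kHz bands (0-8 kHz) of the temporal
      SD of band power in dB.
    """
    x = np.asarray(waveform, dtype=float)
    if pitch.voiced_duration < 2.0:
        raise InsufficientDataError(
            f"need >= 2 s of voiced phonation, got {pitch.voiced_duration:.2f} s"
        )
    st = _semitones(pitch.voiced_f0)
    std_f0 = float(np.std(st, ddof=1))

    f0_med = float(np.median(pitch.voiced_f0))
    peaks = _cycle_peaks(x, fs, f0_med)
    periods = np.diff(peaks)
    ok = (periods > 0.8 / F0_MAX) & (periods < 2.5 / F0_MIN)
    periods = periods[ok]
    if len(periods) < 3:
        raise InsufficientDataError("too few glottal cycles for jitter")
    jitter = float(np.mean(np.abs(np.diff(periods))) / np.mean(periods) * 100.0)

    frames, _ = _frames(x, fs)
    acf = _frame_acf(frames)
    flags = _subharmonic_flags(frames, acf, fs, pitch.voiced)
    psi = float(100.0 * flags.sum() / pitch.voiced.sum())

    std_psd = _std_band_power(frames[pitch.voiced], fs)
    return {"stdF0_a": std_f0, "jitter": jitter, "PSI": psi, "stdPSD": std_psd}


def _std_band_power(frames: np.ndarray, fs: float, n_bands: int = 8,
                    band_hz: float = 1000.0) -> float:
    """Mean over 1 kHz bands of the temporal SD of band power in dB."""
    win = np.hanning(frames.shape[1])
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    freqs = np.fft.rfftfreq(frames.shape[1], 1 / fs)
    sds = []
    for b in range(n_bands):
        sel = (freqs >= b * band_hz) & (freqs < (b + 1) * band_hz)
        power = spec[:, sel].sum(axis=1)
        floor = 1e-12 * power.max() if power.max() > 0 else 1.0
        level_db = 10.0 * np.log10(np.maximum(power, floor))
        sds.append(np.std(level_db, ddof=1))
    return float(np.mean(sds))


# ---------------------------------------------------------------------------
# timing features (connected speech)
# ---------------------------------------------------------------------------

def timing_features(seg: Segmentation) -> dict:
    """Interval-timing features EST, RST, AST and GVI from a segmentation.

    * ``EST`` — Shannon entropy (base 2) of the incidence proportions of
      the three interval types; bounded by log2(3).
    * ``RST`` — interval count per minute.
    * ``AST`` — difference of RST between the overlapping late
      ([0.4T, T]) and early ([0, 0.6T]) windows, divided by the total
      duration in minutes (positive = acceleration of speech timing).
    * ``GVI`` — pauses flanked by voiced intervals on both sides, per
      minute.
    """
    if len(seg) < 10:
        raise InsufficientDataError(
            f"timing features need >= 10 intervals, got {len(seg)}"
        )
    n = len(seg)
    counts = np.array([sum(lab == t for lab in seg.labels) for t in LABELS])
    p = counts[counts > 0] / n
    est = float(-(p * np.log2(p)).sum())

    minutes = seg.total_duration / 60.0
    rst = n / minutes

    t0 = seg.starts[0]
    T = seg.total_duration
    mid = (seg.starts + seg.ends) / 2 - t0

    def rst_window(lo: float, hi: float) -> float:
        c = int(((mid >= lo) & (mid < hi)).sum())
        return c / ((hi - lo) / 60.0)

    early = rst_window(0.0, 0.6 * T)
    late = rst_window(0.4 * T, T)
    ast = (late - early) / minutes

    gvi_count = 0
    for i in range(1, n - 1):
        if (
            seg.labels[i] == "pause"
            and seg.labels[i - 1] == "voiced"
            and seg.labels[i + 1] == "voiced"
        ):
            gvi_count += 1
    gvi = gvi_count / minutes
    return {"EST": est, "RST": rst, "AST": ast, "GVI": gvi}


# ---------------------------------------------------------------------------
# syllable features
# ---------------------------------------------------------------------------

def syllable_features(waveform: np.ndarray, fs: float, seg: Segmentation) -> dict:
    """Diadochokinetic and speech-rate features VD, DDKI, DDKR, NSR.

    Voice onsets are the starts of voiced intervals.  VD is the mean
    voiced-interval duration (ms); DDKI the SD of onset-to-onset
    durations (ms); DDKR the inverse median onset-to-onset duration
    (syllables/s).  NSR counts syllable nuclei — energy peaks inside
    voiced intervals at least 100 ms apart and above 0.3x the median
    peak energy — per second of speech.
    """
    x = np.asarray(waveform, dtype=float)
    voiced_mask = seg.of_label("voiced")
    onsets = seg.starts[voiced_mask]
    if len(onsets) < 3:
        raise InsufficientDataError(
            f"syllable features need >= 3 voice onsets, got {len(onsets)}"
        )
    vd = float(np.mean(seg.durations[voiced_mask]) * 1000.0)
    gaps = np.diff(onsets)
    ddki = float(np.std(gaps, ddof=1) * 1000.0)
    ddkr = float(1.0 / np.median(gaps))

    frames, times = _frames(x, fs)
    env = np.sqrt(np.mean(frames**2, axis=1))
    distance = max(1, int(round(0.100 / STEP_S)))
    peaks, props = spsig.find_peaks(env, distance=distance)
    in_voiced = np.zeros(len(peaks), dtype=bool)
    for k, pk in enumerate(peaks):
        t = times[pk]
        for s, e, lab in zip(seg.starts, seg.ends, seg.labels):
            if lab == "voiced" and s <= t < e:
                in_voiced[k] = True
                break
    peaks = peaks[in_voiced]
    if len(peaks):
        heights = env[peaks]
        keep = heights >= 0.3 * np.median(heights)
        n_syll = int(keep.sum())
    else:
        n_syll = 0
    nsr = n_syll / seg.total_duration
    return {"VD": vd, "DDKI": ddki, "DDKR": ddkr, "NSR": nsr}


# ---------------------------------------------------------------------------
# prosodic pitch variability (connected speech)
# ---------------------------------------------------------------------------

def prosody_stdf0(pitch: PitchTrack) -> float:
    """Robust pitch variability of connected speech in semitones.

    F0 is expressed in semitones re the subject median; frames more than
    6 st away from the median (octave errors) are excluded and the
    robust SD is 1.4826 x the median absolute deviation of the modal
    frames.
    """
    if pitch.voiced_duration < 5.0:
        raise InsufficientDataError(
            f"prosodic stdF0 needs >= 5 s voiced speech, got "
            f"{pitch.voiced_duration:.2f} s"
        )
    st = _semitones(pitch.voiced_f0)
    modal = st[np.abs(st) <= 6.0]
    if len(modal) < 8:
        raise InsufficientDataError("too few modal frames for prosodic stdF0")
    med = np.median(modal)
    mad = np.median(np.abs(modal - med))
    return float(1.4826 * mad)
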