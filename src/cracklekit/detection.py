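"""Per-channel crackle detection and breath-phase segmentation.

Crackles are short explosive transients superimposed on the breath sound.
The detector band-passes the channel (default 100-2000 Hz), scores each
sample as rectified amplitude over a trailing background estimate, and
declares an event where the score exceeds a threshold, the rise from the
threshold crossing to the peak is fast (default < 3 ms), and the event is
separated from its neighbours by a dead time.  The background estimate is a
robust (median-based) trailing RMS so that the crackles themselves do not
inflate it.

Breath segmentation either accepts known boundaries (synthetic recordings
carry them in their annotation) or estimates them from the low-frequency
breath-sound envelope.  Each breath is split into inspiration and
expiration, each phase into equal thirds, and every crackle receives the
standard 1-6 timing code (1 = early inspiration ... 6 = late expiration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, uniform_filter1d
from scipy.signal import butter, find_peaks, sosfilt, sosfiltfilt

__all__ = [
    "BreathSegment",
    "CrackleEvent",
    "DetectorConfig",
    "segment_breaths",
    "detect_crackles",
]


@dataclass(frozen=True)
class BreathSegment:
    """One full breath: inspiration [insp_start, insp_end), expiration
    [insp_end, exp_end).  Times in seconds."""

    breath_index: int
    insp_start: float
    insp_end: float
    exp_end: float

    def __post_init__(self) -> None:
        if not (self.insp_start < self.insp_end < self.exp_end):
            raise ValueError("breath boundaries must satisfy "
                             "insp_start < insp_end < exp_end")

    def contains(self, t: float) -> bool:
        return self.insp_start <= t < self.exp_end

    def phase_of(self, t: float) -> str:
        return "inspiration" if t < self.insp_end else "expiration"

    def timing_code(self, t: float) -> int:
        """1-6 code for the phase-third containing time ``t``.

        Thirds are computed on each phase's own duration: codes 1-3 are the
        early/mid/late thirds of inspiration, 4-6 of expiration.
        """
        if not self.contains(t):
            raise ValueError(f"time {t} s is outside breath {self.breath_index}")
        if t < self.insp_end:
            frac = (t - self.insp_start) / (self.insp_end - self.insp_start)
            base = 1
        else:
            frac = (t - self.insp_end) / (self.exp_end - self.insp_end)
            base = 4
        return base + min(2, int(frac * 3.0))


@dataclass
class CrackleEvent:
    """One detected crackle on one channel."""

    channel: int
    onset_time: float        # s
    peak_time: float         # s
    waveform: np.ndarray | None
    peak_amplitude: float    # arbitrary units, |highest deflection|
    breath_index: int
    timing_code: int

    def __post_init__(self) -> None:
        if self.onset_time > self.peak_time + 1e-12:
            raise ValueError("onset_time must not exceed peak_time")
        if not 1 <= self.timing_code <= 6:
            raise ValueError("timing_code must be in 1..6")
        if not self.peak_amplitude > 0:
            raise ValueError("peak_amplitude must be positive")


@dataclass(frozen=True)
class DetectorConfig:
    band: tuple[float, float] = (100.0, 2000.0)   # Hz, transient scoring band
    hp_cutoff: float = 60.0        # Hz, high-pass for windows and amplitudes
    bg_window_ms: float = 200.0    # trailing background estimation window
    bg_block_ms: float = 50.0      # robust background: block size
    threshold: float = 5.5         # score = |bandpassed| / background RMS
    max_rise_ms: float = 3.0       # threshold crossing -> peak
    dead_time_ms: float = 10.0     # minimum separation between events
    window_ms: float = 30.0        # extracted window, centred on the peak

    # breath segmentation
    seg_lowpass: float = 150.0     # Hz (below the crackle pitch range)
    seg_env_ms: float = 250.0      # envelope smoothing
    min_phase_s: float = 0.6       # shortest plausible phase


# ----------------------------------------------------------------------
# breath segmentation

def segment_breaths(
    signal: np.ndarray,
    sample_rate: float,
    known_boundaries=None,
    config: DetectorConfig | None = None,
) -> list[BreathSegment]:
    """Segment a single channel into full breaths.

    When ``known_boundaries`` is given (a sequence of
    ``(insp_start, insp_end, exp_end)`` triples, e.g. from a synthetic
    annotation) it is used verbatim.  Otherwise boundaries are estimated
    from the low-frequency envelope: the signal is low-passed, its smoothed
    RMS envelope is split at troughs, and the resulting phases are paired
    into breaths with the louder phase of each pair taken as inspiration.
    Only full breaths are returned.
    """
    cfg = config or DetectorConfig()
    if known_boundaries is not None:
        segments = []
        for i, (a, b, c) in enumerate(known_boundaries):
            segments.append(BreathSegment(i, float(a), float(b), float(c)))
        return segments

    x = np.asarray(signal, dtype=float)
    if x.size < sample_rate * 2:
        warnings.warn("signal shorter than one plausible breath; no segments")
        return []
    sos = butter(4, cfg.seg_lowpass, btype="lowpass", fs=sample_rate, output="sos")
    low = sosfiltfilt(sos, x)
    win = max(int(cfg.seg_env_ms / 1000.0 * sample_rate), 1)
    env = np.sqrt(uniform_filter1d(low * low, size=win, mode="nearest"))
    # clip at the 95th percentile: individual loud crackles must not set
    # the scale of the breath envelope
    env = np.minimum(env, np.percentile(env, 90))
    if env.max() < 1e-12:
        warnings.warn("no detectable breath cycle (flat envelope)")
        return []

    min_dist = max(int(cfg.min_phase_s * sample_rate), 1)
    prom = 0.25 * (env.max() - env.min())
    if prom <= 0:
        warnings.warn("no detectable breath cycle (flat envelope)")
        return []
    troughs, _ = find_peaks(-env, distance=min_dist, prominence=prom)
    # phase boundaries: start of signal, internal troughs, end of signal
    bounds = np.concatenate([[0], troughs, [x.size - 1]]) / sample_rate
    if len(bounds) < 3:
        warnings.warn("no detectable breath cycle")
        return []
    # robust envelope level per phase
    levels = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        ia, ib = int(a * sample_rate), max(int(b * sample_rate), int(a * sample_rate) + 1)
        levels.append(float(np.median(env[ia:ib])))
    # pair consecutive phases into (inspiration, expiration) breaths; choose
    # the pairing offset that best matches "inspiration louder"
    def score(offset: int) -> float:
        s = 0.0
        for k in range(offset, len(levels) - 1, 2):
            s += levels[k] - levels[k + 1]
        return s
    offset = 0 if score(0) >= score(1) else 1
    segments = []
    idx = 0
    for k in range(offset, len(levels) - 1, 2):
        a, b, c = bounds[k], bounds[k + 1], bounds[k + 2]
        # drop partial breaths touching the signal edges unless they span
        # a plausible full cycle
        if (c - a) < 2 * cfg.min_phase_s:
            continue
        segments.append(BreathSegment(idx, float(a), float(b), float(c)))
        idx += 1
    if not segments:
        warnings.warn("no detectable breath cycle")
    return segments


# ----------------------------------------------------------------------
# crackle detection

def _robust_trailing_background(bp: np.ndarray, sample_rate: float,
                                cfg: DetectorConfig) -> np.ndarray:
    """Trailing background level, robust to the crackles themselves.

    |bandpassed| is summarized per block by its median (scaled to the RMS of
    a Gaussian), and each sample's background is the median of the trailing
    blocks covering ``bg_window_ms``.
    """
    block = max(int(cfg.bg_block_ms / 1000.0 * sample_rate), 1)
    n_blocks = int(np.ceil(bp.size / block))
    pad = n_blocks * block - bp.size
    absb = np.abs(bp)
    if pad:
        absb = np.concatenate([absb, absb[-pad:]])
    block_med = np.median(absb.reshape(n_blocks, block), axis=1) / 0.6745
    k = max(int(round(cfg.bg_window_ms / cfg.bg_block_ms)), 1)
    bg_blocks = np.empty(n_blocks)
    for i in range(n_blocks):
        lo = max(0, i - k)
        prev = block_med[lo:i]
        bg_blocks[i] = np.median(prev) if prev.size else block_med[i]
    bg = np.repeat(bg_blocks, block)[: bp.size]
    # scale-relative floor: in a (near-)noiseless channel the filter tails
    # of a crackle must not remain supra-threshold indefinitely
    floor = 2e-4 * float(np.max(np.abs(bp)), )
    return np.maximum(bg, max(floor, 1e-12))


def detect_crackles(
    signal: np.ndarray,
    sample_rate: float,
    segments: list[BreathSegment],
    config: DetectorConfig | None = None,
    channel: int = 0,
) -> list[CrackleEvent]:
    """Detect crackle transients on one channel.

    Every returned event lies inside a full breath, events are separated by
    at least the configured dead time, and each event carries a window of
    the (60 Hz high-passed) signal centred on its highest |deflection| and
    truncated at the breath boundaries.  An empty list is a valid result.
    """
    cfg = config or DetectorConfig()
    if not segments:
        return []
    x = np.asarray(signal, dtype=float)
    fs = sample_rate
    sos_hp = butter(2, cfg.hp_cutoff, btype="highpass", fs=fs, output="sos")
    hp = sosfiltfilt(sos_hp, x)
    # causal band-pass for scoring: zero-phase filtering would pre-ring
    # ahead of the transient and defeat the rise-time criterion
    sos_bp = butter(4, cfg.band, btype="bandpass", fs=fs, output="sos")
    bp = sosfilt(sos_bp, x)
    bg = _robust_trailing_background(bp, fs, cfg)
    score = np.abs(bp) / bg

    above = score > cfg.threshold
    if not above.any():
        return []
    dead = int(cfg.dead_time_ms / 1000.0 * fs)
    max_rise = int(cfg.max_rise_ms / 1000.0 * fs)
    half_win = int(cfg.window_ms / 2000.0 * fs)
    abs_hp = np.abs(hp)

    # non-maximum suppression: take supra-threshold samples in decreasing
    # |amplitude| order, each claiming a dead-time neighbourhood
    cand = np.nonzero(above)[0]
    order = cand[np.argsort(-abs_hp[cand], kind="stable")]
    taken = np.zeros(x.size, dtype=bool)
    peaks = []
    for i in order:
        if taken[i]:
            continue
        peaks.append(int(i))
        taken[max(i - dead, 0): i + dead + 1] = True

    # short running-max envelope: |hp| touches zero at every baseline
    # crossing, so onsets must be judged on the envelope instead
    env = maximum_filter1d(abs_hp, size=2 * max(int(0.001 * fs), 1) + 1)

    events: list[CrackleEvent] = []
    for peak in sorted(peaks):
        amp = abs_hp[peak]
        # local onset: the transient must emerge from below 35% of its peak
        # within the rise limit (ring tails of a preceding crackle never do)
        lo = max(peak - 5 * max_rise, 0)
        quiet = np.nonzero(env[lo:peak] < 0.35 * amp)[0]
        if quiet.size == 0:
            continue
        onset = lo + int(quiet[-1])
        if peak - onset > max_rise:
            continue  # slow rise: not an explosive transient
        t_peak = peak / fs
        seg = next((s for s in segments if s.contains(t_peak)), None)
        if seg is None:
            continue  # outside any full breath
        w_lo = max(peak - half_win, int(seg.insp_start * fs))
        w_hi = min(peak + half_win, int(seg.exp_end * fs), x.size)
        events.append(CrackleEvent(
            channel=channel,
            onset_time=onset / fs,
            peak_time=t_peak,
            waveform=hp[w_lo:w_hi].copy(),
            peak_amplitude=float(amp),
            breath_index=seg.breath_index,
            timing_code=seg.timing_code(t_peak),
        ))
    events.sort(key=lambda e: e.onset_time)
    return events
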