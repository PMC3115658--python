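"""Half-period decomposition of crackle waveforms and per-crackle features.

The crackle waveform is decomposed at its baseline crossings.  The
half-period containing the highest |deflection| is T1 (its amplitude is
A1); subsequent half-periods T2, T3, ... are enumerated rightward until the
per-half-period amplitude falls below a floor (default 10% of the highest
peak) or the window ends.  From the decomposition the standard per-crackle
features are computed:

====================  =====================================================
zxs                   baseline crossings spanned by the retained
                      half-periods (n half-periods -> n + 1 crossings)
t1                    first half-period, ms
pitch                 2000 / (T1+T2+T3+T4) Hz, durations in ms
t2_over_t1            T2 / T1
duration_variability  SD(T1..Tn) x 100 / mean(T1..Tn), %
timing                1-6 phase-third code (assigned by the detector)
ctc                   crackle transmission coefficient, % (filled in by the
                      family stage; unset here)
amplitude             A1, arbitrary units
a2_over_a1, a3_over_a1
amplitude_variability SD(A1..An) x 100 / mean(A1..An), %
polarity              +1 if the highest peak is upward, -1 if downward
====================  =====================================================

Variabilities use the sample standard deviation (ddof=1).  Pitch is
computed from the half-period durations themselves, not from a spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "HalfPeriodDecomposition",
    "CrackleFeatures",
    "DecompositionError",
    "decompose_half_periods",
    "compute_features",
    "patient_feature_summary",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "zxs", "t1", "pitch", "t2_over_t1", "duration_variability", "timing",
    "ctc", "amplitude", "a2_over_a1", "a3_over_a1", "amplitude_variability",
    "polarity",
]


class DecompositionError(ValueError):
    """Raised when a window cannot be decomposed into >= 4 half-periods."""


@dataclass
class HalfPeriodDecomposition:
    """Half-periods retained around the highest peak.

    ``T``/``A`` hold the rightward enumeration T1, T2, ... (T1 contains the
    highest peak, so A1 is its amplitude); ``n_left`` counts additional
    half-periods above the floor to the *left* of T1.  Those contribute to
    the crossing count ``zxs`` but not to the duration features, which by
    definition read rightward from T1.
    """

    T: np.ndarray
    A: np.ndarray
    peak_sign: int
    n: int
    n_left: int = 0

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.n + self.n_left < 4:
            raise DecompositionError(
                f"need >= 4 half-periods, got {self.n + self.n_left}")
        if np.any(self.T <= 0) or np.any(self.A <= 0):
            raise DecompositionError("half-period durations and amplitudes "
                                     "must be positive")

    @property
    def zxs(self) -> int:
        """Baseline crossings bounding the retained half-periods."""
        return self.n + self.n_left + 1


@dataclass
class CrackleFeatures:
    zxs: int
    t1: float
    pitch: float
    t2_over_t1: float
    duration_variability: float
    timing: int
    amplitude: float
    a2_over_a1: float
    a3_over_a1: float
    amplitude_variability: float
    polarity: int
    ctc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _crossing_times(w: np.ndarray) -> np.ndarray:
    """Baseline-crossing positions (fractional sample indices).

    Crossings between samples of opposite sign are linearly interpolated;
    runs of exact zeros count once, at the run centre (or at the run edge
    when the run touches the array boundary).
    """
    s = np.sign(w)
    nz = np.nonzero(s)[0]
    if nz.size < 2:
        return np.zeros(0)
    times = []
    # leading zero run followed by signal: baseline departure point
    if nz[0] > 0:
        times.append(float(nz[0] - 1))
    prev = nz[0]
    for i in nz[1:]:
        if s[i] != s[prev]:
            if i == prev + 1:
                t = prev + w[prev] / (w[prev] - w[i])
            else:  # separated by a zero run
                t = 0.5 * (prev + i)
            times.append(float(t))
        prev = i
    if nz[-1] < w.size - 1:
        times.append(float(nz[-1] + 1))
    return np.asarray(times)


def _segment_amplitude(w: np.ndarray, c0: float, c1: float) -> tuple[float, int]:
    """Peak |amplitude| of the half-period between crossings c0 and c1.

    The discrete maximum is refined by a three-point parabolic fit so that
    half-periods sampled by only a few points still report their true crest
    (needed to compare the amplitudes of nearly-equal half-periods).
    Returns (amplitude, index of the discrete maximum).
    """
    i0, i1 = int(np.ceil(c0 - 1e-9)), int(np.floor(c1 + 1e-9)) + 1
    i0, i1 = max(i0, 0), min(i1, w.size)
    if i1 <= i0:
        mid = min(max(int(round(0.5 * (c0 + c1))), 0), w.size - 1)
        return float(abs(w[mid])), mid
    seg = np.abs(w[i0:i1])
    j = int(np.argmax(seg))
    amp = float(seg[j])
    if 0 < j < seg.size - 1:
        y0, y1, y2 = seg[j - 1], seg[j], seg[j + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < -1e-12:
            amp = float(y1 - (y0 - y2) ** 2 / (8.0 * denom))
    return amp, i0 + j


def decompose_half_periods(
    waveform: np.ndarray,
    sample_rate: float,
    amplitude_floor: float = 0.10,
    detrend: bool = True,
) -> HalfPeriodDecomposition:
    """Decompose a crackle window into half-periods around its highest peak.

    The window is (optionally) mean-detrended, its baseline crossings are
    located by linear interpolation, and per-half-period amplitudes are
    measured.  T1 is the half-period carrying the highest peak (the
    leftmost one when several are equal within sampling accuracy);
    enumeration proceeds rightward until a half-period's amplitude falls
    below ``amplitude_floor`` times the highest peak or the window ends.
    Half-periods above the floor to the left of T1 are counted toward the
    crossing total.

    Raises
    ------
    DecompositionError
        If fewer than 4 half-periods remain above the floor.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 8:
        raise DecompositionError("window too short")
    if detrend:
        # a plain mean is biased by the crackle's own (sign-asymmetric)
        # lobes; the median tracks the true baseline far more closely
        w = w - np.median(w)
    crossings = _crossing_times(w)
    if crossings.size < 2:
        raise DecompositionError("fewer than two baseline crossings")
    # window edges bound the first/last half-periods when the signal starts
    # or ends off-baseline (edge durations are then window-truncated)
    if crossings[0] > 0.75:
        crossings = np.concatenate([[0.0], crossings])
    if crossings[-1] < w.size - 1.75:
        crossings = np.concatenate([crossings, [float(w.size - 1)]])
    n_seg = crossings.size - 1
    amps = np.empty(n_seg)
    peak_idx = np.empty(n_seg, dtype=int)
    for k in range(n_seg):
        amps[k], peak_idx[k] = _segment_amplitude(w, crossings[k], crossings[k + 1])
    a1 = float(amps.max())
    if a1 <= 0:
        raise DecompositionError("flat window")
    # leftmost half-period within sampling accuracy of the maximum
    left = int(np.nonzero(amps >= (1.0 - 0.01) * a1)[0][0])

    T, A = [], []
    for k in range(left, n_seg):
        if amps[k] < amplitude_floor * a1 and k > left:
            break
        T.append((crossings[k + 1] - crossings[k]) / sample_rate * 1000.0)
        A.append(amps[k])
    # half-periods left of T1 extend the crackle's crossing count only
    n_left = 0
    for k in range(left - 1, -1, -1):
        if amps[k] < amplitude_floor * a1:
            break
        n_left += 1
    if len(T) + n_left < 4:
        raise DecompositionError(
            f"only {len(T) + n_left} half-periods above the amplitude floor")
    return HalfPeriodDecomposition(
        T=np.asarray(T), A=np.asarray(A),
        peak_sign=int(np.sign(w[peak_idx[left]])), n=len(T), n_left=n_left,
    )


def compute_features(d: HalfPeriodDecomposition, timing_code: int) -> CrackleFeatures:
    """Per-crackle features from a half-period decomposition.

    ``pitch = 2000 / (T1+T2+T3+T4)`` for durations in ms; ``zxs`` counts the
    baseline crossings bounding the retained half-periods (n + 1);
    variabilities are sample-SD x 100 / mean.  The transmission coefficient
    is left unset (the family stage fills it in).
    """
    if d.n < 4:
        raise DecompositionError(
            "pitch needs four half-periods rightward of the peak")
    T, A = d.T, d.A
    return CrackleFeatures(
        zxs=d.zxs,
        t1=float(T[0]),
        pitch=2000.0 / float(T[:4].sum()),
        t2_over_t1=float(T[1] / T[0]),
        duration_variability=float(np.std(T, ddof=1) / np.mean(T) * 100.0),
        timing=int(timing_code),
        amplitude=float(A[0]),
        a2_over_a1=float(A[1] / A[0]),
        a3_over_a1=float(A[2] / A[0]),
        amplitude_variability=float(np.std(A, ddof=1) / np.mean(A) * 100.0),
        polarity=d.peak_sign,
    )


def patient_feature_summary(
    features: pd.DataFrame,
    n_breaths: int,
    phase: str | None = None,
) -> pd.DataFrame:
    """Per-patient summary: median and mean of each feature per phase, plus
    the crackle rate (crackles per full breath).

    ``features`` must carry one row per crackle with the feature columns and
    a ``phase`` column.  Phases with no crackles are flagged missing (NaN
    summaries) rather than zero; the crackle *rate* for an absent phase is
    genuinely 0.

    Returns a frame indexed by phase with ``<feature>`` (median),
    ``<feature>_mean``, ``crackle_rate``, ``n_crackles`` and ``missing``.
    """
    if n_breaths < 1:
        raise ValueError("n_breaths must be >= 1")
    phases = [phase] if phase else ["inspiration", "expiration"]
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    rows = {}
    for ph in phases:
        sub = features[features["phase"] == ph] if len(features) else features
        if len(sub) == 0:
            row = {c: np.nan for c in cols}
            row.update({f"{c}_mean": np.nan for c in cols})
            row.update({"crackle_rate": 0.0, "n_crackles": 0, "missing": True})
        else:
            row = {c: float(sub[c].median()) for c in cols}
            row.update({f"{c}_mean": float(sub[c].mean()) for c in cols})
            row.update({
                "crackle_rate": len(sub) / n_breaths,
                "n_crackles": len(sub),
                "missing": False,
            })
        rows[ph] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "phase"
    return out
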