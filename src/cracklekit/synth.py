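"""Synthetic multichannel lung-sound recordings with ground-truth crackles.

The generator produces seeded, fully annotated recordings so that every
downstream stage (detection, waveform decomposition, crackle families,
classification) can be validated without real patient data.

Model
-----
A crackle is rendered as a train of half-sine segments with alternating
sign: the k-th half-period has duration ``T_k`` and amplitude ``A_k``.  The
first half-period (duration ``T1``) carries the highest peak, subsequent
durations grow by the ``T2/T1`` ratio, and amplitudes follow a geometric
decay.  This makes the half-period decomposition performed by
:mod:`cracklekit.crackle_features` exactly invertible: pitch is
``2/(T1+T2+T3+T4)`` by construction.

A recording contains ``n_breaths`` breaths (inspiration then expiration,
with known phase boundaries), a low-frequency breath-sound component whose
envelope follows the phases, white background noise, and crackles placed at
3-D source locations drawn from the profile's spatial pattern.  Each crackle
is projected onto the microphones of its side: the nearest ipsilateral
microphone records the mother crackle, and further ipsilateral microphones
receive delayed, attenuated copies whose amplitude ratios are allocated so
that the *expected measured* crackle transmission coefficient equals the
profile's transmission level.

Patient-to-patient variation is modelled explicitly: each synthetic patient
draws latent means (rates, pitch, half-period count, transmission, polarity
fraction, amplitude scale) from the profile's between-patient distributions,
and individual crackles scatter around those latent means.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .profiles import ChannelGeometry, DiseaseProfile, QUADRANTS

__all__ = [
    "SynthConfig",
    "PatientParams",
    "ChannelHit",
    "TrueCrackle",
    "BreathTruth",
    "GroundTruthAnnotation",
    "half_period_schedule",
    "render_crackle",
    "synthesize_crackle",
    "sample_patient",
    "synthesize_recording",
]


@dataclass(frozen=True)
class SynthConfig:
    """Tunable constants of the recording synthesizer (all optional)."""

    sample_rate: int = 8000          # Hz
    insp_fraction: float = 0.45      # inspiratory share of the breath cycle
    breath_sound_rms: float = 0.18   # in-phase RMS of the breath-sound component
    breath_band: tuple[float, float] = (40.0, 250.0)  # Hz
    exp_gain: float = 0.55           # expiratory breath-sound gain vs inspiratory
    timing_frac_mean: float = 0.55   # crackle position within its phase
    timing_frac_sd: float = 0.18
    duration_jitter_sd: float = 0.30   # multiplicative half-period jitter
    amplitude_jitter_sd: float = 0.08
    pitch_within_cv: float = 0.12    # within-patient pitch scatter
    n_within_sd: float = 1.0         # within-patient half-period-count scatter
    amp_between_sigma: float = 0.6   # log-amplitude between-patient sigma
    amp_within_sigma: float = 0.45   # log-amplitude within-patient sigma
    min_amplitude: float = 3.0       # mother peak floor, arbitrary units
    max_amplitude: float = 60.0
    min_child_ratio: float = 0.5     # weakest audible child / mother ratio
    max_child_ratio: float = 0.95
    family_ctc_sd: float = 0.04      # per-family scatter of the CTC target
    focal_sigma_cm: float = 2.0      # source spread within the focal region


# ----------------------------------------------------------------------
# crackle waveform

def half_period_schedule(
    pitch: float, n_half_periods: int, t2_over_t1: float, amplitude_decay: float
) -> tuple[np.ndarray, np.ndarray]:
    """Nominal half-period durations (ms) and relative amplitudes.

    ``T1 = 2000 / (pitch * (1 + 3*t2_over_t1))`` so that
    ``pitch = 2000 / (T1+T2+T3+T4)`` with the later half-periods equal to
    ``t2_over_t1 * T1``.  Amplitudes decay geometrically from 1.
    """
    t1 = 2000.0 / (pitch * (1.0 + 3.0 * t2_over_t1))
    durations = np.full(n_half_periods, t2_over_t1 * t1)
    durations[0] = t1
    amplitudes = amplitude_decay ** np.arange(n_half_periods, dtype=float)
    return durations, amplitudes


def render_crackle(
    durations_ms: np.ndarray,
    amplitudes: np.ndarray,
    polarity: int,
    sample_rate: float,
    t_offset_s: float = 0.0,
) -> np.ndarray:
    """Sample a half-sine crackle on the sampling grid.

    ``t_offset_s`` shifts the grid relative to the waveform onset (used to
    place crackles at sub-sample onset times inside a recording).
    """
    durations_ms = np.asarray(durations_ms, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if durations_ms.ndim != 1 or durations_ms.size != amplitudes.size:
        raise ValueError("durations and amplitudes must be 1-D and equal length")
    if np.any(durations_ms <= 0):
        raise ValueError("half-period durations must be positive")
    bounds = np.concatenate([[0.0], np.cumsum(durations_ms)])
    total_ms = bounds[-1]
    n_samp = int(np.floor((total_ms / 1000.0 - t_offset_s) * sample_rate - 1e-9)) + 1
    if n_samp < 1:
        return np.zeros(0)
    t_ms = (np.arange(n_samp) / sample_rate + t_offset_s) * 1000.0
    seg = np.clip(np.searchsorted(bounds, t_ms, side="right") - 1, 0, durations_ms.size - 1)
    u = (t_ms - bounds[seg]) / durations_ms[seg]
    signs = polarity * (-1.0) ** np.arange(durations_ms.size)
    return signs[seg] * amplitudes[seg] * np.sin(np.pi * u)


def synthesize_crackle(
    pitch: float,
    n_half_periods: int,
    t2_over_t1: float,
    amplitude_decay: float,
    polarity: int,
    sample_rate: float,
) -> np.ndarray:
    """Render a single noiseless crackle waveform window.

    Parameters mirror the per-crackle features: the first four half-periods
    satisfy ``pitch = 2/(T1+T2+T3+T4)``, ``T2/T1`` equals the requested
    ratio, and half-period amplitudes decay geometrically.  ``polarity``
    sets the sign of the highest peak (+1 upward, -1 downward).
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if n_half_periods < 4:
        raise ValueError("a crackle needs at least 4 half-periods")
    if not 0.0 < amplitude_decay <= 1.0:
        raise ValueError("amplitude_decay must be in (0, 1]")
    if polarity not in (-1, 1):
        raise ValueError("polarity must be +1 or -1")
    if sample_rate < 8.0 * pitch:
        raise ValueError(
            f"sample_rate {sample_rate} Hz too low to resolve half-periods of a "
            f"{pitch} Hz crackle (need >= {8.0 * pitch:.0f} Hz)"
        )
    durations, amplitudes = half_period_schedule(
        pitch, n_half_periods, t2_over_t1, amplitude_decay
    )
    return render_crackle(durations, amplitudes, polarity, sample_rate)


# ----------------------------------------------------------------------
# ground-truth annotation containers

@dataclass
class ChannelHit:
    """One crackle as received on one channel."""
    channel: int
    onset_ms: float
    peak_ms: float
    amplitude: float


@dataclass
class TrueCrackle:
    index: int
    breath_index: int
    phase: str                      # "inspiration" | "expiration"
    timing_code: int                # 1..6
    source: tuple[float, float, float]   # cm
    pitch_hz: float                 # realized 2000 / sum(T1..T4)
    t1_ms: float
    n_half_periods: int
    polarity: int
    mother_channel: int
    ctc_target: float               # expected measured CTC, %
    channels: dict[int, ChannelHit] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = {str(k): asdict(v) for k, v in self.channels.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrueCrackle":
        channels = {int(k): ChannelHit(**v) for k, v in d.pop("channels").items()}
        d["source"] = tuple(d["source"])
        return cls(channels=channels, **d)


@dataclass
class BreathTruth:
    breath_index: int
    insp_start: float   # s
    insp_end: float
    exp_end: float


@dataclass
class GroundTruthAnnotation:
    sample_rate: int
    duration: float
    breaths: list[BreathTruth]
    crackles: list[TrueCrackle]
    focal_quadrant: str | None = None

    def breath_boundaries(self) -> list[tuple[float, float, float]]:
        return [(b.insp_start, b.insp_end, b.exp_end) for b in self.breaths]

    def hits_on_channel(self, channel: int) -> list[tuple[TrueCrackle, ChannelHit]]:
        out = []
        for c in self.crackles:
            if channel in c.channels:
                out.append((c, c.channels[channel]))
        return out

    def to_json_lines(self, path) -> None:
        """One JSON record per crackle, preceded by a header record."""
        with open(path, "w") as fh:
            header = {
                "record": "header",
                "sample_rate": self.sample_rate,
                "duration": self.duration,
                "focal_quadrant": self.focal_quadrant,
                "breaths": [asdict(b) for b in self.breaths],
            }
            fh.write(json.dumps(header) + "\n")
            for c in self.crackles:
                fh.write(json.dumps({"record": "crackle", **c.to_dict()}) + "\n")

    @classmethod
    def from_json_lines(cls, path) -> "GroundTruthAnnotation":
        breaths: list[BreathTruth] = []
        crackles: list[TrueCrackle] = []
        header = None
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                kind = d.pop("record")
                if kind == "header":
                    header = d
                    breaths = [BreathTruth(**b) for b in d.pop("breaths")]
                else:
                    crackles.append(TrueCrackle.from_dict(d))
        if header is None:
            raise ValueError("annotation file has no header record")
        return cls(
            sample_rate=int(header["sample_rate"]),
            duration=float(header["duration"]),
            breaths=breaths,
            crackles=crackles,
            focal_quadrant=header.get("focal_quadrant"),
        )


# ----------------------------------------------------------------------
# patient-level latent parameters

@dataclass(frozen=True)
class PatientParams:
    """Latent per-patient means drawn from a :class:`DiseaseProfile`."""

    profile_name: str
    insp_rate: float
    exp_rate: float
    pitch: float
    t2_over_t1: float
    n_half_periods: float
    amplitude_decay: float
    positive_polarity_fraction: float
    transmission: float
    log_amplitude: float


def sample_patient(profile: DiseaseProfile, rng: np.random.Generator) -> PatientParams:
    """Draw one patient's latent means from the profile's between-patient
    distributions.  Rates are censored at zero; bounded quantities are
    clipped to their physical ranges."""
    cv = profile.amplitude_sd / profile.amplitude_mean
    sigma_ln = math.sqrt(math.log(1.0 + cv * cv))
    log_median = math.log(profile.amplitude_mean) - 0.5 * sigma_ln * sigma_ln
    return PatientParams(
        profile_name=profile.name,
        insp_rate=max(0.0, rng.normal(profile.insp_crackle_rate_mean,
                                      profile.insp_crackle_rate_sd)),
        exp_rate=max(0.0, rng.normal(profile.exp_crackle_rate_mean,
                                     profile.exp_crackle_rate_sd)),
        pitch=float(np.clip(rng.normal(profile.pitch_mean, profile.pitch_sd),
                            120.0, 850.0)),
        t2_over_t1=float(np.clip(rng.normal(profile.t2_over_t1, 0.05), 1.0, 2.0)),
        n_half_periods=float(np.clip(
            rng.normal(profile.n_half_periods_mean, profile.n_half_periods_sd),
            4.0, 12.0)),
        amplitude_decay=float(np.clip(rng.normal(profile.amplitude_decay, 0.03),
                                      0.35, 0.90)),
        positive_polarity_fraction=float(np.clip(
            rng.normal(profile.positive_polarity_fraction,
                       profile.positive_polarity_sd), 0.05, 0.95)),
        transmission=float(np.clip(
            rng.normal(profile.transmission_level, profile.transmission_sd),
            0.0, 0.85)),
        log_amplitude=float(rng.normal(log_median, 0.6)),
    )


# ----------------------------------------------------------------------
# source locations

def _lung_box(geometry: ChannelGeometry) -> dict:
    """Lung volume model derived from the microphone bounding box."""
    pos = geometry.positions
    x_out = float(np.abs(pos[:, 0]).max()) + 2.0
    return {
        "x_inner": 1.0,
        "x_outer": x_out,
        "y": (float(pos[:, 1].min()) + 2.0, float(pos[:, 1].max()) - 2.0),
        "z": (max(float(pos[:, 2].min()) - 1.0, 0.0), float(pos[:, 2].max()) + 3.0),
        "z_split": 14.0,
    }


def _sample_source(pattern: str, box: dict, rng: np.random.Generator,
                   focal_region: dict | None, sigma: float) -> np.ndarray:
    if pattern == "focal":
        assert focal_region is not None
        lo = np.array([focal_region["x"][0], focal_region["y"][0], focal_region["z"][0]])
        hi = np.array([focal_region["x"][1], focal_region["y"][1], focal_region["z"][1]])
        center = np.asarray(focal_region["center"])
        return np.clip(center + rng.normal(0.0, sigma, 3), lo, hi)
    side = -1.0 if rng.random() < 0.5 else 1.0
    x = side * rng.uniform(box["x_inner"], box["x_outer"])
    y = rng.uniform(*box["y"])
    z_lo, z_hi = box["z"]
    if pattern == "basal":
        # linear density, twice as dense at the bottom as at the top:
        # f(u) = (2 - u)/1.5 for u in [0, 1] measured upward from the base
        u = 2.0 - math.sqrt(4.0 - 3.0 * rng.random())
        z = z_lo + u * (z_hi - z_lo)
    else:
        z = rng.uniform(z_lo, z_hi)
    return np.array([x, y, z])


def _pick_focal_region(box: dict, rng: np.random.Generator) -> tuple[dict, str]:
    side = "left" if rng.random() < 0.5 else "right"
    vert = "bottom" if rng.random() < 0.7 else "top"   # lower-lobe bias
    sign = -1.0 if side == "left" else 1.0
    xr = sorted((sign * box["x_inner"], sign * box["x_outer"]))
    zr = (box["z"][0], box["z_split"]) if vert == "bottom" else (box["z_split"], box["z"][1])
    region = {
        "x": tuple(xr),
        "y": box["y"],
        "z": zr,
    }
    margin = 1.5
    center = np.array([
        rng.uniform(region["x"][0] + margin, region["x"][1] - margin),
        rng.uniform(region["y"][0] + margin, region["y"][1] - margin),
        rng.uniform(region["z"][0] + margin, region["z"][1] - margin),
    ])
    region["center"] = center
    return region, f"{vert}-{side}"


# ----------------------------------------------------------------------
# child-channel amplitude allocation

def _allocate_children(
    ctc_target: float,
    ordered_channels: np.ndarray,
    rng: np.random.Generator,
    cfg: SynthConfig,
) -> dict[int, float]:
    """Assign child/mother amplitude ratios to ipsilateral channels.

    The per-family budget ``ctc_target * n_other`` (the sum of ratios the
    measured CTC formula will average) is distributed over channels nearest
    the source first.  Ratios below ``min_child_ratio`` would be inaudible
    to the detector, so the final fractional remainder is realized as one
    floor-ratio child with matching probability, which keeps the *expected*
    measured CTC equal to the target.
    """
    budget = ctc_target * len(ordered_channels)
    ratios: dict[int, float] = {}
    for ch in ordered_channels:
        if budget < 1e-12:
            break
        if budget >= cfg.min_child_ratio:
            r = min(cfg.max_child_ratio, budget)
            ratios[int(ch)] = r
            budget -= r
        else:
            if rng.random() < budget / cfg.min_child_ratio:
                ratios[int(ch)] = cfg.min_child_ratio
            budget = 0.0
    return ratios


# ----------------------------------------------------------------------
# recording synthesis

def _breath_schedule(duration: float, n_breaths: int, insp_fraction: float
                     ) -> list[BreathTruth]:
    cycle = duration / n_breaths
    out = []
    for b in range(n_breaths):
        start = b * cycle
        out.append(BreathTruth(
            breath_index=b,
            insp_start=start,
            insp_end=start + insp_fraction * cycle,
            exp_end=start + cycle,
        ))
    return out


def _timing_code(phase: str, frac: float) -> int:
    third = min(2, int(frac * 3.0))
    return (1 if phase == "inspiration" else 4) + third


def synthesize_recording(
    profile: DiseaseProfile,
    geometry: ChannelGeometry,
    duration: float = 20.0,
    n_breaths: int = 3,
    seed: int | np.random.Generator = 0,
    config: SynthConfig | None = None,
    patient: PatientParams | None = None,
) -> tuple[np.ndarray, GroundTruthAnnotation]:
    """Generate one multichannel recording plus its ground-truth annotation.

    Returns
    -------
    signal : ndarray, shape (n_channels, n_samples)
        Arbitrary-unit sound pressure, float64.
    annotation : GroundTruthAnnotation
        Breath boundaries and every inserted crackle (per-channel onsets,
        peak times and amplitudes, plus the generating parameters).
    """
    cfg = config or SynthConfig()
    if duration < 2.0 * n_breaths:
        raise ValueError("duration must allow at least 2 s per breath")
    for side in ("left", "right"):
        if len(geometry.channels_on_side(side)) < 2:
            raise ValueError(
                f"geometry needs >= 2 channels on the {side} side "
                "(CTC is undefined otherwise)"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = cfg.sample_rate
    n_samples = int(round(duration * fs))
    n_ch = geometry.n_channels

    if patient is None:
        patient = sample_patient(profile, rng)

    breaths = _breath_schedule(duration, n_breaths, cfg.insp_fraction)

    # --- background: white noise + phase-modulated breath sound
    signal = rng.normal(0.0, profile.noise_rms, size=(n_ch, n_samples))
    env = np.zeros(n_samples)
    for b in breaths:
        for (t0, t1, gain) in (
            (b.insp_start, b.insp_end, 1.0),
            (b.insp_end, b.exp_end, cfg.exp_gain),
        ):
            s0, s1 = int(t0 * fs), min(int(t1 * fs), n_samples)
            if s1 > s0:
                u = np.linspace(0.0, 1.0, s1 - s0, endpoint=False)
                env[s0:s1] = gain * np.sin(np.pi * u) ** 0.7
    sos = butter(4, cfg.breath_band, btype="bandpass", fs=fs, output="sos")
    for ch in range(n_ch):
        bnoise = sosfiltfilt(sos, rng.normal(0.0, 1.0, n_samples))
        bnoise /= max(np.sqrt(np.mean(bnoise**2)), 1e-12)
        signal[ch] += cfg.breath_sound_rms * env * bnoise

    # --- crackle sources
    box = _lung_box(geometry)
    focal_region = None
    focal_name = None
    if profile.spatial_pattern == "focal":
        focal_region, focal_name = _pick_focal_region(box, rng)

    crackles: list[TrueCrackle] = []
    index = 0
    for b in breaths:
        for phase, rate, (t0, t1) in (
            ("inspiration", patient.insp_rate, (b.insp_start, b.insp_end)),
            ("expiration", patient.exp_rate, (b.insp_end, b.exp_end)),
        ):
            count = rng.poisson(rate)
            phase_dur = t1 - t0
            for _ in range(count):
                src = _sample_source(profile.spatial_pattern, box, rng,
                                     focal_region, cfg.focal_sigma_cm)
                side = "left" if src[0] < 0 else "right"
                ipsi = geometry.channels_on_side(side)
                dists = np.linalg.norm(geometry.positions[ipsi] - src, axis=1)
                order = np.argsort(dists)
                mother = int(ipsi[order[0]])
                others = ipsi[order[1:]]

                # waveform parameters
                pitch_c = float(np.clip(
                    rng.normal(patient.pitch, cfg.pitch_within_cv * patient.pitch),
                    100.0, 0.1 * fs))
                n_c = int(np.clip(round(rng.normal(patient.n_half_periods,
                                                   cfg.n_within_sd)), 4, 14))
                durations, rel_amp = half_period_schedule(
                    pitch_c, n_c, patient.t2_over_t1, patient.amplitude_decay)
                durations = durations * np.clip(
                    rng.normal(1.0, cfg.duration_jitter_sd, n_c), 0.4, 2.0)
                rel_amp = rel_amp * np.clip(
                    rng.normal(1.0, cfg.amplitude_jitter_sd, n_c), 0.75, 1.25)
                rel_amp[1:] = np.minimum(rel_amp[1:], 0.97 * rel_amp[0])
                rel_amp /= rel_amp[0]
                polarity = 1 if rng.random() < patient.positive_polarity_fraction else -1
                amp = float(np.clip(math.exp(rng.normal(patient.log_amplitude,
                                                        cfg.amp_within_sigma)),
                                    cfg.min_amplitude, cfg.max_amplitude))
                total_ms = float(durations.sum())

                # timing: keep the whole waveform inside its phase
                frac_hi = min(0.90, 1.0 - (total_ms / 1000.0 + 0.005) / phase_dur)
                frac = float(np.clip(rng.normal(cfg.timing_frac_mean,
                                                cfg.timing_frac_sd), 0.03, frac_hi))
                emit_t = t0 + frac * phase_dur   # emission at the source

                # transmission: target CTC for this family and child ratios;
                # the family-to-family scatter shrinks with the level so a
                # zero-transmission profile emits on exactly one channel
                sd_fam = min(cfg.family_ctc_sd, patient.transmission)
                c_target = float(np.clip(rng.normal(patient.transmission,
                                                    sd_fam), 0.0, 0.88))
                ratios = _allocate_children(c_target, others, rng, cfg)

                n_other = len(ipsi) - 1
                hits: dict[int, ChannelHit] = {}
                d_m = dists[order[0]]
                for ch, ratio in [(mother, 1.0)] + list(ratios.items()):
                    d_ch = float(np.linalg.norm(geometry.positions[ch] - src))
                    onset_s = emit_t + (d_ch - d_m) / geometry.sound_speed / 1000.0
                    start = int(math.ceil(onset_s * fs - 1e-9))
                    t_off = start / fs - onset_s
                    w = render_crackle(durations, ratio * amp * rel_amp,
                                       polarity, fs, t_offset_s=t_off)
                    stop = min(start + w.size, n_samples)
                    if stop > start:
                        signal[ch, start:stop] += w[: stop - start]
                    hits[int(ch)] = ChannelHit(
                        channel=int(ch),
                        onset_ms=onset_s * 1000.0,
                        peak_ms=onset_s * 1000.0 + durations[0] / 2.0,
                        amplitude=ratio * amp,
                    )

                crackles.append(TrueCrackle(
                    index=index,
                    breath_index=b.breath_index,
                    phase=phase,
                    timing_code=_timing_code(phase, frac),
                    source=tuple(float(v) for v in src),
                    pitch_hz=2000.0 / float(durations[:4].sum()),
                    t1_ms=float(durations[0]),
                    n_half_periods=n_c,
                    polarity=polarity,
                    mother_channel=mother,
                    ctc_target=100.0 * sum(ratios.values()) / max(n_other, 1),
                    channels=hits,
                ))
                index += 1

    annotation = GroundTruthAnnotation(
        sample_rate=fs, duration=duration, breaths=breaths,
        crackles=crackles, focal_quadrant=focal_name,
    )
    return signal, annotation
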