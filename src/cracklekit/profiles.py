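"""Disease profiles and chest-surface microphone geometry.

A :class:`DiseaseProfile` holds the generative parameters of one diagnostic
group: crackle rates per breath phase, the waveform parameters (pitch, half
periods, amplitude decay, polarity), the target crackle transmission level,
and the spatial pattern of crackle sources over the lungs.  The built-in
profiles encode the published group statistics for interstitial pulmonary
fibrosis (IPF), congestive heart failure (CHF), and pneumonia (PN): IPF
crackles are numerous, high pitched, short (T1 ~1.2 ms), weakly transmitted
and uniformly distributed; CHF and PN crackles are lower pitched, longer and
more strongly transmitted, with CHF sources accentuated toward the lung
bases and PN sources confined to a single focal region.

A :class:`ChannelGeometry` describes the microphone array: per-channel 3-D
positions (cm), left/right side membership, chest quadrant assignment, and
the effective sound speed used for arrival-time modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "DiseaseProfile",
    "ChannelGeometry",
    "builtin_profile",
    "builtin_profile_names",
    "default_geometry",
    "SPATIAL_PATTERNS",
    "QUADRANTS",
]

SPATIAL_PATTERNS = ("uniform", "basal", "focal")
QUADRANTS = ("top-left", "top-right", "bottom-left", "bottom-right")
SIDES = ("left", "right")


@dataclass(frozen=True)
class DiseaseProfile:
    """Generative parameters of one diagnostic group.

    Rates and feature means/SDs describe *between-patient* variation; the
    synthesizer layers additional within-patient crackle-to-crackle scatter
    on top (see :mod:`cracklekit.synth`).

    Parameters
    ----------
    name
        Group label (``IPF``, ``CHF``, ``PN``, or a custom name).
    insp_crackle_rate_mean, insp_crackle_rate_sd
        Inspiratory crackles per breath, mean and between-patient SD.
    exp_crackle_rate_mean, exp_crackle_rate_sd
        Expiratory crackles per breath.
    pitch_mean, pitch_sd
        Crackle pitch in Hz (pitch = 2/(T1+T2+T3+T4) for half-periods in s).
    t1_mean, t1_sd
        Nominal first half-period in milliseconds.
    n_half_periods_mean, n_half_periods_sd
        Number of half-periods retained above the amplitude floor.
    t2_over_t1
        Ratio of the second (and later) half-period durations to the first.
    amplitude_decay
        Geometric per-half-period amplitude decay factor, in (0, 1).
    positive_polarity_fraction, positive_polarity_sd
        Proportion of crackles whose highest peak is upward.
    transmission_level, transmission_sd
        Target crackle transmission coefficient / 100, in [0, 1].
    amplitude_mean, amplitude_sd
        Peak amplitude of the mother crackle, arbitrary units.
    spatial_pattern
        ``uniform`` | ``basal`` | ``focal`` distribution of sources.
    noise_rms
        Background white-noise RMS, same arbitrary units as amplitude.
    """

    name: str
    insp_crackle_rate_mean: float
    insp_crackle_rate_sd: float
    exp_crackle_rate_mean: float
    exp_crackle_rate_sd: float
    pitch_mean: float
    pitch_sd: float
    t1_mean: float
    t1_sd: float
    n_half_periods_mean: float
    n_half_periods_sd: float
    t2_over_t1: float
    amplitude_decay: float
    positive_polarity_fraction: float
    positive_polarity_sd: float = 0.15
    transmission_level: float = 0.2
    transmission_sd: float = 0.06
    amplitude_mean: float = 9.0
    amplitude_sd: float = 9.0
    spatial_pattern: str = "uniform"
    noise_rms: float = 0.12

    def __post_init__(self) -> None:
        positive = {
            "insp_crackle_rate_mean": self.insp_crackle_rate_mean,
            "insp_crackle_rate_sd": self.insp_crackle_rate_sd,
            "exp_crackle_rate_mean": self.exp_crackle_rate_mean,
            "exp_crackle_rate_sd": self.exp_crackle_rate_sd,
            "pitch_mean": self.pitch_mean,
            "pitch_sd": self.pitch_sd,
            "t1_mean": self.t1_mean,
            "t1_sd": self.t1_sd,
            "n_half_periods_mean": self.n_half_periods_mean,
            "n_half_periods_sd": self.n_half_periods_sd,
            "t2_over_t1": self.t2_over_t1,
            "amplitude_mean": self.amplitude_mean,
            "amplitude_sd": self.amplitude_sd,
            "noise_rms": self.noise_rms,
        }
        for key, value in positive.items():
            if not value > 0:
                raise ValueError(f"{key} must be strictly positive, got {value}")
        for key, value in {
            "positive_polarity_fraction": self.positive_polarity_fraction,
            "transmission_level": self.transmission_level,
        }.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{key} must be in [0, 1], got {value}")
        if not 0.0 < self.amplitude_decay < 1.0:
            raise ValueError(
                f"amplitude_decay must be in (0, 1), got {self.amplitude_decay}"
            )
        if self.spatial_pattern not in SPATIAL_PATTERNS:
            raise ValueError(
                f"spatial_pattern must be one of {SPATIAL_PATTERNS}, "
                f"got {self.spatial_pattern!r}"
            )
        # pitch and T1 must be jointly consistent: the synthesizer derives
        # half-periods from pitch, and 2/(4*t1) should reproduce pitch_mean
        # to within 20%.
        implied = 2000.0 / (4.0 * self.t1_mean)
        if abs(implied - self.pitch_mean) > 0.20 * self.pitch_mean:
            raise ValueError(
                f"pitch_mean ({self.pitch_mean} Hz) and t1_mean ({self.t1_mean} ms) "
                f"are inconsistent: 2/(4*T1) = {implied:.1f} Hz deviates by more "
                "than 20%"
            )

    def replace(self, **kwargs) -> "DiseaseProfile":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DiseaseProfile":
        return cls(**d)


# Built-in group profiles ship as packaged YAML resources.
_BUILTINS_CACHE: dict[str, DiseaseProfile] | None = None


def _builtins() -> dict[str, DiseaseProfile]:
    global _BUILTINS_CACHE
    if _BUILTINS_CACHE is None:
        text = resources.files("cracklekit").joinpath("data/profiles.yaml").read_text()
        raw = yaml.safe_load(text)
        _BUILTINS_CACHE = {k: DiseaseProfile(**v) for k, v in raw.items()}
    return _BUILTINS_CACHE


def builtin_profile_names() -> tuple[str, ...]:
    return tuple(_builtins())


def builtin_profile(name: str) -> DiseaseProfile:
    """Return the built-in :class:`DiseaseProfile` for a diagnostic group.

    Raises
    ------
    KeyError
        If ``name`` is not one of the known groups; the message lists them.
    """
    key = name.upper()
    known = _builtins()
    if key not in known:
        raise KeyError(
            f"unknown disease profile {name!r}; known profiles: "
            f"{', '.join(known)}"
        )
    return known[key]


@dataclass
class ChannelGeometry:
    """Microphone array layout on a chest-surface model.

    Coordinates are centimetres: x left(-)/right(+), y back(-)/front(+),
    z caudal(0)/cranial.  ``sound_speed`` is in cm/ms.
    """

    positions: np.ndarray  # (n_channels, 3)
    side: tuple[str, ...]
    quadrant: tuple[str, ...]
    sound_speed: float = 3.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.side = tuple(self.side)
        self.quadrant = tuple(self.quadrant)
        n = self.positions.shape[0]
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_channels, 3)")
        if len(self.side) != n or len(self.quadrant) != n:
            raise ValueError("side and quadrant must have one entry per channel")
        for s in self.side:
            if s not in SIDES:
                raise ValueError(f"side labels must be in {SIDES}, got {s!r}")
        for q in self.quadrant:
            if q not in QUADRANTS:
                raise ValueError(f"quadrant labels must be in {QUADRANTS}, got {q!r}")
        if not self.sound_speed > 0:
            raise ValueError("sound_speed must be positive")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def channels_on_side(self, side: str) -> np.ndarray:
        """Indices of all channels on the given side."""
        return np.array([i for i, s in enumerate(self.side) if s == side], dtype=int)

    def ipsilateral(self, channel: int) -> np.ndarray:
        """Indices of all channels on the same side as ``channel`` (inclusive)."""
        return self.channels_on_side(self.side[channel])

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def to_dict(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "side": list(self.side),
            "quadrant": list(self.quadrant),
            "sound_speed": float(self.sound_speed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelGeometry":
        return cls(
            positions=np.asarray(d["positions"], dtype=float),
            side=tuple(d["side"]),
            quadrant=tuple(d["quadrant"]),
            sound_speed=float(d.get("sound_speed", 3.0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ChannelGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_geometry(sound_speed: float | None = None) -> ChannelGeometry:
    """The packaged 16-channel array: 14 posterior microphones (7 per side)
    plus one anterior microphone per side.  Posterior surface at y = -10 cm;
    quadrants split at z = 14 cm."""
    text = resources.files("cracklekit").joinpath("data/geometry.yaml").read_text()
    geom = ChannelGeometry.from_dict(yaml.safe_load(text))
    if sound_speed is not None:
        geom.sound_speed = float(sound_speed)
    return geom
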