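"""Per-breath aggregate crackle features.

These capture how a breath's crackles are distributed over the chest:
counts per quadrant, the six pairwise quadrant percentage differences, and
maximum inter-crackle distances per axis and overall, computed both on the
localized source positions and on the mother-microphone positions ("channel
distances").  A crackle's quadrant is that of its mother channel, so the
features degrade gracefully for single-channel families.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .family_ctc import CrackleFamily
from .profiles import ChannelGeometry, QUADRANTS

__all__ = ["BreathAggregate", "aggregate_breath", "QUADRANT_PAIRS"]

# fixed ordering of the 6 pairwise quadrant comparisons
QUADRANT_PAIRS = (
    ("top-left", "top-right"),
    ("top-left", "bottom-left"),
    ("top-left", "bottom-right"),
    ("top-right", "bottom-left"),
    ("top-right", "bottom-right"),
    ("bottom-left", "bottom-right"),
)


@dataclass
class BreathAggregate:
    breath_index: int
    crackles_per_breath: int
    quadrant_counts: dict[str, int]
    quadrant_pct_differences: dict[str, float]   # keyed "top-left|top-right" etc.
    max_distance_x: float
    max_distance_y: float
    max_distance_z: float
    max_distance_overall: float
    max_channel_distance_x: float
    max_channel_distance_y: float
    max_channel_distance_z: float
    max_channel_distance_overall: float

    def to_vector(self) -> np.ndarray:
        """Fixed-order numeric vector for breath-level classification."""
        return np.array(
            [self.crackles_per_breath]
            + [self.quadrant_counts[q] for q in QUADRANTS]
            + [self.quadrant_pct_differences[f"{a}|{b}"] for a, b in QUADRANT_PAIRS]
            + [self.max_distance_x, self.max_distance_y, self.max_distance_z,
               self.max_distance_overall,
               self.max_channel_distance_x, self.max_channel_distance_y,
               self.max_channel_distance_z, self.max_channel_distance_overall],
            dtype=float,
        )

    @staticmethod
    def vector_names() -> list[str]:
        return (
            ["crackles_per_breath"]
            + [f"n_{q}" for q in QUADRANTS]
            + [f"pctdiff_{a}|{b}" for a, b in QUADRANT_PAIRS]
            + ["max_distance_x", "max_distance_y", "max_distance_z",
               "max_distance_overall",
               "max_channel_distance_x", "max_channel_distance_y",
               "max_channel_distance_z", "max_channel_distance_overall"]
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _max_distances(points: np.ndarray) -> tuple[float, float, float, float]:
    if points.shape[0] < 2:
        return 0.0, 0.0, 0.0, 0.0
    per_axis = points.max(axis=0) - points.min(axis=0)
    diff = points[:, None, :] - points[None, :, :]
    overall = float(np.sqrt((diff ** 2).sum(axis=2)).max())
    return float(per_axis[0]), float(per_axis[1]), float(per_axis[2]), overall


def aggregate_breath(
    families: list[CrackleFamily],
    geometry: ChannelGeometry,
    breath_index: int = 0,
) -> BreathAggregate:
    """Aggregate the localized crackle families of one breath.

    Quadrant counts always sum to the breath total.  The pairwise quadrant
    percentage difference for quadrants (i, j) is
    ``100 * (n_i - n_j) / max(n_i + n_j, 1)``.  Zero crackles yield all-zero
    aggregates.  Every family must have a source location (run the
    localization stage first).
    """
    counts = {q: 0 for q in QUADRANTS}
    sources = []
    channels = []
    for fam in families:
        q = geometry.quadrant[fam.mother.channel]
        counts[q] += 1
        if fam.source_location is None:
            raise ValueError("family has no source location; localize first")
        sources.append(fam.source_location)
        channels.append(geometry.positions[fam.mother.channel])
    total = len(families)
    assert sum(counts.values()) == total  # conservation, checked every breath
    pct = {}
    for a, b in QUADRANT_PAIRS:
        na, nb = counts[a], counts[b]
        pct[f"{a}|{b}"] = 100.0 * (na - nb) / max(na + nb, 1)
    src = np.asarray(sources, dtype=float) if sources else np.zeros((0, 3))
    chn = np.asarray(channels, dtype=float) if channels else np.zeros((0, 3))
    dx, dy, dz, dall = _max_distances(src)
    cx, cy, cz, call_ = _max_distances(chn)
    return BreathAggregate(
        breath_index=breath_index,
        crackles_per_breath=total,
        quadrant_counts=counts,
        quadrant_pct_differences=pct,
        max_distance_x=dx, max_distance_y=dy, max_distance_z=dz,
        max_distance_overall=dall,
        max_channel_distance_x=cx, max_channel_distance_y=cy,
        max_channel_distance_z=cz, max_channel_distance_overall=call_,
    )
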