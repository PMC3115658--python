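"""Crackle families, the crackle transmission coefficient, and source
localization.

A single physical crackling event is often recorded by several microphones
on the same side of the chest; the set of simultaneous detections is a
*crackle family* and its largest-amplitude member the *mother crackle*
(recorded nearest the source, hence earliest).  The crackle transmission
coefficient (CTC) measures how strongly the sound reaches the other
ipsilateral microphones:

    CTC = 100 / (N - 1) * sum over the N-1 non-mother ipsilateral channels
          of min(A_c / A_mother, 1)

where ``A_c`` is the family member's peak amplitude on that channel (0 if
the channel recorded nothing).  CTC is 0% when no other channel detects the
event and 100% when every ipsilateral channel receives it at the mother's
amplitude.  The formula interpolates those published endpoints with the
mean amplitude ratio — the simplest monotone choice — and is used
consistently by the synthesizer, so it should be read as an approximation
of the original instrument's definition.

Sources are localized by multilateration on arrival-time differences:
delays relative to the mother are predicted as distance / sound_speed and
the squared delay residuals are minimized over candidate positions inside
the chest volume.  Families with fewer than 3 members fall back to the
mother microphone's position projected a default depth into the chest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .detection import CrackleEvent
from .profiles import ChannelGeometry

__all__ = ["CrackleFamily", "group_families", "compute_ctc", "localize_crackle"]


@dataclass
class CrackleFamily:
    mother: CrackleEvent
    children: list[CrackleEvent] = field(default_factory=list)
    ctc: float | None = None
    source_location: tuple[float, float, float] | None = None
    localization_fallback: bool = False
    flagged: bool = False   # CTC undefined (fewer than 2 ipsilateral channels)

    @property
    def members(self) -> list[CrackleEvent]:
        return [self.mother] + self.children

    @property
    def size(self) -> int:
        return 1 + len(self.children)


def group_families(
    events: list[CrackleEvent],
    geometry: ChannelGeometry,
    window_ms: float = 10.0,
) -> list[CrackleFamily]:
    """Greedy grouping of per-channel events into crackle families.

    Repeatedly takes the largest-amplitude unassigned event as a mother and
    attaches every unassigned ipsilateral event within ``+/- window_ms`` of
    its peak, at most one per channel (nearest in time wins).  Every event
    ends up in exactly one family.  Families are returned sorted by the
    mother's peak time.
    """
    window_s = window_ms / 1000.0
    unassigned = sorted(events, key=lambda e: -e.peak_amplitude)
    taken: set[int] = set()
    families: list[CrackleFamily] = []
    for mother in unassigned:
        if id(mother) in taken:
            continue
        taken.add(id(mother))
        ipsi = set(int(c) for c in geometry.ipsilateral(mother.channel))
        candidates: dict[int, CrackleEvent] = {}
        for ev in unassigned:
            if id(ev) in taken or ev.channel == mother.channel:
                continue
            if ev.channel not in ipsi:
                continue
            if abs(ev.peak_time - mother.peak_time) > window_s:
                continue
            best = candidates.get(ev.channel)
            if best is None or (abs(ev.peak_time - mother.peak_time)
                                < abs(best.peak_time - mother.peak_time)):
                candidates[ev.channel] = ev
        children = sorted(candidates.values(), key=lambda e: e.peak_time)
        for ch_ev in children:
            taken.add(id(ch_ev))
        families.append(CrackleFamily(mother=mother, children=children))
    families.sort(key=lambda f: f.mother.peak_time)
    return families


def compute_ctc(family: CrackleFamily, geometry: ChannelGeometry) -> float:
    """Crackle transmission coefficient of a family, in percent.

    Raises
    ------
    ValueError
        If the mother's side has fewer than 2 channels (the family is also
        flagged); the CTC is undefined in that case.
    """
    ipsi = geometry.ipsilateral(family.mother.channel)
    n = len(ipsi)
    if n < 2:
        family.flagged = True
        raise ValueError(
            "CTC undefined: fewer than 2 channels on the mother's side")
    a_mother = family.mother.peak_amplitude
    total = 0.0
    for child in family.children:
        total += min(child.peak_amplitude / a_mother, 1.0)
    ctc = 100.0 * total / (n - 1)
    family.ctc = float(np.clip(ctc, 0.0, 100.0))
    return family.ctc


def _fallback_position(family: CrackleFamily, geometry: ChannelGeometry,
                       depth_cm: float) -> np.ndarray:
    """Mother microphone position pushed ``depth_cm`` toward the chest
    interior (the direction of the array centroid)."""
    p = geometry.positions[family.mother.channel]
    inward = geometry.centroid() - p
    norm = np.linalg.norm(inward)
    if norm < 1e-9:
        return p.copy()
    return p + depth_cm * inward / norm


def localize_crackle(
    family: CrackleFamily,
    geometry: ChannelGeometry,
    default_depth_cm: float = 8.0,
    regularization: float = 0.02,
) -> tuple[float, float, float]:
    """Estimate the family's source position from arrival-time differences.

    With >= 3 members, minimizes the squared mismatch between observed
    peak-time delays (relative to the mother) and delays predicted as
    distance / sound_speed, within a box around the microphone array; a
    weak pull toward the fallback position regularizes the
    depth direction, which one or two delay differences cannot constrain.
    Smaller families get the fallback position directly and the family is
    marked accordingly.
    """
    x0 = _fallback_position(family, geometry, default_depth_cm)
    if family.size < 3:
        family.source_location = tuple(float(v) for v in x0)
        family.localization_fallback = True
        return family.source_location

    pos = geometry.positions
    v = geometry.sound_speed  # cm/ms
    p_m = pos[family.mother.channel]
    t_m = family.mother.peak_time
    obs = np.array([(c.peak_time - t_m) * 1000.0 for c in family.children])  # ms
    p_c = np.stack([pos[c.channel] for c in family.children])

    lo = pos.min(axis=0) - 5.0
    hi = pos.max(axis=0) + 5.0

    def residuals(x):
        d_m = np.linalg.norm(x - p_m)
        d_c = np.linalg.norm(p_c - x, axis=1)
        pred = (d_c - d_m) / v
        return np.concatenate([(obs - pred) * v,            # cm
                               regularization * (x - x0)])

    try:
        sol = least_squares(residuals, np.clip(x0, lo, hi), bounds=(lo, hi))
        ok = sol.success and np.all(np.isfinite(sol.x))
    except Exception:
        ok = False
    if not ok:
        family.source_location = tuple(float(v_) for v_ in x0)
        family.localization_fallback = True
        return family.source_location
    family.source_location = tuple(float(v_) for v_ in sol.x)
    family.localization_fallback = False
    return family.source_location
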