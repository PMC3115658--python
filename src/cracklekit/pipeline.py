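"""End-to-end analysis: recording -> detected crackles -> families/CTC ->
features -> per-breath aggregates -> per-patient summaries, plus synthetic
cohort construction for evaluation studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate_features import BreathAggregate, aggregate_breath
from .classification_eval import cross_validate  # noqa: F401  (re-export)
from .crackle_features import (DecompositionError, compute_features,
                               decompose_half_periods, patient_feature_summary,
                               FEATURE_COLUMNS)
from .detection import BreathSegment, DetectorConfig, detect_crackles, segment_breaths
from .family_ctc import CrackleFamily, compute_ctc, group_families, localize_crackle
from .profiles import ChannelGeometry, DiseaseProfile
from .synth import GroundTruthAnnotation, SynthConfig, synthesize_recording

__all__ = ["RecordingAnalysis", "analyze_recording", "build_cohort",
           "summarize_cohort"]


@dataclass
class RecordingAnalysis:
    """Everything the pipeline extracts from one multichannel recording."""

    segments: list[BreathSegment]
    events_per_channel: dict[int, list]
    families: list[CrackleFamily]
    crackles: pd.DataFrame          # one row per family (mother crackle)
    breaths: pd.DataFrame           # one row per full breath (aggregates)
    n_discarded: int = 0            # events failing the half-period floor


def analyze_recording(
    signal: np.ndarray,
    sample_rate: float,
    geometry: ChannelGeometry,
    breath_boundaries=None,
    detector: DetectorConfig | None = None,
    family_window_ms: float = 10.0,
) -> RecordingAnalysis:
    """Run detection, family grouping, CTC, localization, per-crackle
    features, and per-breath aggregates on one recording.

    ``signal`` is (n_channels, n_samples).  Breath boundaries may be given
    (synthetic mode) or are estimated from channel 0.  The per-crackle
    feature table contains one row per crackle *family*; the features are
    those of the mother crackle, with the family CTC filled in.
    """
    cfg = detector or DetectorConfig()
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.shape[0] != geometry.n_channels:
        raise ValueError(
            f"signal has {signal.shape[0]} channels but the geometry "
            f"defines {geometry.n_channels}")
    segments = segment_breaths(signal[0], sample_rate,
                               known_boundaries=breath_boundaries, config=cfg)
    events_per_channel = {}
    all_events = []
    for ch in range(signal.shape[0]):
        evs = detect_crackles(signal[ch], sample_rate, segments, cfg, channel=ch)
        events_per_channel[ch] = evs
        all_events.extend(evs)
    all_events.sort(key=lambda e: e.peak_time)

    families = group_families(all_events, geometry, window_ms=family_window_ms)
    rows = []
    discarded = 0
    kept_families = []
    for fam in families:
        try:
            ctc = compute_ctc(fam, geometry)
        except ValueError:
            discarded += 1
            continue
        localize_crackle(fam, geometry)
        try:
            d = decompose_half_periods(fam.mother.waveform, sample_rate)
            feats = compute_features(d, fam.mother.timing_code)
        except DecompositionError:
            discarded += 1
            continue
        feats.ctc = ctc
        row = feats.to_dict()
        row.update({
            "breath": fam.mother.breath_index,
            "phase": ("inspiration" if fam.mother.timing_code <= 3
                      else "expiration"),
            "channel": fam.mother.channel,
            "peak_time": fam.mother.peak_time,
            "family_size": fam.size,
            "x": fam.source_location[0],
            "y": fam.source_location[1],
            "z": fam.source_location[2],
        })
        rows.append(row)
        kept_families.append(fam)

    crackles = pd.DataFrame(rows)
    breath_rows = []
    for seg in segments:
        fams = [f for f in kept_families
                if f.mother.breath_index == seg.breath_index]
        agg = aggregate_breath(fams, geometry, breath_index=seg.breath_index)
        rec = dict(zip(BreathAggregate.vector_names(), agg.to_vector()))
        rec["breath"] = seg.breath_index
        breath_rows.append(rec)
    breaths = pd.DataFrame(breath_rows)
    return RecordingAnalysis(
        segments=segments, events_per_channel=events_per_channel,
        families=kept_families, crackles=crackles, breaths=breaths,
        n_discarded=discarded,
    )


def build_cohort(
    groups: dict[str, tuple[DiseaseProfile, int]],
    geometry: ChannelGeometry,
    seed: int = 0,
    duration: float = 20.0,
    n_breaths: int = 3,
    synth: SynthConfig | None = None,
    detector: DetectorConfig | None = None,
    use_true_boundaries: bool = True,
    audio_dir=None,
) -> dict[str, pd.DataFrame]:
    """Synthesize and analyze a cohort: one recording per patient.

    ``groups`` maps a group label to (profile, n_patients).  Per-patient
    seeds are spawned deterministically from ``seed``.  Returns the pooled
    ``crackles``, ``breaths`` and per-patient ``summaries`` tables (each
    carrying ``patient`` and ``group`` columns).  When ``audio_dir`` is
    given, every recording is also written there as WAV plus a JSON-lines
    annotation.
    """
    scfg = synth or SynthConfig()
    root = np.random.SeedSequence(seed)
    crackle_frames, breath_frames, summary_frames = [], [], []
    for gname, (profile, n_patients) in groups.items():
        child_seeds = root.spawn(n_patients)
        for i, ss in enumerate(child_seeds):
            pid = f"{gname}-{i:03d}"
            rng = np.random.default_rng(ss)
            sigs, ann = synthesize_recording(
                profile, geometry, duration=duration, n_breaths=n_breaths,
                seed=rng, config=scfg)
            if audio_dir is not None:
                from pathlib import Path
                from .io import write_wav
                adir = Path(audio_dir)
                adir.mkdir(parents=True, exist_ok=True)
                write_wav(adir / f"{pid}.wav", sigs, scfg.sample_rate)
                ann.to_json_lines(adir / f"{pid}.annotation.jsonl")
            res = analyze_recording(
                sigs, scfg.sample_rate, geometry,
                breath_boundaries=ann.breath_boundaries() if use_true_boundaries
                else None,
                detector=detector)
            ck = res.crackles.assign(patient=pid, group=gname)
            bt = res.breaths.assign(patient=pid, group=gname)
            crackle_frames.append(ck)
            breath_frames.append(bt)
            if len(res.crackles):
                summ = patient_feature_summary(res.crackles, n_breaths=n_breaths)
            else:
                summ = patient_feature_summary(
                    pd.DataFrame(columns=FEATURE_COLUMNS + ["phase"]),
                    n_breaths=n_breaths)
            summ = summ.reset_index().assign(patient=pid, group=gname)
            summary_frames.append(summ)
    crackles = pd.concat([f for f in crackle_frames if len(f)], ignore_index=True)
    breaths = pd.concat(breath_frames, ignore_index=True)
    summaries = pd.concat(summary_frames, ignore_index=True)
    return {"crackles": crackles, "breaths": breaths, "summaries": summaries}


def summarize_cohort(crackles: pd.DataFrame, n_breaths: int) -> pd.DataFrame:
    """Per-patient feature summaries (medians) from a pooled crackle table."""
    frames = []
    for (pid, grp), g in crackles.groupby(["patient", "group"]):
        s = patient_feature_summary(g, n_breaths=n_breaths)
        frames.append(s.reset_index().assign(patient=pid, group=grp))
    return pd.concat(frames, ignore_index=True)
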