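"""File I/O: multichannel WAV, event tables, family tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .detection import CrackleEvent
from .family_ctc import CrackleFamily

__all__ = [
    "write_wav", "read_wav",
    "events_to_frame", "events_from_frame",
    "families_to_frame",
]


def write_wav(path, signal: np.ndarray, sample_rate: int) -> None:
    """Write a (n_channels, n_samples) float signal as float32 WAV."""
    data = np.asarray(signal, dtype=np.float32)
    if data.ndim == 1:
        data = data[None, :]
    wavfile.write(path, int(sample_rate), data.T.copy())


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a WAV file; returns ((n_channels, n_samples) float64, rate).

    Integer PCM is rescaled to [-1, 1); float data is passed through.
    """
    rate, data = wavfile.read(path)
    data = np.atleast_2d(data.T if data.ndim == 2 else data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    else:
        data = data.astype(np.float64)
    return data, int(rate)


def events_to_frame(events: list[CrackleEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "channel": e.channel,
        "onset_ms": e.onset_time * 1000.0,
        "peak_ms": e.peak_time * 1000.0,
        "amplitude": e.peak_amplitude,
        "breath": e.breath_index,
        "timing_code": e.timing_code,
    } for e in events])


def events_from_frame(frame: pd.DataFrame) -> list[CrackleEvent]:
    """Rebuild events from a CSV table (waveforms are not stored)."""
    return [CrackleEvent(
        channel=int(r.channel),
        onset_time=float(r.onset_ms) / 1000.0,
        peak_time=float(r.peak_ms) / 1000.0,
        waveform=None,
        peak_amplitude=float(r.amplitude),
        breath_index=int(r.breath),
        timing_code=int(r.timing_code),
    ) for r in frame.itertuples()]


def families_to_frame(families: list[CrackleFamily]) -> pd.DataFrame:
    rows = []
    for fam in families:
        loc = fam.source_location or (np.nan, np.nan, np.nan)
        rows.append({
            "mother_channel": fam.mother.channel,
            "mother_peak_ms": fam.mother.peak_time * 1000.0,
            "mother_amplitude": fam.mother.peak_amplitude,
            "breath": fam.mother.breath_index,
            "timing_code": fam.mother.timing_code,
            "member_channels": ";".join(str(c.channel) for c in fam.children),
            "member_amplitudes": ";".join(f"{c.peak_amplitude:.6g}"
                                          for c in fam.children),
            "ctc": fam.ctc,
            "x": loc[0], "y": loc[1], "z": loc[2],
            "localization_fallback": fam.localization_fallback,
        })
    return pd.DataFrame(rows)
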