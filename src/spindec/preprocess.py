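"""Channel QC, artifact masking, referencing, and band filtering.

All signal arguments are ``channels x samples`` float arrays in µV (apply
:meth:`RawRecording.to_uv` first); single-channel input may be 1-D where
noted.  Filters are zero-phase: a 4th-order Butterworth design applied
forward and backward (8th-order effective magnitude, zero net phase).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from spindec.synthetic import RawRecording


@dataclass(frozen=True)
class BandDef:
    name: str
    low_hz: float
    high_hz: float


#: canonical LFP decomposition used throughout the pipeline
BANDS: tuple[BandDef, ...] = (
    BandDef("1-4", 1.0, 4.0),
    BandDef("4-8", 4.0, 8.0),
    BandDef("8-12", 8.0, 12.0),
    BandDef("12-30", 12.0, 30.0),
    BandDef("30-90", 30.0, 90.0),
    BandDef("90-200", 90.0, 200.0),
    BandDef("200-300", 200.0, 300.0),
)
SPIKE_BAND = BandDef("spike", 300.0, 6000.0)
LFP_BROADBAND = BandDef("lfp", 1.0, 300.0)

IMPEDANCE_LOW_OHM = 1e5
IMPEDANCE_HIGH_OHM = 2e6


@dataclass
class ChannelQC:
    """Functional-channel bookkeeping from the impedance table.

    A site is functional when its 1 kHz impedance lies in the closed window
    [100 kΩ, 2 MΩ]; lower suggests a short, higher a broken or delaminated
    trace.
    """

    impedance_ohm: np.ndarray
    functional: np.ndarray

    @property
    def n_functional(self) -> int:
        return int(self.functional.sum())


def channel_qc(impedance_ohm: np.ndarray) -> ChannelQC:
    z = np.asarray(impedance_ohm, dtype=float)
    functional = (z >= IMPEDANCE_LOW_OHM) & (z <= IMPEDANCE_HIGH_OHM)
    return ChannelQC(impedance_ohm=z, functional=functional)


def drop_disconnected(recording: RawRecording, qc: ChannelQC) -> RawRecording:
    """Restrict a recording to its functional channels, order preserved."""
    if len(qc.functional) != recording.n_channels:
        raise ValueError("QC table does not cover all channels")
    keep = np.nonzero(qc.functional)[0]
    if keep.size == 0:
        raise ValueError("no functional channels remain after impedance QC")
    return RawRecording(
        samples=recording.samples[keep],
        scale_uv_per_count=recording.scale_uv_per_count,
        fs=recording.fs,
        channel_positions_um=recording.channel_positions_um[keep],
        t0_s=recording.t0_s,
    )


def reject_artifacts(
    signal: np.ndarray,
    fs: float,
    window_ms: float = 50.0,
    std_thresh_uv: float = 25.0,
) -> np.ndarray:
    """Flag high-variance windows as invalid; returns a boolean validity mask.

    The trace is tiled per channel into consecutive non-overlapping windows
    of ``window_ms``; every sample of a window whose sample standard
    deviation exceeds ``std_thresh_uv`` is marked invalid (False).  The
    signal itself is untouched — downstream stages consult the mask, which
    keeps the timebase aligned with the video.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    n_ch, n = x.shape
    w = int(round(window_ms / 1000.0 * fs))
    if w < 2:
        raise ValueError("window too short for a standard deviation")
    if w > n:
        raise ValueError("artifact window longer than the trace")
    mask = np.ones_like(x, dtype=bool)
    n_full = n // w
    body = x[:, : n_full * w].reshape(n_ch, n_full, w)
    bad = body.std(axis=2, ddof=1) > std_thresh_uv
    mask[:, : n_full * w] = np.repeat(~bad, w, axis=1)
    tail = n - n_full * w
    if tail >= 2:
        bad_tail = x[:, n_full * w :].std(axis=1, ddof=1) > std_thresh_uv
        mask[:, n_full * w :] = ~bad_tail[:, None]
    return mask if signal.ndim == 2 else mask[0]


def masked_fraction(mask: np.ndarray) -> float:
    return float(1.0 - np.mean(mask))


def common_median_reference(signal: np.ndarray) -> np.ndarray:
    """Subtract the across-channel median at every sample.

    Removes any waveform common to all channels exactly; with an even
    channel count the median is the mean of the two central values.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        warnings.warn("common median reference needs >= 2 channels; passing through")
        return x.copy()
    return x - np.median(x, axis=0, keepdims=True)


def _sos_bandpass(low_hz: float, high_hz: float, fs: float, order: int):
    nyq = fs / 2.0
    if not 0.0 < low_hz < high_hz:
        raise ValueError("need 0 < low < high")
    if high_hz >= nyq:
        raise ValueError(f"high edge {high_hz} Hz at or above Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    poles = np.concatenate([np.roots(section[3:]) for section in sos])
    if np.any(np.abs(poles) >= 1.0):
        raise ValueError("unstable band-pass design; move edges away from Nyquist")
    return sos


def bandpass(
    signal: np.ndarray, fs: float, low_hz: float, high_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, reflected edges)."""
    sos = _sos_bandpass(low_hz, high_hz, fs, order)
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def notch(signal: np.ndarray, fs: float, f0: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase second-order IIR notch for mains interference.

    Q = 30 keeps the stop band narrow: 50 Hz is suppressed by well over
    20 dB while 45 and 55 Hz pass essentially unattenuated.
    """
    b, a = sps.iirnotch(f0, q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(signal, dtype=float), axis=-1)


def split_lfp_bands(
    signal: np.ndarray, fs: float, bands: tuple[BandDef, ...] = BANDS, order: int = 4
) -> dict[str, np.ndarray]:
    """Decompose the broadband LFP into the seven canonical bands.

    The input is first restricted to the 1–300 Hz broadband, then each band
    is extracted with the same zero-phase Butterworth band-pass.
    """
    broadband = bandpass(signal, fs, LFP_BROADBAND.low_hz, LFP_BROADBAND.high_hz, order)
    return {b.name: bandpass(broadband, fs, b.low_hz, b.high_hz, order) for b in bands}


def downsample(signal: np.ndarray, fs: float, target_fs: float = 1000.0) -> np.ndarray:
    """Anti-aliased decimation to ``target_fs`` (which must divide ``fs``).

    An 8th-order zero-phase Butterworth low-pass at 0.4 x target_fs precedes
    sample picking, so components near and above the new Nyquist are
    suppressed while the band of interest is untouched.
    """
    q = fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError("target_fs must divide fs")
    q = int(round(q))
    if q == 1:
        return np.asarray(signal, dtype=float).copy()
    sos = sps.butter(8, 0.4 * target_fs, btype="low", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)
    return filtered[..., ::q]


def mask_to_rle(mask: np.ndarray) -> dict:
    """Run-length encode a boolean validity mask for JSON storage."""
    m = np.atleast_2d(mask)
    runs = []
    for row in m:
        edges = np.flatnonzero(np.diff(row.astype(np.int8)))
        bounds = np.concatenate([[0], edges + 1, [len(row)]])
        runs.append(
            [[int(a), int(b), bool(row[a])] for a, b in zip(bounds[:-1], bounds[1:])]
        )
    return {"n_samples": int(m.shape[1]), "runs": runs}


def rle_to_mask(d: dict) -> np.ndarray:
    rows = []
    for runs in d["runs"]:
        row = np.empty(d["n_samples"], dtype=bool)
        for a, b, v in runs:
            row[a:b] = v
        rows.append(row)
    return np.vstack(rows)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(json.dumps(mask_to_rle(mask)))


def read_mask(path: str | Path) -> np.ndarray:
    return rle_to_mask(json.loads(Path(path).read_text()))
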