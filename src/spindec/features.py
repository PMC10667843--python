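"""Frame-aligned predictor tensors and band/movement correlations.

Every video frame is paired with the 300 ms of neural signal that precedes
it, summarized by 26 windows of 50 ms stepped by 10 ms and right-aligned to
the frame time (the last window ends exactly at the frame).  Spike-count
tensors hold per-channel counts in each window; local-motor-potential (LMP)
tensors hold the window mean of a band-filtered LFP.  Causality is strict:
frame ``n`` sees only samples in ``(t_n - 300 ms, t_n]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from spindec.preprocess import downsample
from spindec.spikes import SpikeTrain
from spindec.synthetic import KinematicsTrack


@dataclass
class FeatureParams:
    window_ms: float = 50.0
    step_ms: float = 10.0
    lookback_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.window_ms < self.step_ms:
            raise ValueError("window must be at least one step")
        if self.lookback_ms < self.window_ms:
            raise ValueError("lookback must cover at least one window")
        span = (self.lookback_ms - self.window_ms) / self.step_ms
        if abs(span - round(span)) > 1e-9:
            raise ValueError("(lookback - window) must be an integer number of steps")

    @property
    def bins_per_frame(self) -> int:
        return int(round((self.lookback_ms - self.window_ms) / self.step_ms)) + 1


@dataclass
class FeatureTensor:
    """frames x bins x channels predictor array aligned to kinematics."""

    data: np.ndarray
    frame_times_s: np.ndarray
    modality: str  # 'spike_count' | 'lmp_band'
    valid: np.ndarray  # per frame

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("frame_times_s", data=self.frame_times_s)
            f.create_dataset("valid", data=self.valid)
            f.attrs["modality"] = self.modality

    @classmethod
    def from_hdf5(cls, path) -> "FeatureTensor":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][...],
                frame_times_s=f["frame_times_s"][...],
                modality=str(f.attrs["modality"]),
                valid=f["valid"][...],
            )


def _window_edges(frame_times: np.ndarray, params: FeatureParams):
    """(frames x bins) start and end times of each lookback window."""
    b = np.arange(params.bins_per_frame)
    starts_off = (-params.lookback_ms + b * params.step_ms) / 1000.0
    ends_off = starts_off + params.window_ms / 1000.0
    t = np.asarray(frame_times, dtype=float)[:, None]
    return t + starts_off[None, :], t + ends_off[None, :]


def bin_spike_counts(
    trains: list[SpikeTrain],
    frame_times: np.ndarray,
    params: FeatureParams | None = None,
    t_start: float = 0.0,
) -> FeatureTensor:
    """Spike counts per channel in each of the 26 lookback windows.

    Windows are half-open ``(start, end]`` so a window partition conserves
    total counts.  Frames whose lookback reaches before ``t_start`` (the
    beginning of the recording) are marked invalid.
    """
    params = params or FeatureParams()
    starts, ends = _window_edges(frame_times, params)
    n_frames, n_bins = starts.shape
    tensor = np.zeros((n_frames, n_bins, len(trains)), dtype=np.int64)
    for c, train in enumerate(trains):
        ts = np.asarray(train.timestamps_s, dtype=float)
        if len(ts) == 0:
            continue
        # half-open (start, end]: count = #(ts <= end) - #(ts <= start)
        hi = np.searchsorted(ts, ends, side="right")
        lo = np.searchsorted(ts, starts, side="right")
        tensor[:, :, c] = hi - lo
    valid = starts[:, 0] >= t_start - 1e-12
    return FeatureTensor(tensor, np.asarray(frame_times, float), "spike_count", valid)


def lmp_features(
    band_signal: np.ndarray,
    fs: float,
    frame_times: np.ndarray,
    params: FeatureParams | None = None,
    mask: np.ndarray | None = None,
    t0: float = 0.0,
    max_invalid_frac: float = 0.5,
) -> FeatureTensor:
    """Local motor potential: window means of one band's multichannel signal.

    Uses the same 26-window lookback geometry as the spike counts.  Samples
    flagged invalid by the artifact mask are excluded from each mean; a
    window with more than ``max_invalid_frac`` of its samples invalid makes
    its frame flagged invalid.
    """
    params = params or FeatureParams()
    x = np.atleast_2d(np.asarray(band_signal, dtype=float))
    n_ch, n = x.shape
    m = np.ones_like(x, dtype=bool) if mask is None else np.atleast_2d(mask)
    # prefix sums over (signal * mask) and mask let every window mean be O(1)
    csum = np.concatenate([np.zeros((n_ch, 1)), np.cumsum(x * m, axis=1)], axis=1)
    ccnt = np.concatenate([np.zeros((n_ch, 1)), np.cumsum(m, axis=1)], axis=1)
    starts, ends = _window_edges(frame_times, params)
    # sample indices i with start < t0 + i/fs <= end  ->  range (i0, i1]
    eps = 1e-6
    i0 = np.clip(np.floor((starts - t0) * fs + eps).astype(int) + 1, 0, n)
    i1 = np.clip(np.floor((ends - t0) * fs + eps).astype(int) + 1, 0, n)
    total = np.maximum(i1 - i0, 0)
    n_frames, n_bins = starts.shape
    tensor = np.zeros((n_frames, n_bins, n_ch))
    too_invalid = np.zeros((n_frames, n_bins), dtype=bool)
    for c in range(n_ch):
        s = csum[c][i1] - csum[c][i0]
        k = ccnt[c][i1] - ccnt[c][i0]
        with np.errstate(invalid="ignore", divide="ignore"):
            tensor[:, :, c] = np.where(k > 0, s / np.maximum(k, 1), 0.0)
        too_invalid |= (total > 0) & (k < (1.0 - max_invalid_frac) * total)
    covered = (starts[:, 0] >= t0 - 1e-12) & (ends[:, -1] <= t0 + n / fs + 1e-9)
    valid = covered & ~too_invalid.any(axis=1)
    return FeatureTensor(tensor, np.asarray(frame_times, float), "lmp_band", valid)


def band_movement_correlation(
    band_signal: np.ndarray,
    fs: float,
    kin: KinematicsTrack,
    joint: str = "toe",
    axis: str = "x",
    intermediate_fs: float = 1000.0,
    per_channel: bool = False,
):
    """Pearson correlation between a band signal and a joint coordinate.

    Each channel is anti-alias decimated to ``intermediate_fs``, linearly
    interpolated onto the frame times, and correlated with the joint
    coordinate over moving frames only.  By default the per-channel signed
    r's are aggregated as the mean of their magnitudes (after referencing,
    a movement-locked component may flip sign across the shank, so signed
    averaging would cancel genuine structure); ``per_channel=True`` returns
    the signed values instead.
    """
    x = np.atleast_2d(np.asarray(band_signal, dtype=float))
    moving = kin.state == "moving"
    if moving.sum() < 3:
        return np.nan
    coord = kin.joint_coord(joint, axis)[moving]
    low = downsample(x, fs, intermediate_fs)
    t_low = np.arange(low.shape[1]) / intermediate_fs
    rs = np.empty(x.shape[0])
    for c in range(x.shape[0]):
        at_frames = np.interp(kin.frame_times_s, t_low, low[c])[moving]
        if at_frames.std() == 0 or coord.std() == 0:
            rs[c] = np.nan
            continue
        rs[c], _ = stats.pearsonr(at_frames, coord)
    if per_channel:
        return rs
    return float(np.nanmean(np.abs(rs)))


def band_correlations(
    band_signals: dict[str, np.ndarray],
    fs: float,
    kin: KinematicsTrack,
    joint: str = "toe",
    axis: str = "x",
) -> dict[str, float]:
    """Band-name -> Pearson r map across an LFP decomposition."""
    return {
        name: band_movement_correlation(sig, fs, kin, joint, axis)
        for name, sig in band_signals.items()
    }


class MinMaxNormalizer:
    """Per-column min-max scaling to [0, 1], invertible.

    Joint coordinates are normalized per session before decoding; the
    stored constants allow mapping predictions back to pixels.
    """

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.range_: np.ndarray | None = None

    def fit(self, y: np.ndarray) -> "MinMaxNormalizer":
        y = np.atleast_2d(np.asarray(y, dtype=float))
        self.min_ = y.min(axis=0)
        rng = y.max(axis=0) - self.min_
        self.range_ = np.where(rng > 0, rng, 1.0)
        return self

    def transform(self, y: np.ndarray) -> np.ndarray:
        if self.min_ is None:
            raise RuntimeError("fit first")
        return (np.asarray(y, dtype=float) - self.min_) / self.range_

    def fit_transform(self, y: np.ndarray) -> np.ndarray:
        return self.fit(y).transform(y)

    def inverse_transform(self, y: np.ndarray) -> np.ndarray:
        if self.min_ is None:
            raise RuntimeError("fit first")
        return np.asarray(y, dtype=float) * self.range_ + self.min_
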