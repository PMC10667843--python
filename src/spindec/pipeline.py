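"""End-to-end synthetic run: simulate, preprocess, detect, analyze.

One entry point, :func:`run_pipeline`, takes a :class:`SimConfig` (or a YAML
file via :func:`spindec.synthetic.config_from_yaml`) and executes the whole
chain on the simulated session, returning every intermediate product and the
summary numbers.  Deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spindec import preprocess as pp
from spindec import spikes as sp
from spindec.features import FeatureParams, band_correlations, bin_spike_counts
from spindec.synthetic import GroundTruth, KinematicsTrack, RawRecording, SimConfig, simulate_session
from spindec.trajectory import (
    TrajectoryParams,
    average_trajectory,
    firing_rates,
    pca_embed,
    segment_step_cycles,
    state_separation,
)


@dataclass
class PipelineResult:
    recording: RawRecording
    kinematics: KinematicsTrack
    ground_truth: GroundTruth
    mask: np.ndarray
    spike_band: np.ndarray
    lfp_bands: dict[str, np.ndarray]
    trains: list[sp.SpikeTrain]
    detection: dict[str, float]  # recall/precision vs ground truth
    snr: np.ndarray  # per channel with spikes
    band_toe_r: dict[str, float]
    features: object  # FeatureTensor of spike counts
    trajectory: dict[str, float] = field(default_factory=dict)


def channel_ground_truth(
    gt: GroundTruth,
    channel: int,
    required_amp_uv: float,
    optional_amp_uv: float,
    mask_row: np.ndarray | None = None,
    fs: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike times a detector must find on one channel, and borderline ones.

    Units whose amplitude on the channel reaches ``required_amp_uv`` are
    required; units between ``optional_amp_uv`` and that level are counted
    as acceptable detections but not demanded.  Times falling on masked
    samples are excluded (the detector is forbidden to report them).
    """
    required, optional = [], []
    for u in range(len(gt.spike_times)):
        a = gt.amplitudes_uv[u, channel]
        if a >= required_amp_uv:
            required.append(gt.spike_times[u])
        elif a >= optional_amp_uv:
            optional.append(gt.spike_times[u])
    req = np.sort(np.concatenate(required)) if required else np.empty(0)
    opt = np.sort(np.concatenate(optional)) if optional else np.empty(0)
    if mask_row is not None and fs is not None:
        def keep(ts: np.ndarray) -> np.ndarray:
            idx = np.clip(np.round(ts * fs).astype(int), 0, len(mask_row) - 1)
            return ts[mask_row[idx]]
        req, opt = keep(req), keep(opt)
    return req, opt


def run_pipeline(
    config: SimConfig,
    detection: sp.DetectionParams | None = None,
    feature_params: FeatureParams | None = None,
    with_trajectory: bool = True,
) -> PipelineResult:
    detection = detection or sp.DetectionParams()
    feature_params = feature_params or FeatureParams()

    rec, kin, gt = simulate_session(config)
    x = rec.to_uv()
    x = pp.common_median_reference(x)
    mask = pp.reject_artifacts(x, rec.fs)
    x = pp.notch(x, rec.fs)
    spike_band = pp.bandpass(x, rec.fs, pp.SPIKE_BAND.low_hz, pp.SPIKE_BAND.high_hz)
    lfp_bands = pp.split_lfp_bands(x, rec.fs)

    trains = sp.detect_spikes(spike_band, rec.fs, detection, mask)

    # detection quality against ground truth, pooled over channels
    recalls, precisions, weights = [], [], []
    snrs = []
    for ch, train in enumerate(trains):
        thr = abs(sp.detection_threshold(spike_band[ch], detection.k, mask[ch]))
        req, opt = channel_ground_truth(
            gt, ch, required_amp_uv=1.3 * thr, optional_amp_uv=0.7 * thr,
            mask_row=mask[ch], fs=rec.fs,
        )
        if len(req):
            r, p = sp.evaluate_detection(train, req, optional_times_s=opt)
            recalls.append(r)
            precisions.append(p)
            weights.append(len(req))
        if len(train) >= 10:
            snrs.append(sp.compute_snr(train, spike_band[ch], rec.fs, mask[ch]))
    w = np.asarray(weights, dtype=float)
    det = {
        "recall": float(np.average(recalls, weights=w)) if len(w) else np.nan,
        "precision": float(np.average(precisions, weights=w)) if len(w) else np.nan,
    }

    band_r = band_correlations(lfp_bands, rec.fs, kin)

    feats = bin_spike_counts(trains, kin.frame_times_s, feature_params)

    traj: dict[str, float] = {}
    if with_trajectory:
        tp = TrajectoryParams()
        times, rates = firing_rates(gt.spike_times, config.duration_s, tp)
        emb = pca_embed(rates, tp, times_s=times)
        states = np.where(kin.schedule.state(times), "moving", "stationary")
        cycles = segment_step_cycles(kin)
        if len(cycles) >= 2:
            _, closure = average_trajectory(emb, cycles)
            traj["closure"] = closure
            traj["n_cycles"] = float(len(cycles))
        if (states == "moving").sum() >= 2 and (states == "stationary").sum() >= 2:
            traj["state_separation"] = state_separation(emb, states)
        traj["ev_top3"] = float(emb.explained_variance_ratio.sum())

    return PipelineResult(
        recording=rec,
        kinematics=kin,
        ground_truth=gt,
        mask=mask,
        spike_band=spike_band,
        lfp_bands=lfp_bands,
        trains=trains,
        detection=det,
        snr=np.asarray(snrs),
        band_toe_r=band_r,
        features=feats,
        trajectory=traj,
    )
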