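"""Ground-truthed synthetic intraspinal recordings and hindlimb kinematics.

The generator emulates a wheel-running session recorded with a linear
multi-site electrode in the ventral horn, synchronized to joint tracking
video: phase-tuned spiking units with exponentially decaying spatial
amplitude footprints, a movement-locked low-frequency field component at the
step frequency, 1/f background, 50 Hz mains interference, and intermittent
high-variance motion artifacts.  Everything is deterministic under the
config seed, and every latent component (spike times, per-channel
amplitudes, artifact intervals, the locked LFP waveform) is returned as
ground truth so downstream stages can be verified exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

JOINTS = ("toe", "ankle", "knee", "hip", "iliac")

# per-joint limit-cycle geometry (pixels): centers, x/y excursions, phase lags.
# The toe travels farthest; excursion shrinks toward the iliac crest.
_JOINT_CENTER_X = {"toe": 300.0, "ankle": 280.0, "knee": 260.0, "hip": 240.0, "iliac": 220.0}
_JOINT_CENTER_Y = {"toe": 80.0, "ankle": 120.0, "knee": 160.0, "hip": 200.0, "iliac": 240.0}
_JOINT_AMP_X = {"toe": 40.0, "ankle": 28.0, "knee": 18.0, "hip": 10.0, "iliac": 6.0}
_JOINT_AMP_Y = {"toe": 14.0, "ankle": 10.0, "knee": 7.0, "hip": 4.0, "iliac": 2.0}
_JOINT_PHASE = {"toe": 0.0, "ankle": 0.4, "knee": 0.8, "hip": 1.2, "iliac": 1.6}

INT16_SCALE_UV = 0.195  # µV per count, Intan-style


@dataclass
class SimConfig:
    """Parameters of one simulated recording session.

    Defaults describe a realistic awake wheel-running session: 20 kHz raw
    sampling, 60 fps video, a 32-site linear shank at 40 µm pitch, 40
    phase-tuned units with ~150 µV peaks over ~10 µV noise, stepping at
    3.5 Hz roughly 70% of the time.
    """

    seed: int = 0
    duration_s: float = 20.0
    fs_raw: float = 20_000.0
    fs_video: float = 60.0
    n_channels: int = 32
    channel_pitch_um: float = 40.0
    n_units: int = 40
    step_freq_hz: float = 3.5
    tuning_concentration: float = 2.5  # von Mises kappa
    base_rate_hz: float = 5.0
    peak_rate_hz: float = 60.0
    unit_amp_uv: float = 150.0  # negative-peak amplitude of a typical unit
    footprint_lambda_um: float = 60.0
    noise_rms_uv: float = 5.0
    pink_rms_uv: float = 5.0  # 1/f background
    mains_amp_uv: float = 5.0
    lfp_locked_amp_uv: float = 30.0
    artifact_rate_hz: float = 0.05
    artifact_dur_ms: float = 100.0
    artifact_amp_uv: float = 200.0
    moving_fraction: float = 0.7
    refractory_ms: float = 2.0
    mean_bout_s: float = 4.0  # mean duration of a moving bout

    def validate(self) -> None:
        if self.fs_raw < 2 * 6000:
            raise ValueError("fs_raw must cover the 300-6000 Hz spike band (>= 12 kHz)")
        for name in (
            "duration_s", "fs_raw", "fs_video", "channel_pitch_um", "step_freq_hz",
            "base_rate_hz", "peak_rate_hz", "unit_amp_uv", "footprint_lambda_um",
            "artifact_dur_ms", "artifact_amp_uv", "mean_bout_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("tuning_concentration", "noise_rms_uv", "pink_rms_uv",
                     "mains_amp_uv", "lfp_locked_amp_uv", "artifact_rate_hz",
                     "refractory_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.moving_fraction <= 1.0:
            raise ValueError("moving_fraction must be in [0, 1]")
        if self.n_channels < 1 or self.n_units < 0:
            raise ValueError("n_channels >= 1 and n_units >= 0 required")
        if self.peak_rate_hz < self.base_rate_hz:
            raise ValueError("peak_rate_hz must be >= base_rate_hz")

    def channel_positions_um(self) -> np.ndarray:
        return np.arange(self.n_channels) * self.channel_pitch_um


class GaitSchedule:
    """Piecewise-constant moving/stationary bouts and the gait phase clock.

    The phase advances at ``2*pi*step_freq`` while moving and freezes while
    stationary, so phase is continuous and monotone within moving bouts.
    """

    def __init__(self, bouts: list[tuple[float, float, str]], step_freq_hz: float):
        self.bouts = bouts
        self.step_freq_hz = step_freq_hz
        # cumulative moving time at each bout start, for O(1) phase lookup
        self._starts = np.array([b[0] for b in bouts])
        self._ends = np.array([b[1] for b in bouts])
        self._moving = np.array([b[2] == "moving" for b in bouts])
        cum = np.concatenate([[0.0], np.cumsum(np.where(self._moving, self._ends - self._starts, 0.0))])
        self._cum_moving = cum[:-1]

    def state(self, t: np.ndarray) -> np.ndarray:
        """Boolean moving indicator at times ``t``."""
        idx = np.clip(np.searchsorted(self._starts, t, side="right") - 1, 0, len(self.bouts) - 1)
        return self._moving[idx]

    def moving_time(self, t: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(self._starts, t, side="right") - 1, 0, len(self.bouts) - 1)
        within = np.where(self._moving[idx], t - self._starts[idx], 0.0)
        return self._cum_moving[idx] + within

    def phase(self, t: np.ndarray) -> np.ndarray:
        """Unwrapped gait phase (radians) at times ``t``."""
        return 2.0 * np.pi * self.step_freq_hz * self.moving_time(t)


@dataclass
class KinematicsTrack:
    """Per-frame 2-D joint coordinates with gait-phase and state labels."""

    frame_times_s: np.ndarray
    x: dict[str, np.ndarray]  # joint -> pixels
    y: dict[str, np.ndarray]
    phase: np.ndarray  # gait phase in [0, 2*pi)
    phase_label: np.ndarray  # 'swing' | 'stance'
    state: np.ndarray  # 'moving' | 'stationary'
    schedule: GaitSchedule | None = None

    @property
    def fs_video(self) -> float:
        return 1.0 / float(np.median(np.diff(self.frame_times_s)))

    def joint_coord(self, joint: str, axis: str) -> np.ndarray:
        if axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        return (self.x if axis == "x" else self.y)[joint]

    def coordinate_matrix(self) -> np.ndarray:
        """frames x 10 array, columns ordered toe_x, toe_y, ..., iliac_y."""
        return np.column_stack([self.joint_coord(j, ax) for j in JOINTS for ax in ("x", "y")])

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {
            "frame": np.arange(len(self.frame_times_s)),
            "time_s": self.frame_times_s,
        }
        for j in JOINTS:
            cols[f"{j}_x"] = self.x[j]
            cols[f"{j}_y"] = self.y[j]
        cols["phase"] = self.phase
        cols["phase_label"] = self.phase_label
        cols["state"] = self.state
        return pd.DataFrame(cols)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class GroundTruth:
    """Latent quantities of a simulated session, for exact verification."""

    spike_times: list[np.ndarray]  # per unit, seconds
    home_channel: np.ndarray  # per unit
    amplitudes_uv: np.ndarray  # units x channels, negative-peak amplitude
    preferred_phase: np.ndarray  # per unit, radians
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)
    lfp_locked_uv: np.ndarray | None = None  # per raw sample

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spike_times_s": [st.tolist() for st in self.spike_times],
            "home_channel": self.home_channel.tolist(),
            "amplitudes_uv": self.amplitudes_uv.tolist(),
            "preferred_phase": self.preferred_phase.tolist(),
            "artifact_intervals_s": [list(iv) for iv in self.artifact_intervals],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            spike_times=[np.asarray(st, dtype=float) for st in d["spike_times_s"]],
            home_channel=np.asarray(d["home_channel"], dtype=int),
            amplitudes_uv=np.asarray(d["amplitudes_uv"], dtype=float),
            preferred_phase=np.asarray(d["preferred_phase"], dtype=float),
            artifact_intervals=[tuple(iv) for iv in d["artifact_intervals_s"]],
        )


@dataclass
class RawRecording:
    """Multichannel raw voltage as int16 counts plus acquisition metadata."""

    samples: np.ndarray  # channels x time, int16
    scale_uv_per_count: float
    fs: float
    channel_positions_um: np.ndarray
    t0_s: float = 0.0

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def to_uv(self) -> np.ndarray:
        """Voltage in µV as float64, channels x time."""
        return self.samples.astype(np.float64) * self.scale_uv_per_count

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples.shape[1]) / self.fs

    def write(self, stem: str | Path) -> None:
        """Write ``<stem>.bin`` (flat int16, channel-major frames) + ``<stem>.json``."""
        stem = Path(stem)
        # channel-major frames: sample 0 of all channels, then sample 1, ...
        self.samples.T.astype("<i2").tofile(stem.with_suffix(".bin"))
        meta = {
            "fs": self.fs,
            "n_channels": int(self.n_channels),
            "scale_uv_per_count": self.scale_uv_per_count,
            "channel_positions_um": self.channel_positions_um.tolist(),
            "t0_s": self.t0_s,
            "dtype": "int16-le",
        }
        stem.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def read(cls, stem: str | Path) -> "RawRecording":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        flat = np.fromfile(stem.with_suffix(".bin"), dtype="<i2")
        n_ch = int(meta["n_channels"])
        samples = flat.reshape(-1, n_ch).T.copy()
        return cls(
            samples=samples,
            scale_uv_per_count=float(meta["scale_uv_per_count"]),
            fs=float(meta["fs"]),
            channel_positions_um=np.asarray(meta["channel_positions_um"], dtype=float),
            t0_s=float(meta.get("t0_s", 0.0)),
        )


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, tag])


def _draw_bouts(config: SimConfig, rng: np.random.Generator) -> list[tuple[float, float, str]]:
    """Alternating moving/stationary bouts with exponential durations.

    Mean moving-bout length is ``mean_bout_s``; the stationary mean is set so
    the long-run moving fraction equals ``moving_fraction``.
    """
    f = config.moving_fraction
    T = config.duration_s
    if f <= 0.0:
        return [(0.0, T, "stationary")]
    if f >= 1.0:
        return [(0.0, T, "moving")]
    mean_mov = config.mean_bout_s
    mean_stat = mean_mov * (1.0 - f) / f
    bouts: list[tuple[float, float, str]] = []
    t = 0.0
    state = "moving" if rng.random() < f else "stationary"
    while t < T:
        mean = mean_mov if state == "moving" else mean_stat
        dur = rng.exponential(mean)
        end = min(t + dur, T)
        bouts.append((t, end, state))
        t = end
        state = "stationary" if state == "moving" else "moving"
    return bouts


def simulate_kinematics(config: SimConfig) -> KinematicsTrack:
    """Simulate joint tracking for one session.

    During moving bouts each joint traces a smooth limit cycle at the step
    frequency with joint-specific excursions and phase lags (the toe travels
    farthest); during stationary bouts coordinates hold their bout-entry pose
    up to sub-pixel tracking jitter.  Swing is the half-cycle in which the
    toe-x velocity is positive (limb advancing in the travel direction).
    """
    config.validate()
    if config.duration_s < 3.0 / config.step_freq_hz:
        raise ValueError("duration_s must cover at least 3 full step cycles")
    rng = _rng(config, 1)
    schedule = GaitSchedule(_draw_bouts(config, rng), config.step_freq_hz)

    n_frames = int(np.floor(config.duration_s * config.fs_video))
    t = np.arange(n_frames) / config.fs_video
    moving = schedule.state(t)
    phi = schedule.phase(t)

    x: dict[str, np.ndarray] = {}
    y: dict[str, np.ndarray] = {}
    for j in JOINTS:
        cx, cy = _JOINT_CENTER_X[j], _JOINT_CENTER_Y[j]
        # the phase clock freezes during stationary bouts, so the pose is
        # automatically held at its bout-entry value there
        ph = phi + _JOINT_PHASE[j]
        xj = cx + _JOINT_AMP_X[j] * np.cos(ph)
        yj = cy + _JOINT_AMP_Y[j] * np.sin(ph)
        # sub-pixel tracking jitter everywhere
        xj = xj + 0.3 * rng.standard_normal(n_frames)
        yj = yj + 0.3 * rng.standard_normal(n_frames)
        x[j], y[j] = xj, yj

    # toe-x velocity d/dt[A cos(phi)] > 0  <=>  sin(phi) < 0
    swing = np.sin(phi + _JOINT_PHASE["toe"]) < 0.0
    phase_label = np.where(moving & swing, "swing", "stance")
    state = np.where(moving, "moving", "stationary")
    return KinematicsTrack(
        frame_times_s=t,
        x=x,
        y=y,
        phase=np.mod(phi, 2.0 * np.pi),
        phase_label=phase_label,
        state=state,
        schedule=schedule,
    )


def simulate_units(config: SimConfig, kin: KinematicsTrack) -> GroundTruth:
    """Draw phase-tuned spike trains and spatial amplitude footprints.

    Each unit fires as an inhomogeneous Poisson process whose rate is
    ``base + (peak - base) * exp(kappa * (cos(phase - mu) - 1))`` while the
    animal is moving (the von Mises bump normalized to reach ``peak`` at the
    preferred phase ``mu``) and ``base`` while stationary, thinned to respect
    an absolute refractory period.  Per-channel amplitudes decay
    exponentially with distance from the unit's home site.
    """
    config.validate()
    if kin.schedule is None:
        raise ValueError("kinematics track must carry its gait schedule")
    if kin.frame_times_s[-1] + 1.0 / config.fs_video < config.duration_s - 1e-9:
        raise ValueError("kinematics track does not cover the configured duration")
    rng = _rng(config, 2)
    n_units = config.n_units
    kappa = config.tuning_concentration
    home = rng.integers(0, config.n_channels, size=n_units)
    mu = rng.uniform(0.0, 2.0 * np.pi, size=n_units)
    # per-unit amplitude spread around the nominal peak (roughly 90-210 µV
    # at the 150 µV default, matching the range typical of ventral-horn SUs)
    amp0 = config.unit_amp_uv * rng.uniform(0.6, 1.4, size=n_units)
    pos = config.channel_positions_um()
    dist = np.abs(pos[None, :] - pos[home][:, None])  # units x channels
    with np.errstate(divide="ignore"):
        decay = (
            np.exp(-dist / config.footprint_lambda_um)
            if config.footprint_lambda_um > 0
            else (dist == 0).astype(float)
        )
    amplitudes = amp0[:, None] * decay

    refr = config.refractory_ms / 1000.0
    spike_times: list[np.ndarray] = []
    for u in range(n_units):
        # thinning against the peak rate
        lam = config.peak_rate_hz
        n_cand = rng.poisson(lam * config.duration_s)
        cand = np.sort(rng.uniform(0.0, config.duration_s, size=n_cand))
        phi = kin.schedule.phase(cand)
        moving = kin.schedule.state(cand)
        tuning = np.exp(kappa * (np.cos(phi - mu[u]) - 1.0))
        rate = np.where(
            moving,
            config.base_rate_hz + (config.peak_rate_hz - config.base_rate_hz) * tuning,
            config.base_rate_hz,
        )
        keep = rng.random(n_cand) < rate / lam
        times = cand[keep]
        if refr > 0 and len(times) > 1:
            accepted = [times[0]]
            for s in times[1:]:
                if s - accepted[-1] >= refr:
                    accepted.append(s)
            times = np.asarray(accepted)
        spike_times.append(times)

    return GroundTruth(
        spike_times=spike_times,
        home_channel=home,
        amplitudes_uv=amplitudes,
        preferred_phase=mu,
    )


def spike_template(fs: float, width_ms: float = 1.2) -> np.ndarray:
    """Biphasic extracellular template: sharp negative peak, smaller positive
    rebound, ~1.2 ms support, normalized so the trough equals -1.

    The trough sits exactly at the center sample so that an inserted spike's
    ground-truth time coincides with the local minimum of the trace.
    """
    n = int(round(width_ms / 1000.0 * fs))
    n += (n + 1) % 2  # odd length -> exact center sample
    t = (np.arange(n) - n // 2) / fs * 1000.0  # ms relative to trough
    neg = -np.exp(-0.5 * (t / 0.10) ** 2)
    pos = 0.35 * np.exp(-0.5 * ((t - 0.35) / 0.22) ** 2)
    w = neg + pos
    return w / np.abs(w.min())


def _pink_noise(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """1/f-power background, spectrum flattened below 1 Hz, scaled to rms."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, 1.0))
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def synthesize_raw(
    gt: GroundTruth, kin: KinematicsTrack, config: SimConfig
) -> RawRecording:
    """Render the int16 raw trace from ground truth.

    The trace is the sum of spike templates scaled by each unit's per-channel
    amplitude, a movement-locked sinusoid at the step frequency (gated by the
    moving state, shared across channels up to a per-channel gain), 1/f
    background, white noise, 50 Hz mains, and boxcar-windowed high-variance
    artifact bursts.  The locked component is returned in the ground truth.
    """
    config.validate()
    if kin.schedule is None:
        raise ValueError("kinematics track must carry its gait schedule")
    rng = _rng(config, 3)
    n = int(round(config.duration_s * config.fs_raw))
    n_ch = config.n_channels
    sig = np.zeros((n_ch, n), dtype=np.float64)
    t = np.arange(n) / config.fs_raw

    # --- spikes ---
    tmpl = spike_template(config.fs_raw)
    half = len(tmpl) // 2
    for u, times in enumerate(gt.spike_times):
        idx = np.round(times * config.fs_raw).astype(int)
        idx = idx[(idx - half >= 0) & (idx + half < n)]
        amps = gt.amplitudes_uv[u]
        for ch in np.nonzero(amps > 1e-3)[0]:
            a = amps[ch]
            for i in idx:
                sig[ch, i - half : i + half + 1] += a * tmpl

    # --- movement-locked LFP component at the step frequency ---
    phi = kin.schedule.phase(t)
    moving = kin.schedule.state(t)
    # in phase with the toe-x oscillation (cos of the gait phase); the
    # per-channel gain falls off smoothly along the shank (dorso-ventral
    # amplitude gradient), so the component is not purely common-mode
    locked = config.lfp_locked_amp_uv * np.cos(phi + _JOINT_PHASE["toe"]) * moving
    lfp_gain = np.linspace(1.5, 0.5, n_ch)
    sig += lfp_gain[:, None] * locked[None, :]

    # --- background and interference ---
    for ch in range(n_ch):
        if config.pink_rms_uv > 0:
            sig[ch] += _pink_noise(rng, n, config.fs_raw, config.pink_rms_uv)
        if config.noise_rms_uv > 0:
            sig[ch] += config.noise_rms_uv * rng.standard_normal(n)
    if config.mains_amp_uv > 0:
        mains_phase = rng.uniform(0.0, 2.0 * np.pi)
        mains_gain = 1.0 + 0.2 * (rng.random(n_ch) - 0.5)
        mains = config.mains_amp_uv * np.sin(2.0 * np.pi * 50.0 * t + mains_phase)
        sig += mains_gain[:, None] * mains[None, :]

    # --- motion artifacts: boxcar bursts of high-variance noise ---
    artifacts: list[tuple[float, float]] = []
    if config.artifact_rate_hz > 0:
        n_art = rng.poisson(config.artifact_rate_hz * config.duration_s)
        starts = np.sort(rng.uniform(0.0, config.duration_s, size=n_art))
        dur = config.artifact_dur_ms / 1000.0
        for s in starts:
            e = min(s + dur, config.duration_s)
            i0, i1 = int(s * config.fs_raw), int(e * config.fs_raw)
            if i1 <= i0:
                continue
            gains = 0.5 + rng.random(n_ch)  # channel-specific coupling
            burst = rng.standard_normal(i1 - i0)
            sig[:, i0:i1] += config.artifact_amp_uv * gains[:, None] * burst[None, :]
            artifacts.append((s, e))

    counts = np.round(sig / INT16_SCALE_UV)
    if np.abs(counts).max(initial=0) >= 2**15:
        raise ValueError("synthesized trace saturates the int16 range; lower amplitudes")
    gt.artifact_intervals = artifacts
    gt.lfp_locked_uv = locked
    return RawRecording(
        samples=counts.astype(np.int16),
        scale_uv_per_count=INT16_SCALE_UV,
        fs=config.fs_raw,
        channel_positions_um=config.channel_positions_um(),
    )


def simulate_session(config: SimConfig) -> tuple[RawRecording, KinematicsTrack, GroundTruth]:
    """Full simulation: kinematics, units, and the rendered raw recording."""
    kin = simulate_kinematics(config)
    gt = simulate_units(config, kin)
    rec = synthesize_raw(gt, kin, config)
    return rec, kin, gt


def config_from_yaml(path: str | Path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML mapping (unknown keys rejected)."""
    import yaml

    d = yaml.safe_load(Path(path).read_text()) or {}
    names = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg
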