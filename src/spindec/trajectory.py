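"""Low-dimensional neural-state analysis of locomotion.

Spike trains are converted to smooth firing rates with a 50 ms Gaussian
kernel, the time x unit (or time x channel, for downsampled LFP) matrix is
embedded with PCA onto its first three principal components, and the
resulting trajectory is summarized per step cycle (phase-binned average
loop) and per behavioral state (moving vs stationary separation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA

from spindec.synthetic import KinematicsTrack


@dataclass
class TrajectoryParams:
    rate_kernel_ms: float = 50.0  # Gaussian sigma
    n_pcs: int = 3
    lfp_fs: float = 1000.0
    rate_fs: float = 100.0  # sampling of the rate grid; resolves the kernel

    def __post_init__(self) -> None:
        if self.rate_kernel_ms <= 0:
            raise ValueError("rate kernel must be > 0")
        if self.n_pcs < 2:
            raise ValueError("need at least 2 principal components")


@dataclass
class Embedding:
    """PC scores over time with variance bookkeeping and annotations."""

    times_s: np.ndarray
    scores: np.ndarray  # time x n_pcs, zero column mean
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # n_pcs x channels
    mean: np.ndarray
    state: np.ndarray | None = None
    cycles: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        cols = {"time_s": self.times_s}
        for i in range(self.scores.shape[1]):
            cols[f"pc{i + 1}"] = self.scores[:, i]
        if self.state is not None:
            cols["state"] = self.state
        return pd.DataFrame(cols)


def firing_rates(
    spike_times: list[np.ndarray],
    duration_s: float,
    params: TrajectoryParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel rate estimate for each unit on a uniform grid.

    Each train is binned at ``rate_fs`` and convolved with a unit-area
    Gaussian of sigma ``rate_kernel_ms``, so the time integral of every
    unit's rate equals its spike count (up to edge truncation).
    Returns (times, time x unit rate matrix in spikes/s).
    """
    params = params or TrajectoryParams()
    dt = 1.0 / params.rate_fs
    n = int(round(duration_s * params.rate_fs))
    edges = np.arange(n + 1) * dt
    sigma_bins = params.rate_kernel_ms / 1000.0 / dt
    rates = np.zeros((n, len(spike_times)))
    for u, ts in enumerate(spike_times):
        counts, _ = np.histogram(ts, bins=edges)
        rates[:, u] = ndimage.gaussian_filter1d(
            counts.astype(float), sigma_bins, mode="constant", truncate=6.0
        ) / dt
    times = edges[:-1] + dt / 2.0
    return times, rates


def pca_embed(
    matrix: np.ndarray,
    params: TrajectoryParams | None = None,
    times_s: np.ndarray | None = None,
    standardize: bool = False,
) -> Embedding:
    """Project a time x channel matrix onto its leading principal components.

    Columns are centered (and optionally z-scored); component signs follow a
    deterministic convention: the largest-magnitude loading of each
    component is made positive.
    """
    params = params or TrajectoryParams()
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < params.n_pcs:
        raise ValueError("matrix must be time x channel with >= n_pcs channels")
    mean = X.mean(axis=0)
    Xc = X - mean
    if standardize:
        sd = Xc.std(axis=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=params.n_pcs, svd_solver="full")
    scores = pca.fit_transform(Xc)
    comps = pca.components_
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1.0
            scores[:, i] *= -1.0
    if times_s is None:
        times_s = np.arange(len(X), dtype=float)
    return Embedding(
        times_s=np.asarray(times_s, dtype=float),
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=comps,
        mean=mean,
    )


@dataclass
class StepCycle:
    start_s: float
    end_s: float
    swing: tuple[float, float]
    stance: tuple[float, float]


def segment_step_cycles(kin: KinematicsTrack) -> list[StepCycle]:
    """Delimit step cycles at stance-to-swing transitions of the toe.

    Only transitions inside moving bouts count; each cycle spans swing
    followed by stance, and every frame belongs to at most one cycle.
    """
    labels = np.asarray(kin.phase_label)
    moving = np.asarray(kin.state) == "moving"
    t = kin.frame_times_s
    is_swing = labels == "swing"
    onset = np.flatnonzero(is_swing[1:] & ~is_swing[:-1] & moving[1:]) + 1
    cycles: list[StepCycle] = []
    for a, b in zip(onset[:-1], onset[1:]):
        if not moving[a:b].all():
            continue  # bout boundary inside the putative cycle
        seg = is_swing[a:b]
        sw_end = a + int(np.argmin(seg)) if not seg.all() else b
        cycles.append(
            StepCycle(
                start_s=t[a],
                end_s=t[b],
                swing=(t[a], t[sw_end]),
                stance=(t[sw_end], t[b]),
            )
        )
    return cycles


def average_trajectory(
    emb: Embedding,
    cycles: list[StepCycle],
    n_bins: int = 50,
    phase_shuffle_seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Phase-binned average loop over step cycles and its closure statistic.

    Each cycle is time-normalized to [0, 1), PC scores are averaged in
    ``n_bins`` fixed phase bins across cycles.  The closure statistic is the
    gap between the first and last bin means divided by the loop diameter;
    small values mean the average trajectory forms a closed loop.  With
    ``phase_shuffle_seed`` set, each cycle's samples are circularly shifted
    by a random phase before averaging — a destruction control under which
    a genuine loop collapses toward a point.
    """
    if not cycles:
        raise ValueError("no step cycles to average")
    rng = (
        np.random.default_rng(phase_shuffle_seed)
        if phase_shuffle_seed is not None
        else None
    )
    k = emb.scores.shape[1]
    sums = np.zeros((n_bins, k))
    counts = np.zeros(n_bins)
    for cyc in cycles:
        sel = (emb.times_s >= cyc.start_s) & (emb.times_s < cyc.end_s)
        if sel.sum() < 2:
            continue
        phase = (emb.times_s[sel] - cyc.start_s) / (cyc.end_s - cyc.start_s)
        if rng is not None:
            phase = np.mod(phase + rng.random(), 1.0)
        bins = np.minimum((phase * n_bins).astype(int), n_bins - 1)
        np.add.at(sums, bins, emb.scores[sel])
        np.add.at(counts, bins, 1.0)
    filled = counts > 0
    if filled.sum() < 2:
        raise ValueError("too few samples per cycle for the requested bins")
    loop = np.full((n_bins, k), np.nan)
    loop[filled] = sums[filled] / counts[filled, None]
    pts = loop[filled]
    diam = float(np.max(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)))
    first = loop[np.argmax(filled)]
    last = loop[n_bins - 1 - int(np.argmax(filled[::-1]))]
    closure = float(np.linalg.norm(first - last) / diam) if diam > 0 else 0.0
    return loop, closure


def loop_diameter(loop: np.ndarray) -> float:
    pts = loop[~np.isnan(loop).any(axis=1)]
    return float(np.max(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)))


def state_separation(emb: Embedding, states: np.ndarray) -> float:
    """Moving/stationary separation of the neural state.

    Score = distance between the moving and stationary centroids in PC
    space divided by the pooled within-state RMS spread; a score above 1
    indicates a clear neural state change between behaviors.
    """
    s = np.asarray(states)
    moving = emb.scores[s == "moving"]
    stat = emb.scores[s == "stationary"]
    if len(moving) < 2 or len(stat) < 2:
        raise ValueError("need samples in both states")
    c_m, c_s = moving.mean(axis=0), stat.mean(axis=0)
    d2_m = np.sum((moving - c_m) ** 2, axis=1)
    d2_s = np.sum((stat - c_s) ** 2, axis=1)
    pooled_rms = np.sqrt(np.concatenate([d2_m, d2_s]).mean())
    dist = float(np.linalg.norm(c_m - c_s))
    return dist / pooled_rms if pooled_rms > 0 else np.inf
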