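"""Synthetic cohorts: roaming matrices with planted individuality structure,
frame-level trajectories with developmental stages and lethargus, and
single-worm grayscale frames.

The matrix-level generator plants known "individuality dimensions": each
individual i draws a coefficient c_{i,d} ~ Normal(0, strength_d) for each
archetype loading pattern, and its roaming fraction in bin k is

    p_{i,k} = stress_s(k) * logistic(baseline_k + sum_d c_{i,d} u_d[k] + eps_{i,k})

with eps iid Normal(0, noise_sd). The loadings u_d are the orthonormal
archetype directions rescaled to unit per-bin RMS (u_d = sqrt(K) a_d for K
bins), so a strength is the per-bin signal-to-noise ratio of its dimension.
The logistic link keeps fractions in [0, 1]; stage-dependent stress factors
scale mean roaming propensity multiplicatively so downstream
relative-effect estimates recover them directly. Planted coefficients are
returned for recovery tests.

Trajectory-level generation draws alternating exponential roam/dwell
episodes per stage, turns them into an x-y random walk with state- and
stage-dependent speed and heading-change statistics, and inserts near-zero
speed lethargus spans between stages, giving the stage detector unambiguous
targets. All generators are reproducible from a single seed via spawned
substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "PopulationSpec",
    "IndividualityStructure",
    "StressEffectProfile",
    "KinematicParams",
    "make_archetypes",
    "generate_roaming_matrix",
    "generate_state_sequence",
    "generate_trajectory",
    "generate_worm_frame",
]

#: default per-stage baseline log-odds of roaming (L1..adult); roaming
#: propensity rises with age
DEFAULT_STAGE_BASELINE = (-1.1, -0.6, -0.2, 0.2, 0.4)


@dataclass
class PopulationSpec:
    """Cohort layout: who is measured where, under which condition."""

    n_individuals: int = 456
    n_experiments: int = 1
    conditions: dict[str, int] | None = None  # label -> count; default one condition
    n_stages: int = 5
    bins_per_stage_fine: int = 75
    bins_per_stage_rank: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.n_individuals, self.n_experiments, self.n_stages) < 1:
            raise ValueError("counts must be positive")
        if min(self.bins_per_stage_fine, self.bins_per_stage_rank) < 1:
            raise ValueError("bins per stage must be positive")
        if self.conditions is None:
            self.conditions = {"control": self.n_individuals}
        if sum(self.conditions.values()) != self.n_individuals:
            raise ValueError("per-condition counts must sum to n_individuals")

    @property
    def n_rank_bins(self) -> int:
        return self.n_stages * self.bins_per_stage_rank

    def labels(self) -> pd.DataFrame:
        """Individual, experiment (round-robin) and condition labels."""
        conds = np.concatenate(
            [np.repeat(label, count) for label, count in self.conditions.items()]
        )
        return pd.DataFrame(
            {
                "individual_id": np.arange(self.n_individuals),
                "experiment_id": np.arange(self.n_individuals) % self.n_experiments,
                "condition": conds,
            }
        )


def make_archetypes(
    names: list[str], n_stages: int = 5, bins_per_stage: int = 10
) -> np.ndarray:
    """Orthonormal loading patterns over the rank bins.

    Built-ins: ``homogeneous`` (constant sign — a consistent individual),
    ``single_switch`` (sign flip at the L3 midpoint), ``double_switch``
    (flips at the L1/L2 and L4/adult boundaries, so L1 and adulthood share
    a sign). Raw sign patterns are Gram-Schmidt orthonormalized in the
    order given.
    """
    k = n_stages * bins_per_stage
    stage = np.arange(k) // bins_per_stage
    raw = []
    for name in names:
        if name == "homogeneous":
            v = np.ones(k)
        elif name == "single_switch":
            v = np.where(np.arange(k) < k / 2, 1.0, -1.0)
        elif name == "double_switch":
            v = np.where((stage == 0) | (stage == n_stages - 1), 1.0, -1.0)
        else:
            raise ValueError(f"unknown archetype {name!r}")
        raw.append(v)
    out = []
    for v in raw:
        for u in out:
            v = v - (v @ u) * u
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise ValueError("archetypes are linearly dependent")
        out.append(v / norm)
    return np.array(out)


@dataclass
class IndividualityStructure:
    """Planted individuality dimensions for the matrix generator."""

    archetypes: list[str] | np.ndarray = field(
        default_factory=lambda: ["homogeneous", "single_switch", "double_switch"]
    )
    strengths: tuple[float, ...] = (1.5, 1.0, 0.7)
    noise_sd: float = 1.0

    def loading_matrix(self, n_stages: int, bins_per_stage: int) -> np.ndarray:
        if isinstance(self.archetypes, np.ndarray):
            A = np.asarray(self.archetypes, dtype=float)
            A = A / np.linalg.norm(A, axis=1, keepdims=True)
        else:
            A = make_archetypes(list(self.archetypes), n_stages, bins_per_stage)
        if len(self.strengths) != A.shape[0]:
            raise ValueError("one strength per archetype required")
        if any(s < 0 for s in self.strengths):
            raise ValueError("strengths must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        G = A @ A.T
        if not np.allclose(G, np.eye(A.shape[0]), atol=1e-8):
            raise ValueError("archetypes must be mutually orthogonal")
        return A


@dataclass
class StressEffectProfile:
    """Per-stage multiplicative factors on mean roaming propensity."""

    factors: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    label: str = "none"

    def __post_init__(self):
        if any(f < 0 for f in self.factors):
            raise ValueError("stress factors must be >= 0")


def generate_roaming_matrix(
    spec: PopulationSpec,
    structure: IndividualityStructure | None = None,
    stress: StressEffectProfile | None = None,
    baseline: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Cohort roaming-fraction matrix with planted individuality structure.

    Returns ``(matrix, labels, coefficients)``: the (n_individuals,
    n_rank_bins) matrix of roaming fractions in [0, 1], the label frame
    (individual_id, experiment_id, condition), and the planted per-individual
    archetype coefficients for recovery tests.
    """
    if structure is None:
        structure = IndividualityStructure()
    k = spec.n_rank_bins
    A = structure.loading_matrix(spec.n_stages, spec.bins_per_stage_rank)
    if A.shape[1] != k:
        raise ValueError(
            f"archetype length {A.shape[1]} != n_stages x bins_per_stage_rank = {k}"
        )
    stage_of_bin = np.arange(k) // spec.bins_per_stage_rank
    if baseline is None:
        base = np.asarray(DEFAULT_STAGE_BASELINE[: spec.n_stages])[stage_of_bin]
    else:
        base = np.asarray(baseline, dtype=float)
        if base.shape != (k,):
            raise ValueError("baseline must have one value per rank bin")
    if stress is not None:
        if len(stress.factors) != spec.n_stages:
            raise ValueError("one stress factor per stage required")
        factor = np.asarray(stress.factors)[stage_of_bin]
    else:
        factor = np.ones(k)

    n = spec.n_individuals
    streams = [
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(n)
    ]
    strengths = np.asarray(structure.strengths, dtype=float)
    # loadings at unit per-bin RMS: strengths are per-bin SNR vs noise_sd
    U = A * np.sqrt(k)
    coeffs = np.empty((n, A.shape[0]))
    logits = np.empty((n, k))
    for i, rng in enumerate(streams):
        c = rng.normal(0.0, 1.0, size=A.shape[0]) * strengths
        eps = rng.normal(0.0, structure.noise_sd, size=k) if structure.noise_sd else 0.0
        coeffs[i] = c
        logits[i] = base + c @ U + eps
    matrix = factor * (1.0 / (1.0 + np.exp(-logits)))
    np.clip(matrix, 0.0, 1.0, out=matrix)
    return matrix, spec.labels(), coeffs


@dataclass
class KinematicParams:
    """Kinematic fixture parameters for trajectory-level generation.

    Speeds in µm/s, durations in hours or seconds as named. Roam speeds
    exceed dwell speeds within every stage; heading changes are small while
    roaming (fast, straight runs) and large while dwelling (frequent
    reorientation).
    """

    fps: float = 3.0
    roam_speed_mean: tuple[float, ...] = (60.0, 90.0, 110.0, 130.0, 150.0)
    roam_speed_sd: tuple[float, ...] = (10.0, 12.0, 14.0, 16.0, 18.0)
    dwell_speed_mean: tuple[float, ...] = (4.0, 5.0, 5.0, 6.0, 6.0)
    dwell_speed_sd: tuple[float, ...] = (2.0, 2.0, 2.0, 2.5, 2.5)
    roam_heading_sd: float = 1.5  # deg per frame; roaming runs are straight
    dwell_heading_sd: float = 60.0
    roam_episode_mean_s: float = 60.0
    dwell_episode_mean_s: float = 120.0
    stage_duration_h: tuple[float, ...] = (12.0, 8.0, 8.0, 10.0, 24.0)
    lethargus_duration_h: float = 0.5
    lethargus_speed_sd: float = 0.2  # well below quiescence detection levels

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for r, d in zip(self.roam_speed_mean, self.dwell_speed_mean):
            if r <= d:
                raise ValueError("roam speed mean must exceed dwell speed mean")
        if self.lethargus_duration_h <= 0:
            raise ValueError("durations must be positive")

    def scaled(self, time_scale: float) -> "KinematicParams":
        """Copy with stage/lethargus durations multiplied by ``time_scale``.

        Used to run the full five-stage pipeline on short recordings while
        preserving the ratio of lethargus to stage length.
        """
        return KinematicParams(
            fps=self.fps,
            roam_speed_mean=self.roam_speed_mean,
            roam_speed_sd=self.roam_speed_sd,
            dwell_speed_mean=self.dwell_speed_mean,
            dwell_speed_sd=self.dwell_speed_sd,
            roam_heading_sd=self.roam_heading_sd,
            dwell_heading_sd=self.dwell_heading_sd,
            roam_episode_mean_s=self.roam_episode_mean_s,
            dwell_episode_mean_s=self.dwell_episode_mean_s,
            stage_duration_h=tuple(h * time_scale for h in self.stage_duration_h),
            lethargus_duration_h=self.lethargus_duration_h * time_scale,
            lethargus_speed_sd=self.lethargus_speed_sd,
        )


def generate_state_sequence(
    params: KinematicParams,
    stage: int,
    duration_s: float,
    seed: int | np.random.Generator | None = None,
    roam_episode_mean_s: float | None = None,
    dwell_episode_mean_s: float | None = None,
) -> np.ndarray:
    """Per-frame roam(1)/dwell(0) labels from alternating exponential episodes.

    The expected roaming fraction is the renewal-theory ratio
    roam_mean / (roam_mean + dwell_mean).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not 0 <= stage < len(params.roam_speed_mean):
        raise ValueError(f"stage {stage} out of range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    roam_mean = (
        params.roam_episode_mean_s if roam_episode_mean_s is None else roam_episode_mean_s
    )
    dwell_mean = (
        params.dwell_episode_mean_s
        if dwell_episode_mean_s is None
        else dwell_episode_mean_s
    )
    n_frames = int(round(duration_s * params.fps))
    if roam_mean <= 0:
        return np.zeros(n_frames, dtype=np.int8)
    if dwell_mean <= 0:
        return np.ones(n_frames, dtype=np.int8)
    # start state from the stationary distribution of the alternating renewal
    state = int(rng.random() < roam_mean / (roam_mean + dwell_mean))
    labels = np.empty(n_frames, dtype=np.int8)
    t = 0.0
    frame = 0
    while frame < n_frames:
        mean = roam_mean if state else dwell_mean
        t += rng.exponential(mean)
        end = min(n_frames, int(round(t * params.fps)))
        labels[frame:end] = state
        frame = end
        state = 1 - state
    return labels


@dataclass
class SyntheticTrajectory:
    """A generated trajectory plus its ground truth."""

    trajectory: Trajectory
    state_labels: np.ndarray  # 1 roam, 0 dwell, -1 lethargus, per frame
    stage_of_frame: np.ndarray  # 0..4, -1 during lethargus
    lethargus_spans: list[tuple[int, int]]
    roaming_fraction_by_stage: np.ndarray


def generate_trajectory(
    params: KinematicParams,
    state_sequences: list[np.ndarray] | None = None,
    seed: int | None = None,
) -> SyntheticTrajectory:
    """Frame-level x-y trajectory across 5 stages with lethargus gaps.

    Speeds are drawn per frame from the state- and stage-specific normal
    distributions (clipped at 0); the heading performs a random walk with
    state-dependent step SD; lethargus spans between stages move at near-zero
    speed. Frame count is fps x total duration.
    """
    rng = np.random.default_rng(seed)
    n_stages = len(params.stage_duration_h)
    if state_sequences is None:
        state_sequences = [
            generate_state_sequence(params, s, params.stage_duration_h[s] * 3600.0, rng)
            for s in range(n_stages)
        ]
    if len(state_sequences) != n_stages:
        raise ValueError(f"expected {n_stages} state sequences")

    leth_frames = int(round(params.lethargus_duration_h * 3600.0 * params.fps))
    labels_parts: list[np.ndarray] = []
    stage_parts: list[np.ndarray] = []
    lethargus_spans: list[tuple[int, int]] = []
    pos = 0
    for s, seq in enumerate(state_sequences):
        seq = np.asarray(seq, dtype=np.int8)
        labels_parts.append(seq)
        stage_parts.append(np.full(seq.size, s, dtype=np.int8))
        pos += seq.size
        if s < n_stages - 1:
            labels_parts.append(np.full(leth_frames, -1, dtype=np.int8))
            stage_parts.append(np.full(leth_frames, -1, dtype=np.int8))
            lethargus_spans.append((pos, pos + leth_frames))
            pos += leth_frames
    labels = np.concatenate(labels_parts)
    stage_of_frame = np.concatenate(stage_parts)
    n = labels.size

    speed = np.empty(n)
    heading_sd = np.empty(n)
    for s in range(n_stages):
        roam = (stage_of_frame == s) & (labels == 1)
        dwell = (stage_of_frame == s) & (labels == 0)
        speed[roam] = rng.normal(
            params.roam_speed_mean[s], params.roam_speed_sd[s], roam.sum()
        )
        speed[dwell] = rng.normal(
            params.dwell_speed_mean[s], params.dwell_speed_sd[s], dwell.sum()
        )
    heading_sd[labels == 1] = params.roam_heading_sd
    heading_sd[labels == 0] = params.dwell_heading_sd
    leth = labels == -1
    speed[leth] = np.abs(rng.normal(0.0, params.lethargus_speed_sd, leth.sum()))
    heading_sd[leth] = params.dwell_heading_sd
    np.clip(speed, 0.0, None, out=speed)

    heading = np.cumsum(
        np.deg2rad(rng.normal(0.0, 1.0, n) * heading_sd), dtype=float
    ) + rng.uniform(0, 2 * np.pi)
    step = speed / params.fps
    x = np.concatenate([[0.0], np.cumsum(step * np.cos(heading))[:-1]])
    y = np.concatenate([[0.0], np.cumsum(step * np.sin(heading))[:-1]])
    frames = np.arange(n)
    traj = Trajectory(
        frame=frames, time_s=frames / params.fps, x_um=x, y_um=y, fps=params.fps
    )
    frac = np.array(
        [
            np.mean(seq == 1) if np.asarray(seq).size else np.nan
            for seq in state_sequences
        ]
    )
    return SyntheticTrajectory(
        trajectory=traj,
        state_labels=labels,
        stage_of_frame=stage_of_frame,
        lethargus_spans=lethargus_spans,
        roaming_fraction_by_stage=frac,
    )


def generate_worm_frame(
    area_px: int,
    image_side: int = 151,
    worm_level: float = 90.0,
    background_level: float = 200.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_blobs: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """A grayscale frame with a dark blob of ~``area_px`` pixels, plus the
    matching background frame.

    The blob is a disk centred in the frame (shifted copies for
    ``n_blobs > 1``), darker than the background as a worm appears in
    transmitted light. ``area_px = 0`` gives a uniform background frame.
    """
    if area_px < 0 or area_px >= image_side**2:
        raise ValueError("area_px must be in [0, image_side^2)")
    if worm_level >= background_level:
        raise ValueError("worm must be darker than the background")
    rng = np.random.default_rng(seed)
    background = np.full((image_side, image_side), background_level, dtype=float)
    frame = background.copy()
    if area_px > 0:
        radius = np.sqrt(area_px / (np.pi * n_blobs))
        yy, xx = np.mgrid[:image_side, :image_side]
        centers = [(image_side / 2, image_side / 2)]
        if n_blobs > 1:
            offset = image_side / 4
            centers = [
                (image_side / 2 + offset * np.cos(2 * np.pi * j / n_blobs),
                 image_side / 2 + offset * np.sin(2 * np.pi * j / n_blobs))
                for j in range(n_blobs)
            ]
        for cy, cx in centers:
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            frame[mask] = worm_level
    if noise_sd > 0:
        frame = frame + rng.normal(0.0, noise_sd, frame.shape)
        background = background + rng.normal(0.0, noise_sd, background.shape)
    return frame, background
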