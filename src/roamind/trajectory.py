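"""From raw centroid trajectories to stage-normalized roaming profiles.

The processing chain is: rolling kinematics (speed and absolute angular
velocity averaged over a 10 s window) -> lethargus detection and stage
segmentation (midpoints of the four long quiescent spans are the stage
boundaries) -> per-frame roaming/dwelling classification (a diagonal
through the speed x angular-velocity plane, with a stage-specific slope)
-> age normalization (each stage divided into a fixed number of
equal-duration time bins; roaming fraction and mean roaming speed per bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "KinematicSeries",
    "StageSegmentation",
    "StageSegmentationError",
    "ClassifierConfig",
    "BinnedBehavior",
    "rolling_kinematics",
    "detect_stages",
    "classify_states",
    "age_normalize",
    "process_trajectory",
]

ROAM, DWELL, QUIESCENT = 1, 0, -1
STAGE_NAMES = ("L1", "L2", "L3", "L4", "Adult")


class StageSegmentationError(RuntimeError):
    """Raised when a recording does not yield the expected lethargus spans."""


@dataclass
class Trajectory:
    """Frame-level centroid trajectory at a fixed frame rate.

    Positions in µm, time in seconds. Sampling must be uniform at 1/fps;
    gaps are reported, never silently filled.
    """

    frame: np.ndarray
    time_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    fps: float

    def __post_init__(self):
        for name in ("frame", "time_s", "x_um", "y_um"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time_s.size
        if not (self.frame.size == self.x_um.size == self.y_um.size == n):
            raise ValueError("trajectory columns must have equal length")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time_s.size

    def check_uniform(self, rtol: float = 1e-3) -> None:
        """Raise listing offending frames if sampling deviates from 1/fps."""
        dt = np.diff(self.time_s)
        expected = 1.0 / self.fps
        bad = np.nonzero(np.abs(dt - expected) > rtol * expected)[0]
        if bad.size:
            raise ValueError(
                f"non-uniform sampling at frame(s) {bad[:20].tolist()}"
                + ("..." if bad.size > 20 else "")
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame.astype(int),
                "time_s": self.time_s,
                "x_um": self.x_um,
                "y_um": self.y_um,
            }
        )


@dataclass
class KinematicSeries:
    """Per-frame rolling speed (µm/s) and absolute angular velocity (deg/s)."""

    speed: np.ndarray
    angular_velocity: np.ndarray
    fps: float
    window_s: float
    edge_flag: np.ndarray  # True where the rolling window was truncated

    def __len__(self) -> int:
        return self.speed.size


def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    # centered rolling mean with truncated edges
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def rolling_kinematics(traj: Trajectory, window_s: float = 10.0) -> KinematicSeries:
    """Rolling speed and absolute angular velocity of a trajectory.

    Instantaneous speed is the frame-to-frame displacement times fps; heading
    is the direction of the displacement vector, and angular velocity the
    absolute heading change per frame interval (wrapped to <= 180 deg)
    times fps. Both are then averaged over a centered rolling window of
    ``round(window_s * fps)`` frames. Frames with zero displacement keep the
    previous heading, so a stationary animal has angular velocity 0.
    """
    window = int(round(window_s * traj.fps))
    n = len(traj)
    if n < max(window, 3):
        raise ValueError("trajectory shorter than the rolling window")
    traj.check_uniform()

    dx = np.diff(traj.x_um)
    dy = np.diff(traj.y_um)
    step = np.hypot(dx, dy)  # length n-1
    inst_speed = np.empty(n)
    inst_speed[1:] = step * traj.fps
    inst_speed[0] = inst_speed[1]

    heading = np.arctan2(dy, dx)
    moving = step > 0
    if moving.any():
        # carry last defined heading through stationary frames
        idx = np.where(moving, np.arange(step.size), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(moving)
        idx[idx < 0] = first
        heading = heading[idx]
    else:
        heading = np.zeros(step.size)
    dtheta = np.diff(heading)  # length n-2
    dtheta = np.abs((dtheta + np.pi) % (2 * np.pi) - np.pi)
    inst_ang = np.zeros(n)
    inst_ang[1:-1] = np.rad2deg(dtheta) * traj.fps
    inst_ang[0] = inst_ang[1] if n > 2 else 0.0
    inst_ang[-1] = inst_ang[-2] if n > 2 else 0.0

    speed = _rolling_mean(inst_speed, window)
    ang = _rolling_mean(inst_ang, window)
    half = window // 2
    edge = np.zeros(n, dtype=bool)
    edge[:half] = True
    if half:
        edge[-half:] = True
    return KinematicSeries(
        speed=speed,
        angular_velocity=ang,
        fps=traj.fps,
        window_s=window_s,
        edge_flag=edge,
    )


@dataclass
class StageSegmentation:
    """Stage boundaries of one recording.

    ``boundaries`` are the four lethargus-midpoint frames separating
    L1|L2|L3|L4|Adult; ``lethargus_spans`` the detected quiescent spans
    (frame intervals, end-exclusive) excluded from behavioral fractions.
    """

    hatch_frame: int
    boundaries: np.ndarray  # 4 lethargus midpoints, strictly increasing
    n_frames: int
    lethargus_spans: list[tuple[int, int]] = field(default_factory=list)
    stage_names: tuple[str, ...] = STAGE_NAMES

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=int)
        if np.any(np.diff(b) <= 0) or b[0] <= self.hatch_frame or b[-1] >= self.n_frames:
            raise ValueError("boundaries must be increasing and interior")
        self.boundaries = b

    @property
    def n_stages(self) -> int:
        return self.boundaries.size + 1

    def stage_edges(self) -> np.ndarray:
        return np.concatenate([[self.hatch_frame], self.boundaries, [self.n_frames]])

    def stage_of_frame(self) -> np.ndarray:
        """Stage index (0..4) per frame; frames before hatching get stage 0."""
        return np.searchsorted(
            self.boundaries, np.arange(self.n_frames), side="right"
        )

    def quiescent_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_frames, dtype=bool)
        for a, b in self.lethargus_spans:
            mask[a:b] = True
        return mask


def detect_stages(
    kin: KinematicSeries,
    quiescence_speed_quantile: float = 0.05,
    min_quiescence_min: float = 20.0,
    smooth_frames: int = 300,
    n_boundaries: int = 4,
) -> StageSegmentation:
    """Find lethargus spans and define stage boundaries at their midpoints.

    The rolling speed is further smoothed over ``smooth_frames`` frames;
    spans where the smoothed speed falls below the given quantile of the
    individual's own smoothed-speed distribution, lasting at least
    ``min_quiescence_min`` minutes, are candidate lethargus periods. The
    four longest are taken as the molts; each contributes its midpoint
    frame as a stage boundary.
    """
    sm = _rolling_mean(kin.speed, smooth_frames)
    thr = np.quantile(sm, quiescence_speed_quantile)
    below = sm <= thr
    min_frames = int(round(min_quiescence_min * 60.0 * kin.fps))

    spans = []
    d = np.diff(below.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if below[0]:
        starts = np.concatenate([[0], starts])
    if below[-1]:
        ends = np.concatenate([ends, [below.size]])
    for a, b in zip(starts, ends):
        if b - a >= min_frames:
            spans.append((int(a), int(b)))
    if len(spans) < n_boundaries:
        raise StageSegmentationError(
            f"found {len(spans)} quiescent span(s) >= {min_quiescence_min} min, "
            f"need {n_boundaries}; individual should be excluded"
        )
    spans.sort(key=lambda ab: ab[1] - ab[0], reverse=True)
    spans = sorted(spans[:n_boundaries])
    boundaries = np.array([(a + b) // 2 for a, b in spans])
    return StageSegmentation(
        hatch_frame=0,
        boundaries=boundaries,
        n_frames=len(kin),
        lethargus_spans=spans,
    )


@dataclass
class ClassifierConfig:
    """Diagonal roaming/dwelling classifier in the speed x turning plane.

    The 50 x 50 joint histogram of 10 s speed (bin width 7.59 µm/s) and
    absolute angular velocity (bin width 3.6 deg/s) is split by a diagonal
    of stage-specific slope; points below the diagonal (fast and straight)
    are roaming. Since the diagonal is linear the per-bin rule reduces to a
    per-frame inequality on the continuous values.
    """

    speed_bin_um_s: float = 7.59
    angular_velocity_bin_deg_s: float = 3.6
    slopes: tuple[float, ...] = (5.0, 2.5, 2.3, 2.0, 1.5)
    n_hist_bins: int = 50

    def __post_init__(self):
        if self.speed_bin_um_s <= 0 or self.angular_velocity_bin_deg_s <= 0:
            raise ValueError("bin widths must be positive")

    def slope_for_stage(self, stage: int) -> float:
        try:
            return self.slopes[stage]
        except IndexError:
            raise ValueError(f"no classifier slope configured for stage {stage}")


def classify_states(
    kin: KinematicSeries,
    seg: StageSegmentation,
    cfg: ClassifierConfig | None = None,
) -> np.ndarray:
    """Per-frame labels: 1 roaming, 0 dwelling, -1 quiescent (lethargus).

    A frame in stage s is roaming iff speed / speed_bin >
    slope_s x (angular_velocity / angvel_bin). Frames on the diagonal, and
    frames whose speed falls in the lowest histogram bin, are dwelling.
    Lethargus frames are labelled quiescent and excluded downstream.
    """
    cfg = cfg or ClassifierConfig()
    if len(kin) != seg.n_frames:
        raise ValueError("kinematics and segmentation cover different frame ranges")
    stage = seg.stage_of_frame()
    if stage.max() >= len(cfg.slopes):
        raise ValueError(f"no classifier slope configured for stage {stage.max()}")
    slopes = np.asarray(cfg.slopes)[stage]
    s_units = kin.speed / cfg.speed_bin_um_s
    a_units = kin.angular_velocity / cfg.angular_velocity_bin_deg_s
    roam = (s_units > slopes * a_units) & (s_units >= 1.0)
    labels = roam.astype(np.int8)
    labels[seg.quiescent_mask()] = QUIESCENT
    return labels


@dataclass
class BinnedBehavior:
    """Age-normalized per-bin roaming fraction and mean roaming speed."""

    roaming_fraction: np.ndarray  # NaN where a bin has no scored frames
    roaming_speed: np.ndarray  # NaN where a bin has no roaming frames
    bins_per_stage: int
    stage_of_bin: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.roaming_fraction.size


def age_normalize(
    labels: np.ndarray,
    kin: KinematicSeries,
    seg: StageSegmentation,
    bins_per_stage: int = 75,
) -> BinnedBehavior:
    """Divide each stage into equal-duration bins and summarize behavior.

    Per bin: roaming fraction = roaming frames / (roaming + dwelling frames)
    (quiescent frames excluded from both counts) and mean rolling speed over
    the roaming frames. Empty bins are flagged as NaN.
    """
    labels = np.asarray(labels)
    if labels.size != seg.n_frames:
        raise ValueError("labels and segmentation cover different frame ranges")
    edges = seg.stage_edges()
    n_stages = seg.n_stages
    frac = np.full(n_stages * bins_per_stage, np.nan)
    rspeed = np.full(n_stages * bins_per_stage, np.nan)
    stage_of_bin = np.repeat(np.arange(n_stages), bins_per_stage)
    for s in range(n_stages):
        bin_edges = np.linspace(edges[s], edges[s + 1], bins_per_stage + 1)
        bin_edges = np.round(bin_edges).astype(int)
        for j in range(bins_per_stage):
            sl = slice(bin_edges[j], bin_edges[j + 1])
            lab = labels[sl]
            n_roam = int(np.sum(lab == ROAM))
            n_dwell = int(np.sum(lab == DWELL))
            k = s * bins_per_stage + j
            if n_roam + n_dwell > 0:
                frac[k] = n_roam / (n_roam + n_dwell)
            if n_roam > 0:
                rspeed[k] = float(np.mean(kin.speed[sl][lab == ROAM]))
    return BinnedBehavior(
        roaming_fraction=frac,
        roaming_speed=rspeed,
        bins_per_stage=bins_per_stage,
        stage_of_bin=stage_of_bin,
    )


def process_trajectory(
    traj: Trajectory,
    bins_per_stage: int = 75,
    cfg: ClassifierConfig | None = None,
    window_s: float = 10.0,
    **detect_kwargs,
) -> tuple[BinnedBehavior, StageSegmentation, np.ndarray]:
    """Full chain: kinematics -> stages -> classification -> binning."""
    kin = rolling_kinematics(traj, window_s=window_s)
    seg = detect_stages(kin, **detect_kwargs)
    labels = classify_states(kin, seg, cfg)
    binned = age_normalize(labels, kin, seg, bins_per_stage)
    return binned, seg, labels
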