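"""Plain-text I/O: trajectory TSV, roaming-matrix CSV, model JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .individuality import WeightedPCA
from .trajectory import Trajectory

__all__ = [
    "read_trajectory_tsv",
    "write_trajectory_tsv",
    "read_roaming_matrix",
    "write_roaming_matrix",
    "write_pc_model",
    "read_pc_model",
]

TRAJ_COLUMNS = ["frame", "time_s", "x_um", "y_um"]


def write_trajectory_tsv(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False)


def read_trajectory_tsv(path: str | Path, fps: float | None = None) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} lacks column(s) {missing}")
    if fps is None:
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        fps = 1.0 / dt
    return Trajectory(
        frame=df["frame"].to_numpy(),
        time_s=df["time_s"].to_numpy(),
        x_um=df["x_um"].to_numpy(),
        y_um=df["y_um"].to_numpy(),
        fps=fps,
    )


def write_roaming_matrix(
    matrix: np.ndarray,
    labels: pd.DataFrame,
    matrix_path: str | Path,
    labels_path: str | Path,
) -> None:
    """Matrix CSV with a header row of bin labels, plus a labels CSV."""
    cols = [f"bin_{k}" for k in range(np.asarray(matrix).shape[1])]
    pd.DataFrame(np.asarray(matrix), columns=cols).to_csv(matrix_path, index=False)
    labels.to_csv(labels_path, index=False)


def read_roaming_matrix(
    matrix_path: str | Path, labels_path: str | Path
) -> tuple[np.ndarray, pd.DataFrame]:
    matrix = pd.read_csv(matrix_path).to_numpy(dtype=float)
    labels = pd.read_csv(labels_path)
    if matrix.shape[0] != len(labels):
        raise ValueError("matrix and labels disagree on the number of individuals")
    return matrix, labels


def write_pc_model(model: WeightedPCA, path: str | Path, **metadata) -> None:
    payload = {
        "components": model.components_.tolist(),
        "explained_variance": model.explained_variance_.tolist(),
        "explained_variance_ratio": model.explained_variance_ratio_.tolist(),
        "center": model.center,
        "mean": model.mean_.tolist(),
        **metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_pc_model(path: str | Path) -> WeightedPCA:
    payload = json.loads(Path(path).read_text())
    model = WeightedPCA(center=payload.get("center", False))
    model.components_ = np.asarray(payload["components"], dtype=float)
    model.explained_variance_ = np.asarray(payload["explained_variance"], dtype=float)
    model.explained_variance_ratio_ = np.asarray(
        payload["explained_variance_ratio"], dtype=float
    )
    model.mean_ = np.asarray(payload["mean"], dtype=float)
    model.weights_ = None
    model.n_features_in_ = model.components_.shape[1]
    return model
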