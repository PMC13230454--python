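"""Ordered endocardial contour sequences and their on-disk formats.

A contour is 49 ordered (x, y) points along the LV endocardium, running
basal-septal (index 0) through the apex (index 24) to basal-lateral
(index 48).  Coordinates are 0-based pixels, x = column, y = row, origin
at the top-left of the frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_POINTS = 49
APEX_INDEX = 24

__all__ = ["ContourSequence", "N_POINTS", "APEX_INDEX"]


@dataclass
class ContourSequence:
    """Per-frame ordered 49-point contours.

    points: float array (n_frames, 49, 2) of (x, y) pixel coordinates
    frame_indices: original video frame index of each row
    """

    points: np.ndarray
    frame_indices: np.ndarray = field(default=None)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[1:] != (N_POINTS, 2):
            raise ValueError(
                f"points must be (n_frames, {N_POINTS}, 2), got {self.points.shape}")
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.points))
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if len(self.frame_indices) != len(self.points):
            raise ValueError("frame_indices length must match points")

    def __len__(self):
        return len(self.points)

    # ------------------------------------------------------------------
    def to_csv(self, path) -> None:
        n, k, _ = self.points.shape
        df = pd.DataFrame({
            "frame": np.repeat(self.frame_indices, k),
            "point_index": np.tile(np.arange(k), n),
            "x": self.points[:, :, 0].ravel(),
            "y": self.points[:, :, 1].ravel(),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ContourSequence":
        df = pd.read_csv(path)
        frames = np.unique(df["frame"].to_numpy())
        pts = np.empty((len(frames), N_POINTS, 2))
        for i, f in enumerate(frames):
            sub = df[df["frame"] == f].sort_values("point_index")
            if len(sub) != N_POINTS:
                raise ValueError(f"frame {f} has {len(sub)} points, expected {N_POINTS}")
            pts[i, :, 0] = sub["x"].to_numpy()
            pts[i, :, 1] = sub["y"].to_numpy()
        return cls(pts, frames)

    def to_json(self, path) -> None:
        payload = {
            "frame_indices": self.frame_indices.tolist(),
            "points": self.points.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ContourSequence":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.asarray(payload["points"]),
                   np.asarray(payload["frame_indices"]))
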