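"""Optimisation loop and contour-consistent augmentation.

Training minimises the mean squared contour-point error with Adam
(learning rate 1e-4, beta1 "momentum" 0.9, weight decay 1e-4 in coupled
L2 form).  Augmentation applies one photometric and one geometric
transform per clip — identical across the frames of the clip and pushed
through the contour coordinates, so inputs and targets stay aligned:

* brightness: additive Gaussian with variance 75 on the 8-bit scale
  (sigma = sqrt(75) by default; a sigma = 75 reading is selectable);
* contrast: scaling by 1 +/- U(0, 0.3) about the clip mean;
* geometry: shift up to 6.25% of the side, isotropic scale within
  +/-20%, rotation within +/-40 degrees, all about the frame centre.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import AffineTransform, warp

from .head import ContourModel, mse_loss
from .nn import Adam, Tensor

__all__ = ["TrainConfig", "AugmentParams", "augment", "fit"]


@dataclass
class AugmentParams:
    """Bounds of the random clip transforms (zero disables a transform)."""

    brightness_variance: float = 75.0  # 8-bit scale
    contrast_factor: float = 0.3
    max_shift_frac: float = 0.0625
    max_scale_frac: float = 0.20
    max_rotation_deg: float = 40.0
    #: "variance": additive sigma = sqrt(brightness_variance);
    #: "sigma": brightness_variance is used as sigma directly
    brightness_mode: str = "variance"

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9  # Adam's first-moment decay ("momentum")
    weight_decay: float = 1e-4
    epochs: int = 50
    seed: int = 0
    augment: bool = False
    augment_params: AugmentParams = field(default_factory=AugmentParams)
    checkpoint_dir: str | None = None
    log_path: str | None = None


def _geometric_matrix(rng: np.random.Generator, ap: AugmentParams,
                      shape) -> np.ndarray:
    """Random shift/scale/rotation about the frame centre, as 3x3 (x, y)."""
    h, w = shape
    angle = np.deg2rad(rng.uniform(-ap.max_rotation_deg, ap.max_rotation_deg)) \
        if ap.max_rotation_deg else 0.0
    scale = 1.0 + rng.uniform(-ap.max_scale_frac, ap.max_scale_frac) \
        if ap.max_scale_frac else 1.0
    if ap.max_shift_frac:
        dx = rng.uniform(-ap.max_shift_frac, ap.max_shift_frac) * w
        dy = rng.uniform(-ap.max_shift_frac, ap.max_shift_frac) * h
    else:
        dx = dy = 0.0
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    c, s = np.cos(angle), np.sin(angle)
    rs = scale * np.array([[c, -s], [s, c]])
    m = np.eye(3)
    m[:2, :2] = rs
    m[:2, 2] = [cx - rs[0] @ [cx, cy] + dx, cy - rs[1] @ [cx, cy] + dy]
    return m


def augment(clip: np.ndarray, points: np.ndarray, ap: AugmentParams,
            rng_seed) -> tuple:
    """One random photometric + geometric transform of a clip.

    clip: (T, H, W) frames in [0, 1] or [0, 255]; points: (T, 49, 2)
    contour coordinates.  The same transform is applied to every frame
    and mapped through the contours; transformed points falling outside
    the frame are clipped to its boundary so loss targets stay finite.
    With all bounds zero this is the identity.
    """
    rng = np.random.default_rng(rng_seed) \
        if rng_seed is None or isinstance(rng_seed, (int, np.integer)) \
        else rng_seed  # generator-like objects pass through

    clip = np.asarray(clip, dtype=float)
    pts = np.asarray(points, dtype=float).copy()
    t, h, w = clip.shape
    eight_bit = clip.max() > 1.0
    unit = 1.0 if eight_bit else 1.0 / 255.0

    out = clip.copy()
    if ap.brightness_variance:
        sigma = (np.sqrt(ap.brightness_variance)
                 if ap.brightness_mode == "variance"
                 else ap.brightness_variance)
        out = out + rng.normal(0.0, sigma) * unit
    if ap.contrast_factor:
        c = 1.0 + rng.uniform(-ap.contrast_factor, ap.contrast_factor)
        mean = out.mean()
        out = mean + c * (out - mean)
    out = np.clip(out, 0.0, 255.0 if eight_bit else 1.0)

    m = _geometric_matrix(rng, ap, (h, w))
    if not np.allclose(m, np.eye(3)):
        tform = AffineTransform(matrix=m)
        warped = np.empty_like(out)
        for i in range(t):
            warped[i] = warp(out[i], tform.inverse, order=1,
                             preserve_range=True, mode="constant")
        out = warped
        ones = np.ones((*pts.shape[:2], 1))
        hom = np.concatenate([pts, ones], axis=-1)
        pts = hom @ m.T[:, :2]
    pts[..., 0] = np.clip(pts[..., 0], 0, w - 1)
    pts[..., 1] = np.clip(pts[..., 1], 0, h - 1)
    return out, pts


def fit(model: ContourModel, dataset, tc: TrainConfig | None = None):
    """Minimise the contour MSE over a dataset of (clip, points) pairs.

    dataset: sequence of ``(frames, points)`` with frames (T, H, W) in
    [0, 1] and points (T, 49, 2).  Runs one Adam step per clip; returns
    ``(model, history)`` where history is the per-epoch mean loss.
    Aborts with a diagnostic if the loss turns non-finite.
    """
    if tc is None:
        tc = TrainConfig()
    rng = np.random.default_rng(tc.seed)
    opt = Adam(model.parameters(), lr=tc.learning_rate, beta1=tc.beta1,
               weight_decay=tc.weight_decay)
    history = []
    best = np.inf
    ckpt = Path(tc.checkpoint_dir) if tc.checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)
    for epoch in range(tc.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for i in order:
            frames, points = dataset[i]
            if tc.augment:
                frames, points = augment(frames, points, tc.augment_params, rng)
            chunk = np.broadcast_to(np.asarray(frames, dtype=np.float32),
                                    (3, *np.shape(frames)))
            opt.zero_grad()
            pred = model(Tensor(chunk))
            loss = mse_loss(pred, points)
            val = float(loss.data)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, sample {i}: {val}")
            loss.backward()
            opt.step()
            losses.append(val)
        history.append(float(np.mean(losses)))
        if ckpt:
            model.save(ckpt / "last.npz")
            if history[-1] < best:
                best = history[-1]
                model.save(ckpt / "best.npz")
    if tc.log_path:
        with open(tc.log_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "loss"])
            writer.writerows(enumerate(history, start=1))
    return model, history
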