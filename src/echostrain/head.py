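"""FCN-style multiscale fusion and the 49-point contour regressor.

The three encoder outputs are channel-unified to width D (default 1024)
by per-frame 3x3 convolutions, progressively upsampled and summed down
to the 28x28 grid, globally average-pooled per time step, temporally
interpolated from 32 token steps to the 64 clip frames, and mapped by a
single linear layer to 98 scalars (49 x-coordinates then 49
y-coordinates) per frame.
"""

from __future__ import annotations

import numpy as np

from .contours import ContourSequence, N_POINTS
from .nn import Conv2d, Linear, Module, Tensor, no_grad, upsample2x
from .swin import ModelConfig, VideoSwinEncoder

__all__ = [
    "FusionHead",
    "ContourModel",
    "mse_loss",
    "temporal_interp_matrix",
    "stitch_chunks",
]


def temporal_interp_matrix(t_in: int, t_out: int) -> np.ndarray:
    """Linear-interpolation matrix (t_out, t_in) between frame centres.

    Output frame j sits at source coordinate (j + 0.5) * t_in / t_out - 0.5
    (the half-pixel-centre convention), clipped to the valid range, so a
    constant input maps to the same constant output.
    """
    m = np.zeros((t_out, t_in))
    for j in range(t_out):
        p = np.clip((j + 0.5) * t_in / t_out - 0.5, 0, t_in - 1)
        lo = int(np.floor(p))
        hi = min(lo + 1, t_in - 1)
        w = p - lo
        m[j, lo] += 1 - w
        m[j, hi] += w
    return m


class FusionHead(Module):
    """unify channels -> progressive upsample+add -> pool -> linear."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.fusion_dim
        dims = cfg.stage_dims
        self.conv1 = Conv2d(dims[0], d, rng)
        self.conv2 = Conv2d(dims[1], d, rng)
        self.conv3 = Conv2d(dims[2], d, rng)
        self.head = Linear(d, 2 * cfg.n_points, rng)
        # start predictions at the frame centre
        self.head.bias.data[:] = 0.5
        self.n_points = cfg.n_points
        self.output_scale = cfg.output_scale

    @staticmethod
    def _conv(conv: Conv2d, f: Tensor) -> Tensor:
        """Apply a 2D conv per time step: (T, H, W, C) -> (T, D, H, W)."""
        return conv(f.transpose(0, 3, 1, 2))

    def unify_channels(self, f1: Tensor, f2: Tensor, f3: Tensor):
        return (self._conv(self.conv1, f1), self._conv(self.conv2, f2),
                self._conv(self.conv3, f3))

    @staticmethod
    def fuse(f1u: Tensor, f2u: Tensor, f3u: Tensor) -> Tensor:
        """Progressive x2 upsampling and addition onto the finest grid."""
        f2p = f2u + upsample2x(f3u)
        return f1u + upsample2x(f2p)  # (T, D, H1, W1)

    def regress(self, fused: Tensor, n_frames: int) -> Tensor:
        """(T, D, H, W) fused map -> (n_frames, 49, 2) coordinates."""
        z = fused.mean(axis=(2, 3))  # (T, D) global average pool
        m = Tensor(temporal_interp_matrix(z.shape[0], n_frames))
        z = m @ z  # (n_frames, D)
        y = self.head(z) * self.output_scale  # (n_frames, 98): x block, y block
        k = self.n_points
        xy = y.reshape(n_frames, 2, k)
        return xy.transpose(0, 2, 1)

    def forward(self, feats, n_frames: int) -> Tensor:
        f1u, f2u, f3u = self.unify_channels(*feats)
        return self.regress(self.fuse(f1u, f2u, f3u), n_frames)


class ContourModel(Module):
    """Encoder + fusion head: one chunk in, one contour per frame out."""

    def __init__(self, cfg: ModelConfig = None,
                 rng: np.random.Generator | None = None):
        if cfg is None:
            cfg = ModelConfig()
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder = VideoSwinEncoder(cfg, rng)
        self.fusion = FusionHead(cfg, rng)

    def forward(self, chunk) -> Tensor:
        """(3, T, H, W) chunk -> (T, 49, 2) contour tensor."""
        chunk = Tensor._wrap(chunk)
        n_frames = chunk.shape[1]
        feats = self.encoder.encode(chunk)
        return self.fusion(feats, n_frames)

    def predict(self, chunk) -> np.ndarray:
        with no_grad():
            return self.forward(Tensor(np.asarray(chunk))).data

    def predict_video(self, batch) -> ContourSequence:
        """Run every chunk of a ChunkBatch and stitch the overlaps."""
        preds = [self.predict(c) for c in batch.data]
        pts = stitch_chunks(preds, batch.chunk_starts, batch.n_original_frames)
        return ContourSequence(pts)


def mse_loss(pred, gt):
    """Mean over frames of the mean squared point-to-point distance.

    L = (1/T) sum_t (1/49) sum_i ||y_ti - yhat_ti||^2.  Accepts Tensors
    (differentiable) or arrays; frame counts must match.
    """
    pred = Tensor._wrap(pred)
    gt = Tensor._wrap(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    d = pred - gt
    return (d * d).sum(axis=-1).mean()


def stitch_chunks(preds, chunk_starts, n_frames: int) -> np.ndarray:
    """Merge per-chunk (T, 49, 2) predictions into one per-frame array.

    On the 10 overlapped frames the later chunk's prediction wins (it has
    more forward context); padded frames beyond the video end are dropped.
    """
    out = np.zeros((n_frames, N_POINTS, 2))
    for pred, start in zip(preds, chunk_starts):
        pred = np.asarray(pred)
        stop = min(start + pred.shape[0], n_frames)
        out[start:stop] = pred[:stop - start]
    return out
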