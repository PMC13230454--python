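"""Video loading, normalisation and chunking.

Raw echo clips (multi-frame DICOM, or AVI/MP4 when an ffmpeg backend is
available) are converted to 8-bit grayscale, centre-cropped to a square
of side min(H, W), resized to 224x224 (bilinear), scaled to [0, 1] and
cut into 64-frame chunks with a 10-frame overlap; a chunk running past
the end of the video repeats the final frame.  Chunks are replicated to
three channels and stacked as (chunk, 3, 64, 224, 224).

Coordinates follow the 0-based x = column, y = row convention with the
origin at the top-left; :class:`CoordinateMap` records the crop offset
and scale so annotations can be mapped into and out of the 224x224
model frame (half-pixel-centre convention, exact affine round trip).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

TARGET_SIZE = 224
CHUNK_LEN = 64
CHUNK_OVERLAP = 10
CHUNK_STRIDE = CHUNK_LEN - CHUNK_OVERLAP

__all__ = [
    "FrameSequence",
    "ChunkBatch",
    "CoordinateMap",
    "load_video",
    "normalize_and_resize",
    "chunk",
]


@dataclass
class FrameSequence:
    """Ordered grayscale frames of one echo video.

    frames: (n, H, W) array, 8-bit semantics (values within [0, 255];
        normalised sequences use [0, 1], a subset of that range)
    frame_rate: acquisition rate in Hz (None when the source lacks it)
    pixel_spacing: mm per pixel (None when unknown)
    """

    frames: np.ndarray
    frame_rate: float | None = None
    pixel_spacing: float | None = None
    source_id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) == 0:
            raise ValueError("frames must be a nonempty (n, H, W) stack")
        if self.frames.min() < 0 or self.frames.max() > 255:
            raise ValueError("intensities must lie within [0, 255]")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self):
        return self.frames.shape[1:]


@dataclass(frozen=True)
class CoordinateMap:
    """Affine map between source pixels and the 224x224 model frame."""

    x_offset: float
    y_offset: float
    scale: float

    def to_model(self, points: np.ndarray) -> np.ndarray:
        """(…, 2) source (x, y) -> model coordinates."""
        pts = np.asarray(points, dtype=float)
        off = np.array([self.x_offset, self.y_offset])
        return (pts - off + 0.5) * self.scale - 0.5

    def to_source(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        off = np.array([self.x_offset, self.y_offset])
        return (pts + 0.5) / self.scale - 0.5 + off


@dataclass
class ChunkBatch:
    """Pre-processed clips stacked for the encoder.

    data: (n_chunks, 3, 64, 224, 224) float array in [0, 1]
    chunk_starts: original frame index at which each chunk begins
    """

    data: np.ndarray
    chunk_starts: list
    n_original_frames: int
    coordinate_map: CoordinateMap | None = None
    frame_rate: float | None = None
    pixel_spacing: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5 or self.data.shape[1] != 3 \
                or self.data.shape[2] != CHUNK_LEN:
            raise ValueError(
                f"data must be (n, 3, {CHUNK_LEN}, H, W), got {self.data.shape}")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("chunk values must lie in [0, 1]")
        diffs = np.diff(self.chunk_starts)
        if len(diffs) and not np.all(diffs == CHUNK_STRIDE):
            raise ValueError(f"chunk starts must step by {CHUNK_STRIDE}")

    def save(self, path) -> None:
        """Portable container: .npz array plus a JSON sidecar."""
        path = str(path)
        np.savez_compressed(path if path.endswith(".npz") else path + ".npz",
                            data=self.data.astype(np.float32))
        meta = {
            "chunk_starts": [int(s) for s in self.chunk_starts],
            "n_original_frames": int(self.n_original_frames),
            "frame_rate": self.frame_rate,
            "pixel_spacing": self.pixel_spacing,
        }
        if self.coordinate_map is not None:
            meta["coordinate_map"] = {
                "x_offset": self.coordinate_map.x_offset,
                "y_offset": self.coordinate_map.y_offset,
                "scale": self.coordinate_map.scale,
            }
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, path) -> "ChunkBatch":
        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        with np.load(base + ".npz") as f:
            data = f["data"]
        with open(base + ".json") as fh:
            meta = json.load(fh)
        cmap = None
        if meta.get("coordinate_map"):
            cmap = CoordinateMap(**meta["coordinate_map"])
        return cls(data, meta["chunk_starts"], meta["n_original_frames"],
                   cmap, meta.get("frame_rate"), meta.get("pixel_spacing"))


# ----------------------------------------------------------------------
# loading


def _to_gray8(frames: np.ndarray) -> np.ndarray:
    """Any frame stack -> (n, H, W) uint8 grayscale."""
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        rgb = frames[..., :3].astype(float)
        frames = rgb @ np.array([0.299, 0.587, 0.114])  # ITU-R BT.601 luma
    if frames.ndim != 3:
        raise ValueError(f"unsupported frame stack shape {frames.shape}")
    if frames.dtype != np.uint8:
        frames = frames.astype(float)
        lo, hi = frames.min(), frames.max()
        if hi > 255 or lo < 0:  # rescale out-of-range sources to 8 bit
            frames = (frames - lo) / max(hi - lo, 1e-12) * 255.0
        frames = np.clip(np.round(frames), 0, 255).astype(np.uint8)
    return frames


def _load_dicom(path) -> FrameSequence:
    import pydicom

    ds = pydicom.dcmread(path)
    frames = _to_gray8(ds.pixel_array)
    rate = None
    if getattr(ds, "CineRate", None):
        rate = float(ds.CineRate)
    elif getattr(ds, "RecommendedDisplayFrameRate", None):
        rate = float(ds.RecommendedDisplayFrameRate)
    elif getattr(ds, "FrameTime", None):
        rate = 1000.0 / float(ds.FrameTime)
    spacing = None
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    elif getattr(ds, "SequenceOfUltrasoundRegions", None):
        region = ds.SequenceOfUltrasoundRegions[0]
        if getattr(region, "PhysicalDeltaX", None):
            spacing = abs(float(region.PhysicalDeltaX)) * 10.0  # cm -> mm
    return FrameSequence(frames, rate, spacing, source_id=str(path))


def load_video(path) -> FrameSequence:
    """Read a multi-frame DICOM or AVI/MP4 file as 8-bit grayscale.

    Raises ``IOError`` for unreadable files and ``ValueError`` for
    sources with zero frames.
    """
    path = str(path)
    if path.lower().endswith((".avi", ".mp4", ".mov", ".mkv")):
        import imageio.v3 as iio

        try:
            frames = iio.imread(path)
            meta = iio.immeta(path)
        except Exception as exc:  # noqa: BLE001 - backend-specific errors
            raise IOError(f"could not read video {path}: {exc}") from exc
        fs = FrameSequence(_to_gray8(frames), meta.get("fps"),
                           source_id=path)
        return fs
    try:
        return _load_dicom(path)
    except (ValueError, TypeError):
        raise
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not read DICOM {path}: {exc}") from exc


# ----------------------------------------------------------------------
# normalisation and chunking


def normalize_and_resize(fs: FrameSequence):
    """Centre-crop to a square, resize to 224x224, scale to [0, 1].

    Returns the normalised sequence and the :class:`CoordinateMap` that
    carries annotations into the model frame.  Already-normalised input
    (224x224, [0, 1]) passes through unchanged.
    """
    frames = fs.frames.astype(float)
    n, h, w = frames.shape
    if (h, w) == (TARGET_SIZE, TARGET_SIZE) and frames.max() <= 1.0:
        return fs, CoordinateMap(0.0, 0.0, 1.0)
    side = min(h, w)
    y0, x0 = (h - side) // 2, (w - side) // 2
    cropped = frames[:, y0:y0 + side, x0:x0 + side]
    if side != TARGET_SIZE:
        resized = np.empty((n, TARGET_SIZE, TARGET_SIZE))
        for i in range(n):
            resized[i] = _sk_resize(cropped[i], (TARGET_SIZE, TARGET_SIZE),
                                    order=1, anti_aliasing=False,
                                    preserve_range=True)
    else:
        resized = cropped
    if fs.frames.max() > 1.0:
        resized = resized / 255.0
    scale = TARGET_SIZE / side
    out = FrameSequence(np.clip(resized, 0.0, 1.0), fs.frame_rate,
                        (fs.pixel_spacing / scale if fs.pixel_spacing else None),
                        fs.source_id)
    return out, CoordinateMap(float(x0), float(y0), scale)


def chunk_starts_for(n_frames: int) -> list:
    """Chunk start indices 0, 54, 108, ... until the video is covered."""
    starts = [0]
    while starts[-1] + CHUNK_LEN < n_frames:
        starts.append(starts[-1] + CHUNK_STRIDE)
    return starts


def chunk(fs: FrameSequence, coordinate_map: CoordinateMap | None = None
          ) -> ChunkBatch:
    """Cut a normalised sequence into overlapping 64-frame chunks."""
    frames = np.asarray(fs.frames, dtype=np.float32)
    if frames.shape[1:] != (TARGET_SIZE, TARGET_SIZE):
        raise ValueError("chunk() expects a 224x224-normalised sequence")
    if frames.max() > 1.0:
        raise ValueError("chunk() expects values in [0, 1]")
    n = len(frames)
    starts = chunk_starts_for(n)
    chunks = np.empty((len(starts), 3, CHUNK_LEN, TARGET_SIZE, TARGET_SIZE),
                      dtype=np.float32)
    for ci, s in enumerate(starts):
        seg = frames[s:s + CHUNK_LEN]
        if len(seg) < CHUNK_LEN:  # repeat the final frame to fill the chunk
            pad = np.repeat(seg[-1:], CHUNK_LEN - len(seg), axis=0)
            seg = np.concatenate([seg, pad], axis=0)
        chunks[ci] = seg[None].repeat(3, axis=0)
    return ChunkBatch(chunks, starts, n, coordinate_map,
                      fs.frame_rate, fs.pixel_spacing)
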