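"""Synthetic pulsating-ventricle phantom with exact ground truth.

The phantom emulates a grayscale apical-view clip: a dark half-elliptical
LV cavity inside bright myocardial tissue with multiplicative
Rayleigh-like speckle.  The cavity contour follows a cosine length curve

    L(t) = L0 * (1 - s * (0.5 - 0.5 cos(2 pi t / F)))

so end-diastole falls at cycle starts, end-systole at half cycles, and
the true GLS is -100 s by construction.  Ground-truth 49-point contours
are sampled at equal arc length from basal-septal over the apex to
basal-lateral and rescaled so their chord-sum length equals L(t) to
machine precision; reference masks, ED/ES indices and the configured
GLS are recorded alongside.

Geometry is a deterministic function of the configuration; the seed
only drives the speckle texture (and the optional noise added to
standalone length curves), so two phantoms differing only in seed share
identical truth contours.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as _sk_polygon

from .contours import ContourSequence, N_POINTS
from .preprocess import FrameSequence
from .strain import LengthSeries

__all__ = [
    "PhantomConfig",
    "make_length_curve",
    "make_phantom_video",
    "make_fixture_dataset",
    "write_multiframe_dicom",
]


@dataclass
class PhantomConfig:
    """Study conditions of one phantom clip.

    base_length: ED contour length L0 in pixels (a normal adult LV
        endocardium spans roughly 250-300 px at this resolution)
    shortening_frac: fractional ED->ES shortening s; true GLS = -100 s
        (0.18 is the middle of the normal clinical range)
    n_cycles / frames_per_cycle / frame_rate: two annotated cycles at
        50 Hz with a 0.8 s period, typical of clinical acquisitions
    noise_sigma: SD of Gaussian noise added to standalone length curves,
        as a fraction of L0
    speckle_density: blend weight of the multiplicative speckle texture
    brightness: tissue gray level (8-bit)
    """

    base_length: float = 260.0
    shortening_frac: float = 0.18
    n_cycles: int = 2
    frames_per_cycle: int = 40
    frame_rate: float = 50.0
    noise_sigma: float = 0.0
    speckle_density: float = 0.4
    brightness: float = 200.0
    cavity_level: float = 25.0
    aspect: float = 2.2  # long-axis / half-base-width ratio
    frame_shape: tuple = (224, 224)
    pixel_spacing: float = 0.4  # mm / px
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.shortening_frac < 1:
            raise ValueError("shortening_frac must lie in (0, 1)")
        if self.n_cycles < 1 or self.frames_per_cycle < 4:
            raise ValueError("need >= 1 cycle of >= 4 frames")

    @property
    def true_gls(self) -> float:
        return -100.0 * self.shortening_frac


# ----------------------------------------------------------------------
# length curve


def make_length_curve(cfg: PhantomConfig):
    """Cosine length series with its ED/ES indices and true GLS.

    Returns ``(LengthSeries, truth)`` where truth records the noiseless
    ED/ES frame indices and the configured GLS.
    """
    n = cfg.n_cycles * cfg.frames_per_cycle
    t = np.arange(n)
    phase = 0.5 - 0.5 * np.cos(2 * np.pi * t / cfg.frames_per_cycle)
    lengths = cfg.base_length * (1.0 - cfg.shortening_frac * phase)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        lengths = lengths + rng.normal(
            0.0, cfg.noise_sigma * cfg.base_length, size=n)
        lengths = np.maximum(lengths, 1e-6)
    truth = {
        "ed_frames": [c * cfg.frames_per_cycle for c in range(cfg.n_cycles)],
        "es_frames": [c * cfg.frames_per_cycle + cfg.frames_per_cycle // 2
                      for c in range(cfg.n_cycles)],
        "gls": cfg.true_gls,
    }
    return LengthSeries(lengths, cfg.frame_rate), truth


# ----------------------------------------------------------------------
# geometry


from functools import lru_cache


@lru_cache(maxsize=8)
def _unit_geometry(aspect: float, n_dense: int = 4096):
    """Cached (dense polyline, 49-point sampling, 49-point chord length)."""
    dense = _unit_half_ellipse(aspect, n_dense)
    unit49 = _equal_arclength_points(dense, N_POINTS)
    chord = float(np.linalg.norm(np.diff(unit49, axis=0), axis=1).sum())
    return dense, unit49, chord


def _unit_half_ellipse(aspect: float, n_dense: int = 4096) -> np.ndarray:
    """Dense half-ellipse polyline, base width 2, apex upward.

    Runs from the left (septal) base corner over the apex to the right
    (lateral) corner; y grows downward (image convention), so the apex
    has the smallest y.
    """
    theta = np.linspace(np.pi, 0.0, n_dense)
    x = np.cos(theta)
    y = -aspect * np.sin(theta)
    return np.column_stack([x, y])


def _equal_arclength_points(poly: np.ndarray, k: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], k)
    x = np.interp(targets, s, poly[:, 0])
    y = np.interp(targets, s, poly[:, 1])
    return np.column_stack([x, y])


def _truth_contours(cfg: PhantomConfig, lengths: np.ndarray) -> np.ndarray:
    """(n, 49, 2) contours whose chord-sum length equals lengths[t]."""
    h, w = cfg.frame_shape
    _, unit49, chord = _unit_geometry(cfg.aspect)
    # anchor at the base midpoint: the ventricle contracts toward its base
    anchor = np.array([w / 2.0, 0.62 * h])
    return anchor + unit49[None] * (lengths[:, None, None] / chord)


def _dense_mask(cfg: PhantomConfig, length: float) -> np.ndarray:
    """Cavity mask rasterised from the dense polyline (truth path)."""
    h, w = cfg.frame_shape
    dense, _, chord = _unit_geometry(cfg.aspect)
    dense = dense[::8]  # ~500 vertices: sub-pixel accurate, 8x faster fill
    anchor = np.array([w / 2.0, 0.62 * h])
    poly = anchor + dense * (length / chord)
    rr, cc = _sk_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    return mask


def make_phantom_video(cfg: PhantomConfig):
    """Render the phantom clip with all ground truths.

    Returns ``(FrameSequence, ContourSequence, masks, truth)`` where
    ``masks`` is a (n, H, W) boolean stack of cavity masks and ``truth``
    records lengths, ED/ES indices and GLS.
    """
    noiseless = PhantomConfig(**{**asdict(cfg), "noise_sigma": 0.0})
    ls, truth = make_length_curve(noiseless)
    contours = _truth_contours(cfg, ls.lengths)
    h, w = cfg.frame_shape
    n = len(ls)
    rng = np.random.default_rng(cfg.seed)
    frames = np.empty((n, h, w), dtype=np.uint8)
    masks = np.empty((n, h, w), dtype=bool)
    for t in range(n):
        mask = _dense_mask(cfg, ls.lengths[t])
        masks[t] = mask
        img = np.full((h, w), cfg.brightness, dtype=float)
        img[mask] = cfg.cavity_level
        img = gaussian_filter(img, sigma=1.5)  # soften the endocardial edge
        if cfg.speckle_density > 0:
            ray = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=(h, w))
            ray = gaussian_filter(ray, sigma=1.0)  # correlated grain
            img = img * (1.0 - cfg.speckle_density + cfg.speckle_density * ray)
        frames[t] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    fs = FrameSequence(frames, cfg.frame_rate, cfg.pixel_spacing,
                       source_id=f"phantom-seed{cfg.seed}")
    truth = dict(truth, lengths=ls.lengths.tolist(),
                 config=asdict(cfg))
    return fs, ContourSequence(contours), masks, truth


# ----------------------------------------------------------------------
# fixtures on disk


def write_multiframe_dicom(path, frames: np.ndarray, frame_rate: float,
                           pixel_spacing: float | None = None) -> None:
    """Write an 8-bit grayscale multi-frame ultrasound DICOM file."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    frames = np.asarray(frames, dtype=np.uint8)
    n, h, w = frames.shape
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UltrasoundMultiFrameImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = h, w
    ds.NumberOfFrames = n
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.CineRate = int(round(frame_rate))
    ds.RecommendedDisplayFrameRate = int(round(frame_rate))
    if pixel_spacing is not None:
        ds.PixelSpacing = [f"{pixel_spacing:.6f}", f"{pixel_spacing:.6f}"]
    ds.PixelData = frames.tobytes()
    ds.save_as(path, enforce_file_format=True)


def make_fixture_dataset(n_videos: int, out_dir, seed: int = 0,
                         shortening_range=(0.10, 0.25),
                         base_length_range=(230.0, 280.0),
                         val_fraction: float = 0.25,
                         **config_overrides) -> dict:
    """Write phantom videos + truths to disk and split train/val.

    Each ``video_XXX`` directory holds ``video.dcm``, ``contours.csv``
    and ``truth.json``; the deterministic split is returned (and saved
    as ``split.json``).
    """
    if n_videos < 2:
        raise ValueError("need at least two videos to split")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    dirs = []
    for i in range(n_videos):
        cfg = PhantomConfig(
            base_length=float(rng.uniform(*base_length_range)),
            shortening_frac=float(rng.uniform(*shortening_range)),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            **config_overrides,
        )
        fs, contours, _, truth = make_phantom_video(cfg)
        vdir = out_dir / f"video_{i:03d}"
        vdir.mkdir(exist_ok=True)
        write_multiframe_dicom(vdir / "video.dcm", fs.frames,
                               cfg.frame_rate, cfg.pixel_spacing)
        contours.to_csv(vdir / "contours.csv")
        with open(vdir / "truth.json", "w") as fh:
            json.dump(truth, fh)
        dirs.append(str(vdir))
    order = rng.permutation(n_videos)
    n_val = max(1, int(round(val_fraction * n_videos)))
    split = {
        "val": sorted(dirs[i] for i in order[:n_val]),
        "train": sorted(dirs[i] for i in order[n_val:]),
    }
    with open(out_dir / "split.json", "w") as fh:
        json.dump(split, fh)
    return split
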