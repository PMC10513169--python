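"""Semi-artificial training data for catheter-balloon segmentation.

A gadolinium-filled balloon at the tip of a wedge catheter appears on
T1-weighted real-time MR images as a compact hyper-intense blob.  This module
emulates that appearance by adding a rotated 2D anisotropic Gaussian to a
background image and deriving the ground-truth mask analytically (all pixels
within 1.5 standard deviations of the Gaussian profile).

Real cardiac MR backgrounds are not distributed with the package, so a
procedural phantom generator stands in for them: a low-intensity textured
background, mid-intensity chamber/vessel-like structures (where balloons are
placed), and hyper-intense fat-like bands near the border that exercise
false-positive robustness.  User-supplied real images can be substituted via
:func:`load_dataset`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GaussianCatheterParams",
    "AnnotatedFrame",
    "DynamicFrames",
    "DatasetConfig",
    "generate_phantom",
    "generate_phantom_stack",
    "gaussian_profile",
    "gaussian_field",
    "make_gt_mask",
    "simulate_catheter",
    "sample_catheter_params",
    "build_dataset",
    "build_dynamic_dataset",
    "save_dataset",
    "load_dataset",
    "save_dynamics",
    "load_dynamics",
]

#: admissible per-axis standard deviations of the balloon Gaussian (pixels)
SIGMA_CHOICES = (1.5, 2.5)
#: admissible peak amplitudes, percent of the underlying centre-pixel intensity
AMPLITUDE_CHOICES = (200, 300, 400)
#: ground-truth mask radius in standard deviations (Mahalanobis distance)
MASK_RADIUS_SD = 1.5


@dataclass(frozen=True)
class GaussianCatheterParams:
    """Parameters of one simulated balloon signal.

    The balloon is a unit-peak 2D Gaussian with diagonal covariance
    ``diag(sigma_x**2, sigma_y**2)`` rotated by ``theta_deg``
    (counter-clockwise in (row, col) space) about ``(center_row, center_col)``,
    scaled to a peak of ``amplitude_pct`` percent of the underlying image
    intensity at the centre pixel.
    """

    center_row: float
    center_col: float
    sigma_x: float
    sigma_y: float
    theta_deg: int
    amplitude_pct: int
    mask_radius_sd: float = MASK_RADIUS_SD

    def __post_init__(self) -> None:
        if self.sigma_x not in SIGMA_CHOICES or self.sigma_y not in SIGMA_CHOICES:
            raise ValueError(
                f"sigma_x/sigma_y must be in {SIGMA_CHOICES}, "
                f"got ({self.sigma_x}, {self.sigma_y})"
            )
        if not (0 <= int(self.theta_deg) <= 359) or self.theta_deg != int(self.theta_deg):
            raise ValueError(f"theta_deg must be an integer in [0, 359], got {self.theta_deg}")
        if self.amplitude_pct not in AMPLITUDE_CHOICES:
            raise ValueError(
                f"amplitude_pct must be in {AMPLITUDE_CHOICES}, got {self.amplitude_pct}"
            )

    def validate_center(self, shape: tuple[int, int]) -> None:
        """Raise if the centre does not lie strictly inside ``shape``."""
        r, c = self.center_row, self.center_col
        if not (0 < r < shape[0] - 1 and 0 < c < shape[1] - 1):
            raise ValueError(f"center ({r}, {c}) not strictly inside image of shape {shape}")


@dataclass
class AnnotatedFrame:
    """One 2D grayscale image with its binary balloon ground-truth mask."""

    image: np.ndarray
    gt_mask: np.ndarray
    has_catheter: bool
    subject_id: str = ""
    slice_index: int = 0
    dynamic_index: int = 0
    params: GaussianCatheterParams | None = None

    def __post_init__(self) -> None:
        if self.image.shape != self.gt_mask.shape:
            raise ValueError("image and gt_mask must have identical shape")
        if self.has_catheter != bool(self.gt_mask.any()):
            raise ValueError("has_catheter inconsistent with gt_mask content")


@dataclass
class DynamicFrames:
    """Three contiguous slices of one dynamic, with per-slice ground truth.

    At most one slice carries a balloon (``catheter_slice``; -1 when the
    dynamic is catheter-free).
    """

    slices: np.ndarray  # (3, H, W)
    gt_masks: np.ndarray  # (3, H, W) uint8
    dynamic_index: int
    subject_id: str = ""
    catheter_slice: int = -1
    true_center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.slices.shape[0] != 3 or self.slices.shape != self.gt_masks.shape:
            raise ValueError("a dynamic holds exactly 3 slices with matching masks")


@dataclass
class DatasetConfig:
    """Reproducible train/validation dataset description.

    Defaults mirror the reference recipe: an 8/4 subject split and a 10 %
    share of catheter-free training frames.
    """

    n_subjects_train: int = 8
    n_subjects_val: int = 4
    frames_per_subject: int = 10
    negative_fraction: float = 0.10
    image_shape: tuple[int, int] = (128, 128)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.negative_fraction <= 1.0):
            raise ValueError(f"negative_fraction must be in [0, 1], got {self.negative_fraction}")
        self.image_shape = tuple(self.image_shape)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# phantom backgrounds


def _phantom_structures(shape: tuple[int, int], rng: np.random.Generator,
                        jitter: float = 0.0):
    """Draw the geometric layout of one phantom.

    Returns (image, placement_mask).  ``jitter`` perturbs structure positions
    by up to that many pixels — used to emulate contiguous parallel slices of
    the same anatomy.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)

    # textured low-intensity background
    base = 0.08 + 0.05 * ndimage.gaussian_filter(rng.standard_normal(shape), 6.0)

    img = base
    placement = np.zeros(shape, dtype=bool)

    # chamber-like ellipses, mid intensity
    n_chambers = rng.integers(2, 4)
    for _ in range(n_chambers):
        cy = rng.uniform(0.25, 0.75) * rows + rng.uniform(-jitter, jitter)
        cx = rng.uniform(0.25, 0.75) * cols + rng.uniform(-jitter, jitter)
        a = rng.uniform(0.09, 0.18) * rows
        b = rng.uniform(0.07, 0.14) * cols
        phi = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(phi) + dx * np.sin(phi)
        v = -dy * np.sin(phi) + dx * np.cos(phi)
        d2 = (u / a) ** 2 + (v / b) ** 2
        inside = d2 <= 1.0
        level = rng.uniform(0.35, 0.55)
        img = np.where(inside, level + 0.05 * (1.0 - d2), img)
        placement |= inside

    # a vessel-like tube: capsule around a random chord
    p0 = np.array([rng.uniform(0.15, 0.85) * rows, rng.uniform(0.1, 0.4) * cols])
    p1 = np.array([rng.uniform(0.15, 0.85) * rows, rng.uniform(0.6, 0.9) * cols])
    p0 += rng.uniform(-jitter, jitter, 2)
    p1 += rng.uniform(-jitter, jitter, 2)
    seg = p1 - p0
    seg_len2 = float(seg @ seg) + 1e-9
    t = np.clip(((yy - p0[0]) * seg[0] + (xx - p0[1]) * seg[1]) / seg_len2, 0, 1)
    dist = np.hypot(yy - (p0[0] + t * seg[0]), xx - (p0[1] + t * seg[1]))
    width = rng.uniform(3.0, 5.0)
    tube = dist <= width
    img = np.where(tube, rng.uniform(0.35, 0.5), img)
    placement |= tube

    # hyper-intense fat-like band near a random border
    edge = rng.integers(0, 4)
    offset = rng.uniform(2, 8)
    thickness = rng.uniform(2.5, 6.0)
    wave = 1.5 * np.sin(2 * np.pi * (xx if edge < 2 else yy) / cols * rng.uniform(1, 3))
    coord = {0: yy, 1: rows - 1 - yy, 2: xx, 3: cols - 1 - xx}[int(edge)]
    band = np.abs(coord - offset - wave) <= thickness / 2
    img = np.where(band, rng.uniform(0.9, 1.2), img)

    img = ndimage.gaussian_filter(img, 0.7)
    return img, placement


def generate_phantom(shape: tuple[int, int], rng_seed: int) -> np.ndarray:
    """Generate one deterministic cardiac-like phantom background.

    The phantom contains a low-intensity background, at least one
    mid-intensity chamber/vessel-like structure and a hyper-intense fat-like
    band near the border.  Bit-identical for a fixed seed.
    """
    rows, cols = shape
    if rows < 64 or cols < 64:
        raise ValueError(f"phantom shape must be at least 64x64, got {shape}")
    rng = np.random.default_rng(rng_seed)
    img, _ = _phantom_structures((rows, cols), rng)
    img = img + 0.01 * rng.standard_normal((rows, cols))
    return np.clip(img, 0.0, None)


def generate_phantom_stack(shape: tuple[int, int], rng_seed: int,
                           n_slices: int = 3) -> np.ndarray:
    """Generate ``n_slices`` contiguous-slice phantoms of one 'anatomy'.

    Slices share the structural layout drawn from ``rng_seed`` with small
    per-slice positional jitter and independent noise, emulating parallel
    imaging planes through the same anatomy.
    """
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError(f"phantom shape must be at least 64x64, got {shape}")
    out = np.empty((n_slices,) + tuple(shape))
    for k in range(n_slices):
        # same structural draw per slice (seeded identically), jittered,
        # with independent per-slice acquisition noise
        rng_noise = np.random.default_rng((rng_seed, 977, k))
        rng_struct = np.random.default_rng(rng_seed)
        img, _ = _phantom_structures(tuple(shape), rng_struct, jitter=2.0 * k)
        out[k] = np.clip(img + 0.01 * rng_noise.standard_normal(shape), 0.0, None)
    return out


def _placement_mask(shape: tuple[int, int], rng_seed: int,
                    margin: int) -> np.ndarray:
    """Interior of chamber/vessel structures, at least ``margin`` px from the
    image border, for the phantom drawn from ``rng_seed``."""
    rng = np.random.default_rng(rng_seed)
    _, placement = _phantom_structures(tuple(shape), rng)
    placement = ndimage.binary_erosion(placement, iterations=2)
    m = np.zeros(shape, dtype=bool)
    m[margin:-margin, margin:-margin] = True
    return placement & m


# ---------------------------------------------------------------------------
# the balloon signal model


def _rotation(theta_deg: float) -> np.ndarray:
    th = math.radians(theta_deg)
    return np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])


def mahalanobis_distance(params: GaussianCatheterParams,
                         rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Covariance-scaled distance of pixels from the balloon centre.

    The covariance is ``R(theta) @ diag(sx^2, sy^2) @ R(theta).T`` with the
    rotation applied counter-clockwise about the centre in (row, col) space.
    """
    d = np.stack([np.asarray(rows, float) - params.center_row,
                  np.asarray(cols, float) - params.center_col])
    # rotate the offset into the Gaussian's principal frame
    local = _rotation(-params.theta_deg) @ d.reshape(2, -1)
    md = np.hypot(local[0] / params.sigma_x, local[1] / params.sigma_y)
    return md.reshape(np.shape(rows))


def gaussian_profile(params: GaussianCatheterParams,
                     pixel: tuple[float, float]) -> float:
    """Unit-peak balloon profile ``exp(-d^2 / 2)`` at one pixel, where ``d``
    is the Mahalanobis distance from the centre."""
    d = mahalanobis_distance(params, np.array(pixel[0]), np.array(pixel[1]))
    return float(np.exp(-0.5 * d**2))


def gaussian_field(params: GaussianCatheterParams,
                   shape: tuple[int, int]) -> np.ndarray:
    """Unit-peak balloon profile evaluated on the whole pixel grid."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    d = mahalanobis_distance(params, yy, xx)
    return np.exp(-0.5 * d**2)


def make_gt_mask(params: GaussianCatheterParams,
                 shape: tuple[int, int]) -> np.ndarray:
    """Ground-truth balloon mask: pixels within ``mask_radius_sd`` standard
    deviations of the Gaussian profile (a rotated ellipse with semi-axes
    ``1.5*sigma_x`` and ``1.5*sigma_y``)."""
    params.validate_center(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    d = mahalanobis_distance(params, yy, xx)
    return (d <= params.mask_radius_sd).astype(np.uint8)


def simulate_catheter(image: np.ndarray,
                      params: GaussianCatheterParams,
                      subject_id: str = "",
                      slice_index: int = 0,
                      dynamic_index: int = 0) -> AnnotatedFrame:
    """Add one balloon signal to ``image`` and derive its ground truth.

    The signal is additive: ``out = image + A * G`` where ``G`` is the
    unit-peak profile and the peak increment ``A`` equals ``amplitude_pct``
    percent of the input intensity at the centre pixel, so the background
    texture under the balloon is preserved.
    """
    image = np.asarray(image, dtype=np.float64)
    params.validate_center(image.shape)
    r0 = int(round(params.center_row))
    c0 = int(round(params.center_col))
    underlying = float(image[r0, c0])
    if underlying <= 0.0:
        raise ValueError(
            f"cannot place balloon at ({r0}, {c0}): centre-pixel intensity is "
            "zero, so the relative amplitude is undefined"
        )
    amp = params.amplitude_pct / 100.0 * underlying
    out = image + amp * gaussian_field(params, image.shape)
    return AnnotatedFrame(
        image=out,
        gt_mask=make_gt_mask(params, image.shape),
        has_catheter=True,
        subject_id=subject_id,
        slice_index=slice_index,
        dynamic_index=dynamic_index,
        params=params,
    )


def sample_catheter_params(placement: tuple[float, float],
                           rng: np.random.Generator) -> GaussianCatheterParams:
    """Draw balloon parameters: sigma_x, sigma_y independently uniform on
    {1.5, 2.5}; integer rotation uniform on [0, 359]; amplitude uniform on
    {200, 300, 400} percent."""
    return GaussianCatheterParams(
        center_row=float(placement[0]),
        center_col=float(placement[1]),
        sigma_x=float(rng.choice(SIGMA_CHOICES)),
        sigma_y=float(rng.choice(SIGMA_CHOICES)),
        theta_deg=int(rng.integers(0, 360)),
        amplitude_pct=int(rng.choice(AMPLITUDE_CHOICES)),
    )


# ---------------------------------------------------------------------------
# dataset assembly

_PLACEMENT_MARGIN = int(math.ceil(3 * max(SIGMA_CHOICES)))  # px from image border


def _subject_seed(base_seed: int, split: str, idx: int) -> int:
    ss = np.random.SeedSequence([base_seed, {"train": 1, "val": 2}[split], idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _frame_seed(subject_seed: int, frame_idx: int) -> int:
    ss = np.random.SeedSequence([subject_seed, frame_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _sample_placement(shape, subject_seed, rng) -> tuple[int, int]:
    mask = _placement_mask(shape, subject_seed, _PLACEMENT_MARGIN)
    cand = np.argwhere(mask)
    if len(cand) == 0:  # pathological layout: fall back to the safe interior
        m = _PLACEMENT_MARGIN
        return (int(rng.integers(m, shape[0] - m)), int(rng.integers(m, shape[1] - m)))
    r, c = cand[rng.integers(len(cand))]
    return int(r), int(c)


def _build_split(config: DatasetConfig, split: str, n_subjects: int) -> list[AnnotatedFrame]:
    rng = np.random.default_rng([config.rng_seed, {"train": 1, "val": 2}[split]])
    n_frames = n_subjects * config.frames_per_subject
    n_neg = int(round(config.negative_fraction * n_frames))
    # spread negatives deterministically across the split
    neg_slots = set(np.round(np.linspace(0, n_frames - 1, n_neg)).astype(int)) if n_neg else set()

    frames: list[AnnotatedFrame] = []
    k = 0
    for s in range(n_subjects):
        sid = f"{split}{s:02d}"
        sseed = _subject_seed(config.rng_seed, split, s)
        for f in range(config.frames_per_subject):
            # one source slice (background) per frame, as in a multi-slice
            # stack acquired per subject
            fseed = _frame_seed(sseed, f)
            background = generate_phantom(config.image_shape, fseed)
            if k in neg_slots:
                frames.append(AnnotatedFrame(
                    image=background,
                    gt_mask=np.zeros(config.image_shape, dtype=np.uint8),
                    has_catheter=False,
                    subject_id=sid,
                ))
            else:
                placement = _sample_placement(config.image_shape, fseed, rng)
                params = sample_catheter_params(placement, rng)
                frames.append(simulate_catheter(background, params, subject_id=sid))
            k += 1
    return frames


def build_dataset(config: DatasetConfig) -> tuple[list[AnnotatedFrame], list[AnnotatedFrame]]:
    """Build reproducible train and validation frame sets.

    One phantom background per subject, one frame per balloon placement (at
    most one balloon per frame), an exact ``negative_fraction`` share of
    catheter-free frames per split, and a subject-level split (no background
    shared between train and validation).
    """
    train = _build_split(config, "train", config.n_subjects_train)
    val = _build_split(config, "val", config.n_subjects_val)
    return train, val


def build_dynamic_dataset(n_dynamics: int,
                          image_shape: tuple[int, int] = (128, 128),
                          rng_seed: int = 0,
                          negative_fraction: float = 0.25,
                          n_subjects: int = 4,
                          subject_prefix: str = "dyn") -> list[DynamicFrames]:
    """Build per-dynamic triplets of contiguous slices for tracking tests.

    Each positive dynamic carries one balloon in exactly one (random) slice;
    ``negative_fraction`` of dynamics are catheter-free.  Slices of one
    dynamic are jittered phantoms of the same subject anatomy.
    """
    rng = np.random.default_rng([rng_seed, 7])
    n_neg = int(round(negative_fraction * n_dynamics))
    neg_slots = set(np.round(np.linspace(0, n_dynamics - 1, n_neg)).astype(int)) if n_neg else set()

    dynamics: list[DynamicFrames] = []
    for d in range(n_dynamics):
        subj = d % n_subjects
        sseed = _subject_seed(rng_seed, "val", 1000 + subj)
        stack = generate_phantom_stack(image_shape, (sseed + d) % (2**31), 3)
        gt = np.zeros_like(stack, dtype=np.uint8)
        cath_slice = -1
        center = None
        if d not in neg_slots:
            cath_slice = int(rng.integers(0, 3))
            placement = _sample_placement(image_shape, (sseed + d) % (2**31), rng)
            params = sample_catheter_params(placement, rng)
            frame = simulate_catheter(stack[cath_slice], params)
            stack[cath_slice] = frame.image
            gt[cath_slice] = frame.gt_mask
            center = (params.center_row, params.center_col)
        dynamics.append(DynamicFrames(
            slices=stack, gt_masks=gt, dynamic_index=d,
            subject_id=f"{subject_prefix}{subj:02d}",
            catheter_slice=cath_slice, true_center=center,
        ))
    return dynamics


# ---------------------------------------------------------------------------
# on-disk format: per-frame NPZ + CSV manifest (+ optional 8-bit PNG preview)


def save_dataset(frames: Sequence[AnnotatedFrame], out_dir: str | Path,
                 split: str = "train", png_preview: bool = False) -> Path:
    """Write frames as lossless NPZ pairs plus a CSV manifest.

    Returns the manifest path.  Appends to an existing manifest so several
    splits can share one directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    new = not manifest.exists()
    with open(manifest, "a", newline="") as fh:
        w = csv.writer(fh)
        if new:
            w.writerow(["subject_id", "frame_path", "has_catheter", "split"])
        for i, f in enumerate(frames):
            name = f"{split}_{i:05d}.npz"
            np.savez(out / name, image=f.image.astype(np.float32),
                     gt_mask=f.gt_mask.astype(np.uint8))
            if png_preview:
                from PIL import Image
                lo, hi = f.image.min(), f.image.max()
                u8 = ((f.image - lo) / max(hi - lo, 1e-12) * 255).astype(np.uint8)
                Image.fromarray(u8).save(out / f"{split}_{i:05d}.png")
            w.writerow([f.subject_id, name, int(f.has_catheter), split])
    return manifest


def save_dynamics(dynamics: Sequence[DynamicFrames], out_dir: str | Path) -> Path:
    """Write per-dynamic NPZ triplets plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "dynamics_manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["dynamic_index", "subject_id", "path", "catheter_slice"])
        for d in dynamics:
            name = f"dyn_{d.dynamic_index:05d}.npz"
            center = (np.nan, np.nan) if d.true_center is None else d.true_center
            np.savez(out / name, slices=d.slices.astype(np.float32),
                     gt_masks=d.gt_masks.astype(np.uint8),
                     true_center=np.asarray(center, dtype=np.float64))
            w.writerow([d.dynamic_index, d.subject_id, name, d.catheter_slice])
    return manifest


def load_dynamics(manifest: str | Path) -> list[DynamicFrames]:
    """Load dynamics written by :func:`save_dynamics`."""
    manifest = Path(manifest)
    base = manifest.parent
    out = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            with np.load(base / row["path"]) as z:
                center = z["true_center"]
                out.append(DynamicFrames(
                    slices=z["slices"].astype(np.float64),
                    gt_masks=z["gt_masks"].astype(np.uint8),
                    dynamic_index=int(row["dynamic_index"]),
                    subject_id=row["subject_id"],
                    catheter_slice=int(row["catheter_slice"]),
                    true_center=None if np.isnan(center[0]) else tuple(center),
                ))
    return out


def load_dataset(manifest: str | Path,
                 split: str | None = None) -> list[AnnotatedFrame]:
    """Load frames listed in a manifest written by :func:`save_dataset`."""
    manifest = Path(manifest)
    base = manifest.parent
    frames = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            if split is not None and row["split"] != split:
                continue
            with np.load(base / row["frame_path"]) as z:
                frames.append(AnnotatedFrame(
                    image=z["image"].astype(np.float64),
                    gt_mask=z["gt_mask"].astype(np.uint8),
                    has_catheter=bool(int(row["has_catheter"])),
                    subject_id=row["subject_id"],
                ))
    return frames
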