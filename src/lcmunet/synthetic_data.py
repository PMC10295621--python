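"""Seeded generator of lesion-like image/mask pairs, augmentation, and I/O.

Real dermoscopic, ultrasound and endoscopic lesion photographs share a few
coarse statistics that matter to a binary segmenter: a roughly elliptical
foreground whose intensity is offset from a textured background, soft
(blurred) boundaries, sensor noise, and occasional thin dark occluders
(body hair) crossing the lesion.  The generator emulates exactly these
features: a low-frequency textured background, a union of one to three
overlapping ellipses with a random bright/dark contrast offset, Gaussian
boundary blur, additive Gaussian noise, and optional curvilinear hair
strokes.  The ground-truth mask is the exact pre-blur ellipse union.

Everything is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


class GenerationError(RuntimeError):
    pass


class PairingError(RuntimeError):
    pass


@dataclass(frozen=True)
class SegSample:
    """One RGB image in [0,1] (3,H,W) with its binary mask (1,H,W)."""

    image: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[0] != 3:
            raise ValueError("image must have shape (3, H, W)")
        if self.mask.shape != (1,) + self.image.shape[1:]:
            raise ValueError("mask must have shape (1, H, W)")
        uniq = np.unique(self.mask)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("mask must be strictly binary")


@dataclass(frozen=True)
class GenConfig:
    n_samples: int = 16
    image_size: tuple[int, int] = (256, 256)
    lesion_area_range: tuple[float, float] = (0.05, 0.30)
    contrast_range: tuple[float, float] = (0.25, 0.45)
    noise_sigma: float = 0.03
    hair_occluders: int = 3
    blur_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("lesion_area_range must satisfy 0 < lo < hi < 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


def _ellipse_union(rng: np.random.Generator, shape: tuple[int, int],
                   area_range: tuple[float, float]) -> np.ndarray:
    """Binary union of 1-3 overlapping ellipses with area inside the bounds."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    lo, hi = area_range
    for _ in range(64):
        target = rng.uniform(lo, hi)
        n_ell = rng.integers(1, 4)
        cy = rng.uniform(0.3, 0.7) * h
        cx = rng.uniform(0.3, 0.7) * w
        base_r = np.sqrt(target * h * w / (np.pi * n_ell)) * rng.uniform(0.9, 1.3)
        mask = np.zeros(shape, dtype=bool)
        for _k in range(n_ell):
            ey = cy + rng.uniform(-0.5, 0.5) * base_r
            ex = cx + rng.uniform(-0.5, 0.5) * base_r
            ra = base_r * rng.uniform(0.7, 1.3)
            rb = base_r * rng.uniform(0.7, 1.3)
            theta = rng.uniform(0, np.pi)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - ex) * ct + (yy - ey) * st
            v = -(xx - ex) * st + (yy - ey) * ct
            mask |= (u / ra) ** 2 + (v / rb) ** 2 <= 1.0
        frac = mask.mean()
        if lo <= frac <= hi:
            return mask
    raise GenerationError(
        f"could not draw a lesion with area fraction in [{lo}, {hi}]")


def _background(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Low-frequency textured RGB background (skin-toned base)."""
    h, w = shape
    base = np.array([0.72, 0.55, 0.48]) + rng.uniform(-0.08, 0.08, size=3)
    img = np.empty((3, h, w), dtype=np.float64)
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                      sigma=max(h, w) / 16.0)
    texture /= max(np.abs(texture).max(), 1e-9)
    for c in range(3):
        img[c] = base[c] + 0.06 * texture
    return img


def _hair_strokes(rng: np.random.Generator, shape: tuple[int, int],
                  n: int) -> np.ndarray:
    """Thin dark curvilinear strokes; boolean stencil."""
    h, w = shape
    stencil = np.zeros(shape, dtype=bool)
    t = np.linspace(0.0, 1.0, 4 * max(h, w))
    for _ in range(n):
        y0, x0 = rng.uniform(0, h), rng.uniform(0, w)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.5, 1.2) * max(h, w)
        amp = rng.uniform(0.02, 0.08) * length
        freq = rng.uniform(1.0, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        s = (t - 0.5) * length
        wob = amp * np.sin(2 * np.pi * freq * t + phase)
        ys = y0 + s * np.sin(angle) + wob * np.cos(angle)
        xs = x0 + s * np.cos(angle) - wob * np.sin(angle)
        keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        stencil[ys[keep].astype(int), xs[keep].astype(int)] = True
    return ndimage.binary_dilation(stencil, iterations=1)


def generate_sample(rng: np.random.Generator, cfg: GenConfig) -> SegSample:
    h, w = cfg.image_size
    mask = _ellipse_union(rng, (h, w), cfg.lesion_area_range)
    img = _background(rng, (h, w))
    contrast = rng.uniform(*cfg.contrast_range)
    sign = -1.0 if rng.uniform() < 0.5 else 1.0   # dark or bright lesion
    lesion_tint = rng.uniform(0.85, 1.15, size=3)
    offset = ndimage.gaussian_filter(mask.astype(np.float64), cfg.blur_sigma)
    for c in range(3):
        img[c] += sign * contrast * lesion_tint[c] * offset
    if cfg.hair_occluders > 0:
        hair = _hair_strokes(rng, (h, w), int(cfg.hair_occluders))
        img[:, hair] *= rng.uniform(0.25, 0.5)
    img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return SegSample(image=img,
                     mask=mask[None].astype(np.float32),
                     meta={"contrast": float(contrast), "sign": float(sign),
                           "area_fraction": float(mask.mean())})


def generate_dataset(cfg: GenConfig) -> list[SegSample]:
    """A list of samples fully determined by ``cfg`` (including its seed)."""
    rng = np.random.default_rng(cfg.seed)
    return [generate_sample(rng, cfg) for _ in range(cfg.n_samples)]


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    """One concrete draw of the augmentation pipeline; defaults are neutral."""

    angle: float = 0.0            # degrees
    zoom: float = 1.0
    brightness: float = 0.0
    contrast: float = 1.0
    crop_frac: float = 1.0
    crop_cy: float = 0.5          # crop centre in relative coords
    crop_cx: float = 0.5


def draw_augment_params(rng: np.random.Generator, *,
                        max_angle: float = 30.0,
                        zoom_range: tuple[float, float] = (0.8, 1.2),
                        jitter: float = 0.2,
                        crop_range: tuple[float, float] = (0.8, 1.0)) -> AugmentParams:
    return AugmentParams(
        angle=float(rng.uniform(-max_angle, max_angle)),
        zoom=float(rng.uniform(*zoom_range)),
        brightness=float(rng.uniform(-jitter, jitter)),
        contrast=float(rng.uniform(1.0 - jitter, 1.0 + jitter)),
        crop_frac=float(rng.uniform(*crop_range)),
        crop_cy=float(rng.uniform(0.4, 0.6)),
        crop_cx=float(rng.uniform(0.4, 0.6)),
    )


def _geometric(channel: np.ndarray, p: AugmentParams, order: int) -> np.ndarray:
    h, w = channel.shape
    out = channel
    if p.angle != 0.0:
        out = ndimage.rotate(out, p.angle, reshape=False, order=order,
                             mode="nearest")
    if p.zoom != 1.0:
        centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        matrix = np.eye(2) / p.zoom
        off = centre - matrix @ centre
        out = ndimage.affine_transform(out, matrix, offset=off, order=order,
                                       mode="nearest")
    if p.crop_frac != 1.0:
        ch = max(2, int(round(p.crop_frac * h)))
        cw = max(2, int(round(p.crop_frac * w)))
        y0 = int(round(p.crop_cy * h - ch / 2.0))
        x0 = int(round(p.crop_cx * w - cw / 2.0))
        y0 = min(max(y0, 0), h - ch)
        x0 = min(max(x0, 0), w - cw)
        crop = out[y0:y0 + ch, x0:x0 + cw]
        zy, zx = h / ch, w / cw
        out = ndimage.zoom(crop, (zy, zx), order=order, mode="nearest")
        out = out[:h, :w]
        if out.shape != (h, w):
            out = np.pad(out, ((0, h - out.shape[0]), (0, w - out.shape[1])),
                         mode="edge")
    return out


def apply_augment(s: SegSample, p: AugmentParams) -> SegSample:
    """Apply one concrete transform draw; geometry shared by image and mask."""
    img = np.stack([_geometric(c, p, order=1) for c in s.image.astype(np.float64)])
    img = np.clip(p.contrast * img + p.brightness, 0.0, 1.0)
    m = _geometric(s.mask[0].astype(np.float64), p, order=0)
    mask = (m >= 0.5).astype(np.float32)[None]
    return SegSample(image=img.astype(np.float32), mask=mask,
                     meta={**s.meta, "augment": p.__dict__.copy()})


def augment(s: SegSample, seed: int) -> SegSample:
    """Seeded random rotation, zoom, photometric jitter and crop-resize."""
    rng = np.random.default_rng(seed)
    return apply_augment(s, draw_augment_params(rng))


# ---------------------------------------------------------------------------
# folder I/O and splitting
# ---------------------------------------------------------------------------

TARGET_SIZE = (256, 256)


def save_folder(samples, path) -> None:
    """Write samples as 8-bit PNGs under ``path``/images and ``path``/masks."""
    root = Path(path)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        stem = f"sample_{i:04d}"
        rgb = np.round(s.image.transpose(1, 2, 0) * 255.0).astype(np.uint8)
        Image.fromarray(rgb).save(root / "images" / f"{stem}.png")
        mk = (s.mask[0] * 255.0).astype(np.uint8)
        Image.fromarray(mk, mode="L").save(root / "masks" / f"{stem}.png")


def load_folder(path, *, image_size: tuple[int, int] = TARGET_SIZE) -> list[SegSample]:
    """Load paired PNGs, resizing images bilinearly and masks nearest-neighbour."""
    root = Path(path)
    images = sorted((root / "images").glob("*.png"))
    if not images:
        raise FileNotFoundError(f"no images found under {root / 'images'}")
    samples = []
    for img_path in images:
        mask_path = root / "masks" / img_path.name
        if not mask_path.exists():
            raise PairingError(f"no mask for image stem {img_path.stem!r}")
        img = Image.open(img_path).convert("RGB")
        if img.size != image_size[::-1]:
            img = img.resize(image_size[::-1], Image.BILINEAR)
        mask = Image.open(mask_path).convert("L")
        if mask.size != image_size[::-1]:
            mask = mask.resize(image_size[::-1], Image.NEAREST)
        arr = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
        mk = (np.asarray(mask, dtype=np.float32) > 127.0).astype(np.float32)[None]
        samples.append(SegSample(image=arr, mask=mk, meta={"stem": img_path.stem}))
    return samples


def split(samples, train_frac: float = 0.8, seed: int = 0):
    """Disjoint, exhaustive, seed-reproducible shuffle split."""
    if len(samples) < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(round(train_frac * len(samples)))
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return train, test
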