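"""Synthetic underwater scenes with pixel masks.

Scenes emulate the structure of shallow-water benthic survey imagery: four
foreground classes (echinus = spiny disc, holothurian = elongated capsule,
scallop = fan, starfish = five-armed star) composited over a textured
seabed, with heavy instance imbalance dominated by echinus, then degraded
by a blue-green color cast, contrast compression, blur and sensor noise.
Degradations never touch the mask.  Everything is a pure function of the
seed.  Datasets are written in the VOC dialect: images and single-channel
indexed PNG masks plus split list files.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw

CLASS_NAMES = ("background", "echinus", "holothurian", "scallop", "starfish")
IGNORE_LABEL = 255

# indexed-PNG palette: background, then one saturated color per class
_PALETTE = [(0, 0, 0), (128, 0, 128), (128, 96, 0), (224, 192, 128), (224, 96, 0)]


@dataclass(frozen=True)
class Degradation:
    color_cast_strength: float = 0.5
    blur_sigma: float = 1.0
    contrast_factor: float = 0.6
    noise_sd: float = 0.03


@dataclass(frozen=True)
class SceneSpec:
    image_size: tuple = (128, 128)
    # expected instances per scene; echinus:scallop ~ 27:1 as in benthic surveys
    instances_per_class: tuple = (4.0, 0.8, 0.15, 0.6)
    object_scale_range: tuple = (0.10, 0.28)     # fraction of min(H, W)
    degradation: Degradation = field(default_factory=Degradation)
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.instances_per_class):
            raise ValueError("expected instance counts must be >= 0")
        lo, hi = self.object_scale_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("object_scale_range must satisfy 0 < lo <= hi <= 1")


def easy_spec(size=(128, 128), seed=0) -> SceneSpec:
    """Mild degradation, large and class-balanced objects; the learnability
    setting in which the four species are separable by shape and color."""
    return SceneSpec(image_size=size,
                     instances_per_class=(1.4, 1.0, 0.8, 1.0),
                     object_scale_range=(0.30, 0.52),
                     degradation=Degradation(0.2, 0.3, 0.9, 0.01),
                     seed=seed)


class Scene(NamedTuple):
    image: np.ndarray        # (h, w, 3) uint8
    mask: np.ndarray         # (h, w) uint8 labels 0..4
    instances: dict          # class name -> count actually placed


# ---------------------------------------------------------------------------
# shape stamps
# ---------------------------------------------------------------------------

def _star_polygon(cy, cx, r, arms, inner, phase):
    ang = phase + np.linspace(0, 2 * np.pi, 2 * arms, endpoint=False)
    rad = np.where(np.arange(2 * arms) % 2 == 0, r, r * inner)
    return cy + rad * np.sin(ang), cx + rad * np.cos(ang)


def _stamp(cls: int, r: float, rng) -> np.ndarray:
    """Boolean footprint of one instance on a local grid."""
    side = int(np.ceil(r * 3)) | 1
    c = side // 2
    m = np.zeros((side, side), bool)
    if cls == 1:      # echinus: disc with many short spines
        yy, xx = _star_polygon(c, c, r * 1.05, 14, 0.72, rng.uniform(0, np.pi))
        rr, cc = skdraw.polygon(yy, xx, m.shape)
        m[rr, cc] = True
    elif cls == 2:    # holothurian: elongated rotated capsule
        rr, cc = skdraw.ellipse(c, c, r * 0.38, r * 1.1,
                                rotation=rng.uniform(0, np.pi), shape=m.shape)
        m[rr, cc] = True
    elif cls == 3:    # scallop: fan (circular sector)
        phase = rng.uniform(0, 2 * np.pi)
        ang = phase + np.linspace(-1.15, 1.15, 13)
        yy = np.concatenate([[c], c + r * 1.1 * np.sin(ang)])
        xx = np.concatenate([[c], c + r * 1.1 * np.cos(ang)])
        rr, cc = skdraw.polygon(yy, xx, m.shape)
        m[rr, cc] = True
    else:             # starfish: five arms
        yy, xx = _star_polygon(c, c, r * 1.15, 5, 0.45, rng.uniform(0, np.pi))
        rr, cc = skdraw.polygon(yy, xx, m.shape)
        m[rr, cc] = True
    return m


_BASE_COLOR = {1: (0.22, 0.10, 0.26), 2: (0.42, 0.34, 0.18),
               3: (0.78, 0.68, 0.52), 4: (0.82, 0.42, 0.16)}


# ---------------------------------------------------------------------------
# scene synthesis
# ---------------------------------------------------------------------------

def _seabed(h, w, rng) -> np.ndarray:
    base = np.array([0.18, 0.32, 0.38])
    grad = np.linspace(-0.05, 0.05, h)[:, None, None]
    tex = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), 4)
    tex = 0.06 * tex[..., None] / max(tex.std(), 1e-6)
    grain = 0.02 * rng.normal(0, 1, (h, w, 3))
    return np.clip(base + grad + tex + grain, 0, 1)


def apply_degradation(img: np.ndarray, deg: Degradation, rng) -> np.ndarray:
    """Color cast -> contrast compression -> blur -> additive noise, in [0,1]."""
    s = deg.color_cast_strength
    cast = np.array([1 - 0.65 * s, 1 - 0.12 * s, 1.0])
    haze = np.array([0.05, 0.28, 0.34])
    img = img * cast * (1 - 0.25 * s) + 0.25 * s * haze
    mean = img.mean(axis=(0, 1), keepdims=True)
    img = mean + (img - mean) * deg.contrast_factor
    if deg.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, (deg.blur_sigma, deg.blur_sigma, 0))
    if deg.noise_sd > 0:
        img = img + rng.normal(0, deg.noise_sd, img.shape)
    return np.clip(img, 0, 1)


def generate_scene(spec: SceneSpec, rng=None) -> Scene:
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    h, w = spec.image_size
    img = _seabed(h, w, rng)
    mask = np.zeros((h, w), np.uint8)
    counts = dict.fromkeys(CLASS_NAMES[1:], 0)
    lo, hi = spec.object_scale_range
    for cls in (1, 2, 3, 4):
        n = rng.poisson(spec.instances_per_class[cls - 1])
        for _ in range(n):
            placed = False
            for _attempt in range(8):
                r = rng.uniform(lo, hi) * min(h, w) / 2
                stamp = _stamp(cls, r, rng)
                sh, sw = stamp.shape
                if sh >= h or sw >= w:
                    continue
                y = rng.integers(0, h - sh)
                x = rng.integers(0, w - sw)
                region = mask[y:y + sh, x:x + sw]
                if (region[stamp] != 0).mean() > 0.25:
                    continue                       # too much overlap; retry
                region[stamp] = cls
                color = np.array(_BASE_COLOR[cls]) * rng.uniform(0.8, 1.2)
                tex = 0.08 * rng.normal(0, 1, (sh, sw))
                patch = img[y:y + sh, x:x + sw]
                patch[stamp] = np.clip(color + tex[stamp, None], 0, 1)
                placed = True
                break
            if placed:
                counts[CLASS_NAMES[cls]] += 1
            else:
                warnings.warn(f"could not place a {CLASS_NAMES[cls]} instance; "
                              "scene left partial", stacklevel=2)
    img = apply_degradation(img, spec.degradation, rng)
    return Scene((img * 255).round().astype(np.uint8), mask, counts)


# ---------------------------------------------------------------------------
# dataset layout
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    root: Path
    splits: dict                      # split name -> list of sample ids
    class_names: tuple = CLASS_NAMES

    def ids(self, split: str):
        return self.splits[split]


def split_ids(ids, ratios=(8, 1, 1), seed: int = 0) -> dict:
    """Disjoint train/val/test split by largest-remainder rounding."""
    ids = list(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    total = np.asarray(ratios, float)
    quota = len(ids) * total / total.sum()
    base = np.floor(quota).astype(int)
    rem = quota - base
    for i in np.argsort(-rem)[: len(ids) - base.sum()]:
        base[i] += 1
    names = ("train", "val", "test")
    out, start = {}, 0
    for name, n in zip(names, base):
        out[name] = sorted(ids[j] for j in order[start:start + n])
        start += n
    return out


def _palette_image(mask: np.ndarray) -> Image.Image:
    im = Image.fromarray(mask, mode="P")
    pal = np.zeros((256, 3), np.uint8)
    pal[: len(_PALETTE)] = _PALETTE
    pal[IGNORE_LABEL] = (255, 255, 255)
    im.putpalette(pal.ravel().tolist())
    return im


def write_dataset(root, scenes: dict, ratios=(8, 1, 1), seed: int = 0) -> DatasetManifest:
    """Write ``{sample_id: Scene}`` as a VOC-style tree and split lists."""
    root = Path(root)
    (root / "JPEGImages").mkdir(parents=True, exist_ok=True)
    (root / "SegmentationClass").mkdir(parents=True, exist_ok=True)
    lists = root / "ImageSets" / "Segmentation"
    lists.mkdir(parents=True, exist_ok=True)
    for sid, scene in scenes.items():
        Image.fromarray(scene.image).save(root / "JPEGImages" / f"{sid}.png")
        _palette_image(scene.mask).save(root / "SegmentationClass" / f"{sid}.png")
    splits = split_ids(scenes.keys(), ratios, seed)
    for name, sids in splits.items():
        (lists / f"{name}.txt").write_text("".join(f"{s}\n" for s in sids))
    return DatasetManifest(root, splits)


def read_dataset(root) -> DatasetManifest:
    root = Path(root)
    lists = root / "ImageSets" / "Segmentation"
    if not lists.is_dir():
        raise FileNotFoundError(f"no split lists under {lists}")
    splits = {p.stem: p.read_text().split() for p in sorted(lists.glob("*.txt"))}
    return DatasetManifest(root, splits)


def load_sample(manifest: DatasetManifest, sample_id: str):
    """(image uint8 HxWx3, mask uint8 HxW); validates the mask's label set."""
    img = np.asarray(Image.open(manifest.root / "JPEGImages" / f"{sample_id}.png").convert("RGB"))
    mpath = manifest.root / "SegmentationClass" / f"{sample_id}.png"
    mask = np.asarray(Image.open(mpath))
    bad = set(np.unique(mask)) - set(range(len(manifest.class_names))) - {IGNORE_LABEL}
    if bad:
        raise ValueError(f"mask {mpath} contains invalid labels {sorted(bad)}")
    return img, mask


def load_split(manifest: DatasetManifest, split: str):
    """Stacked (images float32 NCHW in [-1,1], masks int64 NHW) for a split."""
    imgs, masks = [], []
    for sid in manifest.ids(split):
        img, mask = load_sample(manifest, sid)
        imgs.append(img)
        masks.append(mask)
    x = np.stack(imgs).astype(np.float32) / 127.5 - 1.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2)), np.stack(masks).astype(np.int64)


def generate_dataset(n_scenes: int, spec: SceneSpec | None = None, seed: int = 0,
                     size=(128, 128)) -> dict:
    """n seeded scenes as ``{id: Scene}``; scene i uses seed ``seed + i``."""
    spec = spec or SceneSpec(image_size=size)
    out = {}
    for i in range(n_scenes):
        s = SceneSpec(spec.image_size, spec.instances_per_class,
                      spec.object_scale_range, spec.degradation, seed=seed + i)
        out[f"scene_{i:05d}"] = generate_scene(s)
    return out
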