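"""Seeded generator of dermoscopy-like image/mask fixtures.

Each sample is a textured skin background with one darker lesion whose
boundary is an ellipse perturbed by random radial harmonics; the ground
truth mask is exactly the rendered lesion support.  Optional artifact
overlays emulate the nuisance structures of real dermoscopy: dark hairs,
bright air/oil bubble rings, pen marks drawn around the lesion, and
specular reflections.  Per-class presets give the seven lesion classes
distinguishable morphology (e.g. melanoma boundaries are far more irregular
than the near-elliptic melanocytic nevi).

Everything is a function of ``(seed, index)``: the same pair always yields
bit-identical pixels, and a written dataset can be reproduced exactly from
its manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, line
from skimage.measure import perimeter as _perimeter

from .data import LESION_CLASSES, ImageSample, write_class_labels

#: Morphology presets per lesion class: boundary irregularity (radial
#: harmonic amplitude), lesion/skin contrast range, area-fraction range and
#: an RGB tint added to the lesion colour.
CLASS_PRESETS: dict[str, dict] = {
    "NV":    dict(irregularity=0.06, contrast=(0.35, 0.50), area_fraction=(0.08, 0.18), tint=(0.00, 0.00, 0.00)),
    "MEL":   dict(irregularity=0.30, contrast=(0.30, 0.50), area_fraction=(0.10, 0.25), tint=(-0.02, -0.02, 0.00)),
    "BKL":   dict(irregularity=0.14, contrast=(0.22, 0.38), area_fraction=(0.08, 0.20), tint=(0.02, 0.00, -0.02)),
    "BCC":   dict(irregularity=0.16, contrast=(0.12, 0.25), area_fraction=(0.05, 0.12), tint=(0.04, 0.00, 0.00)),
    "AKIEC": dict(irregularity=0.20, contrast=(0.06, 0.14), area_fraction=(0.05, 0.15), tint=(0.05, 0.02, 0.00)),
    "DF":    dict(irregularity=0.05, contrast=(0.28, 0.42), area_fraction=(0.02, 0.06), tint=(0.02, 0.01, 0.00)),
    "VASC":  dict(irregularity=0.08, contrast=(0.20, 0.38), area_fraction=(0.04, 0.12), tint=(0.16, -0.06, -0.04)),
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic dermoscopy generator.

    ``seed`` fixes the whole sample stream; sample ``index`` selects an
    independent substream, so datasets are reproducible and order-free.
    """

    n_samples: int = 16
    height: int = 96
    width: int = 128
    seed: int = 0
    area_fraction: tuple[float, float] = (0.05, 0.20)
    irregularity: float = 0.12
    contrast: tuple[float, float] = (0.25, 0.45)
    hair: bool = False
    bubbles: bool = False
    pen_marks: bool = False
    reflections: bool = False
    hair_density: int = 6
    bubble_density: int = 3
    pen_density: int = 2
    reflection_density: int = 2
    lesion_class: str | None = None
    class_mix: tuple[str, ...] | None = None
    noise_sigma: float = 0.01
    edge_sigma: float = 0.6

    def __post_init__(self):
        lo, hi = self.area_fraction
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"area_fraction range must satisfy 0 < lo < hi < 1, got {self.area_fraction}")
        if self.lesion_class is not None and self.lesion_class not in LESION_CLASSES:
            raise ValueError(f"unknown lesion class {self.lesion_class!r}")
        if self.class_mix is not None:
            bad = set(self.class_mix) - set(LESION_CLASSES)
            if bad:
                raise ValueError(f"unknown classes in class_mix: {sorted(bad)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["area_fraction"] = list(d["area_fraction"])
        d["contrast"] = list(d["contrast"])
        if d["class_mix"] is not None:
            d["class_mix"] = list(d["class_mix"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        d["area_fraction"] = tuple(d["area_fraction"])
        d["contrast"] = tuple(d["contrast"])
        if d.get("class_mix") is not None:
            d["class_mix"] = tuple(d["class_mix"])
        return cls(**d)


def _apply_preset(config: SynthConfig, cls: str) -> SynthConfig:
    preset = CLASS_PRESETS[cls]
    return dataclasses.replace(
        config,
        irregularity=preset["irregularity"],
        contrast=preset["contrast"],
        area_fraction=preset["area_fraction"],
    )


def _sample_rng(config: SynthConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))


def _lesion_mask(rng: np.random.Generator, H: int, W: int,
                 area_fraction: tuple[float, float], irregularity: float
                 ) -> np.ndarray:
    """Elliptic blob with radial harmonic boundary perturbation.

    The mask threshold is picked as a quantile of the radial field, so the
    foreground fraction matches the sampled target fraction to within one
    pixel in H*W.
    """
    lo, hi = area_fraction
    margin = 0.02 * (hi - lo)
    f = rng.uniform(lo + margin, hi - margin)
    if f * H * W < 4:
        raise ValueError(
            f"area fraction {f:.4f} infeasible for image size {H}x{W}")
    cy = H * (0.5 + rng.uniform(-0.08, 0.08))
    cx = W * (0.5 + rng.uniform(-0.08, 0.08))
    aspect = rng.uniform(0.6, 1.0)
    phi = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    u = (dx * np.cos(phi) + dy * np.sin(phi))
    v = (-dx * np.sin(phi) + dy * np.cos(phi)) * (1.0 / aspect)
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    perturb = np.zeros_like(theta)
    for k in range(2, 7):
        amp = irregularity * rng.uniform(0.3, 1.0) / np.sqrt(k)
        perturb += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    radial = rho / np.clip(1.0 + perturb, 0.25, None)
    threshold = np.quantile(radial, f)
    return (radial <= threshold).astype(np.uint8)


def _skin_field(rng: np.random.Generator, H: int, W: int) -> np.ndarray:
    base = np.array([0.80, 0.62, 0.54]) + rng.uniform(-0.05, 0.05, size=3)
    lowfreq = gaussian_filter(rng.normal(size=(H, W)), sigma=max(H, W) / 10.0)
    lowfreq /= max(np.abs(lowfreq).max(), 1e-9)
    texture = gaussian_filter(rng.normal(size=(H, W)), sigma=1.2)
    texture /= max(np.abs(texture).max(), 1e-9)
    skin = base[None, None, :] + 0.04 * lowfreq[..., None] + 0.015 * texture[..., None]
    return skin


def _add_hair(rng, img, density):
    H, W, _ = img.shape
    for _ in range(rng.poisson(density)):
        y0, x0 = rng.uniform(0, H), rng.uniform(0, W)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.4, 1.0) * min(H, W)
        curve = rng.uniform(-0.8, 0.8)
        npts = 12
        ts = np.linspace(0, 1, npts)
        ys = y0 + length * ts * np.sin(ang + curve * ts)
        xs = x0 + length * ts * np.cos(ang + curve * ts)
        shade = rng.uniform(0.15, 0.35)
        for i in range(npts - 1):
            rr, cc = line(int(ys[i]), int(xs[i]), int(ys[i + 1]), int(xs[i + 1]))
            keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            img[rr[keep], cc[keep]] *= shade


def _add_bubbles(rng, img, density):
    H, W, _ = img.shape
    for _ in range(rng.poisson(density)):
        r = rng.uniform(3, max(4, min(H, W) // 12))
        cy, cx = rng.uniform(r, H - r), rng.uniform(r, W - r)
        rr, cc = disk((cy, cx), r, shape=(H, W))
        img[rr, cc] += 0.04
        rr2, cc2 = disk((cy, cx), max(r - 1.5, 1), shape=(H, W))
        ring = np.zeros((H, W), bool)
        ring[rr, cc] = True
        ring[rr2, cc2] = False
        img[ring] += 0.22


def _add_pen_marks(rng, img, mask, density):
    H, W, _ = img.shape
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return
    cy, cx = ys.mean(), xs.mean()
    rmax = np.hypot(ys - cy, xs - cx).max()
    for _ in range(rng.poisson(density)):
        radius = rmax * rng.uniform(1.25, 1.6)
        t0 = rng.uniform(0, 2 * np.pi)
        span = rng.uniform(0.5, 1.6)
        ts = np.linspace(t0, t0 + span, 40)
        ys_a = (cy + radius * np.sin(ts)).astype(int)
        xs_a = (cx + radius * np.cos(ts)).astype(int)
        colour = np.array([0.10, 0.10, rng.uniform(0.25, 0.45)])
        for dy in (0, 1):
            for dx in (0, 1):
                yy, xx = ys_a + dy, xs_a + dx
                keep = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
                img[yy[keep], xx[keep]] = colour


def _add_reflections(rng, img, density):
    H, W, _ = img.shape
    for _ in range(rng.poisson(density)):
        r = rng.uniform(1.5, max(2.5, min(H, W) / 24))
        cy, cx = rng.uniform(r, H - r), rng.uniform(r, W - r)
        rr, cc = disk((cy, cx), r, shape=(H, W))
        img[rr, cc] = 0.97


def generate_sample(config: SynthConfig, index: int) -> tuple[ImageSample, np.ndarray]:
    """Render sample ``index``: returns the image sample and its exact mask."""
    rng = _sample_rng(config, index)
    cls = config.lesion_class
    if config.class_mix:
        cls = config.class_mix[rng.integers(len(config.class_mix))]
    cfg = _apply_preset(config, cls) if cls else config

    H, W = cfg.height, cfg.width
    mask = _lesion_mask(rng, H, W, cfg.area_fraction, cfg.irregularity)

    skin = _skin_field(rng, H, W)
    contrast = rng.uniform(*cfg.contrast)
    tint = np.array(CLASS_PRESETS[cls]["tint"]) if cls else np.zeros(3)
    lesion_colour_drop = contrast * np.array([1.00, 1.15, 1.05]) - tint
    mottle = gaussian_filter(rng.normal(size=(H, W)), sigma=2.0)
    mottle /= max(np.abs(mottle).max(), 1e-9)
    soft = gaussian_filter(mask.astype(np.float64), sigma=cfg.edge_sigma)
    lesion_field = skin - lesion_colour_drop[None, None, :] * (0.9 + 0.2 * mottle[..., None])
    img = skin * (1.0 - soft[..., None]) + lesion_field * soft[..., None]

    if cfg.hair:
        _add_hair(rng, img, cfg.hair_density)
    if cfg.bubbles:
        _add_bubbles(rng, img, cfg.bubble_density)
    if cfg.pen_marks:
        _add_pen_marks(rng, img, mask, cfg.pen_density)
    if cfg.reflections:
        _add_reflections(rng, img, cfg.reflection_density)

    img += rng.normal(scale=config.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    sample = ImageSample(id=f"SYN_{config.seed}_{index:05d}", image=img,
                         mask=mask, class_label=cls)
    return sample, mask


def generate_samples(config: SynthConfig) -> list[ImageSample]:
    """All ``n_samples`` samples of the configured stream (masks attached)."""
    return [generate_sample(config, i)[0] for i in range(config.n_samples)]


def boundary_irregularity(mask: np.ndarray) -> float:
    """Roughness statistic: perimeter^2 / (4 pi area) - 1 (0 for a disk)."""
    area = int(np.asarray(mask).sum())
    if area == 0:
        return 0.0
    p = _perimeter(np.asarray(mask, dtype=bool), neighborhood=8)
    return float(p * p / (4.0 * np.pi * area) - 1.0)


def generate_dataset(config: SynthConfig, out_dir: str | Path) -> dict:
    """Write images (JPEG), masks (PNG 0/255), labels CSV and a manifest."""
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    masks_dir = out_dir / "masks"
    try:
        images_dir.mkdir(parents=True, exist_ok=True)
        masks_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directories under {out_dir}: {exc}") from exc

    entries = []
    labels: dict[str, str] = {}
    for i in range(config.n_samples):
        sample, mask = generate_sample(config, i)
        img_path = images_dir / f"{sample.id}.jpg"
        mask_path = masks_dir / f"{sample.id}_segmentation.png"
        Image.fromarray((sample.image * 255).round().astype(np.uint8)).save(
            img_path, quality=95)
        Image.fromarray(mask * 255).save(mask_path)
        if sample.class_label:
            labels[sample.id] = sample.class_label
        entries.append({"id": sample.id, "index": i,
                        "class": sample.class_label,
                        "image": str(img_path.relative_to(out_dir)),
                        "mask": str(mask_path.relative_to(out_dir))})
    if labels:
        write_class_labels(out_dir / "labels.csv", labels)
    manifest = {"config": config.to_dict(), "samples": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_manifest(path: str | Path) -> tuple[SynthConfig, list[dict]]:
    with open(Path(path)) as fh:
        manifest = json.load(fh)
    return SynthConfig.from_dict(manifest["config"]), manifest["samples"]
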