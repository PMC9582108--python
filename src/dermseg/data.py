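"""Reading, preprocessing and augmenting dermoscopic image/mask pairs.

Images are RGB float32 in [0, 1]; masks are uint8 in {0, 1} with 1 = lesion.
The on-disk layout follows the ISIC convention of paired directories with
matching stems: ``<id>.jpg`` (or ``.png``) and ``<id>_segmentation.png``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

#: The seven lesion classes used for per-class reporting.
LESION_CLASSES = ("AKIEC", "BCC", "BKL", "DF", "MEL", "NV", "VASC")

#: Network input size (rows, cols) used for training and inference.
DEFAULT_TARGET = (384, 512)

MASK_SUFFIX = "_segmentation"


@dataclass
class ImageSample:
    """One dermoscopic image, optionally with its mask and class label."""

    id: str
    image: np.ndarray                      # (H, W, 3) float32 in [0, 1]
    mask: np.ndarray | None = None         # (H, W) uint8 in {0, 1}
    class_label: str | None = None
    provenance: str = "original"           # original | vflip | hflip | vhflip
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


def load_image(path: str | Path) -> ImageSample:
    """Load a JPEG/PNG image as float RGB; grayscale is replicated to 3 channels."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float32) / 255.0
    except FileNotFoundError:
        raise FileNotFoundError(f"image not found: {path}") from None
    except OSError as exc:
        raise OSError(f"cannot decode image {path}: {exc}") from exc
    return ImageSample(id=path.stem, image=arr)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a PNG mask and binarize it (8-bit value > 127 -> lesion)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except FileNotFoundError:
        raise FileNotFoundError(f"mask not found: {path}") from None
    except OSError as exc:
        raise OSError(f"cannot decode mask {path}: {exc}") from exc
    return (arr > 127).astype(np.uint8)


def load_sample(image_path: str | Path, mask_path: str | Path,
                class_label: str | None = None) -> ImageSample:
    """Load a paired image and mask; a constant mask sets a warning flag."""
    sample = load_image(image_path)
    mask = load_mask(mask_path)
    flags = ()
    if mask.min() == mask.max():
        flags = ("constant_mask",)
    return replace(sample, mask=mask, class_label=class_label, flags=flags)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values 0/255."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(Path(path))


def resize_image(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a float image, clipped back to [0, 1]."""
    if 0 in image.shape:
        raise ValueError(f"cannot resize zero-sized image of shape {image.shape}")
    if image.shape[:2] == tuple(target):
        return image.astype(np.float32)
    out = _sk_resize(image, target, order=1, mode="edge", anti_aliasing=False,
                     preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def resize_mask(mask: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask (binarity preserved)."""
    if 0 in mask.shape:
        raise ValueError(f"cannot resize zero-sized mask of shape {mask.shape}")
    if mask.shape[:2] == tuple(target):
        return mask.astype(np.uint8)
    out = _sk_resize(mask.astype(np.uint8), target, order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out.astype(np.uint8)


def resize_normalize(sample: ImageSample,
                     target: tuple[int, int] = DEFAULT_TARGET) -> ImageSample:
    """Resize to the network input size; values normalised to [0, 1].

    Images are resized bilinearly, masks with nearest-neighbour so they stay
    binary.  Idempotent: applying it twice equals applying it once.
    """
    image = resize_image(sample.image, target)
    mask = resize_mask(sample.mask, target) if sample.mask is not None else None
    return replace(sample, image=image, mask=mask)


_FLIPS = (
    ("vflip", lambda a: a[::-1]),
    ("hflip", lambda a: a[:, ::-1]),
    ("vhflip", lambda a: a[::-1, ::-1]),
)


def augment_flips(samples) -> list[ImageSample]:
    """Return originals plus vertical, horizontal and double flips (4x count).

    Image and mask are flipped jointly; ids and class labels are preserved
    and the ``provenance`` field records the transform.
    """
    out: list[ImageSample] = []
    for s in samples:
        out.append(s)
        for name, op in _FLIPS:
            out.append(replace(
                s,
                image=np.ascontiguousarray(op(s.image)),
                mask=np.ascontiguousarray(op(s.mask)) if s.mask is not None else None,
                provenance=name,
            ))
    return out


def encode_targets(mask: np.ndarray) -> np.ndarray:
    """Binary mask -> (H, W, 2) one-hot; channel 0 background, 1 lesion."""
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary to one-hot encode")
    fg = m.astype(np.float32)
    return np.stack([1.0 - fg, fg], axis=-1)


def decode_targets(onehot: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_targets` (per-pixel argmax)."""
    return np.argmax(onehot, axis=-1).astype(np.uint8)


def read_class_labels(path: str | Path) -> dict[str, str]:
    """Parse an ``image_id,class`` CSV into an id -> class mapping."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                [f.strip() for f in reader.fieldnames[:2]] != ["image_id", "class"]:
            raise ValueError(
                f"{path}: expected CSV header 'image_id,class', got {reader.fieldnames}")
        for row in reader:
            image_id, cls = row["image_id"].strip(), row["class"].strip()
            if cls not in LESION_CLASSES:
                raise ValueError(
                    f"{path}: unknown class {cls!r} for {image_id}; "
                    f"valid classes are {', '.join(LESION_CLASSES)}")
            if image_id in mapping:
                raise ValueError(f"{path}: duplicate image id {image_id!r}")
            mapping[image_id] = cls
    return mapping


def write_class_labels(path: str | Path, mapping: dict[str, str]) -> None:
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "class"])
        for image_id, cls in mapping.items():
            writer.writerow([image_id, cls])


def discover_pairs(images_dir: str | Path, masks_dir: str | Path | None = None,
                   mask_suffix: str = MASK_SUFFIX) -> list[tuple[str, Path, Path]]:
    """Find (id, image_path, mask_path) pairs by matching stems."""
    images_dir = Path(images_dir)
    masks_dir = Path(masks_dir) if masks_dir is not None else images_dir
    pairs = []
    for img in sorted(images_dir.iterdir()):
        if img.suffix.lower() not in (".jpg", ".jpeg", ".png") or \
                img.stem.endswith(mask_suffix):
            continue
        mask = masks_dir / f"{img.stem}{mask_suffix}.png"
        if mask.exists():
            pairs.append((img.stem, img, mask))
    return pairs


def load_dataset(images_dir: str | Path, masks_dir: str | Path | None = None,
                 labels: dict[str, str] | None = None,
                 target: tuple[int, int] | None = None) -> list[ImageSample]:
    """Load and optionally resize every image/mask pair under a directory."""
    samples = []
    for image_id, img_path, mask_path in discover_pairs(images_dir, masks_dir):
        s = load_sample(img_path, mask_path,
                        class_label=labels.get(image_id) if labels else None)
        if target is not None:
            s = resize_normalize(s, target)
        samples.append(s)
    return samples
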