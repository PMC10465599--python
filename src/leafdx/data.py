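"""Seeded synthetic leaf-image generator with six deficiency phenotypes.

The six classes follow the standard visual diagnostics of cucurbit
nutrient stress, encoded as stylized, deterministic colour/texture
patterns on an elliptical leaf laid over a dark background:

* ``nitrogen_deficient``   - uniform yellowing of the whole blade
  (chlorophyll loss lowers the green channel relative to healthy tissue).
* ``phosphorus_deficient`` - dark purplish patches on otherwise green tissue
  (anthocyanin accumulation).
* ``potassium_deficient``  - scorched brown ring along the leaf margin.
* ``calcium_deficient``    - small dark necrotic spots near the leaf apex.
* ``iron_deficient``       - interveinal chlorosis: pale yellow lamina with
  green veins (midrib plus lateral veins).
* ``no_deficiency``        - uniform green blade.

These are synthetic stand-ins for real photographs, chosen so the classes
are separable by colour and texture; the base pattern for a label is a
deterministic function of the label and the image size, and all
stochasticity (additive Gaussian pixel noise) flows from the dataset seed.

The default class counts reproduce the study proportions of the reference
ridge-gourd survey (2259 / 2250 / 1923 / 1910 / 2216 / 2142 images,
12,700 in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from PIL import Image


class ClassLabel(NamedTuple):
    """A deficiency class: integer id (1-6) and canonical name."""

    id: int
    name: str


CLASSES: tuple[ClassLabel, ...] = (
    ClassLabel(1, "nitrogen_deficient"),
    ClassLabel(2, "phosphorus_deficient"),
    ClassLabel(3, "potassium_deficient"),
    ClassLabel(4, "calcium_deficient"),
    ClassLabel(5, "iron_deficient"),
    ClassLabel(6, "no_deficiency"),
)

CLASS_NAMES: tuple[str, ...] = tuple(c.name for c in CLASSES)

#: Class counts of the reference field survey (12,700 images in total).
STUDY_CLASS_COUNTS: dict[str, int] = {
    "nitrogen_deficient": 2259,
    "phosphorus_deficient": 2250,
    "potassium_deficient": 1923,
    "calcium_deficient": 1910,
    "iron_deficient": 2216,
    "no_deficiency": 2142,
}

_BY_NAME = {c.name: c for c in CLASSES}
_BY_ID = {c.id: c for c in CLASSES}


def label_of(key: int | str | ClassLabel) -> ClassLabel:
    """Resolve a class id, name or ClassLabel to the canonical ClassLabel."""
    if isinstance(key, ClassLabel):
        key = key.id
    if isinstance(key, (int, np.integer)):
        try:
            return _BY_ID[int(key)]
        except KeyError:
            raise ValueError(f"unknown class id: {key!r}") from None
    try:
        return _BY_NAME[key]
    except KeyError:
        raise ValueError(f"unknown class label: {key!r}") from None


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for a synthetic dataset.

    Parameters
    ----------
    class_counts
        Images per class, keyed by class name. Defaults to the study
        proportions (12,700 images); tests use much smaller counts.
    image_size
        (height, width) in pixels, at least (16, 16).
    noise_sigma
        Std of additive Gaussian pixel noise on the [0, 1] intensity scale.
    seed
        Root seed; the generator is a pure function of the spec.
    """

    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_CLASS_COUNTS)
    )
    image_size: tuple[int, int] = (64, 64)
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in self.class_counts:
            label_of(name)
        if any(n < 0 for n in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        if sum(self.class_counts.values()) <= 0:
            raise ValueError("dataset must contain at least one image")
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValueError("image_size must be at least (16, 16)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class LabeledImage:
    """An H x W x 3 float image on [0, 1] with its class label and id."""

    pixels: np.ndarray
    label: ClassLabel
    id: str


# Background grey and the stylized tissue colours (R, G, B on [0, 1]).
_BACKGROUND = np.array([0.06, 0.06, 0.06])
_HEALTHY_GREEN = np.array([0.13, 0.60, 0.14])
_N_YELLOW = np.array([0.72, 0.52, 0.10])  # green mean below healthy by design
_P_BASE = np.array([0.15, 0.45, 0.12])
_P_PURPLE = np.array([0.28, 0.06, 0.32])
_K_GREEN = np.array([0.15, 0.55, 0.13])
_K_SCORCH = np.array([0.45, 0.24, 0.06])
_CA_GREEN = np.array([0.16, 0.58, 0.14])
_CA_NECROTIC = np.array([0.10, 0.06, 0.03])
_FE_CHLOROTIC = np.array([0.70, 0.68, 0.20])
_FE_VEIN = np.array([0.12, 0.50, 0.12])


def _unit_grid(image_size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = image_size
    yy = np.linspace(-1.0, 1.0, h)[:, None] * np.ones((1, w))
    xx = np.ones((h, 1)) * np.linspace(-1.0, 1.0, w)[None, :]
    return yy, xx


def leaf_mask(image_size: tuple[int, int]) -> np.ndarray:
    """Ground-truth boolean mask of the elliptical leaf blade."""
    yy, xx = _unit_grid(image_size)
    return (yy / 0.80) ** 2 + (xx / 0.92) ** 2 <= 1.0


def _ellipse_radius(image_size: tuple[int, int]) -> np.ndarray:
    """Normalized elliptical radius (1.0 on the leaf boundary)."""
    yy, xx = _unit_grid(image_size)
    return np.sqrt((yy / 0.80) ** 2 + (xx / 0.92) ** 2)


def base_pattern(label: int | str | ClassLabel, image_size: tuple[int, int]) -> np.ndarray:
    """Deterministic noiseless phenotype image for a class.

    The pattern depends only on (label, image_size); ``render_leaf`` adds
    seeded noise on top of it.
    """
    lab = label_of(label)
    h, w = image_size
    mask = leaf_mask(image_size)
    r = _ellipse_radius(image_size)
    yy, xx = _unit_grid(image_size)

    img = np.empty((h, w, 3))
    img[:] = _BACKGROUND

    if lab.name == "no_deficiency":
        tissue = np.broadcast_to(_HEALTHY_GREEN, (h, w, 3)).copy()
    elif lab.name == "nitrogen_deficient":
        tissue = np.broadcast_to(_N_YELLOW, (h, w, 3)).copy()
    elif lab.name == "phosphorus_deficient":
        tissue = np.broadcast_to(_P_BASE, (h, w, 3)).copy()
        # three fixed purplish blobs
        for cy, cx, rad in ((-0.35, -0.30, 0.28), (0.25, 0.30, 0.32), (0.45, -0.35, 0.22)):
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
            tissue[blob] = _P_PURPLE
    elif lab.name == "potassium_deficient":
        tissue = np.broadcast_to(_K_GREEN, (h, w, 3)).copy()
        tissue[r >= 0.72] = _K_SCORCH
    elif lab.name == "calcium_deficient":
        tissue = np.broadcast_to(_CA_GREEN, (h, w, 3)).copy()
        # necrotic spots clustered toward the apex (top of the blade)
        for cy, cx in ((-0.62, 0.0), (-0.45, -0.28), (-0.45, 0.28), (-0.25, 0.0), (-0.15, -0.40)):
            spot = (yy - cy) ** 2 + (xx - cx) ** 2 <= 0.11**2
            tissue[spot] = _CA_NECROTIC
    elif lab.name == "iron_deficient":
        tissue = np.broadcast_to(_FE_CHLOROTIC, (h, w, 3)).copy()
        vein = np.abs(xx) <= 0.05  # midrib
        lateral = (np.floor((yy + 1.0) * h / 2.0).astype(int) % max(h // 8, 2)) == 0
        tissue[vein | lateral] = _FE_VEIN
    else:  # pragma: no cover - label_of already validated
        raise ValueError(f"unknown class label: {label!r}")

    img[mask] = tissue[mask]
    return img


def render_leaf(
    label: int | str | ClassLabel,
    image_size: tuple[int, int] = (64, 64),
    noise_sigma: float = 0.0,
    rng: np.random.Generator | int | None = None,
    image_id: str | None = None,
) -> LabeledImage:
    """Render one synthetic leaf image: base pattern + Gaussian noise.

    ``rng`` may be a Generator, an int seed, or None (no noise drawn when
    sigma is 0). Pixels are clipped to [0, 1].
    """
    lab = label_of(label)
    h, w = image_size
    if h < 16 or w < 16:
        raise ValueError("image_size must be at least (16, 16)")
    img = base_pattern(lab, image_size)
    if noise_sigma > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return LabeledImage(pixels=img, label=lab, id=image_id or f"{lab.name}_0")


def generate_dataset(spec: DatasetSpec) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Generate all images of a spec plus their manifest.

    Returns ``(images, manifest)`` where the manifest has columns
    ``id, path, label`` (path is the relative PNG path used by
    :func:`write_dataset`). Two calls with equal specs produce
    byte-identical images and manifests.
    """
    root = np.random.SeedSequence(spec.seed)
    images: list[LabeledImage] = []
    rows: list[dict[str, str]] = []
    # one child stream per class, consumed in Table order, so the result is
    # a pure function of the spec regardless of which classes are present
    streams = {c.name: np.random.default_rng(s) for c, s in zip(CLASSES, root.spawn(len(CLASSES)))}
    for cls in CLASSES:
        count = spec.class_counts.get(cls.name, 0)
        rng = streams[cls.name]
        for i in range(count):
            image_id = f"{cls.name}_{i:05d}"
            img = render_leaf(cls, spec.image_size, spec.noise_sigma, rng, image_id)
            images.append(img)
            rows.append({"id": image_id, "path": f"{cls.name}/{image_id}.png", "label": cls.name})
    manifest = pd.DataFrame(rows, columns=["id", "path", "label"])
    return images, manifest


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.round(pixels * 255.0), 0, 255).astype(np.uint8)


def from_uint8(arr: np.ndarray) -> np.ndarray:
    return arr.astype(np.float64) / 255.0


def write_dataset(images: Sequence[LabeledImage], manifest: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write 8-bit RGB PNGs plus ``manifest.csv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = {img.id: img for img in images}
    for row in manifest.itertuples(index=False):
        img = by_id[row.id]
        path = out / row.path
        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(to_uint8(img.pixels)).save(path)
    manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"


def read_dataset(manifest_path: str | Path) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Load a dataset written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    root = manifest_path.parent
    images = []
    for row in manifest.itertuples(index=False):
        arr = from_uint8(np.asarray(Image.open(root / row.path).convert("RGB")))
        images.append(LabeledImage(pixels=arr, label=label_of(row.label), id=row.id))
    return images, manifest


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(
    images: Sequence[LabeledImage],
    train_fraction: float,
    seed: int = 0,
) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Stratified train/test split with a seeded per-class shuffle.

    The per-class train count is round-half-up(train_fraction * class
    count); any rounding drift against round-half-up(fraction * total) is
    corrected on the largest class so totals are deterministic.
    """
    if not images:
        raise ValueError("dataset is empty")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    by_class: dict[str, list[LabeledImage]] = {c.name: [] for c in CLASSES}
    for img in images:
        by_class[img.label.name].append(img)
    present = [c.name for c in CLASSES if by_class[c.name]]
    counts = {name: len(by_class[name]) for name in present}
    train_counts = {name: _round_half_up(train_fraction * n) for name, n in counts.items()}
    # correct rounding drift against the overall target, largest classes
    # first, one image at a time, so each class stays within 1/total_c of
    # the requested fraction
    target_total = _round_half_up(train_fraction * sum(counts.values()))
    drift = target_total - sum(train_counts.values())
    step = 1 if drift > 0 else -1
    order = sorted(present, key=lambda n: (-counts[n], CLASSES.index(_BY_NAME[n])))
    i = 0
    while drift != 0 and order:
        name = order[i % len(order)]
        adjusted = train_counts[name] + step
        if 0 <= adjusted <= counts[name] and abs(adjusted - train_fraction * counts[name]) <= 1.0:
            train_counts[name] = adjusted
            drift -= step
        i += 1
        if i > 10 * len(order):  # cannot satisfy both; keep per-class rounding
            break
    rng = np.random.default_rng(seed)
    train: list[LabeledImage] = []
    test: list[LabeledImage] = []
    for name in present:
        pool = list(by_class[name])
        order = rng.permutation(len(pool))
        n_train = train_counts[name]
        train.extend(pool[i] for i in order[:n_train])
        test.extend(pool[i] for i in order[n_train:])
    return train, test


def stratified_train_counts(class_counts: dict[str, int], train_fraction: float) -> dict[str, int]:
    """Per-class train counts under the split rule (exposed for inspection)."""
    return {name: _round_half_up(train_fraction * n) for name, n in class_counts.items()}
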