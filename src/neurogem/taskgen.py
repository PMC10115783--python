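"""Synthetic tasks with the structure the encodings assume, plus benchmark readers.

Two generators make the package fully testable offline:

- **Blob tasks** emulate MNIST-like data: 28×28 single-channel images whose
  class identity is carried by a fixed template of spatially localized
  Gaussian bumps, observed under i.i.d. pixel noise. Localized structure is
  deliberate — spatial gene fields need spatial signal to find, just as digit
  strokes concentrate information in the center of the frame.
- **Glyph pools** emulate Omniglot: many classes, few samples each, every
  class a jittered rendering of a random polyline "character", split into
  disjoint train/test class sets for N-way K-shot episodes.

Real benchmarks load through :func:`read_idx` (the MNIST IDX container) and
:func:`load_image_folders` (directory-per-class layouts). Synthetic images
are floats in [0, 1]; benchmark pixels are rescaled to [0, 1] on load.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BlobTaskSpec",
    "GlyphPoolSpec",
    "Dataset",
    "GlyphPool",
    "make_blob_task",
    "make_glyph_pool",
    "read_idx",
    "load_image_folders",
]


@dataclass(frozen=True)
class BlobTaskSpec:
    n_classes: int = 5
    samples_per_class: int = 1000
    grid_size: int = 28
    bumps_per_class: int = 3
    noise_sd: float = 0.1
    holdout_fraction: float = 0.2
    seed: int = 0


@dataclass(frozen=True)
class GlyphPoolSpec:
    n_classes: int = 120
    samples_per_class: int = 20
    grid_size: int = 12
    min_strokes: int = 2
    max_strokes: int = 4
    train_fraction: float = 0.75
    jitter: float = 0.03
    noise_sd: float = 0.03
    max_template_similarity: float = 0.85  # cosine; redraw near-duplicate classes
    seed: int = 0


@dataclass
class Dataset:
    """Flat-image classification task with a train stream and a hold-out set."""

    train_x: np.ndarray
    train_y: np.ndarray
    holdout_x: np.ndarray
    holdout_y: np.ndarray
    grid_size: int

    @property
    def n_features(self) -> int:
        return self.train_x.shape[1]


@dataclass
class GlyphPool:
    """Class-keyed episodic pool with a disjoint train/test class split."""

    classes: dict  # label -> (n, d) float array
    train_classes: list
    test_classes: list
    grid_size: int

    @property
    def train_pool(self) -> dict:
        return {c: self.classes[c] for c in self.train_classes}

    @property
    def test_pool(self) -> dict:
        return {c: self.classes[c] for c in self.test_classes}


def _gaussian_bump(grid: np.ndarray, cx: float, cy: float, s: float) -> np.ndarray:
    gx, gy = grid
    return np.exp(-(((gx - cx) ** 2 + (gy - cy) ** 2) / s**2))


def make_blob_task(spec: BlobTaskSpec) -> Dataset:
    """Balanced multi-class images: fixed class template + pixel noise.

    At ``noise_sd = 0`` all samples of a class are identical, so classes are
    linearly separable by construction. Deterministic in ``spec.seed``.
    """
    if spec.n_classes < 2:
        raise ValueError("need at least two classes")
    if spec.grid_size < 2:
        raise ValueError(f"degenerate grid size {spec.grid_size}")
    rng = np.random.default_rng(spec.seed)
    g = spec.grid_size
    axis = np.linspace(0.0, 1.0, g)
    grid = np.meshgrid(axis, axis, indexing="ij")

    templates = []
    for _ in range(spec.n_classes):
        img = np.zeros((g, g))
        for _ in range(spec.bumps_per_class):
            cx, cy = rng.uniform(0.2, 0.8, 2)
            s = rng.uniform(0.08, 0.2)
            img += rng.uniform(0.5, 1.0) * _gaussian_bump(grid, cx, cy, s)
        templates.append(img / max(img.max(), 1e-12))

    xs, ys = [], []
    for label, tpl in enumerate(templates):
        noise = rng.normal(0.0, spec.noise_sd, (spec.samples_per_class, g, g))
        xs.append(np.clip(tpl[None] + noise, 0.0, 1.0).reshape(spec.samples_per_class, -1))
        ys.append(np.full(spec.samples_per_class, label))
    x = np.concatenate(xs)
    y = np.concatenate(ys)

    order = rng.permutation(len(x))
    x, y = x[order], y[order]
    n_hold = int(round(spec.holdout_fraction * len(x)))
    return Dataset(
        train_x=x[n_hold:], train_y=y[n_hold:],
        holdout_x=x[:n_hold], holdout_y=y[:n_hold],
        grid_size=g,
    )


def _render_polyline(verts: np.ndarray, g: int, pen_sd: float) -> np.ndarray:
    axis = np.linspace(0.0, 1.0, g)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    img = np.zeros((g, g))
    for a, b in zip(verts[:-1], verts[1:]):
        for t in np.linspace(0.0, 1.0, 3 * g):
            p = (1 - t) * a + t * b
            img = np.maximum(
                img, np.exp(-(((gx - p[0]) ** 2 + (gy - p[1]) ** 2) / pen_sd**2))
            )
    return img


def make_glyph_pool(spec: GlyphPoolSpec) -> GlyphPool:
    """Episodic pool of polyline glyph classes with jittered renderings.

    Class templates are rejection-sampled so that no two classes render to
    near-identical images (cosine similarity capped by the spec): characters
    drawn from real alphabets are mutually distinguishable, and a pool that
    violates that would mis-state the difficulty of the few-shot problem.
    """
    rng = np.random.default_rng(spec.seed)
    n_train = int(round(spec.train_fraction * spec.n_classes))
    n_test = spec.n_classes - n_train
    if n_test < 1:
        raise ValueError(
            f"class split leaves {n_test} test classes; lower train_fraction"
        )
    g = spec.grid_size
    pen = 1.2 / g
    classes: dict[int, np.ndarray] = {}
    kept_templates: list[np.ndarray] = []
    for label in range(spec.n_classes):
        for _attempt in range(50):
            n_strokes = int(rng.integers(spec.min_strokes, spec.max_strokes + 1))
            verts = rng.uniform(0.15, 0.85, (n_strokes + 1, 2))
            tpl = _render_polyline(verts, g, pen).reshape(-1)
            unit = tpl / max(np.linalg.norm(tpl), 1e-12)
            if all(float(unit @ u) <= spec.max_template_similarity
                   for u in kept_templates):
                break
        kept_templates.append(unit)
        samples = []
        for _ in range(spec.samples_per_class):
            shift = rng.normal(0.0, spec.jitter, (1, 2))
            wobble = rng.normal(0.0, spec.jitter / 2, verts.shape)
            img = _render_polyline(verts + shift + wobble, g, pen)
            img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, 1.0)
            samples.append(img.reshape(-1))
        classes[label] = np.stack(samples)
    labels = list(range(spec.n_classes))
    return GlyphPool(
        classes=classes,
        train_classes=labels[:n_train],
        test_classes=labels[n_train:],
        grid_size=g,
    )


# -- standard-format readers ----------------------------------------------

_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
               0x0D: ">f4", 0x0E: ">f8"}


def read_idx(path, expect_images: bool | None = None) -> np.ndarray:
    """Parse an IDX container (the MNIST distribution format).

    The big-endian header is two zero bytes, a dtype code, and the number of
    dimensions, followed by one 4-byte big-endian size per dimension.
    ``expect_images=True`` insists on a 3-D payload, ``False`` on 1-D labels.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 4:
        raise ValueError(f"{path}: truncated IDX header at offset {len(raw)} (need 4 bytes)")
    zeros, dtype_code, ndim = raw[0] << 8 | raw[1], raw[2], raw[3]
    if zeros != 0 or dtype_code not in _IDX_DTYPES:
        raise ValueError(f"{path}: bad IDX magic {raw[:4].hex()} at offset 0")
    if expect_images is True and ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image file, header says {ndim}-D")
    if expect_images is False and ndim != 1:
        raise ValueError(f"{path}: expected a 1-D label file, header says {ndim}-D")
    header_end = 4 + 4 * ndim
    if len(raw) < header_end:
        raise ValueError(f"{path}: truncated dimension table at offset {len(raw)}")
    dims = struct.unpack(f">{ndim}I", raw[4:header_end])
    dtype = np.dtype(_IDX_DTYPES[dtype_code])
    expected = int(np.prod(dims)) * dtype.itemsize
    if len(raw) - header_end < expected:
        raise ValueError(
            f"{path}: truncated payload at offset {len(raw)} (need {header_end + expected})"
        )
    data = np.frombuffer(raw, dtype=dtype, count=int(np.prod(dims)), offset=header_end)
    return data.reshape(dims)


def load_image_folders(root, size: int | None = None) -> dict:
    """Directory-per-class image layout → class-keyed float pool in [0, 1].

    Requires pillow only when actually called on image files; synthetic pools
    never touch it.
    """
    from PIL import Image  # local import: optional dependency path

    root = Path(root)
    pool: dict[str, np.ndarray] = {}
    for cdir in sorted(p for p in root.iterdir() if p.is_dir()):
        imgs = []
        for f in sorted(cdir.iterdir()):
            if f.suffix.lower() not in {".png", ".jpg", ".jpeg", ".bmp", ".gif"}:
                continue
            im = Image.open(f).convert("L")
            if size is not None:
                im = im.resize((size, size))
            imgs.append(np.asarray(im, dtype=np.float64).reshape(-1) / 255.0)
        if imgs:
            pool[cdir.name] = np.stack(imgs)
    if not pool:
        raise FileNotFoundError(f"no class folders with images under {root}")
    return pool
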