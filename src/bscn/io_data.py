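"""Dataset I/O, patch extraction, augmentation, and train/test splits.

Supports the directory layouts of the common fundus benchmarks (DRIVE,
STARE, HRF, CHASE_DB1) plus the in-package synthetic scenes, without ever
downloading anything: a :class:`DatasetSpec` names the root, filename
patterns and split scheme, and :func:`make_splits` reproduces the published
protocols — DRIVE 20 train / 20 test with 18,000 + 2,000 patches, STARE
leave-one-out over 20 images, HRF 38 + 9 with 36,000 + 4,000 patches,
CHASE_DB1 first 20 / last 8.

Augmentation follows the published family: exponential contrast on the S
and V channels of HSV (coefficient grid -0.6..0.8 step 0.2), scaling
0.75..1.05 step 0.05, translation -80..100 px step 20, and optional
rotation (disabled by default).  Identity parameters are an exact no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DatasetSpec",
    "PatchPair",
    "AugmentParams",
    "SplitPlan",
    "load_image_label",
    "extract_patches",
    "augment",
    "make_splits",
]

HSV_GAMMA_GRID = tuple(np.round(np.arange(-0.6, 0.8001, 0.2), 10))
SCALE_GRID = tuple(np.round(np.arange(0.75, 1.0501, 0.05), 10))
SHIFT_GRID = tuple(range(-80, 101, 20))

_IMG_SUFFIXES = (".png", ".gif", ".tif", ".tiff", ".ppm", ".jpg", ".jpeg")


class DataError(ValueError):
    """Inconsistent dataset contents (sizes, counts, missing labels)."""


@dataclass
class DatasetSpec:
    name: str                       # DRIVE | STARE | HRF | CHASE_DB1 | SYNTH
    root: Path
    image_pattern: str = "*_image.png"
    label_pattern: str = "{stem}_label.png"
    fov_pattern: str | None = "{stem}_fov.png"
    image_ids: list[str] = field(default_factory=list)  # explicit order
    train_ids: list[str] | None = None   # SYNTH / manual splits
    test_ids: list[str] | None = None

    def __post_init__(self):
        self.root = Path(self.root)
        if self.name not in ("DRIVE", "STARE", "HRF", "CHASE_DB1", "SYNTH"):
            raise ValueError(f"unknown dataset name {self.name!r}")

    def list_ids(self):
        if self.image_ids:
            return list(self.image_ids)
        stems = []
        suffix_len = len(Path(self.image_pattern).suffix)
        tag = self.image_pattern.replace("*", "").rsplit(".", 1)[0]
        for p in sorted(self.root.glob(self.image_pattern)):
            stem = p.name[: len(p.name) - suffix_len]
            if tag:
                stem = stem.replace(tag, "")
            stems.append(stem)
        return stems


@dataclass
class PatchPair:
    image_patch: np.ndarray   # [size, size, 3]
    label_patch: np.ndarray   # [size, size] binary
    image_id: str
    corner: tuple[int, int]   # top-left (row, col), half-open extent


@dataclass(frozen=True)
class AugmentParams:
    hsv_gamma: float = 0.0
    scale: float = 1.0
    shift: tuple[int, int] = (0, 0)
    rotation_deg: float | None = None

    @classmethod
    def sample(cls, rng, rotation_set=None):
        """Draw one setting from the published grids."""
        rot = None
        if rotation_set:
            rot = float(rng.choice(list(rotation_set)))
        return cls(
            hsv_gamma=float(rng.choice(HSV_GAMMA_GRID)),
            scale=float(rng.choice(SCALE_GRID)),
            shift=(int(rng.choice(SHIFT_GRID)), int(rng.choice(SHIFT_GRID))),
            rotation_deg=rot,
        )


# ------------------------------------------------------------------ loading


def _find_file(root, pattern, stem):
    cand = root / pattern.format(stem=stem)
    if cand.exists():
        return cand
    base = pattern.format(stem=stem)
    stem_only = Path(base).stem
    for suf in _IMG_SUFFIXES:
        alt = root / f"{stem_only}{suf}"
        if alt.exists():
            return alt
    return None


def load_image_label(spec: DatasetSpec, image_id):
    """Load (image in [0,1], binary label, fov mask) for one image id."""
    import imageio.v3 as iio

    img_path = _find_file(spec.root, spec.image_pattern.replace("*", "{stem}"),
                          image_id)
    if img_path is None:
        raise IOError(f"image for id {image_id!r} not found under {spec.root}")
    lbl_path = _find_file(spec.root, spec.label_pattern, image_id)
    if lbl_path is None:
        raise IOError(f"label for id {image_id!r} not found under {spec.root}")
    image = np.asarray(iio.imread(img_path)).astype(np.float64)
    if image.ndim == 2:
        image = np.repeat(image[..., None], 3, axis=2)
    if image.max() > 1.0:
        image = image / 255.0
    label = np.asarray(iio.imread(lbl_path))
    if label.ndim == 3:
        label = label[..., 0]
    label = (label > 0).astype(np.uint8)
    if label.shape != image.shape[:2]:
        raise DataError(
            f"{image_id}: label {label.shape} does not match image "
            f"{image.shape[:2]}"
        )
    fov = None
    if spec.fov_pattern:
        fov_path = _find_file(spec.root, spec.fov_pattern, image_id)
        if fov_path is not None:
            fov = np.asarray(iio.imread(fov_path))
            if fov.ndim == 3:
                fov = fov[..., 0]
            fov = (fov > 0).astype(np.uint8)
            if fov.shape != label.shape:
                raise DataError(f"{image_id}: fov shape mismatch")
    if fov is None:
        fov = np.ones_like(label)
    return image, label, fov


# ------------------------------------------------------------------ patches


def extract_patches(image, label, size=50, count=None, seed=0, mode="random"):
    """Cut aligned image/label patches.

    random mode: ``count`` uniformly placed in-bounds patches, reproducible
    for a fixed seed.  grid mode: non-overlapping tiling, partial tiles
    dropped.  Patches are half-open [r, r+size) x [c, c+size).
    """
    image = np.asarray(image)
    label = np.asarray(label)
    rows, cols = label.shape
    if size > rows or size > cols:
        raise ValueError(f"patch size {size} exceeds image dims {rows}x{cols}")
    patches = []
    if mode == "grid":
        for r in range(0, rows - size + 1, size):
            for c in range(0, cols - size + 1, size):
                patches.append(PatchPair(
                    image[r : r + size, c : c + size].copy(),
                    label[r : r + size, c : c + size].copy(),
                    image_id="", corner=(r, c)))
    elif mode == "random":
        if count is None:
            raise ValueError("random mode requires count")
        rng = np.random.default_rng(seed)
        rr = rng.integers(0, rows - size + 1, count)
        cc = rng.integers(0, cols - size + 1, count)
        for r, c in zip(rr.tolist(), cc.tolist()):
            patches.append(PatchPair(
                image[r : r + size, c : c + size].copy(),
                label[r : r + size, c : c + size].copy(),
                image_id="", corner=(r, c)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return patches


# --------------------------------------------------------------- augmenting


def _int_shift(arr, dy, dx):
    """Integer translation with zero fill; (dy, dx) move content down/right."""
    out = np.zeros_like(arr)
    rows, cols = arr.shape[:2]
    src_r = slice(max(0, -dy), min(rows, rows - dy))
    src_c = slice(max(0, -dx), min(cols, cols - dx))
    dst_r = slice(max(0, dy), min(rows, rows + dy))
    dst_c = slice(max(0, dx), min(cols, cols + dx))
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def _recentre(arr, shape):
    """Place a (possibly differently sized) array centred on a zero canvas."""
    out = np.zeros(shape[:2] + arr.shape[2:], dtype=arr.dtype)
    r_off = (shape[0] - arr.shape[0]) // 2
    c_off = (shape[1] - arr.shape[1]) // 2
    rs = slice(max(0, r_off), max(0, r_off) + min(arr.shape[0], shape[0]))
    cs = slice(max(0, c_off), max(0, c_off) + min(arr.shape[1], shape[1]))
    ar = slice(max(0, -r_off), max(0, -r_off) + (rs.stop - rs.start))
    ac = slice(max(0, -c_off), max(0, -c_off) + (cs.stop - cs.start))
    out[rs, cs] = arr[ar, ac]
    return out


def augment(image, label, params: AugmentParams):
    """Apply one augmentation setting identically to image and label.

    Contrast: S and V channels of HSV raised to the power (1 + hsv_gamma),
    so gamma 0 is the identity, negative gammas brighten/saturate and
    positive gammas darken.  Geometry: scale about the centre (canvas size
    preserved, zero fill), optional rotation, then integer translation.
    Labels use nearest-neighbour resampling and are re-binarised at 0.5.
    Identity parameters return the inputs unchanged (exact).
    """
    from skimage import color, transform

    image = np.asarray(image, dtype=np.float64)
    label = np.asarray(label)
    out_img, out_lbl = image, label
    if params.hsv_gamma != 0.0:
        hsv = color.rgb2hsv(out_img)
        hsv[..., 1] = hsv[..., 1] ** (1.0 + params.hsv_gamma)
        hsv[..., 2] = hsv[..., 2] ** (1.0 + params.hsv_gamma)
        out_img = color.hsv2rgb(hsv)
    if params.scale != 1.0:
        shape = out_img.shape
        scaled_img = transform.rescale(out_img, params.scale, order=1,
                                       channel_axis=2, anti_aliasing=False)
        scaled_lbl = transform.rescale(out_lbl.astype(np.float64),
                                       params.scale, order=0,
                                       anti_aliasing=False)
        out_img = _recentre(scaled_img, shape)
        out_lbl = (_recentre(scaled_lbl, shape) > 0.5).astype(label.dtype)
    if params.rotation_deg is not None and params.rotation_deg != 0.0:
        out_img = transform.rotate(out_img, params.rotation_deg, order=1,
                                   mode="constant", cval=0.0)
        out_lbl = (transform.rotate(out_lbl.astype(np.float64),
                                    params.rotation_deg, order=0,
                                    mode="constant", cval=0.0) > 0.5
                   ).astype(label.dtype)
    dy, dx = params.shift
    if (dy, dx) != (0, 0):
        out_img = _int_shift(out_img, dy, dx)
        out_lbl = _int_shift(out_lbl, dy, dx)
    return out_img, out_lbl


# ------------------------------------------------------------------- splits


@dataclass
class SplitPlan:
    """folds: list of (train_ids, test_ids); patch budgets for train/val."""

    folds: list[tuple[list[str], list[str]]]
    n_train_patches: int | None = None
    n_val_patches: int | None = None
    patch_size: int = 50


def make_splits(spec: DatasetSpec) -> SplitPlan:
    """Build the published split protocol for the named dataset."""
    ids = spec.list_ids()
    name = spec.name
    if name == "DRIVE":
        if spec.train_ids is None:
            if len(ids) != 40:
                raise DataError(
                    f"DRIVE expects 40 images (20 train + 20 test), found "
                    f"{len(ids)}")
            train, test = ids[:20], ids[20:]
        else:
            train, test = list(spec.train_ids), list(spec.test_ids or [])
        return SplitPlan([(train, test)], 18_000, 2_000)
    if name == "STARE":
        if len(ids) != 20:
            raise DataError(f"STARE expects 20 images, found {len(ids)}")
        folds = [([i for i in ids if i != held], [held]) for held in ids]
        return SplitPlan(folds)
    if name == "HRF":
        if spec.train_ids is not None:
            train, test = list(spec.train_ids), list(spec.test_ids or [])
        else:
            if len(ids) < 47:
                raise DataError(
                    f"HRF expects >= 47 images for the 38/9 split, found "
                    f"{len(ids)}")
            train, test = ids[:38], ids[38:47]
        return SplitPlan([(train, test)], 36_000, 4_000)
    if name == "CHASE_DB1":
        if len(ids) != 28:
            raise DataError(f"CHASE_DB1 expects 28 images, found {len(ids)}")
        return SplitPlan([(ids[:20], ids[20:])])
    # SYNTH: explicit user split
    train = list(spec.train_ids) if spec.train_ids is not None else ids
    test = list(spec.test_ids) if spec.test_ids is not None else []
    return SplitPlan([(train, test)])
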