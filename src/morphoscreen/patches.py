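"""Frames, patch geometry, dissection and leakage-free dataset splits.

A brightfield frame (natively 1408 x 1040 px) is dissected into square
224 x 224 patches on a fixed grid; patches inherit the frame's class label,
and train/validation/test membership is decided at the *image* level so no
frame ever contributes patches to two partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .labels import CLASSES, check_label

PATCH_SIZE = 224
NATIVE_HEIGHT = 1040
NATIVE_WIDTH = 1408

#: backbone-standard intensity standardization applied after per-patch
#: min-max scaling to [0, 1]
STANDARD_MEAN = 0.5
STANDARD_STD = 0.25


@dataclass
class BrightfieldImage:
    """One grayscale frame plus acquisition metadata."""

    image_id: str
    pixels: np.ndarray  # 2-D float array, intensities in [0, 1]
    well_id: str | None = None
    hour: int | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError(f"non-finite intensities in frame {self.image_id!r}")
        if self.hour is not None and not (0 <= int(self.hour) <= 48):
            raise ValueError(f"hour must be in 0..48, got {self.hour}")
        if self.condition is not None:
            check_label(self.condition)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class PatchGridSpec:
    """Row/column offsets of disjoint ``patch_size`` tiles inside a frame."""

    patch_size: int = PATCH_SIZE
    row_offsets: tuple[int, ...] = ()
    col_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if any(o < 0 for o in self.row_offsets + self.col_offsets):
            raise ValueError("grid offsets must be non-negative")

    @property
    def rows(self) -> int:
        return len(self.row_offsets)

    @property
    def cols(self) -> int:
        return len(self.col_offsets)

    @property
    def patches_per_frame(self) -> int:
        return self.rows * self.cols

    @classmethod
    def native(cls) -> "PatchGridSpec":
        """The default 4 x 4 grid for the native 1408 x 1040 geometry.

        Rows are four contiguous 224-px bands vertically centered in
        1040 px (top margin 72 px); columns are four 224-px bands equally
        spaced across 1408 px with symmetric margins.  Yields the
        bookkeeping-consistent 16 patches per frame (64 frames -> 1024
        patches, 22 frames -> 352 patches per class).
        """
        rows = tuple(72 + i * 224 for i in range(4))        # 72, 296, 520, 744
        cols = tuple(103 + i * (224 + 102) for i in range(4))  # 103, 429, 755, 1081
        return cls(patch_size=PATCH_SIZE, row_offsets=rows, col_offsets=cols)

    @classmethod
    def tiling(
        cls, height: int, width: int, patch_size: int = PATCH_SIZE
    ) -> "PatchGridSpec":
        """Maximal non-overlapping grid for an arbitrary frame geometry.

        Fits as many disjoint ``patch_size`` bands as possible along each
        axis, distributing the leftover pixels evenly between margins and
        gaps.
        """
        if height < patch_size or width < patch_size:
            raise ValueError(
                f"frame {height}x{width} smaller than patch size {patch_size}"
            )

        def axis_offsets(dim: int) -> tuple[int, ...]:
            n = dim // patch_size
            slack = dim - n * patch_size
            gap = slack // (n + 1)
            margin = (dim - n * patch_size - (n - 1) * gap) // 2
            return tuple(margin + i * (patch_size + gap) for i in range(n))

        return cls(
            patch_size=patch_size,
            row_offsets=axis_offsets(height),
            col_offsets=axis_offsets(width),
        )

    @classmethod
    def for_frame(
        cls, height: int, width: int, patch_size: int = PATCH_SIZE
    ) -> "PatchGridSpec":
        """Native grid for the native geometry, maximal tiling otherwise."""
        if (height, width) == (NATIVE_HEIGHT, NATIVE_WIDTH) and patch_size == PATCH_SIZE:
            return cls.native()
        return cls.tiling(height, width, patch_size)

    def validate_for(self, height: int, width: int) -> None:
        if height < self.patch_size or width < self.patch_size:
            raise ValueError(
                f"frame {height}x{width} smaller than patch size {self.patch_size}"
            )
        if any(o + self.patch_size > height for o in self.row_offsets) or any(
            o + self.patch_size > width for o in self.col_offsets
        ):
            raise ValueError("grid offsets out of frame bounds")


@dataclass
class Patch:
    """A single-channel 224 x 224 tile cut from a parent frame."""

    image_id: str
    grid_row: int
    grid_col: int
    pixels: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("patch pixels must be square and 2-D")
        if self.label is not None:
            check_label(self.label)

    @property
    def patch_id(self) -> str:
        return f"{self.image_id}:r{self.grid_row}c{self.grid_col}"


def dissect_image(image: BrightfieldImage, grid: PatchGridSpec) -> list[Patch]:
    """Cut a frame into row-major grid patches, copying pixel content exactly."""
    h, w = image.shape
    grid.validate_for(h, w)
    ps = grid.patch_size
    patches = []
    for r, ro in enumerate(grid.row_offsets):
        for c, co in enumerate(grid.col_offsets):
            patches.append(
                Patch(
                    image_id=image.image_id,
                    grid_row=r,
                    grid_col=c,
                    pixels=image.pixels[ro : ro + ps, co : co + ps].copy(),
                    label=image.condition,
                )
            )
    return patches


def stack_to_three_channels(patch: Patch | np.ndarray) -> np.ndarray:
    """Replicate a single-channel patch into the (H, W, 3) input format.

    All three output channels are bit-equal to the input channel.
    """
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    if pixels.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel patch, got shape {pixels.shape}")
    return np.repeat(pixels[:, :, None], 3, axis=2)


def normalize_patch(pixels: np.ndarray) -> np.ndarray:
    """Per-patch min-max scaling to [0, 1] followed by mean/SD standardization.

    A constant patch maps to zero after standardization.
    """
    pixels = np.asarray(pixels, dtype=np.float32)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi > lo:
        scaled = (pixels - lo) / (hi - lo)
    else:
        scaled = np.full_like(pixels, STANDARD_MEAN)
    return (scaled - STANDARD_MEAN) / STANDARD_STD


@dataclass(frozen=True)
class DatasetSplit:
    """Image-level train/validation/test membership (pairwise disjoint)."""

    train: frozenset[str]
    val: frozenset[str]
    test: frozenset[str]

    def __post_init__(self) -> None:
        if self.train & self.val or self.train & self.test or self.val & self.test:
            raise ValueError("split partitions must be pairwise disjoint")

    def to_json(self, path: str | Path) -> None:
        payload = {k: sorted(getattr(self, k)) for k in ("train", "val", "test")}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        payload = json.loads(Path(path).read_text())
        return cls(*(frozenset(payload[k]) for k in ("train", "val", "test")))


def split_images(
    images_per_class: Mapping[str, Sequence[str]],
    counts: tuple[int, int, int] = (64, 22, 22),
    seed: int = 0,
) -> DatasetSplit:
    """Per-class image-level split with exact counts.

    ``images_per_class`` maps each class label to its available image ids.
    With the default counts each class needs at least 108 images
    (64 train + 22 validation + 22 test).  Deterministic for a given seed.
    """
    n_train, n_val, n_test = counts
    need = n_train + n_val + n_test
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    val: set[str] = set()
    test: set[str] = set()
    for label in sorted(images_per_class, key=lambda l: CLASSES.index(check_label(l))):
        ids = list(images_per_class[label])
        if len(ids) < need:
            raise ValueError(
                f"class {label!r} has {len(ids)} images; {need} required for counts {counts}"
            )
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        train.update(shuffled[:n_train])
        val.update(shuffled[n_train : n_train + n_val])
        test.update(shuffled[n_train + n_val : need])
    return DatasetSplit(frozenset(train), frozenset(val), frozenset(test))


@dataclass
class PatchSet:
    """A lazy, labeled set of patches defined by (image, grid position) rows.

    The index carries one row per patch; pixel content is materialized on
    demand so datasets of thousands of 224 x 224 patches never need to sit
    in memory at once.
    """

    index: pd.DataFrame  # columns: image_id, grid_row, grid_col, label
    images: Mapping[str, BrightfieldImage] = field(repr=False)
    grid: PatchGridSpec = field(default_factory=PatchGridSpec.native)

    def __len__(self) -> int:
        return len(self.index)

    @property
    def counts_per_class(self) -> dict[str, int]:
        counts = self.index["label"].value_counts().to_dict()
        return {lab: int(counts.get(lab, 0)) for lab in CLASSES}

    @property
    def labels(self) -> np.ndarray:
        return self.index["label"].to_numpy()

    def iter_batches(
        self, batch_size: int = 128
    ) -> Iterator[tuple[np.ndarray, np.ndarray, list[str]]]:
        """Yield (pixels (B, ps, ps), label indices (B,), patch ids)."""
        ps = self.grid.patch_size
        rows = self.index
        for start in range(0, len(rows), batch_size):
            chunk = rows.iloc[start : start + batch_size]
            pix = np.empty((len(chunk), ps, ps), dtype=np.float32)
            ids = []
            for k, row in enumerate(chunk.itertuples(index=False)):
                img = self.images[row.image_id]
                ro = self.grid.row_offsets[row.grid_row]
                co = self.grid.col_offsets[row.grid_col]
                pix[k] = img.pixels[ro : ro + ps, co : co + ps]
                ids.append(f"{row.image_id}:r{row.grid_row}c{row.grid_col}")
            y = np.array([CLASSES.index(l) for l in chunk["label"]], dtype=np.int64)
            yield pix, y, ids

    def materialize(self) -> list[Patch]:
        out = []
        for pix, y, ids in self.iter_batches(batch_size=256):
            for k, pid in enumerate(ids):
                image_id, pos = pid.rsplit(":", 1)
                r, c = pos[1:].split("c")
                out.append(
                    Patch(image_id, int(r), int(c), pix[k], label=CLASSES[y[k]])
                )
        return out


def build_patch_dataset(
    images: Mapping[str, BrightfieldImage] | Iterable[BrightfieldImage],
    split: DatasetSplit,
    grid: PatchGridSpec | None = None,
) -> dict[str, PatchSet]:
    """Expand an image-level split into per-partition labeled patch sets.

    Every image contributes ``rows x cols`` patches that inherit its class
    label; per-class patch counts are therefore images x patches-per-frame
    (64 frames and the native grid give 1024 training patches per class).
    """
    if not isinstance(images, Mapping):
        images = {img.image_id: img for img in images}
    grid = grid or PatchGridSpec.native()
    out: dict[str, PatchSet] = {}
    for part in ("train", "val", "test"):
        ids = sorted(getattr(split, part))
        rows = []
        for image_id in ids:
            img = images[image_id]
            if img.condition is None:
                raise ValueError(f"image {image_id!r} has no class label")
            grid.validate_for(*img.shape)
            for r in range(grid.rows):
                for c in range(grid.cols):
                    rows.append((image_id, r, c, img.condition))
        index = pd.DataFrame(
            rows, columns=["image_id", "grid_row", "grid_col", "label"]
        )
        out[part] = PatchSet(index=index, images=images, grid=grid)
    return out


# ---------------------------------------------------------------------------
# frame I/O


def read_frame(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG frame as float32 intensities in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an RGB read of a grayscale image
        arr = arr.mean(axis=2)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32) / np.iinfo(arr.dtype).max
    return arr.astype(np.float32)


def load_manifest(manifest_csv: str | Path) -> dict[str, BrightfieldImage]:
    """Load frames listed in a manifest CSV (image_id, path, well, hour, condition)."""
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv)
    images = {}
    for row in df.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest_csv.parent / path
        images[row.image_id] = BrightfieldImage(
            image_id=row.image_id,
            pixels=read_frame(path),
            well_id=None if pd.isna(row.well) else str(row.well),
            hour=None if pd.isna(row.hour) else int(row.hour),
            condition=None if pd.isna(row.condition) else str(row.condition),
        )
    return images
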