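"""Raw 12-bit mammogram views -> model-ready 224x224 three-channel inputs.

The pipeline mirrors how full-field digital mammograms are prepared for an
ImageNet-pretrained vision transformer:

1. pixel-average subsampling with a k x k kernel (default 5), which takes
   the native 70 um pitch to 350 um;
2. fixed-range normalization of the 12-bit values into [0, 255];
3. duplication of the single grey channel into three RGB channels;
4. direct anisotropic bilinear resize to 224 x 224;
5. (optional, default on) per-channel ImageNet standardization, matching
   the statistics the pretrained backbone was trained with.

Normalization is deliberately fixed-range (v * 255/4095) rather than
per-image min-max: the bilateral-asymmetry signal the four-view model
exploits relies on absolute intensity comparability across the views of a
case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

VIEWS = ("LCC", "RCC", "LMLO", "RMLO")
"""Canonical view order: the concatenation order of the global sequence."""

MAX_12BIT = 4095
NATIVE_PITCH_UM = 70.0

# ImageNet channel statistics, on the [0, 1] scale.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class RawMammogram:
    """A single-view 12-bit mammogram.

    pixels are integers in [0, 4095]; pixel_pitch_um is the physical pixel
    size (70 um native; k-fold larger after k x k averaging).
    """

    pixels: np.ndarray
    view: str
    pixel_pitch_um: float = NATIVE_PITCH_UM
    case_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if self.pixels.min() < 0 or self.pixels.max() > MAX_12BIT:
            raise ValueError("pixel values must lie in [0, 4095]")


@dataclass
class ModelInputImage:
    """A 224x224x3 (or side x side x 3) float image ready for the model."""

    pixels: np.ndarray
    case_id: str = ""
    view: str = ""


def pixel_average_downsample(img: RawMammogram, k: int = 5) -> RawMammogram:
    """Subsample by averaging k x k windows, truncated at the edges.

    Output dims are ceil(H/k) x ceil(W/k) — edge windows may be partial —
    and each output value is the rounded arithmetic mean of its window.
    This edge convention is what maps 2558x3327 -> 512x666 and
    3327x4091 -> 666x819 at k=5.
    """
    if not isinstance(k, (int, np.integer)) or k <= 0:
        raise ValueError(f"kernel size must be a positive integer, got {k!r}")
    px = img.pixels
    h, w = px.shape
    row_idx = np.arange(0, h, k)
    col_idx = np.arange(0, w, k)
    sums = np.add.reduceat(np.add.reduceat(px.astype(np.float64), row_idx, axis=0),
                           col_idx, axis=1)
    row_counts = np.minimum(row_idx + k, h) - row_idx
    col_counts = np.minimum(col_idx + k, w) - col_idx
    means = sums / np.outer(row_counts, col_counts)
    out = np.rint(means).astype(px.dtype if np.issubdtype(px.dtype, np.integer) else np.int32)
    return RawMammogram(pixels=out, view=img.view,
                        pixel_pitch_um=img.pixel_pitch_um * k, case_id=img.case_id)


def normalize_to_255(img: RawMammogram | np.ndarray) -> np.ndarray:
    """Fixed-range linear map of 12-bit values onto [0, 255] (v * 255/4095)."""
    px = img.pixels if isinstance(img, RawMammogram) else np.asarray(img)
    if px.min() < 0 or px.max() > MAX_12BIT:
        raise ValueError("input values must lie in [0, 4095]")
    return px.astype(np.float32) * np.float32(255.0 / MAX_12BIT)


def stack_channels(img: np.ndarray) -> np.ndarray:
    """Duplicate a 2-D grey image into three identical channels (H, W, 3)."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    return np.repeat(img[:, :, None], 3, axis=2)


def resize_to_model(img: np.ndarray, side: int = 224) -> np.ndarray:
    """Bilinear resize of an (H, W, 3) image to (side, side, 3).

    Aspect ratio is not preserved: the resize is direct and anisotropic.
    An input already at the target size is returned unchanged (copy).
    """
    img = np.asarray(img, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {img.shape}")
    if side < 2:
        raise ValueError(f"target side must be >= 2, got {side}")
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("input spatial dims must be >= 2")
    if img.shape[:2] == (side, side):
        return img.copy()
    out = np.empty((side, side, 3), dtype=np.float32)
    for c in range(3):
        chan = Image.fromarray(img[:, :, c], mode="F")
        out[:, :, c] = np.asarray(chan.resize((side, side), Image.BILINEAR),
                                  dtype=np.float32)
    return out


def standardize(img: np.ndarray,
                mean: np.ndarray = IMAGENET_MEAN,
                std: np.ndarray = IMAGENET_STD) -> np.ndarray:
    """Scale [0, 255] pixels to [0, 1] and apply per-channel mean/std."""
    return (np.asarray(img, dtype=np.float32) / 255.0 - mean) / std


def preprocess_view(img: RawMammogram, kernel: int = 5, side: int = 224,
                    do_standardize: bool = True) -> ModelInputImage:
    """Full single-view pipeline: downsample, normalize, stack, resize."""
    down = pixel_average_downsample(img, kernel) if kernel > 1 else img
    grey = normalize_to_255(down)
    rgb = resize_to_model(stack_channels(grey), side)
    if do_standardize:
        rgb = standardize(rgb)
    return ModelInputImage(pixels=rgb, case_id=img.case_id, view=img.view)


def preprocess_case(views: list[RawMammogram], kernel: int = 5, side: int = 224,
                    do_standardize: bool = True) -> list[ModelInputImage]:
    """Preprocess the four views of a case into canonical LCC, RCC, LMLO,
    RMLO order (the order in which the global sequence is concatenated).

    Raises ValueError if any view is missing or duplicated.
    """
    by_view = {}
    for v in views:
        if v.view in by_view:
            raise ValueError(f"duplicated view {v.view!r}")
        by_view[v.view] = v
    missing = [name for name in VIEWS if name not in by_view]
    if missing or len(views) != 4:
        raise ValueError(f"a case needs exactly one of each view; missing {missing}, "
                         f"got {len(views)} images")
    return [preprocess_view(by_view[name], kernel, side, do_standardize)
            for name in VIEWS]


def case_to_array(views: list[ModelInputImage]) -> np.ndarray:
    """Stack four preprocessed views into a (4, side, side, 3) float32 array."""
    return np.stack([np.asarray(v.pixels, dtype=np.float32) for v in views])
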