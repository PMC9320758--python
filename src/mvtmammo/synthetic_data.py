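"""Synthetic four-view mammogram cases with relational class structure.

The real screening dataset this emulates is private; what matters for the
method is not photorealism but the *statistical structure the model must
exploit*: a malignant case shows a focal finding in both ipsilateral views
(CC and MLO) of exactly one breast, while a benign case is bilaterally
symmetric.  The generator encodes malignancy purely relationally:

* every breast carries a smooth blob texture; for benign cases the left
  and right textures are correlated, for malignant cases they are drawn
  independently (bilateral asymmetry);
* every case carries exactly one focal blob per breast.  Benign cases
  place the *same* blob (same mirrored position, same contrast) in both
  breasts; malignant cases place a true lesion in one breast and a
  distractor at an independent position in the other, with a bilateral
  contrast gap (lesion c + g/2, distractor c - g/2, random sign).  Each
  breast's blob appears at geometrically consistent positions in its CC
  and MLO views (ipsilateral correspondence).

Because every single image contains one focal blob with the same marginal
contrast distribution regardless of class, a single-image intensity
summary carries (by construction) no class information — the signal lives
in the *relations* between views, which is exactly what the global
transformer blocks are meant to capture.

Geometry mimics the source population: two canvas sizes (2558x3327 and
3327x4091 at native scale), 12-bit integers, four views per case.  A
shrink factor (default 1/8) keeps desk-scale experiments fast; full-size
rendering is a flag away.

Randomness is drawn from numpy SeedSequences keyed by (seed, case_index)
and (seed, case_index, view), so any case can be regenerated bit-for-bit
in isolation, independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio

from .preprocessing import VIEWS, RawMammogram, MAX_12BIT, NATIVE_PITCH_UM

__all__ = ["GeneratorConfig", "SyntheticCase", "generate_case",
           "generate_dataset", "iter_cases", "write_dataset", "read_dataset",
           "cohort_config"]

FULL_CANVASES = ((2558, 3327), (3327, 4091))


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    Contrast/amplitude units are 12-bit intensity levels; positions and
    radii are in breast coordinates, i.e. fractions of the canvas.
    """

    n_cases: int = 100
    malignant_fraction: float = 470 / 949
    canvas_sizes: tuple[tuple[int, int], ...] = FULL_CANVASES
    scale: float = 0.125          # shrink factor for the canvases (1.0 = native)
    n_texture_blobs: int = 18
    texture_amplitude: float = 300.0
    texture_sigma_range: tuple[float, float] = (0.08, 0.22)
    background_level: float = 900.0
    noise_sigma: float = 25.0
    lesion_radius_range: tuple[float, float] = (0.09, 0.14)
    lesion_contrast_range: tuple[float, float] = (900.0, 1600.0)
    # Malignant cases split the pair contrast c into c +/- mismatch/2 with a
    # random sign, creating a bilateral contrast gap.  Benign cases draw one
    # contrast from the SAME c +/- mismatch/2 mixture and use it for both
    # breasts, so the per-image contrast marginal is identical across
    # classes — the gap is visible only by comparing the two breasts.
    contrast_mismatch_range: tuple[float, float] = (600.0, 1000.0)
    benign_texture_jitter: float = 0.15   # relative amplitude jitter, left vs right
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise ValueError("malignant_fraction must lie in [0, 1]")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if any(h <= 0 or w <= 0 for h, w in self.canvas_sizes):
            raise ValueError("canvas dims must be positive")
        if self.lesion_radius_range[1] >= 0.5:
            raise ValueError("lesion radius must be smaller than the canvas")

    @property
    def n_malignant(self) -> int:
        return int(round(self.n_cases * self.malignant_fraction))


def cohort_config(**overrides) -> GeneratorConfig:
    """The source-cohort preset: 949 cases -> 3796 images, 470 malignant
    and 479 benign."""
    base = dict(n_cases=949, malignant_fraction=470 / 949)
    base.update(overrides)
    return GeneratorConfig(**base)


@dataclass
class SyntheticCase:
    """Four raw views in canonical order plus ground truth."""

    case_id: str
    views: list[RawMammogram]          # LCC, RCC, LMLO, RMLO
    label: str                         # 'benign' | 'malignant'
    lesion_masks: list[np.ndarray]     # boolean, one per view; empty unless malignant
    seed: int


# ------------------------------------------------------------------ geometry

_MLO_ANGLE = np.deg2rad(28.0)


def _view_point(u: float, v: float, view: str) -> tuple[float, float]:
    """Map a breast-coordinate point into view coordinates.

    CC views use the identity; MLO views rotate about the canvas centre,
    emulating the oblique projection.  Right-side views are mirrored
    horizontally, so a bilaterally matched pair of findings sits at
    mirrored pixel locations.
    """
    if view.endswith("MLO"):
        cu, cv = u - 0.5, v - 0.5
        ca, sa = np.cos(_MLO_ANGLE), np.sin(_MLO_ANGLE)
        u, v = cu * ca - cv * sa + 0.5, cu * sa + cv * ca + 0.5
    if view.startswith("R"):
        u = 1.0 - u
    return u, v


def _render_blobs(shape: tuple[int, int], view: str,
                  centers: np.ndarray, sigmas: np.ndarray,
                  amps: np.ndarray) -> np.ndarray:
    """Sum of isotropic gaussian blobs given in breast coordinates."""
    h, w = shape
    vv, uu = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    out = np.zeros(shape, dtype=np.float64)
    for (cu, cv), s, a in zip(centers, sigmas, amps):
        cu, cv = _view_point(cu, cv, view)
        out += a * np.exp(-((uu - cu) ** 2 + (vv - cv) ** 2) / (2 * s * s))
    return out


def _render_lesion(shape: tuple[int, int], view: str, cu: float, cv: float,
                   radius: float, contrast: float, aspect: float,
                   theta: float) -> tuple[np.ndarray, np.ndarray]:
    """One soft-edged elliptical finding; returns (intensity, mask)."""
    h, w = shape
    vv, uu = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    cu, cv = _view_point(cu, cv, view)
    du, dv = uu - cu, vv - cv
    ct, st = np.cos(theta), np.sin(theta)
    x1 = (du * ct + dv * st) / radius
    x2 = (-du * st + dv * ct) / (radius * aspect)
    q = x1 * x1 + x2 * x2
    intensity = contrast * np.exp(-q / 2.0)
    return intensity, q <= 2.0


# ----------------------------------------------------------------- generator

def _case_label(config: GeneratorConfig, case_index: int) -> str:
    return "malignant" if case_index < config.n_malignant else "benign"


def generate_case(config: GeneratorConfig, case_index: int) -> SyntheticCase:
    """Render the four views of one case, deterministically from
    (config.seed, case_index)."""
    if not 0 <= case_index < config.n_cases:
        raise ValueError(f"case_index {case_index} out of range")
    label = _case_label(config, case_index)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, case_index)))

    canvas = config.canvas_sizes[rng.integers(len(config.canvas_sizes))]
    shape = (max(2, int(round(canvas[0] * config.scale))),
             max(2, int(round(canvas[1] * config.scale))))

    # Breast textures: shared blob geometry; amplitudes correlated (benign)
    # or redrawn independently (malignant).
    k = config.n_texture_blobs
    centers = rng.uniform(0.05, 0.95, (k, 2))
    sigmas = rng.uniform(*config.texture_sigma_range, k)
    amps_left = rng.uniform(0.2, 1.0, k) * config.texture_amplitude
    if label == "benign":
        jitter = rng.normal(1.0, config.benign_texture_jitter, k)
        amps_right = amps_left * np.clip(jitter, 0.5, 1.5)
        centers_right, sigmas_right = centers, sigmas
    else:
        centers_right = rng.uniform(0.05, 0.95, (k, 2))
        sigmas_right = rng.uniform(*config.texture_sigma_range, k)
        amps_right = rng.uniform(0.2, 1.0, k) * config.texture_amplitude

    # Focal findings: one per breast, always.
    def draw_finding():
        return dict(
            cu=rng.uniform(0.3, 0.7), cv=rng.uniform(0.3, 0.7),
            radius=rng.uniform(*config.lesion_radius_range),
            contrast=rng.uniform(*config.lesion_contrast_range),
            aspect=rng.uniform(0.6, 1.0), theta=rng.uniform(0, np.pi),
        )

    shared = draw_finding()
    gap = rng.uniform(*config.contrast_mismatch_range)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    c = shared["contrast"]
    if label == "benign":
        # One value from the same c +/- gap/2 mixture, used bilaterally.
        shared["contrast"] = c + sign * gap / 2.0
        finding = {"L": shared, "R": dict(shared)}   # bilaterally matched
        lesion_side = None
    else:
        lesion_side = "L" if rng.random() < 0.5 else "R"
        other = draw_finding()                        # independent distractor
        shared["contrast"] = c + sign * gap / 2.0
        other["contrast"] = c - sign * gap / 2.0
        finding = {lesion_side: shared,
                   "R" if lesion_side == "L" else "L": other}

    views: list[RawMammogram] = []
    masks: list[np.ndarray] = []
    case_id = f"case{case_index:04d}"
    for view_idx, view in enumerate(VIEWS):
        side = view[0]  # 'L' or 'R'
        if side == "L":
            c, s, a = centers, sigmas, amps_left
        else:
            c, s, a = centers_right, sigmas_right, amps_right
        img = config.background_level + _render_blobs(shape, view, c, s, a)
        f = finding[side]
        intensity, mask = _render_lesion(shape, view, f["cu"], f["cv"], f["radius"],
                                         f["contrast"], f["aspect"], f["theta"])
        img += intensity
        view_rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, case_index, view_idx)))
        img += view_rng.normal(0.0, config.noise_sigma, shape)
        pixels = np.clip(np.rint(img), 0, MAX_12BIT).astype(np.uint16)
        views.append(RawMammogram(pixels=pixels, view=view,
                                  pixel_pitch_um=NATIVE_PITCH_UM / config.scale,
                                  case_id=case_id))
        is_lesion_view = label == "malignant" and side == lesion_side
        masks.append(mask if is_lesion_view else np.zeros(shape, dtype=bool))

    return SyntheticCase(case_id=case_id, views=views, label=label,
                         lesion_masks=masks, seed=config.seed)


def iter_cases(config: GeneratorConfig):
    for i in range(config.n_cases):
        yield generate_case(config, i)


def _manifest_rows(case: SyntheticCase):
    for raw in case.views:
        yield dict(case_id=case.case_id, view=raw.view,
                   path=f"{case.case_id}_{raw.view}.png", label=case.label)


def generate_dataset(config: GeneratorConfig) -> tuple[list[SyntheticCase], pd.DataFrame]:
    """Materialize the cohort and its manifest (4 rows per case)."""
    cases = list(iter_cases(config))
    manifest = pd.DataFrame([row for c in cases for row in _manifest_rows(c)])
    return cases, manifest


def write_dataset(cases: list[SyntheticCase], directory: str | Path,
                  write_masks: bool = False) -> pd.DataFrame:
    """Write one 16-bit grayscale PNG per view plus manifest.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        for raw, mask in zip(case.views, case.lesion_masks):
            name = f"{case.case_id}_{raw.view}.png"
            iio.imwrite(directory / name, raw.pixels.astype(np.uint16))
            rows.append(dict(case_id=case.case_id, view=raw.view,
                             path=name, label=case.label))
            if write_masks:
                mask_dir = directory / "masks"
                mask_dir.mkdir(exist_ok=True)
                iio.imwrite(mask_dir / name, (mask * 255).astype(np.uint8))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def read_dataset(directory: str | Path) -> tuple[list[SyntheticCase], pd.DataFrame]:
    """Load a written dataset back into SyntheticCase objects (no masks)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    cases = []
    for case_id, group in manifest.groupby("case_id", sort=True):
        by_view = {row.view: row for row in group.itertuples()}
        views = []
        for view in VIEWS:
            row = by_view[view]
            pixels = np.asarray(iio.imread(directory / row.path))
            views.append(RawMammogram(pixels=pixels, view=view, case_id=str(case_id)))
        labels = set(group["label"])
        if len(labels) != 1:
            raise ValueError(f"inconsistent labels for case {case_id}: {labels}")
        cases.append(SyntheticCase(case_id=str(case_id), views=views,
                                   label=labels.pop(),
                                   lesion_masks=[np.zeros((1, 1), bool)] * 4,
                                   seed=-1))
    return cases, manifest
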