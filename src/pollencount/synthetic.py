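"""Seeded generator of Alexander-stain-like pollen scenes with ground truth.

The generator renders what the stain produces under a brightfield
microscope, reduced to the features the counting pipeline actually exploits:

* a pale slide background (high intensity in all channels),
* viable grains as dark-blue ellipses — *dark in both the red and green
  channels*,
* non-viable grains as light-blue ellipses — dark in red but *bright in
  green*, which is the entire viability-discrimination mechanism,
* optional touching clusters (the watershed's job), sub-threshold specks and
  oversized low-circularity streaks (the size/circularity filter's job),
  sensor noise, and a linear illumination gradient (the background
  subtraction's job).

Every object's geometry and class are recorded, so true total count, viable
count and percent viability are known exactly and can stand in for manual
counts.

Stain colour model (mean RGB before jitter and noise): viable (70, 50, 120),
non-viable (150, 190, 220), background (235, 225, 230), debris (60, 60, 70).

Random-stream order for a fixed seed: grain class shuffle, per-grain area /
eccentricity / orientation draws, free-grain placement, clustered-grain
placement, per-grain colour jitter (interleaved with rendering), small
debris, large debris, pixel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .imaging import RgbImage

__all__ = [
    "GenerationError",
    "SceneParams",
    "GrainTruth",
    "GroundTruth",
    "BenchmarkRanges",
    "generate_scene",
    "generate_benchmark",
]

VIABLE_RGB = (70, 50, 120)
NONVIABLE_RGB = (150, 190, 220)
BACKGROUND_RGB = (235, 225, 230)
DEBRIS_RGB = (60, 60, 70)

_MAX_PACKING_FRACTION = 0.30
_PLACEMENT_TRIES = 2000


class GenerationError(RuntimeError):
    """Raised when a scene cannot be generated under the given parameters."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic micrograph.

    Defaults describe a typical well-prepared slide: 50 grains at 80%
    viability, areas inside the standard 100-900 pixel^2 counting window
    (sampled from [150, 850] so rasterization cannot push a grain out of
    it), nearly round grains (eccentricity <= 0.6 keeps circularity above
    ~0.9), no clusters or debris, and mild sensor noise (sd 2 intensity
    levels).
    """

    width: int = 1024
    height: int = 768
    n_viable: int = 40
    n_nonviable: int = 10
    grain_area_range: tuple[float, float] = (150.0, 850.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    cluster_fraction: float = 0.0
    n_debris_small: int = 0
    n_debris_large: int = 0
    noise_sd: float = 2.0
    illumination_gradient: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_viable, self.n_nonviable, self.n_debris_small,
               self.n_debris_large) < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.grain_area_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad grain_area_range ({lo}, {hi})")
        if hi > self.width * self.height:
            raise ValueError("grain_area_range exceeds the image area")
        elo, ehi = self.eccentricity_range
        if not 0 <= elo <= ehi < 1:
            raise ValueError("eccentricity_range must lie within [0, 1)")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GrainTruth:
    """Geometry and class of one rendered object."""

    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (major, minor)
    orientation: float  # radians
    grain_class: str  # viable | nonviable | debris
    area_px: int  # rasterized pixel count


@dataclass(frozen=True)
class GroundTruth:
    """Exact annotation of a generated scene; debris is not pollen."""

    grains: tuple[GrainTruth, ...]

    @property
    def true_viable(self) -> int:
        return sum(g.grain_class == "viable" for g in self.grains)

    @property
    def true_total(self) -> int:
        return sum(g.grain_class in ("viable", "nonviable") for g in self.grains)

    @property
    def true_pv(self) -> float | None:
        if self.true_total == 0:
            return None
        return 100.0 * self.true_viable / self.true_total


def _ellipse_pixels(shape, center, semi_major, semi_minor, theta):
    """Rows/cols of pixels whose centres lie inside the ellipse (inclusive)."""
    r0, c0 = center
    rad = max(semi_major, semi_minor) + 1.5
    rlo = max(0, int(math.floor(r0 - rad)))
    rhi = min(shape[0], int(math.ceil(r0 + rad)) + 1)
    clo = max(0, int(math.floor(c0 - rad)))
    chi = min(shape[1], int(math.ceil(c0 + rad)) + 1)
    yy, xx = np.mgrid[rlo:rhi, clo:chi]
    dy = yy - r0
    dx = xx - c0
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
    return yy[inside], xx[inside]


def _rough_blob_pixels(shape, center, r_base, phase, n_lobes=12, amplitude=0.35):
    """Pixels of a spiky star-shaped blob (low-circularity large debris).

    The sinusoidally modulated radius inflates the perimeter so circularity
    drops to ~0.15 while the area stays above 900 pixel^2 for r_base >= 18 —
    rejected by both halves of every catalogued filter.
    """
    r0, c0 = center
    rad = r_base * (1 + amplitude) + 1.5
    rlo = max(0, int(math.floor(r0 - rad)))
    rhi = min(shape[0], int(math.ceil(r0 + rad)) + 1)
    clo = max(0, int(math.floor(c0 - rad)))
    chi = min(shape[1], int(math.ceil(c0 + rad)) + 1)
    yy, xx = np.mgrid[rlo:rhi, clo:chi]
    dy = yy - r0
    dx = xx - c0
    ang = np.arctan2(dy, dx)
    inside = np.hypot(dy, dx) <= r_base * (1 + amplitude * np.sin(n_lobes * ang + phase))
    return yy[inside], xx[inside]


def _axes_from_area(area: float, eccentricity: float) -> tuple[float, float]:
    ratio = math.sqrt(1.0 - eccentricity**2)  # minor / major
    major = math.sqrt(area / (math.pi * ratio))
    return major, major * ratio


def _place_free(rng, radius, placed, height, width, gap=4.0):
    margin = radius + 2.0
    if height - margin <= margin or width - margin <= margin:
        raise GenerationError("image too small for the requested object size")
    for _ in range(_PLACEMENT_TRIES):
        r = rng.uniform(margin, height - margin)
        c = rng.uniform(margin, width - margin)
        if all(
            math.hypot(r - pr, c - pc) >= radius + prad + gap
            for pr, pc, prad in placed
        ):
            return r, c
    raise GenerationError(
        "could not place an object without overlap; reduce counts or size"
    )


def _place_clustered(rng, radius, placed, height, width):
    """Attach a grain to an existing one so the pair touches/overlaps.

    Pollen grains are rigid, so clustered grains sit nearly tangent with
    only slight projected interpenetration: centre separation is
    0.85-0.98 x the sum of the two radii (always above 1.2 x their mean).
    The pair merges into one blob after thresholding, yet each grain keeps
    a distinct distance-map lobe for the watershed to find; deeper overlap
    would engulf a small grain in a large one with no neck left to cut.
    """
    if not placed:
        return _place_free(rng, radius, placed, height, width)
    for _ in range(_PLACEMENT_TRIES):
        ai = int(rng.integers(len(placed)))
        ar, ac, arad = placed[ai]
        sep = rng.uniform(0.85, 0.98) * (radius + arad)
        ang = rng.uniform(0, 2 * math.pi)
        r = ar + sep * math.sin(ang)
        c = ac + sep * math.cos(ang)
        margin = radius + 2.0
        if not (margin <= r <= height - margin and margin <= c <= width - margin):
            continue
        if all(
            j == ai or math.hypot(r - pr, c - pc) >= radius + prad + 4.0
            for j, (pr, pc, prad) in enumerate(placed)
        ):
            return r, c
    raise GenerationError("could not attach a clustered grain; scene too dense")


def generate_scene(
    params: SceneParams, areas: np.ndarray | None = None
) -> tuple[RgbImage, GroundTruth]:
    """Render one synthetic micrograph; deterministic for a fixed seed.

    ``areas`` optionally fixes each grain's target area (pixel^2) instead of
    sampling from ``params.grain_area_range``; the sampling draw still
    happens so the random stream (and hence all downstream geometry) is the
    same either way.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    n = params.n_viable + params.n_nonviable

    classes = ["viable"] * params.n_viable + ["nonviable"] * params.n_nonviable
    classes = [classes[i] for i in rng.permutation(n)] if n else []

    sampled = rng.uniform(*params.grain_area_range, size=n)
    if areas is None:
        areas = sampled
    else:
        areas = np.asarray(areas, dtype=float)
        if areas.shape != (n,):
            raise ValueError(f"need {n} grain areas, got shape {areas.shape}")
    eccs = rng.uniform(*params.eccentricity_range, size=n)
    thetas = rng.uniform(0, math.pi, size=n)

    if areas.sum() > _MAX_PACKING_FRACTION * h * w:
        raise GenerationError(
            f"requested grain area {areas.sum():.0f} px^2 exceeds "
            f"{_MAX_PACKING_FRACTION:.0%} of the image"
        )

    axes = [_axes_from_area(a, e) for a, e in zip(areas, eccs)]
    radii = [ax[0] for ax in axes]

    n_clustered = int(round(params.cluster_fraction * n))
    placed: list[tuple[float, float, float]] = []
    centers: list[tuple[float, float]] = []
    for i in range(n - n_clustered):
        r, c = _place_free(rng, radii[i], placed, h, w)
        placed.append((r, c, radii[i]))
        centers.append((r, c))
    for i in range(n - n_clustered, n):
        r, c = _place_clustered(rng, radii[i], placed, h, w)
        placed.append((r, c, radii[i]))
        centers.append((r, c))

    img = np.empty((h, w, 3), dtype=float)
    img[:] = BACKGROUND_RGB

    base = {"viable": VIABLE_RGB, "nonviable": NONVIABLE_RGB}
    grains: list[GrainTruth] = []
    for i in range(n):
        jitter = rng.normal(0.0, 5.0, size=3)
        color = np.clip(np.asarray(base[classes[i]], float) + jitter, 0, 255)
        rows, cols = _ellipse_pixels((h, w), centers[i], *axes[i], thetas[i])
        img[rows, cols] = color
        grains.append(
            GrainTruth(centers[i], axes[i], thetas[i], classes[i], int(len(rows)))
        )

    # sub-threshold specks: dark, area well below the 100 px^2 filter floor
    for _ in range(params.n_debris_small):
        area = rng.uniform(10, 60)
        ecc = rng.uniform(0.0, 0.7)
        theta = rng.uniform(0, math.pi)
        major, minor = _axes_from_area(area, ecc)
        r, c = _place_free(rng, major, placed, h, w)
        placed.append((r, c, major))
        rows, cols = _ellipse_pixels((h, w), (r, c), major, minor, theta)
        img[rows, cols] = DEBRIS_RGB
        grains.append(
            GrainTruth((r, c), (major, minor), theta, "debris", int(len(rows)))
        )

    # oversized foreign matter: dark spiky blobs, area > 900 px^2 and
    # circularity far below 0.4
    for _ in range(params.n_debris_large):
        r_base = rng.uniform(18, 28)
        phase = rng.uniform(0, 2 * math.pi)
        outer = r_base * 1.35
        r, c = _place_free(rng, outer, placed, h, w)
        placed.append((r, c, outer))
        rows, cols = _rough_blob_pixels((h, w), (r, c), r_base, phase)
        img[rows, cols] = DEBRIS_RGB
        grains.append(
            GrainTruth((r, c), (r_base * 1.35, r_base * 0.65), phase, "debris",
                       int(len(rows)))
        )

    if params.illumination_gradient:
        img = img + np.linspace(-25.0, 25.0, w)[None, :, None]
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)

    pixels = np.clip(img, 0, 255).round().astype(np.uint8)
    return (
        RgbImage(pixels, id=f"scene-{params.seed:08d}"),
        GroundTruth(grains=tuple(grains)),
    )


@dataclass(frozen=True)
class BenchmarkRanges:
    """Spread of ground truth across a benchmark image set.

    Totals and viabilities span wide ranges so correlations against
    automatic counts are well supported.  A fraction of grains is drawn
    from the small end of the counting window ([~100, 200) px^2): real
    pollen spans the whole window, and these small grains are what
    distinguishes the 100-900 size filter from the 200-900 one.
    """

    total: tuple[int, int] = (20, 120)
    viability_pct: tuple[float, float] = (10.0, 95.0)
    grain_area: tuple[float, float] = (215.0, 850.0)
    small_grain_area: tuple[float, float] = (115.0, 190.0)
    small_grain_fraction: float = 0.10


def generate_benchmark(
    n_images: int = 31,
    truth_ranges: BenchmarkRanges | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    scene_template: SceneParams | None = None,
) -> tuple[list[tuple[RgbImage, GroundTruth]], pd.DataFrame]:
    """Generate a benchmark image set plus its ground-truth count table.

    Per image, the true total is uniform over ``truth_ranges.total`` and the
    viable count follows a uniform viability; each grain falls in the
    small-area window with the configured fraction (binomially).  Scenes
    inherit clustering / debris / noise settings from ``scene_template``
    (default: 10% clustered grains, 5 small specks, 1 large fibre, noise
    sd 2 — a realistic but benign slide).

    Returns the scene list and a DataFrame with columns image_id,
    manual_total, manual_viable (ground truth standing in for manual
    counts).  When ``out_dir`` is given, also writes images/<id>.png and
    truth.csv there.
    """
    if n_images < 3:
        raise ValueError("a benchmark needs at least 3 images")
    tr = truth_ranges or BenchmarkRanges()
    template = scene_template or SceneParams(
        cluster_fraction=0.10, n_debris_small=5, n_debris_large=1
    )
    rng = np.random.default_rng(seed)

    scenes: list[tuple[RgbImage, GroundTruth]] = []
    rows = []
    for i in range(n_images):
        total = int(rng.integers(tr.total[0], tr.total[1] + 1))
        pv = rng.uniform(*tr.viability_pct)
        viable = int(round(total * pv / 100.0))
        n_small = int(rng.binomial(total, tr.small_grain_fraction))
        areas = np.concatenate(
            [
                rng.uniform(*tr.small_grain_area, size=n_small),
                rng.uniform(*tr.grain_area, size=total - n_small),
            ]
        )
        rng.shuffle(areas)
        params = replace(
            template,
            n_viable=viable,
            n_nonviable=total - viable,
            grain_area_range=tr.grain_area,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, truth = generate_scene(params, areas=areas)
        img = RgbImage(img.pixels, id=f"bench-{i:03d}.png")
        scenes.append((img, truth))
        rows.append(
            {
                "image_id": img.id,
                "manual_total": truth.true_total,
                "manual_viable": truth.true_viable,
            }
        )
    manual = pd.DataFrame(rows, columns=["image_id", "manual_total", "manual_viable"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        for img, _ in scenes:
            iio.imwrite(out_dir / "images" / img.id, img.pixels)
        manual.to_csv(out_dir / "truth.csv", index=False)
    return scenes, manual
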