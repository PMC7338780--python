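"""The image-processing chain that turns a stained-pollen micrograph into counts.

Alexander staining renders viable pollen dark blue and non-viable pollen
light blue on a pale background.  Both stain classes are dark in the *red*
channel, while only viable (dark-blue) grains are dark in the *green*
channel; thresholding each channel for dark objects therefore counts total
pollen (red) and viable pollen (green), and their ratio is the percent
viability PV = 100 * viable / total.

Stages, in execution order:

1. optional contrast enhancement (percentile stretch),
2. rolling-ball background subtraction (illumination flattening),
3. channel split,
4. per-channel: auto-threshold binarization (dark foreground), binary
   refinement (dilate, fill holes, erode), distance-transform watershed to
   split touching grains, particle measurement, and size/circularity
   filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import (
    gaussian,
    threshold_isodata,
    threshold_mean,
    threshold_otsu,
)
from skimage.morphology import h_maxima
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed
from skimage.transform import resize

from .imaging import (
    BinaryMask,
    GrayImage,
    LabelImage,
    Particle,
    ParticleFilter,
    RgbImage,
    ScenarioSpec,
    filter_particles,
    measure_particles,
)

__all__ = [
    "ConfigurationError",
    "PipelineConfig",
    "ImageCountResult",
    "subtract_background",
    "enhance_contrast",
    "split_channels",
    "binarize",
    "refine_mask",
    "watershed_split",
    "count_channel",
    "percent_viability",
    "process_image",
    "THRESHOLD_METHODS",
]


class ConfigurationError(ValueError):
    """Raised for invalid pipeline configuration values."""


def _threshold_relative(pixels: np.ndarray, fraction: float = 0.75) -> float:
    """Fixed fraction of the modal (background) intensity.

    A stained grain is substantially darker than the slide in its diagnostic
    channel, and the pale background is always the dominant histogram mode
    (grains cover well under a third of a countable slide).  Anchoring the
    threshold to the background mode makes the foreground criterion "at
    least 25% darker than the slide", which cleanly includes both stain
    classes in the red channel and only the dark-blue class in the green
    channel — histogram splitters (isodata, Otsu) instead wander between the
    two stain modes when their proportions shift, clipping light-blue grains
    out of the red channel or light-blue grains into the green one.
    """
    counts = np.bincount(pixels.ravel(), minlength=256)
    # ties resolve to the brightest candidate: background is the pale mode
    mode = int(np.flatnonzero(counts == counts.max()).max())
    return fraction * mode


THRESHOLD_METHODS = {
    "relative": _threshold_relative,
    "isodata": threshold_isodata,
    "otsu": threshold_otsu,
    "mean": threshold_mean,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters.

    background_radius
        Rolling-ball radius in pixels; must exceed the grain radius
        (~10-17 px for grains of 100-900 pixel^2) so grains are not
        absorbed into the background estimate.  Default 50.
    threshold_method
        "relative" (default): 75% of the modal background intensity —
        robust to shifting stain-class proportions; or a histogram
        auto-threshold: "isodata" (iterative intermeans), "otsu", "mean".
    morph_iterations
        Dilation/erosion repetitions in mask refinement (3x3 element).
    connectivity
        Foreground connectivity for labelling, 4 or 8 (default 8).
    exclude_edges
        Drop particles touching the image border (off by default: the
        grains cut by the frame still count toward the tally).
    contrast_saturation_pct
        When set, percentile contrast stretch saturating this percentage
        of pixels is applied before background subtraction.  Off by
        default; it is a rescue step for weakly stained images and can
        inflate the viable count if overused.
    min_peak_distance
        Minimum separation (px) between watershed seed maxima.
    """

    background_radius: float = 50.0
    threshold_method: str = "relative"
    morph_iterations: int = 1
    connectivity: int = 8
    exclude_edges: bool = False
    contrast_saturation_pct: float | None = None
    min_peak_distance: int = 5

    def __post_init__(self) -> None:
        if self.background_radius <= 0:
            raise ConfigurationError("background_radius must be > 0")
        if self.threshold_method not in THRESHOLD_METHODS:
            raise ConfigurationError(
                f"unknown threshold method {self.threshold_method!r}; "
                f"choose from {sorted(THRESHOLD_METHODS)}"
            )
        if self.morph_iterations < 1:
            raise ConfigurationError("morph_iterations must be >= 1")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")
        if self.contrast_saturation_pct is not None and not (
            0 <= self.contrast_saturation_pct < 100
        ):
            raise ConfigurationError("contrast_saturation_pct must be in [0, 100)")
        if self.min_peak_distance < 1:
            raise ConfigurationError("min_peak_distance must be >= 1")


@dataclass(frozen=True)
class ImageCountResult:
    """Counts for one image under one scenario.

    viability_pct is None when total_count is 0 (no pollen detected: PV is
    undefined, which is distinct from 0% viable).  over_100 flags the known
    failure mode where the green channel yields more particles than the red
    one and PV exceeds 100%; such values are reported as-is, never clipped.
    """

    image_id: str
    total_count: int
    viable_count: int
    viability_pct: float | None
    over_100: bool = False
    scenario_name: str = ""


def _structuring_element(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def _rolling_background(plane_inverted: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background of an inverted (dark-background) plane.

    For radii above ~12 px the plane is block-mean downscaled so the ball
    runs at a reduced radius, and the background is bilinearly upscaled —
    the standard large-radius strategy; the approximation error is far below
    the noise floor of 8-bit micrographs.
    """
    shrink = max(1, int(radius // 12))
    if shrink == 1:
        return rolling_ball(plane_inverted, radius=radius)
    h, w = plane_inverted.shape
    small = resize(
        plane_inverted.astype(float),
        (max(1, h // shrink), max(1, w // shrink)),
        order=1,
        mode="edge",
        anti_aliasing=True,
        preserve_range=True,
    )
    bg_small = rolling_ball(small, radius=max(1.0, radius / shrink))
    return resize(bg_small, (h, w), order=1, mode="edge", preserve_range=True)


def subtract_background(image: RgbImage, radius: float) -> RgbImage:
    """Remove smooth illumination variation per channel (rolling ball).

    The ball is rolled under the inverted intensity surface (grains are dark
    on a pale background) and only the spatially varying part of the estimate
    is subtracted, so a background-flat image passes through nearly
    unchanged.
    """
    if radius <= 0:
        raise ConfigurationError("background radius must be > 0")
    if radius >= min(image.height, image.width):
        raise ConfigurationError(
            f"background radius {radius} must be smaller than the image "
            f"({image.height} x {image.width})"
        )
    out = np.empty_like(image.pixels)
    for c in range(3):
        plane = image.pixels[:, :, c].astype(float)
        inv = 255.0 - plane
        bg = _rolling_background(inv, radius)
        # level-preserving: subtract only the variation around the median
        corrected = inv - (bg - np.median(bg))
        out[:, :, c] = np.clip(255.0 - corrected, 0, 255).round().astype(np.uint8)
    return RgbImage(out, id=image.id)


def enhance_contrast(image: RgbImage, saturated_pct: float) -> RgbImage:
    """Per-channel linear stretch saturating ``saturated_pct`` % of pixels.

    Half the saturated fraction clips at each tail.  Channels with zero
    dynamic range are left untouched.
    """
    if not 0 <= saturated_pct < 100:
        raise ConfigurationError("saturated_pct must be in [0, 100)")
    out = np.empty_like(image.pixels)
    tail = saturated_pct / 2.0
    for c in range(3):
        plane = image.pixels[:, :, c]
        lo, hi = np.percentile(plane, [tail, 100.0 - tail])
        if hi <= lo:
            out[:, :, c] = plane
            continue
        stretched = (plane.astype(float) - lo) * (255.0 / (hi - lo))
        out[:, :, c] = np.clip(stretched, 0, 255).round().astype(np.uint8)
    return RgbImage(out, id=image.id)


def split_channels(image: RgbImage) -> tuple[GrayImage, GrayImage, GrayImage]:
    """Split into red, green and blue planes.

    Downstream counting uses red (all pollen is dark there) and green (only
    viable, dark-blue pollen is dark there); blue is returned for
    completeness but unused.
    """
    px = image.pixels
    return (
        GrayImage(px[:, :, 0].copy(), "red"),
        GrayImage(px[:, :, 1].copy(), "green"),
        GrayImage(px[:, :, 2].copy(), "blue"),
    )


def binarize(channel: GrayImage, method: str = "relative") -> BinaryMask:
    """Auto-threshold a channel; foreground = pixels darker than the threshold.

    Stained pollen is darker than the slide background in its diagnostic
    channel, so foreground is the population at or below the threshold (the
    dark-object side under the threshold convention of the histogram
    methods).  A constant channel has no contrast and yields an empty mask.
    """
    try:
        thresh_fn = THRESHOLD_METHODS[method]
    except KeyError:
        raise ConfigurationError(
            f"unknown threshold method {method!r}; choose from {sorted(THRESHOLD_METHODS)}"
        ) from None
    px = channel.pixels
    if px.min() == px.max():
        return np.zeros(px.shape, dtype=bool)
    return px <= thresh_fn(px)


def refine_mask(mask: BinaryMask, iterations: int = 1) -> BinaryMask:
    """Dilate, fill holes, erode (3x3 square element).

    Closes pale grain interiors (poorly stained centres) and reconnects
    ragged outlines; dilation and erosion are near-inverse on convex shapes
    so grain areas are preserved to within a few percent.
    """
    mask = np.asarray(mask, dtype=bool)
    if iterations < 1:
        raise ConfigurationError("iterations must be >= 1")
    se = np.ones((3, 3), dtype=bool)
    out = ndi.binary_dilation(mask, structure=se, iterations=iterations)
    out = ndi.binary_fill_holes(out)
    out = ndi.binary_erosion(out, structure=se, iterations=iterations)
    return out


def watershed_split(
    mask: BinaryMask, min_peak_distance: int = 5, connectivity: int = 8
) -> LabelImage:
    """Separate touching grains with a distance-transform watershed.

    Seeds are the regional maxima of the lightly smoothed (sigma = 0.7 px)
    Euclidean distance map that have prominence > 0.5 px (h-maxima).  The
    prominence criterion is what keeps elongated objects whole: a fibre's
    distance ridge is flat, so it contributes a single seed, while two
    overlapping grains always dip at the neck and seed twice.  Seeds closer
    than ``min_peak_distance`` px are merged.  Output labels are renumbered
    1..n.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    structure = _structuring_element(connectivity)
    components, _ = ndi.label(mask, structure=structure)
    dist = ndi.distance_transform_edt(mask)
    smoothed = gaussian(dist, sigma=0.7, preserve_range=True)
    peaks = h_maxima(smoothed, 0.5)
    markers, n_markers = ndi.label(peaks, structure=_structuring_element(8))
    if n_markers == 0:
        return components.astype(np.int32)
    markers = _merge_close_markers(markers, n_markers, min_peak_distance)
    labels = watershed(-smoothed, markers, mask=mask)
    # renumber to a contiguous 1..n set for a valid label raster
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[labels]


def _merge_close_markers(
    markers: np.ndarray, n_markers: int, min_distance: int
) -> np.ndarray:
    """Union seed components whose centroids are closer than min_distance."""
    if n_markers < 2:
        return markers
    centroids = ndi.center_of_mass(markers > 0, markers, range(1, n_markers + 1))
    centroids = np.asarray(centroids)
    parent = list(range(n_markers))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_markers):
        for j in range(i + 1, n_markers):
            if np.hypot(*(centroids[i] - centroids[j])) < min_distance:
                parent[find(i)] = find(j)
    remap = np.zeros(n_markers + 1, dtype=np.int32)
    for i in range(n_markers):
        remap[i + 1] = find(i) + 1
    return remap[markers]


def _drop_edge_particles(
    particles: list[Particle], labels: LabelImage
) -> list[Particle]:
    border = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    edge_labels = set(np.unique(border)) - {0}
    return [p for p in particles if p.label not in edge_labels]


def count_channel(
    channel: GrayImage,
    particle_filter: ParticleFilter,
    config: PipelineConfig | None = None,
) -> tuple[int, list[Particle]]:
    """Binarize, refine, watershed, measure and filter one channel.

    Returns the surviving particle count and the particles themselves.
    """
    config = config or PipelineConfig()
    mask = binarize(channel, config.threshold_method)
    mask = refine_mask(mask, config.morph_iterations)
    labels = watershed_split(mask, config.min_peak_distance, config.connectivity)
    particles = measure_particles(labels)
    if config.exclude_edges:
        particles = _drop_edge_particles(particles, labels)
    kept = filter_particles(particles, particle_filter)
    return len(kept), kept


def percent_viability(viable_count: int, total_count: int) -> float | None:
    """PV = 100 * viable / total.

    Returns None (undefined) when total_count is 0 — "no pollen" must stay
    distinguishable from "0% viable".  Values above 100% are returned as-is
    with a warning: they signal miscounting (typically under-detection in
    the red channel), a failure mode that must surface, not be hidden.
    """
    if viable_count < 0 or total_count < 0:
        raise ValueError("counts must be non-negative")
    if total_count == 0:
        return None
    pv = 100.0 * viable_count / total_count
    if pv > 100.0:
        warnings.warn(
            f"viability {pv:.1f}% exceeds 100% "
            f"(viable={viable_count}, total={total_count}): "
            "likely red-channel undercount or green-channel overcount",
            stacklevel=2,
        )
    return pv


def _prepare(image: RgbImage, config: PipelineConfig) -> tuple[GrayImage, GrayImage]:
    """Shared scenario-independent front end: contrast, background, split."""
    if config.contrast_saturation_pct is not None:
        image = enhance_contrast(image, config.contrast_saturation_pct)
    image = subtract_background(image, config.background_radius)
    red, green, _ = split_channels(image)
    return red, green


def measure_channels(
    image: RgbImage, config: PipelineConfig | None = None
) -> tuple[list[Particle], list[Particle]]:
    """Run the pipeline up to (unfiltered) particle measurement.

    Everything before filtering is scenario-independent, so sweeping many
    scenarios over one image only needs this once; each scenario then merely
    re-filters the measured particles.
    """
    config = config or PipelineConfig()
    red, green = _prepare(image, config)
    wide_open = ParticleFilter(0, float("inf"), 0.0, 1.0)
    _, red_particles = count_channel(red, wide_open, config)
    _, green_particles = count_channel(green, wide_open, config)
    return red_particles, green_particles


def process_image(
    image: RgbImage,
    scenario: ScenarioSpec,
    config: PipelineConfig | None = None,
) -> ImageCountResult:
    """Full chain for one image: counts in both channels plus viability."""
    config = config or PipelineConfig()
    red_particles, green_particles = measure_channels(image, config)
    total = len(filter_particles(red_particles, scenario.red_filter))
    viable = len(filter_particles(green_particles, scenario.green_filter))
    pv = percent_viability(viable, total)
    return ImageCountResult(
        image_id=image.id,
        total_count=total,
        viable_count=viable,
        viability_pct=pv,
        over_100=(pv is not None and pv > 100.0),
        scenario_name=scenario.name,
    )
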