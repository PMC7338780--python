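"""Domain types and particle-measurement primitives.

The measurement unit throughout is the pixel: particle *area* is an exact
foreground-pixel count (pixel^2), *perimeter* is a contour-length estimate in
pixels, and *circularity* is the dimensionless ratio 4*pi*area/perimeter^2
(1 for a perfect circle), clipped to 1.0 because the discrete perimeter
estimator can slightly undershoot the true contour length on small round
objects.

The perimeter estimator is the weighted boundary-step (chain-code style)
estimator used by :func:`skimage.measure.regionprops` — straight steps weigh
1, diagonal steps sqrt(2), with corner correction.  It is the package's
canonical estimator: circularity filter thresholds are only meaningful
relative to a fixed perimeter definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import regionprops

__all__ = [
    "RgbImage",
    "GrayImage",
    "BinaryMask",
    "LabelImage",
    "Particle",
    "ParticleFilter",
    "ScenarioSpec",
    "InvalidMeasurementError",
    "circularity",
    "measure_particles",
    "filter_particles",
]


class InvalidMeasurementError(ValueError):
    """Raised for geometrically impossible particle measurements."""


# Binary masks and label rasters are plain numpy arrays; these aliases name
# their roles.  A BinaryMask is a 2-D boolean array (True = foreground); a
# LabelImage is a 2-D non-negative integer array (0 = background, labels
# forming a contiguous set 1..n).
BinaryMask = np.ndarray
LabelImage = np.ndarray


@dataclass
class RgbImage:
    """An 8-bit RGB micrograph with an identifier.

    ``pixels`` is a (height, width, 3) uint8 array in red, green, blue order.
    """

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"RgbImage requires a (height, width, 3) array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("RgbImage must have positive height and width")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("RgbImage intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class GrayImage:
    """A single 8-bit intensity plane, optionally tagged with its source channel."""

    pixels: np.ndarray
    channel_tag: str = "none"

    _TAGS = frozenset({"red", "green", "blue", "none"})

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("GrayImage intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.channel_tag not in self._TAGS:
            raise ValueError(f"unknown channel tag {self.channel_tag!r}")
        self.pixels = px


@dataclass(frozen=True)
class Particle:
    """One measured connected object.

    area is the exact pixel count; perimeter the contour-length estimate;
    circularity = min(1, 4*pi*area/perimeter^2); centroid in (row, col),
    0-based.
    """

    label: int
    area: int
    perimeter: float
    circularity: float
    centroid: tuple[float, float]


@dataclass(frozen=True)
class ParticleFilter:
    """Closed-interval size (pixel^2) and circularity acceptance windows."""

    size_min: float
    size_max: float
    circ_min: float
    circ_max: float

    def __post_init__(self) -> None:
        if not 0 <= self.size_min <= self.size_max:
            raise ValueError(
                f"inverted or negative size interval [{self.size_min}, {self.size_max}]"
            )
        if not 0 <= self.circ_min <= self.circ_max <= 1:
            raise ValueError(
                f"circularity interval [{self.circ_min}, {self.circ_max}] "
                "must satisfy 0 <= min <= max <= 1"
            )

    def accepts(self, particle: Particle) -> bool:
        """Both bounds of both windows are inclusive."""
        return (
            self.size_min <= particle.area <= self.size_max
            and self.circ_min <= particle.circularity <= self.circ_max
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """A named filter pair: red channel counts all pollen, green the viable."""

    name: str
    red_filter: ParticleFilter
    green_filter: ParticleFilter


def circularity(area: float, perimeter: float) -> float:
    """Shape circularity 4*pi*area / perimeter**2, clipped to 1.0.

    Parameters
    ----------
    area : float
        Object area in pixel^2, >= 1.
    perimeter : float
        Contour length in pixels, > 0.

    Returns
    -------
    float
        Value in (0, 1].  The clip makes the upper filter bound of 1
        attainable despite discrete perimeter underestimation.
    """
    if area < 1:
        raise InvalidMeasurementError(f"area must be >= 1, got {area}")
    if perimeter <= 0:
        raise InvalidMeasurementError(f"perimeter must be > 0, got {perimeter}")
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def measure_particles(labels: LabelImage) -> list[Particle]:
    """Measure every labelled object in a label raster.

    Returns one :class:`Particle` per positive label, ordered by label.  An
    empty label image yields an empty list.  The sum of particle areas equals
    the number of labelled pixels exactly.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label image must be 2-D")
    out: list[Particle] = []
    for rp in regionprops(labels):
        area = int(rp.area)
        perim = float(rp.perimeter)
        if area == 1 or perim <= 0:
            # single-pixel or degenerate object: treat as a tiny square
            perim = max(perim, 4.0 * math.sqrt(area))
        out.append(
            Particle(
                label=int(rp.label),
                area=area,
                perimeter=perim,
                circularity=circularity(area, perim),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    out.sort(key=lambda p: p.label)
    return out


def filter_particles(
    particles: list[Particle], particle_filter: ParticleFilter
) -> list[Particle]:
    """Keep exactly the particles inside both closed windows, order preserved."""
    return [p for p in particles if particle_filter.accepts(p)]
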