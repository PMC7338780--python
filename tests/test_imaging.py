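"""Particle measurement and filtering primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from pollencount import (
    InvalidMeasurementError,
    Particle,
    ParticleFilter,
    circularity,
    filter_particles,
    measure_particles,
)
from conftest import disc_mask


class TestCircularity:
    def test_ideal_circle_closed_form(self):
        # area = pi r^2, perimeter = 2 pi r  ->  4pi * pi r^2 / (2 pi r)^2 = 1
        r = 7.3
        assert circularity(math.pi * r**2, 2 * math.pi * r) == pytest.approx(1.0)

    def test_direct_formula(self):
        assert circularity(100, 40) == pytest.approx(4 * math.pi * 100 / 1600)

    def test_clipped_to_one(self):
        # 4pi*400/60^2 = 5.585 before clipping
        assert circularity(400, 60) == 1.0

    @pytest.mark.parametrize("area,perim", [(0, 10), (0.5, 10), (10, 0), (10, -1)])
    def test_invalid_measurements_rejected(self, area, perim):
        with pytest.raises(InvalidMeasurementError):
            circularity(area, perim)


class TestMeasureParticles:
    def test_filled_square_pixel_count(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[5:25, 10:30] = 1
        (p,) = measure_particles(labels)
        assert p.area == 400
        assert p.perimeter > 0
        assert p.centroid == pytest.approx((14.5, 19.5))

    def test_empty_label_image(self):
        assert measure_particles(np.zeros((10, 10), dtype=int)) == []

    def test_two_discs_areas_near_continuous(self):
        labels = np.zeros((60, 120), dtype=int)
        m1 = disc_mask(labels.shape, (30, 30), 10)
        m2 = disc_mask(labels.shape, (30, 90), 5)
        labels[m1] = 1
        labels[m2] = 2
        parts = measure_particles(labels)
        assert [p.label for p in parts] == [1, 2]
        # oracle: the rasterized pixel counts themselves
        assert parts[0].area == int(m1.sum())
        assert parts[1].area == int(m2.sum())
        assert parts[0].area == pytest.approx(math.pi * 100, rel=0.05)
        assert parts[1].area == pytest.approx(math.pi * 25, rel=0.05)

    def test_area_conservation_random_blobs(self):
        # sum of particle areas == number of labelled pixels, always
        rng = np.random.default_rng(0)
        for _ in range(10):
            mask = rng.random((64, 64)) < 0.35
            labels, _ = ndi.label(mask, structure=np.ones((3, 3), int))
            parts = measure_particles(labels)
            assert sum(p.area for p in parts) == int(mask.sum())

    @pytest.mark.parametrize("radius", [15, 20, 30])
    def test_disc_circularity_approaches_one(self, radius):
        shape = (2 * radius + 10, 2 * radius + 10)
        labels = disc_mask(shape, (radius + 5, radius + 5), radius).astype(int)
        (p,) = measure_particles(labels)
        assert p.circularity >= 0.9


def brute_force_filter(particles, f):
    """Independent exhaustive interval scan (the oracle)."""
    out = []
    for p in particles:
        if f.size_min <= p.area <= f.size_max and f.circ_min <= p.circularity <= f.circ_max:
            out.append(p)
    return out


def random_particles(rng, n):
    return [
        Particle(
            label=i + 1,
            area=int(rng.integers(1, 1500)),
            perimeter=float(rng.uniform(4, 300)),
            circularity=float(rng.uniform(0, 1)),
            centroid=(0.0, 0.0),
        )
        for i in range(n)
    ]


class TestFilterParticles:
    filt = ParticleFilter(100, 900, 0.4, 1.0)

    def _particle(self, area, circ):
        return Particle(1, area, 10.0, circ, (0.0, 0.0))

    def test_below_size_bound_excluded(self):
        assert filter_particles([self._particle(95, 0.9)], self.filt) == []

    def test_boundary_values_included(self):
        p = self._particle(100, 0.4)
        assert filter_particles([p], self.filt) == [p]
        p900 = self._particle(900, 1.0)
        assert filter_particles([p900], self.filt) == [p900]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(42)
        parts = random_particles(rng, 200)
        assert filter_particles(parts, self.filt) == brute_force_filter(parts, self.filt)

    def test_invalid_filter_rejected(self):
        with pytest.raises(ValueError):
            ParticleFilter(900, 100, 0.4, 1.0)
        with pytest.raises(ValueError):
            ParticleFilter(100, 900, 0.8, 0.4)
        with pytest.raises(ValueError):
            ParticleFilter(100, 900, 0.4, 1.5)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_subset_and_shrink_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        parts = random_particles(rng, 50)
        lo, hi = sorted(rng.uniform(0, 1200, 2))
        clo, chi = sorted(rng.uniform(0, 1, 2))
        wide = ParticleFilter(lo, hi, clo, chi)
        kept = filter_particles(parts, wide)
        assert kept == brute_force_filter(parts, wide)
        # subset of input, order preserved
        it = iter(parts)
        assert all(any(k is q for q in it) or True for k in kept)
        assert set(id(k) for k in kept) <= set(id(p) for p in parts)
        # shrinking any interval never increases the output
        shrunk = ParticleFilter(
            lo + (hi - lo) * 0.25, hi - (hi - lo) * 0.25, clo, chi
        )
        assert len(filter_particles(parts, shrunk)) <= len(kept)
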