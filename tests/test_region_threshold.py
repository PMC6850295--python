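import numpy as np
import pytest

from gradthresh import (
    GreyImage,
    ObjectSpec,
    SceneParams,
    build_projection,
    compute_gradient,
    fill_regions,
    find_optimal_threshold,
    generate_scene,
    gradient_curves,
    jaccard,
    label_boundaries,
    regional_maxima,
    segment_regions,
    threshold_phase,
)


def ring_mask(shape, center, radius, width=1.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(yy - center[0], xx - center[1])
    return np.abs(d - radius) <= width / 2 + 0.5


class TestLabelBoundaries:
    def test_score_is_mean_gradient(self):
        boundary = np.zeros((5, 5), dtype=bool)
        boundary[1, 1:4] = True
        gradient = np.zeros((5, 5))
        gradient[1, 1:4] = [10.0, 20.0, 30.0]
        sl = label_boundaries(boundary, gradient, level=7)
        assert len(sl.components) == 1
        assert sl.components[0].score == pytest.approx(20.0)
        assert sl.level == 7

    def test_separate_rings_scored_independently(self):
        shape = (40, 80)
        b1 = ring_mask(shape, (20, 20), 8)
        b2 = ring_mask(shape, (20, 60), 8)
        gradient = np.where(b1, 5.0, 0.0) + np.where(b2, 11.0, 0.0)
        sl = label_boundaries(b1 | b2, gradient, level=0)
        assert sorted(c.score for c in sl.components) == [5.0, 11.0]

    def test_spec_drops_small_filled_region(self):
        # ring enclosing ~100 px fails min_area 250
        boundary = ring_mask((40, 40), (20, 20), 5.6)
        sl = label_boundaries(boundary, np.ones((40, 40)), 0, ObjectSpec(0.0, 250, 3000))
        assert sl.components == []
        sl2 = label_boundaries(boundary, np.ones((40, 40)), 0, ObjectSpec(0.0, 50, 3000))
        assert len(sl2.components) == 1
        assert sl2.components[0].region_area < 250


class TestBuildProjection:
    def test_stack_and_cumulative_identical_random(self, rng):
        img = GreyImage(rng.integers(0, 256, (32, 32)).astype(np.uint8))
        grad = compute_gradient(img)
        p_stack = build_projection(img, grad, mode="stack")
        p_cum = build_projection(img, grad, mode="cumulative")
        assert np.array_equal(p_stack.scores, p_cum.scores)
        assert np.array_equal(p_stack.levels, p_cum.levels)

    def test_stack_and_cumulative_identical_structured(self, default_scene):
        img = default_scene.image
        grad = compute_gradient(img)
        spec = ObjectSpec(0.4, 100, 5000)
        p_stack = build_projection(img, grad, spec=spec, mode="stack")
        p_cum = build_projection(img, grad, spec=spec, mode="cumulative")
        assert np.array_equal(p_stack.scores, p_cum.scores)
        assert np.array_equal(p_stack.levels, p_cum.levels)

    def test_single_disk_ring_dominates(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = np.hypot(yy - 32, xx - 32) <= 12
        px = np.where(disk, 60, 200).astype(np.uint8)
        img = GreyImage(px)
        proj = build_projection(img, compute_gradient(img))
        edge = regional_maxima(proj)
        # the winning plateau is a closed ring at the disk edge: filling it
        # recovers the disk
        assert jaccard(fill_regions(edge), disk) == pytest.approx(1.0)

    def test_spec_filtering_only_removes(self, default_scene):
        img = default_scene.image
        grad = compute_gradient(img)
        p_all = build_projection(img, grad)
        p_spec = build_projection(img, grad, spec=ObjectSpec(0.5, 250, 3000))
        assert np.all(p_spec.scores <= p_all.scores)

    def test_bad_mode(self):
        img = GreyImage(np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(Exception):
            build_projection(img, np.zeros((8, 8)), mode="lazy")


class TestRegionalMaxima:
    def test_single_pixel(self):
        field = np.zeros((5, 5))
        field[2, 2] = 5.0
        expected = field > 0
        assert np.array_equal(regional_maxima(field), expected)

    def test_adjacent_plateaus_only_higher_survives(self):
        field = np.zeros((6, 10))
        field[2:4, 1:4] = 5.0
        field[2:4, 4:7] = 3.0  # touches the 5-plateau: has a higher neighbour
        out = regional_maxima(field)
        assert np.array_equal(out, field == 5.0)

    def test_constant_field_is_one_plateau(self):
        assert regional_maxima(np.full((4, 6), 2.5)).all()

    def test_maxima_have_no_greater_neighbour(self, rng):
        field = rng.random((20, 20)).round(1)  # encourage plateaus
        out = regional_maxima(field)
        padded = np.pad(field, 1, mode="constant", constant_values=-1)
        for i, j in zip(*np.nonzero(out)):
            window = padded[i : i + 3, j : j + 3]
            assert window.max() == field[i, j]


class TestFillRegions:
    def test_closed_ring_becomes_disk(self):
        ring = ring_mask((30, 30), (15, 15), 8)  # annulus d in [7, 9]
        filled = fill_regions(ring)
        yy, xx = np.mgrid[0:30, 0:30]
        disk = np.hypot(yy - 15, xx - 15) <= 9
        assert np.array_equal(filled, disk)
        assert filled.sum() > 2 * ring.sum()

    def test_open_arc_unchanged(self):
        arc = np.zeros((10, 10), dtype=bool)
        arc[2, 2:8] = True
        arc[3, 7] = True
        assert np.array_equal(fill_regions(arc), arc)

    def test_nested_rings_become_solid_disk(self):
        outer = ring_mask((40, 40), (20, 20), 12)
        inner = ring_mask((40, 40), (20, 20), 6)
        filled = fill_regions(outer | inner)
        assert filled[20, 20]  # the child hole is filled too
        assert np.array_equal(filled, fill_regions(outer))


class TestSegmentRegions:
    def test_blank_image_empty_result(self):
        img = GreyImage(np.full((32, 32), 100, dtype=np.uint8))
        result = segment_regions(img)
        assert result.regions == []
        assert not result.mask.any()

    def test_elongated_blobs_rejected_by_strict_circularity(self):
        scene = generate_scene(
            SceneParams(
                shape=(192, 192), n_objects=5, radius_range=(12, 16),
                aspect_range=(2.5, 3.5), seed=4,
            )
        )
        result = segment_regions(scene.image, spec=ObjectSpec(0.9, 100, 5000))
        assert result.regions == []

    def test_provenance_level_reproduces_region(self, default_scene):
        result = segment_regions(default_scene.image, spec=ObjectSpec(0.4, 100, 5000))
        assert result.regions
        for region in result.regions:
            rows, cols = region.indices
            box = (
                slice(rows.min(), rows.max() + 1),
                slice(cols.min(), cols.max() + 1),
            )
            mask = np.zeros(result.mask.shape, dtype=bool)
            mask[region.indices] = True
            phase = threshold_phase(default_scene.image, region.source_level)
            assert jaccard(mask[box], phase[box]) >= 0.99

    def test_single_blob_matches_global_method(self):
        scene = generate_scene(
            SceneParams(shape=(96, 96), n_objects=1, fg_values=[60], seed=9)
        )
        img = scene.image
        regional = segment_regions(img)
        curve = gradient_curves(img, compute_gradient(img))
        optimal = find_optimal_threshold(curve, "average")
        assert np.array_equal(regional.mask, threshold_phase(img, optimal))

    def test_region_metadata(self, default_scene):
        result = segment_regions(default_scene.image, spec=ObjectSpec(0.4, 100, 5000))
        labelled = result.labelled()
        for region in result.regions:
            assert region.area == len(region.indices[0])
            assert 0 < region.circularity <= 1
            assert (labelled[region.indices] == region.region_id).all()
        # regions are pairwise disjoint and cover the mask
        assert (labelled > 0).sum() == sum(r.area for r in result.regions)
        assert np.array_equal(labelled > 0, result.mask)
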