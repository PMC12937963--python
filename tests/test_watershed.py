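import numpy as np
import pytest
from scipy import ndimage

from oracles import (distance_map_bruteforce, flood_fill_components,
                     meyer_flood, otsu_exhaustive)
from wedseg.watershed import (BOUNDARY, WatershedConfig, build_markers,
                              connected_components, distance_transform_l2,
                              encode_three_class, make_watershed_mask,
                              morphological_open, otsu_binarize,
                              sure_background, sure_foreground, to_grayscale,
                              unknown_region, watershed_fill, WatershedMasker)


class TestGrayscale:
    def test_gray_input_passthrough(self):
        img = np.full((4, 4, 3), 97, dtype=np.uint8)
        np.testing.assert_array_equal(to_grayscale(img), np.full((4, 4), 97))

    def test_pure_red(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[..., 0] = 255
        assert to_grayscale(img)[0, 0] == 76  # round(0.299 * 255)

    def test_wrong_channels(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4), dtype=np.uint8))


class TestOtsu:
    def test_two_level_image(self):
        gray = np.array([[10, 10], [200, 200]], dtype=np.uint8)
        t, mask = otsu_binarize(gray, "dark_foreground")
        assert t == 10
        np.testing.assert_array_equal(mask, [[1, 1], [0, 0]])

    def test_polarity_mirror(self):
        gray = np.array([[10, 10], [200, 200]], dtype=np.uint8)
        _, mask = otsu_binarize(gray, "bright_foreground")
        np.testing.assert_array_equal(mask, [[0, 0], [1, 1]])

    def test_constant_image_all_foreground(self):
        gray = np.full((3, 3), 55, dtype=np.uint8)
        t, mask = otsu_binarize(gray, "dark_foreground")
        assert t == 55
        assert mask.all()

    def test_matches_exhaustive_search(self):
        """Threshold equals brute-force argmax of between-class variance on
        random histograms (unimodal, bimodal, sparse)."""
        rng = np.random.default_rng(0)
        for trial in range(200):
            kind = trial % 3
            if kind == 0:
                vals = rng.integers(0, 256, size=64).astype(np.uint8)
            elif kind == 1:
                vals = np.concatenate([
                    rng.normal(60, 15, 40), rng.normal(190, 20, 40)
                ]).clip(0, 255).astype(np.uint8)
            else:
                vals = rng.choice([3, 9, 200], size=30).astype(np.uint8)
            t, _ = otsu_binarize(vals.reshape(1, -1))
            assert t == otsu_exhaustive(vals), f"trial {trial}"


class TestMorphology:
    def test_speckle_removed(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[3, 3] = 1
        assert morphological_open(mask, 3, 1).sum() == 0

    def test_solid_square_survives(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[2:7, 2:7] = 1
        np.testing.assert_array_equal(morphological_open(mask, 3, 1), mask)

    def test_all_ones_border_padding(self):
        mask = np.ones((6, 6), dtype=np.uint8)
        assert morphological_open(mask, 3, 2).all()

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            morphological_open(np.ones((4, 4), dtype=np.uint8), 4, 1)

    def test_dilation_of_single_pixel(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 1
        out = sure_background(mask, 3, 1)
        expected = np.zeros((5, 5), dtype=np.uint8)
        expected[1:4, 1:4] = 1
        np.testing.assert_array_equal(out, expected)

    def test_dilation_monotone_in_iterations(self):
        rng = np.random.default_rng(1)
        mask = (rng.random((12, 12)) < 0.2).astype(np.uint8)
        one = sure_background(mask, 3, 1)
        two = sure_background(mask, 3, 2)
        assert (two >= one).all()

    def test_empty_mask_stays_empty(self):
        assert sure_background(np.zeros((5, 5), dtype=np.uint8), 3, 1).sum() == 0


class TestDistanceTransform:
    def test_all_background_zero(self):
        assert distance_transform_l2(np.zeros((4, 4), dtype=np.uint8)).sum() == 0

    def test_single_pixel(self):
        mask = np.zeros((3, 3), dtype=np.uint8)
        mask[1, 1] = 1
        assert distance_transform_l2(mask)[1, 1] == 1.0

    def test_frame_counts_as_background(self):
        dist = distance_transform_l2(np.ones((3, 3), dtype=np.uint8))
        expected = np.array([[1, 1, 1], [1, 2, 1], [1, 1, 1]], dtype=float)
        np.testing.assert_array_equal(dist, expected)

    def test_matches_bruteforce_on_random_masks(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            mask = (rng.random((8, 8)) < 0.6).astype(np.uint8)
            np.testing.assert_allclose(distance_transform_l2(mask),
                                       distance_map_bruteforce(mask), atol=1e-9)


class TestSureForeground:
    def test_threshold_arithmetic(self):
        dist = np.array([[0, 1, 2]], dtype=float)
        np.testing.assert_array_equal(sure_foreground(dist, 0.7), [[0, 0, 1]])

    def test_all_zero_distance(self):
        assert sure_foreground(np.zeros((3, 3)), 0.5).sum() == 0

    def test_disc_core_strict_subset(self):
        mask = np.zeros((11, 11), dtype=np.uint8)
        yy, xx = np.mgrid[0:11, 0:11]
        mask[(yy - 5) ** 2 + (xx - 5) ** 2 <= 16] = 1
        dist = distance_map_bruteforce(mask)
        core = sure_foreground(dist, 0.5)
        assert 0 < core.sum() < mask.sum()
        assert (mask[core == 1] == 1).all()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            sure_foreground(np.ones((2, 2)), 1.0)


class TestUnknownRegion:
    def test_equal_inputs_give_empty(self):
        m = np.ones((3, 3), dtype=np.uint8)
        assert unknown_region(m, m).sum() == 0

    def test_ring_around_center(self):
        dilated = np.zeros((5, 5), dtype=np.uint8)
        dilated[1:4, 1:4] = 1
        fg = np.zeros((5, 5), dtype=np.uint8)
        fg[2, 2] = 1
        unknown = unknown_region(dilated, fg)
        assert unknown.sum() == 8 and unknown[2, 2] == 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            unknown_region(np.zeros((2, 2)), np.zeros((3, 3)))


class TestConnectedComponents:
    def test_empty(self):
        _, n = connected_components(np.zeros((3, 3), dtype=np.uint8))
        assert n == 0

    def test_diagonal_connectivity(self):
        mask = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        assert connected_components(mask, 8)[1] == 1
        assert connected_components(mask, 4)[1] == 2

    def test_row_major_label_order(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[4:6, 0:2] = 1  # bottom-left block
        mask[0:2, 3:5] = 1  # top-right block: discovered first
        labels, n = connected_components(mask, 8)
        assert n == 2
        assert labels[0, 3] == 1 and labels[4, 0] == 2

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            connected_components(np.ones((2, 2), dtype=np.uint8), 6)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(11)
        for trial in range(200):
            h, w = rng.integers(2, 17, size=2)
            mask = (rng.random((h, w)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            labels, n = connected_components(mask, connectivity)
            ref_labels, ref_n = flood_fill_components(mask, connectivity)
            assert n == ref_n, f"trial {trial}"
            np.testing.assert_array_equal(labels, ref_labels)


class TestBuildMarkers:
    def test_shift_by_one(self):
        cc = np.array([[0, 1], [0, 1]])
        markers = build_markers(cc, 1, np.zeros((2, 2), dtype=np.uint8))
        np.testing.assert_array_equal(markers, [[1, 2], [1, 2]])

    def test_unknown_everywhere(self):
        cc = np.array([[0, 1], [0, 1]])
        markers = build_markers(cc, 1, np.ones((2, 2), dtype=np.uint8))
        assert (markers == 0).all()

    def test_component_with_unknown_ring(self):
        cc = np.zeros((5, 5), dtype=int)
        cc[2, 2] = 1
        unknown = np.zeros((5, 5), dtype=np.uint8)
        unknown[1:4, 1:4] = 1
        unknown[2, 2] = 0
        markers = build_markers(cc, 1, unknown)
        assert markers[2, 2] == 2
        assert (markers[1:4, 1:4].sum() == 2)  # ring is 0
        assert markers[0, 0] == 1


class TestWatershedFill:
    def test_markers_cover_everything(self):
        markers = np.array([[1, 2], [1, 2]])
        out = watershed_fill(np.zeros((2, 2)), markers)
        np.testing.assert_array_equal(out, markers)

    def test_strip_with_ridge(self):
        elevation = np.array([[0, 0, 0, 5, 0, 0, 0]], dtype=float)
        markers = np.array([[2, 0, 0, 0, 0, 0, 3]])
        out = watershed_fill(elevation, markers)
        np.testing.assert_array_equal(out, [[2, 2, 2, BOUNDARY, 3, 3, 3]])

    def test_all_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            watershed_fill(np.zeros((2, 2)), np.zeros((2, 2), dtype=int))

    def test_two_seeds_uniform_elevation(self):
        """A nucleus seed inside a background ring: the flooded region stays
        connected around the seed and a boundary forms against the ring's
        flood front."""
        markers = np.zeros((7, 7), dtype=int)
        markers[0, :] = 1
        markers[6, :] = 1
        markers[3, 3] = 2
        out = watershed_fill(np.zeros((7, 7)), markers)
        assert (out != 0).all()
        assert (out == 2).sum() >= 1
        assert (out == BOUNDARY).any()
        ref = meyer_flood(np.zeros((7, 7)), markers)
        np.testing.assert_array_equal(out, ref)

    def test_matches_bruteforce_meyer_oracle(self):
        """Exact label agreement with list-scan Meyer flooding on >= 200
        random small grids with random elevations and marker layouts."""
        rng = np.random.default_rng(21)
        for trial in range(200):
            h, w = rng.integers(2, 13, size=2)
            elevation = rng.integers(0, 5, size=(h, w)).astype(float)
            markers = np.zeros((h, w), dtype=int)
            n_seeds = rng.integers(1, 4)
            for label in range(1, n_seeds + 1):
                markers[rng.integers(h), rng.integers(w)] = label
            out = watershed_fill(elevation, markers)
            ref = meyer_flood(elevation, markers)
            np.testing.assert_array_equal(out, ref, err_msg=f"trial {trial}")


class TestEncodeThreeClass:
    def test_all_background(self):
        np.testing.assert_array_equal(
            encode_three_class(np.ones((2, 2), dtype=int)), np.zeros((2, 2)))

    def test_strip_mapping(self):
        ws = np.array([[2, 2, 2, BOUNDARY, 3, 3, 3]])
        np.testing.assert_array_equal(encode_three_class(ws),
                                      [[1, 1, 1, 2, 1, 1, 1]])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            encode_three_class(np.zeros((2, 2), dtype=int))


class TestFullChain:
    def test_blank_image_all_background(self):
        img = np.full((64, 64, 3), 180, dtype=np.uint8)
        assert make_watershed_mask(img).sum() == 0

    def test_two_separated_nuclei(self, separated_nuclei_image):
        mask = make_watershed_mask(separated_nuclei_image)
        assert set(np.unique(mask)) <= {0, 1, 2}
        labels, n = ndimage.label(mask == 1)
        assert n == 2
        # each region contains its disc center
        assert mask[40, 40] == 1 and mask[90, 90] == 1
        assert labels[40, 40] != labels[90, 90]

    def test_touching_nuclei_split_by_edges(self, touching_nuclei_image):
        mask = make_watershed_mask(touching_nuclei_image)
        _, n = ndimage.label(mask == 1, structure=np.ones((3, 3)))
        assert n == 2
        # without the edge class the two nuclei would fuse into one blob
        _, n_union = ndimage.label(mask > 0, structure=np.ones((3, 3)))
        assert n_union == 1

    def test_stage_inclusions(self, easy_pair):
        gray = to_grayscale(easy_pair.image)
        _, binary = otsu_binarize(gray)
        opened = morphological_open(binary, 3, 2)
        dilated = sure_background(opened, 3, 3)
        fg = sure_foreground(distance_transform_l2(opened), 0.7)
        assert (opened <= dilated).all()
        assert (fg <= opened).all()

    def test_rerun_bit_exact(self, easy_pair):
        a = make_watershed_mask(easy_pair.image)
        b = make_watershed_mask(easy_pair.image)
        np.testing.assert_array_equal(a, b)

    def test_gradient_elevation_variant_runs(self, separated_nuclei_image):
        config = WatershedConfig(elevation="gradient")
        mask = make_watershed_mask(separated_nuclei_image, config)
        assert set(np.unique(mask)) <= {0, 1, 2}

    def test_transformer_stacks_masks(self, easy_pair):
        out = WatershedMasker().fit([]).transform([easy_pair.image,
                                                   easy_pair.image])
        assert out.shape == (2, 64, 64)
        np.testing.assert_array_equal(out[0], out[1])
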