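"""Bead segmentation and chromogen quantification against ground truth."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree
from skimage.draw import disk

from her2calib import bead_quant as bq
from her2calib.synthetic import DAB_RGB, SpotLayout


class TestGreyscale:
    def test_pure_white_maps_to_uniform_maximum(self):
        img = np.full((10, 10, 3), 255, dtype=np.uint8)
        grey = bq.to_greyscale(img)
        assert np.allclose(grey, 255.0 * bq._LUMA.sum())
        assert grey.shape == (10, 10)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            bq.to_greyscale(np.zeros((5, 5)))

    def test_known_channels_give_the_weighted_sum(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (8, 8, 3))
        grey = bq.to_greyscale(img)
        expected = (0.2125 * img[..., 0] + 0.7154 * img[..., 1]
                    + 0.0721 * img[..., 2])
        assert np.allclose(grey, expected)


class TestDetection:
    def test_recovers_every_bead_within_one_pixel(self, calibrator_slide):
        img, truth = calibrator_slide
        circles = bq.remove_overlaps(bq.detect_beads(bq.to_greyscale(img)))
        assert len(circles) == len(truth)
        tree = cKDTree(truth[["x", "y"]].to_numpy(dtype=float))
        d, _ = tree.query([[c.x, c.y] for c in circles])
        assert d.max() <= 1.0

    def test_circles_below_radius_range_ignored(self):
        img = np.full((60, 60), 255.0)
        for cy, cx in [(15, 15), (40, 40)]:
            rr, cc = disk((cy, cx), 2)
            img[rr, cc] = 0.0
        assert bq.detect_beads(img, (5, 8)) == []

    def test_blank_image_yields_nothing(self):
        assert bq.detect_beads(np.full((50, 50), 255.0)) == []

    def test_invalid_radius_range_rejected(self):
        with pytest.raises(ValueError):
            bq.detect_beads(np.zeros((5, 5)), (8, 5))


def _circle(x, y, r, acc=1.0):
    return bq.BeadDetection(x=x, y=y, radius=r, accumulator=acc)


def _conflicts(a, b, tol):
    return np.hypot(a.x - b.x, a.y - b.y) < tol * (a.radius + b.radius)


def _is_maximal_conflict_free(kept, all_circles, tol):
    """Brute-force oracle: conflict-free, and no excluded circle fits."""
    for a, b in itertools.combinations(kept, 2):
        if _conflicts(a, b, tol):
            return False
    excluded = [c for c in all_circles if c not in kept]
    for c in excluded:
        if not any(_conflicts(c, k, tol) for k in kept):
            return False
    return True


class TestOverlapRemoval:
    def test_two_identical_circles_keep_one(self):
        out = bq.remove_overlaps([_circle(10, 10, 5, 0.9), _circle(10, 10, 5, 0.8)])
        assert len(out) == 1 and out[0].accumulator == 0.9

    def test_disjoint_set_unchanged(self):
        circles = [_circle(0, 0, 3), _circle(20, 0, 3), _circle(0, 20, 3)]
        assert bq.remove_overlaps(circles) == circles

    @pytest.mark.parametrize("seed", range(8))
    def test_result_is_a_maximal_conflict_free_subset(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        circles = [_circle(float(rng.uniform(0, 30)), float(rng.uniform(0, 30)),
                           float(rng.uniform(2, 6)), float(rng.uniform(0.2, 1)))
                   for _ in range(n)]
        kept = bq.remove_overlaps(circles, tolerance=1.0)
        assert _is_maximal_conflict_free(kept, circles, 1.0)

    def test_chain_keeps_alternating_strongest(self):
        # pairwise-overlapping chain: greedy keeps strongest then skips
        chain = [_circle(i * 8.0, 0, 5, acc) for i, acc in
                 enumerate([0.5, 0.9, 0.6, 0.8])]
        kept = bq.remove_overlaps(chain, tolerance=1.0)
        assert [c.accumulator for c in kept] == [0.9, 0.8]
        assert _is_maximal_conflict_free(kept, chain, 1.0)


class TestStainIntensity:
    def _uniform_bead(self, vector, shape=(40, 40)):
        img = np.full(shape + (3,), 255.0)
        rr, cc = disk((20, 20), 8)
        img[rr, cc] = 255.0 - np.asarray(vector)
        return img

    def test_background_only_bead_measures_zero(self):
        img = np.full((40, 40, 3), 255.0)
        val = bq.stain_intensity(img, _circle(20, 20, 6))
        assert val == pytest.approx(0.0)

    def test_vector_parallel_to_profile_recovers_magnitude(self):
        m = 80.0
        img = self._uniform_bead(m * DAB_RGB)
        val = bq.stain_intensity(img, _circle(20, 20, 6))
        assert val == pytest.approx(m, rel=1e-12)

    def test_circle_outside_bounds_rejected(self):
        img = np.full((40, 40, 3), 255.0)
        with pytest.raises(ValueError):
            bq.stain_intensity(img, _circle(38, 20, 6))

    def test_non_unit_profile_shape_rejected(self):
        img = np.full((40, 40, 3), 255.0)
        with pytest.raises(ValueError):
            bq.stain_intensity(img, _circle(20, 20, 6), dab_profile=np.ones(4))

    def test_rendered_bead_intensities_recovered(self, calibrator_slide):
        img, truth = calibrator_slide
        summary = bq.quantify_image(img)
        true_means = truth.groupby("spot_id")["intensity"].mean()
        assert np.allclose(summary["mean_intensity"], true_means.to_numpy(),
                           atol=0.1)


class TestSpotSummaries:
    def test_spot_means_nondecreasing_in_concentration(self, calibrator_slide):
        img, _ = calibrator_slide
        summary = bq.quantify_image(img)
        pos = summary[~summary["is_negative"]].sort_values("concentration")
        assert (np.diff(pos["mean_intensity"].to_numpy()) >= -1e-9).all()

    def test_summary_matches_direct_computation(self, calibrator_slide):
        img, _ = calibrator_slide
        grey = bq.to_greyscale(img)
        layout = SpotLayout()
        circles = bq.assign_spots(
            bq.remove_overlaps(bq.detect_beads(grey)), layout)
        for c in circles:
            c.stain_intensity = bq.stain_intensity(img, c, max_sample_radius=5)
        summary = bq.summarize_spots(circles, layout)
        vals0 = [c.stain_intensity for c in circles if c.spot_id == 0]
        row0 = summary[summary["spot_id"] == 0].iloc[0]
        assert row0["n_beads"] == len(vals0)
        assert row0["mean_intensity"] == pytest.approx(np.mean(vals0))
        assert row0["sd_intensity"] == pytest.approx(np.std(vals0, ddof=1))

    def test_empty_spot_flagged_not_dropped(self):
        layout = SpotLayout()
        summary = bq.summarize_spots([], layout)
        assert (summary["n_beads"] == 0).all()
        assert summary["mean_intensity"].isna().all()


class TestDuplicateAveraging:
    def _runs(self):
        base = pd.DataFrame({
            "spot_id": [0, 1], "concentration": [26e3, 40e3],
            "is_negative": [False, False], "n_beads": [24, 24],
            "mean_intensity": [10.0, 30.0], "sd_intensity": [1.0, 2.0]})
        other = base.copy()
        other["mean_intensity"] = [20.0, 50.0]
        return base, other

    def test_identical_runs_average_to_themselves(self):
        a, _ = self._runs()
        out = bq.average_duplicates(a, a.copy())
        assert np.allclose(out["mean_intensity"], a["mean_intensity"])

    def test_means_ten_and_twenty_average_fifteen(self):
        a, b = self._runs()
        out = bq.average_duplicates(a, b)
        assert out["mean_intensity"].tolist() == [15.0, 40.0]

    def test_symmetric_in_arguments(self):
        a, b = self._runs()
        pd.testing.assert_frame_equal(bq.average_duplicates(a, b),
                                      bq.average_duplicates(b, a))

    def test_mismatched_layout_rejected(self):
        a, b = self._runs()
        b["spot_id"] = [1, 0]
        with pytest.raises(ValueError):
            bq.average_duplicates(a, b)
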