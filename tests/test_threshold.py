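"""Normalization, Otsu thresholding and area-based segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_otsu
from lvquant.phantom import LesionWedge, PhantomSpec, generate_phantom
from lvquant.roi import MyocardialMask, lv_center
from lvquant.threshold import (
    EnhancementPolarity,
    IntensityHistogram,
    NormalizedROI,
    area_fraction,
    normalize_intensity,
    otsu_threshold,
    quantify_area,
    segment_enhanced,
)


class TestNormalization:
    def test_linear_map_of_three_values(self):
        img = np.array([[10.0, 20.0, 30.0]])
        mask = np.ones_like(img, dtype=bool)
        out = normalize_intensity(img, mask)
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0])
        assert not out.degenerate

    def test_constant_roi_flagged_degenerate(self):
        out = normalize_intensity(np.full((3, 3), 7.0), np.ones((3, 3), bool))
        assert out.degenerate
        assert np.all(out.values == 0.5)

    def test_output_spans_unit_interval_exactly(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(5, 90, (32, 32))
        mask = rng.random((32, 32)) < 0.5
        out = normalize_intensity(img, mask)
        assert out.values.min() == 0.0
        assert out.values.max() == 1.0
        # values outside the ROI are NaN
        assert np.isnan(out.image[~mask]).all()


class TestOtsu:
    def test_two_well_separated_clusters(self):
        # values {1,1,2,2,8,8,9,9} on unit-width bins over [0, 10]:
        # the optimal cut separates {1,1,2,2} from {8,8,9,9}
        values = np.array([1, 1, 2, 2, 8, 8, 9, 9]) / 10.0
        hist = IntensityHistogram.from_values(values, n_bins=10)
        res = otsu_threshold(hist)
        assert res.class_counts == (4, 4)
        assert 0.3 <= res.threshold <= 0.8

    def test_two_equal_spikes_split_evenly(self):
        hist = IntensityHistogram(counts=[5, 5], bin_edges=[0.0, 0.5, 1.0])
        res = otsu_threshold(hist)
        assert res.threshold == 0.5
        assert res.class_counts == (5, 5)

    def test_bimodal_gaussian_mixture_threshold_between_modes(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate(
            [rng.normal(0.3, 0.02, 5000), rng.normal(0.7, 0.02, 5000)]
        ).clip(0, 1)
        res = otsu_threshold(IntensityHistogram.from_values(vals, n_bins=256))
        assert 0.45 < res.threshold < 0.55

    def test_close_to_reference_implementation(self):
        """Agrees with scikit-image's Otsu to within a bin width on
        generic bimodal data (conventions differ only at ties/edges)."""
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(9)
        vals = np.concatenate(
            [rng.normal(0.35, 0.08, 3000), rng.normal(0.75, 0.05, 2000)]
        ).clip(0, 1)
        res = otsu_threshold(IntensityHistogram.from_values(vals, n_bins=256))
        ref = threshold_otsu(vals, nbins=256)
        assert abs(res.threshold - ref) <= 2 / 256

    def test_single_nonempty_bin_rejected(self):
        hist = IntensityHistogram(counts=[0, 9, 0], bin_edges=[0, 0.25, 0.5, 1.0])
        with pytest.raises(ValueError, match="single nonempty bin"):
            otsu_threshold(hist)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 500), min_size=2, max_size=64).filter(
            lambda c: sum(1 for v in c if v > 0) >= 2
        )
    )
    def test_matches_exhaustive_within_class_minimizer(self, counts):
        """Maximizing sigma_b^2 and minimizing sigma_w^2 select the same cut."""
        n = len(counts)
        edges = np.linspace(0, 1, n + 1)
        hist = IntensityHistogram(counts=np.array(counts), bin_edges=edges)
        res = otsu_threshold(hist)
        expected = brute_force_otsu(np.array(counts, float), edges)
        assert res.threshold == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 500), min_size=2, max_size=64).filter(
            lambda c: sum(1 for v in c if v > 0) >= 2
        )
    )
    def test_variance_decomposition_conserved(self, counts):
        """sigma_b^2(t) + sigma_w^2(t) equals the total variance at every cut."""
        n = len(counts)
        hist = IntensityHistogram(counts=np.array(counts), bin_edges=np.linspace(0, 1, n + 1))
        res = otsu_threshold(hist)
        c = np.asarray(counts, float)
        centers = hist.bin_centers
        mu = (c * centers).sum() / c.sum()
        total_var = (c * (centers - mu) ** 2).sum() / c.sum()
        ok = ~np.isnan(res.sigma_b2)
        np.testing.assert_allclose(
            res.sigma_b2[ok] + res.sigma_w2[ok], total_var, atol=1e-12
        )


class TestSegmentation:
    def _norm(self, values):
        img = np.asarray(values, float).reshape(1, -1)
        return normalize_intensity(img, np.ones_like(img, bool))

    def test_hyper_all_below_threshold_gives_empty_lesion(self):
        hist = IntensityHistogram(counts=[4, 4], bin_edges=[0, 0.5, 1.0])
        res = otsu_threshold(hist)
        norm = self._norm([0.1, 0.2, 0.3, 0.2])
        # renormalized values span [0,1]; force a threshold above all of them
        res.threshold = 1.0
        assert segment_enhanced(norm, res, "hyper").sum() == 0

    def test_hypo_counts_below_threshold(self):
        norm = self._norm([0.1, 0.1, 0.1, 0.1, 0.9, 0.9, 0.9, 0.9])
        res = otsu_threshold(IntensityHistogram.from_values(norm.values, n_bins=2))
        lesion = segment_enhanced(norm, res, EnhancementPolarity("hypo"))
        assert lesion.sum() == 4

    def test_polarity_flip_complements_lesion(self):
        rng = np.random.default_rng(5)
        norm = self._norm(rng.uniform(0, 1, 200))
        res = otsu_threshold(IntensityHistogram.from_values(norm.values, n_bins=64))
        hyper = segment_enhanced(norm, res, "hyper")
        hypo = segment_enhanced(norm, res, "hypo")
        at_threshold = norm.image == res.threshold
        assert not np.any(hyper & hypo)
        assert np.array_equal(hyper | hypo | at_threshold, ~np.isnan(norm.image))

    def test_degenerate_roi_yields_empty_lesion_with_warning(self):
        norm = NormalizedROI(image=np.full((2, 2), 0.5), values=np.full(4, 0.5), degenerate=True)
        res = otsu_threshold(IntensityHistogram(counts=[1, 1], bin_edges=[0, 0.5, 1]))
        with pytest.warns(UserWarning, match="degenerate"):
            lesion = segment_enhanced(norm, res, "hyper")
        assert lesion.sum() == 0


class TestAreaFraction:
    def test_bounds(self):
        mask = np.ones((4, 4), bool)
        assert area_fraction(np.zeros((4, 4), bool), mask) == 0.0
        assert area_fraction(mask, mask) == 100.0

    def test_lesion_outside_mask_rejected(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError, match="outside"):
            area_fraction(np.ones((4, 4), bool), mask)

    def test_noiseless_quarter_wedge_recovered(self, wedge_phantom):
        _, img, truth = wedge_phantom
        mask = MyocardialMask(truth.myocardium_mask, lv_center(truth.myocardium_mask))
        pct, otsu, _ = quantify_area(img, mask, "hyper")
        assert pct == pytest.approx(25.0, abs=1.0)
        assert otsu is not None


class TestPipelineRecovery:
    def test_noiseless_transmural_wedges_recovered_within_1p5_points(self):
        rng = np.random.default_rng(12)
        for _ in range(15):
            span = float(rng.uniform(30, 300))
            spec = PhantomSpec(
                wedges=(LesionWedge(float(rng.uniform(0, 360)), span),)
            )
            img, truth = generate_phantom(spec)
            mask = MyocardialMask(truth.myocardium_mask, lv_center(truth.myocardium_mask))
            pct, _, _ = quantify_area(img, mask, "hyper")
            assert abs(pct - truth.true_fraction_area) <= 1.5
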