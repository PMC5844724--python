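"""Texture-feature extraction: closed forms, oracle equivalence, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larctex import (
    MaskedImage,
    compute_first_order,
    compute_histogram_features,
    discretize,
    extract_features,
)

from conftest import random_masked_image
from oracles import naive_binning, naive_features


class TestDiscretize:
    def test_uniform_identity_case(self):
        hist = discretize(np.arange(32, dtype=float), n_bins=32)
        assert np.allclose(hist.probabilities, 1 / 32)
        assert hist.counts.sum() == 32

    def test_degenerate_range_single_bin(self):
        hist = discretize(np.full(10, 7.0), n_bins=32)
        assert hist.counts[0] == 10
        assert hist.counts[1:].sum() == 0
        assert (np.diff(hist.bin_edges) > 0).all()

    def test_matches_naive_binning_oracle(self, rng):
        values = rng.random(1000)
        hist = discretize(values, n_bins=16)
        assert hist.counts.tolist() == naive_binning(values, 16)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty ROI"):
            discretize([], n_bins=8)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            discretize([1.0, 2.0], n_bins=1)


class TestFirstOrder:
    def test_hand_evaluated_small_sample(self):
        mean, sd, _, _ = compute_first_order([1, 2, 3, 4])
        assert mean == pytest.approx(2.5)
        assert sd == pytest.approx(np.sqrt(5 / 3), abs=1e-12)  # 1.29099...

    def test_zero_variance_gives_undefined_shape_stats(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            _, sd, skew, kurt = compute_first_order([5.0] * 8)
        assert sd == 0.0
        assert np.isnan(skew) and np.isnan(kurt)

    def test_gaussian_limit(self, rng):
        # moderate-n version of the Gaussian-limit check; the full 10^6-draw
        # version runs in the acceptance suite
        x = rng.standard_normal(200_000)
        _, _, skew, kurt = compute_first_order(x)
        assert abs(skew) < 3 * np.sqrt(6 / x.size)
        assert abs(kurt - 3) < 3 * np.sqrt(24 / x.size)


class TestHistogramFeatures:
    @pytest.mark.parametrize("k", [2, 4, 8, 32])
    def test_uniform_k_bins_closed_form(self, k):
        hist = discretize(np.arange(k, dtype=float), n_bins=k)
        uniformity, _, entropy = compute_histogram_features(hist)
        assert entropy == pytest.approx(np.log2(k), abs=1e-12)
        assert uniformity == pytest.approx(1 / k, abs=1e-12)

    def test_single_bin_degenerate(self):
        hist = discretize(np.full(5, 3.0), n_bins=8)
        uniformity, energy, entropy = compute_histogram_features(hist, np.full(5, 3.0))
        assert entropy == 0.0
        assert uniformity == 1.0
        assert energy == 1.0  # zero-range convention

    def test_two_bin_symmetric_case(self):
        hist = discretize([0.0, 0.0, 1.0, 1.0], n_bins=2)
        uniformity, _, entropy = compute_histogram_features(hist)
        assert entropy == pytest.approx(1.0)
        assert uniformity == pytest.approx(0.5)

    def test_printed_uniformity_variant_is_index_weighted(self):
        hist = discretize(np.arange(4, dtype=float), n_bins=4)
        std, _, _ = compute_histogram_features(hist)
        printed, _, _ = compute_histogram_features(hist, uniformity_mode="printed")
        # sum_i i * (1/4)^2 = 10/16 vs 4 * (1/4)^2 = 1/4
        assert std == pytest.approx(0.25)
        assert printed == pytest.approx(10 / 16)


class TestExtractFeatures:
    def test_constant_roi(self):
        img = MaskedImage(pixels=np.full((8, 8), 7.0), mask=np.ones((8, 8), bool))
        with pytest.warns(RuntimeWarning):
            f = extract_features(img)
        assert f.mean == 7.0
        assert f.sd == 0.0
        assert f.entropy == 0.0
        assert f.uniformity == 1.0
        assert np.isnan(f.skewness) and np.isnan(f.kurtosis)

    def test_matches_naive_loop_oracle(self, rng):
        for _ in range(25):
            img = random_masked_image(rng)
            got = extract_features(img, n_bins=32).as_dict()
            want = naive_features(img.intensities, n_bins=32)
            for name, v in got.items():
                assert v == pytest.approx(want[name], abs=1e-10), name

    def test_mask_external_pixels_ignored(self, rng):
        img = random_masked_image(rng)
        other = img.pixels.copy()
        other[~img.mask] = -1e6
        img2 = MaskedImage(pixels=other, mask=img.mask)
        assert extract_features(img).as_dict() == extract_features(img2).as_dict()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty ROI"):
            MaskedImage(pixels=np.zeros((4, 4)), mask=np.zeros((4, 4), bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            MaskedImage(pixels=np.zeros((4, 4)), mask=np.ones((4, 3), bool))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    values=st.lists(st.integers(min_value=-10**6, max_value=10**6), min_size=3, max_size=80),
    shift=st.integers(min_value=-10**6, max_value=10**6),
)
def test_affine_shift_and_permutation_invariance(values, shift):
    """x -> x + c moves the mean by c and leaves every other feature fixed
    (energy via its min-max normalisation); pixel order never matters.

    Integer intensities keep the shifted values exactly representable, so
    the discretization boundaries are bit-identical before and after."""
    values = np.asarray(values, dtype=float)
    size = values.size
    img = MaskedImage(
        pixels=values.reshape(1, size), mask=np.ones((1, size), bool)
    )
    perm = np.random.default_rng(0).permutation(size)
    img_perm = MaskedImage(
        pixels=values[perm].reshape(1, size), mask=np.ones((1, size), bool)
    )
    img_shift = MaskedImage(
        pixels=(values + shift).reshape(1, size), mask=np.ones((1, size), bool)
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f = extract_features(img, n_bins=8)
        fp = extract_features(img_perm, n_bins=8)
        fs = extract_features(img_shift, n_bins=8)
    for name, v in f.as_dict().items():
        got = getattr(fp, name)
        assert got == pytest.approx(v, nan_ok=True, rel=1e-9, abs=1e-9), name
    assert fs.mean == pytest.approx(f.mean + shift, rel=1e-6, abs=1e-6)
    for name in ("sd", "skewness", "kurtosis", "uniformity", "entropy", "energy"):
        assert getattr(fs, name) == pytest.approx(
            getattr(f, name), nan_ok=True, rel=1e-6, abs=1e-6
        ), name
    assert 0.0 <= f.entropy <= np.log2(8) + 1e-12
    assert 1 / 8 - 1e-12 <= f.uniformity <= 1.0


def test_two_bin_entropy_uniformity_anti_monotone():
    """As a two-bin histogram approaches (1/2, 1/2), entropy rises and
    uniformity falls, strictly."""
    ps = np.linspace(0.05, 0.5, 10)
    ent, uni = [], []
    for p in ps:
        n = 1000
        k = int(round(p * n))
        values = np.concatenate([np.zeros(k), np.ones(n - k)])
        hist = discretize(values, n_bins=2)
        u, _, h = compute_histogram_features(hist)
        ent.append(h)
        uni.append(u)
    assert all(np.diff(ent) > 0)
    assert all(np.diff(uni) < 0)
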