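"""Score-CAM, SmoothGrad and jet-overlay rendering."""

import numpy as np
import pytest
from scipy.ndimage import binary_dilation
from scipy.stats import spearmanr

from plaquecam import (
    CANVAS_SHAPE,
    DegenerateHeatmapError,
    render_jet_overlay,
    score_cam,
    select_top_channels,
    smooth_grad,
    standardize_sample,
)
from plaquecam.model import ActivationStack, LinearScoringModel, ScoringModel
from plaquecam.synthetic import render_phantom, sample_phantom_spec
from tests.conftest import make_standardized


class RegionMeanModel(ScoringModel):
    """Toy: SY score is a sigmoid of the image mean, channels are fixed."""

    def __init__(self, channels, gain=0.05):
        self._stack = ActivationStack(np.asarray(channels, dtype=float), "toy")
        self.gain = gain

    def predict_proba(self, image):
        z = self.gain * float(np.mean(image.pixels))
        p = 1.0 / (1.0 + np.exp(-z))
        return np.array([1 - p, p])

    def activations(self, image):
        return self._stack


def _variance_stack(variances):
    rng = np.random.default_rng(0)
    chans = []
    for v in variances:
        c = rng.standard_normal((8, 8))
        c = (c - c.mean()) / c.std() * np.sqrt(v)
        chans.append(c)
    return ActivationStack(np.stack(chans), "toy")


def test_top_channels_ordered_by_variance():
    stack = _variance_stack([0.1, 5.0, 2.0])
    assert select_top_channels(stack, k=2) == [1, 2]


def test_top_channels_clamps_k():
    stack = _variance_stack([0.1, 5.0, 2.0])
    assert select_top_channels(stack, k=10) == [1, 2, 0]


def test_top_channels_tie_break_is_stable():
    stack = ActivationStack(np.ones((4, 6, 6)), "toy")
    assert select_top_channels(stack, k=4) == [0, 1, 2, 3]


def test_single_positive_channel_equals_normalized_field():
    channel = np.zeros(CANVAS_SHAPE)
    channel[40:120, 60:200] = 3.0
    model = RegionMeanModel([channel])
    pixels = np.full(CANVAS_SHAPE, 100, dtype=np.uint8)
    hm = score_cam(model, make_standardized(pixels), "SY", k=1)
    expected = channel / 3.0
    assert not hm.degenerate
    assert np.allclose(hm.values, expected)


def test_all_nonpositive_weights_flag_degenerate():
    """Masking can only lower the score -> ReLU annihilates the map."""

    class AntiModel(RegionMeanModel):
        def predict_proba(self, image):
            p = super().predict_proba(image)
            return p[::-1]  # SY prob falls as masked content grows

    channel = np.zeros(CANVAS_SHAPE)
    channel[10:50, 10:50] = 1.0
    hm = score_cam(AntiModel([channel]), make_standardized(np.full(CANVAS_SHAPE, 120, np.uint8)), "SY", k=1)
    assert hm.degenerate
    assert hm.values.max() == 0.0


def test_score_cam_matches_exhaustive_channel_scoring():
    """Brute-force oracle: score every channel mask directly and combine."""
    rng = np.random.default_rng(4)
    channels = rng.uniform(0, 1, size=(4, 28, 64))
    model = RegionMeanModel(channels, gain=0.02)
    pixels = rng.integers(0, 256, CANVAS_SHAPE).astype(np.uint8)
    image = make_standardized(pixels)
    hm = score_cam(model, image, "SY", k=None)

    from skimage.transform import resize

    baseline = model.predict_proba(make_standardized(np.zeros(CANVAS_SHAPE, np.uint8)))[1]
    field = np.zeros(CANVAS_SHAPE)
    for c in channels:
        up = resize(c, CANVAS_SHAPE, order=1, mode="edge", anti_aliasing=False, preserve_range=True)
        norm = (up - up.min()) / (up.max() - up.min())
        masked = make_standardized(norm * pixels)
        field += (model.predict_proba(masked)[1] - baseline) * norm
    field = np.maximum(field, 0)
    expected = (field - field.min()) / (field.max() - field.min())
    assert np.allclose(hm.values, expected)


def test_faster_variant_equals_exhaustive_when_k_covers_stack(bk_oracle, sy_standardized):
    std, _ = sy_standardized
    fast = score_cam(bk_oracle, std, "SY", k=3)  # oracle stack has 3 channels
    full = score_cam(bk_oracle, std, "SY", k=None)
    assert np.array_equal(fast.values, full.values)


def test_heatmap_localizes_on_attended_band(bk_oracle):
    """>= 80% of heatmap mass falls inside the dilated black blob."""
    for seed in range(10):
        sample = render_phantom(sample_phantom_spec("SY", rng_seed=600 + seed))
        std, (truth,) = standardize_sample(
            sample.image, sample.plaque_mask, sample.refs,
            extra_masks=(sample.composition_truth,),
        )
        hm = score_cam(bk_oracle, std, "SY", k=3)
        assert not hm.degenerate
        blob = binary_dilation(truth == 1, iterations=bk_oracle.downsample)
        assert hm.values[blob].sum() / hm.values.sum() >= 0.80


def test_heatmap_correlates_with_attended_indicator(bk_oracle, sy_standardized):
    std, truth = sy_standardized
    hm = score_cam(bk_oracle, std, "SY", k=3)
    inside = std.plaque_mask
    rho = spearmanr(hm.values[inside], (truth == 1)[inside].astype(float)).statistic
    assert rho > 0


def test_nondegenerate_heatmap_spans_unit_interval(bk_oracle, sy_standardized):
    std, _ = sy_standardized
    hm = score_cam(bk_oracle, std, "SY", k=3)
    assert hm.values.min() == 0.0 and hm.values.max() == 1.0


def test_smooth_grad_no_noise_is_plain_gradient(bk_oracle, sy_standardized):
    std, _ = sy_standardized
    sal = smooth_grad(bk_oracle, std, "SY", n=1, noise=0.0, seed=0)
    assert np.array_equal(sal.values, np.abs(bk_oracle.gradient(std, "SY")))


def test_smooth_grad_linear_model_recovers_weight_magnitudes():
    rng = np.random.default_rng(1)
    weights = rng.normal(0, 1e-6, CANVAS_SHAPE)
    model = LinearScoringModel(weights)
    image = make_standardized(rng.integers(0, 256, CANVAS_SHAPE).astype(np.uint8))
    sal = smooth_grad(model, image, "SY", n=5, noise=0.2, seed=0)
    ratio = sal.values / np.abs(weights)
    assert ratio.std() / ratio.mean() < 1e-6  # proportional to |w| everywhere


def test_smooth_grad_reproducible_at_study_settings(bk_oracle, sy_standardized):
    std, _ = sy_standardized
    a = smooth_grad(bk_oracle, std, "SY", n=20, noise=0.30, seed=9)
    b = smooth_grad(bk_oracle, std, "SY", n=20, noise=0.30, seed=9)
    assert np.array_equal(a.values, b.values)
    assert a.n_samples == 20 and a.noise_level == 0.30


def test_smooth_grad_variance_shrinks_with_n(bk_oracle, sy_standardized):
    std, _ = sy_standardized
    spread = {}
    for n in (1, 5, 20):
        maps = [smooth_grad(bk_oracle, std, "SY", n=n, noise=0.3, seed=s).values for s in range(6)]
        spread[n] = float(np.var(np.stack(maps), axis=0).mean())
    assert spread[20] < spread[5] < spread[1]


def test_smooth_grad_input_validation(bk_oracle, sy_standardized):
    std, _ = sy_standardized
    with pytest.raises(ValueError):
        smooth_grad(bk_oracle, std, "SY", n=0)

    class NoGrad(RegionMeanModel):
        pass

    with pytest.raises(NotImplementedError):
        smooth_grad(NoGrad(np.ones((1, 4, 4))), std, "SY")


def test_jet_overlay_endpoints(bk_oracle, sy_standardized):
    std, _ = sy_standardized
    hm = score_cam(bk_oracle, std, "SY", k=3)
    rgb = render_jet_overlay(hm, std, restrict_to_plaque=True)
    inside = std.plaque_mask
    hot = inside & (hm.values == 1.0)
    cold = inside & (hm.values == 0.0)
    assert rgb[hot][:, 0].mean() > rgb[hot][:, 2].mean()  # hottest: red over blue
    assert rgb[cold][:, 2].mean() > rgb[cold][:, 0].mean()  # coldest: blue over red
    outside = ~inside
    gray = np.repeat(std.pixels[..., None], 3, axis=2)
    assert np.array_equal(rgb[outside], gray[outside])


def test_jet_overlay_refuses_degenerate_maps(sy_standardized):
    from plaquecam.cam import Heatmap

    std, _ = sy_standardized
    degenerate = Heatmap(np.zeros(CANVAS_SHAPE), "SY", degenerate=True)
    with pytest.raises(DegenerateHeatmapError):
        render_jet_overlay(degenerate, std)
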