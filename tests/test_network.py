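import numpy as np
import pytest

import cspd.nn as nn
from cspd.forward import SpatiotemporalBlock
from cspd.network import (CspdModel, FeatureExtractor, GeneratorSpec,
                          LossSpec, TrainConfig, block_to_input,
                          build_discriminator, build_generator, compute_loss,
                          load_model, predict_flow_separated, save_model)
from cspd.ulm import UlmImage


def _numeric_grad(f, x, eps=1e-2):
    # coarse central differences: the framework computes in float32, so the
    # step must be large relative to the rounding noise
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def _check_layer_grad(layer, x, tol=2e-2):
    """Compare the layer's backward pass with numeric gradients of sum(y^2)/2."""
    def loss():
        y = layer.forward(x, train=True)
        return 0.5 * float(np.sum(y ** 2))

    for p in layer.params():
        p.grad[...] = 0.0
    y = layer.forward(x, train=True)
    gx = layer.backward(y.copy())
    np.testing.assert_allclose(gx, _numeric_grad(loss, x), atol=tol)
    for p in layer.params():
        np.testing.assert_allclose(p.grad, _numeric_grad(loss, p.value),
                                   atol=tol)


def test_conv2d_gradients(rng):
    layer = nn.Conv2d(2, 3, 3, rng)
    _check_layer_grad(layer, rng.standard_normal((2, 2, 5, 5)) * 0.5)


def test_upsample_bilinear_gradients(rng):
    layer = nn.UpsampleBilinear2x()
    _check_layer_grad(layer, rng.standard_normal((1, 2, 4, 4)))


def test_conv_transpose_gradients(rng):
    layer = nn.ConvTranspose2x2(2, 2, rng)
    _check_layer_grad(layer, rng.standard_normal((1, 2, 4, 4)) * 0.5)


def test_maxpool_gradients(rng):
    layer = nn.MaxPool2x2()
    # distinct values so the argmax is stable under the fd perturbation
    x = rng.permutation(64).reshape(1, 1, 8, 8).astype(float)
    _check_layer_grad(layer, x)


def test_batchnorm_gradients(rng):
    layer = nn.BatchNorm2d(2)
    _check_layer_grad(layer, rng.standard_normal((3, 2, 4, 4)), tol=3e-2)


def test_generator_output_shape_and_determinism(rng):
    spec = GeneratorSpec(in_frames=4, n_levels=1, base_channels=4,
                         upsampling=4, tail_channels=4)
    g1 = build_generator(spec, seed=5)
    g2 = build_generator(spec, seed=5)
    x = rng.standard_normal((2, 4, 16, 16))
    y1 = g1.forward(x, train=False)
    y2 = g2.forward(x, train=False)
    assert y1.shape == (2, 1, 64, 64)
    np.testing.assert_array_equal(y1, y2)


def test_generator_spec_validation():
    with pytest.raises(ValueError):
        GeneratorSpec(upsampling=3)
    with pytest.raises(ValueError):
        GeneratorSpec(n_levels=0)


def test_critic_scalar_score(rng):
    critic = build_discriminator(32, base_channels=4, seed=0)
    y = critic.forward(rng.standard_normal((3, 1, 32, 32)), train=False)
    assert y.shape == (3,) or y.shape == (3, 1)


def test_clip_params(rng):
    critic = build_discriminator(32, base_channels=4, seed=0)
    for p in critic.params():
        p.value[...] = 10 * rng.standard_normal(p.value.shape)
    nn.clip_params(critic.params(), 0.01)
    for p in critic.params():
        assert np.all(np.abs(p.value) <= 0.01 + 1e-12)


def test_compute_loss_modes(rng):
    pred = rng.random((1, 1, 16, 16))
    target = rng.random((1, 1, 16, 16))
    spec = LossSpec(mode="l1")
    total, comps = compute_loss(pred, target, spec)
    assert total == pytest.approx(np.mean(np.abs(pred - target)))
    fe = FeatureExtractor(seed=7)
    spec_f = LossSpec(mode="l1+feature", lambda1=1e-3)
    total_f, comps_f = compute_loss(pred, target, spec_f,
                                    feature_extractor=fe)
    assert total_f == pytest.approx(comps_f["l1"] +
                                    1e-3 * comps_f["feature"])
    spec_a = LossSpec(mode="l1+adversarial", lambda2=1e-2)
    scores = np.array([0.3])
    total_a, comps_a = compute_loss(pred, target, spec_a,
                                    critic_scores=scores)
    assert comps_a["adversarial"] == pytest.approx(-0.3)
    with pytest.raises(ValueError):
        LossSpec(mode="l2")


def _tiny_pairs(rng, t=4, grid=16, n_planes=2, blocks_per_plane=2):
    pairs = []
    for _ in range(n_planes):
        blocks = []
        for _ in range(blocks_per_plane):
            data = rng.standard_normal((grid, grid, t))
            blocks.append(SpatiotemporalBlock(
                data=data, pixel_pitch=0.025, frame_rate=1000.0,
                kind="clutter_filtered"))
        counts = np.zeros((4 * grid, 4 * grid))
        idx = rng.integers(0, 4 * grid, size=(30, 2))
        counts[idx[:, 0], idx[:, 1]] = rng.integers(1, 5, size=30)
        pairs.append((blocks, UlmImage(counts=counts, upsampling=4,
                                       pixel_pitch=0.025 / 4)))
    return pairs


@pytest.fixture(scope="module")
def tiny_results():
    rng = np.random.default_rng(3)
    pairs = _tiny_pairs(rng)
    spec = GeneratorSpec(in_frames=4, n_levels=1, base_channels=4,
                         tail_channels=4)
    model = CspdModel.from_pairs(pairs, spec)
    return model.fit(TrainConfig(max_epochs=3, validation_fraction=0.25,
                                 batch_size=2))


def test_fit_smoke_and_history(tiny_results):
    h = tiny_results.history
    assert len(h) == 3
    assert np.all(np.isfinite(np.asarray(h["train_loss"], dtype=float)))
    assert tiny_results.best_val_loss < np.inf


def test_prediction_nonnegative(tiny_results, rng):
    blk = SpatiotemporalBlock(data=rng.standard_normal((16, 16, 4)),
                              pixel_pitch=0.025, frame_rate=1000.0,
                              kind="clutter_filtered")
    out = tiny_results.predict(blk)
    assert out.shape == (64, 64)
    assert out.min() >= 0.0


def test_save_load_roundtrip(tiny_results, tmp_path, rng):
    p = tmp_path / "model.npz"
    save_model(p, tiny_results)
    loaded = load_model(p)
    blk = SpatiotemporalBlock(data=rng.standard_normal((16, 16, 4)),
                              pixel_pitch=0.025, frame_rate=1000.0,
                              kind="clutter_filtered")
    np.testing.assert_array_equal(tiny_results.predict(blk),
                                  loaded.predict(blk))


def test_predict_flow_separated_runs(tiny_results, rng):
    blk = SpatiotemporalBlock(data=rng.standard_normal((16, 16, 4)),
                              pixel_pitch=0.025, frame_rate=1000.0,
                              kind="clutter_filtered")
    out = predict_flow_separated(tiny_results, blk, n_bands=2)
    assert out.shape == (64, 64)
    assert out.max() <= 1.0 + 1e-9


def test_adversarial_training_smoke(rng):
    pairs = _tiny_pairs(rng, n_planes=2, blocks_per_plane=2)
    spec = GeneratorSpec(in_frames=4, n_levels=1, base_channels=4,
                         tail_channels=4)
    model = CspdModel.from_pairs(pairs, spec,
                                 LossSpec(mode="l1+adversarial"))
    res = model.fit(TrainConfig(max_epochs=2, validation_fraction=0.25,
                                batch_size=2, critic_steps=1))
    assert len(res.history) == 2


def test_feature_loss_training_smoke(rng):
    pairs = _tiny_pairs(rng, n_planes=2, blocks_per_plane=2)
    spec = GeneratorSpec(in_frames=4, n_levels=1, base_channels=4,
                         tail_channels=4)
    model = CspdModel.from_pairs(pairs, spec, LossSpec(mode="l1+feature"))
    res = model.fit(TrainConfig(max_epochs=2, validation_fraction=0.25,
                                batch_size=2))
    assert len(res.history) == 2


def test_block_to_input_frames_and_collapse(rng):
    blk = SpatiotemporalBlock(data=rng.standard_normal((8, 8, 6)),
                              pixel_pitch=0.025, frame_rate=1000.0,
                              kind="clutter_filtered")
    x = block_to_input(blk)
    assert x.shape == (6, 8, 8)
    xc = block_to_input(blk, collapse=True)
    assert xc.shape == (1, 8, 8)
    with pytest.raises(ValueError):
        block_to_input(blk.with_data(blk.data, kind="raw"))


def test_input_frame_mismatch_rejected(tiny_results, rng):
    blk = SpatiotemporalBlock(data=rng.standard_normal((16, 16, 9)),
                              pixel_pitch=0.025, frame_rate=1000.0,
                              kind="clutter_filtered")
    with pytest.raises(ValueError):
        tiny_results.predict(blk)
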