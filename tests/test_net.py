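"""Classifier architecture: stage features, fusion gating, CBAM, forward."""

import numpy as np
import pytest

from scintivur.nn import Tensor
from scintivur.net import (
    CBAM,
    GatedFusion,
    NetConfig,
    bilinear_resize,
    build_model,
    load_checkpoint,
    save_checkpoint,
)


def tiny_config(**overrides) -> NetConfig:
    base = dict(img_size=64, window_size=4, embed_dim=8, num_heads=(1, 2, 4, 8))
    base.update(overrides)
    return NetConfig(**base)


@pytest.fixture(scope="module")
def model():
    return build_model(tiny_config(), seed=3)


@pytest.fixture(scope="module")
def images():
    return np.random.default_rng(0).normal(size=(3, 1, 64, 64))


class TestStageFeatures:
    def test_spatial_dims_strictly_decrease(self, model, images):
        fs = model.extract_stage_features(images)
        dims = [f.shape[-1] for f in fs.stages]
        assert dims == [16, 8, 4, 2]
        chans = [f.shape[1] for f in fs.stages]
        assert chans == [8, 16, 32, 64]

    def test_eval_determinism(self, model, images):
        a = model.extract_stage_features(images).stages
        b = model.extract_stage_features(images).stages
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))

    def test_batch_dimension_propagates(self, model):
        imgs = np.random.default_rng(1).normal(size=(5, 1, 64, 64))
        fs = model.extract_stage_features(imgs)
        assert all(f.shape[0] == 5 for f in fs.stages)

    def test_wrong_input_size_rejected(self, model):
        with pytest.raises(ValueError, match="expected input"):
            model(np.zeros((1, 1, 32, 32)))

    def test_indivisible_input_rejected_at_construction(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(img_size=100)


class TestBilinearResize:
    def test_identity_when_sizes_match(self):
        x = Tensor(np.random.default_rng(0).normal(size=(1, 2, 4, 4)))
        assert bilinear_resize(x, (4, 4)) is x

    def test_constant_preserved(self):
        x = Tensor(np.full((1, 1, 8, 8), 3.25))
        out = bilinear_resize(x, (3, 3))
        assert np.allclose(out.data, 3.25)

    def test_checkerboard_average(self):
        x = Tensor(np.array([[1.0, 2.0], [3.0, 4.0]])[None, None])
        out = bilinear_resize(x, (1, 1))
        assert out.data.item() == pytest.approx(2.5)


class TestGatedFusion:
    def test_zero_logits_give_uniform_weights(self):
        rng = np.random.default_rng(0)
        gf = GatedFusion([4, 4, 4, 4], 4, gate=True, rng=rng)
        assert np.allclose(gf.alphas().data, 0.25)

    def test_softmax_matches_scalar_oracle(self):
        rng = np.random.default_rng(0)
        gf = GatedFusion([4, 4], 4, gate=True, rng=rng)
        gf.gate_logits.data = np.array([10.0, 0.0])
        e10 = np.exp(10.0)
        expected = np.array([e10 / (e10 + 1.0), 1.0 / (e10 + 1.0)])
        assert np.allclose(gf.alphas().data, expected, rtol=1e-12)
        assert gf.alphas().data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_identical_features_pass_through_for_any_gates(self):
        rng = np.random.default_rng(0)
        gf = GatedFusion([3, 3, 3, 3], 3, gate=True, rng=rng)
        for proj in gf.projections:  # identity projections isolate the gating sum
            proj.weight.data = np.eye(3)
            proj.bias.data = np.zeros(3)
        x = Tensor(rng.normal(size=(2, 3, 4, 4)))
        for logits in ([0.0, 0, 0, 0], [5.0, -2.0, 1.0, 0.3]):
            gf.gate_logits.data = np.array(logits)
            fused = gf([x, x, x, x])
            assert np.allclose(fused.data, x.data, atol=1e-12)

    def test_misaligned_inputs_rejected(self):
        rng = np.random.default_rng(0)
        gf = GatedFusion([3, 3], 3, gate=True, rng=rng)
        a = Tensor(np.zeros((1, 3, 4, 4)))
        b = Tensor(np.zeros((1, 3, 2, 2)))
        with pytest.raises(ValueError, match="aligned"):
            gf([a, b])

    def test_gradients_flow_to_gate_logits(self):
        rng = np.random.default_rng(0)
        gf = GatedFusion([2, 2], 2, gate=True, rng=rng)
        x = Tensor(rng.normal(size=(1, 2, 2, 2)))
        y = Tensor(rng.normal(size=(1, 2, 2, 2)))
        (gf([x, y]) ** 2).sum().backward()
        assert gf.gate_logits.grad is not None
        assert np.abs(gf.gate_logits.grad).sum() > 0


class TestCBAM:
    def test_zero_input_gives_zero_output(self):
        cbam = CBAM(16, 4, np.random.default_rng(0))
        out = cbam(Tensor(np.zeros((2, 16, 5, 5))))
        assert np.allclose(out.data, 0.0)

    def test_attention_maps_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        cbam = CBAM(16, 4, rng)
        x = Tensor(rng.normal(size=(2, 16, 5, 5)) * 10)
        mc = cbam.channel_gate(x)
        ms = cbam.spatial_gate(x)
        assert np.all((mc.data > 0) & (mc.data < 1))
        assert np.all((ms.data > 0) & (ms.data < 1))
        assert mc.shape == (2, 16)
        assert ms.shape == (2, 1, 5, 5)

    def test_matches_straight_line_equation_evaluation(self):
        """Independent numpy evaluation of the channel/spatial gating chain."""
        rng = np.random.default_rng(7)
        cbam = CBAM(8, 2, rng)
        x = rng.normal(size=(1, 8, 3, 3))

        def sigmoid(v):
            return 1.0 / (1.0 + np.exp(-v))

        w1, w2 = cbam.fc1.weight.data, cbam.fc2.weight.data
        mlp = lambda v: np.maximum(v @ w1, 0.0) @ w2
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        mc = sigmoid(mlp(avg) + mlp(mx))  # channel attention
        fprime = mc[:, :, None, None] * x
        stacked = np.concatenate(
            [fprime.mean(axis=1, keepdims=True), fprime.max(axis=1, keepdims=True)], axis=1
        )
        k = cbam.spatial_kernel.data
        pad = np.pad(stacked, ((0, 0), (0, 0), (3, 3), (3, 3)))
        conv = np.zeros((1, 1, 3, 3))
        for i in range(3):
            for j in range(3):
                conv[0, 0, i, j] = (pad[0, :, i : i + 7, j : j + 7] * k[0]).sum()
        ms = sigmoid(conv + cbam.spatial_bias.data)
        expected = ms * fprime
        out = cbam(Tensor(x))
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_channel_reduction_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CBAM(8, 16, np.random.default_rng(0))


class TestForward:
    def test_probabilities_normalised(self, model, images):
        logits = model(images)
        probs = logits.softmax(axis=-1).data
        assert logits.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_batch_permutation_equivariance(self, model, images):
        base = model(images).data
        perm = [2, 0, 1]
        permuted = model(images[perm]).data
        np.testing.assert_allclose(permuted, base[perm], atol=1e-10)

    @pytest.mark.parametrize("variant", ["A", "B", "C", "D", "E", "full"])
    def test_ablation_variants_constructible(self, variant, images):
        cfg = NetConfig.variant(
            variant, img_size=64, window_size=4, embed_dim=8, num_heads=(1, 2, 4, 8)
        )
        m = build_model(cfg, seed=0)
        out = m(images)
        assert out.shape == (3, 2)
        if variant == "A":
            with pytest.raises(ValueError):
                m.gate_alphas()

    def test_gate_weights_stay_normalised_after_training_steps(self, images):
        from scintivur.nn import AdamW, cross_entropy

        m = build_model(tiny_config(), seed=0)
        opt = AdamW(m.parameters(), lr=1e-2)
        for _ in range(3):
            loss = cross_entropy(m(images), np.array([0, 1, 0]))
            m.zero_grad()
            loss.backward()
            opt.step()
            assert m.gate_alphas().sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(m.gate_alphas() > 0)

    def test_checkpoint_round_trip(self, tmp_path, model, images):
        save_checkpoint(model, tmp_path / "ckpt")
        restored = load_checkpoint(tmp_path / "ckpt")
        np.testing.assert_allclose(restored(images).data, model(images).data, atol=1e-12)

    def test_pretrained_weights_unavailable(self):
        with pytest.raises(NotImplementedError):
            NetConfig(pretrained=True)


def test_tiny_network_overfits_a_small_phantom_set():
    """Capacity sanity: 8 scans with a strong effect reach 100% train accuracy."""
    from scintivur.nn import AdamW, cross_entropy
    from scintivur.nn.autograd import default_dtype
    from scintivur.phantom import generate_patient, strong_effect_config
    from scintivur.preprocess import normalise, preprocess_scan
    from skimage.transform import resize

    cfg = strong_effect_config()
    grades = [(0, 0), (4, 0), (0, 0), (0, 5), (3, 3), (0, 0), (5, 0), (0, 0)]
    imgs, labels = [], []
    for i, (gl, gr) in enumerate(grades):
        scan = generate_patient(cfg, gl, gr, patient_seed=i)
        _, left, right = preprocess_scan(scan.image, f"p{i}")
        roi = left if gl >= gr else right
        imgs.append(resize(normalise(roi), (64, 64), order=1))
        labels.append(scan.label)
    x = np.stack(imgs)[:, None]
    y = np.array(labels)
    with default_dtype(np.float32):
        m = build_model(tiny_config(), seed=0)
        opt = AdamW(m.parameters(), lr=3e-3, weight_decay=0.0)
        for epoch in range(200):
            loss = cross_entropy(m(x), y)
            m.zero_grad()
            loss.backward()
            opt.step()
            acc = float(np.mean((m.predict_proba(x) >= 0.5) == y))
            if acc == 1.0:
                break
        assert acc == 1.0, f"failed to overfit: acc={acc} after {epoch + 1} epochs"
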