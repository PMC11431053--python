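"""Classifier architecture contracts: pyramid shapes, the 1x1 conv block,
auxiliary classifiers, fusion and checkpointing."""

import numpy as np
import pytest

from octex.autograd import Tensor
from octex.network import (
    Backbone,
    FeatureEncodingModule,
    ModelConfig,
    OCTClassifier,
    _AuxClassifier,
    load_checkpoint,
    save_checkpoint,
)

TINY = dict(n_textons=4, texton_dim=16)


@pytest.fixture(scope="module")
def tiny_model():
    return OCTClassifier(ModelConfig(backbone_profile="test", **TINY))


def test_test_profile_pyramid_shapes(tiny_model, rng):
    out = tiny_model.backbone(Tensor(rng.normal(size=(1, 1, 224, 224)).astype(np.float32)))
    assert [t.shape[2:] for t in out] == [(56, 56), (28, 28), (14, 14), (7, 7)]


def test_wrong_input_size_rejected(tiny_model):
    with pytest.raises(ValueError):
        tiny_model.backbone(Tensor(np.zeros((1, 1, 200, 224), dtype=np.float32)))


def test_batching_consistency(tiny_model, rng):
    """Per-item results of a batched forward equal single-item forwards."""
    tiny_model.eval()
    x = rng.normal(size=(3, 1, 128, 128)).astype(np.float32)
    batched = tiny_model(Tensor(x))["fused_logits"].data
    for i in range(3):
        single = tiny_model(Tensor(x[i : i + 1]))["fused_logits"].data
        np.testing.assert_allclose(batched[i], single[0], atol=1e-4)


class TestConvBlock:
    def test_output_channels_and_nonnegativity(self, rng):
        mod = FeatureEncodingModule(in_ch=6, n_textons=4, dim=128,
                                    rng=np.random.default_rng(0))
        mod.eval()
        out = mod.conv_block(Tensor(rng.normal(size=(2, 6, 9, 9)).astype(np.float32)))
        assert out.shape == (2, 128, 9, 9)
        assert (out.data >= 0).all()

    def test_identity_initialized_1x1_passes_rectified_input(self, rng):
        """Identity 1x1 weights with frozen (neutral) normalisation reduce
        the block to a plain rectifier."""
        mod = FeatureEncodingModule(in_ch=8, n_textons=2, dim=8,
                                    rng=np.random.default_rng(0))
        mod.conv.weight.data = np.eye(8, dtype=np.float32).reshape(8, 8, 1, 1)
        mod.conv.bias.data = np.zeros(8, dtype=np.float32)
        mod.eval()  # running stats are mean 0 / var 1: normalisation is a no-op
        x = rng.normal(size=(1, 8, 5, 5)).astype(np.float32)
        out = mod.conv_block(Tensor(x))
        np.testing.assert_allclose(out.data, np.maximum(x, 0.0), atol=1e-4)


class TestAuxClassifier:
    def test_scale_invariance_from_l2_normalisation(self, rng):
        head = _AuxClassifier(12, 5, rng=np.random.default_rng(1))
        v = rng.normal(size=(2, 12)).astype(np.float32)
        a = head(Tensor(v)).data
        b = head(Tensor(10.0 * v)).data
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_zero_weights_give_bias(self):
        head = _AuxClassifier(6, 3, rng=np.random.default_rng(1))
        head.fc.weight.data = np.zeros_like(head.fc.weight.data)
        head.fc.bias.data = np.array([0.5, -0.5, 1.0], dtype=np.float32)
        out = head(Tensor(np.ones((1, 6), dtype=np.float32))).data
        np.testing.assert_allclose(out[0], [0.5, -0.5, 1.0], atol=1e-7)

    def test_hand_computed_2x2_case(self):
        head = _AuxClassifier(2, 2, rng=np.random.default_rng(1))
        head.fc.weight.data = np.array([[1.0, 0.0], [1.0, 1.0]], dtype=np.float32)
        head.fc.bias.data = np.array([0.0, 1.0], dtype=np.float32)
        out = head(Tensor(np.array([[3.0, 4.0]], dtype=np.float32))).data
        np.testing.assert_allclose(out[0], [0.6, 0.6 + 0.8 + 1.0], atol=1e-6)


def test_fused_probs_sum_to_one_and_match_scale_sum(tiny_model, rng):
    tiny_model.eval()
    out = tiny_model(Tensor(rng.normal(size=(2, 1, 128, 128)).astype(np.float32)))
    total = sum(lg.data for lg in out["scale_logits"])
    np.testing.assert_allclose(out["fused_logits"].data, total, atol=1e-5)
    np.testing.assert_allclose(out["probs"].data.sum(axis=-1), 1.0, atol=1e-6)


@pytest.mark.parametrize(
    "flags",
    [
        dict(use_pyramid=False, use_encoding=True, deep_supervision=True),  # single-scale TE
        dict(use_pyramid=True, use_encoding=False, deep_supervision=True),  # pyramid, no TE
        dict(use_pyramid=True, use_encoding=True, deep_supervision=False),  # main loss only
    ],
)
def test_ablation_variants_train_one_step(flags, rng):
    """Each structural ablation runs a full forward/backward/update."""
    from octex.autograd import SGD

    model = OCTClassifier(ModelConfig(backbone_profile="test", **TINY, **flags))
    opt = SGD(model.parameters(), lr=0.01, momentum=0.9)
    x = Tensor(rng.normal(size=(4, 1, 128, 128)).astype(np.float32))
    terms = model.loss(model(x), np.array([0, 1, 3, 4]))
    expected_terms = (len(model.scale_indices) if flags["deep_supervision"] else 0) + 1
    assert len([k for k in terms if k != "total"]) == expected_terms
    terms["total"].backward()
    opt.step()
    assert all(np.isfinite(p.data).all() for p in model.parameters())


def test_deep_supervision_total_is_sum_of_terms(tiny_model, rng):
    out = tiny_model(Tensor(rng.normal(size=(2, 1, 128, 128)).astype(np.float32)))
    terms = tiny_model.loss(out, np.array([1, 2]))
    parts = [float(v.data) for k, v in terms.items() if k != "total"]
    assert float(terms["total"].data) == pytest.approx(sum(parts), rel=1e-6)


def test_checkpoint_round_trip(tmp_path, tiny_model, rng):
    tiny_model.norm_mean[:] = 123.4
    tiny_model.norm_std[:] = 45.6
    save_checkpoint(tiny_model, tmp_path / "ckpt.npz")
    back = load_checkpoint(tmp_path / "ckpt.npz")
    assert back.config == tiny_model.config
    assert back.norm_mean[0] == pytest.approx(123.4)
    x = Tensor(rng.normal(size=(1, 1, 128, 128)).astype(np.float32))
    tiny_model.eval()
    np.testing.assert_allclose(back(x)["fused_logits"].data,
                               tiny_model(x)["fused_logits"].data, atol=1e-6)


def test_reference_profile_pyramid_shapes():
    """The deep bottleneck backbone (101-layer layout) honours the same
    four-scale contract at 224x224."""
    bb = Backbone("reference", rng=np.random.default_rng(0))
    bb.eval()
    out = bb(Tensor(np.random.default_rng(1).normal(size=(1, 1, 224, 224)).astype(np.float32)))
    assert [t.shape[1:] for t in out] == [
        (256, 56, 56), (512, 28, 28), (1024, 14, 14), (2048, 7, 7)]
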