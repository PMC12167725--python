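"""Network architecture, weighted cross-entropy and layer gradients."""

import numpy as np
import pytest

from srfseg.errors import ConfigError, ContractError, DataError
from srfseg.nn import (
    ClassWeights,
    NetworkConfig,
    UNet3D,
    build_unet,
    deep_supervision_loss,
    load_model,
    save_model,
    weighted_ce,
    weighted_ce_grad,
)
from srfseg.nn.layers import Conv3d, ConvTranspose2, InstanceNorm3d


def test_desk_config_output_shapes():
    model = build_unet(NetworkConfig(levels=2, base_channels=8), seed=0)
    x = np.zeros((1, 2, 32, 32, 32), dtype=np.float32)
    scores = model.forward(x)
    assert scores[0].shape == (1, 3, 32, 32, 32)
    assert scores[1].shape == (1, 3, 16, 16, 16)
    assert len(scores) == 2


def test_full_config_shape_arithmetic_without_running():
    cfg = NetworkConfig(levels=4, base_channels=16)
    assert cfg.divisor == 8
    assert 160 % cfg.divisor == 0  # the full-size patch divides cleanly


def test_indivisible_patch_names_required_divisor():
    model = build_unet(NetworkConfig(levels=3, base_channels=4), seed=0)
    with pytest.raises(ContractError, match="divisible by 4"):
        model.forward(np.zeros((1, 2, 30, 30, 30), dtype=np.float32))


def test_same_seed_gives_identical_parameters():
    a = build_unet(NetworkConfig(levels=2, base_channels=4), seed=5)
    b = build_unet(NetworkConfig(levels=2, base_channels=4), seed=5)
    for (pa, _, ka), (pb, _, kb) in zip(a.param_items(), b.param_items()):
        np.testing.assert_array_equal(pa[ka], pb[kb])
    c = build_unet(NetworkConfig(levels=2, base_channels=4), seed=6)
    assert any(
        not np.array_equal(pa[ka], pc[kc])
        for (pa, _, ka), (pc, _, kc) in zip(a.param_items(), c.param_items())
    )


def test_checkpoint_roundtrip(tmp_path):
    model = build_unet(NetworkConfig(levels=2, base_channels=4), seed=3)
    model.patch_edge = 16
    x = np.random.default_rng(0).normal(size=(2, 16, 16, 16)).astype(np.float32)
    before = model.predict(x)
    save_model(model, tmp_path / "m.npz")
    loaded = load_model(tmp_path / "m.npz")
    assert loaded.patch_edge == 16
    np.testing.assert_array_equal(loaded.predict(x), before)


def test_softmax_probabilities_sum_to_one():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=(3, 4, 4, 4)) * 10
    _, grad = weighted_ce_grad(scores, np.zeros((4, 4, 4), dtype=np.uint8))
    s = scores - scores.max(axis=0)
    p = np.exp(s) / np.exp(s).sum(axis=0)
    assert np.allclose(p.sum(axis=0), 1.0, atol=1e-6)


def test_uniform_scores_on_background_give_ln3():
    scores = np.zeros((3, 4, 4, 4))
    labels = np.zeros((4, 4, 4), dtype=np.uint8)
    assert weighted_ce(scores, labels) == pytest.approx(np.log(3.0), abs=1e-6)


def test_confident_correct_scores_drive_loss_to_zero():
    labels = (np.arange(27).reshape(3, 3, 3) % 3).astype(np.uint8)
    losses = []
    for conf in (2.0, 5.0, 10.0):
        scores = np.full((3, 3, 3, 3), -conf)
        for k in range(3):
            scores[k][labels == k] = conf
        losses.append(weighted_ce(scores, labels))
    assert losses[0] > losses[1] > losses[2]
    assert losses[-1] < 1e-6


def test_two_voxel_weighted_mean_is_5a_plus_b_over_6():
    # voxel 0: true class 1 (kidney, weight 5), voxel 1: true background
    scores = np.array([[[0.2]], [[1.0]], [[-0.3]]])[:, :, :, None]  # (3,1,1,1)
    scores = np.concatenate([scores, scores * -0.5], axis=3)  # two voxels
    labels = np.array([[[1, 0]]], dtype=np.uint8)

    def ce(vec, true):
        vec = vec - vec.max()
        return -(vec[true] - np.log(np.exp(vec).sum()))

    a = ce(scores[:, 0, 0, 0], 1)
    b = ce(scores[:, 0, 0, 1], 0)
    expected = (5 * a + b) / 6
    assert weighted_ce(scores, labels) == pytest.approx(expected, abs=1e-9)


def test_loss_symmetric_under_left_right_relabel():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=(3, 5, 5, 5))
    labels = (rng.random((5, 5, 5)) * 3).astype(np.uint8)
    swapped_scores = scores[[0, 2, 1]]
    swapped_labels = labels.copy()
    swapped_labels[labels == 1] = 2
    swapped_labels[labels == 2] = 1
    assert weighted_ce(scores, labels) == pytest.approx(
        weighted_ce(swapped_scores, swapped_labels), abs=1e-12
    )


def test_single_voxel_gradient_matches_finite_differences():
    """Analytic softmax-CE gradient w*(p - onehot)/sum_w vs central differences."""
    rng = np.random.default_rng(2)
    scores = rng.normal(size=(3, 1, 1, 1))
    labels = np.array([[[1]]], dtype=np.uint8)
    _, grad = weighted_ce_grad(scores, labels)
    eps = 1e-6
    for k in range(3):
        up, down = scores.copy(), scores.copy()
        up[k] += eps
        down[k] -= eps
        num = (weighted_ce(up, labels) - weighted_ce(down, labels)) / (2 * eps)
        assert grad[0, k, 0, 0, 0] == pytest.approx(num, abs=1e-4)


def test_invalid_labels_rejected():
    with pytest.raises(DataError):
        weighted_ce(np.zeros((3, 2, 2, 2)), np.full((2, 2, 2), 3, dtype=np.uint8))


def test_deep_supervision_reductions():
    rng = np.random.default_rng(3)
    scores0 = rng.normal(size=(3, 4, 4, 4))
    scores1 = rng.normal(size=(3, 2, 2, 2))
    labels = (rng.random((4, 4, 4)) * 3).astype(np.uint8)
    base = weighted_ce(scores0, labels)
    # single scale reduces to the plain loss
    assert deep_supervision_loss([scores0], labels, scale_weights=[1.0]) == pytest.approx(base)
    # a vanishing-weight coarse scale contributes nothing
    almost = deep_supervision_loss([scores0, scores1], labels, scale_weights=[1.0, 1e-15])
    assert almost == pytest.approx(base, abs=1e-9)
    # uniform scores at every scale: ln 3 for any scale weighting
    flat = deep_supervision_loss(
        [np.zeros((3, 4, 4, 4)), np.zeros((3, 2, 2, 2))], labels * 0, scale_weights=[0.7, 0.3]
    )
    assert flat == pytest.approx(np.log(3.0), abs=1e-9)


def test_deep_supervision_length_mismatch():
    with pytest.raises(ContractError):
        deep_supervision_loss([np.zeros((3, 2, 2, 2))], np.zeros((2, 2, 2), dtype=np.uint8),
                              scale_weights=[1.0, 1.0])


def test_class_weights_defaults_and_validation():
    w = ClassWeights()
    np.testing.assert_array_equal(w.as_array(), [1.0, 5.0, 5.0])
    with pytest.raises(ContractError):
        ClassWeights(background=0.0)


def test_network_config_validation():
    with pytest.raises(ConfigError):
        NetworkConfig(levels=1)
    with pytest.raises(ConfigError):
        NetworkConfig(in_channels=3)


# ---- layer-level exactness against float64 oracles -------------------------


def _conv_oracle(x, W, b):
    d, h, w = x.shape[1:4]
    k = W.shape[0]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0))).astype(np.float64)
    y = np.zeros((*x.shape[:4], W.shape[-1]))
    for a in range(k):
        for bb in range(k):
            for c in range(k):
                y += np.einsum(
                    "ndhwi,io->ndhwo",
                    xp[:, a : a + d, bb : bb + h, c : c + w],
                    W[a, bb, c].astype(np.float64),
                )
    return y + b


def test_conv3d_forward_and_backward_match_dense_oracle():
    rng = np.random.default_rng(4)
    conv = Conv3d(3, 4, 3, np.random.default_rng(7))
    x = rng.normal(size=(2, 5, 6, 4, 3)).astype(np.float32)
    y = conv.forward(x)
    np.testing.assert_allclose(
        y, _conv_oracle(x, conv.params["W"], conv.params["b"]), rtol=1e-4, atol=1e-5
    )
    dy = rng.normal(size=y.shape).astype(np.float32)
    conv.zero_grad()
    dx = conv.backward(dy.copy())
    # dW oracle
    d, h, w = x.shape[1:4]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0))).astype(np.float64)
    for a in range(3):
        for bb in range(3):
            for c in range(3):
                ref = np.einsum(
                    "ndhwi,ndhwo->io", xp[:, a : a + d, bb : bb + h, c : c + w],
                    dy.astype(np.float64),
                )
                np.testing.assert_allclose(conv.grads["W"][a, bb, c], ref, rtol=1e-4, atol=1e-5)
    # dx oracle: full correlation with flipped kernel
    dyp = np.pad(dy, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0))).astype(np.float64)
    W64 = conv.params["W"].astype(np.float64)
    dx_ref = np.zeros_like(x, dtype=np.float64)
    for a in range(3):
        for bb in range(3):
            for c in range(3):
                dx_ref += np.einsum(
                    "ndhwo,io->ndhwi",
                    dyp[:, 2 - a : 2 - a + d, 2 - bb : 2 - bb + h, 2 - c : 2 - c + w],
                    W64[a, bb, c],
                )
    np.testing.assert_allclose(dx, dx_ref, rtol=1e-4, atol=1e-5)


def test_transposed_conv_doubles_and_inverts_exactly():
    rng = np.random.default_rng(5)
    up = ConvTranspose2(3, 2, np.random.default_rng(8))
    x = rng.normal(size=(2, 3, 4, 2, 3)).astype(np.float32)
    y = up.forward(x)
    assert y.shape == (2, 6, 8, 4, 2)
    ref = np.einsum("ndhwi,iabco->ndhwabco", x.astype(np.float64),
                    up.params["W"].astype(np.float64))
    ref = ref.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(2, 6, 8, 4, 2) + up.params["b"]
    np.testing.assert_allclose(y, ref, rtol=1e-5, atol=1e-6)
    dy = rng.normal(size=y.shape).astype(np.float32)
    up.zero_grad()
    dx = up.backward(dy)
    dt = dy.astype(np.float64).reshape(2, 3, 2, 4, 2, 2, 2, 2).transpose(0, 1, 3, 5, 2, 4, 6, 7)
    np.testing.assert_allclose(
        up.grads["W"], np.einsum("ndhwi,ndhwabco->iabco", x.astype(np.float64), dt),
        rtol=1e-4, atol=1e-5,
    )
    np.testing.assert_allclose(
        dx, np.einsum("ndhwabco,iabco->ndhwi", dt, up.params["W"].astype(np.float64)),
        rtol=1e-4, atol=1e-5,
    )


def test_instance_norm_normalizes_and_gradients_check():
    rng = np.random.default_rng(6)
    norm = InstanceNorm3d(3)
    x = (rng.normal(size=(2, 4, 4, 4, 3)) * 3 + 1).astype(np.float32)
    y = norm.forward(x)
    assert np.allclose(y.mean(axis=(1, 2, 3)), 0.0, atol=1e-4)
    assert np.allclose(y.std(axis=(1, 2, 3)), 1.0, atol=1e-2)
    # finite-difference check of the input gradient (smooth layer)
    R = rng.normal(size=y.shape).astype(np.float32)
    norm.zero_grad()
    dx = norm.backward(R)
    eps = 1e-3
    flat = x.reshape(-1)
    for j in rng.integers(flat.size, size=5):
        old = flat[j]
        flat[j] = old + eps
        up = float((norm.forward(x) * R).sum())
        flat[j] = old - eps
        down = float((norm.forward(x) * R).sum())
        flat[j] = old
        num = (up - down) / (2 * eps)
        assert dx.reshape(-1)[j] == pytest.approx(num, abs=5e-2, rel=5e-2)
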