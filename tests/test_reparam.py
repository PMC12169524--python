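"""Fusion algebra: examples, direct-composition oracles, and the
train/deploy equivalence property across precisions."""

import warnings

import numpy as np
import pytest

from repdet import autograd as ag
from repdet.autograd import Tensor
from repdet.reparam import (
    BNParams,
    ConvKernel,
    RepC3,
    RepConv,
    fold_bn,
    fuse_branches,
    fuse_repconv,
    identity_to_3x3,
    pad_1x1_to_3x3,
    silu,
)


def random_kernel(rng, cout, cin, k, stride=1, dtype=np.float64, bias=True):
    return ConvKernel(
        rng.normal(size=(cout, cin, k, k)).astype(dtype),
        rng.normal(size=cout).astype(dtype) if bias else None,
        stride=stride,
    )


def random_bn(rng, c, dtype=np.float64, eps=1e-3):
    return BNParams(
        rng.normal(size=c).astype(dtype),
        rng.uniform(0.2, 2.0, c).astype(dtype),
        rng.normal(size=c).astype(dtype),
        rng.normal(size=c).astype(dtype),
        eps=eps,
    )


# ------------------------------------------------------------------- fold_bn
class TestFoldBN:
    def test_identity_bn_is_noop(self):
        k = ConvKernel(np.full((1, 1, 1, 1), 2.5), np.zeros(1))
        out = fold_bn(k, BNParams([0.0], [1.0], [1.0], [0.0], eps=1e-30))
        np.testing.assert_allclose(out.weights, k.weights)
        np.testing.assert_allclose(out.bias, [0.0])

    def test_hand_example(self):
        # scale = gamma/sqrt(var) = 3/2; w' = 2*1.5 = 3; b' = 1 + (0-4)*1.5 = -5
        k = ConvKernel(np.full((1, 1, 1, 1), 2.0), np.zeros(1))
        bn = BNParams([4.0], [4.0], [3.0], [1.0], eps=1e-30)
        out = fold_bn(k, bn)
        np.testing.assert_allclose(out.weights, [[[[3.0]]]])
        np.testing.assert_allclose(out.bias, [-5.0], atol=1e-9)
        # cross-check by composing conv then normalization on a random input
        x = np.random.default_rng(0).normal(size=(1, 1, 4, 4))
        np.testing.assert_allclose(out.apply(x), bn.apply(k.apply(x)), atol=1e-9)

    def test_direct_composition_oracle_float32(self):
        rng = np.random.default_rng(1)
        k = random_kernel(rng, 5, 3, 3, dtype=np.float32)
        bn = random_bn(rng, 5, dtype=np.float32)
        fused = fold_bn(k, bn)
        worst = 0.0
        for _ in range(100):
            x = rng.normal(size=(1, 3, 8, 8)).astype(np.float32)
            worst = max(worst, np.abs(bn.apply(k.apply(x)) - fused.apply(x)).max())
        assert worst <= 1e-5

    def test_channel_mismatch_raises(self):
        k = ConvKernel(np.zeros((2, 1, 1, 1)))
        with pytest.raises(ValueError, match="channel mismatch"):
            fold_bn(k, BNParams([0.0], [1.0], [1.0], [0.0]))

    def test_idempotent_under_identity_bn(self):
        rng = np.random.default_rng(2)
        k = random_kernel(rng, 4, 4, 3)
        ident = BNParams.identity(4)
        once = fold_bn(k, ident)
        twice = fold_bn(once, ident)
        np.testing.assert_allclose(once.weights, twice.weights, atol=1e-12)


# ------------------------------------------------------------ pad / identity
class TestPadAndIdentity:
    def test_scalar_placement(self):
        out = pad_1x1_to_3x3(ConvKernel(np.full((1, 1, 1, 1), 5.0)))
        expect = np.zeros((3, 3))
        expect[1, 1] = 5.0
        np.testing.assert_array_equal(out.weights[0, 0], expect)

    def test_zero_kernel(self):
        out = pad_1x1_to_3x3(ConvKernel(np.zeros((2, 3, 1, 1))))
        assert not out.weights.any()

    def test_conv_equivalence_oracle(self):
        rng = np.random.default_rng(3)
        k = random_kernel(rng, 4, 6, 1)
        padded = pad_1x1_to_3x3(k)
        x = rng.normal(size=(2, 6, 7, 7))
        np.testing.assert_allclose(padded.apply(x), k.apply(x), atol=1e-10)

    def test_rejects_3x3(self):
        with pytest.raises(ValueError, match="1x1"):
            pad_1x1_to_3x3(ConvKernel(np.zeros((1, 1, 3, 3))))

    def test_identity_kernel_is_identity(self):
        rng = np.random.default_rng(4)
        k = identity_to_3x3(4)
        x = rng.normal(size=(1, 4, 5, 5))
        np.testing.assert_allclose(k.apply(x), x, atol=1e-12)

    def test_identity_with_bn_scales(self):
        k = identity_to_3x3(1, BNParams([0.0], [1.0], [2.0], [0.0], eps=1e-30))
        x = np.random.default_rng(5).normal(size=(1, 1, 4, 4))
        np.testing.assert_allclose(k.apply(x), 2.0 * x, atol=1e-9)

    def test_off_center_zero(self):
        k = identity_to_3x3(6)
        off = k.weights.copy()
        off[:, :, 1, 1] = 0.0
        assert not off.any()


# ---------------------------------------------------------------------- silu
class TestSiLU:
    def test_zero(self):
        assert silu(0.0) == 0.0

    def test_asymptote(self):
        assert abs(silu(20.0) - 20.0) <= 1e-7

    def test_unit_value(self):
        assert abs(silu(1.0) - 1.0 / (1.0 + np.exp(-1.0))) < 1e-9
        assert abs(silu(1.0) - 0.731059) < 1e-6

    def test_array(self):
        x = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(silu(x), x / (1 + np.exp(-x)), atol=1e-12)


# ------------------------------------------------------------------- RepConv
def randomized_repconv(rng, cin, cout, stride):
    block = RepConv(cin, cout, stride=stride, rng=rng)
    for bn in (block.bn3, block.bn1, block.bn_id):
        if bn is None:
            continue
        bn.running_mean = rng.normal(size=cout).astype(np.float32)
        bn.running_var = rng.uniform(0.2, 2.0, cout).astype(np.float32)
        bn.gamma.data = rng.normal(size=cout).astype(np.float32)
        bn.beta.data = rng.normal(size=cout).astype(np.float32)
    block.eval()
    return block


class TestRepConvFusion:
    def test_zero_block_fuses_to_zero(self):
        block = RepConv(4, 4, rng=np.random.default_rng(0))
        block.conv3.weight.data[:] = 0
        block.conv1.weight.data[:] = 0
        block.bn3.gamma.data[:] = 1
        block.bn1.gamma.data[:] = 1
        block.bn_id = None
        block.eval()
        block.fuse()
        assert not block.fused.conv.weight.data.any()
        x = np.random.default_rng(1).normal(size=(1, 4, 6, 6)).astype(np.float32)
        with ag.no_grad():
            out = block(Tensor(x)).data
        np.testing.assert_array_equal(out, np.zeros_like(out))

    def test_train_deploy_equivalence_8ch(self):
        rng = np.random.default_rng(7)
        block = randomized_repconv(rng, 8, 8, 1)
        x = rng.normal(size=(1, 8, 16, 16)).astype(np.float32)
        with ag.no_grad():
            before = block(Tensor(x)).data
        block.fuse()
        with ag.no_grad():
            after = block(Tensor(x)).data
        assert np.abs(before - after).max() <= 1e-4

    def test_fused_has_fewer_params(self):
        for cin, cout in [(4, 4), (8, 16), (16, 8)]:
            block = RepConv(cin, cout, stride=2, rng=np.random.default_rng(0))
            before = block.num_params()
            block.fuse()
            assert block.num_params() < before

    def test_refusing_warns(self):
        block = RepConv(4, 4, rng=np.random.default_rng(0))
        block.fuse()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fuse_repconv(block)
        assert any("already fused" in str(w.message) for w in caught)

    def test_deploy_forward_single_conv(self):
        block = randomized_repconv(np.random.default_rng(8), 4, 4, 1)
        x = np.zeros((1, 4, 5, 5), dtype=np.float32)
        start = ag.CONV_CALLS
        with ag.no_grad():
            block(Tensor(x))
        train_calls = ag.CONV_CALLS - start
        block.fuse()
        start = ag.CONV_CALLS
        with ag.no_grad():
            block(Tensor(x))
        assert ag.CONV_CALLS - start == 1
        assert train_calls > 1

    def test_identity_requires_matching_channels(self):
        with pytest.raises(ValueError, match="identity"):
            RepConv(4, 8, identity=True)


# --------------------------------------------------- equivalence property
def multibranch_oracle(k3, bn3, k1, bn1, bn_id, x):
    """Independent float64 composition of the three branches + SiLU."""
    y = bn3.apply(k3.apply(x)) + bn1.apply(k1.apply(x))
    if bn_id is not None:
        y = y + bn_id.apply(x)
    return y * (1.0 / (1.0 + np.exp(-np.clip(y, -60, 60))))


@pytest.mark.parametrize("dtype,tol", [(np.float32, 1e-4), (np.float64, 1e-9)])
def test_fusion_equivalence_200_random_blocks(dtype, tol):
    """Algebraic route vs direct multi-branch composition, both precisions."""
    rng = np.random.default_rng(99)
    worst = 0.0
    for trial in range(200):
        c = int(rng.choice([4, 8, 16]))
        stride = int(rng.choice([1, 2]))
        with_id = stride == 1 and bool(rng.integers(2))
        k3 = random_kernel(rng, c, c, 3, stride, dtype)
        k1 = ConvKernel(
            rng.normal(size=(c, c, 1, 1)).astype(dtype), None, stride=stride, padding=0
        )
        bn3, bn1 = random_bn(rng, c, dtype), random_bn(rng, c, dtype)
        bn_id = random_bn(rng, c, dtype) if with_id else None
        fused = fuse_branches(k3, bn3, k1, bn1, bn_id)
        x = rng.normal(size=(1, c, 10, 10)).astype(dtype)
        expect = multibranch_oracle(k3, bn3, k1, bn1, bn_id, x)
        got = fused.apply(x)
        got = got * (1.0 / (1.0 + np.exp(-np.clip(got, -60, 60))))  # SiLU on the fused path
        worst = max(worst, float(np.abs(expect - got).max()))
    assert worst <= tol, f"worst discrepancy {worst}"


# --------------------------------------------------------------------- RepC3
class TestRepC3:
    def test_shape_contract(self):
        rng = np.random.default_rng(0)
        block = RepC3(64, 64, rng=rng)
        block.eval()
        x = rng.normal(size=(1, 64, 40, 40)).astype(np.float32)
        with ag.no_grad():
            out = block(Tensor(x))
        assert out.shape == (1, 64, 40, 40)

    def test_zero_weights_zero_output(self):
        block = RepC3(8, 8, rng=np.random.default_rng(0))
        for p in block.parameters():
            p.data[:] = 0
        block.eval()
        x = np.random.default_rng(1).normal(size=(1, 8, 6, 6)).astype(np.float32)
        with ag.no_grad():
            out = block(Tensor(x)).data
        np.testing.assert_array_equal(out, np.zeros_like(out))

    def test_channel_mismatch(self):
        block = RepC3(8, 8, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            block(Tensor(np.zeros((1, 4, 6, 6), dtype=np.float32)))

    def test_fused_matches_train_mode(self):
        rng = np.random.default_rng(11)
        block = RepC3(16, 16, rng=rng)
        for rep in block.reps:
            h = rep.cout
            for bn in (rep.bn3, rep.bn1, rep.bn_id):
                bn.running_mean = rng.normal(size=h).astype(np.float32) * 0.1
                bn.running_var = rng.uniform(0.5, 1.5, h).astype(np.float32)
        block.eval()
        x = rng.normal(size=(1, 16, 12, 12)).astype(np.float32)
        with ag.no_grad():
            before = block(Tensor(x)).data
        block.fuse()
        with ag.no_grad():
            after = block(Tensor(x)).data
        assert np.abs(before - after).max() <= 1e-4

    def test_three_repeats(self):
        assert len(RepC3(8, 8, rng=np.random.default_rng(0)).reps) == 3
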