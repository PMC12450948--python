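"""Structural reparameterization: BN folding, branch fusion, equivalence."""

import numpy as np
import pytest

from maizedet.backbone import (
    BackboneConfig, ConvBNActSpec, RepConv, RepHGBackbone, StageSpec,
    build_backbone, fold_bn_into_conv, fuse_repconv, identity_to_kernel,
    pad_1x1_to_3x3, reparameterize, spec_of,
)
from maizedet.metrics import count_params
from maizedet.nn import ConvBNAct, Tensor, no_grad
from maizedet.nn.tensor import conv2d


def _random_spec(rng, cin=4, cout=6, k=3, bias=False):
    # kernel scaled so activations stay O(1): the 1e-5 max-abs contract is
    # stated for unit-scale features in 32-bit arithmetic
    return ConvBNActSpec(
        W=(0.2 * rng.normal(size=(cout, cin, k, k))).astype(np.float32),
        b=rng.normal(size=cout).astype(np.float32) if bias else None,
        gamma=rng.uniform(0.5, 2, cout).astype(np.float32),
        beta=rng.normal(size=cout).astype(np.float32),
        mean=rng.normal(size=cout).astype(np.float32),
        var=rng.uniform(0.5, 2, cout).astype(np.float32),
        eps=1e-5,
    )


class TestBNFolding:
    def test_identity_bn_returns_conv_unchanged(self, rng):
        w = rng.normal(size=(6, 4, 3, 3)).astype(np.float32)
        b = rng.normal(size=6).astype(np.float32)
        spec = ConvBNActSpec(W=w, b=b, gamma=np.ones(6, np.float32),
                             beta=np.zeros(6, np.float32), mean=np.zeros(6, np.float32),
                             var=np.ones(6, np.float32), eps=0.0)
        wf, bf = fold_bn_into_conv(spec)
        assert np.allclose(wf, w) and np.allclose(bf, b)

    def test_pure_scale_shift(self):
        w = np.ones((2, 1, 1, 1), np.float32)
        spec = ConvBNActSpec(W=w, b=None, gamma=np.full(2, 2, np.float32),
                             beta=np.full(2, 3, np.float32), mean=np.zeros(2, np.float32),
                             var=np.ones(2, np.float32), eps=0.0)
        wf, bf = fold_bn_into_conv(spec)
        assert np.allclose(wf, 2 * w) and np.allclose(bf, 3.0)

    def test_fused_equals_sequential_conv_bn(self, rng):
        """Oracle: conv -> eval-mode BN vs the single folded conv."""
        spec = _random_spec(rng)
        wf, bf = fold_bn_into_conv(spec)
        for _ in range(10):
            x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
            y_seq = None
            raw = conv2d(Tensor(x), Tensor(spec.W), None, 1, 1).data
            y_seq = (spec.gamma[:, None, None] * (raw[0] - spec.mean[:, None, None])
                     / np.sqrt(spec.var + spec.eps)[:, None, None]
                     + spec.beta[:, None, None])
            y_fused = conv2d(Tensor(x), Tensor(wf), Tensor(bf), 1, 1).data[0]
            assert np.abs(y_seq - y_fused).max() < 1e-5

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            ConvBNActSpec(W=np.zeros((4, 2, 3, 3), np.float32), b=None,
                          gamma=np.ones(3, np.float32), beta=np.zeros(3, np.float32),
                          mean=np.zeros(3, np.float32), var=np.ones(3, np.float32))


class TestKernelConversions:
    def test_pad_scalar_kernel(self):
        w1 = np.array([[[[2.5]]]], np.float32)
        w3 = pad_1x1_to_3x3(w1)
        assert w3.shape == (1, 1, 3, 3)
        assert w3[0, 0, 1, 1] == 2.5 and np.count_nonzero(w3) == 1
        assert np.array_equal(pad_1x1_to_3x3(np.zeros((2, 3, 1, 1), np.float32)),
                              np.zeros((2, 3, 3, 3)))

    def test_padded_conv_equals_pointwise_conv(self, rng):
        w1 = rng.normal(size=(5, 3, 1, 1)).astype(np.float32)
        x = Tensor(rng.normal(size=(2, 3, 7, 7)).astype(np.float32))
        y1 = conv2d(x, Tensor(w1), None, 1, 0).data
        y3 = conv2d(x, Tensor(pad_1x1_to_3x3(w1)), None, 1, 1).data
        assert np.abs(y1 - y3).max() < 1e-6

    def test_pad_rejects_non_1x1(self, rng):
        with pytest.raises(ValueError):
            pad_1x1_to_3x3(rng.normal(size=(2, 2, 3, 3)))

    def test_identity_kernel_is_identity_map(self, rng):
        k = identity_to_kernel(1)
        assert k.shape == (1, 1, 3, 3) and k[0, 0, 1, 1] == 1 and k.sum() == 1
        k4 = identity_to_kernel(4)
        x = Tensor(rng.normal(size=(2, 4, 6, 6)).astype(np.float32))
        assert np.array_equal(conv2d(x, Tensor(k4), None, 1, 1).data, x.data)

    def test_identity_branch_composed_with_bn_equals_bn(self, rng):
        """Dirac kernel + folded BN stats == standalone BN on random inputs."""
        c = 4
        gamma = rng.uniform(0.5, 2, c).astype(np.float32)
        beta = rng.normal(size=c).astype(np.float32)
        mean = rng.normal(size=c).astype(np.float32)
        var = rng.uniform(0.5, 2, c).astype(np.float32)
        spec = ConvBNActSpec(W=identity_to_kernel(c), b=None, gamma=gamma,
                             beta=beta, mean=mean, var=var, eps=1e-5)
        wf, bf = fold_bn_into_conv(spec)
        x = rng.normal(size=(1, c, 5, 5)).astype(np.float32)
        via_conv = conv2d(Tensor(x), Tensor(wf), Tensor(bf), 1, 1).data[0]
        direct = (gamma[:, None, None] * (x[0] - mean[:, None, None])
                  / np.sqrt(var + 1e-5)[:, None, None] + beta[:, None, None])
        assert np.abs(via_conv - direct).max() < 1e-6


def _exercise_bn_stats(module, rng, cin, n=3):
    """Run a few train-mode batches so running statistics are non-trivial."""
    module.train()
    for _ in range(n):
        module(Tensor(rng.normal(size=(2, cin, 8, 8)).astype(np.float32)))
    module.eval()


class TestRepConvFusion:
    def test_single_branch_identity_bn(self, rng):
        rc = RepConv(3, 5, rng=rng)
        # zero out the non-3x3 branches and make BN the identity
        rc.pointwise.conv.weight.data[:] = 0
        bn3 = rc.dense.bn
        bn3.gamma.data[:] = 1; bn3.beta.data[:] = 0
        bn3.running_mean[:] = 0; bn3.running_var[:] = 1 - bn3.eps
        w, b = fuse_repconv(rc)
        assert np.allclose(w, rc.dense.conv.weight.data, atol=1e-6)

    def test_fused_matches_branch_sum(self, rng):
        rc = RepConv(4, 4, rng=rng)  # identity branch present
        _exercise_bn_stats(rc, rng, 4)
        xs = [rng.normal(size=(1, 4, 9, 9)).astype(np.float32) for _ in range(10)]
        with no_grad():
            before = [rc(Tensor(x)).data for x in xs]
        rc.fuse()
        with no_grad():
            after = [rc(Tensor(x)).data for x in xs]
        for a, b in zip(before, after):
            assert np.abs(a - b).max() <= 1e-5

    def test_fusion_reduces_parameters_and_is_idempotent(self, rng):
        rc = RepConv(4, 4, rng=rng)
        n_before = count_params(rc).total_params
        rc.fuse()
        n_after = count_params(rc).total_params
        assert n_after < n_before
        w1 = rc.fused_conv.weight.data.copy()
        rc.fuse()  # no-op
        assert np.array_equal(rc.fused_conv.weight.data, w1)


class TestBackbone:
    def test_stride_pyramid_shapes(self, rng):
        bb = build_backbone(rng=rng)
        bb.eval()
        with no_grad():
            p3, p4, p5 = bb(Tensor(rng.normal(size=(1, 3, 128, 128)).astype(np.float32)))
        assert p3.shape[-2:] == (16, 16)
        assert p4.shape[-2:] == (8, 8)
        assert p5.shape[-2:] == (4, 4)
        assert tuple(s.stride for s in bb.out_specs) == (8, 16, 32)
        assert p3.shape[1] == bb.out_specs[0].channels

    def test_degenerate_single_block_config(self, rng):
        cfg = BackboneConfig(stem_mid=8, stem_out=8, stages=[
            StageSpec(8, 16, 1, 1, False), StageSpec(8, 16, 1, 1, True),
            StageSpec(8, 16, 1, 1, True), StageSpec(8, 16, 1, 1, True)])
        bb = build_backbone(cfg, rng=rng)
        bb.eval()
        with no_grad():
            feats = bb(Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32)))
        assert len(feats) == 3

    def test_deploy_mode_builds_fused(self, rng):
        bb = build_backbone(mode="deploy", rng=rng)
        assert all(rc.fused for rc in bb.modules() if isinstance(rc, RepConv))
        with pytest.raises(ValueError):
            build_backbone(mode="banana")

    def test_reparameterize_whole_backbone_equivalence(self, rng):
        bb = build_backbone(rng=rng)
        for m in bb.modules():
            if isinstance(m, RepConv):
                _exercise_bn_stats(m, rng, m.cin, n=1)
        bb.eval()
        xs = [rng.normal(size=(1, 3, 64, 64)).astype(np.float32) for _ in range(3)]
        with no_grad():
            before = [np.concatenate([f.data.ravel() for f in bb(Tensor(x))]) for x in xs]
        n_before = count_params(bb).total_params
        reparameterize(bb)
        n_after = count_params(bb).total_params
        with no_grad():
            after = [np.concatenate([f.data.ravel() for f in bb(Tensor(x))]) for x in xs]
        assert n_after < n_before
        for a, b in zip(before, after):
            assert np.abs(a - b).max() <= 1e-5
        # idempotent
        reparameterize(bb)
        assert count_params(bb).total_params == n_after
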