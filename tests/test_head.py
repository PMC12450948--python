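"""Detection heads: DFL decoding, deformable alignment, weight sharing."""

import numpy as np
import pytest

from maizedet.head import (
    DecoupledHead, TDADH, build_head, dfl_decode, dfl_expectation,
    dynamic_deform_conv,
)
from maizedet.metrics import count_params
from maizedet.nn import Tensor, no_grad
from maizedet.nn.tensor import conv2d


class TestDFL:
    def test_one_hot_bin(self):
        logits = np.full((4, 16), -20.0, np.float32)
        logits[:, 3] = 20.0
        x1, y1, x2, y2 = dfl_decode(logits, stride=1, scale=1.0, anchor_point=(10, 10))
        assert x1 == pytest.approx(10 - 3, abs=1e-4)
        assert y2 == pytest.approx(10 + 3, abs=1e-4)

    def test_uniform_logits_give_midpoint(self):
        logits = np.zeros((4, 16), np.float32)
        x1, _, x2, _ = dfl_decode(logits, stride=1, scale=1.0, anchor_point=(0, 0))
        assert -x1 == pytest.approx(7.5) and x2 == pytest.approx(7.5)

    def test_matches_brute_force_expectation(self, rng):
        logits = rng.normal(size=(5, 4, 16)).astype(np.float32)
        exp = dfl_expectation(Tensor(logits), 16).data
        # independent oracle: direct sum over bins
        z = np.exp(logits - logits.max(-1, keepdims=True))
        p = z / z.sum(-1, keepdims=True)
        oracle = (p * np.arange(16)).sum(-1)
        assert np.abs(exp - oracle).max() < 1e-6
        assert (exp >= 0).all() and (exp <= 15).all()

    def test_scale_and_stride_multiply_distance(self):
        logits = np.zeros((4, 16), np.float32)
        x1a, *_ = dfl_decode(logits, stride=8, scale=1.0, anchor_point=(100, 100))
        x1b, *_ = dfl_decode(logits, stride=8, scale=0.5, anchor_point=(100, 100))
        assert (100 - x1a) == pytest.approx(2 * (100 - x1b))

    def test_monotone_in_larger_bin_logit(self, rng):
        logits = rng.normal(size=(1, 16)).astype(np.float32)
        base = dfl_expectation(Tensor(logits), 16).data[0]
        bumped = logits.copy()
        bumped[0, 12] += 1.0  # bin 12 is above the current expectation? ensure larger
        k = int(np.ceil(base))
        bumped = logits.copy()
        bumped[0, min(k + 1, 15)] += 1.0
        assert dfl_expectation(Tensor(bumped), 16).data[0] >= base


class TestDeformConv:
    def test_zero_offsets_unit_mask_is_plain_conv(self, rng):
        x = Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))
        w = Tensor(rng.normal(size=(5, 4, 3, 3)).astype(np.float32))
        off = Tensor(np.zeros((1, 18, 6, 6), np.float32))
        mask = Tensor(np.ones((1, 9, 6, 6), np.float32))
        with no_grad():
            y = dynamic_deform_conv(x, off, mask, w)
            y_ref = conv2d(x, w, None, 1, 1)
        assert np.abs(y.data - y_ref.data).max() < 1e-5

    def test_zero_mask_gives_bias_only(self, rng):
        x = Tensor(rng.normal(size=(1, 4, 5, 5)).astype(np.float32))
        w = Tensor(rng.normal(size=(3, 4, 3, 3)).astype(np.float32))
        b = Tensor(np.array([1.0, -2.0, 0.5], np.float32))
        with no_grad():
            y = dynamic_deform_conv(x, Tensor(np.zeros((1, 18, 5, 5), np.float32)),
                                    Tensor(np.zeros((1, 9, 5, 5), np.float32)), w, b)
        assert np.allclose(y.data, b.data[None, :, None, None], atol=1e-6)

    def test_integer_shift_reproduces_translated_response(self, rng):
        """Shifting every tap by (dx=1, dy=0) on a 1-px-translated image
        reproduces the untranslated response in the valid interior."""
        img = rng.normal(size=(1, 2, 8, 8)).astype(np.float32)
        shifted = np.roll(img, shift=-1, axis=3)  # content moves left by 1
        w = Tensor(rng.normal(size=(3, 2, 3, 3)).astype(np.float32))
        zero_off = Tensor(np.zeros((1, 18, 8, 8), np.float32))
        ones = Tensor(np.ones((1, 9, 8, 8), np.float32))
        off = np.zeros((1, 18, 8, 8), np.float32)
        off[:, 1::2] = 1.0  # (dy, dx) per tap: dx = +1
        with no_grad():
            y_ref = dynamic_deform_conv(Tensor(shifted), zero_off, ones, w).data
            y_shift = dynamic_deform_conv(Tensor(img), Tensor(off), ones, w).data
        interior = (slice(None), slice(None), slice(2, 6), slice(2, 6))
        assert np.abs(y_ref[..., :, :7][interior] - y_shift[..., :, :7][interior]).max() < 1e-4

    def test_channel_mismatch_raises(self, rng):
        x = Tensor(np.zeros((1, 4, 5, 5), np.float32))
        w = Tensor(np.zeros((3, 4, 3, 3), np.float32))
        with pytest.raises(ValueError):
            dynamic_deform_conv(x, Tensor(np.zeros((1, 10, 5, 5), np.float32)),
                                Tensor(np.zeros((1, 9, 5, 5), np.float32)), w)


class TestSharedHead:
    def test_output_channels(self, rng):
        head = build_head((64, 64, 64), num_classes=1, reg_max=16, width=64, rng=rng)
        head.eval()
        feats = [Tensor(rng.normal(size=(1, 64, s, s)).astype(np.float32))
                 for s in (8, 4, 2)]
        with no_grad():
            cls_out, reg_out = head(feats)
        assert [c.shape[1] for c in cls_out] == [1, 1, 1]
        assert [r.shape[1] for r in reg_out] == [64, 64, 64]

    def test_shared_conv_mutation_visible_at_all_levels(self, rng):
        head = build_head((64, 64, 64), width=64, rng=rng)
        head.eval()
        feats = [Tensor(rng.normal(size=(1, 64, s, s)).astype(np.float32))
                 for s in (8, 4, 2)]
        with no_grad():
            _, reg_before = head(feats)
            head.conv_reg.weight.data += 0.5
            _, reg_after = head(feats)
        for b, a in zip(reg_before, reg_after):
            assert np.abs(b.data - a.data).max() > 1e-4

    def test_serialized_head_has_single_shared_copy(self, rng):
        head = build_head((64, 64, 64), width=64, rng=rng)
        names = [k for k, _ in head.named_parameters()]
        assert sum("conv_reg" in n and "weight" in n for n in names) == 1
        assert sum("shared1.conv" in n for n in names) == 1

    def test_fewer_params_than_decoupled_head(self, rng):
        shared = build_head((64, 128, 256), width=96, shared=True, rng=rng)
        decoupled = build_head((64, 128, 256), shared=False, rng=rng)
        assert count_params(shared).total_params < count_params(decoupled).total_params

    def test_scale_per_level_initialized_to_one(self, rng):
        head = build_head((64, 64, 64), width=64, rng=rng)
        assert head.scale_values() == [1.0, 1.0, 1.0]
        assert len(head.scales) == 3

    def test_width_not_divisible_by_groups_raises(self, rng):
        with pytest.raises(ValueError):
            build_head((64, 64, 64), width=60, gn_groups=16, rng=rng)

    def test_layer_attention_one_hot_selects_single_layer(self, rng):
        head = TDADH((64, 64, 64), width=64, rng=rng)
        head.eval()
        x = Tensor(rng.normal(size=(1, 64, 6, 6)).astype(np.float32))
        with no_grad():
            xp = head.proj[0](x)
            f1, f2, inter = head.interaction(xp)
            # force the attention logits to a one-hot on layer 0
            head.cls_att[0].weight.data[:] = 0
            head.cls_att[0].bias.data[:] = np.array([40.0, -40.0], np.float32)
            out = head.task_decompose(f1, f2, inter, head.cls_att)
        assert np.abs(out.data - f1.data).max() < 1e-4

    def test_layer_attention_uniform_is_layer_mean(self, rng):
        head = TDADH((64, 64, 64), width=64, rng=rng)
        head.eval()
        x = Tensor(rng.normal(size=(1, 64, 6, 6)).astype(np.float32))
        with no_grad():
            xp = head.proj[0](x)
            f1, f2, inter = head.interaction(xp)
            head.cls_att[0].weight.data[:] = 0
            head.cls_att[0].bias.data[:] = 40.0  # sigmoid -> (1, 1)
            out = head.task_decompose(f1, f2, inter, head.cls_att)
        assert np.abs(out.data - (f1.data + f2.data)).max() < 1e-4

    def test_gradient_reaches_offset_and_mask_generator(self, rng):
        head = TDADH((32, 32, 32), width=32, rng=rng)
        head.train()
        feats = [Tensor(rng.normal(size=(1, 32, s, s)).astype(np.float32))
                 for s in (8, 4, 2)]
        _, reg_out = head(feats)
        loss = sum((r * r).mean() for r in reg_out)
        loss.backward()
        assert head.offset_mask.weight.grad is not None
        assert np.abs(head.offset_mask.weight.grad).sum() > 0
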