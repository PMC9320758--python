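"""Four-view model: shared embeddings, local/global stacks, head,
parameter accounting and checkpoint import/export."""

import numpy as np
import pytest

import mvtmammo as m
from mvtmammo._tensor import Tensor
from mvtmammo.multiview_model import extract_patches
from mvtmammo.transformer_core import transformer_block_forward


def toy_model(**overrides):
    return m.MultiViewTransformer(m.make_config("toy", **overrides), seed=7)


def random_case(side=32, n_views=4, seed=0):
    r = np.random.default_rng(seed)
    return r.normal(size=(n_views, side, side, 3)).astype(np.float32)


class TestEmbeddings:
    @pytest.mark.parametrize("side,patch,expected_len", [
        (224, 16, 197),
        (32, 8, 17),
    ])
    def test_sequence_length(self, side, patch, expected_len):
        cfg = m.MVTConfig(image_side=side, patch_size=patch, d_embed=32, n_heads=2,
                          depth_total=2, n_local=1, n_global=1)
        model = m.MultiViewTransformer(cfg, seed=0)
        seq = model.embed_views(random_case(side)[None])
        assert seq.shape == (1, 4, expected_len, 32)

    def test_class_token_shared_across_views_at_init(self):
        model = toy_model()
        seq = model.embed_views(random_case()[None]).data[0]
        for v in range(1, 4):
            assert np.array_equal(seq[0, 0], seq[v, 0])

    def test_indivisible_side_rejected(self):
        with pytest.raises(ValueError):
            m.MVTConfig(image_side=30, patch_size=16)

    def test_patch_flatten_order_matches_conv_weight_layout(self):
        # One white pixel at (r, c) of channel k must excite exactly the
        # weight entry a (d, C, P, P) conv would use.
        img = np.zeros((1, 1, 8, 8, 3), dtype=np.float32)
        img[0, 0, 2, 5, 1] = 1.0
        patches = extract_patches(img, 4)  # 2x2 grid of 4x4 patches
        assert patches.shape == (1, 1, 4, 48)
        # pixel (2,5) lives in patch row 0, col 1 -> patch index 1
        nz = np.nonzero(patches[0, 0])
        assert nz[0].tolist() == [1]
        # flat offset = channel*P*P + local_r*P + local_c = 1*16 + 2*4 + 1
        assert nz[1].tolist() == [1 * 16 + 2 * 4 + 1]


class TestLocalGlobalStacks:
    def test_empty_local_stack_is_identity(self):
        model = toy_model(n_local=0, n_global=4)
        seq = model.embed_views(random_case()[None])
        assert np.array_equal(model.forward_local(seq).data, seq.data)

    def test_weight_sharing_makes_view_permutation_equivariant(self):
        model = toy_model()
        x = random_case()
        perm = [2, 0, 3, 1]
        out = model.forward_local(model.embed_views(x[None])).data[0]
        out_p = model.forward_local(model.embed_views(x[perm][None])).data[0]
        assert np.allclose(out[perm], out_p, atol=1e-5)

    def test_batched_views_equal_sequential_processing(self):
        model = toy_model()
        x = random_case()
        batched = model.forward_local(model.embed_views(x[None])).data[0]
        for v in range(4):
            seq = model.embed_views(x[v][None, None])
            single = model.forward_local(seq).data[0, 0]
            assert np.allclose(batched[v], single, atol=1e-5)

    @pytest.mark.parametrize("seq_len,expected", [(197, 788), (17, 68)])
    def test_concat_length_is_4n_plus_4(self, seq_len, expected):
        seqs = Tensor(np.random.default_rng(0).normal(size=(1, 4, seq_len, 8)))
        assert m.MultiViewTransformer.concat_views(seqs).shape == (1, expected, 8)

    def test_concat_starts_with_first_view(self):
        seqs = Tensor(np.random.default_rng(0).normal(size=(1, 4, 17, 8)))
        out = m.MultiViewTransformer.concat_views(seqs)
        assert np.array_equal(out.data[0, :17], seqs.data[0, 0])

    def test_empty_global_stack_is_identity(self):
        model = toy_model(n_local=4, n_global=0)
        seq = Tensor(np.random.default_rng(0).normal(size=(1, 68, 32)))
        assert np.array_equal(model.forward_global(seq).data, seq.data)

    def test_single_global_block_equals_block_forward(self):
        model = toy_model(n_local=3, n_global=1)
        seq = np.random.default_rng(0).normal(size=(1, 68, 32)).astype(np.float32)
        expected = transformer_block_forward(seq, model.global_blocks[0])
        assert np.allclose(model.forward_global(Tensor(seq)).data, expected, atol=1e-6)


class TestClassification:
    def test_zero_head_ties_resolve_to_benign(self):
        model = toy_model()
        model.w_head.data[:] = 0
        model.b_head.data[:] = 0
        pred = model.predict_case(random_case())
        assert np.allclose(pred.probabilities, [0.5, 0.5])
        assert pred.predicted_class == "benign"

    def test_softmax_closed_form(self):
        logits = np.array([2.0, 2.0 + np.log(3.0)])
        p = np.exp(logits - logits.max())
        p /= p.sum()
        assert p[1] == pytest.approx(0.75, abs=1e-9)
        model = toy_model()
        model.w_head.data[:] = 0
        model.b_head.data[:] = logits
        pred = model.predict_case(random_case())
        assert pred.probabilities[1] == pytest.approx(0.75, abs=1e-5)
        assert pred.predicted_class == "malignant"

    def test_eval_forward_is_deterministic_and_finite(self):
        model = toy_model()
        x = random_case()
        a, b = model.predict_case(x), model.predict_case(x)
        assert np.array_equal(a.logits, b.logits)
        assert np.all(np.isfinite(a.logits))

    def test_probabilities_sum_to_one(self):
        pred = toy_model().predict_case(random_case())
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zeroed_blocks_reduce_to_embeddings_plus_head(self):
        # With every block's output and MLP-out projection zeroed the
        # residual stream passes the embeddings straight to the head.
        model = toy_model()
        for blk in model.local_blocks + model.global_blocks:
            for t in (blk.w_out, blk.b_out, blk.w_fc2, blk.b_fc2):
                t.data[:] = 0
        x = random_case()
        logits = model.forward_batch(x[None]).data[0]
        from mvtmammo._tensor import layer_norm
        seq = model.concat_views(model.embed_views(x[None]))
        normed = layer_norm(seq, model.norm_g, model.norm_b)
        expected = (normed[:, 0, :] @ model.w_head + model.b_head).data[0]
        assert np.allclose(logits, expected, atol=1e-5)

    def test_gradient_flows_from_every_view(self):
        # Rebuild the forward pass with the patch tokens as a leaf so the
        # gradient w.r.t. each view's pixels is observable.
        from mvtmammo._tensor import concat, layer_norm
        model = toy_model()
        cfg = model.config
        pt = Tensor(extract_patches(random_case()[None], cfg.patch_size),
                    requires_grad=True)
        emb = pt @ model.embeddings.w_patch + model.embeddings.b_patch
        lead = emb.shape[:-2]
        cls = model.embeddings.cls_token.reshape(1, cfg.d_embed).broadcast_to(
            (*lead, 1, cfg.d_embed))
        seq = concat([cls, emb], axis=-2) + model.embeddings.pos_embed
        seq = model.forward_global(model.concat_views(model.forward_local(seq)))
        seq = layer_norm(seq, model.norm_g, model.norm_b)
        logits = seq[:, 0, :] @ model.w_head + model.b_head
        logits.sum().backward()
        grads_per_view = np.abs(pt.grad[0]).sum(axis=(1, 2))
        assert np.all(grads_per_view > 0)

    def test_no_global_blocks_swap_symmetry(self):
        # With no global mixing and the mean-of-class-tokens fusion,
        # swapping the left and right breasts permutes the views but
        # cannot change the benign probability at initialization.
        model = toy_model(n_local=4, n_global=0)
        x = random_case()
        swapped = x[[1, 0, 3, 2]]  # LCC<->RCC, LMLO<->RMLO
        p1 = model.predict_case(x).probabilities
        p2 = model.predict_case(swapped).probabilities
        assert np.allclose(p1, p2, atol=1e-5)


class TestParameterAccounting:
    def test_toy_enumeration_example(self):
        cfg = m.MVTConfig(d_embed=8, n_heads=2, depth_total=2, n_local=1,
                          n_global=1, patch_size=4, image_side=8, channels=1)
        assert m.parameter_count_formula(cfg) == 1962
        assert m.count_parameters(cfg) == 1962

    @pytest.mark.parametrize("split", [(0, 12), (2, 10), (4, 8), (8, 4), (12, 0)])
    def test_count_invariant_to_split(self, split):
        base = m.make_config("tiny", n_local=split[0], n_global=split[1])
        assert m.count_parameters(base) == m.parameter_count_formula(base)
        ref = m.make_config("tiny", n_local=2, n_global=10)
        assert m.parameter_count_formula(base) == m.parameter_count_formula(ref)

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            m.make_config("tiny", n_local=5, n_global=5)


class TestCheckpoints:
    def test_roundtrip_preserves_logits(self, tmp_path):
        model = toy_model()
        x = random_case()
        before = model.predict_case(x).logits
        m.save_checkpoint(model, tmp_path / "model.npz")
        loaded = m.load_checkpoint(tmp_path / "model.npz")
        assert np.array_equal(loaded.predict_case(x).logits, before)

    @staticmethod
    def synth_deit_state(d=32, depth=4, patch=8, side=32, seed=0, n_cls=1000):
        r = np.random.default_rng(seed)
        n = (side // patch) ** 2
        state = {
            "cls_token": r.normal(size=(1, 1, d)),
            "pos_embed": r.normal(size=(1, n + 1, d)),
            "patch_embed.proj.weight": r.normal(size=(d, 3, patch, patch)),
            "patch_embed.proj.bias": r.normal(size=(d,)),
            "norm.weight": r.normal(size=(d,)),
            "norm.bias": r.normal(size=(d,)),
            "head.weight": r.normal(size=(n_cls, d)),
            "head.bias": r.normal(size=(n_cls,)),
        }
        for i in range(depth):
            b = f"blocks.{i}."
            state.update({
                b + "norm1.weight": r.normal(size=(d,)),
                b + "norm1.bias": r.normal(size=(d,)),
                b + "attn.qkv.weight": r.normal(size=(3 * d, d)),
                b + "attn.qkv.bias": r.normal(size=(3 * d,)),
                b + "attn.proj.weight": r.normal(size=(d, d)),
                b + "attn.proj.bias": r.normal(size=(d,)),
                b + "norm2.weight": r.normal(size=(d,)),
                b + "norm2.bias": r.normal(size=(d,)),
                b + "mlp.fc1.weight": r.normal(size=(4 * d, d)),
                b + "mlp.fc1.bias": r.normal(size=(4 * d,)),
                b + "mlp.fc2.weight": r.normal(size=(d, 4 * d)),
                b + "mlp.fc2.bias": r.normal(size=(4 * d // 4,)),
            })
        return {k: v.astype(np.float32) for k, v in state.items()}

    def test_block_mapping_splits_local_then_global(self):
        state = self.synth_deit_state()
        cfg = m.make_config("toy", n_local=2, n_global=2)
        model = m.load_pretrained_deit(state, cfg)
        # source block 2 must land on global block 0
        assert np.allclose(model.global_blocks[0].w_qkv.data,
                           state["blocks.2.attn.qkv.weight"].T)
        assert np.allclose(model.local_blocks[1].b_fc1.data,
                           state["blocks.1.mlp.fc1.bias"])
        # head is re-initialized, not imported
        assert model.w_head.data.shape == (32, 2)

    def test_imported_tensors_equal_source_exactly(self):
        state = self.synth_deit_state()
        model = m.load_pretrained_deit(state, m.make_config("toy"))
        assert np.array_equal(model.embeddings.cls_token.data,
                              state["cls_token"].reshape(-1))
        assert np.array_equal(model.norm_g.data, state["norm.weight"])

    def test_mismatched_width_raises_named_error(self):
        state = self.synth_deit_state(d=32)
        cfg = m.MVTConfig(image_side=32, patch_size=8, d_embed=64, n_heads=2,
                          depth_total=4, n_local=1, n_global=3)
        with pytest.raises(m.IncompatibleCheckpointError, match="cls_token"):
            m.load_pretrained_deit(state, cfg)

    def test_position_table_resampled_with_warning(self):
        state = self.synth_deit_state(side=32)  # 17 positions
        cfg = m.make_config("toy", image_side=64)  # 65 positions
        with pytest.warns(UserWarning, match="resampling position"):
            model = m.load_pretrained_deit(state, cfg)
        assert model.embeddings.pos_embed.data.shape == (65, 32)
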