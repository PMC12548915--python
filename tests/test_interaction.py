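"""Compound-CYP interaction block: pseudo-substructure appending, additive
multihead attention, set normalization, the full attention block against a
brute-force oracle, pooling and attention-mass DCI scores."""

import numpy as np
import pytest

from cypdfi.featurize import compute_substructures
from cypdfi.model import (
    AttentionTensor,
    DFIModel,
    ModelConfig,
    dci_scores_from_attention,
    pool_isoenzymes,
)
from cypdfi.nn import Tensor

rng = np.random.default_rng(7)


@pytest.fixture()
def block(tiny_model):
    tiny_model.eval()
    return tiny_model.interaction


class TestAppendPseudo:
    def test_concatenation_layout(self, block):
        hs = Tensor(rng.standard_normal((2, 4, 8)))
        mask = np.ones((2, 4), dtype=bool)
        keys, full_mask = block.append_pseudo(hs, mask)
        assert keys.shape == (2, 4 + 3, 8)
        assert np.array_equal(keys.data[:, :4], hs.data)
        # last n_pseudo rows are the shared global parameters, identical
        # for every compound in the batch
        assert np.array_equal(keys.data[0, 4:], block.pseudo.data)
        assert np.array_equal(keys.data[1, 4:], block.pseudo.data)
        assert full_mask[:, 4:].all()

    def test_default_pseudo_count_is_ten(self, panel):
        model = DFIModel(ModelConfig(h=8, heads=2), panel)
        assert model.interaction.pseudo.shape == (10, 8)


class TestAdditiveAttention:
    def test_identical_keys_give_uniform_rows(self, block):
        key = rng.standard_normal(8)
        kv = Tensor(np.tile(key, (1, 6, 1)))
        q = Tensor(rng.standard_normal((5, 8)))
        _, attn = block.additive_attention(q, kv, np.ones((1, 6), dtype=bool))
        assert np.allclose(attn.data, 1.0 / 6.0, atol=1e-12)

    def test_rows_sum_to_one(self, block):
        kv = Tensor(rng.standard_normal((3, 7, 8)))
        q = Tensor(rng.standard_normal((5, 8)))
        mask = np.ones((3, 7), dtype=bool)
        mask[1, 4:] = False
        _, attn = block.additive_attention(q, kv, mask)
        assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(attn.data[1, :, :, 4:] == 0.0)

    def test_two_key_hand_oracle(self, panel):
        """Additive attention weights equal softmax of v' tanh(Wq q + Wk k)
        computed by hand for a 1-head, 2-key instance."""
        cfg = ModelConfig(h=4, heads=1, n_pseudo=1, dropout=0.0, seed=0)
        block = DFIModel(cfg, panel).eval().interaction
        q = rng.standard_normal((5, 4))
        k = rng.standard_normal((1, 2, 4))
        e = np.tanh((q @ block.Wq.data)[:, None, :] + (k[0] @ block.Wk.data)[None, :, :])
        e = e @ block.v.data[0]  # (5 queries, 2 keys)
        expect = np.exp(e) / np.exp(e).sum(axis=-1, keepdims=True)
        _, attn = block.additive_attention(Tensor(q), Tensor(k), np.ones((1, 2), dtype=bool))
        assert np.allclose(attn.data[0, 0], expect, atol=1e-10)

    def test_all_keys_masked_raises(self, block):
        kv = Tensor(rng.standard_normal((1, 3, 8)))
        q = Tensor(rng.standard_normal((5, 8)))
        with pytest.raises(ValueError):
            block.additive_attention(q, kv, np.zeros((1, 3), dtype=bool))


class TestMabForward:
    def test_output_shape_independent_of_key_count(self, block):
        q = Tensor(rng.standard_normal((5, 8)))
        for L in (1, 4, 9):
            out, _ = block.mab(q, Tensor(rng.standard_normal((2, L, 8))), np.ones((2, L), dtype=bool))
            assert out.shape == (2, 5, 8)

    def test_key_permutation_equivariance(self, block):
        q = Tensor(rng.standard_normal((5, 8)))
        y = rng.standard_normal((1, 6, 8))
        perm = np.array([3, 0, 5, 1, 4, 2])
        mask = np.ones((1, 6), dtype=bool)
        out1, a1 = block.mab(q, Tensor(y), mask)
        out2, a2 = block.mab(q, Tensor(y[:, perm]), mask)
        assert np.allclose(out1.data, out2.data, atol=1e-10)
        assert np.allclose(a1.data[..., perm], a2.data, atol=1e-10)

    def test_brute_force_oracle_three_keys(self, panel):
        """mab matches an independent numpy transcription of the attention
        block (pre-norm additive attention, residual, set-normalized RFF)."""
        cfg = ModelConfig(h=4, heads=2, n_pseudo=1, dropout=0.0, seed=0)
        block = DFIModel(cfg, panel).eval().interaction
        x = rng.standard_normal((5, 4))
        y = rng.standard_normal((1, 3, 4))

        def setnorm(v, gamma, beta):
            mu, var = v.mean(), v.var()
            return ((v - mu) / np.sqrt(var + 1e-5)) * gamma + beta

        xn = setnorm(x, block.norm_q.gamma.data, block.norm_q.beta.data)
        yn = setnorm(y[0], block.norm_k.gamma.data, block.norm_k.beta.data)
        heads, dh = 2, 2
        zs = []
        attn_ref = np.zeros((heads, 5, 3))
        for i in range(heads):
            Wq = block.Wq.data[:, i * dh : (i + 1) * dh]
            Wk = block.Wk.data[:, i * dh : (i + 1) * dh]
            Wv = block.Wv.data[:, i * dh : (i + 1) * dh]
            e = np.tanh((xn @ Wq)[:, None, :] + (yn @ Wk)[None, :, :])  # (5, 3, dh)
            e = e @ block.v.data[i]
            a = np.exp(e) / np.exp(e).sum(axis=-1, keepdims=True)
            attn_ref[i] = a
            zs.append(a @ (yn @ Wv))
        z = np.concatenate(zs, axis=-1) @ block.out_proj.W.data + block.out_proj.b.data
        h1 = x + z
        h1n = setnorm(h1, block.norm_mid.gamma.data, block.norm_mid.beta.data)

        def gelu(v):
            from scipy.special import erf

            return v * 0.5 * (1 + erf(v / np.sqrt(2)))

        rff = gelu(gelu(h1n @ block.rff1.W.data + block.rff1.b.data) @ block.rff2.W.data + block.rff2.b.data)
        expected = h1 + rff

        out, attn = block.mab(Tensor(x), Tensor(y), np.ones((1, 3), dtype=bool))
        assert np.allclose(attn.data[0], attn_ref, atol=1e-5)
        assert np.allclose(out.data[0], expected, atol=1e-5)

    def test_batch_padding_independence(self, tiny_model):
        """A compound's attention rows are identical alone or padded inside a
        batch with a longer compound."""
        tiny_model.eval()
        s_small = compute_substructures("CCO")
        s_big = compute_substructures("CC(=O)Nc1ccc(O)cc1")
        from cypdfi.featurize import build_molecular_graph

        g_small = build_molecular_graph("CCO")
        g_big = build_molecular_graph("CC(=O)Nc1ccc(O)cc1")
        alone = tiny_model.encode_compounds([s_small], [g_small])
        batched = tiny_model.encode_compounds([s_small, s_big], [g_small, g_big])
        L = alone["attention"].shape[-1]
        n_pseudo = tiny_model.cfg.n_pseudo
        a_alone = alone["attention"].data[0]
        a_batched = batched["attention"].data[0]
        # real columns
        assert np.allclose(a_alone[..., : s_small.n], a_batched[..., : s_small.n], atol=1e-10)
        # pseudo columns sit at the tail in both layouts
        assert np.allclose(a_alone[..., -n_pseudo:], a_batched[..., -n_pseudo:], atol=1e-10)
        # padded positions carry exactly zero
        assert np.all(a_batched[..., s_small.n : -n_pseudo] == 0.0)
        assert np.allclose(alone["hi"].data[0], batched["hi"].data[0], atol=1e-10)


class TestPoolingAndScores:
    def test_pool_mean_of_identical_rows(self):
        r = rng.standard_normal(8)
        out = pool_isoenzymes(Tensor(np.tile(r, (5, 1))))
        assert np.allclose(out.data, r)

    def test_pool_hand_arithmetic(self):
        rows = np.zeros((5, 2))
        rows[0] = (1, 0)
        rows[1] = (0, 1)
        assert np.allclose(pool_isoenzymes(Tensor(rows)).data, (0.2, 0.2))

    @pytest.mark.parametrize(
        "real_mass, expected",
        [(0.0, 0.0), (1.0, 1.0)],
    )
    def test_all_mass_extremes(self, real_mass, expected):
        n, n_pseudo = 4, 2
        w = np.zeros((4, 5, n + n_pseudo))
        if real_mass:
            w[:, :, :n] = 1.0 / n
        else:
            w[:, :, n:] = 1.0 / n_pseudo
        scores = dci_scores_from_attention(AttentionTensor(weights=w, n=n)).scores
        assert np.allclose(scores, expected)

    def test_uniform_attention_arithmetic(self):
        n, n_pseudo = 20, 10
        w = np.full((4, 5, n + n_pseudo), 1.0 / (n + n_pseudo))
        scores = dci_scores_from_attention(AttentionTensor(weights=w, n=n)).scores
        assert np.allclose(scores, 20.0 / 30.0)

    def test_score_plus_pseudo_mass_is_one(self, tiny_model):
        tiny_model.eval()
        from cypdfi.featurize import build_molecular_graph

        enc = tiny_model.encode_compounds(
            [compute_substructures("CCO")], [build_molecular_graph("CCO")]
        )
        attn = enc["attention"].data[0]
        n_real = compute_substructures("CCO").n
        real = attn[:2, :, :n_real].sum(axis=-1)
        pseudo = attn[:2, :, n_real:].sum(axis=-1)
        assert np.allclose(real + pseudo, 1.0, atol=1e-6)
        assert np.allclose(enc["dci_scores"].data[0], real, atol=1e-12)


class TestAuxiliaryGradientRouting:
    def test_free_heads_receive_no_auxiliary_gradient(self, tiny_model):
        """Heads 2-3 of the attention projections get exactly zero gradient
        from the auxiliary loss; value/output projections get none at all."""
        from cypdfi.featurize import build_molecular_graph
        from cypdfi.losses import auxiliary_loss

        tiny_model.eval()
        block = tiny_model.interaction
        enc = tiny_model.encode_compounds(
            [compute_substructures("CCO")], [build_molecular_graph("CCO")]
        )
        labels = np.full((1, 2, 5), np.nan)
        labels[0, 0, 1] = 1.0
        labels[0, 1, 3] = 0.0
        loss, n_sup = auxiliary_loss(enc["dci_scores"], labels)
        assert n_sup == 2
        loss.backward()
        h, heads = tiny_model.cfg.h, tiny_model.cfg.heads
        dh = h // heads
        for W in (block.Wq, block.Wk):
            assert W.grad is not None
            assert np.any(W.grad[:, : 2 * dh] != 0.0)
            assert np.all(W.grad[:, 2 * dh :] == 0.0)
        assert np.any(block.v.grad[:2] != 0.0)
        assert np.all(block.v.grad[2:] == 0.0)
        assert block.Wv.grad is None
        assert block.out_proj.W.grad is None
        # the pseudo rows do receive auxiliary gradient
        assert block.pseudo.grad is not None and np.any(block.pseudo.grad != 0.0)
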