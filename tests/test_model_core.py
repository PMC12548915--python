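"""Encoders: substructure MLP, edge-attributed GIN graph encoder, CYP panel
encoder — zero maps, hand-arithmetic oracles, invariances."""

import numpy as np
import pytest

from cypdfi.cyp import CypPanel
from cypdfi.featurize import build_molecular_graph, compute_substructures
from cypdfi.model import DFIModel, ModelConfig
from cypdfi.nn import Tensor


def leaky(x, slope=0.01):
    return np.where(x > 0, x, slope * x)


class TestSubstructureEncoder:
    def test_zero_parameters_give_zero_rows(self, tiny_model):
        enc = tiny_model.substructure_encoder
        enc.proj.W.data[:] = 0.0
        enc.proj.b.data[:] = 0.0
        tiny_model.eval()
        s = compute_substructures("CCO")
        out, mask = enc([s])
        assert np.all(out.data == 0.0)
        assert mask.sum() == s.n

    def test_eval_mode_deterministic(self, tiny_model):
        tiny_model.eval()
        s = compute_substructures("CC(=O)O")
        a, _ = tiny_model.substructure_encoder([s])
        b, _ = tiny_model.substructure_encoder([s])
        assert np.array_equal(a.data, b.data)

    def test_hand_arithmetic_oracle(self, panel):
        # h=2: rows must equal LeakyReLU(x W + b) computed by hand
        cfg = ModelConfig(h=2, heads=2, n_pseudo=1, dropout=0.0, seed=0)
        model = DFIModel(cfg, panel)
        model.eval()
        enc = model.substructure_encoder
        s = compute_substructures("CCO")
        W = np.arange(4 * 2, dtype=float).reshape(4, 2) * 0.1 - 0.3
        b = np.array([0.05, -0.2])
        enc.proj.W.data = W
        enc.proj.b.data = b
        out, _ = enc([s])
        for k, bit in enumerate(s.bits):
            x = enc.table.data[bit]
            assert np.allclose(out.data[0, k], leaky(x @ W + b), atol=1e-12)

    def test_empty_batch_raises(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.substructure_encoder([])


class TestGraphEncoder:
    def test_single_node_graph_equals_node_embedding(self, tiny_model):
        tiny_model.eval()
        g = build_molecular_graph("C")
        out = tiny_model.graph_encoder([g])
        assert out.shape == (1, tiny_model.cfg.h)
        assert np.all(np.isfinite(out.data))

    def test_atom_order_permutation_invariance(self, tiny_model):
        tiny_model.eval()
        # same molecule, different SMILES atom orders survive canonicalization
        a = tiny_model.graph_encoder([build_molecular_graph("OC(C)=O")])
        b = tiny_model.graph_encoder([build_molecular_graph("CC(=O)O")])
        assert np.allclose(a.data, b.data, atol=1e-12)

    def test_one_layer_oracle_on_path_graph(self, panel):
        """One GIN-with-edge-features layer + mean pool, checked against an
        independent numpy computation on the 2-node ethane graph."""
        cfg = ModelConfig(h=4, heads=2, n_pseudo=1, dropout=0.0, seed=0, gin_layers=1)
        model = DFIModel(cfg, panel)
        model.eval()
        enc = model.graph_encoder
        g = build_molecular_graph("CC")
        out = enc([g]).data[0]

        # reference: x_i = sum_c Emb_c(node feats); e = sum_c Emb_c(edge feats)
        x = np.stack(
            [
                sum(emb.weight.data[g.node_features[i, c]] for c, emb in enumerate(enc.node_embeddings))
                for i in range(2)
            ]
        )
        e = np.stack(
            [
                sum(emb.weight.data[g.edge_features[k, c]] for c, emb in enumerate(enc.edge_embeddings[0]))
                for k in range(2)
            ]
        )
        msg = leaky(x[g.edge_index[0]] + e)
        agg = np.zeros_like(x)
        for k, dstk in enumerate(g.edge_index[1]):
            agg[dstk] += msg[k]
        W, b = enc.convs[0].W.data, enc.convs[0].b.data
        nodes = leaky((x + agg) @ W + b)
        assert np.allclose(out, nodes.mean(axis=0), atol=1e-10)

    def test_finite_at_default_init(self, tiny_model):
        out = tiny_model.graph_encoder([build_molecular_graph("CC(=O)Nc1ccc(O)cc1")])
        assert np.all(np.isfinite(out.data))


class TestCypEncoder:
    def test_zero_map(self, tiny_model):
        tiny_model.eval()
        enc = tiny_model.cyp_encoder
        enc.proj.W.data[:] = 0.0
        enc.proj.b.data[:] = 0.0
        out = enc(np.zeros((5, 480)))
        assert out.shape == (5, tiny_model.cfg.h)
        assert np.all(out.data == 0.0)

    def test_shared_across_batch(self, tiny_model):
        """The panel encoding does not depend on the compounds in the batch."""
        tiny_model.eval()
        s1 = [compute_substructures("CCO")]
        s2 = [compute_substructures(x) for x in ("CCO", "c1ccccc1", "CC(=O)O")]
        g1 = [build_molecular_graph("CCO")]
        g2 = [build_molecular_graph(x) for x in ("CCO", "c1ccccc1", "CC(=O)O")]
        he1 = tiny_model.encode_compounds(s1, g1)["he"]
        he2 = tiny_model.encode_compounds(s2, g2)["he"]
        assert np.array_equal(he1.data, he2.data)

    def test_hand_arithmetic_oracle(self, panel):
        cfg = ModelConfig(h=2, heads=2, n_pseudo=1, dropout=0.0, seed=0)
        model = DFIModel(cfg, panel)
        model.eval()
        enc = model.cyp_encoder
        rng = np.random.default_rng(5)
        L = rng.standard_normal((5, 480))
        W = rng.standard_normal((480, 2)) * 0.1
        b = np.array([0.1, -0.1])
        enc.proj.W.data = W
        enc.proj.b.data = b
        out = enc(L)
        assert np.allclose(out.data, leaky(L @ W + b), atol=1e-12)

    def test_wrong_width_raises(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.cyp_encoder(np.zeros((5, 128)))


class TestWeightSharing:
    def test_drug_and_food_share_encoder_parameters(self, tiny_model):
        """A pair's two compounds pass through literally the same parameter
        objects: the model owns one substructure encoder, one graph encoder
        and one interaction block."""
        names = [n for n, _ in tiny_model.named_parameters()]
        assert not any("drug" in n or "food" in n for n in names)
        s = compute_substructures("CCO")
        g = build_molecular_graph("CCO")
        tiny_model.eval()
        trace = tiny_model.forward_single(s, g, s, g)
        assert np.array_equal(
            trace.drug_substructure_embeddings, trace.food_substructure_embeddings
        )
        assert np.array_equal(trace.drug_graph_embedding, trace.food_graph_embedding)


def test_panel_validation():
    with pytest.raises(ValueError):
        CypPanel(embeddings=np.zeros((4, 480)))
    with pytest.raises(ValueError):
        CypPanel(embeddings=np.zeros((5, 100)))
    p = CypPanel.synthetic(3)
    q = CypPanel.synthetic(3)
    assert np.array_equal(p.embeddings, q.embeddings)


def test_panel_embedding_table_round_trip(tmp_path):
    p = CypPanel.synthetic(1)
    path = tmp_path / "panel.tsv"
    p.to_embedding_table(path)
    q = CypPanel.from_embedding_table(path)
    assert np.allclose(p.embeddings, q.embeddings)


def test_panel_from_fasta(tmp_path):
    from cypdfi.cyp import ISOENZYMES, sequence_hash_embedding

    path = tmp_path / "panel.fasta"
    with open(path, "w") as fh:
        for i, iso in enumerate(ISOENZYMES):
            fh.write(f">{iso} synthetic\n" + "ACDEFGHIKLMNPQRSTVWY" * (i + 2) + "\n")
    p = CypPanel.from_fasta(path)
    assert p.sequences is not None
    assert np.allclose(p.embeddings[0], sequence_hash_embedding(p.sequences[0]))
    # distinct sequences map to distinct embeddings
    assert not np.allclose(p.embeddings[0], p.embeddings[1])
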