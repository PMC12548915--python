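"""The DFI prediction network.

Architecture overview (all compound-side parameters shared between the drug
and the food compound of a pair):

* **Substructure encoder** — each on-bit of the 1024-bit radius-2
  fingerprint indexes a trainable 2h-dim row; a one-layer MLP
  (Linear -> LeakyReLU -> Dropout) maps rows to h-dim substructure
  embeddings.
* **Graph encoder** — stacked edge-attributed GIN convolutions over the
  heavy-atom graph, followed by global mean pooling to a single h-vector.
* **CYP450 encoder** — the injected 5x480 panel embeddings pass through a
  one-layer MLP to a 5xh query matrix, shared by every pair in a batch.
* **Compound-CYP interaction block** — n_pseudo trainable pseudo-substructure
  rows are appended to the compound's real substructure embeddings; a
  Set-Transformer-style multihead attention block (additive attention,
  4 heads, set normalization, residual + row-wise feedforward) attends from
  the 5 isoenzyme queries to the n + n_pseudo keys.  Head 0 is bound to
  substrate signals and head 1 to inhibition signals; the attention mass a
  head places on the *real* substructures is that compound's predicted
  substrate/inhibition probability per isoenzyme (DCI score).  Mean pooling
  over the 5 attended isoenzyme rows yields the compound-integrated CYP450
  embedding.
* **Cross-modality fusion** — the drug's CYP-integrated embedding is fused
  with the food's graph embedding by a vector outer product (and vice
  versa); the two flattened h^2 blocks are concatenated to a 2h^2 vector.
* **Prediction head** — a four-layer feedforward stack ending in a sigmoid
  produces the interaction probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .cyp import EMBEDDING_DIM, ISOENZYMES, CypPanel
from .featurize import (
    EDGE_VOCAB_SIZES,
    N_BITS,
    NODE_VOCAB_SIZES,
    VOCAB_VERSION,
    MolecularGraph,
    SubstructureSet,
)
from .nn import Tensor

N_ISO = len(ISOENZYMES)

__all__ = [
    "ModelConfig",
    "DFIModel",
    "AttentionTensor",
    "DciScoreMatrix",
    "ForwardTrace",
    "pool_isoenzymes",
    "dci_scores_from_attention",
    "fuse",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the model and its training procedure.

    Defaults follow the reference configuration: embedding width h=128,
    n_pseudo=10 pseudo-substructures, 4 attention heads, dropout 0.3,
    auxiliary coefficient alpha=5, batch size 1024, AdamW with learning rate
    1e-4 and weight decay 1e-4, at most 100 epochs with early-stopping
    patience 10.
    """

    h: int = 128
    n_pseudo: int = 10
    heads: int = 4
    dropout: float = 0.3
    alpha: float = 5.0
    batch_size: int = 1024
    lr: float = 1e-4
    weight_decay: float = 1e-4
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    gin_layers: int = 3
    head_hidden: int | None = None  # first hidden width of the head; default 4h
    leaky_slope: float = 0.01
    restore_best: bool = True  # load the best-validation checkpoint after training;
    # False keeps the final-epoch parameters (robust when the validation
    # partition is too small for reliable checkpoint selection)

    def __post_init__(self):
        if self.h % self.heads != 0:
            raise ValueError("h must be divisible by the number of heads")
        if self.n_pseudo < 1:
            raise ValueError("n_pseudo must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.head_hidden is None:
            self.head_hidden = 4 * self.h

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class AttentionTensor:
    """Per-head attention rows over n real + n_pseudo pseudo substructures."""

    weights: np.ndarray  # (heads, 5, n + n_pseudo)
    n: int  # count of real substructures
    head_roles: dict[int, str] = field(
        default_factory=lambda: {0: "substrate", 1: "inhibition", 2: "free", 3: "free"}
    )

    @property
    def n_pseudo(self) -> int:
        return self.weights.shape[2] - self.n


@dataclass(frozen=True)
class DciScoreMatrix:
    """2x5 attention-mass scores: rows (substrate, inhibition), columns the
    canonical isoenzyme order."""

    scores: np.ndarray  # (2, 5) in [0, 1]


@dataclass(frozen=True)
class ForwardTrace:
    """All intermediates of one drug-food forward pass (eval mode)."""

    drug_substructure_embeddings: np.ndarray  # (n_d, h)
    food_substructure_embeddings: np.ndarray  # (n_f, h)
    drug_graph_embedding: np.ndarray  # (h,)
    food_graph_embedding: np.ndarray  # (h,)
    drug_cyp_embedding: np.ndarray  # (h,)
    food_cyp_embedding: np.ndarray  # (h,)
    drug_attention: AttentionTensor
    food_attention: AttentionTensor
    drug_dci: DciScoreMatrix
    food_dci: DciScoreMatrix
    fusion: np.ndarray  # (2 h^2,)
    y_hat: float


# ---------------------------------------------------------------------------
# stateless operations
# ---------------------------------------------------------------------------


def pool_isoenzymes(oe: Tensor) -> Tensor:
    """Mean over the isoenzyme axis: (..., 5, h) -> (..., h)."""
    return oe.mean(axis=-2)


def dci_scores_from_attention(attention: AttentionTensor) -> DciScoreMatrix:
    """Sum of attention mass on the real substructures, heads 0 (substrate)
    and 1 (inhibition)."""
    real = attention.weights[:2, :, : attention.n].sum(axis=2)  # (2, 5)
    return DciScoreMatrix(scores=real)


def fuse(hi_d: Tensor, hg_f: Tensor, hi_f: Tensor, hg_d: Tensor) -> Tensor:
    """Cross-modality fusion: row-major flattened outer products, drug block
    first.  Inputs (..., h); output (..., 2 h^2)."""
    h = hi_d.shape[-1]
    for t in (hg_f, hi_f, hg_d):
        if t.shape[-1] != h:
            raise ValueError("fusion inputs must share the embedding width")
    lead = hi_d.shape[:-1]
    block_d = (hi_d.reshape(*lead, h, 1) * hg_f.reshape(*lead, 1, h)).reshape(*lead, h * h)
    block_f = (hi_f.reshape(*lead, h, 1) * hg_d.reshape(*lead, 1, h)).reshape(*lead, h * h)
    return nn.concat([block_d, block_f], axis=-1)


# ---------------------------------------------------------------------------
# sub-networks
# ---------------------------------------------------------------------------


class SubstructureEncoder(nn.Module):
    """Trainable 1024 x 2h bit table -> Linear(2h, h) -> LeakyReLU -> Dropout."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.table = Tensor(rng.normal(0.0, 0.02, size=(N_BITS, 2 * cfg.h)), requires_grad=True)
        self.proj = nn.Linear(2 * cfg.h, cfg.h, rng)
        self.drop = nn.Dropout(cfg.dropout)
        self.slope = cfg.leaky_slope

    def __call__(self, sets: list[SubstructureSet], rng=None) -> tuple[Tensor, np.ndarray]:
        """Batch-encode substructure sets.

        Returns ``(embeddings, mask)`` with embeddings (B, L, h) padded to the
        largest set in the batch and a boolean mask marking real positions.
        """
        if not sets:
            raise ValueError("empty batch of substructure sets")
        lengths = [s.n for s in sets]
        L = max(lengths)
        idx = np.zeros((len(sets), L), dtype=np.intp)
        mask = np.zeros((len(sets), L), dtype=bool)
        for i, s in enumerate(sets):
            idx[i, : s.n] = s.bits
            mask[i, : s.n] = True
        rows = nn.gather(self.table, idx.reshape(-1)).reshape(len(sets), L, 2 * self.table.shape[1] // 2)
        out = self.drop((rows @ self.proj.W + self.proj.b).leaky_relu(self.slope), rng)
        # zero the padded rows so downstream masked ops see exact zeros
        return out * Tensor(mask[:, :, None].astype(np.float64)), mask


class GraphEncoder(nn.Module):
    """Stacked edge-attributed GIN convolutions with global mean pooling."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        h = cfg.h
        self.node_embeddings = [nn.Embedding(v, h, rng) for v in NODE_VOCAB_SIZES]
        self.edge_embeddings = [
            [nn.Embedding(v, h, rng) for v in EDGE_VOCAB_SIZES] for _ in range(cfg.gin_layers)
        ]
        self.convs = [nn.Linear(h, h, rng) for _ in range(cfg.gin_layers)]
        self.slope = cfg.leaky_slope

    def __call__(self, graphs: list[MolecularGraph], rng=None) -> Tensor:
        if not graphs:
            raise ValueError("empty batch of graphs")
        for g in graphs:
            if g.num_nodes == 0:
                raise ValueError("graph with no nodes")
        nodes = np.concatenate([g.node_features for g in graphs])
        offsets = np.cumsum([0] + [g.num_nodes for g in graphs])
        src = np.concatenate([g.edge_index[0] + off for g, off in zip(graphs, offsets)]).astype(np.intp)
        dst = np.concatenate([g.edge_index[1] + off for g, off in zip(graphs, offsets)]).astype(np.intp)
        efeat = np.concatenate([g.edge_features for g in graphs])
        graph_ids = np.concatenate(
            [np.full(g.num_nodes, i, dtype=np.intp) for i, g in enumerate(graphs)]
        )
        n_nodes = nodes.shape[0]

        x = self.node_embeddings[0](nodes[:, 0])
        for c in range(1, len(self.node_embeddings)):
            x = x + self.node_embeddings[c](nodes[:, c])
        for layer, (conv, eembs) in enumerate(zip(self.convs, self.edge_embeddings)):
            if len(src):
                e = eembs[0](efeat[:, 0])
                for c in range(1, len(eembs)):
                    e = e + eembs[c](efeat[:, c])
                msg = (nn.gather(x, src) + e).leaky_relu(self.slope)
                agg = nn.segment_sum(msg, dst, n_nodes)
                x = conv(x + agg)
            else:
                x = conv(x)
            x = x.leaky_relu(self.slope)
        pooled = nn.segment_sum(x, graph_ids, len(graphs))
        counts = np.asarray([g.num_nodes for g in graphs], dtype=np.float64)[:, None]
        return pooled * Tensor(1.0 / counts)


class CypEncoder(nn.Module):
    """Linear(480, h) -> LeakyReLU -> Dropout over the injected panel table."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Linear(EMBEDDING_DIM, cfg.h, rng)
        self.drop = nn.Dropout(cfg.dropout)
        self.slope = cfg.leaky_slope

    def __call__(self, panel_embeddings: np.ndarray, rng=None) -> Tensor:
        emb = np.asarray(panel_embeddings, dtype=np.float64)
        if emb.shape != (N_ISO, EMBEDDING_DIM):
            raise ValueError(f"panel embeddings must be {(N_ISO, EMBEDDING_DIM)}, got {emb.shape}")
        return self.drop(self.proj(Tensor(emb)).leaky_relu(self.slope), rng)


class InteractionBlock(nn.Module):
    """Compound-CYP interaction block.

    Appends the shared pseudo-substructure rows to each compound's real
    substructure embeddings and runs one multihead attention block
    ``MAB(x, y) = (x + z) + RFF(SetNorm(x + z))`` with
    ``z = Multihead(SetNorm(x), SetNorm(y), SetNorm(y))`` where attention
    scores are additive: ``e = v_i' tanh(W_q q + W_k k)`` per head.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        h, heads = cfg.h, cfg.heads
        self.heads = heads
        self.dh = h // heads
        self.pseudo = Tensor(rng.normal(0.0, 0.02, size=(cfg.n_pseudo, h)), requires_grad=True)
        self.Wq = Tensor(nn.xavier_uniform(rng, h, h), requires_grad=True)
        self.Wk = Tensor(nn.xavier_uniform(rng, h, h), requires_grad=True)
        self.v = Tensor(nn.xavier_uniform(rng, heads, self.dh), requires_grad=True)
        self.Wv = Tensor(nn.xavier_uniform(rng, h, h), requires_grad=True)
        self.out_proj = nn.Linear(h, h, rng)
        self.norm_q = nn.SetNorm(h)
        self.norm_k = nn.SetNorm(h)
        self.norm_mid = nn.SetNorm(h)
        self.rff1 = nn.Linear(h, h, rng)
        self.rff2 = nn.Linear(h, h, rng)

    # -- pieces ---------------------------------------------------------------
    def append_pseudo(self, hs: Tensor, mask: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """Concatenate the shared pseudo rows after the (padded) real rows.

        hs: (B, L, h); returns keys (B, L + n_pseudo, h) and extended mask.
        """
        B = hs.shape[0]
        n_pseudo = self.pseudo.shape[0]
        tiled = self.pseudo.reshape(1, n_pseudo, -1) * Tensor(np.ones((B, 1, 1)))
        keys = nn.concat([hs, tiled], axis=1)
        full_mask = np.concatenate([mask, np.ones((B, n_pseudo), dtype=bool)], axis=1)
        return keys, full_mask

    def additive_attention(
        self, q: Tensor, kv: Tensor, key_mask: np.ndarray | None
    ) -> tuple[Tensor, Tensor]:
        """Masked additive multihead attention.

        q: (5, h) shared queries; kv: (B, L, h).  Returns the attended value
        rows (B, 5, h) and the attention tensor (B, heads, 5, L).
        """
        B, L, h = kv.shape
        heads, dh = self.heads, self.dh
        qp = (q @ self.Wq).reshape(N_ISO, heads, dh).transpose(1, 0, 2)  # (heads, 5, dh)
        kp = (kv @ self.Wk).reshape(B, L, heads, dh).transpose(0, 2, 1, 3)  # (B, heads, L, dh)
        scores = nn.additive_scores(qp, kp, self.v)  # (B, heads, 5, L)
        mask = None if key_mask is None else key_mask[:, None, None, :]
        attn = nn.masked_softmax(scores, mask, axis=-1)
        vp = (kv @ self.Wv).reshape(B, L, heads, dh).transpose(0, 2, 1, 3)  # (B, heads, L, dh)
        z = (attn @ vp).transpose(0, 2, 1, 3).reshape(B, N_ISO, heads * dh)
        return self.out_proj(z), attn

    def rff(self, x: Tensor) -> Tensor:
        return self.rff2(self.rff1(x).gelu()).gelu()

    def mab(self, x: Tensor, y: Tensor, key_mask: np.ndarray | None) -> tuple[Tensor, Tensor]:
        """One multihead attention block; x (5, h) queries, y (B, L, h) keys."""
        z, attn = self.additive_attention(self.norm_q(x), self.norm_k(y, key_mask), key_mask)
        h1 = x.reshape(1, N_ISO, -1) + z  # broadcast residual over the batch
        out = h1 + self.rff(self.norm_mid(h1))
        return out, attn

    def __call__(
        self, hs: Tensor, mask: np.ndarray, he: Tensor
    ) -> tuple[Tensor, Tensor, Tensor, int]:
        """Returns (compound-integrated CYP embedding (B, h),
        attention (B, heads, 5, L_real + n_pseudo),
        dci scores (B, 2, 5), n_real_padded)."""
        keys, full_mask = self.append_pseudo(hs, mask)
        oe, attn = self.mab(he, keys, full_mask)
        hi = pool_isoenzymes(oe)
        L_real = hs.shape[1]
        scores = attn[:, :2, :, :L_real].sum(axis=-1)  # (B, 2, 5); padded real cols are exactly 0
        return hi, attn, scores, L_real


class PredictionHead(nn.Module):
    """Four-layer feedforward head: 2h^2 -> H1 -> 2h -> h -> 1 (sigmoid)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        h = cfg.h
        d_in = 2 * h * h
        H1 = cfg.head_hidden
        self.fc1 = nn.Linear(d_in, H1, rng)
        self.bn1 = nn.BatchNorm1d(H1)
        self.fc2 = nn.Linear(H1, 2 * h, rng)
        self.fc3 = nn.Linear(2 * h, h, rng)
        self.bn3 = nn.BatchNorm1d(h)
        self.fc4 = nn.Linear(h, 1, rng)
        self.drop = nn.Dropout(cfg.dropout)
        self.slope = cfg.leaky_slope

    def __call__(self, hf: Tensor, rng=None) -> Tensor:
        x = self.drop(self.bn1(self.fc1(hf)).leaky_relu(self.slope), rng)
        x = self.drop(self.fc2(x).leaky_relu(self.slope), rng)
        x = self.drop(self.bn3(self.fc3(x)).leaky_relu(self.slope), rng)
        return self.fc4(x).sigmoid().reshape(-1)


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------


class DFIModel(nn.Module):
    """Full drug-food interaction network with shared compound-side weights."""

    def __init__(self, cfg: ModelConfig, panel: CypPanel, rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.Generator(np.random.PCG64(cfg.seed))
        self.cfg = cfg
        self.panel_embeddings = np.asarray(panel.embeddings, dtype=np.float64)
        self.substructure_encoder = SubstructureEncoder(cfg, rng)
        self.graph_encoder = GraphEncoder(cfg, rng)
        self.cyp_encoder = CypEncoder(cfg, rng)
        self.interaction = InteractionBlock(cfg, rng)
        self.head = PredictionHead(cfg, rng)

    # -- compound-level pass ---------------------------------------------------
    def encode_compounds(
        self,
        sets: list[SubstructureSet],
        graphs: list[MolecularGraph],
        rng: np.random.Generator | None = None,
    ) -> dict:
        """Encode a batch of (unique) compounds through the shared branches."""
        hs, mask = self.substructure_encoder(sets, rng)
        hg = self.graph_encoder(graphs, rng)
        he = self.cyp_encoder(self.panel_embeddings, rng)
        hi, attn, dci, L_real = self.interaction(hs, mask, he)
        return {
            "hs": hs,
            "mask": mask,
            "hg": hg,
            "he": he,
            "hi": hi,
            "attention": attn,
            "dci_scores": dci,
            "L_real": L_real,
        }

    # -- pair-level pass --------------------------------------------------------
    def forward_pairs(
        self,
        sets: list[SubstructureSet],
        graphs: list[MolecularGraph],
        drug_idx: np.ndarray,
        food_idx: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> dict:
        """Forward pass for a batch of pairs over a pool of unique compounds.

        ``drug_idx``/``food_idx`` index into ``sets``/``graphs``; compound-level
        computation is shared across the pairs that reuse a compound.
        """
        enc = self.encode_compounds(sets, graphs, rng)
        drug_idx = np.asarray(drug_idx, dtype=np.intp)
        food_idx = np.asarray(food_idx, dtype=np.intp)
        hi_d = nn.gather(enc["hi"], drug_idx)
        hi_f = nn.gather(enc["hi"], food_idx)
        hg_d = nn.gather(enc["hg"], drug_idx)
        hg_f = nn.gather(enc["hg"], food_idx)
        hf = fuse(hi_d, hg_f, hi_f, hg_d)
        y_hat = self.head(hf, rng)
        enc.update({"fusion": hf, "y_hat": y_hat, "drug_idx": drug_idx, "food_idx": food_idx})
        return enc

    def forward_single(
        self, drug_set, drug_graph, food_set, food_graph
    ) -> ForwardTrace:
        """Eval-mode forward pass for one pair, retaining all intermediates."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward_pairs(
                [drug_set, food_set], [drug_graph, food_graph], np.array([0]), np.array([1])
            )
        finally:
            if was_training:
                self.train()
        n_pseudo = self.cfg.n_pseudo
        L_real = out["L_real"]

        def _attention(i: int, n: int) -> AttentionTensor:
            w = out["attention"].data[i]  # (heads, 5, L_real + n_pseudo)
            w = np.concatenate([w[:, :, :n], w[:, :, L_real:]], axis=2)
            return AttentionTensor(weights=w, n=n)

        att_d = _attention(0, drug_set.n)
        att_f = _attention(1, food_set.n)
        y = float(out["y_hat"].data[0])
        if not 0.0 < y < 1.0:
            raise ValueError("predicted score left (0, 1)")
        return ForwardTrace(
            drug_substructure_embeddings=out["hs"].data[0, : drug_set.n],
            food_substructure_embeddings=out["hs"].data[1, : food_set.n],
            drug_graph_embedding=out["hg"].data[0],
            food_graph_embedding=out["hg"].data[1],
            drug_cyp_embedding=out["hi"].data[0],
            food_cyp_embedding=out["hi"].data[1],
            drug_attention=att_d,
            food_attention=att_f,
            drug_dci=dci_scores_from_attention(att_d),
            food_dci=dci_scores_from_attention(att_f),
            fusion=out["fusion"].data[0],
            y_hat=y,
        )


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(model: DFIModel, path) -> None:
    """Serialize parameters, buffers, config, panel and vocab version."""
    state = model.state_dict()
    meta = {"config": asdict(model.cfg), "vocab_version": VOCAB_VERSION}
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        __panel__=model.panel_embeddings,
        **state,
    )


def load_checkpoint(path) -> DFIModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        if meta["vocab_version"] != VOCAB_VERSION:
            raise ValueError(
                f"checkpoint was written with vocab version {meta['vocab_version']}, "
                f"this build uses {VOCAB_VERSION}"
            )
        cfg = ModelConfig(**meta["config"])
        panel = CypPanel(embeddings=data["__panel__"])
        model = DFIModel(cfg, panel)
        state = {k: data[k] for k in data.files if not k.startswith("__")}
        model.load_state_dict(state)
    return model
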