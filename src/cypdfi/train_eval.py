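"""Training loop, metrics and multi-seed aggregation.

Training minimizes ``L = L1 + alpha * L2`` with AdamW, monitors the total
validation loss each epoch, keeps the best-validation parameters and stops
early after ``patience`` epochs without improvement.  Compound-level
computation (substructure encoding, graph encoding, the interaction block)
is deduplicated within each batch: every unique compound is encoded once and
pair-level fusion gathers from the shared pool.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .cyp import CypPanel
from .data_io import DfiExample
from .featurize import build_molecular_graph, compute_substructures
from .losses import DciLabelMatrix, auxiliary_loss, primary_loss, total_loss
from .model import DFIModel, ModelConfig
from .nn import gather

__all__ = [
    "TrainingHistory",
    "MetricsReport",
    "PairDataset",
    "train",
    "evaluate",
    "repeat_runs",
    "predict_scores",
    "dci_recovery_scores",
    "dci_recovery_auroc",
]


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = "max_epochs"


@dataclass
class MetricsReport:
    auroc: float
    auprc: float
    f1: float
    precision: float
    recall: float
    threshold: float = 0.5
    note: str = ""
    per_seed: dict[int, "MetricsReport"] | None = None
    std: dict[str, float] | None = None

    def as_dict(self) -> dict:
        d = {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "threshold": self.threshold,
        }
        if self.std is not None:
            d["std"] = self.std
        return d


class PairDataset:
    """Featurized pair table over a deduplicated compound pool."""

    def __init__(
        self,
        examples: list[DfiExample],
        dci: dict[str, DciLabelMatrix] | None = None,
        _cache: dict | None = None,
    ):
        if not examples:
            raise ValueError("empty example list")
        cache = _cache if _cache is not None else {}
        smiles_to_idx: dict[str, int] = {}
        self.compound_ids: list[str] = []
        self.sets = []
        self.graphs = []
        drug_idx, food_idx, y = [], [], []
        for ex in examples:
            for comp in (ex.drug, ex.food):
                if comp.smiles not in smiles_to_idx:
                    if comp.smiles not in cache:
                        cache[comp.smiles] = (
                            compute_substructures(comp.smiles),
                            build_molecular_graph(comp.smiles),
                        )
                    s, g = cache[comp.smiles]
                    smiles_to_idx[comp.smiles] = len(self.sets)
                    self.sets.append(s)
                    self.graphs.append(g)
                    self.compound_ids.append(comp.id)
            drug_idx.append(smiles_to_idx[ex.drug.smiles])
            food_idx.append(smiles_to_idx[ex.food.smiles])
            y.append(ex.label)
        self.drug_idx = np.asarray(drug_idx, dtype=np.intp)
        self.food_idx = np.asarray(food_idx, dtype=np.intp)
        self.y = np.asarray(y, dtype=np.float64)
        n_comp = len(self.sets)
        self.labels = np.full((n_comp, 2, 5), np.nan)
        if dci:
            for i, cid in enumerate(self.compound_ids):
                if cid in dci:
                    self.labels[i] = dci[cid].values

    def __len__(self) -> int:
        return self.y.size


def _batch_forward(model: DFIModel, data: PairDataset, pair_sel: np.ndarray, rng=None):
    """Forward one batch of pairs; returns (out dict, local drug/food idx)."""
    d_glob = data.drug_idx[pair_sel]
    f_glob = data.food_idx[pair_sel]
    uniq, inverse = np.unique(np.concatenate([d_glob, f_glob]), return_inverse=True)
    local_d = inverse[: d_glob.size]
    local_f = inverse[d_glob.size :]
    sets = [data.sets[i] for i in uniq]
    graphs = [data.graphs[i] for i in uniq]
    out = model.forward_pairs(sets, graphs, local_d, local_f, rng)
    out["uniq"] = uniq
    return out, local_d, local_f


def _batch_losses(model: DFIModel, data: PairDataset, pair_sel, rng=None):
    out, local_d, local_f = _batch_forward(model, data, pair_sel, rng)
    l1 = primary_loss(out["y_hat"], data.y[pair_sel])
    scores = out["dci_scores"]
    from .nn import concat

    both_scores = concat([gather(scores, local_d), gather(scores, local_f)], axis=0)
    both_labels = np.concatenate(
        [data.labels[data.drug_idx[pair_sel]], data.labels[data.food_idx[pair_sel]]], axis=0
    )
    l2, n_sup = auxiliary_loss(both_scores, both_labels)
    loss = total_loss(l1, l2, model.cfg.alpha)
    return loss, l1, l2, n_sup


def train(
    cfg: ModelConfig,
    train_examples: list[DfiExample],
    valid_examples: list[DfiExample],
    dci: dict[str, DciLabelMatrix] | None,
    panel: CypPanel,
    log_path=None,
    _cache: dict | None = None,
) -> tuple[DFIModel, TrainingHistory]:
    """Train a model from scratch with early stopping on validation loss."""
    if not train_examples or not valid_examples:
        raise ValueError("train and validation partitions must be non-empty")
    cache = _cache if _cache is not None else {}
    data_train = PairDataset(train_examples, dci, _cache=cache)
    data_valid = PairDataset(valid_examples, dci, _cache=cache)
    rng = np.random.Generator(np.random.PCG64([cfg.seed, 17]))
    model = DFIModel(cfg, panel, rng=np.random.Generator(np.random.PCG64([cfg.seed, 23])))
    from .nn import AdamW

    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = TrainingHistory()
    best_val = np.inf
    best_state = None
    epochs_since_best = 0
    log_fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(cfg.max_epochs):
            model.train()
            order = rng.permutation(len(data_train))
            tot_l1 = tot_l2 = tot = 0.0
            n_sup_epoch = 0
            n_batches = 0
            for start in range(0, len(order), cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                if sel.size < 2:
                    continue  # batch statistics undefined for a single pair
                loss, l1, l2, n_sup = _batch_losses(model, data_train, sel, rng)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                tot_l1 += float(l1.data)
                tot_l2 += float(l2.data)
                tot += float(loss.data)
                n_sup_epoch += n_sup
                n_batches += 1
            model.eval()
            val_tot = val_l1 = 0.0
            n_val = 0
            for start in range(0, len(data_valid), cfg.batch_size):
                sel = np.arange(start, min(start + cfg.batch_size, len(data_valid)))
                vloss, vl1, _, _ = _batch_losses(model, data_valid, sel)
                val_tot += float(vloss.data) * sel.size
                val_l1 += float(vl1.data) * sel.size
                n_val += sel.size
            val_tot /= n_val
            val_l1 /= n_val
            record = {
                "epoch": epoch,
                "train_l1": tot_l1 / max(n_batches, 1),
                "train_l2": tot_l2 / max(n_batches, 1),
                "train_total": tot / max(n_batches, 1),
                "valid_total": val_tot,
                "valid_l1": val_l1,
                "n_supervised": n_sup_epoch,
            }
            history.epochs.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
            # checkpoint/stopping monitor: the validation value of the
            # optimized objective (L1 + alpha L2)
            if val_tot < best_val - 1e-12:
                best_val = val_tot
                best_state = copy.deepcopy(model.state_dict()) if cfg.restore_best else None
                history.best_epoch = epoch
                epochs_since_best = 0
            else:
                epochs_since_best += 1
                if epochs_since_best >= cfg.patience:
                    history.stop_reason = "early_stop"
                    break
        else:
            history.stop_reason = "max_epochs"
    finally:
        if log_fh:
            log_fh.close()
    if cfg.restore_best and best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def predict_scores(model: DFIModel, examples: list[DfiExample], batch_size: int = 1024) -> np.ndarray:
    """Eval-mode interaction scores for a list of pairs."""
    data = PairDataset(examples)
    model.eval()
    scores = np.empty(len(data))
    for start in range(0, len(data), batch_size):
        sel = np.arange(start, min(start + batch_size, len(data)))
        out, _, _ = _batch_forward(model, data, sel)
        scores[sel] = out["y_hat"].data
    return scores


def evaluate(model: DFIModel, examples: list[DfiExample], threshold: float = 0.5) -> MetricsReport:
    """Five-metric report at the fixed threshold."""
    scores = predict_scores(model, examples)
    y = np.asarray([e.label for e in examples])
    pred = (scores >= threshold).astype(int)
    if len(np.unique(y)) < 2:
        return MetricsReport(
            auroc=float("nan"),
            auprc=float("nan"),
            f1=f1_score(y, pred, zero_division=0),
            precision=precision_score(y, pred, zero_division=0),
            recall=recall_score(y, pred, zero_division=0),
            threshold=threshold,
            note="AUROC/AUPRC undefined: evaluation set contains a single class",
        )
    return MetricsReport(
        auroc=float(roc_auc_score(y, scores)),
        auprc=float(average_precision_score(y, scores)),
        f1=float(f1_score(y, pred, zero_division=0)),
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        threshold=threshold,
    )


def repeat_runs(
    cfg: ModelConfig,
    train_examples: list[DfiExample],
    valid_examples: list[DfiExample],
    test_examples: list[DfiExample],
    dci: dict[str, DciLabelMatrix] | None,
    panel: CypPanel,
    seeds: list[int],
    _cache: dict | None = None,
) -> tuple[MetricsReport, list[DFIModel]]:
    """Train and evaluate once per seed; aggregate mean and sample std."""
    if not seeds:
        raise ValueError("need at least one seed")
    from dataclasses import replace

    per_seed: dict[int, MetricsReport] = {}
    models = []
    cache = _cache if _cache is not None else {}
    for seed in seeds:
        model, _ = train(
            replace(cfg, seed=seed), train_examples, valid_examples, dci, panel, _cache=cache
        )
        per_seed[seed] = evaluate(model, test_examples)
        models.append(model)
    keys = ("auroc", "auprc", "f1", "precision", "recall")
    values = {k: np.array([getattr(per_seed[s], k) for s in seeds]) for k in keys}
    mean = {k: float(np.mean(v)) for k, v in values.items()}
    std = {k: float(np.std(v, ddof=1)) if len(seeds) > 1 else 0.0 for k, v in values.items()}
    report = MetricsReport(
        auroc=mean["auroc"],
        auprc=mean["auprc"],
        f1=mean["f1"],
        precision=mean["precision"],
        recall=mean["recall"],
        per_seed=per_seed,
        std=std,
    )
    return report, models


# ---------------------------------------------------------------------------
# attention-derived DCI recovery
# ---------------------------------------------------------------------------


def dci_recovery_scores(
    model: DFIModel, smiles_list: list[str]
) -> np.ndarray:
    """Eval-mode attention-mass DCI score matrices, shape (n, 2, 5)."""
    sets = [compute_substructures(s) for s in smiles_list]
    graphs = [build_molecular_graph(s) for s in smiles_list]
    model.eval()
    enc = model.encode_compounds(sets, graphs)
    return enc["dci_scores"].data


def dci_recovery_auroc(
    model: DFIModel,
    compounds,
    true_dci: dict[str, DciLabelMatrix],
) -> float:
    """AUROC of attention-derived DCI scores against known labels, pooled
    over all labeled (compound, type, isoenzyme) cells."""
    comps = [c for c in compounds if c.id in true_dci]
    if not comps:
        raise ValueError("no compounds with DCI labels")
    scores = dci_recovery_scores(model, [c.smiles for c in comps])
    labels = np.stack([true_dci[c.id].values for c in comps])
    finite = np.isfinite(labels)
    y = labels[finite]
    s = scores[finite]
    if len(np.unique(y)) < 2:
        raise ValueError("labeled cells contain a single class")
    return float(roc_auc_score(y, s))
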