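"""scikit-learn-style estimator facade.

:class:`DFIClassifier` wraps the full pipeline — featurization, the shared
encoders, the CYP-attention interaction block, fusion and the prediction
head — behind the familiar ``fit`` / ``predict`` / ``predict_proba``
interface so it composes with sklearn model selection.  ``X`` is an
(n, 2) array-like of SMILES strings (drug column first); ``y`` is binary.
CYP450 annotations, the isoenzyme panel and a validation fraction are fit
parameters, not features.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cyp import CypPanel
from .data_io import DfiExample
from .featurize import CompoundRecord, CompoundRole, canonicalize_smiles
from .losses import DciLabelMatrix
from .model import ModelConfig
from .train_eval import dci_recovery_scores, predict_scores, train

__all__ = ["DFIClassifier"]


class DFIClassifier(ClassifierMixin, BaseEstimator):
    """Binary drug-food interaction classifier with CYP450 attention
    regularization.

    Parameters mirror :class:`~cypdfi.model.ModelConfig`; ``alpha=0``
    disables the auxiliary attention supervision (the ablated model).

    Examples
    --------
    >>> clf = DFIClassifier(h=32, max_epochs=5)
    >>> clf.fit(X, y, dci=annotations)          # doctest: +SKIP
    >>> clf.predict_proba(X_new)[:, 1]          # doctest: +SKIP
    """

    def __init__(
        self,
        h: int = 128,
        n_pseudo: int = 10,
        heads: int = 4,
        dropout: float = 0.3,
        alpha: float = 5.0,
        batch_size: int = 1024,
        lr: float = 1e-4,
        weight_decay: float = 1e-4,
        max_epochs: int = 100,
        patience: int = 10,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.h = h
        self.n_pseudo = n_pseudo
        self.heads = heads
        self.dropout = dropout
        self.alpha = alpha
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------------
    def _config(self) -> ModelConfig:
        return ModelConfig(
            h=self.h,
            n_pseudo=self.n_pseudo,
            heads=self.heads,
            dropout=self.dropout,
            alpha=self.alpha,
            batch_size=self.batch_size,
            lr=self.lr,
            weight_decay=self.weight_decay,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=self.random_state,
        )

    @staticmethod
    def _examples(X, y=None) -> list[DfiExample]:
        X = np.asarray(X, dtype=object)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of (drug, food) SMILES strings")
        if y is None:
            y = np.zeros(X.shape[0], dtype=int)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary")
        examples = []
        for i, ((d, f), label) in enumerate(zip(X, y)):
            examples.append(
                DfiExample(
                    drug=CompoundRecord(id=f"d{i}", smiles=canonicalize_smiles(d), role=CompoundRole.DRUG),
                    food=CompoundRecord(id=f"f{i}", smiles=canonicalize_smiles(f), role=CompoundRole.FOOD),
                    label=int(label),
                )
            )
        return examples

    # -- sklearn API -----------------------------------------------------------
    def fit(self, X, y, dci: dict[str, DciLabelMatrix] | None = None, panel: CypPanel | None = None):
        """Fit on (drug, food) SMILES pairs.

        ``dci`` maps *canonical SMILES* (or the positional ids ``d{i}``) to
        annotation matrices; ``panel`` defaults to the seeded synthetic
        isoenzyme panel.
        """
        examples = self._examples(X, y)
        if panel is None:
            panel = CypPanel.synthetic(self.random_state)
        # key DCI by compound id; accept SMILES-keyed maps too
        dci_by_id: dict[str, DciLabelMatrix] = {}
        if dci:
            for ex in examples:
                for comp in (ex.drug, ex.food):
                    if comp.id in dci:
                        dci_by_id[comp.id] = dci[comp.id]
                    elif comp.smiles in dci:
                        dci_by_id[comp.id] = dci[comp.smiles]
        rng = np.random.Generator(np.random.PCG64([self.random_state, 7]))
        order = rng.permutation(len(examples))
        n_valid = max(2, int(round(self.validation_fraction * len(examples))))
        if len(examples) - n_valid < 2:
            raise ValueError("too few examples for an internal validation split")
        valid = [examples[i] for i in order[:n_valid]]
        tr = [examples[i] for i in order[n_valid:]]
        self.model_, self.history_ = train(self._config(), tr, valid, dci_by_id, panel)
        self.panel_ = panel
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        scores = predict_scores(self.model_, self._examples(X))
        return np.column_stack([1.0 - scores, scores])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def dci_scores(self, smiles: list[str]) -> np.ndarray:
        """Attention-derived (n, 2, 5) substrate/inhibition scores per
        compound against the isoenzyme panel."""
        check_is_fitted(self, "model_")
        return dci_recovery_scores(self.model_, [canonicalize_smiles(s) for s in smiles])
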