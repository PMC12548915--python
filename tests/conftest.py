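import numpy as np
import pytest

from cypdfi.cyp import CypPanel
from cypdfi.model import DFIModel, ModelConfig


@pytest.fixture(scope="session")
def panel() -> CypPanel:
    return CypPanel.synthetic(0)


@pytest.fixture(scope="session")
def tiny_cfg() -> ModelConfig:
    return ModelConfig(h=8, heads=4, n_pseudo=3, dropout=0.3, seed=0)


@pytest.fixture()
def tiny_model(tiny_cfg, panel) -> DFIModel:
    return DFIModel(tiny_cfg, panel, rng=np.random.Generator(np.random.PCG64(1)))


@pytest.fixture(scope="session")
def trained_recovery_model(panel):
    """A model trained on a small benchmark plus one held-out drug carrying
    a planted positive substrate cell, for attention-recovery checks."""
    from cypdfi.synthetic import SyntheticConfig, make_benchmark
    from cypdfi.train_eval import train

    bench = make_benchmark(SyntheticConfig(n_drugs=60, n_foods=30, seed=5))
    parts = bench["split"].assign(bench["examples"])
    cfg = ModelConfig(h=32, n_pseudo=10, batch_size=256, lr=1e-3, max_epochs=30, patience=30, seed=0)
    model, _ = train(cfg, parts["train"], parts["valid"], bench["observed_dci"], panel)
    drugs_by_id = {d.id: d for d in bench["drugs"]}
    test_ids = sorted({e.drug.id for e in parts["test"]})
    for did in test_ids:
        values = bench["true_dci"][did].values
        pos = np.argwhere(values == 1.0)
        if len(pos) == 1 and pos[0][0] == 0:  # exactly one planted substrate cell
            return model, bench, drugs_by_id[did], tuple(pos[0])
    # fall back to any drug with a positive substrate cell
    for did in test_ids:
        values = bench["true_dci"][did].values
        pos = np.argwhere(values[0] == 1.0)
        if len(pos) and np.any(values == 0.0):
            return model, bench, drugs_by_id[did], (0, int(pos[0][0]))
    raise RuntimeError("benchmark produced no suitable held-out drug")


@pytest.fixture(scope="session")
def small_benchmark():
    """Desk-scale benchmark shared across tests (generation is fast)."""
    from cypdfi.synthetic import SyntheticConfig, make_benchmark

    return make_benchmark(SyntheticConfig(n_drugs=30, n_foods=20, seed=3))
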