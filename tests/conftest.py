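import numpy as np
import pandas as pd
import pytest

from splicegrade.annotation_io import AnnotationMap
from splicegrade.synthetic_data import (
    SimulationConfig,
    plan_effects,
    simulate_annotation,
    simulate_experiment,
)


@pytest.fixture
def toy_ann() -> AnnotationMap:
    """Three genes: two isoforms, one isoform, three isoforms."""
    tx_gene = {
        "t1a": "g1",
        "t1b": "g1",
        "t2a": "g2",
        "t3a": "g3",
        "t3b": "g3",
        "t3c": "g3",
    }
    tx_bt = {"t1a": "Pc", "t1b": "NMD", "t2a": "Pc", "t3a": "Pc", "t3b": "RI", "t3c": "PT"}
    symbols = {"g1": "Alpha", "g2": "Beta", "g3": "Gamma"}
    return AnnotationMap(tx_gene, tx_bt, symbols)


@pytest.fixture(scope="session")
def small_sim():
    """One shared 2-tissue simulation with planted DE and usage switches."""
    cfg = SimulationConfig(n_tissues=2, n_genes=300, seed=11)
    ann = simulate_annotation(cfg)
    effects = plan_effects(cfg, ann, n_de=25, n_dtu=20, n_both=10, log2fc=1.5, delta_psi=0.25)
    return simulate_experiment(cfg, effects, ann=ann)


def group_series(sizes: dict[str, int]) -> pd.Series:
    labels, idx = [], []
    for g, n in sizes.items():
        for r in range(n):
            labels.append(g)
            idx.append(f"{g}_r{r}")
    return pd.Series(labels, index=idx)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
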