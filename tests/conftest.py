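import numpy as np
import pandas as pd
import pytest

from heritex import (
    SimulationConfig,
    TruthTable,
    boxcox_transform,
    build_default_fixture,
    simulate_expression,
    simulate_genotypes,
)
from heritex.simulate import replicate_plan


@pytest.fixture(scope="session")
def default_fx():
    """The default 'small' study fixture (built once per session)."""
    return build_default_fixture(seed=0)


@pytest.fixture(scope="session")
def transformed_expression(default_fx):
    """Per-gene Box-Cox transformed FPKM of the default fixture."""
    fpkm = default_fx.expression.fpkm
    return pd.DataFrame(
        {g: boxcox_transform(fpkm[g].to_numpy())[0] for g in fpkm.columns},
        index=fpkm.index,
    )


@pytest.fixture(scope="session")
def small_genotypes():
    """100 inbred lines x 1,000 markers, two subpopulations."""
    cfg = SimulationConfig(n_genotypes=100, n_markers=1000, seed=11)
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def independent_genotypes():
    """LD-free genotypes for null-calibration tests."""
    cfg = SimulationConfig(
        n_genotypes=200, n_markers=1000, divergence_F=0.01, ld_scale_bp=0.0, seed=13
    )
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def replicated_expression():
    """200 genotypes x 3 replicates, 100 genes at target H2 = 0.5."""
    cfg = SimulationConfig(
        n_genotypes=200, replicates_per_genotype=3, n_markers=100, seed=21
    )
    g, _ = simulate_genotypes(cfg)
    truth = TruthTable(per_gene_target_H2={f"g{i:03d}": 0.5 for i in range(100)})
    rmap = replicate_plan(g.sample_ids, 3)
    expr = simulate_expression(g, truth, rmap, seed=22)
    return expr, rmap
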