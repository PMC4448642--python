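import numpy as np
import pandas as pd
import pytest

from doscomp import core_io, simulate as sim


@pytest.fixture(scope="session")
def small_cfg():
    """A small but fully featured count-level panel configuration."""
    return sim.PanelConfig(
        n_genes_amplified=60,
        n_genes_background=240,
        n_background_chromosomes=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return sim.simulate_panel(small_cfg)


@pytest.fixture(scope="session")
def ratio_panel_small():
    """A ratio-level panel (150 genes) with truth, for classifier tests."""
    cfg = sim.PanelConfig(n_genes_amplified=150, seed=7)
    panel, truth = sim.simulate_ratio_panel(cfg)
    return panel, truth


def make_pair_panel(rng, n_genes=30, n_reps=2, copy_log2=0.585, x_sd=0.12, y_sd=0.5):
    """Random aneuploid-euploid pair RatioPanel for pairwise-rule tests."""
    rows = []
    for i in range(n_genes):
        x = copy_log2 + rng.normal(0.0, x_sd, n_reps)
        y = rng.normal(copy_log2, y_sd, n_reps)
        for r in range(n_reps):
            rows.append((f"g{i:03d}", f"s_r{r + 1}", "3n", x[r], y[r]))
    return core_io.RatioPanel(
        pd.DataFrame(rows, columns=["gene_id", "sample_id", "dose", "x", "y"])
    )


def make_pair_annotation(n_genes=30, chromosome="chrA"):
    return core_io.GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": [f"g{i:03d}" for i in range(n_genes)],
                "chromosome": chromosome,
                "start": np.arange(n_genes) * 2000 + 30_000,
                "end": np.arange(n_genes) * 2000 + 31_000,
                "subtelomeric": False,
            }
        )
    )
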