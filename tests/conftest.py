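import numpy as np
import pandas as pd
import pytest

from ihtseq import SampleDesign, SimConfig, simulate_counts, simulate_null


@pytest.fixture(scope="session")
def small_sim():
    """A 300-gene, 8-group x 4-replicate dataset with 10% DE per treatment."""
    cfg = SimConfig(n_genes=300, seed=101)
    counts, design, truth = simulate_counts(cfg)
    return counts, design, truth


@pytest.fixture(scope="session")
def null_sim():
    """A 2-group null dataset (no true DE) for calibration checks."""
    cfg = SimConfig(
        n_genes=400, groups={"control": 4, "treated": 4}, seed=77, dispersion=0.1
    )
    return simulate_null(cfg)


@pytest.fixture()
def four_vs_four_design():
    assignments = {f"t{i}": "treated" for i in range(4)}
    assignments.update({f"c{i}": "control" for i in range(4)})
    return SampleDesign(assignments, "control")


@pytest.fixture()
def toy_log_expr(four_vs_four_design):
    """3 genes x 8 samples with hand-checkable values."""
    rng = np.random.default_rng(5)
    data = rng.normal(5.0, 1.0, size=(3, 8))
    cols = [f"t{i}" for i in range(4)] + [f"c{i}" for i in range(4)]
    return pd.DataFrame(data, index=["g1", "g2", "g3"], columns=cols)
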