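import warnings

import numpy as np
import pandas as pd
import pytest

from termeth.design import default_methylome_design
from termeth.simulate import SimulationDesign, simulate_genome, simulate_methylomes

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign(
        seed=7,
        n_genes=12,
        n_scaffolds=1,
        scaffold_len=40_000,
        gene_len=1_500,
        caste_dmr_spec=[(0, 0.75, 0.45)],
        mean_coverage=20,
    )


@pytest.fixture(scope="session")
def small_bundle(small_design):
    genome, annotation, truth = simulate_genome(small_design)
    counts, controls = simulate_methylomes(genome, annotation, truth, small_design)
    return {
        "design": small_design,
        "genome": genome,
        "annotation": annotation,
        "truth": truth,
        "counts": counts,
        "controls": controls,
        "study": small_design.methylome_design(),
    }


@pytest.fixture()
def methylome_design():
    return default_methylome_design()


def make_window_table(m: np.ndarray, u: np.ndarray, samples, width: int = 200):
    """Window count table from (n_windows, n_samples) count matrices."""
    n = m.shape[0]
    df = pd.DataFrame(
        {"scaffold": "s", "start": np.arange(n) * width}
    )
    df["end"] = df["start"] + width
    df["n_cpg"] = 1
    for j, s in enumerate(samples):
        df[f"m_{s}"] = m[:, j]
        df[f"u_{s}"] = u[:, j]
    return df
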