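import numpy as np
import pandas as pd
import pytest

from hemimeth.io import pair_dyads
from hemimeth.simulate import SimulationConfig, simulate_study

FOUR_LINE_REPORT = (
    "chr1\t100\t+\t8\t2\tCG\tCGG\n"
    "chr1\t101\t-\t3\t7\tCG\tCGG\n"
    "chr1\t200\t+\t5\t0\tCG\tCGG\n"
    "chr1\t201\t-\t0\t5\tCG\tCGG\n"
)


@pytest.fixture
def four_line_report(tmp_path):
    """Two CpG dyads with counts 8/2, 3/7, 5/0, 0/5 (levels 80, 30, 100, 0)."""
    path = tmp_path / "fixture.CpG_report.txt"
    path.write_text(FOUR_LINE_REPORT)
    return path


@pytest.fixture(scope="session")
def default_bundle():
    """One default-configuration study (seed 0), shared across tests."""
    return simulate_study(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def mef_dyads(default_bundle):
    """Paired dyad tables for the three MEF conditions of the default study."""
    return {
        pert: pair_dyads(default_bundle.calls[("MEF", pert)], min_depth=5)
        for pert in ("control", "sh-Dnmt1", "Tet1")
    }


def make_profiles(rows):
    """Helper: build a gene-profile frame from (gene_id, n_cpg, level, amd)."""
    df = pd.DataFrame(rows, columns=["gene_id", "n_cpg", "gene_level", "gene_amd"])
    df["plus_mean"] = df["gene_level"] + df["gene_amd"] / 2
    df["minus_mean"] = df["gene_level"] - df["gene_amd"] / 2
    df["total_depth"] = df["n_cpg"] * 60
    return df
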