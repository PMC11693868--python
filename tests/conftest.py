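import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ribosel.expression import compute_fpkm
from ribosel.io import AbundanceTable, LibrarySpec
from ribosel.simulate import SimulationParams, simulate_experiment

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

LIB_IDS = ("A_cyto", "A_ribo", "B_cyto", "B_ribo")


def make_table(counts_by_tx: dict[str, dict[str, float]], tx2gene: dict[str, str],
               lengths: dict[str, float] | None = None,
               totals: dict[str, float] | None = None) -> AbundanceTable:
    """Build a small AbundanceTable directly from per-transcript count dicts."""
    counts = pd.DataFrame(counts_by_tx).T.reindex(columns=list(LIB_IDS)).fillna(0.0).sort_index()
    counts.index.name = "transcript_id"
    lens = pd.Series(lengths or {t: 1000.0 for t in counts.index}).reindex(counts.index)
    tots = pd.Series(totals) if totals else counts.sum().clip(lower=1.0)
    fpkm = compute_fpkm(counts, lens, tots)
    specs = tuple(
        LibrarySpec(lib, lib[0], "cytosolic" if lib.endswith("cyto") else "ribosome",
                    max(int(tots[lib]), 1))
        for lib in LIB_IDS
    )
    return AbundanceTable(counts=counts, fpkm=fpkm,
                          tx2gene=pd.Series(tx2gene).reindex(counts.index),
                          lengths=lens, specs=specs)


@pytest.fixture(scope="session")
def default_sim():
    """Default planted-effect experiment shared by recovery and invariant tests."""
    params = SimulationParams(seed=11)
    catalog, structure, table, truth = simulate_experiment(params)
    return params, catalog, structure, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
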