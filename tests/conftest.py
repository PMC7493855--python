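import numpy as np
import pandas as pd
import pytest

from ipmsflow.synthetic_data import SimulationParams, simulate_all
from ipmsflow.tables_io import QuantTable

QUANT_COLS = ["protein_id", "gene_symbol", "experiment_id", "channel",
              "lfq_intensity", "spectral_count"]


def make_quant(rows):
    """rows: (protein, gene, experiment, channel, lfq, sc)."""
    return QuantTable(pd.DataFrame(rows, columns=QUANT_COLS))


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic scenario, shared across the session."""
    return simulate_all(SimulationParams(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_toy_cascade_inputs(rng, n_proteins=None):
    """Random small inputs for cascade-vs-oracle comparisons.

    Returns (quant: stage->list of row-lists, crapome: dict protein->record,
    expressed: stage->set).  Proteins are named p0..; an anchor protein with
    positive intensity in both channels of every experiment keeps channel
    totals positive so normalization is defined.
    """
    if n_proteins is None:
        n_proteins = int(rng.integers(3, 51))
    proteins = [f"p{i}" for i in range(n_proteins)]
    stages = ["OPC", "OL"]
    quant = {}
    for stage in stages:
        reps = []
        for rep in range(2):
            exp = f"{stage}_r{rep}"
            rows = []
            for p in proteins:
                present = rng.random() < 0.8
                if not present and p != proteins[0]:
                    continue
                bait = float(rng.lognormal(10, 1)) if (rng.random() < 0.85 or p == proteins[0]) else 0.0
                control = float(rng.lognormal(10, 1)) if (rng.random() < 0.7 or p == proteins[0]) else 0.0
                rows.append((p, p.upper(), exp, "bait", bait, int(rng.integers(0, 50))))
                rows.append((p, p.upper(), exp, "control", control, int(rng.integers(0, 50))))
            reps.append(rows)
        quant[stage] = reps
    crapome = {}
    for p in proteins:
        if rng.random() < 0.5:
            max_sc = int(rng.integers(0, 400))
            crapome[p] = {"n_experiments": int(rng.integers(1, 300)),
                          "max_spectral_count": max_sc,
                          "avg_spectral_count": max_sc * float(rng.uniform(0.2, 1.0))}
    expressed = {}
    for stage in stages:
        genes = [p.upper() for p in proteins if rng.random() < 0.8]
        expressed[stage] = set(genes) or {proteins[0].upper()}
    return quant, crapome, expressed
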