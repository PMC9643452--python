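import numpy as np
import pandas as pd
import pytest

import pmdclock as pc

WORLD_SEED = 2


@pytest.fixture(scope="session")
def sim_config():
    return pc.SimulationConfig(seed=WORLD_SEED)


@pytest.fixture(scope="session")
def default_culture(sim_config):
    """Default 7-lineage serial culture: (beta, sheet, truth)."""
    return pc.simulate_culture(sim_config, pc.standard_scenario())


@pytest.fixture(scope="session")
def trained_clock(sim_config, default_culture):
    """Reference model -> PD normalization -> final PMD clock, with metrics.

    Session-scoped because elastic-net cross-validation dominates suite
    runtime; all clock tests share one trained pipeline.
    """
    beta, sheet, truth = default_culture
    sheet_i = sheet.set_index("sample_id")
    ref_cols = sheet_i.index[sheet_i["lineage"] == "line0"]
    reference = pc.train_reference_model(
        beta[ref_cols], sheet_i.loc[ref_cols, "cum_pd"], seed=WORLD_SEED
    )
    norm = pc.normalize_pds(
        reference, sheet, beta, reference_lineage="line0"
    ).set_index("sample_id")
    model, metrics = pc.train_replitali(
        beta, norm["normalized_pd"], truth["probes"], seed=WORLD_SEED
    )
    return {
        "reference": reference,
        "normalized": norm,
        "model": model,
        "metrics": metrics,
    }


def random_genome(rng, length=2000, n_frac=0.01, name="rand"):
    letters = np.array(list("ACGT"))
    seq = rng.choice(letters, size=length)
    n_mask = rng.random(length) < n_frac
    seq[n_mask] = "N"
    return pc.GenomeSequence(name, "".join(seq))
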