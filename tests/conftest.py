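import numpy as np
import pandas as pd
import pytest

from twinpheno import (SimulationConfig, default_bifactor_spec,
                       simulate_dataset)


@pytest.fixture(scope="session")
def bifactor_spec():
    return default_bifactor_spec()


@pytest.fixture(scope="session")
def paper_scale_data():
    """One dataset at the default study conditions (173 pairs + singletons)."""
    return simulate_dataset(SimulationConfig(seed=20260913))


def latent_pair_table(config: SimulationConfig, phenotype: str) -> pd.DataFrame:
    """Pair table (zygosity, age, y1, y2) of noiseless latent phenotypes."""
    data, lat = simulate_dataset(config, return_latents=True)
    df = data[["pair_id", "twin", "zygosity", "age"]].copy()
    df["score"] = lat[phenotype].to_numpy()
    counts = df.groupby("pair_id")["twin"].nunique()
    df = df[df.pair_id.isin(counts[counts == 2].index)]
    wide = df.pivot_table(index="pair_id", columns="twin", values="score")
    meta = df.drop_duplicates("pair_id").set_index("pair_id")
    return pd.DataFrame({"zygosity": meta["zygosity"], "age": meta["age"],
                         "y1": wide[1], "y2": wide[2]}).reset_index()
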