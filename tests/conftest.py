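import numpy as np
import pandas as pd
import pytest

from ebbflow.io_core import Dataset, OTUTable, SampleMetadata, validate_dataset
from ebbflow.synthetic_data import SimConfig, generate_dataset

META_DEFAULTS = {
    "bottle_id": "b1",
    "event_id": "e1",
    "site_id": "s1",
    "tide_direction": "incoming",
    "tidal_height_m": 1.0,
    "salinity_ppt": 28.0,
    "temperature_c": 10.0,
    "timestamp": pd.Timestamp("2017-03-01T08:00:00"),
    "role": "field",
}


def make_metadata(rows):
    """Build SampleMetadata from partial per-replicate dicts."""
    full = []
    for row in rows:
        d = dict(META_DEFAULTS)
        d.update(row)
        full.append(d)
    df = pd.DataFrame(full).set_index(pd.Index(
        [r["replicate_id"] for r in rows], name="replicate_id"))
    return SampleMetadata(df.drop(columns=["replicate_id"], errors="ignore"))


def make_dataset(counts: dict, meta_rows) -> Dataset:
    """counts: replicate_id -> list of counts; meta_rows as for make_metadata."""
    otu_ids = [f"O{i}" for i in range(len(next(iter(counts.values()))))]
    table = OTUTable(pd.DataFrame(counts, index=otu_ids))
    return validate_dataset(table, make_metadata(meta_rows))


SMALL_SIM = SimConfig(
    n_otus=60, n_spurious_otus=6, n_differential_otus=8,
    reads_per_replicate=2000, seed=0,
)


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic dataset + truth, shared across fast tests."""
    return generate_dataset(SMALL_SIM)


@pytest.fixture(scope="session")
def default_sim():
    """One default-sized synthetic dataset + truth."""
    return generate_dataset(SimConfig(seed=11))
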