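import numpy as np
import pandas as pd
import pytest

from tropirep import synthetic
from tropirep.litdb import LiteratureTable, allocate_citations

#: Reduced tree counts used where many ensemble refits are needed; the
#: statistical properties under test do not depend on ensemble size.
FAST_MODEL_PARAMS = dict(
    rf_n_estimators=150, gbt_n_estimators=200, gbt_learning_rate=0.05
)


@pytest.fixture(scope="session")
def syn_config():
    return synthetic.SyntheticConfig(seed=42, n_articles=150)


@pytest.fixture(scope="session")
def stack(syn_config):
    return synthetic.gen_stack(syn_config)


@pytest.fixture(scope="session")
def biomes(stack):
    return synthetic.gen_biomes(stack, n_biomes=4, seed=42)


@pytest.fixture(scope="session")
def literature(stack, syn_config):
    table, _ = synthetic.gen_literature(stack, syn_config)
    return table


def make_table(rows, citations):
    """Small literature table from (article_id, lon, lat, habitats) rows."""
    loc = pd.DataFrame(rows, columns=["article_id", "longitude", "latitude", "habitats"])
    loc["habitats"] = loc["habitats"].map(frozenset)
    counts = loc["article_id"].value_counts()
    art = pd.DataFrame(
        {
            "article_id": list(counts.index),
            "total_citations": [citations[a] for a in counts.index],
            "n_locations": counts.to_numpy(),
        }
    )
    return allocate_citations(LiteratureTable(loc, art, provenance="test"))
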