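import logging

import numpy as np
import pandas as pd
import pytest

from otunet import OtuTable

logging.getLogger("otunet").setLevel(logging.ERROR)


def make_table(counts, taxonomy=None, meta=None):
    """Small OtuTable from a dict {otu_id: [counts per sample]}."""
    df = pd.DataFrame(counts).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    if taxonomy is None:
        taxonomy = {o: "k__Bacteria;p__P;c__C;o__O;f__F;g__;s__" for o in df.index}
    if meta is None:
        meta = pd.DataFrame(
            {
                "habitat": "bog",
                "compartment": "peat",
                "plant": "Sphagnum",
                "month": "July",
                "location": "L1",
            },
            index=df.columns,
        )
    return OtuTable(df, meta, pd.Series(taxonomy))


@pytest.fixture
def toy_table():
    """3 OTUs x 4 samples with one chloroplast and one methanogen lineage."""
    return make_table(
        {
            "otu1": [5, 0, 3, 2],
            "otu2": [1, 8, 0, 4],
            "otu3": [0, 2, 7, 1],
        },
        taxonomy={
            "otu1": "k__Bacteria;p__Cyanobacteria;c__Chloroplast;o__;f__;g__;s__",
            "otu2": "k__Archaea;p__Euryarchaeota;c__;o__Methanobacteriales;f__;g__;s__",
            "otu3": "k__Bacteria;p__Proteobacteria;c__;o__Rhizobiales;f__Methylocystaceae;g__;s__",
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
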