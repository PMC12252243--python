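import warnings

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from protcomm import CommunityDataset, prepare
from protcomm.simulate import scenario, simulate_dataset


@pytest.fixture
def toy_dataset() -> CommunityDataset:
    """4 samples x 5 ASVs with metadata, soil, quality, and a tree."""
    samples = ["S1", "S2", "S3", "S4"]
    asvs = [f"A{i}" for i in range(1, 6)]
    counts = pd.DataFrame(
        [
            [10, 0, 5, 1, 4],
            [0, 8, 5, 0, 7],
            [3, 3, 3, 0, 1],
            [6, 1, 0, 0, 13],
        ],
        index=samples,
        columns=asvs,
    )
    taxonomy = pd.Series(
        {
            "A1": "domain:Eukaryota;division:Alveolata;class:Ciliophora;genus:Oxytricha",
            "A2": "domain:Eukaryota;division:Rhizaria;class:Cercozoa;genus:Cercomonas",
            "A3": "domain:Eukaryota;division:Chlorophyta;genus:Scenedesmus",
            "A4": "domain:Eukaryota;division:Fungi;genus:Fusarium",
            "A5": "domain:Eukaryota;division:Stramenopiles;class:Peronosporomycetes;genus:Pythium",
        }
    )
    metadata = pd.DataFrame(
        {
            "cultivation_mode": ["greenhouse", "greenhouse", "hilly", "paddy"],
            "growth_stage": ["flowering", "fruiting", "flowering", "fruiting"],
        },
        index=samples,
    )
    soil = pd.DataFrame(
        np.arange(8, dtype=float).reshape(4, 2) + 0.5,
        index=samples,
        columns=["TN", "pH"],
    )
    quality = pd.DataFrame(
        {"fruit_weight": [150.0, 140.0, 160.0, 155.0], "seed_number": [10.0, 12.0, 9.0, 11.0]},
        index=samples,
    )
    tree = TreeNode.read(
        ["((A1:0.2,A2:0.2):0.8,((A3:0.5,A4:0.5):0.3,A5:0.8):0.2);"],
        convert_underscores=False,
    )
    return CommunityDataset(
        counts=counts, taxonomy=taxonomy, metadata=metadata, tree=tree,
        soil=soil, quality=quality,
    )


@pytest.fixture(scope="session")
def selection_dataset() -> CommunityDataset:
    """Prepared (filtered + rarefied) dataset under environmental filtering."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return prepare(simulate_dataset(scenario("selection", seed=1)), seed=5)


@pytest.fixture(scope="session")
def neutral_dataset() -> CommunityDataset:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return prepare(simulate_dataset(scenario("neutral", seed=1)), seed=5)
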