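"""Shared fixtures: tiny hand-built tables and a small synthetic dataset."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from microtnt import curation, evaluate, synthdata
from microtnt.io_model import CommunityTable, SampleTable, TaxonomyTable

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def tiny_counts() -> CommunityTable:
    data = pd.DataFrame(
        [[10, 0, 5, 3, 2], [0, 8, 2, 0, 0], [4, 4, 4, 4, 4]],
        index=["S1", "S2", "S3"],
        columns=[f"ASV{i}" for i in range(1, 6)],
    )
    return CommunityTable(data, unit="counts", rank="asv")


@pytest.fixture()
def tiny_taxonomy() -> TaxonomyTable:
    rows = {
        "ASV1": ["Bacteria", "Proteobacteria", "Gamma", "Thiotrichales", "Thiotrichaceae", "Cocleimonas"],
        "ASV2": ["Bacteria", "Proteobacteria", "Gamma", "Thiotrichales", "Thiotrichaceae", "Cocleimonas"],
        "ASV3": ["Bacteria", "Gemmatimonadota", "Gemmatimonadetes", "Gemmatimonadales", "Gemmatimonadaceae", ""],
        "ASV4": ["Bacteria", "Chloroflexi", "Anaerolineae", "SBR1031", "A4b", ""],
        "ASV5": ["Bacteria", "Planctomycetota", "Planctomycetes", "Pirellulales", "Pirellulaceae", "Blastopirellula"],
    }
    frame = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["Kingdom", "Phylum", "Class", "Order", "Family", "Genus"],
    )
    return TaxonomyTable(frame)


@pytest.fixture()
def tiny_samples() -> SampleTable:
    frame = pd.DataFrame(
        {
            "tnt_pmol_g": [0.0, 1.2, 0.03],
            "met_2-ADNT": [0.0, 0.5, 0.8],
            "met_4-ADNT": [0.0, 0.2, 0.0],
            "env_mud": [55.0, 20.0, 40.0],
            "env_tn": [0.11, 0.05, 0.09],
            "cruise": ["c1", "c1", "c2"],
            "experiment": ["e1", "e1", "e1"],
            "area": ["a1", "a1", "a2"],
            "lat": [54.51, 54.512, 54.52],
            "lon": [10.32, 10.321, 10.33],
            "date": ["2017-06-15"] * 3,
            "replicate_group": ["S1", "S2", "S3"],
        },
        index=["S1", "S2", "S3"],
    )
    return SampleTable(
        frame,
        env_columns=["env_mud", "env_tn"],
        metabolite_columns=["met_2-ADNT", "met_4-ADNT"],
    )


@pytest.fixture(scope="session")
def small_dataset() -> synthdata.SyntheticDataset:
    """A reduced synthetic dataset shared across fast tests."""
    return synthdata.generate(
        synthdata.SynthConfig(n_samples=60, n_taxa=120, n_indicator_taxa=10, seed=11)
    )


@pytest.fixture(scope="session")
def small_features(small_dataset):
    averaged = curation.average_replicates(
        small_dataset.community, small_dataset.samples
    )
    response = curation.binarize_response(small_dataset.samples)
    fm = evaluate.build_input_features(averaged, small_dataset.taxonomy, 0.08, "asv")
    return fm, response


def separable_data(n: int = 40, p: int = 5, seed: int = 0):
    """A dataset with one perfectly separating feature."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"s{i:02d}" for i in range(n)],
        columns=[f"f{j}" for j in range(p)],
    )
    y = pd.Series(["present" if i % 2 else "absent" for i in range(n)], index=X.index)
    X["f0"] = np.where(y == "present", 5.0, -5.0) + rng.normal(0, 0.1, n)
    return X, y
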