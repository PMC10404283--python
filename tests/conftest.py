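import numpy as np
import pandas as pd
import pytest

import beetlenet as bn


@pytest.fixture
def toy_survey_df() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s2", "s2"],
            "species_id": ["spA", "spB", "spA", "spB"],
            "count": [2, 1, 4, 3],
            "biomass": [20.0, 5.0, 44.0, 12.0],
        }
    )


@pytest.fixture
def toy_survey(toy_survey_df) -> bn.SurveyTable:
    return bn.SurveyTable(toy_survey_df)


@pytest.fixture(scope="session")
def planted_500():
    """One mid-size planted community shared by the heavier inference tests."""
    spec = bn.PlantedCommunitySpec(n_samples=500, seed=7)
    survey, species_meta, sample_meta, truth = bn.make_planted_community(spec)
    matrix = bn.build_biomass_matrix(survey, value_kind="biomass")
    return spec, matrix, species_meta, truth


def random_graph(n_nodes: int, p_edge: float, seed: int):
    """Seeded Erdos-Renyi graph with string node labels."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(f"v{i}" for i in range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(f"v{i}", f"v{j}")
    return g
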