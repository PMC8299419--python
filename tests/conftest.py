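import pandas as pd
import pytest
from hypothesis import settings

from lifecor.scoring import ScoreTable, pass_column

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
from lifecor.simulate import SyntheticConfig, generate_panel


def make_score_table(dataset_id, r_by_gene, thresholds=(0.4, 0.7)):
    """Build a gene-level ScoreTable from a gene -> r mapping (NaN allowed)."""
    df = pd.DataFrame({"r": pd.Series(r_by_gene, dtype=float)})
    df["slope"] = df["r"] * 100.0
    df["n_used"] = 8
    for t in thresholds:
        df[pass_column(t)] = df["r"].abs() >= t
    return ScoreTable(dataset_id=dataset_id, scores=df,
                      thresholds=tuple(thresholds), key="gene")


@pytest.fixture(scope="session")
def small_panel():
    """A compact 4-dataset panel with the two default planted genes."""
    cfg = SyntheticConfig.with_default_planted(
        n_strains=30, strains_per_dataset=20, n_datasets=4,
        n_features_per_dataset=120, seed=11,
    )
    datasets, lifespans, truth = generate_panel(cfg)
    return cfg, datasets, lifespans, truth
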