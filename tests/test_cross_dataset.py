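import numpy as np
import pandas as pd
import pytest

from lifecor.cross_dataset import (
    overlap_matrix,
    presence_histogram,
    shared_gene_ranking,
    sign_pattern_matrix,
)
from lifecor.scoring import score_dataset
from lifecor.selection import match_strains, select_extremes
from tests.conftest import make_score_table


class TestOverlapMatrix:
    def test_jaccard_of_partially_overlapping_hit_sets(self):
        a = make_score_table("A", {"g1": 0.5, "g2": 0.6, "g3": 0.7, "g4": 0.1})
        b = make_score_table("B", {"g1": 0.1, "g2": -0.5, "g3": 0.5, "g4": 0.9})
        om = overlap_matrix([a, b], threshold=0.4)
        # hits A={g1,g2,g3}, B={g2,g3,g4}; intersection 2, union 4
        assert om.fraction.loc["A", "B"] == pytest.approx(0.5)
        assert om.intersection.loc["A", "B"] == 2
        assert om.union.loc["A", "B"] == 4

    def test_identical_hit_sets_give_one(self):
        a = make_score_table("A", {"g1": 0.5, "g2": 0.1})
        b = make_score_table("B", {"g1": -0.8, "g2": 0.2})
        om = overlap_matrix([a, b], threshold=0.4)
        assert om.fraction.loc["A", "B"] == 1.0
        assert om.fraction.loc["A", "A"] == 1.0

    def test_disjoint_hit_sets_give_zero(self):
        a = make_score_table("A", {"g1": 0.5, "g2": 0.0})
        b = make_score_table("B", {"g1": 0.0, "g2": 0.5})
        assert overlap_matrix([a, b], 0.4).fraction.loc["A", "B"] == 0.0

    def test_restricted_to_shared_measured_universe(self):
        # g3 is unmeasured in B, so it cannot count against the pair
        a = make_score_table("A", {"g1": 0.5, "g2": 0.5, "g3": 0.9})
        b = make_score_table("B", {"g1": 0.5, "g2": 0.5})
        assert overlap_matrix([a, b], 0.4).fraction.loc["A", "B"] == 1.0

    def test_empty_union_is_undefined_marker(self):
        a = make_score_table("A", {"g1": 0.0})
        b = make_score_table("B", {"g1": 0.1})
        assert np.isnan(overlap_matrix([a, b], 0.4).fraction.loc["A", "B"])

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        tables = [
            make_score_table(f"D{i}", {f"g{j}": rng.uniform(-1, 1)
                                       for j in range(30)})
            for i in range(3)
        ]
        om = overlap_matrix(tables, 0.4)
        pd.testing.assert_frame_equal(om.fraction, om.fraction.T,
                                      check_names=False)

    def test_requires_two_tables(self):
        with pytest.raises(ValueError):
            overlap_matrix([make_score_table("A", {"g1": 0.5})], 0.4)


class TestSharedGeneRanking:
    def test_presence_outranks_mean_abs_r(self):
        tables = [
            make_score_table("D1", {"X": 0.6, "Y": 0.9}),
            make_score_table("D2", {"X": -0.6, "Y": 0.9}),
            make_score_table("D3", {"X": 0.6, "Y": 0.1}),
        ]
        ranking = shared_gene_ranking(tables, 0.4)
        assert list(ranking.index) == ["X", "Y"]
        assert ranking.loc["X", "presence_count"] == 3
        assert ranking.loc["Y", "presence_count"] == 2
        assert ranking.loc["X", "mean_abs_r"] == pytest.approx(0.6)
        assert ranking.loc["Y", "mean_abs_r"] == pytest.approx(0.9)

    def test_signed_r_retained_and_failures_masked(self):
        tables = [
            make_score_table("D1", {"X": 0.6}),
            make_score_table("D2", {"X": -0.6}),
            make_score_table("D3", {"X": 0.2}),
        ]
        row = shared_gene_ranking(tables, 0.4).loc["X"]
        assert row["r_D1"] == 0.6 and row["r_D2"] == -0.6
        assert np.isnan(row["r_D3"])  # measured but failing
        assert row["n_measured"] == 3

    def test_unmeasured_gene_excluded_from_denominator(self):
        tables = [
            make_score_table("D1", {"X": 0.6}),
            make_score_table("D2", {"Y": 0.6}),
        ]
        ranking = shared_gene_ranking(tables, 0.4)
        assert ranking.loc["X", "n_measured"] == 1
        assert np.isnan(ranking.loc["X", "r_D2"])

    def test_nothing_passing_gives_zero_presence(self):
        tables = [make_score_table("D1", {"X": 0.1, "Y": 0.2})]
        ranking = shared_gene_ranking(tables, 0.4)
        assert (ranking["presence_count"] == 0).all()

    def test_gene_id_breaks_exact_ties(self):
        tables = [make_score_table("D1", {"b": 0.5, "a": 0.5, "c": -0.5})]
        assert list(shared_gene_ranking(tables, 0.4).index) == ["a", "b", "c"]


class TestPresenceHistogram:
    def test_counts_per_presence_value(self):
        tables = [
            make_score_table(f"D{i}", {"X": 0.9, "Y": 0.9 if i < 2 else 0.0,
                                       "Z": 0.0})
            for i in range(3)
        ]
        ranking = shared_gene_ranking(tables, 0.4)
        hist = presence_histogram(ranking, 3)
        assert hist.to_dict() == {0: 1, 1: 0, 2: 1, 3: 1}

    def test_sums_to_number_of_ranked_genes(self):
        rng = np.random.default_rng(1)
        tables = [
            make_score_table(f"D{i}", {f"g{j}": rng.uniform(-1, 1)
                                       for j in range(50)})
            for i in range(4)
        ]
        ranking = shared_gene_ranking(tables, 0.4)
        assert presence_histogram(ranking, 4).sum() == len(ranking)

    def test_empty_ranking_gives_all_zero(self):
        ranking = shared_gene_ranking([make_score_table("D1", {})], 0.4)
        hist = presence_histogram(ranking, 1)
        assert (hist == 0).all()


class TestSignPatternMatrix:
    def test_mixed_sign_universal_gene_pattern(self):
        tables = [
            make_score_table(f"D{i}", {"U": 0.9 if i < 4 else -0.9})
            for i in range(8)
        ]
        patterns = sign_pattern_matrix(shared_gene_ranking(tables, 0.4), 5)
        row = patterns.loc["U"]
        assert (row.iloc[:4] > 0).all() and (row.iloc[4:] < 0).all()

    def test_unmeasured_is_missing_marker_never_zero(self):
        tables = [
            make_score_table("D1", {"U": 0.9}),
            make_score_table("D2", {"V": 0.9}),
        ]
        patterns = sign_pattern_matrix(shared_gene_ranking(tables, 0.4), 10)
        assert np.isnan(patterns.loc["U", "r_D2"])
        assert (patterns.to_numpy(na_value=1.0) != 0).all()

    def test_top_n_limits_rows(self):
        tables = [make_score_table("D1", {f"g{i}": 0.5 for i in range(20)})]
        ranking = shared_gene_ranking(tables, 0.4)
        assert len(sign_pattern_matrix(ranking, 10)) == 10
        with pytest.raises(ValueError):
            sign_pattern_matrix(ranking, 0)


class TestThresholdMonotonicity:
    def test_presence_and_overlap_never_increase_with_threshold(self, small_panel):
        cfg, datasets, lifespans, _ = small_panel
        tables = []
        for ds in datasets:
            plan = select_extremes(match_strains(ds, lifespans), mode="tails")
            tables.append(score_dataset(ds, plan))
        low = shared_gene_ranking(tables, 0.4)["presence_count"]
        high = shared_gene_ranking(tables, 0.7)["presence_count"]
        assert (high.reindex(low.index, fill_value=0) <= low).all()
        om_low = overlap_matrix(tables, 0.4)
        om_high = overlap_matrix(tables, 0.7)
        assert (om_high.intersection.to_numpy()
                <= om_low.intersection.to_numpy()).all()
        assert (om_high.union.to_numpy() <= om_low.union.to_numpy()).all()

    def test_null_presence_counts_track_binomial_composition(self):
        # background-only panel: presence ~ Bin(n_datasets, p0) with p0 the
        # analytic null pass rate at |r| >= 0.4 over 8 strains (~0.33)
        from scipy import stats

        from lifecor.simulate import SyntheticConfig, generate_panel

        cfg = SyntheticConfig(n_strains=8, strains_per_dataset=8,
                              n_datasets=4, n_features_per_dataset=800,
                              seed=17)
        datasets, lifespans, _ = generate_panel(cfg)
        tables = []
        for ds in datasets:
            plan = select_extremes(match_strains(ds, lifespans), mode="tails")
            tables.append(score_dataset(ds, plan))
        ranking = shared_gene_ranking(tables, 0.4)
        t0 = 0.4 * np.sqrt(6 / (1 - 0.16))
        p0 = 2 * stats.t.sf(t0, df=6)
        observed = ranking["presence_count"].mean()
        expected = 4 * p0
        # binomial mean, MC slack: sd of the mean ~ sqrt(4*p0*(1-p0)/800)
        assert observed == pytest.approx(expected, abs=0.12)
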