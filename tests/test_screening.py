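import numpy as np
import pandas as pd
import pytest

from oracles import (
    oracle_auc_fine_grid,
    oracle_best_aggregate,
    oracle_borda,
)
from vsbench.screening import (
    RecoveryCurve,
    ScoreTable,
    aggregate_ensemble,
    auc_at_fraction,
    average_duplicate_scores,
    consensus_rank,
    read_score_table,
    recovery_curve,
    retrieved_at_fraction,
)


def table_from(scores, labels=None):
    df = pd.DataFrame(scores)
    lab = pd.Series(labels, index=df.index) if labels is not None else None
    return ScoreTable(scores=df, labels=lab)


def ranked_series(n, actives_first):
    """n ligands with distinct scores; actives (3) either first or last."""
    ids = [f"L{k:03d}" for k in range(n)]
    scores = pd.Series(np.arange(n, dtype=float), index=ids)
    flags = [k < 3 for k in range(n)] if actives_first else [k >= n - 3
                                                             for k in range(n)]
    return scores, pd.Series(flags, index=ids)


class TestAggregateEnsemble:
    def test_single_model_is_identity(self):
        t = table_from({"m1": {"a": -5.0, "b": -2.0}})
        out = aggregate_ensemble(t)
        assert out["a"] == -5.0 and out["b"] == -2.0

    def test_best_takes_minimum(self):
        t = table_from({"m1": {"a": -5.0}, "m2": {"a": -7.2}})
        assert aggregate_ensemble(t)["a"] == -7.2

    def test_matches_brute_force_on_random_table(self, rng):
        df = pd.DataFrame(
            rng.normal(-7, 2, size=(50, 7)),
            index=[f"L{k}" for k in range(50)],
            columns=[f"m{k}" for k in range(7)],
        )
        got = aggregate_ensemble(ScoreTable(scores=df))
        want = oracle_best_aggregate(df)
        for lig, v in want.items():
            assert got[lig] == pytest.approx(v)

    def test_model_subset_and_unknown_model(self):
        t = table_from({"m1": {"a": -5.0}, "m2": {"a": -7.2}})
        assert aggregate_ensemble(t, models=["m1"])["a"] == -5.0
        with pytest.raises(KeyError):
            aggregate_ensemble(t, models=["nope"])

    def test_all_nan_ligand_rejected(self):
        df = pd.DataFrame({"m1": {"a": -5.0, "b": np.nan}, "m2": {"a": -1.0,
                                                                  "b": -2.0}})
        t = ScoreTable(scores=df)
        with pytest.raises(ValueError):
            aggregate_ensemble(t, models=["m1"])


class TestRecoveryCurve:
    def test_all_actives_first(self):
        scores, labels = ranked_series(30, actives_first=True)
        c = recovery_curve(scores, labels)
        assert c.fractions[0] == 0.0 and c.recovered[0] == 0.0
        assert c.recovered[3] == 1.0  # after 3 ligands = fraction 0.1
        assert c.recovered[-1] == 1.0 and c.fractions[-1] == 1.0

    def test_all_actives_last(self):
        scores, labels = ranked_series(30, actives_first=False)
        c = recovery_curve(scores, labels)
        assert np.all(c.recovered[: 30 - 3 + 1] == 0.0)

    def test_invariant_under_monotone_score_transform(self, screen_231):
        agg = aggregate_ensemble(screen_231)
        c1 = recovery_curve(agg, screen_231.labels)
        c2 = recovery_curve(np.exp(agg / 3.0), screen_231.labels)
        np.testing.assert_allclose(c1.recovered, c2.recovered)

    def test_needs_both_classes(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            recovery_curve(s, pd.Series([True, True], index=["a", "b"]))
        with pytest.raises(ValueError):
            recovery_curve(s, pd.Series([False, False], index=["a", "b"]))

    def test_full_retrieval_scenario_at_ten_percent(self):
        # 7 peptide actives all inside the top 10% of a 231-ligand ranking
        ids = [f"L{k:03d}" for k in range(231)]
        scores = pd.Series(np.arange(231, dtype=float), index=ids)
        labels = pd.Series([k < 7 for k in range(231)], index=ids)
        c = recovery_curve(scores, labels)
        assert float(np.interp(0.1, c.fractions, c.recovered)) == 1.0
        assert retrieved_at_fraction(scores, labels, 0.1) == 7


class TestAucAtFraction:
    def test_worst_ranking_zero_area(self):
        scores, labels = ranked_series(100, actives_first=False)
        c = recovery_curve(scores, labels)
        assert auc_at_fraction(c, 0.1) == 0.0

    def test_perfect_ranking_matches_fine_grid_oracle(self):
        ids = [f"L{k:03d}" for k in range(231)]
        scores = pd.Series(np.arange(231, dtype=float), index=ids)
        labels = pd.Series([k < 11 for k in range(231)], index=ids)
        c = recovery_curve(scores, labels)
        got = auc_at_fraction(c, 0.1)
        want = oracle_auc_fine_grid(c.fractions, c.recovered, 0.1)
        assert got == pytest.approx(want, abs=1e-6)
        assert auc_at_fraction(c, 0.1, "ideal", n_actives=11) == pytest.approx(1.0)

    def test_random_curves_match_fine_grid_oracle(self, rng):
        for _ in range(5):
            ids = [f"L{k}" for k in range(60)]
            scores = pd.Series(rng.normal(size=60), index=ids)
            labels = pd.Series(rng.random(60) < 0.2, index=ids)
            if not labels.any() or labels.all():
                continue
            c = recovery_curve(scores, labels)
            for x in (0.1, 0.37, 1.0):
                assert auc_at_fraction(c, x) == pytest.approx(
                    oracle_auc_fine_grid(c.fractions, c.recovered, x), abs=1e-6
                )

    def test_bounds_and_monotonicity_in_x(self, screen_231):
        agg = aggregate_ensemble(screen_231)
        c = recovery_curve(agg, screen_231.labels)
        prev = 0.0
        for x in (0.05, 0.1, 0.3, 0.7, 1.0):
            a = auc_at_fraction(c, x)
            assert 0.0 <= a <= x
            assert a >= prev
            prev = a
            n = auc_at_fraction(c, x, "ideal", n_actives=int(screen_231.labels.sum()))
            assert 0.0 <= n <= 1.0

    def test_invalid_fraction(self, screen_231):
        agg = aggregate_ensemble(screen_231)
        c = recovery_curve(agg, screen_231.labels)
        with pytest.raises(ValueError):
            auc_at_fraction(c, 0.0)


class TestRetrievedAtFraction:
    def test_counts_match_direct_oracle(self, rng):
        ids = [f"L{k}" for k in range(120)]
        scores = pd.Series(rng.normal(size=120), index=ids)
        labels = pd.Series(rng.random(120) < 0.15, index=ids)
        k = int(np.ceil(0.1 * 120))
        order = scores.sort_values().index
        want = int(labels.loc[order[:k]].sum())
        assert retrieved_at_fraction(scores, labels, 0.1) == want


class TestAverageDuplicateScores:
    def test_mean_of_two_states(self):
        rows = pd.DataFrame(
            {"parent_id": ["A", "A"], "variant_id": ["A.1", "A.2"],
             "score": [-8.0, -6.0]}
        )
        out = average_duplicate_scores(rows)
        assert out["A"] == -7.0

    def test_identity_without_duplicates(self):
        rows = pd.DataFrame(
            {"parent_id": ["A", "B"], "variant_id": ["A.1", "B.1"],
             "score": [-8.0, -6.0]}
        )
        out = average_duplicate_scores(rows)
        assert list(out.index) == ["A", "B"]
        assert out.tolist() == [-8.0, -6.0]

    def test_collapses_to_unique_parent_count(self, rng):
        parents = [f"P{k:03d}" for k in range(115)]
        rows = []
        for v in range(500):
            p = parents[int(rng.integers(0, 115))]
            rows.append({"parent_id": p, "variant_id": f"{p}.{v}",
                         "score": float(rng.normal(-7, 1))})
        df = pd.DataFrame(rows)
        out = average_duplicate_scores(df)
        assert len(out) == df["parent_id"].nunique()

    def test_non_finite_score_rejected(self):
        rows = pd.DataFrame(
            {"parent_id": ["A"], "variant_id": ["A.1"], "score": [np.nan]}
        )
        with pytest.raises(ValueError):
            average_duplicate_scores(rows)


class TestConsensusRank:
    def test_identical_rankings_unchanged(self):
        r = pd.Series([1, 2, 3], index=["x", "y", "z"], dtype=float)
        out = consensus_rank(r, r)
        assert list(out.index) == ["x", "y", "z"]
        assert out["rank"].tolist() == [1, 2, 3]

    def test_reversed_rankings_tie_to_lexicographic(self):
        ids = ["delta", "alpha", "charlie", "bravo"]
        ra = pd.Series([1, 2, 3, 4], index=ids, dtype=float)
        rb = pd.Series([4, 3, 2, 1], index=ids, dtype=float)
        out = consensus_rank(ra, rb)
        assert np.all(out["mean_rank"] == 2.5)
        assert list(out.index) == ["alpha", "bravo", "charlie", "delta"]

    def test_matches_borda_oracle(self, rng):
        ids = [f"L{k:02d}" for k in range(25)]
        ra = pd.Series(rng.permutation(25) + 1.0, index=ids)
        rb = pd.Series(rng.permutation(25) + 1.0, index=ids)
        out = consensus_rank(ra, rb)
        assert list(out.index) == oracle_borda(ra, rb)

    def test_mismatched_sets_report_difference(self):
        ra = pd.Series([1.0], index=["a"])
        rb = pd.Series([1.0], index=["b"])
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            consensus_rank(ra, rb)


class TestScoreTableIO:
    def test_long_csv_round_trip(self, tmp_path, screen_231):
        long = screen_231.scores.stack().rename("score").reset_index()
        long.columns = ["ligand_id", "model_id", "score"]
        long["label"] = long["ligand_id"].map(
            lambda i: "active" if screen_231.labels[i] else "decoy"
        )
        path = tmp_path / "scores.csv"
        long.to_csv(path, index=False)
        back = read_score_table(path)
        assert back.scores.shape == screen_231.scores.shape
        assert int(back.labels.sum()) == int(screen_231.labels.sum())
        np.testing.assert_allclose(
            back.scores.loc[screen_231.scores.index, screen_231.scores.columns],
            screen_231.scores,
            rtol=1e-12,
        )

    def test_curve_coordinate_validation(self):
        with pytest.raises(ValueError):
            RecoveryCurve(fractions=np.array([0.0, 0.5, 0.4]),
                          recovered=np.array([0.0, 0.5, 1.0]))
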