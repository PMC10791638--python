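"""Node metrics, age regressions, and the cohort paired comparison."""

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_symmetric
from coroost import metrics
from coroost.association import AssociationMatrix


def as_assoc(M, bats=None, year=None):
    n = M.shape[0]
    bats = bats or [f"B{i:02d}" for i in range(n)]
    x = (np.asarray(M) > 0).astype(np.int64)
    zeros = np.zeros((n, n), dtype=np.int64)
    return AssociationMatrix(
        bats=list(bats), sri=np.asarray(M, float), x=x, y_ab=zeros, y_a=zeros, year=year
    )


def roster_frame(rows):
    return pd.DataFrame(
        rows, columns=["tag_id", "sex", "age_class_at_capture", "capture_year", "cohort_year"]
    )


class TestDegree:
    def test_isolated_and_saturated(self):
        M = np.zeros((4, 4))
        A = as_assoc(M)
        assert metrics.node_degree(A, A.bats[0]) == 0
        M2 = random_symmetric(4, np.random.default_rng(0), low=0.1)
        A2 = as_assoc(M2)
        assert metrics.node_degree(A2, A2.bats[0]) == 3

    def test_absent_bat_fatal(self):
        A = as_assoc(np.zeros((3, 3)))
        with pytest.raises(KeyError):
            metrics.node_degree(A, "nope")

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            M = random_symmetric(8, rng)
            M[M < 0.5] = 0.0
            A = as_assoc(M)
            for i, bat in enumerate(A.bats):
                expected = sum(1 for j in range(8) if j != i and M[i, j] > 0)
                assert metrics.node_degree(A, bat) == expected


class TestBetweenness:
    def test_path_graph_center(self):
        M = np.array([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]])
        bc = metrics.betweenness_centrality(as_assoc(M))
        assert bc["B01"] == 1.0
        assert bc["B00"] == bc["B02"] == 0.0

    def test_complete_graph_all_zero(self):
        M = random_symmetric(5, np.random.default_rng(2), low=0.1)
        bc = metrics.betweenness_centrality(as_assoc(M))
        assert all(v == 0.0 for v in bc.values())

    @pytest.mark.parametrize("seed", range(25))
    def test_binary_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        M = random_symmetric(n, rng)
        M[M < 0.6] = 0.0  # sparse, possibly disconnected
        A = as_assoc(M)
        bc = metrics.betweenness_centrality(A)
        adj = (M > 0).tolist()
        expected = oracles.brute_betweenness(adj)
        for i, bat in enumerate(A.bats):
            assert bc[bat] == pytest.approx(expected[i], abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_weighted_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(3, 7))
        M = random_symmetric(n, rng)
        M[M < 0.4] = 0.0
        A = as_assoc(M)
        bc = metrics.betweenness_centrality(A, mode="weighted")
        weights = [
            [1.0 / M[i][j] if M[i][j] > 0 else 0.0 for j in range(n)] for i in range(n)
        ]
        expected = oracles.brute_weighted_betweenness(weights)
        for i, bat in enumerate(A.bats):
            assert bc[bat] == pytest.approx(expected[i], abs=1e-9)


class TestCVSRI:
    def test_equal_positive_values_give_zero(self):
        M = np.full((4, 4), 0.3)
        np.fill_diagonal(M, 0.0)
        A = as_assoc(M)
        assert metrics.cv_sri(A, A.bats[0]) == pytest.approx(0.0)

    def test_hand_computation(self):
        M = np.zeros((4, 4))
        M[0, 1:] = M[1:, 0] = [0.4, 0.0, 0.2]
        A = as_assoc(M)
        vals = np.array([0.4, 0.0, 0.2])
        expected = vals.std(ddof=1) / vals.mean()
        assert metrics.cv_sri(A, A.bats[0]) == pytest.approx(expected)

    def test_zero_mean_undefined(self):
        A = as_assoc(np.zeros((3, 3)))
        assert np.isnan(metrics.cv_sri(A, A.bats[0]))

    def test_exclude_zeros_flag(self):
        M = np.zeros((4, 4))
        M[0, 1:] = M[1:, 0] = [0.4, 0.0, 0.2]
        A = as_assoc(M)
        vals = np.array([0.4, 0.2])
        expected = vals.std(ddof=1) / vals.mean()
        assert metrics.cv_sri(A, A.bats[0], include_zeros=False) == pytest.approx(
            expected
        )


class TestNodeMetricTable:
    def test_unknown_age_bats_shape_topology_not_rows(self):
        # metrics computed on the full network, rows only for known-aged
        M = np.array(
            [
                [0, 0.5, 0, 0],
                [0.5, 0, 0.5, 0],
                [0, 0.5, 0, 0.5],
                [0, 0, 0.5, 0],
            ]
        )
        bats = ["K1", "U1", "K2", "U2"]
        A = as_assoc(M, bats=bats, year=2016)
        roster = roster_frame(
            [
                ("K1", "F", "juvenile", 2014, 2014),
                ("K2", "F", "juvenile", 2013, 2013),
                ("U1", "F", "adult", 2014, np.nan),
                ("U2", "F", "adult", 2014, np.nan),
            ]
        )
        rows = metrics.node_metric_table({2016: A}, roster)
        assert set(rows["tag_id"]) == {"K1", "K2"}
        # K2's betweenness comes from paths through U bats
        k2 = rows.loc[rows["tag_id"] == "K2"].iloc[0]
        full_bc = metrics.betweenness_centrality(A)
        assert k2["betweenness"] == full_bc["K2"] > 0
        assert k2["exact_age"] == 3


class TestAgeRegression:
    def test_exact_linear_metric(self):
        rows = pd.DataFrame(
            {
                "tag_id": [f"B{i}" for i in range(10)],
                "year": 2016,
                "exact_age": list(range(1, 11)),
                "degree": [2 * a for a in range(1, 11)],
                "betweenness": 0.0,
                "cv_sri": 0.0,
            }
        )
        reg = metrics.age_metric_regression(rows, "degree")
        assert reg.slope == pytest.approx(2.0)
        assert reg.p_value < 1e-10
        assert reg.n_per_age == {a: 1 for a in range(1, 11)}

    def test_zero_age_variance_fatal(self):
        rows = pd.DataFrame(
            {
                "tag_id": ["A", "B", "C"],
                "year": 2016,
                "exact_age": [2, 2, 2],
                "degree": [1, 2, 3],
                "betweenness": 0.0,
                "cv_sri": 0.0,
            }
        )
        with pytest.raises(ValueError, match="variance"):
            metrics.age_metric_regression(rows, "degree")

    def test_null_metric_p_is_calibrated(self):
        # age-independent metric: slope p-values uniform, ~5% rejections
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            rows = pd.DataFrame(
                {
                    "tag_id": [f"B{i}" for i in range(30)],
                    "year": 2016,
                    "exact_age": rng.integers(1, 8, size=30),
                    "degree": rng.normal(size=30),
                    "betweenness": 0.0,
                    "cv_sri": 0.0,
                }
            )
            reg = metrics.age_metric_regression(rows, "degree")
            rejections += reg.p_value < 0.05
        # 99% binomial CI around 0.05 for 300 replicates
        assert 0.017 <= rejections / n_rep <= 0.083


class TestCohortPairedTest:
    @staticmethod
    def make_network(sri_same, sri_diff, n_per_cohort=4):
        # two cohorts; within-cohort SRI sri_same, between sri_diff
        n = 2 * n_per_cohort
        M = np.full((n, n), sri_diff)
        M[:n_per_cohort, :n_per_cohort] = sri_same
        M[n_per_cohort:, n_per_cohort:] = sri_same
        np.fill_diagonal(M, 0.0)
        bats = [f"B{i:02d}" for i in range(n)]
        roster = roster_frame(
            [
                (b, "F", "juvenile", 2014 if i < n_per_cohort else 2013,
                 2014 if i < n_per_cohort else 2013)
                for i, b in enumerate(bats)
            ]
        )
        return as_assoc(M, bats=bats, year=2016), roster

    def test_identical_within_among_gives_t_zero_p_one(self):
        A, roster = self.make_network(0.3, 0.3)
        res = metrics.cohort_paired_test({2016: A}, roster)
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0
        assert res.df == 7

    def test_assortative_network_detected(self):
        rng = np.random.default_rng(4)
        A, roster = self.make_network(0.6, 0.1)
        A.sri += rng.normal(0, 0.01, A.sri.shape)
        A.sri = (A.sri + A.sri.T) / 2
        np.fill_diagonal(A.sri, 0.0)
        res = metrics.cohort_paired_test({2016: A}, roster)
        assert res.t_statistic > 0
        assert res.p_value < 0.01
        assert (res.per_bat["mean_within"] > res.per_bat["mean_among"]).all()

    def test_starts_first_year_with_enough_known_aged(self):
        A1, roster = self.make_network(0.3, 0.3)
        # year 2015 network contains no known-aged bats
        M = random_symmetric(4, np.random.default_rng(5))
        A0 = as_assoc(M, bats=["U1", "U2", "U3", "U4"], year=2015)
        roster = pd.concat(
            [
                roster,
                roster_frame(
                    [(f"U{i}", "F", "adult", 2014, np.nan) for i in range(1, 5)]
                ),
            ],
            ignore_index=True,
        )
        res = metrics.cohort_paired_test({2015: A0, 2016: A1}, roster)
        assert res.start_year == 2016

    def test_no_qualifying_bats_fatal(self):
        M = random_symmetric(4, np.random.default_rng(6))
        A = as_assoc(M, bats=["U1", "U2", "U3", "U4"], year=2016)
        roster = roster_frame(
            [(f"U{i}", "F", "adult", 2014, np.nan) for i in range(1, 5)]
        )
        with pytest.raises(ValueError):
            metrics.cohort_paired_test({2016: A}, roster)
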