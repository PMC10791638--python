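"""Mantel tests, MRQAP-DSP, matrix scaling, fold differences."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_symmetric
from coroost import inference
from coroost.association import AssociationMatrix
from coroost.inference import COOCCURRENCE, PREV_ASSOCIATION


def as_assoc(M, bats=None, year=None):
    n = M.shape[0]
    bats = bats or [f"B{i:02d}" for i in range(n)]
    zeros = np.zeros((n, n), dtype=np.int64)
    return AssociationMatrix(
        bats=list(bats), sri=M, x=zeros, y_ab=zeros, y_a=zeros, year=year
    )


class TestScaleMatrix:
    def test_zero_mean_unit_sd_symmetric(self):
        rng = np.random.default_rng(0)
        M = random_symmetric(10, rng)
        Z = inference.scale_matrix(M)
        off = Z[~np.eye(10, dtype=bool)]
        assert abs(off.mean()) < 1e-12
        assert off.std(ddof=1) == pytest.approx(1.0)
        np.testing.assert_allclose(Z, Z.T)
        assert np.all(np.diag(Z) == 0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        M = random_symmetric(8, rng)
        Z1 = inference.scale_matrix(M)
        Z2 = inference.scale_matrix(3.5 * M + 2.0)
        np.testing.assert_allclose(Z1, Z2, atol=1e-12)

    def test_two_value_matrix_matches_hand_zscore(self):
        M = np.array(
            [[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=float
        )
        Z = inference.scale_matrix(M)
        vals = np.array([1, 0, 0, 1, 0, 0], dtype=float)
        z = (vals - vals.mean()) / vals.std(ddof=1)
        assert Z[0, 1] == pytest.approx(z[0])
        assert Z[0, 2] == pytest.approx(z[1])

    def test_constant_matrix_fatal(self):
        with pytest.raises(ValueError):
            inference.scale_matrix(np.ones((4, 4)))


class TestMantel:
    def test_identity_r_one_minimal_p(self):
        rng = np.random.default_rng(2)
        M = random_symmetric(12, rng)
        res = inference.mantel_test(M, M.copy(), n_perm=99, rng=rng)
        assert res.r == pytest.approx(1.0)
        assert res.p_two_tailed == pytest.approx(1 / 100)

    def test_anti_identity_r_minus_one(self):
        rng = np.random.default_rng(3)
        M = random_symmetric(10, rng)
        res = inference.mantel_test(M, -M + 2.0, n_perm=99, rng=rng)
        assert res.r == pytest.approx(-1.0)

    def test_constant_matrix_reported_na(self):
        rng = np.random.default_rng(4)
        M = random_symmetric(6, rng)
        res = inference.mantel_test(M, np.ones((6, 6)) - np.eye(6), n_perm=99, rng=rng)
        assert np.isnan(res.r) and np.isnan(res.p_two_tailed)

    def test_misaligned_indices_fatal(self):
        rng = np.random.default_rng(5)
        A = as_assoc(random_symmetric(5, rng), bats=list("ABCDE"))
        B = as_assoc(random_symmetric(5, rng), bats=list("ABCDF"))
        with pytest.raises(ValueError, match="aligned"):
            inference.mantel_test(A, B, n_perm=9)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        A, B = random_symmetric(10, rng), random_symmetric(10, rng)
        r1 = inference.mantel_test(A, B, n_perm=199, rng=np.random.default_rng(42))
        r2 = inference.mantel_test(A, B, n_perm=199, rng=np.random.default_rng(42))
        assert r1 == r2

    def test_spearman_option_is_rank_based(self):
        rng = np.random.default_rng(7)
        M = random_symmetric(8, rng)
        res = inference.mantel_test(
            M, np.exp(4 * M), n_perm=99, rng=rng, method="spearman"
        )
        assert res.r == pytest.approx(1.0)  # monotone transform

    def test_agrees_with_skbio_oracle(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(8)
        for _ in range(5):
            A, B = random_symmetric(9, rng), random_symmetric(9, rng)
            ours = inference.mantel_test(A, B, n_perm=99, rng=rng)
            r_ref, p_ref, _ = skbio_distance.mantel(
                skbio_distance.DistanceMatrix(A),
                skbio_distance.DistanceMatrix(B),
                method="pearson",
                permutations=0,
            )
            assert ours.r == pytest.approx(float(r_ref), abs=1e-12)


class TestAlignYears:
    def test_identical_indices_unchanged(self):
        rng = np.random.default_rng(9)
        A = as_assoc(random_symmetric(5, rng))
        B = as_assoc(random_symmetric(5, rng))
        out = inference.align_years(A, B)
        assert out is not None
        assert out[2] == A.bats

    def test_disjoint_indices_skipped(self):
        rng = np.random.default_rng(10)
        A = as_assoc(random_symmetric(4, rng), bats=list("ABCD"))
        B = as_assoc(random_symmetric(4, rng), bats=list("EFGH"))
        assert inference.align_years(A, B) is None

    def test_partial_overlap_count(self):
        rng = np.random.default_rng(11)
        A = as_assoc(random_symmetric(6, rng), bats=list("ABCDEF"))
        B = as_assoc(random_symmetric(6, rng), bats=list("DEFGHI"))
        out = inference.align_years(A, B)
        assert out is not None and out[2] == ["D", "E", "F"]
        assert out[0].n_bats == 3


class TestMRQAP:
    def test_identity_regression(self):
        rng = np.random.default_rng(12)
        M = random_symmetric(10, rng)
        res = inference.mrqap_dsp(M, {"x1": M.copy()}, n_perm=99, rng=rng)
        assert res.coefficients["x1"] == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_point_estimates_match_closed_form(self):
        rng = np.random.default_rng(13)
        n = 15
        Y = random_symmetric(n, rng)
        X1, X2 = random_symmetric(n, rng), random_symmetric(n, rng)
        res = inference.mrqap_dsp(Y, {"a": X1, "b": X2}, n_perm=19, rng=rng)
        iu = np.triu_indices(n, k=1)
        y = inference.scale_matrix(Y)[iu]
        D = np.column_stack(
            [np.ones(len(y)), inference.scale_matrix(X1)[iu], inference.scale_matrix(X2)[iu]]
        )
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert res.coefficients["a"] == pytest.approx(beta[1], abs=1e-8)
        assert res.coefficients["b"] == pytest.approx(beta[2], abs=1e-8)

    def test_collinear_predictors_fatal(self):
        rng = np.random.default_rng(14)
        X1 = random_symmetric(8, rng)
        Y = random_symmetric(8, rng)
        with pytest.raises(ValueError, match="collinear"):
            inference.mrqap_dsp(Y, {"a": X1, "b": 2.0 * X1 + 1.0}, n_perm=9, rng=rng)

    def test_planted_effects_recovered(self):
        rng = np.random.default_rng(15)
        n = 40
        X1, X2 = random_symmetric(n, rng), random_symmetric(n, rng)
        Z1, Z2 = inference.scale_matrix(X1), inference.scale_matrix(X2)
        noise = random_symmetric(n, rng, low=-1, high=1)
        sd_noise = np.sqrt(max(1.0 - 0.8**2 - 0.1**2, 0.0))
        Y = 0.8 * Z1 + 0.1 * Z2 + sd_noise * inference.scale_matrix(noise)
        res = inference.mrqap_dsp(Y, {"x1": X1, "x2": X2}, n_perm=199, rng=rng)
        assert res.coefficients["x1"] == pytest.approx(0.8, abs=0.06)
        assert res.coefficients["x2"] == pytest.approx(0.1, abs=0.06)
        assert res.p_two_tailed["x1"] < 0.05

    def test_seeded_reproducibility(self):
        rng0 = np.random.default_rng(16)
        Y = random_symmetric(10, rng0)
        X = random_symmetric(10, rng0)
        r1 = inference.mrqap_dsp(Y, {"x": X}, n_perm=99, rng=np.random.default_rng(1))
        r2 = inference.mrqap_dsp(Y, {"x": X}, n_perm=99, rng=np.random.default_rng(1))
        assert r1.p_two_tailed == r2.p_two_tailed

    def test_too_few_bats_fatal(self):
        rng = np.random.default_rng(17)
        with pytest.raises(ValueError):
            inference.mrqap_dsp(
                random_symmetric(3, rng), {"x": random_symmetric(3, rng)}, n_perm=9
            )


class TestFoldDifference:
    @staticmethod
    def result(prev, cooc):
        return inference.MRQAPResult(
            predictors=[PREV_ASSOCIATION, COOCCURRENCE],
            coefficients={PREV_ASSOCIATION: prev, COOCCURRENCE: cooc},
            p_two_tailed={PREV_ASSOCIATION: 0.01, COOCCURRENCE: 0.01},
            p_one_tailed={PREV_ASSOCIATION: 0.01, COOCCURRENCE: 0.01},
            r_squared=0.5,
            n_bats=20,
            n_permutations=99,
            focal_year=2017,
            comparison_year=2016,
        )

    def test_direct_ratio(self):
        assert inference.fold_difference(self.result(0.1, 0.8)) == pytest.approx(8.0)

    def test_equal_effects_give_one(self):
        assert inference.fold_difference(self.result(0.4, 0.4)) == pytest.approx(1.0)

    def test_zero_divisor_undefined(self):
        assert inference.fold_difference(self.result(0.0, 0.8)) is None

    def test_missing_predictor_fatal(self):
        res = inference.MRQAPResult(
            predictors=["x"],
            coefficients={"x": 0.5},
            p_two_tailed={"x": 0.1},
            p_one_tailed={"x": 0.1},
            r_squared=0.2,
            n_bats=10,
            n_permutations=9,
        )
        with pytest.raises(ValueError):
            inference.fold_difference(res)


class TestYearGapSummary:
    def test_single_comparison_single_row(self):
        res = inference.MantelResult(0.5, 0.01, 0.01, 99, 20, (2015, 2016))
        df = inference.year_gap_summary(mantel_results=[res])
        assert len(df) == 1
        assert df.iloc[0]["year_gap"] == 1

    def test_mean_per_gap(self):
        rs = [
            inference.MantelResult(0.6, 0.01, 0.01, 99, 20, (2015, 2016)),
            inference.MantelResult(0.4, 0.01, 0.01, 99, 20, (2016, 2017)),
            inference.MantelResult(0.2, 0.01, 0.01, 99, 20, (2015, 2017)),
        ]
        df = inference.year_gap_summary(mantel_results=rs, mean_per_gap=True)
        gap1 = df.loc[df["year_gap"] == 1, "value"].item()
        assert gap1 == pytest.approx(0.5)
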