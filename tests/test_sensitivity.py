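import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spongenet.correlation import CorrelationMatrix, PairSet, pearson_matrix
from spongenet.io import ExpressionMatrix, ValidationError
from spongenet.sensitivity import (
    classify_module,
    partial_correlation,
    scan_triplets,
    scan_triplets_from_correlations,
    select_triplets,
    sensitivity_correlation,
)


def residual_partial_oracle(x, y, z):
    """Partial correlation as the Pearson r of the two Z-regression residuals."""
    zc = z - z.mean()
    rx = (x - x.mean()) - (x - x.mean()) @ zc / (zc @ zc) * zc
    ry = (y - y.mean()) - (y - y.mean()) @ zc / (zc @ zc) * zc
    return rx @ ry / np.sqrt((rx @ rx) * (ry @ ry))


def sample_r(a, b):
    return float(np.corrcoef(a, b)[0, 1])


class TestPartialCorrelation:
    def test_uncorrelated_confounder_leaves_pearson(self):
        assert partial_correlation(0.8, 0.0, 0.0) == pytest.approx(0.8, abs=1e-15)

    def test_fully_mediated_numerator_vanishes(self):
        assert partial_correlation(0.48, -0.8, -0.6) == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_denominator_undefined_not_crash(self):
        assert np.isnan(partial_correlation(0.6, 1.0, 0.5))
        assert np.isnan(partial_correlation(0.6, 0.5, -1.0))

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(200):
            n = 50
            z = rng.standard_normal(n)
            x = rng.uniform(-2, 2) * z + rng.standard_normal(n)
            y = rng.uniform(-2, 2) * z + rng.standard_normal(n)
            formula = partial_correlation(
                sample_r(x, y), sample_r(x, z), sample_r(z, y)
            )
            worst = max(worst, abs(formula - residual_partial_oracle(x, y, z)))
        assert worst < 1e-10

    @given(
        st.floats(-0.99, 0.99),
        st.floats(-0.99, 0.99),
        st.floats(-0.99, 0.99),
    )
    def test_symmetric_in_the_two_confounder_arms(self, r_xy, r_xz, r_zy):
        assert partial_correlation(r_xy, r_xz, r_zy) == partial_correlation(
            r_xy, r_zy, r_xz
        )

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(-0.9, 0.9, (3, 4, 3))
        vec = partial_correlation(r[0], r[1], r[2])
        for i in range(4):
            for j in range(3):
                assert vec[i, j] == partial_correlation(
                    r[0, i, j], r[1, i, j], r[2, i, j]
                )


class TestSensitivity:
    def test_direct_interaction_limit(self):
        assert sensitivity_correlation(0.8, 0.8) == 0.0

    def test_fully_mediated_limit(self):
        assert sensitivity_correlation(0.48, 0.0) == 0.48

    def test_zero_confounder_identity_exact(self):
        # a miRNA uncorrelated with both partners forces S = 0 exactly
        partial = partial_correlation(0.6, 0.0, 0.0)
        assert sensitivity_correlation(0.6, partial) == 0.0

    def test_single_zero_arm_rescales_rather_than_cancels(self):
        # with only one arm zero the denominator still inflates the partial,
        # so S is (mildly) negative, not zero
        partial = partial_correlation(0.8, 0.0, 0.5)
        assert partial == pytest.approx(0.8 / np.sqrt(0.75), abs=1e-15)
        assert sensitivity_correlation(0.8, partial) < 0.0

    def test_undefined_partial_propagates(self):
        assert np.isnan(sensitivity_correlation(0.6, float("nan")))

    @pytest.mark.parametrize("n", [50, 200, 1000])
    def test_pure_sponge_partial_vanishes_at_root_n_rate(self, n):
        """With X independent of Y given Z, sample rho_XY|Z shrinks like 1/sqrt(n)."""
        rng = np.random.default_rng(n)
        partials = []
        for _ in range(40):
            z = rng.standard_normal(n)
            x = -z + rng.standard_normal(n)
            y = -z + rng.standard_normal(n)
            partials.append(
                partial_correlation(sample_r(x, y), sample_r(x, z), sample_r(z, y))
            )
        assert np.mean(np.abs(partials)) < 3.0 / np.sqrt(n)


class TestClassify:
    @pytest.mark.parametrize(
        "r_xz,expected",
        [(-0.4, "pure"), (0.4, "mixed"), (0.0, "ambiguous"), (float("nan"), "undefined")],
    )
    def test_sign_rule(self, r_xz, expected):
        assert classify_module(r_xz) == expected

    def test_undefined_partial_forces_undefined(self):
        assert classify_module(-0.4, float("nan")) == "undefined"


def _pairset(pairs):
    frame = pd.DataFrame(pairs, columns=["mrna", "lncrna", "r"])
    return PairSet(frame, float(frame["r"].min()), 99.0)


def _corr(row_ids, col_ids, r):
    r = np.asarray(r, dtype=float)
    return CorrelationMatrix(row_ids, col_ids, r, None, np.full_like(r, 50, dtype=int))


class TestScanTriplets:
    def test_cardinality_pairs_times_mirnas(self):
        pairs = _pairset([("m1", "l1", 0.8), ("m2", "l2", 0.7)])
        xz = _corr(["m1", "m2"], ["mirA", "mirB", "mirC"], np.zeros((2, 3)))
        zy = _corr(["mirA", "mirB", "mirC"], ["l1", "l2"], np.zeros((3, 2)))
        scan = scan_triplets_from_correlations(pairs, xz, zy)
        assert scan.n_triplets == 6
        assert len(scan.to_frame()) == 6

    def test_mirna_uncorrelated_with_both_partners_gives_zero_s(self):
        pairs = _pairset([("m1", "l1", 0.8)])
        xz = _corr(["m1"], ["mirA"], [[0.0]])
        zy = _corr(["mirA"], ["l1"], [[0.0]])
        scan = scan_triplets_from_correlations(pairs, xz, zy)
        assert scan.s[0, 0] == 0.0

    def test_matrix_scan_equals_per_triplet_formula(self):
        rng = np.random.default_rng(9)
        pairs = _pairset([("m1", "l2", 0.6), ("m2", "l1", 0.5), ("m1", "l1", 0.7)])
        xz = _corr(["m1", "m2"], ["a", "b"], rng.uniform(-0.9, 0.9, (2, 2)))
        zy = _corr(["a", "b"], ["l1", "l2"], rng.uniform(-0.9, 0.9, (2, 2)))
        scan = scan_triplets_from_correlations(pairs, xz, zy)
        frame = scan.to_frame()
        for row in frame.itertuples():
            expected = row.r_xy - partial_correlation(row.r_xy, row.r_xz, row.r_zy)
            assert row.s == pytest.approx(expected, abs=1e-14)
            assert row.s == pytest.approx(row.r_xy - row.partial, abs=1e-12)

    def test_undefined_component_propagates(self):
        pairs = _pairset([("m1", "l1", 0.8)])
        xz = _corr(["m1"], ["mirA"], [[np.nan]])
        zy = _corr(["mirA"], ["l1"], [[0.5]])
        scan = scan_triplets_from_correlations(pairs, xz, zy)
        assert np.isnan(scan.s[0, 0])
        assert scan.to_frame()["module_class"].iloc[0] == "undefined"

    def test_expression_entry_point_matches_correlation_entry_point(self):
        rng = np.random.default_rng(10)
        X = ExpressionMatrix(pd.DataFrame(rng.standard_normal((4, 40)), index=list("wxyz")))
        Y = ExpressionMatrix(pd.DataFrame(rng.standard_normal((3, 40)), index=list("pqr")))
        Z = ExpressionMatrix(pd.DataFrame(rng.standard_normal((2, 40)), index=list("ab")))
        pairs = _pairset([("w", "p", sample_r(X.data.loc["w"], Y.data.loc["p"]))])
        scan = scan_triplets(pairs, X, Y, Z, min_pairs=3)
        xz = pearson_matrix(X.subset_genes(["w"]), Z, min_pairs=3, compute_p=False)
        zy = pearson_matrix(Z, Y.subset_genes(["p"]), min_pairs=3, compute_p=False)
        scan2 = scan_triplets_from_correlations(pairs, xz, zy)
        np.testing.assert_array_equal(scan.s, scan2.s)

    def test_heatmap_layout(self):
        pairs = _pairset([("m1", "l1", 0.8), ("m2", "l2", 0.7)])
        xz = _corr(["m1", "m2"], ["mirA", "mirB"], np.zeros((2, 2)))
        zy = _corr(["mirA", "mirB"], ["l1", "l2"], np.zeros((2, 2)))
        heat = scan_triplets_from_correlations(pairs, xz, zy).to_heatmap()
        assert list(heat.index) == ["m1|l1", "m2|l2"]
        assert list(heat.columns) == ["mirA", "mirB"]


class TestSelectTriplets:
    def _scan_with_scores(self, scores):
        pairs = _pairset([(f"m{i}", f"l{i}", 0.9) for i in range(len(scores))])
        n = len(scores)
        scan = scan_triplets_from_correlations(
            pairs,
            _corr([f"m{i}" for i in range(n)], ["mir"], np.zeros((n, 1))),
            _corr(["mir"], [f"l{i}" for i in range(n)], np.zeros((1, n))),
        )
        scan.s = np.asarray(scores, dtype=float).reshape(n, 1)
        return scan

    def test_fixed_mode_is_strictly_greater(self):
        scan = self._scan_with_scores([0.1, 0.31, 0.6, 0.3])
        sel = select_triplets(scan, mode="fixed", s_threshold=0.3)
        assert sorted(sel.frame["s"]) == [0.31, 0.6]  # 0.3 itself excluded

    def test_percentile_zero_keeps_all(self):
        scan = self._scan_with_scores([0.1, 0.2, 0.3])
        sel = select_triplets(scan, mode="percentile", percentile=0)
        assert len(sel) == 3

    def test_percentile_cutoff_is_order_statistic(self):
        rng = np.random.default_rng(12)
        scores = rng.uniform(-0.2, 0.8, 1000)
        scan = self._scan_with_scores(scores)
        sel = select_triplets(scan, mode="percentile", percentile=99)
        assert sel.cutoff == np.sort(scores)[989]
        assert len(sel) == 11

    def test_undefined_scores_never_selected(self):
        scan = self._scan_with_scores([0.5, float("nan")])
        sel = select_triplets(scan, mode="fixed", s_threshold=0.0)
        assert len(sel) == 1

    def test_unknown_mode_rejected(self):
        scan = self._scan_with_scores([0.5])
        with pytest.raises(ValidationError):
            select_triplets(scan, mode="bogus")
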