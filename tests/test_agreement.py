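"""Agreement engine: weight families, hand-computed fixtures, oracle
equivalence, invariances, and the kappa prevalence paradox."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bronchoscore import (
    AgreementError,
    cohen_weighted_kappa,
    counts_from_assignments,
    gwet_agreement,
    interpret_band,
    make_weights,
    pair_table_to_counts,
    pairwise_agreement,
    paradox_fixture,
    percent_agreement,
)
from oracles import gwet_oracle


class TestWeights:
    def test_identity_q2(self):
        w = make_weights("identity", 2)
        assert np.array_equal(w.w, np.eye(2))
        assert w.total == 2.0

    def test_linear_q3(self):
        w = make_weights("linear", 3).w
        assert w[0, 1] == pytest.approx(0.5)
        assert w[0, 2] == pytest.approx(0.0)

    def test_ordinal_q3(self):
        w = make_weights("ordinal", 3).w
        assert w[0, 1] == pytest.approx(2 / 3)
        assert w[0, 2] == pytest.approx(0.0)

    @pytest.mark.parametrize("kind",
                             ["identity", "linear", "quadratic", "ordinal"])
    @pytest.mark.parametrize("q", [2, 3, 5, 9])
    def test_invariants(self, kind, q):
        w = make_weights(kind, q).w
        assert np.allclose(np.diag(w), 1.0)
        assert np.allclose(w, w.T)
        assert w.min() >= 0.0 and w.max() <= 1.0
        if kind == "identity":
            assert np.allclose(w - np.eye(q), 0.0)

    def test_single_category_rejected(self):
        with pytest.raises(AgreementError):
            make_weights("identity", 1)


class TestHandFixtures:
    def test_two_rater_binary_pairs(self):
        """{(0,0),(0,1),(1,1),(0,0)}: p_a=0.75, pi=(0.625,0.375),
        p_e=0.46875, AC1=0.529412."""
        counts = counts_from_assignments(
            np.array([[0, 0], [0, 1], [1, 1], [0, 0]]), 2
        )
        est = gwet_agreement(counts, make_weights("identity", 2))
        assert est.p_a == pytest.approx(0.75)
        assert est.p_e == pytest.approx(0.46875)
        assert est.coefficient == pytest.approx(0.529412, abs=5e-7)

    def test_paradox_table(self):
        """[[90,5],[4,1]]: percent agreement 0.91, kappa 0.134615,
        AC1 0.8995592 — high raw agreement, tiny kappa."""
        table = paradox_fixture()
        w = make_weights("identity", 2)
        counts = pair_table_to_counts(table)
        assert counts.shape == (100, 2)
        pa = percent_agreement(counts)
        assert pa.coefficient == pytest.approx(0.91)
        ac1 = gwet_agreement(counts, w)
        assert ac1.p_a == pytest.approx(0.91)
        assert ac1.p_e == pytest.approx(0.10395)
        assert ac1.coefficient == pytest.approx(0.8995592, abs=5e-7)
        kap = cohen_weighted_kappa(table, w)
        assert kap.p_e == pytest.approx(0.896)
        assert kap.coefficient == pytest.approx(0.134615, abs=5e-7)
        # the paradox: same observed agreement, opposite verdicts
        assert ac1.coefficient - kap.coefficient > 0.7

    def test_kappa_trivial_tables(self):
        w = make_weights("identity", 2)
        assert cohen_weighted_kappa(
            np.diag([7, 3]), w).coefficient == pytest.approx(1.0)
        assert cohen_weighted_kappa(
            np.ones((2, 2)), w).coefficient == pytest.approx(0.0)


class TestOracleEquivalence:
    def test_matches_direct_summation(self):
        """Random small instances agree with the naive per-subject
        summation to 1e-12 for every weight family."""
        rng = np.random.default_rng(42)
        kinds = ["identity", "linear", "quadratic", "ordinal"]
        for trial in range(200):
            n = rng.integers(2, 11)
            r = rng.integers(2, 5)
            q = rng.integers(2, 6)
            cats = rng.integers(0, q, size=(n, r)).astype(float)
            counts = counts_from_assignments(cats, q)
            w = make_weights(kinds[trial % 4], q)
            try:
                est = gwet_agreement(counts, w)
            except AgreementError:
                continue  # degenerate draw
            coef, p_a, p_e = gwet_oracle(counts, w.w)
            assert est.coefficient == pytest.approx(coef, abs=1e-12)
            assert est.p_a == pytest.approx(p_a, abs=1e-12)
            assert est.p_e == pytest.approx(p_e, abs=1e-12)

    def test_identity_weights_reduce_to_ac1_formula(self):
        """With identity weights the generic weighted path equals the
        unweighted formula (T_w = q) exactly."""
        rng = np.random.default_rng(7)
        cats = rng.integers(0, 3, size=(12, 4)).astype(float)
        counts = counts_from_assignments(cats, 3)
        est = gwet_agreement(counts, make_weights("identity", 3))
        n, q = counts.shape
        r_i = counts.sum(1)
        pa = np.mean(
            (counts * (counts - 1)).sum(1)[r_i >= 2]
            / (r_i * (r_i - 1))[r_i >= 2]
        )
        pi = (counts / r_i[:, None]).mean(0)
        pe = (pi * (1 - pi)).sum() / (q - 1)
        assert est.p_a == pytest.approx(pa, abs=1e-15)
        assert est.p_e == pytest.approx(pe, abs=1e-15)
        assert est.coefficient == pytest.approx(
            (pa - pe) / (1 - pe), abs=1e-15
        )

    @pytest.mark.parametrize("kind",
                             ["identity", "linear", "quadratic", "ordinal"])
    def test_perfect_agreement_is_exactly_one(self, kind):
        rng = np.random.default_rng(3)
        cats = np.tile(rng.integers(0, 4, size=(15, 1)), (1, 4)).astype(float)
        counts = counts_from_assignments(cats, 4)
        est = gwet_agreement(counts, make_weights(kind, 4))
        assert est.coefficient == 1.0

    def test_independent_uniform_raters_near_zero(self):
        """Raters assigning categories independently and uniformly carry no
        agreement signal: the coefficient sits within 3 SE of zero."""
        rng = np.random.default_rng(2026)
        cats = rng.integers(0, 3, size=(2000, 4)).astype(float)
        counts = counts_from_assignments(cats, 3)
        est = gwet_agreement(counts, make_weights("identity", 3))
        assert abs(est.coefficient) < 3 * est.se


class TestInvariances:
    def test_subject_permutation_and_rater_relabel(self):
        rng = np.random.default_rng(11)
        cats = rng.integers(0, 4, size=(20, 4)).astype(float)
        counts = counts_from_assignments(cats, 4)
        w = make_weights("ordinal", 4)
        base = gwet_agreement(counts, w)
        perm = rng.permutation(20)
        shuffled = gwet_agreement(counts[perm], w)
        relabeled = counts_from_assignments(cats[:, ::-1], 4)
        swapped = gwet_agreement(relabeled, w)
        for other in (shuffled, swapped):
            assert other.coefficient == pytest.approx(
                base.coefficient, abs=1e-14
            )
            assert other.se == pytest.approx(base.se, abs=1e-14)

    @pytest.mark.parametrize("kind", ["identity", "ordinal"])
    def test_pair_table_transpose(self, kind):
        rng = np.random.default_rng(5)
        table = rng.integers(0, 20, size=(4, 4))
        table[0, 0] += 30
        w = make_weights(kind, 4)
        k1 = cohen_weighted_kappa(table, w)
        k2 = cohen_weighted_kappa(table.T, w)
        assert k2.coefficient == pytest.approx(k1.coefficient, abs=1e-14)
        a1 = gwet_agreement(pair_table_to_counts(table), w)
        a2 = gwet_agreement(pair_table_to_counts(table.T), w)
        assert a2.coefficient == pytest.approx(a1.coefficient, abs=1e-14)


class TestKappaCrossCheck:
    """Dual route: our kappa vs statsmodels' independent implementation."""

    @pytest.mark.parametrize("wt", [None, "linear"])
    def test_against_statsmodels(self, wt):
        from statsmodels.stats.inter_rater import cohens_kappa

        rng = np.random.default_rng(13)
        table = rng.integers(0, 25, size=(4, 4)) + np.diag([20, 5, 5, 10])
        kind = "identity" if wt is None else "linear"
        ours = cohen_weighted_kappa(table, make_weights(kind, 4))
        theirs = cohens_kappa(table, wt=wt, return_results=True)
        assert ours.coefficient == pytest.approx(theirs.kappa, abs=1e-10)
        if wt is None:
            assert ours.se == pytest.approx(
                np.sqrt(theirs.var_kappa), rel=1e-6
            )


class TestPairwise:
    def test_four_raters_six_pairs(self):
        rng = np.random.default_rng(17)
        wide = pd.DataFrame(
            rng.integers(0, 3, size=(30, 4)).astype(float),
            columns=["student", "expert1", "expert2", "expert3"],
        )
        out = pairwise_agreement(wide, make_weights("ordinal", 3))
        assert len(out) == 6
        assert all(est is not None for _, _, est, _ in out)

    def test_two_raters_pair_equals_overall(self):
        rng = np.random.default_rng(19)
        wide = pd.DataFrame(
            rng.integers(0, 4, size=(25, 2)).astype(float),
            columns=["a", "b"],
        )
        w = make_weights("ordinal", 4)
        (a, b, est, reason), = pairwise_agreement(wide, w)
        overall = gwet_agreement(
            counts_from_assignments(wide.to_numpy(), 4), w
        )
        assert est.coefficient == pytest.approx(
            overall.coefficient, abs=1e-14
        )

    def test_identical_pair_is_one(self):
        wide = pd.DataFrame({"a": [0.0, 1, 2, 1], "b": [0.0, 1, 2, 1]})
        (_, _, est, _), = pairwise_agreement(wide, make_weights("ordinal", 3))
        assert est.coefficient == 1.0

    def test_disjoint_pair_flagged_absent(self):
        wide = pd.DataFrame(
            {"a": [0.0, 1, np.nan, np.nan], "b": [np.nan, np.nan, 1.0, 0]}
        )
        (_, _, est, reason), = pairwise_agreement(
            wide, make_weights("identity", 2)
        )
        assert est is None
        assert "no co-rated" in reason


class TestBandsAndErrors:
    @pytest.mark.parametrize(
        ("value", "band"),
        [(0.94, "almost_perfect"), (0.47, "moderate"), (0.15, "slight_poor"),
         (0.20, "slight_poor"), (0.21, "fair"), (0.40, "fair"),
         (0.60, "moderate"), (0.61, "substantial"), (0.80, "substantial"),
         (0.81, "almost_perfect"), (1.05, "almost_perfect"),
         (-0.3, "slight_poor")],
    )
    def test_landis_koch_bands(self, value, band):
        assert interpret_band(value) == band

    def test_all_single_rated_is_error(self):
        counts = np.eye(3, dtype=int)
        with pytest.raises(AgreementError, match="undefined"):
            gwet_agreement(counts, make_weights("identity", 3))

    def test_empty_cross_table_is_error(self):
        with pytest.raises(AgreementError):
            cohen_weighted_kappa(np.zeros((2, 2)), make_weights("identity", 2))

    def test_ci_brackets_coefficient(self):
        rng = np.random.default_rng(23)
        cats = rng.integers(0, 3, size=(40, 4)).astype(float)
        counts = counts_from_assignments(cats, 3)
        est = gwet_agreement(counts, make_weights("ordinal", 3))
        assert est.ci_low <= est.coefficient <= est.ci_high
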