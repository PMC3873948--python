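"""G statistics, BH adjustment, per-gene tests and their null calibration."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cistrans.data import GeneCountRecord, LibraryTotals
from cistrans.gtests import (
    DegenerateTableError,
    bh_adjust,
    cis_test,
    g_2x2_arrays,
    g_gof_arrays,
    g_test_2x2,
    g_test_given_ratio,
    magnitudes,
    run_all_tests,
    tde_test,
    trans_test,
)
from cistrans.normalization import NormalizationFactors

IDENT = NormalizationFactors.identity((100.0,) * 4)
TOTALS = LibraryTotals(100, 100, 100, 100)


def g_oracle_entropy(a, b, c, d):
    """Independent route to the 2x2 G statistic via the entropy identity.

    G = 2 [ sum O ln O - sum rows ln rows - sum cols ln cols + N ln N ].
    """
    cells = np.array([a, b, c, d], dtype=float)
    rows = np.array([a + b, c + d], dtype=float)
    cols = np.array([a + c, b + d], dtype=float)
    n = cells.sum()
    xlx = lambda v: np.sum(np.where(v > 0, v * np.log(np.where(v > 0, v, 1)), 0.0))
    return 2.0 * (xlx(cells) - xlx(rows) - xlx(cols) + n * math.log(n))


class TestG2x2:
    def test_proportional_rows_give_zero(self):
        g, p = g_test_2x2(10, 20, 100, 200)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_against_direct_formula(self):
        g, p = g_test_2x2(30, 10, 10, 30)
        assert g == pytest.approx(g_oracle_entropy(30, 10, 10, 30), abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(g, 1))

    def test_exhaustive_small_tables_match_oracle(self):
        """All 2x2 tables with every margin <= 25 agree with the entropy oracle."""
        rng = np.indices((26,) * 4).reshape(4, -1)
        a, b, c, d = (v.astype(float) for v in rng)
        ok = (
            (a + b <= 25) & (c + d <= 25) & (a + c <= 25) & (b + d <= 25)
            & (a + b > 0) & (c + d > 0) & (a + c > 0) & (b + d > 0)
        )
        a, b, c, d = a[ok], b[ok], c[ok], d[ok]
        G, _, deg = g_2x2_arrays(a, b, c, d)
        assert not deg.any()
        oracle = np.array(
            [g_oracle_entropy(*t) for t in zip(a, b, c, d)]
        )
        assert np.max(np.abs(G - oracle)) < 1e-10

    def test_spot_check_against_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 400, size=4)
            g, p = g_test_2x2(a, b, c, d)
            ref = stats.chi2_contingency(
                [[a, b], [c, d]], correction=False, lambda_="log-likelihood"
            )
            assert g == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            g_test_2x2(0, 0, 5, 5)
        with pytest.raises(DegenerateTableError):
            g_test_2x2(0, 5, 0, 5)


class TestGGivenRatio:
    def test_observed_equals_expected(self):
        assert g_test_given_ratio(50, 50, 1.0) == (0.0, 1.0)

    @pytest.mark.parametrize("r,k", [(2.0, 5), (0.5, 10), (3.0, 7)])
    def test_observed_matching_null_proportion_is_exact_zero(self, r, k):
        x1, x2 = int(round(2 * r * k)), 2 * k
        g, p = g_test_given_ratio(x1, x2, x1 / x2)
        assert g == 0.0 and p == 1.0

    def test_against_hand_formula(self):
        # E1 = E2 = 50 under ratio 1
        g, p = g_test_given_ratio(80, 20, 1.0)
        expected = 2 * (80 * math.log(80 / 50) + 20 * math.log(20 / 50))
        assert g == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(expected, 1))

    def test_zero_total_degenerate(self):
        assert g_test_given_ratio(0, 0, 1.0) == (0.0, 1.0)

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            g_test_given_ratio(5, 5, 0.0)


class TestPerGeneTests:
    def test_tde_null_case(self):
        rec = GeneCountRecord("g", 100, 100, 1, 1)
        g, p = tde_test(rec, TOTALS, IDENT)
        assert g == 0.0 and p == 1.0

    def test_tde_matches_direct_formula(self):
        rec = GeneCountRecord("g", 150, 50, 1, 1)
        g, _ = tde_test(rec, TOTALS, IDENT)
        expected = 2 * (150 * math.log(150 / 100) + 50 * math.log(50 / 100))
        assert g == pytest.approx(expected, abs=1e-10)

    def test_tde_zero_when_ratio_matches_depths(self):
        f = NormalizationFactors.identity((200.0, 100.0, 100.0, 100.0))
        rec = GeneCountRecord("g", 80, 40, 1, 1)
        g, _ = tde_test(rec, LibraryTotals(200, 100, 100, 100), f)
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_cis_null_case(self):
        rec = GeneCountRecord("g", 1, 1, 60, 60)
        g, p = cis_test(rec, TOTALS, IDENT)
        assert g == 0.0 and p == 1.0

    def test_cis_bias_factor_fully_explains_imbalance(self):
        rec = GeneCountRecord("g", 1, 1, 120, 60, bias_factor=2.0)
        g, p = cis_test(rec, TOTALS, IDENT)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_cis_matches_direct_formula(self):
        rec = GeneCountRecord("g", 1, 1, 120, 60)
        g, _ = cis_test(rec, TOTALS, IDENT)
        expected = 2 * (120 * math.log(120 / 90) + 60 * math.log(60 / 90))
        assert g == pytest.approx(expected, abs=1e-10)

    def test_trans_no_effect(self):
        rec = GeneCountRecord("g", 100, 100, 100, 100)
        g, p = trans_test(rec, IDENT)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_trans_matches_2x2_oracle(self):
        rec = GeneCountRecord("g", 100, 100, 150, 50)
        g, _ = trans_test(rec, IDENT)
        assert g == pytest.approx(g_oracle_entropy(100, 100, 150, 50), abs=1e-10)

    def test_trans_bias_divides_h1(self):
        # h1 = 200 with bias 2 behaves like h1 = 100: no trans signal
        rec = GeneCountRecord("g", 100, 100, 200, 100, bias_factor=2.0)
        g, p = trans_test(rec, IDENT)
        assert g == pytest.approx(0.0, abs=1e-12)


class TestBH:
    @staticmethod
    def bh_brute(p):
        """Literal step-up definition: q_(i) = min_{j>=i} m p_(j) / j, capped."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        for rank_i, idx in enumerate(order, start=1):
            candidates = [
                m * p[order[j - 1]] / j for j in range(rank_i, m + 1)
            ]
            q[idx] = min(1.0, min(candidates))
        return q

    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal(self):
        assert bh_adjust([0.01] * 7) == pytest.approx([0.01] * 7)

    def test_small_vector_by_hand(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert bh_adjust(p) == pytest.approx(self.bh_brute(p))

    def test_random_vectors_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            p = rng.random(n) ** rng.uniform(0.3, 3.0)
            assert bh_adjust(p) == pytest.approx(self.bh_brute(p), abs=1e-12)

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_q_at_least_p_and_monotone(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestMagnitudes:
    def test_fourfold_allelic_ratio(self):
        rec = GeneCountRecord("g", 100, 100, 200, 50)
        m = magnitudes(rec, IDENT)
        assert m.cis_mag == pytest.approx(2.0)

    def test_trans_cancellation(self):
        rec = GeneCountRecord("g", 160, 40, 80, 20)
        m = magnitudes(rec, IDENT)
        assert m.trans_mag == pytest.approx(0.0, abs=1e-12)
        assert m.cis_mag == pytest.approx(2.0)

    def test_balanced_gene_zero_magnitudes(self):
        rec = GeneCountRecord("g", 70, 70, 35, 35)
        m = magnitudes(rec, IDENT)
        assert m.cis_mag == 0.0 and m.trans_mag == 0.0

    def test_zero_count_with_pseudo_defined(self):
        rec = GeneCountRecord("g", 100, 100, 50, 0)
        m = magnitudes(rec, IDENT, pseudo=0.5)
        assert m.defined and np.isfinite(m.cis_mag)

    def test_zero_count_without_pseudo_undefined(self):
        rec = GeneCountRecord("g", 100, 100, 50, 0)
        m = magnitudes(rec, IDENT, pseudo=0.0)
        assert not m.defined and math.isnan(m.cis_mag)


class TestRunAllTests:
    def make_null_records(self, n, seed, n_expr=1000):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(
            [n_expr, n_expr, n_expr / 2, n_expr / 2], size=(n, 4)
        )
        return [
            GeneCountRecord(f"g{i}", *(int(v) for v in row))
            for i, row in enumerate(counts)
        ]

    def test_single_gene_q_equals_p(self):
        recs = [GeneCountRecord("g", 120, 80, 70, 30)]
        df = run_all_tests(recs, TOTALS, IDENT)
        for fam in ("tde", "cis", "trans"):
            assert df[f"q_{fam}"][0] == pytest.approx(df[f"p_{fam}"][0])

    def test_gene_order_permutation(self):
        recs = self.make_null_records(50, seed=5)
        df = run_all_tests(recs, TOTALS, IDENT)
        perm = list(reversed(range(50)))
        df2 = run_all_tests([recs[i] for i in perm], TOTALS, IDENT)
        merged = df.set_index("gene_id").loc[df2["gene_id"]]
        assert np.allclose(merged["G_cis"].to_numpy(), df2["G_cis"].to_numpy())
        assert np.allclose(merged["q_trans"].to_numpy(), df2["q_trans"].to_numpy())

    def test_global_null_has_almost_no_discoveries(self):
        """Under the global null BH admits essentially no significant calls."""
        recs = self.make_null_records(10000, seed=17)
        totals = LibraryTotals(*(int(c) for c in np.array(
            [[r.p1, r.p2, r.h1, r.h2] for r in recs]).sum(axis=0)))
        eff = NormalizationFactors.identity(totals.as_tuple())
        df = run_all_tests(recs, totals, eff)
        for fam in ("tde", "cis", "trans"):
            assert df[f"sig_{fam}"].mean() <= 0.005

    def test_degenerate_rows_kept_and_flagged(self):
        recs = [
            GeneCountRecord("ok", 100, 90, 60, 40),
            GeneCountRecord("dead", 30, 30, 0, 0),
        ]
        df = run_all_tests(recs, TOTALS, IDENT)
        assert len(df) == 2
        row = df[df.gene_id == "dead"].iloc[0]
        assert row["p_cis"] == 1.0 and "deg_cis" in row["flags"]


class TestNullCalibration:
    """Uncorrected rejection rates of the raw tests under the Poisson null."""

    N_GENES = 10000
    N_EXPR = 1000

    def test_cis_test_calibrated(self):
        rng = np.random.default_rng(101)
        h = rng.poisson(self.N_EXPR / 2, size=(self.N_GENES, 2))
        _, p, _ = g_gof_arrays(h[:, 0], h[:, 1], 1.0)
        assert abs(np.mean(p <= 0.05) - 0.05) <= 0.01

    def test_trans_test_calibrated(self):
        rng = np.random.default_rng(103)
        par = rng.poisson(self.N_EXPR, size=(self.N_GENES, 2))
        hyb = rng.poisson(self.N_EXPR / 2, size=(self.N_GENES, 2))
        _, p, _ = g_2x2_arrays(par[:, 0], par[:, 1], hyb[:, 0], hyb[:, 1])
        assert abs(np.mean(p <= 0.05) - 0.05) <= 0.01

    def test_bias_correction_restores_null_and_omission_inflates(self):
        """A gene-level mapping bias c = 2 is absorbed by the corrected null;
        ignoring it inflates the rejection rate far beyond Monte-Carlo noise."""
        c = 2.0
        rng = np.random.default_rng(107)
        lam = self.N_EXPR / 2
        h1 = rng.poisson(c * lam, size=self.N_GENES)
        h2 = rng.poisson(lam, size=self.N_GENES)
        _, p_corr, _ = g_gof_arrays(h1, h2, c)
        _, p_raw, _ = g_gof_arrays(h1, h2, 1.0)
        rate_corr = np.mean(p_corr <= 0.05)
        rate_raw = np.mean(p_raw <= 0.05)
        assert abs(rate_corr - 0.05) <= 0.01
        mc_se = math.sqrt(0.05 * 0.95 / self.N_GENES)
        assert rate_raw > rate_corr + 3 * mc_se


class TestFormAndBiasSwitches:
    def make_records(self):
        rng = np.random.default_rng(77)
        counts = rng.poisson([400, 400, 200, 200], size=(300, 4))
        return [
            GeneCountRecord(f"g{i}", *(int(v) for v in row))
            for i, row in enumerate(counts)
        ]

    def test_independence_form_close_to_gof(self):
        """With genes tiny relative to the library, re-estimating the null
        ratio from a 2x2 table barely moves the statistics."""
        recs = self.make_records()
        totals = LibraryTotals(*(int(v) for v in np.array(
            [[r.p1, r.p2, r.h1, r.h2] for r in recs]).sum(axis=0)))
        f = NormalizationFactors.identity(totals.as_tuple())
        gof = run_all_tests(recs, totals, f, form="gof")
        ind = run_all_tests(recs, totals, f, form="independence")
        assert np.corrcoef(gof["G_tde"], ind["G_tde"])[0, 1] > 0.999
        assert np.corrcoef(gof["G_cis"], ind["G_cis"])[0, 1] > 0.999

    def test_unknown_form_rejected(self):
        recs = self.make_records()[:5]
        with pytest.raises(ValueError, match="form"):
            run_all_tests(recs, TOTALS, IDENT, form="bayes")

    def test_trans_bias_switch(self):
        """A gene whose hybrid imbalance is pure mapping bias shows no trans
        signal when the correction is applied, and a spurious one when the
        division of h1 is switched off."""
        rec = GeneCountRecord("g", 100, 100, 200, 100, bias_factor=2.0)
        g_on, _ = trans_test(rec, IDENT, apply_bias=True)
        g_off, _ = trans_test(rec, IDENT, apply_bias=False)
        assert g_on == pytest.approx(0.0, abs=1e-12)
        assert g_off > 5.0
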