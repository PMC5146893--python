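"""Genotyping error models, beta moments, lineage tests, call filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dtctrace import (
    ErrorRateEstimate,
    GenotypeMatrix,
    GoldStandardCriteria,
    beta_from_moments,
    betabinom_tail,
    estimate_error_rates,
    filter_somatic_calls,
    lineage_pvalues,
    select_gold_standard,
)


def _matrix(ref, alt, roles):
    loci = [f"l{i}" for i in range(len(roles))]
    return GenotypeMatrix(
        ref=pd.DataFrame({"c": ref}, index=loci),
        alt=pd.DataFrame({"c": alt}, index=loci),
        roles=pd.Series(roles, index=loci),
    )


def _estimate(p, var, cell="c"):
    return ErrorRateEstimate(
        cell_id=cell, p_fp=p, var_fp=var, p_fn=p, var_fn=var, locus_dropout=0.0,
        n_hom_covered=100, n_het_covered=100, n_het_total=100,
        n_fp_events=0, n_fn_events=0,
    )


class TestSelectGoldStandard:
    baf = pd.Series({"a": 0.5, "b": 0.2, "c": 0.95, "d": 0.95})
    blood = pd.DataFrame(
        {"genotype": ["het", "het", "hom_alt", "hom_alt"], "coverage": [30, 30, 30, 30]},
        index=["a", "b", "c", "d"],
    )
    tumor = blood.copy()
    cn = pd.Series({"a": "1+1", "b": "1+1", "c": "2+0", "d": "1+1"})

    def test_criteria(self):
        roles = select_gold_standard(self.baf, self.blood, self.tumor, self.cn)
        assert roles["a"] == "germline_het_gold"  # BAF 0.5, het/het, 30x, 1+1
        assert roles["b"] == "germline_other"  # BAF outside het window
        assert roles["c"] == "germline_other"  # aberrant 2+0 copy number
        assert roles["d"] == "germline_hom_gold"

    def test_low_coverage_excluded(self):
        blood = self.blood.assign(coverage=[5, 30, 30, 30])
        roles = select_gold_standard(self.baf, blood, self.tumor, self.cn)
        assert roles["a"] == "germline_other"

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            GoldStandardCriteria(het_baf_window=(0.7, 0.3))


class TestEstimateErrorRates:
    def test_direct_arithmetic(self):
        """50 covered het-gold, 20 without alt: p_fn = 0.40, var = 0.0048."""
        ref = [1] * 50 + [2] * 10
        alt = [1] * 30 + [0] * 20 + [1] * 10
        roles = ["germline_het_gold"] * 50 + ["germline_hom_gold"] * 10
        est = estimate_error_rates(_matrix(ref, alt, roles), "c")
        assert est.p_fn == pytest.approx(0.40)
        assert est.var_fn == pytest.approx(0.4 * 0.6 / 50)

    def test_pseudocall_on_zero_errors(self):
        """100 covered hom-gold with no alt reads: p_fp = 1/101."""
        ref = [3] * 100 + [1] * 10
        alt = [0] * 100 + [1] * 10
        roles = ["germline_hom_gold"] * 100 + ["germline_het_gold"] * 10
        est = estimate_error_rates(_matrix(ref, alt, roles), "c")
        assert est.p_fp == pytest.approx(1 / 101)
        assert est.fp_pseudocall
        assert est.var_fp == pytest.approx((1 / 101) * (100 / 101) / 100)

    def test_dropout_fraction(self):
        """138 of 200 het-gold without coverage: dropout 0.69."""
        ref = [0] * 138 + [2] * 62 + [5] * 10
        alt = [0] * 138 + [1] * 62 + [0] * 10
        roles = ["germline_het_gold"] * 200 + ["germline_hom_gold"] * 10
        est = estimate_error_rates(_matrix(ref, alt, roles), "c")
        assert est.locus_dropout == pytest.approx(0.69)

    def test_zero_covered_gold_flagged(self):
        est = estimate_error_rates(
            _matrix([0, 0], [0, 0], ["germline_het_gold", "germline_hom_gold"]), "c"
        )
        assert est.undefined and np.isnan(est.p_fp)


class TestBetaFromMoments:
    @pytest.mark.parametrize("mu,var,a,b", [
        (0.5, 1 / 12, 1.0, 1.0),  # uniform
        (0.5, 0.05, 2.0, 2.0),
    ])
    def test_known_inversions(self, mu, var, a, b):
        assert beta_from_moments(mu, var) == pytest.approx((a, b))
        dist = stats.beta(a, b)
        assert (dist.mean(), dist.var()) == pytest.approx((mu, var))

    @given(
        mu=st.floats(0.01, 0.99),
        frac=st.floats(0.01, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_recovers_moments(self, mu, frac):
        var = frac * mu * (1 - mu)
        a, b = beta_from_moments(mu, var)
        assert a / (a + b) == pytest.approx(mu, rel=1e-12)
        assert a * b / ((a + b) ** 2 * (a + b + 1)) == pytest.approx(var, rel=1e-9)

    @pytest.mark.parametrize("mu,var", [(0.5, 0.25), (0.5, 0.3), (0.0, 0.01), (0.5, 0.0)])
    def test_invalid_moments_rejected(self, mu, var):
        with pytest.raises(ValueError):
            beta_from_moments(mu, var)


class TestLineagePvalues:
    def test_k_zero_fp_model_is_one(self):
        t = lineage_pvalues(10, 0, _estimate(0.002, 1e-6))
        assert t.p_fp_model == 1.0

    def test_n_zero_uninformative(self):
        t = lineage_pvalues(0, 0, _estimate(0.002, 1e-6))
        assert t.p_fp_model == 1.0 and t.p_fn_model == 1.0
        assert "no_covered_loci" in t.flags

    def test_fp_pvalue_monotone_in_k(self):
        est = _estimate(0.01, 1e-5)
        ps = [lineage_pvalues(20, k, est).p_fp_model for k in range(21)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_fn_pvalue_monotone_in_misses(self):
        est = _estimate(0.44, 0.004)
        ps = [lineage_pvalues(20, k, est).p_fn_model for k in range(21)]
        # p_fn tests >= n-k misses: more detections -> larger p
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_degenerate_variance_falls_back_to_binomial(self):
        est = _estimate(0.01, 0.0)
        t = lineage_pvalues(10, 3, est)
        assert "fp_binomial_fallback" in t.flags
        assert t.p_fp_model == pytest.approx(float(stats.binom.sf(2, 10, 0.01)))

    def test_overdispersion_widens_far_tail(self):
        """Beta-binomial dominates the binomial in the far upper tail.

        The survival functions of a binomial and a mean-matched
        beta-binomial cross once a little above the mean; beyond one
        beta-binomial SD the overdispersed tail is always the heavier.
        """
        for n, mu, var_frac in [(20, 0.05, 0.3), (50, 0.1, 0.5), (30, 0.02, 0.2)]:
            var = var_frac * mu * (1 - mu)
            a, b = beta_from_moments(mu, var)
            rho = 1.0 / (a + b + 1)
            sd_bb = np.sqrt(n * mu * (1 - mu) * (1 + (n - 1) * rho))
            for k in range(int(np.ceil(n * mu + sd_bb)), n + 1):
                bb = betabinom_tail(k, n, a, b)
                bi = float(stats.binom.sf(k - 1, n, mu))
                assert bb >= bi - 1e-12

    @staticmethod
    def _tail_exact(k, n, a, b):
        """Independent oracle: exact rational arithmetic summation."""
        from fractions import Fraction
        from math import comb

        fa = Fraction(a).limit_denominator(10**12)
        fb = Fraction(b).limit_denominator(10**12)
        den = Fraction(1)
        for i in range(n):
            den *= fa + fb + i
        total = Fraction(0)
        for j in range(k, n + 1):
            num = Fraction(comb(n, j))
            for i in range(j):
                num *= fa + i
            for i in range(n - j):
                num *= fb + i
            total += num / den
        return float(total)

    def test_matches_exact_rational_summation(self):
        """Log-space tail equals exact fraction arithmetic, deep tails included."""
        for n, k, mu, var in [(20, 6, 0.002, 1e-6), (30, 5, 0.05, 5e-4), (50, 30, 0.44, 0.01)]:
            a, b = beta_from_moments(mu, var)
            assert betabinom_tail(k, n, a, b) == pytest.approx(
                self._tail_exact(k, n, a, b), rel=1e-10
            )

    def test_matches_scipy_on_bulk_tails(self):
        """scipy's beta-binomial agrees where its tails are not tiny."""
        for n, k, mu, var in [(30, 3, 0.05, 5e-4), (50, 25, 0.44, 0.01), (20, 1, 0.1, 2e-3)]:
            a, b = beta_from_moments(mu, var)
            assert betabinom_tail(k, n, a, b) == pytest.approx(
                float(stats.betabinom.sf(k - 1, n, a, b)), rel=1e-7
            )

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            lineage_pvalues(5, 6, _estimate(0.01, 1e-5))


class TestFilterSomaticCalls:
    def _df(self, **overrides):
        base = {
            "allelic_fraction": 0.40, "alt_fwd": 6, "alt_rev": 6,
            "in_panel": False, "region": "exonic",
        }
        base.update(overrides)
        return pd.DataFrame([base])

    def test_clean_variant_retained(self):
        retained, report = filter_somatic_calls(self._df())
        assert len(retained) == 1
        assert report.set_index("rule").loc["retained", "n"] == 1

    @pytest.mark.parametrize("overrides,rule", [
        ({"allelic_fraction": 0.10}, "allelic_fraction_lt_0.15"),
        ({"alt_fwd": 12, "alt_rev": 0, "allelic_fraction": 0.30}, "complete_strand_bias"),
        ({"in_panel": True}, "panel_of_normals"),
        ({"region": "centromere"}, "blacklist_region"),
        ({"region": "repeat"}, "blacklist_region"),
        ({"region": "intergenic"}, "blacklist_region"),
    ])
    def test_discard_rules(self, overrides, rule):
        retained, report = filter_somatic_calls(self._df(**overrides))
        assert len(retained) == 0
        assert report.set_index("rule").loc[rule, "n"] == 1

    def test_af_boundary_is_strict(self):
        retained, _ = filter_somatic_calls(self._df(allelic_fraction=0.15))
        assert len(retained) == 1

    def test_missing_annotation_held_out_not_passed(self):
        df = pd.concat([self._df(), self._df(region=None)], ignore_index=True)
        retained, report = filter_somatic_calls(df)
        assert len(retained) == 1
        assert report.set_index("rule").loc["held_out_missing_annotation", "n"] == 1


class TestParameterRecovery:
    def test_rates_recovered_from_simulated_cells(self, default_cohort):
        """Pooled per-cell estimates land within 3 SE of generative rates."""
        cfg = default_cohort.config
        ests = [
            estimate_error_rates(default_cohort.genotypes, c)
            for c in default_cohort.genotypes.cells
        ]
        n_fp = sum(e.n_fp_events for e in ests)
        n_hom = sum(e.n_hom_covered for e in ests)
        n_fn = sum(e.n_fn_events for e in ests)
        n_het = sum(e.n_het_covered for e in ests)
        for obs, n, truth in [
            (n_fp / n_hom, n_hom, cfg.fp_rate),
            (n_fn / n_het, n_het, cfg.allelic_dropout_rate),
        ]:
            se = np.sqrt(truth * (1 - truth) / n)
            assert abs(obs - truth) < 3 * se
        drops = [e.locus_dropout for e in ests]
        se_drop = np.std(drops, ddof=1) / np.sqrt(len(drops))
        assert abs(np.mean(drops) - cfg.locus_dropout_rate) < 3 * se_drop
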