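"""Poisson DNV enrichment, attributable fraction and saturation estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from trioburden import (
    DnvEnrichmentModel,
    attributable_fraction,
    estimate_risk_genes_and_saturation,
    poisson_upper_p,
)
from trioburden.dnv import classify_family, expected_by_family
from trioburden.synth import damaging_mutability


def brute_force_poisson_upper(observed, lam):
    """Independent oracle: 1 - sum of pmf below the observation, with the
    pmf accumulated term by term (term_k+1 = term_k * lam / (k+1))."""
    if observed == 0:
        return 1.0
    total, term = 0.0, math.exp(-lam)
    for k in range(observed):
        total += term
        term *= lam / (k + 1)
    return 1.0 - total


class TestPoissonUpperP:
    def test_headline_value(self):
        assert poisson_upper_p(2, 2 / 2042.5) == pytest.approx(4.79e-7, rel=1e-3)

    def test_zero_observed_is_whole_sample_space(self):
        assert poisson_upper_p(0, 5.0) == 1.0

    def test_closed_form_at_three_observed(self):
        assert poisson_upper_p(3, 1.0) == pytest.approx(1 - math.exp(-1) * (1 + 1 + 0.5), rel=1e-12)

    @pytest.mark.parametrize("observed", [1, 2, 5, 20, 60, 120, 200])
    @pytest.mark.parametrize("lam", [0.001, 0.3, 1.0, 7.5, 22.0, 50.0])
    def test_agrees_with_pmf_summation(self, observed, lam):
        assert poisson_upper_p(observed, lam) == pytest.approx(
            brute_force_poisson_upper(observed, lam), abs=1e-12
        )

    def test_monotone_in_observed_and_expected(self):
        ps = [poisson_upper_p(k, 3.0) for k in range(0, 30)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        ps = [poisson_upper_p(5, lam) for lam in np.linspace(0.1, 20, 50)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_upper_p(2, 0.0)
        with pytest.raises(ValueError):
            poisson_upper_p(-1, 1.0)


class TestAttributableFraction:
    def test_study_numbers(self):
        assert attributable_fraction(33, 22.0, 90) == pytest.approx(11 / 90)
        assert attributable_fraction(33, 22.0, 90) > 0.12

    def test_equal_counts_give_zero(self):
        assert attributable_fraction(10, 10.0, 90) == 0.0

    def test_deficit_floors_at_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert attributable_fraction(5, 10.0, 90) == 0.0

    def test_zero_probands_rejected(self):
        with pytest.raises(ValueError):
            attributable_fraction(1, 0.5, 0)

    def test_recovery_from_simulated_cohort(self, study_scale_universe):
        """A cohort generated at 15% attributable fraction recovers it."""
        from trioburden.synth import simulate_dnv_count_table

        gm = study_scale_universe.gene_models
        mu_dam = damaging_mutability(gm)
        exp_dam = float(2 * 90 * mu_dam.sum())
        rng = np.random.default_rng(31)
        # spike spread over 5 risk genes totalling 0.15 * 90 excess DNVs
        risk = mu_dam.sort_values().index[-5:]
        folds = pd.Series(1.0 + (0.15 * 90) / (2 * 90 * mu_dam.loc[risk].sum()), index=risk)
        estimates = []
        for _ in range(300):
            counts = simulate_dnv_count_table(gm, 90, rng, risk_folds=folds)
            obs = int(counts["protein_damaging"].sum())
            estimates.append(max(0.0, (obs - exp_dam) / 90))
        mean_est = float(np.mean(estimates))
        mc_err = float(np.std(estimates) / np.sqrt(len(estimates)))
        assert mean_est == pytest.approx(0.15, abs=max(0.01, 4 * mc_err))


def toy_gene_models():
    idx = [f"g{i}" for i in range(4)]
    df = pd.DataFrame(
        {
            "p_synonymous": [1e-5, 2e-5, 5e-6, 1e-5],
            "p_missense": [3e-5, 4e-5, 1e-5, 2e-5],
            "p_splice_canonical": [1e-6] * 4,
            "p_stopgain": [2e-6, 3e-6, 1e-6, 2e-6],
            "p_stoploss": [1e-7] * 4,
            "p_startloss": [1e-7] * 4,
            "pli": [0.99, 0.5, np.nan, 0.95],
            "dmis_fraction": [0.3, 0.25, 0.3, 0.4],
        },
        index=idx,
    )
    df["p_frameshift"] = 1.25 * df["p_stopgain"]
    return df


class TestDnvEnrichmentModel:
    def test_class_table_observed_expected_consistency(self):
        gm = toy_gene_models()
        dnvs = pd.DataFrame(
            [
                {"gene": "g0", "functional_class": "missense", "metasvm": "D", "mpc": None},
                {"gene": "g0", "functional_class": "stopgain", "metasvm": None, "mpc": None},
                {"gene": "g1", "functional_class": "synonymous", "metasvm": None, "mpc": None},
                {"gene": "g2", "functional_class": "missense", "metasvm": "T", "mpc": 0.4},
            ]
        )
        res = DnvEnrichmentModel(dnvs, gm, n_trios=50).fit()
        tab = res.class_table("all")
        assert tab.loc["total", "observed"] == 4
        assert tab.loc["syn", "observed"] == 1
        assert tab.loc["d_mis", "observed"] == 1
        assert tab.loc["t_mis", "observed"] == 1
        assert tab.loc["lof", "observed"] == 1
        assert tab.loc["protein_damaging", "observed"] == 2
        exp = expected_by_family(gm, 50)
        assert tab.loc["total", "expected"] == pytest.approx(exp["total"].sum())
        # enrichment x expected == observed
        for _, r in tab.iterrows():
            if r["expected"] > 0:
                assert r["enrichment"] * r["expected"] == pytest.approx(r["observed"])

    def test_constrained_subset_only_counts_high_pli_genes(self):
        gm = toy_gene_models()
        dnvs = pd.DataFrame(
            [
                {"gene": "g0", "functional_class": "stopgain", "metasvm": None, "mpc": None},
                {"gene": "g1", "functional_class": "stopgain", "metasvm": None, "mpc": None},
            ]
        )
        res = DnvEnrichmentModel(dnvs, gm, n_trios=50).fit()
        assert res.class_table("pli_ge_0.9").loc["lof", "observed"] == 1

    def test_bonferroni_threshold_three_tests_per_gene(self):
        gm = toy_gene_models()
        res = DnvEnrichmentModel(pd.DataFrame(columns=["gene", "functional_class"]), gm,
                                 n_trios=50, n_genes=19347).fit()
        assert res.per_gene_threshold == pytest.approx(0.05 / (3 * 19347))
        assert res.per_gene_threshold == pytest.approx(8.6e-7, rel=0.01)

    def test_all_zero_observed_gives_enrichment_zero_p_one(self):
        gm = toy_gene_models()
        res = DnvEnrichmentModel(pd.DataFrame(columns=["gene", "functional_class"]), gm, n_trios=50).fit()
        tab = res.class_table("all")
        assert (tab["observed"] == 0).all()
        assert (tab["p"] == 1.0).all()
        assert (tab["enrichment"] == 0.0).all()

    def test_small_lambda_two_hits_p_is_half_lambda_squared(self):
        gm = toy_gene_models()
        dnvs = pd.DataFrame([{"gene": "g0", "functional_class": "stopgain"}] * 2)
        res = DnvEnrichmentModel(dnvs, gm, n_trios=50).fit()
        row = res.per_gene.set_index(["gene", "class_family"]).loc[("g0", "lof")]
        lam = row["expected"]
        assert row["p"] == pytest.approx(lam**2 / 2, rel=0.01)

    def test_gene_with_zero_observed_not_significant(self):
        gm = toy_gene_models()
        res = DnvEnrichmentModel(pd.DataFrame(columns=["gene", "functional_class"]), gm, n_trios=50).fit()
        assert not res.per_gene["significant"].any()

    def test_summary_renders(self):
        gm = toy_gene_models()
        res = DnvEnrichmentModel(pd.DataFrame(columns=["gene", "functional_class"]), gm, n_trios=50).fit()
        s = res.summary()
        assert "attributable fraction" in s and "Bonferroni" in s


class TestClassFamilies:
    @pytest.mark.parametrize(
        "fclass,metasvm,mpc,expect",
        [
            ("missense", "D", None, {"d_mis": True, "t_mis": False, "protein_damaging": True}),
            ("missense", "T", 2.5, {"d_mis": True}),
            ("missense", "T", 1.0, {"d_mis": False, "t_mis": True, "protein_altering": True}),
            ("stopgain", None, None, {"lof": True, "protein_damaging": True, "syn": False}),
            ("frameshift", None, None, {"lof": True}),
            ("splice_canonical", None, None, {"lof": True}),
            ("synonymous", None, None, {"syn": True, "protein_altering": False}),
        ],
    )
    def test_membership(self, fclass, metasvm, mpc, expect):
        got = classify_family(fclass, metasvm, mpc)
        for k, v in expect.items():
            assert got[k] == v, k


class TestSaturation:
    def test_zero_excess_gives_zero_estimate(self):
        mu = pd.Series({"a": 1e-5, "b": 2e-5})
        counts = pd.Series({"a": 0, "b": 0})
        est = estimate_risk_genes_and_saturation(counts, mu, 90, [250, 1000], replicates=100, seed=1)
        assert est.n_risk_genes == 0.0
        assert est.saturation == {250: 0.0, 1000: 0.0}

    def test_requires_enough_replicates(self):
        mu = pd.Series({"a": 1e-5})
        with pytest.raises(ValueError, match="replicates"):
            estimate_risk_genes_and_saturation(pd.Series({"a": 3}), mu, 90, [100], replicates=10, seed=1)

    def test_saturation_monotone_in_cohort_size(self, study_scale_universe):
        gm = study_scale_universe.gene_models
        mu = damaging_mutability(gm)
        mu = mu * (22.0 / (2 * 90 * mu.sum()))
        rng = np.random.default_rng(6)
        counts = pd.Series(rng.poisson(2 * 90 * mu), index=mu.index)
        top = mu.sort_values().index[-1]
        counts[top] += 3
        counts[mu.sort_values().index[-10:-1]] += 1
        est = estimate_risk_genes_and_saturation(counts, mu, 90, [250, 500, 1000], replicates=120, seed=2)
        sizes = sorted(est.saturation)
        vals = [est.saturation[s] for s in sizes]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_planted_risk_gene_count_recovered(self, study_scale_universe):
        """Self-consistency: a cohort simulated from M planted risk genes
        yields an interval covering M."""
        from trioburden.synth import simulate_dnv_count_table

        gm = study_scale_universe.gene_models
        mu = damaging_mutability(gm)
        mu_scaled = mu * (22.0 / (2 * 90 * mu.sum()))
        gm2 = gm.copy()
        scale = 22.0 / (2 * 90 * damaging_mutability(gm).sum())
        for c in gm2.columns:
            if c.startswith("p_"):
                gm2[c] = gm2[c] * scale
        rng = np.random.default_rng(12)
        M = 40
        risk = list(pd.Series(mu_scaled).sample(n=M, weights=mu_scaled, random_state=3).index)
        excess_total = 11.0  # matches the study's excess scale
        lam_extra = excess_total * (mu_scaled.loc[risk] / mu_scaled.loc[risk].sum())
        counts = pd.Series(rng.poisson(2 * 90 * mu_scaled), index=mu_scaled.index)
        counts.loc[risk] += rng.poisson(lam_extra.to_numpy())
        est = estimate_risk_genes_and_saturation(counts, mu_scaled, 90, [250], replicates=150, seed=4)
        lo, hi = est.interval
        assert lo <= M <= hi
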