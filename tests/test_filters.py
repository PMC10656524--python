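"""The three filter cascades and the kinship/duplicate QC."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from trioburden import (
    DnvFilterConfig,
    Family,
    SampleCall,
    TransmittedFilterConfig,
    TrioVariantCall,
    dnv_filter,
    duplicate_and_kinship,
    recessive_filter,
    transmitted_filter,
)
from trioburden.filters import king_ibd_proxy, naive_denovo_prescreen

TRIO = Family("F1", "kid", "dad", "mom", 1, True)


def sample(gt=(0, 0), dp=30, ad_alt=0, gq=99):
    return SampleCall(gt=gt, dp=dp, ad_ref=None if dp is None else dp - (ad_alt or 0), ad_alt=ad_alt, gq=gq)


def call(
    fclass="missense",
    kid=None,
    dad=None,
    mom=None,
    metasvm=None,
    mpc=None,
    mafs=None,
    vqsr=True,
):
    return TrioVariantCall(
        chrom="1",
        pos=100,
        ref="A",
        alt="G",
        family_id="F1",
        samples={
            "kid": kid or sample(gt=(0, 1), dp=17, ad_alt=8),
            "dad": dad or sample(dp=20),
            "mom": mom or sample(dp=20),
        },
        gene_id="GENE1",
        functional_class=fclass,
        metasvm=metasvm,
        mpc=mpc,
        maf_popmax_sources=mafs or {"exac": 0.0, "bravo": 0.0, "gnomad": 0.0},
        vqsr_pass=vqsr,
    )


class TestDnvFilter:
    def test_clean_dnv_passes(self):
        v = dnv_filter(call(), TRIO)
        assert v.passed and v.failed_rule is None

    def test_alt_ratio_threshold_is_028_below_ten_alt_reads(self):
        # 8 alt reads of 32 -> ratio 0.25: below the 0.28 bound that applies under 10 reads
        v = dnv_filter(call(kid=sample(gt=(0, 1), dp=32, ad_alt=8)), TRIO)
        assert not v.passed and v.failed_rule == "proband_alt_ratio"
        # 10 alt reads of 50 -> ratio 0.20 is allowed at >= 10 reads
        v = dnv_filter(call(kid=sample(gt=(0, 1), dp=50, ad_alt=10)), TRIO)
        assert v.passed

    def test_parent_alt_ratio_bound(self):
        v = dnv_filter(call(dad=sample(dp=50, ad_alt=2)), TRIO)  # 0.04 > 0.035
        assert not v.passed and v.failed_rule == "parent_alt_ratio"
        v = dnv_filter(call(dad=sample(dp=200, ad_alt=7)), TRIO)  # 0.035 inclusive
        assert v.passed

    def test_depth_alt_reads_class_and_maf_rules(self):
        assert dnv_filter(call(mom=sample(dp=9)), TRIO).failed_rule == "trio_depth"
        assert dnv_filter(call(kid=sample(gt=(0, 1), dp=12, ad_alt=4)), TRIO).failed_rule == "proband_alt_reads"
        assert dnv_filter(call(fclass="other"), TRIO).failed_rule == "exonic_class"
        assert dnv_filter(call(mafs={"exac": 5e-4}), TRIO).failed_rule == "population_maf"
        assert dnv_filter(call(mafs={"exac": 4e-4}), TRIO).passed  # inclusive bound

    def test_missing_support_fails_explicitly(self):
        v = dnv_filter(call(dad=sample(dp=None)), TRIO)
        assert v.failed_rule == "missing_support"

    def test_requires_complete_trio(self):
        duo = Family("F2", "kid", None, "mom", 1, True)
        with pytest.raises(ValueError, match="trio"):
            dnv_filter(call(), duo)

    def test_metrics_recorded_even_on_failure(self):
        v = dnv_filter(call(mom=sample(dp=9)), TRIO)
        assert v.metrics["proband_alt_ratio"] == pytest.approx(8 / 17)

    def test_tightening_thresholds_is_monotone(self):
        """No fail can become a pass when any threshold tightens (property)."""
        rng = np.random.default_rng(42)
        base = DnvFilterConfig()
        tight = DnvFilterConfig(min_trio_dp=12, min_proband_alt_reads=6,
                                min_alt_ratio_low=0.30, min_alt_ratio_high=0.25,
                                max_parent_alt_ratio=0.02, max_maf=1e-4)
        for _ in range(200):
            dp_k = int(rng.integers(5, 60))
            c = call(
                kid=sample(gt=(0, 1), dp=dp_k, ad_alt=int(rng.integers(0, dp_k + 1))),
                dad=sample(dp=int(rng.integers(5, 60)), ad_alt=int(rng.integers(0, 4))),
                mom=sample(dp=int(rng.integers(5, 60)), ad_alt=int(rng.integers(0, 4))),
                mafs={"exac": float(rng.choice([0.0, 1e-5, 2e-4, 1e-3]))},
            )
            if dnv_filter(c, TRIO, tight).passed:
                assert dnv_filter(c, TRIO, base).passed


class TestTransmittedFilter:
    def test_rare_dmis_passes(self):
        c = call(metasvm="D", mafs={"bravo": 1.48e-5, "gnomad": 1.48e-5, "exac": 0.0})
        v = transmitted_filter(c, TRIO, in_cohort_af=1e-3)
        assert v.passed

    def test_tolerated_missense_fails_class_rule(self):
        c = call(metasvm="T", mpc=1.0)
        assert transmitted_filter(c, TRIO, 0.0).failed_rule == "damaging_class"

    def test_mpc_alone_can_mark_damaging(self):
        c = call(metasvm="T", mpc=2.0)
        assert transmitted_filter(c, TRIO, 0.0).passed

    def test_in_cohort_frequency_bound(self):
        c = call(metasvm="D")
        assert transmitted_filter(c, TRIO, in_cohort_af=0.01).failed_rule == "cohort_maf"
        assert transmitted_filter(c, TRIO, in_cohort_af=5e-3).passed  # inclusive

    def test_vqsr_maf_depth_gq_rules(self):
        assert transmitted_filter(call(metasvm="D", vqsr=False), TRIO, 0.0).failed_rule == "vqsr"
        assert transmitted_filter(call(metasvm="D", mafs={"bravo": 1e-4}), TRIO, 0.0).failed_rule == "population_maf"
        assert transmitted_filter(call(metasvm="D", kid=sample(gt=(0, 1), dp=7, ad_alt=3)), TRIO, 0.0).failed_rule == "proband_depth"
        assert transmitted_filter(call(metasvm="D", kid=sample(gt=(0, 1), dp=30, ad_alt=12, gq=19)), TRIO, 0.0).failed_rule == "gq"

    def test_missing_gq_fails_missing_support(self):
        c = call(metasvm="D", kid=sample(gt=(0, 1), dp=30, ad_alt=12, gq=None))
        assert transmitted_filter(c, TRIO, 0.0).failed_rule == "missing_support"


def gene_calls(configs):
    """Build per-gene calls from (kid_gt, dad_gt, mom_gt, fclass) tuples."""
    out = []
    for i, (kid_gt, dad_gt, mom_gt, fclass) in enumerate(configs):
        out.append(
            TrioVariantCall(
                chrom="1", pos=1000 + i, ref="A", alt="T", family_id="F1",
                samples={
                    "kid": sample(gt=kid_gt, dp=30, ad_alt=15 if sum(kid_gt) == 1 else (30 if sum(kid_gt) == 2 else 0)),
                    "dad": sample(gt=dad_gt, dp=30, ad_alt=15 if sum(dad_gt) else 0),
                    "mom": sample(gt=mom_gt, dp=30, ad_alt=15 if sum(mom_gt) else 0),
                },
                gene_id="G", functional_class=fclass, metasvm="D" if fclass == "missense" else None,
                maf_popmax_sources={"bravo": 0.0}, vqsr_pass=True,
            )
        )
    return out


class TestRecessiveFilter:
    def test_trans_compound_het_passes_cis_fails(self):
        calls = gene_calls([
            ((0, 1), (0, 1), (0, 0), "missense"),   # from father
            ((0, 1), (0, 0), (0, 1), "stopgain"),   # from mother
        ])
        results = recessive_filter(calls, TRIO, {})
        comphet = [r for r in results if r[0].startswith("comphet")]
        assert len(comphet) == 1 and comphet[0][1].passed

    def test_same_parent_pair_is_cis(self):
        calls = gene_calls([
            ((0, 1), (0, 0), (0, 1), "missense"),
            ((0, 1), (0, 0), (0, 1), "stopgain"),
        ])
        results = recessive_filter(calls, TRIO, {})
        comphet = [r for r in results if r[0].startswith("comphet")]
        assert comphet and not comphet[0][1].passed and comphet[0][1].failed_rule == "cis_configuration"

    def test_singleton_gets_homozygotes_only(self):
        solo = Family("F9", "kid", None, None, 1, True)
        calls = [
            TrioVariantCall(
                chrom="1", pos=5, ref="A", alt="T", family_id="F9",
                samples={"kid": sample(gt=(1, 1), dp=30, ad_alt=30)},
                gene_id="G", functional_class="stopgain", maf_popmax_sources={"bravo": 0.0},
            ),
            TrioVariantCall(
                chrom="1", pos=6, ref="A", alt="T", family_id="F9",
                samples={"kid": sample(gt=(0, 1), dp=30, ad_alt=15)},
                gene_id="G", functional_class="stopgain", maf_popmax_sources={"bravo": 0.0},
            ),
        ]
        results = recessive_filter(calls, solo, {})
        assert [r[0].split(":")[0] for r in results] == ["hom"]
        assert results[0][1].passed

    def test_inframe_indel_is_admissible(self):
        calls = gene_calls([((1, 1), (0, 1), (0, 1), "inframe_indel")])
        results = recessive_filter(calls, TRIO, {})
        assert results and results[0][1].passed


class TestKinship:
    @staticmethod
    def simulate_family_genotypes(rng, n_common=4000, n_rare=60):
        af = rng.uniform(0.05, 0.5, n_common)
        fa = (rng.random((2, n_common)) < af).astype(int)
        mo = (rng.random((2, n_common)) < af).astype(int)
        other = (rng.random((2, n_common)) < af).astype(int)
        kid = fa[rng.integers(0, 2, n_common), np.arange(n_common)] + mo[
            rng.integers(0, 2, n_common), np.arange(n_common)
        ]
        common = pd.DataFrame(
            {"dad": fa.sum(0), "mom": mo.sum(0), "kid": kid, "other": other.sum(0)}
        ).T
        common.columns = [f"c{i}" for i in range(n_common)]
        rare = pd.DataFrame(0, index=common.index, columns=[f"r{i}" for i in range(4 * n_rare)])
        for j, s in enumerate(common.index):
            rare.loc[s, [f"r{i}" for i in range(j * n_rare, (j + 1) * n_rare)]] = 1
        return pd.concat([common, rare], axis=1), np.array([False] * n_common + [True] * (4 * n_rare))

    def test_parent_offspring_proxy_in_expected_band(self):
        rng = np.random.default_rng(7)
        g, rare_mask = self.simulate_family_genotypes(rng)
        prox = king_ibd_proxy(g.loc[:, ~rare_mask])
        assert 0.45 <= prox.loc["kid", "dad"] <= 0.55
        assert 0.45 <= prox.loc["kid", "mom"] <= 0.55
        assert abs(prox.loc["dad", "other"]) < 0.1
        assert prox.loc["dad", "dad"] == 1.0

    def test_duplicate_detection_keeps_deeper_sample(self):
        rng = np.random.default_rng(8)
        g, rare_mask = self.simulate_family_genotypes(rng)
        g.loc["dup_of_dad"] = g.loc["dad"]
        depth = pd.Series({"dad": 60.0, "mom": 55.0, "kid": 58.0, "other": 50.0, "dup_of_dad": 40.0})
        rep = duplicate_and_kinship(g, rare_mask, depth)
        assert ("dad", "dup_of_dad") in rep.duplicates
        assert rep.sharing.loc["dad", "dup_of_dad"] == 1.0

    def test_unrelated_pair_shares_few_rare_variants(self):
        rng = np.random.default_rng(9)
        g, rare_mask = self.simulate_family_genotypes(rng)
        rep = duplicate_and_kinship(g, rare_mask, pd.Series(50.0, index=g.index))
        assert rep.sharing.loc["dad", "other"] < 0.2
        assert rep.sharing.loc["dad", "mom"] < 0.8

    def test_sample_without_rare_variants_is_flagged_undefined(self):
        g = pd.DataFrame({"r1": [1, 0], "r2": [1, 0]}, index=["a", "b"])
        rep = duplicate_and_kinship(g, np.array([True, True]), pd.Series({"a": 1.0, "b": 1.0}))
        assert rep.undefined_samples == ["b"]


def test_prescreen_requires_mendelian_violation():
    assert naive_denovo_prescreen(call(), TRIO)
    assert not naive_denovo_prescreen(call(dad=sample(gt=(0, 1), dp=30, ad_alt=15)), TRIO)


def test_order_independence_of_conjunctive_rules():
    """The pass/fail verdict depends only on the record: evaluating with any
    single rule relaxed and re-tightened gives the same verdict."""
    c = call(kid=sample(gt=(0, 1), dp=32, ad_alt=8), mafs={"exac": 1e-3})
    v = dnv_filter(c, TRIO)
    assert not v.passed
    for f in dataclasses.fields(DnvFilterConfig):
        again = dnv_filter(c, TRIO, DnvFilterConfig(**{f.name: getattr(DnvFilterConfig(), f.name)}))
        assert again.passed == v.passed
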