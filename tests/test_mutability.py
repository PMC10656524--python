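"""The context mutability model against brute-force enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trioburden import (
    CaptureRegions,
    ContextRateTable,
    Transcript,
    classify_substitution,
    expected_dnv_count,
    gene_mutability,
    per_base_probabilities,
)
from trioburden.mutability import FRAMESHIFT_FACTOR, MUTATION_CLASSES, enumerate_substitutions

ORF = "ATGAAATGCCGATTAGGCTGCTGCTGGTAA"  # 10 codons, ATG...TAA
GENETIC_CODE = {}
_BASES = "ACGT"
from Bio.Seq import Seq  # noqa: E402

for a in _BASES:
    for b in _BASES:
        for c in _BASES:
            GENETIC_CODE[a + b + c] = str(Seq(a + b + c).translate())


def toy_transcript(orf=ORF, strand="+", flank="GGGGG"):
    contig = flank + orf + "C" * len(flank)
    if strand == "-":
        contig = str(Seq(contig).reverse_complement())
    return Transcript("toy", "ctg", strand, [(len(flank), len(flank) + len(orf))], contig)


def brute_force_class(orf: str, i: int, alt: str) -> str:
    """Independent oracle: mutate the ORF string and compare translations."""
    codon_i, off = i // 3, i % 3
    if codon_i == 0:
        return "startloss"
    codon = orf[3 * codon_i: 3 * codon_i + 3]
    new = codon[:off] + alt + codon[off + 1:]
    ref_aa, new_aa = GENETIC_CODE[codon], GENETIC_CODE[new]
    if ref_aa == "*":
        return "synonymous" if new_aa == "*" else "stoploss"
    if new_aa == "*":
        return "stopgain"
    return "synonymous" if new_aa == ref_aa else "missense"


class TestClassification:
    def test_every_substitution_matches_translation_oracle(self):
        t = toy_transcript()
        for i, ref in enumerate(ORF):
            for alt in _BASES:
                if alt == ref:
                    continue
                got = classify_substitution(t, 5 + i, alt)
                assert got == brute_force_class(ORF, i, alt), (i, ref, alt)

    def test_minus_strand_classification_matches_plus(self):
        tp, tm = toy_transcript(), toy_transcript(strand="-")
        for i, ref in enumerate(ORF):
            for alt in _BASES:
                if alt == ref:
                    continue
                # genomic position/alt of the same transcript change on '-'
                gpos_minus = len(tm.contig_seq) - 1 - (5 + i)
                galt = str(Seq(alt).complement())
                assert classify_substitution(tm, gpos_minus, galt) == classify_substitution(tp, 5 + i, alt)

    def test_site_outside_transcript_raises(self):
        with pytest.raises(ValueError, match="outside"):
            classify_substitution(toy_transcript(), 1, "A")


class TestPerBaseProbabilities:
    def test_interior_sites_and_uniform_rates(self):
        rates = ContextRateTable.uniform(1e-8)
        arr, skipped = per_base_probabilities("AAA", rates)
        assert arr.shape == (1, 3) and skipped == 0
        assert np.allclose(arr, 1e-8)
        arr, _ = per_base_probabilities("ACGT", rates)
        assert arr.shape == (2, 3)

    def test_inflated_context_only_hits_matching_sites(self):
        entries = {(ctx, alt): 1e-8 for ctx in
                   [a + b + c for a in _BASES for b in _BASES for c in _BASES]
                   for alt in _BASES if alt != ctx[1]}
        entries[("ACG", "T")] = 5e-7
        rates = ContextRateTable(entries)
        seq = "AACGAA"  # ACG context at interior index 1 (sequence position 2)
        arr, _ = per_base_probabilities(seq, rates)
        # row 1 is the C of ACG; its T column is inflated
        assert arr[1].max() == 5e-7
        assert np.count_nonzero(arr == 5e-7) == 1

    def test_non_acgt_site_skipped(self):
        rates = ContextRateTable.uniform(1e-8)
        with pytest.warns(UserWarning, match="skipped"):
            arr, skipped = per_base_probabilities("ANAAT", rates)
        assert skipped >= 1


class TestGeneMutability:
    def test_class_sums_equal_exhaustive_enumeration(self):
        rates = ContextRateTable.uniform(1e-8)
        t = toy_transcript()
        gm = gene_mutability(t, rates)
        # oracle: every one of the 90 substitutions counted by its class
        sums = {c: 0.0 for c in MUTATION_CLASSES}
        for i, ref in enumerate(ORF):
            for alt in _BASES:
                if alt != ref:
                    sums[brute_force_class(ORF, i, alt)] += 1e-8
        for c in ("synonymous", "missense", "stopgain", "stoploss", "startloss"):
            assert gm.p_class[c] == pytest.approx(sums[c], rel=1e-12), c

    def test_frameshift_is_snapshot_of_stopgain(self, small_universe):
        gm = small_universe.gene_models
        assert np.allclose(gm["p_frameshift"], FRAMESHIFT_FACTOR * gm["p_stopgain"], rtol=1e-12)

    def test_capture_restriction_removes_excluded_half(self):
        rates = ContextRateTable.uniform(1e-8)
        t = toy_transcript()
        full = gene_mutability(t, rates)
        half = CaptureRegions({"ctg": [(5, 20)]})  # first 15 coding bases only
        gm_half = gene_mutability(t, rates, capture=half)
        assert sum(gm_half.p_class[c] for c in MUTATION_CLASSES if c != "frameshift") == pytest.approx(
            15 * 3 * 1e-8
        )
        assert gm_half.p_class["missense"] <= full.p_class["missense"]

    def test_capture_monotonicity(self):
        rates = ContextRateTable.uniform(1e-8)
        t = toy_transcript()
        small = gene_mutability(t, rates, capture=CaptureRegions({"ctg": [(5, 14)]}))
        large = gene_mutability(t, rates, capture=CaptureRegions({"ctg": [(5, 26)]}))
        for c in MUTATION_CLASSES:
            assert large.p_class[c] >= small.p_class[c]

    def test_strand_invariance(self):
        rng = np.random.default_rng(5)
        entries = {}
        for a in _BASES:
            for b in _BASES:
                for c in _BASES:
                    for alt in _BASES:
                        if alt != b:
                            entries[(a + b + c, alt)] = float(np.exp(rng.normal(np.log(1e-8), 0.4)))
        rates = ContextRateTable(entries).symmetrized()
        plus = gene_mutability(toy_transcript(), rates)
        minus = gene_mutability(toy_transcript(strand="-"), rates)
        for c in MUTATION_CLASSES:
            assert plus.p_class[c] == pytest.approx(minus.p_class[c], rel=1e-9), c

    def test_conservation_against_per_substitution_table(self, small_universe):
        """Sum of class probabilities equals the sum of all per-site per-alt rates."""
        for gid in list(small_universe.transcripts)[:10]:
            gm_row = small_universe.gene_models.loc[gid]
            enum = small_universe.site_tables[gid]
            class_sum = sum(gm_row[f"p_{c}"] for c in MUTATION_CLASSES if c != "frameshift")
            assert class_sum == pytest.approx(enum["rate"].sum(), rel=1e-9)


class TestExpectedDnvCount:
    @pytest.mark.parametrize("p,n,expected", [(1e-5, 90, 1.8e-3), (0.0, 90, 0.0), (2.5e-4, 0, 0.0)])
    def test_diploid_scaling(self, p, n, expected):
        assert expected_dnv_count(p, n) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            expected_dnv_count(-1e-9, 90)

    def test_poisson_simulation_mean_matches_expectation(self):
        rng = np.random.default_rng(17)
        p = 3.1e-4
        lam = expected_dnv_count(p, 90)
        draws = rng.poisson(lam, size=10_000)
        assert draws.mean() == pytest.approx(lam, rel=0.05)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(rate=st.floats(min_value=1e-10, max_value=1e-6))
def test_uniform_rate_scales_linearly(rate):
    """Mutability is linear in the context rate (property)."""
    t = toy_transcript()
    base = gene_mutability(t, ContextRateTable.uniform(1e-8))
    scaled = gene_mutability(t, ContextRateTable.uniform(rate))
    for c in MUTATION_CLASSES:
        assert scaled.p_class[c] == pytest.approx(base.p_class[c] * rate / 1e-8, rel=1e-9)


def test_context_table_requires_all_entries():
    with pytest.raises(ValueError, match="192"):
        ContextRateTable({("AAA", "C"): 1e-8})


def test_context_table_roundtrip(tmp_path):
    table = ContextRateTable.uniform(2e-8)
    table.to_tsv(tmp_path / "rates.tsv")
    again = ContextRateTable.from_tsv(tmp_path / "rates.tsv")
    assert np.allclose(table.matrix, again.matrix)
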