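"""Variant filter cascades and sample-level kinship QC.

Three conjunctive rule cascades — de novo, rare transmitted dominant, and
recessive — each return a :class:`FilterVerdict` naming the first failing
rule (in documented order) while recording the metric computed for every
rule. Thresholds default to the study values and are configurable; all
printed <=/>= boundaries are inclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Family, Pedigree, TrioVariantCall
from .mutability import LOF_CLASSES

EXONIC_CLASSES = frozenset(
    {"synonymous", "missense", "splice_canonical", "frameshift", "stopgain", "stoploss", "startloss", "inframe_indel"}
)


@dataclass
class FilterVerdict:
    passed: bool
    failed_rule: str | None
    metrics: dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.passed != (self.failed_rule is None):
            raise ValueError("passed must be equivalent to failed_rule being None")


def is_lof(call: TrioVariantCall) -> bool:
    return call.functional_class in LOF_CLASSES


def is_dmis(call: TrioVariantCall, mpc_threshold: float = 2.0) -> bool:
    """Damaging missense: MetaSVM 'D' or MPC >= 2."""
    if call.functional_class != "missense":
        return False
    if call.metasvm == "D":
        return True
    return call.mpc is not None and call.mpc >= mpc_threshold


def is_damaging(call: TrioVariantCall, mpc_threshold: float = 2.0) -> bool:
    return is_lof(call) or is_dmis(call, mpc_threshold)


@dataclass
class DnvFilterConfig:
    min_trio_dp: int = 10
    min_proband_alt_reads: int = 5
    min_alt_ratio_low: float = 0.28   # applies below high_alt_read_count alt reads
    min_alt_ratio_high: float = 0.20
    high_alt_read_count: int = 10
    max_parent_alt_ratio: float = 0.035
    max_maf: float = 4e-4
    maf_source: str = "exac"


def naive_denovo_prescreen(call: TrioVariantCall, family: Family) -> bool:
    """Mendelian pre-screen when no upstream DNV caller output is supplied:
    proband heterozygous, both parents homozygous reference."""
    if family.kind != "trio":
        return False
    p = call.samples[family.proband_id]
    f = call.samples[family.father_id]
    m = call.samples[family.mother_id]
    return p.is_het and f.is_hom_ref and m.is_hom_ref


def dnv_filter(call: TrioVariantCall, family: Family, config: DnvFilterConfig | None = None) -> FilterVerdict:
    """De novo cascade: class, trio depth, proband alt support/ratio,
    parental contamination, and population-frequency rules, in that order."""
    cfg = config or DnvFilterConfig()
    if family.kind != "trio":
        raise ValueError(f"dnv_filter requires a complete trio; family {family.family_id} is a {family.kind}")
    p = call.samples[family.proband_id]
    fa = call.samples[family.father_id]
    mo = call.samples[family.mother_id]

    metrics: dict[str, object] = {}
    metrics["functional_class"] = call.functional_class
    dps = {sid: call.samples[sid].effective_dp for sid in (family.proband_id, family.father_id, family.mother_id)}
    metrics["trio_dp"] = dps
    metrics["proband_alt_reads"] = p.ad_alt
    metrics["proband_alt_ratio"] = p.alt_ratio
    metrics["parent_alt_ratios"] = (fa.alt_ratio, mo.alt_ratio)
    maf = call.maf(cfg.maf_source)
    metrics["population_maf"] = maf

    if any(v is None for v in dps.values()) or p.ad_alt is None or p.alt_ratio is None:
        return FilterVerdict(False, "missing_support", metrics)
    if fa.alt_ratio is None or mo.alt_ratio is None:
        return FilterVerdict(False, "missing_support", metrics)

    if call.functional_class not in EXONIC_CLASSES:
        return FilterVerdict(False, "exonic_class", metrics)
    if any(dp < cfg.min_trio_dp for dp in dps.values()):
        return FilterVerdict(False, "trio_depth", metrics)
    if p.ad_alt < cfg.min_proband_alt_reads:
        return FilterVerdict(False, "proband_alt_reads", metrics)
    ratio_min = cfg.min_alt_ratio_low if p.ad_alt < cfg.high_alt_read_count else cfg.min_alt_ratio_high
    if p.alt_ratio < ratio_min:
        return FilterVerdict(False, "proband_alt_ratio", metrics)
    if fa.alt_ratio > cfg.max_parent_alt_ratio or mo.alt_ratio > cfg.max_parent_alt_ratio:
        return FilterVerdict(False, "parent_alt_ratio", metrics)
    if maf is not None and maf > cfg.max_maf:
        return FilterVerdict(False, "population_maf", metrics)
    return FilterVerdict(True, None, metrics)


@dataclass
class TransmittedFilterConfig:
    max_maf: float = 5e-5
    maf_source: str = "bravo"
    max_cohort_maf: float = 5e-3
    min_proband_dp: int = 8
    min_gq: int = 20
    mpc_threshold: float = 2.0


def transmitted_filter(
    call: TrioVariantCall,
    family: Family,
    in_cohort_af: float,
    config: TransmittedFilterConfig | None = None,
) -> FilterVerdict:
    """Rare transmitted dominant cascade: VQSR, population and in-cohort
    frequency, proband depth and GQ, and damaging-class rules."""
    cfg = config or TransmittedFilterConfig()
    p = call.samples[family.proband_id]
    maf = call.maf(cfg.maf_source)
    metrics: dict[str, object] = {
        "vqsr_pass": call.vqsr_pass,
        "population_maf": maf,
        "cohort_maf": in_cohort_af,
        "proband_dp": p.effective_dp,
        "proband_gq": p.gq,
        "damaging_class": is_damaging(call, cfg.mpc_threshold),
    }
    if p.gq is None or p.effective_dp is None:
        return FilterVerdict(False, "missing_support", metrics)
    if not call.vqsr_pass:
        return FilterVerdict(False, "vqsr", metrics)
    if maf is not None and maf > cfg.max_maf:
        return FilterVerdict(False, "population_maf", metrics)
    if in_cohort_af > cfg.max_cohort_maf:
        return FilterVerdict(False, "cohort_maf", metrics)
    if p.effective_dp < cfg.min_proband_dp:
        return FilterVerdict(False, "proband_depth", metrics)
    if p.gq < cfg.min_gq:
        return FilterVerdict(False, "gq", metrics)
    if not is_damaging(call, cfg.mpc_threshold):
        return FilterVerdict(False, "damaging_class", metrics)
    return FilterVerdict(True, None, metrics)


@dataclass
class RecessiveFilterConfig:
    max_maf: float = 1e-3
    maf_source: str = "bravo"
    max_cohort_maf: float = 1e-2
    min_proband_dp: int = 8
    min_gq: int = 20
    mpc_threshold: float = 2.0


def _recessive_record_verdict(
    call: TrioVariantCall, family: Family, in_cohort_af: float, cfg: RecessiveFilterConfig
) -> FilterVerdict:
    p = call.samples[family.proband_id]
    damaging = is_damaging(call, cfg.mpc_threshold) or call.functional_class == "inframe_indel"
    maf = call.maf(cfg.maf_source)
    metrics: dict[str, object] = {
        "vqsr_pass": call.vqsr_pass,
        "population_maf": maf,
        "cohort_maf": in_cohort_af,
        "proband_dp": p.effective_dp,
        "proband_gq": p.gq,
        "damaging_class": damaging,
    }
    if p.gq is None or p.effective_dp is None:
        return FilterVerdict(False, "missing_support", metrics)
    if not call.vqsr_pass:
        return FilterVerdict(False, "vqsr", metrics)
    if maf is not None and maf > cfg.max_maf:
        return FilterVerdict(False, "population_maf", metrics)
    if in_cohort_af > cfg.max_cohort_maf:
        return FilterVerdict(False, "cohort_maf", metrics)
    if p.effective_dp < cfg.min_proband_dp:
        return FilterVerdict(False, "proband_depth", metrics)
    if p.gq < cfg.min_gq:
        return FilterVerdict(False, "gq", metrics)
    if not damaging:
        return FilterVerdict(False, "damaging_class", metrics)
    return FilterVerdict(True, None, metrics)


def recessive_filter(
    calls_in_gene: list[TrioVariantCall],
    family: Family,
    in_cohort_afs: dict[tuple, float],
    config: RecessiveFilterConfig | None = None,
) -> list[tuple[str, FilterVerdict]]:
    """Recessive genotype configurations in one gene for one family.

    Returns homozygous hits and, for families with both parents, parent-
    phased compound-heterozygous pairs (one passing het inherited from each
    parent). Probands without both parents contribute homozygotes only.
    """
    cfg = config or RecessiveFilterConfig()
    verdicts = {
        c.site_key: _recessive_record_verdict(c, family, in_cohort_afs.get(c.site_key, 0.0), cfg)
        for c in calls_in_gene
    }
    out: list[tuple[str, FilterVerdict]] = []
    passing = []
    for c in calls_in_gene:
        v = verdicts[c.site_key]
        p = c.samples[family.proband_id]
        if p.is_hom_alt:
            out.append((f"hom:{c.chrom}:{c.pos}:{c.ref}:{c.alt}", v))
        elif p.is_het and v.passed:
            passing.append(c)

    if family.kind == "trio":
        for a, b in itertools.combinations(passing, 2):
            pa = _parent_origin(a, family)
            pb = _parent_origin(b, family)
            label = f"comphet:{a.chrom}:{a.pos}+{b.chrom}:{b.pos}"
            if pa and pb and pa != pb:
                out.append((label, FilterVerdict(True, None, {"origins": (pa, pb)})))
            elif pa and pb:  # both from the same parent: in cis, not a hit
                out.append((label, FilterVerdict(False, "cis_configuration", {"origins": (pa, pb)})))
    return out


def _parent_origin(call: TrioVariantCall, family: Family) -> str | None:
    fa = call.samples[family.father_id]
    mo = call.samples[family.mother_id]
    fa_has = (fa.n_alt_alleles or 0) > 0
    mo_has = (mo.n_alt_alleles or 0) > 0
    if fa_has and not mo_has:
        return "father"
    if mo_has and not fa_has:
        return "mother"
    return None


@dataclass
class KinshipReport:
    """Pairwise duplicate and relatedness QC over the cohort."""

    sharing: pd.DataFrame                     # rare-variant Jaccard sharing, samples x samples
    ibd_proxy: pd.DataFrame                   # KING-style 2*phi, samples x samples
    duplicates: list[tuple[str, str]]         # (retained, discarded)
    parent_offspring_flags: list[tuple[str, str, float]]  # pairs outside [0.45, 0.55]
    undefined_samples: list[str]              # no rare variants: sharing undefined


def rare_variant_sharing(rare_sites: dict[str, set]) -> pd.DataFrame:
    """Jaccard sharing of rare-variant sites between every sample pair."""
    samples = sorted(rare_sites)
    n = len(samples)
    mat = np.ones((n, n))
    for i, a in enumerate(samples):
        for j in range(i + 1, n):
            b = samples[j]
            union = rare_sites[a] | rare_sites[b]
            mat[i, j] = mat[j, i] = (len(rare_sites[a] & rare_sites[b]) / len(union)) if union else np.nan
    return pd.DataFrame(mat, index=samples, columns=samples)


def king_ibd_proxy(genotypes: pd.DataFrame) -> pd.DataFrame:
    """IBD-sharing proxy (~ PLINK pi-hat) from biallelic genotype counts.

    ``genotypes``: samples x sites matrix of alt-allele counts {0,1,2}.
    Uses the within-pair robust kinship estimate
    phi = (N_het_both - 2 * N_opposite_hom) / (N_het_i + N_het_j)
    and reports 2*phi, which is ~1 for duplicates, ~0.5 for parent-offspring
    pairs, and ~0 for unrelated pairs.
    """
    g = genotypes.to_numpy(dtype=float)
    samples = list(genotypes.index)
    n = len(samples)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            gi, gj = g[i], g[j]
            ok = ~(np.isnan(gi) | np.isnan(gj))
            het_i = np.sum(gi[ok] == 1)
            het_j = np.sum(gj[ok] == 1)
            if het_i + het_j == 0:
                continue
            het_both = np.sum((gi[ok] == 1) & (gj[ok] == 1))
            opp_hom = np.sum(((gi[ok] == 0) & (gj[ok] == 2)) | ((gi[ok] == 2) & (gj[ok] == 0)))
            phi = (het_both - 2.0 * opp_hom) / (het_i + het_j)
            out[i, j] = out[j, i] = 2.0 * phi
    return pd.DataFrame(out, index=samples, columns=samples)


def duplicate_and_kinship(
    genotypes: pd.DataFrame,
    rare_mask: np.ndarray,
    mean_depth: pd.Series,
    pedigree: Pedigree | None = None,
    duplicate_threshold: float = 0.80,
    po_band: tuple[float, float] = (0.45, 0.55),
) -> KinshipReport:
    """Duplicate detection and parent-offspring plausibility QC.

    ``genotypes``: samples x sites alt-allele counts; ``rare_mask`` marks the
    rare columns used for duplicate sharing (common columns feed the IBD
    proxy). Pairs sharing >= 80% of rare variants are flagged duplicate and
    the sample with greater mean depth is retained; proband-parent pairs
    with an IBD proxy outside [0.45, 0.55] are flagged.
    """
    rare = genotypes.loc[:, rare_mask]
    rare_sites = {
        s: set(rare.columns[np.nan_to_num(rare.loc[s].to_numpy(dtype=float)) > 0]) for s in genotypes.index
    }
    undefined = [s for s, sites in rare_sites.items() if not sites]
    sharing = rare_variant_sharing(rare_sites)

    common = genotypes.loc[:, ~np.asarray(rare_mask)]
    ibd = king_ibd_proxy(common) if common.shape[1] else pd.DataFrame(
        np.eye(len(genotypes)), index=genotypes.index, columns=genotypes.index
    )

    duplicates: list[tuple[str, str]] = []
    samples = list(genotypes.index)
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            frac = sharing.loc[a, b]
            if pd.notna(frac) and frac >= duplicate_threshold:
                keep, drop = (a, b) if mean_depth.get(a, 0) >= mean_depth.get(b, 0) else (b, a)
                duplicates.append((keep, drop))

    po_flags: list[tuple[str, str, float]] = []
    if pedigree is not None:
        for fam in pedigree.families:
            for parent in (fam.father_id, fam.mother_id):
                if parent and parent in ibd.index and fam.proband_id in ibd.index:
                    val = float(ibd.loc[fam.proband_id, parent])
                    if not po_band[0] <= val <= po_band[1]:
                        po_flags.append((fam.proband_id, parent, val))
    return KinshipReport(sharing, ibd, duplicates, po_flags, undefined)


def in_cohort_af(
    calls: list[TrioVariantCall], pedigree: Pedigree, exclude: set[str] | None = None
) -> dict[tuple, float]:
    """In-cohort alternate-allele frequency per site, over founders only
    (parents plus parentless probands), excluding flagged duplicates."""
    exclude = exclude or set()
    founders = [s for s in pedigree.founder_ids if s not in exclude]
    ac: dict[tuple, int] = {}
    an: dict[tuple, int] = {}
    seen: dict[tuple, set] = {}
    for c in calls:
        key = c.site_key
        seen.setdefault(key, set())
        for sid in founders:
            if sid in c.samples and sid not in seen[key]:
                s = c.samples[sid]
                alleles = [a for a in s.gt if a is not None]
                an[key] = an.get(key, 0) + len(alleles)
                ac[key] = ac.get(key, 0) + sum(alleles)
                seen[key].add(sid)
    return {k: (ac[k] / an[k] if an.get(k) else 0.0) for k in an}
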