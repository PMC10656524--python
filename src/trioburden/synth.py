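"""Synthetic gene universes and trio cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
Poisson DNV process over per-gene, per-class mutabilities derived from a
trinucleotide-context rate table; a multinomial transmitted-variant process
within pLI strata; spiked risk genes with configurable fold-enrichment of
damaging DNVs; genotype-level read support (Poisson depth, Beta-distributed
heterozygous allele balance, a small error-allele rate in homozygous
reference calls); and deliberately planted filter-violating records and
duplicate samples, all recorded in a ground-truth object. All randomness
flows from a single seed through named substreams, so adding a stage never
perturbs earlier draws.

It does not attempt real human sequence, linkage disequilibrium, or
population structure.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .cohort import CaptureRegions, Family, Pedigree
from .mutability import (
    BASES,
    ContextRateTable,
    Transcript,
    enumerate_substitutions,
    gene_mutability,
    gene_models_frame,
)
from .transmitted import N_STRATA, PLI_QUARTILE_BOUNDS, assign_strata

_STOP_CODONS = ("TAA", "TAG", "TGA")

#: rule ids the generator can plant, mapped to the cascade they belong to
PLANTABLE_DNV_RULES = (
    "exonic_class",
    "trio_depth",
    "proband_alt_reads",
    "proband_alt_ratio",
    "parent_alt_ratio",
    "population_maf",
    "missing_support",
)
PLANTABLE_TRANSMITTED_RULES = (
    "vqsr",
    "population_maf",
    "cohort_maf",
    "proband_depth",
    "gq",
    "damaging_class",
)


@dataclass
class SyntheticCohortSpec:
    """Generative parameters of a synthetic trio-exome study.

    Defaults mirror the study conditions: 90 trios / 13 duos / 11
    singletons over a 2,000-gene desk-scale exome whose context rates are
    calibrated so the cohort-level expected total DNV count is ~99.7.
    """

    seed: int
    n_genes: int = 2000
    n_trios: int = 90
    n_duos: int = 13
    n_singletons: int = 11
    target_total_expected_dnvs: float = 99.7
    context_rate_sigma: float = 0.5        # log-normal spread of context rates
    mean_cds_codons: float = 150.0         # log-normal gene size
    cds_log_sigma: float = 0.4
    pli_strata_weights: tuple = (0.225, 0.225, 0.225, 0.225, 0.10)
    dmis_beta: tuple = (3.0, 7.0)          # per-gene damaging-missense fraction
    n_risk_genes: int = 0
    risk_fold: float | None = None         # damaging-DNV fold in risk genes
    target_attributable_fraction: float | None = None
    transmitted_L: tuple = (40, 50, 60, 50, 20)  # damaging het totals per stratum
    depth_mean: float = 60.0
    het_alt_beta: tuple = (20.0, 20.0)
    error_allele_rate: float = 0.005
    default_gq: int = 99
    planted_dnv_rules: tuple = ()
    planted_transmitted_rules: tuple = ()
    n_duplicate_pairs: int = 0
    n_common_background_sites: int = 800   # drive the IBD-proxy precision
    n_rare_per_founder: int = 25           # drive duplicate-sharing detection

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory; no implicit randomness")
        for name in ("n_genes", "n_trios", "n_duos", "n_singletons", "n_risk_genes", "n_duplicate_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.risk_fold is not None and self.risk_fold < 1:
            raise ValueError("risk_fold must be >= 1")
        af = self.target_attributable_fraction
        if af is not None and not 0.0 <= af < 1.0:
            raise ValueError("target attributable fraction must be in [0, 1)")
        if len(self.transmitted_L) != N_STRATA:
            raise ValueError(f"transmitted_L must have {N_STRATA} entries")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream: a fresh generator keyed by (seed, stream name)."""
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)))


@dataclass
class SyntheticUniverse:
    """A generated gene universe and everything derived from it."""

    spec: SyntheticCohortSpec
    transcripts: dict[str, Transcript]
    rates: ContextRateTable
    gene_models: pd.DataFrame              # gene_models_frame() layout
    site_tables: dict[str, pd.DataFrame]   # all possible SNVs per gene
    capture: CaptureRegions

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "contigs.fa",
            "exons": out / "exons.tsv",
            "rates": out / "context_rates.tsv",
            "genes": out / "genes.tsv",
            "bed": out / "capture.bed",
        }
        with open(paths["fasta"], "w") as fh:
            for gid in sorted(self.transcripts):
                t = self.transcripts[gid]
                fh.write(f">{t.contig}\n{t.contig_seq}\n")
        rows = []
        for gid in sorted(self.transcripts):
            t = self.transcripts[gid]
            for s, e in t.exons:
                rows.append((gid, t.contig, s, e, t.strand))
        pd.DataFrame(rows, columns=["gene", "contig", "start", "end", "strand"]).to_csv(
            paths["exons"], sep="\t", index=False
        )
        self.rates.to_tsv(paths["rates"])
        self.gene_models.reset_index().to_csv(paths["genes"], sep="\t", index=False, float_format="%.8g")
        with open(paths["bed"], "w") as fh:
            for contig in sorted(self.capture.intervals):
                for s, e in self.capture.intervals[contig]:
                    fh.write(f"{contig}\t{s}\t{e}\n")
        return paths


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"]
    non_stop = [a + b + c for a in BASES for b in BASES for c in BASES if a + b + c not in _STOP_CODONS]
    idx = rng.integers(0, len(non_stop), size=n_codons - 2)
    codons.extend(non_stop[i] for i in idx)
    codons.append(_STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _draw_pli(rng: np.random.Generator, weights) -> float:
    b1, b2, b3 = PLI_QUARTILE_BOUNDS
    k = rng.choice(5, p=np.asarray(weights) / np.sum(weights))
    if k == 0:
        return float(rng.uniform(0, b1))
    if k == 1:
        return float(np.exp(rng.uniform(np.log(b1), np.log(b2))))
    if k == 2:
        return float(np.exp(rng.uniform(np.log(b2), np.log(b3))))
    if k == 3:
        return float(rng.uniform(b3, 1.0))
    return float("nan")


def simulate_gene_universe(spec: SyntheticCohortSpec) -> SyntheticUniverse:
    """Random ORFs, a context-rate table calibrated to the target DNV scale,
    pLI drawn from the stated stratum mixture, and derived mutabilities."""
    if spec.n_genes < 10:
        raise ValueError("n_genes must be >= 10 (pLI strata unfillable below that)")
    rng = spec.rng("universe")

    base_rate = 1.5e-8
    log_rates = rng.normal(np.log(base_rate), spec.context_rate_sigma, size=192)
    entries = {}
    i = 0
    for c0 in BASES:
        for c1 in BASES:
            for c2 in BASES:
                for alt in BASES:
                    if alt != c1:
                        entries[(c0 + c1 + c2, alt)] = float(np.exp(log_rates[i]))
                        i += 1
    rates = ContextRateTable(entries)

    transcripts: dict[str, Transcript] = {}
    pli = {}
    dmis = {}
    expr = {}
    flank = 12
    n_codons = np.maximum(
        12, np.round(np.exp(rng.normal(np.log(spec.mean_cds_codons), spec.cds_log_sigma, spec.n_genes))).astype(int)
    )
    strands = rng.choice(["+", "-"], size=spec.n_genes, p=[0.6, 0.4])
    for g in range(spec.n_genes):
        gid = f"G{g:04d}"
        orf = _random_orf(rng, int(n_codons[g]))
        strand = strands[g]
        insert = orf if strand == "+" else _revcomp(orf)
        contig_seq = _random_seq(rng, flank) + insert + _random_seq(rng, flank)
        transcripts[gid] = Transcript(
            gene_id=gid,
            contig=f"c{gid}",
            strand=strand,
            exons=[(flank, flank + len(orf))],
            contig_seq=contig_seq,
        )
        pli[gid] = _draw_pli(rng, spec.pli_strata_weights)
        dmis[gid] = float(rng.beta(*spec.dmis_beta))
        expr[gid] = float(np.exp(rng.normal(1.0, 1.0)))

    capture = CaptureRegions({t.contig: [(0, len(t.contig_seq))] for t in transcripts.values()})

    models = [
        gene_mutability(transcripts[gid], rates, capture=capture, pli=pli[gid],
                        dmis_fraction=dmis[gid], mean_expression=expr[gid])
        for gid in sorted(transcripts)
    ]
    frame = gene_models_frame(models)
    target_sum = spec.target_total_expected_dnvs / (2.0 * spec.n_trios)
    scale = target_sum / float(
        (frame["p_synonymous"] + frame["p_missense"] + frame["p_splice_canonical"]
         + frame["p_stopgain"] + frame["p_stoploss"] + frame["p_startloss"] + frame["p_frameshift"]).sum()
    )
    rates = rates.scaled(scale)
    for c in frame.columns:
        if c.startswith("p_"):
            frame[c] = frame[c] * scale

    site_tables = {
        gid: enumerate_substitutions(transcripts[gid], rates, capture=capture) for gid in sorted(transcripts)
    }
    return SyntheticUniverse(
        spec=spec, transcripts=transcripts, rates=rates, gene_models=frame,
        site_tables=site_tables, capture=capture,
    )


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    risk_genes: list[str] = field(default_factory=list)
    risk_folds: dict[str, float] = field(default_factory=dict)
    attributable_fraction: float = 0.0
    dnv_sites: list[dict] = field(default_factory=list)
    transmitted_counts: dict[str, int] = field(default_factory=dict)
    planted_violations: list[dict] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["duplicate_pairs"] = [tuple(p) for p in d.get("duplicate_pairs", [])]
        return cls(**d)


@dataclass
class _SimVariant:
    contig: str
    pos: int           # 0-based
    ref: str
    alt: str
    gene: str | None
    fclass: str | None
    metasvm: str | None
    mpc: float | None
    mafs: dict
    vqsr_pass: bool
    genotypes: dict    # sample -> (gt tuple, dp, ad_ref, ad_alt, gq); absent -> default hom-ref


@dataclass
class SimulatedCohort:
    """In-memory cohort plus serialization to VCF/PED/BED and ground truth."""

    spec: SyntheticCohortSpec
    universe: SyntheticUniverse
    pedigree: Pedigree
    extra_samples: list[str]
    variants: list[_SimVariant]
    truth: GroundTruth

    @property
    def sample_ids(self) -> list[str]:
        return self.pedigree.sample_ids + self.extra_samples

    def genotype_matrix(self) -> pd.DataFrame:
        """Samples x sites matrix of alt-allele counts (kinship QC input)."""
        samples = self.sample_ids
        cols = {}
        for v in self.variants:
            key = f"{v.contig}:{v.pos}:{v.ref}:{v.alt}"
            col = np.zeros(len(samples))
            for i, s in enumerate(samples):
                if s in v.genotypes:
                    gt = v.genotypes[s][0]
                    col[i] = np.nan if any(a is None for a in gt) else sum(gt)
            cols[key] = col
        return pd.DataFrame(cols, index=samples)

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = self.universe.write(out)
        paths["ped"] = out / "cohort.ped"
        paths["vcf"] = out / "cohort.vcf"
        paths["truth"] = out / "ground_truth.json"
        _write_ped(self.pedigree, paths["ped"])
        _write_vcf(self, paths["vcf"])
        self.truth.to_json(paths["truth"])
        return paths


def _write_ped(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for fam in ped.families:
            for pid, sex in ((fam.father_id, 1), (fam.mother_id, 2)):
                if pid:
                    fh.write(f"{fam.family_id}\t{pid}\t0\t0\t{sex}\t1\n")
            fh.write(
                f"{fam.family_id}\t{fam.proband_id}\t{fam.father_id or 0}\t{fam.mother_id or 0}\t"
                f"{fam.proband_sex}\t2\n"
            )


def _write_vcf(cohort: SimulatedCohort, path) -> None:
    header = pysam.VariantHeader()
    contigs = sorted({t.contig for t in cohort.universe.transcripts.values()} | {"cBG"})
    for c in contigs:
        length = len(cohort.universe.transcripts[c[1:]].contig_seq) if c != "cBG" else 100000
        header.contigs.add(c, length=max(length, 1000))
    header.filters.add("FAIL_VQSR", None, None, "Failed variant quality score recalibration")
    header.info.add("GENE", 1, "String", "Gene id")
    header.info.add("FCLASS", 1, "String", "Functional class")
    header.info.add("METASVM", 1, "String", "MetaSVM deleteriousness call (D/T)")
    header.info.add("MPC", 1, "Float", "MPC score")
    header.info.add("AF_GNOMAD", 1, "Float", "Population allele frequency (gnomAD-like)")
    header.info.add("AF_BRAVO", 1, "Float", "Population allele frequency (BRAVO-like)")
    header.info.add("AF_EXAC", 1, "Float", "Population allele frequency (ExAC-like)")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    samples = cohort.sample_ids
    for s in samples:
        header.add_sample(s)

    default_rng = cohort.spec.rng("vcf_defaults")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(cohort.variants, key=lambda x: (x.contig, x.pos, x.ref, x.alt)):
            rec = vcf.new_record(contig=v.contig, start=v.pos, alleles=(v.ref, v.alt))
            if v.gene:
                rec.info["GENE"] = v.gene
            if v.fclass:
                rec.info["FCLASS"] = v.fclass
            if v.metasvm:
                rec.info["METASVM"] = v.metasvm
            if v.mpc is not None:
                rec.info["MPC"] = v.mpc
            for src, key in (("gnomad", "AF_GNOMAD"), ("bravo", "AF_BRAVO"), ("exac", "AF_EXAC")):
                if src in v.mafs:
                    rec.info[key] = v.mafs[src]
            if not v.vqsr_pass:
                rec.filter.add("FAIL_VQSR")
            else:
                rec.filter.add("PASS")
            for s in samples:
                fs = rec.samples[s]
                if s in v.genotypes:
                    gt, dp, ad_ref, ad_alt, gq = v.genotypes[s]
                else:
                    dp = int(max(10, default_rng.poisson(cohort.spec.depth_mean)))
                    ad_alt = 0
                    ad_ref = dp
                    gt, gq = (0, 0), cohort.spec.default_gq
                fs["GT"] = gt
                if dp is not None:
                    fs["DP"] = dp
                if ad_ref is not None or ad_alt is not None:
                    fs["AD"] = (ad_ref, ad_alt)
                if gq is not None:
                    fs["GQ"] = gq
            vcf.write(rec)


def _make_pedigree(spec: SyntheticCohortSpec, rng: np.random.Generator) -> Pedigree:
    families = []
    i = 0
    for _ in range(spec.n_trios):
        fid = f"F{i:03d}"
        families.append(Family(fid, f"{fid}p", f"{fid}f", f"{fid}m", int(rng.integers(1, 3)), True))
        i += 1
    for _ in range(spec.n_duos):
        fid = f"F{i:03d}"
        families.append(Family(fid, f"{fid}p", None, f"{fid}m", int(rng.integers(1, 3)), True))
        i += 1
    for _ in range(spec.n_singletons):
        fid = f"F{i:03d}"
        families.append(Family(fid, f"{fid}p", None, None, int(rng.integers(1, 3)), True))
        i += 1
    return Pedigree(families)


def _hom_ref_support(rng, spec, max_ratio=None):
    while True:
        dp = int(max(10, rng.poisson(spec.depth_mean)))
        ad_alt = int(rng.binomial(dp, spec.error_allele_rate))
        if max_ratio is None or ad_alt / dp <= max_ratio:
            return ((0, 0), dp, dp - ad_alt, ad_alt, spec.default_gq)


def _het_support(rng, spec, min_alt=5, ratio_rule=True, min_dp=10):
    a, b = spec.het_alt_beta
    while True:
        dp = int(max(min_dp, rng.poisson(spec.depth_mean)))
        ad_alt = int(rng.binomial(dp, rng.beta(a, b)))
        ratio = ad_alt / dp
        if ad_alt < min_alt:
            continue
        if ratio_rule:
            need = 0.28 if ad_alt < 10 else 0.20
            if ratio < need:
                continue
        return ((0, 1), dp, dp - ad_alt, ad_alt, spec.default_gq)


def resolve_risk_parameters(
    spec: SyntheticCohortSpec, gene_models: pd.DataFrame, risk_genes: list[str]
) -> tuple[float, float]:
    """Reconcile risk fold and target attributable fraction.

    Expected excess damaging DNVs = sum_risk 2 * N * p_damaging * (fold-1);
    the attributable fraction is that excess over N. Given a target
    fraction the fold is derived; given both, they must agree or the
    feasible fraction is reported in the error.
    """
    dmis_frac = gene_models["dmis_fraction"]
    p_dam = (
        gene_models["p_stopgain"] + gene_models["p_stoploss"] + gene_models["p_startloss"]
        + gene_models["p_splice_canonical"] + gene_models["p_frameshift"]
        + dmis_frac * gene_models["p_missense"]
    )
    p_risk = float(p_dam.loc[risk_genes].sum())
    if spec.target_attributable_fraction is not None:
        if p_risk <= 0:
            raise ValueError("risk genes carry zero damaging mutability; any nonzero target fraction is infeasible")
        fold = 1.0 + spec.target_attributable_fraction / (2.0 * p_risk)
        if spec.risk_fold is not None:
            feasible = 2.0 * p_risk * (spec.risk_fold - 1.0)
            if not np.isclose(feasible, spec.target_attributable_fraction, rtol=0.01):
                raise ValueError(
                    f"target attributable fraction {spec.target_attributable_fraction} infeasible at "
                    f"fold {spec.risk_fold}; the feasible fraction is {feasible:.4f}"
                )
            fold = spec.risk_fold
        return fold, spec.target_attributable_fraction
    fold = spec.risk_fold if spec.risk_fold is not None else 1.0
    return fold, 2.0 * p_risk * (fold - 1.0)


def damaging_mutability(gene_models: pd.DataFrame) -> pd.Series:
    """LoF-class plus dmis_fraction-weighted missense mutability per gene."""
    return (
        gene_models["p_stopgain"] + gene_models["p_stoploss"] + gene_models["p_startloss"]
        + gene_models["p_splice_canonical"] + gene_models["p_frameshift"]
        + gene_models["dmis_fraction"] * gene_models["p_missense"]
    )


def simulate_dnv_count_table(
    gene_models: pd.DataFrame,
    n_trios: int,
    rng: np.random.Generator,
    risk_folds: pd.Series | None = None,
) -> pd.DataFrame:
    """Fast count-level DNV draw: per-gene Poisson counts per class family.

    Damaging classes (LoF + damaging share of missense) are scaled by the
    per-gene fold; tolerated classes are not. Returns columns syn, t_mis,
    d_mis, lof, protein_damaging, protein_altering, total.
    """
    fold = pd.Series(1.0, index=gene_models.index)
    if risk_folds is not None:
        fold.loc[risk_folds.index] = risk_folds.astype(float)
    scale = 2.0 * n_trios
    dmis_frac = gene_models["dmis_fraction"]
    lam_syn = scale * gene_models["p_synonymous"]
    lam_tmis = scale * gene_models["p_missense"] * (1 - dmis_frac)
    lam_dmis = scale * gene_models["p_missense"] * dmis_frac * fold
    p_lof = (
        gene_models["p_stopgain"] + gene_models["p_stoploss"] + gene_models["p_startloss"]
        + gene_models["p_splice_canonical"] + gene_models["p_frameshift"]
    )
    lam_lof = scale * p_lof * fold
    out = pd.DataFrame(
        {
            "syn": rng.poisson(lam_syn),
            "t_mis": rng.poisson(lam_tmis),
            "d_mis": rng.poisson(lam_dmis),
            "lof": rng.poisson(lam_lof),
        },
        index=gene_models.index,
    )
    out["protein_damaging"] = out["d_mis"] + out["lof"]
    out["protein_altering"] = out["t_mis"] + out["d_mis"] + out["lof"]
    out["total"] = out["protein_altering"] + out["syn"]
    return out


def _sample_site(rng, table: pd.DataFrame, classes) -> pd.Series | None:
    sub = table[table["functional_class"].isin(classes)]
    if not len(sub):
        return None
    w = sub["rate"].to_numpy()
    return sub.iloc[int(rng.choice(len(sub), p=w / w.sum()))]


def simulate_cohort(spec: SyntheticCohortSpec, universe: SyntheticUniverse) -> SimulatedCohort:
    """Draw a full cohort: DNVs, transmitted variants, background genotypes,
    planted violations and duplicate samples, with ground truth."""
    ped = _make_pedigree(spec, spec.rng("pedigree"))
    trios = ped.trios
    gm = universe.gene_models
    truth = GroundTruth()
    variants: list[_SimVariant] = []

    # --- risk genes and DNV process -------------------------------------
    rng = spec.rng("dnv")
    genes = list(gm.index)
    if spec.n_risk_genes:
        mu_dam = damaging_mutability(gm)
        w = mu_dam.to_numpy() / mu_dam.sum()
        risk = [genes[i] for i in rng.choice(len(genes), size=spec.n_risk_genes, replace=False, p=w)]
        fold, af = resolve_risk_parameters(spec, gm, risk)
        truth.risk_genes = sorted(risk)
        truth.risk_folds = {g: fold for g in risk}
        truth.attributable_fraction = af
    counts = simulate_dnv_count_table(
        gm, len(trios), rng,
        risk_folds=pd.Series(truth.risk_folds) if truth.risk_folds else None,
    )
    for gid in genes:
        table = universe.site_tables[gid]
        t = universe.transcripts[gid]
        row = counts.loc[gid]
        jobs = (
            [("synonymous", ("synonymous",), None)] * int(row["syn"])
            + [("missense_t", ("missense",), "T")] * int(row["t_mis"])
            + [("missense_d", ("missense",), "D")] * int(row["d_mis"])
        )
        lof_snv_classes = ("stopgain", "stoploss", "startloss", "splice_canonical")
        for _ in range(int(row["lof"])):
            jobs.append(("lof", lof_snv_classes, None))
        for kind, classes, metasvm in jobs:
            fam = trios[int(rng.integers(0, len(trios)))]
            if kind == "lof" and rng.random() < (1.25 / (1 + 1.25)) and len(table):
                # frameshift share of LoF: a 1-bp insertion at a coding site
                cds_pos = t.cds_positions
                g = int(cds_pos[int(rng.integers(0, len(cds_pos)))])
                ref = t.contig_seq[g]
                alt = ref + BASES[int(rng.integers(0, 4))]
                fclass = "frameshift"
                pos, refa, alta = g, ref, alt
            else:
                site = _sample_site(rng, table, classes)
                if site is None:
                    continue
                pos, refa, alta, fclass = int(site["pos"]), site["ref"], site["alt"], site["functional_class"]
            gts = {
                fam.proband_id: _het_support(rng, spec),
                fam.father_id: _hom_ref_support(rng, spec, max_ratio=0.035),
                fam.mother_id: _hom_ref_support(rng, spec, max_ratio=0.035),
            }
            mpc = float(rng.uniform(2.0, 4.0)) if metasvm == "D" else float(rng.uniform(0.0, 1.5))
            variants.append(
                _SimVariant(t.contig, pos, refa, alta, gid, fclass,
                            metasvm, mpc, {"gnomad": 0.0, "bravo": 0.0, "exac": 0.0}, True, gts)
            )
            truth.dnv_sites.append(
                {"gene": gid, "family": fam.family_id, "contig": t.contig, "pos": pos,
                 "ref": refa, "alt": alta, "functional_class": fclass, "metasvm": metasvm}
            )

    # --- transmitted process: multinomial within pLI strata --------------
    rng = spec.rng("transmitted")
    strata = assign_strata(gm["pli"])
    mu_dam = damaging_mutability(gm)
    for k in range(1, N_STRATA + 1):
        members = [g for g in genes if strata[g] == k and mu_dam[g] > 0]
        L_k = int(spec.transmitted_L[k - 1])
        if not members or L_k == 0:
            continue
        w = mu_dam.loc[members].to_numpy()
        alloc = rng.multinomial(L_k, w / w.sum())
        for gid, c in zip(members, alloc):
            truth.transmitted_counts[gid] = truth.transmitted_counts.get(gid, 0) + int(c)
            table = universe.site_tables[gid]
            t = universe.transcripts[gid]
            for _ in range(int(c)):
                if rng.random() < 0.5:
                    site = _sample_site(rng, table, ("stopgain", "stoploss", "startloss", "splice_canonical"))
                    metasvm = None
                else:
                    site = _sample_site(rng, table, ("missense",))
                    metasvm = "D"
                if site is None:
                    continue
                fam = trios[int(rng.integers(0, len(trios)))]
                parent = fam.father_id if rng.random() < 0.5 else fam.mother_id
                gts = {
                    fam.proband_id: _het_support(rng, spec, min_alt=1, ratio_rule=False, min_dp=8),
                    parent: _het_support(rng, spec, min_alt=1, ratio_rule=False, min_dp=8),
                }
                other = fam.mother_id if parent == fam.father_id else fam.father_id
                gts[other] = _hom_ref_support(rng, spec)
                mpc = float(rng.uniform(2.0, 4.0)) if metasvm == "D" else None
                variants.append(
                    _SimVariant(t.contig, int(site["pos"]), site["ref"], site["alt"], gid,
                                site["functional_class"], metasvm, mpc,
                                {"gnomad": 1e-6, "bravo": 1e-6, "exac": 1e-6}, True, gts)
                )

    # --- background sites for kinship / duplicates -----------------------
    rng = spec.rng("background")
    n_common, n_rare_per_founder = spec.n_common_background_sites, spec.n_rare_per_founder
    bg_pos = iter(range(100, 99000, 7))
    founders = ped.founder_ids
    for _ in range(n_common):
        pos = next(bg_pos)
        af = float(rng.uniform(0.1, 0.5))
        gts = {}
        fam_alleles: dict[str, dict[str, tuple]] = {}
        for fam in ped.families:
            pa = tuple(int(rng.random() < af) for _ in range(2))
            ma = tuple(int(rng.random() < af) for _ in range(2))
            child = (pa[int(rng.integers(0, 2))], ma[int(rng.integers(0, 2))])
            for sid, gt in ((fam.father_id, pa), (fam.mother_id, ma), (fam.proband_id, child)):
                if sid:
                    gts[sid] = _support_for_gt(rng, spec, gt)
        variants.append(
            _SimVariant("cBG", pos, "A", "G", None, "other", None, None,
                        {"gnomad": af, "bravo": af, "exac": af}, True, gts)
        )
    for founder in founders:
        fam = ped.family_of(founder)
        for _ in range(n_rare_per_founder):
            pos = next(bg_pos)
            gts = {founder: _support_for_gt(rng, spec, (0, 1))}
            if founder in (fam.father_id, fam.mother_id) and rng.random() < 0.5:
                gts[fam.proband_id] = _support_for_gt(rng, spec, (0, 1))
            variants.append(
                _SimVariant("cBG", pos, "C", "T", None, "other", None, None,
                            {"gnomad": 1e-5, "bravo": 1e-5, "exac": 1e-5}, True, gts)
            )

    # --- duplicate samples ------------------------------------------------
    extra = []
    if spec.n_duplicate_pairs:
        rng_d = spec.rng("duplicates")
        chosen = [founders[i] for i in rng_d.choice(len(founders), spec.n_duplicate_pairs, replace=False)]
        for orig in chosen:
            dup = f"DUP_{orig}"
            extra.append(dup)
            for v in variants:
                if orig in v.genotypes:
                    v.genotypes[dup] = v.genotypes[orig]
            truth.duplicate_pairs.append((orig, dup))

    # --- planted filter violations ---------------------------------------
    rng_p = spec.rng("plants")
    plant_pos = iter(range(99001, 99900, 11))
    for rule in spec.planted_dnv_rules:
        fam = trios[int(rng_p.integers(0, len(trios)))]
        v = _plant_dnv_violation(rng_p, spec, fam, rule, next(plant_pos))
        variants.append(v)
        truth.planted_violations.append(
            {"cascade": "dnv", "rule": rule, "family": fam.family_id,
             "contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt}
        )
    for rule in spec.planted_transmitted_rules:
        fam = trios[int(rng_p.integers(0, len(trios)))]
        v, af = _plant_transmitted_violation(rng_p, spec, fam, rule, next(plant_pos))
        variants.append(v)
        truth.planted_violations.append(
            {"cascade": "transmitted", "rule": rule, "family": fam.family_id,
             "contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
             "in_cohort_af": af}
        )

    return SimulatedCohort(spec=spec, universe=universe, pedigree=ped,
                           extra_samples=extra, variants=variants, truth=truth)


def _support_for_gt(rng, spec, gt):
    if sum(gt) == 0:
        return _hom_ref_support(rng, spec)
    if sum(gt) == 1:
        return _het_support(rng, spec, min_alt=1, ratio_rule=False, min_dp=8)
    dp = int(max(10, rng.poisson(spec.depth_mean)))
    ad_ref = int(rng.binomial(dp, spec.error_allele_rate))
    return ((1, 1), dp, ad_ref, dp - ad_ref, spec.default_gq)


def _plant_dnv_violation(rng, spec, fam, rule, pos) -> _SimVariant:
    """A trio record that passes the whole DNV cascade except ``rule``."""
    proband = _het_support(rng, spec)
    father = _hom_ref_support(rng, spec, max_ratio=0.035)
    mother = _hom_ref_support(rng, spec, max_ratio=0.035)
    fclass, maf = "missense", 0.0
    if rule == "exonic_class":
        fclass = "other"
    elif rule == "trio_depth":
        father = ((0, 0), 6, 6, 0, spec.default_gq)
    elif rule == "proband_alt_reads":
        proband = ((0, 1), 10, 7, 3, spec.default_gq)  # ratio 0.30 ok, reads below 5
    elif rule == "proband_alt_ratio":
        proband = ((0, 1), 30, 24, 6, spec.default_gq)  # 6 reads, ratio 0.20 < 0.28
    elif rule == "parent_alt_ratio":
        mother = ((0, 0), 50, 47, 3, spec.default_gq)   # ratio 0.06
    elif rule == "population_maf":
        maf = 1e-3
    elif rule == "missing_support":
        father = ((0, 0), None, None, None, spec.default_gq)
    else:
        raise ValueError(f"unknown plantable DNV rule {rule!r}")
    gts = {fam.proband_id: proband, fam.father_id: father, fam.mother_id: mother}
    return _SimVariant("cBG", pos, "G", "A", "G0000", fclass, "T", 0.5,
                       {"gnomad": maf, "bravo": maf, "exac": maf}, True, gts)


def _plant_transmitted_violation(rng, spec, fam, rule, pos):
    """A transmitted-candidate record failing exactly ``rule``.

    Returns the record and the in-cohort allele frequency under which it
    should be evaluated (the cascade takes that frequency as an input).
    """
    proband = _het_support(rng, spec, min_alt=1, ratio_rule=False, min_dp=8)
    parent = _het_support(rng, spec, min_alt=1, ratio_rule=False, min_dp=8)
    gts = {fam.proband_id: proband, fam.father_id: parent,
           fam.mother_id: _hom_ref_support(rng, spec)}
    fclass, metasvm, mpc = "stopgain", None, None
    maf, vqsr, cohort_af = 1e-6, True, 1e-4
    if rule == "vqsr":
        vqsr = False
    elif rule == "population_maf":
        maf = 1e-3
    elif rule == "cohort_maf":
        cohort_af = 1e-2
    elif rule == "proband_depth":
        gts[fam.proband_id] = ((0, 1), 5, 3, 2, spec.default_gq)
    elif rule == "gq":
        p = list(proband)
        gts[fam.proband_id] = (p[0], p[1], p[2], p[3], 10)
    elif rule == "damaging_class":
        fclass, metasvm, mpc = "missense", "T", 0.5
    else:
        raise ValueError(f"unknown plantable transmitted rule {rule!r}")
    v = _SimVariant("cBG", pos, "T", "C", "G0001", fclass, metasvm, mpc,
                    {"gnomad": maf, "bravo": maf, "exac": maf}, vqsr, gts)
    return v, cohort_af


def emit_fixture_suite(out_dir, seed: int = 20240907) -> dict[str, Path]:
    """Tiny deterministic fixture cohort (3 trios, 20 genes) with one planted
    violation per filter rule and one duplicate pair."""
    spec = SyntheticCohortSpec(
        seed=seed,
        n_genes=20,
        n_trios=3,
        n_duos=1,
        n_singletons=1,
        target_total_expected_dnvs=6.0,
        transmitted_L=(2, 2, 2, 2, 1),
        planted_dnv_rules=tuple(r for r in PLANTABLE_DNV_RULES),
        planted_transmitted_rules=tuple(r for r in PLANTABLE_TRANSMITTED_RULES),
        n_duplicate_pairs=1,
    )
    uni = simulate_gene_universe(spec)
    cohort = simulate_cohort(spec, uni)
    return cohort.write(out_dir)
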