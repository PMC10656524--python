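"""End-to-end orchestration of the analysis stages.

Stages run in dependency order: cohort I/O, kinship/duplicate QC, the
filter cascades, mutability-based DNV enrichment, transmitted binomial
enrichment, and (when gene-set inputs are supplied) gene-set logistic
enrichment. A manifest records per-stage record counts, output checksums
and the seed, so a re-run with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Pedigree, read_pedigree, read_variants, union_capture
from .config import RunConfig
from .dnv import DnvEnrichmentModel
from .filters import (
    dnv_filter,
    duplicate_and_kinship,
    in_cohort_af,
    naive_denovo_prescreen,
    transmitted_filter,
)
from .synth import damaging_mutability
from .transmitted import TransmittedEnrichmentModel

log = logging.getLogger("trioburden")


def load_cohort(cohort_dir) -> tuple[Pedigree, list]:
    d = Path(cohort_dir)
    ped = read_pedigree(d / "cohort.ped")
    calls = read_variants(d / "cohort.vcf", ped)
    return ped, calls


def genotype_frame(calls, sample_ids) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Samples x sites genotype matrix, rare-site mask and mean depth,
    assembled from per-family call records (kinship QC inputs)."""
    sites: dict[tuple, dict] = {}
    rare: dict[tuple, bool] = {}
    depth: dict[str, list] = {s: [] for s in sample_ids}
    for c in calls:
        key = c.site_key
        sites.setdefault(key, {})
        af = c.maf("gnomad")
        rare[key] = af is None or af <= 1e-3
        for sid, sc in c.samples.items():
            if sid in depth:
                n = sc.n_alt_alleles
                sites[key][sid] = np.nan if n is None else n
                if sc.effective_dp is not None:
                    depth[sid].append(sc.effective_dp)
    keys = sorted(sites)
    mat = pd.DataFrame(
        {f"{k[0]}:{k[1]}:{k[2]}:{k[3]}": [sites[k].get(s, 0.0) for s in sample_ids] for k in keys},
        index=sample_ids,
    )
    rare_mask = np.array([rare[k] for k in keys])
    mean_depth = pd.Series({s: (np.mean(v) if v else 0.0) for s, v in depth.items()})
    return mat, rare_mask, mean_depth


def vcf_genotype_matrix(vcf_path, rare_af: float = 1e-3) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """All-samples genotype matrix straight from a VCF (kinship QC input).

    Unlike :func:`genotype_frame` this includes samples absent from the
    pedigree (e.g. planted duplicates). Returns (matrix, rare-site mask,
    mean depth); rarity is judged on the gnomAD-like AF annotation.
    """
    import pysam

    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    cols: dict[str, list] = {}
    rare: list[bool] = []
    depth_sum = {s: 0.0 for s in samples}
    depth_n = {s: 0 for s in samples}
    for rec in vcf:
        if not rec.alts or len(rec.alts) != 1:
            continue
        key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
        if key in cols:
            continue
        af = rec.info.get("AF_GNOMAD")
        rare.append(af is None or float(af) <= rare_af)
        col = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            col.append(np.nan if gt is None or any(a is None for a in gt) else float(sum(gt)))
            dp = rec.samples[s].get("DP")
            if dp is not None:
                depth_sum[s] += dp
                depth_n[s] += 1
        cols[key] = col
    mat = pd.DataFrame(cols, index=samples)
    mean_depth = pd.Series({s: depth_sum[s] / depth_n[s] if depth_n[s] else 0.0 for s in samples})
    return mat, np.asarray(rare), mean_depth


def run_dnv_stage(calls, ped: Pedigree, config: RunConfig) -> pd.DataFrame:
    """Mendelian pre-screen plus the DNV cascade; returns passing DNVs."""
    rows = []
    n_candidates = 0
    for fam in ped.trios:
        fam_calls = [c for c in calls if c.family_id == fam.family_id]
        for c in fam_calls:
            if not naive_denovo_prescreen(c, fam):
                continue
            n_candidates += 1
            v = dnv_filter(c, fam, config.dnv_filter)
            rows.append(
                {
                    "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                    "family": fam.family_id, "gene": c.gene_id,
                    "functional_class": c.functional_class, "metasvm": c.metasvm, "mpc": c.mpc,
                    "passed": v.passed, "failed_rule": v.failed_rule,
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "family", "gene",
                                     "functional_class", "metasvm", "mpc", "passed", "failed_rule"])
    log.info("dnv stage: %d candidates in, %d pass", n_candidates, int(df["passed"].sum()) if len(df) else 0)
    return df


def run_transmitted_stage(calls, ped: Pedigree, config: RunConfig, exclude: set | None = None) -> pd.DataFrame:
    """Transmitted cascade over proband-het calls with a carrier parent."""
    afs = in_cohort_af(calls, ped, exclude=exclude)
    rows = []
    for fam in ped.families:
        for c in calls:
            if c.family_id != fam.family_id:
                continue
            p = c.samples[fam.proband_id]
            if not p.is_het:
                continue
            carrier = None
            for par in (fam.father_id, fam.mother_id):
                if par and (c.samples[par].n_alt_alleles or 0) > 0:
                    carrier = par
            if carrier is None:
                continue
            v = transmitted_filter(c, fam, afs.get(c.site_key, 0.0), config.transmitted_filter)
            rows.append(
                {
                    "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                    "family": fam.family_id, "gene": c.gene_id,
                    "functional_class": c.functional_class,
                    "passed": v.passed, "failed_rule": v.failed_rule,
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "family", "gene",
                                     "functional_class", "passed", "failed_rule"])
    log.info("transmitted stage: %d candidates in, %d pass", len(df), int(df["passed"].sum()) if len(df) else 0)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on the inputs named in the configuration.

    Requires ``inputs.cohort_dir`` (the layout the simulator writes).
    Returns the manifest, which is also written to the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo_into(out)
    manifest: dict = {"seed": config.seed, "stages": {}}

    cohort_dir = config.inputs.get("cohort_dir")
    if not cohort_dir:
        raise ValueError("config.inputs must name cohort_dir")

    def _stage(name, fn):
        try:
            result = fn()
        except Exception as e:  # halt with stage context
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
        manifest["stages"][name] = {"status": "ok", **(result or {})}

    state: dict = {}

    def _io():
        ped, calls = load_cohort(cohort_dir)
        state["ped"], state["calls"] = ped, calls
        gm = pd.read_csv(Path(cohort_dir) / "genes.tsv", sep="\t").set_index("gene")
        state["gene_models"] = gm
        capture = union_capture([Path(cohort_dir) / "capture.bed"])
        return {"n_families": len(ped.families), "n_records": len(calls), "n_genes": len(gm),
                "capture_bases": capture.total_bases}

    def _qc():
        ped = state["ped"]
        mat, rare_mask, mean_depth = vcf_genotype_matrix(Path(cohort_dir) / "cohort.vcf")
        rep = duplicate_and_kinship(mat, rare_mask, mean_depth, ped,
                                    duplicate_threshold=config.thresholds.duplicate_sharing_threshold,
                                    po_band=config.thresholds.ibd_band)
        state["kinship"] = rep
        rep.sharing.to_csv(out / "kinship_sharing.tsv", sep="\t")
        rep.ibd_proxy.to_csv(out / "kinship_ibd.tsv", sep="\t")
        return {"n_duplicates": len(rep.duplicates), "n_po_flags": len(rep.parent_offspring_flags)}

    def _filters():
        dnv = run_dnv_stage(state["calls"], state["ped"], config)
        trans = run_transmitted_stage(state["calls"], state["ped"], config)
        dnv.to_csv(out / "dnv_filtered.tsv", sep="\t", index=False)
        trans.to_csv(out / "transmitted_filtered.tsv", sep="\t", index=False)
        state["dnv"], state["trans"] = dnv, trans
        return {"dnv_in": len(dnv), "dnv_pass": int(dnv["passed"].sum()) if len(dnv) else 0,
                "trans_in": len(trans), "trans_pass": int(trans["passed"].sum()) if len(trans) else 0}

    def _enrich_dnv():
        gm = state["gene_models"]
        passing = state["dnv"][state["dnv"]["passed"]]
        model = DnvEnrichmentModel(passing.rename(columns={"gene": "gene"}), gm,
                                   n_trios=len(state["ped"].trios),
                                   alpha=config.thresholds.alpha,
                                   pli_cutoff=config.thresholds.pli_constrained_cutoff)
        res = model.fit()
        state["dnv_results"] = res
        res.class_table("all").to_csv(out / "dnv_class_table.tsv", sep="\t")
        res.per_gene.to_csv(out / "dnv_per_gene.tsv", sep="\t", index=False)
        return {"attributable_fraction": res.attributable_fraction_,
                "n_significant": int(res.per_gene["significant"].sum())}

    def _enrich_transmitted():
        gm = state["gene_models"]
        passing = state["trans"][state["trans"]["passed"]]
        observed = passing.groupby("gene").size() if len(passing) else pd.Series(dtype=int)
        table = pd.DataFrame({"mutability": damaging_mutability(gm), "pli": gm["pli"]})
        res = TransmittedEnrichmentModel(observed, table, alpha=config.thresholds.alpha).fit()
        state["trans_results"] = res
        res.per_gene.to_csv(out / "transmitted_per_gene.tsv", sep="\t")
        return {"n_significant": int(res.per_gene["significant"].sum())}

    _stage("io", _io)
    _stage("kinship_qc", _qc)
    _stage("filters", _filters)
    _stage("dnv_enrichment", _enrich_dnv)
    _stage("transmitted_enrichment", _enrich_transmitted)

    manifest["checksums"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.tsv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
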