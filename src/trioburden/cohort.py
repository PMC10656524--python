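"""Cohort I/O: pedigree, variant calls, and capture regions.

Coordinates: VCF is 1-based inclusive on disk, BED 0-based half-open; all
internal arithmetic is 0-based half-open with conversion at the I/O
boundary. Variant records are held per (variant, family), with multi-allelic
sites decomposed into biallelic records and missing FORMAT values kept as
missing (never coerced to zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam


@dataclass(frozen=True)
class Family:
    family_id: str
    proband_id: str
    father_id: str | None
    mother_id: str | None
    proband_sex: int
    affected: bool

    @property
    def kind(self) -> str:
        n = (self.father_id is not None) + (self.mother_id is not None)
        return {2: "trio", 1: "duo", 0: "singleton"}[n]

    @property
    def members(self) -> list[str]:
        out = [self.proband_id]
        if self.father_id:
            out.append(self.father_id)
        if self.mother_id:
            out.append(self.mother_id)
        return out


@dataclass
class Pedigree:
    families: list[Family]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for fam in self.families:
            for sid in fam.members:
                if sid in seen and seen[sid] != fam.family_id:
                    raise ValueError(f"sample {sid} belongs to two families ({seen[sid]}, {fam.family_id})")
                seen[sid] = fam.family_id
        probands = [f.proband_id for f in self.families]
        if len(set(probands)) != len(probands):
            raise ValueError("a proband appears in more than one family")

    @property
    def trios(self) -> list[Family]:
        return [f for f in self.families if f.kind == "trio"]

    @property
    def duos(self) -> list[Family]:
        return [f for f in self.families if f.kind == "duo"]

    @property
    def singletons(self) -> list[Family]:
        return [f for f in self.families if f.kind == "singleton"]

    @property
    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for f in self.families:
            out.extend(f.members)
        return out

    @property
    def founder_ids(self) -> list[str]:
        """Parents plus parentless probands; the in-cohort MAF denominator."""
        out: list[str] = []
        for f in self.families:
            out.extend([s for s in (f.father_id, f.mother_id) if s])
            if f.kind == "singleton":
                out.append(f.proband_id)
        return out

    def family_of(self, sample_id: str) -> Family:
        for f in self.families:
            if sample_id in f.members:
                return f
        raise KeyError(sample_id)


def read_pedigree(path) -> Pedigree:
    """Parse a 6-column PED file and resolve trio/duo/singleton roles.

    Offspring are rows with at least one declared parent, or affected rows;
    a parent id that references no genotyped row demotes the family to
    duo/singleton with a warning. Duplicated sample ids are a hard error.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family_id", "sample_id", "father_id", "mother_id", "sex", "phenotype"],
        dtype=str,
        comment="#",
    )
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicated sample id(s) in PED: {dups}")
    present = set(df["sample_id"])
    families: list[Family] = []
    for _, row in df.iterrows():
        father = None if row.father_id in ("0", "", None) else row.father_id
        mother = None if row.mother_id in ("0", "", None) else row.mother_id
        affected = str(row.phenotype) == "2"
        if father is None and mother is None and not affected:
            continue  # founder row: becomes a parent of some proband
        for pid, label in ((father, "father"), (mother, "mother")):
            if pid is not None and pid not in present:
                warnings.warn(
                    f"family {row.family_id}: {label} {pid} not in PED; treating as absent",
                    stacklevel=2,
                )
                if label == "father":
                    father = None
                else:
                    mother = None
        families.append(
            Family(
                family_id=str(row.family_id),
                proband_id=str(row.sample_id),
                father_id=father,
                mother_id=mother,
                proband_sex=int(row.sex) if str(row.sex) in "12" else 0,
                affected=affected,
            )
        )
    return Pedigree(families)


@dataclass
class SampleCall:
    """Genotype and read support of one sample at one biallelic site."""

    gt: tuple[int | None, int | None]
    dp: int | None
    ad_ref: int | None
    ad_alt: int | None
    gq: int | None

    @property
    def effective_dp(self) -> int | None:
        """DP, falling back to the AD sum when DP is missing."""
        if self.dp is not None:
            return self.dp
        if self.ad_ref is not None and self.ad_alt is not None:
            return self.ad_ref + self.ad_alt
        return None

    @property
    def alt_ratio(self) -> float | None:
        dp = self.effective_dp
        if dp is None or dp == 0 or self.ad_alt is None:
            return None
        return self.ad_alt / dp

    @property
    def n_alt_alleles(self) -> int | None:
        if any(a is None for a in self.gt):
            return None
        return sum(1 for a in self.gt if a == 1)

    @property
    def is_het(self) -> bool:
        return self.n_alt_alleles == 1

    @property
    def is_hom_alt(self) -> bool:
        return self.n_alt_alleles == 2

    @property
    def is_hom_ref(self) -> bool:
        return self.n_alt_alleles == 0


@dataclass
class TrioVariantCall:
    """One decomposed biallelic variant in one family."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    family_id: str
    samples: dict[str, SampleCall]
    gene_id: str | None = None
    functional_class: str | None = None
    metasvm: str | None = None  # "D", "T" or None
    mpc: float | None = None
    maf_popmax_sources: dict[str, float] = field(default_factory=dict)
    vqsr_pass: bool = True

    def __post_init__(self):
        for sid, s in self.samples.items():
            if s.ad_alt is not None and s.dp is not None and s.ad_alt > s.dp:
                raise ValueError(f"{self.site_key}: AD_alt > DP for sample {sid}")
        for src, f in self.maf_popmax_sources.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.site_key}: frequency {f} for {src} outside [0,1]")

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def maf(self, source: str) -> float | None:
        return self.maf_popmax_sources.get(source)


def trim_allele_pair(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Normalize an allele pair by trimming the shared suffix then prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


_DEFAULT_INFO_KEYS = {
    "gene_id": "GENE",
    "functional_class": "FCLASS",
    "metasvm": "METASVM",
    "mpc": "MPC",
}


def read_variants(
    path,
    pedigree: Pedigree,
    info_keys: dict[str, str] | None = None,
    maf_info_keys: dict[str, str] | None = None,
    annotations: pd.DataFrame | None = None,
) -> list[TrioVariantCall]:
    """Read a VCF into per-(variant, family) biallelic records.

    Annotation fields come from configurable INFO keys (defaults: GENE,
    FCLASS, METASVM, MPC, plus ``maf_info_keys`` mapping source name ->
    INFO key) or from a side-car ``annotations`` table indexed by
    (chrom, pos, ref, alt) with matching columns — the side-car wins.
    Multi-allelic rows are decomposed; FORMAT values absent for a sample
    stay missing.
    """
    keys = {**_DEFAULT_INFO_KEYS, **(info_keys or {})}
    maf_keys = maf_info_keys or {"gnomad": "AF_GNOMAD", "bravo": "AF_BRAVO", "exac": "AF_EXAC"}
    ann = None
    if annotations is not None:
        ann = annotations.set_index(["chrom", "pos", "ref", "alt"]) if not isinstance(annotations.index, pd.MultiIndex) else annotations

    vcf = pysam.VariantFile(str(path))
    vcf_samples = set(vcf.header.samples)
    missing = [s for s in pedigree.sample_ids if s not in vcf_samples]
    if missing:
        raise ValueError(f"pedigree samples absent from VCF: {sorted(missing)}")

    calls: list[TrioVariantCall] = []
    for rec in vcf.fetch() if vcf.index is not None else vcf:
        alts = rec.alts or ()
        for alt_i, alt in enumerate(alts):
            pos0, ref, alt_a = trim_allele_pair(rec.pos - 1, rec.ref, alt)
            info = dict(rec.info)
            mafs = {}
            for src, k in maf_keys.items():
                v = info.get(k)
                if v is not None:
                    v = v[alt_i] if isinstance(v, tuple) else v
                    mafs[src] = float(v)

            def _info_scalar(k):
                v = info.get(k)
                if isinstance(v, tuple):
                    v = v[alt_i] if alt_i < len(v) else v[0]
                return v

            gene = _info_scalar(keys["gene_id"])
            fclass = _info_scalar(keys["functional_class"])
            metasvm = _info_scalar(keys["metasvm"])
            mpc = _info_scalar(keys["mpc"])
            if ann is not None:
                key = (rec.chrom, pos0, ref, alt_a)
                if key in ann.index:
                    arow = ann.loc[key]
                    gene = arow.get("gene_id", gene)
                    fclass = arow.get("functional_class", fclass)
                    metasvm = arow.get("metasvm", metasvm)
                    mpc = arow.get("mpc", mpc)
                    for col in arow.index:
                        if col.startswith("maf_"):
                            val = arow[col]
                            if pd.notna(val):
                                mafs[col[4:]] = float(val)
            vqsr = not list(rec.filter.keys()) or list(rec.filter.keys()) == ["PASS"]

            for fam in pedigree.families:
                samples = {}
                for sid in fam.members:
                    fs = rec.samples[sid]
                    gt_raw = fs.get("GT")
                    allele_code = lambda a: None if a is None else (1 if a == alt_i + 1 else 0)
                    gt = (None, None) if gt_raw is None else tuple(allele_code(a) for a in gt_raw)
                    if len(gt) == 1:
                        gt = (gt[0], gt[0])
                    ad = fs.get("AD")
                    ad_ref = ad_alt = None
                    if ad is not None and ad[0] is not None:
                        ad_ref = int(ad[0])
                        if len(ad) > alt_i + 1 and ad[alt_i + 1] is not None:
                            ad_alt = int(ad[alt_i + 1])
                    dp = fs.get("DP")
                    gq = fs.get("GQ")
                    samples[sid] = SampleCall(
                        gt=gt,
                        dp=None if dp is None else int(dp),
                        ad_ref=ad_ref,
                        ad_alt=ad_alt,
                        gq=None if gq is None else int(gq),
                    )
                calls.append(
                    TrioVariantCall(
                        chrom=rec.chrom,
                        pos=pos0,
                        ref=ref,
                        alt=alt_a,
                        family_id=fam.family_id,
                        samples=samples,
                        gene_id=None if gene is None else str(gene),
                        functional_class=None if fclass is None else str(fclass),
                        metasvm=None if metasvm in (None, ".", "missing") else str(metasvm),
                        mpc=None if mpc is None or (isinstance(mpc, float) and np.isnan(mpc)) else float(mpc),
                        maf_popmax_sources=mafs,
                        vqsr_pass=bool(vqsr),
                    )
                )
    return calls


class CaptureRegions:
    """Union of capture intervals per contig, 0-based half-open, merged."""

    def __init__(self, intervals: dict[str, np.ndarray]):
        self.intervals: dict[str, np.ndarray] = {}
        for contig, arr in intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if np.any(arr[:, 1] <= arr[:, 0]):
                bad = arr[arr[:, 1] <= arr[:, 0]][0]
                raise ValueError(f"malformed interval [{bad[0]}, {bad[1]}) on {contig}")
            self.intervals[contig] = _merge(arr)

    @property
    def total_bases(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.intervals.values()))

    def covers(self, contig: str, positions) -> np.ndarray:
        """Boolean mask of which 0-based positions fall inside the capture."""
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        arr = self.intervals.get(contig)
        if arr is None or arr.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        k = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = k >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[ok] = positions[ok] < arr[k[ok], 1]
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, CaptureRegions):
            return NotImplemented
        if set(self.intervals) != set(other.intervals):
            return False
        return all(np.array_equal(self.intervals[c], other.intervals[c]) for c in self.intervals)


def _merge(arr: np.ndarray) -> np.ndarray:
    if arr.size == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def union_capture(beds: Sequence) -> CaptureRegions:
    """Union of one or more BED3 files into merged capture regions."""
    if not beds:
        raise ValueError("at least one BED file is required")
    per_contig: dict[str, list[list[int]]] = {}
    for bed in beds:
        with open(bed) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{bed}:{lineno}: fewer than 3 BED columns")
                contig, start, end = parts[0], int(parts[1]), int(parts[2])
                if end <= start:
                    raise ValueError(f"{bed}:{lineno}: malformed interval [{start}, {end})")
                per_contig.setdefault(contig, []).append([start, end])
    return CaptureRegions({c: np.asarray(v) for c, v in per_contig.items()})


def write_cohort_summary(pedigree: Pedigree, calls: Iterable[TrioVariantCall], path) -> pd.DataFrame:
    """Write a per-family variant-count summary TSV and return it."""
    rows = []
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.family_id] = counts.get(c.family_id, 0) + 1
    for fam in pedigree.families:
        rows.append(
            {
                "family_id": fam.family_id,
                "kind": fam.kind,
                "proband_id": fam.proband_id,
                "n_variant_records": counts.get(fam.family_id, 0),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
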