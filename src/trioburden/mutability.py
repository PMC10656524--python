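"""Trinucleotide-context de novo mutability model.

Every coding base is assigned, for each possible single-nucleotide change,
a per-generation haploid mutation probability looked up from a 192-entry
(64 contexts x 3 alternate bases) substitution-rate table. The coding
consequence of each possible substitution is determined from the genetic
code and summed per functional class to give gene-specific mutation
probabilities. Frameshift indels are not modelled from sequence; their
probability is the stop-gain probability scaled by a fixed factor of 1.25.
In-frame indels are not modelled at all.

Classes modelled: synonymous, missense, splice_canonical (the +/-2 intronic
bases of each internal exon junction), stopgain, stoploss, startloss, and
the derived frameshift class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G

#: functional classes carried by the model, in canonical order
MUTATION_CLASSES = (
    "synonymous",
    "missense",
    "splice_canonical",
    "stopgain",
    "stoploss",
    "startloss",
    "frameshift",
)

#: loss-of-function class union used throughout the enrichment analyses
LOF_CLASSES = frozenset({"stopgain", "stoploss", "frameshift", "splice_canonical", "startloss"})

#: frameshift probability = FRAMESHIFT_FACTOR x stop-gain probability
FRAMESHIFT_FACTOR = 1.25

# amino-acid code table indexed by codon integer (c0*16 + c1*4 + c2); 20 == stop
_AA_CODE = np.empty(64, dtype=np.int8)
_AA_LETTERS = sorted(set(standard_dna_table.forward_table.values()))
for _codon_idx in range(64):
    _codon = BASES[_codon_idx >> 4] + BASES[(_codon_idx >> 2) & 3] + BASES[_codon_idx & 3]
    if _codon in standard_dna_table.stop_codons:
        _AA_CODE[_codon_idx] = 20
    else:
        _AA_CODE[_codon_idx] = _AA_LETTERS.index(standard_dna_table.forward_table[_codon])
_STOP = 20


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string to int8 codes; non-ACGT characters become -1."""
    lut = np.full(128, -1, dtype=np.int8)
    for b, i in _BASE_CODE.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return lut[arr]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class ContextRateTable:
    """Per-base, per-generation substitution rates keyed by (trinucleotide, alt).

    Stored internally as a (64, 4) matrix ``R[context_index, alt_code]`` with
    zeros on the ref==alt diagonal; ``context_index = 16*left + 4*center + right``.
    """

    def __init__(self, rates: Mapping[tuple[str, str], float]):
        matrix = np.zeros((64, 4), dtype=float)
        seen = set()
        for (ctx, alt), rate in rates.items():
            ctx = ctx.upper()
            alt = alt.upper()
            if len(ctx) != 3 or any(b not in _BASE_CODE for b in ctx) or alt not in _BASE_CODE:
                raise ValueError(f"malformed context entry ({ctx!r}, {alt!r})")
            if alt == ctx[1]:
                raise ValueError(f"alt equals reference base in context {ctx!r}")
            if rate <= 0:
                raise ValueError(f"rate for ({ctx}, {alt}) must be > 0, got {rate}")
            idx = (_BASE_CODE[ctx[0]] << 4) | (_BASE_CODE[ctx[1]] << 2) | _BASE_CODE[ctx[2]]
            matrix[idx, _BASE_CODE[alt]] = rate
            seen.add((ctx, alt))
        if len(seen) != 192:
            raise ValueError(f"context table must carry all 192 (context, alt) rates; got {len(seen)}")
        self.matrix = matrix

    @classmethod
    def uniform(cls, rate: float) -> "ContextRateTable":
        entries = {}
        for c0 in BASES:
            for c1 in BASES:
                for c2 in BASES:
                    for alt in BASES:
                        if alt != c1:
                            entries[(c0 + c1 + c2, alt)] = rate
        return cls(entries)

    @classmethod
    def from_tsv(cls, path) -> "ContextRateTable":
        df = pd.read_csv(path, sep="\t", dtype={"context": str, "alt": str})
        return cls({(r.context, r.alt): r.rate for r in df.itertuples()})

    def to_tsv(self, path) -> None:
        rows = []
        for idx in range(64):
            ctx = BASES[idx >> 4] + BASES[(idx >> 2) & 3] + BASES[idx & 3]
            for alt in BASES:
                if alt != ctx[1]:
                    rows.append((ctx, alt, self.matrix[idx, _BASE_CODE[alt]]))
        pd.DataFrame(rows, columns=["context", "alt", "rate"]).to_csv(path, sep="\t", index=False)

    def rate(self, context: str, alt: str) -> float:
        context = context.upper()
        idx = (_BASE_CODE[context[0]] << 4) | (_BASE_CODE[context[1]] << 2) | _BASE_CODE[context[2]]
        return float(self.matrix[idx, _BASE_CODE[alt.upper()]])

    def scaled(self, factor: float) -> "ContextRateTable":
        out = ContextRateTable.__new__(ContextRateTable)
        out.matrix = self.matrix * factor
        return out

    def reverse_complemented(self) -> "ContextRateTable":
        """Table with every (context, alt) mapped to its reverse complement."""
        out = np.zeros_like(self.matrix)
        for idx in range(64):
            l, c, r = idx >> 4, (idx >> 2) & 3, idx & 3
            rc_idx = (int(_COMPLEMENT_CODE[r]) << 4) | (int(_COMPLEMENT_CODE[c]) << 2) | int(_COMPLEMENT_CODE[l])
            for alt in range(4):
                if alt != c:
                    out[rc_idx, _COMPLEMENT_CODE[alt]] = self.matrix[idx, alt]
        res = ContextRateTable.__new__(ContextRateTable)
        res.matrix = out
        return res

    def is_strand_symmetric(self, rtol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, self.reverse_complemented().matrix, rtol=rtol))

    def symmetrized(self) -> "ContextRateTable":
        """Average each entry with its reverse-complement partner."""
        res = ContextRateTable.__new__(ContextRateTable)
        res.matrix = 0.5 * (self.matrix + self.reverse_complemented().matrix)
        return res

    @property
    def total(self) -> float:
        return float(self.matrix.sum())


@dataclass
class Transcript:
    """A coding transcript: strand-aware CDS intervals on a contig.

    ``exons`` are genomic 0-based half-open CDS intervals in genomic order.
    The spliced CDS (transcript strand) must start with ATG and end with a
    stop codon for classification to label start/stop disruption sensibly,
    but this is not enforced.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    contig_seq: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon [{s},{e}) in {self.gene_id}")
        self.exons = sorted(self.exons)

    @property
    def cds_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in transcript (5'->3') order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.exons])
        return pos[::-1] if self.strand == "-" else pos

    @property
    def cds_seq(self) -> str:
        s = "".join(self.contig_seq[a:b] for a, b in self.exons)
        return revcomp(s) if self.strand == "-" else s

    def splice_positions(self) -> np.ndarray:
        """Genomic positions of canonical splice bases (+/-2 bp intronic)."""
        sites: list[int] = []
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 - e1 >= 4:  # needs a real intron
                sites.extend((e1, e1 + 1, s2 - 2, s2 - 1))
        return np.asarray(sorted(sites), dtype=np.int64)


def classify_substitution(transcript: Transcript, site: int, alt: str) -> str:
    """Functional class of a single-nucleotide change at a genomic position.

    ``site`` is 0-based genomic; ``alt`` is the alternate base on the genomic
    (+) strand. Canonical splice positions classify as ``splice_canonical``
    irrespective of the alt; otherwise the codon containing the site is
    mutated and translated.
    """
    if alt.upper() not in _BASE_CODE:
        raise ValueError(f"invalid alt base {alt!r}")
    if site in set(transcript.splice_positions().tolist()):
        return "splice_canonical"
    cds_pos = transcript.cds_positions
    hits = np.nonzero(cds_pos == site)[0]
    if hits.size == 0:
        raise ValueError(f"position {site} is outside the modeled transcript {transcript.gene_id}")
    i = int(hits[0])
    alt_code = _BASE_CODE[alt.upper()]
    if transcript.strand == "-":
        alt_code = int(_COMPLEMENT_CODE[alt_code])
    cds = encode_seq(transcript.cds_seq)
    if alt_code == cds[i]:
        raise ValueError("alt equals the reference base")
    return _classify_cds_change(cds, i, alt_code)


def _classify_cds_change(cds: np.ndarray, i: int, alt_code: int) -> str:
    codon_i = i // 3
    off = i % 3
    c = cds[3 * codon_i: 3 * codon_i + 3]
    ref_codon = (int(c[0]) << 4) | (int(c[1]) << 2) | int(c[2])
    new_codon = ref_codon + (alt_code - int(c[off])) * (4 ** (2 - off))
    if codon_i == 0:
        return "startloss"
    ref_aa, new_aa = int(_AA_CODE[ref_codon]), int(_AA_CODE[new_codon])
    if ref_aa == _STOP:
        return "synonymous" if new_aa == _STOP else "stoploss"
    if new_aa == _STOP:
        return "stopgain"
    return "synonymous" if new_aa == ref_aa else "missense"


def per_base_probabilities(seq: str, rates: ContextRateTable) -> tuple[np.ndarray, int]:
    """Per-site, per-alt substitution probabilities for the interior of ``seq``.

    Returns an array of shape ``(len(seq) - 2, 3)`` — one row per interior
    position, columns ordered by the three non-reference bases in alphabetical
    order — and the count of sites skipped because of non-ACGT characters
    (skipped rows are zero).
    """
    if len(seq) < 3:
        raise ValueError("sequence must have length >= 3 to carry a trinucleotide context")
    codes = encode_seq(seq)
    n = len(seq) - 2
    out = np.zeros((n, 3), dtype=float)
    skipped = 0
    for k in range(n):
        l, c, r = codes[k], codes[k + 1], codes[k + 2]
        if l < 0 or c < 0 or r < 0:
            skipped += 1
            continue
        idx = (int(l) << 4) | (int(c) << 2) | int(r)
        row = [self_rate for alt, self_rate in enumerate(rates.matrix[idx]) if alt != c]
        out[k] = row
    if skipped:
        warnings.warn(f"{skipped} site(s) skipped (non-ACGT context)", stacklevel=2)
    return out, skipped


@dataclass
class DepthAdjustment:
    """Per-gene sequencing-depth multiplier in [0, 1]; defaults to 1."""

    multipliers: dict[str, float] = field(default_factory=dict)

    def get(self, gene_id: str) -> float:
        return self.multipliers.get(gene_id, 1.0)

    @classmethod
    def from_tsv(cls, path) -> "DepthAdjustment":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))))

    @classmethod
    def from_site_coverage(
        cls, coverage: pd.DataFrame, min_reads: int = 8, min_sample_frac: float = 0.9
    ) -> "DepthAdjustment":
        """Multiplier = fraction of a gene's bases adequately covered.

        ``coverage`` has one row per (gene, base) with a column
        ``frac_samples_ge_{min_reads}`` giving the fraction of samples with at
        least ``min_reads`` independent reads at that base. A base counts as
        covered when that fraction is >= ``min_sample_frac``.
        """
        col = f"frac_samples_ge_{min_reads}"
        if col not in coverage.columns:
            raise ValueError(f"coverage table lacks column {col!r}")
        ok = coverage[col] >= min_sample_frac
        frac = ok.groupby(coverage["gene"]).mean()
        return cls(frac.to_dict())


@dataclass
class GeneModel:
    """Per-gene mutability by functional class plus annotation covariates."""

    gene_id: str
    p_class: dict[str, float]
    pli: float | None = None
    dmis_fraction: float = 0.30
    gc_content: float | None = None
    coding_length: int | None = None
    mean_expression: float | None = None
    n_skipped_sites: int = 0

    def __post_init__(self):
        for c, v in self.p_class.items():
            if v < 0:
                raise ValueError(f"negative class probability {c}={v} for {self.gene_id}")

    @property
    def p_lof(self) -> float:
        return sum(self.p_class.get(c, 0.0) for c in LOF_CLASSES)

    @property
    def p_missense(self) -> float:
        return self.p_class.get("missense", 0.0)

    @property
    def p_dmis(self) -> float:
        return self.dmis_fraction * self.p_missense

    @property
    def p_damaging(self) -> float:
        return self.p_lof + self.p_dmis

    @property
    def p_protein_altering(self) -> float:
        return self.p_missense + self.p_lof

    @property
    def p_total(self) -> float:
        return sum(self.p_class.values())


def _capture_mask(capture, contig: str, positions: np.ndarray) -> np.ndarray:
    if capture is None:
        return np.ones(positions.shape, dtype=bool)
    return capture.covers(contig, positions)


# for a reference code c, the three alternate codes in alphabetical order
_ALT_LUT = np.array([[a for a in range(4) if a != c] for c in range(4)], dtype=np.int8)
_CLASS_CODE = {c: i for i, c in enumerate(MUTATION_CLASSES)}
_CLASS_NAMES = np.array(MUTATION_CLASSES)


def enumerate_substitutions(
    transcript: Transcript,
    rates: ContextRateTable,
    capture=None,
) -> pd.DataFrame:
    """All possible SNVs of a transcript with their rate and functional class.

    One row per (genomic position, genomic alt) within the captured CDS and
    canonical splice sites: columns pos (0-based genomic), ref, alt (genomic
    strand), rate, functional_class. Sites lacking an in-contig trinucleotide
    context or with a non-ACGT context are omitted; the caller can compare
    row counts to detect skips.
    """
    contig_codes = encode_seq(transcript.contig_seq)
    cds_pos = transcript.cds_positions
    cds = encode_seq(transcript.cds_seq)
    n = cds_pos.size

    keep = _capture_mask(capture, transcript.contig, cds_pos)
    keep &= (cds_pos >= 1) & (cds_pos < len(contig_codes) - 1)
    left = np.where(keep, contig_codes[np.clip(cds_pos - 1, 0, None)], -1)
    center = np.where(keep, contig_codes[cds_pos], -1)
    right = np.where(keep, contig_codes[np.clip(cds_pos + 1, None, len(contig_codes) - 1)], -1)
    keep &= (left >= 0) & (center >= 0) & (right >= 0)

    idx = np.nonzero(keep)[0]
    parts = []
    if idx.size:
        g = cds_pos[idx]
        c = center[idx].astype(np.int64)
        ctx = (left[idx].astype(np.int64) << 4) | (c << 2) | right[idx].astype(np.int64)
        galt = _ALT_LUT[c]                          # (m, 3) genomic alt codes
        rate = rates.matrix[ctx[:, None], galt]     # (m, 3)
        talt = _COMPLEMENT_CODE[galt] if transcript.strand == "-" else galt

        # vectorized consequence of changing cds position i to transcript alt
        i = idx.astype(np.int64)
        codon_i, off = i // 3, i % 3
        c0 = cds[3 * codon_i].astype(np.int64)
        c1 = cds[3 * codon_i + 1].astype(np.int64)
        c2 = cds[3 * codon_i + 2].astype(np.int64)
        ref_codon = (c0 << 4) | (c1 << 2) | c2
        scale = (4 ** (2 - off)).astype(np.int64)
        new_codon = ref_codon[:, None] + (talt.astype(np.int64) - cds[i].astype(np.int64)[:, None]) * scale[:, None]
        ref_aa = _AA_CODE[ref_codon][:, None]
        new_aa = _AA_CODE[new_codon]
        cls = np.select(
            [
                (codon_i == 0)[:, None] & np.ones_like(new_aa, dtype=bool),
                ref_aa == _STOP,
                new_aa == _STOP,
                new_aa == ref_aa,
            ],
            [
                _CLASS_CODE["startloss"],
                np.where(new_aa == _STOP, _CLASS_CODE["synonymous"], _CLASS_CODE["stoploss"]),
                _CLASS_CODE["stopgain"],
                _CLASS_CODE["synonymous"],
            ],
            default=_CLASS_CODE["missense"],
        )
        parts.append((np.repeat(g, 3), np.repeat(c, 3), galt.ravel(), rate.ravel(), cls.ravel()))

    sp = _capture_splice(transcript, capture)
    sp = sp[(sp >= 1) & (sp < len(contig_codes) - 1)]
    if sp.size:
        l = contig_codes[sp - 1].astype(np.int64)
        c = contig_codes[sp].astype(np.int64)
        r = contig_codes[sp + 1].astype(np.int64)
        ok = (l >= 0) & (c >= 0) & (r >= 0)
        sp, l, c, r = sp[ok], l[ok], c[ok], r[ok]
        ctx = (l << 4) | (c << 2) | r
        galt = _ALT_LUT[c]
        rate = rates.matrix[ctx[:, None], galt]
        cls = np.full(galt.shape, _CLASS_CODE["splice_canonical"], dtype=np.int64)
        parts.append((np.repeat(sp, 3), np.repeat(c, 3), galt.ravel(), rate.ravel(), cls.ravel()))

    if not parts:
        return pd.DataFrame(columns=["pos", "ref", "alt", "rate", "functional_class"])
    pos = np.concatenate([p[0] for p in parts])
    refc = np.concatenate([p[1] for p in parts])
    altc = np.concatenate([p[2] for p in parts])
    rate = np.concatenate([p[3] for p in parts])
    cls = np.concatenate([p[4] for p in parts])
    bases = np.array(list(BASES))
    return pd.DataFrame(
        {
            "pos": pos.astype(np.int64),
            "ref": bases[refc.astype(np.int64)],
            "alt": bases[altc.astype(np.int64)],
            "rate": rate,
            "functional_class": _CLASS_NAMES[cls],
        }
    )


def _capture_splice(transcript: Transcript, capture) -> np.ndarray:
    sp = transcript.splice_positions()
    if sp.size == 0:
        return sp
    return sp[_capture_mask(capture, transcript.contig, sp)]


def gene_mutability(
    transcript: Transcript,
    rates: ContextRateTable,
    capture=None,
    depth: DepthAdjustment | None = None,
    pli: float | None = None,
    dmis_fraction: float = 0.30,
    mean_expression: float | None = None,
) -> GeneModel:
    """Sum per-substitution probabilities into per-class gene mutabilities.

    ``p_class[c]`` is the depth multiplier times the sum, over all captured
    CDS/splice bases and alternate alleles whose consequence is ``c``, of the
    context-table rate. The frameshift probability is then set to
    ``1.25 x p_stopgain``; in-frame indels are not modelled.
    """
    enum = enumerate_substitutions(transcript, rates, capture)
    mult = depth.get(transcript.gene_id) if depth is not None else 1.0
    if not 0.0 <= mult <= 1.0:
        raise ValueError(f"depth multiplier for {transcript.gene_id} outside [0,1]: {mult}")
    p_class = {c: 0.0 for c in MUTATION_CLASSES}
    if len(enum):
        sums = enum.groupby("functional_class")["rate"].sum()
        for c, v in sums.items():
            p_class[c] = mult * float(v)
    else:
        warnings.warn(f"gene {transcript.gene_id}: no captured coding bases; probabilities are 0", stacklevel=2)
    p_class["frameshift"] = FRAMESHIFT_FACTOR * p_class["stopgain"]

    cds = transcript.cds_seq
    gc = (cds.count("G") + cds.count("C")) / len(cds) if cds else float("nan")
    n_sites = int(transcript.cds_positions.size + transcript.splice_positions().size)
    n_enumerated = len(enum) // 3 if len(enum) else 0
    return GeneModel(
        gene_id=transcript.gene_id,
        p_class=p_class,
        pli=pli,
        dmis_fraction=dmis_fraction,
        gc_content=gc,
        coding_length=len(cds),
        mean_expression=mean_expression,
        n_skipped_sites=max(0, n_sites - n_enumerated),
    )


def expected_dnv_count(p: float, n_trios: int) -> float:
    """Expected DNVs in a cohort: probability x 2 haploid genomes x trios."""
    if p < 0 or n_trios < 0:
        raise ValueError("probability and trio count must be nonnegative")
    return 2.0 * n_trios * p


def gene_models_frame(models: Iterable[GeneModel]) -> pd.DataFrame:
    """Tabulate GeneModels into the DataFrame the enrichment models consume."""
    rows = []
    for m in models:
        row = {"gene": m.gene_id, "pli": np.nan if m.pli is None else m.pli, "dmis_fraction": m.dmis_fraction,
               "gc_content": m.gc_content, "coding_length": m.coding_length, "mean_expression": m.mean_expression}
        for c in MUTATION_CLASSES:
            row[f"p_{c}"] = m.p_class.get(c, 0.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
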