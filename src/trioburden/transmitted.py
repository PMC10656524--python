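"""Rare transmitted-variant enrichment and case-control burden.

Genes are stratified into five sets by published pLI quartile boundaries
(the fifth stratum holds genes without a pLI score). Within stratum k the
observed total of rare damaging heterozygous variants L_k is redistributed
over genes proportionally to mutability,

    expected_{j,k} = L_k * mutability_j / sum_{set k} mutability_j,

which conserves sum_j expected_{j,k} = L_k exactly. Per-gene enrichment is
tested one-sided against Binomial(n = L_k, p = mutability share); the
genome-wide threshold is 0.05 / n_genes. Case-control burden per gene is a
one-sided Fisher's exact test on allele counts with an exact-conditional
one-sided confidence bound on the odds ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: pLI quartile boundaries (upper-exclusive; values at a boundary go up)
PLI_QUARTILE_BOUNDS = (6.4e-8, 1.9e-3, 0.48)

#: stratum labels 1..5; 5 = missing pLI
N_STRATA = 5


def assign_strata(pli: pd.Series) -> pd.Series:
    """Stratum index (1-5) per gene from its pLI score.

    1: pli < 6.4e-8; 2: [6.4e-8, 1.9e-3); 3: [1.9e-3, 0.48); 4: [0.48, 1];
    5: missing. Boundary values are assigned upward.
    """
    vals = pli.astype(float)
    finite = vals.dropna()
    if ((finite < 0) | (finite > 1)).any():
        bad = finite[(finite < 0) | (finite > 1)]
        raise ValueError(f"pLI outside [0,1] for: {list(bad.index[:5])}")
    b1, b2, b3 = PLI_QUARTILE_BOUNDS
    out = pd.Series(5, index=pli.index, dtype=int)
    out[vals < b1] = 1
    out[(vals >= b1) & (vals < b2)] = 2
    out[(vals >= b2) & (vals < b3)] = 3
    out[(vals >= b3) & (vals <= 1.0)] = 4
    return out


@dataclass
class TransmittedStratum:
    """One pLI stratum: its gene set, variant total and expectations."""

    k: int
    genes: pd.Index
    L_k: int
    mutability: pd.Series
    expected: pd.Series

    @property
    def conserved(self) -> bool:
        return bool(np.isclose(self.expected.sum(), self.L_k, rtol=0, atol=1e-9 * max(1, self.L_k)))


def expected_transmitted(mutability: pd.Series, L_k: int) -> pd.Series:
    """Redistribute the stratum total over genes proportional to mutability."""
    if L_k < 0:
        raise ValueError("L_k must be >= 0")
    if (mutability <= 0).any():
        raise ValueError("all gene mutabilities in a stratum must be > 0 (exclude zeros first)")
    if L_k == 0:
        return pd.Series(0.0, index=mutability.index)
    return L_k * mutability / mutability.sum()


def per_gene_binomial_test(observed: int, L_k: int, mutability_share: float) -> float:
    """One-sided upper-tail p from Binomial(n=L_k, p=mutability share)."""
    if observed > L_k:
        raise ValueError(f"observed ({observed}) cannot exceed the stratum total L_k ({L_k})")
    if observed == 0:
        return 1.0
    return float(stats.binom.sf(observed - 1, L_k, mutability_share))


class TransmittedEnrichmentModel:
    """pLI-stratified binomial enrichment of rare transmitted variants.

    Parameters
    ----------
    observed : Series
        Damaging heterozygous variant count per gene (filtered upstream;
        de novo damaging variants may be included per the binomial analysis).
    gene_table : DataFrame
        Indexed by gene with columns ``mutability`` (damaging-class
        probability feeding the expectation) and ``pli``.
    n_genes : int, optional
        Bonferroni divisor; defaults to the number of genes with nonzero
        mutability.
    """

    def __init__(
        self,
        observed: pd.Series,
        gene_table: pd.DataFrame,
        n_genes: int | None = None,
        alpha: float = 0.05,
    ):
        self.gene_table = gene_table
        self.observed = observed.reindex(gene_table.index).fillna(0).astype(int)
        self.alpha = alpha
        usable = gene_table["mutability"] > 0
        self.n_genes = int(n_genes) if n_genes is not None else int(usable.sum())
        self.excluded_genes = list(gene_table.index[~usable])

    def fit(self) -> "TransmittedEnrichmentResults":
        strata_idx = assign_strata(self.gene_table["pli"])
        usable = self.gene_table["mutability"] > 0
        if self.excluded_genes:
            warnings.warn(
                f"{len(self.excluded_genes)} zero-mutability gene(s) excluded from stratification",
                stacklevel=2,
            )
        strata: list[TransmittedStratum] = []
        rows = []
        for k in range(1, N_STRATA + 1):
            mask = (strata_idx == k) & usable
            genes = self.gene_table.index[mask]
            mu = self.gene_table.loc[genes, "mutability"]
            L_k = int(self.observed.loc[genes].sum())
            exp = expected_transmitted(mu, L_k) if len(genes) else pd.Series(dtype=float)
            strata.append(TransmittedStratum(k=k, genes=genes, L_k=L_k, mutability=mu, expected=exp))
            share = mu / mu.sum() if len(genes) and mu.sum() > 0 else mu
            for g in genes:
                obs = int(self.observed.loc[g])
                e = float(exp.loc[g])
                rows.append(
                    {
                        "gene": g,
                        "stratum": k,
                        "L_k": L_k,
                        "observed": obs,
                        "expected": e,
                        "enrichment": obs / e if e > 0 else (np.nan if obs else 0.0),
                        "p": per_gene_binomial_test(obs, L_k, float(share.loc[g])) if L_k else 1.0,
                    }
                )
        per_gene = pd.DataFrame(rows).set_index("gene")
        threshold = self.alpha / self.n_genes
        per_gene["significant"] = per_gene["p"] <= threshold
        return TransmittedEnrichmentResults(
            model=self, strata=strata, per_gene=per_gene, threshold=threshold
        )


@dataclass
class TransmittedEnrichmentResults:
    model: TransmittedEnrichmentModel
    strata: list[TransmittedStratum]
    per_gene: pd.DataFrame
    threshold: float

    @property
    def significant_genes(self) -> pd.DataFrame:
        return self.per_gene[self.per_gene["significant"]]

    def summary(self) -> str:
        lines = [
            "Rare transmitted variant enrichment (pLI-stratified binomial)",
            "=============================================================",
            f"gene universe: {self.model.n_genes}   genome-wide threshold: {self.threshold:.3g} "
            f"({self.model.alpha}/{self.model.n_genes})",
            "",
            "stratum  genes  L_k  conserved",
        ]
        for s in self.strata:
            lines.append(f"{s.k:>7}  {len(s.genes):>5}  {s.L_k:>3}  {s.conserved}")
        sig = self.significant_genes
        lines.append("")
        lines.append(f"genome-wide significant genes: {len(sig)}")
        for g, r in sig.iterrows():
            lines.append(
                f"  {g} (stratum {int(r.stratum)}): obs {int(r.observed)}, exp {r.expected:.3g}, "
                f"{r.enrichment:.1f}-fold, binomial p = {r.p:.3g}"
            )
        return "\n".join(lines)


@dataclass
class BurdenResult:
    """One-sided Fisher's exact case-control burden for one gene."""

    gene: str
    case_ac: int
    case_an: int
    ctrl_ac: int
    ctrl_an: int
    odds_ratio: float
    ci_lower: float
    ci_upper: float  # always inf (one-sided)
    p: float
    degenerate: bool = False


def fisher_burden(
    case_ac: int,
    case_an: int,
    ctrl_ac: int,
    ctrl_an: int,
    gene: str = "",
    alpha: float = 0.05,
    ci: bool = True,
) -> BurdenResult:
    """One-sided (greater) Fisher's exact test on alternate-allele counts.

    The 2x2 table is [[case_ac, case_an - case_ac], [ctrl_ac, ctrl_an -
    ctrl_ac]]. The odds ratio is the sample odds ratio; the one-sided
    (1-alpha) confidence interval is (exact conditional lower bound, inf),
    the lower bound solving P(X >= case_ac | psi) = alpha under Fisher's
    noncentral hypergeometric distribution.
    """
    if case_ac > case_an or ctrl_ac > ctrl_an:
        raise ValueError("allele count cannot exceed allele number")
    if min(case_ac, case_an, ctrl_ac, ctrl_an) < 0:
        raise ValueError("counts must be nonnegative")
    a, b = case_ac, case_an - case_ac
    c, d = ctrl_ac, ctrl_an - ctrl_ac
    if (a + b == 0) or (c + d == 0) or (a + c == 0):
        return BurdenResult(gene, case_ac, case_an, ctrl_ac, ctrl_an,
                            np.nan, np.nan, np.inf, 1.0, degenerate=True)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if b == 0 or c == 0:
        oratio = np.inf
    else:
        oratio = (a * d) / (b * c)
    ci_lower = _exact_or_lower(a, b, c, d, alpha) if ci else np.nan
    return BurdenResult(gene, case_ac, case_an, ctrl_ac, ctrl_an, float(oratio), ci_lower, np.inf, float(p))


def _exact_or_lower(a: int, b: int, c: int, d: int, alpha: float) -> float:
    """Exact conditional one-sided lower confidence bound on the odds ratio."""
    M = a + b + c + d
    n_type1 = a + c      # alt alleles overall
    N_draw = a + b       # case margin
    k_max = min(n_type1, N_draw)
    if a == 0:
        return 0.0

    def tail(log_psi: float) -> float:
        dist = stats.nchypergeom_fisher(M, n_type1, N_draw, np.exp(log_psi))
        return float(dist.sf(a - 1))

    lo, hi = -50.0, 50.0
    if tail(lo) >= alpha:
        return 0.0
    if tail(hi) <= alpha:
        return np.inf
    sol = optimize.brentq(lambda x: tail(x) - alpha, lo, hi, xtol=1e-10)
    return float(np.exp(sol))


def burden_table(rows: list[BurdenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "case_ac": r.case_ac,
                "case_an": r.case_an,
                "ctrl_ac": r.ctrl_ac,
                "ctrl_an": r.ctrl_an,
                "odds_ratio": r.odds_ratio,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "p": r.p,
            }
            for r in rows
        ]
    )
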