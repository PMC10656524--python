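"""De novo variant enrichment against the mutability expectation model.

The cohort-level analysis compares observed DNV counts per functional class
with the class expectation 2 x N_trios x sum_genes p_class using a one-sided
Poisson test; the per-gene analysis tests protein-altering, protein-damaging
and LoF counts per gene with a Bonferroni threshold of 0.05 / (3 x n_genes).
The excess of observed over expected damaging DNVs divided by the cohort
size is the attributable fraction; a Monte Carlo procedure estimates how
many risk genes carry that excess and how gene discovery saturates with
future cohort size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mutability import LOF_CLASSES

#: functional class families reported in the cohort-level table, in order
CLASS_FAMILIES = ("total", "syn", "t_mis", "d_mis", "lof", "protein_altering", "protein_damaging")

#: class families tested per gene
PER_GENE_FAMILIES = ("protein_altering", "protein_damaging", "lof")


def poisson_upper_p(observed: int, expected: float) -> float:
    """One-sided upper-tail Poisson probability P(X >= observed).

    Computed at full numeric precision via the survival function (the
    regularized upper incomplete gamma function); no normal approximation.
    """
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if expected <= 0:
        raise ValueError("expected count must be > 0")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, expected))


def attributable_fraction(observed_damaging: int, expected_damaging: float, n_probands: int) -> float:
    """Fraction of cases attributable to damaging DNVs: (obs - exp) / N."""
    if n_probands == 0:
        raise ValueError("n_probands must be > 0")
    if observed_damaging < expected_damaging:
        warnings.warn("observed < expected; attributable fraction floored at 0", stacklevel=2)
        return 0.0
    return (observed_damaging - expected_damaging) / n_probands


def classify_family(functional_class: str, metasvm: str | None, mpc: float | None, mpc_threshold: float = 2.0) -> dict[str, bool]:
    """Membership of one DNV in each reported class family."""
    lof = functional_class in LOF_CLASSES
    mis = functional_class == "missense"
    dmis = mis and (metasvm == "D" or (mpc is not None and mpc >= mpc_threshold))
    syn = functional_class == "synonymous"
    return {
        "total": lof or mis or syn,
        "syn": syn,
        "t_mis": mis and not dmis,
        "d_mis": dmis,
        "lof": lof,
        "protein_altering": mis or lof,
        "protein_damaging": dmis or lof,
    }


def expected_by_family(gene_models: pd.DataFrame, n_trios: int) -> pd.DataFrame:
    """Per-gene expected DNV counts per class family (2 x N x p).

    ``gene_models`` is indexed by gene with columns ``p_<class>`` for the
    seven modelled classes plus ``dmis_fraction`` (used to split missense
    mass into damaging and tolerated parts).
    """
    dmis_frac = gene_models.get("dmis_fraction", pd.Series(0.3, index=gene_models.index))
    p_lof = sum(gene_models[f"p_{c}"] for c in sorted(LOF_CLASSES))
    p_mis = gene_models["p_missense"]
    p_syn = gene_models["p_synonymous"]
    p_dmis = dmis_frac * p_mis
    scale = 2.0 * n_trios
    out = pd.DataFrame(
        {
            "total": scale * (p_syn + p_mis + p_lof),
            "syn": scale * p_syn,
            "t_mis": scale * (p_mis - p_dmis),
            "d_mis": scale * p_dmis,
            "lof": scale * p_lof,
            "protein_altering": scale * (p_mis + p_lof),
            "protein_damaging": scale * (p_dmis + p_lof),
        },
        index=gene_models.index,
    )
    return out


@dataclass
class SaturationEstimate:
    """Monte Carlo estimate of the number of DNV risk genes and of the
    fraction discoverable at future cohort sizes."""

    n_risk_genes: float
    interval: tuple[float, float]
    saturation: dict[int, float]
    excess_dnvs: float
    multihit_observed: int
    replicates: int
    seed: int
    min_hits: int = 1


class DnvEnrichmentModel:
    """Cohort-level and per-gene one-sided Poisson DNV enrichment.

    Parameters
    ----------
    dnvs : DataFrame
        One row per filtered DNV with columns ``gene``, ``functional_class``
        and optionally ``metasvm``, ``mpc``.
    gene_models : DataFrame
        Indexed by gene, columns ``p_<class>`` (mutability per class),
        ``pli``, ``dmis_fraction``.
    n_trios : int
        Number of complete trios (probands with both parents).
    n_genes : int, optional
        Gene universe size for the Bonferroni divisor; defaults to the
        number of genes with nonzero total mutability.
    """

    def __init__(
        self,
        dnvs: pd.DataFrame,
        gene_models: pd.DataFrame,
        n_trios: int,
        n_genes: int | None = None,
        alpha: float = 0.05,
        pli_cutoff: float = 0.9,
        mpc_threshold: float = 2.0,
    ):
        if n_trios <= 0:
            raise ValueError("n_trios must be positive")
        self.dnvs = dnvs.reset_index(drop=True)
        self.gene_models = gene_models
        self.n_trios = int(n_trios)
        self.alpha = alpha
        self.pli_cutoff = pli_cutoff
        self.mpc_threshold = mpc_threshold
        self.expected = expected_by_family(gene_models, n_trios)
        nonzero = (self.expected["total"] > 0).sum()
        self.n_genes = int(n_genes) if n_genes is not None else int(nonzero)

    def _membership(self) -> pd.DataFrame:
        rows = []
        for r in self.dnvs.itertuples():
            fam = classify_family(
                r.functional_class,
                getattr(r, "metasvm", None),
                getattr(r, "mpc", None),
                self.mpc_threshold,
            )
            fam["gene"] = r.gene
            rows.append(fam)
        if not rows:
            return pd.DataFrame(columns=["gene", *CLASS_FAMILIES])
        return pd.DataFrame(rows)

    def fit(self) -> "DnvEnrichmentResults":
        membership = self._membership()

        # cohort-level class table for all genes and the constrained subset
        tables = {}
        for label, gene_mask in (
            ("all", pd.Series(True, index=self.gene_models.index)),
            ("pli_ge_0.9", self.gene_models["pli"] >= self.pli_cutoff),
        ):
            genes = set(self.gene_models.index[gene_mask.fillna(False)])
            exp = self.expected.loc[sorted(genes & set(self.expected.index))].sum()
            rows = []
            for fam in CLASS_FAMILIES:
                if len(membership):
                    obs = int(membership.loc[membership["gene"].isin(genes), fam].sum())
                else:
                    obs = 0
                rows.append(_enrichment_row(fam, obs, float(exp[fam]), self.n_trios))
            tables[label] = pd.DataFrame(rows).set_index("unit")

        per_gene = self._per_gene(membership)
        threshold = self.alpha / (len(PER_GENE_FAMILIES) * self.n_genes)
        per_gene["significant"] = per_gene["p"] <= threshold

        dmg = tables["all"].loc["protein_damaging"]
        af = attributable_fraction(int(dmg["observed"]), float(dmg["expected"]), self.n_trios)
        lo, hi = _poisson_ci(int(dmg["observed"]))
        af_ci = (
            max(0.0, (lo - float(dmg["expected"])) / self.n_trios),
            max(0.0, (hi - float(dmg["expected"])) / self.n_trios),
        )
        return DnvEnrichmentResults(
            model=self,
            class_tables=tables,
            per_gene=per_gene,
            per_gene_threshold=threshold,
            attributable_fraction_=af,
            attributable_fraction_ci=af_ci,
        )

    def _per_gene(self, membership: pd.DataFrame) -> pd.DataFrame:
        rows = []
        zero_expectation = self.expected["total"] <= 0
        for fam in PER_GENE_FAMILIES:
            if len(membership):
                obs_by_gene = membership.groupby("gene")[fam].sum().astype(int)
            else:
                obs_by_gene = pd.Series(dtype=int)
            for gene in self.expected.index:
                if zero_expectation[gene]:
                    continue
                exp = float(self.expected.loc[gene, fam])
                obs = int(obs_by_gene.get(gene, 0))
                if exp <= 0:
                    if obs > 0:
                        rows.append({"gene": gene, "class_family": fam, "observed": obs,
                                     "expected": exp, "enrichment": np.inf, "p": np.nan})
                    continue
                rows.append(
                    {
                        "gene": gene,
                        "class_family": fam,
                        "observed": obs,
                        "expected": exp,
                        "enrichment": obs / exp,
                        "p": poisson_upper_p(obs, exp),
                    }
                )
        return pd.DataFrame(rows, columns=["gene", "class_family", "observed", "expected", "enrichment", "p"])


def _enrichment_row(unit: str, observed: int, expected: float, n_trios: int) -> dict:
    if expected > 0:
        p = poisson_upper_p(observed, expected)
        enrichment = observed / expected
    else:
        p = np.nan if observed else 1.0
        enrichment = np.nan if observed else 0.0
    return {
        "unit": unit,
        "observed": observed,
        "rate": observed / n_trios,
        "expected": expected,
        "expected_rate": expected / n_trios,
        "enrichment": enrichment,
        "p": p,
    }


def _poisson_ci(observed: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) central CI for a Poisson mean given one count."""
    a = 1.0 - level
    lo = 0.0 if observed == 0 else stats.chi2.ppf(a / 2, 2 * observed) / 2
    hi = stats.chi2.ppf(1 - a / 2, 2 * (observed + 1)) / 2
    return lo, hi


@dataclass
class DnvEnrichmentResults:
    """Fitted DNV enrichment: class tables, per-gene tests, diagnostics."""

    model: DnvEnrichmentModel
    class_tables: dict[str, pd.DataFrame]
    per_gene: pd.DataFrame
    per_gene_threshold: float
    attributable_fraction_: float
    attributable_fraction_ci: tuple[float, float]

    def class_table(self, subset: str = "all") -> pd.DataFrame:
        return self.class_tables[subset]

    @property
    def significant_genes(self) -> pd.DataFrame:
        return self.per_gene[self.per_gene["significant"]]

    def qq_data(self, class_family: str = "protein_damaging") -> pd.DataFrame:
        """Observed vs expected -log10 p for the per-gene tests (QQ plot)."""
        sub = self.per_gene[self.per_gene["class_family"] == class_family].dropna(subset=["p"])
        p = np.sort(sub["p"].to_numpy())
        n = len(p)
        exp = (np.arange(1, n + 1) - 0.5) / n
        return pd.DataFrame({"expected_neglog10": -np.log10(exp), "observed_neglog10": -np.log10(p)})

    def estimate_saturation(
        self,
        future_sizes: list[int],
        replicates: int = 500,
        seed: int = 0,
        min_hits: int = 1,
    ) -> SaturationEstimate:
        counts = (
            self.per_gene[self.per_gene["class_family"] == "protein_damaging"]
            .set_index("gene")["observed"]
        )
        mu = self.model.expected["protein_damaging"] / (2.0 * self.model.n_trios)
        return estimate_risk_genes_and_saturation(
            counts, mu, self.model.n_trios, future_sizes, replicates=replicates, seed=seed, min_hits=min_hits
        )

    def summary(self) -> str:
        lines = [
            "De novo variant enrichment",
            "==========================",
            f"trios: {self.model.n_trios}   gene universe: {self.model.n_genes}",
            f"per-gene Bonferroni threshold: {self.per_gene_threshold:.3g} "
            f"({self.model.alpha} / (3 x {self.model.n_genes}))",
            "",
        ]
        for label, tab in self.class_tables.items():
            lines.append(f"[{label}]")
            disp = tab.copy()
            disp["rate"] = disp["rate"].round(2)
            disp["expected"] = disp["expected"].round(1)
            disp["expected_rate"] = disp["expected_rate"].round(2)
            disp["enrichment"] = disp["enrichment"].round(2)
            disp["p"] = disp["p"].round(2)
            lines.append(disp.to_string())
            lines.append("")
        af_lo, af_hi = self.attributable_fraction_ci
        lines.append(
            f"attributable fraction (damaging DNVs): {self.attributable_fraction_:.3f} "
            f"[{af_lo:.3f}, {af_hi:.3f}]"
        )
        sig = self.significant_genes
        lines.append(f"genome-wide significant gene tests: {len(sig)}")
        for r in sig.itertuples():
            lines.append(f"  {r.gene} ({r.class_family}): obs {r.observed}, exp {r.expected:.2e}, "
                         f"{r.enrichment:.1f}-fold, p = {r.p:.3g}")
        return "\n".join(lines)


def estimate_risk_genes_and_saturation(
    dnv_gene_multiplicities: pd.Series,
    damaging_mutability: pd.Series,
    n_trios: int,
    future_sizes: list[int],
    replicates: int = 500,
    seed: int = 0,
    min_hits: int = 1,
    max_risk_genes: int | None = None,
) -> SaturationEstimate:
    """Monte Carlo risk-gene count and gene-discovery saturation.

    The observed excess of damaging DNVs over expectation is assumed to be
    carried by M mutability-weighted risk genes. For each candidate M the
    excess DNVs are scattered multinomially (probability proportional to
    mutability) over a random M-gene risk set on top of Poisson background
    hits for every gene, and the expected number of multi-hit genes (>= 2
    damaging DNVs) is matched to the observed multi-hit count — fewer risk
    genes concentrate the excess and produce more recurrences. The interval
    contains the M whose simulated multi-hit distribution covers the
    observation centrally. Saturation at a future cohort size is the
    expected fraction of the M risk genes attaining >= ``min_hits`` damaging
    DNVs.

    ``replicates`` must be >= 100 for a stable profile.
    """
    if replicates < 100:
        raise ValueError("replicates must be >= 100")
    rng = np.random.default_rng(seed)

    mu = damaging_mutability.reindex(dnv_gene_multiplicities.index.union(damaging_mutability.index)).fillna(0.0)
    counts = dnv_gene_multiplicities.reindex(mu.index).fillna(0).astype(int)
    expected_total = float(2.0 * n_trios * mu.sum())
    observed_total = int(counts.sum())
    excess = observed_total - expected_total
    multihit_obs = int((counts >= 2).sum())

    if excess <= 0:
        return SaturationEstimate(
            n_risk_genes=0.0,
            interval=(0.0, 0.0),
            saturation={n: 0.0 for n in future_sizes},
            excess_dnvs=max(0.0, excess),
            multihit_observed=multihit_obs,
            replicates=replicates,
            seed=seed,
            min_hits=min_hits,
        )

    weights = mu.to_numpy()
    weights = weights / weights.sum()
    lam_bg = 2.0 * n_trios * mu.to_numpy()
    n_excess = int(round(excess))
    n_genes = len(mu)
    cap = max_risk_genes or min(n_genes, max(10 * n_excess, 200))

    grid = np.unique(np.round(np.geomspace(1, cap, num=40)).astype(int))
    mean_c2 = np.empty(len(grid))
    cover = np.zeros(len(grid), dtype=bool)
    for gi, m in enumerate(grid):
        c2 = _simulate_multihit(rng, weights, lam_bg, n_excess, m, replicates)
        mean_c2[gi] = c2.mean()
        lo, hi = np.quantile(c2, [0.025, 0.975])
        cover[gi] = lo <= multihit_obs <= hi

    # mean multi-hit count decreases in M; pick the best match then refine
    best = int(grid[np.argmin(np.abs(mean_c2 - multihit_obs))])
    lo_grid = max(1, best // 2)
    hi_grid = min(cap, max(best * 2, best + 5))
    fine = np.arange(lo_grid, hi_grid + 1)
    fine_c2 = np.empty(len(fine))
    fine_cover = np.zeros(len(fine), dtype=bool)
    for gi, m in enumerate(fine):
        c2 = _simulate_multihit(rng, weights, lam_bg, n_excess, int(m), max(100, replicates // 2))
        fine_c2[gi] = c2.mean()
        qlo, qhi = np.quantile(c2, [0.025, 0.975])
        fine_cover[gi] = qlo <= multihit_obs <= qhi
    m_hat = float(fine[np.argmin(np.abs(fine_c2 - multihit_obs))])

    covered = np.concatenate([grid[cover], fine[fine_cover]])
    interval = (float(covered.min()), float(covered.max())) if covered.size else (m_hat, m_hat)

    saturation: dict[int, float] = {}
    m_int = max(1, int(round(m_hat)))
    excess_per_trio = excess / n_trios
    for n_f in sorted(future_sizes):
        vals = np.empty(replicates)
        for r in range(replicates):
            risk = _weighted_sample(rng, weights, m_int)
            w_risk = weights[risk] / weights[risk].sum()
            lam = 2.0 * n_f * mu.to_numpy()[risk] + n_f * excess_per_trio * w_risk
            vals[r] = np.mean(stats.poisson.sf(min_hits - 1, lam))
        saturation[int(n_f)] = float(vals.mean())
    sat_sorted = dict(sorted(saturation.items()))

    return SaturationEstimate(
        n_risk_genes=m_hat,
        interval=interval,
        saturation=sat_sorted,
        excess_dnvs=float(excess),
        multihit_observed=multihit_obs,
        replicates=replicates,
        seed=seed,
        min_hits=min_hits,
    )


def _weighted_sample(rng: np.random.Generator, weights: np.ndarray, m: int) -> np.ndarray:
    m = min(m, int((weights > 0).sum()))
    return rng.choice(len(weights), size=m, replace=False, p=weights)


def _simulate_multihit(
    rng: np.random.Generator,
    weights: np.ndarray,
    lam_bg: np.ndarray,
    n_excess: int,
    m: int,
    replicates: int,
) -> np.ndarray:
    out = np.empty(replicates)
    for r in range(replicates):
        counts = rng.poisson(lam_bg)
        risk = _weighted_sample(rng, weights, m)
        w = weights[risk] / weights[risk].sum()
        counts[risk] += rng.multinomial(n_excess, w)
        out[r] = np.sum(counts >= 2)
    return out
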