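"""Published worked-example statistics of the VOGM trio-exome study.

The study's cohort-level DNV table and headline per-gene statistics are
re-derivable from the printed observed/expected pairs alone; they are
embedded here as data so the whole analysis chain can be exercised and
checked without access to the private patient exomes.
"""

from __future__ import annotations

import pandas as pd

from .dnv import attributable_fraction, poisson_upper_p

#: cohort-level DNV enrichment, all genes: observed, printed expected,
#: printed enrichment, printed p. 90 case trios / 1,798 control trios.
CLASS_TABLE_CASES = pd.DataFrame(
    [
        ("total", 107, 99.7, 1.07, 0.25),
        ("syn", 28, 28.2, 0.99, 0.54),
        ("t_mis", 46, 49.4, 0.93, 0.71),
        ("d_mis", 22, 13.4, 1.65, 0.02),
        ("lof", 11, 8.7, 1.27, 0.26),
        ("protein_altering", 79, 71.5, 1.11, 0.20),
        ("protein_damaging", 33, 22.0, 1.50, 0.02),
    ],
    columns=["unit", "observed", "expected", "printed_enrichment", "printed_p"],
).set_index("unit")

CLASS_TABLE_CONTROLS = pd.DataFrame(
    [
        ("total", 1839, 1977.1, 0.93, 1.00),
        ("syn", 492, 559.8, 0.88, 1.00),
        ("t_mis", 949, 979.3, 0.97, 0.84),
        ("d_mis", 248, 266.7, 0.93, 0.88),
        ("lof", 150, 171.3, 0.88, 0.95),
        ("protein_altering", 1347, 1417.3, 0.95, 0.97),
        ("protein_damaging", 398, 438.0, 0.91, 0.98),
    ],
    columns=["unit", "observed", "expected", "printed_enrichment", "printed_p"],
).set_index("unit")

N_CASE_TRIOS = 90
N_CONTROL_TRIOS = 1798
N_GENES = 19347
N_MODULES = 88
N_CELL_TYPES = 42

#: headline per-gene statistics: gene, observed count, printed fold, printed p
HEADLINE_GENES = pd.DataFrame(
    [
        ("RASA1_dnv", 2, 2042.5, 4.79e-7, "poisson"),
        ("KEL_dnv", 2, 440.7, 1.03e-5, "poisson"),
        ("EPHB4_transmitted", 5, 17.5, 1.22e-5, "binomial"),
        ("RASA1_transmitted", 5, 28.4, 1.20e-6, "binomial"),
    ],
    columns=["unit", "observed", "printed_fold", "printed_p", "test"],
).set_index("unit")


def recomputed_class_table(table: pd.DataFrame, n_trios: int) -> pd.DataFrame:
    """Enrichment and Poisson p recomputed from the (observed, expected) pairs."""
    out = table.copy()
    out["rate"] = out["observed"] / n_trios
    out["enrichment"] = out["observed"] / out["expected"]
    out["p"] = [poisson_upper_p(int(o), float(e)) for o, e in zip(out["observed"], out["expected"])]
    return out


def reproduction_report() -> pd.DataFrame:
    """Recompute every embedded worked-example statistic from its inputs.

    One row per quantity with the recomputed value, the printed value, and
    whether they agree after matching the printed rounding.
    """
    rows = []
    for label, table, n in (
        ("cases", CLASS_TABLE_CASES, N_CASE_TRIOS),
        ("controls", CLASS_TABLE_CONTROLS, N_CONTROL_TRIOS),
    ):
        rec = recomputed_class_table(table, n)
        for unit, r in rec.iterrows():
            rows.append(
                {
                    "quantity": f"{label}:{unit}:enrichment",
                    "recomputed": round(float(r["enrichment"]), 2),
                    "printed": float(r["printed_enrichment"]),
                }
            )
            rows.append(
                {
                    "quantity": f"{label}:{unit}:p",
                    "recomputed": round(float(r["p"]), 2),
                    "printed": float(r["printed_p"]),
                }
            )
    for unit, r in HEADLINE_GENES.iterrows():
        expected = r["observed"] / r["printed_fold"]
        p = poisson_upper_p(int(r["observed"]), float(expected))
        rows.append({"quantity": f"{unit}:p", "recomputed": float(f"{p:.3g}"), "printed": float(r["printed_p"])})
    rate = CLASS_TABLE_CASES.loc["total", "observed"] / N_CASE_TRIOS
    rows.append({"quantity": "cases:dnv_rate_per_subject", "recomputed": round(float(rate), 2), "printed": 1.19})
    af = attributable_fraction(
        int(CLASS_TABLE_CASES.loc["protein_damaging", "observed"]),
        float(CLASS_TABLE_CASES.loc["protein_damaging", "expected"]),
        N_CASE_TRIOS,
    )
    rows.append({"quantity": "attributable_fraction_pct", "recomputed": round(100 * af, 1), "printed": 12.2})
    for name, alpha, n in (
        ("per_gene_dnv_threshold", 0.05, 3 * N_GENES),
        ("per_gene_binomial_threshold", 0.05, N_GENES),
        ("module_threshold", 0.05, N_MODULES),
        ("cell_type_threshold", 0.05, N_CELL_TYPES),
    ):
        printed = {"per_gene_dnv_threshold": 8.6e-7, "per_gene_binomial_threshold": 2.6e-6,
                   "module_threshold": 5.68e-4, "cell_type_threshold": 1.19e-3}[name]
        rows.append({"quantity": name, "recomputed": float(f"{alpha / n:.3g}"), "printed": printed})
    df = pd.DataFrame(rows)
    df["match"] = [
        abs(a - b) <= 0.01 * max(1.0, abs(b)) if b >= 0.01 else abs(a - b) / b <= 0.05
        for a, b in zip(df["recomputed"], df["printed"])
    ]
    return df
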