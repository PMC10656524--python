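"""Covariate-adjusted indicator logistic-regression gene-set enrichment.

Two orientations are supported and recorded, mirroring the two analyses:
module enrichment regresses the disease indicator on the set indicator
(is_disease ~ is_set + covariates), cell-type enrichment regresses the set
indicator on the disease indicator (is_set ~ is_disease + covariates).
Covariates are transformed (log10 for length-like and expression-like
columns, raw for fractions) and z-scored before fitting, so results are
invariant to affine rescaling of the inputs. Complete separation is
detected and, when a fallback is allowed, refit with Jeffreys-penalised
(Firth) logistic regression and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_COVARIATE_TRANSFORMS = {
    "gc_content": None,
    "gene_length": "log10",
    "coding_length": "log10",
    "mean_expression": "log10",
}


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class GeneUniverse:
    """Background gene set with set/disease membership flags and covariates.

    ``sets`` and ``diseases`` are boolean DataFrames (genes x labels);
    ``covariates`` is numeric (genes x covariate). All three share the gene
    index.
    """

    sets: pd.DataFrame
    diseases: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self):
        idx = self.sets.index
        if not (self.diseases.index.equals(idx) and self.covariates.index.equals(idx)):
            raise ValueError("sets, diseases and covariates must share the gene index")
        if not np.isfinite(self.covariates.to_numpy(dtype=float)).all():
            raise ValueError("covariates must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.sets.index

    def exclude_unassigned(self, unassigned_set_id: str) -> "GeneUniverse":
        """Drop the unassigned ('gray') set from testing; genes exclusively in
        it leave the background entirely."""
        if unassigned_set_id not in self.sets.columns:
            return self
        others = self.sets.drop(columns=[unassigned_set_id])
        keep = others.any(axis=1) | ~self.sets[unassigned_set_id]
        return GeneUniverse(
            sets=others.loc[keep],
            diseases=self.diseases.loc[keep],
            covariates=self.covariates.loc[keep],
        )


@dataclass
class EnrichmentFit:
    """One set x disease logistic enrichment fit."""

    set_id: str
    disease_id: str
    orientation: str  # "module" (is_disease ~ is_set) or "celltype" (is_set ~ is_disease)
    coef: float
    se: float
    p: float
    significant: bool | None = None
    separation: bool = False
    method: str = "mle"
    n: int = 0


def _design(
    universe: GeneUniverse,
    set_id: str,
    disease_id: str,
    orientation: str,
    covariate_transforms: dict | None,
) -> tuple[np.ndarray, np.ndarray]:
    is_set = universe.sets[set_id].to_numpy(dtype=float)
    is_dis = universe.diseases[disease_id].to_numpy(dtype=float)
    if orientation == "module":
        y, x = is_dis, is_set
    elif orientation == "celltype":
        y, x = is_set, is_dis
    else:
        raise ValueError(f"orientation must be 'module' or 'celltype', got {orientation!r}")
    for v, name in ((is_set, set_id), (is_dis, disease_id)):
        if v.sum() == 0 or v.sum() == len(v):
            raise ValueError(f"indicator {name!r} has no genes on one side (all-in or all-out)")
    transforms = {**DEFAULT_COVARIATE_TRANSFORMS, **(covariate_transforms or {})}
    cols = [x]
    for c in universe.covariates.columns:
        v = universe.covariates[c].to_numpy(dtype=float)
        if transforms.get(c) == "log10":
            if (v <= 0).any():
                raise ValueError(f"covariate {c} must be positive for a log10 transform")
            v = np.log10(v)
        sd = v.std()
        cols.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
    X = sm.add_constant(np.column_stack(cols), prepend=True)
    return y, X


def fit_enrichment(
    universe: GeneUniverse,
    set_id: str,
    disease_id: str,
    orientation: str = "module",
    covariate_transforms: dict | None = None,
    allow_penalized_fallback: bool = True,
) -> EnrichmentFit:
    """Indicator logistic enrichment of one gene set for one disease list.

    Returns the Wald test on the indicator coefficient. On complete or
    quasi-complete separation the fit is redone with Firth's penalised
    likelihood and flagged (or raises if the fallback is disabled).
    """
    y, X = _design(universe, set_id, disease_id, orientation, covariate_transforms)
    separation = False
    method = "mle"
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            coef, se = res.params[1], res.bse[1]
            p = res.pvalues[1]
            if not np.isfinite(se) or se > 1e3:
                raise sm.tools.sm_exceptions.PerfectSeparationError("unstable standard error")
        except Exception:
            separation = True
            if not allow_penalized_fallback:
                raise RuntimeError(
                    f"separation fitting {set_id} x {disease_id}; penalized fallback disabled"
                ) from None
            coef_v, se_v = firth_logit(y, X)
            coef, se = coef_v[1], se_v[1]
            z = coef / se
            p = 2 * stats.norm.sf(abs(z))
            method = "firth"
    return EnrichmentFit(
        set_id=set_id,
        disease_id=disease_id,
        orientation=orientation,
        coef=float(coef),
        se=float(se),
        p=float(p),
        separation=separation,
        method=method,
        n=len(y),
    )


def firth_logit(y: np.ndarray, X: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Firth (Jeffreys-penalised) logistic regression by modified Newton scoring.

    Returns (coefficients, standard errors). The penalised score adds
    h_i (1/2 - p_i) to each observation's contribution, where h are the
    leverages of the weighted hat matrix; estimates exist even under
    complete separation.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # leverages of the weighted hat matrix
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(w)[:, None], info_inv, X * np.sqrt(w)[:, None])
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # step-halving for stability
        for _ in range(20):
            if np.all(np.abs(X @ (beta + step)) < 500):
                break
            step *= 0.5
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    info = (X.T * w) @ X
    cov = np.linalg.pinv(info)
    return beta, np.sqrt(np.diag(cov))


class GenesetEnrichmentModel:
    """All set x disease logistic enrichments with Bonferroni control.

    ``bonferroni_n`` defaults to the number of sets in the *input* universe
    (before dropping the unassigned set), matching the convention of
    dividing by the full module count.
    """

    def __init__(
        self,
        universe: GeneUniverse,
        orientation: str = "module",
        alpha: float = 0.05,
        unassigned_set_id: str | None = None,
        bonferroni_n: int | None = None,
        covariate_transforms: dict | None = None,
    ):
        self.orientation = orientation
        self.alpha = alpha
        self.bonferroni_n = bonferroni_n if bonferroni_n is not None else universe.sets.shape[1]
        self.covariate_transforms = covariate_transforms
        self.universe = universe.exclude_unassigned(unassigned_set_id) if unassigned_set_id else universe

    def fit(self) -> "GenesetEnrichmentResults":
        threshold = bonferroni_threshold(self.alpha, self.bonferroni_n)
        fits: list[EnrichmentFit] = []
        for set_id in self.universe.sets.columns:
            for disease_id in self.universe.diseases.columns:
                f = fit_enrichment(
                    self.universe, set_id, disease_id, self.orientation, self.covariate_transforms
                )
                f.significant = f.p <= threshold and f.coef > 0
                fits.append(f)
        return GenesetEnrichmentResults(model=self, fits=fits, threshold=threshold)


@dataclass
class GenesetEnrichmentResults:
    model: GenesetEnrichmentModel
    fits: list[EnrichmentFit]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set": f.set_id,
                    "disease": f.disease_id,
                    "coef": f.coef,
                    "se": f.se,
                    "p": f.p,
                    "significant": f.significant,
                    "separation": f.separation,
                    "method": f.method,
                }
                for f in self.fits
            ]
        )

    def matrix(self, value: str = "p") -> pd.DataFrame:
        df = self.to_frame()
        return df.pivot(index="set", columns="disease", values=value)

    def summary(self) -> str:
        df = self.to_frame()
        sig = df[df["significant"].astype(bool)]
        lines = [
            f"Gene-set enrichment ({self.model.orientation} orientation)",
            f"tests: {len(df)}   Bonferroni threshold: {self.threshold:.3g} "
            f"({self.model.alpha}/{self.model.bonferroni_n})",
            f"significant: {len(sig)}",
        ]
        for r in sig.itertuples():
            lines.append(f"  {r.set} x {r.disease}: log-odds {r.coef:.2f} (se {r.se:.2f}), p = {r.p:.3g}")
        return "\n".join(lines)
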