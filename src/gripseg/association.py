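"""Covariate-adjusted linear-model families with per-family BH-FDR.

Every association is an ordinary-least-squares fit with an intercept,
reporting the coefficient, classical standard error, t statistic and
two-sided p-value for one named predictor.  P-values are corrected for
multiple comparisons with the Benjamini-Hochberg step-up procedure within
a declared family (e.g. the five cognitive outcomes for one predictor, or
the nine network-level segregation measures).

Validation-analysis variants (extra covariates such as SM-MMSE, GDS, BMI,
waist-hip ratio or scan interval, or swapping intracranial for grey-matter
volume) only change the covariate list, never the family structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .phenotypes import drop_incomplete


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    predictor: str
    covariates: tuple[str, ...]
    family_id: str
    n: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.predictor in self.covariates:
            raise ValueError(f"predictor {self.predictor!r} also listed as covariate")


@dataclass(frozen=True)
class AssociationResult:
    spec: ModelSpec
    coefficient: float
    se: float
    t: float
    df: int
    p_uncorrected: float
    p_fdr: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_fdr is not None and self.p_fdr < 0.05


def _design(data: pd.DataFrame, columns: list[str]) -> np.ndarray:
    x = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in columns])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"rank-deficient design: columns {['intercept'] + columns} have rank {rank}")
    return x


def fit_ols(spec: ModelSpec, data: pd.DataFrame) -> AssociationResult:
    """OLS with intercept; coefficient/SE/t/p for ``spec.predictor``.

    Rows missing any model variable are dropped listwise (logged).
    """
    cols = [spec.outcome, spec.predictor, *spec.covariates]
    rows = drop_incomplete(data, cols, context=f"{spec.family_id}:{spec.outcome}")
    n = len(rows)
    design_cols = [spec.predictor, *spec.covariates]
    if n <= len(design_cols) + 2:
        raise ValueError(f"too few complete rows (n={n}) for {len(design_cols)} predictors")
    x = _design(rows, design_cols)
    y = rows[spec.outcome].to_numpy(float)
    fit = sm.OLS(y, x).fit()
    if fit.ssr <= 0 and fit.df_resid > 0:
        raise ValueError("zero residual variance: outcome is an exact linear combination")
    j = 1  # predictor sits right after the intercept
    return AssociationResult(
        spec=replace(spec, n=n),
        coefficient=float(fit.params[j]),
        se=float(fit.bse[j]),
        t=float(fit.tvalues[j]),
        df=int(fit.df_resid),
        p_uncorrected=float(fit.pvalues[j]),
    )


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    p̃(i) = min_{j >= i} (p(j) * m / j) over the ascending sort, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def residualize(y: np.ndarray | pd.Series, covariates: pd.DataFrame | np.ndarray
                ) -> np.ndarray:
    """Residuals of y after OLS projection onto [intercept, covariates]."""
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    x = np.column_stack([np.ones(len(y)), c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def run_family(family_id: str, outcomes: list[str], predictor: str,
               covariates: list[str], data: pd.DataFrame,
               exclude_from_correction: list[str] | None = None,
               ) -> list[AssociationResult]:
    """Fit one model per outcome and BH-adjust within the family.

    ``exclude_from_correction`` lists outcomes reported alongside the family
    but left out of the adjustment (e.g. global segregation next to the nine
    network-level measures); their ``p_fdr`` is their own uncorrected p.
    """
    excluded = set(exclude_from_correction or [])
    results = [
        fit_ols(ModelSpec(out, predictor, tuple(covariates), family_id), data)
        for out in outcomes
    ]
    member_idx = [i for i, r in enumerate(results) if r.spec.outcome not in excluded]
    adj = bh_fdr([results[i].p_uncorrected for i in member_idx])
    out: list[AssociationResult] = []
    adj_map = dict(zip(member_idx, adj))
    for i, r in enumerate(results):
        p_fdr = float(adj_map[i]) if i in adj_map else r.p_uncorrected
        out.append(replace(r, p_fdr=p_fdr))
    return out


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Long table mirroring the reported columns: measure, coefficient, SE, t, p's."""
    rows = [
        {
            "family": r.spec.family_id,
            "outcome": r.spec.outcome,
            "predictor": r.spec.predictor,
            "n": r.spec.n,
            "coefficient": r.coefficient,
            "se": r.se,
            "t": r.t,
            "df": r.df,
            "p_uncorrected": r.p_uncorrected,
            "p_fdr": r.p_fdr,
            "significant": r.significant,
        }
        for r in results
    ]
    cols = ["family", "outcome", "predictor", "n", "coefficient", "se", "t",
            "df", "p_uncorrected", "p_fdr", "significant"]
    return pd.DataFrame(rows, columns=cols)
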