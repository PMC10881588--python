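"""Residualized single-mediator analysis with bootstrap inference.

The design mirrors regress-out-first mediation: nuisance covariates (age,
sex, education, intracranial volume — or grey-matter volume in the
validation variant) are first regressed out of the independent variable x
(handgrip strength), the mediator m (a functional-connectivity measure)
and the dependent variable y (a cognitive score); mediation is then run on
the residuals.

Path model (all OLS with intercept, on residuals):

    m ~ x          -> a
    y ~ x + m      -> c' (direct), b
    y ~ x          -> c  (total)

indirect effect = a*b, proportion mediated = a*b / c, and for OLS on one
sample the identity c = c' + a*b holds exactly.  Inference on the indirect
effect uses a subject-level nonparametric bootstrap (percentile CI by
default; bias-corrected-accelerated available), with a two-sided sign-based
bootstrap p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import residualize

#: |c| below this multiple of sd(y)/sd(x) flags the mediated proportion unstable
_PROPORTION_GUARD = 1e-8


@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    proportion_mediated: float   # nan when flagged unstable
    proportion_unstable: bool
    ci_low: float
    ci_high: float
    p_boot: float
    ci_level: float
    n_boot: int
    seed: int
    method: str


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    a = _slope(x, m)
    c = _slope(x, y)
    design = np.column_stack([np.ones_like(x), x, m])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    c_prime, b = float(coef[1]), float(coef[2])
    return a, b, c, c_prime


def mediate(x, m, y, covariates=None, n_boot: int = 5000, seed: int = 0,
            ci_level: float = 0.95, method: str = "percentile") -> MediationResult:
    """Single-mediator analysis of x -> m -> y with covariates regressed out.

    Parameters
    ----------
    x, m, y
        Equal-length vectors: independent variable, mediator, dependent
        variable.
    covariates
        Optional n x k array regressed out of all three variables before the
        path fits (residuals are treated as data, including in the bootstrap).
    n_boot
        Bootstrap resamples (>= 100); the study design used 5000.
    seed
        Mandatory reproducibility seed for the resampling.
    method
        ``"percentile"`` (default) or ``"bca"`` confidence interval for the
        indirect effect.
    """
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must have equal length")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if method not in {"percentile", "bca"}:
        raise ValueError(f"unknown CI method: {method}")
    if covariates is not None:
        x = residualize(x, covariates)
        m = residualize(m, covariates)
        y = residualize(y, covariates)

    a, b, c, c_prime = _paths(x, m, y)
    indirect = a * b
    scale = (np.std(y) / np.std(x)) if np.std(x) > 0 else 1.0
    unstable = abs(c) < _PROPORTION_GUARD * max(scale, 1.0)
    proportion = np.nan if unstable else indirect / c

    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ab, bb, _, _ = _paths(x[idx], m[idx], y[idx])
        boots[i] = ab * bb

    alpha = 1.0 - ci_level
    if method == "percentile":
        lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        lo, hi = _bca_interval(boots, indirect, x, m, y, alpha)
    # two-sided sign-crossing p from the bootstrap distribution
    frac_le = np.mean(boots <= 0.0)
    frac_ge = np.mean(boots >= 0.0)
    p_boot = float(min(1.0, 2.0 * min(frac_le, frac_ge)))

    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, indirect=indirect,
        proportion_mediated=proportion, proportion_unstable=bool(unstable),
        ci_low=float(lo), ci_high=float(hi), p_boot=p_boot,
        ci_level=ci_level, n_boot=n_boot, seed=seed, method=method,
    )


def _bca_interval(boots, theta_hat, x, m, y, alpha):
    """Bias-corrected and accelerated bootstrap CI for the indirect effect."""
    z0 = stats.norm.ppf(np.clip(np.mean(boots < theta_hat), 1e-10, 1 - 1e-10))
    n = len(x)
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        aj, bj, _, _ = _paths(x[mask], m[mask], y[mask])
        jack[i] = aj * bj
        mask[i] = True
    d = jack.mean() - jack
    denom = 6.0 * (np.sum(d ** 2) ** 1.5)
    acc = np.sum(d ** 3) / denom if denom > 0 else 0.0
    out = []
    for q in (alpha / 2, 1 - alpha / 2):
        zq = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + zq) / (1 - acc * (z0 + zq)))
        out.append(np.percentile(boots, 100 * adj))
    return out[0], out[1]
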