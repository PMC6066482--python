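"""Simple (single-mediator) mediation with a bias-corrected bootstrap CI.

The causal chain tested is genotype dosage (x) -> network strength (m) ->
cognition (y), with age and cigarettes/day as covariates in both the
mediator and outcome models:

    m = i1 + a x + covariates
    y = i2 + c' x + b m + covariates
    y = i3 + c x + covariates

The indirect effect is a*b, with the exact OLS identity c = c' + a*b when
the three models share the covariate set.  Its sampling distribution is
bootstrapped by resampling subject rows with replacement; the interval is
the bias-corrected (BC, no acceleration) percentile interval, and mediation
is flagged significant when the interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    level: float
    seed: int | None

    @property
    def significant(self) -> bool:
        """Mediation decision rule: the BC interval excludes zero."""
        return (self.ci_lower > 0) or (self.ci_upper < 0)


def _as_matrix(
    x: pd.Series | np.ndarray,
    m: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not (len(m) == len(y) == n):
        raise ValueError("x, m, y must have equal length")
    C = (
        np.asarray(covariates, dtype=float)
        if covariates is not None and np.size(covariates)
        else np.empty((n, 0))
    )
    if C.shape[0] != n:
        raise ValueError("covariates must align with subjects")
    if np.isnan(x).any() or np.isnan(m).any() or np.isnan(y).any() or np.isnan(C).any():
        raise ValueError("missing values; drop incomplete subjects first")
    return x, m, y, C


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design in mediation model")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_mediation(
    x: pd.Series | np.ndarray,
    m: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float, float, float]:
    """Point estimates (a, b, c, c_prime) from the three OLS fits."""
    x, m, y, C = _as_matrix(x, m, y, covariates)
    n = len(x)
    ones = np.ones((n, 1))
    p_max = 3 + C.shape[1]
    if n <= p_max:
        raise ValueError(f"need n > {p_max} subjects for the outcome model")
    a = _ols(np.hstack([ones, x[:, None], C]), m)[1]
    bo = _ols(np.hstack([ones, x[:, None], m[:, None], C]), y)
    c_prime, b = bo[1], bo[2]
    c = _ols(np.hstack([ones, x[:, None], C]), y)[1]
    return float(a), float(b), float(c), float(c_prime)


def _bootstrap_indirect(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    idx: np.ndarray,
) -> np.ndarray:
    """Indirect effects a*b for each bootstrap index row (vectorized).

    Solves the mediator- and outcome-model normal equations for all
    resamples at once via batched pseudo-inverse; degenerate resamples
    (e.g. a constant dosage column) yield the minimum-norm solution rather
    than an error, which is inconsequential at the tail probabilities BC
    intervals use.
    """
    n = len(x)
    ones = np.ones(n)
    Xm = np.column_stack([ones, x] + [C[:, k] for k in range(C.shape[1])])
    Xy = np.column_stack([ones, x, m] + [C[:, k] for k in range(C.shape[1])])
    Xm_b = Xm[idx]                      # (B, n, pm)
    Xy_b = Xy[idx]                      # (B, n, py)
    m_b = m[idx]                        # (B, n)
    y_b = y[idx]
    XtX_m = np.einsum("bni,bnj->bij", Xm_b, Xm_b)
    Xty_m = np.einsum("bni,bn->bi", Xm_b, m_b)
    XtX_y = np.einsum("bni,bnj->bij", Xy_b, Xy_b)
    Xty_y = np.einsum("bni,bn->bi", Xy_b, y_b)
    beta_m = np.einsum("bij,bj->bi", np.linalg.pinv(XtX_m), Xty_m)
    beta_y = np.einsum("bij,bj->bi", np.linalg.pinv(XtX_y), Xty_y)
    return beta_m[:, 1] * beta_y[:, 2]


def bc_bootstrap_ci(
    x: pd.Series | np.ndarray,
    m: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Bias-corrected bootstrap CI for the indirect effect a*b.

    Subject rows are resampled jointly with replacement.  The bias
    correction shifts the percentile endpoints by z0, the normal quantile
    of the fraction of bootstrap indirects below the full-sample estimate;
    no acceleration term is used.  Returns (lower, upper, bootstrap draws).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x, m, y, C = _as_matrix(x, m, y, covariates)
    a, b, _, _ = fit_mediation(x, m, y, pd.DataFrame(C) if C.size else None)
    point = a * b
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    draws = _bootstrap_indirect(x, m, y, C, idx)
    if np.allclose(draws, draws[0]):
        warnings.warn("all bootstrap indirect effects identical; degenerate interval",
                      stacklevel=2)
        return float(draws[0]), float(draws[0]), draws
    frac = np.mean(draws < point)
    # guard the probit at 0/1 (all draws on one side of the estimate)
    frac = min(max(frac, 1 / (n_boot + 1)), n_boot / (n_boot + 1))
    z0 = norm.ppf(frac)
    alpha = 1 - level
    lo_q = norm.cdf(2 * z0 + norm.ppf(alpha / 2))
    hi_q = norm.cdf(2 * z0 + norm.ppf(1 - alpha / 2))
    lo, hi = np.quantile(draws, [lo_q, hi_q])
    return float(lo), float(hi), draws


def mediate(
    x: pd.Series | np.ndarray,
    m: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> MediationResult:
    """Full mediation analysis: paths, indirect effect and BC bootstrap CI."""
    a, b, c, c_prime = fit_mediation(x, m, y, covariates)
    lo, hi, _ = bc_bootstrap_ci(
        x, m, y, covariates, n_boot=n_boot, level=level, seed=seed
    )
    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, indirect=a * b,
        ci_lower=lo, ci_upper=hi, n_boot=n_boot, level=level, seed=seed,
    )
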