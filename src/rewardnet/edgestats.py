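"""Covariate-adjusted edge-wise group comparison with a permutation null.

For each edge, the group difference in strength is measured by the t
statistic of the group coefficient in ``strength ~ group + age +
cigarettes/day`` (equivalent to a covariate-adjusted two-sample t).  The
null distribution is obtained by permuting group labels while covariates
stay attached to their subjects, recomputing the full-model t each time.
The two-sided permutation p uses the add-one estimator
``(1 + #{|t*| >= |t_obs|}) / (B + 1)`` so p is never zero; family-wise
control is Bonferroni over the 276 edges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

_TIE_EPS = 1e-12  # |t*| >= |t_obs| comparisons tolerate float noise


@dataclass
class EdgeTestResult:
    edge: tuple[str, str]
    t_value: float
    p_perm: float
    significant: bool = False


def _design_checks(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == np.linalg.matrix_rank(X):
                raise ValueError(f"design matrix rank-deficient: column {names[j]!r} is collinear")
        raise ValueError("design matrix rank-deficient")


def _group_indicator(groups: pd.Series, case_label: str) -> np.ndarray:
    levels = set(groups)
    if case_label not in levels:
        raise ValueError(f"case label {case_label!r} not among group labels {sorted(levels)}")
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {sorted(levels)}")
    g = (groups == case_label).to_numpy(dtype=float)
    if g.sum() < 2 or (len(g) - g.sum()) < 2:
        raise ValueError("each group needs at least 2 subjects")
    return g


def adjusted_t(
    strengths: np.ndarray | pd.Series,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    case_label: str = "HA",
) -> float:
    """t of the group coefficient from ``strength ~ group + covariates``.

    Sign convention: positive t means the case group (default HA) has
    higher adjusted strength.  With no covariates this reduces to the
    classical pooled two-sample t.
    """
    y = np.asarray(strengths, dtype=float)
    g = _group_indicator(groups, case_label)
    n = len(y)
    cols = [np.ones(n), g]
    names = ["intercept", "group"]
    if covariates is not None and covariates.shape[1] > 0:
        cols.extend(covariates[c].to_numpy(dtype=float) for c in covariates.columns)
        names.extend(map(str, covariates.columns))
    X = np.column_stack(cols)
    _design_checks(X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - X.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    # exact fit: a zero-residual model has no noise to scale t by
    tol = 1e-12 * max(1.0, float(np.abs(y).max()))
    if se < tol:
        return 0.0 if abs(beta[1]) < tol else float(np.sign(beta[1]) * np.inf)
    return float(beta[1] / se)


def _adjusted_t_batch(
    Y_res: np.ndarray, G_res: np.ndarray, df: int
) -> np.ndarray:
    """t statistics for every (permutation, edge) pair.

    ``Y_res`` (n, E) and ``G_res`` (B, n) are strength columns and group
    indicators residualized on the covariate design; by Frisch-Waugh the
    full-model group t equals the t from regressing the residualized
    strength on the residualized indicator, with the full model's df.
    """
    gnorm2 = np.einsum("bn,bn->b", G_res, G_res)  # (B,)
    ok = gnorm2 > 0
    num = G_res @ Y_res  # (B, E)
    ynorm2 = np.einsum("ne,ne->e", Y_res, Y_res)  # (E,)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / gnorm2[:, None]
        rss = ynorm2[None, :] - beta**2 * gnorm2[:, None]
        rss = np.maximum(rss, 0.0)
        t = beta / np.sqrt(rss / df / gnorm2[:, None])
    t[~ok, :] = np.nan
    # zero residual variance with nonzero beta -> +-inf; with zero beta -> 0
    t = np.where((rss == 0) & (beta == 0), 0.0, t)
    return t


def permutation_test(
    strengths: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
    case_label: str = "HA",
    threshold: float | None = None,
    exhaustive: bool = False,
) -> list[EdgeTestResult]:
    """Permutation p-values for every edge column of ``strengths``.

    ``strengths`` is a subjects x edges DataFrame (columns are edge labels);
    ``groups`` and ``covariates`` are aligned on the same subjects.  Label
    permutations are sampled with replacement from the assignment space,
    except in ``exhaustive`` mode where all distinct case/control
    assignments are enumerated and the exact p is returned.
    """
    if not exhaustive and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if list(strengths.columns) != list(dict.fromkeys(strengths.columns)):
        raise ValueError("duplicate edge columns in strengths table")
    groups = groups.loc[strengths.index]
    g_obs = _group_indicator(groups, case_label)
    n = len(g_obs)
    Y = strengths.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("NaN strengths present; drop or impute undefined edges first")

    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None and covariates.shape[1] > 0:
        covariates = covariates.loc[strengths.index]
        cols.extend(covariates[c].to_numpy(dtype=float) for c in covariates.columns)
        names.extend(map(str, covariates.columns))
    C = np.column_stack(cols)
    _design_checks(np.column_stack([C, g_obs]), names + ["group"])
    df = n - (C.shape[1] + 1)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")

    # project covariates (incl. intercept) out of strengths and labels
    coefY, *_ = np.linalg.lstsq(C, Y, rcond=None)
    Y_res = Y - C @ coefY

    if exhaustive:
        n_case = int(g_obs.sum())
        assignments = itertools.combinations(range(n), n_case)
        G = np.zeros((0, n))
        rows = []
        for comb in assignments:
            row = np.zeros(n)
            row[list(comb)] = 1.0
            rows.append(row)
        G = np.array(rows)
    else:
        rng = np.random.default_rng(seed)
        G = rng.permuted(np.tile(g_obs, (n_permutations, 1)), axis=1)

    coefG, *_ = np.linalg.lstsq(C, np.vstack([g_obs, G]).T, rcond=None)
    GR = np.vstack([g_obs, G]) - (C @ coefG).T
    t_all = _adjusted_t_batch(Y_res, GR, df)
    t_obs, t_perm = t_all[0], t_all[1:]

    abs_obs = np.abs(t_obs)
    exceed = (np.abs(t_perm) >= abs_obs[None, :] - _TIE_EPS).sum(axis=0)
    B = t_perm.shape[0]
    if exhaustive:
        # observed assignment is in the enumeration: exact p
        p = exceed / B
    else:
        p = (1 + exceed) / (B + 1)

    results = []
    for k, col in enumerate(strengths.columns):
        edge = col if isinstance(col, tuple) else tuple(col.split("--"))
        res = EdgeTestResult(edge=edge, t_value=float(t_obs[k]), p_perm=float(p[k]))
        if threshold is not None:
            res.significant = res.p_perm < threshold
        results.append(res)
    return results


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha / m controlling family-wise error."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def diff_connections(
    results: list[EdgeTestResult], threshold: float
) -> list[tuple[str, str]]:
    """Edges significant at the corrected threshold, strongest first.

    Ordered by |t| descending; ties broken lexicographically by edge label.
    """
    seen = set()
    for r in results:
        if r.edge in seen:
            raise ValueError(f"duplicate edge {r.edge} in results")
        seen.add(r.edge)
    hits = [r for r in results if r.p_perm < threshold]
    hits.sort(key=lambda r: (-abs(r.t_value), r.edge))
    return [r.edge for r in hits]
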