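"""Chained-equations multiple imputation and Rubin pooling.

Only ~31% of the cohort has primary-care outcomes, so QALYs/year and
primary (hence total) costs/year are imputed by chained equations:
each incomplete variable is regressed on the auxiliary predictors and
the other targets, coefficients and the residual scale are drawn from
their posterior, and missing values are filled either by predictive
mean matching (PMM, the default — robust to the right-skew of costs)
or by normal draws.  Estimates from the m completed datasets are
combined with Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mr import CausalEstimate

DEFAULT_PREDICTORS = ["age", "sex", "bmi", "prs"]


@dataclass
class ImputationSpec:
    m: int = 100  # number of imputed datasets
    predictors: tuple = tuple(DEFAULT_PREDICTORS)
    iterations: int = 10
    method: str = "pmm"  # or "norm"
    k_pmm: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if self.method not in {"pmm", "norm"}:
            raise ValueError("method must be 'pmm' or 'norm'")


def _posterior_draw_fit(X: np.ndarray, y: np.ndarray, rng) -> tuple[np.ndarray, float, np.ndarray]:
    """Bayesian-linear-regression posterior draw of (beta, sigma)."""
    n, p = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = (resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    L = np.linalg.cholesky(XtX_inv * sigma2 + 1e-12 * np.eye(p))
    beta = beta_hat + L @ rng.standard_normal(p)
    return beta, float(np.sqrt(sigma2)), beta_hat


def _impute_one(df: pd.DataFrame, targets, predictors, spec: ImputationSpec, rng) -> pd.DataFrame:
    out = df.copy()
    miss = {t: df[t].isna().to_numpy() for t in targets}
    # initial fill: random draws from the observed margins
    for t in targets:
        obs = df.loc[~miss[t], t].to_numpy()
        out.loc[miss[t], t] = rng.choice(obs, size=miss[t].sum(), replace=True)
    for _ in range(spec.iterations):
        for t in targets:
            others = [u for u in targets if u != t]
            cols = list(predictors) + others
            X = np.column_stack([np.ones(len(out))] + [out[c].to_numpy(float) for c in cols])
            y = out[t].to_numpy(float)
            obs_mask = ~miss[t]
            beta, sigma, beta_hat = _posterior_draw_fit(X[obs_mask], y[obs_mask], rng)
            pred_mis = X[miss[t]] @ beta
            if spec.method == "norm":
                out.loc[miss[t], t] = pred_mis + rng.standard_normal(miss[t].sum()) * sigma
            else:  # predictive mean matching against observed fitted values
                pred_obs = X[obs_mask] @ beta_hat
                y_obs = y[obs_mask]
                order = np.argsort(pred_obs)
                sorted_pred = pred_obs[order]
                pos = np.searchsorted(sorted_pred, pred_mis)
                # donor = one of the k nearest observed fitted values,
                # vectorised as a random offset around the insertion point
                k = spec.k_pmm
                offsets = rng.integers(-k, k + 1, size=len(pred_mis))
                idx = np.clip(pos + offsets, 0, len(sorted_pred) - 1)
                out.loc[miss[t], t] = y_obs[order[idx]]
    return out


def chained_impute(data: pd.DataFrame, targets, spec: ImputationSpec) -> list[pd.DataFrame]:
    """m completed copies of ``data`` with the target columns imputed.

    Predictors must be complete; targets may be partially missing (an
    all-missing target is an error).  With no missing values the output
    equals the input for every imputation.  Fully deterministic under
    ``spec.seed``.
    """
    targets = list(targets)
    for t in targets:
        if data[t].isna().all():
            raise ValueError(f"column {t!r} is entirely missing; cannot impute")
    for c in spec.predictors:
        if data[c].isna().any():
            raise ValueError(f"predictor {c!r} has missing values")
    completed = []
    for i in range(spec.m):
        rng = np.random.default_rng([spec.seed, i])
        if not any(data[t].isna().any() for t in targets):
            completed.append(data.copy())
            continue
        completed.append(_impute_one(data, targets, spec.predictors, spec, rng))
    return completed


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of per-imputation estimates."""

    beta: float
    se: float
    m: int
    within_var: float
    between_var: float
    median_p: float  # across-imputation median p, reported alongside
    outcome: str = ""
    method: str = "2SLS (Rubin-pooled)"
    df: float = np.inf

    @property
    def ci95(self) -> tuple[float, float]:
        crit = stats.t.ppf(0.975, self.df) if np.isfinite(self.df) else 1.96
        return (self.beta - crit * self.se, self.beta + crit * self.se)

    @property
    def p(self) -> float:
        t = self.beta / self.se
        if np.isfinite(self.df):
            return float(2 * stats.t.sf(abs(t), self.df))
        return float(2 * stats.norm.sf(abs(t)))


def pool_rubin(estimates: list[CausalEstimate]) -> PooledEstimate:
    """Rubin's rules: pooled point = mean; total variance = W + (1+1/m)B.

    Also reports the across-imputation median p value (used for the
    endogeneity tests, where a pooled chi-square is not well defined).
    """
    if len(estimates) < 2:
        raise ValueError("pooling requires at least 2 estimates")
    outcomes = {e.outcome for e in estimates}
    if len(outcomes) > 1:
        raise ValueError(f"inconsistent outcomes across imputations: {sorted(outcomes)}")
    m = len(estimates)
    betas = np.array([e.beta for e in estimates])
    within = float(np.mean([e.se**2 for e in estimates]))
    between = float(np.var(betas, ddof=1))
    total = within + (1 + 1 / m) * between
    # Barnard-Rubin small-sample degrees of freedom
    if between > 0:
        r = (1 + 1 / m) * between / within
        df = (m - 1) * (1 + 1 / r) ** 2
    else:
        df = np.inf
    return PooledEstimate(
        beta=float(betas.mean()),
        se=float(np.sqrt(total)),
        m=m,
        within_var=within,
        between_var=between,
        median_p=float(np.median([e.p for e in estimates])),
        outcome=estimates[0].outcome,
        df=df,
    )


def pool_p_values(ps) -> dict:
    """Median p across imputations (plus the mean, labelled)."""
    ps = np.asarray(list(ps), float)
    return {"median_p": float(np.median(ps)), "mean_p": float(np.mean(ps))}
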