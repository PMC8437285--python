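"""Individual-level causal estimation with a polygenic-score instrument.

Two-stage least squares under an additive structural mean model gives
the mean change in each outcome per +1 kg/m^2 of BMI; a multivariable
OLS comparator, the first-stage F statistic and endogeneity (Hausman)
tests complete the main analysis.  Standard errors are
heteroskedasticity-robust (HC1 sandwich) throughout, matching the
econometric default of the standard IV software.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_COVARIATES = ["age", "sex"] + [f"pc{k}" for k in range(1, 41)]


@dataclass(frozen=True)
class RegressionSpec:
    """What to regress on what.

    The instrument appears only in the first stage; covariates are
    identical across stages.  Categorical covariates (recruitment
    centre) enter as one-hot indicators with the first level dropped.
    """

    outcome: str
    exposure: str = "bmi"
    instrument: str = "prs"
    covariates: tuple = tuple(DEFAULT_COVARIATES)
    categorical: tuple = ("centre",)

    def with_outcome(self, outcome: str) -> "RegressionSpec":
        return replace(self, outcome=outcome)


@dataclass
class CausalEstimate:
    """Effect of +1 kg/m^2 BMI on an outcome, with robust inference."""

    beta: float
    se: float
    n: int
    method: str
    outcome: str = ""
    first_stage_F: float | None = None
    df: dict = field(default_factory=dict)

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    @property
    def p(self) -> float:
        if self.se == 0:
            return 0.0 if self.beta != 0 else 1.0
        return float(2 * stats.norm.sf(abs(self.beta / self.se)))

    @property
    def beta_pct(self) -> float:
        """Percentage-of-a-QALY twin: 100 x the raw coefficient."""
        return 100.0 * self.beta

    @property
    def se_pct(self) -> float:
        return 100.0 * self.se

    def to_row(self) -> dict:
        lo, hi = self.ci95
        return {
            "method": self.method,
            "outcome": self.outcome,
            "beta": self.beta,
            "se": self.se,
            "ci_lo": lo,
            "ci_hi": hi,
            "p": self.p,
            "n": self.n,
            "first_stage_F": self.first_stage_F,
        }


def design_matrices(data: pd.DataFrame, spec: RegressionSpec):
    """Listwise-complete y, exposure, instrument and covariate matrix.

    Returns (y, x, z, C, names) with C including an intercept and
    one-hot centre indicators (first level dropped).  Raises on
    collinear covariate columns, naming them.
    """
    cols = [spec.outcome, spec.exposure, spec.instrument]
    cols += [c for c in spec.covariates if c in data.columns]
    cols += [c for c in spec.categorical if c in data.columns]
    sub = data[cols].dropna()
    y = sub[spec.outcome].to_numpy(float)
    x = sub[spec.exposure].to_numpy(float)
    z = sub[spec.instrument].to_numpy(float)
    blocks = [np.ones((len(sub), 1))]
    names = ["const"]
    for c in spec.covariates:
        if c in sub.columns:
            blocks.append(sub[c].to_numpy(float)[:, None])
            names.append(c)
    for c in spec.categorical:
        if c in sub.columns:
            dummies = pd.get_dummies(sub[c], prefix=c, drop_first=True)
            blocks.append(dummies.to_numpy(float))
            names.extend(dummies.columns.tolist())
    C = np.hstack(blocks)
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # name offending columns: those whose removal restores full rank
        bad = []
        for j in range(C.shape[1]):
            keep = [k for k in range(C.shape[1]) if k != j]
            if np.linalg.matrix_rank(C[:, keep]) == rank:
                bad.append(names[j])
        raise ValueError(f"collinear covariate columns: {bad}")
    if np.var(z) == 0:
        raise ValueError("instrument has zero variance")
    return y, x, z, C, names


def _hc1(bread: np.ndarray, score: np.ndarray, n: int, k: int) -> np.ndarray:
    meat = score.T @ score
    return bread @ meat @ bread.T * (n / (n - k))


def two_stage_least_squares(data: pd.DataFrame, spec: RegressionSpec) -> CausalEstimate:
    """Just-identified IV estimate with HC1 sandwich standard errors.

    Solves (Z'W) b = Z'y with W = [exposure, covariates] and
    Z = [instrument, covariates]; the sandwich uses the structural
    residuals y - W b.
    """
    y, x, z, C, _ = design_matrices(data, spec)
    n = len(y)
    W = np.column_stack([x, C])
    Z = np.column_stack([z, C])
    k = W.shape[1]
    if n <= k + 1:
        raise ValueError("too few rows for the requested specification")
    ZtW = Z.T @ W
    b = np.linalg.solve(ZtW, Z.T @ y)
    resid = y - W @ b
    bread = np.linalg.inv(ZtW)
    V = _hc1(bread, Z * resid[:, None], n, k)
    F = first_stage_F(data, spec)
    return CausalEstimate(
        beta=float(b[0]), se=float(np.sqrt(V[0, 0])), n=n, method="2SLS",
        outcome=spec.outcome, first_stage_F=F,
    )


def first_stage_F(data: pd.DataFrame, spec: RegressionSpec) -> float:
    """Robust F for the instrument in the first-stage regression.

    With a single instrument this is the squared HC1 t statistic of the
    instrument coefficient in exposure ~ instrument + covariates.
    """
    _, x, z, C, _ = design_matrices(data, spec)
    fit = sm.OLS(x, np.column_stack([z, C])).fit(cov_type="HC1")
    return float(fit.tvalues[0] ** 2)


def ols_comparator(data: pd.DataFrame, spec: RegressionSpec) -> CausalEstimate:
    """Conventional multivariable linear regression, exposure entered directly."""
    y, x, _, C, _ = design_matrices(data, spec)
    fit = sm.OLS(y, np.column_stack([x, C])).fit(cov_type="HC1")
    return CausalEstimate(
        beta=float(fit.params[0]), se=float(fit.bse[0]), n=len(y), method="OLS",
        outcome=spec.outcome,
    )


@dataclass
class HausmanResult:
    statistic: float
    p: float
    form: str  # "regression" or "classic"
    fallback: bool = False  # classic form degenerated, regression used


def hausman_endogeneity(data: pd.DataFrame, spec: RegressionSpec, form: str = "regression") -> HausmanResult:
    """Endogeneity test contrasting the IV and OLS estimates.

    ``regression`` (default): control-function form — the first-stage
    residual is added to the OLS outcome model and its robust squared t
    is referred to chi-square(1).  ``classic``: the Hausman contrast
    (b_IV - b_OLS)^2 / (V_IV - V_OLS); if the variance difference is not
    positive, falls back to the regression form with a flag.
    """
    y, x, z, C, _ = design_matrices(data, spec)
    if form == "classic":
        iv = two_stage_least_squares(data, spec)
        ols = ols_comparator(data, spec)
        dv = iv.se**2 - ols.se**2
        if dv > 0:
            stat = (iv.beta - ols.beta) ** 2 / dv
            return HausmanResult(float(stat), float(stats.chi2.sf(stat, 1)), "classic")
        res = hausman_endogeneity(data, spec, form="regression")
        return HausmanResult(res.statistic, res.p, "regression", fallback=True)
    if form != "regression":
        raise ValueError("form must be 'regression' or 'classic'")
    Zm = np.column_stack([z, C])
    v = x - Zm @ np.linalg.lstsq(Zm, x, rcond=None)[0]
    if np.var(v) < 1e-12 * max(np.var(x), 1.0):
        # perfect instrument: no endogenous variation left to test
        return HausmanResult(0.0, 1.0, "regression")
    fit = sm.OLS(y, np.column_stack([x, C, v])).fit(cov_type="HC1")
    t = fit.tvalues[-1]
    stat = float(t**2)
    return HausmanResult(stat, float(stats.chi2.sf(stat, 1)), "regression")


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Serialise a collection of CausalEstimates as a tidy table."""
    return pd.DataFrame([e.to_row() for e in estimates])
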