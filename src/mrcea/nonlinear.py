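"""Stratified and nonlinear MR: the dose-response curve over BMI.

The whole-sample IV estimate averages over the BMI range.  To expose
nonlinearity, the cohort is stratified on "PRS-free BMI" (the residual
of BMI on the instrument and covariates, which cannot induce collider
bias because it is independent of the instrument by construction), the
IV analysis is repeated within each stratum — localised average causal
effects (LACE) — and a variance-weighted cubic in the stratum mean BMI
is fitted through the stratum estimates.  Age-band and WHO BMI-category
stratifications reuse the same machinery; the fitted curve is what the
policy engine integrates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mr import CausalEstimate, RegressionSpec, design_matrices, two_stage_least_squares

AGE_BANDS = ((40, 50, "40-49"), (50, 55, "50-54"), (55, 60, "55-59"), (60, 65, "60-64"), (65, 200, "65+"))
WHO_BMI_BANDS = ((0.0, 25.0, "normal"), (25.0, 30.0, "overweight"), (30.0, 100.0, "obese"))


@dataclass
class StratumEstimate:
    label: str
    n: int
    mean_bmi: float
    estimate: CausalEstimate
    lo: float | None = None  # stratifying-variable bounds, where defined
    hi: float | None = None


def prs_free_bmi(data: pd.DataFrame, spec: RegressionSpec) -> pd.Series:
    """Residual BMI after removing the instrument and covariates.

    OLS residual of exposure on instrument + covariates; orthogonal to
    the instrument by construction, hence safe for stratification.
    """
    _, x, z, C, _ = design_matrices(data, spec)
    Zm = np.column_stack([z, C])
    resid = x - Zm @ np.linalg.lstsq(Zm, x, rcond=None)[0]
    sub = data[[spec.outcome, spec.exposure, spec.instrument]
               + [c for c in spec.covariates if c in data.columns]
               + [c for c in spec.categorical if c in data.columns]].dropna()
    return pd.Series(resid, index=sub.index, name="prs_free_bmi")


def quantile_lace(
    data: pd.DataFrame, spec: RegressionSpec, n_quantiles: int = 10, min_stratum: int = 500
) -> list[StratumEstimate]:
    """2SLS within each quantile of PRS-free BMI (LACE estimates)."""
    if n_quantiles < 1:
        raise ValueError("n_quantiles must be >= 1")
    resid = prs_free_bmi(data, spec)
    sub = data.loc[resid.index]
    if n_quantiles == 1:
        est = two_stage_least_squares(sub, spec)
        return [StratumEstimate("all", est.n, float(sub[spec.exposure].mean()), est)]
    bins = pd.qcut(resid, n_quantiles, labels=False, duplicates="drop")
    out = []
    for q in range(int(bins.max()) + 1):
        rows = sub[bins == q]
        if len(rows) == 0:
            raise ValueError(f"empty stratum {q}")
        if len(rows) < min_stratum:
            raise ValueError(f"stratum {q} has {len(rows)} < {min_stratum} individuals")
        est = two_stage_least_squares(rows, spec)
        out.append(
            StratumEstimate(
                label=f"q{q + 1}", n=len(rows), mean_bmi=float(rows[spec.exposure].mean()), estimate=est
            )
        )
    return out


def stratified_estimates(data: pd.DataFrame, spec: RegressionSpec, by: str = "age") -> list[StratumEstimate]:
    """Main-analysis 2SLS repeated within age bands or WHO BMI categories."""
    bands = AGE_BANDS if by == "age" else WHO_BMI_BANDS if by == "bmi" else None
    if bands is None:
        raise ValueError("by must be 'age' or 'bmi'")
    var = "age" if by == "age" else spec.exposure
    out = []
    for i, (lo, hi, label) in enumerate(bands):
        lo_eff = -np.inf if i == 0 else lo  # youngest/leanest band absorbs the tail
        rows = data[(data[var] >= lo_eff) & (data[var] < hi)]
        if len(rows) == 0:
            continue
        est = two_stage_least_squares(rows, spec)
        out.append(
            StratumEstimate(label=label, n=len(rows), mean_bmi=float(rows[spec.exposure].mean()),
                            estimate=est, lo=lo, hi=hi)
        )
    return out


def strata_heterogeneity(strata: list[StratumEstimate]) -> tuple[float, int, float]:
    """Cochran-style Q across stratum estimates (null: common effect)."""
    betas = np.array([s.estimate.beta for s in strata])
    ws = np.array([1.0 / s.estimate.se**2 for s in strata])
    pooled = float((ws * betas).sum() / ws.sum())
    q = float((ws * (betas - pooled) ** 2).sum())
    df = len(strata) - 1
    return q, df, float(stats.chi2.sf(q, df))


@dataclass
class DoseResponseCurve:
    """Effect of +1 kg/m^2 as a function of BMI.

    Holds both a piecewise-constant representation (one effect per
    stratum, with its BMI support) and a smooth variance-weighted
    polynomial (cubic by default) in the stratum mean BMI, with the
    coefficient covariance of the weighted fit.
    """

    coefs: np.ndarray  # polynomial coefficients, ascending powers
    cov: np.ndarray
    pieces: pd.DataFrame  # columns: lo, hi, mean_bmi, beta, se
    domain: tuple[float, float] = (18.5, 45.0)
    degraded: bool = False  # degree reduced for lack of strata

    @property
    def degree(self) -> int:
        return len(self.coefs) - 1

    def _piece_arrays(self):
        # cached numpy view of the sorted pieces (hot path in MC loops)
        cache = self.__dict__.get("_pieces_np")
        if cache is None:
            srt = self.pieces.sort_values("lo")
            cache = (
                srt["lo"].to_numpy(float),
                srt["hi"].to_numpy(float),
                srt["beta"].to_numpy(float),
            )
            self.__dict__["_pieces_np"] = cache
        return cache

    def effect(self, bmi, form: str = "smooth") -> np.ndarray:
        """Per-unit effect at the given BMI value(s)."""
        b = np.atleast_1d(np.asarray(bmi, float))
        if ((b < self.domain[0]) | (b > self.domain[1])).any():
            raise ValueError(f"BMI outside curve domain {self.domain}")
        if form == "smooth":
            out = np.polynomial.polynomial.polyval(b, self.coefs)
        elif form == "piecewise":
            lo, hi, beta = self._piece_arrays()
            idx = np.clip(np.searchsorted(lo, b, side="right") - 1, 0, len(lo) - 1)
            out = beta[idx]
        else:
            raise ValueError("form must be 'smooth' or 'piecewise'")
        return out if np.ndim(bmi) else float(out[0])

    def integrate_effect(self, b0: float, b1: float, form: str = "smooth", extend: bool = False) -> float:
        """Exact integral of the effect from b0 to b1 (signed).

        Outside the curve domain the integral is an error unless
        ``extend`` is set, in which case the effect is extended as a
        constant at its boundary value (polynomials are not trusted to
        extrapolate).
        """
        return float(self.integrate_effect_many(b0, b1, form=form, extend=extend))

    def integrate_effect_many(self, b0, b1, form: str = "smooth", extend: bool = False) -> np.ndarray:
        """Vectorised :meth:`integrate_effect` over arrays of endpoints."""
        b0 = np.asarray(b0, float)
        b1 = np.asarray(b1, float)
        lo = np.minimum(b0, b1)
        hi = np.maximum(b0, b1)
        d_lo, d_hi = self.domain
        if not extend and ((lo < d_lo) | (hi > d_hi)).any():
            raise ValueError(f"integration range outside curve domain {self.domain}")
        in_lo = np.clip(lo, d_lo, d_hi)
        in_hi = np.clip(hi, d_lo, d_hi)
        if form == "smooth":
            anti = np.polynomial.polynomial.polyint(self.coefs)
            inner = np.polynomial.polynomial.polyval(in_hi, anti) - np.polynomial.polynomial.polyval(in_lo, anti)
        elif form == "piecewise":
            plo, phi, beta = self._piece_arrays()
            seg = np.clip(
                np.minimum(in_hi[..., None], phi) - np.maximum(in_lo[..., None], plo), 0.0, None
            )
            inner = seg @ beta
        else:
            raise ValueError("form must be 'smooth' or 'piecewise'")
        total = inner
        if extend:
            total = total + np.clip(d_lo - lo, 0.0, None) * self.effect(d_lo, form=form)
            total = total + np.clip(hi - d_hi, 0.0, None) * self.effect(d_hi, form=form)
        return np.where(b1 >= b0, total, -total)

    def se_effect(self, bmi) -> np.ndarray:
        """Pointwise SE of the smooth curve from the coefficient covariance."""
        b = np.atleast_1d(np.asarray(bmi, float))
        X = np.vander(b, N=len(self.coefs), increasing=True)
        var = np.einsum("ij,jk,ik->i", X, self.cov, X)
        out = np.sqrt(var)
        return out if np.ndim(bmi) else float(out[0])


def fit_dose_response(strata: list[StratumEstimate], degree: int = 3) -> DoseResponseCurve:
    """Variance-weighted polynomial through the stratum estimates.

    Cubic by default ("cubic variance-weighted least squares"); with
    fewer than degree+1 strata the degree drops with a flag.  Weights
    are 1/se^2 and the coefficient covariance is (X'WX)^-1, the
    fixed-effect meta-regression convention.
    """
    if len(strata) < 2:
        raise ValueError("need at least 2 strata to fit a curve")
    degraded = False
    if len(strata) < degree + 1:
        warnings.warn(f"only {len(strata)} strata: reducing polynomial degree")
        degree = len(strata) - 1
        degraded = True
    x = np.array([s.mean_bmi for s in strata])
    y = np.array([s.estimate.beta for s in strata])
    w = np.array([1.0 / s.estimate.se**2 for s in strata])
    X = np.vander(x, N=degree + 1, increasing=True)
    XtWX = X.T @ (X * w[:, None])
    coefs = np.linalg.solve(XtWX, X.T @ (w * y))
    cov = np.linalg.inv(XtWX)

    # piecewise support: stratum boundaries from midpoints between sorted means
    order = np.argsort(x)
    mids = (x[order][:-1] + x[order][1:]) / 2
    lo = np.concatenate([[min(18.5, x.min() - 1)], mids])
    hi = np.concatenate([mids, [max(45.0, x.max() + 1)]])
    pieces = pd.DataFrame(
        {
            "lo": lo,
            "hi": hi,
            "mean_bmi": x[order],
            "beta": y[order],
            "se": np.array([s.estimate.se for s in strata])[order],
            "label": np.array([s.label for s in strata], dtype=object)[order],
        }
    )
    domain = (float(min(18.5, x.min() - 1)), float(max(45.0, x.max() + 1)))
    return DoseResponseCurve(coefs=coefs, cov=cov, pieces=pieces, domain=domain, degraded=degraded)


def limited_condition_variant(cohort, restricted_ids, spec: RegressionSpec | None = None) -> CausalEstimate:
    """Main QALY estimate with outcomes rebuilt from a restricted catalogue.

    Mirrors decision-analytic practice of modelling only cancer,
    cardiovascular disease, cerebrovascular disease and type 2
    diabetes: the QALY outcome is re-predicted using only the
    restricted conditions and the identical 2SLS specification re-run.
    """
    from .outcomes import cohort_annual_qalys, compute_prs

    if cohort.ledgers is None or cohort.catalogue is None:
        raise ValueError("cohort must carry ledger outcomes and a catalogue")
    restricted = cohort.catalogue.restrict(restricted_ids)
    events = cohort.ledgers.condition_events
    events = events[events["condition"].isin(restricted.condition_ids)]
    qaly = cohort_annual_qalys(cohort.people, events, restricted)
    data = cohort.people.copy()
    data["prs"] = compute_prs(cohort.dosages, cohort.config.weight_table(), cohort.snp_ids)
    data["qalys_per_year"] = qaly
    if spec is None:
        spec = RegressionSpec(outcome="qalys_per_year")
    return two_stage_least_squares(data, spec)


def qaly_prediction_uncertainty(cohort, spec: RegressionSpec | None = None, B: int = 100, seed: int = 0) -> CausalEstimate:
    """Propagate catalogue prediction uncertainty into the QALY estimate.

    Re-draws each condition decrement from N(decrement, se) B times,
    rebuilds the QALY outcome and re-estimates; the reported variance is
    the within-draw mean plus (1 + 1/B) times the between-draw variance
    (Rubin-style pooling over prediction draws).
    """
    from .outcomes import UtilityCatalogue, cohort_annual_qalys, compute_prs

    if cohort.ledgers is None or cohort.catalogue is None:
        raise ValueError("cohort must carry ledger outcomes and a catalogue")
    cat = cohort.catalogue
    if cat.decrement_ses is None:
        raise ValueError("catalogue has no decrement SEs")
    if spec is None:
        spec = RegressionSpec(outcome="qalys_per_year")
    rng = np.random.default_rng(seed)
    data = cohort.people.copy()
    data["prs"] = compute_prs(cohort.dosages, cohort.config.weight_table(), cohort.snp_ids)
    betas, variances = [], []
    for _ in range(B):
        dec = np.clip(rng.normal(cat.decrements, cat.decrement_ses), 0.0, None)
        drawn = UtilityCatalogue(
            decrements=pd.Series(dec, index=cat.decrements.index),
            intercept=cat.intercept, age_coef=cat.age_coef, sex_coef=cat.sex_coef, floor=cat.floor,
        )
        data["qalys_per_year"] = cohort_annual_qalys(
            cohort.people, cohort.ledgers.condition_events, drawn, strict=False
        )
        est = two_stage_least_squares(data, spec)
        betas.append(est.beta)
        variances.append(est.se**2)
    beta = float(np.mean(betas))
    total_var = float(np.mean(variances) + (1 + 1 / B) * np.var(betas, ddof=1))
    return CausalEstimate(beta=beta, se=np.sqrt(total_var), n=est.n, method="2SLS+pred-uncertainty",
                          outcome=spec.outcome)
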