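"""Summary-statistic MR sensitivity estimators.

Operates on per-SNP association summaries (beta on exposure, beta on
outcome, with SEs) and implements the standard robust-estimator panel:
inverse-variance weighted (IVW), MR-Egger, weighted median, simple and
weighted mode, plus Cochran's Q heterogeneity.  Two-sample formulas are
applied to one-sample summaries and ratio SEs use the no-measurement-
error (NOME) first-order approximation, as is conventional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mr import CausalEstimate, RegressionSpec


@dataclass(frozen=True)
class SummarySet:
    """Per-SNP exposure and outcome associations.

    ``harmonised`` records that effect alleles were already oriented to
    the exposure-increasing direction by the external weight table, in
    which case Egger must not re-flip on the (noisy) measured signs —
    doing so silently negates the direct effects of weak SNPs.
    """

    table: pd.DataFrame  # columns: snp, beta_exp, se_exp, beta_out, se_out
    harmonised: bool = False

    def __post_init__(self) -> None:
        req = {"snp", "beta_exp", "se_exp", "beta_out", "se_out"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"summary table missing columns: {sorted(missing)}")
        if (self.table[["se_exp", "se_out"]] <= 0).any().any():
            raise ValueError("summary SEs must be positive")

    def __len__(self) -> int:
        return len(self.table)

    def oriented(self) -> "SummarySet":
        """Flip SNPs so every exposure beta is positive (Egger requirement).

        A no-op for harmonised sets: their orientation is fixed by the
        external weight table, not by the in-sample estimates.
        """
        if self.harmonised:
            return self
        t = self.table.copy()
        flip = t["beta_exp"] < 0
        t.loc[flip, ["beta_exp", "beta_out"]] *= -1
        return SummarySet(t, harmonised=True)

    @property
    def ratios(self) -> np.ndarray:
        return (self.table["beta_out"] / self.table["beta_exp"]).to_numpy()

    @property
    def ratio_ses(self) -> np.ndarray:
        # NOME / first-order delta approximation
        return (self.table["se_out"] / self.table["beta_exp"].abs()).to_numpy()


def per_snp_summaries(data: pd.DataFrame, dosages, snp_ids, spec: RegressionSpec) -> SummarySet:
    """Covariate-adjusted per-SNP regressions of exposure and outcome.

    Each SNP is regressed separately (standard summary-MR input).  The
    covariate projection is shared across SNPs, so the whole set costs
    one QR plus vectorised per-SNP slopes.  Monomorphic SNPs are
    excluded with a warning.
    """
    dosages = np.asarray(dosages, float)
    cols = [spec.outcome, spec.exposure] + [c for c in spec.covariates if c in data.columns]
    cols += [c for c in spec.categorical if c in data.columns]
    sub = data[cols].dropna()
    keep = data.index.get_indexer(sub.index)
    G = dosages[keep]
    blocks = [np.ones((len(sub), 1))]
    for c in spec.covariates:
        if c in sub.columns:
            blocks.append(sub[c].to_numpy(float)[:, None])
    for c in spec.categorical:
        if c in sub.columns:
            blocks.append(pd.get_dummies(sub[c], prefix=c, drop_first=True).to_numpy(float))
    C = np.hstack(blocks)
    p = C.shape[1]
    n = len(sub)

    Q, _ = np.linalg.qr(C)

    def residualise(M):
        return M - Q @ (Q.T @ M)

    x_t = residualise(sub[spec.exposure].to_numpy(float))
    y_t = residualise(sub[spec.outcome].to_numpy(float))
    G_t = residualise(G)

    gg = np.einsum("ij,ij->j", G_t, G_t)
    mono = gg <= 1e-12
    if mono.any():
        bad = [snp_ids[j] for j in np.where(mono)[0]]
        warnings.warn(f"excluding monomorphic SNPs: {bad}")
    ok = ~mono
    gg = gg[ok]
    G_t = G_t[:, ok]
    ids = [s for s, m in zip(snp_ids, ok) if m]

    def slopes(v):
        gv = G_t.T @ v
        b = gv / gg
        rss = v @ v - b**2 * gg
        sigma2 = rss / (n - p - 1)
        return b, np.sqrt(sigma2 / gg)

    bx, sx = slopes(x_t)
    by, sy = slopes(y_t)
    # dosages count the effect allele of the weight table, so the set is
    # orientation-harmonised by construction
    return SummarySet(
        pd.DataFrame({"snp": ids, "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy}),
        harmonised=True,
    )


def ivw_estimate(s: SummarySet) -> CausalEstimate:
    """Inverse-variance-weighted slope through the origin.

    Weighted regression of outcome betas on exposure betas with weights
    1/se_out^2; the SE uses a multiplicative random-effects scale
    max(1, sqrt(Q/(L-1))) to absorb overdispersion.
    """
    t = s.table
    w = 1.0 / t["se_out"] ** 2
    sxx = float((w * t["beta_exp"] ** 2).sum())
    beta = float((w * t["beta_exp"] * t["beta_out"]).sum()) / sxx
    se_fixed = np.sqrt(1.0 / sxx)
    L = len(t)
    phi = 1.0
    if L > 1:
        q, _, _ = cochran_q(s, beta)
        phi = max(1.0, np.sqrt(q / (L - 1)))
    return CausalEstimate(beta=beta, se=float(se_fixed * phi), n=L, method="IVW")


@dataclass
class EggerResult:
    slope: CausalEstimate
    intercept: float
    intercept_se: float

    @property
    def intercept_p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.intercept / self.intercept_se)))


def egger_estimate(s: SummarySet) -> EggerResult:
    """MR-Egger: weighted regression with a free (pleiotropy) intercept.

    Exposure betas are orientation-flipped positive first.  The
    intercept estimates the average directional pleiotropic effect per
    SNP; a low intercept p indicates directional pleiotropy.
    """
    if len(s) < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    t = s.oriented().table
    w = (1.0 / t["se_out"] ** 2).to_numpy()
    X = np.column_stack([np.ones(len(t)), t["beta_exp"].to_numpy()])
    y = t["beta_out"].to_numpy()
    XtWX = X.T @ (X * w[:, None])
    coef = np.linalg.solve(XtWX, X.T @ (w * y))
    resid = y - X @ coef
    L = len(t)
    phi2 = max(1.0, float((w * resid**2).sum()) / (L - 2))
    cov = np.linalg.inv(XtWX) * phi2
    slope = CausalEstimate(beta=float(coef[1]), se=float(np.sqrt(cov[1, 1])), n=L, method="MR-Egger")
    return EggerResult(slope=slope, intercept=float(coef[0]), intercept_se=float(np.sqrt(cov[0, 0])))


def weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """50th weighted percentile with standard midpoint interpolation.

    Tied ratios are merged (weights summed) first, so the result does
    not depend on input order.
    """
    r, inverse = np.unique(np.asarray(ratios, float), return_inverse=True)
    w = np.zeros(len(r))
    np.add.at(w, inverse, np.asarray(weights, float))
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth: float) -> float:
    grid = np.linspace(ratios.min() - 3 * bandwidth, ratios.max() + 3 * bandwidth, 1024)
    dens = np.zeros_like(grid)
    wn = weights / weights.sum()
    for r, w in zip(ratios, wn):
        dens += w * np.exp(-0.5 * ((grid - r) / bandwidth) ** 2)
    return float(grid[np.argmax(dens)])


def _mad_bandwidth(ratios: np.ndarray, phi: float) -> float:
    mad = np.median(np.abs(ratios - np.median(ratios)))
    h = phi * 1.4826 * mad
    if h <= 0:
        h = phi * max(np.std(ratios), 1e-8)
    return h


@dataclass
class MedianModeResults:
    weighted_median: CausalEstimate
    simple_mode: CausalEstimate
    weighted_mode: CausalEstimate


def median_and_mode_estimates(
    s: SummarySet, mode_bandwidth: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MedianModeResults:
    """Weighted median and kernel-mode estimators with bootstrap SEs.

    Per-SNP Wald ratios are combined as (i) the inverse-variance
    weighted median and (ii) the mode of a Gaussian-kernel density of
    the ratios (unweighted = simple mode; IVW-weighted = weighted
    mode), bandwidth phi x 1.4826 x MAD.  SEs come from a parametric
    bootstrap of the ratios.
    """
    if len(s) < 3:
        raise ValueError("median/mode estimators require at least 3 SNPs")
    if mode_bandwidth <= 0:
        raise ValueError("mode bandwidth must be positive")
    r = s.ratios
    se_r = s.ratio_ses
    w = 1.0 / se_r**2
    L = len(r)

    def point(rr):
        h = _mad_bandwidth(rr, mode_bandwidth)
        return (
            weighted_median(rr, w),
            _kde_mode(rr, np.ones(L), h),
            _kde_mode(rr, w, h),
        )

    est = point(r)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 3))
    for b in range(n_boot):
        draws[b] = point(rng.normal(r, se_r))
    ses = draws.std(axis=0, ddof=1)
    names = ("weighted median", "simple mode", "weighted mode")
    ests = [
        CausalEstimate(beta=e, se=float(sd), n=L, method=m)
        for e, sd, m in zip(est, ses, names)
    ]
    return MedianModeResults(*ests)


def cochran_q(s: SummarySet, beta_ivw: float) -> tuple[float, int, float]:
    """Cochran's Q of per-SNP Wald ratios about the IVW estimate.

    Q = sum_j w_j (ratio_j - beta)^2 with w_j = beta_exp_j^2/se_out_j^2
    (the IVW weights expressed on the ratio scale); df = L - 1.
    """
    if len(s) < 2:
        raise ValueError("Cochran's Q requires at least 2 SNPs")
    t = s.table
    w = (t["beta_exp"] ** 2 / t["se_out"] ** 2).to_numpy()
    q = float((w * (s.ratios - beta_ivw) ** 2).sum())
    df = len(s) - 1
    return q, df, float(stats.chi2.sf(q, df))


def sensitivity_panel(s: SummarySet, seed: int = 0, n_boot: int = 1000) -> pd.DataFrame:
    """The full sensitivity-estimator table for one outcome."""
    ivw = ivw_estimate(s)
    egger = egger_estimate(s)
    mm = median_and_mode_estimates(s, n_boot=n_boot, seed=seed)
    q, df, qp = cochran_q(s, ivw.beta)
    rows = [ivw, egger.slope, mm.weighted_median, mm.simple_mode, mm.weighted_mode]
    out = pd.DataFrame([e.to_row() for e in rows])
    out.attrs["egger_intercept"] = egger.intercept
    out.attrs["egger_intercept_se"] = egger.intercept_se
    out.attrs["egger_intercept_p"] = egger.intercept_p
    out.attrs["cochran_q"] = q
    out.attrs["cochran_q_df"] = df
    out.attrs["cochran_q_p"] = qp
    return out
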