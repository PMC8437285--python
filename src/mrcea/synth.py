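"""Seeded synthetic cohorts with known causal ground truth.

The generator emulates the statistical structure the analysis assumes: a
polygenic score built from independent Hardy-Weinberg SNPs instruments
BMI; a latent confounder raises both BMI and the outcomes; BMI drives
chronic-condition incidence, mortality and healthcare use, which in turn
produce QALYs and annual costs; most of the cohort is missing
primary-care outcomes.

Two outcome channels are provided:

``annual``
    emits per-person QALYs/year and costs/year directly from the
    structural model.  Used for replicate-heavy simulation studies
    (coverage, pleiotropy, nonlinearity), where event-level detail is
    irrelevant, and the only channel supporting per-SNP pleiotropy and
    nonlinear (callable) true effects.

``ledger``
    emits dated condition, prescription, appointment and inpatient
    event ledgers plus deaths.  Condition onsets follow constant
    per-condition hazards that are log-linear in BMI and the confounder;
    the hazard scale is calibrated analytically so the net BMI effect on
    QALYs/year (morbidity + mortality channels) equals
    ``true_qaly_effect`` at the reference BMI, and event rates are
    calibrated so the net cost effect equals ``true_cost_effect``.

All randomness flows from ``GeneratorConfig.seed`` through named
substreams, so stages can be re-run independently and cohorts are
bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .outcomes import DAYS_PER_YEAR, UtilityCatalogue

# substream labels -> offsets mixed into the seed sequence
_STREAMS = {
    "defaults": 0,
    "genotypes": 1,
    "confounder": 2,
    "bmi": 3,
    "covariates": 4,
    "ledger": 5,
    "annual": 6,
    "missingness": 7,
}

N_PCS = 40
N_CENTRES = 22
REFERENCE_BMI = 27.4  # cohort mean, the expansion point for calibration

#: conditions named after the restricted set used in conventional
#: decision-analytic models, then generic chronic conditions
RESTRICTED_CONDITIONS = (
    "cancer",
    "cardiovascular_disease",
    "cerebrovascular_disease",
    "type_2_diabetes",
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def default_condition_ids(n_conditions: int) -> list[str]:
    ids = list(RESTRICTED_CONDITIONS[: min(4, n_conditions)])
    ids += [f"cond_{k:02d}" for k in range(len(ids) + 1, n_conditions + 1)]
    return ids


def default_catalogue(n_conditions: int = 24, seed: int = 0) -> UtilityCatalogue:
    """Synthetic utility-decrement catalogue (stand-in for a published one).

    Decrements are drawn once (deterministically in ``seed``) from
    U(0.02, 0.12), the range typical of chronic-condition catalogues.
    """
    rng = _rng(seed, "defaults")
    dec = rng.uniform(0.02, 0.12, size=n_conditions)
    ses = 0.1 * dec
    ids = default_condition_ids(n_conditions)
    return UtilityCatalogue(
        decrements=pd.Series(dec, index=ids),
        decrement_ses=pd.Series(ses, index=ids),
    )


def default_tariffs(n_drugs: int = 50, seed: int = 0) -> pd.Series:
    """Synthetic drug tariff table (drug id -> GBP per item)."""
    rng = _rng(seed, "defaults")
    prices = np.round(rng.lognormal(mean=2.2, sigma=1.0, size=n_drugs), 2)
    return pd.Series(prices, index=[f"drug_{k:03d}" for k in range(n_drugs)], name="tariff")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions the analysis assumes: 69
    instrument SNPs whose score explains ~1.6% of BMI variance (first-
    stage F ~ 5,168 at the full biobank n, scaling with n), BMI mean 27.4
    and SD 4.8 kg/m^2, a net effect of +1 kg/m^2 of -0.0065 QALYs/year
    and +GBP 42.23/year, 31% primary-care outcome coverage, and a
    24-condition utility catalogue standing in for the full 240.
    """

    n_individuals: int
    n_snps: int = 69
    allele_freqs: np.ndarray | None = None  # default: U(0.1, 0.9), deterministic
    snp_betas: np.ndarray | None = None  # default: scaled so PRS R^2 = prs_r2
    prs_r2: float = 0.0164  # share of BMI variance explained by the score
    bmi_mean: float = REFERENCE_BMI
    bmi_sd: float = 4.8
    confounder_effect_bmi: float = 1.0  # kg/m^2 per confounder SD
    confounder_effect_qaly: float = -0.03  # QALY fraction per confounder SD
    confounder_effect_cost: float = 150.0  # GBP/year per confounder SD
    true_qaly_effect: float | Callable = -0.0065  # QALY fraction per kg/m^2
    true_cost_effect: float | Callable = 42.23  # GBP/year per kg/m^2
    pleiotropy_qaly: np.ndarray | None = None  # per-SNP direct QALY effects
    pleiotropy_cost: np.ndarray | None = None
    primary_care_coverage: float = 0.31
    n_conditions: int = 24
    qaly_resid_sd: float = 0.15  # annual-channel noise
    cost_resid_sd: float = 600.0
    qaly_base: float = 0.80  # annual-channel mean QALY at reference BMI
    cost_base: float = 700.0
    age_effect_qaly: float = -0.004  # per year of age beyond the mean
    age_effect_cost: float = 20.0
    condition_hazards: np.ndarray | None = None  # per-condition baseline hazards /yr
    death_rate: float = 0.004  # baseline mortality hazard per year
    death_bmi_loghr: float = 0.02  # log-hazard per kg/m^2
    followup_primary_mean: float = 8.1
    followup_sd: float = 0.8
    followup_secondary_lag: float = 2.0  # secondary averaged over 2 fewer years
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        rng = _rng(self.seed, "defaults")
        if self.allele_freqs is None:
            self.allele_freqs = rng.uniform(0.1, 0.9, size=self.n_snps)
        self.allele_freqs = np.asarray(self.allele_freqs, float)
        if self.allele_freqs.shape != (self.n_snps,):
            raise ValueError("allele_freqs length must equal n_snps")
        if ((self.allele_freqs <= 0) | (self.allele_freqs >= 1)).any():
            raise ValueError("allele frequencies must lie strictly inside (0, 1)")
        if self.snp_betas is None:
            # long-tailed per-allele effect magnitudes (many small hits, a
            # few large ones), rescaled so the score explains prs_r2 of
            # BMI variance; the dispersion of instrument strengths is
            # itself a feature summary-MR estimators rely on
            raw = np.abs(rng.normal(0.03, 0.12, size=self.n_snps))
            var_raw = float(np.sum(raw**2 * 2 * self.allele_freqs * (1 - self.allele_freqs)))
            target_var = self.prs_r2 * self.bmi_sd**2
            self.snp_betas = raw * np.sqrt(target_var / var_raw)
        self.snp_betas = np.asarray(self.snp_betas, float)
        if self.snp_betas.shape != (self.n_snps,):
            raise ValueError("snp_betas length must equal n_snps")
        for name in ("pleiotropy_qaly", "pleiotropy_cost"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, float)
                if v.shape != (self.n_snps,):
                    raise ValueError(f"{name} length must equal n_snps")
                setattr(self, name, v)
        if not 0.0 <= self.primary_care_coverage <= 1.0:
            raise ValueError("primary_care_coverage must lie in [0, 1]")
        if self.death_rate < 0:
            raise ValueError("death_rate must be non-negative")

    @property
    def prs_variance(self) -> float:
        f = self.allele_freqs
        return float(np.sum(self.snp_betas**2 * 2 * f * (1 - f)))

    def snp_ids(self) -> list[str]:
        return [f"rs{1000 + j}" for j in range(self.n_snps)]

    def weight_table(self):
        from .outcomes import SnpWeightTable

        return SnpWeightTable(
            pd.DataFrame({"snp": self.snp_ids(), "effect_allele": "A", "beta": self.snp_betas})
        )


@dataclass
class Ledgers:
    condition_events: pd.DataFrame  # person_id, condition, onset_day
    prescriptions: pd.DataFrame  # person_id, day, drug_id
    appointments: pd.DataFrame  # person_id, day
    inpatient: pd.DataFrame  # person_id, day, cost
    tariffs: pd.Series  # drug id -> GBP


@dataclass
class SyntheticCohort:
    """Generated cohort: genotypes, covariates, BMI, outcomes, truth."""

    people: pd.DataFrame  # age, sex, centre, pc1..40, confounder, bmi, follow-ups, death_day
    dosages: np.ndarray  # n x m effect-allele counts in {0, 1, 2}
    snp_ids: list[str]
    config: GeneratorConfig
    annual: pd.DataFrame | None = None  # annual-channel outcomes
    ledgers: Ledgers | None = None
    catalogue: UtilityCatalogue | None = None

    @property
    def n(self) -> int:
        return len(self.people)

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.people.index, columns=self.snp_ids)

    def analysis_table(self) -> pd.DataFrame:
        """People + PRS + annual outcomes, ready for regression."""
        from .outcomes import compute_prs

        df = self.people.copy()
        df["prs"] = compute_prs(self.dosages, self.config.weight_table(), self.snp_ids)
        if self.annual is not None:
            df = df.join(self.annual)
        return df


# ---------------------------------------------------------------------------
# stage operations


def generate_genotypes(config: GeneratorConfig) -> np.ndarray:
    """Hardy-Weinberg dosages: SNP j ~ Binomial(2, f_j), independent."""
    rng = _rng(config.seed, "genotypes")
    return rng.binomial(2, config.allele_freqs, size=(config.n_individuals, config.n_snps)).astype(np.int8)


def generate_confounder(config: GeneratorConfig) -> np.ndarray:
    return _rng(config.seed, "confounder").standard_normal(config.n_individuals)


def generate_bmi(dosages: np.ndarray, confounder: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """BMI = mean + dosages . betas (centred) + confounding + residual noise.

    The residual SD is chosen so the marginal SD is ~``bmi_sd``.
    """
    dosages = np.asarray(dosages)
    if dosages.shape != (config.n_individuals, config.n_snps):
        raise ValueError("dosage matrix shape does not match config")
    if confounder.shape != (config.n_individuals,):
        raise ValueError("confounder length does not match config")
    genetic = dosages @ config.snp_betas
    genetic = genetic - 2 * config.allele_freqs @ config.snp_betas  # centre
    resid_var = config.bmi_sd**2 - config.prs_variance - config.confounder_effect_bmi**2
    if resid_var < -1e-9:
        raise ValueError("bmi_sd too small for the genetic + confounder variance")
    resid_var = max(resid_var, 0.0)
    noise = _rng(config.seed, "bmi").normal(0.0, np.sqrt(resid_var), config.n_individuals)
    return config.bmi_mean + genetic + config.confounder_effect_bmi * confounder + noise


def generate_covariates(config: GeneratorConfig) -> pd.DataFrame:
    rng = _rng(config.seed, "covariates")
    n = config.n_individuals
    age = np.clip(rng.normal(56.9, 8.0, n), 39.0, 72.0)
    sex = rng.integers(0, 2, n)
    centre = rng.integers(1, N_CENTRES + 1, n)
    pcs = rng.standard_normal((n, N_PCS))
    fu_p = np.clip(rng.normal(config.followup_primary_mean, config.followup_sd, n), 4.0, 12.0)
    fu_s = fu_p - config.followup_secondary_lag
    df = pd.DataFrame({"age": age, "sex": sex, "centre": centre})
    for k in range(N_PCS):
        df[f"pc{k + 1}"] = pcs[:, k]
    df["followup_primary_years"] = fu_p
    df["followup_secondary_years"] = fu_s
    df.index.name = "person_id"
    return df


def _cumulative_effect(effect, bmi: np.ndarray, ref: float) -> np.ndarray:
    """Integral of a (possibly BMI-dependent) per-unit effect from ref to BMI."""
    if callable(effect):
        lo = min(float(np.min(bmi)), ref) - 1.0
        hi = max(float(np.max(bmi)), ref) + 1.0
        grid = np.linspace(lo, hi, 4001)
        cum = cumulative_trapezoid(effect(grid), grid, initial=0.0)
        at_ref = np.interp(ref, grid, cum)
        return np.interp(bmi, grid, cum) - at_ref
    return float(effect) * (np.asarray(bmi) - ref)


def generate_annual_outcomes(
    bmi: np.ndarray,
    confounder: np.ndarray,
    dosages: np.ndarray,
    covariates: pd.DataFrame,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Reduced-form outcome channel: QALYs/year and costs/year directly.

    Structural model (per person):
      qalys/yr = base + F_q(BMI) + c_q U + a_q (age - mean) + G . p_q + e_q
      cost/yr  = base + F_c(BMI) + c_c U + a_c (age - mean) + G . p_c + e_c
    where F' is the true per-unit effect (scalar or BMI-dependent) and
    p are the per-SNP pleiotropy vectors.  Cost noise is right-skewed
    (centred gamma); total cost splits 55/45 into primary/secondary.
    """
    rng = _rng(config.seed, "annual")
    n = config.n_individuals
    age_c = covariates["age"].to_numpy() - 56.9
    qaly = (
        config.qaly_base
        + _cumulative_effect(config.true_qaly_effect, bmi, config.bmi_mean)
        + config.confounder_effect_qaly * confounder
        + config.age_effect_qaly * age_c
        + rng.normal(0.0, config.qaly_resid_sd, n)
    )
    shape = 2.0
    scale = config.cost_resid_sd / np.sqrt(shape)
    cost_noise = rng.gamma(shape, scale, n) - shape * scale
    cost = (
        config.cost_base
        + _cumulative_effect(config.true_cost_effect, bmi, config.bmi_mean)
        + config.confounder_effect_cost * confounder
        + config.age_effect_cost * age_c
        + cost_noise
    )
    if config.pleiotropy_qaly is not None:
        qaly = qaly + dosages @ config.pleiotropy_qaly
    if config.pleiotropy_cost is not None:
        cost = cost + dosages @ config.pleiotropy_cost
    primary = 0.55 * cost
    secondary = 0.45 * cost
    return pd.DataFrame(
        {
            "qalys_per_year": qaly,
            "primary_cost_per_year": primary,
            "secondary_cost_per_year": secondary,
            "total_cost_per_year": primary + secondary,
        },
        index=covariates.index,
    )


# -- ledger channel ----------------------------------------------------------


def _active_fraction(h: np.ndarray, T: float) -> np.ndarray:
    """Expected fraction of [0, T] spent with a constant-hazard-h condition."""
    hT = h * T
    return 1.0 - np.where(hT > 0, -np.expm1(-hT) / np.where(hT > 0, hT, 1.0), 1.0)


def _active_fraction_deriv(h: np.ndarray, T: float) -> np.ndarray:
    """d/dh of the expected active fraction."""
    hT = h * T
    return np.where(hT > 0, (-np.expm1(-hT) - hT * np.exp(-hT)) / np.where(hT > 0, h**2 * T, 1.0), T / 2.0)


@dataclass
class LedgerCalibration:
    """Analytic calibration of the ledger channel at the reference BMI.

    With constant hazards h_k(b,u) = h0_k exp(kappa s_k (b-ref) + c_u u),
    the expected QALY slope from condition k is
    -d_k f'(h0_k) h0_k kappa s_k with f the expected active fraction, so
    kappa (and the confounder loading c_u) solve linear equations; the
    mortality channel's contribution enters through the alive-fraction
    derivative.  Event-rate slopes are linear, so the cost calibration is
    exact by construction.  Valid at (ref BMI, U=0); curvature of exp()
    makes the population-average slope differ by a few percent.
    """

    hazards: np.ndarray  # baseline per-condition hazards /year
    kappa: float  # BMI log-hazard scale
    cond_slopes: np.ndarray  # per-condition raw slopes s_k
    conf_loading: float  # confounder log-hazard loading
    qaly_mortality_slope: float
    rx_rate: float
    rx_bmi_loglin: float
    rx_cond_loglin: float
    appt_rate: float
    appt_bmi_loglin: float
    inpt_rate: float
    inpt_bmi_loglin: float
    inpt_conf_loglin: float
    inpt_mean_cost: float
    mean_rx_cost: float
    cond_count_slope: float  # d E[sum active fractions] / d BMI at ref


def calibrate_ledger(config: GeneratorConfig, catalogue: UtilityCatalogue, tariffs: pd.Series) -> LedgerCalibration:
    if callable(config.true_qaly_effect) or callable(config.true_cost_effect):
        raise ValueError("the ledger channel requires scalar true effects")
    T = config.followup_primary_mean
    K = config.n_conditions
    rng = _rng(config.seed, "defaults")
    if config.condition_hazards is not None:
        hazards = np.asarray(config.condition_hazards, float)
        if hazards.shape != (K,) or (hazards <= 0).any():
            raise ValueError("condition_hazards must be K positive rates")
    else:
        hazards = rng.uniform(0.01, 0.04, K)
    slopes = np.ones(K)
    dec = catalogue.decrements.to_numpy()[:K]

    # mortality channel: E[QALY] ~ u_bar * alive_fraction(lambda(b))
    lam = config.death_rate
    u_bar = config.qaly_base
    alive_deriv = -_active_fraction_deriv(np.array([lam]), T)[0]  # d alive_frac/d lam
    mort_slope = u_bar * alive_deriv * lam * config.death_bmi_loghr

    per_cond = dec * _active_fraction_deriv(hazards, T) * hazards * slopes
    denom = float(np.sum(per_cond))
    kappa = -(config.true_qaly_effect - mort_slope) / denom
    conf_loading = -config.confounder_effect_qaly / denom

    # cost channels: 20% prescriptions, 15% appointments, 65% inpatient.
    # Rates are mean-normalised log-linear in BMI (and the confounder for
    # inpatient), so they are never negative and the population-average
    # derivative is exactly (log-linear coefficient) x (mean rate).
    mean_rx_cost = float(tariffs.mean()) + 1.27
    rx_rate, appt_rate, inpt_rate = 8.0, 4.0, 0.25
    inpt_mean_cost = 1500.0
    target = config.true_cost_effect
    cond_count_slope = float(
        np.sum(kappa * slopes * hazards * _active_fraction_deriv(hazards, T))
    )
    rx_cond_loglin = 0.05  # healthcare use rises with active conditions
    rx_bmi_loglin = (0.20 * target / mean_rx_cost) / rx_rate - rx_cond_loglin * cond_count_slope
    appt_bmi_loglin = (0.15 * target / 30.0) / appt_rate
    inpt_bmi_loglin = 0.65 * target / (inpt_mean_cost * 1.0484) / inpt_rate
    inpt_conf_loglin = config.confounder_effect_cost / (inpt_mean_cost * 1.0484 * inpt_rate)
    return LedgerCalibration(
        hazards=hazards,
        kappa=kappa,
        cond_slopes=slopes,
        conf_loading=conf_loading,
        qaly_mortality_slope=mort_slope,
        rx_rate=rx_rate,
        rx_bmi_loglin=rx_bmi_loglin,
        rx_cond_loglin=rx_cond_loglin,
        appt_rate=appt_rate,
        appt_bmi_loglin=appt_bmi_loglin,
        inpt_rate=inpt_rate,
        inpt_bmi_loglin=inpt_bmi_loglin,
        inpt_conf_loglin=inpt_conf_loglin,
        inpt_mean_cost=inpt_mean_cost,
        mean_rx_cost=mean_rx_cost,
        cond_count_slope=cond_count_slope,
    )


def _poisson_events(rng, rate_per_year, horizon_days):
    """Draw event counts and uniform event days for each person."""
    lam = np.clip(rate_per_year, 0.0, None) * horizon_days / DAYS_PER_YEAR
    counts = rng.poisson(lam)
    person = np.repeat(np.arange(len(counts)), counts)
    days = (rng.random(counts.sum()) * np.repeat(horizon_days, counts)).astype(int)
    return person, days


def generate_outcomes(
    bmi: np.ndarray,
    confounder: np.ndarray,
    covariates: pd.DataFrame,
    config: GeneratorConfig,
    catalogue: UtilityCatalogue | None = None,
    tariffs: pd.Series | None = None,
) -> tuple[Ledgers, np.ndarray]:
    """Ledger outcome channel: condition/cost event ledgers plus deaths.

    Returns the ledgers and a per-person ``death_day`` array (NaN while
    alive through follow-up).  Event days are 0-based offsets from
    recruitment; every event falls within follow-up and before death.
    """
    if catalogue is None:
        catalogue = default_catalogue(config.n_conditions, config.seed)
    if tariffs is None:
        tariffs = default_tariffs(seed=config.seed)
    cal = calibrate_ledger(config, catalogue, tariffs)
    rng = _rng(config.seed, "ledger")
    n = config.n_individuals
    ids = covariates.index.to_numpy()
    db = bmi - config.bmi_mean
    fu_p_days = np.round(covariates["followup_primary_years"].to_numpy() * DAYS_PER_YEAR).astype(int)
    fu_s_days = np.round(covariates["followup_secondary_years"].to_numpy() * DAYS_PER_YEAR).astype(int)

    # deaths: exponential with BMI-dependent hazard
    death_day = np.full(n, np.nan)
    if config.death_rate > 0:
        lam = config.death_rate * np.exp(config.death_bmi_loghr * db)
        t_death = rng.exponential(1.0 / lam) * DAYS_PER_YEAR
        died = t_death < fu_p_days
        death_day[died] = np.floor(t_death[died])
    event_end = np.where(np.isnan(death_day), fu_p_days, death_day).astype(int)

    # condition onsets: time-to-first-event under constant hazards
    cond_ids = catalogue.condition_ids[: config.n_conditions]
    frames = []
    loghaz_shift = cal.kappa * db + cal.conf_loading * confounder
    for k, cond in enumerate(cond_ids):
        h = cal.hazards[k] * np.exp(cal.cond_slopes[k] * loghaz_shift)
        onset = rng.exponential(1.0 / h) * DAYS_PER_YEAR
        has = onset < event_end
        if has.any():
            frames.append(
                pd.DataFrame(
                    {"person_id": ids[has], "condition": cond, "onset_day": onset[has].astype(int)}
                )
            )
    condition_events = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["person_id", "condition", "onset_day"])
    )

    # active-time-weighted condition count feeds healthcare-use rates
    n_active = np.zeros(n)
    if len(condition_events):
        pos = pd.Index(ids).get_indexer(condition_events["person_id"])
        frac = np.clip(
            (event_end[pos] - condition_events["onset_day"].to_numpy()) / np.maximum(fu_p_days[pos], 1),
            0.0,
            1.0,
        )
        np.add.at(n_active, pos, frac)

    def norm_exp_rate(base, loglin):
        f = np.exp(loglin - loglin.mean())
        return base * f / f.mean()

    # the BMI gradient through the condition-count term is already folded
    # into the calibrated log-linear BMI coefficient
    rx_rate = norm_exp_rate(cal.rx_rate, cal.rx_bmi_loglin * db + cal.rx_cond_loglin * n_active)
    p_rx, d_rx = _poisson_events(rng, rx_rate, event_end)
    prescriptions = pd.DataFrame(
        {
            "person_id": ids[p_rx],
            "day": d_rx,
            "drug_id": rng.choice(tariffs.index.to_numpy(), size=len(p_rx)),
        }
    )
    appt_rate = norm_exp_rate(cal.appt_rate, cal.appt_bmi_loglin * db)
    p_ap, d_ap = _poisson_events(rng, appt_rate, event_end)
    appointments = pd.DataFrame({"person_id": ids[p_ap], "day": d_ap})

    sec_end = np.minimum(event_end, fu_s_days)
    # confounder -> cost routed through the (high-value) inpatient channel
    inpt_rate = norm_exp_rate(
        cal.inpt_rate, cal.inpt_bmi_loglin * db + cal.inpt_conf_loglin * confounder
    )
    p_in, d_in = _poisson_events(rng, inpt_rate, sec_end)
    costs = rng.gamma(1.5, cal.inpt_mean_cost / 1.5, size=len(p_in))
    inpatient = pd.DataFrame({"person_id": ids[p_in], "day": d_in, "cost": np.round(costs, 2)})

    ledgers = Ledgers(
        condition_events=condition_events,
        prescriptions=prescriptions,
        appointments=appointments,
        inpatient=inpatient,
        tariffs=tariffs,
    )
    return ledgers, death_day


def generate_cohort(config: GeneratorConfig, channel: str = "annual", catalogue: UtilityCatalogue | None = None) -> SyntheticCohort:
    """End-to-end generation: genotypes -> BMI -> covariates -> outcomes."""
    if channel not in {"annual", "ledger", "both"}:
        raise ValueError("channel must be 'annual', 'ledger' or 'both'")
    dosages = generate_genotypes(config)
    confounder = generate_confounder(config)
    bmi = generate_bmi(dosages, confounder, config)
    people = generate_covariates(config)
    people["confounder"] = confounder
    people["bmi"] = bmi
    people["death_day"] = np.nan
    annual = None
    ledgers = None
    if channel in {"annual", "both"}:
        annual = generate_annual_outcomes(bmi, confounder, dosages, people, config)
    if channel in {"ledger", "both"}:
        if catalogue is None:
            catalogue = default_catalogue(config.n_conditions, config.seed)
        ledgers, death_day = generate_outcomes(bmi, confounder, people, config, catalogue)
        people["death_day"] = death_day
    return SyntheticCohort(
        people=people,
        dosages=dosages,
        snp_ids=config.snp_ids(),
        config=config,
        annual=annual,
        ledgers=ledgers,
        catalogue=catalogue,
    )


def apply_missingness(
    cohort: SyntheticCohort,
    coverage: float | None = None,
    mechanism: str = "mcar",
    mar_age_coef: float = 0.1,
) -> SyntheticCohort:
    """Mask primary-care outcomes (QALYs, primary costs) for the uncovered.

    MCAR by default; the MAR option makes coverage logistic in age with
    the stated log-odds per year, recalibrated so the marginal coverage
    stays at the requested value.
    """
    if cohort.annual is None:
        raise ValueError("cohort has no annual outcomes to mask")
    coverage = cohort.config.primary_care_coverage if coverage is None else coverage
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    rng = _rng(cohort.config.seed, "missingness")
    n = cohort.n
    if mechanism == "mcar":
        observed = rng.random(n) < coverage
    elif mechanism == "mar":
        age_c = cohort.people["age"].to_numpy() - cohort.people["age"].mean()
        from scipy.optimize import brentq
        from scipy.special import expit, logit

        if coverage in (0.0, 1.0):
            observed = np.full(n, bool(coverage))
        else:
            a0 = brentq(lambda a: expit(a + mar_age_coef * age_c).mean() - coverage, -30, 30)
            observed = rng.random(n) < expit(a0 + mar_age_coef * age_c)
    else:
        raise ValueError("mechanism must be 'mcar' or 'mar'")
    annual = cohort.annual.copy()
    annual.loc[~observed, ["qalys_per_year", "primary_cost_per_year"]] = np.nan
    annual.loc[~observed, "total_cost_per_year"] = np.nan
    annual["primary_care_observed"] = observed
    return replace(cohort, annual=annual)
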