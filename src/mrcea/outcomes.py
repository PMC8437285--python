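"""Construction of the two regression outcomes.

The analysis regresses two person-level quantities on BMI: mean QALYs per
year of follow-up and mean total healthcare cost (GBP) per year.  QALYs
are built Sullivan-style from a catalogue of chronic-condition utility
decrements applied to each person's condition history day by day; costs
are assembled from prescription, appointment and inpatient-episode
ledgers with fixed tariffs.

Conventions
-----------
* 365-day years, 0-based day offsets from recruitment, half-open
  intervals; a condition is active from its onset day (inclusive).
* A person contributes utility 0 from their death day onward, through
  the end of the averaging window ("a QALY of 0 indicates ... death").
* Person-level QALYs/year is the unweighted mean of per-year means; a
  partial final year is averaged over its own length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365

PRESCRIPTION_FEE = 1.27  # GBP dispensing fee per prescription (Nov 2019 tariff)
APPOINTMENT_COST = 30.0  # GBP per GP-practice appointment
SECONDARY_INFLATION = 0.0484  # 2016/17 -> Nov 2019 NHS cost inflation

#: canonical schema of the per-person outcome table
ANNUAL_OUTCOME_COLUMNS = (
    "qalys_per_year",
    "primary_cost_per_year",
    "secondary_cost_per_year",
    "total_cost_per_year",
)


# ---------------------------------------------------------------------------
# instrument definition


@dataclass(frozen=True)
class SnpWeightTable:
    """Per-SNP instrument weights: effect allele and per-allele BMI effect."""

    table: pd.DataFrame  # columns: snp, effect_allele, beta (kg/m^2 per allele)

    def __post_init__(self) -> None:
        required = {"snp", "effect_allele", "beta"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"weight table missing columns: {sorted(missing)}")
        if self.table["snp"].duplicated().any():
            dups = self.table.loc[self.table["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate SNP ids in weight table: {dups}")
        if not np.isfinite(self.table["beta"]).all():
            raise ValueError("non-finite weight in SNP weight table")

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp"].tolist()

    @property
    def betas(self) -> np.ndarray:
        return self.table["beta"].to_numpy(float)


def compute_prs(dosages, weights: SnpWeightTable, snp_ids=None) -> np.ndarray:
    """Polygenic score: weighted sum of effect-allele dosages.

    ``dosages`` is either a DataFrame whose columns are SNP ids, or an
    (n, m) array accompanied by ``snp_ids``.  Effect-allele orientation
    is assumed already harmonised.  Raises if any weighted SNP is absent.
    """
    if isinstance(dosages, pd.DataFrame):
        cols = list(dosages.columns)
        mat = dosages.to_numpy(float)
    else:
        if snp_ids is None:
            raise ValueError("snp_ids required when dosages is an array")
        cols = list(snp_ids)
        mat = np.asarray(dosages, float)
    index = {s: j for j, s in enumerate(cols)}
    absent = [s for s in weights.snp_ids if s not in index]
    if absent:
        raise KeyError(f"SNPs missing from dosage matrix: {absent}")
    order = [index[s] for s in weights.snp_ids]
    return mat[:, order] @ weights.betas


# ---------------------------------------------------------------------------
# utility catalogue and daily utility


@dataclass(frozen=True)
class UtilityCatalogue:
    """Condition -> utility-decrement catalogue with a baseline utility model.

    Baseline utility is linear in age and sex,
    ``baseline = intercept + age_coef * (age - 40) + sex_coef * sex``,
    and daily utility is baseline minus the decrements of all conditions
    with onset on or before the day, clamped below at ``floor`` (EQ-5D
    permits states worse than death, hence the negative default floor).
    """

    decrements: pd.Series  # condition id -> QALY-fraction decrement, >= 0
    intercept: float = 0.94
    age_coef: float = -0.002  # per year of age beyond 40
    sex_coef: float = 0.01
    floor: float = -0.594
    decrement_ses: pd.Series | None = None  # optional prediction SEs

    def __post_init__(self) -> None:
        if (self.decrements < 0).any():
            bad = self.decrements[self.decrements < 0].index.tolist()
            raise ValueError(f"negative utility decrements: {bad}")
        ages = np.array([39.0, 72.0])
        if (self.floor > self.baseline(ages, np.array([0.0, 0.0]))).any():
            raise ValueError("utility floor exceeds baseline within the age range")

    def baseline(self, age, sex):
        return self.intercept + self.age_coef * (np.asarray(age) - 40.0) + self.sex_coef * np.asarray(sex)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.decrements.index)

    def restrict(self, condition_ids) -> "UtilityCatalogue":
        """Sub-catalogue with only the listed conditions (must be a subset)."""
        ids = list(condition_ids)
        if not ids:
            raise ValueError("restricted condition set is empty")
        unknown = set(ids) - set(self.decrements.index)
        if unknown:
            raise KeyError(f"conditions not in catalogue: {sorted(unknown)}")
        ses = self.decrement_ses.loc[ids] if self.decrement_ses is not None else None
        return UtilityCatalogue(
            decrements=self.decrements.loc[ids],
            intercept=self.intercept,
            age_coef=self.age_coef,
            sex_coef=self.sex_coef,
            floor=self.floor,
            decrement_ses=ses,
        )


def daily_utility(active_conditions, age, sex, catalogue: UtilityCatalogue, strict: bool = True) -> float:
    """Utility on a single day given the set of active condition ids."""
    total = 0.0
    for cond in active_conditions:
        if cond not in catalogue.decrements.index:
            if strict:
                raise KeyError(f"unknown condition id: {cond!r}")
            warnings.warn(f"skipping unknown condition id {cond!r}")
            continue
        total += catalogue.decrements[cond]
    return max(catalogue.floor, float(catalogue.baseline(age, sex)) - total)


def daily_utility_profile(events, followup_days, age, sex, catalogue, death_day=None, strict=True):
    """Reference daily-resolution utility series for one person.

    ``events`` is an iterable of ``(condition_id, onset_day)``.  Days at or
    after ``death_day`` contribute 0.  Intended for small-scale validation;
    the cohort-scale path uses exact interval arithmetic instead.
    """
    days = np.arange(int(followup_days))
    util = np.empty(len(days))
    active: list[str] = []
    onsets = sorted(events, key=lambda e: e[1])
    k = 0
    current = daily_utility(active, age, sex, catalogue, strict=strict)
    for d in days:
        while k < len(onsets) and onsets[k][1] <= d:
            active.append(onsets[k][0])
            current = daily_utility(active, age, sex, catalogue, strict=strict)
            k += 1
        util[d] = current
    if death_day is not None:
        util[days >= death_day] = 0.0
    return util


def annualize_qalys(daily_utilities, death_day=None) -> float:
    """Mean QALYs per year from a daily utility series.

    The window is split into 365-day years (final year possibly partial);
    the person-level value is the unweighted mean of per-year mean
    utilities, with days from ``death_day`` onward contributing 0.
    """
    util = np.asarray(daily_utilities, float).copy()
    n = len(util)
    if n == 0:
        raise ValueError("empty follow-up window")
    if death_day is not None:
        if death_day < 0:
            raise ValueError("death before the start of the follow-up window")
        util[int(death_day):] = 0.0
    yearly = [util[s : s + DAYS_PER_YEAR].mean() for s in range(0, n, DAYS_PER_YEAR)]
    return float(np.mean(yearly))


def person_qalys(events, followup_days, age, sex, catalogue, death_day=None, strict=True) -> float:
    """Exact per-person QALYs/year via interval arithmetic.

    Equivalent to building the daily profile and averaging, but O(#events)
    instead of O(#days): utility is piecewise constant between onsets, so
    each (possibly clamped) level is integrated over its interval within
    each 365-day year.
    """
    followup_days = int(followup_days)
    if followup_days <= 0:
        raise ValueError("empty follow-up window")
    end = followup_days
    if death_day is not None:
        if death_day < 0:
            raise ValueError("death before the start of the follow-up window")
        end = min(end, int(death_day))

    base = float(catalogue.baseline(age, sex))
    onsets = []
    for cond, day in events:
        if cond not in catalogue.decrements.index:
            if strict:
                raise KeyError(f"unknown condition id: {cond!r}")
            warnings.warn(f"skipping unknown condition id {cond!r}")
            continue
        onsets.append((int(day), float(catalogue.decrements[cond])))
    onsets.sort()

    # breakpoints: onset days within [0, end) plus year boundaries
    n_years = int(np.ceil(followup_days / DAYS_PER_YEAR))
    year_sums = np.zeros(n_years)
    points = [0, end]
    points += [d for d, _ in onsets if 0 < d < end]
    points += [y * DAYS_PER_YEAR for y in range(1, n_years) if y * DAYS_PER_YEAR < end]
    points = sorted(set(points))

    level = base - sum(dec for d, dec in onsets if d <= 0)
    k = sum(1 for d, _ in onsets if d <= 0)
    for a, b in zip(points[:-1], points[1:]):
        while k < len(onsets) and onsets[k][0] <= a:
            level -= onsets[k][1]
            k += 1
        clamped = max(catalogue.floor, level)
        y0 = a // DAYS_PER_YEAR  # [a, b) never straddles a year boundary
        year_sums[y0] += clamped * (b - a)
    # days in [end, followup_days) contribute 0 (death); year lengths
    lengths = np.full(n_years, DAYS_PER_YEAR, float)
    lengths[-1] = followup_days - (n_years - 1) * DAYS_PER_YEAR
    return float(np.mean(year_sums / lengths))


def cohort_annual_qalys(people: pd.DataFrame, condition_events: pd.DataFrame, catalogue: UtilityCatalogue, strict: bool = True) -> pd.Series:
    """QALYs/year for every person in a cohort.

    ``people`` needs columns ``age``, ``sex``, ``followup_primary_years``
    and ``death_day`` (NaN if alive); ``condition_events`` has columns
    ``person_id``, ``condition``, ``onset_day``.
    """
    events_by_person: dict = {}
    if len(condition_events):
        for pid, grp in condition_events.groupby("person_id"):
            events_by_person[pid] = list(zip(grp["condition"], grp["onset_day"]))
    out = {}
    for pid, row in people.iterrows():
        death = row["death_day"] if "death_day" in row and np.isfinite(row.get("death_day", np.nan)) else None
        fd = int(round(row["followup_primary_years"] * DAYS_PER_YEAR))
        out[pid] = person_qalys(
            events_by_person.get(pid, []), fd, row["age"], row["sex"], catalogue, death_day=death, strict=strict
        )
    return pd.Series(out, name="qalys_per_year")


# ---------------------------------------------------------------------------
# cost assembly


@dataclass
class CostAssemblyReport:
    n_prescriptions: int = 0
    n_unmatched_drugs: int = 0
    unmatched_ids: list = field(default_factory=list)


def assemble_annual_costs(
    prescriptions: pd.DataFrame,
    appointments: pd.DataFrame,
    inpatient: pd.DataFrame,
    tariffs: pd.Series,
    followup_primary_years: pd.Series,
    followup_secondary_years: pd.Series,
    prescription_fee: float = PRESCRIPTION_FEE,
    appointment_cost: float = APPOINTMENT_COST,
    inflation: float = SECONDARY_INFLATION,
) -> tuple[pd.DataFrame, CostAssemblyReport]:
    """Per-person annualised primary, secondary and total healthcare costs.

    Primary cost = sum over prescriptions of (drug tariff + dispensing
    fee) plus a flat cost per appointment, divided by primary follow-up
    years.  Secondary cost = inpatient episode costs inflated to Nov-2019
    prices, divided by (shorter) secondary follow-up years.  Prescriptions
    whose drug id has no tariff are excluded and counted, mirroring
    unmatched-drug handling in routine costing.
    """
    if (tariffs < 0).any():
        bad = tariffs[tariffs < 0].index.tolist()
        raise ValueError(f"negative drug tariffs: {bad}")
    report = CostAssemblyReport(n_prescriptions=len(prescriptions))

    idx = followup_primary_years.index
    rx_cost = pd.Series(0.0, index=idx)
    if len(prescriptions):
        matched = prescriptions["drug_id"].isin(tariffs.index)
        report.n_unmatched_drugs = int((~matched).sum())
        report.unmatched_ids = sorted(prescriptions.loc[~matched, "drug_id"].unique().tolist())
        rx = prescriptions[matched]
        per_rx = tariffs.loc[rx["drug_id"]].to_numpy(float) + prescription_fee
        rx_cost = rx_cost.add(pd.Series(per_rx, index=rx["person_id"].to_numpy()).groupby(level=0).sum(), fill_value=0.0)

    appt_cost = pd.Series(0.0, index=idx)
    if len(appointments):
        counts = appointments.groupby("person_id").size()
        appt_cost = appt_cost.add(counts * appointment_cost, fill_value=0.0)

    sec_cost = pd.Series(0.0, index=idx)
    if len(inpatient):
        sec_cost = sec_cost.add(inpatient.groupby("person_id")["cost"].sum(), fill_value=0.0)

    primary = (rx_cost + appt_cost) / followup_primary_years
    secondary = sec_cost * (1.0 + inflation) / followup_secondary_years
    out = pd.DataFrame(
        {
            "primary_cost_per_year": primary,
            "secondary_cost_per_year": secondary,
            "total_cost_per_year": primary + secondary,
        }
    )
    return out, report


def validate_annual_outcome(df: pd.DataFrame, tol: float = 1e-9) -> None:
    """Check the AnnualOutcome schema invariants."""
    for col in ANNUAL_OUTCOME_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"annual outcome table missing column {col!r}")
    q = df["qalys_per_year"].dropna()
    if (q > 1.0 + tol).any():
        raise ValueError("QALYs per year exceed 1")
    for col in ANNUAL_OUTCOME_COLUMNS[1:]:
        v = df[col].dropna()
        if (v < -tol).any():
            raise ValueError(f"negative values in {col}")
    both = df.dropna(subset=["primary_cost_per_year", "secondary_cost_per_year", "total_cost_per_year"])
    if not np.allclose(
        both["total_cost_per_year"],
        both["primary_cost_per_year"] + both["secondary_cost_per_year"],
        atol=1e-6,
    ):
        raise ValueError("total cost is not primary + secondary")
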