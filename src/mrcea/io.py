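"""Standard-format I/O: CSV tables, YAML sidecars, optional VCF dosages.

Cohorts are interchanged as a directory of CSV tables (people,
dosages, one CSV per event ledger) plus a YAML sidecar with the true
generating parameters.  SNP weights, tariffs and utility catalogues
are single CSVs with documented headers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .outcomes import SnpWeightTable, UtilityCatalogue
from .synth import GeneratorConfig, Ledgers, SyntheticCohort


def _config_to_dict(config: GeneratorConfig) -> dict:
    d = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        if callable(v):
            v = "<callable>"
        d[f.name] = v
    return d


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.people.to_csv(outdir / "people.csv")
    cohort.dosage_frame().to_csv(outdir / "dosages.csv")
    if cohort.annual is not None:
        cohort.annual.to_csv(outdir / "annual_outcomes.csv")
    if cohort.ledgers is not None:
        led = cohort.ledgers
        led.condition_events.to_csv(outdir / "condition_events.csv", index=False)
        led.prescriptions.to_csv(outdir / "prescriptions.csv", index=False)
        led.appointments.to_csv(outdir / "appointments.csv", index=False)
        led.inpatient.to_csv(outdir / "inpatient.csv", index=False)
        led.tariffs.rename_axis("drug_id").to_csv(outdir / "tariffs.csv")
    if cohort.catalogue is not None:
        write_catalogue(cohort.catalogue, outdir / "catalogue.csv")
    with open(outdir / "true_params.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(cohort.config), fh)


def read_cohort(indir) -> SyntheticCohort:
    indir = Path(indir)
    with open(indir / "true_params.yaml") as fh:
        params = yaml.safe_load(fh)
    for key in ("allele_freqs", "snp_betas", "pleiotropy_qaly", "pleiotropy_cost"):
        if params.get(key) is not None:
            params[key] = np.asarray(params[key], float)
    config = GeneratorConfig(**params)
    people = pd.read_csv(indir / "people.csv", index_col="person_id")
    dosage_df = pd.read_csv(indir / "dosages.csv", index_col="person_id")
    annual = None
    if (indir / "annual_outcomes.csv").exists():
        annual = pd.read_csv(indir / "annual_outcomes.csv", index_col="person_id")
    ledgers = None
    if (indir / "condition_events.csv").exists():
        ledgers = Ledgers(
            condition_events=pd.read_csv(indir / "condition_events.csv"),
            prescriptions=pd.read_csv(indir / "prescriptions.csv"),
            appointments=pd.read_csv(indir / "appointments.csv"),
            inpatient=pd.read_csv(indir / "inpatient.csv"),
            tariffs=pd.read_csv(indir / "tariffs.csv", index_col="drug_id")["tariff"],
        )
    catalogue = read_catalogue(indir / "catalogue.csv") if (indir / "catalogue.csv").exists() else None
    return SyntheticCohort(
        people=people,
        dosages=dosage_df.to_numpy(np.int8),
        snp_ids=dosage_df.columns.tolist(),
        config=config,
        annual=annual,
        ledgers=ledgers,
        catalogue=catalogue,
    )


def read_snp_weights(path) -> SnpWeightTable:
    """CSV with columns snp, effect_allele, beta."""
    return SnpWeightTable(pd.read_csv(path))


def write_snp_weights(weights: SnpWeightTable, path) -> None:
    weights.table.to_csv(path, index=False)


def write_catalogue(catalogue: UtilityCatalogue, path) -> None:
    df = pd.DataFrame({"condition": catalogue.condition_ids, "decrement": catalogue.decrements.to_numpy()})
    if catalogue.decrement_ses is not None:
        df["decrement_se"] = catalogue.decrement_ses.to_numpy()
    df.attrs = {}
    header = {
        "intercept": catalogue.intercept,
        "age_coef": catalogue.age_coef,
        "sex_coef": catalogue.sex_coef,
        "floor": catalogue.floor,
    }
    with open(path, "w") as fh:
        fh.write("# " + yaml.safe_dump(header, default_flow_style=True).strip() + "\n")
        df.to_csv(fh, index=False)


def read_catalogue(path) -> UtilityCatalogue:
    with open(path) as fh:
        first = fh.readline()
        header = yaml.safe_load(first.lstrip("# ").strip()) if first.startswith("#") else {}
        df = pd.read_csv(fh)
    ses = None
    if "decrement_se" in df.columns:
        ses = pd.Series(df["decrement_se"].to_numpy(), index=df["condition"])
    return UtilityCatalogue(
        decrements=pd.Series(df["decrement"].to_numpy(), index=df["condition"]),
        decrement_ses=ses,
        **{k: float(v) for k, v in (header or {}).items()},
    )


def read_dosages_vcf(path) -> pd.DataFrame:
    """Effect-allele dosages from VCF genotypes (GT fields).

    Counts ALT alleles per sample per variant; the ALT allele is taken
    as the effect allele (harmonisation is the caller's concern).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    rows, ids = [], []
    for variant in vcf:
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        gts = np.asarray(variant.genotypes)[:, :2]
        rows.append((gts > 0).sum(axis=1))
    return pd.DataFrame(np.array(rows).T, index=samples, columns=ids)


def ingest_cohort(people_path, dosage_path=None, dosage_vcf=None) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Read and validate an externally supplied cohort table.

    Returns (people, dosages, rejected) where ``rejected`` reports rows
    failing validation (non-positive BMI, negative follow-up) with the
    reason.  Dosages come from a plain CSV matrix or a VCF.
    """
    people = pd.read_csv(people_path, index_col=0)
    required = ["age", "sex", "bmi", "followup_primary_years"]
    missing = [c for c in required if c not in people.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    reasons = []
    bad_bmi = ~(people["bmi"] > 10)
    for idx in people.index[bad_bmi]:
        reasons.append({"person_id": idx, "reason": "non-positive or implausible BMI"})
    bad_fu = ~(people["followup_primary_years"] > 0)
    for idx in people.index[bad_fu]:
        reasons.append({"person_id": idx, "reason": "non-positive follow-up"})
    rejected = pd.DataFrame(reasons, columns=["person_id", "reason"])
    people = people[~(bad_bmi | bad_fu)]
    dosages = None
    if dosage_vcf is not None:
        dosages = read_dosages_vcf(dosage_vcf)
    elif dosage_path is not None:
        dosages = pd.read_csv(dosage_path, index_col=0)
        bad = ~dosages.isin([0, 1, 2]).all(axis=1)
        for idx in dosages.index[bad]:
            rejected.loc[len(rejected)] = {"person_id": idx, "reason": "dosage outside {0,1,2}"}
        dosages = dosages[~bad]
    return people, dosages, rejected
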