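"""Multi-site cohort simulation.

Generates subject tables emulating a six-site OCD case-control study:
412 patients and 368 controls by default, with demographic covariates
(age, sex, intracranial volume, education), clinical scores (Y-BOCS total,
age of onset, illness duration), lifetime depression/anxiety comorbidity
flags, psychotropic medication status, and five binary symptom-dimension
indicators (aggression/checking, contamination/cleaning, symmetry/ordering,
sexual/religious, hoarding).

Subgroup membership uses deterministic quota fill — exact configured counts
apportioned across sites by largest remainder, with the member subset drawn
once from the seeded generator — rather than Bernoulli draws, so subgroup
sizes match the configuration exactly.  Clinical fields can be masked for a
configured number of patients to emulate sites where clinical information
was not collected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import InvalidConfigError

__all__ = ["CohortConfig", "simulate_cohort", "COHORT_COLUMNS", "read_cohort_csv", "write_cohort_csv"]

COHORT_COLUMNS = [
    "subject_id",
    "site",
    "dx",
    "age",
    "sex",
    "icv",
    "education",
    "ybocs_total",
    "age_onset",
    "duration",
    "med",
    "dep_lifetime",
    "anx_lifetime",
    "dim_aggr",
    "dim_contam",
    "dim_symm",
    "dim_sexrel",
    "dim_hoard",
]

DIM_COLUMNS = ["dim_aggr", "dim_contam", "dim_symm", "dim_sexrel", "dim_hoard"]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters.

    Default group sizes, covariate summaries, subgroup counts, and
    missing-data counts reproduce the six-site case-control design this
    package mirrors: per-site patient/control splits summing to 412/368;
    patient age 32.1 (SD 9.6) vs control 30.2 (SD 9.3) years, truncated to
    the 18-65 inclusion window; 176 medicated, 101 with lifetime
    depression, 83 with lifetime anxiety; symptom-dimension prevalences
    236/202/168/130/87 of 412; and clinical-information availability
    masking 81 patients for Y-BOCS/dimensions, 24 for the depression flag,
    139 for the anxiety flag, and 14 for medication status.

    Quota fields accept either an absolute count or a fraction in [0, 1]
    (interpreted as a prevalence of the patient group).
    """

    sites: tuple[str, ...] = ("site1", "site2", "site3", "site4", "site5", "site6")
    patients_per_site: tuple[int, ...] = (69, 69, 69, 69, 68, 68)
    controls_per_site: tuple[int, ...] = (62, 62, 61, 61, 61, 61)
    age_patients: tuple[float, float] = (32.1, 9.6)
    age_controls: tuple[float, float] = (30.2, 9.3)
    age_bounds: tuple[float, float] = (18.0, 65.0)
    male_frac_patients: float = 202 / 412
    male_frac_controls: float = 195 / 368
    icv: tuple[float, float] = (1.5e6, 1.5e5)          # mm^3
    education_patients: tuple[float, float] = (13.7, 2.8)
    education_controls: tuple[float, float] = (14.6, 3.1)
    ybocs: tuple[float, float] = (24.9, 6.2)
    age_onset: tuple[float, float] = (20.1, 8.7)
    n_medicated: float = 176
    n_depression: float = 101
    n_anxiety: float = 83
    # symptom-dimension lifetime prevalences (fractions of the observed
    # patient pool; 236/202/168/130/87 of 412 on the full sample)
    n_dims: tuple[float, ...] = (236 / 412, 202 / 412, 168 / 412, 130 / 412, 87 / 412)
    missing_clinical: int = 81       # patients with Y-BOCS + dimensions masked
    missing_depression: int = 24
    missing_anxiety: int = 139
    missing_medication: int = 14

    @property
    def n_patients(self) -> int:
        return int(sum(self.patients_per_site))

    @property
    def n_controls(self) -> int:
        return int(sum(self.controls_per_site))


def _resolve_quota(value: float, total: int, name: str) -> int:
    """A quota given as a count, or a prevalence in (0, 1) of ``total``."""
    value = float(value)
    if 0.0 < value < 1.0:
        return int(round(value * total))
    if value.is_integer() and 0 <= value <= total:
        return int(value)
    raise InvalidConfigError(f"{name}={value} is neither a prevalence in [0, 1] nor a count <= {total}")


def _validate(config: CohortConfig) -> None:
    if len(config.patients_per_site) != len(config.sites) or len(
        config.controls_per_site
    ) != len(config.sites):
        raise InvalidConfigError("per-site group sizes must match the site list")
    for frac, name in [
        (config.male_frac_patients, "male_frac_patients"),
        (config.male_frac_controls, "male_frac_controls"),
    ]:
        if not 0.0 <= frac <= 1.0:
            raise InvalidConfigError(f"{name}={frac} outside [0, 1]")


def _apportion(quota: int, site_sizes: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of an exact count across sites."""
    total = site_sizes.sum()
    share = quota * site_sizes / total
    base = np.floor(share).astype(int)
    rem = quota - base.sum()
    order = np.argsort(-(share - base), kind="stable")
    base[order[:rem]] += 1
    return np.minimum(base, site_sizes)


def _quota_fill(
    rng: np.random.Generator, quota: int, site_index: np.ndarray, n_sites: int
) -> np.ndarray:
    """0/1 vector over patients with exact per-site quotas, seeded subset."""
    out = np.zeros(len(site_index), dtype=float)
    sizes = np.bincount(site_index, minlength=n_sites)
    per_site = _apportion(quota, sizes)
    for s in range(n_sites):
        members = np.flatnonzero(site_index == s)
        chosen = rng.choice(members, size=per_site[s], replace=False)
        out[chosen] = 1.0
    return out


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Normal draws with out-of-range values redrawn (truncation)."""
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, bad.sum())
        bad = (x < lo) | (x > hi)
    return x


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate a cohort table; reproducible for a fixed (config, seed)."""
    config = config or CohortConfig()
    _validate(config)
    rng = np.random.default_rng(seed)

    rows_site, rows_dx = [], []
    for i, site in enumerate(config.sites):
        rows_site += [site] * (config.patients_per_site[i] + config.controls_per_site[i])
        rows_dx += [1] * config.patients_per_site[i] + [0] * config.controls_per_site[i]
    site = np.asarray(rows_site)
    dx = np.asarray(rows_dx, dtype=int)
    n = len(dx)
    pat = dx == 1

    df = pd.DataFrame(index=range(n), columns=COHORT_COLUMNS, dtype=object)
    df["subject_id"] = [f"sub{i + 1:04d}" for i in range(n)]
    df["site"] = site
    df["dx"] = dx

    age = np.empty(n)
    age[pat] = _truncnorm(rng, *config.age_patients, *config.age_bounds, pat.sum())
    age[~pat] = _truncnorm(rng, *config.age_controls, *config.age_bounds, (~pat).sum())
    df["age"] = np.round(age, 1)
    sex = np.empty(n)
    sex[pat] = rng.random(pat.sum()) < config.male_frac_patients
    sex[~pat] = rng.random((~pat).sum()) < config.male_frac_controls
    df["sex"] = sex.astype(int)
    df["icv"] = np.round(_truncnorm(rng, *config.icv, 8e5, 2.5e6, n), 0)
    edu = np.empty(n)
    edu[pat] = _truncnorm(rng, *config.education_patients, 6, 25, pat.sum())
    edu[~pat] = _truncnorm(rng, *config.education_controls, 6, 25, (~pat).sum())
    df["education"] = np.round(edu, 1)

    # clinical fields: patients only
    n_pat = pat.sum()
    ybocs = np.round(_truncnorm(rng, *config.ybocs, 0, 40, n_pat))
    onset = _truncnorm(rng, *config.age_onset, 6, 60, n_pat)
    onset = np.minimum(onset, age[pat])              # onset cannot postdate age
    clinical = pd.DataFrame(index=np.flatnonzero(pat))
    clinical["ybocs_total"] = ybocs
    clinical["age_onset"] = np.round(onset, 1)
    clinical["duration"] = np.round(age[pat] - clinical["age_onset"], 1)

    site_index = pd.Categorical(site[pat], categories=config.sites).codes
    n_sites = len(config.sites)

    # Availability masking is site-concentrated: sites drop out of a
    # clinical field from the last site backwards (emulating cohorts that
    # did not collect it), with a seeded partial subset in the boundary
    # site.  Quota counts then apply to the *observed* patients, so
    # subgroup n's match the configuration exactly after masking.
    def site_mask(count: int) -> np.ndarray:
        masked = np.zeros(n_pat, dtype=bool)
        for s in range(n_sites - 1, -1, -1):
            if count <= 0:
                break
            members = np.flatnonzero(site_index == s)
            if count >= len(members):
                masked[members] = True
                count -= len(members)
            else:
                masked[rng.choice(members, size=count, replace=False)] = True
                count = 0
        return masked

    def flag_column(quota_value: float, missing_count: int, name: str):
        masked = site_mask(missing_count)
        observed = ~masked
        quota = _resolve_quota(quota_value, int(observed.sum()), name)
        col = np.full(n_pat, np.nan)
        col[observed] = _quota_fill(
            rng, quota, site_index[observed], n_sites
        )
        return col, masked

    clinical["med"], _ = flag_column(config.n_medicated, config.missing_medication, "n_medicated")
    clinical["dep_lifetime"], _ = flag_column(
        config.n_depression, config.missing_depression, "n_depression"
    )
    clinical["anx_lifetime"], _ = flag_column(
        config.n_anxiety, config.missing_anxiety, "n_anxiety"
    )
    dims_masked = site_mask(config.missing_clinical)
    clinical.loc[clinical.index[dims_masked], "ybocs_total"] = np.nan
    observed = ~dims_masked
    for col, quota in zip(DIM_COLUMNS, config.n_dims):
        vals = np.full(n_pat, np.nan)
        vals[observed] = _quota_fill(
            rng, _resolve_quota(quota, int(observed.sum()), col), site_index[observed], n_sites
        )
        clinical[col] = vals

    for col in clinical.columns:
        df.loc[clinical.index, col] = clinical[col]
    # controls: unmedicated, comorbidity-free; other clinical fields missing
    ctrl_idx = np.flatnonzero(~pat)
    df.loc[ctrl_idx, ["med", "dep_lifetime", "anx_lifetime"]] = 0.0

    for col in df.columns:
        if col not in ("subject_id", "site"):
            df[col] = pd.to_numeric(df[col])
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
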