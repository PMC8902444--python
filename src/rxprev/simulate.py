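"""Synthetic prescription-registry generator.

Emulates a nationwide dispensing registry of the NorPD kind at the level the
downstream pipeline needs: longitudinal refill streams per patient per drug
group, an AChEI initiation process with a configurable persistent fraction, a
death process recorded at year+month resolution, institutionalization-style
dropout (hard cessation of all community dispensings), and a consistent
aggregate general-population table of drug users by calendar year x 1-year
age x sex.

Every simulated patient initiates AChEI treatment once (the real registry
extract covers exactly the people with at least one AChEI dispensing).  Drug
group use is drawn independently per patient per 365-day follow-up window,
so a window's configured probability is the exact Bernoulli parameter of the
"at least one matching dispensing in that window" indicator - which is what
the prevalence pipeline estimates.  A background stream of an unrelated drug
(pantoprazole) every ~90 days keeps every non-censored patient visible in
the registry, so the second-year registry-presence exclusion is independent
of use of the studied groups.
"""

from __future__ import annotations

import calendar
import datetime as dt
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import episodes
from .prevalence import WINDOWS

#: ATC codes used to realize each drug group, so that prefix matching is
#: exercised on real codes (e.g. betablockers are matched by the C07 prefix).
GROUP_CODES: Mapping[str, tuple[str, ...]] = {
    "haloperidol": ("N05AD01",),
    "citalopram_escitalopram": ("N06AB10", "N06AB04"),
    "verapamil": ("C08DA01",),
    "betablockers": ("C07AB02", "C07AB03", "C07AG02"),
    "digitalis": ("C01AA04", "C01AA05"),
    "diuretics": ("C03CA01", "C03AA03"),
}

#: AChEIs with market-share weights and daily unit-consumption rates.
ACHEI_DRUGS: tuple[tuple[str, float, int, str], ...] = (
    ("N06DA02", 0.74, 1, "tablet"),     # donepezil
    ("N06DA03", 0.16, 2, "capsule"),    # rivastigmine, two units/day
    ("N06DA04", 0.10, 1, "tablet"),     # galantamine
)

BACKGROUND_ATC = "A02BC01"  # pantoprazole: in none of the studied groups

#: General-population target spec: either a flat proportion, or a list of
#: (sex-or-None, age_lo, age_hi, proportion) bands, first match wins.
RateSpec = Union[float, Sequence[tuple[Optional[str], int, int, float]]]


class SimulationConfig(BaseModel):
    """Parameters of the synthetic registry.

    Defaults emulate the study conditions: calendar coverage 2004-2016,
    AChEI initiation 2008-2013, ~63% women, ages peaking around 80 at
    initiation, and per-window use probabilities of the studied drug groups
    at the order of magnitude seen in elderly Norwegians (betablockers
    ~30%, citalopram/escitalopram ~15%, digitalis ~3%, verapamil ~1.5%,
    haloperidol ~1%).
    """

    n_patients: int = Field(default=1000, ge=0)
    calendar_span: tuple[int, int] = (2004, 2016)
    achei_initiation_years: tuple[int, int] = (2008, 2013)
    sex_ratio_female: float = Field(default=0.63, ge=0.0, le=1.0)
    birth_year_distribution: Optional[dict[int, float]] = None
    drug_use_probability: dict[str, float] = Field(
        default_factory=lambda: {
            "betablockers": 0.30,
            "citalopram_escitalopram": 0.15,
            "digitalis": 0.03,
            "verapamil": 0.015,
            "haloperidol": 0.01,
        }
    )
    gp_prevalence: Optional[dict[str, RateSpec]] = None
    persistent_fraction: float = Field(default=0.85, ge=0.0, le=1.0)
    prior_use_fraction: float = Field(default=0.04, ge=0.0, le=1.0)
    institutionalization_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    refill_interval_days: tuple[int, int] = (75, 100)
    units_per_dispensation: tuple[int, int] = (90, 100)
    treatment_duration_days: tuple[int, int] = (400, 1100)
    annual_death_hazard: tuple[tuple[int, float], ...] = (
        (0, 0.002),
        (70, 0.02),
        (80, 0.06),
        (90, 0.15),
    )
    gp_cell_population: int = Field(default=1000, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        y0, y1 = self.calendar_span
        a0, a1 = self.achei_initiation_years
        if y0 > y1 or a0 > a1:
            raise ValueError("year ranges must be non-empty (start <= end)")
        if not (y0 <= a0 and a1 <= y1):
            raise ValueError("calendar_span must contain achei_initiation_years")
        for name, p in self.drug_use_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"drug_use_probability[{name!r}] must be in [0, 1]")
            if name not in GROUP_CODES:
                raise ValueError(f"no ATC codes registered for drug group {name!r}")
        for lo, hi in (self.refill_interval_days, self.units_per_dispensation,
                       self.treatment_duration_days):
            if lo < 1 or hi < lo:
                raise ValueError("integer ranges must satisfy 1 <= low <= high")
        for age, h in self.annual_death_hazard:
            if not 0.0 <= h <= 1.0:
                raise ValueError("death hazards must be probabilities")
        if self.birth_year_distribution is not None:
            if not self.birth_year_distribution:
                raise ValueError("birth_year_distribution must be non-empty")
            if any(w < 0 for w in self.birth_year_distribution.values()):
                raise ValueError("birth-year weights must be non-negative")
        return self


PATIENT_COLUMNS = ["patient_id", "sex", "birth_year", "death_year", "death_month"]
RECORD_COLUMNS = ["patient_id", "dispense_date", "atc_code", "n_units", "n_ddd", "formulation"]
POPULATION_COLUMNS = ["year", "age", "sex", "drug_group", "users", "population"]


def _default_birth_weights(config: SimulationConfig) -> dict[int, float]:
    # Ages at initiation roughly normal around 80 (sd 8): most initiators in
    # their 70s-80s, a tail above the 88-year cap to exercise the exclusion.
    mid_init = (config.achei_initiation_years[0] + config.achei_initiation_years[1]) // 2
    years = np.arange(mid_init - 98, mid_init - 39)
    ages = mid_init - years
    w = np.exp(-0.5 * ((ages - 80) / 8.0) ** 2)
    return dict(zip(years.tolist(), (w / w.sum()).tolist()))


def _hazard_at(age: int, bands: Sequence[tuple[int, float]]) -> float:
    h = 0.0
    for lo, hz in sorted(bands):
        if age >= lo:
            h = hz
    return h


def _month_end(year: int, month: int) -> dt.date:
    return dt.date(year, month, calendar.monthrange(year, month)[1])


def generate_registry(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (patients, dispensing records) as two data frames.

    Deterministic under a fixed seed.  No dispensing is dated after the end
    of the patient's death month, after an institutionalization cessation
    date, or outside the calendar span.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    span_start = dt.date(config.calendar_span[0], 1, 1)
    span_end = dt.date(config.calendar_span[1], 12, 31)

    patients: dict[str, list] = {c: [] for c in PATIENT_COLUMNS}
    rec: dict[str, list] = {c: [] for c in RECORD_COLUMNS}

    if n == 0:
        return _to_frames(patients, rec)

    a0, a1 = config.achei_initiation_years
    init_years = rng.integers(a0, a1 + 1, n)
    init_offsets = rng.integers(0, 365, n)
    sexes = np.where(rng.random(n) < config.sex_ratio_female, "F", "M")
    bw = config.birth_year_distribution or _default_birth_weights(config)
    b_years = np.array(sorted(bw))
    b_p = np.array([bw[y] for y in b_years], dtype=float)
    b_p = b_p / b_p.sum()
    birth_years = rng.choice(b_years, size=n, p=b_p)
    persistent = rng.random(n) < config.persistent_fraction
    prior_use = rng.random(n) < config.prior_use_fraction
    dropout = rng.random(n) < config.institutionalization_fraction
    achei_idx = rng.choice(len(ACHEI_DRUGS), size=n, p=[d[1] for d in ACHEI_DRUGS])

    groups = sorted(config.drug_use_probability)
    # Per-window use indicators, drawn independently per group and window.
    window_keys = sorted(WINDOWS)
    use_flags = {
        g: rng.random((n, len(window_keys))) < config.drug_use_probability[g]
        for g in groups
    }

    r_lo, r_hi = config.refill_interval_days
    u_lo, u_hi = config.units_per_dispensation
    d_lo, d_hi = config.treatment_duration_days

    for i in range(n):
        pid = f"P{i:06d}"
        index_date = dt.date(int(init_years[i]), 1, 1) + dt.timedelta(days=int(init_offsets[i]))
        birth_year = int(birth_years[i])

        # Death process: yearly Bernoulli at the age-band hazard from the
        # initiation year onward; the month is uniform.
        death_year: Optional[int] = None
        death_month: Optional[int] = None
        for y in range(int(init_years[i]), config.calendar_span[1] + 1):
            if rng.random() < _hazard_at(y - birth_year, config.annual_death_hazard):
                death_year, death_month = y, int(rng.integers(1, 13))
                break

        trunc = span_end
        if death_year is not None:
            trunc = min(trunc, _month_end(death_year, death_month))
        if dropout[i]:
            trunc = min(trunc, index_date + dt.timedelta(days=int(rng.integers(0, 365))))

        atc, _, rate, formulation = ACHEI_DRUGS[int(achei_idx[i])]

        # --- AChEI stream (constructed pre-censoring, then truncated) ---
        stream: list[tuple[int, int]] = []  # (day offset from index, n_units)
        if persistent[i]:
            duration = int(rng.integers(d_lo, d_hi + 1))
            t = 0
            while t <= duration:
                stream.append((t, int(rng.integers(u_lo, u_hi + 1)) * rate))
                t += int(rng.integers(r_lo, r_hi + 1))
            if not _stream_is_persistent(stream, index_date, atc):
                stream.append((220, 90 * rate))
                stream.sort()
        else:
            # A single small dispensing violates all three rules: no refill in
            # [210, 240], under 210 days of total supply, supply ends < 210.
            u_days = min(int(rng.integers(u_lo, u_hi + 1)), 150)
            stream.append((0, u_days * rate))

        if prior_use[i]:
            # Earlier incident use 2-4 years before index, separated from the
            # index period by far more than the 365-day washout.
            back = int(rng.integers(731 + 90, 1461))
            stream.insert(0, (-back, 30 * rate))

        for day, units in stream:
            date = index_date + dt.timedelta(days=day)
            if date < span_start or date > trunc:
                continue
            _push(rec, pid, date, atc, units, units / rate, formulation)

        # --- background stream: keeps the patient registry-visible ---
        day = -1460
        while day <= 729:
            date = index_date + dt.timedelta(days=day)
            if span_start <= date <= trunc:
                _push(rec, pid, date, BACKGROUND_ATC, 100, 100.0, "tablet")
            day += 90

        # --- studied drug groups, per follow-up window ---
        for g in groups:
            codes = GROUP_CODES[g]
            for j, w in enumerate(window_keys):
                if not use_flags[g][i, j]:
                    continue
                lo, hi = WINDOWS[w]
                offset = int(rng.integers(lo, hi + 1))
                date = index_date + dt.timedelta(days=offset)
                if date < span_start or date > trunc:
                    continue
                if g == "digitalis":
                    # digitoxin was the Norwegian standard until it was
                    # replaced by digoxin around 2011
                    code = "C01AA04" if date.year < 2011 else "C01AA05"
                else:
                    code = codes[int(rng.integers(0, len(codes)))]
                units = int(rng.integers(30, 101))
                _push(rec, pid, date, code, units, float(units), "tablet")

        patients["patient_id"].append(pid)
        patients["sex"].append(str(sexes[i]))
        patients["birth_year"].append(birth_year)
        patients["death_year"].append(death_year)
        patients["death_month"].append(death_month)

    return _to_frames(patients, rec)


def _stream_is_persistent(stream: list[tuple[int, int]], index_date: dt.date, atc: str) -> bool:
    disp = [
        episodes.Dispensing(index_date + dt.timedelta(days=d), atc, u)
        for d, u in sorted(stream)
    ]
    periods = episodes.build_use_periods(disp)
    period = episodes.select_index_period(periods)
    return episodes.classify_persistent(period)[0]


def _push(rec: dict, pid: str, date: dt.date, atc: str, units: int, ddd: float, form: str) -> None:
    rec["patient_id"].append(pid)
    rec["dispense_date"].append(date)
    rec["atc_code"].append(atc)
    rec["n_units"].append(int(units))
    rec["n_ddd"].append(round(float(ddd), 2))
    rec["formulation"].append(form)


def _to_frames(patients: dict, rec: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    pdf = pd.DataFrame(patients)
    pdf["death_year"] = pdf["death_year"].astype("Int64") if len(pdf) else pdf.get("death_year")
    pdf["death_month"] = pdf["death_month"].astype("Int64") if len(pdf) else pdf.get("death_month")
    rdf = pd.DataFrame(rec)
    rdf["dispense_date"] = pd.to_datetime(rdf["dispense_date"]) if len(rdf) else pd.Series(dtype="datetime64[ns]")
    rdf = rdf.sort_values(["patient_id", "dispense_date", "atc_code"], kind="stable").reset_index(drop=True)
    return pdf, rdf


def _resolve_rate(spec, sex: str, age: int) -> float:
    if isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "__product__":
        return _resolve_rate(spec[1], sex, age) * _resolve_rate(spec[2], sex, age)
    if isinstance(spec, (int, float)):
        return float(spec)
    for band_sex, lo, hi, rate in spec:
        if (band_sex is None or band_sex == sex) and lo <= age <= hi:
            return float(rate)
    return 0.0


def generate_population_counts(
    config: SimulationConfig,
    target_prevalence: Optional[Mapping[str, RateSpec]] = None,
) -> pd.DataFrame:
    """Aggregate general-population users/population by year x age x sex x group.

    ``users = round(population * target)`` per cell; ages run 0-89 (the
    1-year resolution available for the general population stops at 89).
    ``target_prevalence`` maps drug-group name to either a flat proportion or
    age/sex bands; it defaults to ``config.gp_prevalence`` and then to the
    study-population window probabilities (prevalence ratio 1).
    """
    if target_prevalence is None:
        target_prevalence = config.gp_prevalence or dict(config.drug_use_probability)
    # Concomitant-use "groups": drug use is drawn independently in the study
    # population, so the consistent joint target is the product of the
    # component targets.  Emitted as ordinary drug_group rows named "a+b".
    targets: dict[str, object] = dict(target_prevalence)
    for a, b in (("betablockers", "citalopram_escitalopram"), ("verapamil", "citalopram_escitalopram")):
        name = f"{a}+{b}"
        if a in targets and b in targets and name not in targets:
            targets[name] = ("__product__", targets[a], targets[b])
    rows: dict[str, list] = {c: [] for c in POPULATION_COLUMNS}
    years = range(config.calendar_span[0], config.calendar_span[1] + 1)
    pop = config.gp_cell_population
    for group, spec in targets.items():
        for year in years:
            for sex in ("F", "M"):
                for age in range(0, 90):
                    rate = _resolve_rate(spec, sex, age)
                    if not 0.0 <= rate <= 1.0:
                        raise ValueError(
                            f"target prevalence for {group!r} at ({sex}, {age}) is {rate}, outside [0, 1]"
                        )
                    rows["year"].append(year)
                    rows["age"].append(age)
                    rows["sex"].append(sex)
                    rows["drug_group"].append(group)
                    rows["users"].append(int(round(pop * rate)))
                    rows["population"].append(pop)
    return pd.DataFrame(rows)
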