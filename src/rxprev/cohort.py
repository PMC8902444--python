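"""Inclusion/exclusion cascade for the persistent new-user cohort.

Candidates are all patients with at least one AChEI dispensing.  For each,
use periods are built from the AChEI stream, the index period is selected,
and the cascade below is applied; the first failing check is logged as the
exclusion reason:

1. ``not_incident`` - index date before the earliest date at which the
   365-day washout can be verified (one year after data start);
2. ``index_outside_window`` - index date outside the inclusion window
   (default 2008-01-01 to 2013-12-31, so that 4 years of pre-index and
   2 years of post-index data exist);
3. ``over_age_cap`` - age at index (index year minus birth year) above the
   cap (default 88, set by the general-population table ending at age 89);
4. ``died_within_2y`` - death year at most two calendar years after the
   initiation year;
5. ``absent_from_registry_y2`` - no dispensing of any drug in days
   [365, 729] after index (e.g. moved to a nursing home, whose dispensings
   a community-pharmacy registry does not capture);
6. ``not_persistent`` - none of the three refill-pattern persistence rules
   holds for the index period.

The censoring exclusions (death, registry absence) run before the
persistence check: a dispensing stream cut short by death or
institutionalization cannot be classified by refill rules, and attributing
such patients to non-persistence would mislabel them.

Members are stratified into two age groups, at and under 80 versus 81-88.
No lower age bound is enforced.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import episodes

EXCLUSION_REASONS = (
    "not_incident",
    "index_outside_window",
    "over_age_cap",
    "died_within_2y",
    "absent_from_registry_y2",
    "not_persistent",
)

AGE_GROUP_YOUNG = "37-80"
AGE_GROUP_OLD = "81-88"

MEMBER_COLUMNS = [
    "patient_id", "sex", "birth_year", "index_date", "age_at_index",
    "age_group", "n_prescriptions", "treatment_length",
]


def age_group_label(age: int) -> str:
    return AGE_GROUP_YOUNG if age <= 80 else AGE_GROUP_OLD


def select_cohort(
    patients: pd.DataFrame,
    records: pd.DataFrame,
    *,
    gap_days: int = 365,
    rates: Optional[Mapping[str, float]] = None,
    index_window: tuple[dt.date, dt.date] = (dt.date(2008, 1, 1), dt.date(2013, 12, 31)),
    earliest_index_date: dt.date = dt.date(2005, 1, 1),
    age_cap: int = 88,
    horizon_days: int = 240,
    rule_day: int = 210,
    registry_window: tuple[int, int] = (365, 729),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cascade; returns (members, exclusion log) data frames.

    ``patients`` and ``records`` follow the canonical registry schema with
    ``dispense_date`` as datetime64.  Every patient with an AChEI dispensing
    lands in exactly one of the two outputs.
    """
    if records.empty:
        return (
            pd.DataFrame(columns=MEMBER_COLUMNS),
            pd.DataFrame(columns=["patient_id", "reason"]),
        )

    pat = patients.set_index("patient_id")
    achei_mask = records["atc_code"].str.startswith(episodes.ACHEI_PREFIX)
    achei = records.loc[achei_mask].sort_values(["patient_id", "dispense_date"], kind="stable")

    # all dispensing dates per patient (for the registry-presence check)
    all_dates = {
        pid: np.sort(g.to_numpy())
        for pid, g in records.groupby("patient_id")["dispense_date"]
    }

    members: list[dict] = []
    exclusions: list[dict] = []

    for pid, g in achei.groupby("patient_id", sort=True):
        disp = [
            episodes.Dispensing(date=d.date(), atc_code=a, n_units=int(u))
            for d, a, u in zip(g["dispense_date"], g["atc_code"], g["n_units"])
        ]
        periods = episodes.build_use_periods(disp, gap_days=gap_days, rates=rates)
        index_period = episodes.select_index_period(periods)
        index_date = index_period.start_date
        row = pat.loc[pid]
        birth_year = int(row["birth_year"])
        age = index_date.year - birth_year

        reason = None
        if index_date < earliest_index_date:
            reason = "not_incident"
        elif not (index_window[0] <= index_date <= index_window[1]):
            reason = "index_outside_window"
        elif age > age_cap:
            reason = "over_age_cap"
        elif pd.notna(row["death_year"]) and int(row["death_year"]) <= index_date.year + 2:
            reason = "died_within_2y"
        else:
            dates = all_dates[pid]
            lo = np.datetime64(index_date + dt.timedelta(days=registry_window[0]))
            hi = np.datetime64(index_date + dt.timedelta(days=registry_window[1]))
            i = np.searchsorted(dates, lo, side="left")
            if i >= len(dates) or dates[i] > hi:
                reason = "absent_from_registry_y2"
            elif not episodes.classify_persistent(index_period, horizon_days, rule_day, rates)[0]:
                reason = "not_persistent"

        if reason is not None:
            exclusions.append({"patient_id": pid, "reason": reason})
        else:
            members.append(
                {
                    "patient_id": pid,
                    "sex": row["sex"],
                    "birth_year": birth_year,
                    "index_date": pd.Timestamp(index_date),
                    "age_at_index": age,
                    "age_group": age_group_label(age),
                    "n_prescriptions": index_period.n_prescriptions,
                    "treatment_length": episodes.treatment_length(index_period),
                }
            )

    members_df = pd.DataFrame(members, columns=MEMBER_COLUMNS)
    exclusions_df = pd.DataFrame(exclusions, columns=["patient_id", "reason"])
    return members_df, exclusions_df


def summarize_cohort(members: pd.DataFrame) -> pd.DataFrame:
    """Counts by sex x age group with percent female, plus an overall row."""
    if members.empty:
        return pd.DataFrame(columns=["age_group", "n", "n_female", "n_male", "pct_female"])
    rows = []
    strata = list(members["age_group"].drop_duplicates().sort_values()) + ["all"]
    for ag in strata:
        sub = members if ag == "all" else members[members["age_group"] == ag]
        n = len(sub)
        nf = int((sub["sex"] == "F").sum())
        rows.append(
            {
                "age_group": ag,
                "n": n,
                "n_female": nf,
                "n_male": n - nf,
                "pct_female": 100.0 * nf / n,
            }
        )
    return pd.DataFrame(rows)
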