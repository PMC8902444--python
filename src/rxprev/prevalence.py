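"""Windowed prevalence of drug-group use around the index date.

Follow-up runs from 1,460 days (4 years) before the index date to 729 days
(2 years) after, cut into six fixed 365-day windows labelled -4, -3, -2, -1,
+1, +2.  For each window and stratum the quantity of interest is the
proportion of cohort members who filled at least one prescription matching a
drug group (prefix match on the ATC code), with a Wilson score 95% CI.
Cells with fewer than five users are flagged for suppression at reporting
time; the underlying counts are kept for standardization.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

#: Window ordinal -> (first day, last day) relative to the index date (day 0).
#: The six windows partition [-1460, 729]; window +1 is days 0-364.
WINDOWS: Mapping[int, tuple[int, int]] = {
    -4: (-1460, -1096),
    -3: (-1095, -731),
    -2: (-730, -366),
    -1: (-365, -1),
    1: (0, 364),
    2: (365, 729),
}

_FULL_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
_PARTIAL_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")


@dataclass(frozen=True)
class DrugGroup:
    """A named set of ATC prefixes; membership is prefix-based."""

    name: str
    prefixes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.prefixes:
            raise ValueError("a drug group needs at least one ATC prefix")
        for p in self.prefixes:
            if not _PARTIAL_ATC_RE.match(p):
                raise ValueError(f"invalid ATC prefix {p!r}")

    @staticmethod
    def union(name: str, groups: Sequence["DrugGroup"]) -> "DrugGroup":
        prefixes = tuple(dict.fromkeys(itertools.chain.from_iterable(g.prefixes for g in groups)))
        return DrugGroup(name=name, prefixes=prefixes)


#: The five studied groups: haloperidol and citalopram/escitalopram carry a
#: known Torsades-de-Pointes risk; verapamil, betablockers and the digitalis
#: glycosides lower heart rate.
DEFAULT_GROUPS: tuple[DrugGroup, ...] = (
    DrugGroup("haloperidol", ("N05AD01",)),
    DrugGroup("citalopram_escitalopram", ("N06AB10", "N06AB04")),
    DrugGroup("verapamil", ("C08DA01",)),
    DrugGroup("betablockers", ("C07",)),
    DrugGroup("digitalis", ("C01A",)),
)

#: The two studied concomitant-use pairs.
DEFAULT_COMBINATIONS: tuple[tuple[str, str], ...] = (
    ("betablockers", "citalopram_escitalopram"),
    ("verapamil", "citalopram_escitalopram"),
)


def match_group(atc_code: str, group: DrugGroup) -> bool:
    """True iff any of the group's prefixes is a prefix of the full ATC code."""
    if not isinstance(atc_code, str) or not _FULL_ATC_RE.match(atc_code):
        raise ValueError(f"malformed ATC code {atc_code!r}")
    return any(atc_code.startswith(p) for p in group.prefixes)


def wilson_ci(n_users: int, n_total: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1].

    With x successes out of n, z the normal quantile for the chosen
    confidence: center = (x + z^2/2)/(n + z^2),
    halfwidth = z*sqrt(x(n-x)/n + z^2/4)/(n + z^2).  The bounds are exactly
    0 at x = 0 and exactly 1 at x = n.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_users <= n_total:
        raise ValueError("need 0 <= n_users <= n_total")
    x, n = float(n_users), float(n_total)
    z = norm.ppf(0.5 + confidence / 2.0)
    center = (x + z * z / 2.0) / (n + z * z)
    halfwidth = z * np.sqrt(x * (n - x) / n + z * z / 4.0) / (n + z * z)
    low = 0.0 if n_users == 0 else max(center - halfwidth, 0.0)
    high = 1.0 if n_users == n_total else min(center + halfwidth, 1.0)
    return float(low), float(high)


def assign_windows(day_offsets: pd.Series, windows: Mapping[int, tuple[int, int]] = WINDOWS) -> pd.Series:
    """Map integer day offsets from the index date to window ordinals (NaN outside)."""
    conditions = [(day_offsets >= lo) & (day_offsets <= hi) for lo, hi in windows.values()]
    return pd.Series(
        np.select(conditions, list(windows.keys()), default=np.nan),
        index=day_offsets.index,
    )


def _user_window_pairs(
    members: pd.DataFrame,
    records: pd.DataFrame,
    group: DrugGroup,
    windows: Mapping[int, tuple[int, int]],
) -> pd.DataFrame:
    """Distinct (patient_id, window) pairs with >=1 dispensing matching ``group``."""
    codes = records["atc_code"]
    mask = np.zeros(len(records), dtype=bool)
    for p in group.prefixes:
        mask |= codes.str.startswith(p).to_numpy()
    hits = records.loc[mask, ["patient_id", "dispense_date"]]
    merged = hits.merge(members[["patient_id", "index_date"]], on="patient_id", how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["patient_id", "window"])
    day = (merged["dispense_date"] - merged["index_date"]).dt.days
    merged["window"] = assign_windows(day, windows)
    merged = merged.dropna(subset=["window"])
    merged["window"] = merged["window"].astype(int)
    return merged[["patient_id", "window"]].drop_duplicates()


def _cells_from_pairs(
    members: pd.DataFrame,
    pairs: pd.DataFrame,
    group_name: str,
    windows: Mapping[int, tuple[int, int]],
    by: Sequence[str],
    suppression_threshold: int,
    confidence: float,
) -> pd.DataFrame:
    members = members.copy()
    if not by:
        members["stratum"] = "all"
        by = ("stratum",)
        strata = pd.DataFrame({"stratum": ["all"]})
    else:
        strata = members[list(by)].drop_duplicates()

    totals = members.groupby(list(by), observed=True).size().rename("n_total").reset_index()
    flagged = pairs.merge(members[["patient_id", *by]], on="patient_id", how="inner")
    counts = (
        flagged.groupby(["window", *by], observed=True)["patient_id"]
        .nunique()
        .rename("n_users")
        .reset_index()
    )

    grid = strata.merge(pd.DataFrame({"window": list(windows.keys())}), how="cross")
    cells = grid.merge(counts, on=["window", *by], how="left").fillna({"n_users": 0})
    cells["n_users"] = cells["n_users"].astype(int)
    cells = cells.merge(totals, on=list(by), how="left")
    cells["drug_group"] = group_name
    cells["proportion"] = cells["n_users"] / cells["n_total"]
    bounds = [wilson_ci(u, t, confidence) for u, t in zip(cells["n_users"], cells["n_total"])]
    cells["ci_low"] = [b[0] for b in bounds]
    cells["ci_high"] = [b[1] for b in bounds]
    cells["suppressed"] = cells["n_users"] < suppression_threshold
    order = ["drug_group", *by, "window"]
    return cells.sort_values(order, kind="stable").reset_index(drop=True)[
        ["drug_group", *by, "window", "n_users", "n_total", "proportion", "ci_low", "ci_high", "suppressed"]
    ]


def window_prevalence(
    members: pd.DataFrame,
    records: pd.DataFrame,
    group: DrugGroup,
    windows: Mapping[int, tuple[int, int]] = WINDOWS,
    by: Sequence[str] = ("sex", "age_group"),
    suppression_threshold: int = 5,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-window proportion of members with >=1 dispensing matching ``group``.

    ``members`` needs columns ``patient_id``, ``index_date`` and the ``by``
    stratifiers; ``records`` needs ``patient_id``, ``dispense_date``,
    ``atc_code`` (dates as datetime64).  Returns one row per
    window x stratum with user count, denominator, proportion, Wilson CI and
    suppression flag.  The denominator is the fixed stratum size: the cohort
    is a closed persistent-survivor population, so every member contributes
    to all six windows.
    """
    if members.empty:
        return _empty_cells(by)
    pairs = _user_window_pairs(members, records, group, windows)
    return _cells_from_pairs(members, pairs, group.name, windows, tuple(by), suppression_threshold, confidence)


def combination_prevalence(
    members: pd.DataFrame,
    records: pd.DataFrame,
    group_a: DrugGroup,
    group_b: DrugGroup,
    windows: Mapping[int, tuple[int, int]] = WINDOWS,
    by: Sequence[str] = ("sex", "age_group"),
    suppression_threshold: int = 5,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Concomitant use: >=1 dispensing of each group within the same window."""
    if members.empty:
        return _empty_cells(by)
    pairs_a = _user_window_pairs(members, records, group_a, windows)
    pairs_b = _user_window_pairs(members, records, group_b, windows)
    both = pairs_a.merge(pairs_b, on=["patient_id", "window"], how="inner")
    name = f"{group_a.name}+{group_b.name}" if group_a.name != group_b.name else group_a.name
    return _cells_from_pairs(members, both, name, windows, tuple(by), suppression_threshold, confidence)


def any_of_groups_prevalence(
    members: pd.DataFrame,
    records: pd.DataFrame,
    groups: Sequence[DrugGroup],
    windows: Mapping[int, tuple[int, int]] = WINDOWS,
    by: Sequence[str] = ("sex", "age_group"),
    suppression_threshold: int = 5,
    confidence: float = 0.95,
    name: str = "any_of_groups",
) -> pd.DataFrame:
    """Proportion with >=1 dispensing in the union of the given groups."""
    union = DrugGroup.union(name, list(groups))
    return window_prevalence(members, records, union, windows, by, suppression_threshold, confidence)


def _empty_cells(by: Sequence[str]) -> pd.DataFrame:
    cols = ["drug_group", *(by or ("stratum",)), "window", "n_users", "n_total",
            "proportion", "ci_low", "ci_high", "suppressed"]
    return pd.DataFrame(columns=cols)
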