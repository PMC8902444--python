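"""Year-shifted direct age standardization and prevalence ratios.

The general population cannot be followed longitudinally the way the cohort
can, so drug use in a follow-up window X years away from the index year is
compared with the general population with both calendar year and age shifted
accordingly.  Windows -4..-1 shift years and ages by -4..-1; the first
post-index year is the initiation year itself (shift 0) and the second
post-index year shifts by +1.  For example, use in the 81-88 age group four
years before initiation (initiations 2008-2013) is compared with the 77- to
84-year-olds in 2004-2009, and use in the second year after with the 82- to
89-year-olds in 2009-2014.

For each initiation year y the general-population rate is directly
standardized to the age distribution of that year's initiators (weights as
counts): u_y = sum_a w_a * rate(y+shift, a+shift), N_y = sum_a w_a, and the
pooled adjusted prevalence over initiation years is sum_y u_y / sum_y N_y.
The prevalence ratio divides the cohort proportion by this adjusted value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Window ordinal -> year/age shift applied to the general population.
WINDOW_SHIFT: Mapping[int, int] = {-4: -4, -3: -3, -2: -2, -1: -1, 1: 0, 2: 1}

MAX_GP_AGE = 89  # 1-year age resolution in the population table stops here


def comparison_cells(
    window: int, ages: Iterable[int], initiation_years: Iterable[int]
) -> set[tuple[int, int]]:
    """The (calendar year, age) cells of the general population that a window
    is compared against, given initiator ages and initiation years."""
    shift = WINDOW_SHIFT[window]
    return {
        (y + shift, a + shift)
        for y in initiation_years
        for a in ages
        if 0 <= a + shift <= MAX_GP_AGE
    }


@dataclass(frozen=True)
class AdjustedPrevalence:
    """Age-adjusted general-population prevalence for one window/sex/group."""

    sex: str
    window: int
    drug_group: str
    value: float
    components: tuple[tuple[int, float, float], ...]  # (initiation year, u_y, N_y)


class PopulationTable:
    """Rate lookup over the long-format population-counts frame."""

    def __init__(self, population: pd.DataFrame):
        self._years = set(population["year"].unique().tolist())
        key = population.set_index(["year", "age", "sex", "drug_group"])
        self._users = key["users"].to_dict()
        self._pop = key["population"].to_dict()

    @property
    def years(self) -> set[int]:
        return self._years

    def rate(self, year: int, age: int, sex: str, group: str) -> float:
        if year not in self._years:
            raise KeyError(f"population table has no data for calendar year {year}")
        k = (year, age, sex, group)
        if k not in self._pop:
            raise KeyError(f"population table has no cell for {k}")
        return self._users[k] / self._pop[k]


def age_adjust_one_year(
    pop: PopulationTable | pd.DataFrame,
    ref: Mapping[int, float] | pd.Series,
    year: int,
    shift: int,
    sex: str,
    group: str,
) -> tuple[float, float]:
    """Directly standardized (u_y, N_y) for one initiation year.

    ``ref`` maps initiator age to a non-negative weight (a count of
    initiators).  Ages that shift outside [0, 89] are dropped from both sums
    (renormalization) with a logged warning.
    """
    if isinstance(pop, pd.DataFrame):
        pop = PopulationTable(pop)
    ref = dict(ref.items() if hasattr(ref, "items") else ref)
    u_y = 0.0
    n_y = 0.0
    dropped = []
    for age, weight in sorted(ref.items()):
        if weight < 0:
            raise ValueError("reference weights must be non-negative")
        if weight == 0:
            continue
        shifted = age + shift
        if not 0 <= shifted <= MAX_GP_AGE:
            dropped.append(age)
            continue
        u_y += weight * pop.rate(year + shift, shifted, sex, group)
        n_y += weight
    if dropped:
        logger.warning(
            "age_adjust_one_year(year=%d, shift=%+d, sex=%s, group=%s): "
            "dropped reference ages %s shifting outside [0, %d]; remaining weight renormalized",
            year, shift, sex, group, dropped, MAX_GP_AGE,
        )
    return u_y, n_y


def adjusted_prevalence(
    pop: PopulationTable | pd.DataFrame,
    ref_by_year: Mapping[int, Mapping[int, float]],
    window: int,
    sex: str,
    group: str,
    initiation_years: Sequence[int] = tuple(range(2008, 2014)),
) -> AdjustedPrevalence:
    """Pooled adjusted prevalence sum_y u_y / sum_y N_y over initiation years.

    ``ref_by_year`` maps each initiation year to that year's initiator age
    distribution (for the sex and age stratum at hand).  Raises if the
    population table lacks a needed (shifted) calendar year.
    """
    if isinstance(pop, pd.DataFrame):
        pop = PopulationTable(pop)
    shift = WINDOW_SHIFT[window]
    components = []
    for y in initiation_years:
        if (y + shift) not in pop.years:
            raise KeyError(
                f"population table is missing calendar year {y + shift} "
                f"(initiation year {y}, window {window:+d})"
            )
        ref = ref_by_year.get(y, {})
        u_y, n_y = age_adjust_one_year(pop, ref, y, shift, sex, group)
        components.append((y, u_y, n_y))
    total_n = sum(c[2] for c in components)
    value = sum(c[1] for c in components) / total_n if total_n > 0 else float("nan")
    return AdjustedPrevalence(
        sex=sex, window=window, drug_group=group, value=value, components=tuple(components)
    )


def prevalence_ratio(sp_proportion: float, gp: AdjustedPrevalence | float) -> float | None:
    """Cohort proportion divided by the adjusted general-population value.

    Returns None when the general-population prevalence is zero or undefined.
    """
    value = gp.value if isinstance(gp, AdjustedPrevalence) else float(gp)
    if not value > 0:
        return None
    return sp_proportion / value


def reference_distributions(
    members: pd.DataFrame, sex: str, age_group: str | None = None
) -> dict[int, dict[int, float]]:
    """Initiator age counts per initiation year for a sex (and age stratum).

    These are the direct-standardization weights ("the actual year as
    reference"): the age distribution of the cohort members of that sex who
    initiated in that calendar year.
    """
    sub = members[members["sex"] == sex]
    if age_group is not None:
        sub = sub[sub["age_group"] == age_group]
    out: dict[int, dict[int, float]] = {}
    years = pd.DatetimeIndex(sub["index_date"]).year
    for (year, age), n in sub.groupby([years, sub["age_at_index"]]).size().items():
        out.setdefault(int(year), {})[int(age)] = float(n)
    return out


def gp_prevalence_table(
    population: pd.DataFrame,
    members: pd.DataFrame,
    groups: Sequence[str],
    windows: Sequence[int] = tuple(WINDOW_SHIFT),
    by_age_group: bool = True,
    initiation_years: Sequence[int] = tuple(range(2008, 2014)),
) -> pd.DataFrame:
    """Adjusted GP prevalence for every window x sex (x age group) x group.

    Strata without members are skipped.  Only groups present in the
    population table are computable; others raise via the rate lookup.
    """
    pop = PopulationTable(population)
    rows = []
    sexes = sorted(members["sex"].unique()) if len(members) else []
    age_groups = sorted(members["age_group"].unique()) if by_age_group else [None]
    for sex in sexes:
        for ag in age_groups:
            ref_by_year = reference_distributions(members, sex, ag)
            if not any(ref_by_year.values()):
                continue
            for group in groups:
                for w in windows:
                    ap = adjusted_prevalence(pop, ref_by_year, w, sex, group, initiation_years)
                    rows.append(
                        {
                            "drug_group": group,
                            "sex": sex,
                            "age_group": ag if ag is not None else "all",
                            "window": w,
                            "gp_prevalence": ap.value,
                        }
                    )
    return pd.DataFrame(rows, columns=["drug_group", "sex", "age_group", "window", "gp_prevalence"])
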