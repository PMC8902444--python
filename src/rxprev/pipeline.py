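"""End-to-end analysis: cohort -> windowed prevalence -> standardization.

``run_analysis`` is the library entry point the CLI wraps: it takes the three
registry frames and a :class:`~rxprev.config.PipelineConfig` and returns all
result tables, including a merged report with, per drug group x sex x age
group x window, the cohort proportion, the year-shifted age-adjusted
general-population proportion, and their ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cohort import select_cohort, summarize_cohort
from .config import PipelineConfig
from .prevalence import (
    DrugGroup,
    any_of_groups_prevalence,
    combination_prevalence,
    window_prevalence,
)
from .standardize import gp_prevalence_table

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    members: pd.DataFrame
    exclusions: pd.DataFrame
    cohort_summary: pd.DataFrame
    prevalence: pd.DataFrame          # single groups, long format
    combinations: pd.DataFrame        # concomitant-use pairs, long format
    any_of_groups: pd.DataFrame       # union of the single groups
    gp_adjusted: pd.DataFrame         # adjusted GP prevalence, long format
    table1: pd.DataFrame              # merged Prop SP / Prop GP / Ratio

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "cohort": self.members,
            "exclusions": self.exclusions,
            "cohort_summary": self.cohort_summary,
            "prevalence": self.prevalence,
            "combinations": self.combinations,
            "any_of_groups": self.any_of_groups,
            "gp_adjusted": self.gp_adjusted,
            "table1": self.table1,
        }


def _groups(config: PipelineConfig) -> dict[str, DrugGroup]:
    return {name: DrugGroup(name, tuple(prefixes)) for name, prefixes in config.drug_groups.items()}


def run_analysis(
    patients: pd.DataFrame,
    records: pd.DataFrame,
    population: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    config = config or PipelineConfig()
    groups = _groups(config)

    members, exclusions = select_cohort(
        patients,
        records,
        gap_days=config.gap_days,
        rates=config.daily_rates,
        index_window=(config.index_window_start, config.index_window_end),
        earliest_index_date=config.earliest_index_date,
        age_cap=config.age_cap,
        horizon_days=config.horizon_days,
        rule_day=config.rule_day,
        registry_window=config.registry_presence_window,
    )
    logger.info(
        "cohort: %d members, %d excluded (of %d AChEI-ever candidates)",
        len(members), len(exclusions), len(members) + len(exclusions),
    )
    if members.empty:
        logger.warning("empty cohort: all result tables will be empty")

    summary = summarize_cohort(members)

    kwargs = dict(
        by=("sex", "age_group"),
        suppression_threshold=config.suppression_threshold,
        confidence=config.confidence,
    )
    prevalence = pd.concat(
        [window_prevalence(members, records, g, **kwargs) for g in groups.values()],
        ignore_index=True,
    ) if not members.empty else window_prevalence(members, records, next(iter(groups.values())), **kwargs)
    logger.info("prevalence: %d cells over %d groups", len(prevalence), len(groups))

    combo_frames = []
    for a, b in config.combinations:
        combo_frames.append(combination_prevalence(members, records, groups[a], groups[b], **kwargs))
    combos = pd.concat(combo_frames, ignore_index=True) if combo_frames else prevalence.iloc[0:0]

    union = any_of_groups_prevalence(
        members, records, list(groups.values()), name="any_of_" + "_".join(groups), **kwargs
    )

    # GP side: single groups plus combination groups, provided the population
    # table carries them (combination rows are optional).
    gp_group_names = list(groups)
    available = set(population["drug_group"].unique()) if len(population) else set()
    combo_names = [f"{a}+{b}" for a, b in config.combinations if f"{a}+{b}" in available]
    gp = gp_prevalence_table(
        population,
        members,
        [g for g in gp_group_names if g in available] + combo_names,
        initiation_years=config.initiation_years,
    ) if not members.empty and len(population) else pd.DataFrame(
        columns=["drug_group", "sex", "age_group", "window", "gp_prevalence"]
    )

    sp = pd.concat([prevalence, combos], ignore_index=True) if len(prevalence) or len(combos) else prevalence
    table1 = sp.merge(gp, on=["drug_group", "sex", "age_group", "window"], how="left")
    table1["prevalence_ratio"] = table1["proportion"] / table1["gp_prevalence"]
    table1 = table1.rename(columns={"proportion": "prop_sp", "gp_prevalence": "prop_gp"})[
        ["drug_group", "sex", "age_group", "window", "n_users", "n_total",
         "prop_sp", "ci_low", "ci_high", "suppressed", "prop_gp", "prevalence_ratio"]
    ]

    return AnalysisResult(
        members=members,
        exclusions=exclusions,
        cohort_summary=summary,
        prevalence=prevalence,
        combinations=combos,
        any_of_groups=union,
        gp_adjusted=gp,
        table1=table1,
    )
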