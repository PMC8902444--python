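"""ATC matching, Wilson intervals, windowed and combination prevalence."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

from rxprev.prevalence import (
    DEFAULT_GROUPS,
    WINDOWS,
    DrugGroup,
    any_of_groups_prevalence,
    combination_prevalence,
    match_group,
    wilson_ci,
    window_prevalence,
)

BETABLOCKERS = DrugGroup("betablockers", ("C07",))
CITALOPRAM = DrugGroup("citalopram_escitalopram", ("N06AB10", "N06AB04"))
DIGITALIS = DrugGroup("digitalis", ("C01A",))


class TestMatchGroup:
    @pytest.mark.parametrize(
        "code,group,expect",
        [
            ("C07AB02", BETABLOCKERS, True),
            ("C08DA01", BETABLOCKERS, False),
            ("C01AA05", DIGITALIS, True),
            ("N06AB04", CITALOPRAM, True),
            ("N06AB05", CITALOPRAM, False),
        ],
    )
    def test_prefix_matching(self, code, group, expect):
        assert match_group(code, group) is expect

    @pytest.mark.parametrize("bad", ["C07", "c07ab02", "C07AB2", "", "C07AB021"])
    def test_malformed_code_rejected(self, bad):
        with pytest.raises(ValueError, match="malformed"):
            match_group(bad, BETABLOCKERS)

    def test_group_requires_prefixes(self):
        with pytest.raises(ValueError):
            DrugGroup("empty", ())


class TestWilson:
    def test_known_value(self):
        low, high = wilson_ci(50, 100, 0.95)
        assert round(low, 4) == 0.4038 and round(high, 4) == 0.5962

    def test_degenerate_endpoints_exact(self):
        assert wilson_ci(0, 50)[0] == 0.0
        assert wilson_ci(100, 100)[1] == 1.0

    def test_x0_upper_bound_closed_form(self):
        # at x=0 the interval degenerates to [0, z^2/(n+z^2)]
        from scipy.stats import norm

        z = norm.ppf(0.975)
        n = 37
        assert wilson_ci(0, n)[1] == pytest.approx(z * z / (n + z * z), rel=1e-12)

    @pytest.mark.parametrize("x,n", [(0, 10), (1, 10), (5, 10), (9, 10), (10, 10), (3, 250)])
    def test_agrees_with_statsmodels(self, x, n):
        low, high = wilson_ci(x, n)
        sm_low, sm_high = proportion_confint(x, n, alpha=0.05, method="wilson")
        assert low == pytest.approx(sm_low, abs=1e-10)
        assert high == pytest.approx(sm_high, abs=1e-10)

    def test_contains_point_estimate(self):
        for x, n in [(0, 8), (2, 9), (7, 7), (13, 200)]:
            low, high = wilson_ci(x, n)
            assert low <= x / n <= high

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 3)


def members_frame(n, index=dt.date(2010, 6, 1)):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "index_date": pd.Timestamp(index),
            "sex": ["F"] * n,
            "age_group": ["37-80"] * n,
        }
    )


def record(pid, index, day, atc):
    return {
        "patient_id": pid,
        "dispense_date": pd.Timestamp(index) + pd.Timedelta(days=day),
        "atc_code": atc,
    }


class TestWindowPrevalence:
    INDEX = dt.date(2010, 6, 1)

    def cells(self, records, n=10, **kwargs):
        members = members_frame(n, self.INDEX)
        return window_prevalence(members, pd.DataFrame(records), BETABLOCKERS, **kwargs)

    def test_no_matching_dispensings_all_zero(self):
        cells = self.cells([record("P0", self.INDEX, 10, "N06AB10")])
        assert (cells["n_users"] == 0).all()
        assert (cells["proportion"] == 0.0).all()
        assert (cells["n_total"] == 10).all()

    @pytest.mark.parametrize(
        "day,window",
        [(-1460, -4), (-1096, -4), (-1095, -3), (-366, -2), (-365, -1), (-1, -1),
         (0, 1), (364, 1), (365, 2), (729, 2)],
    )
    def test_window_boundaries(self, day, window):
        cells = self.cells([record("P0", self.INDEX, day, "C07AB02")])
        hit = cells[cells["n_users"] > 0]
        assert list(hit["window"]) == [window]

    @pytest.mark.parametrize("day", [-1461, 730])
    def test_outside_followup_counts_nowhere(self, day):
        cells = self.cells([record("P0", self.INDEX, day, "C07AB02")])
        assert (cells["n_users"] == 0).all()

    def test_user_counted_once_per_window(self):
        cells = self.cells(
            [record("P0", self.INDEX, 10, "C07AB02"), record("P0", self.INDEX, 20, "C07AB03")]
        )
        assert cells.loc[cells["window"] == 1, "n_users"].item() == 1

    def test_suppression_flags_cells_under_five_users(self):
        records = [record(f"P{i}", self.INDEX, 10, "C07AB02") for i in range(4)]
        records += [record(f"P{i}", self.INDEX, 400, "C07AB02") for i in range(5)]
        cells = self.cells(records, n=20)
        by_window = cells.set_index("window")
        assert by_window.loc[1, "suppressed"]          # 4 users < 5
        assert not by_window.loc[2, "suppressed"]      # 5 users
        assert (cells["suppressed"] == (cells["n_users"] < 5)).all()

    def test_wilson_attached(self):
        records = [record(f"P{i}", self.INDEX, 10, "C07AB02") for i in range(4)]
        cells = self.cells(records, n=10)
        row = cells[cells["window"] == 1].iloc[0]
        assert (row["ci_low"], row["ci_high"]) == wilson_ci(4, 10)


class TestCombinationAndUnion:
    INDEX = dt.date(2010, 6, 1)

    def test_same_window_required(self):
        members = members_frame(3, self.INDEX)
        records = pd.DataFrame(
            [
                record("P0", self.INDEX, -100, "C07AB02"),   # window -1
                record("P0", self.INDEX, 100, "N06AB10"),    # window +1
                record("P1", self.INDEX, 50, "C07AB02"),     # both in +1
                record("P1", self.INDEX, 60, "N06AB04"),
            ]
        )
        cells = combination_prevalence(members, records, BETABLOCKERS, CITALOPRAM)
        counts = cells.set_index("window")["n_users"]
        assert counts[1] == 1
        assert counts[-1] == 0

    def test_combination_with_itself_is_marginal(self):
        members = members_frame(5, self.INDEX)
        records = pd.DataFrame([record("P0", self.INDEX, 5, "C07AB02")])
        combo = combination_prevalence(members, records, BETABLOCKERS, BETABLOCKERS)
        single = window_prevalence(members, records, BETABLOCKERS)
        assert (combo["n_users"].to_numpy() == single["n_users"].to_numpy()).all()

    def test_union_adds_disjoint_users(self):
        members = members_frame(10, self.INDEX)
        records = pd.DataFrame(
            [record("P0", self.INDEX, 5, "C07AB02"), record("P1", self.INDEX, 5, "N06AB10")]
        )
        cells = any_of_groups_prevalence(members, records, [BETABLOCKERS, CITALOPRAM])
        assert cells.set_index("window").loc[1, "proportion"] == pytest.approx(0.2)

    def test_union_of_single_group_is_marginal(self):
        members = members_frame(5, self.INDEX)
        records = pd.DataFrame([record("P0", self.INDEX, 5, "C07AB02")])
        union = any_of_groups_prevalence(members, records, [BETABLOCKERS])
        single = window_prevalence(members, records, BETABLOCKERS)
        assert (union["n_users"].to_numpy() == single["n_users"].to_numpy()).all()


class TestStructuralInvariants:
    """Set-theoretic relations on the full synthetic analysis."""

    def key(self, df):
        return df.set_index(["sex", "age_group", "window"])

    def test_combination_below_marginals(self, mid_analysis):
        for _, combo in mid_analysis.combinations.groupby("drug_group"):
            name = combo["drug_group"].iloc[0]
            a, b = name.split("+")
            ca = self.key(mid_analysis.prevalence[mid_analysis.prevalence["drug_group"] == a])
            cb = self.key(mid_analysis.prevalence[mid_analysis.prevalence["drug_group"] == b])
            ck = self.key(combo)
            assert (ck["n_users"] <= ca.loc[ck.index, "n_users"]).all()
            assert (ck["n_users"] <= cb.loc[ck.index, "n_users"]).all()

    def test_union_bounds(self, mid_analysis):
        union = self.key(mid_analysis.any_of_groups)
        per_group = {
            g: self.key(df) for g, df in mid_analysis.prevalence.groupby("drug_group")
        }
        stack = pd.concat(
            [df.loc[union.index, "n_users"] for df in per_group.values()], axis=1
        )
        assert (union["n_users"] >= stack.max(axis=1)).all()
        assert (union["n_users"] <= stack.sum(axis=1)).all()

    def test_denominator_constant_across_windows(self, mid_analysis):
        for (_, _, _), g in mid_analysis.prevalence.groupby(["drug_group", "sex", "age_group"]):
            assert g["n_total"].nunique() == 1
            assert len(g) == len(WINDOWS)

    def test_suppression_exactly_below_threshold(self, mid_analysis):
        for df in (mid_analysis.prevalence, mid_analysis.combinations):
            assert (df["suppressed"] == (df["n_users"] < 5)).all()

    def test_ci_contains_proportion(self, mid_analysis):
        df = mid_analysis.prevalence
        assert (df["ci_low"] <= df["proportion"] + 1e-15).all()
        assert (df["ci_high"] >= df["proportion"] - 1e-15).all()
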