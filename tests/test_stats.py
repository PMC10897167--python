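"""Factorial ANOVA, Fisher's LSD, and Bonferroni alpha conventions."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import saxstrain as sx


def balanced_table(cell_values):
    """Build a long table from {(age, genotype): [values]}."""
    rows = []
    for (age, genotype), values in cell_values.items():
        for i, v in enumerate(values):
            rows.append({"sample_id": f"{age}{genotype}{i}", "age": age,
                         "genotype": genotype, "sex": "M", "value": float(v)})
    return pd.DataFrame(rows)


def manual_two_way_ss(data):
    """Textbook balanced two-way decomposition (independent oracle)."""
    grand = data["value"].mean()
    n = data.groupby(["age", "genotype"])["value"].count().iloc[0]
    a_means = data.groupby("age")["value"].mean()
    b_means = data.groupby("genotype")["value"].mean()
    cell_means = data.groupby(["age", "genotype"])["value"].mean()
    b_levels = data["genotype"].nunique()
    a_levels = data["age"].nunique()
    ss_a = n * b_levels * ((a_means - grand) ** 2).sum()
    ss_b = n * a_levels * ((b_means - grand) ** 2).sum()
    ss_cells = n * ((cell_means - grand) ** 2).sum()
    ss_int = ss_cells - ss_a - ss_b
    ss_tot = ((data["value"] - grand) ** 2).sum()
    return ss_a, ss_b, ss_int, ss_tot - ss_cells


class TestTwoWayAnova:
    def test_matches_manual_decomposition(self):
        rng = np.random.default_rng(5)
        cells = {(a, g): 10 + rng.normal(0, 2, 6)
                 for a in ("4mo", "15mo") for g in ("Ctrl", "KO")}
        data = balanced_table(cells)
        table = sx.two_way_anova(data).table
        ss_a, ss_b, ss_int, ss_res = manual_two_way_ss(data)
        assert table.loc["age", "ss"] == pytest.approx(ss_a, abs=1e-10)
        assert table.loc["genotype", "ss"] == pytest.approx(ss_b, abs=1e-10)
        assert table.loc["age:genotype", "ss"] == pytest.approx(ss_int, abs=1e-10)
        assert table.loc["residual", "ss"] == pytest.approx(ss_res, abs=1e-10)

    def test_balanced_ss_additivity(self):
        rng = np.random.default_rng(9)
        cells = {(a, g): rng.normal(5, 1, 5)
                 for a in ("4mo", "12mo", "15mo") for g in ("Ctrl", "KO")}
        data = balanced_table(cells)
        anova = sx.two_way_anova(data)
        total = ((data["value"] - data["value"].mean()) ** 2).sum()
        assert anova.table["ss"].sum() == pytest.approx(total, rel=1e-12)
        assert anova.ss_type == 1

    def test_unbalanced_uses_type_two(self):
        cells = {("4mo", "Ctrl"): [1.0, 2.0, 3.0], ("4mo", "KO"): [2.0, 3.0],
                 ("15mo", "Ctrl"): [4.0, 5.0], ("15mo", "KO"): [5.0, 6.0, 7.0]}
        anova = sx.two_way_anova(balanced_table(cells))
        assert anova.ss_type == 2

    def test_empty_cell_error_names_the_cell(self):
        cells = {("4mo", "Ctrl"): [1.0, 2.0], ("4mo", "KO"): [2.0, 3.0],
                 ("15mo", "Ctrl"): [4.0, 5.0]}
        with pytest.raises(ValueError, match="15mo.*KO"):
            sx.two_way_anova(balanced_table(cells))

    def test_crossed_effect_detected_with_power(self):
        # a pure interaction of 2 sd should be flagged in >= 80% of seeds
        hits = 0
        n_sims = 100
        for s in range(n_sims):
            means = {("4mo", "Ctrl"): 0.0, ("4mo", "KO"): 0.0,
                     ("15mo", "Ctrl"): 0.0, ("15mo", "KO"): 2.0}
            data = sx.simulate_group_outcomes(["4mo", "15mo"], ["Ctrl", "KO"],
                                              means, sd=1.0, n_per_cell=8, seed=s)
            p = sx.two_way_anova(data).table.loc["age:genotype", "p"]
            hits += p < 0.05
        assert hits >= 0.8 * n_sims


class TestOneWayAnova:
    def test_two_groups_f_equals_squared_t(self):
        rng = np.random.default_rng(2)
        data = balanced_table({("4mo", "Ctrl"): rng.normal(0, 1, 8),
                               ("15mo", "Ctrl"): rng.normal(0.5, 1, 8)})
        anova = sx.one_way_anova(data, factor="age")
        a = data.loc[data["age"] == "4mo", "value"]
        b = data.loc[data["age"] == "15mo", "value"]
        t, p = sps.ttest_ind(a, b)
        assert anova.table.loc["age", "f"] == pytest.approx(t**2, rel=1e-10)
        assert anova.table.loc["age", "p"] == pytest.approx(p, rel=1e-10)

    def test_oracle_ss_agreement(self):
        rng = np.random.default_rng(3)
        groups = {a: rng.normal(i, 1, 6) for i, a in enumerate(("2mo", "12mo", "24mo", "30mo"))}
        data = balanced_table({(a, "Ctrl"): v for a, v in groups.items()})
        anova = sx.one_way_anova(data, factor="age")
        grand = data["value"].mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        assert anova.table.loc["age", "ss"] == pytest.approx(ss_between, abs=1e-10)
        assert anova.table.loc["residual", "ss"] == pytest.approx(ss_within, abs=1e-10)

    def test_null_type_i_error_near_nominal(self):
        rejections = 0
        n_sims = 400
        rng = np.random.default_rng(77)
        for _ in range(n_sims):
            data = balanced_table(
                {(a, "Ctrl"): rng.normal(0, 1, 5) for a in ("2", "12", "24", "30")}
            )
            rejections += sx.one_way_anova(data, "age").table.loc["age", "p"] < 0.05
        lo, hi = sps.binom.interval(0.999, n_sims, 0.05)
        assert lo <= rejections <= hi

    def test_single_group_is_an_error(self):
        data = balanced_table({("4mo", "Ctrl"): [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            sx.one_way_anova(data, factor="age")


class TestFisherLsd:
    def test_hand_worked_example(self):
        # means 10 vs 12, MSE 4, n = 5 each, df = 16 -> |t| = 1.581, p = 0.133
        table = pd.DataFrame(
            {"ss": [0.0, 64.0], "df": [3.0, 16.0], "ms": [0.0, 4.0],
             "f": [np.nan, np.nan], "p": [np.nan, np.nan]},
            index=["age", "residual"],
        )
        data = balanced_table({("A", "Ctrl"): [10.0] * 5, ("B", "Ctrl"): [12.0] * 5})
        anova = sx.AnovaTable(table, ("age",), "value", 1, data)
        res = sx.fisher_lsd(anova, "A", "B")
        assert abs(res.t_statistic) == pytest.approx(1.581, abs=1e-3)
        assert res.p_value == pytest.approx(0.133, abs=1e-3)

    def test_identical_cells_give_p_one(self):
        data = balanced_table({("4mo", "Ctrl"): [1.0, 2.0, 3.0],
                               ("4mo", "KO"): [1.0, 2.0, 3.0],
                               ("15mo", "Ctrl"): [4.0, 5.0, 6.0],
                               ("15mo", "KO"): [4.0, 5.0, 6.0]})
        anova = sx.two_way_anova(data)
        res = sx.fisher_lsd(anova, ("4mo", "Ctrl"), ("4mo", "KO"))
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_equals_pooled_t_with_single_family(self):
        rng = np.random.default_rng(8)
        data = balanced_table({("A", "Ctrl"): rng.normal(0, 1, 7),
                               ("B", "Ctrl"): rng.normal(1, 1, 7)})
        anova = sx.one_way_anova(data, "age")
        res = sx.fisher_lsd(anova, "A", "B")
        t, p = sps.ttest_ind(data.loc[data["age"] == "A", "value"],
                             data.loc[data["age"] == "B", "value"])
        assert res.t_statistic == pytest.approx(t, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_unknown_cell_is_an_error(self):
        data = balanced_table({("4mo", "Ctrl"): [1.0, 2.0], ("4mo", "KO"): [2.0, 3.0],
                               ("15mo", "Ctrl"): [1.0, 2.0], ("15mo", "KO"): [2.0, 3.0]})
        anova = sx.two_way_anova(data)
        with pytest.raises(ValueError, match="not present"):
            sx.fisher_lsd(anova, ("4mo", "Ctrl"), ("99mo", "KO"))


class TestBonferroni:
    @pytest.mark.parametrize(
        "m, exact, printed",
        [(4, 0.0125, None), (1, 0.05, None), (7, 0.05 / 7, 0.007), (6, 0.05 / 6, 0.008)],
    )
    def test_families(self, m, exact, printed):
        alpha = sx.bonferroni_alpha(m)
        assert alpha.exact == pytest.approx(exact, rel=1e-12)
        if printed is not None:
            assert alpha.printed == printed

    def test_inverse_identity(self):
        for m in (1, 2, 3, 4, 5, 6, 7, 8, 10, 12):
            alpha = sx.bonferroni_alpha(m)
            assert alpha.exact * m == 0.05
        assert math.isclose(sx.bonferroni_alpha(11).exact * 11, 0.05, rel_tol=1e-15)

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            sx.bonferroni_alpha(0)
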