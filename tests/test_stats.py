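"""Statistics layer: normality gate, ANOVA/Tukey, t-test, ANCOVA, folds."""

import numpy as np
import pandas as pd
import pytest

from mitomorph.stats import (
    CollinearityWarning,
    ancova_covariates,
    bonferroni_alpha,
    compare_groups,
    fold_change,
    normality_gate,
    one_way_anova,
    paired_condition_test,
    shapiro_wilk,
    unpaired_t,
)


def make_records(group_values: dict, metric="footprint_um2", condition="normal"):
    rows = []
    for line, values in group_values.items():
        for i, v in enumerate(values):
            rows.append({"cell_id": f"{line}_{i}", "line": line,
                         "condition": condition, metric: v})
    return pd.DataFrame(rows)


class TestNormalityGate:
    def test_reports_per_group_and_passes_gaussian(self, rng):
        rec = make_records({
            "Control": rng.normal(10, 2, 20),
            "PINK1": rng.normal(12, 2, 20),
        })
        rep = normality_gate(rec, "footprint_um2")
        assert len(rep) == 2
        assert rep["normal"].all()

    def test_degenerate_group_errors(self):
        rec = make_records({"Control": [5.0, 5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="degenerate"):
            normality_gate(rec, "footprint_um2")

    def test_too_few_values_errors_naming_group(self):
        rec = make_records({"Control": [1.0, 2.0]})
        with pytest.raises(ValueError, match="Control"):
            normality_gate(rec, "footprint_um2")

    def test_detects_exponential_samples(self):
        hits = 0
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            _, p = shapiro_wilk(rng.exponential(size=50))
            hits += p < 0.05
        assert hits / 1000 > 0.90

    def test_warns_on_non_normal_group(self, rng):
        rec = make_records({"Control": rng.exponential(size=60) ** 2})
        with pytest.warns(UserWarning, match="non-normal"):
            rep = normality_gate(rec, "footprint_um2")
        assert not rep["normal"].all()


class TestCompareGroups:
    def test_five_groups_use_adjusted_alpha_0_005(self, rng):
        rec = make_records({g: rng.normal(10, 1, 12)
                            for g in ["Control", "LRRK2", "PINK1", "PinkParkin", "A53T"]})
        rep = compare_groups(rec, "footprint_um2")
        tukey = rep[rep["test"] == "Tukey"]
        assert len(tukey) == 10
        assert np.allclose(tukey["adjusted_alpha"], 0.005)

    def test_strong_shift_is_detected(self, rng):
        hits = 0
        for seed in range(300):
            r = np.random.default_rng(seed)
            rec = make_records({
                "Control": r.normal(0, 1, 12), "B": r.normal(0, 1, 12),
                "C": r.normal(0, 1, 12), "D": r.normal(3, 1, 12),
            })
            rep = compare_groups(rec, "footprint_um2")
            omnibus = rep[rep["test"] == "ANOVA1"].iloc[0]
            hits += bool(omnibus["significant"])
        assert hits / 300 > 0.99

    def test_two_way_reports_main_and_interaction_effects(self, rng):
        rows = []
        for line in ["Control", "PINK1"]:
            for cond in ["normal", "H2O2"]:
                shift = 2.0 if (line, cond) == ("PINK1", "H2O2") else 0.0
                for v in rng.normal(shift, 1, 10):
                    rows.append({"line": line, "condition": cond, "m": v})
        rep = compare_groups(pd.DataFrame(rows), "m", design="two_way")
        labels = set(rep.loc[rep["test"] == "ANOVA2", "groups"])
        assert labels == {"line", "condition", "linexcondition"}

    def test_two_way_empty_cell_errors(self, rng):
        rows = [{"line": "Control", "condition": "normal", "m": v}
                for v in rng.normal(0, 1, 10)]
        rows += [{"line": "PINK1", "condition": "H2O2", "m": v}
                 for v in rng.normal(0, 1, 10)]
        with pytest.raises(ValueError, match="cell"):
            compare_groups(pd.DataFrame(rows), "m", design="two_way")

    def test_explicit_family_size_overrides_default(self, rng):
        rec = make_records({g: rng.normal(10, 1, 8) for g in "abcd"})
        rep = compare_groups(rec, "footprint_um2", n_comparisons=6)
        tukey = rep[rep["test"] == "Tukey"]
        assert np.allclose(tukey["adjusted_alpha"], 0.05 / 6)
        assert tukey["adjusted_alpha"].iloc[0] == pytest.approx(0.0083, abs=5e-5)


class TestPairedConditionTest:
    def test_identical_samples_give_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        rec = pd.concat([
            make_records({"PINK1": vals}, condition="normal"),
            make_records({"PINK1": vals}, condition="H2O2"),
        ])
        rep = paired_condition_test(rec, "footprint_um2", "PINK1")
        assert rep["p_value"].iloc[0] == pytest.approx(1.0)

    def test_statistic_matches_closed_form(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        t, p = unpaired_t(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_exp = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_exp)

    def test_missing_condition_errors(self):
        rec = make_records({"PINK1": [1.0, 2.0, 3.0]}, condition="normal")
        with pytest.raises(ValueError, match="H2O2"):
            paired_condition_test(rec, "footprint_um2", "PINK1")


class TestAncova:
    def _records(self, rng, age_slope=0.0, n_per_line=12, lines=("Control", "PINK1")):
        rows = []
        ages = {"Control": [56, 49], "PINK1": [52], "A53T": [52]}
        sexes = {"Control": ["male", "female"], "PINK1": ["female"], "A53T": ["female"]}
        for line in lines:
            for i in range(n_per_line):
                age = ages[line][i % len(ages[line])]
                sex = sexes[line][i % len(sexes[line])]
                rows.append({
                    "line": line, "donor_age": age, "donor_sex": sex,
                    "m": rng.normal(10, 1) + age_slope * age,
                })
        return pd.DataFrame(rows)

    def test_single_donor_line_triggers_confound_warning(self, rng):
        rec = self._records(rng)
        with pytest.warns(CollinearityWarning):
            rep = ancova_covariates(rec, "m")
        assert rep["confounded"].all()

    def test_location_shift_of_age_leaves_line_effect_unchanged(self):
        # identifiable design: ages vary within every line
        rng = np.random.default_rng(11)
        rows = []
        for line in ("Control", "PINK1"):
            for _ in range(20):
                rows.append({
                    "line": line, "donor_age": float(rng.integers(30, 75)),
                    "donor_sex": rng.choice(["male", "female"]),
                    "m": rng.normal(10, 1),
                })
        rec = pd.DataFrame(rows)
        rep1 = ancova_covariates(rec, "m")
        rec2 = rec.assign(donor_age=rec["donor_age"] + 100)
        rep2 = ancova_covariates(rec2, "m")
        f1 = rep1.loc[rep1["groups"] == "line", "statistic"].iloc[0]
        f2 = rep2.loc[rep2["groups"] == "line", "statistic"].iloc[0]
        assert f1 == pytest.approx(f2, rel=1e-6)

    def test_age_slope_recovered_within_three_se(self):
        # ages vary within lines here, so the covariate is identifiable
        rng = np.random.default_rng(7)
        rows = []
        for line in ("Control", "PINK1"):
            for _ in range(30):
                age = float(rng.integers(30, 75))
                sex = rng.choice(["male", "female"])
                rows.append({"line": line, "donor_age": age, "donor_sex": sex,
                             "m": rng.normal(0, 1) + 0.5 * age})
        rep = ancova_covariates(pd.DataFrame(rows), "m")
        params = rep.attrs["params"]
        bse = rep.attrs["bse"]
        assert abs(params["_age"] - 0.5) < 3 * bse["_age"]

    def test_null_covariates_are_calibrated(self):
        hits = 0
        n_rep = 300
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            rows = []
            for line in ("Control", "PINK1"):
                for _ in range(15):
                    rows.append({
                        "line": line,
                        "donor_age": float(rng.integers(30, 75)),
                        "donor_sex": rng.choice(["male", "female"]),
                        "m": rng.normal(0, 1),
                    })
            rep = ancova_covariates(pd.DataFrame(rows), "m")
            p = rep.loc[rep["groups"] == "donor_age", "p_value"].iloc[0]
            hits += p < 0.05
        assert 0.02 <= hits / n_rep <= 0.09


class TestFoldChange:
    def test_printed_group_means_reproduce_published_folds(self):
        fc = fold_change({"Control": 2.9, "PINK1": 6.1, "PinkParkin": 7.6}, "Control")
        by_group = dict(zip(fc["group"], fc["fold_change"]))
        assert by_group["PINK1"] == 2.1
        assert by_group["PinkParkin"] == 2.6
        assert by_group["Control"] == 1.0

    def test_rounding_is_half_up(self):
        fc = fold_change({"ref": 2.0, "x": 2.5}, "ref", decimals=1)
        assert dict(zip(fc["group"], fc["fold_change"]))["x"] == 1.3  # 1.25 -> 1.3

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError, match="zero"):
            fold_change({"ref": 0.0, "x": 1.0}, "ref")

    def test_bonferroni_alpha_exact(self):
        assert bonferroni_alpha(5) == pytest.approx(0.005)
        assert bonferroni_alpha(2) == pytest.approx(0.05)  # one pair
        assert bonferroni_alpha(5, n_comparisons=6) == pytest.approx(0.05 / 6)
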