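"""Repeatability, agreement, correlation and RM-ANOVA correctness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import brute_force_rm_anova, random_long_dataset
from redcam.errors import StatisticError
from redcam.stats import (
    bland_altman,
    bonferroni_pairwise,
    clinician_anova,
    pearson,
    rm_anova,
    within_subject_sd,
)


class TestWithinSubjectSd:
    def test_identical_duplicates(self):
        assert within_subject_sd([(1.0, 1.0), (2.5, 2.5)]) == 0.0

    def test_hand_values(self):
        assert within_subject_sd([(1, 2), (3, 3)]) == pytest.approx(0.5)
        assert within_subject_sd([(0, 1), (0, 1)]) == pytest.approx(np.sqrt(0.5))

    def test_single_measurements_rejected(self):
        with pytest.raises(StatisticError):
            within_subject_sd([(1.0,), (2.0,)])


class TestBlandAltman:
    def test_identical_raters(self):
        res = bland_altman([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.mean_diff == 0 and res.loa_low == 0 and res.loa_high == 0

    def test_hand_values(self):
        a = np.array([0.0, 0.2, 0.0, 0.2])
        b = np.array([0.1, 0.1, 0.1, 0.1])  # differences −0.1, 0.1, −0.1, 0.1
        res = bland_altman(a, b)
        assert res.mean_diff == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(0.11547, abs=1e-5)
        assert res.loa_high == pytest.approx(0.22632, abs=1e-4)
        assert res.loa_low == pytest.approx(-0.22632, abs=1e-4)
        # CIs contain their limit
        assert res.ci_low_pair[0] < res.loa_low < res.ci_low_pair[1]
        assert res.ci_high_pair[0] < res.loa_high < res.ci_high_pair[1]

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(size=20)
        ab, ba = bland_altman(a, b), bland_altman(b, a)
        assert ab.mean_diff == pytest.approx(-ba.mean_diff)
        assert ab.loa_low == pytest.approx(-ba.loa_high)
        assert ab.loa_high == pytest.approx(-ba.loa_low)

    def test_too_few_pairs(self):
        with pytest.raises(StatisticError):
            bland_altman([1, 2], [1, 2])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_value(self):
        r, p = pearson([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.98198, abs=1e-5)

    def test_zero_variance(self):
        with pytest.raises(StatisticError):
            pearson([1, 1, 1], [1, 2, 3])


class TestRmAnova:
    def test_constant_within_factor_levels(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(4):
            base = rng.normal()
            for a in ("x", "y"):
                for b in ("u", "v", "w"):
                    # response depends on subject and B, never on A
                    rows.append({"subject": s, "A": a, "B": b, "value": base + hash(b) % 7})
        df = pd.DataFrame(rows)
        tab = rm_anova(df, dv="value", within=["A", "B"])
        row = tab.effect("A")
        assert row["ss"] == pytest.approx(0.0, abs=1e-12)
        assert row["F"] == 0.0 and row["p"] == 1.0

    def test_two_level_factor_equals_squared_paired_t(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(8):
            for lvl in ("a", "b"):
                rows.append({"subject": s, "f": lvl, "value": rng.normal() + (0.5 if lvl == "b" else 0)})
        df = pd.DataFrame(rows)
        tab = rm_anova(df, dv="value", within=["f"])
        wide = df.pivot(index="subject", columns="f", values="value")
        t_stat, t_p = sps.ttest_rel(wide["a"], wide["b"])
        row = tab.effect("f")
        assert row["F"] == pytest.approx(t_stat**2, abs=1e-8)
        assert row["p"] == pytest.approx(t_p, abs=1e-10)

    def test_matches_brute_force_oracle(self):
        """SS decomposition equals explicit nested sums on 25 random
        balanced 2×3×2×2 within-subject datasets, and SS/df conserve."""
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            df = random_long_dataset(rng)
            tab = rm_anova(
                df, dv="value",
                within=["processing_arm", "camera", "lighting", "magnification"],
            )
            arr = (
                df.groupby(["subject", "processing_arm", "camera", "lighting", "magnification"])
                ["value"].mean().to_numpy().reshape(4, 2, 3, 2, 2)
            )
            oracle = brute_force_rm_anova(arr)
            factor_axis = {"processing_arm": 1, "camera": 2, "lighting": 3, "magnification": 4}
            checked = 0
            for row in tab.table.itertuples():
                axes = frozenset(factor_axis[f] for f in row.effect.split("*"))
                ss_o, df_o = oracle[axes]
                assert row.ss == pytest.approx(ss_o, abs=1e-8)
                assert row.df == df_o
                err_o, err_df_o = oracle[axes | {0}]
                assert row.error_ss == pytest.approx(err_o, abs=1e-8)
                assert row.error_df == err_df_o
                checked += 1
            assert checked == 15
            # conservation: subject + effects + error strata = total
            ss_sum = tab.subject_ss + (tab.table.ss + tab.table.error_ss).sum()
            assert ss_sum == pytest.approx(tab.total_ss, abs=1e-8)
            df_sum = (len(arr[0].ravel()) - 1) * 0  # placeholder for clarity
            df_sum = (4 - 1) + (tab.table.df + tab.table.error_df).sum()
            assert df_sum == tab.total_df

    def test_agrees_with_pingouin(self):
        """Independent cross-check against pingouin's two-way RM-ANOVA."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        rows = []
        for s in range(6):
            for a in ("a1", "a2"):
                for b in ("b1", "b2", "b3"):
                    rows.append(
                        {"subject": s, "A": a, "B": b,
                         "value": rng.normal() + (0.8 if a == "a2" else 0) + 0.3 * (b == "b3")}
                    )
        df = pd.DataFrame(rows)
        ours = rm_anova(df, dv="value", within=["A", "B"])
        theirs = pg.rm_anova(data=df, dv="value", within=["A", "B"], subject="subject", detailed=True)
        for effect, key in [("A", "A"), ("B", "B"), ("A*B", "A * B")]:
            ref = theirs[theirs["Source"] == key].iloc[0]
            row = ours.effect(effect)
            assert row["F"] == pytest.approx(float(ref["F"]), rel=1e-6)
            assert row["p"] == pytest.approx(float(ref["p_unc"]), rel=1e-6)

    def test_replicates_are_averaged(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(4):
            for lvl in ("a", "b"):
                for rep in (1, 2):
                    rows.append({"subject": s, "f": lvl, "value": rng.normal(), "rep": rep})
        df = pd.DataFrame(rows)
        tab_rep = rm_anova(df, dv="value", within=["f"])
        averaged = df.groupby(["subject", "f"], as_index=False)["value"].mean()
        tab_avg = rm_anova(averaged, dv="value", within=["f"])
        assert tab_rep.effect("f")["F"] == pytest.approx(tab_avg.effect("f")["F"])

    def test_unbalanced_names_missing_cells(self):
        df = pd.DataFrame(
            {"subject": [1, 1, 2], "f": ["a", "b", "a"], "value": [0.0, 1.0, 2.0]}
        )
        with pytest.raises(StatisticError, match="missing cells"):
            rm_anova(df, dv="value", within=["f"])

    def test_type_one_error_calibration(self):
        """Under pure noise, each main effect rejects at ~5%: the rejection
        rate over 200 simulations lies in the binomial-plausible band."""
        rejections = np.zeros(4)
        factors = ["processing_arm", "camera", "lighting", "magnification"]
        for seed in range(200):
            rng = np.random.default_rng(50_000 + seed)
            df = random_long_dataset(rng)
            tab = rm_anova(df, dv="value", within=factors)
            for i, f in enumerate(factors):
                rejections[i] += tab.effect(f)["p"] < 0.05
        rates = rejections / 200
        assert ((rates >= 0.01) & (rates <= 0.10)).all()

    def test_power_for_injected_interaction(self):
        """A processing_arm×camera interaction at the default effect size
        is detected in ≥80% of simulations."""
        hits = 0
        n_sim = 40
        for seed in range(n_sim):
            rng = np.random.default_rng(90_000 + seed)
            df = random_long_dataset(rng)
            # inject: pre-arm responses shift by a camera-dependent offset
            delta = {"c1": -1.0, "c2": 0.0, "c3": 1.0}
            mask = df["processing_arm"] == "pre"
            df.loc[mask, "value"] += df.loc[mask, "camera"].map(delta)
            tab = rm_anova(
                df, dv="value",
                within=["processing_arm", "camera", "lighting", "magnification"],
            )
            hits += tab.effect("processing_arm*camera")["p"] < 0.05
        assert hits / n_sim >= 0.8


class TestBonferroni:
    def _df(self, levels, rng, effect=None):
        rows = []
        for s in range(6):
            base = rng.normal()
            for lvl in levels:
                shift = (effect or {}).get(lvl, 0.0)
                rows.append({"subject": s, "f": lvl, "value": base + shift + 0.1 * rng.normal()})
        return pd.DataFrame(rows)

    def test_two_levels_no_correction(self):
        rng = np.random.default_rng(1)
        out = bonferroni_pairwise(self._df(["a", "b"], rng), "f", "value")
        assert len(out) == 1
        assert out.p_adj.iloc[0] == pytest.approx(min(1.0, out.p.iloc[0]))

    def test_three_levels_three_pairs(self):
        rng = np.random.default_rng(2)
        out = bonferroni_pairwise(self._df(["a", "b", "c"], rng), "f", "value")
        assert len(out) == 3
        assert (out.p_adj == (out.p * 3).clip(upper=1.0)).all()

    def test_identical_levels_p_one(self):
        df = pd.DataFrame(
            [
                {"subject": s, "f": lvl, "value": float(s)}
                for s in range(5)
                for lvl in ("a", "b", "c")
            ]
        )
        out = bonferroni_pairwise(df, "f", "value")
        assert (out.p_adj == 1.0).all()

    def test_single_level_rejected(self):
        df = pd.DataFrame({"subject": [1, 2], "f": ["a", "a"], "value": [0.0, 1.0]})
        with pytest.raises(StatisticError):
            bonferroni_pairwise(df, "f", "value")


class TestClinicianAnova:
    def _grades(self, n_images, offsets, noise, rng):
        rows = []
        for i in range(n_images):
            base = rng.uniform(0, 4)
            for j, off in enumerate(offsets):
                rows.append(
                    {"image": i, "rater": f"r{j}", "grade": base + off + noise * rng.normal()}
                )
        return pd.DataFrame(rows)

    def test_identical_raters_f_zero(self):
        rng = np.random.default_rng(0)
        f, p, _ = clinician_anova(self._grades(10, [0, 0, 0], 0.0, rng))
        assert f == 0.0 and p == 1.0

    def test_pure_offsets_infinite_f(self):
        rng = np.random.default_rng(1)
        f, p, _ = clinician_anova(self._grades(10, [0.0, 0.5, 1.0], 0.0, rng))
        assert np.isinf(f) and p == 0.0

    def test_consistent_with_rm_anova(self):
        rng = np.random.default_rng(2)
        grades = self._grades(12, [0.0, 0.2, 0.1], 0.3, rng)
        f, p, _ = clinician_anova(grades)
        tab = rm_anova(grades, dv="grade", within=["rater"], subject="image")
        assert f == pytest.approx(tab.effect("rater")["F"], abs=1e-10)
        assert p == pytest.approx(tab.effect("rater")["p"], abs=1e-10)
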