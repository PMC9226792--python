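import itertools

import numpy as np
import pandas as pd
import pytest

from stopsig.simulate import default_group_params, simulate_measures
from stopsig.stats import (MissingCellError, bonferroni_adjust,
                           independent_t_test, mixed_rm_anova,
                           pairwise_followup, screen_participants)


class TestTTest:
    def test_identical_samples(self):
        r = independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0
        assert r.p == 1.0

    def test_hand_computed_example(self):
        r = independent_t_test([1, 2, 3], [4, 5, 6])
        assert r.t == pytest.approx(-3.674, abs=1e-3)
        assert r.df == 4

    def test_zero_variance_equal_means(self):
        r = independent_t_test([5.0, 5.0], [5.0, 5.0])
        assert (r.t, r.p) == (0.0, 1.0)

    def test_type_one_error_calibrated(self):
        """Null simulation: rejection rate at alpha=.05 over 1000
        replicates stays in [0.035, 0.065]."""
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(1000):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            if independent_t_test(x, y).p < 0.05:
                rejections += 1
        assert 0.035 <= rejections / 1000 <= 0.065

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            independent_t_test([1.0], [2.0, 3.0])


def brute_force_split_plot(table, dv, subject, between, within):
    """Independent oracle: sums of squares by explicit enumeration of every
    marginal mean with plain Python loops."""
    recs = table.to_dict(orient="records")
    y = [r[dv] for r in recs]
    grand = sum(y) / len(y)

    def mean_where(**cond):
        vals = [r[dv] for r in recs
                if all(r[k] == v for k, v in cond.items())]
        return sum(vals) / len(vals)

    def levels(col):
        return sorted({r[col] for r in recs})

    g, (a, b) = between, within
    subj_grp = {r[subject]: r[between] for r in recs}
    la, lb = len(levels(a)), len(levels(b))
    ss = {}
    ss[g] = sum(la * lb * sum(1 for s in subj_grp if subj_grp[s] == gi)
                * (mean_where(**{g: gi}) - grand) ** 2 for gi in levels(g))
    ss["subj"] = la * lb * sum(
        (mean_where(**{subject: s}) - mean_where(**{g: subj_grp[s]})) ** 2
        for s in subj_grp)
    n_subj = len(subj_grp)
    ss[a] = n_subj * lb * sum(
        (mean_where(**{a: ai}) - grand) ** 2 for ai in levels(a))
    ss[f"{g}:{a}"] = lb * sum(
        sum(1 for s in subj_grp if subj_grp[s] == gi)
        * (mean_where(**{g: gi, a: ai}) - mean_where(**{g: gi})
           - mean_where(**{a: ai}) + grand) ** 2
        for gi in levels(g) for ai in levels(a))
    ss["subj:a"] = lb * sum(
        (mean_where(**{subject: s, a: ai}) - mean_where(**{subject: s})
         - mean_where(**{g: subj_grp[s], a: ai})
         + mean_where(**{g: subj_grp[s]})) ** 2
        for s in subj_grp for ai in levels(a))
    ss[b] = n_subj * la * sum(
        (mean_where(**{b: bi}) - grand) ** 2 for bi in levels(b))
    ss[f"{g}:{b}"] = la * sum(
        sum(1 for s in subj_grp if subj_grp[s] == gi)
        * (mean_where(**{g: gi, b: bi}) - mean_where(**{g: gi})
           - mean_where(**{b: bi}) + grand) ** 2
        for gi in levels(g) for bi in levels(b))
    ss["subj:b"] = la * sum(
        (mean_where(**{subject: s, b: bi}) - mean_where(**{subject: s})
         - mean_where(**{g: subj_grp[s], b: bi})
         + mean_where(**{g: subj_grp[s]})) ** 2
        for s in subj_grp for bi in levels(b))
    ss[f"{a}:{b}"] = n_subj * sum(
        (mean_where(**{a: ai, b: bi}) - mean_where(**{a: ai})
         - mean_where(**{b: bi}) + grand) ** 2
        for ai in levels(a) for bi in levels(b))
    ss[f"{g}:{a}:{b}"] = sum(
        sum(1 for s in subj_grp if subj_grp[s] == gi)
        * (mean_where(**{g: gi, a: ai, b: bi})
           - mean_where(**{g: gi, a: ai}) - mean_where(**{g: gi, b: bi})
           - mean_where(**{a: ai, b: bi}) + mean_where(**{g: gi})
           + mean_where(**{a: ai}) + mean_where(**{b: bi}) - grand) ** 2
        for gi in levels(g) for ai in levels(a) for bi in levels(b))
    ss_total = sum((v - grand) ** 2 for v in y)
    ss["resid"] = ss_total - sum(ss.values())
    return ss


class TestMixedAnova:
    def _toy(self, seed=0, n_per_group=2, la=2, lb=2):
        rng = np.random.default_rng(seed)
        rows = []
        for grp in ("ctl", "vga"):
            for s in range(n_per_group):
                sid = f"{grp}{s}"
                for ai in range(la):
                    for bi in range(lb):
                        rows.append(dict(
                            subject=sid, group=grp, trial=f"t{ai}",
                            electrode=f"e{bi}",
                            y=float(rng.integers(0, 10))))
        return pd.DataFrame(rows)

    def test_matches_brute_force_oracle(self):
        """Every SS / F of the 2x2x2 design equals explicit enumeration."""
        for seed in range(5):
            df = self._toy(seed=seed)
            res = mixed_rm_anova(df, "y", "subject", "group",
                                 ["trial", "electrode"])
            oracle = brute_force_split_plot(df, "y", "subject", "group",
                                            ("trial", "electrode"))
            errors = {"group": "subj", "trial": "subj:a",
                      "group:trial": "subj:a", "electrode": "subj:b",
                      "group:electrode": "subj:b",
                      "trial:electrode": "resid",
                      "group:trial:electrode": "resid"}
            by_name = {r.effect: r for r in res}
            for eff, err in errors.items():
                key = {"group": "group", "trial": "trial",
                       "electrode": "electrode"}.get(eff, eff)
                r = by_name[eff]
                expected_ss = oracle[eff if eff in oracle else key]
                assert r.ss_effect == pytest.approx(expected_ss, rel=1e-9,
                                                    abs=1e-9)
                assert r.ss_error == pytest.approx(oracle[err], rel=1e-9,
                                                   abs=1e-9)

    def test_identical_groups_give_zero_f(self):
        df = self._toy(seed=3, n_per_group=3)
        # mirror group values: replace vga subjects with copies of ctl
        ctl = df[df.group == "ctl"].copy()
        vga = ctl.copy()
        vga["group"] = "vga"
        vga["subject"] = vga["subject"].str.replace("ctl", "vga")
        both = pd.concat([ctl, vga], ignore_index=True)
        res = {r.effect: r for r in mixed_rm_anova(
            both, "y", "subject", "group", ["trial", "electrode"])}
        assert res["group"].F == pytest.approx(0.0, abs=1e-12)

    def test_partial_eta_sq_identity(self):
        df = self._toy(seed=7, n_per_group=4)
        for r in mixed_rm_anova(df, "y", "subject", "group",
                                ["trial", "electrode"]):
            if np.isfinite(r.F):
                ident = (r.F * r.df_num) / (r.F * r.df_num + r.df_den)
                assert r.partial_eta_sq == pytest.approx(ident, rel=1e-9)

    def test_agrees_with_pingouin_one_within(self):
        pg = pytest.importorskip("pingouin")
        df = self._toy(seed=1, n_per_group=5, la=3, lb=1)
        df = df[df.electrode == "e0"]
        ours = {r.effect: r for r in mixed_rm_anova(
            df, "y", "subject", "group", ["trial"])}
        theirs = pg.mixed_anova(df, dv="y", within="trial",
                                subject="subject", between="group")
        f_by_src = dict(zip(theirs["Source"], theirs["F"]))
        assert ours["group"].F == pytest.approx(f_by_src["group"], rel=1e-9)
        assert ours["trial"].F == pytest.approx(f_by_src["trial"], rel=1e-9)
        assert ours["group:trial"].F == pytest.approx(
            f_by_src["Interaction"], rel=1e-9)

    def test_missing_cell_rejected(self):
        df = self._toy(seed=0).iloc[:-1]
        with pytest.raises(MissingCellError):
            mixed_rm_anova(df, "y", "subject", "group",
                           ["trial", "electrode"])

    def test_null_calibration(self):
        """Type-I error of the group main effect over 200 null studies
        (identical group-level parameters) stays near alpha=.05."""
        ctl = default_group_params()["control"]
        null = {"a": ctl, "b": ctl}
        rejections = 0
        n_studies = 200
        for k in range(n_studies):
            df = simulate_measures(n_per_group=8, group_effects=null,
                                   seed=10_000 + k)
            sub = df[(df.component == "N2stop")]
            cell = (sub.groupby(["subject", "group", "direction",
                                 "electrode"], observed=True)["amplitude_uv"]
                    .mean().reset_index())
            res = {r.effect: r for r in mixed_rm_anova(
                cell, "amplitude_uv", "subject", "group",
                ["direction", "electrode"])}
            if res["group"].p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_studies <= 0.08

    def test_power_for_injected_interaction(self):
        """The group x direction N2 interaction injected by making one
        group's N2 shallower is detected in >= 80% of replicate studies at
        full scale (n=30/group)."""
        import dataclasses
        effects = default_group_params()
        detected = 0
        n_rep = 20
        for k in range(n_rep):
            df = simulate_measures(n_per_group=30, group_effects=effects,
                                   seed=20_000 + k)
            sub = df[(df.component == "N2stop") & (df.condition == "proactive")]
            cell = (sub.groupby(["subject", "group", "direction",
                                 "electrode"], observed=True)["amplitude_uv"]
                    .mean().reset_index())
            res = {r.effect: r for r in mixed_rm_anova(
                cell, "amplitude_uv", "subject", "group",
                ["direction", "electrode"])}
            if res["group"].p < 0.05:
                detected += 1
        assert detected / n_rep >= 0.8


class TestBonferroni:
    def test_definition_and_cap(self):
        assert bonferroni_adjust([0.01], 3) == [pytest.approx(0.03)]
        assert bonferroni_adjust([0.5], 3) == [1.0]
        assert bonferroni_adjust([0.04, 0.04], 2) == [
            pytest.approx(0.08), pytest.approx(0.08)]

    def test_order_preserving(self):
        ps = [0.3, 0.01, 0.2, 0.001]
        adj = bonferroni_adjust(ps, 4)
        assert [sorted(ps).index(p) for p in ps] == \
               [sorted(adj).index(a) for a in adj]

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2, 0.3], 2)

    def test_followup_family(self):
        df = simulate_measures(n_per_group=5, seed=1)
        sub = df[df.component == "P3cue"]
        out = pairwise_followup(sub, "amplitude_uv", "group",
                                ["condition", "electrode"])
        assert len(out) == 6  # 2 conditions x 3 electrodes
        assert (out["p_bonferroni"] >= out["p"]).all()


class TestScreening:
    def test_thresholds(self):
        table = pd.DataFrame({
            "subject": ["a", "b", "c"],
            "vat": [2.82, 1.05, 2.0],
            "group": ["vga", "control", "control"]})
        out = screen_participants(table)
        assert list(out["vga_eligible"]) == [True, False, False]
        assert list(out["control_eligible"]) == [False, True, False]
        assert list(out["eligible_for_assigned_group"]) == [True, True, False]

    def test_out_of_range_rejected(self):
        table = pd.DataFrame({"subject": ["a"], "vat": [6.0],
                              "group": ["vga"]})
        with pytest.raises(ValueError):
            screen_participants(table)
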