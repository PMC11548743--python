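"""Rank-transform 2x2 repeated-measures ANOVA against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from ethousv.anova import (
    RankRMAnova2x2,
    normality_screen,
    one_way_binned_anova,
    rank_transform,
    run_battery,
)


def oracle_rm_anova(y):
    """Brute-force cell-means decomposition for an (n, 2, 2) table.

    Written independently of the implementation: explicit python loops over
    subjects and cells, textbook formulas, F from scipy's F distribution.
    """
    from scipy.stats import f as fdist

    n = y.shape[0]
    grand = sum(y[s, a, b] for s in range(n) for a in range(2) for b in range(2)) / (
        4 * n
    )
    ms = [sum(y[s, a, b] for a in range(2) for b in range(2)) / 4 for s in range(n)]
    ma = [sum(y[s, a, b] for s in range(n) for b in range(2)) / (2 * n) for a in range(2)]
    mb = [sum(y[s, a, b] for s in range(n) for a in range(2)) / (2 * n) for b in range(2)]
    msa = [[sum(y[s, a, b] for b in range(2)) / 2 for a in range(2)] for s in range(n)]
    msb = [[sum(y[s, a, b] for a in range(2)) / 2 for b in range(2)] for s in range(n)]
    mab = [[sum(y[s, a, b] for s in range(n)) / n for b in range(2)] for a in range(2)]

    ss_a = 2 * n * sum((ma[a] - grand) ** 2 for a in range(2))
    ss_ea = 2 * sum(
        (msa[s][a] - ms[s] - ma[a] + grand) ** 2 for s in range(n) for a in range(2)
    )
    ss_b = 2 * n * sum((mb[b] - grand) ** 2 for b in range(2))
    ss_eb = 2 * sum(
        (msb[s][b] - ms[s] - mb[b] + grand) ** 2 for s in range(n) for b in range(2)
    )
    ss_ab = n * sum(
        (mab[a][b] - ma[a] - mb[b] + grand) ** 2 for a in range(2) for b in range(2)
    )
    ss_eab = sum(
        (
            y[s, a, b]
            - msa[s][a]
            - msb[s][b]
            - mab[a][b]
            + ms[s]
            + ma[a]
            + mb[b]
            - grand
        )
        ** 2
        for s in range(n)
        for a in range(2)
        for b in range(2)
    )
    out = {}
    for name, ss, sse in (
        ("lighting", ss_a, ss_ea),
        ("phase", ss_b, ss_eb),
        ("interaction", ss_ab, ss_eab),
    ):
        F = (ss / 1) / (sse / (n - 1))
        out[name] = (F, float(fdist.sf(F, 1, n - 1)), ss / (ss + sse))
    return out


def long_table(y, boxes=None):
    n = y.shape[0]
    boxes = boxes or [chr(65 + i) for i in range(n)]
    rows = []
    for s in range(n):
        for ai, a in enumerate(["after_change", "before_change"]):
            for bi, b in enumerate(["early", "late"]):
                rows.append((boxes[s], a, b, y[s, ai, bi]))
    return pd.DataFrame(rows, columns=["box", "lighting", "phase", "value"])


class TestRankTransform:
    def test_order_statistics(self):
        assert rank_transform([3.2, 1.1, 5.0]).tolist() == [2, 1, 3]

    def test_average_ranks_at_ties(self):
        assert rank_transform([2, 2, 7]).tolist() == [1.5, 1.5, 3]

    def test_all_equal_midrank(self):
        assert rank_transform([4, 4, 4, 4]).tolist() == [2.5] * 4

    def test_monotone_preserves_order(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        r = rank_transform(x)
        order_x = np.argsort(x)
        assert (np.diff(r[order_x]) > 0).all()


class TestNormalityScreen:
    def test_normal_samples_mostly_pass(self):
        rng = np.random.default_rng(1)
        rates = {t: 0 for t in ("anderson_darling", "dagostino_pearson",
                                "shapiro_wilk", "kolmogorov_smirnov")}
        reps = 200
        for _ in range(reps):
            rep = normality_screen({"cell": rng.normal(size=100)})
            for _, r in rep.iterrows():
                rates[r["test"]] += r["passed"]
        for t, k in rates.items():
            assert 0.88 <= k / reps <= 0.99, (t, k / reps)

    def test_exponential_sample_fails_shapiro(self):
        rng = np.random.default_rng(2)
        fails = 0
        reps = 100
        for _ in range(reps):
            rep = normality_screen({"cell": rng.exponential(size=50)})
            row = rep[rep["test"] == "shapiro_wilk"].iloc[0]
            fails += not row["passed"]
        assert fails / reps > 0.95

    def test_tiny_cell_skipped(self, caplog):
        with caplog.at_level("INFO"):
            rep = normality_screen({"tiny": np.array([1.0, 2.0])})
        assert len(rep) == 0
        assert "skipped" in caplog.text


class TestRmAnova2x2:
    def test_all_cells_equal_gives_zero_f(self):
        y = np.full((6, 2, 2), 3.0)
        res = RankRMAnova2x2(long_table(y), rank=False).fit()
        for e in res.effects:
            assert e.F == 0.0 and e.p == 1.0

    def test_pure_additive_effect_without_noise_is_infinite_f(self):
        y = np.zeros((6, 2, 2))
        y[:, 1, :] = 1.0  # lighting shift, identical for every subject
        res = RankRMAnova2x2(long_table(y), rank=False).fit()
        eff = {e.effect: e for e in res.effects}
        assert eff["lighting"].F == np.inf and eff["lighting"].p == 0.0

    def test_matches_brute_force_oracle_on_100_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            y = rng.normal(size=(6, 2, 2))
            res = RankRMAnova2x2(long_table(y), rank=False).fit()
            exp = oracle_rm_anova(y)
            assert res.n_subjects == 6
            for e in res.effects:
                F, p, eta = exp[e.effect]
                assert e.F == pytest.approx(F, abs=1e-8)
                assert e.p == pytest.approx(p, abs=1e-8)
                assert e.partial_eta_sq == pytest.approx(eta, abs=1e-8)
                assert (e.df_num, e.df_den) == (1, 5)

    def test_agrees_with_statsmodels_anova_rm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(9)
        y = rng.normal(size=(6, 2, 2))
        data = long_table(y)
        res = RankRMAnova2x2(data, rank=False).fit()
        sm = AnovaRM(
            data, depvar="value", subject="box", within=["lighting", "phase"]
        ).fit()
        tbl = sm.anova_table
        eff = {e.effect: e for e in res.effects}
        assert eff["lighting"].F == pytest.approx(tbl.loc["lighting", "F Value"])
        assert eff["phase"].F == pytest.approx(tbl.loc["phase", "F Value"])
        assert eff["interaction"].F == pytest.approx(
            tbl.loc["lighting:phase", "F Value"]
        )

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(5, 2, 2))
        r1 = RankRMAnova2x2(long_table(y), rank=False).fit()
        r2 = RankRMAnova2x2(long_table(y + 42.0), rank=False).fit()
        for e1, e2 in zip(r1.effects, r2.effects):
            assert e1.F == pytest.approx(e2.F, abs=1e-9)

    def test_ranked_fit_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        y = np.abs(rng.normal(size=(6, 2, 2))) + 0.1
        r1 = RankRMAnova2x2(long_table(y), rank=True).fit()
        r2 = RankRMAnova2x2(long_table(np.exp(y)), rank=True).fit()
        for e1, e2 in zip(r1.effects, r2.effects):
            assert e1.F == pytest.approx(e2.F, abs=1e-9)

    def test_incomplete_subject_dropped_with_warning(self, caplog):
        y = np.random.default_rng(6).normal(size=(4, 2, 2))
        data = long_table(y)
        data = data[~((data.box == "D") & (data.lighting == "after_change"))]
        with caplog.at_level("WARNING"):
            res = RankRMAnova2x2(data, rank=False).fit()
        assert res.n_subjects == 3
        assert res.dropped_subjects == ["D"]

    def test_fewer_than_two_complete_subjects_rejected(self):
        y = np.random.default_rng(7).normal(size=(2, 2, 2))
        data = long_table(y)
        data = data[data.box == "A"]
        with pytest.raises(ValueError, match="subjects"):
            RankRMAnova2x2(data, rank=False).fit()

    def test_summary_names_the_design(self):
        y = np.random.default_rng(8).normal(size=(6, 2, 2))
        res = RankRMAnova2x2(
            long_table(y), rank=True, category="fighting", session_type="light_to_dark"
        ).fit()
        s = res.summary()
        assert "fighting" in s and "lighting" in s and "n = 6" in s


class TestBattery:
    def test_full_study_fits_exactly_30_analyses(self, truth_study):
        battery = truth_study["battery"]
        fits = battery.groupby(["category", "session_type"]).ngroups
        assert fits == 30  # 15 categories x 2 session types
        assert set(battery["effect"]) == {"lighting", "phase", "interaction"}
        assert (battery["df_num"] == 1).all()

    def test_type_i_error_rate_near_alpha_under_null(self):
        """200 null studies at the cell-mean level: the lighting effect of
        the rank RM-ANOVA rejects at about the nominal 5%."""
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 200
        for _ in range(reps):
            y = rng.normal(size=(6, 2, 2))
            res = RankRMAnova2x2(long_table(y), rank=True).fit()
            eff = {e.effect: e for e in res.effects}
            rejections += eff["lighting"].p < 0.05
        assert 0.01 <= rejections / reps <= 0.10

    def test_missing_category_skipped_and_counted(self, caplog):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(6, 2, 2))
        cells = long_table(y)
        cells["session_type"] = "light_to_dark"
        cells["category"] = "fighting"
        with caplog.at_level("WARNING"):
            table = run_battery(
                cells, categories=["fighting", "ghost"],
                session_types=["light_to_dark"], rank=False,
            )
        assert table.groupby("category").ngroups == 1
        assert "ghost" in caplog.text

    def test_holm_flag_only_tightens(self):
        rng = np.random.default_rng(13)
        rows = []
        for cat in ("a", "b", "c"):
            y = rng.normal(size=(6, 2, 2))
            t = long_table(y)
            t["session_type"] = "s"
            t["category"] = cat
            rows.append(t)
        cells = pd.concat(rows)
        raw = run_battery(cells, rank=False)
        holm = run_battery(cells, rank=False, holm=True)
        assert (holm["significant"] <= raw["significant"]).all()


def test_one_way_binned_anova_detects_group_shift():
    rng = np.random.default_rng(14)
    groups = {
        "05:50-06:00": rng.poisson(5, 40),
        "06:00-06:10": rng.poisson(12, 40),
        "17:50-18:00": rng.poisson(5, 40),
        "18:00-18:10": rng.poisson(5, 40),
    }
    F, p = one_way_binned_anova(groups)
    assert p < 0.001 and F > 10
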