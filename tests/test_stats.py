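"""Statistical layer: ANOVA decomposition against independent oracles,
BH step-up adjustment, Spearman rank correlations and normality checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromove import stats as nstats
from neuromove import synthetic as syn


def _mixed_dataset(seed=1, n_per_group=8, g_eff=2.0, h_eff=1.5, gh_eff=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, gn in enumerate(["healthy", "stroke"]):
        for s in range(n_per_group):
            sid = f"{gn}{s}"
            base = rng.normal(10, 2)
            for h, hn in enumerate(["dominant", "nondominant"]):
                rows.append({
                    "subject": sid, "group": gn, "hand": hn,
                    "y": base + g_eff * g + h_eff * h + gh_eff * g * h + rng.normal(0, 1),
                })
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_pingouin_on_group_by_hand(self):
        import pingouin as pg

        df = _mixed_dataset()
        res = nstats.mixed_anova(df, dv="y", between="group", within=("hand",))
        ref = pg.mixed_anova(df, dv="y", within="hand", subject="subject",
                             between="group")
        ref = ref.set_index("Source")
        got = {r["effect"]: r for _, r in res.table.iterrows()}
        for mine, theirs in (("group", "group"), ("hand", "hand"),
                             ("group:hand", "Interaction")):
            assert got[mine]["F"] == pytest.approx(ref.loc[theirs, "F"], rel=1e-9)
            assert got[mine]["p"] == pytest.approx(ref.loc[theirs, "p_unc"], rel=1e-9)
            assert got[mine]["eta2p"] == pytest.approx(ref.loc[theirs, "np2"], rel=1e-9)

    def test_toy_dataset_matches_cell_means_oracle(self):
        # brute-force sums-of-squares from explicit cell means, 2x2 design
        df = _mixed_dataset(seed=3, n_per_group=6)
        Y = df.pivot_table(index="subject", columns="hand", values="y")
        groups = df.drop_duplicates("subject").set_index("subject")["group"]
        grand = Y.to_numpy().mean()
        ss_total = ((Y.to_numpy() - grand) ** 2).sum()
        # between: group effect and subject-within-group error
        subj_mean = Y.mean(axis=1)
        g_mean = subj_mean.groupby(groups).mean()
        n_w = Y.shape[1]
        ss_group = n_w * sum(
            (g_mean[g] - grand) ** 2 * (groups == g).sum() for g in g_mean.index
        )
        ss_subj = n_w * sum(
            (subj_mean[s] - g_mean[groups[s]]) ** 2 for s in Y.index
        )
        res = nstats.mixed_anova(df, dv="y", within=("hand",))
        g_row = res.effect("group")
        f_oracle = (ss_group / 1) / (ss_subj / (len(Y) - 2))
        assert g_row["F"] == pytest.approx(f_oracle, rel=1e-9)
        assert g_row["eta2p"] == pytest.approx(ss_group / (ss_group + ss_subj), rel=1e-9)

    def test_sum_of_squares_identity_three_within(self):
        rng = np.random.default_rng(0)
        rows = []
        for gn in ["healthy", "stroke"]:
            for s in range(5):
                for h in ["d", "n"]:
                    for c in ["SAU", "MAU"]:
                        for hemi in ["contra", "ipsi"]:
                            rows.append({
                                "subject": f"{gn}{s}", "group": gn, "hand": h,
                                "condition": c, "hemisphere": hemi,
                                "y": rng.normal(0, 1),
                            })
        df = pd.DataFrame(rows)
        res = nstats.mixed_anova(df, dv="y", within=("hand", "condition", "hemisphere"))
        assert len(res.table) == 15  # full factorial incl. the 4-way interaction
        assert ((res.table["eta2p"] >= 0) & (res.table["eta2p"] <= 1)).all()
        # SS identity: effect SS plus every distinct subject/error term
        # tiles the total SS about the grand mean (balanced design)
        ss_effects = res.table["ss_effect"].sum()
        # each within-error term appears twice (for the effect and its
        # group interaction); the purely-within rows enumerate them once,
        # plus the between-subject error from the "group" row
        err_rows = res.table[~res.table["effect"].str.contains("group")]
        ss_errors = err_rows["ss_error"].sum() + res.effect("group")["ss_error"]
        ss_total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert ss_effects + ss_errors == pytest.approx(ss_total, rel=1e-9)

    def test_constant_dv_gives_zero_f_and_eta(self):
        df = _mixed_dataset()
        df["y"] = 7.0
        res = nstats.mixed_anova(df, dv="y", within=("hand",))
        assert (res.table["F"] == 0.0).all()
        assert (res.table["eta2p"] == 0.0).all()
        assert (res.table["p"] == 1.0).all()

    def test_type_one_error_calibrated_under_null(self):
        cfg = syn.CohortConfig(
            n_per_group=21,
            group_effects={k: (0.0, 0.0) for k in syn._default_group_effects()},
        )
        rej = 0
        n_sim = 120
        for i in range(n_sim):
            tab = syn.sample_metrics_cohort(cfg, seed=3000 + i)
            res = nstats.mixed_anova(tab, dv="ipe", within=("hand",))
            rej += res.effect("group")["p"] < 0.05
        assert 0.01 <= rej / n_sim <= 0.10

    def test_incomplete_subjects_dropped_listwise(self):
        df = _mixed_dataset(n_per_group=6)
        df = df[~((df.subject == "healthy0") & (df.hand == "dominant"))]
        res = nstats.mixed_anova(df, dv="y", within=("hand",))
        # 12 subjects, one incomplete -> 11 retained, df = 11 - 2 = 9
        assert res.effect("group")["df_den"] == 9

    def test_too_few_subjects_is_error(self):
        df = _mixed_dataset(n_per_group=1)
        with pytest.raises(ValueError):
            nstats.mixed_anova(df, dv="y", within=("hand",))

    def test_more_than_two_within_levels_guarded(self):
        rng = np.random.default_rng(0)
        rows = [
            {"subject": f"s{s}", "group": g, "w": w, "y": rng.normal()}
            for g in ["a", "b"] for s in range(6) for w in ["x", "y", "z"]
        ]
        with pytest.raises(NotImplementedError, match="levels"):
            nstats.mixed_anova(pd.DataFrame(rows), dv="y", within=("w",))


class TestBHAdjust:
    def test_known_step_up_values(self):
        out = nstats.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])
        out2 = nstats.bh_adjust([0.005, 0.9])
        np.testing.assert_allclose(out2, [0.01, 0.9])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 37)
        mine = nstats.bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(mine, ref, rtol=1e-12)

    def test_all_equal_and_empty(self):
        np.testing.assert_allclose(nstats.bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)
        assert nstats.bh_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nstats.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_monotone_bounded_and_stable_under_reapplication(self, pvals):
        adj = nstats.bh_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in raw p
        assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(pvals) - 1e-12)
        # step-up adjustment is inflationary: re-applying it can only
        # keep or raise values (full idempotence does not hold for the
        # adjusted scale in general)
        assert np.all(nstats.bh_adjust(adj) >= adj - 1e-12)


class TestPosthoc:
    def test_single_comparison_unadjusted(self):
        df = _mixed_dataset()
        out = nstats.posthoc_pairwise(df, dv="y", factor="hand")
        assert len(out) == 1
        assert out.loc[0, "p_adj"] == pytest.approx(out.loc[0, "p_unc"])
        assert out.loc[0, "paired"]  # hand is within-subject

    def test_identical_samples_give_t0_p1(self):
        df = _mixed_dataset()
        df["y"] = df.groupby("subject")["y"].transform("mean")  # same per hand
        out = nstats.posthoc_pairwise(df, dv="y", factor="hand")
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p_unc"] == 1.0

    def test_between_factor_uses_independent_test(self):
        df = _mixed_dataset()
        out = nstats.posthoc_pairwise(df, dv="y", factor="group")
        assert not out.loc[0, "paired"]

    def test_empty_family_gives_empty_table(self):
        df = _mixed_dataset().iloc[:0]
        out = nstats.posthoc_pairwise(df, dv="y", factor="hand")
        assert out.empty


def _spearman_oracle(x, y):
    """Average-rank Spearman via explicit Pearson on midranks."""
    def midrank(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
            i = j
        return ranks
    rx, ry = midrank(x), midrank(y)
    rx -= rx.mean(); ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestSpearman:
    def test_strictly_monotone_gives_plus_minus_one(self):
        x = np.arange(10.0)
        up = nstats.spearman_partial(x, np.exp(x))
        down = nstats.spearman_partial(x, -(x**3))
        assert up.rho == pytest.approx(1.0)
        assert up.r_s2 == pytest.approx(1.0)
        assert up.reported
        assert down.rho == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self, rng):
        for _ in range(25):
            x = rng.integers(0, 5, 30).astype(float)  # heavy ties
            y = rng.integers(0, 4, 30).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = nstats.spearman_partial(x, y)
            assert res.rho == pytest.approx(_spearman_oracle(x, y), abs=1e-12)

    def test_matches_scipy_spearmanr(self, rng):
        from scipy.stats import spearmanr

        x = rng.normal(size=40)
        y = rng.normal(size=40)
        res = nstats.spearman_partial(x, y)
        ref = spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)

    def test_zero_variance_flagged_undefined(self):
        res = nstats.spearman_partial(np.ones(10), np.arange(10.0))
        assert not res.defined
        assert not res.reported

    def test_partial_removes_covariate_driven_association(self, rng):
        z = rng.normal(size=200)
        x = z + rng.normal(0, 0.1, 200)
        y = z + rng.normal(0, 0.1, 200)
        plain = nstats.spearman_partial(x, y)
        part = nstats.spearman_partial(x, y, covariates=[z])
        assert plain.r_s2 > 0.25
        assert abs(part.rho) < 0.3

    def test_too_few_cases_is_error(self):
        with pytest.raises(ValueError):
            nstats.spearman_partial([1, 2, 3], [1, 2, 3])

    @given(
        seed=st.integers(0, 1000),
        a=st.floats(0.1, 5.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariant_to_strictly_monotone_transforms(self, seed, a):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = nstats.spearman_partial(x, y).rho
        t1 = nstats.spearman_partial(np.exp(a * x), y).rho
        t2 = nstats.spearman_partial(x, a * y + 3.0).rho
        assert base == pytest.approx(t1, abs=1e-12)
        assert base == pytest.approx(t2, abs=1e-12)


class TestEffectSizeAndNormality:
    @pytest.mark.parametrize(
        "eta,label",
        [(0.01, "negligible"), (0.02, "small"), (0.12, "small"),
         (0.13, "medium"), (0.25, "medium"), (0.26, "large"), (0.30, "large")],
    )
    def test_effect_size_landmarks(self, eta, label):
        assert nstats.effect_size_label(eta) == label

    def test_out_of_range_eta_rejected(self):
        with pytest.raises(ValueError):
            nstats.effect_size_label(1.5)

    def test_shapiro_flag_rate_under_normality(self, rng):
        flags = sum(
            nstats.shapiro_check(rng.normal(size=50))[1] for _ in range(200)
        )
        assert 0.01 <= flags / 200 <= 0.10

    def test_shapiro_power_against_exponential(self, rng):
        flags = sum(
            nstats.shapiro_check(rng.exponential(size=50))[1] for _ in range(100)
        )
        assert flags / 100 > 0.9

    def test_constant_sample_is_error(self):
        with pytest.raises(ValueError):
            nstats.shapiro_check(np.full(10, 3.0))

    def test_out_of_range_n_is_error(self):
        with pytest.raises(ValueError):
            nstats.shapiro_check([1.0, 2.0])
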