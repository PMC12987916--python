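"""Statistical battery: ANCOVA, Holm, post-hoc contrasts, Levene, Fisher."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

from sitpipe.cohort_sim import SimConfig, simulate_cohort
from sitpipe.group_stats import (
    count_atypical,
    fisher_exact_2x2,
    fit_ancova,
    hedges_g,
    holm_adjust,
    levene_median,
    posthoc_contrasts,
    run_stat_battery,
)
from sitpipe.io_formats import PhenotypeRecord
from sitpipe.relatedness import sensitivity_exclusions

CONTROL_MEANS = {"li_word": -1.5, "li_praxis": -1.2, "li_spatial": 1.0, "li_face": 0.8}


def _record(word, praxis, spatial, face):
    return PhenotypeRecord("X", li_word=word, li_praxis=praxis,
                           li_spatial=spatial, li_face=face)


class TestCountAtypical:
    def test_all_opposite_signs(self):
        assert count_atypical(_record(1.0, 1.0, -1.0, -1.0), CONTROL_MEANS) == 4

    def test_all_typical(self):
        assert count_atypical(_record(-1.0, -1.0, 1.0, 1.0), CONTROL_MEANS) == 0

    def test_zero_index_counts_as_typical(self):
        assert count_atypical(_record(0.0, -1.0, 1.0, 1.0), CONTROL_MEANS) == 0

    def test_zero_control_mean_rejected(self):
        means = dict(CONTROL_MEANS, li_word=0.0)
        with pytest.raises(ValueError, match="zero"):
            count_atypical(_record(1.0, -1.0, 1.0, 1.0), means)


class TestAncova:
    def test_balanced_no_covariate_matches_one_way_anova(self):
        """With covariates balanced within groups and orthogonal to the
        outcome, the Type II group test reduces to the closed-form one-way
        ANOVA (up to the residual degrees of freedom)."""
        # per-group outcome block [1,2,2,1]+offset with age [30,40,30,40]
        # and sex [M,M,F,F]: covariates are exactly orthogonal to both the
        # outcome and the group factor, so SS_age = SS_sex = 0
        block = np.array([1.0, 2.0, 2.0, 1.0])
        y = np.concatenate([np.tile(block + off, 5) for off in (0.0, 1.0, 2.0)])
        group = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        age = [30.0, 40.0, 30.0, 40.0] * 15
        sex = ["M", "M", "F", "F"] * 15
        res = fit_ancova(y, group, age, sex)
        groups = [y[:20], y[20:40], y[40:]]
        grand = y.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        n = 60
        f_oneway = (ss_between / 2) / (ss_within / (n - 3))
        assert res.df_num == 2 and res.df_den == n - 5
        assert res.eta2_partial == pytest.approx(ss_between / (ss_between + ss_within))
        assert res.F == pytest.approx(f_oneway * (n - 5) / (n - 3))

    def test_constant_outcome_degenerate(self):
        res = fit_ancova([1.0] * 30, ["a", "b", "c"] * 10,
                         list(range(30)), ["M", "F"] * 15)
        assert res.degenerate and res.F == 0.0 and res.eta2_partial == 0.0

    def test_eta2_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(33)
        y = rng.normal(0, 1, 60)
        group = ["a", "b", "c"] * 20
        age = list(rng.normal(40, 10, 60))
        sex = ["M", "F"] * 30
        r1 = fit_ancova(y, group, age, sex)
        r2 = fit_ancova(7.3 * y - 2.0, group, age, sex)
        assert r1.eta2_partial == pytest.approx(r2.eta2_partial, abs=1e-10)

    def test_missing_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_ancova([1.0, np.nan] * 10, ["a", "b"] * 10, list(range(20)), ["M", "F"] * 10)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == [0.03]

    def test_two_values_hand_computed(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_matches_direct_step_down_definition(self):
        """Random vectors against a hand-written step-down oracle."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            m = int(rng.integers(1, 10))
            p = rng.uniform(0, 1, m)
            order = np.argsort(p)
            adj_sorted = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, min(1.0, (m - rank) * p[idx]))
                adj_sorted[idx] = running
            assert holm_adjust(p) == pytest.approx(list(adj_sorted))

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(18)
        p = sorted(rng.uniform(0, 1, 6))
        adj = holm_adjust(p)
        assert all(a >= r for a, r in zip(adj, p))
        assert adj == sorted(adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestPosthoc:
    def _data(self, rng, shift=0.0):
        n = 25
        y = np.concatenate([rng.normal(0, 1, n), rng.normal(shift, 1, n), rng.normal(0, 1, n)])
        group = ["solved"] * n + ["unsolved"] * n + ["control"] * n
        age = list(rng.normal(40, 10, 3 * n))
        sex = ["M", "F"] * (3 * n // 2) + ["M"] * (3 * n % 2)
        return y, group, age, sex

    def test_identical_groups_zero_effect(self):
        y = np.tile(np.arange(10.0), 3)
        group = ["solved"] * 10 + ["unsolved"] * 10 + ["control"] * 10
        age = list(np.tile(np.arange(10.0), 3) + 30)
        sex = (["M", "F"] * 15)
        for c in posthoc_contrasts(y, group, age, sex):
            assert c.emm_diff == pytest.approx(0.0, abs=1e-10)
            assert c.hedges_g == pytest.approx(0.0, abs=1e-10)

    def test_balanced_covariates_reduce_to_raw_mean_difference(self):
        """With covariate patterns identical across groups the adjusted
        difference equals the raw mean difference exactly."""
        rng = np.random.default_rng(40)
        n = 24
        y = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n), rng.normal(0, 1, n)])
        group = ["solved"] * n + ["unsolved"] * n + ["control"] * n
        age = list(np.tile(np.arange(30.0, 54.0), 3))
        sex = ["M", "F"] * (3 * n // 2)
        contrasts = posthoc_contrasts(y, group, age, sex)
        raw = {g: np.mean([v for v, gg in zip(y, group) if gg == g])
               for g in ("solved", "unsolved", "control")}
        for c in contrasts:
            assert c.emm_diff == pytest.approx(raw[c.group_a] - raw[c.group_b], abs=1e-9)

    def test_tukey_p_not_below_pairwise_p(self):
        rng = np.random.default_rng(41)
        y, group, age, sex = self._data(rng, shift=0.8)
        for c in posthoc_contrasts(y, group, age, sex):
            a = [v for v, g in zip(y, group) if g == c.group_a]
            b = [v for v, g in zip(y, group) if g == c.group_b]
            _, p_raw = sps.ttest_ind(a, b)
            assert c.p_tukey >= p_raw - 1e-9

    def test_hedges_g_approaches_cohens_d(self):
        """The small-sample correction vanishes as df grows."""
        rng = np.random.default_rng(42)
        n = 5001  # df = 10^4
        a = rng.normal(0.5, 1, n)
        b = rng.normal(0.0, 1, n)
        df = 2 * n - 2
        pooled = math.sqrt(((n - 1) * a.var(ddof=1) + (n - 1) * b.var(ddof=1)) / df)
        d = (a.mean() - b.mean()) / pooled
        assert abs(hedges_g(a, b) - d) < 1e-3


class TestLevene:
    def test_power_against_inflated_variance(self):
        rng = np.random.default_rng(50)
        rejections = 0
        reps = 200
        for _ in range(reps):
            vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 2, 50),
                                   rng.normal(0, 1, 50)])
            groups = ["a"] * 50 + ["b"] * 50 + ["c"] * 50
            if levene_median(vals, groups)["p"] < 0.05:
                rejections += 1
        assert rejections / reps > 0.8

    def test_constant_data_degenerate(self):
        out = levene_median([1.0] * 30, ["a", "b", "c"] * 10)
        assert out["degenerate"]

    def test_matches_brown_forsythe_anova_on_deviations(self):
        """The statistic equals a one-way ANOVA F on absolute deviations
        from group medians."""
        rng = np.random.default_rng(51)
        samples = [rng.normal(0, s, 40) for s in (1.0, 1.5, 2.0)]
        vals = np.concatenate(samples)
        groups = ["a"] * 40 + ["b"] * 40 + ["c"] * 40
        devs = [np.abs(s - np.median(s)) for s in samples]
        f_oracle, p_oracle = sps.f_oneway(*devs)
        out = levene_median(vals, groups)
        assert out["W"] == pytest.approx(f_oracle)
        assert out["p"] == pytest.approx(p_oracle)


class TestFisher:
    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2([[5, 14], [5, 14]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        """Exhaustive enumeration over the hypergeometric support."""
        table = [[5, 14], [4, 15]]
        r1, r2 = 19, 19
        c1 = 9
        n = 38
        observed = sps.hypergeom.pmf(5, n, r1, c1)
        p_oracle = sum(
            sps.hypergeom.pmf(a, n, r1, c1)
            for a in range(max(0, c1 - r2), min(r1, c1) + 1)
            if sps.hypergeom.pmf(a, n, r1, c1) <= observed * (1 + 1e-9)
        )
        assert fisher_exact_2x2(table) == pytest.approx(p_oracle)

    def test_extreme_table_closed_form(self):
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(2 / math.comb(20, 10))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 4]])


class TestBattery:
    def test_null_effects_rarely_trigger_posthoc(self):
        """With no planted group effects (equal flip probabilities), the
        Holm gate holds each family's false-trigger rate at the nominal
        5%, so across the three families most replicates trigger no
        post-hoc stage at all."""
        from sitpipe.cohort_sim import simulate_phenotypes
        from test_cohort_sim import _toy_individuals

        effects = {k: 0.0 for k in
                   ("frontal_petalia", "frontal_bending", "occipital_petalia",
                    "occipital_bending", "sinus", "li_word", "li_praxis",
                    "li_spatial", "li_face")}
        inds, labels = _toy_individuals(25)
        rng = np.random.default_rng(99)
        triggered = 0
        reps = 100
        for _ in range(reps):
            recs, _ = simulate_phenotypes(inds, labels, effects,
                                          {"control": 0.08, "case": 0.08}, rng)
            b = run_stat_battery(recs, inds, labels)
            if b["posthoc"]:
                triggered += 1
        # three Holm families at familywise 0.05 each: joint false-trigger
        # probability is about 1 - 0.95^3 ~ 0.14
        assert triggered / reps <= 0.25

    def test_planted_torque_effects_detected_in_majority_of_seeds(self):
        """With the default planted effects, occipital bending passes the
        Holm gate and frontal bending (zero planted effect) does not, in
        the majority of seeds."""
        occ_hits, frontal_quiet = 0, 0
        seeds = range(8)
        for seed in seeds:
            c = simulate_cohort(SimConfig(seed=seed))
            b = run_stat_battery(c.phenotypes, c.individuals, c.ground_truth.group_labels)
            occ_hits += "occipital_bending" in b["posthoc"]
            frontal_quiet += b["ancova"]["frontal_bending"].p_holm > 0.05
        assert occ_hits > len(seeds) / 2
        assert frontal_quiet > len(seeds) / 2

    def test_exclusion_sets_yield_four_reduced_bundles(self, default_cohort):
        sets = sensitivity_exclusions(list(default_cohort.ground_truth.sib_pairs))
        assert len(sets) == 4
        for excl in sets:
            b = run_stat_battery(
                default_cohort.phenotypes,
                default_cohort.individuals,
                default_cohort.ground_truth.group_labels,
                exclusion_set=excl,
            )
            assert b["n_individuals"] == 74
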