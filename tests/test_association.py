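"""Association statistics: partial Spearman, BH-FDR, concordance, meal
summaries, OLS, DerSimonian-Laird meta-analysis, paired t, clustering."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.meta_analysis import combine_effects

from twinbile.association import (
    bh_fdr,
    cluster_species,
    linear_association,
    meta_random_effects,
    paired_ttest,
    partial_spearman,
    prevalence_filter,
    replicate_concordance,
    species_screen,
    summarize_meal,
    tertile_code,
)
from twinbile.prediction import MicrobiomeProfile
from twinbile.synthetic import simulate_microbiome


def _bh_bruteforce(pvals):
    """Step-up BH from the definition: q_(i) = min_{j>=i} m p_(j) / j, capped."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((m * p[order] / (np.arange(m) + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestPrevalenceFilter:
    def test_strict_threshold(self):
        n = 100
        cols = {}
        for prev in (20, 21, 100):
            col = np.zeros(n)
            col[:prev] = 1.0
            cols[f"p{prev}"] = col
        df = pd.DataFrame(cols)
        df = df.div(df.sum(axis=1).replace(0, 1.0), axis=0)
        df["p100"] = df["p100"].where(df.sum(axis=1) > 0, 1.0)
        kept = prevalence_filter(MicrobiomeProfile(df.div(df.sum(axis=1), axis=0)), 0.20)
        assert "p21" in kept and "p100" in kept
        assert "p20" not in kept


class TestPartialSpearman:
    def test_no_covariates_equals_plain_spearman(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=80), rng.normal(size=80)
        rho, p, n = partial_spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_identity_gives_rho_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        rho, p, _ = partial_spearman(x, x, z)
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_confounder_removed(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=1000)
        x = z + rng.normal(size=1000)
        y = z + rng.normal(size=1000)
        rho_marg, _, _ = partial_spearman(x, y)
        rho_part, _, _ = partial_spearman(x, y, z)
        assert rho_marg > 0.4
        assert abs(rho_part) < 0.05

    def test_matches_pingouin(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=120),
                "y": rng.normal(size=120),
                "z1": rng.normal(size=120),
                "z2": rng.normal(size=120),
            }
        )
        df["y"] += 0.5 * df["x"] + 0.3 * df["z1"]
        # pingouin ranks the covariates as well; feed it our convention's
        # rank-transformed covariates so the two constructions coincide
        ranked = df[["z1", "z2"]].apply(lambda c: stats.rankdata(c))
        rho, p, _ = partial_spearman(df["x"].to_numpy(), df["y"].to_numpy(), ranked)
        ref = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"], method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=200)
        x = z + rng.normal(size=200)
        y = 0.5 * z + rng.normal(size=200)
        rho1, _, _ = partial_spearman(x, y, z)
        rho2, _, _ = partial_spearman(np.exp(x), y**3, z)
        assert rho1 == pytest.approx(rho2, abs=1e-10)

    def test_zero_residual_variance_rejected(self):
        z = np.arange(10.0)
        with pytest.raises(ValueError):
            partial_spearman(z, np.ones(10) * 2, None)


class TestBhFdr:
    def test_example_four_pvalues(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(1e-6, 1.0, allow_nan=False), min_size=1, max_size=8
        )
    )
    def test_matches_bruteforce_oracle(self, pvals):
        assert np.allclose(bh_fdr(pvals), _bh_bruteforce(pvals), atol=1e-12)

    def test_order_equivariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.001, 1.0, 20)
        perm = rng.permutation(20)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_q_at_least_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.001, 1.0, 50)
        assert (bh_fdr(p) >= p - 1e-12).all()


class TestConcordance:
    def _screen(self, rows):
        return pd.DataFrame(rows, columns=["feature", "estimate", "p", "q"])

    def test_gates_and_sign(self):
        disc = self._screen(
            [
                ("s1", 0.3, 1e-4, 0.01),
                ("s2", 0.3, 1e-4, 0.01),
                ("s3", 0.3, 0.02, 0.06),
            ]
        )
        val = self._screen(
            [
                ("s1", 0.2, 0.04, 0.2),
                ("s2", -0.2, 0.04, 0.2),
                ("s3", 0.3, 0.001, 0.01),
            ]
        )
        conc, missing = replicate_concordance(disc, val)
        assert conc == ["s1"]  # s2 flips sign, s3 fails the discovery gate
        assert missing == []

    def test_missing_from_validation_reported(self):
        disc = self._screen([("s1", 0.3, 1e-4, 0.01)])
        val = self._screen([("other", 0.2, 0.04, 0.2)])
        conc, missing = replicate_concordance(disc, val)
        assert conc == [] and missing == ["s1"]


class TestMealSummary:
    def _long(self, values, times=(0, 30, 120, 240, 360)):
        return pd.DataFrame(
            {
                "sample_id": ["s1"] * len(times),
                "analyte": ["tg"] * len(times),
                "timepoint_min": times,
                "value": values,
            }
        )

    def test_peak_and_delta(self):
        tab = summarize_meal(self._long([1.0, 1.5, 2.5, 2.0, 1.5]), "tg", 6.0)
        row = tab.iloc[0]
        assert row["baseline"] == 1.0 and row["peak"] == 2.5 and row["delta"] == 1.5

    def test_window_restricts_peak(self):
        tab = summarize_meal(self._long([1.0, 1.5, 2.5, 3.0, 3.5]), "tg", 2.0)
        assert tab.iloc[0]["peak"] == 2.5  # 4h and 6h values out of window

    def test_monotone_decreasing_negative_delta(self):
        tab = summarize_meal(self._long([2.0, 1.8, 1.5, 1.2, 1.0]), "tg", 6.0)
        assert tab.iloc[0]["delta"] < 0  # time-0 is not a peak candidate

    def test_missing_baseline_errors(self):
        df = self._long([1.0, 1.5, 2.5, 2.0, 1.5])
        with pytest.raises(ValueError, match="time-0"):
            summarize_meal(df[df["timepoint_min"] > 0], "tg", 6.0)


class TestLinearAssociation:
    def test_exact_linear_relationship(self):
        x = np.linspace(0, 1, 30)
        rec = linear_association(2.0 * x, x)
        assert rec.estimate == pytest.approx(2.0, abs=1e-10)
        assert rec.p < 1e-20

    def test_null_coverage(self):
        rng = np.random.default_rng(7)
        covered = 0
        for _ in range(200):
            x = rng.normal(size=60)
            y = rng.normal(size=60)
            rec = linear_association(y, x)
            covered += rec.ci[0] <= 0.0 <= rec.ci[1]
        assert 180 <= covered <= 200  # ~95% nominal

    def test_r_squared_and_f_reported(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=318)
        y = 0.2 * x + rng.normal(size=318)
        rec = linear_association(y, x)
        assert rec.extra["df_resid"] == 316
        assert rec.extra["r_squared"] > 0
        assert rec.extra["f_stat"] > 0

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        cov = pd.DataFrame({"dup": x})
        with pytest.raises(ValueError, match="rank-deficient"):
            linear_association(rng.normal(size=40), x, cov)

    def test_tertile_code(self):
        codes = tertile_code(np.arange(9.0))
        assert codes.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]


class TestMetaAnalysis:
    def test_hand_arithmetic_dl(self):
        res = meta_random_effects([0.4, 0.6], [0.1, 0.1])
        # w = 100 each; Q = 100*0.01 + 100*0.01 = 2; denom = 200 - 20000/200 = 100
        assert res.tau2 == pytest.approx(0.01, abs=1e-10)
        assert res.pooled_beta == pytest.approx(0.5, abs=1e-10)

    def test_homogeneous_reduces_to_fixed_effect(self):
        res = meta_random_effects([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert res.tau2 == 0.0
        w = 1.0 / np.array([0.01, 0.04, 0.09])
        assert res.pooled_se == pytest.approx(np.sqrt(1.0 / w.sum()), abs=1e-12)
        assert res.pooled_beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_statsmodels_dl(self):
        betas = np.array([0.32, 0.26, 0.07, 0.5])
        ses = np.array([0.07, 0.066, 0.05, 0.2])
        res = meta_random_effects(betas, ses)
        ref = combine_effects(betas, ses**2, method_re="dl")
        assert res.tau2 == pytest.approx(ref.tau2, abs=1e-10)
        pooled_ref = ref.summary_frame().loc["random effect", "eff"]
        assert res.pooled_beta == pytest.approx(pooled_ref, abs=1e-10)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.01, 1.0)), min_size=2, max_size=6
        )
    )
    def test_pooled_within_study_range(self, studies):
        betas = [b for b, _ in studies]
        ses = [s for _, s in studies]
        res = meta_random_effects(betas, ses)
        assert min(betas) - 1e-9 <= res.pooled_beta <= max(betas) + 1e-9

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            meta_random_effects([0.5], [0.1])


class TestPairedTtest:
    def test_symmetric_differences_give_p_one(self):
        before = np.zeros(5)
        after = np.array([-1.0, 0.0, 1.0, -2.0, 2.0])
        mean, ci, p = paired_ttest(before, after)
        assert mean == 0.0 and p == pytest.approx(1.0)

    def test_constant_shift_is_error(self):
        with pytest.raises(ValueError, match="zero difference variance"):
            paired_ttest(np.arange(5.0), np.arange(5.0) + 1.0)

    def test_matches_scipy_ci(self):
        rng = np.random.default_rng(10)
        b = rng.normal(size=30)
        a = b + rng.normal(-0.5, 1.0, 30)
        mean, ci, p = paired_ttest(b, a)
        ref = stats.ttest_rel(a, b)
        assert p == pytest.approx(ref.pvalue)
        lo, hi = ref.confidence_interval()
        assert ci == (pytest.approx(lo), pytest.approx(hi))


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        df = pd.DataFrame([[0.1, 0.2], [0.1, 0.2], [5.0, 5.0]], index=list("abc"))
        order, Z = cluster_species(df)
        assert Z[0, 2] == 0.0
        assert set(order[:2]) == {"a", "b"} or set(order[-2:]) == {"a", "b"}

    def test_complete_linkage_height_is_max_distance(self):
        df = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc"))
        _, Z = cluster_species(df)
        assert Z[0, 2] == 1.0  # first merge {0,1}
        assert Z[-1, 2] == 10.0  # complete linkage: max pairwise distance

    def test_row_permutation_invariance_up_to_relabel(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(6, 3)), index=list("abcdef"))
        order1, _ = cluster_species(df)
        perm = df.sample(frac=1.0, random_state=12)
        order2, _ = cluster_species(perm)
        # same partition structure: adjacency of the two deepest merges preserved
        assert set(order1) == set(order2)
        d1 = {order1.index(i) for i in "ab"}
        d2 = {order2.index(i) for i in "ab"}
        assert (max(d1) - min(d1)) == (max(d2) - min(d2))

    def test_missing_entries_rejected(self):
        df = pd.DataFrame([[0.1, np.nan], [0.2, 0.3]])
        with pytest.raises(ValueError):
            cluster_species(df)


class TestSpeciesScreen:
    def test_planted_species_found_and_null_controlled(self):
        from twinbile.synthetic import calibrated_coupling, couple_metabolite

        prof = simulate_microbiome(300, 40, np.full(40, 0.8), seed=30)
        rng = np.random.default_rng(31)
        covs = pd.DataFrame(
            {"age": rng.uniform(30, 70, 300), "bmi": rng.normal(26, 4, 300)}
        )
        coup = calibrated_coupling(prof, (0,), (1.0,), target_r2=0.3)
        y, _ = couple_metabolite(prof, coup, seed=31)
        screen = species_screen(prof, y, covs, prevalence=0.2)
        top = screen.sort_values("q").iloc[0]
        assert top["feature"] == "sp_0000"
        assert top["q"] < 0.05

    def test_constant_covariate_dropped(self):
        prof = simulate_microbiome(100, 10, np.full(10, 0.9), seed=32)
        rng = np.random.default_rng(33)
        covs = pd.DataFrame({"sex": np.zeros(100), "age": rng.uniform(30, 70, 100)})
        screen = species_screen(prof, rng.normal(size=100), covs)
        assert len(screen) == 10  # runs despite the constant column
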