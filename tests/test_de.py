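"""Moderated linear models, empirical-Bayes shrinkage, BH adjustment and
permutation FDR, each against an independent oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitonorm import (
    LinearFits,
    SampleDesign,
    ValidationError,
    adjust_bh,
    differential_features,
    empirical_bayes_moderation,
    fit_linear_models,
    pairwise_permutation_fdr,
)
from mitonorm.de import _welch_t, trigamma_inverse
from tests.conftest import make_design


def _paired_two_tp(rng, n_feat=8, n_part=5):
    design = make_design(n_part, timepoints=("BL", "PN"))
    vals = pd.DataFrame(
        rng.normal(20, 1, (n_feat, 2 * n_part)),
        index=[f"F{i}" for i in range(n_feat)],
        columns=design.samples,
    )
    return vals, design


class TestLinearFits:
    def test_paired_contrast_equals_mean_within_participant_difference(
            self, rng):
        vals, design = _paired_two_tp(rng)
        fits = fit_linear_models(vals, design, "phase")
        part = design.participant_of()
        tp = design.timepoint_of()
        for f in vals.index:
            diffs = []
            for p in part.unique():
                cols = part.index[(part == p)]
                bl = cols[(tp[cols] == "BL")][0]
                pn = cols[(tp[cols] == "PN")][0]
                diffs.append(vals.loc[f, pn] - vals.loc[f, bl])
            assert fits.coefficients.loc[f, "PN-BL"] == pytest.approx(
                np.mean(diffs), abs=1e-10)

    def test_participant_shift_does_not_move_contrasts(self, rng):
        vals, design = _paired_two_tp(rng)
        fits0 = fit_linear_models(vals, design, "phase")
        shifted = vals.copy()
        p1_cols = design.participant_of().index[
            design.participant_of() == "P01"]
        shifted[p1_cols] += 5.0
        fits1 = fit_linear_models(shifted, design, "phase")
        pd.testing.assert_frame_equal(fits0.coefficients, fits1.coefficients,
                                      atol=1e-10, rtol=0)

    def test_coefficients_match_normal_equations(self, rng):
        """Six-feature fixture against an explicit matrix-algebra solve."""
        design = make_design(3)
        vals = pd.DataFrame(
            rng.normal(0, 1, (6, 12)),
            index=[f"F{i}" for i in range(6)],
            columns=design.samples,
        )
        fits = fit_linear_models(vals, design, "vs-baseline")
        tp = design.timepoint_of()
        part = design.participant_of()
        X = np.column_stack(
            [np.ones(12)]
            + [(tp == t).to_numpy(float) for t in ("PN", "PH", "PR")]
            + [(part == p).to_numpy(float) for p in ("P02", "P03")]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ vals.to_numpy().T)
        for j, t in enumerate(("PN", "PH", "PR")):
            np.testing.assert_allclose(
                fits.coefficients[f"{t}-BL"].to_numpy(), beta[1 + j],
                atol=1e-10)
        resid = vals.to_numpy().T - X @ beta
        s2 = (resid ** 2).sum(axis=0) / (12 - 6)
        np.testing.assert_allclose(fits.s2.to_numpy(), s2, atol=1e-12)

    def test_rank_deficient_design_lists_aliased_terms(self, rng):
        # participants nested in timepoints: block aliases the contrasts
        rows = [("a", "P01", "BL", "proteomics"),
                ("b", "P01", "PN", "proteomics"),
                ("c", "P02", "PH", "proteomics"),
                ("d", "P02", "PR", "proteomics")]
        design = SampleDesign(pd.DataFrame(
            rows, columns=["sample", "participant", "timepoint", "layer"]))
        vals = pd.DataFrame(rng.normal(0, 1, (3, 4)),
                            index=list("xyz"), columns=list("abcd"))
        with pytest.raises(ValidationError, match="aliased"):
            fit_linear_models(vals, design, "phase")

    def test_missing_values_rejected(self, rng):
        vals, design = _paired_two_tp(rng)
        vals.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            fit_linear_models(vals, design, "phase")


class TestEmpiricalBayes:
    def _fits_from_s2(self, s2, d=27.0):
        g = len(s2)
        return LinearFits(
            coefficients=pd.DataFrame(np.ones((g, 1)), columns=["c"],
                                      index=[f"F{i}" for i in range(g)]),
            s2=pd.Series(s2, index=[f"F{i}" for i in range(g)]),
            df_residual=d,
            stdev_unscaled=pd.Series([1.0], index=["c"]),
            contrast_cov=np.array([[1.0]]),
            contrast_names=["c"],
        )

    def test_equal_variances_give_infinite_prior(self):
        """Observed variances no more dispersed than chi-square sampling
        allows: infinite prior df, every posterior variance collapses to
        the common prior value, and moderated t is proportional to the
        ordinary t (which, with equal s2, it already is)."""
        fits = self._fits_from_s2(np.full(50, 0.7))
        stats = empirical_bayes_moderation(fits)
        assert math.isinf(stats.df_prior)
        post = stats.s2_posterior.to_numpy()
        np.testing.assert_allclose(post, stats.s2_prior, rtol=1e-12)
        # the chi-square bias correction puts the prior slightly above the
        # common observed value (matching the limma reference behaviour)
        assert stats.s2_prior == pytest.approx(0.7, rel=0.05)
        ordinary = 1.0 / np.sqrt(0.7)
        ratio = stats.table["t[c]"].to_numpy() / ordinary
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)

    def test_extreme_dispersion_recovers_ordinary_t(self, rng):
        """When log-variances are far more dispersed than chi-square sampling
        allows, the prior df collapses to ~0 and the moderated t approaches
        the ordinary t (away from the vanishing shrinkage floor)."""
        s2 = np.exp(rng.normal(0, 40, 4000))
        fits = self._fits_from_s2(s2)
        stats = empirical_bayes_moderation(fits)
        assert stats.df_prior < 0.06
        bulk = s2 > np.quantile(s2, 0.2)
        ordinary = 1.0 / np.sqrt(s2[bulk])
        np.testing.assert_allclose(
            stats.table["t[c]"].to_numpy()[bulk], ordinary, rtol=5e-3)

    def test_prior_recovery_on_simulated_variances(self):
        """s2 ~ s02 * chi2_d / d with inverse-chi-square prior (d0=4,
        s02=2): recovered within +-25% / +-10%."""
        r = np.random.default_rng(7)
        d0, s02, d, g = 4.0, 2.0, 27.0, 5000
        sigma2 = d0 * s02 / r.chisquare(d0, g)
        s2 = sigma2 * r.chisquare(d, g) / d
        stats = empirical_bayes_moderation(self._fits_from_s2(s2, d))
        assert abs(stats.df_prior - d0) / d0 < 0.25
        assert abs(stats.s2_prior - s02) / s02 < 0.10

    def test_posterior_is_precision_weighted_average(self, rng):
        s2 = np.exp(rng.normal(0, 1, 300))
        stats = empirical_bayes_moderation(self._fits_from_s2(s2))
        d0, s02, d = stats.df_prior, stats.s2_prior, stats.df_residual
        expected = (d0 * s02 + d * s2) / (d0 + d)
        np.testing.assert_allclose(stats.s2_posterior.to_numpy(), expected,
                                   rtol=1e-12)

    def test_matches_limma_reference_values(self):
        """Frozen oracle: the same fixture fitted with Bioconductor limma
        3.58.1 (lmFit + eBayes, timepoint + participant design)."""
        r = np.random.default_rng(42)
        g, p = 12, 4
        base = r.normal(20, 1, (g, 1))
        effect = np.concatenate([np.zeros(6), r.normal(0, 1.5, 6)])
        vals = np.zeros((g, 2 * p))
        for i in range(p):
            pe = r.normal(0, 0.3, g)
            noise_sd = r.uniform(0.1, 0.6, g)
            vals[:, i] = base[:, 0] + pe + r.normal(0, noise_sd)
            vals[:, p + i] = base[:, 0] + pe + effect + r.normal(0, noise_sd)
        cols = [f"P{i + 1}_BL" for i in range(p)] + [
            f"P{i + 1}_PN" for i in range(p)]
        df = pd.DataFrame(vals, index=[f"F{i:02d}" for i in range(g)],
                          columns=cols)
        design = SampleDesign(pd.DataFrame({
            "sample": cols,
            "participant": [c.split("_")[0] for c in cols],
            "timepoint": [c.split("_")[1] for c in cols],
            "layer": "proteomics",
        }))
        stats = empirical_bayes_moderation(
            fit_linear_models(df, design, "phase"))
        assert stats.df_prior == pytest.approx(2.011982, abs=1e-5)
        assert stats.s2_prior == pytest.approx(0.04061516, rel=1e-5)
        t_limma = np.array([
            -0.4685314283, -1.0088388499, -1.6716382141, -0.6487511283,
            0.0349525619, 0.7835500229, 0.0952006871, 19.9448044158,
            2.7917982491, -9.1355388958, 6.2720621665, -9.6263382464,
        ])
        np.testing.assert_allclose(stats.table["t[PN-BL]"].to_numpy(),
                                   t_limma, atol=1e-8)

    def test_f_equals_squared_t_for_single_contrast(self, rng):
        vals, design = _paired_two_tp(rng, n_feat=20)
        stats = empirical_bayes_moderation(
            fit_linear_models(vals, design, "phase"))
        np.testing.assert_allclose(stats.table["F"].to_numpy(),
                                   stats.table["t[PN-BL]"].to_numpy() ** 2,
                                   rtol=1e-12)

    def test_trigamma_inverse_inverts(self):
        from scipy.special import polygamma
        for x in (1e-5, 0.05, 0.5, 3.0, 1e4):
            y = trigamma_inverse(x)
            assert float(polygamma(1, y)) == pytest.approx(x, rel=1e-6)


def _bh_bruteforce(p):
    """Independent step-up implementation straight from the definition:
    adj(p_i) = min over thresholds p_j >= p_i of p_(j) * m / rank(j)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for pos, i in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestBenjaminiHochberg:
    def test_worked_example(self):
        out = adjust_bh(np.array([0.005, 0.01, 0.03, 0.04]))
        np.testing.assert_allclose(out, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_bh(np.array([0.123]))[0] == pytest.approx(0.123)

    def test_constant_vector_unchanged(self):
        np.testing.assert_allclose(adjust_bh(np.full(7, 0.2)),
                                   np.full(7, 0.2))

    def test_matches_bruteforce_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            mine = adjust_bh(p)
            np.testing.assert_allclose(mine, _bh_bruteforce(p), atol=1e-12)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_missing_p_propagates_and_is_excluded_from_m(self):
        p = np.array([0.01, np.nan, 0.04])
        out = adjust_bh(p)
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], adjust_bh(p[[0, 2]]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh(np.array([0.5, 1.2]))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30),
           st.randoms(use_true_random=False))
    def test_order_equivariance(self, plist, shuffler):
        p = np.array(plist)
        perm = list(range(len(p)))
        shuffler.shuffle(perm)
        perm = np.array(perm)
        direct = adjust_bh(p)[perm]
        permuted = adjust_bh(p[perm])
        np.testing.assert_allclose(direct, permuted, atol=1e-12)
        assert np.all(permuted >= p[perm] - 1e-12)  # adjusted >= raw


class TestPermutationFdr:
    def _three_vs_three(self, rng):
        design = make_design(3, timepoints=("BL", "PN"))
        vals = pd.DataFrame(
            rng.normal(0, 1, (30, 6))
            + np.array([0, 1, 0, 1, 1, 0]) * rng.normal(1, 0.5, (30, 1)),
            index=[f"F{i}" for i in range(30)],
            columns=design.samples,
        )
        return vals, design

    def test_exhaustive_matches_full_enumeration(self, rng):
        vals, design = self._three_vs_three(rng)
        res = pairwise_permutation_fdr(vals, design, ("PN", "BL"),
                                       n_perm=1000, seed=0)
        assert res.exhaustive and res.n_permutations == 20

        tp = design.timepoint_of().reindex(vals.columns)
        pool = vals[[*vals.columns[(tp == "BL").to_numpy()],
                     *vals.columns[(tp == "PN").to_numpy()]]].to_numpy()
        null_abs = np.concatenate([
            np.abs(_welch_t(pool[:, np.setdiff1d(np.arange(6), comb)],
                            pool[:, list(comb)]))
            for comb in itertools.combinations(range(6), 3)
        ])
        t_obs = np.abs(_welch_t(pool[:, :3], pool[:, 3:]))
        q_expected = []
        for tg in t_obs:
            fdrs = [
                ((null_abs >= c).sum() / 20) / max(1, (t_obs >= c).sum())
                for c in t_obs if c <= tg
            ]
            q_expected.append(min(1.0, min(fdrs)))
        np.testing.assert_allclose(res.table["q"].to_numpy(), q_expected,
                                   atol=1e-12)

    def test_doubling_values_leaves_t_unchanged(self, rng):
        """The Welch statistic is scale-free."""
        vals, design = self._three_vs_three(rng)
        res1 = pairwise_permutation_fdr(vals, design, ("PN", "BL"), seed=0)
        res2 = pairwise_permutation_fdr(2.0 * vals, design, ("PN", "BL"),
                                        seed=0)
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_null_q_values_control_false_positives(self):
        """Pure-noise features: the q <= 0.05 call rate stays near or below
        its nominal level across seeds."""
        design = make_design(10, timepoints=("BL", "PN"))
        rates = []
        for seed in range(6):
            r = np.random.default_rng(seed)
            vals = pd.DataFrame(
                r.normal(0, 1, (500, 20)),
                index=[f"F{i}" for i in range(500)],
                columns=design.samples,
            )
            res = pairwise_permutation_fdr(vals, design, ("PN", "BL"),
                                           n_perm=300, seed=seed)
            rates.append(float((res.table["q"] <= 0.05).mean()))
        binom_sd = math.sqrt(0.05 * 0.95 / 500)
        assert np.mean(rates) <= 0.05 + 2 * binom_sd

    def test_q_monotone_in_abs_t(self, rng):
        vals, design = self._three_vs_three(rng)
        res = pairwise_permutation_fdr(vals, design, ("PN", "BL"), seed=0)
        t_order = res.table["t"].abs().sort_values(ascending=False).index
        q_sorted = res.table.loc[t_order, "q"].to_numpy()
        assert np.all(np.diff(q_sorted) >= -1e-12)
        assert ((res.table["q"] >= 0) & (res.table["q"] <= 1)).all()

    def test_paired_mode_exhaustive_sign_flips(self, rng):
        design = make_design(4, timepoints=("BL", "PN"))
        vals = pd.DataFrame(rng.normal(0, 1, (10, 8)) ,
                            index=[f"F{i}" for i in range(10)],
                            columns=design.samples)
        res = pairwise_permutation_fdr(vals, design, ("PN", "BL"),
                                       mode="paired", seed=0)
        assert res.exhaustive and res.n_permutations == 16

    def test_sampled_when_space_is_large(self, rng):
        design = make_design(10, timepoints=("BL", "PN"))
        vals = pd.DataFrame(rng.normal(0, 1, (20, 20)),
                            index=[f"F{i}" for i in range(20)],
                            columns=design.samples)
        res = pairwise_permutation_fdr(vals, design, ("PN", "BL"),
                                       n_perm=200, seed=1)
        assert not res.exhaustive and res.n_permutations == 200

    def test_needs_three_per_group(self, rng):
        design = make_design(2, timepoints=("BL", "PN"))
        vals = pd.DataFrame(rng.normal(0, 1, (5, 4)),
                            index=[f"F{i}" for i in range(5)],
                            columns=design.samples)
        with pytest.raises(ValidationError):
            pairwise_permutation_fdr(vals, design, ("PN", "BL"))


class TestDifferentialFeatures:
    def _stats_and_perm(self, rng, strong=0):
        vals, design = _paired_two_tp(rng, n_feat=40, n_part=5)
        if strong:
            tp = design.timepoint_of().reindex(vals.columns)
            vals.iloc[:strong, (tp == "PN").to_numpy()] += 5.0
        stats = empirical_bayes_moderation(
            fit_linear_models(vals, design, "phase"))
        perm = pairwise_permutation_fdr(vals, design, ("PN", "BL"), seed=0)
        return stats, perm

    def test_empty_global_set_empties_all(self, rng):
        stats, perm = self._stats_and_perm(rng)
        sets = differential_features(stats, perm, alpha_global=1e-12,
                                     alpha_pairwise=0.9)
        assert sets["global"] == set()
        assert sets["PN-BL"] == set()

    def test_alpha_global_one_reduces_to_q_threshold(self, rng):
        stats, perm = self._stats_and_perm(rng, strong=8)
        sets = differential_features(stats, perm, alpha_global=1.0,
                                     alpha_pairwise=0.05)
        q_set = set(perm.table.index[(perm.table["q"] < 0.05).to_numpy()])
        assert sets["PN-BL"] == q_set

    def test_intersection_is_conservative(self, rng):
        stats, perm = self._stats_and_perm(rng, strong=8)
        sets = differential_features(stats, perm, alpha_global=0.01,
                                     alpha_pairwise=0.05)
        assert sets["PN-BL"] <= sets["global"]

    def test_alpha_validation(self, rng):
        stats, perm = self._stats_and_perm(rng)
        with pytest.raises(ValidationError):
            differential_features(stats, perm, alpha_global=0.0)
        with pytest.raises(ValidationError):
            differential_features(stats, perm, alpha_pairwise=1.5)
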