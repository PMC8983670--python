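"""Filtering, imputation, moderated testing, FDR and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import stresswaves as sw
from stresswaves.phospho import PeptideMatrix


def make_pm(values, conditions, **sample_cols):
    samples = pd.DataFrame({"sample": list(values.columns), "condition": conditions})
    for k, v in sample_cols.items():
        samples[k] = v
    return PeptideMatrix(values=values, samples=samples)


def two_group_pm(rng, n_pep=200, n=6, effect=0.0, sd=0.3):
    cols = [f"c{i}" for i in range(n)] + [f"s{i}" for i in range(n)]
    base = rng.normal(20, 2, n_pep)
    y = base[:, None] + rng.normal(0, sd, (n_pep, 2 * n))
    y[:, n:] += effect
    values = pd.DataFrame(y, columns=cols, index=[f"p{i}" for i in range(n_pep)])
    return make_pm(values, ["control"] * n + ["stress"] * n)


class TestFilterMissing:
    def test_fully_observed_kept(self, rng):
        pm = two_group_pm(rng)
        out = sw.filter_missing(pm, thr=2)
        assert len(out.values) == len(pm.values)

    def test_peptide_missing_everywhere_dropped(self, rng):
        pm = two_group_pm(rng, n_pep=5, n=6)
        vals = pm.values.copy()
        vals.iloc[0, [0, 1, 2, 6, 7, 8]] = np.nan  # 3 missing in each condition
        pm2 = make_pm(vals, pm.samples["condition"].tolist())
        out = sw.filter_missing(pm2, thr=2)
        assert "p0" not in out.values.index

    def test_boundary_exactly_thr_missing_kept(self, rng):
        pm = two_group_pm(rng, n_pep=3, n=6)
        vals = pm.values.copy()
        vals.iloc[0, [0, 1]] = np.nan  # 2 missing in control only
        pm2 = make_pm(vals, pm.samples["condition"].tolist())
        out = sw.filter_missing(pm2, thr=2)
        assert "p0" in out.values.index

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_brute_force_keep_set(self, seed):
        r = np.random.default_rng(seed)
        n_pep, n = 30, 4
        cols = [f"x{i}" for i in range(3 * n)]
        conds = ["a"] * n + ["b"] * n + ["c"] * n
        y = r.normal(20, 1, (n_pep, 3 * n))
        y[r.random((n_pep, 3 * n)) < 0.4] = np.nan
        values = pd.DataFrame(y, columns=cols, index=[f"p{i}" for i in range(n_pep)])
        pm = make_pm(values, conds)
        out = sw.filter_missing(pm, thr=1)
        expected = set()
        for p in values.index:
            for cond in ("a", "b", "c"):
                cs = [c for c, cc in zip(cols, conds) if cc == cond]
                if values.loc[p, cs].isna().sum() <= 1:
                    expected.add(p)
                    break
        assert set(out.values.index) == expected

    def test_negative_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            sw.filter_missing(two_group_pm(rng), thr=-1)


class TestImputeMinprob:
    def test_complete_matrix_unchanged(self, rng):
        pm = two_group_pm(rng)
        out = sw.impute_minprob(pm, seed=1)
        pd.testing.assert_frame_equal(out.values, pm.values)

    def test_imputed_values_sit_in_the_low_tail(self, rng):
        pm = two_group_pm(rng, n_pep=1000)
        vals = pm.values.copy()
        miss = rng.random(vals.shape) < 0.2
        arr = vals.to_numpy()
        arr[miss] = np.nan
        pm2 = make_pm(pd.DataFrame(arr, index=vals.index, columns=vals.columns),
                      pm.samples["condition"].tolist())
        out = sw.impute_minprob(pm2, q=0.01, seed=2)
        for j, col in enumerate(vals.columns):
            m = miss[:, j]
            if m.sum() < 10:
                continue
            imputed_mean = out.values.loc[m, col].mean()
            observed_median = pm2.values[col].median()
            assert imputed_mean < observed_median

    def test_seed_reproducibility(self, rng):
        pm = two_group_pm(rng, n_pep=100)
        arr = pm.values.to_numpy()
        arr[rng.random(arr.shape) < 0.2] = np.nan
        pm2 = make_pm(pd.DataFrame(arr, index=pm.values.index, columns=pm.values.columns),
                      pm.samples["condition"].tolist())
        a = sw.impute_minprob(pm2, seed=9)
        b = sw.impute_minprob(pm2, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_all_missing_sample_rejected(self, rng):
        pm = two_group_pm(rng, n_pep=10)
        arr = pm.values.to_numpy()
        arr[:, 0] = np.nan
        pm2 = make_pm(pd.DataFrame(arr, index=pm.values.index, columns=pm.values.columns),
                      pm.samples["condition"].tolist())
        with pytest.raises(ValueError):
            sw.impute_minprob(pm2)


class TestModeratedDiff:
    def test_null_pvalues_uniform(self):
        """Under the null the moderated p-values are uniform (KS test)."""
        r = np.random.default_rng(42)
        pm = two_group_pm(r, n_pep=5000, n=6, effect=0.0)
        res = sw.moderated_diff(pm, ("stress", "control"))
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_zero_prior_df_matches_ordinary_t(self):
        r = np.random.default_rng(7)
        pm = two_group_pm(r, n_pep=300, n=5, effect=0.2)
        res = sw.moderated_diff(pm, ("stress", "control"), prior_df=0)
        y = pm.values.to_numpy()
        t, p = stats.ttest_ind(y[:, 5:], y[:, :5], axis=1)
        np.testing.assert_allclose(res.table["t"], t, atol=1e-8)
        np.testing.assert_allclose(res.table["p"], p, atol=1e-8)

    def test_planted_effect_detected_with_high_power(self):
        """log2FC 1 at sd 0.3, n=6/6: essentially always detected at FDR 0.05."""
        r = np.random.default_rng(11)
        detected = 0
        n_rep = 200
        for _ in range(n_rep):
            pm = two_group_pm(r, n_pep=50, n=6, effect=0.0, sd=0.3)
            arr = pm.values.to_numpy()
            arr[:5, 6:] += 1.0  # plant 5 responders
            res = sw.moderated_diff(pm, ("stress", "control"))
            detected += (res.table["fdr"].iloc[:5] < 0.05).all()
        assert detected / n_rep >= 0.9

    def test_sign_and_magnitude_of_logfc(self, rng):
        pm = two_group_pm(rng, n_pep=500, n=6, effect=0.7, sd=0.1)
        res = sw.moderated_diff(pm, ("stress", "control"))
        assert res.table["log2fc"].mean() == pytest.approx(0.7, abs=0.02)

    def test_block_centring_absorbs_block_shifts(self):
        r = np.random.default_rng(3)
        pm = two_group_pm(r, n_pep=400, n=6, effect=0.0, sd=0.2)
        blocks = ["b1", "b2"] * 6
        arr = pm.values.to_numpy()
        arr[:, np.array(blocks) == "b2"] += r.normal(0, 3, (400, 1))
        values = pd.DataFrame(arr, index=pm.values.index, columns=pm.values.columns)
        pm2 = make_pm(values, pm.samples["condition"].tolist(), block=blocks)
        res_blocked = sw.moderated_diff(pm2, ("stress", "control"), block_col="block")
        ks = stats.kstest(res_blocked.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_summary_mentions_test_and_counts(self, rng):
        pm = two_group_pm(rng, n_pep=50)
        res = sw.moderated_diff(pm, ("stress", "control"))
        out = res.summary()
        assert "moderated t" in out and "50 features" in out


class TestBhFdr:
    def test_hand_computed_step_up(self):
        """p=(.01,.02,.03,.04): step-up gives .04 everywhere."""
        np.testing.assert_allclose(
            sw.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert sw.bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(sw.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.random(200)
        q = sw.bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sw.bh_fdr([0.5, 1.5])


class TestEnrichmentStats:
    @pytest.mark.parametrize(
        "n_phospho,n_total,expected",
        [(10132, 16302, 62), (253, 269, 94), (188, 206, 91)],
    )
    def test_reported_percentages_from_counts(self, n_phospho, n_total, expected):
        """The printed phosphopeptide percentages reproduce exactly from their
        numerator/denominator pairs under round-half-up."""
        is_phospho = np.repeat([True, False], [n_phospho, n_total - n_phospho])
        significant = np.ones(n_total, dtype=bool)
        out = sw.enrichment_stats(is_phospho, significant)
        assert out["fraction_phospho_sig"] == expected

    def test_no_association_table(self):
        is_phospho = np.repeat([True, False], [20, 20])
        significant = np.tile([True, False], 20)
        out = sw.enrichment_stats(is_phospho, significant)
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["fisher_p"] == pytest.approx(1.0)

    def test_enrichment_detected(self):
        is_phospho = np.repeat([True, False], [100, 100])
        significant = np.concatenate([np.ones(80, bool), np.zeros(20, bool),
                                      np.ones(20, bool), np.zeros(80, bool)])
        out = sw.enrichment_stats(is_phospho, significant)
        assert out["odds_ratio"] > 1
        assert out["fisher_p"] < 1e-10

    def test_zero_significant_flagged(self):
        out = sw.enrichment_stats(np.array([True, False]), np.array([False, False]))
        assert np.isnan(out["fraction_phospho_sig"])


class TestInteractionAnova:
    @staticmethod
    def sex_pm(r, n_pep=500, n=5, stress_eff=0.0, sex_eff=0.0, inter=0.0, sd=0.3):
        conds, sexes, cols = [], [], []
        data = []
        base = r.normal(20, 1, n_pep)
        k = 0
        for cond in ("control", "stress"):
            for sex in ("m", "f"):
                for i in range(n):
                    cols.append(f"{cond}_{sex}_{i}")
                    conds.append(cond)
                    sexes.append(sex)
                    mu = base.copy()
                    if cond == "stress":
                        mu = mu + stress_eff
                    if sex == "f":
                        mu = mu + sex_eff
                    if cond == "stress" and sex == "f":
                        mu = mu + inter
                    data.append(mu + r.normal(0, sd, n_pep))
                    k += 1
        values = pd.DataFrame(np.column_stack(data), columns=cols,
                              index=[f"p{i}" for i in range(n_pep)])
        return make_pm(values, conds, sex=sexes)

    def test_additive_truth_gives_uniform_interaction_p(self):
        r = np.random.default_rng(5)
        pm = self.sex_pm(r, n_pep=3000, stress_eff=0.5, sex_eff=0.3, inter=0.0)
        out = sw.interaction_anova(pm)
        ks = stats.kstest(out["p_interaction"], "uniform")
        assert ks.pvalue > 0.01
        assert (out["p_condition"] < 0.05).mean() > 0.9

    def test_crossover_interaction_detected_as_noise_vanishes(self):
        r = np.random.default_rng(6)
        pm = self.sex_pm(r, n_pep=100, stress_eff=0.0, inter=1.0, sd=0.01)
        out = sw.interaction_anova(pm)
        assert (out["p_interaction"] < 1e-6).all()
        # magnitude of the crossover contrast (sign depends on level coding)
        assert abs(out["interaction_effect"].mean()) == pytest.approx(1.0, abs=0.01)

    def test_equal_cell_means_give_p_one(self):
        """With identical replicate sets in all four cells, every effect sum
        of squares is exactly zero, so all p-values are 1."""
        reps = np.array([19.0, 20.0, 21.0])
        vals = pd.DataFrame(
            [np.tile(reps, 4)], index=["p0"],
            columns=[f"s{i}" for i in range(12)],
        )
        pm = make_pm(vals, ["control"] * 6 + ["stress"] * 6,
                     sex=(["m"] * 3 + ["f"] * 3) * 2)
        out = sw.interaction_anova(pm)
        assert out.loc["p0", ["p_interaction", "p_condition", "p_sex"]].min() > 0.999

    def test_empty_cell_rejected(self, rng):
        pm = self.sex_pm(rng, n_pep=5)
        samples = pm.samples.reset_index()
        samples.loc[samples["sex"] == "f", "condition"] = "stress"
        pm2 = PeptideMatrix(values=pm.values, samples=samples)
        with pytest.raises(ValueError):
            sw.interaction_anova(pm2)


class TestPipelineProperties:
    def test_filter_impute_test_deterministic(self, phospho_sim):
        def run():
            pm = PeptideMatrix(
                values=phospho_sim.values,
                samples=phospho_sim.samples,
                peptides=phospho_sim.peptides,
            )
            pm = sw.filter_missing(pm, thr=2)
            pm = sw.impute_minprob(pm, q=0.01, seed=100)
            return sw.moderated_diff(pm, ("stress_6min", "control")).table

        pd.testing.assert_frame_equal(run(), run())

    def test_pipeline_finds_planted_wave_and_respects_site_rule(self, phospho_sim):
        pm = PeptideMatrix(
            values=phospho_sim.values,
            samples=phospho_sim.samples,
            peptides=phospho_sim.peptides,
        )
        pm = sw.filter_missing(pm, thr=2)
        pm = sw.impute_minprob(pm, q=0.01, seed=100)
        res = sw.moderated_diff(pm, ("stress_6min", "control"))
        sig = res.table["fdr"] < 0.05
        truth = phospho_sim.truth.loc[res.table.index, "responsive"]
        # discoveries are overwhelmingly planted responders
        assert truth[sig].mean() > 0.9
        # site labels only exist with localization probability > 0.75
        pep = pm.peptides
        assert (pep.loc[pep["site"] != "", "localization_probability"] > 0.75).all()
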