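"""Attention aggregation and the cohort statistics behind the figures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from akiwatch import aggregate_attention, group_tests, onset_stats, repeated_anova
from akiwatch.interpret import export_heatmap


def weighted_average_oracle(alphas, betas):
    """Independent loop-based recomputation of the aggregation formula."""
    n, V, T = alphas.shape
    S = np.zeros((V, T))
    for v in range(V):
        num = np.zeros(T)
        den = 0.0
        for s in range(n):
            num += betas[s, v] * alphas[s, v, :]
            den += betas[s, v]
        S[v] = num / den
    return S


def _random_attention(rng, n=10, V=4, T=28):
    alphas = rng.random((n, V, T))
    alphas /= alphas.sum(axis=2, keepdims=True)
    betas = rng.random((n, V))
    betas /= betas.sum(axis=1, keepdims=True)
    return alphas, betas


class TestAggregateAttention:
    def test_single_sample_returns_alpha(self, rng):
        alphas, betas = _random_attention(rng, n=1)
        s = aggregate_attention(alphas, betas, list("abcd"))
        np.testing.assert_allclose(s.daily.to_numpy(), alphas[0], atol=1e-12)

    def test_degenerate_weights_pick_first_sample(self, rng):
        alphas, _ = _random_attention(rng, n=2)
        betas = np.array([[1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 0.0, 0.0]])
        s = aggregate_attention(alphas, betas, list("abcd"))
        np.testing.assert_allclose(s.daily.to_numpy(), alphas[0], atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        alphas, betas = _random_attention(rng)
        s = aggregate_attention(alphas, betas, list("abcd"))
        np.testing.assert_allclose(s.daily.to_numpy(),
                                   weighted_average_oracle(alphas, betas),
                                   atol=1e-12)

    def test_permutation_invariant_over_samples(self, rng):
        alphas, betas = _random_attention(rng)
        s1 = aggregate_attention(alphas, betas, list("abcd"))
        perm = rng.permutation(len(alphas))
        s2 = aggregate_attention(alphas[perm], betas[perm], list("abcd"))
        np.testing.assert_allclose(s1.daily.to_numpy(), s2.daily.to_numpy(),
                                   atol=1e-12)

    def test_weekly_binning_preserves_mean(self, rng):
        alphas, betas = _random_attention(rng, T=28)
        s = aggregate_attention(alphas, betas, list("abcd"))
        np.testing.assert_allclose(s.weekly.mean(axis=1).to_numpy(),
                                   s.daily.mean(axis=1).to_numpy(), atol=1e-12)
        assert list(s.weekly.columns) == ["week_-4", "week_-3",
                                          "week_-2", "week_-1"]

    def test_unweighted_flag(self, rng):
        alphas, betas = _random_attention(rng)
        s = aggregate_attention(alphas, betas, list("abcd"), weighted=False)
        np.testing.assert_allclose(s.daily.to_numpy(), alphas.mean(axis=0),
                                   atol=1e-12)

    def test_overall_is_mean_variable_attention(self, rng):
        alphas, betas = _random_attention(rng)
        s = aggregate_attention(alphas, betas, list("abcd"))
        np.testing.assert_allclose(s.overall.to_numpy(), betas.mean(axis=0),
                                   atol=1e-12)


class TestRepeatedAnova:
    def test_identical_columns(self):
        Y = np.tile([[1.0], [2.0], [5.0]], (1, 4))
        F, p = repeated_anova(Y)
        assert (F, p) == (0.0, 1.0)

    def test_parallel_profiles_infinite_f(self):
        # constant within-subject differences: MS_error = 0
        F, p = repeated_anova(np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]]))
        assert F == np.inf and p == 0.0

    def test_hand_computed_sums_of_squares(self):
        Y = np.array([[1.0, 3.0], [2.0, 2.0], [4.0, 7.0]])
        n, k = Y.shape
        grand = Y.mean()
        ss_time = n * ((Y.mean(0) - grand) ** 2).sum()
        ss_subj = k * ((Y.mean(1) - grand) ** 2).sum()
        ss_err = ((Y - grand) ** 2).sum() - ss_time - ss_subj
        want_F = (ss_time / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        F, p = repeated_anova(Y)
        assert F == pytest.approx(want_F)
        assert p == pytest.approx(stats.f.sf(want_F, k - 1, (n - 1) * (k - 1)))

    def test_pingouin_cross_check(self, rng):
        import pingouin as pg

        n, k = 12, 4
        Y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
        F, p = repeated_anova(Y)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "time": np.tile(np.arange(k), n),
            "value": Y.ravel(),
        })
        res = pg.rm_anova(data=long, dv="value", within="time",
                          subject="subject")
        assert F == pytest.approx(float(res["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(res["p_unc"].iloc[0]), rel=1e-9)

    def test_incomplete_matrix_rejected(self):
        Y = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            repeated_anova(Y)


def _cohort_frame(onsets_by_drug_site):
    rows = []
    pid = 0
    for (drug, site), onsets in onsets_by_drug_site.items():
        for o in onsets:
            rows.append({"person_id": pid, "site_id": site, "drug": drug,
                         "label": "case", "onset_day": o})
            pid += 1
    return pd.DataFrame(rows)


class TestOnsetStats:
    def test_odd_length_median(self):
        cohort = _cohort_frame({("d", "s"): [5, 12, 25] * 7})
        out = onset_stats(cohort, min_cell=20)
        assert out["overall"]["median"] == 12.0

    def test_small_cells_dropped(self):
        cohort = _cohort_frame({("d1", "s"): list(range(1, 31)),
                                ("d2", "s"): [5] * 10})
        out = onset_stats(cohort, min_cell=20)
        assert set(out["cells"]["drug"]) == {"d1"}

    def test_generator_calibration(self):
        from akiwatch import AkiCriteria, SiteSimConfig, apply_eligibility
        from akiwatch.synthetic import generate_site

        cfg = SiteSimConfig(site_id="V", n_patients=900, seed=17,
                            drug_mix={"vancomycin": 1.0}, aki_frac=0.5)
        cohort = apply_eligibility(generate_site(cfg), "vancomycin",
                                   AkiCriteria())
        out = onset_stats(cohort, min_cell=20)
        assert abs(out["overall"]["median"] - 12.0) <= 2.0

    def test_identical_distributions_large_p(self, rng):
        onsets = rng.integers(1, 60, 400)
        cohort = _cohort_frame({("d1", "s"): onsets.tolist(),
                                ("d2", "s"): onsets.tolist()})
        pairs = onset_stats(cohort)["drug_pairs"]
        assert pairs["p"].iloc[0] > 0.99  # same data -> t = 0


class TestGroupTests:
    def test_chi2_hand_example(self):
        # 2x2 table [[20, 10], [10, 20]]: chi2 = 6.667 uncorrected
        df = pd.DataFrame({
            "label": ["case"] * 30 + ["control"] * 30,
            "flag": [1] * 20 + [0] * 10 + [1] * 10 + [0] * 20,
        })
        out = group_tests(df).set_index("characteristic")
        assert out.loc["flag", "statistic"] == pytest.approx(20 / 3)
        ref = stats.chi2_contingency([[20, 10], [10, 20]],
                                     correction=False)
        assert out.loc["flag", "p"] == pytest.approx(ref.pvalue)

    def test_welch_t_power_on_planted_shift(self, rng):
        df = pd.DataFrame({
            "label": ["case"] * 100 + ["control"] * 100,
            "x": np.concatenate([rng.normal(1.0, 1, 100),
                                 rng.normal(0.0, 1, 100)]),
        })
        out = group_tests(df).set_index("characteristic")
        assert out.loc["x", "test"] == "welch_t"
        assert out.loc["x", "p"] < 1e-6

    def test_identical_groups_large_p(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"label": ["case", "control"] * 100,
                           "x": np.concatenate([x, x])[:200]})
        df.loc[df["label"] == "control", "x"] = \
            df.loc[df["label"] == "case", "x"].to_numpy()
        out = group_tests(df).set_index("characteristic")
        assert out.loc["x", "p"] > 0.9


class TestExportHeatmap:
    def test_csv_sorted_by_overall_descending(self, tmp_path, rng):
        alphas, betas = _random_attention(rng)
        s = aggregate_attention(alphas, betas, list("abcd"))
        path = tmp_path / "heat.csv"
        export_heatmap(s, path, render=False)
        table = pd.read_csv(path, index_col=0)
        assert table.shape == (4, 4)
        assert list(table.index) == list(
            s.overall.sort_values(ascending=False).index)

    def test_re_export_byte_identical(self, tmp_path, rng):
        alphas, betas = _random_attention(rng)
        s = aggregate_attention(alphas, betas, list("abcd"))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        export_heatmap(s, p1, render=False)
        export_heatmap(s, p2, render=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_render_writes_image(self, tmp_path, rng):
        alphas, betas = _random_attention(rng)
        s = aggregate_attention(alphas, betas, list("abcd"))
        export_heatmap(s, tmp_path / "h.csv", render=True)
        assert (tmp_path / "h.csv.png").exists()


class TestPlantedDriftLocalization:
    """A prodromal ramp peaking in the final pre-onset week must place the
    variable's maximum aggregated attention in week -1 in >= 80% of runs."""

    def test_final_week_attention_peak(self):
        from akiwatch.model import IMVLSTMClassifier

        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            n, T, V, k = 300, 28, 6, 2
            X = rng.normal(size=(n, T, V))
            y = rng.integers(0, 2, n)
            t = np.arange(T)
            # standardized equivalent of the generator's lymphocyte decline
            # (-2.5 %/week on an sd-6 lab): about -0.42 sd per week
            X[y == 1, :, k] += -0.42 * (t + 1) / 7.0
            clf = IMVLSTMClassifier(epochs=150, patience=20, seed=seed)
            ntr = int(0.7 * n)
            clf.fit(X[:ntr], y[:ntr], X_val=X[ntr:], y_val=y[ntr:])
            _, alphas, betas = clf.attention(X[y == 1])
            s = aggregate_attention(alphas, betas,
                                    [f"v{i}" for i in range(V)])
            hits += s.weekly.loc["v2"].idxmax() == "week_-1"
        assert hits >= 8
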