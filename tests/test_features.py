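"""Paired screening tests, daily grids, windows and splits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from akiwatch import (AkiCriteria, SiteSimConfig, WindowSpec,
                      apply_eligibility, build_grid, build_window_tensor,
                      generate_site, make_windows, mcnemar, paired_t,
                      select_predictors, split_622)
from akiwatch.features import WindowScaler, variable_catalog, window_count


class TestPairedT:
    def test_identical_vectors_p_one(self):
        with pytest.warns(UserWarning):
            t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_example(self):
        # d = [1, 1, 2]: mean 4/3, sd sqrt(1/3), se 1/3 -> t = 4
        t, p = paired_t([2.0, 3.0, 5.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(4.0)
        assert p == pytest.approx(2 * stats.t.sf(4.0, df=2))

    def test_agrees_with_one_sample_t_on_differences(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        t, p = paired_t(x, y)
        t_ref, p_ref = stats.ttest_1samp(x - y, 0.0)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_scipy_ttest_rel_cross_check(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        t, p = paired_t(x, y)
        t_ref, p_ref = stats.ttest_rel(x, y)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)


class TestMcnemar:
    def test_symmetric_discordance(self):
        chi2, p = mcnemar(5, 5)
        assert (chi2, p) == (0.0, 1.0)

    def test_direct_formula(self):
        chi2, p = mcnemar(10, 2)
        assert chi2 == pytest.approx(16 / 3)
        assert p == pytest.approx(stats.chi2.sf(16 / 3, 1))

    def test_no_discordance(self):
        assert mcnemar(0, 0) == (0.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcnemar(-1, 2)

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        table = [[40, 13], [6, 41]]
        res = sm_mcnemar(table, exact=False, correction=False)
        chi2, p = mcnemar(13, 6)
        assert chi2 == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)


@pytest.fixture(scope="module")
def grid_setup():
    cfg = SiteSimConfig(site_id="G", n_patients=120, seed=21,
                        drug_mix={"celecoxib": 1.0}, aki_frac=0.35)
    bundle = generate_site(cfg)
    cohort = apply_eligibility(bundle, "celecoxib", AkiCriteria())
    catalog = variable_catalog(bundle, exclude_drugs=("celecoxib",))
    grid = build_grid(bundle, cohort, catalog, n_days=61, start_day=-28)
    return bundle, cohort, grid


class TestDailyGrid:
    def test_forward_fill_between_observations(self, grid_setup):
        bundle, cohort, grid = grid_setup
        j = grid.variables.index("hemoglobin")
        meas = bundle.measurement
        hb = meas[meas["variable_label"] == "hemoglobin"]
        row = cohort[cohort["label"].notna()].iloc[0]
        pid = row["person_id"]
        obs = hb[hb["person_id"] == pid].copy()
        obs["day"] = (obs["date"] - row["index_date"]).dt.days
        obs = obs[(obs["day"] >= grid.start_day) & (obs["day"] < grid.n_days)]
        mat = grid.data[pid]
        days = sorted(obs["day"])
        for a, b in zip(days, days[1:]):
            # value holds constant strictly between observations
            vals = mat[grid.row(a):grid.row(b), j]
            assert np.allclose(vals, vals[0])

    def test_binary_columns_zero_filled(self, grid_setup):
        bundle, cohort, grid = grid_setup
        binary = [j for j, k in enumerate(grid.kinds)
                  if k in ("drug", "procedure", "condition")]
        for pid, mat in list(grid.data.items())[:10]:
            assert np.isin(mat[:, binary], [0.0, 1.0]).all()

    def test_no_missing_cells(self, grid_setup):
        _, _, grid = grid_setup
        for mat in grid.data.values():
            assert np.isfinite(mat).all()

    def test_condition_persists_after_diagnosis(self, grid_setup):
        _, _, grid = grid_setup
        cond_idx = [j for j, k in enumerate(grid.kinds) if k == "condition"]
        for pid, mat in grid.data.items():
            for j in cond_idx:
                col = mat[:, j]
                assert (np.diff(col) >= 0).all()  # 0 -> 1 at most once


class TestSelectPredictors:
    def test_drift_variables_selected(self, grid_setup):
        _, cohort, grid = grid_setup
        sel = select_predictors(cohort, grid).set_index("variable")
        # planted prodromal drift must be detected
        assert sel.loc["lymphocytes", "selected"]
        assert sel.loc["prothrombin_time", "selected"]
        # serum creatinine doubles at onset by construction
        assert sel.loc["serum_creatinine", "selected"]

    def test_null_variable_rarely_selected(self, grid_setup):
        _, cohort, grid = grid_setup
        sel = select_predictors(cohort, grid).set_index("variable")
        # stationary labs without drift: sodium / potassium
        null_p = sel.loc[["sodium", "potassium"], "p_value"]
        assert (null_p > 0.001).all()


class TestWindows:
    @staticmethod
    def _toy_grid(n_rows=96, start_day=0, V=2):
        from akiwatch.features import DailyGrid

        g = DailyGrid(variables=["a", "b"], kinds=["lab", "lab"],
                      n_days=start_day + n_rows, start_day=start_day)
        g.data[1] = np.arange(n_rows * V, dtype=float).reshape(n_rows, V)
        return g

    @staticmethod
    def _row(label="control", onset=np.nan):
        return pd.Series({"person_id": 1, "site_id": "S", "drug": "d",
                          "label": label, "onset_day": onset})

    def test_count_formula_matches_enumeration(self):
        # exhaustive small-instance check of the window-count formula
        spec = WindowSpec(length=28, stride=14, lookback=0)
        for L in range(0, 121):
            g = self._toy_grid(n_rows=max(L, 1))
            g.n_days = L
            g.data[1] = g.data[1][:L]
            wins = make_windows(g, self._row(), spec)
            assert len(wins) == window_count(L, 28, 14)

    def test_case_onset_40_labeling(self):
        # onset at day 40: [0, 28) is positive (40 in (28, 42]); the window
        # starting at day 14 would cross onset and is not emitted
        spec = WindowSpec(length=28, stride=14, horizon=14, lookback=0)
        g = self._toy_grid(n_rows=61)
        wins = make_windows(g, self._row("case", 40), spec)
        assert [w["start_day"] for w in wins] == [0]
        assert wins[0]["label"] == 1

    def test_control_windows_all_negative(self):
        spec = WindowSpec(length=28, stride=14, lookback=0)
        g = self._toy_grid(n_rows=61)
        wins = make_windows(g, self._row(), spec)
        assert len(wins) == 3
        assert all(w["label"] == 0 for w in wins)

    def test_no_post_onset_days_in_case_windows(self):
        spec = WindowSpec(length=28, stride=14, lookback=28)
        g = self._toy_grid(n_rows=89, start_day=-28)
        for onset in range(1, 61):
            wins = make_windows(g, self._row("case", onset), spec)
            for w in wins:
                assert w["start_day"] + spec.length <= onset
            # positive iff one window ends within the horizon before onset
            n_pos = sum(w["label"] for w in wins)
            assert n_pos <= 1

    def test_short_grid_zero_windows(self):
        spec = WindowSpec(length=28, stride=14, lookback=0)
        g = self._toy_grid(n_rows=20)
        g.n_days = 20
        g.data[1] = g.data[1][:20]
        assert make_windows(g, self._row(), spec) == []


class TestSplit:
    @staticmethod
    def _windows(n_persons=10, per_person=3, case_frac=0.5, seed=0):
        from akiwatch.features import WindowTensor

        rng = np.random.default_rng(seed)
        rows, data, labels = [], [], []
        for pid in range(n_persons):
            is_case = pid < int(case_frac * n_persons)
            for w in range(per_person):
                rows.append({"person_id": pid, "start_day": 14 * w,
                             "site_id": "S", "drug": "d",
                             "is_case": is_case})
                labels.append(int(is_case and w == per_person - 1))
                data.append(rng.normal(size=(28, 3)))
        return WindowTensor(np.stack(data), np.array(labels),
                            pd.DataFrame(rows), ["a", "b", "c"],
                            ["lab"] * 3)

    def test_exact_622_person_counts(self):
        wt = self._windows(10)
        tr, va, te = split_622(wt, seed=0)
        sizes = [w.meta["person_id"].nunique() for w in (tr, va, te)]
        assert sizes == [6, 2, 2]

    def test_person_disjoint(self):
        wt = self._windows(20)
        tr, va, te = split_622(wt, seed=1)
        sets = [set(w.meta["person_id"]) for w in (tr, va, te)]
        assert not (sets[0] & sets[1] or sets[0] & sets[2]
                    or sets[1] & sets[2])

    def test_stratification(self):
        wt = self._windows(100, case_frac=0.5)
        for seed in range(5):
            tr, va, te = split_622(wt, seed=seed)
            for w in (tr, va, te):
                frac = w.meta.drop_duplicates("person_id")["is_case"].mean()
                assert abs(frac - 0.5) <= 0.10

    def test_windows_follow_their_person(self):
        wt = self._windows(10)
        tr, va, te = split_622(wt, seed=3)
        assert len(tr) + len(va) + len(te) == len(wt)

    def test_too_few_persons_rejected(self):
        wt = self._windows(4)
        with pytest.raises(ValueError):
            split_622(wt, seed=0)


class TestWindowScaler:
    def test_continuous_standardized_binary_untouched(self):
        from akiwatch.features import WindowTensor

        rng = np.random.default_rng(0)
        data = rng.normal(5, 3, size=(40, 28, 2))
        data[:, :, 1] = (data[:, :, 1] > 5).astype(float)
        wt = WindowTensor(data, np.zeros(40, int),
                          pd.DataFrame({"person_id": np.arange(40),
                                        "is_case": False}),
                          ["lab_x", "drug_y"], ["lab", "drug"])
        out = WindowScaler().fit_transform(wt)
        lab = out.data[:, :, 0].ravel()
        assert abs(lab.mean()) < 1e-10 and abs(lab.std() - 1) < 1e-10
        np.testing.assert_array_equal(out.data[:, :, 1], data[:, :, 1])


def test_full_tensor_positive_windows_only_for_cases(grid_setup):
    _, cohort, grid = grid_setup
    wt = build_window_tensor(grid, cohort, WindowSpec())
    pos_persons = set(wt.meta.loc[wt.labels == 1, "person_id"])
    case_persons = set(cohort.loc[cohort["label"] == "case", "person_id"])
    assert pos_persons <= case_persons


class TestScreeningPower:
    """Monte-Carlo power/level of the predictor screen on generated sites."""

    def test_drift_selected_noise_rarely(self):
        drift_hits = 0
        noise_hits = 0
        n_runs = 20
        for seed in range(n_runs):
            cfg = SiteSimConfig(site_id="P", n_patients=100, seed=300 + seed,
                                drug_mix={"naproxen": 1.0}, aki_frac=0.35)
            bundle = generate_site(cfg)
            cohort = apply_eligibility(bundle, "naproxen", AkiCriteria())
            catalog = [("lymphocytes", "lab"), ("sodium", "lab"),
                       ("serum_creatinine", "lab")]
            grid = build_grid(bundle, cohort, catalog, n_days=61)
            sel = select_predictors(cohort, grid).set_index("variable")
            drift_hits += bool(sel.loc["lymphocytes", "selected"])
            noise_hits += bool(sel.loc["sodium", "selected"])
        assert drift_hits >= 18      # planted drift: >= 90% power
        assert noise_hits <= 5       # null variable: near the 5% level
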