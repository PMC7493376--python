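import numpy as np
import pandas as pd
import pytest
from scipy import stats

from petrad.phantom import CohortSpec, make_feature_cohort
from petrad.selection import (SelectionConfig, correlation_dedupe, delong_auc_ci,
                              point_biserial, select_features, threshold_select)


class TestPointBiserial:
    def test_matches_scipy_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=40)
            y = rng.integers(0, 2, size=40)
            if len(np.unique(y)) < 2:
                continue
            assert point_biserial(x, y) == pytest.approx(
                stats.pointbiserialr(y, x).statistic, abs=1e-12)

    def test_textbook_example(self):
        assert point_biserial(np.array([1, 2, 3, 4]),
                              np.array([0, 0, 1, 1])) == pytest.approx(0.8944, abs=5e-5)

    def test_equal_class_means_give_zero(self):
        x = np.array([1.0, 2.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        assert point_biserial(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_separation_gives_unit_magnitude(self):
        x = np.array([1.0, 1.0, 5.0, 5.0])
        y = np.array([0, 0, 1, 1])
        assert abs(point_biserial(x, y)) == pytest.approx(1.0)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            point_biserial(np.ones(10), np.r_[np.zeros(5), np.ones(5)])


def _table(rng, n=40):
    y = pd.Series(np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)], name="label")
    f1 = rng.normal(size=n) + 1.2 * y.to_numpy()
    f2 = 2.0 * f1 + rng.normal(scale=1e-3, size=n)   # near-duplicate of f1
    f3 = rng.normal(size=n)
    return pd.DataFrame({"f1": f1, "f2": f2, "f3": f3}), y


class TestCorrelationDedupe:
    def test_duplicate_deleted_keeping_better_rpb(self, rng):
        table, y = _table(rng)
        reduced, audit = correlation_dedupe(table, y)
        assert set(reduced.columns) <= {"f1", "f2", "f3"}
        assert "f3" in reduced.columns
        assert sum(c in reduced.columns for c in ("f1", "f2")) == 1
        kept = [c for c in ("f1", "f2") if c in reduced.columns][0]
        dropped = "f2" if kept == "f1" else "f1"
        rk = abs(point_biserial(table[kept].to_numpy(), y.to_numpy()))
        rd = abs(point_biserial(table[dropped].to_numpy(), y.to_numpy()))
        assert rk >= rd
        assert any(e["feature"] == dropped and e.get("displaced_by") == kept
                   for e in audit)

    def test_uncorrelated_table_unchanged(self, rng):
        table = pd.DataFrame(rng.normal(size=(60, 6)),
                             columns=[f"g{i}" for i in range(6)])
        y = pd.Series(rng.integers(0, 2, size=60))
        y.iloc[:5] = 0
        y.iloc[-5:] = 1
        reduced, _ = correlation_dedupe(table, y)
        assert list(reduced.columns) == list(table.columns)

    def test_chain_matches_fixed_point_oracle(self, rng):
        """f1~f2, f2~f3, f1 !~ f3: compare against an independent fixed-point
        implementation of the stated rule."""
        for trial in range(5):
            r = np.random.default_rng(trial)
            n = 80
            y = pd.Series(np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)])
            z = r.normal(size=n)
            f1 = z + r.normal(scale=0.55, size=n)
            f2 = z + r.normal(scale=0.05, size=n) + 0.3 * y.to_numpy()
            f3 = z + r.normal(scale=0.55, size=n) + 0.6 * y.to_numpy()
            table = pd.DataFrame({"f1": f1, "f2": f2, "f3": f3})
            reduced, _ = correlation_dedupe(table, y)

            # independent oracle: sets + explicit passes
            cols = list(table.columns)
            corr = table.corr().abs()
            rpb = {c: abs(point_biserial(table[c].to_numpy(), y.to_numpy()))
                   for c in cols}
            alive = set(cols)
            while True:
                before = set(alive)
                for f in cols:
                    if f not in alive:
                        continue
                    grp = [f] + [g for g in cols if g in alive and g != f
                                 and corr.loc[f, g] > 0.9]
                    if len(grp) > 1:
                        best = max(grp, key=lambda g: (rpb[g], -cols.index(g)))
                        for g in grp:
                            if g != best:
                                alive.discard(g)
                if alive == before:
                    break
            assert set(reduced.columns) == alive

    def test_idempotent(self, rng):
        table, y = _table(rng)
        once, _ = correlation_dedupe(table, y)
        twice, _ = correlation_dedupe(once, y)
        assert list(once.columns) == list(twice.columns)

    def test_survivors_pairwise_below_threshold(self, rng):
        spec = CohortSpec(n_per_class=(30, 30), n_features=30,
                          blocks=[[0, 1, 2], [5, 6]], block_r=0.97, seed=2)
        c = make_feature_cohort(spec)
        reduced, _ = correlation_dedupe(c.features, c.labels)
        corr = reduced.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.9 + 1e-12


class TestThresholdSelect:
    def test_perfect_separator_selected_with_auc_one(self, rng):
        n = 30
        y = pd.Series(np.r_[np.zeros(n, int), np.ones(n, int)])
        table = pd.DataFrame({
            "sep": np.r_[rng.normal(0, 0.1, n), rng.normal(10, 0.1, n)],
            "noise": rng.normal(size=2 * n),
        })
        res = threshold_select(table, y)
        assert "sep" in res.selected
        assert res.auc["sep"] == pytest.approx(1.0)

    def test_sign_invariance(self, rng):
        table, y = _table(rng)
        res_pos = select_features(table, y)
        flipped = table.copy()
        flipped["f1"] = -flipped["f1"]
        flipped["f2"] = -flipped["f2"]
        res_neg = select_features(flipped, y)
        assert res_pos.selected == res_neg.selected

    def test_row_reordering_never_changes_result(self, rng):
        table, y = _table(rng)
        res = select_features(table, y)
        perm = rng.permutation(len(y))
        res_perm = select_features(table.iloc[perm].reset_index(drop=True),
                                   y.iloc[perm].reset_index(drop=True))
        assert res.selected == res_perm.selected

    def test_all_noise_survivor_count_matches_null_tail(self):
        """Expected survivors = p * P(|r_pb| > 0.25) under the exact null
        (r^2 ~ Beta(1/2, (n-2)/2)); observed mean must sit within binomial error."""
        n, p, reps = 60, 40, 30
        tail = 1.0 - stats.beta.cdf(0.25 ** 2, 0.5, (n - 2) / 2)
        counts = []
        for s in range(reps):
            c = make_feature_cohort(CohortSpec(n_per_class=(n // 2, n // 2),
                                               n_features=p, seed=1000 + s))
            res = select_features(c.features, c.labels)
            counts.append(len(res.selected))
        expected = p * tail
        se = np.sqrt(p * tail * (1 - tail) / reps)
        assert np.mean(counts) == pytest.approx(expected, abs=4 * se)

    def test_empty_selection_warns(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        y = pd.Series(rng.integers(0, 2, size=200))
        y.iloc[:3] = 0
        y.iloc[-3:] = 1
        res = select_features(table, y)
        if not res.selected:
            assert res.warnings


class TestPlantedRecovery:
    def test_three_planted_features_recovered(self):
        """3 informative features (effect 1.5) among 105 noise, n=60: the
        two-step procedure recovers all three in >= 80% of 20 replicates and
        survivors always satisfy the pairwise correlation bound."""
        informative = {3: 1.5, 47: 1.5, 90: 1.5}
        hits = 0
        for s in range(20):
            c = make_feature_cohort(CohortSpec(n_per_class=(30, 30), n_features=108,
                                               informative=informative, seed=s))
            res = select_features(c.features, c.labels)
            planted = {c.features.columns[i] for i in informative}
            if planted <= set(res.selected):
                hits += 1
            survivors = c.features[res.selected]
            if len(res.selected) > 1:
                corr = survivors.corr().abs().to_numpy()
                np.fill_diagonal(corr, 0)
                assert corr.max() <= 0.9 + 1e-12
        assert hits >= 16


class TestDelongCi:
    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=100)
        y[:5], y[-5:] = 0, 1
        score = rng.normal(size=100) + y
        auc, (lo, hi) = delong_auc_ci(y, score)
        assert auc == pytest.approx(roc_auc_score(y, score), abs=1e-12)
        assert 0 <= lo <= auc <= hi <= 1

    def test_ci_narrows_with_sample_size(self, rng):
        widths = []
        for n in (40, 400):
            y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
            score = rng.normal(size=n) + 1.0 * y
            _, (lo, hi) = delong_auc_ci(y, score)
            widths.append(hi - lo)
        assert widths[1] < widths[0]
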