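"""Metric oracles: RMSE/MAE, bootstrap, Wilcoxon exactness, Welch/BH,
ROC/PR, and uncertainty diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pepimpute import evaluation as ev
from pepimpute.datamodel import DataError


def table_from_errors(pairs, method="m", sample_ids=None, missing_frac=None, sigma=None):
    """Build an error table from (pred, truth) pairs."""
    n = len(pairs)
    return pd.DataFrame(
        {
            "method": method,
            "peptide_id": [f"p{i}" for i in range(n)],
            "sample_id": sample_ids if sample_ids is not None else ["s0"] * n,
            "row": range(n),
            "col": 0,
            "pred": [p for p, _ in pairs],
            "truth": [t for _, t in pairs],
            "abs_error": [abs(p - t) for p, t in pairs],
            "missing_frac": missing_frac if missing_frac is not None else 0.0,
            "sigma": sigma if sigma is not None else np.nan,
        }
    )


class TestAbundanceMetrics:
    def test_samplewise_rmse_closed_forms(self):
        t = table_from_errors([(0, 0), (0, 0), (3, 0), (4, 0)], sample_ids=["a", "a", "b", "b"])
        out = ev.samplewise_rmse(t)
        assert out["a"] == 0.0
        assert out["b"] == pytest.approx(np.sqrt(12.5))  # errors {3, 4}

    def test_metric_brute_force_oracle(self, rng):
        preds = rng.normal(size=50)
        truths = rng.normal(size=50)
        samples = rng.choice(["a", "b", "c"], size=50).tolist()
        t = table_from_errors(list(zip(preds, truths)), sample_ids=samples)
        sw = ev.samplewise_rmse(t)
        for s in "abc":
            errs = [abs(p - q) for p, q, smp in zip(preds, truths, samples) if smp == s]
            assert sw[s] == pytest.approx(np.sqrt(np.mean(np.square(errs))), rel=1e-12)
        assert ev.dataset_mae(t) == pytest.approx(np.mean(np.abs(preds - truths)), rel=1e-12)
        assert ev.dataset_rmse(t) == pytest.approx(np.sqrt(np.mean((preds - truths) ** 2)), rel=1e-12)

    def test_mae_examples(self):
        assert ev.dataset_mae(table_from_errors([(1, 0), (-1, 0)])) == pytest.approx(1.0)
        assert ev.dataset_mae(table_from_errors([(0, 0)] * 3)) == 0.0
        with pytest.raises(DataError):
            ev.dataset_mae(table_from_errors([]))


class TestBootstrap:
    def test_constant_list(self):
        lo, hi = ev.bootstrap_ci([2.5] * 10)
        assert lo == hi == 2.5

    def test_seed_reproducibility(self, rng):
        vals = rng.normal(size=30)
        assert ev.bootstrap_ci(vals, seed=4) == ev.bootstrap_ci(vals, seed=4)

    def test_coverage_simulation(self):
        rng = np.random.default_rng(0)
        covered = 0
        for _ in range(200):
            lo, hi = ev.bootstrap_ci(rng.normal(size=100), reps=300, seed=int(rng.integers(2**31)))
            covered += lo <= 0 <= hi
        assert covered >= 180  # nominal 95%, requiring only 90%

    def test_too_few_values(self):
        with pytest.raises(DataError):
            ev.bootstrap_ci([1.0])


def wilcoxon_enumeration(d):
    """Exact one-sided p (H1: median < 0) by full sign-flip enumeration."""
    d = np.asarray([x for x in d if x != 0])
    n = len(d)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def _tables(self, errors_by_method):
        return {
            name: table_from_errors([(e, 0.0) for e in errs])
            for name, errs in errors_by_method.items()
        }

    def test_uniform_winner(self, rng):
        a = rng.uniform(0.1, 0.5, size=30)
        tables = self._tables({"A": a, "B": a + rng.uniform(0.05, 0.2, size=30)})
        pmat, wins = ev.pairwise_wilcoxon_matrix(tables)
        assert pmat.loc["A", "B"] < 0.05
        assert wins["A"] == 1.0 and wins["B"] == 0.0

    def test_identical_methods_half_points(self, rng):
        a = rng.uniform(size=20)
        tables = self._tables({"A": a, "B": a.copy()})
        pmat, wins = ev.pairwise_wilcoxon_matrix(tables)
        assert wins["A"] == wins["B"] == 0.5

    def test_exact_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for n in (6, 8, 10):
            for _ in range(5):
                a = rng.uniform(0.0, 1.0, size=n)
                b = rng.uniform(0.0, 1.0, size=n)
                tables = self._tables({"A": a, "B": b})
                pmat, _ = ev.pairwise_wilcoxon_matrix(tables)
                expect = wilcoxon_enumeration(a - b)
                assert pmat.loc["A", "B"] == pytest.approx(min(1.0, 2 * expect), rel=1e-10)

    def test_win_count_conservation(self, rng):
        k = 4
        tables = self._tables({f"M{i}": rng.uniform(0.1, 1.0, size=25) for i in range(k)})
        _, wins = ev.pairwise_wilcoxon_matrix(tables)
        assert wins.sum() == pytest.approx(k * (k - 1) / 2)

    def test_mismatched_test_sets_error(self, rng):
        t1 = table_from_errors([(1, 0), (2, 0)])
        t2 = table_from_errors([(1, 0), (2, 0), (3, 0)])
        with pytest.raises(DataError):
            ev.pairwise_wilcoxon_matrix({"A": t1, "B": t2})


class TestStratifiedRmse:
    def test_all_mass_in_one_bin(self):
        t = table_from_errors([(1, 0)] * 4, missing_frac=[0.5] * 4)
        out = ev.stratified_rmse(t, [0.0, 0.5, 1.0])
        assert list(out["bin"]) == ["[0.5,1)"]

    def test_partition_property(self, rng):
        fracs = rng.uniform(0, 1, size=40)
        t = table_from_errors(list(zip(rng.normal(size=40), rng.normal(size=40))), missing_frac=fracs)
        out = ev.stratified_rmse(t, [0.0, 0.25, 0.5, 0.75, 1.0])
        # group sizes over bins sum to the full table
        work = t.copy()
        sizes = []
        edges = [0.0, 0.25, 0.5, 0.75, 1.0]
        for lo, hi in zip(edges[:-1], edges[1:]):
            last = hi == 1.0
            sel = (fracs >= lo) & ((fracs <= hi) if last else (fracs < hi))
            sizes.append(sel.sum())
            if sel.sum():
                errs = work["abs_error"][sel]
                row = out[(out["bin"] == f"[{lo:g},{hi:g})")]
                assert row["rmse"].iloc[0] == pytest.approx(np.sqrt(np.mean(errs**2)), rel=1e-12)
        assert sum(sizes) == 40

    def test_bad_bins(self):
        with pytest.raises(DataError):
            ev.stratified_rmse(table_from_errors([(1, 0)]), [0.1, 1.0])


class TestWelchDE:
    def test_identical_groups(self):
        m = np.array([[1.0, 2.0, 1.0, 2.0]])
        out = ev.welch_de(m, ["a", "a", "b", "b"])
        assert out["t"][0] == pytest.approx(0.0)
        assert out["p"][0] == pytest.approx(1.0)

    def test_hand_computed_welch(self):
        m = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        out = ev.welch_de(m, ["a", "a", "a", "b", "b", "b"])
        assert out["t"][0] == pytest.approx(-3.6742, abs=1e-4)
        assert out["df"][0] == pytest.approx(4.0)
        assert out["p"][0] == pytest.approx(0.0214, abs=5e-4)

    def test_scipy_cross_check(self, rng):
        from scipy import stats

        m = rng.normal(size=(10, 8))
        groups = ["a"] * 4 + ["b"] * 4
        out = ev.welch_de(m, groups)
        ref = stats.ttest_ind(m[:, :4], m[:, 4:], axis=1, equal_var=False)
        np.testing.assert_allclose(out["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(out["p"], ref.pvalue, rtol=1e-10)

    def test_bh_step_up(self):
        from statsmodels.stats.multitest import multipletests

        m = np.vstack(
            [np.array([0.0, 0.1, 5.0, 5.2]) + i * 0 for i in range(4)]
        ) + np.arange(4)[:, None] * 0.01
        m[1] += np.array([0, 0, -4.0, -4.0])  # vary effect sizes
        out = ev.welch_de(m, ["a", "a", "b", "b"])
        expect = multipletests(out["p"], method="fdr_bh")[1]
        np.testing.assert_allclose(out["q"], expect)
        # the textbook example: p = {.01,.02,.03,.04}, m=4 -> all q = .04
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, 0.04)

    def test_exclusion_rule(self):
        m = np.array([[1.0, np.nan, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        out = ev.welch_de(m, ["a", "a", "b", "b"])
        assert not out["tested"][0] and out["tested"][1]

    def test_needs_two_conditions(self):
        with pytest.raises(DataError):
            ev.welch_de(np.ones((2, 4)), ["a"] * 4)


class TestRocPr:
    def test_perfect_separation(self):
        labels = [True] * 5 + [False] * 5
        q = [0.001] * 5 + [0.9] * 5
        res = ev.roc_pr(labels, q)
        assert res.auc == pytest.approx(1.0)
        assert res.fdr_point == (0.0, 1.0)

    def test_random_scores_near_half(self, rng):
        labels = rng.random(2000) < 0.5
        q = rng.random(2000)
        res = ev.roc_pr(labels, q)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_concordance_oracle(self, rng):
        for _ in range(10):
            labels = rng.random(30) < 0.4
            if labels.all() or not labels.any():
                continue
            q = rng.random(30)
            res = ev.roc_pr(labels, q)
            pos = q[labels]
            neg = q[~labels]
            conc = np.mean([(p < n) + 0.5 * (p == n) for p in pos for n in neg])
            assert res.auc == pytest.approx(conc, rel=1e-10)

    def test_monotone_transform_invariance(self, rng):
        labels = rng.random(50) < 0.5
        labels[0], labels[1] = True, False
        q = rng.random(50)
        assert ev.roc_pr(labels, q).auc == pytest.approx(ev.roc_pr(labels, q**3).auc)

    def test_single_class_errors(self):
        with pytest.raises(DataError):
            ev.roc_pr([True, True], [0.1, 0.2])


class TestUncertaintyDiagnostics:
    def test_quantile_rmse_sorting_property(self, rng):
        err = np.sort(rng.uniform(size=40))
        t = table_from_errors([(e, 0.0) for e in err], sigma=err + 0.01)  # sigma rank == error rank
        out = ev.uncertainty_quantile_rmse(t, (0.25, 0.5, 0.75, 1.0))
        assert (np.diff(out["rmse"]) >= -1e-12).all()
        assert out["rmse"].iloc[-1] == pytest.approx(ev.dataset_rmse(t))

    def test_quantile_rmse_brute_force(self, rng):
        errs = rng.uniform(size=17)
        sig = rng.uniform(size=17)
        t = table_from_errors([(e, 0.0) for e in errs], sigma=sig)
        out = ev.uncertainty_quantile_rmse(t, (0.5,))
        count = int(np.ceil(0.5 * 17))
        keep = np.argsort(sig, kind="stable")[:count]
        assert out["rmse"][0] == pytest.approx(np.sqrt(np.mean(errs[keep] ** 2)), rel=1e-12)

    def test_sigma_required(self):
        with pytest.raises(DataError):
            ev.uncertainty_quantile_rmse(table_from_errors([(1, 0)]))


class TestFilteredDE:
    def _setup(self, rng):
        n, s = 40, 8
        groups = ["a"] * 4 + ["b"] * 4
        m = rng.normal(size=(n, s))
        labels = np.zeros(n, dtype=bool)
        labels[:8] = True
        m[:8, 4:] += 3.0
        imputed = rng.random((n, s)) < 0.3
        sigma = rng.uniform(0.1, 1.0, size=(n, s))
        return m, imputed, sigma, groups, labels

    def test_infinite_threshold_equals_unfiltered(self, rng):
        m, imputed, sigma, groups, labels = self._setup(rng)
        full = ev.de_from_matrix(m, groups, labels)
        filt = ev.uncertainty_filtered_de(m, imputed, sigma, groups, labels, threshold=1e9)
        assert filt.auc == pytest.approx(full.auc)

    def test_tiny_threshold_reverts_all_imputed(self, rng):
        m, imputed, sigma, groups, labels = self._setup(rng)
        reverted = m.copy()
        reverted[imputed] = np.nan
        direct = ev.de_from_matrix(reverted, groups, labels)
        filt = ev.uncertainty_filtered_de(m, imputed, sigma, groups, labels, threshold=1e-6)
        assert filt.auc == pytest.approx(direct.auc)
        assert filt.n_excluded == direct.n_excluded

    def test_threshold_validation(self, rng):
        m, imputed, sigma, groups, labels = self._setup(rng)
        with pytest.raises(DataError):
            ev.uncertainty_filtered_de(m, imputed, sigma, groups, labels, threshold=0.0)
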