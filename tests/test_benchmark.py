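import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import sigdecon as sd
from sigdecon.benchmark import (
    censor_half,
    compose_mixtures,
    cox_regression,
    roc_auc,
    sample_survival,
    simulate_proportions,
)


# ------------------------------------------------------- survival sampling
class TestSampleSurvival:
    def test_values_come_from_pool(self, clinical_pool, rng):
        t = sample_survival(clinical_pool, 100, rng)
        assert np.isin(t, clinical_pool["time"].to_numpy()).all()

    def test_without_replacement_is_permutation(self, clinical_pool):
        n = len(clinical_pool)
        t = sample_survival(
            clinical_pool, n, np.random.default_rng(0), replace_draw=False
        )
        np.testing.assert_allclose(np.sort(t), np.sort(clinical_pool["time"]))

    def test_seeded_draw_reproducible(self, clinical_pool):
        a = sample_survival(clinical_pool, 50, np.random.default_rng(3))
        b = sample_survival(clinical_pool, 50, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sample_survival(pd.DataFrame({"time": []}), 5, np.random.default_rng(0))


# ------------------------------------------------------------- proportions
class TestSimulateProportions:
    types = [f"t{i}" for i in range(5)]

    def test_rows_are_simplex(self, rng):
        cfg = sd.SimulationConfig(n_samples=50, slope=0.7)
        props = simulate_proportions(cfg, rng.exponential(10, 50), "t2", self.types, rng)
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)
        assert (props.to_numpy() >= 0).all()

    def test_no_effect_means_equal_intercept(self, rng):
        cfg = sd.SimulationConfig(n_samples=5000, slope=0.0)
        props = simulate_proportions(
            cfg, rng.exponential(10, 5000), "t0", self.types, rng
        )
        se = np.sqrt(0.2 * 0.8 / 101) / np.sqrt(5000)  # Dirichlet sd / sqrt(N)
        assert np.allclose(props.mean(axis=0), 0.2, atol=4 * se)

    def test_positive_slope_induces_positive_association(self, rng):
        cfg = sd.SimulationConfig(n_samples=1000, slope=1.0)
        times = rng.exponential(10, 1000)
        props = simulate_proportions(cfg, times, "t3", self.types, rng)
        z = (times - times.mean()) / times.std()
        assert np.corrcoef(z, props["t3"])[0, 1] > 0.3

    def test_infeasible_baseline_rejected(self, rng):
        cfg = sd.SimulationConfig(n_samples=10, intercept=0.3)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_proportions(cfg, rng.exponential(10, 10), "t0", self.types, rng)

    def test_unknown_variable_type_rejected(self, rng):
        cfg = sd.SimulationConfig(n_samples=10)
        with pytest.raises(ValueError, match="not among"):
            simulate_proportions(cfg, rng.exponential(10, 10), "zz", self.types, rng)


# ---------------------------------------------------------------- mixtures
class TestComposeMixtures:
    def test_single_type_returns_a_replicate_profile(self, ref_default):
        leaves = ref_default.hierarchy.leaves
        props = pd.DataFrame(
            [np.eye(len(leaves))[0]], columns=leaves, index=["pure"]
        )
        bulk = compose_mixtures(props, ref_default, np.random.default_rng(1))
        ref_cpm = sd.cpm(ref_default.counts)
        reps = ref_default.replicates_of(leaves[0])
        diffs = [
            np.abs(bulk["pure"].to_numpy() - ref_cpm[r].to_numpy()).max() for r in reps
        ]
        assert min(diffs) < 1e-9

    def test_columns_sum_to_a_million(self, ref_default, rng):
        leaves = ref_default.hierarchy.leaves
        props = pd.DataFrame(
            rng.dirichlet(np.ones(len(leaves)), size=5),
            columns=leaves, index=[f"m{i}" for i in range(5)],
        )
        bulk = compose_mixtures(props, ref_default, rng)
        np.testing.assert_allclose(bulk.sum(axis=0), 1e6, rtol=1e-9)

    def test_foreign_mixing_is_linear(self, ref_default, default_hierarchy, rng):
        leaves = ref_default.hierarchy.leaves
        props = pd.DataFrame(
            rng.dirichlet(np.ones(len(leaves)), size=3),
            columns=leaves, index=[f"m{i}" for i in range(3)],
        )
        foreign = sd.generate_foreign_profile(sd.GenerativeSpec(seed=7), default_hierarchy)
        b0 = compose_mixtures(props, ref_default, np.random.default_rng(9))
        b5 = compose_mixtures(
            props, ref_default, np.random.default_rng(9),
            foreign_profile=foreign, foreign_prop=0.5,
        )
        fg = foreign.reindex(b0.index).fillna(0.0)
        fg = fg / fg.sum() * 1e6
        expected = 0.5 * b0.to_numpy() + 0.5 * fg.to_numpy()[:, None]
        np.testing.assert_allclose(b5.to_numpy(), expected, rtol=1e-9)

    def test_foreign_prop_without_profile_rejected(self, ref_default, rng):
        props = pd.DataFrame(
            [[1.0] + [0] * 7], columns=ref_default.hierarchy.leaves, index=["m"]
        )
        with pytest.raises(ValueError, match="foreign"):
            compose_mixtures(props, ref_default, rng, foreign_prop=0.5)


# ---------------------------------------------------------------- censoring
class TestCensorHalf:
    def test_counts_and_halving(self):
        times = np.array([8.0, 8.0, 8.0, 8.0])
        clin = censor_half(times, np.random.default_rng(0))
        assert (clin["event"] == 0).sum() == 2
        assert sorted(clin["time"]) == [4.0, 4.0, 8.0, 8.0]
        assert (clin.loc[clin["event"] == 0, "time"] == 4.0).all()

    def test_floor_half_censored(self, rng):
        clin = censor_half(rng.exponential(10, 11), rng)
        assert (clin["event"] == 0).sum() == 5

    def test_event_times_unchanged(self, rng):
        times = rng.exponential(10, 20)
        clin = censor_half(times, np.random.default_rng(4))
        kept = clin.loc[clin["event"] == 1, "time"].to_numpy()
        assert np.isin(kept, times).all()

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            censor_half(np.array([3.0]), rng)


# ---------------------------------------------------------- Cox regression
def cox_oracle(X, times, events, tol=1e-12):
    """Newton-Raphson on the Cox partial likelihood (no tied event times)."""
    X = np.asarray(X, float)
    beta = np.zeros(X.shape[1])
    order = np.argsort(-times)  # descending: risk set is a prefix
    Xo, to, eo = X[order], times[order], events[order]
    for _ in range(200):
        grad = np.zeros_like(beta)
        hess = np.zeros((beta.size, beta.size))
        eta = Xo @ beta
        w = np.exp(eta)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w[:, None] * Xo, axis=0)
        s2 = np.cumsum(w[:, None, None] * Xo[:, :, None] * Xo[:, None, :], axis=0)
        for i in np.flatnonzero(eo == 1):
            xbar = s1[i] / s0[i]
            grad += Xo[i] - xbar
            hess -= s2[i] / s0[i] - np.outer(xbar, xbar)
        step = np.linalg.solve(hess, grad)
        beta -= step
        if np.abs(step).max() < tol:
            break
    return beta


class TestCoxRegression:
    def test_matches_newton_raphson_oracle_on_10_records(self, rng):
        n, k = 10, 2
        F = rng.dirichlet(np.ones(3), size=n)[:, :k] * 0.8 + 0.05
        times = np.sort(rng.exponential(10, n))  # distinct almost surely
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1])
        fractions = pd.DataFrame(
            F, columns=["a", "b"], index=[f"s{i}" for i in range(n)]
        )
        clin = pd.DataFrame(
            {"sample_id": fractions.index, "time": times, "event": events}
        )
        res = cox_regression(fractions, clin, epsilon=1e-6)
        eps = 1e-6
        Fc = np.clip(F, eps, 1 - eps)
        X = np.log(Fc / (1 - Fc))
        beta = cox_oracle(X, times, events)
        np.testing.assert_allclose(
            res["coef"].to_numpy(), beta, atol=1e-6
        )

    def test_strong_effect_sign_recovered(self, rng):
        """With a strong planted slope and noiseless fractions the fitted
        hazard coefficient for the variable type is negative (more of the
        protective type = longer survival = lower hazard) in >= 95% of runs."""
        types = [f"t{i}" for i in range(5)]
        hits = 0
        n_runs = 40
        for r in range(n_runs):
            run_rng = np.random.default_rng(1000 + r)
            times = run_rng.exponential(10, 120)
            cfg = sd.SimulationConfig(n_samples=120, slope=1.0, seed=r)
            props = simulate_proportions(cfg, times, "t2", types, run_rng)
            clin = censor_half(times, run_rng)
            res = cox_regression(props, clin).set_index("cell_type")
            hits += res.loc["t2", "coef"] < 0
        assert hits / n_runs >= 0.95

    def test_zero_events_rejected(self, rng):
        fractions = pd.DataFrame(
            rng.dirichlet(np.ones(3), size=6),
            columns=list("abc"), index=[f"s{i}" for i in range(6)],
        )
        clin = pd.DataFrame(
            {"sample_id": fractions.index, "time": np.arange(1.0, 7.0), "event": 0}
        )
        with pytest.raises(ValueError, match="no events"):
            cox_regression(fractions, clin)

    def test_collinear_covariates_fall_back_to_ridge(self, rng):
        base = rng.uniform(0.1, 0.4, size=30)
        fractions = pd.DataFrame(
            {"a": base, "b": base, "c": 1 - 2 * base},  # a and b identical
            index=[f"s{i}" for i in range(30)],
        )
        clin = pd.DataFrame(
            {
                "sample_id": fractions.index,
                "time": rng.exponential(10, 30),
                "event": rng.integers(0, 2, 30) | 1,
            }
        )
        res = cox_regression(fractions, clin)
        assert res["ridge"].all()
        assert np.isfinite(res["p_value"]).all()


# ------------------------------------------------------------------- ROC
def runs_frame(p_pos, p_neg):
    rows = []
    for i, p in enumerate(p_pos):
        rows.append((i, "pos_type", p, True))
        for j, q in enumerate(np.atleast_1d(p_neg[i])):
            rows.append((i, f"neg{j}", q, False))
    return pd.DataFrame(rows, columns=["run", "cell_type", "p_value", "is_variable"])


class TestRocAuc:
    def test_perfect_separation(self):
        runs = runs_frame([0.001] * 5, [[0.5, 0.9]] * 5)
        res = roc_auc(runs)
        assert res.auc == 1.0
        assert res.roc.iloc[0][["fpr", "tpr"]].tolist() == [0.0, 0.0]
        assert res.roc.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]
        assert (np.diff(res.roc["tpr"]) >= 0).all()
        assert (np.diff(res.roc["fpr"]) >= 0).all()

    def test_random_scores_near_half(self, rng):
        runs = runs_frame(rng.uniform(size=500), rng.uniform(size=(500, 1)))
        assert abs(roc_auc(runs).auc - 0.5) < 0.05

    def test_auc_equals_mann_whitney_u(self, rng):
        p_pos = rng.uniform(size=8)
        p_neg = rng.uniform(size=(8, 2))
        runs = runs_frame(p_pos, p_neg)
        res = roc_auc(runs)
        u = mannwhitneyu(1 - p_pos, 1 - p_neg.ravel(), alternative="two-sided")
        assert res.auc == pytest.approx(u.statistic / (8 * 16), abs=1e-12)

    def test_single_class_rejected(self):
        runs = runs_frame([0.01], [[]])  # no negatives at all
        runs = runs[runs["is_variable"]]
        with pytest.raises(ValueError, match="one class"):
            roc_auc(runs)

    def test_multiple_positives_per_run_rejected(self):
        runs = runs_frame([0.01, 0.02], [[0.5], [0.5]])
        runs.loc[runs.index[-1], "is_variable"] = True
        with pytest.raises(ValueError, match="exactly one"):
            roc_auc(runs)


# ------------------------------------------------------------ end to end
@pytest.fixture(scope="module")
def tiny_args(ref_default, signature_default, clinical_pool):
    cfg = sd.SimulationConfig(n_samples=60, slope=1.0, runs_per_condition=4, seed=3)
    return cfg, ref_default, signature_default, clinical_pool


class TestRunBenchmark:
    def test_deterministic_under_seed(self, tiny_args):
        a = sd.run_benchmark(*tiny_args)
        b = sd.run_benchmark(*tiny_args)
        pd.testing.assert_frame_equal(a.runs, b.runs)
        assert a.auc == b.auc

    def test_variable_type_cycles_round_robin(self, tiny_args):
        cfg, ref, sig, pool = tiny_args
        res = sd.run_benchmark(cfg, ref, sig, pool)
        variable = (
            res.runs[res.runs["is_variable"]].sort_values("run")["cell_type"].tolist()
        )
        assert variable == list(sig.columns[:4])

    def test_oracle_proportions_detect_strong_signal(
        self, ref_default, signature_default, clinical_pool
    ):
        """Bypassing deconvolution, a strong planted slope is still
        detectable from the true proportions (the compositional sum-to-one
        constraint makes the joint logit covariates nearly dependent, so
        oracle mode is noisier than one might expect — see methods note —
        but far from chance at S = 1)."""
        cfg = sd.SimulationConfig(
            n_samples=250, slope=1.0, runs_per_condition=16, seed=13
        )
        orc = sd.run_benchmark(
            cfg, ref_default, signature_default, clinical_pool,
            oracle_proportions=True,
        )
        assert orc.auc > 0.65
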