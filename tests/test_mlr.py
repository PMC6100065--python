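import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from qspr.datamodel import DescriptorMatrix
from qspr.mlr import (
    HeuristicConfig,
    collinearity_prune,
    fit_ols,
    heuristic_search,
    log_f_pvalue,
    one_parameter_screen,
)
from qspr.synthetic import SyntheticSpec, generate_linear_qspr


def matrix_from(X, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"d{i}" for i in range(X.shape[1])]
    ids = [f"c{i}" for i in range(X.shape[0])]
    return DescriptorMatrix(frame=pd.DataFrame(X, index=ids, columns=names))


class TestFitOls:
    def test_exact_line(self):
        m = fit_ols(np.array([0.0, 1, 2, 3]), np.array([1.0, 3, 5, 7]))
        assert m.intercept == pytest.approx(1.0, abs=1e-12)
        assert m.coefficients[0] == pytest.approx(2.0, abs=1e-12)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_response_r2_zero(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([-1.0, -1.0, 1.0, 1.0])  # centered, orthogonal to x
        m = fit_ols(x, y)
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_against_normal_equations_oracle(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        A = np.column_stack([np.ones(5), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        m = fit_ols(X, y)
        assert np.allclose([m.intercept, *m.coefficients], beta, atol=1e-10)

    def test_full_stats_against_statsmodels(self, rng):
        for _ in range(10):
            n, k = int(rng.integers(8, 30)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, k))
            y = X @ rng.normal(size=k) + rng.normal(size=n)
            m = fit_ols(X, y)
            ref = sm.OLS(y, sm.add_constant(X)).fit()
            assert m.r2 == pytest.approx(ref.rsquared, abs=1e-10)
            assert m.f_stat == pytest.approx(ref.fvalue, rel=1e-10)
            assert np.allclose(m.t_stats, ref.tvalues[1:], atol=1e-8)
            assert np.allclose(m.coefficients, ref.params[1:], atol=1e-10)

    def test_rank_deficient_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="rank"):
            fit_ols(np.column_stack([x, 2 * x]), rng.normal(size=10))

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ols(rng.normal(size=(3, 2)), rng.normal(size=3))


class TestLogFPValue:
    def test_matches_scipy_in_normal_range(self):
        for f, k, n in [(2.5, 1, 50), (10.0, 3, 100), (100.0, 5, 200)]:
            assert log_f_pvalue(f, k, n) == pytest.approx(
                sps.f.logsf(f, k, n - k - 1), rel=1e-9
            )

    def test_finite_and_monotone_deep_in_tail(self):
        # scipy underflows here; the expansion must stay finite and ordered
        vals = [log_f_pvalue(f, 10, 306) for f in (1e4, 1e5, 1e6)]
        assert all(np.isfinite(v) for v in vals)
        assert vals[0] > vals[1] > vals[2]


class TestScreen:
    def test_thresholds_enforced(self, rng):
        n = 60
        x_good = rng.normal(size=n)
        y = 2 * x_good + rng.normal(scale=0.1, size=n)
        x_weak = rng.normal(size=n)  # unrelated: R^2 ~ 1/n < 0.1
        m = matrix_from(np.column_stack([x_good, x_weak]), ["good", "weak"])
        survivors, stats = one_parameter_screen(m, y)
        assert survivors == ["good"]
        assert stats["weak"]["r2"] < 0.1

    def test_survivors_match_exhaustive_per_column_oracle(self, rng):
        n, p = 50, 12
        X = rng.normal(size=(n, p))
        y = X[:, 0] - 0.5 * X[:, 3] + rng.normal(scale=0.8, size=n)
        m = matrix_from(X)
        cfg = HeuristicConfig()
        survivors, _ = one_parameter_screen(m, y, cfg)
        expected = []
        for j, name in enumerate(m.descriptor_names):
            ref = sm.OLS(y, sm.add_constant(X[:, j])).fit()
            if (
                ref.fvalue >= cfg.f_min
                and ref.rsquared >= cfg.r2_min
                and abs(ref.tvalues[1]) >= cfg.t_min
            ):
                expected.append(name)
        assert survivors == expected


class TestCollinearityPrune:
    def test_duplicated_column_keeps_higher_r2(self, rng):
        x = rng.normal(size=40)
        X = np.column_stack([x, x.copy(), rng.normal(size=40)])
        m = matrix_from(X, ["a", "b", "c"])
        kept = collinearity_prune(["a", "b", "c"], m, {"a": 0.5, "b": 0.6, "c": 0.4}, 0.1)
        assert "b" in kept and "a" not in kept

    def test_orthogonal_survivors_all_retained(self):
        X = np.eye(4)[:, :3]  # exactly orthogonal columns
        m = matrix_from(X, ["a", "b", "c"])
        kept = collinearity_prune(["a", "b", "c"], m, {"a": 0.9, "b": 0.8, "c": 0.7}, 0.5)
        assert kept == ["a", "b", "c"]

    def test_hand_traced_greedy_scan(self, rng):
        # 6 descriptors; d0 best R2; d1 correlated with d0 -> dropped;
        # d2 independent -> kept; d3 correlated with d2 -> dropped;
        # d4, d5 independent -> kept
        n = 500
        z = rng.normal(size=(n, 4))
        X = np.column_stack(
            [z[:, 0], z[:, 0] + 0.05 * rng.normal(size=n), z[:, 1],
             z[:, 1] + 0.05 * rng.normal(size=n), z[:, 2], z[:, 3]]
        )
        m = matrix_from(X)
        r2 = {"d0": 0.9, "d1": 0.8, "d2": 0.7, "d3": 0.6, "d4": 0.5, "d5": 0.4}
        kept = collinearity_prune(list(r2), m, r2, 0.5)
        assert kept == ["d0", "d2", "d4", "d5"]


def brute_force_heuristic(m, y, cfg):
    """Independent execution of the stepwise rules with statsmodels fits and
    exhaustive candidate loops (no shared code with the implementation)."""
    X = m.values
    names = m.descriptor_names
    col = {nm: i for i, nm in enumerate(names)}
    n = len(y)

    def ols(subset):
        res = sm.OLS(y, sm.add_constant(X[:, [col[s] for s in subset]])).fit()
        return res

    def logp(res, k):
        lp = sps.f.logsf(res.fvalue, k, n - k - 1)
        if not np.isfinite(lp):
            a, b = (n - k - 1) / 2, k / 2
            x = (n - k - 1) / ((n - k - 1) + k * res.fvalue)
            from scipy.special import betaln

            lp = a * np.log(x) - np.log(a) - betaln(a, b)
        return lp

    corr = np.corrcoef(X, rowvar=False)

    # stage 1: one-parameter screen
    surv = []
    one_r2 = {}
    for nm in names:
        res = ols([nm])
        one_r2[nm] = res.rsquared
        if (
            res.fvalue >= cfg.f_min
            and res.rsquared >= cfg.r2_min
            and abs(res.tvalues[1]) >= cfg.t_min
        ):
            surv.append(nm)
    if not surv:
        return None

    # stage 2: greedy de-correlation of the ranking
    ranked = sorted(surv, key=lambda nm: (-one_r2[nm], col[nm]))
    seeds = []
    for cand in ranked:
        if all(abs(corr[col[cand], col[k]]) <= cfg.one_param_collinearity for k in seeds):
            seeds.append(cand)

    def entry(subset):
        res = ols(subset)
        k = len(subset)
        return {
            "set": tuple(sorted(col[s] for s in subset)),
            "names": list(subset),
            "r2": res.rsquared,
            "f": res.fvalue,
            "logp": logp(res, k),
            "t": res.tvalues[1:],
        }

    def ok(e):
        if np.any(np.abs(e["t"]) < cfg.t_min) or e["f"] < cfg.f_min:
            return False
        sig = [nm for nm, t in zip(e["names"], e["t"]) if abs(t) >= cfg.t_min]
        for a, b in itertools.combinations(sig, 2):
            if abs(corr[col[a], col[b]]) >= cfg.significant_pair_corr_max:
                return False
        return True

    beam = sorted((entry([s]) for s in seeds), key=lambda e: (-e["f"], e["set"]))[: cfg.n_best]
    everything = {e["set"]: e for e in beam}
    for _size in range(2, cfg.max_descriptors + 1):
        nxt = {}
        for parent in beam:
            for cand in surv:
                if cand in parent["names"]:
                    continue
                if any(
                    abs(corr[col[cand], col[inc]]) >= cfg.pair_corr_max
                    for inc in parent["names"]
                ):
                    continue
                child_names = parent["names"] + [cand]
                key = tuple(sorted(col[s] for s in child_names))
                if key in nxt:
                    continue
                e = entry(child_names)
                if not ok(e):
                    continue
                if not (
                    e["logp"] < parent["logp"]
                    or (e["logp"] == parent["logp"] and e["r2"] > parent["r2"])
                ):
                    continue
                nxt[key] = e
        if not nxt:
            break
        beam = sorted(nxt.values(), key=lambda e: (-e["f"], e["set"]))[: cfg.n_best]
        everything.update({e["set"]: e for e in beam})

    best_by_f = sorted(everything.values(), key=lambda e: (-e["f"], e["set"]))[: cfg.n_best]
    return sorted(best_by_f, key=lambda e: (-e["r2"], e["set"]))[0]


class TestHeuristicSearch:
    def test_planted_two_descriptor_model_recovered(self, rng):
        n, p = 200, 50
        X = rng.normal(size=(n, p))
        y = 3 * X[:, 0] - 2 * X[:, 1] + rng.normal(scale=0.3, size=n)
        m = matrix_from(X)
        model, _ = heuristic_search(m, y)
        assert {"d0", "d1"} <= set(model.descriptor_names)
        by_name = dict(zip(model.descriptor_names, model.coefficients))
        se = dict(zip(model.descriptor_names, model.se_coefficients))
        assert abs(by_name["d0"] - 3) < 3 * se["d0"]
        assert abs(by_name["d1"] + 2) < 3 * se["d1"]

    def test_max_descriptor_cap(self, rng):
        m, y, _ = generate_linear_qspr(SyntheticSpec(seed=0, n_descriptors=60))
        for cap in (2, 10):
            model, _ = heuristic_search(m, y, HeuristicConfig(max_descriptors=cap))
            assert len(model.descriptor_names) <= cap

    def test_matches_brute_force_execution(self, rng):
        cfg = HeuristicConfig(max_descriptors=3)
        mismatches = 0
        for seed in range(15):
            r = np.random.default_rng(seed)
            n, p = 40, int(r.integers(5, 9))
            X = r.normal(size=(n, p))
            X[:, 1] = X[:, 0] + 0.3 * r.normal(size=n)  # planted collinearity
            k_true = int(r.integers(1, 4))
            coefs = r.normal(size=k_true) + np.sign(r.normal(size=k_true))
            y = X[:, :k_true] @ coefs + r.normal(scale=0.5, size=n)
            m = matrix_from(X)
            expected = brute_force_heuristic(m, y, cfg)
            try:
                model, _ = heuristic_search(m, y, cfg)
            except ValueError:
                assert expected is None
                continue
            assert expected is not None
            assert sorted(model.descriptor_names) == sorted(expected["names"])
            assert model.r2 == pytest.approx(expected["r2"], abs=1e-10)
            assert model.f_stat == pytest.approx(expected["f"], rel=1e-10)
        assert mismatches == 0

    def test_no_survivor_raises(self, rng):
        X = rng.normal(size=(100, 5))
        y = rng.normal(size=100)  # pure noise: nothing passes R^2 >= 0.1
        with pytest.raises(ValueError, match="no valid one-parameter correlation"):
            heuristic_search(matrix_from(X), y)

    def test_deterministic_trace(self):
        m, y, _ = generate_linear_qspr(SyntheticSpec(seed=4, n_descriptors=80))
        m1, t1 = heuristic_search(m, y)
        m2, t2 = heuristic_search(m, y)
        assert m1.descriptor_names == m2.descriptor_names
        assert t1.per_size == t2.per_size
        assert t1.best_by_f == t2.best_by_f

    def test_trace_stats_rederivable_from_raw_data(self):
        m, y, _ = generate_linear_qspr(SyntheticSpec(seed=2, n_descriptors=40, support=(0, 1, 2), coefficients=(2.0, 1.5, 1.0)))
        _, trace = heuristic_search(m, y)
        for size, entries in trace.per_size.items():
            for e in entries[:3]:
                refit = fit_ols(m.select(e["descriptors"]).values, y)
                assert refit.r2 == pytest.approx(e["r2"], abs=1e-10)
                assert refit.f_stat == pytest.approx(e["f"], rel=1e-10)

    def test_each_size_has_a_more_significant_parent(self):
        """Accepted expansions are strictly more significant (lower F-test
        log p-value) than some model one size smaller."""
        m, y, _ = generate_linear_qspr(SyntheticSpec(seed=6))
        _, trace = heuristic_search(m, y)
        sizes = sorted(trace.per_size)
        assert len(sizes) > 1
        for prev, cur in zip(sizes, sizes[1:]):
            max_parent_logp = max(e["logp"] for e in trace.per_size[prev])
            for e in trace.per_size[cur]:
                assert e["logp"] < max_parent_logp

    def test_noise_only_rarely_returns_and_low_r2(self):
        """Chance-correlation guard: with y independent of 200x50 noise
        descriptors the search almost always refuses; any model it does
        return has modest R^2."""
        returned = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = r.normal(size=(200, 50))
            y = r.normal(size=200)
            try:
                model, _ = heuristic_search(matrix_from(X), y)
            except ValueError:
                continue
            returned += 1
            assert model.r2 < 0.25
        assert returned <= 5
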