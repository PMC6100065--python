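"""Heuristic stepwise multi-linear regression.

The model is Y = a0 + a1*X1 + ... + an*Xn.  Descriptor selection follows
the CODESSA-style heuristic:

1. every descriptor is fitted alone against the property and is eliminated
   if its one-parameter F < 1.0, R^2 < 0.1 or |t| of the slope < 1.5;
2. the survivors are ranked by one-parameter R^2 and greedily de-correlated:
   scanning down the ranking, a descriptor is dropped when its pair
   correlation with an already-retained one exceeds 0.1 (only the higher-R^2
   member of a collinear pair is kept) — this pruned list seeds the search;
3. starting from the seed one-parameter models, descriptors are appended one
   at a time.  A candidate may join a model only if its pair correlation
   with every included descriptor stays below 0.99 and, among descriptors
   that are t-significant in the expanded fit, below 0.8 ("significant pair
   correlation").  An expansion is accepted only if every coefficient keeps
   |t| >= 1.5, the overall F satisfies the F-test floor, and the expanded
   correlation is more significant than its parent.  Significance is
   compared through the p-value of the overall F-test (evaluated in log
   space, with an asymptotic tail expansion once the p-value underflows):
   the raw F statistic itself is not comparable across model sizes, because
   adding a genuinely informative descriptor typically lowers F (the
   numerator degrees of freedom double long before R^2 can) even though the
   correlation has become more significant, and a raw-F rule would freeze
   the search at one descriptor;
4. the ten best models by F at each size are carried forward, up to ten
   descriptors; the final answer is the highest-R^2 member of the overall
   ten-best-by-F list.

Expansion candidates are drawn from all screening survivors (the 0.1
pair-correlation cut only thins the seed ranking); the 0.99/0.8 thresholds
are what the expansion itself enforces.  All ties are broken by descriptor
column order, making the search deterministic.

Statistics use the standard OLS definitions: R^2 = 1 - SSE/SST, overall
F = (R^2/k)/((1-R^2)/(n-k-1)), per-coefficient t = a_i/SE(a_i) with the
unbiased sigma^2 = SSE/(n-k-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from qspr.datamodel import DescriptorMatrix


def log_f_pvalue(f_stat: float, k: int, n: int) -> float:
    """log of the upper-tail p-value of the overall F-test with (k, n-k-1)
    degrees of freedom, stable deep in the tail.

    Falls back to the leading term of the incomplete-beta expansion
    I_x(a, b) ~ x^a / (a B(a, b)) once the p-value underflows; the
    approximation is only used where it is accurate to O(x) relative error,
    so the significance ordering across model sizes stays correct.
    """
    if not np.isfinite(f_stat):
        return -np.inf
    d1, d2 = float(k), float(n - k - 1)
    if d2 <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    logp = stats.f.logsf(f_stat, d1, d2)
    if np.isfinite(logp):
        return float(logp)
    a, b = d2 / 2.0, d1 / 2.0
    x = d2 / (d2 + d1 * f_stat)
    return float(a * np.log(x) - np.log(a) - special.betaln(a, b))


@dataclass
class MLRModel:
    """Fitted multi-linear correlation with per-model and per-term stats."""

    descriptor_names: list[str]
    intercept: float
    coefficients: np.ndarray
    r2: float
    f_stat: float
    t_stats: np.ndarray  # per slope, same order as descriptor_names
    se_coefficients: np.ndarray
    rmse_train: float
    n_train: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.descriptor_names):
            raise ValueError(
                f"design has {X.shape} but model expects {len(self.descriptor_names)} descriptors"
            )
        return self.intercept + X @ self.coefficients

    def predict_matrix(self, m: DescriptorMatrix) -> np.ndarray:
        return self.predict(m.select(self.descriptor_names).values)


@dataclass
class HeuristicConfig:
    """Thresholds of the heuristic search (defaults as commonly recommended:
    one-parameter floors F >= 1.0, R^2 >= 0.1, |t| >= 1.5; seed-list pair
    correlation cut 0.1; expansion collinearity 0.99 and significant pair
    correlation 0.8; at most ten descriptors; ten-model beam)."""

    f_min: float = 1.0
    r2_min: float = 0.1
    t_min: float = 1.5
    one_param_collinearity: float = 0.1
    pair_corr_max: float = 0.99
    significant_pair_corr_max: float = 0.8
    max_descriptors: int = 10
    n_best: int = 10
    use_significant_pair_rule: bool = True

    def __post_init__(self) -> None:
        if self.max_descriptors < 1:
            raise ValueError("max_descriptors must be >= 1")
        for name in (
            "f_min",
            "r2_min",
            "t_min",
            "one_param_collinearity",
            "pair_corr_max",
            "significant_pair_corr_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SelectionTrace:
    """Everything the search looked at: one-parameter statistics, the
    eliminated descriptors with reasons, per-size candidate lists, and the
    final ten-best-by-R^2 / ten-best-by-F lists."""

    one_param_stats: dict[str, dict[str, float]] = field(default_factory=dict)
    eliminated: dict[str, str] = field(default_factory=dict)
    seeds: list[str] = field(default_factory=list)
    per_size: dict[int, list[dict]] = field(default_factory=dict)
    best_by_r2: list[dict] = field(default_factory=list)
    best_by_f: list[dict] = field(default_factory=list)


def fit_ols(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> MLRModel:
    """Ordinary least squares with intercept and the full statistics block.

    Rejects rank-deficient designs and samples too small for the residual
    degrees of freedom (requires n > k + 1).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if names is None:
        names = [f"x{i + 1}" for i in range(k)]
    if len(names) != k:
        raise ValueError("names length must match column count")
    if n != len(y):
        raise ValueError("X and y have different numbers of rows")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < k + 1:
        raise ValueError("rank-deficient design matrix")

    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise ValueError("response is constant; R^2 undefined")
    r2 = 1.0 - sse / sst
    dof = n - k - 1
    sigma2 = sse / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(se > 0, beta / se, np.inf)
        f_stat = (r2 / k) / ((1.0 - r2) / dof) if r2 < 1.0 else np.inf
    return MLRModel(
        descriptor_names=list(names),
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        r2=float(r2),
        f_stat=float(f_stat),
        t_stats=t_all[1:].copy(),
        se_coefficients=se[1:].copy(),
        rmse_train=float(np.sqrt(sse / n)),
        n_train=n,
    )


def one_parameter_screen(
    m: DescriptorMatrix, y: np.ndarray, cfg: HeuristicConfig | None = None
) -> tuple[list[str], dict[str, dict[str, float]]]:
    """One-descriptor fits for every column; survivors must pass all three
    floors (F >= f_min, R^2 >= r2_min, |t| >= t_min).

    Returns (survivor names in column order, per-descriptor stats).
    """
    cfg = cfg or HeuristicConfig()
    y = np.asarray(y, dtype=float).ravel()
    X = m.values
    n = len(y)
    if np.isnan(X).any():
        raise ValueError("descriptor matrix contains missing values; prefilter first")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(xc**2, axis=0)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    if syy <= 0:
        raise ValueError("response is constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sxx > 0, sxy**2 / (sxx * syy), 0.0)
        f = np.where(r2 < 1.0, r2 * (n - 2) / (1.0 - r2), np.inf)
    t = np.sign(sxy) * np.sqrt(f)

    stats: dict[str, dict[str, float]] = {}
    survivors: list[str] = []
    for idx, name in enumerate(m.descriptor_names):
        stats[name] = {"r2": float(r2[idx]), "f": float(f[idx]), "t": float(t[idx])}
        if r2[idx] >= cfg.r2_min and f[idx] >= cfg.f_min and abs(t[idx]) >= cfg.t_min:
            survivors.append(name)
    return survivors, stats


def collinearity_prune(
    survivors: list[str],
    m: DescriptorMatrix,
    one_param_r2: dict[str, float],
    threshold: float = 0.1,
) -> list[str]:
    """Greedy de-correlation of the survivor ranking.

    Scanning survivors in decreasing one-parameter R^2 (ties by column
    order), a candidate is dropped when |Pearson r| with any retained
    descriptor exceeds the threshold, so only the higher-R^2 member of each
    collinear pair is kept.
    """
    order = {name: i for i, name in enumerate(m.descriptor_names)}
    ranked = sorted(survivors, key=lambda nm: (-one_param_r2[nm], order[nm]))
    corr = _correlation_lookup(m)
    kept: list[str] = []
    for cand in ranked:
        if all(abs(corr(cand, other)) <= threshold for other in kept):
            kept.append(cand)
    return kept


def _correlation_lookup(m: DescriptorMatrix):
    X = m.values
    xc = X - X.mean(axis=0)
    norms = np.sqrt(np.sum(xc**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = np.where(norms > 0, xc / norms, 0.0)
    corr_matrix = xn.T @ xn
    index = {name: i for i, name in enumerate(m.descriptor_names)}

    def corr(a: str, b: str) -> float:
        return float(corr_matrix[index[a], index[b]])

    return corr


def _model_entry(model: MLRModel, order: dict[str, int]) -> dict:
    return {
        "descriptors": list(model.descriptor_names),
        "r2": model.r2,
        "f": model.f_stat,
        "logp": log_f_pvalue(model.f_stat, len(model.descriptor_names), model.n_train),
        "model": model,
        "_key": tuple(sorted(order[n] for n in model.descriptor_names)),
    }


def _more_significant(child: dict, parent: dict) -> bool:
    """Strict significance ordering: lower F-test p-value wins; exact
    p-value ties (e.g. two exact fits) fall back to the higher R^2."""
    if child["logp"] < parent["logp"]:
        return True
    return child["logp"] == parent["logp"] and child["r2"] > parent["r2"]


def heuristic_search(
    m: DescriptorMatrix, y: np.ndarray, cfg: HeuristicConfig | None = None
) -> tuple[MLRModel, SelectionTrace]:
    """Run the full heuristic selection; returns the best model and trace.

    Raises ``ValueError("no valid one-parameter correlation")`` if screening
    eliminates everything.
    """
    cfg = cfg or HeuristicConfig()
    y = np.asarray(y, dtype=float).ravel()
    trace = SelectionTrace()
    order = {name: i for i, name in enumerate(m.descriptor_names)}

    survivors, stats = one_parameter_screen(m, y, cfg)
    trace.one_param_stats = stats
    for name in m.descriptor_names:
        if name not in survivors:
            st = stats[name]
            reasons = []
            if st["r2"] < cfg.r2_min:
                reasons.append("r2")
            if st["f"] < cfg.f_min:
                reasons.append("f")
            if abs(st["t"]) < cfg.t_min:
                reasons.append("t")
            trace.eliminated[name] = "screen:" + "+".join(reasons)
    if not survivors:
        raise ValueError("no valid one-parameter correlation")

    r2_map = {nm: stats[nm]["r2"] for nm in survivors}
    seeds = collinearity_prune(survivors, m, r2_map, cfg.one_param_collinearity)
    trace.seeds = seeds
    for name in survivors:
        if name not in seeds:
            trace.eliminated[name] = "collinear-seed"

    corr = _correlation_lookup(m)
    frame = m.frame

    def fit(names: list[str]) -> MLRModel:
        return fit_ols(frame[names].to_numpy(), y, names=names)

    def sort_entries(entries: list[dict], by: str) -> list[dict]:
        return sorted(entries, key=lambda e: (-e[by], e["_key"]))

    def admissible(model: MLRModel) -> bool:
        if np.any(np.abs(model.t_stats) < cfg.t_min):
            return False
        if model.f_stat < cfg.f_min:
            return False
        if cfg.use_significant_pair_rule:
            sig = [
                nm
                for nm, t in zip(model.descriptor_names, model.t_stats)
                if abs(t) >= cfg.t_min
            ]
            for a in range(len(sig)):
                for b in range(a + 1, len(sig)):
                    if abs(corr(sig[a], sig[b])) >= cfg.significant_pair_corr_max:
                        return False
        return True

    # size-1 candidate models from the pruned seed list
    current: list[dict] = []
    for nm in seeds:
        try:
            model = fit([nm])
        except ValueError:
            continue
        current.append(_model_entry(model, order))
    if not current:
        raise ValueError("no valid one-parameter correlation")
    current = sort_entries(current, "f")[: cfg.n_best]

    all_entries: dict[tuple, dict] = {e["_key"]: e for e in current}
    trace.per_size[1] = [
        {"descriptors": e["descriptors"], "r2": e["r2"], "f": e["f"], "logp": e["logp"]}
        for e in current
    ]

    pool = survivors  # expansion pool: every screening survivor, column order
    for size in range(2, cfg.max_descriptors + 1):
        expansions: dict[tuple, dict] = {}
        for parent in current:
            included = parent["descriptors"]
            for cand in pool:
                if cand in included:
                    continue
                if any(abs(corr(cand, inc)) >= cfg.pair_corr_max for inc in included):
                    continue
                names = included + [cand]
                key = tuple(sorted(order[nm] for nm in names))
                if key in expansions:
                    continue
                try:
                    model = fit(names)
                except ValueError:
                    continue
                if not admissible(model):
                    continue
                entry = _model_entry(model, order)
                if not _more_significant(entry, parent):
                    continue
                expansions[key] = entry
        if not expansions:
            break
        current = sort_entries(list(expansions.values()), "f")[: cfg.n_best]
        for e in current:
            all_entries[e["_key"]] = e
        trace.per_size[size] = [
            {"descriptors": e["descriptors"], "r2": e["r2"], "f": e["f"], "logp": e["logp"]}
            for e in current
        ]

    entries = list(all_entries.values())
    best_by_f = sort_entries(entries, "f")[: cfg.n_best]
    best_by_r2 = sort_entries(entries, "r2")[: cfg.n_best]
    trace.best_by_f = [
        {"descriptors": e["descriptors"], "r2": e["r2"], "f": e["f"]} for e in best_by_f
    ]
    trace.best_by_r2 = [
        {"descriptors": e["descriptors"], "r2": e["r2"], "f": e["f"]} for e in best_by_r2
    ]
    winner = sort_entries(best_by_f, "r2")[0]
    return winner["model"], trace
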