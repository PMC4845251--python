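"""Trait-based prediction models: best-subset OLS, LOO-CV, LMG and PMVD.

Community biomass, net diversity effect and complementarity are regressed on
the ten community-level trait variables.  Model search enumerates every
predictor subset up to a size cap and scores each candidate by
leave-one-out cross-validated mean squared prediction error, computed with
the exact OLS identity ``e_(i) = e_i / (1 - h_ii)`` (hat-matrix leverages)
rather than n refits.

Relative importance decomposes the selected model's R^2 over predictors by
averaging sequential R^2 increments over regressor orderings:

* LMG weights all ``k!`` orderings equally (the Shapley decomposition of
  R^2);
* PMVD uses data-dependent ordering weights proportional to
  ``prod_{i<k} 1 / (R2_full - R2(first i regressors))``, which concentrates
  weight on orderings that explain variance early; as a consequence a
  regressor with no partial contribution receives a vanishing share (its
  denominators are regularized with a small epsilon).

Both decompositions are exact enumerations, limited to subsets of at most 8
predictors.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PredictorMatrix",
    "SelectionReport",
    "TRAIT_VARIABLES",
    "assemble_matrix",
    "ols_r2",
    "loocv_mse",
    "best_subset_by_loocv",
    "lmg_importance",
    "pmvd_importance",
    "importance_table",
]

#: The ten community trait variables used as model predictors.
TRAIT_VARIABLES = (
    "Biom st1", "d13C", "H.growth", "L.area", "LDMC",
    "N", "Nyield/ET", "REW", "R.growth", "WUE",
)

RESPONSES = ("biomass", "net_effect", "complementarity")


@dataclass
class PredictorMatrix:
    """Standardized predictors and responses, rows = communities."""

    X: pd.DataFrame              # standardized predictors
    responses: pd.DataFrame      # one column per response (original units)
    standardization: pd.DataFrame  # mean/sd per predictor column
    scope: str = "whole"

    @property
    def n(self) -> int:
        return len(self.X)


@dataclass
class SelectionReport:
    """Outcome of best-subset selection for one response."""

    response: str
    selected: tuple[str, ...]          # winner subset, ordered by importance
    r2: float
    cv_mse: float
    cv_mse_by_size: dict[int, float]   # best CV-MSE per subset size
    best_by_size: dict[int, tuple[str, ...]]
    importance_lmg: dict[str, float]   # normalized shares (sum 1)
    importance_pmvd: dict[str, float]
    n: int
    max_size: int
    low_r2: bool = False
    n_skipped: int = 0


class RankDeficientError(np.linalg.LinAlgError):
    pass


def _design(X: np.ndarray, cols: tuple[int, ...]) -> np.ndarray:
    n = X.shape[0]
    return np.column_stack([np.ones(n), X[:, list(cols)]])


def _solve_ols(X1: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    G = X1.T @ X1
    # tiny systems: direct solve with a condition guard
    try:
        beta = np.linalg.solve(G, X1.T @ y)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientError(str(exc)) from exc
    if not np.all(np.isfinite(beta)):
        raise RankDeficientError("non-finite OLS solution")
    return beta, G


def ols_r2(X: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> float:
    """R^2 of the OLS fit of y on the given predictor columns (with intercept)."""
    y = np.asarray(y, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("response has zero variance")
    if not cols:
        return 0.0
    X1 = _design(np.asarray(X, dtype=float), tuple(cols))
    beta, _ = _solve_ols(X1, y)
    resid = y - X1 @ beta
    return 1.0 - float(resid @ resid) / sst


def loocv_mse(X: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> float:
    """Leave-one-out CV mean squared prediction error via the hat identity.

    ``e_(i) = e_i / (1 - h_ii)`` where ``h_ii`` are leverages of the design
    with intercept.  Raises :class:`RankDeficientError` when the subset is
    rank deficient or a leverage reaches 1 (an observation its own sole
    support — the identity degenerates).
    """
    y = np.asarray(y, dtype=float)
    X1 = _design(np.asarray(X, dtype=float), tuple(cols))
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise RankDeficientError(f"rank-deficient subset {cols}")
    beta, G = _solve_ols(X1, y)
    resid = y - X1 @ beta
    h = np.einsum("ij,ji->i", X1, np.linalg.solve(G, X1.T))
    if np.any(h >= 1.0 - 1e-10):
        raise RankDeficientError(f"leverage ~1 in subset {cols}")
    press = resid / (1.0 - h)
    return float(np.mean(press**2))


def best_subset_by_loocv(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    max_size: int = 5,
    response: str = "",
    low_r2_threshold: float = 0.3,
) -> SelectionReport:
    """Exhaustive best-subset search scored by LOO-CV error.

    All ``C(p, k)`` subsets for each size ``k <= max_size`` are fit by OLS;
    the winner minimizes CV-MSE, with ties broken by smaller subset then
    lexicographic predictor order.  Rank-deficient subsets are skipped with
    a warning.  The winner's predictors are ordered by their LMG importance
    share and both LMG and PMVD shares are attached.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j + 1}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    max_size = min(max_size, p)
    if n <= max_size + 2:
        raise ValueError(
            f"n = {n} rows is too small for subsets of size {max_size} "
            f"(need n > max_size + 2)"
        )

    n_skipped = 0
    best_by_size: dict[int, tuple[int, ...]] = {}
    cv_by_size: dict[int, float] = {}
    for k in range(1, max_size + 1):
        best: tuple[float, tuple[int, ...]] | None = None
        for cols in itertools.combinations(range(p), k):
            try:
                mse = loocv_mse(Xa, y, cols)
            except RankDeficientError:
                n_skipped += 1
                continue
            if best is None or mse < best[0] - 1e-15:
                best = (mse, cols)
        if best is None:
            warnings.warn(f"all size-{k} subsets rank deficient; size skipped",
                          stacklevel=2)
            continue
        cv_by_size[k] = best[0]
        best_by_size[k] = best[1]
    if n_skipped:
        warnings.warn(f"{n_skipped} rank-deficient subsets skipped", stacklevel=2)
    if not cv_by_size:
        raise RankDeficientError("no estimable subset found")

    # overall winner: lowest CV-MSE; near-ties (relative to the response
    # variance) go to the smaller subset
    min_cv = min(cv_by_size.values())
    tie_tol = 1e-9 * float(np.var(y)) + 1e-9 * min_cv
    win_k = min(k for k, v in cv_by_size.items() if v <= min_cv + tie_tol)
    win_cols = best_by_size[win_k]
    r2 = ols_r2(Xa, y, win_cols)

    lmg = lmg_importance(Xa, y, win_cols)
    pmvd = pmvd_importance(Xa, y, win_cols)
    order = sorted(range(len(win_cols)), key=lambda i: -lmg["normalized"][i])
    selected = tuple(names[win_cols[i]] for i in order)
    return SelectionReport(
        response=response,
        selected=selected,
        r2=r2,
        cv_mse=cv_by_size[win_k],
        cv_mse_by_size={k: cv_by_size[k] for k in sorted(cv_by_size)},
        best_by_size={k: tuple(names[j] for j in best_by_size[k])
                      for k in sorted(best_by_size)},
        importance_lmg={selected[i]: lmg["normalized"][order[i]]
                        for i in range(len(order))},
        importance_pmvd={selected[i]: pmvd["normalized"][order[i]]
                         for i in range(len(order))},
        n=n,
        max_size=max_size,
        low_r2=r2 < low_r2_threshold,
        n_skipped=n_skipped,
    )


def _subset_r2_cache(X: np.ndarray, y: np.ndarray,
                     cols: tuple[int, ...]) -> dict[frozenset, float]:
    cache: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, len(cols) + 1):
        for sub in itertools.combinations(cols, r):
            cache[frozenset(sub)] = ols_r2(X, y, sub)
    return cache


def lmg_importance(
    X: np.ndarray, y: np.ndarray, subset: tuple[int, ...]
) -> dict[str, np.ndarray]:
    """LMG shares: mean R^2 increment of each predictor over all orderings.

    Computed by Shapley weighting over sub-subsets (equivalent to averaging
    over the ``k!`` orderings).  Returns raw shares (summing to the full
    R^2) and shares normalized to sum 1.
    """
    subset = tuple(subset)
    k = len(subset)
    if k == 0:
        raise ValueError("empty subset")
    if k > 8:
        raise ValueError(
            f"subset of size {k} > 8: enumeration over orderings is not "
            f"tractable here; sample orderings instead (not implemented)"
        )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cache = _subset_r2_cache(X, y, subset)
    raw = np.zeros(k)
    for i, j in enumerate(subset):
        others = [c for c in subset if c != j]
        for r in range(0, k):
            w = math.factorial(r) * math.factorial(k - 1 - r) / math.factorial(k)
            for sub in itertools.combinations(others, r):
                s = frozenset(sub)
                raw[i] += w * (cache[s | {j}] - cache[s])
    full = cache[frozenset(subset)]
    normalized = raw / full if full > 0 else np.full(k, 1.0 / k)
    return {"raw": raw, "normalized": normalized, "r2": full}


def pmvd_importance(
    X: np.ndarray, y: np.ndarray, subset: tuple[int, ...], eps: float = 1e-12
) -> dict[str, np.ndarray]:
    """Proportional marginal variance decomposition shares.

    Ordering weights are ``w(r) ∝ prod_{i=1}^{k-1} 1 / max(R2_full -
    R2(r_1..r_i), eps)``: orderings whose leading regressors leave little
    variance unexplained dominate, so a regressor with zero partial
    contribution ends up entering last under all heavy orderings and its
    share tends to 0.  Falls back to LMG (with a warning) if every ordering
    weight degenerates to 0.
    """
    subset = tuple(subset)
    k = len(subset)
    if k == 0:
        raise ValueError("empty subset")
    if k > 8:
        raise ValueError("subset size > 8 not supported for PMVD enumeration")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cache = _subset_r2_cache(X, y, subset)
    full = cache[frozenset(subset)]
    if k == 1:
        return {"raw": np.array([full]), "normalized": np.array([1.0]), "r2": full}

    raw = np.zeros(k)
    index = {j: i for i, j in enumerate(subset)}
    total_w = 0.0
    for perm in itertools.permutations(subset):
        prefix: set = set()
        increments = np.zeros(k)
        w = 1.0
        for pos, j in enumerate(perm):
            before = cache[frozenset(prefix)]
            prefix.add(j)
            after = cache[frozenset(prefix)]
            increments[index[j]] = after - before
            if pos < k - 1:
                w /= max(full - after, eps)
        raw += w * increments
        total_w += w
    if total_w <= 0 or not np.isfinite(total_w):
        warnings.warn("degenerate PMVD ordering weights; falling back to LMG",
                      stacklevel=2)
        return lmg_importance(X, y, subset)
    raw /= total_w
    normalized = raw / full if full > 0 else np.full(k, 1.0 / k)
    return {"raw": raw, "normalized": normalized, "r2": full}


# ---------------------------------------------------------------------------
# matrix assembly and reporting


def assemble_matrix(
    cwm_table: pd.DataFrame,
    partition_effects: pd.DataFrame,
    period_metrics: pd.DataFrame,
    design,
    scope: str = "whole",
) -> PredictorMatrix:
    """Build the communities x 10-traits predictor matrix plus responses.

    Rows are mixture compositions (replicate pots averaged).  With
    ``scope="whole"`` each trait is averaged over all periods and the
    responses (biomass, net effect, complementarity) are summed over
    periods; with a period label as scope only that period's values enter.
    Predictor columns are z-standardized; the constants are recorded.
    """
    period_labels = [p.label for p in design.periods]
    if scope != "whole" and scope not in period_labels:
        raise ValueError(f"unknown scope {scope!r}")
    scopes = period_labels if scope == "whole" else [scope]

    pot_comp = {p.pot_id: "-".join(p.composition) for p in design.pots
                if p.richness >= 2}

    cw = cwm_table[cwm_table["period"].isin(scopes)].copy()
    cw = cw[cw["pot_id"].isin(pot_comp)]
    cw["composition"] = cw["pot_id"].map(pot_comp)
    Xdf = (
        cw.groupby(["composition", "trait"])["value"].mean().unstack("trait")
    )
    missing_cols = [t for t in TRAIT_VARIABLES if t not in Xdf.columns]
    gaps = Xdf[list(TRAIT_VARIABLES) if not missing_cols else Xdf.columns].isna()
    if missing_cols or gaps.any().any():
        holes = [f"{c}:{t}" for c, row in gaps.iterrows() for t, bad in row.items() if bad]
        raise ValueError(
            f"predictor matrix incomplete; missing variables {missing_cols}, "
            f"missing cells {holes[:10]}"
        )
    Xdf = Xdf[list(TRAIT_VARIABLES)]

    eff = partition_effects[
        (partition_effects["unit_type"] != "sward")
        & (partition_effects["period"].isin(scopes))
    ]
    resp = (
        eff.groupby("composition")[["net_effect", "complementarity"]]
        .sum()
    )
    pm = period_metrics[period_metrics["period"].isin(scopes)].copy()
    pm = pm[pm["pot_id"].isin(pot_comp)]
    pm["composition"] = pm["pot_id"].map(pot_comp)
    # mean over replicate pots within period, then sum over periods
    resp["biomass"] = (
        pm.groupby(["composition", "period"])["biomass"].mean()
        .groupby("composition").sum()
    )
    common = Xdf.index.intersection(resp.index)
    Xdf, resp = Xdf.loc[common], resp.loc[common, list(RESPONSES)]

    means, sds = Xdf.mean(), Xdf.std(ddof=0)
    const = [c for c in Xdf.columns if sds[c] == 0]
    if const:
        raise ValueError(f"constant predictor column(s) cannot be standardized: {const}")
    Z = (Xdf - means) / sds
    standardization = pd.DataFrame({"mean": means, "sd": sds})
    return PredictorMatrix(X=Z, responses=resp, standardization=standardization,
                           scope=scope)


def importance_table(reports: list[SelectionReport], metric: str = "pmvd") -> pd.DataFrame:
    """Long summary table: per response, R^2 and % of R^2 per selected trait."""
    if metric not in ("lmg", "pmvd"):
        raise ValueError(f"unknown importance metric {metric!r}")
    rows = []
    for rep in reports:
        shares = rep.importance_pmvd if metric == "pmvd" else rep.importance_lmg
        for rank, trait in enumerate(rep.selected, start=1):
            rows.append({
                "response": rep.response, "r2": rep.r2, "rank": rank,
                "trait": trait, "pct_r2": 100.0 * shares[trait],
                "metric": metric, "n": rep.n,
            })
    return pd.DataFrame(rows)
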