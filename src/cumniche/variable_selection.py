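"""Two-step environmental variable selection.

Step 1 removes collinearity: while any pair of variables has |Pearson r| at
or above the threshold (default 0.7), the pair with the largest |r| is found
and the member with the larger variance inflation factor is dropped. This is
the iterative pairwise-exclusion strategy familiar from collinearity tools
in the SDM literature.

Step 2 keeps variables whose contribution to a presence-background model is
at least a threshold percentage (default 5%). The default importance
estimator is an L2-regularised logistic presence-background classifier with
linear + quadratic features; contributions are jackknife gains — the drop in
model fit when a variable is excluded, normalised to sum to 100%. The
estimator is pluggable so an external ENM can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "vif",
    "collinearity_filter",
    "importance_filter",
    "select_variables",
    "jackknife_gain_importance",
]


@dataclass
class SelectionConfig:
    correlation_threshold: float = 0.7
    contribution_threshold: float = 5.0
    importance_estimator: str = "jackknife-gain"

    def __post_init__(self) -> None:
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must be in (0, 1)")
        if not 0 <= self.contribution_threshold < 100:
            raise ValueError("contribution_threshold must be in [0, 100)")


@dataclass
class SelectionResult:
    kept: list[str]
    dropped_collinear: list[tuple[str, str, float, float]] = field(default_factory=list)
    dropped_low_contribution: list[tuple[str, float]] = field(default_factory=list)
    contributions: dict[str, float] = field(default_factory=dict)
    vifs: dict[str, float] = field(default_factory=dict)
    correlation: dict[str, dict[str, float]] | None = None

    def to_dict(self) -> dict:
        return {
            "kept": list(self.kept),
            "dropped_collinear": [
                {"name": n, "partner": p, "abs_r": r, "vif": v}
                for n, p, r, v in self.dropped_collinear
            ],
            "dropped_low_contribution": [
                {"name": n, "contribution_pct": c}
                for n, c in self.dropped_low_contribution
            ],
            "contributions": dict(self.contributions),
            "vifs": dict(self.vifs),
            "correlation": self.correlation,
        }


def _r2_on_others(X: np.ndarray, k: int) -> float:
    """R² of column k regressed (with intercept) on all other columns."""
    y = X[:, k]
    others = np.delete(X, k, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError(f"constant column at index {k}")
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def vif(values: np.ndarray, names: list[str] | None = None) -> dict[str, float]:
    """Variance inflation factor per variable: VIF_k = 1 / (1 - R²_k).

    R²_k comes from regressing variable k on all other variables. Perfect
    collinearity yields +inf, never an exception. A single variable has
    VIF 1 by convention.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("VIF requires a 2-D matrix with at least 3 rows")
    k = X.shape[1]
    names = list(names) if names is not None else [f"v{i}" for i in range(k)]
    out: dict[str, float] = {}
    for j in range(k):
        if k == 1:
            out[names[j]] = 1.0
            continue
        r2 = _r2_on_others(X, j)
        out[names[j]] = float("inf") if r2 >= 1.0 - 1e-12 else max(1.0, 1.0 / (1.0 - r2))
    return out


def collinearity_filter(
    values: np.ndarray,
    names: list[str] | None = None,
    threshold: float = 0.7,
) -> SelectionResult:
    """Iteratively drop variables until all pairwise |Pearson r| < threshold.

    At each step the pair with maximal |r| is located and its member with the
    larger VIF is dropped (ties broken by dropping the lexicographically
    later name). Terminates because each step removes one variable; the
    surviving set always satisfies the pairwise bound.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D point × variable matrix")
    names = list(names) if names is not None else [f"v{i}" for i in range(X.shape[1])]
    active = list(range(X.shape[1]))
    dropped: list[tuple[str, str, float, float]] = []

    while len(active) >= 2:
        sub = X[:, active]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        absc = np.abs(corr)
        i, j = np.unravel_index(np.nanargmax(absc), absc.shape)
        if absc[i, j] < threshold:
            break
        vifs = vif(sub, [names[a] for a in active])
        ni, nj = names[active[i]], names[active[j]]
        vi, vj = vifs[ni], vifs[nj]
        # floating jitter makes symmetric pairs differ at ~1e-15; treat as tied
        tied = vi == vj or (
            np.isfinite(vi) and np.isfinite(vj) and np.isclose(vi, vj, rtol=1e-9)
        )
        if (vi > vj and not tied) or (tied and ni > nj):
            loser, partner, vloser = i, nj, vi
        else:
            loser, partner, vloser = j, ni, vj
        dropped.append((names[active[loser]], partner, float(absc[i, j]), vloser))
        del active[loser]

    if not active:
        raise ValueError("no variables survive collinearity filter")
    kept = [names[a] for a in active]
    final_vifs = vif(X[:, active], kept) if len(active) >= 1 and X.shape[0] >= 3 else {}
    corr_map = None
    if len(active) >= 2:
        c = np.corrcoef(X[:, active], rowvar=False)
        corr_map = {
            a: {b: float(c[ia, ib]) for ib, b in enumerate(kept)}
            for ia, a in enumerate(kept)
        }
    return SelectionResult(
        kept=kept, dropped_collinear=dropped, vifs=final_vifs, correlation=corr_map
    )


# ---------------------------------------------------------------------------
# Step 2: presence-background importance


def _quadratic_features(X: np.ndarray, cols: list[int]) -> np.ndarray:
    sub = X[:, cols]
    return np.column_stack([sub, sub**2])


def _model_gain(X: np.ndarray, y: np.ndarray, cols: list[int], C: float = 1.0) -> float:
    """Mean log-likelihood improvement over the null (intercept-only) model."""
    if not cols:
        return 0.0
    feats = StandardScaler().fit_transform(_quadratic_features(X, cols))
    clf = LogisticRegression(C=C, max_iter=1000)
    clf.fit(feats, y)
    p = np.clip(clf.predict_proba(feats)[:, 1], 1e-12, 1 - 1e-12)
    ll = float(np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    pbar = y.mean()
    ll0 = float(pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    return max(0.0, ll - ll0)


def jackknife_gain_importance(
    presence_values: np.ndarray,
    background_values: np.ndarray,
    names: list[str],
) -> dict[str, float]:
    """Jackknife contributions (%) of each variable to a presence-background fit.

    For each variable v the model is refit without v; the raw contribution is
    the drop in training gain relative to the full model, floored at zero
    (with the variable-alone gain as a fallback signal when drops are all
    zero). Contributions are normalised to sum to 100%.
    """
    X = np.vstack([presence_values, background_values])
    y = np.concatenate(
        [np.ones(len(presence_values)), np.zeros(len(background_values))]
    )
    k = X.shape[1]
    if k == 1:
        return {names[0]: 100.0}
    full = _model_gain(X, y, list(range(k)))
    drops = np.array(
        [max(0.0, full - _model_gain(X, y, [j for j in range(k) if j != v]))
         for v in range(k)]
    )
    if drops.sum() <= 0:
        # degenerate full fit: fall back to variable-alone gains
        drops = np.array([_model_gain(X, y, [v]) for v in range(k)])
    if drops.sum() <= 0:
        drops = np.ones(k)
    pct = 100.0 * drops / drops.sum()
    return {n: float(p) for n, p in zip(names, pct)}


_ESTIMATORS: dict[str, Callable[[np.ndarray, np.ndarray, list[str]], dict[str, float]]] = {
    "jackknife-gain": jackknife_gain_importance,
}


def register_estimator(
    name: str, fn: Callable[[np.ndarray, np.ndarray, list[str]], dict[str, float]]
) -> None:
    """Register a custom presence-background importance estimator."""
    _ESTIMATORS[name] = fn


def importance_filter(
    presence_values: np.ndarray,
    background_values: np.ndarray,
    names: list[str],
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Keep variables contributing at least the threshold % to the model.

    If every variable falls below the threshold, the single best one is kept
    (with a warning) so downstream breadth computation never sees an empty
    variable set.
    """
    config = config or SelectionConfig()
    presence_values = np.asarray(presence_values, dtype=float)
    background_values = np.asarray(background_values, dtype=float)
    if presence_values.shape[1] != background_values.shape[1]:
        raise ValueError("presence and background matrices must share columns")
    if len(names) != presence_values.shape[1]:
        raise ValueError("names do not match matrix columns")
    if presence_values.shape[0] < 10:
        warnings.warn(
            f"only {presence_values.shape[0]} presence rows; importance "
            "estimates will be unstable",
            stacklevel=2,
        )
    try:
        estimator = _ESTIMATORS[config.importance_estimator]
    except KeyError:
        raise ValueError(
            f"unknown importance estimator {config.importance_estimator!r}; "
            f"available: {sorted(_ESTIMATORS)}"
        ) from None
    try:
        contributions = estimator(presence_values, background_values, list(names))
    except Exception as exc:  # estimator diagnostics travel with the error
        raise RuntimeError(f"importance estimator failed: {exc!r}") from exc

    kept = [n for n in names if contributions[n] >= config.contribution_threshold]
    if not kept:
        best = max(names, key=lambda n: contributions[n])
        warnings.warn(
            "no variable reaches the contribution threshold; keeping the "
            f"single best variable {best!r}",
            stacklevel=2,
        )
        kept = [best]
    dropped = [(n, contributions[n]) for n in names if n not in kept]
    return SelectionResult(
        kept=kept, dropped_low_contribution=dropped, contributions=contributions
    )


def select_variables(
    presence_values: np.ndarray,
    background_values: np.ndarray,
    names: list[str],
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Full two-step selection: collinearity filter, then importance filter.

    Correlations and VIFs are computed on the pooled presence + background
    values (standardised upstream).
    """
    config = config or SelectionConfig()
    pooled = np.vstack([presence_values, background_values])
    step1 = collinearity_filter(pooled, names, threshold=config.correlation_threshold)
    idx = [names.index(n) for n in step1.kept]
    step2 = importance_filter(
        np.asarray(presence_values)[:, idx],
        np.asarray(background_values)[:, idx],
        step1.kept,
        config,
    )
    return SelectionResult(
        kept=step2.kept,
        dropped_collinear=step1.dropped_collinear,
        dropped_low_contribution=step2.dropped_low_contribution,
        contributions=step2.contributions,
        vifs=step1.vifs,
        correlation=step1.correlation,
    )
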