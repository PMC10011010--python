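"""Resampling-based inference on functional means.

Two procedures:

* a two-sample permutation t-test on the pointwise Welch t-statistic, with
  familywise control through the permutation null of the maximum absolute
  statistic over the grid;
* a one-way functional ANOVA whose null distribution is obtained by
  bootstrap resampling of group-centered curves with the labels held fixed
  (the add-one rule gives the p-value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import FunctionalSample

DEFAULT_GRID_STEP = 1.0


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class PermTestResult:
    grid_s: np.ndarray
    t_obs: np.ndarray
    pointwise_crit: np.ndarray
    max_crit: float
    alpha: float
    n_perm: int
    reject_regions: tuple[tuple[float, float], ...]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "max_crit": self.max_crit,
            "grid_s": self.grid_s.tolist(),
            "t_obs": self.t_obs.tolist(),
            "pointwise_crit": self.pointwise_crit.tolist(),
            "reject_regions": [list(r) for r in self.reject_regions],
        }


@dataclass(frozen=True)
class FanovaResult:
    statistic_obs: float
    p_value: float
    n_boot: int
    grid_s: np.ndarray
    group_means: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic_obs": self.statistic_obs,
            "p_value": self.p_value,
            "n_boot": self.n_boot,
        }


def _default_grid(sample: FunctionalSample, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    lo, hi = sample.basis.domain
    return np.arange(lo, hi + step / 2, step)


def _welch_t(XA: np.ndarray, XB: np.ndarray) -> np.ndarray:
    """Pointwise Welch two-sample t statistic; rows are curves."""
    nA, nB = XA.shape[0], XB.shape[0]
    mA, mB = XA.mean(axis=0), XB.mean(axis=0)
    vA = XA.var(axis=0, ddof=1)
    vB = XB.var(axis=0, ddof=1)
    denom = np.sqrt(vA / nA + vB / nB)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mA - mB) / denom
    return np.where(denom > 0, t, 0.0)


def pointwise_tstat(
    groupA: FunctionalSample,
    groupB: FunctionalSample,
    grid_s: np.ndarray | None = None,
    nu: int = 0,
) -> np.ndarray:
    """Welch t-statistic between the two groups at each grid time."""
    if groupA.n_curves < 2 or groupB.n_curves < 2:
        raise InferenceError("each group needs at least 2 curves")
    if groupA.basis.n_basis != groupB.basis.n_basis:
        raise InferenceError("groups must share a basis")
    grid = _default_grid(groupA) if grid_s is None else np.asarray(grid_s, float)
    return _welch_t(groupA.evaluate(grid, nu=nu), groupB.evaluate(grid, nu=nu))


def permutation_ttest(
    groupA: FunctionalSample,
    groupB: FunctionalSample,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
    grid_s: np.ndarray | None = None,
    nu: int = 0,
) -> PermTestResult:
    """Permutation t-test on functional means.

    Rejection regions come from the (1-alpha) quantile of the permutation
    null of max_t |t| (familywise control); the pointwise quantiles are
    reported for plotting.
    """
    if seed is None:
        raise InferenceError("a seed is required for reproducibility")
    if n_perm < 100:
        raise InferenceError("n_perm must be at least 100")
    if groupA.n_curves < 2 or groupB.n_curves < 2:
        raise InferenceError("each group needs at least 2 curves")
    grid = _default_grid(groupA) if grid_s is None else np.asarray(grid_s, float)
    XA = groupA.evaluate(grid, nu=nu)
    XB = groupB.evaluate(grid, nu=nu)
    nA = XA.shape[0]
    X = np.vstack([XA, XB])
    t_obs = _welch_t(XA, XB)

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    null_abs = np.empty((n_perm, grid.size))
    for p in range(n_perm):
        idx = rng.permutation(n)
        null_abs[p] = np.abs(_welch_t(X[idx[:nA]], X[idx[nA:]]))
    pointwise_crit = np.quantile(null_abs, 1.0 - alpha, axis=0)
    max_crit = float(np.quantile(null_abs.max(axis=1), 1.0 - alpha))

    reject = np.abs(t_obs) > max_crit
    return PermTestResult(
        grid_s=grid,
        t_obs=t_obs,
        pointwise_crit=pointwise_crit,
        max_crit=max_crit,
        alpha=alpha,
        n_perm=n_perm,
        reject_regions=_runs_to_intervals(grid, reject),
    )


def _runs_to_intervals(grid: np.ndarray, mask: np.ndarray) -> tuple[tuple[float, float], ...]:
    out = []
    in_run = False
    start = 0.0
    for g, m in zip(grid, mask):
        if m and not in_run:
            in_run, start = True, g
        elif not m and in_run:
            out.append((float(start), float(prev)))
            in_run = False
        prev = g
    if in_run:
        out.append((float(start), float(grid[-1])))
    return tuple(out)


def _fanova_stat(X: np.ndarray, labels: np.ndarray, t: np.ndarray) -> float:
    """Integrated F-type statistic: between-group over within-group mean
    squares of the curves, both integrated over the grid."""
    groups = np.unique(labels)
    n, G = X.shape[0], groups.size
    grand = X.mean(axis=0)
    bss = np.zeros(t.size)
    wss = np.zeros(t.size)
    for g in groups:
        Xg = X[labels == g]
        mg = Xg.mean(axis=0)
        bss += Xg.shape[0] * (mg - grand) ** 2
        wss += np.sum((Xg - mg) ** 2, axis=0)
    num = np.trapezoid(bss, t) / (G - 1)
    den = np.trapezoid(wss, t) / (n - G)
    return float(num / den) if den > 0 else np.inf


def fanova(
    sample: FunctionalSample,
    labels: np.ndarray,
    n_boot: int = 500,
    seed: int | None = None,
    grid_s: np.ndarray | None = None,
) -> FanovaResult:
    """One-way functional ANOVA with a bootstrap null distribution.

    Under H0 the group-centered curves are exchangeable, so the null is
    built by resampling them with replacement while keeping the label
    layout fixed; ``p = (1 + #{stat* >= stat_obs}) / (1 + n_boot)``.
    """
    if seed is None:
        raise InferenceError("a seed is required for reproducibility")
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise InferenceError("fanova needs at least two groups")
    for g in groups:
        if np.sum(labels == g) < 2:
            raise InferenceError("each group needs at least 2 curves")
    grid = _default_grid(sample) if grid_s is None else np.asarray(grid_s, float)
    X = sample.evaluate(grid)
    stat_obs = _fanova_stat(X, labels, grid)

    centered = X.copy()
    means = {}
    for g in groups:
        mg = X[labels == g].mean(axis=0)
        means[g] = mg
        centered[labels == g] -= mg

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    count = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if _fanova_stat(centered[idx], labels, grid) >= stat_obs:
            count += 1
    p_value = (1.0 + count) / (1.0 + n_boot)
    return FanovaResult(
        statistic_obs=stat_obs,
        p_value=float(p_value),
        n_boot=n_boot,
        grid_s=grid,
        group_means={int(g): means[g] for g in groups},
    )


def group_mean_curves(
    sample: FunctionalSample, labels: np.ndarray
) -> tuple[dict, np.ndarray]:
    """Coefficient-space group means plus the grand mean (valid because all
    curves share one basis; the grand mean is the size-weighted average)."""
    labels = np.asarray(labels)
    if labels.size != sample.n_curves:
        raise InferenceError("labels must align with curves")
    means = {}
    for g in np.unique(labels):
        means[int(g)] = sample.coefficients[labels == g].mean(axis=0)
    grand = sample.coefficients.mean(axis=0)
    return means, grand
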