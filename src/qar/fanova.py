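"""Functional ANOVA for two groups of activity curves.

Each subject contributes a curve of per-minute activity scores on the
knot grid t = 1..D minutes.  Curves are smoothed by interpolating cubic
splines and evaluated on a dense uniform grid; the two-sample hypothesis
H0: mu_1(t) = mu_2(t) is tested with

* the globalized pointwise F-test (GPF): the classical one-way ANOVA F
  statistic computed at every grid point, averaged over the domain
  (trapezoid rule / domain length), and
* the F-max test: the supremum of the pointwise F over the grid.

Both null distributions come from group-label permutation of whole
curves, with the add-one rule p = (1 + #{stat* >= stat}) / (B + 1), so
p-values are exact-in-expectation at any sample size and never zero.
Velocity (the spline's first derivative, score/minute) is compared with
the same machinery.  Pointwise distribution summaries, Spearman rank
correlations and scalar group comparisons (exact small-sample Wilcoxon
rank sum, Pearson chi-square) round out the toolbox.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline

from .errors import ConfigError, ContractError, DataError, ShapeError

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityCurve",
    "GroupedCurves",
    "FanovaResult",
    "build_curves",
    "pointwise_F",
    "gpf_test",
    "fmax_test",
    "mean_function_tests",
    "velocity",
    "pointwise_distribution",
    "spearman_corr",
    "curve_total",
    "scalar_group_compare",
]

DEFAULT_DENSE_SIZE = 221
DEFAULT_RESAMPLES = 1000


@dataclass
class ActivityCurve:
    """One subject's minute-score curve with its spline smoother."""

    subject_id: str
    group: str
    knots: np.ndarray
    values: np.ndarray
    spline: CubicSpline

    def __call__(self, t):
        return self.spline(t)


@dataclass
class GroupedCurves:
    """Curves from exactly two groups on a shared dense grid.

    ``matrix`` holds the dense-grid evaluations, (n_subjects, n_grid);
    ``labels`` the group of each row.  Velocity curves reuse this type
    (``units`` marks them), so every test accepts either.
    """

    curves: list
    grid: np.ndarray
    matrix: np.ndarray
    labels: np.ndarray
    units: str = "score"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.groups = [str(g) for g in dict.fromkeys(self.labels.tolist())]
        if len(self.groups) != 2:
            raise DataError(f"need exactly 2 groups, got {self.groups}")
        for g in self.groups:
            if (self.labels == g).sum() < 2:
                raise DataError(f"group {g!r} has fewer than 2 subjects")

    def group_matrix(self, group: str) -> np.ndarray:
        return self.matrix[self.labels == group]


@dataclass
class FanovaResult:
    """Outcome of one resampling mean-function test."""

    method: str
    statistic: float
    p_value: float
    n_resamples: int
    pointwise_F: np.ndarray
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n_resamples": int(self.n_resamples),
            "seed": self.seed,
        }


def build_curves(
    minute_scores,
    labels,
    subject_ids=None,
    dense_size: int = DEFAULT_DENSE_SIZE,
    knots=None,
) -> GroupedCurves:
    """Assemble and smooth subject curves onto a common dense grid.

    ``minute_scores`` is (n_subjects, n_minutes); smoothing is an
    interpolating cubic spline (not-a-knot ends) through the knots
    t = 1..n_minutes, evaluated on a ``dense_size``-point uniform grid
    spanning the knot range.
    """
    X = np.asarray(minute_scores, dtype=float)
    if X.ndim != 2:
        raise ShapeError("minute_scores must be (n_subjects, n_minutes); ragged input?")
    n_subjects, n_minutes = X.shape
    if knots is None:
        knots = np.arange(1.0, n_minutes + 1.0)
    knots = np.asarray(knots, dtype=float)
    if knots.size != n_minutes or np.any(np.diff(knots) <= 0):
        raise ShapeError("knots must be strictly increasing and match curve length")
    if not np.all(np.isfinite(X)):
        raise DataError("curve values must be finite")
    if subject_ids is None:
        subject_ids = [f"S{j:03d}" for j in range(n_subjects)]

    grid = np.linspace(knots[0], knots[-1], dense_size)
    curves, rows = [], []
    for j in range(n_subjects):
        spline = CubicSpline(knots, X[j])
        curves.append(
            ActivityCurve(
                subject_id=str(subject_ids[j]),
                group=str(labels[j]),
                knots=knots,
                values=X[j],
                spline=spline,
            )
        )
        rows.append(spline(grid))
    return GroupedCurves(
        curves=curves, grid=grid, matrix=np.asarray(rows), labels=np.asarray(labels)
    )


def _f_statistic(matrix: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    """One-way ANOVA F per column for the 2-group split given by mask1.

    mask1 may be (n,) for a single split or (B, n) for B permutations;
    returns (n_grid,) or (B, n_grid).  Columns with zero within-group
    variance yield +inf (flagged by callers).
    """
    X = matrix
    single = mask1.ndim == 1
    M = np.atleast_2d(mask1).astype(float)
    n = X.shape[0]
    n1 = M.sum(axis=1, keepdims=True)
    n2 = n - n1
    s1 = M @ X
    total = X.sum(axis=0, keepdims=True)
    m1 = s1 / n1
    m2 = (total - s1) / n2
    grand = total / n
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    sq_total = (X**2).sum(axis=0, keepdims=True)
    ssw = sq_total - n1 * m1**2 - n2 * m2**2
    ssw = np.maximum(ssw, 0.0)  # guard tiny negative rounding
    msw = ssw / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(msw > 0, ssb / np.where(msw > 0, msw, 1.0), np.inf)
    F = np.where((msw == 0) & (ssb == 0), 0.0, F)
    return F[0] if single else F


def pointwise_F(grouped: GroupedCurves, t=None) -> np.ndarray:
    """Classical one-way ANOVA F of curve values at each time point.

    Between-group mean square over within-group mean square, with 1 and
    N-2 degrees of freedom for two groups.  ``t`` defaults to the dense
    grid; scalar or array times are interpolated from the subjects'
    splines.  Degenerate points (zero within-group variance but distinct
    means) are flagged +inf.
    """
    mask1 = grouped.labels == grouped.groups[0]
    if t is None:
        X = grouped.matrix
    else:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        X = np.asarray([c(t) for c in grouped.curves])
    F = _f_statistic(X, mask1)
    if np.any(np.isinf(F)):
        logger.warning("infinite pointwise F at %d grid point(s)", int(np.isinf(F).sum()))
    return F


def _gpf_stat(F: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Domain-averaged F via the trapezoid rule, ignoring infinite points."""
    F = np.atleast_2d(F)
    finite = np.isfinite(F)
    if not finite.all():
        F = np.where(finite, F, 0.0)
    span = grid[-1] - grid[0]
    return np.trapezoid(F, grid, axis=1) / span


def mean_function_tests(
    grouped: GroupedCurves,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | None = None,
):
    """GPF and F-max tests from one shared set of label permutations.

    Returns ``(gpf_result, fmax_result)``.  Sharing the resampling draws
    keeps the two tests consistent and halves the cost.
    """
    if n_resamples < 99:
        logger.warning("n_resamples=%d is very small; p-values will be coarse", n_resamples)
    rng = np.random.default_rng(seed)
    X = grouped.matrix
    grid = grouped.grid
    mask1 = grouped.labels == grouped.groups[0]
    n = X.shape[0]

    F_obs = _f_statistic(X, mask1)
    finite = np.isfinite(F_obs)
    if not finite.all():
        logger.warning(
            "excluding %d infinite grid point(s) from the GPF integral",
            int((~finite).sum()),
        )
    gpf_obs = float(_gpf_stat(F_obs, grid)[0])
    fmax_obs = float(np.max(F_obs[finite])) if finite.any() else np.inf

    perm_masks = np.empty((n_resamples, n), dtype=bool)
    idx = np.arange(n)
    n1 = int(mask1.sum())
    for b in range(n_resamples):
        perm = rng.permutation(idx)
        m = np.zeros(n, dtype=bool)
        m[perm[:n1]] = True
        perm_masks[b] = m
    F_null = _f_statistic(X, perm_masks)
    gpf_null = _gpf_stat(F_null, grid)
    with np.errstate(invalid="ignore"):
        fmax_null = np.nanmax(np.where(np.isfinite(F_null), F_null, np.nan), axis=1)
    fmax_null = np.where(np.isnan(fmax_null), np.inf, fmax_null)

    gpf_p = (1 + int(np.sum(gpf_null >= gpf_obs))) / (n_resamples + 1)
    fmax_p = (1 + int(np.sum(fmax_null >= fmax_obs))) / (n_resamples + 1)
    gpf = FanovaResult("GPF", gpf_obs, gpf_p, n_resamples, F_obs, seed)
    fmax = FanovaResult("Fmax", fmax_obs, fmax_p, n_resamples, F_obs, seed)
    return gpf, fmax


def gpf_test(
    grouped: GroupedCurves, n_resamples: int = DEFAULT_RESAMPLES, seed: int | None = None
) -> FanovaResult:
    """Globalized pointwise F-test with a permutation null."""
    return mean_function_tests(grouped, n_resamples, seed)[0]


def fmax_test(
    grouped: GroupedCurves, n_resamples: int = DEFAULT_RESAMPLES, seed: int | None = None
) -> FanovaResult:
    """F-max test (supremum of the pointwise F) with a permutation null."""
    return mean_function_tests(grouped, n_resamples, seed)[1]


def velocity(grouped: GroupedCurves) -> GroupedCurves:
    """First derivative of each smoothed curve (score/minute).

    The analytic spline derivative is evaluated on the same dense grid;
    the result is a ``GroupedCurves`` so the mean-function tests apply
    unchanged.
    """
    if grouped.grid.size < 2:
        raise ShapeError("need at least 2 grid points to differentiate")
    rows, curves = [], []
    for c in grouped.curves:
        dspl = c.spline.derivative()
        rows.append(dspl(grouped.grid))
        curves.append(
            ActivityCurve(
                subject_id=c.subject_id,
                group=c.group,
                knots=c.knots,
                values=dspl(c.knots),
                spline=dspl,
            )
        )
    return GroupedCurves(
        curves=curves,
        grid=grouped.grid,
        matrix=np.asarray(rows),
        labels=grouped.labels,
        units="score/minute",
    )


def pointwise_distribution(grouped: GroupedCurves, times=(3, 7, 9, 11, 22)):
    """Per-group subject values and means at the requested times.

    Returns ``{group: {"values": (n_g, n_times), "mean": (n_times,)}}``;
    the mean is the sample mean function evaluated at each time.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    knots = grouped.curves[0].knots
    if np.any(times < knots[0]) or np.any(times > knots[-1]):
        raise DataError(
            f"times must lie within the curve domain [{knots[0]}, {knots[-1]}]"
        )
    values = np.asarray([c(times) for c in grouped.curves])
    out = {}
    for g in grouped.groups:
        vals = values[grouped.labels == g]
        out[g] = {"values": vals, "mean": vals.mean(axis=0)}
    return out


def spearman_corr(x, y):
    """Spearman rank correlation with midrank ties; two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ShapeError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("Spearman correlation undefined for a constant sample")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def curve_total(curve: ActivityCurve, n_grid: int = DEFAULT_DENSE_SIZE) -> float:
    """Total movement: trapezoidal area under the smoothed curve over the
    knot span, the scalar used for between-subject correlations."""
    grid = np.linspace(curve.knots[0], curve.knots[-1], n_grid)
    return float(np.trapezoid(curve(grid), grid))


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Handles ties via midranks; feasible for pooled n <= ~14.
    """
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n, n1 = pooled.size, x.size
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    total = comb(n, n1)
    count = 0
    for combo in combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= dev_obs - 1e-12:
            count += 1
    return count / total


def scalar_group_compare(values, labels, kind: str = "continuous") -> float:
    """Two-group comparison of a scalar: rank sum or chi-square p-value.

    ``kind="continuous"``: Wilcoxon rank sum, exact by enumeration when
    the pooled sample size is <= 12, normal approximation (tie-corrected,
    continuity-corrected) otherwise.  ``kind="categorical"``: Pearson
    chi-square on the group x category contingency table.
    """
    labels = np.asarray(labels)
    values = np.asarray(values)
    if values.size != labels.size:
        raise ShapeError("values and labels must align")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ContractError(f"need exactly 2 groups, got {uniq}")
    x = values[labels == uniq[0]]
    y = values[labels == uniq[1]]
    if x.size == 0 or y.size == 0:
        raise ContractError("both groups must be non-empty")

    if kind == "categorical":
        cats = list(dict.fromkeys(values.tolist()))
        table = np.array(
            [[np.sum((labels == g) & (values == c)) for c in cats] for g in uniq]
        )
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(p)
    if kind != "continuous":
        raise ConfigError(f"unknown comparison kind {kind!r}")

    x = x.astype(float)
    y = y.astype(float)
    if x.size + y.size <= 12:
        return _exact_ranksum_p(x, y)
    _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(p)
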