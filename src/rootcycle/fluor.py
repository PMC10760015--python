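"""Fluorescence quantification: CTCF, scaling, change-point cutoffs and the
permutation/bootstrap anticorrelation test.

CTCF (corrected total cell fluorescence) subtracts the expected background of
a region — its area times the mean background intensity — from the region's
integrated density. Intensities are rendered comparable across cell files by
min-max scaling within each file; time courses are expressed relative to
their own baseline frame. Signal/background cutoffs come from a single-split
least-squares change-point on the sorted intensities. Anticorrelation between
probe pairs is tested by permutation (one-sided toward negative correlation,
exact for very small n) with a bootstrap percentile confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats


def ctcf(integrated_density: float, area: float, background_mean: float):
    """Corrected total cell fluorescence: density - area x mean background.

    Accepts scalars or aligned arrays; negative results are reported as-is.
    """
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("ROI area must be positive")
    return np.asarray(integrated_density, dtype=float) - area * np.asarray(
        background_mean, dtype=float)


def ctcf_table(rois: pd.DataFrame) -> pd.DataFrame:
    """Apply CTCF to an ROI measurement table (adds a ``ctcf`` column)."""
    required = {"area", "integrated_density", "background_mean"}
    missing = required - set(rois.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    out = rois.copy()
    out["ctcf"] = ctcf(rois["integrated_density"].to_numpy(),
                       rois["area"].to_numpy(),
                       rois["background_mean"].to_numpy())
    return out


def scale_per_group(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1] independently within each group (cell file).

    Invariant under per-group affine transforms. A constant group is mapped
    to 0.5 everywhere with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for g in pd.unique(groups):
        mask = groups == g
        v = values[mask]
        lo, hi = v.min(), v.max()
        if hi == lo:
            warnings.warn(f"group {g!r} is constant; scaled to 0.5", stacklevel=2)
            out[mask] = 0.5
        else:
            out[mask] = (v - lo) / (hi - lo)
    return out


def relative_change_series(series: pd.DataFrame, baseline_frame: int = 0,
                           value_col: str = "intensity") -> pd.DataFrame:
    """Per-nucleus ratio to the baseline frame (ratio 1 at baseline).

    ``series`` is long-form with nucleus_id / frame / intensity columns.
    Nuclei with a non-positive baseline are dropped with a warning.
    """
    out = []
    for nid, g in series.groupby("nucleus_id", sort=True):
        g = g.sort_values("frame")
        base_rows = g[g["frame"] == baseline_frame]
        base = float(base_rows[value_col].iloc[0]) if len(base_rows) else np.nan
        if not (base > 0):
            warnings.warn(f"nucleus {nid!r} has non-positive baseline; dropped",
                          stacklevel=2)
            continue
        g = g.copy()
        g["ratio"] = g[value_col] / base
        out.append(g)
    if not out:
        return series.iloc[0:0].assign(ratio=np.nan)
    return pd.concat(out, ignore_index=True)


def changepoint_threshold(values: np.ndarray) -> tuple[float | None, bool]:
    """Signal/background cutoff from a single least-squares change-point.

    Sorts the values, scans every split point exhaustively for the one that
    minimizes the total within-segment sum of squared deviations, and returns
    the midpoint between the two boundary values. Returns ``(None, True)``
    when all values are equal (no cutoff exists).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 4:
        raise ValueError("need at least 4 values for a change-point")
    if v[0] == v[-1]:
        return None, True
    # prefix sums give every split's within-segment SSE in O(1)
    c1, c2 = np.cumsum(v), np.cumsum(v ** 2)
    best_cost, best_i = math.inf, 1
    for i in range(1, n):
        s1, s2 = c1[i - 1], c2[i - 1]
        left = s2 - s1 ** 2 / i
        r1, r2 = c1[-1] - s1, c2[-1] - s2
        right = r2 - r1 ** 2 / (n - i)
        cost = left + right
        if cost < best_cost - 1e-12:
            best_cost, best_i = cost, i
    return float(0.5 * (v[best_i - 1] + v[best_i])), False


@dataclass
class AnticorrelationResult:
    observed_correlation: float
    p_value: float
    ci_lower: float
    ci_upper: float
    n_permutations: int
    n_bootstrap: int
    seed: int
    method: str
    exact: bool

    def __post_init__(self) -> None:
        if not (-1 - 1e-12 <= self.observed_correlation <= 1 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value outside (0, 1]")
        if self.ci_lower > self.ci_upper:
            raise ValueError("inverted confidence interval")


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def anticorrelation_test(
    a: np.ndarray, b: np.ndarray, n_perm: int = 9999, n_boot: int = 2000,
    seed: int = 0, method: str = "spearman", two_sided: bool = False,
) -> AnticorrelationResult:
    """Directional permutation test for anticorrelation with a bootstrap CI.

    The null distribution permutes ``b``; the one-sided p-value counts
    permuted correlations at or below the observed one, with the add-one
    convention for sampled permutations. For n <= 7 all n! permutations are
    enumerated and the p-value is the exact tail fraction. The 95 percent
    confidence interval is the percentile bootstrap over cell indices.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("input vectors must have equal length")
    n = len(a)
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    r_obs = _corr(a, b, method)
    rng = np.random.default_rng(seed)

    exact = n <= 7
    if exact:
        perms = np.array([_corr(a, b[list(p)], method)
                          for p in permutations(range(n))])
        tail = np.sum(perms <= r_obs + 1e-12)
        if two_sided:
            tail = np.sum(np.abs(perms) >= abs(r_obs) - 1e-12)
        p = float(tail / len(perms))
        n_used = len(perms)
    else:
        perms = np.empty(n_perm)
        for i in range(n_perm):
            perms[i] = _corr(a, rng.permutation(b), method)
        if two_sided:
            hits = np.sum(np.abs(perms) >= abs(r_obs) - 1e-12)
        else:
            hits = np.sum(perms <= r_obs + 1e-12)
        p = float((1 + hits) / (n_perm + 1))
        n_used = n_perm
    p = min(p, 1.0) if p > 0 else 1.0 / (n_used + 1)

    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.ptp(a[idx]) == 0 or np.ptp(b[idx]) == 0:
            boot[i] = np.nan
            continue
        boot[i] = _corr(a[idx], b[idx], method)
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    return AnticorrelationResult(
        observed_correlation=r_obs, p_value=p, ci_lower=float(lo),
        ci_upper=float(hi), n_permutations=n_used, n_bootstrap=n_boot,
        seed=seed, method=method, exact=exact,
    )
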