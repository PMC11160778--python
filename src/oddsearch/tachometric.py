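"""Tachometric-curve estimation and its scalar summaries.

The tachometric curve is the fraction of correct choices as a function of
processing time (PT), computed in wide overlapping bins (50 ms) that slide in
small steps (1 ms).  Two binning-independent summaries bracket it:

* **floor accuracy** — percent correct over trials with PT < 100 ms, where
  choices are uninformed guesses (chance is 0.25 with four choice targets);
* **ceiling accuracy** — percent correct over trials with PT > 150 ms, where
  choices are informed by the color cue.

Binomial proportions carry Agresti-Coull 95% confidence intervals;
between-condition comparisons use a trial-level percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "FLOOR_PT_MS",
    "CEILING_PT_MS",
    "AccuracyEstimate",
    "TachometricCurve",
    "DifferenceCurve",
    "BootstrapComparison",
    "agresti_coull_ci",
    "compute_tachometric",
    "floor_accuracy",
    "ceiling_accuracy",
    "region_accuracy",
    "difference_curve",
    "mean_rt",
    "resample_compare",
]

#: Uninformed choices: PT strictly below this bound (ms).
FLOOR_PT_MS = 100.0
#: Informed choices: PT strictly above this bound (ms).  Trials in the
#: 100-150 ms transition band belong to neither summary.
CEILING_PT_MS = 150.0


def agresti_coull_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Agresti-Coull confidence interval for a binomial proportion.

    Add-z^2 adjusted Wald interval, clipped to [0, 1].  Raises on ``n == 0``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method="agresti_coull")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


@dataclass(frozen=True)
class AccuracyEstimate:
    """A binomial proportion correct with its Agresti-Coull 95% CI."""

    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    region: Literal["floor", "ceiling", "custom"] = "custom"

    @property
    def defined(self) -> bool:
        return self.n > 0

    @property
    def ci_span_pp(self) -> float:
        """CI span in percentage points (reliability gauge)."""
        return 100.0 * (self.ci_high - self.ci_low)

    @property
    def se(self) -> float:
        """Binomial standard error of the proportion."""
        if self.n == 0:
            return float("nan")
        return float(np.sqrt(self.proportion * (1.0 - self.proportion) / self.n))

    @classmethod
    def from_counts(cls, k: int, n: int,
                    region: str = "custom") -> "AccuracyEstimate":
        if n == 0:
            return cls(0, 0, float("nan"), float("nan"), float("nan"), region)
        lo, hi = agresti_coull_ci(k, n)
        return cls(int(k), int(n), k / n, lo, hi, region)


@dataclass
class TachometricCurve:
    """Sliding-bin fraction correct versus processing time.

    ``fraction_correct`` is NaN (undefined, never zero) in empty bins, and the
    CI columns follow suit.  Bin ``j`` covers the half-open window
    ``[pt_grid[j] - w/2, pt_grid[j] + w/2)``.
    """

    pt_grid: np.ndarray
    n_trials: np.ndarray
    n_correct: np.ndarray
    fraction_correct: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    bin_width_ms: float = 50.0
    step_ms: float = 1.0

    @property
    def defined(self) -> np.ndarray:
        return self.n_trials > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pt": self.pt_grid, "n": self.n_trials, "k": self.n_correct,
            "frac": self.fraction_correct,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


def compute_tachometric(trials: pd.DataFrame, bin_width_ms: float = 50.0,
                        step_ms: float = 1.0,
                        pt_range: tuple[float, float] | None = None,
                        conf: float = 0.95) -> TachometricCurve:
    """Estimate the tachometric curve of a trial set.

    Parameters
    ----------
    trials
        Trial table with ``pt_ms`` and ``correct`` columns.
    bin_width_ms, step_ms
        Width of each PT bin and spacing of consecutive bin centers.
    pt_range
        (lo, hi) of bin centers; defaults to the span of the observed PTs.
    conf
        Confidence level of the per-bin Agresti-Coull intervals.
    """
    if bin_width_ms <= 0 or step_ms <= 0:
        raise ValueError("bin_width_ms and step_ms must be positive")
    pt = trials["pt_ms"].to_numpy(dtype=float)
    correct = trials["correct"].to_numpy(dtype=bool)

    if pt_range is None:
        if len(pt):
            lo, hi = float(np.floor(pt.min())), float(np.ceil(pt.max()))
        else:
            lo, hi = 0.0, 0.0
    else:
        lo, hi = map(float, pt_range)
    grid = np.arange(lo, hi + 0.5 * step_ms, step_ms)

    order = np.argsort(pt, kind="stable")
    pt_sorted = pt[order]
    corr_sorted = correct[order]
    cum_correct = np.concatenate([[0], np.cumsum(corr_sorted)])

    half = bin_width_ms / 2.0
    left = np.searchsorted(pt_sorted, grid - half, side="left")
    right = np.searchsorted(pt_sorted, grid + half, side="left")
    n = (right - left).astype(int)
    k = (cum_correct[right] - cum_correct[left]).astype(int)

    frac = np.full(len(grid), np.nan)
    ci_lo = np.full(len(grid), np.nan)
    ci_hi = np.full(len(grid), np.nan)
    m = n > 0
    frac[m] = k[m] / n[m]
    if m.any():
        lo_v, hi_v = proportion_confint(k[m], n[m], alpha=1.0 - conf,
                                        method="agresti_coull")
        ci_lo[m] = np.clip(lo_v, 0.0, 1.0)
        ci_hi[m] = np.clip(hi_v, 0.0, 1.0)
    return TachometricCurve(grid, n, k, frac, ci_lo, ci_hi,
                            bin_width_ms, step_ms)


def region_accuracy(trials: pd.DataFrame, pt_lo: float = -np.inf,
                    pt_hi: float = np.inf,
                    region: str = "custom") -> AccuracyEstimate:
    """Proportion correct over trials with ``pt_lo < PT < pt_hi`` (strict)."""
    pt = trials["pt_ms"].to_numpy(dtype=float)
    m = (pt > pt_lo) & (pt < pt_hi)
    k = int(trials["correct"].to_numpy(dtype=bool)[m].sum())
    return AccuracyEstimate.from_counts(k, int(m.sum()), region)


def floor_accuracy(trials: pd.DataFrame) -> AccuracyEstimate:
    """Accuracy of uninformed choices (PT strictly below 100 ms)."""
    return region_accuracy(trials, pt_hi=FLOOR_PT_MS, region="floor")


def ceiling_accuracy(trials: pd.DataFrame) -> AccuracyEstimate:
    """Accuracy of informed choices (PT strictly above 150 ms)."""
    return region_accuracy(trials, pt_lo=CEILING_PT_MS, region="ceiling")


@dataclass
class DifferenceCurve:
    """Per-bin difference between two tachometric curves with its SE band."""

    pt_grid: np.ndarray
    difference: np.ndarray
    se: np.ndarray
    bin_width_ms: float
    step_ms: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.difference)


def difference_curve(curve_s: TachometricCurve,
                     curve_d: TachometricCurve) -> DifferenceCurve:
    """Subtract two curves bin by bin (same minus different, typically).

    The per-bin standard error combines the two binomial SEs in quadrature;
    bins undefined in either input stay undefined.
    """
    if (len(curve_s.pt_grid) != len(curve_d.pt_grid)
            or not np.allclose(curve_s.pt_grid, curve_d.pt_grid)
            or curve_s.bin_width_ms != curve_d.bin_width_ms
            or curve_s.step_ms != curve_d.step_ms):
        raise ValueError("curves must share grid and bin parameters")
    diff = curve_s.fraction_correct - curve_d.fraction_correct
    with np.errstate(invalid="ignore", divide="ignore"):
        var_s = curve_s.fraction_correct * (1 - curve_s.fraction_correct) / curve_s.n_trials
        var_d = curve_d.fraction_correct * (1 - curve_d.fraction_correct) / curve_d.n_trials
    se = np.sqrt(var_s + var_d)
    return DifferenceCurve(curve_s.pt_grid.copy(), diff, se,
                           curve_s.bin_width_ms, curve_s.step_ms)


def mean_rt(trials: pd.DataFrame) -> tuple[float, float, int]:
    """Mean RT with SEM over all supplied trials (correct and errors, all PTs).

    SEM is NaN for fewer than two trials.
    """
    rt = trials["rt_ms"].to_numpy(dtype=float)
    n = len(rt)
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(rt.mean())
    sem = float(rt.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, sem, n


@dataclass
class BootstrapComparison:
    """Result of a resampling comparison of two trial sets."""

    statistic: str
    observed_a: float
    observed_b: float
    observed_diff: float
    p_value: float
    distribution: np.ndarray = field(repr=False)
    n_boot: int = 10_000
    seed: int | None = None


def resample_compare(trials_a: pd.DataFrame, trials_b: pd.DataFrame,
                     statistic: Literal["floor", "ceiling"],
                     n_boot: int = 10_000, seed: int | None = None,
                     ) -> BootstrapComparison:
    """Bootstrap test for a floor- or ceiling-accuracy difference.

    Trials are resampled with replacement within each group; the two-sided
    p-value is the (add-one smoothed) fraction of the bootstrap distribution
    of ``stat_a - stat_b`` on the far side of zero, doubled and capped at 1.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    if statistic == "floor":
        lo, hi = -np.inf, FLOOR_PT_MS
    elif statistic == "ceiling":
        lo, hi = CEILING_PT_MS, np.inf
    else:
        raise ValueError("statistic must be 'floor' or 'ceiling'")

    rng = np.random.default_rng(seed)

    def _prep(t: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        if len(t) == 0:
            raise ValueError("empty trial group")
        pt = t["pt_ms"].to_numpy(dtype=float)
        return (pt > lo) & (pt < hi), t["correct"].to_numpy(dtype=bool)

    in_a, corr_a = _prep(trials_a)
    in_b, corr_b = _prep(trials_b)

    def _stat(mask: np.ndarray, corr: np.ndarray, idx: np.ndarray) -> np.ndarray:
        m = mask[idx]
        n = m.sum(axis=1)
        k = (m & corr[idx]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, k / np.maximum(n, 1), np.nan)

    obs_a = corr_a[in_a].mean() if in_a.any() else float("nan")
    obs_b = corr_b[in_b].mean() if in_b.any() else float("nan")

    # chunked so index matrices stay small at large n_boot * n_trials
    chunks = []
    chunk = max(1, int(2_000_000 // max(len(corr_a), len(corr_b), 1)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx_a = rng.integers(0, len(corr_a), size=(b, len(corr_a)))
        idx_b = rng.integers(0, len(corr_b), size=(b, len(corr_b)))
        chunks.append(_stat(in_a, corr_a, idx_a) - _stat(in_b, corr_b, idx_b))
        done += b
    dist = np.concatenate(chunks)
    dist = dist[np.isfinite(dist)]

    n_lo = int((dist <= 0).sum())
    n_hi = int((dist >= 0).sum())
    p = 2.0 * (min(n_lo, n_hi) + 1) / (len(dist) + 1)
    return BootstrapComparison(statistic, float(obs_a), float(obs_b),
                               float(obs_a - obs_b), min(p, 1.0), dist,
                               n_boot, seed)
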