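"""Inter-subject alignment and pooling of tachometric curves.

Two subjects' curves y1 and y2 are aligned by the affine-plus-shift map

    z(j) = g * y2(j + delta) + b

where g is a gain, b a baseline shift, and delta a displacement along the PT
axis (ms).  The optimal parameters minimize the mean absolute deviation
between z and y1 over the bins where both are defined.  Only delta has a
substantive use downstream: it is applied to one subject's RTs (which shifts
the PTs equally) before the two trial sets are pooled; g and b are alignment
diagnostics.

The L1 objective is piecewise linear, so the optimum is found by a
deterministic coarse-to-fine grid search rather than smooth optimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .tachometric import TachometricCurve
from .trials import shift_rts

__all__ = ["AlignmentParams", "transform_curve", "align_curves",
           "pool_subjects"]


@dataclass(frozen=True)
class AlignmentParams:
    """Optimal (gain, baseline, PT shift) and the achieved L1 objective."""

    gain: float
    baseline: float
    shift_ms: float
    objective: float  # mean |z - y1| per overlapping bin at the optimum
    n_overlap: int


def _shift_steps(delta_ms: float, step_ms: float) -> int:
    s = delta_ms / step_ms
    r = round(s)
    if abs(s - r) > 1e-9:
        raise ValueError(
            f"delta {delta_ms} ms is not a multiple of the grid step {step_ms} ms")
    return int(r)


def transform_curve(curve: TachometricCurve, g: float, b: float,
                    delta_ms: float) -> TachometricCurve:
    """Apply z(j) = g * y(j + delta) + b on the curve's own grid.

    Bins shifted outside the grid become undefined.  The returned object
    carries the transformed fractions and CIs (same map applied); its count
    columns are the shifted raw counts kept for overlap bookkeeping, so the
    count/fraction identity of measured curves does not hold for transformed
    ones.
    """
    s = _shift_steps(delta_ms, curve.step_ms)
    m = len(curve.pt_grid)

    def pull(a: np.ndarray, fill: float) -> np.ndarray:
        out = np.full(m, fill, dtype=float)
        src_lo, src_hi = max(0, s), min(m, m + s)
        dst_lo, dst_hi = max(0, -s), min(m, m - s)
        out[dst_lo:dst_hi] = a[src_lo:src_hi]
        return out

    frac = g * pull(curve.fraction_correct, np.nan) + b
    n = pull(curve.n_trials.astype(float), 0.0).astype(int)
    k = pull(curve.n_correct.astype(float), 0.0).astype(int)
    ci_lo = g * pull(curve.ci_low, np.nan) + b
    ci_hi = g * pull(curve.ci_high, np.nan) + b
    return TachometricCurve(curve.pt_grid.copy(), n, k, frac, ci_lo, ci_hi,
                            curve.bin_width_ms, curve.step_ms)


def _objective_grid(y1: np.ndarray, y2: np.ndarray, s: int,
                    g_grid: np.ndarray, b_grid: np.ndarray
                    ) -> tuple[float, float, float, int]:
    """Min over (g, b) of mean |g*y2(j+s) + b - y1(j)|; returns (obj, g, b, n)."""
    m = len(y1)
    src_lo, src_hi = max(0, s), min(m, m + s)
    dst_lo, dst_hi = max(0, -s), min(m, m - s)
    a = y1[dst_lo:dst_hi]
    c = y2[src_lo:src_hi]
    ok = np.isfinite(a) & np.isfinite(c)
    if not ok.any():
        return np.inf, np.nan, np.nan, 0
    a, c = a[ok], c[ok]
    # residual tensor (g, b, bin) evaluated blockwise over g to bound memory
    best = (np.inf, np.nan, np.nan)
    for gi in range(0, len(g_grid), 16):
        gs = g_grid[gi:gi + 16]
        r = np.abs(gs[:, None, None] * c[None, None, :]
                   + b_grid[None, :, None] - a[None, None, :]).mean(axis=2)
        j = np.unravel_index(np.argmin(r), r.shape)
        if r[j] < best[0]:
            best = (float(r[j]), float(gs[j[0]]), float(b_grid[j[1]]))
    return best[0], best[1], best[2], int(ok.sum())


def align_curves(curve1: TachometricCurve, curve2: TachometricCurve,
                 delta_range_ms: tuple[float, float] = (-60.0, 60.0),
                 g_range: tuple[float, float] = (0.5, 1.5),
                 g_step: float = 0.01,
                 b_range: tuple[float, float] = (-0.25, 0.25),
                 b_step: float = 0.005,
                 min_overlap: int = 10,
                 min_bin_n: int = 25) -> AlignmentParams:
    """Find (g, b, delta) minimizing mean |g*y2(j+delta)+b - y1(j)|.

    The search is exhaustive over integer-step delta candidates with a
    coarse (g, b) grid, then refined around the best delta with the full
    resolution grids.  The objective is normalized per overlapping bin so
    small overlaps are not rewarded; deltas whose overlap falls below
    ``min_overlap`` bins are excluded.  Bins estimated from fewer than
    ``min_bin_n`` trials are masked out of the objective — sparse tail bins
    are individually so noisy that their exclusion from the overlap would
    otherwise be rewarded more than any true alignment.  Ties are broken
    toward smallest |delta|, then smallest |b|, then g closest to 1.
    """
    if (curve1.bin_width_ms != curve2.bin_width_ms
            or curve1.step_ms != curve2.step_ms
            or len(curve1.pt_grid) != len(curve2.pt_grid)
            or not np.allclose(curve1.pt_grid, curve2.pt_grid)):
        raise ValueError("curves must share grid and bin parameters")
    step = curve1.step_ms
    y1 = np.where(curve1.n_trials >= min_bin_n,
                  np.asarray(curve1.fraction_correct, dtype=float), np.nan)
    y2 = np.where(curve2.n_trials >= min_bin_n,
                  np.asarray(curve2.fraction_correct, dtype=float), np.nan)

    d_lo = _shift_steps(delta_range_ms[0], step)
    d_hi = _shift_steps(delta_range_ms[1], step)
    deltas = np.arange(d_lo, d_hi + 1)

    g_coarse = np.round(np.arange(g_range[0], g_range[1] + 1e-9, 5 * g_step), 10)
    b_coarse = np.round(np.arange(b_range[0], b_range[1] + 1e-9, 5 * b_step), 10)
    g_fine = np.round(np.arange(g_range[0], g_range[1] + 1e-9, g_step), 10)
    b_fine = np.round(np.arange(b_range[0], b_range[1] + 1e-9, b_step), 10)

    coarse = []
    for s in deltas:
        obj, g, b, n = _objective_grid(y1, y2, int(s), g_coarse, b_coarse)
        if n >= min_overlap:
            coarse.append((obj, int(s)))
    if not coarse:
        raise ValueError("no delta candidate with sufficient overlap")
    best_coarse_delta = min(coarse)[1]

    cands = []
    for s in range(best_coarse_delta - 5, best_coarse_delta + 6):
        if s < d_lo or s > d_hi:
            continue
        obj, g, b, n = _objective_grid(y1, y2, s, g_fine, b_fine)
        if n >= min_overlap:
            cands.append((obj, abs(s * step), abs(b), abs(g - 1.0),
                          g, b, s, n))
    obj, _, _, _, g, b, s, n = min(cands)
    return AlignmentParams(gain=g, baseline=b, shift_ms=float(s * step),
                           objective=obj, n_overlap=n)


def pool_subjects(trials_by_subject: Mapping[str, pd.DataFrame],
                  shifts_ms: Mapping[str, float]) -> pd.DataFrame:
    """Shift each subject's RTs by its alignment delta and concatenate.

    ``shifts_ms[subject]`` is subtracted from that subject's RTs (and hence
    PTs); subjects without an entry are pooled unshifted.  Provenance stays
    in the ``subject_id`` column.
    """
    parts = []
    for subject, df in trials_by_subject.items():
        delta = float(shifts_ms.get(subject, 0.0))
        parts.append(shift_rts(df, delta) if delta != 0.0 else df.copy())
    return pd.concat(parts, ignore_index=True)
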