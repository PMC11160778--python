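"""Composed analyses: history-conditioned curves and S-D contrasts.

These helpers wire the history classifiers to the tachometric estimators,
reproducing the standard figure-level analyses: same-versus-different
tachometric curves, their difference curve, and the binning-independent
floor/ceiling contrasts used to test whether a history effect is present in
the guessing versus the informed regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .history import classify_history
from .tachometric import (AccuracyEstimate, DifferenceCurve, TachometricCurve,
                          ceiling_accuracy, compute_tachometric,
                          difference_curve, floor_accuracy)

__all__ = ["history_split_curves", "RegionContrast", "region_contrast"]


def history_split_curves(trials: pd.DataFrame, dimension: str, N: int = 1,
                         bin_width_ms: float = 50.0, step_ms: float = 1.0,
                         pt_range: tuple[float, float] | None = None,
                         ) -> tuple[TachometricCurve, TachometricCurve,
                                    DifferenceCurve]:
    """Tachometric curves for NS and ND trials plus their S-D difference.

    Both curves are estimated on a shared PT grid (by default the span of
    all supplied trials) so they subtract bin for bin.
    """
    labels = classify_history(trials, dimension, N)
    if pt_range is None:
        pt = trials["pt_ms"].to_numpy(dtype=float)
        pt_range = (float(np.floor(pt.min())), float(np.ceil(pt.max())))
    s_letter = "C" if dimension == "outcome" else "S"
    d_letter = "E" if dimension == "outcome" else "D"
    curve_s = compute_tachometric(trials.loc[(labels == s_letter).to_numpy()],
                                  bin_width_ms, step_ms, pt_range)
    curve_d = compute_tachometric(trials.loc[(labels == d_letter).to_numpy()],
                                  bin_width_ms, step_ms, pt_range)
    return curve_s, curve_d, difference_curve(curve_s, curve_d)


@dataclass(frozen=True)
class RegionContrast:
    """S-D accuracy contrast in one PT region, with its z score."""

    region: str
    est_s: AccuracyEstimate
    est_d: AccuracyEstimate

    @property
    def difference(self) -> float:
        return self.est_s.proportion - self.est_d.proportion

    @property
    def se(self) -> float:
        return float(np.sqrt(self.est_s.se ** 2 + self.est_d.se ** 2))

    @property
    def z(self) -> float:
        return self.difference / self.se

    def exceeds_band(self, n_se: float = 2.5) -> bool:
        """Does |S - D| exceed an ``n_se``-wide standard-error band?"""
        return abs(self.z) > n_se


def region_contrast(trials: pd.DataFrame, dimension: str, N: int = 1,
                    region: str = "floor") -> RegionContrast:
    """Floor- or ceiling-region S-D contrast for one history dimension.

    Unlike the per-bin difference curve, this aggregate is independent of
    the sliding-bin parameters and its bins are not mutually correlated, so
    it is the quantity of choice for band-exceedance decisions.
    """
    labels = classify_history(trials, dimension, N)
    s_letter = "C" if dimension == "outcome" else "S"
    d_letter = "E" if dimension == "outcome" else "D"
    sub_s = trials.loc[(labels == s_letter).to_numpy()]
    sub_d = trials.loc[(labels == d_letter).to_numpy()]
    if region == "floor":
        return RegionContrast(region, floor_accuracy(sub_s),
                              floor_accuracy(sub_d))
    if region == "ceiling":
        return RegionContrast(region, ceiling_accuracy(sub_s),
                              ceiling_accuracy(sub_d))
    raise ValueError("region must be 'floor' or 'ceiling'")
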