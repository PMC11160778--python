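"""History-free accuracy model of the tachometric curve.

Accuracy as a function of processing time is modeled as a four-parameter
logistic,

    p(correct | pt) = floor + (ceiling - floor) * sigmoid((pt - center) / width)

with the floor the uninformed (guessing) accuracy, the ceiling the informed
asymptote, and center/width the location and time scale of the perceptual
rise (ms).  The model is fitted by direct maximization of the Bernoulli
likelihood: a deterministic coarse grid pick of starting values followed by
bounded quasi-Newton refinement.  Standard errors come from the numerically
differentiated observed information at the optimum; estimates pinned at a
parameter bound are flagged and their Wald intervals should not be trusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

__all__ = ["SigmoidAccuracyModel", "SigmoidAccuracyResults"]

PARAM_NAMES = ("floor", "ceiling", "center", "width")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return special.expit(x)


class SigmoidAccuracyModel:
    """Maximum-likelihood fit of the floor/ceiling logistic accuracy curve.

    Parameters
    ----------
    correct
        Boolean outcome per trial.
    pt_ms
        Processing time per trial (ms).
    """

    def __init__(self, correct: np.ndarray, pt_ms: np.ndarray):
        self.correct = np.asarray(correct, dtype=bool)
        self.pt = np.asarray(pt_ms, dtype=float)
        if len(self.correct) != len(self.pt):
            raise ValueError("correct and pt_ms must have equal length")
        if len(self.pt) == 0 or np.ptp(self.pt) == 0:
            raise ValueError("degenerate PT range")
        self._bounds = [
            (1e-4, 1.0 - 1e-4),
            (1e-4, 1.0 - 1e-4),
            (float(self.pt.min()), float(self.pt.max())),
            (0.5, 200.0),
        ]

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "SigmoidAccuracyModel":
        return cls(trials["correct"].to_numpy(), trials["pt_ms"].to_numpy())

    def predict(self, params: np.ndarray, pt: np.ndarray) -> np.ndarray:
        fl, ce, c, w = params
        return fl + (ce - fl) * _sigmoid((np.asarray(pt, float) - c) / w)

    def nloglike(self, params: np.ndarray) -> float:
        p = np.clip(self.predict(params, self.pt), 1e-12, 1.0 - 1e-12)
        ll = np.where(self.correct, np.log(p), np.log1p(-p))
        return -float(ll.sum())

    def _start_params(self) -> np.ndarray:
        lo_m = self.pt < 100.0
        hi_m = self.pt > 150.0
        fl = self.correct[lo_m].mean() if lo_m.any() else 0.25
        ce = self.correct[hi_m].mean() if hi_m.any() else 0.75
        fl = float(np.clip(fl, 0.02, 0.98))
        ce = float(np.clip(ce, 0.02, 0.98))
        best, best_nll = None, np.inf
        for c in (90.0, 105.0, 120.0, 135.0, 150.0):
            for w in (3.0, 6.0, 12.0, 25.0, 60.0):
                th = np.array([fl, ce, c, w])
                nll = self.nloglike(th)
                if nll < best_nll:
                    best, best_nll = th, nll
        return best

    def fit(self) -> "SigmoidAccuracyResults":
        start = self._start_params()
        res = optimize.minimize(self.nloglike, start, method="L-BFGS-B",
                                bounds=self._bounds,
                                options={"maxiter": 500})
        params = res.x

        flags = {}
        for name, val, (lo, hi) in zip(PARAM_NAMES, params, self._bounds):
            at_bound = val - lo < 1e-3 * max(1.0, abs(lo)) or \
                hi - val < 1e-3 * max(1.0, abs(hi))
            flags[f"{name}_at_boundary"] = bool(at_bound)

        # observed information computed with the width on a log scale: the
        # sampling distribution of a positive scale parameter is right-skewed
        # and the symmetric interval on log(width) respects that
        bse = np.full(4, np.nan)
        cov = np.full((4, 4), np.nan)
        se_log_width = np.nan
        if not any(flags.values()):
            def nll_t(phi: np.ndarray) -> float:
                th = phi.copy()
                th[3] = np.exp(phi[3])
                return self.nloglike(th)

            phi_hat = params.copy()
            phi_hat[3] = np.log(params[3])
            try:
                H = approx_hess(phi_hat, nll_t)
                cov_t = np.linalg.inv(H)
                d = np.diag(cov_t)
                if (d > 0).all():
                    bse = np.sqrt(d)
                    se_log_width = bse[3]
                    bse[3] = params[3] * se_log_width  # delta method
                    jac = np.diag([1.0, 1.0, 1.0, params[3]])
                    cov = jac @ cov_t @ jac
                else:
                    flags["hessian_not_pd"] = True
            except np.linalg.LinAlgError:
                flags["hessian_not_pd"] = True
        no_boundary = not any(v for k, v in flags.items()
                              if k.endswith("_at_boundary"))
        flags["width_uninformative"] = bool(
            flags.get("width_at_boundary", False)
            or (no_boundary and not np.isfinite(bse[3]))  # singular information
            or (np.isfinite(bse[3]) and bse[3] > abs(params[3])))
        return SigmoidAccuracyResults(self, params, bse, cov,
                                      llf=-res.fun, converged=bool(res.success),
                                      flags=flags,
                                      se_log_width=float(se_log_width))


@dataclass
class SigmoidAccuracyResults:
    """Estimates, uncertainties and diagnostics of a sigmoid-accuracy fit."""

    model: SigmoidAccuracyModel
    _params: np.ndarray
    _bse: np.ndarray
    cov_params: np.ndarray
    llf: float
    converged: bool
    flags: dict
    se_log_width: float = float("nan")

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=PARAM_NAMES)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._bse, index=PARAM_NAMES)

    @property
    def nobs(self) -> int:
        return len(self.model.pt)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        lo = self._params - z * self._bse
        hi = self._params + z * self._bse
        if np.isfinite(self.se_log_width):
            w = self._params[3]
            lo[3] = w * np.exp(-z * self.se_log_width)
            hi[3] = w * np.exp(z * self.se_log_width)
        return pd.DataFrame({"lower": lo, "upper": hi}, index=PARAM_NAMES)

    def predict(self, pt: np.ndarray) -> np.ndarray:
        return self.model.predict(self._params, pt)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Sigmoid accuracy model (Bernoulli MLE)",
            f"  n trials: {self.nobs}   log-likelihood: {self.llf:.1f}   "
            f"converged: {self.converged}",
            f"  {'param':<8}{'estimate':>10}{'std err':>10}"
            f"{'[0.025':>10}{'0.975]':>10}",
        ]
        for name in PARAM_NAMES:
            lines.append(
                f"  {name:<8}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}")
        active = [k for k, v in self.flags.items() if v]
        if active:
            lines.append(f"  flags: {', '.join(active)}")
        return "\n".join(lines)
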