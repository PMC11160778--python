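"""Conditional-independence test of interaction between history variables.

Do two selection-history variables (say, target-color history A and
target-location history B) influence the current choice independently, or do
they interact?  Under conditional independence of A and B given the outcome
C — P(A,B|C) = P(A|C) P(B|C) — Bayes' rule collapses the joint-condition
accuracy to a function of the two marginal-condition accuracies and the
overall accuracy (the prior):

    P(C=1|A,B) = pa*pb / (pa*pb + (1-pa)*(1-pb) * prior/(1-prior))

with pa = P(C=1|A), pb = P(C=1|B).  The analysis measures the left side
directly from jointly-conditioned trials and predicts it from the right
side; points on the measured-vs-predicted diagonal indicate no functional
interaction.  A regression slope (beta2) near 1 across all sequences of a
given history length summarizes the same thing.

Accuracies here are over *informed* trials only (PT > 150 ms, the ceiling
region).  Sequences whose measured CI spans 15 percentage points or more
are flagged unreliable and excluded from the slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .history import DIMENSIONS, enumerate_sequences, sequence_labels
from .tachometric import CEILING_PT_MS, AccuracyEstimate, ceiling_accuracy

__all__ = [
    "predict_joint",
    "conditional_accuracy",
    "InteractionPoint",
    "SlopeEstimate",
    "InteractionModel",
    "InteractionResults",
    "interaction_analysis",
    "interaction_slope",
]

#: Reliability rule: measured 95% CI must span fewer percentage points.
DEFAULT_CI_SPAN_PP = 15.0


def predict_joint(p_a: float, p_b: float, prior: float) -> float:
    """Joint-condition accuracy predicted under conditional independence.

    Parameters are the two marginal conditional accuracies and the overall
    probability correct (the prior); the prior must be strictly inside
    (0, 1).  The result lies in [0, 1], is symmetric in (p_a, p_b), and
    reduces to p_a when p_b equals the prior (an uninformative condition).
    """
    for name, v in (("p_a", p_a), ("p_b", p_b), ("prior", prior)):
        if not np.isfinite(v) or not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a probability, got {v}")
    if prior in (0.0, 1.0):
        raise ValueError("prior of 0 or 1 is degenerate")
    num = p_a * p_b
    den = num + (1.0 - p_a) * (1.0 - p_b) * prior / (1.0 - prior)
    if den == 0.0:
        # p_a = p_b = 0: both conditions guarantee an error
        return 0.0
    return float(num / den)


def conditional_accuracy(trials: pd.DataFrame,
                         member: pd.Series | np.ndarray) -> AccuracyEstimate:
    """Informed-choice accuracy (PT > 150 ms) among trials in a condition.

    ``member`` is a boolean mask aligned with ``trials``.  With an all-True
    mask this reduces to the unconditional ceiling accuracy.
    """
    m = np.asarray(member, dtype=bool)
    return ceiling_accuracy(trials.loc[m])


@dataclass(frozen=True)
class InteractionPoint:
    """One history sequence's measured vs predicted informed accuracy."""

    label: str
    H: int
    measured: AccuracyEstimate
    predicted_p: float
    label_a: str
    label_b: str
    component_a: AccuracyEstimate
    component_b: AccuracyEstimate
    prior: float
    reliable: bool

    @property
    def measured_p(self) -> float:
        return self.measured.proportion


@dataclass(frozen=True)
class SlopeEstimate:
    """Regression slope of predicted on measured accuracy (beta2)."""

    beta2: float
    ci_low: float
    ci_high: float
    ols_ci_low: float
    ols_ci_high: float
    intercept: float
    n_points: int
    n_boot: int
    seed: int | None


class InteractionModel:
    """Measured-versus-predicted interaction analysis of two history variables.

    Parameters
    ----------
    trials
        Pooled, session-ordered trial table.
    dims_a, dims_b
        The two history variables, each a tuple of dimensions.  Pairs use
        singletons, e.g. ``("color",)`` vs ``("location",)``; the
        three-variable analysis shares the outcome dimension:
        ``("color", "outcome")`` vs ``("location", "outcome")``.
    H
        History length in trials (1-4): every one of the H preceding trials
        carries its own relation letters.
    ci_span_threshold_pp
        Reliability rule on the measured CI span, in percentage points.
    prior_scope
        ``"ceiling"`` (default) computes the prior over informed trials
        (PT > 150 ms), matching the informed-accuracy components;
        ``"all"`` uses all trials.
    """

    def __init__(self, trials: pd.DataFrame,
                 dims_a: Sequence[str] = ("color",),
                 dims_b: Sequence[str] = ("location",),
                 H: int = 1,
                 ci_span_threshold_pp: float = DEFAULT_CI_SPAN_PP,
                 prior_scope: str = "ceiling"):
        if not 1 <= H <= 4:
            raise ValueError("H must be in 1..4")
        dims_a, dims_b = tuple(dims_a), tuple(dims_b)
        for d in dims_a + dims_b:
            if d not in DIMENSIONS:
                raise ValueError(f"unknown dimension {d!r}")
        if set(dims_a) == set(dims_b):
            raise ValueError("dims_a and dims_b must differ")
        if prior_scope not in ("ceiling", "all"):
            raise ValueError("prior_scope must be 'ceiling' or 'all'")
        self.trials = trials
        self.dims_a = dims_a
        self.dims_b = dims_b
        self.union_dims = tuple(d for d in DIMENSIONS
                                if d in set(dims_a) | set(dims_b))
        self.H = H
        self.ci_span_threshold_pp = float(ci_span_threshold_pp)
        self.prior_scope = prior_scope

    def _project(self, joint_label: str, dims: tuple[str, ...]) -> str:
        """Restrict a joint sequence label to a subset of dimensions."""
        w = len(self.union_dims)
        keep = [i for i, d in enumerate(self.union_dims) if d in dims]
        groups = [joint_label[t * w:(t + 1) * w] for t in range(self.H)]
        return "".join("".join(grp[i] for i in keep) for grp in groups)

    def fit(self, n_boot: int = 10_000, seed: int | None = 0
            ) -> "InteractionResults":
        """Compute all interaction points and the beta2 slope summary."""
        trials = self.trials
        joint = sequence_labels(trials, self.union_dims, self.H)
        lab_a = sequence_labels(trials, self.dims_a, self.H)
        lab_b = sequence_labels(trials, self.dims_b, self.H)

        pt = trials["pt_ms"].to_numpy(dtype=float)
        correct = trials["correct"].to_numpy(dtype=bool)
        ceil_mask = pt > CEILING_PT_MS
        if self.prior_scope == "ceiling":
            prior_est = AccuracyEstimate.from_counts(
                int(correct[ceil_mask].sum()), int(ceil_mask.sum()), "ceiling")
        else:
            prior_est = AccuracyEstimate.from_counts(
                int(correct.sum()), len(correct), "custom")
        prior = prior_est.proportion

        def table(labels: pd.Series) -> dict[str, AccuracyEstimate]:
            out: dict[str, AccuracyEstimate] = {}
            arr = labels.to_numpy()
            for lab in pd.unique(arr[pd.notna(arr)]):
                m = (arr == lab) & ceil_mask
                out[lab] = AccuracyEstimate.from_counts(
                    int(correct[m].sum()), int(m.sum()), "ceiling")
            return out
        acc_joint = table(joint)
        acc_a = table(lab_a)
        acc_b = table(lab_b)

        empty = AccuracyEstimate.from_counts(0, 0, "ceiling")
        points = []
        for lab in enumerate_sequences(self.union_dims, self.H):
            meas = acc_joint.get(lab, empty)
            la = self._project(lab, self.dims_a)
            lb = self._project(lab, self.dims_b)
            ca = acc_a.get(la, empty)
            cb = acc_b.get(lb, empty)
            if ca.defined and cb.defined and 0.0 < prior < 1.0:
                pred = predict_joint(ca.proportion, cb.proportion, prior)
            else:
                pred = float("nan")
            reliable = (meas.defined and np.isfinite(pred)
                        and meas.ci_span_pp < self.ci_span_threshold_pp)
            points.append(InteractionPoint(
                label=lab, H=self.H, measured=meas, predicted_p=pred,
                label_a=la, label_b=lb, component_a=ca, component_b=cb,
                prior=prior, reliable=reliable))

        slope = None
        n_rel = sum(p.reliable for p in points)
        if n_rel >= 3:
            slope = interaction_slope(points, n_boot=n_boot, seed=seed)
        return InteractionResults(model=self, points=points,
                                  prior=prior_est, slope=slope)


@dataclass
class InteractionResults:
    """Points and slope summary from :meth:`InteractionModel.fit`."""

    model: InteractionModel
    points: list[InteractionPoint]
    prior: AccuracyEstimate
    slope: SlopeEstimate | None = None
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            rows.append({
                "label": p.label, "H": p.H,
                "n": p.measured.n, "k": p.measured.k,
                "measured": p.measured.proportion,
                "ci_low": p.measured.ci_low, "ci_high": p.measured.ci_high,
                "predicted": p.predicted_p,
                "p_a": p.component_a.proportion,
                "p_b": p.component_b.proportion,
                "reliable": p.reliable,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Interaction analysis (conditional-independence benchmark)",
            f"  A = {'+'.join(m.dims_a)}, B = {'+'.join(m.dims_b)}, "
            f"H = {m.H}",
            f"  informed-trial prior P(C=1) = {self.prior.proportion:.4f} "
            f"(n = {self.prior.n})",
            f"  sequences: {len(self.points)}  "
            f"reliable (CI span < {m.ci_span_threshold_pp:g} pp): "
            f"{sum(p.reliable for p in self.points)}",
        ]
        if self.slope is not None:
            s = self.slope
            lines.append(
                f"  beta2 = {s.beta2:.3f}  "
                f"bootstrap 95% CI [{s.ci_low:.3f}, {s.ci_high:.3f}]  "
                f"OLS 95% CI [{s.ols_ci_low:.3f}, {s.ols_ci_high:.3f}]")
        else:
            lines.append("  beta2: not estimated (fewer than 3 reliable points)")
        lines.append("")
        with pd.option_context("display.width", 120):
            lines.append(self.to_frame().to_string(index=False,
                                                   float_format="%.4f"))
        return "\n".join(lines)


def interaction_analysis(trials: pd.DataFrame,
                         dims_a: Sequence[str], dims_b: Sequence[str],
                         H: int,
                         ci_span_threshold_pp: float = DEFAULT_CI_SPAN_PP,
                         prior_scope: str = "ceiling",
                         seed: int | None = 0) -> list[InteractionPoint]:
    """Functional wrapper: all interaction points for one (A, B, H) setting."""
    model = InteractionModel(trials, dims_a, dims_b, H,
                             ci_span_threshold_pp, prior_scope)
    return model.fit(seed=seed).points


def interaction_slope(points: Sequence[InteractionPoint],
                      n_boot: int = 10_000,
                      seed: int | None = 0) -> SlopeEstimate:
    """beta2: least-squares slope of predicted (y) on measured (x) accuracy.

    Restricted to reliable points.  The primary CI is a percentile bootstrap
    over points (robust to the heteroscedastic binomial errors); the
    closed-form OLS interval is reported alongside.
    """
    rel = [p for p in points if p.reliable]
    if len(rel) < 3:
        raise ValueError("need at least 3 reliable points")
    x = np.array([p.measured_p for p in rel])
    y = np.array([p.predicted_p for p in rel])

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    beta2 = float(fit.params[1])
    ols_lo, ols_hi = map(float, fit.conf_int()[1])

    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    n = len(rel)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        vx = xb.var()
        slopes[i] = (np.cov(xb, yb, bias=True)[0, 1] / vx if vx > 0 else np.nan)
    slopes = slopes[np.isfinite(slopes)]
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return SlopeEstimate(beta2=beta2, ci_low=float(lo), ci_high=float(hi),
                         ols_ci_low=ols_lo, ols_ci_high=ols_hi,
                         intercept=float(fit.params[0]),
                         n_points=len(rel), n_boot=n_boot, seed=seed)
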