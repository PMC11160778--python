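"""Generative model of urgent oddball-search sessions.

The simulated agent reproduces the statistical structure the analyses
assume, with tunable, known ground truth:

* target color uniform over two values (repetition prior 0.5) and target
  quadrant uniform over four (repetition prior 0.25), independent across
  trials;
* Gap drawn from a discrete 0-225 ms grid; RT from a truncated normal on
  (0, 450] ms; PT = RT - Gap;
* choices arbitrate between an *informed* route (probability rises
  logistically with PT) and a *guess* route (softmax over four location
  weights), so accuracy sits at chance (0.25) for short PTs and at a
  ceiling for long PTs;
* selection history enters through two leaky integrators gated by trial
  outcome: a per-quadrant guess weight (location priming, slow decay) and a
  per-color gain on the informed-accuracy latent (color priming, fast
  decay).  Rewarded events push their quadrant/color up, errors push down.
* an optional interaction term couples the two traces; at its default of 0
  the color and location histories act conditionally independently, which
  is the structure the interaction analysis assumes under the null.

All latent trajectories and raw uniform draws are logged, so the emitted
choices can be replayed deterministically from the log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .psychometric import SigmoidAccuracyModel, SigmoidAccuracyResults
from .trials import COLORS, QUADRANTS

__all__ = ["GenerativeParams", "generate_session", "generate_trials",
           "replay_choices", "recover_parameters"]


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the synthetic behavioral model (times in ms)."""

    n_trials: int = 1000
    seed: int = 0
    gap_values: tuple[float, ...] = tuple(float(g) for g in range(0, 226, 25))
    rt_mean_ms: float = 275.0
    rt_sd_ms: float = 60.0
    rt_max_ms: float = 450.0
    floor_base: float = 0.25
    ceiling_base: float = 0.70
    sigmoid_center_ms: float = 125.0
    sigmoid_width_ms: float = 6.0
    color_gain_kappa: float = 0.7
    color_decay_trials: float = 5.0
    location_bias_kappa: float = 0.8
    location_decay_trials: float = 9.0
    interaction_strength: float = 0.0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 < self.floor_base < 1.0 or not 0.0 < self.ceiling_base < 1.0:
            raise ValueError("floor_base and ceiling_base must be in (0, 1)")
        if self.rt_sd_ms <= 0 or self.sigmoid_width_ms <= 0:
            raise ValueError("scale parameters must be positive")
        if self.color_decay_trials <= 0 or self.location_decay_trials <= 0:
            raise ValueError("decay constants must be positive")
        if not self.gap_values or min(self.gap_values) < 0:
            raise ValueError("gap_values must be non-negative and non-empty")

    def history_free(self) -> "GenerativeParams":
        """Copy with all history couplings switched off."""
        return replace(self, color_gain_kappa=0.0, location_bias_kappa=0.0,
                       interaction_strength=0.0)

    @property
    def guess_offset(self) -> float:
        """Logit offset on the target's guess weight giving ``floor_base``.

        Zero for the default chance level of 1/4; nonzero values tilt the
        structural guess toward (or away from) the target.
        """
        fb = self.floor_base
        return math.log(3.0 * fb / (1.0 - fb))


def _draw_primitives(params: GenerativeParams, rng: np.random.Generator
                     ) -> dict[str, np.ndarray]:
    n = params.n_trials
    a = (0.0 - params.rt_mean_ms) / params.rt_sd_ms
    b = (params.rt_max_ms - params.rt_mean_ms) / params.rt_sd_ms
    return {
        "color": rng.integers(0, 2, size=n),
        "quad": rng.integers(0, 4, size=n),
        "gap": rng.choice(np.asarray(params.gap_values, float), size=n),
        "rt": stats.truncnorm.rvs(a, b, loc=params.rt_mean_ms,
                                  scale=params.rt_sd_ms, size=n,
                                  random_state=rng),
        "u_arb": rng.random(n),
        "u_inf": rng.random(n),
        "u_guess": rng.random(n),
    }


def _choice_given_latents(target_quad: int, w: np.ndarray, q: float,
                          p_ceil: float, u_arb: float, u_inf: float,
                          u_guess: float, guess_offset: float) -> int:
    """Deterministic choice rule given latents and uniform draws."""
    if u_arb < q:  # informed route
        if u_inf < p_ceil:
            return target_quad
        others = [k for k in range(4) if k != target_quad]
        return others[min(int(u_guess * 3), 2)]
    z = w.astype(float).copy()
    z[target_quad] += guess_offset
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    return min(int((np.cumsum(p) <= u_guess).sum()), 3)


def generate_session(params: GenerativeParams,
                     subject_id: str = "sim",
                     session_id: str = "s000",
                     seed: int | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one session; returns (trial table, latent log).

    The latent log holds, per trial, the four guess weights and two color
    gains *before* the post-trial update, the informed-route probability
    ``q``, the informed accuracy ``p_ceil``, the three uniform draws the
    choice rule consumed, and the route taken.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    d = _draw_primitives(params, rng)
    n = params.n_trials
    pt = d["rt"] - d["gap"]
    q_all = special.expit((pt - params.sigmoid_center_ms)
                          / params.sigmoid_width_ms)

    eta_base = special.logit(params.ceiling_base)
    lam_w = math.exp(-1.0 / params.location_decay_trials)
    lam_g = math.exp(-1.0 / params.color_decay_trials)
    off = params.guess_offset

    history_free = (params.color_gain_kappa == 0.0
                    and params.location_bias_kappa == 0.0
                    and params.interaction_strength == 0.0)

    w = np.zeros(4)
    gain = np.zeros(2)
    choice = np.empty(n, dtype=int)
    lat = np.empty((n, 8))

    if history_free:
        # latents are identically zero: the whole session vectorizes
        p_ceil = special.expit(eta_base)
        informed = d["u_arb"] < q_all
        corr_inf = d["u_inf"] < p_ceil
        other_pick = np.minimum((d["u_guess"] * 3).astype(int), 2)
        others = np.array([[k for k in range(4) if k != t] for t in range(4)])
        z = np.zeros((n, 4))
        z[np.arange(n), d["quad"]] += off
        p = np.exp(z - z.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        guess_choice = (np.cumsum(p, axis=1)
                        <= d["u_guess"][:, None]).sum(axis=1).clip(0, 3)
        choice = np.where(
            informed,
            np.where(corr_inf, d["quad"], others[d["quad"], other_pick]),
            guess_choice)
        lat[:, 0:4] = 0.0
        lat[:, 4:6] = 0.0
        lat[:, 6] = q_all
        lat[:, 7] = p_ceil
    else:
        for t in range(n):
            tq = int(d["quad"][t])
            tc = int(d["color"][t])
            joint = gain[tc] * w[tq]
            p_ceil = special.expit(eta_base + gain[tc]
                                   + params.interaction_strength * joint)
            lat[t, 0:4] = w
            lat[t, 4:6] = gain
            lat[t, 6] = q_all[t]
            lat[t, 7] = p_ceil
            ch = _choice_given_latents(tq, w, q_all[t], p_ceil,
                                       d["u_arb"][t], d["u_inf"][t],
                                       d["u_guess"][t], off)
            choice[t] = ch
            sgn = 1.0 if ch == tq else -1.0
            w *= lam_w
            gain *= lam_g
            w[tq] += sgn * params.location_bias_kappa
            gain[tc] += sgn * params.color_gain_kappa

    correct = choice == d["quad"]
    trials = pd.DataFrame({
        "subject_id": subject_id,
        "session_id": session_id,
        "trial_index": np.arange(n),
        "gap_ms": d["gap"],
        "rt_ms": d["rt"],
        "pt_ms": pt,
        "target_color": np.asarray(COLORS)[d["color"]],
        "target_quadrant": np.asarray(QUADRANTS)[d["quad"]],
        "choice_quadrant": np.asarray(QUADRANTS)[choice],
        "correct": correct,
        "target_x_deg": np.nan,
        "target_y_deg": np.nan,
    })
    latents = pd.DataFrame(
        lat, columns=["w_right", "w_up", "w_left", "w_down",
                      "gain_red", "gain_green", "q", "p_ceil"])
    latents["u_arb"] = d["u_arb"]
    latents["u_inf"] = d["u_inf"]
    latents["u_guess"] = d["u_guess"]
    latents["informed"] = d["u_arb"] < q_all
    return trials, latents


def generate_trials(params: GenerativeParams, n_sessions: int = 1,
                    subject_id: str = "sim") -> pd.DataFrame:
    """Simulate ``n_sessions`` independent sessions and concatenate them.

    Per-session seeds are derived from ``params.seed`` (kept below 2**31),
    so the output is reproducible from the single top-level seed.
    """
    rng = np.random.default_rng(params.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_sessions)
    parts = []
    for i, s in enumerate(seeds):
        t, _ = generate_session(params, subject_id=subject_id,
                                session_id=f"s{i:03d}", seed=int(s))
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


def replay_choices(trials: pd.DataFrame, latents: pd.DataFrame,
                   params: GenerativeParams) -> np.ndarray:
    """Re-derive choices from the latent log; must match the emitted ones."""
    quad_code = {q: k for k, q in enumerate(QUADRANTS)}
    tq = trials["target_quadrant"].map(quad_code).to_numpy()
    out = np.empty(len(trials), dtype=int)
    wcols = ["w_right", "w_up", "w_left", "w_down"]
    W = latents[wcols].to_numpy()
    for t in range(len(trials)):
        out[t] = _choice_given_latents(
            int(tq[t]), W[t], float(latents["q"].iat[t]),
            float(latents["p_ceil"].iat[t]), float(latents["u_arb"].iat[t]),
            float(latents["u_inf"].iat[t]), float(latents["u_guess"].iat[t]),
            params.guess_offset)
    return out


def recover_parameters(trials: pd.DataFrame,
                       min_trials: int = 5000) -> SigmoidAccuracyResults:
    """Fit the history-free sigmoid accuracy model to a trial table.

    Thin wrapper over :class:`~oddsearch.psychometric.SigmoidAccuracyModel`
    enforcing a minimum sample size; the four recovered parameters
    (floor, ceiling, center, width) come with Wald CIs and boundary flags.
    """
    if len(trials) < min_trials:
        raise ValueError(f"need at least {min_trials} trials, "
                         f"got {len(trials)}")
    return SigmoidAccuracyModel.from_trials(trials).fit()
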