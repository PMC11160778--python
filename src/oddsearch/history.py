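"""Selection-history labeling of trials.

Each trial is classified post hoc by what happened on the preceding trials of
the same session, along three dimensions:

* **color** — did the preceding target(s) share the current trial's target
  color?  Letters ``S`` (same) / ``D`` (different).
* **location** — did the preceding target(s) land in the current trial's
  target quadrant?  Letters ``S`` / ``D`` (``D`` means *each* predecessor was
  elsewhere; the predecessors need not agree with one another).
* **outcome** — were the preceding trials correct (``C``) or errors (``E``)?
  Outcome letters describe the past trials themselves, not a relation to the
  current one.

Two labeling schemes are provided:

* ``run`` mode (:func:`classify_history`, :func:`classify_joint_history`):
  the *N* immediately preceding trials must form a homogeneous run (all S,
  all D, all C, or all E).  "At least N" semantics hold, so 2S trials are a
  subset of 1S trials.
* ``sequence`` mode (:func:`sequence_labels`): each of the *H* preceding
  trials carries its own letters, giving e.g. the 16 color-by-location
  sequences at H = 2.  The two schemes coincide at depth 1.

Histories never cross a session boundary: a trial with fewer than the
required within-session predecessors belongs to no condition.  Trials must be
in temporal order within each session (as produced by
:func:`oddsearch.trials.load_trials`).
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "classify_history",
    "classify_color_history",
    "classify_location_history",
    "classify_outcome_history",
    "classify_joint_history",
    "classify_single_event",
    "sequence_labels",
    "enumerate_sequences",
    "single_event_name",
]

DIMENSIONS = ("color", "location", "outcome")

_DIM_COLUMN = {
    "color": "target_color",
    "location": "target_quadrant",
    "outcome": "correct",
}
_ALPHABET = {"color": ("S", "D"), "location": ("S", "D"),
             "outcome": ("C", "E")}


def _session_groups(trials: pd.DataFrame) -> Iterable[np.ndarray]:
    """Positional index arrays of each session, in stored order."""
    keys = trials["subject_id"].astype(str) + "\x00" + trials["session_id"].astype(str)
    codes, _ = pd.factorize(keys, sort=False)
    order = np.arange(len(trials))
    for c in np.unique(codes):
        yield order[codes == c]


def _relation_letters(values: np.ndarray, dim: str, i: int, js: Sequence[int]) -> list[str]:
    """Letters of past trials ``js`` relative to current trial ``i``."""
    out = []
    for j in js:
        if dim == "outcome":
            out.append("C" if values[j] else "E")
        else:
            out.append("S" if values[j] == values[i] else "D")
    return out


def classify_history(trials: pd.DataFrame, dimension: str, N: int) -> pd.Series:
    """Run-mode history label per trial: homogeneous depth-``N`` runs.

    Returns a Series aligned with ``trials`` holding ``"S"``/``"D"`` (or
    ``"C"``/``"E"`` for the outcome dimension) where the *N* immediately
    preceding same-session trials all carry that letter relative to the
    current trial, and ``None`` otherwise (mixed runs, or fewer than *N*
    predecessors).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    col = _DIM_COLUMN[dimension]
    values = trials[col].to_numpy()
    labels = np.full(len(trials), None, dtype=object)
    for idx in _session_groups(trials):
        v = values[idx]
        for pos in range(N, len(idx)):
            letters = _relation_letters(v, dimension, pos,
                                        range(pos - N, pos))
            if len(set(letters)) == 1:
                labels[idx[pos]] = letters[0]
    return pd.Series(labels, index=trials.index, name=f"{N}{dimension}")


def classify_color_history(trials: pd.DataFrame, N: int) -> pd.Series:
    """NS/ND membership by target color (see :func:`classify_history`)."""
    return classify_history(trials, "color", N)


def classify_location_history(trials: pd.DataFrame, N: int) -> pd.Series:
    """NS/ND membership by target quadrant (see :func:`classify_history`)."""
    return classify_history(trials, "location", N)


def classify_outcome_history(trials: pd.DataFrame, N: int) -> pd.Series:
    """NC/NE membership by previous outcomes (see :func:`classify_history`)."""
    return classify_history(trials, "outcome", N)


def classify_joint_history(trials: pd.DataFrame, dims: Sequence[str],
                           N: int) -> pd.Series:
    """Conjunction of run-mode conditions over the same ``N``-trial window.

    The label concatenates the per-dimension letters in ``dims`` order, e.g.
    ``"SC"`` for same-color runs that were all rewarded (the 1SC / 2SC ...
    conditions) or ``"SSC"`` for the color+location+outcome triple.  ``None``
    where any dimension's run is inhomogeneous or too short.
    """
    dims = tuple(dims)
    if not dims:
        raise ValueError("dims must be non-empty")
    parts = [classify_history(trials, d, N) for d in dims]
    combined = []
    for row in zip(*[p.to_numpy() for p in parts]):
        combined.append(None if any(x is None for x in row) else "".join(row))
    return pd.Series(combined, index=trials.index,
                     name=f"{N}{'x'.join(dims)}")


def classify_single_event(trials: pd.DataFrame, dimension: str,
                          relation: str, lag: int) -> pd.Series:
    """Membership in the lagged single-event condition 1R(lag-1)x.

    A trial belongs iff the trial exactly ``lag`` positions earlier in the
    same session bears ``relation`` (``"S"``/``"D"``) to it; the ``lag - 1``
    intervening trials are unconstrained.  ``lag == 1`` reduces to the
    depth-1 run condition.  These conditions trace how a single repeat or
    switch decays over subsequent trials.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if dimension not in ("color", "location"):
        raise ValueError("single-event relations are defined for color/location")
    if relation not in ("S", "D"):
        raise ValueError("relation must be 'S' or 'D'")
    values = trials[_DIM_COLUMN[dimension]].to_numpy()
    member = np.zeros(len(trials), dtype=bool)
    for idx in _session_groups(trials):
        v = values[idx]
        for pos in range(lag, len(idx)):
            same = v[pos - lag] == v[pos]
            member[idx[pos]] = same if relation == "S" else not same
    return pd.Series(member, index=trials.index,
                     name=single_event_name(relation, lag))


def single_event_name(relation: str, lag: int) -> str:
    """Canonical name of a lagged single event, e.g. lag 5 S -> ``"1S4x"``."""
    return f"1{relation}" if lag == 1 else f"1{relation}{lag - 1}x"


def sequence_labels(trials: pd.DataFrame, dims: Sequence[str],
                    H: int) -> pd.Series:
    """Sequence-mode label: each of the ``H`` preceding trials letter-coded.

    The label lists the preceding trials oldest first; within each trial the
    letters follow ``dims`` order.  With dims (color, location) and H = 1 the
    four labels are SS, SD, DS, DD; at H = 2 there are 16.  ``None`` for
    trials with fewer than ``H`` within-session predecessors.
    """
    dims = tuple(dims)
    if H < 1:
        raise ValueError("H must be >= 1")
    if not dims:
        raise ValueError("dims must be non-empty")
    for d in dims:
        if d not in DIMENSIONS:
            raise ValueError(f"unknown dimension {d!r}")
    values = {d: trials[_DIM_COLUMN[d]].to_numpy() for d in dims}
    labels = np.full(len(trials), None, dtype=object)
    for idx in _session_groups(trials):
        v = {d: values[d][idx] for d in dims}
        for pos in range(H, len(idx)):
            letters = []
            for j in range(pos - H, pos):
                for d in dims:
                    letters.extend(_relation_letters(v[d], d, pos, [j]))
            labels[idx[pos]] = "".join(letters)
    return pd.Series(labels, index=trials.index,
                     name=f"{H}x{'x'.join(dims)}")


def enumerate_sequences(dims: Sequence[str], H: int) -> list[str]:
    """All sequence-mode labels for ``dims`` at history length ``H``.

    The count is ``(prod of per-dimension alphabet sizes) ** H``: 4 labels
    for color-by-location at H = 1, 16 at H = 2, 8 for the
    color-location-outcome triple at H = 1.
    """
    dims = tuple(dims)
    if H < 1:
        raise ValueError("H must be >= 1")
    per_trial = ["".join(p) for p in
                 itertools.product(*[_ALPHABET[d] for d in dims])]
    return ["".join(p) for p in itertools.product(per_trial, repeat=H)]
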