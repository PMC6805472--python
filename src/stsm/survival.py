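"""Survival step functions and the area between survival curves (ABS).

The survival function S(t) of a subgroup is estimated nonparametrically by the
Kaplan-Meier product-limit estimator from right-censored observations, giving
a right-continuous, non-increasing step function with S(0) = 1.

The signed Area Between Survival functions,

    ABS(T | S1, S2) = integral_0^T [S1(t) - S2(t)] dt,

is the elementary dissimilarity between two subgroups: it is computed exactly
as a sum of rectangles over the merged jump grid of both step functions,
truncated at a time horizon T.  The normalization area ABS_norm is the ABS
between the alive (censored) subgroup -- whose survival curve is constantly
1 -- and the deceased subgroup; no attribute can separate survival more
strongly than the survival status itself, so ABS_norm bounds the survival
impact scale used for attribute weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .casebase import CaseBase

__all__ = [
    "StepSurvivalFunction",
    "km_estimate",
    "survival_at",
    "abs_area",
    "abs_norm",
    "plot_abs",
]


@dataclass(frozen=True)
class StepSurvivalFunction:
    """Right-continuous non-increasing step function on [0, inf).

    The function is 1 on [0, first jump) and ``probs[i]`` on
    ``[jump_times[i], jump_times[i+1])``; beyond the last jump it stays at
    ``probs[-1]``.  With no jumps it is constantly 1.
    """

    jump_times: np.ndarray  # strictly increasing, >= 0
    probs: np.ndarray       # survival probability after each jump, in [0, 1]
    n_obs: int

    def __post_init__(self) -> None:
        jt = np.asarray(self.jump_times, dtype=float)
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "probs", p)
        if jt.shape != p.shape:
            raise ValueError("jump_times and probs must have equal length")
        if len(jt) and (np.any(np.diff(jt) <= 0) or jt[0] < 0):
            raise ValueError("jump_times must be strictly increasing and non-negative")
        if len(p) and (np.any(np.diff(p) > 0) or np.any(p < 0) or np.any(p > 1)):
            raise ValueError("probs must be non-increasing within [0, 1]")

    def __call__(self, t):
        return survival_at(self, t)


def _km_arrays(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimate as bare arrays (fast path for the cutoff scan)."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    # distinct observation times; at a tied time the deaths are evaluated with
    # everyone observed at that time still at risk (standard KM convention:
    # events before censorings at equal times)
    ut, first = np.unique(t, return_index=True)
    deaths = np.add.reduceat(e, first) if len(t) else np.array([])
    at_risk = len(t) - first
    has_death = deaths > 0
    jt = ut[has_death]
    surv = np.cumprod(1.0 - deaths[has_death] / at_risk[has_death])
    return jt, surv


def km_estimate(times, events) -> StepSurvivalFunction:
    """Kaplan-Meier product-limit estimate from right-censored observations.

    ``events[i] = 1`` means death observed at ``times[i]``, 0 means the case
    was censored then.  Jumps occur only at distinct event times; with no
    events at all the estimate is constantly 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one observation")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0 (censored) or 1 (death)")
    jt, surv = _km_arrays(times, events)
    return StepSurvivalFunction(jt, surv, n_obs=len(times))


def _eval_steps(jump_times: np.ndarray, probs: np.ndarray, t: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(jump_times, t, side="right")
    out = np.ones_like(t, dtype=float)
    nz = idx > 0
    out[nz] = probs[idx[nz] - 1]
    return out


def survival_at(S: StepSurvivalFunction, t):
    """Right-continuous evaluation of S at scalar or array ``t`` (t >= 0)."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("t must be non-negative")
    out = _eval_steps(S.jump_times, S.probs, np.atleast_1d(arr))
    return float(out[0]) if arr.ndim == 0 else out


def _area_between(jt1, p1, jt2, p2, T: float) -> float:
    grid = np.concatenate(([0.0], jt1[jt1 < T], jt2[jt2 < T], [T]))
    grid = np.unique(grid)
    left = grid[:-1]
    widths = np.diff(grid)
    s1 = _eval_steps(jt1, p1, left)
    s2 = _eval_steps(jt2, p2, left)
    return float(np.sum((s1 - s2) * widths))


def abs_area(S1: StepSurvivalFunction, S2: StepSurvivalFunction, T: float) -> float:
    """Signed area between two survival step functions on [0, T].

    Exact rectangle summation over the merged jump grid; antisymmetric under
    swapping the arguments (bit-exact, since each rectangle term negates
    exactly).  ``|abs_area| <= T`` always.
    """
    if T <= 0:
        raise ValueError("time horizon T must be positive")
    return _area_between(S1.jump_times, S1.probs, S2.jump_times, S2.probs, T)


def abs_norm(cb: "CaseBase", T: float) -> float:
    """Normalization area: ABS between the alive and the deceased subgroup.

    The alive (censored) subgroup has the constant-1 survival curve; the
    deceased subgroup's curve is its Kaplan-Meier estimate (all events).  The
    result is strictly positive and is the maximal survival impact any
    attribute of the case base could show.
    """
    events = cb.events
    times = cb.times
    if (events == 1).sum() == 0:
        raise ValueError("ABS_norm undefined: no deceased cases")
    if (events == 0).sum() == 0:
        raise ValueError("ABS_norm undefined: no alive (censored) cases")
    s_alive = km_estimate(times[events == 0], np.zeros((events == 0).sum(), dtype=int))
    s_dead = km_estimate(times[events == 1], np.ones((events == 1).sum(), dtype=int))
    return abs_area(s_alive, s_dead, T)


def plot_abs(S1: StepSurvivalFunction, S2: StepSurvivalFunction, T: float,
             labels: tuple[str, str] = ("group 1", "group 2"),
             path: str | None = None):
    """Plot two survival curves with the area between them shaded.

    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.unique(np.concatenate(([0.0], S1.jump_times, S2.jump_times, [T])))
    grid = grid[grid <= T]
    fine = np.union1d(grid, np.nextafter(grid, np.inf))
    y1 = survival_at(S1, fine)
    y2 = survival_at(S2, fine)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(fine, y1, where="post", label=labels[0])
    ax.step(fine, y2, where="post", label=labels[1])
    ax.fill_between(fine, y1, y2, step="post", alpha=0.3, color="grey",
                    label="ABS")
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability S(t)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
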