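"""Dichotomization of numeric attributes by the smoothed ABS-maximizing cutoff.

Survival curves can only be estimated per nominal value, so a numeric
attribute is converted into a two-level nominal one: every unique observed
value c (except the maximum) is tried as a cutoff, the case base is split
into the groups "value <= c" and "value > c", and the absolute area between
the two groups' survival curves is computed.  Raw |ABS| peaks at extreme
cutoffs, where one group holds only a handful of cases and its survival curve
degenerates into a few large steps; the weighting function

    WF(c) = (p (1 - p))^q,   p = #{value <= c} / #{values available},

down-weights those unbalanced splits (q = 0 disables smoothing; larger q
favours mid-range cutoffs).  The chosen cutoff maximizes WF(c) * |ABS(c)|,
ties broken by the smallest c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .casebase import AttributeSpec, CaseBase
from .survival import _area_between, _km_arrays

__all__ = [
    "CutoffResult",
    "candidate_cutoffs",
    "proportion_le",
    "weighting_function",
    "find_cutoff",
    "dichotomize",
    "cutoff_labels",
    "cutoff_scan",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CutoffResult:
    """Chosen dichotomization cutoff for one numeric attribute."""

    attribute: str
    cutoff: float
    abs_at_cutoff: float  # signed ABS between the <=c and >c groups at the horizon
    p: float              # proportion of non-missing values <= cutoff
    weighted_abs: float   # WF(cutoff) * |abs_at_cutoff|
    q: float              # smoothing exponent used


def candidate_cutoffs(values) -> np.ndarray:
    """Sorted distinct observed values, excluding the maximum.

    Excluding the maximum guarantees the "greater than c" group is never
    empty.  Raises for a constant attribute (nothing to dichotomize).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    uniq = np.unique(vals)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct values to dichotomize")
    return uniq[:-1]


def proportion_le(values, c: float) -> float:
    """Share of (non-missing) values that are <= c."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no values available")
    return float(np.mean(vals <= c))


def weighting_function(p: float, q: float) -> float:
    """Cutoff smoothing weight (p(1-p))^q; maximal at p = 0.5, 1 when q = 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if q < 0:
        raise ValueError("q must be >= 0")
    return float((p * (1.0 - p)) ** q)


def cutoff_scan(cb: CaseBase, attribute: str, T: float, q: float = 2.0) -> np.ndarray:
    """Per-candidate diagnostics for one numeric attribute.

    Returns a structured array with fields ``cutoff, abs, p, wf, weighted``
    (one row per candidate cutoff), the raw material behind the chosen cutoff
    and useful for diagnostic plots/tables.
    """
    spec = cb.spec(attribute)
    if spec.kind != "numeric":
        raise TypeError(f"attribute {attribute!r} is {spec.kind}, not numeric")
    vals = cb.df[attribute].to_numpy(dtype=float)
    keep = ~np.isnan(vals)
    vals = vals[keep]
    times = cb.times[keep]
    events = cb.events[keep]
    cands = candidate_cutoffs(vals)
    out = np.zeros(len(cands),
                   dtype=[("cutoff", float), ("abs", float), ("p", float),
                          ("wf", float), ("weighted", float)])
    for i, c in enumerate(cands):
        le = vals <= c
        jt1, p1 = _km_arrays(times[le], events[le])
        jt2, p2 = _km_arrays(times[~le], events[~le])
        a = _area_between(jt1, p1, jt2, p2, T)
        p = float(le.mean())
        wf = (p * (1.0 - p)) ** q
        out[i] = (c, a, p, wf, wf * abs(a))
    return out


def find_cutoff(cb: CaseBase, attribute: str, T: float, q: float = 2.0) -> CutoffResult:
    """Cutoff maximizing the smoothed |ABS| between the induced groups.

    Ties in the weighted ABS are broken by the smallest cutoff, so the result
    is deterministic and independent of record order.
    """
    scan = cutoff_scan(cb, attribute, T, q)
    best = int(np.argmax(scan["weighted"]))  # argmax returns the first (smallest c)
    row = scan[best]
    return CutoffResult(attribute=attribute, cutoff=float(row["cutoff"]),
                        abs_at_cutoff=float(row["abs"]), p=float(row["p"]),
                        weighted_abs=float(row["weighted"]), q=q)


def cutoff_labels(c: float) -> tuple[str, str]:
    """The two nominal labels a cutoff at c produces (for <=c and >c)."""
    return f"le_{c:g}", f"gt_{c:g}"


def dichotomize(cb: CaseBase, attribute: str, c: float) -> CaseBase:
    """Replace a numeric attribute by its two-level nominal version at cutoff c.

    Values <= c map to the first label of :func:`cutoff_labels`, values > c to
    the second; missing values stay missing.  The dichotomized attribute is
    thereafter an ordinary nominal attribute (re-running the cutoff search on
    it raises a type error).
    """
    spec = cb.spec(attribute)
    if spec.kind != "numeric":
        raise TypeError(f"attribute {attribute!r} is {spec.kind}, not numeric")
    vals = cb.df[attribute].to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size == 0 or not (finite.min() <= c < finite.max()):
        raise ValueError(
            f"cutoff {c} outside the observed value range "
            f"[{finite.min() if finite.size else 'NA'}, {finite.max() if finite.size else 'NA'})")
    lo, hi = cutoff_labels(c)
    col = np.where(np.isnan(vals), None, np.where(vals <= c, lo, hi))
    df = cb.df.copy()
    df[attribute] = col
    schema = [AttributeSpec(s.name, "nominal", s.positive_label)
              if s.name == attribute else s for s in cb.schema]
    return CaseBase(schema, df, check=False)
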