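"""Benchmark similarity measures: HEOM, DVDM and uniform random pick.

These are the standard heterogeneous-data distance functions the STSM is
compared against:

* HEOM (Heterogeneous Euclidean-Overlap Metric): overlap distance on nominal
  attributes (0 if equal, 1 otherwise), range-normalized absolute difference
  on numeric attributes, unknown values at maximal distance 1, Euclidean
  aggregation across attributes.
* DVDM (Discretized Value Difference Metric, Wilson & Martinez): numeric
  attributes are binned into a fixed number of equal-width intervals over the
  training range; each value's distance to another is the summed squared
  difference of class-conditional probabilities P(class | value); Euclidean
  aggregation across attributes.  With a randomized class attribute (a
  therapy arm) the conditional probabilities carry almost no signal, which is
  exactly the failure mode the benchmark exposes.
* random pick: k candidates drawn uniformly without replacement.

Each measure exposes a retriever with the same interface as
:class:`stsm.similarity.STSMRetriever`, so the evaluation harness treats all
measures uniformly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .casebase import CaseBase, CaseRecord
from .similarity import RetrievalResult, _top_k

__all__ = [
    "NumericRanges",
    "numeric_ranges",
    "heom_distance",
    "HeomRetriever",
    "DvdmModel",
    "dvdm_train",
    "dvdm_distance",
    "DvdmRetriever",
    "random_retrieve",
    "RandomRetriever",
]

log = logging.getLogger(__name__)

NumericRanges = dict[str, tuple[float, float]]


def _is_missing(v: object) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def numeric_ranges(cb: CaseBase) -> NumericRanges:
    """Observed (min, max) per numeric attribute in the training case base."""
    out: NumericRanges = {}
    for s in cb.descriptive:
        if s.kind == "numeric":
            col = cb.df[s.name].to_numpy(dtype=float)
            col = col[~np.isnan(col)]
            if col.size:
                out[s.name] = (float(col.min()), float(col.max()))
    return out


# ---------------------------------------------------------------------------
# HEOM
# ---------------------------------------------------------------------------

def heom_distance(c1: CaseRecord, c2: CaseRecord, ranges: NumericRanges) -> float:
    """HEOM distance between two records sharing a schema.

    Per attribute: unknown in either record -> 1; nominal -> overlap (0 if
    equal else 1); numeric -> |v1 - v2| / range, capped at 1 for values
    outside the training range.  Aggregated by the Euclidean norm.
    """
    total = 0.0
    attrs = set(c1.values) | set(c2.values)
    for a in attrs:
        v1, v2 = c1.value(a), c2.value(a)
        if _is_missing(v1) or _is_missing(v2):
            d = 1.0
        elif a in ranges:
            lo, hi = ranges[a]
            if hi == lo:
                if v1 != v2:
                    log.warning("zero range for %r with differing values", a)
                    d = 1.0
                else:
                    d = 0.0
            else:
                d = min(abs(float(v1) - float(v2)) / (hi - lo), 1.0)
        else:
            d = 0.0 if v1 == v2 else 1.0
        total += d * d
    return math.sqrt(total)


class HeomRetriever:
    """Vectorized HEOM retrieval: one accumulated squared-distance matrix."""

    higher_is_better = False

    def __init__(self, cb: CaseBase):
        self.cb = cb
        self.ids = cb.ids
        self.id_rank = np.argsort(np.argsort(self.ids.astype(str)))
        self.ranges = numeric_ranges(cb)
        n = cb.n_cases
        d2 = np.zeros((n, n))
        for s in cb.descriptive:
            if s.kind == "numeric":
                x = cb.df[s.name].to_numpy(dtype=float)
                lo, hi = self.ranges.get(s.name, (0.0, 0.0))
                span = hi - lo
                if span == 0:
                    d = (x[:, None] != x[None, :]).astype(float)
                else:
                    d = np.minimum(np.abs(x[:, None] - x[None, :]) / span, 1.0)
                miss = np.isnan(x)
                d[miss, :] = 1.0
                d[:, miss] = 1.0
            else:
                v = cb.df[s.name].to_numpy(dtype=object)
                miss = np.array([_is_missing(x) for x in v])
                d = (v[:, None] != v[None, :]).astype(float)
                d[miss, :] = 1.0
                d[:, miss] = 1.0
            d2 += d * d
        self._dist = np.sqrt(d2)

    def scores(self, query_index: int) -> np.ndarray:
        return self._dist[query_index]

    def neighbor_indices(self, query_index: int, k: int) -> np.ndarray:
        return _top_k(self._dist[query_index], False, query_index, k, self.id_rank)

    def retrieve(self, query_id: str, k: int) -> RetrievalResult:
        qi = self.cb.index_of(query_id)
        if k >= self.cb.n_cases:
            raise ValueError("k must be smaller than the case-base size")
        idx = self.neighbor_indices(qi, k)
        d = self._dist[qi]
        return RetrievalResult(query_id, [(str(self.ids[i]), float(d[i])) for i in idx])

    def neighbor_matrix(self, k: int) -> np.ndarray:
        n = self.cb.n_cases
        out = np.empty((n, k), dtype=np.intp)
        for i in range(n):
            out[i] = self.neighbor_indices(i, k)
        return out


# ---------------------------------------------------------------------------
# DVDM
# ---------------------------------------------------------------------------

@dataclass
class DvdmModel:
    """Class-conditional probability tables for the discretized VDM."""

    class_attribute: str
    classes: list[str]
    n_intervals: int
    bin_edges: dict[str, np.ndarray]          # numeric attribute -> interior edges
    prob: dict[str, dict[object, np.ndarray]]  # attr -> value/bin -> P(class | value)


def _dvdm_code(model: DvdmModel, attribute: str, value: object):
    """Map a raw value to the model's nominal value or bin index (None if missing)."""
    if _is_missing(value):
        return None
    if attribute in model.bin_edges:
        return int(np.searchsorted(model.bin_edges[attribute], float(value),
                                   side="right"))
    return str(value)


def dvdm_train(cb: CaseBase, class_attribute: str,
               n_intervals: int = 5) -> DvdmModel:
    """Estimate P(class | value) tables; numerics binned equal-width.

    The class attribute must be nominal (or the arm column) with >= 2
    observed classes.  Each numeric attribute is cut into ``n_intervals``
    equal-width bins over its observed training range; probabilities are
    relative frequencies among the cases carrying the value/bin.
    """
    if n_intervals < 2:
        raise ValueError("n_intervals must be >= 2")
    cols = {s.name for s in cb.schema}
    if class_attribute not in cols:
        raise ValueError(f"class attribute {class_attribute!r} not in schema")
    cls_col = cb.df[class_attribute]
    classes = sorted(cls_col.dropna().astype(str).unique())
    if len(classes) < 2:
        raise ValueError("class attribute must have at least 2 observed classes")
    cls_idx = {c: i for i, c in enumerate(classes)}
    y = cls_col.astype(str).map(cls_idx).to_numpy()

    bin_edges: dict[str, np.ndarray] = {}
    prob: dict[str, dict[object, np.ndarray]] = {}
    for s in cb.descriptive:
        if s.name == class_attribute:
            continue
        if s.kind == "numeric":
            x = cb.df[s.name].to_numpy(dtype=float)
            finite = x[~np.isnan(x)]
            if finite.size == 0:
                continue
            lo, hi = float(finite.min()), float(finite.max())
            # interior edges; values land in bins 0..n_intervals-1 via searchsorted
            edges = np.linspace(lo, hi, n_intervals + 1)[1:-1]
            bin_edges[s.name] = edges
            codes = np.where(np.isnan(x), -1,
                             np.searchsorted(edges, x, side="right"))
        else:
            v = cb.df[s.name].to_numpy(dtype=object)
            codes = np.array([str(x) if not _is_missing(x) else -1 for x in v],
                             dtype=object)
        table: dict[object, np.ndarray] = {}
        for code in set(codes[np.array([c != -1 for c in codes])]):
            mask = codes == code
            counts = np.bincount(y[mask], minlength=len(classes)).astype(float)
            table[code] = counts / counts.sum()
        prob[s.name] = table
    return DvdmModel(class_attribute, classes, n_intervals, bin_edges, prob)


def _dvdm_attr_distance(model: DvdmModel, attribute: str,
                        v1: object, v2: object) -> float:
    c1 = _dvdm_code(model, attribute, v1)
    c2 = _dvdm_code(model, attribute, v2)
    if c1 is None or c2 is None:
        return 0.0  # unknown values treated as maximally similar
    if c1 == c2:
        return 0.0
    tab = model.prob.get(attribute, {})
    p1 = tab.get(c1)
    p2 = tab.get(c2)
    if p1 is None or p2 is None:
        return 0.0
    return float(np.sum((p1 - p2) ** 2))


def dvdm_distance(model: DvdmModel, c1: CaseRecord, c2: CaseRecord) -> float:
    """Euclidean aggregation of per-attribute squared class-probability distances."""
    total = 0.0
    for a in model.prob:
        d = _dvdm_attr_distance(model, a, c1.value(a), c2.value(a))
        total += d * d
    return math.sqrt(total)


class DvdmRetriever:
    """Vectorized DVDM retrieval via per-attribute pairwise distance tables."""

    higher_is_better = False

    def __init__(self, cb: CaseBase, class_attribute: str | None = None,
                 n_intervals: int = 5):
        if class_attribute is None:
            class_attribute = cb.arm_column
            if class_attribute is None:
                raise ValueError("no arm column; specify class_attribute")
        self.cb = cb
        self.ids = cb.ids
        self.id_rank = np.argsort(np.argsort(self.ids.astype(str)))
        self.model = dvdm_train(cb, class_attribute, n_intervals)
        n = cb.n_cases
        d2 = np.zeros((n, n))
        for a, tab in self.model.prob.items():
            values = list(tab)
            lut = {v: i for i, v in enumerate(values)}
            codes = np.array(
                [lut.get(_dvdm_code(self.model, a, v), len(values))
                 for v in cb.df[a].to_numpy(dtype=object)], dtype=np.intp)
            V = len(values)
            pm = np.zeros((V + 1, V + 1))
            P = np.stack([tab[v] for v in values]) if V else np.zeros((0, 0))
            for i in range(V):
                diff = np.sum((P - P[i]) ** 2, axis=1)
                pm[i, :V] = diff
            # row/col V is the unknown slot: distance 0 against everything
            d = pm[codes[:, None], codes[None, :]]
            d2 += d * d
        self._dist = np.sqrt(d2)

    def scores(self, query_index: int) -> np.ndarray:
        return self._dist[query_index]

    def neighbor_indices(self, query_index: int, k: int) -> np.ndarray:
        return _top_k(self._dist[query_index], False, query_index, k, self.id_rank)

    def retrieve(self, query_id: str, k: int) -> RetrievalResult:
        qi = self.cb.index_of(query_id)
        if k >= self.cb.n_cases:
            raise ValueError("k must be smaller than the case-base size")
        idx = self.neighbor_indices(qi, k)
        d = self._dist[qi]
        return RetrievalResult(query_id, [(str(self.ids[i]), float(d[i])) for i in idx])

    def neighbor_matrix(self, k: int) -> np.ndarray:
        n = self.cb.n_cases
        out = np.empty((n, k), dtype=np.intp)
        for i in range(n):
            out[i] = self.neighbor_indices(i, k)
        return out


# ---------------------------------------------------------------------------
# random pick
# ---------------------------------------------------------------------------

class RandomRetriever:
    """Uniform random retrieval (without replacement), reproducible per seed."""

    higher_is_better = True

    def __init__(self, cb: CaseBase, seed: int | np.random.Generator = 0):
        self.cb = cb
        self.ids = cb.ids
        self.rng = (seed if isinstance(seed, np.random.Generator)
                    else np.random.default_rng(seed))

    def neighbor_indices(self, query_index: int, k: int) -> np.ndarray:
        n = self.cb.n_cases
        pool = np.delete(np.arange(n), query_index)
        return self.rng.choice(pool, size=k, replace=False)

    def retrieve(self, query_id: str, k: int) -> RetrievalResult:
        qi = self.cb.index_of(query_id)
        if k >= self.cb.n_cases:
            raise ValueError("k must be smaller than the case-base size")
        idx = self.neighbor_indices(qi, k)
        return RetrievalResult(query_id, [(str(self.ids[i]), 0.0) for i in idx])

    def neighbor_matrix(self, k: int) -> np.ndarray:
        n = self.cb.n_cases
        out = np.empty((n, k), dtype=np.intp)
        for i in range(n):
            out[i] = self.neighbor_indices(i, k)
        return out


def random_retrieve(cb: CaseBase, query_id: str, k: int,
                    seed: int = 0) -> RetrievalResult:
    """k candidates drawn uniformly without replacement, excluding the query."""
    return RandomRetriever(cb, seed).retrieve(query_id, k)
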