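"""Training and application of the survival-time-based similarity measure (STSM).

Training (on a case base with survival outcomes):

* numeric attributes are dichotomized at their smoothed ABS-maximizing cutoff
  and thereafter treated as nominal;
* for every value of every attribute a Kaplan-Meier survival curve is fitted
  over the cases carrying that value;
* the local similarity of two values v, v* of one attribute is
  ``exp(-|ABS(T | v, v*)|)``, the exponentially mapped area between their
  survival curves (1 for identical values, lower for survival-discriminating
  pairs, 1 whenever either value is unknown);
* each attribute's weight is its maximal pairwise |ABS| divided by ABS_norm,
  the area between the alive and deceased subgroups -- the strongest survival
  separation the case base admits;
* attributes whose weight falls below a configurable threshold are dropped
  (feature selection; off by default).

Retrieval aggregates the local similarities of two cases into the global score

    sim_global(c, c*) = sqrt( sum_i (w_i * sim_local_i)^2 ).

Because the local similarities already encode survival impact, the survival
weights default to w_i = 1 inside this formula (using them there would count
survival twice); the computed weights drive feature selection and reporting,
and can be switched on for use with non-survival local measures.

By default times are rescaled by the horizon T before the exponential map, so
|ABS| lies in [0, 1] regardless of the time unit; without this, areas measured
in days would be of order 10^2-10^3 and exp(-|ABS|) would collapse to zero for
every distinct pair.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .casebase import AttributeSpec, CaseBase, CaseRecord, pool_rare_values
from .nominalize import CutoffResult, cutoff_labels, dichotomize, find_cutoff
from .survival import StepSurvivalFunction, abs_area, abs_norm, km_estimate

__all__ = [
    "ModelConfig",
    "LocalSimilarityTable",
    "SimilarityModel",
    "RetrievalResult",
    "train",
    "local_similarity",
    "attribute_weight",
    "select_features",
    "global_similarity",
    "retrieve",
    "STSMRetriever",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Training/retrieval configuration.

    ``q`` is the cutoff-smoothing exponent; ``normalize_time`` rescales areas
    by 1/T before the exponential map (recommended; see module docstring);
    ``use_weights_in_global`` injects the survival weights into the global
    formula (off by default -- survival would count twice);
    ``normalize_global`` divides the global score by sqrt(sum w_i^2) so
    identical cases score exactly 1; ``feature_threshold`` drops attributes
    with weight below it; ``min_value_count`` pools rarer nominal values
    before training (1 = off).
    """

    q: float = 2.0
    normalize_time: bool = True
    use_weights_in_global: bool = False
    normalize_global: bool = False
    feature_threshold: float = 0.0
    min_value_count: int = 1
    T: float | None = None  # None: the maximum observed time in training data


@dataclass
class LocalSimilarityTable:
    """Symmetric value-pair similarity lookup for one attribute."""

    attribute: str
    values: list[str]
    sim: np.ndarray        # (V, V) similarities in (0, 1], diagonal 1
    abs_matrix: np.ndarray  # (V, V) signed pairwise ABS (raw time units)

    def similarity(self, v1: str, v2: str) -> float:
        i = self.values.index(v1)
        j = self.values.index(v2)
        return float(self.sim[i, j])


@dataclass
class RetrievalResult:
    """Ranked nearest cases for one query (scores non-increasing)."""

    query_id: str
    neighbors: list[tuple[str, float]]

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.neighbors]

    @property
    def scores(self) -> list[float]:
        return [s for _, s in self.neighbors]


@dataclass
class SimilarityModel:
    """Trained STSM artifact: curves, similarity tables, weights, cutoffs."""

    schema: list[AttributeSpec]
    config: ModelConfig
    T: float
    abs_norm_: float
    cutoffs: dict[str, CutoffResult]
    survival_functions: dict[str, dict[str, StepSurvivalFunction]]
    tables: dict[str, LocalSimilarityTable]
    weights: dict[str, float]
    retained: list[str]
    excluded: list[str] = field(default_factory=list)

    # -- value handling -----------------------------------------------------

    def _as_label(self, attribute: str, value: object) -> str | None:
        """Map a raw value to the trained nominal label (None if unknown/missing)."""
        if value is None:
            return None
        if isinstance(value, float) and math.isnan(value):
            return None
        if attribute in self.cutoffs:
            try:
                v = float(value)  # raw numeric value: route through the cutoff
            except (TypeError, ValueError):
                label = str(value)
            else:
                lo, hi = cutoff_labels(self.cutoffs[attribute].cutoff)
                return lo if v <= self.cutoffs[attribute].cutoff else hi
        else:
            label = str(value)
        return label

    def to_dict(self) -> dict:
        return {
            "schema": [asdict(s) for s in self.schema],
            "config": asdict(self.config),
            "T": self.T,
            "abs_norm": self.abs_norm_,
            "cutoffs": {a: asdict(c) for a, c in self.cutoffs.items()},
            "survival_functions": {
                a: {v: {"jump_times": S.jump_times.tolist(),
                        "probs": S.probs.tolist(), "n_obs": S.n_obs}
                    for v, S in per_value.items()}
                for a, per_value in self.survival_functions.items()},
            "tables": {a: {"values": t.values, "sim": t.sim.tolist(),
                           "abs": t.abs_matrix.tolist()}
                       for a, t in self.tables.items()},
            "weights": self.weights,
            "retained": self.retained,
            "excluded": self.excluded,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "SimilarityModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            schema=[AttributeSpec(**s) for s in d["schema"]],
            config=ModelConfig(**d["config"]),
            T=d["T"],
            abs_norm_=d["abs_norm"],
            cutoffs={a: CutoffResult(**c) for a, c in d["cutoffs"].items()},
            survival_functions={
                a: {v: StepSurvivalFunction(np.array(s["jump_times"]),
                                            np.array(s["probs"]), s["n_obs"])
                    for v, s in per.items()}
                for a, per in d["survival_functions"].items()},
            tables={a: LocalSimilarityTable(a, t["values"],
                                            np.array(t["sim"], dtype=float),
                                            np.array(t["abs"], dtype=float))
                    for a, t in d["tables"].items()},
            weights=d["weights"],
            retained=d["retained"],
            excluded=d.get("excluded", []),
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(cb: CaseBase, config: ModelConfig | None = None) -> SimilarityModel:
    """Train the STSM: dichotomize, fit curves, build tables, weight, select."""
    config = config or ModelConfig()
    if cb.n_cases < 2:
        raise ValueError("training requires at least 2 cases")
    if (cb.events == 1).sum() == 0 or (cb.events == 0).sum() == 0:
        raise ValueError("training requires at least one deceased and one alive case")

    work = cb
    if config.min_value_count > 1:
        work = pool_rare_values(work, config.min_value_count)

    T = config.T if config.T is not None else float(work.times.max())
    if T <= 0:
        raise ValueError("time horizon T must be positive")

    cutoffs: dict[str, CutoffResult] = {}
    excluded: list[str] = []
    for spec in list(work.descriptive):
        if spec.kind != "numeric":
            continue
        vals = work.df[spec.name].to_numpy(dtype=float)
        if len(np.unique(vals[~np.isnan(vals)])) < 2:
            log.warning("attribute %r is constant; excluded from the model", spec.name)
            excluded.append(spec.name)
            continue
        res = find_cutoff(work, spec.name, T, config.q)
        cutoffs[spec.name] = res
        work = dichotomize(work, spec.name, res.cutoff)

    norm_area = abs_norm(work, T)
    scale = T if config.normalize_time else 1.0

    survs: dict[str, dict[str, StepSurvivalFunction]] = {}
    tables: dict[str, LocalSimilarityTable] = {}
    weights: dict[str, float] = {}
    times, events = work.times, work.events
    for spec in work.descriptive:
        if spec.name in excluded:
            continue
        col = work.df[spec.name]
        observed = col.dropna().astype(str)
        values = sorted(observed.unique())
        if len(values) < 2:
            log.warning("attribute %r has <2 observed values; excluded", spec.name)
            excluded.append(spec.name)
            continue
        per_value: dict[str, StepSurvivalFunction] = {}
        for v in values:
            mask = (col.astype(str) == v) & col.notna().to_numpy()
            per_value[v] = km_estimate(times[mask.to_numpy()], events[mask.to_numpy()])
        V = len(values)
        amat = np.zeros((V, V))
        for i in range(V):
            for j in range(i + 1, V):
                a = abs_area(per_value[values[i]], per_value[values[j]], T)
                amat[i, j] = a
                amat[j, i] = -a
        sim = np.exp(-np.abs(amat) / scale)
        np.fill_diagonal(sim, 1.0)
        survs[spec.name] = per_value
        tables[spec.name] = LocalSimilarityTable(spec.name, values, sim, amat)
        w = float(np.max(np.abs(amat)) / norm_area)
        if w > 1.0:
            log.warning("attribute %r has weight %.3f > 1 (subgroup separates "
                        "survival more than the pooled status split)", spec.name, w)
        weights[spec.name] = w

    retained = [a for a in tables if weights[a] >= config.feature_threshold]
    if not retained:
        log.warning("feature threshold %.3g removed every attribute",
                    config.feature_threshold)
    return SimilarityModel(schema=list(cb.schema), config=config, T=T,
                           abs_norm_=norm_area, cutoffs=cutoffs,
                           survival_functions=survs, tables=tables,
                           weights=weights, retained=retained, excluded=excluded)


# ---------------------------------------------------------------------------
# similarity queries
# ---------------------------------------------------------------------------

def local_similarity(model: SimilarityModel, attribute: str,
                     v1: object, v2: object) -> float:
    """Local similarity of two values of one attribute, in (0, 1].

    1 if either value is unknown/missing, 1 for equal values, otherwise the
    trained ``exp(-|ABS|)`` table entry.  A value never seen in training is
    treated as unknown (similarity 1) with a logged warning.
    """
    if attribute not in model.tables:
        raise KeyError(f"attribute {attribute!r} is not part of the trained model")
    l1 = model._as_label(attribute, v1)
    l2 = model._as_label(attribute, v2)
    if l1 is None or l2 is None:
        return 1.0
    table = model.tables[attribute]
    for lab in (l1, l2):
        if lab not in table.values:
            log.warning("value %r of attribute %r was never seen in training; "
                        "treated as unknown", lab, attribute)
            return 1.0
    if l1 == l2:
        return 1.0
    return table.similarity(l1, l2)


def attribute_weight(model: SimilarityModel, attribute: str) -> float:
    """Survival-impact weight: max pairwise |ABS| over ABS_norm (>= 0)."""
    if attribute not in model.weights:
        raise KeyError(f"attribute {attribute!r} is not part of the trained model")
    return model.weights[attribute]


def select_features(model: SimilarityModel, threshold: float) -> list[str]:
    """Attributes with weight >= threshold, in schema order."""
    order = [s.name for s in model.schema]
    kept = [a for a in order if a in model.weights and model.weights[a] >= threshold]
    if not kept:
        log.warning("threshold %.3g exceeds every attribute weight", threshold)
    return kept


def _effective_weights(model: SimilarityModel) -> dict[str, float]:
    if model.config.use_weights_in_global:
        return {a: model.weights[a] for a in model.retained}
    return {a: 1.0 for a in model.retained}


def global_similarity(model: SimilarityModel, c1: CaseRecord, c2: CaseRecord) -> float:
    """Euclidean aggregation of weighted local similarities over retained attributes."""
    w = _effective_weights(model)
    total = 0.0
    for a in model.retained:
        s = local_similarity(model, a, c1.value(a), c2.value(a))
        total += (w[a] * s) ** 2
    score = math.sqrt(total)
    if model.config.normalize_global:
        denom = math.sqrt(sum(v * v for v in w.values()))
        score = score / denom if denom > 0 else 0.0
    return score


# ---------------------------------------------------------------------------
# retrieval
# ---------------------------------------------------------------------------

class STSMRetriever:
    """Vectorized k-nearest retrieval under a trained model.

    Encodes every case's retained attribute values as indices into padded
    per-attribute similarity tables once, so scoring a query against the whole
    case base is a single table gather.
    """

    higher_is_better = True

    def __init__(self, model: SimilarityModel, cb: CaseBase):
        self.model = model
        self.cb = cb
        self.ids = cb.ids
        self.id_rank = np.argsort(np.argsort(self.ids.astype(str)))
        attrs = model.retained
        self._attrs = attrs
        n, p = cb.n_cases, len(attrs)
        vmax = max((len(model.tables[a].values) for a in attrs), default=0)
        # index vmax is the "unknown" slot: similarity 1 against everything
        tables = np.ones((p, vmax + 1, vmax + 1))
        codes = np.full((n, p), vmax, dtype=np.intp)
        for j, a in enumerate(attrs):
            t = model.tables[a]
            V = len(t.values)
            tables[j, :V, :V] = t.sim
            tables[j, :V, V] = 1.0
            tables[j, V, :V] = 1.0
            lut = {v: i for i, v in enumerate(t.values)}
            col = cb.df[a]
            for i, raw in enumerate(col.to_numpy(dtype=object)):
                lab = model._as_label(a, raw)
                codes[i, j] = lut.get(lab, vmax) if lab is not None else vmax
        self._tables = tables
        self._codes = codes
        w = _effective_weights(model)
        self._w = np.array([w[a] for a in attrs])
        self._denom = math.sqrt(float((self._w ** 2).sum())) or 1.0

    def scores(self, query_index: int) -> np.ndarray:
        """Global similarity of the query case against every case (incl. itself)."""
        p = len(self._attrs)
        if p == 0:
            return np.zeros(len(self.ids))
        sel = self._tables[np.arange(p)[None, :],
                           self._codes[query_index][None, :],
                           self._codes]
        g = np.sqrt(((self._w * sel) ** 2).sum(axis=1))
        if self.model.config.normalize_global:
            g = g / self._denom
        return g

    def neighbor_indices(self, query_index: int, k: int) -> np.ndarray:
        s = self.scores(query_index)
        return _top_k(s, True, query_index, k, self.id_rank)

    def retrieve(self, query_id: str, k: int) -> RetrievalResult:
        qi = self.cb.index_of(query_id)
        if k >= self.cb.n_cases:
            raise ValueError("k must be smaller than the case-base size")
        idx = self.neighbor_indices(qi, k)
        s = self.scores(qi)
        return RetrievalResult(query_id, [(str(self.ids[i]), float(s[i])) for i in idx])

    def neighbor_matrix(self, k: int) -> np.ndarray:
        """(n, k) neighbor row indices for every case as query (leave-one-out)."""
        n = self.cb.n_cases
        out = np.empty((n, k), dtype=np.intp)
        for i in range(n):
            out[i] = self.neighbor_indices(i, k)
        return out


def _top_k(score: np.ndarray, higher_is_better: bool, self_index: int | None,
           k: int, id_rank: np.ndarray) -> np.ndarray:
    """Best-k indices; ties broken by ascending case id; query excluded."""
    key = -score if higher_is_better else score
    order = np.lexsort((id_rank, key))
    if self_index is not None:
        order = order[order != self_index]
    return order[:k]


def retrieve(model: SimilarityModel, cb: CaseBase, query_id: str,
             k: int) -> RetrievalResult:
    """The k most similar cases to ``query_id`` (the query itself excluded)."""
    return STSMRetriever(model, cb).retrieve(query_id, k)
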