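"""Biomarker-detection evaluation harness and weight reporting.

The central question: do the k most similar cases of a query share the
query's biomarker status?  For each case base, a similarity model is trained
once on the full case base; then every case in turn acts as query and its k
nearest neighbors (query excluded; urn model -- the case base is never
depleted) are retrieved.  For every biomarker attribute, all
(query status, neighbor status) pairs are pooled into a confusion table with
"biomarker present" as the positive class, from which accuracy, precision,
recall and F1 follow.  Means and sample SDs are taken across repeated
independently generated case bases.

Biomarker status comes from the generator's ground truth (mode membership for
the numeric biomarkers), never from the model's own learned cutoff, so the
evaluation cannot reward a model with its own discretization.

The weight report summarizes the trained survival-impact weights per
iteration: average over all attributes, over noise attributes only, and per
biomarker with the relative difference to the all-attribute average (weights
scaled by 10 for readability, which cancels in every ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .casebase import CaseBase
from .comparators import DvdmRetriever, HeomRetriever, RandomRetriever
from .datagen import GroundTruth
from .similarity import ModelConfig, SimilarityModel, STSMRetriever, train

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "WeightReport",
    "make_retriever",
    "loocv_biomarker_detection",
    "summarize",
    "weight_report",
    "benchmark_suite",
    "MEASURES",
]

MEASURES = ("stsm", "heom", "dvdm", "random")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled (query status, neighbor status) counts; positive = present."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if np.isnan(p) or np.isnan(r) or (p + r) == 0:
            return float("nan")
        return 2 * p * r / (p + r)


def make_retriever(measure: str, cb: CaseBase, *,
                   model: SimilarityModel | None = None,
                   config: ModelConfig | None = None,
                   seed: int = 0, n_intervals: int = 5):
    """Build the retriever for one of the benchmark measures.

    For ``stsm`` a pre-trained model may be passed; otherwise one is trained
    on the full case base.  ``dvdm`` uses the (randomized) therapy arm as its
    class attribute; ``random`` is seeded for reproducibility.
    """
    if measure == "stsm":
        if model is None:
            model = train(cb, config)
        return STSMRetriever(model, cb)
    if measure == "heom":
        return HeomRetriever(cb)
    if measure == "dvdm":
        return DvdmRetriever(cb, n_intervals=n_intervals)
    if measure == "random":
        return RandomRetriever(cb, seed)
    raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")


def loocv_biomarker_detection(cb: CaseBase, truth: GroundTruth, measure="stsm",
                              k: int = 10, *, model: SimilarityModel | None = None,
                              config: ModelConfig | None = None,
                              seed: int = 0) -> dict[str, ConfusionCounts]:
    """Leave-one-out biomarker matching under one similarity measure.

    ``measure`` is a name from :data:`MEASURES` or an already-built retriever
    object.  Returns per-biomarker pooled confusion counts; each table totals
    ``n_cases * k`` exactly.
    """
    if k >= cb.n_cases:
        raise ValueError("k must be smaller than the case-base size")
    retriever = (measure if not isinstance(measure, str)
                 else make_retriever(measure, cb, model=model, config=config,
                                     seed=seed))
    nbrs = retriever.neighbor_matrix(k)  # (n, k) row indices
    out: dict[str, ConfusionCounts] = {}
    for bm in truth.biomarkers:
        status = truth.status(bm)
        q = np.repeat(status[:, None], k, axis=1)
        nb = status[nbrs]
        out[bm] = ConfusionCounts(
            tp=int(np.sum(q & nb)), fp=int(np.sum(~q & nb)),
            fn=int(np.sum(q & ~nb)), tn=int(np.sum(~q & ~nb)))
    return out


@dataclass
class EvaluationReport:
    """Per-measure, per-biomarker mean (SD) metrics over repeated case bases."""

    table: pd.DataFrame  # index (measure, biomarker); columns metric_mean/metric_sd
    raw_counts: dict[str, list[dict[str, ConfusionCounts]]]

    def mean_accuracy(self, measure: str, biomarker: str) -> float:
        return float(self.table.loc[(measure, biomarker), "accuracy_mean"])


_METRICS = ("accuracy", "precision", "recall", "f1")


def summarize(counts: dict[str, list[dict[str, ConfusionCounts]]]) -> EvaluationReport:
    """Aggregate per-case-base confusion counts into a mean/SD table.

    ``counts[measure]`` is a list (one entry per case base) of per-biomarker
    :class:`ConfusionCounts`.  Metrics are computed per case base and then
    averaged; the SD is the sample standard deviation across case bases (0
    for a single case base).  Undefined precision/recall (zero denominator)
    is excluded from the mean.
    """
    rows = []
    for measure, per_cb in counts.items():
        if not per_cb:
            raise ValueError(f"no case bases for measure {measure!r}")
        biomarkers = list(per_cb[0])
        for bm in biomarkers:
            row: dict[str, object] = {"measure": measure, "biomarker": bm}
            for metric in _METRICS:
                vals = np.array([getattr(c[bm], metric) for c in per_cb])
                ok = ~np.isnan(vals)
                row[f"{metric}_mean"] = float(vals[ok].mean()) if ok.any() else float("nan")
                row[f"{metric}_sd"] = (float(vals[ok].std(ddof=1))
                                       if ok.sum() > 1 else 0.0)
            rows.append(row)
    table = pd.DataFrame(rows).set_index(["measure", "biomarker"])
    return EvaluationReport(table=table, raw_counts=counts)


def benchmark_suite(config=None, n_repeats: int = 10, k: int = 10,
                    base_seed: int = 1, measures=MEASURES,
                    model_config: ModelConfig | None = None,
                    ) -> tuple["EvaluationReport", "WeightReport"]:
    """Full biomarker-detection benchmark over repeated generated case bases.

    Generates ``n_repeats`` case bases with seeds ``base_seed .. base_seed +
    n_repeats - 1``, trains one similarity model per case base, runs the
    leave-one-out biomarker detection for every measure, and returns the
    metric summary plus the attribute-weight report.
    """
    import dataclasses

    from .datagen import GeneratorConfig, generate_case_base

    config = config or GeneratorConfig()
    counts: dict[str, list] = {m: [] for m in measures}
    models = []
    for i in range(n_repeats):
        cb, gt = generate_case_base(dataclasses.replace(config, seed=base_seed + i))
        model = train(cb, model_config)
        models.append(model)
        for m in measures:
            counts[m].append(loocv_biomarker_detection(
                cb, gt, m, k, model=model, seed=base_seed + i))
    return summarize(counts), weight_report(models, config.biomarker_names)


@dataclass
class WeightReport:
    """Per-iteration attribute-weight summary (weights scaled by 10)."""

    table: pd.DataFrame          # rows IT#i / Mean / SD
    biomarker_over_noise: float   # ratio of suite-mean biomarker to noise weight
    biomarker_over_all: float     # suite mean of per-iteration bm/all ratios


def weight_report(models: list[SimilarityModel],
                  biomarker_attrs: list[str]) -> WeightReport:
    """Summarize trained attribute weights across suite iterations.

    Weights are multiplied by 10 in the table for readability (ratios are
    unaffected).  Relative columns give the percentage difference of each
    weight to the all-attribute average of the same iteration, rounded to
    integer percent.
    """
    if not models:
        raise ValueError("need at least one trained model")
    rows = []
    bm_means, noise_means, all_means, bm_over_all = [], [], [], []
    for i, m in enumerate(models, start=1):
        w = m.weights
        bms = [b for b in biomarker_attrs if b in w]
        noise = [a for a in w if a not in biomarker_attrs]
        avg_all = float(np.mean(list(w.values())))
        avg_noise = float(np.mean([w[a] for a in noise])) if noise else float("nan")
        avg_bm = float(np.mean([w[b] for b in bms])) if bms else float("nan")
        row: dict[str, object] = {
            "iteration": f"IT#{i}",
            "avg_all_x10": 10 * avg_all,
            "avg_non_biomarker_x10": 10 * avg_noise,
            "avg_non_biomarker_rel_pct": round((avg_noise - avg_all) / avg_all * 100),
        }
        for b in bms:
            row[f"{b}_x10"] = 10 * w[b]
            row[f"{b}_rel_pct"] = round((w[b] - avg_all) / avg_all * 100)
        rows.append(row)
        bm_means.append(avg_bm)
        noise_means.append(avg_noise)
        all_means.append(avg_all)
        bm_over_all.append(avg_bm / avg_all)
    df = pd.DataFrame(rows).set_index("iteration")
    mean_row = df.mean(numeric_only=True)
    sd_row = df.std(numeric_only=True, ddof=1) if len(df) > 1 else df.iloc[0] * 0.0
    df.loc["Mean"] = mean_row
    df.loc["SD"] = sd_row
    return WeightReport(
        table=df,
        biomarker_over_noise=float(np.mean(bm_means) / np.mean(noise_means)),
        biomarker_over_all=float(np.mean(bm_over_all)),
    )
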