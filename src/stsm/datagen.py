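"""Synthetic survival case-base generator for a two-arm randomized trial.

Emulates an in-silico clinical trial data set with known, adjustable
biomarker structure, so that similarity measures can be benchmarked against
ground truth:

* ``n_cases`` patients randomized 1:1 over two therapy arms;
* 24 noise attributes drawn from the normal, exponential, Weibull and uniform
  families (6 per family by default), carrying no survival signal;
* four biomarker attributes, one numeric and one nominal per arm.  The
  numeric biomarker is a two-mode mixture (defaults: around 80 = "absent",
  around 120 = "present"); the nominal biomarker is a binomial draw with a
  configurable prevalence.  A biomarker that is present in a case belonging
  to its matching arm multiplies the case's event time by the effect
  multiplier, turning the case into a long-time survivor; present biomarkers
  in the other arm have no effect (predictive, arm-conditional biomarkers).
  By symmetry the two arms have equal overall survival.
* survival: exponential baseline event times, administrative censoring at the
  horizon, plus a fraction of cases with an independent uniform censoring
  time.  Times are on a normalized scale with the administrative horizon at 1.

The generating draws are recorded as per-case ground truth (``present`` /
``absent`` per biomarker -- for the numeric biomarker this is mode
membership, not a post-hoc threshold), which the evaluation harness scores
against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .casebase import AttributeSpec, CaseBase

__all__ = [
    "NoiseSpec",
    "NumericBiomarkerSpec",
    "NominalBiomarkerSpec",
    "GeneratorConfig",
    "GroundTruth",
    "default_noise_specs",
    "generate_case_base",
    "generate_suite",
    "verify_marginals",
]


@dataclass(frozen=True)
class NoiseSpec:
    """One survival-neutral attribute: name, distribution family and parameters."""

    name: str
    family: str  # normal | exponential | weibull | uniform
    params: tuple[float, ...] = ()

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "normal":
            loc, scale = self.params
            return rng.normal(loc, scale, n)
        if self.family == "exponential":
            (scale,) = self.params
            return rng.exponential(scale, n)
        if self.family == "weibull":
            shape, scale = self.params
            return scale * rng.weibull(shape, n)
        if self.family == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, n)
        raise ValueError(f"unknown noise family {self.family!r}")


def default_noise_specs(n: int = 24) -> list[NoiseSpec]:
    """n noise attributes spread evenly over the four distribution families."""
    families = [
        ("normal", (50.0, 10.0)),
        ("exponential", (1.0,)),
        ("weibull", (1.5, 1.0)),
        ("uniform", (0.0, 1.0)),
    ]
    specs = []
    for i in range(n):
        fam, params = families[i % len(families)]
        specs.append(NoiseSpec(f"{fam}_{i // len(families) + 1}", fam, params))
    return specs


@dataclass(frozen=True)
class NumericBiomarkerSpec:
    """Two-mode numeric biomarker; the high mode marks 'present'."""

    name: str
    arm: str
    absent_loc: float = 80.0
    present_loc: float = 120.0
    scale: float = 5.0
    present_weight: float = 0.5


@dataclass(frozen=True)
class NominalBiomarkerSpec:
    """Binomial nominal biomarker with labels for present/absent."""

    name: str
    arm: str
    prevalence: float = 0.3
    present_label: str = "present"
    absent_label: str = "absent"


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parametrization of the synthetic trial generator."""

    n_cases: int = 1000
    arms: tuple[str, str] = ("A", "B")
    arm_prob: float = 0.5
    noise: tuple[NoiseSpec, ...] = tuple(default_noise_specs(24))
    numeric_biomarkers: tuple[NumericBiomarkerSpec, ...] = (
        NumericBiomarkerSpec("bm_num_a", "A"),
        NumericBiomarkerSpec("bm_num_b", "B"),
    )
    nominal_biomarkers: tuple[NominalBiomarkerSpec, ...] = (
        NominalBiomarkerSpec("bm_nom_a", "A"),
        NominalBiomarkerSpec("bm_nom_b", "B"),
    )
    effect_multiplier: float = 3.0      # event-time factor per present+matching biomarker
    arm_conditional: bool = True        # False: biomarkers act in both arms (prognostic)
    baseline_mean: float = 1.0          # exponential baseline event time
    admin_horizon: float = 1.0          # administrative censoring time
    censor_rate: float = 0.2            # fraction with an independent U(0, horizon) censor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if not 0.0 <= self.arm_prob <= 1.0:
            raise ValueError("arm_prob must be in [0, 1]")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if self.effect_multiplier <= 0:
            raise ValueError("effect_multiplier must be positive")
        if self.baseline_mean <= 0 or self.admin_horizon <= 0:
            raise ValueError("baseline_mean and admin_horizon must be positive")
        for b in self.nominal_biomarkers:
            if not 0.0 <= b.prevalence <= 1.0:
                raise ValueError("prevalence must be in [0, 1]")
        for b in self.numeric_biomarkers:
            if not 0.0 <= b.present_weight <= 1.0:
                raise ValueError("present_weight must be in [0, 1]")

    @property
    def biomarker_names(self) -> list[str]:
        return ([b.name for b in self.numeric_biomarkers]
                + [b.name for b in self.nominal_biomarkers])

    @property
    def noise_names(self) -> list[str]:
        return [s.name for s in self.noise]


@dataclass
class GroundTruth:
    """Per-case biomarker presence flags, aligned with the case base rows."""

    frame: pd.DataFrame  # index: case id; one boolean column per biomarker

    def status(self, biomarker: str) -> np.ndarray:
        return self.frame[biomarker].to_numpy(dtype=bool)

    @property
    def biomarkers(self) -> list[str]:
        return list(self.frame.columns)


def generate_case_base(config: GeneratorConfig) -> tuple[CaseBase, GroundTruth]:
    """Draw one synthetic case base plus its biomarker ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    ids = [f"case_{i + 1:04d}" for i in range(n)]
    arm = np.where(rng.random(n) < config.arm_prob, config.arms[0], config.arms[1])

    cols: dict[str, np.ndarray] = {}
    truth: dict[str, np.ndarray] = {}
    log_mult = np.zeros(n)

    for spec in config.numeric_biomarkers:
        present = rng.random(n) < spec.present_weight
        loc = np.where(present, spec.present_loc, spec.absent_loc)
        cols[spec.name] = rng.normal(loc, spec.scale)
        truth[spec.name] = present
        active = present & ((arm == spec.arm) if config.arm_conditional else True)
        log_mult += np.where(active, np.log(config.effect_multiplier), 0.0)

    for spec in config.nominal_biomarkers:
        present = rng.random(n) < spec.prevalence
        cols[spec.name] = np.where(present, spec.present_label, spec.absent_label)
        truth[spec.name] = present
        active = present & ((arm == spec.arm) if config.arm_conditional else True)
        log_mult += np.where(active, np.log(config.effect_multiplier), 0.0)

    for spec in config.noise:
        cols[spec.name] = spec.draw(rng, n)

    event_time = rng.exponential(config.baseline_mean, n) * np.exp(log_mult)
    censor_time = np.full(n, config.admin_horizon)
    indep = rng.random(n) < config.censor_rate
    censor_time[indep] = rng.uniform(0.0, config.admin_horizon, int(indep.sum()))
    observed = np.minimum(event_time, censor_time)
    status = (event_time <= censor_time).astype(int)

    schema = [AttributeSpec("id", "id"),
              AttributeSpec("survival_time", "survival_time"),
              AttributeSpec("survival_status", "survival_status"),
              AttributeSpec("arm", "arm")]
    data = {"id": ids, "survival_time": observed, "survival_status": status,
            "arm": arm}
    for spec in config.numeric_biomarkers:
        schema.append(AttributeSpec(spec.name, "numeric"))
        data[spec.name] = cols[spec.name]
    for spec in config.nominal_biomarkers:
        schema.append(AttributeSpec(spec.name, "nominal",
                                    positive_label=spec.present_label))
        data[spec.name] = cols[spec.name]
    for spec in config.noise:
        schema.append(AttributeSpec(spec.name, "numeric"))
        data[spec.name] = cols[spec.name]

    cb = CaseBase(schema, pd.DataFrame(data))
    gt = GroundTruth(pd.DataFrame(truth, index=pd.Index(ids, name="id")))
    return cb, gt


def generate_suite(config: GeneratorConfig, n_repeats: int,
                   base_seed: int | None = None) -> list[tuple[CaseBase, GroundTruth]]:
    """n_repeats independent case bases with identical base configuration.

    Per-repeat seeds are derived deterministically from ``base_seed`` (default:
    ``config.seed``) via a seed sequence, so repeats are pairwise independent
    and the whole suite is reproducible from one integer.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    base = config.seed if base_seed is None else base_seed
    seeds = np.random.SeedSequence(base).generate_state(n_repeats) % (2 ** 31)
    return [generate_case_base(dataclasses.replace(config, seed=int(s)))
            for s in seeds]


def verify_marginals(suite: list[tuple[CaseBase, GroundTruth]]) -> dict:
    """Diagnostic summary of a generated suite.

    Reports the arm-A fraction, the per-arm median observed survival ratio
    (should be near 1: the arms perform equally well overall), the censoring
    fraction, each nominal biomarker's empirical prevalence, and the
    effect-size check: median observed time of cases with at least one
    present-and-matching biomarker versus all other cases.
    """
    if not suite:
        raise ValueError("suite must be non-empty")
    arm_frac, med_ratio, cens, effect = [], [], [], []
    prevalence: dict[str, list[float]] = {}
    for cb, gt in suite:
        arm_col = cb.arm_column
        arms = sorted(cb.df[arm_col].dropna().unique()) if arm_col else []
        times = cb.times
        if len(arms) == 2:
            a = cb.df[arm_col] == arms[0]
            arm_frac.append(float(a.mean()))
            med_a = float(np.median(times[a.to_numpy()]))
            med_b = float(np.median(times[(~a).to_numpy()]))
            med_ratio.append(med_a / med_b if med_b > 0 else np.nan)
        cens.append(float((cb.events == 0).mean()))
        matching = np.zeros(cb.n_cases, dtype=bool)
        for bm in gt.biomarkers:
            spec_obj = cb.spec(bm)
            present = gt.status(bm)
            if spec_obj.kind == "nominal":
                prevalence.setdefault(bm, []).append(float(present.mean()))
            if arm_col is not None:
                # a biomarker named ..._a/_b matches the corresponding arm label
                suffix = bm.rsplit("_", 1)[-1].upper()
                matching |= present & (cb.df[arm_col].str.upper() == suffix).to_numpy()
            else:
                matching |= present
        if matching.any() and (~matching).any():
            effect.append(float(np.median(times[matching]))
                          / float(np.median(times[~matching])))
    return {
        "n_case_bases": len(suite),
        "arm_a_fraction": float(np.mean(arm_frac)) if arm_frac else np.nan,
        "arm_median_survival_ratio": float(np.nanmean(med_ratio)) if med_ratio else np.nan,
        "censoring_fraction": float(np.mean(cens)),
        "nominal_prevalence": {k: float(np.mean(v)) for k, v in prevalence.items()},
        "effect_median_time_ratio": float(np.mean(effect)) if effect else np.nan,
    }
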