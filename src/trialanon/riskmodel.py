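"""Quantitative re-identification risk for clinical-trial releases.

Risk is computed only over quasi-identifiers.  Records sharing the same
quasi-identifier tuple form an *equivalence class* of size ``f``; an adversary
who knows a target's quasi-identifiers and that the target is in the data can
do no better than pick one of ``f`` candidates, so the per-record risk is
``1/f`` (prosecutor model).  When the dataset is a fraction ``pi`` of a wider
population, the adversary only knows the target is in the *population*; the
class size there is estimated as ``f/pi`` and the per-record risk becomes
``min(1, pi/f)`` (journalist model).

Three attacks are modelled and the overall risk is their maximum:

* **T1, deliberate attack** — ``avg_data_risk * p(attempt)``, where the
  attempt probability reflects the strength of security, privacy and
  contractual controls around the data (weakest-link over a checklist).
* **T2, inadvertent acquaintance recognition** — ``avg_data_risk(acquaintance
  QIs) * p(acquaintance)`` with ``p(acquaintance) = 1 - (1 - v)**150``:
  the chance that an analyst personally knows one of the trial participants,
  where ``v`` is the fraction of the therapeutic-area trial population
  enrolled in these studies and 150 is the Dunbar number (the typical size of
  a person's stable social circle).
* **T3, data breach** — ``avg_data_risk * p(breach)``, with the breach
  probability taken from published health-data breach rates.

A release is certified when the overall risk is at or below the threshold
(default 0.09, the value recommended by the EMA's clinical-data publication
guidance and adopted by Health Canada) *and*, under the strict-average
criterion, the estimated number of records that are unique in the population
is effectively zero.  Population uniqueness is estimated under the
independence log-linear model of the quasi-identifier cross-classification
(a spectrum-based Ewens–Pitman species-model alternative is also provided).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import gammaln

from .codebook import VariableSpec, is_missing

#: default certification threshold (EMA / Health Canada recommendation)
RISK_THRESHOLD = 0.09
#: Dunbar number: modelled count of people an analyst personally knows
DUNBAR_NUMBER = 150
#: strict-average zero-cutoff: "no population uniques" means fewer than this
#: many expected unique records
ZERO_UNIQUES_CUTOFF = 0.1
#: probability comparisons use this absolute tolerance
PROB_TOL = 1e-12

#: sentinel used to group missing QI values into their own class
_MISSING_CLASS = "<missing>"


class RiskModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# equivalence partitions

@dataclass
class EquivalencePartition:
    """Counts of records per distinct quasi-identifier tuple."""

    classes: dict[tuple, int]
    n: int
    attack: str | None = None

    def __post_init__(self) -> None:
        if sum(self.classes.values()) != self.n:
            raise RiskModelError("class sizes do not sum to n")
        if any(f < 1 for f in self.classes.values()):
            raise RiskModelError("every equivalence class must have f >= 1")

    @property
    def sizes(self) -> np.ndarray:
        return np.asarray(list(self.classes.values()), dtype=float)

    @property
    def sample_uniques(self) -> int:
        """Number of records alone in their class."""
        return int(np.sum(self.sizes == 1))

    def spectrum(self) -> dict[int, int]:
        """Frequency-of-frequencies: class size -> number of classes."""
        sizes, counts = np.unique(self.sizes.astype(int), return_counts=True)
        return dict(zip(sizes.tolist(), counts.tolist()))


def partition(
    table: pd.DataFrame, qis: Sequence[VariableSpec | str], attack: str | None = None
) -> EquivalencePartition:
    """Group records by their quasi-identifier tuple.

    Missing QI values form their own category (conservative: they are not
    merged with any observed value).
    """
    names = [q.name if isinstance(q, VariableSpec) else str(q) for q in qis]
    if not names:
        raise RiskModelError("at least one quasi-identifier is required")
    missing_cols = [c for c in names if c not in table.columns]
    if missing_cols:
        raise RiskModelError(f"quasi-identifiers not in table: {missing_cols}")
    if len(table) == 0:
        raise RiskModelError("cannot partition an empty table")

    def norm(v: Any) -> Any:
        return _MISSING_CLASS if is_missing(v) else str(v)

    tuples = [
        tuple(norm(v) for v in row)
        for row in table[names].itertuples(index=False, name=None)
    ]
    classes: dict[tuple, int] = {}
    for t in tuples:
        classes[t] = classes.get(t, 0) + 1
    return EquivalencePartition(classes=classes, n=len(table), attack=attack)


# ---------------------------------------------------------------------------
# data risk

def prosecutor_avg_risk(p: EquivalencePartition) -> float:
    """Average per-record risk when the adversary knows the target is in the
    sample: (1/n) * sum over records of 1/f_i = (#classes)/n."""
    return float(len(p.classes) / p.n)


def prosecutor_max_risk(p: EquivalencePartition) -> float:
    return float(1.0 / p.sizes.min())


def journalist_avg_risk(p: EquivalencePartition, pi: float) -> float:
    """Average per-record risk when the adversary only knows the target is in
    the population sampled at fraction *pi*: per-record min(1, pi/f_i).

    Equals the prosecutor risk at pi = 1.
    """
    if not 0 < pi <= 1:
        raise RiskModelError(f"sampling fraction must be in (0, 1], got {pi}")
    sizes = p.sizes
    per_class = np.minimum(1.0, pi / sizes)  # risk of each record in the class
    return float(np.sum(sizes * per_class) / p.n)


def journalist_max_risk(p: EquivalencePartition, pi: float) -> float:
    if not 0 < pi <= 1:
        raise RiskModelError(f"sampling fraction must be in (0, 1], got {pi}")
    return float(min(1.0, pi / p.sizes.min()))


# ---------------------------------------------------------------------------
# population uniqueness

def _log_rising(x: float, m: int) -> float:
    """log of the rising factorial x(x+1)...(x+m-1)."""
    if m == 0:
        return 0.0
    return float(gammaln(x + m) - gammaln(x))


def _expected_classes(n: int, alpha: float, theta: float) -> float:
    """E[K_n] under Pitman(alpha, theta)."""
    return (theta / alpha) * math.expm1(
        _log_rising(theta + alpha, n) - _log_rising(theta, n)
    )


def _expected_singletons(n: int, alpha: float, theta: float) -> float:
    """E[K_{1,n}]: expected number of singleton classes in a sample of n."""
    return n * math.exp(
        _log_rising(theta + alpha, n - 1) - _log_rising(theta + 1, n - 1)
    )


def _fit_pitman(n: int, k: int, k1: int) -> tuple[float, float]:
    """Method-of-moments fit of (alpha, theta) matching the observed number
    of classes K and singleton classes K1.

    For fixed alpha, E[K_n] is increasing in theta, so theta is solved by
    bisection; alpha is then solved to match the singleton count.  Boundary
    cases (no feasible root) fall back to the feasible value closest to the
    observed singleton count.
    """
    theta_lo, theta_hi = 1e-9, 1e9

    def theta_for(alpha: float) -> float | None:
        f = lambda th: _expected_classes(n, alpha, th) - k
        lo, hi = f(theta_lo), f(theta_hi)
        if lo > 0:  # even theta -> 0 yields more classes than observed
            return None
        if hi < 0:  # cannot reach K even with huge theta
            return theta_hi
        return float(brentq(f, theta_lo, theta_hi, xtol=1e-10, rtol=1e-12))

    def singleton_gap(alpha: float) -> float | None:
        th = theta_for(alpha)
        if th is None:
            return None
        return _expected_singletons(n, alpha, th) - k1

    alphas = np.linspace(1e-6, 1 - 1e-6, 60)
    gaps = [(a, singleton_gap(a)) for a in alphas]
    feasible = [(a, g) for a, g in gaps if g is not None]
    if not feasible:
        # degenerate spectrum; pure Ewens fallback
        return 1e-6, max(float(k), 1e-6)
    # look for a sign change to bracket the root
    for (a0, g0), (a1, g1) in zip(feasible, feasible[1:]):
        if g0 == 0:
            return a0, theta_for(a0)  # type: ignore[return-value]
        if g0 * g1 < 0:
            root = float(
                brentq(lambda a: singleton_gap(a), a0, a1, xtol=1e-8)
            )
            return root, theta_for(root)  # type: ignore[return-value]
    best = min(feasible, key=lambda ag: abs(ag[1]))
    return best[0], theta_for(best[0])  # type: ignore[return-value]


def _loglinear_uniques(p: EquivalencePartition, pi: float) -> float:
    """Independence log-linear estimator of population uniqueness.

    Each singleton's cell probability is estimated from the product of the
    sample marginal proportions of its quasi-identifier values (the
    independence log-linear model of the QI cross-classification); none of
    the remaining N - n unsampled individuals falls into that cell with
    probability (1 - p_cell)^(N - n), which is exactly the probability that
    the sample unique is also a population unique.  Summing over sample
    singletons gives the expected count.  At pi = 1 the exponent vanishes
    and the exact singleton count is returned.
    """
    n = p.n
    big_n = max(int(round(n / pi)), n)
    tuples = list(p.classes)
    dim = len(tuples[0]) if tuples else 0
    if dim == 0:
        return 0.0
    marginals: list[dict] = [{} for _ in range(dim)]
    for t, f in p.classes.items():
        for j, v in enumerate(t):
            marginals[j][v] = marginals[j].get(v, 0) + f
    est = 0.0
    for t, f in p.classes.items():
        if f != 1:
            continue
        p_cell = 1.0
        for j, v in enumerate(t):
            p_cell *= marginals[j][v] / n
        est += (1.0 - p_cell) ** (big_n - n)
    return est


def _pitman_uniques(p: EquivalencePartition, pi: float) -> float:
    """Pitman-model estimator: fit (alpha, theta) by method of moments on
    (number of classes, number of singletons); each population singleton
    under the fitted model appears in the sample with probability pi,
    giving pi * E[K_{1,N}] at N = n / pi."""
    k1 = p.sample_uniques
    n, k = p.n, len(p.classes)
    if k == n:
        # all records distinct: no spectrum information to discount;
        # conservatively treat every sample unique as a population unique
        return float(k1)
    alpha, theta = _fit_pitman(n, k, k1)
    big_n = max(int(round(n / pi)), n)
    return pi * _expected_singletons(big_n, alpha, theta)


def estimate_population_uniques(
    p: EquivalencePartition, pi: float, method: str = "loglinear"
) -> float:
    """Expected number of sample records whose *population* equivalence class
    has size one, for a sample drawn at fraction *pi* of the population.

    ``method="loglinear"`` (default) uses the independence log-linear model
    of the quasi-identifier cross-classification — the standard approach for
    population-uniqueness estimation from a sample — and reduces to exact
    counting at pi = 1.  ``method="pitman"`` fits a two-parameter
    Ewens-Pitman species model to the class-size spectrum instead; it is
    more conservative on heavy-tailed spectra.  Either estimate is clamped
    to [0, sample uniques].
    """
    if not 0 < pi <= 1:
        raise RiskModelError(f"sampling fraction must be in (0, 1], got {pi}")
    k1 = p.sample_uniques
    if pi == 1:
        return float(k1)
    if k1 == 0:
        return 0.0
    if method == "loglinear":
        est = _loglinear_uniques(p, pi)
    elif method == "pitman":
        est = _pitman_uniques(p, pi)
    else:
        raise RiskModelError(f"unknown uniqueness estimator {method!r}")
    return float(min(max(est, 0.0), k1))


@dataclass
class DataRisk:
    """Data-side risk summary for one attack's quasi-identifier set."""

    avg_risk: float
    max_risk: float
    sample_uniques: int
    est_population_uniques: float
    sampling_fraction: float
    estimator: str

    def to_dict(self) -> dict:
        return {
            "avg_risk": self.avg_risk,
            "max_risk": self.max_risk,
            "sample_uniques": self.sample_uniques,
            "est_population_uniques": self.est_population_uniques,
            "sampling_fraction": self.sampling_fraction,
            "estimator": self.estimator,
        }


def compute_data_risk(p: EquivalencePartition, pi: float = 1.0) -> DataRisk:
    """Average/max data risk plus population-uniqueness estimate.

    Uses journalist risk when pi < 1 is known, prosecutor risk otherwise
    (the two coincide at pi = 1).
    """
    if pi < 1.0:
        avg = journalist_avg_risk(p, pi)
        mx = journalist_max_risk(p, pi)
        estimator = "journalist+loglinear"
    else:
        avg = prosecutor_avg_risk(p)
        mx = prosecutor_max_risk(p)
        estimator = "prosecutor+exact"
    return DataRisk(
        avg_risk=avg,
        max_risk=mx,
        sample_uniques=p.sample_uniques,
        est_population_uniques=estimate_population_uniques(p, pi),
        sampling_fraction=pi,
        estimator=estimator,
    )


# ---------------------------------------------------------------------------
# context risk

def acquaintance_probability(v: float, n_acquaintances: int = DUNBAR_NUMBER) -> float:
    """Probability that an analyst personally knows someone in the
    therapeutic-area trial population: 1 - (1 - v)**n_acquaintances.

    *v* is the proportion of that population enrolled in the current studies;
    the exponent defaults to the Dunbar number, 150.
    """
    if not 0 <= v <= 1:
        raise RiskModelError(f"recruitment proportion v must be in [0, 1], got {v}")
    return float(1.0 - (1.0 - v) ** n_acquaintances)


_LEVELS = ("high", "medium", "low")


def default_context_config() -> dict:
    """Checklist structure and the attempt-probability lookup shipped with
    the package (configuration values, not empirical claims)."""
    text = resources.files("trialanon").joinpath("data/context_defaults.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class ContextAssessment:
    """Context-side risk inputs: checklist answers and scalar probabilities."""

    answers: dict[str, str]
    p_attempt: float
    v: float
    p_breach: float
    p_acquaintance: float = field(init=False)

    def __post_init__(self) -> None:
        for name, x in (("p_attempt", self.p_attempt), ("v", self.v),
                        ("p_breach", self.p_breach)):
            if not 0 <= x <= 1:
                raise RiskModelError(f"{name} must be in [0, 1], got {x}")
        self.p_acquaintance = acquaintance_probability(self.v)

    def to_dict(self) -> dict:
        return {
            "answers": dict(self.answers),
            "p_attempt": self.p_attempt,
            "v": self.v,
            "p_breach": self.p_breach,
            "p_acquaintance": self.p_acquaintance,
        }


def context_from_checklist(
    answers: Mapping[str, str],
    v: float,
    p_breach: float | None = None,
    config: Mapping[str, Any] | None = None,
) -> ContextAssessment:
    """Convert checklist answers into a conservative attempt probability.

    Each control item (grouped into security, privacy and contractual
    controls) is answered high/medium/low.  A group is as strong as its
    weakest item, the context as its weakest group, and the attempt
    probability is looked up from the configured table for that weakest
    level — so strengthening any single control can never increase
    ``p_attempt``.
    """
    cfg = dict(config) if config is not None else default_context_config()
    groups: Mapping[str, Sequence[str]] = cfg["groups"]
    table: Mapping[str, float] = cfg["p_attempt"]
    missing = [
        item for items in groups.values() for item in items if item not in answers
    ]
    if missing:
        raise RiskModelError(f"checklist answers missing items: {missing}")
    for item, level in answers.items():
        if level not in _LEVELS:
            raise RiskModelError(f"item {item!r}: unknown control level {level!r}")

    rank = {lev: i for i, lev in enumerate(_LEVELS)}  # high=0 ... low=2
    weakest = "high"
    for items in groups.values():
        group_weakest = max((answers[i] for i in items), key=lambda l: rank[l])
        if rank[group_weakest] > rank[weakest]:
            weakest = group_weakest
    return ContextAssessment(
        answers={i: answers[i] for items in groups.values() for i in items},
        p_attempt=float(table[weakest]),
        v=float(v),
        p_breach=float(cfg["p_breach"] if p_breach is None else p_breach),
    )


# ---------------------------------------------------------------------------
# attacks, overall risk, certification

@dataclass
class RiskAssessment:
    t1: float
    t2: float
    t3: float
    overall: float
    threshold: float = RISK_THRESHOLD
    strict_average_ok: bool = True
    certified: bool = False
    est_population_uniques: float = 0.0

    def to_dict(self) -> dict:
        return {
            "t1": self.t1, "t2": self.t2, "t3": self.t3,
            "overall": self.overall, "threshold": self.threshold,
            "strict_average_ok": self.strict_average_ok,
            "certified": self.certified,
            "est_population_uniques": self.est_population_uniques,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def attack_risks(
    data_public: DataRisk, data_acq: DataRisk, ctx: ContextAssessment
) -> tuple[float, float, float]:
    """The three attack risks.

    T1 (deliberate) and T3 (breach) act on the public quasi-identifiers;
    T2 (acquaintance) acts on the acquaintance set, which includes them.
    """
    t1 = data_public.avg_risk * ctx.p_attempt
    t2 = data_acq.avg_risk * ctx.p_acquaintance
    t3 = data_public.avg_risk * ctx.p_breach
    return float(t1), float(t2), float(t3)


def overall_risk(t1: float, t2: float, t3: float) -> float:
    """Overall risk: the maximum across the three attacks."""
    for name, t in (("t1", t1), ("t2", t2), ("t3", t3)):
        if not -PROB_TOL <= t <= 1 + PROB_TOL:
            raise RiskModelError(f"{name} must be a probability, got {t}")
    return float(max(t1, t2, t3))


def certify(
    t1: float,
    t2: float,
    t3: float,
    est_population_uniques: float = 0.0,
    threshold: float = RISK_THRESHOLD,
    strict: bool = True,
) -> RiskAssessment:
    """Assemble the final verdict.

    Certified iff the overall (max) risk is at or below *threshold* and, when
    the strict-average criterion applies, the estimated number of population-
    unique records is below the zero-cutoff (0.1 expected records).
    """
    overall = overall_risk(t1, t2, t3)
    strict_ok = (not strict) or (est_population_uniques < ZERO_UNIQUES_CUTOFF)
    return RiskAssessment(
        t1=t1, t2=t2, t3=t3, overall=overall, threshold=threshold,
        strict_average_ok=strict_ok,
        certified=bool(overall <= threshold + PROB_TOL and strict_ok),
        est_population_uniques=float(est_population_uniques),
    )


def assess(
    table: pd.DataFrame,
    public_qis: Sequence[VariableSpec | str],
    acq_qis: Sequence[VariableSpec | str],
    ctx: ContextAssessment,
    threshold: float = RISK_THRESHOLD,
    strict: bool = True,
) -> tuple[RiskAssessment, DataRisk, DataRisk]:
    """One-call risk assessment of a subject-level quasi-identifier view."""
    pi = ctx.v if 0 < ctx.v < 1 else 1.0
    dr_pub = compute_data_risk(partition(table, public_qis, "public"), pi)
    dr_acq = compute_data_risk(partition(table, acq_qis, "acquaintance"), pi)
    t1, t2, t3 = attack_risks(dr_pub, dr_acq, ctx)
    ra = certify(
        t1, t2, t3,
        est_population_uniques=dr_pub.est_population_uniques,
        threshold=threshold, strict=strict,
    )
    return ra, dr_pub, dr_acq
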