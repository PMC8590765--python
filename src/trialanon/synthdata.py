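"""Synthetic multi-study trial worlds with known re-identification ground truth.

A *world* consists of a fully enumerated therapeutic-area population — every
individual's public quasi-identifier profile (age, sex, country) — plus one or
more trial cohorts sampled from it without replacement.  Because the whole
population is materialised, every quantity the risk model estimates has an
exact answer: the recruitment proportion ``v`` is known by construction, and
population uniqueness can be counted by brute force.

The sampled studies emulate the modalities of a multiple-sclerosis-like trial
pool: demographics with site and country, visit calendars with real dates
(jittered around a nominal schedule so relative-day conversion is
non-trivial), a bounded ordinal disability score (0–10 in 0.5 steps, random
walk across visits, like the EDSS), and relapse-like events at a configurable
rate per patient-year.

Population profiles are drawn from a product of categorical distributions
with a Zipf-skewed country margin, so population uniqueness occurs at
realistic rates rather than being an artifact of a uniform generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codebook import (
    Codebook,
    HierarchyLevel,
    TableSpec,
    VariableSpec,
    codebook_from_dict,
)


class SynthError(ValueError):
    pass


#: country -> (region, continent): the shipped generalization ladder
COUNTRY_LADDER: dict[str, tuple[str, str]] = {
    "CH": ("Western Europe", "Europe"),
    "DE": ("Western Europe", "Europe"),
    "FR": ("Western Europe", "Europe"),
    "IT": ("Southern Europe", "Europe"),
    "ES": ("Southern Europe", "Europe"),
    "GB": ("Northern Europe", "Europe"),
    "SE": ("Northern Europe", "Europe"),
    "PL": ("Eastern Europe", "Europe"),
    "US": ("North America", "America"),
    "CA": ("North America", "America"),
    "AU": ("Oceania", "Oceania"),
    "JP": ("East Asia", "Asia"),
}


@dataclass
class WorldSpec:
    """Conditions under which a synthetic world is generated.

    Defaults describe a modest three-study pool recruiting 10% of a
    2000-person therapeutic-area population, with MS-like demographics
    (age 18–60 centred in the late thirties, ~70% female) and a one-year
    follow-up with quarterly visits.
    """

    population_size: int = 2000
    study_sizes: tuple[int, ...] = (80, 60, 60)
    age_range: tuple[int, int] = (18, 60)
    age_mean: float = 38.0
    age_sd: float = 10.0
    sex_categories: tuple[str, ...] = ("F", "M")
    sex_probs: tuple[float, ...] = (0.7, 0.3)
    countries: tuple[str, ...] = tuple(COUNTRY_LADDER)
    country_zipf_s: float = 1.0
    sites_per_country: int = 3
    visit_days: tuple[int, ...] = (1, 91, 181, 271, 361)
    visit_jitter: int = 3
    edss_start_mean: float = 2.5
    edss_start_sd: float = 1.5
    edss_max_step: float = 1.0
    relapse_rate: float = 0.5  # events per patient-year
    followup_years: float = 1.0
    missingness: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if sum(self.study_sizes) > self.population_size:
            raise SynthError(
                f"cannot sample {sum(self.study_sizes)} subjects from a "
                f"population of {self.population_size}"
            )
        if not 0 <= self.missingness < 1:
            raise SynthError("missingness rate must be in [0, 1)")
        if self.relapse_rate < 0 or self.visit_jitter < 0:
            raise SynthError("rates must be non-negative")

    @property
    def v(self) -> float:
        """Recruitment proportion: sampled subjects over population size."""
        return sum(self.study_sizes) / self.population_size


@dataclass
class SyntheticWorld:
    spec: WorldSpec
    population: pd.DataFrame
    studies: dict[str, dict[str, pd.DataFrame]]
    codebook: Codebook
    truth: dict = field(default_factory=dict)

    def pooled(self, table: str) -> pd.DataFrame:
        """Concatenate one table across studies."""
        frames = [t[table] for t in self.studies.values() if table in t]
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# codebook for generated worlds

def world_codebook(spec: WorldSpec) -> Codebook:
    ladder = [
        {"name": "region",
         "map": {c: COUNTRY_LADDER[c][0] for c in spec.countries}},
        {"name": "continent",
         "map": {c: COUNTRY_LADDER[c][1] for c in spec.countries}},
    ]
    doc = {
        "version": "",
        "tables": [
            {
                "name": "demography",
                "key": "subject_id",
                "subject_table": True,
                "variables": [
                    {"name": "subject_id", "privacy_class": "direct_identifier",
                     "value_type": "text"},
                    {"name": "age", "privacy_class": "quasi_public",
                     "value_type": "integer", "units": "years",
                     "range": list(spec.age_range),
                     "aliases": ["AGE", "age_yrs"]},
                    {"name": "sex", "privacy_class": "quasi_public",
                     "value_type": "category",
                     "categories": list(spec.sex_categories),
                     "aliases": ["SEX"]},
                    {"name": "country", "privacy_class": "quasi_public",
                     "value_type": "category",
                     "categories": list(spec.countries),
                     "hierarchy": ladder},
                    {"name": "site_id", "privacy_class": "direct_identifier",
                     "value_type": "text"},
                    {"name": "enrollment_date", "privacy_class": "date",
                     "value_type": "date"},
                    {"name": "ms_duration_years",
                     "privacy_class": "quasi_acquaintance",
                     "value_type": "integer", "units": "years",
                     "range": [0, 40]},
                ],
            },
            {
                "name": "visits",
                "key": "subject_id",
                "variables": [
                    {"name": "subject_id", "privacy_class": "direct_identifier",
                     "value_type": "text"},
                    {"name": "visit_number", "privacy_class": "other",
                     "value_type": "integer"},
                    {"name": "visit_date", "privacy_class": "date",
                     "value_type": "date"},
                ],
            },
            {
                "name": "scores",
                "key": "subject_id",
                "variables": [
                    {"name": "subject_id", "privacy_class": "direct_identifier",
                     "value_type": "text"},
                    {"name": "visit_number", "privacy_class": "other",
                     "value_type": "integer"},
                    {"name": "edss", "privacy_class": "sensitive",
                     "value_type": "real", "units": "EDSS points",
                     "range": [0, 10]},
                ],
            },
            {
                "name": "events",
                "key": "subject_id",
                "variables": [
                    {"name": "subject_id", "privacy_class": "direct_identifier",
                     "value_type": "text"},
                    {"name": "event_date", "privacy_class": "date",
                     "value_type": "date"},
                    {"name": "event_type", "privacy_class": "other",
                     "value_type": "category", "categories": ["relapse"]},
                ],
            },
        ],
    }
    return codebook_from_dict(doc)


# ---------------------------------------------------------------------------
# generation

def _zipf_probs(k: int, s: float) -> np.ndarray:
    w = 1.0 / np.arange(1, k + 1) ** s
    return w / w.sum()


def _draw_ages(rng: np.random.Generator, n: int, spec: WorldSpec) -> np.ndarray:
    a = rng.normal(spec.age_mean, spec.age_sd, size=n)
    return np.clip(np.rint(a), spec.age_range[0], spec.age_range[1]).astype(int)


def _edss_walk(rng: np.random.Generator, n_visits: int, spec: WorldSpec) -> list[float]:
    start = np.clip(rng.normal(spec.edss_start_mean, spec.edss_start_sd), 0.0, 10.0)
    x = round(start * 2) / 2
    out = [x]
    max_halves = int(round(spec.edss_max_step * 2))
    for _ in range(n_visits - 1):
        step = rng.integers(-max_halves, max_halves + 1) / 2
        x = float(np.clip(x + step, 0.0, 10.0))
        out.append(x)
    return out


def generate_world(spec: WorldSpec | None = None) -> SyntheticWorld:
    """Generate a population and its sampled trial studies, deterministic
    under ``spec.seed``, with the ground-truth record filled in by exact
    enumeration over the generated population."""
    spec = spec or WorldSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_pop = spec.population_size
    population = pd.DataFrame(
        {
            "person_id": [f"POP{i:06d}" for i in range(n_pop)],
            "age": _draw_ages(rng, n_pop, spec),
            "sex": rng.choice(spec.sex_categories, size=n_pop, p=spec.sex_probs),
            "country": rng.choice(
                spec.countries, size=n_pop,
                p=_zipf_probs(len(spec.countries), spec.country_zipf_s)),
        }
    )

    # exact population equivalence-class sizes on the public QI profile
    qi_cols = ["age", "sex", "country"]
    class_size = population.groupby(qi_cols)["person_id"].transform("size")
    population = population.assign(_class_size=class_size)

    # sample the study cohorts without replacement, disjoint across studies
    total_n = sum(spec.study_sizes)
    sampled = rng.choice(n_pop, size=total_n, replace=False)
    offsets = np.cumsum((0,) + spec.study_sizes)

    studies: dict[str, dict[str, pd.DataFrame]] = {}
    pop_unique_by_subject: dict[str, bool] = {}
    base_date = date(2015, 1, 1)
    followup_days = int(round(spec.followup_years * 365))

    for s_idx, n_s in enumerate(spec.study_sizes):
        study = f"S{s_idx + 1:02d}"
        idx = sampled[offsets[s_idx]:offsets[s_idx + 1]]
        people = population.iloc[idx]
        subject_ids = [f"{study}-{j + 1:04d}" for j in range(n_s)]
        sites = [
            f"{c}{rng.integers(1, spec.sites_per_country + 1):02d}"
            for c in people["country"]
        ]
        enroll = [
            base_date + timedelta(days=int(rng.integers(0, 3 * 365)))
            for _ in range(n_s)
        ]
        demog = pd.DataFrame(
            {
                "subject_id": subject_ids,
                "age": people["age"].to_numpy(),
                "sex": people["sex"].to_numpy(),
                "country": people["country"].to_numpy(),
                "site_id": sites,
                "enrollment_date": [d.isoformat() for d in enroll],
                "ms_duration_years": rng.integers(0, 31, size=n_s),
            }
        )
        for sid, unique in zip(subject_ids, (people["_class_size"] == 1)):
            pop_unique_by_subject[sid] = bool(unique)

        visit_rows, score_rows, event_rows = [], [], []
        for sid, e0 in zip(subject_ids, enroll):
            scores = _edss_walk(rng, len(spec.visit_days), spec)
            for vnum, (day, edss) in enumerate(zip(spec.visit_days, scores), 1):
                jitter = 0 if day == 1 else int(
                    rng.integers(-spec.visit_jitter, spec.visit_jitter + 1))
                vdate = e0 + timedelta(days=day - 1 + jitter)
                visit_rows.append((sid, vnum, vdate.isoformat()))
                score_rows.append((sid, vnum, edss))
            n_events = rng.poisson(spec.relapse_rate * spec.followup_years)
            for _ in range(n_events):
                edate = e0 + timedelta(days=int(rng.integers(0, followup_days)))
                event_rows.append((sid, edate.isoformat(), "relapse"))
        studies[study] = {
            "demography": demog,
            "visits": pd.DataFrame(
                visit_rows, columns=["subject_id", "visit_number", "visit_date"]),
            "scores": pd.DataFrame(
                score_rows, columns=["subject_id", "visit_number", "edss"]),
            "events": pd.DataFrame(
                event_rows, columns=["subject_id", "event_date", "event_type"]),
        }

    truth = {
        "v": total_n / n_pop,
        "population_uniques": int((population["_class_size"] == 1).sum()),
        "sample_population_uniques": int(sum(pop_unique_by_subject.values())),
        "pop_unique_by_subject": pop_unique_by_subject,
        "missing_cells": [],
        "missing_rate_realized": 0.0,
    }

    world = SyntheticWorld(
        spec=spec,
        population=population.drop(columns=["_class_size"]),
        studies=studies,
        codebook=world_codebook(spec),
        truth=truth,
    )
    if spec.missingness > 0:
        _apply_world_missingness(world, rng)
    return world


#: (table, column) cells eligible for missingness injection inside a world;
#: QI columns are kept complete so uniqueness ground truth stays exact
_WORLD_ELIGIBLE = {("scores", "edss")}


def _apply_world_missingness(world: SyntheticWorld, rng: np.random.Generator) -> None:
    cells = []
    n_eligible = 0
    for study, tables in world.studies.items():
        for tname, df in tables.items():
            for col in df.columns:
                if (tname, col) not in _WORLD_ELIGIBLE:
                    continue
                mask = rng.random(len(df)) < world.spec.missingness
                n_eligible += len(df)
                df.loc[mask, col] = np.nan
                for i in df.index[mask]:
                    cells.append((study, tname, str(df.at[i, "subject_id"]), col))
    world.truth["missing_cells"] = cells
    world.truth["missing_rate_realized"] = (
        len(cells) / n_eligible if n_eligible else 0.0
    )


def inject_missingness(
    tables: Mapping[str, pd.DataFrame],
    rate: float,
    seed: int,
    key_columns: Sequence[str] = ("subject_id",),
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Blank each eligible cell independently with probability *rate*.

    Key columns are never blanked.  Returns the modified tables and an info
    record with the realized rate and the blanked cell coordinates.
    """
    if not 0 <= rate < 1:
        raise SynthError("missingness rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    cells: list[tuple[str, int, str]] = []
    n_eligible = 0
    for name, df in tables.items():
        new = df.copy()
        for col in df.columns:
            if col in key_columns:
                continue
            mask = rng.random(len(df)) < rate
            n_eligible += len(df)
            new.loc[mask, col] = np.nan
            cells.extend((name, int(i), col) for i in df.index[mask])
        out[name] = new
    info = {
        "rate_requested": rate,
        "rate_realized": len(cells) / n_eligible if n_eligible else 0.0,
        "n_eligible": n_eligible,
        "cells": cells,
    }
    return out, info


# ---------------------------------------------------------------------------
# worked-example fixtures

def worked_example_tables() -> dict[str, pd.DataFrame]:
    """Small, byte-stable fixtures used across the documentation and tests:

    * ``partition``: six records whose (sex, age) tuples form equivalence
      classes of sizes {3, 2, 1}, so the prosecutor average risk is 0.5;
    * ``pseudo_clinical`` / ``pseudo_imaging``: two tables sharing subject
      ``0001-017``, exercising cross-table pseudonym consistency;
    * ``dates``: events on, after and before the reference date, exercising
      the no-day-0 study-day convention (day 1 and day -1).
    """
    part = pd.DataFrame(
        {
            "subject_id": [f"0001-{i:03d}" for i in range(1, 7)],
            "sex": ["M", "M", "M", "F", "F", "F"],
            "age": [30, 30, 30, 30, 30, 40],
        }
    )
    clinical = pd.DataFrame(
        {
            "subject_id": ["0001-017", "0001-018"],
            "age": [42, 35],
            "sex": ["F", "M"],
        }
    )
    imaging = pd.DataFrame(
        {
            "subject_id": ["0001-017", "0001-018", "0001-017"],
            "scan": ["T1w", "T1w", "FLAIR"],
        }
    )
    dates = pd.DataFrame(
        {
            "subject_id": ["0001-017"] * 3,
            "event_date": ["2016-03-01", "2016-03-11", "2016-02-29"],
        }
    )
    return {
        "partition": part,
        "pseudo_clinical": clinical,
        "pseudo_imaging": imaging,
        "dates": dates,
    }
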