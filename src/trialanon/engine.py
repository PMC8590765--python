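"""The anonymise-until-safe loop.

Mandatory steps are applied first to every release: the subject identifier is
pseudonymised (producing the protected link file), calendar dates are offset
to per-subject relative study days, and direct identifiers such as the site
id are suppressed.  The three attack risks are then recomputed after each
candidate transformation, and a greedy ladder search generalizes or
suppresses quasi-identifiers — always picking the step with the greatest
marginal reduction in overall risk — until the release certifies (overall
risk at or below the threshold and, under the strict-average criterion, no
estimated population uniques), or the ladders are exhausted.

Each ladder is a sequence of weak coarsenings, so the risk trajectory is
non-increasing by construction.  The run produces an auditable
:class:`AnonymisationReport` whose transform log, replayed against the
original tables with the original link file, reproduces the release
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import riskmodel, transforms
from .codebook import Codebook, VariableSpec, is_missing, quasi_identifiers
from .riskmodel import (
    RISK_THRESHOLD,
    ContextAssessment,
    DataRisk,
    EquivalencePartition,
    RiskAssessment,
)
from .transforms import LinkFile, TransformLog


class EngineError(ValueError):
    pass


class CannotCertifyError(RuntimeError):
    """Raised when the transformation ladders are exhausted while the
    overall risk is still above the threshold; carries the report so far."""

    def __init__(self, message: str, report: "AnonymisationReport"):
        super().__init__(message)
        self.report = report


# ---------------------------------------------------------------------------
# plans

@dataclass(frozen=True)
class PlanStep:
    kind: str  # generalize_numeric | generalize_categorical | add_uniform_noise
    #        | suppress_column | suppress_cells
    params: tuple[tuple[str, Any], ...]

    @classmethod
    def make(cls, kind: str, **params: Any) -> "PlanStep":
        return cls(kind=kind, params=tuple(sorted(params.items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


@dataclass
class TransformPlan:
    """Per-quasi-identifier ladders of privacy transformations.

    Each ladder is ordered from mildest to harshest; successive steps must
    weakly coarsen (wider bands, higher hierarchy levels, finally
    suppression).  ``utility`` weights express how valuable a variable is to
    the intended research: among equally risk-reducing steps the engine
    transforms the *least* valuable variable first.
    """

    ladders: dict[str, list[PlanStep]]
    utility: dict[str, float] = field(default_factory=dict)

    def weight(self, var: str) -> float:
        return self.utility.get(var, 1.0)


def default_plan(cb: Codebook, table: str, utility: Mapping[str, float] | None = None
                 ) -> TransformPlan:
    """Build a sensible ladder for every quasi-identifier of *table*:
    numeric QIs get 5-, 10- and 20-wide bands then suppression; categorical
    QIs climb their codebook hierarchy then suppression."""
    ladders: dict[str, list[PlanStep]] = {}
    for v in quasi_identifiers(cb, table, "acquaintance"):
        steps: list[PlanStep] = []
        if v.value_type in ("integer", "real"):
            for w in (5, 10, 20):
                steps.append(PlanStep.make("generalize_numeric", width=w,
                                           anchor=0, integer=True))
        elif v.hierarchy:
            for i in range(1, len(v.hierarchy) + 1):
                steps.append(PlanStep.make("generalize_categorical", level=i))
        steps.append(PlanStep.make("suppress_column"))
        ladders[v.name] = steps
    return TransformPlan(ladders=ladders, utility=dict(utility or {}))


# ---------------------------------------------------------------------------
# reports

@dataclass
class AnonymisationReport:
    """The auditable record linking a release to its methodology."""

    input_fingerprint: str
    codebook_version: str
    context: dict
    trajectory: list[dict]
    final: RiskAssessment
    data_risk_public: DataRisk
    data_risk_acquaintance: DataRisk
    log: TransformLog
    variable_summary: dict[str, str]
    suppressed_cell_counts: dict[str, int]
    status: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "input_fingerprint": self.input_fingerprint,
            "codebook_version": self.codebook_version,
            "seed": self.seed,
            "context": self.context,
            "trajectory": self.trajectory,
            "final": self.final.to_dict(),
            "data_risk_public": self.data_risk_public.to_dict(),
            "data_risk_acquaintance": self.data_risk_acquaintance.to_dict(),
            "transform_log": json.loads(self.log.to_json()),
            "variable_summary": self.variable_summary,
            "suppressed_cell_counts": self.suppressed_cell_counts,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = [
            "Anonymisation report",
            "====================",
            f"status:             {self.status}",
            f"input fingerprint:  {self.input_fingerprint[:16]}…",
            f"codebook version:   {self.codebook_version}",
            f"threshold:          {self.final.threshold}",
            f"overall risk:       {self.final.overall:.6f}"
            f"  (T1={self.final.t1:.6f}, T2={self.final.t2:.6f},"
            f" T3={self.final.t3:.6f})",
            f"est. pop. uniques:  {self.final.est_population_uniques:.4f}",
            f"strict average ok:  {self.final.strict_average_ok}",
            "",
            "Risk trajectory:",
        ]
        traj = pd.DataFrame(self.trajectory)
        lines.append(traj.to_string(index=False))
        lines += ["", "Variable summary:"]
        for var, desc in self.variable_summary.items():
            lines.append(f"  {var}: {desc}")
        if self.suppressed_cell_counts:
            lines += ["", "Cells suppressed by anonymisation:"]
            for var, n in sorted(self.suppressed_cell_counts.items()):
                lines.append(f"  {var}: {n}")
        return "\n".join(lines)


def fingerprint_tables(tables: Mapping[str, pd.DataFrame]) -> str:
    h = hashlib.sha256()
    for name in sorted(tables):
        h.update(name.encode())
        h.update(tables[name].to_csv(index=False).encode())
    return h.hexdigest()


def build_report(
    trajectory: list[dict],
    log: TransformLog,
    final: RiskAssessment,
    *,
    input_fingerprint: str = "",
    codebook_version: str = "",
    context: dict | None = None,
    data_risk_public: DataRisk | None = None,
    data_risk_acquaintance: DataRisk | None = None,
    variable_summary: dict[str, str] | None = None,
    seed: int = 0,
) -> AnonymisationReport:
    """Assemble the report from a run's trajectory, transform log and final
    assessment; suppressed-cell counts are derived from the log."""
    if not trajectory:
        raise EngineError("report requires a non-empty risk trajectory")
    counts: dict[str, int] = {}
    for (_, _, var) in log.suppressed_cells():
        counts[var] = counts.get(var, 0) + 1
    return AnonymisationReport(
        input_fingerprint=input_fingerprint,
        codebook_version=codebook_version,
        context=context or {},
        trajectory=trajectory,
        final=final,
        data_risk_public=data_risk_public,
        data_risk_acquaintance=data_risk_acquaintance,
        log=log,
        variable_summary=variable_summary or {},
        suppressed_cell_counts=counts,
        status="certified" if final.certified else "not_certified",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# the loop

def _var_table(cb: Codebook, tables: Mapping[str, pd.DataFrame], var: str) -> str:
    for t in cb.tables:
        if t.name in tables and var in (v.name for v in t.variables):
            return t.name
    raise EngineError(f"variable {var!r} not found in any input table")


def _subject_qi_view(
    tables: Mapping[str, pd.DataFrame], cb: Codebook, key: str
) -> pd.DataFrame:
    """One row per subject with every quasi-identifier (joined across
    tables, first value per subject)."""
    pieces: list[pd.DataFrame] = []
    for t in cb.tables:
        if t.name not in tables:
            continue
        qis = [v.name for v in t.variables
               if v.privacy_class in ("quasi_public", "quasi_acquaintance")]
        present = [q for q in qis if q in tables[t.name].columns]
        if not present:
            continue
        piece = tables[t.name][[key] + present].groupby(key, sort=True).first()
        pieces.append(piece)
    if not pieces:
        base = pd.concat([df[[key]] for df in tables.values()])
        return base.drop_duplicates().set_index(key).sort_index()
    view = pieces[0]
    for piece in pieces[1:]:
        view = view.join(piece, how="outer")
    return view.sort_index()


def _step_seed(seed: int, var: str, step_index: int) -> int:
    h = hashlib.sha256(f"{seed}:{var}:{step_index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _apply_step(
    df: pd.DataFrame,
    var: str,
    step: PlanStep,
    spec: VariableSpec,
    seed: int,
    table_name: str | None = None,
    log: TransformLog | None = None,
    key: str | None = None,
) -> pd.DataFrame:
    p = step.param_dict
    if step.kind == "suppress_column":
        return transforms.suppress_column(df, var, table_name=table_name, log=log)
    out = df.copy()
    if step.kind == "generalize_numeric":
        out[var] = transforms.generalize_numeric(
            df[var], width=p["width"], anchor=p.get("anchor", 0),
            integer=p.get("integer", True), variable=var,
            table_name=table_name, log=log)
    elif step.kind == "generalize_categorical":
        out[var] = transforms.generalize_categorical(
            df[var], spec, p["level"], table_name=table_name, log=log)
    elif step.kind == "add_uniform_noise":
        out[var] = transforms.add_uniform_noise(
            df[var], k=p["k"], seed=seed, integer=p.get("integer", False),
            clip=tuple(spec.value_range) if spec.value_range else None,
            variable=var, table_name=table_name, log=log)
    elif step.kind == "suppress_cells":
        m = p.get("min_count", 5)
        counts = df[var].map(df[var].value_counts())
        mask = counts.notna() & (counts < m)
        out = transforms.suppress_cells(df, var, mask, key=key,
                                        table_name=table_name, log=log)
    else:
        raise EngineError(f"unknown transform kind {step.kind!r}")
    return out


def _evaluate(
    base_tables: Mapping[str, pd.DataFrame],
    cb: Codebook,
    ctx: ContextAssessment,
    key: str,
    plan: TransformPlan,
    state: Mapping[str, int],
    threshold: float,
    strict: bool,
    seed: int,
) -> RiskAssessment:
    """Risk of the release that would result from applying, for each QI, the
    ladder step selected in *state* (-1 = untransformed)."""
    tables = {name: df for name, df in base_tables.items()}
    for var, step_idx in state.items():
        if step_idx < 0:
            continue
        step = plan.ladders[var][step_idx]
        tname = _var_table(cb, tables, var)
        spec = cb.table(tname).variable(var)
        tables[tname] = _apply_step(
            tables[tname], var, step, spec, _step_seed(seed, var, step_idx),
            key=key)
    view = _subject_qi_view(tables, cb, key).reset_index()
    ra, _, _ = _assess_view(view, tables, cb, ctx, key, threshold, strict)
    return ra


def _assess_view(
    view: pd.DataFrame,
    tables: Mapping[str, pd.DataFrame],
    cb: Codebook,
    ctx: ContextAssessment,
    key: str,
    threshold: float,
    strict: bool,
) -> tuple[RiskAssessment, DataRisk, DataRisk]:
    pub = [c for c in view.columns if c != key and _privacy_class(cb, c) == "quasi_public"]
    acq = [c for c in view.columns if c != key and _privacy_class(cb, c)
           in ("quasi_public", "quasi_acquaintance")]
    pi = ctx.v if 0 < ctx.v < 1 else 1.0
    n = len(view)
    if n == 0:
        raise EngineError("no subjects found")
    dr_pub = riskmodel.compute_data_risk(_partition_or_trivial(view, pub, n), pi)
    dr_acq = riskmodel.compute_data_risk(_partition_or_trivial(view, acq, n), pi)
    t1, t2, t3 = riskmodel.attack_risks(dr_pub, dr_acq, ctx)
    ra = riskmodel.certify(
        t1, t2, t3, est_population_uniques=dr_pub.est_population_uniques,
        threshold=threshold, strict=strict)
    return ra, dr_pub, dr_acq


def _partition_or_trivial(view: pd.DataFrame, qis: list[str], n: int
                          ) -> EquivalencePartition:
    if qis:
        return riskmodel.partition(view, qis)
    # every quasi-identifier suppressed: all records indistinguishable
    return EquivalencePartition(classes={(): n}, n=n)


def _privacy_class(cb: Codebook, var: str) -> str:
    for t in cb.tables:
        for v in t.variables:
            if v.name == var:
                return v.privacy_class
    return "other"


def anonymise(
    tables: Mapping[str, pd.DataFrame],
    cb: Codebook,
    ctx: ContextAssessment,
    plan: TransformPlan | None = None,
    threshold: float = RISK_THRESHOLD,
    seed: int = 0,
    strict: bool = True,
    study: str | None = None,
    link: LinkFile | None = None,
) -> tuple[dict[str, pd.DataFrame], LinkFile, AnonymisationReport]:
    """Anonymise a set of study tables until the release certifies.

    Returns the released tables, the protected link file (to be stored
    separately from the release) and the anonymisation report.  Raises
    :class:`CannotCertifyError`, carrying the report so far, if the plan's
    ladders are exhausted while the risk is still above the threshold.
    """
    from .codebook import validate_table

    for name, df in tables.items():
        res = validate_table(cb, name, df, study=study)
        fatal = [f for f in res.findings if f.kind != "extra_column"]
        if fatal:
            raise EngineError(
                f"table {name!r} fails codebook validation: "
                + "; ".join(f"{f.kind}:{f.column}" for f in fatal[:10])
            )

    keys = {cb.table(name).key for name in tables}
    if len(keys) != 1:
        raise EngineError(f"tables disagree on the subject key: {sorted(keys)}")
    key = keys.pop()
    fingerprint = fingerprint_tables(tables)
    log = TransformLog()

    # --- mandatory steps -------------------------------------------------
    work, linkfile = transforms.pseudonymise(tables, key, seed, log=log, link=link)

    # per-subject reference date: earliest date across all date variables
    ref_dates: dict[str, Any] = {}
    for name, df in work.items():
        date_vars = [v.name for v in cb.table(name).variables
                     if v.value_type == "date" and v.name in df.columns]
        for var in date_vars:
            for sid, val in zip(df[key], df[var]):
                d = transforms._parse_date(val)
                if d is None:
                    continue
                sid = str(sid)
                if sid not in ref_dates or d < ref_dates[sid]:
                    ref_dates[sid] = d
    for name in list(work):
        date_vars = [v.name for v in cb.table(name).variables
                     if v.value_type == "date" and v.name in work[name].columns]
        if date_vars:
            work[name] = transforms.to_relative_days(
                work[name], date_vars, ref_dates, key=key,
                table_name=name, log=log)

    for name in list(work):
        direct = [v.name for v in cb.table(name).variables
                  if v.privacy_class == "direct_identifier"
                  and v.name != key and v.name in work[name].columns]
        for var in direct:
            work[name] = transforms.suppress_column(
                work[name], var, table_name=name, log=log)

    # --- greedy ladder loop ----------------------------------------------
    plan = plan or default_plan(cb, _subject_table_name(cb, tables))
    ladder_vars = [v for v in _codebook_order(cb)
                   if v in plan.ladders and _var_in_tables(work, v)]
    state: dict[str, int] = {v: -1 for v in ladder_vars}

    ra = _evaluate(work, cb, ctx, key, plan, state, threshold, strict, seed)
    trajectory = [_traj_entry(0, ra, None, None)]
    iteration = 0
    while not ra.certified:
        candidates: list[tuple[float, float, int, str, RiskAssessment]] = []
        for order, var in enumerate(ladder_vars):
            nxt = state[var] + 1
            if nxt >= len(plan.ladders[var]):
                continue
            trial = dict(state)
            trial[var] = nxt
            ra_c = _evaluate(work, cb, ctx, key, plan, trial, threshold,
                             strict, seed)
            candidates.append((ra_c.overall, plan.weight(var), order, var, ra_c))
        if not candidates:
            final, dr_pub, dr_acq = _finalize(work, cb, ctx, key, plan, state,
                                              threshold, strict, seed, log)
            report = build_report(
                trajectory, log, final, input_fingerprint=fingerprint,
                codebook_version=cb.version, context=ctx.to_dict(),
                data_risk_public=dr_pub, data_risk_acquaintance=dr_acq,
                variable_summary=_summary(plan, state, ladder_vars), seed=seed)
            raise CannotCertifyError(
                f"transformation ladders exhausted at overall risk "
                f"{ra.overall:.4f} > threshold {threshold}", report)
        overall, _, _, var, ra = min(candidates, key=lambda c: (c[0], c[1], c[2]))
        state[var] += 1
        iteration += 1
        step = plan.ladders[var][state[var]]
        trajectory.append(_traj_entry(iteration, ra, var, step))

    released, final, dr_pub, dr_acq = _finalize_release(
        work, cb, ctx, key, plan, state, threshold, strict, seed, log)
    report = build_report(
        trajectory, log, final, input_fingerprint=fingerprint,
        codebook_version=cb.version, context=ctx.to_dict(),
        data_risk_public=dr_pub, data_risk_acquaintance=dr_acq,
        variable_summary=_summary(plan, state, ladder_vars), seed=seed)
    return released, linkfile, report


def _finalize_release(work, cb, ctx, key, plan, state, threshold, strict, seed, log):
    released = {name: df.copy() for name, df in work.items()}
    for var, step_idx in state.items():
        if step_idx < 0:
            continue
        step = plan.ladders[var][step_idx]
        tname = _var_table(cb, released, var)
        spec = cb.table(tname).variable(var)
        released[tname] = _apply_step(
            released[tname], var, step, spec, _step_seed(seed, var, step_idx),
            table_name=tname, log=log, key=key)
    view = _subject_qi_view(released, cb, key).reset_index()
    final, dr_pub, dr_acq = _assess_view(view, released, cb, ctx, key,
                                         threshold, strict)
    return released, final, dr_pub, dr_acq


def _finalize(work, cb, ctx, key, plan, state, threshold, strict, seed, log):
    _, final, dr_pub, dr_acq = _finalize_release(
        work, cb, ctx, key, plan, state, threshold, strict, seed, log)
    return final, dr_pub, dr_acq


def _traj_entry(iteration: int, ra: RiskAssessment, var: str | None,
                step: PlanStep | None) -> dict:
    return {
        "iteration": iteration,
        "variable": var,
        "step": step.kind if step else None,
        "params": step.param_dict if step else None,
        "t1": ra.t1, "t2": ra.t2, "t3": ra.t3,
        "overall": ra.overall,
        "est_population_uniques": ra.est_population_uniques,
    }


def _summary(plan: TransformPlan, state: Mapping[str, int],
             ladder_vars: Sequence[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for var in ladder_vars:
        idx = state[var]
        if idx < 0:
            out[var] = "untouched"
        else:
            step = plan.ladders[var][idx]
            out[var] = f"{step.kind}({', '.join(f'{k}={v}' for k, v in step.params)})"
    return out


def _codebook_order(cb: Codebook) -> list[str]:
    out = []
    for t in cb.tables:
        for v in t.variables:
            if v.name not in out:
                out.append(v.name)
    return out


def _var_in_tables(tables: Mapping[str, pd.DataFrame], var: str) -> bool:
    return any(var in df.columns for df in tables.values())


def _subject_table_name(cb: Codebook, tables: Mapping[str, pd.DataFrame]) -> str:
    for t in cb.tables:
        if t.subject_table and t.name in tables:
            return t.name
    return next(iter(tables))


# ---------------------------------------------------------------------------
# replay

def replay(
    tables: Mapping[str, pd.DataFrame],
    log: TransformLog,
    cb: Codebook,
    link: LinkFile,
) -> dict[str, pd.DataFrame]:
    """Re-apply a transform log to the original tables, reproducing the
    released tables exactly (the audit property of the report)."""
    work = {name: df.copy() for name, df in tables.items()}
    for e in log.entries:
        p = e.params
        if e.kind == "pseudonymise":
            df = work[e.table]
            df = df.copy()
            df[e.variable] = [link.mapping[str(v)] for v in df[e.variable]]
            work[e.table] = df
        elif e.kind == "relative_days":
            refs = {k: v for k, v in p["ref_dates"].items()}
            work[e.table] = transforms.to_relative_days(
                work[e.table], [e.variable], refs, key=p["key"],
                table_name=e.table)
        elif e.kind == "suppress_column":
            work[e.table] = transforms.suppress_column(work[e.table], e.variable)
        elif e.kind == "suppress_cells":
            df = work[e.table]
            keycol = p.get("key")
            keys = set(p["suppressed_keys"])
            if keycol:
                mask = df[keycol].astype(str).isin(keys)
            else:
                mask = df.index.astype(str).isin(keys)
            work[e.table] = transforms.suppress_cells(
                df, e.variable, pd.Series(mask, index=df.index))
        elif e.kind == "generalize_numeric":
            df = work[e.table].copy()
            df[e.variable] = transforms.generalize_numeric(
                df[e.variable], width=p["width"], anchor=p.get("anchor", 0),
                integer=p.get("integer", True))
            work[e.table] = df
        elif e.kind == "generalize_categorical":
            tname = e.table
            spec = cb.table(tname).variable(e.variable)
            df = work[tname].copy()
            df[e.variable] = transforms.generalize_categorical(
                df[e.variable], spec, p["level"])
            work[tname] = df
        elif e.kind == "add_uniform_noise":
            df = work[e.table].copy()
            spec = cb.table(e.table).variable(e.variable)
            df[e.variable] = transforms.add_uniform_noise(
                df[e.variable], k=p["k"], seed=p["seed"],
                integer=p.get("integer", False),
                clip=tuple(p["clip"]) if p.get("clip") else None)
            work[e.table] = df
        else:
            raise EngineError(f"cannot replay unknown transform {e.kind!r}")
    return work
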