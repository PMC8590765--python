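"""ETL, QC and versioned releases.

Per-study source tables are harmonised through the codebook — aliases
resolved, types validated — and pooled into a generic relational store: a
long entity–attribute–value observations table in SQLite, with provenance
columns (source table, source row) on every observation.

QC reports per-variable missingness, structural anomalies (values outside
declared ranges or categories), and the *anonymisation reconciliation*: with
the anonymisation report in hand, every missing cell is classified as either
source-missing (never captured) or suppressed by the anonymisation, so that
downstream analysts can tell the two apart.

A data release is a snapshot: a deterministic canonical serialisation of the
store, content-hashed (SHA-256, order-independent), carrying the codebook
version and an optional pointer to its upstream snapshot to form a
provenance chain.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, Mapping

import pandas as pd

from .codebook import Codebook, Finding, is_missing, resolve_aliases, validate_table
from .engine import AnonymisationReport


class WrangleError(ValueError):
    pass


class ReferentialError(WrangleError):
    pass


#: finding kinds expected to differ between a source codebook and an
#: anonymised release derived from it: suppressed columns are absent, banded
#: numeric values are no longer numeric, coarsened categories are no longer
#: in the source category list
RELEASE_WAIVE = ("extra_column", "missing_column", "type_violation",
                 "out_of_category", "out_of_range")


_SCHEMA = """
CREATE TABLE IF NOT EXISTS studies (study TEXT PRIMARY KEY);
CREATE TABLE IF NOT EXISTS subjects (
    subject TEXT PRIMARY KEY,
    study TEXT NOT NULL REFERENCES studies(study)
);
CREATE TABLE IF NOT EXISTS observations (
    subject TEXT NOT NULL REFERENCES subjects(subject),
    study TEXT NOT NULL,
    source_table TEXT NOT NULL,
    source_row INTEGER NOT NULL,
    variable TEXT NOT NULL,
    visit TEXT,
    value TEXT
);
"""


class RelationalStore:
    """Pooled long-form store: studies, subjects and observations."""

    def __init__(self, path: str = ":memory:"):
        self.conn = sqlite3.connect(path)
        self.conn.executescript(_SCHEMA)

    def add_study(self, study: str) -> None:
        self.conn.execute("INSERT OR IGNORE INTO studies VALUES (?)", (study,))

    def add_subject(self, subject: str, study: str) -> None:
        self.conn.execute(
            "INSERT OR IGNORE INTO subjects VALUES (?, ?)", (subject, study))

    def add_observation(self, subject: str, study: str, source_table: str,
                        source_row: int, variable: str, visit: str | None,
                        value: str | None) -> None:
        row = self.conn.execute(
            "SELECT 1 FROM subjects WHERE subject = ?", (subject,)).fetchone()
        if row is None:
            raise ReferentialError(
                f"observation references unknown subject {subject!r} "
                f"(study {study!r}, table {source_table!r})")
        self.conn.execute(
            "INSERT INTO observations VALUES (?, ?, ?, ?, ?, ?, ?)",
            (subject, study, source_table, source_row, variable, visit, value))

    def observations(self) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT * FROM observations", self.conn)

    def subjects(self) -> pd.DataFrame:
        return pd.read_sql_query("SELECT * FROM subjects", self.conn)

    def studies(self) -> list[str]:
        return [r[0] for r in
                self.conn.execute("SELECT study FROM studies ORDER BY study")]


def _cell_str(v: Any) -> str | None:
    if is_missing(v):
        return None
    s = str(v)
    # normalise float-formatted integers ("42.0" -> "42")
    try:
        f = float(s)
        if f == int(f) and ("." in s or "e" in s.lower()):
            return str(int(f))
    except (ValueError, OverflowError):
        pass
    return s


def harmonise(
    study_tables: Mapping[str, Mapping[str, pd.DataFrame]],
    cb: Codebook,
    path: str = ":memory:",
    waive: tuple[str, ...] = ("extra_column",),
) -> RelationalStore:
    """Pool per-study source tables into the relational store.

    Each table is alias-resolved and validated first; any finding whose kind
    is not waived is fatal.  Subjects are registered from the codebook's
    subject table before other tables are loaded, so an observation that
    references an unknown subject fails with a referential error.  Row
    counts are conserved: every source row is traceable through its
    (source table, source row) provenance.
    """
    store = RelationalStore(path)
    subject_tables = [t.name for t in cb.tables if t.subject_table]

    resolved: dict[str, dict[str, pd.DataFrame]] = {}
    for study, tables in study_tables.items():
        store.add_study(study)
        resolved[study] = {}
        for tname, df in tables.items():
            res = validate_table(cb, tname, df, study=study)
            fatal = [f for f in res.findings if f.kind not in waive]
            if fatal:
                msgs = "; ".join(
                    f"{f.kind}: {study}/{tname}/{f.column}" for f in fatal[:10])
                raise WrangleError(f"validation failed: {msgs}")
            resolved[study][tname] = resolve_aliases(cb, tname, df, study=study)

    # register subjects first (demography-type tables)
    for study, tables in resolved.items():
        for tname in subject_tables:
            if tname not in tables:
                continue
            key = cb.table(tname).key
            for subj in tables[tname][key]:
                store.add_subject(str(subj), study)

    for study, tables in resolved.items():
        for tname, df in tables.items():
            spec = cb.table(tname)
            # every non-key column becomes an observation; released tables may
            # carry derived columns (e.g. *_day) beyond the codebook's list
            declared = [c for c in df.columns if c != spec.key]
            has_visit = "visit_number" in df.columns
            for i, row in enumerate(df.itertuples(index=False)):
                rowd = dict(zip(df.columns, row))
                subj = str(rowd[spec.key])
                visit = _cell_str(rowd["visit_number"]) if has_visit else None
                for var in declared:
                    store.add_observation(
                        subj, study, tname, i, var, visit,
                        _cell_str(rowd[var]))
    store.conn.commit()
    return store


def export_tables(store: RelationalStore, cb: Codebook
                  ) -> dict[str, dict[str, pd.DataFrame]]:
    """Reconstruct wide per-study tables from the store (inverse of
    :func:`harmonise` up to provenance renumbering)."""
    obs = store.observations()
    subj = store.subjects().set_index("subject")["study"].to_dict()
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for (study, tname), grp in obs.groupby(["study", "source_table"]):
        spec = cb.table(tname)
        rows = []
        for (subject, srow), cells in grp.groupby(["subject", "source_row"]):
            row = {spec.key: subject}
            for _, c in cells.iterrows():
                row[c["variable"]] = c["value"]
            rows.append(((subject, srow), row))
        rows.sort(key=lambda r: r[0])
        cols = [spec.key] + [v.name for v in spec.variables
                             if v.name != spec.key]
        df = pd.DataFrame([r[1] for r in rows])
        ordered = [c for c in cols if c in df.columns]
        ordered += [c for c in df.columns if c not in ordered]
        df = df.reindex(columns=ordered)
        out.setdefault(study, {})[tname] = df
    return out


# ---------------------------------------------------------------------------
# QC

@dataclass
class QCResult:
    missingness: dict[str, float]
    findings: list[Finding]
    reconciliation: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {"missingness": self.missingness,
             "findings": [f.to_dict() for f in self.findings],
             "reconciliation": self.reconciliation}, indent=2)


def missing_cells(
    tables: Mapping[str, pd.DataFrame],
    cb: Codebook,
    key_map: Mapping[str, str] | None = None,
) -> set[tuple[str, str, str]]:
    """Coordinates (table, subject, variable) of every missing cell in a set
    of wide tables.  *key_map* translates subject ids, e.g. original to
    anonymised via the link file, so source coordinates can be compared with
    a release."""
    cells: set[tuple[str, str, str]] = set()
    for name, df in tables.items():
        key = cb.table(name).key
        for _, row in df.iterrows():
            subj = str(row[key])
            if key_map is not None:
                subj = key_map.get(subj, subj)
            for col in df.columns:
                if col != key and is_missing(row[col]):
                    cells.add((name, subj, col))
    return cells


def qc_checks(
    store: RelationalStore,
    cb: Codebook,
    report: AnonymisationReport | None = None,
    source_missing: set[tuple[str, str, str]] | None = None,
) -> QCResult:
    """Missingness, structural anomalies, and — when the anonymisation
    report is available — reconciliation of every missing cell as
    source-missing vs suppressed-by-anonymisation.

    With *source_missing* (coordinates from :func:`missing_cells` on the
    pre-anonymisation tables, subject ids mapped through the link file), a
    missing cell that is neither suppressed by the log nor missing at source
    is counted as *unexplained*; without it, non-suppressed missing cells
    are attributed to the source."""
    obs = store.observations()
    missingness: dict[str, float] = {}
    findings: list[Finding] = []

    for (tname, var), grp in obs.groupby(["source_table", "variable"]):
        n = len(grp)
        n_missing = int(grp["value"].isna().sum())
        missingness[f"{tname}.{var}"] = n_missing / n if n else 0.0
        try:
            spec = cb.table(tname).variable(var)
        except Exception:
            spec = None
        if spec is None:
            continue
        if spec.value_range is not None and spec.value_type in ("integer", "real"):
            lo, hi = spec.value_range
            for _, c in grp.dropna(subset=["value"]).iterrows():
                try:
                    x = float(c["value"])
                except ValueError:
                    continue
                if not lo <= x <= hi:
                    findings.append(Finding(
                        "range_anomaly", column=f"{tname}.{var}",
                        value=c["value"],
                        message=f"value {x} outside [{lo}, {hi}] "
                                f"(subject {c['subject']})"))
        if spec.value_type == "category" and spec.categories is not None:
            for _, c in grp.dropna(subset=["value"]).iterrows():
                if c["value"] not in spec.categories:
                    findings.append(Finding(
                        "out_of_category", column=f"{tname}.{var}",
                        value=c["value"],
                        message=f"subject {c['subject']}"))

    recon = {"suppressed": 0, "source_missing": 0, "unexplained": 0}
    if report is not None:
        suppressed = report.log.suppressed_cells()
        for _, c in obs[obs["value"].isna()].iterrows():
            coord = (c["source_table"], c["subject"], c["variable"])
            if coord in suppressed:
                recon["suppressed"] += 1
            elif source_missing is None or coord in source_missing:
                recon["source_missing"] += 1
            else:
                recon["unexplained"] += 1
    else:
        recon["source_missing"] = int(obs["value"].isna().sum())
    return QCResult(missingness=missingness, findings=findings,
                    reconciliation=recon)


# ---------------------------------------------------------------------------
# releases

@dataclass
class ReleaseSnapshot:
    version: str
    content_hash: str
    codebook_version: str
    created: str
    qc_summary: dict = field(default_factory=dict)
    parent: str | None = None

    def to_dict(self) -> dict:
        return {
            "version": self.version, "content_hash": self.content_hash,
            "codebook_version": self.codebook_version, "created": self.created,
            "qc_summary": self.qc_summary, "parent": self.parent,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def canonical_serialization(store: RelationalStore) -> str:
    """Deterministic RFC-4180 text form of the store's content.

    Provenance row numbers and creation metadata are excluded and rows are
    sorted, so the hash depends only on the data cells — identical content
    gives an identical hash regardless of input row order.
    """
    obs = store.observations()[
        ["study", "subject", "source_table", "variable", "visit", "value"]
    ].fillna("")
    obs = obs.sort_values(list(obs.columns), kind="mergesort")
    return obs.to_csv(index=False, lineterminator="\n")


def snapshot(
    store: RelationalStore,
    cb: Codebook,
    qc: QCResult | None = None,
    version: str | None = None,
    parent: str | None = None,
) -> ReleaseSnapshot:
    content = canonical_serialization(store)
    digest = hashlib.sha256(content.encode()).hexdigest()
    summary: dict = {}
    if qc is not None:
        summary = {
            "n_findings": len(qc.findings),
            "reconciliation": qc.reconciliation,
            "mean_missingness": (
                sum(qc.missingness.values()) / len(qc.missingness)
                if qc.missingness else 0.0),
        }
    return ReleaseSnapshot(
        version=version or digest[:12],
        content_hash=digest,
        codebook_version=cb.version,
        created=datetime.now(timezone.utc).isoformat(),
        qc_summary=summary,
        parent=parent,
    )


def diff_releases(a: RelationalStore, b: RelationalStore) -> dict:
    """Row-level change summary between two stores, keyed by provenance
    (study, subject, source table, source row, variable)."""
    keycols = ["study", "subject", "source_table", "source_row", "variable"]

    def indexed(store: RelationalStore) -> dict[tuple, Any]:
        obs = store.observations()
        return {
            tuple(row[k] for k in keycols): row["value"]
            for _, row in obs.iterrows()
        }

    da, db = indexed(a), indexed(b)
    added = sorted(k for k in db if k not in da)
    removed = sorted(k for k in da if k not in db)
    changed = sorted(
        k for k in da if k in db and (da[k] or "") != (db[k] or ""))
    return {
        "added": [list(k) for k in added],
        "removed": [list(k) for k in removed],
        "changed": [
            {"key": list(k), "old": da[k], "new": db[k]} for k in changed],
    }
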