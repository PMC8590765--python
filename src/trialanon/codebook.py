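"""Machine-readable codebooks: the data specification that drives everything else.

A codebook describes every table of a study pool — its subject key, its
variables, their types and allowed values — and, crucially for disclosure
control, the *privacy class* of each variable:

``direct_identifier``
    uniquely identifying on its own (patient number, site id); removed or
    pseudonymised before release.
``quasi_public``
    knowable by any adversary from public registries (age, sex, region).
``quasi_acquaintance``
    knowable by acquaintances — neighbours, relatives, co-workers — such as
    medical history or key event dates.  The acquaintance quasi-identifier
    set always *includes* the public one.
``sensitive`` / ``date`` / ``other``
    analysis payload, calendar dates (offset to study days on release), and
    everything else.

Variables may carry a *generalization hierarchy*: an ordered ladder of
coarsenings (e.g. country → region → continent).  Each level must be a strict
coarsening of the previous one — blocks only ever merge, never split — which
is what guarantees that walking up the ladder can only lower re-identification
risk.

The on-disk dialect is a single YAML document per project (see
``load_codebook``); a content hash of the canonical form serves as the
codebook version.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

PRIVACY_CLASSES = (
    "direct_identifier",
    "quasi_public",
    "quasi_acquaintance",
    "sensitive",
    "date",
    "other",
)
VALUE_TYPES = ("integer", "real", "category", "date", "text")

#: canonical missing sentinel on disk (empty field); in memory we accept
#: None / NaN / "" interchangeably and normalise via :func:`is_missing`.
MISSING = ""

_ISO_DATE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


class CodebookError(ValueError):
    """Raised for parse failures and invariant violations in a codebook."""


def is_missing(value: Any) -> bool:
    """True if *value* is the missing sentinel in any of its spellings."""
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return value is pd.NA or value is pd.NaT


@dataclass(frozen=True)
class HierarchyLevel:
    """One rung of a generalization ladder: raw value -> block label."""

    name: str
    mapping: Mapping[str, str]


@dataclass
class VariableSpec:
    name: str
    privacy_class: str
    value_type: str
    units: str | None = None
    categories: list[str] | None = None
    value_range: tuple[float, float] | None = None
    hierarchy: list[HierarchyLevel] = field(default_factory=list)
    aliases: list[str] = field(default_factory=list)

    def validate(self) -> list[str]:
        problems: list[str] = []
        if self.privacy_class not in PRIVACY_CLASSES:
            problems.append(
                f"variable {self.name!r}: unknown privacy_class {self.privacy_class!r}"
            )
        if self.value_type not in VALUE_TYPES:
            problems.append(
                f"variable {self.name!r}: unknown value_type {self.value_type!r}"
            )
        if self.privacy_class == "date" and self.value_type != "date":
            problems.append(
                f"variable {self.name!r}: privacy_class 'date' requires value_type "
                f"'date', got {self.value_type!r}"
            )
        problems.extend(self._validate_hierarchy())
        return problems

    def _validate_hierarchy(self) -> list[str]:
        """Check the ladder strictly coarsens: same block at level i implies
        same block at level i+1, for every pair of raw values."""
        problems: list[str] = []
        if not self.hierarchy:
            return problems
        domain = set(self.hierarchy[0].mapping)
        for level in self.hierarchy[1:]:
            if set(level.mapping) != domain:
                problems.append(
                    f"variable {self.name!r}: hierarchy level {level.name!r} does "
                    "not cover the same raw values as the first level"
                )
        for prev, nxt in zip(self.hierarchy, self.hierarchy[1:]):
            # group raw values by their block at `prev`; each block must map
            # to a single block at `nxt` (blocks are unions, never splits)
            blocks: dict[str, set[str]] = {}
            for raw in prev.mapping:
                if raw not in nxt.mapping:
                    continue
                blocks.setdefault(prev.mapping[raw], set()).add(nxt.mapping[raw])
            for label, targets in blocks.items():
                if len(targets) > 1:
                    problems.append(
                        f"variable {self.name!r}: hierarchy level {nxt.name!r} "
                        f"splits block {label!r} of level {prev.name!r} into "
                        f"{sorted(targets)}"
                    )
        return problems

    def level_index(self, level: int | str) -> int:
        """Resolve a ladder level given by position (0 = raw) or by name."""
        if isinstance(level, int):
            if not 0 <= level <= len(self.hierarchy):
                raise CodebookError(
                    f"variable {self.name!r}: hierarchy level {level} out of range"
                )
            return level
        for i, lv in enumerate(self.hierarchy, start=1):
            if lv.name == level:
                return i
        raise CodebookError(f"variable {self.name!r}: unknown hierarchy level {level!r}")


@dataclass
class TableSpec:
    name: str
    key: str
    variables: list[VariableSpec]
    subject_table: bool = False

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise CodebookError(f"table {self.name!r}: unknown variable {name!r}")

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]


@dataclass
class Codebook:
    tables: list[TableSpec]
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            self.version = self.content_hash()[:12]

    def table(self, name: str) -> TableSpec:
        for t in self.tables:
            if t.name == name:
                return t
        raise CodebookError(f"unknown table {name!r}")

    @property
    def table_names(self) -> list[str]:
        return [t.name for t in self.tables]

    def content_hash(self) -> str:
        canon = json.dumps(_to_dict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def validate(self) -> None:
        problems: list[str] = []
        for t in self.tables:
            if t.key not in t.variable_names:
                problems.append(
                    f"table {t.name!r}: subject-key column {t.key!r} is not a "
                    "declared variable"
                )
            seen: set[str] = set()
            for v in t.variables:
                if v.name in seen:
                    problems.append(f"table {t.name!r}: duplicate variable {v.name!r}")
                seen.add(v.name)
                problems.extend(f"table {t.name!r}: {p}" for p in v.validate())
            # aliases unique within a table role
            alias_owner: dict[str, str] = {}
            for v in t.variables:
                for a in v.aliases:
                    if a in alias_owner and alias_owner[a] != v.name:
                        problems.append(
                            f"table {t.name!r}: alias {a!r} claimed by both "
                            f"{alias_owner[a]!r} and {v.name!r}"
                        )
                    alias_owner[a] = v.name
        if problems:
            raise CodebookError(
                "codebook invariant violations:\n  - " + "\n  - ".join(problems)
            )


# ---------------------------------------------------------------------------
# loading

def _parse_variable(raw: Mapping[str, Any], table: str) -> VariableSpec:
    try:
        name = str(raw["name"])
        pclass = str(raw["privacy_class"])
        vtype = str(raw["value_type"])
    except KeyError as exc:  # pragma: no cover - defensive
        raise CodebookError(
            f"table {table!r}: variable entry missing field {exc}"
        ) from None
    hierarchy = []
    for lev in raw.get("hierarchy", []) or []:
        hierarchy.append(
            HierarchyLevel(
                name=str(lev["name"]),
                mapping={str(k): str(v) for k, v in lev["map"].items()},
            )
        )
    rng = raw.get("range")
    return VariableSpec(
        name=name,
        privacy_class=pclass,
        value_type=vtype,
        units=raw.get("units"),
        categories=[str(c) for c in raw["categories"]] if raw.get("categories") else None,
        value_range=(float(rng[0]), float(rng[1])) if rng else None,
        hierarchy=hierarchy,
        aliases=[str(a) for a in raw.get("aliases", []) or []],
    )


def codebook_from_dict(doc: Mapping[str, Any]) -> Codebook:
    if not isinstance(doc, Mapping) or "tables" not in doc:
        raise CodebookError("codebook document must be a mapping with a 'tables' list")
    tables = []
    for traw in doc["tables"]:
        tables.append(
            TableSpec(
                name=str(traw["name"]),
                key=str(traw["key"]),
                variables=[_parse_variable(v, traw["name"]) for v in traw["variables"]],
                subject_table=bool(traw.get("subject_table", False)),
            )
        )
    cb = Codebook(tables=tables, version=str(doc.get("version", "")))
    cb.validate()
    return cb


def load_codebook(path: str) -> Codebook:
    """Load and validate a codebook from its YAML document.

    Parse errors are fatal and carry line context from the YAML parser;
    invariant violations are fatal and list every violation found.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise CodebookError(f"cannot parse codebook {path}: {exc}") from exc
    return codebook_from_dict(doc)


def _to_dict(cb: Codebook) -> dict:
    return {
        "tables": [
            {
                "name": t.name,
                "key": t.key,
                "subject_table": t.subject_table,
                "variables": [
                    {
                        "name": v.name,
                        "privacy_class": v.privacy_class,
                        "value_type": v.value_type,
                        "units": v.units,
                        "categories": v.categories,
                        "range": list(v.value_range) if v.value_range else None,
                        "hierarchy": [
                            {"name": h.name, "map": dict(h.mapping)}
                            for h in v.hierarchy
                        ]
                        or None,
                        "aliases": v.aliases or None,
                    }
                    for v in t.variables
                ],
            }
            for t in cb.tables
        ]
    }


def dump_codebook(cb: Codebook, path: str) -> None:
    doc = _to_dict(cb)
    doc["version"] = cb.version
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# queries

def quasi_identifiers(cb: Codebook, table: str, attack: str) -> list[VariableSpec]:
    """Quasi-identifiers of *table* for an attack model, in codebook order.

    ``attack="public"`` returns the registry-knowable QIs only;
    ``attack="acquaintance"`` returns the public QIs plus those an
    acquaintance would know — always a superset of the public list.
    """
    if attack not in ("public", "acquaintance"):
        raise CodebookError(f"unknown attack type {attack!r}")
    wanted = {"quasi_public"}
    if attack == "acquaintance":
        wanted.add("quasi_acquaintance")
    return [v for v in cb.table(table).variables if v.privacy_class in wanted]


# ---------------------------------------------------------------------------
# alias resolution and validation

def resolve_aliases(
    cb: Codebook, table_name: str, table: pd.DataFrame, study: str | None = None
) -> pd.DataFrame:
    """Rename study-specific source columns to their canonical names.

    An alias may be scoped to a study as ``"STUDY:colname"``; unscoped aliases
    apply to every study.  Resolution is idempotent: canonical columns are
    left untouched.
    """
    spec = cb.table(table_name)
    rename: dict[str, str] = {}
    for v in spec.variables:
        for a in v.aliases:
            if ":" in a:
                scope, col = a.split(":", 1)
                if study is not None and scope == study:
                    rename[col] = v.name
            else:
                rename[a] = v.name
    # never clobber an existing canonical column
    rename = {
        src: dst for src, dst in rename.items()
        if src in table.columns and dst not in table.columns
    }
    return table.rename(columns=rename)


@dataclass
class Finding:
    kind: str
    column: str | None = None
    row: int | None = None
    value: Any = None
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "column": self.column,
            "row": self.row,
            "value": None if self.value is None else str(self.value),
            "message": self.message,
        }


@dataclass
class ValidationResult:
    table: str
    findings: list[Finding]

    @property
    def passed(self) -> bool:
        return not self.findings

    def to_json(self) -> str:
        return json.dumps(
            {"table": self.table, "passed": self.passed,
             "findings": [f.to_dict() for f in self.findings]},
            indent=2,
        )


def _parses_as(value: Any, vtype: str) -> bool:
    if vtype == "text":
        return True
    s = str(value).strip()
    if vtype == "integer":
        try:
            f = float(s)
        except ValueError:
            return False
        return f == int(f)
    if vtype == "real":
        try:
            float(s)
        except ValueError:
            return False
        return True
    if vtype == "date":
        if isinstance(value, (date, datetime)):
            return True
        if not _ISO_DATE.match(s):
            return False
        try:
            date.fromisoformat(s)
        except ValueError:
            return False
        return True
    return True


def validate_table(
    cb: Codebook,
    table_name: str,
    table: pd.DataFrame,
    study: str | None = None,
) -> ValidationResult:
    """Structural (source) validation of one table against its spec.

    Deviations are data, not exceptions: the result lists missing/extra
    columns (after alias resolution), type violations, out-of-category and
    out-of-range values, and duplicate subject keys.  An empty finding list
    means the table passes.
    """
    spec = cb.table(table_name)
    df = resolve_aliases(cb, table_name, table, study=study)
    findings: list[Finding] = []

    declared = set(spec.variable_names)
    present = list(df.columns)
    for col in spec.variable_names:
        if col not in present:
            findings.append(
                Finding("missing_column", column=col,
                        message=f"declared column {col!r} absent")
            )
    for col in present:
        if col not in declared:
            findings.append(
                Finding("extra_column", column=col,
                        message=f"column {col!r} not declared in codebook")
            )

    if spec.key in df.columns:
        dup = df[spec.key][df[spec.key].duplicated()]
        if spec.subject_table:
            for idx in dup.index:
                findings.append(
                    Finding("duplicate_key", column=spec.key, row=int(idx),
                            value=df.at[idx, spec.key],
                            message="duplicate subject key")
                )

    for v in spec.variables:
        if v.name not in df.columns:
            continue
        col = df[v.name]
        for idx, val in col.items():
            if is_missing(val):
                continue
            if not _parses_as(val, v.value_type):
                findings.append(
                    Finding("type_violation", column=v.name, row=int(idx), value=val,
                            message=f"not a valid {v.value_type}")
                )
                continue
            if v.value_type == "category" and v.categories is not None:
                if str(val) not in v.categories:
                    findings.append(
                        Finding("out_of_category", column=v.name, row=int(idx),
                                value=val,
                                message=f"value {val!r} not in declared categories")
                    )
            if v.value_range is not None and v.value_type in ("integer", "real"):
                x = float(val)
                lo, hi = v.value_range
                if not (lo <= x <= hi):
                    findings.append(
                        Finding("out_of_range", column=v.name, row=int(idx), value=val,
                                message=f"value {x} outside [{lo}, {hi}]")
                    )
    return ValidationResult(table=table_name, findings=findings)
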