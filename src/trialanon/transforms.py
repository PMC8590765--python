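"""Privacy transformations: pseudonymisation, date offsetting, generalization,
suppression, noise, and metadata scrubbing.

Every transform is a pure function of (input, parameters, seed) and records a
log entry; replaying a :class:`TransformLog` on the original tables (with the
original link file) reproduces the released tables exactly.  That replay
property is what makes the anonymisation report auditable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codebook import VariableSpec, is_missing


class TransformError(ValueError):
    pass


# ---------------------------------------------------------------------------
# logging

@dataclass
class TransformLogEntry:
    kind: str
    table: str | None
    variable: str | None
    params: dict
    n_affected: int

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "table": self.table, "variable": self.variable,
            "params": self.params, "n_affected": self.n_affected,
        }


@dataclass
class TransformLog:
    entries: list[TransformLogEntry] = field(default_factory=list)
    findings: list[dict] = field(default_factory=list)

    def add(self, kind: str, table: str | None, variable: str | None,
            params: dict, n_affected: int) -> None:
        self.entries.append(TransformLogEntry(kind, table, variable,
                                              dict(params), int(n_affected)))

    def flag(self, **finding: Any) -> None:
        self.findings.append(finding)

    def to_json(self) -> str:
        return json.dumps(
            {"entries": [e.to_dict() for e in self.entries],
             "findings": self.findings}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TransformLog":
        doc = json.loads(text)
        log = cls()
        for e in doc["entries"]:
            log.add(e["kind"], e["table"], e["variable"], e["params"],
                    e["n_affected"])
        log.findings = list(doc.get("findings", []))
        return log

    def suppressed_cells(self) -> set[tuple[str, str, str]]:
        """Coordinates (table, subject key, variable) of every cell the
        anonymisation blanked — used by QC to reconcile missingness."""
        cells: set[tuple[str, str, str]] = set()
        for e in self.entries:
            for key in e.params.get("suppressed_keys", []):
                cells.add((e.table or "", str(key), e.variable or ""))
        return cells


# ---------------------------------------------------------------------------
# pseudonymisation

@dataclass
class LinkFile:
    """Protected bijection original subject id -> anonymised id.

    Kept out of the release: written, if at all, to a separate directory
    accessible only to the anonymisation team.
    """

    mapping: dict[str, str]
    created: str
    scope: str = "study-pool"

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) != len(self.mapping):
            raise TransformError("link file mapping must be a bijection")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"original_id": list(self.mapping), "anon_id": list(self.mapping.values())}
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "LinkFile":
        df = pd.read_csv(path, dtype=str)
        return cls(mapping=dict(zip(df["original_id"], df["anon_id"])),
                   created=datetime.now(timezone.utc).isoformat())


def _make_anon_ids(originals: list[str], seed: int) -> dict[str, str]:
    """Sequential zero-padded ids assigned in a seed-shuffled order.

    The numeric offset is bumped (deterministically) until no original id
    occurs as a substring of any anonymised id, so the release can never leak
    an original identifier fragment through the new ids.  Originals shorter
    than three characters are exempt from the check: a one- or two-digit
    fragment is an unavoidable substring of any zero-padded numbering and
    identifies nothing.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(originals))
    width = max(6, len(str(len(originals))))
    guarded = [o for o in originals if len(o) >= 3]
    offset = 0
    for _ in range(1000):
        ids = {originals[i]: f"P{offset + rank + 1:0{width}d}"
               for rank, i in enumerate(order)}
        if not any(orig in anon for orig in guarded for anon in ids.values()):
            return ids
        offset += len(originals) + 1
    raise TransformError(
        "could not find an anonymised id range free of original-id fragments")


def pseudonymise(
    tables: Mapping[str, pd.DataFrame],
    key: str,
    seed: int,
    log: TransformLog | None = None,
    link: LinkFile | None = None,
) -> tuple[dict[str, pd.DataFrame], LinkFile]:
    """Replace the subject identifier with a newly generated anonymised id,
    consistently across all tables, and return the protected link file.

    The same original id always maps to the same anonymised id so that a
    subject's clinical, visit and imaging records remain linkable after
    anonymisation.  Passing an existing *link* replays a previous mapping.
    """
    id_types: set[type] = set()
    originals: list[str] = []
    seen: set[str] = set()
    for name, df in tables.items():
        if key not in df.columns:
            raise TransformError(f"table {name!r} has no key column {key!r}")
        for v in df[key]:
            id_types.add(type(v))
            s = str(v)
            if s not in seen:
                seen.add(s)
                originals.append(s)
    if len(id_types) > 1:
        raise TransformError(
            f"subject key {key!r} typed differently across tables: "
            f"{sorted(t.__name__ for t in id_types)}"
        )
    if link is None:
        mapping = _make_anon_ids(originals, seed)
        link = LinkFile(mapping=mapping,
                        created=datetime.now(timezone.utc).isoformat())
    else:
        missing = [o for o in originals if o not in link.mapping]
        if missing:
            raise TransformError(f"link file lacks ids: {missing[:5]}")
        mapping = link.mapping
    out: dict[str, pd.DataFrame] = {}
    for name, df in tables.items():
        new = df.copy()
        new[key] = [mapping[str(v)] for v in df[key]]
        out[name] = new
        if log is not None:
            log.add("pseudonymise", name, key, {"seed": seed}, len(df))
    return out, link


# ---------------------------------------------------------------------------
# dates

def _parse_date(v: Any) -> date | None:
    if is_missing(v):
        return None
    if isinstance(v, datetime):
        return v.date()
    if isinstance(v, date):
        return v
    try:
        return date.fromisoformat(str(v).strip())
    except ValueError:
        return None


def study_day(d: date, ref: date) -> int:
    """Relative study day with no day 0: the reference date is day 1, the
    day before it is day -1."""
    delta = (d - ref).days
    return delta + 1 if delta >= 0 else delta


def to_relative_days(
    table: pd.DataFrame,
    date_vars: Sequence[str],
    ref_dates: Mapping[str, date | str],
    key: str = "subject_id",
    table_name: str | None = None,
    log: TransformLog | None = None,
) -> pd.DataFrame:
    """Offset calendar dates to per-subject relative study days.

    Each date column ``X`` is replaced by an integer study-day column named
    ``X_day`` (``X`` suffixed ``_date`` becomes ``X_day``); the absolute date
    column is removed.  Unparseable dates are suppressed with a logged
    finding rather than failing the run.
    """
    refs = {str(k): _parse_date(v) for k, v in ref_dates.items()}
    out = table.copy()
    for var in date_vars:
        if var not in out.columns:
            raise TransformError(f"date variable {var!r} not in table")
        newcol = re.sub(r"_date$", "", var) + "_day"
        days: list[Any] = []
        suppressed_keys: list[str] = []
        for idx, row in table.iterrows():
            subj = str(row[key])
            ref = refs.get(subj)
            if ref is None:
                raise TransformError(f"no reference date for subject {subj!r}")
            d = _parse_date(row[var])
            if d is None:
                if not is_missing(row[var]):
                    suppressed_keys.append(subj)
                    if log is not None:
                        log.flag(kind="unparseable_date", table=table_name,
                                 variable=var, subject=subj, value=str(row[var]))
                days.append(np.nan)
            else:
                days.append(study_day(d, ref))
        out[newcol] = pd.array(days, dtype="Int64")
        out = out.drop(columns=[var])
        if log is not None:
            log.add("relative_days", table_name, var,
                    {"new_column": newcol, "key": key,
                     "ref_dates": {k: v.isoformat() for k, v in refs.items()
                                   if v is not None},
                     "suppressed_keys": suppressed_keys},
                    len(table))
    return out


# ---------------------------------------------------------------------------
# generalization and noise

def band_label(value: float, width: float, anchor: float = 0.0,
               integer: bool = True) -> str:
    k = int(np.floor((value - anchor) / width))
    lo = anchor + k * width
    if integer:
        lo_i = int(round(lo))
        hi_i = int(round(lo + width)) - 1
        return f"{lo_i}-{hi_i}"
    return f"{lo:g}-{lo + width:g}"


def generalize_numeric(
    values: pd.Series,
    width: float,
    anchor: float = 0.0,
    integer: bool = True,
    variable: str | None = None,
    table_name: str | None = None,
    log: TransformLog | None = None,
) -> pd.Series:
    """Generalize a numeric column into left-closed, right-open bands
    [anchor + k*width, anchor + (k+1)*width), labelled "lo-hi"
    (hi = lo + width - 1 for integer data; five-year age bands by default
    convention: width 5, anchor 0).  Non-numeric values fall into their own
    missing band."""
    if width <= 0:
        raise TransformError(f"band width must be positive, got {width}")

    def one(v: Any) -> str:
        if is_missing(v):
            return "missing"
        try:
            x = float(v)
        except (TypeError, ValueError):
            return "missing"
        return band_label(x, width, anchor, integer)

    out = values.map(one)
    if log is not None:
        log.add("generalize_numeric", table_name, variable or values.name,
                {"width": width, "anchor": anchor, "integer": integer},
                len(values))
    return out


def add_uniform_noise(
    values: pd.Series,
    k: float,
    seed: int,
    integer: bool = False,
    clip: tuple[float, float] | None = None,
    variable: str | None = None,
    table_name: str | None = None,
    log: TransformLog | None = None,
) -> pd.Series:
    """Perturb a numeric column by independent Uniform(-k, k) noise.

    Integer variables are rounded after perturbation; *clip* bounds the
    result to the variable's declared valid range (no impossible ages).
    Deterministic under *seed*.
    """
    if k <= 0:
        raise TransformError(f"noise half-width must be positive, got {k}")
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-k, k, size=len(values))
    x = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
    y = x + noise
    if clip is not None:
        y = np.clip(y, clip[0], clip[1])
    if integer:
        y = np.rint(y)
    out = pd.Series(y, index=values.index, name=values.name)
    out[pd.isna(x)] = np.nan
    if integer:
        out = out.astype("Int64")
    if log is not None:
        log.add("add_uniform_noise", table_name, variable or values.name,
                {"k": k, "seed": seed, "integer": integer,
                 "clip": list(clip) if clip else None},
                len(values))
    return out


# ---------------------------------------------------------------------------
# suppression

def suppress_column(
    table: pd.DataFrame, var: str,
    table_name: str | None = None, log: TransformLog | None = None,
) -> pd.DataFrame:
    """Remove a column from the release entirely (e.g. SiteID, so that a
    site's location cannot be recovered from public recruitment registries)."""
    if var not in table.columns:
        raise TransformError(f"cannot suppress unknown column {var!r}")
    out = table.drop(columns=[var])
    if log is not None:
        log.add("suppress_column", table_name, var, {}, len(table))
    return out


def suppress_cells(
    table: pd.DataFrame,
    var: str,
    predicate: Callable[[pd.Series], pd.Series] | pd.Series,
    key: str | None = None,
    table_name: str | None = None,
    log: TransformLog | None = None,
) -> pd.DataFrame:
    """Blank the cells of *var* where *predicate* holds (callable on the
    column, or a boolean mask).  Affected rows' subject keys are recorded so
    QC can later distinguish suppressed from source-missing cells."""
    if var not in table.columns:
        raise TransformError(f"cannot suppress unknown column {var!r}")
    mask = predicate(table[var]) if callable(predicate) else predicate
    mask = mask.astype(bool)
    out = table.copy()
    out.loc[mask, var] = np.nan
    keys = [str(v) for v in table.loc[mask, key]] if key else \
           [str(i) for i in table.index[mask]]
    if log is not None:
        log.add("suppress_cells", table_name, var,
                {"suppressed_keys": keys, "key": key}, int(mask.sum()))
    return out


def generalize_categorical(
    values: pd.Series,
    spec: VariableSpec,
    level: int | str,
    table_name: str | None = None,
    log: TransformLog | None = None,
) -> pd.Series:
    """Map a categorical column up its codebook generalization ladder.

    Level 0 is the identity; values absent from the hierarchy map to the
    missing sentinel with a logged finding.
    """
    idx = spec.level_index(level)
    if idx == 0:
        if log is not None:
            log.add("generalize_categorical", table_name, spec.name,
                    {"level": 0}, len(values))
        return values.copy()
    mapping = spec.hierarchy[idx - 1].mapping

    def one(v: Any) -> Any:
        if is_missing(v):
            return np.nan
        s = str(v)
        if s not in mapping:
            if log is not None:
                log.flag(kind="unmapped_category", table=table_name,
                         variable=spec.name, value=s)
            return np.nan
        return mapping[s]

    out = values.map(one)
    if log is not None:
        log.add("generalize_categorical", table_name, spec.name,
                {"level": idx, "level_name": spec.hierarchy[idx - 1].name},
                len(values))
    return out


# ---------------------------------------------------------------------------
# sidecar metadata scrubbing

#: patterns whose presence in a *kept* value indicates identifying content
#: accidentally recorded in an acquisition field
DENY_PATTERNS = (
    re.compile(r"\d{4}-\d{2}-\d{2}"),          # ISO date
    re.compile(r"\d{1,2}/\d{1,2}/\d{2,4}"),    # slash date
    re.compile(r"\b(19|20)\d{6}\b"),           # YYYYMMDD
    re.compile(r"^[A-Z][a-z]+ [A-Z][a-z]+$"),  # "First Last"
    re.compile(r"^[A-Za-z]+\^[A-Za-z]+"),      # DICOM caret name "DOE^JOHN"
)


def scrub_sidecar(
    header: Mapping[str, Any],
    keep_list: Iterable[str],
    log: TransformLog | None = None,
) -> dict[str, Any]:
    """Strip an image-sidecar key/value header down to a keep-list of
    non-identifying acquisition parameters (default-deny policy).

    Kept values are additionally screened against a deny-list of date-like
    and name-like patterns; a kept key whose value matches is dropped with a
    logged finding, catching identifying details erroneously inserted into
    retained metadata fields at acquisition time.
    """
    keep = set(keep_list)
    out: dict[str, Any] = {}
    for k, v in header.items():
        if k not in keep:
            continue
        if isinstance(v, str) and any(p.search(v) for p in DENY_PATTERNS):
            if log is not None:
                log.flag(kind="identifying_value_in_kept_field", variable=k,
                         value=v)
            continue
        out[k] = v
    if log is not None:
        log.add("scrub_sidecar", None, None,
                {"keep_list": sorted(keep)}, len(out))
    return out
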