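"""Longitudinal cohort model for vestibular-schwannoma checkup records.

A cohort is a set of patients monitored under a wait-and-scan (WaS) protocol.
Each checkup records pure-tone audiometry for both ears, speech audiometry of
the diseased ear, MRI-based tumor descriptors (maximal 1D size, Koos grade),
and the treatment decision made at that visit (continue WaS, or switch to
active treatment).

Missingness is an explicit tri-state: a value is *present*, *missing*, or
*present at the audiometer ceiling* (a measurement that saturated the
instrument, encoded as the ceiling level and flagged — it is NOT missing).
No imputation is ever performed; cleaning only drops incomplete records.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Audiometric test frequencies, kHz.
AUDIO_FREQS_KHZ: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
#: Basic range: frequencies up to and including 4 kHz.
BASIC_FREQS_KHZ: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0)

#: Default audiometer ceiling, dB HL. Saturated measurements are stored at
#: this level and flagged, configurable per reader call.
DEFAULT_CEILING_DB = 110.0

#: Average month length in days, used by the month/day conversion helpers.
DAYS_PER_MONTH = 365.25 / 12.0

WAS = "WaS"
ACTIVE = "Active"

#: Scalar per-checkup fields that may be missing.
SCALAR_FIELDS = ("srt", "sds", "mdl", "mdr", "size_mm", "koos", "decision")
#: Fields expressed in dB that may saturate at the audiometer ceiling.
CEILING_CAPABLE = ("srt", "mdl")


class SchemaError(ValueError):
    """A mandatory column is absent from the input table."""


class IntegrityError(ValueError):
    """The input table violates a structural invariant (e.g. duplicate visit)."""


class EmptyCohortError(ValueError):
    """Cleaning removed every record; callers must not treat this as success."""


def freq_label(f: float) -> str:
    """Render a frequency key the way column names spell it (1.0 -> "1")."""
    return f"{f:g}"


def _audio_field(ear: str, f: float) -> str:
    return f"pta_{ear}_{freq_label(f)}"


def days_to_months(days: float) -> float:
    return days / DAYS_PER_MONTH


def months_to_days(months: float) -> float:
    return months * DAYS_PER_MONTH


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _full_audiogram(m: Mapping[float, float | None] | None) -> dict[float, float | None]:
    out: dict[float, float | None] = {f: None for f in AUDIO_FREQS_KHZ}
    if m:
        for f, v in m.items():
            key = float(f)
            if key not in out:
                raise ValueError(f"unknown audiometric frequency {f} kHz")
            out[key] = None if _is_missing(v) else float(v)
    return out


@dataclass(frozen=True)
class CheckupRecord:
    """One diagnostic visit of one patient.

    ``t`` is days since the patient's first checkup.  ``ceiling`` lists field
    names (e.g. ``"srt"``, ``"pta_vs_8"``) whose value saturated the
    audiometer; those values are present, at the ceiling level.
    """

    patient_id: str
    t: float
    pta_vs: Mapping[float, float | None] = field(default_factory=dict)
    pta_h: Mapping[float, float | None] = field(default_factory=dict)
    srt: float | None = None
    sds: float | None = None
    mdl: float | None = None
    mdr: float | None = None
    size_mm: float | None = None
    koos: int | None = None
    decision: str | None = None
    ceiling: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "pta_vs", _full_audiogram(self.pta_vs))
        object.__setattr__(self, "pta_h", _full_audiogram(self.pta_h))
        object.__setattr__(self, "ceiling", frozenset(self.ceiling))
        if self.t < 0:
            raise ValueError(f"negative checkup time t={self.t}")
        for name in ("srt", "mdl"):
            v = getattr(self, name)
            if v is not None and not (-10.0 <= v <= 130.0):
                raise ValueError(f"{name}={v} outside [-10, 130] dB")
        for name in ("sds", "mdr"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100] %")
        for ear, gram in (("vs", self.pta_vs), ("h", self.pta_h)):
            for f, v in gram.items():
                if v is not None and not (-10.0 <= v <= 130.0):
                    raise ValueError(f"pta_{ear}@{f}kHz={v} outside [-10, 130] dB")
        if self.koos is not None and self.koos not in (1, 2, 3, 4):
            raise ValueError(f"koos={self.koos} not in {{1,2,3,4}}")
        if self.size_mm is not None and self.size_mm < 0:
            raise ValueError(f"size_mm={self.size_mm} < 0")
        if self.decision is not None and self.decision not in (WAS, ACTIVE):
            raise ValueError(f"decision={self.decision!r} not in {{WaS, Active}}")

    # -- field access by name, spanning scalars and audiogram entries -------

    def value(self, name: str):
        """Fetch a field by its flat name ("srt", "pta_vs_0.25", ...)."""
        if name in SCALAR_FIELDS:
            return getattr(self, name)
        for ear, gram in (("vs", self.pta_vs), ("h", self.pta_h)):
            for f in AUDIO_FREQS_KHZ:
                if name == _audio_field(ear, f):
                    return gram[f]
        raise KeyError(name)

    def has(self, name: str) -> bool:
        """True if the named field (or field group "pta_vs"/"pta_h") is present.

        A ceiling-flagged value counts as present.
        """
        if name in ("pta_vs", "pta_h"):
            gram = self.pta_vs if name == "pta_vs" else self.pta_h
            return all(v is not None for v in gram.values())
        return not _is_missing(self.value(name))

    def at_ceiling(self, name: str) -> bool:
        return name in self.ceiling


@dataclass(frozen=True)
class PatientHistory:
    """Time-ordered checkups of one patient.

    At most one checkup may carry an Active decision, and if present it is the
    last one: the switch to active treatment ends the wait-and-scan follow-up.
    """

    patient_id: str
    checkups: tuple[CheckupRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "checkups", tuple(self.checkups))
        if not self.checkups:
            raise ValueError(f"patient {self.patient_id}: empty history")
        for c in self.checkups:
            if c.patient_id != self.patient_id:
                raise IntegrityError(
                    f"checkup of {c.patient_id} inside history of {self.patient_id}"
                )
        ts = [c.t for c in self.checkups]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise IntegrityError(f"patient {self.patient_id}: t not strictly increasing")
        actives = [i for i, c in enumerate(self.checkups) if c.decision == ACTIVE]
        if len(actives) > 1 or (actives and actives[0] != len(self.checkups) - 1):
            raise IntegrityError(
                f"patient {self.patient_id}: Active decision must be unique and last"
            )

    @property
    def outcome(self) -> str:
        return ACTIVE if self.checkups[-1].decision == ACTIVE else WAS


@dataclass(frozen=True)
class Cohort:
    histories: tuple[PatientHistory, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "histories", tuple(self.histories))
        ids = [h.patient_id for h in self.histories]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate patient_id in cohort")

    @property
    def n_patients(self) -> int:
        return len(self.histories)

    @property
    def n_checkups(self) -> int:
        return sum(len(h.checkups) for h in self.histories)

    def __iter__(self):
        return iter(self.histories)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

#: Canonical CSV column for every flat field name.  A schema mapping passed to
#: the reader overrides entries of this dict (field name -> CSV column).
DEFAULT_SCHEMA: dict[str, str] = {
    "patient_id": "patient_id",
    "t": "t_days",
    **{_audio_field(ear, f): _audio_field(ear, f) for ear in ("vs", "h") for f in AUDIO_FREQS_KHZ},
    **{name: name for name in SCALAR_FIELDS},
}

_NA_TOKENS = {"", "n/a", "na", "nan", "none", "null", "."}


def default_schema_path() -> Path:
    """Path of the shipped column-schema config file."""
    return Path(__file__).parent / "data" / "cohort_schema.json"


def _parse_cell(raw: str | None, colname: str, bad: list):
    if raw is None or raw.strip().lower() in _NA_TOKENS:
        return None
    try:
        return float(raw)
    except ValueError:
        bad.append((colname, raw))
        return None


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    ceiling_db: float = DEFAULT_CEILING_DB,
    provenance: str | None = None,
) -> Cohort:
    """Read a one-row-per-checkup CSV into a :class:`Cohort`.

    Missing cells may be empty or any of the usual NA spellings; unparseable
    numeric cells become missing and are counted in a log summary.  Values at
    or above ``ceiling_db`` in dB fields are kept and ceiling-flagged.
    """
    path = Path(path)
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: no header row")
        header = set(reader.fieldnames)
        for mandatory in ("patient_id", "t", "decision"):
            if cols[mandatory] not in header:
                raise SchemaError(f"{path}: missing mandatory column {cols[mandatory]!r}")
        rows = list(reader)

    bad: list[tuple[str, str]] = []
    by_patient: dict[str, list[CheckupRecord]] = {}
    seen: set[tuple[str, float]] = set()
    for row in rows:
        pid = (row.get(cols["patient_id"]) or "").strip()
        if not pid:
            raise IntegrityError(f"{path}: row with empty patient_id")
        t = _parse_cell(row.get(cols["t"]), cols["t"], bad)
        if t is None:
            raise IntegrityError(f"{path}: patient {pid}: unparseable checkup time")
        if (pid, t) in seen:
            raise IntegrityError(f"{path}: duplicate checkup (patient {pid}, t={t})")
        seen.add((pid, t))

        ceiling: set[str] = set()

        def scalar(name: str):
            v = _parse_cell(row.get(cols[name]), cols[name], bad)
            if v is not None and name in CEILING_CAPABLE and v >= ceiling_db:
                ceiling.add(name)
            return v

        def audiogram(ear: str) -> dict[float, float | None]:
            out = {}
            for f in AUDIO_FREQS_KHZ:
                name = _audio_field(ear, f)
                v = _parse_cell(row.get(cols[name]), cols[name], bad)
                if v is not None and v >= ceiling_db:
                    ceiling.add(name)
                out[f] = v
            return out

        koos_v = scalar("koos")
        decision_raw = (row.get(cols["decision"]) or "").strip()
        rec = CheckupRecord(
            patient_id=pid,
            t=t,
            pta_vs=audiogram("vs"),
            pta_h=audiogram("h"),
            srt=scalar("srt"),
            sds=scalar("sds"),
            mdl=scalar("mdl"),
            mdr=scalar("mdr"),
            size_mm=scalar("size_mm"),
            koos=int(koos_v) if koos_v is not None else None,
            decision=decision_raw if decision_raw else None,
            ceiling=frozenset(ceiling),
        )
        by_patient.setdefault(pid, []).append(rec)

    if bad:
        logger.warning(
            "%s: %d unparseable numeric cells treated as missing (first: %r)",
            path, len(bad), bad[0],
        )
    histories = tuple(
        PatientHistory(pid, tuple(sorted(recs, key=lambda r: r.t)))
        for pid, recs in by_patient.items()
    )
    return Cohort(histories, provenance=provenance if provenance is not None else str(path))


def write_cohort(cohort: Cohort, path: str | Path, schema: Mapping[str, str] | None = None) -> None:
    """Write a cohort back to the canonical CSV dialect (round-trip safe)."""
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    fieldnames = [cols["patient_id"], cols["t"]] + [
        cols[name]
        for name in list(DEFAULT_SCHEMA)
        if name not in ("patient_id", "t")
    ]

    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, float) and v.is_integer():
            return str(int(v))
        return repr(v) if isinstance(v, float) else str(v)

    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(fieldnames)
        for hist in cohort:
            for rec in hist.checkups:
                row = [rec.patient_id, fmt(rec.t)]
                for name in list(DEFAULT_SCHEMA):
                    if name in ("patient_id", "t"):
                        continue
                    row.append(fmt(rec.value(name)))
                w.writerow(row)


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

@dataclass
class CleaningReport:
    required: tuple[str, ...]
    n_checkups_before: int
    n_checkups_after: int
    n_patients_before: int
    n_patients_after: int
    removed_by_field: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=list, indent=2)


def clean_complete(
    cohort: Cohort,
    required: Iterable[str],
    report_path: str | Path | None = None,
) -> tuple[Cohort, CleaningReport]:
    """Drop checkups lacking any of the ``required`` fields.

    Surviving records are never altered (no imputation).  ``required`` names
    flat fields ("srt", "koos", "pta_vs_1", ...) or the whole-audiogram groups
    "pta_vs" / "pta_h".  Raises :class:`EmptyCohortError` if nothing survives.
    """
    required = tuple(required)
    removed_by_field: dict[str, int] = {name: 0 for name in required}
    histories = []
    for hist in cohort:
        kept = []
        for rec in hist.checkups:
            gaps = [name for name in required if not rec.has(name)]
            if gaps:
                for name in gaps:
                    removed_by_field[name] += 1
            else:
                kept.append(rec)
        if kept:
            histories.append(PatientHistory(hist.patient_id, tuple(kept)))
    report = CleaningReport(
        required=required,
        n_checkups_before=cohort.n_checkups,
        n_checkups_after=sum(len(h.checkups) for h in histories),
        n_patients_before=cohort.n_patients,
        n_patients_after=len(histories),
        removed_by_field=removed_by_field,
    )
    print(
        f"clean_complete: kept {report.n_checkups_after}/{report.n_checkups_before} "
        f"checkups, {report.n_patients_after}/{report.n_patients_before} patients",
        file=sys.stderr,
    )
    if report_path is not None:
        Path(report_path).write_text(report.to_json())
    if not histories:
        raise EmptyCohortError("cleaning removed every checkup")
    return Cohort(tuple(histories), provenance=cohort.provenance), report
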