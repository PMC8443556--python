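"""Row-based (per-checkup) and column-based (per-patient) derived metrics.

Two feature layouts are produced from a cohort:

* the case-based-reasoning (CBR) table — one row per checkup, each row
  augmented with audiogram summaries per ear X in {VS, H} and frequency range
  n in {4, 8}: the mean threshold ``PTA_X_ARn``, and the slope/intercept of a
  least-squares line through the audiogram, ``PTA_X_SRn`` / ``PTA_X_IRn``;
  plus inter-ear differences ``PTA_D_ARn = PTA_VS_ARn - PTA_H_ARn``;

* the personalized-dynamic-analysis (PDA) table — one row per patient, each
  base variable's checkup series summarized by its time-average (``_AC``),
  least-squares slope and intercept against time (``_SC``, ``_IC``, slope in
  variable units per day), last difference (``_LD``, last minus previous
  checkup) and total difference (``_TD``, last minus first).

All summaries follow the completeness rule: a row-based metric is missing if
any in-range threshold is missing; a column-based series uses only the
checkups where the base variable is present.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    ACTIVE,
    AUDIO_FREQS_KHZ,
    BASIC_FREQS_KHZ,
    CheckupRecord,
    Cohort,
    PatientHistory,
    freq_label,
)

logger = logging.getLogger(__name__)

RANGES: dict[str, tuple[float, ...]] = {"basic": BASIC_FREQS_KHZ, "full": AUDIO_FREQS_KHZ}
_RANGE_SUFFIX = {"basic": "4", "full": "8"}

#: Abscissa conventions for the audiogram line fit; "khz" regresses threshold
#: on frequency in kHz, "log2khz" on log2(frequency), "index" on 0..k-1.
ABSCISSAE = ("khz", "log2khz", "index")

#: Default base variables summarized per patient for the PDA table.
DEFAULT_PDA_BASE: tuple[str, ...] = (
    "Koos", "Size", "SRT",
    "PTA_VS_AR4", "PTA_VS_AR8", "PTA_D_AR4", "PTA_D_AR8",
)

COLUMN_METRICS = ("AC", "SC", "IC", "LD", "TD")


def _range_freqs(range_id: str) -> tuple[float, ...]:
    try:
        return RANGES[range_id]
    except KeyError:
        raise ValueError(f"unknown range_id {range_id!r}; expected 'basic' or 'full'")


def pta_average(audiogram: Mapping[float, float | None], range_id: str) -> float | None:
    """Mean threshold over the range, or None if any in-range value is missing."""
    freqs = _range_freqs(range_id)
    vals = [audiogram.get(f) for f in freqs]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        return None
    return float(np.mean([float(v) for v in vals]))


def pta_linfit(
    audiogram: Mapping[float, float | None],
    range_id: str,
    abscissa: str = "khz",
) -> tuple[float, float] | None:
    """Least-squares (slope, intercept) of threshold vs frequency over the range.

    Slope units depend on the abscissa convention (dB/kHz by default).
    Returns None if any in-range threshold is missing.
    """
    if abscissa not in ABSCISSAE:
        raise ValueError(f"unknown abscissa {abscissa!r}; expected one of {ABSCISSAE}")
    freqs = _range_freqs(range_id)
    vals = [audiogram.get(f) for f in freqs]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        return None
    y = np.array([float(v) for v in vals])
    if abscissa == "khz":
        x = np.array(freqs)
    elif abscissa == "log2khz":
        x = np.log2(freqs)
    else:
        x = np.arange(len(freqs), dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# CBR table
# ---------------------------------------------------------------------------

def _raw_columns() -> list[str]:
    cols = [f"PTA_VS_{freq_label(f)}" for f in AUDIO_FREQS_KHZ]
    cols += [f"PTA_H_{freq_label(f)}" for f in AUDIO_FREQS_KHZ]
    cols += ["SRT", "SDS", "MDL", "MDR", "Size", "Koos"]
    return cols


def cbr_feature_vector(rec: CheckupRecord, abscissa: str = "khz") -> dict[str, float | None]:
    """Expand one checkup into the flat CBR feature mapping (without target)."""
    out: dict[str, float | None] = {}
    for ear, gram in (("VS", rec.pta_vs), ("H", rec.pta_h)):
        for f in AUDIO_FREQS_KHZ:
            out[f"PTA_{ear}_{freq_label(f)}"] = gram[f]
    out["SRT"] = rec.srt
    out["SDS"] = rec.sds
    out["MDL"] = rec.mdl
    out["MDR"] = rec.mdr
    out["Size"] = rec.size_mm
    out["Koos"] = float(rec.koos) if rec.koos is not None else None
    for range_id, n in _RANGE_SUFFIX.items():
        for ear, gram in (("VS", rec.pta_vs), ("H", rec.pta_h)):
            avg = pta_average(gram, range_id)
            fit = pta_linfit(gram, range_id, abscissa=abscissa)
            out[f"PTA_{ear}_AR{n}"] = avg
            out[f"PTA_{ear}_SR{n}"] = fit[0] if fit else None
            out[f"PTA_{ear}_IR{n}"] = fit[1] if fit else None
        a_vs, a_h = out[f"PTA_VS_AR{n}"], out[f"PTA_H_AR{n}"]
        out[f"PTA_D_AR{n}"] = (a_vs - a_h) if (a_vs is not None and a_h is not None) else None
    return out


def cbr_columns() -> list[str]:
    """Feature column order of the CBR table (target column excluded)."""
    derived = []
    for n in ("4", "8"):
        for ear in ("VS", "H"):
            derived += [f"PTA_{ear}_AR{n}", f"PTA_{ear}_SR{n}", f"PTA_{ear}_IR{n}"]
        derived.append(f"PTA_D_AR{n}")
    return _raw_columns() + derived


def build_cbr_dataset(cohort: Cohort, abscissa: str = "khz") -> pd.DataFrame:
    """One row per checkup, anonymized (no patient id, no time); target 'decision'."""
    rows = []
    for hist in cohort:
        for rec in hist.checkups:
            v = cbr_feature_vector(rec, abscissa=abscissa)
            v["decision"] = rec.decision
            rows.append(v)
    df = pd.DataFrame(rows, columns=cbr_columns() + ["decision"])
    return df.astype({c: float for c in cbr_columns()})


# ---------------------------------------------------------------------------
# column summaries / PDA table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnSummary:
    """Temporal summary of one variable over a patient's checkups.

    ``sc`` and ``ld`` are None for single-point series; a single point has
    ``ac == ic == value`` and ``td == 0``.
    """

    ac: float
    sc: float | None
    ic: float
    ld: float | None
    td: float

    def metric(self, name: str) -> float | None:
        return {"AC": self.ac, "SC": self.sc, "IC": self.ic, "LD": self.ld, "TD": self.td}[name]


def column_summary(series: Sequence[tuple[float, float]]) -> ColumnSummary:
    """Summarize ``(t_days, value)`` points with strictly increasing t."""
    if len(series) == 0:
        raise ValueError("empty series")
    t = np.array([p[0] for p in series], dtype=float)
    v = np.array([p[1] for p in series], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("series times must be strictly increasing")
    ac = float(np.mean(v))
    if len(series) == 1:
        return ColumnSummary(ac=ac, sc=None, ic=float(v[0]), ld=None, td=0.0)
    slope, intercept = np.polyfit(t, v, 1)
    # snap float-precision residue to an exact zero (a constant series must
    # have slope 0, not +-1e-18 whose sign is numerical noise)
    tol = 1e-12 * max(1.0, float(np.max(np.abs(v))))
    if abs(slope) < tol:
        slope = 0.0
    return ColumnSummary(
        ac=ac,
        sc=float(slope),
        ic=float(intercept),
        ld=float(v[-1] - v[-2]),
        td=float(v[-1] - v[0]),
    )


def _base_variable_series(hist: PatientHistory, var: str, abscissa: str) -> list[tuple[float, float]]:
    pts = []
    for rec in hist.checkups:
        if var == "Koos":
            val = float(rec.koos) if rec.koos is not None else None
        elif var == "Size":
            val = rec.size_mm
        elif var in ("SRT", "SDS", "MDL", "MDR"):
            val = getattr(rec, var.lower())
        else:
            val = cbr_feature_vector(rec, abscissa=abscissa).get(var)
            if val is None and var not in cbr_columns():
                raise KeyError(f"unknown PDA base variable {var!r}")
        if val is not None:
            pts.append((rec.t, float(val)))
    return pts


def pda_columns(base_variables: Sequence[str] = DEFAULT_PDA_BASE) -> list[str]:
    return [f"{var}_{m}" for var in base_variables for m in COLUMN_METRICS]


def build_pda_dataset(
    cohort: Cohort,
    base_variables: Sequence[str] = DEFAULT_PDA_BASE,
    abscissa: str = "khz",
) -> pd.DataFrame:
    """One row per patient; target 'outcome' = Active iff the history ends Active.

    Summaries cover the patient's wait-and-scan follow-up, including the final
    checkup at which an Active decision (if any) was made — its measurements
    were taken while the patient was still under observation.
    """
    rows = []
    index = []
    for hist in cohort:
        row: dict[str, float | None] = {}
        for var in base_variables:
            pts = _base_variable_series(hist, var, abscissa)
            summ = column_summary(pts) if pts else None
            for m in COLUMN_METRICS:
                row[f"{var}_{m}"] = summ.metric(m) if summ is not None else None
        if len(hist.checkups) == 1:
            logger.warning(
                "patient %s has a single checkup; slope and last-difference "
                "features are missing", hist.patient_id,
            )
        row["outcome"] = hist.outcome
        rows.append(row)
        index.append(hist.patient_id)
    df = pd.DataFrame(rows, columns=pda_columns(base_variables) + ["outcome"],
                      index=pd.Index(index, name="patient_id"))
    return df.astype({c: float for c in pda_columns(base_variables)})


def write_feature_matrix(df: pd.DataFrame, path, target: str) -> None:
    """Write a feature table as CSV with a sidecar JSON schema of column names."""
    import json
    from pathlib import Path

    path = Path(path)
    df.to_csv(path, index=df.index.name is not None)
    schema = {
        "target": target,
        "features": [c for c in df.columns if c != target],
        "index": df.index.name,
    }
    path.with_suffix(path.suffix + ".schema.json").write_text(json.dumps(schema, indent=2))
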