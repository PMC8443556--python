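"""Synthetic longitudinal vestibular-schwannoma cohorts.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised and tested without patient data:

* ~93 patients, ~43% of whom eventually switch to active treatment;
* 3-8 checkups per patient (active patients decide earlier: median 3 vs 5),
  roughly yearly;
* worse hearing in the diseased ear, with a high-frequency-weighted offset,
  and faster hearing deterioration in the eventually-active group;
* Koos grade skewed low in the wait-and-scan group and non-decreasing in
  time (tumors are not modelled as shrinking);
* slow tumor growth concentrated in the actively treated group;
* record-level missingness of audiometric fields, and audiometer ceiling
  saturation of SRT.

Class labels follow a *planted rule* mirroring the longitudinal reference
tree: every active patient either jumps one Koos grade at the decision
checkup or grows faster than the 0.0064 mm/day size-slope threshold (or
both); wait-and-scan patients do neither.  A configurable label-noise rate
flips patient outcomes after the fact, emulating decisions driven by factors
outside the recorded variables.  Koos grade and tumor size are never missing
(checkups are MRI-driven); missingness is confined to audiometric fields.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import (
    ACTIVE,
    AUDIO_FREQS_KHZ,
    DEFAULT_CEILING_DB,
    WAS,
    CheckupRecord,
    Cohort,
    PatientHistory,
)

#: Tumor-size slope (mm/day) separating "growing" from "stable" in the
#: longitudinal reference tree; about 2.3 mm/year.
GROWTH_THRESHOLD_MM_PER_DAY = 0.0064


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; defaults emulate the source cohort's makeup."""

    n_patients: int = 93
    p_active: float = 0.43
    seed: int = 0

    # checkup counts (values, probabilities) — medians 3 (active) and 5 (WaS)
    checkups_active: tuple[int, ...] = (3, 4, 5)
    checkups_active_p: tuple[float, ...] = (0.60, 0.25, 0.15)
    checkups_was: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    checkups_was_p: tuple[float, ...] = (0.10, 0.20, 0.30, 0.20, 0.12, 0.08)

    # inter-checkup interval, days
    interval_mean_days: float = 330.0
    interval_sd_days: float = 60.0
    interval_min_days: float = 90.0

    # audiograms, dB HL per frequency (0.25..8 kHz)
    healthy_curve_db: tuple[float, ...] = (10, 10, 10, 15, 20, 25, 30, 35)
    vs_offset_db: tuple[float, ...] = (5, 7, 10, 15, 20, 25, 30, 35)
    patient_sd_db: float = 6.0
    audio_noise_sd_db: float = 3.0
    prog_active_db_per_year: float = 4.0
    prog_was_db_per_year: float = 2.0
    prog_sd_db_per_year: float = 2.0
    ceiling_db: float = DEFAULT_CEILING_DB

    # tumor size, mm; growth, mm/day
    size_base_mean_mm: float = 12.0
    size_base_sd_mm: float = 4.0
    size_min_mm: float = 2.0
    growth_active_range: tuple[float, float] = (0.009, 0.030)
    growth_was_mean: float = 0.001
    growth_was_sd: float = 0.0015
    growth_was_max: float = 0.004
    size_noise_sd_mm: float = 0.1

    # active-treatment mechanism mix: Koos jump only / growth only / both
    p_koos_only: float = 0.45
    p_growth_only: float = 0.40

    # Koos baseline distributions over grades 1..4
    koos_base_was_p: tuple[float, ...] = (0.45, 0.35, 0.15, 0.05)
    koos_base_active_p: tuple[float, ...] = (0.20, 0.35, 0.30, 0.15)

    # speech audiometry linkage and noise
    srt_noise_sd_db: float = 5.0
    sds_noise_sd: float = 8.0

    missing_rate: float = 0.05
    label_noise: float = 0.05

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("p_active", "missing_rate", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_koos_only + self.p_growth_only > 1.0 + 1e-9:
            raise ValueError("mechanism probabilities exceed 1")
        if self.growth_active_range[0] <= GROWTH_THRESHOLD_MM_PER_DAY:
            import warnings
            warnings.warn(
                "active growth-rate range starts at or below the reference "
                "slope threshold; planted-rule consistency is not guaranteed"
            )


def _round_to(x: np.ndarray | float, step: float) -> np.ndarray | float:
    return np.round(np.asarray(x) / step) * step


def generate(config: SyntheticConfig = SyntheticConfig()) -> Cohort:
    """Draw a seeded, reproducible cohort satisfying all cohort invariants."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    freqs = np.array(AUDIO_FREQS_KHZ)
    histories = []
    for i in range(cfg.n_patients):
        pid = f"SYN{i:04d}"
        active = bool(rng.random() < cfg.p_active)

        if active:
            n_k = int(rng.choice(cfg.checkups_active, p=cfg.checkups_active_p))
            u = rng.random()
            koos_jump = u < cfg.p_koos_only or u >= cfg.p_koos_only + cfg.p_growth_only
            growing = u >= cfg.p_koos_only
        else:
            n_k = int(rng.choice(cfg.checkups_was, p=cfg.checkups_was_p))
            koos_jump = growing = False

        intervals = np.maximum(
            rng.normal(cfg.interval_mean_days, cfg.interval_sd_days, n_k - 1),
            cfg.interval_min_days,
        )
        times = np.concatenate([[0.0], np.cumsum(intervals)])

        # hearing model: patient-level baseline + linear deterioration
        base_shift = rng.normal(0.0, cfg.patient_sd_db)
        healthy_base = np.array(cfg.healthy_curve_db) + base_shift
        vs_base = healthy_base + np.array(cfg.vs_offset_db) * rng.uniform(0.6, 1.4)
        rate = max(0.0, rng.normal(
            cfg.prog_active_db_per_year if active else cfg.prog_was_db_per_year,
            cfg.prog_sd_db_per_year,
        ))

        # tumor model
        size0 = max(cfg.size_min_mm, rng.normal(cfg.size_base_mean_mm, cfg.size_base_sd_mm))
        if growing:
            slope = rng.uniform(*cfg.growth_active_range)
        else:
            slope = min(cfg.growth_was_max, rng.normal(cfg.growth_was_mean, cfg.growth_was_sd))
        koos_grades = (1, 2, 3, 4)
        if koos_jump:
            koos0 = int(rng.choice((1, 2, 3), p=_renorm(cfg.koos_base_active_p[:3])))
        else:
            koos0 = int(rng.choice(koos_grades,
                                   p=cfg.koos_base_active_p if active else cfg.koos_base_was_p))

        checkups = []
        for j, t in enumerate(times):
            years = t / 365.25
            vs_thr = vs_base + rate * years + rng.normal(0, cfg.audio_noise_sd_db, 8)
            h_thr = healthy_base + 0.5 * years + rng.normal(0, cfg.audio_noise_sd_db, 8)
            vs_thr = np.clip(_round_to(vs_thr, 5.0), -10.0, cfg.ceiling_db)
            h_thr = np.clip(_round_to(h_thr, 5.0), -10.0, cfg.ceiling_db)

            size = max(0.5, size0 + slope * t + rng.normal(0, cfg.size_noise_sd_mm))
            size = float(_round_to(size, 0.1))
            koos = koos0 + (1 if (koos_jump and j == n_k - 1) else 0)

            low = vs_thr[:4].mean()  # 0.25-2 kHz of the diseased ear
            srt = float(np.clip(round(low + rng.normal(0, cfg.srt_noise_sd_db)), -10, cfg.ceiling_db))
            sds = float(np.clip(round(100 - 0.9 * max(0.0, vs_thr[:6].mean() - 20)
                                      + rng.normal(0, cfg.sds_noise_sd)), 0, 100))
            mdl = float(np.clip(round(srt + 25 + rng.normal(0, 5)), -10, cfg.ceiling_db))
            mdr = float(np.clip(round(sds - abs(rng.normal(0, 5))), 0, 100))

            ceiling = set()
            for name, v in (("srt", srt), ("mdl", mdl)):
                if v >= cfg.ceiling_db:
                    ceiling.add(name)

            # audiometric missingness; MRI descriptors are always recorded
            scal = {"srt": srt, "sds": sds, "mdl": mdl, "mdr": mdr}
            for name in list(scal):
                if rng.random() < cfg.missing_rate:
                    scal[name] = None
                    ceiling.discard(name)
            pta_vs = dict(zip(AUDIO_FREQS_KHZ, vs_thr))
            pta_h = dict(zip(AUDIO_FREQS_KHZ, h_thr))
            if rng.random() < cfg.missing_rate / 2:
                pta_vs = {f: None for f in AUDIO_FREQS_KHZ}
            if rng.random() < cfg.missing_rate / 2:
                pta_h = {f: None for f in AUDIO_FREQS_KHZ}
            for ear, gram in (("vs", pta_vs), ("h", pta_h)):
                for f, v in gram.items():
                    if v is not None and v >= cfg.ceiling_db:
                        ceiling.add(f"pta_{ear}_{f:g}")

            checkups.append(CheckupRecord(
                patient_id=pid,
                t=float(t),
                pta_vs=pta_vs,
                pta_h=pta_h,
                srt=scal["srt"], sds=scal["sds"], mdl=scal["mdl"], mdr=scal["mdr"],
                size_mm=size,
                koos=koos,
                decision=ACTIVE if (active and j == n_k - 1) else WAS,
                ceiling=frozenset(ceiling),
            ))

        # label noise: flip the recorded outcome, not the generating mechanisms
        if rng.random() < cfg.label_noise:
            last = checkups[-1]
            flipped = WAS if active else ACTIVE
            checkups[-1] = dataclasses.replace(last, decision=flipped)
        histories.append(PatientHistory(pid, tuple(checkups)))

    return Cohort(tuple(histories), provenance=f"synthetic(seed={cfg.seed})")


def _renorm(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    return arr / arr.sum()


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------

def summarize(cohort: Cohort) -> dict:
    """Group-wise descriptive report (deterministic for a given cohort)."""
    by_group: dict[str, list[PatientHistory]] = {WAS: [], ACTIVE: []}
    for hist in cohort:
        by_group[hist.outcome].append(hist)

    def mean_audiogram(hists: list[PatientHistory], ear: str) -> dict[str, float | None]:
        out = {}
        for f in AUDIO_FREQS_KHZ:
            vals = []
            for h in hists:
                rec = h.checkups[0]
                gram = rec.pta_vs if ear == "vs" else rec.pta_h
                if gram[f] is not None:
                    vals.append(gram[f])
            out[f"{f:g}"] = float(np.mean(vals)) if vals else None
        return out

    def koos_hist(hists: list[PatientHistory]) -> dict[int, int]:
        counts = {g: 0 for g in (1, 2, 3, 4)}
        for h in hists:
            k = h.checkups[0].koos
            if k is not None:
                counts[k] += 1
        return counts

    report: dict = {
        "n_patients": cohort.n_patients,
        "n_checkups": cohort.n_checkups,
        "fraction_active": (
            len(by_group[ACTIVE]) / cohort.n_patients if cohort.n_patients else 0.0
        ),
        "groups": {},
    }
    for grp, hists in by_group.items():
        report["groups"][grp] = {
            "n": len(hists),
            "median_checkups": float(np.median([len(h.checkups) for h in hists])) if hists else None,
            "initial_audiogram_vs": mean_audiogram(hists, "vs"),
            "initial_audiogram_h": mean_audiogram(hists, "h"),
            "initial_koos_histogram": koos_hist(hists),
        }
    return report


def write_provenance(config: SyntheticConfig, path) -> None:
    """Dump the generating configuration as JSON next to an emitted CSV."""
    from pathlib import Path

    Path(path).write_text(json.dumps(dataclasses.asdict(config), indent=2))
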