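"""File formats: patient records, allocation tables, configs, reports, logs.

Patient records travel as a flat CSV with raw pain scores and quit flags
per visit (empty cells = not yet observed); the reader derives the
categorical outcome of each visit through the outcome classifier and
rejects files with hard violations such as a non-monotone quit pattern.
Allocation tables and interim reports are plain CSV; configs and scenario
truths are YAML (JSON is accepted, being a YAML subset); every mutating
run can emit a deterministic JSON manifest binding together the config
hash, input digests and seeds, and an append-only JSON-lines audit log
carries the wall-clock trail.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adaptation import AllocationTable
from .config import TrialConfig
from .errors import RecordValidationError
from .outcomes import (
    OutcomeCategory,
    PatientRecord,
    classify_outcome,
    validate_record,
)
from .posterior import PosteriorSummary
from .simulator import ScenarioTruth

logger = logging.getLogger("bayesrar")

PATIENT_CSV_COLUMNS = [
    "patient_id",
    "arm",
    "enrollment_week",
    "baseline_pain",
    "pain_4",
    "quit_4",
    "pain_8",
    "quit_8",
    "pain_12",
    "quit_12",
]


def _cell(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_patient_csv(
    path: str | Path,
    schedule: tuple[int, ...] = (4, 8, 12),
) -> list[PatientRecord]:
    """Read patient records, deriving visit outcomes from raw scores.

    A visit is observed iff its ``quit_w`` cell is filled; ``quit_w = 0``
    requires a ``pain_w`` score. Soft findings (gaps, a filled pain score
    with no quit flag) are logged as warnings; hard violations reject the
    whole file with the offending row numbers.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in PATIENT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError(f"{path}: missing columns {missing}")
    records: list[PatientRecord] = []
    bad_rows: list[int] = []
    messages: list[str] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        rownum = pos + 2  # 1-based with header
        visits: dict[int, OutcomeCategory] = {}
        try:
            baseline = float(row.baseline_pain)
            for week in schedule:
                pain = _cell(getattr(row, f"pain_{week}"))
                quit_ = _cell(getattr(row, f"quit_{week}"))
                if quit_ is None:
                    if pain is not None:
                        logger.warning(
                            "%s row %d: pain_%d filled but quit_%d empty; "
                            "visit treated as unobserved",
                            path, rownum, week, week,
                        )
                    continue
                visits[week] = classify_outcome(baseline, pain, bool(quit_))
            record = PatientRecord(
                patient_id=str(row.patient_id),
                arm=int(row.arm),
                enrollment_week=float(row.enrollment_week),
                baseline_pain=baseline,
                visit_outcomes=visits,
            )
        except (ValueError, TypeError) as exc:
            bad_rows.append(rownum)
            messages.append(f"row {rownum}: {exc}")
            continue
        report = validate_record(record, schedule)
        for v in report:
            if v.is_error:
                bad_rows.append(rownum)
                messages.append(f"row {rownum}: {v.message}")
            else:
                logger.warning("%s row %d: %s", path, rownum, v.message)
        records.append(record)
    if bad_rows:
        raise RecordValidationError(
            f"{path}: invalid rows {sorted(set(bad_rows))}: " + "; ".join(messages),
            rows=sorted(set(bad_rows)),
        )
    return records


def write_patient_csv(
    records: Iterable[PatientRecord],
    path: str | Path,
    schedule: tuple[int, ...] = (4, 8, 12),
) -> None:
    """Write records in the raw-score CSV dialect.

    Simulated patients carry their raw scores; for plain records a
    representative score consistent with each category is emitted
    (quarter / three-quarter of baseline for efficacy / no efficacy).
    """
    rows = []
    for rec in records:
        row: dict = {
            "patient_id": rec.patient_id,
            "arm": rec.arm,
            "enrollment_week": rec.enrollment_week,
            "baseline_pain": rec.baseline_pain,
        }
        pains = getattr(rec, "pain_scores", None)
        for week in schedule:
            cat = rec.visit_outcomes.get(week)
            if cat is None:
                row[f"pain_{week}"] = ""
                row[f"quit_{week}"] = ""
            elif cat is OutcomeCategory.QUIT:
                row[f"pain_{week}"] = ""
                row[f"quit_{week}"] = 1
            else:
                if pains is not None and pains.get(week) is not None:
                    pain = pains[week]
                elif cat is OutcomeCategory.NOTQUIT_EFF:
                    pain = 0.25 * rec.baseline_pain
                else:
                    pain = 0.75 * rec.baseline_pain
                row[f"pain_{week}"] = pain
                row[f"quit_{week}"] = 0
        rows.append(row)
    pd.DataFrame(rows, columns=PATIENT_CSV_COLUMNS).to_csv(path, index=False)


# -- allocation tables -----------------------------------------------------


def write_table_csv(table: AllocationTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_table_csv(path: str | Path) -> AllocationTable:
    df = pd.read_csv(path, keep_default_na=False, dtype={"stratum": str})
    return AllocationTable.from_frame(df)


def write_edc_table(table: AllocationTable, path: str | Path) -> None:
    """EDC-import variant: one ``target_group`` column (plus stratum if any)."""
    df = pd.DataFrame({"target_group": [s.arm for s in table.slots]})
    strata = [s.stratum for s in table.slots]
    if any(s is not None for s in strata):
        df["stratum"] = [s if s is not None else "" for s in strata]
    df.to_csv(path, index=False)


# -- configs and scenarios -------------------------------------------------


def read_config(path: str | Path) -> TrialConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return TrialConfig.from_dict(data)


def write_config(config: TrialConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_scenario(path: str | Path) -> ScenarioTruth:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ScenarioTruth.from_dict(data)


def write_scenario(truth: ScenarioTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh, sort_keys=True)


# -- reports ---------------------------------------------------------------


def write_summary_report(
    summary: PosteriorSummary,
    path: str | Path,
    labels: Sequence[str] | None = None,
    fmt: str = "csv",
) -> None:
    """Flat per-arm interim report; pass blinded labels for DSMB output."""
    frame = summary.to_frame(labels)
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format="%.6f")
    elif fmt == "json":
        payload = {
            "arms": frame.to_dict(orient="records"),
            "n_draws": summary.n_draws,
            "m_imputations": summary.m_imputations,
            "seed": summary.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


# -- manifests and audit log -----------------------------------------------


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Deterministic provenance record for one run.

    Contains the byte digest of every input file, the canonical config
    hash, all seeds, and the software version — everything needed to
    reproduce the run exactly. Reruns with identical inputs and seeds
    produce byte-identical manifests.
    """

    command: str
    config_hash: str
    config_file_digest: str | None
    input_digests: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, int | None] = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, separators=(",", ":"))


def append_manifest(manifest: RunManifest, path: str | Path) -> None:
    """Append one manifest line (manifest files are append-only JSON lines)."""
    with open(path, "a") as fh:
        fh.write(manifest.to_json() + "\n")


def append_audit_entry(path: str | Path, entry: dict) -> None:
    """Append a timestamped JSON-lines audit entry (the wall-clock trail)."""
    stamped = {"timestamp": datetime.now(timezone.utc).isoformat(), **entry}
    with open(path, "a") as fh:
        fh.write(json.dumps(stamped, sort_keys=True, default=float) + "\n")
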