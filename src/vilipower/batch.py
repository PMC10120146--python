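"""Scenario I/O, batch reports and the seeded fixture generator.

Scenario files are flat JSON objects (or lists of objects) with keys
``name, ps, peep, vt, c, f, pt`` plus optional waveform/regional keys
``ti, r, waveform, posture, gradient_span``; batch CSV files use the same
headers.  Pressures are cmH2O, volumes L, times s, frequency breaths/min.
Reports are emitted as TSV (stable column order) or JSON, with energies in
both cmH2O·L and joules.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from . import regional as regional_mod
from . import targets as targets_mod
from . import waveform as waveform_mod
from .energetics import ThresholdPolicy, partition
from .errors import VilipowerError
from .scenario import VentilationScenario

SCENARIO_KEYS = ("ps", "peep", "vt", "c", "f", "pt")
OPTIONAL_KEYS = ("ti", "r", "waveform", "posture", "gradient_span")

REPORT_COLUMNS = [
    "name", "ps", "peep", "vt", "c", "f", "pt", "error",
    "w_elastic", "w_drive", "hr_drive", "hr_elastic", "sr_drive", "sr_elastic",
    "hazardous_energy_drive", "hazardous_energy_elastic",
    "driving_power", "elastic_power", "damaging_power_drive", "damaging_power_elastic",
    "driving_power_j", "elastic_power_j", "damaging_power_drive_j",
    "damaging_power_elastic_j",
]


@dataclass
class BatchRecord:
    """One named scenario row, or its row-level validation failure."""

    name: str
    raw: dict
    scenario: VentilationScenario | None = None
    error: str | None = None


@dataclass
class ScenarioBatch:
    """A named collection of scenario records with row-level error capture."""

    records: list[BatchRecord] = field(default_factory=list)
    source: str | None = None

    def __iter__(self) -> Iterator[BatchRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def valid(self) -> list[BatchRecord]:
        return [r for r in self.records if r.scenario is not None]

    @property
    def errors(self) -> list[BatchRecord]:
        return [r for r in self.records if r.error is not None]


def _coerce_record(name: str, raw: dict) -> BatchRecord:
    kwargs = {}
    for key in SCENARIO_KEYS:
        value = raw.get(key)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        kwargs[key] = float(value)
    try:
        scenario = VentilationScenario(name=name, **kwargs)
    except (VilipowerError, TypeError) as exc:
        return BatchRecord(name=name, raw=raw, error=str(exc))
    return BatchRecord(name=name, raw=raw, scenario=scenario)


def batch_from_rows(rows: list[dict], source: str | None = None) -> ScenarioBatch:
    """Build a batch from parsed row dicts, enforcing unique names."""
    batch = ScenarioBatch(source=source)
    seen: set[str] = set()
    for i, raw in enumerate(rows):
        name = str(raw.get("name") or f"scenario_{i}")
        if name in seen:
            batch.records.append(
                BatchRecord(name=name, raw=raw, error=f"duplicate scenario name {name!r}")
            )
            continue
        seen.add(name)
        batch.records.append(_coerce_record(name, raw))
    return batch


def load_batch(path: str | Path) -> ScenarioBatch:
    """Load scenarios from a JSON file (object or list) or a CSV table."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        rows = payload if isinstance(payload, list) else [payload]
    elif path.suffix.lower() in (".csv", ".tsv"):
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        rows = pd.read_csv(path, sep=sep).to_dict(orient="records")
    else:
        raise ValueError(f"unsupported scenario file type: {path.suffix!r}")
    return batch_from_rows(rows, source=str(path))


def run_report(
    batch: ScenarioBatch,
    *,
    desired_ratio: float | None = None,
    variant: str = "drive",
    kind: str = "hazard",
    regional: bool = False,
    policy: ThresholdPolicy = "clamp",
    log: bool = True,
) -> pd.DataFrame:
    """One report row per scenario; row-level failures never abort the batch.

    Optionally appends inverse-solved targets (``desired_ratio``) and
    regional hazard-spread summaries.  Output row order follows the batch.
    """
    rows = []
    for record in batch:
        row: dict = {"name": record.name, "error": record.error}
        if record.scenario is not None:
            s = record.scenario
            row.update({k: getattr(s, k) for k in SCENARIO_KEYS})
            try:
                row.update(partition(s, policy).as_dict())
                if desired_ratio is not None:
                    rx = targets_mod.prescribe(s, desired_ratio, variant, kind)
                    row.update(
                        {
                            "target_dp": rx.target_dp,
                            "target_ps": rx.target_ps,
                            "target_vt": rx.target_vt,
                        }
                    )
                if regional:
                    posture = record.raw.get("posture") or "supine"
                    span = record.raw.get("gradient_span")
                    span = None if span is None or pd.isna(span) else float(span)
                    prof = regional_mod.regional_hazard(
                        s, posture=posture, pleural_gradient_span=span
                    )
                    row["hr_drive_nondependent"] = prof.hr_drive_local[-1]
                    row["hr_drive_dependent"] = prof.hr_drive_local[0]
            except VilipowerError as exc:
                row["error"] = str(exc)
        rows.append(row)
    columns = REPORT_COLUMNS + [
        c for c in ("target_dp", "target_ps", "target_vt",
                    "hr_drive_nondependent", "hr_drive_dependent")
        if any(c in r for r in rows)
    ]
    report = pd.DataFrame(rows).reindex(columns=columns)
    if log:
        n_err = int(report["error"].notna().sum()) if len(report) else 0
        print(
            f"vilipower: {len(report)} scenario(s), {n_err} error row(s)",
            file=sys.stderr,
        )
    return report


def write_report(report: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write a report as TSV (default) or JSON records."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        path.write_text(report.to_json(orient="records", indent=2))
    elif fmt == "tsv":
        report.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unsupported report format {fmt!r}")


def generate_fixtures(seed: int, n: int) -> ScenarioBatch:
    """Seeded random scenario grid spanning the clinically plausible range.

    PEEP ~ U[0, 15] cmH2O, DP ~ U[5, 25] cmH2O (so Ps = PEEP + DP),
    Pt ~ U[PEEP, Ps], V_T ~ U[0.2, 0.8] L, f ~ U[10, 35] breaths/min.
    The same seed always reproduces the same batch.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n!r}")
    rng = np.random.default_rng(seed)
    peep = rng.uniform(0.0, 15.0, n)
    dp = rng.uniform(5.0, 25.0, n)
    ps = peep + dp
    pt = rng.uniform(peep, ps)
    vt = rng.uniform(0.2, 0.8, n)
    f = rng.uniform(10.0, 35.0, n)
    rows = [
        {
            "name": f"fixture_{i:04d}",
            "ps": float(ps[i]),
            "peep": float(peep[i]),
            "vt": float(vt[i]),
            "f": float(f[i]),
            "pt": float(pt[i]),
        }
        for i in range(n)
    ]
    return batch_from_rows(rows, source=f"fixtures(seed={seed}, n={n})")


def batch_to_json(batch: ScenarioBatch) -> str:
    """Serialize a batch back to the flat-JSON scenario list format."""
    rows = []
    for record in batch:
        if record.scenario is not None:
            rows.append(record.scenario.as_dict())
        else:
            rows.append({**record.raw, "error": record.error})
    return json.dumps(rows, indent=2)
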