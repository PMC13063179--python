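"""Delimited-text readers and writers for the screening pipeline.

Canonical interchange is comma-separated UTF-8 with a header row.  Schemas:

- ``plate_map.csv``: plate_id, well, role, content, pool_id, i_tot_nM
  (content is a ``;``-joined compound list or a control-ligand name)
- ``cq_results.csv``: plate_id, well, cq (empty field = censored)
- ``ground_truth.csv``: compound_id, class, kd_nM, shift_cycles
- stage outputs: qc_report.csv, hits.csv, deconvolution_plan.csv,
  summary.csv, kd_report.csv

Readers join map and Cq tables on (plate_id, well), reject duplicate keys
and Cq rows without a map entry, and report offending line numbers.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .affinity import KdEstimate
from .screen import (
    HitCall,
    HitStatus,
    QCReport,
    ScreenSummary,
    WellRecord,
    WellRole,
)
from .simulate import CompoundSpec

__all__ = [
    "ParseError",
    "MAP_COLUMNS",
    "CQ_COLUMNS",
    "read_plate_tables",
    "write_plate_map",
    "write_cq_results",
    "write_ground_truth",
    "read_ground_truth",
    "write_qc_report",
    "write_hits",
    "read_hits",
    "write_deconvolution_plan",
    "read_deconvolution_plan",
    "write_summary",
    "write_kd_report",
    "read_dilution_series",
]

MAP_COLUMNS = ["plate_id", "well", "role", "content", "pool_id", "i_tot_nM"]
CQ_COLUMNS = ["plate_id", "well", "cq"]
HIT_COLUMNS = ["subject", "pool_id", "delta_cq", "counter_delta_cq", "status", "note"]


class ParseError(ValueError):
    """Malformed or inconsistent input table."""


def _read_csv(path: str, required: Sequence[str], unit_alternatives: Mapping[str, str] = {}) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    columns = list(df.columns)
    missing = [c for c in required if c not in columns and c not in unit_alternatives]
    for canonical, alt in unit_alternatives.items():
        if canonical not in columns and alt not in columns:
            missing.append(canonical)
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {missing}; found {columns}"
        )
    return df


def _parse_float(path: str, line: int, name: str, raw: str) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError:
        raise ParseError(f"{path}:{line}: {name} is not a number: {raw!r}") from None
    if not math.isfinite(value):
        raise ParseError(f"{path}:{line}: {name} must be finite, got {raw!r}")
    return value


def read_plate_tables(map_path: str, cq_path: str) -> List[WellRecord]:
    """Join a plate map with Cq results into validated well records.

    Map wells without a Cq row are kept with a censored Cq; Cq rows without
    a map entry are orphans and rejected.
    """
    map_df = _read_csv(
        map_path, MAP_COLUMNS[:-1], unit_alternatives={"i_tot_nM": "i_tot_uM"}
    )
    cq_df = _read_csv(cq_path, CQ_COLUMNS)
    conc_col = "i_tot_nM" if "i_tot_nM" in map_df.columns else "i_tot_uM"
    conc_scale = 1.0 if conc_col == "i_tot_nM" else 1_000.0

    cq_by_key: Dict[Tuple[str, str], Optional[float]] = {}
    for idx, row in cq_df.iterrows():
        line = int(idx) + 2  # header is line 1
        key = (row["plate_id"].strip(), row["well"].strip())
        if key in cq_by_key:
            raise ParseError(
                f"{cq_path}:{line}: duplicate Cq entry for well {key[0]}:{key[1]}"
            )
        cq_by_key[key] = _parse_float(cq_path, line, "cq", row["cq"])

    records: List[WellRecord] = []
    seen: Dict[Tuple[str, str], int] = {}
    for idx, row in map_df.iterrows():
        line = int(idx) + 2
        key = (row["plate_id"].strip(), row["well"].strip())
        if key in seen:
            raise ParseError(
                f"{map_path}:{line}: duplicate map entry for well {key[0]}:{key[1]} "
                f"(first at line {seen[key]})"
            )
        seen[key] = line
        content_raw = row["content"].strip()
        content = tuple(c for c in content_raw.split(";") if c) if content_raw else ()
        pool_raw = row["pool_id"].strip()
        i_tot = _parse_float(map_path, line, conc_col, row[conc_col])
        if i_tot is not None:
            i_tot *= conc_scale
        try:
            records.append(
                WellRecord(
                    plate_id=key[0],
                    well=key[1],
                    role=WellRole(row["role"].strip()),
                    content=content,
                    i_tot=i_tot,
                    pool_id=pool_raw or None,
                    cq=cq_by_key.pop(key, None),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{map_path}:{line}: {exc}") from None

    if cq_by_key:
        orphan = next(iter(cq_by_key))
        raise ParseError(
            f"{cq_path}: {len(cq_by_key)} Cq row(s) without a plate-map entry, "
            f"e.g. well {orphan[0]}:{orphan[1]}"
        )
    return records


def write_plate_map(wells: Sequence[WellRecord], path: str) -> None:
    rows = [
        {
            "plate_id": w.plate_id,
            "well": w.well,
            "role": w.role.value,
            "content": ";".join(w.content),
            "pool_id": w.pool_id or "",
            "i_tot_nM": "" if w.i_tot is None else repr(w.i_tot),
        }
        for w in wells
    ]
    pd.DataFrame(rows, columns=MAP_COLUMNS).to_csv(path, index=False)


def write_cq_results(wells: Sequence[WellRecord], path: str) -> None:
    rows = [
        {
            "plate_id": w.plate_id,
            "well": w.well,
            "cq": "" if w.cq is None else repr(w.cq),
        }
        for w in wells
    ]
    pd.DataFrame(rows, columns=CQ_COLUMNS).to_csv(path, index=False)


def write_ground_truth(library: Sequence[CompoundSpec], path: str) -> None:
    rows = [
        {
            "compound_id": c.compound_id,
            "class": c.compound_class,
            "kd_nM": "" if not math.isfinite(c.kd) else repr(c.kd),
            "shift_cycles": repr(c.interference_shift),
        }
        for c in library
    ]
    pd.DataFrame(
        rows, columns=["compound_id", "class", "kd_nM", "shift_cycles"]
    ).to_csv(path, index=False)


def read_ground_truth(path: str) -> List[CompoundSpec]:
    df = _read_csv(path, ["compound_id", "class", "kd_nM", "shift_cycles"])
    out: List[CompoundSpec] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        kd = _parse_float(path, line, "kd_nM", row["kd_nM"])
        shift = _parse_float(path, line, "shift_cycles", row["shift_cycles"]) or 0.0
        out.append(
            CompoundSpec(
                compound_id=row["compound_id"].strip(),
                compound_class=row["class"].strip(),
                kd=kd if kd is not None else math.inf,
                interference_shift=shift,
            )
        )
    return out


def write_qc_report(qc: QCReport, path: str, efficiency: float = 1.0) -> None:
    row = qc.rounded()
    row["fold_range"] = round(qc.fold_range(efficiency), 1)
    pd.DataFrame([row]).to_csv(path, index=False)


def write_hits(calls: Sequence[HitCall], path: str) -> None:
    rows = [
        {
            "subject": c.subject,
            "pool_id": c.pool_id or "",
            "delta_cq": repr(c.delta_cq),
            "counter_delta_cq": ""
            if c.counter_delta_cq is None
            else repr(c.counter_delta_cq),
            "status": c.status.value,
            "note": c.note,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, index=False)


def read_hits(path: str) -> List[HitCall]:
    df = _read_csv(path, HIT_COLUMNS)
    out: List[HitCall] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        delta = _parse_float(path, line, "delta_cq", row["delta_cq"])
        if delta is None:
            raise ParseError(f"{path}:{line}: delta_cq is required")
        counter = (
            _parse_float(path, line, "counter_delta_cq", row["counter_delta_cq"])
            if row["counter_delta_cq"].strip()
            else None
        )
        try:
            status = HitStatus(row["status"].strip())
        except ValueError:
            raise ParseError(
                f"{path}:{line}: unknown status {row['status']!r}"
            ) from None
        out.append(
            HitCall(
                subject=row["subject"].strip(),
                pool_id=row["pool_id"].strip() or None,
                delta_cq=delta,
                counter_delta_cq=counter,
                status=status,
                note=row["note"],
            )
        )
    return out


def write_deconvolution_plan(plan: Sequence[Tuple[str, float]], path: str) -> None:
    rows = [
        {"compound_id": cid, "retest_conc_nM": repr(conc)} for cid, conc in plan
    ]
    pd.DataFrame(rows, columns=["compound_id", "retest_conc_nM"]).to_csv(
        path, index=False
    )


def read_deconvolution_plan(path: str) -> List[Tuple[str, float]]:
    df = _read_csv(path, ["compound_id", "retest_conc_nM"])
    out: List[Tuple[str, float]] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        conc = _parse_float(path, line, "retest_conc_nM", row["retest_conc_nM"])
        if conc is None:
            raise ParseError(f"{path}:{line}: retest_conc_nM is required")
        out.append((row["compound_id"].strip(), conc))
    return out


def write_summary(summary: ScreenSummary, path: str) -> None:
    pd.DataFrame([summary.as_dict()]).to_csv(path, index=False)


def write_kd_report(estimate: KdEstimate, path: str, per_well_path: Optional[str] = None) -> None:
    """One-row summary plus an optional per-well breakdown table."""
    pd.DataFrame(
        [
            {
                "mean_kd_nM": "" if estimate.mean_kd is None else repr(estimate.mean_kd),
                "sd_kd_nM": "" if estimate.sd_kd is None else repr(estimate.sd_kd),
                "n_used": estimate.n_used,
                "n_censored_low": estimate.n_censored_low,
                "n_censored_high": estimate.n_censored_high,
            }
        ]
    ).to_csv(path, index=False)
    if per_well_path is not None:
        rows = [
            {
                "replicate_id": w.replicate_id,
                "i_tot_nM": repr(w.i_tot),
                "cq": "" if w.cq is None else repr(w.cq),
                "kd_nM": "" if est.kd is None else repr(est.kd),
                "censor": est.censor or "",
            }
            for w, est in estimate.per_well
        ]
        pd.DataFrame(
            rows, columns=["replicate_id", "i_tot_nM", "cq", "kd_nM", "censor"]
        ).to_csv(per_well_path, index=False)


def read_dilution_series(path: str):
    """Read a ``well,i_tot_nM,cq`` dilution-series table.

    Returns a list of :class:`~cqscreen.affinity.WellMeasurement`.
    """
    from .affinity import WellMeasurement

    df = _read_csv(path, ["well", "i_tot_nM", "cq"])
    out = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        i_tot = _parse_float(path, line, "i_tot_nM", row["i_tot_nM"])
        if i_tot is None:
            raise ParseError(f"{path}:{line}: i_tot_nM is required")
        cq = _parse_float(path, line, "cq", row["cq"])
        out.append(WellMeasurement(cq=cq, i_tot=i_tot, replicate_id=row["well"].strip()))
    return out
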