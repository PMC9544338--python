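"""Readers/writers for the plain-text formats used across the package.

Traces travel as long-format CSV (``well,time_s,signal``), plate maps as
``well,role,compound_id,concentration_uM`` CSV, hit calls as TSV, BRET
series as ``time_s,donor,acceptor`` CSV plus a JSON sidecar with the
injection indices, and parameter sets / fit results / summaries as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bret_analysis import BretSeries, BretSummary
from .errors import InvalidInputError
from .hts_screen import HitCall, ScreenPlate, Well
from .kinetic_models import KineticParams, KineticTrace

TRACE_COLUMNS = ["well", "time_s", "signal"]
PLATE_MAP_COLUMNS = ["well", "role", "compound_id", "concentration_uM"]


# -- traces -----------------------------------------------------------------

def traces_to_frame(traces: dict[str, KineticTrace]) -> pd.DataFrame:
    frames = []
    for well_id in sorted(traces):
        tr = traces[well_id]
        frames.append(pd.DataFrame({"well": well_id, "time_s": tr.times, "signal": tr.signal}))
    return pd.concat(frames, ignore_index=True)


def write_traces_csv(traces: dict[str, KineticTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.10g")


def read_traces_csv(
    path,
    assay_kind: str,
    injection_indices: dict[str, int] | None = None,
) -> dict[str, KineticTrace]:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"trace CSV missing columns: {sorted(missing)}")
    out = {}
    for well_id, grp in df.groupby("well", sort=True):
        inj = None
        if assay_kind == "displacement":
            if not injection_indices or str(well_id) not in injection_indices:
                raise InvalidInputError(f"no injection index for well {well_id!r}")
            inj = int(injection_indices[str(well_id)])
        out[str(well_id)] = KineticTrace(
            grp["time_s"].to_numpy(),
            grp["signal"].to_numpy(),
            assay_kind,
            injection_index=inj,
            well_id=str(well_id),
        )
    return out


# -- plates -----------------------------------------------------------------

def write_plate_map_csv(plate: ScreenPlate, path) -> None:
    rows = [
        {
            "well": wid,
            "role": well.role,
            "compound_id": well.compound_id or "",
            "concentration_uM": well.concentration_uM if well.concentration_uM is not None else "",
        }
        for wid, well in sorted(plate.wells.items())
    ]
    pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS).to_csv(path, index=False)


def write_plate(plate: ScreenPlate, map_path, traces_path) -> None:
    write_plate_map_csv(plate, map_path)
    traces = {wid: w.trace for wid, w in plate.wells.items() if w.trace is not None}
    write_traces_csv(traces, traces_path)


def read_plate(map_path, traces_path, plate_id: str = "plate") -> ScreenPlate:
    pmap = pd.read_csv(map_path, dtype={"well": str, "role": str}, keep_default_na=False)
    missing = set(PLATE_MAP_COLUMNS) - set(pmap.columns)
    if missing:
        raise InvalidInputError(f"plate map missing columns: {sorted(missing)}")
    traces = read_traces_csv(traces_path, "binding_hydrolysis")
    wells: dict[str, Well] = {}
    for _, row in pmap.iterrows():
        wid = str(row["well"])
        conc = row["concentration_uM"]
        wells[wid] = Well(
            role=str(row["role"]),
            compound_id=str(row["compound_id"]) or None,
            concentration_uM=float(conc) if str(conc) != "" else None,
            trace=traces.get(wid),
        )
    return ScreenPlate(plate_id=plate_id, wells=wells)


# -- hit calls --------------------------------------------------------------

def hits_to_frame(hits: list[HitCall]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(h) for h in hits])


def write_hits_tsv(hits: list[HitCall], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- BRET -------------------------------------------------------------------

def write_bret(series: BretSeries, csv_path, sidecar_path) -> None:
    pd.DataFrame(
        {"time_s": series.times, "donor": series.donor, "acceptor": series.acceptor}
    ).to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = {
        "injection_index": series.injection_index,
        "second_injection_index": series.second_injection_index,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_bret(csv_path, sidecar_path) -> BretSeries:
    df = pd.read_csv(csv_path)
    missing = {"time_s", "donor", "acceptor"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"BRET CSV missing columns: {sorted(missing)}")
    sidecar = json.loads(Path(sidecar_path).read_text())
    return BretSeries(
        times=df["time_s"].to_numpy(),
        donor=df["donor"].to_numpy(),
        acceptor=df["acceptor"].to_numpy(),
        injection_index=int(sidecar["injection_index"]),
        second_injection_index=(
            int(sidecar["second_injection_index"])
            if sidecar.get("second_injection_index") is not None
            else None
        ),
    )


# -- JSON helpers -----------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def params_to_json(params: KineticParams, path) -> None:
    write_json(params, path)


def params_from_json(path) -> KineticParams:
    return KineticParams(**json.loads(Path(path).read_text()))


def summary_to_json(summary: BretSummary, path) -> None:
    write_json(summary, path)
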