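"""Plain-text readers and writers shared by all pipeline stages.

Spectra travel as two-column CSV (field_G, intensity) with a JSON sidecar
for the acquisition settings; kinetic series as CSV with the temperature in
a header comment; feature tables and oil records as CSV; spin systems and
pipeline configs as YAML.  A minimal JCAMP-DX (XYDATA / XYPOINTS) reader is
provided for interoperability.  Every writer round-trips through its reader
to an equal in-memory value.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .chemometrics import FeatureMatrix
from .kinetics import KineticSeries
from .spin_sim import AcquisitionSettings, SpinSystem, Spectrum
from .stability_model import OilRecord

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "read_jcamp",
    "write_series",
    "read_series",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_oil_records",
    "read_oil_records",
    "load_spin_systems",
    "dump_spin_systems",
]


# -- spectra ----------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"field_G": spectrum.field, "intensity": spectrum.intensity})
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(asdict(spectrum.meta), indent=2) + "\n")


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = AcquisitionSettings()
    if sidecar.exists():
        meta = AcquisitionSettings(**json.loads(sidecar.read_text()))
    return Spectrum(df["field_G"].to_numpy(), df["intensity"].to_numpy(), meta)


def read_jcamp(path: str | Path) -> Spectrum:
    """Read a minimal JCAMP-DX record (XYPOINTS or AFFN XYDATA=(X++(Y..Y)))."""
    lines = Path(path).read_text().splitlines()
    params: dict[str, str] = {}
    data_mode = None
    xs: list[float] = []
    ys: list[float] = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "XYDATA":
                data_mode = "xydata"
            elif key == "XYPOINTS":
                data_mode = "xypoints"
            elif key == "END":
                data_mode = None
            else:
                params[key] = value
                data_mode = None
            continue
        if data_mode == "xypoints":
            for pair in line.replace(";", " ").split():
                x_str, _, y_str = pair.partition(",")
                xs.append(float(x_str))
                ys.append(float(y_str))
        elif data_mode == "xydata":
            vals = [float(v) for v in line.replace(",", " ").split()]
            if len(vals) >= 2:
                xs.append(vals[0])
                ys.extend(vals[1:])
    if data_mode is None and not ys:
        raise ValueError(f"no XYDATA/XYPOINTS block found in {path}")

    yfac = float(params.get("YFACTOR", 1.0))
    if xs and len(xs) == len(ys):  # XYPOINTS: explicit abscissae
        field = np.asarray(xs)
    else:  # XYDATA: first X per line, uniform grid reconstructed from header
        first = float(params.get("FIRSTX", xs[0] if xs else 0.0))
        last = float(params.get("LASTX", xs[-1] if xs else len(ys) - 1))
        field = np.linspace(first, last, len(ys))
    intensity = np.asarray(ys) * yfac
    return Spectrum(field, intensity)


# -- kinetic series ---------------------------------------------------------

def write_series(series: KineticSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# temperature_C: {series.temperature}\n")
        fh.write("time_min,intensity\n")
        for t, i in zip(series.time, series.intensity):
            fh.write(f"{float(t)!r},{float(i)!r}\n")


def read_series(path: str | Path) -> KineticSeries:
    temperature = 90.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            temperature = float(first.split(":")[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    return KineticSeries(
        df["time_min"].to_numpy(), df["intensity"].to_numpy(), temperature=temperature
    )


# -- feature matrices -------------------------------------------------------

def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.insert(0, "group", matrix.groups if matrix.groups is not None else "")
    out.index.name = "sample"
    header = (
        f"# scaling_state: {matrix.scaling_state}\n"
        f"# assay_columns: {','.join(matrix.assay_columns)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        out.to_csv(fh)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    state = "raw"
    assay_cols: tuple[str, ...] = ()
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("# scaling_state:"):
                state = line.split(":", 1)[1].strip()
            elif line.startswith("# assay_columns:"):
                raw = line.split(":", 1)[1].strip()
                assay_cols = tuple(c for c in raw.split(",") if c)
            elif line.startswith("#"):
                pass
            else:
                fh.seek(pos)
                break
            pos = fh.tell()
        df = pd.read_csv(fh, index_col="sample")
    groups = None
    if "group" in df.columns:
        g = df.pop("group")
        if g.notna().any() and (g.astype(str) != "").any():
            groups = g
    return FeatureMatrix(df, groups=groups, scaling_state=state, assay_columns=assay_cols)


# -- oil records ------------------------------------------------------------

_FA_KEYS = ("C16:0", "C18:0", "C18:1", "C18:2")
_UNITS_ROW = {
    "method": "",
    "yield_pct": "% w/w",
    "PV": "ueq O2/g",
    "TPC": "mg CA/g",
    "RSA": "umol trolox/g",
    "FFA": "%",
    "AUC_measured": "a.u.",
}


def write_oil_records(records: Sequence[OilRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "method": r.method,
            "yield_pct": r.yield_pct,
            "PV": r.PV,
            "TPC": r.TPC,
            "RSA": r.RSA,
            "FFA": r.FFA,
            "AUC_measured": r.AUC_measured,
            "yield_sd": r.yield_sd,
            "PV_sd": r.PV_sd,
            "TPC_sd": r.TPC_sd,
            "RSA_sd": r.RSA_sd,
            "FFA_sd": r.FFA_sd,
            "AUC_sd": r.AUC_sd,
        }
        for k in _FA_KEYS:
            row[k] = r.fatty_acids.get(k)
            row[f"{k}_sd"] = r.fatty_acids_sd.get(k)
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        units = ",".join(_UNITS_ROW.get(c, "") for c in df.columns)
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False)


def read_oil_records(path: str | Path) -> list[OilRecord]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            fh.seek(0)
        df = pd.read_csv(fh)
    records = []
    for _, row in df.iterrows():
        def get(name):
            v = row.get(name)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        fa = {k: float(row[k]) for k in _FA_KEYS if k in row and pd.notna(row[k])}
        fa_sd = {
            k: float(row[f"{k}_sd"])
            for k in _FA_KEYS
            if f"{k}_sd" in row and pd.notna(row[f"{k}_sd"])
        }
        records.append(
            OilRecord(
                method=str(row["method"]),
                yield_pct=get("yield_pct"),
                PV=get("PV"),
                TPC=get("TPC"),
                RSA=get("RSA"),
                FFA=get("FFA"),
                fatty_acids=fa,
                AUC_measured=get("AUC_measured"),
                yield_sd=get("yield_sd"),
                PV_sd=get("PV_sd"),
                TPC_sd=get("TPC_sd"),
                RSA_sd=get("RSA_sd"),
                FFA_sd=get("FFA_sd"),
                fatty_acids_sd=fa_sd,
                AUC_sd=get("AUC_sd"),
            )
        )
    return records


# -- spin systems (YAML) ----------------------------------------------------

def load_spin_systems(path: str | Path) -> list[SpinSystem]:
    doc = yaml.safe_load(Path(path).read_text())
    entries = doc["systems"] if isinstance(doc, dict) else doc
    return [SpinSystem(**e) for e in entries]


def dump_spin_systems(systems: Sequence[SpinSystem], path: str | Path) -> None:
    doc = {"systems": [asdict(s) for s in systems]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
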