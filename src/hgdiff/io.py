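"""CSV/JSON/YAML readers and writers and the run configuration.

One CSV dialect per data kind, shared across the package:

* diffusion tables — ``C1,C2,X1,D11,sd11,D12,sd12,D21,sd21,D22,sd22``
* dispersion peaks — ``t_s,V_volts``
* Job series — ``x,response``
* titrations — ``ratio,ddelta_<proton>,...``

Readers validate the header and report offending columns by name;
writers round-trip losslessly (full float precision).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DIK_COLUMNS, DiffusionMatrix, TernaryComposition
from .stoichiometry import JobSeries, TitrationSeries
from .taylor import DispersionPeak, TaylorInstrument

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_dik_csv",
    "write_dik_csv",
    "read_peak_csv",
    "write_peak_csv",
    "read_job_csv",
    "read_titration_csv",
    "write_report",
]


class SchemaError(ValueError):
    """A file does not conform to the expected column schema."""


_KNOWN_CONFIG_KEYS = {
    "instrument", "system", "tolerances", "out_dir", "log_level", "seed",
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    instrument: dict = field(default_factory=dict)
    system: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=dict)
    out_dir: str = "results"
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_CONFIG_KEYS
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def make_instrument(self) -> TaylorInstrument:
        return TaylorInstrument(**self.instrument)


def _require_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; "
                          f"found {list(df.columns)}")


def read_dik_csv(path: str | Path) -> list[tuple[TernaryComposition, DiffusionMatrix]]:
    """Read a diffusion-coefficient table; malformed rows are reported by line."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DIK_COLUMNS, path)
    rows, errors = [], []
    for idx, r in df.iterrows():
        try:
            comp = TernaryComposition(float(r["C1"]), float(r["C2"]))
            mat = DiffusionMatrix(
                D11=float(r["D11"]), D12=float(r["D12"]),
                D21=float(r["D21"]), D22=float(r["D22"]),
                sd11=float(r["sd11"]), sd12=float(r["sd12"]),
                sd21=float(r["sd21"]), sd22=float(r["sd22"]),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {idx + 2}: {exc}")   # +2: header + 1-based
            continue
        rows.append((comp, mat))
    if errors:
        raise SchemaError(f"{path}: " + "; ".join(errors))
    return rows


def write_dik_csv(rows: list[tuple[TernaryComposition, DiffusionMatrix]],
                  path: str | Path) -> None:
    recs = []
    for comp, m in rows:
        recs.append({
            "C1": comp.C1, "C2": comp.C2, "X1": comp.X1,
            "D11": m.D11, "sd11": m.sd11 if m.sd11 is not None else 0.0,
            "D12": m.D12, "sd12": m.sd12 if m.sd12 is not None else 0.0,
            "D21": m.D21, "sd21": m.sd21 if m.sd21 is not None else 0.0,
            "D22": m.D22, "sd22": m.sd22 if m.sd22 is not None else 0.0,
        })
    pd.DataFrame(recs, columns=DIK_COLUMNS).to_csv(path, index=False)


def read_peak_csv(path: str | Path,
                  instrument: TaylorInstrument) -> DispersionPeak:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["t_s", "V_volts"], path)
    return DispersionPeak(t=df["t_s"].to_numpy(), V=df["V_volts"].to_numpy(),
                          instrument=instrument)


def write_peak_csv(peak: DispersionPeak, path: str | Path) -> None:
    pd.DataFrame({"t_s": peak.t, "V_volts": peak.V}).to_csv(path, index=False)


def read_job_csv(path: str | Path, C_total: float,
                 wavelength: float | None = None) -> JobSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["x", "response"], path)
    return JobSeries(C_total=C_total, x=df["x"].to_numpy(),
                     y=df["response"].to_numpy(), wavelength=wavelength)


def read_titration_csv(path: str | Path, C_guest: float) -> TitrationSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if "ratio" not in df.columns:
        raise SchemaError(f"{path}: missing column ['ratio']")
    protons = [c for c in df.columns if c.startswith("ddelta_")]
    if not protons:
        raise SchemaError(f"{path}: no ddelta_<proton> columns")
    return TitrationSeries(
        ratio=df["ratio"].to_numpy(),
        ddelta={c.removeprefix("ddelta_"): df[c].to_numpy() for c in protons},
        C_guest=C_guest,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a report dict to JSON (numpy types coerced)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
        fh.write("\n")
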