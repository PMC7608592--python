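"""CSV schemas, validated readers/writers and the run configuration.

All tables are UTF-8, comma-delimited, dot-decimal CSV with a required header.
Unit suffixes are embedded in the column names to prevent unit drift.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import pandas as pd
import yaml

from .nmr import AmidePeak, ZZDataset
from .progress import ProgressCurve

__all__ = [
    "SchemaError",
    "RATE_TABLE_SCHEMA",
    "PROGRESS_CURVE_SCHEMA",
    "ZZ_SCHEMA",
    "PEAK_SCHEMA",
    "read_table",
    "write_table",
    "read_rate_table",
    "read_progress_curve",
    "write_progress_curve",
    "read_zz_dataset",
    "write_zz_dataset",
    "read_peak_pairs",
    "write_peak_pairs",
    "RunConfig",
]


class SchemaError(ValueError):
    """A table failed schema validation."""


RATE_TABLE_SCHEMA = {
    "bG1P_uM": float,
    "bG16BP_uM": float,
    "ET_uM": float,
    "v0_uM_per_s": float,
    "replicate": int,
}
PROGRESS_CURVE_SCHEMA = {"time_s": float, "value": float, "kind": str}
ZZ_SCHEMA = {
    "t_mix_s": float,
    "I_AA": float,
    "I_BB": float,
    "I_AB": float,
    "I_BA": float,
}
PEAK_SCHEMA = {
    "residue": int,
    "resname": str,
    "state": str,
    "dH_ppm": float,
    "dN_ppm": float,
    "intensity": float,
}


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read and validate a CSV against a column schema (order preserved)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file does not exist")
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise SchemaError(f"{path}: not valid UTF-8 ({exc})") from exc
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty table") from exc
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if len(frame) == 0:
        raise SchemaError(f"{path}: table has a header but no rows")
    for col, dtype in schema.items():
        if dtype is str:
            frame[col] = frame[col].astype(str)
            continue
        try:
            converted = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise SchemaError(
                f"{path}: column {col!r} has non-{dtype.__name__} value near line {line}"
            ) from exc
        frame[col] = converted.astype(dtype)
    return frame[list(schema)]


def write_table(path, frame: pd.DataFrame, schema: dict) -> None:
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"cannot write table: missing column(s) {missing}")
    frame[list(schema)].to_csv(path, index=False, encoding="utf-8")


def read_rate_table(path) -> pd.DataFrame:
    return read_table(path, RATE_TABLE_SCHEMA)


def read_progress_curve(path) -> ProgressCurve:
    frame = read_table(path, PROGRESS_CURVE_SCHEMA)
    kinds = frame["kind"].unique()
    if len(kinds) != 1:
        raise SchemaError(f"{path}: progress curve mixes kinds {list(kinds)}")
    return ProgressCurve(
        frame["time_s"].to_numpy(), frame["value"].to_numpy(), kind=str(kinds[0])
    )


def write_progress_curve(path, curve: ProgressCurve) -> None:
    frame = pd.DataFrame(
        {"time_s": curve.times, "value": curve.values, "kind": curve.kind}
    )
    write_table(path, frame, PROGRESS_CURVE_SCHEMA)


def read_zz_dataset(path) -> ZZDataset:
    frame = read_table(path, ZZ_SCHEMA)
    return ZZDataset(
        mixing_times=frame["t_mix_s"].to_numpy(),
        I_AA=frame["I_AA"].to_numpy(),
        I_BB=frame["I_BB"].to_numpy(),
        I_AB=frame["I_AB"].to_numpy(),
        I_BA=frame["I_BA"].to_numpy(),
    )


def write_zz_dataset(path, data: ZZDataset) -> None:
    frame = pd.DataFrame(
        {
            "t_mix_s": data.mixing_times,
            "I_AA": data.I_AA,
            "I_BB": data.I_BB,
            "I_AB": data.I_AB,
            "I_BA": data.I_BA,
        }
    )
    write_table(path, frame, ZZ_SCHEMA)


def _split_residue(residue: str):
    return residue[0], int(residue[1:])


def write_peak_pairs(path, pairs) -> None:
    rows = []
    for pair in pairs:
        for peak in pair:
            code, pos = _split_residue(peak.residue)
            rows.append(
                (pos, code, peak.state_label, peak.dH, peak.dN, peak.intensity)
            )
    frame = pd.DataFrame(rows, columns=list(PEAK_SCHEMA))
    write_table(path, frame, PEAK_SCHEMA)


def read_peak_pairs(path) -> list:
    frame = read_table(path, PEAK_SCHEMA)
    pairs = {}
    for _, row in frame.iterrows():
        residue = f"{row['resname']}{row['residue']}"
        peak = AmidePeak(
            residue, row["dH_ppm"], row["dN_ppm"], row["intensity"], row["state"]
        )
        pairs.setdefault(residue, {})[row["state"]] = peak
    out = []
    for residue, states in pairs.items():
        if "A" in states and "B" in states:
            out.append((states["A"], states["B"]))
    if not out:
        raise SchemaError(f"{path}: no residue has both A and B state peaks")
    return out


@dataclass
class RunConfig:
    """Flat run configuration; round-trips losslessly, unknown keys rejected."""

    units: str = "uM,s"
    out_dir: str = "out"
    seed: int = 0
    filter_max_bG16BP_uM: float | None = None
    lag_window_frac: float = 0.1
    rtol: float = 1e-8
    atol: float = 1e-12
    noise_relative_sd: float = 0.02

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
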