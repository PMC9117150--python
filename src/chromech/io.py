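"""Reading and writing the delimited-text formats the pipelines use.

Curve files are plain CSV with columns ``time_s, distance_um, force_pN``;
oscillation traces are CSV with metadata header lines of the form
``# key: value`` (frequency_Hz, pretension_pN, trap_stiffness_pN_per_um)
followed by columns ``time_s, trap_position_um, force_pN[, bead_position_um]``.
A manifest CSV lists curve files with group labels.  Output tables carry a
``# key: value`` provenance comment block.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .curves import ForceExtensionCurve
from .rheology import OscillationTrace

__all__ = [
    "read_curve",
    "write_curve",
    "read_trace",
    "write_trace",
    "read_manifest",
    "write_table",
    "write_run_record",
]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def read_curve(path, cycle_label: str | None = None) -> ForceExtensionCurve:
    """Read one force-extension curve from CSV/TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    label = cycle_label if cycle_label is not None else path.stem
    return ForceExtensionCurve.from_dataframe(df, cycle_label=label)


def write_curve(curve: ForceExtensionCurve, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": curve.time if curve.time is not None else np.arange(len(curve), dtype=float),
            "distance_um": curve.distance,
            "force_pN": curve.force,
        }
    )
    df.to_csv(path, index=False)


def read_trace(path) -> OscillationTrace:
    """Read an oscillation trace with its ``# key: value`` metadata header."""
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(":")
            try:
                meta[key.strip()] = float(value)
            except ValueError:
                pass
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    for required in ("frequency_Hz", "pretension_pN"):
        if required not in meta:
            raise ValueError(f"{path}: missing '# {required}:' metadata line")
    bead = df["bead_position_um"].to_numpy() if "bead_position_um" in df.columns else None
    return OscillationTrace(
        time=df["time_s"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        trap_position=df["trap_position_um"].to_numpy(),
        bead_position=bead,
        drive_frequency=meta["frequency_Hz"],
        pre_tension=meta["pretension_pN"],
    )


def write_trace(trace: OscillationTrace, path, trap_stiffness: float | None = None) -> None:
    cols = {
        "time_s": trace.time,
        "trap_position_um": trace.trap_position,
        "force_pN": trace.force,
    }
    if trace.bead_position is not None:
        cols["bead_position_um"] = trace.bead_position
    header = [
        f"# frequency_Hz: {trace.drive_frequency}",
        f"# pretension_pN: {trace.pre_tension}",
    ]
    if trap_stiffness is not None:
        header.append(f"# trap_stiffness_pN_per_um: {trap_stiffness}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_manifest(path) -> pd.DataFrame:
    """Manifest CSV: columns ``file`` and optional ``group``; paths resolved
    relative to the manifest's directory."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    if "file" not in df.columns:
        raise ValueError(f"{path}: manifest needs a 'file' column")
    df["file"] = [str((path.parent / f).resolve()) for f in df["file"]]
    if "group" not in df.columns:
        df["group"] = ""
    return df


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """CSV with a ``# key: value`` provenance comment block."""
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def write_run_record(path, command: str, params: dict, seed) -> None:
    record = {
        "software": "chromech",
        "version": __version__,
        "command": command,
        "seed": seed,
        "params": params,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
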