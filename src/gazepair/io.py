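"""File formats: gaze / highlight / trial-log CSVs and the session manifest.

Everything is plain CSV with versioned headers — the data volumes are
small and auditability of intermediate files matters more than byte
efficiency. Angles are stored in degrees, times in seconds, hexagon ids
0-based with -1 for "none"/"outside". All writer/reader pairs round-trip
losslessly (floats are written with shortest-repr formatting).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import GazeStream, HighlightLog, Session
from .errors import IntegrityError, SchemaError

SCHEMA_VERSION = 1

GAZE_COLUMNS = ["t_s", "lx_deg", "ly_deg", "rx_deg", "ry_deg", "lvalid", "rvalid"]
HIGHLIGHT_COLUMNS = ["frame_time_s", "hex_id"]
TRIAL_COLUMNS = [
    "trial",
    "condition",
    "participant",
    "target_hex",
    "responder",
    "response_hex",
    "rt_s",
    "correct",
    "points_delta",
]


def _check_columns(df: pd.DataFrame, expected, path) -> None:
    if list(df.columns) != expected:
        raise SchemaError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at line {row}")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
            raise SchemaError(f"{path}: missing value in column {col!r} at line {row}")
        # numpy's string->float conversion is correctly rounded; pandas'
        # fast parser is not, and these files must round-trip exactly
        df[col] = df[col].to_numpy(dtype=str).astype(float)
    return df


# ---------------------------------------------------------------------------
# Gaze streams
# ---------------------------------------------------------------------------


def write_gaze_csv(stream: GazeStream, path) -> None:
    pd.DataFrame(
        {
            "t_s": stream.t,
            "lx_deg": stream.lx,
            "ly_deg": stream.ly,
            "rx_deg": stream.rx,
            "ry_deg": stream.ry,
            "lvalid": stream.lvalid.astype(int),
            "rvalid": stream.rvalid.astype(int),
        }
    ).to_csv(path, index=False)


def read_gaze_csv(path, participant: str = "", trial: int = 0) -> GazeStream:
    """Read one participant-trial gaze stream, validating schema and order."""
    df = pd.read_csv(path, dtype=str, float_precision="round_trip")
    _check_columns(df, GAZE_COLUMNS, path)
    df = _numeric(df, GAZE_COLUMNS, path)
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise IntegrityError(f"{path}: timestamps are not strictly increasing")
    return GazeStream(
        participant=participant,
        trial=trial,
        t=t,
        lx=df["lx_deg"].to_numpy(float),
        ly=df["ly_deg"].to_numpy(float),
        rx=df["rx_deg"].to_numpy(float),
        ry=df["ry_deg"].to_numpy(float),
        lvalid=df["lvalid"].to_numpy(float).astype(bool),
        rvalid=df["rvalid"].to_numpy(float).astype(bool),
    )


# ---------------------------------------------------------------------------
# Highlight logs
# ---------------------------------------------------------------------------


def write_highlight_csv(log: HighlightLog, path) -> None:
    pd.DataFrame({"frame_time_s": log.frame_t, "hex_id": log.hexes}).to_csv(path, index=False)


def read_highlight_csv(path, frame_rate: float = 60.0) -> HighlightLog:
    df = pd.read_csv(path, dtype=str, float_precision="round_trip")
    _check_columns(df, HIGHLIGHT_COLUMNS, path)
    df = _numeric(df, HIGHLIGHT_COLUMNS, path)
    t = df["frame_time_s"].to_numpy(float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise IntegrityError(f"{path}: frame times are not strictly increasing")
    return HighlightLog(t, df["hex_id"].to_numpy(float).astype(int), frame_rate)


# ---------------------------------------------------------------------------
# Trial logs
# ---------------------------------------------------------------------------


def trial_log_frame(session: Session) -> pd.DataFrame:
    """Collect every trial record of a session into one tidy table."""
    rows = []
    for participant, results in session.individual.items():
        for res in results:
            rec = res.record
            rows.append(
                {
                    "trial": res.stream.trial,
                    "condition": rec.condition,
                    "participant": participant,
                    "target_hex": rec.target_hex,
                    "responder": rec.responder if rec.responder is not None else "",
                    "response_hex": rec.response_hex if rec.response_hex is not None else -1,
                    "rt_s": rec.rt,
                    "correct": int(rec.correct),
                    "points_delta": rec.points_delta,
                }
            )
    for cond, trials in session.pairs.items():
        for pt in trials:
            rec = pt.record
            rows.append(
                {
                    "trial": pt.trial,
                    "condition": cond,
                    "participant": "pair",
                    "target_hex": rec.target_hex,
                    "responder": rec.responder if rec.responder is not None else "",
                    "response_hex": rec.response_hex if rec.response_hex is not None else -1,
                    "rt_s": rec.rt,
                    "correct": int(rec.correct),
                    "points_delta": rec.points_delta,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trial_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"condition": str, "participant": str, "responder": str}
    )
    _check_columns(df, TRIAL_COLUMNS, path)
    df["responder"] = df["responder"].fillna("")
    return df


# ---------------------------------------------------------------------------
# Session manifest
# ---------------------------------------------------------------------------


def write_session(session: Session, out_dir) -> Path:
    """Write all artifacts of a simulated session; returns the manifest path.

    Layout: per paired trial two gaze CSVs and two highlight CSVs, per
    individual trial one gaze CSV per participant, one combined trial log,
    the grid config, and a YAML manifest naming all parts.
    """
    from . import grid as grid_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "master_seed": session.master_seed,
        "grid_config": "grid.yaml",
        "trial_log": "trials.csv",
        "conditions": list(session.conditions),
        "individual": {},
        "pairs": {},
    }
    grid_mod.write_grid_config(session.grid, out / "grid.yaml")
    write_trial_log(trial_log_frame(session), out / "trials.csv")

    for participant, results in session.individual.items():
        entries = []
        for res in results:
            name = f"individual_{participant}_{res.stream.trial:03d}_gaze.csv"
            write_gaze_csv(res.stream, out / name)
            entries.append({"trial": res.stream.trial, "gaze": name})
        manifest["individual"][participant] = entries

    for cond, trials in session.pairs.items():
        entries = []
        for pt in trials:
            files = {
                "trial": pt.trial,
                "gaze_a": f"{cond}_{pt.trial:03d}_a_gaze.csv",
                "gaze_b": f"{cond}_{pt.trial:03d}_b_gaze.csv",
                "highlight_a": f"{cond}_{pt.trial:03d}_a_highlight.csv",
                "highlight_b": f"{cond}_{pt.trial:03d}_b_highlight.csv",
            }
            write_gaze_csv(pt.a.stream, out / files["gaze_a"])
            write_gaze_csv(pt.b.stream, out / files["gaze_b"])
            write_highlight_csv(pt.highlight_a, out / files["highlight_a"])
            write_highlight_csv(pt.highlight_b, out / files["highlight_b"])
            entries.append(files)
        manifest["pairs"][cond] = entries

    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_manifest(manifest_path) -> dict:
    """Load and validate a session manifest; referenced files must exist."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "schema_version" not in manifest:
        raise SchemaError(f"{manifest_path}: not a session manifest")
    if manifest["schema_version"] != SCHEMA_VERSION:
        raise SchemaError(
            f"{manifest_path}: schema version {manifest['schema_version']} "
            f"not supported (reader is at {SCHEMA_VERSION})"
        )
    base = manifest_path.parent
    referenced = [manifest["grid_config"], manifest["trial_log"]]
    for entries in manifest.get("individual", {}).values():
        referenced.extend(e["gaze"] for e in entries)
    for entries in manifest.get("pairs", {}).values():
        for e in entries:
            referenced.extend((e["gaze_a"], e["gaze_b"], e["highlight_a"], e["highlight_b"]))
    missing = [f for f in referenced if not os.path.exists(base / f)]
    if missing:
        raise IntegrityError(f"{manifest_path}: missing referenced files {missing}")
    manifest["_base"] = str(base)
    return manifest
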