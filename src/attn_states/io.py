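"""Text-format readers/writers (BIDS-style events, parcellated BOLD,
confound tables, result maps)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import BoldRun

__all__ = [
    "read_events_tsv",
    "read_bold_tsv",
    "write_confounds_tsv",
    "read_confounds_tsv",
    "write_map_tsv",
    "read_map_tsv",
]

MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
TISSUE_COLS = ["white_matter", "csf", "global_signal"]


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    """Read a BIDS-style events TSV into the internal trial table
    (onset_s, trial_type, rt_ms, responded, correct, ssd_ms)."""
    ev = pd.read_csv(path, sep="\t", na_values=["n/a"])
    required = {"onset", "trial_type", "response_time"}
    missing = required - set(ev.columns)
    if missing:
        raise ValueError(f"events table lacks columns: {sorted(missing)}")
    rt_ms = ev["response_time"].to_numpy(dtype=float) * 1000.0
    out = pd.DataFrame({
        "trial_index": np.arange(len(ev)),
        "trial_type": ev["trial_type"],
        "onset_s": ev["onset"].astype(float),
        "rt_ms": rt_ms,
        "responded": ~np.isnan(rt_ms),
        "correct": ev["correct"].astype(bool) if "correct" in ev else True,
        "ssd_ms": ev["ssd"].to_numpy(dtype=float) * 1000.0 if "ssd" in ev else np.nan,
    })
    return out


def read_bold_tsv(path: str | Path) -> BoldRun:
    """Read a frames x parcels BOLD TSV (+ optional JSON sidecar with
    tr_s / t0_s / coupling)."""
    path = Path(path)
    sig = pd.read_csv(path, sep="\t").to_numpy(dtype=float).T
    tr_s, t0_s, coupling = 0.8, 0.0, None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        tr_s = float(meta.get("tr_s", tr_s))
        t0_s = float(meta.get("t0_s", t0_s))
        if meta.get("coupling") is not None:
            coupling = np.asarray(meta["coupling"], dtype=float)
    return BoldRun(signal=sig, tr_s=tr_s, t0_s=t0_s, coupling=coupling)


def write_confounds_tsv(bold: BoldRun, path: str | Path) -> None:
    if bold.motion is None or bold.tissue is None:
        raise ValueError("run has no confound series")
    df = pd.DataFrame(np.hstack([bold.motion, bold.tissue]),
                      columns=MOTION_COLS + TISSUE_COLS)
    df.to_csv(path, sep="\t", index=False)


def read_confounds_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (motion6, tissue3) arrays."""
    df = pd.read_csv(path, sep="\t")
    missing = set(MOTION_COLS + TISSUE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"confound table lacks columns: {sorted(missing)}")
    return df[MOTION_COLS].to_numpy(dtype=float), df[TISSUE_COLS].to_numpy(dtype=float)


def write_map_tsv(values: np.ndarray, path: str | Path,
                  betas: np.ndarray | None = None,
                  variances: np.ndarray | None = None) -> None:
    """Write a per-unit statistic map (unit id, z, optional beta/var)."""
    df = pd.DataFrame({"unit": np.arange(len(values)), "z": values})
    if betas is not None:
        df["beta"] = betas
    if variances is not None:
        df["var"] = variances
    df.to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if "z" not in df.columns:
        raise ValueError("map table lacks a 'z' column")
    return df["z"].to_numpy(dtype=float)
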