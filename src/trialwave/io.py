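"""Delimited-text I/O for sessions, maps, and cluster results.

Sessions travel as long-format delimited text with header columns
``subject``, ``trial``, ``rt_ms`` (0-based trial indices; an empty ``rt_ms``
cell means no key press), or as one-subject-per-file single-column text.
Power maps are written as TSV matrices (rows = trials, columns labeled by
frequency in cycles/trial) with a JSON sidecar carrying the grid metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorSummary, Session
from .clusterperm import ClusterPermutationResults
from .tft import FrequencyGrid, TFTMap

__all__ = [
    "read_sessions",
    "read_single_column",
    "write_sessions",
    "read_sample_sheet",
    "write_map_tsv",
    "read_map_tsv",
    "write_summaries_tsv",
    "write_cluster_json",
    "write_cluster_intervals_tsv",
]


def read_sessions(path: str | Path, sep: str | None = None) -> list[Session]:
    """Read long-format sessions (columns subject, trial, rt_ms).

    Trials are 0-based in files; missing ``rt_ms`` cells become absent
    responses.  Subjects keep their order of first appearance.  Raises on
    missing columns, duplicate trial indices, or gaps in the trial range.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject": str})
    required = {"subject", "trial", "rt_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    sessions = []
    for subject, sub in df.groupby("subject", sort=False):
        trials = sub["trial"].to_numpy(dtype=int)
        if np.unique(trials).size != trials.size:
            raise ValueError(f"{path}: subject {subject!r} has duplicate trials")
        T = trials.max() + 1
        if set(trials) != set(range(T)):
            raise ValueError(
                f"{path}: subject {subject!r} trials are not contiguous 0..{T - 1}")
        rts = np.full(T, np.nan)
        rts[trials] = sub["rt_ms"].to_numpy(dtype=float)
        sessions.append(Session(subject_id=str(subject), rts=rts))
    return sessions


def read_single_column(path: str | Path, subject_id: str | None = None) -> Session:
    """Read a one-subject file: one RT per line, blank line = no response."""
    path = Path(path)
    rts = []
    for line in path.read_text().splitlines():
        line = line.strip()
        rts.append(float(line) if line else np.nan)
    if not rts:
        raise ValueError(f"{path}: empty file")
    return Session(subject_id=subject_id or path.stem, rts=np.asarray(rts))


def write_sessions(sessions: list[Session], path: str | Path,
                   sep: str = ",") -> None:
    """Write sessions in long format (absent responses as empty cells)."""
    rows = []
    for s in sessions:
        for t, v in enumerate(s.rts):
            rows.append((s.subject_id, t, "" if np.isnan(v) else v))
    df = pd.DataFrame(rows, columns=["subject", "trial", "rt_ms"])
    df.to_csv(path, sep=sep, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet with columns subject, group[, path]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    groups = df["group"].unique()
    if len(groups) != 2:
        raise ValueError(f"{path}: expected exactly 2 groups, found {list(groups)}")
    return df


def write_map_tsv(tft_map: TFTMap, path: str | Path) -> None:
    """Write a power map as TSV plus a .json sidecar with grid metadata."""
    path = Path(path)
    cols = [f"{f:.6f}" for f in tft_map.grid.frequencies]
    df = pd.DataFrame(tft_map.power, columns=cols)
    df.insert(0, "trial", np.arange(tft_map.grid.T))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "subject_id": tft_map.subject_id,
        "T": tft_map.grid.T,
        "f_max": tft_map.grid.f_max,
        "step": tft_map.grid.step,
        "n_frequencies": tft_map.grid.n_frequencies,
        "coi_half_widths": _coi_half_widths(tft_map).tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def _coi_half_widths(tft_map: TFTMap) -> np.ndarray:
    """Per-frequency edge half-width implied by the COI mask."""
    T = tft_map.grid.T
    widths = np.zeros(tft_map.grid.n_frequencies, dtype=int)
    for k in range(widths.size):
        col = tft_map.coi_mask[:, k]
        widths[k] = int(np.argmax(~col)) if not col.all() else (T + 1) // 2
    return widths


def read_map_tsv(path: str | Path) -> TFTMap:
    """Round-trip a map written by :func:`write_map_tsv`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    power = df.drop(columns=["trial"]).to_numpy(dtype=float)
    grid = FrequencyGrid(
        T=int(meta["T"]), f_max=float(meta["f_max"]),
        frequencies=np.arange(1, meta["n_frequencies"] + 1) / meta["T"],
    )
    t_idx = np.arange(grid.T)[:, None]
    hw = np.asarray(meta["coi_half_widths"], dtype=int)[None, :]
    coi = (t_idx < hw) | (t_idx > grid.T - 1 - hw)
    return TFTMap(power=power, grid=grid, coi_mask=coi,
                  subject_id=meta.get("subject_id"))


def write_summaries_tsv(summaries: list[BehaviorSummary],
                        path: str | Path) -> None:
    """One row per subject: class counts, mean RT, RT_SD."""
    pd.DataFrame([s.to_dict() for s in summaries]).to_csv(
        path, sep="\t", index=False)


def write_cluster_json(results: ClusterPermutationResults,
                       path: str | Path) -> None:
    Path(path).write_text(results.to_json(indent=2))


def write_cluster_intervals_tsv(results: ClusterPermutationResults,
                                path: str | Path) -> None:
    """BED-like TSV of significant-cluster trial spans (0-based half-open)."""
    rows = [
        {"cluster": i, "trial_start": start, "trial_end": end}
        for i, start, end in results.significant_trial_intervals()
    ]
    pd.DataFrame(rows, columns=["cluster", "trial_start", "trial_end"]).to_csv(
        path, sep="\t", index=False)
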