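"""Reading and writing the package's plain-text table formats.

Traces travel as long-format CSV/TSV with header
``neuron_id,time_s,fluorescence`` (comma or tab auto-detected from the
header line); per-trace summaries and ground-truth event tables are TSV.
Floats are written with 6 significant digits and the single missing-value
token is ``NA``.
"""

from __future__ import annotations

import configparser
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import DetectionParams, FluorescenceTrace, TraceSummary
from .stats import PhaseProtocol

__all__ = [
    "read_traces",
    "write_traces",
    "read_summaries",
    "write_summaries",
    "write_truth",
    "read_config",
]

TRACE_COLUMNS = ["neuron_id", "time_s", "fluorescence"]
SUMMARY_COLUMNS = ["neuron_id", "phase", "n_events", "duration_s", "frequency_hz", "amplitude"]
_DT_TOL = 1e-6


def _detect_delimiter(path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_traces(path) -> list[FluorescenceTrace]:
    """Read long-format traces; one FluorescenceTrace per neuron_id.

    Rows for each neuron must be time-sorted with uniform sampling
    (validated to 1e-6 s); violations are reported with file line numbers
    (1-based, header = line 1).
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header must be {TRACE_COLUMNS}")
    for col in ("time_s", "fluorescence"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col} value {df.loc[bad[0], col]!r} at line {bad[0] + 2}"
            )
        if df[col].isna().any():
            line = int(df.index[df[col].isna()][0]) + 2
            raise ValueError(f"{path}: empty {col} cell at line {line}")
        df[col] = numeric

    traces = []
    for neuron_id, grp in df.groupby("neuron_id", sort=False):
        t = grp["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError(f"{path}: neuron {neuron_id!r} has fewer than 2 samples")
        steps = np.diff(t)
        if (steps <= 0).any():
            line = int(grp.index[int(np.argmax(steps <= 0)) + 1]) + 2
            raise ValueError(f"{path}: time not strictly increasing at line {line}")
        dt = steps[0]
        off = np.abs(steps - dt) > _DT_TOL
        if off.any():
            line = int(grp.index[int(np.argmax(off)) + 1]) + 2
            raise ValueError(
                f"{path}: non-uniform sampling for neuron {neuron_id!r} at line {line} "
                f"(step {steps[np.argmax(off)]:g} s vs dt {dt:g} s)"
            )
        traces.append(
            FluorescenceTrace(
                neuron_id=str(neuron_id),
                values=grp["fluorescence"].to_numpy(),
                t0=float(t[0]),
                dt=float(dt),
            )
        )
    return traces


def write_traces(traces, path) -> None:
    """Write traces as long-format CSV (header ``neuron_id,time_s,fluorescence``)."""
    frames = [
        pd.DataFrame(
            {"neuron_id": tr.neuron_id, "time_s": tr.times, "fluorescence": tr.values}
        )
        for tr in traces
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRACE_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.6g")


def write_summaries(summaries, path) -> None:
    """Write per-trace summaries as TSV; missing amplitude becomes ``NA``."""
    rows = [
        {
            "neuron_id": s.neuron_id,
            "phase": s.phase,
            "n_events": s.n_events,
            "duration_s": s.duration,
            "frequency_hz": s.frequency,
            "amplitude": s.amplitude,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_summaries(path) -> list[TraceSummary]:
    """Read a summary TSV back into TraceSummary objects (``NA`` -> missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        amp = row["amplitude"]
        out.append(
            TraceSummary(
                neuron_id=str(row["neuron_id"]),
                phase=str(row["phase"]) if not pd.isna(row["phase"]) else "",
                n_events=int(row["n_events"]),
                duration=float(row["duration_s"]),
                frequency=float(row["frequency_hz"]),
                amplitude=None if pd.isna(amp) else float(amp),
            )
        )
    return out


def write_truth(truth_rows, path) -> None:
    """Write ground-truth onsets as TSV ``neuron_id, phase, onset_s``."""
    df = pd.DataFrame(truth_rows, columns=["neuron_id", "phase", "onset_s"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_config(path) -> tuple[DetectionParams, PhaseProtocol]:
    """Read detection/protocol settings from a plain ``key = value`` file.

    Recognized keys (all optional, flat or under [detection]/[protocol]
    sections): threshold, half_window, min_gap, pre_duration,
    wash_duration, post_duration.
    """
    cp = configparser.ConfigParser(inline_comment_prefixes=("#",))
    text = Path(path).read_text()
    try:
        cp.read_string(text)
        items: dict[str, str] = {}
        for section in cp.sections():
            items.update(dict(cp[section]))
        items.update(dict(cp.defaults()))
    except configparser.MissingSectionHeaderError:
        cp.read_string("[detection]\n" + text)
        items = dict(cp["detection"])
    det = DetectionParams(
        threshold=float(items.get("threshold", 1.2)),
        half_window=float(items.get("half_window", 10.0)),
        min_gap=float(items.get("min_gap", 2.0)),
    )
    proto = PhaseProtocol(
        pre_duration=float(items.get("pre_duration", 120.0)),
        wash_duration=float(items.get("wash_duration", 60.0)),
        post_duration=float(items.get("post_duration", 120.0)),
    )
    return det, proto
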