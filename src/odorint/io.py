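"""CSV and TOML I/O for plate counts, fluorescence traces, and results.

All interchange is plain UTF-8 CSV with a header row.  Schemas:

* plate counts:   ``plate_id,genotype,assay_type,n_toward,n_away,n_middle``
* scored plates:  plate-count columns plus
  ``choice_index,pct_correct,pct_wrong,pct_no_choice,pct_incorrect``
* traces (long):  ``trace_id,neuron_class,genotype,stimulus,time_s,F``
* stimulus epochs: ``trace_id,t_onset_s,t_removal_s``
* trace metrics:  ``trace_id,on_response,off_response,off_latency,threshold_crossed``
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calcium import FluorescenceTrace, GroupSummary, ResponseMetrics
from .scoring import ASSAY_TYPES, ChoiceSummary, PlateCount

logger = logging.getLogger("odorint")

PLATE_COLUMNS = ["plate_id", "genotype", "assay_type", "n_toward", "n_away", "n_middle"]
TRACE_COLUMNS = ["trace_id", "neuron_class", "genotype", "stimulus", "time_s", "F"]
EPOCH_COLUMNS = ["trace_id", "t_onset_s", "t_removal_s"]


class ValidationError(ValueError):
    """Malformed input file; the message names the offending row."""


def read_plate_counts(path: str | Path) -> list[PlateCount]:
    """Read and validate a plate-count CSV."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("%s: no plate rows", path)
        return []
    records = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            records.append(
                PlateCount(
                    plate_id=str(row["plate_id"]),
                    genotype=str(row["genotype"]),
                    assay_type=str(row["assay_type"]),
                    n_toward=int(row["n_toward"]),
                    n_away=int(row["n_away"]),
                    n_middle=int(row["n_middle"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path} line {lineno}: {exc}") from exc
    return records


def write_plate_counts(plates: Sequence[PlateCount], path: str | Path) -> None:
    pd.DataFrame([asdict(p) for p in plates], columns=PLATE_COLUMNS).to_csv(
        path, index=False
    )


def write_scored_plates(
    plates: Sequence[PlateCount], summaries: Sequence[ChoiceSummary], path: str | Path
) -> None:
    rows = []
    for p, s in zip(plates, summaries, strict=True):
        rows.append({**asdict(p), **asdict(s)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces(path: str | Path, epochs_path: str | Path) -> list[FluorescenceTrace]:
    """Read long-format traces plus their stimulus epochs.

    Every ``trace_id`` in the trace file must have exactly one epoch row;
    sampling must be uniform within 1e-6 s.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    ep = pd.read_csv(epochs_path)
    missing = [c for c in EPOCH_COLUMNS if c not in ep.columns]
    if missing:
        raise ValidationError(f"{epochs_path}: missing columns {missing}")
    if ep["trace_id"].duplicated().any():
        dups = ep.loc[ep["trace_id"].duplicated(), "trace_id"].tolist()
        raise ValidationError(f"{epochs_path}: duplicate epoch rows for {dups}")
    epochs = ep.set_index("trace_id")
    traces = []
    for trace_id, grp in df.groupby("trace_id", sort=False):
        if trace_id not in epochs.index:
            raise ValidationError(f"{path}: trace {trace_id!r} has no epoch row")
        row = epochs.loc[trace_id]
        t_onset = float(row["t_onset_s"])
        t_removal = float(row["t_removal_s"])
        if t_removal <= t_onset:
            raise ValidationError(
                f"{epochs_path}: trace {trace_id!r} has t_removal <= t_onset"
            )
        grp = grp.sort_values("time_s")
        try:
            traces.append(
                FluorescenceTrace(
                    trace_id=str(trace_id),
                    neuron_class=str(grp["neuron_class"].iloc[0]),
                    genotype=str(grp["genotype"].iloc[0]),
                    stimulus=str(grp["stimulus"].iloc[0]),
                    time=grp["time_s"].to_numpy(float),
                    F=grp["F"].to_numpy(float),
                    t_onset=t_onset,
                    t_removal=t_removal,
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: trace {trace_id!r}: {exc}") from exc
    return traces


def write_traces(
    traces: Sequence[FluorescenceTrace], path: str | Path, epochs_path: str | Path
) -> None:
    frames = []
    epochs = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id,
                    "neuron_class": tr.neuron_class,
                    "genotype": tr.genotype,
                    "stimulus": tr.stimulus,
                    "time_s": tr.time,
                    "F": tr.F,
                }
            )
        )
        epochs.append(
            {"trace_id": tr.trace_id, "t_onset_s": tr.t_onset, "t_removal_s": tr.t_removal}
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    pd.DataFrame(epochs, columns=EPOCH_COLUMNS).to_csv(epochs_path, index=False)


def write_metrics(metrics: Sequence[ResponseMetrics], path: str | Path) -> None:
    pd.DataFrame([asdict(m) for m in metrics]).to_csv(path, index=False)


def write_group_summary(summary: GroupSummary, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": summary.time, "mean_dff_pct": summary.mean, "sem_dff_pct": summary.sem}
    ).to_csv(path, index=False)


def read_tidy_groups(path: str | Path) -> dict[str, np.ndarray]:
    """Read a tidy ``group,value`` CSV into label -> values arrays."""
    df = pd.read_csv(path)
    for col in ("group", "value"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return {
        str(label): grp["value"].to_numpy(float)
        for label, grp in df.groupby("group", sort=False)
    }


def load_config(path: str | Path) -> dict:
    """Load a TOML pipeline configuration."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)
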