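"""Quantification of stimulus-locked GCaMP fluorescence traces.

All metrics are expressed on the percent ΔF/F scale: for each frame,
ΔF = F − F_base where F_base is the mean raw intensity over the 10 s
immediately before stimulus onset, and dff = 100 · ΔF / F_base.

* ON response: mean dff over a window after stimulus onset minus mean dff
  over the 10-s window before onset.
* OFF response: mean dff over a window after stimulus removal minus mean dff
  over the 10-s window before removal.
* OFF latency: time after removal at which dff first reaches the pre-removal
  mean + ``k_sd`` standard deviations (sample SD); capped at 40 s when the
  threshold is never reached before the recording ends.

Window lengths depend on the neuron class: sensory neurons AWB and ASH use
10-s windows; the interneurons AVA, AIB and RIM use 5-s windows, with an
alternative second-10-s ON window for AVA (its IAA-evoked suppression
develops slowly).  All windows are left-closed, right-open on the frame
grid; the removal frame itself is the first candidate for a threshold
crossing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FluorescenceTrace",
    "DffTrace",
    "ResponseWindows",
    "ResponseMetrics",
    "GroupSummary",
    "baseline",
    "dff",
    "on_response",
    "off_response",
    "off_latency",
    "summarize_group",
    "default_windows",
    "quantify",
]

NEURON_CLASSES = ("AWB", "ASH", "AVA", "AIB", "RIM", "other")

#: pre-onset / pre-removal reference window length (s)
PRE_DURATION = 10.0


class InsufficientBaselineError(ValueError):
    """Trace does not cover the required pre-stimulus window."""


@dataclass(frozen=True)
class FluorescenceTrace:
    """Raw fluorescence series with stimulus marks.

    ``time`` must be uniformly sampled (default 5 frames/s); ``t_onset`` and
    ``t_removal`` mark the stimulus epoch in the same time base.
    """

    trace_id: str
    neuron_class: str
    genotype: str
    stimulus: str
    time: np.ndarray
    F: np.ndarray
    t_onset: float
    t_removal: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "F", np.asarray(self.F, dtype=float))
        if self.time.ndim != 1 or self.time.shape != self.F.shape:
            raise ValueError("time and F must be 1-D arrays of equal length")
        if len(self.time) < 2:
            raise ValueError("trace must contain at least two frames")
        steps = np.diff(self.time)
        if np.any(np.abs(steps - steps[0]) > 1e-6):
            raise ValueError(
                f"trace {self.trace_id}: sampling is not uniform within 1e-6 s"
            )
        if self.t_removal <= self.t_onset:
            raise ValueError("t_removal must be after t_onset")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class DffTrace:
    """Baseline-normalized trace (percent ΔF/F) with stimulus marks."""

    trace_id: str
    neuron_class: str
    time: np.ndarray
    dff_pct: np.ndarray
    f_base: float
    t_onset: float
    t_removal: float

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class ResponseWindows:
    """Quantification windows, as offsets (s) from onset / removal."""

    on_offset: float
    on_duration: float
    off_offset: float
    off_duration: float
    pre_duration: float = PRE_DURATION

    def __post_init__(self) -> None:
        if self.on_duration <= 0 or self.off_duration <= 0 or self.pre_duration <= 0:
            raise ValueError("window durations must be positive")
        if self.on_offset < 0 or self.off_offset < 0:
            raise ValueError("window offsets must be nonnegative")


@dataclass(frozen=True)
class ResponseMetrics:
    trace_id: str
    on_response: float
    off_response: float
    off_latency: float
    threshold_crossed: bool


@dataclass(frozen=True)
class GroupSummary:
    """Per-frame mean and SEM across traces, aligned to stimulus onset."""

    time: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int


def _window_mean(time: np.ndarray, values: np.ndarray, start: float, stop: float,
                 what: str) -> float:
    """Mean of ``values`` over the left-closed, right-open interval
    [start, stop) on the frame grid."""
    mask = (time >= start - 1e-9) & (time < stop - 1e-9)
    if not mask.any():
        raise ValueError(f"{what} window [{start}, {stop}) contains no frames")
    return float(values[mask].mean())


def baseline(trace: FluorescenceTrace) -> float:
    """Mean raw intensity over the 10 s before stimulus onset (F_base)."""
    start = trace.t_onset - PRE_DURATION
    if trace.time[0] > start + 1e-9:
        raise InsufficientBaselineError(
            f"trace {trace.trace_id}: needs {PRE_DURATION} s of pre-onset "
            f"baseline, recording starts at {trace.time[0]} s"
        )
    return _window_mean(trace.time, trace.F, start, trace.t_onset, "baseline")


def dff(trace: FluorescenceTrace) -> DffTrace:
    """Convert a raw trace to percent ΔF/F about its pre-onset baseline."""
    f_base = baseline(trace)
    if f_base <= 0:
        raise ValueError(
            f"trace {trace.trace_id}: non-physical baseline intensity {f_base}"
        )
    return DffTrace(
        trace_id=trace.trace_id,
        neuron_class=trace.neuron_class,
        time=trace.time,
        dff_pct=100.0 * (trace.F - f_base) / f_base,
        f_base=f_base,
        t_onset=trace.t_onset,
        t_removal=trace.t_removal,
    )


def _event_response(d: DffTrace, t_event: float, offset: float, duration: float) -> float:
    stop = t_event + offset + duration
    if stop > d.time[-1] + d.dt + 1e-9:
        raise ValueError(
            f"trace {d.trace_id}: response window ends at {stop} s but the "
            f"recording ends at {d.time[-1]} s"
        )
    resp = _window_mean(d.time, d.dff_pct, t_event + offset, stop, "response")
    pre = _window_mean(d.time, d.dff_pct, t_event - PRE_DURATION, t_event, "pre-event")
    return resp - pre


def on_response(d: DffTrace, windows: ResponseWindows) -> float:
    """Windowed mean dff after onset minus the 10-s pre-onset mean."""
    return _event_response(d, d.t_onset, windows.on_offset, windows.on_duration)


def off_response(d: DffTrace, windows: ResponseWindows) -> float:
    """Windowed mean dff after removal minus the 10-s pre-removal mean."""
    return _event_response(d, d.t_removal, windows.off_offset, windows.off_duration)


def off_latency(
    d: DffTrace, k_sd: float = 3.0, cap: float = 40.0
) -> tuple[float, bool]:
    """Time after stimulus removal for dff to reach the crossing threshold.

    The threshold is the mean of the 10-s pre-removal window plus ``k_sd``
    sample standard deviations.  Returns ``(latency, crossed)``; if the
    signal never reaches the threshold before the recording ends, the
    latency is ``cap`` and ``crossed`` is False.
    """
    pre_mask = (d.time >= d.t_removal - PRE_DURATION - 1e-9) & (
        d.time < d.t_removal - 1e-9
    )
    if pre_mask.sum() < 2:
        raise ValueError(
            f"trace {d.trace_id}: insufficient pre-removal window for latency"
        )
    pre = d.dff_pct[pre_mask]
    threshold = pre.mean() + k_sd * pre.std(ddof=1)
    post_mask = d.time >= d.t_removal - 1e-9
    if not post_mask.any():
        raise ValueError(f"trace {d.trace_id}: no post-removal frames")
    t_post = d.time[post_mask]
    v_post = d.dff_pct[post_mask]
    crossing = np.nonzero(v_post >= threshold)[0]
    if crossing.size == 0:
        return float(cap), False
    return float(t_post[crossing[0]] - d.t_removal), True


def summarize_group(traces: Sequence[DffTrace]) -> GroupSummary:
    """Per-frame mean and SEM (SD/sqrt(n)) across onset-aligned traces.

    Traces whose onset-aligned grids differ by less than half a frame are
    snapped onto the first trace's grid; larger mismatches are an error.
    """
    if not traces:
        raise ValueError("no traces to summarize")
    ref = traces[0]
    ref_rel = ref.time - ref.t_onset
    stacked = [ref.dff_pct]
    for tr in traces[1:]:
        rel = tr.time - tr.t_onset
        if len(rel) != len(ref_rel) or np.any(np.abs(rel - ref_rel) > ref.dt / 2):
            raise ValueError(
                f"trace {tr.trace_id}: time grid incompatible with {ref.trace_id}"
            )
        stacked.append(tr.dff_pct)
    arr = np.vstack(stacked)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return GroupSummary(time=ref_rel, mean=mean, sem=sem, n=n)


def default_windows(neuron_class: str, variant: str = "primary") -> ResponseWindows:
    """Class-specific quantification windows.

    AWB and ASH use 10-s ON and OFF windows; AVA, AIB and RIM use 5-s
    windows.  ``variant="ava_late"`` selects AVA's alternative ON window,
    the second 10 s after onset.
    """
    if variant not in ("primary", "ava_late"):
        raise ValueError(f"unknown window variant {variant!r}")
    if variant == "ava_late":
        if neuron_class != "AVA":
            raise ValueError("ava_late windows apply to AVA only")
        return ResponseWindows(on_offset=10.0, on_duration=10.0,
                               off_offset=0.0, off_duration=5.0)
    if neuron_class in ("AWB", "ASH"):
        return ResponseWindows(0.0, 10.0, 0.0, 10.0)
    if neuron_class in ("AVA", "AIB", "RIM"):
        return ResponseWindows(0.0, 5.0, 0.0, 5.0)
    raise ValueError(
        f"no default windows for neuron class {neuron_class!r}; pass explicit windows"
    )


def quantify(
    trace: FluorescenceTrace,
    windows: ResponseWindows | None = None,
    k_sd: float = 3.0,
    cap: float = 40.0,
    window_variant: str = "primary",
) -> ResponseMetrics:
    """ΔF/F conversion plus ON/OFF responses and OFF latency for one trace."""
    d = dff(trace)
    w = windows if windows is not None else default_windows(
        trace.neuron_class, window_variant
    )
    latency, crossed = off_latency(d, k_sd=k_sd, cap=cap)
    return ResponseMetrics(
        trace_id=trace.trace_id,
        on_response=on_response(d, w),
        off_response=off_response(d, w),
        off_latency=latency,
        threshold_crossed=crossed,
    )
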