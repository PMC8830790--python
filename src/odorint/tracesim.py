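"""Synthetic GCaMP-like fluorescence traces with known ground truth.

Each trace is a deterministic response kernel plus i.i.d. Gaussian noise:

* baseline intensity ``f0`` before stimulus onset;
* a saturating-exponential ON component (time constant ``on_tau``) toward
  ``f0 * (1 + on_amplitude/100)`` during the stimulus;
* an OFF component starting ``off_latency_true`` seconds after stimulus
  removal, relaxing with time constant ``off_tau`` toward the post-stimulus
  asymptote shifted by ``off_amplitude`` percent of f0.

Amplitudes are signed percentages of f0, so the ground truth is directly
comparable to the percent ΔF/F metrics of :mod:`odorint.calcium`.  For
components that rise after removal (``off_amplitude > 0``) the latency
parameter is the delay of the rise, i.e. the event the threshold-crossing
latency detector should recover; for flat or decaying OFF components no
crossing event exists and the detector is expected to report the cap.

The preset library encodes the qualitative response patterns of the AWB and
ASH sensory neurons and the AVA/AIB/RIM interneurons to isoamyl alcohol
(IAA), 2-nonanone, and their mixture, for wild-type and for a cilium-
defective (osm-5-like) genotype: e.g. 2-nonanone suppresses AWB during
exposure and activates it on removal, IAA does the opposite, ASH responds
to 2-nonanone but not IAA, and the interneurons are suppressed by IAA.  The
osm-5-like variants shrink amplitudes and lengthen the OFF latency of the
AWB responses to 2-nonanone and to the mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .calcium import FluorescenceTrace

__all__ = [
    "TraceSimConfig",
    "NeuronPreset",
    "simulate_trace",
    "simulate_traces",
    "preset_library",
    "get_preset",
]


@dataclass(frozen=True)
class TraceSimConfig:
    """Ground-truth parameters for one synthetic trace.

    Amplitudes in percent of ``f0``; times in seconds.  Sampling is 5
    frames/s by default, matching the imaging protocol the analysis
    assumes (10-s baseline, stimulus epoch, >= 40 s after removal).
    """

    f0: float = 100.0
    dt: float = 0.2
    pre_duration: float = 10.0
    stim_duration: float = 30.0
    post_duration: float = 40.0
    on_amplitude: float = 0.0
    on_tau: float = 0.3
    off_amplitude: float = 0.0
    off_latency_true: float = 0.0
    off_tau: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.pre_duration < 10.0:
            raise ValueError("pre_duration must cover the 10-s baseline window")
        if self.stim_duration <= 0 or self.post_duration <= 0:
            raise ValueError("stimulus and post-removal epochs must be positive")
        if self.post_duration < self.off_latency_true:
            raise ValueError("post_duration must cover off_latency_true")
        if self.on_tau <= 0 or self.off_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")


@dataclass(frozen=True)
class NeuronPreset:
    """Named ground-truth configuration for one imaging panel."""

    neuron_class: str
    stimulus: str  # "iaa", "nonanone", "mixture"
    genotype: str  # "wild_type", "osm5_like"
    config: TraceSimConfig

    @property
    def key(self) -> str:
        return f"{self.neuron_class}:{self.stimulus}:{self.genotype}"


def _kernel_dff(t: np.ndarray, config: TraceSimConfig) -> np.ndarray:
    """Noise-free percent ΔF/F at frame times ``t``.

    The stimulus switches halfway between frames, so the frame recorded at
    the onset (removal) mark already reflects half a frame interval of the
    new condition.
    """
    t_on = config.pre_duration
    t_off = t_on + config.stim_duration
    half = config.dt / 2.0
    out = np.zeros_like(t)
    during = (t >= t_on) & (t < t_off)
    out[during] = config.on_amplitude * (
        1.0 - np.exp(-(t[during] - t_on + half) / config.on_tau)
    )
    plateau = config.on_amplitude * (1.0 - np.exp(-config.stim_duration / config.on_tau))
    after = t >= t_off
    rel = t[after] - t_off - config.off_latency_true + half
    rise = np.where(rel >= 0, 1.0 - np.exp(-np.maximum(rel, 0.0) / config.off_tau), 0.0)
    out[after] = plateau + config.off_amplitude * rise
    return out


def simulate_trace(
    config: TraceSimConfig,
    trace_id: str = "sim",
    neuron_class: str = "other",
    genotype: str = "wild_type",
    stimulus: str = "odor",
    rng: np.random.Generator | None = None,
) -> FluorescenceTrace:
    """Generate one trace; noise SD is ``noise_sd`` percent of ``f0``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    total = config.pre_duration + config.stim_duration + config.post_duration
    n = int(round(total / config.dt))
    t = np.arange(n) * config.dt
    f = config.f0 * (1.0 + _kernel_dff(t, config) / 100.0)
    if config.noise_sd > 0:
        f = f + rng.normal(0.0, config.noise_sd / 100.0 * config.f0, size=n)
    return FluorescenceTrace(
        trace_id=trace_id,
        neuron_class=neuron_class,
        genotype=genotype,
        stimulus=stimulus,
        time=t,
        F=f,
        t_onset=config.pre_duration,
        t_removal=config.pre_duration + config.stim_duration,
    )


def simulate_traces(
    preset: NeuronPreset,
    n: int,
    seed: int = 0,
    noise_sd: float | None = None,
) -> list[FluorescenceTrace]:
    """Independent replicate traces from one preset, one RNG substream each."""
    cfg = preset.config
    if noise_sd is not None:
        cfg = replace(cfg, noise_sd=noise_sd)
    streams = np.random.SeedSequence(seed).spawn(n)
    return [
        simulate_trace(
            cfg,
            trace_id=f"{preset.key}-{i:03d}",
            neuron_class=preset.neuron_class,
            genotype=preset.genotype,
            stimulus=preset.stimulus,
            rng=np.random.default_rng(ss),
        )
        for i, ss in enumerate(streams)
    ]


def _cfg(on: float, off: float, lat: float = 0.0, on_tau: float = 0.3,
         off_tau: float = 1.0, noise: float = 1.0) -> TraceSimConfig:
    return TraceSimConfig(
        on_amplitude=on, off_amplitude=off, off_latency_true=lat,
        on_tau=on_tau, off_tau=off_tau, noise_sd=noise,
    )


def _presets() -> Iterator[NeuronPreset]:
    wt, mut = "wild_type", "osm5_like"
    # AWB: activated by IAA, suppressed by 2-nonanone and by the mixture;
    # removal of 2-nonanone or the mixture evokes a delayed rise whose
    # latency lengthens and amplitude shrinks in the osm-5-like genotype.
    yield NeuronPreset("AWB", "iaa", wt, _cfg(on=40.0, off=-40.0, off_tau=5.0))
    yield NeuronPreset("AWB", "iaa", mut, _cfg(on=12.0, off=-12.0, off_tau=5.0))
    yield NeuronPreset("AWB", "nonanone", wt, _cfg(on=-25.0, off=45.0, lat=1.0))
    yield NeuronPreset("AWB", "nonanone", mut, _cfg(on=-15.0, off=20.0, lat=2.0))
    yield NeuronPreset("AWB", "mixture", wt, _cfg(on=-25.0, off=40.0, lat=1.0))
    yield NeuronPreset("AWB", "mixture", mut, _cfg(on=-15.0, off=18.0, lat=2.0))
    # ASH: activated by 2-nonanone (rapid decay on removal), blind to IAA.
    yield NeuronPreset("ASH", "nonanone", wt, _cfg(on=50.0, off=-50.0, off_tau=2.0))
    yield NeuronPreset("ASH", "nonanone", mut, _cfg(on=15.0, off=-15.0, off_tau=2.0))
    yield NeuronPreset("ASH", "iaa", wt, _cfg(on=0.0, off=0.0))
    # AVA: suppressed by IAA, quiet for 2-nonanone and (wild type) the
    # mixture; in the osm-5-like genotype the mixture recovers IAA-like
    # suppression because the blocking repellent signal is weakened.
    yield NeuronPreset("AVA", "iaa", wt, _cfg(on=-30.0, off=30.0, lat=1.0, off_tau=0.5))
    yield NeuronPreset("AVA", "iaa", mut, _cfg(on=-25.0, off=25.0, lat=1.0, off_tau=0.5))
    yield NeuronPreset("AVA", "nonanone", wt, _cfg(on=0.0, off=0.0))
    yield NeuronPreset("AVA", "mixture", wt, _cfg(on=0.0, off=0.0))
    yield NeuronPreset("AVA", "mixture", mut, _cfg(on=-20.0, off=20.0, lat=1.0, off_tau=0.5))
    # AIB: suppressed by all three stimuli in wild type.
    yield NeuronPreset("AIB", "iaa", wt, _cfg(on=-25.0, off=25.0, lat=1.0, off_tau=0.5))
    yield NeuronPreset("AIB", "nonanone", wt, _cfg(on=-20.0, off=20.0, lat=1.0, off_tau=0.5))
    yield NeuronPreset("AIB", "mixture", wt, _cfg(on=-25.0, off=25.0, lat=1.0, off_tau=0.5))
    yield NeuronPreset("AIB", "nonanone", mut, _cfg(on=0.0, off=0.0))
    yield NeuronPreset("AIB", "mixture", mut, _cfg(on=-12.0, off=12.0, lat=1.0, off_tau=0.5))
    # RIM: processes IAA-related signals only, independently of osm-5.
    yield NeuronPreset("RIM", "iaa", wt, _cfg(on=-25.0, off=25.0, lat=1.0, off_tau=0.5))
    yield NeuronPreset("RIM", "iaa", mut, _cfg(on=-22.0, off=22.0, lat=1.0, off_tau=0.5))
    yield NeuronPreset("RIM", "mixture", wt, _cfg(on=-20.0, off=20.0, lat=1.0, off_tau=0.5))
    yield NeuronPreset("RIM", "mixture", mut, _cfg(on=-20.0, off=20.0, lat=1.0, off_tau=0.5))
    yield NeuronPreset("RIM", "nonanone", wt, _cfg(on=0.0, off=0.0))


def preset_library() -> list[NeuronPreset]:
    """All panel presets (neuron class x stimulus x genotype)."""
    return list(_presets())


def get_preset(neuron_class: str, stimulus: str, genotype: str = "wild_type") -> NeuronPreset:
    for p in preset_library():
        if (p.neuron_class, p.stimulus, p.genotype) == (neuron_class, stimulus, genotype):
            return p
    raise KeyError(f"no preset {neuron_class}:{stimulus}:{genotype}")
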