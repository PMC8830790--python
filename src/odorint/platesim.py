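"""Agent-based chemotaxis plate simulator.

Worms perform a biased run-and-tumble walk on a 10-cm assay plate.  Each
odorant contributes a static isotropic Gaussian "perceived signal" field
centred on its spot; the attractant enters with positive sign and the
repellent with negative sign, scaled by genotype-specific sensory gains.  A
worm modulates its tumble (reorientation) rate by the temporal derivative of
the perceived signal along its path — runs up the perceived gradient are
extended, runs down it are shortened — which is the classic pirouette
strategy of *C. elegans* gradient navigation.  Sodium-azide spots beside the
odor and the control immobilize any worm entering a trap disk, freezing the
final distribution.

The plate is scored like the bench assay: final positions are partitioned by
the two lines x = ±R/3 into an odor-side strip, a middle strip, and a
control-side strip, yielding a :class:`~odorint.scoring.PlateCount`.

Geometry and protocol defaults follow the bench assay: 10-cm plate, odor and
control spots 3.33 cm from the center on opposite sides (co-located on the
odor side for pairing assays), 1-h duration, >50 worms started at the plate
center.  Motility parameters are desk-scale stand-ins for real worm
locomotion (speed 0.15 mm/s, spontaneous tumble rate 0.25/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .scoring import PlateCount

__all__ = [
    "PlateSimConfig",
    "WormState",
    "GenotypeGains",
    "odor_field",
    "step_worm",
    "simulate_plate",
    "simulate_plates",
    "genotype_presets",
    "attractant_presets",
    "ODORANT_AMPLITUDES",
    "GENOTYPE_PRESETS",
]

#: Default perceived-signal amplitudes per odorant spot (dimensionless), for
#: the volumes used on the bench: 1 uL isoamyl alcohol, 1 uL 2-nonanone,
#: 0.02 uL benzaldehyde.  Amplitudes scale linearly with spotted volume.
ODORANT_AMPLITUDES: dict[str, float] = {
    "iaa": 12.0,
    "nonanone": 40.0,
    "benzaldehyde": 11.0,
}


@dataclass(frozen=True)
class GenotypeGains:
    """Multiplicative sensory gains applied to the odor field."""

    g_att: float
    g_rep: float


#: wild type senses both odorants fully; the osm-5-like cilium-defective
#: preset mildly reduces attractant sensing and strongly reduces repellent
#: sensing, so single-odorant chemotaxis keeps its sign while the pairing
#: response collapses toward attraction.
GENOTYPE_PRESETS: dict[str, GenotypeGains] = {
    "wild_type": GenotypeGains(g_att=1.0, g_rep=1.0),
    "osm5_like": GenotypeGains(g_att=0.60, g_rep=0.18),
}


@dataclass(frozen=True)
class PlateSimConfig:
    """Parameters of the virtual assay plate.

    Distances in cm, times in s, rates in 1/s.  ``attractant_amplitude`` /
    ``repellent_amplitude`` set the peak perceived signal of each odor spot;
    ``tumble_gain`` (beta) couples the signal derivative to the tumble rate.
    ``suppression_gain`` optionally gates the attractant term by the local
    repellent signal (0 disables the gate; blocking then emerges purely from
    linear repellent dominance).
    """

    plate_radius: float = 5.0
    source_offset: float = 3.33
    trap_radius: float = 0.5
    duration: float = 3600.0
    dt: float = 1.0
    n_worms: int = 60
    speed: float = 0.015
    base_tumble_rate: float = 0.25
    tumble_gain: float = 10.0
    lambda_max: float = 2.0
    field_sigma: float = 2.0
    attractant_amplitude: float = ODORANT_AMPLITUDES["iaa"]
    repellent_amplitude: float = ODORANT_AMPLITUDES["nonanone"]
    g_att: float = 1.0
    g_rep: float = 1.0
    suppression_gain: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.source_offset < self.plate_radius):
            raise ValueError("source_offset must lie inside the plate")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        for name in ("speed", "base_tumble_rate", "tumble_gain", "lambda_max",
                     "attractant_amplitude", "repellent_amplitude",
                     "g_att", "g_rep", "suppression_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_worms < 1:
            raise ValueError("n_worms must be at least 1")


@dataclass
class WormState:
    """Position (cm), heading (rad) and immobilization flag of one worm."""

    x: float
    y: float
    heading: float
    immobilized: bool = False
    signal: float = 0.0  # perceived signal at the current position


def _sources(config: PlateSimConfig, assay_type: str) -> tuple[tuple[float, float], tuple[float, float]]:
    """(attractant position, repellent position); pairing co-locates both on
    the odor side."""
    odor = (config.source_offset, 0.0)
    opposite = (-config.source_offset, 0.0)
    if assay_type == "attractant":
        return odor, opposite  # repellent position unused (amplitude gated)
    if assay_type == "repellent":
        return opposite, odor  # attractant position unused
    if assay_type == "pairing":
        return odor, odor
    raise ValueError(f"unknown assay_type {assay_type!r}")


def _field_xy(
    x: np.ndarray | float,
    y: np.ndarray | float,
    config: PlateSimConfig,
    assay_type: str,
):
    att_pos, rep_pos = _sources(config, assay_type)
    s2 = 2.0 * config.field_sigma**2
    a_att = config.g_att * config.attractant_amplitude if assay_type != "repellent" else 0.0
    a_rep = config.g_rep * config.repellent_amplitude if assay_type != "attractant" else 0.0
    g_att = np.exp(-((x - att_pos[0]) ** 2 + (y - att_pos[1]) ** 2) / s2)
    g_rep = np.exp(-((x - rep_pos[0]) ** 2 + (y - rep_pos[1]) ** 2) / s2)
    att_term = a_att * g_att
    if config.suppression_gain > 0.0:
        att_term = att_term / (1.0 + config.suppression_gain * a_rep * g_rep)
    return att_term - a_rep * g_rep


def odor_field(point: tuple[float, float], config: PlateSimConfig, assay_type: str = "pairing") -> float:
    """Perceived signal S at ``point``: attractant Gaussian minus repellent
    Gaussian, weighted by the genotype gains."""
    x, y = point
    if math.hypot(x, y) > config.plate_radius + 1e-9:
        raise ValueError("point lies outside the plate")
    return float(_field_xy(x, y, config, assay_type))


def _trap_centers(config: PlateSimConfig) -> np.ndarray:
    return np.array([[config.source_offset, 0.0], [-config.source_offset, 0.0]])


def step_worm(
    state: WormState,
    config: PlateSimConfig,
    rng: np.random.Generator,
    assay_type: str = "pairing",
) -> WormState:
    """Advance one worm by one time step (scalar reference kernel).

    The tumble rate is lambda = base_rate * exp(-beta * dS/dt), clamped to
    [0, lambda_max]; the per-step tumble probability is 1 - exp(-lambda*dt).
    A tumbling worm redraws its heading uniformly and does not advance;
    otherwise it runs speed*dt along its heading, reflecting at the plate
    edge.  Entering either azide trap disk immobilizes the worm permanently.
    """
    if state.immobilized:
        return state
    s_now = float(_field_xy(state.x, state.y, config, assay_type))
    ds_dt = (s_now - state.signal) / config.dt
    lam = config.base_tumble_rate * math.exp(-config.tumble_gain * ds_dt)
    lam = min(max(lam, 0.0), config.lambda_max)
    p_tumble = 1.0 - math.exp(-lam * config.dt)
    if rng.random() < p_tumble:
        new = WormState(state.x, state.y, rng.uniform(0.0, 2.0 * math.pi),
                        False, s_now)
    else:
        nx = state.x + config.speed * config.dt * math.cos(state.heading)
        ny = state.y + config.speed * config.dt * math.sin(state.heading)
        heading = state.heading
        r = math.hypot(nx, ny)
        if r > config.plate_radius:
            # fold the overshoot back inside and reverse the radial component
            scale = (2.0 * config.plate_radius - r) / r
            nx, ny = nx * scale, ny * scale
            heading = math.atan2(ny, nx) + math.pi
        new = WormState(nx, ny, heading, False, s_now)
    for cx, cy in _trap_centers(config):
        if math.hypot(new.x - cx, new.y - cy) <= config.trap_radius:
            new.immobilized = True
            break
    return new


def _simulate_positions(
    config: PlateSimConfig, assay_type: str, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized walk of all worms; returns final (n_worms, 2) positions."""
    n = config.n_worms
    n_steps = int(round(config.duration / config.dt))
    x = np.zeros(n)
    y = np.zeros(n)
    heading = rng.uniform(0.0, 2.0 * np.pi, size=n)
    mobile = np.ones(n, dtype=bool)
    s_prev = np.full(n, _field_xy(0.0, 0.0, config, assay_type), dtype=float)
    step = config.speed * config.dt
    traps = _trap_centers(config)
    for _ in range(n_steps):
        if not mobile.any():
            break
        s_now = _field_xy(x, y, config, assay_type)
        ds_dt = (s_now - s_prev) / config.dt
        lam = np.clip(
            config.base_tumble_rate * np.exp(-config.tumble_gain * ds_dt),
            0.0,
            config.lambda_max,
        )
        p_tumble = 1.0 - np.exp(-lam * config.dt)
        u = rng.random(n)
        new_headings = rng.uniform(0.0, 2.0 * np.pi, size=n)
        tumble = mobile & (u < p_tumble)
        run = mobile & ~tumble
        heading = np.where(tumble, new_headings, heading)
        x = np.where(run, x + step * np.cos(heading), x)
        y = np.where(run, y + step * np.sin(heading), y)
        # reflecting boundary
        r = np.hypot(x, y)
        out = run & (r > config.plate_radius)
        if out.any():
            scale = (2.0 * config.plate_radius - r[out]) / r[out]
            x[out] *= scale
            y[out] *= scale
            heading[out] = np.arctan2(y[out], x[out]) + np.pi
        s_prev = np.where(mobile, s_now, s_prev)
        # azide traps freeze worms where they stand
        for cx, cy in traps:
            trapped = mobile & (np.hypot(x - cx, y - cy) <= config.trap_radius)
            mobile &= ~trapped
    return np.column_stack([x, y])


def simulate_plate(
    config: PlateSimConfig,
    assay_type: str,
    plate_id: str = "sim",
    genotype: str = "wild_type",
    rng: np.random.Generator | None = None,
) -> PlateCount:
    """Run one plate and score the final positions into the three strips."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pos = _simulate_positions(config, assay_type, rng)
    bound = config.plate_radius / 3.0
    n_toward = int(np.sum(pos[:, 0] > bound))
    n_away = int(np.sum(pos[:, 0] < -bound))
    n_middle = config.n_worms - n_toward - n_away
    return PlateCount(
        plate_id=plate_id,
        genotype=genotype,
        assay_type=assay_type,
        n_toward=n_toward,
        n_away=n_away,
        n_middle=n_middle,
    )


def simulate_plates(
    config: PlateSimConfig,
    assay_type: str,
    n_plates: int,
    genotype: str = "wild_type",
    seed: int | None = None,
) -> list[PlateCount]:
    """Simulate ``n_plates`` independent plates.

    Each plate gets its own RNG stream spawned deterministically from the
    master seed, so plates are independent and the batch is reproducible.
    """
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    streams = master.spawn(n_plates)
    return [
        simulate_plate(
            config,
            assay_type,
            plate_id=f"{genotype}-{assay_type}-{i:03d}",
            genotype=genotype,
            rng=np.random.default_rng(ss),
        )
        for i, ss in enumerate(streams)
    ]


def genotype_presets(name: str) -> GenotypeGains:
    """Sensory-gain preset for a named genotype."""
    try:
        return GENOTYPE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown genotype preset {name!r}; known: {sorted(GENOTYPE_PRESETS)}"
        ) from None


def attractant_presets(odorant: str) -> float:
    """Perceived-signal amplitude for a named attractant spot."""
    try:
        return ODORANT_AMPLITUDES[odorant]
    except KeyError:
        raise KeyError(
            f"unknown odorant {odorant!r}; known: {sorted(ODORANT_AMPLITUDES)}"
        ) from None


def configure(
    genotype: str = "wild_type",
    attractant: str = "iaa",
    seed: int = 0,
    **overrides,
) -> PlateSimConfig:
    """Convenience constructor applying genotype and odorant presets."""
    gains = genotype_presets(genotype)
    base = PlateSimConfig(
        attractant_amplitude=attractant_presets(attractant),
        g_att=gains.g_att,
        g_rep=gains.g_rep,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base
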