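"""Simulation configuration.

All tunable constants of the model live here, grouped by mechanism, with the
units used throughout the package (µm, ms unless stated, Hz, simulated hours
for phase durations).  Every stochastic component draws from its own named
seed stream derived from the top-level seed, so a run is fully reproducible
from the config alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

SCENARIOS = (
    "wt",
    "activity_block",
    "guidance_block",
    "block_ap",
    "ephrina2_ko",
    "ephrina5_ko",
    "epha_ki",
    "binocular_uncorr",
    "binocular_corr",
    "onoff",
)

#: named RNG streams; each gets ``SeedSequence(seed, stream_index)``
SEED_STREAMS = ("layout", "waves", "spikes", "growth", "synapses", "scenario")


@dataclass
class WaveParams:
    """Retinal wave generator (velocities in µm/s, times in s, areas in mm²)."""

    velocity: float = 130.0          # mean front velocity
    velocity_sd: float = 10.0        # between-wave speed variability
    inter_wave_interval: float = 90.0  # mean interval between waves covering a point
    mean_area: float = 0.95          # mean wave footprint area
    refractory: float = 30.0         # recently covered tissue does not seed new waves


@dataclass
class BurstParams:
    """Burst scheduling on wavefront arrival.

    The stated triplet (90 s coverage interval, 50 spikes/burst, 0.5 Hz mean
    rate) is mutually inconsistent by ~11%; a per-wave participation
    probability of 0.9 reconciles it exactly: 50 spikes x 0.9 / 90 s = 0.5 Hz.
    """

    burst_rate: float = 20.0         # Hz, generic RGCs
    burst_duration: float = 2.5      # s
    participation: float = 0.9       # per-wave cell participation probability
    # ON/OFF scenario
    on_rate: float = 24.0            # Hz
    off_rate: float = 20.0           # Hz
    on_duration: float = 2.0         # s (typeset value unavailable; ON bursts
    off_duration: float = 2.5        # s  shorter but faster than OFF)
    on_participation: float = 0.67   # fraction of waves an ON cell joins
    on_lead: float = 1.0             # s, ON bursts lead OFF bursts
    cycles_per_wave: int = 3         # burst cycles per wave (ON/OFF scenario)
    cycle_period: float = 4.0        # s between cycle onsets


@dataclass
class GuidanceParams:
    """Chemoaffinity (net ephrinA/EphA effect) parameters."""

    gamma_lm: float = 2.0            # relative guidance strength, ML axis
    gamma_ap: float = 1.0            # relative guidance strength, AP axis
    specificity: float = 1.0         # wild-type chemospecificity s
    affinity_width: float = 0.7      # decay scale of A, as fraction of L_c
    sigmoid_power: float = 4.0       # steepness of the sigmoid-like decay family
    s_min_factor: float = 1.0 / 3.0  # knockout floor relative to WT specificity
    ki_fraction: float = 0.5         # EphA knock-in: fraction of RGCs altered
    ki_gain: float = 3.0             # EphA knock-in: specificity multiplier


@dataclass
class NeuronParams:
    """Integrate-and-fire collicular neurons with maturation and homeostasis."""

    tau_m: float = 20.0              # ms, excitation decay ("membrane") constant
    tau_ampa: float = 5.0            # ms, synaptic input decay constant
    threshold: float = 2.05          # calibrated: ~3 coincident unit inputs fire
    #                                  an immature neuron, ~12 a mature one
    refractory_ms: int = 2           # absolute refractory, prevents same-ms doubles
    att0: float = 0.2                # EPSP attenuation g(S) = 1/(att0 + att1*S)
    att1: float = 0.8
    target_rate: float = 0.5         # Hz, homeostatic set point rho
    rate_window_s: int = 1200        # 20-minute moving window for rate estimates
    tau_size_h: float = 10.0         # hours, maturation time constant
    size_min: float = 0.05           # lower clip of neuron size S
    size_init: float = 0.05          # starting size (immature)
    h_init: float = 0.5              # homeostatic synaptic scale
    h_min: float = 0.05
    h_max: float = 8.0
    h_tau_s: float = 1800.0           # homeostatic adaptation time constant, s
    release_mod_width: float = 2.0   # decay width of trophic-release modifier,
    #                                  in units of (r - rho)/rho
    release_mod_floor: float = 0.05  # lower bound of the modifier


@dataclass
class FieldParams:
    """Extracellular growth (B) and repulsive (P) factor grids."""

    grid_cell_um: float = 10.0
    tau_b_s: float = 300.0           # 5 min decay
    tau_p_s: float = 300.0
    update_dt_s: float = 1.0
    # release magnitudes are normalised so a fully immature, silent neuron's
    # footprint saturates at B = 1.0 (and symmetrically P = 1.0)


@dataclass
class ArborParams:
    """Axon segment trees: growth, branching, retraction."""

    segment_len: float = 11.0        # µm
    extension_rate: float = 0.5      # min^-1 base probability
    branch_rate: float = 0.25        # min^-1 base probability
    retraction_rate: float = 0.5     # min^-1 base probability
    growth_dt_s: float = 60.0        # growth events evaluated once per minute
    budget_n: int = 5                # max new segments ...
    budget_window_s: float = 600.0   # ... per sliding 10-minute window
    size_frac: float = 0.25          # arbor size parameter = segments needed to
    #                                  stretch this fraction of L_c
    lambda_hop: float = 0.5          # per-hop decay of the trophic neighbourhood
    heading_jitter_deg: float = 15.0
    lm_jitter_sd: float = 0.2        # trunk entry ML offset, fraction of ML width
    w_b: float = 1.0                 # weight of extracellular B in exposure G
    w_t: float = 0.5                 # weight of trophic neighbourhood in G
    w_p: float = 1.0                 # weight of extracellular P in repulsion R
    repulsion_base: float = 0.5      # chemorepulsion floor in R


@dataclass
class SynapseParams:
    """Synapse lifecycle and trophic bookkeeping."""

    formation_rate: float = 0.4      # base probability per 500 ms check
    check_dt_s: float = 0.5          # formation/retraction cadence
    max_per_segment: int = 4         # "maximum of four synapses" (the equation-
    #                                  adjacent statement; the figure text says 3)
    pair_ratio_cap: float = 0.3      # max fraction of a cell's input from one RGC
    accept_rate_width: float = 1.0   # decay width of acceptance vs rate excess
    count_scale_mult: float = 8.0    # synapse-count regulator nu, as multiple of
    #                                  the arbor-size parameter
    tau_coinc_ms: float = 12.0       # pre/post coincidence kernel ("tens of ms")
    t_init: float = 0.5              # trophic state of a new synapse
    destab_rate: float = 0.03        # T decrement per unit bound destabiliser
    stab_rate: float = 0.08           # T increment per unit converted factor
    omega: float = 0.75              # own-weight in trophic support (75%/25%)
    retract_base: float = 0.05       # base retraction probability per 500 ms
    retract_reg_floor: float = 0.25  # floor of the synapse-count regulator


@dataclass
class SimulationConfig:
    scenario: str = "wt"
    profile: str = "tiny"
    seed: int = 0
    n_rgc: int = 300
    n_sc: int = 800
    retina_radius_mm: float = 2.25   # mouse-like retina; waves (~1 mm across)
    #                                  then span a small fraction of it
    aspect: float = 1.6              # AP : ML extent of the colliculus
    phase1_h: float = 6.0            # molecular-guidance-only phase
    phase2_h: float = 8.0            # activity-dependent phase
    combined: bool = False           # activity-dependent feedback from t = 0
    snapshot_min: float = 60.0       # metric snapshot cadence, simulated minutes
    waves: WaveParams = field(default_factory=WaveParams)
    bursts: BurstParams = field(default_factory=BurstParams)
    guidance: GuidanceParams = field(default_factory=GuidanceParams)
    neurons: NeuronParams = field(default_factory=NeuronParams)
    fields: FieldParams = field(default_factory=FieldParams)
    arbors: ArborParams = field(default_factory=ArborParams)
    synapses: SynapseParams = field(default_factory=SynapseParams)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.phase1_h < 0 or self.phase2_h < 0:
            raise ValueError("phase durations must be >= 0")
        if self.combined and self.scenario == "activity_block":
            raise ValueError("combined phases are meaningless with activity blocked")

    # -- seeds ---------------------------------------------------------------
    def seed_for(self, stream: str) -> np.random.SeedSequence:
        if stream not in SEED_STREAMS:
            raise KeyError(f"unknown seed stream {stream!r}")
        return np.random.SeedSequence(self.seed, spawn_key=(SEED_STREAMS.index(stream),))

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(self.seed_for(stream))

    @property
    def binocular(self) -> bool:
        return self.scenario.startswith("binocular")


#: scale profiles: (n_rgc, n_sc, phase1_h, phase2_h).  The reduced profile
#: matches the smallest published run (2515 RGCs onto 6772 collicular cells);
#: paper scale is the full 10 K -> 25 K system.
PROFILES = {
    "tiny": (300, 800, 6.0, 8.0),
    "reduced": (2515, 6772, 48.0, 60.0),
    "paper": (10000, 25000, 48.0, 60.0),
}


def apply_profile(cfg: SimulationConfig, profile: str) -> SimulationConfig:
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    n_rgc, n_sc, p1, p2 = PROFILES[profile]
    cfg.profile = profile
    cfg.n_rgc, cfg.n_sc, cfg.phase1_h, cfg.phase2_h = n_rgc, n_sc, p1, p2
    return cfg


# ---------------------------------------------------------------------------
# YAML round-trip

_GROUPS = {
    "waves": WaveParams,
    "bursts": BurstParams,
    "guidance": GuidanceParams,
    "neurons": NeuronParams,
    "fields": FieldParams,
    "arbors": ArborParams,
    "synapses": SynapseParams,
}


def config_to_dict(cfg: SimulationConfig) -> dict[str, Any]:
    return dataclasses.asdict(cfg)


def config_from_dict(data: dict[str, Any]) -> SimulationConfig:
    data = dict(data)
    kwargs: dict[str, Any] = {}
    top_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    for key, value in data.items():
        if key not in top_fields:
            raise ValueError(f"unknown configuration key {key!r}")
        if key in _GROUPS:
            cls = _GROUPS[key]
            known = {f.name for f in dataclasses.fields(cls)}
            extra = set(value) - known
            if extra:
                raise ValueError(
                    f"unknown key(s) {sorted(extra)} in section {key!r}"
                )
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return SimulationConfig(**kwargs)


def save_config(cfg: SimulationConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path: str) -> SimulationConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
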