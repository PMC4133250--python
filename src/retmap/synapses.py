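"""Synapse lifecycle: formation, acceptance, trophic bookkeeping, retraction.

Every synapse carries a trophic state ``T`` in [0, 1] and two cleft
quantities.  Each presynaptic spike deposits one unit of destabilising
pro-factor into the cleft; over tens of milliseconds the resident pro-factor
binds (destabilising the synapse in proportion, gated by the segment's
chemoaffinity).  A postsynaptic spike converts the still-unbound pro-factor
into growth-promoting factor, moving ``T`` toward 1 in proportion to the
converted amount, the chemoaffinity, and the postsynaptic trophic-release
modifier — so trophic reward requires a post spike within tens of ms of
vesicle release.  All synapses have unit efficacy; plasticity acts only
through creation and retraction.

Survival is comparative: a synapse's trophic support (a 75%/25% blend of its
own ``T`` with the hop-discounted mean over nearby axonal synapses) is judged
against the mean over its axon's synapses and, separately, the mean over its
dendrite's synapses; only below-average synapses can retract, worst
performers most often.

Storage is struct-of-arrays with capacity doubling; removed synapses are
masked, never compacted, so synapse ids are stable for the whole run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SynapseParams
from .guidance import decay_sigmoid

_NONE = -1


# ---------------------------------------------------------------------------
# Trophic state updates (scalar reference; the numba kernel mirrors these and
# is tested against them event-for-event)

def bound_fraction(dt_ms: float, tau_coinc_ms: float) -> float:
    """Fraction of resident cleft pro-factor bound after ``dt_ms``."""
    return 1.0 - np.exp(-dt_ms / tau_coinc_ms)


def on_pre_spike(
    t_state: float,
    cleft_pro: float,
    last_ms: float,
    t_ms: float,
    affinity: float,
    params: SynapseParams,
) -> tuple[float, float, float]:
    """Apply a presynaptic spike; returns (T, cleft_pro, cleft_nt).

    Resident pro-factor binds in a Δt-dependent fraction and destabilises the
    synapse (T moves toward 0, gated by chemoaffinity); one fresh unit is
    released minus the bound amount; any unconverted growth factor is cleared.
    """
    if t_ms < last_ms:
        raise ValueError("event time precedes the synapse's last event")
    bound = cleft_pro * bound_fraction(t_ms - last_ms, params.tau_coinc_ms)
    t_state = max(0.0, t_state - params.destab_rate * affinity * bound)
    cleft_pro = cleft_pro - bound + 1.0
    return t_state, cleft_pro, 0.0


def on_post_spike(
    t_state: float,
    cleft_pro: float,
    last_ms: float,
    t_ms: float,
    affinity: float,
    params: SynapseParams,
    release_mod: float = 1.0,
) -> tuple[float, float, float]:
    """Apply a postsynaptic spike; returns (T, cleft_pro, cleft_nt).

    The unbound remainder of the cleft pro-factor converts to growth factor
    and stabilises the synapse (T toward 1), scaled by chemoaffinity and the
    postsynaptic trophic-release modifier; the bound portion destabilises as
    on any event.  Conversion efficacy therefore decays with the time since
    the presynaptic spike on the coincidence timescale.
    """
    if t_ms < last_ms:
        raise ValueError("event time precedes the synapse's last event")
    bound = cleft_pro * bound_fraction(t_ms - last_ms, params.tau_coinc_ms)
    cleft_nt = cleft_pro - bound
    t_state = max(0.0, t_state - params.destab_rate * affinity * bound)
    t_state = min(1.0, t_state + params.stab_rate * affinity * release_mod * cleft_nt)
    return t_state, 0.0, cleft_nt


# ---------------------------------------------------------------------------
# Population container

_FIELDS = {
    "rgc": np.int32,
    "seg": np.int64,
    "post": np.int32,
    "t_state": np.float64,
    "cleft_pro": np.float64,
    "cleft_nt": np.float64,
    "last_ms": np.float64,
    "affinity": np.float64,
    "alive": np.bool_,
    "created_ms": np.int64,
}


class SynapseSystem:
    """All synapses of a run."""

    def __init__(self, n_rgc: int, n_post: int, params: SynapseParams | None = None):
        self.params = params or SynapseParams()
        self.n_rgc = n_rgc
        self.n_post = n_post
        self._n = 0
        self._cap = 256
        for name, dtype in _FIELDS.items():
            setattr(self, "_" + name, np.zeros(self._cap, dtype=dtype))
        self.n_in = np.zeros(n_post, dtype=np.int64)       # innervation counts
        self.n_axonal = np.zeros(n_rgc, dtype=np.int64)    # synapses per axon
        self.pair_count: dict[tuple[int, int], int] = {}

    def __getattr__(self, name):
        if name in _FIELDS:
            return getattr(self, "_" + name)[: self._n]
        raise AttributeError(name)

    def _grow(self) -> None:
        self._cap *= 2
        for name, dtype in _FIELDS.items():
            old = getattr(self, "_" + name)
            new = np.zeros(self._cap, dtype=dtype)
            new[: self._n] = old[: self._n]
            setattr(self, "_" + name, new)

    @property
    def n_total(self) -> int:
        return self._n

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def add(self, rgc: int, seg: int, post: int, affinity: float, t_ms: float) -> int:
        if self._n == self._cap:
            self._grow()
        i = self._n
        self._rgc[i] = rgc
        self._seg[i] = seg
        self._post[i] = post
        self._t_state[i] = self.params.t_init
        self._cleft_pro[i] = 0.0
        self._cleft_nt[i] = 0.0
        self._last_ms[i] = float(t_ms)
        self._affinity[i] = affinity
        self._alive[i] = True
        self._created_ms[i] = int(t_ms)
        self._n += 1
        self.n_in[post] += 1
        self.n_axonal[rgc] += 1
        key = (int(rgc), int(post))
        self.pair_count[key] = self.pair_count.get(key, 0) + 1
        return i

    def remove(self, ids: np.ndarray) -> None:
        ids = np.atleast_1d(ids)
        ids = ids[self.alive[ids]]
        self._alive[ids] = False
        for sid in ids:
            rgc, post = int(self._rgc[sid]), int(self._post[sid])
            self.n_in[post] -= 1
            self.n_axonal[rgc] -= 1
            key = (rgc, post)
            self.pair_count[key] -= 1
            if self.pair_count[key] == 0:
                del self.pair_count[key]

    def per_segment_counts(self, n_segments: int) -> np.ndarray:
        live = self.alive
        return np.bincount(self.seg[live], minlength=n_segments)

    # -- formation ----------------------------------------------------------
    def formation_probability(self, g, n_axonal) -> np.ndarray:
        """Probability per 500 ms check: base × (rising in the segment's
        growth exposure) × (damped by the axon's synapse count via the
        arbor-size-linked regulator)."""
        p = self.params
        return np.clip(
            p.formation_rate
            * np.clip(np.asarray(g, dtype=float), 0.0, 1.0)
            * decay_sigmoid(
                np.asarray(n_axonal, dtype=float) / self._count_scale, 1.0
            ),
            0.0,
            1.0,
        )

    @property
    def _count_scale(self) -> float:
        return getattr(self, "count_scale", 20.0)

    def acceptance_probability(
        self, post_rate, pair_n, n_in, target_rate: float
    ) -> np.ndarray:
        """Postsynaptic acceptance: decays as the cell's rate exceeds target,
        and is zero once the candidate pair would exceed the per-pair share
        cap of the cell's innervation."""
        p = self.params
        excess = np.maximum(0.0, (np.asarray(post_rate, dtype=float) - target_rate)
                            / target_rate)
        prob = decay_sigmoid(excess, p.accept_rate_width, 2.0)
        ratio = np.asarray(pair_n, dtype=float) / np.maximum(
            np.asarray(n_in, dtype=float), 1.0
        )
        return np.where(ratio >= p.pair_ratio_cap, 0.0, prob)

    # -- survival -----------------------------------------------------------
    def trophic_support(self, t_bar_local: np.ndarray) -> np.ndarray:
        """ω-blend of a synapse's own T with its axonal neighbourhood mean."""
        w = self.params.omega
        return w * self.t_state + (1.0 - w) * t_bar_local

    def trophic_support_values(self, ids: np.ndarray, t_bar_local: np.ndarray):
        w = self.params.omega
        return w * self.t_state[ids] + (1.0 - w) * t_bar_local

    def retraction_probability(
        self, t_support: np.ndarray, group_mean: np.ndarray, n_count: np.ndarray
    ) -> np.ndarray:
        """Comparative retraction: positive only below the group mean, rising
        with the shortfall, modulated by the synapse-count regulator."""
        p = self.params
        mean = np.maximum(np.asarray(group_mean, dtype=float), 1e-12)
        shortfall = np.clip(1.0 - np.asarray(t_support) / mean, 0.0, 1.0)
        reg = p.retract_reg_floor + (1.0 - p.retract_reg_floor) * (
            1.0 - decay_sigmoid(
                np.asarray(n_count, dtype=float) / self._count_scale, 1.0
            )
        )
        return np.clip(p.retract_base * shortfall * reg, 0.0, 1.0)

    # -- state restore ------------------------------------------------------
    def set_state(self, arrays: dict) -> None:
        """Replace the full synapse table (checkpoint restore)."""
        n = len(arrays["rgc"])
        self._n = n
        self._cap = max(256, n)
        for name, dtype in _FIELDS.items():
            buf = np.zeros(self._cap, dtype=dtype)
            buf[:n] = arrays[name]
            setattr(self, "_" + name, buf)
        live = np.flatnonzero(self.alive)
        self.n_in = np.bincount(
            self.post[live], minlength=self.n_post
        ).astype(np.int64)
        self.n_axonal = np.bincount(
            self.rgc[live], minlength=self.n_rgc
        ).astype(np.int64)
        self.pair_count = {}
        for sid in live:
            key = (int(self.rgc[sid]), int(self.post[sid]))
            self.pair_count[key] = self.pair_count.get(key, 0) + 1

    # -- export -------------------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        live = np.flatnonzero(self.alive)
        return pd.DataFrame(
            {
                "synapse_id": live,
                "rgc_id": self.rgc[live],
                "segment_id": self.seg[live],
                "post_cell_id": self.post[live],
                "T": self.t_state[live],
                "created_ms": self.created_ms[live],
            }
        )
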