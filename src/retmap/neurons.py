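"""Integrate-and-fire collicular neurons with maturation and homeostasis.

The excitation variable ``E`` is summed synaptic input, not a membrane
voltage: it decays with a membrane-like time constant, is driven by the
synaptic input trace ``I`` (AMPA-like, ms decay), and resets to zero on a
spike.  Neurons mature by growing their electrical size ``S``; the somatic
effect of a unit input is attenuated as ``1 / (att0 + att1 * S)``, so an
immature neuron reaches threshold on ~3 near-coincident unit inputs while a
mature one needs ~12.  Maturation relaxes toward a firing-rate-gated target
with an hours-scale time constant and reverses when the cell falls silent.

Homeostatic controls: a synaptic scale ``h`` multiplies every input and
adapts to hold the 20-minute firing-rate estimate at the 0.5 Hz target, and
trophic feedback to innervating synapses is down-regulated as the rate rises
above target (presynaptic competition for postsynaptic resources).
"""

from __future__ import annotations

import numpy as np

from .config import NeuronParams
from .guidance import decay_sigmoid


class NeuronPopulation:
    """Vectorised state for all collicular neurons of one run."""

    def __init__(self, n: int, params: NeuronParams | None = None):
        self.params = params or NeuronParams()
        p = self.params
        self.n = n
        self.size = np.full(n, p.size_init)
        self.excitation = np.zeros(n)
        self.syn_input = np.zeros(n)
        self.h = np.full(n, p.h_init)
        self.refractory = np.zeros(n, dtype=np.int32)
        self.rate = np.zeros(n)                       # Hz, moving-window estimate
        self.n_innervating = np.zeros(n, dtype=np.int64)
        # per-second spike counts over the moving window (ring buffer)
        self._ring = np.zeros((n, int(p.rate_window_s)), dtype=np.int32)
        self._ring_pos = 0
        self._ring_filled = 0
        self._ring_sum = np.zeros(n, dtype=np.int64)

    # -- decay factors -------------------------------------------------------
    @property
    def alpha_m(self) -> float:
        return float(np.exp(-1.0 / self.params.tau_m))

    @property
    def alpha_ampa(self) -> float:
        return float(np.exp(-1.0 / self.params.tau_ampa))

    def attenuation(self, size=None) -> np.ndarray:
        """Input efficacy g(S): larger (mature) neurons see smaller EPSPs."""
        p = self.params
        if size is None:
            size = self.size
        return 1.0 / (p.att0 + p.att1 * np.asarray(size))

    # -- 1 ms integration (reference implementation; the engine uses the
    #    numba kernel, which must agree with this step exactly) -------------
    def integrate_step(self, spikes_in: np.ndarray) -> np.ndarray:
        """Advance all neurons one millisecond.

        ``spikes_in`` is the per-neuron count of presynaptic vesicle releases
        in this millisecond.  Returns a boolean array of neurons that fired;
        their excitation is reset to zero and a short absolute refractory
        prevents same-millisecond double counting.
        """
        spikes_in = np.asarray(spikes_in)
        if np.any(spikes_in < 0):
            raise ValueError("negative spike count")
        p = self.params
        self.syn_input = self.syn_input * self.alpha_ampa + self.h * spikes_in
        drive = self.attenuation() * self.syn_input
        self.excitation = self.excitation * self.alpha_m + (1.0 - self.alpha_m) * drive
        can_fire = self.refractory <= 0
        fired = can_fire & (self.excitation >= p.threshold)
        self.excitation[fired] = 0.0
        self.refractory[fired] = p.refractory_ms
        self.refractory[self.refractory > 0] -= 1
        return fired

    # -- rate estimation (per-second cadence) -------------------------------
    def push_second(self, counts: np.ndarray) -> None:
        """Append one second of per-neuron spike counts to the moving window."""
        self._ring_sum += counts - self._ring[:, self._ring_pos]
        self._ring[:, self._ring_pos] = counts
        self._ring_pos = (self._ring_pos + 1) % self._ring.shape[1]
        self._ring_filled = min(self._ring_filled + 1, self._ring.shape[1])
        self.rate = self._ring_sum / max(self._ring_filled, 1)

    # -- slow dynamics -------------------------------------------------------
    def update_size(self, dt_s: float) -> None:
        """Relax size toward a rate-gated maturity target (hours scale).

        At or above the target rate the neuron matures toward ``S = 1``;
        a silent neuron shrinks back toward the immature floor.
        """
        if dt_s < 0:
            raise ValueError("dt must be >= 0")
        p = self.params
        target = np.clip(self.rate / p.target_rate, 0.0, 1.0)
        a = np.exp(-dt_s / (p.tau_size_h * 3600.0))
        self.size = np.clip(target + (self.size - target) * a, p.size_min, 1.0)

    def update_homeostasis(self, dt_s: float = 1.0) -> None:
        """Multiplicative synaptic-scale adaptation toward the target rate."""
        p = self.params
        err = (p.target_rate - self.rate) / p.target_rate
        self.h = np.clip(self.h * np.exp(err * dt_s / p.h_tau_s), p.h_min, p.h_max)

    def trophic_release_modifier(self, rate=None) -> np.ndarray:
        """Multiplier in (0, 1] applied to trophic feedback a cell releases.

        Unity at or below the target rate, decaying as the rate rises above
        it, down to a small floor — over-active cells starve their synapses
        of trophic support.
        """
        p = self.params
        r = self.rate if rate is None else np.asarray(rate, dtype=float)
        excess = np.maximum(0.0, (r - p.target_rate) / p.target_rate)
        mod = decay_sigmoid(excess, p.release_mod_width, 2.0)
        return np.maximum(mod, p.release_mod_floor)

    # -- constitutive factor release ----------------------------------------
    def release_rates(self, tau_b_s: float, tau_p_s: float):
        """Per-neuron release rates of growth factor B and repulsive factor P.

        B release is maximal for immature, silent neurons; P for mature,
        over-active ones.  Magnitudes are normalised so a fully immature,
        silent neuron's footprint saturates at concentration 1.0.
        """
        p = self.params
        deficit = np.clip(1.0 - self.rate / p.target_rate, 0.0, 1.0)
        excess = np.clip((self.rate - p.target_rate) / p.target_rate, 0.0, 1.0)
        immaturity = (1.0 - self.size) / (1.0 - p.size_min)
        rel_b = (immaturity + deficit) / 2.0 / tau_b_s
        rel_p = (self.size + excess) / 2.0 / tau_p_s
        return rel_b, rel_p
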