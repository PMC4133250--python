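"""Extracellular growth (B, BDNF-like) and repulsive (P, proBDNF-like) fields.

Concentrations live on the 10×10 µm collicular grid, constant within each
square.  Release is constitutive: each neuron deposits uniformly over the
grid squares its 25 µm dendritic disk overlaps (diffusion is confined to the
dendritic footprint; there is no inter-square transport), and concentrations
decay exponentially with minutes-scale time constants.  Updates use the exact
one-step solution for piecewise-constant release, so a zero-release grid
decays exactly exponentially.
"""

from __future__ import annotations

import numpy as np

from .config import FieldParams
from .geometry import SpatialGrid


class FactorGrid:
    """B and P concentrations per grid square, with per-neuron footprints."""

    def __init__(self, grid: SpatialGrid, params: FieldParams | None = None):
        self.params = params or FieldParams()
        self.grid = grid
        n_sq = grid.n_squares
        self.b = np.zeros(n_sq)
        self.p = np.zeros(n_sq)
        # footprints: (neuron, square) pairs from the dendrite index
        sq = np.repeat(
            np.arange(n_sq, dtype=np.int64), np.diff(grid._sq_indptr)
        )
        self._fp_squares = sq
        self._fp_neurons = grid._sq_cells.astype(np.int64)

    def deposit_and_decay(
        self, release_b: np.ndarray, release_p: np.ndarray, dt_s: float
    ) -> None:
        """Advance the fields by ``dt_s`` seconds.

        ``release_b``/``release_p`` are per-neuron release rates (concentration
        per second per covered square), held constant over the step; each
        square integrates the summed release of all neurons whose dendrites
        overlap it and decays toward that source's fixed point.
        """
        if dt_s <= 0:
            raise ValueError("dt must be > 0")
        p = self.params
        rate_b = np.bincount(
            self._fp_squares, weights=release_b[self._fp_neurons],
            minlength=self.grid.n_squares,
        )
        rate_p = np.bincount(
            self._fp_squares, weights=release_p[self._fp_neurons],
            minlength=self.grid.n_squares,
        )
        db = np.exp(-dt_s / p.tau_b_s)
        dp = np.exp(-dt_s / p.tau_p_s)
        self.b = self.b * db + rate_b * p.tau_b_s * (1.0 - db)
        self.p = self.p * dp + rate_p * p.tau_p_s * (1.0 - dp)

    def sample(self, x_um, y_um):
        """(B, P) of the squares containing the given positions."""
        idx = self.grid.square_of(x_um, y_um)
        return self.b[idx], self.p[idx]

    def sample_squares(self, flat_idx: np.ndarray):
        return self.b[flat_idx], self.p[flat_idx]

    @property
    def total_b(self) -> float:
        return float(self.b.sum())

    @property
    def total_p(self) -> float:
        return float(self.p.sum())
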