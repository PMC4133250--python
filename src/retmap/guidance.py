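"""Chemoaffinity: the net effect of ephrinA/EphA gradients.

Countering molecular gradients are not represented explicitly — only their
hypothesised net effect: every RGC carries a retinotopically correct
termination zone (RC-TZ), and the chemoaffinity ``A`` of an axon segment is
maximal there and decays with axis-wise distance, sharper along ML than AP
(``gamma_lm = 2 * gamma_ap``) and sharper for higher chemospecificity ``s``.
Mutant scenarios transform the per-RGC profiles:

* ephrinA2 KO — specificity unchanged for axons targeting the anterior pole,
  falling linearly to a floor for those targeting the posterior pole;
* ephrinA5 KO — specificity at the floor for every RGC;
* EphA knock-in — a random half of RGCs have their TZ compressed into the
  anterior third and specificity tripled;
* axis blocks — the corresponding guidance weight is zeroed (a blocked axis
  contributes a neutral factor to ``A``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GuidanceParams
from .geometry import ColliculusLayout, RetinaLayout, retinotopic_target


def decay_sigmoid(x, k: float, power: float = 4.0):
    """Sigmoid-like decay family: ``exp(-(x/k)^power)``.

    Near-unity plateau for small ``x`` (flat to order ``x^power``), strictly
    decreasing, and asymptotically zero.  ``k`` sets the decay scale.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("decay_sigmoid is defined for x >= 0")
    out = np.exp(-((x / k) ** power))
    return float(out) if out.ndim == 0 else out


@dataclass
class GuidanceProfiles:
    """Per-RGC guidance state (vectorised over the retina)."""

    tz: np.ndarray           # (n, 2) RC-TZ in collicular µm
    specificity: np.ndarray  # (n,) chemospecificity s > 0
    gamma_lm: np.ndarray     # (n,) ML guidance weight
    gamma_ap: np.ndarray     # (n,) AP guidance weight
    altered: np.ndarray      # (n,) bool, True for mutation-affected RGCs

    @property
    def n_rgc(self) -> int:
        return len(self.tz)

    def copy(self) -> "GuidanceProfiles":
        return GuidanceProfiles(
            self.tz.copy(),
            self.specificity.copy(),
            self.gamma_lm.copy(),
            self.gamma_ap.copy(),
            self.altered.copy(),
        )


def build_profiles(
    retina: RetinaLayout,
    colliculus: ColliculusLayout,
    params: GuidanceParams | None = None,
) -> GuidanceProfiles:
    """Wild-type profiles: TZ from the retinotopic map, uniform specificity."""
    params = params or GuidanceParams()
    n = retina.n_cells
    return GuidanceProfiles(
        tz=retinotopic_target(retina.xy, colliculus),
        specificity=np.full(n, params.specificity),
        gamma_lm=np.full(n, params.gamma_lm),
        gamma_ap=np.full(n, params.gamma_ap),
        altered=np.zeros(n, dtype=bool),
    )


def chemoaffinity(
    profiles: GuidanceProfiles,
    rgc_idx: np.ndarray,
    seg_xy: np.ndarray,
    ap_length: float,
    params: GuidanceParams | None = None,
) -> np.ndarray:
    """Chemoaffinity ``A`` in (0, 1] of positions ``seg_xy`` for RGCs
    ``rgc_idx``.

    Product of per-axis decay terms; each axis distance is scaled by the
    collicular length, weighted by the axis guidance strength, and sharpened
    by the RGC's chemospecificity.  A zero axis weight removes that axis's
    contribution entirely.
    """
    params = params or GuidanceParams()
    seg_xy = np.atleast_2d(np.asarray(seg_xy, dtype=float))
    rgc_idx = np.atleast_1d(rgc_idx)
    dx = np.abs(seg_xy[:, 0] - profiles.tz[rgc_idx, 0]) / ap_length
    dy = np.abs(seg_xy[:, 1] - profiles.tz[rgc_idx, 1]) / ap_length
    s = profiles.specificity[rgc_idx]
    a_ap = decay_sigmoid(
        profiles.gamma_ap[rgc_idx] * s * dx, params.affinity_width, params.sigmoid_power
    )
    a_lm = decay_sigmoid(
        profiles.gamma_lm[rgc_idx] * s * dy, params.affinity_width, params.sigmoid_power
    )
    out = np.asarray(a_ap * a_lm)
    return out if out.size > 1 or np.asarray(rgc_idx).ndim else float(out[0])


def apply_scenario(
    profiles: GuidanceProfiles,
    scenario: str,
    seed: int | np.random.SeedSequence = 0,
    ap_length: float | None = None,
    params: GuidanceParams | None = None,
) -> GuidanceProfiles:
    """Return profiles transformed for a guidance scenario.

    ``scenario`` is one of ``wt``, ``ephrina2_ko``, ``ephrina5_ko``,
    ``epha_ki``, ``block_ap``, ``guidance_block`` (scenarios without a
    guidance manipulation — activity block, binocular, ON/OFF — are treated
    as wild type).
    """
    params = params or GuidanceParams()
    out = profiles.copy()
    s_min = params.s_min_factor * params.specificity
    if scenario in ("wt", "activity_block", "binocular_uncorr", "binocular_corr",
                    "onoff"):
        return out
    if scenario == "ephrina2_ko":
        # losing collicular ephrinA2 removes the repulsion that confines
        # high-EphA (temporal, anterior-targeting) axons: specificity falls
        # most for the anterior-most TZs and is unchanged at the posterior
        # pole, so disruptions concentrate in anterior colliculus
        x = out.tz[:, 0]
        lo, hi = x.min(), x.max()
        frac = (hi - x) / (hi - lo) if hi > lo else np.zeros_like(x)
        out.specificity = out.specificity - (out.specificity - s_min) * frac
        out.altered[:] = True
    elif scenario == "ephrina5_ko":
        out.specificity = np.full_like(out.specificity, s_min)
        out.altered[:] = True
    elif scenario == "epha_ki":
        if ap_length is None:
            ap_length = float(out.tz[:, 0].max())
        rng = np.random.default_rng(seed)
        n = out.n_rgc
        subset = rng.random(n) < params.ki_fraction
        out.tz[subset, 0] = out.tz[subset, 0] / 3.0  # compress into anterior third
        out.specificity[subset] *= params.ki_gain
        out.altered = subset
    elif scenario == "block_ap":
        out.gamma_ap[:] = 0.0
        out.altered[:] = True
    elif scenario == "guidance_block":
        out.gamma_ap[:] = 0.0
        out.gamma_lm[:] = 0.0
        out.altered[:] = True
    else:
        raise ValueError(f"unknown guidance scenario {scenario!r}")
    return out
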