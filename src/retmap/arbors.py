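"""Segment-tree axon arbors: trunks, probabilistic growth and tip retraction.

Each RGC axon enters the colliculus anteriorly and lays down a permanent
trunk of 11 µm segments that traverses the full AP extent along a curved
trajectory holding its relative ML position (with a Gaussian entry offset).
Interstitial branching then builds the arbor: tips may extend along their
heading (small jitter), extended-but-unbranched segments may branch
orthogonally, and only tips may retract.  Growth probabilities rise with the
segment's growth-factor exposure ``G``, fall with its repulsion ``R``, and
are damped as the arbor grows past the size parameter (the number of
segments spanning 25% of the collicular length); every RGC is capped at 5
new segments per sliding 10-minute window.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import ArborParams
from .geometry import ColliculusLayout, RetinaLayout, SpatialGrid
from .guidance import GuidanceProfiles, chemoaffinity, decay_sigmoid

_NONE = -1


class ArborSystem:
    """All arbors of a run, stored struct-of-arrays for vectorised updates."""

    def __init__(
        self,
        colliculus: ColliculusLayout,
        grid: SpatialGrid,
        profiles: GuidanceProfiles,
        n_rgc: int,
        params: ArborParams | None = None,
        guidance_params=None,
    ):
        self.params = params or ArborParams()
        self.colliculus = colliculus
        self.grid = grid
        self.profiles = profiles
        self.guidance_params = guidance_params
        self.n_rgc = n_rgc
        # segment arrays (append-only; dead segments keep their slot)
        self.seg_rgc = np.empty(0, dtype=np.int32)
        self.seg_parent = np.empty(0, dtype=np.int64)
        self.seg_child_ext = np.empty(0, dtype=np.int64)
        self.seg_child_branch = np.empty(0, dtype=np.int64)
        self.seg_x1 = np.empty(0)
        self.seg_y1 = np.empty(0)
        self.seg_x2 = np.empty(0)
        self.seg_y2 = np.empty(0)
        self.seg_heading = np.empty(0)
        self.seg_alive = np.empty(0, dtype=bool)
        self.seg_trunk = np.empty(0, dtype=bool)
        self.seg_affinity = np.empty(0)
        self.seg_square = np.empty(0, dtype=np.int64)
        self.seg_has_cand = np.empty(0, dtype=bool)
        self.seg_candidates: list[np.ndarray] = []
        self.roots = np.full(n_rgc, _NONE, dtype=np.int64)
        self.n_seg = np.zeros(n_rgc, dtype=np.int64)  # excludes trunk segments
        self._recent_growth: list[deque] = [deque() for _ in range(n_rgc)]
        self.growth_log: list[tuple[float, int]] = []
        # trophic-neighbourhood weight matrix cache
        self._arbor_triplets: dict[int, tuple] = {}
        self._dirty: set[int] = set(range(n_rgc))
        self._w_matrix = None

    # -- arbor size parameter ------------------------------------------------
    @property
    def size_param(self) -> float:
        """Segments needed to span ``size_frac`` of the collicular length."""
        return max(
            self.params.size_frac * self.colliculus.ap_length / self.params.segment_len,
            1.0,
        )

    # -- segment bookkeeping -------------------------------------------------
    def _append_segment(
        self, rgc: int, parent: int, x1, y1, x2, y2, heading, trunk: bool
    ) -> int:
        sid = len(self.seg_rgc)
        self.seg_rgc = np.append(self.seg_rgc, np.int32(rgc))
        self.seg_parent = np.append(self.seg_parent, parent)
        self.seg_child_ext = np.append(self.seg_child_ext, _NONE)
        self.seg_child_branch = np.append(self.seg_child_branch, _NONE)
        self.seg_x1 = np.append(self.seg_x1, x1)
        self.seg_y1 = np.append(self.seg_y1, y1)
        self.seg_x2 = np.append(self.seg_x2, x2)
        self.seg_y2 = np.append(self.seg_y2, y2)
        self.seg_heading = np.append(self.seg_heading, heading)
        self.seg_alive = np.append(self.seg_alive, True)
        self.seg_trunk = np.append(self.seg_trunk, trunk)
        mx, my = (x1 + x2) / 2.0, (y1 + y2) / 2.0
        aff = chemoaffinity(
            self.profiles, np.array([rgc]), np.array([[mx, my]]),
            self.colliculus.ap_length, self.guidance_params,
        )
        self.seg_affinity = np.append(self.seg_affinity, aff)
        self.seg_square = np.append(self.seg_square, self.grid.square_of(mx, my))
        cand = self.grid.overlapping_dendrites(x1, y1, x2, y2).astype(np.int64)
        self.seg_candidates.append(cand)
        self.seg_has_cand = np.append(self.seg_has_cand, len(cand) > 0)
        if not trunk:
            self.n_seg[rgc] += 1
        self._dirty.add(rgc)
        return sid

    def is_tip(self, sid: int) -> bool:
        return (
            self.seg_child_ext[sid] == _NONE and self.seg_child_branch[sid] == _NONE
        )

    def tips(self) -> np.ndarray:
        return np.flatnonzero(
            self.seg_alive
            & (self.seg_child_ext == _NONE)
            & (self.seg_child_branch == _NONE)
        )

    def branchable(self) -> np.ndarray:
        """Segments that have extended but carry no branch yet."""
        return np.flatnonzero(
            self.seg_alive
            & (self.seg_child_ext != _NONE)
            & (self.seg_child_branch == _NONE)
        )

    # -- initial trunks ------------------------------------------------------
    def init_trunks(self, rng: np.random.Generator) -> None:
        """Extend every axon along the AP axis as a permanent trunk.

        ML entry position is the TZ's ML position plus a Gaussian offset
        (SD = ``lm_jitter_sd`` × ML width); the trunk's curvature holds its
        relative ML position across the tapered outline, overshooting the
        termination zone to the posterior end.
        """
        coll = self.colliculus
        p = self.params
        rgc_l, parent_l, x1_l, y1_l, x2_l, y2_l, head_l = [], [], [], [], [], [], []
        child_ext: list[int] = []
        next_id = len(self.seg_rgc)
        for i in range(self.n_rgc):
            tzx, tzy = self.profiles.tz[i]
            jitter = rng.normal(0.0, p.lm_jitter_sd * coll.ml_width)
            hw_tz = float(coll.half_width(tzx))
            rel = np.clip((tzy + jitter) / hw_tz, -0.93, 0.93) if hw_tz > 0 else 0.0
            x = coll.ap_length * 0.005
            y = rel * float(coll.half_width(x))
            prev = _NONE
            while True:
                # chord of fixed length along the curve y(x) = rel * hw(x):
                # fixed-point iteration on the AP step
                dx = p.segment_len
                for _ in range(4):
                    y_probe = rel * float(
                        coll.half_width(min(x + dx, coll.ap_length))
                    )
                    chord = np.hypot(dx, y_probe - y)
                    dx *= p.segment_len / chord
                x2 = x + dx
                if x2 > coll.ap_length * 0.985:
                    break
                y2 = rel * float(coll.half_width(x2))
                sid = next_id
                rgc_l.append(i)
                parent_l.append(prev)
                x1_l.append(x)
                y1_l.append(y)
                x2_l.append(x2)
                y2_l.append(y2)
                head_l.append(np.arctan2(y2 - y, x2 - x))
                child_ext.append(_NONE)
                if prev == _NONE:
                    self.roots[i] = sid
                else:
                    child_ext[prev - (next_id - len(child_ext) + 1)] = sid
                prev = sid
                next_id += 1
                x, y = x2, y2
        self._bulk_append(
            rgc_l, parent_l, child_ext, x1_l, y1_l, x2_l, y2_l, head_l, trunk=True
        )

    def _bulk_append(
        self, rgc_l, parent_l, child_ext_l, x1_l, y1_l, x2_l, y2_l, head_l, trunk
    ) -> None:
        n_new = len(rgc_l)
        if n_new == 0:
            return
        rgc = np.asarray(rgc_l, dtype=np.int32)
        x1, y1 = np.asarray(x1_l, dtype=float), np.asarray(y1_l, dtype=float)
        x2, y2 = np.asarray(x2_l, dtype=float), np.asarray(y2_l, dtype=float)
        self.seg_rgc = np.concatenate([self.seg_rgc, rgc])
        self.seg_parent = np.concatenate(
            [self.seg_parent, np.asarray(parent_l, dtype=np.int64)]
        )
        self.seg_child_ext = np.concatenate(
            [self.seg_child_ext, np.asarray(child_ext_l, dtype=np.int64)]
        )
        self.seg_child_branch = np.concatenate(
            [self.seg_child_branch, np.full(n_new, _NONE, dtype=np.int64)]
        )
        self.seg_x1 = np.concatenate([self.seg_x1, x1])
        self.seg_y1 = np.concatenate([self.seg_y1, y1])
        self.seg_x2 = np.concatenate([self.seg_x2, x2])
        self.seg_y2 = np.concatenate([self.seg_y2, y2])
        self.seg_heading = np.concatenate(
            [self.seg_heading, np.asarray(head_l, dtype=float)]
        )
        self.seg_alive = np.concatenate([self.seg_alive, np.ones(n_new, dtype=bool)])
        self.seg_trunk = np.concatenate(
            [self.seg_trunk, np.full(n_new, trunk, dtype=bool)]
        )
        mx, my = (x1 + x2) / 2.0, (y1 + y2) / 2.0
        aff = chemoaffinity(
            self.profiles, rgc, np.column_stack([mx, my]),
            self.colliculus.ap_length, self.guidance_params,
        )
        self.seg_affinity = np.concatenate([self.seg_affinity, np.atleast_1d(aff)])
        self.seg_square = np.concatenate(
            [self.seg_square, self.grid.square_of(mx, my)]
        )
        has = np.empty(n_new, dtype=bool)
        for j, (a, b, c, d) in enumerate(zip(x1, y1, x2, y2)):
            cand = self.grid.overlapping_dendrites(a, b, c, d).astype(np.int64)
            self.seg_candidates.append(cand)
            has[j] = len(cand) > 0
        self.seg_has_cand = np.concatenate([self.seg_has_cand, has])
        if not trunk:
            self.n_seg += np.bincount(rgc, minlength=self.n_rgc)
        self._dirty.update(np.unique(rgc).tolist())

    # -- growth probabilities ------------------------------------------------
    def growth_probability(self, base_per_min: float, g, r, n_seg) -> np.ndarray:
        """Per-event success probability for extension or branching.

        ``base × clip01(G - R) × sigmoid(N_seg / size_param)``: the first term
        rises with growth-factor exposure and falls with repulsion; the second
        damps growth as the arbor outgrows the size parameter.
        """
        per_min = base_per_min * self.params.growth_dt_s / 60.0
        term1 = np.clip(np.asarray(g) - np.asarray(r), 0.0, 1.0)
        term2 = decay_sigmoid(np.asarray(n_seg, dtype=float) / self.size_param, 1.0)
        return np.clip(per_min * term1 * term2, 0.0, 1.0)

    def retraction_probability(self, base_per_min: float, r) -> np.ndarray:
        """Tip retraction: base rate scaled up by chemorepulsion and P."""
        per_min = base_per_min * self.params.growth_dt_s / 60.0
        return np.clip(per_min * np.clip(np.asarray(r, dtype=float), 0.0, 1.0), 0.0, 1.0)

    # -- budget --------------------------------------------------------------
    def budget_ok(self, rgc: int, t_s: float) -> bool:
        q = self._recent_growth[rgc]
        while q and q[0] <= t_s - self.params.budget_window_s:
            q.popleft()
        return len(q) < self.params.budget_n

    def _record_growth(self, rgc: int, t_s: float) -> None:
        self._recent_growth[rgc].append(t_s)
        self.growth_log.append((t_s, rgc))

    # -- growth events -------------------------------------------------------
    def try_extend(self, sid: int, t_s: float, rng: np.random.Generator) -> int:
        """Attempt to extend tip ``sid``; returns the new segment id or -1.

        The caller has already drawn growth success; this applies the budget
        and geometry (heading jitter, domain containment).
        """
        if not self.is_tip(sid):
            raise ValueError(f"segment {sid} is not a tip")
        rgc = int(self.seg_rgc[sid])
        if not self.budget_ok(rgc, t_s):
            return _NONE
        heading = self.seg_heading[sid] + rng.normal(
            0.0, np.deg2rad(self.params.heading_jitter_deg)
        )
        return self._grow_from(sid, heading, t_s, rng, branch=False)

    def try_branch(self, sid: int, t_s: float, rng: np.random.Generator) -> int:
        """Attempt an orthogonal branch from extended, unbranched ``sid``."""
        if self.seg_child_ext[sid] == _NONE or self.seg_child_branch[sid] != _NONE:
            raise ValueError(f"segment {sid} is not eligible to branch")
        rgc = int(self.seg_rgc[sid])
        if not self.budget_ok(rgc, t_s):
            return _NONE
        side = 1.0 if rng.random() < 0.5 else -1.0
        heading = self.seg_heading[sid] + side * np.pi / 2.0
        return self._grow_from(sid, heading, t_s, rng, branch=True)

    def _grow_from(self, sid, heading, t_s, rng, branch: bool) -> int:
        x1, y1 = self.seg_x2[sid], self.seg_y2[sid]
        x2 = x1 + self.params.segment_len * np.cos(heading)
        y2 = y1 + self.params.segment_len * np.sin(heading)
        if not bool(self.colliculus.contains(x2, y2, margin=1.0)):
            return _NONE
        rgc = int(self.seg_rgc[sid])
        new = self._append_segment(rgc, sid, x1, y1, x2, y2, heading, trunk=False)
        if branch:
            self.seg_child_branch[sid] = new
        else:
            self.seg_child_ext[sid] = new
        self._record_growth(rgc, t_s)
        return new

    def retract_tip(self, sid: int) -> None:
        """Remove tip ``sid`` (trunk segments are permanent); the parent may
        become a tip, so retraction cascades can prune a whole ectopic branch
        over time without ever disconnecting the tree."""
        if not self.seg_alive[sid]:
            raise ValueError(f"segment {sid} is not alive")
        if not self.is_tip(sid):
            raise ValueError(f"segment {sid} is not a tip")
        if self.seg_trunk[sid]:
            raise ValueError("trunk segments are permanent")
        parent = self.seg_parent[sid]
        if parent != _NONE:
            if self.seg_child_ext[parent] == sid:
                self.seg_child_ext[parent] = _NONE
            elif self.seg_child_branch[parent] == sid:
                self.seg_child_branch[parent] = _NONE
        self.seg_alive[sid] = False
        rgc = int(self.seg_rgc[sid])
        self.n_seg[rgc] -= 1
        self._dirty.add(rgc)

    # -- trophic neighbourhood ----------------------------------------------
    def _arbor_segments(self, rgc: int) -> np.ndarray:
        return np.flatnonzero(self.seg_alive & (self.seg_rgc == rgc))

    def _rebuild_arbor_weights(self, rgc: int) -> None:
        segs = self._arbor_segments(rgc)
        m = len(segs)
        if m == 0:
            self._arbor_triplets[rgc] = (
                np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0)
            )
            return
        # all-pairs hop distances within the arbor via csgraph (trees are
        # tiny, so a dense m x m distance matrix is cheap)
        local = np.full(len(self.seg_rgc), -1, dtype=np.int64)
        local[segs] = np.arange(m)
        pa = self.seg_parent[segs]
        ok = (pa != _NONE) & (self.seg_alive[pa.clip(0)])
        ci = np.flatnonzero(ok)
        pj = local[pa[ok]]
        adj = sp.csr_matrix(
            (np.ones(2 * len(ci)), (np.concatenate([ci, pj]),
                                    np.concatenate([pj, ci]))),
            shape=(m, m),
        )
        dist = sp.csgraph.shortest_path(adj, method="D", unweighted=True)
        rows_l, cols_l = np.nonzero(np.isfinite(dist))
        lam = self.params.lambda_hop
        self._arbor_triplets[rgc] = (
            segs[rows_l], segs[cols_l], lam ** dist[rows_l, cols_l]
        )

    def weight_matrix(self) -> sp.csr_matrix:
        """Sparse matrix W with W[i, j] = lambda^(tree hop distance) for
        segments i, j of the same arbor (0 across arbors)."""
        if self._dirty or self._w_matrix is None:
            for rgc in self._dirty:
                self._rebuild_arbor_weights(rgc)
            self._dirty.clear()
            n = len(self.seg_rgc)
            rows = np.concatenate(
                [t[0] for t in self._arbor_triplets.values()]
                or [np.empty(0, np.int64)]
            )
            cols = np.concatenate(
                [t[1] for t in self._arbor_triplets.values()]
                or [np.empty(0, np.int64)]
            )
            vals = np.concatenate(
                [t[2] for t in self._arbor_triplets.values()] or [np.empty(0)]
            )
            self._w_matrix = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        return self._w_matrix

    def trophic_neighbourhood(self, seg_t_sum: np.ndarray) -> np.ndarray:
        """T̄ per segment: hop-discounted sum of synapse trophic values over
        the whole arbor (``seg_t_sum`` is the per-segment sum of synapse T)."""
        return self.weight_matrix() @ seg_t_sum

    # -- exposure ------------------------------------------------------------
    def exposure(self, b: np.ndarray, p: np.ndarray, t_bar: np.ndarray):
        """Growth exposure G and repulsion R for every segment slot.

        ``G = A (w_b B + w_t T̄)`` — chemoaffinity gates the efficacy of
        growth and trophic factors; ``R = (1 - A)(r0 + w_p P)`` — the inverse
        of chemoaffinity gates repulsion.
        """
        prm = self.params
        a = self.seg_affinity
        g = a * (prm.w_b * b + prm.w_t * t_bar)
        r = (1.0 - a) * (prm.repulsion_base + prm.w_p * p)
        return g, r

    # -- export --------------------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        alive = np.flatnonzero(self.seg_alive)
        return pd.DataFrame(
            {
                "segment_id": alive,
                "parent_id": self.seg_parent[alive],
                "rgc_id": self.seg_rgc[alive],
                "x1": self.seg_x1[alive],
                "y1": self.seg_y1[alive],
                "x2": self.seg_x2[alive],
                "y2": self.seg_y2[alive],
                "is_trunk": self.seg_trunk[alive],
            }
        )
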