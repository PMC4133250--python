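"""Multi-rate scenario runner.

Development unfolds in two phases: a molecular phase in which axons grow
under chemoaffinity and constitutively released factors alone, and an
activity phase in which pre-computed retinal-wave spike trains drive the
collicular network, trophic feedback stabilises correlated synapses, and
homeostatic controls regulate firing rates.  A combined variant enables
activity-dependent feedback from the moment interstitial branching begins.

Cadences (simulated time): neural integration at 1 ms (silent stretches are
skipped — all millisecond dynamics decay to exact zero between waves, so the
skip is equivalence-preserving); synapse formation and comparative retraction
every 500 ms; extracellular fields, firing-rate windows and homeostatic
scaling every 1 s; axon growth events and neuron maturation every 60 s.

Every stochastic component draws from its own named stream, so a run is a
pure function of (config, seeds); checkpoints capture the complete dynamic
state plus RNG states and resume bit-identically.
"""

from __future__ import annotations

import json

import numpy as np

from .arbors import ArborSystem
from .config import SimulationConfig
from .fields import FactorGrid
from .geometry import SpatialGrid, build_colliculus, build_retina
from .guidance import apply_scenario, build_profiles
from .kernel import step_window
from .neurons import NeuronPopulation
from .synapses import SynapseSystem
from .waves import SpikeTrain, generate_waves, onoff_spikes, spikes_from_waves

WINDOW_MS = 500

STATE_VERSION = 1


def schedule_tick(t_ms: int) -> set[str]:
    """Update groups due at simulated time ``t_ms`` (a 500 ms boundary)."""
    due = {"synapses"}
    if t_ms % 1000 == 0:
        due |= {"fields", "rates"}
    if t_ms % 60000 == 0:
        due |= {"growth", "size"}
    return due


class Simulation:
    """One scenario run.  Build, then :meth:`run`."""

    def __init__(self, config: SimulationConfig, store=None):
        self.cfg = config
        self.store = store
        cfg = config

        class_scheme = "onoff" if cfg.scenario == "onoff" else "generic"
        layout_seed = cfg.seed_for("layout")
        self.retina = build_retina(
            cfg.n_rgc, eye="L", class_scheme=class_scheme,
            seed=layout_seed, radius_mm=cfg.retina_radius_mm,
        )
        if cfg.binocular:
            # congruent right retina: identical packing, distinct eye label
            self.retina_r = build_retina(
                cfg.n_rgc, eye="R", class_scheme=class_scheme,
                seed=layout_seed, radius_mm=cfg.retina_radius_mm,
            )
            self.n_rgc_total = 2 * cfg.n_rgc
            self.eye_of = np.repeat(np.array([0, 1], dtype=np.int8), cfg.n_rgc)
        else:
            self.retina_r = None
            self.n_rgc_total = cfg.n_rgc
            self.eye_of = np.zeros(cfg.n_rgc, dtype=np.int8)

        self.colliculus = build_colliculus(
            cfg.n_sc, aspect=cfg.aspect, seed=cfg.seed_for("layout").spawn(1)[0]
        )
        self.grid = SpatialGrid(self.colliculus)

        wt = build_profiles(self.retina, self.colliculus, cfg.guidance)
        profiles = apply_scenario(
            wt, cfg.scenario, seed=cfg.seed_for("scenario"),
            ap_length=self.colliculus.ap_length, params=cfg.guidance,
        )
        if cfg.binocular:
            wt_r = build_profiles(self.retina_r, self.colliculus, cfg.guidance)
            profiles = _concat_profiles(profiles, wt_r)
        self.profiles = profiles

        self.arbors = ArborSystem(
            self.colliculus, self.grid, self.profiles, self.n_rgc_total,
            cfg.arbors, cfg.guidance,
        )
        self.arbors.init_trunks(cfg.rng("growth"))
        self._rng_growth = cfg.rng("growth")  # fresh stream for growth events
        self._rng_synapse = cfg.rng("synapses")

        self.neurons = NeuronPopulation(self.colliculus.n_cells, cfg.neurons)
        self.fields = FactorGrid(self.grid, cfg.fields)
        self.synapses = SynapseSystem(
            self.n_rgc_total, self.colliculus.n_cells, cfg.synapses
        )
        self.synapses.count_scale = (
            self.arbors.size_param * cfg.synapses.count_scale_mult
        )

        self.t_ms = 0
        self.total_ms = int(round((cfg.phase1_h + cfg.phase2_h) * 3600 * 1000))
        if cfg.scenario == "activity_block":
            self.act_start_ms = self.total_ms  # never reached
        elif cfg.combined:
            self.act_start_ms = 0
        else:
            self.act_start_ms = int(round(cfg.phase1_h * 3600 * 1000))

        # activity bookkeeping
        self._train: SpikeTrain | None = None
        self._train_offset_ms = 0
        self._sec_counts = np.zeros(self.colliculus.n_cells, dtype=np.int64)
        self._release_mod = np.ones(self.colliculus.n_cells)
        self._csr_dirty = True
        self._fired_cell = np.empty(
            self.colliculus.n_cells * (WINDOW_MS // 2 + 1), dtype=np.int32
        )
        self._fired_ms = np.empty_like(self._fired_cell, dtype=np.int64)
        self._seg_b = np.zeros(0)
        self._seg_p = np.zeros(0)
        self._extra_train_counter = 0
        self.sc_spike_total = 0
        self.snapshots: list[dict] = []
        self._refresh_field_samples()

        if self.store is not None:
            self.store.save_config(cfg)

    # ------------------------------------------------------------------ waves
    def _make_train(self, duration_s: float, correlated: bool | None = None,
                    seed_offset: int = 0) -> SpikeTrain:
        cfg = self.cfg

        def child(ss: np.random.SeedSequence, idx: int) -> np.random.SeedSequence:
            # deterministic idx-th child (spawn(n)[0] is the same child for
            # every n, so distinct streams need distinct spawn keys)
            return np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=ss.spawn_key + (idx,)
            )

        waves_ss = cfg.seed_for("waves")
        spikes_ss = cfg.seed_for("spikes")
        wave_seed = child(waves_ss, seed_offset)
        spike_seed = child(spikes_ss, seed_offset)
        if cfg.binocular:
            if correlated is None:
                correlated = cfg.scenario == "binocular_corr"
            wave_seed_r = (
                wave_seed if correlated else child(waves_ss, seed_offset + 1)
            )
            spike_seed_r = (
                spike_seed if correlated else child(spikes_ss, seed_offset + 1)
            )
            waves_l = generate_waves(self.retina, duration_s, cfg.waves, wave_seed)
            waves_r = generate_waves(self.retina_r, duration_s, cfg.waves, wave_seed_r)
            tl = spikes_from_waves(
                waves_l, cfg.n_rgc, duration_s, cfg.bursts, seed=spike_seed
            )
            tr = spikes_from_waves(
                waves_r, cfg.n_rgc, duration_s, cfg.bursts, seed=spike_seed_r
            )
            return SpikeTrain.from_events(
                np.concatenate([tl.times_ms, tr.times_ms]),
                np.concatenate([tl.cells, tr.cells + cfg.n_rgc]),
                self.n_rgc_total,
                duration_s,
            )
        waves = generate_waves(self.retina, duration_s, cfg.waves, wave_seed)
        if cfg.scenario == "onoff":
            return onoff_spikes(
                waves, self.retina, duration_s, cfg.bursts, seed=spike_seed
            )
        return spikes_from_waves(
            waves, cfg.n_rgc, duration_s, cfg.bursts, seed=spike_seed
        )

    # ------------------------------------------------------------------- CSRs
    def _rebuild_csr(self) -> None:
        syn = self.synapses
        live = np.flatnonzero(syn.alive)
        by_rgc = live[np.argsort(syn.rgc[live], kind="stable")]
        self._pre_indptr = np.searchsorted(
            syn.rgc[by_rgc], np.arange(self.n_rgc_total + 1)
        ).astype(np.int64)
        self._pre_syn = by_rgc.astype(np.int64)
        by_post = live[np.argsort(syn.post[live], kind="stable")]
        self._post_indptr = np.searchsorted(
            syn.post[by_post], np.arange(self.colliculus.n_cells + 1)
        ).astype(np.int64)
        self._post_syn = by_post.astype(np.int64)
        self._csr_dirty = False

    def _refresh_field_samples(self) -> None:
        if len(self.arbors.seg_square):
            self._seg_b, self._seg_p = self.fields.sample_squares(
                self.arbors.seg_square
            )
        else:
            self._seg_b = np.zeros(0)
            self._seg_p = np.zeros(0)

    # -------------------------------------------------------------- main loop
    @property
    def activity_on(self) -> bool:
        return self._train is not None and self.t_ms >= self.act_start_ms

    def run(self, until_ms: int | None = None) -> "Simulation":
        end = self.total_ms if until_ms is None else min(until_ms, self.total_ms)
        while self.t_ms < end:
            if self._train is None and self.t_ms >= self.act_start_ms \
                    and self.act_start_ms < self.total_ms:
                dur_s = (self.total_ms - self.act_start_ms) / 1000.0
                self._train = self._make_train(dur_s)
                self._train_offset_ms = self.act_start_ms
            self._tick()
        if self.store is not None:
            self.store.save_tables(self)
        return self

    def run_extra_activity(self, hours: float, correlated: bool | None = None):
        """Extend the run with a fresh activity period (e.g. switching a
        binocular simulation from independent to synchronised waves)."""
        dur_ms = int(round(hours * 3600 * 1000))
        self._extra_train_counter += 10
        self._train = self._make_train(
            dur_ms / 1000.0, correlated=correlated,
            seed_offset=self._extra_train_counter,
        )
        self._train_offset_ms = self.t_ms
        self.total_ms = self.t_ms + dur_ms
        return self.run()

    def _tick(self) -> None:
        t0 = self.t_ms
        if self.activity_on:
            self._process_window(t0)
        self.t_ms = t0 + WINDOW_MS
        due = schedule_tick(self.t_ms)
        self._synapse_tick()
        if "rates" in due:
            self.neurons.push_second(self._sec_counts)
            self._sec_counts[:] = 0
            if self.activity_on:
                self.neurons.update_homeostasis(1.0)
            self._release_mod = self.neurons.trophic_release_modifier()
        if "fields" in due:
            rel_b, rel_p = self.neurons.release_rates(
                self.cfg.fields.tau_b_s, self.cfg.fields.tau_p_s
            )
            self.fields.deposit_and_decay(rel_b, rel_p, 1.0)
            self._refresh_field_samples()
        if "growth" in due:
            self._growth_tick()
        if "size" in due:
            self.neurons.update_size(60.0)
        snap_ms = int(self.cfg.snapshot_min * 60000)
        if snap_ms > 0 and self.t_ms % snap_ms == 0:
            self._snapshot()

    # -------------------------------------------------- 1 ms window (kernel)
    def _process_window(self, t0: int) -> None:
        train = self._train
        rel0 = t0 - self._train_offset_ms
        lo = np.searchsorted(train.times_ms, rel0)
        hi = np.searchsorted(train.times_ms, rel0 + WINDOW_MS)
        no_events = lo == hi
        if no_events and not (
            np.any(self.neurons.excitation > 1e-12)
            or np.any(self.neurons.syn_input > 1e-12)
            or np.any(self.neurons.refractory > 0)
        ):
            return  # silent window: skipping is exact
        if self._csr_dirty:
            self._rebuild_csr()
        n = self.cfg.neurons
        syn = self.synapses
        n_fired = step_window(
            np.int64(t0),
            np.int64(WINDOW_MS),
            train.times_ms[lo:hi] + np.int64(self._train_offset_ms),
            train.cells[lo:hi],
            self._pre_indptr,
            self._pre_syn,
            self._post_indptr,
            self._post_syn,
            syn.post,
            syn.affinity,
            syn.t_state,
            syn.cleft_pro,
            syn.last_ms,
            self.neurons.excitation,
            self.neurons.syn_input,
            self.neurons.size,
            self.neurons.h,
            self.neurons.refractory,
            self._release_mod,
            n.threshold,
            self.neurons.alpha_m,
            self.neurons.alpha_ampa,
            n.att0,
            n.att1,
            np.int32(n.refractory_ms),
            syn.params.destab_rate,
            syn.params.stab_rate,
            1.0 / syn.params.tau_coinc_ms,
            True,
            self._sec_counts,
            self._fired_cell,
            self._fired_ms,
        )
        if n_fired > len(self._fired_cell):  # pragma: no cover - sized generously
            raise RuntimeError("spike buffer overflow")
        self.sc_spike_total += n_fired
        if self.store is not None and self.store.record_spikes:
            self.store.append_spikes(
                self._fired_cell[:n_fired], self._fired_ms[:n_fired]
            )

    # --------------------------------------------------------- synapse cycle
    def _synapse_tick(self) -> None:
        arb = self.arbors
        syn = self.synapses
        rng = self._rng_synapse
        n_segments = len(arb.seg_rgc)
        if n_segments == 0:
            return
        live = np.flatnonzero(syn.alive)
        seg_of_live = syn.seg[live]
        t_of_live = syn.t_state[live]
        seg_counts = np.bincount(seg_of_live, minlength=n_segments)
        seg_t_sum = np.bincount(
            seg_of_live, weights=t_of_live, minlength=n_segments
        )
        w_mat = arb.weight_matrix()
        t_bar = w_mat @ seg_t_sum

        # formation
        elig = np.flatnonzero(
            arb.seg_alive
            & arb.seg_has_cand
            & (seg_counts < syn.params.max_per_segment)
        )
        if len(elig):
            g = arb.seg_affinity[elig] * (
                arb.params.w_b * self._seg_b[elig]
                + arb.params.w_t * t_bar[elig]
            )
            p_form = syn.formation_probability(g, syn.n_axonal[arb.seg_rgc[elig]])
            hits = elig[rng.random(len(elig)) < p_form]
            if len(hits):
                # batched target draws and acceptance for this cycle's hits
                posts = np.array(
                    [
                        arb.seg_candidates[sid][
                            rng.integers(len(arb.seg_candidates[sid]))
                        ]
                        for sid in hits
                    ],
                    dtype=np.int64,
                )
                rgcs = arb.seg_rgc[hits]
                pair_n = np.array(
                    [
                        syn.pair_count.get((int(r), int(p)), 0)
                        for r, p in zip(rgcs, posts)
                    ]
                )
                p_acc = syn.acceptance_probability(
                    self.neurons.rate[posts], pair_n, syn.n_in[posts],
                    self.cfg.neurons.target_rate,
                )
                accepted = rng.random(len(hits)) < p_acc
                for sid, post in zip(hits[accepted], posts[accepted]):
                    syn.add(int(arb.seg_rgc[sid]), int(sid), int(post),
                            float(arb.seg_affinity[sid]), self.t_ms)
                if accepted.any():
                    self._csr_dirty = True

        # comparative retraction (axonal then dendritic check per cycle);
        # synapses formed in this very tick are not yet part of `live`
        if len(live) == 0:
            return
        neigh_cnt = w_mat @ seg_counts.astype(float)
        denom = neigh_cnt[seg_of_live] - 1.0
        t_bar_local = np.where(
            denom > 0,
            (t_bar[seg_of_live] - t_of_live) / np.maximum(denom, 1e-12),
            t_of_live,
        )
        t_sup = syn.trophic_support_values(live, t_bar_local)

        rgc_of = syn.rgc[live]
        ax_mean = _group_mean(t_sup, rgc_of, self.n_rgc_total)
        p16 = syn.retraction_probability(
            t_sup, ax_mean[rgc_of], syn.n_axonal[rgc_of]
        )
        kill = rng.random(len(live)) < p16
        post_of = syn.post[live]
        den_mean = _group_mean(t_sup, post_of, self.colliculus.n_cells)
        p17 = syn.retraction_probability(
            t_sup, den_mean[post_of], syn.n_in[post_of]
        )
        kill |= (~kill) & (rng.random(len(live)) < p17)
        if kill.any():
            syn.remove(live[kill])
            self._csr_dirty = True

    # ------------------------------------------------------------ growth step
    def _growth_tick(self) -> None:
        arb = self.arbors
        syn = self.synapses
        rng = self._rng_growth
        t_s = self.t_ms / 1000.0
        n_segments = len(arb.seg_rgc)
        if n_segments == 0:
            return
        live_syn = np.flatnonzero(syn.alive)
        seg_t_sum = np.bincount(
            syn.seg[live_syn], weights=syn.t_state[live_syn], minlength=n_segments
        )
        t_bar = arb.trophic_neighbourhood(seg_t_sum)
        g, r = arb.exposure(self._seg_b, self._seg_p, t_bar)

        tips = arb.tips()
        if len(tips):
            p_ext = arb.growth_probability(
                arb.params.extension_rate, g[tips], r[tips],
                arb.n_seg[arb.seg_rgc[tips]],
            )
            for sid in tips[rng.random(len(tips)) < p_ext]:
                arb.try_extend(int(sid), t_s, rng)
        branchable = arb.branchable()
        if len(branchable):
            p_br = arb.growth_probability(
                arb.params.branch_rate, g[branchable], r[branchable],
                arb.n_seg[arb.seg_rgc[branchable]],
            )
            for sid in branchable[rng.random(len(branchable)) < p_br]:
                arb.try_branch(int(sid), t_s, rng)
        # retraction only at tips (trunk permanent); recompute exposure since
        # extensions and branches just changed the segment set
        self._refresh_field_samples()
        n_now = len(arb.seg_rgc)
        if n_now > len(seg_t_sum):
            seg_t_sum = np.pad(seg_t_sum, (0, n_now - len(seg_t_sum)))
        t_bar = arb.trophic_neighbourhood(seg_t_sum)
        _, r_now = arb.exposure(self._seg_b, self._seg_p, t_bar)
        tips = arb.tips()
        tips = tips[~arb.seg_trunk[tips]]
        if len(tips):
            p_ret = arb.retraction_probability(
                arb.params.retraction_rate, r_now[tips]
            )
            for sid in tips[rng.random(len(tips)) < p_ret]:
                on_tip = np.flatnonzero(syn.alive & (syn.seg == sid))
                if len(on_tip):
                    syn.remove(on_tip)
                arb.retract_tip(int(sid))
                self._csr_dirty = True

    # -------------------------------------------------------------- snapshots
    def _snapshot(self) -> None:
        from .metrics import projection_map, summary_metrics

        pm = projection_map(self)
        snap = {"t_h": self.t_ms / 3.6e6, **summary_metrics(self, pm)}
        self.snapshots.append(snap)
        if self.store is not None:
            self.store.append_metrics(snap)

    # ------------------------------------------------------------ checkpoints
    def state_dict(self) -> dict:
        arb, syn, neu = self.arbors, self.synapses, self.neurons
        cand_ptr = np.cumsum([0] + [len(c) for c in arb.seg_candidates])
        growth_times = [t for q in arb._recent_growth for t in q]
        growth_ptr = np.cumsum([0] + [len(q) for q in arb._recent_growth])
        return {
            "version": np.int64(STATE_VERSION),
            "t_ms": np.int64(self.t_ms),
            "total_ms": np.int64(self.total_ms),
            "act_start_ms": np.int64(self.act_start_ms),
            "extra_counter": np.int64(self._extra_train_counter),
            "train_offset": np.int64(self._train_offset_ms),
            "sc_spike_total": np.int64(self.sc_spike_total),
            "sec_counts": self._sec_counts,
            "release_mod": self._release_mod,
            # arbors
            "seg_rgc": arb.seg_rgc, "seg_parent": arb.seg_parent,
            "seg_child_ext": arb.seg_child_ext,
            "seg_child_branch": arb.seg_child_branch,
            "seg_x1": arb.seg_x1, "seg_y1": arb.seg_y1,
            "seg_x2": arb.seg_x2, "seg_y2": arb.seg_y2,
            "seg_heading": arb.seg_heading, "seg_alive": arb.seg_alive,
            "seg_trunk": arb.seg_trunk, "seg_affinity": arb.seg_affinity,
            "seg_square": arb.seg_square,
            "cand_flat": (np.concatenate(arb.seg_candidates)
                          if arb.seg_candidates else np.empty(0, np.int64)),
            "cand_ptr": cand_ptr,
            "roots": arb.roots, "n_seg": arb.n_seg,
            "growth_times": np.asarray(growth_times, dtype=float),
            "growth_ptr": growth_ptr,
            "growth_log": np.asarray(arb.growth_log, dtype=float).reshape(-1, 2),
            # synapses
            "syn_rgc": syn.rgc, "syn_seg": syn.seg, "syn_post": syn.post,
            "syn_t": syn.t_state, "syn_cleft": syn.cleft_pro,
            "syn_cleft_nt": syn.cleft_nt,
            "syn_last": syn.last_ms, "syn_aff": syn.affinity,
            "syn_alive": syn.alive, "syn_created": syn.created_ms,
            # neurons
            "n_size": neu.size, "n_exc": neu.excitation, "n_inp": neu.syn_input,
            "n_h": neu.h, "n_refr": neu.refractory, "n_rate": neu.rate,
            "ring": neu._ring, "ring_pos": np.int64(neu._ring_pos),
            "ring_filled": np.int64(neu._ring_filled), "ring_sum": neu._ring_sum,
            # fields
            "field_b": self.fields.b, "field_p": self.fields.p,
            # rngs
            "rng_growth": np.frombuffer(
                json.dumps(self._rng_growth.bit_generator.state).encode(), np.uint8
            ),
            "rng_synapse": np.frombuffer(
                json.dumps(self._rng_synapse.bit_generator.state).encode(), np.uint8
            ),
        }

    def load_state(self, st: dict) -> None:
        if int(st["version"]) != STATE_VERSION:
            raise ValueError(
                f"checkpoint schema version {int(st['version'])} does not match "
                f"this code's version {STATE_VERSION}"
            )
        arb, syn, neu = self.arbors, self.synapses, self.neurons
        self.t_ms = int(st["t_ms"])
        self.total_ms = int(st["total_ms"])
        self.act_start_ms = int(st["act_start_ms"])
        self._extra_train_counter = int(st["extra_counter"])
        self._train_offset_ms = int(st["train_offset"])
        self.sc_spike_total = int(st["sc_spike_total"])
        self._sec_counts = st["sec_counts"].copy()
        self._release_mod = st["release_mod"].copy()
        for name in ("rgc", "parent", "child_ext", "child_branch", "x1", "y1",
                     "x2", "y2", "heading", "alive", "trunk", "affinity",
                     "square"):
            setattr(arb, f"seg_{name}", st[f"seg_{name}"].copy())
        ptr = st["cand_ptr"]
        flat = st["cand_flat"]
        arb.seg_candidates = [
            flat[ptr[i]: ptr[i + 1]].astype(np.int64) for i in range(len(ptr) - 1)
        ]
        arb.seg_has_cand = np.diff(ptr).astype(np.int64) > 0
        arb.roots = st["roots"].copy()
        arb.n_seg = st["n_seg"].copy()
        from collections import deque

        gptr = st["growth_ptr"]
        gt = st["growth_times"]
        arb._recent_growth = [
            deque(gt[gptr[i]: gptr[i + 1]].tolist()) for i in range(len(gptr) - 1)
        ]
        arb.growth_log = [tuple(row) for row in st["growth_log"]]
        arb._arbor_triplets = {}
        arb._dirty = set(range(arb.n_rgc))
        arb._w_matrix = None
        syn.set_state(
            {
                "rgc": st["syn_rgc"], "seg": st["syn_seg"],
                "post": st["syn_post"], "t_state": st["syn_t"],
                "cleft_pro": st["syn_cleft"], "cleft_nt": st["syn_cleft_nt"],
                "last_ms": st["syn_last"], "affinity": st["syn_aff"],
                "alive": st["syn_alive"], "created_ms": st["syn_created"],
            }
        )
        neu.size = st["n_size"].copy()
        neu.excitation = st["n_exc"].copy()
        neu.syn_input = st["n_inp"].copy()
        neu.h = st["n_h"].copy()
        neu.refractory = st["n_refr"].copy()
        neu.rate = st["n_rate"].copy()
        neu._ring = st["ring"].copy()
        neu._ring_pos = int(st["ring_pos"])
        neu._ring_filled = int(st["ring_filled"])
        neu._ring_sum = st["ring_sum"].copy()
        self.fields.b = st["field_b"].copy()
        self.fields.p = st["field_p"].copy()
        self._rng_growth.bit_generator.state = json.loads(
            st["rng_growth"].tobytes().decode()
        )
        self._rng_synapse.bit_generator.state = json.loads(
            st["rng_synapse"].tobytes().decode()
        )
        # regenerate the pre-computed activity for the remaining period
        self._train = None
        if self.act_start_ms < self.total_ms and self.t_ms >= self.act_start_ms:
            if self._extra_train_counter:
                dur_s = (self.total_ms - self._train_offset_ms) / 1000.0
                self._train = self._make_train(
                    dur_s, seed_offset=self._extra_train_counter
                )
            else:
                dur_s = (self.total_ms - self.act_start_ms) / 1000.0
                self._train = self._make_train(dur_s)
        self._csr_dirty = True
        self._refresh_field_samples()


def _group_mean(values, groups, n_groups):
    s = np.bincount(groups, weights=values, minlength=n_groups)
    c = np.bincount(groups, minlength=n_groups)
    return s / np.maximum(c, 1)


def _concat_profiles(a, b):
    from .guidance import GuidanceProfiles

    return GuidanceProfiles(
        np.vstack([a.tz, b.tz]),
        np.concatenate([a.specificity, b.specificity]),
        np.concatenate([a.gamma_lm, b.gamma_lm]),
        np.concatenate([a.gamma_ap, b.gamma_ap]),
        np.concatenate([a.altered, b.altered]),
    )


def run_scenario(config: SimulationConfig, store=None) -> Simulation:
    """Build and run one scenario to completion."""
    return Simulation(config, store=store).run()


def run_fixed_network(
    config: SimulationConfig,
    hours: float,
    synapses_per_cell: int = 12,
    seed_offset: int = 0,
) -> tuple[np.ndarray, "Simulation"]:
    """Closed-loop homeostasis benchmark on a frozen, retinotopic network.

    Builds the layouts, wires every collicular neuron to ``synapses_per_cell``
    RGCs whose termination zones lie nearest to it (a stand-in for a refined
    innervation), disables all structural plasticity, and drives the network
    with wave input for ``hours`` simulated hours with homeostatic synaptic
    scaling active.  Returns the per-hour population mean firing rate (spike
    counts over each hour) and the simulation object.
    """
    from scipy.spatial import cKDTree

    sim = Simulation(config)
    # frozen innervation: nearest TZs, capped per-pair by the acceptance rule
    tree = cKDTree(sim.profiles.tz)
    _, nearest = tree.query(sim.colliculus.xy, k=synapses_per_cell)
    rng = np.random.default_rng(config.seed_for("synapses").spawn(7)[0])
    mid = sim.arbors.roots  # attach to each RGC's trunk root segment
    for post in range(sim.colliculus.n_cells):
        for rgc in np.atleast_1d(nearest[post]):
            sid = int(mid[rgc])
            sim.synapses.add(
                int(rgc), sid, int(post), float(sim.arbors.seg_affinity[sid]), 0
            )
    sim._csr_dirty = True
    # activity from t = 0, structural dynamics off
    sim.act_start_ms = 0
    sim.total_ms = int(hours * 3600 * 1000)
    sim._train = sim._make_train(hours * 3600.0, seed_offset=seed_offset)
    sim._train_offset_ms = 0
    hourly = []
    prev = 0
    for h in range(int(np.ceil(hours))):
        end = min(int((h + 1) * 3600 * 1000), sim.total_ms)
        while sim.t_ms < end:
            t0 = sim.t_ms
            sim._process_window(t0)
            sim.t_ms = t0 + WINDOW_MS
            if sim.t_ms % 1000 == 0:
                sim.neurons.push_second(sim._sec_counts)
                sim._sec_counts[:] = 0
                sim.neurons.update_homeostasis(1.0)
                sim._release_mod = sim.neurons.trophic_release_modifier()
            if sim.t_ms % 60000 == 0:
                sim.neurons.update_size(60.0)
        hourly.append((sim.sc_spike_total - prev) / sim.colliculus.n_cells / 3600.0)
        prev = sim.sc_spike_total
    return np.asarray(hourly), sim


def resume(store) -> Simulation:
    """Reconstruct a simulation from the latest checkpoint in ``store`` and
    continue it to completion; the trajectory is identical to an
    uninterrupted run with the same config and seeds."""
    cfg = store.load_config()
    sim = Simulation(cfg)
    sim.store = store
    sim.load_state(store.load_checkpoint())
    return sim.run()
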