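"""Axon arbor trees: trunks, growth/retraction rules, budgets, trophic sums."""

import numpy as np
import pytest

from retmap import build_colliculus, build_retina, build_profiles, SpatialGrid
from retmap.arbors import _NONE, ArborSystem
from retmap.config import ArborParams


@pytest.fixture()
def system(retina, colliculus, grid):
    profiles = build_profiles(retina, colliculus)
    sys = ArborSystem(colliculus, grid, profiles, 40)
    sys.init_trunks(np.random.default_rng(0))
    return sys


@pytest.fixture()
def zero_jitter_system(retina, colliculus, grid):
    profiles = build_profiles(retina, colliculus)
    params = ArborParams(lm_jitter_sd=0.0)
    sys = ArborSystem(colliculus, grid, profiles, 30, params)
    sys.init_trunks(np.random.default_rng(0))
    return sys


class TestTrunks:
    def test_trunks_span_ap_extent(self, system, colliculus):
        for i in range(system.n_rgc):
            segs = np.flatnonzero(system.seg_trunk & (system.seg_rgc == i))
            assert system.seg_x1[segs].min() < 0.05 * colliculus.ap_length
            assert system.seg_x2[segs].max() > 0.9 * colliculus.ap_length

    def test_segment_lengths_11um(self, system):
        L = np.hypot(
            system.seg_x2 - system.seg_x1, system.seg_y2 - system.seg_y1
        )
        # trunk segments are chords of the curved trajectory; the handful of
        # chords at the steeply tapered posterior end are within 0.5%
        np.testing.assert_allclose(L, 11.0, rtol=5e-3)

    def test_zero_jitter_trunk_passes_through_tz(self, zero_jitter_system):
        sys = zero_jitter_system
        for i in range(sys.n_rgc):
            tzx, tzy = sys.profiles.tz[i]
            segs = np.flatnonzero(sys.seg_trunk & (sys.seg_rgc == i))
            # trunk ML position at the AP position closest to the TZ
            k = np.argmin(np.abs((sys.seg_x1[segs] + sys.seg_x2[segs]) / 2 - tzx))
            y = (sys.seg_y1[segs[k]] + sys.seg_y2[segs[k]]) / 2
            assert abs(y - tzy) < 12.0

    def test_entry_offset_sd_matches_config(self, retina, colliculus, grid):
        profiles = build_profiles(retina, colliculus)
        params = ArborParams(lm_jitter_sd=0.1)
        sys = ArborSystem(colliculus, grid, profiles, 1000, params)
        sys.init_trunks(np.random.default_rng(1))
        offsets = []
        for i in range(sys.n_rgc):
            root = sys.roots[i]
            tzx, tzy = sys.profiles.tz[i]
            hw_tz = float(colliculus.half_width(tzx))
            rel_actual = sys.seg_y1[root] / float(
                colliculus.half_width(sys.seg_x1[root])
            )
            offsets.append(rel_actual * hw_tz - tzy)
        sd = np.std(offsets)
        expected = 0.1 * colliculus.ml_width
        # clipping at the outline trims the tails a little
        assert 0.6 * expected < sd <= 1.1 * expected

    def test_n_seg_excludes_trunk(self, system):
        assert np.all(system.n_seg == 0)
        assert system.seg_trunk.all()


class TestGrowthEvents:
    @staticmethod
    def _interior_tip(system, rng):
        """Create a tip pointing into the domain by branching mid-trunk."""
        for sid in system.branchable():
            new = system.try_branch(int(sid), 0.0, rng)
            if new != _NONE:
                return new
        pytest.fail("could not create an interior branch")

    def test_extension_continues_heading(self, system, rng):
        tip = self._interior_tip(system, rng)
        new = system.try_extend(tip, 60.0, rng)
        assert new != _NONE
        dh = (system.seg_heading[new] - system.seg_heading[tip] + np.pi) % (
            2 * np.pi
        ) - np.pi
        assert abs(dh) < np.deg2rad(60)
        assert system.seg_child_ext[tip] == new
        assert not system.seg_trunk[new]

    def test_branch_orthogonal(self, system, rng):
        parent = int(system.branchable()[5])
        new = system.try_branch(parent, 60.0, rng)
        if new == _NONE:  # geometry rejection possible at the rim
            pytest.skip("branch left the domain")
        dh = (system.seg_heading[new] - system.seg_heading[parent]) % (2 * np.pi)
        assert min(abs(dh - np.pi / 2), abs(dh - 3 * np.pi / 2)) < 1e-9

    def test_extension_requires_tip(self, system, rng):
        interior = int(np.flatnonzero(system.seg_child_ext != _NONE)[0])
        with pytest.raises(ValueError):
            system.try_extend(interior, 60.0, rng)

    def test_retraction_requires_tip_and_spares_trunk(self, system, rng):
        interior = int(np.flatnonzero(system.seg_child_ext != _NONE)[0])
        with pytest.raises(ValueError):
            system.retract_tip(interior)
        trunk_tip = int(system.tips()[0])
        with pytest.raises(ValueError):
            system.retract_tip(trunk_tip)

    def test_retraction_restores_parent_as_tip(self, system, rng):
        tip = self._interior_tip(system, rng)
        new = system.try_extend(tip, 60.0, rng)
        assert new != _NONE
        assert not system.is_tip(tip)
        system.retract_tip(new)
        assert system.is_tip(tip)

    def test_growth_budget_enforced_under_saturation(self, system, rng):
        """With growth signals at maximum, no RGC ever adds more than 5
        segments in any sliding 10-minute window."""
        t = 0.0
        for _ in range(120):  # 2 simulated hours of growth checks
            t += 60.0
            tips = system.tips()
            for sid in tips[:200]:
                system.try_extend(int(sid), t, rng)
            branchable = system.branchable()
            for sid in branchable[:200]:
                system.try_branch(int(sid), t, rng)
        times = np.array([tt for tt, _ in system.growth_log])
        rgcs = np.array([r for _, r in system.growth_log])
        for i in np.unique(rgcs):
            ts = np.sort(times[rgcs == i])
            for k, t0 in enumerate(ts):
                assert ((ts > t0 - 600.0) & (ts <= t0)).sum() <= 5

    def test_probability_shapes(self, system):
        p = system.growth_probability(0.5, np.array([1.0]), np.array([0.0]),
                                      np.array([0]))
        assert 0 < p[0] <= 1
        # saturating repulsion kills growth
        p0 = system.growth_probability(0.5, np.array([0.0]), np.array([5.0]),
                                       np.array([0]))
        assert p0[0] == 0.0
        # large arbors grow more slowly at equal exposure
        p_small = system.growth_probability(0.5, np.array([1.0]),
                                            np.array([0.0]), np.array([0]))
        p_large = system.growth_probability(0.5, np.array([1.0]),
                                            np.array([0.0]),
                                            np.array([3 * system.size_param]))
        assert p_large[0] < p_small[0] / 10

    def test_far_tip_retracts_more_often(self, system, rng):
        """Paired comparison: retraction probability at saturating repulsion
        exceeds that at zero repulsion."""
        p_near = system.retraction_probability(0.5, np.array([0.0]))
        p_far = system.retraction_probability(0.5, np.array([1.0]))
        assert p_far[0] > p_near[0]
        assert p_near[0] == 0.0


class TestTreeIntegrity:
    def test_random_event_stream_preserves_structure(self, system, rng):
        """Fuzz: random valid extend/branch/retract sequences keep the forest
        acyclic, connected, 11 µm-per-segment and within child limits."""
        t = 0.0
        for step in range(300):
            t += 60.0
            choice = rng.integers(3)
            if choice == 0:
                tips = system.tips()
                if len(tips):
                    system.try_extend(int(rng.choice(tips)), t, rng)
            elif choice == 1:
                br = system.branchable()
                if len(br):
                    system.try_branch(int(rng.choice(br)), t, rng)
            else:
                tips = system.tips()
                tips = tips[~system.seg_trunk[tips]]
                if len(tips):
                    system.retract_tip(int(rng.choice(tips)))
        alive = np.flatnonzero(system.seg_alive)
        # child pointers are mutual and alive
        for sid in alive:
            for child in (system.seg_child_ext[sid], system.seg_child_branch[sid]):
                if child != _NONE:
                    assert system.seg_alive[child]
                    assert system.seg_parent[child] == sid
        # every alive segment reaches its root without cycles
        for sid in alive[:: max(1, len(alive) // 100)]:
            seen = set()
            cur = sid
            while system.seg_parent[cur] != _NONE:
                assert cur not in seen
                seen.add(cur)
                cur = system.seg_parent[cur]
            assert cur == system.roots[system.seg_rgc[sid]]
        # n_seg bookkeeping consistent
        for i in range(system.n_rgc):
            live = system.seg_alive & (system.seg_rgc == i) & ~system.seg_trunk
            assert system.n_seg[i] == live.sum()


class TestTrophicNeighbourhood:
    def test_matches_bruteforce_on_random_trees(self, system, rng):
        """W @ segT equals a brute-force hop-distance-weighted sum."""
        for _ in range(60):  # grow a few extra segments
            tips = system.tips()
            system.try_extend(int(rng.choice(tips)), 1e9, rng)
        n = len(system.seg_rgc)
        seg_t = rng.random(n) * system.seg_alive
        got = system.trophic_neighbourhood(seg_t)
        lam = system.params.lambda_hop
        # brute force over a sample of segments
        for sid in rng.choice(np.flatnonzero(system.seg_alive), 30):
            # BFS over the whole arbor
            rgc = system.seg_rgc[sid]
            segs = np.flatnonzero(system.seg_alive & (system.seg_rgc == rgc))
            adj = {int(s): [] for s in segs}
            for s in segs:
                pa = system.seg_parent[s]
                if pa != _NONE and system.seg_alive[pa]:
                    adj[int(s)].append(int(pa))
                    adj[int(pa)].append(int(s))
            from collections import deque

            dist = {int(sid): 0}
            q = deque([int(sid)])
            while q:
                u = q.popleft()
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        q.append(v)
            expected = sum(lam ** d * seg_t[s] for s, d in dist.items())
            assert got[sid] == pytest.approx(expected, rel=1e-9)

    def test_no_synapses_zero_neighbourhood(self, system):
        n = len(system.seg_rgc)
        assert np.all(system.trophic_neighbourhood(np.zeros(n)) == 0.0)
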