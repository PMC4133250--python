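"""Outcome metrics: termination zones, retinotopic order, ectopic counts,
ocular dominance and ON/OFF segregation.

All metrics are pure functions of the persisted synapse table plus the
static layouts, so any checkpoint can be re-analysed offline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats


# ---------------------------------------------------------------------------
# Termination zones and projection maps

def termination_zone(xy: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Synapse-weighted centroid, RMS spread and a bimodality flag for one
    RGC's synapse positions.

    The flag is raised when a two-cluster split along the principal axis
    separates the synapses by more than three times the mean within-cluster
    spread — the signature of a genuinely dual (ectopic) arborisation rather
    than a broad single one.
    """
    xy = np.atleast_2d(xy)
    if len(xy) == 0:
        raise ValueError("termination zone of a disconnected RGC is undefined")
    centroid = xy.mean(axis=0)
    spread = float(np.sqrt(((xy - centroid) ** 2).sum(axis=1).mean()))
    bimodal = False
    if len(xy) >= 8:
        centred = xy - centroid
        # principal axis
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        proj = centred @ vt[0]
        order = np.argsort(proj)
        best = 0.0
        lo = max(3, len(xy) // 4)  # both clusters must be substantial
        for cut in range(lo, len(xy) - lo + 1):
            a, b = proj[order[:cut]], proj[order[cut:]]
            sep = b.mean() - a.mean()
            within = (len(a) * a.std() + len(b) * b.std()) / len(xy)
            best = max(best, sep / max(within, 1e-9))
        # a single Gaussian cluster peaks near 2.7 on this score
        bimodal = best > 3.5
    return centroid, spread, bimodal


def projection_map(sim) -> pd.DataFrame:
    """Per-RGC summary: TZ estimate, spread, synapse count, TZ error."""
    syn = sim.synapses
    arb = sim.arbors
    live = np.flatnonzero(syn.alive)
    mid_x = (arb.seg_x1 + arb.seg_x2) / 2.0
    mid_y = (arb.seg_y1 + arb.seg_y2) / 2.0
    sx, sy = mid_x[syn.seg[live]], mid_y[syn.seg[live]]
    rgc = syn.rgc[live]
    rows = []
    for i in range(sim.n_rgc_total):
        mask = rgc == i
        n = int(mask.sum())
        tz_true = sim.profiles.tz[i]
        if n == 0:
            rows.append((i, np.nan, np.nan, np.nan, 0, np.nan, False))
            continue
        xy = np.column_stack([sx[mask], sy[mask]])
        c, spread, bimodal = termination_zone(xy)
        err = float(np.hypot(c[0] - tz_true[0], c[1] - tz_true[1]))
        rows.append((i, c[0], c[1], spread, n, err, bimodal))
    df = pd.DataFrame(
        rows,
        columns=["rgc_id", "tz_x", "tz_y", "spread", "n_syn", "tz_error",
                 "bimodal"],
    )
    retina_xy = (
        np.vstack([sim.retina.xy, sim.retina_r.xy])
        if sim.retina_r is not None
        else sim.retina.xy
    )
    df["nt"] = retina_xy[:, 0]
    df["dv"] = retina_xy[:, 1]
    df["eye"] = sim.eye_of
    df["altered"] = sim.profiles.altered
    return df


def summary_metrics(sim, pm: pd.DataFrame | None = None) -> dict[str, float]:
    if pm is None:
        pm = projection_map(sim)
    ok = pm["n_syn"] > 0
    lin = retinotopic_linearity(pm)
    return {
        "n_synapses": int(sim.synapses.n_alive),
        "n_segments": int(sim.arbors.seg_alive.sum()),
        "frac_connected": float(ok.mean()),
        "median_tz_error": float(pm.loc[ok, "tz_error"].median()) if ok.any() else np.nan,
        "mean_spread": float(pm.loc[ok, "spread"].mean()) if ok.any() else np.nan,
        "linearity_ap": lin["ap"],
        "linearity_ml": lin["ml"],
        "mean_sc_rate": float(sim.neurons.rate.mean()),
    }


# ---------------------------------------------------------------------------
# Retinotopic order

def retinotopic_linearity(pm: pd.DataFrame, min_connected: int = 10) -> dict:
    """Rank correlation of retinal position with TZ position per axis.

    NT should map to AP (temporal anterior, hence negative NT/AP rank
    correlation is reported as its magnitude) and DV to ML.
    """
    ok = pm["n_syn"] > 0
    if ok.sum() < min_connected:
        raise ValueError("too few connected RGCs for a linearity estimate")
    sub = pm[ok]
    r_ap = sstats.spearmanr(sub["nt"], sub["tz_x"]).statistic
    r_ml = sstats.spearmanr(sub["dv"], sub["tz_y"]).statistic
    # NT -> AP is orientation-reversing by convention (temporal -> anterior)
    return {"ap": float(-r_ap), "ml": float(r_ml)}


# ---------------------------------------------------------------------------
# Ectopic projections

def ectopic_count(
    pm: pd.DataFrame,
    ap_length: float,
    n_bands: int = 7,
    n_locations: int = 4,
    per_location: int = 3,
    threshold_frac: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Disrupted-projection counts in ``n_bands`` DV bands × ``n_locations``
    NT locations (up to ``n_bands × per_location × n_locations / n_bands``…
    i.e. 12 marked axons per band with the defaults).

    A marked axon counts as disrupted when its TZ estimate is displaced from
    the retinotopically correct TZ by more than ``threshold_frac`` of the
    collicular length, or when its arborisation is flagged bimodal.
    """
    rng = np.random.default_rng(seed)
    ok = pm[pm["n_syn"] > 0]
    band_edges = np.linspace(-1, 1, n_bands + 1)
    loc_edges = np.linspace(-1, 1, n_locations + 1)
    rows = []
    for b in range(n_bands):
        in_band = ok[(ok["dv"] >= band_edges[b]) & (ok["dv"] < band_edges[b + 1])]
        marked_total, disrupted = 0, 0
        for l in range(n_locations):
            cell = in_band[
                (in_band["nt"] >= loc_edges[l]) & (in_band["nt"] < loc_edges[l + 1])
            ]
            take = min(per_location, len(cell))
            if take == 0:
                continue
            pick = cell.iloc[rng.permutation(len(cell))[:take]]
            marked_total += take
            disp = pick["tz_error"] > threshold_frac * ap_length
            disrupted += int((disp | pick["bimodal"]).sum())
        rows.append((b, marked_total, disrupted))
    return pd.DataFrame(rows, columns=["band", "n_marked", "n_disrupted"])


# ---------------------------------------------------------------------------
# Ocular dominance / class segregation

def ocular_dominance(sim) -> pd.DataFrame:
    """Per collicular cell: left-eye share of its synaptic input."""
    if sim.retina_r is None:
        raise ValueError("ocular dominance requires a binocular run")
    syn = sim.synapses
    live = np.flatnonzero(syn.alive)
    eye = sim.eye_of[syn.rgc[live]]
    post = syn.post[live]
    n_cells = sim.colliculus.n_cells
    left = np.bincount(post[eye == 0], minlength=n_cells)
    right = np.bincount(post[eye == 1], minlength=n_cells)
    total = left + right
    with np.errstate(invalid="ignore"):
        od = np.where(total > 0, left / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {"cell_id": np.arange(n_cells), "n_left": left, "n_right": right,
         "od": od}
    )


def class_dominance(sim) -> pd.DataFrame:
    """Per collicular cell: ON share of its synaptic input (ON/OFF runs)."""
    from .geometry import CLASS_ON

    syn = sim.synapses
    live = np.flatnonzero(syn.alive)
    classes = sim.retina.cell_class[syn.rgc[live]]
    post = syn.post[live]
    n_cells = sim.colliculus.n_cells
    on = np.bincount(post[classes == CLASS_ON], minlength=n_cells)
    total = np.bincount(post, minlength=n_cells)
    od = np.where(total > 0, on / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {"cell_id": np.arange(n_cells), "n_on": on, "n_total": total, "od": od}
    )


def od_histogram(od: np.ndarray, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Unit-area histogram of per-cell dominance ratios."""
    od = od[np.isfinite(od)]
    hist, edges = np.histogram(od, bins=bins, range=(0, 1), density=True)
    return hist, edges


def dip_statistic(x: np.ndarray) -> float:
    """Hartigan-style dip: largest deviation of the empirical CDF from the
    closest unimodal (single-peaked density) CDF, computed by the greatest
    convex minorant / least concave majorant construction."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 4 or x[0] == x[-1]:
        return 0.0
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    best = 0.0
    # candidate modal interval endpoints: scan all split points of the sorted
    # sample; left part fitted by its convex minorant, right by its concave
    # majorant (sufficient for the modest sample sizes used here)
    gcm = _greatest_convex_minorant(x, ecdf_hi)
    lcm = _least_concave_majorant(x, ecdf_lo)
    for split in range(n):
        lo_dev = np.max(np.abs(gcm[: split + 1] - ecdf_hi[: split + 1])) if split >= 0 else 0
        hi_dev = np.max(np.abs(lcm[split:] - ecdf_lo[split:]))
        dev = max(lo_dev, hi_dev)
        if split == 0 or dev < best:
            best = dev
    return float(best / 2.0)


def _greatest_convex_minorant(x, y):
    # lower convex hull of (x, y), evaluated at x
    hull = [0]
    for i in range(1, len(x)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            if (y[i2] - y[i1]) * (x[i] - x[i2]) >= (y[i] - y[i2]) * (x[i2] - x[i1]):
                hull.pop()
            else:
                break
        hull.append(i)
    out = np.empty_like(y)
    for a, b in zip(hull[:-1], hull[1:]):
        t = (x[a:b + 1] - x[a]) / max(x[b] - x[a], 1e-300)
        out[a:b + 1] = y[a] + t * (y[b] - y[a])
    out[hull[-1]] = y[hull[-1]]
    return out


def _least_concave_majorant(x, y):
    return -_greatest_convex_minorant(x, -y)


def dip_test(x: np.ndarray, n_boot: int = 200, seed: int = 0) -> tuple[float, float]:
    """Dip statistic plus bootstrap p-value against the uniform null."""
    rng = np.random.default_rng(seed)
    d = dip_statistic(x)
    n = len(x)
    null = np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])
    p = float((null >= d).mean())
    return d, p


def od_dip_test(
    n_a: np.ndarray,
    n_b: np.ndarray,
    min_total: int = 6,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Dip statistic of the dominance distribution against a count-aware null.

    Per-cell dominance ratios built from small synapse counts are discrete,
    which inflates the dip against a continuous null.  Here the null is the
    unsegregated model: each cell's class-A count is Binomial(N_cell, p̂)
    with the pooled class fraction p̂, so the reported p-value measures
    multimodality beyond counting noise.
    """
    n_a = np.asarray(n_a, dtype=int)
    n_b = np.asarray(n_b, dtype=int)
    tot = n_a + n_b
    keep = tot >= min_total
    n_a, tot = n_a[keep], tot[keep]
    if len(tot) < 10:
        raise ValueError("too few innervated cells")
    p_hat = n_a.sum() / tot.sum()
    d_obs = dip_statistic(n_a / tot)
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    for i in range(n_boot):
        sim_a = rng.binomial(tot, p_hat)
        null[i] = dip_statistic(sim_a / tot)
    return d_obs, float((null >= d_obs).mean())


def od_overdispersion(n_a: np.ndarray, n_b: np.ndarray, min_total: int = 6) -> float:
    """Variance of per-cell dominance ratios relative to the binomial
    (unsegregated) expectation; > 1 indicates class-selective innervation."""
    n_a = np.asarray(n_a, dtype=float)
    tot = n_a + np.asarray(n_b, dtype=float)
    keep = tot >= min_total
    n_a, tot = n_a[keep], tot[keep]
    if len(tot) < 10:
        raise ValueError("too few innervated cells")
    p_hat = n_a.sum() / tot.sum()
    od = n_a / tot
    return float(np.var(od) / np.mean(p_hat * (1 - p_hat) / tot))


def od_overdispersion_test(
    n_a: np.ndarray,
    n_b: np.ndarray,
    min_total: int = 6,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Overdispersion ratio plus its one-sided bootstrap p-value under the
    unsegregated binomial null (class labels i.i.d. per synapse)."""
    n_a = np.asarray(n_a, dtype=int)
    tot = n_a + np.asarray(n_b, dtype=int)
    keep = tot >= min_total
    n_a, tot = n_a[keep], tot[keep]
    if len(tot) < 10:
        raise ValueError("too few innervated cells")
    p_hat = n_a.sum() / tot.sum()

    def ratio(a):
        od = a / tot
        return np.var(od) / np.mean(p_hat * (1 - p_hat) / tot)

    obs = ratio(n_a)
    rng = np.random.default_rng(seed)
    null = np.array([ratio(rng.binomial(tot, p_hat)) for _ in range(n_boot)])
    return float(obs), float((null >= obs).mean())


def bimodality_mass(od: np.ndarray, margin: float = 0.25) -> float:
    """Fraction of innervated cells dominated by one input class
    (dominance ratio outside [margin, 1-margin])."""
    od = od[np.isfinite(od)]
    if len(od) == 0:
        return float("nan")
    return float(np.mean((od < margin) | (od > 1.0 - margin)))


# ---------------------------------------------------------------------------
# Spatial segregation

def spatial_segregation_score(
    xy: np.ndarray,
    od: np.ndarray,
    k: int = 8,
    n_perm: int = 0,
    seed: int = 0,
):
    """Moran's I of thresholded dominance over the collicular lattice.

    Dominance ratios are binarised at 0.5 (+1 / -1); weights are the
    k-nearest-neighbour graph.  High positive scores mean banded (spatially
    organised) segregation, ~0 salt-and-pepper.  With ``n_perm`` > 0 a
    permutation null envelope is returned as (score, null_scores).
    """
    from scipy.spatial import cKDTree

    ok = np.isfinite(od)
    xy, od = xy[ok], od[ok]
    n = len(od)
    if n < k + 1:
        raise ValueError("too few innervated cells")
    z = np.where(od > 0.5, 1.0, -1.0)
    z = z - z.mean()
    tree = cKDTree(xy)
    _, idx = tree.query(xy, k=k + 1)
    neigh = idx[:, 1:]
    w_sum = n * k
    num = float((z[:, None] * z[neigh]).sum())
    den = float((z**2).sum())
    score = (n / w_sum) * num / den if den > 0 else 0.0
    if n_perm <= 0:
        return score
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        zp = rng.permutation(z)
        null[i] = (n / w_sum) * float((zp[:, None] * zp[neigh]).sum()) / den
    return score, null


# ---------------------------------------------------------------------------
# Dual maps (EphA knock-in)

def dual_map_split(pm: pd.DataFrame, wt_pm: pd.DataFrame | None = None) -> dict:
    """Per-subset retinotopic linearity for knock-in runs plus the AP shift
    of the unaltered sub-map (positive = posterior shift relative to the
    comparison map, the knock-in signature)."""
    altered = pm[pm["altered"] & (pm["n_syn"] > 0)]
    unaltered = pm[~pm["altered"] & (pm["n_syn"] > 0)]
    out: dict[str, float] = {}
    if len(altered) >= 10:
        out["altered_linearity_ap"] = retinotopic_linearity(
            altered.assign(n_syn=1)
        )["ap"]
    if len(unaltered) >= 10:
        out["unaltered_linearity_ap"] = retinotopic_linearity(
            unaltered.assign(n_syn=1)
        )["ap"]
    out["unaltered_mean_ap"] = float(unaltered["tz_x"].mean())
    if wt_pm is not None:
        wt_ok = wt_pm[wt_pm["n_syn"] > 0]
        out["ap_shift_vs_wt"] = out["unaltered_mean_ap"] - float(
            wt_ok["tz_x"].mean()
        )
    return out
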