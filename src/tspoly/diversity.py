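"""Per-site and windowed population-genetic statistics.

pi uses the unbiased n/(n-1) pairwise factor on haploidized alleles (seeded
random assignment of heterozygotes, matching the genotype pipeline); Fst is
the Weir & Cockerham (1984) variance-components estimator on diploid
genotypes, with windows aggregated as a ratio of sums (the "weighted"
convention); LD distances are between site positions with same-position
pairs excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def harmonic(n: int) -> float:
    """a_n = sum_{i=1..n} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def theta_watterson(S: float, n: int, L: float) -> float:
    """Watterson's per-site theta: S / (a_{n-1} L)."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if L < 1:
        raise ValueError("need at least one accessible site")
    return S / (harmonic(n - 1) * L)


def _site_pi_terms(hap: np.ndarray) -> np.ndarray:
    """Unbiased per-site mean pairwise difference from a 0/1/-1 matrix."""
    h = np.asarray(hap)
    miss = h < 0
    m = (~miss).sum(axis=0).astype(float)
    s = np.where(miss, 0, h).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = s / m
        term = 2.0 * p * (1.0 - p) * m / (m - 1.0)
    term[m < 2] = 0.0
    return term


def pi_pairwise(hap: np.ndarray, L: float) -> float:
    """Mean pairwise diversity per accessible site over ``L`` sites."""
    if L == 0:
        return float("nan")
    if hap.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes")
    return float(_site_pi_terms(hap).sum() / L)


def dxy(hap_a: np.ndarray, hap_b: np.ndarray, L: float) -> float:
    """Mean between-lineage pairwise difference per accessible-in-both site."""
    if L == 0:
        return float("nan")
    pa = np.asarray(hap_a).mean(axis=0)
    pb = np.asarray(hap_b).mean(axis=0)
    return float(np.sum(pa * (1 - pb) + pb * (1 - pa)) / L)


def tajimas_d(S: int, n: int, pi_total: float) -> float:
    """Tajima's D with the standard 1989 constants; NA when S = 0."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4 haplotypes")
    if S == 0:
        return float("nan")
    a1 = harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_total - S / a1) / np.sqrt(var))


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst


def _wc_components(genotypes_by_pop: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site variance components (a, b, c) of the 1984 estimator.

    Each array is (n_sites, n_individuals) diploid codes {0,1,2,-1}.  Sites
    where any population has fewer than 2 non-missing genotypes get NaN.
    """
    r = len(genotypes_by_pop)
    if r < 2:
        raise ValueError("need at least two populations")
    n_sites = genotypes_by_pop[0].shape[0]
    n_i = np.empty((r, n_sites))
    p_i = np.empty((r, n_sites))
    h_i = np.empty((r, n_sites))
    for k, g in enumerate(genotypes_by_pop):
        ok = g >= 0
        n = ok.sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i[k] = np.where(ok, g, 0).sum(axis=1) / (2.0 * n)
            h_i[k] = np.where(ok & (g == 1), 1, 0).sum(axis=1) / n
        n_i[k] = n
    bad = (n_i < 2).any(axis=0)

    nbar = n_i.mean(axis=0)
    nsum = n_i.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2.0
    for arr in (a, b, c):
        arr[bad] = np.nan
    # monomorphic sites carry no information: zero components
    mono = (pbar <= 0) | (pbar >= 1)
    for arr in (a, b, c):
        arr[mono & ~bad] = 0.0
    return a, b, c


def fst_weir_cockerham(genotypes_by_pop: list[np.ndarray], mode: str = "window"):
    """WC (1984) Fst.  ``mode='site'`` returns per-site a/(a+b+c); ``'window'``
    returns the ratio-of-sums Sum(a)/Sum(a+b+c) over informative sites.
    Monomorphic input yields NaN."""
    a, b, c = _wc_components(genotypes_by_pop)
    denom = a + b + c
    if mode == "site":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = a / denom
        return out
    if mode != "window":
        raise ValueError("mode must be 'site' or 'window'")
    ok = np.isfinite(denom) & (denom != 0)
    if not ok.any():
        return float("nan")
    return float(a[ok].sum() / denom[ok].sum())


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def pair_ld(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(r^2, D) for two 0/1 allele vectors (missing coded < 0 and dropped).

    Alleles are taken as given (use derived coding for phase-sign logic):
    D = P(x=1, y=1) - p_x p_y.
    """
    ok = (x >= 0) & (y >= 0)
    x = x[ok].astype(float)
    y = y[ok].astype(float)
    if len(x) == 0:
        return float("nan"), float("nan")
    px, py = x.mean(), y.mean()
    D = (x * y).mean() - px * py
    denom = px * (1 - px) * py * (1 - py)
    if denom <= 0:
        return float("nan"), D
    return float(D * D / denom), float(D)


def ld_decay(
    hap: np.ndarray,
    positions: np.ndarray,
    window: int = 30_000,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Mean r^2 as a function of pairwise distance, for all site pairs
    within ``window`` bp.  Same-position pairs are excluded (min distance 1).
    Returns a DataFrame with columns distance, mean_r2, n_pairs."""
    h = np.asarray(hap, dtype=float)
    pos = np.asarray(positions)
    p = h.mean(axis=0)
    keep = (np.minimum(p, 1 - p) >= maf_min) & (p > 0) & (p < 1)
    h = h[:, keep]
    pos = pos[keep]
    sums: dict[int, list[float]] = {}
    n = h.shape[1]
    if n >= 2:
        hc = h - h.mean(axis=0)
        sd = hc.std(axis=0)
        j0 = 0
        for i in range(n):
            for j in range(i + 1, n):
                d = int(pos[j] - pos[i])
                if d > window:
                    break
                if d == 0:
                    continue
                r = float((hc[:, i] * hc[:, j]).mean() / (sd[i] * sd[j]))
                sums.setdefault(d, []).append(r * r)
    rows = [
        {"distance": d, "mean_r2": float(np.mean(v)), "n_pairs": len(v)}
        for d, v in sorted(sums.items())
    ]
    return pd.DataFrame(rows, columns=["distance", "mean_r2", "n_pairs"])


# ---------------------------------------------------------------------------
# Window scan


def make_windows(length: int, window: int, step: int | None = None) -> np.ndarray:
    """Window start positions over [0, length): all starts s with
    s + window <= length (plus a final partial window only if length < window)."""
    step = step or window
    if window % step != 0 and step != window:
        pass
    starts = np.arange(0, max(length - window, 0) + 1, step, dtype=np.int64)
    if len(starts) == 0:
        starts = np.array([0], dtype=np.int64)
    return starts


def window_scan(
    gm,
    *,
    sct: pd.DataFrame | None = None,
    window: int = 20_000,
    step: int | None = None,
    min_accessible: int = 5000,
    fst_pairs: list[tuple[tuple, tuple]] | None = None,
    mask=None,
    seed: int = 0,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Windowed S, theta_w, pi, Tajima's D, Fst, tsSNP density, het excess.

    ``fst_pairs`` lists pairs of (species, population) selectors, population
    ``None`` meaning the whole species.  Accessible length per window is the
    window size minus masked bp (the matrix is assumed to carry calls for
    every accessible position class); windows below ``min_accessible`` in any
    species are flagged excluded, as are windows overlapping the mask.
    """
    from .genomeio import random_haploidize

    species = gm.species_present
    length = int(genome_length if genome_length is not None else gm.pos.max() + 1)
    starts = make_windows(length, window, step)
    hap = random_haploidize(gm, seed)
    cols = {sp: gm.columns_for(sp) for sp in species}
    ts_flag = None
    if sct is not None:
        ts_flag = sct["site_class"].astype(str).str.startswith("ts").to_numpy()

    rows = []
    chrom0 = gm.chrom[0] if gm.n_sites else "chr1"
    for start in starts:
        end = start + window
        in_w = (gm.pos >= start) & (gm.pos < end)
        masked_bp = 0
        if mask is not None and len(mask.intervals):
            for c, s0, e0 in mask.intervals:
                if c == chrom0:
                    masked_bp += max(0, min(end, e0) - max(start, s0))
        acc_len = window - masked_bp
        row = {"chrom": chrom0, "start": int(start), "end": int(end)}
        excluded = acc_len < min_accessible or masked_bp > 0
        row["n_accessible"] = acc_len
        for sp in species:
            acc = gm.accessible[sp]
            sel = in_w & acc
            sub = hap[np.ix_(sel, cols[sp])].T  # (haplotypes, sites)
            n_hap = sub.shape[0]
            if sub.size:
                valid = sub >= 0
                alt = ((sub == 1) & valid).sum(axis=0)
                tot = valid.sum(axis=0)
                seg = (alt > 0) & (alt < tot)
            else:
                seg = np.array([], dtype=bool)
            S = int(seg.sum())
            row[f"S_{sp}"] = S
            row[f"theta_w_{sp}"] = (
                theta_watterson(S, n_hap, acc_len) if n_hap >= 2 and acc_len else np.nan
            )
            row[f"pi_{sp}"] = pi_pairwise(sub, acc_len) if n_hap >= 2 and acc_len else np.nan
            pi_tot = float(_site_pi_terms(sub).sum()) if sub.size else 0.0
            row[f"tajimas_d_{sp}"] = (
                tajimas_d(S, n_hap, pi_tot) if (n_hap >= 4 and S > 0) else np.nan
            )
            g = gm.genotypes[np.ix_(sel, cols[sp])]
            het = g == 1
            okg = g >= 0
            with np.errstate(divide="ignore", invalid="ignore"):
                ho = het.sum(axis=1) / okg.sum(axis=1)
                pfreq = np.where(okg, g, 0).sum(axis=1) / (2.0 * okg.sum(axis=1))
            he = 2 * pfreq * (1 - pfreq)
            poly = (pfreq > 0) & (pfreq < 1)
            row[f"het_excess_{sp}"] = (
                float((ho[poly] - he[poly]).mean()) if poly.any() else np.nan
            )
            if ts_flag is not None and acc_len:
                row[f"ts_density_{sp}"] = float(ts_flag[sel].sum() / acc_len)
        if fst_pairs:
            for (sp_a, pop_a), (sp_b, pop_b) in fst_pairs:
                ca = gm.columns_for(sp_a, pop_a)
                cb = gm.columns_for(sp_b, pop_b)
                acc = gm.accessible[gm.sample_map.species_of(gm.samples[ca[0]])]
                accb = gm.accessible[gm.sample_map.species_of(gm.samples[cb[0]])]
                sel = in_w & acc & accb
                ga = gm.genotypes[np.ix_(sel, ca)]
                gb = gm.genotypes[np.ix_(sel, cb)]
                name = f"fst_{sp_a}{'_' + str(pop_a) if pop_a else ''}_vs_{sp_b}{'_' + str(pop_b) if pop_b else ''}"
                row[name] = (
                    fst_weir_cockerham([ga, gb], "window") if sel.any() else np.nan
                )
        row["excluded"] = excluded
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distance profiles


def _merge_clusters(features: pd.DataFrame, collapse_gap: int) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in zip(features["start"], features["end"]))
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s - merged[-1][1] < collapse_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _distance_to_clusters(pos: np.ndarray, clusters: list[tuple[int, int]]) -> np.ndarray:
    """Distance from each position to the nearest cluster edge; -1 inside."""
    out = np.full(len(pos), np.inf)
    for s, e in clusters:
        inside = (pos >= s) & (pos < e)
        d = np.where(pos < s, s - pos, np.where(pos >= e, pos - e + 1, 0))
        out = np.minimum(out, d.astype(float))
        out[inside] = -1.0
    return out


def feature_distance_profile(
    site_pos: np.ndarray,
    site_val: np.ndarray,
    features: pd.DataFrame,
    gene_table: pd.DataFrame | None = None,
    *,
    collapse_gap: int = 10_000,
    bin_width: int = 500,
    max_dist: int = 50_000,
    n_random_sets: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean of a per-site statistic in distance bins from the nearest merged
    feature cluster, with a min/max envelope over random same-size gene sets
    drawn from ``gene_table``.  Sites inside a focal cluster contribute to no
    bin."""
    if len(features) == 0:
        raise ValueError("feature set is empty")
    pos = np.asarray(site_pos)
    val = np.asarray(site_val, dtype=float)

    def profile(feat: pd.DataFrame) -> np.ndarray:
        clusters = _merge_clusters(feat, collapse_gap)
        d = _distance_to_clusters(pos, clusters)
        nb = max_dist // bin_width
        means = np.full(nb, np.nan)
        ok = (d >= 0) & (d < max_dist)
        if ok.any():
            bins = (d[ok] // bin_width).astype(int)
            v = val[ok]
            for b in range(nb):
                m = bins == b
                if m.any():
                    means[b] = float(v[m].mean())
        return means

    main = profile(features)
    nb = len(main)
    lo = np.full(nb, np.nan)
    hi = np.full(nb, np.nan)
    if gene_table is not None and len(gene_table) >= len(features):
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_random_sets):
            idx = rng.choice(len(gene_table), size=len(features), replace=False)
            draws.append(profile(gene_table.iloc[idx]))
        arr = np.vstack(draws)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanmin(arr, axis=0)
            hi = np.nanmax(arr, axis=0)
    return pd.DataFrame(
        {
            "bin_start": np.arange(nb) * bin_width,
            "mean": main,
            "envelope_min": lo,
            "envelope_max": hi,
        }
    )


def tsnp_footprint(
    anchor_pos: np.ndarray,
    site_pos: np.ndarray,
    site_val: np.ndarray,
    *,
    bin_width: int = 50,
    max_dist: int = 2_000,
) -> pd.DataFrame:
    """Mean per-site statistic in ``bin_width`` bp bins of distance to the
    nearest anchor site (e.g. pi at four-fold sites around hq tsSNPs)."""
    nb = max_dist // bin_width
    if len(anchor_pos) == 0:
        return pd.DataFrame(
            {"bin_start": np.arange(nb) * bin_width, "mean": np.full(nb, np.nan), "n": 0}
        )
    anchors = np.sort(np.asarray(anchor_pos))
    pos = np.asarray(site_pos)
    idx = np.searchsorted(anchors, pos)
    left = np.abs(pos - anchors[np.clip(idx - 1, 0, len(anchors) - 1)])
    right = np.abs(anchors[np.clip(idx, 0, len(anchors) - 1)] - pos)
    d = np.minimum(left, right)
    means = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    bins = (d // bin_width).astype(int)
    val = np.asarray(site_val, dtype=float)
    for b in range(nb):
        m = (bins == b) & (d < max_dist)
        counts[b] = int(m.sum())
        if m.any():
            means[b] = float(val[m].mean())
    return pd.DataFrame(
        {"bin_start": np.arange(nb) * bin_width, "mean": means, "n": counts}
    )


def divergence_time(dxy_4fold: float, pi_anc_4fold: float, mu: float) -> float:
    """Net-divergence split time T = (dxy - pi_anc) / (2 mu) in generations."""
    if dxy_4fold < pi_anc_4fold:
        warnings.warn("dxy below ancestral diversity; divergence time undefined")
        return float("nan")
    return (dxy_4fold - pi_anc_4fold) / (2.0 * mu)
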