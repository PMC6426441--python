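"""Simulation-calibrated interspecific Fst outlier scan.

The null distribution of window Fst is built by simulating many independent
20 kb segments under a neutral demographic model and pushing each through
the same diploid-genotype Fst computation as the observed windows.  Each
observed non-overlapping window gets a one-sided low-tail rank p-value
p = (r + 1)/(n + 1) (never exactly 0), Bonferroni correction over the tested
windows, and significant windows are collapsed into candidate balanced
regions with a two-state Bernoulli hidden Markov model; regions must be
supported in both selfer subpopulations, and an additional conditional test
re-ranks each region against only the null segments with the highest
outcrosser diversity (emulating an unusually diverse founder population).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import fst_weir_cockerham, pi_pairwise
from .simulate.coalescent import simulate_segment
from .simulate.demography import DemographicModel
from .simulate.diploid import make_diploids

# ---------------------------------------------------------------------------
# Null distribution


@dataclass
class NullDistribution:
    """Per-segment window Fst values plus companion outcrosser diversity."""

    fst: dict[str, np.ndarray]  # comparison name -> per-segment Fst (NaN allowed)
    pi_outcrosser: np.ndarray
    meta: dict = field(default_factory=dict)

    def sorted_fst(self, comparison: str, conditional_mask: np.ndarray | None = None):
        v = self.fst[comparison]
        if conditional_mask is not None:
            v = v[conditional_mask]
        return np.sort(v[np.isfinite(v)])

    @property
    def comparisons(self) -> list[str]:
        return list(self.fst)

    def to_frame(self) -> pd.DataFrame:
        d = {f"fst_{k}": v for k, v in self.fst.items()}
        d["pi_outcrosser"] = self.pi_outcrosser
        return pd.DataFrame(d)


def build_null(
    model: DemographicModel,
    n_segments: int,
    sample_sizes: dict[str, int],
    seed: int,
    L: int = 20_000,
    comparisons: list[tuple[str, str]] | None = None,
    outcrosser: str = "outcrosser",
) -> NullDistribution:
    """Simulate ``n_segments`` neutral segments and record window Fst.

    ``sample_sizes`` gives diploid counts per population and must match the
    observed panel.  ``comparisons`` is a list of (population, outcrosser)
    label pairs; by default every non-outcrosser population is compared with
    the outcrosser.  Monomorphic segments yield NaN and are excluded from
    p-value ranks (their count is recorded in ``meta``).
    """
    if n_segments < 1000:
        raise ValueError("need >= 1000 segments for p-value resolution")
    pops = [p for p in sample_sizes if p in model.labels]
    if comparisons is None:
        comparisons = [(p, outcrosser) for p in pops if p != outcrosser]
    n_hap = {p: 2 * sample_sizes[p] for p in pops}
    selfing = {p.label: p.selfing_rate for p in model.populations}
    fst = {f"{a}_vs_{b}": np.full(n_segments, np.nan) for a, b in comparisons}
    pi_out = np.full(n_segments, np.nan)

    for i in range(n_segments):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        hs = simulate_segment(model, n_hap, L, rng=rng)
        gm = make_diploids(hs, selfing, rng=rng)
        # columns by simulation population label via sample names
        pop_cols = {
            p: np.array(
                [j for j, s in enumerate(gm.samples) if s.rsplit("_", 1)[0] == p]
            )
            for p in pops
        }
        for a, b in comparisons:
            ga = gm.genotypes[:, pop_cols[a]]
            gb = gm.genotypes[:, pop_cols[b]]
            fst[f"{a}_vs_{b}"][i] = fst_weir_cockerham([ga, gb], "window")
        oc = np.flatnonzero(hs.pop_of == outcrosser)
        if len(oc) >= 2:
            pi_out[i] = pi_pairwise(hs.haplotypes[oc], L)
    n_na = {k: int(np.isnan(v).sum()) for k, v in fst.items()}
    return NullDistribution(
        fst,
        pi_out,
        meta={
            "n_segments": n_segments,
            "L": L,
            "sample_sizes": dict(sample_sizes),
            "seed": seed,
            "n_monomorphic": n_na,
        },
    )


def window_pvalue(null_sorted: np.ndarray, fst_obs: float) -> float:
    """One-sided low-tail rank p-value (r + 1)/(n + 1); ties count as <=."""
    if not np.isfinite(fst_obs):
        return float("nan")
    n = len(null_sorted)
    if n == 0:
        raise ValueError("empty null distribution")
    r = int(np.searchsorted(null_sorted, fst_obs, side="right"))
    return (r + 1) / (n + 1)


def bonferroni(pvals: np.ndarray) -> np.ndarray:
    """p_adj = min(1, p * m), m = number of non-NA tests; NA stays NA."""
    p = np.asarray(pvals, dtype=float)
    m = int(np.isfinite(p).sum())
    out = np.minimum(1.0, p * m)
    return out


# ---------------------------------------------------------------------------
# Two-state Bernoulli HMM


@dataclass
class HMMParams:
    """Background/balanced two-state HMM with Bernoulli emissions."""

    initial: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    transition: np.ndarray = field(
        default_factory=lambda: np.array([[0.99, 0.01], [0.01, 0.99]])
    )
    emission: np.ndarray = field(default_factory=lambda: np.array([0.01, 0.9]))
    # emission[s] = P(significant | state s); state 1 = balanced

    def validate(self) -> None:
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.emission <= 0) or np.any(self.emission >= 1):
            raise ValueError("emission probabilities must be in (0, 1)")


_EPS = 1e-9


def _obs_logprob(params: HMMParams, track: np.ndarray) -> np.ndarray:
    e = np.clip(params.emission, _EPS, 1 - _EPS)
    return np.where(track[:, None] == 1, np.log(e), np.log1p(-e))


def viterbi(track: np.ndarray, params: HMMParams) -> np.ndarray:
    """Most likely state path; ties broken toward background (state 0)."""
    track = np.asarray(track, dtype=int)
    T = len(track)
    if T == 0:
        return np.zeros(0, dtype=int)
    logA = np.log(np.clip(params.transition, _EPS, 1))
    logpi = np.log(np.clip(params.initial, _EPS, 1))
    logB = _obs_logprob(params, track)
    delta = logpi + logB[0]
    back = np.zeros((T, 2), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA  # cand[i, j]
        # argmax over i with tie toward background: state 0 wins ties
        best = np.where(cand[1] > cand[0], 1, 0)
        delta = cand[best, [0, 1]] + logB[t]
        back[t] = best
    path = np.zeros(T, dtype=int)
    path[-1] = 1 if delta[1] > delta[0] else 0
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def baum_welch(
    tracks: list[np.ndarray],
    params: HMMParams | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> HMMParams:
    """EM fit of the two-state Bernoulli HMM over one or more tracks
    (chromosomes); the state distribution resets at each track boundary."""
    p = params or HMMParams()
    p.validate()
    tracks = [np.asarray(t, dtype=int) for t in tracks if len(t)]
    if not tracks:
        return p
    flat = np.concatenate(tracks)
    if flat.min() == flat.max():
        return p  # degenerate: EM cannot separate states
    prev_ll = -np.inf
    A = p.transition.copy()
    pi0 = p.initial.copy()
    e = p.emission.copy()
    for _ in range(max_iter):
        ll = 0.0
        g_sum = np.zeros(2)
        g_obs = np.zeros(2)
        xi_sum = np.zeros((2, 2))
        pi_new = np.zeros(2)
        for track in tracks:
            T = len(track)
            B = np.where(track[:, None] == 1, e, 1 - e)
            alpha = np.zeros((T, 2))
            scale = np.zeros(T)
            alpha[0] = pi0 * B[0]
            scale[0] = alpha[0].sum()
            alpha[0] /= scale[0]
            for t in range(1, T):
                alpha[t] = (alpha[t - 1] @ A) * B[t]
                scale[t] = alpha[t].sum()
                alpha[t] /= scale[t]
            beta = np.zeros((T, 2))
            beta[-1] = 1.0
            for t in range(T - 2, -1, -1):
                beta[t] = (A @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            ll += float(np.log(scale).sum())
            pi_new += gamma[0]
            g_sum += gamma.sum(axis=0)
            g_obs += (gamma * track[:, None]).sum(axis=0)
            for t in range(T - 1):
                x = alpha[t][:, None] * A * (B[t + 1] * beta[t + 1])[None, :]
                xi_sum += x / x.sum()
        A = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        pi0 = pi_new / pi_new.sum()
        e = np.clip(g_obs / g_sum, _EPS, 1 - _EPS)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return HMMParams(pi0, A, e)


# ---------------------------------------------------------------------------
# Regions


@dataclass
class BalRegion:
    chrom: str
    start: int
    end: int
    windows: list[int] = field(default_factory=list)

    def overlaps(self, other: "BalRegion") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def hmm_collapse(
    windows: pd.DataFrame,
    significant: np.ndarray,
    params_init: HMMParams | None = None,
    fit: bool = True,
) -> list[BalRegion]:
    """Collapse significant windows into regions.

    The HMM is fitted genome-wide (Baum-Welch from the fixed initialisation,
    chromosome tracks separated) and decoded by Viterbi per chromosome.  A
    region is a connected run of windows that are Viterbi-balanced or
    Bonferroni-significant and that contains at least one significant
    window: significant windows always seed a region, and the HMM's role is
    to bridge adjacent significant windows across gaps, as in joining
    adjacent significant segments.  Degenerate all-same tracks skip EM.
    """
    sig = np.asarray(significant, dtype=bool)
    chroms = windows["chrom"].to_numpy()
    tracks = []
    chrom_order = list(dict.fromkeys(chroms.tolist()))
    for c in chrom_order:
        tracks.append(sig[chroms == c].astype(int))
    params = params_init or HMMParams()
    if fit and not all(t.min() == t.max() for t in tracks if len(t)):
        params = baum_welch(tracks, params)
    regions: list[BalRegion] = []
    for c, track in zip(chrom_order, tracks):
        idx = np.flatnonzero(chroms == c)
        if len(track) == 0:
            continue
        if track.min() == track.max():
            state = np.full(len(track), int(track[0]))
        else:
            state = viterbi(track, params)
        keep = (state == 1) | (track == 1)
        # maximal runs of keep containing >= 1 significant window
        i = 0
        while i < len(keep):
            if not keep[i]:
                i += 1
                continue
            j = i
            while j < len(keep) and keep[j]:
                j += 1
            if track[i:j].any():
                w = idx[i:j]
                regions.append(
                    BalRegion(
                        c,
                        int(windows["start"].iloc[w[0]]),
                        int(windows["end"].iloc[w[-1]]),
                        windows=[int(x) for x in w],
                    )
                )
            i = j
    return regions


def intersect_subpops(regions_a: list[BalRegion], regions_b: list[BalRegion]) -> list[BalRegion]:
    """Keep regions overlapping (>= 1 bp) a region of the other subpopulation;
    overlapping pairs are unioned and merged transitively."""
    kept = []
    for ra in regions_a:
        for rb in regions_b:
            if ra.overlaps(rb):
                kept.append(
                    BalRegion(
                        ra.chrom,
                        min(ra.start, rb.start),
                        max(ra.end, rb.end),
                        sorted(set(ra.windows) | set(rb.windows)),
                    )
                )
    # transitive merge
    kept.sort(key=lambda r: (r.chrom, r.start))
    merged: list[BalRegion] = []
    for r in kept:
        if merged and merged[-1].overlaps(r):
            last = merged[-1]
            merged[-1] = BalRegion(
                last.chrom,
                min(last.start, r.start),
                max(last.end, r.end),
                sorted(set(last.windows) | set(r.windows)),
            )
        else:
            merged.append(r)
    return merged


def conditional_scan(
    nd: NullDistribution,
    regions: list[BalRegion],
    window_fst: pd.DataFrame,
    comparison: str,
    founder_pi_percentile: float = 0.99,
) -> list[float]:
    """Rank each region's most extreme window Fst against only the null
    segments whose outcrosser diversity is in the top (1 - percentile)
    fraction — the elevated-founder-diversity null."""
    pi = nd.pi_outcrosser
    thr = np.nanquantile(pi, founder_pi_percentile)
    mask = pi >= thr
    if int(mask.sum()) < 100:
        raise ValueError("conditional null subset below 100 segments")
    null_sorted = nd.sorted_fst(comparison, conditional_mask=mask)
    col = f"fst_{comparison}"
    out = []
    for r in regions:
        vals = window_fst[col].iloc[r.windows].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        obs = float(np.min(vals)) if len(vals) else float("nan")
        out.append(window_pvalue(null_sorted, obs))
    return out


# ---------------------------------------------------------------------------
# Full scan


@dataclass
class ScanResult:
    windows: pd.DataFrame  # per-window fst, p, p_adj, significant per comparison
    regions_by_comparison: dict[str, list[BalRegion]]
    regions: list[BalRegion]  # intersected across subpopulations
    conditional_p: list[float]


def scan(
    window_stats: pd.DataFrame,
    nd: NullDistribution,
    comparisons: list[str] | None = None,
    alpha: float = 0.05,
    founder_pi_percentile: float = 0.99,
    hmm_params: HMMParams | None = None,
) -> ScanResult:
    """Run the full outlier scan on observed window Fst values.

    ``window_stats`` must carry ``fst_<comparison>`` columns for windows in
    genome order (non-overlapping); windows flagged ``excluded`` are not
    tested.  Regions significant in every comparison (both subpopulations)
    make the final set.
    """
    comparisons = comparisons or nd.comparisons
    ws = window_stats.reset_index(drop=True)
    tested = ~ws.get("excluded", pd.Series(False, index=ws.index)).to_numpy(bool)
    per_comp_regions = {}
    for comp in comparisons:
        null_sorted = nd.sorted_fst(comp)
        col = f"fst_{comp}"
        fst_obs = ws[col].to_numpy(dtype=float)
        p = np.full(len(ws), np.nan)
        for i in np.flatnonzero(tested & np.isfinite(fst_obs)):
            p[i] = window_pvalue(null_sorted, fst_obs[i])
        p_adj = bonferroni(p)
        sig = np.where(np.isfinite(p_adj), p_adj < alpha, False)
        ws[f"p_{comp}"] = p
        ws[f"p_adj_{comp}"] = p_adj
        ws[f"significant_{comp}"] = sig
        per_comp_regions[comp] = hmm_collapse(ws, sig, hmm_params)
    regions = per_comp_regions[comparisons[0]]
    for comp in comparisons[1:]:
        regions = intersect_subpops(regions, per_comp_regions[comp])
    cond = conditional_scan(nd, regions, ws, comparisons[0], founder_pi_percentile)
    return ScanResult(ws, per_comp_regions, regions, cond)


def region_report(
    result: ScanResult,
    hq_sites: pd.DataFrame | None = None,
    gene_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotated candidate-region table."""
    rows = []
    ws = result.windows
    for k, r in enumerate(result.regions):
        row = {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "n_windows": len(r.windows),
            "conditional_p": result.conditional_p[k],
        }
        for stat in ("theta_w", "tajimas_d"):
            cols = [c for c in ws.columns if c.startswith(stat)]
            for c in cols:
                row[f"mean_{c}"] = float(np.nanmean(ws[c].iloc[r.windows]))
        pcols = [c for c in ws.columns if c.startswith("p_adj_")]
        if pcols:
            row["min_p_adj"] = float(np.nanmin(ws[pcols].iloc[r.windows].to_numpy()))
        if hq_sites is not None and len(hq_sites):
            m = (
                (hq_sites["chrom"] == r.chrom)
                & (hq_sites["pos"] >= r.start)
                & (hq_sites["pos"] < r.end)
            )
            if "pass" in hq_sites:
                m &= hq_sites["pass"]
            row["n_hq_tsSNPs"] = int(m.sum())
        if gene_table is not None and len(gene_table):
            m = (
                (gene_table["chrom"] == r.chrom)
                & (gene_table["start"] < r.end)
                & (gene_table["end"] > r.start)
            )
            row["genes"] = ",".join(gene_table.loc[m, "name"]) if m.any() else ""
        rows.append(row)
    cols = ["chrom", "start", "end", "n_windows", "conditional_p"]
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)
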