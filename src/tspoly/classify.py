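"""Site sharing classes across species and derived-allele analyses.

A biallelic site accessible in all compared species is species-specific
(segregating in exactly one), two-way trans-specific (exactly two), three-way
trans-specific (all three), a fixed difference (each species monomorphic but
not all for the same allele), or invariant.  Classes are mutually exclusive
and exhaustive over accessible biallelic sites; everything else is excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import pair_ld
from .genomeio import GenotypeMatrix, MaskSet, random_haploidize


def _allele_counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(alt copies, total non-missing copies) per site for one species matrix."""
    g = gm.genotypes
    ok = g >= 0
    alt = np.where(ok, g, 0).sum(axis=1)
    total = 2 * ok.sum(axis=1)
    return alt.astype(np.int64), total.astype(np.int64)


def classify_sites(
    gms: dict[str, GenotypeMatrix],
    mode: str = "3way",
    ancestral: np.ndarray | None = None,
) -> pd.DataFrame:
    """Partition aligned sites into sharing classes across 2 or 3 species.

    ``gms`` maps species name to its genotype matrix; all matrices must be on
    identical coordinates.  ``ancestral`` is an optional per-site array of
    'ref'/'alt'/'unknown' used to add derived counts and frequencies.
    """
    species = sorted(gms)
    if mode == "3way" and len(species) != 3:
        raise ValueError("3way mode needs exactly three species")
    if mode == "2way" and len(species) != 2:
        raise ValueError("2way mode needs exactly two species")
    ref_gm = gms[species[0]]
    for sp in species[1:]:
        g = gms[sp]
        if g.n_sites != ref_gm.n_sites or np.any(g.pos != ref_gm.pos) or np.any(
            g.chrom != ref_gm.chrom
        ):
            raise ValueError("genotype matrices are not on shared coordinates")

    n = ref_gm.n_sites
    seg = {}
    mono_alt = {}
    counts = {}
    accessible_all = np.ones(n, dtype=bool)
    for sp in species:
        gm = gms[sp]
        alt, total = _allele_counts(gm)
        counts[sp] = (alt, total)
        acc = gm.accessible.get(gm.species_present[0], np.ones(n, bool)) & (total > 0)
        accessible_all &= acc
        seg[sp] = (alt > 0) & (alt < total)
        mono_alt[sp] = alt == total

    cls = np.full(n, "excluded", dtype=object)
    seg_mat = np.vstack([seg[sp] for sp in species])
    n_seg = seg_mat.sum(axis=0)
    all_mono = n_seg == 0
    mono_mat = np.vstack([mono_alt[sp] for sp in species])
    same_allele = mono_mat.all(axis=0) | (~mono_mat).all(axis=0)

    acc = accessible_all
    cls[acc & all_mono & same_allele] = "invariant"
    cls[acc & all_mono & ~same_allele] = "fixed_difference"
    for i, sp in enumerate(species):
        only = acc & (n_seg == 1) & seg_mat[i]
        cls[only] = f"ss_{sp}"
    if len(species) == 3:
        for i in range(3):
            for j in range(i + 1, 3):
                pair = acc & (n_seg == 2) & seg_mat[i] & seg_mat[j]
                cls[pair] = f"ts_{species[i]}_{species[j]}"
        cls[acc & (n_seg == 3)] = "ts_3way"
    else:
        pair = acc & (n_seg == 2)
        cls[pair] = f"ts_{species[0]}_{species[1]}"

    out = {"chrom": ref_gm.chrom, "pos": ref_gm.pos, "site_class": cls}
    for sp in species:
        alt, total = counts[sp]
        out[f"alt_{sp}"] = alt
        out[f"total_{sp}"] = total
        if ancestral is not None:
            der = np.where(
                ancestral == "ref", alt, np.where(ancestral == "alt", total - alt, -1)
            )
            out[f"derived_{sp}"] = der
            with np.errstate(divide="ignore", invalid="ignore"):
                freq = np.where(der >= 0, der / np.maximum(total, 1), np.nan)
            freq = np.where(total == 0, np.nan, freq)
            out[f"derived_freq_{sp}"] = freq
    return pd.DataFrame(out)


def class_counts(sct: pd.DataFrame) -> pd.Series:
    return sct["site_class"].value_counts()


# ---------------------------------------------------------------------------
# Spectra


def daf_spectrum(
    sct: pd.DataFrame, species: str, class_filter: str | list[str], n_bins: int = 10
) -> pd.DataFrame:
    """Normalized histogram of derived allele frequency for one site class."""
    if isinstance(class_filter, str):
        class_filter = [class_filter]
    pick = sct["site_class"].isin(class_filter)
    f = sct.loc[pick, f"derived_freq_{species}"].to_numpy(dtype=float)
    f = f[np.isfinite(f) & (f > 0) & (f < 1)]
    edges = np.linspace(0, 1, n_bins + 1)
    hist, _ = np.histogram(f, bins=edges)
    frac = hist / hist.sum() if hist.sum() else np.zeros(n_bins)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": hist, "fraction": frac}
    )


def ts_fraction_by_daf(sct: pd.DataFrame, species: str, n_bins: int = 10) -> pd.DataFrame:
    """Per DAF bin, the fraction of segregating sites that are trans-specific."""
    f = sct[f"derived_freq_{species}"].to_numpy(dtype=float)
    is_ts = sct["site_class"].astype(str).str.startswith("ts").to_numpy()
    is_seg = sct["site_class"].astype(str).str.startswith(("ts", "ss")).to_numpy()
    ok = np.isfinite(f) & (f > 0) & (f < 1) & is_seg
    edges = np.linspace(0, 1, n_bins + 1)
    bins = np.clip(np.digitize(f, edges) - 1, 0, n_bins - 1)
    frac = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = ok & (bins == b)
        if m.any():
            frac[b] = float(is_ts[m].mean())
    return pd.DataFrame({"bin_start": edges[:-1], "ts_fraction": frac})


# ---------------------------------------------------------------------------
# Rarefaction


def rarefaction(
    gms: dict[str, GenotypeMatrix],
    focal: str,
    subsample_sizes: list[int],
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean numbers of species-specific and trans-specific segregating sites
    discovered in random subsamples of the focal species' individuals; the
    partner species keep their full panels."""
    rng = np.random.default_rng(seed)
    gm = gms[focal]
    n_ind = len(gm.samples)
    others = [sp for sp in gms if sp != focal]
    seg_other = np.zeros(gm.n_sites, dtype=bool)
    for sp in others:
        alt, total = _allele_counts(gms[sp])
        seg_other |= (alt > 0) & (alt < total)
    rows = []
    for size in subsample_sizes:
        if size < 2:
            raise ValueError("subsample size must be >= 2")
        if size > n_ind:
            raise ValueError(f"subsample size {size} exceeds panel of {n_ind}")
        ts_counts, ss_counts = [], []
        for _ in range(n_reps):
            cols = rng.choice(n_ind, size=size, replace=False)
            g = gm.genotypes[:, cols]
            ok = g >= 0
            alt = np.where(ok, g, 0).sum(axis=1)
            total = 2 * ok.sum(axis=1)
            seg = (alt > 0) & (alt < total)
            ts_counts.append(int((seg & seg_other).sum()))
            ss_counts.append(int((seg & ~seg_other).sum()))
        rows.append(
            {
                "size": size,
                "ts_mean": float(np.mean(ts_counts)),
                "ss_mean": float(np.mean(ss_counts)),
                "ts_sd": float(np.std(ts_counts)),
                "ss_sd": float(np.std(ss_counts)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Frequency-matched resampling


def matched_resample_fraction(
    sct: pd.DataFrame,
    annotations: pd.DataFrame,
    species: str,
    target_class: str,
    reference_class: str,
    statistic: str = "nonsyn_fraction",
    n_draw: int = 20_000,
    n_bins: int = 10,
    n_reps: int = 1000,
    seed: int = 0,
) -> dict:
    """Compare an annotation statistic between site classes at matched DAF.

    Per replicate, ``n_draw`` target-class sites are drawn, binned by derived
    allele frequency into ``n_bins`` bins, and the same per-bin counts are
    drawn from the reference class (without replacement within a replicate).
    Returns the two replicate distributions and an empirical two-sided p.
    """
    if statistic not in ("nonsyn_fraction", "genic_fraction"):
        raise ValueError("statistic must be nonsyn_fraction or genic_fraction")
    rng = np.random.default_rng(seed)
    t = sct.merge(annotations, on=["chrom", "pos"], how="left")
    f = t[f"derived_freq_{species}"].to_numpy(dtype=float)
    usable = np.isfinite(f) & (f > 0) & (f < 1)
    tgt = np.flatnonzero(usable & (t["site_class"] == target_class).to_numpy())
    ref = np.flatnonzero(usable & (t["site_class"] == reference_class).to_numpy())
    if len(tgt) == 0 or len(ref) == 0:
        raise ValueError("empty target or reference class")
    n_draw = min(n_draw, len(tgt))
    edges = np.linspace(0, 1, n_bins + 1)
    bin_of = np.clip(np.digitize(f, edges) - 1, 0, n_bins - 1)
    ref_by_bin = {b: np.flatnonzero(bin_of[ref] == b) for b in range(n_bins)}

    if statistic == "nonsyn_fraction":
        nonsyn = (t["effect"] == "nonsynonymous").to_numpy()
        cds = t["cds"].to_numpy(dtype=bool)

        def stat(idx):
            c = cds[idx]
            return float(nonsyn[idx][c].mean()) if c.any() else np.nan

    else:
        genic = t["genic"].to_numpy(dtype=bool)

        def stat(idx):
            return float(genic[idx].mean())

    target_stats, reference_stats = [], []
    warned = False
    for _ in range(n_reps):
        draw_t = rng.choice(tgt, size=n_draw, replace=False)
        need = np.bincount(bin_of[draw_t], minlength=n_bins)
        avail = np.array([len(ref_by_bin[b]) for b in range(n_bins)])
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = np.where(need > 0, avail / np.maximum(need, 1), np.inf)
        factor = min(1.0, float(np.min(factors)))
        if factor < 1.0 and not warned:
            warnings.warn("reference class too small in some DAF bins; reducing draw")
            warned = True
        draw_r = []
        kept_t = []
        for b in range(n_bins):
            k = int(np.floor(need[b] * factor))
            if k == 0:
                continue
            pool = ref[ref_by_bin[b]]
            draw_r.append(rng.choice(pool, size=k, replace=False))
            tb = draw_t[bin_of[draw_t] == b]
            kept_t.append(tb[:k])
        draw_r = np.concatenate(draw_r) if draw_r else np.array([], dtype=int)
        kept = np.concatenate(kept_t) if kept_t else np.array([], dtype=int)
        target_stats.append(stat(kept))
        reference_stats.append(stat(draw_r))
    ts = np.array(target_stats)
    rs = np.array(reference_stats)
    ok = np.isfinite(ts) & np.isfinite(rs)
    p = 2.0 * min(float((rs[ok] >= ts[ok]).mean()), float((rs[ok] <= ts[ok]).mean()))
    return {
        "target": ts,
        "reference": rs,
        "p_two_sided": min(1.0, p),
        "statistic": statistic,
    }


# ---------------------------------------------------------------------------
# High-quality three-way tsSNP filter


def hq_ts_filter(
    sct: pd.DataFrame,
    gm: GenotypeMatrix,
    masks: MaskSet | None = None,
    ld_r2_min: float = 0.2,
    seed: int = 0,
    ancestral: np.ndarray | None = None,
    concordance_min: float = 0.98,
) -> pd.DataFrame:
    """Stringent filter for three-way trans-specific SNPs.

    A candidate passes iff (i) within each species some other passing
    candidate is in coupling-phase LD with it (r^2 > ``ld_r2_min`` and D > 0
    under derived coding); (ii) it overlaps no masked interval; (iii) its
    per-species mean depth is at most the species mean + 2 SD (skipped with a
    warning when depth is absent); (iv) per-species mean concordance exceeds
    ``concordance_min`` (skipped when absent); (v) its minor allele is
    carried by at least two individuals in every species.  The circular LD
    criterion is iterated to a fixed point.
    """
    cand = np.flatnonzero((sct["site_class"] == "ts_3way").to_numpy())
    n_c = len(cand)
    species = gm.species_present
    hap = random_haploidize(gm, seed)

    not_masked = np.ones(n_c, dtype=bool)
    if masks is not None and masks.intervals:
        not_masked = ~masks.contains(gm.chrom[cand], gm.pos[cand])

    coverage_ok = np.ones(n_c, dtype=bool)
    if gm.depth is not None:
        for sp in species:
            cols = gm.columns_for(sp)
            site_mean = np.nanmean(gm.depth[:, cols], axis=1)
            thr = np.nanmean(site_mean) + 2 * np.nanstd(site_mean)
            coverage_ok &= site_mean[cand] <= thr
    else:
        warnings.warn("depth absent; skipping coverage criterion")

    concordance_ok = np.ones(n_c, dtype=bool)
    if gm.concordance is not None:
        for sp in species:
            cols = gm.columns_for(sp)
            site_mean = np.nanmean(gm.concordance[:, cols], axis=1)
            concordance_ok &= site_mean[cand] > concordance_min
    else:
        warnings.warn("concordance absent; skipping concordance criterion")

    multi_carrier = np.ones(n_c, dtype=bool)
    for sp in species:
        cols = gm.columns_for(sp)
        g = gm.genotypes[np.ix_(cand, cols)]
        ok = g >= 0
        alt_copies = np.where(ok, g, 0).sum(axis=1)
        total = 2 * ok.sum(axis=1)
        minor_is_alt = alt_copies * 2 <= total
        carriers_alt = (g > 0).sum(axis=1)
        carriers_ref = (ok & (g < 2)).sum(axis=1)
        carriers = np.where(minor_is_alt, carriers_alt, carriers_ref)
        multi_carrier &= carriers >= 2

    static_pass = not_masked & coverage_ok & concordance_ok & multi_carrier

    # derived-coded alleles for the phase sign
    alleles = hap[cand].astype(np.int8)
    if ancestral is not None:
        flip = ancestral[cand] == "alt"
        alleles[flip] = np.where(alleles[flip] >= 0, 1 - alleles[flip], -1)

    active = static_pass.copy()
    in_phase = np.zeros(n_c, dtype=bool)
    sp_cols = {sp: gm.columns_for(sp) for sp in species}
    for _ in range(n_c + 1):
        idx_active = np.flatnonzero(active)
        new_phase = np.zeros(n_c, dtype=bool)
        for ci in idx_active:
            ok_all = True
            for sp in species:
                cols = sp_cols[sp]
                x = alleles[ci, cols]
                found = False
                for cj in idx_active:
                    if cj == ci:
                        continue
                    r2, D = pair_ld(x, alleles[cj, cols])
                    if np.isfinite(r2) and r2 > ld_r2_min and D > 0:
                        found = True
                        break
                if not found:
                    ok_all = False
                    break
            new_phase[ci] = ok_all
        next_active = static_pass & new_phase
        in_phase = new_phase
        if np.array_equal(next_active, active):
            break
        active = next_active

    return pd.DataFrame(
        {
            "chrom": gm.chrom[cand],
            "pos": gm.pos[cand],
            "in_phase_ld": in_phase,
            "not_masked": not_masked,
            "coverage_ok": coverage_ok,
            "concordance_ok": concordance_ok,
            "multi_carrier": multi_carrier,
            "pass": active,
        }
    )


# ---------------------------------------------------------------------------
# Neutral shared-polymorphism probability


@dataclass
class SharedPolyParams:
    """Inputs for the neutral trans-specific polymorphism expectation."""

    N1: float
    N2: float
    T: float
    L: float
    mu: float

    def __post_init__(self) -> None:
        if min(self.N1, self.N2, self.T, self.L, self.mu) <= 0:
            raise ValueError("all parameters must be > 0")


def neutral_ts_probability(p: SharedPolyParams) -> tuple[float, float]:
    """Expected neutral trans-specific SNP count and P(>= 1).

    A neutral polymorphism shared by descent must persist for T generations
    in both daughter species; each lineage loses it at rate ~1/(2N) per
    generation, so E = L * 4 Nmax mu * exp(-T/(2 N1)) * exp(-T/(2 N2)) with
    the ancestral theta taken from the larger population, and
    P = 1 - exp(-E).  Overflow-safe for large T/N.
    """
    log_e = (
        np.log(p.L)
        + np.log(4.0 * max(p.N1, p.N2) * p.mu)
        - p.T / (2.0 * p.N1)
        - p.T / (2.0 * p.N2)
    )
    E = float(np.exp(log_e)) if log_e > -700 else 0.0
    P = float(-np.expm1(-E))
    return E, P
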