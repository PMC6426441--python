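"""ABBA-BABA D statistics and identity-by-descent segment summaries.

D is the frequency-based (Durand-type) statistic comparing one focal diploid
individual (P2, derived dosage 0 / 0.5 / 1) with allele frequencies in a
sister population (P1) and a candidate donor (P3), polarized so the
outgroup is fixed ancestral.  Significance comes from a delete-one block
jackknife over contiguous genomic blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class DStatResult:
    D: float
    sum_abba: float
    sum_baba: float
    n_blocks: int
    se: float
    Z: float


def d_statistic(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    positions: np.ndarray,
    block_size: int = 1_000_000,
    chrom: np.ndarray | None = None,
) -> DStatResult:
    """Compute D = sum(ABBA - BABA) / sum(ABBA + BABA) with jackknife SE.

    ``p1`` and ``p3`` are per-site derived-allele frequencies; ``p2`` is one
    individual's derived dosage in {0, 0.5, 1}.  Sites must already be
    restricted to those where the outgroup is fixed ancestral.  Blocks are
    contiguous ``block_size``-bp windows (truncated at chromosome ends).
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    p3 = np.asarray(p3, float)
    pos = np.asarray(positions)
    ok = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(p3)
    abba = (1 - p1[ok]) * p2[ok] * p3[ok]
    baba = p1[ok] * (1 - p2[ok]) * p3[ok]
    tot_a, tot_b = float(abba.sum()), float(baba.sum())
    denom = tot_a + tot_b
    if denom == 0:
        return DStatResult(float("nan"), 0.0, 0.0, 0, float("nan"), float("nan"))
    D = (tot_a - tot_b) / denom

    if chrom is None:
        chrom_ok = np.zeros(int(ok.sum()), dtype=object)
        chrom_ok[:] = "0"
    else:
        chrom_ok = np.asarray(chrom, dtype=object)[ok]
    block_ids = np.array(
        [f"{c}:{int(p) // block_size}" for c, p in zip(chrom_ok, pos[ok])], dtype=object
    )
    blocks = pd.unique(block_ids)
    B = len(blocks)
    if B < 2:
        return DStatResult(D, tot_a, tot_b, B, float("nan"), float("nan"))
    # weighted delete-one block jackknife (blocks carry unequal information)
    d_del = np.empty(B)
    w = np.empty(B)
    for k, b in enumerate(blocks):
        m = block_ids != b
        a, bb = float(abba[m].sum()), float(baba[m].sum())
        d_del[k] = (a - bb) / (a + bb) if (a + bb) > 0 else D
        w[k] = denom - (a + bb)  # this block's ABBA+BABA weight
    if w.sum() <= 0 or np.any(w < 0):
        return DStatResult(D, tot_a, tot_b, B, float("nan"), float("nan"))
    h = denom / np.maximum(w, 1e-300)
    theta_J = B * D - float(np.sum((1.0 - w / denom) * d_del))
    var = float(
        np.mean((h * D - (h - 1.0) * d_del - theta_J) ** 2 / np.maximum(h - 1.0, 1e-12))
    )
    se = float(np.sqrt(var)) if var > 0 else float("nan")
    Z = D / se if se and se > 0 else float("nan")
    return DStatResult(D, tot_a, tot_b, B, se, Z)


def derived_freqs_and_dosage(
    gm, ancestral: np.ndarray, species=None, population=None, sample: str | None = None
) -> np.ndarray:
    """Per-site derived-allele frequency of a population, or one sample's
    derived dosage.  Sites with unknown ancestral state yield NaN."""
    if sample is not None:
        j = gm.samples.index(sample)
        g = gm.genotypes[:, [j]]
    else:
        g = gm.genotypes[:, gm.columns_for(species, population)]
    ok = g >= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = np.where(ok, g, 0).sum(axis=1) / (2.0 * ok.sum(axis=1))
    der = np.where(
        ancestral == "ref", alt_freq, np.where(ancestral == "alt", 1 - alt_freq, np.nan)
    )
    return der


# ---------------------------------------------------------------------------
# IBD segments


def read_ibd_segments(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    need = {"sample_a", "sample_b", "chrom", "start", "end"}
    if not need.issubset(t.columns):
        raise ValueError(f"IBD table needs columns {sorted(need)}")
    return t


def ibd_summary(
    segments: pd.DataFrame,
    regions: list | None,
    genome_size: int,
    min_length: int = 1000,
) -> dict:
    """Per-pair IBD totals and inside/outside-region length stratification.

    A segment belongs to a region when its midpoint falls inside; lengths
    inside vs outside are compared by a Wilcoxon rank-sum test.  Segments
    shorter than ``min_length`` are dropped.
    """
    t = segments.copy()
    if len(t):
        t["length"] = t["end"] - t["start"]
        t = t[t["length"] >= min_length].reset_index(drop=True)
    if not len(t):
        return {
            "pairs": pd.DataFrame(columns=["sample_a", "sample_b", "total_bp", "fraction"]),
            "median_inside": float("nan"),
            "median_outside": float("nan"),
            "p_ranksum": float("nan"),
            "region_cov_fraction": float("nan"),
            "genome_cov_fraction": 0.0,
        }
    pairs = (
        t.groupby(["sample_a", "sample_b"], as_index=False)["length"]
        .sum()
        .rename(columns={"length": "total_bp"})
    )
    pairs["fraction"] = pairs["total_bp"] / genome_size

    mid = (t["start"] + t["end"]) // 2
    inside = np.zeros(len(t), dtype=bool)
    region_bp = 0
    if regions:
        for r in regions:
            inside |= (
                (t["chrom"] == r.chrom) & (mid >= r.start) & (mid < r.end)
            ).to_numpy()
            region_bp += r.end - r.start
    li = t.loc[inside, "length"].to_numpy()
    lo = t.loc[~inside, "length"].to_numpy()
    p = (
        float(sps.mannwhitneyu(li, lo, alternative="two-sided").pvalue)
        if len(li) and len(lo)
        else float("nan")
    )

    # fraction of region bp covered by any segment vs genome-wide fraction
    def covered(mask_rows, total_bp):
        if not total_bp:
            return float("nan")
        ivs = sorted(
            (int(s), int(e)) for s, e in zip(t.loc[mask_rows, "start"], t.loc[mask_rows, "end"])
        )
        cov, last_end, last_start = 0, None, None
        for s, e in ivs:
            if last_end is None or s > last_end:
                if last_end is not None:
                    cov += last_end - last_start
                last_start, last_end = s, e
            else:
                last_end = max(last_end, e)
        if last_end is not None:
            cov += last_end - last_start
        return cov / total_bp

    return {
        "pairs": pairs,
        "median_inside": float(np.median(li)) if len(li) else float("nan"),
        "median_outside": float(np.median(lo)) if len(lo) else float("nan"),
        "p_ranksum": p,
        "region_cov_fraction": covered(inside, region_bp),
        "genome_cov_fraction": covered(np.ones(len(t), bool), genome_size),
    }


def naive_ibd_segments(
    gm, seed: int = 0, min_length: int = 1000
) -> pd.DataFrame:
    """SYNTHETIC fixture generator: maximal runs of genotype identity between
    haploidized sample pairs, at least ``min_length`` bp.  This is a toy
    stand-in for phasing-based IBD detection and is NOT equivalent to it;
    use only for constructing test inputs."""
    from .genomeio import random_haploidize

    hap = random_haploidize(gm, seed)
    pos = gm.pos
    rows = []
    n = hap.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            same = hap[:, i] == hap[:, j]
            k = 0
            while k < len(same):
                if not same[k]:
                    k += 1
                    continue
                m = k
                while m < len(same) and same[m]:
                    m += 1
                start, end = int(pos[k]), int(pos[m - 1]) + 1
                if end - start >= min_length:
                    rows.append(
                        {
                            "sample_a": gm.samples[i],
                            "sample_b": gm.samples[j],
                            "chrom": gm.chrom[k],
                            "start": start,
                            "end": end,
                        }
                    )
                k = m
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "chrom", "start", "end"])
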