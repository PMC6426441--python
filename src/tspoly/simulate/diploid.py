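"""Bridge haplotypes to diploid genotype matrices.

Individuals are formed by pairing consecutive haplotypes within each
population; with probability F = sigma/(2 - sigma) the second haplotype is
replaced by a copy of the first (instant-homozygosity approximation to
equilibrium inbreeding).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from ..genomeio import GenotypeMatrix, SampleMap
from .coalescent import HaplotypeSet


def species_of_pop(pop_label: str) -> str:
    """Map a simulation population label to its species name."""
    return pop_label.split("_")[0]


def make_diploids(
    hs: HaplotypeSet,
    selfing_rate: float | Mapping[str, float],
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    chrom: str = "chr1",
    pos_offset: int = 0,
    sample_prefix: str = "",
) -> GenotypeMatrix:
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or generator) is mandatory")
        rng = np.random.default_rng(seed)

    pops = list(dict.fromkeys(hs.pop_of.tolist()))
    cols = []
    names, species, subpops = [], [], []
    hap = hs.haplotypes
    for pop in pops:
        idx = np.flatnonzero(hs.pop_of == pop)
        if len(idx) % 2 != 0:
            raise ValueError(f"population {pop!r} has an odd haplotype count")
        idx = rng.permutation(idx)  # random union of gametes within the pool
        sigma = (
            float(selfing_rate.get(pop, 0.0))
            if isinstance(selfing_rate, Mapping)
            else float(selfing_rate)
        )
        F = sigma / (2.0 - sigma)
        for j in range(0, len(idx), 2):
            h1 = hap[idx[j]]
            h2 = h1 if rng.random() < F else hap[idx[j + 1]]
            cols.append((h1 + h2).astype(np.int8))
            names.append(f"{sample_prefix}{pop}_{j // 2:03d}")
            sp = species_of_pop(pop)
            species.append(sp)
            subpops.append(pop.split("_", 1)[1] if "_" in pop else ".")
    genotypes = (
        np.vstack(cols).T if cols else np.zeros((hs.n_sites, 0), dtype=np.int8)
    )
    sm = SampleMap(
        pd.DataFrame({"sample": names, "species": species, "population": subpops})
    )
    n = hs.n_sites
    return GenotypeMatrix(
        chrom=np.array([chrom] * n, dtype=object),
        pos=hs.positions + pos_offset,
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        genotypes=genotypes,
        sample_map=sm,
    )
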