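"""Synthetic multi-window study generator with known truth.

A "genome" is a concatenation of independently simulated 20 kb segments, a
configurable few of which carry an ancient balanced locus.  The generator
emits the joint genotype matrix (all species), a mask set, a gene table with
NLR-like clusters placed on the balanced windows, and a truth table of
balanced-region coordinates.  One root seed drives everything; each window
uses a stream derived deterministically from (seed, window index), so any
window can be re-simulated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genomeio import GenotypeMatrix, MaskSet, write_sample_map, write_vcf
from .coalescent import BalancedLocusSpec, simulate_segment
from .demography import DemographicModel, scaled_capsella_model
from .diploid import make_diploids

DEFAULT_DIPLOIDS = {"outcrosser": 8, "selfer1_E": 8, "selfer1_W": 8, "selfer2": 8}


@dataclass
class StudyConfig:
    n_windows: int = 100
    window_length: int = 20_000
    n_balanced: int = 2
    balanced_windows: list[int] | None = None
    balanced_span: int = 5  # windows per balanced region (odd); the example
    # candidate regions in the source system span hundreds of kb
    t_bal: float | None = None  # default: 5x the oldest split of the model
    class_freq: float = 0.5
    model: DemographicModel | None = None
    include_selfer2: bool = True
    n_diploids: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DIPLOIDS))
    mask_windows: list[int] = field(default_factory=list)
    chrom: str = "chr1"

    def resolve(self) -> "StudyConfig":
        model = self.model or scaled_capsella_model(include_selfer2=self.include_selfer2)
        balanced = self.balanced_windows
        if balanced is None:
            # deterministic, evenly spread placement
            if self.n_balanced > 0:
                step = self.n_windows / self.n_balanced
                balanced = sorted({int((i + 0.5) * step) for i in range(self.n_balanced)})
            else:
                balanced = []
        if len(balanced) != len(set(balanced)):
            raise ValueError("duplicate balanced window indices")
        span = int(self.balanced_span)
        if span < 1 or span % 2 == 0:
            raise ValueError("balanced_span must be a positive odd window count")
        half = span // 2
        covered: set[int] = set()
        for w in balanced:
            if not half <= w < self.n_windows - half:
                raise ValueError(
                    f"balanced window {w} leaves no room for a {span}-window footprint"
                )
            block = set(range(w - half, w + half + 1))
            if block & covered:
                raise ValueError("balanced footprints overlap")
            covered |= block
        for w in list(self.mask_windows):
            if not 0 <= w < self.n_windows:
                raise ValueError(f"window index {w} outside the genome")
        if covered & set(self.mask_windows):
            raise ValueError("a balanced window cannot also be masked")
        n_dip = {k: v for k, v in self.n_diploids.items() if k in model.labels}
        missing = [l for l in model.labels if l not in n_dip]
        if missing:
            raise ValueError(f"no sample sizes for populations {missing}")
        t_bal = self.t_bal if self.t_bal is not None else 5.0 * model.oldest_split_time
        if t_bal <= model.oldest_split_time:
            raise ValueError("t_bal must exceed the oldest split")
        return StudyConfig(
            n_windows=self.n_windows,
            window_length=self.window_length,
            n_balanced=len(balanced),
            balanced_windows=list(balanced),
            balanced_span=span,
            t_bal=t_bal,
            class_freq=self.class_freq,
            model=model,
            include_selfer2=self.include_selfer2,
            n_diploids=n_dip,
            mask_windows=list(self.mask_windows),
            chrom=self.chrom,
        )


@dataclass
class SyntheticStudy:
    gm: GenotypeMatrix
    mask: MaskSet
    genes: pd.DataFrame  # chrom start end name is_nlr
    truth: pd.DataFrame  # chrom start end window focal_pos
    ancestral: np.ndarray  # per-site 'ref' (the reference is ancestral by construction)
    config: StudyConfig
    seed: int

    def write(self, outdir) -> None:
        import pathlib

        d = pathlib.Path(outdir)
        d.mkdir(parents=True, exist_ok=True)
        write_vcf(self.gm, d / "study.vcf")
        write_sample_map(self.gm.sample_map, d / "samples.tsv")
        self.mask.write_bed(d / "mask.bed")
        self.truth.to_csv(d / "truth.tsv", sep="\t", index=False)
        with open(d / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for i, row in self.genes.iterrows():
                attr = f"ID=gene{i};Name={row['name']}"
                fh.write(
                    f"{row['chrom']}\tsynthetic\tgene\t{row['start'] + 1}\t{row['end']}\t.\t+\t.\t{attr}\n"
                )


def window_rng(seed: int, window: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(window,)))


def synthetic_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    cfg = (config or StudyConfig()).resolve()
    model = cfg.model
    Lw = cfg.window_length
    n_hap = {p: 2 * n for p, n in cfg.n_diploids.items()}
    selfing = {p.label: p.selfing_rate for p in model.populations}

    parts = []
    truth_rows = []
    half = cfg.balanced_span // 2
    # a balanced region emulates an immunity-gene (NLR-like) cluster: a run
    # of balanced_span windows, each carrying its own ancient balanced
    # polymorphism, as in multi-gene clusters under joint balancing
    # (between-window linkage is not modelled)
    covered = {
        w + d for w in cfg.balanced_windows for d in range(-half, half + 1)
    }
    for w in cfg.balanced_windows:
        truth_rows.append(
            {
                "chrom": cfg.chrom,
                "start": (w - half) * Lw,
                "end": (w + half + 1) * Lw,
                "window": w,
                "focal_pos": w * Lw + Lw // 2,
            }
        )
    for w in range(cfg.n_windows):
        rng = window_rng(seed, w)
        balanced = None
        if w in covered:
            balanced = BalancedLocusSpec(
                focal_pos=Lw // 2, t_bal=cfg.t_bal, class_freq=cfg.class_freq
            )
        hs = simulate_segment(model, n_hap, Lw, rng=rng, balanced=balanced)
        gmw = make_diploids(
            hs, selfing, rng=rng, chrom=cfg.chrom, pos_offset=w * Lw
        )
        parts.append(gmw)

    gm0 = parts[0]
    gm = GenotypeMatrix(
        chrom=np.concatenate([p.chrom for p in parts]),
        pos=np.concatenate([p.pos for p in parts]),
        ref=np.concatenate([p.ref for p in parts]),
        alt=np.concatenate([p.alt for p in parts]),
        genotypes=np.vstack([p.genotypes for p in parts]),
        sample_map=gm0.sample_map,
    )
    mask = MaskSet(
        [(cfg.chrom, w * Lw, (w + 1) * Lw) for w in cfg.mask_windows] or [],
        label="pericentromere",
    ) if cfg.mask_windows else MaskSet([], label="pericentromere")
    if cfg.mask_windows:
        gm = gm.apply_mask(mask)

    gene_rows = []
    for w in range(cfg.n_windows):
        base = w * Lw
        if w in cfg.balanced_windows:
            gene_rows.append(
                {
                    "chrom": cfg.chrom,
                    "start": base + Lw // 2 - 2000,
                    "end": base + Lw // 2 + 2000,
                    "name": f"NLR_cluster_w{w}",
                    "is_nlr": True,
                }
            )
        gene_rows.append(
            {
                "chrom": cfg.chrom,
                "start": base + 2000,
                "end": base + 5000,
                "name": f"gene_w{w}",
                "is_nlr": False,
            }
        )
    genes = pd.DataFrame(gene_rows)
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "window", "focal_pos"]
    )
    ancestral = np.full(gm.n_sites, "ref", dtype=object)
    return SyntheticStudy(gm, mask, genes, truth, ancestral, cfg, seed)
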