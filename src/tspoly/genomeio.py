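"""Genome matrix construction and standard-format IO.

Coordinates are 0-based half-open everywhere inside the package; the 1-based
convention only appears at the VCF/GFF boundary.  Genotypes are coded
0 hom-ref, 1 het, 2 hom-alt, -1 missing.  Accessibility is a per-species
boolean mask over sites rather than row deletion, so multi-species
intersections are plain logical ANDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SPECIES = ("outcrosser", "selfer1", "selfer2")
SPECIES_ALIASES = {
    "cg": "outcrosser",
    "cr": "selfer1",
    "co": "selfer2",
    "outcrosser": "outcrosser",
    "selfer1": "selfer1",
    "selfer2": "selfer2",
}


def normalize_species(name: str) -> str:
    """Map Cg/Cr/Co aliases to canonical names; other labels pass through
    unchanged (the matrix machinery is not tied to the three-species study)."""
    return SPECIES_ALIASES.get(str(name).lower(), str(name))


@dataclass
class SampleMap:
    """sample -> species / population assignment (plus optional coordinates)."""

    table: pd.DataFrame  # columns: sample, species, population, lat, lon

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample", "species", "population"}
        if not required.issubset(t.columns):
            raise ValueError(f"sample map needs columns {sorted(required)}")
        if t["sample"].duplicated().any():
            dup = t.loc[t["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r} in sample map")
        t = t.copy()
        t["species"] = [normalize_species(s) for s in t["species"]]
        for col in ("lat", "lon"):
            if col not in t.columns:
                t[col] = np.nan
        self.table = t.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def species_of(self, sample: str) -> str:
        row = self.table.loc[self.table["sample"] == sample]
        if row.empty:
            raise KeyError(f"sample {sample!r} not in sample map")
        return row["species"].iloc[0]

    def population_of(self, sample: str) -> str:
        row = self.table.loc[self.table["sample"] == sample]
        if row.empty:
            raise KeyError(f"sample {sample!r} not in sample map")
        return str(row["population"].iloc[0])


def read_sample_map(path) -> SampleMap:
    t = pd.read_csv(path, sep="\t")
    return SampleMap(t)


def write_sample_map(sm: SampleMap, path) -> None:
    sm.table.to_csv(path, sep="\t", index=False)


@dataclass
class MaskSet:
    """Genomic intervals to exclude, 0-based half-open."""

    intervals: list[tuple[str, int, int]]
    label: str = "custom"

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0 or end <= start:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        hit = np.zeros(len(pos), dtype=bool)
        for c, s, e in self.intervals:
            hit |= (chrom == c) & (pos >= s) & (pos < e)
        return hit

    @classmethod
    def read_bed(cls, path, label: str = "custom") -> "MaskSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                ivs.append((f[0], int(f[1]), int(f[2])))
        return cls(ivs, label)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e in self.intervals:
                fh.write(f"{c}\t{s}\t{e}\t{self.label}\n")


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype codes with per-species accessibility masks."""

    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int64, 0-based
    ref: np.ndarray  # (n_sites,) str
    alt: np.ndarray  # (n_sites,) str ('.' for invariant rows)
    genotypes: np.ndarray  # (n_sites, n_samples) int8
    sample_map: SampleMap
    accessible: dict[str, np.ndarray] = field(default_factory=dict)
    depth: np.ndarray | None = None
    concordance: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.pos)
        if self.genotypes.shape[0] != n:
            raise ValueError("genotypes rows must match number of sites")
        if self.genotypes.shape[1] != len(self.sample_map.samples):
            raise ValueError("genotype columns must match sample map")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        variant = self.alt != "."
        if np.any(self.ref[variant] == self.alt[variant]):
            raise ValueError("alt must differ from ref at variant rows")
        present = {self.sample_map.species_of(s) for s in self.samples}
        for sp in present:
            self.accessible.setdefault(sp, np.ones(n, dtype=bool))

    @property
    def samples(self) -> list[str]:
        return self.sample_map.samples

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def species_present(self) -> list[str]:
        seen = []
        for s in self.samples:
            sp = self.sample_map.species_of(s)
            if sp not in seen:
                seen.append(sp)
        return seen

    def columns_for(self, species: str | None = None, population: str | None = None) -> np.ndarray:
        t = self.sample_map.table
        keep = np.ones(len(t), dtype=bool)
        if species is not None:
            keep &= (t["species"] == normalize_species(species)).to_numpy()
        if population is not None:
            keep &= (t["population"].astype(str) == str(population)).to_numpy()
        return np.flatnonzero(keep)

    def subset_samples(self, cols: np.ndarray) -> "GenotypeMatrix":
        sm = SampleMap(self.sample_map.table.iloc[cols].reset_index(drop=True))
        return replace(
            self,
            genotypes=self.genotypes[:, cols],
            sample_map=sm,
            accessible={k: v.copy() for k, v in self.accessible.items()},
            depth=None if self.depth is None else self.depth[:, cols],
            concordance=None if self.concordance is None else self.concordance[:, cols],
        )

    def split_by_species(self) -> dict[str, "GenotypeMatrix"]:
        return {sp: self.subset_samples(self.columns_for(sp)) for sp in self.species_present}

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            ref=self.ref[keep],
            alt=self.alt[keep],
            genotypes=self.genotypes[keep],
            accessible={k: v[keep] for k, v in self.accessible.items()},
            depth=None if self.depth is None else self.depth[keep],
            concordance=None if self.concordance is None else self.concordance[keep],
        )

    def apply_mask(self, mask: MaskSet, species: list[str] | None = None) -> "GenotypeMatrix":
        """Set accessibility to False inside masked intervals (idempotent)."""
        hit = mask.contains(self.chrom, self.pos)
        acc = {k: v.copy() for k, v in self.accessible.items()}
        for sp in species or list(acc):
            acc[sp] = acc[sp] & ~hit
        return replace(self, accessible=acc)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, sample_map: SampleMap) -> GenotypeMatrix:
    """Read a VCF with GT (optional DP and CC FORMAT tags) into a matrix.

    Biallelic and invariant records are accepted; multiallelic records are
    excluded and counted in a warning.  Columns are ordered as in the sample
    map; every VCF sample must have a map entry.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    mapped = set(sample_map.samples)
    for s in vcf.samples:
        if s not in mapped:
            raise ValueError(f"VCF sample {s!r} missing from sample map")
    order = [vcf.samples.index(s) for s in sample_map.samples if s in vcf.samples]
    if len(order) != len(sample_map.samples):
        missing = sorted(set(sample_map.samples) - set(vcf.samples))
        raise ValueError(f"sample map entries not in VCF: {missing}")

    chroms, poss, refs, alts, rows = [], [], [], [], []
    dps, ccs = [], []
    has_dp = has_cc = True
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) > 1:
            n_multi += 1
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS - 1)
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else ".")
        gt = rec.gt_types.astype(np.int8)
        gt[gt == 3] = -1
        rows.append(gt[order])
        if has_dp:
            try:
                dp = rec.format("DP")
                dps.append(dp[order, 0].astype(float) if dp is not None else None)
                has_dp = dp is not None
            except Exception:
                has_dp = False
        if has_cc:
            try:
                cc = rec.format("CC")
                ccs.append(cc[order, 0].astype(float) if cc is not None else None)
                has_cc = cc is not None
            except Exception:
                has_cc = False
    if n_multi:
        warnings.warn(f"excluded {n_multi} multiallelic records")
    n = len(poss)
    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=(
            np.vstack(rows) if rows else np.zeros((0, len(sample_map.samples)), np.int8)
        ),
        sample_map=sample_map,
        depth=np.vstack(dps) if has_dp and dps and n else None,
        concordance=np.vstack(ccs) if has_cc and ccs and n else None,
    )
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(gm.chrom.tolist()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for i in range(gm.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in gm.genotypes[i])
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i] + 1}\t.\t{gm.ref[i]}\t{gm.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Filters


def apply_missingness_filter(gm: GenotypeMatrix, max_missing_frac: float = 0.30) -> GenotypeMatrix:
    """Mark a site inaccessible for a species when more than
    ``max_missing_frac`` of that species' samples are missing there."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    acc = {k: v.copy() for k, v in gm.accessible.items()}
    for sp in gm.species_present:
        cols = gm.columns_for(sp)
        if len(cols) == 0:
            continue
        frac = (gm.genotypes[:, cols] == -1).mean(axis=1)
        acc[sp] = acc[sp] & (frac <= max_missing_frac)
    return replace(gm, accessible=acc)


# ---------------------------------------------------------------------------
# Annotation

_BASES = "ACGT"
_CODON_TABLE = {}


def _build_codon_table() -> dict[str, str]:
    # standard nuclear genetic code, amino acids in TCAG base order
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    table = {}
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = aas[i]
                i += 1
    return table


_CODON_TABLE = _build_codon_table()
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def translate_codon(codon: str) -> str:
    return _CODON_TABLE.get(codon.upper(), "X")


def codon_degeneracy(codon: str, codon_pos: int) -> int:
    """Number of bases at ``codon_pos`` (0-2) preserving the amino acid."""
    codon = codon.upper()
    aa = translate_codon(codon)
    if aa == "X":
        return 0
    n = 0
    for b in _BASES:
        alt = codon[:codon_pos] + b + codon[codon_pos + 1 :]
        if translate_codon(alt) == aa:
            n += 1
    return n


@dataclass
class _Transcript:
    tid: str
    strand: str
    exons: list[tuple[int, int]]  # genomic 0-based half-open, sorted by start
    phase: int
    chrom: str

    def coding_positions(self) -> list[int]:
        pos = []
        for s, e in self.exons:
            pos.extend(range(s, e))
        if self.strand == "-":
            pos.reverse()
        return pos[self.phase :]


def _parse_gff(gff_path):
    cols = ["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    t = pd.read_csv(gff_path, sep="\t", comment="#", header=None, names=cols, dtype={"chrom": str})
    return t


def _attr(attrs: str, key: str) -> str | None:
    for fieldv in attrs.split(";"):
        fieldv = fieldv.strip()
        if fieldv.startswith(key + "="):
            return fieldv[len(key) + 1 :]
    return None


EFFECT_SEVERITY = {"nonsynonymous": 0, "synonymous": 1, "noncoding": 2, "NA": 3}


def annotate_sites(gm: GenotypeMatrix, fasta_path, gff_path) -> pd.DataFrame:
    """Annotate each site: genic / cds flags, fold degeneracy, ref->alt effect.

    Degeneracy comes from the standard codon table; CDS strand and phase are
    respected.  When several annotations overlap one site, the single primary
    effect is chosen by the fixed severity ranking
    nonsynonymous > synonymous > noncoding.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    gff = _parse_gff(gff_path)

    from intervaltree import IntervalTree

    gene_trees: dict[str, IntervalTree] = {}
    for _, row in gff[gff["type"].isin(["gene", "mRNA"])].iterrows():
        gene_trees.setdefault(row.chrom, IntervalTree()).addi(row.start - 1, row.end, None)

    # assemble transcripts from CDS features
    cds = gff[gff["type"] == "CDS"]
    transcripts: dict[str, _Transcript] = {}
    for _, row in cds.iterrows():
        tid = _attr(row.attributes, "Parent") or _attr(row.attributes, "ID") or "?"
        tr = transcripts.get(tid)
        if tr is None:
            phase = 0 if row.phase in (".", None) else int(row.phase)
            transcripts[tid] = tr = _Transcript(tid, row.strand, [], phase, row.chrom)
        tr.exons.append((row.start - 1, row.end))

    # per-site coding context: (chrom,pos) -> list of (codon_genomic_pos_triplet, strand, codon_offset)
    site_codons: dict[tuple[str, int], list] = {}
    for tr in transcripts.values():
        tr.exons.sort()
        coding = tr.coding_positions()
        if len(coding) % 3 != 0:
            warnings.warn(f"CDS length of {tr.tid} not divisible by 3; marking NA")
            continue
        for ci in range(0, len(coding), 3):
            triplet = coding[ci : ci + 3]
            for off in range(3):
                site_codons.setdefault((tr.chrom, triplet[off]), []).append(
                    (triplet, tr.strand, off)
                )

    n = gm.n_sites
    genic = np.zeros(n, dtype=bool)
    is_cds = np.zeros(n, dtype=bool)
    degeneracy = np.full(n, -1, dtype=np.int8)  # -1 encodes NA
    effect = np.full(n, "noncoding", dtype=object)

    for i in range(n):
        c, p = str(gm.chrom[i]), int(gm.pos[i])
        tree = gene_trees.get(c)
        if tree is not None and tree.overlaps(p):
            genic[i] = True
        ctxs = site_codons.get((c, p))
        if not ctxs:
            continue
        is_cds[i] = True
        best_eff = "NA"
        best_deg = -1
        for triplet, strand, off in ctxs:
            try:
                bases = [fa[c][q] for q in triplet]
            except KeyError:
                continue
            if strand == "-":
                codon = "".join(b.translate(_COMP) for b in bases)
                cpos = 2 - off
                refb = str(gm.ref[i]).translate(_COMP)
                altb = str(gm.alt[i]).translate(_COMP) if gm.alt[i] != "." else None
            else:
                codon = "".join(bases)
                cpos = off
                refb = str(gm.ref[i])
                altb = str(gm.alt[i]) if gm.alt[i] != "." else None
            if len(codon) != 3 or "N" in codon:
                continue
            ref_codon = codon[:cpos] + refb + codon[cpos + 1 :]
            deg = codon_degeneracy(ref_codon, cpos)
            if altb is None:
                eff = "synonymous"  # invariant site: no change
            else:
                alt_codon = codon[:cpos] + altb + codon[cpos + 1 :]
                eff = (
                    "synonymous"
                    if translate_codon(ref_codon) == translate_codon(alt_codon)
                    else "nonsynonymous"
                )
            if EFFECT_SEVERITY[eff] < EFFECT_SEVERITY[best_eff]:
                best_eff = eff
                best_deg = deg
        if best_eff != "NA":
            effect[i] = best_eff
            degeneracy[i] = best_deg
        else:
            effect[i] = "NA"

    return pd.DataFrame(
        {
            "chrom": gm.chrom,
            "pos": gm.pos,
            "genic": genic,
            "cds": is_cds,
            "degeneracy": degeneracy,
            "effect": effect,
        }
    )


# ---------------------------------------------------------------------------
# Polarization and haploidization


def polarize(gm: GenotypeMatrix, outgroup_alleles: np.ndarray) -> np.ndarray:
    """Assign per-site ancestral state from >=1 outgroup base calls.

    ``outgroup_alleles`` is (n_sites, n_outgroups) of bases; '.', 'N' or ''
    mean missing.  The ancestral allele is called only when all outgroups are
    present and agree and the shared base equals ref or alt; anything else is
    'unknown' (a policy, not an error)."""
    og = np.asarray(outgroup_alleles, dtype=object)
    if og.ndim == 1:
        og = og[:, None]
    if og.shape[0] != gm.n_sites:
        raise ValueError("outgroup call rows must match sites")
    out = np.full(gm.n_sites, "unknown", dtype=object)
    for i in range(gm.n_sites):
        calls = [str(b).upper() for b in og[i]]
        if any(b in (".", "N", "", "NONE") for b in calls):
            continue
        if len(set(calls)) != 1:
            continue
        b = calls[0]
        if b == str(gm.ref[i]).upper():
            out[i] = "ref"
        elif b == str(gm.alt[i]).upper():
            out[i] = "alt"
    return out


def random_haploidize(gm: GenotypeMatrix, seed: int) -> np.ndarray:
    """One allele per sample per site: het calls are assigned ref or alt with
    probability 1/2 under the seeded generator; hom calls map deterministically.
    Returns (n_sites, n_samples) int8 with 0 ref, 1 alt, -1 missing."""
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    g = gm.genotypes
    out = np.full(g.shape, -1, dtype=np.int8)
    out[g == 0] = 0
    out[g == 2] = 1
    het = g == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out
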