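"""Haplogroup collapsing and windowed neighbour-joining trees.

Haplotypes over marker tsSNPs are collapsed into haplogroups by
single-linkage clustering at a small Hamming radius; windowed trees are
classical neighbour-joining on Jukes-Cantor distances computed from
genotype-derived pseudo-sequences (or any supplied alignment), used to show
clustering by allelic class rather than by species inside a balanced region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Haplogroups


def collapse_haplotypes(
    marker_alleles: np.ndarray,
    samples: list[str],
    max_diff: int = 1,
) -> pd.DataFrame:
    """Cluster samples' marker-site haplotypes into haplogroups.

    ``marker_alleles`` is (n_samples, n_markers) of 0/1 with negative values
    marking incomplete calls (those samples are dropped with a warning).
    Distinct haplotype strings are single-linkage clustered at Hamming
    distance <= ``max_diff``; clusters are labelled A, B, C... by descending
    pooled sample frequency (ties by lexicographic haplotype string).
    """
    m = np.asarray(marker_alleles)
    complete = (m >= 0).all(axis=1)
    if not complete.any():
        raise ValueError("no sample has complete marker calls")
    if not complete.all():
        dropped = [s for s, ok in zip(samples, complete) if not ok]
        warnings.warn(f"dropping {len(dropped)} samples with incomplete marker calls")
    idx = np.flatnonzero(complete)
    strings = ["".join(str(int(v)) for v in m[i]) for i in idx]
    uniq = sorted(set(strings))
    # single-linkage = connected components of the <=max_diff graph
    parent = list(range(len(uniq)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            d = sum(a != b for a, b in zip(uniq[i], uniq[j]))
            if d <= max_diff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    comp_of = {s: find(k) for k, s in enumerate(uniq)}
    counts: dict[int, int] = {}
    minstr: dict[int, str] = {}
    for s in strings:
        c = comp_of[s]
        counts[c] = counts.get(c, 0) + 1
        minstr[c] = min(minstr.get(c, s), s)
    order = sorted(counts, key=lambda c: (-counts[c], minstr[c]))
    label_of = {c: chr(ord("A") + k) for k, c in enumerate(order)}
    rows = [
        {
            "sample": samples[i],
            "haplotype": s,
            "haplogroup": label_of[comp_of[s]],
        }
        for i, s in zip(idx, strings)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distances


def jc_distance(p_mismatch: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3); NA at saturation."""
    if p_mismatch < 0:
        raise ValueError("mismatch fraction must be >= 0")
    if p_mismatch >= 0.75:
        warnings.warn("mismatch fraction at or beyond JC saturation (0.75)")
        return float("nan")
    if p_mismatch == 0:
        return 0.0
    return -0.75 * math.log1p(-(4.0 / 3.0) * p_mismatch)


# ---------------------------------------------------------------------------
# Neighbour joining


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(f"{c._nwk()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between all leaf pairs."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node):
            if node.is_leaf():
                return {node.name: 0.0}
            acc: dict[str, float] = {}
            for child, bl in node.children:
                sub = walk(child)
                sub = {k: v + bl for k, v in sub.items()}
                for k1, v1 in acc.items():
                    for k2, v2 in sub.items():
                        dists[tuple(sorted((k1, k2)))] = v1 + v2
                acc.update(sub)
            return acc

        walk(self)
        return dists

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions (as the smaller-side frozensets by
        canonical form) defining the unrooted topology."""
        all_leaves = frozenset(self.leaves())
        parts: set[frozenset] = set()

        def walk(node):
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                sub = walk(child)
                if 1 < len(sub) < len(all_leaves) - 1:
                    parts.add(min(sub, all_leaves - sub, key=lambda s: sorted(s)))
                below = below | sub
            return below

        walk(self)
        return parts


def nj_tree(dm: np.ndarray, labels: list[str]) -> TreeNode:
    """Canonical neighbour joining with deterministic tie-breaking.

    Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k); the minimal-Q
    pair joins (ties by lexicographic label pair); branch lengths follow the
    standard update, negative lengths are clamped to 0 with the deficit
    moved to the sister branch.
    """
    d = np.asarray(dm, dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise ValueError("distance matrix and labels disagree")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(name=l) for l in labels]
    names = list(labels)
    d = d.copy()

    while len(nodes) > 3:
        r = len(nodes)
        sums = d.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, *sorted((names[i], names[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        bi = 0.5 * dij + (sums[i] - sums[j]) / (2.0 * (r - 2))
        bj = dij - bi
        if bi < 0:
            bj += -bi  # transfer the deficit to the sister branch
            bi = 0.0
        if bj < 0:
            bi += -bj
            bj = 0.0
        new = TreeNode(children=[(nodes[i], bi), (nodes[j], bj)])
        dnew = 0.5 * (d[:, i] + d[:, j] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                d2[a, b] = d[ka, kb]
            d2[a, -1] = d2[-1, a] = max(dnew[ka], 0.0)
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(n for n in (names[i], names[j]))]
        d = d2

    # resolve the final three nodes with the three-point formulas
    a, b, c = 0, 1, 2
    ba = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    bb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    bc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lens = [ba, bb, bc]
    for k in range(3):
        if lens[k] < 0:
            deficit = -lens[k]
            lens[k] = 0.0
            for m in range(3):
                if m != k:
                    lens[m] += deficit / 2.0
    return TreeNode(children=[(nodes[0], lens[0]), (nodes[1], lens[1]), (nodes[2], lens[2])])


# ---------------------------------------------------------------------------
# Window trees


def window_trees(
    alleles: np.ndarray,
    positions: np.ndarray,
    samples: list[str],
    length: int,
    window: int = 1000,
    haplogroup_of: dict[str, str] | None = None,
    min_informative: int = 2,
) -> pd.DataFrame:
    """Per 1 kb window: JC distance matrix, NJ tree (newick) and mean
    between-haplogroup per-bp divergence.  Windows with fewer than
    ``min_informative`` segregating sites get no tree and NA divergence.
    """
    h = np.asarray(alleles)
    pos = np.asarray(positions)
    rows = []
    for start in range(0, length, window):
        end = min(start + window, length)
        sel = (pos >= start) & (pos < end)
        sub = h[:, sel] if h.ndim == 2 else h[sel]
        wlen = end - start
        p_seg = sub.mean(axis=0)
        n_inf = int(((p_seg > 0) & (p_seg < 1)).sum())
        nwk = None
        divergence = float("nan")
        if n_inf >= min_informative:
            n = len(samples)
            dm = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    p = float((sub[i] != sub[j]).sum()) / wlen
                    dm[i, j] = dm[j, i] = jc_distance(p) if p < 0.75 else 3.0
            if n >= 3:
                nwk = nj_tree(dm, samples).newick()
            if haplogroup_of is not None:
                diffs = []
                for i in range(n):
                    for j in range(i + 1, n):
                        gi = haplogroup_of.get(samples[i])
                        gj = haplogroup_of.get(samples[j])
                        if gi is not None and gj is not None and gi != gj:
                            diffs.append(float((sub[i] != sub[j]).sum()) / wlen)
                if diffs:
                    divergence = float(np.mean(diffs))
        rows.append(
            {
                "start": start,
                "end": end,
                "n_informative": n_inf,
                "tree": nwk,
                "between_group_divergence": divergence,
            }
        )
    return pd.DataFrame(rows)
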