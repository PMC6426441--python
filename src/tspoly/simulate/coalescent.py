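"""Hudson-style coalescent with recombination, demography and balanced loci.

Lineages carry their true ancestral material as segment lists with
per-segment descendant counts; material that reaches its local MRCA is
retired, so the event loop and the mutation pass only ever touch genealogy
that can produce segregating sites.  Events (coalescence within a
population, recombination, migration, allelic-class switching) compete as
exponential clocks between deterministic demographic events (splits,
size-epoch boundaries, migration-epoch boundaries, the balancing time).
Mutations are dropped as a Poisson process under infinite sites and
discretised to integer base-pair positions, re-drawing position collisions.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .demography import DemographicModel

MAX_EVENTS = 2_000_000


@dataclass
class BalancedLocusSpec:
    """An ancient balanced polymorphism to inject into a segment.

    Two allelic classes segregate at ``focal_pos``; lineages coalesce only
    within their class until ``t_bal`` generations ago, far above the species
    split, when the classes merge.  ``class_freq`` is the frequency of class
    A, either one number for all populations or a mapping per population
    label (populations not listed fall back to ``default_freq``).
    """

    focal_pos: int
    t_bal: float
    class_freq: float | Mapping[str, float] = 0.5
    default_freq: float = 0.5

    def freq(self, pop: str) -> float:
        if isinstance(self.class_freq, Mapping):
            f = float(self.class_freq.get(pop, self.default_freq))
        else:
            f = float(self.class_freq)
        if not 0.0 < f < 1.0:
            raise ValueError("class frequencies must be in (0, 1)")
        return f


@dataclass
class HaplotypeSet:
    """Binary haplotypes at segregating sites of one simulated segment."""

    L: int
    positions: np.ndarray  # int64, sorted, in [0, L)
    haplotypes: np.ndarray  # (n_hap, n_sites) int8, 1 = derived
    pop_of: np.ndarray  # (n_hap,) population labels
    truth: dict = field(default_factory=dict)

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


def _masks_to_matrix(masks: list[int], n_hap: int) -> np.ndarray:
    if not masks:
        return np.zeros((n_hap, 0), dtype=np.int8)
    nbytes = (n_hap + 7) // 8
    buf = b"".join(m.to_bytes(nbytes, "little") for m in masks)
    arr = np.frombuffer(buf, dtype=np.uint8).reshape(len(masks), nbytes)
    bits = np.unpackbits(arr, axis=1, bitorder="little")[:, :n_hap]
    return np.ascontiguousarray(bits.T).astype(np.int8)


def _merge_segments(a: list, b: list, n_full: int) -> list:
    """Union of two ancestral segment lists, summing descendant counts in
    overlaps and retiring parts that reach the local MRCA (count n_full)."""
    bounds = sorted({x for l, r, _ in a for x in (l, r)} | {x for l, r, _ in b for x in (l, r)})
    out: list[list] = []
    ia = ib = 0
    for x1, x2 in zip(bounds, bounds[1:]):
        c = 0
        while ia < len(a) and a[ia][1] <= x1:
            ia += 1
        if ia < len(a) and a[ia][0] <= x1 < a[ia][1]:
            c += a[ia][2]
        while ib < len(b) and b[ib][1] <= x1:
            ib += 1
        if ib < len(b) and b[ib][0] <= x1 < b[ib][1]:
            c += b[ib][2]
        if 0 < c < n_full:
            if out and out[-1][1] == x1 and out[-1][2] == c:
                out[-1][1] = x2
            else:
                out.append([x1, x2, c])
    return [(l, r, c) for l, r, c in out]


def _split_segments(segs: list, b: float) -> tuple[list, list]:
    left, right = [], []
    for l, r, c in segs:  # noqa: E741
        if r <= b:
            left.append((l, r, c))
        elif l >= b:
            right.append((l, r, c))
        else:
            left.append((l, b, c))
            right.append((b, r, c))
    return left, right


class _Lineage:
    __slots__ = ("node", "segs", "pop", "cls")

    def __init__(self, node, segs, pop, cls):
        self.node = node
        self.segs = segs  # list of (left, right, n_descendants)
        self.pop = pop
        self.cls = cls  # 0 / 1 / None (unconstrained fragment)

    @property
    def left(self):
        return self.segs[0][0]

    @property
    def right(self):
        return self.segs[-1][1]

    def covers(self, x: float) -> bool:
        return any(l <= x < r for l, r, _ in self.segs)


class _Engine:
    """One segment simulation; single use."""

    def __init__(self, model, n_per_pop, L, rng, balanced):
        self.model = model
        self.L = float(L)
        self.rng = rng
        self.balanced = balanced
        self.t_bal = balanced.t_bal if balanced is not None else math.inf
        if balanced is not None:
            if not 0 <= balanced.focal_pos < L:
                raise ValueError("focal_pos must lie within the segment")
            if balanced.t_bal <= model.oldest_split_time:
                raise ValueError("t_bal must exceed the oldest split time")
        for lab in n_per_pop:
            if lab not in model.labels:
                raise KeyError(f"unknown population {lab!r}")

        self.lineages: list[_Lineage] = []
        self.pop_of: list[str] = []
        node = 0
        for lab, n in n_per_pop.items():
            n = int(n)
            if balanced is not None and n >= 2:
                f = balanced.freq(lab)
                n_a = min(max(int(round(f * n)), 1), n - 1)
            else:
                n_a = n
            for i in range(n):
                cls = 0 if (balanced is None or i < n_a) else 1
                self.lineages.append(_Lineage(node, [(0.0, self.L, 1)], lab, cls))
                self.pop_of.append(lab)
                node += 1
        self.n_hap = node
        self.node_time: list[float] = [0.0] * node
        self.next_node = node
        self.edges: list[tuple] = []  # (parent, child, left, right, tc, tp)
        self.breakpoints: list[float] = []
        self.focal = float(balanced.focal_pos) + 0.5 if balanced is not None else None

        times = set()
        for s in model.splits:
            times.add(s.time)
        for p in model.populations:
            for t0, _ in p.sizes:
                if t0 > 0:
                    times.add(t0)
        for m in model.migration_epochs:
            times.add(m.start)
            times.add(m.end)
        if balanced is not None:
            times.add(balanced.t_bal)
        self.schedule = sorted(t for t in times if t > 0)
        self._r_eff = {p.label: model.effective_recombination(p.label) for p in model.populations}
        self._pop = {p.label: p for p in model.populations}
        # beyond ~2 expected class switches before t_bal, linkage to the
        # focal allele is gone and the class constraint is vacuous: such
        # fragments carry label None and coalesce freely
        self._d_free = {}
        if balanced is not None:
            for p in model.populations:
                r_eff = self._r_eff[p.label]
                self._d_free[p.label] = (
                    2.0 / (r_eff * balanced.t_bal) if r_eff > 0 else math.inf
                )

    # -- event helpers -------------------------------------------------

    def _apply_fixed(self, t: float) -> None:
        for s in self.model.splits:
            if s.time == t:
                for lin in self.lineages:
                    if lin.pop == s.derived:
                        lin.pop = s.ancestral
        if self.balanced is not None and t == self.t_bal:
            for lin in self.lineages:
                lin.cls = 0
            self.balanced = None  # classes merged; no further switching

    def _coalesce_pair(self, ia: int, ib: int, t: float) -> None:
        a = self.lineages[ia]
        b = self.lineages[ib]
        parent = self.next_node
        self.next_node += 1
        self.node_time.append(t)
        for child in (a, b):
            tc = self.node_time[child.node]
            for l, r, _ in child.segs:  # noqa: E741
                self.edges.append((parent, child.node, l, r, tc, t))
        segs = _merge_segments(a.segs, b.segs, self.n_hap)
        cls = a.cls if a.cls is not None else b.cls
        pop = a.pop
        for idx in sorted((ia, ib), reverse=True):
            self.lineages.pop(idx)
        if segs:
            self.lineages.append(_Lineage(parent, segs, pop, cls))

    def _coalesce(self, group: list[int], t: float) -> None:
        k = len(group)
        i = int(self.rng.integers(k))
        j = int(self.rng.integers(k - 1))
        if j >= i:
            j += 1
        self._coalesce_pair(group[i], group[j], t)

    def _coalesce_mixed(self, payload, t: float) -> None:
        """A pair involving at least one unconstrained (None-class) lineage."""
        none_idx, labeled_idx = payload
        kn, kl = len(none_idx), len(labeled_idx)
        nn_pairs = kn * (kn - 1) // 2
        u = int(self.rng.integers(nn_pairs + kn * kl))
        if u < nn_pairs:
            i = int(self.rng.integers(kn))
            j = int(self.rng.integers(kn - 1))
            if j >= i:
                j += 1
            self._coalesce_pair(none_idx[i], none_idx[j], t)
        else:
            i = int(self.rng.integers(kn))
            j = int(self.rng.integers(kl))
            self._coalesce_pair(none_idx[i], labeled_idx[j], t)

    def _fragment_label(self, segs: list, pop: str, current):
        if self.balanced is None or current is None:
            return current
        left, right = segs[0][0], segs[-1][1]
        if left <= self.focal < right:
            return current
        gap = left - self.focal if self.focal < left else self.focal - right
        if gap > self._d_free.get(pop, math.inf):
            return None
        # re-attached to a random background chromosome of this population
        return 0 if self.rng.random() < self.balanced.freq(pop) else 1

    def _recombine(self, idx: int, t: float) -> None:
        lin = self.lineages[idx]
        b = lin.left + self.rng.random() * (lin.right - lin.left)
        left, right = _split_segments(lin.segs, b)
        if not left or not right:
            return  # breakpoint fell in a material gap at an edge
        self.breakpoints.append(b)
        cls_left = cls_right = lin.cls
        if self.balanced is not None and lin.cls is not None:
            if self.focal is not None and self.focal < b:
                cls_right = self._fragment_label(right, lin.pop, lin.cls)
            else:
                cls_left = self._fragment_label(left, lin.pop, lin.cls)
        self.lineages[idx] = _Lineage(lin.node, left, lin.pop, cls_left)
        self.lineages.append(_Lineage(lin.node, right, lin.pop, cls_right))

    # -- main loop ------------------------------------------------------

    def run(self) -> None:
        rng = self.rng
        model = self.model
        t = 0.0
        sched_i = 0
        events = 0
        mig_by_dest: dict[str, list] = {}
        for m in model.migration_epochs:
            mig_by_dest.setdefault(m.dest, []).append(m)

        while len(self.lineages) > 1:
            events += 1
            if events > MAX_EVENTS:
                raise RuntimeError("model did not coalesce within the event budget")

            balanced_active = self.balanced is not None and t < self.t_bal
            rates: list[tuple[float, str, object]] = []
            if balanced_active:
                by_pop: dict[str, tuple[list, list, list]] = {}
                for i, lin in enumerate(self.lineages):
                    g = by_pop.setdefault(lin.pop, ([], [], []))
                    g[2 if lin.cls is None else lin.cls].append(i)
                for pop, (g0, g1, gn) in by_pop.items():
                    ne = self._pop[pop].effective_size_at(t)
                    f = self.balanced.freq(pop)
                    for idxs, frac in ((g0, f), (g1, 1.0 - f)):
                        k = len(idxs)
                        if k >= 2:
                            rates.append(
                                (k * (k - 1) / 2.0 / (2.0 * ne * frac), "coal", idxs)
                            )
                    kn, kl = len(gn), len(g0) + len(g1)
                    pairs = kn * (kn - 1) / 2.0 + kn * kl
                    if pairs > 0:
                        rates.append((pairs / (2.0 * ne), "coal_mixed", (gn, g0 + g1)))
            else:
                groups: dict[str, list[int]] = {}
                for i, lin in enumerate(self.lineages):
                    groups.setdefault(lin.pop, []).append(i)
                for pop, idxs in groups.items():
                    k = len(idxs)
                    if k >= 2:
                        ne = self._pop[pop].effective_size_at(t)
                        rates.append((k * (k - 1) / 2.0 / (2.0 * ne), "coal", idxs))
            if model.rho > 0:
                for i, lin in enumerate(self.lineages):
                    r_eff = self._r_eff[lin.pop]
                    span = lin.right - lin.left
                    if r_eff > 0 and span > 0:
                        rates.append((r_eff * span, "rec", i))
            if balanced_active and model.rho > 0:
                for i, lin in enumerate(self.lineages):
                    if lin.cls is None:
                        continue  # unconstrained fragment: no class to switch
                    r_eff = self._r_eff[lin.pop]
                    if r_eff <= 0:
                        continue
                    if lin.left <= self.focal < lin.right:
                        continue  # carries the focal site; class is pinned
                    gap = (
                        lin.left - self.focal
                        if self.focal < lin.left
                        else self.focal - lin.right
                    )
                    if gap > 0:
                        rates.append((r_eff * gap, "switch", i))
            for dest, epochs in mig_by_dest.items():
                k = sum(1 for lin in self.lineages if lin.pop == dest)
                if k == 0:
                    continue
                for m in epochs:
                    if m.start <= t < m.end and m.rate > 0:
                        rates.append((k * m.rate, "mig", m))

            total = sum(r for r, _, _ in rates)
            next_fixed = self.schedule[sched_i] if sched_i < len(self.schedule) else math.inf
            if total <= 0:
                if math.isinf(next_fixed):
                    raise RuntimeError("model cannot coalesce: no events possible")
                t = next_fixed
                self._apply_fixed(t)
                sched_i += 1
                continue
            dt = rng.exponential(1.0 / total)
            if t + dt >= next_fixed:
                t = next_fixed
                self._apply_fixed(t)
                sched_i += 1
                continue
            t += dt

            u = rng.random() * total
            acc = 0.0
            for r, kind, payload in rates:
                acc += r
                if u <= acc:
                    break
            if kind == "coal":
                self._coalesce(payload, t)
            elif kind == "coal_mixed":
                self._coalesce_mixed(payload, t)
            elif kind == "rec":
                self._recombine(payload, t)
            elif kind == "switch":
                lin = self.lineages[payload]
                f = self.balanced.freq(lin.pop)
                lin.cls = 0 if rng.random() < f else 1
            else:  # migration: one lineage in dest traces back to source
                cand = [i for i, lin in enumerate(self.lineages) if lin.pop == payload.dest]
                lin = self.lineages[cand[rng.integers(len(cand))]]
                lin.pop = payload.source

    # -- mutation dropping ----------------------------------------------

    def drop_mutations(self, reserved: set[int]) -> list[tuple[int, int]]:
        """Poisson mutations on edges; returns (int position, leaf bitmask).

        Edges only cover true ancestral material below local MRCAs, so every
        accepted mutation is segregating.  Mutations are grouped by
        breakpoint interval; within one interval the marginal tree is fixed,
        so all leaf masks come from one pass over the interval's edges in
        ascending node id (children always precede their parents)."""
        rng = self.rng
        mu = self.model.mu
        if not self.edges:
            return []
        edges = self.edges
        e_l = np.array([e[2] for e in edges])
        e_r = np.array([e[3] for e in edges])
        e_child = np.array([e[1] for e in edges])
        e_parent = np.array([e[0] for e in edges])
        areas = (e_r - e_l) * np.array([e[5] - e[4] for e in edges])
        total_area = float(areas.sum())
        k = rng.poisson(mu * total_area)
        if k == 0:
            return []
        cum = np.cumsum(areas)
        eidx = np.searchsorted(cum, rng.random(k) * total_area, side="right")
        bps = sorted(self.breakpoints)

        used = set(reserved)
        muts: list[tuple[int, float, int, int]] = []
        for j in range(k):
            e = edges[eidx[j]]
            pos = None
            for _ in range(64):
                x = e[2] + rng.random() * (e[3] - e[2])
                p = int(x)
                if p not in used:
                    pos = p
                    break
            if pos is None:
                continue
            used.add(pos)
            muts.append((bisect_right(bps, x), x, int(e[1]), pos))

        full = (1 << self.n_hap) - 1
        out: list[tuple[int, int]] = []
        by_iv: dict[int, list] = {}
        for iv, x, child, pos in muts:
            by_iv.setdefault(iv, []).append((x, child, pos))
        order = np.argsort(e_parent, kind="stable")
        for iv, items in by_iv.items():
            x0 = items[0][0]
            sel = order[((e_l <= x0) & (x0 < e_r))[order]]
            masks: dict[int, int] = {}
            for j in sel:
                c = int(e_child[j])
                p = int(e_parent[j])
                cm = (1 << c) if c < self.n_hap else masks.get(c, 0)
                masks[p] = masks.get(p, 0) | cm
            for x, child, pos in items:
                m = (1 << child) if child < self.n_hap else masks.get(child, 0)
                if 0 < m < full:
                    out.append((pos, m))
        return out


def simulate_segment(
    model: DemographicModel,
    n_per_pop: Mapping[str, int],
    L: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    balanced: BalancedLocusSpec | None = None,
) -> HaplotypeSet:
    """Simulate one segment of length ``L`` bp under ``model``.

    ``n_per_pop`` maps population label to number of sampled haplotypes.
    Exactly one of ``seed`` / ``rng`` must be provided: the generator drives
    every random choice, so a fixed seed reproduces the segment exactly.
    """
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or generator) is mandatory")
        rng = np.random.default_rng(seed)
    eng = _Engine(model, dict(n_per_pop), L, rng, balanced)
    eng.run()
    reserved = set()
    if balanced is not None:
        reserved.add(int(balanced.focal_pos))
    muts = eng.drop_mutations(reserved)
    if balanced is not None:
        # class A = the initially assigned class-0 sample lineages
        mask = 0
        node = 0
        for lab, n in n_per_pop.items():
            n = int(n)
            f = balanced.freq(lab)
            n_a = min(max(int(round(f * n)), 1), n - 1) if n >= 2 else n
            for i in range(n):
                if i < n_a:
                    mask |= 1 << node
                node += 1
        muts.append((int(balanced.focal_pos), mask))
    muts.sort()
    positions = np.array([p for p, _ in muts], dtype=np.int64)
    hap = _masks_to_matrix([m for _, m in muts], eng.n_hap)
    truth = {"seed": seed, "balanced": balanced}
    return HaplotypeSet(int(L), positions, hap, np.array(eng.pop_of, dtype=object), truth)


def simulate_balanced_segment(
    model: DemographicModel,
    spec: BalancedLocusSpec,
    n_per_pop: Mapping[str, int],
    L: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> HaplotypeSet:
    """Segment with an ancient balanced polymorphism at ``spec.focal_pos``."""
    return simulate_segment(model, n_per_pop, L, seed, rng=rng, balanced=spec)
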