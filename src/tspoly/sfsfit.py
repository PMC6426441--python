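"""Joint folded site-frequency spectra and desk-scale demographic fitting.

The observed joint minor-allele spectrum is built from four-fold degenerate
(or otherwise neutral) sites with complete calls, counting one allele per
selfing individual and both alleles per outcrossing individual.  The
expected spectrum under a demographic model is estimated by simulating many
unlinked segments with the package's own coalescent; fitting maximises the
multinomial composite log-likelihood with a bounded derivative-free simplex
search, using common random numbers so the objective surface is
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .simulate.coalescent import simulate_segment
from .simulate.demography import DemographicModel


@dataclass
class JointSFS:
    counts: np.ndarray  # (nA+1, nB+1) folded joint minor-allele counts
    nA: int  # allele copies sampled in pop A
    nB: int
    popA: str = "A"
    popB: str = "B"

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def fold_cell(i: int, j: int, nA: int, nB: int) -> tuple[int, int]:
    """Map a derived-count cell to its joint minor-allele cell."""
    tot = i + j
    n = nA + nB
    if tot > n - tot or (tot * 2 == n and i > nA - i):
        return nA - i, nB - j
    return i, j


def fold_joint(counts: np.ndarray) -> np.ndarray:
    """Fold a derived-count joint SFS to minor-allele convention (idempotent)."""
    nA = counts.shape[0] - 1
    nB = counts.shape[1] - 1
    out = np.zeros_like(counts, dtype=float)
    for i in range(nA + 1):
        for j in range(nB + 1):
            fi, fj = fold_cell(i, j, nA, nB)
            out[fi, fj] += counts[i, j]
    return out


def joint_sfs(
    gm,
    popA: tuple[str, str | None],
    popB: tuple[str, str | None],
    selfing_species: set[str] = frozenset({"selfer1", "selfer2"}),
    site_filter: np.ndarray | None = None,
) -> JointSFS:
    """Observed folded joint SFS for two populations.

    ``popA``/``popB`` are (species, population) selectors.  Selfing species
    contribute one allele per individual; their heterozygous calls are
    ignored, which at the site level means sites with any het or missing
    call in either population are dropped ("complete information").
    ``site_filter`` optionally restricts sites (e.g. four-fold degenerate).
    """
    import warnings

    cols = {}
    is_selfer = {}
    for key, (sp, pop) in (("A", popA), ("B", popB)):
        cols[key] = gm.columns_for(sp, pop)
        is_selfer[key] = sp in selfing_species
    keep = np.ones(gm.n_sites, dtype=bool)
    if site_filter is not None:
        keep &= np.asarray(site_filter, dtype=bool)
    gA = gm.genotypes[:, cols["A"]]
    gB = gm.genotypes[:, cols["B"]]
    for g, key in ((gA, "A"), (gB, "B")):
        keep &= (g >= 0).all(axis=1)
        if is_selfer[key]:
            keep &= (g != 1).all(axis=1)
    gA, gB = gA[keep], gB[keep]

    def copies(g, selfer):
        if selfer:
            return (g // 2).sum(axis=1), g.shape[1]
        return g.sum(axis=1), 2 * g.shape[1]

    cA, nA = copies(gA, is_selfer["A"])
    cB, nB = copies(gB, is_selfer["B"])
    counts = np.zeros((nA + 1, nB + 1))
    np.add.at(counts, (cA, cB), 1.0)
    counts = fold_joint(counts)
    if counts.sum() == 0:
        warnings.warn("no qualifying sites for the joint SFS")
    return JointSFS(counts, nA, nB, str(popA), str(popB))


def expected_sfs(
    model: DemographicModel,
    n_sims: int,
    sample_sizes: dict[str, int],
    seed: int,
    segment_length: int = 2000,
    max_segments: int = 200_000,
) -> JointSFS:
    """Monte-Carlo expectation of the folded joint SFS under ``model``.

    Unlinked (recombination-free) segments are simulated until at least
    ``n_sims`` segregating sites have accumulated; empty cells get a 0.5
    pseudo-count before normalisation over polymorphic cells.
    """
    pops = list(sample_sizes)
    if len(pops) != 2:
        raise ValueError("expected_sfs works on two sampled populations")
    nA, nB = sample_sizes[pops[0]], sample_sizes[pops[1]]
    m0 = model.with_overrides(rho=0.0)
    counts = np.zeros((nA + 1, nB + 1))
    rng = np.random.default_rng(seed)
    got = 0
    for k in range(max_segments):
        hs = simulate_segment(m0, sample_sizes, segment_length, rng=rng)
        if hs.n_sites == 0:
            continue
        a_idx = hs.pop_of == pops[0]
        b_idx = hs.pop_of == pops[1]
        cA = hs.haplotypes[a_idx].sum(axis=0)
        cB = hs.haplotypes[b_idx].sum(axis=0)
        np.add.at(counts, (cA, cB), 1.0)
        got += hs.n_sites
        if got >= n_sims:
            break
    counts = fold_joint(counts)
    counts[0, 0] = 0.0
    poly = np.ones_like(counts, dtype=bool)
    poly[0, 0] = False
    counts[poly & (counts == 0)] = 0.5
    probs = counts / counts[poly].sum()
    return JointSFS(probs, nA, nB, pops[0], pops[1])


def composite_loglik(observed: JointSFS, expected: JointSFS) -> float:
    """Multinomial composite log-likelihood sum m_i log p_i over polymorphic cells."""
    if observed.counts.shape != expected.counts.shape:
        raise ValueError("observed and expected SFS dimensions differ")
    m = observed.counts.copy()
    p = expected.counts
    m[0, 0] = 0.0
    used = m > 0
    if not used.any():
        return 0.0
    if np.any(p[used] <= 0):
        raise ValueError("expected SFS has zero mass in an observed cell")
    return float(np.sum(m[used] * np.log(p[used])))


@dataclass
class FitResult:
    params: dict[str, float]
    loglik: float
    aic: float
    converged: bool
    n_evaluations: int
    bootstrap_ci: dict[str, tuple[float, float]] | None = None
    starts: list[dict] = field(default_factory=list)


def fit_model(
    observed: JointSFS,
    model_factory,
    bounds: dict[str, tuple[float, float]],
    sample_sizes: dict[str, int],
    n_starts: int = 3,
    seed: int = 0,
    n_sims: int = 10_000,
    max_iter: int = 60,
    n_boot: int = 0,
) -> FitResult:
    """Maximise the composite likelihood over <= 6 free parameters.

    ``model_factory(**params)`` must return a DemographicModel.  The search
    is a bounded Nelder-Mead simplex on log10-transformed parameters from
    ``n_starts`` seeded starts; the expectation uses a fixed seed per
    evaluation (common random numbers), making the objective deterministic.
    Optional parametric bootstrap refits ``n_boot`` simulated datasets at
    the point estimate and reports percentile confidence intervals.
    """
    names = list(bounds)
    if len(names) > 6:
        raise ValueError("at most 6 free parameters at desk scale")
    lo = np.log10([bounds[k][0] for k in names])
    hi = np.log10([bounds[k][1] for k in names])
    if np.any(lo > hi):
        raise ValueError("bounds must satisfy lo <= hi")
    rng = np.random.default_rng(seed)
    obj_seed = int(rng.integers(2**31 - 1))
    n_eval = 0

    def objective(x, obs):
        nonlocal n_eval
        n_eval += 1
        x = np.clip(x, lo, hi)
        params = {k: float(10**v) for k, v in zip(names, x)}
        model = model_factory(**params)
        exp = expected_sfs(model, n_sims, sample_sizes, seed=obj_seed)
        return -composite_loglik(obs, exp)

    if np.all(lo == hi):
        point = {k: float(10**v) for k, v in zip(names, lo)}
        ll = -objective(lo, observed)
        return FitResult(point, ll, 2 * len(names) - 2 * ll, True, n_eval)

    starts = [0.5 * (lo + hi)]
    for _ in range(n_starts - 1):
        starts.append(lo + rng.random(len(names)) * (hi - lo))

    def run_fit(obs):
        best = None
        records = []
        for x0 in starts:
            res = minimize(
                objective,
                x0,
                args=(obs,),
                method="Nelder-Mead",
                options={"maxiter": max_iter, "xatol": 0.01, "fatol": 0.5},
            )
            x = np.clip(res.x, lo, hi)
            rec = {
                "params": {k: float(10**v) for k, v in zip(names, x)},
                "loglik": -float(res.fun),
                "converged": bool(res.success or res.fun < np.inf),
            }
            records.append(rec)
            if best is None or rec["loglik"] > best["loglik"]:
                best = rec
        return best, records

    best, records = run_fit(observed)
    k = len(names)
    result = FitResult(
        best["params"],
        best["loglik"],
        2 * k - 2 * best["loglik"],
        best["converged"],
        n_eval,
        starts=records,
    )
    if n_boot > 0:
        fitted = model_factory(**best["params"])
        total = int(observed.total)
        boots: dict[str, list[float]] = {k_: [] for k_ in names}
        for b in range(n_boot):
            bseed = int(rng.integers(2**31 - 1))
            exp = expected_sfs(fitted, n_sims, sample_sizes, seed=bseed)
            probs = exp.counts.ravel()
            draw = np.random.default_rng(bseed + 1).multinomial(total, probs / probs.sum())
            obs_b = JointSFS(draw.reshape(exp.counts.shape).astype(float), exp.nA, exp.nB)
            bb, _ = run_fit(obs_b)
            for k_ in names:
                boots[k_].append(bb["params"][k_])
        result.bootstrap_ci = {
            k_: (
                float(np.percentile(boots[k_], 2.5)),
                float(np.percentile(boots[k_], 97.5)),
            )
            for k_ in names
        }
    return result
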