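"""Demographic models: populations, splits, migration epochs, selfing.

Times are in generations before present (backward in time), sizes are diploid
effective sizes.  A model must form a single tree of splits so that every
lineage can ultimately coalesce in the root population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class Population:
    """One population with a piecewise-constant size trajectory.

    ``sizes`` is a list of ``(start_time, diploid_Ne)`` epochs sorted by
    start time; the first entry must start at 0.  ``selfing_rate`` is the
    fraction of self-fertilisation sigma in [0, 1].
    """

    label: str
    sizes: list[tuple[float, float]] = field(default_factory=list)
    selfing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.sizes:
            raise ValueError(f"population {self.label!r} has no size epochs")
        self.sizes = sorted(self.sizes)
        if self.sizes[0][0] != 0:
            raise ValueError(f"population {self.label!r}: first epoch must start at t=0")
        if any(n <= 0 for _, n in self.sizes):
            raise ValueError(f"population {self.label!r}: sizes must be > 0")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")

    @property
    def inbreeding_coefficient(self) -> float:
        """Equilibrium F = sigma / (2 - sigma)."""
        return self.selfing_rate / (2.0 - self.selfing_rate)

    def size_at(self, t: float) -> float:
        n = self.sizes[0][1]
        for start, size in self.sizes:
            if start <= t:
                n = size
            else:
                break
        return n

    def effective_size_at(self, t: float) -> float:
        return self.size_at(t) / (1.0 + self.inbreeding_coefficient)


@dataclass
class Split:
    """Backward in time, lineages of ``derived`` move into ``ancestral`` at ``time``."""

    time: float
    derived: str
    ancestral: str


@dataclass
class MigrationEpoch:
    """Forward-time migration from ``source`` into ``dest`` at per-generation
    migrant fraction ``rate``, active on [start, end) generations before present.

    Backward in time a lineage currently in ``dest`` traces back to ``source``
    at rate ``rate`` per generation.
    """

    start: float
    end: float
    source: str
    dest: str
    rate: float


@dataclass
class DemographicModel:
    populations: list[Population]
    splits: list[Split] = field(default_factory=list)
    migration_epochs: list[MigrationEpoch] = field(default_factory=list)
    mu: float = 7e-9
    rho: float = 3.6e-8  # crossovers / bp / generation

    def __post_init__(self) -> None:
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        self.splits = sorted(self.splits, key=lambda s: s.time)
        for s in self.splits:
            if s.time < 0:
                raise ValueError("split times must be >= 0")
            if s.derived not in labels or s.ancestral not in labels:
                raise ValueError(f"split references unknown population: {s}")
        for m in self.migration_epochs:
            if not (0 <= m.start < m.end):
                raise ValueError("migration epoch must satisfy 0 <= start < end")
            if m.source not in labels or m.dest not in labels:
                raise ValueError(f"migration epoch references unknown population: {m}")
            if m.rate < 0:
                raise ValueError("migration rate must be >= 0")
        if self.mu <= 0 or self.rho < 0:
            raise ValueError("mu must be > 0 and rho >= 0")
        # the model must coalesce: splits must form a tree with a single root
        merged = {s.derived for s in self.splits}
        roots = [l for l in labels if l not in merged]
        if len(roots) != 1:
            raise ValueError(
                f"model must coalesce to a single ancestral population; roots={roots}"
            )
        self.root = roots[0]

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.populations]

    def population(self, label: str) -> Population:
        for p in self.populations:
            if p.label == label:
                return p
        raise KeyError(label)

    @property
    def oldest_split_time(self) -> float:
        return max((s.time for s in self.splits), default=0.0)

    def effective_recombination(self, label: str) -> float:
        p = self.population(label)
        return self.rho * (1.0 - p.inbreeding_coefficient)

    def with_overrides(self, **kwargs) -> "DemographicModel":
        return replace(self, **kwargs)


# Species aliases used throughout: outcrosser (Cg), selfer1 (Cr, split into
# E/W subpopulations), selfer2 (Co).
OUTCROSSER = "outcrosser"
SELFER1_E = "selfer1_E"
SELFER1_W = "selfer1_W"
SELFER2 = "selfer2"


def default_capsella_model(
    *,
    n_outcrosser: float = 694_643.0,
    n_selfer1_E: float = 100_000.0,
    n_selfer1_W: float = 50_000.0,
    n_selfer2: float = 14_643.0,
    n_bottleneck: float = 7.0,
    t_split_selfer1: float = 170_000.0,
    t_bottleneck_duration: float = 10_000.0,
    t_split_ew: float = 10_000.0,
    t_split_selfer2: float = 1.8e6,
    selfing_rate_selfer1: float = 0.97,
    selfing_rate_selfer2: float = 0.99,
    migration_rate: float = 1e-7,
    mu: float = 7e-9,
    rho: float = 3.6e-8,
) -> DemographicModel:
    """Three-species model inspired by the Capsella system.

    An outcrossing species of large size; a young selfer founded
    ``t_split_selfer1`` generations ago through a bottleneck of
    ``n_bottleneck`` diploid founders (default 7, i.e. 14 effective
    chromosomes at the top of the reported 2-14 range), splitting into E/W
    subpopulations ``t_split_ew`` generations ago; an old selfer of small
    size diverged ``t_split_selfer2`` generations ago.  Bidirectional low
    gene flow connects the outcrosser and the young selfer from its founding
    until the E/W split, after which migration runs only from the eastern
    selfer subpopulation into the outcrosser.
    """
    if not 1 <= n_bottleneck <= 7:
        raise ValueError("founder bottleneck must be 1-7 diploids")
    t_bot = t_split_selfer1 - t_bottleneck_duration
    pops = [
        Population(OUTCROSSER, [(0.0, n_outcrosser)], 0.0),
        Population(
            SELFER1_E,
            [(0.0, n_selfer1_E), (t_bot, n_bottleneck)],
            selfing_rate_selfer1,
        ),
        Population(SELFER1_W, [(0.0, n_selfer1_W)], selfing_rate_selfer1),
        Population(SELFER2, [(0.0, n_selfer2)], selfing_rate_selfer2),
    ]
    splits = [
        Split(t_split_ew, SELFER1_W, SELFER1_E),
        Split(t_split_selfer1, SELFER1_E, OUTCROSSER),
        Split(t_split_selfer2, SELFER2, OUTCROSSER),
    ]
    mig = [
        MigrationEpoch(t_split_ew, t_split_selfer1, OUTCROSSER, SELFER1_E, migration_rate),
        MigrationEpoch(t_split_ew, t_split_selfer1, SELFER1_E, OUTCROSSER, migration_rate),
        MigrationEpoch(0.0, t_split_ew, SELFER1_E, OUTCROSSER, migration_rate),
    ]
    return DemographicModel(pops, splits, mig, mu=mu, rho=rho)


def scaled_capsella_model(scale: float = 300.0, *, include_selfer2: bool = True,
                          **overrides) -> DemographicModel:
    """Desk-scale version of :func:`default_capsella_model`.

    Population sizes and times are divided by ``scale`` and the mutation rate
    is multiplied by it, which preserves per-segment diversity (theta) while
    shrinking genealogies; the crossover rate is kept at its per-bp value so
    the per-segment population recombination rate drops by the same factor,
    keeping ancestral recombination graphs small.  The founder bottleneck
    size stays at its literal diploid count (it is a count of founding
    individuals, not a drift parameter to rescale); its duration scales.
    Migration fractions are per-generation rates and scale up by ``scale``.
    """
    base = default_capsella_model(**overrides)
    c = float(scale)
    m0 = overrides.get("migration_rate", 1e-7) * c
    # the founder bottleneck must stay effectively complete under scaling:
    # the full model spends ~1400 coalescent units in it (no neutral
    # retention at all), so the scaled duration is floored at 20 units
    nb = overrides.get("n_bottleneck", 7.0)
    sig = overrides.get("selfing_rate_selfer1", 0.97)
    ne_eff_bot = nb / (1.0 + sig / (2.0 - sig))
    t_bot = max(10_000.0 / c, 20.0 * 2.0 * ne_eff_bot)
    kw = dict(
        n_outcrosser=694_643.0 / c,
        n_selfer1_E=100_000.0 / c,
        n_selfer1_W=50_000.0 / c,
        n_selfer2=14_643.0 / c,
        n_bottleneck=overrides.get("n_bottleneck", 7.0),
        t_split_selfer1=170_000.0 / c,
        t_bottleneck_duration=t_bot,
        t_split_ew=10_000.0 / c,
        t_split_selfer2=1.8e6 / c,
        selfing_rate_selfer1=base.population(SELFER1_E).selfing_rate,
        selfing_rate_selfer2=base.population(SELFER2).selfing_rate,
        migration_rate=m0,
        mu=base.mu * c,
        rho=base.rho,
    )
    model = default_capsella_model(**kw)
    if not include_selfer2:
        pops = [p for p in model.populations if p.label != SELFER2]
        splits = [s for s in model.splits if s.derived != SELFER2]
        model = DemographicModel(pops, splits, model.migration_epochs,
                                 mu=model.mu, rho=model.rho)
    return model
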