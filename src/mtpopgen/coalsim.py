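"""Coalescent simulator for a non-recombining mtDNA locus.

Synthetic-data engine for the whole package: it generates the datasets the
analyses are tested on and serves as the null/bootstrap distribution engine
for neutrality p-values and mismatch-model significance.

Time is measured in *mutational units*: mutations fall on a branch of length
``t`` as Poisson(``t``), and while ``k`` lineages remain they coalesce at
rate ``k(k-1)/theta``. Under a constant-size model this gives the standard
expectations E[pairwise differences] = theta and E[S] = theta * a1. The
sudden-expansion model switches the coalescence intensity from the present
scale ``theta1`` to the ancestral scale ``theta0`` at time ``tau/2`` before
present, so the expected pairwise-difference mode sits near ``tau``,
matching the mismatch-distribution parameterisation.

Mutations are placed under an infinite-sites approximation on the finite
rCRS coordinates of the configured regions: each mutation takes a previously
unused position, chosen in a region with probability proportional to the
region's rate share; the derived base is drawn uniformly from the three
non-reference bases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    BASES,
    PopulationDataset,
    RegionSet,
    STAT_REGIONS,
    VariantProfile,
)

THETA1_INF = float("inf")


@dataclass(frozen=True)
class DemographicModel:
    """``constant`` (size theta0) or ``sudden_expansion`` (theta1 now,
    theta0 before time tau/2, tau in mutational units)."""

    kind: str = "constant"
    theta0: float = 5.0
    theta1: float = float("nan")
    tau: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sudden_expansion"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.theta0 < 0:
            raise ValueError("theta0 must be >= 0")
        if self.kind == "sudden_expansion":
            if not (self.theta1 >= 0) or not (self.tau >= 0):
                raise ValueError("sudden_expansion needs theta1 >= 0 and tau >= 0")

    @staticmethod
    def constant(theta: float) -> "DemographicModel":
        return DemographicModel("constant", theta0=theta)

    @staticmethod
    def expansion(tau: float, theta0: float, theta1: float) -> "DemographicModel":
        return DemographicModel("sudden_expansion", theta0=theta0,
                                theta1=theta1, tau=tau)


@dataclass
class Genealogy:
    """Timed binary genealogy. Nodes ``0..n-1`` are tips; ``parent[root]``
    is −1. Times are in mutational units, increasing into the past."""

    parent: np.ndarray
    time: np.ndarray
    n: int

    @property
    def num_nodes(self) -> int:
        return len(self.parent)

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(self.num_nodes)
        for v in range(self.num_nodes):
            p = self.parent[v]
            if p >= 0:
                bl[v] = self.time[p] - self.time[v]
        return bl

    def tip_counts(self) -> np.ndarray:
        """Number of descendant tips below each node."""
        counts = np.zeros(self.num_nodes, dtype=int)
        counts[: self.n] = 1
        for v in np.argsort(self.time):  # children have smaller times
            p = self.parent[v]
            if p >= 0:
                counts[p] += counts[v]
        return counts

    @property
    def tmrca(self) -> float:
        return float(self.time.max())


def _coalescence_scale(model: DemographicModel, t: float) -> float:
    if model.kind == "constant":
        return model.theta0
    return model.theta1 if t < model.tau / 2.0 else model.theta0


def simulate_genealogy(
    n: int, model: DemographicModel, rng: np.random.Generator
) -> Genealogy:
    """Kingman coalescent with piecewise-constant population scale."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    next_node = n
    boundary = model.tau / 2.0 if model.kind == "sudden_expansion" else np.inf
    while len(active) > 1:
        k = len(active)
        theta = _coalescence_scale(model, t)
        if theta == 0.0:
            dt = 0.0
        elif np.isinf(theta):
            dt = np.inf
        else:
            dt = rng.exponential(theta / (k * (k - 1)))
        if t < boundary and t + dt >= boundary:
            t = boundary  # re-draw under the ancestral scale
            continue
        t += dt
        if np.isinf(t):
            raise ValueError("coalescence never happens (theta infinite forever)")
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        active = [x for x in active if x not in (a, b)] + [next_node]
        next_node += 1
    return Genealogy(parent, time, n)


def simulate_split_genealogy(
    n_per_deme: Sequence[int],
    theta: float,
    split_time: float,
    rng: np.random.Generator,
) -> Genealogy:
    """Two-deme clean split, no migration: lineages coalesce only within
    their deme until ``split_time`` (mutational units), then in a single
    ancestral population of the same scale."""
    if len(n_per_deme) != 2:
        raise ValueError("exactly two demes supported")
    n = int(sum(n_per_deme))
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    demes = [list(range(n_per_deme[0])), list(range(n_per_deme[0], n))]
    t = 0.0
    next_node = n
    while t < split_time and any(len(d) > 1 for d in demes):
        rates = [len(d) * (len(d) - 1) / theta for d in demes]
        total = sum(rates)
        if total == 0:
            break
        dt = rng.exponential(1.0 / total)
        if t + dt >= split_time:
            break
        t += dt
        which = rng.choice(2, p=[r / total for r in rates])
        d = demes[which]
        i, j = rng.choice(len(d), size=2, replace=False)
        a, b = d[i], d[j]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        demes[which] = [x for x in d if x not in (a, b)] + [next_node]
        next_node += 1
    active = demes[0] + demes[1]
    t = max(t, split_time)
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(theta / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        active = [x for x in active if x not in (a, b)] + [next_node]
        next_node += 1
    return Genealogy(parent, time, n)


def synthetic_reference(region_set: RegionSet, seed: int = 7_654_321) -> str:
    """Deterministic synthetic reference sequence spanning the full
    coordinate range of the region set (stand-in for the rCRS; positions
    outside the regions are filled but never used)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    length = region_set.regions[-1][1]
    return "".join(rng.choice(list(BASES), size=length))


def drop_mutations(
    tree: Genealogy,
    region_set: RegionSet,
    rates: Sequence[float],
    rng: np.random.Generator,
    reference: str | None = None,
    sample_ids: Sequence[str] | None = None,
) -> list[VariantProfile]:
    """Scatter mutations on the genealogy, infinite-sites on finite positions.

    ``rates`` are relative per-site rates per region; the region share of
    each mutation is proportional to rate × region length, and the overall
    branch mutation rate is one per unit of (mutational-unit) branch length.
    """
    if len(rates) != len(region_set.regions):
        raise ValueError("one rate per region required")
    if reference is None:
        reference = synthetic_reference(region_set)
    weights = np.array(
        [r * (e - s + 1) for r, (s, e) in zip(rates, region_set.regions)], float
    )
    if weights.sum() <= 0:
        raise ValueError("all region rates are zero")
    shares = weights / weights.sum()
    free: list[list[int]] = [list(range(s, e + 1)) for s, e in region_set.regions]
    bl = tree.branch_lengths()
    mut_positions: dict[int, list[tuple[int, str]]] = {}  # node -> muts on its branch
    n_muts = rng.poisson(bl)
    for node in range(tree.num_nodes):
        for _ in range(int(n_muts[node])):
            region_idx = int(rng.choice(len(shares), p=shares))
            if not free[region_idx]:
                raise ValueError(
                    "positions exhausted in region "
                    f"{region_set.regions[region_idx]}; lower theta or enlarge regions"
                )
            pick = int(rng.integers(len(free[region_idx])))
            pos = free[region_idx].pop(pick)
            ref_base = reference[pos - 1].upper()
            alts = [b for b in BASES if b != ref_base]
            base = alts[int(rng.integers(3))]
            mut_positions.setdefault(node, []).append((pos, base))
    # accumulate root->tip mutation sets
    children: dict[int, list[int]] = {}
    root = int(np.flatnonzero(tree.parent == -1)[0])
    for v in range(tree.num_nodes):
        if tree.parent[v] >= 0:
            children.setdefault(int(tree.parent[v]), []).append(v)
    tip_variants: dict[int, frozenset] = {}
    stack = [(root, frozenset())]
    while stack:
        node, acc = stack.pop()
        acc = acc | frozenset(mut_positions.get(node, []))
        if node < tree.n:
            tip_variants[node] = acc
        for c in children.get(node, []):
            stack.append((c, acc))
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(tree.n)]
    return [
        VariantProfile(sample_ids[i], tip_variants[i]) for i in range(tree.n)
    ]


@dataclass
class SimConfig:
    """End-to-end simulation configuration (seed is mandatory)."""

    n: int
    seed: int
    model: DemographicModel = field(default_factory=lambda: DemographicModel.constant(5.0))
    region_set: RegionSet = STAT_REGIONS
    rates: Sequence[float] | None = None
    population: str = "pop1"
    split: tuple[int, int, float] | None = None  # (n_deme1, n_deme2, split_time)

    def effective_rates(self) -> Sequence[float]:
        if self.rates is not None:
            return self.rates
        return [1.0] * len(self.region_set.regions)


def simulate_dataset(
    config: SimConfig,
) -> tuple[PopulationDataset, dict]:
    """Generate a dataset plus the ground truth used to make it."""
    rng = np.random.Generator(np.random.PCG64(config.seed))
    reference = synthetic_reference(config.region_set)
    if config.split is not None:
        n1, n2, t_split = config.split
        tree = simulate_split_genealogy(
            (n1, n2), config.model.theta0, t_split, rng
        )
        pop_of = {}
        profiles = drop_mutations(
            tree, config.region_set, config.effective_rates(), rng, reference
        )
        for i, prof in enumerate(profiles):
            pop_of[prof.sample_id] = "deme1" if i < n1 else "deme2"
    else:
        tree = simulate_genealogy(config.n, config.model, rng)
        profiles = drop_mutations(
            tree, config.region_set, config.effective_rates(), rng, reference
        )
        pop_of = {p.sample_id: config.population for p in profiles}
    ds = PopulationDataset(profiles, pop_of, config.region_set)
    truth = {
        "model": config.model,
        "genealogy": tree,
        "reference": reference,
        "seed": config.seed,
    }
    return ds, truth


def truth_summary_json(truth: dict) -> str:
    m = truth["model"]
    return json.dumps(
        {
            "model": {"kind": m.kind, "theta0": m.theta0,
                      "theta1": None if np.isnan(m.theta1) else m.theta1,
                      "tau": None if np.isnan(m.tau) else m.tau},
            "tmrca_mutational_units": truth["genealogy"].tmrca,
            "seed": truth["seed"],
        },
        indent=2,
    )
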