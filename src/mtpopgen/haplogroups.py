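"""Haplogroup tree handling, classification, and admixture partitioning.

A haplogroup tree is a rooted tree of named clades, each carrying the
substitutions that define it relative to its parent; the expected variant
set of a clade is the union along the root-to-clade path, with
back-mutations (suffixed ``!`` in the table) deleting earlier expectations.
Classification scores a sample against every clade by the fraction of
expected variants observed. This is a deliberately simple, deterministic
classifier for clean (synthetic or curated) data — it does not attempt the
weighted scoring of full-database tools like HaploGrep and is not a
replacement for them on noisy real data.

Admixture between a hybrid population and two putative parental pools is
partitioned by haplogroup sharing: the fraction of the hybrid's haplogroup
frequency mass belonging to parent 1's haplogroups, to parent 2's
(after removing haplogroups shared with parent 1 — parent 1 takes
precedence), and the unshared remainder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import RegionSet, VariantProfile


@dataclass(frozen=True)
class TreeNode:
    parent: str | None
    #: (position, derived_base, is_back_mutation)
    defining_variants: frozenset[tuple[int, str, bool]]


@dataclass
class HaplogroupTree:
    nodes: dict[str, TreeNode]

    def __post_init__(self) -> None:
        roots = [n for n, nd in self.nodes.items() if nd.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        for name, nd in self.nodes.items():
            if nd.parent is not None and nd.parent not in self.nodes:
                raise ValueError(f"node {name!r} references unknown parent {nd.parent!r}")
        # cycle check by walking every node to the root
        for name in self.nodes:
            seen = set()
            cur: str | None = name
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle involving {cur!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    @property
    def root(self) -> str:
        return next(n for n, nd in self.nodes.items() if nd.parent is None)

    def path(self, name: str) -> list[str]:
        out: list[str] = []
        cur: str | None = name
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out[::-1]

    def depth(self, name: str) -> int:
        return len(self.path(name)) - 1

    def expected_variants(
        self, name: str, region_set: RegionSet | None = None
    ) -> frozenset[tuple[int, str]]:
        """Union of defining variants along the root-to-node path;
        back-mutations remove the matching earlier expectation. Optionally
        restricted to positions inside a region set."""
        expected: set[tuple[int, str]] = set()
        for node in self.path(name):
            for pos, base, is_back in self.nodes[node].defining_variants:
                if is_back:
                    expected = {(p, b) for p, b in expected if p != pos}
                else:
                    expected.add((pos, base))
        if region_set is not None:
            expected = {(p, b) for p, b in expected if p in region_set}
        return frozenset(expected)


def _parse_variant(token: str) -> tuple[int, str, bool]:
    is_back = token.endswith("!")
    if is_back:
        token = token[:-1]
    base = token[-1].upper()
    pos = int(token[:-1])
    return pos, base, is_back


def load_tree_table(path: str) -> HaplogroupTree:
    """Load a haplogroup tree from TSV rows
    ``name<TAB>parent<TAB>space-separated variants`` (root row: empty parent;
    variants like ``16223T``, back-mutations suffixed ``!``)."""
    nodes: dict[str, TreeNode] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"row {lineno}: expected at least 2 columns")
            name = parts[0].strip()
            parent = parts[1].strip() or None
            if name in nodes:
                raise ValueError(f"row {lineno}: duplicate haplogroup name {name!r}")
            var_field = parts[2].strip() if len(parts) > 2 else ""
            try:
                variants = frozenset(
                    _parse_variant(tok) for tok in var_field.split() if tok
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"row {lineno}: bad variant token") from exc
            nodes[name] = TreeNode(parent, variants)
    try:
        return HaplogroupTree(nodes)
    except ValueError as exc:
        # map structural failures back to offending rows where possible
        raise ValueError(str(exc)) from exc


def assign_haplogroup(
    profile: VariantProfile,
    tree: HaplogroupTree,
    region_set: RegionSet | None = None,
) -> tuple[str, float, str | None]:
    """Best-matching haplogroup for a profile.

    Every clade is scored by matched = |expected ∩ observed| over the
    expected set restricted to the profile's regions, and by the completeness
    fraction matched/|expected| (defined as 1.0 for an empty expected set,
    e.g. the root). The best clade maximises the matched count, then the
    completeness fraction, then path depth, with remaining ties broken by
    lexicographically smaller name. The runner-up is the second-ranked clade.
    """
    if not tree.nodes:
        raise ValueError("empty haplogroup tree")
    observed = set(profile.variants)
    ranked: list[tuple[int, float, int, str]] = []
    for name in tree.nodes:
        expected = tree.expected_variants(name, region_set)
        matched = len(expected & observed)
        score = matched / len(expected) if expected else 1.0
        ranked.append((matched, score, tree.depth(name), name))
    ranked.sort(key=lambda r: (-r[0], -r[1], -r[2], r[3]))
    best = ranked[0]
    runner_up = ranked[1][3] if len(ranked) > 1 else None
    return best[3], best[1], runner_up


def classify_dataset(
    profiles: Iterable[VariantProfile],
    tree: HaplogroupTree,
    region_set: RegionSet | None = None,
) -> pd.DataFrame:
    rows = []
    for prof in profiles:
        best, score, runner = assign_haplogroup(prof, tree, region_set)
        rows.append({"sample_id": prof.sample_id, "haplogroup": best,
                     "score": score, "runner_up": runner})
    return pd.DataFrame(rows).set_index("sample_id")


def name_novel_subhaplogroup(
    parent_name: str,
    clade_exclusive_variants: Iterable[tuple[int, str]],
    screened_regions: RegionSet,
    clade_depth_order: Sequence[tuple[int, str]] | None = None,
) -> str:
    """Name a previously unreported subclade ``parent_position``.

    The chosen position is the clade-exclusive substitution closest to the
    tip of the clade's phylogeny, preferring one inside the screened
    regions; if none falls inside, the tip-most variant overall.
    ``clade_depth_order`` lists the exclusive variants from root-side to tip
    (defaults to the iteration order of ``clade_exclusive_variants``).
    """
    variants = list(clade_exclusive_variants)
    if not variants:
        raise ValueError("need at least one exclusive variant")
    order = list(clade_depth_order) if clade_depth_order is not None else variants
    tip_first = order[::-1]
    for pos, _base in tip_first:
        if pos in screened_regions:
            return f"{parent_name}_{pos}"
    pos, _base = tip_first[0]
    return f"{parent_name}_{pos}"


@dataclass
class FrequencyTable:
    freq: pd.DataFrame  # rows: populations, columns: haplogroups

    def __post_init__(self) -> None:
        if (self.freq.values < 0).any():
            raise ValueError("frequencies must be non-negative")
        rowsums = self.freq.sum(axis=1)
        if not ((rowsums - 1.0).abs() < 1e-9).all():
            raise ValueError("each population row must sum to 1")

    @property
    def populations(self) -> list[str]:
        return list(self.freq.index)

    @property
    def haplogroups(self) -> list[str]:
        return list(self.freq.columns)

    def row(self, population: str) -> pd.Series:
        return self.freq.loc[population]


def build_frequency_table(
    calls: Mapping[str, str], pops: Mapping[str, str]
) -> FrequencyTable:
    """Per-population relative haplogroup frequencies from per-sample calls."""
    uncalled = sorted(set(pops) - set(calls))
    if uncalled:
        raise ValueError(f"samples without haplogroup call: {uncalled[:5]}")
    df = pd.DataFrame(
        {"population": [pops[s] for s in calls], "haplogroup": list(calls.values())}
    )
    counts = df.groupby(["population", "haplogroup"]).size().unstack(fill_value=0)
    counts = counts.sort_index(axis=0).sort_index(axis=1)
    n = counts.sum(axis=1)
    if (n == 0).any():
        raise ValueError("empty population in frequency table")
    return FrequencyTable(counts.div(n, axis=0))


@dataclass
class AdmixturePartition:
    population: str
    parent1_share: float
    parent2_share: float
    unshared: float

    def __post_init__(self) -> None:
        total = self.parent1_share + self.parent2_share + self.unshared
        if abs(total - 1.0) > 1e-9:
            raise ValueError("partition fractions must sum to 1")
        for v in (self.parent1_share, self.parent2_share, self.unshared):
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError("fractions must lie in [0, 1]")


def admixture_partition(
    hybrid_row: pd.Series,
    parent1_set: set[str],
    parent2_raw_set: set[str],
    population: str | None = None,
) -> AdmixturePartition:
    """Two-parent shared-haplogroup partition of a hybrid population.

    Haplogroups present in both parental pools count toward parent 1
    (parent-1 precedence: parent 2's effective set is
    ``parent2_raw_set - parent1_set``); the remainder of the hybrid's
    frequency mass is unshared.
    """
    parent2_set = set(parent2_raw_set) - set(parent1_set)
    p1 = float(hybrid_row[hybrid_row.index.isin(parent1_set)].sum())
    p2 = float(hybrid_row[hybrid_row.index.isin(parent2_set)].sum())
    total = float(hybrid_row.sum())
    unshared = total - p1 - p2
    return AdmixturePartition(
        population or str(hybrid_row.name), p1, p2, max(unshared, 0.0)
    )


def admixture_table(
    freqs: FrequencyTable,
    hybrids: Sequence[str],
    parent1_set: set[str],
    parent2_raw_set: set[str],
) -> pd.DataFrame:
    rows = []
    for pop in hybrids:
        part = admixture_partition(freqs.row(pop), parent1_set, parent2_raw_set, pop)
        rows.append({
            "population": part.population,
            "parent1_share": part.parent1_share,
            "parent2_share": part.parent2_share,
            "unshared": part.unshared,
        })
    return pd.DataFrame(rows).set_index("population")
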