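"""Sequence ingestion and rCRS-relative variant profiles.

Samples are represented by their substitutions relative to a reference
sequence (rCRS coordinates, 1-based inclusive) restricted to a configured
set of screened regions. Insertions, deletions and heteroplasmies are
ignored on ingest: every downstream statistic operates on substitution
differences only. Missing data (IUPAC ambiguity codes, ``N``, gaps) are
tracked per position and handled by pairwise deletion in all distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = ("A", "C", "G", "T")

#: statistics window used for diversity/structure computations
DEFAULT_STAT_REGIONS = ((8001, 9000), (9801, 10900), (16051, 16400))
#: wider screened window used at ingest
DEFAULT_SCREEN_REGIONS = ((8001, 9000), (9801, 10900), (16001, 16569))


@dataclass(frozen=True)
class RegionSet:
    """Ordered, non-overlapping set of 1-based inclusive coordinate ranges."""

    regions: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        regs = tuple((int(s), int(e)) for s, e in self.regions)
        object.__setattr__(self, "regions", regs)
        if not regs:
            raise ValueError("RegionSet needs at least one region")
        prev_end = 0
        for start, end in regs:
            if start < 1 or end < start:
                raise ValueError(f"invalid region ({start}, {end})")
            if start <= prev_end:
                raise ValueError("regions must be sorted and non-overlapping")
            prev_end = end

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for s, e in self.regions)

    def __contains__(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.regions)

    def positions(self) -> Iterator[int]:
        for s, e in self.regions:
            yield from range(s, e + 1)

    def region_of(self, position: int) -> tuple[int, int]:
        for s, e in self.regions:
            if s <= position <= e:
                return (s, e)
        raise KeyError(f"position {position} outside regions")

    def restrict(self, other: "RegionSet") -> "RegionSet":
        """Intersection with another region set (used to truncate the
        screened window down to the statistics window)."""
        out = []
        for s, e in self.regions:
            for s2, e2 in other.regions:
                lo, hi = max(s, s2), min(e, e2)
                if lo <= hi:
                    out.append((lo, hi))
        return RegionSet(tuple(sorted(out)))


STAT_REGIONS = RegionSet(DEFAULT_STAT_REGIONS)
SCREEN_REGIONS = RegionSet(DEFAULT_SCREEN_REGIONS)


@dataclass(frozen=True)
class VariantProfile:
    """A sample's substitutions relative to the reference.

    ``variants`` is a frozenset of ``(position, derived_base)`` pairs;
    ``missing`` the positions with no confident call.
    """

    sample_id: str
    variants: frozenset[tuple[int, str]]
    missing: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", frozenset(self.variants))
        object.__setattr__(self, "missing", frozenset(self.missing))
        pos_seen = set()
        for pos, base in self.variants:
            if base not in BASES:
                raise ValueError(f"{self.sample_id}: bad derived base {base!r}")
            if pos in pos_seen:
                raise ValueError(f"{self.sample_id}: duplicate variant position {pos}")
            pos_seen.add(pos)
        if pos_seen & set(self.missing):
            raise ValueError(f"{self.sample_id}: variant positions marked missing")

    @property
    def variant_positions(self) -> frozenset[int]:
        return frozenset(p for p, _ in self.variants)

    def allele(self, position: int) -> str | None:
        """Derived base at position, None meaning reference allele."""
        if position in self.missing:
            raise KeyError(f"{position} is missing in {self.sample_id}")
        for pos, base in self.variants:
            if pos == position:
                return base
        return None

    def restricted(self, region_set: RegionSet) -> "VariantProfile":
        return VariantProfile(
            self.sample_id,
            frozenset((p, b) for p, b in self.variants if p in region_set),
            frozenset(p for p in self.missing if p in region_set),
        )

    def key(self) -> str:
        """Canonical haplotype key: slash-joined sorted variants, ``.`` if none."""
        if not self.variants:
            return "."
        return "/".join(f"{p}{b}" for p, b in sorted(self.variants))


@dataclass
class PopulationDataset:
    """Aligned variant profiles plus population labels."""

    profiles: list[VariantProfile]
    pop_of: dict[str, str]
    region_set: RegionSet

    def __post_init__(self) -> None:
        missing = [p.sample_id for p in self.profiles if p.sample_id not in self.pop_of]
        if missing:
            raise ValueError(f"samples without population label: {missing[:5]}")
        for prof in self.profiles:
            for pos, _ in prof.variants:
                if pos not in self.region_set:
                    raise ValueError(
                        f"{prof.sample_id}: variant at {pos} outside region set"
                    )
        if not self.populations:
            raise ValueError("dataset needs at least one population")

    @property
    def n(self) -> int:
        return len(self.profiles)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.profiles:
            seen.setdefault(self.pop_of[p.sample_id], None)
        return list(seen)

    def subset(self, population: str) -> "PopulationDataset":
        profs = [p for p in self.profiles if self.pop_of[p.sample_id] == population]
        if not profs:
            raise KeyError(f"no samples in population {population!r}")
        return PopulationDataset(
            profs, {p.sample_id: population for p in profs}, self.region_set
        )

    def restricted(self, region_set: RegionSet) -> "PopulationDataset":
        eff = self.region_set.restrict(region_set)
        return PopulationDataset(
            [p.restricted(eff) for p in self.profiles], dict(self.pop_of), eff
        )


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("shape mismatch")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def pairwise_differences(
    a: VariantProfile, b: VariantProfile, region_set: RegionSet
) -> tuple[int, int]:
    """Substitution differences between two profiles with pairwise deletion.

    Returns ``(diff_count, compared_sites)``: the number of positions, called
    in both samples, at which the alleles differ, and the number of sites
    compared (region length minus the union of missing positions).
    """
    excl = a.missing | b.missing
    alle_a = {p: x for p, x in a.variants if p not in excl}
    alle_b = {p: x for p, x in b.variants if p not in excl}
    diff = 0
    for pos in alle_a.keys() | alle_b.keys():
        if alle_a.get(pos) != alle_b.get(pos):
            diff += 1
    return diff, region_set.total_length - len(excl)


def encode_matrix(ds: PopulationDataset) -> tuple[list[int], np.ndarray]:
    """Integer-encode profiles over segregating positions.

    Returns the sorted list of positions carrying at least one variant and an
    ``(n, S)`` int8 matrix with 0 = reference allele, 1.. = alternative
    alleles, −1 = missing. Positions that are missing in some samples but
    never variant are irrelevant to difference counts per-position, but still
    shrink ``compared_sites``; that bookkeeping stays in
    :func:`pairwise_differences` / :func:`distance_matrix`.
    """
    positions = sorted({p for prof in ds.profiles for p, _ in prof.variants})
    index = {p: i for i, p in enumerate(positions)}
    allele_code: dict[tuple[int, str], int] = {}
    mat = np.zeros((ds.n, len(positions)), dtype=np.int8)
    for i, prof in enumerate(ds.profiles):
        for pos, base in prof.variants:
            code = allele_code.setdefault((pos, base), len(
                [k for k in allele_code if k[0] == pos]) + 1)
            mat[i, index[pos]] = code
        for pos in prof.missing:
            if pos in index:
                mat[i, index[pos]] = -1
    return positions, mat


def distance_matrix(ds: PopulationDataset) -> tuple[DistanceMatrix, np.ndarray]:
    """All-pairs difference counts and compared-site counts.

    Returns a :class:`DistanceMatrix` of difference counts and the matching
    matrix of compared sites (pairwise deletion).
    """
    n = ds.n
    _, mat = encode_matrix(ds)
    miss_sets = [prof.missing for prof in ds.profiles]
    L = ds.region_set.total_length
    d = np.zeros((n, n))
    comp = np.full((n, n), float(L))
    called = mat >= 0
    for i in range(n):
        both = called[i] & called[i + 1:]
        neq = (mat[i] != mat[i + 1:]) & both
        d[i, i + 1:] = neq.sum(axis=1)
        for j in range(i + 1, n):
            comp[i, j] = comp[j, i] = L - len(miss_sets[i] | miss_sets[j])
    d = d + d.T
    labels = [p.sample_id for p in ds.profiles]
    return DistanceMatrix(labels, d), comp


def collapse_haplotypes(ds: PopulationDataset) -> pd.DataFrame:
    """Collapse identical variant sets into haplotypes.

    Haplotype identity is exact equality of variant sets (missing positions
    excluded). Returns a table indexed by haplotype key with one count column
    per population; counts sum to the population sample sizes.
    """
    pops = ds.populations
    rows: dict[str, dict[str, int]] = {}
    for prof in ds.profiles:
        key = prof.key()
        row = rows.setdefault(key, {p: 0 for p in pops})
        row[ds.pop_of[prof.sample_id]] += 1
    table = pd.DataFrame.from_dict(rows, orient="index", columns=pops).fillna(0)
    return table.astype(int)


# ---------------------------------------------------------------------------
# I/O

def load_reference(path: str) -> str:
    """Read a reference (rCRS) FASTA; returns the sequence as a string
    indexed in code with 1-based coordinates."""
    rec = next(SeqIO.parse(path, "fasta"))
    return str(rec.seq).upper()


def _profile_from_bases(
    sample_id: str,
    bases: Mapping[int, str],
    region_set: RegionSet,
    reference: str,
) -> VariantProfile:
    variants, missing = set(), set()
    for pos, base in bases.items():
        ref = reference[pos - 1].upper()
        if base in BASES:
            if base != ref:
                variants.add((pos, base))
        else:
            missing.add(pos)
    return VariantProfile(sample_id, frozenset(variants), frozenset(missing))


def read_fasta(
    path: str, region_set: RegionSet, reference: str
) -> list[VariantProfile]:
    """Read aligned sequences into variant profiles.

    Three record layouts are accepted, distinguished per record:

    * full-length: sequence length equals the reference length; the
      configured regions are extracted by coordinate;
    * concatenated: sequence length equals ``region_set.total_length``;
      interpreted as the regions joined in order;
    * per-region: header of the form ``sample|start-end``; all regions of a
      sample are combined into one profile.

    Bases equal to the reference produce no variant; IUPAC ambiguity codes
    and gaps are recorded as missing.
    """
    per_sample: dict[str, dict[int, str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        rid = rec.id
        if "|" in rid:
            sample, _, span = rid.rpartition("|")
            try:
                start, end = (int(x) for x in span.split("-"))
            except ValueError as exc:
                raise ValueError(f"record {rid}: cannot parse region header") from exc
            if (start, end) not in region_set.regions:
                raise ValueError(f"record {rid}: region {start}-{end} not configured")
            if len(seq) != end - start + 1:
                raise ValueError(
                    f"record {rid}: length {len(seq)} inconsistent with region "
                    f"{start}-{end}"
                )
            bases = dict(zip(range(start, end + 1), seq))
        elif len(seq) == len(reference):
            sample = rid
            bases = {p: seq[p - 1] for p in region_set.positions()}
        elif len(seq) == region_set.total_length:
            sample = rid
            bases = dict(zip(region_set.positions(), seq))
        else:
            raise ValueError(
                f"record {rid}: length {len(seq)} matches neither the reference "
                f"({len(reference)}) nor the concatenated regions "
                f"({region_set.total_length})"
            )
        if sample not in per_sample:
            order.append(sample)
        per_sample.setdefault(sample, {}).update(bases)
    return [
        _profile_from_bases(s, per_sample[s], region_set, reference) for s in order
    ]


def write_fasta(
    profiles: Sequence[VariantProfile],
    region_set: RegionSet,
    reference: str,
    path: str,
) -> None:
    """Write profiles as concatenated-region FASTA (missing sites as N)."""
    records = []
    for prof in profiles:
        alle = dict(prof.variants)
        chars = []
        for pos in region_set.positions():
            if pos in prof.missing:
                chars.append("N")
            else:
                chars.append(alle.get(pos, reference[pos - 1].upper()))
        records.append(SeqRecord(Seq("".join(chars)), id=prof.sample_id, description=""))
    SeqIO.write(records, path, "fasta")


def read_population_map(path: str) -> dict[str, str]:
    """Two-column TSV ``sample_id<TAB>population``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample_id"], df["population"]))


def load_dataset(
    fasta_path: str,
    pops_path: str,
    reference: str,
    region_set: RegionSet = STAT_REGIONS,
) -> PopulationDataset:
    profiles = read_fasta(fasta_path, region_set, reference)
    return PopulationDataset(profiles, read_population_map(pops_path), region_set)
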