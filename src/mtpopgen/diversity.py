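"""Molecular diversity indices and neutrality tests.

Per-population summary statistics for mtDNA samples: haplotype counts,
polymorphic sites, Nei's gene diversity with its sampling standard error,
nucleotide diversity, mean number of pairwise differences (MNPd), Tajima's D
and Fu's Fs, with p-values from coalescent simulation under selective
neutrality (constant population size, theta fixed at the observed MNPd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import PopulationDataset, collapse_haplotypes, distance_matrix, encode_matrix
from . import coalsim

NA = float("nan")

#: significance thresholds used for report stars
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.02, "*"))


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for thresh, stars in STAR_THRESHOLDS:
        if p <= thresh:
            return stars
    return ""


@dataclass
class DiversitySummary:
    population: str
    n: int
    k: int
    S: int
    H: float
    H_se: float
    pi: float
    MNPd: float
    tajima_D: float
    fu_Fs: float
    p_D: float = NA
    p_Fs: float = NA


def gene_diversity(counts: Sequence[int]) -> tuple[float, float]:
    """Nei's gene (haplotype) diversity and its standard error.

    H = n/(n-1) * (1 - sum p_i^2); the variance is Nei's (1987) sampling
    variance
    V = 2/(n(n-1)) * { 2(n-2) [sum p_i^3 - (sum p_i^2)^2] + sum p_i^2 - (sum p_i^2)^2 }.
    """
    counts = [int(c) for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise ValueError("gene diversity needs n >= 2")
    p = np.array(counts, float) / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    H = n / (n - 1) * (1.0 - sum2)
    V = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2
    )
    return H, math.sqrt(max(V, 0.0))


def nucleotide_diversity(ds: PopulationDataset) -> tuple[float, float]:
    """Per-site nucleotide diversity and mean number of pairwise differences.

    MNPd = 2/(n(n-1)) * sum_{i<j} d_ij; pi averages d_ij / compared_sites_ij
    over pairs (pairwise deletion of missing data).
    """
    n = ds.n
    if n < 2:
        raise ValueError("need n >= 2")
    dm, comp = distance_matrix(ds)
    iu = np.triu_indices(n, 1)
    diffs = dm.d[iu]
    mnpd = float(diffs.sum() * 2.0 / (n * (n - 1)))
    pi = float(np.mean(diffs / comp[iu]))
    return pi, mnpd


def polymorphic_sites(ds: PopulationDataset) -> int:
    """Number of positions with at least two alleles among called samples."""
    _, mat = encode_matrix(ds)
    S = 0
    for col in mat.T:
        called = col[col >= 0]
        if called.size and np.unique(called).size > 1:
            S += 1
    return S


def tajimas_d(n: int, S: int, MNPd: float) -> float:
    """Tajima's (1989) D from sample size, segregating sites and MNPd.

    Returns NaN when S = 0 (statistic undefined).
    """
    if S == 0:
        return NA
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return NA
    return (MNPd - S / a1) / math.sqrt(var)


def _log_stirling_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |S_n^j|, j=0..n.

    Computed by the recurrence |S_{m+1}^j| = m|S_m^j| + |S_m^{j-1}| carried
    in log space (log-sum-exp), stable up to the sample sizes used here
    (largest study group n = 664).
    """
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S_0^0| = 1
    for m in range(n):
        new = np.full(n + 1, -np.inf)
        if m > 0:
            new[: n + 1] = math.log(m) + row
        new[1:] = np.logaddexp(new[1:], row[:-1])
        row = new
    return row


def fus_fs(n: int, k: int, theta: float) -> float:
    """Fu's (1997) Fs from the Ewens sampling formula.

    S' = P(K >= k | theta) = sum_{j=k}^n |S_n^j| theta^j / (theta)_n with
    (theta)_n the rising factorial; Fs = ln(S' / (1 - S')). theta is the
    MNPd estimate of the scaled mutation rate. Returns NaN when theta <= 0,
    +/-inf when S' saturates numerically.
    """
    if not (1 <= k <= n):
        raise ValueError("need 1 <= k <= n")
    if not theta > 0:
        return NA
    logs = _log_stirling_row(n)
    j = np.arange(n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    log_terms = logs + j * math.log(theta) - log_rising
    from scipy.special import logsumexp

    log_sp = float(logsumexp(log_terms[k:]))
    if log_sp >= 0.0:
        return math.inf
    sp = math.exp(log_sp)
    if sp <= 0.0:
        return -math.inf
    # ln(S'/(1-S')) via log1p for stability near the tails
    return log_sp - math.log1p(-sp)


def _stats_for_dataset(ds: PopulationDataset) -> tuple[float, float]:
    pi, mnpd = nucleotide_diversity(ds)
    S = polymorphic_sites(ds)
    D = tajimas_d(ds.n, S, mnpd)
    k = len(collapse_haplotypes(ds))
    Fs = fus_fs(ds.n, k, mnpd) if mnpd > 0 else NA
    return D, Fs


def neutrality_pvalues(
    ds: PopulationDataset, reps: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Simulation p-values for Tajima's D and Fu's Fs.

    ``reps`` constant-size coalescent datasets are simulated with theta fixed
    at the observed MNPd and matched n; p is the fraction of simulated
    statistics <= observed (left tail, the direction diagnostic of
    expansion). Simulated NaN statistics (monomorphic replicates) count as
    non-extreme.
    """
    if reps < 100:
        raise ValueError("use at least 100 replicates")
    _, mnpd_obs = nucleotide_diversity(ds)
    D_obs, Fs_obs = _stats_for_dataset(ds)
    if mnpd_obs <= 0:
        return NA, NA
    rng = np.random.Generator(np.random.PCG64(seed))
    model = coalsim.DemographicModel.constant(mnpd_obs)
    hits_D = hits_Fs = 0
    for _ in range(reps):
        tree = coalsim.simulate_genealogy(ds.n, model, rng)
        profiles = coalsim.drop_mutations(
            tree, ds.region_set, [1.0] * len(ds.region_set.regions), rng
        )
        sim = PopulationDataset(
            profiles, {p.sample_id: "sim" for p in profiles}, ds.region_set
        )
        D_sim, Fs_sim = _stats_for_dataset(sim)
        if np.isfinite(D_sim) and np.isfinite(D_obs) and D_sim <= D_obs:
            hits_D += 1
        if np.isfinite(Fs_sim) and np.isfinite(Fs_obs) and Fs_sim <= Fs_obs:
            hits_Fs += 1
    return hits_D / reps, hits_Fs / reps


def diversity_summary(
    ds: PopulationDataset,
    population: str,
    reps: int = 0,
    seed: int = 0,
) -> DiversitySummary:
    """Full per-population summary; set ``reps`` > 0 for simulation p-values."""
    sub = ds.subset(population)
    counts = collapse_haplotypes(sub)[population]
    H, H_se = gene_diversity(counts)
    pi, mnpd = nucleotide_diversity(sub)
    S = polymorphic_sites(sub)
    D = tajimas_d(sub.n, S, mnpd)
    Fs = fus_fs(sub.n, len(counts), mnpd) if mnpd > 0 else NA
    p_D = p_Fs = NA
    if reps:
        p_D, p_Fs = neutrality_pvalues(sub, reps=reps, seed=seed)
    return DiversitySummary(
        population=population, n=sub.n, k=int((counts > 0).sum()), S=S,
        H=H, H_se=H_se, pi=pi, MNPd=mnpd, tajima_D=D, fu_Fs=Fs,
        p_D=p_D, p_Fs=p_Fs,
    )


def diversity_table(
    ds: PopulationDataset, reps: int = 0, seed: int = 0
) -> pd.DataFrame:
    """Per-population summary table (one row per population).

    Populations with fewer than 20 samples are flagged in ``small_sample``,
    since their indices are unreliable.
    """
    rows = []
    for i, pop in enumerate(ds.populations):
        s = diversity_summary(ds, pop, reps=reps, seed=seed + i)
        rows.append(
            {
                "population": s.population, "n": s.n, "k": s.k,
                "k_over_n": s.k / s.n, "S": s.S, "H": s.H, "H_se": s.H_se,
                "pi": s.pi, "MNPd": s.MNPd,
                "tajima_D": s.tajima_D, "p_D": s.p_D,
                "D_stars": significance_stars(s.p_D),
                "fu_Fs": s.fu_Fs, "p_Fs": s.p_Fs,
                "Fs_stars": significance_stars(s.p_Fs),
                "small_sample": s.n < 20,
            }
        )
    return pd.DataFrame(rows).set_index("population")
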