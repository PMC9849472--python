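"""Population structure: AMOVA pairwise Fst, gene flow, classical MDS.

Fst follows the Excoffier–Smouse–Quattro AMOVA on the matrix of pairwise
sequence differences; significance comes from permuting individuals between
the two populations. Gene flow M = Nem is the haploid island-model inversion
M = (1 - Fst) / (2 Fst). The Fst matrix is embedded by classical (Torgerson)
metric MDS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DistanceMatrix, PopulationDataset, distance_matrix

logger = logging.getLogger(__name__)

NA = float("nan")


@dataclass
class FstMatrix:
    populations: list[str]
    fst: np.ndarray
    significance: np.ndarray  # permutation p-values, NaN on diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fst, index=self.populations, columns=self.populations)

    def pvalues_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.significance, index=self.populations, columns=self.populations
        )


@dataclass
class MdsEmbedding:
    populations: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    stress: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates,
            index=self.populations,
            columns=[f"dim{i+1}" for i in range(self.coordinates.shape[1])],
        )


def _amova_fst(d: np.ndarray, sizes: list[int]) -> float:
    """AMOVA Fst from a pairwise-difference matrix ordered by population.

    SS_total = (1/N) sum_{i<j} d_ij;  SS_within = sum_p (1/n_p) sum_{i<j in p} d_ij;
    sigma_b^2 = SS_within/(N-2); nbar = (N - sum n_p^2 / N)/(P-1);
    sigma_a^2 = (SS_among/(P-1) - sigma_b^2)/nbar; Fst = sigma_a^2/(sigma_a^2+sigma_b^2).
    """
    N = sum(sizes)
    P = len(sizes)
    iu = np.triu_indices(N, 1)
    ss_total = d[iu].sum() / N
    ss_within = 0.0
    start = 0
    for n_p in sizes:
        block = d[start : start + n_p, start : start + n_p]
        ss_within += np.triu(block, 1).sum() / n_p
        start += n_p
    ss_among = ss_total - ss_within
    sigma_b = ss_within / (N - 2)
    nbar = (N - sum(n**2 for n in sizes) / N) / (P - 1)
    sigma_a = (ss_among / (P - 1) - sigma_b) / nbar
    denom = sigma_a + sigma_b
    if denom == 0:
        return NA
    return sigma_a / denom


def pairwise_fst(
    ds: PopulationDataset,
    popA: str,
    popB: str,
    permutations: int = 0,
    seed: int = 0,
) -> tuple[float, float]:
    """AMOVA Fst between two populations, optional permutation p-value.

    The p-value is the fraction of ``permutations`` random reassignments of
    individuals to the two groups (sizes preserved) whose Fst is >= observed.
    Small negative Fst estimates are reported as computed, not clipped.
    """
    a = ds.subset(popA)
    b = ds.subset(popB)
    if a.n < 2 or b.n < 2:
        raise ValueError("each population needs >= 2 samples")
    merged = PopulationDataset(
        a.profiles + b.profiles,
        {**{p.sample_id: popA for p in a.profiles},
         **{p.sample_id: popB for p in b.profiles}},
        ds.region_set,
    )
    dm, _ = distance_matrix(merged)
    d = dm.d
    sizes = [a.n, b.n]
    obs = _amova_fst(d, sizes)
    if permutations <= 0 or not np.isfinite(obs):
        return obs, NA
    rng = np.random.Generator(np.random.PCG64(seed))
    N = a.n + b.n
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(N)
        dp = d[np.ix_(perm, perm)]
        f = _amova_fst(dp, sizes)
        if np.isfinite(f) and f >= obs:
            hits += 1
    return obs, (hits + 1) / (permutations + 1)


def fst_matrix(
    ds: PopulationDataset, permutations: int = 0, seed: int = 0
) -> FstMatrix:
    pops = ds.populations
    P = len(pops)
    fst = np.zeros((P, P))
    pval = np.full((P, P), NA)
    for i in range(P):
        for j in range(i + 1, P):
            f, p = pairwise_fst(
                ds, pops[i], pops[j], permutations=permutations,
                seed=seed + 1000 * i + j,
            )
            fst[i, j] = fst[j, i] = f
            pval[i, j] = pval[j, i] = p
    return FstMatrix(pops, fst, pval)


def gene_flow_M(fst: float) -> float:
    """Island-model migrant number for a haploid maternal locus.

    M = (1 - Fst) / (2 Fst); Fst <= 0 maps to +inf (panmixia), Fst = 1 to 0.
    """
    if not np.isfinite(fst):
        return NA
    if fst <= 0:
        if fst < 0:
            logger.warning("negative Fst %.4g floored at 0 for gene flow", fst)
        return math.inf
    return (1.0 - fst) / (2.0 * fst)


def gene_flow_matrix(fst: FstMatrix) -> pd.DataFrame:
    P = len(fst.populations)
    M = np.full((P, P), math.inf)
    for i in range(P):
        for j in range(P):
            if i != j:
                M[i, j] = gene_flow_M(fst.fst[i, j])
    np.fill_diagonal(M, NA)
    return pd.DataFrame(M, index=fst.populations, columns=fst.populations)


def classical_mds(fst: FstMatrix, dims: int = 2) -> MdsEmbedding:
    """Classical (Torgerson) metric MDS of the Fst matrix.

    Negative Fst entries are floored at 0 before embedding. The doubly
    centered Gram matrix B = -1/2 J D^2 J is eigendecomposed; coordinates
    use the top ``dims`` non-negative eigenpairs; stress is the fraction of
    total absolute eigenvalue mass not captured.
    """
    D = np.array(fst.fst, float)
    if D.shape[0] < 3:
        raise ValueError("MDS needs at least 3 populations")
    bad = [
        (fst.populations[i], fst.populations[j])
        for i, j in zip(*np.where(~np.isfinite(D)))
        if i < j
    ]
    if bad:
        raise ValueError(f"Fst matrix has undefined entries for pairs: {bad}")
    if (D < 0).any():
        logger.warning("negative Fst entries floored at 0 for MDS")
        D = np.maximum(D, 0.0)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.zeros((n, dims))
    for k in range(dims):
        if eigvals[k] > 0:
            coords[:, k] = eigvecs[:, k] * math.sqrt(eigvals[k])
    total = np.abs(eigvals).sum()
    captured = sum(max(eigvals[k], 0.0) for k in range(dims))
    stress = 1.0 - captured / total if total > 0 else 0.0
    return MdsEmbedding(list(fst.populations), coords, eigvals, stress)
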