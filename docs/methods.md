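# Methods

`mtpopgen` analyses samples of partial human mtDNA sequences — a set of
coding-region windows plus the first hypervariable segment (HVS-I) of the
control region — the way matrilineal population studies of East and
Southeast Asia typically do: per-population diversity and neutrality
statistics, AMOVA-based differentiation, mismatch-distribution demography,
haplogroup classification and admixture accounting, median-joining
networks, and rho-statistic clade dating. This note records the models, the
defaults, the numerical choices, and what the built-in simulator does and
does not emulate.

## Sequence representation and regions

Samples are stored as variant profiles: the set of substitutions relative
to a reference sequence in rCRS coordinates (1-based, positions 1–16569),
restricted to a configured `RegionSet`. Two region sets matter in practice:

* the **screened** windows `{8001–9000, 9801–10900, 16001–16569}` used at
  ingest (2669 positions), and
* the **statistics** windows `{8001–9000, 9801–10900, 16051–16400}`
  (2450 sites, the default `STAT_REGIONS`) on which all diversity and
  structure statistics are computed; the HVS-I flanks are trimmed because
  their call quality and alignment are least reliable.

All sequence lengths are computed from the configured bounds, never
hard-coded. Insertions, deletions and heteroplasmies are ignored on ingest;
every downstream statistic operates on substitution differences. IUPAC
ambiguity codes and gaps become per-position missing data, handled by
pairwise deletion: a pair's difference count ignores positions missing in
either sample, and its compared-site count shrinks accordingly. Haplotype
identity is exact equality of variant sets with missing positions excluded
— deterministic and close to Arlequin's default haplotype definition.

## Diversity and neutrality

* **Gene diversity** H = n/(n−1)(1 − Σp²) with Nei's (1987) sampling
  variance for the standard error.
* **MNPd / π**: MNPd is the mean pairwise difference count over all
  n(n−1)/2 pairs; π divides each pair by its own compared-site count before
  averaging, so π = MNPd/L exactly only when no data are missing.
* **Tajima's D** uses the 1989 constants (a1, a2, b1, b2, c1, c2, e1, e2);
  S = 0 returns NaN rather than a value.
* **Fu's Fs** evaluates the Ewens sampling formula
  S′ = Σ_{j≥k} |S_n^j| θ^j / (θ)_n with unsigned Stirling numbers of the
  first kind, computed by the triangular recurrence carried in log space
  (log-sum-exp). This is stable through n ≈ 700, covering the largest
  sample size the package is designed for (a 664-sample group); Fs =
  ln(S′/(1−S′)) with log1p in the tails. θ is the MNPd estimate (θπ),
  mirroring Arlequin's convention.
* **Neutrality p-values** come from coalescent simulation under selective
  neutrality: constant-size replicates with θ fixed at the observed MNPd
  and matched n (default 1000 replicates), p = fraction of simulated
  statistics ≤ observed. The left tail is used for both D and Fs because
  the alternative of interest is population expansion, which drives both
  statistics negative. Report formatting stars p ≤ 0.02 / 0.01 / 0.001,
  and groups with n < 20 are flagged as unreliable.

The π standard error in reports is a bootstrap-over-individuals Monte Carlo
SE rather than a full covariance expression; the H SE is analytic.

## Structure

Pairwise **Fst** is the Excoffier–Smouse–Quattro AMOVA on the matrix of
pairwise difference counts: SS_total = (1/N)Σ_{i<j}d_ij, SS_within =
Σ_p(1/n_p)Σ_{i<j∈p}d_ij, σ_b² = SS_within/(N−2), n̄ = (N − Σn_p²/N)/(P−1),
σ_a² = (SS_among/(P−1) − σ_b²)/n̄, Fst = σ_a²/(σ_a²+σ_b²). Small negative
estimates are reported as computed — they are floored at zero only inside
gene-flow inversion and MDS, with a logged warning. Significance is by
permutation of individuals between the two populations (Arlequin's
approach), seedable, with the (hits+1)/(B+1) estimator. Note the estimator
is not literally invariant to replicating every sample: its finite-sample
terms make k-fold replication converge to the population-level Fst; the
test suite checks this stability property rather than exact invariance.

**Gene flow** M = Nem uses the haploid island-model inversion
M = (1−Fst)/(2Fst); Fst ≤ 0 maps to +inf and Fst = 1 to 0. The package
reports the full pairwise M matrix; collapsing it into a single
per-population number is left to the caller, since no principled default
aggregation exists.

**MDS** is classical (Torgerson) metric scaling of the Fst matrix: double
centering B = −½JD²J, top-2 eigenpairs, negative eigenvalues excluded, and
stress defined as the fraction of absolute eigenvalue mass not captured.
Euclidean-embeddable inputs are recovered exactly (to 1e−9 in tests).

## Mismatch distributions and the sudden-expansion model

The observed histogram of pairwise differences is fitted by the
Rogers–Harpending sudden-expansion expectation (τ in mutational units, θ0
and θ1 the scaled sizes before and after expansion), with θ1 capped at 1e5,
which behaves as infinite under finite arithmetic. The fit minimises the
plain sum of squared deviations (SSD) between observed and expected class
frequencies — generalised least squares is deliberately not used — by
multi-start Nelder–Mead over a 3×3×3 grid of initial values (τ ∈ {mean/2,
mean, 2·mean}, θ0 ∈ {0, 0.1, 1}, θ1 ∈ {10, 100, cap}), with parameters
optimised on a log1p scale to keep them non-negative. The observed spectrum
is truncated at its largest class J with the model's tail mass pooled into
J. A single-class spectrum yields a τ = 0 fit with a warning.

Harpending's raggedness r = Σ(x_i − x_{i−1})² quantifies smoothness. Both
SSD and r get parametric-bootstrap p-values: B datasets re-simulated under
the fitted model, each re-fitted, p = fraction of replicates at or above
the observed statistic (reported as < 1/B when none is). The expansion
verdict follows the standard rule for these data: expansion is called when
Fu's Fs is significantly negative (p ≤ 0.01) *and* the SSD does not reject
the expansion model (p > 0.02).

## Dating

The rho statistic is the mean substitution count over root-to-tip paths of
a supplied clade genealogy (Newick with integer branch lengths; the package
does not infer trees). Saillard's standard error is
σ = (1/n)√(Σ_l n_l² m_l) over branches. Ages use a complete-mtDNA clock of
one substitution per m = 3.624 kyr with a Gompertz-shaped correction for
purifying selection:

    T(ka) = m·ρ·exp(−exp(−0.0263(ρ + 40.28)))

The correction factor lies in (0,1), discounts young clades most, and tends
to 1 as ρ grows; T is strictly increasing in ρ. Confidence bounds apply the
correction factor evaluated at the central ρ to ρ ± 1.96σ, giving symmetric
intervals whose lower bound may be negative (reported as computed). Report
rounding is one decimal, half-up. A star-genealogy fallback computes ρ from
differences to a supplied root haplotype with σ = √(ρ/n).

For partial sequences the clock is a length-weighted combination of
per-region rates — HVS-I at 1.602e−7 and coding DNA at 3.42e−8
substitutions/site/year (the latter equivalent to one substitution per
13,786 years over 2121 coding sites). `combine_rates` always reports the
value computed from its inputs; a fixed per-sequence interval (e.g. the
commonly used 8,940-year shorthand for this window combination, which is
not exactly reproducible from the component rates) can be supplied as an
explicit override.

## Median-joining networks

Haplotypes are compared over the union of their segregating positions. The
minimum spanning network is the union of all minimum spanning trees (an
edge survives iff its weight equals the bottleneck path weight between its
endpoints, obtained from any one MST). Median joining then iterates:
propose, for every connected triplet of the MSN, the per-position majority
haplotype (ties among three distinct derived bases keep the ancestral
base); greedily accept proposals that reduce the minimum spanning cost
(ε = 0 by default, the standard mtDNA setting; all positions weighted
equally); prune medians whose removal no longer raises the cost; stop at a
fixpoint. Candidates are scanned in lexicographic key order, so the result
is deterministic. Inputs above 5000 distinct haplotypes are refused. On
homoplasy-free data the network connects the observed haplotypes at exactly
the generating tree's mutation count, with medians only at unobserved
internal haplotypes.

## The coalescent simulator

The generator measures time in mutational units: mutations arrive on a
branch of length t as Poisson(t), and k lineages coalesce at rate
k(k−1)/θ. This makes E[pairwise differences] = θ and E[S] = θ·a1 under the
constant model, and lets mismatch τ and the dating clock interconvert
without hidden scaling. The sudden-expansion model switches the coalescence
scale from θ1 (present) to θ0 (ancestral) at time τ/2 before present, so
the expected pairwise-difference mode sits near τ. A two-deme clean split
(no migration, common ancestral scale) supports the structure tests.
Mutations are placed infinite-sites on the finite coordinates of the
configured regions — each mutation consumes an unused position, chosen in a
region with probability proportional to rate × length, with the derived
base uniform over the three non-reference bases; position exhaustion is an
error suggesting a lower θ. All randomness flows through a seeded
`numpy.random.Generator` (PCG64), so runs are reproducible bit-for-bit.

What the simulator emulates: multi-population, region-structured mtDNA
samples with per-region rates, constant-size or sudden-expansion
demography, and known ground truth (genealogy, model, labels). What it does
not: recurrent/back mutation (no homoplasy), rate heterogeneity beyond the
region level, migration beyond a clean split, selection, sequencing error,
and indels. Passing tests therefore demonstrate correctness of the
statistics under the infinite-sites neutral model, not robustness to the
noise real partial-sequencing data carry.

## Problem sizes in the test suite

The recovery and calibration suites run at sizes chosen to keep Monte-Carlo
standard errors comfortably inside the asserted tolerances while finishing
in minutes: τ-recovery at n = 100 × 40 replicates, TMRCA recovery and CI
coverage at n = 50 tips × 200 star clades, null-calibration of the
neutrality p-values at 30 datasets × 100 null replicates, oracle
equivalence of the Ewens formula against 1e5 Chinese-restaurant draws, and
pairwise-distribution equivalence of the expansion expectation against
4000 two-tip simulations.

## Known limitations

* The haplogroup classifier counts defining-variant matches only (no
  penalty for private or conflicting variants) and is meant for clean,
  curated or simulated data — it is not a HaploGrep replacement.
* Admixture partitioning operates at whatever haplogroup resolution the
  caller supplies and on frequency mass, not lineage counts.
* AMOVA is single-level (pairwise) only; no hierarchical designs.
* The mismatch machinery fits the demographic sudden-expansion model only,
  not the spatial-expansion variant.
* Dating assumes the supplied genealogy and substitution counts are exact;
  uncertainty from tree estimation is not propagated.
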