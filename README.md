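# mtpopgen

Population-genetic analysis of partial human mtDNA sequences — the kind of
matrilineal survey used to study the origins and admixture of East and
Southeast Asian populations from a few sequenced windows of the
mitochondrial genome (coding regions 8001–9000 and 9801–10900 plus HVS-I of
the control region, in rCRS coordinates).

It is written for population geneticists and molecular anthropologists who
want, in one scriptable Python package with a CLI:

* **Diversity and neutrality** per population: haplotype count k, gene
  diversity Ĥ ± SE (Nei), nucleotide diversity π, mean number of pairwise
  differences (MNPd), polymorphic sites S, Tajima's D and Fu's Fs with
  p-values from coalescent simulation under selective neutrality.
* **Structure**: pairwise Fst by AMOVA on pairwise sequence differences
  (Excoffier–Smouse–Quattro) with permutation significance, island-model
  gene flow M = Nem = (1−Fst)/(2Fst), and classical MDS of the Fst matrix.
* **Demographic history**: mismatch distributions, least-squares fits of
  the Rogers–Harpending sudden-expansion model (τ, θ₀, θ₁), SSD and
  Harpending's raggedness with parametric-bootstrap p-values, and the
  standard expansion verdict (significant negative Fs + non-rejected SSD).
* **Haplogroups**: a simplified tree-table classifier, frequency tables,
  novel-subclade naming (`M7b2a_8389` style), and two-parent
  shared-haplogroup admixture partitioning.
* **Networks**: minimum spanning and median-joining haplotype networks
  (Bandelt ε = 0).
* **Dating**: ρ-statistic TMRCA with Saillard standard errors and a
  Gompertz-corrected molecular clock,

      T(ka) = m·ρ·exp(−exp(−0.0263(ρ + 40.28))),  m = 3.624 kyr/substitution,

  plus length-weighted per-region rate calibration for partial sequences.
* **A coalescent simulator** (Kingman, mutational time units,
  infinite-sites on the configured regions, constant / sudden-expansion /
  two-deme split models) that generates test data with known truth and
  drives all simulation p-values and bootstraps.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

Simulate a 40-sample population under a sudden expansion (τ = 6, θ₀ = 0.5,
θ₁ = 10⁵), then analyse it:

```bash
cat > sim.json <<'JSON'
{"n": 40, "seed": 7,
 "model": {"kind": "sudden_expansion", "tau": 6.0, "theta0": 0.5, "theta1": 100000.0}}
JSON
mtpopgen simulate --config sim.json --out demo
mtpopgen diversity --fasta demo.fasta --pops demo.pops.tsv \
    --reference demo.ref.fasta --reps 1000 --seed 1 --out demo.div.tsv
mtpopgen mismatch --fasta demo.fasta --pops demo.pops.tsv \
    --reference demo.ref.fasta -B 100 --seed 1 --out demo.mm.tsv
```

`demo.div.tsv`:

```
population  n   k   k_over_n  S    H         H_se        pi          MNPd     tajima_D  p_D  D_stars  fu_Fs     p_Fs  Fs_stars  small_sample
pop1        40  39  0.975     123  0.998718  0.00597186  0.00282104  6.91154  -2.80078  0    ***      -44.1362  0     ***       False
```

`demo.mm.tsv`:

```
population  tau      theta0   theta1   SSD         p_SSD  raggedness  p_rag
pop1        6.65445  0.63203  83.1079  0.00101712  0.79   0.00647765  0.9
```

Reading the numbers: nearly every sampled lineage is a distinct haplotype
(k/n = 0.975, Ĥ ≈ 0.999), Tajima's D = −2.80 and Fu's Fs = −44.1 are both
extremely negative with simulation p-values of 0/1000 (starred ≤ 0.001) —
the classic signature of recent expansion — and the fitted mismatch
expansion time τ̂ = 6.65 recovers the generating τ = 6 while the SSD
p-value of 0.79 shows the sudden-expansion model is not rejected. Under the
standard rule (significant negative Fs, non-significant SSD) this
population is called expanding.

Dating a clade genealogy (Newick branch lengths = substitution counts):

```bash
printf '(a:1,b:0);\n' > clade.nwk
mtpopgen date --tree clade.nwk --out demo.dates.tsv
```

```
clade  n  rho  sigma  T_kyr  ci_low  ci_high
clade  2  0.5  0.5    1.3    -1.2    3.8
```

A two-lineage clade separated by one substitution has ρ = 0.5, Saillard
σ = 0.5, and a corrected-clock age of 1.3 kyr with 95% CI (−1.2; 3.8).

Other subcommands: `structure`, `haplogroups`, `admix`, `network`, and
`all` (full pipeline from a JSON config, writing the complete report
bundle plus a seeded run log).

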