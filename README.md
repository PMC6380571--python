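# rhodate

Molecular dating of clades with the **ρ (rho) statistic**, for population
geneticists and phylogeographers who date haplogroups from
mutation-annotated genealogies (e.g. mtDNA or Y-chromosome trees).

Given a rooted genealogy whose edges carry mutation counts, ρ is the mean
number of mutations over all paths from the most recent common ancestor
(MRCA) to the sampled sequences:

    ρ = (1/n) Σ_i L_i ,      L_i = Σ_{j∈Ψ_i} R_j ,

where `R_j` is the count on edge `j` and `Ψ_i` the root path of leaf `i`.
Under the infinite-sites model `R_j | T_j ~ Poisson(μ T_j)`, so
`E[ρ] = μT` and **ρ/μ is an unbiased estimator of the clade's TMRCA** `T`,
with `μ` the whole-sequence mutation rate per lineage per generation.

The package provides:

- the ρ estimator with three estimated standard errors — the edge-weighted
  **Saillard** form `sqrt((1/n²) Σ_j n_j² R_j)`, a **distinct-haplotype star**
  approximation `sqrt((1/n²) Σ_h f_h² ℓ_h)`, and the star-genealogy **lower
  bound** `sqrt(ρ/n)` — which satisfy `lower ≤ haplotype-star ≤ Saillard` on
  every tree;
- Wald confidence intervals `(ρ ± z·e.s.e.)/μ` and delta-method propagation
  of mutation-rate uncertainty into the age;
- a constant-size Kingman coalescent simulator (haploid convention,
  `θ = 2Nμ`) with Poisson infinite-sites mutation dropping and plain-text
  fixture export (newick in a mutation-count and a time dialect, FASTA);
- simulation experiments measuring the bias of ρ/μ and the coverage of the
  three Wald intervals as a function of θ.

## Worked example

The 4-leaf tree `((L1:0,L2:0,L3:1)A:1,L4:0)root;` (branch lengths are
mutation counts) has path counts L = (1, 1, 2, 0), so ρ = 1. With
μ = 0.01 per generation (s.e. 0.001):

```sh
$ rhodate estimate --tree w.nwk --dialect mutations --mu 0.01 --se-mu 0.001
# tree = w.nwk
# dialect = mutations
# mu = 0.01
# se_mu = 0.001
# se_method = saillard
# level = 0.95
# clamp_zero = False
rho     ese     t_hat   ci_low  ci_high n       se_t_hat_delta
1.0     0.7905694150420949      100.0   -54.94875807614039      254.9487580761404       4       79.68688725254614
```

The clade is dated at ρ/μ = 100 generations; the Saillard standard error of
ρ is `sqrt((3²·1 + 1²·1)/4²) ≈ 0.7906`, giving the 95% Wald interval
(−54.9, 254.9) generations (the lower end is not clamped at zero), and
folding in the rate uncertainty by the delta method gives an age standard
error of ≈ 79.7 generations. The same library calls are
`read_tree`, `compute_rho`, `estimate_age` and `age_se_delta` in
`rhodate`.

Simulation experiments run from the CLI, e.g.

```sh
rhodate bias-experiment --n 100 --big-n 1000 --mu 0.00234 --reps 10000 \
    --seed 1 --out-dir out/
rhodate coverage-experiment --theta-grid 1,5,10,20 --reps 2000 --seed 1 \
    --out-dir out/
```

writing TSVs with a `#`-prefixed provenance header. A small coverage run
(n = 20, N = 500, 200 replicates per θ) illustrates the characteristic
pattern — Saillard coverage approaching the nominal 95% as θ grows while the
haplotype-star coverage moves away from it, and the lower bound poor
throughout:

```
 theta  n     N  reps  coverage_saillard  coverage_cox  coverage_lower
   1.0 20 500.0   200               0.73         0.700           0.485
   5.0 20 500.0   200               0.90         0.735           0.430
  20.0 20 500.0   200               0.94         0.605           0.460
```

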