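# Methods

## The estimator

A clade's genealogy is a rooted tree whose root is the most recent common
ancestor (MRCA) of the `n` sampled sequences. Edge `j` has time length `T_j`
generations and carries `R_j` mutations; `Ψ_i` is the set of edges on the path
from the root to leaf `i`, and `L_i = Σ_{j∈Ψ_i} R_j` is the number of
mutations separating leaf `i` from the ancestral haplotype. The rho statistic
is the mean of these path counts,

    ρ = (1/n) Σ_i L_i = (1/n) Σ_j n_j R_j ,

where `n_j` is the number of leaves below edge `j`. Under the infinite-sites
model with whole-sequence mutation rate `μ` per lineage per generation,
`R_j | T_j ~ Poisson(μ T_j)` independently across edges, so each
`L_i | {T_j} ~ Poisson(μT)` where `T` is the TMRCA, and

    E[ρ] = μT        ⇒        E[ρ/μ] = T .

ρ/μ is therefore an unbiased estimator of the TMRCA whether the `T_j` are
treated as fixed or as the outcome of a coalescent process. The `L_i` are
generally *not* independent — leaves below a shared edge share its mutations —
which affects the variance, not the mean. `compute_rho` evaluates both the
leaf form and the edge form of ρ and requires the two integer totals to agree
exactly, as a structural self-check. All formulas are edge-based, so
multifurcating trees are supported without special handling, and `n = 1` is
legal (ρ = L_1).

## Three standard errors

Conditionally on the tree, `Var(ρ) = (1/n²) Σ_j n_j² μT_j`. Replacing the
unobservable `μT_j` by its unbiased proxy `R_j` gives the **Saillard**
plug-in estimator

    ese_saillard = sqrt( (1/n²) Σ_j n_j² R_j ) ,

which accounts for the covariance of the `L_i` through the `n_j²` weights.

The **distinct-haplotype star** estimator applies the same formula to a
fictitious star tree whose "leaves" are the distinct haplotypes: block `h` of
the haplotype partition has multiplicity `f_h` and root distance `ℓ_h`
(mutations), giving

    ese_cox = sqrt( (1/n²) Σ_h f_h² ℓ_h ) .

This treats the per-haplotype mutation counts as independent, which they are
not when haplotypes share internal edges. The algebraic form here is a
**reconstruction** from the verbal characterisation of the estimator
("star-like in the distinct haplotypes", i.e. the Saillard formula at the
haplotype level); the original expression is not reprinted in the sources
available to this package, and users with access to it should cross-check.

The **lower bound** assumes a perfectly star-like genealogy of the sequences:

    ese_lower = sqrt(ρ/n) .

Ordering. For every genealogy `ese_lower ≤ ese_cox ≤ ese_saillard`. Both
inequalities are algebraic, not statistical: the leaves below a mutated edge
`j` are a disjoint union of haplotype blocks, so `Σ_{h∋j} f_h = n_j` and hence
`Σ_{h∋j} f_h² ≤ n_j²` (Saillard ≥ Cox), while `f_h² ≥ f_h` gives
`Σ_h f_h² ℓ_h ≥ Σ_i L_i = nρ` (Cox ≥ lower). On a star tree all three
coincide at `sqrt(ρ/n)`. Because the three Wald intervals share the centre
ρ/μ, their hit indicators are nested replicate by replicate, which is why the
coverage curves are ordered pointwise, not just on average.

Haplotype identity uses the infinite-sites rule: two leaves carry the same
haplotype iff every edge in the symmetric difference of their root paths
bears zero mutations. Under recurrent mutation this is an approximation; it
is documented, not configurable.

## Intervals and rate-error propagation

The Wald interval for the age at level `1-α` is `(ρ ± z · e.s.e.)/μ` with `z`
the exact standard-normal quantile (1.959964 at 0.95, rather than the rounded
1.96; the difference is far below Monte-Carlo resolution and the level is
configurable). The lower end is **not** truncated at zero by default — the
coverage experiment must evaluate the interval as defined — though a
`clamp_zero` flag exists for reporting.

When the mutation rate itself carries an estimated standard error `se_μ`, the
first-order delta method with ρ and μ̂ treated as independent (no covariance
term is available) gives

    SE(ρ/μ) = sqrt( ese_ρ²/μ² + ρ² se_μ²/μ⁴ ) .

## The simulator and what it does (not) emulate

Genealogies come from the constant-size Kingman coalescent in the **haploid
convention**: with `k` lineages left, the waiting time to the next merger is
Exponential with rate `k(k−1)/(2N)` generations, and a uniform random pair
merges; `θ = 2Nμ`. Waiting times are continuous exponentials (no
discrete-generation Wright–Fisher approximation). `E[TMRCA] = 2N(1−1/n)`.
Mutations are then dropped per edge as independent `Poisson(μT_j)` draws;
`export_fixture` can realise them as unique sites of a sequence alignment
(default length 500), erroring if the mutation total exceeds the length.

Default study condition (the defaults of `CoalescentConfig`): haploid
`N = 1000`, `n = 100`, `μ = 0.00234` per generation per whole sequence
(derived as 1.8×10⁻⁷ per bp per year × 26-year generations × 500 bp), hence
`θ = 4.68`, with 10,000 replicates.

The generator emulates exactly the model under which ρ's properties are
derived. It does **not** emulate: recurrent or back mutation (finite sites),
site-to-site rate heterogeneity, purifying selection, population growth or
structure, or phylogenetic reconstruction error (the estimator sees the true
simulated genealogy, whereas real analyses see an inferred one). Passing
tests therefore validate the mathematics and the implementation, not the
robustness of ρ dating to violations of the infinite-sites clock model on
real data.

## Randomness and determinism

All randomness flows from one integer seed. Each replicate uses an
independent `numpy` `SeedSequence` substream keyed by `(seed, replicate id)`,
so records are independent of evaluation order and identical configurations
reproduce bit-identical output; each θ value in the coverage experiment gets
its own substream of the base seed, and within a θ the three standard-error
methods are evaluated on the same replicates (a matched comparison).

## Experiments and problem sizes

`run_bias_experiment` records `(T_true, ρ/μ)` pairs, the mean signed error,
and the least-squares regression of estimate on truth **through the origin**
(`slope = Σxy/Σx²`, `se = sqrt(Σ(y−bx)²/((m−1)Σx²))`; plain, unweighted).
The slope's significance check uses the normal approximation. At the default
condition the mean error is a mean-zero Monte-Carlo draw with standard error
of roughly 6–7 generations at 10⁴ replicates, against a mean TMRCA of ~1980.

`run_coverage_experiment` varies θ through μ at fixed `n` and `N` (coverage
on the generations scale is invariant to which factor of θ varies) over a
default grid {0.5, 1, 2, 5, 10, 20, 50} spanning the transition near θ ≈ 10:
Saillard coverage is anti-conservative at small θ and approaches the nominal
level as θ grows, the distinct-haplotype-star coverage moves the opposite way
and sits below it everywhere, and the lower bound is poor throughout.

Test-suite problem sizes: the bias study runs at the full condition (10⁴
replicates); variance-oracle checks use 10⁴ mutation redraws on a fixed
20-leaf tree; coverage trends use 2,000 replicates at each of
θ ∈ {1, 5, 10, 20}; estimator-ordering checks fuzz 1,000 random
multifurcating trees. Monte-Carlo assertions use 4-standard-error bands, with
the variance comparison's band derived from the fourth central moment.

## Numerical choices

- Ultrametricity tolerance: relative 10⁻⁹ (coalescent times are exact sums
  of simulated reals; anything looser would mask bookkeeping bugs).
- Mutations-dialect newick: branch lengths must be exact integers; a
  `round_mutations` flag accepts deviations up to 10⁻⁶. Silent rounding is
  off by default because it hides data errors.
- The newick root is taken as the MRCA; explicitly unrooted input (`[&U]`)
  is rejected, and re-rooting is out of scope.
- ρ = 0 (no mutations) yields a degenerate interval (0, 0) and all three
  standard errors equal to 0.

## Known limitations

- The distinct-haplotype star standard error is a reconstruction (above).
- No support for variable population size, recombination, selection, or
  multiple-merger coalescents; no tree inference.
- Conversion to calendar time is a plain multiplier (`--generation-time`);
  calibration of μ itself is out of scope.
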