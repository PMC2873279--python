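# Methods

`junglecoal` implements a multilocus population-genetic analysis of the
origin of domestic chickens (*Gallus gallus domesticus*) relative to red
junglefowl (*G. g. gallus*, "R") and green junglefowl (*G. varius*, "G"),
exercised end to end on a built-in coalescent simulator that emulates the
original sampling design: ~26 autosomal intron alignments (227–1,121 bp) for
18 *Gallus* chromota — two sequenced breeds of four diploid birds each, two
single-representative breeds, four red and four green junglefowl — plus an
outgroup.

All scaled parameters are per-site and dimensionless: θ = 4N_e μg is the
expected pairwise diversity of a population and τ = t_s μ the expected
substitutions per lineage since a species split (μ in substitutions/site/yr,
g the generation time in years).

## Haplotype calling (`locus_io`)

Haplotypes are equivalence classes of aligned intron sequences under exact
column-wise identity.  Two pragmatic rules handle real-data artifacts:

- `N` is a missing site and matches any base.  A sequence containing `N`
  merges into the first fully resolved class it is compatible with and
  founds its own class otherwise.  This maximizes the use of incompletely
  sequenced clones without inventing alleles; ambiguity codes other than `N`
  are rejected.
- The alignment gap `-` is a fifth character state for haplotype identity
  (intron alleles include indel variation) but is always excluded from
  distance computations, which are per-nucleotide-site.  A flag
  (`indels_distinct=False`) collapses indel-only variants for sensitivity
  analysis, since published haplotype counts do not state the convention.

Hardy–Weinberg expected homozygote counts use the plug-in n_ind·Σp̂²; the
small-sample form (nΣp̂²−1)/(n−1) is available behind `corrected=True`.
Sharing summaries classify each distinct haplotype by the set of species
pools carrying it (all three / chicken+R / chicken+G / R+G / single-pool);
the pairwise "shared proportion" of a locus is the number of haplotypes
carried by both pools over the number carried by either.

## Distances and diversity (`popgen_stats`)

p-distances use pairwise deletion (sites with `-` or `N` in either sequence
are dropped).  Corrections: JC69 d = −(3/4)ln(1−4p/3) and K2P
d = −½ln(1−2P−Q) − ¼ln(1−2Q).  π is the mean over all within-group
chromosome pairs, d the mean over between-group pairs; across-locus
summaries are unweighted means ± s.d. over loci (a length-weighted variant
is flag-selectable; published summaries appear unweighted).  The default
correction for tables is JC69 — at π < 2% the JC/K2P difference is below
reporting precision.

The Ewens infinite-alleles expectation E(H) = Σ_{i=0}^{n−1} θ/(θ+i) is
evaluated with θ = π·L (per-locus diversity times aligned length), which
reproduces the published E(H) columns from the printed (π, L, n).

## Phase-resampling consensus tree (`phase_tree`)

Phase between introns is unknown for cloned diploid sequences, so an
individual is represented by concatenating one uniformly chosen haplotype
copy per locus.  Per draw: pairwise p-distances with pairwise deletion
across sites and loci → Saitou–Nei neighbor joining → rooting at the edge
separating all outgroup individuals.  Clade support is the proportion of
draws (default R = 1,000; desk scale 200) whose rooted tree contains the
clade, and the average-difference tree is NJ on the p-distances averaged
over draws (p_a).  Numerical conventions: Q-minimizing pair ties break to
the lowest index pair, branch lengths clamp at 0, and a draw whose outgroups
are not separable counts as non-monophyletic for every focal clade (logged).
Unrooted bipartition scoring is available (`rooted=False`); rooted is the
default.

## Two-species likelihood (`tsl`)

For one sequence per species at a locus of L compared sites, the number of
differences is modeled as k ~ Poisson(L(2τ + x)) with the ancestral
coalescent contribution x ~ Exp(θ).  Marginally

P(k|L,θ,τ) = (1+Lθ)^{-1} (Lθ/(1+Lθ))^k e^{-m} Σ_{j≤k} (βm)^j/j!,
β = (1+Lθ)/(Lθ), m = 2τL,

computed in log space by finite logsumexp (no cancellation); the Poisson
limit is used below Lθ = 1e-12, and the closed form is validated against
adaptive quadrature to 1e-10.  The joint log-likelihood over loci is
maximized by bounded L-BFGS-B from five deterministic starts spreading the
weighted mean difference d̄ = Σk/ΣL between θ and 2τ, because the surface is
a ridge along θ + 2τ ≈ d̄; the fit reports the Hessian eigenvalues at the
optimum so the ridge is visible to callers.  Counts k are raw differences
(no multiple-hit correction) — the likelihood already models the
substitution process.  The resampling wrapper redraws one chromosome per
species per locus (default 1,000 times) and reports mean ± s.d. and median
in percent.

## Three-species coalescent MCMC (`msc_mcmc`)

A Metropolis-within-Gibbs sampler for
(θ_C, θ_R, θ_G, θ_CR, θ_RCG, τ_CR, τ_RCG) under the multispecies coalescent
with fixed topology ((C,R),G).  Latent per-locus genealogies treat every
chromosome (both copies of each diploid) as a tip.  Sequence likelihood is
Jukes–Cantor via Felsenstein pruning with site-pattern compression; gaps and
N are missing data.  JC69 is the minimal model consistent with the distance
corrections used elsewhere in the pipeline.

The genealogy prior is the structured coalescent: within a population with
parameter θ each lineage pair coalesces at rate 2/θ; populations C and R
merge into CR at τ_CR and CR joins G at τ_RCG.  Validity constraints (a node
joining C- and R-descended lineages lies above τ_CR; anything involving G
above τ_RCG) are enforced by rejection.  The density factorizes over
populations through sufficient statistics (coalescence counts and
integrated pair-time), so θ updates are O(1).

Moves per sweep:

- multiplicative random walks on each θ and τ (fixed genealogies);
- a **rubber-band** move for each τ: node ages in the populations bounded by
  the moving τ are rescaled linearly with it — descendant populations scale
  by τ'/τ, the ancestral band maps linearly onto its fixed upper anchor
  (τ_RCG for τ_CR) and, because the root population has no upper anchor,
  every node above τ_RCG scales multiplicatively with it.  The acceptance
  ratio carries the Jacobian of this deterministic time map.  Without this
  move the boundary times are pinned by the latent node ages and the chain
  mixes prohibitively slowly;
- per locus: a node-age slide (uniform within the parent/children bracket;
  multiplicative for the root) and a nearest-neighbour interchange drawn
  symmetrically over (node, child-slot) pairs, both with incremental pruning
  along the ancestor path only; an occasional independence redraw of the
  genealogy from the coalescent prior (likelihood-ratio acceptance);
- a global scaling of all seven parameters and every node age (Jacobian
  accounted), which travels along the θ+2τ ridge.

Correctness is verified by prior recovery — with zero-length loci the
parameter marginals must reproduce the independent gamma priors to within
Monte-Carlo error, a check the test suite runs on every chain kernel — and
by cross-checking cached log-likelihoods and sufficient statistics against
from-scratch evaluation after long move sequences.

Priors are gamma distributions whose means are moment estimates from the
data: pooled π for the ancestral θs, half the net between-species divergence
for the τs, and — for the extant θs — the within-species identity fraction
inverted through f = 1/(1+θL) (the same moment-generating-function identity
behind P_C).  The identity fraction weights recent coalescence, which
matters because under a shallow split (τ_CR ≪ θ_CR) within-species π is
dominated by ancestral diversity and overestimates extant θ several-fold; a
prior centred on π would then misplace the posterior of the weakly
identified trio (θ_C, θ_R, τ_CR).  For the same reason the default shape is
1 (an exponential — the maximally diffuse gamma with the given mean): the
plug-in moments are rough, and a shape-2 prior both overweights them and
vanishes at the origin, biasing small-valued parameters upward.  The
original analysis's exact prior values are not published; these are stated
substitutes, the shape is configurable, and alternative prior sets are
accepted via the API to reproduce the robustness check that estimates do not
depend much on them.  The τ ordering τ_CR ≤ τ_RCG truncates the product
prior (violating proposals are rejected).

Genealogies are initialized from the data rather than the prior: UPGMA on
JC distances per locus, with node ages pushed up where the species-boundary
constraints require.  Starting near data-consistent node ages removes most
of the burn-in transient, which matters at the desk profile's short burn-in.

Chain profiles: the faithful profile is 10,000 burn-in + 200,000 iterations
with thinning 2 and six independent runs (100,000 retained genealogy samples
per run); the desk profile used by tests and example analyses is 2,000 +
20,000 with two runs.  Runs are compared by across-run dispersion of the
posterior means: a parameter is flagged non-converged when the s.d. of run
means exceeds 10% of the pooled posterior s.d.

## Calibration (`calibrate`)

μ = d/(2T) from a calibration divergence and split time (defaults: quail vs
chicken, d = 12 ± 0.5% at T = 35 Myr, giving 1.7±0.07 × 10⁻⁹/site/yr); the
mtDNA D-loop rate is 1.7× the nuclear rate (the observed d_mt/d_nuc ratio in
the green-junglefowl comparison block).  Conversions: t = τ/μ or d/(2μ);
N_e = θ/(4μg) with g = 1 yr.  Errors propagate linearly.

The identity-by-descent probability for two haplotypes of length L sampled
across a species boundary is P_C = e^{−2τL}/(1 + θ_anc L): zero mutations on
both branches since the split, averaged over the exponential ancestral
coalescent contribution (whose moment generating function supplies the
1/(1+θL) factor).  The formula is validated against a Monte-Carlo
coalescent-plus-Poisson oracle.  Note the naive e^{−2μtL} (ignoring
ancestral polymorphism, ≈ 0.047 at L = 250 and t = 3.6 Myr) does not
reproduce the published "<0.005 at L > 250 bp" threshold; the mixture
formula here is this package's definition and the discrepancy is a known
open point, so that threshold is not asserted anywhere.

## Simulator (`synth`)

A structured-coalescent simulator on the per-site mutation time scale, so θ
and τ are consumed without unit conversion.  Default truth is the published
three-species posterior point estimate (θ_C = 0.26%, θ_R = 0.11%,
θ_G = 0.34%, θ_CR = 0.71%, θ_RCG = 1.61%, τ_CR = 0.01%, τ_RCG = 0.63%),
with a quail-like outgroup at τ_out = 0.06 so the outgroup divergence is
≈ 12%.  Default locus lengths are the 26 autosomal intron lengths with
complete three-species data.  Sequences evolve by Jukes–Cantor from a
uniform random ancestral sequence (introns are treated as unconstrained);
mutation counts are Poisson(L × branch length).

Optional features mirroring the study: recent unidirectional introgression
(lineages of configured recipient individuals jump to the donor population
at a recent time with probability 1 by default, mimicking the two admixed
green junglefowl, in which every cross-species shared haplotype was found);
per-breed inbreeding (with coefficient s an individual carries two copies of
one chromosome at a locus with probability s; the default study profile uses
s = 0.4 for the two sequenced breeds, chosen to reproduce the observed
roughly two-fold homozygote excess); missing-data injection to exercise the
incomplete-matrix code path; and a maternal haploid mtDNA-like locus
simulated with N_e/4 and a 1.7× substitution rate.

What the simulator does not emulate: intralocus recombination, selection,
population growth, geographic structure within species, base-composition
bias, and sequencing/cloning error.  Two consequences matter for
interpreting test results.  First, at the study-truth parameters the model
makes chickens and red junglefowl nearly panmictic (τ_CR ≪ θ), so within-
species π for C and R is dominated by the ancestral θ_CR — simulated π_C is
≈ 0.7%, matching the *observed* study diversity, and species-clade support
for C and R is weak, unlike the strong clustering in the real data (which
suggests population structure beyond the clean isolation model).  Clade-
support properties are therefore tested under a deep-divergence scenario
where the model predicts certain monophyly.  Second, coalescent expectations
such as E[π] = θ hold only for isolated populations and are tested in that
regime.  The simulator is cross-validated against msprime on a
two-population scenario in `analysis/01_simulate_catalog.py`.

## Problem sizes in the test suite

Tests run the pipeline at desk scale: phase resampling at R = 200, TSL
recovery over 100 replicate 26-locus data sets, Monte-Carlo oracles at 10⁴–
10⁵ replicates, and a single desk-profile MCMC chain for the coverage check.
These sizes are the package's own test design; the faithful profiles
(R = 1,000; six 210k-iteration chains) are available via configuration.
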