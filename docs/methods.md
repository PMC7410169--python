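# Methods

`demarg` samples ancestral recombination graphs (ARGs) for a small set of
genomes conditional on a user-defined demographic model, and reads
introgressed tracts off the sampled ARGs as lineages that follow a
*migration band*.  This note records the model, the discretizations and
numerical choices, what the synthetic-data generator does and does not
emulate, and the known limitations.

## The model

**Demography.** A model is a rooted population tree with piecewise-constant
diploid effective sizes, a discrete grid of K coalescence times
(years before present, densest near the leaves; the default grid has
K = 20 points from 0 to 15 Mya), and a set of migration bands.  Divergence
and migration events sit at *half time-points*, the arithmetic midpoints of
adjacent grid times; user-supplied event times are rounded to the nearest
half time-point (ties toward the younger one).  Sampling ages are rounded to
the nearest grid time.  All user-facing times are in years and are converted
to coalescent units through the generation time (default 29 years).

A migration band `source -> dest` (forwards in time) at half time t with
prior rate p_M (default 0.01) means: a lineage traced backwards that sits in
`dest` when it crosses t follows the migrant path — relabelling to `source`
— with prior probability p_M, and stays with probability 1 − p_M.  The
*population path* of a lineage is the resulting assignment of one population
per grid time.  With at most one migration per path (the default), a lineage
has 1 + (number of bands whose destination lies on its resident path)
paths; the maximum path count over lineages is the P in the threading
complexity O(L·n·k²·P²).

**Ghost populations** (e.g. an unsampled "super-archaic" hominin) carry no
samples and no size: the coalescence intensity inside them is zero.  Under
the max-one-migration rule at most one migrant lineage can occupy a ghost
population at a genomic position, so no within-ghost coalescence is ever
needed and the ghost's size is irrelevant to the inference.

**Threading HMM.** One MCMC iteration removes each haploid lineage in turn
from every local tree ("unthreading") and re-samples its coalescence points
("threading") with a hidden Markov model along the compressed columns.  A
state is (branch, time, path): the branch of the local tree coalesced onto,
the grid time of coalescence, and the population path of the new branch.
States are enumerated subject to co-location (the new branch's path and the
target branch's path occupy the same population at the coalescence time);
when the fixed tree already carries a migrant branch, migrant paths are
pruned (max-one-migration), but coalescing onto the migrant branch *below*
the band — inherited introgression — remains available via resident paths.

The re-coalescence prior over states discretizes the structured coalescent:
traced from its sampling age upward, the new lineage coalesces out of
interval m (between grid times m and m+1) with probability
1 − exp(−c_m Δ_m / (2 N_pop(m))), where c_m is the number of co-located
fixed branches and Δ_m the interval length in generations; the event is
assigned to the grid time at the top of the interval and divided equally
among the c_m branches.  Every band opportunity on the path multiplies in
p_M (taken) or 1 − p_M (passed).  Survival mass remaining past the oldest
grid time is added to the path's states at the top time (forced
coalescence), which keeps the relative path weights exact — with no data,
the prior probability that the threaded lineage crosses a band is exactly
its p_M-weighted path prior (this is asserted by a dynamic-programming test).

Between adjacent columns the state persists with probability
exp(−r·b·span) (r recombination rate per bp per generation, b the new
branch length in generations, span the width of the column in bases); the
complementary recombination mass re-coalesces according to the prior above.
Across a recombination breakpoint of the *fixed* partial ARG, states are
carried over by (branch leaf-set, time, path) identity; survival mass of
states with no counterpart is forced through re-coalescence.  Rows of every
transition matrix sum to one.  The exact transition structure of the
original threading samplers differs in detail (it resolves where on the new
branch the recombination occurred); forward likelihood and sampled-path
posteriors here are validated against exhaustive path enumeration of this
model on small instances to 1e-8 relative error, which is the correctness
contract.

**Emissions.** A symmetric two-state substitution model per column,
conditioned on the ancestral state (allele 0) at the root: the emission of a
column for a candidate state is the Felsenstein-pruning likelihood of the
observed alleles on the local tree with the new branch attached, with flip
probability (1 − exp(−2 μ t))/2 per branch.  Compression scaling: an
invariant compressed column representing c bases uses rate μ·c; a variant
column keeps a single representative site at rate μ.  Missing alleles
contribute likelihood one; an all-missing column has emission one in every
state, and in the zero-rate limit an invariant column's emission tends to
one.  Because emissions are shared by states with the same (branch, time)
and by columns with identical data and rate, both are grouped before
computation; the forward pass is scaled per column (log-space is tested
against it on small instances but not used in production, for speed).

**MCMC schedule.** The production defaults mirror a standard run: 2000
iterations, 500 burn-in, one retained sample every 20 iterations (75
samples), with migrant states disabled for the first 100 iterations
(`start_mig`) so the chain first establishes a sound ARG.  Initialization
threads the lineages sequentially in input order with migrant states off.
Unphased diploids have their phase randomized at load time and re-sampled
during their re-threading: at each heterozygous column the two alleles are
re-assigned to the individual's two lineages proportional to the emission
likelihood under the current local tree.  A single seeded generator drives
all randomness; identical (data, model, config, seed) reproduce the sample
stream byte for byte.

**Calling.** For a band and diploid individual, P_het(col) and P_hom(col)
are the fractions of retained ARG samples in which exactly one or both of
the individual's lineages are migrant (their ancestral line crosses the
band) at the column; P_any = P_het + P_hom by construction.  Regions are
maximal runs of columns with P_any ≥ 0.5 (inclusive threshold), converted
to base pairs; a region's zygosity is assigned by bp-weighted majority of
hom vs het mass within the run, and no smoothing is applied across
sub-threshold gaps (a merge distance knob exists, default 0).  Diploid
coverage is (het/2 + hom)/callable.  Haploid samples (the outgroup) are
excluded from individual-level calling.

## Synthetic data

The simulator builds the same demographic model in msprime (population
splits, piecewise sizes, ancient sampling ages), adds the migration bands as
instantaneous pulses with user proportions, and records a census one
generation above each pulse time.  A tract is *truth-migrant* for a haploid
lineage exactly where its census ancestor sits in the band's source
population — the basewise oracle that power studies score against.
Mutations are dropped under a binary model from a synthetic piecewise rate
map (gamma-distributed 100-kb window rates rescaled to average exactly
1.45e-8 per generation per site); recombination is constant 5e-9 per bp per
generation by default.  Degradation utilities randomize the phase of
unphased diploids (the unordered genotype per site is invariant) and apply
BED-style missingness masks.

The deep-introgression preset mirrors the study design: 2 African + 2
Neanderthal (ages 115 and 52 ky) + 1 Denisovan (72 ky) unphased diploids, a
haploid chimpanzee outgroup, pulses Hum→Nea 8%, Sup→Den 4%, Sup→Afr 0.5% at
a common migration time, and control bands Sup→Nea / Hum→Den carrying no
migrants.  The recent-introgression preset adds a European population
(split 100 kya, size 2,100, exponential growth 0.002/generation from 42 kya
to a present size of 37,236) with a 2% Neanderthal pulse at 50 kya and an
optional 5% reverse pulse at 250 kya for direction-confusion experiments.

Default sizes: African 23,700; archaic populations use a simplified
three-epoch decline (Neanderthal 2,000 / 3,400 / 5,000 and Denisovan
2,000 / 2,500 / 5,000 going backwards; full PSMC trajectories can be passed
as piecewise sizes); Neanderthal–Denisovan ancestor 10,000;
modern–archaic ancestor 18,500.  Divergences: Nea–Den 415 kya,
human–archaic 575 kya, super-archaic 1.0 or 1.5 Mya, chimpanzee 6 Mya.

What the generator does *not* emulate: a real recombination map (constant
rate by default, though any map can be passed), sequencing error and
genotype-quality masking (missingness is injected only through explicit BED
masks), and real mutation-map structure beyond window-scale rate variation.
Passing tests on these data shows the sampler recovers truth under its own
model class with realistic rates and ages; it does not certify performance
under real-data artefacts.

## Scaled-down studies

The power / false-positive / dating studies replicate the full design
(100 × 2 Mb windows, 2000-iteration chains) at desk scale: a few windows of
50–100 kb, compression 20, chains of 50–70 iterations with ~10–14 retained
samples, rates aggregated basewise across windows.  Two design choices keep
the scaled estimand aligned with the full-scale one:

- Power-study windows are conditioned on containing at least one truth
  tract for the focal band (basewise TP is measured on truth bases only, so
  this is an efficiency device, not a bias), with the tract union covering
  between 5% and 60% of the window — at megabase scale a deep tract
  essentially always has non-migrant flanks, whereas a short replicate
  window is easily saturated edge to edge, which removes the boundary
  contrast the HMM uses.
- False-positive rates are estimated exclusively from no-migration control
  windows, matching the study design they replicate; call overhang at the
  edges of true tracts (the documented ascertainment bias toward longer
  regions) is therefore not counted as false-positive mass.

At this scale the estimates are lumpy: a single spurious region of a few kb
moves a per-band FP estimate by percents, and short truth tracts (a few kb)
are genuinely sub-detectable, so measured power runs below full-scale
values, most visibly for older migration times.  Uncertainty is therefore
quoted from window-level replication rather than basewise binomial counts.

## Dating by the frequency spectrum

Called regions for a band are classified by joint zygosity across the
recipient diploids (for two Neanderthals: Alt{Het,Hom} × Vin{Het,Hom}; the
all-hom class is "doubly homozygous" — migrant on all four lineages).  The
older the pulse, the larger the doubly-homozygous share of called bases.  A
candidate migration time is *accepted* when the bootstrap confidence
intervals (resampling introgressed elements, bp-weighted fractions, 95%,
100 replicates by default) of its simulated, caller-ascertained spectrum
overlap the observed intervals in every category.  No likelihood over
spectra is defined — only the CI-overlap rule.

## Numerical choices and degenerate inputs

- Coalescence times tie freely on the grid: internal branches may have zero
  length (child and parent at the same grid time); leaf branches must be
  strictly positive.  Coalescence onto a branch exactly at its bottom node's
  time is excluded (it would duplicate states on the child branch).
- Internal nodes are renumbered canonically after every edit — sorted by
  (time, descendant leaf-set) — so serialized ARGs are byte-stable per seed.
- The unthread record stores, per segment, the sibling's leaf set, the
  coalescence time, and both the removed branch's and the parent branch's
  path ids; re-threading from a record reconstructs the original ARG
  exactly (round-trip asserted).
- Forward scaling is per column; a column whose likelihood is zero in every
  state raises with the column index rather than silently underflowing.
- Sites with more than two observed alleles are dropped at load time with a
  counter; 'N' is missing; masking is explicit via BED intervals only (an
  invariant compressed column is missing for a lineage when more than half
  its bases are masked).

## Limitations

- Only leaf-lineage re-threading moves are implemented; internal-branch and
  interval-resampling moves found in older threading samplers are not.
  Mixing over configurations that require several coordinated changes (e.g.
  homozygous introgression shared by all four archaic lineages) is
  correspondingly slower, and short chains under-call such regions.
- At most one migration per population path; back-migrations and multiple
  stacked events at one position are outside the state space by design.
- The transition model is a self-consistent discretized SMC (validated
  against enumeration), not a formula-level reimplementation of any
  particular legacy sampler.
- Two bands sharing one half time-point for the same recipient are weighted
  independently (a path takes at most one of them; each contributes its own
  p_M / 1−p_M factor).
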