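# Methods

`psmckit` infers demographic history from diploid consensus genomes: the
per-site IUPAC consensus of one individual (or of an in-silico pseudo-diploid
built from two individuals) is the only sequence input the pipeline needs.
This note records the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## The coalescent HMM

The core model is the pairwise sequentially Markovian coalescent HMM over a
binned diploid genome. The genome is cut into windows of `s` = 100 bp; each
window is observed as `K` (contains at least one heterozygous call), `T`
(callable and all homozygous) or `N` (more than 90% of the window missing).
The hidden state of a window is the discretised time to the most recent
common ancestor (TMRCA) of the two haplotypes, measured in units of 2·N0
generations and cut into `n` log-spaced atomic intervals

    t_j = 0.1 · (exp((j/n)·ln(1 + 10·t_max)) − 1),   j = 0..n,  t_max = 15,

with the last interval extended to infinity for probability mass. Relative
population sizes λ_k (one per atomic interval) are tied into groups by a
time-segmentation pattern; the default `4+25*2+4+6` gives 64 atomic
intervals and 28 free parameters.

Model pieces, all with exact closed forms (no quadrature):

* **Prior** — the pairwise coalescent distribution over intervals under the
  piecewise-exponential survival function with hazard 1/λ.
* **Emission** — P(K | state j) = 1 − exp(−θ·t̄_j), with t̄_j the interval's
  conditional mean TMRCA under the current λ and θ = 4·N0·μ·s the per-window
  scaled mutation rate. `N` is emitted with probability one in every state,
  so masked windows carry no emission information but keep the spatial chain
  intact — this is the mechanism that makes repeat-masking matter.
* **Transition** — with probability 1 − exp(−ρ·t̄_i) the window's genealogy
  recombines; the breakpoint height is uniform on [0, t̄_i] and the erased
  lineage re-coalesces from there under the same λ (the SMC kernel). The
  re-coalescence integrals reduce to piecewise-exponential expressions, so
  the transition matrix is assembled from stable array arithmetic
  (row sums are exact to machine precision).

### Fitting

Expected start/emission/transition counts come from a scaled forward–backward
pass (numba-accelerated; a pure-numpy reference implementation is kept and
tested against brute-force enumeration). The M-step maximises the expected
complete-data objective over ρ and the tied λ with L-BFGS-B on log
parameters; a candidate is accepted only when the surrogate improves, so the
objective trace is non-decreasing by construction (generalized EM). The
default is 25 EM iterations.

Two deliberate departures from a fully joint Baum–Welch update:

* **θ is anchored, not iterated.** On the log-spaced grid the likelihood is
  almost exactly invariant under (θ, ρ, λ) → (cθ, cρ, λ/c) — a scale ridge
  along which joint EM drifts freely while the likelihood changes by a few
  units per genome. θ is therefore set once by moment matching: solve
  Σ_j π_j(1)·(1 − e^(−θ·t̄_j)) = observed K-fraction under the flat (λ = 1)
  prior. This pins the time/size scale; `update_theta=True` restores the
  joint update for comparison.
* **A smoothness prior on λ.** The M-step objective carries a quadratic
  penalty `smooth · Σ (Δ log λ)²` on adjacent free groups (default
  `smooth = 15`). Weakly identified intervals — especially recent ones,
  where windows carry little information — otherwise wander by factors of
  2 while improving the fit by fractions of a log-unit per megabase. The
  weight was calibrated on simulated constant-size and clean-split
  scenarios: large enough to damp the wander, small enough that a ten-fold
  bottleneck (|Δ log λ| ≈ 2.3) and the pseudo-diploid explosion (|Δ log λ|
  ≫ 1) pass through essentially unchanged. `smooth=0` gives plain maximum
  likelihood. With the penalty active the EM monotonicity guarantee applies
  to the penalised objective (`objective_trace`); in practice the raw
  log-likelihood trace has been monotone as well in every scenario tested.

### Scaling

With mutation rate μ per base per year and generation time g years
(defaults μ = 2×10⁻⁹, g = 5, the laticaudine values commonly transferred to
hydrophiine sea snakes — the pipeline treats both as free parameters):

    μ_gen = μ·g,   N0 = θ/(4·μ_gen·s),   time_j = 2·N0·t_j·g years,
    Ne_k = N0·λ_k.

## Pseudo-diploids and divergence read-off

A haploid is derived from a consensus by choosing one allele uniformly at
each heterozygous site (seeded, one draw per individual per run, with
sub-seeds derived from the master seed and the individual's name so any
draw is replayable). Two haploids from different individuals combine into a
pseudo-diploid whose heterozygosity is the per-site mismatch fraction over
co-called sites — an uncorrected Jukes–Cantor distance. Because no
cross-population coalescence postdates the populations' divergence, the
pseudo-diploid's inferred Ne explodes for all times more recent than the
split.

The divergence time is read off as the oldest step boundary such that, at it
and at every more recent step, the pseudo-diploid Ne exceeds C times the
larger of the two single-individual Nes at the same time. C = 10 by default
("nearly infinity"); C is reported with every estimate. Increasing C makes
the criterion stricter and can only shorten the qualifying run of recent
steps, so the estimate is weakly *decreasing* in C. The estimate's
resolution is bounded below by the time grid (about 8% per atomic interval
at the default settings); on 10 Mb simulations with a clean split at 500 kyr
the read-off lands within about 10% of the truth.

## Distances and trees

The uncorrected pseudo-diploid distance p is corrected for multiple hits by
Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)·p) (default), or the pure Poisson
transform d = −ln(1 − p) (config switch). At p ≈ 0.005 the choice moves d by
< 0.1% and never changes the NJ topology (asserted in tests). Neighbor
joining is the canonical Saitou–Nei algorithm; Q-minimisation ties are
broken by the lowest (i, j) index pair, negative branch lengths are retained
(not clamped) and flagged, and the unrooted tree is serialised with a
trifurcating root. The implementation is cross-checked against an
independent NJ implementation (scikit-bio) and against exact path-length
matrices of random trees.

## D-statistics

For a quartet (H1, H2, H3, outgroup), one allele is sampled per individual
per site; sites with any missing call, a heterozygous outgroup, or more than
two alleles are excluded. With A the outgroup allele and B the alternative,
D = (nABBA − nBABA)/(nABBA + nBABA). Significance uses a delete-one block
jackknife over contiguous blocks (default 5 Mb of physical coordinate;
unweighted, since blocks are near-equal by construction): SE² =
((m−1)/m)·Σ(D₍₋ⱼ₎ − D̄)², Z = D/SE, with empty blocks skipped. If all
leave-one-out estimates coincide the SE is zero and Z is flagged infinite
rather than fabricated. A convenience runs all three H1/H2/H3 rotations.

## The synthetic-data generator

The generator realises exactly the generative model the HMM inverts, plus
the two extensions the analyses need:

* **Single genome** — TMRCA tracks from the SMC: initial T from the
  piecewise-constant-Ne coalescent, breakpoints at rate 2·T·r per bp,
  uniform-height erasure and re-coalescence (SMC, not SMC'). Mutations drop
  per site with probability 1 − exp(−2·T·μ); heterozygous sites get a random
  two-base IUPAC code.
* **Clean split pair** — within-individual tracks drawn unconstrained, the
  cross-population track floored at the split time. The four haploids are
  assembled from private branches (below the within-individual TMRCA,
  clamped at the cross TMRCA) plus population trunk branches (up to the
  cross TMRCA), so a pseudo-diploid built downstream from one haploid of
  each individual reproduces the cross-track mismatch probability
  1 − exp(−2·μ·T_cross) in expectation rather than inflating it.
* **Quartet sites** — independent per-site genealogies under
  ((H1,H2),H3),O with constant Ne and an optional pulse H3→H2 of proportion
  f (migrant lineages join the H3 population at the pulse time); one
  mutation is placed uniformly on each genealogy, so every site is
  biallelic. Sites carry contiguous coordinates grouped into jackknife
  blocks; linkage is emulated only through block assignment.

Known simplifications: SMC rather than SMC' resampling; the quartet
outgroup lineage coalesces only after the ingroup root (no ingroup–outgroup
lineage sorting — the H1/H2 exchange symmetry of the null is exact either
way); quartet sites are unlinked given their block; one shared cross-track
approximates the four cross-pair histories of the split construction.
Passing tests therefore demonstrate correct inversion of this model family
and the qualitative robustness patterns, not performance on real sequencing
artifacts (mapping error, base-calling error, CpG hypermutability are all
absent).

All randomness flows through PCG64 streams derived from a master seed plus a
stage label (SHA-256, truncated to 31 bits), so every stage is bit-reproducible
and independently replayable.

## Problem sizes and defaults used in the test suite

Recovery scenarios run on 10 Mb single-contig genomes (8 Mb for the
repeat-mask comparison) with N = 10⁴, μ = r = 10⁻⁸ per generation, the
default pattern and 25 EM iterations; the split scenario uses τ = 10⁵
generations (500 kyr at g = 5). D-statistic calibration uses 10 replicates
of 10⁵ sites in 100 blocks per condition (f = 0 and f = 0.2 with a short
internal branch). With these sizes the full suite fits comfortably on one
CPU.

The planted-artifact workflow emulates repeat-driven alignment error by
overwriting 10% of the genome (25 regions of 32 kb) with dense apparent
heterozygosity (2% per site). Unmasked, these windows are almost all `K`:
the moment-matched θ inflates several-fold and the trajectory distorts
grossly; masked, the same windows become `N` and the truth is recovered —
the repeat-mask sensitivity contrast.

## Known limitations

* Absolute Ne and times inherit the θ anchor's small-sample error (a few
  percent on 10 Mb) and scale linearly with the assumed μ and g.
* Very recent (< 0.1·2N0 generations) and very ancient (near t_max)
  intervals are weakly identified; the smoothness prior shrinks them toward
  their neighbours rather than reporting them independently.
* The divergence read-off assumes the two populations' sizes are comparable
  to the pseudo-diploid's plateau; with extreme size contrasts the C
  threshold may need adjustment (it is config-exposed).
* No bootstrap resampling of segments; uncertainty on trajectories is not
  quantified.
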