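# Methods

`driftscape` studies *drift robustness*: the observation that small
asexual populations, which cannot hold fitness peaks surrounded by
small-effect deleterious mutations, settle on lower peaks whose
deleterious neighbors are large-effect or lethal — and therefore purged
by selection even when drift is strong.  The package has three layers:
an exact origin-fixation Markov model of the phenomenon, a synthetic
genotype–fitness landscape plus forward Wright–Fisher simulator that
reproduce it in a polymorphic population, and the analysis pipeline
that measures it.

## The origin-fixation chain

In the weak-mutation regime a population is monomorphic almost always,
and evolution is a Markov chain over genotypes with per-generation
transition probability `u_ij * pi_ij` (mutation supply times fixation
probability).  The landscape family has a wild type at fitness 1, a
*drift-fragile* peak at `1 + s` reached through `n` beneficial steps of
size `s/n`, and a *drift-robust* peak at `1 + s − ε` (0 < ε < s)
reached in a single step.  Beneficial supply rates follow an
exponential distribution of effects, `p_b(x) = u_b · μ · ρ(x)` with
`ρ(x) = exp(−x/s̄)/s̄`; every back/deleterious edge carries the overall
rate `μ`.  Two quantities summarise the chain:

* the flux ratio `M = κ^{n−1}` with `κ = u_b/s̄ < 1` (μ cancels
  exactly), measuring how much more mutational supply feeds the fragile
  slope than the robust step;
* the stationary occupancy ratio `R(N) = x*_fragile / x*_robust =
  M · e^{2ε(N−1)}`, whose crossing of 1 defines the critical population
  size

  `N_crit = 1 + (n−1) · ln(1/κ) / (2ε)`.

Below `N_crit` the chain concentrates on the lower, drift-robust peak.

### Fixation kernels and parameterisation

Edges carry *additive (Malthusian) selection coefficients*: `s/n` per
fragile step, `s − ε` for the robust step, with the backward
coefficient equal to minus the forward one.  Under this convention the
Kimura kernel `π = (1 − e^{−2s})/(1 − e^{−2Ns})` and the exact
Sella–Hirsh kernel with fitness ratio `e^{s}` obey the detailed-balance
identity `π_ij/π_ji = e^{2s(N−1)} = (w_j/w_i)^{2(N−1)}` *exactly*, so
the closed-form `N_crit` is an identity of the chain for both kernels
and for every `n` (the intermediate fragile steps cancel
telescopically).  Had we parameterised the kernels with Wrightian
ratios `1 + s`, the cancellation would hold only to first order in the
step sizes; we prefer the convention that makes the model's central
identity exact.  Both kernels are kept as separate code paths; under
this parameterisation they coincide numerically, which is itself the
statement that Kimura's diffusion form is exact on the log-fitness
scale.

### Numerics

* The stationary distribution is computed by the
  Grassmann–Taksar–Heyman elimination scheme — a deterministic,
  subtraction-free direct solve with entrywise *relative* accuracy.
  Origin-fixation chains routinely have stationary components tens of
  orders of magnitude apart; generic least-squares eigen-solves lose
  all relative accuracy on the small components.
* For root-finding in `N`, `R(N)` is evaluated as a log-space
  detailed-balance cycle product (the chain is a tree, hence
  reversible, so the product equals the eigenvector ratio exactly; a
  property test verifies the equivalence to 1e−8 relative wherever both
  are representable in double precision).  This keeps `N_crit`
  computable even where individual fixation probabilities underflow
  (`2Ns` of thousands).
* The neutral limit `π = 1/N` is used analytically for `|s| < 1e−12`;
  `N = 1` returns 1.  Non-integer `N` is allowed everywhere in the
  analytic layer; the simulators take integers.
* `n_crit_numeric` brackets the root by doubling an upper bound from
  `N = 8` and then applies Brent's method with absolute tolerance 1e−6.
* The robust up-step rate defaults to `p_b(s)` (the small-ε
  approximation that makes `R(N_crit) = 1` exact); `p_b(s − ε)` is
  available behind the `use_epsilon_in_u14` flag.

### Monte-Carlo oracle

`simulate_origin_fixation` samples the chain directly (categorical
sampling of transition-matrix rows) as an independent stochastic check.
Because the chain holds its state for many generations, occupancy
counts are heavily autocorrelated; the goodness-of-fit statistic
therefore uses the number of *regeneration cycles* (returns to the
analytically most-occupied state, independent by the strong Markov
property) as the effective sample size.  The chains used in the
acceptance checks are chosen with mutation rates large enough to mix
well within 10^6 generations (thousands of regenerations); slowly
mixing parameter sets would need impractically long trajectories, which
is a statement about the simulation budget, not about the analytic
solution.

## The synthetic landscape

The generator emulates the statistical structure of a digital-organism
genome: length `L = 50` over a 26-letter alphabet, multiplicative
fitness, wild type at fitness 1, about a third of point mutations
lethal, and coexisting small-effect (< 5 %) and large-effect (≥ 5 %)
deleterious classes plus exactly-neutral and beneficial mutations.
Five site classes:

* **core_lethal** (fraction 0.34): any substitution is lethal.
* **additive_small** (0.40): *plain* sites carry only small
  deleterious states (effects uniform in 0.001–0.03).  *Pathway* sites
  carry one weakly beneficial state (0.2–0.4 %), three exactly-neutral
  states, and large-effect deleterious states elsewhere (5–40 %).
* **module_member** (0.08): two 2-site modules; all members at their
  target states multiply fitness by `1 + S` with `S` in 0.05–0.08, so
  losing a member is a large-effect deleterious mutation.
* **modifier** (0.04): one ON state per modifier grants a 4 % benefit
  and converts every substitution at its target sites (pathway sites)
  into a lethal; the ON state itself is lethal on backgrounds where a
  target is already occupied (sign epistasis — the epistatic route to
  drift robustness observed in digital evolution).
* **neutral** (0.14): exactly neutral.

### Why these numbers produce the phenomenon

The population sizes of the scaled-down study are `N = 100` (small) and
`N = 2000` (large) with genomic mutation rate `U = 0.1` per division
and at most one mutation per offspring.  The pathway benefits `b` are
chosen so that `2·N·b` is ≈ 0.4–0.8 at `N = 100` (effectively neutral:
gains are not maintained, and with four neutral reversion channels per
site against one gain channel, equilibrium occupancy stays low) but
≈ 8–16 at `N = 2000` (firmly held).  Every *occupied* pathway site
contributes its reversion states to the small-effect deleterious
neighborhood, while an unoccupied pathway site contributes none — so
the small-effect-deleterious fraction of an evolved genotype rises with
the number of fragile gains it holds.  Large populations therefore end
with both higher fitness and a more drift-fragile neighborhood; small
populations end lower but depleted of small-effect deleterious
mutations; and in the drift test (10 populations of 50 for 10^3
generations per genotype) the large-population genotypes have more to
lose and lose it.  Reverting deleterious mutations at birth (the third
treatment) removes the maintenance cost of fragile gains, so small
populations climb the fragile routes, reversing the DFE contrast and
raising final fitness.  The modifier loci add the observed epistatic
signature — beneficial steps that trade deleterious likelihood for
lethal likelihood — without driving the main contrast.

Two preset configurations anchor the analysis layer: a *drift-fragile*
preset (additive routes only, peak neighborhood entirely < 5 %) and a
*drift-robust* preset (modules and modifiers only, with a 6 % modifier
benefit so that every viable deleterious neighbor of the peak,
including modifier reversions, is ≥ 5 %).

### What the generator does not emulate

Real (and digital) genomes have correlated, context-dependent mutation
effects, insertions/deletions, variable genome length, and fitness
measured through a replication machinery; the generator's effects are
independent per site apart from the explicit module/modifier epistasis,
and its class fractions are fixed at draw time.  Passing tests
therefore show that the drift-robustness mechanism operates when the
landscape offers the two kinds of peaks — not that any particular
organism's landscape does.

## Forward evolution

Discrete Wright–Fisher generations at constant `N`: parents sampled
proportional to fitness (non-viable genotypes occupy slots but never
reproduce; the run aborts only if the whole population is non-viable),
each offspring mutated with probability `U` at one uniform site to a
uniform non-identical state.  The `revert_deleterious` treatment
re-evaluates each mutant against its parent and replaces any
lower-fitness offspring with an unmutated copy.  Every distinct mutant
becomes a genealogy record; records not ancestral to the living
population are pruned every 100 generations (ids are renumbered, so
external references should be taken only from the returned run).  The
line of descent of any surviving genotype is replayed exactly from the
ancestor; consecutive LOD entries differ by at most one site.  All
randomness flows from one explicit NumPy generator per run, and
replicate seeds are derived as SHA-256 hashes of (master seed,
treatment, replicate), so any replicate is reproducible in isolation.

The scaled-down study uses 30 replicates per treatment, `N = 100`
vs `N = 2000`, 2·10^4 generations, and the drift assay at `N = 50` for
10^3 generations; these sizes keep the full study within minutes on a
single core while leaving the selection-scale separation that the
design above requires.

## Analysis definitions

* Fitness effect `s = w_m/w_0 − 1`; classes: lethal (`w_m = 0`),
  beneficial (`s > 0`), neutral (`|s| < 1e−12`; the landscape makes
  neutrals exact, so no biological tolerance is needed), small-effect
  deleterious (`−0.05 < s < 0`), large-effect deleterious
  (`s ≤ −0.05`; the 5 % boundary itself counts as large).
* A beneficial LOD step is *maintained* if it attains a new running
  fitness maximum and fitness never subsequently drops below the
  pre-step value for five or more consecutive LOD entries; shorter dips
  must recover.  "Pre-step value" is read as the immediate predecessor
  `w_{i−1}`; the alternative running-maximum reading is available via
  `baseline="running_max"` but not used.
* Equal-fitness cohorts take the *last* genotype per lineage at each
  fitness value and keep values with more than 20 lineages on both
  sides; exact fitness matching is the default, with an optional
  relative-tolerance binning for continuous-valued landscapes.
* Epistatic signatures compare the viable-deleterious and lethal
  likelihoods before and after each maintained step and flag relative
  reductions ≥ 50 % and absolute reductions ≥ 0.1.  When a step toggles
  a modifier with `k` pristine targets, the lethal likelihood rises by
  exactly `k/L` while the deleterious likelihood falls by `(k−1)/L`
  (the toggled modifier's own reversion states become deleterious).
* Treatment comparisons use one-tailed Mann–Whitney U tests with the
  direction fixed a priori by the drift-robustness hypothesis (small <
  large for the small-effect fraction, small > large for drift-test
  relative fitness, reversed for the no-deleterious treatment),
  Spearman rank correlation for decline-versus-DFE relationships, and
  Bonferroni correction across cohort families.

## Known limitations

* The origin-fixation layer covers the two-peak family and arbitrary
  user-supplied tree-structured chains; chains with cycles would need a
  general (non-reversible) treatment of the occupancy ratio.
* The eigenvector pipeline is limited to parameter regimes where
  fixation probabilities are representable in double precision
  (roughly `2Ns ≲ 700`); beyond that the log-space product carries the
  analysis.
* The forward simulator is asexual, unstructured, and constant-`N`;
  there is no recombination, no spatial structure, and no evolvable
  mutation rate.
* Generation counting is strict Wright–Fisher; systems with overlapping
  reproduction schedules map onto it only approximately.
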