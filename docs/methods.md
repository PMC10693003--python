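# Methods

## Model

The simulator tracks two haploid, non-mutating types — an
antibiotic-sensitive wild type and a resistant mutant — competing for a
fixed number of spaces in each patch of a small metapopulation. The state
is the vector of per-patch `(wild, mutant)` counts; agents of a type are
exchangeable, so all phases are implemented as count-level draws
(binomial, multinomial, hypergeometric) that are distributionally
identical to per-agent iteration. One step is one generation.

**Death.** Each agent of type `t` dies with probability
`p_death = min(1, Z_t · A)` (kill coefficient × antibiotic
concentration), independently.

**Birth.** Each agent of type `t` proposes one offspring with probability
`p_birth = R_t · e0 / K`, where `e0` is the number of empty spaces in the
patch at the start of the generation and `K` the patch capacity. Death
and birth draws are both taken on the generation-start counts
(simultaneous evaluation); offspring occupy spaces free after the deaths,
and when proposals exceed the free spaces the retained offspring are
drawn without replacement from the pooled proposals (hypergeometric
across types, unbiased between them). Simultaneous evaluation is a
deliberate choice: it makes the deterministic balance
`N·Z·A = N·R·(1 − N/K)` exact, so a single type's quasi-stationary mean
occupancy equals the effective carrying capacity `(1 − Z·A/R)·K`.
Evaluating birth on post-death empties instead would inflate the
equilibrium (to ≈1422 rather than 1200 at `Z·A/R = 0.25`, `K = 1600`)
and break the closed-form link between dose and equilibrium occupancy
that the rest of the analysis (normalized resistance `R/Z`, expected
migrants) relies on.

**Migration.** Edge weights are absolute dispersal propensities: an agent
in patch `i` crosses the outgoing edge `(i, j)` of weight `w` with
probability `m · w` per generation (total capped at 1). Conditional on
migrating, the destination distribution is the normalized outgoing-weight
distribution. All moves in a generation are resolved one at a time in a
uniformly random global order; a move into a patch with no empty space at
processing time is aborted and the agent stays. Migration conserves the
total agent count exactly. Two consequences of the flux convention:

* the expected number of migrants per step along an edge leaving a patch
  at occupancy `N` is `m·w·N` — at the mutant's effective carrying
  capacity and unit weight this is `m·K·(1 − A/(R/Z))`, the regime
  diagnostic used throughout;
* asymmetric stars are dynamically meaningful. Under the alternative
  convention (fixed per-agent migration probability with weight-normalized
  destinations), a star leaf's single outgoing edge makes the
  leaf→hub/hub→leaf weight *ratio* cancel entirely, so inward- and
  outward-biased stars would collapse onto the balanced star. With flux
  weights, the inward-biased (IN>OUT, default ratio 2:1) star delivers
  mutants to the hub twice as fast and is measurably the fastest-spreading
  star variant, consistent with subpopulation-level theory that inward
  migration strengthens a star's amplifying tendency.

**Bottleneck (optional).** Every `bottleneck_every` generations each
patch is thinned binomially to `bottleneck_fraction`, emulating the
serial-transfer dilution of an evolution experiment; smaller fractions
mean stronger drift.

**Seeding.** Founders are scattered uniformly at random over all spaces
(multivariate hypergeometric across patches); the founder mutants are
placed in a designated non-hub patch (`P3` by convention, matching the
P1–P4/P2-hub labelling used for all four-patch scenarios). In the rare
event the uniform scatter leaves the introduction patch short of the
requested mutants, the deficit is moved in from the fullest other patch
before conversion, keeping the mutant count exact.

## Parameters and calibration

| parameter | default | meaning |
|---|---|---|
| `K` (capacity) | 1600 | spaces per patch |
| `A` (antibiotic) | 0.25 | dose, in units of the mutant's normalized resistance `R/Z = 1` |
| mutant `R, Z` | 1.0, 1.0 | growth propensity and kill coefficient; effective capacity 1200 |
| wild `R, Z` | 1.0, 1.5 | kill coefficient calibrated so the mutant's low-density per-generation growth advantage is 20% |
| founders | 1000 (1 mutant) | ≈1:1000 initial resistant:sensitive ratio |
| generations | 240 | five days at a 30-minute generation time (`steps = days·24·60/t`) |
| replicates | 100 | per scenario arm (acceptance checks use 50) |
| migration levels | 0.1 / 1 / 10 | expected mutant migrants per edge per step at the mutant's effective capacity; `m = level / (K·(1 − A/(R/Z)))` |
| asymmetry ratio | 2:1 | IN>OUT or OUT>IN weight ratio on star routes |
| bottleneck | 0.1 every 48 steps | daily thinning in the bottleneck presets |

The wild-type kill coefficient comes from a documented helper
(`calibrate_wild_kill_rate`): with both types sharing `R`, the low-density
growth-factor ratio `(1 − Z_m·A)(1+R) / ((1 − Z_w·A)(1+R))` is set to 1.2.
The migration levels are calibrated, not copied — no absolute migration
probabilities are pinned down by the study design — and are fixed
configuration, chosen so that the three levels bracket the
`expected migrants ≈ 1` regime from an order of magnitude below to an
order of magnitude above.

## Exact oracle

For instances whose state space
`Π_i (K_i+1)(K_i+2)/2` is below a configurable limit (default 2×10⁵), the
package builds the exact transition kernels of the phases: per-patch
demography (simultaneous death+birth, including the hypergeometric
overflow rule) as a tensor product over patches, and migration as the
exact mixture over binomial migrant counts, multinomial destination
assignments, and all processing orders with full-patch rejection
(enumerated recursively with memoization). The one-generation kernel is
demography followed by migration; standalone `death` and `birth` kernels
are also exposed for phase-level tests. Absorption is defined by first
hitting one of three classes — mutant fixation (no wild, ≥1 mutant), wild
fixation (no mutant, ≥1 wild), or extinction — and the standard
first-step linear system `(I − Q)x = r` is solved with a dense LU for
the three class probabilities and the expected absorption time. Row sums
are verified to 1e−12 and the class probabilities to 1e−10; a singular
system (no absorbing class reachable) raises a structural error.
The simulator is validated against the oracle on one-patch (K ≤ 3),
two-patch (K = 2) and small asymmetric-star instances: over 10⁴ runs all
absorption frequencies lie within three binomial standard errors of the
exact values.

## Observables and fitting

The headline observable is the metapopulation mutant fraction per
generation, averaged over replicates. Replicates whose total population
hits zero have an undefined fraction and are excluded from the mean from
the extinction step onward (and counted separately) rather than imputed
as zero, so extinction is not conflated with wild-type fixation.
Time-to-majority is the first generation at or above a 50% threshold
(configurable); the per-patch spread order sorts patches by first
threshold crossing with ties broken by label and never-crossing patches
flagged last. The star-minus-mixed gap curve carries a pooled standard
error from the two ensembles.

Spread curves are summarised by a three-parameter logistic
`f(t) = plateau / (1 + ((plateau − N0)/N0)·e^{−rt})` with `N0` fixed at
the known inoculation proportion (0.001), fitted by bounded
trust-region nonlinear least squares on the proportion scale
(`scipy.optimize.least_squares`, tolerances 1e−15). Initialisation is
deterministic — `r` from the log-slope of the sub-plateau points,
plateau from the maximum observed proportion clipped to `(N0, 1]` — so
the fit is reproducible and its SSE never exceeds the initialisation's.
When the fitted plateau is pinned at `N0` (flat data) the rate is
reported as 0, since it is unidentified there. Noiseless synthetic
curves are recovered to ≤1e−6 relative error; under Gaussian noise of
SD 0.02 the rate estimate's mean bias is well inside ±5% over 200
datasets.

## What the synthetic scenarios do and do not emulate

The scenario presets reproduce the *structure* of a four-patch
serial-transfer evolution experiment: topology (balanced, inward- and
outward-biased stars; well-mixed control), uniform selection, a single
rare resistant founder outside the hub, five experiment-days of
generations, and optional daily bottlenecks. They do not emulate
de-novo mutation, within-patch spatial structure, resource dynamics,
plating/measurement noise, or the volumetric details of dispersal-pool
pipetting; passing tests therefore speak to the model's internal
consistency and to topology/migration effects *within this model class*,
not to any particular wet-lab system.

## Topology contrasts: what the model does and does not show

Two robust qualitative results, measured at 50 replicates per arm and
reported by `scripts/acceptance.py`:

* **Fast migration favours the well-mixed network.** At 10 expected
  migrants per edge per step the well-mixed ensemble runs ahead of the
  star through the sweep (mid-run gap ≈ −0.05 to −0.12) and remains at
  or above it at the final generation; the star's extra hop through the
  hub only delays spread when migrants are plentiful.
* **Hub-first spread.** At the low migration level the mutant's second
  patch (after the introduction leaf) is the hub in essentially every
  star replicate that spreads at all, while in the well-mixed network
  the second patch is statistically uniform over the three candidates.

One expected phenomenon did **not** materialise: a transient ensemble-mean
advantage of the *balanced* star over the well-mixed control at slow
migration. Extensive characterisation (200–1000 replicates per arm;
expected migrants 0.03–10; per-agent, per-edge-flux and
immigration-normalized migration conventions; with and without 1:100
daily bottlenecks) found the well-mixed mean fraction at or above the
balanced star's at every generation; apparent star leads at ~50
replicates are establishment-probability noise (SD ≈ 0.05 per arm).
The mechanism is structural: with equal source rates, the complete graph
colonises its three satellite patches in parallel at the same per-patch
rate at which the star colonises its single hub, so hub concentration
cannot outrun parallel seeding unless per-arrival establishment is far
harder than these demographic rules make it. The corresponding
directional test is left failing by design rather than weakened, as a
documented negative result; the inward-biased star remains the fastest
star variant, and the spread-order and suppression results above are the
model's positive topology findings.

## Numerical and design notes

* One `numpy` `Generator` per replicate, seeded `base_seed + replicate`;
  runs are bit-reproducible given (graph, parameters, seed).
* Migration moves are materialised as an explicit event list and shuffled
  with the replicate's generator; at the preset migration levels the list
  holds tens of events per generation, so the Python-level resolution is
  not a bottleneck (a 50-replicate, 240-generation arm runs in ~3 s).
* Degenerate inputs are rejected early with typed errors (invalid
  parameters, invalid/duplicate/dangling graph records, oversized state
  spaces, empty-metapopulation fractions).
* Acceptance-scale problem sizes: 50 replicates per scenario arm,
  10⁴ oracle-comparison runs per tiny instance, 2000 neutral runs, 200
  noisy fit datasets. The quasi-stationary occupancy check uses 50
  replicates averaged over generations 150–250 of a 250-generation run;
  its ±3 SE band (~±1.5 agents around 1200) comfortably contains the
  real O(Var/K) curvature shift (≈ −0.4) without being sensitive to it.
* JSON graph documents, tidy trajectory/summary CSVs and run-metadata
  JSON (with a SHA-256 configuration hash) are the only file formats.
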