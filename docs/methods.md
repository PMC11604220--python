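# Methods

## The transcription-cycle model

`polkin` models the life cycle of RNA polymerase II (RNAPII) on a single
yeast gene as a continuous-time Markov chain on a lattice of 120 bp
compartments.  Every step is a Poisson process, and hard-core exclusion
(at most one polymerase per compartment, the TASEP convention) couples the
steps: a move whose target compartment is occupied has zero propensity.

Two gene classes differ only in how RNAPII arrives:

* **STM genes** (bound by sequence-specific factors *and* coactivators such
  as SAGA, Mediator, SWI/SNF) recruit RNAPII exclusively at the upstream
  activating sequence (UAS): association `k1`, dissociation `k-1`, transfer
  to the promoter `k2` and reversal `k-2`.
* **TFO genes** (transcription-factor-only) recruit RNAPII directly at the
  promoter at rate `k3` and have no UAS compartment.

At the promoter the polymerase waits in a pre-TFIIH sub-state where it may
still dissociate (`k-3`) or reverse to the UAS (`k-2`); arrival of TFIIH
(`k4`) is the committed step, after which only initiation (`k5`) remains.
Initiation relocates the polymerase into the first of ten 120 bp transcript
bins (a 1.2 kb model gene, the median yeast transcript length); elongation
hops between adjacent bins occur at `(k6 / 60) / 120` per second with `k6`
in bp/min, and each hop requires the successor bin to be empty.  The
terminator is a bona fide 120 bp compartment entered from the last bin at
the hop rate and vacated at the release rate `k7` (the termination pause).

Default rates (per second unless noted):

| rate | default | provenance |
|------|---------|------------|
| k1   | 0.002   | UAS association, single-molecule imaging |
| k-1  | 0.003   | UAS dissociation |
| k2   | free, 0.03-0.1  | aggregate transfer incl. early GTF assembly |
| k-2  | free, 0-0.07    | promoter-to-UAS reversal |
| k3   | 0.002   | direct promoter recruitment (set equal to k1) |
| k-3  | free, 0-0.03    | promoter dissociation (pre-TFIIH only) |
| k4   | free, 0.0075-0.0275 | TFIIH recruitment |
| k5   | 0.1     | initiation, from TFIIH residency |
| k6   | 1000 bp/min | elongation |
| k7   | 0.0325  | terminator release (~30 s pause, lower bound of published dwells) |

Modelling decisions where the design was genuinely open:

* **Blocking semantics.** Occupied-target moves are removed from the
  propensity set rather than fired-and-rejected; this keeps the chain Markov
  with the stated rates.
* **Commitment.** After TFIIH arrival both `k-3` and `k-2` are disabled;
  dissociation is possible only "until TFIIH is recruited", and reversal is
  treated as equally committed.
* **Initiation requires bin 1 empty**, since it physically relocates the
  polymerase.
* **Exclusion applies to the UAS and terminator** exactly as to transcript
  bins.
* **Units.** `k6` is stored internally in bp/s; user-facing configuration
  accepts bp/min.

## Simulation and the exact oracle

The state space is tiny (3 promoter sub-states x 2^(bins + terminator +
UAS) flags; 6,144 states for a TFO gene, 12,288 for STM), so the chain is
enumerated once into a CSR transition table.  That table is the single
source of truth: the Gillespie simulator and the exact stationary solver
both consume it, which makes "engine and oracle share the transition
structure" a construction property rather than a test hope.

**Gillespie engine.**  Direct method (two uniforms per event), compiled with
numba.  Each simulated gene runs 1000 s from an all-empty initial state and
records the *time-weighted* occupancy of every compartment over the final
60 s; population profiles average 100,000 independent genes by default
(10,000 in the test and acceptance runs, which keeps every Monte-Carlo
standard error far below the effects being tested).  Per-gene RNG streams
are drawn from the master seed by gene index, so results are independent of
execution order.  The time-weighted window average is unbiased for a
piecewise-constant process; at the default rates every relaxation time is
well below the 940 s burn-in (the slowest mode, promoter filling, has
tau ~ 29 s).  Where a parameterisation relaxes more slowly — e.g. the
balanced two-state limit `k4 = 0`, `k3 = k-3 = 0.002`, tau = 250 s — the
tests lengthen the run so the start-empty transient decays below the
sampling error rather than loosening the tolerance.

**Exact oracle.**  `ctmc_stationary_occupancy` restricts the table to the
states reachable from the initial condition (so rate-zeroed chains stay
irreducible on their support), finds the closed communicating class via
strongly connected components, and solves `pi Q = 0` with a sparse LU
factorisation, replacing one balance equation by the normalisation
constraint.  The solve refuses architectures above a configurable state cap
(10^5) and chains with multiple closed classes.  Flux balance — initiation
flux `k5 * P(post-TFIIH, bin 1 empty)` equal to termination flux
`k7 * P(terminator occupied)` — holds to ~1e-14 and is asserted to 1e-8.

## The minimal model

The minimal model asks whether published dwell times alone predict the
promoter/terminator enrichment: a promoter with instantaneous refill, ten
120 bp bins, and a terminator pause.  With literal instantaneous refill the
promoter compartment is occupied 100% of the time, which would make the
reported promoter occupancy independent of the dwell time.  The package
therefore reports the occupancy attributable to the *currently engaged*
polymerase: escape flux x dwell time, which at stationarity equals
P(bin 1 empty) exactly (the escape propensity is `(1/dwell) 1{bin 1 empty}`).
This reading reproduces the expected low-density behaviour (occupancy
proportional to residence time per compartment), falls below the
transcript-bin occupancy for sub-second dwell times, and saturates at 1
when the gene body is uncongested.

The published ranges (dwell 5-20 s, elongation 1000-3000 bp/min,
termination 5-70 s) are crossed into a default 4 x 3 x 2 = 24-combination
sweep.  The qualitative orderings are phase-dependent in the standard
open-TASEP sense: with entry rate `alpha = 1/dwell`, hop rate `p`, and exit
rate `beta = 1/termination`, the low-density phase (`alpha < p/2 < beta`)
gives promoter > mean transcript-bin occupancy whenever the dwell exceeds
the per-bin elongation time, while `beta < p/2` (the 70 s termination rows)
jams the gene from the terminator backwards.  The sweep reports occupancies
and two flags (promoter above / terminator above the mean transcript bin);
under Monte-Carlo simulation a flag is set only when the difference exceeds
twice its standard error.

## Ensemble fitting

Fitting compares a model-predicted *region vector* — UAS (STM only),
promoter, transcript (mean of the ten bins), 3'UTR (terminator) — against
an empirical one (CPM-normalised cleavage signal per region per bp) by
cosine similarity, which is scale invariant and therefore insensitive to
the unknown units conversion.  A grid search over the free rates (STM:
`k2, k-2, k-3, k4`; TFO: `k-3, k4`; default 10 points per rate over the
functional ranges) simulates every Cartesian point and keeps all models
scoring at least 0.995.  When no model reaches the threshold — as happens
for transcript-dominated, promoter-depleted target shapes — the best
`fallback_top_n` models are returned with an explicit fallback flag.
Ensemble *counts* depend on the grid resolution and are deliberately not
asserted anywhere; containment of a known generating parameter point and
the ensemble-average prediction quality are the tested properties.

For display and for perturbation analysis, predictions are L2-scaled to the
empirical magnitude.  Perturbation deltas calibrate the unit factor on each
member's *baseline* prediction and apply that same factor to the perturbed
prediction; rescaling the perturbed run independently would cancel any
proportional occupancy loss (cosine/L2 scaling is blind to overall
magnitude), hiding exactly the effect being modelled.  Range-valued
perturbations (e.g. `k2` 0.004-0.04 under TFIIB depletion) are sub-gridded
within each ensemble member and the envelope of deltas reported.  Baseline
and perturbed runs share each member's fit seed, so the identity scenario
yields exactly zero.  The agreement metric for delta vectors is again
cosine similarity (sign disagreements score negative); the choice of metric
for perturbation fits was open and is documented as this package's.

TFO fits use three regions (no UAS compartment exists in the TFO model); a
configuration flag to include an empirical UAS bin is provided but off by
default.

## Genomic signal

Coordinates are 0-based half-open internally; the conventional inclusive
offsets (UAS -500..-151, promoter -150..+25 relative to the TSS, transcript
+26 to TES-76, terminator TES-75..+150) are converted at the boundary, so
the promoter spans 176 bases — the off-by-one convention is fixed here and
unit-tested because the printed offsets are ambiguous by +-1.  Genes whose
transcript cannot accommodate the +26/-76 encroachment are excluded with a
logged reason.  Where no measured TSS/TES exists, median UTR lengths (47 bp
5', 118 bp 3') place them relative to the coding bounds.

Metagene profiles average replicates per base first, then bin three
segments (1 kb upstream, length-normalised transcript, 1 kb downstream)
into 100 bins each; segment binning uses floor-spaced edges so constant
segments are reproduced exactly and no signal leaks across segment
boundaries.  Metasite profiles average +-250 bp windows around oriented
points (minus-strand windows mirrored) at base resolution and then apply
the sliding-window smoother (window 10, step 5).  Smoothing windows start
every `step` positions, are truncated at the signal boundary, and report
window centers — the edge policy is unstated in the conventions this
follows and fixed here.  Background subtraction is element-wise and
deliberately does not clip negatives (depletion is signal).  Expression
filtering keeps genes with replicate-mean nascent counts >= 50 (inclusive).
Relative region enrichment divides per-gene region values of a factor by a
reference factor per replicate, averages over genes, and uses the
between-replicate dispersion for a z-score: difference of ratios divided by
the root of summed squared standard errors, with two-sided normal p-values
— the dispersion construction is underdetermined in the source conventions
and documented as this package's choice.

## Synthetic data

`synth_region_vectors` generates fitting targets with known truth: simulate
occupancy at given rates, aggregate to regions, L2-scale to a pseudo-CPMn
magnitude (default norm 100), and apply replicate noise.  The default noise
model is multiplicative Gaussian on region values (three replicates,
relative SD 0.05) because real fits consume region-level replicate means; a
Poisson counts-then-CPM mode exists for end-to-end genomics tests.  What
the generator does *not* emulate: nuclease sequence preference, nucleosome
occupancy, fragment-level sampling, or between-gene heterogeneity within a
class — passing tests demonstrate the correctness of the computations, not
robustness to those real-data features.

`synth_genome_fixture` writes a miniature genome (bedGraph coverage, BED6
genes and sites, nascent-count TSV, manifest) in which each gene's four
regions have exactly specified per-bp means, or alternatively each metagene
segment is painted constant, so region fractions and profile bins can be
asserted without tolerance.

## Problem sizes and numerical choices

Tests and the acceptance script run 10,000 genes per condition and a 5^4
recovery grid — sizes at which every assertion's Monte-Carlo error is far
below its tolerance while a full run completes in minutes on one CPU; the
library default remains 100,000 genes.  Agreement tests use 3-standard-error
tolerances; the stationary solve is checked to 1e-10 normalisation and the
oracle flux balance to 1e-8.  Ties in the grid ensemble are ordered by
descending score with stable sorting, making all outputs byte-reproducible
from a manifest (no timestamps are written).

## Known limitations

* One polymerase per 120 bp compartment is coarser than the ~35 bp
  footprint; no backtracking, promoter-proximal pausing, or nucleosome
  competition.
* The ensemble is a grid, not a posterior: scores are not likelihoods and
  the 0.995 threshold has no probabilistic calibration.
* The exact oracle is limited to architectures within the state cap
  (default 10^5 states, ~15 transcript bins).
* Empirical region vectors are class averages; per-gene fitting is out of
  scope.
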