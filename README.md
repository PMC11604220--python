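# polkin

Stochastic kinetics of the yeast RNA polymerase II (RNAPII) transcription
cycle, with ensemble fitting to region-binned occupancy data.

Genome-wide assays of RNAPII disagree about where the polymerase spends its
time: crosslinking-based occupancy (ChIP-seq) is dominated by the
transcribed region, while nuclease-fusion cleavage mapping (ChEC-seq2)
highlights the enhancer/UAS, promoter and terminator.  `polkin` is built
for researchers who want to ask, quantitatively, which kinetic regimes of
the transcription cycle are compatible with a measured occupancy profile —
and what a chemical-genetic perturbation must have done to the underlying
rates.

## The model

A gene is a lattice of 120 bp compartments: an optional UAS, a promoter, N
transcript bins (default 10, a 1.2 kb gene) and a terminator.  RNAPII moves
through a continuous-time Markov chain with hard-core exclusion (at most
one polymerase per compartment; blocked moves have zero propensity):

    UAS association/dissociation        k1, k-1        (STM genes)
    UAS -> promoter transfer/reversal   k2, k-2        (STM genes)
    direct promoter recruitment         k3             (TFO genes)
    promoter dissociation               k-3            (until TFIIH arrives)
    TFIIH recruitment (committed step)  k4
    initiation / promoter escape        k5
    elongation                          k6  (bp/min; hop rate (k6/60)/120 per bin)
    terminator release                  k7

Occupancy is the time-weighted fraction of a measurement window each
compartment is occupied, averaged over many independent gene copies
(Gillespie direct method, numba-compiled), with an exact
stationary-distribution oracle for verification.  Fitting is a grid search
over the free rates (`k2, k-2, k-3, k4`); every rate set whose predicted
region vector (UAS, promoter, transcript mean, 3'UTR) has cosine similarity
>= 0.995 with the data joins the *ensemble*,

    cos(M, E) = sum_i M_i E_i / (||M||_2 ||E||_2),

so conclusions rest on the full set of data-consistent models rather than a
single best fit.  The package also includes the genomic-signal layer that
produces such region vectors from coverage tracks (CPM normalisation,
strand-aware region definitions, metagene/metasite profiles, smoothing,
background subtraction), a minimal dwell-time model for
back-of-the-envelope occupancy predictions, and synthetic-data generators
with known ground truth.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

Simulate a transcription-factor-only (TFO) gene at published rates, fit the
free rates back from the resulting region vector, and model a TFIIB
depletion:

```python
from polkin import (GeneArchitecture, SimulationConfig, FitConfig,
                    TranscriptionCycleModel, PerturbationScenario,
                    aggregate_regions, simulate_population)
from polkin.presets import published_rates

rates = published_rates("TFO").replace(k_rev3=0.015, k4=0.0175)
arch = GeneArchitecture()                       # promoter + 10 bins + terminator
prof = simulate_population(rates, arch, SimulationConfig(n_genes=10_000, seed=0))
print(prof.to_frame().head(3))
#   compartment  occupancy      se
#      promoter     0.0662  0.0019
#         bin_1     0.0069  0.0004
#         bin_2     0.0076  0.0004
print(prof.terminations)                        # 8640 mRNAs across 10,000 genes

target = aggregate_regions(prof, "TFO")
cfg = FitConfig(fixed_rates=published_rates("TFO"),
                free_ranges={"k_rev3": (0.0, 0.03), "k4": (0.0075, 0.0275)},
                resolution=5, threshold=0.995,
                sim=SimulationConfig(n_genes=10_000, seed=1))
res = TranscriptionCycleModel(target, cfg).fit()
print(res.summary())
# ensemble size:     9
# best similarity:   0.999995
# free rate ranges in ensemble (/s):
#   k_rev3   min 0      median 0.015   max 0.03
#   k4       min 0.0175 median 0.0175  max 0.0225

delta = res.perturb(PerturbationScenario("tfiib", {"k3": 0.0008}))
print(delta.to_frame())
#       region  delta_mean  delta_min  delta_max
#     promoter     -0.0372    -0.0400    -0.0348
#   transcript     -0.0045    -0.0052    -0.0039
#         3UTR     -0.0191    -0.0212    -0.0170
```

The occupancy profile shows the promoter-and-terminator-dominated shape
characteristic of cleavage-based occupancy: the polymerase waits ~10x
longer at the promoter and ~4x longer at the terminator than in any single
transcript bin.  The fit recovers the generating rates (the k4 axis is
well constrained, the k-3 axis is a ridge — the data admit a family of
models, which is exactly what the ensemble reports), and dropping the
recruitment rate k3 from 0.002 to 0.0008 /s drains occupancy from every
region, with the largest loss at the promoter.

The same stages are available from the shell:

```sh
polkin synth --kind regions --seed 3 --out synth/
polkin fit --regions-tsv synth/regions.tsv --gene-class TFO --seed 5 --out fit/
polkin perturb --regions-tsv synth/regions.tsv --gene-class TFO \
       --scenario tfiib-20min --model 1 --seed 5 --out pert/
polkin minimal-sweep --out sweep/
```

Every run writes a `manifest.yaml`; rerunning from a manifest reproduces
the outputs byte for byte.

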