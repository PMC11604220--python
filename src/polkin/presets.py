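"""Published rate constants and named perturbation scenarios.

The transcription-cycle rates split into two groups.  *Fixed* rates come from
single-molecule and imaging literature: UAS association/dissociation
(k1 = 0.002 /s, k-1 = 0.003 /s), direct promoter recruitment (k3 = 0.002 /s,
taken equal to k1), initiation from TFIIH residency (k5 = 0.1 /s), elongation
(k6 = 1 kb/min) and terminator release at the short end of the published
pause times (k7 = 0.0325 /s, ~30 s dwell).  *Free* rates — transfer k2,
reversal k-2, promoter dissociation k-3 and TFIIH recruitment k4 — have no
published values and are explored over functional ranges during fitting.

``chip_forced_rates`` is the parameterisation required to reproduce
ChIP-seq-shaped occupancy: no promoter dissociation, effectively
instantaneous TFIIH recruitment (realised as a large finite rate, 50 /s),
doubled initiation and a termination rate of 0.14 /s (~4.3-fold above the
maximum published value).

``perturbation_scenarios`` enumerates the chemical-genetic perturbation
models (TFIIB depletion, TFIIH-kinase inhibition, Gcn4 mutants), keyed by
``(scenario_name, gene_class, model_number)``.
"""

from __future__ import annotations

from .fitting import PerturbationScenario
from .kinetics import RateSet

__all__ = [
    "published_rates",
    "functional_ranges",
    "chip_forced_rates",
    "perturbation_scenarios",
    "scenario",
    "SCENARIO_NAMES",
    "FREE_RATE_MIDPOINTS",
]

#: Functional ranges of the free rates (/s) explored during fitting.
_FUNCTIONAL_RANGES = {
    "chec": {"k2": (0.03, 0.1), "k_rev2": (0.0, 0.07), "k_rev3": (0.0, 0.03),
             "k4": (0.0075, 0.0275)},
    "chip": {"k2": (0.03, 0.1), "k_rev2": (0.0, 0.1), "k_rev3": (0.0, 0.03),
             "k4": (0.025, 0.1)},
    "gcn4": {"k2": (0.03, 0.1), "k_rev2": (0.0, 0.04), "k_rev3": (0.0, 0.03),
             "k4": (0.01, 0.03)},
}

#: Midpoints of the standard-growth functional ranges, used as reference
#: free-rate values when a single point parameterisation is needed.
FREE_RATE_MIDPOINTS = {"k2": 0.065, "k_rev2": 0.035, "k_rev3": 0.015, "k4": 0.0175}


def functional_ranges(dataset: str = "chec") -> dict:
    """Free-rate ranges for a dataset flavour ('chec', 'chip' or 'gcn4')."""
    try:
        return dict(_FUNCTIONAL_RANGES[dataset])
    except KeyError:
        raise ValueError(f"unknown dataset {dataset!r}; choose from {sorted(_FUNCTIONAL_RANGES)}")


def published_rates(gene_class: str, *, free_at_midpoint: bool = False) -> RateSet:
    """Selected published rates for one gene class (free rates zero or midpoints)."""
    free = FREE_RATE_MIDPOINTS if free_at_midpoint else {}
    common = dict(k5=0.1, k7=0.0325)
    if gene_class == "STM":
        return RateSet.create(
            "STM", k1=0.002, k_rev1=0.003,
            k2=free.get("k2", 0.0), k_rev2=free.get("k_rev2", 0.0),
            k_rev3=free.get("k_rev3", 0.0), k4=free.get("k4", 0.0),
            k6_bp_per_min=1000.0, **common,
        )
    if gene_class == "TFO":
        return RateSet.create(
            "TFO", k3=0.002,
            k_rev3=free.get("k_rev3", 0.0), k4=free.get("k4", 0.0),
            k6_bp_per_min=1000.0, **common,
        )
    raise ValueError(f"unknown gene_class {gene_class!r}")


#: Documented cap standing in for "instantaneous" TFIIH recruitment.
INSTANT_K4 = 50.0


def chip_forced_rates(gene_class: str) -> RateSet:
    """Rates forced to reproduce ChIP-seq-shaped occupancy.

    Promoter dissociation off, TFIIH recruitment effectively instantaneous
    (k4 = 50 /s cap), initiation doubled and termination at 0.14 /s.
    """
    base = published_rates(gene_class, free_at_midpoint=True)
    return base.replace(k_rev3=0.0, k4=INSTANT_K4, k5=0.2, k7=0.14)


def _scn(label: str, **replacements) -> PerturbationScenario:
    return PerturbationScenario(label=label, replacements=replacements)


#: (name, gene_class, model #) -> scenario.  Ranges are (lo, hi) tuples.
_SCENARIOS = {
    # TFIIB depletion, 20 min
    ("tfiib-20min", "STM", 1): _scn("TFIIB degradation 20 min, STM 1", k2=(0.004, 0.04)),
    ("tfiib-20min", "STM", 2): _scn("TFIIB degradation 20 min, STM 2", k_rev1=0.04, k2=(0.004, 0.04)),
    ("tfiib-20min", "STM", 3): _scn("TFIIB degradation 20 min, STM 3", k1=0.0006, k2=(0.004, 0.04)),
    ("tfiib-20min", "TFO", 1): _scn("TFIIB degradation 20 min, TFO 1", k3=0.0008),
    ("tfiib-20min", "TFO", 2): _scn("TFIIB degradation 20 min, TFO 2", k3=0.0008, k_rev3=(0.0, 0.12)),
    # TFIIB depletion, 60 min
    ("tfiib-60min", "STM", 1): _scn("TFIIB degradation 60 min, STM 1", k2=(0.002, 0.02)),
    ("tfiib-60min", "STM", 2): _scn("TFIIB degradation 60 min, STM 2", k_rev1=0.06, k2=(0.002, 0.02)),
    ("tfiib-60min", "STM", 3): _scn("TFIIB degradation 60 min, STM 3", k1=0.0005, k2=(0.002, 0.02)),
    ("tfiib-60min", "TFO", 1): _scn("TFIIB degradation 60 min, TFO 1", k3=0.0004),
    ("tfiib-60min", "TFO", 2): _scn("TFIIB degradation 60 min, TFO 2", k3=0.0004, k_rev3=(0.0, 0.24)),
    # TFIIH-kinase (Kin28) inhibition with CMK
    ("kin28-cmk", "STM", 1): _scn("TFIIH inhibition, STM 1", k5=0.02),
    ("kin28-cmk", "STM", 2): _scn("TFIIH inhibition, STM 2", k_rev3=(0.0, 0.24), k5=0.02),
    ("kin28-cmk", "STM", 3): _scn("TFIIH inhibition, STM 3", k_rev1=0.06, k5=0.02),
    ("kin28-cmk", "STM", 4): _scn("TFIIH inhibition, STM 4", k1=0.0005, k5=0.02),
    ("kin28-cmk", "TFO", 1): _scn("TFIIH inhibition, TFO 1", k5=0.02),
    ("kin28-cmk", "TFO", 2): _scn("TFIIH inhibition, TFO 2", k_rev3=(0.0, 0.24), k5=0.02),
    ("kin28-cmk", "TFO", 3): _scn("TFIIH inhibition, TFO 3", k3=0.0005, k5=0.02),
    # Gcn4 positioning-domain mutant and null
    ("gcn4-pd", "STM", 1): _scn("gcn4-pd, STM 1", k_rev3=(0.0, 0.048)),
    ("gcn4-pd", "STM", 2): _scn("gcn4-pd, STM 2", k2=(0.009, 0.09), k_rev3=(0.0, 0.039)),
    ("gcn4-null", "STM", 1): _scn("gcn4 null, STM 1", k1=0.0006),
}

SCENARIO_NAMES = tuple(sorted({k[0] for k in _SCENARIOS}))


def perturbation_scenarios() -> dict:
    return dict(_SCENARIOS)


def scenario(name: str, gene_class: str, model: int = 1) -> PerturbationScenario:
    """Look up a named perturbation scenario for a gene class and model number."""
    try:
        return _SCENARIOS[(name, gene_class, model)]
    except KeyError:
        avail = sorted(f"{n}/{gc}/{m}" for n, gc, m in _SCENARIOS)
        raise ValueError(
            f"no scenario {name!r} for {gene_class} model {model}; available: {avail}"
        )
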