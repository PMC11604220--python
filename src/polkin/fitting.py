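"""Ensemble grid-search fitting of free transcription-cycle rates to region signals.

The fitting target is a :class:`RegionVector`: the mean signal over the UAS
(STM only), promoter, transcribed region and 3'UTR of a gene class, either in
model occupancy units or in empirical CPM-normalised cleavage units.  Because
the empirical units are arbitrary, agreement is measured by cosine similarity
(scale invariant); model predictions are L2-scaled to the empirical magnitude
only for display and for perturbation deltas.

Rather than a single best fit, the fit returns an *ensemble*: every grid
point whose prediction has cosine similarity above a threshold (default
0.995).  If no point reaches the threshold (as happens when the target shape
is transcript-dominated, the ChIP-like case) the best ``fallback_top_n``
models are returned with a fallback flag.

The model object follows the statsmodels convention:

>>> res = TranscriptionCycleModel(empirical, config).fit()   # doctest: +SKIP
>>> res.summary()                                            # doctest: +SKIP
>>> delta = res.perturb(scenario)                            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .engine import OccupancyProfile, simulate_population
from .kinetics import GeneArchitecture, RateSet, SimulationConfig

__all__ = [
    "RegionVector",
    "FitConfig",
    "PerturbationScenario",
    "TranscriptionCycleModel",
    "EnsembleFitResults",
    "ModelEnsemble",
    "PerturbationResult",
    "aggregate_regions",
    "cosine_similarity",
    "l2_scale",
    "grid_search",
    "apply_perturbation",
    "score_perturbation_fit",
    "ZeroVectorError",
    "REGION_LABELS",
]

REGION_LABELS = {
    "STM": ("UAS", "promoter", "transcript", "3UTR"),
    "TFO": ("promoter", "transcript", "3UTR"),
}


class ZeroVectorError(ValueError):
    """Cosine similarity / L2 scaling is undefined for a zero vector."""


@dataclass(frozen=True)
class RegionVector:
    """Per-region scalar signal for one gene class.

    ``values`` follow the fixed label order of the class (STM: UAS, promoter,
    transcript, 3'UTR; TFO drops the UAS).  ``units`` tags whether the values
    are model occupancies or empirical CPMn.
    """

    gene_class: str
    values: np.ndarray
    units: str = "occupancy"

    def __post_init__(self) -> None:
        if self.gene_class not in REGION_LABELS:
            raise ValueError(f"unknown gene_class {self.gene_class!r}")
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.labels),):
            raise ValueError(
                f"{self.gene_class} region vector needs {len(self.labels)} values "
                f"({', '.join(self.labels)}), got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("region values must be finite")
        if self.units in ("occupancy", "CPMn") and np.any(vals < 0):
            raise ValueError(f"{self.units} region values must be non-negative")

    @property
    def labels(self) -> tuple[str, ...]:
        return REGION_LABELS[self.gene_class]

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.labels), name=self.units)


def aggregate_regions(profile: OccupancyProfile, gene_class: str) -> RegionVector:
    """Collapse a per-compartment profile to region means.

    UAS, promoter and 3'UTR (terminator compartment) are copied; the
    transcript value is the arithmetic mean of the transcript bins.
    """
    labels = profile.labels
    needed = ("UAS", "promoter", "terminator") if gene_class == "STM" else ("promoter", "terminator")
    for lab in needed:
        if lab not in labels:
            raise ValueError(f"profile lacks compartment {lab!r} required for {gene_class}")
    if gene_class == "TFO" and "UAS" in labels:
        raise ValueError("TFO aggregation got a profile with a UAS compartment")
    bins = [l for l in labels if l.startswith("bin_")]
    transcript = float(np.mean([profile[l] for l in bins]))
    vals = [profile["promoter"], transcript, profile["terminator"]]
    if gene_class == "STM":
        vals.insert(0, profile["UAS"])
    return RegionVector(gene_class, np.array(vals), units="occupancy")


def _check_match(a: RegionVector, b: RegionVector) -> None:
    if a.gene_class != b.gene_class:
        raise ValueError(f"gene classes differ: {a.gene_class} vs {b.gene_class}")


def cosine_similarity(model: RegionVector, empirical: RegionVector) -> float:
    """sum(M_i E_i) / (||M|| ||E||); scale invariant, in [-1, 1]."""
    _check_match(model, empirical)
    nm, ne = model.norm, empirical.norm
    if nm == 0 or ne == 0:
        raise ZeroVectorError("cosine similarity undefined for a zero vector")
    return float(np.dot(model.values, empirical.values) / (nm * ne))


def l2_scale(model: RegionVector, empirical: RegionVector) -> RegionVector:
    """Rescale the model vector to the empirical L2 magnitude (unit bridge)."""
    _check_match(model, empirical)
    if model.norm == 0:
        raise ZeroVectorError("cannot L2-scale a zero model vector")
    if empirical.norm == 0:
        raise ZeroVectorError("cannot L2-scale to a zero empirical vector")
    return RegionVector(
        model.gene_class, model.values * (empirical.norm / model.norm), units=empirical.units
    )


# Free parameters explored per class (published functional ranges are the
# defaults; see polkin.presets).
_DEFAULT_FREE = {
    "STM": ("k2", "k_rev2", "k_rev3", "k4"),
    "TFO": ("k_rev3", "k4"),
}


@dataclass(frozen=True)
class FitConfig:
    """Grid-search settings: free ranges, resolution, threshold, simulation size."""

    fixed_rates: RateSet = field(default=None)  # type: ignore[assignment]
    free_ranges: dict = field(default=None)     # rate name -> (lo, hi)
    resolution: int = 10
    threshold: float = 0.995
    fallback_top_n: int = 50
    sim: SimulationConfig = field(default_factory=lambda: SimulationConfig(n_genes=10_000))
    arch: GeneArchitecture | None = None

    def __post_init__(self) -> None:
        from .presets import published_rates, functional_ranges

        if self.fixed_rates is None:
            object.__setattr__(self, "fixed_rates", published_rates("TFO"))
        gc = self.fixed_rates.gene_class
        if self.free_ranges is None:
            ranges = functional_ranges()
            object.__setattr__(
                self, "free_ranges", {k: ranges[k] for k in _DEFAULT_FREE[gc]}
            )
        if self.arch is None:
            object.__setattr__(self, "arch", GeneArchitecture(has_uas=(gc == "STM")))
        if self.resolution < 2:
            raise ValueError("grid resolution must be >= 2")
        if not (-1.0 < self.threshold <= 1.0):
            raise ValueError(f"similarity threshold must be in (-1, 1], got {self.threshold}")
        for name, (lo, hi) in self.free_ranges.items():
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")

    @property
    def gene_class(self) -> str:
        return self.fixed_rates.gene_class

    def grid_axes(self) -> dict:
        return {
            name: np.linspace(lo, hi, self.resolution)
            for name, (lo, hi) in self.free_ranges.items()
        }

    def grid_points(self) -> list[dict]:
        axes = self.grid_axes()
        names = list(axes)
        return [dict(zip(names, combo)) for combo in product(*axes.values())]


@dataclass(frozen=True)
class PerturbationScenario:
    """Named rate replacements modelling an experimental perturbation.

    ``replacements`` maps rate names to either an absolute value or a
    ``(lo, hi)`` range; ranges are sub-gridded within each ensemble member
    and the envelope of predictions reported.
    """

    label: str
    replacements: dict

    def __post_init__(self) -> None:
        from .kinetics import RATE_NAMES

        valid = {n for n in RATE_NAMES if n != "hop"} | {"k6"}
        for name, val in self.replacements.items():
            if name not in valid:
                raise ValueError(f"scenario {self.label!r} touches unknown rate {name!r}")
            vals = val if isinstance(val, (tuple, list)) else (val,)
            if any(v < 0 for v in vals):
                raise ValueError(f"scenario {self.label!r}: rate {name} must be >= 0")


class TranscriptionCycleModel:
    """Transcription-cycle kinetic model to be fitted to one region vector.

    Parameters
    ----------
    empirical
        Region-binned signal for one gene class (CPMn or occupancy units).
    config
        Grid-search configuration; defaults follow the published rate table
        for the empirical vector's gene class.
    """

    def __init__(self, empirical: RegionVector, config: FitConfig | None = None):
        from .presets import published_rates

        if config is None:
            config = FitConfig(fixed_rates=published_rates(empirical.gene_class))
        if config.gene_class != empirical.gene_class:
            raise ValueError(
                f"config is for {config.gene_class}, empirical data for {empirical.gene_class}"
            )
        if empirical.norm == 0:
            raise ZeroVectorError("empirical region vector is zero")
        self.empirical = empirical
        self.config = config

    @classmethod
    def from_tsv(cls, path, gene_class: str, config: FitConfig | None = None,
                 value_col: str = "value") -> "TranscriptionCycleModel":
        """Build from a TSV with columns (gene_class, region, value[, se])."""
        df = pd.read_csv(path, sep="\t")
        sub = df[df["gene_class"] == gene_class].set_index("region")
        labels = REGION_LABELS[gene_class]
        missing = [l for l in labels if l not in sub.index]
        if missing:
            raise ValueError(f"TSV lacks regions {missing} for class {gene_class}")
        vec = RegionVector(gene_class, sub.loc[list(labels), value_col].to_numpy(),
                           units="CPMn")
        return cls(vec, config)

    # -- fitting ------------------------------------------------------------
    def _simulate_point(self, rates: RateSet, seed: int) -> RegionVector:
        cfg = replace(self.config.sim, seed=seed)
        profile = simulate_population(rates, self.config.arch, cfg)
        return aggregate_regions(profile, self.config.gene_class)

    def fit(self) -> "EnsembleFitResults":
        """Simulate every grid point, score against the data, form the ensemble."""
        points = self.config.grid_points()
        if not points:
            raise ValueError("empty parameter grid")
        rates_list, predictions, scores = [], [], []
        for i, free in enumerate(points):
            rates = self.config.fixed_rates.replace(**free)
            pred = self._simulate_point(rates, seed=self.config.sim.seed + i)
            rates_list.append(rates)
            predictions.append(pred)
            scores.append(cosine_similarity(pred, self.empirical))
        scores_arr = np.array(scores)
        passing = np.flatnonzero(scores_arr >= self.config.threshold)
        fallback = len(passing) == 0
        if fallback:
            order = np.argsort(scores_arr)[::-1][: self.config.fallback_top_n]
        else:
            order = passing[np.argsort(scores_arr[passing])[::-1]]
        return EnsembleFitResults(
            model=self,
            member_indices=order,
            all_rates=rates_list,
            all_predictions=predictions,
            all_scores=scores_arr,
            fallback=fallback,
        )


class EnsembleFitResults:
    """Ensemble of rate sets consistent with the data, with their scores.

    Members are sorted by descending cosine similarity.  ``predicted_regions``
    is the ensemble-average prediction: the mean of the members' L2-scaled
    region vectors, in empirical units.
    """

    def __init__(self, model, member_indices, all_rates, all_predictions, all_scores, fallback):
        self.model = model
        self.empirical = model.empirical
        self.threshold = model.config.threshold
        self.fallback = bool(fallback)
        self._indices = np.asarray(member_indices)
        self._all_rates = all_rates
        self._all_predictions = all_predictions
        self._all_scores = all_scores
        self.members: list[RateSet] = [all_rates[i] for i in self._indices]
        self.scores = all_scores[self._indices]
        self.member_predictions: list[RegionVector] = [all_predictions[i] for i in self._indices]

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def free_names(self) -> list[str]:
        return list(self.model.config.free_ranges)

    @property
    def predicted_regions(self) -> RegionVector:
        scaled = np.array([l2_scale(p, self.empirical).values for p in self.member_predictions])
        return RegionVector(self.empirical.gene_class, scaled.mean(axis=0),
                            units=self.empirical.units)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rates, score in zip(self.members, self.scores):
            row = {name: getattr(rates, name) for name in self.free_names}
            row["score"] = score
            rows.append(row)
        return pd.DataFrame(rows)

    def contains(self, **free_rates: float) -> bool:
        """True when a member matches the given free-rate values (to 1e-12)."""
        for rates in self.members:
            if all(abs(getattr(rates, k) - v) < 1e-12 for k, v in free_rates.items()):
                return True
        return False

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def summary(self) -> str:
        cfg = self.model.config
        df = self.to_frame()
        lines = [
            "Transcription-cycle ensemble fit",
            "=" * 46,
            f"gene class:        {cfg.gene_class}",
            f"grid points:       {len(self._all_rates)} "
            f"({cfg.resolution} per free rate)",
            f"threshold:         {self.threshold}",
            f"ensemble size:     {self.n_members}"
            + ("  [FALLBACK: no model reached threshold]" if self.fallback else ""),
            f"best similarity:   {self.scores.max():.6f}",
            "",
            "free rate ranges in ensemble (/s):",
        ]
        for name in self.free_names:
            lines.append(
                f"  {name:8s} min {df[name].min():.5g}  median {df[name].median():.5g}"
                f"  max {df[name].max():.5g}"
            )
        lines.append("")
        lines.append("region            empirical     ensemble mean")
        pred = self.predicted_regions
        for lab in self.empirical.labels:
            lines.append(f"  {lab:12s} {self.empirical[lab]:>12.5g} {pred[lab]:>14.5g}")
        return "\n".join(lines)

    def perturb(self, scenario: PerturbationScenario, subgrid: int = 4) -> "PerturbationResult":
        return apply_perturbation(self, scenario, subgrid=subgrid)


#: spec-facing alias
ModelEnsemble = EnsembleFitResults


def grid_search(empirical: RegionVector, config: FitConfig) -> EnsembleFitResults:
    """Functional facade over ``TranscriptionCycleModel(empirical, config).fit()``."""
    return TranscriptionCycleModel(empirical, config).fit()


@dataclass(frozen=True)
class PerturbationResult:
    """Region-wise occupancy changes (perturbed - baseline) across an ensemble."""

    scenario: PerturbationScenario
    labels: tuple[str, ...]
    delta_mean: np.ndarray
    delta_sd: np.ndarray
    delta_min: np.ndarray
    delta_max: np.ndarray
    n_members: int

    def __getitem__(self, label: str) -> float:
        return float(self.delta_mean[self.labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.labels,
                "delta_mean": self.delta_mean,
                "delta_sd": self.delta_sd,
                "delta_min": self.delta_min,
                "delta_max": self.delta_max,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def delta_vector(self) -> RegionVector:
        gc = "STM" if len(self.labels) == 4 else "TFO"
        return RegionVector(gc, self.delta_mean, units="delta")


def apply_perturbation(
    ensemble: EnsembleFitResults, scenario: PerturbationScenario, subgrid: int = 4
) -> PerturbationResult:
    """Re-simulate every ensemble member with the scenario's rate replacements.

    Deltas are computed on L2-scaled predictions in empirical units: each
    member's baseline prediction is scaled to the empirical magnitude, and
    the *same* member-specific scale factor converts the perturbed
    prediction, so a genuine proportional loss of occupancy shows up as a
    negative delta rather than being cancelled by rescaling.
    Range-valued replacements are sub-gridded
    within each member; the envelope across members and sub-points is
    reported.  Baseline and perturbed runs reuse the member's fit seed, so an
    identity scenario gives exactly zero deltas.
    """
    if ensemble.n_members == 0:
        raise ValueError("cannot perturb an empty ensemble")
    model = ensemble.model
    emp = ensemble.empirical
    deltas = []
    for m, (rates, baseline) in enumerate(zip(ensemble.members, ensemble.member_predictions)):
        if baseline.norm == 0:
            raise ZeroVectorError("cannot calibrate units on a zero baseline prediction")
        unit_factor = emp.norm / baseline.norm
        base_scaled = baseline.values * unit_factor
        fixed, ranged = {}, {}
        for name, val in scenario.replacements.items():
            (ranged if isinstance(val, (tuple, list)) else fixed)[name] = val
        sub_points = [{}]
        for name, (lo, hi) in ranged.items():
            sub_points = [
                {**pt, name: v} for pt in sub_points for v in np.linspace(lo, hi, subgrid)
            ]
        seed = model.config.sim.seed + int(ensemble._indices[m])
        for pt in sub_points:
            perturbed = rates.replace(**fixed, **pt)
            pred = model._simulate_point(perturbed, seed=seed)
            deltas.append(pred.values * unit_factor - base_scaled)
    arr = np.array(deltas)
    return PerturbationResult(
        scenario=scenario,
        labels=emp.labels,
        delta_mean=arr.mean(axis=0),
        delta_sd=arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(arr.shape[1]),
        delta_min=arr.min(axis=0),
        delta_max=arr.max(axis=0),
        n_members=ensemble.n_members,
    )


def score_perturbation_fit(delta_model: RegionVector, delta_empirical: RegionVector) -> float:
    """Cosine similarity between model and empirical region-wise changes.

    Both vectors may be negative region-wise; sign disagreement is penalised
    (opposite deltas score -1).
    """
    _check_match(delta_model, delta_empirical)
    nm, ne = delta_model.norm, delta_empirical.norm
    if nm == 0 or ne == 0:
        raise ZeroVectorError("perturbation score undefined for a zero delta vector")
    return float(np.dot(delta_model.values, delta_empirical.values) / (nm * ne))
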