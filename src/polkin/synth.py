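"""Synthetic inputs with known ground truth.

Two generators cover the pipeline's inputs.  ``synth_region_vectors``
emulates the replicate-averaged region signal the kinetic model is fitted
to: it simulates occupancy at known rates, aggregates to regions, applies
replicate-level noise and rescales to a pseudo-CPMn magnitude, returning the
ground truth alongside.  ``synth_genome_fixture`` writes a miniature genome
on disk — bedGraph coverage, BED6 genes and sites, nascent-count TSV — whose
region means and site profiles are constructed exactly, so downstream
signal computations can be asserted against closed-form expectations.

Replicate noise defaults to multiplicative Gaussian on region values
(matching the region-level replicate means the fits consume, amplitude =
relative SD); a Poisson counts-then-CPM mode exists for end-to-end genomics
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import simulate_population
from .fitting import RegionVector, aggregate_regions, l2_scale
from .gsignal import write_bed6
from .kinetics import GeneArchitecture, RateSet, SimulationConfig

__all__ = ["NoiseSpec", "FixtureSpec", "synth_region_vectors", "synth_genome_fixture",
           "write_manifest"]


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate-noise model for synthetic region vectors."""

    model: str = "gaussian-on-regions"   # none | gaussian-on-regions | poisson-counts-then-cpm
    amplitude: float = 0.05              # relative SD (gaussian) or count depth (poisson)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian-on-regions", "poisson-counts-then-cpm"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def synth_region_vectors(
    true_rates: RateSet,
    arch: GeneArchitecture,
    cfg: SimulationConfig,
    noise: NoiseSpec,
    target_norm: float = 100.0,
) -> tuple[list[RegionVector], dict]:
    """Replicate region vectors from known rates, plus the ground truth.

    Returns ``(replicates, truth)`` where ``truth`` holds the rates and the
    noise-free aggregate (both in occupancy units and scaled to the
    pseudo-CPMn magnitude ``target_norm``).
    """
    profile = simulate_population(true_rates, arch, cfg)
    clean = aggregate_regions(profile, true_rates.gene_class)
    target = RegionVector(clean.gene_class,
                          np.full(len(clean.labels), target_norm / np.sqrt(len(clean.labels))),
                          units="CPMn")
    clean_scaled = l2_scale(clean, target)
    rng = np.random.default_rng(noise.seed)
    reps = []
    for _ in range(noise.n_replicates):
        if noise.model == "none":
            vals = clean_scaled.values.copy()
        elif noise.model == "gaussian-on-regions":
            vals = clean_scaled.values * (1.0 + noise.amplitude * rng.standard_normal(len(clean.labels)))
            vals = np.maximum(vals, 0.0)
        else:  # poisson-counts-then-cpm: values as expected counts at a depth
            depth = noise.amplitude if noise.amplitude > 0 else 1.0
            lam = clean_scaled.values * depth
            vals = rng.poisson(lam).astype(float) / depth
        reps.append(RegionVector(clean.gene_class, vals, units="CPMn"))
    truth = {
        "rates": true_rates,
        "occupancy": clean,
        "scaled": clean_scaled,
        "profile": profile,
    }
    return reps, truth


@dataclass(frozen=True)
class FixtureSpec:
    """Layout of a synthetic genome fixture.

    Each gene gets the four canonical regions with the requested per-bp mean
    coverage; one oriented point site is placed in each gene's promoter with
    a delta of ``site_height`` at offset 0.  Genes alternate strand when
    ``alternate_strands`` is set.  All construction is exact so downstream
    region/metagene/metasite computations can be checked bit-for-bit.
    """

    n_genes: int = 4
    gene_length: int = 1200
    flank: int = 1000
    region_means: tuple = (2.0, 4.0, 6.0, 8.0)   # UAS, promoter, transcript, terminator
    segment_constant: tuple = ()  # (upstream flank, TSS..TES body, downstream flank):
                                  # when set, paints metagene segments instead of regions
    background: float = 0.0
    site_height: float = 50.0
    alternate_strands: bool = True
    nascent_counts: tuple = ()                    # default: 100 per gene
    contig: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.gene_length < 103:
            raise ValueError("gene_length too short for the region encroachments")
        if len(self.region_means) != 4:
            raise ValueError("region_means must give (UAS, promoter, transcript, terminator)")

    @property
    def pitch(self) -> int:
        # genome spacing per gene: flanks on both sides plus slack
        return self.gene_length + 2 * self.flank + 200

    @property
    def contig_length(self) -> int:
        return self.pitch * self.n_genes + 2 * self.flank


def synth_genome_fixture(spec: FixtureSpec, outdir) -> dict:
    """Write a synthetic genome fixture; returns paths, tables and ground truth.

    Files written: ``coverage.bedgraph`` (0-based half-open), ``genes.bed``,
    ``sites.bed`` (BED6), ``nascent_counts.tsv``, ``truth_regions.tsv`` and a
    ``manifest.yaml``.  Raises before writing anything if the genes do not
    fit on the contig.
    """
    outdir = Path(outdir)
    n = spec.contig_length
    genes = []
    for i in range(spec.n_genes):
        strand = "-" if (spec.alternate_strands and i % 2) else "+"
        left = spec.flank + 600 + i * spec.pitch
        if strand == "+":
            tss, tes = left, left + spec.gene_length - 1
        else:
            tss, tes = left + spec.gene_length - 1, left
        hi_flank = max(tss, tes) + spec.flank
        if hi_flank + 1 > n or min(tss, tes) - spec.flank - 500 < 0:
            raise ValueError("fixture packing infeasible: gene flanks leave the contig")
        genes.append({"gene_id": f"g{i:03d}", "contig": spec.contig, "strand": strand,
                      "tss": tss, "tes": tes})
    genes_df = pd.DataFrame(genes)
    counts = (list(spec.nascent_counts) or [100.0] * spec.n_genes)
    if len(counts) != spec.n_genes:
        raise ValueError("nascent_counts length must match n_genes")
    genes_df["nascent_count"] = counts

    from .gsignal import define_regions

    regions, excluded = define_regions(genes_df)
    if len(excluded):
        raise ValueError(f"fixture genes excluded by region rules: {excluded.to_dict('records')}")

    coverage = np.full(n, float(spec.background))
    if spec.segment_constant:
        up, body, down = spec.segment_constant
        for g in genes_df.itertuples(index=False):
            lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
            coverage[lo:hi + 1] = body
            if g.strand == "+":
                coverage[g.tss - spec.flank:g.tss] = up
                coverage[g.tes + 1:g.tes + 1 + spec.flank] = down
            else:
                coverage[g.tss + 1:g.tss + 1 + spec.flank] = up
                coverage[g.tes - spec.flank:g.tes] = down
    else:
        mean_of = dict(zip(("UAS", "promoter", "transcript", "terminator"), spec.region_means))
        for r in regions.itertuples(index=False):
            coverage[r.start:r.end] = mean_of[r.region]

    sites = []
    for g in genes_df.itertuples(index=False):
        pos = g.tss - 100 if g.strand == "+" else g.tss + 100
        sites.append({"contig": spec.contig, "position": pos, "strand": g.strand})
    site_positions = [s["position"] for s in sites]

    outdir.mkdir(parents=True, exist_ok=True)
    from .gsignal import CoverageTrack

    track = CoverageTrack(data={spec.contig: coverage}, units="counts")
    track.write_bedgraph(outdir / "coverage.bedgraph")

    bed = pd.DataFrame({
        "contig": genes_df["contig"],
        "start": np.minimum(genes_df["tss"], genes_df["tes"]),
        "end": np.maximum(genes_df["tss"], genes_df["tes"]) + 1,
        "name": genes_df["gene_id"],
        "score": 0,
        "strand": genes_df["strand"],
    })
    write_bed6(bed, outdir / "genes.bed")
    sites_bed = pd.DataFrame({
        "contig": [s["contig"] for s in sites],
        "start": site_positions,
        "end": [p + 1 for p in site_positions],
        "name": [f"site{i:03d}" for i in range(len(sites))],
        "score": 0,
        "strand": [s["strand"] for s in sites],
    })
    write_bed6(sites_bed, outdir / "sites.bed")
    genes_df[["gene_id", "nascent_count"]].to_csv(
        outdir / "nascent_counts.tsv", sep="\t", index=False
    )

    total = spec.n_genes * sum(spec.region_means)
    truth = pd.DataFrame({
        "region": ("UAS", "promoter", "transcript", "terminator"),
        "per_bp_mean": spec.region_means,
        "fraction_of_total": np.array(spec.region_means) / sum(spec.region_means),
    })
    truth.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False, float_format="%.10g")

    write_manifest(outdir / "manifest.yaml", {
        "generator": "synth_genome_fixture",
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in spec.__dict__.items()},
    })
    return {
        "genes": genes_df,
        "sites": pd.DataFrame(sites),
        "regions": regions,
        "track": track,
        "truth": truth,
        "paths": {name: outdir / name for name in
                  ("coverage.bedgraph", "genes.bed", "sites.bed",
                   "nascent_counts.tsv", "truth_regions.tsv", "manifest.yaml")},
    }


def write_manifest(path, payload: dict) -> None:
    """Plain-text manifest recording the generating configuration and version."""
    doc = {"polkin_version": __version__, **payload}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
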