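"""Genomic-signal computations: coverage tracks, gene regions, meta-profiles.

Implements the occupancy-track arithmetic used to turn per-base cleavage
coverage into the region vectors that the kinetic model is fitted to:

* CPM normalisation of raw count tracks;
* gene-region definitions (UAS -500..-151, promoter -150..+25 relative to
  the TSS; transcript +26..TES-76; terminator TES-75..TES+150), strand-aware;
* per-gene region signal, as per-bp means or as fraction of the gene total;
* metagene profiles (1 kb upstream / length-normalised transcript / 1 kb
  downstream, 100 bins each) and metasite profiles (oriented points, +/-250 bp);
* sliding-window smoothing (window 10, step 5) and background subtraction;
* the >=50 mean-nascent-count expression filter and relative region
  enrichment between factors with replicate-based z-scores.

Coordinates are handled internally as 0-based half-open intervals; the
conventional inclusive offsets relative to TSS/TES (TSS = offset 0) are
converted at the boundary.  Under that convention the promoter spans 176
bases.

Gene annotations are plain pandas DataFrames with columns ``gene_id, contig,
strand, tss, tes`` plus optional ``gene_class`` and ``nascent_count``
(replicate-mean); ``tss``/``tes`` are 0-based base positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoverageTrack",
    "MetaProfile",
    "cpm_normalize",
    "define_regions",
    "region_signal",
    "metagene",
    "metasite",
    "smooth",
    "subtract_background",
    "filter_expressed",
    "relative_region_enrichment",
    "ratio_zscore",
    "infer_tss_tes",
    "read_bed6",
    "write_bed6",
    "REGION_OFFSETS",
]

#: Inclusive offsets (start, end) of each gene region relative to its anchor
#: (TSS for UAS/promoter/transcript start, TES for transcript end/terminator).
REGION_OFFSETS = {
    "UAS": (-500, -151),
    "promoter": (-150, 25),
    "transcript": (26, -76),   # +26 from TSS to -76 from TES
    "terminator": (-75, 150),
}

#: Median yeast UTR lengths used when no measured TSS/TES is available.
DEFAULT_5UTR = 47
DEFAULT_3UTR = 118


@dataclass
class CoverageTrack:
    """Per-base signal arrays keyed by contig, with a units tag."""

    data: dict = field(default_factory=dict)  # contig -> float ndarray
    units: str = "counts"
    convention: str = "0-based"  # genome coordinate convention tag

    def __post_init__(self) -> None:
        clean = {}
        for contig, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite coverage on contig {contig!r}")
            if self.units == "counts" and arr.min(initial=0.0) < 0:
                raise ValueError(f"negative raw counts on contig {contig!r}")
            clean[contig] = arr
        self.data = clean

    @property
    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def contig_length(self, contig: str) -> int:
        return len(self.data[contig])

    def __getitem__(self, contig: str) -> np.ndarray:
        return self.data[contig]

    # -- bedGraph (4-column, 0-based half-open) -----------------------------
    @classmethod
    def read_bedgraph(cls, path, contig_lengths: dict, units: str = "counts") -> "CoverageTrack":
        data = {c: np.zeros(n) for c, n in contig_lengths.items()}
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["contig", "start", "end", "value"],
                         dtype={"contig": str, "start": int, "end": int, "value": float})
        prev: dict[str, int] = {}
        for contig, start, end, value in df.itertuples(index=False):
            if contig not in data:
                raise ValueError(f"bedGraph contig {contig!r} absent from contig_lengths")
            if not (0 <= start < end <= len(data[contig])):
                raise ValueError(f"interval {contig}:{start}-{end} out of bounds")
            if start < prev.get(contig, 0):
                raise ValueError(f"bedGraph not sorted at {contig}:{start}")
            prev[contig] = end
            data[contig][start:end] = value
        return cls(data=data, units=units)

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for contig in sorted(self.data):
                arr = self.data[contig]
                # run-length encode constant stretches
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(arr)]])
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{contig}\t{s}\t{e}\t{v:.10g}\n")


@dataclass(frozen=True)
class MetaProfile:
    """Averaged signal profile over aligned features."""

    positions: np.ndarray       # relative bin coordinates
    values: np.ndarray
    n_features: int
    smoothing: str = "none"

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("meta-profile values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "signal": self.values})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Track arithmetic
# ---------------------------------------------------------------------------

def cpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale per-base values so they sum to 1e6 genome-wide."""
    total = track.total
    if total <= 0:
        raise ValueError("cannot CPM-normalise an empty track (total signal is 0)")
    return CoverageTrack(
        data={c: arr * (1e6 / total) for c, arr in track.data.items()}, units="CPM"
    )


def subtract_background(specific, control):
    """Element-wise specific - control; negative values are retained.

    Works on two :class:`CoverageTrack` or two :class:`MetaProfile` objects of
    identical shape and units (e.g. subtracting the soluble-nuclease control).
    """
    if isinstance(specific, MetaProfile) and isinstance(control, MetaProfile):
        if len(specific.values) != len(control.values):
            raise ValueError("meta-profile shapes differ")
        return MetaProfile(specific.positions, specific.values - control.values,
                           specific.n_features, specific.smoothing)
    if isinstance(specific, CoverageTrack) and isinstance(control, CoverageTrack):
        if specific.units != control.units:
            raise ValueError(f"unit mismatch: {specific.units} vs {control.units}")
        if set(specific.data) != set(control.data) or any(
            len(specific[c]) != len(control[c]) for c in specific.data
        ):
            raise ValueError("track shapes differ")
        return CoverageTrack(
            data={c: specific[c] - control[c] for c in specific.data},
            units=specific.units + "-corrected",
        )
    raise TypeError("specific and control must both be CoverageTrack or both MetaProfile")


def smooth(signal: np.ndarray, window: int = 10, step: int = 5):
    """Sliding-window mean; returns ``(centers, means)``.

    Windows start every ``step`` positions and are truncated at the signal
    boundary; each output position is the center of its (possibly truncated)
    window.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if n == 0:
        raise ValueError("cannot smooth an empty signal")
    starts = np.arange(0, n, step)
    centers, means = [], []
    for s in starts:
        chunk = signal[s : s + window]
        centers.append(s + (len(chunk) - 1) / 2.0)
        means.append(chunk.mean())
    return np.array(centers), np.array(means)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def infer_tss_tes(cds_start: int, cds_end: int, strand: str,
                  tss: int | None = None, tes: int | None = None) -> tuple[int, int]:
    """Fill missing TSS/TES from coding bounds using median UTR lengths.

    When a measured site is unavailable the TSS is placed 47 bp (median 5'UTR)
    upstream of the coding start and the TES 118 bp (median 3'UTR) downstream
    of the coding end, respecting strand.
    """
    if strand == "+":
        tss = cds_start - DEFAULT_5UTR if tss is None else tss
        tes = cds_end + DEFAULT_3UTR if tes is None else tes
    elif strand == "-":
        tss = cds_end + DEFAULT_5UTR if tss is None else tss
        tes = cds_start - DEFAULT_3UTR if tes is None else tes
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return tss, tes


def _region_bounds(tss: int, tes: int, strand: str) -> dict:
    """Inclusive genomic (start, end) per region for one gene."""
    if strand == "+":
        return {
            "UAS": (tss - 500, tss - 151),
            "promoter": (tss - 150, tss + 25),
            "transcript": (tss + 26, tes - 76),
            "terminator": (tes - 75, tes + 150),
        }
    return {
        "UAS": (tss + 151, tss + 500),
        "promoter": (tss - 25, tss + 150),
        "transcript": (tes + 76, tss - 26),
        "terminator": (tes - 150, tes + 75),
    }


def define_regions(genes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene UAS/promoter/transcript/terminator intervals.

    Returns ``(regions, excluded)``.  ``regions`` has one row per gene and
    region with 0-based half-open ``start``/``end``; genes whose transcript is
    too short to accommodate the +26/-76 encroachment are reported in
    ``excluded`` with a reason instead.
    """
    rows, excluded = [], []
    for g in genes.itertuples(index=False):
        if g.strand not in ("+", "-"):
            excluded.append({"gene_id": g.gene_id, "reason": f"bad strand {g.strand!r}"})
            continue
        length = (g.tes - g.tss) if g.strand == "+" else (g.tss - g.tes)
        if length <= 0:
            excluded.append({"gene_id": g.gene_id, "reason": "TSS/TES order inconsistent with strand"})
            continue
        if length < 26 + 76 + 1:
            excluded.append({
                "gene_id": g.gene_id,
                "reason": f"transcript of {length} bp shorter than +26/-76 encroachment",
            })
            continue
        for region, (lo, hi) in _region_bounds(g.tss, g.tes, g.strand).items():
            rows.append({
                "gene_id": g.gene_id, "contig": g.contig, "strand": g.strand,
                "region": region, "start": lo, "end": hi + 1,  # half-open
            })
    return pd.DataFrame(rows), pd.DataFrame(excluded, columns=["gene_id", "reason"])


def region_signal(track: CoverageTrack, regions: pd.DataFrame, mode: str = "per-bp-mean") -> pd.DataFrame:
    """Per-gene per-region signal.

    ``per-bp-mean`` divides the region sum by its length; ``fraction-of-total``
    further normalises each gene's four length-normalised values to sum to 1.
    """
    if mode not in ("per-bp-mean", "fraction-of-total"):
        raise ValueError(f"unknown mode {mode!r}")
    out_rows = []
    for r in regions.itertuples(index=False):
        arr = track[r.contig]
        if not (0 <= r.start < r.end <= len(arr)):
            raise ValueError(
                f"region {r.region} of gene {r.gene_id} ({r.contig}:{r.start}-{r.end}) "
                "outside the coverage track"
            )
        out_rows.append({
            "gene_id": r.gene_id, "region": r.region,
            "value": float(arr[r.start:r.end].mean()),
        })
    df = pd.DataFrame(out_rows)
    wide = df.pivot(index="gene_id", columns="region", values="value")
    wide = wide[[c for c in ("UAS", "promoter", "transcript", "terminator") if c in wide.columns]]
    if mode == "fraction-of-total":
        totals = wide.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise ValueError(f"zero total signal for gene(s) {bad}; fractions undefined")
        wide = wide.div(totals, axis=0)
    wide.columns.name = None
    return wide


# ---------------------------------------------------------------------------
# Meta-profiles
# ---------------------------------------------------------------------------

def _segment_bins(values: np.ndarray, nbins: int) -> np.ndarray:
    """Mean of ``values`` in ``nbins`` equal slices (last bases absorb remainders)."""
    edges = np.floor(np.linspace(0, len(values), nbins + 1)).astype(int)
    out = np.empty(nbins)
    for i in range(nbins):
        lo, hi = edges[i], edges[i + 1]
        out[i] = values[lo:hi].mean() if hi > lo else values[min(lo, len(values) - 1)]
    return out


def _replicate_mean(tracks) -> CoverageTrack:
    tracks = [tracks] if isinstance(tracks, CoverageTrack) else list(tracks)
    if len(tracks) == 1:
        return tracks[0]
    base = tracks[0]
    data = {c: np.mean([t[c] for t in tracks], axis=0) for c in base.data}
    return CoverageTrack(data=data, units=base.units)


def metagene(tracks, genes: pd.DataFrame, flank: int = 1000,
             bins_per_segment: int = 100) -> MetaProfile:
    """Average profile over genes: upstream flank, length-normalised transcript,
    downstream flank, each in ``bins_per_segment`` bins (300 bins total).

    ``tracks`` may be a single :class:`CoverageTrack` or an iterable of
    replicates, which are averaged per base first.  Genes whose flanks leave
    the contig are skipped with a warning entry in the profile count.
    """
    track = _replicate_mean(tracks)
    per_gene = []
    for g in genes.itertuples(index=False):
        arr = track[g.contig]
        if g.strand == "+":
            lo, hi = g.tss - flank, g.tes + flank + 1
            if lo < 0 or hi > len(arr):
                continue
            sig = arr[lo:hi]
            up, body, down = sig[:flank], sig[flank:flank + (g.tes - g.tss + 1)], sig[-flank:]
        else:
            lo, hi = g.tes - flank, g.tss + flank + 1
            if lo < 0 or hi > len(arr):
                continue
            sig = arr[lo:hi][::-1]
            up, body, down = sig[:flank], sig[flank:flank + (g.tss - g.tes + 1)], sig[-flank:]
        per_gene.append(np.concatenate([
            _segment_bins(up, bins_per_segment),
            _segment_bins(body, bins_per_segment),
            _segment_bins(down, bins_per_segment),
        ]))
    if not per_gene:
        raise ValueError("no usable genes for the metagene profile")
    values = np.mean(per_gene, axis=0)
    positions = np.arange(3 * bins_per_segment)
    return MetaProfile(positions, values, n_features=len(per_gene))


def metasite(tracks, sites: pd.DataFrame, flank: int = 250,
             smooth_window: int = 10, smooth_step: int = 5) -> MetaProfile:
    """Base-resolution average over oriented sites, then sliding-window smoothed.

    ``sites`` needs columns ``contig, position, strand``; minus-strand windows
    are mirrored before averaging.  Sites whose window leaves the contig are
    excluded.
    """
    track = _replicate_mean(tracks)
    windows = []
    for s in sites.itertuples(index=False):
        arr = track[s.contig]
        lo, hi = s.position - flank, s.position + flank + 1
        if lo < 0 or hi > len(arr):
            continue
        win = arr[lo:hi]
        windows.append(win[::-1] if s.strand == "-" else win)
    if not windows:
        raise ValueError("no usable sites for the metasite profile")
    mean = np.mean(windows, axis=0)
    offsets = np.arange(-flank, flank + 1)
    if smooth_window <= 1:
        return MetaProfile(offsets, mean, n_features=len(windows))
    centers, values = smooth(mean, window=smooth_window, step=smooth_step)
    return MetaProfile(centers - flank, values, n_features=len(windows),
                       smoothing=f"window={smooth_window},step={smooth_step}")


# ---------------------------------------------------------------------------
# Gene filtering and enrichment
# ---------------------------------------------------------------------------

def filter_expressed(genes: pd.DataFrame, min_mean_count: float = 50.0) -> pd.DataFrame:
    """Keep genes whose replicate-mean nascent count is >= the threshold.

    Genes with a missing count are excluded (they cannot demonstrate
    expression).
    """
    if "nascent_count" not in genes.columns:
        raise ValueError("genes need a 'nascent_count' column (replicate mean)")
    counts = pd.to_numeric(genes["nascent_count"], errors="coerce")
    return genes[counts >= min_mean_count].copy()


def ratio_zscore(ratio_a: float, se_a: float, ratio_b: float, se_b: float) -> tuple[float, float]:
    """z-score and two-sided normal p-value for a difference of two ratios."""
    denom = float(np.hypot(se_a, se_b))
    if denom == 0:
        raise ValueError("both standard errors are zero; z undefined")
    z = (ratio_a - ratio_b) / denom
    return z, float(2 * stats.norm.sf(abs(z)))


def relative_region_enrichment(factor_reps, reference_reps) -> pd.DataFrame:
    """Region enrichment of a factor relative to a reference factor.

    Inputs are per-replicate DataFrames (gene x region, e.g. from
    :func:`region_signal`).  Per replicate, each gene's region values are
    divided by the reference's; genes with a zero reference region are skipped
    for that replicate.  Output has one row per region with the
    across-replicate mean ratio and its standard error (dispersion between
    biological replicates).
    """
    factor_reps, reference_reps = list(factor_reps), list(reference_reps)
    if len(factor_reps) != len(reference_reps) or not factor_reps:
        raise ValueError("factor and reference need the same (nonzero) replicate count")
    per_rep = []
    for fac, ref in zip(factor_reps, reference_reps):
        common = fac.index.intersection(ref.index)
        fac, ref = fac.loc[common], ref.loc[common]
        ok = (ref != 0).all(axis=1)
        ratios = fac[ok] / ref[ok]
        per_rep.append(ratios.mean(axis=0))
    mat = pd.concat(per_rep, axis=1)
    n = mat.shape[1]
    out = pd.DataFrame({
        "ratio": mat.mean(axis=1),
        "se": mat.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        "n_replicates": n,
    })
    out.index.name = "region"
    return out


# ---------------------------------------------------------------------------
# BED6 IO
# ---------------------------------------------------------------------------

def read_bed6(path) -> pd.DataFrame:
    """BED6 (0-based half-open) -> DataFrame with contig/start/end/name/score/strand."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end", "name", "score", "strand"],
                     dtype={"contig": str, "start": int, "end": int,
                            "name": str, "strand": str})
    if ((df["end"] <= df["start"]).any()):
        raise ValueError("BED6 intervals must satisfy start < end")
    if not df["strand"].isin(["+", "-", "."]).all():
        raise ValueError("BED6 strand column must be '+', '-' or '.'")
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    df[["contig", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )
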