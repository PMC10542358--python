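"""Windowed GC skew / GC fraction, observed-vs-expected grids and sequence
contexts around m5C sites.

GC skew = (#G - #C) / (#G + #C) and GC fraction = (#G + #C) / window length,
computed on fixed non-overlapping windows tiled from coordinate 0 (the
terminal partial window is dropped). R-loops form where the transcribed
(sense) strand is G-rich, so skew is always expressed on the sense strand:
windows overlapping a minus-strand transcript have their plus-strand skew
negated. Windows containing N, or with no G and no C, carry an undefined
skew and are excluded from grid statistics.

The enrichment grid bins windows by (skew, GC fraction): observed = windows
inside R-loop peaks, expected = every other window in the genome, ratio =
(obs proportion) / (exp proportion) per cell, faceted by transcribing strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeSequence, Interval, PipelineError, reverse_complement
from .calling import rank_top_fraction

FACETS = ("+", "-", ".")


def windowed_gc_stats(genome: GenomeSequence, window_size: int = 50,
                      transcripts: list[Interval] | None = None,
                      rloops: list[Interval] | None = None,
                      step: int | None = None) -> pd.DataFrame:
    """Per-window GC skew and GC fraction over the whole genome.

    Columns: chrom, start, gc_skew (NaN when undefined: window has N or no
    G/C), gc_fraction, has_n, facet_strand, in_rloop. Skew is sense-strand
    (sign flipped on minus-facet windows); gc_fraction is strand-symmetric.
    Facet assignment: the transcript with the largest overlap wins; windows
    overlapping no transcript are intergenic (facet "."). in_rloop is any
    overlap with an R-loop interval.
    """
    if window_size < 2:
        raise PipelineError("window_size must be >= 2")
    step = step or window_size
    frames = []
    for chrom, seq in genome.items():
        starts = np.arange(0, len(seq) - window_size + 1, step, dtype=np.int64)
        if len(starts) == 0:
            continue
        arr = np.frombuffer(seq.encode(), dtype="S1")
        # windows as a (n, window_size) view
        win = arr[starts[:, None] + np.arange(window_size)]
        g = (win == b"G").sum(axis=1)
        c = (win == b"C").sum(axis=1)
        has_n = (win == b"N").any(axis=1)
        gc = g + c
        with np.errstate(divide="ignore", invalid="ignore"):
            skew = np.where(gc > 0, (g - c) / np.maximum(gc, 1), np.nan)
        skew = np.where(has_n, np.nan, skew)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "gc_skew": skew,
            "gc_fraction": gc / window_size, "has_n": has_n,
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "gc_skew", "gc_fraction", "has_n"])

    df["facet_strand"] = _assign_facets(df, window_size, transcripts or [])
    flip = df["facet_strand"] == "-"
    df.loc[flip, "gc_skew"] = -df.loc[flip, "gc_skew"]
    df["in_rloop"] = _overlaps_any(df, window_size, rloops or [])
    return df


def _assign_facets(windows: pd.DataFrame, window_size: int,
                   transcripts: list[Interval]) -> np.ndarray:
    """Transcribing strand per window; largest overlap wins, first wins ties."""
    facet = np.full(len(windows), ".", dtype=object)
    best = np.zeros(len(windows), dtype=np.int64)
    starts = windows["start"].to_numpy()
    chroms = windows["chrom"].to_numpy()
    for tx in transcripts:
        mask = chroms == tx.chrom
        if not mask.any():
            continue
        s = starts[mask]
        ov = np.minimum(s + window_size, tx.end) - np.maximum(s, tx.start)
        ov = np.clip(ov, 0, None)
        better = ov > best[mask]
        idx = np.flatnonzero(mask)[better]
        facet[idx] = tx.strand
        best[idx] = ov[better]
    return facet


def _overlaps_any(windows: pd.DataFrame, window_size: int,
                  intervals: list[Interval]) -> np.ndarray:
    out = np.zeros(len(windows), dtype=bool)
    starts = windows["start"].to_numpy()
    chroms = windows["chrom"].to_numpy()
    for iv in intervals:
        mask = chroms == iv.chrom
        if not mask.any():
            continue
        s = starts[mask]
        out[np.flatnonzero(mask)] |= (s < iv.end) & (iv.start < s + window_size)
    return out


@dataclass
class EnrichmentGrid:
    """Observed-vs-expected window counts binned by (GC skew, GC fraction)."""

    facet_strand: str
    skew_edges: np.ndarray    # bins over [-1, 1]
    gc_edges: np.ndarray      # bins over [0, 1]
    observed: np.ndarray      # (n_skew_bins, n_gc_bins) counts
    expected: np.ndarray
    n_observed_undefined: int = 0
    n_expected_undefined: int = 0

    @property
    def ratio(self) -> np.ndarray:
        """(obs/obs_total) / (exp/exp_total); NaN where the expected cell is empty."""
        obs_t, exp_t = self.observed.sum(), self.expected.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (self.observed / max(obs_t, 1)) / (self.expected / max(exp_t, 1))
        return np.where(self.expected > 0, r, np.nan)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        ratio = self.ratio
        for i in range(len(self.skew_edges) - 1):
            for j in range(len(self.gc_edges) - 1):
                rows.append({
                    "facet_strand": self.facet_strand,
                    "skew_bin_low": self.skew_edges[i],
                    "skew_bin_high": self.skew_edges[i + 1],
                    "gc_bin_low": self.gc_edges[j],
                    "gc_bin_high": self.gc_edges[j + 1],
                    "observed": int(self.observed[i, j]),
                    "expected": int(self.expected[i, j]),
                    "ratio": ratio[i, j],
                })
        return pd.DataFrame(rows)


def _bin_edges(width: float, low: float, high: float) -> np.ndarray:
    n = round((high - low) / width)
    if not math.isclose(n * width, high - low, rel_tol=1e-9):
        raise PipelineError(f"bin width {width} does not evenly divide [{low}, {high}]")
    return np.linspace(low, high, n + 1)


def _bin_2d(skew: np.ndarray, gc: np.ndarray, skew_edges: np.ndarray,
            gc_edges: np.ndarray) -> np.ndarray:
    h, _, _ = np.histogram2d(skew, gc, bins=[skew_edges, gc_edges])
    return h.astype(np.int64)


def build_obs_exp_grid(windows: pd.DataFrame, skew_bin_width: float = 0.1,
                       gc_bin_width: float = 0.05) -> dict[str, EnrichmentGrid]:
    """One enrichment grid per transcribing-strand facet.

    Observed = R-loop windows in the facet; expected = all non-R-loop windows
    genome-wide (intergenic included — "the remainder of the genome"), each
    expressed on its own sense strand. Windows with undefined skew are
    counted separately, never binned.
    """
    skew_edges = _bin_edges(skew_bin_width, -1.0, 1.0)
    gc_edges = _bin_edges(gc_bin_width, 0.0, 1.0)
    defined = windows["gc_skew"].notna().to_numpy()
    exp_mask = ~windows["in_rloop"].to_numpy()
    exp_rows = windows[exp_mask & defined]
    exp_grid = _bin_2d(exp_rows["gc_skew"].to_numpy(), exp_rows["gc_fraction"].to_numpy(),
                       skew_edges, gc_edges)
    n_exp_undef = int((exp_mask & ~defined).sum())

    grids: dict[str, EnrichmentGrid] = {}
    for facet in FACETS:
        obs_mask = windows["in_rloop"].to_numpy() & (windows["facet_strand"] == facet).to_numpy()
        if not obs_mask.any():
            continue
        obs_rows = windows[obs_mask & defined]
        obs = _bin_2d(obs_rows["gc_skew"].to_numpy(),
                      obs_rows["gc_fraction"].to_numpy(), skew_edges, gc_edges)
        grids[facet] = EnrichmentGrid(
            facet, skew_edges, gc_edges, obs, exp_grid,
            n_observed_undefined=int((obs_mask & ~defined).sum()),
            n_expected_undefined=n_exp_undef,
        )
    if not grids:
        raise PipelineError("no R-loop windows in any facet")
    return grids


def site_grid_distribution(sites: pd.DataFrame, windows: pd.DataFrame,
                           window_size: int, skew_bin_width: float = 0.1,
                           gc_bin_width: float = 0.05
                           ) -> tuple[dict[str, np.ndarray], int]:
    """Site counts per (skew, GC) grid cell, faceted by site strand.

    Each site maps to the window containing it; sites in windows with
    undefined skew, or outside every window, go to the excluded count.
    """
    skew_edges = _bin_edges(skew_bin_width, -1.0, 1.0)
    gc_edges = _bin_edges(gc_bin_width, 0.0, 1.0)
    win = windows.set_index(["chrom", "start"])
    counts = {f: np.zeros((len(skew_edges) - 1, len(gc_edges) - 1), dtype=np.int64)
              for f in FACETS}
    excluded = 0
    for rec in sites.itertuples():
        key = (rec.chrom, (rec.pos // window_size) * window_size)
        if key not in win.index:
            excluded += 1
            continue
        row = win.loc[key]
        if pd.isna(row["gc_skew"]):
            excluded += 1
            continue
        skew = float(row["gc_skew"])
        # window skew is sense-strand for the window facet; express on the
        # site's own strand
        if row["facet_strand"] == "-":
            skew = -skew
        if rec.strand == "-":
            skew = -skew
        i = min(int((skew + 1.0) / (skew_edges[1] - skew_edges[0])), len(skew_edges) - 2)
        j = min(int(row["gc_fraction"] / (gc_edges[1] - gc_edges[0])), len(gc_edges) - 2)
        counts[rec.strand][i, j] += 1
    return counts, excluded


@dataclass
class ContextMatrix:
    """Positional base counts around m5C sites, read 5'->3' on the site strand."""

    flank_k: int
    counts: np.ndarray            # shape (4, 2k+1), rows A/C/G/T
    n_sites: int
    n_excluded: int               # N-containing or out-of-bounds windows

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank_k, self.flank_k + 1)

    def frequency(self, base: str) -> np.ndarray:
        i = "ACGT".index(base)
        total = self.counts.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(total > 0, self.counts[i] / np.maximum(total, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        total = self.counts.sum(axis=0)
        df = pd.DataFrame({"offset": self.offsets})
        for b in "ACGT":
            df[f"freq_{b}"] = self.frequency(b)
        df["n"] = total
        return df


def extract_contexts(genome: GenomeSequence, sites: pd.DataFrame,
                     flank_k: int = 10) -> ContextMatrix:
    """Base composition of the ±flank_k window around each site.

    Windows are read on the site's strand (reverse-complemented for minus
    sites) so offset 0 is the methylated C itself; windows containing N or
    running off a chromosome end are excluded and counted.
    """
    if flank_k < 1:
        raise PipelineError("flank_k must be >= 1")
    width = 2 * flank_k + 1
    counts = np.zeros((4, width), dtype=np.int64)
    included = excluded = 0
    idx = {b: i for i, b in enumerate("ACGT")}
    for rec in sites.itertuples():
        seq = genome[rec.chrom]
        lo, hi = rec.pos - flank_k, rec.pos + flank_k + 1
        if lo < 0 or hi > len(seq):
            excluded += 1
            continue
        window = seq[lo:hi]
        if "N" in window:
            excluded += 1
            continue
        if rec.strand == "-":
            window = reverse_complement(window)
        for j, b in enumerate(window):
            counts[idx[b], j] += 1
        included += 1
    return ContextMatrix(flank_k, counts, included, excluded)


def compare_top_bottom_contexts(calls: pd.DataFrame, genome: GenomeSequence,
                                flank_k: int = 10, quantile: float = 0.1
                                ) -> tuple[ContextMatrix, ContextMatrix]:
    """Contexts of the top- vs bottom-methylated called sites on the + strand.

    Ranks by methylation fraction with coverage / coordinate tie-breaks; the
    two subsets are disjoint for quantile <= 0.5.
    """
    if not (0 < quantile <= 0.5):
        raise PipelineError("quantile must be in (0, 0.5]")
    plus = calls[(calls["status"] == "called") & (calls["strand"] == "+")]
    if len(plus) < 2:
        raise PipelineError("need at least 2 called + strand sites")
    top = rank_top_fraction(plus, quantile)
    k = len(top)
    ranked = plus.sort_values(["meth_fraction", "coverage", "chrom", "pos"],
                              ascending=[False, False, True, True], kind="stable")
    bottom = ranked.tail(k)
    return extract_contexts(genome, top, flank_k), extract_contexts(genome, bottom, flank_k)
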