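"""R-loop peak filtering and overlap enrichment.

DRIP-seq peaks that survive RNaseH pre-treatment are artifacts (RNaseH
destroys genuine DNA:RNA hybrids), so untreated peaks sufficiently covered by
RNaseH-condition peaks are removed; the remainder is the RNaseH-sensitive,
high-confidence R-loop set. A site is "in an R-loop" when its position falls
inside one of these peaks (point containment, strand-blind — DRIP peaks are
unstranded). Enrichment of a site class against the unmethylated-C background
is a 2x2 Fisher exact test with a Haldane-corrected odds ratio.

Interval machinery uses merge + binary search (sort-and-sweep); the test
suite keeps an all-pairs brute-force oracle against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Interval, PipelineError


def merge_intervals(intervals: list[Interval]) -> dict[str, np.ndarray]:
    """Union of intervals per chromosome as sorted (starts, ends) arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out: list[list[int]] = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=np.int64).reshape(-1, 2)
    return merged


def _intersection_length(start: int, end: int, merged: np.ndarray) -> int:
    """Total overlap of [start, end) with a merged (disjoint, sorted) span set."""
    if merged.size == 0:
        return 0
    starts, ends = merged[:, 0], merged[:, 1]
    lo = np.searchsorted(ends, start, side="right")
    hi = np.searchsorted(starts, end, side="left")
    if lo >= hi:
        return 0
    s = np.maximum(starts[lo:hi], start)
    e = np.minimum(ends[lo:hi], end)
    return int(np.sum(e - s))


def subtract_rnaseh(peaks_untreated: list[Interval], peaks_rnaseh: list[Interval],
                    removal_overlap_frac: float = 0.5) -> list[Interval]:
    """Remove untreated peaks sufficiently covered by RNaseH-condition peaks.

    A peak is removed iff the summed length of its intersections with the
    RNaseH peak set is >= removal_overlap_frac * its own length. With
    removal_overlap_frac -> 0 (but > 0 overlap) this approaches any-overlap
    removal. Output preserves input order and is a subset of the input, so
    the operation is idempotent.
    """
    if not (0 <= removal_overlap_frac <= 1):
        raise PipelineError("removal_overlap_frac must be in [0, 1]")
    merged = merge_intervals(peaks_rnaseh)
    kept = []
    for peak in peaks_untreated:
        spans = merged.get(peak.chrom, np.empty((0, 2), dtype=np.int64))
        overlap = _intersection_length(peak.start, peak.end, spans)
        if removal_overlap_frac == 0:
            removed = overlap > 0
        else:
            removed = overlap >= removal_overlap_frac * len(peak)
        if not removed:
            kept.append(peak)
    return kept


def annotate_sites_in_peaks(sites: pd.DataFrame, peaks: list[Interval]) -> np.ndarray:
    """Boolean per site: does its position fall inside any peak? Strand ignored."""
    merged = merge_intervals(peaks)
    result = np.zeros(len(sites), dtype=bool)
    pos = sites["pos"].to_numpy(dtype=np.int64)
    chroms = sites["chrom"].to_numpy()
    for chrom, spans in merged.items():
        mask = chroms == chrom
        if not mask.any() or spans.size == 0:
            continue
        p = pos[mask]
        idx = np.searchsorted(spans[:, 0], p, side="right") - 1
        ok = (idx >= 0) & (p < spans[np.clip(idx, 0, None), 1])
        result[mask] = ok
    return result


@dataclass(frozen=True)
class OverlapSummary:
    """2x2 overlap enrichment of one site class vs a background set."""

    class_name: str
    n_class: int
    n_class_in: int
    n_background: int
    n_background_in: int
    odds_ratio: float       # Haldane-corrected when a cell is zero; NaN if undefined
    p_value: float          # two-sided Fisher exact

    @property
    def fraction_class_in(self) -> float:
        return self.n_class_in / self.n_class if self.n_class else float("nan")

    @property
    def fraction_background_in(self) -> float:
        return (self.n_background_in / self.n_background
                if self.n_background else float("nan"))

    @property
    def table(self) -> np.ndarray:
        return np.array([
            [self.n_class_in, self.n_class - self.n_class_in],
            [self.n_background_in, self.n_background - self.n_background_in],
        ])


def overlap_enrichment(class_sites: pd.DataFrame, background_sites: pd.DataFrame,
                       peaks: list[Interval],
                       class_name: str = "class") -> OverlapSummary:
    """Fisher exact enrichment of in-peak fractions, class vs background."""
    if len(class_sites) == 0 or len(background_sites) == 0:
        raise PipelineError("class and background site sets must be non-empty")
    c_in = int(annotate_sites_in_peaks(class_sites, peaks).sum())
    b_in = int(annotate_sites_in_peaks(background_sites, peaks).sum())
    n_c, n_b = len(class_sites), len(background_sites)
    table = np.array([[c_in, n_c - c_in], [b_in, n_b - b_in]])
    if not peaks:
        return OverlapSummary(class_name, n_c, 0, n_b, 0, float("nan"), 1.0)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        t = table + 0.5  # Haldane correction
    else:
        t = table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return OverlapSummary(class_name, n_c, c_in, n_b, b_in, float(odds), float(p))


def overlap_by_class(site_sets: dict[str, pd.DataFrame],
                     background_sites: pd.DataFrame,
                     peaks: list[Interval]) -> pd.DataFrame:
    """One OverlapSummary row per site class against a shared background."""
    rows = []
    for name, sites in site_sets.items():
        if len(sites) == 0:
            continue
        s = overlap_enrichment(sites, background_sites, peaks, class_name=name)
        rows.append({
            "class": s.class_name, "n_total": s.n_class, "n_in_rloop": s.n_class_in,
            "fraction_in_rloop": s.fraction_class_in,
            "background_n": s.n_background, "background_in": s.n_background_in,
            "background_fraction": s.fraction_background_in,
            "odds_ratio": s.odds_ratio, "p_value": s.p_value,
        })
    return pd.DataFrame(rows)
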