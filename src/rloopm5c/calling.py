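"""m5C site calling from bisulfite count tables.

The statistical model: after bisulfite treatment an unmethylated cytosine
reads as T except with a small non-conversion probability eps, estimated from
an unmethylated spike-in RNA. At a genomic site with coverage n and
n_unconverted reads still reading C, the evidence for methylation is the
one-sided exact binomial tail P(X >= n_unconverted | n, eps). P-values are
corrected across all tested sites by Benjamini-Hochberg; a site is *called*
when q < alpha and coverage passes the minimum. Sites below the coverage
minimum are reported as untested rather than dropped, so they remain
available as the unmethylated-C background set.

"Best" sites are the called sites with coverage > 25 reads and methylation
> 10% (strict inequalities, as published).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .core import PipelineError

CALL_COLUMNS = ["chrom", "pos", "strand", "coverage", "n_unconverted",
                "meth_fraction", "p", "q", "status", "best"]


@dataclass(frozen=True)
class NonconversionEstimate:
    """Spike-in non-conversion rate with a 95% Clopper-Pearson interval."""

    rate: float
    ci_low: float
    ci_high: float
    n_unconverted: int
    coverage: int


def estimate_nonconversion(spikein_counts: pd.DataFrame) -> NonconversionEstimate:
    """Pooled non-conversion rate over the spike-in cytosine positions.

    eps = sum(n_unconverted) / sum(coverage); the 95% CI is Clopper-Pearson,
    so a zero numerator still yields an informative upper bound.
    """
    if len(spikein_counts) == 0:
        raise PipelineError("empty spike-in count table")
    u = int(spikein_counts["n_unconverted"].sum())
    n = int(u + spikein_counts["n_converted"].sum())
    if n == 0:
        raise PipelineError("spike-in has zero total coverage")
    lo, hi = proportion_confint(u, n, alpha=0.05, method="beta")
    return NonconversionEstimate(u / n, float(lo), float(hi), u, n)


def call_sites(counts: pd.DataFrame, epsilon: float, alpha: float = 0.05,
               min_call_coverage: int = 10) -> pd.DataFrame:
    """Call methylated sites in one condition against the non-conversion rate.

    Returns one row per input site with p, BH q, status in
    {called, not_called, untested} and an (initially unset) best flag.
    """
    if not (0 <= epsilon < 0.5):
        raise PipelineError(f"epsilon must be in [0, 0.5), got {epsilon}")
    if (counts["n_unconverted"] < 0).any() or (counts["n_converted"] < 0).any():
        raise PipelineError("negative counts")

    out = counts[["chrom", "pos", "strand"]].copy()
    u = counts["n_unconverted"].to_numpy(dtype=np.int64)
    n = u + counts["n_converted"].to_numpy(dtype=np.int64)
    out["coverage"] = n
    out["n_unconverted"] = u
    with np.errstate(invalid="ignore"):
        out["meth_fraction"] = np.where(n > 0, u / np.maximum(n, 1), 0.0)

    # one-sided exact tail P(X >= u); sf(u - 1) handles u = 0 -> p = 1
    p = stats.binom.sf(u - 1, n, epsilon)
    p = np.where(n > 0, p, 1.0)
    out["p"] = p

    tested = n >= min_call_coverage
    q = np.full(len(out), np.nan)
    if tested.sum() > 0:
        _, q_tested, _, _ = multipletests(p[tested], alpha=alpha, method="fdr_bh")
        q[tested] = q_tested
    out["q"] = q

    status = np.where(~tested, "untested",
                      np.where(q < alpha, "called", "not_called"))
    out["status"] = status
    out["best"] = False
    return out


def flag_best(calls: pd.DataFrame, min_coverage: int = 25,
              min_meth: float = 0.10) -> pd.DataFrame:
    """Set the best flag: called AND coverage > 25 AND methylation > 10%.

    Both thresholds are strict, exactly as published (coverage 25 or
    methylation 0.10 do not qualify).
    """
    calls = calls.copy()
    calls["best"] = ((calls["status"] == "called")
                     & (calls["coverage"] > min_coverage)
                     & (calls["meth_fraction"] > min_meth))
    return calls


def rank_top_fraction(calls: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """The ceil(fraction * N) called sites with highest methylation.

    Ties break by higher coverage, then by (chrom, pos) lexicographic order.
    """
    if not (0 < fraction <= 1):
        raise PipelineError(f"fraction must be in (0, 1], got {fraction}")
    called = calls[calls["status"] == "called"]
    if len(called) == 0:
        raise PipelineError("no called sites to rank")
    k = math.ceil(fraction * len(called))
    ranked = called.sort_values(
        ["meth_fraction", "coverage", "chrom", "pos"],
        ascending=[False, False, True, True], kind="stable",
    )
    return ranked.head(k)


def unmethylated_background(calls_by_condition: dict[str, pd.DataFrame],
                            epsilon: float, min_coverage: int = 25,
                            meth_factor: float = 2.0) -> pd.DataFrame:
    """The unmethylated-C background set for enrichment comparisons.

    A site qualifies when, in every condition, it has coverage > min_coverage,
    meth_fraction <= meth_factor * epsilon, and is not called anywhere.
    """
    if not calls_by_condition:
        raise PipelineError("no call tables supplied")
    keys = ["chrom", "pos", "strand"]
    verdicts = []
    for calls in calls_by_condition.values():
        ok = ((calls["coverage"] > min_coverage)
              & (calls["meth_fraction"] <= meth_factor * epsilon)
              & (calls["status"] != "called"))
        verdicts.append(calls[keys].assign(ok=ok.to_numpy()))
    merged = verdicts[0]
    for v in verdicts[1:]:
        merged = merged.merge(v, on=keys, how="inner", suffixes=("", "_r"))
        merged["ok"] = merged["ok"] & merged.pop("ok_r")
    return merged[merged["ok"]][keys].reset_index(drop=True)
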