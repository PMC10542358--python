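"""TRDMT1-dependence and damage-induction classification.

A called site is TRDMT1-dependent when its WT methylation exceeds the KO
methylation by at least a configurable fold (default two-fold, the published
rule), computed on pseudocount-adjusted fractions so a methylation-free KO
sample yields a finite fold:

    fold = ((u_wt + c) / (n_wt + 2c)) / ((u_ko + c) / (n_ko + 2c))

with c reads of pseudocount (default 0.5). Dependence is assessed within the
matching damage condition; damage induction uses the same fold rule on
+damage vs -damage counts within one genotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PipelineError

SITE_KEYS = ["chrom", "pos", "strand"]

LABEL_DEPENDENT = "TRDMT1-dependent"
LABEL_INDEPENDENT = "TRDMT1-independent"
LABEL_UNCLASSIFIABLE = "unclassifiable"
LABEL_KO_ONLY = "independent-KO-only"  # called in KO but not WT; audit only


def _adjusted_fraction(u: np.ndarray, n: np.ndarray, c: float) -> np.ndarray:
    return (u + c) / (n + 2 * c)


def pseudocount_fold(u_num: np.ndarray, n_num: np.ndarray,
                     u_den: np.ndarray, n_den: np.ndarray,
                     pseudocount: float) -> np.ndarray:
    """Ratio of pseudocount-adjusted methylation fractions (numerator/denominator)."""
    return (_adjusted_fraction(u_num, n_num, pseudocount)
            / _adjusted_fraction(u_den, n_den, pseudocount))


def classify_dependence(wt_calls: pd.DataFrame, ko_calls: pd.DataFrame,
                        fold_threshold: float = 2.0,
                        pseudocount_reads: float = 0.5) -> pd.DataFrame:
    """Label every WT-called site as dependent / independent / unclassifiable.

    Input call tables must come from the same damage condition. A site called
    in WT but with zero KO coverage (or absent from the KO table) is
    unclassifiable. Sites not called in WT are not classified.
    """
    if fold_threshold <= 1:
        raise PipelineError("fold_threshold must be > 1")
    wt = wt_calls[wt_calls["status"] == "called"]
    merged = wt.merge(ko_calls[SITE_KEYS + ["coverage", "n_unconverted",
                                            "meth_fraction"]],
                      on=SITE_KEYS, how="left", suffixes=("_wt", "_ko"))

    u_wt = merged["n_unconverted_wt"].to_numpy(float)
    n_wt = merged["coverage_wt"].to_numpy(float)
    u_ko = merged["n_unconverted_ko"].to_numpy()
    n_ko = merged["coverage_ko"].to_numpy()
    missing = pd.isna(n_ko) | (np.nan_to_num(n_ko, nan=0.0) == 0)

    u_ko = np.nan_to_num(np.asarray(u_ko, dtype=float), nan=0.0)
    n_ko = np.nan_to_num(np.asarray(n_ko, dtype=float), nan=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = pseudocount_fold(u_wt, n_wt, u_ko, n_ko, pseudocount_reads)

    label = np.where(missing, LABEL_UNCLASSIFIABLE,
                     np.where(fold >= fold_threshold, LABEL_DEPENDENT,
                              LABEL_INDEPENDENT))
    out = merged[SITE_KEYS].copy()
    out["wt_meth"] = merged["meth_fraction_wt"].to_numpy()
    out["ko_meth"] = np.where(missing, np.nan, merged["meth_fraction_ko"].to_numpy(float))
    out["wt_coverage"] = n_wt.astype(int)
    out["ko_coverage"] = n_ko.astype(int)
    out["fold"] = np.where(missing, np.nan, fold)
    out["label"] = label
    out["best"] = merged["best"].to_numpy() if "best" in merged else False
    return out


def ko_only_sites(wt_calls: pd.DataFrame, ko_calls: pd.DataFrame) -> pd.DataFrame:
    """Sites called in KO but not in WT, labeled for audit.

    These fall outside the dependent/independent dichotomy and are excluded
    from class summaries by default.
    """
    ko = ko_calls[ko_calls["status"] == "called"]
    wt_called = wt_calls[wt_calls["status"] == "called"][SITE_KEYS]
    merged = ko.merge(wt_called.assign(_wt=True), on=SITE_KEYS, how="left")
    out = merged[merged["_wt"].isna()][SITE_KEYS + ["meth_fraction", "coverage"]].copy()
    out["label"] = LABEL_KO_ONLY
    return out.reset_index(drop=True)


def classify_damage_induction(calls_nodmg: pd.DataFrame, calls_dmg: pd.DataFrame,
                              fold_threshold: float = 2.0,
                              pseudocount_reads: float = 0.5) -> pd.DataFrame:
    """Flag damage-induced sites within one genotype (+damage vs -damage).

    Uses the same pseudocount fold rule; sites with zero -damage coverage get
    fold NaN and damage_induced left unset (pd.NA).
    """
    dmg = calls_dmg[calls_dmg["status"] == "called"]
    merged = dmg.merge(calls_nodmg[SITE_KEYS + ["coverage", "n_unconverted"]],
                       on=SITE_KEYS, how="left", suffixes=("_dmg", "_nodmg"))
    u_d = merged["n_unconverted_dmg"].to_numpy(float)
    n_d = merged["coverage_dmg"].to_numpy(float)
    u_0 = np.nan_to_num(merged["n_unconverted_nodmg"].to_numpy(float), nan=0.0)
    n_0raw = merged["coverage_nodmg"].to_numpy()
    missing = pd.isna(n_0raw) | (np.nan_to_num(np.asarray(n_0raw, float), nan=0.0) == 0)
    n_0 = np.nan_to_num(np.asarray(n_0raw, dtype=float), nan=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = pseudocount_fold(u_d, n_d, u_0, n_0, pseudocount_reads)
    out = merged[SITE_KEYS].copy()
    out["fold_damage"] = np.where(missing, np.nan, fold)
    out["damage_induced"] = pd.array(
        np.where(missing, None, fold >= fold_threshold), dtype="boolean")
    return out


def summarize_site_classes(dependence_calls: pd.DataFrame,
                           condition: str | None = None) -> pd.DataFrame:
    """Count dependent / independent / unclassifiable sites (one row per label).

    Counts always sum to the number of classified input sites.
    """
    labels = [LABEL_DEPENDENT, LABEL_INDEPENDENT, LABEL_UNCLASSIFIABLE]
    counts = dependence_calls["label"].value_counts() if len(dependence_calls) else {}
    rows = [{"label": lab, "n_sites": int(counts.get(lab, 0))} for lab in labels]
    df = pd.DataFrame(rows)
    if condition is not None:
        df.insert(0, "condition", condition)
    return df
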