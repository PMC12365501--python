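"""Benchmark metrics for spike-in evaluations.

Given a result table and the ground truth of a spike-in design, these
functions count true/false positives at an FDR threshold, trace the
TPR-FDP curve along the p-value ranking, summarize log2FC estimation
error per truth class, and check null p-value uniformity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NoPositivesError, UnknownProteinError
from .simulate import GroundTruth


@dataclass(frozen=True)
class BenchmarkCounts:
    """Confusion counts at a fixed threshold."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be nonnegative")


def tpr(counts: BenchmarkCounts) -> float:
    """True positive rate TP / (TP + FN)."""
    denom = counts.TP + counts.FN
    if denom == 0:
        raise NoPositivesError("TPR undefined without truth positives")
    return counts.TP / denom


def fdp(counts: BenchmarkCounts) -> float:
    """False discovery proportion FP / (TP + FP); zero when nothing is
    called."""
    denom = counts.TP + counts.FP
    if denom == 0:
        return 0.0
    return counts.FP / denom


def _truth_map(results: pd.DataFrame, truth: GroundTruth) -> pd.Series:
    known = set(truth.table.index)
    missing = set(results["protein"]) - known
    if missing:
        raise UnknownProteinError(
            f"result protein(s) absent from truth: {sorted(missing)[:5]}"
        )
    return truth.is_da()


def counts_at_fdr(results: pd.DataFrame, truth: GroundTruth,
                  level: float = 0.05) -> BenchmarkCounts:
    """Confusion counts calling proteins with BH-adjusted p <= level.

    Proteins whose fit failed (or whose contrast was not estimable) are
    never called: they count as negatives.
    """
    is_da = _truth_map(results, truth)
    da = results["protein"].map(is_da).to_numpy(bool)
    fitted = results["status"].isin(["ok", "reduced"]).to_numpy()
    called = fitted & (results["adj_pvalue"].to_numpy(float) <= level)
    tp = int((called & da).sum())
    fp = int((called & ~da).sum())
    fn = int((~called & da).sum())
    tn = int((~called & ~da).sum())
    return BenchmarkCounts(TP=tp, FP=fp, FN=fn, TN=tn)


@dataclass(frozen=True)
class TprFdpCurve:
    """TPR-FDP operating curve along the p-value ranking."""

    points: pd.DataFrame        # columns: threshold, TPR, FDP
    at_fdr: BenchmarkCounts     # counts at the marked FDR cutoff
    fdr_mark: float


def tpr_fdp_curve(results: pd.DataFrame, truth: GroundTruth,
                  fdr_mark: float = 0.05) -> TprFdpCurve:
    """Cumulative TPR and FDP walking down the ranked protein list.

    Proteins are ranked by p ascending, ties broken by |t| descending and
    then protein id, so repeated runs give identical curves.  The marked
    point uses BH-adjusted p <= ``fdr_mark``.
    """
    is_da = _truth_map(results, truth)
    sub = results[results["status"].isin(["ok", "reduced"])].copy()
    sub["abst"] = sub["t"].abs()
    sub = sub.sort_values(["pvalue", "abst", "protein"],
                          ascending=[True, False, True], kind="mergesort")
    da = sub["protein"].map(is_da).to_numpy(bool)
    n_pos = int(results["protein"].map(is_da).sum())
    cum_tp = np.cumsum(da)
    cum_fp = np.cumsum(~da)
    with np.errstate(invalid="ignore"):
        curve = pd.DataFrame({
            "threshold": sub["pvalue"].to_numpy(float),
            "TPR": cum_tp / n_pos if n_pos else np.nan,
            "FDP": cum_fp / np.maximum(cum_tp + cum_fp, 1),
        })
    return TprFdpCurve(points=curve.reset_index(drop=True),
                       at_fdr=counts_at_fdr(results, truth, fdr_mark),
                       fdr_mark=fdr_mark)


def logfc_error_summary(results: pd.DataFrame, truth: GroundTruth
                        ) -> pd.DataFrame:
    """Bias / SD / median of log2FC estimates per truth class.

    Classes are the distinct true log2FC values per contrast, with the
    background (truth zero) labelled ``null``.
    """
    rows = []
    for contrast, grp in results.groupby("contrast", sort=True):
        ok = grp[grp["status"].isin(["ok", "reduced"])]
        true_fc = truth.log2fc(contrast).reindex(ok["protein"]).to_numpy()
        est = ok["logFC"].to_numpy(float)
        is_da = truth.is_da().reindex(ok["protein"]).to_numpy(bool)
        classes = np.where(is_da, true_fc, np.nan)
        for cls in [np.nan] + sorted(set(classes[~np.isnan(classes)])):
            sel = np.isnan(classes) if np.isnan(cls) else classes == cls
            if not sel.any():
                continue
            err = est[sel] - (0.0 if np.isnan(cls) else cls)
            rows.append({
                "contrast": contrast,
                "class": "null" if np.isnan(cls) else f"fc={cls:g}",
                "true_log2fc": 0.0 if np.isnan(cls) else cls,
                "n": int(sel.sum()),
                "bias": float(np.mean(err)),
                "sd": float(np.std(err, ddof=1)) if sel.sum() > 1 else 0.0,
                "median": float(np.median(est[sel])),
            })
    return pd.DataFrame(rows)


def pvalue_uniformity(pvalues, n_bins: int = 20, spike_tol: float = 1e-3):
    """KS distance from uniform plus a fixed-width histogram.

    The mass at (numerically) one is reported separately: ridge shrinkage
    of null log2FCs drives their t statistics to ~0 and piles p-values
    onto 1, a spike a histogram bin would smear.  ``spike_tol`` counts
    p >= 1 - spike_tol as sitting on the spike (shrunken-to-zero effects
    give p within rounding of 1, not exactly 1).
    """
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    ks = float(stats.kstest(p, "uniform").statistic)
    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    spike = float(np.mean(p >= 1.0 - spike_tol))
    return {"ks": ks, "hist_counts": counts, "hist_edges": edges,
            "spike_mass_at_one": spike, "n": int(p.size)}
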