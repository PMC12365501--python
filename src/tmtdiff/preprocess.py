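"""PSM-level transformations and filters applied before summarization.

The default pipeline is deliberately minimal: log2 transform, channel
median centering, and the spike-in study filters (minimum observed values,
duplicate-spectrum resolution, ambiguous shared-intensity exclusion).
Imputation is absent by default; a hook accepts a user function so custom
imputation can be injected.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assay import FeatureAssay, SampleAnnotation, validate_link
from .errors import (
    EmptyColumnError,
    NonPositiveIntensityError,
    NoReferenceInRunError,
    NoStableBackgroundError,
)


@dataclass
class FilterReport:
    """Accounting of one filtering rule."""

    rule: str
    features_before: int
    features_removed: int
    notes: dict = field(default_factory=dict)

    @property
    def features_after(self) -> int:
        return self.features_before - self.features_removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"rule": self.rule, "features_before": self.features_before,
              "features_removed": self.features_removed,
              "features_after": self.features_after}]
        )


def combine_reports(reports) -> pd.DataFrame:
    """Stack chained filter reports; removed counts sum to before - after."""
    return pd.concat([r.to_frame() for r in reports], ignore_index=True)


def log2_transform(assay: FeatureAssay) -> FeatureAssay:
    """Elementwise log2 of the observed intensities."""
    if assay.log2:
        raise ValueError("assay is already on log2 scale")
    vals = assay.values
    if (vals <= 0).any().any():
        bad = vals.stack()
        bad = bad[bad <= 0]
        raise NonPositiveIntensityError(
            f"non-positive intensity {bad.iloc[0]} at {bad.index[0]}"
        )
    out = np.log2(vals)
    return replace(assay, values=out, log2=True,
                   history=assay.history + ("log2_transform",))


def normalize_channel_median(assay: FeatureAssay,
                             scope: str = "per_run") -> FeatureAssay:
    """Center each channel by subtracting its median log2 intensity.

    ``per_run`` (default) centers every sample column by the median of its
    own observed values, so each column's observed median is exactly zero
    afterwards.  ``global`` pools the columns carrying the same channel
    label across runs and subtracts their common median, preserving
    channel-level offsets within runs.
    """
    if not assay.log2:
        raise ValueError("channel-median normalization expects log2 data")
    vals = assay.values
    empty = vals.notna().sum(axis=0) == 0
    if empty.any():
        raise EmptyColumnError(
            f"channel {vals.columns[empty][0]!r} has no observed values"
        )
    if scope == "per_run":
        med = vals.median(axis=0, skipna=True)
        out = vals - med
    elif scope == "global":
        channel_of = {s: str(s).split(":", 1)[1] for s in vals.columns}
        med = {}
        for ch in set(channel_of.values()):
            cols = [s for s in vals.columns if channel_of[s] == ch]
            med.update({c: np.nanmedian(vals[cols].to_numpy()) for c in cols})
        out = vals - pd.Series(med)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return assay.with_values(out, f"normalize_channel_median[{scope}]")


def normalize_reference(
    assay: FeatureAssay,
    ann: SampleAnnotation,
    drop_reference: bool = False,
) -> FeatureAssay:
    """Normalize each run against its reference channel(s), per feature.

    Within every run, the per-feature median across that run's reference
    columns is subtracted from all of the run's columns.  With a single
    reference channel this turns it into an all-zero column.
    """
    if not assay.log2:
        raise ValueError("reference normalization expects log2 data")
    validate_link(assay, ann)
    t = ann.table
    vals = assay.values.copy()
    runs = t.loc[assay.sample_ids, "run"]
    for run, cols in runs.groupby(runs).groups.items():
        cols = list(cols)
        refs = [s for s in cols if t.loc[s, "is_reference"]]
        if not refs:
            raise NoReferenceInRunError(f"run {run!r} has no reference channel")
        ref_profile = vals[refs].median(axis=1, skipna=True)
        vals[cols] = vals[cols].sub(ref_profile, axis=0)
    out = assay.with_values(vals, "normalize_reference")
    if drop_reference:
        keep = [s for s in out.sample_ids
                if not t.loc[s, "is_reference"]]
        out = out.subset_samples(keep, "drop_reference_after_normalize")
    return out


def filter_min_observed(assay: FeatureAssay, min_obs: int):
    """Drop features observed in fewer than ``min_obs`` samples.

    The spike-in convention is ``min_obs=6`` on a 10-plex: PSMs with fewer
    than six out of ten intensity values are removed.
    """
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    nobs = assay.values.notna().sum(axis=1)
    keep = nobs[nobs >= min_obs].index
    report = FilterReport("filter_min_observed", assay.n_features,
                          assay.n_features - len(keep),
                          {"min_obs": min_obs})
    return assay.subset_features(keep, "filter_min_observed"), report


def resolve_duplicate_psms(assay: FeatureAssay):
    """Keep one spectrum per (run, peptide): the one with maximal summed
    intensity over its observed values."""
    if assay.level != "psm":
        raise ValueError("duplicate-PSM resolution applies to PSM level")
    meta = assay.feature_meta
    sums = assay.values.sum(axis=1, skipna=True)
    keep = []
    for _, grp in meta.groupby(["run", "peptide_id"], sort=False):
        if len(grp) == 1:
            keep.append(grp.index[0])
        else:
            s = sums.loc[grp.index]
            # deterministic: ties broken by feature_id order
            keep.append(s.sort_index().idxmax())
    report = FilterReport("resolve_duplicate_psms", assay.n_features,
                          assay.n_features - len(keep))
    return assay.subset_features(keep, "resolve_duplicate_psms"), report


def remove_shared_intensity_spectra(assay: FeatureAssay):
    """Exclude groups of spectra with identical intensity vectors but
    conflicting protein assignments.

    Identical reporter vectors (missing pattern included) within a run that
    map to different proteins indicate an ambiguous spectrum matched in
    multiple search spaces; all members of such a group are removed.
    """
    if assay.level != "psm":
        raise ValueError("shared-intensity exclusion applies to PSM level")
    meta = assay.feature_meta
    vals = assay.values
    drop = set()
    for _, grp in meta.groupby("run", sort=False):
        if len(grp) < 2:
            continue
        sub = vals.loc[grp.index]
        # hashable signature per row: values with NaN encoded distinctly
        arr = sub.to_numpy()
        sig = [tuple(-np.inf if math.isnan(v) else v for v in row)
               for row in arr]
        buckets: dict = {}
        for fid, s in zip(sub.index, sig):
            buckets.setdefault(s, []).append(fid)
        for fids in buckets.values():
            if len(fids) < 2:
                continue
            prots = set(meta.loc[fids, "protein_id"])
            if len(prots) > 1:
                drop.update(fids)
    keep = [f for f in assay.feature_ids if f not in drop]
    report = FilterReport("remove_shared_intensity_spectra", assay.n_features,
                          len(drop))
    return assay.subset_features(keep, "remove_shared_intensity_spectra"), report


def _pairwise_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation on pairwise-complete observations.

    Fewer than 3 complete pairs, or zero variance on either side, yields 0:
    the correlation is a removal criterion and insufficient evidence should
    not remove.
    """
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return 0.0
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(xs, ys)[0, 1])


def multibatch_custom_normalize(
    assay: FeatureAssay,
    ann: SampleAnnotation,
    background_ids: set,
    profile: pd.Series,
    corr_threshold: float = 0.25,
    snr: pd.Series | None = None,
    snr_threshold: float = 20.0,
    stable_fraction: float = 0.5,
):
    """Bespoke normalization for spike-in designs where most proteins are DA.

    Three steps: (1) background PSMs whose Pearson correlation with the
    spike-in dilution profile exceeds ``corr_threshold`` are removed;
    (2) PSMs with summed signal-to-noise below ``snr_threshold`` are
    removed; (3) per run, every sample is divided by the geometric mean
    (log-scale mean) of the ``stable_fraction`` of background PSMs with the
    smallest cross-sample standard deviation in that run.

    Only usable when the non-DA background is known, as in benchmark
    spike-in studies.
    """
    if not background_ids:
        raise ValueError("background_ids must be nonempty")
    profile = profile.reindex(assay.sample_ids).astype(float)
    meta = assay.feature_meta
    vals = assay.values
    n0 = assay.n_features
    is_bg = meta["protein_id"].isin(set(background_ids))

    # step 1: drop correlated background features
    pvec = profile.to_numpy()
    drop_corr = [
        fid for fid in meta.index[is_bg]
        if _pairwise_pearson(vals.loc[fid].to_numpy(), pvec) > corr_threshold
    ]
    assay1 = assay.subset_features(
        [f for f in assay.feature_ids if f not in set(drop_corr)],
        "multibatch_corr_filter",
    )

    # step 2: signal-to-noise filter
    if snr is not None:
        snr = snr.reindex(assay1.feature_ids)
        low = snr < snr_threshold
        keep = [f for f, bad in zip(assay1.feature_ids, low) if not bad]
    else:
        keep = assay1.feature_ids
    assay2 = assay1.subset_features(keep, "multibatch_snr_filter")

    # step 3: stable-background geometric-mean normalization, per run
    meta2 = assay2.feature_meta
    on_log = assay2.log2
    logvals = assay2.values if on_log else np.log2(assay2.values)
    is_bg2 = meta2["protein_id"].isin(set(background_ids))
    run_of = {s: ann.table.loc[s, "run"] for s in assay2.sample_ids}
    out = assay2.values.copy()
    for run in sorted(set(run_of.values()), key=str):
        cols = [s for s in assay2.sample_ids if run_of[s] == run]
        sub = logvals.loc[:, cols]
        present = is_bg2 & (sub.notna().sum(axis=1) > 0)
        bg_ids = list(meta2.index[present])
        if not bg_ids:
            raise NoStableBackgroundError(
                f"no background feature survives in run {run!r}"
            )
        sd = sub.loc[bg_ids].std(axis=1, ddof=1).fillna(np.inf)
        n_stable = max(1, math.ceil(stable_fraction * len(bg_ids)))
        # smallest SD first; ties broken by feature_id for determinism
        order = sd.to_frame("sd").assign(fid=sd.index.astype(str)) \
                  .sort_values(["sd", "fid"], kind="mergesort")
        stable = list(order.index[:n_stable])
        shift = sub.loc[stable].mean(axis=0, skipna=True)
        if on_log:
            out[cols] = out[cols].sub(shift, axis=1)
        else:
            out[cols] = out[cols].div(np.exp2(shift), axis=1)
    normalized = assay2.with_values(out, "multibatch_stable_normalize")
    report = FilterReport(
        "multibatch_custom_normalize", n0, n0 - normalized.n_features,
        {"corr_removed": len(drop_corr),
         "snr_removed": assay1.n_features - assay2.n_features},
    )
    return normalized, report


def apply_imputation(assay: FeatureAssay, impute_fn) -> FeatureAssay:
    """Injection point for user-supplied imputation (assay -> assay).

    The default workflows never impute; robust modeling makes the
    missing-at-random assumption workable without it.
    """
    out = impute_fn(assay)
    return out.with_values(out.values, "apply_imputation")
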