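"""Aggregate PSM-level features into protein-level abundance profiles.

Two summarizers are provided: Tukey median polish applied per protein
within each run (or within each mixture, stacking technical-repeat runs as
extra rows), and the one-step median sweep with median aggregation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .assay import (
    FeatureAssay,
    SampleAnnotation,
    make_sample_id,
    protein_assay_from_profiles,
    validate_link,
)
from .polish import median_polish


def collapse_annotation_per_mixture(ann: SampleAnnotation,
                                    sample_ids) -> SampleAnnotation:
    """Annotation for mixture-level samples (one per mixture x channel).

    Technical-repeat runs of a mixture measure the same biological samples,
    so design variables must agree across them; the collapsed row keeps the
    shared values and uses the mixture as the run identifier.
    """
    t = ann.table.loc[list(sample_ids)]
    rows = []
    drop = {"tech_rep"}
    for (mixture, channel), grp in t.groupby(["mixture", "channel"],
                                             sort=False, observed=True):
        row = {}
        for col in t.columns:
            if col in drop:
                continue
            vals = grp[col].unique()
            if col != "run" and len(vals) > 1:
                raise ValueError(
                    f"column {col!r} differs across technical repeats of "
                    f"mixture {mixture!r} channel {channel!r}"
                )
            row[col] = vals[0]
        row["run"] = mixture
        row["mixture"] = mixture
        row["channel"] = channel
        rows.append((make_sample_id(mixture, channel), row))
    frame = pd.DataFrame([r for _, r in rows],
                         index=pd.Index([i for i, _ in rows],
                                        name="sample_id"))
    return SampleAnnotation(frame)


def summarize_protein(
    assay: FeatureAssay,
    ann: SampleAnnotation,
    scope: str = "per_run",
    tol: float = 1e-6,
    max_iter: int = 100,
):
    """Median-polish each protein's PSM submatrix into a channel profile.

    With ``scope="per_run"`` the polish runs on each protein x run block
    and yields one abundance per (protein, run, channel); the returned
    annotation is the input one.  With ``scope="per_mixture"`` all runs of
    a mixture are stacked as extra PSM rows over the shared channels,
    yielding one abundance per (protein, mixture, channel) and a collapsed
    annotation.  The protein abundance for a column is
    ``overall + column_effect``; columns without any observed PSM stay
    missing.  Proteins entirely missing in a group are simply absent there;
    no data ever crosses group boundaries.

    Returns ``(protein_assay, annotation_for_its_samples)``.
    """
    if not assay.log2:
        raise ValueError("summarization expects log2 data")
    if assay.level != "psm":
        raise ValueError("summarization expects a PSM-level assay")
    validate_link(assay, ann)
    meta = assay.feature_meta
    V = assay.values.to_numpy()
    sample_ids = list(assay.sample_ids)
    run_of_col = ann.table.loc[sample_ids, "run"].to_numpy()

    if scope == "per_run":
        out_samples = sample_ids
        out_ann = ann
        groups = {}
        for j, r in enumerate(run_of_col):
            groups.setdefault(r, []).append(j)
        # within a run, the block columns are the run's samples themselves
        out_col_of = {g: (cols, list(range(len(cols))), np.array(cols))
                      for g, cols in
                      ((g, groups[g]) for g in groups)}
    elif scope == "per_mixture":
        mix_of_col = ann.table.loc[sample_ids, "mixture"].to_numpy()
        chan_of_col = ann.table.loc[sample_ids, "channel"].to_numpy()
        out_ann = collapse_annotation_per_mixture(ann, sample_ids)
        out_samples = out_ann.sample_ids
        out_pos = {s: k for k, s in enumerate(out_samples)}
        groups = {}
        for j, m in enumerate(mix_of_col):
            groups.setdefault(m, []).append(j)
        out_col_of = {}
        for g, cols in groups.items():
            chans = list(dict.fromkeys(chan_of_col[j] for j in cols))
            chan_pos = {c: k for k, c in enumerate(chans)}
            block_pos = [chan_pos[chan_of_col[j]] for j in cols]
            out_idx = np.array([out_pos[make_sample_id(g, c)] for c in chans])
            out_col_of[g] = (cols, block_pos, out_idx)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    run_of_feat = meta["run"].to_numpy()
    runs_of_group = {
        g: set(run_of_col[j] for j in cols)
        for g, (cols, _, _) in out_col_of.items()
    }
    prot_codes, prot_labels = pd.factorize(meta["protein_id"], sort=True)
    feat_rows_of = {p: np.flatnonzero(prot_codes == k)
                    for k, p in enumerate(prot_labels)}

    n_out = len(out_samples)
    profiles = np.full((len(prot_labels), n_out), np.nan)
    out_pos_all = {s: k for k, s in enumerate(out_samples)}
    parent_link: dict = {}
    fids = np.asarray(meta.index)
    for k, protein in enumerate(prot_labels):
        rows_p = feat_rows_of[protein]
        parent_link[protein] = frozenset(fids[rows_p])
        for g, (cols, block_pos, out_idx) in out_col_of.items():
            rows = rows_p[np.isin(run_of_feat[rows_p],
                                  list(runs_of_group[g]))]
            if rows.size == 0:
                continue
            if scope == "per_run":
                block = V[np.ix_(rows, cols)]
                out_idx_g = np.array([out_pos_all[sample_ids[j]] for j in cols])
            else:
                width = int(max(block_pos)) + 1
                block = np.full((rows.size, width), np.nan)
                sub = V[np.ix_(rows, cols)]
                for jj, bp in enumerate(block_pos):
                    col_vals = sub[:, jj]
                    have = ~np.isnan(col_vals)
                    block[have, bp] = col_vals[have]
                out_idx_g = out_idx
            if np.isnan(block).all():
                continue
            fit = median_polish(block, tol=tol, max_iter=max_iter)
            profile = fit.overall + fit.col_effects
            observed_col = ~np.isnan(block).all(axis=0)
            profiles[k, out_idx_g[observed_col]] = profile[observed_col]

    frame = pd.DataFrame(profiles,
                         index=pd.Index(prot_labels, name="feature_id"),
                         columns=out_samples)
    keep = frame.notna().any(axis=1)
    frame = frame.loc[keep]
    parent_link = {p: parent_link[p] for p in frame.index}
    out = protein_assay_from_profiles(
        frame, parent_link=parent_link,
        history=assay.history + (f"summarize_protein[{scope}]",),
    )
    return out, out_ann


def median_sweep_summarize(
    assay: FeatureAssay,
    ann: SampleAnnotation,
    normalize_proteins: bool = True,
):
    """One-step median sweep followed by per-channel median aggregation.

    Each PSM row is centered by subtracting its own median (a one-step
    polish removing the spectrum-specific effect); per protein and channel,
    the centered values are aggregated by their median.  Optionally the
    protein summaries are column-median normalized; the multibatch variant
    switches this off because the data were already custom-normalized.
    """
    if not assay.log2:
        raise ValueError("summarization expects log2 data")
    if assay.level != "psm":
        raise ValueError("summarization expects a PSM-level assay")
    validate_link(assay, ann)
    vals = assay.values
    centered = vals.sub(vals.median(axis=1, skipna=True), axis=0)
    proteins = assay.feature_meta["protein_id"]
    profiles = centered.groupby(proteins, observed=True).median()
    profiles.index.name = "feature_id"
    profiles = profiles.sort_index()
    if normalize_proteins:
        profiles = profiles - profiles.median(axis=0, skipna=True)
    parent_link = {
        p: frozenset(idx)
        for p, idx in proteins.groupby(proteins, observed=True).groups.items()
    }
    out = protein_assay_from_profiles(
        profiles, parent_link=parent_link,
        history=assay.history + ("median_sweep_summarize",),
    )
    return out, ann
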