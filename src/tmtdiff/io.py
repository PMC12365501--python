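"""Readers and writers for PSM tables, sample annotations and result tables.

All files are plain text (TSV/CSV, UTF-8).  The delimiter is auto-detected
from the extension (``.tsv`` -> tab, anything else -> comma) and can be
overridden.  Missing values serialize as ``NA``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .assay import FeatureAssay, SampleAnnotation, make_sample_id
from .errors import (
    DuplicateCellError,
    MissingColumnError,
    MissingRequiredError,
    NonNumericIntensityError,
)

#: default column names of the long PSM layout
LONG_COLUMNS = {
    "protein": "Protein",
    "peptide": "Peptide",
    "spectrum": "Spectrum",
    "run": "Run",
    "channel": "Channel",
    "intensity": "Intensity",
}

RESULT_COLUMNS = [
    "protein", "contrast", "logFC", "se", "t", "df", "pvalue", "adj_pvalue",
    "status",
]


def _sep_for(path, sep=None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith(".tsv") else ","


def _read_table(path, sep=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path, sep), dtype=str,
                       keep_default_na=False, na_values=["NA", ""])


def _require(df: pd.DataFrame, names) -> None:
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise MissingColumnError(f"missing column(s): {missing}")


def _to_float(series: pd.Series, what: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        raise NonNumericIntensityError(
            f"non-numeric {what} value {series[bad].iloc[0]!r}"
        )
    return out


def _feature_ids(meta: pd.DataFrame) -> pd.Index:
    """Spectrum id when unique across runs, otherwise run-qualified."""
    if meta["spectrum_id"].is_unique:
        return pd.Index(meta["spectrum_id"], name="feature_id")
    return pd.Index(
        meta["run"].astype(str) + ":" + meta["spectrum_id"].astype(str),
        name="feature_id",
    )


def read_psm_table(
    path,
    layout: str = "long",
    column_map: dict | None = None,
    zero_is_missing: bool = True,
    channel_prefix: str = "channel.",
    sep: str | None = None,
) -> FeatureAssay:
    """Read a PSM-level quantification table into a raw-scale assay.

    Parameters
    ----------
    layout:
        ``"long"`` (one row per (spectrum, run, channel)) or ``"wide"``
        (one row per PSM, one intensity column per channel, named
        ``<channel_prefix><channel>``).
    column_map:
        overrides for the default column names (keys: protein, peptide,
        spectrum, run, channel, intensity).
    zero_is_missing:
        treat zero intensities as missing (reporter-ion zero is
        non-physical); on by default.
    """
    cmap = dict(LONG_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = _read_table(path, sep)
    if layout == "long":
        _require(df, [cmap[k] for k in
                      ("protein", "peptide", "spectrum", "run", "channel",
                       "intensity")])
        df = df.rename(columns={v: k for k, v in cmap.items()})
        df["intensity"] = _to_float(df["intensity"], "intensity")
        key = ["spectrum", "run", "channel"]
        if df.duplicated(key).any():
            dup = df.loc[df.duplicated(key), key].iloc[0].tolist()
            raise DuplicateCellError(f"duplicate (spectrum, run, channel) {dup}")
        df["sample_id"] = [
            make_sample_id(r, c) for r, c in zip(df["run"], df["channel"])
        ]
        meta = (
            df.groupby("spectrum", sort=False)
            .agg(protein_id=("protein", "first"),
                 peptide_id=("peptide", "first"),
                 run=("run", "first"))
            .reset_index()
            .rename(columns={"spectrum": "spectrum_id"})
        )
        meta.index = _feature_ids(meta)
        fid_of = dict(zip(meta["spectrum_id"], meta.index)) \
            if meta["spectrum_id"].is_unique else None
        if fid_of is None:
            df["feature_id"] = df["run"].astype(str) + ":" + df["spectrum"].astype(str)
        else:
            df["feature_id"] = df["spectrum"].map(fid_of)
        values = df.pivot(index="feature_id", columns="sample_id",
                          values="intensity")
        values = values.reindex(meta.index)
        values.columns.name = None
    elif layout == "wide":
        _require(df, [cmap[k] for k in ("protein", "peptide", "spectrum", "run")])
        chan_cols = [c for c in df.columns if c.startswith(channel_prefix)]
        if not chan_cols:
            raise MissingColumnError(
                f"no channel columns with prefix {channel_prefix!r}"
            )
        df = df.rename(columns={v: k for k, v in cmap.items()})
        if df.duplicated(["spectrum", "run"]).any():
            raise DuplicateCellError("duplicate (spectrum, run) row in wide table")
        meta = df[["spectrum", "protein", "peptide", "run"]].rename(
            columns={"spectrum": "spectrum_id", "protein": "protein_id",
                     "peptide": "peptide_id"}
        )
        meta.index = _feature_ids(meta)
        long = []
        for col in chan_cols:
            channel = col[len(channel_prefix):]
            vals = _to_float(df[col], "intensity")
            long.append(pd.DataFrame({
                "feature_id": meta.index,
                "sample_id": [make_sample_id(r, channel) for r in df["run"]],
                "intensity": vals.values,
            }))
        values = (
            pd.concat(long)
            .pivot(index="feature_id", columns="sample_id", values="intensity")
            .reindex(meta.index)
        )
        values.columns.name = None
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if zero_is_missing:
        values = values.mask(values == 0)
    meta = meta[["protein_id", "peptide_id", "spectrum_id", "run"]]
    return FeatureAssay(values=values, feature_meta=meta, level="psm",
                        log2=False, history=("read_psm_table",))


def write_psm_table(assay: FeatureAssay, path, sep: str | None = None) -> None:
    """Write a PSM-level assay in the long layout (observed cells only)."""
    meta = assay.feature_meta
    rows = []
    for fid in assay.feature_ids:
        vals = assay.values.loc[fid]
        obs = vals.dropna()
        m = meta.loc[fid]
        for sid, v in obs.items():
            run, channel = str(sid).split(":", 1)
            rows.append((m["protein_id"], m["peptide_id"], m["spectrum_id"],
                         run, channel, v))
    out = pd.DataFrame(rows, columns=[LONG_COLUMNS[k] for k in
                                      ("protein", "peptide", "spectrum", "run",
                                       "channel", "intensity")])
    out.to_csv(path, sep=_sep_for(path, sep), index=False, na_rep="NA")


def read_sample_annotation(path, sep: str | None = None) -> SampleAnnotation:
    """Read a sample-annotation table (CSV/TSV with Run, Channel, ...)."""
    df = _read_table(path, sep)
    rename = {c: c.strip().lower().replace(" ", "_") for c in df.columns}
    canonical = {"biorreplicate": "bio_replicate", "bioreplicate": "bio_replicate",
                 "techrep": "tech_rep", "isreference": "is_reference"}
    df = df.rename(columns=rename).rename(columns=canonical)
    for col in ("run", "channel"):
        if col not in df.columns:
            raise MissingRequiredError(f"annotation lacks required column {col!r}")
    return SampleAnnotation.from_frame(df)


def write_sample_annotation(ann: SampleAnnotation, path,
                            sep: str | None = None) -> None:
    ann.table.to_csv(path, sep=_sep_for(path, sep), index=True, na_rep="NA")


def write_result_table(results: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a result table as TSV with fixed column and row order.

    Rows are sorted by (protein, contrast) lexicographically so repeated
    runs produce byte-identical files.
    """
    out = results.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[RESULT_COLUMNS].sort_values(
        ["protein", "contrast"], kind="mergesort"
    )
    out.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_result_table(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, keep_default_na=False, na_values=["NA", ""])
    return df
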