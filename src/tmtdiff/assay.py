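"""Core containers for multiplexed quantitative proteomics data.

A :class:`FeatureAssay` holds an intensity matrix (features x samples) at a
declared level (``psm`` or ``protein``) together with feature metadata.
Samples are the quantified columns of a multiplexed experiment, one per
(run, channel) pair, described by a :class:`SampleAnnotation`.  An
:class:`AssayChain` links the successive assays of an analysis (raw ->
log2 -> normalized -> summarized) so no transformation loses its input.

Missing intensities are always ``NaN``; zero is a value, never a sentinel.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DuplicateSampleError,
    MissingRequiredError,
    UnannotatedSampleError,
)

logger = logging.getLogger(__name__)

#: feature-metadata columns recognised at PSM level
PSM_META_COLUMNS = ("protein_id", "peptide_id", "spectrum_id", "run")


@dataclass(frozen=True)
class FeatureAssay:
    """An intensity matrix with feature metadata at a declared level.

    Parameters
    ----------
    values:
        ``features x samples`` matrix as a DataFrame indexed by feature_id
        with sample_id columns.  Missing entries are ``NaN``.
    feature_meta:
        DataFrame indexed by feature_id.  At PSM level it carries
        ``protein_id``, ``peptide_id``, ``spectrum_id`` and ``run``;
        at protein level only ``protein_id``.
    level:
        ``"psm"`` or ``"protein"``.
    log2:
        whether ``values`` are on log2 scale.
    parent_link:
        optional map feature_id -> frozenset of parent feature_ids in the
        assay this one was derived from.
    history:
        names of the operations that produced this assay, oldest first.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    level: str
    log2: bool
    parent_link: dict | None = None
    history: tuple = ()

    def __post_init__(self):
        if self.level not in ("psm", "protein"):
            raise ValueError(f"unknown assay level {self.level!r}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature_id {dup!r}")
        if not self.values.index.equals(self.feature_meta.index):
            raise ValueError("values and feature_meta must share the same index")
        if self.level == "protein":
            pid = self.feature_meta["protein_id"]
            if not (pid.index == pid.values).all() and pid.duplicated().any():
                raise ValueError("protein-level feature_ids must map 1:1 to proteins")

    # -- convenience ----------------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def observed_mask(self) -> pd.DataFrame:
        return self.values.notna()

    def with_values(self, values: pd.DataFrame, step: str) -> "FeatureAssay":
        """Same metadata, new matrix, provenance extended by ``step``."""
        return replace(self, values=values, history=self.history + (step,))

    def subset_features(self, feature_ids, step: str) -> "FeatureAssay":
        keep = self.values.index.isin(set(feature_ids))
        return replace(
            self,
            values=self.values.loc[keep],
            feature_meta=self.feature_meta.loc[keep],
            history=self.history + (step,),
        )

    def subset_samples(self, sample_ids, step: str) -> "FeatureAssay":
        cols = [s for s in self.values.columns if s in set(sample_ids)]
        return replace(self, values=self.values[cols], history=self.history + (step,))


REQUIRED_ANNOTATION = ("run", "channel")
DEFAULT_ANNOTATION_COLUMNS = (
    "run", "channel", "mixture", "condition", "bio_replicate", "tech_rep",
    "is_reference",
)


def make_sample_id(run, channel) -> str:
    """The ``<run>:<channel>`` naming convention for quantified samples."""
    return f"{run}:{channel}"


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample design variables, one row per quantified (run, channel).

    The wrapped frame is indexed by sample_id and holds at least ``run`` and
    ``channel``; ``mixture`` defaults to the run, ``is_reference`` to False.
    Arbitrary extra covariate columns are carried through untouched.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        for col in REQUIRED_ANNOTATION:
            if col not in t.columns:
                raise MissingRequiredError(f"annotation lacks required column {col!r}")
        if not t.index.is_unique:
            dup = t.index[t.index.duplicated()][0]
            raise DuplicateSampleError(f"duplicate sample_id {dup!r}")
        pairs = t[["run", "channel"]].astype(str).agg(":".join, axis=1)
        if pairs.duplicated().any():
            raise DuplicateSampleError(
                f"duplicate (run, channel) pair {pairs[pairs.duplicated()].iloc[0]!r}"
            )
        if t[["run", "channel"]].isna().any().any():
            raise MissingRequiredError("run/channel must not contain missing values")
        # each run must belong to exactly one mixture
        if "mixture" in t.columns:
            if t["mixture"].isna().any():
                raise MissingRequiredError("mixture must not contain missing values")
            nmix = t.groupby("run", observed=True)["mixture"].nunique()
            if (nmix > 1).any():
                bad = nmix[nmix > 1].index[0]
                raise MissingRequiredError(f"run {bad!r} maps to multiple mixtures")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleAnnotation":
        """Normalize a raw frame: synthesize sample_id and defaults."""
        t = frame.copy()
        if "sample_id" in t.columns:
            synthesized = t.apply(
                lambda r: make_sample_id(r["run"], r["channel"]), axis=1
            )
            if (t["sample_id"].astype(str) != synthesized).any():
                raise DuplicateSampleError(
                    "explicit sample_id column conflicts with the <run>:<channel> "
                    "convention"
                )
            t = t.set_index("sample_id")
            t.index.name = "sample_id"
        else:
            t.index = pd.Index(
                [make_sample_id(r, c) for r, c in zip(t["run"], t["channel"])],
                name="sample_id",
            )
        if "mixture" not in t.columns:
            t["mixture"] = t["run"]
        if "is_reference" not in t.columns:
            t["is_reference"] = False
        else:
            t["is_reference"] = (
                t["is_reference"]
                .map(
                    lambda v: str(v).strip().lower() in ("true", "1", "yes", "t"),
                    na_action="ignore",
                )
                .fillna(False)
                .astype(bool)
            )
        return cls(t)

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def subset(self, sample_ids) -> "SampleAnnotation":
        return SampleAnnotation(self.table.loc[list(sample_ids)])

    def reference_samples(self) -> list:
        return list(self.table.index[self.table["is_reference"]])


def validate_link(assay: FeatureAssay, ann: SampleAnnotation):
    """Check that every assay sample is annotated; return the pair.

    The annotation may be a superset of the assay (subsetting is allowed);
    the reverse is an :class:`UnannotatedSampleError`.
    """
    missing = [s for s in assay.sample_ids if s not in ann.table.index]
    if missing:
        raise UnannotatedSampleError(
            f"assay sample(s) missing from annotation: {missing[:5]}"
        )
    return assay, ann


def drop_reference_channels(assay: FeatureAssay, ann: SampleAnnotation) -> FeatureAssay:
    """Remove reference-channel columns from the assay.

    Feature rows left without any observed value are retained; filtering is
    a separate, reported step.
    """
    validate_link(assay, ann)
    refs = set(ann.reference_samples())
    keep = [s for s in assay.sample_ids if s not in refs]
    if not keep:
        logger.warning("all %d channels are flagged reference; assay is empty",
                       assay.n_samples)
    return assay.subset_samples(keep, "drop_reference_channels")


@dataclass
class AssayChain:
    """Ordered, named assays sharing one annotation.

    Raw input data are never lost: each transformation appends a new assay
    so every intermediate stays linked and inspectable.
    """

    annotation: SampleAnnotation
    assays: list = field(default_factory=list)  # list[(name, FeatureAssay)]

    def add(self, name: str, assay: FeatureAssay) -> None:
        extra = set(assay.sample_ids) - set(self.annotation.sample_ids)
        if extra:
            raise UnannotatedSampleError(
                f"assay {name!r} has unannotated samples: {sorted(extra)[:5]}"
            )
        if assay.parent_link is not None and self.assays:
            prev = self.assays[-1][1]
            prev_ids = set(prev.feature_ids)
            for fid, parents in assay.parent_link.items():
                if not set(parents) <= prev_ids:
                    raise ValueError(
                        f"parent link of {fid!r} does not resolve in the "
                        f"preceding assay"
                    )
        self.assays.append((name, assay))

    def __getitem__(self, name: str) -> FeatureAssay:
        for n, a in self.assays:
            if n == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [n for n, _ in self.assays]

    @property
    def latest(self) -> FeatureAssay:
        return self.assays[-1][1]


def assay_from_matrix(
    values: pd.DataFrame,
    feature_meta: pd.DataFrame,
    level: str = "psm",
    log2: bool = False,
    **kw,
) -> FeatureAssay:
    """Convenience constructor used by simulators and tests."""
    values = values.astype(float)
    return FeatureAssay(values=values, feature_meta=feature_meta, level=level,
                        log2=log2, **kw)


def protein_assay_from_profiles(
    profiles: pd.DataFrame, parent_link: dict | None = None, history: tuple = ()
) -> FeatureAssay:
    """Build a protein-level assay from a protein x sample profile matrix."""
    meta = pd.DataFrame({"protein_id": profiles.index}, index=profiles.index)
    meta.index.name = "feature_id"
    return FeatureAssay(
        values=profiles.astype(float),
        feature_meta=meta,
        level="protein",
        log2=True,
        parent_link=parent_link,
        history=history,
    )
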