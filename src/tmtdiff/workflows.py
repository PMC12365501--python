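"""End-to-end named differential-abundance workflows.

Four named workflows cover the protein-level and PSM-level robust ridge
linear mixed models:

``protein_rrilmm``
    log2 -> channel-median normalization -> median-polish summarization
    per run -> per-protein LMM with a ridge-penalized condition effect and
    random intercepts for run (and mixture when runs are technical
    repeats) -> empirical-Bayes moderation -> contrast Wald tests.
``protein_rrilmm_mixture``
    same, but peptide ions are summarized over all technical fractions of
    a mixture, giving one protein value per biological replicate, with a
    mixture random intercept.
``psm_rrilmm``
    models normalized PSM intensities directly with random intercepts for
    sample (run:channel), psm (spectrum) and run.  Proteins whose model is
    unidentifiable (one-hit wonders) are reported as fit failures -- no
    silent model switching.
``psm_rrilmm_refit``
    identical, but failed proteins are refitted under the largest
    identifiable sub-model and flagged ``reduced``.

Robustness (Huber M-estimation) and ridge penalization are independent
switches, so the lmm / rlmm / rilmm / rrilmm ablation grid is a config
choice, not separate code paths.  Every workflow is a pure function of
(input data, config): re-running reproduces results exactly.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assay import AssayChain, FeatureAssay, SampleAnnotation, \
    drop_reference_channels, validate_link
from .design import FitOptions, ModelSpec, build_design, \
    detect_one_hit_wonder, reduce_model
from .ebayes import VariancePrior, estimate_variance_prior
from .errors import IrreducibleModelError, SingularFitError, TmtdiffError
from .inference import make_contrasts, test_contrasts
from .mixedmodel import ProteinFit, fit_robust_ridge
from .preprocess import filter_min_observed, log2_transform, \
    normalize_channel_median
from .summarize import median_sweep_summarize, summarize_protein

logger = logging.getLogger(__name__)

WORKFLOWS = ("protein_rrilmm", "protein_rrilmm_mixture", "psm_rrilmm",
             "psm_rrilmm_refit", "custom")


@dataclass
class WorkflowConfig:
    """Configuration shared by the named workflows.

    ``robust`` and ``ridge`` toggle Huber M-estimation and the ridge
    penalty on the condition effect; with both off the model is a vanilla
    linear mixed model.  ``condition`` names the annotation column whose
    levels are compared; contrast strings are written against its
    coefficient names (e.g. ``"conditionB - conditionA"``).
    """

    workflow: str = "protein_rrilmm"
    condition: str = "condition"
    contrasts: list = field(default_factory=list)
    fdr_level: float = 0.05
    robust: bool = True
    ridge: bool = True
    drop_reference: bool = True
    normalize_scope: str = "per_run"
    min_obs: int | None = None
    extra_fixed: list = field(default_factory=list)
    model: ModelSpec | None = None   # required for workflow == "custom"
    level: str = "protein"           # custom workflow input level
    summarizer: str = "median_polish"  # or "median_sweep" (custom workflow)
    options: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self):
        if self.workflow not in WORKFLOWS:
            raise ValueError(f"unknown workflow {self.workflow!r}; "
                             f"expected one of {WORKFLOWS}")
        if self.workflow == "custom" and self.model is None:
            raise ValueError("custom workflow requires an explicit ModelSpec")


@dataclass
class WorkflowResult:
    """Results plus the per-protein fits, moderation prior and the chain
    of intermediate assays (raw input is never lost)."""

    results: pd.DataFrame
    fits: dict
    prior: VariancePrior
    notes: list
    chain: "AssayChain | None" = None


def all_pairwise_contrasts(levels, column: str = "condition") -> list:
    """Contrast strings for every pairwise comparison, later minus
    earlier level (the spike-in studies compare all dilution pairs)."""
    levels = list(levels)
    return [f"{column}{b} - {column}{a}"
            for a, b in itertools.combinations(levels, 2)]


def observation_frame(assay: FeatureAssay, ann: SampleAnnotation
                      ) -> pd.DataFrame:
    """Long table of observed intensities joined with sample annotation.

    One row per observed cell with the response ``y``, the feature columns
    (``protein_id``, ``psm`` = feature id) and every annotation column;
    ``sample`` is the run:channel sample id.
    """
    validate_link(assay, ann)
    V = assay.values.to_numpy()
    fi, sj = np.nonzero(~np.isnan(V))
    sample_ids = np.asarray(assay.sample_ids, dtype=object)
    feat_ids = np.asarray(assay.feature_ids, dtype=object)
    obs = pd.DataFrame({
        "y": V[fi, sj],
        "sample": sample_ids[sj],
        "psm": feat_ids[fi],
        "protein_id": assay.feature_meta["protein_id"].to_numpy()[fi],
    })
    t = ann.table.loc[list(sample_ids)]
    for col in t.columns:
        obs[col] = t[col].to_numpy()[sj]
    return obs


def _drop_single_level_terms(spec: ModelSpec, obs: pd.DataFrame,
                             notes: list) -> ModelSpec:
    """Remove random terms that are constant across the whole dataset."""
    drop = [t for t in spec.random_terms
            if t in obs.columns and obs[t].nunique() < 2]
    if drop:
        notes.append(f"dropped single-level random term(s): {drop}")
        logger.info("dropped single-level random term(s): %s", drop)
        spec = spec.without_random(drop)
    return spec


def _identifiable(rows: pd.DataFrame, spec: ModelSpec) -> bool:
    one_hit, _ = detect_one_hit_wonder(rows, spec)
    if one_hit:
        return False
    for term in spec.random_terms:
        if rows[term].nunique() < 2:
            return False
    dm = build_design(rows, spec)
    return len(rows) > dm.p_fixed


def fit_protein_models(obs: pd.DataFrame, spec: ModelSpec,
                       refit: bool = False) -> dict:
    """Fit the per-protein mixed model for every protein in ``obs``.

    Returns protein_id -> :class:`ProteinFit` or ``None`` for failures.
    With ``refit`` the model is reduced (confounded random terms removed)
    instead of failing; such fits carry ``status == "reduced"``.
    """
    fits: dict = {}
    for protein, rows in obs.groupby("protein_id", sort=True):
        fits[protein] = _fit_one(rows, spec, refit)
    return fits


def _fit_one(rows: pd.DataFrame, spec: ModelSpec, refit: bool):
    reduced = False
    spec_p = spec
    try:
        if not _identifiable(rows, spec_p):
            if not refit:
                return None
            spec_p = reduce_model(spec_p, rows)
            reduced = spec_p.random_terms != spec.random_terms
        dm = build_design(rows, spec_p)
        if len(rows) <= dm.p_fixed:
            return None
        fit = fit_robust_ridge(rows["y"].to_numpy(float), dm, spec_p)
    except (SingularFitError, IrreducibleModelError):
        return None
    except TmtdiffError:
        return None
    if reduced:
        fit.status = "reduced"
    return fit


def _condition_spec(cfg: WorkflowConfig, random_terms: list) -> ModelSpec:
    if cfg.ridge:
        fixed, ridge = list(cfg.extra_fixed), [cfg.condition]
    else:
        fixed, ridge = [cfg.condition] + list(cfg.extra_fixed), []
    return ModelSpec(fixed_terms=fixed, random_terms=list(random_terms),
                     ridge_terms=ridge, robust=cfg.robust,
                     options=cfg.options)


def _infer(fits: dict, cfg: WorkflowConfig) -> tuple:
    ok = [(f.sigma2, f.df_res) for f in fits.values()
          if f is not None and np.isfinite(f.sigma2) and f.sigma2 > 0]
    if len(ok) >= 2:
        s2, df = zip(*ok)
        prior = estimate_variance_prior(np.array(s2), np.array(df))
    else:
        # too few proteins to borrow strength: no moderation
        prior = VariancePrior(d0=0.0, s0_sq=1.0)
    contrasts = make_contrasts(cfg.contrasts)
    results = test_contrasts(fits, prior, contrasts)
    return results, prior


def _preprocess_psm(assay: FeatureAssay, ann: SampleAnnotation,
                    cfg: WorkflowConfig, notes: list):
    if cfg.drop_reference and ann.table["is_reference"].any():
        assay = drop_reference_channels(assay, ann)
        notes.append("dropped reference channels")
    if cfg.min_obs is not None:
        assay, rep = filter_min_observed(assay, cfg.min_obs)
        notes.append(f"filter_min_observed removed {rep.features_removed}")
    if not assay.log2:
        assay = log2_transform(assay)
    assay = normalize_channel_median(assay, scope=cfg.normalize_scope)
    return assay


def run_workflow(assay: FeatureAssay, ann: SampleAnnotation,
                 cfg: WorkflowConfig) -> WorkflowResult:
    """Dispatch a named workflow on a PSM-level assay."""
    if not cfg.contrasts:
        raise ValueError("cfg.contrasts must name at least one contrast")
    notes: list = []
    chain = AssayChain(annotation=ann)
    chain.add("raw", assay)
    if cfg.workflow in ("protein_rrilmm", "protein_rrilmm_mixture"):
        psm = _preprocess_psm(assay, ann, cfg, notes)
        chain.add("psm_normalized", psm)
        scope = "per_run" if cfg.workflow == "protein_rrilmm" \
            else "per_mixture"
        prot, prot_ann = summarize_protein(psm, ann, scope=scope)
        if set(prot.sample_ids) <= set(ann.sample_ids):
            chain.add("protein", prot)
        obs = observation_frame(prot, prot_ann.subset(prot.sample_ids))
        if cfg.workflow == "protein_rrilmm":
            random_terms = ["run"]
            reps = prot_ann.table.groupby("mixture", observed=True)["run"] \
                                 .nunique()
            if (reps > 1).any():
                random_terms.append("mixture")
        else:
            random_terms = ["mixture"]
        spec = _condition_spec(cfg, random_terms)
        refit = False
    elif cfg.workflow in ("psm_rrilmm", "psm_rrilmm_refit"):
        psm = _preprocess_psm(assay, ann, cfg, notes)
        chain.add("psm_normalized", psm)
        obs = observation_frame(psm, ann.subset(psm.sample_ids))
        spec = _condition_spec(cfg, ["sample", "psm", "run"])
        refit = cfg.workflow == "psm_rrilmm_refit"
    else:  # custom
        data = assay
        if data.level == "psm" and cfg.level == "protein":
            data = _preprocess_psm(data, ann, cfg, notes)
            if cfg.summarizer == "median_sweep":
                data, ann = median_sweep_summarize(data, ann)
            else:
                data, ann = summarize_protein(data, ann)
        elif data.level == "psm":
            data = _preprocess_psm(data, ann, cfg, notes)
        obs = observation_frame(data, ann.subset(data.sample_ids))
        spec = cfg.model
        refit = False

    spec = _drop_single_level_terms(spec, obs, notes)
    fits = fit_protein_models(obs, spec, refit=refit)
    results, prior = _infer(fits, cfg)
    n_failed = sum(f is None for f in fits.values())
    if n_failed:
        notes.append(f"{n_failed} protein(s) failed to fit")
    return WorkflowResult(results=results, fits=fits, prior=prior,
                          notes=notes, chain=chain)


def _named(workflow: str):
    def runner(assay, ann, cfg: WorkflowConfig | None = None,
               **kw) -> pd.DataFrame:
        cfg = replace(cfg, workflow=workflow) if cfg is not None else \
            WorkflowConfig(workflow=workflow, **kw)
        return run_workflow(assay, ann, cfg).results
    runner.__name__ = f"run_{workflow}"
    runner.__doc__ = (
        f"Run the {workflow} workflow on a PSM-level assay and return the "
        f"result table; keyword arguments populate a WorkflowConfig."
    )
    return runner


run_protein_rrilmm = _named("protein_rrilmm")
run_protein_rrilmm_mixture = _named("protein_rrilmm_mixture")
run_psm_rrilmm = _named("psm_rrilmm")
run_psm_rrilmm_refit = _named("psm_rrilmm_refit")
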