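"""Hierarchical spike-in simulator for multiplexed labeled proteomics.

The generator mirrors the layout of a multi-mixture TMT benchmark: samples
multiplexed as channels within runs, runs grouped into mixtures (with
optional technical-repeat runs), reference channels carrying the pooled
average, spike-in (differentially abundant) proteins over a constant
background, and quantification at PSM level with run-, mixture-, sample-,
spectrum- and residual-level Gaussian variation on log2 scale.
Missingness is missing-at-random given the PSM baseline (low-abundance
biased); outliers are additive log2 shifts of random sign.

Everything is reproducible from the design's seed: an identical design
yields a bit-identical assay.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, roots_hermitenorm

from .assay import FeatureAssay, SampleAnnotation, make_sample_id
from .errors import InvalidDesignError, StratumTooSmallError
from .inference import parse_contrast


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one simulated spike-in experiment.

    The default plex template mirrors a 10-plex spike-in: five mixtures of
    ten channels, two of them reference, four conditions with two channels
    each.  Condition effects of a DA protein follow a dilution-like
    profile: its log2 fold change ``fc`` (cycled through ``log2fc_grid``)
    is spread linearly over the conditions, so the first-vs-last contrast
    equals ``fc`` exactly.  Standard deviations are on log2 scale.
    """

    n_mixtures: int = 5
    runs_per_mixture: int = 1
    n_channels: int = 10
    n_reference_channels: int = 2
    conditions: tuple = ("A", "B", "C", "D")
    n_proteins: int = 1000
    background_fraction: float = 0.8
    log2fc_grid: tuple = (0.5, 1.0, 2.0)
    psm_rate: float = 2.5
    one_hit_fraction: float | None = None
    sd_run: float = 0.3
    sd_mixture: float = 0.15
    sd_sample: float = 0.2
    sd_psm: float = 0.4
    sd_resid: float = 0.25
    baseline_mean: float = 16.0
    baseline_sd: float = 2.0
    peptide_sd: float = 1.0
    miss_intercept: float = 3.07
    miss_slope: float = 0.3
    mcar_rate: float | None = None
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 5.0
    seed: int = 0

    def __post_init__(self):
        sds = (self.sd_run, self.sd_mixture, self.sd_sample, self.sd_psm,
               self.sd_resid, self.baseline_sd, self.peptide_sd)
        if any(s < 0 for s in sds):
            raise InvalidDesignError("standard deviations must be >= 0")
        for name in ("background_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InvalidDesignError(f"{name} must be in [0, 1]")
        n_cond_channels = self.n_channels - self.n_reference_channels
        if n_cond_channels < len(self.conditions):
            raise InvalidDesignError(
                "not enough non-reference channels to cover all conditions"
            )
        if self.psm_rate <= 0:
            raise InvalidDesignError("psm_rate must be positive")

    @property
    def n_runs(self) -> int:
        return self.n_mixtures * self.runs_per_mixture

    def channel_conditions(self) -> dict:
        """Channel -> condition allocation (round-robin; references last)."""
        alloc = {}
        n_sample = self.n_channels - self.n_reference_channels
        for j in range(self.n_channels):
            ch = f"ch{j + 1:02d}"
            if j < n_sample:
                alloc[ch] = self.conditions[j % len(self.conditions)]
            else:
                alloc[ch] = "Reference"
        return alloc


@dataclass(frozen=True)
class GroundTruth:
    """Per-protein truth: DA flag and condition-effect vector."""

    table: pd.DataFrame          # index protein_id: is_DA, fc
    cond_effects: pd.DataFrame   # protein x condition log2 effects

    def __post_init__(self):
        null = ~self.table["is_DA"]
        if not np.allclose(self.cond_effects.loc[null].to_numpy(), 0.0):
            raise InvalidDesignError(
                "background proteins must have zero condition effects"
            )

    def is_da(self) -> pd.Series:
        return self.table["is_DA"]

    def log2fc(self, contrast) -> pd.Series:
        """True log2FC of a contrast over condition coefficients.

        ``contrast`` is a string like ``"conditionD - conditionA"`` or a
        name -> weight map; names are ``condition<label>``.
        """
        weights = parse_contrast(contrast) if isinstance(contrast, str) \
            else dict(contrast)
        out = pd.Series(0.0, index=self.cond_effects.index)
        for name, w in weights.items():
            if not name.startswith("condition"):
                raise KeyError(f"not a condition coefficient: {name!r}")
            label = name[len("condition"):]
            out = out + w * self.cond_effects[label]
        return out


def _zero_truncated_poisson(rng, lam: float, size: int) -> np.ndarray:
    """ZTP sampling by inverse CDF on U(exp(-lam), 1)."""
    u = rng.uniform(np.exp(-lam), 1.0, size=size)
    k = np.ones(size, dtype=int)
    cdf = np.exp(-lam) * np.ones(size)
    pmf = np.exp(-lam) * lam
    term = pmf * np.ones(size)
    cdf = cdf + term
    active = u > cdf
    while active.any():
        k[active] += 1
        term = term * lam / k
        # recompute only where still active (term is per-element)
        cdf = cdf + np.where(active, term, 0.0)
        active = u > cdf
    return k


def simulate_spikein(design: SimDesign):
    """Generate (PSM-level raw-scale assay, annotation, ground truth).

    Each protein draws a PSM (peptide-ion) count; every peptide ion is
    re-identified as a distinct spectrum in every run.  On log2 scale a
    cell is baseline + peptide offset + condition effect + run + mixture +
    sample + spectrum random effects + residual noise; reference channels
    carry the across-condition average profile.  Values are exponentiated
    to raw scale; missingness and outliers are applied last.
    """
    rng = np.random.default_rng(design.seed)
    P = design.n_proteins
    alloc = design.channel_conditions()
    channels = list(alloc)
    nch = design.n_channels
    cond_labels = list(design.conditions)
    K = len(cond_labels)

    # --- structure -----------------------------------------------------------
    runs, mixtures_of_run = [], []
    for m in range(design.n_mixtures):
        mix = f"m{m + 1:02d}"
        for t in range(design.runs_per_mixture):
            runs.append(f"{mix}r{t + 1}")
            mixtures_of_run.append(mix)
    n_runs = len(runs)

    ann_rows = []
    for r, run in enumerate(runs):
        mix = mixtures_of_run[r]
        t = r % design.runs_per_mixture + 1
        for ch in channels:
            cond = alloc[ch]
            ann_rows.append({
                "run": run, "channel": ch, "mixture": mix,
                "condition": cond,
                "bio_replicate": f"{mix}:{ch}",
                "tech_rep": f"t{t}",
                "is_reference": cond == "Reference",
            })
    ann = SampleAnnotation.from_frame(pd.DataFrame(ann_rows))

    # --- per-protein truth ---------------------------------------------------
    protein_ids = np.array([f"P{i + 1:05d}" for i in range(P)])
    n_da = P - int(round(design.background_fraction * P))
    is_da = np.zeros(P, bool)
    if n_da > 0:
        is_da[rng.choice(P, size=n_da, replace=False)] = True
    fc = np.zeros(P)
    grid = np.asarray(design.log2fc_grid, float)
    fc[is_da] = grid[np.arange(n_da) % len(grid)]
    # dilution-like spread of the effect across conditions
    spread = np.linspace(0.0, 1.0, K)
    cond_eff = fc[:, None] * spread[None, :]          # P x K
    truth = GroundTruth(
        table=pd.DataFrame({"is_DA": is_da, "fc": fc},
                           index=pd.Index(protein_ids, name="protein_id")),
        cond_effects=pd.DataFrame(cond_eff, index=protein_ids,
                                  columns=cond_labels),
    )

    # --- feature structure ---------------------------------------------------
    if design.one_hit_fraction is not None:
        forced = rng.random(P) < design.one_hit_fraction
        k = _zero_truncated_poisson(rng, design.psm_rate, P)
        k = np.maximum(k, 2)
        k[forced] = 1
    else:
        k = _zero_truncated_poisson(rng, design.psm_rate, P)
    pep_protein = np.repeat(np.arange(P), k)           # j -> protein index
    npep = len(pep_protein)
    base_prot = rng.normal(design.baseline_mean, design.baseline_sd, P)
    pep_offset = rng.normal(0.0, design.peptide_sd, npep)
    pep_base = base_prot[pep_protein] + pep_offset

    # channel effect per protein (condition effect or reference average)
    chan_eff = np.zeros((P, nch))
    for j, ch in enumerate(channels):
        cond = alloc[ch]
        if cond == "Reference":
            chan_eff[:, j] = cond_eff.mean(axis=1)
        else:
            chan_eff[:, j] = cond_eff[:, cond_labels.index(cond)]

    # --- random effects ------------------------------------------------------
    u_run = rng.normal(0.0, design.sd_run, (P, n_runs))
    u_mix = rng.normal(0.0, design.sd_mixture, (P, design.n_mixtures))
    u_samp = rng.normal(0.0, design.sd_sample, (P, n_runs, nch))
    u_psm = rng.normal(0.0, design.sd_psm, (n_runs, npep))
    mix_idx = np.array([mixtures_of_run[r] for r in range(n_runs)])
    mix_pos = {m: i for i, m in enumerate(dict.fromkeys(mix_idx))}

    # --- assemble log2 matrix (features run-major) ---------------------------
    n_feat = n_runs * npep
    n_cols = n_runs * nch
    log2y = np.full((n_feat, n_cols), np.nan)
    pp = pep_protein
    for r in range(n_runs):
        rows = slice(r * npep, (r + 1) * npep)
        cols = slice(r * nch, (r + 1) * nch)
        block = (
            pep_base[:, None]
            + chan_eff[pp, :]
            + u_run[pp, r][:, None]
            + u_mix[pp, mix_pos[mix_idx[r]]][:, None]
            + u_samp[pp, r, :]
            + u_psm[r][:, None]
            + rng.normal(0.0, design.sd_resid, (npep, nch))
        )
        log2y[rows, cols] = block

    # --- missingness ---------------------------------------------------------
    present = ~np.isnan(log2y)
    if design.mcar_rate is not None:
        pmiss_feat = np.full(npep, float(design.mcar_rate))
    else:
        pmiss_feat = expit(design.miss_intercept
                           - design.miss_slope * pep_base)
    pmiss = np.tile(pmiss_feat, n_runs)[:, None]
    drop = present & (rng.random(log2y.shape) < pmiss)
    log2y[drop] = np.nan

    # --- outliers ------------------------------------------------------------
    if design.outlier_fraction > 0:
        obs = ~np.isnan(log2y)
        hit = obs & (rng.random(log2y.shape) < design.outlier_fraction)
        signs = rng.choice([-1.0, 1.0], size=int(hit.sum()))
        log2y[hit] += signs * design.outlier_magnitude

    # --- wrap ----------------------------------------------------------------
    sample_ids = [make_sample_id(run, ch) for run in runs for ch in channels]
    feature_ids, meta_rows = [], []
    for r, run in enumerate(runs):
        for j in range(npep):
            prot = protein_ids[pep_protein[j]]
            feature_ids.append(f"{run}:{prot}:pep{j}")
            meta_rows.append((prot, f"{prot}:pep{j}",
                              f"{run}:{prot}:pep{j}", run))
    meta = pd.DataFrame(meta_rows,
                        columns=["protein_id", "peptide_id", "spectrum_id",
                                 "run"],
                        index=pd.Index(feature_ids, name="feature_id"))
    values = pd.DataFrame(np.exp2(log2y), index=meta.index,
                          columns=sample_ids)
    keep = values.notna().any(axis=1)
    assay = FeatureAssay(values=values.loc[keep],
                         feature_meta=meta.loc[keep],
                         level="psm", log2=False,
                         history=("simulate_spikein",))
    return assay, ann, truth


def missingness_intercept_for_rate(design: SimDesign, rate: float) -> float:
    """Intercept achieving a target marginal missing rate.

    The marginal rate is the expectation of
    ``logistic(intercept - slope * baseline)`` over the Gaussian PSM
    baseline; it is computed by Gauss-Hermite quadrature and inverted
    with a bracketing root finder (deterministic, no sampling).
    """
    sd = float(np.hypot(design.baseline_sd, design.peptide_sd))
    nodes, weights = roots_hermitenorm(80)
    w = weights / weights.sum()
    b = design.baseline_mean + sd * nodes

    def marginal(a):
        return float(np.sum(w * expit(a - design.miss_slope * b))) - rate

    return float(brentq(marginal, -100.0, 100.0, xtol=1e-10))


def permute_mock_labels(
    ann: SampleAnnotation,
    strata,
    seed: int,
    mock_col: str = "mock_condition",
    include_reference: bool = False,
) -> SampleAnnotation:
    """Randomly split each stratum's samples into two mock conditions.

    Within every stratum (unique combination of the ``strata`` columns)
    the samples are assigned to ``mock1``/``mock2`` as evenly as possible,
    uniformly at random.  As no protein is differentially abundant between
    mock groups, downstream p-values should be uniform -- the standard
    negative-control check.  Reference channels are excluded unless
    ``include_reference``.
    """
    rng = np.random.default_rng(seed)
    t = ann.table.copy()
    eligible = t.index if include_reference else t.index[~t["is_reference"]]
    labels = pd.Series(pd.NA, index=t.index, dtype="object")
    sub = t.loc[eligible]
    for _, grp in sub.groupby(list(strata), sort=True, observed=True):
        ids = list(grp.index)
        if len(ids) < 2:
            raise StratumTooSmallError(
                f"stratum of sample(s) {ids} has fewer than 2 samples"
            )
        perm = rng.permutation(len(ids))
        half = (len(ids) + 1) // 2
        for pos, i in enumerate(perm):
            labels[ids[i]] = "mock1" if pos < half else "mock2"
    t[mock_col] = labels
    return SampleAnnotation(t)
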