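"""Declarative per-protein model specification and design construction.

A :class:`ModelSpec` names the fixed terms, the random intercept terms
(grouping factors such as run, mixture, sample = run:channel, psm =
spectrum id) and the ridge-penalized terms.  Ridge terms are encoded as
full indicator blocks -- no reference level is dropped -- attached to the
random design with one shared variance component per term, so all levels
shrink symmetrically toward zero.  Fixed factors use treatment coding.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import NoObservationsError, UnknownTermError


@dataclass
class FitOptions:
    """Tuning constants of the robust ridge REML fit.

    ``huber_k`` is the Huber tuning constant (1.345 gives 95% efficiency
    under Gaussian errors).  ``reml_tol`` bounds the profiled-objective
    convergence, ``irls_tol`` the coefficient change between robustness
    iterations.  ``varcomp_floor`` is the smallest admissible variance
    ratio sigma_b^2/sigma^2; a block optimized onto the floor is flagged.
    """

    huber_k: float = 1.345
    reml_tol: float = 1e-8
    max_reml_iter: int = 200
    max_irls_iter: int = 20
    irls_tol: float = 1e-6
    varcomp_floor: float = 1e-10
    varcomp_ceiling: float = 1e8

    def __post_init__(self):
        for name in ("huber_k", "reml_tol", "irls_tol", "varcomp_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ModelSpec:
    """Model declaration over annotation / feature-metadata columns."""

    fixed_terms: list = field(default_factory=list)
    random_terms: list = field(default_factory=list)
    ridge_terms: list = field(default_factory=list)
    robust: bool = True
    intercept: bool = True
    options: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self):
        overlap = set(self.fixed_terms) & set(self.ridge_terms)
        if overlap:
            raise ValueError(
                f"terms cannot be both fixed and ridge-penalized: {overlap}"
            )

    def without_random(self, terms) -> "ModelSpec":
        keep = [t for t in self.random_terms if t not in set(terms)]
        return ModelSpec(fixed_terms=list(self.fixed_terms),
                         random_terms=keep,
                         ridge_terms=list(self.ridge_terms),
                         robust=self.robust, intercept=self.intercept,
                         options=self.options)


@dataclass
class ZBlock:
    """One random/penalized block: indicator columns sharing a variance
    component."""

    label: str
    matrix: np.ndarray
    names: list
    penalized: bool


@dataclass
class DesignMatrices:
    """Assembled design: fixed ``X`` (full column rank) plus Z blocks."""

    X: np.ndarray
    fixed_names: list
    blocks: list
    coef_names: list
    coef_index: dict
    dropped_reference: set
    notes: list

    @property
    def n_obs(self) -> int:
        return self.X.shape[0] if self.X.ndim == 2 else len(self.X)

    @property
    def p_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def T(self) -> np.ndarray:
        """Concatenated [X | Z_1 | ... | Z_B]."""
        mats = [self.X] + [b.matrix for b in self.blocks]
        return np.concatenate([m for m in mats if m.shape[1] > 0], axis=1) \
            if any(m.shape[1] for m in mats) else np.empty((self.n_obs, 0))


def _indicator(codes: np.ndarray, q: int) -> np.ndarray:
    mat = np.zeros((len(codes), q))
    mat[np.arange(len(codes)), codes] = 1.0
    return mat


def _is_numeric(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series) and not \
        isinstance(series.dtype, pd.CategoricalDtype)


def build_design(rows: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Build fixed and random design matrices from an observation table.

    ``rows`` has one row per observed intensity and carries every column a
    term references (sample-level covariates joined with feature-level
    metadata).  Fixed factors are treatment-coded against their first
    (sorted) level; rank-deficient fixed columns are dropped with a
    recorded note.  Ridge terms become full indicator blocks; random terms
    become per-level indicator blocks, one variance-component label each.
    """
    n = len(rows)
    if n == 0:
        raise NoObservationsError("no observations to build a design from")
    for term in (list(spec.fixed_terms) + list(spec.random_terms)
                 + list(spec.ridge_terms)):
        if term not in rows.columns:
            raise UnknownTermError(f"model term {term!r} not found in data")

    cols = []
    names = []
    dropped_reference: set = set()
    notes: list = []
    if spec.intercept:
        cols.append(np.ones(n))
        names.append("Intercept")
    for term in spec.fixed_terms:
        s = rows[term]
        if _is_numeric(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(term)
        else:
            codes, levels = pd.factorize(s.astype(str), sort=True)
            start = 1 if spec.intercept else 0
            if start == 1:
                dropped_reference.add(f"{term}{levels[0]}")
            for k in range(start, len(levels)):
                cols.append((codes == k).astype(float))
                names.append(f"{term}{levels[k]}")
    if cols:
        X = np.column_stack(cols)
    else:
        X = np.empty((n, 0))

    # reduce X to full column rank (pivoted QR)
    if X.shape[1] > 1:
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0)
        rank = int((diag > tol).sum())
        if rank < X.shape[1]:
            keep = np.sort(piv[:rank])
            lost = [names[j] for j in piv[rank:]]
            notes.append(f"dropped rank-deficient fixed column(s): {lost}")
            X = X[:, keep]
            names = [names[j] for j in keep]

    blocks = []
    for term in spec.ridge_terms:
        s = rows[term]
        if _is_numeric(s):
            blocks.append(ZBlock(f"ridge_{term}", s.to_numpy(float)[:, None],
                                 [term], True))
        else:
            codes, levels = pd.factorize(s.astype(str), sort=True)
            blocks.append(ZBlock(
                f"ridge_{term}", _indicator(codes, len(levels)),
                [f"{term}{lv}" for lv in levels], True,
            ))
    for term in spec.random_terms:
        codes, levels = pd.factorize(rows[term].astype(str), sort=True)
        blocks.append(ZBlock(
            term, _indicator(codes, len(levels)),
            [f"{term}[{lv}]" for lv in levels], False,
        ))

    coef_names = list(names)
    for b in blocks:
        coef_names.extend(b.names)
    if len(set(coef_names)) != len(coef_names):
        raise ValueError("coefficient names collide across terms")
    coef_index = {nm: i for i, nm in enumerate(coef_names)}
    return DesignMatrices(X=X, fixed_names=names, blocks=blocks,
                          coef_names=coef_names, coef_index=coef_index,
                          dropped_reference=dropped_reference, notes=notes)


def detect_one_hit_wonder(rows: pd.DataFrame, spec: ModelSpec):
    """Check whether any random term is confounded with the residual.

    A grouping factor whose every level holds at most one observation
    carries no replication: its variance component cannot be separated
    from the residual.  A protein quantified by a single PSM per run is
    the canonical case (the sample- and psm-level terms collapse).
    Returns ``(flag, diagnosis)`` where diagnosis maps each random term to
    whether it is confounded.
    """
    diagnosis = {}
    for term in spec.random_terms:
        if term not in rows.columns:
            diagnosis[term] = True
            continue
        sizes = rows.groupby(term, observed=True).size()
        diagnosis[term] = bool((sizes <= 1).all())
    return any(diagnosis.values()), diagnosis


#: preferred removal order when reducing a degenerate model
_REDUCTION_PRIORITY = ("psm", "sample")


def _aliased_terms(rows: pd.DataFrame, terms) -> set:
    """Random terms whose level partition duplicates another term's.

    Two grouping factors inducing the same partition of the observations
    carry a single identifiable variance component; the higher-priority
    term (psm, then sample, then the later one) is marked for removal.
    """
    parts = {}
    for t in terms:
        if t in rows.columns:
            codes, _ = pd.factorize(rows[t].astype(str))
            parts[t] = codes
    out = set()
    names = list(parts)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ca, cb = parts[a], parts[b]
            n_ab = len(set(zip(ca, cb)))
            if len(set(ca)) == n_ab == len(set(cb)):
                prio = [t for t in _REDUCTION_PRIORITY if t in (a, b)]
                out.add(prio[0] if prio else b)
    return out


def reduce_model(spec: ModelSpec, rows: pd.DataFrame) -> ModelSpec:
    """Drop residual-confounded random terms, largest identifiable
    sub-model first.

    Terms are removed in a fixed order -- the psm (spectrum) term first,
    then the sample term, then any remaining degenerate factor -- until no
    random term is confounded with the residual, aliased with another
    random term (identical grouping partition, as when one spectrum per
    run makes psm and run indistinguishable), or single-level.  Raises
    :class:`IrreducibleModelError` when even the fixed-only model cannot
    be estimated.
    """
    from .errors import IrreducibleModelError

    current = spec
    while current.random_terms:
        _, diagnosis = detect_one_hit_wonder(rows, current)
        single = {
            t for t in current.random_terms
            if t in rows.columns and rows[t].nunique() < 2
        }
        aliased = _aliased_terms(rows, current.random_terms)
        bad = {t for t, conf in diagnosis.items() if conf} | single | aliased
        if not bad:
            break
        ordered = [t for t in _REDUCTION_PRIORITY if t in bad]
        ordered += [t for t in current.random_terms
                    if t in bad and t not in ordered]
        current = current.without_random([ordered[0]])
    dm = build_design(rows, current)
    if len(rows) <= dm.p_fixed:
        raise IrreducibleModelError(
            "no identifiable sub-model: observations do not exceed the "
            "fixed-effect rank"
        )
    return current
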