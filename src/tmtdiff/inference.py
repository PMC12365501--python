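"""Wald tests on contrasts of per-protein model coefficients.

A contrast is a linear combination ``L' theta`` of named coefficients --
typically a difference of condition effects, giving the log2 fold change
between two conditions.  The moderated t statistic divides the contrast
estimate by its standard error computed from the mixed-model-equations
covariance and the empirical-Bayes posterior variance; its degrees of
freedom are the effective residual df plus the prior df.  Contrasts on
ridge-penalized (BLUP) coefficients are allowed -- that is what makes the
ridge workflows testable.
"""
from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ebayes import VariancePrior, posterior_variance
from .errors import UnknownCoefficientError
from .mixedmodel import ProteinFit

#: df used for the t reference when the prior df is infinite (effectively
#: the normal distribution)
_DF_CAP = 1e6

RESULT_STATUS = ("ok", "reduced", "not_estimable", "fit_failed")

_TERM_RE = re.compile(
    r"\s*(?P<sign>[+-]?)\s*(?:(?P<num>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*\*\s*)?"
    r"(?P<name>[A-Za-z_][^\s+-]*)"
)


def parse_contrast(text: str) -> dict:
    """Parse ``"conditionB - conditionA"`` (optionally with numeric
    multipliers like ``0.5*conditionB``) into a name -> weight map."""
    weights: dict = {}
    pos = 0
    text = text.strip()
    while pos < len(text):
        m = _TERM_RE.match(text, pos)
        if m is None:
            raise ValueError(f"cannot parse contrast {text!r} at {text[pos:]!r}")
        sign = -1.0 if m.group("sign") == "-" else 1.0
        num = float(m.group("num")) if m.group("num") else 1.0
        name = m.group("name")
        weights[name] = weights.get(name, 0.0) + sign * num
        pos = m.end()
    if not weights or all(v == 0 for v in weights.values()):
        raise ValueError(f"contrast {text!r} is identically zero")
    return weights


def make_contrasts(specs) -> dict:
    """Normalize a contrast specification into {name: {coef: weight}}.

    Accepts a list of contrast strings (each its own name) or a mapping of
    name -> (string or weight dict).
    """
    if isinstance(specs, dict):
        items = specs.items()
    else:
        items = [(s, s) for s in specs]
    out = {}
    for name, val in items:
        out[name] = parse_contrast(val) if isinstance(val, str) else dict(val)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN passes through."""
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _resolve(contrast: dict, fit: ProteinFit):
    """Weight vector of a contrast over one fit's coefficients.

    Names matching a treatment-coding reference level resolve to zero
    (the reference is the baseline); any other unknown name makes the
    contrast non-estimable for this fit.
    """
    idx = {nm: i for i, nm in enumerate(fit.coef_names)}
    L = np.zeros(len(fit.coef_names))
    for name, wgt in contrast.items():
        if name in idx:
            L[idx[name]] += wgt
        elif name in fit.dropped_reference:
            continue
        else:
            return None
    return L


def test_contrasts(
    fits: dict,
    prior: VariancePrior,
    contrasts,
) -> pd.DataFrame:
    """Moderated Wald tests for every protein x contrast.

    ``fits`` maps protein_id to a :class:`ProteinFit` or ``None`` (fit
    failure).  Returns the result table with one row per protein and
    contrast: log2FC, its standard error, moderated t, total df, two-sided
    p, and BH-adjusted p computed within each contrast across the
    successfully fitted proteins.
    """
    contrasts = make_contrasts(contrasts) if not isinstance(contrasts, dict) \
        or not all(isinstance(v, dict) for v in contrasts.values()) \
        else contrasts
    all_names = set()
    for fit in fits.values():
        if fit is not None:
            all_names.update(fit.coef_names)
            all_names.update(fit.dropped_reference)
    if all_names:
        for cname, weights in contrasts.items():
            for n in weights:
                if n not in all_names:
                    raise UnknownCoefficientError(
                        f"contrast {cname!r} names coefficient {n!r} absent "
                        f"from every fit"
                    )

    rows = []
    for protein in sorted(fits, key=str):
        fit = fits[protein]
        if fit is None or fit.status == "failed":
            for cname in contrasts:
                rows.append((protein, cname, np.nan, np.nan, np.nan, np.nan,
                             np.nan, "fit_failed"))
            continue
        s2_post = float(posterior_variance(fit.sigma2, fit.df_res, prior))
        d0 = prior.d0
        df_total = min(fit.df_res + d0, _DF_CAP)
        for cname, weights in contrasts.items():
            L = _resolve(weights, fit)
            if L is None:
                rows.append((protein, cname, np.nan, np.nan, np.nan, np.nan,
                             np.nan, "not_estimable"))
                continue
            logfc = float(L @ fit.coef)
            var_u = float(L @ fit.vcov_unscaled @ L)
            se = float(np.sqrt(max(var_u, 0.0) * s2_post))
            if se == 0:
                t = np.nan
                p = np.nan
                status = "not_estimable"
            else:
                t = logfc / se
                p = float(2.0 * stats.t.sf(abs(t), df_total))
                status = "reduced" if fit.status == "reduced" else "ok"
            rows.append((protein, cname, logfc, se, t, df_total, p, status))

    res = pd.DataFrame(
        rows, columns=["protein", "contrast", "logFC", "se", "t", "df",
                       "pvalue", "status"],
    )
    res["adj_pvalue"] = np.nan
    fitted = res["status"].isin(["ok", "reduced"])
    for cname in contrasts:
        sel = fitted & (res["contrast"] == cname)
        res.loc[sel, "adj_pvalue"] = bh_adjust(res.loc[sel, "pvalue"])
    return res[["protein", "contrast", "logFC", "se", "t", "df", "pvalue",
                "adj_pvalue", "status"]]
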