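"""Tukey median polish for robust additive two-way decomposition.

The polish alternately sweeps row and column medians out of a matrix,
yielding ``overall + row_effect + col_effect + residual``.  It is the
workhorse used to summarize the PSM x channel matrix of a protein into a
per-channel abundance profile: PSM-specific offsets are absorbed by the
row effects, the channel profile by ``overall + col_effects``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AllMissingError


@dataclass
class PolishFit:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool

    def fitted(self) -> np.ndarray:
        return (self.overall + self.row_effects[:, None]
                + self.col_effects[None, :])


def _nanmedian(a: np.ndarray, axis: int) -> np.ndarray:
    """Median over observed cells; all-missing slices contribute 0.

    Sort-based (NaN sorts last) rather than ``np.nanmedian``: the polish
    calls this on many small matrices and the masked-array path of the
    numpy routine dominates the runtime otherwise.  Even counts average
    the two central order statistics.
    """
    if axis == 0:
        a = a.T
    s = np.sort(a, axis=1)
    cnt = a.shape[1] - np.isnan(a).sum(axis=1)
    out = np.zeros(a.shape[0])
    rows = np.flatnonzero(cnt > 0)
    c = cnt[rows]
    out[rows] = 0.5 * (s[rows, (c - 1) // 2] + s[rows, c // 2])
    return out


def _med1d(v: np.ndarray) -> float:
    s = np.sort(v)
    n = len(s)
    return 0.5 * (s[(n - 1) // 2] + s[n // 2])


def median_polish(matrix, tol: float = 1e-6, max_iter: int = 100) -> PolishFit:
    """Fit an additive two-way model by alternating median sweeps.

    Rows are swept first, then columns; the overall term accumulates the
    medians of the effect vectors at each sweep.  Medians are taken over
    observed (non-NaN) cells only.  Iteration stops when the change in the
    L1 norm of the residuals falls below ``tol * (1 + residual L1)``.

    Only fitted values and effect *differences* are contractual: the
    allocation of level between overall, row and column effects follows
    the rows-first convention and is not unique.  Non-convergence (possible
    with oscillation on missing patterns) is flagged, not raised.
    """
    z = np.asarray(matrix, dtype=float)
    if z.ndim != 2:
        raise ValueError("median_polish expects a 2-D matrix")
    obs = ~np.isnan(z)
    if not obs.any():
        raise AllMissingError("matrix has no observed value")
    z = z.copy()
    nr, nc = z.shape
    row = np.zeros(nr)
    col = np.zeros(nc)
    overall = 0.0
    oldsum = np.nansum(np.abs(z))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rdelta = _nanmedian(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = _med1d(col)
        col -= delta
        overall += delta

        cdelta = _nanmedian(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = _med1d(row)
        row -= delta
        overall += delta

        newsum = np.nansum(np.abs(z))
        # scale by the residual L1 (not the raw data): the residual path is
        # location-invariant, so the polish stays exactly equivariant under
        # adding a constant to the input
        if abs(newsum - oldsum) < tol * (1.0 + newsum):
            converged = True
            break
        oldsum = newsum
    return PolishFit(overall=float(overall), row_effects=row, col_effects=col,
                     residuals=z, iterations=it, converged=converged)
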