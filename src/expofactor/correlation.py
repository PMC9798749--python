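"""Mixed-type correlation matrix estimation.

A wide environmental panel mixes continuous composites with ordinal and
binary survey items.  Factor-analysing such a panel on Pearson
correlations attenuates everything touching a categorical column, so the
standard remedy is a latent-normal ("item factor analysis") treatment:

* continuous-continuous pairs  -> Pearson r
* continuous-ordinal pairs     -> polyserial rho (two-step ML)
* ordinal-ordinal pairs        -> polychoric rho (two-step ML)

Two-step means thresholds are fixed at the inverse-normal of the
observed cumulative margins, then the single correlation parameter is
maximised against the bivariate-normal cell likelihood.  Pairwise
deletion is used throughout; the pooled matrix is smoothed to the
nearest PSD correlation matrix (eigenvalue clipping) when pairwise
deletion leaves it indefinite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri

from ._bvnorm import bvn_rectangle
from .manifest import VariableManifest

MIN_PAIRWISE_N = 10
RHO_BOUND = 0.999
EIG_FLOOR = 1e-6


@dataclass
class Thresholds:
    """Inverse-normal cut points for an ordinal variable (k-1 of them)."""

    tau: np.ndarray

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.size and not np.all(np.diff(self.tau) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if not np.all(np.isfinite(self.tau)):
            raise ValueError("thresholds must be finite")

    @property
    def edges(self) -> np.ndarray:
        """tau padded with -inf/+inf — integration limits per category."""
        return np.concatenate([[-np.inf], self.tau, [np.inf]])


@dataclass
class CorrelationMatrix:
    """Symmetric mixed-type correlation estimate with per-pair provenance."""

    values: np.ndarray
    names: list[str]
    method: np.ndarray | None = None  # dtype=object, per-pair tag
    pairwise_n: np.ndarray | None = None
    smoothed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.names, columns=self.names).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CorrelationMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), list(df.columns))


def estimate_thresholds(counts) -> Thresholds:
    """Thresholds from category frequencies: tau_k = ndtri(cumprop_k).

    Zero-frequency categories are collapsed into their neighbour (a
    warning is emitted) since they contribute no threshold information.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D frequency vector")
    if np.any(counts < 0):
        raise ValueError("negative category counts")
    nonzero = counts[counts > 0]
    if nonzero.size < 2:
        raise ValueError("need at least 2 nonempty categories")
    if nonzero.size < counts.size:
        warnings.warn(
            "empty categories collapsed during threshold estimation", stacklevel=2
        )
    cum = np.cumsum(nonzero)[:-1] / nonzero.sum()
    return Thresholds(ndtri(cum))


def _table_loglik(table: np.ndarray, edges_r: np.ndarray, edges_c: np.ndarray,
                  rho: float) -> float:
    lo1 = edges_r[:-1][:, None]
    hi1 = edges_r[1:][:, None]
    lo2 = edges_c[:-1][None, :]
    hi2 = edges_c[1:][None, :]
    probs = bvn_rectangle(lo1, hi1, lo2, hi2, rho)
    probs = np.maximum(probs, 1e-300)
    return float(np.sum(table * np.log(probs)))


def _drop_zero_margins(table: np.ndarray) -> np.ndarray:
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("zero-margin categories merged out of contingency table",
                      stacklevel=3)
    return table[np.ix_(rows, cols)]


def polychoric_pair(table) -> float:
    """Two-step ML polychoric correlation from a contingency table.

    Thresholds come from the margins; rho maximises the bivariate-normal
    cell likelihood, clipped to (-0.999, 0.999).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.sum() <= 0:
        raise ValueError("contingency table must be 2-D with positive total")
    table = _drop_zero_margins(table)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 categories per margin after merging")

    edges_r = estimate_thresholds(table.sum(axis=1)).edges
    edges_c = estimate_thresholds(table.sum(axis=0)).edges

    def neg_ll(rho):
        return -_table_loglik(table, edges_r, edges_c, rho)

    res = minimize_scalar(neg_ll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": 1e-7})
    rho = float(res.x)
    if abs(rho) >= RHO_BOUND - 1e-4:
        rho = float(np.sign(rho) * RHO_BOUND)
        warnings.warn("polychoric estimate at boundary (near-perfect association)",
                      stacklevel=2)
    return rho


def polyserial_pair(continuous, ordinal) -> float:
    """Two-step ML polyserial correlation (continuous x ordinal).

    The continuous variable is standardised; conditional on z the latent
    response behind the ordinal item is N(rho z, 1 - rho^2), so each
    observation contributes Phi((tau_j - rho z)/s) - Phi((tau_{j-1} -
    rho z)/s).
    """
    x = np.asarray(continuous, dtype=float)
    y = np.asarray(ordinal)
    if x.size != y.size:
        raise ValueError("columns must be aligned")
    if x.size < MIN_PAIRWISE_N:
        raise ValueError(f"need at least {MIN_PAIRWISE_N} complete pairs")
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValueError("zero-variance continuous column")
    z = (x - x.mean()) / sd

    cats, codes = np.unique(y, return_inverse=True)
    if cats.size < 2:
        raise ValueError("ordinal column has a single category")
    counts = np.bincount(codes, minlength=cats.size).astype(float)
    edges = estimate_thresholds(counts).edges
    hi = edges[1:][codes]
    lo = edges[:-1][codes]

    def neg_ll(rho):
        s = np.sqrt(1.0 - rho * rho)
        p = ndtr((hi - rho * z) / s) - ndtr((lo - rho * z) / s)
        return -float(np.sum(np.log(np.maximum(p, 1e-300))))

    res = minimize_scalar(neg_ll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": 1e-7})
    rho = float(res.x)
    if abs(rho) >= RHO_BOUND - 1e-4:
        rho = float(np.sign(rho) * RHO_BOUND)
        warnings.warn("polyserial estimate at boundary", stacklevel=2)
    return rho


def nearest_psd(matrix: np.ndarray) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clip to PSD and rescale to unit diagonal.

    Returns ``(smoothed, changed)``.  PSD input is returned unchanged,
    which makes the operation idempotent.
    """
    R = np.asarray(matrix, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("input must have unit diagonal")
    R = 0.5 * (R + R.T)
    if np.linalg.eigvalsh(R)[0] >= 0.0:
        return R, False
    out = R
    for _ in range(100):
        w, v = np.linalg.eigh(out)
        if w[0] >= 0.0:
            break
        w = np.maximum(w, EIG_FLOOR)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = 0.5 * (out + out.T)
        np.fill_diagonal(out, 1.0)
    return out, True


def _pair_method(level_i: str, level_j: str) -> str:
    ord_i = level_i in ("ordinal", "binary")
    ord_j = level_j in ("ordinal", "binary")
    if ord_i and ord_j:
        return "polychoric"
    if ord_i or ord_j:
        return "polyserial"
    return "pearson"


def mixed_correlation_matrix(
    table: pd.DataFrame,
    manifest: VariableManifest,
    deletion: str = "pairwise",
) -> CorrelationMatrix:
    """Full mixed-type correlation matrix with pairwise deletion.

    Per-pair estimators are dispatched from the manifest's declared
    levels; an indefinite pooled matrix is smoothed to the nearest PSD
    correlation matrix.
    """
    manifest.validate_table(table)
    if deletion not in ("pairwise", "listwise"):
        raise ValueError("deletion must be 'pairwise' or 'listwise'")
    if deletion == "listwise":
        table = table.dropna()

    cols = list(table.columns)
    p = len(cols)
    R = np.eye(p)
    method = np.empty((p, p), dtype=object)
    method[np.diag_indices(p)] = "diag"
    npair = np.zeros((p, p), dtype=int)
    np.fill_diagonal(npair, len(table))

    data = {c: table[c].to_numpy(dtype=float) for c in cols}
    levels = {c: manifest[c].level for c in cols}

    for i in range(p):
        xi = data[cols[i]]
        for j in range(i + 1, p):
            xj = data[cols[j]]
            mask = ~(np.isnan(xi) | np.isnan(xj))
            n = int(mask.sum())
            if n < MIN_PAIRWISE_N:
                raise ValueError(
                    f"fewer than {MIN_PAIRWISE_N} complete pairs for "
                    f"({cols[i]!r}, {cols[j]!r})"
                )
            a, b = xi[mask], xj[mask]
            tag = _pair_method(levels[cols[i]], levels[cols[j]])
            if tag == "pearson":
                r = float(np.corrcoef(a, b)[0, 1])
            elif tag == "polyserial":
                if levels[cols[i]] == "continuous":
                    r = polyserial_pair(a, b.astype(int))
                else:
                    r = polyserial_pair(b, a.astype(int))
            else:
                ai = a.astype(int)
                bi = b.astype(int)
                tab = np.zeros((ai.max() + 1, bi.max() + 1))
                np.add.at(tab, (ai, bi), 1.0)
                r = polychoric_pair(tab)
            R[i, j] = R[j, i] = r
            method[i, j] = method[j, i] = tag
            npair[i, j] = npair[j, i] = n

    smoothed_R, changed = nearest_psd(R)
    return CorrelationMatrix(
        smoothed_R, cols, method=method, pairwise_n=npair, smoothed=changed
    )
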