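"""Quasi-confirmatory bifactor modeling on a correlation matrix.

Every item loads on a general factor plus exactly one specific factor;
all factors are mutually orthogonal.  The model-implied correlation is

    Sigma(theta) = lam_g lam_g' + sum_s lam_s lam_s' + diag(psi),
    psi_i = 1 - lam_g,i^2 - lam_s,i^2,

and loadings are estimated by unweighted least squares on the
off-diagonal of the (polychoric/mixed) correlation matrix, with
multi-start seeded optimisation and a canonical sign convention.  This
replaces mean-and-variance-adjusted weighted least squares: the
population solution is identical and no asymptotic covariance matrix of
the correlation estimates is needed, but chi-square-scale fit indices
are approximations and are documented as such.

Also provided: item pruning below a specific-loading cutoff, CFI /
RMSEA / SRMR, bifactor reliability indices (ECV, omega-hierarchical,
factor determinacy), and regression-method orthogonal factor scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

from .correlation import CorrelationMatrix, Thresholds
from .efa import RotatedSolution
from .manifest import VariableManifest

MIN_ITEMS_PER_FACTOR = 3


@dataclass
class BifactorModelSpec:
    """Item list plus each item's single specific-factor assignment."""

    items: list[str]
    assignment: np.ndarray  # specific-factor index per item, 0-based
    n_specific: int
    cutoff: float = 0.30
    excluded: list[str] = field(default_factory=list)
    ties: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        if len(self.items) != len(self.assignment):
            raise ValueError("assignment must cover every item")
        if self.assignment.size and (self.assignment.min() < -1
                                     or self.assignment.max() >= self.n_specific):
            raise ValueError("assignment indices out of range")

    @property
    def p(self) -> int:
        return len(self.items)

    @property
    def assigned(self) -> np.ndarray:
        """Boolean mask: items carrying a free specific loading.

        ``assignment == -1`` fixes an item's specific loading to zero
        (general-factor-only item; the nested one-factor model when all
        items are so marked).
        """
        return self.assignment >= 0

    def factor_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment[self.assigned],
                           minlength=self.n_specific)


@dataclass
class BifactorFit:
    spec: BifactorModelSpec
    lambda_g: np.ndarray
    lambda_s: np.ndarray
    psi: np.ndarray
    n_obs: int
    f_min: float
    df: int
    t_stat: float  # (N-1) * F_min
    t_baseline: float
    df_baseline: int
    converged: bool = True

    def implied(self) -> np.ndarray:
        L = self.loading_matrix()
        sigma = L @ L.T
        np.fill_diagonal(sigma, 1.0)
        return sigma

    def loading_matrix(self) -> np.ndarray:
        """Full orthogonal block: column 0 = general, then specifics."""
        p = self.spec.p
        L = np.zeros((p, 1 + self.spec.n_specific))
        L[:, 0] = self.lambda_g
        m = self.spec.assigned
        L[np.nonzero(m)[0], 1 + self.spec.assignment[m]] = self.lambda_s[m]
        return L

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.spec.items,
                "specific_factor": self.spec.assignment + 1,
                "lambda_g": self.lambda_g,
                "lambda_s": self.lambda_s,
                "psi": self.psi,
            }
        )


@dataclass
class FitIndices:
    cfi: float
    rmsea: float
    srmr: float


@dataclass
class BifactorIndices:
    ecv: float
    omega_h: float
    omega_hs: np.ndarray  # per specific factor; NaN where undefined
    fd: np.ndarray  # per factor, general first


@dataclass
class FactorScores:
    scores: pd.DataFrame  # columns: general, spec_1..spec_S
    determinacy: np.ndarray
    n_dropped: int = 0


# ---------------------------------------------------------------------------
# model configuration from an EFA pattern
# ---------------------------------------------------------------------------

def configure_bifactor(rotated: RotatedSolution, item_names: list[str],
                       cutoff: float = 0.30) -> BifactorModelSpec:
    """Assign each item to the specific factor of its largest |loading|.

    Items with no pattern loading reaching the cutoff are excluded (and
    recorded); ties go to the lower factor index (and are recorded).
    """
    L = np.abs(rotated.loadings)
    items, assignment, excluded, ties = [], [], [], []
    for i, name in enumerate(item_names):
        row = L[i]
        if row.max() < cutoff:
            excluded.append(name)
            continue
        best = int(np.argmax(row))  # argmax takes the lowest index on ties
        if np.sum(np.isclose(row, row.max(), atol=1e-12)) > 1:
            ties.append(name)
        items.append(name)
        assignment.append(best)
    spec = BifactorModelSpec(items, np.asarray(assignment, int),
                             n_specific=L.shape[1], cutoff=cutoff,
                             excluded=excluded, ties=ties)
    small = np.nonzero(spec.factor_sizes() < MIN_ITEMS_PER_FACTOR)[0]
    if small.size:
        warnings.warn(
            f"specific factors with < {MIN_ITEMS_PER_FACTOR} items "
            f"(identification risk): {[int(s) + 1 for s in small]}",
            stacklevel=2,
        )
    return spec


# ---------------------------------------------------------------------------
# ULS fitting
# ---------------------------------------------------------------------------

def _offdiag_mask(p: int) -> np.ndarray:
    return ~np.eye(p, dtype=bool)


def _uls_objective(theta: np.ndarray, R: np.ndarray, assign: np.ndarray,
                   n_specific: int):
    p = R.shape[0]
    lam_g = theta[:p]
    lam_s = np.where(assign >= 0, theta[p:], 0.0)
    L = np.zeros((p, 1 + n_specific))
    L[:, 0] = lam_g
    m = assign >= 0
    L[np.nonzero(m)[0], 1 + assign[m]] = lam_s[m]
    sigma = L @ L.T
    E = R - sigma
    np.fill_diagonal(E, 0.0)
    f = 0.25 * float(np.sum(E * E))  # 1/2 * sum over unique pairs
    G = -(E @ L)  # d f / d L (symmetry factor 2 cancels the 1/2)
    grad_g = G[:, 0]
    grad_s = np.zeros(p)
    grad_s[m] = G[np.nonzero(m)[0], 1 + assign[m]]
    # Heywood guard: smooth penalty when communality approaches 1
    comm = lam_g**2 + lam_s**2
    over = np.maximum(comm - 0.9975, 0.0)
    f += 1e3 * float(np.sum(over**2))
    pen = 4e3 * over
    grad_g = grad_g + pen * lam_g
    grad_s = grad_s + pen * lam_s
    return f, np.concatenate([grad_g, grad_s])


def fit_bifactor(R: CorrelationMatrix | np.ndarray, spec: BifactorModelSpec,
                 n_obs: int, n_starts: int = 5, seed: int = 0) -> BifactorFit:
    """ULS bifactor fit with seeded multi-start optimisation.

    Signs are canonicalised so the mean loading of every factor is
    nonnegative.  ``psi`` is reported as 1 - lam_g^2 - lam_s^2, floored
    at 0 for Heywood-capped items.
    """
    Rm = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, float)
    p = spec.p
    if Rm.shape[0] != p:
        raise ValueError("correlation matrix does not match spec items")
    sizes = spec.factor_sizes()
    if np.any(sizes < MIN_ITEMS_PER_FACTOR):
        warnings.warn("specific factor with < 3 items; solution may be "
                      "under-identified", stacklevel=2)

    rng = np.random.default_rng(seed)
    best = None
    trajectories = []
    for start in range(n_starts):
        if start == 0:
            lam_g0 = np.full(p, 0.5)
            lam_s0 = np.full(p, 0.4)
        else:
            lam_g0 = rng.uniform(0.2, 0.7, p)
            lam_s0 = rng.uniform(0.1, 0.6, p)
        lam_s0 = np.where(spec.assigned, lam_s0, 0.0)
        x0 = np.concatenate([lam_g0, lam_s0])
        s_bounds = [(-0.999, 0.999) if a else (0.0, 0.0)
                    for a in spec.assigned]
        res = minimize(
            _uls_objective, x0, args=(Rm, spec.assignment, spec.n_specific),
            jac=True, method="L-BFGS-B",
            bounds=[(-0.999, 0.999)] * p + s_bounds,
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
        )
        trajectories.append(float(res.fun))
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"bifactor fit failed to converge across {n_starts} starts; "
            f"best objectives: {trajectories}"
        )

    lam_g = best.x[:p].copy()
    lam_s = best.x[p:].copy()
    # canonical signs: mean loading per factor nonnegative
    if lam_g.mean() < 0:
        lam_g = -lam_g
    for s in range(spec.n_specific):
        m = spec.assignment == s
        if m.any() and lam_s[m].mean() < 0:
            lam_s[m] = -lam_s[m]
    psi = np.maximum(1.0 - lam_g**2 - lam_s**2, 0.0)

    # recompute F at the canonical solution (sign flips leave it unchanged)
    f_min, _ = _uls_objective(np.concatenate([lam_g, lam_s]), Rm,
                              spec.assignment, spec.n_specific)
    n_free = p + int(spec.assigned.sum())
    n_moments = p * (p - 1) // 2
    df = n_moments - n_free
    if df <= 0:
        warnings.warn("model is saturated or under-identified (df <= 0)",
                      stacklevel=2)
    E0 = Rm.copy()
    np.fill_diagonal(E0, 0.0)
    f_baseline = 0.25 * float(np.sum(E0 * E0))
    return BifactorFit(
        spec=spec, lambda_g=lam_g, lambda_s=lam_s, psi=psi, n_obs=n_obs,
        f_min=float(f_min), df=df, t_stat=(n_obs - 1) * float(f_min),
        t_baseline=(n_obs - 1) * f_baseline, df_baseline=n_moments,
        converged=True,
    )


def prune_and_refit(fit: BifactorFit, R: CorrelationMatrix, n_obs: int,
                    cutoff: float = 0.30, seed: int = 0
                    ) -> tuple[BifactorFit, list[dict]]:
    """Iteratively drop items with |lambda_s| below the cutoff and refit.

    A specific factor is never reduced below 3 items (a warning is
    issued and its remaining weak items are kept).  Returns the final
    fit and the removal audit.
    """
    audit: list[dict] = []
    current = fit
    names = list(R.names)
    while True:
        spec = current.spec
        weak = (np.abs(current.lambda_s) < cutoff) & spec.assigned
        sizes = spec.factor_sizes()
        keep = np.ones(spec.p, dtype=bool)
        blocked: list[int] = []
        # remove weakest first so a factor stops exactly at 3 items
        order = np.argsort(np.abs(current.lambda_s))
        remaining = sizes.copy()
        for i in order:
            if not weak[i]:
                continue
            s = spec.assignment[i]
            if remaining[s] <= MIN_ITEMS_PER_FACTOR:
                blocked.append(i)
                continue
            keep[i] = False
            remaining[s] -= 1
            audit.append({"item": spec.items[i], "lambda_s": float(current.lambda_s[i]),
                          "factor": int(s) + 1, "action": "dropped"})
        if blocked:
            warnings.warn(
                "pruning stopped for factors at the 3-item floor; weak items "
                f"kept: {[spec.items[i] for i in blocked]}", stacklevel=2)
        if keep.all():
            return current, audit
        if not keep.any():
            raise ValueError("pruning would empty the model")
        new_items = [it for it, k in zip(spec.items, keep) if k]
        new_assign = spec.assignment[keep]
        # renumber factors in case one vanished entirely
        used = np.unique(new_assign)
        remap = {int(s): j for j, s in enumerate(used)}
        new_assign = np.asarray([remap[int(s)] for s in new_assign])
        new_spec = BifactorModelSpec(new_items, new_assign, len(used),
                                     cutoff=cutoff, excluded=spec.excluded,
                                     ties=spec.ties)
        idx = [names.index(it) for it in new_items]
        sub_R = CorrelationMatrix(R.values[np.ix_(idx, idx)], new_items)
        current = fit_bifactor(sub_R, new_spec, n_obs, seed=seed)


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

def fit_indices(fit: BifactorFit, R: CorrelationMatrix | np.ndarray | None = None
                ) -> FitIndices:
    """CFI / RMSEA from the (N-1)*F statistic; SRMR from raw residuals."""
    if fit.df <= 0:
        raise ValueError("fit indices undefined for a saturated model (df <= 0)")
    T, df = fit.t_stat, fit.df
    Tb, dfb = fit.t_baseline, fit.df_baseline
    excess = max(T - df, 0.0)
    rmsea = float(np.sqrt(excess / (df * (fit.n_obs - 1))))
    denom = max(Tb - dfb, T - df, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - excess / denom
    if R is None:
        srmr = float(np.sqrt(4.0 * fit.f_min / (fit.spec.p * (fit.spec.p - 1))))
    else:
        Rm = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, float)
        E = Rm - fit.implied()
        iu = np.triu_indices(fit.spec.p, k=1)
        srmr = float(np.sqrt(np.mean(E[iu] ** 2)))
    return FitIndices(cfi=float(cfi), rmsea=rmsea, srmr=srmr)


def plugin_fit_indices(t_stat: float, df: int, n_obs: int,
                       t_baseline: float, df_baseline: int
                       ) -> tuple[float, float]:
    """(RMSEA, CFI) from summary statistics alone."""
    if df <= 0:
        raise ValueError("df must be positive")
    excess = max(t_stat - df, 0.0)
    rmsea = float(np.sqrt(excess / (df * (n_obs - 1))))
    denom = max(t_baseline - df_baseline, t_stat - df, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - excess / denom
    return rmsea, float(cfi)


def bifactor_indices(fit: BifactorFit, R: CorrelationMatrix | np.ndarray | None = None
                     ) -> BifactorIndices:
    """ECV, omega-hierarchical (and per-subfactor omega_HS), determinacy.

    Determinacy uses FD_f = sqrt([L' R^-1 L]_ff) with the full
    orthogonal loading block; the model-implied matrix is used when no
    sample matrix is supplied.
    """
    lam_g, lam_s, psi = fit.lambda_g, fit.lambda_s, fit.psi
    ss_g = float(np.sum(lam_g**2))
    ss_s = float(np.sum(lam_s**2))
    ecv = ss_g / (ss_g + ss_s) if ss_g + ss_s > 0 else np.nan

    sum_g = float(np.sum(lam_g)) ** 2
    sum_s_by_factor = np.array([
        float(np.sum(lam_s[fit.spec.assignment == s])) ** 2
        for s in range(fit.spec.n_specific)
    ])
    total_var = sum_g + float(sum_s_by_factor.sum()) + float(np.sum(psi))
    omega_h = sum_g / total_var

    omega_hs = np.full(fit.spec.n_specific, np.nan)
    for s in range(fit.spec.n_specific):
        m = fit.spec.assignment == s
        if not m.any() or np.allclose(lam_s[m], 0.0):
            continue  # undefined: reported as NaN
        gs = float(np.sum(lam_g[m])) ** 2
        ss = float(np.sum(lam_s[m])) ** 2
        tot = gs + ss + float(np.sum(psi[m]))
        omega_hs[s] = ss / tot

    L = fit.loading_matrix()
    Rm = fit.implied() if R is None else (
        R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, float))
    try:
        Rinv = np.linalg.inv(Rm)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; ridge 1e-8 applied",
                      stacklevel=2)
        Rinv = np.linalg.inv(Rm + 1e-8 * np.eye(Rm.shape[0]))
    fd = np.sqrt(np.clip(np.diag(L.T @ Rinv @ L), 0.0, 1.0))
    return BifactorIndices(ecv=ecv, omega_h=float(omega_h),
                           omega_hs=omega_hs, fd=fd)


# ---------------------------------------------------------------------------
# factor scores
# ---------------------------------------------------------------------------

def normal_scores(column: np.ndarray, thresholds: Thresholds) -> np.ndarray:
    """Conditional-normal score per ordinal category.

    E[Z | tau_{j-1} < Z <= tau_j] = (phi(tau_{j-1}) - phi(tau_j)) /
    (Phi(tau_j) - Phi(tau_{j-1})) — keeps scoring on the latent-normal
    scale of the polychoric measurement model.
    """
    edges = thresholds.edges
    pdf = norm.pdf(edges)
    cdf = ndtr(edges)
    num = pdf[:-1] - pdf[1:]
    den = np.maximum(cdf[1:] - cdf[:-1], 1e-12)
    means = num / den
    codes = column.astype(int)
    return means[codes]


def standardize_items(table: pd.DataFrame, manifest: VariableManifest
                      ) -> pd.DataFrame:
    """Continuous columns z-scored; ordinal columns -> normal scores."""
    from .correlation import estimate_thresholds

    out = {}
    for col in table.columns:
        x = table[col].to_numpy(float)
        info = manifest[col]
        if info.level == "continuous":
            sd = np.nanstd(x, ddof=1)
            if sd <= 0:
                raise ValueError(f"zero-variance column {col!r}")
            out[col] = (x - np.nanmean(x)) / sd
        else:
            obs = x[~np.isnan(x)].astype(int)
            counts = np.bincount(obs, minlength=int(obs.max()) + 1).astype(float)
            th = estimate_thresholds(counts)
            z = np.full_like(x, np.nan)
            z[~np.isnan(x)] = normal_scores(obs, th)
            out[col] = z
    return pd.DataFrame(out, index=table.index)


def factor_scores(items_standardized: pd.DataFrame, fit: BifactorFit,
                  R: CorrelationMatrix | np.ndarray,
                  indices: BifactorIndices | None = None,
                  orthogonalize: bool = False) -> FactorScores:
    """Regression-method scores F = X R^-1 L, re-standardised per column.

    Rows with any missing item are dropped (listwise scoring) and the
    drop count reported.  Raw regression scores of an orthogonal model
    are themselves inter-correlated (their implied covariance is
    L' R^-1 L); the attached determinacy describes *these* scores.
    With ``orthogonalize=True`` the scores are symmetrically whitened
    (ZCA) so their sample correlations are exactly zero — the form to
    use when the factors enter a downstream model as orthogonal
    predictors — at the cost of a slightly lower correlation with the
    true factors than the determinacy suggests.
    """
    X = items_standardized[fit.spec.items]
    complete = X.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    Xc = X.loc[complete].to_numpy(float)
    Xc = Xc - Xc.mean(axis=0)
    Rm = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, float)
    L = fit.loading_matrix()
    W = np.linalg.solve(Rm, L)
    S = Xc @ W
    if orthogonalize:
        C = np.cov(S, rowvar=False)
        w, v = np.linalg.eigh(C)
        S = S @ (v / np.sqrt(np.maximum(w, 1e-12))) @ v.T
    sd = S.std(axis=0, ddof=1)
    S = S / np.where(sd > 0, sd, 1.0)
    cols = ["general"] + [f"spec_{s + 1}" for s in range(fit.spec.n_specific)]
    frame = pd.DataFrame(S, columns=cols, index=X.index[complete])
    det = (indices or bifactor_indices(fit, R)).fd
    return FactorScores(scores=frame, determinacy=det, n_dropped=n_dropped)
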