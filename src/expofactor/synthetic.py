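"""Synthetic cohorts with a planted exposome bifactor structure.

Restricted cohort data cannot ship with the package, so every
downstream stage is exercised on cohorts drawn from the generative
model the analysis assumes: orthogonal standard-normal latent scores
(one general adversity factor g plus S specific factors), items

    y*_i = lambda_g,i * g + lambda_s,i * s_a(i) + sqrt(psi_i) * eps_i,
    psi_i = 1 - lambda_g,i^2 - lambda_s,i^2,

with continuous items observed directly and ordinal/binary items
discretised at fixed inverse-normal thresholds.  Family clustering is
injected as an exchangeable shared component: each latent column is
sqrt(icc)*u_family + sqrt(1-icc)*e_child, so the within-family
correlation of true scores equals ``icc_family``.  Missingness is MCAR.

Outcomes mirror the published association models: a continuous
psychopathology score driven mostly by the general factor and the
day-to-day subfactor, and binary obesity / advanced-puberty indicators
from logistic models on the general factor.  Demographic covariates
(low household income, low parental education) are coupled to g at
strengths chosen to reproduce the reported standardized group contrasts
(d = 1.40 and 1.16 on the general factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .manifest import VariableInfo, VariableManifest

def _coupling_for_d(d: float) -> float:
    """Latent coupling a such that a median split of a*g + sqrt(1-a^2)*noise
    yields a two-group Cohen's d of ``d`` on g.

    Group means are +/- a*sqrt(2/pi), within-group variance 1 - a^2*(2/pi),
    so d = 2a*sqrt(c)/sqrt(1 - a^2 c) with c = 2/pi, giving
    a^2 = d^2 / (c*(4 + d^2)).
    """
    c = 2.0 / np.pi
    return float(np.sqrt(d * d / (c * (4.0 + d * d))))


@dataclass
class GenerativeSpec:
    """Parameters of the planted bifactor measurement model."""

    n_subjects: int
    n_specific: int
    items_per_factor: int
    loading_general: np.ndarray  # per item
    loading_specific: np.ndarray  # per item, on its assigned factor
    item_levels: list[str]  # "continuous" | "ordinal" | "binary"
    thresholds: dict[int, np.ndarray] = field(default_factory=dict)
    cluster_sizes: tuple[int, ...] = (1,)
    icc_family: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.loading_general = np.asarray(self.loading_general, float)
        self.loading_specific = np.asarray(self.loading_specific, float)
        p = self.n_items
        if not (len(self.loading_general) == len(self.loading_specific)
                == len(self.item_levels) == p):
            raise ValueError("per-item arrays must have length n_specific*items_per_factor")
        uniq = 1.0 - self.loading_general**2 - self.loading_specific**2
        if np.any(uniq <= 0):
            raise ValueError("lambda_g^2 + lambda_s^2 must be < 1 for every item")
        if not 0.0 <= self.icc_family < 1.0:
            raise ValueError("icc_family must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for i, lvl in enumerate(self.item_levels):
            if lvl == "continuous":
                continue
            tau = np.asarray(self.thresholds.get(i, []), float)
            if tau.size == 0:
                raise ValueError(f"ordinal item {i} needs thresholds")
            if tau.size > 1 and not np.all(np.diff(tau) > 0):
                raise ValueError(f"thresholds for item {i} must be strictly increasing")
            if lvl == "binary" and tau.size != 1:
                raise ValueError(f"binary item {i} needs exactly 1 threshold")

    @property
    def n_items(self) -> int:
        return self.n_specific * self.items_per_factor

    @property
    def uniqueness(self) -> np.ndarray:
        return 1.0 - self.loading_general**2 - self.loading_specific**2

    def item_factor(self, i: int) -> int:
        return i // self.items_per_factor

    @property
    def item_names(self) -> list[str]:
        return [f"item_{i:03d}" for i in range(self.n_items)]

    def manifest(self) -> VariableManifest:
        infos = []
        for i, lvl in enumerate(self.item_levels):
            ncat = None
            if lvl != "continuous":
                ncat = len(self.thresholds[i]) + 1
            infos.append(VariableInfo(self.item_names[i], lvl, ncat,
                                      block=f"factor_{self.item_factor(i) + 1}"))
        return VariableManifest(infos)

    def population_loading_matrix(self) -> np.ndarray:
        """True items x (1 + n_specific) orthogonal loading block."""
        L = np.zeros((self.n_items, 1 + self.n_specific))
        L[:, 0] = self.loading_general
        for i in range(self.n_items):
            L[i, 1 + self.item_factor(i)] = self.loading_specific[i]
        return L


@dataclass
class OutcomeSpec:
    """Planted effect sizes for the downstream association models."""

    beta_general: float = 0.285
    beta_specific: tuple[float, ...] = (0.518, 0.083, -0.021, 0.027, -0.019, 0.014)
    beta_covariates: dict[str, float] = field(
        default_factory=lambda: {"age_z": 0.007, "female": -0.017,
                                 "low_income": 0.0, "low_parent_ed": 0.0}
    )
    r2_target: float | None = 0.382
    logistic_or_general: float = 1.41
    obesity_prevalence: float = 0.167
    puberty_or_general: float = 1.30
    puberty_or_daytoday: float = 1.31
    puberty_prevalence: float = 0.065
    seed: int = 0


def default_generative_spec(
    n_subjects: int = 4000,
    n_specific: int = 6,
    items_per_factor: int = 6,
    icc_family: float = 0.3,
    missing_rate: float = 0.02,
    seed: int = 0,
    levels_cycle: tuple[str, ...] = ("continuous", "binary", "ordinal", "ordinal",
                                     "ordinal", "continuous"),
) -> GenerativeSpec:
    """Cohort emulating the published panel at desk scale.

    Loadings cycle through moderate-to-strong values typical of the
    reported solution; measurement levels mix continuous composites with
    binary and 3-5 category ordinal items; ~15% of children sit in
    two-child families (sibling/twin pairs).
    """
    p = n_specific * items_per_factor
    lg = np.tile([0.55, 0.45, 0.60, 0.40, 0.50, 0.35], p // 6 + 1)[:p]
    ls = np.tile([0.50, 0.55, 0.40, 0.60, 0.45, 0.55], p // 6 + 1)[:p]
    levels = [levels_cycle[i % len(levels_cycle)] for i in range(p)]
    thresholds: dict[int, np.ndarray] = {}
    tau_cycle = {
        "binary": [np.array([0.0]), np.array([0.43]), np.array([-0.6])],
        "ordinal": [np.array([-1.0, 1.0]), np.array([-0.5, 0.5, 1.2]),
                    np.array([-1.2, -0.3, 0.4, 1.1])],
    }
    counters = {"binary": 0, "ordinal": 0}
    for i, lvl in enumerate(levels):
        if lvl == "continuous":
            continue
        opts = tau_cycle[lvl]
        thresholds[i] = opts[counters[lvl] % len(opts)]
        counters[lvl] += 1
    # families of 2 for ~15% of subjects, singletons otherwise
    cluster_sizes = tuple([2] * 3 + [1] * 34)
    return GenerativeSpec(
        n_subjects=n_subjects,
        n_specific=n_specific,
        items_per_factor=items_per_factor,
        loading_general=lg,
        loading_specific=ls,
        item_levels=levels,
        thresholds=thresholds,
        cluster_sizes=cluster_sizes,
        icc_family=icc_family,
        missing_rate=missing_rate,
        seed=seed,
    )


def _family_ids(n: int, cluster_sizes: tuple[int, ...]) -> np.ndarray:
    sizes = []
    i = 0
    total = 0
    while total < n:
        s = cluster_sizes[i % len(cluster_sizes)]
        sizes.append(min(s, n - total))
        total += sizes[-1]
        i += 1
    return np.repeat(np.arange(len(sizes)), sizes)


def simulate_latent_scores(spec: GenerativeSpec) -> pd.DataFrame:
    """True orthogonal factor scores with exchangeable family clustering.

    Columns ``g, s1..sS`` are independent standard normal in population;
    the within-family correlation of each column equals ``icc_family``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    fam = _family_ids(n, spec.cluster_sizes)
    n_fam = int(fam[-1]) + 1
    k = 1 + spec.n_specific
    u = rng.standard_normal((n_fam, k))
    e = rng.standard_normal((n, k))
    icc = spec.icc_family
    scores = np.sqrt(icc) * u[fam] + np.sqrt(1.0 - icc) * e
    cols = ["g"] + [f"s{j + 1}" for j in range(spec.n_specific)]
    out = pd.DataFrame(scores, columns=cols)
    out["family_id"] = fam
    return out


def simulate_item_responses(latent: pd.DataFrame, spec: GenerativeSpec
                            ) -> pd.DataFrame:
    """Item table from the planted loadings; ordinal items discretised."""
    rng = np.random.default_rng(spec.seed + 1)
    n = len(latent)
    g = latent["g"].to_numpy()
    S = latent[[f"s{j + 1}" for j in range(spec.n_specific)]].to_numpy()
    eps = rng.standard_normal((n, spec.n_items))
    psi = spec.uniqueness
    out = np.empty((n, spec.n_items))
    for i in range(spec.n_items):
        ystar = (spec.loading_general[i] * g
                 + spec.loading_specific[i] * S[:, spec.item_factor(i)]
                 + np.sqrt(psi[i]) * eps[:, i])
        if spec.item_levels[i] == "continuous":
            out[:, i] = ystar
        else:
            out[:, i] = np.searchsorted(spec.thresholds[i], ystar)
    table = pd.DataFrame(out, columns=spec.item_names)
    if spec.missing_rate > 0:
        mask = rng.random((n, spec.n_items)) < spec.missing_rate
        table = table.mask(mask)
    return table


def simulate_covariates(latent: pd.DataFrame, seed: int = 0,
                        d_income: float = 1.40, d_parent_ed: float = 1.16
                        ) -> pd.DataFrame:
    """Demographics with income/education contrasts planted on g.

    ``low_income`` and ``low_parent_ed`` are median splits of latent
    indices a*g + sqrt(1-a^2)*noise, with a chosen so the two-group
    Cohen's d on g equals the requested contrast.
    """
    rng = np.random.default_rng(seed + 2)
    n = len(latent)
    g = latent["g"].to_numpy()
    a_inc = _coupling_for_d(d_income)
    a_pe = _coupling_for_d(d_parent_ed)
    u_inc = a_inc * g + np.sqrt(1 - a_inc**2) * rng.standard_normal(n)
    u_pe = a_pe * g + np.sqrt(1 - a_pe**2) * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "age_z": rng.standard_normal(n),
            "female": (rng.random(n) < 0.477).astype(int),
            "low_income": (u_inc > 0).astype(int),
            "low_parent_ed": (u_pe > 0).astype(int),
        }
    )


def simulate_outcomes(latent: pd.DataFrame, covariates: pd.DataFrame,
                      ospec: OutcomeSpec) -> pd.DataFrame:
    """Continuous psychopathology score plus binary obesity/puberty.

    The residual variance of the continuous outcome is chosen so the
    full-model population R^2 equals ``r2_target``; logistic intercepts
    are solved so marginal prevalences hit their targets with the
    planted per-SD odds ratios.
    """
    if len(latent) != len(covariates):
        raise ValueError("latent and covariate tables must be row-aligned")
    rng = np.random.default_rng(ospec.seed + 3)
    n = len(latent)
    g = latent["g"].to_numpy()
    n_spec = sum(c.startswith("s") and c[1:].isdigit() for c in latent.columns)
    betas_s = np.asarray(ospec.beta_specific, float)[:n_spec]
    eta = ospec.beta_general * g
    for j, b in enumerate(betas_s):
        eta = eta + b * latent[f"s{j + 1}"].to_numpy()
    for name, b in ospec.beta_covariates.items():
        if b and name in covariates:
            x = covariates[name].to_numpy(float)
            eta = eta + b * (x - x.mean()) / max(x.std(), 1e-12)
    var_eta = float(np.var(eta))
    if var_eta > 1.0 + 1e-9 and ospec.r2_target is None:
        raise ValueError("implied linear-predictor variance exceeds 1")
    if ospec.r2_target is not None:
        if not 0.0 < ospec.r2_target < 1.0:
            raise ValueError("r2_target must be in (0, 1)")
        sigma2 = var_eta * (1.0 - ospec.r2_target) / ospec.r2_target
    else:
        sigma2 = 1.0 - var_eta
    y = eta + np.sqrt(sigma2) * rng.standard_normal(n)
    y = y / np.sqrt(var_eta + sigma2)  # standardized in population

    def binary(beta_terms: np.ndarray, prevalence: float, rand) -> np.ndarray:
        lo, hi = -30.0, 30.0
        alpha = brentq(lambda a: expit(a + beta_terms).mean() - prevalence, lo, hi)
        return (rand < expit(alpha + beta_terms)).astype(int)

    b_obes = np.log(ospec.logistic_or_general) * g
    obesity = binary(b_obes, ospec.obesity_prevalence, rng.random(n))
    b_pub = np.log(ospec.puberty_or_general) * g
    if n_spec >= 1:
        b_pub = b_pub + np.log(ospec.puberty_or_daytoday) * latent["s1"].to_numpy()
    puberty = binary(b_pub, ospec.puberty_prevalence, rng.random(n))

    return pd.DataFrame({"p_factor": y, "obesity": obesity, "puberty": puberty})


@dataclass
class SimulatedCohort:
    items: pd.DataFrame
    latent: pd.DataFrame
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    manifest: VariableManifest
    spec: GenerativeSpec

    @property
    def family_id(self) -> np.ndarray:
        return self.latent["family_id"].to_numpy()

    def write_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.items.to_csv(outdir / "items.csv", index=False)
        self.latent.to_csv(outdir / "latent_scores.csv", index=False)
        self.covariates.to_csv(outdir / "covariates.csv", index=False)
        self.outcomes.to_csv(outdir / "outcomes.csv", index=False)
        self.manifest.to_csv(outdir / "manifest.csv")


def simulate_cohort(spec: GenerativeSpec, ospec: OutcomeSpec | None = None
                    ) -> SimulatedCohort:
    """Full cohort: latent scores, items, covariates and outcomes."""
    ospec = ospec or OutcomeSpec(seed=spec.seed)
    latent = simulate_latent_scores(spec)
    items = simulate_item_responses(latent, spec)
    covariates = simulate_covariates(latent, seed=spec.seed)
    outcomes = simulate_outcomes(latent, covariates, ospec)
    return SimulatedCohort(items, latent, covariates, outcomes,
                           spec.manifest(), spec)
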