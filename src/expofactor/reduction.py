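"""Iterative redundancy reduction of a wide variable panel.

Before the final EFA, a wide exposure panel is shrunk by an explicit,
auditable loop that replaces expert curation: on each pass the mixed
correlation matrix is estimated, an oblimin EFA at the parallel-analysis
factor count supplies communalities, groups of near-duplicate variables
(pairwise |r| >= r_merge) collapse to a single representative (or a
mean-of-standardized composite), and variables whose communality falls
below a floor are dropped.  The loop stops when a pass takes no action
or the iteration cap is reached; every removal is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import mixed_correlation_matrix
from .efa import extract_minres, retain_factors
from .manifest import VariableInfo, VariableManifest


@dataclass
class ReductionConfig:
    r_merge: float = 0.90
    min_communality: float = 0.10
    max_iterations: int = 9
    composite_rule: str = "representative"  # or "mean-of-standardized"
    pa_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.min_communality < self.r_merge <= 1.0:
            raise ValueError("need 0 < min_communality < r_merge <= 1")
        if self.composite_rule not in ("representative", "mean-of-standardized"):
            raise ValueError(f"unknown composite_rule {self.composite_rule!r}")


@dataclass
class ReductionResult:
    surviving: list[str]
    audit: list[dict] = field(default_factory=list)
    iterations: int = 0
    table: pd.DataFrame | None = None
    manifest: VariableManifest | None = None

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.audit, columns=["iteration", "variable",
                                                 "action", "reason", "value"])


def _merge_groups(R: np.ndarray, names: list[str], r_merge: float) -> list[list[int]]:
    """Connected components of the |r| >= r_merge graph (size > 1 only)."""
    p = len(names)
    parent = list(range(p))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(p):
        for j in range(i + 1, p):
            if abs(R[i, j]) >= r_merge:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(p):
        groups.setdefault(find(i), []).append(i)
    return [g for g in groups.values() if len(g) > 1]


def reduce_redundancy(table: pd.DataFrame, manifest: VariableManifest,
                      config: ReductionConfig | None = None) -> ReductionResult:
    """Run the reduction loop; returns survivors, audit trail, and the
    reduced table/manifest for downstream stages."""
    config = config or ReductionConfig()
    if table.shape[1] < 3:
        raise ValueError("need at least 3 variables to reduce")
    work = table.copy()
    man = manifest.subset(list(work.columns))
    audit: list[dict] = []
    iteration = 0

    for iteration in range(1, config.max_iterations + 1):
        R = mixed_correlation_matrix(work, man)
        n_eff = len(work)
        k, _, _ = retain_factors(R, n_eff, seed=config.pa_seed)
        k = min(k, work.shape[1] - 1)
        unrot = extract_minres(R, k)
        comm = dict(zip(R.names, unrot.communalities))
        acted = False

        # (1) collapse near-duplicate groups
        for group in _merge_groups(R.values, R.names, config.r_merge):
            gnames = [R.names[i] for i in group]
            if len(gnames) == work.shape[1]:
                raise ValueError("all variables collapse into one composite; "
                                 "degenerate panel")
            if config.composite_rule == "representative":
                keep = max(gnames, key=lambda nm: comm[nm])
                for nm in gnames:
                    if nm == keep:
                        continue
                    audit.append({"iteration": iteration, "variable": nm,
                                  "action": "merged", "reason": f"|r| >= "
                                  f"{config.r_merge} with {keep}",
                                  "value": comm[nm]})
                    work = work.drop(columns=nm)
                acted = True
            else:
                levels = {man[nm].level for nm in gnames}
                if levels != {"continuous"}:
                    warnings.warn(
                        "mean-of-standardized composite requested for a "
                        f"non-continuous group {gnames}; keeping representative",
                        stacklevel=2)
                    keep = max(gnames, key=lambda nm: comm[nm])
                    for nm in gnames:
                        if nm != keep:
                            audit.append({"iteration": iteration, "variable": nm,
                                          "action": "merged",
                                          "reason": f"representative {keep}",
                                          "value": comm[nm]})
                            work = work.drop(columns=nm)
                    acted = True
                    continue
                comp_name = f"composite_{iteration}_" + gnames[0]
                z = work[gnames].apply(
                    lambda c: (c - c.mean()) / c.std(ddof=1))
                work = work.drop(columns=gnames)
                work[comp_name] = z.mean(axis=1)
                for nm in gnames:
                    audit.append({"iteration": iteration, "variable": nm,
                                  "action": "merged",
                                  "reason": f"composite {comp_name}",
                                  "value": comm[nm]})
                man = VariableManifest(
                    [v for v in man if v.name in work.columns and
                     v.name != comp_name]
                    + [VariableInfo(comp_name, "continuous", block="composite")])
                acted = True
        man = man.subset([c for c in work.columns if c in man])
        if any(c not in man for c in work.columns):
            extra = [VariableInfo(c, "continuous", block="composite")
                     for c in work.columns if c not in man]
            man = VariableManifest(list(man.variables) + extra)

        # (2) drop low-communality variables (skip if merging already acted
        # this pass, since communalities refer to the pre-merge panel)
        if not acted:
            for nm in list(work.columns):
                if comm.get(nm, 1.0) < config.min_communality:
                    audit.append({"iteration": iteration, "variable": nm,
                                  "action": "dropped",
                                  "reason": f"communality < {config.min_communality}",
                                  "value": comm[nm]})
                    work = work.drop(columns=nm)
                    acted = True
            man = man.subset(list(work.columns))

        if not acted:
            break
        if work.shape[1] < 3:
            raise ValueError("reduction left fewer than 3 variables")

    return ReductionResult(
        surviving=list(work.columns), audit=audit, iterations=iteration,
        table=work, manifest=man,
    )
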