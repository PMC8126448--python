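"""Dynamic-network-marker (DNM) identification.

A DNM is a module of the fasted-state network whose members show (a) high
eigenvector centrality, (b) the largest paired change in centrality relative
to the baseline network, (c) elevated between-individual coefficient of
variation (a stochasticity proxy), and (d) a large contribution to the
network modularity. Module-wise heterogeneity of centrality, centrality
change and log CV is tested with one-way fixed-effects GLMs (F tests);
candidate modules are ranked on the four criteria and the best mean rank is
selected, gated on the fasted CV GLM being significant.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import IntensityTensor
from .exceptions import DesignError
from .topology import ModulePartition

LOG_FLOOR = 1e-12  # centralities numerically zero off the dominant component


def between_individual_cv(tensor: IntensityTensor) -> pd.DataFrame:
    """Between-individual CV (sample sd / mean of natural-scale intensity)
    per metabolite and condition. Columns: cv_post, cv_fasted."""
    if tensor.n_individuals < 2:
        raise DesignError("CV needs >= 2 individuals")
    mean = tensor.values.mean(axis=1)
    sd = tensor.values.std(axis=1, ddof=1)
    cv = sd / mean
    return pd.DataFrame(
        {"cv_post": cv[:, 0], "cv_fasted": cv[:, 1]},
        index=pd.Index(tensor.metabolite_ids, name="metabolite_id"),
    )


@dataclass
class GlmResult:
    """One-way fixed-effects GLM of a per-metabolite response on module."""

    F: float
    df1: int
    df2: int
    p: float
    group_table: pd.DataFrame  # module, n, predicted mean (back-transformed), CI
    log_transformed: bool
    excluded_singletons: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "log_transformed": self.log_transformed,
            "excluded_singletons": self.excluded_singletons,
        }


def module_glm(
    response: pd.Series,
    modules: pd.Series,
    log_transform: bool = False,
    exclude_singletons: bool = True,
) -> GlmResult:
    """F-test of the module factor on a per-metabolite response.

    With ``log_transform`` the response is floored at 1e-12 and natural-logged
    before fitting; group predictions are back-transformed by exp (naive,
    no bias correction). Singleton modules can be excluded (as for networks
    where one-metabolite modules carry no within-group information). If all
    responses are identical the F statistic is 0 with p = 1.
    """
    modules = modules.reindex(response.index)
    sizes = modules.value_counts()
    excluded = sorted(int(lab) for lab in sizes.index[sizes == 1]) if exclude_singletons else []
    keep = ~modules.isin(excluded)
    y = response[keep].to_numpy(dtype=float)
    g = modules[keep].to_numpy()
    labels = np.unique(g)
    if labels.size < 2:
        raise DesignError("module GLM needs >= 2 (non-singleton) modules")
    if log_transform:
        if np.any(y < 0):
            raise ValueError("log GLM requires non-negative responses")
        y = np.log(np.maximum(y, LOG_FLOOR))

    n_total = y.size
    k = labels.size
    df1, df2 = k - 1, n_total - k
    grand = y.mean()
    means = np.array([y[g == lab].mean() for lab in labels])
    ns = np.array([(g == lab).sum() for lab in labels])
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((y[g == lab] - m) ** 2).sum() for lab, m in zip(labels, means)))
    if ss_within == 0 and ss_between == 0:
        f_stat, p = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df1) / (ss_within / df2)
        p = float(stats.f.sf(f_stat, df1, df2))
    sigma = np.sqrt(ss_within / df2) if df2 > 0 else 0.0
    tcrit = stats.t.ppf(0.975, df2) if df2 > 0 else np.nan
    se = sigma / np.sqrt(ns)
    lo, hi = means - tcrit * se, means + tcrit * se
    back = np.exp if log_transform else (lambda v: v)
    group_table = pd.DataFrame(
        {
            "module": labels,
            "n": ns,
            "pred_mean": back(means),
            "ci_low": back(lo),
            "ci_high": back(hi),
        }
    )
    return GlmResult(float(f_stat), int(df1), int(df2), float(p), group_table,
                     log_transform, excluded)


@dataclass
class DnmReport:
    """Module-level summary, GLM F-tests, candidate ranking and selection."""

    module_summary: pd.DataFrame
    glms: dict[str, GlmResult]
    selected_module: int | None
    dnm_detected: bool
    flags: list[str]
    excluded_singletons: list[int]

    def selected_members(self, partition: ModulePartition) -> set[str]:
        if self.selected_module is None:
            return set()
        return partition.members(self.selected_module)

    def to_dict(self) -> dict:
        return {
            "selected_module": self.selected_module,
            "dnm_detected": self.dnm_detected,
            "flags": self.flags,
            "excluded_singletons": self.excluded_singletons,
            "glms": {name: g.to_dict() for name, g in self.glms.items()},
            "module_summary": self.module_summary.reset_index().to_dict(orient="records"),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float) + "\n")


def rank_dnm_candidates(
    partition_fast: ModulePartition,
    partition_post: ModulePartition,
    centrality: pd.DataFrame,  # columns c_post, c_fasted, delta_c
    cv: pd.DataFrame,  # columns cv_post, cv_fasted
    alpha: float = 0.05,
    baseline_f_ratio: float = 3.0,
) -> DnmReport:
    """Rank fasted-network modules as DNM candidates and select the best.

    Each non-singleton fasted module is ranked (1 = largest) on mean fasted
    eigenvector centrality, mean paired centrality change, mean fasted CV,
    and its modularity contribution; the composite score is the mean of the
    four rank positions and the smallest composite wins, ties broken by
    larger module size then smaller label.

    Detection gate: a DNM is declared only if fasted CV heterogeneity is
    significant (p < alpha) *and* markedly stronger than at baseline
    (F_fasted > baseline_f_ratio * F_post). The second clause matters
    because modules are estimated from the same individuals whose spread the
    CV measures, which inflates the fasted F even without any real
    perturbation; the baseline network is equally affected, so the contrast
    is calibrated. Without the gate the report flags "no DNM detected"
    while still listing ranks.
    """
    modules_fast = partition_fast.assignment
    modules_post = partition_post.assignment
    flags: list[str] = []

    glms: dict[str, GlmResult] = {
        "centrality": module_glm(centrality["c_fasted"], modules_fast, log_transform=True),
        "delta_centrality": module_glm(centrality["delta_c"], modules_fast, log_transform=False),
        "cv_fasted": module_glm(cv["cv_fasted"], modules_fast, log_transform=True),
        "cv_post": module_glm(cv["cv_post"], modules_post, log_transform=True),
    }

    excluded = partition_fast.singleton_labels()
    eligible = [lab for lab in partition_fast.labels if lab not in excluded]
    rows = []
    for lab in eligible:
        members = sorted(partition_fast.members(lab))
        rows.append(
            {
                "module": lab,
                "size": len(members),
                "mean_centrality": float(centrality.loc[members, "c_fasted"].mean()),
                "mean_delta_centrality": float(centrality.loc[members, "delta_c"].mean()),
                "mean_cv_fasted": float(cv.loc[members, "cv_fasted"].mean()),
                "mean_cv_post": float(cv.loc[members, "cv_post"].mean()),
                "q_contrib": partition_fast.q_contrib[lab],
            }
        )
    summary = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame()

    selected: int | None = None
    if len(eligible) < 2:
        flags.append("fewer than 2 eligible modules: no candidate ranking")
        dnm_detected = False
    else:
        criteria = ["mean_centrality", "mean_delta_centrality", "mean_cv_fasted", "q_contrib"]
        for crit in criteria:
            summary[f"rank_{crit}"] = summary[crit].rank(ascending=False, method="average")
        summary["composite_rank"] = summary[[f"rank_{c}" for c in criteria]].mean(axis=1)
        order = summary.sort_values(
            by=["composite_rank", "size"],
            ascending=[True, False],
            kind="mergesort",  # stable; index (ascending label) breaks remaining ties
        )
        selected = int(order.index[0])
        f_fast, f_post = glms["cv_fasted"].F, glms["cv_post"].F
        dnm_detected = (glms["cv_fasted"].p < alpha) and (
            f_fast > baseline_f_ratio * max(f_post, 1e-12)
        )
        if not dnm_detected:
            flags.append(
                "no DNM detected: fasted CV heterogeneity is not both significant "
                f"(p={glms['cv_fasted'].p:.3g}) and markedly stronger than baseline "
                f"(F_fasted={f_fast:.3g} vs F_post={f_post:.3g})"
            )
        if glms["cv_post"].p < alpha:
            flags.append(
                "baseline CV heterogeneity is itself nominally significant "
                f"(p={glms['cv_post'].p:.3g}); advisory only"
            )
    return DnmReport(summary, glms, selected, dnm_detected, flags, excluded)
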