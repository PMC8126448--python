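"""Paired differential metabolite expression with empirical-Bayes moderation.

The model is the standard moderated paired t: per metabolite g the
within-subject log2 differences d[g, i] have mean lfc_g and sample variance
s2_g with d_g = n - 1 residual degrees of freedom. A scaled inverse-chi-square
prior s2 ~ s0^2 * d0 / chi^2_d0 is fitted to the observed variances by the
method of moments on log s2 (Smyth-type hierarchy), giving the posterior
variance

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and the moderated statistic t_g = lfc_g / sqrt(s2_tilde_g / n) on d0 + d_g
degrees of freedom. d0 = 0 recovers the classical paired t; d0 = inf pools
all metabolites to the common prior variance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .dataio import IntensityTensor
from .exceptions import DegenerateDataError, DesignError

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ModerationPrior:
    """Hyperparameters of the scaled inverse-chi-square variance prior."""

    d0: float  # prior degrees of freedom; math.inf = variances fully pooled
    s0_sq: float  # prior variance, (log2 units)^2

    def __post_init__(self) -> None:
        if not (self.d0 > 0 or self.d0 == 0):
            raise ValueError("d0 must be >= 0 (inf allowed)")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


def paired_differences(tensor: IntensityTensor) -> pd.DataFrame:
    """Within-subject log2 differences d[g, i] = log2(fasted) - log2(post)."""
    if tensor.n_individuals < 2:
        raise DesignError("paired analysis needs at least 2 individuals")
    logv = tensor.log2_values()
    return pd.DataFrame(
        logv[:, :, 1] - logv[:, :, 0],
        index=pd.Index(tensor.metabolite_ids, name="metabolite_id"),
        columns=tensor.individual_ids,
    )


def _trigamma_inverse(x: float, max_iter: int = 100) -> float:
    # Newton iteration for psi'(y) = x, y > 0 (monotone decreasing).
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float | np.ndarray) -> ModerationPrior:
    """Method-of-moments fit of the variance prior from observed s2_g.

    Matches the first two moments of log s2_g under s2_g ~ s0^2 F(d_g, d0).
    If the empirical spread of log s2_g is at or below the value implied by
    finite sampling alone, the prior df is reported as infinite and s0^2 is
    the (bias-corrected) geometric-mean variance.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = df >= 1
    if ok.sum() < 10:
        raise DesignError("need at least 10 metabolites with >= 1 residual df")
    s2, df = s2[ok], df[ok]
    if np.all(s2 == 0):
        raise DegenerateDataError("all sample variances are zero")
    # zero variances cannot enter the log; offset them to the smallest positive
    tiny = s2[s2 > 0].min() * 1e-8
    z = np.log(np.maximum(s2, tiny))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = e.size
    e_mean = float(e.mean())
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    excess = e_var - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        return ModerationPrior(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - math.log(half_d0)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderated_paired_test(
    differences: pd.DataFrame, prior: ModerationPrior
) -> pd.DataFrame:
    """Moderated t statistics and two-sided P values from paired differences."""
    n = differences.shape[1]
    if n < 2:
        raise DesignError("moderated paired test needs >= 2 individuals")
    d = differences.to_numpy(dtype=float)
    lfc = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    dg = float(n - 1)
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + dg * s2) / (prior.d0 + dg)
        df_total = prior.d0 + dg
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2_post / n)
    t = np.where(lfc == 0, 0.0, t)  # 0/0 -> 0 by convention
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {"lfc": lfc, "s2": s2, "t_mod": t, "p": p, "df": df_total},
        index=differences.index,
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def run_diffexpr(
    tensor: IntensityTensor,
    alpha: float = DEFAULT_ALPHA,
    prior: ModerationPrior | None = None,
) -> pd.DataFrame:
    """Full paired differential-expression table.

    Columns: lfc, s2, t_mod, p, p_adj, change_class. A metabolite is called
    an increase iff p_adj < alpha and lfc > 0, a decrease iff p_adj < alpha
    and lfc < 0 (strict inequality at the alpha boundary), else no_change.
    """
    diffs = paired_differences(tensor)
    if prior is None:
        prior = estimate_prior(diffs.to_numpy().var(axis=1, ddof=1), diffs.shape[1] - 1)
    table = moderated_paired_test(diffs, prior)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["change_class"] = classify(table, alpha=alpha)
    table.attrs["prior"] = prior
    table.attrs["alpha"] = alpha
    return table


def classify(table: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.Series:
    sig = table["p_adj"] < alpha
    cls = np.where(
        sig & (table["lfc"] > 0),
        "increase",
        np.where(sig & (table["lfc"] < 0), "decrease", "no_change"),
    )
    return pd.Series(cls, index=table.index, name="change_class")


def classify_and_summarize(
    table: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Counts of no_change / decrease / increase, overall and per super pathway."""
    cls = table["change_class"] if "change_class" in table else classify(table, alpha)
    order = ["no_change", "decrease", "increase"]
    rows = {"all": cls.value_counts().reindex(order, fill_value=0)}
    if annotations is not None and "super_pathway" in annotations.columns:
        pathway = annotations["super_pathway"].reindex(cls.index).fillna("Unknown")
        for pw, sub in cls.groupby(pathway):
            rows[str(pw)] = sub.value_counts().reindex(order, fill_value=0)
    out = pd.DataFrame(rows).T[order].astype(int)
    out.index.name = "group"
    return out


def volcano_table(
    table: pd.DataFrame, lower_q: float = 0.025, upper_q: float = 0.975
) -> pd.DataFrame:
    """Volcano-plot table: LFC vs -log10 adjusted P, with metabolites whose
    LFC falls strictly outside the [lower_q, upper_q] LFC quantiles labelled
    extreme. Quantiles use linear interpolation."""
    lfc = table["lfc"].to_numpy(dtype=float)
    lo, hi = np.quantile(lfc, [lower_q, upper_q], method="linear")
    out = table[["lfc", "p_adj"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p_adj"] = -np.log10(out["p_adj"].to_numpy())
    out["extreme_lfc"] = (lfc < lo) | (lfc > hi)
    out.attrs["lfc_quantiles"] = (float(lo), float(hi))
    return out
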