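"""Per-condition metabolite association networks from mutual information.

Pairwise mutual information between metabolites is estimated across
individuals within one condition and indirect edges are pruned with the
data-processing inequality (DPI), the conditioning step of the ARACNE
algorithm: in every triple the weakest edge is the candidate indirect link
and is removed.

Two MI estimators are provided. The default is the Gaussian-copula
(Spearman) estimator: the Spearman correlation r_s (Pearson on ranks) is
mapped to the implied Gaussian correlation r = 2 sin(pi r_s / 6) — the
classical bivariate-normal identity, making the estimator consistent — and
MI = -1/2 ln(1 - r^2). At the study's sample size (8 individuals per
condition) a binned plug-in estimate is extremely noisy, while the
rank-Gaussian form is exactly invariant to monotone transforms and well
behaved at small n. The
binned plug-in estimator (equal-frequency bins, ceil(sqrt(n)) bins) is kept
as an alternative.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DesignError

_R2_CLAMP = 1.0 - 1e-12

ESTIMATORS = ("gaussian_spearman", "binned_empirical")


def _spearman_mi(x: np.ndarray) -> np.ndarray:
    ranks = rankdata(x, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        # corrcoef would return nan; give constant rows harmless ranks and
        # zero their MI afterwards
        ranks[constant] = np.arange(x.shape[1])
    r_s = np.corrcoef(ranks)
    r = 2.0 * np.sin(np.pi * np.clip(r_s, -1.0, 1.0) / 6.0)
    r2 = np.clip(r**2, 0.0, _R2_CLAMP)
    mi = -0.5 * np.log1p(-r2)
    mi[constant, :] = 0.0
    mi[:, constant] = 0.0
    return mi, constant


def _binned_mi(x: np.ndarray) -> np.ndarray:
    g, n = x.shape
    bins = math.ceil(math.sqrt(n))
    # equal-frequency binning via ranks
    labels = np.minimum((rankdata(x, axis=1, method="ordinal") - 1) * bins // n, bins - 1).astype(int)
    sd = x.std(axis=1)
    constant = sd == 0
    mi = np.zeros((g, g))
    for i in range(g):
        li = labels[i]
        for j in range(i + 1, g):
            joint = np.zeros((bins, bins))
            np.add.at(joint, (li, labels[j]), 1.0)
            joint /= n
            pi = joint.sum(axis=1, keepdims=True)
            pj = joint.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = joint * np.log(joint / (pi * pj))
            val = float(np.nansum(term))
            mi[i, j] = mi[j, i] = max(val, 0.0)
    mi[constant, :] = 0.0
    mi[:, constant] = 0.0
    return mi, constant


def pairwise_mi(
    slice_log2: pd.DataFrame,
    estimator: str = "gaussian_spearman",
    unit: str = "nats",
) -> pd.DataFrame:
    """Symmetric metabolite x metabolite MI matrix for one condition slice.

    ``slice_log2`` is metabolites x individuals (log2 intensities; both
    estimators are rank-based so any monotone scale gives the same result).
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    if unit not in ("nats", "bits"):
        raise ValueError("unit must be 'nats' or 'bits'")
    x = slice_log2.to_numpy(dtype=float)
    if x.shape[1] < 4:
        raise DesignError("mutual information needs >= 4 individuals")
    mi, constant = _spearman_mi(x) if estimator == "gaussian_spearman" else _binned_mi(x)
    if constant.any():
        names = list(slice_log2.index[constant])
        warnings.warn(f"constant metabolites, MI set to 0: {names[:5]}")
    np.fill_diagonal(mi, 0.0)
    if unit == "bits":
        mi = mi / math.log(2.0)
    return pd.DataFrame(mi, index=slice_log2.index, columns=slice_log2.index)


@dataclass
class MiNetwork:
    """Weighted undirected metabolite graph after DPI pruning."""

    graph: nx.Graph
    condition: str = ""

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def dpi_kept_edges(mi: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Boolean mask of edges surviving the data-processing inequality.

    Edge (i, j) is dropped iff some third node k satisfies
    MI(i, j) < min(MI(i, k), MI(j, k)) - eps. All decisions are made against
    the original matrix simultaneously, so the result is independent of node
    ordering and idempotent.
    """
    n = mi.shape[0]
    weakest_bound = np.empty((n, n))
    for i in range(n):
        # max over k of min(MI[i,k], MI[j,k]) for all j at once
        weakest_bound[i] = np.minimum(mi[i][None, :], mi).max(axis=1)
    keep = ~(mi < weakest_bound - eps)
    np.fill_diagonal(keep, False)
    return keep


def dpi_prune(
    mi: pd.DataFrame, eps: float = 0.0, weight_floor: float = 0.0, condition: str = ""
) -> MiNetwork:
    """ARACNE-style pruning of an MI matrix into a weighted network.

    After the DPI step, edges with weight <= ``weight_floor`` (default 0,
    which also removes exact-zero MI) are dropped. Nodes are retained even
    if isolated.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    m = mi.to_numpy(dtype=float)
    if not np.allclose(m, m.T):
        raise ValueError("MI matrix must be symmetric")
    keep = dpi_kept_edges(m, eps=eps)
    keep &= m > max(weight_floor, 0.0)
    g = nx.Graph(condition=condition)
    g.add_nodes_from(mi.index)
    ii, jj = np.where(np.triu(keep, k=1))
    g.add_weighted_edges_from(
        (mi.index[i], mi.index[j], float(m[i, j])) for i, j in zip(ii, jj)
    )
    return MiNetwork(g, condition=condition)


def network_summary(net: MiNetwork) -> dict[str, float]:
    g = net.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    weights = np.array([d["weight"] for _, _, d in g.edges(data=True)], dtype=float)
    return {
        "condition": net.condition,
        "nodes": n,
        "edges": e,
        "density": e / (n * (n - 1) / 2) if n > 1 else 0.0,
        "weight_min": float(weights.min()) if e else 0.0,
        "weight_median": float(np.median(weights)) if e else 0.0,
        "weight_max": float(weights.max()) if e else 0.0,
    }


def write_network(net: MiNetwork, graphml_path, edges_path) -> None:
    nx.write_graphml(net.graph, graphml_path)
    rows = [
        {"source": u, "target": v, "mi_weight": d["weight"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "mi_weight"]).to_csv(
        edges_path, sep="\t", index=False
    )
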