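"""Multilevel PLS-DA and higher-order SVD of the intensity tensor.

The supervised analysis respects the paired design by first splitting each
subject's pair of log2 profiles into the subject mean and the within-subject
deviations (multilevel decomposition); PLS-DA is then fitted to the
deviations with a +/-1 condition response. The tensor analysis applies the
higher-order SVD: one ordinary SVD per mode unfolding yields orthonormal
factor matrices, and the core tensor is the input contracted against them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.cross_decomposition import PLSRegression

from .dataio import IntensityTensor
from .exceptions import DesignError


def multilevel_center(tensor: IntensityTensor) -> tuple[pd.DataFrame, pd.Series]:
    """Within-subject deviation matrix of log2 intensities.

    Returns (X, y): X is samples x metabolites (condition-major sample order,
    each sample's log2 profile minus its subject's mean over the two
    conditions) and y the condition label per sample. With two conditions the
    deviations are exactly +/- half the paired difference, so per-subject sums
    are zero for every metabolite.
    """
    logv = tensor.log2_values()  # (G, I, 2)
    dev = logv - logv.mean(axis=2, keepdims=True)
    # stack to samples x metabolites, post-absorptive block first
    x = np.concatenate([dev[:, :, 0].T, dev[:, :, 1].T], axis=0)
    samples = tensor.sample_ids()
    labels = [cond for cond in tensor.conditions for _ in tensor.individual_ids]
    X = pd.DataFrame(x, index=samples, columns=tensor.metabolite_ids)
    return X, pd.Series(labels, index=samples, name="condition")


@dataclass
class PlsdaModel:
    """Fitted two-class PLS-DA on within-subject deviations."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # metabolites x components, unit-norm columns
    explained_variance: np.ndarray  # fraction of X variance per component
    centroids: pd.DataFrame  # condition x components
    ellipses: dict[str, dict] = field(default_factory=dict)  # 95% normal ellipses


def _ellipse_params(points: np.ndarray, coverage: float = 0.95) -> dict:
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    r = chi2.ppf(coverage, df=2)
    return {
        "center": center,
        "cov": cov,
        "semi_axes": np.sqrt(np.maximum(evals, 0.0) * r),
        "angle_rad": float(np.arctan2(evecs[1, -1], evecs[0, -1])),
        "coverage": coverage,
    }


def ellipse_contains(ellipse: dict, point: np.ndarray) -> bool:
    """Whether a point lies inside the coverage ellipse (Mahalanobis test)."""
    diff = np.asarray(point) - ellipse["center"]
    cov = np.atleast_2d(ellipse["cov"])
    md2 = float(diff @ np.linalg.solve(cov, diff))
    return md2 <= chi2.ppf(ellipse["coverage"], df=2)


def ellipses_overlap(e1: dict, e2: dict, n_points: int = 720) -> bool:
    """Approximate overlap test: any boundary point of one ellipse inside the
    other, or either center inside the other."""
    for a, b in ((e1, e2), (e2, e1)):
        if ellipse_contains(b, a["center"]):
            return True
        evals, evecs = np.linalg.eigh(np.atleast_2d(a["cov"]))
        radii = np.sqrt(np.maximum(evals, 0.0) * chi2.ppf(a["coverage"], df=2))
        theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
        circle = np.vstack([np.cos(theta), np.sin(theta)]).T
        boundary = a["center"][None, :] + (circle * radii) @ evecs.T
        if any(ellipse_contains(b, pt) for pt in boundary):
            return True
    return False


def plsda_fit(
    X: pd.DataFrame, conditions: pd.Series, n_components: int = 2
) -> PlsdaModel:
    """NIPALS PLS-DA with a single +/-1 dummy response (fasted = +1).

    Loadings are the unit-norm X weights; per-component explained X variance
    is ||t_a p_a^T||^2 / ||X||^2 from the scores and X loadings (recorded as
    computed; PLS maximizes covariance, so the fractions need not decrease).
    Component signs are fixed so the fasted centroid is positive on
    component 1 and, for later components, so the largest-|weight| metabolite
    has a positive weight.
    """
    conditions = conditions.reindex(X.index)
    levels = sorted(conditions.unique())
    if len(levels) < 2:
        raise DesignError("PLS-DA needs both conditions present")
    counts = conditions.value_counts()
    if (counts < 2).any():
        raise DesignError("PLS-DA needs >= 2 samples per condition")
    y = np.where(conditions.to_numpy() == "fasted", 1.0, -1.0)

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X.to_numpy(dtype=float), y)
    scores = pls.x_scores_.copy()
    weights = pls.x_weights_.copy()
    ploads = pls.x_loadings_.copy()

    # deterministic sign convention
    for a in range(n_components):
        if a == 0:
            flip = scores[y == 1.0, 0].mean() < 0
        else:
            j = int(np.argmax(np.abs(weights[:, a])))
            flip = weights[j, a] < 0
        if flip:
            scores[:, a] *= -1
            weights[:, a] *= -1
            ploads[:, a] *= -1

    total_ss = float(np.sum(np.asarray(X, dtype=float) ** 2))
    ev = np.array(
        [
            float(np.sum(scores[:, a] ** 2) * np.sum(ploads[:, a] ** 2)) / total_ss
            if total_ss > 0
            else 0.0
            for a in range(n_components)
        ]
    )

    comp_names = [f"comp{a + 1}" for a in range(n_components)]
    scores_df = pd.DataFrame(scores, index=X.index, columns=comp_names)
    loadings_df = pd.DataFrame(weights, index=X.columns, columns=comp_names)
    centroids = scores_df.groupby(conditions).mean()
    ellipses = {
        str(cond): _ellipse_params(scores_df.loc[conditions == cond, comp_names[:2]].to_numpy())
        for cond in levels
    }
    return PlsdaModel(scores_df, loadings_df, ev, centroids, ellipses)


def select_top_loadings(
    model: PlsdaModel, lower_q: float = 0.05, upper_q: float = 0.95
) -> dict[str, list[str]]:
    """Metabolites whose loading lies strictly outside the per-component
    loading quantiles (linear interpolation)."""
    out: dict[str, list[str]] = {}
    for comp in model.loadings.columns:
        w = model.loadings[comp].to_numpy(dtype=float)
        lo, hi = np.quantile(w, [lower_q, upper_q], method="linear")
        mask = (w < lo) | (w > hi)
        out[comp] = list(model.loadings.index[mask])
    return out


# ---------------------------------------------------------------------------
# Higher-order SVD


@dataclass
class HosvdResult:
    """HOSVD of the (optionally metabolite-centered) log2 tensor."""

    core: np.ndarray
    factors: list[np.ndarray]  # per mode: metabolite, individual, condition
    mode_singular_values: list[np.ndarray]
    contributions: pd.Series  # metabolite -> overall contribution score
    centered: bool


def _unfold(t: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


def _fold(mat: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    full = [shape[mode]] + [s for i, s in enumerate(shape) if i != mode]
    return np.moveaxis(mat.reshape(full), 0, mode)


def mode_product(t: np.ndarray, m: np.ndarray, mode: int) -> np.ndarray:
    """n-mode product of a tensor with a matrix."""
    return _fold(m @ _unfold(t, mode), mode, tuple(
        m.shape[0] if i == mode else s for i, s in enumerate(t.shape)
    ))


def hosvd(tensor: IntensityTensor, center: bool = True) -> HosvdResult:
    """Higher-order SVD of the metabolite x individual x condition log2 tensor.

    Factor matrices are the left singular vectors of each mode unfolding;
    the core is the tensor contracted with their transposes, so the
    untruncated reconstruction is exact. Centering (default) subtracts each
    metabolite's mean over all samples. ``contributions`` are row norms of
    the metabolite factor weighted by the core energy per component,
    sqrt(sum_j U[g, j]^2 * E_j) with E_j the squared norm of core slice j.
    """
    t = tensor.log2_values()
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite values in log2 tensor")
    if center:
        t = t - t.mean(axis=(1, 2), keepdims=True)
    factors: list[np.ndarray] = []
    svals: list[np.ndarray] = []
    for mode in range(3):
        u, s, _ = np.linalg.svd(_unfold(t, mode), full_matrices=False)
        factors.append(u)
        svals.append(s)
    core = t
    for mode, u in enumerate(factors):
        core = mode_product(core, u.T, mode)
    energy = np.sum(core.reshape(core.shape[0], -1) ** 2, axis=1)
    u1 = factors[0]
    contrib = np.sqrt((u1[:, : energy.size] ** 2) @ energy)
    contributions = pd.Series(
        contrib, index=pd.Index(tensor.metabolite_ids, name="metabolite_id"), name="contribution"
    ).sort_values(ascending=False)
    return HosvdResult(core, factors, svals, contributions, centered=center)


def hosvd_reconstruct(result: HosvdResult) -> np.ndarray:
    """Rebuild the (centered) tensor from core and factors."""
    t = result.core
    for mode, u in enumerate(result.factors):
        t = mode_product(t, u, mode)
    return t
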