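"""Network topology: modularity partitioning, eigenvector centrality, module matching.

Modules are found with the leading-eigenvector method: recursive spectral
bisection of the (generalized) modularity matrix B = A - k k^T / 2m, where a
group is split by the sign of B's leading eigenvector and the split is
accepted only if it increases the modularity Q. Determinism conventions:
eigenvector sign is fixed so its first nonzero entry is positive, entries
exactly zero join the positive side, and isolated (zero-strength) nodes form
singleton modules. All computations use the weighted adjacency (MI weights)
unless ``weighted=False``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, NumericalError
from .netinfer import MiNetwork

_SPLIT_TOL = 1e-12


@dataclass
class ModulePartition:
    """Assignment of metabolites to topological modules, with modularity."""

    assignment: pd.Series  # metabolite -> int module label, contiguous from 1
    Q: float
    q_contrib: dict[int, float]  # module -> contribution to Q (sums to Q)
    condition: str = ""

    @property
    def labels(self) -> list[int]:
        return sorted(self.q_contrib)

    def members(self, label: int) -> set[str]:
        return set(self.assignment.index[self.assignment == label])

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    def singleton_labels(self) -> list[int]:
        sizes = self.sizes()
        return sorted(sizes.index[sizes == 1])


def _adjacency(net: MiNetwork, weighted: bool) -> tuple[np.ndarray, list[str]]:
    import networkx as nx

    nodes = list(net.graph.nodes)
    a = nx.to_numpy_array(net.graph, nodelist=nodes, weight="weight" if weighted else None)
    return a, nodes


def _leading_eigvec(b: np.ndarray) -> tuple[float, np.ndarray]:
    evals, evecs = np.linalg.eigh(b)
    v = evecs[:, -1]
    nz = np.nonzero(v)[0]
    if nz.size and v[nz[0]] < 0:
        v = -v
    return float(evals[-1]), v


def leading_eigenvector_partition(
    net: MiNetwork, weighted: bool = True
) -> ModulePartition:
    """Recursive leading-eigenvector modularity partition of one network."""
    a, nodes = _adjacency(net, weighted)
    n = len(nodes)
    labels = np.zeros(n, dtype=int)
    if n == 0:
        return ModulePartition(
            pd.Series(dtype=int, name="module"), 0.0, {}, net.condition
        )
    k = a.sum(axis=1)
    m2 = float(k.sum())  # 2m
    isolated = np.where(k == 0)[0]
    connected = np.where(k > 0)[0]

    next_label = 0
    if m2 > 0 and connected.size:
        b = a - np.outer(k, k) / m2
        groups: list[np.ndarray] = [connected]
        final: list[np.ndarray] = []
        while groups:
            g = groups.pop()
            if g.size == 1:
                final.append(g)
                continue
            bg = b[np.ix_(g, g)]
            bg = bg - np.diag(bg.sum(axis=1))  # generalized modularity matrix
            _, v = _leading_eigvec(bg)
            s = np.where(v >= 0, 1.0, -1.0)  # zeros join the positive group
            if np.all(s == s[0]):
                final.append(g)
                continue
            dq = float(s @ bg @ s) / (2.0 * m2)
            if dq <= _SPLIT_TOL:
                final.append(g)
                continue
            groups.append(g[s > 0])
            groups.append(g[s < 0])
        # deterministic label order: by smallest member index
        for g in sorted(final, key=lambda idx: idx.min()):
            next_label += 1
            labels[g] = next_label
    elif connected.size:
        next_label += 1
        labels[connected] = next_label
    for i in isolated:  # singleton modules, in node order
        next_label += 1
        labels[i] = next_label

    assignment = pd.Series(labels, index=pd.Index(nodes, name="metabolite_id"), name="module")
    q_contrib: dict[int, float] = {}
    for lab in range(1, next_label + 1):
        idx = np.where(labels == lab)[0]
        if m2 > 0:
            sub = a[np.ix_(idx, idx)].sum() / m2
            deg = k[idx].sum() / m2
            q_contrib[lab] = float(sub - deg**2)
        else:
            q_contrib[lab] = 0.0
    q = float(sum(q_contrib.values()))
    return ModulePartition(assignment, q, q_contrib, net.condition)


def modularity(net: MiNetwork, assignment: pd.Series, weighted: bool = True) -> float:
    """Modularity Q of an arbitrary assignment on a network's adjacency."""
    a, nodes = _adjacency(net, weighted)
    k = a.sum(axis=1)
    m2 = float(k.sum())
    if m2 == 0:
        return 0.0
    lab = assignment.reindex(nodes).to_numpy()
    same = lab[:, None] == lab[None, :]
    return float(((a - np.outer(k, k) / m2) * same).sum() / m2)


def eigenvector_centrality(
    net: MiNetwork, weighted: bool = True, tol: float = 1e-12, max_iter: int = 10**6
) -> pd.Series:
    """Eigenvector centrality, non-negative and max-normalized to 1.

    Computed per connected component as the Perron eigenvector of the
    (weighted) adjacency; components are then placed on a common scale by
    weighting each component's unit-max vector by the ratio of its dominant
    eigenvalue to the global one, so the dominant component attains 1 and
    weaker components score proportionally lower. Isolated nodes get 0.
    """
    import networkx as nx

    a, nodes = _adjacency(net, weighted)
    n = len(nodes)
    cent = np.zeros(n)
    if n == 0:
        return pd.Series(dtype=float, name="centrality")
    index_of = {node: i for i, node in enumerate(nodes)}
    comp_data = []
    for comp in nx.connected_components(net.graph):
        idx = np.array(sorted(index_of[c] for c in comp))
        if idx.size == 1:
            comp_data.append((idx, 0.0, np.zeros(1)))
            continue
        sub = a[np.ix_(idx, idx)]
        lam, v = _leading_eigvec(sub)
        v = np.abs(v)  # Perron vector of a connected non-negative matrix
        resid = float(np.linalg.norm(sub @ v - lam * v))
        if resid > max(tol, 1e-9) * max(np.linalg.norm(v), 1.0) * max(abs(lam), 1.0):
            raise NumericalError(
                f"eigenvector centrality did not converge (residual {resid:.2e})"
            )
        vmax = v.max()
        comp_data.append((idx, lam, v / vmax if vmax > 0 else v))
    lam_max = max((lam for _, lam, _ in comp_data), default=0.0)
    for idx, lam, v in comp_data:
        scale = lam / lam_max if lam_max > 0 else 0.0
        cent[idx] = v * scale
    return pd.Series(cent, index=pd.Index(nodes, name="metabolite_id"), name="centrality")


def centrality_table(c_post: pd.Series, c_fasted: pd.Series) -> pd.DataFrame:
    """Per-metabolite centralities for both conditions and the paired change."""
    if set(c_post.index) != set(c_fasted.index):
        raise AlignmentError("centrality series cover different metabolite sets")
    out = pd.DataFrame(
        {"c_post": c_post, "c_fasted": c_fasted.reindex(c_post.index)}
    )
    out["delta_c"] = out["c_fasted"] - out["c_post"]
    return out


@dataclass
class ModuleMatch:
    """Best-overlap mapping of fasted modules onto post-absorptive modules."""

    mapping: dict[int, int]  # fasted label -> post label
    jaccard: dict[int, float]  # fasted label -> best Jaccard
    membership_changed: pd.Series  # metabolite -> bool


def jaccard_matrix(p_a: ModulePartition, p_b: ModulePartition) -> pd.DataFrame:
    """Full Jaccard overlap matrix, rows = modules of a, columns = modules of b."""
    rows = {}
    for la in p_a.labels:
        ma = p_a.members(la)
        rows[la] = {
            lb: len(ma & p_b.members(lb)) / len(ma | p_b.members(lb)) for lb in p_b.labels
        }
    return pd.DataFrame(rows).T.sort_index()


def match_modules(p_post: ModulePartition, p_fast: ModulePartition) -> ModuleMatch:
    """Map each fasted module to its maximal-Jaccard post-absorptive module.

    Ties break toward the smaller baseline label. A metabolite is flagged as
    having changed membership iff its post-absorptive module differs from the
    module its fasted module maps to.
    """
    if set(p_post.assignment.index) != set(p_fast.assignment.index):
        raise AlignmentError("partitions cover different metabolite sets")
    mapping: dict[int, int] = {}
    jac: dict[int, float] = {}
    for lf in p_fast.labels:
        mf = p_fast.members(lf)
        best_lab, best_j = None, -1.0
        for lp in p_post.labels:  # ascending labels: ties keep the smaller
            j = len(mf & p_post.members(lp)) / len(mf | p_post.members(lp))
            if j > best_j:
                best_lab, best_j = lp, j
        mapping[lf] = int(best_lab)
        jac[lf] = best_j
    mapped = p_fast.assignment.map(mapping)
    changed = mapped != p_post.assignment.reindex(p_fast.assignment.index)
    changed.name = "membership_changed"
    return ModuleMatch(mapping, jac, changed)
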