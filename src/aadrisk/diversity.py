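"""Alpha/beta diversity, ordination, permutation testing and baseline
hierarchical clustering, implemented from the defining formulas.

Shannon entropy and the Jensen-Shannon distance use base-2 logarithms, so
entropy is in bits and the distance lies in [0, 1].  PCoA is classical
scaling (Gower double-centering); PERMANOVA uses the pseudo-F statistic
with seeded label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "ClusterAssignment",
    "shannon",
    "jensen_shannon_distance",
    "bray_curtis",
    "pairwise_distances",
    "pcoa",
    "permanova",
    "cluster_baseline",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise sample distances with zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if d.shape[0] != len(self.ids):
            raise ValueError("ids length does not match matrix size")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have zero diagonal")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.data = (d + d.T) / 2.0
        np.fill_diagonal(self.data, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p: float
    n_permutations: int


@dataclass
class ClusterAssignment:
    clusters: pd.Series  # subject -> contiguous cluster ID (1-based)
    linkage: np.ndarray  # scipy linkage record


def _check_prob(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("relative abundances must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError(f"vector must sum to 1 (got {p.sum():.6g})")
    return p


def shannon(p, base: float = 2.0) -> float:
    """Shannon entropy H = -sum p_i log p_i, with 0 log 0 = 0 (bits)."""
    p = _check_prob(p)
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(base))).sum())


def jensen_shannon_distance(p, q) -> float:
    """sqrt of the Jensen-Shannon divergence (base-2 logs), in [0, 1]."""
    p = _check_prob(p)
    q = _check_prob(q)
    if p.shape != q.shape:
        raise ValueError("vectors must have equal length")
    m = (p + q) / 2.0
    div = shannon(m) - 0.5 * shannon(p) - 0.5 * shannon(q)
    return float(np.sqrt(max(div, 0.0)))


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) for count or
    abundance vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("vectors must be non-negative")
    denom = (u + v).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(u - v).sum() / denom)


def pairwise_distances(values: pd.DataFrame, metric: str = "braycurtis") -> DissimilarityMatrix:
    """All pairwise distances between the columns (samples) of ``values``.

    metric: "braycurtis" (raw counts or abundances) or "jensenshannon"
    (columns are normalized to sum to 1 first).
    """
    ids = list(values.columns)
    mat = values.to_numpy(dtype=float)
    n = len(ids)
    if metric == "jensenshannon":
        mat = mat / mat.sum(axis=0)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "braycurtis":
                d[i, j] = bray_curtis(mat[:, i], mat[:, j])
            elif metric == "jensenshannon":
                d[i, j] = jensen_shannon_distance(mat[:, i], mat[:, j])
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[j, i] = d[i, j]
    return DissimilarityMatrix(ids, d)


def pcoa(dm: DissimilarityMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical scaling: double-center -d^2/2, eigendecompose, scale
    eigenvectors by sqrt of the positive eigenvalues.

    Negative eigenvalues (from non-Euclidean input) are excluded from both
    the axes and the proportion-explained denominator.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d = dm.data
    n = d.shape[0]
    b = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ b @ centering
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0.0) * 1e-12 if evals.size else evals > 0
    evals_pos = evals[pos]
    evecs_pos = evecs[:, pos]
    k = min(n_axes, evals_pos.size)
    coords = evecs_pos[:, :k] * np.sqrt(evals_pos[:k])
    if k < n_axes:
        coords = np.hstack([coords, np.zeros((n, n_axes - k))])
    total = evals_pos.sum()
    prop = (evals_pos[:n_axes] / total) if total > 0 else np.zeros(min(n_axes, evals_pos.size))
    if prop.size < n_axes:
        prop = np.concatenate([prop, np.zeros(n_axes - prop.size)])
    return OrdinationResult(
        pd.DataFrame(coords, index=dm.ids,
                     columns=[f"PCoA{i + 1}" for i in range(n_axes)]),
        evals_pos,
        prop,
    )


def _permanova_ss_within(d2: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += sub.sum() / (2.0 * len(idx))
    return ss


def permanova(dm: DissimilarityMatrix, groups, n_permutations: int = 9999,
              seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_among/(g-1)) / (SS_within/(N-g)); the p-value is
    (1 + #{permuted F >= observed}) / (n_permutations + 1), so it can
    never be exactly zero.
    """
    groups = np.asarray(groups)
    n = dm.data.shape[0]
    if len(groups) != n:
        raise ValueError("groups length must match matrix size")
    uniq = np.unique(groups)
    g = len(uniq)
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    d2 = dm.data ** 2
    ss_total = d2.sum() / (2.0 * n)

    def pseudo_f(lbl: np.ndarray) -> float:
        ss_w = _permanova_ss_within(d2, lbl)
        ss_a = ss_total - ss_w
        return (ss_a / (g - 1)) / (ss_w / (n - g))

    f_obs = pseudo_f(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if pseudo_f(rng.permutation(groups)) >= f_obs:
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return PermanovaResult(float(f_obs), float(p), n_permutations)


def correlation_distance(profiles: pd.DataFrame) -> DissimilarityMatrix:
    """1 - Pearson correlation between the rows (subjects) of ``profiles``."""
    mat = profiles.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if len(flat):
        raise ValueError(
            f"zero-variance profile(s): {list(profiles.index[flat])}"
        )
    d = 1.0 - np.corrcoef(mat)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return DissimilarityMatrix(list(profiles.index), d)


def cluster_baseline(profiles: pd.DataFrame, threshold: float = 0.4) -> ClusterAssignment:
    """Average-linkage clustering of subjects on correlation distance.

    ``profiles``: subjects x features baseline abundances.  Clusters are
    the connected groups obtained by cutting the dendrogram at cophenetic
    distance <= ``threshold`` (0.4 by default).
    """
    dm = correlation_distance(profiles)
    if len(dm.ids) == 1:
        return ClusterAssignment(
            pd.Series([1], index=pd.Index(dm.ids, name="subject_id")),
            np.zeros((0, 4)),
        )
    z = _average_linkage(squareform(dm.data, checks=False))
    labels = fcluster(z, t=threshold, criterion="distance")
    # relabel contiguously in order of first appearance
    remap: dict[int, int] = {}
    out = []
    for lbl in labels:
        if lbl not in remap:
            remap[lbl] = len(remap) + 1
        out.append(remap[lbl])
    return ClusterAssignment(
        pd.Series(out, index=pd.Index(dm.ids, name="subject_id")), z
    )
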