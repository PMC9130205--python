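"""Distance matrices, matrix correlation, Mantel test and graph summaries.

Population relationships derived from haplogroup-frequency vectors are
validated against an external reference distance matrix (typically pairwise
Fst computed upstream).  Frequency vectors are compared by unweighted
Euclidean distance

    d_mn = sqrt( sum_k (h_mk - h_nk)**2 )

and two distance matrices are compared by the Pearson correlation of their
off-diagonal upper triangles, with significance from a Mantel permutation
test (rows and columns of one matrix permuted jointly; one-sided p with the
+1 correction, so p can never be exactly zero).

Graph summaries for a set of central vectors: classical metric MDS
coordinates, edges below a fraction of the maximal distance, and the
minimum spanning tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import csgraph_from_dense
from scipy.sparse.csgraph import minimum_spanning_tree as _csgraph_mst
from scipy.spatial.distance import pdist, squareform

from .freqmatrix import FrequencyMatrix

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "euclidean_matrix",
    "matrix_correlation",
    "mantel_test",
    "mds_embedding",
    "threshold_edges",
    "minimum_spanning_tree",
    "read_distance_csv",
    "write_distance_csv",
    "read_phylip",
    "write_phylip",
]


@dataclass
class DistanceMatrix:
    """Labeled square symmetric distance matrix with zero diagonal."""

    values: pd.DataFrame

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric (1e-12)")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        if list(self.values.index) != list(self.values.columns):
            raise ValueError("row and column labels must match")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def reordered(self, labels: Sequence[str]) -> "DistanceMatrix":
        missing = set(labels) - set(self.labels)
        if missing:
            raise ValueError("labels not in matrix: " + ", ".join(sorted(missing)))
        return DistanceMatrix(self.values.loc[list(labels), list(labels)])

    @classmethod
    def from_array(cls, values, labels: Sequence[str]) -> "DistanceMatrix":
        arr = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        return cls(pd.DataFrame(arr, index=labels, columns=labels))


@dataclass
class MantelResult:
    """Observed matrix correlation and its one-sided permutation p-value."""

    r_observed: float
    p_value: float
    n_permutations: int
    seed: Optional[int]


def euclidean_matrix(freq: Union[FrequencyMatrix, pd.DataFrame]) -> DistanceMatrix:
    """Unweighted Euclidean distances between population frequency vectors.

    Unusable (fully unclassified) populations are excluded with a warning.
    """
    if isinstance(freq, FrequencyMatrix):
        if freq.unusable_populations:
            warnings.warn(
                "excluding unusable populations: "
                + ", ".join(map(str, freq.unusable_populations)),
                stacklevel=2,
            )
        values = freq.usable_values()
    else:
        values = freq
    if len(values) < 2:
        raise ValueError("need at least 2 usable populations")
    d = squareform(pdist(values.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix.from_array(d, list(values.index))


def _common_triangles(
    d1: DistanceMatrix, d2: DistanceMatrix
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    common = [lab for lab in d1.labels if lab in set(d2.labels)]
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} shared labels between matrices; need >= 3"
        )
    a = d1.reordered(common).to_numpy()
    b = d2.reordered(common).to_numpy()
    iu = np.triu_indices(len(common), k=1)
    return a[iu], b[iu], common


def matrix_correlation(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Pearson correlation of two distance matrices over the off-diagonal
    upper triangle; labels are intersected and reordered automatically."""
    x, y, _ = _common_triangles(d1, d2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: constant distances")
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 9999,
    seed: Optional[int] = None,
) -> MantelResult:
    """One-sided Mantel permutation test of association between two
    distance matrices.

    Rows and columns of ``d2`` are permuted jointly; the p-value is
    ``(1 + #{r_perm >= r_obs}) / (1 + n_permutations)``.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    common = [lab for lab in d1.labels if lab in set(d2.labels)]
    if len(common) < 3:
        raise ValueError("need >= 3 shared labels")
    a = d1.reordered(common).to_numpy()
    b = d2.reordered(common).to_numpy()
    n = len(common)
    iu = np.triu_indices(n, k=1)
    x = a[iu]
    if np.ptp(x) == 0 or np.ptp(b[iu]) == 0:
        raise ValueError("correlation undefined: constant distances")
    # standardize x once; correlation = mean(zx * zy)
    zx = (x - x.mean()) / x.std()
    y = b[iu]
    zy = (y - y.mean()) / y.std()
    r_obs = float(np.mean(zx * zy))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = b[perm][:, perm][iu]
        zyp = (yp - yp.mean()) / yp.std()
        if float(np.mean(zx * zyp)) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(
        r_observed=r_obs,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


def mds_embedding(d: DistanceMatrix, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric multidimensional scaling.

    Double-centers the squared distances and takes the top ``dims``
    eigenpairs; negative eigenvalues (non-Euclidean input) are truncated
    with a warning.
    """
    n = len(d)
    if not 0 < dims < n:
        raise ValueError(f"dims must be in [1, {n - 1}], got {dims}")
    D2 = d.to_numpy() ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if (evals[:dims] < -1e-9 * max(1.0, abs(evals[0]))).any():
        warnings.warn(
            "non-Euclidean distances: negative eigenvalues truncated",
            stacklevel=2,
        )
    lam = np.clip(evals[:dims], 0.0, None)
    coords = evecs[:, :dims] * np.sqrt(lam)
    return pd.DataFrame(
        coords,
        index=d.labels,
        columns=[f"dim{i + 1}" for i in range(dims)],
    )


def threshold_edges(
    d: DistanceMatrix, fraction: float = 0.35
) -> list[tuple[str, str, float]]:
    """Edges (i, j, d_ij) with distance strictly below ``fraction`` times
    the maximal distance."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    v = d.to_numpy()
    labels = d.labels
    cutoff = fraction * v.max()
    edges = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if v[i, j] < cutoff:
                edges.append((labels[i], labels[j], float(v[i, j])))
    return edges


def minimum_spanning_tree(d: DistanceMatrix) -> list[tuple[str, str, float]]:
    """Minimum spanning tree over the complete distance graph: n - 1 edges
    connecting all labels with minimal total weight."""
    if len(d) < 2:
        raise ValueError("need at least 2 labels")
    # null_value=inf keeps genuine zero distances as edges
    graph = csgraph_from_dense(d.to_numpy(), null_value=np.inf)
    mst = _csgraph_mst(graph).tocoo()
    labels = d.labels
    edges = [
        (labels[min(i, j)], labels[max(i, j)], float(w))
        for i, j, w in zip(mst.row, mst.col, mst.data)
    ]
    return sorted(edges)


def write_distance_csv(d: DistanceMatrix, path) -> None:
    d.values.to_csv(path, index_label="")


def read_distance_csv(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(df)


def write_phylip(d: DistanceMatrix, path) -> None:
    """PHYLIP-style square matrix: first line n, then one row per label."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(d)}\n")
        v = d.to_numpy()
        for lab, row in zip(d.labels, v):
            fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def read_phylip(path) -> DistanceMatrix:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    if len(rows) != n:
        raise ValueError(f"expected {n} rows, found {len(rows)}")
    return DistanceMatrix.from_array(np.asarray(rows), labels)
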