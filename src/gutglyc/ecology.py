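"""Community-level regional comparison: Bray-Curtis, PCoA, PERMANOVA.

The regional comparison asks whether gut microbial composition differs
between the Northern and Southern populations: a Bray-Curtis dissimilarity
matrix over genus profiles, classical principal-coordinates ordination for
visualisation, and a seeded permutation test (PERMANOVA pseudo-F) for
significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import GenusAbundanceTable


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarity with participant labels."""

    participant_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.participant_ids):
            raise ValueError("dissimilarity matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix not symmetric")
        if np.abs(np.diag(v)).max() > 1e-12:
            raise ValueError("dissimilarity diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.participant_ids, columns=self.participant_ids
        )


def bray_curtis(table: GenusAbundanceTable) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity: d(x, y) = sum|x_i - y_i| / sum(x_i + y_i).

    All-zero abundance rows are undefined under Bray-Curtis and raise an
    error naming the participant.
    """
    X = table.values
    sums = X.sum(axis=1)
    if (sums <= 0).any():
        bad = table.participant_ids[int(np.argmax(sums <= 0))]
        raise ValueError(f"all-zero abundance row for participant {bad!r}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DissimilarityMatrix(list(table.participant_ids), d)


def pcoa(d: DissimilarityMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical principal-coordinates analysis (metric MDS).

    Eigendecomposition of the double-centred ``-D^2/2`` matrix. Axes are
    ordered by eigenvalue; negative eigenvalues (which arise because
    Bray-Curtis is non-Euclidean) are excluded both from the returned axes
    and from the explained-variance denominator. The sign of each axis is
    fixed by making its largest-magnitude coordinate positive.

    Returns ``(coordinates, explained)`` - an n x k DataFrame indexed by
    participant and the explained-variance fractions per returned axis. If
    fewer than ``k`` positive eigenvalues exist, the result is truncated
    with a warning.
    """
    n = d.n
    if k > n - 1:
        raise ValueError("k must be at most n - 1")
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10 * max(eigval.max(), 1.0)
    n_pos = int(pos.sum())
    if k > n_pos:
        import warnings

        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating from k={k}",
            stacklevel=2,
        )
        k = n_pos
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    for j in range(k):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    explained = eigval[:k] / eigval[pos].sum()
    cols = [f"PCoA{j + 1}" for j in range(k)]
    return pd.DataFrame(coords, index=d.participant_ids, columns=cols), explained


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from squared distances and group labels.

    SS_total = sum of all pairwise d^2 / N; SS_within = sum over groups of
    within-group pairwise d^2 / n_g; F = (SS_between/(a-1)) / (SS_within/(N-a)).
    """
    n = d2.shape[0]
    groups, inv = np.unique(labels, return_inverse=True)
    a = len(groups)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(a):
        idx = np.flatnonzero(inv == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permutation_test(
    d: DissimilarityMatrix,
    groups,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA of a dissimilarity matrix.

    Computes the PERMANOVA pseudo-F for the observed grouping, then
    permutes the labels as a whole ``n_perm`` times (seeded) and reports
    the add-one permutation p-value
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``, whose floor is
    ``1/(1 + n_perm)``.
    """
    labels = np.asarray(groups)
    if len(labels) != d.n:
        raise ValueError("group labels do not match matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    d2 = d.values**2
    f_obs = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _pseudo_f(d2, perm) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(f_obs), float(p)
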