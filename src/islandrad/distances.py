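"""Patristic distance matrices and clade branch-length samples.

On an ultrametric chronogram the cophenetic (patristic) distance between two
tips equals twice the age of their MRCA, so the distance matrix is a direct
readout of divergence times.  Clade branch-length distributions — the edge
lengths inside a clade's crown subtree — are the raw material for the
diversification-tempo contrast: a clade whose diversification is a recent
burst has many short terminal edges and a few long stems, which skews the
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .chronogram import Chronogram, _leaf_label

__all__ = [
    "DistanceMatrix",
    "BranchLengthSample",
    "cophenetic_distances",
    "clade_branch_lengths",
    "sample_skewness",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric tip-to-tip patristic distance matrix in my."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n) float

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self) -> str:
        return self.to_dataframe().to_csv()


def cophenetic_distances(chronogram: Chronogram) -> DistanceMatrix:
    """Full matrix of tip-to-tip path lengths along the tree, in my.

    On an ultrametric tree ``d(i, j) = 2 * age(MRCA(i, j))``.
    """
    pdm = chronogram.tree.phylogenetic_distance_matrix()
    labels = chronogram.tip_labels
    taxa = {t.label: t for t in chronogram.tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels=labels, values=out)


@dataclass(frozen=True)
class BranchLengthSample:
    """Edge lengths (my) of a clade's subtree, for tempo contrasts."""

    clade_id: str
    lengths: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=float))
        if np.any(self.lengths <= 0):
            raise ValueError("branch lengths must be strictly positive")

    def __len__(self) -> int:
        return len(self.lengths)

    def to_csv(self) -> str:
        return pd.Series(self.lengths, name="branch_length_my").to_csv(index=False)


def clade_branch_lengths(
    chronogram: Chronogram,
    clade_tips: set[str] | list[str] | tuple[str, ...],
    *,
    include_stem: bool = False,
    clade_id: str | None = None,
) -> BranchLengthSample:
    """Branch lengths of every edge inside the clade spanned by ``clade_tips``.

    The tip set must be monophyletic (exactly the leaf set of its MRCA).  The
    clade's stem edge — the branch subtending the crown node — predates crown
    diversification and is excluded unless ``include_stem`` is set.
    """
    tips = set(clade_tips)
    node = chronogram.mrca(tips)
    members = set(chronogram.clade_tip_labels(node))
    if members != tips:
        raise ValueError(
            "tip set is not monophyletic: MRCA also spans "
            f"{sorted(members - tips)}"
        )
    lengths: list[float] = []
    for desc in node.preorder_iter():
        if desc is node:
            continue
        lengths.append(desc.edge.length)
    if include_stem and node is not chronogram.root:
        lengths.append(node.edge.length)
    return BranchLengthSample(
        clade_id=clade_id or "+".join(sorted(tips)[:2]),
        lengths=np.array(lengths),
    )


def sample_skewness(x, *, adjusted: bool = False) -> float:
    """Fisher–Pearson sample skewness g1 = m3 / m2^(3/2).

    ``m_k`` is the k-th central sample moment.  With ``adjusted=True`` the
    small-sample corrected statistic G1 = g1 * sqrt(n(n-1)) / (n-2) is
    returned.  Requires at least three observations and nonzero variance.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("skewness needs a 1-d sample of length >= 3")
    if np.isclose(np.var(x), 0.0):
        raise ValueError("skewness undefined for a (near-)constant sample")
    return float(stats.skew(x, bias=not adjusted))
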