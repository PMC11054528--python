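"""Scale-comparison chemometrics: correlation matrices, minimum-descriptor
census, pairwise disparities, hierarchical clustering and PCA.

Computed LogP scales disagree with one another and, more so, with
chromatographically measured lipophilicity; these tools quantify that
disagreement. The clustering objects are the *index columns* (lipophilicity
scales / chromatographic indices), each represented by its vector of values
over the compounds, standardized first so scale units do not dominate;
Ward linkage (Ward.D2 convention: Euclidean input, squared update) with
Euclidean distances is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from ._util import round_half_away
from .datasets import COMPUTED_LOGP_SCALES, load_table1, load_table3

__all__ = [
    "IndexTable",
    "Dendrogram",
    "build_fixture_index_table",
    "correlation_matrix",
    "min_descriptor_census",
    "pairwise_disparity",
    "hca",
    "pca",
    "PCAResult",
]


@dataclass
class IndexTable:
    """Compounds x lipophilicity/affinity indices, with column origins.

    ``origins`` maps each column to ``"computed"`` or ``"experimental"``.
    """

    frame: pd.DataFrame
    origins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicate index column names")


def build_fixture_index_table() -> IndexTable:
    """Combine the bundled tables into one index table: the ten computed
    LogP columns plus the experimental CHI LogP, CHI_IAM and logK_HSA."""
    t1, t3 = load_table1(), load_table3()
    data = {s: [r.computed_logp[s] for r in t1] for s in COMPUTED_LOGP_SCALES}
    data["CHI_LogP"] = [r.chi_logp for r in t1]
    data["CHI_IAM"] = [r.chi_iam for r in t3]
    data["LogK_HSA"] = [r.logk_hsa for r in t3]
    frame = pd.DataFrame(data, index=[r.compound_id for r in t1])
    frame.index.name = "compound_id"
    origins = {s: "computed" for s in COMPUTED_LOGP_SCALES}
    origins.update({"CHI_LogP": "experimental", "CHI_IAM": "experimental", "LogK_HSA": "experimental"})
    return IndexTable(frame, origins)


def _frame(table: IndexTable | pd.DataFrame) -> pd.DataFrame:
    return table.frame if isinstance(table, IndexTable) else table


def correlation_matrix(table: IndexTable | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the index columns (symmetric, unit
    diagonal). Errors out naming any constant column."""
    frame = _frame(table)
    if len(frame) < 3:
        raise ValueError("need at least 3 compounds for correlations")
    constant = frame.columns[frame.std(ddof=1) == 0].tolist()
    if constant:
        raise ValueError(f"constant columns have undefined correlation: {constant}")
    return frame.corr(method="pearson")


def min_descriptor_census(
    table: IndexTable | pd.DataFrame, columns: tuple[str, ...] = COMPUTED_LOGP_SCALES
) -> dict[str, float]:
    """Count, per scale, the compounds for which it is the row minimum.

    Exact ties are split fractionally among the minimizing scales (none
    occur in the bundled data), so counts always sum to the row count.
    """
    frame = _frame(table)[list(columns)]
    census = dict.fromkeys(columns, 0.0)
    for _, row in frame.iterrows():
        lo = row.min()
        winners = row.index[row == lo]
        for w in winners:
            census[w] += 1.0 / len(winners)
    return census


def pairwise_disparity(
    table: IndexTable | pd.DataFrame, compound_id, scale_a: str, scale_b: str
) -> float:
    """Absolute difference between two scales for one compound, rounded to
    2 decimals for reporting."""
    frame = _frame(table)
    for s in (scale_a, scale_b):
        if s not in frame.columns:
            raise KeyError(f"unknown scale: {s!r}")
    row = frame.loc[compound_id]
    return round_half_away(abs(float(row[scale_a]) - float(row[scale_b])), 2)


@dataclass
class Dendrogram:
    """Agglomerative clustering result over index columns.

    ``linkage`` is a scipy linkage matrix; ``heights`` (Ward distances) are
    non-decreasing along the merge sequence.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into k clusters (labels -> cluster id)."""
        if k > len(self.labels):
            raise ValueError(f"cannot cut {len(self.labels)} leaves into {k} clusters")
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assignment)))

    def to_newick(self) -> str:
        """Serialize to newick text (heights as branch lengths)."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree)


def hca(
    table: IndexTable | pd.DataFrame,
    standardize_first: bool = True,
    objects: str = "columns",
) -> Dendrogram:
    """Ward/Euclidean hierarchical clustering of index columns.

    Columns are standardized (z-scores over compounds) before clustering so
    differently scaled indices are comparable; set ``objects="rows"`` to
    cluster compounds instead.
    """
    frame = _frame(table)
    if standardize_first:
        sd = frame.std(ddof=1)
        constant = frame.columns[sd == 0].tolist()
        if constant:
            raise ValueError(f"constant columns cannot be standardized: {constant}")
        frame = (frame - frame.mean()) / sd
    if objects == "columns":
        data, labels = frame.to_numpy(dtype=float).T, [str(c) for c in frame.columns]
    elif objects == "rows":
        data, labels = frame.to_numpy(dtype=float), [str(i) for i in frame.index]
    else:
        raise ValueError(f"objects must be 'columns' or 'rows', got {objects!r}")
    if len(labels) < 2:
        raise ValueError("need at least 2 objects to cluster")
    Z = hierarchy.linkage(data, method="ward", metric="euclidean")
    return Dendrogram(linkage=Z, labels=labels)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # compounds x components
    loadings: pd.DataFrame  # columns x components, orthonormal
    explained_variance_ratio: np.ndarray


def pca(table: IndexTable | pd.DataFrame, standardize_first: bool = True) -> PCAResult:
    """Principal component analysis of the index table (SVD based).

    Columns are standardized by default (PCA on the correlation matrix).
    Loadings are orthonormal with a fixed sign convention (the largest-
    magnitude element of each loading vector is positive); scores times
    loadings' transpose reconstructs the centered/standardized data.
    """
    frame = _frame(table)
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise ValueError("PCA needs at least 2 compounds and 2 columns")
    sd = frame.std(ddof=1)
    constant = frame.columns[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant columns: {constant}")
    X = (frame - frame.mean()) / sd if standardize_first else frame - frame.mean()
    U, s, Vt = np.linalg.svd(X.to_numpy(dtype=float), full_matrices=False)
    # sign convention: largest-|.| loading element positive
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = s**2
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(U * s, index=frame.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=frame.columns, columns=comp_names),
        explained_variance_ratio=var / var.sum(),
    )
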