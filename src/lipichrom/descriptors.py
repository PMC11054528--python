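"""Molecular-descriptor matrix loading and pre-filtering.

Descriptor matrices (compounds x named descriptors, computed externally by
tools such as AlvaDesc, Chemicalize or SwissADME) are pruned before model
building: constant and near-constant columns carry no information and
highly inter-correlated columns destabilize regression, so both are
removed, and the survivors are standardized to column z-scores.

Matrices are plain :class:`pandas.DataFrame` objects (index = compound ids,
columns = descriptor names); :class:`DescriptorMatrix` optionally attaches
block labels (e.g. "RDF descriptors", "CATS 3D", "Drug-like indices").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorMatrix",
    "read_descriptor_csv",
    "filter_constant",
    "filter_correlated",
    "standardize",
]


@dataclass
class DescriptorMatrix:
    """A descriptor matrix with optional per-descriptor block labels."""

    frame: pd.DataFrame
    blocks: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate(self.frame)

    @property
    def compound_ids(self) -> list:
        return list(self.frame.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)


def _validate(frame: pd.DataFrame) -> None:
    if frame.columns.duplicated().any():
        dupes = sorted(set(frame.columns[frame.columns.duplicated()]))
        raise ValueError(f"duplicate descriptor names: {dupes}")
    values = frame.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = frame.columns[~np.isfinite(values).all(axis=0)].tolist()
        raise ValueError(f"non-finite values in descriptor columns: {bad}")


def read_descriptor_csv(path: str | Path) -> pd.DataFrame:
    """Read a descriptor CSV (first column = compound id, header =
    descriptor names). Missing or non-numeric entries are rejected, never
    silently imputed."""
    frame = pd.read_csv(path, index_col=0)
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric descriptor entries ({exc})") from exc
    _validate(frame)
    return frame


def filter_constant(
    frame: pd.DataFrame, near_constant_fraction: float = 0.95
) -> tuple[pd.DataFrame, list[str]]:
    """Drop constant and near-constant descriptor columns.

    A column is removed when its variance is zero or when its most frequent
    value accounts for at least ``near_constant_fraction`` of the rows
    (default 0.95, a conventional descriptor-software cut-off).
    """
    if frame.shape[1] == 0:
        raise ValueError("empty descriptor matrix")
    n = len(frame)
    removed: list[str] = []
    for col in frame.columns:
        series = frame[col]
        mode_frac = series.value_counts().iloc[0] / n
        if series.nunique() <= 1 or mode_frac >= near_constant_fraction:
            removed.append(col)
    kept = frame.drop(columns=removed)
    if kept.shape[1] == 0:
        raise ValueError("all descriptor columns removed as (near-)constant")
    return kept, removed


def filter_correlated(
    frame: pd.DataFrame, r_threshold: float = 0.95
) -> tuple[pd.DataFrame, list[str]]:
    """Drop the later member of every descriptor pair with |Pearson r| >=
    ``r_threshold``.

    The scan is greedy in column order: a column survives iff no *earlier
    surviving* column correlates with it at or above the threshold, so
    earlier columns always win. Deterministic given column order.
    """
    if frame.shape[1] < 2:
        return frame, []
    corr = frame.corr().abs().to_numpy()
    cols = list(frame.columns)
    kept_idx: list[int] = []
    removed: list[str] = []
    for j in range(len(cols)):
        if any(corr[i, j] >= r_threshold for i in kept_idx):
            removed.append(cols[j])
        else:
            kept_idx.append(j)
    return frame.iloc[:, kept_idx], removed


def standardize(frame: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores (mean 0, sample standard deviation 1, ddof=1)."""
    sd = frame.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(
            f"zero-variance columns {zero}; run filter_constant before standardize"
        )
    return (frame - frame.mean()) / sd
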