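"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, all pure functions of their parameters plus a seed:

* descriptor matrices with a planted sparse linear retention signal —
  a stand-in for a real compounds x descriptors matrix, sized 26 x 200 by
  default so exhaustive subset oracles stay feasible;
* noisy linear calibration runs (retention time vs literature index);
* index tables with planted correlated column groups, mimicking the
  computed-vs-experimental two-group structure.

Descriptor marginals are standard normal by default (real descriptor
blocks are heavier-tailed; a lognormal mode is available), with optional
equicorrelation within the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import IndexTable

__all__ = [
    "SyntheticSpec",
    "gen_descriptor_matrix",
    "gen_calibration_run",
    "gen_index_table",
]


@dataclass
class SyntheticSpec:
    """Recipe for a descriptor matrix with a planted linear signal.

    ``informative`` maps descriptor column index -> true coefficient; the
    response is intercept + sum(coef * descriptor) + N(0, noise_sd).
    """

    n_compounds: int = 26
    n_descriptors: int = 200
    informative: dict[int, float] = field(default_factory=dict)
    intercept: float = 0.0
    noise_sd: float = 0.5
    descriptor_correlation: float = 0.0  # within-pool equicorrelation
    marginal: str = "normal"  # or "lognormal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.descriptor_correlation < 1.0:
            raise ValueError("descriptor_correlation must lie in [0, 1)")
        bad = [i for i in self.informative if not 0 <= i < self.n_descriptors]
        if bad:
            raise ValueError(f"informative indices out of range: {bad}")
        if self.marginal not in ("normal", "lognormal"):
            raise ValueError(f"unknown marginal: {self.marginal!r}")


def gen_descriptor_matrix(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Generate (descriptor matrix, response, truth record).

    The truth record retains the planted coefficients and intercept for
    recovery scoring.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_compounds, spec.n_descriptors
    rho = spec.descriptor_correlation
    Z = rng.standard_normal((n, m))
    if rho > 0:
        latent = rng.standard_normal((n, 1))
        Z = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * Z
    if spec.marginal == "lognormal":
        Z = np.exp(Z)
    names = [f"d{j}" for j in range(m)]
    X = pd.DataFrame(Z, index=range(1, n + 1), columns=names)
    X.index.name = "compound_id"
    y = np.full(n, spec.intercept, dtype=float)
    for j, coef in spec.informative.items():
        y += coef * Z[:, j]
    y += rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
    truth = {
        "informative": {names[j]: c for j, c in spec.informative.items()},
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
    }
    return X, y, truth


def gen_calibration_run(
    slope: float,
    intercept: float,
    n_standards: int = 10,
    rt_range: tuple[float, float] = (0.5, 5.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a calibration-standards table (id, rt_min, literature_index).

    Retention times are uniform over ``rt_range``; literature indices are
    slope*t + intercept plus Gaussian noise.
    """
    if n_standards < 2:
        raise ValueError("need at least 2 standards")
    lo, hi = rt_range
    if not hi > lo:
        raise ValueError(f"degenerate retention-time range: {rt_range}")
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(lo, hi, size=n_standards))
    y = slope * t + intercept
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_standards)
    return pd.DataFrame(
        {"id": [f"std{i + 1}" for i in range(n_standards)], "rt_min": t, "literature_index": y}
    )


def gen_index_table(
    n_compounds: int,
    column_groups: list[tuple[int, float]],
    seed: int | None = None,
) -> IndexTable:
    """Index table with independent groups of equicorrelated columns.

    Each group ``(n_columns, within_r)`` shares a latent factor:
    column = sqrt(r)*latent + sqrt(1-r)*noise, giving pairwise correlation
    ``within_r`` in expectation within the group and ~0 across groups.
    """
    rng = np.random.default_rng(seed)
    data, origins = {}, {}
    for g, (n_cols, r) in enumerate(column_groups):
        if not 0.0 <= r < 1.0:
            raise ValueError(f"within_r must lie in [0, 1), got {r}")
        latent = rng.standard_normal(n_compounds)
        for c in range(n_cols):
            name = f"g{g + 1}_c{c + 1}"
            noise = rng.standard_normal(n_compounds)
            data[name] = np.sqrt(r) * latent + np.sqrt(1.0 - r) * noise
            origins[name] = f"group{g + 1}"
    frame = pd.DataFrame(data, index=range(1, n_compounds + 1))
    frame.index.name = "compound_id"
    return IndexTable(frame, origins)
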