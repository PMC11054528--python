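"""Genetic-algorithm descriptor selection over ordinary-least-squares MLR.

Quantitative structure-retention relationship (QSRR) models regress a
chromatographic endpoint (CHI, CHI_IAM, logK_HSA, ...) on a small subset of
molecular descriptors. With thousands of candidate descriptors and ~26
compounds, subset selection is the hard part; a genetic algorithm searches
the space of fixed-size descriptor subsets, scoring each by an internal
validation criterion (leave-one-out Q2 by default) of the OLS fit on the
training compounds only.

GA protocol (QSARINS-style defaults): population 10, per-gene mutation
probability 0.20, 500 generations per model size, tournament selection,
uniform crossover repaired to fixed subset size, elitism. Fitness values
are cached per descriptor subset, so the cost is bounded by the number of
distinct subsets visited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

__all__ = [
    "MLRModel",
    "GAConfig",
    "SingularDesignError",
    "split_train_validation",
    "fit_mlr",
    "predict",
    "ga_select",
    "format_equation",
]


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient."""


@dataclass
class MLRModel:
    """An OLS multiple-linear-regression model on a descriptor subset."""

    descriptor_names: list[str]
    coefficients: np.ndarray  # response units per descriptor unit
    intercept: float
    coefficient_uncertainties: np.ndarray  # standard errors, same order
    intercept_uncertainty: float
    training_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.coefficient_uncertainties = np.asarray(
            self.coefficient_uncertainties, dtype=float
        )
        if len(self.descriptor_names) < 1:
            raise ValueError("a model needs at least one descriptor")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("non-finite coefficients")


@dataclass
class GAConfig:
    """Genetic-algorithm settings for descriptor-subset search."""

    model_size: int
    population_size: int = 10
    mutation_rate: float = 0.20  # per-gene replacement probability
    generations: int = 500  # per model size
    fitness: str = "q2_loo"  # or "r2"
    seed: int | None = None
    elitism: bool = True
    tournament_size: int = 2
    n_best: int = 10

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.model_size < 1:
            raise ValueError("model_size must be >= 1")
        if self.fitness not in ("q2_loo", "r2"):
            raise ValueError(f"unknown fitness criterion: {self.fitness!r}")


def split_train_validation(
    compound_ids: Sequence,
    response: Sequence[float] | None = None,
    n_train: int = 19,
    n_validation: int = 7,
    strategy: str = "systematic",
    seed: int | None = None,
) -> tuple[list, list]:
    """Split compounds into training and validation groups.

    ``systematic`` (default) sorts compounds by response value and sends
    every (n/n_validation)-th rank to validation, spreading the validation
    set across the response range; ``random`` uses a seeded permutation.
    """
    ids = list(compound_ids)
    n = len(ids)
    if n_train + n_validation != n:
        raise ValueError(
            f"n_train + n_validation = {n_train + n_validation} != {n} compounds"
        )
    if strategy == "systematic":
        if response is None:
            raise ValueError("systematic split requires response values")
        order = sorted(range(n), key=lambda i: (float(response[i]), ids[i]))
        # 1-based validation ranks i*n/n_validation, i = 1..n_validation
        val_ranks = {
            int(math.floor(i * n / n_validation + 0.5)) for i in range(1, n_validation + 1)
        }
        validation = [ids[order[r - 1]] for r in sorted(val_ranks)]
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        validation = [ids[i] for i in sorted(rng.permutation(n)[:n_validation])]
    else:
        raise ValueError(f"unknown split strategy: {strategy!r}")
    val_set = set(validation)
    train = [i for i in ids if i not in val_set]
    return train, validation


def _design(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    A = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if A.ndim == 1:
        A = A[:, None]
    return np.column_stack([np.ones(len(A)), A])


def fit_mlr(X: pd.DataFrame, y: Sequence[float]) -> MLRModel:
    """OLS fit of the response on the given descriptor columns.

    Coefficient uncertainties are the usual standard errors from
    sigma^2 (X'X)^-1 with n - p - 1 residual degrees of freedom.
    """
    names = list(X.columns)
    A = _design(X)
    yv = np.asarray(y, dtype=float)
    n, p1 = A.shape
    if n <= p1:
        raise ValueError(f"need more compounds ({n}) than parameters ({p1})")
    if np.linalg.matrix_rank(A) < p1:
        raise SingularDesignError(
            f"rank-deficient design; collinear columns among {_collinear(X)}"
        )
    beta, _, _, _ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ beta
    dof = n - p1
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    return MLRModel(
        descriptor_names=names,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        coefficient_uncertainties=se[1:],
        intercept_uncertainty=float(se[0]),
        training_ids=list(X.index),
    )


def _collinear(X: pd.DataFrame) -> list[str]:
    """Name columns implicated in rank deficiency via pivoted QR."""
    A = _design(X)
    _, r, piv = sla.qr(A, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    dropped = [piv[i] for i in range(len(diag)) if diag[i] <= tol]
    names = ["<intercept>"] + list(X.columns)
    return [names[j] for j in sorted(dropped)]


def predict(model: MLRModel, X: pd.DataFrame) -> np.ndarray:
    """Evaluate intercept + sum(coefficient * descriptor) for each row."""
    missing = [c for c in model.descriptor_names if c not in X.columns]
    if missing:
        raise KeyError(f"descriptor columns missing from input: {missing}")
    A = X[model.descriptor_names].to_numpy(dtype=float)
    return model.intercept + A @ model.coefficients


def _subset_fitness(
    A: np.ndarray, yv: np.ndarray, cols: tuple[int, ...], criterion: str
) -> float:
    """Fitness of one descriptor subset; -inf for singular designs.

    Uses the hat-matrix LOO shortcut for q2_loo, so each evaluation is a
    single least-squares solve.
    """
    n = len(yv)
    D = np.column_stack([np.ones(n), A[:, cols]])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        return -np.inf
    beta, _, _, _ = np.linalg.lstsq(D, yv, rcond=None)
    resid = yv - D @ beta
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_tot == 0:
        return -np.inf
    if criterion == "r2":
        return 1.0 - float(resid @ resid) / ss_tot
    h = np.einsum("ij,ji->i", D, np.linalg.solve(D.T @ D, D.T))
    if np.any(h >= 1.0 - 1e-12):
        return -np.inf
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    return 1.0 - press / ss_tot


def ga_select(X: pd.DataFrame, y: Sequence[float], config: GAConfig) -> list[MLRModel]:
    """Search descriptor subsets of size ``config.model_size`` by GA.

    ``X`` and ``y`` should be the *training* compounds only; fitness never
    sees validation data. Returns the best distinct subsets found (up to
    ``config.n_best``), refit with :func:`fit_mlr` and ranked by fitness.
    Fully reproducible given ``config.seed``.
    """
    names = list(X.columns)
    m = len(names)
    k = config.model_size
    n = len(X)
    if k >= n - 1:
        raise ValueError(f"model_size {k} infeasible for {n} training compounds")
    if k > m:
        raise ValueError(f"model_size {k} exceeds {m} candidate descriptors")
    A = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(chrom: tuple[int, ...]) -> float:
        if chrom not in cache:
            cache[chrom] = _subset_fitness(A, yv, chrom, config.fitness)
        return cache[chrom]

    def random_chrom() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(m, size=k, replace=False)))

    def tournament(pop: list[tuple[int, ...]]) -> tuple[int, ...]:
        picks = rng.integers(0, len(pop), size=config.tournament_size)
        return max((pop[i] for i in picks), key=fitness)

    def crossover(a: tuple[int, ...], b: tuple[int, ...]) -> list[int]:
        union = list(set(a) | set(b))
        if len(union) <= k:
            child = set(union)
            while len(child) < k:
                child.add(int(rng.integers(0, m)))
            return list(child)
        return list(rng.choice(union, size=k, replace=False))

    def mutate(genes: list[int]) -> tuple[int, ...]:
        out = set(genes)
        for g in genes:
            if rng.random() < config.mutation_rate:
                out.discard(g)
                repl = int(rng.integers(0, m))
                while repl in out:
                    repl = int(rng.integers(0, m))
                out.add(repl)
        return tuple(sorted(out))

    population = [random_chrom() for _ in range(config.population_size)]
    best = max(population, key=fitness)
    for _ in range(config.generations):
        nxt: list[tuple[int, ...]] = []
        if config.elitism:
            nxt.append(best)
        while len(nxt) < config.population_size:
            child = mutate(crossover(tournament(population), tournament(population)))
            nxt.append(child)
        population = nxt
        gen_best = max(population, key=fitness)
        if fitness(gen_best) > fitness(best):
            best = gen_best

    ranked = sorted(
        (c for c in cache if np.isfinite(cache[c])), key=lambda c: -cache[c]
    )[: config.n_best]
    models = []
    for chrom in ranked:
        sub = X.iloc[:, list(chrom)]
        model = fit_mlr(sub, yv)
        model.ga_fitness = cache[chrom]  # type: ignore[attr-defined]
        models.append(model)
    return models


def format_equation(model: MLRModel, response_name: str = "y", ndigits: int = 3) -> str:
    """Render a model as a flat equation with +/- standard errors,
    e.g. ``y = 3.375(+/-1.761)X1 + ... + 90.055(+/-20.430)``."""
    terms = []
    for name, c, se in zip(
        model.descriptor_names, model.coefficients, model.coefficient_uncertainties
    ):
        sign = "-" if c < 0 else "+"
        terms.append(f"{sign} {abs(c):.{ndigits}f}(±{se:.{ndigits}f}){name}")
    sign = "-" if model.intercept < 0 else "+"
    terms.append(
        f"{sign} {abs(model.intercept):.{ndigits}f}(±{model.intercept_uncertainty:.{ndigits}f})"
    )
    body = " ".join(terms)
    if body.startswith("+ "):
        body = body[2:]
    return f"{response_name} = {body}"
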