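"""Model validation statistics and the Williams-plot applicability domain.

The statistic battery follows standard QSAR/QSRR reporting: on the training
set R2, RMSE_tr and leave-one-out Q2; on the external validation set R2_ext,
RMSE_P and Lin's concordance correlation coefficient (CCC). RMSE uses the
n-denominator convention by default (the QSARINS RMSE_tr/RMSE_P form), with
a degrees-of-freedom variant available.

The applicability domain (AD) is assessed on the Williams plot: leverage
h_i = x_i' (X'X)^-1 x_i (intercept column included) against standardized
residuals (residual / RMSE_train). A point is outside the domain when
h > h* = 3(p+1)/n_train or |standardized residual| > 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .qsrr import MLRModel, fit_mlr, predict

__all__ = [
    "ValidationReport",
    "r2_and_rmse",
    "q2_loo",
    "press_residuals",
    "ccc",
    "williams_ad",
    "validate_model",
    "plot_williams",
]


def _as1d(v: Sequence[float]) -> np.ndarray:
    return np.asarray(v, dtype=float).ravel()


def r2_and_rmse(
    y_observed: Sequence[float],
    y_predicted: Sequence[float],
    rmse_denominator: str = "n",
    n_params: int | None = None,
) -> tuple[float, float]:
    """Coefficient of determination and root-mean-square error.

    r2 = 1 - SS_res / SS_tot about the observed mean. ``rmse_denominator``
    is ``"n"`` (default) or ``"dof"`` (n - p - 1, requires ``n_params``).
    """
    yo, yp = _as1d(y_observed), _as1d(y_predicted)
    if len(yo) != len(yp) or len(yo) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ss_tot = float(np.sum((yo - yo.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed response has zero variance; R2 undefined")
    ss_res = float(np.sum((yo - yp) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if rmse_denominator == "n":
        denom = len(yo)
    elif rmse_denominator == "dof":
        if n_params is None:
            raise ValueError("dof denominator requires n_params")
        denom = len(yo) - n_params - 1
        if denom <= 0:
            raise ValueError("non-positive residual degrees of freedom")
    else:
        raise ValueError(f"unknown rmse_denominator: {rmse_denominator!r}")
    return r2, float(np.sqrt(ss_res / denom))


def press_residuals(
    X: pd.DataFrame, y: Sequence[float], method: str = "hat"
) -> np.ndarray:
    """Leave-one-out prediction residuals y_i - yhat_(i).

    ``method="hat"`` uses the exact OLS shortcut e_i / (1 - h_i);
    ``method="refit"`` literally refits without each compound. The two
    agree to machine precision and are kept as mutual cross-checks.
    """
    yv = _as1d(y)
    n = len(yv)
    A = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    if method == "hat":
        beta, _, _, _ = np.linalg.lstsq(A, yv, rcond=None)
        resid = yv - A @ beta
        h = np.einsum("ij,ji->i", A, np.linalg.solve(A.T @ A, A.T))
        if np.any(h >= 1.0 - 1e-10):
            raise np.linalg.LinAlgError("leave-one-out undefined: leverage ~ 1")
        return resid / (1.0 - h)
    if method == "refit":
        out = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            beta, _, _, _ = np.linalg.lstsq(A[keep], yv[keep], rcond=None)
            out[i] = yv[i] - A[i] @ beta
        return out
    raise ValueError(f"unknown method: {method!r}")


def q2_loo(X: pd.DataFrame, y: Sequence[float], method: str = "hat") -> float:
    """Leave-one-out cross-validated R2: 1 - PRESS / SS_tot."""
    yv = _as1d(y)
    if len(yv) <= X.shape[1] + 2:
        raise ValueError("too few compounds for leave-one-out validation")
    pr = press_residuals(X, yv, method=method)
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    return 1.0 - float(pr @ pr) / ss_tot


def ccc(y_observed: Sequence[float], y_predicted: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (sample moments).

    CCC = 2 cov(o, p) / (var(o) + var(p) + (mean(o) - mean(p))^2),
    penalizing both scatter and location/scale shift; 1 means perfect
    agreement with the identity line.
    """
    yo, yp = _as1d(y_observed), _as1d(y_predicted)
    if len(yo) != len(yp) or len(yo) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    vo, vp = yo.var(), yp.var()  # n-denominator
    cov = float(np.mean((yo - yo.mean()) * (yp - yp.mean())))
    denom = vo + vp + (yo.mean() - yp.mean()) ** 2
    if denom == 0:
        raise ValueError("both vectors constant; CCC undefined")
    return 2.0 * cov / float(denom)


def williams_ad(
    model: MLRModel,
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    X_query: pd.DataFrame | None = None,
    y_query: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Williams-plot applicability-domain flags.

    Returns one row per compound (training first, then query) with columns
    ``leverage``, ``std_residual``, ``in_domain`` and ``set``. The critical
    leverage is h* = 3(p+1)/n_train and the residual cut-off is +/-3
    standardized units (residual / n-denominator RMSE_train).
    """
    cols = model.descriptor_names
    At = np.column_stack([np.ones(len(X_train)), X_train[cols].to_numpy(dtype=float)])
    yt = _as1d(y_train)
    xtx_inv = np.linalg.inv(At.T @ At)
    p1 = At.shape[1]
    h_star = 3.0 * p1 / len(At)
    _, rmse_train = r2_and_rmse(yt, predict(model, X_train))

    def _rows(A, X, y, tag):
        h = np.einsum("ij,jk,ik->i", A, xtx_inv, A)
        std = (np.asarray(y, float) - predict(model, X)) / rmse_train
        return pd.DataFrame(
            {
                "leverage": h,
                "std_residual": std,
                "in_domain": (h <= h_star) & (np.abs(std) <= 3.0),
                "set": tag,
            },
            index=X.index,
        )

    out = _rows(At, X_train, yt, "training")
    if X_query is not None:
        Aq = np.column_stack(
            [np.ones(len(X_query)), X_query[cols].to_numpy(dtype=float)]
        )
        out = pd.concat([out, _rows(Aq, X_query, _as1d(y_query), "validation")])
    out.attrs["h_star"] = h_star
    return out


@dataclass
class ValidationReport:
    """The full statistic battery plus per-compound AD flags."""

    r2_train: float
    rmse_train: float
    q2_loo: float
    r2_ext: float
    rmse_p: float
    ccc_ext: float
    ad_flags: pd.DataFrame
    h_star: float

    def as_row(self) -> dict[str, float]:
        return {
            "R2": self.r2_train,
            "RMSE_tr": self.rmse_train,
            "Q2_LOO": self.q2_loo,
            "R2_EXT": self.r2_ext,
            "RMSE_P": self.rmse_p,
            "CCC_Ext": self.ccc_ext,
        }


def validate_model(
    model: MLRModel,
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    X_val: pd.DataFrame,
    y_val: Sequence[float],
    rmse_denominator: str = "n",
) -> ValidationReport:
    """Compute the six-statistic battery and Williams AD flags for a model."""
    cols = model.descriptor_names
    n_params = len(cols)
    yt, yv = _as1d(y_train), _as1d(y_val)
    r2_tr, rmse_tr = r2_and_rmse(
        yt, predict(model, X_train), rmse_denominator, n_params
    )
    q2 = q2_loo(X_train[cols], yt)
    r2_ext, rmse_p = r2_and_rmse(
        yv, predict(model, X_val), rmse_denominator, n_params
    )
    ccc_ext = ccc(yv, predict(model, X_val))
    flags = williams_ad(model, X_train, yt, X_val, yv)
    return ValidationReport(
        r2_train=r2_tr,
        rmse_train=rmse_tr,
        q2_loo=q2,
        r2_ext=r2_ext,
        rmse_p=rmse_p,
        ccc_ext=ccc_ext,
        ad_flags=flags,
        h_star=flags.attrs["h_star"],
    )


def plot_williams(ad_flags: pd.DataFrame, h_star: float, path: str) -> None:
    """Save a Williams plot (leverage vs standardized residual)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for tag, color in [("training", "tab:green"), ("validation", "tab:purple")]:
        sub = ad_flags[ad_flags["set"] == tag]
        ax.scatter(sub["leverage"], sub["std_residual"], c=color, label=tag, s=25)
    ax.axvline(h_star, ls="--", c="k", lw=0.8)
    ax.axhline(3, ls=":", c="gray", lw=0.8)
    ax.axhline(-3, ls=":", c="gray", lw=0.8)
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
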