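"""Linear binding-free-energy models and their stability analysis.

The model is

    dG_pred = alpha * dE_vdw + beta * dE_coul + gamma * dG_solv (+ delta)

fitted by ordinary least squares against experimental free energies
dG_exp = RT ln(Ki) (T = 298 K, 1 M standard state).  Four variants exist:
the full three-term model and a vdW-only reduction, each with and without
the intercept delta.  Model stability is probed by leave-one-out
cross-validation: the standard deviation of each coefficient over the n
refits, and the mean gap <ddG> between the full-model prediction and the
leave-one-out model's prediction.

All fits are closed-form linear algebra; nothing here is stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem_io import (EnergyTableRow, ki_to_dg, pki_to_dg,  # noqa: F401 re-export
                      GAS_CONSTANT_KCAL, DEFAULT_TEMPERATURE)
from .energy import EnergyTerms

VARIANTS = ("full_int", "full_noint", "vdwonly_int", "vdwonly_noint")
_FULL_TERMS = ("dE_vdw", "dE_coul", "dG_solv")
_VDW_TERMS = ("dE_vdw",)


class FitError(ValueError):
    """Raised for invalid fitting inputs (rank deficiency, too few rows)."""


@dataclass
class FitStatistics:
    """Coefficient of determination and root-mean-square error.

    ``r2`` uses the mean-anchored total sum of squares for every variant,
    including the no-intercept ones; it is ``None`` (flagged undefined) when
    the observations have zero variance.
    """

    r2: float | None
    rmse: float
    n: int


@dataclass
class LooReport:
    coef_std: dict[str, float]
    mean_ddg: float
    per_fold: list[tuple[str, dict[str, float], float]]
    ddg_mode: str = "left_out"


@dataclass
class LieceModel:
    variant: str
    alpha: float
    beta: float | None
    gamma: float | None
    delta: float | None
    n_train: int
    fit: FitStatistics
    loo: LooReport | None = None

    @property
    def coefficients(self) -> dict[str, float]:
        out = {"alpha": self.alpha}
        if self.beta is not None:
            out["beta"] = self.beta
        if self.gamma is not None:
            out["gamma"] = self.gamma
        if self.delta is not None:
            out["delta"] = self.delta
        return out


def _variant_terms(variant: str) -> tuple[tuple[str, ...], bool]:
    if variant not in VARIANTS:
        raise FitError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    terms = _FULL_TERMS if variant.startswith("full") else _VDW_TERMS
    intercept = variant.endswith("_int")
    return terms, intercept


def _design(rows: Sequence[EnergyTableRow], variant: str
            ) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], bool]:
    terms, intercept = _variant_terms(variant)
    X = np.array([[getattr(r, t) for t in terms] for r in rows], dtype=float)
    if intercept:
        X = np.hstack([X, np.ones((len(rows), 1))])
    y = np.array([r.dg_exp for r in rows], dtype=float)
    return X, y, terms, intercept


def _solve_ols(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> np.ndarray:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the collinearity via QR pivoting
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-10 * max(abs(np.diag(R)).max(), 1e-300)]
        raise FitError(f"rank-deficient design matrix; collinear column(s): "
                       f"{bad or list(names)}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def fit_statistics(pred: Sequence[float], obs: Sequence[float]) -> FitStatistics:
    """RMSE and mean-anchored R^2 between predictions and observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise FitError("pred and obs must be equal-length 1-D sequences")
    if len(obs) < 2:
        raise FitError("need at least two observations")
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return FitStatistics(r2=None, rmse=rmse, n=len(obs))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return FitStatistics(r2=r2, rmse=rmse, n=len(obs))


def _coef_names(terms: tuple[str, ...], intercept: bool) -> list[str]:
    names = {"dE_vdw": "alpha", "dE_coul": "beta", "dG_solv": "gamma"}
    out = [names[t] for t in terms]
    if intercept:
        out.append("delta")
    return out


def fit_liece(rows: Sequence[EnergyTableRow], variant: str = "full_int"
              ) -> LieceModel:
    """Ordinary-least-squares fit of one model variant.

    No-intercept variants regress through the origin.  Requires at least one
    more row than free coefficients.
    """
    X, y, terms, intercept = _design(rows, variant)
    p = X.shape[1]
    if len(rows) < p + 1:
        raise FitError(f"need at least {p + 1} rows to fit {variant}, "
                       f"got {len(rows)}")
    names = _coef_names(terms, intercept)
    coef = _solve_ols(X, y, names)
    cmap = dict(zip(names, (float(c) for c in coef)))
    stats = fit_statistics(X @ coef, y)
    return LieceModel(
        variant=variant,
        alpha=cmap["alpha"],
        beta=cmap.get("beta"),
        gamma=cmap.get("gamma"),
        delta=cmap.get("delta"),
        n_train=len(rows),
        fit=stats,
    )


def predict_dg(model: LieceModel, terms: EnergyTerms | EnergyTableRow) -> float:
    """dG_pred for one pose's energy terms under a fitted model (kcal/mol)."""
    val = model.alpha * terms.dE_vdw
    if model.beta is not None:
        val += model.beta * terms.dE_coul
    if model.gamma is not None:
        val += model.gamma * terms.dG_solv
    if model.delta is not None:
        val += model.delta
    return float(val)


def loo_cv(rows: Sequence[EnergyTableRow], variant: str = "full_int",
           full_model: LieceModel | None = None,
           ddg_mode: str = "left_out",
           std_ddof: int = 0) -> LooReport:
    """Leave-one-out stability analysis.

    ``coef_std`` is the (population, ``ddof=0`` by default) standard
    deviation of each coefficient over the n refits.  ``mean_ddg`` is the
    signed arithmetic mean of [full-model prediction - loo-model prediction];
    with ``ddg_mode='left_out'`` the gap is evaluated on the left-out ligand
    only, with ``'all'`` it is averaged over every ligand in the set before
    averaging over folds.
    """
    if ddg_mode not in ("left_out", "all"):
        raise FitError(f"unknown ddg_mode {ddg_mode!r}")
    terms, intercept = _variant_terms(variant)
    p = len(terms) + int(intercept)
    if len(rows) < p + 2:
        raise FitError(
            f"leave-one-out for {variant} needs at least {p + 2} rows "
            f"(each fold must retain a residual degree of freedom)")
    if full_model is None:
        full_model = fit_liece(rows, variant)

    coef_names = _coef_names(terms, intercept)
    coef_samples = {k: [] for k in coef_names}
    fold_gaps = []
    per_fold = []
    for i, left_out in enumerate(rows):
        subset = [r for j, r in enumerate(rows) if j != i]
        try:
            m = fit_liece(subset, variant)
        except FitError as exc:
            raise FitError(
                f"leave-one-out fold {i} (ligand {left_out.ligand_id}): {exc}"
            ) from exc
        for k, v in m.coefficients.items():
            coef_samples[k].append(v)
        loo_pred = predict_dg(m, left_out)
        if ddg_mode == "left_out":
            gap = predict_dg(full_model, left_out) - loo_pred
        else:
            gap = float(np.mean([predict_dg(full_model, r) - predict_dg(m, r)
                                 for r in rows]))
        fold_gaps.append(gap)
        per_fold.append((left_out.ligand_id, m.coefficients, loo_pred))

    coef_std = {k: float(np.std(v, ddof=std_ddof))
                for k, v in coef_samples.items()}
    return LooReport(coef_std=coef_std,
                     mean_ddg=float(np.mean(fold_gaps)),
                     per_fold=per_fold,
                     ddg_mode=ddg_mode)


def evaluate_external(model: LieceModel, rows: Sequence[EnergyTableRow]
                      ) -> FitStatistics:
    """Apply a fitted model to an external (test) set and score it."""
    if not rows:
        raise FitError("cannot evaluate a model on an empty row list")
    pred = [predict_dg(model, r) for r in rows]
    obs = [r.dg_exp for r in rows]
    return fit_statistics(pred, obs)
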