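"""Regression-based decomposition of the Erreygers index into determinants.

The outcome is modelled with a survey-weighted binomial GLM with logit link,

    logit P(y = 1 | X) = alpha + sum_k beta_k X_k,

where the X_k are dummies for the non-reference levels of each categorical
determinant.  In the linear-additive decomposition of a concentration index,

    CI_y = sum_k (beta_k * Xbar_k / mu) * C_k + residual,

each determinant's share of the measured inequity is the product of its
*elasticity* (eta_k = effect_k * Xbar_k / mu, the proportional response of
the outcome to a proportional change in the determinant) and the wealth
concentration C_k of the determinant itself.  Because the outcome model is
nonlinear, the effect entering the elasticity is the average marginal effect
(discrete change from the reference level, averaged over the weighted
sample), and the unexplained residual is defined as the remainder
ECI_y - sum_k eta_k * C_k, which makes the decomposition add up exactly.

Per-determinant concentration can be measured with either the Erreygers
index of the dummy (default) or the standard relative index; the
elasticity-times-index product is what the decomposition pins down.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .errors import (RankDeficiencyError, SchemaError, SeparationError,
                     ValidationError)
from .inequality import ConcentrationResult, RankedDataset, concentration_index

_SEPARATION_COEF = 15.0


@dataclass(frozen=True)
class DeterminantSpec:
    """A categorical determinant: ordered levels and a reference level.

    Each non-reference level becomes one dummy, named ``"<name>=<level>"``.
    Level matching is by string representation, so integer-coded and
    string-coded inputs behave identically.
    """

    name: str
    levels: tuple
    reference: object = None

    def __post_init__(self) -> None:
        if len(set(map(str, self.levels))) != len(self.levels):
            raise ValidationError(f"duplicate levels for determinant '{self.name}'")
        if self.reference is None:
            object.__setattr__(self, "reference", self.levels[0])
        if str(self.reference) not in set(map(str, self.levels)):
            raise ValidationError(
                f"reference '{self.reference}' not a level of '{self.name}'")

    @property
    def nonreference(self) -> tuple:
        return tuple(l for l in self.levels if str(l) != str(self.reference))

    def dummy_name(self, level) -> str:
        return f"{self.name}={level}"

    @classmethod
    def binary(cls, name: str) -> "DeterminantSpec":
        return cls(name=name, levels=(0, 1), reference=0)

    @staticmethod
    def list_from_json(path: str | Path) -> list["DeterminantSpec"]:
        with open(path) as fh:
            raw = json.load(fh)
        return [DeterminantSpec(name=d["name"], levels=tuple(d["levels"]),
                                reference=d.get("reference"))
                for d in raw]


def build_design(frame: pd.DataFrame, determinants: Sequence[DeterminantSpec],
                 ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dummy-encode the determinants; returns (dummies, name -> dummy columns)."""
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, list[str]] = {}
    for spec in determinants:
        if spec.name not in frame.columns:
            raise SchemaError(f"determinant '{spec.name}' not in dataset")
        vals = frame[spec.name].astype(str).str.strip()
        known = set(map(str, spec.levels))
        unknown = sorted(set(vals) - known)
        if unknown:
            raise ValidationError(
                f"determinant '{spec.name}' has unknown levels {unknown}")
        groups[spec.name] = []
        for level in spec.nonreference:
            dummy = spec.dummy_name(level)
            cols[dummy] = (vals == str(level)).to_numpy(float)
            groups[spec.name].append(dummy)
    return pd.DataFrame(cols, index=frame.index), groups


@dataclass
class OutcomeModelFit:
    """A converged weighted binomial-logit fit of the outcome on the dummies."""

    intercept: float
    coefficients: dict[str, float]
    vcov: pd.DataFrame
    converged: bool
    iterations: int
    loglik: float
    determinants: tuple[DeterminantSpec, ...]
    dummy_groups: dict[str, list[str]]

    @property
    def dummy_columns(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, dummies: pd.DataFrame) -> np.ndarray:
        beta = np.array([self.coefficients[c] for c in self.dummy_columns])
        lin = self.intercept + dummies[self.dummy_columns].to_numpy(float) @ beta
        return expit(lin)


def _check_rank(Xw: np.ndarray, names: list[str]) -> None:
    _, R, piv = scipy.linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xw.shape) * np.finfo(float).eps
    deficient = piv[diag <= tol]
    if len(deficient):
        bad = [names[i] for i in deficient]
        raise RankDeficiencyError(f"collinear design columns: {bad}")


def fit_outcome_model(rd: RankedDataset, determinants: Sequence[DeterminantSpec],
                      outcome: str = "cmhs") -> OutcomeModelFit:
    """Fit the weighted binomial-logit outcome model by IRLS.

    Convergence is declared when the IRLS coefficient update stabilises
    (tolerance 1e-8, at most 100 iterations).  Dummies with zero weighted
    variance, collinear dummy sets, and apparent perfect separation are
    reported as distinct errors.
    """
    y = rd.outcome_values(outcome)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError(f"outcome '{outcome}' is not binary")
    w = rd.weights
    wn = w / w.sum()
    D, groups = build_design(rd.base.df, determinants)
    for col in D.columns:
        share = float(wn @ D[col].to_numpy(float))
        if share in (0.0, 1.0):
            raise ValidationError(
                f"dummy '{col}' has zero weighted variance (share={share})")
    X = sm.add_constant(D.to_numpy(float))
    names = ["const"] + list(D.columns)
    _check_rank(np.sqrt(w)[:, None] * X, names)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", PerfectSeparationWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit(
                maxiter=100, tol=1e-8)
        except Exception as exc:  # statsmodels raises on hard separation
            if "separation" in str(exc).lower():
                raise SeparationError(str(exc)) from exc
            raise
    separation_warned = any(issubclass(c.category, PerfectSeparationWarning)
                            for c in caught)
    params = np.asarray(res.params, float)
    converged = bool(getattr(res, "converged", True))
    diverged = np.max(np.abs(params)) > _SEPARATION_COEF
    if diverged and (separation_warned or not converged):
        raise SeparationError(
            "logit fit diverged: perfect separation suspected "
            f"(max |coef| = {np.max(np.abs(params)):.2f})")
    iterations = len(res.fit_history.get("deviance", [])) - 1
    vcov = pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names)
    return OutcomeModelFit(
        intercept=float(params[0]),
        coefficients=dict(zip(D.columns, params[1:])),
        vcov=vcov, converged=converged, iterations=max(iterations, 0),
        loglik=float(res.llf), determinants=tuple(determinants),
        dummy_groups=groups)


def average_marginal_effects(fit: OutcomeModelFit, rd: RankedDataset) -> dict[str, float]:
    """Discrete-change AMEs on the probability scale, one per dummy.

    For each determinant level the effect is the weighted mean of
    p(level) - p(reference) with all other covariates held at their observed
    values (the factor-variable AME).
    """
    if not fit.converged:
        raise ValidationError("average marginal effects require a converged fit")
    D, _ = build_design(rd.base.df, fit.determinants)
    w = rd.weights
    wn = w / w.sum()
    ames: dict[str, float] = {}
    for spec in fit.determinants:
        group = fit.dummy_groups[spec.name]
        D0 = D.copy()
        D0[group] = 0.0
        p0 = fit.predict(D0)
        for level in spec.nonreference:
            dummy = spec.dummy_name(level)
            D1 = D0.copy()
            D1[dummy] = 1.0
            ames[dummy] = float(wn @ (fit.predict(D1) - p0))
    return ames


@dataclass
class DecompositionRow:
    """One dummy's elasticity, wealth concentration, and inequity contribution."""

    determinant: str
    level: object
    marginal_effect: float
    mean_x: float
    elasticity: float
    determinant_index: float
    contribution_abs: float = None  # type: ignore[assignment]
    contribution_pct: float | None = None

    def __post_init__(self) -> None:
        if self.contribution_abs is None:
            self.contribution_abs = self.elasticity * self.determinant_index


@dataclass
class DecompositionResult:
    """Per-determinant contributions to the outcome ECI, plus the residual."""

    outcome_result: ConcentrationResult
    rows: list[DecompositionRow]
    residual_abs: float
    residual_pct: float | None
    determinant_index_kind: str = "eci"

    def __post_init__(self) -> None:
        total = sum(r.contribution_abs for r in self.rows) + self.residual_abs
        if abs(total - self.outcome_result.eci) > 1e-12 * max(1.0, abs(total)):
            raise ValidationError("contributions + residual != outcome ECI")

    @property
    def explained_abs(self) -> float:
        return sum(r.contribution_abs for r in self.rows)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome_result.to_dict(),
            "determinant_index_kind": self.determinant_index_kind,
            "rows": [vars(r) for r in self.rows],
            "residual_abs": self.residual_abs,
            "residual_pct": self.residual_pct,
        }


def decompose(rd: RankedDataset, determinants: Sequence[DeterminantSpec],
              outcome: str = "cmhs",
              determinant_index: str = "eci") -> DecompositionResult:
    """Decompose the outcome ECI into per-determinant contributions.

    ``determinant_index`` selects how each dummy's own wealth concentration
    C_k is measured: its Erreygers index (``"eci"``, default) or its standard
    relative index (``"ci"``).  Percent columns are relative to the outcome
    ECI and undefined (None) when it is zero.
    """
    if determinant_index not in ("eci", "ci"):
        raise ValidationError("determinant_index must be 'eci' or 'ci'")
    outcome_result = concentration_index(rd, outcome)
    fit = fit_outcome_model(rd, determinants, outcome)
    ames = average_marginal_effects(fit, rd)
    D, _ = build_design(rd.base.df, determinants)
    w = rd.weights
    wn = w / w.sum()
    r = rd.rank
    rbar = float(wn @ r)
    mu = outcome_result.mu
    eci_y = outcome_result.eci

    rows: list[DecompositionRow] = []
    for spec in determinants:
        for level in spec.nonreference:
            dummy = spec.dummy_name(level)
            x = D[dummy].to_numpy(float)
            xbar = float(wn @ x)
            cov = float(wn @ ((x - xbar) * (r - rbar)))
            c_k = 8.0 * cov if determinant_index == "eci" else 2.0 * cov / xbar
            eta = ames[dummy] * xbar / mu
            contribution = eta * c_k
            pct = 100.0 * contribution / eci_y if eci_y != 0.0 else None
            rows.append(DecompositionRow(
                determinant=spec.name, level=level,
                marginal_effect=ames[dummy], mean_x=xbar, elasticity=eta,
                determinant_index=c_k, contribution_abs=contribution,
                contribution_pct=pct))

    residual = eci_y - sum(row.contribution_abs for row in rows)
    residual_pct = 100.0 * residual / eci_y if eci_y != 0.0 else None
    return DecompositionResult(outcome_result=outcome_result, rows=rows,
                               residual_abs=residual, residual_pct=residual_pct,
                               determinant_index_kind=determinant_index)


def decomposition_report(d: DecompositionResult) -> pd.DataFrame:
    """Tabulate a decomposition with per-determinant Sum rows and a Residuals row."""
    out: list[dict] = []
    for name in dict.fromkeys(r.determinant for r in d.rows):
        group = [r for r in d.rows if r.determinant == name]
        for r in group:
            out.append({"determinant": r.determinant, "level": str(r.level),
                        "marginal_effect": r.marginal_effect, "mean_x": r.mean_x,
                        "elasticity": r.elasticity,
                        "determinant_index": r.determinant_index,
                        "contribution_abs": r.contribution_abs,
                        "contribution_pct": r.contribution_pct})
        out.append({"determinant": name, "level": "Sum",
                    "contribution_abs": sum(r.contribution_abs for r in group),
                    "contribution_pct": (sum(r.contribution_pct for r in group)
                                         if all(r.contribution_pct is not None
                                                for r in group) else None)})
    out.append({"determinant": "Residuals", "level": "",
                "contribution_abs": d.residual_abs,
                "contribution_pct": d.residual_pct})
    return pd.DataFrame(out)
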