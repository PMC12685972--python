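"""Weighted concentration indices and concentration curves.

The socioeconomic dimension is household wealth.  Records are ranked from
poorest to richest by the weighted fractional rank

    r_i = (W_{<i} + w_i / 2) / W,

the midpoint of each record's weight band in the cumulative wealth ordering;
its weighted mean is exactly 0.5.  The (relative) concentration index of an
outcome y with mean mu is

    CI = 2 * cov_w(y, r) / mu,

positive when the outcome is concentrated among the rich.  For a binary
outcome the attainable CI range shrinks to [mu - 1, 1 - mu], so the
Erreygers-corrected index

    ECI = 4 * mu * CI

is used for cross-survey comparison: it spans [-1, 1] and satisfies the
mirror property ECI(1 - y) = -ECI(y).

Standard errors come from the "convenient regression" of
2 * var_w(r) * y / mu on r (whose WLS slope equals CI exactly), with
heteroskedasticity-robust variance; weights are treated as precision
weights, with no allowance for multi-stage sampling design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError, ZeroMeanOutcomeError
from .records import SurveyDataset, add_cmhs

_IDENTITY_TOL = 1e-10


def _fractional_rank(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted fractional ranks of x (ties kept in stable input order).

    Returns (ranks aligned to input order, ascending sort permutation).
    """
    order = np.argsort(x, kind="stable")
    ws = w[order]
    W = ws.sum()
    cum_before = np.cumsum(ws) - ws
    r_sorted = (cum_before + 0.5 * ws) / W
    rank = np.empty_like(r_sorted)
    rank[order] = r_sorted
    return rank, order


@dataclass
class RankedDataset:
    """A survey dataset augmented with weighted fractional wealth ranks."""

    base: SurveyDataset
    rank: np.ndarray
    sort_order: np.ndarray
    wealth_variable: str = "wealth_score"

    def __post_init__(self) -> None:
        w = self.weights
        rbar = (w / w.sum()) @ self.rank
        if abs(rbar - 0.5) > 1e-9:
            raise ValidationError(f"weighted mean rank {rbar!r} != 0.5")
        if np.any(self.rank <= 0) or np.any(self.rank >= 1):
            raise ValidationError("ranks must lie strictly inside (0, 1)")

    @property
    def weights(self) -> np.ndarray:
        return self.base.df["weight"].to_numpy(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self.base.df.assign(rank=self.rank)

    def outcome_values(self, outcome: str) -> np.ndarray:
        df = self.base.df
        if outcome not in df.columns:
            if outcome == "cmhs":
                df = add_cmhs(self.base).df
            else:
                raise ValidationError(f"unknown outcome variable '{outcome}'")
        y = df[outcome].to_numpy(float)
        if np.isnan(y).any():
            raise ValidationError(f"outcome '{outcome}' has missing values")
        return y


def weighted_fractional_rank(ds: SurveyDataset, wealth: str | None = None) -> RankedDataset:
    """Rank records poorest-to-richest by wealth, weighting by survey weight.

    ``wealth`` defaults to the continuous ``wealth_score`` when fully
    observed, else ``wealth_quintile`` (ties within a quintile are broken by
    stable input order).
    """
    df = ds.df
    if wealth is None:
        if "wealth_score" in df.columns and df["wealth_score"].notna().all():
            wealth = "wealth_score"
        elif "wealth_quintile" in df.columns:
            wealth = "wealth_quintile"
        else:
            raise ValidationError("no wealth_score or wealth_quintile column")
    x = df[wealth].to_numpy(float)
    if np.isnan(x).any():
        raise ValidationError(f"missing values in wealth variable '{wealth}'")
    if np.all(x == x[0]) and len(x) > 1:
        warnings.warn("all wealth values identical; ranks follow input order",
                      stacklevel=2)
    rank, order = _fractional_rank(x, df["weight"].to_numpy(float))
    return RankedDataset(base=ds, rank=rank, sort_order=order, wealth_variable=wealth)


@dataclass(frozen=True)
class ConcentrationResult:
    """mu, CI, ECI and their standard errors for one outcome."""

    mu: float
    ci: float
    eci: float
    se_ci: float
    se_eci: float
    n: int
    total_weight: float
    outcome: str = ""
    binary: bool = True

    def __post_init__(self) -> None:
        if abs(self.eci - 4.0 * self.mu * self.ci) > _IDENTITY_TOL:
            raise ValidationError("ECI != 4 * mu * CI")
        if self.binary:
            if not (0.0 < self.mu <= 1.0):
                raise ValidationError(f"degenerate outcome mean {self.mu}")
            lo, hi = self.mu - 1.0, 1.0 - self.mu
            if not (lo - 1e-9 <= self.ci <= hi + 1e-9):
                raise ValidationError(f"CI {self.ci} outside [mu-1, 1-mu]")
            if abs(self.eci) > 1.0 + 1e-9:
                raise ValidationError(f"ECI {self.eci} outside [-1, 1]")

    def to_dict(self) -> dict:
        return {"outcome": self.outcome, "mu": self.mu, "ci": self.ci,
                "eci": self.eci, "se_ci": self.se_ci, "se_eci": self.se_eci,
                "n": self.n, "total_weight": self.total_weight}


def erreygers_from_mean_and_ci(mu: float, ci: float) -> float:
    """Erreygers correction of a relative concentration index: 4 * mu * CI."""
    return 4.0 * mu * ci


def concentration_index(rd: RankedDataset, outcome: str = "cmhs") -> ConcentrationResult:
    """Weighted CI and ECI of an outcome over the wealth ranks.

    Raises :class:`ZeroMeanOutcomeError` when the outcome mean is zero; a
    binary outcome with mean one yields ECI = 0 with a degeneracy warning.
    """
    y = rd.outcome_values(outcome)
    w = rd.weights
    wn = w / w.sum()
    r = rd.rank
    mu = float(wn @ y)
    if mu == 0.0:
        raise ZeroMeanOutcomeError("undefined index: zero mean outcome")
    binary = bool(np.isin(y, (0.0, 1.0)).all())
    rbar = float(wn @ r)
    cov = float(wn @ ((y - mu) * (r - rbar)))
    ci = 2.0 * cov / mu
    eci = 4.0 * mu * ci
    if binary and mu == 1.0:
        warnings.warn("degenerate outcome (mu = 1): indices are zero", stacklevel=2)
        return ConcentrationResult(mu=mu, ci=0.0, eci=0.0, se_ci=0.0, se_eci=0.0,
                                   n=len(y), total_weight=float(w.sum()),
                                   outcome=outcome, binary=binary)
    if len(y) > 2:  # the convenient regression needs residual df
        var_r = float(wn @ (r - rbar) ** 2)
        lhs = 2.0 * var_r * (y / mu)
        res = sm.WLS(lhs, sm.add_constant(r), weights=w).fit(cov_type="HC1")
        se_ci = float(res.bse[1])
    else:
        se_ci = float("nan")
    return ConcentrationResult(mu=mu, ci=ci, eci=eci, se_ci=se_ci,
                               se_eci=4.0 * mu * se_ci, n=len(y),
                               total_weight=float(w.sum()),
                               outcome=outcome, binary=binary)


def concentration_index_bruteforce(rd: RankedDataset, outcome: str = "cmhs") -> float:
    """Independent weighted-sum form of the CI: (2/mu) * sum(w_i y_i r_i) - 1.

    Test oracle only; intended for modest n.
    """
    y = rd.outcome_values(outcome)
    w = rd.weights
    wn = w / w.sum()
    mu = float(wn @ y)
    if mu == 0.0:
        raise ZeroMeanOutcomeError("undefined index: zero mean outcome")
    return 2.0 / mu * float(np.sum(wn * y * rd.rank)) - 1.0


@dataclass(frozen=True)
class CurveOrdinates:
    """Concentration-curve ordinates: cumulative population vs outcome share."""

    points: np.ndarray = field(repr=False)  # shape (m, 2): columns (p, L)

    def __post_init__(self) -> None:
        p, L = self.points[:, 0], self.points[:, 1]
        if np.any(np.diff(p) < -1e-12) or np.any(np.diff(L) < -1e-12):
            raise ValidationError("curve ordinates must be non-decreasing")
        if not (p[0] == 0 and L[0] == 0 and p[-1] == 1 and L[-1] == 1):
            raise ValidationError("curve must run from (0,0) to (1,1)")

    @property
    def p(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def L(self) -> np.ndarray:
        return self.points[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["p", "L"])


def concentration_curve(rd: RankedDataset, outcome: str = "cmhs") -> CurveOrdinates:
    """Cumulative weighted outcome share against cumulative population share.

    Records are traversed poorest to richest; a curve below the 45-degree
    diagonal indicates a pro-rich distribution.
    """
    y = rd.outcome_values(outcome)
    w = rd.weights
    wn = w / w.sum()
    mu = float(wn @ y)
    if mu == 0.0:
        raise ZeroMeanOutcomeError("undefined curve: zero mean outcome")
    o = rd.sort_order
    p = np.concatenate(([0.0], np.cumsum(wn[o])))
    L = np.concatenate(([0.0], np.cumsum(wn[o] * y[o]) / mu))
    p[-1] = 1.0
    L[-1] = 1.0
    return CurveOrdinates(points=np.column_stack([p, L]))


CurvePosition = Literal["pro_rich", "pro_poor", "crossing", "on_diagonal"]

#: Default interior population shares at which curves are classified.
POSITION_GRID = np.linspace(0.05, 0.95, 19)


def curve_position(curve: CurveOrdinates, tol: float = 1e-12,
                   at: np.ndarray | None = POSITION_GRID) -> CurvePosition:
    """Classify a concentration curve by the sign pattern of L - p.

    By default the comparison is made at a fixed interior grid of population
    shares (L linearly interpolated), the usual pointwise dominance check;
    per-record ordinates in the extreme tails are dominated by single-record
    noise in finite samples.  Pass ``at=None`` to compare at every interior
    sample ordinate instead.
    """
    if at is None:
        p, L = curve.p[1:-1], curve.L[1:-1]
    else:
        p = np.asarray(at, float)
        L = np.interp(p, curve.p, curve.L)
    d = L - p
    below = bool(np.any(d < -tol))
    above = bool(np.any(d > tol))
    if below and above:
        return "crossing"
    if below:
        return "pro_rich"
    if above:
        return "pro_poor"
    return "on_diagonal"
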