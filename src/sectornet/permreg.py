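"""Node-level linear regression with permutation-based significance.

Observations on members of one network are not independent, so classical
standard errors are untrustworthy.  The approach used throughout coalition
sociometry is to keep ordinary-least-squares point estimates but draw the
null distribution of each coefficient from random permutations of the
outcome vector across members (Y-permutation): permuting y breaks any
association with the design while preserving both the outcome distribution
and the dependence structure among the predictors.

Two permutation schemes are available:

* ``"y"`` (default): re-order the raw outcome vector and refit.
* ``"freedman_lane"``: for each coefficient, fit the model without that
  column, permute its residuals, add them back to the reduced fit, and refit
  the full model — a residual-permutation scheme with better behaviour when
  nuisance covariates carry strong signal.

Two-sided p-values use the add-one rule p = (1 + #{|b*| >= |b|}) / (1 + B),
so no permutation p-value is ever exactly zero.  With ``exact=True`` all n!
permutations (identity included) are enumerated instead and the p-value is a
plain proportion.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CITIES, SECTORS, MemberRoster

_EXACT_LIMIT = 8  # n! permutations enumerated; 8! = 40320 is the practical cap


class CollinearityError(ValueError):
    """Raised when a design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def build_design(
    roster: MemberRoster,
    focal: np.ndarray | pd.Series,
    focal_name: str = "focal",
    city_reference: str = "Boston",
    sector_reference: str = "Researcher",
) -> pd.DataFrame:
    """Design matrix: intercept, one focal predictor, and the covariate dummies.

    Covariates are the ones a coalition evaluation conditions on: city of
    origin (dummies, reference level omitted), original-member tenure
    indicator, and sector (dummies, reference omitted).  Levels with no
    members are dropped with a warning.  A constant focal vector is
    inestimable and rejected.
    """
    focal = np.asarray(focal, dtype=float)
    if focal.shape != (roster.n,):
        raise ValueError(
            f"focal vector has shape {focal.shape}, expected ({roster.n},)"
        )
    if np.isnan(focal).any():
        raise ValueError("focal vector contains NaN; encode undefined values first")
    if np.ptp(focal) == 0:
        raise ValueError(f"focal predictor {focal_name!r} is constant: inestimable")
    if city_reference not in CITIES:
        raise ValueError(f"unknown city reference {city_reference!r}")
    if sector_reference not in SECTORS:
        raise ValueError(f"unknown sector reference {sector_reference!r}")

    data: dict[str, np.ndarray] = {
        "intercept": np.ones(roster.n),
        focal_name: focal,
    }
    for city in CITIES:
        if city == city_reference:
            continue
        col = (roster.cities == city).astype(float)
        if col.sum() == 0:
            warnings.warn(f"city level {city!r} has no members; dummy dropped",
                          stacklevel=2)
            continue
        data[f"city[{city}]"] = col
    data["original_member"] = roster.original_member.astype(float)
    for sector in SECTORS:
        if sector == sector_reference:
            continue
        col = (roster.sectors == sector).astype(float)
        if col.sum() == 0:
            warnings.warn(f"sector level {sector!r} has no members; dummy dropped",
                          stacklevel=2)
            continue
        data[f"sector[{sector}]"] = col
    return pd.DataFrame(data, index=list(roster.member_ids))


def _as_matrix(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def ols_fit(
    X: pd.DataFrame | np.ndarray, y: np.ndarray | pd.Series
) -> tuple[pd.Series, float]:
    """Ordinary least squares: coefficients and R^2 = 1 - RSS/TSS.

    Rank-deficient designs raise :class:`CollinearityError` pointing at
    :func:`collinearity_screen` rather than silently pseudo-inverting.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if y.shape != (Xm.shape[0],):
        raise ValueError(f"y has shape {y.shape}, expected ({Xm.shape[0]},)")
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise CollinearityError(
            "design matrix is rank deficient; run collinearity_screen on the "
            "candidate predictors and drop one of each flagged pair"
        )
    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    resid = y - Xm @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float((resid**2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    # Guard tiny negative drift when rss ~ tss at machine precision.
    r2 = min(1.0, max(0.0, r2)) if abs(r2) < 1e-12 or r2 > 1 else r2
    return pd.Series(beta, index=names, name="coef"), r2


@dataclass(frozen=True)
class PermRegressionResult:
    """OLS point estimates with permutation p-values.

    ``pvalues`` are two-sided on |beta|.  ``n_permutations`` is the number of
    random draws (or the full factorial count when exact).
    """

    coef: pd.Series = field(repr=False)
    pvalues: pd.Series = field(repr=False)
    r_squared: float
    n_permutations: int
    seed: int | None
    scheme: str
    focal: str | None = None
    exact: bool = False

    def significance_marker(self, name: str) -> str:
        """Conventional table marker: ** <=0.01, * <=0.05, + <=0.10."""
        p = float(self.pvalues[name])
        if p <= 0.01:
            return "**"
        if p <= 0.05:
            return "*"
        if p <= 0.10:
            return "+"
        return ""

    def to_record(self) -> dict:
        return {
            "coef": {k: float(v) for k, v in self.coef.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "r_squared": float(self.r_squared),
            "n_permutations": int(self.n_permutations),
            "seed": self.seed,
            "scheme": self.scheme,
            "focal": self.focal,
            "exact": self.exact,
        }


def _permutation_indices(
    n: int, n_perms: int, rng: np.random.Generator
) -> np.ndarray:
    idx = np.tile(np.arange(n), (n_perms, 1))
    return rng.permuted(idx, axis=1)


def permutation_pvalues(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    n_perms: int = 10_000,
    seed: int | None = None,
    scheme: str = "y",
    focal: str | None = None,
    exact: bool = False,
) -> PermRegressionResult:
    """Fit OLS and attach permutation p-values for every coefficient.

    Random draws are controlled by ``seed`` (bit-reproducible results for a
    fixed seed).  ``exact=True`` enumerates all n! re-orderings of y (only
    feasible for n <= 8) and reports plain-proportion p-values; otherwise the
    add-one-corrected estimate over ``n_perms`` random re-orderings is used.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    coef, r2 = ols_fit(Xm, y)
    coef.index = names
    n = Xm.shape[0]
    pinv = np.linalg.pinv(Xm)  # k x n; rank already checked by ols_fit

    if exact:
        if n > _EXACT_LIMIT:
            raise ValueError(f"exact enumeration limited to n <= {_EXACT_LIMIT}")
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    else:
        if n_perms < 100:
            raise ValueError("n_perms must be at least 100")
        rng = np.random.default_rng(seed)
        perms = _permutation_indices(n, n_perms, rng)
    n_draws = perms.shape[0]

    observed = np.abs(coef.to_numpy())
    if scheme == "y":
        betas = y[perms] @ pinv.T  # (draws, k)
        exceed = (np.abs(betas) >= observed[None, :] - 1e-12).sum(axis=0)
    elif scheme == "freedman_lane":
        exceed = np.zeros(len(names), dtype=np.int64)
        for j in range(len(names)):
            reduced = np.delete(Xm, j, axis=1)
            fitted = reduced @ np.linalg.lstsq(reduced, y, rcond=None)[0]
            resid = y - fitted
            ystar = fitted[None, :] + resid[perms]
            beta_j = ystar @ pinv[j]
            exceed[j] = int((np.abs(beta_j) >= observed[j] - 1e-12).sum())
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    if exact:
        pvals = exceed / n_draws  # identity permutation makes these positive
    else:
        pvals = (1 + exceed) / (1 + n_draws)
    return PermRegressionResult(
        coef=coef,
        pvalues=pd.Series(pvals, index=names, name="p_perm"),
        r_squared=r2,
        n_permutations=n_draws,
        seed=None if exact else seed,
        scheme=scheme,
        focal=focal,
        exact=exact,
    )


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CollinearityReport:
    """Pairwise |r| among candidate predictors with flagged pairs."""

    correlations: pd.DataFrame = field(repr=False)
    flagged: tuple[tuple[str, str, float], ...]
    excluded_zero_variance: tuple[str, ...]
    threshold: float

    @property
    def retained(self) -> tuple[str, ...]:
        """Candidates that can coexist: drop the later member of each flagged pair."""
        dropped: set[str] = set()
        for a, b, _ in self.flagged:
            if a not in dropped:
                dropped.add(b)
        return tuple(
            c
            for c in self.correlations.columns
            if c not in dropped
        )

    def refuse_if_flagged(self, *names: str) -> None:
        """Reject a model specification containing a flagged pair."""
        for a, b, r in self.flagged:
            if a in names and b in names:
                raise CollinearityError(
                    f"predictors {a!r} and {b!r} are too highly correlated "
                    f"(|r| = {r:.2f} > {self.threshold}); fit them in separate models"
                )


def collinearity_screen(
    candidates: dict[str, np.ndarray | pd.Series],
    threshold: float = 0.70,
) -> CollinearityReport:
    """Screen candidate member-level predictors for pairwise collinearity.

    Zero-variance candidates are excluded up front.  Any pair with absolute
    Pearson correlation above ``threshold`` is flagged; flagged pairs must be
    fit in separate models (``refuse_if_flagged``).
    """
    if not candidates:
        raise ValueError("need at least one candidate predictor")
    kept: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name, vec in candidates.items():
        arr = np.asarray(vec, dtype=float)
        if np.isnan(arr).any():
            raise ValueError(f"candidate {name!r} contains NaN")
        if np.ptp(arr) == 0:
            excluded.append(name)
        else:
            kept[name] = arr
    names = list(kept)
    k = len(names)
    corr = pd.DataFrame(np.eye(k), index=names, columns=names)
    flagged: list[tuple[str, str, float]] = []
    for i in range(k):
        for j in range(i + 1, k):
            r = float(np.corrcoef(kept[names[i]], kept[names[j]])[0, 1])
            corr.iloc[i, j] = corr.iloc[j, i] = r
            if abs(r) > threshold:
                flagged.append((names[i], names[j], abs(r)))
    return CollinearityReport(
        correlations=corr,
        flagged=tuple(flagged),
        excluded_zero_variance=tuple(excluded),
        threshold=threshold,
    )
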