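"""Regression engines shared by the cohort and screen pipelines.

Two fitting routes are provided: Huber M-estimation for quantitative
(residualized lipid or robust-Z) responses, and maximum-likelihood logistic
regression for the binary disease outcome.  Both return a :class:`FitResult`
carrying per-term estimates, a (pseudo-)BIC and convergence diagnostics, so
that downstream model selection treats them uniformly.

The robust fits use iteratively reweighted least squares with the Huber psi
function and a median-absolute-deviation residual scale re-estimated each
iteration; because a robust fit has no canonical likelihood, its BIC is a
Gaussian pseudo-BIC evaluated at the weighted residual variance (see
:func:`gaussian_pseudo_bic`).  With no outliers (all Huber weights one at the
optimum) both the coefficients and the pseudo-BIC reduce exactly to their
ordinary-least-squares textbook forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.robust.norms import HuberT
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "FitResult",
    "huber_irls_fit",
    "logistic_fit",
    "pval_from_t",
    "gaussian_pseudo_bic",
]

#: Huber tuning constant giving 95% efficiency under Gaussian errors.
DEFAULT_HUBER_TUNING = 1.345

#: Floor applied to the residual scale so log-variance terms stay finite.
SCALE_FLOOR = 1e-10


@dataclass
class FitResult:
    """One fitted regression model.

    Attributes
    ----------
    coefficients : pandas.DataFrame
        Indexed by term name with columns ``estimate``, ``se``, ``tvalue``,
        ``pvalue``.  Inestimable terms (dropped for rank deficiency) appear
        as all-NaN rows.
    scale : float
        Robust residual scale (response units); for logistic fits 1.0.
    n, k : int
        Sample size and number of estimated parameters entering the BIC
        penalty (coefficients, plus one for the scale in Gaussian fits).
    bic : float
        Schwarz criterion (pseudo-BIC for robust fits).
    converged : bool
    iterations : int
    family : str
        ``"gaussian-robust"`` or ``"binomial"``.
    inestimable : tuple of str
        Terms excluded from estimation (collinear or separated).
    messages : list of str
        Warning records accumulated during fitting.
    """

    coefficients: pd.DataFrame
    scale: float
    n: int
    k: int
    bic: float
    converged: bool
    iterations: int
    family: str
    inestimable: tuple = ()
    messages: list = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return self.coefficients["estimate"]

    @property
    def pvalues(self) -> pd.Series:
        return self.coefficients["pvalue"]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<FitResult {self.family} n={self.n} k={self.k} "
            f"bic={self.bic:.3f} converged={self.converged}>"
        )


def pval_from_t(t: float) -> float:
    """Two-sided normal-approximation p-value for a t (or Wald z) statistic.

    Computes ``2 - 2 * Phi(|t|)`` with ``Phi`` the standard normal CDF,
    evaluated through the survival function for numerical accuracy in the
    far tail.  Non-finite statistics propagate as NaN rather than raising,
    because they mark inestimable terms upstream.
    """
    t = np.asarray(t, dtype=float)
    out = np.where(np.isfinite(t), 2.0 * stats.norm.sf(np.abs(t)), np.nan)
    return float(out) if out.ndim == 0 else out


def _design_matrix(
    terms: Mapping[str, np.ndarray] | pd.DataFrame,
    add_intercept: bool,
) -> pd.DataFrame:
    if isinstance(terms, pd.DataFrame):
        X = terms.copy()
    else:
        X = pd.DataFrame({name: np.asarray(col, dtype=float) for name, col in terms.items()})
    if X.columns.duplicated().any():
        raise ValueError("term names must be unique")
    if add_intercept and "const" not in X.columns:
        X.insert(0, "const", 1.0)
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values")
    return X


def _drop_dependent_columns(X: pd.DataFrame) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Greedily drop columns that are linearly dependent on earlier ones."""
    arr = X.to_numpy(dtype=float)
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(arr.shape[1]):
        cand = arr[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(X.columns[j])
    return X.iloc[:, keep], tuple(dropped)


def _coef_table(
    terms: Sequence[str],
    est: Mapping[str, float],
    se: Mapping[str, float],
) -> pd.DataFrame:
    rows = {}
    for name in terms:
        if name in est:
            e, s = est[name], se[name]
            t = e / s if s > 0 else np.nan
            rows[name] = (e, s, t, pval_from_t(t))
        else:
            rows[name] = (np.nan, np.nan, np.nan, np.nan)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["estimate", "se", "tvalue", "pvalue"]
    )


def gaussian_pseudo_bic(n: int, k: int, sigma2: float) -> float:
    """Gaussian BIC ``n*log(sigma2) + k*log(n)`` with a variance floor.

    ``k`` must already include every estimated parameter (regression
    coefficients plus one for the residual scale).  Equals the textbook
    ``n*log(RSS/n) + k*log(n)`` when ``sigma2`` is the unweighted mean
    squared residual.
    """
    if n <= k:
        raise ValueError("underdetermined: n <= k")
    sigma2 = max(float(sigma2), SCALE_FLOOR**2)
    return n * np.log(sigma2) + k * np.log(n)


def huber_irls_fit(
    response,
    terms: Mapping[str, np.ndarray] | pd.DataFrame,
    *,
    tuning: float = DEFAULT_HUBER_TUNING,
    max_iter: int = 50,
    tol: float = 1e-8,
    add_intercept: bool = True,
) -> FitResult:
    """Huber M-estimated linear regression via IRLS.

    The residual scale is re-estimated each iteration as the scaled median
    absolute deviation (factor 1.4826) of the current residuals.  An exactly
    noise-free response short-circuits to the least-squares solution with
    the scale floored, since a zero MAD would leave the weights undefined.

    Rank-deficient designs do not raise: dependent columns are dropped and
    reported as inestimable terms with NaN coefficient rows.
    """
    y = np.asarray(response, dtype=float)
    X = _design_matrix(terms, add_intercept)
    if len(y) != len(X):
        raise ValueError("response and terms must be aligned")
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(y).any():
        raise ValueError("response contains missing values")

    all_terms = list(X.columns)
    Xf, dropped = _drop_dependent_columns(X)
    messages = []
    if dropped:
        messages.append(f"inestimable terms dropped for collinearity: {dropped}")

    arr = Xf.to_numpy(dtype=float)
    # Noise-free guard: exact linear response makes the MAD scale collapse.
    ols_beta, *_ = np.linalg.lstsq(arr, y, rcond=None)
    ols_resid = y - arr @ ols_beta
    if np.max(np.abs(ols_resid)) <= 1e-10 * max(1.0, np.max(np.abs(y))):
        est = dict(zip(Xf.columns, ols_beta))
        se = {name: 0.0 for name in Xf.columns}
        table = _coef_table(all_terms, est, se)
        k = len(Xf.columns) + 1
        bic = gaussian_pseudo_bic(len(y), k, SCALE_FLOOR**2)
        return FitResult(
            table, SCALE_FLOOR, len(y), k, bic, True, 0,
            "gaussian-robust", dropped, messages + ["exact fit: scale floored"],
        )

    model = sm.RLM(y, arr, M=HuberT(t=tuning))
    res = model.fit(maxiter=max_iter, tol=tol, conv="coefs", scale_est="mad")
    iterations = len(res.fit_history.get("params", []))
    converged = iterations < max_iter
    if not converged:
        messages.append(f"IRLS did not converge within {max_iter} iterations")

    est = dict(zip(Xf.columns, res.params))
    se = dict(zip(Xf.columns, res.bse))
    table = _coef_table(all_terms, est, se)

    # Pseudo-BIC at the Huber-weighted residual variance.
    w = res.weights
    r = y - arr @ res.params
    sigma2 = float(np.sum(w * r**2) / np.sum(w))
    k = len(Xf.columns) + 1  # coefficients + scale
    bic = gaussian_pseudo_bic(len(y), k, sigma2)
    return FitResult(
        table, max(float(res.scale), SCALE_FLOOR), len(y), k, bic,
        converged, iterations, "gaussian-robust", dropped, messages,
    )


def logistic_fit(
    response,
    terms: Mapping[str, np.ndarray] | pd.DataFrame,
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
    add_intercept: bool = True,
) -> FitResult:
    """Maximum-likelihood logistic regression with Wald z statistics.

    BIC is ``-2*loglik + k*log(n)``.  Complete separation is detected from
    the optimizer's warning stream; the affected fit is returned with all
    slope terms marked inestimable rather than reporting divergent
    coefficients.
    """
    y = np.asarray(response, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial response must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class response: logistic model inestimable")
    X = _design_matrix(terms, add_intercept)
    if len(y) != len(X):
        raise ValueError("response and terms must be aligned")

    all_terms = list(X.columns)
    Xf, dropped = _drop_dependent_columns(X)
    messages = []
    if dropped:
        messages.append(f"inestimable terms dropped for collinearity: {dropped}")

    arr = Xf.to_numpy(dtype=float)
    separated = False
    res = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, arr).fit(disp=0, maxiter=max_iter, tol=tol)
        except np.linalg.LinAlgError:
            # Newton's Hessian goes singular when the likelihood is
            # unbounded along a separating direction
            separated = True
        separated = separated or any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
        # divergent coefficients betray quasi-separation even when the
        # optimizer reports success
        if res is not None:
            separated = separated or bool(np.any(np.abs(res.params) > 1e2))
    converged = (
        res is not None
        and bool(res.mle_retvals.get("converged", False))
        and not separated
    )
    iterations = int(res.mle_retvals.get("iterations", 0)) if res is not None else 0

    if separated:
        messages.append("complete separation detected: coefficients inestimable")
        table = _coef_table(all_terms, {}, {})
        return FitResult(
            table, 1.0, len(y), arr.shape[1], np.nan, False, iterations,
            "binomial", tuple(all_terms), messages,
        )

    est = dict(zip(Xf.columns, res.params))
    se = dict(zip(Xf.columns, res.bse))
    table = _coef_table(all_terms, est, se)
    k = arr.shape[1]
    bic = -2.0 * float(res.llf) + k * np.log(len(y))
    if not converged:
        messages.append("logistic fit did not converge")
    return FitResult(
        table, 1.0, len(y), k, bic, converged, iterations,
        "binomial", dropped, messages,
    )
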