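"""The four-model pairwise interaction battery.

For a response y and two genetic predictors x_A, x_B the battery fits the
nested models

    M1: y ~ x_A
    M2: y ~ x_B
    M3: y ~ x_A + x_B            (additive effects, AE)
    M4: y ~ x_A + x_B + x_A*x_B  (genetic interaction, GI)

(optionally also the intercept-only M0 used by the screen arm), selects the
best model by BIC, and extracts per-term p-values from the full model — M3
or M4, whichever BIC prefers.  The two-step classifier then labels each
(pair, trait) unit GI, AE or none from the FDR-adjusted p-values together
with the selected model.

Quantitative traits are fitted robustly (Huber IRLS on residualized
outcomes); the binary disease trait uses logistic regression with the
covariates inside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .regression import FitResult, huber_irls_fit, logistic_fit
from .selection import ModelComparison, compare_models

__all__ = [
    "assess_testability",
    "PairInteractionModel",
    "PairInteractionResults",
    "classify_pair",
    "ALPHA_GI",
    "ALPHA_EXCL",
    "ALPHA_SINGLE",
]

#: Two-step classification thresholds on FDR-adjusted p-values.
ALPHA_GI = 0.005      # interaction term, GI call
ALPHA_EXCL = 0.01     # interaction term must exceed this (or be untestable) for AE
ALPHA_SINGLE = 0.005  # each single-predictor term, AE call


def assess_testability(x1, x2, min_joint: int = 1) -> tuple[bool, int]:
    """Decide whether the interaction term of a pair is estimable.

    ``joint_exposed`` counts samples exposed to both predictors (x1>0 and
    x2>0); the interaction is testable when at least ``min_joint`` such
    samples exist and the product column is not collinear with the main
    effects.  The default of a single doubly-exposed sample reflects that
    informative human "double knock-outs" are extraordinarily rare (as few
    as three carriers can carry a pairwise burden signal).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("predictor vectors must be aligned")
    joint = int(np.sum((x1 > 0) & (x2 > 0)))
    if joint < min_joint:
        return False, joint
    X = np.column_stack([np.ones_like(x1), x1, x2, x1 * x2])
    if np.linalg.matrix_rank(X) < 4:
        return False, joint
    return True, joint


@dataclass
class PairInteractionResults:
    """Fitted battery for one (pair, trait) unit.

    Carries the per-model fits and BICs, the BIC-selected best model, the
    effect estimates and raw p-values taken from the full model, and the
    testability diagnostics.  FDR adjustment and classification happen at
    scan level, across the whole family of units.
    """

    pair: tuple
    fits: dict                      # model id (0..4) -> FitResult or None
    comparison: ModelComparison
    full_model: Optional[int]       # 3 or 4: source of single-term p-values
    testable: bool
    n_joint: int
    names: tuple = ("A", "B")
    extras: dict = field(default_factory=dict)

    @property
    def best_model(self):
        return self.comparison.best_model

    @property
    def delta_bic(self) -> float:
        return self.comparison.delta_bic

    def bic(self, model_id: int) -> float:
        f = self.fits.get(model_id)
        return f.bic if f is not None and np.isfinite(f.bic) else np.nan

    def _term(self, which: str, col: str) -> float:
        """Look up a coefficient column for term A, B or AB."""
        if which == "AB":
            f = self.fits.get(4)
            name = "x_a:x_b"
        else:
            f = self.fits.get(self.full_model) if self.full_model else None
            name = "x_a" if which == "A" else "x_b"
        if f is None or name not in f.coefficients.index:
            return np.nan
        return float(f.coefficients.loc[name, col])

    @property
    def beta_a(self) -> float:
        return self._term("A", "estimate")

    @property
    def beta_b(self) -> float:
        return self._term("B", "estimate")

    @property
    def beta_ab(self) -> float:
        return self._term("AB", "estimate")

    @property
    def p_a(self) -> float:
        return self._term("A", "pvalue")

    @property
    def p_b(self) -> float:
        return self._term("B", "pvalue")

    @property
    def p_ab(self) -> float:
        return self._term("AB", "pvalue") if self.testable else np.nan

    @property
    def n(self) -> int:
        for f in self.fits.values():
            if f is not None:
                return f.n
        return 0

    def summary(self) -> str:
        a, b = self.names
        lines = [
            f"Pairwise interaction battery: {a} x {b}",
            f"  n = {self.n}, doubly exposed = {self.n_joint}, "
            f"interaction testable = {self.testable}",
            "  Model BICs:",
        ]
        for mid in sorted(self.fits):
            f = self.fits[mid]
            mark = " *" if mid == self.best_model else ""
            bic = f"{f.bic:.2f}" if f is not None and np.isfinite(f.bic) else "n/a"
            lines.append(f"    M{mid}: {bic}{mark}")
        lines.append(
            f"  best = M{self.best_model}, delta BIC = {self.delta_bic:.2f}"
            if self.comparison.available else "  comparison unavailable"
        )
        lines.append(
            f"  beta_A = {self.beta_a:.4f} (p={self.p_a:.3g}), "
            f"beta_B = {self.beta_b:.4f} (p={self.p_b:.3g}), "
            f"beta_AB = {self.beta_ab:.4f} (p={self.p_ab:.3g})"
        )
        return "\n".join(lines)


class PairInteractionModel:
    """statsmodels-style model object for one predictor pair.

    Parameters
    ----------
    endog : array-like
        Residualized quantitative trait, robust-Z response, or 0/1 disease
        status.
    xa, xb : array-like
        The two genetic predictors (carrier indicator, 0/1/2 dosage, PRS,
        or siRNA presence indicator), aligned to ``endog``.
    family : {"gaussian-robust", "binomial"}
    covariates : DataFrame, optional
        Entered into every model of the battery (used by the logistic
        disease models, where outcomes are not pre-residualized).
    include_baseline : bool
        Also fit the intercept-only M0 (screen arm convention).
    min_joint : int
        Minimum doubly-exposed count for interaction testability.
    """

    def __init__(
        self,
        endog,
        xa,
        xb,
        *,
        family: str = "gaussian-robust",
        covariates: Optional[pd.DataFrame] = None,
        include_baseline: bool = False,
        min_joint: int = 1,
        names: tuple = ("A", "B"),
        pair_id: Optional[tuple] = None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.xa = np.asarray(xa, dtype=float)
        self.xb = np.asarray(xb, dtype=float)
        if not (len(self.endog) == len(self.xa) == len(self.xb)):
            raise ValueError("endog and predictors must be aligned")
        if family not in ("gaussian-robust", "binomial"):
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.covariates = covariates
        self.include_baseline = include_baseline
        self.min_joint = min_joint
        self.names = tuple(names)
        self.pair_id = pair_id or self.names

    def _fit_one(self, cols: Mapping[str, np.ndarray], **kw) -> Optional[FitResult]:
        terms = {"const": np.ones(len(self.endog))}
        if self.covariates is not None:
            for c in self.covariates.columns:
                terms[c] = self.covariates[c].to_numpy(dtype=float)
        terms.update(cols)
        try:
            if self.family == "binomial":
                return logistic_fit(self.endog, terms, **kw)
            return huber_irls_fit(self.endog, terms, **kw)
        except (ValueError, np.linalg.LinAlgError):
            return None

    def fit(self, **fit_kw) -> PairInteractionResults:
        testable, n_joint = assess_testability(self.xa, self.xb, self.min_joint)
        xa, xb = self.xa, self.xb
        fits: dict = {}
        if self.include_baseline:
            fits[0] = self._fit_one({}, **fit_kw)
        fits[1] = self._fit_one({"x_a": xa}, **fit_kw)
        fits[2] = self._fit_one({"x_b": xb}, **fit_kw)
        fits[3] = self._fit_one({"x_a": xa, "x_b": xb}, **fit_kw)
        fits[4] = (
            self._fit_one({"x_a": xa, "x_b": xb, "x_a:x_b": xa * xb}, **fit_kw)
            if testable else None
        )
        comparison = compare_models(fits)
        # Full model for single-term p-values: the better of M3/M4 by BIC.
        full = None
        b3, b4 = fits.get(3), fits.get(4)
        if b3 is not None and b3.converged:
            full = 3
        if (
            b4 is not None and b4.converged and np.isfinite(b4.bic)
            and (full is None or b4.bic < b3.bic)
        ):
            full = 4
        return PairInteractionResults(
            pair=self.pair_id,
            fits=fits,
            comparison=comparison,
            full_model=full,
            testable=testable,
            n_joint=n_joint,
            names=self.names,
        )


def classify_pair(
    p_ab_fdr: float,
    p_a_fdr: float,
    p_b_fdr: float,
    best_model,
    testable: bool,
    *,
    alpha_gi: float = ALPHA_GI,
    alpha_excl: float = ALPHA_EXCL,
    alpha_single: float = ALPHA_SINGLE,
) -> str:
    """Two-step GI/AE classification of one (pair, trait) unit.

    GI: the FDR-adjusted interaction p is below ``alpha_gi`` and BIC picked
    the interaction model (M4).  AE: the interaction p exceeds
    ``alpha_excl`` (or is untestable), both single-term adjusted p's are
    below ``alpha_single``, and BIC picked the additive model (M3).
    Everything else — including interaction p's falling in the deliberate
    band between the two thresholds — is "none".
    """
    p_ab_missing = (not testable) or (p_ab_fdr is None) or np.isnan(p_ab_fdr)
    if not p_ab_missing and p_ab_fdr < alpha_gi and best_model == 4:
        return "GI"
    interaction_excluded = p_ab_missing or p_ab_fdr > alpha_excl
    singles_ok = (
        not np.isnan(p_a_fdr) and not np.isnan(p_b_fdr)
        and p_a_fdr < alpha_single and p_b_fdr < alpha_single
    )
    if interaction_excluded and singles_ok and best_model == 3:
        return "AE"
    return "none"
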