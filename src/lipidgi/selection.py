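"""Model selection by BIC and multiple-testing correction.

A battery of nested regressions for one predictor pair is reduced to a
single best-fitting model via Schwarz's criterion; Benjamini–Hochberg
step-up adjustment runs over the family of per-term p-values pooled across
pairs and traits within one test design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from statsmodels.stats.multitest import multipletests

from .regression import FitResult

__all__ = ["ModelComparison", "compare_models", "bh_fdr", "DELTA_BIC_EVIDENCE"]

#: Raftery's threshold: a BIC gap above this is taken as meaningful evidence
#: that the lowest-BIC model truly describes the data.
DELTA_BIC_EVIDENCE = 2.0


@dataclass
class ModelComparison:
    """BIC ranking of a model battery.

    ``delta_bic`` is the gap from the best model to the runner-up (>= 0);
    with fewer than two comparable fits the comparison is unavailable.
    """

    bics: list  # ordered (model_id, bic), ascending bic
    best_model: object
    delta_bic: float
    available: bool = True

    def strong_evidence(self) -> bool:
        return self.available and self.delta_bic > DELTA_BIC_EVIDENCE


def compare_models(fits: Mapping[object, FitResult]) -> ModelComparison:
    """Select the best-fitting model (lowest BIC) from a battery.

    Unconverged fits are excluded.  Exact BIC ties are broken toward the
    model with fewer estimated parameters, which keeps the additive-vs-
    interaction classification deterministic and favours parsimony.
    """
    usable = {
        mid: f for mid, f in fits.items()
        if f is not None and f.converged and np.isfinite(f.bic)
    }
    if len(usable) < 2:
        return ModelComparison([], None, np.nan, available=False)
    # sort by (bic, k) so ties resolve to the smaller model
    order = sorted(usable.items(), key=lambda kv: (kv[1].bic, kv[1].k))
    bics = [(mid, f.bic) for mid, f in order]
    best = order[0][0]
    delta = order[1][1].bic - order[0][1].bic
    return ModelComparison(bics, best, float(delta))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with missing-value passthrough.

    Missing entries (NaN — inestimable interaction terms) stay missing and
    do not count toward the family size m.  Adjusted values are >= raw and
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if not mask.any():
        return out
    obs = p[mask]
    if (obs < 0).any() or (obs > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(obs, method="fdr_bh")[1]
    return out
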