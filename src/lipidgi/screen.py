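"""The combinatorial-RNAi (coRNAi) screen arm.

A cell microarray screen measures fluorescent-LDL uptake per cell in
images of spots carrying siRNA against one gene (paired with a
non-silencing control) or against two genes simultaneously.  The arm
proceeds:

1. image-level quality filtering (cell number, sharpness, background);
2. per-array robust Z-scores: a treatment's per-replicate mean intensity
   centred by the array's negative-control median and scaled by the
   control MAD;
3. a five-model robust regression battery per gene pair on the pooled
   replicate Z-scores (intercept-only M0 up to the full interaction M4),
   with BIC selection and Raftery's delta-BIC > 2 evidence rule;
4. one pooled FDR family of 3 x (number of pairs) p-values, the same
   two-step GI/AE rule as the cohort arm, a taxonomy for significant
   interactions (aggravating / alleviating / suppressive), and a
   validation rule for an independent replication screen.

The fitted product-term coefficient is the Interaction Value: the observed
double-knockdown Z minus the additive expectation from the two single
knockdowns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interaction import (
    ALPHA_EXCL,
    ALPHA_GI,
    ALPHA_SINGLE,
    PairInteractionModel,
    PairInteractionResults,
    classify_pair,
)
from .selection import DELTA_BIC_EVIDENCE, bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "CONTROL_LABEL",
    "qc_filter_images",
    "robust_z_scores",
    "median_robust_z",
    "fit_screen_models",
    "screen_scan",
    "classify_gi_type",
    "validate_gi_calls",
    "total_experiments",
    "SCREEN_RESULT_COLUMNS",
]

#: Label of the non-silencing negative-control siRNA slot.
CONTROL_LABEL = "CTRL"

SCREEN_RESULT_COLUMNS = [
    "pair", "beta_0", "beta_a", "beta_b", "interaction_value",
    "bic_m0", "bic_m1", "bic_m2", "bic_m3", "bic_m4",
    "best_model", "delta_bic", "evidence",
    "p_a", "p_b", "p_ab", "p_a_fdr", "p_b_fdr", "p_ab_fdr",
    "classification", "gi_type",
]


def total_experiments(n_arrays: int, spots_per_array: int) -> int:
    """Total siRNA-spot experiments across all imaged arrays."""
    if n_arrays <= 0 or spots_per_array <= 0:
        raise ValueError("counts must be positive")
    return int(n_arrays) * int(spots_per_array)


def treatment_label(gene_a: str, gene_b: str) -> str:
    """Canonical (order-independent) treatment label."""
    return "__".join(sorted((str(gene_a), str(gene_b))))


def qc_filter_images(
    measurements: pd.DataFrame,
    *,
    min_cells: int = 20,
    min_sharpness: Optional[float] = None,
    max_background: Optional[float] = None,
    layout: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, dict]:
    """Remove images failing cell-count, sharpness or background criteria.

    When explicit thresholds are not supplied and a layout is available,
    sharpness must exceed the 5th percentile and background stay below the
    95th percentile of the negative-control images.  Returns the filtered
    table and a QC report with per-array pass rates, arrays dropped
    entirely, and arrays flagged because their positive-control knockdown
    is not separated from the negative controls.
    """
    m = measurements.copy()
    if layout is not None:
        roles = layout.set_index(["array_id", "spot_id"])["role"]
        m_roles = m.set_index(["array_id", "spot_id"]).index.map(roles)
        neg = m[np.asarray(m_roles == "negative-control")]
        if min_sharpness is None and len(neg):
            min_sharpness = float(np.percentile(neg["sharpness"], 5))
        if max_background is None and len(neg):
            max_background = float(np.percentile(neg["background"], 95))
    ok = m["cell_count"] >= min_cells
    if min_sharpness is not None:
        ok &= m["sharpness"] >= min_sharpness
    if max_background is not None:
        ok &= m["background"] <= max_background

    passed = m[ok]
    per_array = ok.groupby(m["array_id"]).mean()
    dropped = sorted(set(m["array_id"]) - set(passed["array_id"]))
    for a in dropped:
        logger.warning("array %s dropped: all images failed QC", a)

    flagged = []
    if layout is not None:
        roles = layout.set_index(["array_id", "spot_id"])["role"]
        p_roles = passed.set_index(["array_id", "spot_id"]).index.map(roles)
        for arr, grp in passed.groupby("array_id"):
            r = np.asarray(p_roles)[np.asarray(passed["array_id"] == arr)]
            neg_i = grp.loc[r == "negative-control", "mean_cell_intensity"]
            pos_i = grp.loc[r == "positive-control", "mean_cell_intensity"]
            if len(neg_i) >= 3 and len(pos_i) >= 3:
                mad = stats.median_abs_deviation(neg_i, scale="normal")
                if mad > 0 and abs(pos_i.median() - neg_i.median()) < mad:
                    flagged.append(arr)
    report = {
        "n_input": int(len(m)),
        "n_passed": int(len(passed)),
        "pass_rate": float(ok.mean()) if len(m) else np.nan,
        "per_array_pass_rate": per_array.to_dict(),
        "arrays_dropped": dropped,
        "arrays_flagged": flagged,
    }
    return passed.reset_index(drop=True), report


def robust_z_scores(
    measurements: pd.DataFrame,
    layout: pd.DataFrame,
    *,
    scaled_mad: bool = True,
) -> pd.DataFrame:
    """Per-treatment, per-replicate robust Z-scores.

    Image-level mean cell intensities are first averaged within each
    biological replicate of a treatment; each replicate value is then
    centred by the median and scaled by the MAD of the negative-control
    intensities of the same physical array (the array instance identified
    by ``array_id`` + ``replicate``).  ``scaled_mad`` applies the 1.4826
    normal-consistency factor (the convention of common statistics
    environments); the raw MAD is available behind the switch.

    Arrays whose control MAD is zero are excluded with an error record in
    the log.  Requires >= 3 negative-control values per array instance.
    """
    lay = layout.copy()
    lay["treatment"] = [
        treatment_label(a, b) for a, b in zip(lay["gene_a"], lay["gene_b"])
    ]
    merged = measurements.merge(
        lay[["array_id", "spot_id", "treatment", "role"]],
        on=["array_id", "spot_id"], how="inner",
    )
    scale_kw = "normal" if scaled_mad else 1.0
    rows = []
    for (arr, rep), grp in merged.groupby(["array_id", "replicate"]):
        controls = grp.loc[grp["role"] == "negative-control", "mean_cell_intensity"]
        if len(controls) < 3:
            logger.error("array %s replicate %s: <3 negative controls, skipped", arr, rep)
            continue
        center = float(controls.median())
        mad = float(stats.median_abs_deviation(controls, scale=scale_kw))
        if mad <= 0:
            logger.error("array %s replicate %s: control MAD is zero, excluded", arr, rep)
            continue
        rep_means = grp.groupby("treatment")["mean_cell_intensity"].mean()
        for treatment, value in rep_means.items():
            rows.append({
                "treatment": treatment,
                "array_id": arr,
                "replicate": rep,
                "z": (value - center) / mad,
            })
    return pd.DataFrame(rows, columns=["treatment", "array_id", "replicate", "z"])


def median_robust_z(ztable: pd.DataFrame) -> pd.Series:
    """Median robust Z per treatment across replicates (heatmap statistic)."""
    return ztable.groupby("treatment")["z"].median()


@dataclass
class ScreenFit:
    """Fitted five-model battery for one siRNA pair."""

    pair: tuple
    results: PairInteractionResults

    @property
    def interaction_value(self) -> float:
        return self.results.beta_ab

    @property
    def beta_0(self) -> float:
        f = self.results.fits.get(self.results.full_model)
        if f is None or "const" not in f.coefficients.index:
            return np.nan
        return float(f.coefficients.loc["const", "estimate"])

    @property
    def evidence(self) -> str:
        return "strong" if self.results.comparison.strong_evidence() else "ambiguous"


def _pull(ztable: pd.DataFrame, treatment: str) -> np.ndarray:
    return ztable.loc[ztable["treatment"] == treatment, "z"].to_numpy(dtype=float)


def fit_screen_models(
    z_single_a,
    z_single_b,
    z_double,
    z_controls,
    *,
    pair: tuple = ("A", "B"),
    min_replicates: int = 3,
    **fit_kw,
) -> Optional[ScreenFit]:
    """Fit Models 0-4 to the pooled replicate Z-scores of one pair.

    The response concatenates the negative-control, single-knockdown and
    double-knockdown replicate Z-scores; indicator predictors mark the
    presence of each siRNA.  Control values anchor the baseline intercept.
    Returns ``None`` (pair inestimable) when any required treatment has
    fewer than ``min_replicates`` values.
    """
    za = np.asarray(z_single_a, dtype=float)
    zb = np.asarray(z_single_b, dtype=float)
    zab = np.asarray(z_double, dtype=float)
    zc = np.asarray(z_controls, dtype=float)
    if min(len(za), len(zb), len(zab), len(zc)) < min_replicates:
        return None
    y = np.concatenate([zc, za, zb, zab])
    xa = np.concatenate([np.zeros(len(zc)), np.ones(len(za)),
                         np.zeros(len(zb)), np.ones(len(zab))])
    xb = np.concatenate([np.zeros(len(zc)), np.zeros(len(za)),
                         np.ones(len(zb)), np.ones(len(zab))])
    model = PairInteractionModel(
        y, xa, xb, family="gaussian-robust", include_baseline=True,
        names=pair, pair_id=pair,
    )
    return ScreenFit(pair=tuple(pair), results=model.fit(**fit_kw))


def classify_gi_type(
    beta_a: float,
    beta_b: float,
    beta_ab: float,
    tau: float,
    beta_0: float = 0.0,
) -> str:
    """Taxonomy of a significant genetic interaction.

    Severity is deviation from the control baseline in the direction of
    the dominant single effect M (the single effect of larger magnitude):
    with s(x) = x * sign(M), the joint effect J = b0+bA+bB+bAB is

    * negative-aggravating when s(J) exceeds both the additive expectation
      and the dominant single by more than the tolerance ``tau``;
    * positive-alleviating when s(J) is within ``tau`` of the dominant
      single effect (joint ~ most severe single phenotype);
    * positive-suppressive when s(J) falls short of the dominant single by
      more than ``tau`` (joint 'healthier' than the worst single).

    A joint effect between the single and the additive expectation (partial
    alleviation) is labelled alleviating.  If both singles are within
    ``tau`` of zero the dominant direction is undefined and the pair is
    labelled "emergent" and reported separately.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    singles = np.array([beta_a, beta_b], dtype=float)
    m = singles[np.argmax(np.abs(singles))]
    if abs(m) <= tau:
        return "emergent"
    sign = np.sign(m)
    joint = beta_0 + beta_a + beta_b + beta_ab
    expect = beta_0 + beta_a + beta_b
    s_joint, s_expect, s_m = joint * sign, expect * sign, m * sign
    if s_joint > max(s_expect, s_m) + tau:
        return "negative-aggravating"
    if abs(s_joint - s_m) <= tau:
        return "positive-alleviating"
    if s_joint < s_m - tau:
        return "positive-suppressive"
    return "positive-alleviating"


def screen_scan(
    ztable: pd.DataFrame,
    pairs: Optional[Iterable[tuple[str, str]]] = None,
    *,
    genes: Optional[Sequence[str]] = None,
    alpha_gi: float = ALPHA_GI,
    alpha_excl: float = ALPHA_EXCL,
    alpha_single: float = ALPHA_SINGLE,
    tau: Optional[float] = None,
) -> pd.DataFrame:
    """Run the screen battery over every gene pair and classify the calls.

    ``pairs`` defaults to all unordered pairs of ``genes`` (or of every
    gene seen in single-knockdown treatments).  The FDR family pools the
    three per-term p-values of all pairs (3 x n_pairs slots, minus
    inestimable entries).  ``tau`` overrides the taxonomy tolerance, which
    otherwise defaults per pair to the standard error of the
    double-knockdown replicate mean.
    """
    import itertools

    if pairs is None:
        if genes is None:
            # infer the panel from pair treatments (controls never pair up)
            pair_treatments = ztable.loc[
                ~ztable["treatment"].str.split("__").map(
                    lambda gg: bool({CONTROL_LABEL, "INCENP"} & set(gg))
                ),
                "treatment",
            ]
            genes = sorted({g for t in pair_treatments for g in t.split("__")})
        pairs = list(itertools.combinations(sorted(genes), 2))
    pairs = [tuple(sorted(p)) for p in pairs]

    z_ctrl = _pull(ztable, treatment_label(CONTROL_LABEL, CONTROL_LABEL))
    rows = []
    for a, b in pairs:
        za = _pull(ztable, treatment_label(a, CONTROL_LABEL))
        zb = _pull(ztable, treatment_label(b, CONTROL_LABEL))
        zab = _pull(ztable, treatment_label(a, b))
        fit = fit_screen_models(za, zb, zab, z_ctrl, pair=(a, b))
        if fit is None:
            logger.warning("pair %s__%s inestimable: missing treatment", a, b)
            rows.append({"pair": treatment_label(a, b), "_fit": None, "_tau": np.nan})
            continue
        pair_tau = tau if tau is not None else (
            float(np.std(zab, ddof=1) / np.sqrt(len(zab))) if len(zab) > 1 else 0.0
        )
        rows.append({"pair": treatment_label(a, b), "_fit": fit, "_tau": pair_tau})

    def field(r, attr, default=np.nan):
        return getattr(r["_fit"], attr) if r["_fit"] is not None else default

    table = pd.DataFrame({
        "pair": [r["pair"] for r in rows],
        "beta_0": [field(r, "beta_0") for r in rows],
        "beta_a": [r["_fit"].results.beta_a if r["_fit"] else np.nan for r in rows],
        "beta_b": [r["_fit"].results.beta_b if r["_fit"] else np.nan for r in rows],
        "interaction_value": [field(r, "interaction_value") for r in rows],
    })
    for mid in range(5):
        table[f"bic_m{mid}"] = [
            r["_fit"].results.bic(mid) if r["_fit"] else np.nan for r in rows
        ]
    table["best_model"] = [
        r["_fit"].results.best_model if r["_fit"] and r["_fit"].results.comparison.available
        else np.nan
        for r in rows
    ]
    table["delta_bic"] = [
        r["_fit"].results.delta_bic if r["_fit"] else np.nan for r in rows
    ]
    table["evidence"] = [field(r, "evidence", "unavailable") for r in rows]
    for term in ("a", "b", "ab"):
        table[f"p_{term}"] = [
            getattr(r["_fit"].results, f"p_{term}") if r["_fit"] else np.nan
            for r in rows
        ]

    m = len(table)
    adj = bh_fdr(np.concatenate([table["p_a"], table["p_b"], table["p_ab"]]))
    table["p_a_fdr"], table["p_b_fdr"], table["p_ab_fdr"] = adj[:m], adj[m:2*m], adj[2*m:]

    classifications, gi_types = [], []
    for i, r in enumerate(rows):
        if r["_fit"] is None:
            classifications.append("none")
            gi_types.append("")
            continue
        res = r["_fit"].results
        label = classify_pair(
            table.loc[i, "p_ab_fdr"], table.loc[i, "p_a_fdr"], table.loc[i, "p_b_fdr"],
            res.best_model, res.testable,
            alpha_gi=alpha_gi, alpha_excl=alpha_excl, alpha_single=alpha_single,
        )
        classifications.append(label)
        gi_types.append(
            classify_gi_type(
                table.loc[i, "beta_a"], table.loc[i, "beta_b"],
                table.loc[i, "interaction_value"], r["_tau"],
                beta_0=table.loc[i, "beta_0"],
            ) if label == "GI" else ""
        )
    table["classification"] = classifications
    table["gi_type"] = gi_types
    return table[SCREEN_RESULT_COLUMNS]


def validate_gi_calls(
    primary: pd.DataFrame,
    validation: pd.DataFrame,
    *,
    alpha_validation: float = 0.01,
) -> pd.DataFrame:
    """Confirm primary-screen interaction calls in a replication screen.

    A pair is validated when its replication FDR-adjusted interaction p is
    below ``alpha_validation`` and the replication Interaction Value has
    the same sign as in the primary screen.  Pairs present only in the
    validation table are skipped with a warning.
    """
    prim = primary.set_index("pair")
    rows = []
    for r in validation.itertuples():
        if r.pair not in prim.index:
            logger.warning("validation pair %s absent from primary calls, skipped", r.pair)
            continue
        iv_primary = prim.loc[r.pair, "interaction_value"]
        same_sign = (
            np.isfinite(iv_primary) and np.isfinite(r.interaction_value)
            and np.sign(iv_primary) == np.sign(r.interaction_value)
            and np.sign(iv_primary) != 0
        )
        rows.append({
            "pair": r.pair,
            "interaction_value_primary": iv_primary,
            "interaction_value_validation": r.interaction_value,
            "p_ab_fdr_validation": r.p_ab_fdr,
            "validated": bool(
                np.isfinite(r.p_ab_fdr)
                and r.p_ab_fdr < alpha_validation and same_sign
            ),
        })
    return pd.DataFrame(
        rows, columns=[
            "pair", "interaction_value_primary", "interaction_value_validation",
            "p_ab_fdr_validation", "validated",
        ],
    )
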