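"""The cohort (genetics) arm: residualization, predictor encodings and the
pairwise scan over four test designs.

The scan mirrors a biobank-scale analysis of quantitative lipid traits
(LDLc, HDLc, TG, TC, mg/dl) and a binary coronary-artery-disease outcome:

* quantitative traits are first residualized against the covariate set
  (age, sex, smoking, alcohol, BMI, lipid medication, ten genetic PCs) and
  the residuals enter robust pairwise batteries;
* the binary trait keeps the covariates inside each logistic model;
* predictors come in four pairings — rare-PTV gene burden x gene burden,
  common-SNP dosage x dosage, dosage x burden, and burden x trait-matched
  polygenic score with the gene's own SNPs excluded from the score.

Each design forms its own Benjamini–Hochberg family: (number of pair-trait
units) x 3 tested effects, pooled across traits within the design but never
across designs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .interaction import (
    ALPHA_EXCL,
    ALPHA_GI,
    ALPHA_SINGLE,
    PairInteractionModel,
    classify_pair,
)
from .selection import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "LIPID_TRAITS",
    "COVARIATES",
    "DESIGNS",
    "GeneBurden",
    "residualize_phenotypes",
    "encode_ptv_burden",
    "compute_prs",
    "enumerate_pairs",
    "run_pairwise_scan",
    "condition_on_variant",
    "RESULT_COLUMNS",
]

LIPID_TRAITS = ("LDLc", "HDLc", "TG", "TC")
COVARIATES = (
    "age", "sex", "smoking", "alcohol", "BMI", "lipid_medication",
    "PC1", "PC2", "PC3", "PC4", "PC5", "PC6", "PC7", "PC8", "PC9", "PC10",
)
DESIGNS = ("PTV-PTV", "SNP-SNP", "PTV-SNP", "PTV-PRS")

#: Fixed column order of the per-design results table.
RESULT_COLUMNS = [
    "pair", "trait", "bic_m1", "bic_m2", "bic_m3", "bic_m4",
    "best_model", "delta_bic", "beta_a", "beta_b", "beta_ab",
    "p_a", "p_b", "p_ab", "p_a_fdr", "p_b_fdr", "p_ab_fdr",
    "testable", "n", "n_joint", "classification",
]


def residualize_phenotypes(
    cohort: pd.DataFrame,
    traits: Sequence[str] = LIPID_TRAITS,
    covariates: Sequence[str] = COVARIATES,
) -> pd.DataFrame:
    """Regress each quantitative trait on the covariate set; return residuals.

    One ordinary least-squares fit per trait; residuals are aligned to the
    cohort's sample index, NaN where the trait (or any covariate) was
    missing.  Zero-variance covariate columns are dropped with a warning.
    The binary disease trait is never residualized — its covariates enter
    the logistic battery directly.
    """
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    cov = cohort.loc[:, list(covariates)].astype(float)
    const = [c for c in cov.columns if cov[c].nunique(dropna=True) <= 1]
    if const:
        logger.warning("dropping zero-variance covariates: %s", const)
        cov = cov.drop(columns=const)
    complete = cov.notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("dropping %d samples with missing covariates", n_drop)
    if complete.sum() < len(cov.columns) + 2:
        raise ValueError("too few complete samples to residualize")

    X = sm.add_constant(cov.loc[complete])
    out = pd.DataFrame(index=cohort.index, columns=list(traits), dtype=float)
    for trait in traits:
        y = cohort.loc[complete, trait].astype(float)
        ok = y.notna()
        res = sm.OLS(y[ok], X.loc[ok.index[ok]]).fit()
        out.loc[res.resid.index, trait] = res.resid
    return out


@dataclass
class GeneBurden:
    """Per-sample, per-gene collapsed rare-variant predictor.

    ``burden`` is a samples x genes frame: carrier indicator (0/1) or PTV
    count depending on ``mode``.  ``provenance`` retains the qualifying
    call rows so any burden cell can be traced to its contributing
    variants.
    """

    burden: pd.DataFrame
    mode: str
    provenance: pd.DataFrame

    def carriers(self) -> pd.Series:
        """Carrier count per gene (samples with burden > 0)."""
        return (self.burden > 0).sum(axis=0)


def encode_ptv_burden(
    ptv_calls: pd.DataFrame,
    samples: Sequence,
    *,
    mode: str = "indicator",
    exclude_variants: Iterable[str] = (),
    genes: Optional[Sequence[str]] = None,
) -> GeneBurden:
    """Collapse per-variant PTV calls into a per-gene burden per sample.

    ``ptv_calls`` needs columns ``sample_id``, ``gene``, ``variant_id``.
    Variants in ``exclude_variants`` are ignored before collapsing, which
    supports conditioning a scan on a single prevalent allele; excluding a
    variant can therefore only ever lower a sample's burden.
    """
    if mode not in ("indicator", "count"):
        raise ValueError("mode must be 'indicator' or 'count'")
    required = {"sample_id", "gene", "variant_id"}
    if not required <= set(ptv_calls.columns):
        raise ValueError(f"ptv_calls must have columns {sorted(required)}")
    excl = set(exclude_variants)
    unknown = excl - set(ptv_calls["variant_id"])
    if unknown:
        logger.warning("excluded variants not present in calls: %s", sorted(unknown))
    kept = ptv_calls[~ptv_calls["variant_id"].isin(excl)]
    gene_list = list(genes) if genes is not None else sorted(ptv_calls["gene"].unique())
    counts = (
        kept.groupby(["sample_id", "gene"]).size().unstack(fill_value=0)
        .reindex(index=list(samples), columns=gene_list, fill_value=0)
        .astype(int)
    )
    if mode == "indicator":
        counts = (counts > 0).astype(int)
    return GeneBurden(burden=counts, mode=mode, provenance=kept.copy())


def compute_prs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    exclude_gene_region: Optional[tuple] = None,
) -> pd.Series:
    """Weighted allele-dosage sum per sample.

    ``weights`` needs columns ``snp`` and ``weight`` (and ``chrom``/``pos``
    when a region is excluded).  ``exclude_gene_region`` is a
    ``(chrom, start, end)`` interval; score SNPs falling inside it are
    removed before summation, so a gene is never tested against a score
    that contains its own signal.
    """
    w = weights.copy()
    if exclude_gene_region is not None:
        chrom, start, end = exclude_gene_region
        inside = (
            (w["chrom"].astype(str) == str(chrom))
            & (w["pos"] >= start) & (w["pos"] <= end)
        )
        if inside.any():
            logger.info("excluding %d score SNPs in region %s", int(inside.sum()),
                        exclude_gene_region)
        w = w[~inside]
    if w.empty:
        raise ValueError("no score SNPs remain after exclusion")
    present = w["snp"].isin(dosages.columns)
    if not present.all():
        logger.warning("%d weighted SNPs absent from dosages", int((~present).sum()))
        w = w[present]
    if w.empty:
        raise ValueError("no weighted SNPs present in dosages")
    mat = dosages.loc[:, w["snp"]].to_numpy(dtype=float)
    return pd.Series(mat @ w["weight"].to_numpy(dtype=float), index=dosages.index)


def canonical_pair(a: str, b: str) -> str:
    """Lexicographically sorted pair label joined by '__'."""
    return "__".join(sorted((str(a), str(b))))


def enumerate_pairs(
    design: str,
    *,
    genes: Optional[Sequence[str]] = None,
    snps: Optional[Sequence[str]] = None,
    gene_snp_map: Optional[Mapping[str, str]] = None,
    traits: Sequence[str] = LIPID_TRAITS,
) -> list[tuple[str, str]]:
    """Enumerate the predictor pairs a design tests.

    PTV-PTV and SNP-SNP take unordered pairs of genes / SNPs; PTV-SNP takes
    every (SNP, gene) combination except a lead SNP paired with the burden
    of the gene(s) it is mapped to; PTV-PRS pairs every gene with the
    polygenic score of every tested trait.
    """
    if design == "PTV-PTV":
        return [tuple(sorted(p)) for p in itertools.combinations(sorted(genes), 2)]
    if design == "SNP-SNP":
        return [tuple(sorted(p)) for p in itertools.combinations(sorted(snps), 2)]
    if design == "PTV-SNP":
        if gene_snp_map is None:
            raise ValueError("PTV-SNP design requires a gene<->SNP mapping")
        return [
            (snp, gene)
            for snp in sorted(snps)
            for gene in sorted(genes)
            if gene_snp_map.get(gene) != snp
        ]
    if design == "PTV-PRS":
        return [(gene, f"PRS_{trait}") for gene in sorted(genes) for trait in traits]
    raise ValueError(f"unknown design {design!r}")


def _scan_units(design, pairs, traits):
    """Yield (pair, trait) units; the PRS design binds each score to its trait."""
    if design == "PTV-PRS":
        for gene, prs_label in pairs:
            yield (gene, prs_label), prs_label.removeprefix("PRS_")
    else:
        for pair in pairs:
            for trait in traits:
                yield pair, trait


def run_pairwise_scan(
    design: str,
    *,
    residuals: Optional[pd.DataFrame] = None,
    cohort: Optional[pd.DataFrame] = None,
    burden: Optional[GeneBurden] = None,
    dosages: Optional[pd.DataFrame] = None,
    prs_weights: Optional[Mapping[str, pd.DataFrame]] = None,
    prs_dosages: Optional[pd.DataFrame] = None,
    gene_regions: Optional[pd.DataFrame] = None,
    gene_snp_map: Optional[Mapping[str, str]] = None,
    traits: Sequence[str] = LIPID_TRAITS,
    genes: Optional[Sequence[str]] = None,
    snps: Optional[Sequence[str]] = None,
    min_joint: int = 1,
    alpha_gi: float = ALPHA_GI,
    alpha_excl: float = ALPHA_EXCL,
    alpha_single: float = ALPHA_SINGLE,
) -> pd.DataFrame:
    """Run the four-model battery over every (pair, trait) unit of a design.

    Returns one row per unit in the fixed :data:`RESULT_COLUMNS` order.
    The FDR family is the pooled set of the three per-term p-values of all
    units of this design (missing, inestimable entries excluded); the
    two-step classifier is then applied to every unit.

    The binary trait ``CAD`` may be included in ``traits`` for the SNP-SNP
    design; it requires ``cohort`` for the disease column and covariates.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    if genes is None and burden is not None:
        genes = list(burden.burden.columns)
    if snps is None and dosages is not None:
        snps = list(dosages.columns)
    pairs = enumerate_pairs(
        design, genes=genes, snps=snps, gene_snp_map=gene_snp_map,
        traits=[t for t in traits if t != "CAD"],
    )
    if not pairs:
        raise ValueError("empty pair list")

    prs_cache: dict[tuple[str, str], pd.Series] = {}

    def predictor(kind: str, name: str, gene_excluded: Optional[str] = None) -> pd.Series:
        if kind == "gene":
            return burden.burden[name]
        if kind == "snp":
            return dosages[name]
        if kind == "prs":
            trait = name.removeprefix("PRS_")
            key = (trait, gene_excluded)
            if key not in prs_cache:
                region = None
                if gene_excluded is not None and gene_regions is not None:
                    row = gene_regions.set_index("gene").loc[gene_excluded]
                    region = (row["chrom"], row["start"], row["end"])
                prs_cache[key] = compute_prs(prs_dosages, prs_weights[trait], region)
            return prs_cache[key]
        raise ValueError(kind)

    rows = []
    for pair, trait in _scan_units(design, pairs, traits):
        if design == "PTV-PTV":
            x1, x2 = predictor("gene", pair[0]), predictor("gene", pair[1])
        elif design == "SNP-SNP":
            x1, x2 = predictor("snp", pair[0]), predictor("snp", pair[1])
        elif design == "PTV-SNP":
            x1, x2 = predictor("snp", pair[0]), predictor("gene", pair[1])
        else:  # PTV-PRS: score excludes the tested gene's own region
            gene = pair[0]
            x1, x2 = predictor("prs", pair[1], gene_excluded=gene), predictor("gene", gene)

        if trait == "CAD":
            if cohort is None:
                raise ValueError("CAD battery requires the cohort table")
            y = cohort["CAD"].astype(float)
            cov = cohort.loc[:, [c for c in COVARIATES if c in cohort.columns]]
            idx = y.dropna().index.intersection(x1.index).intersection(x2.index)
            model = PairInteractionModel(
                y.loc[idx], x1.loc[idx], x2.loc[idx], family="binomial",
                covariates=cov.loc[idx], min_joint=min_joint,
                names=pair, pair_id=pair,
            )
        else:
            y = residuals[trait].dropna()
            idx = y.index.intersection(x1.index).intersection(x2.index)
            model = PairInteractionModel(
                y.loc[idx], x1.loc[idx], x2.loc[idx], family="gaussian-robust",
                min_joint=min_joint, names=pair, pair_id=pair,
            )
        res = model.fit()
        rows.append({
            "pair": canonical_pair(*pair) if design in ("PTV-PTV", "SNP-SNP")
                    else f"{pair[0]}__{pair[1]}",
            "trait": trait,
            "bic_m1": res.bic(1), "bic_m2": res.bic(2),
            "bic_m3": res.bic(3), "bic_m4": res.bic(4),
            "best_model": res.best_model if res.comparison.available else np.nan,
            "delta_bic": res.delta_bic,
            "beta_a": res.beta_a, "beta_b": res.beta_b, "beta_ab": res.beta_ab,
            "p_a": res.p_a, "p_b": res.p_b, "p_ab": res.p_ab,
            "testable": res.testable, "n": res.n, "n_joint": res.n_joint,
        })
    table = pd.DataFrame(rows)

    # One pooled FDR family for the whole design: 3 effects per unit.
    flat = np.concatenate([table["p_a"], table["p_b"], table["p_ab"]])
    adj = bh_fdr(flat)
    m = len(table)
    table["p_a_fdr"], table["p_b_fdr"], table["p_ab_fdr"] = (
        adj[:m], adj[m:2 * m], adj[2 * m:]
    )
    table["classification"] = [
        classify_pair(
            r.p_ab_fdr, r.p_a_fdr, r.p_b_fdr, r.best_model, r.testable,
            alpha_gi=alpha_gi, alpha_excl=alpha_excl, alpha_single=alpha_single,
        )
        for r in table.itertuples()
    ]
    return table[RESULT_COLUMNS]


def condition_on_variant(
    ptv_calls: pd.DataFrame,
    samples: Sequence,
    variant_id: str,
    *,
    mode: str = "indicator",
    genes: Optional[Sequence[str]] = None,
    **scan_kwargs,
) -> pd.DataFrame:
    """Sensitivity re-scan with one variant removed from the burden encoding.

    Re-runs the PTV-PTV battery after dropping ``variant_id`` from the
    per-gene burden (e.g. conditioning an LPL signal on its prevalent
    gain-of-function stop allele) and reports before/after results side by
    side with ``_before``/``_after`` suffixes.
    """
    if variant_id not in set(ptv_calls["variant_id"]):
        raise ValueError(f"variant {variant_id!r} not present in PTV calls")
    before = run_pairwise_scan(
        "PTV-PTV",
        burden=encode_ptv_burden(ptv_calls, samples, mode=mode, genes=genes),
        **scan_kwargs,
    )
    after = run_pairwise_scan(
        "PTV-PTV",
        burden=encode_ptv_burden(
            ptv_calls, samples, mode=mode, genes=genes,
            exclude_variants={variant_id},
        ),
        **scan_kwargs,
    )
    return before.merge(
        after, on=["pair", "trait"], suffixes=("_before", "_after")
    )
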