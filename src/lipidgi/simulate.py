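"""Synthetic cohort and screen generators with exportable planted truth.

The generators emit tables with the statistical structure the analysis
assumes, at configurable scale, so every pipeline stage can be exercised
against known ground truth:

* :func:`simulate_cohort` — a biobank-like cohort: covariate-confounded
  Gaussian lipid traits (mg/dl) and a logistic binary disease trait, rare
  per-gene PTV carriers, common 0/1/2 SNP dosages, and per-trait polygenic
  score weights, with planted single-gene, additive and interaction
  effects expressed in trait-SD units.
* :func:`simulate_screen` — a cell-microarray screen: spot layouts with
  negative/positive/transfection controls, log-normal per-image
  intensities whose planted knockdown effects live on the robust-Z scale,
  replicate-level biological noise, and injected quality-control failures.

Both are pure functions of (config, seed): the same configuration always
reproduces identical tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import LIPID_TRAITS
from .screen import CONTROL_LABEL, classify_gi_type, treatment_label

__all__ = [
    "PANEL_GENES",
    "CohortSimConfig",
    "ScreenSimConfig",
    "SimulatedCohort",
    "SimulatedScreen",
    "simulate_cohort",
    "simulate_screen",
]

#: Default 30-gene lipid panel used by both simulators.  The names are the
#: lipid-biology genes the package's analyses are organised around; the
#: genotypes, variants and coordinates attached to them are synthetic.
PANEL_GENES = (
    "APOB", "APOE", "BCAM", "CBLC", "CELSR2", "CETP", "CXCL12", "FAM174A",
    "HAVCR1", "HMGCR", "LDLR", "LDLRAP1", "LPL", "MLXIPL", "MYBPHL",
    "MYLIP", "NCAN", "NPC1L1", "PAFAH1B1", "PAFAH1B2", "PCSK9", "PVRL2",
    "SEZ6L", "SIK3", "SORT1", "TM6SF2", "TMEM57", "TOMM40", "ZNF259",
    "ANGPTL3",
)

TRAIT_MEANS = {"LDLc": 138.3, "HDLc": 55.0, "TG": 150.0, "TC": 200.0}
TRAIT_NOISE_SD = {"LDLc": 33.0, "HDLc": 15.0, "TG": 55.0, "TC": 40.0}

#: Covariate effects per trait, in trait units per covariate unit.  These
#: exist only to create realistic confounding; residualization removes
#: them before any genetic test.
COVARIATE_EFFECTS = {
    "age": 0.4,      # per year
    "sex": -5.0,
    "smoking": 3.0,
    "alcohol": 1.5,
    "BMI": 0.8,      # per kg/m^2
    "lipid_medication": -20.0,
    "PC1": 2.0,
    "PC2": -1.0,
}


def _default_gene_snp_map(genes: Sequence[str]) -> dict[str, str]:
    """One lead SNP per gene; two loci carry two genes each, so a panel of
    30 genes yields 28 distinct SNPs (a SNP is shared within a locus)."""
    genes = list(genes)
    mapping = {}
    # two adjacent gene couples share a locus (and hence a lead SNP)
    share_pairs = [(genes[i], genes[i + 1]) for i in (4, 10)] if len(genes) >= 12 else []
    snp_idx = 1
    for g in genes:
        partner = next((a for a, b in share_pairs if b == g), None)
        if partner is not None and partner in mapping:
            mapping[g] = mapping[partner]
            continue
        mapping[g] = f"rs{100000 + snp_idx}"
        snp_idx += 1
    return mapping


@dataclass
class CohortSimConfig:
    """Generating conditions for the synthetic cohort.

    ``effects`` plants genetic signal, keyed ``"TRAIT|TERM"`` where TERM is
    ``PTV:GENE``, ``SNP:rsID``, ``PRS``, or a product of two such terms
    joined by ``*`` (an interaction).  Values are in units of the trait's
    noise SD (log-odds for the binary trait ``CAD``).
    """

    n_samples: int = 5000
    genes: tuple = PANEL_GENES
    carrier_freq: float | Mapping[str, float] = 0.01
    maf: Optional[Mapping[str, float]] = None        # default: U(0.03, 0.35) per SNP
    variants_per_gene: int = 5
    trait_means: Mapping[str, float] = field(default_factory=lambda: dict(TRAIT_MEANS))
    trait_noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(TRAIT_NOISE_SD))
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(COVARIATE_EFFECTS))
    effects: Mapping[str, float] = field(default_factory=dict)
    n_background_snps: int = 200
    prs_main_effect: float = 0.3     # trait-SD per PRS-SD, every lipid trait
    cad_prevalence: float = 0.08
    seed: int = 0

    def __post_init__(self):
        freqs = (self.carrier_freq.values()
                 if isinstance(self.carrier_freq, Mapping) else [self.carrier_freq])
        if not all(0 < f < 0.5 for f in freqs):
            raise ValueError("carrier frequencies must lie in (0, 0.5)")
        if any(sd <= 0 for sd in self.trait_noise_sd.values()):
            raise ValueError("trait noise SDs must be positive")


@dataclass
class SimulatedCohort:
    """Synthetic cohort bundle: analysis inputs plus planted truth."""

    cohort: pd.DataFrame            # sample_id index; traits, CAD, covariates
    ptv_calls: pd.DataFrame         # sample_id, gene, variant_id
    dosages: pd.DataFrame           # samples x panel SNPs
    prs_dosages: pd.DataFrame       # samples x (panel + background) SNPs
    prs_weights: dict               # trait -> weights table (snp, chrom, pos, weight)
    gene_regions: pd.DataFrame      # gene, chrom, start, end
    gene_snp_map: dict              # gene -> lead SNP
    truth: pd.DataFrame             # trait, term, beta (trait-SD / log-odds units)
    config: CohortSimConfig


def _parse_term(term: str) -> list[str]:
    return term.split("*")


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort from the configured generating model.

    Covariates: age ~ U(40, 69) (a mid-life recruitment window), binary
    lifestyle/medication indicators, BMI ~ N(27, 4), ten standard-normal
    genetic PCs.  Each lipid trait is its mean + covariate signal + the
    planted genetic terms (scaled by the trait noise SD) + Gaussian noise.
    The binary trait comes from a logistic link with the same covariate
    confounding and any planted log-odds terms.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    genes = list(config.genes)
    sample_ids = [f"S{i:07d}" for i in range(n)]

    # ---- covariates ------------------------------------------------------
    cov = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    cov["age"] = rng.uniform(40, 69, n)
    cov["sex"] = rng.binomial(1, 0.5, n)
    cov["smoking"] = rng.binomial(1, 0.3, n)
    cov["alcohol"] = rng.binomial(1, 0.7, n)
    cov["BMI"] = rng.normal(27, 4, n)
    cov["lipid_medication"] = rng.binomial(1, 0.2, n)
    for j in range(1, 11):
        cov[f"PC{j}"] = rng.normal(0, 1, n)

    # ---- rare PTV carriers ----------------------------------------------
    freq = (dict(config.carrier_freq) if isinstance(config.carrier_freq, Mapping)
            else {g: config.carrier_freq for g in genes})
    # skewed variant pool so each gene has a clearly most-prevalent allele
    vprobs = np.array([0.6, 0.2, 0.1, 0.07, 0.03][: config.variants_per_gene])
    vprobs = vprobs / vprobs.sum()
    calls = []
    carrier = pd.DataFrame(0, index=cov.index, columns=genes, dtype=int)
    for g in genes:
        is_carrier = rng.random(n) < freq.get(g, 0.01)
        carrier[g] = is_carrier.astype(int)
        idx = np.flatnonzero(is_carrier)
        variants = rng.choice(config.variants_per_gene, size=len(idx), p=vprobs)
        for i, v in zip(idx, variants):
            calls.append((sample_ids[i], g, f"{g}_v{v + 1}"))
    ptv_calls = pd.DataFrame(calls, columns=["sample_id", "gene", "variant_id"])

    # ---- common dosages and gene coordinates -----------------------------
    gene_snp_map = _default_gene_snp_map(genes)
    panel_snps = sorted(set(gene_snp_map.values()))
    maf = dict(config.maf) if config.maf else {
        s: float(f) for s, f in zip(panel_snps, rng.uniform(0.03, 0.35, len(panel_snps)))
    }
    dosages = pd.DataFrame(
        {s: rng.binomial(2, maf[s], n) for s in panel_snps},
        index=cov.index, dtype=int,
    )
    regions = []
    snp_pos = {}
    for i, g in enumerate(genes):
        chrom = (i % 18) + 1
        start = 1_000_000 * (i + 1)
        regions.append((g, chrom, start, start + 50_000))
        snp_pos.setdefault(gene_snp_map[g], (chrom, start + 25_000))
    gene_regions = pd.DataFrame(regions, columns=["gene", "chrom", "start", "end"])

    # ---- polygenic score: panel SNPs + genome-wide background ------------
    bg_snps = [f"bg{j:05d}" for j in range(config.n_background_snps)]
    bg_maf = rng.uniform(0.05, 0.45, len(bg_snps))
    bg_dos = pd.DataFrame(
        {s: rng.binomial(2, f, n) for s, f in zip(bg_snps, bg_maf)},
        index=cov.index, dtype=int,
    )
    prs_dosages = pd.concat([dosages, bg_dos], axis=1)
    prs_weights: dict[str, pd.DataFrame] = {}
    prs_scores: dict[str, np.ndarray] = {}
    for trait in LIPID_TRAITS:
        w_panel = rng.normal(0, 0.05, len(panel_snps))
        w_bg = rng.normal(0, 0.02, len(bg_snps))
        tbl = pd.DataFrame({
            "snp": panel_snps + bg_snps,
            "chrom": [snp_pos[s][0] for s in panel_snps] + [99] * len(bg_snps),
            "pos": [snp_pos[s][1] for s in panel_snps]
                   + list(range(1, len(bg_snps) + 1)),
            "weight": np.concatenate([w_panel, w_bg]),
        })
        prs_weights[trait] = tbl
        raw = prs_dosages.to_numpy(dtype=float) @ tbl["weight"].to_numpy()
        sd = raw.std()
        prs_scores[trait] = (raw - raw.mean()) / (sd if sd > 0 else 1.0)

    # ---- assemble traits -------------------------------------------------
    def term_vector(term: str, trait: str) -> np.ndarray:
        parts = _parse_term(term)
        vec = np.ones(n)
        for p in parts:
            if p.startswith("PTV:"):
                vec = vec * carrier[p[4:]].to_numpy(dtype=float)
            elif p.startswith("SNP:"):
                vec = vec * dosages[p[4:]].to_numpy(dtype=float)
            elif p == "PRS":
                vec = vec * prs_scores[trait]
            else:
                raise ValueError(f"unknown effect term component {p!r}")
        return vec

    cohort = cov.copy()
    truth_rows = []
    for trait in LIPID_TRAITS:
        sd = config.trait_noise_sd[trait]
        y = np.full(n, config.trait_means[trait], dtype=float)
        for c, eff in config.covariate_effects.items():
            y += eff * cov[c].to_numpy(dtype=float)
        if config.prs_main_effect:
            y += config.prs_main_effect * sd * prs_scores[trait]
            truth_rows.append((trait, "PRS", config.prs_main_effect))
        for key, beta in config.effects.items():
            t, term = key.split("|", 1)
            if t != trait:
                continue
            y += beta * sd * term_vector(term, trait)
            truth_rows.append((trait, term, beta))
        y += rng.normal(0, sd, n)
        # lipid measurements are positive; the floor trims a negligible tail
        cohort[trait] = np.maximum(y, 1.0)

    # binary disease trait through a logistic link
    eta = np.full(n, math.log(config.cad_prevalence / (1 - config.cad_prevalence)))
    eta += 0.04 * (cov["age"] - 55) + 0.3 * cov["sex"] + 0.4 * cov["smoking"]
    eta += 0.03 * (cov["BMI"] - 27)
    for key, beta in config.effects.items():
        t, term = key.split("|", 1)
        if t == "CAD":
            eta += beta * term_vector(term, "LDLc")
            truth_rows.append(("CAD", term, beta))
    cohort["CAD"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)

    cohort = cohort[
        list(LIPID_TRAITS) + ["CAD"] + [c for c in cov.columns]
    ]
    truth = pd.DataFrame(truth_rows, columns=["trait", "term", "beta"])

    # warn about hopeless interaction designs
    for key, beta in config.effects.items():
        t, term = key.split("|", 1)
        parts = _parse_term(term)
        if len(parts) == 2 and all(p.startswith("PTV:") for p in parts) and beta != 0:
            f1, f2 = (freq.get(p[4:], 0.01) for p in parts)
            if n * f1 * f2 < 1:
                import warnings
                warnings.warn(
                    f"expected double-carrier count {n * f1 * f2:.2f} < 1 for "
                    f"planted interaction {term}: design underpowered",
                    stacklevel=2,
                )

    return SimulatedCohort(
        cohort=cohort, ptv_calls=ptv_calls, dosages=dosages,
        prs_dosages=prs_dosages, prs_weights=prs_weights,
        gene_regions=gene_regions, gene_snp_map=gene_snp_map,
        truth=truth, config=config,
    )


# ---------------------------------------------------------------------------
# screen simulator
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Generating conditions for the synthetic coRNAi screen.

    Planted knockdown effects live on the robust-Z scale: ``effects`` maps
    a gene name to its single-knockdown effect and a canonical ``A__B``
    pair label to the pair's interaction effect (both in control-MAD
    units).  Per-image intensities are log-normal — fluorescence is
    positive and right-skewed — with the control log-scale defining the
    Z unit, so planted and recovered values share units.
    """

    genes: tuple = PANEL_GENES
    spots_per_array: int = 384
    replicates_per_treatment: int = 8
    negative_control_spots: int = 8
    positive_control_spots: int = 8
    transfection_control_spots: int = 8
    single_spots_per_gene: int = 2
    images_per_spot: int = 2
    control_log_location: float = math.log(1000.0)  # arbitrary fluorescence units
    control_log_scale: float = 0.02                 # defines one robust-Z unit
    replicate_noise_sd: float = 0.5                 # z units, biological
    image_noise_sd: float = 0.25                    # z units, within replicate
    cells_per_spot_mean: float = 75.0
    qc_failure_rate: float = 0.1365
    effects: Mapping[str, float] = field(default_factory=dict)
    taxonomy_tau: float = 0.25                      # tolerance for truth labels
    seed: int = 0

    def __post_init__(self):
        if self.replicates_per_treatment < 3:
            raise ValueError("need >= 3 replicates per treatment")
        if self.negative_control_spots < 3:
            raise ValueError("need >= 3 negative-control spots per array")


@dataclass
class SimulatedScreen:
    layout: pd.DataFrame        # array_id, spot_id, gene_a, gene_b, role
    measurements: pd.DataFrame  # array_id, spot_id, image_id, replicate, ...
    truth: pd.DataFrame         # pair/gene term, planted beta, taxonomy label
    qc_truth: pd.DataFrame      # image_id, planted_fail
    config: ScreenSimConfig


def _build_layout(config: ScreenSimConfig) -> pd.DataFrame:
    """Distribute controls, single and pairwise knockdowns over array designs.

    Every array design carries the full control block and two spots per
    single-gene knockdown; the pairwise combinations (one spot per pair
    per design) are split across as many designs as capacity requires.
    """
    genes = sorted(config.genes)
    pairs = list(itertools.combinations(genes, 2))
    control_block = (
        [("INCENP", CONTROL_LABEL, "transfection-control")]
        * config.transfection_control_spots
        + [(CONTROL_LABEL, CONTROL_LABEL, "negative-control")]
        * config.negative_control_spots
        + [("LDLR", CONTROL_LABEL, "positive-control")]
        * config.positive_control_spots
    )
    singles = [
        (g, CONTROL_LABEL, "treatment")
        for g in genes for _ in range(config.single_spots_per_gene)
    ]
    capacity = config.spots_per_array - len(control_block) - len(singles)
    if capacity <= 0:
        raise ValueError("spots per array too few to hold panel plus controls")
    n_designs = max(1, math.ceil(len(pairs) / capacity))
    rows = []
    for d in range(n_designs):
        chunk = pairs[d * capacity:(d + 1) * capacity]
        # pair chunks come pre-sorted, so (A,B) and (B,A) never both appear
        spots = control_block + singles + [(a, b, "treatment") for a, b in chunk]
        for spot_id, (a, b, role) in enumerate(spots, start=1):
            rows.append((f"array{d + 1}", spot_id, a, b, role))
    return pd.DataFrame(
        rows, columns=["array_id", "spot_id", "gene_a", "gene_b", "role"]
    )


def simulate_screen(config: ScreenSimConfig) -> SimulatedScreen:
    """Draw a synthetic screen: layout, per-image measurements, truth.

    For a spot carrying genes (a, b), the planted replicate-level Z effect
    is ``e_a + e_b + e_ab`` (control slots contribute zero); each
    biological replicate adds N(0, replicate_noise_sd) and each image
    N(0, image_noise_sd), all on the Z scale, mapped into log-normal
    intensities through the control log-scale.  A configurable fraction of
    images is corrupted into QC failures (too few cells, blurred, or
    high-background).
    """
    rng = np.random.default_rng(config.seed)
    layout = _build_layout(config)
    eff = dict(config.effects)

    def spot_effect(gene_a: str, gene_b: str) -> float:
        e = 0.0
        for g in (gene_a, gene_b):
            if g not in (CONTROL_LABEL, "INCENP"):
                e += eff.get(g, 0.0)
        if gene_a != gene_b and CONTROL_LABEL not in (gene_a, gene_b):
            e += eff.get(treatment_label(gene_a, gene_b), 0.0)
        # positive/transfection controls get fixed strong phenotypes
        if gene_a == "INCENP":
            e += 0.0
        if gene_a == "LDLR" and gene_b == CONTROL_LABEL and "LDLR" not in eff:
            e += -4.0  # positive control: strong uptake knockdown
        return e

    s = config.control_log_scale
    rows = []
    qc_rows = []
    image_counter = 0
    # replicate-level biological noise is drawn once per (treatment, array
    # replicate) so images of the same replicate share it
    for rep in range(1, config.replicates_per_treatment + 1):
        for array_id, grp in layout.groupby("array_id", sort=True):
            rep_noise: dict[str, float] = {}
            for spot in grp.itertuples():
                label = treatment_label(spot.gene_a, spot.gene_b)
                if spot.role == "negative-control":
                    base = 0.0
                else:
                    base = spot_effect(spot.gene_a, spot.gene_b)
                if label not in rep_noise:
                    rep_noise[label] = rng.normal(0, config.replicate_noise_sd)
                is_neg = spot.role == "negative-control"
                z_rep = base + (0.0 if is_neg else rep_noise[label])
                for _ in range(config.images_per_spot):
                    image_counter += 1
                    # negative controls spread with unit SD on the Z scale:
                    # their image-level MAD defines one robust-Z unit
                    img_sd = 1.0 if is_neg else config.image_noise_sd
                    z_img = z_rep + rng.normal(0, img_sd)
                    intensity = math.exp(
                        config.control_log_location + s * z_img
                    )
                    cells = int(rng.poisson(config.cells_per_spot_mean))
                    sharp = rng.normal(1.0, 0.05)
                    background = rng.normal(100.0, 5.0)
                    fail = rng.random() < config.qc_failure_rate
                    if fail:
                        mode = rng.integers(3)
                        if mode == 0:
                            cells = int(rng.poisson(5))
                        elif mode == 1:
                            sharp = 0.5
                        else:
                            background = 200.0
                    rows.append((
                        array_id, spot.spot_id, f"img{image_counter:07d}", rep,
                        intensity, cells, sharp, background,
                    ))
                    qc_rows.append((f"img{image_counter:07d}", fail))

    measurements = pd.DataFrame(rows, columns=[
        "array_id", "spot_id", "image_id", "replicate",
        "mean_cell_intensity", "cell_count", "sharpness", "background",
    ])
    qc_truth = pd.DataFrame(qc_rows, columns=["image_id", "planted_fail"])

    genes = sorted(config.genes)
    truth_rows = [
        {"term": g, "beta": eff.get(g, 0.0), "kind": "single", "taxonomy": ""}
        for g in genes
    ]
    for a, b in itertools.combinations(genes, 2):
        lab = treatment_label(a, b)
        b_ab = eff.get(lab, 0.0)
        tax = ""
        if b_ab != 0.0:
            tax = classify_gi_type(
                eff.get(a, 0.0), eff.get(b, 0.0), b_ab, config.taxonomy_tau
            )
        truth_rows.append(
            {"term": lab, "beta": b_ab, "kind": "interaction", "taxonomy": tax}
        )
    truth = pd.DataFrame(truth_rows, columns=["term", "beta", "kind", "taxonomy"])
    return SimulatedScreen(
        layout=layout, measurements=measurements, truth=truth,
        qc_truth=qc_truth, config=config,
    )
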