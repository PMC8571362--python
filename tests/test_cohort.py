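"""Residualization, predictor encodings and the cohort pairwise scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidgi.cohort import (
    COVARIATES,
    canonical_pair,
    compute_prs,
    condition_on_variant,
    encode_ptv_burden,
    enumerate_pairs,
    residualize_phenotypes,
    run_pairwise_scan,
)


class TestResidualize:
    def test_residuals_orthogonal_to_covariates(self, small_cohort):
        res = residualize_phenotypes(small_cohort.cohort)
        for trait in res.columns:
            r = res[trait].dropna()
            for cov in ("age", "BMI", "PC1", "sex"):
                c = small_cohort.cohort.loc[r.index, cov].astype(float)
                if c.std() == 0:
                    continue
                assert abs(np.corrcoef(r, c)[0, 1]) < 1e-8

    def test_residual_variance_matches_noise_variance(self, rng):
        # trait built from covariates + known noise: residualization should
        # strip the covariate signal and leave the noise variance
        n = 4000
        cov = pd.DataFrame({
            "age": rng.uniform(40, 69, n), "sex": rng.binomial(1, 0.5, n),
            "smoking": rng.binomial(1, 0.3, n), "alcohol": rng.binomial(1, 0.7, n),
            "BMI": rng.normal(27, 4, n), "lipid_medication": rng.binomial(1, 0.2, n),
        } | {f"PC{i}": rng.normal(size=n) for i in range(1, 11)})
        noise_sd = 10.0
        cov["LDLc"] = 100 + 0.5 * cov["age"] + 2.0 * cov["BMI"] + rng.normal(0, noise_sd, n)
        res = residualize_phenotypes(cov, traits=["LDLc"])
        assert res["LDLc"].std() == pytest.approx(noise_sd, rel=0.05)

    def test_zero_variance_covariates_give_centred_trait(self, rng):
        n = 200
        cov = pd.DataFrame({c: np.ones(n) for c in COVARIATES})
        cov["LDLc"] = rng.normal(140, 30, n)
        res = residualize_phenotypes(cov, traits=["LDLc"])
        np.testing.assert_allclose(
            res["LDLc"], cov["LDLc"] - cov["LDLc"].mean(), atol=1e-8
        )

    def test_missing_covariate_column_raises(self, rng):
        with pytest.raises(ValueError, match="missing covariate"):
            residualize_phenotypes(pd.DataFrame({"LDLc": rng.normal(size=10)}))


class TestBurdenEncoding:
    calls = pd.DataFrame({
        "sample_id": ["s1", "s1", "s2", "s3"],
        "gene": ["G1", "G1", "G1", "G2"],
        "variant_id": ["v1", "v2", "v1", "v9"],
    })

    def test_indicator_vs_count_mode(self):
        samples = ["s1", "s2", "s3", "s4"]
        ind = encode_ptv_burden(self.calls, samples, mode="indicator")
        cnt = encode_ptv_burden(self.calls, samples, mode="count")
        assert ind.burden.loc["s1", "G1"] == 1
        assert cnt.burden.loc["s1", "G1"] == 2
        assert ind.burden.loc["s4", "G1"] == 0

    def test_excluding_only_variant_zeroes_burden(self):
        out = encode_ptv_burden(self.calls, ["s1", "s2", "s3"], exclude_variants={"v9"})
        assert out.burden.loc["s3", "G2"] == 0

    def test_exclusion_never_increases_burden(self):
        samples = ["s1", "s2", "s3"]
        full = encode_ptv_burden(self.calls, samples, mode="count").burden
        excl = encode_ptv_burden(
            self.calls, samples, mode="count", exclude_variants={"v1"}
        ).burden
        assert (excl <= full).all().all()

    def test_carrier_count_in_binomial_band(self, rng):
        n, freq = 10_000, 0.01
        carriers = rng.random(n) < freq
        calls = pd.DataFrame({
            "sample_id": [f"s{i}" for i in np.flatnonzero(carriers)],
            "gene": "G1",
            "variant_id": "v1",
        })
        out = encode_ptv_burden(calls, [f"s{i}" for i in range(n)], genes=["G1"])
        lo, hi = stats.binom.ppf([0.005, 0.995], n, freq)
        assert lo <= out.carriers()["G1"] <= hi


class TestPrs:
    dosages = pd.DataFrame(
        {"snp1": [2], "snp2": [1], "snp3": [0]}, index=["s1"], dtype=float
    )
    weights = pd.DataFrame({
        "snp": ["snp1", "snp2", "snp3"],
        "chrom": [1, 2, 3],
        "pos": [100, 200, 300],
        "weight": [0.5, -0.2, 0.1],
    })

    def test_weighted_sum(self):
        assert compute_prs(self.dosages, self.weights)["s1"] == pytest.approx(0.8)

    def test_zero_weights_zero_score(self):
        w = self.weights.assign(weight=0.0)
        assert compute_prs(self.dosages, w)["s1"] == 0.0

    def test_gene_region_exclusion(self):
        score = compute_prs(self.dosages, self.weights, exclude_gene_region=(1, 50, 150))
        assert score["s1"] == pytest.approx(-0.2)

    def test_empty_after_exclusion_errors(self):
        w = self.weights[self.weights.snp == "snp1"]
        with pytest.raises(ValueError, match="no score SNPs"):
            compute_prs(self.dosages, w, exclude_gene_region=(1, 0, 10_000))


class TestPairEnumeration:
    def test_unordered_gene_and_snp_pairs(self):
        genes = [f"G{i}" for i in range(30)]
        snps = [f"rs{i}" for i in range(28)]
        assert len(enumerate_pairs("PTV-PTV", genes=genes)) == 435
        assert len(enumerate_pairs("SNP-SNP", snps=snps)) == 378

    def test_ptv_snp_excludes_own_gene_snp(self):
        genes = [f"G{i}" for i in range(30)]
        snps = [f"rs{i}" for i in range(28)]
        # every gene mapped to one SNP; two SNPs each serve two genes
        mapping = {g: snps[min(i, 27)] for i, g in enumerate(genes)}
        pairs = enumerate_pairs("PTV-SNP", genes=genes, snps=snps, gene_snp_map=mapping)
        assert len(pairs) == 28 * 30 - 30
        assert all(mapping[g] != s for s, g in pairs)

    def test_ptv_prs_pairs_gene_by_trait(self):
        genes = [f"G{i}" for i in range(30)]
        assert len(enumerate_pairs("PTV-PRS", genes=genes)) == 120

    def test_canonical_pair_is_order_independent(self):
        assert canonical_pair("LPL", "APOB") == canonical_pair("APOB", "LPL") == "APOB__LPL"


class TestScan:
    def test_recovers_planted_additive_pair(self, small_cohort):
        res = residualize_phenotypes(small_cohort.cohort)
        burden = encode_ptv_burden(
            small_cohort.ptv_calls, small_cohort.cohort.index,
            genes=list(small_cohort.config.genes),
        )
        table = run_pairwise_scan("PTV-PTV", residuals=res, burden=burden)
        assert set(table.columns) >= {"pair", "trait", "classification", "p_ab_fdr"}
        row = table[(table.pair == "APOB__PCSK9") & (table.trait == "LDLc")].iloc[0]
        assert row.classification == "AE"
        assert row.best_model == 3

    def test_one_row_per_unit_and_single_label(self, small_cohort):
        res = residualize_phenotypes(small_cohort.cohort)
        burden = encode_ptv_burden(
            small_cohort.ptv_calls, small_cohort.cohort.index,
            genes=list(small_cohort.config.genes),
        )
        table = run_pairwise_scan("PTV-PTV", residuals=res, burden=burden)
        assert len(table) == 6 * 4  # C(4,2) pairs x 4 traits
        assert table.classification.isin(["GI", "AE", "none"]).all()
        assert not table.duplicated(["pair", "trait"]).any()

    def test_fdr_pooled_within_design(self, small_cohort):
        res = residualize_phenotypes(small_cohort.cohort)
        burden = encode_ptv_burden(
            small_cohort.ptv_calls, small_cohort.cohort.index,
            genes=list(small_cohort.config.genes),
        )
        table = run_pairwise_scan("PTV-PTV", residuals=res, burden=burden)
        # adjusted values must dominate raw ones
        assert (table.p_a_fdr >= table.p_a - 1e-12).all()
        ok = table.p_ab_fdr.notna()
        assert (table.loc[ok, "p_ab_fdr"] >= table.loc[ok, "p_ab"] - 1e-12).all()

    def test_empty_pair_list_errors(self, small_cohort):
        res = residualize_phenotypes(small_cohort.cohort)
        burden = encode_ptv_burden(
            small_cohort.ptv_calls, small_cohort.cohort.index, genes=["APOB"]
        )
        with pytest.raises(ValueError, match="empty pair list"):
            run_pairwise_scan("PTV-PTV", residuals=res, burden=burden)

    def test_determinism_identical_tables(self, small_cohort):
        res = residualize_phenotypes(small_cohort.cohort)
        burden = encode_ptv_burden(
            small_cohort.ptv_calls, small_cohort.cohort.index,
            genes=list(small_cohort.config.genes),
        )
        t1 = run_pairwise_scan("PTV-PTV", residuals=res, burden=burden)
        t2 = run_pairwise_scan("PTV-PTV", residuals=res, burden=burden)
        pd.testing.assert_frame_equal(t1, t2)


class TestConditioning:
    def _build(self, rng):
        # gene G1 carriers split between v1 (trait-lowering) and v2 (inert)
        n = 3000
        samples = [f"s{i}" for i in range(n)]
        v1 = rng.choice(n, 60, replace=False)
        rest = np.setdiff1d(np.arange(n), v1)
        v2 = rng.choice(rest, 40, replace=False)
        g2 = rng.choice(n, 80, replace=False)
        calls = pd.DataFrame(
            [(samples[i], "G1", "v1") for i in v1]
            + [(samples[i], "G1", "v2") for i in v2]
            + [(samples[i], "G2", "w1") for i in g2],
            columns=["sample_id", "gene", "variant_id"],
        )
        y = rng.normal(0, 1, n)
        y[v1] -= 2.0  # the signal lives entirely in v1
        residuals = pd.DataFrame({"LDLc": y}, index=samples)
        return calls, samples, residuals

    def test_signal_carried_by_single_variant_abrogated(self, rng):
        calls, samples, residuals = self._build(rng)
        out = condition_on_variant(
            calls, samples, "v1", residuals=residuals, traits=["LDLc"]
        )
        row = out[out.pair == "G1__G2"].iloc[0]
        assert row.p_a_before < 1e-6
        assert row.p_a_after > 0.01

    def test_carrier_count_drops_by_sole_carriers(self, rng):
        calls, samples, _ = self._build(rng)
        before = encode_ptv_burden(calls, samples)
        after = encode_ptv_burden(calls, samples, exclude_variants={"v1"})
        only_v1 = (
            set(calls.loc[calls.variant_id == "v1", "sample_id"])
            - set(calls.loc[(calls.gene == "G1") & (calls.variant_id != "v1"),
                            "sample_id"])
        )
        assert before.carriers()["G1"] - after.carriers()["G1"] == len(only_v1)

    def test_absent_variant_errors(self, rng):
        calls, samples, residuals = self._build(rng)
        with pytest.raises(ValueError, match="not present"):
            condition_on_variant(
                calls, samples, "nope", residuals=residuals, traits=["LDLc"]
            )
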