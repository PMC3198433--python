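"""Signature scoring, permutation null, double positives, enrichment."""

import numpy as np
import pandas as pd
import pytest

from mycoresig import CompendiumConfig, beta_for_target_r, synthdata
from mycoresig.compendium import (
    celltype_enrichment,
    classify_double_positive,
    driver_signature_correlation,
    random_geneset_pvalue,
    signature_score,
    tumor_fraction,
)
from mycoresig.containers import CompendiumStudy, ExpressionMatrix
from conftest import small_config
import oracles


def _study(values, genes=None, driver="driver", celltypes=None, tumor=None):
    values = np.asarray(values, dtype=float)
    genes = genes or ["driver"] + [f"g{i}" for i in range(values.shape[0] - 1)]
    samples = [f"s{i}" for i in range(values.shape[1])]
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    ct = pd.Series(celltypes if celltypes is not None else "ct1", index=samples)
    tm = pd.Series(tumor if tumor is not None else False, index=samples)
    return CompendiumStudy(expr, ct, tm, driver).validate()


def _null_study(seed, n_genes=100, n_samples=100):
    cfg = small_config(
        seed=seed, n_genes=n_genes,
        compendium=CompendiumConfig(
            n_samples=n_samples, n_celltypes=10, signature_size=10,
            driver_beta=0.0, n_enriched_celltypes=0,
        ),
    )
    truth = synthdata.plant_truth(cfg)
    truth.enriched_celltypes = set()
    return synthdata.simulate_expression(cfg, truth, "compendium"), truth


class TestSignatureScore:
    def test_single_gene_signature_is_its_standardized_profile(self):
        rng = np.random.default_rng(0)
        values = rng.normal(8, 1, size=(5, 12))
        study = _study(values)
        score = signature_score(study, ["g1"])
        row = values[2]
        np.testing.assert_allclose(score, (row - row.mean()) / row.std())

    def test_constant_matrix_scores_zero(self):
        study = _study(np.full((4, 6), 3.0))
        np.testing.assert_allclose(signature_score(study, ["g0", "g1"]), 0.0)

    def test_matches_standardize_then_average_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.normal(8, 1, size=(10, 20))
        study = _study(values)
        sig = ["g0", "g4", "g7"]
        got = signature_score(study, sig)
        np.testing.assert_allclose(got, oracles.signature_score_oracle(values[[1, 5, 8]]))

    def test_no_present_gene_is_an_error(self):
        study = _study(np.zeros((3, 5)))
        with pytest.raises(ValueError, match="no signature gene"):
            signature_score(study, ["absent"])

    def test_invariant_to_gene_order_and_affine_rescaling(self):
        rng = np.random.default_rng(2)
        values = rng.normal(8, 1, size=(8, 15))
        sig = ["g0", "g2", "g5"]
        base = signature_score(_study(values), sig)
        shuffled = signature_score(_study(values), sig[::-1])
        rescaled_vals = values * rng.uniform(0.5, 2.0, size=(8, 1)) + rng.normal(
            0, 3, size=(8, 1)
        )
        rescaled = signature_score(_study(rescaled_vals), sig)
        np.testing.assert_allclose(base, shuffled)
        np.testing.assert_allclose(base, rescaled, atol=1e-10)


class TestDriverCorrelation:
    def test_perfect_and_anti_correlation(self):
        n = 10
        driver = np.arange(n, dtype=float)
        values = np.vstack([driver, driver * 2 + 1, -driver])
        study = _study(values, genes=["driver", "gpos", "gneg"])
        s_pos = signature_score(study, ["gpos"])
        s_neg = signature_score(study, ["gneg"])
        assert driver_signature_correlation(study, s_pos) == pytest.approx(1.0)
        assert driver_signature_correlation(study, s_neg) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        study = _study(np.vstack([np.ones(5), np.arange(5.0)]), genes=["driver", "g0"])
        with pytest.raises(ValueError, match="zero-variance"):
            driver_signature_correlation(study, signature_score(study, ["g0"]))

    def test_planted_population_correlation_recovered(self):
        """beta solved for r = 0.5 yields estimates within ±0.05 at n = 2000."""
        k = 20
        beta = beta_for_target_r(0.5, k)
        estimates = []
        for seed in range(10):
            cfg = small_config(
                seed=300 + seed, n_genes=200,
                compendium=CompendiumConfig(
                    n_samples=2000, n_celltypes=10, signature_size=k,
                    driver_beta=beta, n_enriched_celltypes=0,
                ),
            )
            truth = synthdata.plant_truth(cfg)
            truth.enriched_celltypes = set()
            study = synthdata.simulate_expression(cfg, truth, "compendium")
            scores = signature_score(study, sorted(truth.signature_genes))
            estimates.append(driver_signature_correlation(study, scores))
        assert abs(np.mean(estimates) - 0.5) < 0.05

    def test_recovered_r_monotone_in_planted_beta(self):
        means = []
        for beta in (0.0, 0.05, 0.1, 0.3):
            rs = []
            for seed in range(3):
                cfg = small_config(
                    seed=400 + seed, n_genes=100,
                    compendium=CompendiumConfig(
                        n_samples=500, n_celltypes=5, signature_size=10,
                        driver_beta=beta, n_enriched_celltypes=0,
                    ),
                )
                truth = synthdata.plant_truth(cfg)
                truth.enriched_celltypes = set()
                study = synthdata.simulate_expression(cfg, truth, "compendium")
                scores = signature_score(study, sorted(truth.signature_genes))
                rs.append(driver_signature_correlation(study, scores))
            means.append(np.mean(rs))
        assert means == sorted(means)


class TestPermutationPvalue:
    def test_lower_bound_when_observed_beats_every_null(self):
        study, truth = _null_study(seed=50)
        p = random_geneset_pvalue(study, 5, observed_r=1.1, b=49, seed=0)
        assert p == pytest.approx(1 / 50)

    def test_deterministic_given_seed(self):
        study, truth = _null_study(seed=51)
        args = dict(signature_size=5, observed_r=0.1, b=99)
        assert random_geneset_pvalue(study, **args, seed=7) == random_geneset_pvalue(
            study, **args, seed=7
        )

    def test_k_too_large_rejected(self):
        study, truth = _null_study(seed=52, n_genes=20)
        with pytest.raises(ValueError, match="exceeds"):
            random_geneset_pvalue(study, 20, 0.0, b=9, seed=0)

    def test_doubling_b_barely_moves_p_on_fixed_data(self):
        study, truth = _null_study(seed=53)
        sig = sorted(truth.signature_genes)
        scores = signature_score(study, sig)
        r = driver_signature_correlation(study, scores)
        b = 200
        p_small = np.mean([
            random_geneset_pvalue(study, 10, r, b=b, seed=s) for s in range(10)
        ])
        p_big = np.mean([
            random_geneset_pvalue(study, 10, r, b=2 * b, seed=s) for s in range(10)
        ])
        assert abs(p_small - p_big) < 3 / (b + 1)


class TestDoublePositive:
    def test_top_quartile_of_eight_increasing_samples(self):
        driver = np.arange(8, dtype=float)
        study = _study(np.vstack([driver, driver]), genes=["driver", "g0"])
        flags = classify_double_positive(study, signature_score(study, ["g0"]), 0.75)
        assert flags.tolist() == [False] * 6 + [True] * 2

    def test_perfect_anticorrelation_flags_nobody(self):
        driver = np.arange(8, dtype=float)
        study = _study(np.vstack([driver, -driver]), genes=["driver", "g0"])
        flags = classify_double_positive(study, signature_score(study, ["g0"]), 0.75)
        assert not flags.any()

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(3)
        driver = rng.normal(0, 1, 40)
        sig_row = rng.normal(0, 1, 40)
        base_study = _study(np.vstack([driver, sig_row]), genes=["driver", "g0"])
        base = classify_double_positive(
            base_study, pd.Series(sig_row, index=base_study.expression.sample_ids), 0.75
        )
        warped = _study(np.vstack([np.exp(driver), sig_row]), genes=["driver", "g0"])
        flags = classify_double_positive(
            warped, pd.Series(np.tanh(sig_row), index=warped.expression.sample_ids), 0.75
        )
        assert flags.tolist() == base.tolist()


class TestCelltypeEnrichment:
    def test_closed_form_hypergeometric_extreme(self):
        """One type holding exactly the 10 flagged of 100 samples has
        p = 1 / C(100, 10)."""
        samples = [f"s{i}" for i in range(100)]
        flags = pd.Series([True] * 10 + [False] * 90, index=samples)
        ct = pd.Series(["hot"] * 10 + ["cold"] * 90, index=samples)
        table = celltype_enrichment(flags, ct).set_index("celltype")
        from math import comb

        assert table.loc["hot", "p"] == pytest.approx(1 / comb(100, 10))
        assert bool(table.loc["hot", "enriched"])

    def test_zero_flagged_gives_all_p_one(self):
        samples = [f"s{i}" for i in range(20)]
        flags = pd.Series(False, index=samples)
        ct = pd.Series(["a"] * 10 + ["b"] * 10, index=samples)
        table = celltype_enrichment(flags, ct)
        assert (table["p"] == 1.0).all()

    def test_agrees_with_resampling_null(self):
        """The hypergeometric closed form matches literal random draws of the
        flagged sample set within Monte-Carlo error."""
        rng = np.random.default_rng(4)
        n, k, n_type = 200, 30, 25
        samples = [f"s{i}" for i in range(n)]
        flag_idx = rng.choice(n, size=k, replace=False)
        flags = pd.Series(np.isin(np.arange(n), flag_idx), index=samples)
        ct = pd.Series(["t1"] * n_type + ["rest"] * (n - n_type), index=samples)
        k_obs = int(flags.iloc[:n_type].sum())
        p_closed = celltype_enrichment(flags, ct).set_index("celltype").loc["t1", "p"]
        draws = 5000
        hits = 0
        for _ in range(draws):
            drawn = rng.choice(n, size=k, replace=False)
            hits += (drawn < n_type).sum() >= k_obs
        p_mc = hits / draws
        assert abs(p_closed - p_mc) < 3 * np.sqrt(p_closed * (1 - p_closed) / draws) + 1e-3

    def test_null_compendium_rarely_flags_types(self):
        rates = []
        for seed in range(10):
            study, _ = _null_study(seed=600 + seed, n_samples=400)
            scores = signature_score(study, study.expression.gene_ids[1:11])
            flags = classify_double_positive(study, scores, 0.75)
            table = celltype_enrichment(flags, study.celltype, 0.05)
            rates.append(table["enriched"].mean())
        assert np.mean(rates) <= 0.05


class TestTumorFraction:
    @pytest.mark.parametrize(
        "counts,expected",
        [((236, 246), "95.9"), ((4690, 8129), "57.7"), ((0, 10), "0.0")],
    )
    def test_formatted_percents(self, counts, expected):
        k, n = counts
        samples = [f"s{i}" for i in range(n)]
        flags = pd.Series(True, index=samples)
        tumor = pd.Series([True] * k + [False] * (n - k), index=samples)
        dp, overall = tumor_fraction(flags, tumor)
        assert dp == (k, n, expected)

    def test_zero_flagged_reported_as_undefined(self):
        samples = ["s0", "s1"]
        flags = pd.Series(False, index=samples)
        tumor = pd.Series([True, False], index=samples)
        dp, overall = tumor_fraction(flags, tumor)
        assert dp == (0, 0, None)
        assert overall == (1, 2, "50.0")
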