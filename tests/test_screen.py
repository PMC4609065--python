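"""Two-stage screening and min-T permutation adjustment."""

import numpy as np
import pytest

from pgxscreen.screen import PermutationConfig, permutation_adjusted_p, screen, stage_pvalues
from pgxscreen.stats import fisher_exact_2x2, model_table_from_doses
from conftest import make_genotypes, make_samples


def toy_cohort(rng, n=24, m=4, causal_col=0):
    """Cohort whose first SNP separates response strongly."""
    calls = rng.integers(0, 3, size=(n, m)).astype(float)
    response = np.tile([1.0, 0.0], n // 2)  # alternate so both stages see both groups
    calls[:, causal_col] = np.where(response == 1, 2.0, 0.0)
    recist = ["PR" if r else "NC" for r in response]
    regimen = ["S-1"] * (n // 2) + ["5-FU/MTX"] * (n - n // 2)
    genotypes = make_genotypes(calls)
    samples = make_samples(recist, regimen=regimen)
    return genotypes, samples


class TestStagePvalues:
    def test_matches_per_snp_fisher(self, rng):
        genotypes, samples = toy_cohort(rng)
        ids = samples.sample_ids
        responses = samples.response_series()
        p = stage_pvalues(genotypes, responses, genotypes.snp_ids, ids, "allele")
        for snp in genotypes.snp_ids:
            table = model_table_from_doses(
                genotypes.dose(snp).loc[ids], responses.loc[ids], "allele"
            ).cells
            assert p[snp] == pytest.approx(fisher_exact_2x2(table), rel=1e-12)

    def test_constant_response_gives_p_one(self, rng):
        genotypes, _ = toy_cohort(rng)
        responses = genotypes.dose("rs1") * 0 + 1
        p = stage_pvalues(
            genotypes, responses, genotypes.snp_ids, genotypes.sample_ids, "allele"
        )
        assert (p == 1.0).all()

    def test_missing_only_snp_gets_nan(self, rng):
        genotypes, samples = toy_cohort(rng)
        genotypes.calls[:, 2] = np.nan
        p = stage_pvalues(
            genotypes,
            samples.response_series(),
            genotypes.snp_ids,
            samples.sample_ids,
            "allele",
        )
        assert np.isnan(p["rs3"])


class TestPermutationAdjustment:
    def test_strong_snp_hits_the_add_one_floor(self, rng):
        genotypes, samples = toy_cohort(rng)
        first, second = samples.sample_ids[: 12], samples.sample_ids
        result = permutation_adjusted_p(
            genotypes, samples.response_series(), genotypes.snp_ids,
            first, second, PermutationConfig(n_perm=199, seed=4),
        )
        assert result.loc["rs1", "perm_p"] == pytest.approx(1 / 200)
        assert (result["perm_p"] >= 1 / 200 - 1e-12).all()

    def test_combined_statistic_dominates_stage_p(self, rng):
        genotypes, samples = toy_cohort(rng)
        first, second = samples.sample_ids[: 12], samples.sample_ids
        result = permutation_adjusted_p(
            genotypes, samples.response_series(), genotypes.snp_ids,
            first, second, PermutationConfig(n_perm=99, seed=4),
        )
        assert (result["combined_T"] >= result["p_stage1"] - 1e-12).all()
        assert (result["combined_T"] >= result["p_stage2"] - 1e-12).all()

    def test_adjusted_p_monotone_in_combined_statistic(self, rng):
        genotypes, samples = toy_cohort(rng, n=40, m=6)
        first, second = samples.sample_ids[: 20], samples.sample_ids
        result = permutation_adjusted_p(
            genotypes, samples.response_series(), genotypes.snp_ids,
            first, second, PermutationConfig(n_perm=99, seed=9),
        ).sort_values("combined_T")
        assert (result["perm_p"].diff().dropna() >= -1e-12).all()

    def test_same_seed_bit_identical(self, rng):
        genotypes, samples = toy_cohort(rng)
        args = (
            genotypes, samples.response_series(), genotypes.snp_ids,
            samples.sample_ids[: 12], samples.sample_ids,
        )
        r1 = permutation_adjusted_p(*args, PermutationConfig(n_perm=99, seed=21))
        r2 = permutation_adjusted_p(*args, PermutationConfig(n_perm=99, seed=21))
        assert r1.equals(r2)

    def test_vectorized_path_matches_slow_oracle(self, rng):
        # recompute the whole min-T adjustment per permutation with plain
        # per-table Fisher tests and compare with the vectorized machinery
        from pgxscreen.screen import _perm_matrix

        genotypes, samples = toy_cohort(rng, n=20, m=3)
        first = samples.sample_ids[:10]
        second = samples.sample_ids
        config = PermutationConfig(n_perm=60, seed=2)
        result = permutation_adjusted_p(
            genotypes, samples.response_series(), genotypes.snp_ids,
            first, second, config,
        )
        y = samples.response_series().loc[second].to_numpy(dtype=int)
        perms = _perm_matrix(y, config.n_perm, config.seed)
        first_pos = [second.index(s) for s in first]
        P = np.empty((config.n_perm + 1, 2, genotypes.n_snps))
        for i in range(config.n_perm + 1):
            yi = perms[i].astype(int)
            for j, snp in enumerate(genotypes.snp_ids):
                dose = genotypes.calls[:, j]
                P[i, 0, j] = fisher_exact_2x2(
                    model_table_from_doses(dose[first_pos], yi[first_pos], "allele").cells
                )
                P[i, 1, j] = fisher_exact_2x2(
                    model_table_from_doses(dose, yi, "allele").cells
                )
        T = P.max(axis=1)
        exceed = (T[1:].min(axis=1)[:, None] <= T[0][None, :]).sum(axis=0)
        expected_adj = (1.0 + exceed) / (config.n_perm + 1.0)
        np.testing.assert_allclose(result["p_stage1"], P[0, 0], rtol=1e-9)
        np.testing.assert_allclose(result["p_stage2"], P[0, 1], rtol=1e-9)
        np.testing.assert_allclose(result["perm_p"], expected_adj, rtol=1e-12)

    def test_nesting_violation_rejected(self, rng):
        genotypes, samples = toy_cohort(rng)
        with pytest.raises(ValueError, match="nested"):
            permutation_adjusted_p(
                genotypes, samples.response_series(), genotypes.snp_ids,
                ["S1", "missing"], samples.sample_ids[:4],
                PermutationConfig(n_perm=10, seed=0),
            )

    def test_nperm_validated(self):
        with pytest.raises(ValueError):
            PermutationConfig(n_perm=0)


class TestScreen:
    def test_injected_causal_snp_is_candidate(self, rng):
        genotypes, samples = toy_cohort(rng, n=40, m=5)
        first = [s for s, r in zip(samples.sample_ids, samples.frame["regimen"]) if r == "S-1"]
        result = screen(
            genotypes, samples, genotypes.snp_ids, first, samples.sample_ids,
            PermutationConfig(n_perm=199, seed=13),
        )
        assert bool(result.loc["rs1", "candidate"])

    def test_zero_alpha_blocks_all_candidates(self, rng):
        genotypes, samples = toy_cohort(rng)
        first = samples.sample_ids[:12]
        result = screen(
            genotypes, samples, genotypes.snp_ids, first, samples.sample_ids,
            PermutationConfig(n_perm=49, seed=1), alpha1=0.0,
        )
        assert not result["candidate"].any()

    def test_empty_snp_set_warns(self, rng):
        genotypes, samples = toy_cohort(rng)
        with pytest.warns(UserWarning):
            result = screen(
                genotypes, samples, [], samples.sample_ids[:12], samples.sample_ids,
                PermutationConfig(n_perm=9, seed=0),
            )
        assert result.empty
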