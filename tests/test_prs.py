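"""Clumping, scoring, and best-threshold selection."""

import numpy as np
import pandas as pd
import pytest

from stratlab import (
    ClumpSpec,
    PopulationModel,
    SummaryStats,
    clump,
    score,
    select_best_threshold,
    simulate_genotypes,
)

from conftest import make_genotypes


def stats_from(geno, p, beta=None):
    v = geno.variants
    return SummaryStats(
        table=pd.DataFrame(
            {
                "variant_id": v["variant_id"],
                "chrom": v["chrom"],
                "pos": v["pos"],
                "effect_allele": v["allele1"],
                "other_allele": v["allele2"],
                "beta": beta if beta is not None else np.ones(len(v)),
                "se": np.ones(len(v)),
                "t": np.ones(len(v)),
                "p": p,
                "n_used": len(geno.sample_ids),
            }
        ),
        pc_set_label="none",
    )


def brute_force_clump(stats, geno, spec):
    """Independent greedy oracle over the full pairwise r² matrix."""
    t = stats.table.dropna(subset=["p"])
    t = t[t["p"] <= spec.p_max].sort_values(["p", "chrom", "pos"])
    d = geno.dosages
    means = np.nanmean(d, axis=0)
    z = np.nan_to_num(d - means, nan=0.0)
    r = np.corrcoef(z.T)
    idx_of = {v: i for i, v in enumerate(geno.variants["variant_id"])}
    remaining = list(t["variant_id"])
    pos = dict(zip(geno.variants["variant_id"], geno.variants["pos"]))
    chrom = dict(zip(geno.variants["variant_id"], geno.variants["chrom"]))
    out = []
    while remaining:
        head = remaining.pop(0)
        out.append(head)
        keep = []
        for v in remaining:
            same = chrom[v] == chrom[head]
            near = abs(pos[v] - pos[head]) <= spec.window_kb * 1000
            if same and near and r[idx_of[v], idx_of[head]] ** 2 > spec.r2_max:
                continue
            keep.append(v)
        remaining = keep
    return out


class TestClump:
    def test_uncorrelated_variants_all_index(self):
        rng = np.random.default_rng(1)
        geno = make_genotypes(rng.integers(0, 3, size=(500, 20)).astype(float))
        st = stats_from(geno, rng.uniform(size=20))
        out = clump(st, geno, ClumpSpec())
        assert sorted(out) == sorted(geno.variants["variant_id"])

    def test_correlated_pair_keeps_more_significant(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, size=400).astype(float)
        geno = make_genotypes(
            np.column_stack([a, a]), pos=[1000, 11000]  # 10 kb apart
        )
        st = stats_from(geno, [1e-4, 1e-8])
        out = clump(st, geno, ClumpSpec())
        assert out == ["v1"]  # the 1e-8 variant

    def test_matches_brute_force_oracle(self):
        model = PopulationModel.from_divergences(
            [0.0], n_variants=100, pop_labels=["x"],
            ld_block_size=5, ld_rho=0.8,
            chrom_lengths={"1": 2_000_000, "2": 2_000_000},
        )
        geno = simulate_genotypes(model, [400], seed=90)
        rng = np.random.default_rng(91)
        st = stats_from(geno, rng.uniform(size=100))
        spec = ClumpSpec(r2_max=0.05, window_kb=200)
        assert clump(st, geno, spec) == brute_force_clump(st, geno, spec)

    def test_input_order_invariance(self):
        model = PopulationModel.from_divergences(
            [0.0], n_variants=60, pop_labels=["x"],
            ld_block_size=4, ld_rho=0.9,
        )
        geno = simulate_genotypes(model, [300], seed=92)
        rng = np.random.default_rng(93)
        p = rng.uniform(size=60)
        st = stats_from(geno, p)
        shuffled = SummaryStats(
            table=st.table.sample(frac=1, random_state=7).reset_index(drop=True),
            pc_set_label="none",
        )
        assert clump(st, geno, ClumpSpec()) == clump(shuffled, geno, ClumpSpec())


class TestScore:
    def test_single_variant_dosage_weighting(self):
        geno = make_genotypes([[0.0], [1.0], [2.0]])
        st = stats_from(geno, [0.001], beta=[0.5])
        s = score(geno, st, ["v0"], threshold=0.01)
        np.testing.assert_allclose(s, [0.0, 0.5, 1.0])

    def test_zero_betas_zero_scores(self, toy_genotypes):
        st = stats_from(toy_genotypes, np.full(12, 0.001), beta=np.zeros(12))
        s = score(toy_genotypes, st, list(toy_genotypes.variants["variant_id"]),
                  threshold=0.01)
        np.testing.assert_array_equal(s, 0.0)

    def test_matches_matrix_product_oracle(self):
        rng = np.random.default_rng(94)
        d = rng.integers(0, 3, size=(50, 20)).astype(float)
        geno = make_genotypes(d)
        betas = rng.standard_normal(20)
        st = stats_from(geno, np.full(20, 1e-4), beta=betas)
        s = score(geno, st, list(geno.variants["variant_id"]), threshold=0.01)
        np.testing.assert_allclose(s, d @ betas, atol=1e-12)

    def test_allele_swap_flips_and_mismatch_raises(self):
        rng = np.random.default_rng(95)
        d = rng.integers(0, 3, size=(30, 2)).astype(float)
        geno = make_genotypes(d, a1=["A", "A"], a2=["G", "G"])
        st = stats_from(geno, [1e-4, 1e-4], beta=[1.0, 1.0])
        st.table.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        s = score(geno, st, ["v0"], threshold=0.01)
        np.testing.assert_allclose(s, 2.0 - d[:, 0])
        st.table.loc[1, ["effect_allele", "other_allele"]] = ["T", "C"]
        with pytest.raises(ValueError, match="allele mismatch"):
            score(geno, st, ["v1"], threshold=0.01)

    def test_missing_dosage_mean_substituted(self):
        d = np.array([[0.0], [2.0], [np.nan], [2.0]])
        geno = make_genotypes(d)
        st = stats_from(geno, [1e-4], beta=[1.0])
        s = score(geno, st, ["v0"], threshold=0.01)
        np.testing.assert_allclose(s, [0.0, 2.0, 4.0 / 3, 2.0])

    def test_doubling_betas_leaves_standardized_prs_unchanged(self, toy_genotypes):
        rng = np.random.default_rng(96)
        betas = rng.standard_normal(12)
        st1 = stats_from(toy_genotypes, np.full(12, 1e-4), beta=betas)
        st2 = stats_from(toy_genotypes, np.full(12, 1e-4), beta=2 * betas)
        vl = list(toy_genotypes.variants["variant_id"])
        from stratlab.prs import standardize
        s1 = standardize(score(toy_genotypes, st1, vl, 0.01))
        s2 = standardize(score(toy_genotypes, st2, vl, 0.01))
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestSelectBestThreshold:
    def _samples(self, n):
        return pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)]})

    def test_trait_built_from_significant_variants(self):
        rng = np.random.default_rng(97)
        n, m = 600, 40
        d = rng.integers(0, 3, size=(n, m)).astype(float)
        geno = make_genotypes(d)
        # trait driven by the first 5 variants, which get p=1e-8 in the stats
        trait = d[:, :5].sum(axis=1) + 0.1 * rng.standard_normal(n)
        p = np.full(m, 0.3)
        p[:5] = 1e-8
        st = stats_from(geno, p, beta=np.r_[np.ones(5), np.zeros(35)])
        clumped = clump(st, geno, ClumpSpec())
        prof = select_best_threshold(
            geno, trait, self._samples(n), st, clumped
        )
        assert prof.chosen_threshold == 0.00005  # smallest grid value admitting them
        assert prof.n_snps_included == 5
        assert abs(prof.score.mean()) < 1e-10
        assert abs(prof.score.std() - 1) < 1e-10

    def test_null_trait_overfitting_ceiling(self):
        rng = np.random.default_rng(98)
        n, m = 2000, 200
        d = rng.integers(0, 3, size=(n, m)).astype(float)
        geno = make_genotypes(d)
        trait = rng.standard_normal(n)
        st = stats_from(geno, rng.uniform(size=m),
                        beta=rng.standard_normal(m) * 0.01)
        clumped = clump(st, geno, ClumpSpec())
        prof = select_best_threshold(geno, trait, self._samples(n), st, clumped)
        x = np.column_stack([np.ones(n), prof.score])
        beta, *_ = np.linalg.lstsq(x, trait, rcond=None)
        resid = trait - x @ beta
        r2 = 1 - resid @ resid / ((trait - trait.mean()) ** 2).sum()
        assert r2 < 0.005

    def test_degenerate_single_threshold_grid(self, toy_genotypes):
        rng = np.random.default_rng(99)
        st = stats_from(toy_genotypes, np.full(12, 0.001))
        clumped = clump(st, toy_genotypes, ClumpSpec())
        trait = rng.standard_normal(toy_genotypes.n_samples)
        prof = select_best_threshold(
            toy_genotypes, trait, self._samples(toy_genotypes.n_samples),
            st, clumped, grid=(0.01,),
        )
        assert prof.chosen_threshold == 0.01
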