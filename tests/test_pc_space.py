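"""PC-space construction, projection, and the four-space bookkeeping."""

import numpy as np
import pytest

from stratlab import (
    PopulationModel,
    build_pc_space,
    make_pc_sets,
    project_samples,
    simulate_genotypes,
)

from conftest import make_genotypes


@pytest.fixture(scope="module")
def panel_and_cohort(two_pop_model):
    geno = simulate_genotypes(two_pop_model, [250, 250], seed=51)
    panel = geno.take_samples(
        np.concatenate([geno.sample_ids[:125], geno.sample_ids[250:375]])
    )
    cohort = geno.take_samples(
        np.concatenate([geno.sample_ids[125:250], geno.sample_ids[375:]])
    )
    return geno, panel, cohort


class TestBuildPCSpace:
    def test_loadings_orthonormal_and_eigenvalues_sorted(self, panel_and_cohort):
        _, panel, _ = panel_and_cohort
        space = build_pc_space(panel, k=10)
        gram = space.loadings.T @ space.loadings
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-8)
        assert (np.diff(space.eigenvalues) <= 1e-10).all()
        assert (space.snp_sds > 0).all()

    def test_panel_scores_centered(self, panel_and_cohort):
        _, panel, _ = panel_and_cohort
        space = build_pc_space(panel, k=5)
        scores = project_samples(space, panel.take_samples(space.panel_ids))
        np.testing.assert_allclose(scores.scores.mean(axis=0), 0, atol=1e-8)

    def test_trace_preservation_full_rank(self):
        rng = np.random.default_rng(2)
        geno = make_genotypes(rng.integers(0, 3, size=(25, 120)).astype(float))
        space = build_pc_space(geno, k=24, prune=False)
        z = geno.standardized()
        # total standardized variance = m (unit variance per polymorphic SNP)
        m_poly = int((z.std(axis=0) > 0).sum())
        assert space.eigenvalues.sum() == pytest.approx(m_poly, rel=1e-10)

    def test_pc1_separates_populations(self):
        model = PopulationModel.from_divergences(
            [0.05, 0.05], n_variants=2000, pop_labels=["a", "b"]
        )
        panel = simulate_genotypes(model, [200, 200], seed=55)
        space = build_pc_space(panel, k=5)
        scores = project_samples(space, panel)
        labels = (panel.sample_info["population"] == "b").to_numpy(float)
        r = np.corrcoef(scores.scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_outlier_removal_shrinks_panel(self):
        # craft one sample lying far along the panel's dominant (population)
        # axis: it must be dropped by the >SD-on-top-PCs rule
        model = PopulationModel.from_divergences(
            [0.05, 0.05], n_variants=1500, pop_labels=["a", "b"]
        )
        base = simulate_genotypes(model, [100, 100], seed=64)
        mean_a = base.dosages[:100].mean(axis=0)
        mean_b = base.dosages[100:].mean(axis=0)
        extreme = np.where(mean_b > mean_a, 2.0, 0.0)
        d = np.vstack([base.dosages, extreme])
        geno = make_genotypes(
            d,
            chrom=base.variants["chrom"],
            pos=base.variants["pos"],
            a1=base.variants["allele1"],
            a2=base.variants["allele2"],
        )
        space = build_pc_space(geno, k=10, prune=False, outlier_sd=6.0)
        assert geno.sample_ids[-1] not in set(space.panel_ids)
        assert len(space.panel_ids) >= 150  # bulk of the panel retained

    def test_k_reduced_when_panel_small(self):
        rng = np.random.default_rng(61)
        geno = make_genotypes(rng.integers(0, 3, size=(12, 200)).astype(float))
        space = build_pc_space(geno, k=20, prune=False)
        assert space.k <= 11

    def test_shrinkage_stub_errors(self, panel_and_cohort):
        _, panel, _ = panel_and_cohort
        with pytest.raises(NotImplementedError):
            build_pc_space(panel, shrinkage=True)


class TestProjection:
    def test_self_projection_equals_eigendecomposition_scores(self):
        rng = np.random.default_rng(62)
        geno = make_genotypes(rng.integers(0, 3, size=(80, 400)).astype(float))
        space = build_pc_space(geno, k=10, prune=False)
        z = geno.standardized(space.snp_means, space.snp_sds)
        # direct eigendecomposition scores, sign-aligned via the loadings
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        direct = z @ space.loadings
        projected = project_samples(space, geno)
        np.testing.assert_allclose(projected.scores, direct, atol=1e-8)
        # and each column is a genuine eigen-score: norm^2/n = eigenvalue
        np.testing.assert_allclose(
            (projected.scores**2).sum(axis=0) / geno.n_samples,
            space.eigenvalues, rtol=1e-8,
        )

    def test_duplicated_sample_gets_identical_coordinates(self, panel_and_cohort):
        _, panel, cohort = panel_and_cohort
        space = build_pc_space(panel, k=5)
        # take_samples forbids duplicate ids; emulate by projecting twice
        one = project_samples(space, cohort.take_samples([cohort.sample_ids[0]]))
        again = project_samples(space, cohort.take_samples([cohort.sample_ids[0]]))
        np.testing.assert_array_equal(one.scores, again.scores)

    def test_cohort_separation_same_orientation_as_panel(self, panel_and_cohort):
        geno, panel, cohort = panel_and_cohort
        space = build_pc_space(panel, k=5)
        ppanel = project_samples(space, panel.take_samples(space.panel_ids))
        pcohort = project_samples(space, cohort)
        lab_p = (panel.take_samples(space.panel_ids)
                 .sample_info["population"] == "b").to_numpy(float)
        lab_c = (cohort.sample_info["population"] == "b").to_numpy(float)
        r_panel = np.corrcoef(ppanel.scores[:, 0], lab_p)[0, 1]
        r_cohort = np.corrcoef(pcohort.scores[:, 0], lab_c)[0, 1]
        assert abs(r_panel) > 0.5 and abs(r_cohort) > 0.5
        assert np.sign(r_panel) == np.sign(r_cohort)

    def test_projection_linearity(self, panel_and_cohort):
        _, panel, cohort = panel_and_cohort
        space = build_pc_space(panel, k=5)
        idx = cohort.variant_index(space.variant_ids)
        g1 = cohort.dosages[0, idx]
        g2 = cohort.dosages[1, idx]
        mix = 0.3 * g1 + 0.7 * g2
        z = (np.vstack([g1, g2, mix]) - space.snp_means) / space.snp_sds
        s = np.nan_to_num(z, nan=0.0) @ space.loadings
        np.testing.assert_allclose(s[2], 0.3 * s[0] + 0.7 * s[1], atol=1e-8)

    def test_missing_variant_listed_in_error(self, panel_and_cohort):
        _, panel, cohort = panel_and_cohort
        space = build_pc_space(panel, k=5)
        truncated = cohort.take_variants(range(cohort.n_variants - 10))
        with pytest.raises(KeyError, match="absent"):
            project_samples(space, truncated)

    def test_allele_swap_flips_dosage(self, panel_and_cohort):
        _, panel, cohort = panel_and_cohort
        space = build_pc_space(panel, k=5)
        baseline = project_samples(space, cohort)
        swapped = cohort.take_variants(range(cohort.n_variants))
        j = cohort.variant_index([space.variant_ids[0]])[0]
        a1 = swapped.variants.loc[j, "allele1"]
        swapped.variants.loc[j, "allele1"] = swapped.variants.loc[j, "allele2"]
        swapped.variants.loc[j, "allele2"] = a1
        swapped.dosages[:, j] = 2.0 - swapped.dosages[:, j]
        again = project_samples(space, swapped)
        np.testing.assert_allclose(again.scores, baseline.scores, atol=1e-10)

    def test_no_structure_no_separation(self):
        model = PopulationModel.from_divergences(
            [0.0, 0.0], n_variants=1000, pop_labels=["a", "b"]
        )
        geno = simulate_genotypes(model, [500, 500], seed=66)
        panel = geno.take_samples(geno.sample_ids[::2])
        cohort = geno.take_samples(geno.sample_ids[1::2])
        space = build_pc_space(panel, k=10)
        proj = project_samples(space, cohort)
        labels = (cohort.sample_info["population"] == "b").to_numpy(float)
        for j in range(10):
            r = np.corrcoef(proj.scores[:, j], labels)[0, 1]
            assert abs(r) < 0.1


class TestMakePCSets:
    def test_cardinality_and_overlap_guard(self, panel_and_cohort):
        geno, panel, cohort = panel_and_cohort
        half = panel.take_samples(panel.sample_ids[:100])
        other = panel.take_samples(panel.sample_ids[100:])
        spaces, coords = make_pc_sets(
            {"cohort": cohort}, {"p1": half, "p2": other}, k=5
        )
        assert set(coords["cohort"]) == {"p1", "p2"}
        with pytest.raises(ValueError, match="overlaps"):
            make_pc_sets({"c": half}, {"p": half}, k=5)
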