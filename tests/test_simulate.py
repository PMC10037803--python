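"""Synthetic-fixture generator: structure, determinism, planted signals."""

import warnings

import numpy as np
import pandas as pd
import pytest

from heritex import (
    SimulationConfig,
    TruthTable,
    build_default_fixture,
    load_genotypes,
    plant_sweep,
    simulate_expression,
    simulate_genotypes,
    simulate_organismal_trait,
    simulate_splicing_counts,
    write_fixture_set,
)
from heritex.simulate import replicate_plan, tile_gene_models, tile_introns


def wc_fst_per_site_oracle(dosage, labels):
    """Independent per-site Weir-Cockerham theta (haploid, two pops)."""
    labs = np.asarray(labels)
    pops = list(dict.fromkeys(labs))
    a1 = dosage[labs == pops[0]] / 2.0
    a2 = dosage[labs == pops[1]] / 2.0
    n1, n2 = len(a1), len(a2)
    p1, p2 = a1.mean(axis=0), a2.mean(axis=0)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 - 1 + n2 - 1)
    nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
    return msp - msg, msp + (nc - 1) * msg


class TestGenotypeSimulation:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_genotypes=50, n_markers=300, seed=1)
        g1, l1 = simulate_genotypes(cfg)
        g2, l2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosage, g2.dosage)
        pd.testing.assert_series_equal(l1, l2)

    def test_inbred_no_heterozygotes(self, small_genotypes):
        g, _ = small_genotypes
        assert set(np.unique(g.dosage)) <= {0.0, 2.0}

    def test_maf_floor_holds(self, small_genotypes):
        g, _ = small_genotypes
        assert (g.maf() >= 0.05 - 1e-12).mean() >= 0.99

    def test_no_divergence_limit_equal_frequencies(self):
        cfg = SimulationConfig(
            n_genotypes=400, n_markers=500, divergence_F=0.001, seed=3
        )
        g, labels = simulate_genotypes(cfg)
        lab = labels.to_numpy()
        gap = np.abs(
            g.dosage[lab == "pop1"].mean(axis=0) - g.dosage[lab == "pop2"].mean(axis=0)
        ) / 2.0
        cfg_hi = SimulationConfig(
            n_genotypes=400, n_markers=500, divergence_F=0.3, seed=3
        )
        gh, lh = simulate_genotypes(cfg_hi)
        gap_hi = np.abs(
            gh.dosage[lh == "pop1"].mean(axis=0) - gh.dosage[lh == "pop2"].mean(axis=0)
        ) / 2.0
        assert gap.mean() < 0.05
        assert gap.mean() < gap_hi.mean() / 3

    def test_balding_nichols_fst_calibration(self):
        # calibration of the frequency model itself: independent sites
        # (the LD copula preserves marginals but inflates estimator variance)
        cfg = SimulationConfig(
            n_genotypes=200, n_markers=10_000, divergence_F=0.1,
            ld_scale_bp=0.0, seed=4,
        )
        g, labels = simulate_genotypes(cfg)
        num, den = wc_fst_per_site_oracle(g.dosage, labels.to_numpy())
        assert np.nansum(num) / np.nansum(den) == pytest.approx(0.1, abs=0.02)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_markers=2, n_chromosomes=5)
        with pytest.raises(ValueError):
            SimulationConfig(maf_floor=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(divergence_F=0.0)


class TestPlantSweep:
    def test_zero_gap_is_noop(self, small_genotypes):
        g, labels = small_genotypes
        g2 = plant_sweep(g, labels, ("chr1", 1, 10_000_000), 0.0)
        assert g2 is g

    def test_planted_window_exceeds_background_fst(self):
        for seed in range(3):
            cfg = SimulationConfig(
                n_genotypes=100, n_markers=1000, n_chromosomes=1, seed=seed
            )
            g, labels = simulate_genotypes(cfg)
            region = ("chr1", 4_000_000, 4_100_000)
            g2 = plant_sweep(g, labels, region, 0.9, seed=seed)
            num, den = wc_fst_per_site_oracle(g2.dosage, labels.to_numpy())
            with np.errstate(invalid="ignore"):
                fst = num / den
            inside = (
                (g2.markers["pos"] >= region[1]) & (g2.markers["pos"] <= region[2])
            ).to_numpy()
            assert inside.sum() > 0
            assert np.nanmin(fst[inside]) > np.nanmean(fst[~inside])

    def test_outside_markers_untouched(self, small_genotypes):
        g, labels = small_genotypes
        region = ("chr1", 4_000_000, 4_100_000)
        g2 = plant_sweep(g, labels, region, 0.9, seed=1)
        outside = ~(
            (g.markers["chrom"] == "chr1")
            & (g.markers["pos"] >= region[1])
            & (g.markers["pos"] <= region[2])
        ).to_numpy()
        np.testing.assert_array_equal(g2.dosage[:, outside], g.dosage[:, outside])

    def test_empty_region_warns_and_noops(self, small_genotypes):
        g, labels = small_genotypes
        with pytest.warns(UserWarning):
            g2 = plant_sweep(g, labels, ("chr1", 1, 2), 0.9)
        np.testing.assert_array_equal(g2.dosage, g.dosage)


class TestExpressionSimulation:
    def test_zero_h2_gene_independent_of_genotype(self):
        cfg = SimulationConfig(n_genotypes=150, replicates_per_genotype=3, n_markers=50, seed=6)
        g, _ = simulate_genotypes(cfg)
        truth = TruthTable(per_gene_target_H2={"gA": 0.0})
        rmap = replicate_plan(g.sample_ids, 3)
        expr = simulate_expression(g, truth, rmap, seed=7)
        from heritex import estimate_h2

        vc = estimate_h2(np.log(expr.fpkm["gA"]), rmap)
        assert vc.h2 < 0.05

    def test_planted_cis_pve_recovered_by_ols_oracle(self):
        cfg = SimulationConfig(n_genotypes=300, replicates_per_genotype=2, n_markers=50, seed=8)
        g, _ = simulate_genotypes(cfg)
        marker = g.markers["id"].iloc[10]
        genes = {f"g{i}": 0.6 for i in range(30)}
        truth = TruthTable(
            planted_cis=[(gid, marker, 0.0, 0.4) for gid in genes],
            per_gene_target_H2=genes,
        )
        rmap = replicate_plan(g.sample_ids, 2)
        expr = simulate_expression(g, truth, rmap, seed=9)
        x = g.column(marker)
        r2s = []
        logm = np.log(expr.fpkm).groupby(rmap.to_numpy()).mean().loc[g.sample_ids]
        for gid in genes:
            y = logm[gid].to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            r2s.append(r * r)
        assert np.mean(r2s) == pytest.approx(0.4, abs=0.05)

    def test_h2_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            TruthTable(per_gene_target_H2={"g": 1.0})

    def test_mean_h2_recovery(self, replicated_expression):
        from heritex import h2_table

        expr, rmap = replicated_expression
        logf = np.log(expr.fpkm)
        h2 = h2_table(logf, rmap)
        assert h2["h2"].mean() == pytest.approx(0.5, abs=0.05)


class TestSplicingSimulation:
    @pytest.fixture(scope="class")
    def splice_setup(self):
        cfg = SimulationConfig(n_genotypes=100, replicates_per_genotype=2, n_markers=200, seed=10)
        g, _ = simulate_genotypes(cfg)
        genes = tile_gene_models(cfg, 20)
        introns = tile_introns(genes, 10)
        rmap = replicate_plan(g.sample_ids, 2)
        return cfg, g, introns, rmap

    def test_expected_psi_matches_target_at_high_depth(self, splice_setup):
        _, g, introns, rmap = splice_setup
        truth = TruthTable()
        u, d = simulate_splicing_counts(
            g, introns, truth, rmap, base_psi_range=(1.0, 1.0), mean_coverage=500.0, seed=11
        )
        sizes = (introns["end"] - introns["start"] + 1).to_numpy()
        psi = u.to_numpy() * sizes[None, :] / d.to_numpy()
        assert psi.mean() == pytest.approx(1.0, abs=0.01)

    def test_no_shift_gives_identical_dosage_class_distributions(self, splice_setup):
        from scipy import stats

        _, g, introns, rmap = splice_setup
        u, d = simulate_splicing_counts(g, introns, TruthTable(), rmap, seed=12)
        sizes = (introns["end"] - introns["start"] + 1).to_numpy()
        psi = u.to_numpy() * sizes[None, :] / np.maximum(d.to_numpy(), 1)
        x = g.column(g.markers["id"].iloc[0])
        samp_rows = np.array([g.sample_ids.index(s) for s in rmap.to_numpy()])
        dose = x[samp_rows]
        ps = [
            stats.ks_2samp(psi[dose == 0, j], psi[dose == 2, j]).pvalue
            for j in range(psi.shape[1])
        ]
        assert min(ps) > 0.001  # no systematic dosage effect

    def test_zero_expression_gives_zero_depth(self, splice_setup):
        _, g, introns, rmap = splice_setup
        u, d = simulate_splicing_counts(
            g, introns, TruthTable(), rmap, zero_expression_frac=1.0, seed=13
        )
        assert (d.to_numpy() == 0).all()

    def test_negative_target_psi_rejected(self, splice_setup):
        _, g, introns, rmap = splice_setup
        truth = TruthTable(
            planted_splice_qtl=[(introns["intron_id"].iloc[0], g.markers["id"].iloc[0], -2.0)]
        )
        with pytest.raises(ValueError):
            simulate_splicing_counts(
                g, introns, truth, rmap, base_psi_range=(0.5, 0.5), seed=14
            )


class TestOrganismalTrait:
    def test_null_trait_controls_familywise_error(self, independent_genotypes):
        from heritex import bonferroni_threshold, lm_scan

        g, _ = independent_genotypes
        trait = simulate_organismal_trait(g, [], seed=15)
        res = lm_scan(np.log(trait), g)
        thr = bonferroni_threshold(0.05, g.n_markers)
        assert (res["p"] <= thr.p).sum() == 0

    def test_large_effect_marker_is_lead(self, independent_genotypes):
        from heritex import bonferroni_threshold, group_peaks, lm_scan

        g, _ = independent_genotypes
        marker = g.markers["id"].iloc[500]
        trait = simulate_organismal_trait(g, [(marker, 1.0)], noise_sd=0.3, seed=16)
        res = lm_scan(np.log(trait), g)
        assert res["p"].idxmin() == marker

    def test_reproducible_under_seed(self, independent_genotypes):
        g, _ = independent_genotypes
        t1 = simulate_organismal_trait(g, [("chr1_1", 0.2)] if "chr1_1" in set(g.markers["id"]) else [], seed=17)
        t2 = simulate_organismal_trait(g, [("chr1_1", 0.2)] if "chr1_1" in set(g.markers["id"]) else [], seed=17)
        pd.testing.assert_series_equal(t1, t2)


class TestFixtureSet:
    def test_write_then_read_round_trips(self, default_fx, tmp_path):
        paths = write_fixture_set(default_fx, tmp_path / "fx")
        g2 = load_genotypes(paths["vcf"])
        np.testing.assert_array_equal(g2.dosage, default_fx.genotypes.dosage)
        expr2 = pd.read_csv(paths["expression"], sep="\t", index_col=0)
        np.testing.assert_allclose(
            expr2.to_numpy(), default_fx.expression.fpkm.to_numpy(), rtol=1e-12
        )
        truth2 = TruthTable.from_json(paths["truth"])
        assert truth2 == default_fx.truth

    def test_truth_references_validate(self, default_fx):
        default_fx.truth.validate_against(
            [g.gene_id for g in default_fx.gene_models],
            list(default_fx.genotypes.markers["id"]),
        )

    def test_fixture_determinism(self):
        fx1 = build_default_fixture(seed=3, n_genes=50, n_introns=10, n_cis=5,
                                    n_trans=2, n_modules=1, module_size=10, n_sqtl=3,
                                    config=SimulationConfig(n_genotypes=60, n_markers=400, seed=3))
        fx2 = build_default_fixture(seed=3, n_genes=50, n_introns=10, n_cis=5,
                                    n_trans=2, n_modules=1, module_size=10, n_sqtl=3,
                                    config=SimulationConfig(n_genotypes=60, n_markers=400, seed=3))
        np.testing.assert_array_equal(fx1.genotypes.dosage, fx2.genotypes.dosage)
        pd.testing.assert_frame_equal(fx1.expression.fpkm, fx2.expression.fpkm)
        assert fx1.truth == fx2.truth
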