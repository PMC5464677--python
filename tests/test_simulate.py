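"""Generator tests: determinism, map-function consistency, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from galmap import simulate
from galmap.simulate import SimConfig, StrainSpec, VarpartParams, GrowthParams


class TestConfigValidation:
    def test_nonpositive_grid_rejected(self):
        with pytest.raises(ValueError, match="glucose_grid"):
            SimConfig(glucose_grid=(1.0, 0.0))
        with pytest.raises(ValueError, match="glucose_grid"):
            SimConfig(glucose_grid=(1.0, -0.5))

    def test_pool_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(pool_fraction=0.0)
        with pytest.raises(ValueError):
            SimConfig(pool_fraction=0.6)
        SimConfig(pool_fraction=0.5)  # boundary allowed

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            VarpartParams(v_bg=-0.1)

    def test_od_ordering_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(od_start=1.0, od_sat=0.5)

    def test_haplotypes_exceed_strains(self):
        with pytest.raises(ValueError):
            simulate.VariantParams(n_strains=5, n_haplotypes=6)


class TestFlowGenerator:
    def test_determinism_byte_identical(self, flow_config):
        a, _ = simulate.gen_flow_experiment(flow_config)
        b, _ = simulate.gen_flow_experiment(flow_config)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_step_function_limit(self):
        # near-zero channel overlap + huge hill coefficient: induced fraction
        # is a step crossing 0.5 exactly at the planted threshold
        cfg = SimConfig(
            seed=2,
            strains=(StrainSpec("s", 0.25, 200.0),),
            channel_sd=0.01,
            measurement_sd_log2=0.0,
            cells_per_well=500,
        )
        cells, truth = simulate.gen_flow_experiment(cfg)
        sub = cells[(cells.strain_id == "s") & (cells.replicate == 1)
                    & (cells.galactose_pct == 0.25)]
        cutoff = 10 ** ((cfg.basal_mean + cfg.induced_mean) / 2)
        frac = sub.groupby("glucose_pct")["yfp"].apply(lambda v: (v > cutoff).mean())
        assert frac.loc[0.5] == 0.0
        assert frac.loc[0.125] == 1.0
        # at g = F50 the mixing weight is exactly 1/2
        assert abs(frac.loc[0.25] - 0.5) < 0.1

    def test_truth_records_planted_values(self, flow_config):
        _, truth = simulate.gen_flow_experiment(flow_config)
        expected = {s.strain_id: s.true_f50 for s in flow_config.strains}
        assert truth.strain_f50 == expected
        assert set(truth.replicate_log2_f50) == {
            (s, r)
            for s in expected
            for r in range(1, flow_config.n_replicates + 1)
        }

    def test_outlier_experiments_logged(self):
        cfg = SimConfig(seed=3, outlier_rate=1.0, outlier_shift=3.0,
                        strains=(StrainSpec("s", 0.1),), n_replicates=2)
        _, truth = simulate.gen_flow_experiment(cfg)
        assert truth.outlier_experiments == [("s", 1), ("s", 2)]


class TestMeiosis:
    def test_zero_distance_always_coinherited(self, rng):
        pos = np.array([1000, 1000])
        hap_a = np.zeros((2000, 2), np.int8)
        hap_b = np.ones((2000, 2), np.int8)
        gam = simulate._meiosis_chrom(hap_a, hap_b, pos, 1_000_000, 1 / 2200, rng)
        assert (gam[:, 0] == gam[:, 1]).all()

    @pytest.mark.parametrize("d_cm", [1.0, 10.0, 50.0])
    def test_haldane_recombinant_fraction(self, d_cm, rng):
        bp_per_cm = 2200.0
        pos = np.array([1, int(1 + d_cm * bp_per_cm)])
        n = 10_000
        gam = simulate._meiosis_chrom(
            np.zeros((n, 2), np.int8),
            np.ones((n, 2), np.int8),
            pos,
            pos[-1] + 1,
            1 / bp_per_cm,
            rng,
        )
        r_obs = float((gam[:, 0] != gam[:, 1]).mean())
        r_exp = (1 - np.exp(-2 * d_cm / 100)) / 2
        se = np.sqrt(r_exp * (1 - r_exp) / n)
        assert abs(r_obs - r_exp) < 3 * se

    def test_50cm_through_generator_api(self):
        cfg = SimConfig(
            seed=21,
            chrom_lengths_bp=(220_001,),
            snp_spacing_bp=110_000,
            n_segregants=10_000,
            intercross_rounds=0,
            qtl=None,
        )
        genomes, _ = simulate.gen_cross_segregants(cfg)
        geno = genomes.genotypes["chr1"]
        assert geno.shape[1] == 2  # markers 50 cM apart (110 kb at 2200 bp/cM)
        r_obs = float((geno[:, 0] != geno[:, 1]).mean())
        r_exp = (1 - np.exp(-1.0)) / 2
        assert abs(r_obs - r_exp) < 3 * np.sqrt(r_exp * (1 - r_exp) / 10_000)

    def test_block_length_shrinks_with_intercrossing(self):
        lengths = []
        for rounds in range(5):
            cfg = SimConfig(
                seed=7,
                chrom_lengths_bp=(2_000_000,),
                snp_spacing_bp=1000,
                n_segregants=300,
                intercross_rounds=rounds,
                qtl=None,
            )
            genomes, _ = simulate.gen_cross_segregants(cfg)
            lengths.append(simulate.mean_block_length(genomes))
        assert all(b < a for a, b in zip(lengths, lengths[1:]))

    def test_zero_segregants_error(self):
        cfg = SimConfig(seed=1)
        object.__setattr__(cfg, "n_segregants", 0)
        with pytest.raises(ValueError, match="at least one segregant"):
            simulate.gen_cross_segregants(cfg)

    def test_determinism(self, small_cross_config):
        a, _ = simulate.gen_cross_segregants(small_cross_config)
        b, _ = simulate.gen_cross_segregants(small_cross_config)
        for c in a.chroms:
            assert (a.genotypes[c] == b.genotypes[c]).all()
        assert (a.phenotypes == b.phenotypes).all()


class TestPoolCounts:
    def test_null_cross_frequencies_near_half(self, null_cross_config):
        genomes, _ = simulate.gen_cross_segregants(null_cross_config)
        counts = simulate.gen_pool_counts(genomes, null_cross_config)
        freq_on = counts.A_on / (counts.A_on + counts.B_on)
        n_pool = int(round(0.05 * null_cross_config.n_segregants))
        # pool sampling + read sampling noise around 0.5
        se = np.sqrt(0.25 / n_pool + 0.25 / null_cross_config.mean_depth)
        assert abs(freq_on.mean() - 0.5) < 3 * se / np.sqrt(len(counts) / 50)

    def test_strong_qtl_polarizes_pools(self):
        cfg = SimConfig(
            seed=17,
            chrom_lengths_bp=(1_000_000, 1_000_000),
            snp_spacing_bp=5000,
            n_segregants=2000,
            qtl=("chr1", 500_000, 5.0),
            segregant_noise_sd=0.05,
            mean_depth=200.0,
        )
        genomes, truth = simulate.gen_cross_segregants(cfg)
        counts = simulate.gen_pool_counts(genomes, cfg)
        qtl_row = counts[(counts.chrom == "chr1") & (counts.pos == truth.qtl[1])]
        f_on = float((qtl_row.A_on / (qtl_row.A_on + qtl_row.B_on)).iloc[0])
        assert f_on < 0.05  # ON pool nearly fixed for the high (B=1) allele
        far = counts[counts.chrom == "chr2"]
        f_far = (far.A_on / (far.A_on + far.B_on)).mean()
        assert abs(f_far - 0.5) < 0.05

    def test_depth_matches_poisson_mean(self):
        cfg = SimConfig(
            seed=19,
            chrom_lengths_bp=(5_000_000, 5_000_000),
            snp_spacing_bp=1000,
            n_segregants=200,
            qtl=None,
        )
        genomes, _ = simulate.gen_cross_segregants(cfg)
        counts = simulate.gen_pool_counts(genomes, cfg)
        assert len(counts) == 10_000
        depth = (counts.A_on + counts.B_on).mean()
        assert abs(depth - cfg.mean_depth) / cfg.mean_depth < 0.02

    def test_tiny_pool_error(self, small_cross_config):
        cfg = simulate.SimConfig(
            seed=1, n_segregants=20, pool_fraction=0.05,
            chrom_lengths_bp=(100_000,), snp_spacing_bp=10_000,
        )
        genomes, _ = simulate.gen_cross_segregants(cfg)
        with pytest.raises(ValueError, match="too small"):
            simulate.gen_pool_counts(genomes, cfg)


class TestVarpartGenerator:
    def test_degenerate_two_levels(self):
        cfg = SimConfig(seed=2, varpart=VarpartParams(v_bg=0.0, epsilon=0.0, v_gal3=0.25))
        table, _ = simulate.gen_varpart_populations(cfg)
        h1 = table[table.hybrid_id == "hybrid1"]
        values = sorted(h1.rep1.unique())
        assert values == pytest.approx([-0.5, 0.5])  # two levels 2E apart, E=0.5
        assert (h1.rep1 == h1.rep2).all()

    def test_determinism(self):
        cfg = SimConfig(seed=9)
        a, _ = simulate.gen_varpart_populations(cfg)
        b, _ = simulate.gen_varpart_populations(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_truth_echo(self):
        cfg = SimConfig(seed=4, varpart=VarpartParams(v_gal3=0.5, v_bg=0.2, epsilon=0.05))
        _, truth = simulate.gen_varpart_populations(cfg)
        assert (truth.v_gal3, truth.v_bg, truth.epsilon) == (0.5, 0.2, 0.05)


class TestGrowthGenerator:
    def test_noise_free_nondecreasing(self):
        cfg = SimConfig(seed=3, growth=GrowthParams(od_noise_sd=0.0))
        curves, _ = simulate.gen_growth_curves(cfg, lags={"s": 2.0})
        od = curves.od600.to_numpy()
        assert (np.diff(od) >= -1e-12).all()

    def test_sampling_interval(self):
        cfg = SimConfig(seed=3)
        curves, _ = simulate.gen_growth_curves(cfg, lags={"s": 1.0})
        dt = np.diff(curves.time_h.to_numpy())
        assert np.allclose(dt, 0.25)

    def test_lag_zero_has_no_plateau(self):
        cfg = SimConfig(seed=3, growth=GrowthParams(od_noise_sd=0.0))
        curves, _ = simulate.gen_growth_curves(cfg, lags={"s": 0.0})
        log2od = np.log2(curves.od600.to_numpy())
        t = curves.time_h.to_numpy()
        rate = np.gradient(log2od, t)
        # before saturation the rate never sits at ~0
        pre_sat = log2od < np.log2(1.0) - 0.1
        assert rate[pre_sat][1:-1].min() > 0.2

    def test_negative_lag_rejected(self):
        cfg = SimConfig(seed=3)
        with pytest.raises(ValueError):
            simulate.gen_growth_curves(cfg, lags={"s": -1.0})


class TestVariantGenerator:
    def test_zero_snps_one_haplotype(self):
        cfg = SimConfig(
            seed=6,
            variants=simulate.VariantParams(
                n_strains=10, n_promoter_snps=1, n_coding_snps=0, n_haplotypes=1
            ),
        )
        from galmap import popgen
        matrix, _, truth = simulate.gen_variant_data(cfg)
        assert truth.n_haplotypes == 1
        n, _, _ = popgen.count_haplotypes(matrix, "all")
        assert n == 1

    def test_planted_haplotype_count_recovered(self):
        from galmap import popgen
        cfg = SimConfig(
            seed=8,
            variants=simulate.VariantParams(
                n_strains=55, n_haplotypes=21, n_promoter_snps=13, n_coding_snps=27
            ),
        )
        matrix, _, truth = simulate.gen_variant_data(cfg)
        assert truth.n_haplotypes == 21
        n, _, _ = popgen.count_haplotypes(matrix, "all")
        assert n == 21

    def test_planted_labels_match_classifier(self):
        from galmap import popgen
        cfg = SimConfig(seed=12)
        matrix, _, truth = simulate.gen_variant_data(cfg)
        labels = popgen.classify_coding_snps(matrix)
        assert list(labels["label"]) == truth.coding_labels

    def test_cds_structure(self):
        cfg = SimConfig(seed=14)
        matrix, outgroup, _ = simulate.gen_variant_data(cfg)
        cds = matrix.ref_cds
        assert len(cds) % 3 == 0
        assert cds.startswith("ATG")
        assert cds[-3:] in simulate.STOP_CODONS
        internal = {cds[i : i + 3] for i in range(3, len(cds) - 3, 3)}
        assert not (internal & simulate.STOP_CODONS)
        assert len(outgroup) == len(cds)

    def test_determinism(self):
        cfg = SimConfig(seed=15)
        a, out_a, _ = simulate.gen_variant_data(cfg)
        b, out_b, _ = simulate.gen_variant_data(cfg)
        assert out_a == out_b
        assert (a.alleles == b.alleles).all()
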