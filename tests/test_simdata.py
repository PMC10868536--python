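import dataclasses

import numpy as np
import pytest
from Bio.Seq import Seq

from featuregp.kinship import ibs_matrix, ld_decay
from featuregp.qc import hwe_exact_test
from featuregp.simdata import (
    SimConfig,
    simulate,
    simulate_genome,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_to_dir,
)

SMALL = dict(
    n_chromosomes=2,
    chrom_length_bp=200_000,
    n_genes=8,
    n_variants_dense=600,
    n_variants_chip=80,
    n_individuals={"validation": 150},
)


class TestConfigValidation:
    def test_chip_larger_than_dense_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_variants_chip=10, n_variants_dense=5)

    def test_fst_one_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(fst=1.0)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_qtl=0)


class TestSimulateGenome:
    def test_zero_genes_gives_empty_annotation(self):
        from featuregp.annotate import classify_variants

        cfg = SimConfig(seed=1, **{**SMALL, "n_genes": 0})
        ref, genes = simulate_genome(cfg)
        assert genes == []
        variants = __import__("pandas").DataFrame(
            {"chrom": "1", "pos": [100, 5000], "ref": "A", "alt": "C",
             "id": ["a", "b"]}
        )
        out = classify_variants(variants, genes, ref)
        assert all(c == {"intergenic"} for c in out["classes"])

    def test_deterministic_under_seed(self, tmp_path):
        cfg = SimConfig(seed=9, **SMALL)
        a = simulate_to_dir(cfg, tmp_path / "a")
        b = simulate_to_dir(cfg, tmp_path / "b")
        assert a.reference.read_bytes() == b.reference.read_bytes()
        assert a.genes.read_bytes() == b.genes.read_bytes()
        assert a.genotypes_dense.read_bytes() == b.genotypes_dense.read_bytes()
        assert a.phenotypes.read_bytes() == b.phenotypes.read_bytes()

    def test_cds_translates_without_internal_stops(self):
        """Oracle: independent codon-table translation of the emitted
        sequences."""
        table = {}
        bases = "TCAG"
        aas = (
            "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        )
        k = 0
        for b1 in bases:
            for b2 in bases:
                for b3 in bases:
                    table[b1 + b2 + b3] = aas[k]
                    k += 1
        cfg = SimConfig(seed=17, **SMALL)
        ref, genes = simulate_genome(cfg)
        assert len(genes) == 8
        for gene in genes:
            cds = gene.coding_sequence(ref)
            assert len(cds) % 3 == 0
            prot = "".join(
                table[cds[i : i + 3]] for i in range(0, len(cds), 3)
            )
            assert "*" not in prot[:-1], gene.gene_id
            assert prot[-1] == "*"

    def test_gene_structure_complete(self):
        cfg = SimConfig(seed=18, **SMALL)
        _, genes = simulate_genome(cfg)
        for g in genes:
            assert len(g.cds) >= 2  # hence >= 1 intron
            assert g.utr5 and g.utr3

    def test_genic_fraction_leaves_intergenic_room(self):
        cfg = SimConfig(seed=19, **SMALL)
        _, genes = simulate_genome(cfg)
        genic = sum(g.end - g.start + 1 for g in genes)
        assert genic <= 0.6 * 2 * 200_000

    def test_impossible_density_fails_with_named_constraint(self):
        cfg = SimConfig(seed=20, **{**SMALL, "n_genes": 200})
        with pytest.raises(ValueError, match="genic fraction"):
            simulate_genome(cfg)


class TestSimulateGenotypes:
    def test_chip_positions_subset_of_dense(self):
        cfg = SimConfig(seed=21, **SMALL)
        ref, _ = simulate_genome(cfg)
        dense, chip = simulate_genotypes(cfg, ref)
        assert set(chip.variants["id"]) <= set(dense.variants["id"])

    def test_hwe_holds_without_structure(self):
        """With one panmictic population the genotype counts pass the exact
        HWE test at nearly every variant."""
        cfg = SimConfig(
            seed=22,
            n_chromosomes=1,
            chrom_length_bp=300_000,
            n_genes=4,
            n_variants_dense=400,
            n_variants_chip=50,
            n_individuals={"validation": 1000},
            fst=0.0,
            missing_rate=0.0,
        )
        ref, _ = simulate_genome(cfg)
        dense, _ = simulate_genotypes(cfg, ref)
        g = dense.genotypes
        passed = 0
        for j in range(dense.n_variants):
            col = g[:, j]
            p = hwe_exact_test(
                int((col == 0).sum()), int((col == 1).sum()),
                int((col == 2).sum()),
            )
            passed += p > 1e-6
        assert passed / dense.n_variants >= 0.99

    def test_no_ld_when_block_length_zero(self):
        cfg = SimConfig(seed=23, **{**SMALL, "ld_block_bp": 0},
                        missing_rate=0.0)
        ref, _ = simulate_genome(cfg)
        dense, _ = simulate_genotypes(cfg, ref)
        t = ld_decay(dense, max_dist=100_000, bin_width=50_000)
        # near vs far bins indistinguishable without block copying
        assert abs(t.mean_r2[0] - t.mean_r2[1]) < 0.01

    def test_ld_decays_with_distance(self):
        near, far = [], []
        for seed in range(5):
            cfg = SimConfig(seed=seed, **{**SMALL, "ld_block_bp": 40_000},
                            missing_rate=0.0)
            ref, _ = simulate_genome(cfg)
            dense, _ = simulate_genotypes(cfg, ref)
            t = ld_decay(dense, max_dist=100_000, bin_width=10_000)
            near.append(t.mean_r2[0])
            far.append(t.mean_r2[9])
        assert np.mean(near) > np.mean(far)

    def test_population_divergence_lowers_cross_ibs(self):
        cfg = SimConfig(
            seed=24,
            **{**SMALL, "n_individuals": {"a": 80, "b": 80}},
            fst=0.15,
            missing_rate=0.0,
        )
        ref, _ = simulate_genome(cfg)
        dense, _ = simulate_genotypes(cfg, ref)
        sim = ibs_matrix(dense).matrix
        pop = dense.samples["population"].to_numpy()
        within = []
        cross = []
        for i in range(len(pop)):
            for k in range(i):
                (within if pop[i] == pop[k] else cross).append(sim[i, k])
        assert np.mean(cross) < np.mean(within)

    def test_missingness_injected_at_configured_rate(self):
        cfg = SimConfig(seed=25, **SMALL, missing_rate=0.05)
        ref, _ = simulate_genome(cfg)
        dense, _ = simulate_genotypes(cfg, ref)
        rate = np.isnan(dense.genotypes).mean()
        assert rate == pytest.approx(0.05, abs=0.01)


class TestSimulatePhenotypes:
    @pytest.fixture(scope="class")
    def geno(self):
        cfg = SimConfig(seed=26, **{**SMALL,
                                    "n_individuals": {"validation": 1000}})
        ref, _ = simulate_genome(cfg)
        dense, _ = simulate_genotypes(cfg, ref)
        return cfg, dense

    def test_realized_h2_matches_target(self, geno):
        cfg, dense = geno
        ph, qtl, ti = simulate_phenotypes(dense, cfg)
        for trait in cfg.trait_set:
            r = qtl.loc[qtl["trait"] == trait, "realized_h2"].iloc[0]
            assert r == pytest.approx(cfg.h2_target, abs=0.02)

    def test_zero_heritability_uncorrelated(self, geno):
        cfg, dense = geno
        cfg0 = dataclasses.replace(cfg, h2_target=0.0)
        ph, _, ti = simulate_phenotypes(dense, cfg0)
        r = np.corrcoef(ph["BF"], ti["tbv_BF"])[0, 1]
        assert abs(r) < 0.08

    def test_near_unit_heritability_recovers_tbv(self, geno):
        cfg, dense = geno
        cfg99 = dataclasses.replace(cfg, h2_target=0.99)
        ph, _, ti = simulate_phenotypes(dense, cfg99)
        assert np.corrcoef(ph["BF"], ti["tbv_BF"])[0, 1] > 0.95

    def test_regression_slope_on_tbv_is_one(self, geno):
        """OLS oracle: phenotype = baseline + tbv + independent noise, so the
        slope of phenotype on tbv is 1."""
        cfg, dense = geno
        ph, _, ti = simulate_phenotypes(dense, cfg)
        x = ti["tbv_LMA"].to_numpy()
        y = ph["LMA"].to_numpy()
        slope = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_class_enrichment_requires_assignments(self, geno):
        cfg, dense = geno
        cfg_c = dataclasses.replace(cfg, qtl_class="intron")
        with pytest.raises(ValueError, match="class_assignments"):
            simulate_phenotypes(dense, cfg_c)

    def test_undersized_class_fails_loudly(self, geno):
        import pandas as pd

        cfg, dense = geno
        cfg_c = dataclasses.replace(cfg, qtl_class="synonymous",
                                    qtl_class_fraction=1.0)
        assignments = pd.DataFrame(
            {
                "id": dense.variant_ids(),
                "classes": [frozenset(["intergenic"])] * dense.n_variants,
            }
        )
        assignments.loc[0, "classes"] = frozenset(["synonymous"])
        with pytest.raises(ValueError, match="synonymous"):
            simulate_phenotypes(dense, cfg_c, assignments)


def test_full_simulation_deterministic_in_memory():
    cfg = SimConfig(seed=30, **SMALL)
    a = simulate(cfg)
    b = simulate(cfg)
    np.testing.assert_array_equal(a["dense"].genotypes, b["dense"].genotypes)
    assert a["phenotypes"].equals(b["phenotypes"])
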