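"""Synthetic genome, two-population genotypes and growth-trait phenotypes.

The generator emulates the structure of a commercial pig breeding dataset in
which real genotypes are proprietary: two validation populations genotyped at
chip density plus small discovery populations, all sharing one genome; marker
density switchable between a dense ("sequence-like") set and a spaced chip
subset; linkage disequilibrium decaying over tens of kb; six growth traits
with moderate heritability; and a truth table of QTL positions, effects and
true breeding values for oracle-based testing.

Model choices
-------------
* Population divergence: Balding-Nichols.  Each population's allele frequency
  at a locus is Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency
  p ~ Uniform(0.05, 0.95), with F the fixation index.
* LD: haplotype-block copying.  Each population carries a small pool of
  founder haplotypes; an individual haplotype copies one founder per block of
  ``ld_block_bp``, so r^2 is high within a block and decays roughly linearly
  with distance up to the block length.  ``ld_block_bp = 0`` disables LD.
* Genetic architecture: ``n_qtl`` loci with Gaussian effects; a configurable
  fraction of QTL can be forced into one genomic class to emulate
  feature-enriched architectures.  The residual is rescaled (after removing
  its sample covariance with the genetic values) so the realised
  narrow-sense h2 matches the target exactly in-sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel, write_gff3
from .genotypes import GenotypeMatrix, variant_key

__all__ = ["SimConfig", "SimOutput", "simulate_genome", "simulate_genotypes",
           "simulate_phenotypes", "simulate", "simulate_to_dir"]

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))

#: trait baselines and phenotypic SDs on plausible scales
#: (days, kg/d, mm, cm^2, mm, %)
TRAIT_BASELINES = {
    "AGE": 160.0,
    "ADG": 0.62,
    "BF": 11.0,
    "LMA": 42.0,
    "LMD": 55.0,
    "LMP": 59.0,
}
TRAIT_SDS = {
    "AGE": 8.0,
    "ADG": 0.05,
    "BF": 1.8,
    "LMA": 3.5,
    "LMD": 4.0,
    "LMP": 1.7,
}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 400_000
    n_genes: int = 20
    n_variants_dense: int = 4_000
    n_variants_chip: int = 400
    n_individuals: dict = field(
        default_factory=lambda: {"validation": 2000, "discovery": 250}
    )
    fst: float = 0.10
    h2_target: float = 0.30
    n_qtl: int = 50
    qtl_class: str = "uniform"
    qtl_class_fraction: float = 1.0
    ld_block_bp: int = 50_000
    n_founder_haplotypes: int = 4
    missing_rate: float = 0.01
    trait_set: tuple = ("AGE", "ADG", "BF", "LMA", "LMD", "LMP")
    sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.n_variants_chip > self.n_variants_dense:
            raise ValueError("n_variants_chip must not exceed n_variants_dense")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError(f"h2_target must be in [0, 1], got {self.h2_target}")
        if not 0.0 <= self.qtl_class_fraction <= 1.0:
            raise ValueError("qtl_class_fraction must be in [0, 1]")
        for name in ("n_chromosomes", "chrom_length_bp", "n_variants_dense",
                     "n_variants_chip", "n_qtl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(n <= 0 for n in self.n_individuals.values()):
            raise ValueError("population sizes must be positive")


@dataclass
class SimOutput:
    reference: Path
    genes: Path
    genotypes_dense: Path
    genotypes_chip: Path
    phenotypes: Path
    truth_qtl: Path
    truth_individuals: Path


# ---------------------------------------------------------------------------
# Genome


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append(rng.choice(np.array(STOP_CODONS)))
    return "".join(codons)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def simulate_genome(config: SimConfig):
    """Random reference plus non-overlapping protein-coding gene models.

    Every gene has a 5' UTR, a CDS split over >= 2 exons (hence >= 1 intron)
    whose length is a multiple of 3 and translates without internal stops,
    and a 3' UTR.  Genes are placed left to right with random intergenic
    gaps; at least 40% of each chromosome remains intergenic, otherwise gene
    placement fails with an explicit error.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    reference: dict[str, str] = {}
    genes: list[GeneModel] = []
    genes_per_chrom = np.full(config.n_chromosomes, config.n_genes //
                              config.n_chromosomes)
    genes_per_chrom[: config.n_genes % config.n_chromosomes] += 1
    for ci in range(config.n_chromosomes):
        chrom = str(ci + 1)
        seq = list(rng.choice(_BASES, size=config.chrom_length_bp))
        cursor = 1  # 1-based
        for gi in range(genes_per_chrom[ci]):
            utr5_len = int(rng.integers(100, 300))
            utr3_len = int(rng.integers(100, 300))
            n_codons = int(rng.integers(100, 300))
            cds_len = 3 * n_codons
            n_cds_exons = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(np.arange(3, cds_len - 3, 3),
                                      size=n_cds_exons - 1, replace=False))
            cds_chunk_lens = np.diff(np.concatenate([[0], cuts, [cds_len]]))
            intron_lens = rng.integers(1_000, 6_000, size=n_cds_exons - 1)
            gene_len = utr5_len + cds_len + utr3_len + int(intron_lens.sum())
            max_start = config.chrom_length_bp - gene_len + 1
            budget = int(0.6 * config.chrom_length_bp)
            if cursor + gene_len - 1 > budget or cursor > max_start:
                raise ValueError(
                    f"cannot place gene {gi + 1} on chromosome {chrom}: "
                    f"genic fraction would exceed 60% "
                    f"(chrom_length_bp={config.chrom_length_bp}, "
                    f"n_genes={config.n_genes})"
                )
            gap_room = (budget - (cursor + gene_len - 1)) // max(
                1, genes_per_chrom[ci] - gi
            )
            start = cursor + int(rng.integers(0, max(1, gap_room)))
            strand = "+" if rng.random() < 0.5 else "-"

            # lay out sense-strand order, then mirror labels for minus strand
            parts = []  # (kind, length) in genomic order
            chunks = list(cds_chunk_lens)
            if strand == "+":
                parts.append(("utr5", utr5_len))
                for k, cl in enumerate(chunks):
                    parts.append(("cds", int(cl)))
                    if k < len(intron_lens):
                        parts.append(("intron", int(intron_lens[k])))
                parts.append(("utr3", utr3_len))
            else:
                parts.append(("utr3", utr3_len))
                for k, cl in enumerate(reversed(chunks)):
                    parts.append(("cds", int(cl)))
                    if k < len(intron_lens):
                        parts.append(("intron", int(intron_lens[k])))
                parts.append(("utr5", utr5_len))

            pos = start
            cds_iv, utr5_iv, utr3_iv = [], [], []
            for kind, length in parts:
                iv = (pos, pos + length - 1)
                if kind == "cds":
                    cds_iv.append(iv)
                elif kind == "utr5":
                    utr5_iv.append(iv)
                elif kind == "utr3":
                    utr3_iv.append(iv)
                pos += length
            end = pos - 1

            # write the coding sequence into the reference
            coding = _random_cds(rng, n_codons)
            if strand == "-":
                genomic_cds = _revcomp(coding)
            else:
                genomic_cds = coding
            offset = 0
            for s, e in cds_iv:
                seq[s - 1 : e] = list(genomic_cds[offset : offset + (e - s + 1)])
                offset += e - s + 1

            # exons: merge adjacent non-intron parts into exon intervals
            exon_iv = []
            pos2 = start
            open_start = None
            for kind, length in parts:
                if kind == "intron":
                    if open_start is not None:
                        exon_iv.append((open_start, pos2 - 1))
                        open_start = None
                else:
                    if open_start is None:
                        open_start = pos2
                pos2 += length
            if open_start is not None:
                exon_iv.append((open_start, pos2 - 1))

            genes.append(
                GeneModel(
                    gene_id=f"gene_{chrom}_{gi + 1}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exon_iv,
                    cds=cds_iv,
                    utr5=utr5_iv,
                    utr3=utr3_iv,
                )
            )
            cursor = end + 1
        reference[chrom] = "".join(seq)
    return reference, genes


# ---------------------------------------------------------------------------
# Genotypes


def simulate_genotypes(config: SimConfig, reference: dict[str, str]):
    """Two-population genotypes with Balding-Nichols divergence and block LD.

    Returns ``(dense, chip)`` :class:`GenotypeMatrix` objects sharing one
    sample table; chip variant positions are an evenly spaced subset of dense
    positions.  Missing calls are injected at ``missing_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    pops = list(config.n_individuals)
    per_chrom = np.full(config.n_chromosomes,
                        config.n_variants_dense // config.n_chromosomes)
    per_chrom[: config.n_variants_dense % config.n_chromosomes] += 1

    var_rows = []
    hap_blocks = {pop: [] for pop in pops}  # per-chrom haplotype matrices
    for ci in range(config.n_chromosomes):
        chrom = str(ci + 1)
        m = int(per_chrom[ci])
        pos = np.sort(
            rng.choice(config.chrom_length_bp, size=m, replace=False) + 1
        )
        refseq = reference[chrom]
        ref_alleles = np.array([refseq[p - 1] for p in pos])
        alts = []
        for r in ref_alleles:
            choices = [b for b in "ACGT" if b != r]
            alts.append(choices[int(rng.integers(0, 3))])
        for p, r, a in zip(pos, ref_alleles, alts):
            var_rows.append({"chrom": chrom, "pos": int(p), "ref": r, "alt": a,
                             "id": variant_key(chrom, int(p), r, a)})

        p_anc = rng.uniform(0.05, 0.95, size=m)
        if config.ld_block_bp > 0:
            block_of = (pos - 1) // config.ld_block_bp
        else:
            block_of = None
        for pop in pops:
            n_hap = 2 * config.n_individuals[pop]
            if config.fst > 0:
                f = config.fst
                a = p_anc * (1 - f) / f
                b = (1 - p_anc) * (1 - f) / f
                p_pop = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
            else:
                p_pop = p_anc
            if block_of is None:
                haps = (rng.random((n_hap, m)) < p_pop).astype(np.int8)
            else:
                k = config.n_founder_haplotypes
                founders = (rng.random((k, m)) < p_pop).astype(np.int8)
                n_blocks = int(block_of.max()) + 1
                choice = rng.integers(0, k, size=(n_hap, n_blocks))
                haps = founders[choice[:, block_of], np.arange(m)]
            hap_blocks[pop].append(haps)

    variants = pd.DataFrame(var_rows)
    geno_parts, sample_rows = [], []
    for pop in pops:
        haps = np.concatenate(hap_blocks[pop], axis=1)
        n = config.n_individuals[pop]
        geno_parts.append((haps[0::2] + haps[1::2]).astype(float))
        sample_rows.extend(
            {"id": f"{pop}_{i + 1}", "population": pop} for i in range(n)
        )
    genotypes = np.concatenate(geno_parts, axis=0)
    samples = pd.DataFrame(sample_rows)
    samples["sex"] = np.where(
        rng.random(len(samples)) < config.sex_ratio, "male", "female"
    )

    complete = genotypes.copy()
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = np.nan

    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].to_numpy()))
    dense = GenotypeMatrix(genotypes[:, order],
                           variants.iloc[order].reset_index(drop=True), samples)
    dense.complete_genotypes = complete[:, order]  # pre-missingness truth

    chip_idx = np.linspace(0, dense.n_variants - 1, config.n_variants_chip)
    chip_idx = np.unique(chip_idx.round().astype(int))
    chip = dense.take_variants(chip_idx)
    chip.complete_genotypes = dense.complete_genotypes[:, chip_idx]
    return dense, chip


# ---------------------------------------------------------------------------
# Phenotypes


def simulate_phenotypes(
    geno: GenotypeMatrix,
    config: SimConfig,
    class_assignments: pd.DataFrame | None = None,
):
    """Growth-trait phenotypes with known QTL architecture.

    Each trait receives an independent draw of ``n_qtl`` QTL with Gaussian
    effects; ``qtl_class_fraction`` of them are forced into ``qtl_class``
    when one is named.  The residual is orthogonalised against the genetic
    values and scaled so that the realised in-sample h2 equals the target.
    Also emits raw "measured" fields (weight, age, backfat, loin depth) so
    the endpoint-adjustment formulas can be exercised on simulated records.

    Returns ``(phenotypes, truth_qtl, truth_individuals)`` DataFrames.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    g_complete = getattr(geno, "complete_genotypes", None)
    dosages = g_complete if g_complete is not None else np.nan_to_num(
        geno.genotypes, nan=0.0
    )
    n, m = dosages.shape
    ids = geno.variant_ids()

    if config.qtl_class != "uniform":
        if class_assignments is None:
            raise ValueError(
                "class_assignments required when qtl_class is not 'uniform'"
            )
        cls = dict(zip(class_assignments["id"], class_assignments["classes"]))
        in_class = np.array(
            [config.qtl_class in cls.get(v, ()) for v in ids]
        )
        n_forced = int(round(config.n_qtl * config.qtl_class_fraction))
        if in_class.sum() < n_forced:
            raise ValueError(
                f"class {config.qtl_class!r} has {int(in_class.sum())} variants, "
                f"fewer than the {n_forced} QTL requested from it"
            )
    else:
        in_class = np.zeros(m, dtype=bool)
        n_forced = 0

    pheno = geno.samples[["id", "population", "sex"]].copy()
    # raw measurement fields for the endpoint-adjustment stage
    pheno["measured_weight_kg"] = np.round(rng.normal(105.0, 6.0, n), 1)
    pheno["measured_age_d"] = np.round(rng.normal(165.0, 9.0, n), 0)
    pheno["measured_bf_mm"] = np.round(np.maximum(rng.normal(11.0, 2.0, n), 4.0), 2)
    pheno["measured_lmd_mm"] = np.round(rng.normal(55.0, 3.5, n), 2)

    qtl_rows = []
    truth_ind = geno.samples[["id"]].copy()
    h2 = config.h2_target
    for trait in config.trait_set:
        forced_pool = np.flatnonzero(in_class)
        free_pool = np.flatnonzero(~in_class) if n_forced else np.arange(m)
        chosen = []
        if n_forced:
            chosen.extend(rng.choice(forced_pool, size=n_forced, replace=False))
        n_free = config.n_qtl - n_forced
        if n_free > 0:
            pool = np.setdiff1d(free_pool, chosen)
            chosen.extend(rng.choice(pool, size=n_free, replace=False))
        chosen = np.array(sorted(chosen))
        effects = rng.normal(0.0, np.sqrt(1.0 / config.n_qtl), size=len(chosen))
        g = dosages[:, chosen] @ effects
        g = g - g.mean()
        var_g = float(g.var())
        e = rng.normal(0.0, 1.0, size=n)
        if var_g > 0:
            e = e - e.mean() - (e @ g) / (g @ g) * g  # de-correlate in sample
        if h2 >= 1.0 - 1e-12:
            e = np.zeros(n)
            g_pheno = g
        elif h2 <= 0 or var_g == 0:
            e = (e - e.mean()) / e.std()
            g_pheno = np.zeros(n)  # no genetic contribution to the phenotype
        else:
            e *= np.sqrt(var_g * (1.0 - h2) / h2) / e.std()
            g_pheno = g
        # rescale to a realistic phenotypic SD; h2 and tbv-slope are unchanged
        raw_sd = float(np.std(g_pheno + e))
        scale = TRAIT_SDS.get(trait, 1.0) / raw_sd if raw_sd > 0 else 1.0
        g, g_pheno, e = g * scale, g_pheno * scale, e * scale
        y = TRAIT_BASELINES.get(trait, 0.0) + g_pheno + e
        pheno[trait] = y
        truth_ind[f"tbv_{trait}"] = g
        var_y = float(np.var(y))
        realized = float(g_pheno.var()) / var_y if var_y > 0 else 0.0
        for j, u in zip(chosen, effects):
            qtl_rows.append({"trait": trait, "id": ids[j], "effect": u * scale,
                             "realized_h2": realized})
    truth_qtl = pd.DataFrame(qtl_rows)
    return pheno, truth_qtl, truth_ind


# ---------------------------------------------------------------------------
# Orchestration


def simulate(config: SimConfig, class_assignments=None):
    """Run the full generator in memory.

    Returns a dict with keys ``reference, genes, dense, chip, phenotypes,
    truth_qtl, truth_individuals``.
    """
    reference, genes = simulate_genome(config)
    dense, chip = simulate_genotypes(config, reference)
    if config.qtl_class != "uniform" and class_assignments is None:
        from .annotate import classify_variants

        class_assignments = classify_variants(dense.variants, genes, reference)
    pheno, truth_qtl, truth_ind = simulate_phenotypes(
        dense, config, class_assignments
    )
    return {
        "reference": reference,
        "genes": genes,
        "dense": dense,
        "chip": chip,
        "phenotypes": pheno,
        "truth_qtl": truth_qtl,
        "truth_individuals": truth_ind,
    }


def simulate_to_dir(config: SimConfig, outdir) -> SimOutput:
    """Run the generator and write FASTA/GFF3/VCF/TSV artifacts to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate(config)
    ref_path = outdir / "reference.fa"
    with open(ref_path, "w") as fh:
        for chrom, seq in sim["reference"].items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    gff_path = outdir / "genes.gff3"
    write_gff3(sim["genes"], gff_path)
    dense_path = outdir / "genotypes_dense.vcf"
    chip_path = outdir / "genotypes_chip.vcf"
    sim["dense"].to_vcf(dense_path)
    sim["chip"].to_vcf(chip_path)
    pheno_path = outdir / "phenotypes.tsv"
    sim["phenotypes"].to_csv(pheno_path, sep="\t", index=False)
    qtl_path = outdir / "truth_qtl.tsv"
    sim["truth_qtl"].to_csv(qtl_path, sep="\t", index=False)
    ind_path = outdir / "truth_individuals.tsv"
    sim["truth_individuals"].to_csv(ind_path, sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        import json

        cfg = dataclasses.asdict(config)
        cfg["trait_set"] = list(cfg["trait_set"])
        json.dump(cfg, fh, indent=2)
    return SimOutput(
        reference=ref_path,
        genes=gff_path,
        genotypes_dense=dense_path,
        genotypes_chip=chip_path,
        phenotypes=pheno_path,
        truth_qtl=qtl_path,
        truth_individuals=ind_path,
    )
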