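"""Genotype container and VCF input/output.

Genotypes are held as an individuals x variants matrix of alternate-allele
dosages (0/1/2) with ``numpy.nan`` marking missing calls.  Variant metadata
(chrom, pos, ref, alt) and sample metadata (population, sex) travel with the
matrix so that downstream stages (QC, annotation, kinship) never have to
re-derive identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical variant identity: positions alone collide for multiallelics."""
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for a cohort.

    Attributes
    ----------
    genotypes : ndarray, shape (n_individuals, n_variants)
        Alternate-allele dosage, float, ``nan`` = missing.
    variants : DataFrame
        Columns ``chrom, pos, ref, alt, id`` (1-based positions).
    samples : DataFrame
        Columns ``id, population, sex``.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame = field(repr=False)
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        n_ind, n_var = self.genotypes.shape
        if len(self.samples) != n_ind:
            raise ValueError(
                f"sample table has {len(self.samples)} rows, matrix has {n_ind}"
            )
        if len(self.variants) != n_var:
            raise ValueError(
                f"variant table has {len(self.variants)} rows, matrix has {n_var}"
            )
        if "id" not in self.variants.columns:
            self.variants = self.variants.assign(
                id=[
                    variant_key(c, p, r, a)
                    for c, p, r, a in zip(
                        self.variants["chrom"],
                        self.variants["pos"],
                        self.variants["ref"],
                        self.variants["alt"],
                    )
                ]
            )

    # -- basic shape / summaries -------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant on non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.genotypes), axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.genotypes), axis=1)

    def variant_ids(self) -> list[str]:
        return list(self.variants["id"])

    # -- subsetting ---------------------------------------------------------

    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.genotypes[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            self.samples,
        )

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.genotypes[index, :],
            self.variants,
            self.samples.iloc[index].reset_index(drop=True),
        )

    def select_by_ids(self, ids) -> "GenotypeMatrix":
        """Subset variants by id, preserving the order of `ids`."""
        lookup = {v: i for i, v in enumerate(self.variants["id"])}
        missing = [v for v in ids if v not in lookup]
        if missing:
            raise KeyError(f"{len(missing)} variant ids absent, first: {missing[0]}")
        return self.take_variants([lookup[v] for v in ids])

    # -- VCF ----------------------------------------------------------------

    def to_vcf(self, path) -> None:
        """Write a minimal VCF v4.2 with GT-only genotype fields."""
        geno = self.genotypes
        codes = np.empty(geno.shape, dtype=object)
        codes[np.isnan(geno)] = "./."
        codes[geno == 0] = "0/0"
        codes[geno == 1] = "0/1"
        codes[geno == 2] = "1/1"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in pd.unique(self.variants["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(str(s) for s in self.samples["id"])
                + "\n"
            )
            var = self.variants
            for j in range(self.n_variants):
                row = var.iloc[j]
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                    f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(codes[:, j]) + "\n"
                )

    @classmethod
    def from_vcf(cls, path, samples: pd.DataFrame | None = None) -> "GenotypeMatrix":
        """Read diploid biallelic genotypes from a VCF via cyvcf2.

        `samples` may supply population/sex metadata keyed on ``id``;
        otherwise both default to "pop1" / "unknown".
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        ids = list(vcf.samples)
        rows, mats = [], []
        for rec in vcf:
            if len(rec.ALT) != 1:
                continue
            g = rec.gt_types.astype(float)  # 0,1,2, 3=unknown
            g[g == 3] = np.nan
            mats.append(g)
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": rec.ALT[0],
                    "id": rec.ID
                    if rec.ID not in (None, ".")
                    else variant_key(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]),
                }
            )
        geno = np.array(mats).T if mats else np.empty((len(ids), 0))
        variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "id"])
        if samples is None:
            samples = pd.DataFrame(
                {"id": ids, "population": "pop1", "sex": "unknown"}
            )
        else:
            samples = (
                pd.DataFrame({"id": ids}).merge(samples, on="id", how="left")
            )
        return cls(geno, variants, samples)
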