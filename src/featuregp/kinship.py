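"""Genomic relationship matrices, IBS similarity and LD decay summaries.

The additive GRM follows VanRaden's first method: columns of the genotype
matrix are centered by twice the observed alternate-allele frequency and the
cross-product is scaled by 2*sum(p_j*(1-p_j)), giving a matrix whose diagonal
averages about 1 in an unstructured sample.  Missing genotypes are imputed at
the frequency mean (2p) before centering, i.e. they contribute nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["GRM", "vanraden_grm", "ibs_matrix", "combine_grm", "ld_decay",
           "LdDecayTable"]


@dataclass
class GRM:
    """Symmetric individual x individual relationship matrix."""

    ids: list[str]
    matrix: np.ndarray = field(repr=False)
    n_markers: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} ids"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("GRM contains non-finite entries")
        asym = np.max(np.abs(self.matrix - self.matrix.T))
        if asym > 1e-10:
            raise ValueError(f"GRM asymmetric beyond tolerance ({asym:.2e})")

    def submatrix(self, ids) -> "GRM":
        idx = [self.ids.index(i) for i in ids]
        return GRM(list(ids), self.matrix[np.ix_(idx, idx)], self.n_markers,
                   self.source)

    def write_tsv(self, path) -> None:
        """Lower-triangle text form: id1, id2, n_markers, value."""
        with open(path, "w") as fh:
            fh.write("id1\tid2\tn_markers\tvalue\n")
            for i in range(len(self.ids)):
                for j in range(i + 1):
                    fh.write(
                        f"{self.ids[i]}\t{self.ids[j]}\t{self.n_markers}\t"
                        f"{self.matrix[i, j]:.10g}\n"
                    )

    @classmethod
    def read_tsv(cls, path, source: str = "") -> "GRM":
        df = pd.read_csv(path, sep="\t")
        ids = list(pd.unique(pd.concat([df["id1"], df["id2"]])))
        index = {s: k for k, s in enumerate(ids)}
        m = np.zeros((len(ids), len(ids)))
        for row in df.itertuples(index=False):
            i, j = index[row.id1], index[row.id2]
            m[i, j] = m[j, i] = row.value
        return cls(ids, m, int(df["n_markers"].iloc[0]) if len(df) else 0, source)


def _centered_dosage(geno: GenotypeMatrix):
    """Mean-imputed, 2p-centered dosage matrix Z and frequencies p."""
    g = geno.genotypes.astype(float).copy()
    p = geno.allele_freq()
    miss = np.isnan(g)
    if miss.any():
        g[miss] = np.broadcast_to(2.0 * p, g.shape)[miss]
    return g - 2.0 * p, p


def vanraden_grm(geno: GenotypeMatrix) -> GRM:
    """Additive GRM, VanRaden method 1: G = Z Z' / (2 sum p(1-p))."""
    if geno.n_individuals < 2:
        raise ValueError("GRM requires at least two individuals")
    z, p = _centered_dosage(geno)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all variants monomorphic: GRM denominator is zero")
    g = (z @ z.T) / denom
    g = (g + g.T) / 2.0  # enforce exact symmetry against rounding
    return GRM(list(geno.samples["id"].astype(str)), g, geno.n_variants,
               source="vanraden")


def ibs_matrix(geno: GenotypeMatrix) -> GRM:
    """Identity-by-state allele-sharing similarity.

    Entry (i,k) is the mean over shared non-missing variants of
    (2 - |g_i - g_k|)/2; the diagonal is 1 by definition.
    """
    g = geno.genotypes
    obs = (~np.isnan(g)).astype(float)
    gz = np.nan_to_num(g)
    # sum_j |g_i - g_k| over shared sites, via the identity
    # |a-b| expanded over dosage values 0/1/2 cannot be factored bilinearly,
    # so loop over the small set of dosage values instead.
    n = geno.n_individuals
    shared = obs @ obs.T
    dist = np.zeros((n, n))
    for a in (0.0, 1.0, 2.0):
        ia = ((gz == a) & (obs > 0)).astype(float)
        for b in (0.0, 1.0, 2.0):
            if a == b:
                continue
            ib = ((gz == b) & (obs > 0)).astype(float)
            dist += abs(a - b) * (ia @ ib.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (2.0 * shared - dist) / (2.0 * shared)
    if np.isnan(sim).any():
        logger.warning(
            "%d individual pairs share no non-missing variants; IBS undefined",
            int(np.isnan(sim).sum() // 2),
        )
    np.fill_diagonal(sim, 1.0)
    sim = (sim + sim.T) / 2.0
    return GRM(list(geno.samples["id"].astype(str)), sim, geno.n_variants,
               source="ibs")


def combine_grm(gf: GRM, gr: GRM, lam: float) -> GRM:
    """Collapse feature and remainder GRMs: G_total = lam*Gf + (1-lam)*Gr."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if gf.ids != gr.ids:
        first = next((a, b) for a, b in zip(gf.ids, gr.ids) if a != b)
        raise ValueError(f"GRM id mismatch, first differing pair: {first}")
    return GRM(
        list(gf.ids),
        lam * gf.matrix + (1.0 - lam) * gr.matrix,
        gf.n_markers + gr.n_markers,
        source=f"combined(lam={lam:.4g})",
    )


@dataclass
class LdDecayTable:
    bin_edges_bp: np.ndarray
    mean_r2: np.ndarray
    pair_count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_bp": self.bin_edges_bp[:-1],
                "bin_end_bp": self.bin_edges_bp[1:],
                "mean_r2": self.mean_r2,
                "pair_count": self.pair_count,
            }
        )


def ld_decay(
    geno: GenotypeMatrix, max_dist: int = 100_000, bin_width: int = 10_000
) -> LdDecayTable:
    """Mean genotype-dosage r^2 binned by intra-chromosomal distance.

    r^2 is the squared Pearson correlation of dosages (composite LD, the
    standard unphased surrogate).  Pairs involving a monomorphic variant are
    skipped and counted in the log.
    """
    edges = np.arange(0, max_dist + bin_width, bin_width)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    skipped = 0
    for chrom in pd.unique(geno.variants["chrom"]):
        idx = np.flatnonzero((geno.variants["chrom"] == chrom).to_numpy())
        pos = geno.variants["pos"].to_numpy()[idx]
        order = np.argsort(pos)
        idx, pos = idx[order], pos[order]
        g = geno.genotypes[:, idx]
        g = np.where(np.isnan(g), np.nanmean(g, axis=0), g)
        sd = g.std(axis=0)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d = pos[b] - pos[a]
                if d > max_dist:
                    break
                if sd[a] == 0 or sd[b] == 0:
                    skipped += 1
                    continue
                r = np.corrcoef(g[:, a], g[:, b])[0, 1]
                k = min(int(d // bin_width), len(sums) - 1)
                sums[k] += r * r
                counts[k] += 1
    if skipped:
        logger.info("ld_decay skipped %d monomorphic pairs", skipped)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdDecayTable(edges, mean, counts)
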