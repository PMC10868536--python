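"""Mixed-linear-model GWAS and FDR-rule preselection of trait-associated SNPs.

The association scan is the EMMAX approximation: the null variance
components (s2g, s2e) are estimated once by REML under y = mu + g + e with
var(g) = G s2g, then every variant is tested by generalised least squares
with the covariance V = G s2g + I s2e held fixed.  A single
eigendecomposition of G whitens the phenotype, the intercept, and every
genotype vector, so the per-variant test reduces to weighted simple
regression.

Preselection uses the proportional threshold rule p_thr = FDR * N / M, where
N is the number of variants with p < 0.05 and M the number tested.  This is
deliberately not Benjamini-Hochberg; a BH option exists for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import chi2

from .annotate import PanelSpec
from .genotypes import GenotypeMatrix
from .kinship import GRM
from .varcomp import VarianceComponents, reml_single

logger = logging.getLogger(__name__)

__all__ = ["GwasResult", "mlm_gwas", "fdr_threshold", "bh_threshold",
           "select_significant"]


@dataclass
class GwasResult:
    """Per-variant association results plus the null-model components."""

    table: pd.DataFrame = field(repr=False)  # chrom,pos,ref,alt,id,beta,se,wald,p,tested
    null_model: VarianceComponents | None = None
    n_individuals: int = 0

    def pvalues(self, tested_only: bool = True) -> np.ndarray:
        t = self.table
        return t.loc[t["tested"], "p"].to_numpy() if tested_only else t["p"].to_numpy()


def mlm_gwas(y_c, geno: GenotypeMatrix, G: GRM | np.ndarray) -> GwasResult:
    """Single-variant mixed-model scan (EMMAX approximation).

    Missing genotypes are mean-imputed for testing.  Monomorphic variants are
    flagged untested (beta, se, p = NaN) rather than dropped.
    """
    y = np.asarray(y_c, dtype=float)
    n = len(y)
    if geno.n_individuals != n:
        raise ValueError("phenotype and genotype sample sizes differ")
    Gm = G.matrix if isinstance(G, GRM) else np.asarray(G, dtype=float)

    null = reml_single(y, Gm)
    w, U = eigh(Gm)
    w = np.maximum(w, 0.0)
    d = null.sigma_g2 * w + null.sigma_e2
    sqrt_winv = 1.0 / np.sqrt(d)

    yt = (U.T @ y) * sqrt_winv
    onet = (U.T @ np.ones(n)) * sqrt_winv

    g = geno.genotypes.astype(float).copy()
    p_freq = geno.allele_freq()
    miss = np.isnan(g)
    if miss.any():
        g[miss] = np.broadcast_to(2.0 * p_freq, g.shape)[miss]
    mono = np.nanstd(geno.genotypes, axis=0) == 0
    xt = (U.T @ g) * sqrt_winv[:, None]

    # GLS with design [1, x] per variant, whitened -> ordinary least squares
    a11 = float(onet @ onet)
    a12 = onet @ xt
    a22 = np.einsum("ij,ij->j", xt, xt)
    b1 = float(onet @ yt)
    b2 = xt.T @ yt
    det = a11 * a22 - a12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a11 * b2 - a12 * b1) / det
        se = np.sqrt(a11 / det)
        wald = (beta / se) ** 2
        pvals = chi2.sf(wald, df=1)
    beta[mono] = se[mono] = wald[mono] = pvals[mono] = np.nan
    if mono.any():
        logger.info("mlm_gwas: %d monomorphic variants flagged untested",
                    int(mono.sum()))
    table = geno.variants[["chrom", "pos", "ref", "alt", "id"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["wald"] = wald
    table["p"] = pvals
    table["tested"] = ~mono
    return GwasResult(table=table, null_model=null, n_individuals=n)


def fdr_threshold(pvals, fdr: float = 0.05) -> float:
    """Proportional FDR threshold: fdr * N / M, N = #{p < 0.05}, M = #tested.

    When every variant has p < 0.05 the threshold equals the FDR itself;
    with no sub-0.05 p-values the threshold is 0 and nothing is selectable.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not 0.0 < fdr < 1.0:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    n_small = int(np.sum(p < 0.05))
    return fdr * n_small / p.size


def bh_threshold(pvals, fdr: float = 0.05) -> float:
    """Benjamini-Hochberg step-up threshold (comparison option, not default)."""
    p = np.sort(np.asarray(pvals, dtype=float))
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    thresh = fdr * np.arange(1, p.size + 1) / p.size
    passing = np.flatnonzero(p <= thresh)
    return float(p[passing[-1]]) if passing.size else 0.0


def select_significant(
    gwas: GwasResult, threshold: float, name: str = "gwas"
) -> PanelSpec:
    """Panel of tested variants with p < threshold, sorted by (chrom, pos)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    t = gwas.table
    hits = t[t["tested"] & (t["p"] < threshold)].sort_values(["chrom", "pos"])
    return PanelSpec(
        name=name,
        variant_ids=list(hits["id"]),
        provenance={"threshold": threshold, "n_tested": int(t["tested"].sum())},
    )
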