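"""Genotype quality control: call-rate, MAF, Hardy-Weinberg and autosome filters.

Thresholds follow common chip-QC practice: individual call rate > 0.90,
variant call rate > 0.90, MAF > 0.05, HWE exact p > 1e-6, autosomes only.
All inequalities are strict; a variant sitting exactly on a threshold fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QcThresholds",
    "hwe_exact_test",
    "filter_individuals",
    "filter_variants",
]


@dataclass(frozen=True)
class QcThresholds:
    min_individual_call_rate: float = 0.90
    min_variant_call_rate: float = 0.90
    min_maf: float = 0.05
    min_hwe_p: float = 1e-6
    autosomes_only: bool = True
    #: "per_population" computes the HWE test within each population and
    #: removes a variant failing in any of them; "pooled" tests all samples.
    hwe_mode: str = "per_population"

    def __post_init__(self) -> None:
        for name in ("min_individual_call_rate", "min_variant_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value from genotype counts.

    Conditions on the allele counts and sums the probabilities of every
    heterozygote count whose null probability does not exceed that of the
    observed count.  The null distribution is evaluated by the standard
    heterozygote-count recurrence (numerically stable, no factorials).
    Monomorphic variants have a single attainable outcome, so p = 1.
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa_hom + n_het + n_bb_hom
    if n == 0:
        raise ValueError("all genotypes missing: HWE test undefined")

    n_rare = 2 * min(n_aa_hom, n_bb_hom) + n_het
    # attainable heterozygote counts share the parity of the rare-allele count
    het_probs = np.zeros(n_rare + 1)
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    het_probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h*(h-1) / (4*(hom_r+1)*(hom_c+1))
    hom_r = (n_rare - mid) // 2
    hom_c = n - mid - hom_r
    h, hr, hc = mid, hom_r, hom_c
    while h > 1:
        het_probs[h - 2] = het_probs[h] * h * (h - 1) / (4.0 * (hr + 1) * (hc + 1))
        h, hr, hc = h - 2, hr + 1, hc + 1
    # upward recurrence: P(h+2)/P(h) = 4*hom_r*hom_c / ((h+2)*(h+1))
    h, hr, hc = mid, hom_r, hom_c
    while h <= n_rare - 2:
        het_probs[h + 2] = het_probs[h] * 4.0 * hr * hc / ((h + 2) * (h + 1))
        h, hr, hc = h + 2, hr - 1, hc - 1
    total = het_probs.sum()
    p_obs = het_probs[n_het] / total
    return float(min(1.0, het_probs[het_probs / total <= p_obs + 1e-12].sum() / total))


def _is_autosome(chrom: str) -> bool:
    c = str(chrom).removeprefix("chr")
    return c.isdigit()


def filter_individuals(
    geno: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> GenotypeMatrix:
    """Drop individuals whose genotype call rate is not above the threshold."""
    keep = geno.individual_call_rate() > thresholds.min_individual_call_rate
    if not keep.any():
        raise ValueError("no individuals pass the call-rate filter")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("individual call-rate filter removed %d individuals", n_drop)
    return geno.take_individuals(keep)


def _hwe_pvals(geno: GenotypeMatrix, mode: str) -> np.ndarray:
    """Per-variant HWE p; under per-population mode, the minimum across pops."""
    groups: list[np.ndarray]
    if mode == "per_population":
        groups = [
            (geno.samples["population"] == pop).to_numpy()
            for pop in pd.unique(geno.samples["population"])
        ]
    elif mode == "pooled":
        groups = [np.ones(geno.n_individuals, dtype=bool)]
    else:
        raise ValueError(f"unknown hwe_mode {mode!r}")
    pvals = np.ones(geno.n_variants)
    for rows in groups:
        g = geno.genotypes[rows]
        n0 = np.nansum(g == 0, axis=0)
        n1 = np.nansum(g == 1, axis=0)
        n2 = np.nansum(g == 2, axis=0)
        for j in range(geno.n_variants):
            tot = n0[j] + n1[j] + n2[j]
            if tot == 0:
                continue
            pvals[j] = min(pvals[j], hwe_exact_test(int(n0[j]), int(n1[j]), int(n2[j])))
    return pvals


def filter_variants(
    geno: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    report: bool = False,
):
    """Apply autosome, call-rate, MAF and HWE filters to variants.

    Returns the filtered :class:`GenotypeMatrix`; with ``report=True`` also a
    per-variant DataFrame of filter outcomes (id, call_rate, maf, hwe_p and
    pass flags).  Order of variants is preserved; the operation is idempotent.
    """
    auto_ok = (
        np.array([_is_autosome(c) for c in geno.variants["chrom"]])
        if thresholds.autosomes_only
        else np.ones(geno.n_variants, dtype=bool)
    )
    call = geno.variant_call_rate()
    maf = geno.maf()
    all_missing = np.isnan(maf)
    hwe_p = _hwe_pvals(geno, thresholds.hwe_mode)

    call_ok = call > thresholds.min_variant_call_rate
    maf_ok = ~all_missing & (maf > thresholds.min_maf)
    hwe_ok = hwe_p > thresholds.min_hwe_p
    keep = auto_ok & call_ok & maf_ok & hwe_ok

    logger.info(
        "variant QC: %d/%d retained (autosome fail %d, call-rate fail %d, "
        "MAF fail %d, HWE fail %d)",
        int(keep.sum()),
        geno.n_variants,
        int((~auto_ok).sum()),
        int((~call_ok).sum()),
        int((~maf_ok).sum()),
        int((~hwe_ok).sum()),
    )
    if not keep.any():
        raise ValueError("no variants pass QC")
    filtered = geno.take_variants(keep)
    if report:
        rep = pd.DataFrame(
            {
                "id": geno.variants["id"],
                "call_rate": call,
                "maf": maf,
                "hwe_p": hwe_p,
                "autosome_pass": auto_ok,
                "call_rate_pass": call_ok,
                "maf_pass": maf_ok,
                "hwe_pass": hwe_ok,
                "pass": keep,
            }
        )
        return filtered, rep
    return filtered
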