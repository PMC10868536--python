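"""Positional variant-consequence classification and class-panel construction.

Variants are classified against strand-aware gene models into the positional
classes used as genomic features: intergenic, intron, upstream / downstream
(5 kb flanks), 5'/3' UTR, noncoding exon, and for coding SNVs synonymous vs
missense decided by translating the affected codon for the reference and
alternate alleles.  A variant overlapping several genes carries every label
it earns, so class panels may share variants (cumulative class proportions
can exceed 100%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

FLANK_BP = 5_000  # upstream/downstream window

CLASS_LABELS = (
    "intergenic",
    "intron",
    "upstream",
    "downstream",
    "three_prime_utr",
    "five_prime_utr",
    "synonymous",
    "missense",
    "noncoding_exon",
)

__all__ = [
    "GeneModel",
    "PanelSpec",
    "classify_variant",
    "classify_variants",
    "build_class_panels",
    "intersect_panels",
    "deduplicate_against_base",
    "read_gff3",
    "write_gff3",
    "load_reference",
]


@dataclass
class GeneModel:
    """One protein-coding gene with a single transcript.

    All intervals are 1-based inclusive (GFF3 convention).  ``cds`` intervals
    are in genomic order; for minus-strand genes the coding sequence is the
    reverse complement of their concatenation in reverse order.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt[0] <= prev[1]:
                raise ValueError(f"{self.gene_id}: overlapping exons {prev}, {nxt}")
        cds_len = sum(e - s + 1 for s, e in self.cds)
        if self.cds and cds_len % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {cds_len} not divisible by 3")

    def coding_sequence(self, reference: dict[str, str]) -> str:
        seq = "".join(reference[self.chrom][s - 1 : e] for s, e in self.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def coding_index(self, pos: int) -> int | None:
        """0-based index of a genomic position within the coding sequence."""
        offset = 0
        for s, e in self.cds:
            if s <= pos <= e:
                idx = offset + (pos - s)
                if self.strand == "-":
                    total = sum(b - a + 1 for a, b in self.cds)
                    idx = total - 1 - idx
                return idx
            offset += e - s + 1
        return None


def _in_any(pos: int, intervals) -> bool:
    return any(s <= pos <= e for s, e in intervals)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def classify_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene_models: list[GeneModel],
    reference: dict[str, str] | None = None,
) -> set[str]:
    """Return the set of class labels for one variant.

    Coding synonymous/missense is decided only for SNVs with a reference
    sequence available; coding INDELs (and coding SNVs whose stated ref
    allele disagrees with the reference sequence) fall back to the positional
    exon label.
    """
    labels: set[str] = set()
    is_snv = len(ref) == 1 and len(alt) == 1
    for gene in gene_models:
        if gene.chrom != chrom:
            continue
        if gene.start <= pos <= gene.end:
            if _in_any(pos, gene.utr5):
                labels.add("five_prime_utr")
            elif _in_any(pos, gene.utr3):
                labels.add("three_prime_utr")
            elif _in_any(pos, gene.cds):
                label = None
                if is_snv and reference is not None:
                    label = _coding_effect(gene, chrom, pos, ref, alt, reference)
                labels.add(label if label else "noncoding_exon")
            elif _in_any(pos, gene.exons):
                labels.add("noncoding_exon")
            else:
                labels.add("intron")
        else:
            # strand-aware 5 kb flanks
            if gene.strand == "+":
                up = gene.start - FLANK_BP <= pos < gene.start
                down = gene.end < pos <= gene.end + FLANK_BP
            else:
                up = gene.end < pos <= gene.end + FLANK_BP
                down = gene.start - FLANK_BP <= pos < gene.start
            if up:
                labels.add("upstream")
            if down:
                labels.add("downstream")
    if not labels:
        labels.add("intergenic")
    return labels


def _coding_effect(gene, chrom, pos, ref, alt, reference) -> str | None:
    genomic_base = reference[chrom][pos - 1].upper()
    if genomic_base != ref.upper():
        logger.warning(
            "variant %s:%d ref %s disagrees with reference base %s; "
            "classified by position only",
            chrom,
            pos,
            ref,
            genomic_base,
        )
        return None
    idx = gene.coding_index(pos)
    if idx is None:
        return None
    cds_seq = gene.coding_sequence(reference)
    codon_start = (idx // 3) * 3
    codon_ref = cds_seq[codon_start : codon_start + 3]
    alt_base = alt.upper()
    if gene.strand == "-":
        alt_base = alt_base.translate(_COMPLEMENT)
    within = idx - codon_start
    codon_alt = codon_ref[:within] + alt_base + codon_ref[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    return "synonymous" if aa_ref == aa_alt else "missense"


def classify_variants(
    variants: pd.DataFrame,
    gene_models: list[GeneModel],
    reference: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Classify a variant table; returns columns ``id`` and ``classes``.

    ``classes`` holds a frozenset of labels per variant.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for row in variants.itertuples(index=False):
        labels = classify_variant(
            row.chrom,
            int(row.pos),
            row.ref,
            row.alt,
            by_chrom.get(row.chrom, []),
            reference,
        )
        out.append(frozenset(labels))
    return pd.DataFrame({"id": variants["id"], "classes": out})


# ---------------------------------------------------------------------------
# Panels


@dataclass
class PanelSpec:
    """An ordered, duplicate-free list of variant ids with provenance."""

    name: str
    variant_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError(f"panel {self.name}: duplicate variant ids")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.variant_ids) + ("\n" if self.variant_ids else ""))

    @classmethod
    def read(cls, path, name: str | None = None) -> "PanelSpec":
        with open(path) as fh:
            ids = [line.strip() for line in fh if line.strip()]
        return cls(name or str(path), ids, {"source": str(path)})


def build_class_panels(
    assignments: pd.DataFrame,
    classes: list[str],
    target_size: int | str = "min",
    seed: int = 0,
) -> dict[str, PanelSpec]:
    """Equal-size random panels, one per genomic class.

    Controlling panel size removes marker count as a confounder when class
    panels are compared as prediction features.  ``target_size="min"`` uses
    the smallest requested class; an explicit size larger than some class is
    an error naming that class.  Sampling is uniform without replacement and
    reproducible under ``seed``.
    """
    members = {
        c: [i for i, cl in zip(assignments["id"], assignments["classes"]) if c in cl]
        for c in classes
    }
    sizes = {c: len(v) for c, v in members.items()}
    if target_size == "min":
        size = min(sizes.values())
    else:
        size = int(target_size)
        for c, n in sizes.items():
            if n < size:
                raise ValueError(
                    f"class {c!r} has {n} variants, fewer than target_size={size}"
                )
    rng = np.random.default_rng(seed)
    panels = {}
    for c in classes:
        ids = members[c]
        take = sorted(rng.choice(len(ids), size=size, replace=False))
        panels[c] = PanelSpec(
            name=c,
            variant_ids=[ids[i] for i in take],
            provenance={"class": c, "seed": seed, "target_size": size},
        )
    return panels


def intersect_panels(panel: PanelSpec, available_variants) -> PanelSpec:
    """Restrict a panel to the variants available in another dataset.

    Keeps panel order.  An empty intersection is an error: the feature
    genomic component would be undefined.
    """
    avail = set(available_variants)
    kept = [v for v in panel.variant_ids if v in avail]
    if not kept:
        raise ValueError(f"panel {panel.name!r} shares no variants with the dataset")
    return PanelSpec(
        name=panel.name,
        variant_ids=kept,
        provenance={**panel.provenance, "intersected": True},
    )


def deduplicate_against_base(panel: PanelSpec, base_variants) -> PanelSpec:
    """Remove panel variants also present in the base (remainder) component."""
    base = set(base_variants)
    return PanelSpec(
        name=panel.name,
        variant_ids=[v for v in panel.variant_ids if v not in base],
        provenance={**panel.provenance, "deduplicated": True},
    )


# ---------------------------------------------------------------------------
# GFF3 / FASTA plumbing


def write_gff3(genes: list[GeneModel], path) -> None:
    def feat(chrom, src, type_, s, e, strand, phase, attrs):
        return f"{chrom}\t{src}\t{type_}\t{s}\t{e}\t.\t{strand}\t{phase}\t{attrs}\n"

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                feat(g.chrom, "sim", "gene", g.start, g.end, g.strand, ".",
                     f"ID={g.gene_id}")
            )
            fh.write(
                feat(g.chrom, "sim", "mRNA", g.start, g.end, g.strand, ".",
                     f"ID={mrna_id};Parent={g.gene_id}")
            )
            for s, e in g.exons:
                fh.write(
                    feat(g.chrom, "sim", "exon", s, e, g.strand, ".",
                         f"Parent={mrna_id}")
                )
            # CDS phase: bases to skip before the first complete codon
            cds = g.cds if g.strand == "+" else list(reversed(g.cds))
            done = 0
            for s, e in cds:
                phase = (3 - done % 3) % 3
                fh.write(
                    feat(g.chrom, "sim", "CDS", s, e, g.strand, phase,
                         f"Parent={mrna_id}")
                )
                done += e - s + 1
            for s, e in g.utr5:
                fh.write(
                    feat(g.chrom, "sim", "five_prime_UTR", s, e, g.strand, ".",
                         f"Parent={mrna_id}")
                )
            for s, e in g.utr3:
                fh.write(
                    feat(g.chrom, "sim", "three_prime_UTR", s, e, g.strand, ".",
                         f"Parent={mrna_id}")
                )


def read_gff3(path) -> list[GeneModel]:
    """Assemble one-transcript gene models from a GFF3 file."""
    cols = ["chrom", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    try:
        df = pd.read_csv(path, sep="\t", comment="#", names=cols, header=None)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []

    def attr(s: str, key: str) -> str | None:
        for part in s.split(";"):
            k, _, v = part.partition("=")
            if k == key:
                return v
        return None

    genes: dict[str, GeneModel] = {}
    mrna_to_gene: dict[str, str] = {}
    for row in df.itertuples(index=False):
        kind = row.type
        if kind == "gene":
            gid = attr(row.attributes, "ID")
            genes[gid] = GeneModel(
                gene_id=gid, chrom=str(row.chrom), strand=row.strand,
                start=int(row.start), end=int(row.end),
            )
        elif kind == "mRNA":
            mrna_to_gene[attr(row.attributes, "ID")] = attr(row.attributes, "Parent")
    for row in df.itertuples(index=False):
        kind = row.type
        if kind in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
            gid = mrna_to_gene.get(attr(row.attributes, "Parent"))
            if gid is None:
                continue
            iv = (int(row.start), int(row.end))
            g = genes[gid]
            {"exon": g.exons, "CDS": g.cds,
             "five_prime_UTR": g.utr5, "three_prime_UTR": g.utr3}[kind].append(iv)
    out = []
    for g in genes.values():
        # re-validate interval structure after assembly
        out.append(GeneModel(g.gene_id, g.chrom, g.strand, g.start, g.end,
                             g.exons, g.cds, g.utr5, g.utr3))
    return sorted(out, key=lambda g: (g.chrom, g.start))


def load_reference(path) -> dict[str, str]:
    """Load a FASTA reference as a chrom -> sequence dict."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}
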