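import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from featuregp.annotate import (
    GeneModel,
    PanelSpec,
    build_class_panels,
    classify_variant,
    classify_variants,
    deduplicate_against_base,
    intersect_panels,
    read_gff3,
    write_gff3,
)


@pytest.fixture
def toy_gene():
    """Plus-strand gene at 10001..12000: UTR5, CDS over two exons, UTR3."""
    return GeneModel(
        gene_id="g1",
        chrom="1",
        strand="+",
        start=10_001,
        end=12_000,
        exons=[(10_001, 10_500), (11_001, 12_000)],
        cds=[(10_201, 10_500), (11_001, 11_699)],  # 300 + 699 = 999 bp
        utr5=[(10_001, 10_200)],
        utr3=[(11_700, 12_000)],
    )


class TestClassifyVariant:
    def test_upstream_by_construction(self, toy_gene):
        assert classify_variant("1", 7_001, "A", "C", [toy_gene]) == {"upstream"}

    def test_downstream(self, toy_gene):
        assert classify_variant("1", 13_000, "A", "C", [toy_gene]) == {"downstream"}

    def test_intron(self, toy_gene):
        assert classify_variant("1", 10_700, "A", "C", [toy_gene]) == {"intron"}

    def test_utrs(self, toy_gene):
        assert classify_variant("1", 10_100, "A", "C", [toy_gene]) == {
            "five_prime_utr"
        }
        assert classify_variant("1", 11_800, "A", "C", [toy_gene]) == {
            "three_prime_utr"
        }

    def test_intergenic_default(self, toy_gene):
        assert classify_variant("1", 500, "A", "C", [toy_gene]) == {"intergenic"}
        assert classify_variant("2", 10_100, "A", "C", [toy_gene]) == {"intergenic"}

    def test_strand_mirror_swaps_flanks(self):
        plus = GeneModel("p", "1", "+", 20_000, 22_000, exons=[(20_000, 22_000)])
        minus = GeneModel("m", "1", "-", 20_000, 22_000, exons=[(20_000, 22_000)])
        before, after = 18_000, 23_500
        assert classify_variant("1", before, "A", "C", [plus]) == {"upstream"}
        assert classify_variant("1", before, "A", "C", [minus]) == {"downstream"}
        assert classify_variant("1", after, "A", "C", [plus]) == {"downstream"}
        assert classify_variant("1", after, "A", "C", [minus]) == {"upstream"}

    def test_synonymous_third_position(self):
        # CDS = ATG GGA TAA; GGA->GGG is Gly->Gly
        seq = "A" * 100 + "ATGGGATAA" + "A" * 100
        gene = GeneModel(
            "g", "1", "+", 101, 109,
            exons=[(101, 109)], cds=[(101, 109)],
        )
        ref = {"1": seq}
        assert classify_variant("1", 106, "A", "G", [gene], ref) == {"synonymous"}
        # GGA->GAA is Gly->Glu
        assert classify_variant("1", 105, "G", "A", [gene], ref) == {"missense"}

    def test_coding_indel_positional_only(self):
        seq = "A" * 100 + "ATGGGATAA" + "A" * 100
        gene = GeneModel("g", "1", "+", 101, 109, exons=[(101, 109)],
                         cds=[(101, 109)])
        labels = classify_variant("1", 105, "GA", "G", [gene], {"1": seq})
        assert labels == {"noncoding_exon"}

    def test_ref_mismatch_falls_back_to_position(self, caplog):
        seq = "A" * 100 + "ATGGGATAA" + "A" * 100
        gene = GeneModel("g", "1", "+", 101, 109, exons=[(101, 109)],
                         cds=[(101, 109)])
        labels = classify_variant("1", 106, "C", "G", [gene], {"1": seq})
        assert labels == {"noncoding_exon"}


def test_minus_strand_coding_effect_matches_full_translation(small_sim):
    """Oracle: mutate the genome, re-extract and translate the whole CDS with
    Biopython, and compare the protein to the reference protein."""
    cfg, sim = small_sim
    ref = sim["reference"]
    rng = np.random.default_rng(5)
    checked = 0
    for gene in sim["genes"]:
        if gene.strand != "-":
            continue
        for s, e in gene.cds:
            for pos in rng.integers(s, e + 1, size=4):
                pos = int(pos)
                base = ref[gene.chrom][pos - 1]
                alt = rng.choice([b for b in "ACGT" if b != base])
                got = classify_variant(gene.chrom, pos, base, alt, [gene], ref)
                mutated = dict(ref)
                chrom_seq = list(ref[gene.chrom])
                chrom_seq[pos - 1] = alt
                mutated[gene.chrom] = "".join(chrom_seq)
                prot_ref = Seq(gene.coding_sequence(ref)).translate()
                prot_alt = Seq(gene.coding_sequence(mutated)).translate()
                expected = "synonymous" if prot_ref == prot_alt else "missense"
                assert got == {expected}, (gene.gene_id, pos, base, alt)
                checked += 1
        if checked >= 12:
            break
    assert checked > 0


def test_every_variant_gets_a_label(small_sim):
    cfg, sim = small_sim
    result = classify_variants(
        sim["dense"].variants, sim["genes"], sim["reference"]
    )
    assert all(len(c) >= 1 for c in result["classes"])
    # simulated geometry: intron + intergenic dominate
    frac = np.mean(
        [bool(c & {"intron", "intergenic"}) for c in result["classes"]]
    )
    assert frac > 0.6


class TestBuildClassPanels:
    @pytest.fixture
    def assignments(self):
        rng = np.random.default_rng(0)
        ids = [f"v{i}" for i in range(200)]
        classes = [
            frozenset(["intron"]) if i < 100
            else frozenset(["intergenic"]) if i < 180
            else frozenset(["intron", "upstream"])
            for i in range(200)
        ]
        return pd.DataFrame({"id": ids, "classes": classes})

    def test_min_rule(self, assignments):
        panels = build_class_panels(assignments, ["intron", "intergenic"], "min", 1)
        assert len(panels["intron"]) == len(panels["intergenic"]) == 80

    def test_deterministic_under_seed(self, assignments):
        a = build_class_panels(assignments, ["intron"], 50, seed=7)
        b = build_class_panels(assignments, ["intron"], 50, seed=7)
        c = build_class_panels(assignments, ["intron"], 50, seed=8)
        assert a["intron"].variant_ids == b["intron"].variant_ids
        assert a["intron"].variant_ids != c["intron"].variant_ids

    def test_membership_purity(self, assignments):
        panels = build_class_panels(
            assignments, ["intron", "upstream"], "min", seed=3
        )
        lookup = dict(zip(assignments["id"], assignments["classes"]))
        for cls, panel in panels.items():
            assert all(cls in lookup[v] for v in panel.variant_ids)

    def test_oversized_target_names_class(self, assignments):
        with pytest.raises(ValueError, match="upstream"):
            build_class_panels(assignments, ["intron", "upstream"], 50, 1)


class TestPanelSetOps:
    def test_intersect_subset_is_identity(self):
        p = PanelSpec("p", ["a", "b", "c"])
        assert intersect_panels(p, ["c", "b", "a", "z"]).variant_ids == [
            "a", "b", "c"
        ]

    def test_intersect_disjoint_raises(self):
        with pytest.raises(ValueError):
            intersect_panels(PanelSpec("p", ["a"]), ["b"])

    def test_intersect_half_overlap_keeps_order(self):
        p = PanelSpec("p", [f"v{i}" for i in range(10)])
        avail = [f"v{i}" for i in range(0, 10, 2)] + ["x"]
        assert intersect_panels(p, avail).variant_ids == [
            "v0", "v2", "v4", "v6", "v8"
        ]

    def test_dedup_disjoint_identity(self):
        p = PanelSpec("p", ["a", "b"])
        assert deduplicate_against_base(p, ["c"]).variant_ids == ["a", "b"]

    def test_dedup_subset_empties(self):
        p = PanelSpec("p", ["a", "b"])
        assert deduplicate_against_base(p, ["a", "b", "c"]).variant_ids == []

    def test_dedup_mixed(self):
        p = PanelSpec("p", ["a", "b", "c", "d"])
        assert deduplicate_against_base(p, ["b", "d"]).variant_ids == ["a", "c"]


def test_gff3_roundtrip(tmp_path, small_sim):
    cfg, sim = small_sim
    path = tmp_path / "genes.gff3"
    write_gff3(sim["genes"], path)
    back = read_gff3(path)
    assert len(back) == len(sim["genes"])
    orig = {g.gene_id: g for g in sim["genes"]}
    for g in back:
        o = orig[g.gene_id]
        assert (g.strand, g.start, g.end) == (o.strand, o.start, o.end)
        assert g.exons == o.exons and g.cds == o.cds
        assert g.utr5 == o.utr5 and g.utr3 == o.utr3


def test_empty_gff3_file_roundtrip(tmp_path):
    path = tmp_path / "empty.gff3"
    write_gff3([], path)
    assert read_gff3(path) == []


def test_empty_gene_set_classifies_all_intergenic():
    variants = pd.DataFrame(
        {"chrom": "1", "pos": [10, 20], "ref": "A", "alt": "C",
         "id": ["a", "b"]}
    )
    out = classify_variants(variants, [], None)
    assert all(c == {"intergenic"} for c in out["classes"])
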