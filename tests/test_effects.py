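"""Genic location, spliced-CDS coordinates and codon-level consequences."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from conftest import make_single_cds_gene, revcomp
from pooldiff.effects import (
    GeneModel,
    GeneModelIndex,
    aggregate_by_gene,
    annotate_effects,
    cds_coordinate,
    consequence,
    load_gene_models,
    locate,
)


def _two_exon_gene(strand: str) -> tuple[GeneModel, dict[str, str]]:
    """utr5(6) + CDS(12, two exons split 7/5 with a 10 bp intron) + utr3(6)."""
    utr5, utr3 = "TTTTTT", "GGGGGG"
    cds = "ATG" + "CCT" + "GAA" + "TAA"  # M P E *
    intron = "GTAAGCATAG"
    tx = utr5 + cds + utr3
    # exon1 = utr5 + first 7 CDS bases; exon2 = remaining 5 CDS + utr3
    exon1 = tx[:13]
    exon2 = tx[13:]
    local = exon1 + intron + exon2
    flank = "CACAC"
    body = local if strand == "+" else revcomp(local)
    seq = flank + body + flank
    off = len(flank)
    span = len(local)

    def g(a, b):  # local -> genomic 0-based half-open
        if strand == "+":
            return (off + a, off + b)
        return (off + span - b, off + span - a)

    exons = sorted([g(0, 13), g(23, 23 + len(exon2))])
    utr5_iv = [g(0, 6)] if strand == "+" else [g(0, 6)]
    cds_iv = sorted([g(6, 13), g(23, 28)])
    utr3_iv = [g(28, 34)]
    model = GeneModel("gX", "chrT", strand, exons=exons, cds=cds_iv,
                      utr5=sorted(utr5_iv), utr3=sorted(utr3_iv))
    return model, {"chrT": seq}


# -------------------------------------------------------------------- locate

def test_locate_regions_within_gene():
    model, contigs = _two_exon_gene("+")
    idx = GeneModelIndex([model])
    # genomic position of the first utr5 base
    a, _ = model.utr5[0]
    assert locate("chrT", a + 1, idx) == ("gX", "five_prime_UTR")
    c0, _ = sorted(model.cds)[0]
    assert locate("chrT", c0 + 1, idx) == ("gX", "CDS")
    u3, _ = model.utr3[0]
    assert locate("chrT", u3 + 1, idx) == ("gX", "three_prime_UTR")
    # intron: between exon1 end and exon2 start
    exons = sorted(model.exons)
    intron_pos = exons[0][1] + 2
    assert locate("chrT", intron_pos + 1, idx) == ("gX", "intron")


def test_locate_far_intergenic_and_near_gene():
    model = GeneModel("gX", "chrT", "+", exons=[(5000, 6000)], cds=[(5000, 6000)])
    idx = GeneModelIndex([model])
    assert locate("chrT", 6500, idx, flank=1000) == ("gX", "other")
    assert locate("chrT", 20_000, idx, flank=1000) == (None, "other")


def test_locate_unknown_contig_raises():
    idx = GeneModelIndex([])
    with pytest.raises(ValueError, match="unknown contig"):
        locate("nope", 1, idx, known_contigs={"chrT"})


def test_locate_matches_generator_truth(power_bundle):
    truth = power_bundle["truth_variants"]
    effects = power_bundle["effects"]
    merged = effects.drop_duplicates(["contig", "pos"]).merge(
        truth, on=["contig", "pos"])
    class_map = {"intronic": "other", "intergenic": "other"}
    expected = merged["true_class"].replace(class_map)
    assert (merged["effect"] == expected).all()
    genic = merged[merged["true_class"].isin(
        ["five_prime_UTR", "synonymous", "non_synonymous", "three_prime_UTR"])]
    assert (genic["gene_id_x"] == genic["gene_id_y"]).all()


# ------------------------------------------------------------ cds coordinates

def test_cds_coordinate_maps_2539_to_codon_847():
    cds = "ATG" + "AAA" * 845 + "GCT" + "TAA"  # codon 847 is GCT
    model, contigs = make_single_cds_gene(cds, "+")
    a, _ = model.cds[0]
    pos1 = a + 2538 + 1  # spliced CDS position 2539
    assert cds_coordinate(pos1, model) == 2539
    out = consequence("chrT", pos1, "G", "T", model, contigs)
    assert out["codon_index"] == 847


@pytest.mark.parametrize("cds_pos,codon", [(1, 1), (3, 1), (4, 2)])
def test_codon_index_boundaries(cds_pos, codon):
    cds = "ATG" + "CCT" * 5 + "TAA"
    model, _ = make_single_cds_gene(cds, "+")
    a, _ = model.cds[0]
    pos1 = a + cds_pos
    assert cds_coordinate(pos1, model) == cds_pos
    assert (cds_coordinate(pos1, model) - 1) // 3 + 1 == codon


def test_cds_coordinate_minus_strand_counts_from_three_prime_end():
    cds = "ATGCCTGAATAA"
    model, contigs = make_single_cds_gene(cds, "-")
    a, b = model.cds[0]
    # the genomic base at b-1 is the complement of the first CDS base
    assert cds_coordinate(b, model) == 1
    assert cds_coordinate(a + 1, model) == len(cds)
    assert contigs["chrT"][b - 1] == "T"  # complement of leading A


def test_cds_coordinate_outside_cds_raises():
    model, _ = make_single_cds_gene("ATGCCTTAA", "+")
    with pytest.raises(ValueError, match="not inside"):
        cds_coordinate(1, model)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_cds_coordinate_roundtrip(strand):
    """Every spliced CDS position maps to exactly one genomic base and back."""
    model, _ = _two_exon_gene(strand)
    seen = {}
    for a, b in model.cds:
        for pos0 in range(a, b):
            seen[cds_coordinate(pos0 + 1, model)] = pos0
    n = sum(b - a for a, b in model.cds)
    assert sorted(seen) == list(range(1, n + 1))


# ---------------------------------------------------------------- consequence

def test_ala_to_ser_non_synonymous_label():
    """A C->A substitution on the genome strand of a minus-strand gene hits
    the first base of codon 847 (GCT) giving TCT: label A847S."""
    cds = "ATG" + "AAA" * 845 + "GCT" + "TAA"
    model, contigs = make_single_cds_gene(cds, "-")
    a, b = model.cds[0]
    pos1 = (b - 1 - 2538) + 1  # genomic base of spliced CDS position 2539
    assert contigs["chrT"][pos1 - 1] == "C"
    out = consequence("chrT", pos1, "C", "A", model, contigs)
    assert out["effect"] == "non_synonymous"
    assert out["cds_pos"] == 2539
    assert out["label"] == "A847S"
    assert (out["ref_aa"], out["alt_aa"]) == ("A", "S")


def test_third_position_leucine_change_synonymous():
    cds = "ATG" + "TTA" + "TAA"  # M L *
    model, contigs = make_single_cds_gene(cds, "+")
    a, _ = model.cds[0]
    pos1 = a + 6  # third base of TTA
    out = consequence("chrT", pos1, "A", "G", model, contigs)  # TTA -> TTG
    assert out["effect"] == "synonymous"
    assert out["ref_aa"] == out["alt_aa"] == "L"


def test_stop_gain_labelled_non_synonymous_star():
    cds = "ATG" + "TCA" + "TAA"  # Ser codon; T C A -> T G A is a stop
    model, contigs = make_single_cds_gene(cds, "+")
    a, _ = model.cds[0]
    out = consequence("chrT", a + 5, "C", "G", model, contigs)
    assert out["effect"] == "non_synonymous"
    assert out["alt_aa"] == "*"
    assert out["label"] == "S2*"


def test_reference_mismatch_detected():
    model, contigs = make_single_cds_gene("ATGCCTTAA", "+")
    a, _ = model.cds[0]
    with pytest.raises(ValueError, match="reference mismatch"):
        consequence("chrT", a + 1, "C", "G", model, contigs)


def test_mutate_and_retranslate_oracle(power_bundle):
    """For every synthetic coding SNP: substitute the variant base into the
    genome, re-extract and translate the whole protein, and diff against the
    unmutated translation.  Effect class, codon index and amino acids must
    agree with consequence() on both strands."""
    bundle = power_bundle
    contigs = bundle["contigs"]
    models = {m.gene_id: m for m in bundle["models"]}
    effects = bundle["effects"]
    coding = effects[effects["effect"].isin(["synonymous", "non_synonymous"])]
    strands_seen = set()
    assert len(coding) >= 20
    for row in coding.itertuples():
        model = models[row.gene_id]
        strands_seen.add(model.strand)
        mutated = dict(contigs)
        seq = mutated[row.contig]
        assert seq[row.pos - 1] == row.ref
        mutated[row.contig] = seq[:row.pos - 1] + row.var + seq[row.pos:]
        before = str(Seq(model.spliced_cds(contigs)).translate(table=1))
        after = str(Seq(model.spliced_cds(mutated)).translate(table=1))
        diffs = [i for i, (x, y) in enumerate(zip(before, after)) if x != y]
        if row.effect == "synonymous":
            assert not diffs
        else:
            assert len(diffs) == 1
            i = diffs[0]
            assert i + 1 == row.codon_index
            assert before[i] == row.ref_aa and after[i] == row.alt_aa
    assert strands_seen == {"+", "-"}


@pytest.mark.parametrize("strand", ["+", "-"])
def test_strand_mirror_gives_identical_annotation(strand):
    """A gene and its reverse-complemented opposite-strand copy yield the same
    effect class and label for the corresponding variant."""
    cds = "ATG" + "GCT" + "CGA" + "TAA"
    model, contigs = make_single_cds_gene(cds, strand)
    a, b = model.cds[0]
    # mutate the first base of codon 2 (GCT -> TCT, A2S)
    cds_pos = 4
    pos1 = (a + cds_pos - 1) + 1 if strand == "+" else (b - 1 - (cds_pos - 1)) + 1
    ref = contigs["chrT"][pos1 - 1]
    var = "T" if strand == "+" else "A"
    out = consequence("chrT", pos1, ref, var, model, contigs)
    assert out["label"] == "A2S"
    assert out["effect"] == "non_synonymous"


# --------------------------------------------------------------- aggregation

def test_effect_classes_partition_all_snps(power_bundle):
    effects = power_bundle["effects"].drop_duplicates(["contig", "pos"])
    snps = power_bundle["snps"]
    assert len(effects) == len(snps)
    allowed = {"five_prime_UTR", "synonymous", "non_synonymous",
               "three_prime_UTR", "other"}
    assert set(effects["effect"]) <= allowed


def test_aggregate_counts_directly():
    effects = pd.DataFrame([
        {"contig": "c", "pos": 1, "gene_id": "g1", "effect": "non_synonymous"},
        {"contig": "c", "pos": 2, "gene_id": "g1", "effect": "synonymous"},
        {"contig": "c", "pos": 3, "gene_id": "g1", "effect": "other"},
    ])
    snps = pd.DataFrame([
        {"contig": "c", "pos": 1, "sel_qualifies": True},
        {"contig": "c", "pos": 2, "sel_qualifies": True},
        {"contig": "c", "pos": 3, "sel_qualifies": False},
    ])
    table = aggregate_by_gene(effects, snps)
    row = table.iloc[0]
    assert (row["n_snps"], row["n_differential"], row["n_nonsyn_differential"]) == (3, 2, 1)


def test_gene_without_snps_absent_or_zero():
    table = aggregate_by_gene(
        pd.DataFrame(columns=["contig", "pos", "gene_id", "effect"]),
        pd.DataFrame(columns=["contig", "pos"]))
    assert table.empty


def test_aggregate_matches_truth(power_bundle):
    truth = power_bundle["truth_variants"]
    table = power_bundle["gene_table"].set_index("gene_id")
    genic = truth[(truth["gene_id"] != "") & (truth["special"] == "")]
    expected = genic.groupby("gene_id").size()
    for gene_id, n in expected.items():
        assert table.loc[gene_id, "n_snps"] == n


def test_gff_roundtrip_preserves_models(default_dataset):
    """Models parsed from the generated GFF3 agree with the generator's own
    interval bookkeeping."""
    ref = default_dataset.reference
    models = {m.gene_id: m for m in load_gene_models(ref.gff3)}
    assert set(models) == {g.gene_id for g in ref.genes}
    for g in ref.genes:
        m = models[g.gene_id]
        assert m.strand == g.strand
        assert sorted(m.exons) == g.genome_exon_intervals()
        assert sorted(m.cds) == g.region_intervals("CDS")
        assert m.spliced_cds(ref.contigs) == g.cds_seq
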