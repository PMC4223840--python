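"""Genic-context and protein-consequence annotation of SNPs against GFF3
gene models.

Each SNP is assigned exactly one effect class: ``five_prime_UTR``,
``synonymous``, ``non_synonymous``, ``three_prime_UTR`` or ``other`` (intronic
or intergenic, i.e. near but not within gene boundaries).  Coding
consequences are computed by substituting the variant base into the spliced
CDS (complemented for minus-strand genes) and translating both codons with
the standard genetic code; stop gains/losses are labelled non-synonymous with
'*' as the amino acid.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "read_fasta",
    "load_gene_models",
    "GeneModelIndex",
    "locate",
    "cds_coordinate",
    "consequence",
    "annotate_effects",
    "aggregate_by_gene",
]

EFFECT_LABELS = ("five_prime_UTR", "synonymous", "non_synonymous",
                 "three_prime_UTR", "other")


def read_fasta(source: str | Path) -> dict[str, str]:
    """Read a FASTA file (path) or FASTA text into {name: sequence}."""
    if isinstance(source, Path) or "\n" not in str(source):
        handle = open(source)
    else:
        handle = _io.StringIO(str(source))
    with handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


@dataclass
class GeneModel:
    """One gene model; intervals are 0-based half-open genomic coordinates
    (GFF3 I/O converts from/to 1-based inclusive)."""

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(a for a, _ in self.exons)

    @property
    def end(self) -> int:
        return max(b for _, b in self.exons)

    def spliced_cds(self, contigs: Mapping[str, str]) -> str:
        """Spliced CDS in coding orientation."""
        seq = "".join(contigs[self.contig][a:b] for a, b in sorted(self.cds))
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def region_of(self, pos0: int) -> str | None:
        """Region at a genomic position: five_prime_UTR | CDS |
        three_prime_UTR | intron, or None if outside the gene span."""
        if not (self.start <= pos0 < self.end):
            return None
        for name, ivals in (("CDS", self.cds), ("five_prime_UTR", self.utr5),
                            ("three_prime_UTR", self.utr3)):
            if any(a <= pos0 < b for a, b in ivals):
                return name
        if any(a <= pos0 < b for a, b in self.exons):
            # exonic but not CDS/UTR (should not occur with complete models)
            return "intron"
        return "intron"


def load_gene_models(source: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (path or text) via gffutils.

    Expects gene/mRNA/exon/CDS/five_prime_UTR/three_prime_UTR features with
    ID/Parent attributes; one transcript per gene (the first mRNA is used if
    several are present).
    """
    text_input = isinstance(source, str) and "\n" in source
    db = gffutils.create_db(
        str(source), dbfn=":memory:", from_string=text_input,
        keep_order=True, merge_strategy="create_unique", force=True)
    models = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue
        mrna = mrnas[0]
        model = GeneModel(gene_id=gene.id, contig=gene.seqid, strand=gene.strand)
        for ftype, attr in (("exon", "exons"), ("CDS", "cds"),
                            ("five_prime_UTR", "utr5"), ("three_prime_UTR", "utr3")):
            ivals = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype=ftype))
            setattr(model, attr, ivals)
        if not model.exons:
            model.exons = sorted(model.utr5 + model.cds + model.utr3)
        models.append(model)
    return models


class GeneModelIndex:
    """Interval index of gene spans per contig for fast position lookup."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = {m.gene_id: m for m in models}
        self.trees: dict[str, IntervalTree] = {}
        for m in models:
            self.trees.setdefault(m.contig, IntervalTree()).addi(m.start, m.end, m.gene_id)

    def overlapping(self, contig: str, pos0: int) -> list[GeneModel]:
        tree = self.trees.get(contig)
        if tree is None:
            return []
        return sorted((self.models[iv.data] for iv in tree[pos0]),
                      key=lambda m: m.gene_id)

    def nearest_within(self, contig: str, pos0: int, flank: int) -> str | None:
        tree = self.trees.get(contig)
        if tree is None:
            return None
        hits = tree[max(0, pos0 - flank):pos0 + flank + 1]
        if not hits:
            return None
        def distance(iv):
            if iv.begin <= pos0 < iv.end:
                return 0
            return min(abs(pos0 - iv.begin), abs(pos0 - (iv.end - 1)))
        best = min(hits, key=lambda iv: (distance(iv), iv.data))
        return best.data if distance(best) <= flank else None


def locate(contig: str, pos1: int, index: GeneModelIndex,
           flank: int = 1000, known_contigs: set[str] | None = None
           ) -> tuple[str | None, str]:
    """Genic region at a 1-based position.

    Returns (gene_id, region) for the overlapping gene (first by id when
    several overlap), or (nearest gene id within ``flank`` or None, "other")
    outside gene boundaries.
    """
    if known_contigs is not None and contig not in known_contigs:
        raise ValueError(f"unknown contig {contig!r}")
    pos0 = pos1 - 1
    hits = index.overlapping(contig, pos0)
    if hits:
        m = hits[0]
        return m.gene_id, m.region_of(pos0)
    return index.nearest_within(contig, pos0, flank), "other"


def cds_coordinate(pos1: int, model: GeneModel) -> int:
    """1-based position within the spliced CDS, in coding-strand orientation
    (for minus-strand genes, counted from the 3'-most genomic CDS base)."""
    pos0 = pos1 - 1
    ivals = sorted(model.cds)
    if not any(a <= pos0 < b for a, b in ivals):
        raise ValueError(f"position {pos1} not inside a CDS interval of {model.gene_id}")
    if model.strand == "+":
        offset = 0
        for a, b in ivals:
            if pos0 >= b:
                offset += b - a
            elif a <= pos0:
                return offset + (pos0 - a) + 1
    else:
        offset = 0
        for a, b in reversed(ivals):
            if pos0 < a:
                offset += b - a
            elif pos0 < b:
                return offset + (b - 1 - pos0) + 1
    raise AssertionError("unreachable")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def consequence(contig: str, pos1: int, ref: str, var: str,
                model: GeneModel, contigs: Mapping[str, str]) -> dict:
    """Protein-level consequence of a coding substitution.

    Returns effect class, 1-based spliced CDS position, codon index, and the
    reference/alternate amino acids with a compact label such as 'A847S'.
    """
    genome_base = contigs[contig][pos1 - 1]
    if genome_base != ref:
        raise ValueError(
            f"reference mismatch at {contig}:{pos1}: pileup says {ref}, genome {genome_base}")
    cds_pos = cds_coordinate(pos1, model)
    ci = (cds_pos - 1) // 3          # 0-based codon index
    within = (cds_pos - 1) % 3
    cds_seq = model.spliced_cds(contigs)
    codon = cds_seq[3 * ci:3 * ci + 3]
    alt_coding = var if model.strand == "+" else var.translate(_COMPLEMENT)
    alt_codon = codon[:within] + alt_coding + codon[within + 1:]
    ref_aa = str(Seq(codon).translate(table=1))
    alt_aa = str(Seq(alt_codon).translate(table=1))
    effect = "synonymous" if ref_aa == alt_aa else "non_synonymous"
    return {
        "effect": effect,
        "cds_pos": cds_pos,
        "codon_index": ci + 1,
        "ref_aa": ref_aa,
        "alt_aa": alt_aa,
        "label": f"{ref_aa}{ci + 1}{alt_aa}",
    }


def annotate_effects(snps: pd.DataFrame, models: Sequence[GeneModel],
                     contigs: Mapping[str, str], flank: int = 1000) -> pd.DataFrame:
    """Annotate every SNP record with its genic effect.

    A SNP overlapping several genes yields one row per gene, flagged in the
    ``multi_gene`` column; every SNP receives exactly one effect class per
    assigned gene.
    """
    index = GeneModelIndex(models)
    known = set(contigs)
    rows = []
    for snp in snps.itertuples():
        if snp.contig not in known:
            raise ValueError(f"SNP on unknown contig {snp.contig!r}")
        pos0 = snp.pos - 1
        hits = index.overlapping(snp.contig, pos0)
        base = {"contig": snp.contig, "pos": snp.pos, "ref": snp.ref, "var": snp.var,
                "gene_id": "", "effect": "other", "cds_pos": pd.NA,
                "codon_index": pd.NA, "ref_aa": "", "alt_aa": "", "label": "",
                "multi_gene": len(hits) > 1}
        if not hits:
            near = index.nearest_within(snp.contig, pos0, flank)
            base["gene_id"] = near or ""
            rows.append(base)
            continue
        for m in hits:
            row = dict(base)
            row["gene_id"] = m.gene_id
            region = m.region_of(pos0)
            if region == "CDS":
                row.update(consequence(snp.contig, snp.pos, snp.ref, snp.var, m, contigs))
            elif region in ("five_prime_UTR", "three_prime_UTR"):
                row["effect"] = region
            else:
                row["effect"] = "other"
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_by_gene(effects: pd.DataFrame, snps: pd.DataFrame,
                      de: pd.DataFrame | None = None) -> pd.DataFrame:
    """Gene-level SNP burden: total SNPs, differential SNPs (qualifying in any
    comparison), non-synonymous differential SNPs; joined with DE calls when
    provided."""
    qual_cols = [c for c in snps.columns if c.endswith("_qualifies")]
    snp_key = snps.set_index(["contig", "pos"])
    qualifies_any = snp_key[qual_cols].any(axis=1) if qual_cols else \
        pd.Series(False, index=snp_key.index)

    genic = effects[effects["gene_id"] != ""]
    rows = []
    for gene_id, grp in genic.groupby("gene_id"):
        keys = list(zip(grp["contig"], grp["pos"]))
        q = np.array([bool(qualifies_any.get(k, False)) for k in keys])
        nonsyn = (grp["effect"] == "non_synonymous").to_numpy()
        rows.append({
            "gene_id": gene_id,
            "n_snps": len(grp),
            "n_differential": int(q.sum()),
            "n_nonsyn_differential": int((q & nonsyn).sum()),
        })
    table = pd.DataFrame(rows, columns=["gene_id", "n_snps", "n_differential",
                                        "n_nonsyn_differential"])
    if de is not None and len(de):
        calls = de[de["call"] != "NS"].groupby("gene_id")["call"] \
            .apply(lambda s: ",".join(sorted(set(s)))).rename("de_call")
        table = table.merge(calls, on="gene_id", how="left")
        table["de_call"] = table["de_call"].fillna("")
        table["de_and_nonsyn"] = (table["de_call"] != "") & (table["n_nonsyn_differential"] > 0)
    return table
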