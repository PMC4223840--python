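"""Synthetic pooled RNA-seq dataset generator.

Emulates the data structure of a three-strain pooled sequencing design: one
susceptible parental strain and two selected phenotypes, each sequenced as a
single RNA pool realised as two technical cDNA libraries.  The generator
emits a toy genome (FASTA), gene models (GFF3), a gene-level count matrix
(Poisson counts around strain-specific rates, with a configurable set of
differentially transcribed genes), per-strain pileup allele-count tables at
planted variant sites (binomial draws around strain-specific true allele
frequencies), and truth tables for both.

Everything is generated at the count level: no reads, no alignment.  Variant
sites are placed so that every genic effect class (5'UTR, synonymous,
non-synonymous, 3'UTR, intronic) occurs on both strands, plus intergenic
sites, one site inside a long homopolymer run and one site whose coverage is
kept below the SNP detection threshold in every strain.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "SimulationConfig",
    "GeneTruth",
    "ReferenceSet",
    "SyntheticDataset",
    "generate_reference",
    "generate_counts",
    "generate_pileups",
    "simulate_dataset",
]

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = tuple(sorted(standard_dna_table.stop_codons))
_NONSTOP_CODONS = tuple(
    sorted(c for c in ("".join(p) for p in itertools.product(_BASES, repeat=3))
           if c not in standard_dna_table.stop_codons)
)

# effect classes the generator plants; "intronic" and "intergenic" both map
# to the pipeline's reported class "other"
EFFECT_CLASSES = (
    "five_prime_UTR",
    "synonymous",
    "non_synonymous",
    "three_prime_UTR",
    "intronic",
    "intergenic",
)


class CapacityError(ValueError):
    """Raised when the requested features do not fit the configured genome."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate_codon(codon: str) -> str:
    return "*" if codon in standard_dna_table.stop_codons else standard_dna_table.forward_table[codon]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    The defaults mirror the pooled design the pipeline targets: three strains
    (one susceptible parent, two selected phenotypes) with two technical
    libraries of one million retained reads each; planted differential genes
    at |log2 fold change| = 2 with per-strain expected counts of several
    hundred reads; variant sites with true alternate-allele frequencies of
    0.05 in the susceptible pool versus 0.55 in the selected pools (a
    50-point difference) at a mean per-strain coverage of 100 reads.
    """

    seed: int = 0
    n_contigs: int = 3
    contig_length: int = 60_000
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (1, 4)
    cds_codons: tuple[int, int] = (80, 300)
    utr5_len: tuple[int, int] = (30, 120)
    utr3_len: tuple[int, int] = (60, 200)
    intron_len: tuple[int, int] = (50, 200)
    intergenic_gap: tuple[int, int] = (300, 900)
    strand_fraction_minus: float = 0.5
    strains: tuple[str, ...] = ("susceptible", "selected_N", "selected_S")
    susceptible_strain: str = "susceptible"
    libraries_per_strain: int = 2
    library_size: int = 1_000_000
    library_sizes: Mapping[str, int] | None = None
    n_de_genes: int = 10
    log2fc_values: tuple[float, ...] = (2.0, -2.0)
    de_minor_mean: tuple[float, float] = (200.0, 1200.0)
    null_mean: tuple[float, float] = (5.0, 1500.0)
    n_variant_sites: int = 60
    coverage_mean: float = 100.0
    true_freqs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "susceptible": (0.05,),
            "selected_N": (0.55,),
            "selected_S": (0.55,),
        }
    )
    site_quality_range: tuple[float, float] = (200.0, 400.0)
    homopolymer_insert_len: int = 13
    lowcov_coverage: int = 8

    def library_manifest(self) -> pd.DataFrame:
        """Library ids, strain membership, role and total read counts."""
        rows = []
        for strain in self.strains:
            role = "parental" if strain == self.susceptible_strain else "selected"
            for i in range(1, self.libraries_per_strain + 1):
                lib = f"{strain}_{i}"
                n = (self.library_sizes or {}).get(lib, self.library_size)
                rows.append((lib, strain, role, int(n)))
        return pd.DataFrame(rows, columns=["library_id", "strain", "role", "N"])

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("n_contigs", "contig_length", "n_genes", "n_variant_sites"):
            if getattr(self, name) < 0 or (name != "n_variant_sites" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.strand_fraction_minus <= 1.0:
            raise ValueError("strand_fraction_minus must be in [0, 1]")
        if self.susceptible_strain not in self.strains:
            raise ValueError("susceptible_strain must be one of strains")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        for strain in self.strains:
            freqs = self.true_freqs.get(strain)
            if not freqs:
                raise ValueError(f"true_freqs missing for strain {strain!r}")
            if any(not 0.0 <= f <= 1.0 for f in freqs):
                raise ValueError("true allele frequencies must lie in [0, 1]")
        if self.homopolymer_insert_len <= 10:
            raise ValueError("homopolymer_insert_len must exceed 10")


@dataclass
class GeneTruth:
    """Internal record of one generated gene (coordinates 0-based half-open,
    on the forward genome strand; transcript structures in coding orientation)."""

    gene_id: str
    contig: str
    strand: str
    start: int                      # genomic span start (0-based)
    span: int                       # genomic span length
    tx_exons: list[tuple[int, int]]  # exon intervals in transcript coords
    local_exons: list[tuple[int, int]]  # exon intervals in gene-local coords
    utr5_len: int
    cds_len: int
    utr3_len: int
    transcript: str                 # spliced transcript, coding orientation

    @property
    def end(self) -> int:
        return self.start + self.span

    @property
    def tx_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds_seq(self) -> str:
        return self.transcript[self.utr5_len:self.utr5_len + self.cds_len]

    @property
    def n_introns(self) -> int:
        return len(self.local_exons) - 1

    def local_to_genome(self, local: int) -> int:
        if self.strand == "+":
            return self.start + local
        return self.start + self.span - 1 - local

    def tx_to_local(self, tx_pos: int) -> int:
        for (ts, te), (ls, _le) in zip(self.tx_exons, self.local_exons):
            if ts <= tx_pos < te:
                return ls + (tx_pos - ts)
        raise ValueError(f"transcript position {tx_pos} outside transcript")

    def tx_to_genome(self, tx_pos: int) -> int:
        return self.local_to_genome(self.tx_to_local(tx_pos))

    def genome_exon_intervals(self) -> list[tuple[int, int]]:
        out = []
        for ls, le in self.local_exons:
            if self.strand == "+":
                out.append((self.start + ls, self.start + le))
            else:
                out.append((self.start + self.span - le, self.start + self.span - ls))
        return sorted(out)

    def intron_local_positions(self) -> list[int]:
        pos = []
        for (_, le), (ns, _) in zip(self.local_exons, self.local_exons[1:]):
            pos.extend(range(le, ns))
        return pos

    def region_intervals(self, region: str) -> list[tuple[int, int]]:
        """Genomic intervals of 'five_prime_UTR' | 'CDS' | 'three_prime_UTR'."""
        bounds = {
            "five_prime_UTR": (0, self.utr5_len),
            "CDS": (self.utr5_len, self.utr5_len + self.cds_len),
            "three_prime_UTR": (self.utr5_len + self.cds_len, self.tx_len),
        }[region]
        a, b = bounds
        out = []
        for (ts, te), (ls, _le) in zip(self.tx_exons, self.local_exons):
            lo, hi = max(ts, a), min(te, b)
            if lo < hi:
                s = ls + (lo - ts)
                e = ls + (hi - ts)
                if self.strand == "+":
                    out.append((self.start + s, self.start + e))
                else:
                    out.append((self.start + self.span - e, self.start + self.span - s))
        return sorted(out)


@dataclass
class ReferenceSet:
    """Generated genome + gene models plus the bookkeeping needed downstream."""

    config: SimulationConfig
    contigs: dict[str, str]
    genes: list[GeneTruth]
    homopolymer: tuple[str, int, int]  # contig, start_1based, end_1based (inclusive)

    @property
    def fasta(self) -> str:
        return write_fasta(self.contigs)

    @property
    def gff3(self) -> str:
        return write_gff3(self.genes)

    def gene(self, gene_id: str) -> GeneTruth:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, plus truth tables."""

    config: SimulationConfig
    reference: ReferenceSet
    counts: pd.DataFrame
    manifest: pd.DataFrame
    pileups: dict[str, pd.DataFrame]
    de_truth: pd.DataFrame
    variant_truth: pd.DataFrame
    categories: pd.DataFrame


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS: ATG start, non-stop internal codons, one stop codon."""
    internal = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in internal) + stop


def _split_lengths(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    """Random composition of `total` into `parts` pieces, each >= minimum."""
    if parts == 1:
        return [total]
    slack = total - parts * minimum
    if slack < 0:
        raise CapacityError("transcript too short for requested exon count")
    cuts = np.sort(rng.integers(0, slack + 1, size=parts - 1))
    pieces = np.diff(np.concatenate(([0], cuts, [slack])))
    return [int(p) + minimum for p in pieces]


def _build_gene(rng: np.random.Generator, gene_id: str, contig: str,
                start: int, strand: str, cfg: SimulationConfig) -> tuple[GeneTruth, str]:
    """Construct one gene; returns its truth record and the forward-strand
    genomic sequence of its span."""
    u5 = int(rng.integers(cfg.utr5_len[0], cfg.utr5_len[1] + 1))
    u3 = int(rng.integers(cfg.utr3_len[0], cfg.utr3_len[1] + 1))
    n_codons = int(rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1))
    cds = _random_cds(rng, n_codons)
    utr5 = "".join(_BASES[i] for i in rng.integers(0, 4, size=u5))
    utr3 = "".join(_BASES[i] for i in rng.integers(0, 4, size=u3))
    transcript = utr5 + cds + utr3
    tx_len = len(transcript)

    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    n_exons = min(n_exons, max(1, tx_len // 30))
    exon_lens = _split_lengths(rng, tx_len, n_exons, 30)
    intron_lens = [int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
                   for _ in range(n_exons - 1)]

    tx_exons, local_exons = [], []
    tx_cursor = local_cursor = 0
    local_seq_parts: list[str] = []
    for i, elen in enumerate(exon_lens):
        tx_exons.append((tx_cursor, tx_cursor + elen))
        local_exons.append((local_cursor, local_cursor + elen))
        local_seq_parts.append(transcript[tx_cursor:tx_cursor + elen])
        tx_cursor += elen
        local_cursor += elen
        if i < n_exons - 1:
            ilen = intron_lens[i]
            local_seq_parts.append(
                "".join(_BASES[j] for j in rng.integers(0, 4, size=ilen)))
            local_cursor += ilen
    local_seq = "".join(local_seq_parts)
    span = len(local_seq)

    gene = GeneTruth(
        gene_id=gene_id, contig=contig, strand=strand, start=start, span=span,
        tx_exons=tx_exons, local_exons=local_exons,
        utr5_len=u5, cds_len=len(cds), utr3_len=u3, transcript=transcript,
    )
    forward_seq = local_seq if strand == "+" else _revcomp(local_seq)
    return gene, forward_seq


def generate_reference(config: SimulationConfig) -> ReferenceSet:
    """Generate the toy genome and gene models.

    Genes are laid out left to right per contig with random intergenic gaps,
    alternating contigs; a homopolymer run of ``homopolymer_insert_len``
    identical bases is written into an intergenic region of the first contig
    and its location recorded.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    contig_names = [f"contig{i + 1}" for i in range(config.n_contigs)]
    arrays = {
        name: np.array(list("ACGT"))[rng.integers(0, 4, size=config.contig_length)]
        for name in contig_names
    }
    cursors = {name: int(rng.integers(*config.intergenic_gap)) + 1200 for name in contig_names}

    # force both strands to be represented, and at least one multi-exon gene
    # per strand so intronic sites exist on both
    strands = ["+", "-"] + [
        "-" if rng.random() < config.strand_fraction_minus else "+"
        for _ in range(config.n_genes - 2)
    ]

    genes: list[GeneTruth] = []
    forced_multiexon = {"+", "-"} if config.exons_per_gene[1] > 1 else set()
    for i in range(config.n_genes):
        gene_id = f"gene{i + 1:04d}"
        strand = strands[i]
        cfg_i = config
        if strand in forced_multiexon and config.exons_per_gene[1] > 1:
            cfg_i = replace(config, exons_per_gene=(max(2, config.exons_per_gene[0]),
                                                    config.exons_per_gene[1]))
            forced_multiexon.discard(strand)
        placed = False
        for name in sorted(contig_names, key=lambda n: cursors[n]):
            start = cursors[name]
            gene, fwd = _build_gene(rng, gene_id, name, start, strand, cfg_i)
            if gene.end + 1200 <= config.contig_length:
                arrays[name][gene.start:gene.end] = list(fwd)
                genes.append(gene)
                cursors[name] = gene.end + int(rng.integers(*config.intergenic_gap))
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"cannot place {config.n_genes} genes on {config.n_contigs} "
                f"contigs of {config.contig_length} bp (failed at {gene_id})")

    # homopolymer run in an intergenic region near the start of contig1
    h_len = config.homopolymer_insert_len
    h_contig = contig_names[0]
    h_start0 = 100  # well inside the leading intergenic margin
    base = "A"
    arrays[h_contig][h_start0:h_start0 + h_len] = base
    # pin flanks to a different base so the run length is exact
    arrays[h_contig][h_start0 - 1] = "C"
    arrays[h_contig][h_start0 + h_len] = "C"

    contigs = {name: "".join(arr) for name, arr in arrays.items()}
    return ReferenceSet(
        config=config, contigs=contigs, genes=genes,
        homopolymer=(h_contig, h_start0 + 1, h_start0 + h_len),
    )


def write_fasta(contigs: Mapping[str, str], width: int = 60) -> str:
    out = []
    for name, seq in contigs.items():
        out.append(f">{name}")
        out.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"


def write_gff3(genes: Sequence[GeneTruth]) -> str:
    """Serialize gene models as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for g in genes:
        s1, e1 = g.start + 1, g.end
        lines.append("\t".join([g.contig, "pooldiff", "gene", str(s1), str(e1),
                                ".", g.strand, ".", f"ID={g.gene_id}"]))
        mrna = f"{g.gene_id}.t1"
        lines.append("\t".join([g.contig, "pooldiff", "mRNA", str(s1), str(e1),
                                ".", g.strand, ".", f"ID={mrna};Parent={g.gene_id}"]))
        for a, b in g.genome_exon_intervals():
            lines.append("\t".join([g.contig, "pooldiff", "exon", str(a + 1), str(b),
                                    ".", g.strand, ".", f"Parent={mrna}"]))
        for region, ftype in (("five_prime_UTR", "five_prime_UTR"),
                              ("three_prime_UTR", "three_prime_UTR")):
            for a, b in g.region_intervals(region):
                lines.append("\t".join([g.contig, "pooldiff", ftype, str(a + 1), str(b),
                                        ".", g.strand, ".", f"Parent={mrna}"]))
        # CDS phase follows transcript order
        cds = g.region_intervals("CDS")
        tx_order = cds if g.strand == "+" else list(reversed(cds))
        cum = 0
        phased = []
        for a, b in tx_order:
            phased.append((a, b, (3 - cum % 3) % 3))
            cum += b - a
        for a, b, phase in sorted(phased):
            lines.append("\t".join([g.contig, "pooldiff", "CDS", str(a + 1), str(b),
                                    ".", g.strand, str(phase), f"Parent={mrna}"]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def generate_counts(config: SimulationConfig,
                    reference: ReferenceSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson gene counts per library, with planted differential genes.

    Each gene has one underlying rate (expected count per library at the
    nominal library size); technical replicates of a strain share the
    strain's rate, which for planted genes is the base rate times
    ``2**log2fc`` in the selected strains.  Counts scale linearly with the
    configured library sizes.  Returns (counts table, DE truth table).
    """
    rng = np.random.default_rng(_substream(config.seed, "counts"))
    manifest = config.library_manifest()
    genes = reference.genes
    gene_ids = [g.gene_id for g in genes]
    exonic_len = {g.gene_id: sum(b - a for a, b in g.genome_exon_intervals())
                  for g in genes}

    de_idx = rng.choice(len(genes), size=config.n_de_genes, replace=False)
    log2fc = {gene_ids[int(g)]: float(config.log2fc_values[k % len(config.log2fc_values)])
              for k, g in enumerate(sorted(de_idx))}

    lo, hi = config.null_mean
    base_mean = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=len(genes))
    sus_mean = base_mean.copy()
    for gid, fc in log2fc.items():
        i = gene_ids.index(gid)
        # the minor strain (whichever ends up lower) keeps its expected count
        # above de_minor_mean so planted effects are well powered
        minor = 10.0 ** rng.uniform(np.log10(config.de_minor_mean[0]),
                                    np.log10(config.de_minor_mean[1]))
        sus_mean[i] = minor if fc > 0 else minor * 2.0 ** (-fc)

    data = {"gene_id": gene_ids,
            "exonic_length_bp": [exonic_len[g] for g in gene_ids]}
    for _, row in manifest.iterrows():
        mult = np.ones(len(genes))
        if row["strain"] != config.susceptible_strain:
            for gid, fc in log2fc.items():
                mult[gene_ids.index(gid)] = 2.0 ** fc
        lam = sus_mean * mult * (row["N"] / config.library_size)
        data[row["library_id"]] = rng.poisson(lam)
    counts = pd.DataFrame(data)

    de_truth = pd.DataFrame(
        {"gene_id": list(log2fc), "log2fc": list(log2fc.values()),
         "susceptible_mean": [sus_mean[gene_ids.index(g)] for g in log2fc]}
    ).sort_values("gene_id").reset_index(drop=True)
    return counts, de_truth


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def _substream(seed: int, label: str) -> np.random.SeedSequence:
    h = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    return np.random.SeedSequence([seed, h])


def _coding_effect(gene: GeneTruth, tx_pos: int, alt_coding: str) -> tuple[str, int, str, str]:
    """Classify a CDS substitution by direct codon replacement.

    Returns (effect, codon_index 1-based, ref_aa, alt_aa); alt_coding is the
    alternate base in coding orientation.
    """
    cds_pos0 = tx_pos - gene.utr5_len
    ci = cds_pos0 // 3
    codon = gene.cds_seq[3 * ci:3 * ci + 3]
    alt_codon = codon[:cds_pos0 % 3] + alt_coding + codon[cds_pos0 % 3 + 1:]
    ref_aa, alt_aa = _translate_codon(codon), _translate_codon(alt_codon)
    effect = "synonymous" if ref_aa == alt_aa else "non_synonymous"
    return effect, ci + 1, ref_aa, alt_aa


def _find_coding_site(rng: np.random.Generator, gene: GeneTruth,
                      want: str) -> tuple[int, str]:
    """Find (tx_pos, alt base in coding orientation) whose substitution is
    synonymous or non-synonymous as requested.  Deterministic scan from a
    random starting codon."""
    n_codons = gene.cds_len // 3
    start = int(rng.integers(1, n_codons - 1))  # skip start and stop codons
    for k in range(n_codons - 2):
        ci = 1 + (start - 1 + k) % (n_codons - 2)
        codon = gene.cds_seq[3 * ci:3 * ci + 3]
        for offset in (2, 0, 1):
            for alt in _BASES:
                if alt == codon[offset]:
                    continue
                alt_codon = codon[:offset] + alt + codon[offset + 1:]
                if alt_codon in standard_dna_table.stop_codons:
                    continue
                syn = _translate_codon(alt_codon) == _translate_codon(codon)
                if (want == "synonymous") == syn:
                    return gene.utr5_len + 3 * ci + offset, alt
    raise CapacityError(f"no {want} site available in {gene.gene_id}")


def generate_pileups(config: SimulationConfig, reference: ReferenceSet
                     ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-strain pileup tables at planted variant sites, plus the truth table.

    Coverage per strain/site is Poisson(coverage_mean); the alternate-allele
    count is Binomial(coverage, strain's true frequency).  Sites cover every
    genic effect class on both strands, plus intergenic sites, one site inside
    the homopolymer run and one site with coverage forced below the SNP
    detection threshold in every strain.
    """
    rng = np.random.default_rng(_substream(config.seed, "pileups"))
    genes = reference.genes
    plus = [g for g in genes if g.strand == "+"]
    minus = [g for g in genes if g.strand == "-"]
    if not plus or not minus:
        raise CapacityError("both strands must carry at least one gene")

    taken: set[tuple[str, int]] = set()
    sites: list[dict] = []

    def genome_base(contig: str, pos0: int) -> str:
        return reference.contigs[contig][pos0]

    def add_site(contig: str, pos0: int, alt_fwd: str, klass: str,
                 gene_id: str | None, strand: str, special: str = "") -> None:
        key = (contig, pos0)
        if key in taken:
            return
        taken.add(key)
        sites.append({
            "contig": contig, "pos": pos0 + 1,
            "ref": genome_base(contig, pos0), "alt": alt_fwd,
            "true_class": klass, "gene_id": gene_id or "",
            "strand": strand, "special": special,
        })

    def random_alt(ref: str) -> str:
        choices = [b for b in _BASES if b != ref]
        return choices[int(rng.integers(0, 3))]

    def place_in_region(gene: GeneTruth, region: str, klass: str) -> None:
        lo, hi = {
            "five_prime_UTR": (0, gene.utr5_len),
            "three_prime_UTR": (gene.utr5_len + gene.cds_len, gene.tx_len),
        }[region]
        tx_pos = int(rng.integers(lo, hi))
        pos0 = gene.tx_to_genome(tx_pos)
        ref = genome_base(gene.contig, pos0)
        add_site(gene.contig, pos0, random_alt(ref), klass, gene.gene_id, gene.strand)

    def place_coding(gene: GeneTruth, want: str) -> None:
        tx_pos, alt_coding = _find_coding_site(rng, gene, want)
        pos0 = gene.tx_to_genome(tx_pos)
        alt_fwd = alt_coding if gene.strand == "+" else alt_coding.translate(_COMPLEMENT)
        add_site(gene.contig, pos0, alt_fwd, want, gene.gene_id, gene.strand)

    def place_intronic(strand_genes: list[GeneTruth]) -> None:
        candidates = [g for g in strand_genes if g.n_introns > 0]
        if not candidates:
            raise CapacityError("no multi-exon gene on required strand for intronic site")
        g = candidates[int(rng.integers(0, len(candidates)))]
        locals_ = g.intron_local_positions()
        local = locals_[int(rng.integers(0, len(locals_)))]
        pos0 = g.local_to_genome(local)
        ref = genome_base(g.contig, pos0)
        add_site(g.contig, pos0, random_alt(ref), "intronic", g.gene_id, g.strand)

    def pick_gene(pool: list[GeneTruth]) -> GeneTruth:
        return pool[int(rng.integers(0, len(pool)))]

    # one site of every genic class on each strand
    for pool in (plus, minus):
        place_in_region(pick_gene(pool), "five_prime_UTR", "five_prime_UTR")
        place_coding(pick_gene(pool), "synonymous")
        place_coding(pick_gene(pool), "non_synonymous")
        place_in_region(pick_gene(pool), "three_prime_UTR", "three_prime_UTR")
        place_intronic(pool)

    # intergenic sites: > 1 kb from every gene span
    spans = sorted((g.contig, g.start, g.end) for g in genes)

    def is_far_intergenic(contig: str, pos0: int, margin: int = 1001) -> bool:
        return all(not (c == contig and s - margin <= pos0 < e + margin)
                   for c, s, e in spans)

    n_intergenic = 0
    attempts = 0
    while n_intergenic < 2 and attempts < 20_000:
        attempts += 1
        contig = f"contig{int(rng.integers(0, config.n_contigs)) + 1}"
        pos0 = int(rng.integers(50, config.contig_length - 50))
        hc, hs, he = reference.homopolymer
        if contig == hc and hs - 3 <= pos0 + 1 <= he + 3:
            continue
        if is_far_intergenic(contig, pos0) and (contig, pos0) not in taken:
            ref = genome_base(contig, pos0)
            add_site(contig, pos0, random_alt(ref), "intergenic", None, ".")
            n_intergenic += 1
    if n_intergenic < 2:
        raise CapacityError("no intergenic space > 1 kb from genes")

    # site inside the homopolymer run (must be filtered out downstream)
    hc, hs, he = reference.homopolymer
    hp_pos0 = (hs - 1) + int(rng.integers(0, he - hs + 1))
    add_site(hc, hp_pos0, random_alt(genome_base(hc, hp_pos0)), "intergenic",
             None, ".", special="homopolymer")

    # low-coverage site (below detection threshold in every strain)
    g = pick_gene(plus)
    tx_pos = int(rng.integers(gene_low := g.utr5_len, gene_low + g.cds_len))
    pos0 = g.tx_to_genome(tx_pos)
    if (g.contig, pos0) in taken:
        pos0 = g.tx_to_genome(tx_pos + 1)
    add_site(g.contig, pos0, random_alt(genome_base(g.contig, pos0)),
             "non_synonymous", g.gene_id, g.strand, special="lowcov")

    # remaining sites: random positions in random genes (any class)
    all_genes = genes
    attempts = 0
    while len(sites) < config.n_variant_sites and attempts < 50_000:
        attempts += 1
        g = all_genes[int(rng.integers(0, len(all_genes)))]
        local = int(rng.integers(0, g.span))
        pos0 = g.local_to_genome(local)
        if (g.contig, pos0) in taken:
            continue
        # classify from the generator's own structures
        intron_locals = None
        tx_pos = None
        for (ts, te), (ls, le) in zip(g.tx_exons, g.local_exons):
            if ls <= local < le:
                tx_pos = ts + (local - ls)
                break
        ref = genome_base(g.contig, pos0)
        if tx_pos is None:
            add_site(g.contig, pos0, random_alt(ref), "intronic", g.gene_id, g.strand)
            continue
        if tx_pos < g.utr5_len:
            add_site(g.contig, pos0, random_alt(ref), "five_prime_UTR", g.gene_id, g.strand)
        elif tx_pos >= g.utr5_len + g.cds_len:
            add_site(g.contig, pos0, random_alt(ref), "three_prime_UTR", g.gene_id, g.strand)
        else:
            alt_coding = random_alt(g.transcript[tx_pos])
            effect, _, _, _ = _coding_effect(g, tx_pos, alt_coding)
            alt_fwd = alt_coding if g.strand == "+" else alt_coding.translate(_COMPLEMENT)
            add_site(g.contig, pos0, alt_fwd, effect, g.gene_id, g.strand)
    if len(sites) < config.n_variant_sites:
        raise CapacityError(
            f"could not place {config.n_variant_sites} variant sites")

    # realize per-strain counts
    qlo, qhi = config.site_quality_range
    truth_rows = []
    pileups: dict[str, list[dict]] = {s: [] for s in config.strains}
    for i, site in enumerate(sites):
        truth = dict(site)
        for strain in config.strains:
            freqs = config.true_freqs[strain]
            f = freqs[i % len(freqs)]
            if site["special"] == "lowcov":
                cov = int(rng.integers(1, config.lowcov_coverage + 1))
            else:
                cov = int(rng.poisson(config.coverage_mean))
                cov = max(cov, 1)
            alt_n = int(rng.binomial(cov, f))
            row = {"contig": site["contig"], "pos_1based": site["pos"],
                   "ref_base": site["ref"], "A": 0, "C": 0, "G": 0, "T": 0,
                   "site_quality": round(float(rng.uniform(qlo, qhi)), 1)}
            row[site["ref"]] = cov - alt_n
            row[site["alt"]] += alt_n
            pileups[strain].append(row)
            truth[f"{strain}_true_freq"] = f
            truth[f"{strain}_coverage"] = cov
            truth[f"{strain}_alt_count"] = alt_n
        truth_rows.append(truth)

    # a few reference-only positions (no variant reads in any strain)
    for _ in range(5):
        g = all_genes[int(rng.integers(0, len(all_genes)))]
        local = int(rng.integers(0, g.span))
        pos0 = g.local_to_genome(local)
        if (g.contig, pos0) in taken:
            continue
        taken.add((g.contig, pos0))
        ref = genome_base(g.contig, pos0)
        for strain in config.strains:
            cov = max(int(rng.poisson(config.coverage_mean)), 1)
            row = {"contig": g.contig, "pos_1based": pos0 + 1, "ref_base": ref,
                   "A": 0, "C": 0, "G": 0, "T": 0,
                   "site_quality": round(float(rng.uniform(qlo, qhi)), 1)}
            row[ref] = cov
            pileups[strain].append(row)

    pileup_frames = {
        s: pd.DataFrame(rows).sort_values(["contig", "pos_1based"]).reset_index(drop=True)
        for s, rows in pileups.items()
    }
    variant_truth = pd.DataFrame(truth_rows).sort_values(
        ["contig", "pos"]).reset_index(drop=True)
    return pileup_frames, variant_truth


# ---------------------------------------------------------------------------
# category map + full dataset
# ---------------------------------------------------------------------------

CATEGORIES = (
    "Candidate", "Detoxification", "Other enzymes", "Cuticle", "Immunity",
    "Hormones and neurotransmitters signaling", "Transcription factors",
    "Intra or extracellular trafficking/chaperonins", "Structure", "Unknown",
)


def generate_categories(config: SimulationConfig, reference: ReferenceSet) -> pd.DataFrame:
    """Uniform random gene -> functional category assignment."""
    rng = np.random.default_rng(_substream(config.seed, "categories"))
    gene_ids = [g.gene_id for g in reference.genes]
    cats = [CATEGORIES[int(i)] for i in rng.integers(0, len(CATEGORIES), size=len(gene_ids))]
    return pd.DataFrame({"gene_id": gene_ids, "category": cats})


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the complete synthetic dataset (genome, models, counts,
    pileups, truth tables, category map).  Deterministic in ``config.seed``."""
    reference = generate_reference(config)
    counts, de_truth = generate_counts(config, reference)
    pileups, variant_truth = generate_pileups(config, reference)
    categories = generate_categories(config, reference)
    return SyntheticDataset(
        config=config, reference=reference, counts=counts,
        manifest=config.library_manifest(), pileups=pileups,
        de_truth=de_truth, variant_truth=variant_truth, categories=categories,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every dataset component to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, text: str) -> None:
        p = outdir / name
        p.write_text(text)
        paths[name] = p

    _write("genome.fasta", ds.reference.fasta)
    _write("models.gff3", ds.reference.gff3)
    _write("counts.tsv", ds.counts.to_csv(sep="\t", index=False))
    _write("manifest.tsv", ds.manifest.to_csv(sep="\t", index=False))
    for strain, frame in ds.pileups.items():
        _write(f"pileup_{strain}.tsv", frame.to_csv(sep="\t", index=False))
    _write("truth_de.tsv", ds.de_truth.to_csv(sep="\t", index=False))
    _write("truth_variants.tsv", ds.variant_truth.to_csv(sep="\t", index=False))
    _write("categories.tsv", ds.categories.to_csv(sep="\t", index=False))
    return paths
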