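"""SNP calling from per-strain pileup allele counts and differential-SNP
classification between strain pairs.

Allele frequencies are plain count ratios, appropriate for pooled sequencing
where each strain's library represents many individuals.  A site becomes a
SNP record when it is outside homopolymer masks, passes the site-quality
floor, has biallelic coverage above ``cov_detect`` (strict >, default 20) in
at least one strain, and shows at least one non-reference read.  A SNP is
*differential* for a comparison when the summed coverage of the two compared
strains is at least ``cov_min`` (default 30) and the absolute allele-frequency
difference is at least ``dfreq_min`` percentage points (default 40).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "mask_homopolymers",
    "load_pileup",
    "allele_frequency",
    "classify_differential",
    "detect_snps",
    "call_differential_snps",
    "write_vcf",
    "round_half_up",
]

_BASES = ("A", "C", "G", "T")


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal round-half-up (report style: 4.15 -> 4.2, not banker's)."""
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def mask_homopolymers(contigs: Mapping[str, str], min_run: int = 11
                      ) -> set[tuple[str, int]]:
    """Positions (contig, 1-based) inside any single-base run of length
    >= ``min_run``, plus the single flanking position on each side.

    The default of 11 implements 'runs longer than 10 nucleotides'.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    masked: set[tuple[str, int]] = set()
    pattern = re.compile(r"(A+|C+|G+|T+)")
    for contig, seq in contigs.items():
        for m in pattern.finditer(seq):
            if m.end() - m.start() >= min_run:
                lo = max(1, m.start())           # 1-based flank before run
                hi = min(len(seq), m.end() + 1)  # 1-based flank after run
                masked.update((contig, p) for p in range(lo, hi + 1))
    return masked


def load_pileup(path_or_frame) -> pd.DataFrame:
    """Read one strain's pileup table (contig, pos_1based, ref_base, A, C, G,
    T, site_quality)."""
    df = path_or_frame.copy() if isinstance(path_or_frame, pd.DataFrame) \
        else pd.read_csv(path_or_frame, sep="\t")
    required = {"contig", "pos_1based", "ref_base", *_BASES, "site_quality"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pileup table missing columns: {sorted(missing)}")
    if (df[list(_BASES)] < 0).any().any():
        raise ValueError("allele counts must be non-negative")
    return df


def allele_frequency(ref_count: int, var_count: int) -> float:
    """Variant-allele frequency in percent among ref+variant reads."""
    if ref_count < 0 or var_count < 0:
        raise ValueError("allele counts must be non-negative")
    total = ref_count + var_count
    if total < 1:
        raise ValueError("undefined allele frequency: zero ref+variant coverage")
    return 100.0 * var_count / total


def classify_differential(freq_sus: float, cov_sus: int,
                          freq_sel: float, cov_sel: int,
                          cov_min: int = 30, dfreq_min: float = 40.0
                          ) -> tuple[bool, float]:
    """Differential-SNP gate for one comparison.

    ``delta`` is selected minus susceptible frequency in percentage points;
    the site qualifies when the summed coverage of the two strains reaches
    ``cov_min`` and |delta| reaches ``dfreq_min``.
    Returns (qualifies, delta).
    """
    delta = freq_sel - freq_sus
    qualifies = (cov_sus + cov_sel >= cov_min) and abs(delta) >= dfreq_min
    return bool(qualifies), float(delta)


def detect_snps(pileups: Mapping[str, pd.DataFrame],
                contigs: Mapping[str, str],
                masked: set[tuple[str, int]] | None = None,
                cov_detect: int = 20, qual_min: float = 0.0) -> pd.DataFrame:
    """Call biallelic SNP records from per-strain pileups.

    The variant allele at a site is the most frequent non-reference allele
    summed over strains (ties broken alphabetically); remaining non-reference
    alleles are excluded from frequency denominators.  Per-strain coverage is
    ref+variant reads.  Sites inside ``masked`` positions, below the quality
    floor in any strain, or without any strain exceeding ``cov_detect``
    biallelic reads are skipped.
    """
    masked = masked or set()
    strains = list(pileups)
    merged: dict[tuple[str, int], dict] = {}
    for strain, frame in pileups.items():
        for row in frame.itertuples():
            key = (row.contig, int(row.pos_1based))
            rec = merged.setdefault(key, {"ref": row.ref_base, "per_strain": {}, "qual": {}})
            if rec["ref"] != row.ref_base:
                raise ValueError(f"inconsistent reference base at {key}")
            rec["per_strain"][strain] = np.array([getattr(row, b) for b in _BASES], int)
            rec["qual"][strain] = float(row.site_quality)

    rows = []
    for (contig, pos), rec in sorted(merged.items()):
        if contig not in contigs:
            raise ValueError(f"pileup contig {contig!r} absent from genome")
        if pos < 1 or pos > len(contigs[contig]):
            raise ValueError(f"pileup position {contig}:{pos} outside contig")
        ref = rec["ref"]
        if ref not in _BASES:
            raise ValueError(f"invalid reference base {ref!r} at {contig}:{pos}")
        if contigs[contig][pos - 1] != ref:
            raise ValueError(
                f"pileup reference base {ref} disagrees with genome at {contig}:{pos}")
        if (contig, pos) in masked:
            continue
        if min(rec["qual"].get(s, np.inf) for s in strains) < qual_min:
            continue
        totals = sum(rec["per_strain"].get(s, np.zeros(4, int)) for s in strains)
        ref_i = _BASES.index(ref)
        nonref = [(int(totals[i]), _BASES[i]) for i in range(4) if i != ref_i]
        var_count, var = max(nonref, key=lambda t: (t[0], -ord(t[1])))
        if var_count == 0:
            continue
        var_i = _BASES.index(var)
        row = {"contig": contig, "pos": pos, "ref": ref, "var": var}
        any_covered = False
        for s in strains:
            counts = rec["per_strain"].get(s, np.zeros(4, int))
            rc, vc = int(counts[ref_i]), int(counts[var_i])
            cov = rc + vc
            row[f"{s}_cov"] = cov
            row[f"{s}_freq"] = allele_frequency(rc, vc) if cov >= 1 else np.nan
            if cov > cov_detect:
                any_covered = True
        if not any_covered:
            continue
        rows.append(row)
    cols = ["contig", "pos", "ref", "var"] + \
        [f"{s}_{k}" for s in strains for k in ("freq", "cov")]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def call_differential_snps(snps: pd.DataFrame,
                           comparisons: Sequence[tuple[str, str]],
                           cov_min: int = 30, dfreq_min: float = 40.0
                           ) -> pd.DataFrame:
    """Annotate SNP records with delta-frequency and the differential gate for
    each (susceptible, selected) comparison, adding columns
    ``{selected}_delta`` and ``{selected}_qualifies``."""
    out = snps.copy()
    for sus, sel in comparisons:
        for s in (sus, sel):
            if f"{s}_freq" not in out.columns:
                raise KeyError(f"strain {s!r} absent from SNP records")
        deltas, quals = [], []
        for row in out.itertuples():
            fs = getattr(row, f"{sus}_freq")
            fe = getattr(row, f"{sel}_freq")
            if np.isnan(fs) or np.isnan(fe):
                deltas.append(np.nan)
                quals.append(False)
                continue
            q, d = classify_differential(
                fs, getattr(row, f"{sus}_cov"), fe, getattr(row, f"{sel}_cov"),
                cov_min=cov_min, dfreq_min=dfreq_min)
            deltas.append(d)
            quals.append(q)
        out[f"{sel}_delta"] = deltas
        out[f"{sel}_qualifies"] = quals
    return out


def write_vcf(snps: pd.DataFrame, strains: Sequence[str],
              path: str | Path | None = None, qualifying_only: bool = True,
              qualify_cols: Sequence[str] = ()) -> str:
    """Minimal VCF 4.2 export of SNP records (ALT = variant allele, INFO
    carries per-strain allele frequency and biallelic depth)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=pooldiff",
    ]
    for s in strains:
        lines.append(f'##INFO=<ID=AF_{s},Number=1,Type=Float,'
                     f'Description="Variant allele frequency (%) in {s}">')
        lines.append(f'##INFO=<ID=DP_{s},Number=1,Type=Integer,'
                     f'Description="Ref+variant read depth in {s}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for row in snps.itertuples():
        if qualifying_only and qualify_cols:
            if not any(bool(getattr(row, c)) for c in qualify_cols):
                continue
        info = ";".join(
            f"AF_{s}={getattr(row, f'{s}_freq'):.1f};DP_{s}={int(getattr(row, f'{s}_cov'))}"
            for s in strains if not np.isnan(getattr(row, f"{s}_freq")))
        lines.append("\t".join([row.contig, str(row.pos), ".", row.ref, row.var,
                                ".", "PASS", info]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
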