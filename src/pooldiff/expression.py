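"""Transcript quantification and differential transcription calling.

The comparison unit is one pooled strain versus the susceptible parent, each
strain being the sum of its technical libraries.  Expression is quantified
as RPKM (reads per kilobase of exon model per million mapped reads);
differential transcription is tested with the Audic-Claverie count test,
whose null hypothesis is that a gene's counts in the two libraries come from
the same (unknown) Poisson rate.  Under a flat prior on the rate, the
posterior predictive of count ``y`` in a library of total ``N2`` given count
``x`` in a library of total ``N1`` is

    p(y | x) = C(x+y, y) * N2**y * N1**(x+1) / (N1+N2)**(x+y+1),

the negative-binomial mass at ``y`` with size ``x+1`` and success probability
``N1/(N1+N2)``.  Genes pass if the BH-adjusted two-sided p-value is below
``alpha`` (default 1e-15) and the RPKM fold change is at least 2 in either
direction; only genes above 0.5 RPKM in at least one strain are tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc, gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LibrarySpec",
    "load_manifest",
    "load_counts",
    "compute_rpkm",
    "strain_rpkm",
    "replicate_concordance",
    "ac_pmf",
    "ac_test",
    "bh_adjust",
    "call_de",
    "overlap_summary",
]


@dataclass(frozen=True)
class LibrarySpec:
    """One sequencing library: id, strain, role, total retained mapped reads."""

    library_id: str
    strain: str
    role: str  # "parental" or "selected"
    N: int

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError(f"library {self.library_id}: N must be positive")
        if self.role not in ("parental", "selected"):
            raise ValueError(f"library {self.library_id}: role must be parental|selected")


def load_manifest(path_or_frame) -> list[LibrarySpec]:
    """Read a library manifest (TSV with columns library_id, strain, role, N)."""
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) \
        else pd.read_csv(path_or_frame, sep="\t")
    libs = [LibrarySpec(str(r.library_id), str(r.strain), str(r.role), int(r.N))
            for r in df.itertuples()]
    ids = [l.library_id for l in libs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library_id in manifest")
    return libs


def load_counts(path_or_frame) -> pd.DataFrame:
    """Read a count table (gene_id, exonic_length_bp, one column per library),
    indexed by gene_id."""
    df = path_or_frame.copy() if isinstance(path_or_frame, pd.DataFrame) \
        else pd.read_csv(path_or_frame, sep="\t")
    df = df.set_index("gene_id")
    if (df["exonic_length_bp"] < 1).any():
        raise ValueError("exonic_length_bp must be >= 1")
    lib_cols = [c for c in df.columns if c != "exonic_length_bp"]
    if (df[lib_cols] < 0).any().any():
        raise ValueError("counts must be non-negative")
    return df


def _manifest_map(libs: Iterable[LibrarySpec]) -> dict[str, LibrarySpec]:
    return {l.library_id: l for l in libs}


def compute_rpkm(counts: pd.DataFrame, libs: Sequence[LibrarySpec]) -> pd.DataFrame:
    """Per-library RPKM: count * 1e9 / (N * exonic_length_bp)."""
    by_id = _manifest_map(libs)
    lib_cols = [c for c in counts.columns if c != "exonic_length_bp"]
    missing = [c for c in lib_cols if c not in by_id]
    if missing:
        raise KeyError(f"libraries absent from manifest: {', '.join(missing)}")
    length = counts["exonic_length_bp"].to_numpy(float)
    out = {}
    for c in lib_cols:
        out[c] = counts[c].to_numpy(float) * 1e9 / (by_id[c].N * length)
    return pd.DataFrame(out, index=counts.index)


def strain_rpkm(counts: pd.DataFrame, libs: Sequence[LibrarySpec]) -> pd.DataFrame:
    """Strain-level RPKM from pooled counts and pooled library totals."""
    length = counts["exonic_length_bp"].to_numpy(float)
    out = {}
    for strain in dict.fromkeys(l.strain for l in libs):
        members = [l for l in libs if l.strain == strain]
        cols = [l.library_id for l in members]
        absent = [c for c in cols if c not in counts.columns]
        if absent:
            raise KeyError(f"count table lacks libraries: {', '.join(absent)}")
        pooled = counts[cols].sum(axis=1).to_numpy(float)
        pooled_n = sum(l.N for l in members)
        out[strain] = pooled * 1e9 / (pooled_n * length)
    return pd.DataFrame(out, index=counts.index)


def replicate_concordance(rpkm: pd.DataFrame, pair: tuple[str, str],
                          detect_min: float = 0.5) -> float:
    """Squared Pearson correlation of two technical replicates' RPKM,
    restricted to genes above the detection threshold in at least one of the
    pair.  The pipeline warns (but proceeds) below r² = 0.9."""
    a, b = rpkm[pair[0]], rpkm[pair[1]]
    keep = (a > detect_min) | (b > detect_min)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 detected genes: correlation undefined")
    r = np.corrcoef(a[keep], b[keep])[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Audic-Claverie test
# ---------------------------------------------------------------------------

def _check_ac_args(x, y, n1, n2) -> None:
    if np.any(np.asarray(x) < 0) or np.any(np.asarray(y) < 0):
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")


def log_ac_pmf(y, x, n1: float, n2: float):
    """Log posterior-predictive probability log p(y | x)."""
    _check_ac_args(x, y, n1, n2)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ln1, ln2, lsum = np.log(n1), np.log(n2), np.log(n1 + n2)
    return (gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1)
            + y * ln2 + (x + 1) * ln1 - (x + y + 1) * lsum)


def ac_pmf(y, x, n1: float, n2: float):
    """Posterior-predictive probability p(y | x) of observing ``y`` counts in
    a library of ``n2`` reads given ``x`` counts in a library of ``n1`` reads,
    under a shared Poisson rate with a flat prior."""
    out = np.exp(log_ac_pmf(y, x, n1, n2))
    return float(out) if np.isscalar(y) or np.ndim(out) == 0 else out


def _ac_tails(x, y, n1: float, n2: float):
    """(P(Y <= y), P(Y >= y)) via the regularized incomplete beta function.

    P(Y <= y) for the negative binomial with size x+1 and success probability
    p = n1/(n1+n2) is I_p(x+1, y+1); the upper tail uses the complementary
    identity I_{1-p}(y, x+1) so that tails far below 1e-15 stay accurate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = n1 / (n1 + n2)
    lower = betainc(x + 1, y + 1, p)
    upper = np.where(y > 0, betainc(np.maximum(y, 1), x + 1, 1 - p), 1.0)
    return lower, upper


def ac_test(x, y, n1: float, n2: float, alternative: str = "two-sided"):
    """Audic-Claverie p-value comparing count ``x`` (library total ``n1``)
    with count ``y`` (library total ``n2``).

    Two-sided p-values double the smaller tail (capped at 1); one-sided
    alternatives 'greater'/'less' refer to ``y`` relative to ``x``.
    """
    _check_ac_args(x, y, n1, n2)
    lower, upper = _ac_tails(x, y, n1, n2)
    if alternative == "two-sided":
        out = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    elif alternative == "greater":
        out = upper
    elif alternative == "less":
        out = lower
    else:
        raise ValueError("alternative must be two-sided|greater|less")
    return float(out) if np.ndim(out) == 0 else out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential-transcription calls
# ---------------------------------------------------------------------------

def call_de(counts: pd.DataFrame, libs: Sequence[LibrarySpec],
            alpha: float = 1e-15, fc_min: float = 2.0,
            detect_min: float = 0.5, fc_epsilon: float = 0.05,
            alternative: str = "two-sided") -> pd.DataFrame:
    """Differential-transcription calls for every selected strain versus the
    parental strain.

    A gene is *detected* if its strain-level RPKM exceeds ``detect_min`` in at
    least one strain.  For each comparison, the AC test runs on pooled strain
    counts (x = susceptible, y = selected) with pooled library totals, BH
    correction is applied across detected genes within the comparison, and
    the call is 'over'/'under' when p_adj < alpha and the fold change
    (selected vs susceptible RPKM, both floored by ``fc_epsilon``) passes
    ``fc_min`` in the corresponding direction; otherwise 'NS'.

    Returns one row per gene per comparison.
    """
    parental = [l.strain for l in libs if l.role == "parental"]
    if len(set(parental)) != 1:
        raise ValueError("exactly one parental strain is required")
    sus = parental[0]
    selected = [s for s in dict.fromkeys(l.strain for l in libs) if s != sus]
    if not selected:
        raise ValueError("at least one selected strain is required")

    srpkm = strain_rpkm(counts, libs)
    detected = (srpkm > detect_min).any(axis=1)
    if not detected.any():
        warnings.warn("no transcripts above the detection threshold")

    pooled = {}
    pooled_n = {}
    for strain in dict.fromkeys(l.strain for l in libs):
        cols = [l.library_id for l in libs if l.strain == strain]
        pooled[strain] = counts[cols].sum(axis=1).to_numpy(int)
        pooled_n[strain] = sum(l.N for l in libs if l.strain == strain)

    frames = []
    for sel in selected:
        x = pooled[sus]
        y = pooled[sel]
        p_raw = ac_test(x, y, pooled_n[sus], pooled_n[sel], alternative=alternative)
        p_raw = np.asarray(p_raw, dtype=float)
        p_adj = np.full_like(p_raw, np.nan)
        mask = detected.to_numpy()
        if mask.any():
            p_adj[mask] = bh_adjust(p_raw[mask])
        fc = (srpkm[sel].to_numpy() + fc_epsilon) / (srpkm[sus].to_numpy() + fc_epsilon)
        sig = mask & (p_adj < alpha)
        call = np.where(sig & (fc >= fc_min), "over",
                        np.where(sig & (fc <= 1.0 / fc_min), "under", "NS"))
        frames.append(pd.DataFrame({
            "gene_id": counts.index,
            "comparison": sel,
            "rpkm_sus": srpkm[sus].to_numpy(),
            "rpkm_sel": srpkm[sel].to_numpy(),
            "fc": fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "call": call,
            "detected": mask,
        }))
    return pd.concat(frames, ignore_index=True)


def overlap_summary(de: pd.DataFrame) -> pd.DataFrame:
    """Cross-comparison overlap of differential genes.

    For every pair of comparisons, counts genes differential in only one, in
    both with concordant direction (shared-over / shared-under), and in both
    with discordant direction; the shared total is the sum of the three
    shared cells.  With a single comparison, returns its totals.
    """
    comps = list(dict.fromkeys(de["comparison"]))
    calls = {
        c: de[(de["comparison"] == c) & (de["call"] != "NS")]
        .set_index("gene_id")["call"] for c in comps
    }
    rows = []
    if len(comps) == 1:
        c = comps[0]
        rows.append({"comparison_a": c, "comparison_b": "", "only_a": int(len(calls[c])),
                     "only_b": 0, "shared_over": 0, "shared_under": 0,
                     "shared_discordant": 0, "shared_total": 0})
    for a, b in combinations(comps, 2):
        ga, gb = calls[a], calls[b]
        shared = ga.index.intersection(gb.index)
        over = int(((ga[shared] == "over") & (gb[shared] == "over")).sum())
        under = int(((ga[shared] == "under") & (gb[shared] == "under")).sum())
        disc = int(len(shared) - over - under)
        rows.append({
            "comparison_a": a, "comparison_b": b,
            "only_a": int(len(ga.index.difference(gb.index))),
            "only_b": int(len(gb.index.difference(ga.index))),
            "shared_over": over, "shared_under": under,
            "shared_discordant": disc, "shared_total": over + under + disc,
        })
    return pd.DataFrame(rows)
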