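"""End-to-end orchestration: synthetic or user-supplied inputs through
quantification, differential transcription, SNP calling, effect annotation
and enrichment, with deterministic file outputs and a run manifest."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import expression, variants, effects as effects_mod, enrichment as enrich_mod
from .simulate import SimulationConfig, simulate_dataset, write_dataset
from .variants import round_half_up


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and offender."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and mode for one pipeline run.

    In synthetic mode a :class:`SimulationConfig` drives data generation (its
    seed is overridden by ``seed`` here); in real mode all input paths must
    be provided.  Threshold defaults: detection above 0.5 RPKM, adjusted
    p < 1e-15 with fold change >= 2 for differential transcription, SNP
    detection coverage > 20 with homopolymer runs > 10 masked, differential
    SNPs at summed coverage >= 30 and >= 40-point frequency difference,
    1 kb flank for near-gene assignment, enrichment at corrected p < 0.05.
    """

    outdir: str | Path = "pooldiff_out"
    mode: str = "synthetic"
    seed: int = 0
    sim: SimulationConfig | None = None
    genome: str | Path | None = None
    gff3: str | Path | None = None
    counts: str | Path | None = None
    manifest: str | Path | None = None
    pileups: dict[str, str] = field(default_factory=dict)  # strain -> path
    categories: str | Path | None = None
    detect_min: float = 0.5
    alpha_de: float = 1e-15
    fc_min: float = 2.0
    cov_detect: int = 20
    qual_min: float = 0.0
    cov_min: int = 30
    dfreq_min: float = 40.0
    flank: int = 1000
    alpha_enrich: float = 0.05
    homopolymer_min_run: int = 11

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise PipelineError(f"config: unknown mode {self.mode!r}")
        for name in ("detect_min", "alpha_de", "fc_min", "cov_detect",
                     "cov_min", "dfreq_min", "flank", "alpha_enrich"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"config: threshold {name} must be positive")
        if self.mode == "real":
            missing = [n for n in ("genome", "gff3", "counts", "manifest", "categories")
                       if getattr(self, n) is None]
            if not self.pileups:
                missing.append("pileups")
            if missing:
                raise PipelineError(
                    f"config: real mode requires inputs: {', '.join(missing)}")


def _percent(n: int, d: int) -> float:
    return round_half_up(100.0 * n / d, 1) if d else 0.0


def summary_table(de: pd.DataFrame, snps: pd.DataFrame,
                  effect_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Report-style summary.

    Expression block: per comparison and for any comparison, counts and
    percentages (one decimal, round half up) of over/under-transcribed genes
    among detected genes.  SNP block: total SNP records, qualifying SNPs and
    affected genes per comparison.  Effect block: the effect-class partition
    of differential SNPs, as percentages.
    """
    comps = list(dict.fromkeys(de["comparison"])) if len(de) else []
    n_detected = int(de[de["comparison"] == comps[0]]["detected"].sum()) if comps else 0
    expr_rows = []
    any_over, any_under, any_de = set(), set(), set()
    for c in comps:
        sub = de[de["comparison"] == c]
        over = set(sub.loc[sub["call"] == "over", "gene_id"])
        under = set(sub.loc[sub["call"] == "under", "gene_id"])
        any_over |= over
        any_under |= under
        any_de |= over | under
        expr_rows.append({
            "comparison": c, "detected": n_detected,
            "de": len(over) + len(under), "de_pct": _percent(len(over) + len(under), n_detected),
            "over": len(over), "over_pct": _percent(len(over), n_detected),
            "under": len(under), "under_pct": _percent(len(under), n_detected),
        })
    if len(comps) > 1:
        expr_rows.append({
            "comparison": "any", "detected": n_detected,
            "de": len(any_de), "de_pct": _percent(len(any_de), n_detected),
            "over": len(any_over), "over_pct": _percent(len(any_over), n_detected),
            "under": len(any_under), "under_pct": _percent(len(any_under), n_detected),
        })
    expression_summary = pd.DataFrame(expr_rows)

    qual_cols = [c for c in snps.columns if c.endswith("_qualifies")]
    snp_rows = [{"metric": "snp_records", "value": len(snps)}]
    any_qual = snps[qual_cols].any(axis=1) if qual_cols and len(snps) else \
        pd.Series(dtype=bool)
    for c in qual_cols:
        snp_rows.append({"metric": f"differential_{c.removesuffix('_qualifies')}",
                         "value": int(snps[c].sum())})
    snp_rows.append({"metric": "differential_any", "value": int(any_qual.sum())})
    if len(effect_table):
        keys = set(map(tuple, snps.loc[any_qual, ["contig", "pos"]].to_numpy())) \
            if len(snps) else set()
        affected = effect_table[
            effect_table.apply(lambda r: (r["contig"], r["pos"]) in keys, axis=1)
            & (effect_table["gene_id"] != "")]["gene_id"].nunique()
        snp_rows.append({"metric": "affected_genes", "value": int(affected)})
    snp_summary = pd.DataFrame(snp_rows)

    # effect-class partition of differential SNPs (one class per SNP; for the
    # rare multi-gene SNP the first assignment is used)
    effect_summary = pd.DataFrame(columns=["effect", "n", "pct"])
    if len(effect_table) and len(snps) and qual_cols:
        keys = set(map(tuple, snps.loc[any_qual, ["contig", "pos"]].to_numpy()))
        first = effect_table.drop_duplicates(subset=["contig", "pos"])
        diff_eff = first[first.apply(lambda r: (r["contig"], r["pos"]) in keys, axis=1)]
        counts = diff_eff["effect"].value_counts()
        total = int(counts.sum())
        effect_summary = pd.DataFrame(
            [{"effect": e, "n": int(counts.get(e, 0)),
              "pct": _percent(int(counts.get(e, 0)), total)}
             for e in effects_mod.EFFECT_LABELS])
    return {"expression": expression_summary, "snps": snp_summary,
            "effects": effect_summary}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write all outputs under ``config.outdir``.

    Returns the result bundle: counts, DE table, overlap table, SNP table,
    effect table, gene-level table, enrichment tables, burden test, summary
    tables, and (in synthetic mode) the truth tables.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    if config.mode == "synthetic":
        sim = config.sim or SimulationConfig()
        from dataclasses import replace
        sim = replace(sim, seed=config.seed)
        ds = simulate_dataset(sim)
        write_dataset(ds, outdir / "synthetic")
        contigs = ds.reference.contigs
        models = effects_mod.load_gene_models(ds.reference.gff3)
        counts = expression.load_counts(ds.counts)
        libs = expression.load_manifest(ds.manifest)
        pileups = {s: variants.load_pileup(f) for s, f in ds.pileups.items()}
        categories = ds.categories
        bundle["truth_de"] = ds.de_truth
        bundle["truth_variants"] = ds.variant_truth
        bundle["dataset"] = ds
    else:
        contigs = effects_mod.read_fasta(Path(config.genome))
        models = effects_mod.load_gene_models(Path(config.gff3))
        counts = expression.load_counts(config.counts)
        libs = expression.load_manifest(config.manifest)
        pileups = {s: variants.load_pileup(p) for s, p in config.pileups.items()}
        categories = pd.read_csv(config.categories, sep="\t")

    # --- expression ---------------------------------------------------
    try:
        rpkm = expression.compute_rpkm(counts, libs)
        for strain in dict.fromkeys(l.strain for l in libs):
            cols = [l.library_id for l in libs if l.strain == strain]
            for i in range(len(cols) - 1):
                r2 = expression.replicate_concordance(rpkm, (cols[i], cols[i + 1]),
                                                      detect_min=config.detect_min)
                if r2 <= 0.9:
                    warnings.warn(
                        f"technical replicates {cols[i]}/{cols[i+1]}: r^2 = {r2:.3f} <= 0.9")
        de = expression.call_de(counts, libs, alpha=config.alpha_de,
                                fc_min=config.fc_min, detect_min=config.detect_min)
        overlap = expression.overlap_summary(de)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(f"expression stage failed: {exc}") from exc

    # --- variants -----------------------------------------------------
    try:
        masked = variants.mask_homopolymers(contigs, min_run=config.homopolymer_min_run)
        snps = variants.detect_snps(pileups, contigs, masked,
                                    cov_detect=config.cov_detect,
                                    qual_min=config.qual_min)
        sus = next(l.strain for l in libs if l.role == "parental")
        comparisons = [(sus, s) for s in dict.fromkeys(l.strain for l in libs)
                       if s != sus]
        snps = variants.call_differential_snps(snps, comparisons,
                                               cov_min=config.cov_min,
                                               dfreq_min=config.dfreq_min)
        strains = list(dict.fromkeys(l.strain for l in libs))
        vcf_text = variants.write_vcf(
            snps, strains, qualifying_only=True,
            qualify_cols=[f"{sel}_qualifies" for _, sel in comparisons])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"variants stage failed: {exc}") from exc

    # --- effects ------------------------------------------------------
    try:
        effect_table = effects_mod.annotate_effects(snps, models, contigs,
                                                    flank=config.flank)
        gene_table = effects_mod.aggregate_by_gene(effect_table, snps, de)
    except Exception as exc:
        raise PipelineError(f"effects stage failed: {exc}") from exc

    # --- enrichment ---------------------------------------------------
    try:
        detected = set(de.loc[de["detected"] & (de["comparison"] == comparisons[0][1]),
                              "gene_id"])
        de_genes = set(de.loc[de["call"] != "NS", "gene_id"]) & detected
        enrich_de = enrich_mod.enrich(de_genes, detected, categories,
                                      alpha=config.alpha_enrich)
        snp_genes = set(gene_table.loc[gene_table["n_differential"] > 0, "gene_id"])
        enrich_snp = enrich_mod.enrich(snp_genes & detected, detected, categories,
                                       alpha=config.alpha_enrich)
        burden = enrich_mod.burden_compare(gene_table, categories)
    except Exception as exc:
        raise PipelineError(f"enrichment stage failed: {exc}") from exc

    summary = summary_table(de, snps, effect_table)

    # --- outputs ------------------------------------------------------
    float_fmt = "%.6g"
    de.to_csv(outdir / "de.tsv", sep="\t", index=False, float_format=float_fmt)
    overlap.to_csv(outdir / "overlap.tsv", sep="\t", index=False)
    snps.to_csv(outdir / "snps.tsv", sep="\t", index=False, float_format=float_fmt)
    (outdir / "differential_snps.vcf").write_text(vcf_text)
    effect_table.to_csv(outdir / "effects.tsv", sep="\t", index=False)
    gene_table.to_csv(outdir / "gene_table.tsv", sep="\t", index=False)
    enrich_de.to_csv(outdir / "enrichment_de.tsv", sep="\t", index=False,
                     float_format=float_fmt)
    enrich_snp.to_csv(outdir / "enrichment_snp.tsv", sep="\t", index=False,
                      float_format=float_fmt)
    (outdir / "burden.json").write_text(json.dumps(burden, indent=1) + "\n")
    for name, frame in summary.items():
        frame.to_csv(outdir / f"summary_{name}.tsv", sep="\t", index=False)

    from . import __version__
    manifest_cfg = {k: (str(v) if isinstance(v, Path) else v)
                    for k, v in asdict(config).items() if k not in ("sim", "outdir")}
    if config.sim or config.mode == "synthetic":
        manifest_cfg["sim"] = asdict(config.sim or SimulationConfig())
        manifest_cfg["sim"]["true_freqs"] = {
            k: list(v) for k, v in manifest_cfg["sim"]["true_freqs"].items()}
    (outdir / "run_manifest.json").write_text(
        json.dumps({"pooldiff_version": __version__, "seed": config.seed,
                    "config": manifest_cfg}, indent=1, default=str, sort_keys=True) + "\n")

    bundle.update(
        counts=counts, rpkm=rpkm, de=de, overlap=overlap, snps=snps,
        vcf=vcf_text, effects=effect_table, gene_table=gene_table,
        enrichment_de=enrich_de, enrichment_snp=enrich_snp, burden=burden,
        summary=summary, categories=categories, models=models, contigs=contigs,
    )
    return bundle
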