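"""End-to-end orchestration: annotate -> QC/segregation -> prioritize ->
burden, file-in/file-out, with per-stage accounting.

Every record dropped by a filter is logged (counts in = counts out +
counts dropped per stage) and the run is deterministic for identical
inputs: reports are byte-identical across re-runs, timestamps are
confined to the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .burden import burden_test
from .cohort import (
    AFFECTED_DEFAULT,
    GenotypeCall,
    read_ped,
    read_vcf_genotypes,
    vaf_germline_check,
)
from .consequence import ConsequenceCall, LofConfig, classify
from .io import read_scores_tsv, write_consequence_tsv
from .prioritize import (
    cross_family_recurrence,
    family_frequency_pct,
    qualifying_variants,
    write_gene_hits,
)
from .reference import CoordinateError, load_fasta, load_gff3, select_transcripts

log = logging.getLogger("famlof.pipeline")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    fasta: str
    gff3: str
    vcf: str
    ped: Optional[str] = None
    scores: Optional[str] = None
    out_dir: str = "famlof_out"
    mode: str = "discovery"  # discovery | burden
    min_families: int = 2
    min_affected_carriers: int = 0
    missense_threshold: float = 20.0
    flank: int = 5000
    n_screened_families: Optional[int] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("discovery", "burden"):
            raise ValueError(f"mode must be discovery or burden, got {self.mode!r}")
        for path in (self.fasta, self.gff3, self.vcf, self.ped, self.scores):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    summary: dict
    calls: list[ConsequenceCall] = field(default_factory=list)
    out_dir: str = ""


def _annotate(variants, transcripts, genome, flank):
    """Each variant against the transcript containing it (first match by
    gene order); variants hitting no transcript are counted and dropped."""
    calls: list[ConsequenceCall] = []
    dropped = 0
    models = sorted(transcripts.values(), key=lambda t: (t.contig, t.span[0]))
    for var in variants:
        hit = None
        for t in models:  # prefer a transcript whose span contains the variant
            lo, hi = t.span
            if t.contig == var.contig and lo <= var.pos <= hi:
                hit = t
                break
        if hit is None:  # fall back to flank proximity
            for t in models:
                lo, hi = t.span
                if t.contig == var.contig and lo - flank <= var.pos <= hi + flank:
                    hit = t
                    break
        if hit is None:
            dropped += 1
            continue
        try:
            calls.append(classify(var, hit, genome, flank=flank))
        except CoordinateError:
            dropped += 1
    return calls, dropped


def _qc_rows(geno_calls: list[GenotypeCall]) -> list[str]:
    rows = ["individual\tvariant\tallele_count\tref_depth\talt_depth\tvaf\tvaf_status"]
    for c in geno_calls:
        if c.allele_count == 1 and c.depth > 0:
            status = vaf_germline_check(c)
        else:
            status = "."
        vaf = f"{c.vaf:.3f}" if c.depth else "."
        ac = c.allele_count if c.allele_count is not None else "."
        rows.append(
            f"{c.individual_id}\t{c.variant_key}\t{ac}\t{c.ref_depth}"
            f"\t{c.alt_depth}\t{vaf}\t{status}"
        )
    return rows


def run_pipeline(config: RunConfig) -> PipelineResult:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome = load_fasta(config.fasta)
    transcripts = select_transcripts(load_gff3(config.gff3))
    variants, geno_calls = read_vcf_genotypes(config.vcf)
    scores = read_scores_tsv(config.scores) if config.scores else {}
    log.info("loaded %d transcripts, %d variants, %d genotype calls",
             len(transcripts), len(variants), len(geno_calls))
    if not variants:
        log.warning("empty VCF: producing empty reports")

    # annotate ----------------------------------------------------------
    calls, n_unplaced = _annotate(variants, transcripts, genome, config.flank)
    log.info("annotate: %d in = %d annotated + %d outside any transcript",
             len(variants), len(calls), n_unplaced)
    write_consequence_tsv(calls, out / "annotated.tsv")

    # QC ---------------------------------------------------------------
    (out / "qc.tsv").write_text("\n".join(_qc_rows(geno_calls)) + "\n")

    lof_config = LofConfig(missense_score_threshold=config.missense_threshold)
    qualifying = qualifying_variants(calls, scores, mode=config.mode, config=lof_config)
    log.info("qualifying (%s mode): %d of %d annotated variants",
             config.mode, len(qualifying), len(calls))
    gene_of = {c.variant.key: c.gene_id for c in calls}
    synonymous = {c.variant.key for c in calls if c.klass == "synonymous"}

    summary: dict = {
        "n_variants": len(variants),
        "n_annotated": len(calls),
        "n_outside_transcripts": n_unplaced,
        "n_qualifying": len(qualifying),
        "mode": config.mode,
        "genes": {},
    }

    pedigree = read_ped(config.ped) if config.ped else []
    if pedigree:
        hits = cross_family_recurrence(
            {k: gene_of[k] for k in qualifying if k in gene_of},
            geno_calls,
            pedigree,
            min_families=config.min_families,
            min_affected_carriers=config.min_affected_carriers,
        )
        write_gene_hits(hits, out / "gene_hits.tsv", out / "gene_hits.json")
        n_screened = config.n_screened_families or len(
            {ind.family_id for ind in pedigree}
        )
        summary["recurrent_genes"] = [
            {
                "gene_id": h.gene_id,
                "n_families": h.n_families,
                "families": sorted(h.families),
                "discordant_families": sorted(
                    fam
                    for fam, segs in h.segregation_by_family.items()
                    if any(s.discordant_affected for s in segs)
                ),
            }
            for h in hits
        ]
        if hits:
            top = hits[0]
            summary["family_frequency_pct"] = round(
                family_frequency_pct(top.n_families, n_screened), 1
            )
        log.info("prioritize: %d genes in >= %d families", len(hits),
                 config.min_families)

        if config.mode == "burden":
            phenos = {}
            for ind in pedigree:
                if ind.phenotype in AFFECTED_DEFAULT:
                    phenos[ind.individual_id] = "case"
                elif ind.phenotype == "unaffected":
                    phenos[ind.individual_id] = "control"
            genes = sorted({gene_of[k] for k in qualifying if k in gene_of})
            burden_rows = [
                "gene\ta\tb\tc\td\tOR\tci_low\tci_high\tp_fisher\tcalibration_OR\tbias_flag"
            ]
            for gene in genes:
                mask = {k for k in qualifying if gene_of.get(k) == gene}
                syn = {k for k in synonymous if gene_of.get(k) == gene}
                res = burden_test(geno_calls, phenos, mask, syn or None, gene_id=gene)
                a, b, c, d = res.table.cells()
                burden_rows.append(
                    f"{gene}\t{a}\t{b}\t{c}\t{d}\t{res.or_point:.2f}"
                    f"\t{res.ci_low:.2f}\t{res.ci_high:.2f}\t{res.p_fisher:.3g}"
                    f"\t{res.calibration_or if res.calibration_or is None else round(res.calibration_or, 2)}"
                    f"\t{res.bias_flag}"
                )
                summary["genes"][gene] = {
                    "table": [a, b, c, d],
                    "or": res.or_point,
                    "ci": [res.ci_low, res.ci_high],
                    "p_fisher": res.p_fisher,
                    "calibration_or": res.calibration_or,
                    "bias_flag": res.bias_flag,
                }
            (out / "burden.tsv").write_text("\n".join(burden_rows) + "\n")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return PipelineResult(summary=summary, calls=calls, out_dir=str(out))
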