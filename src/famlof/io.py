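"""Plain-text writers for the standard formats the pipeline exchanges.

Readers live next to the objects they build (:mod:`famlof.reference`
reads FASTA/GFF3, :mod:`famlof.cohort` reads PED and VCF genotypes);
writers are gathered here.  VCF output is version 4.2 with GT:AD:DP
sample fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .cohort import GenotypeCall
from .consequence import ConsequenceCall, Variant
from .reference import GenomeSequence, TranscriptModel

__all__ = [
    "write_fasta",
    "write_gff3",
    "write_vcf",
    "write_scores_tsv",
    "read_scores_tsv",
    "write_consequence_tsv",
]

_WRAP = 60

CONSEQUENCE_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "alt",
    "gene_id",
    "transcript_id",
    "class",
    "hgvs_c",
    "hgvs_p",
    "ptc_codon",
    "nmd_predicted",
    "extension_residues",
    "is_truncating",
    "note",
]


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _WRAP):
                fh.write(seq[i : i + _WRAP] + "\n")
    try:  # companion .fai index, convenient for external tools
        import pyfaidx

        pyfaidx.Faidx(str(path))
    except Exception:  # pragma: no cover - index is a convenience only
        pass


def write_gff3(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for t in transcripts:
        lo, hi = t.span
        lines.append(
            f"{t.contig}\tfamlof\tgene\t{lo}\t{hi}\t.\t{t.strand}\t.\t"
            f"ID={t.gene_id}"
        )
        lines.append(
            f"{t.contig}\tfamlof\tmRNA\t{lo}\t{hi}\t.\t{t.strand}\t.\t"
            f"ID={t.transcript_id};Parent={t.gene_id}"
        )
        for i, (s, e) in enumerate(t.exons, 1):
            lines.append(
                f"{t.contig}\tfamlof\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
            )
        for s, e in t.exons:
            cs, ce = max(s, t.cds_start_g), min(e, t.cds_end_g)
            if cs <= ce:
                lines.append(
                    f"{t.contig}\tfamlof\tCDS\t{cs}\t{ce}\t.\t{t.strand}\t0\t"
                    f"ID={t.transcript_id}.cds;Parent={t.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf(
    variants: Sequence[Variant],
    calls: Iterable[GenotypeCall],
    genome: GenomeSequence,
    path: str | Path,
    sample_order: Optional[Sequence[str]] = None,
) -> None:
    """VCF 4.2 with GT:AD:DP.  Calls are keyed by (individual, variant);
    individuals absent for a variant are written 0/0 with zero depths."""
    by_key: dict[tuple[str, str], GenotypeCall] = {}
    samples_seen: list[str] = []
    for c in calls:
        if c.individual_id not in samples_seen:
            samples_seen.append(c.individual_id)
        by_key[(c.individual_id, c.variant_key)] = c
    samples = list(sample_order) if sample_order is not None else samples_seen

    header = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for name, seq in genome.contigs.items():
        header.append(f"##contig=<ID={name},length={len(seq)}>")
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )

    body = []
    for v in sorted(variants, key=lambda v: (v.contig, v.pos, v.ref, v.alt)):
        fields = [
            v.contig,
            str(v.pos),
            v.id or ".",
            v.ref,
            v.alt,
            ".",
            "PASS",
            ".",
            "GT:AD:DP",
        ]
        for s in samples:
            c = by_key.get((s, v.key))
            if c is None:
                fields.append("0/0:0,0:0")
            elif c.allele_count is None:
                fields.append("./.:.,.:.")
            else:
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[c.allele_count]
                fields.append(f"{gt}:{c.ref_depth},{c.alt_depth}:{c.depth}")
        body.append("\t".join(fields))
    Path(path).write_text("\n".join(header + body) + "\n")


def write_scores_tsv(
    scores: Mapping[str, float], path: str | Path
) -> None:
    """Deleteriousness scores keyed by 'contig:pos:ref:alt'."""
    lines = ["contig\tpos\tref\talt\tscore"]
    for key in sorted(scores):
        contig, pos, ref, alt = key.split(":")
        lines.append(f"{contig}\t{pos}\t{ref}\t{alt}\t{scores[key]:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scores_tsv(path: str | Path) -> dict[str, float]:
    scores: dict[str, float] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        contig, pos, ref, alt, score = line.split("\t")
        scores[f"{contig}:{pos}:{ref}:{alt}"] = float(score)
    return scores


def write_consequence_tsv(
    calls: Iterable[ConsequenceCall], path: str | Path
) -> None:
    """Consequence report with a stable column order."""
    lines = ["\t".join(CONSEQUENCE_COLUMNS)]
    for c in calls:
        v = c.variant
        lines.append(
            "\t".join(
                str(x) if x is not None else "."
                for x in [
                    v.contig,
                    v.pos,
                    v.ref,
                    v.alt,
                    c.gene_id,
                    c.transcript_id,
                    c.klass,
                    c.hgvs_c or ".",
                    c.hgvs_p or ".",
                    c.ptc_codon,
                    c.nmd_predicted,
                    c.extension_residues,
                    c.is_truncating,
                    c.note or ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
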