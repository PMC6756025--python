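"""A synthetic exosome-nuclease-like worked example.

This module builds a SYNTHETIC transcript model whose exon geometry
reproduces, by construction, the coordinate arithmetic of the published
familial-myeloma *DIS3* variants, without requiring any reference
download:

* exon 13 ends at coding position 1755, so the first base of intron 13
  is c.1755+1; skipping exon 13 (coding length 86, not a multiple of 3)
  frameshifts from codon 557 with a stop 3 codons into the new frame
  (p.Arg557Argfs*3), and the premature stop lies far upstream of the
  last exon junction, so nonsense-mediated decay is predicted;
* exon 14 ends at coding position 1883 (c.1883+1 is its donor +1);
* the CDS is 2877 nt, so the native TAA stop is codon 959 and c.2875 is
  its first base; the T>C substitution there recodes the stop to Gln,
  and the engineered 3'UTR supplies 13 sense codons before the next
  in-frame stop (p.*959Glnext*14).

It is a stand-in fixture: the sequence away from the constrained
positions is random, and nothing here is the real human transcript.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consequence import Variant
from .reference import GenomeSequence, TranscriptModel, revcomp

__all__ = ["SyntheticWorkedExample", "synthetic_dis3_like"]

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

#: coding nt contributed by each exon, transcript order (sums to 2877)
_CODING_LENGTHS = [139] * 11 + [140, 86, 128, 166, 166, 166, 166, 165, 165]
_UTR5_LEN = 50
_UTR3_CODONS = 13  # sense codons before the in-frame 3'UTR stop
_INTRON_LEN = 100
_PAD = 100  # flanking sequence either side of the gene


@dataclass
class SyntheticWorkedExample:
    genome: GenomeSequence
    transcript: TranscriptModel
    splice_donor_variant: Variant  # c.1755+1G>T analogue
    stop_loss_variant: Variant  # c.2875T>C analogue
    skip_exon_tx_index: int  # 0-based transcript-order index of "exon 13"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_sense(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(SENSE_CODONS, size=n_codons))


def synthetic_dis3_like(strand: str = "+", seed: int = 959) -> SyntheticWorkedExample:
    """Build the synthetic worked-example gene (deterministic).

    ``strand='-'`` embeds the reverse complement of the same transcript,
    which must leave every transcript-oriented prediction unchanged.
    """
    rng = np.random.default_rng(seed)
    n_codons = sum(_CODING_LENGTHS) // 3  # 959 incl. stop

    codons = ["ATG"] + list(rng.choice(SENSE_CODONS, size=n_codons - 2)) + ["TAA"]
    codons[556] = "AGA"  # ref codon 557 = Arg; its first base ends exon 12
    cds = "".join(codons)
    # exon 13 covers coding offsets 1669..1754; exon 14 starts at 1755.
    # Force exon 13 to open "GA" (so ref codon 557 stays AGA) and exon 14 to
    # open GG CAA TAA. in the shifted frame: after the skip, codon 557 is
    # A+GG = Arg, 558 = CAA, 559 = TAA (the new stop, fs*3), while the
    # reference frame on exon 14 reads GGC AAT AAA (all sense).
    cds = cds[:1669] + "GA" + cds[1671:]
    cds = cds[:1755] + "GGCAATAAA" + cds[1764:]
    assert len(cds) == sum(_CODING_LENGTHS) == 2877

    utr5 = _random_seq(rng, _UTR5_LEN)
    utr3 = _random_sense(rng, _UTR3_CODONS) + "TGA" + _random_seq(rng, 15)
    introns = [
        "GT" + _random_seq(rng, _INTRON_LEN - 4) + "AG"
        for _ in range(len(_CODING_LENGTHS) - 1)
    ]

    # assemble the transcript-forward genomic region
    region_parts: list[str] = []
    exon_bounds: list[tuple[int, int]] = []  # 0-based half-open, region coords
    cursor = 0
    cds_off = 0
    for i, clen in enumerate(_CODING_LENGTHS):
        piece = cds[cds_off : cds_off + clen]
        cds_off += clen
        if i == 0:
            piece = utr5 + piece
        if i == len(_CODING_LENGTHS) - 1:
            piece = piece + utr3
        region_parts.append(piece)
        exon_bounds.append((cursor, cursor + len(piece)))
        cursor += len(piece)
        if i < len(introns):
            region_parts.append(introns[i])
            cursor += len(introns[i])
    region = "".join(region_parts)

    cds_start_r = _UTR5_LEN  # region coord of first CDS base (0-based)
    cds_end_r = exon_bounds[-1][1] - len(utr3) - 1  # last CDS base
    splice_r = exon_bounds[12][1]  # first base of intron 13 (0-based)
    stop_r = cds_end_r - 2  # first base of the stop codon

    if strand == "+":
        contig_seq = _random_seq(rng, _PAD) + region + _random_seq(rng, _PAD)
        to_g = lambda r: _PAD + r + 1  # noqa: E731
        exons = [(to_g(s), to_g(e - 1)) for s, e in exon_bounds]
        cds_lo, cds_hi = to_g(cds_start_r), to_g(cds_end_r)
        splice_g, splice_ref = to_g(splice_r), region[splice_r]
        stop_g, stop_ref = to_g(stop_r), region[stop_r]
        splice_alt, stop_alt = "T", "C"
    else:
        contig_seq = _random_seq(rng, _PAD) + revcomp(region) + _random_seq(rng, _PAD)
        L = len(region)
        to_g = lambda r: _PAD + (L - 1 - r) + 1  # noqa: E731
        exons = sorted((to_g(e - 1), to_g(s)) for s, e in exon_bounds)
        cds_lo, cds_hi = to_g(cds_end_r), to_g(cds_start_r)
        splice_g, splice_ref = to_g(splice_r), revcomp(region[splice_r])
        stop_g, stop_ref = to_g(stop_r), revcomp(region[stop_r])
        splice_alt, stop_alt = "A", "G"  # genome-forward complements of T, C

    genome = GenomeSequence({"chrS": contig_seq})
    transcript = TranscriptModel(
        transcript_id="SYN_DIS3_LIKE.1",
        gene_id="SYN_DIS3_LIKE",
        contig="chrS",
        strand=strand,
        exons=exons,
        cds_start_g=cds_lo,
        cds_end_g=cds_hi,
    )
    return SyntheticWorkedExample(
        genome=genome,
        transcript=transcript,
        splice_donor_variant=Variant("chrS", splice_g, splice_ref, splice_alt),
        stop_loss_variant=Variant("chrS", stop_g, stop_ref, stop_alt),
        skip_exon_tx_index=12,
    )
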