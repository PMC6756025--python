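"""Shared fixtures: tiny hand-built transcripts and independent oracles.

The oracles here (naive re-splicer, table-driven translator, brute-force
mutate-splice-translate classifier, hypergeometric enumeration) are
deliberately written from scratch so they share no code path with the
package implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from famlof.reference import GenomeSequence, TranscriptModel

# ---------------------------------------------------------------------------
# independent codon table (oracle)
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(cds: str) -> tuple[str, bool]:
    """Table-driven translator independent of the package path."""
    out = []
    for i in range(0, len(cds) - 2, 3):
        aa = CODON_TABLE.get(cds[i : i + 3], "X")
        if aa == "*":
            return "".join(out), True
        out.append(aa)
    return "".join(out), False


def oracle_revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def oracle_splice_cds(transcript: TranscriptModel, contig_seq: str) -> str:
    """Naive per-exon slicing + reverse complement re-splicer."""
    parts = []
    for s, e in transcript.exons:
        lo = max(s, transcript.cds_start_g)
        hi = min(e, transcript.cds_end_g)
        if lo <= hi:
            parts.append(contig_seq[lo - 1 : hi])
    cds = "".join(parts)
    return oracle_revcomp(cds) if transcript.strand == "-" else cds


def oracle_classify_cds_snv(
    transcript: TranscriptModel, contig_seq: str, gpos: int, alt: str
) -> str:
    """Brute-force classification of a CDS SNV: mutate the contig,
    re-splice, translate both alleles, diff the proteins."""
    mutated = contig_seq[: gpos - 1] + alt + contig_seq[gpos:]
    ref_cds = oracle_splice_cds(transcript, contig_seq)
    alt_cds = oracle_splice_cds(transcript, mutated)
    ref_prot, _ = oracle_translate(ref_cds)
    alt_prot, alt_stopped = oracle_translate(alt_cds)
    if alt_prot == ref_prot and alt_stopped:
        return "synonymous"
    if len(alt_prot) < len(ref_prot):
        return "stop_gain"
    if len(alt_prot) > len(ref_prot) or not alt_stopped:
        return "stop_loss"
    return "missense"


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Full hypergeometric enumeration of the two-sided Fisher p."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def hyper(k: int) -> float:
        return (
            math.comb(r1, k)
            * math.comb(n - r1, c1 - k)
            / math.comb(n, c1)
        )

    p_obs = hyper(a)
    total = 0.0
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        p = hyper(k)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


# ---------------------------------------------------------------------------
# toy transcripts
# ---------------------------------------------------------------------------

def make_gene(
    coding_exon_seqs: list[str],
    strand: str = "+",
    utr5: str = "GATTACA",
    utr3: str = "TTGGCCAATT",
    intron_len: int = 30,
    pad: int = 25,
    contig: str = "chrT",
    gene_id: str = "TOY",
    rng_seed: int = 7,
) -> tuple[GenomeSequence, TranscriptModel]:
    """Assemble a transcript from explicit coding-exon sequences.

    The concatenated coding sequences form the CDS; exon 1 additionally
    carries ``utr5`` and the last exon ``utr3``.  Introns are GT..AG.
    For strand '-', the reverse complement of the whole region is stored
    in the contig so the transcript-oriented CDS is unchanged.
    """
    rng = np.random.default_rng(rng_seed)

    def rand(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    pieces = []
    bounds = []
    cursor = 0
    for i, ex in enumerate(coding_exon_seqs):
        piece = ex
        if i == 0:
            piece = utr5 + piece
        if i == len(coding_exon_seqs) - 1:
            piece = piece + utr3
        pieces.append(piece)
        bounds.append((cursor, cursor + len(piece)))
        cursor += len(piece)
        if i < len(coding_exon_seqs) - 1:
            pieces.append("GT" + rand(intron_len - 4) + "AG")
            cursor += intron_len
    region = "".join(pieces)
    cds_lo_r = len(utr5)
    cds_hi_r = bounds[-1][1] - len(utr3) - 1

    if strand == "+":
        contig_seq = rand(pad) + region + rand(pad)
        exons = [(pad + s + 1, pad + e) for s, e in bounds]
        cds_lo, cds_hi = pad + cds_lo_r + 1, pad + cds_hi_r + 1
    else:
        L = len(region)
        contig_seq = rand(pad) + oracle_revcomp(region) + rand(pad)
        g = lambda r: pad + (L - 1 - r) + 1  # noqa: E731
        exons = sorted((g(e - 1), g(s)) for s, e in bounds)
        cds_lo, cds_hi = g(cds_hi_r), g(cds_lo_r)

    genome = GenomeSequence({contig: contig_seq})
    model = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        contig=contig,
        strand=strand,
        exons=exons,
        cds_start_g=cds_lo,
        cds_end_g=cds_hi,
    )
    return genome, model


@pytest.fixture(scope="session")
def toy_three_exon():
    """3-exon plus-strand gene, CDS 90 nt (30 codons), internal exon 33 nt."""
    ex1 = "ATG" + "GCTGAAACCGGT" * 2  # 27 nt
    ex2 = "TGTCATGATCTGGAACGTATTGCCAAGCTTATG"  # 33 nt (11 codons)
    ex3 = "GGTCATAAAGAGCTTCCCTCAGATTAA"  # 27 nt, ends TAA
    return make_gene([ex1, ex2, ex3], strand="+")


@pytest.fixture(scope="session")
def toy_three_exon_minus():
    ex1 = "ATG" + "GCTGAAACCGGT" * 2
    ex2 = "TGTCATGATCTGGAACGTATTGCCAAGCTTATG"
    ex3 = "GGTCATAAAGAGCTTCCCTCAGATTAA"
    return make_gene([ex1, ex2, ex3], strand="-")


@pytest.fixture(scope="session")
def toy_single_exon():
    """Single-exon gene: CDS ATG AAA TAA."""
    return make_gene(["ATGAAATAA"], strand="+")


@pytest.fixture(scope="session")
def reference_sim():
    """One shared synthetic reference (default study conditions, seed 1)."""
    from famlof.simulate import SimulationConfig, simulate_reference

    config = SimulationConfig(seed=1)
    genome, transcripts = simulate_reference(config)
    return config, genome, transcripts
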