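"""Variant consequence prediction on a transcript model.

Implements transcript-aware classification of single-nucleotide variants
(and simple CDS indels): synonymous / missense / stop-gain calls by codon
comparison, canonical +-1/+-2 splice-site disruption modelled as skipping of
the adjacent exon with frameshift and premature-termination-codon (PTC)
calling, nonsense-mediated decay (NMD) prediction by the 50-nt
last-exon-junction rule, and stop-loss readthrough extension into the
3'UTR.  Alleles arrive genome-forward (VCF convention) and are
reverse-complemented internally for minus-strand transcripts; HGVS-style
c. and p. names are transcript-oriented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from Bio.SeqUtils import seq3

from .reference import (
    CoordinateError,
    CPosition,
    GenomeSequence,
    TranscriptModel,
    build_cds,
    g_to_c,
    revcomp,
    translate,
)

__all__ = [
    "Variant",
    "ConsequenceCall",
    "ExonSkipResult",
    "ReadthroughResult",
    "LofConfig",
    "classify",
    "model_exon_skip",
    "predict_nmd",
    "extend_readthrough",
    "is_putative_lof",
    "variant_key",
    "split_multiallelic",
]

TRUNCATING_CLASSES = frozenset(
    {"stop_gain", "frameshift", "splice_donor", "splice_acceptor"}
)
#: classes admitted as putative loss-of-function regardless of score
LOF_CLASSES = TRUNCATING_CLASSES | {"stop_loss"}


class RefMismatchError(ValueError):
    """Variant REF allele disagrees with the reference genome."""


class MultiallelicError(ValueError):
    """Multi-allelic records must be split into biallelic ones first."""


@dataclass(frozen=True)
class Variant:
    """A biallelic variant with genome-forward alleles (VCF convention)."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("REF and ALT must differ")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def variant_key(contig: str, pos: int, ref: str, alt: str) -> str:
    return f"{contig}:{pos}:{ref}:{alt}"


def split_multiallelic(
    contig: str, pos: int, ref: str, alts: list[str], vid: Optional[str] = None
) -> list[Variant]:
    """Split a multi-allelic VCF record into biallelic variants."""
    return [Variant(contig, pos, ref, a, vid) for a in alts]


@dataclass
class ExonSkipResult:
    """Protein-level outcome of removing one internal coding exon."""

    resolved: bool
    mutant_protein: Optional[str] = None
    first_affected_codon: Optional[int] = None
    ptc_codon: Optional[int] = None
    frame_shifted: Optional[bool] = None
    nmd_predicted: Optional[bool] = None
    hgvs_p: Optional[str] = None
    note: str = ""


@dataclass
class ReadthroughResult:
    """Outcome of recoding the native stop and translating into the 3'UTR."""

    substituted_residue: str
    extension_residues: int
    new_stop_found: bool

    @property
    def ext_label(self) -> str:
        """HGVS ext*N with N counting the substituted residue (ext*14 for
        13 additional amino acids)."""
        if not self.new_stop_found:
            return "ext*?"
        return f"ext*{self.extension_residues + 1}"


@dataclass
class ConsequenceCall:
    variant: Variant
    transcript_id: str
    gene_id: str
    klass: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    ptc_codon: Optional[int] = None
    nmd_predicted: Optional[bool] = None
    extension_residues: Optional[int] = None
    is_truncating: bool = False
    note: str = ""


@dataclass
class LofConfig:
    """Qualifying-variant mask settings.

    ``missense_score_threshold`` is the inclusive deleteriousness-score
    cutoff (CADD-like scale; default 20) above which a missense variant
    qualifies in burden mode.
    """

    missense_score_threshold: float = 20.0


def _oriented(allele: str, strand: str) -> str:
    return revcomp(allele) if strand == "-" else allele


def _aa3(residue: str) -> str:
    if residue == "*":
        return "*"
    if residue == "X":
        return "Xaa"
    return seq3(residue)


def _codon_aa(codon: str) -> str:
    """Single-codon translation; '*' for a stop codon."""
    aa, _ = translate(codon + "GGG")  # pad so a stop codon is detectable
    return aa[:1] or "*"


def _validate_ref(variant: Variant, genome: GenomeSequence) -> None:
    ref_obs = genome.fetch(
        variant.contig, variant.pos, variant.pos + len(variant.ref) - 1
    )
    if ref_obs != variant.ref.upper():
        raise RefMismatchError(
            f"{variant.key}: genome has {ref_obs!r}, variant REF is {variant.ref!r}"
        )


# ---------------------------------------------------------------------------
# NMD
# ---------------------------------------------------------------------------

def predict_nmd(transcript: TranscriptModel, ptc_codon: int) -> bool:
    """50-nt rule: a PTC triggers NMD iff its first nucleotide lies at
    least 50 nt upstream of the last exon-exon junction in mRNA
    coordinates.  Single-exon transcripts never trigger NMD.
    """
    exons = transcript.exons_tx_order()
    if len(exons) == 1:
        return False
    ptc_tx = transcript.cds_tx_start + 3 * (ptc_codon - 1)
    last_exon_len = exons[-1][1] - exons[-1][0] + 1
    last_junction_tx = transcript.tx_length - last_exon_len
    return last_junction_tx - ptc_tx >= 50


# ---------------------------------------------------------------------------
# exon skipping
# ---------------------------------------------------------------------------

def _skipped_transcript(
    transcript: TranscriptModel, tx_exon_index: int
) -> TranscriptModel:
    exons_tx = transcript.exons_tx_order()
    kept = [e for i, e in enumerate(exons_tx) if i != tx_exon_index]
    return TranscriptModel(
        transcript_id=transcript.transcript_id + f"_skip{tx_exon_index + 1}",
        gene_id=transcript.gene_id,
        contig=transcript.contig,
        strand=transcript.strand,
        exons=sorted(kept),
        cds_start_g=transcript.cds_start_g,
        cds_end_g=transcript.cds_end_g,
    )


def model_exon_skip(
    transcript: TranscriptModel,
    tx_exon_index: int,
    genome: GenomeSequence,
) -> ExonSkipResult:
    """Remove one internal coding exon from the spliced CDS and re-translate.

    ``tx_exon_index`` is 0-based in transcript order.  The first affected
    codon is the first codon whose underlying nucleotides change, reported
    even when its encoded residue is coincidentally preserved; the
    frameshift stop offset counts that codon as 1 (p.Xaa557Xaafs*3 means a
    stop two codons after the anchor).  Terminal exons are flagged
    unresolved rather than computed.
    """
    n_exons = len(transcript.exons)
    coding = transcript.coding_exon_indices()
    if tx_exon_index in (0, n_exons - 1) or tx_exon_index in (
        coding[0],
        coding[-1],
    ):
        return ExonSkipResult(resolved=False, note="terminal exon, effect unresolved")
    skip_len = transcript.coding_length_of_exon(tx_exon_index)
    if skip_len == 0:
        return ExonSkipResult(resolved=False, note="non-coding exon")

    cds = build_cds(transcript, genome)
    offset_before = sum(
        transcript.coding_length_of_exon(i) for i in range(tx_exon_index)
    )
    mutant_cds = cds[:offset_before] + cds[offset_before + skip_len :]
    frame_shifted = skip_len % 3 != 0
    first_affected = offset_before // 3 + 1

    protein, _ = translate(cds)
    mutant_protein, stop_reached = translate(mutant_cds)

    ptc: Optional[int] = None
    if stop_reached and 3 * len(mutant_protein) < len(mutant_cds) - 3:
        ptc = len(mutant_protein) + 1

    nmd = None
    if ptc is not None:
        nmd = predict_nmd(_skipped_transcript(transcript, tx_exon_index), ptc)

    hgvs_p = _skip_hgvs_p(
        protein, mutant_protein, first_affected, ptc, frame_shifted, skip_len
    )
    return ExonSkipResult(
        resolved=True,
        mutant_protein=mutant_protein,
        first_affected_codon=first_affected,
        ptc_codon=ptc,
        frame_shifted=frame_shifted,
        nmd_predicted=nmd,
        hgvs_p=hgvs_p,
    )


def _skip_hgvs_p(
    protein: str,
    mutant_protein: str,
    first_affected: int,
    ptc: Optional[int],
    frame_shifted: bool,
    skip_len: int,
) -> str:
    ref_aa = protein[first_affected - 1] if first_affected <= len(protein) else "?"
    if frame_shifted:
        new_aa = (
            mutant_protein[first_affected - 1]
            if first_affected <= len(mutant_protein)
            else "*"
        )
        if ptc is not None:
            if ptc == first_affected:
                return f"p.{_aa3(ref_aa)}{first_affected}*"
            return (
                f"p.{_aa3(ref_aa)}{first_affected}{_aa3(new_aa)}"
                f"fs*{ptc - first_affected + 1}"
            )
        return f"p.{_aa3(ref_aa)}{first_affected}{_aa3(new_aa)}fs*?"
    n_del = skip_len // 3
    last = first_affected + n_del - 1
    last_aa = protein[last - 1] if last <= len(protein) else "?"
    if n_del == 1:
        return f"p.{_aa3(ref_aa)}{first_affected}del"
    return f"p.{_aa3(ref_aa)}{first_affected}_{_aa3(last_aa)}{last}del"


# ---------------------------------------------------------------------------
# stop-loss readthrough
# ---------------------------------------------------------------------------

def extend_readthrough(
    variant: Variant,
    transcript: TranscriptModel,
    genome: GenomeSequence,
) -> ReadthroughResult:
    """Recode the native stop codon per the variant and translate in frame
    into the spliced 3'UTR until the next stop.

    ``extension_residues`` counts residues after the substituted one; the
    HGVS label ext*N uses N = extension_residues + 1 (the substituted
    residue occupies the former stop position).
    """
    if not variant.is_snv:
        raise ValueError("readthrough extension is defined for SNVs only")
    cds = build_cds(transcript, genome)
    L = len(cds)
    cpos = g_to_c(transcript, variant.pos)
    if cpos.region != "cds" or cpos.coding_offset <= L - 3:
        raise ValueError(f"{variant.key} does not overlap the stop codon")
    i = cpos.coding_offset - (L - 3) - 1  # 0..2 within the stop codon
    alt_t = _oriented(variant.alt, transcript.strand)
    stop = cds[-3:]
    mutant_codon = stop[:i] + alt_t + stop[i + 1 :]
    sub, reached = translate(mutant_codon + "TAA")  # pad so translate() accepts
    if sub == "":  # still a stop codon
        raise ValueError(f"{variant.key} leaves the stop codon intact")

    utr3 = transcript.spliced_sequence(genome)[transcript.cds_tx_end + 1 :]
    ext = 0
    found = False
    for j in range(0, len(utr3) - 2, 3):
        codon = utr3[j : j + 3]
        aa, stopped = translate(codon + "TAA")
        if aa == "":
            found = True
            break
        ext += 1
    return ReadthroughResult(sub, ext, found)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(
    variant: Variant,
    transcript: TranscriptModel,
    genome: GenomeSequence,
    flank: int = 5000,
    _cds: Optional[str] = None,
) -> ConsequenceCall:
    """Classify one biallelic variant against one transcript.

    SNVs at intronic offsets +1/+2 are splice-donor, -1/-2 splice-acceptor
    calls; these additionally run :func:`model_exon_skip` on the adjacent
    exon and attach its PTC/NMD results.  CDS SNVs are compared codon-wise;
    an SNV converting the native stop into a sense codon is a stop-loss
    with readthrough extension attached.  CDS indels are frameshift when
    the length change is not a multiple of 3, otherwise in-frame ("other").
    """
    if "," in variant.alt:
        raise MultiallelicError(f"{variant.key}: split multi-allelic records first")
    _validate_ref(variant, genome)

    cds = _cds if _cds is not None else build_cds(transcript, genome)
    L = len(cds)
    call = ConsequenceCall(
        variant=variant,
        transcript_id=transcript.transcript_id,
        gene_id=transcript.gene_id,
        klass="other",
    )
    if not variant.is_snv:
        return _classify_indel(variant, transcript, genome, cds, call, flank)

    cpos = g_to_c(transcript, variant.pos, flank=flank)
    ref_t = _oriented(variant.ref, transcript.strand)
    alt_t = _oriented(variant.alt, transcript.strand)
    call.hgvs_c = f"c.{transcript.format_c(cpos)}{ref_t}>{alt_t}"

    if cpos.region == "intron":
        return _classify_intronic(variant, transcript, genome, cpos, call)
    if cpos.region in ("utr5", "utr3"):
        call.klass = cpos.region
        call.hgvs_p = "p.?"
        return call

    # exonic CDS SNV
    off0 = cpos.coding_offset - 1
    codon_i, within = divmod(off0, 3)
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    mutant = codon[:within] + alt_t + codon[within + 1 :]
    last_codon = L // 3 - 1
    if codon_i == last_codon:
        mut_aa, _ = translate(mutant + "TAA")
        if mut_aa == "":
            call.klass = "synonymous"
            call.hgvs_p = f"p.*{codon_i + 1}="
            return call
        call.klass = "stop_loss"
        rt = extend_readthrough(variant, transcript, genome)
        call.extension_residues = rt.extension_residues
        call.hgvs_p = f"p.*{codon_i + 1}{_aa3(rt.substituted_residue)}{rt.ext_label}"
        return call

    ref_aa = _codon_aa(codon)
    mut_aa = _codon_aa(mutant)
    pos_p = codon_i + 1
    if mut_aa == "*":
        call.klass = "stop_gain"
        call.hgvs_p = f"p.{_aa3(ref_aa)}{pos_p}*"
        call.ptc_codon = pos_p
        call.nmd_predicted = predict_nmd(transcript, pos_p)
        call.is_truncating = True
    elif mut_aa == ref_aa:
        call.klass = "synonymous"
        call.hgvs_p = f"p.{_aa3(ref_aa)}{pos_p}="
    else:
        call.klass = "missense"
        call.hgvs_p = f"p.{_aa3(ref_aa)}{pos_p}{_aa3(mut_aa)}"
    return call


def _classify_intronic(
    variant: Variant,
    transcript: TranscriptModel,
    genome: GenomeSequence,
    cpos: CPosition,
    call: ConsequenceCall,
) -> ConsequenceCall:
    off = cpos.intron_offset
    if abs(off) > 2:
        call.klass = "intronic"
        call.hgvs_p = "p.?"
        return call
    call.klass = "splice_donor" if off > 0 else "splice_acceptor"
    call.is_truncating = True
    anchor_tx = transcript.cds_tx_start + (
        cpos.coding_offset - 1 if cpos.coding_offset > 0 else cpos.coding_offset
    )
    exon_idx = transcript.exon_of_tx_index(anchor_tx)
    skip = model_exon_skip(transcript, exon_idx, genome)
    if skip.resolved:
        call.ptc_codon = skip.ptc_codon
        call.nmd_predicted = skip.nmd_predicted
        call.hgvs_p = skip.hgvs_p or "p.?"
        call.note = f"modelled as skip of exon {exon_idx + 1}"
    else:
        call.hgvs_p = "p.?"
        call.note = skip.note
    return call


def _classify_indel(
    variant: Variant,
    transcript: TranscriptModel,
    genome: GenomeSequence,
    cds: str,
    call: ConsequenceCall,
    flank: int,
) -> ConsequenceCall:
    # anchor on the first changed base after left-trimming the shared prefix
    ref, alt = variant.ref, variant.alt
    shared = 0
    while shared < min(len(ref), len(alt)) and ref[shared] == alt[shared]:
        shared += 1
    start = variant.pos + min(shared, len(ref) - 1)
    try:
        cpos = g_to_c(transcript, start, flank=flank)
    except CoordinateError:
        call.klass = "other"
        return call
    call.hgvs_c = f"c.{transcript.format_c(cpos)}{ref}>{alt}"
    if cpos.region != "cds":
        call.klass = cpos.region if cpos.region != "intron" else "intronic"
        call.hgvs_p = "p.?"
        return call
    delta = len(alt) - len(ref)
    if delta % 3 != 0:
        call.klass = "frameshift"
        call.is_truncating = True
        first_affected = (cpos.coding_offset - 1) // 3 + 1
        protein, _ = translate(cds)
        ref_aa = (
            protein[first_affected - 1] if first_affected <= len(protein) else "?"
        )
        call.hgvs_p = f"p.{_aa3(ref_aa)}{first_affected}fs"
    else:
        call.klass = "other"
        call.hgvs_p = "p.?"
        call.note = "in-frame indel"
    return call


# ---------------------------------------------------------------------------
# qualifying-variant gate
# ---------------------------------------------------------------------------

def is_putative_lof(
    call: ConsequenceCall,
    deleteriousness_score: Optional[float] = None,
    config: Optional[LofConfig] = None,
) -> bool:
    """Putative loss-of-function gate used by the burden mask.

    Truncating classes and stop-loss always qualify; missense qualifies
    iff its deleteriousness score meets the inclusive threshold; a missing
    missense score disqualifies with a warning.  The class gate precedes
    the score: a synonymous variant never qualifies regardless of score.
    """
    config = config or LofConfig()
    if call.klass in LOF_CLASSES:
        return True
    if call.klass == "missense":
        if deleteriousness_score is None:
            warnings.warn(
                f"{call.variant.key}: missense without deleteriousness score; "
                "treated as non-qualifying",
                stacklevel=2,
            )
            return False
        return deleteriousness_score >= config.missense_score_threshold
    return False
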