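"""Reference contigs and transcript models: coordinate arithmetic between
genomic and CDS-relative (c.) space, spliced CDS extraction, and translation.

Conventions
-----------
* VCF and GFF3 coordinates are 1-based inclusive on input and in every
  reported position; internal interval arithmetic is 0-based half-open.
* ``exons`` are stored sorted by genomic position regardless of strand;
  transcript-order iteration reverses them for minus-strand models.
* ``cds_start_g``/``cds_end_g`` are the genomic bounds (lowest/highest
  genomic position) of the translated region *including* the stop codon.
* c. numbering follows HGVS: coding positions 1..L, 5'UTR positions are
  negative, 3'UTR positions are ``*k`` (stored internally as ``L + k``),
  intronic positions carry a signed offset from the nearest exonic base
  (donor side ``+k``, acceptor side ``-k``).
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "CPosition",
    "CoordinateError",
    "revcomp",
    "build_cds",
    "translate",
    "g_to_c",
    "c_to_g",
    "load_fasta",
    "load_gff3",
    "select_transcripts",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: default reach, in bp beyond the transcript span, within which genomic
#: positions are still mapped (labelled as flank offsets) rather than rejected
DEFAULT_FLANK = 5000


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """A genomic or c. position falls outside the addressable range."""


@dataclass
class GenomeSequence:
    """In-memory reference: contig name -> uppercase nucleotide string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
        self.contigs = {n: s.upper() for n, s in self.contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        return load_fasta(path)

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self._get(contig))

    def _get(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise CoordinateError(f"contig {contig!r} not in genome") from None

    def fetch(self, contig: str, start: int, end: int) -> str:
        """1-based inclusive slice [start, end]."""
        seq = self._get(contig)
        if start < 1 or end > len(seq) or start > end:
            raise CoordinateError(
                f"{contig}:{start}-{end} outside contig bounds (1-{len(seq)})"
            )
        return seq[start - 1 : end]

    def base(self, contig: str, pos: int) -> str:
        return self.fetch(contig, pos, pos)


@dataclass(frozen=True)
class CPosition:
    """A transcript-relative coordinate in HGVS c. space.

    ``coding_offset`` is the anchor: 1..L within the CDS, <= 0 for 5'UTR
    (c.-k stored as -k) and > L for 3'UTR (c.*k stored as L + k).
    ``intron_offset`` is 0 for exonic positions; +k / -k for intronic
    positions written c.N+k / c.N-k.
    """

    coding_offset: int
    intron_offset: int = 0
    region: str = "cds"  # cds | intron | utr5 | utr3

    def __post_init__(self) -> None:
        if (self.intron_offset != 0) != (self.region == "intron"):
            raise ValueError("intron_offset must be nonzero iff region == 'intron'")
        if self.coding_offset == 0:
            raise ValueError("coding_offset 0 does not exist in c. numbering")


@dataclass
class TranscriptModel:
    """Strand-aware exon/CDS structure of one transcript on one contig."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted by genomic start
    cds_start_g: int
    cds_end_g: int
    _tx_pos: list[int] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]
    _g_to_tx: dict = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 >= s2:
                raise ValueError("exons overlap or touch")
        for s, e in exons:
            if s > e or s < 1:
                raise ValueError(f"bad exon interval ({s}, {e})")
        self.exons = exons
        if not any(s <= self.cds_start_g <= e for s, e in exons) or not any(
            s <= self.cds_end_g <= e for s, e in exons
        ):
            raise ValueError("CDS bounds fall outside exons")
        self._index()

    # -- internal indexes ------------------------------------------------
    def _index(self) -> None:
        pos: list[int] = []
        for s, e in self.exons:
            pos.extend(range(s, e + 1))
        if self.strand == "-":
            pos.reverse()
        self._tx_pos = pos
        self._g_to_tx = {g: i for i, g in enumerate(pos)}

    # -- derived geometry ------------------------------------------------
    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tx_length(self) -> int:
        return len(self._tx_pos)

    def exons_tx_order(self) -> list[tuple[int, int]]:
        return self.exons[::-1] if self.strand == "-" else list(self.exons)

    @property
    def cds_tx_start(self) -> int:
        """0-based transcript index of the first CDS base."""
        g = self.cds_start_g if self.strand == "+" else self.cds_end_g
        return self._g_to_tx[g]

    @property
    def cds_tx_end(self) -> int:
        """0-based transcript index of the last CDS base (incl. stop)."""
        g = self.cds_end_g if self.strand == "+" else self.cds_start_g
        return self._g_to_tx[g]

    @property
    def cds_length(self) -> int:
        return self.cds_tx_end - self.cds_tx_start + 1

    def coding_length_of_exon(self, tx_exon_index: int) -> int:
        """Number of CDS bases contributed by the exon (transcript order)."""
        s, e = self.exons_tx_order()[tx_exon_index]
        lo, hi = max(s, self.cds_start_g), min(e, self.cds_end_g)
        return max(0, hi - lo + 1)

    def coding_exon_indices(self) -> list[int]:
        return [
            i
            for i in range(len(self.exons))
            if self.coding_length_of_exon(i) > 0
        ]

    def exon_of_tx_index(self, tx_index: int) -> int:
        """Transcript-order exon index containing a transcript position."""
        cum = 0
        for i, (s, e) in enumerate(self.exons_tx_order()):
            cum += e - s + 1
            if tx_index < cum:
                return i
        raise CoordinateError(f"tx index {tx_index} beyond transcript")

    # -- sequence --------------------------------------------------------
    def spliced_sequence(self, genome: GenomeSequence) -> str:
        parts = [genome.fetch(self.contig, s, e) for s, e in self.exons]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def validate(self, genome: GenomeSequence) -> list[str]:
        """Check CDS sanity; violations are reported, not fatal."""
        issues: list[str] = []
        cds = build_cds(self, genome)
        if len(cds) % 3 != 0:
            issues.append(f"CDS length {len(cds)} not a multiple of 3")
        if not cds.startswith("ATG"):
            issues.append("CDS does not begin with ATG")
        if len(cds) >= 3 and cds[-3:] not in ("TAA", "TAG", "TGA"):
            issues.append("CDS does not end with a stop codon")
        return issues

    def format_c(self, cpos: CPosition) -> str:
        """Render a CPosition in HGVS c. anchor notation (without 'c.')."""
        off = cpos.coding_offset
        if off <= 0:
            base = str(off)
        elif off > self.cds_length:
            base = f"*{off - self.cds_length}"
        else:
            base = str(off)
        if cpos.intron_offset > 0:
            base += f"+{cpos.intron_offset}"
        elif cpos.intron_offset < 0:
            base += str(cpos.intron_offset)
        return base


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_cds(transcript: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced, strand-oriented coding sequence (includes the stop codon)."""
    if transcript.contig not in genome:
        raise CoordinateError(f"contig {transcript.contig!r} not in genome")
    parts = []
    for s, e in transcript.exons:
        lo, hi = max(s, transcript.cds_start_g), min(e, transcript.cds_end_g)
        if lo <= hi:
            parts.append(genome.fetch(transcript.contig, lo, hi))
    seq = "".join(parts)
    return revcomp(seq) if transcript.strand == "-" else seq


def translate(cds: str) -> tuple[str, bool]:
    """Standard-table translation up to (not including) the first stop.

    Returns ``(residues, stop_reached)``.  Codons containing non-ACGT
    letters translate to ``X`` with a warning.  Trailing partial codons
    are ignored.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    usable = cds[: len(cds) // 3 * 3].upper()
    aa = str(Seq(usable).translate())
    if "X" in aa.split("*", 1)[0]:
        warnings.warn("non-ACGT codon translated as 'X'", stacklevel=2)
    stop_reached = "*" in aa
    return aa.split("*", 1)[0], stop_reached


def _tx_to_coding_offset(transcript: TranscriptModel, tx_index: int) -> int:
    rel = tx_index - transcript.cds_tx_start
    return rel + 1 if rel >= 0 else rel


def _coding_offset_to_tx(transcript: TranscriptModel, coding_offset: int) -> int:
    rel = coding_offset - 1 if coding_offset > 0 else coding_offset
    tx = transcript.cds_tx_start + rel
    if tx < 0 or tx >= transcript.tx_length:
        raise CoordinateError(
            f"coding offset {coding_offset} beyond transcript bounds"
        )
    return tx


def g_to_c(
    transcript: TranscriptModel,
    gpos: int,
    flank: int = DEFAULT_FLANK,
) -> CPosition:
    """Map a genomic position to c. space, strand-aware.

    Exonic positions get region cds/utr5/utr3 with a zero intron offset;
    intronic positions are anchored to the nearest exonic base (donor side
    positive, acceptor side negative, ties to the donor side).  Positions
    up to ``flank`` bp beyond the transcript span are anchored to the
    terminal exonic base and labelled ``intron`` (flank offsets).
    """
    idx = transcript._g_to_tx.get(gpos)
    L = transcript.cds_length
    if idx is not None:
        off = _tx_to_coding_offset(transcript, idx)
        if off <= 0:
            return CPosition(off, 0, "utr5")
        if off > L:
            return CPosition(off, 0, "utr3")
        return CPosition(off, 0, "cds")

    lo, hi = transcript.span
    if gpos < lo - flank or gpos > hi + flank:
        raise CoordinateError(
            f"{transcript.contig}:{gpos} outside span {lo}-{hi} +/- {flank}"
        )

    # nearest exonic genomic neighbours
    starts = [s for s, _ in transcript.exons]
    ends = [e for _, e in transcript.exons]
    i = bisect.bisect_right(ends, gpos)  # exon index after gpos (genomic)
    prev_g = ends[i - 1] if i > 0 else None
    next_g = starts[i] if i < len(starts) else None

    sgn = 1 if transcript.strand == "+" else -1
    best: tuple[int, int] | None = None  # (signed intron offset, anchor tx)
    best_dist = None
    for ng in (prev_g, next_g):
        if ng is None:
            continue
        dist = abs(gpos - ng)
        upstream = sgn * ng < sgn * gpos  # anchor is transcript-upstream
        offset = dist if upstream else -dist
        if (
            best_dist is None
            or dist < best_dist
            or (dist == best_dist and offset > 0)
        ):
            best_dist = dist
            best = (offset, transcript._g_to_tx[ng])
    assert best is not None
    offset, anchor_tx = best
    return CPosition(_tx_to_coding_offset(transcript, anchor_tx), offset, "intron")


def c_to_g(transcript: TranscriptModel, cpos: CPosition) -> int:
    """Inverse of :func:`g_to_c` on its image."""
    anchor_tx = _coding_offset_to_tx(transcript, cpos.coding_offset)
    g = transcript._tx_pos[anchor_tx]
    if cpos.intron_offset == 0:
        return g
    sgn = 1 if transcript.strand == "+" else -1
    return g + sgn * cpos.intron_offset


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def load_fasta(path: str | Path) -> GenomeSequence:
    """Read a multi-contig FASTA into memory."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    contigs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return GenomeSequence(contigs)


def load_gff3(path: str | Path) -> list[TranscriptModel]:
    """Read gene/mRNA/exon/CDS features from a GFF3 file.

    Strict on coordinate validity; unknown attributes are ignored.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (f.start, f.end)
            for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        if not exons or not cds:
            continue
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0] if parents else mrna.id
        models.append(
            TranscriptModel(
                transcript_id=mrna.id,
                gene_id=gene_id,
                contig=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_start_g=cds[0][0],
                cds_end_g=cds[-1][1],
            )
        )
    return models


def select_transcripts(
    models: Iterable[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """One model per gene; ties broken by longest CDS then transcript id."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.cds_length > cur.cds_length
            or (m.cds_length == cur.cds_length and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    return best
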