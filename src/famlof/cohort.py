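"""Pedigrees, depth-resolved genotypes, germline QC and segregation.

PED dialect: 6 tab-separated columns (family, individual, father, mother,
sex, phenotype) with 0 for a missing parent and extended phenotype codes
0/-9 unknown, 1 unaffected, 2 MM, 3 MGUS, 4 other haematological
condition, 5 amyloidosis.  "Affected" for segregation tallies means
MM or MGUS by default (other conditions are reported but not counted),
matching a screen whose phenotype of interest is the myeloma spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

from scipy.stats import binomtest

__all__ = [
    "Individual",
    "GenotypeCall",
    "SegregationSummary",
    "PHENOTYPE_CODES",
    "AFFECTED_DEFAULT",
    "read_ped",
    "write_ped",
    "read_vcf_genotypes",
    "vaf_germline_check",
    "platform_concordance",
    "mendelian_check",
    "segregation",
]

PHENOTYPE_CODES = {
    "0": "unknown",
    "-9": "unknown",
    "1": "unaffected",
    "2": "MM",
    "3": "MGUS",
    "4": "other_heme",
    "5": "amyloidosis",
}
_CODE_OF = {v: k for k, v in PHENOTYPE_CODES.items() if k != "-9"}

#: phenotypes counted as affected in segregation tallies
AFFECTED_DEFAULT = frozenset({"MM", "MGUS"})

PLATFORMS = ("wes", "targeted", "sanger", "array", "simulated")


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "0"  # 1 male, 2 female, 0 unknown
    phenotype: str = "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class GenotypeCall:
    """Per-individual allele count with read depths and platform tag."""

    individual_id: str
    variant_key: str
    allele_count: Optional[int]  # 0/1/2 or None for missing
    ref_depth: int = 0
    alt_depth: int = 0
    platform: str = "wes"

    def __post_init__(self) -> None:
        if self.allele_count not in (None, 0, 1, 2):
            raise ValueError(f"allele_count {self.allele_count!r} invalid")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("read depths must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.depth if self.depth else float("nan")


@dataclass
class SegregationSummary:
    variant_key: str
    family_id: str
    affected_carriers: int = 0
    affected_genotyped: int = 0
    unaffected_carriers: int = 0
    unaffected_genotyped: int = 0
    other_carriers: int = 0
    other_genotyped: int = 0
    mendelian_errors: int = 0
    discordant_affected: bool = False


# ---------------------------------------------------------------------------
# PED I/O
# ---------------------------------------------------------------------------

def read_ped(path: str | Path) -> list[Individual]:
    individuals: list[Individual] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 6:
            raise ValueError(f"PED line has {len(fields)} fields, need 6: {raw!r}")
        fam, iid, father, mother, sex, pheno = fields[:6]
        individuals.append(
            Individual(
                individual_id=iid,
                family_id=fam,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=sex,
                phenotype=PHENOTYPE_CODES.get(pheno, "unknown"),
            )
        )
    _check_parent_refs(individuals)
    return individuals


def _check_parent_refs(individuals: Iterable[Individual]) -> None:
    by_family: dict[str, set[str]] = {}
    for ind in individuals:
        by_family.setdefault(ind.family_id, set()).add(ind.individual_id)
    for ind in individuals:
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None and pid not in by_family[ind.family_id]:
                raise ValueError(
                    f"{ind.individual_id}: parent {pid} not in family {ind.family_id}"
                )


def write_ped(individuals: Iterable[Individual], path: str | Path) -> None:
    lines = []
    for ind in individuals:
        lines.append(
            "\t".join(
                [
                    ind.family_id,
                    ind.individual_id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    ind.sex,
                    _CODE_OF.get(ind.phenotype, "0"),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_vcf_genotypes(
    path: str | Path, platform: str = "wes"
) -> tuple[list, list[GenotypeCall]]:
    """Read biallelic sites from a VCF, consuming GT/AD/DP.

    Returns (variants, genotype calls).  Multi-allelic records raise; a
    split utility exists in :mod:`famlof.consequence`.
    """
    from cyvcf2 import VCF

    from .consequence import MultiallelicError, Variant

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[Variant] = []
    calls: list[GenotypeCall] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise MultiallelicError(
                f"{rec.CHROM}:{rec.POS}: multi-allelic record; split first"
            )
        var = Variant(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], rec.ID)
        variants.append(var)
        gts = rec.genotypes  # [allele1, allele2, phased]
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        for si, sample in enumerate(samples):
            a1, a2 = gts[si][0], gts[si][1]
            if a1 < 0 or a2 < 0:
                ac: Optional[int] = None
            else:
                ac = int(a1 > 0) + int(a2 > 0)
            rd = int(ad[si][0]) if ad is not None and ad[si][0] >= 0 else 0
            alt_d = (
                int(ad[si][1])
                if ad is not None and len(ad[si]) > 1 and ad[si][1] >= 0
                else 0
            )
            calls.append(
                GenotypeCall(
                    individual_id=sample,
                    variant_key=var.key,
                    allele_count=ac,
                    ref_depth=rd,
                    alt_depth=alt_d,
                    platform=platform,
                )
            )
    vcf.close()
    return variants, calls


# ---------------------------------------------------------------------------
# germline QC
# ---------------------------------------------------------------------------

def vaf_germline_check(
    call: GenotypeCall, alpha: float = 0.01, min_depth: int = 10
) -> str:
    """Exact two-sided binomial test of the heterozygous VAF against 0.5.

    Returns ``germline_consistent`` when p >= alpha (the allele balance is
    compatible with a germline heterozygote), ``inconsistent`` otherwise,
    or ``insufficient_depth`` below ``min_depth`` total reads.
    """
    if call.allele_count != 1:
        raise ValueError("VAF germline check applies to heterozygous calls")
    depth = call.depth
    if depth == 0:
        raise ValueError("zero read depth")
    if depth < min_depth:
        return "insufficient_depth"
    p = binomtest(call.alt_depth, depth, 0.5).pvalue
    return "germline_consistent" if p >= alpha else "inconsistent"


def platform_concordance(calls: Iterable[GenotypeCall]) -> str:
    """Concordance of one individual's calls for one variant across
    platforms: ``concordant`` iff all non-missing allele counts agree."""
    counts = [c.allele_count for c in calls if c.allele_count is not None]
    if not counts:
        raise ValueError("need at least one non-missing call")
    if len(counts) == 1:
        return "single_platform"
    return "concordant" if len(set(counts)) == 1 else "discordant"


def mendelian_check(
    child: Optional[int],
    father: Optional[int] = None,
    mother: Optional[int] = None,
) -> int:
    """Count violations of biallelic Mendelian transmission in one trio.

    Missing genotypes skip the corresponding check.  Each parent whose
    genotype is individually incompatible with the child (child hom-alt
    with a hom-ref parent, or vice versa) contributes one error; a
    heterozygous child with two identical homozygous parents is a joint
    violation counted once.
    """
    if child is None:
        return 0
    errors = 0
    for parent in (father, mother):
        if parent is None:
            continue
        if (child == 2 and parent == 0) or (child == 0 and parent == 2):
            errors += 1
    if (
        errors == 0
        and father is not None
        and mother is not None
        and child == 1
        and father == mother
        and father in (0, 2)
    ):
        errors = 1
    return errors


# ---------------------------------------------------------------------------
# segregation
# ---------------------------------------------------------------------------

def segregation(
    variant_key: str,
    family: Iterable[Individual],
    genotypes: Mapping[str, Optional[int]],
    affected: frozenset[str] = AFFECTED_DEFAULT,
) -> SegregationSummary:
    """Tally carriers among affected/unaffected genotyped family members.

    ``genotypes`` maps individual_id -> allele count (None = missing).
    ``discordant_affected`` is a qualitative flag: true iff the family has
    at least one genotyped affected carrier *and* at least one genotyped
    affected non-carrier — the pattern in which the shared-variant
    hypothesis fails to explain all affected relatives.
    """
    family = list(family)
    if not family:
        raise ValueError("empty family")
    fam_id = family[0].family_id
    members = {ind.individual_id: ind for ind in family}
    for iid in genotypes:
        if iid not in members:
            raise ValueError(f"genotyped individual {iid} not in family {fam_id}")

    s = SegregationSummary(variant_key=variant_key, family_id=fam_id)
    for ind in family:
        ac = genotypes.get(ind.individual_id)
        if ac is None:
            continue
        carrier = ac > 0
        if ind.phenotype in affected:
            s.affected_genotyped += 1
            s.affected_carriers += carrier
        elif ind.phenotype == "unaffected":
            s.unaffected_genotyped += 1
            s.unaffected_carriers += carrier
        else:
            s.other_genotyped += 1
            s.other_carriers += carrier
        # trio check where parents are genotyped
        father = genotypes.get(ind.father_id) if ind.father_id else None
        mother = genotypes.get(ind.mother_id) if ind.mother_id else None
        s.mendelian_errors += mendelian_check(ac, father, mother)
    s.discordant_affected = (
        s.affected_carriers >= 1 and s.affected_carriers < s.affected_genotyped
    )
    return s
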