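"""Synthetic study generator: reference contigs with multi-exon genes,
multi-generation pedigrees transmitting an incompletely penetrant dominant
risk allele, depth-resolved genotype calls, and case-control carrier
matrices — everything the pipeline consumes, in standard formats, with no
download.

Every output is a pure function of :class:`SimulationConfig`.  One root
seed feeds named per-component streams (reference, families, phenotypes,
background, depths, case_control) derived through
``numpy.random.SeedSequence((seed, stream_id))``, so adding draws to one
component never perturbs another.

Defaults mirror the familial-myeloma study design: a discovery screen of
23 families with the risk allele spiked into 2 of them and 66 genotyped
individuals, and a burden cohort of 781 cases vs 3534 controls with
carrier frequencies 30/781 and 72/3534.  Carrier penetrance 0.4 against
a background rate 0.02 produces the unaffected carriers and affected
non-carriers seen in real pedigrees; heterozygote read support is
Binomial(depth, 0.5) at Poisson(100) depth, giving germline-like VAF
near 50%.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from types import SimpleNamespace
from typing import Optional, Sequence

import numpy as np

from .cohort import GenotypeCall, Individual, read_ped, read_vcf_genotypes, write_ped
from .consequence import Variant
from .io import (
    read_scores_tsv,
    write_fasta,
    write_gff3,
    write_scores_tsv,
    write_vcf,
)
from .reference import GenomeSequence, TranscriptModel, load_fasta, load_gff3, revcomp

__all__ = [
    "SimulationConfig",
    "simulate_reference",
    "simulate_families",
    "simulate_case_control",
    "make_splice_donor_variant",
    "write_fixture_bundle",
    "read_fixture_bundle",
    "discovery_preset",
    "burden_preset",
]

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
STOP_CODONS = ("TAA", "TAG", "TGA")

_STREAMS = {
    "reference": 0,
    "families": 1,
    "phenotypes": 2,
    "background": 3,
    "depths": 4,
    "case_control": 5,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator; the seed is mandatory."""

    seed: int
    # reference geometry
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (60, 180)
    intron_length_range: tuple[int, int] = (60, 200)
    utr5_length: int = 40
    utr3_length: int = 90
    genes_per_contig: int = 10
    # pedigrees
    n_families: int = 23
    n_spiked_families: int = 2
    pedigree_depth: int = 3
    children_per_couple: int = 2
    n_genotyped_total: Optional[int] = None
    penetrance_carrier: float = 0.4
    penetrance_background: float = 0.02
    background_lof_rate: float = 0.15
    plant_discordant: bool = True
    ascertain_affected_carrier: bool = True
    # case-control
    n_cases: int = 781
    n_controls: int = 3534
    carrier_freq_cases: float = 30 / 781
    carrier_freq_controls: float = 72 / 3534
    syn_carrier_freq: float = 0.10
    # read depths
    mean_depth: float = 100.0
    vaf_bias: float = 0.5  # alt-read probability for heterozygotes

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        if self.penetrance_carrier < self.penetrance_background:
            raise ValueError("penetrance_carrier must be >= penetrance_background")
        for f in (
            self.penetrance_carrier,
            self.penetrance_background,
            self.carrier_freq_cases,
            self.carrier_freq_controls,
            self.syn_carrier_freq,
            self.vaf_bias,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"probability {f} outside [0, 1]")


def discovery_preset(seed: int) -> SimulationConfig:
    """23 families, 66 genotyped individuals, one spiked two-family gene."""
    return SimulationConfig(seed=seed, n_families=23, n_spiked_families=2,
                            n_genotyped_total=66)


def burden_preset(seed: int) -> SimulationConfig:
    """781 cases vs 3534 controls at the published carrier frequencies."""
    return SimulationConfig(seed=seed)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(config.seed), _STREAMS[stream]))
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[TranscriptModel]]:
    """Random contigs with embedded multi-exon genes on both strands.

    Every transcript's spliced CDS starts ATG, ends with a stop, and has
    length divisible by 3 (validated downstream).  Deterministic per seed.
    """
    rng = _rng(config, "reference")
    contigs: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    gene_i = 0
    contig_i = 0
    while gene_i < config.n_genes:
        contig_name = f"chr{contig_i + 1}"
        parts = [_random_seq(rng, 100)]
        cursor = 100
        for _ in range(min(config.genes_per_contig, config.n_genes - gene_i)):
            gene_id = f"G{gene_i + 1:03d}"
            region, exon_bounds, cds_lo_r, cds_hi_r = _random_gene_region(rng, config)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                L = len(region)
                region_out = revcomp(region)
                exons = sorted(
                    (cursor + (L - 1 - (e - 1)) + 1, cursor + (L - 1 - s) + 1)
                    for s, e in exon_bounds
                )
                cds_lo = cursor + (L - 1 - cds_hi_r) + 1
                cds_hi = cursor + (L - 1 - cds_lo_r) + 1
            else:
                region_out = region
                exons = [(cursor + s + 1, cursor + e) for s, e in exon_bounds]
                cds_lo = cursor + cds_lo_r + 1
                cds_hi = cursor + cds_hi_r + 1
            parts.append(region_out)
            cursor += len(region_out)
            spacer = _random_seq(rng, 200)
            parts.append(spacer)
            cursor += len(spacer)
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.t1",
                    gene_id=gene_id,
                    contig=contig_name,
                    strand=strand,
                    exons=exons,
                    cds_start_g=cds_lo,
                    cds_end_g=cds_hi,
                )
            )
            gene_i += 1
        contigs[contig_name] = "".join(parts)
        contig_i += 1
    return GenomeSequence(contigs), transcripts


def _random_gene_region(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[str, list[tuple[int, int]], int, int]:
    """One transcript-forward gene region.

    Returns (region sequence, exon bounds 0-based half-open in region
    coords, cds start, cds end both 0-based inclusive region coords).
    """
    n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    lens = rng.integers(
        config.exon_length_range[0], config.exon_length_range[1] + 1, size=n_ex
    ).tolist()
    total = sum(lens)
    lens[-1] -= total % 3
    total = sum(lens)
    n_codons = total // 3
    cds = (
        "ATG"
        + "".join(rng.choice(SENSE_CODONS, size=n_codons - 2))
        + STOP_CODONS[int(rng.integers(0, 3))]
    )
    utr5 = _random_seq(rng, config.utr5_length)
    utr3 = _random_seq(rng, config.utr3_length)
    intron_lens = rng.integers(
        config.intron_length_range[0],
        config.intron_length_range[1] + 1,
        size=max(0, n_ex - 1),
    ).tolist()

    parts: list[str] = []
    exon_bounds: list[tuple[int, int]] = []
    cursor = 0
    off = 0
    for i, clen in enumerate(lens):
        piece = cds[off : off + clen]
        off += clen
        if i == 0:
            piece = utr5 + piece
        if i == n_ex - 1:
            piece = piece + utr3
        parts.append(piece)
        exon_bounds.append((cursor, cursor + len(piece)))
        cursor += len(piece)
        if i < n_ex - 1:
            intron = "GT" + _random_seq(rng, intron_lens[i] - 4) + "AG"
            parts.append(intron)
            cursor += len(intron)
    region = "".join(parts)
    cds_lo = config.utr5_length
    cds_hi = exon_bounds[-1][1] - config.utr3_length - 1
    return region, exon_bounds, cds_lo, cds_hi


def make_splice_donor_variant(
    transcript: TranscriptModel,
    genome: GenomeSequence,
    exon_tx_index: Optional[int] = None,
) -> Variant:
    """A +1 donor G>T disruption after an internal coding exon.

    The returned alleles are genome-forward; on minus-strand transcripts
    the genomic base complementary to the transcript-oriented G is
    substituted accordingly.
    """
    coding = transcript.coding_exon_indices()
    internal = [
        i
        for i in coding[1:-1]
        if 0 < i < len(transcript.exons) - 1
    ]
    if not internal:
        raise ValueError(f"{transcript.transcript_id}: no internal coding exon")
    if exon_tx_index is None:
        exon_tx_index = internal[len(internal) // 2]
    elif exon_tx_index not in internal:
        raise ValueError(f"exon {exon_tx_index} is not an internal coding exon")
    s, e = transcript.exons_tx_order()[exon_tx_index]
    gpos = e + 1 if transcript.strand == "+" else s - 1
    ref = genome.base(transcript.contig, gpos)
    alt = "T" if transcript.strand == "+" else "A"
    if ref == alt:  # donor motif should make this impossible, but be safe
        alt = "C" if transcript.strand == "+" else "G"
    return Variant(transcript.contig, gpos, ref, alt)


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

@dataclass
class FamilySim:
    individuals: list[Individual]
    variants: list[Variant]
    variant_gene: dict[str, str]  # variant key -> gene id
    genotypes: list[GenotypeCall]  # depth-resolved, genotyped subset only
    allele_counts: dict[str, dict[str, int]]  # variant key -> {individual: ac}
    genotyped_ids: list[str]
    spiked_gene: str
    spiked_variant: Variant


def _family_members(
    fam: str, config: SimulationConfig
) -> list[Individual]:
    """Fixed three-generation topology: founder couple, their children,
    one married-in spouse, and grandchildren via the first child."""
    father = Individual(f"{fam}_F", fam, sex="1", phenotype="unaffected")
    mother = Individual(f"{fam}_M", fam, sex="2", phenotype="unaffected")
    members = [father, mother]
    children = []
    for i in range(config.children_per_couple):
        children.append(
            Individual(
                f"{fam}_C{i + 1}",
                fam,
                father_id=father.individual_id,
                mother_id=mother.individual_id,
                sex=str(1 + i % 2),
                phenotype="unaffected",
            )
        )
    members.extend(children)
    if config.pedigree_depth >= 3 and children:
        spouse = Individual(f"{fam}_S", fam, sex="1" if children[0].sex == "2" else "2",
                            phenotype="unaffected")
        members.append(spouse)
        c0 = children[0]
        father_id = c0.individual_id if c0.sex == "1" else spouse.individual_id
        mother_id = spouse.individual_id if c0.sex == "1" else c0.individual_id
        for j in range(config.children_per_couple):
            members.append(
                Individual(
                    f"{fam}_G{j + 1}",
                    fam,
                    father_id=father_id,
                    mother_id=mother_id,
                    sex=str(1 + j % 2),
                    phenotype="unaffected",
                )
            )
    return members


def _transmit(
    members: Sequence[Individual],
    founder_carriers: set[str],
    rng: np.random.Generator,
) -> dict[str, int]:
    """Strictly Mendelian transmission of a heterozygous founder allele."""
    ac: dict[str, int] = {}
    for ind in members:
        if ind.is_founder:
            ac[ind.individual_id] = 1 if ind.individual_id in founder_carriers else 0
        else:
            inherited = 0
            for pid in (ind.father_id, ind.mother_id):
                pac = ac.get(pid, 0)
                if pac and rng.random() < pac / 2:
                    inherited += 1
            ac[ind.individual_id] = inherited
    return ac


def simulate_families(
    config: SimulationConfig,
    genome: GenomeSequence,
    transcripts: Sequence[TranscriptModel],
    spiked_gene: str,
    spiked_variant: Variant,
) -> FamilySim:
    """Pedigrees with the spiked allele in ``n_spiked_families`` families,
    Poisson background singleton LoF variants elsewhere, phenotypes drawn
    with penetrance f1 (carrier) / f0 (non-carrier), and depth-resolved
    genotype calls for the genotyped subset.
    """
    rng_fam = _rng(config, "families")
    rng_phe = _rng(config, "phenotypes")
    rng_bg = _rng(config, "background")
    rng_dep = _rng(config, "depths")

    by_gene = {t.gene_id: t for t in transcripts}
    if spiked_gene not in by_gene:
        raise ValueError(f"spiked gene {spiked_gene} not among transcripts")

    fam_ids = [f"FAM{i + 1:03d}" for i in range(config.n_families)]
    spiked_fams = fam_ids[: config.n_spiked_families]

    individuals: list[Individual] = []
    variants: list[Variant] = [spiked_variant]
    variant_gene: dict[str, str] = {spiked_variant.key: spiked_gene}
    allele_counts: dict[str, dict[str, int]] = {spiked_variant.key: {}}
    fam_members: dict[str, list[Individual]] = {}

    bg_genes = [t.gene_id for t in transcripts if t.gene_id != spiked_gene]

    for fam in fam_ids:
        members = _family_members(fam, config)
        fam_members[fam] = members
        # spiked allele enters through the founder mother
        if fam in spiked_fams:
            ac = _transmit(members, {f"{fam}_M"}, rng_fam)
            for iid, count in ac.items():
                allele_counts[spiked_variant.key][iid] = count
        # background singleton LoF variants
        n_bg = int(rng_bg.poisson(config.background_lof_rate))
        for _ in range(n_bg):
            if not bg_genes:
                break
            gene = bg_genes[int(rng_bg.integers(0, len(bg_genes)))]
            try:
                t = by_gene[gene]
                internal = [
                    i
                    for i in t.coding_exon_indices()[1:-1]
                    if 0 < i < len(t.exons) - 1
                ]
                if not internal:
                    continue
                exon = internal[int(rng_bg.integers(0, len(internal)))]
                var = make_splice_donor_variant(t, genome, exon)
            except ValueError:
                continue
            if var.key not in variant_gene:
                variants.append(var)
                variant_gene[var.key] = gene
                allele_counts[var.key] = {}
            founder = f"{fam}_F" if rng_bg.random() < 0.5 else f"{fam}_M"
            ac = _transmit(members, {founder}, rng_bg)
            allele_counts[var.key].update(ac)
        individuals.extend(members)

    # phenotypes: carrier status w.r.t. the spiked allele drives penetrance
    phenotyped: list[Individual] = []
    for ind in individuals:
        carrier = allele_counts[spiked_variant.key].get(ind.individual_id, 0) > 0
        p = config.penetrance_carrier if carrier else config.penetrance_background
        if rng_phe.random() < p:
            pheno = "MM" if rng_phe.random() < 0.5 else "MGUS"
        else:
            pheno = "unaffected"
        phenotyped.append(dataclasses.replace(ind, phenotype=pheno))
    individuals = phenotyped

    by_id = {ind.individual_id: ind for ind in individuals}

    def _set_pheno(iid: str, pheno: str) -> None:
        by_id[iid] = dataclasses.replace(by_id[iid], phenotype=pheno)

    # ascertainment: every spiked family has an affected carrier proband
    for fam in spiked_fams if config.ascertain_affected_carrier else []:
        carriers = [
            iid
            for iid in (m.individual_id for m in fam_members[fam])
            if allele_counts[spiked_variant.key].get(iid, 0) > 0
        ]
        if carriers and not any(
            by_id[c].phenotype in ("MM", "MGUS") for c in carriers
        ):
            _set_pheno(carriers[0], "MM")
    # plant one affected non-carrier in the last spiked family (the
    # family-D discordance pattern)
    if config.plant_discordant and spiked_fams:
        fam = spiked_fams[-1]
        noncarriers = [
            m.individual_id
            for m in fam_members[fam]
            if allele_counts[spiked_variant.key].get(m.individual_id, 0) == 0
        ]
        if noncarriers:
            _set_pheno(noncarriers[0], "MM")
    individuals = [by_id[ind.individual_id] for ind in individuals]

    genotyped_ids = _choose_genotyped(config, fam_ids, fam_members, by_id, allele_counts)

    # depth-resolved calls: every genotyped individual at every variant
    calls: list[GenotypeCall] = []
    for var in variants:
        counts = allele_counts[var.key]
        for iid in genotyped_ids:
            ac = counts.get(iid, 0)
            depth = max(1, int(rng_dep.poisson(config.mean_depth)))
            if ac == 0:
                ref_d, alt_d = depth, 0
            elif ac == 1:
                alt_d = int(rng_dep.binomial(depth, config.vaf_bias))
                ref_d = depth - alt_d
            else:
                ref_d, alt_d = 0, depth
            calls.append(
                GenotypeCall(iid, var.key, ac, ref_d, alt_d, platform="simulated")
            )

    return FamilySim(
        individuals=individuals,
        variants=variants,
        variant_gene=variant_gene,
        genotypes=calls,
        allele_counts=allele_counts,
        genotyped_ids=genotyped_ids,
        spiked_gene=spiked_gene,
        spiked_variant=spiked_variant,
    )


def _choose_genotyped(
    config: SimulationConfig,
    fam_ids: list[str],
    fam_members: dict[str, list[Individual]],
    by_id: dict[str, Individual],
    allele_counts: dict[str, dict[str, int]],
) -> list[str]:
    """Genotyped subset: all members, or n_genotyped_total distributed
    across families prioritizing affected members and carriers (the
    familial-screen ascertainment pattern)."""
    if config.n_genotyped_total is None:
        return [m.individual_id for fam in fam_ids for m in fam_members[fam]]
    base, rem = divmod(config.n_genotyped_total, config.n_families)
    chosen: list[str] = []
    for i, fam in enumerate(fam_ids):
        k = base + (1 if i < rem else 0)

        def rank(m: Individual) -> tuple:
            carrier = any(
                counts.get(m.individual_id, 0) > 0
                for counts in allele_counts.values()
            )
            affected = by_id[m.individual_id].phenotype in ("MM", "MGUS")
            return (not (carrier and affected), not affected, not carrier,
                    m.individual_id)

        members = sorted(fam_members[fam], key=rank)
        chosen.extend(m.individual_id for m in members[:k])
    return chosen


# ---------------------------------------------------------------------------
# case-control
# ---------------------------------------------------------------------------

@dataclass
class CaseControlSim:
    phenotypes: dict[str, str]  # individual -> case|control
    genotypes: list[GenotypeCall]
    qualifying: set[str]
    synonymous: set[str]


def simulate_case_control(
    config: SimulationConfig,
    mask_variants: Sequence[str],
    synonymous_variants: Sequence[str] = (),
    exact_counts: bool = False,
) -> CaseControlSim:
    """Case-control carrier matrix over a gene's qualifying mask.

    Bernoulli mode draws carrier status independently per individual at
    the configured arm frequencies; exact-counts mode assigns exactly
    round(freq * n) carriers per arm (hypergeometric assignment), which
    forces the downstream 2x2 analytically.  Each carrier receives one
    variant uniformly from the mask.  Synonymous carrier status, used for
    bias calibration, is drawn at the same frequency in both arms.
    """
    if not mask_variants:
        raise ValueError("mask_variants must be non-empty")
    rng = _rng(config, "case_control")
    cases = [f"case{i + 1:04d}" for i in range(config.n_cases)]
    controls = [f"ctrl{i + 1:04d}" for i in range(config.n_controls)]
    phenotypes = {i: "case" for i in cases} | {i: "control" for i in controls}

    def draw(ids: list[str], freq: float) -> list[str]:
        if exact_counts:
            k = round(freq * len(ids))
            idx = rng.choice(len(ids), size=k, replace=False)
            return [ids[i] for i in sorted(idx)]
        mask = rng.random(len(ids)) < freq
        return [i for i, m in zip(ids, mask) if m]

    calls: list[GenotypeCall] = []

    def emit(iid: str, vkey: str) -> None:
        depth = max(1, int(rng.poisson(config.mean_depth)))
        alt_d = int(rng.binomial(depth, config.vaf_bias))
        calls.append(
            GenotypeCall(iid, vkey, 1, depth - alt_d, alt_d, platform="simulated")
        )

    for ids, freq in ((cases, config.carrier_freq_cases),
                      (controls, config.carrier_freq_controls)):
        for iid in draw(ids, freq):
            emit(iid, mask_variants[int(rng.integers(0, len(mask_variants)))])
    if synonymous_variants:
        for ids in (cases, controls):
            for iid in draw(ids, config.syn_carrier_freq):
                emit(
                    iid,
                    synonymous_variants[
                        int(rng.integers(0, len(synonymous_variants)))
                    ],
                )
    return CaseControlSim(
        phenotypes=phenotypes,
        genotypes=calls,
        qualifying=set(mask_variants),
        synonymous=set(synonymous_variants),
    )


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    directory: str | Path,
    config: SimulationConfig,
    genome: GenomeSequence,
    transcripts: Sequence[TranscriptModel],
    individuals: Sequence[Individual],
    variants: Sequence[Variant],
    calls: Sequence[GenotypeCall],
    scores: Optional[dict[str, float]] = None,
    sample_order: Optional[Sequence[str]] = None,
) -> dict[str, str]:
    """Write FASTA(+fai)/GFF3/VCF/PED/scores/manifest; re-reading the
    bundle reproduces the simulated objects."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(directory / "reference.fa"),
        "gff3": str(directory / "genes.gff3"),
        "vcf": str(directory / "cohort.vcf"),
        "ped": str(directory / "cohort.ped"),
        "scores": str(directory / "scores.tsv"),
        "manifest": str(directory / "manifest.json"),
    }
    write_fasta(genome, paths["fasta"])
    write_gff3(transcripts, paths["gff3"])
    write_vcf(variants, calls, genome, paths["vcf"], sample_order=sample_order)
    write_ped(individuals, paths["ped"])
    write_scores_tsv(scores or {}, paths["scores"])
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "files": {k: Path(v).name for k, v in paths.items() if k != "manifest"},
    }
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


def read_fixture_bundle(directory: str | Path) -> SimpleNamespace:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    genome = load_fasta(directory / manifest["files"]["fasta"])
    transcripts = load_gff3(directory / manifest["files"]["gff3"])
    individuals = read_ped(directory / manifest["files"]["ped"])
    variants, calls = read_vcf_genotypes(directory / manifest["files"]["vcf"],
                                         platform="simulated")
    scores = read_scores_tsv(directory / manifest["files"]["scores"])
    return SimpleNamespace(
        manifest=manifest,
        genome=genome,
        transcripts=transcripts,
        individuals=individuals,
        variants=variants,
        calls=calls,
        scores=scores,
    )
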