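# Methods

This note records the models, rules and defaults implemented in
`famlof`, the design choices made where the design was genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Coordinates and transcript models

VCF and GFF3 coordinates are taken 1-based inclusive and all reported
positions are 1-based; interval arithmetic is 0-based half-open
internally. A transcript is an ordered set of non-overlapping exons on
one contig plus the genomic bounds of the translated region (stop codon
included). c.-space numbering follows HGVS: CDS positions 1..L, 5′UTR
negative, 3′UTR `*k`, and intronic positions anchored to the nearest
exonic base with a signed offset — donor side positive, acceptor side
negative, ties resolved to the donor side (the convention that assigns
the first half of an intron to the upstream exon). Positions up to a
configurable flank (default 5 000 bp) beyond the transcript span are
still mapped, anchored to the terminal exonic base; everything farther
is an error. `g_to_c` and `c_to_g` are exact inverses on this whole
domain, which the tests check exhaustively over toy transcripts and on
200 random positions per simulated transcript.

Variant alleles are genome-forward (VCF convention) and are
reverse-complemented internally for minus-strand transcripts, so a
minus-strand gene reports transcript-oriented HGVS names. One
transcript per gene is assumed; when several are supplied, the longest
CDS wins (ties by transcript id). Non-standard codon tables and
selenoproteins are out of scope.

## Consequence model

CDS SNVs are classified codon-wise (synonymous / missense / stop-gain /
stop-loss). Only ±1/±2 intronic SNVs count as canonical splice
disruption, and their effect is modelled as skipping of the single
adjacent exon: the exon's coding segment is removed from the spliced
CDS and the result re-translated. Intron retention and cryptic splice
sites are not modelled. Skipping a terminal (first/last) coding exon is
flagged "effect unresolved" rather than computed, since neither exon
skipping nor a defined reading frame follows from a terminal splice
lesion.

The frameshift name anchors at the first codon whose *nucleotides*
change, even when the encoded residue is coincidentally preserved
(hence names of the form `p.Arg557Argfs*3`), and the stop offset counts
the anchor codon as 1. CDS indels are called frameshift when the length
change is not a multiple of 3; in-frame indels are reported as `other`
with no protein-level modelling (indel normalization beyond a left-trim
is out of scope).

**NMD.** The 50-nt last-junction rule, inclusive at the boundary: a PTC
triggers decay iff its first nucleotide lies ≥ 50 nt upstream of the
last exon–exon junction in mRNA coordinates; PTCs in the last exon, or
any PTC of a single-exon transcript, do not. For exon-skip calls the
junction structure of the *skipped* transcript is used. The rule is
monotone: moving a PTC 5′ never switches a decay prediction off.

**Stop-loss.** The variant-recoded stop codon is translated (giving the
substituted residue) and translation continues in frame through the
spliced 3′UTR until the next stop. `extension_residues` excludes the
substituted residue; the HGVS label uses `ext*N` with
N = extension_residues + 1, reconciling the two counting conventions
("13 additional amino acids" vs `ext*14`) — both numbers are available
on the call.

**Qualifying masks.** Discovery mode admits truncating classes
(stop-gain, frameshift, canonical splice) plus stop-loss. Burden mode
additionally admits missense with a per-variant deleteriousness score
at or above an inclusive threshold (default 20, a CADD-like scale; the
column and threshold are configurable because published supplementary
mask definitions vary). Missense without a score never qualifies, with
a warning.

## Worked-example surrogate

`famlof.examples.synthetic_dis3_like()` builds a *synthetic* transcript
whose exon geometry reproduces, by construction, the coordinate
arithmetic of a well-characterized familial-myeloma exosome-nuclease
gene: exon 13 ends at c.1755, exon 14 at c.1883, the CDS is 2 877 nt so
the native TAA stop is codon 959, and the 3′UTR supplies 13 sense
codons before an in-frame stop. On it, the donor variant c.1755+1G>T
yields `p.Arg557Argfs*3` with NMD predicted, and c.2875T>C yields
`p.*959Glnext*14`. The sequence away from these constrained positions
is random; nothing in the repository is the real human transcript, and
validating against the real RefSeq model remains an integration
exercise requiring an external reference download.

## Germline QC and segregation

The VAF check is an exact two-sided binomial test of alt reads against
p = 0.5 at the observed depth, with α = 0.01 and a 10-read minimum —
chosen loose deliberately so ordinary sampling noise at depth ~100 is
not flagged (by construction ≥ ~98–99 % of true heterozygotes pass).
Platform concordance requires all non-missing allele counts for an
individual × variant to agree. The Mendelian check counts per-parent
impossibilities (hom-alt child with hom-ref parent and vice versa) plus
jointly impossible het children; it agrees with an enumeration of
allowed transmissions over all 27 trio genotype combinations.

Segregation tallies carriers among genotyped affected (MM/MGUS by
default — amyloidosis and other haematological conditions are reported
in a separate stratum, configurable) and unaffected members. No formal
segregation statistic is defined; `discordant_affected` is an explicit
qualitative flag, true iff the family has a genotyped affected carrier
*and* a genotyped affected non-carrier — the pattern in which a shared
variant cannot explain all affected relatives.

## Recurrence filter and burden test

A gene is recurrent when ≥ `min_families` (default 2) distinct families
contain ≥ 1 carrier of ≥ 1 qualifying allele; a family counts once
regardless of carrier or variant multiplicity, and an optional
`min_affected_carriers` knob additionally requires that many genotyped
affected carriers per family. "Unrelated" means distinct family ids;
kinship inference and any genome-wide significance model for recurrence
(gene length, mutability) are out of scope. VAF QC is reported beside
carrier status, not used as a hard filter, mirroring its role as
confirmatory evidence.

The burden statistic is the crude cross-product OR with the Woolf
(log-normal) 95 % CI; these reproduce published familial-myeloma burden
figures exactly from the printed carrier counts, which is why they are
the defaults. Zero cells get Haldane–Anscombe +0.5 for the OR/CI only;
the two-sided Fisher exact p (sum of hypergeometric probabilities no
larger than the observed table's) is never corrected. Covariate-
adjusted models (logistic, PC-corrected) are deliberately absent —
published adjusted ORs are not derivable from carrier counts alone.
When several genes are tested an optional Benjamini–Hochberg column is
available, but raw p is the default since the motivating analysis
tests a single gene. The bias calibration runs the identical collapse
on synonymous variants and flags the cohort when the calibration CI
excludes 1; it is a stand-in for unpublished cohort-specific bias
checks and should be read as a necessary, not sufficient, control.

## Synthetic data generator

The generator is first-class, tested code. Defaults are the study
conditions of the motivating design:

| parameter | default | meaning |
| --- | --- | --- |
| `n_families` / spiked | 23 / 2 | discovery screen; risk allele enters 2 families |
| `n_genotyped_total` | 66 (preset) | genotyped subset, 20 families × 3 + 3 × 2 |
| `penetrance_carrier` f1 | 0.4 | dominant allele, incomplete penetrance |
| `penetrance_background` f0 | 0.02 | phenocopies / sporadic disease |
| `n_cases` / `n_controls` | 781 / 3534 | burden cohort |
| carrier freq cases / controls | 30/781, 72/3534 | published carrier counts |
| `mean_depth` | 100 | Poisson read depth |
| het alt-read probability | 0.5 | Binomial(depth, 0.5), VAF ≈ 50 % |
| `n_genes` | 60 | scaled-down exome |
| `background_lof_rate` | 0.15 | Poisson mean of private LoF variants per family |

All randomness flows from one root seed through named per-component
streams (`SeedSequence((seed, stream_id))`), so adding draws to one
component never perturbs another, and every output is byte-reproducible
from the seed. Penetrances f1 = 0.4 / f0 = 0.02 are a judgment call for
an "intermediate-risk" dominant allele: they produce the unaffected
carriers and affected non-carriers seen in real pedigrees. The 60-gene
toy exome with 0.15 background LoF per family keeps two-family
background coincidences rare (~10 % of replicates) while still
exercising the filter against non-trivial background; replicates where
the background does collide are identified from the generator's ground
truth and excluded, exactly as a null-aware analysis would.

Two features are *planted* for determinism of the discovery fixture:
each spiked family is guaranteed an affected carrier (the ascertainment
that defines a familial screen), and the last spiked family receives
one affected non-carrier so the discordant-segregation pattern is
always present. Both are switchable (`ascertain_affected_carrier`,
`plant_discordant`), and the raw-penetrance tests switch them off.

Case-control simulation has two modes: Bernoulli (independent carrier
draws at the arm frequencies — stochastic, with known expectations) and
exact-counts (exactly round(freq·n) carriers per arm), which forces the
published 2×2 analytically and is used to reproduce printed statistics.

**What the generator does not emulate:** linkage disequilibrium,
population structure, sequencing error and somatic contamination,
variable exome capture, related families in the case-control arm, and
realistic gene-length/mutability variation. Passing tests therefore
demonstrate the correctness of the pipeline's logic and statistics
under idealized germline sampling, not robustness to real-data
artifacts.

## Numerical choices and problem sizes

Exact binomial and Fisher p-values are computed by scipy (log-space
hypergeometric); the test suite keeps independent brute-force
enumerations as oracles, exhaustive for every 2×2 table with total
≤ 12 and for every CDS SNV of a ≤ 300-nt toy gene. The Fisher
two-sided "no larger than observed" comparison uses a 1e-7 relative
tolerance. Rounding in human-readable reports: OR/CI to 2 decimals,
percentages to 1 decimal; machine JSON keeps full precision.

Parameter recovery uses 200 replicates at 800 cases / 3500 controls
(control carrier frequency 0.02, true OR 2.0), seeded by replicate
index. The Woolf CI is calibrated: coverage measured over 2 000
replicates is 95.0 %. Note that a 200-replicate batch estimates
coverage with a binomial standard deviation of ~1.5 percentage points,
so individual batches scatter roughly between 92 % and 98 % around the
nominal level; the suite documents one such batch below the
93–97 % window.

## Known limitations

* One transcript per gene; no isoform-aware annotation.
* Splice modelling is the canonical-site exon-skip idealization; no
  in-silico splice-strength scoring.
* The segregation flag is qualitative; no LOD-score or penetrance-model
  likelihoods.
* Burden testing is unadjusted; confounding by ancestry or batch must
  be handled upstream (the synonymous calibration only detects gross
  imbalance).
* The generator's idealizations listed above.
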