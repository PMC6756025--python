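# famlof

**Familial germline loss-of-function (LoF) variant prioritization** — a
tested, reusable pipeline for the analysis pattern used in family-based
rare-variant studies of cancer predisposition (the motivating setting is
familial multiple myeloma / MGUS): annotate variant consequences against
transcript models, confirm germline origin and Mendelian segregation in
pedigrees, find genes with qualifying LoF variants recurring across
unrelated families, and test gene-level carrier burden in an independent
case-control series.

It is aimed at statistical-genetics and cancer-genomics analysts who
have cohort VCFs, pedigrees (PED) and transcript models (GFF3 + FASTA),
and want the whole chain — from a splice-site genotype to a gene-level
odds ratio — reproducible from files. A synthetic-cohort generator
produces every input from a seed, so the full pipeline also runs with no
data in hand.

## What it computes

**Consequence model.** For an SNV at the canonical ±1/±2 intronic
positions, the package models splice disruption as skipping of the
adjacent exon: the exon's coding sequence is removed from the spliced
CDS and re-translated. If the skipped length is not a multiple of 3 the
call is a frameshift `p.Xaa{k}Yaafs*{m}`, anchored at the first codon
whose nucleotides change (k), with the new stop m codons downstream
(counting the anchor as 1). A premature termination codon (PTC) is
predicted to trigger nonsense-mediated decay (NMD) by the 50-nt rule:
NMD iff the PTC's first nucleotide lies ≥ 50 nt upstream of the last
exon–exon junction. A variant recoding the native stop is a stop-loss:
translation continues in frame through the 3′UTR until the next stop,
giving `p.*{n}{Res}ext*{N}` with N − 1 extension residues.

**Germline QC.** A heterozygous call with allelic depths (r, a) is
germline-consistent when an exact two-sided binomial test of a against
p = 0.5 at depth r + a gives p ≥ 0.01 (depth ≥ 10), i.e. variant allele
fraction "close to 50 %". Cross-platform concordance and per-trio
Mendelian checks are reported alongside.

**Discovery filter.** A gene is a hit when qualifying variants
(truncating classes + stop-loss; optionally missense with
deleteriousness score ≥ 20) are carried in ≥ 2 distinct families; each
hit carries per-family segregation summaries, including a qualitative
`discordant_affected` flag for families where an affected member does
not carry the shared variant.

**Burden test.** Per gene, individuals carrying ≥ 1 qualifying allele
are collapsed into a 2×2 carrier table (a, b; c, d). The statistic is
the cross-product odds ratio with a Woolf 95 % CI,

OR = ad / bc,  CI = exp( ln OR ± 1.96 · √(1/a + 1/b + 1/c + 1/d) ),

with the Haldane–Anscombe +0.5 correction when a cell is zero, plus a
two-sided Fisher exact p. Systemic case-control bias is probed by
running the identical collapse on a synonymous (neutral) mask: a
calibration OR whose CI excludes 1 flags the dataset.

## Worked example

Reproduce a published familial-myeloma burden table from its carrier
counts (30 of 781 cases, 72 of 3534 controls):

```console
$ famlof burden --counts 30,751,72,3462
OR = 1.92 95%CI:1.25-2.96 p = 0.00575
```

The odds ratio says qualifying-variant carriers are about twice as
frequent among cases; the CI excluding 1 makes the enrichment nominally
significant.

Simulate a discovery cohort (23 families, 66 genotyped individuals, one
gene's splice-donor allele spiked into 2 families) and run the pipeline:

```console
$ famlof simulate --preset discovery --seed 1 --out sim/
discovery bundle: 23 families, 66 genotyped individuals, spiked gene G001
$ famlof run --fasta sim/reference.fa --gff3 sim/genes.gff3 \
             --vcf sim/cohort.vcf --ped sim/cohort.ped --out run/
```

`run/summary.json` then lists `G001` as a recurrent gene in 2 families
(`"recurrent_genes": [{"gene_id": "G001", "n_families": 2, ...}]`),
with `run/annotated.tsv` holding per-variant consequence calls (class,
HGVS c./p., PTC position, NMD prediction) and `run/qc.tsv` the VAF
germline checks.

The library surface mirrors the CLI — e.g.
`famlof.classify(variant, transcript, genome)` returns a consequence
call, and `famlof.burden_test(genotypes, phenotypes, mask)` the burden
result.

## Layout

| module | contents |
| --- | --- |
| `famlof.reference` | genome/transcript models, genomic ⇄ c. coordinate mapping, CDS splice + translate |
| `famlof.consequence` | variant classification, exon-skip modelling, NMD rule, readthrough extension, LoF mask |
| `famlof.cohort` | PED/VCF genotype IO, VAF germline check, platform concordance, Mendelian + segregation analysis |
| `famlof.prioritize` | qualifying-variant masks, cross-family recurrence filter |
| `famlof.burden` | 2×2 collapse, OR/Woolf CI, Fisher exact p, synonymous calibration |
| `famlof.simulate` | seeded generators for reference, pedigrees, case-control cohorts; fixture bundles |
| `famlof.pipeline`, `famlof.cli` | file-level orchestration and the `famlof` command |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
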