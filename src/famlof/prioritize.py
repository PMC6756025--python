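"""Cross-family discovery filter for recurrent putative-LoF genes.

A gene becomes a hit when qualifying variants are carried in at least
``min_families`` distinct families (a family counts once however many
carriers or variants it has); each retained gene carries per-family
variant lists and segregation summaries.  "Unrelated families" means
distinct family ids — kinship inference is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .cohort import (
    AFFECTED_DEFAULT,
    GenotypeCall,
    Individual,
    SegregationSummary,
    segregation,
)
from .consequence import ConsequenceCall, LofConfig, is_putative_lof

__all__ = [
    "FamilyGeneHit",
    "qualifying_variants",
    "cross_family_recurrence",
    "family_frequency_pct",
    "write_gene_hits",
]


@dataclass
class FamilyGeneHit:
    gene_id: str
    families: set[str] = field(default_factory=set)
    variants_by_family: dict[str, list[str]] = field(default_factory=dict)
    segregation_by_family: dict[str, list[SegregationSummary]] = field(
        default_factory=dict
    )

    @property
    def n_families(self) -> int:
        return len(self.families)


def qualifying_variants(
    calls: Iterable[ConsequenceCall],
    scores: Optional[Mapping[str, float]] = None,
    mode: str = "discovery",
    config: Optional[LofConfig] = None,
) -> set[str]:
    """Apply the putative-LoF mask with a mode switch.

    ``discovery`` admits truncating classes and stop-loss only; ``burden``
    additionally admits missense at or above the deleteriousness-score
    threshold.
    """
    if mode not in ("discovery", "burden"):
        raise ValueError(f"mode must be discovery or burden, got {mode!r}")
    scores = scores or {}
    out: set[str] = set()
    for call in calls:
        key = call.variant.key
        if mode == "discovery":
            if call.klass in ("stop_gain", "frameshift", "splice_donor",
                              "splice_acceptor", "stop_loss"):
                out.add(key)
        else:
            if is_putative_lof(call, scores.get(key), config):
                out.add(key)
    return out


def cross_family_recurrence(
    qualifying: Mapping[str, str],
    genotypes: Iterable[GenotypeCall],
    pedigree: Iterable[Individual],
    min_families: int = 2,
    min_affected_carriers: int = 0,
    affected: frozenset[str] = AFFECTED_DEFAULT,
) -> list[FamilyGeneHit]:
    """Genes with qualifying carriers in >= ``min_families`` families.

    ``qualifying`` maps variant key -> gene id.  A family counts toward a
    gene iff >= 1 member carries >= 1 qualifying allele; when
    ``min_affected_carriers`` > 0 the family must additionally have that
    many genotyped *affected* carriers of some qualifying variant.
    Output is sorted by family count (desc) then gene id, and is invariant
    to genotype order and within-family relabeling.
    """
    individuals = {ind.individual_id: ind for ind in pedigree}
    by_family: dict[str, list[Individual]] = {}
    for ind in individuals.values():
        by_family.setdefault(ind.family_id, []).append(ind)

    # (gene, family) -> {variant_key -> {individual -> allele_count}}
    gene_family: dict[tuple[str, str], dict[str, dict[str, Optional[int]]]] = {}
    for call in genotypes:
        gene = qualifying.get(call.variant_key)
        if gene is None:
            continue
        ind = individuals.get(call.individual_id)
        if ind is None:
            raise ValueError(f"genotype for unknown individual {call.individual_id}")
        slot = gene_family.setdefault((gene, ind.family_id), {})
        slot.setdefault(call.variant_key, {})[call.individual_id] = call.allele_count

    hits: dict[str, FamilyGeneHit] = {}
    for (gene, fam), per_variant in gene_family.items():
        segs = [
            segregation(vk, by_family[fam], gts, affected=affected)
            for vk, gts in sorted(per_variant.items())
        ]
        carriers = any(
            ac in (1, 2) for gts in per_variant.values() for ac in gts.values()
        )
        if not carriers:
            continue
        if min_affected_carriers > 0 and not any(
            s.affected_carriers >= min_affected_carriers for s in segs
        ):
            continue
        hit = hits.setdefault(gene, FamilyGeneHit(gene_id=gene))
        hit.families.add(fam)
        hit.variants_by_family[fam] = sorted(per_variant)
        hit.segregation_by_family[fam] = segs

    out = [h for h in hits.values() if h.n_families >= min_families]
    out.sort(key=lambda h: (-h.n_families, h.gene_id))
    return out


def family_frequency_pct(n_hit_families: int, n_screened_families: int) -> float:
    """Percent of screened families carrying a qualifying variant."""
    if n_screened_families <= 0:
        raise ValueError("need a positive number of screened families")
    return 100.0 * n_hit_families / n_screened_families


def write_gene_hits(
    hits: Iterable[FamilyGeneHit], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    """Gene-hit report as TSV (and optional JSON mirror)."""
    rows = ["gene_id\tn_families\tfamilies\tvariants\tdiscordant_families"]
    payload = []
    for h in hits:
        discordant = sorted(
            fam
            for fam, segs in h.segregation_by_family.items()
            if any(s.discordant_affected for s in segs)
        )
        all_vars = sorted({v for vs in h.variants_by_family.values() for v in vs})
        rows.append(
            "\t".join(
                [
                    h.gene_id,
                    str(h.n_families),
                    ",".join(sorted(h.families)),
                    ",".join(all_vars),
                    ",".join(discordant) or ".",
                ]
            )
        )
        payload.append(
            {
                "gene_id": h.gene_id,
                "n_families": h.n_families,
                "families": sorted(h.families),
                "variants_by_family": {k: v for k, v in sorted(h.variants_by_family.items())},
                "discordant_families": discordant,
            }
        )
    Path(tsv_path).write_text("\n".join(rows) + "\n")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
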