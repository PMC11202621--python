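"""Variant effect and impact classification.

Two routes produce :class:`EffectAnnotation` records:

* :func:`parse_ann_field` consumes SnpEff-style pipe-delimited ``ANN``
  INFO entries already present in a VCF;
* :func:`classify_effect` is a minimal internal coding-effect classifier
  for SNVs against gene models and the reference genome, covering the
  effect classes the pipeline needs (intergenic/intronic/synonymous/
  missense/stop and start changes/splice region).  Standard nuclear
  genetic code only.

A site's impact is the maximum over its annotations; candidates whose
maximum impact is MODERATE or HIGH form the functional subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .errors import ConfigurationError, DataConsistencyError
from .somatic_filter import CandidateSet
from .variant_io import (
    GeneModel,
    ReferenceGenome,
    SiteKey,
    VariantSite,
    reverse_complement,
)

logger = logging.getLogger(__name__)

EFFECTS = (
    "intergenic",
    "intronic",
    "synonymous",
    "missense",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "splice_region",
    "other",
)

IMPACT_ORDER = ("MODIFIER", "LOW", "MODERATE", "HIGH")

#: Fixed effect -> impact mapping (SnpEff convention).
IMPACT_BY_EFFECT: dict[str, str] = {
    "intergenic": "MODIFIER",
    "intronic": "MODIFIER",
    "synonymous": "LOW",
    "missense": "MODERATE",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "splice_region": "HIGH",
    "other": "MODIFIER",
}

#: SnpEff (Sequence Ontology) effect terms -> internal effect classes.
_SO_TERM_MAP: dict[str, str] = {
    "intergenic_region": "intergenic",
    "intergenic_variant": "intergenic",
    "intron_variant": "intronic",
    "synonymous_variant": "synonymous",
    "missense_variant": "missense",
    "stop_gained": "stop_gained",
    "stop_lost": "stop_lost",
    "start_lost": "start_lost",
    "splice_region_variant": "splice_region",
}


@dataclass(frozen=True)
class EffectAnnotation:
    effect: str
    impact: str
    gene_id: str
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.impact not in IMPACT_ORDER:
            raise ValueError(f"unknown impact {self.impact!r}")


def parse_ann_field(site: VariantSite) -> list[EffectAnnotation]:
    """Parse a SnpEff 4.3 pipe-delimited ANN field into annotations.

    Unknown effect terms map to other/MODIFIER with a logged warning; an
    absent ANN field yields an empty list.  The parsed list is cached on
    ``site.ann``.
    """
    if not site.ann_raw:
        site.ann = []
        return []
    anns: list[EffectAnnotation] = []
    for entry in site.ann_raw.split(","):
        fields = entry.split("|")
        term = fields[1].strip() if len(fields) > 1 else ""
        # A SnpEff entry may stack terms with '&'; keep the highest-impact one.
        effects = [
            _SO_TERM_MAP.get(t.strip(), None) for t in term.split("&") if t.strip()
        ]
        known = [e for e in effects if e is not None]
        if not known:
            logger.warning("unknown ANN effect term %r -> other/MODIFIER", term)
            effect = "other"
        else:
            effect = max(known, key=lambda e: IMPACT_ORDER.index(IMPACT_BY_EFFECT[e]))
        impact = fields[2].strip() if len(fields) > 2 and fields[2].strip() else ""
        if impact not in IMPACT_ORDER:
            impact = IMPACT_BY_EFFECT[effect]
        gene_name = fields[3].strip() if len(fields) > 3 else ""
        gene_id = fields[4].strip() if len(fields) > 4 and fields[4].strip() else gene_name
        transcript = fields[6].strip() if len(fields) > 6 and fields[6].strip() else None
        anns.append(
            EffectAnnotation(
                effect=effect, impact=impact, gene_id=gene_id, transcript_id=transcript
            )
        )
    site.ann = anns
    return anns


_CODON_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = "*"


def _translate_codon(codon: str) -> str:
    return _CODON_AA[codon]


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of ``pos`` in the spliced CDS on the coding strand."""
    segments = gene.cds_segments
    if gene.strand == "+":
        offset = 0
        for s, e in segments:
            if s <= pos <= e:
                return offset + (pos - s)
            offset += e - s + 1
    else:
        offset = 0
        for s, e in reversed(segments):
            if s <= pos <= e:
                return offset + (e - pos)
            offset += e - s + 1
    return None


def _cds_sequence(gene: GeneModel, reference: ReferenceGenome) -> str:
    parts = [reference.fetch(gene.chrom, s, e) for s, e in gene.cds_segments]
    seq = "".join(parts)
    return seq if gene.strand == "+" else reverse_complement(seq)


def _near_cds_boundary(gene: GeneModel, pos: int, margin: int = 2) -> bool:
    for s, e in gene.cds_segments:
        if s - margin <= pos < s or e < pos <= e + margin:
            return True
    return False


def classify_effect(
    site: VariantSite,
    genes: Sequence[GeneModel],
    reference: ReferenceGenome,
) -> EffectAnnotation:
    """Classify one SNV against gene models and the reference genome.

    Returns the single highest-impact annotation over all overlapping genes
    (intergenic when the site overlaps none).  Strand-aware: on '-' genes
    the codon is read on the reverse complement.
    """
    if not site.is_snv:
        raise ConfigurationError("classify_effect handles SNVs only")
    genome_base = reference.fetch(site.chrom, site.pos, site.pos)
    if genome_base != site.ref:
        raise DataConsistencyError(
            f"{site.chrom}:{site.pos} REF {site.ref} != genome base {genome_base}"
        )
    best: EffectAnnotation | None = None
    for gene in genes:
        if gene.chrom != site.chrom or not gene.contains(site.pos):
            continue
        ann = _classify_in_gene(site, gene, reference)
        if best is None or IMPACT_ORDER.index(ann.impact) > IMPACT_ORDER.index(best.impact):
            best = ann
    if best is None:
        return EffectAnnotation(effect="intergenic", impact="MODIFIER", gene_id="")
    return best


def _classify_in_gene(
    site: VariantSite, gene: GeneModel, reference: ReferenceGenome
) -> EffectAnnotation:
    offset = _cds_offset(gene, site.pos) if gene.cds_segments else None
    if offset is None:
        effect = "splice_region" if gene.cds_segments and _near_cds_boundary(
            gene, site.pos
        ) else "intronic"
        return EffectAnnotation(
            effect=effect, impact=IMPACT_BY_EFFECT[effect], gene_id=gene.gene_id
        )
    cds = _cds_sequence(gene, reference)
    codon_idx = offset // 3
    within = offset % 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon) < 3:
        # trailing partial codon (malformed CDS length); treat conservatively
        return EffectAnnotation(
            effect="other", impact="MODIFIER", gene_id=gene.gene_id
        )
    alt_base = site.alt if gene.strand == "+" else reverse_complement(site.alt)
    mutated = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = _translate_codon(codon)
    aa_alt = _translate_codon(mutated)
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "stop_gained"
    elif aa_ref == "*":
        effect = "stop_lost"
    elif codon_idx == 0 and codon == "ATG":
        effect = "start_lost"
    else:
        effect = "missense"
    return EffectAnnotation(
        effect=effect, impact=IMPACT_BY_EFFECT[effect], gene_id=gene.gene_id
    )


def site_max_impact(site: VariantSite) -> str:
    """Maximum impact over a site's annotations (MODIFIER when unannotated)."""
    anns = site.ann if site.ann is not None else parse_ann_field(site)
    if not anns:
        return "MODIFIER"
    return max((a.impact for a in anns), key=IMPACT_ORDER.index)


def annotate_candidates(
    candidates: CandidateSet,
    genes: Sequence[GeneModel],
    reference: ReferenceGenome,
) -> None:
    """Ensure every candidate carries annotations.

    Sites with an ANN field use it; bare SNVs fall back to the internal
    classifier; bare non-SNVs get no annotation (MODIFIER by convention).
    """
    for site in candidates.sites.values():
        if site.ann_raw:
            parse_ann_field(site)
        elif site.is_snv:
            site.ann = [classify_effect(site, genes, reference)]
        else:
            site.ann = []


def select_moderate_high(candidates: CandidateSet) -> CandidateSet:
    """Subset of candidates whose maximum impact is MODERATE or HIGH."""
    keep: dict[SiteKey, VariantSite] = {}
    for key, site in candidates.sites.items():
        if site_max_impact(site) in ("MODERATE", "HIGH"):
            keep[key] = site
    stage_counts = dict(candidates.stage_counts)
    stage_counts["moderate_high"] = len(keep)
    return CandidateSet(
        sites=keep,
        stage_counts=stage_counts,
        provenance={k: candidates.provenance[k] for k in keep},
    )


def effects_frame(
    candidates: CandidateSet, provenance: Mapping[SiteKey, object] | None = None
) -> "pd.DataFrame":
    """Per-site effect table (chrom, pos, ref, alt, gene, effect, impact, af)."""
    import pandas as pd

    rows = []
    for key, site in candidates.sites.items():
        anns = site.ann or []
        top = max(
            anns, key=lambda a: IMPACT_ORDER.index(a.impact), default=None
        )
        flags = candidates.provenance.get(key)
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "gene": top.gene_id if top else "",
                "effect": top.effect if top else "",
                "impact": top.impact if top else "MODIFIER",
                "population_af": flags.population_af if flags else None,
            }
        )
    return pd.DataFrame(rows)
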