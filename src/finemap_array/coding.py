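"""Coding/regulatory arm: frequency gate plus functional prioritization.

A variant is selected when it lies inside a fine-mapping region (or the MHC
window), exceeds at least one population's minor-allele-frequency threshold
(disjunction — any one population suffices), satisfies at least one of the
three functional criteria (protein-altering/splice effect, CADD phred >= 30,
RegulomeDB category 1a-1e), is not already on the base array, and is not
flagged tri-allelic.  Frequency bounds are strict (>); the CADD bound is
inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable, Mapping, Optional, Sequence

from .records import (
    ARM_CODING,
    AnnotationRecord,
    EffectClass,
    Manifest,
    SelectionRecord,
    ValidationError,
    VariantKey,
)
from .regions import Region, assign_to_regions

DEFAULT_CADD_MIN = 30.0
DEFAULT_REGULOME_CATEGORIES = frozenset({"1a", "1b", "1c", "1d", "1e"})

INCLUDED_EFFECTS = frozenset(
    {EffectClass.NONSYNONYMOUS, EffectClass.STOPGAIN, EffectClass.STOPLOSS, EffectClass.SPLICING}
)


@dataclass(frozen=True)
class FrequencyThresholds:
    """Per-population MAF minima (strict lower bounds).

    Defaults keep power for association in the recently studied African and
    Hispanic samples (lower bar) while requiring commoner variation in the
    European and East Asian reference sets.
    """

    afr: float = 0.01
    amr: float = 0.01
    nfe: float = 0.05
    eas: float = 0.05

    def __post_init__(self) -> None:
        for pop, th in self.as_mapping().items():
            if not (0.0 < th < 0.5):
                raise ValidationError(f"{pop} threshold must lie in (0, 0.5), got {th}")

    def as_mapping(self) -> Mapping[str, float]:
        return {"AFR": self.afr, "AMR": self.amr, "NFE": self.nfe, "EAS": self.eas}


def passes_frequency_filter(rec: AnnotationRecord, th: FrequencyThresholds) -> bool:
    """True iff at least one population's MAF strictly exceeds its threshold."""
    for pop, bound in th.as_mapping().items():
        maf = rec.freqs.get(pop)
        if maf is not None and maf > bound:
            return True
    return False


def is_included_effect(rec: AnnotationRecord) -> bool:
    """Protein-altering (non-synonymous, stop gain/loss) or splice-site variant."""
    return rec.effect_class in INCLUDED_EFFECTS


def passes_cadd(rec: AnnotationRecord, min_cadd: float = DEFAULT_CADD_MIN) -> bool:
    """CADD phred present and >= the bound (inclusive; 30 = top 0.1% deleterious)."""
    return rec.cadd_phred is not None and rec.cadd_phred >= min_cadd


def passes_regulome(
    rec: AnnotationRecord,
    categories: Collection[str] = DEFAULT_REGULOME_CATEGORIES,
) -> bool:
    """RegulomeDB category in 1a-1e (eQTL coincident with TF-binding evidence)."""
    return rec.regulome_category is not None and rec.regulome_category in categories


def select_coding_regulatory(
    annotations: Iterable[AnnotationRecord],
    regions: Sequence[Region],
    manifest: Manifest,
    thresholds: Optional[FrequencyThresholds] = None,
    tri_allelic: Collection[VariantKey] = (),
    min_cadd: float = DEFAULT_CADD_MIN,
    regulome_categories: Collection[str] = DEFAULT_REGULOME_CATEGORIES,
) -> list[SelectionRecord]:
    """Run the full coding/regulatory cascade over an annotation table.

    ``regions`` may include the MHC window alongside merged signal regions;
    a chromosome-6 signal region overlapping the MHC is handled by checking
    non-MHC regions first.  Provenance tags record every sub-criterion that
    fired (``effect:<class>``, ``cadd``, ``regulome``), so per-criterion
    funnel counts remain computable after dedup.
    """
    thresholds = thresholds or FrequencyThresholds()
    annotations = list(annotations)
    tri_allelic = set(tri_allelic)

    non_mhc = [r for r in regions if not r.is_mhc]
    mhc = [r for r in regions if r.is_mhc]
    assignment = assign_to_regions([a.key for a in annotations], non_mhc)

    selected: list[SelectionRecord] = []
    seen: set[VariantKey] = set()
    for ann in annotations:
        if ann.key in seen:
            raise ValidationError(f"duplicate annotation key {ann.key}")
        seen.add(ann.key)

        region = assignment[ann.key]
        if region is None:
            region = next((m for m in mhc if m.contains(ann.key.chrom, ann.key.pos)), None)
        if region is None:
            continue
        if not passes_frequency_filter(ann, thresholds):
            continue

        tags = []
        if is_included_effect(ann):
            tags.append(f"effect:{ann.effect_class.value}")
        if passes_cadd(ann, min_cadd):
            tags.append("cadd")
        if passes_regulome(ann, regulome_categories):
            tags.append("regulome")
        if not tags:
            continue
        if ann.key in manifest or ann.key in tri_allelic:
            continue

        selected.append(
            SelectionRecord(
                key=ann.key,
                arm=ARM_CODING,
                criteria=tuple(tags),
                region_id=region.region_id,
            )
        )
    return selected
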