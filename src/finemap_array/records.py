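"""Core record types shared across the content-selection pipeline.

Every join, dedup and exclusion in the pipeline is keyed on
:class:`VariantKey` — the (chrom, pos, ref, alt) identity of a bi-allelic
variant on GRCh37, 1-based.  Multi-allelic sites are represented as several
keys carrying a tri-allelic flag so that their exclusion is an explicit,
countable filter stage rather than a silent drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

import numpy as np

POPULATIONS_FREQ = ("AFR", "AMR", "NFE", "EAS")
POPULATIONS_PANEL = ("NFE", "AMR", "AA")
POPULATIONS_REPLICATION = ("AMR", "AA")

_ALLELE_CHARS = frozenset("ACGT")


class ValidationError(ValueError):
    """An input value violates a documented invariant."""


class FormatError(ValueError):
    """An external file cannot be parsed as its declared format."""


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort chromosomes numerically where possible ('2' before '10', X/Y last)."""
    return (int(chrom), "") if chrom.isdigit() else (1000, chrom)


@dataclass(frozen=True, order=True)
class VariantKey:
    """Canonical bi-allelic variant identity: chrom / 1-based pos / ref / alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise ValidationError(
                    f"{name} allele must be a non-empty uppercase ACGT string, got {allele!r}"
                )
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt must differ, got {self.ref}/{self.alt}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        """Parse a 'chrom:pos:ref:alt' string."""
        parts = text.strip().split(":")
        if len(parts) != 4:
            raise FormatError(f"expected chrom:pos:ref:alt, got {text!r}")
        chrom, pos, ref, alt = parts
        return cls(chrom, int(pos), ref.upper(), alt.upper())

    @property
    def allele_set(self) -> frozenset:
        return frozenset((self.ref, self.alt))

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or len(self.alt) != 1


class EffectClass(str, Enum):
    """Functional consequence class, as annotated by an effect predictor."""

    NONSYNONYMOUS = "nonsynonymous"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    OTHER = "other"

    @classmethod
    def from_string(cls, text: Optional[str]) -> "EffectClass":
        if text is None:
            return cls.OTHER
        norm = text.strip().lower().replace("-", "").replace("_", "").replace(" ", "")
        aliases = {
            "nonsynonymous": cls.NONSYNONYMOUS,
            "nonsynonymoussnv": cls.NONSYNONYMOUS,
            "missense": cls.NONSYNONYMOUS,
            "stopgain": cls.STOPGAIN,
            "stoploss": cls.STOPLOSS,
            "splicing": cls.SPLICING,
            "splice": cls.SPLICING,
            "synonymous": cls.SYNONYMOUS,
            "synonymoussnv": cls.SYNONYMOUS,
        }
        return aliases.get(norm, cls.OTHER)


@dataclass(frozen=True)
class AnnotationRecord:
    """One variant's functional annotation and population allele frequencies.

    ``freqs`` maps population labels (AFR/AMR/NFE/EAS) to minor allele
    frequencies in [0, 0.5]; a missing frequency means the variant fails
    that population's frequency gate.
    """

    key: VariantKey
    effect_class: EffectClass = EffectClass.OTHER
    cadd_phred: Optional[float] = None
    regulome_category: Optional[str] = None
    freqs: Mapping[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError(f"CADD phred must be non-negative, got {self.cadd_phred}")
        for pop, maf in self.freqs.items():
            if maf is not None and not (0.0 <= maf <= 0.5):
                raise ValidationError(f"MAF for {pop} outside [0, 0.5]: {maf}")


@dataclass(frozen=True)
class ManifestEntry:
    """A variant already present on the base array content."""

    key: VariantKey
    source: str = "base_array"


class Manifest:
    """Base-array content lookup.

    Matching is by exact (chrom, pos) plus unordered allele-set equality
    after uppercasing; strand flipping is not attempted.
    """

    def __init__(self, entries: Iterable[ManifestEntry] = ()):
        self._by_pos: dict[tuple[str, int], list[ManifestEntry]] = {}
        self._keys: set[VariantKey] = set()
        for entry in entries:
            self.add(entry)

    def add(self, entry: ManifestEntry) -> None:
        if entry.key in self._keys:
            raise ValidationError(f"duplicate manifest key {entry.key}")
        self._keys.add(entry.key)
        self._by_pos.setdefault((entry.key.chrom, entry.key.pos), []).append(entry)

    def __len__(self) -> int:
        return len(self._keys)

    def __contains__(self, key: VariantKey) -> bool:
        for entry in self._by_pos.get((key.chrom, key.pos), ()):
            if entry.key.allele_set == key.allele_set:
                return True
        return False

    def entries(self) -> list[ManifestEntry]:
        all_entries = [e for lst in self._by_pos.values() for e in lst]
        return sorted(all_entries, key=lambda e: (chrom_sort_key(e.key.chrom), e.key.pos, e.key.ref, e.key.alt))


@dataclass(frozen=True)
class GenotypeProbabilityRecord:
    """Per-sample genotype probability triples (p0, p1, p2) for one variant."""

    key: VariantKey
    probs: np.ndarray  # shape (N, 3)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 3 or probs.shape[0] < 1:
            raise ValidationError(f"probs must have shape (N, 3), got {probs.shape}")
        if (probs < 0).any():
            raise ValidationError("genotype probabilities must be non-negative")
        if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValidationError("each genotype probability triple must sum to 1 within 1e-6")
        object.__setattr__(self, "probs", probs)


@dataclass(frozen=True)
class ReplicationRecord:
    """Replication summary for one index signal in one study population.

    ``effect_sign`` is relative to the discovery direction: +1 same
    direction, -1 opposite.  ``p_two_sided`` is the published two-sided p.
    """

    population: str
    effect_sign: Optional[int] = None
    p_two_sided: Optional[float] = None

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS_REPLICATION:
            raise ValidationError(f"replication population must be AMR or AA, got {self.population}")
        if self.effect_sign is not None and self.effect_sign not in (1, -1):
            raise ValidationError(f"effect sign must be +1/-1, got {self.effect_sign}")
        if self.p_two_sided is not None and not (0.0 < self.p_two_sided <= 1.0):
            raise ValidationError(f"two-sided p must be in (0, 1], got {self.p_two_sided}")


@dataclass(frozen=True)
class IndexSignal:
    """A lead association variant with its replication records."""

    key: VariantKey
    discovery_direction: int = 1
    replication: Mapping[str, ReplicationRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.discovery_direction not in (1, -1):
            raise ValidationError(
                f"discovery direction must be +1/-1, got {self.discovery_direction}"
            )
        for pop in POPULATIONS_REPLICATION:
            if pop not in self.replication:
                # Entries are required to exist; their fields may be missing.
                object.__setattr__(
                    self,
                    "replication",
                    {**dict(self.replication), pop: ReplicationRecord(pop)},
                )


ARM_CODING = "coding_regulatory"
ARM_FINE_MAPPING = "fine_mapping"


@dataclass
class SelectionRecord:
    """A candidate variant with provenance: which arm and criteria selected it.

    ``criteria`` tags are short strings such as ``effect:stopgain``, ``cadd``,
    ``regulome``, ``status:BOTH`` or ``pool:NFE``; a variant selected by
    several sub-criteria carries all of their tags.
    """

    key: VariantKey
    arm: str
    criteria: tuple[str, ...] = ()
    region_id: Optional[int] = None
    signal_keys: tuple[VariantKey, ...] = ()
    priority: Optional[bool] = None
    bead_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.arm not in (ARM_CODING, ARM_FINE_MAPPING):
            raise ValidationError(f"unknown selection arm {self.arm!r}")

    def merged_with(self, other: "SelectionRecord") -> "SelectionRecord":
        """Union provenance for a variant selected by both arms / several signals."""
        if other.key != self.key:
            raise ValidationError("cannot merge records for different keys")
        arm = self.arm if self.arm == other.arm else ARM_CODING
        criteria = self.criteria + tuple(c for c in other.criteria if c not in self.criteria)
        if self.arm != other.arm:
            criteria = criteria + ("both_arms",) if "both_arms" not in criteria else criteria
        signals = self.signal_keys + tuple(
            k for k in other.signal_keys if k not in self.signal_keys
        )
        region = self.region_id if self.region_id is not None else other.region_id
        return SelectionRecord(self.key, arm, criteria, region, signals)
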