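"""Fine-mapping windows around index signals, plus the fixed MHC window.

Each index signal gets a window extending ``flank`` bp on each side of its
position (default 1 Mb, i.e. a 2-Mb locus).  Overlapping or abutting windows
on one chromosome are merged, so 200 signals typically collapse into fewer
loci.  Coordinates are GRCh37, 1-based, inclusive on both ends; windows are
clipped at position 1.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .records import IndexSignal, ValidationError, VariantKey, chrom_sort_key

DEFAULT_FLANK = 1_000_000

MHC_CHROM = "6"
MHC_START = 27_000_000
MHC_END = 34_000_000


@dataclass(frozen=True)
class Region:
    """A merged fine-mapping window (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    index_keys: tuple[VariantKey, ...] = ()
    is_mhc: bool = False
    region_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"region start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValidationError(f"region start must be >= 1, got {self.start}")
        if not self.index_keys and not self.is_mhc:
            raise ValidationError("non-MHC region must contain at least one index signal")

    @property
    def span(self) -> int:
        """Inclusive length in bp."""
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def mhc_region(region_id: Optional[int] = None) -> Region:
    """The major histocompatibility complex window, chr6:27-34 Mb (GRCh37)."""
    return Region(MHC_CHROM, MHC_START, MHC_END, (), is_mhc=True, region_id=region_id)


def build_regions(
    signals: Sequence[IndexSignal], flank: int = DEFAULT_FLANK
) -> list[Region]:
    """Merge per-signal windows [pos-flank, pos+flank] into disjoint regions.

    Windows that overlap or abut (gap of zero) on the same chromosome are
    merged; each signal ends up in exactly one region.  Region ids are
    assigned sequentially in (chromosome, start) order.
    """
    seen: set[VariantKey] = set()
    for s in signals:
        if s.key in seen:
            raise ValidationError(f"duplicate index signal key {s.key}")
        seen.add(s.key)

    windows = sorted(
        ((s.key.chrom, max(1, s.key.pos - flank), s.key.pos + flank, s.key) for s in signals),
        key=lambda w: (chrom_sort_key(w[0]), w[1], w[2]),
    )
    regions: list[Region] = []
    current: Optional[list] = None  # [chrom, start, end, [keys]]
    for chrom, start, end, key in windows:
        if current is not None and current[0] == chrom and start <= current[2] + 1:
            current[2] = max(current[2], end)
            current[3].append(key)
        else:
            if current is not None:
                regions.append(Region(current[0], current[1], current[2], tuple(current[3])))
            current = [chrom, start, end, [key]]
    if current is not None:
        regions.append(Region(current[0], current[1], current[2], tuple(current[3])))

    return [
        Region(r.chrom, r.start, r.end, r.index_keys, r.is_mhc, region_id=i)
        for i, r in enumerate(regions)
    ]


def assign_to_regions(
    keys: Iterable[VariantKey], regions: Sequence[Region]
) -> dict[VariantKey, Optional[Region]]:
    """Map each key to the region containing it (inclusive bounds), or None.

    Regions must be non-overlapping within each chromosome.
    """
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    starts: dict[str, list[int]] = {}
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping regions on chromosome {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
        starts[chrom] = [r.start for r in rs]

    out: dict[VariantKey, Optional[Region]] = {}
    for key in keys:
        region = None
        if key.chrom in starts:
            i = bisect_right(starts[key.chrom], key.pos) - 1
            if i >= 0 and by_chrom[key.chrom][i].end >= key.pos:
                region = by_chrom[key.chrom][i]
        out[key] = region
    return out


def signals_outside_mhc(signals: Sequence[IndexSignal]) -> list[IndexSignal]:
    """Index signals eligible for the fine-mapping arm (autosomal, non-MHC)."""
    mhc = mhc_region()
    return [s for s in signals if not mhc.contains(s.key.chrom, s.key.pos)]
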