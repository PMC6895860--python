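"""Readers and writers for every external representation the pipeline touches.

Tabular inputs (annotations, manifests, index signals, designability, INFO
scores, genotype probabilities) are tab-separated with headers; reference
panels are VCF 4.x.  Output selections are written as TSV plus BED (0-based
half-open, converted from the internal 1-based inclusive convention).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panels import GenotypePanel
from .records import (
    AnnotationRecord,
    EffectClass,
    FormatError,
    GenotypeProbabilityRecord,
    IndexSignal,
    Manifest,
    ManifestEntry,
    ReplicationRecord,
    SelectionRecord,
    ValidationError,
    VariantKey,
    chrom_sort_key,
)
from .regions import Region
from .report import FunnelReport

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


# ---------------------------------------------------------------------------
# VCF panels
# ---------------------------------------------------------------------------

def read_panel_vcf(path, population_label: str) -> GenotypePanel:
    """Load a population reference panel from VCF.

    Multi-allelic records are split into one bi-allelic key per ALT allele
    and every resulting key is flagged tri-allelic, so their exclusion is a
    countable downstream filter.  The panel is marked phased only if every
    genotype separator in the file is phased ('|').
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises bare Exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    n = len(samples)
    if n == 0:
        raise FormatError(f"VCF {path} has no sample columns")

    keys: list[VariantKey] = []
    allele_cols: list[np.ndarray] = []  # each (2N,) of 0/1/-1 for one key
    tri: set[VariantKey] = set()
    phased_all = True

    for rec_no, v in enumerate(vcf, start=1):
        ref = (v.REF or "").upper()
        alts = [a.upper() for a in (v.ALT or [])]
        usable = [(i, a) for i, a in enumerate(alts) if a and set(a) <= _ACGT]
        if not set(ref) <= _ACGT or not ref:
            raise FormatError(f"{path} record {rec_no}: non-ACGT REF {v.REF!r}")
        if not usable:
            logger.warning("%s record %d: no ACGT ALT allele; skipped", path, rec_no)
            continue

        genotypes = v.genotypes  # per sample: [allele0, allele1, phased]
        alleles = np.full((n, 2), -1, dtype=np.int16)
        for s, g in enumerate(genotypes):
            if len(g) != 3:
                raise FormatError(
                    f"{path} record {rec_no}: mixed or non-diploid ploidy in sample {samples[s]}"
                )
            alleles[s, 0], alleles[s, 1] = g[0], g[1]
            if not g[2]:
                phased_all = False

        flat = alleles.reshape(-1)  # (2N,), haplotype-major within sample
        for alt_index, alt in usable:
            try:
                key = VariantKey(str(v.CHROM).removeprefix("chr"), int(v.POS), ref, alt)
            except ValidationError as exc:
                raise FormatError(f"{path} record {rec_no}: {exc}") from exc
            col = np.where(flat < 0, -1, (flat == alt_index + 1).astype(np.int8))
            keys.append(key)
            allele_cols.append(col.astype(np.int8))
            if len(alts) > 1:
                tri.add(key)

    if not keys:
        raise FormatError(f"VCF {path} contains no usable variant records")
    hap_matrix = np.column_stack(allele_cols)

    if phased_all:
        return GenotypePanel.from_haplotypes(
            population_label, keys, hap_matrix, samples=samples, tri_allelic=tri
        )
    h0, h1 = hap_matrix[0::2], hap_matrix[1::2]
    genos = np.where((h0 < 0) | (h1 < 0), -1, h0 + h1).astype(np.int8)
    return GenotypePanel(
        population_label, keys, genos, None, samples=samples, tri_allelic=tri
    )


# ---------------------------------------------------------------------------
# tabular helpers
# ---------------------------------------------------------------------------

def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def _key_from_row(row) -> VariantKey:
    return VariantKey(str(row.chrom), int(row.pos), str(row.ref).upper(), str(row.alt).upper())


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", ".", "NA", "nan"):
        return None
    return float(value)


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return text if text and text not in (".", "NA") else None


def _parse_sign(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text in ("", ".", "NA"):
        return None
    if text in ("+", "+1", "1", "1.0"):
        return 1
    if text in ("-", "-1", "-1.0"):
        return -1
    raise FormatError(f"cannot parse effect sign {value!r}")


# ---------------------------------------------------------------------------
# annotations / manifest / signals / scores
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = (
    "chrom", "pos", "ref", "alt", "effect", "cadd", "regulome",
    "afr_maf", "amr_maf", "nfe_maf", "eas_maf",
)


def read_annotation_table(path) -> list[AnnotationRecord]:
    """Load the variant annotation table (effect class, CADD, RegulomeDB, MAFs)."""
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    records = []
    for row in df.itertuples(index=False):
        freqs = {
            "AFR": _opt_float(row.afr_maf),
            "AMR": _opt_float(row.amr_maf),
            "NFE": _opt_float(row.nfe_maf),
            "EAS": _opt_float(row.eas_maf),
        }
        records.append(
            AnnotationRecord(
                key=_key_from_row(row),
                effect_class=EffectClass.from_string(_opt_str(row.effect)),
                cadd_phred=_opt_float(row.cadd),
                regulome_category=_opt_str(row.regulome),
                freqs=freqs,
            )
        )
    return records


def read_manifest(path) -> Manifest:
    """Load base-array content as a manifest keyed on position + allele set."""
    df = _read_tsv(path, ("chrom", "pos", "ref", "alt"))
    manifest = Manifest()
    for row in df.itertuples(index=False):
        source = getattr(row, "source", "base_array")
        manifest.add(ManifestEntry(_key_from_row(row), str(source)))
    return manifest


SIGNAL_COLUMNS = (
    "chrom", "pos", "ref", "alt", "discovery_direction",
    "amr_beta_sign", "amr_p2", "aa_beta_sign", "aa_p2",
)


def read_index_signals(path) -> list[IndexSignal]:
    """Load index association signals with their two-population replication stats."""
    df = _read_tsv(path, SIGNAL_COLUMNS)
    signals = []
    for row in df.itertuples(index=False):
        signals.append(
            IndexSignal(
                key=_key_from_row(row),
                discovery_direction=_parse_sign(row.discovery_direction) or 1,
                replication={
                    "AMR": ReplicationRecord("AMR", _parse_sign(row.amr_beta_sign), _opt_float(row.amr_p2)),
                    "AA": ReplicationRecord("AA", _parse_sign(row.aa_beta_sign), _opt_float(row.aa_p2)),
                },
            )
        )
    return signals


def read_score_table(path, column: str) -> dict[VariantKey, float]:
    """Load a per-variant score table (designability or INFO) into a dict."""
    df = _read_tsv(path, ("chrom", "pos", "ref", "alt", column))
    scores: dict[VariantKey, float] = {}
    for row in df.itertuples(index=False):
        value = _opt_float(getattr(row, column))
        if value is not None:
            scores[_key_from_row(row)] = value
    return scores


def read_designability(path) -> dict[VariantKey, float]:
    return read_score_table(path, "score")


def read_info_scores(path) -> dict[VariantKey, float]:
    scores = read_score_table(path, "info")
    for key, value in scores.items():
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"INFO score for {key} outside [0,1]: {value}")
    return scores


def read_genotype_probabilities(path) -> list[GenotypeProbabilityRecord]:
    """Load per-sample genotype probability triples.

    After the four key columns, the remaining numeric columns are consumed in
    groups of three as (p0, p1, p2) per sample.
    """
    df = _read_tsv(path, ("chrom", "pos", "ref", "alt"))
    prob_cols = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    if not prob_cols or len(prob_cols) % 3 != 0:
        raise FormatError(
            f"{path}: expected 3 probability columns per sample, got {len(prob_cols)}"
        )
    records = []
    for row in df.itertuples(index=False):
        values = np.array([getattr(row, c) for c in prob_cols], dtype=float)
        records.append(GenotypeProbabilityRecord(_key_from_row(row), values.reshape(-1, 3)))
    return records


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

SELECTION_COLUMNS = (
    "chrom", "pos", "ref", "alt", "arm", "criteria", "region_id", "priority", "bead_count",
)


def write_selection(
    records: Sequence[SelectionRecord],
    path,
    funnel: Optional[FunnelReport] = None,
    funnel_path=None,
) -> None:
    """Write selected variants as TSV plus an optional funnel-summary text.

    Keys must be unique.  The funnel summary defaults to ``<path>.funnel.txt``.
    """
    keys = [r.key for r in records]
    if len(set(keys)) != len(keys):
        raise ValidationError("selection records contain duplicate keys")
    rows = [
        {
            "chrom": r.key.chrom,
            "pos": r.key.pos,
            "ref": r.key.ref,
            "alt": r.key.alt,
            "arm": r.arm,
            "criteria": ";".join(r.criteria) if r.criteria else ".",
            "region_id": r.region_id if r.region_id is not None else ".",
            "priority": {True: "1", False: "0", None: "."}[r.priority],
            "bead_count": r.bead_count if r.bead_count is not None else ".",
        }
        for r in sorted(records, key=lambda r: (chrom_sort_key(r.key.chrom), r.key.pos, r.key.ref, r.key.alt))
    ]
    pd.DataFrame(rows, columns=SELECTION_COLUMNS).to_csv(path, sep="\t", index=False)

    if funnel is None:
        funnel = FunnelReport()
        funnel.add("selection", n_variants=len(records))
    funnel_path = funnel_path or (str(path) + ".funnel.txt")
    funnel.write(funnel_path)


def read_selection(path) -> list[SelectionRecord]:
    """Re-parse a written selection TSV (round-trips keys and provenance)."""
    df = _read_tsv(path, SELECTION_COLUMNS)
    records = []
    for row in df.itertuples(index=False):
        criteria = _opt_str(row.criteria)
        priority = _opt_str(str(row.priority))
        records.append(
            SelectionRecord(
                key=_key_from_row(row),
                arm=str(row.arm),
                criteria=tuple(criteria.split(";")) if criteria else (),
                region_id=None if _opt_str(str(row.region_id)) is None else int(row.region_id),
                priority=None if priority is None else priority == "1",
                bead_count=None if _opt_str(str(row.bead_count)) is None else int(row.bead_count),
            )
        )
    return records


def write_selection_bed(records: Sequence[SelectionRecord], path) -> None:
    """BED export of selected variants (0-based half-open over the ref allele)."""
    rows = sorted(records, key=lambda r: (chrom_sort_key(r.key.chrom), r.key.pos))
    with open(path, "w") as fh:
        for r in rows:
            start = r.key.pos - 1
            fh.write(f"{r.key.chrom}\t{start}\t{start + len(r.key.ref)}\t{r.key}\n")


def write_regions_bed(regions: Sequence[Region], path) -> None:
    """BED export of fine-mapping regions (1-based inclusive -> 0-based half-open)."""
    rows = sorted(regions, key=lambda r: (chrom_sort_key(r.chrom), r.start))
    with open(path, "w") as fh:
        for r in rows:
            name = "MHC" if r.is_mhc else f"region_{r.region_id}"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")
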