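"""Pairwise linkage disequilibrium (r²) between two loci in a population panel.

r² is the squared correlation of allelic states,

    r² = D² / (pA (1-pA) pB (1-pB)),   D = pAB - pA pB,

computed from the four two-locus gamete (haplotype) frequencies.  With phased
haplotypes the gamete frequencies are direct counts; with unphased diploid
genotypes they are maximum-likelihood estimates from the classic two-locus
EM algorithm, in which only the double-heterozygote cell has ambiguous phase.

r² is *undefined* (returned as ``None``) when either locus is monomorphic in
the pool: a variant cannot be "in LD" with a site that does not vary there.
Downstream selection treats undefined r² as failing the LD requirement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

from .records import ValidationError, VariantKey

if TYPE_CHECKING:  # pragma: no cover
    from .panels import GenotypePanel
    from .regions import Region

logger = logging.getLogger(__name__)

EM_TOL = 1e-8
EM_MAX_ITER = 1000


class UndefinedDataError(ValueError):
    """No pairwise-complete observations at the requested locus pair."""


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """Frequencies of the four two-locus gametes AB, Ab, aB, ab.

    "A"/"B" denote the counted (alternate) allele at each locus; which allele
    is counted does not affect r².
    """

    pAB: float
    pAb: float
    paB: float
    pab: float

    def __post_init__(self) -> None:
        vals = (self.pAB, self.pAb, self.paB, self.pab)
        if any(v < -1e-12 for v in vals):
            raise ValidationError(f"gamete frequencies must be non-negative: {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValidationError(f"gamete frequencies must sum to 1: {vals}")

    @property
    def p_a(self) -> float:
        """Frequency of the counted allele at the first locus."""
        return self.pAB + self.pAb

    @property
    def p_b(self) -> float:
        """Frequency of the counted allele at the second locus."""
        return self.pAB + self.paB

    @property
    def d(self) -> float:
        """Coefficient of linkage disequilibrium D = pAB - pA pB."""
        return self.pAB - self.p_a * self.p_b

    def as_array(self) -> np.ndarray:
        return np.array([self.pAB, self.pAb, self.paB, self.pab], dtype=float)


@dataclass(frozen=True)
class LDResult:
    """Per-population r² between a candidate and an index variant."""

    key_a: VariantKey
    key_b: VariantKey
    r2: dict  # population label -> float or None


def r_squared(h: HaplotypeFrequencies) -> Optional[float]:
    """Squared correlation of allelic states; None if either locus is monomorphic."""
    pa, pb = h.p_a, h.p_b
    denom = pa * (1.0 - pa) * pb * (1.0 - pb)
    if denom <= 0.0:
        return None
    r2 = h.d * h.d / denom
    return min(max(r2, 0.0), 1.0)


def haplotype_freqs_phased(
    hap_a: np.ndarray, hap_b: np.ndarray
) -> HaplotypeFrequencies:
    """Gamete frequencies by direct counting over pairwise-complete haplotypes.

    ``hap_a``/``hap_b`` are integer allele vectors (0/1, -1 for missing), one
    entry per haplotype.
    """
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != b.shape:
        raise ValidationError("haplotype vectors must have equal length")
    complete = (a >= 0) & (b >= 0)
    n = int(complete.sum())
    if n == 0:
        raise UndefinedDataError("no pairwise-complete haplotypes at this locus pair")
    a, b = a[complete], b[complete]
    n_ab = int(((a == 1) & (b == 1)).sum())
    n_aB = int(((a == 0) & (b == 1)).sum())
    n_Ab = int(((a == 1) & (b == 0)).sum())
    n_00 = n - n_ab - n_aB - n_Ab
    return HaplotypeFrequencies(n_ab / n, n_Ab / n, n_aB / n, n_00 / n)


def genotype_counts(geno_a: np.ndarray, geno_b: np.ndarray) -> np.ndarray:
    """3x3 table of two-locus genotype counts over pairwise-complete samples.

    Rows index the alt-allele count at locus A, columns at locus B.
    """
    a = np.asarray(geno_a)
    b = np.asarray(geno_b)
    if a.shape != b.shape:
        raise ValidationError("genotype vectors must have equal length")
    complete = (a >= 0) & (b >= 0)
    a, b = a[complete], b[complete]
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (a.astype(np.int64), b.astype(np.int64)), 1)
    return counts


def _genotype_probs(h: np.ndarray) -> np.ndarray:
    """3x3 genotype probabilities under random union of gametes (HWE)."""
    pAB, pAb, paB, pab = h
    p = np.empty((3, 3))
    p[2, 2] = pAB * pAB
    p[2, 1] = 2 * pAB * pAb
    p[2, 0] = pAb * pAb
    p[1, 2] = 2 * pAB * paB
    p[1, 1] = 2 * (pAB * pab + pAb * paB)
    p[1, 0] = 2 * pAb * pab
    p[0, 2] = paB * paB
    p[0, 1] = 2 * paB * pab
    p[0, 0] = pab * pab
    return p


def log_likelihood(counts: np.ndarray, h: HaplotypeFrequencies) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table under gamete freqs h."""
    counts = np.asarray(counts, dtype=float)
    probs = _genotype_probs(h.as_array())
    mask = counts > 0
    with np.errstate(divide="ignore"):
        terms = counts[mask] * np.log(probs[mask])
    return float(terms.sum())  # -inf if a positive count has zero probability


def em_haplotype_freqs(
    counts: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    return_history: bool = False,
):
    """Maximum-likelihood gamete frequencies from a 3x3 genotype count table.

    The only latent quantity is the phase of double heterozygotes; the E-step
    splits that cell between the coupling (AB/ab) and repulsion (Ab/aB)
    resolutions in proportion to their current expected frequency, and the
    M-step re-tallies gametes.  Initialization is at linkage equilibrium
    (pAB = pA pB), which is deterministic; for non-identifiable tables the
    equilibrium-basin solution is returned.

    Returns None if either locus is monomorphic in the table.  With
    ``return_history`` the per-iteration log-likelihood trace is returned
    alongside the estimate.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3) or (counts < 0).any():
        raise ValidationError("counts must be a non-negative 3x3 table")
    n = counts.sum()
    if n <= 0:
        raise UndefinedDataError("empty genotype table")
    two_n = 2.0 * n

    # Allele counts at each locus are phase-independent margins.
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    p_a = (2 * row[2] + row[1]) / two_n
    p_b = (2 * col[2] + col[1]) / two_n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return (None, []) if return_history else None

    # Fixed gamete tallies from the eight unambiguous cells.
    base_AB = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base_Ab = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base_aB = 2 * counts[0, 2] + counts[1, 2] + counts[0, 1]
    base_ab = 2 * counts[0, 0] + counts[1, 0] + counts[0, 1]
    n_dh = counts[1, 1]

    h = np.array(
        [p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)]
    )
    history: list[float] = []
    for _ in range(max_iter):
        coupling = h[0] * h[3]
        repulsion = h[1] * h[2]
        total = coupling + repulsion
        frac = 0.5 if total <= 0 else coupling / total
        new = np.array(
            [
                base_AB + n_dh * frac,
                base_Ab + n_dh * (1 - frac),
                base_aB + n_dh * (1 - frac),
                base_ab + n_dh * frac,
            ]
        ) / two_n
        if return_history:
            history.append(
                log_likelihood(counts, HaplotypeFrequencies(*np.clip(new, 0, None)))
            )
        delta = np.abs(new - h).max()
        h = new
        if delta < tol:
            break
    freqs = HaplotypeFrequencies(*np.clip(h, 0.0, None) / np.clip(h, 0.0, None).sum())
    return (freqs, history) if return_history else freqs


def pairwise_r2(panel: "GenotypePanel", key_a: VariantKey, key_b: VariantKey) -> Optional[float]:
    """r² between two variants in one panel; None when undefined.

    Phased panels use direct gamete counting; unphased panels use the EM
    estimate.  Samples missing either genotype are dropped pairwise.
    """
    for key in (key_a, key_b):
        if not panel.has(key):
            raise KeyError(f"variant {key} absent from {panel.population} panel")
    if panel.phased:
        try:
            h = haplotype_freqs_phased(panel.hap_column(key_a), panel.hap_column(key_b))
        except UndefinedDataError:
            return None
        return r_squared(h)
    counts = genotype_counts(panel.geno_column(key_a), panel.geno_column(key_b))
    if counts.sum() == 0:
        return None
    h = em_haplotype_freqs(counts)
    if h is None:
        return None
    return r_squared(h)


def ld_neighbors(
    panel: "GenotypePanel",
    index_key: VariantKey,
    region: "Region",
    threshold: float = 0.1,
) -> set[VariantKey]:
    """Region variants with defined r² >= threshold (inclusive) to the index.

    The inclusive bound follows the selection rule r² >= 0.1; variants with
    undefined r² (monomorphic in this pool) are never returned.
    """
    if not panel.has(index_key):
        raise KeyError(f"index {index_key} absent from {panel.population} panel")
    out: set[VariantKey] = set()
    for key in panel.keys_in_region(region):
        r2 = pairwise_r2(panel, index_key, key)
        if r2 is not None and r2 >= threshold:
            out.add(key)
    return out
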