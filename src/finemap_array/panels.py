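"""In-memory genotype panels backing r² computation.

A panel holds one population pool's sample-by-variant genotypes (codes
0/1/2, -1 missing) and, when the source data were phased, the underlying
haplotype-by-variant allele matrix (0/1, -1 missing).  Pools mirror the
reference-panel groupings used for LD lookups: NFE (non-Finnish European),
AMR (Hispanic/Latino), AA (African American).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .records import ValidationError, VariantKey
from .regions import Region


class GenotypePanel:
    """Sample x variant genotype matrix for one population pool."""

    def __init__(
        self,
        population: str,
        keys: Sequence[VariantKey],
        genotypes: np.ndarray,
        haplotypes: Optional[np.ndarray] = None,
        samples: Optional[Sequence[str]] = None,
        tri_allelic: Iterable[VariantKey] = (),
    ):
        self.population = population
        self.keys = list(keys)
        self._index = {k: i for i, k in enumerate(self.keys)}
        if len(self._index) != len(self.keys):
            raise ValidationError("duplicate variant keys in panel")

        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.ndim != 2 or genotypes.shape[1] != len(self.keys):
            raise ValidationError(
                f"genotype matrix shape {genotypes.shape} does not match {len(self.keys)} variants"
            )
        bad = ~np.isin(genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValidationError("genotype codes must be in {0,1,2} or -1 for missing")
        self.genotypes = genotypes

        if haplotypes is not None:
            haplotypes = np.asarray(haplotypes, dtype=np.int8)
            if haplotypes.shape != (2 * genotypes.shape[0], len(self.keys)):
                raise ValidationError(
                    "phased panel requires a haplotype matrix of shape (2N, n_variants)"
                )
            if (~np.isin(haplotypes, (-1, 0, 1))).any():
                raise ValidationError("haplotype alleles must be 0/1 or -1 for missing")
        self.haplotypes = haplotypes

        self.samples = list(samples) if samples is not None else [
            f"{population}_{i}" for i in range(genotypes.shape[0])
        ]
        if len(self.samples) != genotypes.shape[0]:
            raise ValidationError("sample names do not match genotype rows")
        self.tri_allelic: set[VariantKey] = set(tri_allelic)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_haplotypes(
        cls,
        population: str,
        keys: Sequence[VariantKey],
        haplotypes: np.ndarray,
        samples: Optional[Sequence[str]] = None,
        tri_allelic: Iterable[VariantKey] = (),
    ) -> "GenotypePanel":
        """Build a phased panel from a (2N, n_variants) 0/1 allele matrix."""
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        if haplotypes.ndim != 2 or haplotypes.shape[0] % 2 != 0:
            raise ValidationError("haplotype matrix must have an even number of rows")
        h0 = haplotypes[0::2]
        h1 = haplotypes[1::2]
        genotypes = np.where((h0 < 0) | (h1 < 0), -1, h0 + h1).astype(np.int8)
        return cls(population, keys, genotypes, haplotypes, samples, tri_allelic)

    def to_unphased(self) -> "GenotypePanel":
        """The same panel with phase information discarded."""
        return GenotypePanel(
            self.population, self.keys, self.genotypes, None, self.samples, self.tri_allelic
        )

    # -- accessors ---------------------------------------------------------

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_samples

    @property
    def n_variants(self) -> int:
        return len(self.keys)

    def has(self, key: VariantKey) -> bool:
        return key in self._index

    def geno_column(self, key: VariantKey) -> np.ndarray:
        return self.genotypes[:, self._index[key]]

    def hap_column(self, key: VariantKey) -> np.ndarray:
        if self.haplotypes is None:
            raise ValidationError("panel is not phased")
        return self.haplotypes[:, self._index[key]]

    def keys_in_region(self, region: Region) -> list[VariantKey]:
        return [k for k in self.keys if region.contains(k.chrom, k.pos)]

    def allele_frequency(self, key: VariantKey) -> Optional[float]:
        """Alt-allele frequency over non-missing calls; None if all missing."""
        g = self.geno_column(key)
        ok = g >= 0
        if not ok.any():
            return None
        return float(g[ok].sum()) / (2.0 * int(ok.sum()))
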