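"""Genotype container shared by the kinship and population-structure layers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_ALLOWED = (0.0, 1.0, 2.0)


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes as alt-allele dosages.

    ``dosage`` is a float array of shape ``(n_samples, n_loci)`` with values
    in {0, 1, 2} and ``NaN`` marking missing calls.  Sample and locus
    identifiers are kept ordered so that matrices written to VCF round-trip
    byte-stably.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.locus_ids = list(self.locus_ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        observed = self.dosage[~np.isnan(self.dosage)]
        if observed.size and not np.isin(observed, _ALLOWED).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def missing_rate(self) -> float:
        return float(np.isnan(self.dosage).mean()) if self.dosage.size else 0.0

    def allele_frequencies(self) -> np.ndarray:
        """Per-locus alt-allele frequency over non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def row(self, sample_id: str) -> np.ndarray:
        return self.dosage[self.sample_ids.index(sample_id)]

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return GenotypeMatrix(list(ids), self.locus_ids, self.dosage[idx])

    def subset_loci(self, keep) -> "GenotypeMatrix":
        """Subset loci by boolean mask or by locus-ID list (order preserved)."""
        keep = list(keep)
        if keep and isinstance(keep[0], (bool, np.bool_)):
            mask = np.asarray(keep, dtype=bool)
            ids = [l for l, k in zip(self.locus_ids, mask) if k]
            return GenotypeMatrix(self.sample_ids, ids, self.dosage[:, mask])
        idx = [self.locus_ids.index(l) for l in keep]
        return GenotypeMatrix(self.sample_ids, list(keep), self.dosage[:, idx])
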