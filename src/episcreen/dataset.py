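"""Canonical in-memory model for case-control genotype data.

A :class:`GenotypeDataset` holds a samples x variants matrix of minor-allele
dosages coded 0/1/2, with -1 marking a missing genotype.  Codes count copies
of ``allele_a`` (the minor allele as determined in the full dataset before any
QC), so the minor-allele frequency of a variant is simply ``mean(code)/2``
over non-missing entries and odds ratios keep a stable orientation across the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

MISSING: int = -1

_SEXES = ("male", "female", "unknown")
_STATUSES = ("case", "control")


@dataclass(frozen=True)
class VariantInfo:
    """Metadata for one biallelic variant.

    ``pos`` is a 1-based base-pair coordinate (PLINK .map / VCF convention).
    ``allele_a`` is the dosage-counted (minor) allele, ``allele_b`` the other.
    ``gene`` is an optional gene label used to restrict the interaction scan.
    """

    id: str
    chrom: str = "1"
    pos: int = 1
    allele_a: str = "A"
    allele_b: str = "B"
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"variant {self.id}: alleles must differ")


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sample: id, sex, age (years, NaN if unknown), status."""

    id: str
    sex: str = "unknown"
    age: float = float("nan")
    status: str = "control"

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sample {self.id}: invalid sex {self.sex!r}")
        if self.status not in _STATUSES:
            raise ValueError(f"sample {self.id}: invalid status {self.status!r}")


class GenotypeDataset:
    """Samples x variants minor-allele dosage matrix plus metadata.

    Parameters
    ----------
    genotypes
        Integer array of shape (n_samples, n_variants) with values in
        {0, 1, 2, -1}; -1 is missing.  Stored as int8.
    variants, samples
        Per-column and per-row metadata; ids must be unique on each axis.
    """

    def __init__(
        self,
        genotypes: np.ndarray,
        variants: Sequence[VariantInfo],
        samples: Sequence[SampleInfo],
    ) -> None:
        g = np.asarray(genotypes)
        if g.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (samples x variants)")
        if not np.issubdtype(g.dtype, np.integer):
            raise ValueError("genotype matrix must be integer-typed")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {int(g[i, j])} at sample {i}, variant {j}"
            )
        if g.shape != (len(samples), len(variants)):
            raise ValueError(
                f"matrix shape {g.shape} does not match metadata "
                f"({len(samples)} samples, {len(variants)} variants)"
            )
        vids = [v.id for v in variants]
        sids = [s.id for s in samples]
        if len(set(vids)) != len(vids):
            raise ValueError("variant ids are not unique")
        if len(set(sids)) != len(sids):
            raise ValueError("sample ids are not unique")
        self.genotypes: np.ndarray = g.astype(np.int8, copy=True)
        self.variants: list[VariantInfo] = list(variants)
        self.samples: list[SampleInfo] = list(samples)
        self._vindex: dict[str, int] = {v.id: j for j, v in enumerate(self.variants)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._vindex[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in dataset") from None

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([s.status == "case" for s in self.samples], dtype=bool)

    @property
    def status_array(self) -> np.ndarray:
        """1 for case, 0 for control."""
        return self.case_mask.astype(np.int8)

    # -- derived statistics --------------------------------------------------

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def allele_a_frequency(self) -> np.ndarray:
        """Per-variant frequency of allele_a among non-missing genotypes.

        Equals the MAF when codes are in canonical minor orientation; NaN for
        variants with no observed genotypes.
        """
        g = self.genotypes.astype(float)
        obs = g >= 0
        with np.errstate(invalid="ignore"):
            return np.where(
                obs.any(axis=0),
                np.where(g < 0, 0, g).sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1)),
                np.nan,
            )

    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency, folded to [0, 0.5]."""
        f = self.allele_a_frequency()
        return np.minimum(f, 1.0 - f)

    # -- manipulation --------------------------------------------------------

    def subset(
        self,
        sample_idx: Optional[Sequence[int]] = None,
        variant_idx: Optional[Sequence[int]] = None,
    ) -> "GenotypeDataset":
        """Return a new dataset restricted to the given row/column indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeDataset(
            self.genotypes[np.ix_(si, vi)],
            [self.variants[j] for j in vi],
            [self.samples[i] for i in si],
        )

    def with_genes(self, gene_map: dict[str, str]) -> "GenotypeDataset":
        """Return a copy with gene labels applied from a variant-id -> gene map."""
        new_vars = [
            replace(v, gene=gene_map.get(v.id, v.gene)) for v in self.variants
        ]
        return GenotypeDataset(self.genotypes, new_vars, self.samples)

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(self.genotypes, self.variants, self.samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.variants == other.variants
            and self.samples == other.samples
        )

    def __repr__(self) -> str:
        n_ca = int(self.case_mask.sum())
        return (
            f"GenotypeDataset({self.n_samples} samples "
            f"[{n_ca} cases/{self.n_samples - n_ca} controls], "
            f"{self.n_variants} variants)"
        )
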