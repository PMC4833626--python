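"""Core genotype container shared by every analysis stage.

Genotypes are biallelic diploid calls stored as alternate-allele dosage:
0 (hom ref), 1 (het), 2 (hom alt), -1 (missing).  Individual metadata
(id, site, group) and locus metadata (RAD locus id, SNP offset within the
93-bp locus, ref/alt bases) travel with the matrix as pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

#: length in bases of a RAD locus consensus sequence
RAD_LOCUS_LENGTH = 93


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotype calls with metadata.

    Parameters
    ----------
    calls
        ``(n_individuals, n_loci)`` int8 array of alt-allele dosages,
        ``-1`` marking missing calls.
    individuals
        DataFrame with columns ``id``, ``site`` and optionally ``group``.
    loci
        DataFrame with columns ``rad_locus_id``, ``snp_offset`` (1-based
        position of the SNP within the RAD locus), ``ref`` and ``alt``.
    """

    calls: np.ndarray
    individuals: pd.DataFrame
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D individuals x loci array")
        if len(self.individuals) != self.calls.shape[0]:
            raise ValueError(
                f"{len(self.individuals)} individual rows for "
                f"{self.calls.shape[0]} call rows"
            )
        if len(self.loci) != self.calls.shape[1]:
            raise ValueError(
                f"{len(self.loci)} locus rows for {self.calls.shape[1]} call columns"
            )
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("calls must be in {-1, 0, 1, 2}")
        for col in ("id",):
            if col not in self.individuals.columns:
                raise ValueError(f"individuals frame lacks column {col!r}")
        for col in ("rad_locus_id", "snp_offset"):
            if col not in self.loci.columns:
                raise ValueError(f"loci frame lacks column {col!r}")
        key = list(zip(self.loci["rad_locus_id"], self.loci["snp_offset"]))
        if len(set(key)) != len(key):
            raise ValueError("(rad_locus_id, snp_offset) pairs must be unique")
        self.individuals = self.individuals.reset_index(drop=True)
        self.loci = self.loci.reset_index(drop=True)

    # -- basic shape -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def individual_missing_fraction(self) -> np.ndarray:
        """Fraction of missing calls per individual."""
        return self.missing_mask.mean(axis=1)

    def locus_missing_fraction(self) -> np.ndarray:
        """Fraction of missing calls per locus."""
        return self.missing_mask.mean(axis=0)

    # -- subsetting --------------------------------------------------

    def subset(self, individual_idx=None, locus_idx=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given positional indices."""
        ind_idx = (
            np.arange(self.n_individuals)
            if individual_idx is None
            else np.asarray(individual_idx)
        )
        loc_idx = (
            np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        )
        return GenotypeMatrix(
            calls=self.calls[np.ix_(ind_idx, loc_idx)].copy(),
            individuals=self.individuals.iloc[ind_idx].reset_index(drop=True),
            loci=self.loci.iloc[loc_idx].reset_index(drop=True),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.copy(), self.individuals.copy(), self.loci.copy()
        )

    # -- frequencies -------------------------------------------------

    def allele_frequencies(self, individual_idx=None) -> np.ndarray:
        """Alt-allele frequency per locus over the given individuals.

        Loci with no non-missing call in the subset yield NaN.
        """
        calls = self.calls if individual_idx is None else self.calls[individual_idx]
        valid = calls != MISSING
        n_genes = 2 * valid.sum(axis=0)
        alt = np.where(valid, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_genes > 0, alt / np.maximum(n_genes, 1), np.nan)

    def groups(self) -> pd.Series:
        if "group" not in self.individuals.columns:
            raise ValueError("individuals frame has no 'group' column")
        return self.individuals["group"]
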