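"""Post-calling quality filters producing the analysis-ready dataset.

The standard RAD-seq workflow for highly selfing species applies three
filters after genotype calling: drop individuals with more than 25%
missing calls, then drop loci with more than 10% missing calls, then keep
only the first SNP within each RAD locus so retained SNPs are not trivially
linked.  Thresholds are strict inequalities: an individual at exactly the
threshold is retained.  The individual filter runs before the locus filter;
the two do not commute in general.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix


@dataclass
class QcReport:
    """Record of what a QC step removed."""

    step: str
    removed: list
    n_before: int
    n_after: int
    threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "removed": list(self.removed),
            "n_before": self.n_before,
            "n_after": self.n_after,
            "threshold": self.threshold,
        }


def filter_individuals(
    matrix: GenotypeMatrix, max_missing: float = 0.25
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop individuals whose missing-call fraction exceeds ``max_missing``.

    The comparison is strict: an individual with missing fraction exactly
    equal to ``max_missing`` is retained.  Order of retained individuals is
    preserved.
    """
    if matrix.n_individuals == 0:
        raise ValueError("empty matrix")
    frac = matrix.individual_missing_fraction()
    keep = frac <= max_missing
    removed = matrix.individuals.loc[~keep, "id"].tolist()
    report = QcReport(
        step="filter_individuals",
        removed=removed,
        n_before=matrix.n_individuals,
        n_after=int(keep.sum()),
        threshold=max_missing,
    )
    if not keep.any():
        import warnings

        warnings.warn("all individuals removed by missing-data filter")
    return matrix.subset(individual_idx=np.flatnonzero(keep)), report


def filter_loci(
    matrix: GenotypeMatrix, max_missing: float = 0.10
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop loci whose missing-call fraction exceeds ``max_missing`` (strict)."""
    if matrix.n_loci == 0:
        raise ValueError("empty matrix")
    frac = matrix.locus_missing_fraction()
    keep = frac <= max_missing
    removed = [
        (r, int(o))
        for r, o in zip(
            matrix.loci.loc[~keep, "rad_locus_id"], matrix.loci.loc[~keep, "snp_offset"]
        )
    ]
    report = QcReport(
        step="filter_loci",
        removed=removed,
        n_before=matrix.n_loci,
        n_after=int(keep.sum()),
        threshold=max_missing,
    )
    if not keep.any():
        import warnings

        warnings.warn("all loci removed by missing-data filter")
    return matrix.subset(locus_idx=np.flatnonzero(keep)), report


def select_first_snp_per_radlocus(
    matrix: GenotypeMatrix,
) -> tuple[GenotypeMatrix, QcReport]:
    """Keep, within each RAD locus, only the SNP with the smallest offset.

    Offsets must be unique within a RAD locus; a tie is an error because the
    "first SNP" would be ambiguous.
    """
    loci = matrix.loci
    dup = loci.duplicated(subset=["rad_locus_id", "snp_offset"])
    if dup.any():
        raise ValueError("duplicate snp_offset within a RAD locus")
    first_idx = (
        loci.assign(_pos=np.arange(len(loci)))
        .sort_values(["rad_locus_id", "snp_offset"], kind="mergesort")
        .drop_duplicates(subset="rad_locus_id", keep="first")["_pos"]
        .to_numpy()
    )
    first_idx = np.sort(first_idx)  # preserve original locus order
    removed_mask = np.ones(matrix.n_loci, dtype=bool)
    removed_mask[first_idx] = False
    removed = [
        (r, int(o))
        for r, o in zip(
            loci.loc[removed_mask, "rad_locus_id"], loci.loc[removed_mask, "snp_offset"]
        )
    ]
    report = QcReport(
        step="select_first_snp_per_radlocus",
        removed=removed,
        n_before=matrix.n_loci,
        n_after=len(first_idx),
    )
    return matrix.subset(locus_idx=first_idx), report


def standard_qc(
    matrix: GenotypeMatrix,
    max_missing_individual: float = 0.25,
    max_missing_locus: float = 0.10,
    one_snp_per_locus: bool = True,
) -> tuple[GenotypeMatrix, list[QcReport]]:
    """Run the full filter chain in its fixed order.

    Individuals are filtered before loci (the order the filters are applied
    in the upstream workflow); the first-SNP selection runs last.
    """
    reports: list[QcReport] = []
    matrix, rep = filter_individuals(matrix, max_missing_individual)
    reports.append(rep)
    matrix, rep = filter_loci(matrix, max_missing_locus)
    reports.append(rep)
    if one_snp_per_locus:
        matrix, rep = select_first_snp_per_radlocus(matrix)
        reports.append(rep)
    return matrix, reports
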