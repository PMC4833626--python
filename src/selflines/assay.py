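"""Diagnostic-locus panels and lineage assignment from partial genotypes.

A locus is diagnostic for a bipartition of lineage groups when it is
monomorphic within every group (ignoring missing calls) and the two sides
of the partition carry different alleles.  A small panel of such loci,
restricted to RAD loci suitable for a melt-curve assay (a single variable
site with invariant flanks long enough to prime on), suffices to assign
new samples to lineages.  Samples carrying alleles specific to
incompatible sides (e.g. evidence for two groups that no single lineage
explains) are flagged as conflicts and should be discarded or examined as
putative hybrids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, RAD_LOCUS_LENGTH, GenotypeMatrix

__all__ = [
    "DiagnosticPanel",
    "AssignmentResult",
    "find_diagnostic_loci",
    "filter_assay_suitable",
    "build_panel",
    "assign_samples",
]


@dataclass
class DiagnosticLocus:
    locus_index: int  # column in the source matrix
    rad_locus_id: str
    snp_offset: int
    side_of_allele: dict  # dosage allele (0=ref, 1=alt) -> side index (0 or 1)
    support: int  # smallest per-group non-missing call count


@dataclass
class DiagnosticPanel:
    """Loci diagnostic for one bipartition of the lineage groups."""

    partition: tuple  # (frozenset side0, frozenset side1)
    loci: list  # of DiagnosticLocus

    def side_groups(self, side: int):
        return self.partition[side]


@dataclass
class AssignmentResult:
    sample_id: object
    label: object  # group label | "conflict" | "insufficient"
    per_locus_calls: dict  # (panel partition, rad_locus_id) -> sides observed
    evidence: dict  # partition -> set of sides observed


def _validate_partition(groups, partition) -> tuple:
    sideA = frozenset(partition[0])
    sideB = frozenset(partition[1])
    all_groups = set(groups)
    if sideA | sideB != all_groups or sideA & sideB:
        raise ValueError("partition must be a bipartition of the groups")
    return (sideA, sideB)


def find_diagnostic_loci(
    matrix: GenotypeMatrix, grouping, partition
) -> list[DiagnosticLocus]:
    """Loci monomorphic within every group and fixed differently across sides.

    ``partition`` is a pair of iterables of group labels.  Missing calls
    are ignored; a group with no data at a locus disqualifies that locus
    (its allele cannot be certified).
    """
    grouping = np.asarray(grouping)
    groups = pd.unique(grouping)
    sideA, sideB = _validate_partition(groups, partition)

    group_allele = {}  # group -> per-locus fixed allele (0/1) or -9 if polymorphic/empty
    group_support = {}
    for g in groups:
        calls = matrix.calls[grouping == g]
        valid = calls != MISSING
        n = valid.sum(axis=0)
        alt = np.where(valid, calls, 0).sum(axis=0)
        fixed_ref = (alt == 0) & (n > 0)
        fixed_alt = (alt == 2 * n) & (n > 0)
        allele = np.full(matrix.n_loci, -9, dtype=int)
        allele[fixed_ref] = 0
        allele[fixed_alt] = 1
        group_allele[g] = allele
        group_support[g] = n

    out = []
    for j in range(matrix.n_loci):
        alleles = {g: group_allele[g][j] for g in groups}
        if any(a == -9 for a in alleles.values()):
            continue
        aA = {alleles[g] for g in sideA}
        aB = {alleles[g] for g in sideB}
        if len(aA) == 1 and len(aB) == 1 and aA != aB:
            side_of_allele = {aA.pop(): 0, aB.pop(): 1}
            out.append(
                DiagnosticLocus(
                    locus_index=j,
                    rad_locus_id=str(matrix.loci.loc[j, "rad_locus_id"]),
                    snp_offset=int(matrix.loci.loc[j, "snp_offset"]),
                    side_of_allele=side_of_allele,
                    support=int(min(group_support[g][j] for g in groups)),
                )
            )
    return out


def filter_assay_suitable(
    candidates: list[DiagnosticLocus],
    rad_sequences: dict,
    min_flank: int = 18,
) -> list[DiagnosticLocus]:
    """Restrict candidates to melt-assay-suitable RAD loci.

    A locus qualifies when its allele sequences differ at exactly one
    position and that position leaves at least ``min_flank`` invariant
    bases on each side (a documented proxy for "suitable priming sites",
    parameterizable).  Sequences must be the standard RAD locus length.
    """
    out = []
    for cand in candidates:
        seqs = rad_sequences.get(cand.rad_locus_id)
        if seqs is None:
            continue
        s0, s1 = seqs
        if len(s0) != RAD_LOCUS_LENGTH or len(s1) != RAD_LOCUS_LENGTH:
            raise ValueError(
                f"sequence length != {RAD_LOCUS_LENGTH} for {cand.rad_locus_id}"
            )
        diffs = [i for i, (a, b) in enumerate(zip(s0, s1)) if a != b]
        if len(diffs) != 1:
            continue
        pos = diffs[0]  # 0-based
        if pos < min_flank or (len(s0) - 1 - pos) < min_flank:
            continue
        out.append(cand)
    return out


def build_panel(
    partition,
    panel_loci: list[DiagnosticLocus],
    k_per_partition: int = 4,
) -> DiagnosticPanel:
    """Deterministically select k loci: highest support first, ties by id."""
    ordered = sorted(panel_loci, key=lambda c: (-c.support, c.rad_locus_id))
    if len(ordered) < k_per_partition:
        import warnings

        warnings.warn(
            f"only {len(ordered)} suitable loci available "
            f"(requested {k_per_partition}); returning all"
        )
    chosen = ordered[:k_per_partition]
    return DiagnosticPanel(partition=tuple(frozenset(s) for s in partition), loci=chosen)


def _sides_observed(call: int, locus: DiagnosticLocus) -> set:
    """Partition sides evidenced by one dosage call at a panel locus."""
    if call == MISSING:
        return set()
    alleles = {0, 1} if call == 1 else {0 if call == 0 else 1}
    return {locus.side_of_allele[a] for a in alleles if a in locus.side_of_allele}


def assign_samples(
    sample_calls: np.ndarray,
    sample_ids,
    panels: list[DiagnosticPanel],
    panel_locus_columns: dict,
) -> list[AssignmentResult]:
    """Assign samples to lineage groups from panel-locus genotypes.

    ``sample_calls`` is an ``(n_samples, n_loci)`` dosage matrix in the
    coordinate system described by ``panel_locus_columns``, a mapping from
    ``(panel index, rad_locus_id)`` to column index.  Each observed allele
    narrows the compatible groups to its side of that panel's partition; a
    sample is labelled with the single group compatible with every
    observed allele, "conflict" when no group is (including heterozygous
    panel calls, whose two-side evidence is reported, not collapsed), and
    "insufficient" when some panel has no informative call.
    """
    sample_calls = np.atleast_2d(np.asarray(sample_calls))
    results = []
    all_groups = set()
    for p in panels:
        all_groups |= set(p.partition[0]) | set(p.partition[1])

    for i, sid in enumerate(sample_ids):
        compatible = set(all_groups)
        evidence = {}
        per_locus = {}
        insufficient = False
        for pi, panel in enumerate(panels):
            sides_seen: set = set()
            for locus in panel.loci:
                col = panel_locus_columns.get((pi, locus.rad_locus_id))
                if col is None:
                    continue
                sides = _sides_observed(int(sample_calls[i, col]), locus)
                if sides:
                    per_locus[(pi, locus.rad_locus_id)] = sorted(sides)
                sides_seen |= sides
            evidence[pi] = sides_seen
            if not sides_seen:
                insufficient = True
                continue
            # each observed allele restricts to its side; intersect over alleles
            for s in sides_seen:
                compatible &= set(panel.partition[s])
        if not compatible:
            label = "conflict"
        elif len(compatible) == 1 and not insufficient:
            label = next(iter(compatible))
        else:
            label = "insufficient"
        results.append(
            AssignmentResult(
                sample_id=sid,
                label=label,
                per_locus_calls=per_locus,
                evidence=evidence,
            )
        )
    return results
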