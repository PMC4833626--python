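"""Readers and writers for the project's file formats.

Conventions:

* VCF: VCFv4.2, GT-only, biallelic SNP records; CHROM = RAD locus id,
  POS = 1-based SNP offset within the 93-bp locus; missing calls ./. .
  Reading goes through cyvcf2; multiallelic records are rejected with the
  offending locus named.
* Genotype TSV: one row per individual (columns id, site, group, then one
  column per locus named "radid:offset" holding dosages 0/1/2 or "." ).
* Grouping TSV: individual, site, group.  Truth labels, traits, panels and
  per-locus F_ST tables are plain TSVs.  Outlines: one CSV per leaflet
  with x,y per row, tied together by a manifest TSV.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "read_genotypes",
    "write_grouping",
    "read_grouping",
    "write_outlines",
    "read_outlines",
    "write_qc_report",
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path, seed=None) -> None:
    """Write the matrix as an uncompressed GT-only VCFv4.2 file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=selflines\n")
        if seed is not None:
            fh.write(f"##selflines_seed={seed}\n")
        for rad in pd.unique(matrix.loci["rad_locus_id"]):
            fh.write(f"##contig=<ID={rad},length=93>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        ids = "\t".join(str(i) for i in matrix.individuals["id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{ids}\n")
        for j, locus in enumerate(matrix.loci.itertuples()):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in matrix.calls[:, j])
            ref = getattr(locus, "ref", "A") or "A"
            alt = getattr(locus, "alt", "T") or "T"
            fh.write(
                f"{locus.rad_locus_id}\t{locus.snp_offset}\t"
                f"{locus.rad_locus_id}:{locus.snp_offset}\t{ref}\t{alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path, individuals_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a GenotypeMatrix.

    ``individuals_meta`` (id, site, group) is merged on sample id when
    given; otherwise site/group are left empty.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty file")
    vcf = VCF(path)
    samples = list(vcf.samples)
    calls_cols = []
    loci_rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS}; only biallelic "
                "SNPs are supported"
            )
        gts = var.genotype.array()
        a0 = gts[:, 0]
        a1 = gts[:, 1]
        dosage = np.where((a0 < 0) | (a1 < 0), MISSING, a0 + a1).astype(np.int8)
        calls_cols.append(dosage)
        loci_rows.append(
            {
                "rad_locus_id": var.CHROM,
                "snp_offset": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    if not loci_rows:
        raise ValueError(f"{path}: no variant records")
    calls = np.column_stack(calls_cols)
    ind = pd.DataFrame({"id": samples})
    if individuals_meta is not None:
        ind = ind.merge(individuals_meta, on="id", how="left")
    else:
        ind["site"] = pd.NA
        ind["group"] = pd.NA
    return GenotypeMatrix(calls=calls, individuals=ind, loci=pd.DataFrame(loci_rows))


def write_genotypes_tsv(matrix: GenotypeMatrix, path, seed=None) -> None:
    """Write the TSV genotype-matrix dialect (individuals as rows)."""
    cols = [
        f"{r}:{o}" for r, o in zip(matrix.loci["rad_locus_id"], matrix.loci["snp_offset"])
    ]
    df = pd.DataFrame(
        np.where(matrix.calls == MISSING, ".", matrix.calls.astype(str)),
        columns=cols,
    )
    meta = matrix.individuals.copy()
    if "group" not in meta.columns:
        meta["group"] = ""
    if "site" not in meta.columns:
        meta["site"] = ""
    out = pd.concat([meta[["id", "site", "group"]], df], axis=1)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Read the TSV genotype-matrix dialect written by write_genotypes_tsv."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty or "id" not in df.columns:
        raise ValueError(f"{path}: not a genotype TSV")
    meta_cols = [c for c in ("id", "site", "group") if c in df.columns]
    locus_cols = [c for c in df.columns if c not in meta_cols]
    loci_rows = []
    for c in locus_cols:
        try:
            rad, off = c.rsplit(":", 1)
            loci_rows.append({"rad_locus_id": rad, "snp_offset": int(off)})
        except ValueError as err:
            raise ValueError(f"{path}: malformed locus column {c!r}") from err
    vals = df[locus_cols].to_numpy()
    calls = np.where(vals == ".", MISSING, vals).astype(np.int8)
    meta = df[meta_cols].copy()
    meta["site"] = meta.get("site", pd.Series(dtype=str))
    return GenotypeMatrix(calls=calls, individuals=meta, loci=pd.DataFrame(loci_rows))


def read_genotypes(path, fmt: str | None = None, **kw) -> GenotypeMatrix:
    """Dispatch on format: 'vcf' or 'tsv' (inferred from the suffix)."""
    if fmt is None:
        fmt = "vcf" if str(path).endswith(".vcf") else "tsv"
    if fmt == "vcf":
        return read_vcf(path, **kw)
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_grouping(individuals: pd.DataFrame, path) -> None:
    individuals[["id", "site", "group"]].to_csv(path, sep="\t", index=False)


def read_grouping(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "site", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: grouping TSV needs columns {sorted(required)}")
    return df


def write_outlines(outlines, directory, manifest_path) -> None:
    """One x,y CSV per outline plus a manifest TSV (file, label)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (label, pts) in enumerate(outlines):
        fname = f"outline_{i:04d}.csv"
        np.savetxt(directory / fname, pts, delimiter=",", fmt="%.6f")
        rows.append({"file": fname, "label": label})
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)


def read_outlines(directory, manifest_path):
    directory = Path(directory)
    manifest = pd.read_csv(manifest_path, sep="\t")
    out = []
    for r in manifest.itertuples():
        pts = np.loadtxt(directory / r.file, delimiter=",")
        out.append((r.label, pts))
    return out


def write_qc_report(reports, path, seed=None) -> None:
    payload = {"seed": seed, "steps": [r.to_dict() for r in reports]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
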