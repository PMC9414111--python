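"""File formats: VCF (dosage) genotypes, trio map, phenotype and weights TSVs.

The VCF carries one sample column per individual (``<trio>_M/_F/_C``),
hard genotypes in GT and effect-allele dosage in a DS FORMAT field, with
REF = other allele and ALT = effect allele by default.  All tabular
files are plain tab-separated text with headers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .simulate import TrioCohort, TrioGenotypes

__all__ = [
    "VcfData",
    "write_vcf",
    "read_vcf",
    "write_dataset",
    "read_trios",
    "read_phenotypes",
    "write_weights",
]

ROLES = ("mother", "father", "child")
_ROLE_SUFFIX = {"mother": "M", "father": "F", "child": "C"}


@dataclass
class VcfData:
    """Genotype data as read back from a VCF: ALT-allele dosages."""

    sample_ids: list[str]
    snp_ids: list[str]
    ref: list[str]
    alt: list[str]
    dosages: np.ndarray  # (n_samples, n_snps), counting ALT

    def by_role(self, trios: pd.DataFrame) -> dict[str, np.ndarray]:
        """Split sample rows into per-role matrices ordered by family."""
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        out = {}
        for role in ROLES:
            ids = trios.loc[trios["role"] == role, "individual_id"]
            out[role] = self.dosages[[index[i] for i in ids], :]
        return out


def _sample_ids(n_trios: int) -> tuple[list[str], list[str]]:
    trio_ids = [f"F{i + 1:04d}" for i in range(n_trios)]
    samples = []
    for tid in trio_ids:
        samples.extend(f"{tid}_{_ROLE_SUFFIX[r]}" for r in ROLES)
    return trio_ids, samples


def write_vcf(genotypes: TrioGenotypes, weights: pd.DataFrame, path,
              flip_snps: set[str] | frozenset[str] = frozenset()) -> None:
    """Write trio genotypes as an uncompressed VCF v4.2 with GT and DS.

    ``flip_snps`` writes those records in the opposite orientation
    (REF = effect allele, ALT = other allele, dosages complemented),
    which downstream alignment must undo — useful for orientation tests.
    """
    if genotypes.n_trios == 0:
        raise ValueError("refusing to write a VCF for an empty cohort")
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(weights["chrom"].astype(str)):
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DS", 1, "Float", "Effect-allele dosage")
    _, samples = _sample_ids(genotypes.n_trios)
    for s in samples:
        header.add_sample(s)
    role_mats = (genotypes.mother, genotypes.father, genotypes.child)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vf:
        for k, row in enumerate(weights.itertuples(index=False)):
            flip = row.snp_id in flip_snps
            ref, alt = ((row.effect_allele, row.other_allele) if flip
                        else (row.other_allele, row.effect_allele))
            rec = vf.new_record(contig=str(row.chrom), start=int(row.pos) - 1,
                                alleles=(ref, alt), id=row.snp_id)
            for t in range(genotypes.n_trios):
                for r, mat in enumerate(role_mats):
                    d = int(mat[t, k])
                    if flip:
                        d = 2 - d
                    sample = rec.samples[samples[3 * t + r]]
                    sample["GT"] = ((0, 0), (0, 1), (1, 1))[d]
                    sample["DS"] = float(d)
            vf.write(rec)


def read_vcf(path) -> VcfData:
    """Read a VCF into ALT-allele dosage form (DS preferred, GT fallback)."""
    snp_ids, refs, alts, rows = [], [], [], []
    with pysam.VariantFile(os.fspath(path)) as vf:
        sample_ids = list(vf.header.samples)
        for rec in vf:
            snp_ids.append(rec.id)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            col = np.empty(len(sample_ids))
            for i, s in enumerate(sample_ids):
                fmt = rec.samples[s]
                if "DS" in fmt and fmt["DS"] is not None:
                    col[i] = float(fmt["DS"])
                else:
                    gt = fmt["GT"]
                    col[i] = np.nan if gt is None or None in gt else float(sum(gt))
            rows.append(col)
    dosages = (np.stack(rows, axis=1) if rows
               else np.empty((len(sample_ids), 0)))
    return VcfData(sample_ids=sample_ids, snp_ids=snp_ids,
                   ref=refs, alt=alts, dosages=dosages)


def write_weights(weights: pd.DataFrame, path) -> None:
    weights.to_csv(path, sep="\t", index=False)


def read_trios(path) -> pd.DataFrame:
    trios = pd.read_csv(path, sep="\t")
    required = {"family_id", "individual_id", "role"}
    missing = required - set(trios.columns)
    if missing:
        raise ValueError(f"trio map missing column(s): {', '.join(sorted(missing))}")
    bad = set(trios["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"trio map contains unknown role(s): {sorted(bad)}")
    return trios


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dataset(cohort: TrioCohort, outdir) -> dict[str, Path]:
    """Write a simulated cohort: phenotype + trio-map TSVs, plus VCF and
    weights TSV when genotypes were simulated.  Round-trips losslessly
    through :func:`read_vcf` / :func:`read_phenotypes` / :func:`read_trios`.
    """
    if cohort.n_trios == 0:
        raise ValueError("refusing to write an empty cohort")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    trio_ids, samples = _sample_ids(cohort.n_trios)
    trios = pd.DataFrame({
        "family_id": np.repeat(trio_ids, 3),
        "individual_id": samples,
        "role": ROLES * cohort.n_trios,
    })
    paths["trios"] = outdir / "trios.tsv"
    trios.to_csv(paths["trios"], sep="\t", index=False)

    paths["phenotypes"] = outdir / "phenotypes.tsv"
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)

    if cohort.genotypes is not None and cohort.weights is not None:
        paths["vcf"] = outdir / "genotypes.vcf"
        write_vcf(cohort.genotypes, cohort.weights, paths["vcf"])
        paths["weights"] = outdir / "weights.tsv"
        write_weights(cohort.weights, paths["weights"])
    return paths
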