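"""File formats: PED/FAM pedigrees, VCF genotypes, TSV phenotypes/results, BED regions.

Coordinates are half-open zero-based internally; VCF and region strings
(1-based) are converted on read.  All writers emit plain text that the
corresponding reader round-trips.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, LongitudinalPhenotypes, RegionSpec
from .pedigree import (FEMALE, MALE, UNKNOWN, Individual, KinshipMatrix,
                       Pedigree, PedigreeError, validate_pedigree)

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_results",
    "read_results",
    "write_kinship",
]

_SEX_FROM_CODE = {"1": MALE, "2": FEMALE, "0": UNKNOWN}
_CODE_FROM_SEX = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}

RESULT_COLUMNS = ["variant", "test", "stat", "df", "p", "beta",
                  "loglik_null", "loglik_alt", "n", "converged", "note"]


def read_pedigree(path) -> Pedigree:
    """Load a PLINK-style FAM/PED file and validate it.

    Columns: family_id, individual_id, father_id, mother_id, sex
    (1 = male, 2 = female, 0 = unknown), optional trailing columns
    (phenotype etc.) ignored.  "0" marks a missing parent.  A
    half-specified parent pair is completed by synthesizing an anonymous
    founder (with a warning) so real-world files remain loadable.
    """
    members: list[Individual] = []
    seen: set[str] = set()
    extra: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise PedigreeError(
                    f"{path}:{lineno}: expected at least 5 columns "
                    f"(family, id, father, mother, sex), got {len(fields)}"
                )
            fam, ind_id, father, mother, sex_code = fields[:5]
            if sex_code not in _SEX_FROM_CODE:
                raise PedigreeError(
                    f"{path}:{lineno}: sex must be coded 1/2/0, "
                    f"got {sex_code!r}"
                )
            father = None if father == "0" else father
            mother = None if mother == "0" else mother
            if (father is None) != (mother is None):
                if father is None:
                    father = f"{ind_id}.anon_father"
                    extra.append(Individual(father, sex=MALE, family_id=fam))
                else:
                    mother = f"{ind_id}.anon_mother"
                    extra.append(Individual(mother, sex=FEMALE, family_id=fam))
                warnings.warn(
                    f"{path}:{lineno}: individual {ind_id!r} has only one "
                    "parent named; synthesized an anonymous founder"
                )
            members.append(Individual(ind_id, father, mother,
                                      _SEX_FROM_CODE[sex_code], family_id=fam))
            seen.add(ind_id)
    if not members:
        raise PedigreeError(f"{path}: no individuals")
    extra = [e for e in extra if e.id not in seen]
    return validate_pedigree(Pedigree(members + extra))


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for m in ped.members:
            fh.write("\t".join([
                m.family_id, m.id, m.father_id or "0", m.mother_id or "0",
                _CODE_FROM_SEX[m.sex],
            ]) + "\n")


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path, trait: str, time_points: int | None = None,
                    pedigree: Pedigree | None = None,
                    ) -> LongitudinalPhenotypes:
    """Read a longitudinal phenotype table (wide or long layout).

    Wide: one row per individual, visit columns ``{trait}_1 ..
    {trait}_k`` plus covariate columns.  Long: columns ``id``, ``visit``
    (1-based), ``value``, with covariates constant within individual.
    Per-visit missingness (empty cells, absent visits) is preserved as
    NaN.  If ``pedigree`` is given, every id must belong to it.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c) for c in df.columns]
    if "id" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs an 'id' column")
    df["id"] = df["id"].astype(str)

    if {"visit", "value"} <= set(df.columns):
        phen = _phen_from_long(df, trait, time_points, path)
    else:
        phen = _phen_from_wide(df, trait, time_points, path)
    if pedigree is not None:
        missing = [i for i in phen.ids if i not in pedigree]
        if missing:
            raise ValueError(
                f"{path}: {len(missing)} phenotyped individuals not in the "
                f"pedigree (first: {missing[0]!r})"
            )
    return phen


def _phen_from_wide(df, trait, time_points, path):
    visit_cols = []
    t = 1
    while f"{trait}_{t}" in df.columns:
        visit_cols.append(f"{trait}_{t}")
        t += 1
    if not visit_cols:
        raise ValueError(f"{path}: no '{trait}_1'-style visit columns found")
    if time_points is not None and time_points != len(visit_cols):
        raise ValueError(
            f"{path}: expected {time_points} visit columns for {trait!r}, "
            f"found {len(visit_cols)}"
        )
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate id {dup!r}")
    values = df[visit_cols].to_numpy(dtype=float)
    cov = df.drop(columns=visit_cols).set_index("id")
    return LongitudinalPhenotypes(list(df["id"]), trait, values, cov)


def _phen_from_long(df, trait, time_points, path):
    if df.duplicated(subset=["id", "visit"]).any():
        pair = df[df.duplicated(subset=["id", "visit"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate (id, visit) = ({pair['id']!r}, {pair['visit']})"
        )
    k = int(time_points if time_points is not None else df["visit"].max())
    if df["visit"].max() > k or df["visit"].min() < 1:
        raise ValueError(f"{path}: visit numbers outside 1..{k}")
    ids = list(dict.fromkeys(df["id"]))
    pos = {i: j for j, i in enumerate(ids)}
    values = np.full((len(ids), k), np.nan)
    for _, row in df.iterrows():
        values[pos[row["id"]], int(row["visit"]) - 1] = row["value"]
    cov_cols = [c for c in df.columns if c not in ("id", "visit", "value")]
    cov = df.groupby("id", sort=False)[cov_cols].first() if cov_cols else \
        pd.DataFrame(index=pd.Index(ids, name="id"))
    return LongitudinalPhenotypes(ids, trait, values, cov)


def write_phenotypes(phen: LongitudinalPhenotypes, path) -> None:
    phen.to_frame().to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# genotypes


def read_vcf(path, region: RegionSpec | None = None,
             pedigree: Pedigree | None = None) -> GenotypeMatrix:
    """Load biallelic SNV dosages from a VCF.

    Multi-allelic records are skipped with a warning; ``./.`` becomes a
    missing dosage; the ALT-allele frequency is computed from
    non-missing calls.  With a region only contained records load.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if pedigree is not None:
        overlap = [s for s in samples if s in pedigree]
        if not overlap:
            raise ValueError(f"{path}: no VCF samples overlap the pedigree")
        unknown = [s for s in samples if s not in pedigree]
        if unknown:
            # silent founders would corrupt the kinship matrix downstream
            raise ValueError(
                f"{path}: {len(unknown)} VCF samples are not in the "
                f"pedigree (first: {unknown[0]!r})"
            )
    rows, dosage_cols = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record {v.CHROM}:{v.POS}")
            continue
        if region is not None:
            if (str(v.CHROM) != str(region.chrom)
                    or not (region.start <= v.POS - 1 < region.end)):
                continue
        gt = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        rows.append({"chrom": str(v.CHROM), "pos": int(v.POS), "id": vid,
                     "ref": v.REF, "alt": v.ALT[0]})
        dosage_cols.append(dos)
    vcf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    dosages = (np.column_stack(dosage_cols) if dosage_cols
               else np.empty((len(samples), 0)))
    return GenotypeMatrix(samples, variants, dosages)


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genos: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(genos.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genos.ids) + "\n")
        for j, row in genos.variants.iterrows():
            gts = [_GT.get(d, "./.") for d in genos.dosages[:, j]]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# regions, results, kinship


def read_bed(path) -> list[RegionSpec]:
    """BED3/BED4: chrom, start, end, optional name (0-based half-open)."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            label = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
            regions.append(RegionSpec(parts[0], int(parts[1]), int(parts[2]),
                                      label))
    return regions


def write_results(results, path) -> None:
    """Association (or gene-centric / tally) results to TSV.

    Accepts a DataFrame or a list of objects with ``to_dict``; column
    order is fixed for association results so files are stable across
    runs.
    """
    if isinstance(results, pd.DataFrame):
        frame = results.copy()
    else:
        frame = pd.DataFrame([r.to_dict() for r in results])
    if frame.empty:
        frame = pd.DataFrame(columns=RESULT_COLUMNS)
    if set(RESULT_COLUMNS) <= set(frame.columns):
        lead = RESULT_COLUMNS + [c for c in frame.columns
                                 if c not in RESULT_COLUMNS]
        frame = frame[lead]
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_kinship(kin: KinshipMatrix, path, fmt: str = "matrix") -> None:
    """Kinship as a square TSV with id header row/column, or long format."""
    if fmt == "matrix":
        kin.to_frame().to_csv(path, sep="\t", index_label="id")
    elif fmt == "long":
        kin.to_long().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError("fmt must be 'matrix' or 'long'")
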