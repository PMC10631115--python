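"""Readers and writers for the package's tabular formats and PLINK ``.raw``.

Genotypes travel as tab-delimited text: a ``subject_id`` column followed by
one 0/1 column per rsID, with per-SNP metadata (rsid, chrom, pos, maf) in a
sibling ``<stem>.snps.tsv`` file when available.  Phenotypes are CSV with a
``subject_id`` column plus either ``HTN`` directly or ``SBP``/``DBP``/``MEDS``
from which hypertension status is derived.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ibi.preprocess import derive_htn, dominant_code
from ibi.types import MISSING, GenotypeMatrix, TraitVector

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "read_plink_raw",
    "write_phenotypes",
    "read_phenotypes",
    "write_scores",
    "read_scores",
]

#: PLINK .raw bookkeeping columns preceding the genotype columns
_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".snps.tsv")


def write_genotypes(path: str | Path, genotypes: GenotypeMatrix) -> None:
    path = Path(path)
    df = pd.DataFrame(
        genotypes.values, columns=genotypes.snps["rsid"].to_numpy()
    )
    df.insert(0, "subject_id", genotypes.subjects)
    df.to_csv(path, sep="\t", index=False)
    genotypes.snps.to_csv(_meta_path(path), sep="\t", index=False)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read the package's 0/1 tab-delimited genotype format.

    Empty cells and ``NA`` become missing (-1).  SNP metadata is loaded from
    the sibling ``.snps.tsv`` when present, otherwise synthesized with
    unknown chromosome/position and MAF re-estimated from the data.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    subjects = df["subject_id"].to_numpy()
    rsids = [c for c in df.columns if c != "subject_id"]
    values = df[rsids].to_numpy(dtype=np.float64)
    values = np.where(np.isnan(values), MISSING, values).astype(np.int8)
    meta_file = _meta_path(path)
    if meta_file.exists():
        snps = pd.read_csv(meta_file, sep="\t", dtype={"rsid": str, "chrom": str})
        snps = snps.set_index("rsid").loc[rsids].reset_index()
    else:
        snps = pd.DataFrame(
            {"rsid": rsids, "chrom": "0", "pos": 0, "maf": np.nan}
        )
    geno = GenotypeMatrix(values=values, snps=snps, subjects=subjects)
    if geno.snps["maf"].isna().any():
        geno.snps["maf"] = geno.estimated_maf()
    return geno


def read_plink_raw(path: str | Path) -> GenotypeMatrix:
    """Read a PLINK ``.raw`` additive-count export and dominant-code it.

    Genotype headers of the form ``rs123_A`` are stripped to the rsID.
    Chromosome/position are not present in ``.raw`` and default to unknown;
    MAF is re-estimated from the dominant-coded carriers.
    """
    df = pd.read_csv(path, sep=r"\s+")
    geno_cols = [c for c in df.columns if c not in _PLINK_META]
    subjects = df["IID"].astype(str).to_numpy() if "IID" in df else np.arange(len(df))
    counts = df[geno_cols].to_numpy(dtype=np.float64)
    counts = np.where(np.isnan(counts), MISSING, counts).astype(np.int64)
    values = dominant_code(counts)
    rsids = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno_cols]
    snps = pd.DataFrame({"rsid": rsids, "chrom": "0", "pos": 0, "maf": np.nan})
    geno = GenotypeMatrix(values=values, snps=snps, subjects=subjects)
    geno.snps["maf"] = geno.estimated_maf()
    return geno


def write_phenotypes(path: str | Path, trait: TraitVector) -> None:
    df = pd.DataFrame({"subject_id": trait.subjects, "HTN": trait.htn})
    if trait.sbp is not None:
        df["SBP"] = trait.sbp
        df["DBP"] = trait.dbp
        df["MEDS"] = trait.meds
    df.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> TraitVector:
    """Read the phenotype CSV; derive HTN from SBP/DBP/MEDS when absent."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    cols = {c.upper(): c for c in df.columns}
    subjects = df[cols.get("SUBJECT_ID", "subject_id")].to_numpy()
    if "HTN" in cols:
        htn = df[cols["HTN"]].to_numpy()
        sbp = df[cols["SBP"]].to_numpy() if "SBP" in cols else None
        dbp = df[cols["DBP"]].to_numpy() if "DBP" in cols else None
        meds = df[cols["MEDS"]].to_numpy() if "MEDS" in cols else None
        return TraitVector(htn=htn, subjects=subjects, sbp=sbp, dbp=dbp, meds=meds)
    for needed in ("SBP", "DBP", "MEDS"):
        if needed not in cols:
            raise ValueError(f"phenotype file lacks HTN and the {needed} column")
    sbp = df[cols["SBP"]].to_numpy(dtype=np.float64)
    dbp = df[cols["DBP"]].to_numpy(dtype=np.float64)
    meds = df[cols["MEDS"]].to_numpy()
    adj_sbp, adj_dbp, htn = derive_htn(sbp, dbp, meds)
    return TraitVector(htn=htn, subjects=subjects, sbp=adj_sbp, dbp=adj_dbp, meds=meds)


def align(genotypes: GenotypeMatrix, trait: TraitVector) -> tuple[GenotypeMatrix, TraitVector]:
    """Inner-join genotypes and phenotypes on subject id, preserving genotype order."""
    pheno_idx = {s: i for i, s in enumerate(trait.subjects)}
    keep_g, keep_t = [], []
    for i, s in enumerate(genotypes.subjects):
        j = pheno_idx.get(s)
        if j is not None:
            keep_g.append(i)
            keep_t.append(j)
    if not keep_g:
        raise ValueError("no subjects shared between genotypes and phenotypes")
    return genotypes.take_subjects(np.array(keep_g)), trait.take(np.array(keep_t))


def write_scores(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
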