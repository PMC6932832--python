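"""Reading and writing cohort files.

Formats:

* disomic genotypes: PLINK-style PED text (one row per genotyped individual,
  allele pairs in {A, B, 0}) or VCF (GT field, diploid records only; read via
  cyvcf2, written as plain text);
* trisomic chr21 calls: TSV with header
  ``family_id sample_id variant_id allele1 allele2 allele3``, alleles in
  {A, B, .} ('.' in any slot makes the call missing);
* pedigree: FAM-style 6-column text (family, individual, father, mother,
  sex, phenotype; 0 = unknown);
* variant panel / genetic map: TSV
  ``variant_id chromosome position_bp position_cM`` (cM blank off chr21),
  optionally followed by ``info_score source``; the centromere position is
  supplied in configuration, not in the file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    COMPLETE,
    FATHER_ONLY,
    MISSING,
    MOTHER_ONLY,
    Cohort,
    GeneticMap,
    TrioRecord,
    dosage_to_triple,
    triple_to_dosage,
)

log = logging.getLogger(__name__)

_DOSAGE_TO_PAIR = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), MISSING: ("0", "0")}


# ---------------------------------------------------------------- variant map

def write_map_tsv(variants: pd.DataFrame, path) -> None:
    out = variants[["id", "chrom", "pos_bp", "pos_cM", "info_score", "source"]].copy()
    out.columns = ["variant_id", "chromosome", "position_bp", "position_cM",
                   "info_score", "source"]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_map_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = ["variant_id", "chromosome", "position_bp", "position_cM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: map TSV missing columns {missing}")
    out = pd.DataFrame(
        {
            "id": df["variant_id"].astype(str),
            "chrom": df["chromosome"],
            "pos_bp": df["position_bp"].astype(np.int64),
            "pos_cM": pd.to_numeric(df["position_cM"], errors="coerce"),
            "allele_a": "A",
            "allele_b": "B",
            "info_score": pd.to_numeric(df.get("info_score", 1.0), errors="coerce"),
            "source": df.get("source", "genotyped"),
        }
    )
    if out["pos_bp"].min() < 1:
        raise ValueError("position_bp must be 1-based (>= 1)")
    if out["id"].duplicated().any():
        dup = out.loc[out["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicated variant id {dup!r}")
    return out


def genetic_map_from_variants(
    variants: pd.DataFrame, chromosome: str, centromere_bp: int
) -> GeneticMap:
    chr_rows = variants[variants["chrom"] == chromosome].sort_values("pos_bp")
    return GeneticMap(
        chromosome=chromosome,
        ids=tuple(chr_rows["id"]),
        position_bp=chr_rows["pos_bp"].to_numpy(),
        position_cM=chr_rows["pos_cM"].to_numpy(dtype=float),
        centromere_bp=centromere_bp,
    )


# ------------------------------------------------------------------- pedigree

def write_fam(cohort: Cohort, path) -> None:
    rows = []
    for t in cohort.trios:
        if t.has_mother:
            rows.append((t.family_id, t.mother_id, "0", "0", 2, 1))
        if t.has_father:
            rows.append((t.family_id, t.father_id, "0", "0", 1, 1))
        rows.append(
            (t.family_id, t.child_id, t.father_id or "0", t.mother_id or "0", 0, 2)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_fam(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
        dtype=str,
    )
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ValueError(f"duplicated sample id {dup!r} in pedigree")
    return df


# ------------------------------------------------------------------ genotypes

def _geno_rows(cohort: Cohort):
    for t in cohort.trios:
        if t.has_mother:
            yield t.family_id, t.mother_id, "0", "0", 2, 1, t.mother_geno
        if t.has_father:
            yield t.family_id, t.father_id, "0", "0", 1, 1, t.father_geno
        yield (t.family_id, t.child_id, t.father_id or "0", t.mother_id or "0",
               0, 2, t.child_geno)


def write_ped(cohort: Cohort, path) -> None:
    pair = np.array([_DOSAGE_TO_PAIR[d] for d in (0, 1, 2, MISSING)])
    with open(path, "w") as fh:
        for fam, iid, fid, mid, sex, phe, geno in _geno_rows(cohort):
            alleles = pair[np.where(geno == MISSING, 3, geno)]
            fh.write("\t".join([fam, iid, fid, mid, str(sex), str(phe)]))
            fh.write("\t" + "\t".join(a for p in alleles for a in p) + "\n")


def read_ped(path, variants: pd.DataFrame) -> dict:
    """Parse a PED file into {sample_id: dosage vector} following the variant
    panel's column order."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    n_var = len(variants)
    if df.shape[1] != 6 + 2 * n_var:
        raise ValueError(
            f"{path}: expected {6 + 2 * n_var} columns for {n_var} variants, "
            f"found {df.shape[1]}"
        )
    sample_ids = df[1].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        dup = pd.Series(sample_ids)
        raise ValueError(f"duplicated sample id {dup[dup.duplicated()].iloc[0]!r}")
    alle = df.iloc[:, 6:].to_numpy(dtype="U1")
    valid = np.isin(alle, ["A", "B", "0"])
    if not valid.all():
        r, c = np.argwhere(~valid)[0]
        raise ValueError(
            f"{path}: invalid allele {alle[r, c]!r} for sample {sample_ids[r]}"
        )
    a1 = alle[:, 0::2]
    a2 = alle[:, 1::2]
    dos = (a1 == "B").astype(np.int8) + (a2 == "B").astype(np.int8)
    dos[(a1 == "0") | (a2 == "0")] = MISSING
    return {sid: dos[i] for i, sid in enumerate(sample_ids)}


def write_vcf(cohort: Cohort, path) -> None:
    """Minimal diploid VCF (GT only); trisomic child chr21 slots are ./."""
    samples, genos = [], []
    for fam, iid, fid, mid, sex, phe, geno in _geno_rows(cohort):
        samples.append(iid)
        genos.append(geno)
    G = np.vstack(genos)  # (samples, variants)
    gt = np.array(["0/0", "0/1", "1/1", "./."])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(cohort.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        v = cohort.variants
        codes = np.where(G == MISSING, 3, G)
        for j in range(len(v)):
            row = v.iloc[j]
            fields = [str(row["chrom"]), str(row["pos_bp"]), row["id"],
                      row["allele_a"], row["allele_b"], ".", "PASS", ".", "GT"]
            fh.write("\t".join(fields) + "\t" + "\t".join(gt[codes[:, j]]) + "\n")


def read_vcf(path, variants: pd.DataFrame) -> dict:
    """Parse a VCF into {sample_id: dosage vector}; diploid GT records only."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    if len(set(samples)) != len(samples):
        raise ValueError("duplicated sample id in VCF header")
    index = pd.Index(variants["id"])
    G = np.full((len(samples), len(variants)), MISSING, dtype=np.int8)
    for rec in vcf:
        vid = rec.ID
        j = index.get_loc(vid) if vid in index else None
        if j is None:
            raise ValueError(f"VCF variant {vid!r} absent from the map TSV")
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = rec.gt_types
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        G[:, j] = dos.astype(np.int8)
    vcf.close()
    return {sid: G[i] for i, sid in enumerate(samples)}


# ------------------------------------------------------------- trisomic calls

def write_tris_tsv(cohort: Cohort, path) -> None:
    ids = [cohort.variants["id"].iloc[i] for i in cohort.chr21_index]
    with open(path, "w") as fh:
        fh.write("family_id\tsample_id\tvariant_id\tallele1\tallele2\tallele3\n")
        for t in cohort.trios:
            for vid, d in zip(ids, t.child_tris):
                a = dosage_to_triple(int(d))
                fh.write(f"{t.family_id}\t{t.child_id}\t{vid}\t{a[0]}\t{a[1]}\t{a[2]}\n")


def read_tris_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["family_id", "sample_id", "variant_id", "allele1", "allele2", "allele3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trisomic TSV missing columns {missing}")
    dosages = np.empty(len(df), dtype=np.int8)
    for i, (a1, a2, a3) in enumerate(zip(df["allele1"], df["allele2"], df["allele3"])):
        try:
            dosages[i] = triple_to_dosage(a1, a2, a3)
        except ValueError as e:
            raise ValueError(f"{path}: line {i + 2}: {e}") from None
    df["dosage"] = dosages
    return df


# ----------------------------------------------------------------- round trip

def write_cohort(cohort: Cohort, out_dir, prefix: str = "cohort", fmt: str = "ped") -> dict:
    """Write the cohort files; returns the paths keyed by role."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "map": out_dir / f"{prefix}.markers.tsv",
        "pedigree": out_dir / f"{prefix}.fam",
        "trisomic": out_dir / f"{prefix}.tris.tsv",
    }
    write_map_tsv(cohort.variants, paths["map"])
    write_fam(cohort, paths["pedigree"])
    write_tris_tsv(cohort, paths["trisomic"])
    if fmt == "ped":
        paths["genotype"] = out_dir / f"{prefix}.ped"
        write_ped(cohort, paths["genotype"])
    elif fmt == "vcf":
        paths["genotype"] = out_dir / f"{prefix}.vcf"
        write_vcf(cohort, paths["genotype"])
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    return paths


def read_trio_cohort(
    genotype_path,
    pedigree_path,
    trisomic_path,
    map_path,
    centromere_bp: int = 13_000_000,
    chr21_label: str = "21",
) -> Cohort:
    """Assemble a cohort from its files.

    Families whose child has neither parent genotyped are excluded (with the
    reason logged and recorded in ``cohort.exclusions``); samples listed in
    the pedigree but absent from the genotype file are marked unavailable.
    """
    variants = read_map_tsv(map_path)
    gmap = genetic_map_from_variants(variants, chr21_label, centromere_bp)

    genotype_path = Path(genotype_path)
    if genotype_path.suffix == ".vcf" or str(genotype_path).endswith(".vcf.gz"):
        geno = read_vcf(genotype_path, variants)
    else:
        geno = read_ped(genotype_path, variants)

    fam = read_fam(pedigree_path)
    children = fam[(fam["father_id"] != "0") | (fam["mother_id"] != "0")]
    child_ids = set(children["individual_id"])

    tris = read_tris_tsv(trisomic_path)
    bad = set(tris["sample_id"]) - child_ids
    if bad:
        raise ValueError(f"trisomic records for non-child samples: {sorted(bad)[:5]}")
    vindex = pd.Index(variants["id"])
    chr21_ids = [variants["id"].iloc[i]
                 for i in np.flatnonzero((variants["chrom"] == chr21_label).to_numpy())]
    chr21_pos = {vid: k for k, vid in enumerate(chr21_ids)}
    unknown = set(tris["variant_id"]) - set(chr21_pos)
    if unknown:
        raise ValueError(f"trisomic records for unknown/non-chr21 variants: {sorted(unknown)[:5]}")

    tris_by_sample = {}
    for sid, grp in tris.groupby("sample_id", sort=False):
        vec = np.full(len(chr21_ids), MISSING, dtype=np.int8)
        vec[[chr21_pos[v] for v in grp["variant_id"]]] = grp["dosage"].to_numpy()
        tris_by_sample[sid] = vec

    trios, exclusions = [], []
    for _, row in children.iterrows():
        fam_id, cid = row["family_id"], row["individual_id"]
        mid = row["mother_id"] if row["mother_id"] != "0" else None
        fid = row["father_id"] if row["father_id"] != "0" else None
        m_avail = mid is not None and mid in geno
        f_avail = fid is not None and fid in geno
        if not m_avail and not f_avail:
            reason = "neither parent genotyped"
            log.warning("family %s excluded: %s", fam_id, reason)
            exclusions.append((fam_id, reason))
            continue
        avail = COMPLETE if (m_avail and f_avail) else (MOTHER_ONLY if m_avail else FATHER_ONLY)
        child_geno = geno.get(cid)
        if child_geno is None:
            child_geno = np.full(len(variants), MISSING, dtype=np.int8)
        trios.append(
            TrioRecord(
                family_id=fam_id,
                child_id=cid,
                mother_id=mid if m_avail else None,
                father_id=fid if f_avail else None,
                availability=avail,
                mother_geno=geno[mid] if m_avail else None,
                father_geno=geno[fid] if f_avail else None,
                child_geno=child_geno,
                child_tris=tris_by_sample.get(
                    cid, np.full(len(chr21_ids), MISSING, dtype=np.int8)
                ),
            )
        )
    return Cohort(variants=variants, trios=trios, genetic_map=gmap, exclusions=exclusions)
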