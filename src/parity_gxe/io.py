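"""File formats: VCF and dosage-TSV genotypes, registry/covariate TSVs, YAML
configs.

Genotypes are written as minimal VCF v4.2 (GT only, one record per biallelic
variant) and read back through cyvcf2 when it is installed (plain-text
fallback otherwise).  Dosage TSVs have one row per sample (``sample_id`` plus
one column per variant id) with a companion ``.variants.tsv`` carrying the
variant metadata.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simcohort import DosageMatrix

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(g: DosageMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(g.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, row in enumerate(g.variants.itertuples(index=False)):
            gts = "\t".join(_GT_CODES[int(d)] for d in g.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> DosageMatrix:
    """Read GT-derived dosages from a VCF (cyvcf2 when available)."""
    path = Path(path)
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0/1/2, 3 = unknown
        gt[gt == 3] = 0  # missing -> reference; never stored as missing
        rows.append(gt)
        meta.append((str(rec.CHROM), int(rec.POS), rec.ID or ".", rec.REF, rec.ALT[0]))
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    return DosageMatrix(
        dosages=np.array(rows, dtype=np.int8).T, variants=variants, sample_ids=sample_ids
    )


def _read_vcf_text(path: Path) -> DosageMatrix:
    sample_ids: list[str] = []
    rows, meta = [], []
    decode = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1, "1/1": 2, "1|1": 2}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                sample_ids = parts[9:]
                continue
            gts = [decode.get(p.split(":")[0], 0) for p in parts[9:]]
            rows.append(np.array(gts, dtype=np.int8))
            meta.append((parts[0], int(parts[1]), parts[2], parts[3], parts[4]))
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    return DosageMatrix(
        dosages=np.array(rows, dtype=np.int8).T, variants=variants, sample_ids=sample_ids
    )


def write_dosage_tsv(g: DosageMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(g.dosages, columns=g.variants["id"], copy=False)
    df.insert(0, "sample_id", g.sample_ids)
    df.to_csv(path, sep="\t", index=False)
    g.variants.to_csv(path.with_suffix(".variants.tsv"), sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> DosageMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sample_ids = df["sample_id"].astype(str).tolist()
    dosages = df.drop(columns=["sample_id"]).to_numpy(dtype=np.int8)
    vpath = path.with_suffix(".variants.tsv")
    if vpath.exists():
        variants = pd.read_csv(vpath, sep="\t")
    else:
        ids = [c for c in df.columns if c != "sample_id"]
        variants = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, len(ids) + 1), "id": ids,
             "ref": "A", "alt": "G"}
        )
    return DosageMatrix(dosages=dosages, variants=variants, sample_ids=sample_ids)


def write_sumstats(res: pd.DataFrame, path: str | Path) -> None:
    """REGENIE-like summary statistics TSV."""
    out = pd.DataFrame(
        {
            "CHROM": res["chrom"],
            "POS": res["pos"],
            "ID": res["id"],
            "REF": res["other_allele"],
            "ALT": res["effect_allele"],
            "A1": res["effect_allele"],
            "A1FREQ": res["eaf"],
            "N": res["n"],
            "BETA": res["beta"],
            "SE": res["se"],
            "P": res["p"],
            "STRATUM": res["stratum"],
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return pd.DataFrame(
        {
            "chrom": df["CHROM"].astype(str),
            "pos": df["POS"].astype(int),
            "id": df["ID"].astype(str),
            "effect_allele": df["A1"],
            "other_allele": df["REF"],
            "eaf": df["A1FREQ"],
            "beta": df["BETA"],
            "se": df["SE"],
            "p": df["P"],
            "n": df["N"],
            "stratum": df.get("STRATUM", "all"),
        }
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
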