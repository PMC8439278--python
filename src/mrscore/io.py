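"""Readers and writers for the pipeline's on-disk formats.

Tabular data travel as TSV with fixed headers; genotype dosages as
either a plain samples x variants TSV matrix or a minimal VCF v4.2 with
a ``DS`` FORMAT field (read through cyvcf2, falling back to GT hard
calls when DS is absent).  Floats in report tables are written with six
significant digits so reruns diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import GenotypeMatrix, InstrumentRecord

INSTRUMENT_COLUMNS = ["rsid", "chr", "pos", "ea", "oa", "beta", "se", "eaf", "is_indel"]


# --- instrument tables -------------------------------------------------------

def read_instruments(path: str | Path) -> list[InstrumentRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    missing = [c for c in INSTRUMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"instrument table {path} lacks columns: {missing}")
    return [
        InstrumentRecord(
            rsid=str(r.rsid), chrom=str(r.chr), pos=int(r.pos),
            effect_allele=str(r.ea), other_allele=str(r.oa),
            beta=float(r.beta), se=float(r.se), eaf=float(r.eaf),
            is_indel=bool(r.is_indel),
        )
        for r in df.itertuples(index=False)
    ]


def write_instruments(instruments: Sequence[InstrumentRecord], path: str | Path) -> None:
    df = pd.DataFrame([
        dict(rsid=i.rsid, chr=i.chrom, pos=i.pos, ea=i.effect_allele,
             oa=i.other_allele, beta=i.beta, se=i.se, eaf=i.eaf,
             is_indel=int(i.is_indel))
        for i in instruments
    ])
    write_table(df, path)


# --- genotype dosages --------------------------------------------------------

def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Samples x variants dosage matrix; first column is sample_id,
    remaining column names are rsids.  Missing dosages are empty cells."""
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.rsids)
    df.insert(0, "sample_id", genotypes.sample_ids)
    meta = genotypes.variants
    with open(path, "w") as fh:
        for col in ("chrom", "pos", "ref", "alt"):
            fh.write("#" + col + "\t" + "\t".join(map(str, meta[col])) + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    meta: dict[str, list[str]] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, *vals = line[1:].rstrip("\n").split("\t")
            meta[key] = vals
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    rsids = list(df.columns[1:])
    variants = pd.DataFrame(dict(
        rsid=rsids,
        chrom=meta.get("chrom", ["?"] * len(rsids)),
        pos=[int(p) for p in meta.get("pos", ["0"] * len(rsids))],
        ref=meta.get("ref", ["N"] * len(rsids)),
        alt=meta.get("alt", ["N"] * len(rsids)),
    ))
    return GenotypeMatrix(
        dosages=df.iloc[:, 1:].to_numpy(dtype=float),
        sample_ids=df["sample_id"].astype(str).tolist(),
        variants=variants,
    )


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF v4.2 with per-sample DS (dosage of the ALT allele)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        order = np.lexsort((genotypes.variants["pos"].to_numpy(),
                            genotypes.variants["chrom"].to_numpy()))
        for j in order:
            v = genotypes.variants.iloc[j]
            ds = [
                "." if np.isnan(d) else format(d, "g")
                for d in genotypes.dosages[:, j]
            ]
            fh.write(f"{v['chrom']}\t{v['pos']}\t{v['rsid']}\t{v['ref']}\t"
                     f"{v['alt']}\t.\t.\t.\tDS\t" + "\t".join(ds) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read dosages from the DS FORMAT field (GT hard calls as fallback)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, var_rows = [], []
    for rec in vcf:
        try:
            ds = np.asarray(rec.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError, ValueError):
            gt = rec.gt_types.astype(float)  # 0, 1, 3 -> dosage; 2 = unknown
            ds = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        rows.append(ds)
        var_rows.append(dict(rsid=rec.ID or f"{rec.CHROM}:{rec.POS}",
                             chrom=str(rec.CHROM), pos=int(rec.POS),
                             ref=rec.REF, alt=rec.ALT[0] if rec.ALT else "N"))
    return GenotypeMatrix(
        dosages=np.column_stack(rows) if rows else np.empty((len(samples), 0)),
        sample_ids=samples,
        variants=pd.DataFrame(var_rows, columns=["rsid", "chrom", "pos", "ref", "alt"]),
    )


# --- phenotypes, relatedness, truth ------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "dataset": str})


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pihat(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
    need = {"id1", "id2", "pihat"}
    if not need <= set(df.columns):
        raise ValueError(f"PI_HAT table must have columns {sorted(need)}")
    return df


def write_truth(truth: dict, path: str | Path) -> None:
    """Truth record as YAML (or JSON if the path ends in .json)."""
    ser = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in truth.items()
    }
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(ser, fh, indent=1)
        else:
            yaml.safe_dump(ser, fh, sort_keys=False)


def read_truth(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    for k, v in data.items():
        if isinstance(v, list) and v and isinstance(v[0], (int, float)):
            data[k] = np.asarray(v, dtype=float)
    return data


# --- report tables -----------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with six-significant-digit floats for diffable reruns."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
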