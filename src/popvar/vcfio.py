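"""Reading and writing the interchange formats.

VCF v4.2 is the genotype interchange format (read through cyvcf2); the
sample panel, GWAS SNP list, chromosome-length table and array-truth
genotypes are plain TSV.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SampleLookupError, VcfFormatError
from .variants import (
    MISSING,
    FUNCTIONAL_CLASSES,
    GenotypeMatrix,
    make_panel,
    make_variant_table,
    normalize_chrom,
)

#: INFO key carrying the functional-class annotation
ANN_CLASS_KEY = "ANN_CLASS"
#: INFO flag marking presence in a reference catalogue
KNOWN_KEY = "KNOWN"

# cyvcf2 gt_types code: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_GT_TYPE_TO_DOSAGE = {0: 0, 1: 1, 2: MISSING, 3: 2}


def read_vcf(
    path: str | os.PathLike,
    panel: pd.DataFrame | None = None,
    ann_class_key: str = ANN_CLASS_KEY,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a biallelic VCF into a genotype matrix and variant table.

    Multiallelic records are rejected (split them upstream); "./." maps to
    the explicit missing state. The functional class is read from the
    ``ann_class_key`` INFO field when present, else "other"; the novelty flag
    from the ``KNOWN`` INFO flag.

    When a ``panel`` is given, every panel sample must be present in the VCF.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if panel is not None:
        absent = [s for s in panel["sample"] if s not in set(samples)]
        if absent:
            raise SampleLookupError(
                f"panel samples absent from VCF {path}: {absent}"
            )
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    classes: list[str] = []
    known: list[bool] = []
    rsids: list[str] = []
    rows: list[np.ndarray] = []
    for rec_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1:
            raise VcfFormatError(
                f"{path}: record {rec_no} ({v.CHROM}:{v.POS}) is not "
                f"biallelic (ALT={','.join(v.ALT) or '.'})"
            )
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        cls = v.INFO.get(ann_class_key)
        classes.append(cls if cls in FUNCTIONAL_CLASSES else "other")
        known.append(v.INFO.get(KNOWN_KEY) is not None)
        rsids.append(v.ID or ".")
        rows.append(
            np.array(
                [_GT_TYPE_TO_DOSAGE[int(t)] for t in v.gt_types], dtype=np.int8
            )
        )
    vcf.close()
    dosage = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    table = make_variant_table(
        chroms, poss, refs, alts, classes, known, rsid=rsids
    )
    matrix = GenotypeMatrix(
        samples=samples, variants=table[["chrom", "pos", "ref", "alt"]].copy(),
        dosage=dosage,
    )
    return matrix, table


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    path: str | os.PathLike,
    matrix: GenotypeMatrix,
    table: pd.DataFrame | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a genotype matrix as an uncompressed VCF v4.2.

    Round-trips through :func:`read_vcf` bit-exactly (sample order, variant
    keys, dosages, functional classes, known flags).
    """
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for c, n in contig_lengths.items():
            lines.append(f"##contig=<ID={normalize_chrom(c)},length={int(n)}>")
    else:
        for c in dict.fromkeys(matrix.variants["chrom"]):
            lines.append(f"##contig=<ID={c}>")
    lines.append(
        f'##INFO=<ID={ANN_CLASS_KEY},Number=1,Type=String,'
        f'Description="Functional class: synonymous/nonsynonymous/other">'
    )
    lines.append(
        f'##INFO=<ID={KNOWN_KEY},Number=0,Type=Flag,'
        f'Description="Present in a reference catalogue">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    v = matrix.variants
    if table is not None:
        classes = list(table["functional_class"])
        known = list(table["known_flag"])
        rsid = list(table["rsid"]) if "rsid" in table else ["."] * len(v)
    else:
        classes = ["other"] * len(v)
        known = [False] * len(v)
        rsid = ["."] * len(v)
    for j in range(len(v)):
        info = f"{ANN_CLASS_KEY}={classes[j]}"
        if known[j]:
            info += f";{KNOWN_KEY}"
        gts = "\t".join(_DOSAGE_TO_GT[int(g)] for g in matrix.dosage[:, j])
        lines.append(
            f"{v['chrom'].iat[j]}\t{int(v['pos'].iat[j])}\t{rsid[j]}\t"
            f"{v['ref'].iat[j]}\t{v['alt'].iat[j]}\t.\tPASS\t{info}\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_panel(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample panel TSV (`sample  population  latitude  longitude`)."""
    df = pd.read_csv(path, sep="\t")
    return make_panel(
        df["sample"],
        df["population"],
        df["latitude"] if "latitude" in df else None,
        df["longitude"] if "longitude" in df else None,
    )


def write_panel(path: str | os.PathLike, panel: pd.DataFrame) -> None:
    panel.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_gwas_list(path: str | os.PathLike) -> pd.DataFrame:
    """Read a GWAS SNP list TSV (`rsid  chrom  pos  trait`)."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "trait": str})
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(np.int64)
    return df


def read_chrom_lengths(path: str | os.PathLike) -> dict[str, int]:
    """Read an ungapped chromosome length table TSV (`chrom  length`)."""
    df = pd.read_csv(path, sep="\t")
    return {normalize_chrom(c): int(n) for c, n in zip(df["chrom"], df["length"])}


def write_chrom_lengths(
    path: str | os.PathLike, lengths: Mapping[str, int]
) -> None:
    pd.DataFrame(
        {"chrom": list(lengths), "length": [int(v) for v in lengths.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_truth_genotypes(path: str | os.PathLike) -> dict[tuple, int]:
    """Read gold-standard genotypes TSV
    (`sample  chrom  pos  ref  alt  genotype`) into the mapping consumed by
    :func:`popvar.variants.concordance`."""
    df = pd.read_csv(path, sep="\t")
    return {
        (s, normalize_chrom(c), int(p), r, a): int(g)
        for s, c, p, r, a, g in zip(
            df["sample"], df["chrom"], df["pos"], df["ref"], df["alt"],
            df["genotype"],
        )
    }


def write_truth_genotypes(
    path: str | os.PathLike, truth: Mapping[tuple, int]
) -> None:
    rows = [(*k, g) for k, g in truth.items()]
    pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt", "genotype"]
    ).to_csv(path, sep="\t", index=False)


def read_het_sites(path: str | os.PathLike) -> pd.DataFrame:
    """Read heterozygous-site list TSV (`sample  chrom  pos`, 1-based)."""
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(np.int64)
    return df


def het_sites_from_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Extract per-sample heterozygous SNP sites (1-based positions)."""
    rows = []
    v = matrix.variants
    for i, s in enumerate(matrix.samples):
        jj = np.flatnonzero(matrix.dosage[i] == 1)
        for j in jj:
            rows.append((s, v["chrom"].iat[j], int(v["pos"].iat[j])))
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos"])
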