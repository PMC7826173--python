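"""Readers and writers for the formats the toolkit exchanges.

VCF 4.2 (phased GT, DP, AD, QUAL, site-level SAF/SAR in INFO), BED
(0-based half-open), FASTA, and the tab-separated tables used for sex
labels, per-window depth and linked-read molecules.  Reading VCF goes
through cyvcf2; writing uses a small text emitter covering the subset of
the standard this toolkit produces.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import HET, HOM_ALT, HOM_REF, MISSING, CohortVariantSet, SexLabels

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(cohort: CohortVariantSet, path: str | os.PathLike,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a cohort to a VCF 4.2 text file.

    Genotypes are written phased ('|') from the haplotype matrix when the
    cohort carries one, otherwise unphased from genotype codes.
    """
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in dict.fromkeys(cohort.chrom.tolist()):
            lines.append(f"##contig=<ID={name}>")
    lines += [
        '##INFO=<ID=SAF,Number=1,Type=Integer,Description="Alt observations on forward strand">',
        '##INFO=<ID=SAR,Number=1,Type=Integer,Description="Alt observations on reverse strand">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.samples),
    ]
    hap = cohort.hap
    for i in range(cohort.n_sites):
        fields = [
            str(cohort.chrom[i]),
            str(int(cohort.pos[i])),
            ".",
            str(cohort.ref[i]),
            str(cohort.alt[i]),
            f"{float(cohort.qual[i]):g}",
            ".",
            f"SAF={int(cohort.saf[i])};SAR={int(cohort.sar[i])}",
            "GT:DP:AD",
        ]
        cells = []
        for j in range(cohort.n_samples):
            g = int(cohort.gt[i, j])
            if hap is not None and g != MISSING:
                a, b = int(hap[i, 2 * j]), int(hap[i, 2 * j + 1])
                gt = f"{a}|{b}"
            else:
                gt = _GT_STR[g]
            if g == MISSING:
                cells.append(f"{gt}:.:.")
            else:
                cells.append(
                    f"{gt}:{int(cohort.dp[i, j])}:{int(cohort.ad_ref[i, j])},{int(cohort.ad_alt[i, j])}"
                )
        lines.append("\t".join(fields + cells))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str | os.PathLike) -> CohortVariantSet:
    """Load a biallelic VCF into a :class:`CohortVariantSet`.

    Raises on multiallelic records (decompose upstream).  Phase is
    preserved into the haplotype matrix; unphased heterozygotes get an
    arbitrary but deterministic hap order (ref-first).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    chrom, pos, ref, alt, qual, is_snp, saf, sar = [], [], [], [], [], [], [], []
    gt_rows, dp_rows, adr_rows, ada_rows, hap_rows = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {v.CHROM}:{v.POS}; decompose to biallelic primitives first"
            )
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        is_snp.append(len(v.REF) == 1 and len(v.ALT[0]) == 1)
        saf.append(int(v.INFO.get("SAF", 0) or 0))
        sar.append(int(v.INFO.get("SAR", 0) or 0))

        g = np.full(n, MISSING, dtype=np.int8)
        h = np.full(2 * n, MISSING, dtype=np.int8)
        for j, (a, b, *_rest) in enumerate(v.genotypes):
            if a < 0 or b < 0:
                continue
            g[j] = a + b
            h[2 * j], h[2 * j + 1] = a, b
        gt_rows.append(g)
        hap_rows.append(h)

        dp = v.format("DP")
        dp_rows.append(
            np.where(np.isfinite(dp[:, 0]) if dp is not None else False, dp[:, 0], 0).astype(np.int32)
            if dp is not None
            else np.zeros(n, dtype=np.int32)
        )
        ad = v.format("AD")
        if ad is not None:
            ad = np.where(ad < 0, 0, ad)
            adr_rows.append(ad[:, 0].astype(np.int32))
            ada_rows.append(ad[:, 1].astype(np.int32))
        else:
            adr_rows.append(np.zeros(n, dtype=np.int32))
            ada_rows.append(np.zeros(n, dtype=np.int32))

    def stack(rows, dtype):
        return np.array(rows, dtype=dtype) if rows else np.zeros((0, n), dtype=dtype)

    return CohortVariantSet(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        qual=np.array(qual, dtype=float),
        is_snp=np.array(is_snp, dtype=bool),
        saf=np.array(saf, dtype=np.int64),
        sar=np.array(sar, dtype=np.int64),
        samples=samples,
        gt=stack(gt_rows, np.int8),
        dp=stack(dp_rows, np.int32),
        ad_ref=stack(adr_rows, np.int32),
        ad_alt=stack(ada_rows, np.int32),
        hap=stack(hap_rows, np.int8).reshape(-1, 2 * n) if hap_rows else np.zeros((0, 2 * n), np.int8),
    )


def write_sex_tsv(labels: SexLabels, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, sex in labels.mapping.items():
            fh.write(f"{name}\t{sex}\n")


def read_sex_tsv(path: str | os.PathLike) -> SexLabels:
    df = pd.read_csv(path, sep="\t", header=None, names=["individual", "sex"], dtype=str)
    return SexLabels(dict(zip(df["individual"], df["sex"])))


def write_bed(intervals: list[tuple[str, int, int]] | list[tuple[str, int, int, str]],
              path: str | os.PathLike) -> None:
    """Write intervals as BED (0-based half-open), optional 4th name column."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_fasta(records: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_molecules_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False,
              columns=["barcode", "individual", "chrom", "start", "end", "haplotype"])


def read_molecules_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"barcode": str, "individual": str, "chrom": str})
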