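"""Shared containers for cohort variant data and sample metadata.

The central object is :class:`CohortVariantSet`, an array-backed table of
biallelic variants with per-sample genotypes, depths and allele depths, and
(optionally) a phased haplotype matrix.  All sites are biallelic primitives:
multiallelic records must be decomposed upstream and are rejected on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# genotype codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1


@dataclass
class CohortVariantSet:
    """Biallelic cohort variants with per-sample genotype support.

    Attributes
    ----------
    chrom, pos, ref, alt, qual : per-site arrays; ``pos`` is 1-based.
    is_snp : True for SNPs, False for indels.
    saf, sar : site-level alternate-allele observations on the forward and
        reverse strands.
    gt : (n_sites, n_samples) int8 matrix of genotype codes
        (0 hom-ref, 1 het, 2 hom-alt, -1 missing).
    dp, ad_ref, ad_alt : (n_sites, n_samples) per-genotype read support.
    hap : optional (n_sites, 2 * n_samples) int8 phased allele matrix
        (0 ref, 1 alt, -1 missing); haplotype columns are ordered
        (sample0_hap1, sample0_hap2, sample1_hap1, ...).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    is_snp: np.ndarray
    saf: np.ndarray
    sar: np.ndarray
    samples: list[str]
    gt: np.ndarray
    dp: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    hap: np.ndarray | None = None

    def __post_init__(self) -> None:
        s, n = self.gt.shape
        for name in ("chrom", "pos", "ref", "alt", "qual", "is_snp", "saf", "sar"):
            arr = getattr(self, name)
            if len(arr) != s:
                raise ValueError(f"{name} has length {len(arr)}, expected {s}")
        if len(self.samples) != n:
            raise ValueError("sample list does not match genotype matrix width")
        for name in ("dp", "ad_ref", "ad_alt"):
            if getattr(self, name).shape != (s, n):
                raise ValueError(f"{name} shape mismatch")
        if self.hap is not None and self.hap.shape != (s, 2 * n):
            raise ValueError("hap matrix must have 2 columns per sample")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def subset_sites(self, mask: np.ndarray) -> "CohortVariantSet":
        """Return a copy restricted to sites where ``mask`` is True (or an index array)."""
        return replace(
            self,
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            qual=self.qual[mask],
            is_snp=self.is_snp[mask],
            saf=self.saf[mask],
            sar=self.sar[mask],
            gt=self.gt[mask],
            dp=self.dp[mask],
            ad_ref=self.ad_ref[mask],
            ad_alt=self.ad_alt[mask],
            hap=None if self.hap is None else self.hap[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        """Site-level summary as a tidy DataFrame (no per-sample columns)."""
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "qual": self.qual,
                "is_snp": self.is_snp,
                "saf": self.saf,
                "sar": self.sar,
            }
        )


def empty_cohort(samples: list[str]) -> CohortVariantSet:
    n = len(samples)
    z = np.zeros(0, dtype=object)
    return CohortVariantSet(
        chrom=z.copy(),
        pos=np.zeros(0, dtype=np.int64),
        ref=z.copy(),
        alt=z.copy(),
        qual=np.zeros(0),
        is_snp=np.zeros(0, dtype=bool),
        saf=np.zeros(0, dtype=np.int64),
        sar=np.zeros(0, dtype=np.int64),
        samples=list(samples),
        gt=np.zeros((0, n), dtype=np.int8),
        dp=np.zeros((0, n), dtype=np.int32),
        ad_ref=np.zeros((0, n), dtype=np.int32),
        ad_alt=np.zeros((0, n), dtype=np.int32),
        hap=np.zeros((0, 2 * n), dtype=np.int8),
    )


@dataclass
class SexLabels:
    """Mapping from sample name to sex ('M' or 'F')."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values()} - {"M", "F"}
        if bad:
            raise ValueError(f"sex labels must be 'M' or 'F', got {sorted(bad)}")

    def masks(self, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (male, female) masks aligned to ``samples``."""
        missing = [s for s in samples if s not in self.mapping]
        if missing:
            raise KeyError(f"samples without sex label: {missing}")
        sexes = np.array([self.mapping[s] for s in samples])
        return sexes == "M", sexes == "F"

    @property
    def males(self) -> list[str]:
        return [s for s, v in self.mapping.items() if v == "M"]

    @property
    def females(self) -> list[str]:
        return [s for s, v in self.mapping.items() if v == "F"]
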