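"""Tiered male-linked SNP classification and its permutation null.

In a male-heterogametic (XY) system, a Y-linked allele that still maps to
the female reference appears only as a heterozygous genotype in males and
never in females.  A SNP is a *candidate* when every non-missing female is
homozygous for one allele and the other ("male-limited") allele occurs only
as heterozygotes in males; any homozygous carrier of the male-limited
allele disqualifies the SNP.  Candidates are tiered by the fraction of
non-missing males carrying the allele: 100% (full), >88% (all but one of
~10), >77%, >66%.  Tiers are strict inequalities and nested.

The null distribution is obtained by permuting individual sex labels
(preserving group sizes), reclassifying, and recording per-chromosome
counts; a chromosome is flagged when its observed per-Mb count exceeds the
null's 95th per-Mb percentile.  Classification over label permutations is
expressed as matrix products of genotype-state indicators with a batch of
label assignments, so 10,000 iterations stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, CohortVariantSet, SexLabels
from .divstats import chi2_gof

TIERS = {"full": 1.0, "ge88": 0.88, "ge77": 0.77, "ge66": 0.66}
TIER_ORDER = ["full", "ge88", "ge77", "ge66", "none"]


@dataclass
class NullDistribution:
    tier: str
    n_iter: int
    chromosomes: list[str]
    chrom_sizes_bp: dict[str, int]
    null_counts: np.ndarray  # (n_chrom, n_iter)
    observed: np.ndarray  # (n_chrom,)
    flagged: list[str]

    def per_mb(self, counts: np.ndarray) -> np.ndarray:
        mb = np.array([self.chrom_sizes_bp[c] / 1e6 for c in self.chromosomes])
        return counts / mb[..., None] if counts.ndim == 2 else counts / mb

    def summary(self) -> dict:
        null_mb = self.per_mb(self.null_counts)
        return {
            "tier": self.tier,
            "n_iter": self.n_iter,
            "chromosomes": self.chromosomes,
            "observed": self.observed.tolist(),
            "observed_per_mb": self.per_mb(self.observed.astype(float)).tolist(),
            "null_p95_per_mb": np.percentile(null_mb, 95, axis=1).tolist(),
            "flagged": self.flagged,
        }


class _Indicators:
    """Genotype-state indicator matrices reused across label permutations."""

    def __init__(self, gt: np.ndarray):
        self.H = (gt == 1).astype(np.float32)
        self.Mi = (gt == MISSING).astype(np.float32)
        self.any_hom_alt = (gt == 2).any(axis=1)
        self.any_hom_ref = (gt == 0).any(axis=1)
        self.n = gt.shape[1]

    def carrier_fraction(self, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For male-assignment batch P (n x B of 0/1): candidate mask and male carrier fraction.

        Returns (candidate (S x B) bool, frac (S x B) float32); frac is 0
        where not a candidate.
        """
        F = 1.0 - P
        het_m = self.H @ P
        het_f = self.H @ F
        miss_m = self.Mi @ P
        miss_f = self.Mi @ F
        n_m = P.sum(axis=0)
        n_f = F.sum(axis=0)
        nonmiss_m = n_m - miss_m
        nonmiss_f = n_f - miss_f
        female_clean = het_f == 0
        direction_ok = (~self.any_hom_alt | ~self.any_hom_ref)[:, None]
        candidate = (
            female_clean
            & direction_ok
            & (het_m >= 1)
            & (nonmiss_m >= 1)
            & (nonmiss_f >= 1)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(candidate, het_m / np.maximum(nonmiss_m, 1), 0.0)
        return candidate, frac.astype(np.float32)


def _tier_mask(candidate: np.ndarray, frac: np.ndarray, tier: str) -> np.ndarray:
    thr = TIERS[tier]
    if tier == "full":
        return candidate & (frac >= 1.0)
    return candidate & (frac > thr)


def _label_vector(cohort: CohortVariantSet, labels: SexLabels) -> np.ndarray:
    male, female = labels.masks(cohort.samples)
    if male.sum() == 0 or female.sum() == 0:
        raise ValueError("both sexes must be present")
    return male.astype(np.float32)


def classify_tiers(cohort: CohortVariantSet, labels: SexLabels) -> pd.DataFrame:
    """Per-SNP male-linkage catalog.

    Returns a frame (chrom, pos, tier, frac, n_carrier_males, n_males,
    male_limited_allele) over biallelic SNPs; ``tier`` is 'none' for
    non-candidates and for candidates at or below the 66% quota.
    """
    snp = cohort.subset_sites(cohort.is_snp)
    male_vec = _label_vector(snp, labels)
    ind = _Indicators(snp.gt)
    P = male_vec[:, None]
    candidate, frac = ind.carrier_fraction(P)
    candidate, frac = candidate[:, 0], frac[:, 0]

    tier = np.full(snp.n_sites, "none", dtype=object)
    for name in ["ge66", "ge77", "ge88"]:
        tier[_tier_mask(candidate, frac, name)] = name
    tier[_tier_mask(candidate, frac, "full")] = "full"

    male_mask = male_vec.astype(bool)
    het_m = (snp.gt[:, male_mask] == 1).sum(axis=1)
    nonmiss_m = (snp.gt[:, male_mask] != MISSING).sum(axis=1)
    allele = np.where(ind.any_hom_ref, "alt", "ref")  # limited allele is the one never homozygous
    allele = np.where(candidate, allele, ".")
    return pd.DataFrame(
        {
            "chrom": snp.chrom,
            "pos": snp.pos,
            "tier": tier,
            "frac": frac,
            "n_carrier_males": het_m,
            "n_males": nonmiss_m,
            "male_limited_allele": allele,
        }
    )


def permutation_null(
    cohort: CohortVariantSet,
    labels: SexLabels,
    chrom_sizes_bp: dict[str, int],
    tier: str = "ge66",
    n_iter: int = 10_000,
    seed: int = 0,
    batch: int = 512,
) -> NullDistribution:
    """Sex-label permutation null for per-chromosome male-linked SNP counts.

    Each iteration permutes the individual sex labels (group sizes
    preserved), reclassifies every SNP, and records per-chromosome counts at
    the requested tier.  A chromosome is flagged when its observed per-Mb
    count exceeds the 95th percentile of the null per-Mb counts.
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}")
    snp = cohort.subset_sites(cohort.is_snp)
    male_vec = _label_vector(snp, labels)
    ind = _Indicators(snp.gt)

    chroms = sorted(dict.fromkeys(snp.chrom.tolist()))
    missing_sizes = [c for c in chroms if c not in chrom_sizes_bp]
    if missing_sizes:
        raise KeyError(f"no chromosome size for {missing_sizes}")
    C = np.stack([(snp.chrom == c).astype(np.float32) for c in chroms], axis=1)  # S x K

    cand, frac = ind.carrier_fraction(male_vec[:, None])
    obs_mask = _tier_mask(cand, frac, tier)[:, 0].astype(np.float32)
    observed = C.T @ obs_mask

    rng = np.random.default_rng(seed)
    n = len(snp.samples)
    null = np.zeros((len(chroms), n_iter), dtype=np.float32)
    done = 0
    while done < n_iter:
        b = min(batch, n_iter - done)
        P = np.empty((n, b), dtype=np.float32)
        for k in range(b):
            P[:, k] = rng.permutation(male_vec)
        cand_b, frac_b = ind.carrier_fraction(P)
        linked = _tier_mask(cand_b, frac_b, tier).astype(np.float32)
        null[:, done : done + b] = C.T @ linked
        done += b

    mb = np.array([chrom_sizes_bp[c] / 1e6 for c in chroms])
    null_mb = null / mb[:, None]
    obs_mb = observed / mb
    p95 = np.percentile(null_mb, 95, axis=1)
    flagged = [c for c, o, q in zip(chroms, obs_mb, p95) if o > q]
    return NullDistribution(
        tier=tier,
        n_iter=n_iter,
        chromosomes=chroms,
        chrom_sizes_bp=dict(chrom_sizes_bp),
        null_counts=null,
        observed=observed.astype(np.int64),
        flagged=flagged,
    )


def stratum_enrichment(
    catalog: pd.DataFrame,
    stratum: tuple[str, int, int],
    chrom_length: int,
    all_snp_positions: np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Chi-square enrichment of male-linked SNPs inside a stratum.

    Tests the in-stratum vs out-of-stratum split of male-linked SNPs (tier
    != 'none') on the stratum's chromosome against expectations
    proportional to (a) the stratum's length fraction and, when
    ``all_snp_positions`` (1-based, same chromosome) is given, (b) the
    stratum's share of all SNPs.  Returns {"by_length": (chi2, p),
    "by_snp_content": (chi2, p) or None}.
    """
    chrom, start, end = stratum
    linked = catalog[(catalog["tier"] != "none") & (catalog["chrom"] == chrom)]
    if len(linked) == 0:
        raise ValueError("no male-linked SNPs on the stratum chromosome")
    pos0 = linked["pos"].to_numpy() - 1
    inside = int(((pos0 >= start) & (pos0 < end)).sum())
    outside = len(linked) - inside
    len_frac = (end - start) / chrom_length
    results: dict = {"by_length": chi2_gof([inside, outside], [len_frac, 1 - len_frac])}
    if all_snp_positions is not None:
        ap0 = np.asarray(all_snp_positions) - 1
        snp_frac = float(((ap0 >= start) & (ap0 < end)).mean())
        if snp_frac in (0.0, 1.0):
            raise ValueError("degenerate SNP-content fractions")
        results["by_snp_content"] = chi2_gof([inside, outside], [snp_frac, 1 - snp_frac])
    else:
        results["by_snp_content"] = None
    return results
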