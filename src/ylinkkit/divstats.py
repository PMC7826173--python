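"""Diversity and differentiation estimators.

Hudson's male-female F_ST in non-overlapping windows (ratio of sums),
bootstrap confidence band over autosomal windows, Watterson's theta and
X/Y/autosome diversity ratios, plus thin wrappers for the rank and
goodness-of-fit tests used downstream.

Hudson's per-site estimator, for allele frequencies p1, p2 estimated from
n1, n2 sampled chromosomes:

    N = (p1 - p2)^2 - p1 (1 - p1) / (n1 - 1) - p2 (1 - p2) / (n2 - 1)
    D = p1 (1 - p2) + p2 (1 - p1)

and the windowed estimate is sum(N) / sum(D) over usable sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, CohortVariantSet, SexLabels
from .covwin import WindowGrid

__all__ = [
    "hudson_site",
    "fst_windows",
    "bootstrap_autosomal_ci",
    "watterson_theta",
    "theta_from_alignment",
    "diversity_ratios",
    "kruskal_wallis",
    "chi2_gof",
    "BootstrapCI",
    "ThetaEstimate",
]


def hudson_site(p1, p2, n1, n2):
    """Hudson F_ST numerator and denominator for one site (vectorized).

    ``p1``/``p2`` are alt-allele frequencies in the two groups and
    ``n1``/``n2`` the numbers of sampled chromosomes.  Requires n >= 2 in
    each group for the unbiasedness correction.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("Hudson's estimator needs at least 2 chromosomes per group")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _group_freqs(gt: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequency and chromosome count per site within a sample mask."""
    g = gt[:, mask]
    called = g != MISSING
    n_chrom = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
    return p, n_chrom


def fst_windows(
    cohort: CohortVariantSet,
    labels: SexLabels,
    grid: WindowGrid,
    max_missing_per_sex: float = 0.20,
    min_sites: int = 5,
) -> pd.DataFrame:
    """Male-female Hudson F_ST for biallelic SNPs in non-overlapping windows.

    Singleton sites (minor allele on exactly one chromosome cohort-wide) and
    sites with >= ``max_missing_per_sex`` missing genotypes in either sex are
    excluded before windowing.  Windows with fewer than ``min_sites`` usable
    sites, or with a zero denominator, are reported as NaN.

    Returns a tidy frame: chrom, start, end, fst, n_sites.
    """
    male, female = labels.masks(cohort.samples)
    if male.sum() == 0 or female.sum() == 0:
        raise ValueError("both sexes are required for male-female F_ST")

    keep = cohort.is_snp.copy()
    gt = cohort.gt
    called = gt != MISSING

    # singleton filter: minor allele count == 1 over all called chromosomes
    alt_count = np.where(called, gt, 0).sum(axis=1)
    total_chrom = 2 * called.sum(axis=1)
    minor = np.minimum(alt_count, total_chrom - alt_count)
    keep &= minor != 1

    # per-sex missingness filter
    for mask in (male, female):
        miss_frac = (~called[:, mask]).sum(axis=1) / mask.sum()
        keep &= miss_frac < max_missing_per_sex

    p1, n1 = _group_freqs(gt, male)
    p2, n2 = _group_freqs(gt, female)
    keep &= (n1 >= 2) & (n2 >= 2)

    num = np.zeros(cohort.n_sites)
    den = np.zeros(cohort.n_sites)
    if keep.any():
        num[keep], den[keep] = hudson_site(p1[keep], p2[keep], n1[keep], n2[keep])

    rows = []
    for chrom, start, end in grid.windows:
        inwin = keep & (cohort.chrom == chrom) & (cohort.pos - 1 >= start) & (cohort.pos - 1 < end)
        n = int(inwin.sum())
        d = den[inwin].sum()
        if n < min_sites or d == 0:
            fst = np.nan
        else:
            fst = num[inwin].sum() / d
        rows.append((chrom, start, end, fst, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fst", "n_sites"])


@dataclass
class BootstrapCI:
    level: float
    lo: float
    hi: float
    n_boot: int
    seed: int

    def __post_init__(self):
        if not self.lo <= self.hi:
            raise ValueError("lower bound exceeds upper bound")


def bootstrap_autosomal_ci(
    values, n_boot: int = 1000, level: float = 95.0, seed: int = 0
) -> BootstrapCI:
    """Percentile bootstrap CI of the mean of (autosomal) window values.

    Resamples the window values with replacement, keeping the original
    count, and takes the percentile interval of the replicate means.
    NaN windows are dropped first.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite window values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(means, [alpha, 100.0 - alpha])
    return BootstrapCI(level=level, lo=float(lo), hi=float(hi), n_boot=n_boot, seed=seed)


@dataclass
class ThetaEstimate:
    """Watterson's estimator theta_W = S / (a_n * L) per site."""

    S: int
    n: int
    L: int
    theta_per_site: float

    @property
    def a_n(self) -> float:
        return harmonic(self.n - 1)


def harmonic(m: int) -> float:
    """a_n = sum_{i=1}^{m} 1/i."""
    return float(np.sum(1.0 / np.arange(1, m + 1))) if m > 0 else 0.0


def watterson_theta(S: int, n: int, L: int, check_length: bool = True) -> ThetaEstimate:
    """Watterson's theta from S segregating sites among n haplotypes over L sites.

    ``check_length=False`` lifts the S <= L sanity check for infinite-sites
    loci, where one locus can carry several segregating mutations.
    """
    if n < 2:
        raise ValueError("Watterson's estimator needs at least 2 haplotypes")
    if L <= 0:
        raise ValueError("alignment length must be positive")
    if check_length and S > L:
        raise ValueError("more segregating sites than sites")
    a_n = harmonic(n - 1)
    return ThetaEstimate(S=int(S), n=int(n), L=int(L), theta_per_site=S / (a_n * L))


def theta_from_alignment(aln: np.ndarray, L: int | None = None) -> ThetaEstimate:
    """Watterson's theta from a (haplotypes x sites) allele/character matrix.

    A column is segregating when it holds more than one distinct non-missing
    state (missing coded as -1).  ``L`` defaults to the number of columns;
    pass the spanned length in bp when the matrix holds only variant columns.
    """
    aln = np.asarray(aln)
    if aln.ndim != 2 or aln.shape[0] < 2:
        raise ValueError("need a 2-D alignment with at least 2 haplotypes")
    S = 0
    for col in aln.T:
        states = np.unique(col[col != MISSING])
        if states.size > 1:
            S += 1
    return watterson_theta(S, aln.shape[0], L if L is not None else aln.shape[1])


def diversity_ratios(theta_x: float, theta_y: float, theta_a: float) -> tuple[float, float]:
    """(X/A, Y/A) diversity ratios; the neutral expectations are 3/4 and 1/4."""
    if theta_a == 0:
        raise ValueError("autosomal theta is zero; ratios undefined")
    return theta_x / theta_a, theta_y / theta_a


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        # scipy raises on all-identical data; identical groups carry no signal
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def chi2_gof(observed, expected_proportions) -> tuple[float, float]:
    """Chi-square goodness of fit of counts against expected proportions."""
    obs = np.asarray(observed, dtype=float)
    prop = np.asarray(expected_proportions, dtype=float)
    if obs.shape != prop.shape:
        raise ValueError("observed and expected shapes differ")
    if np.any(prop <= 0):
        raise ValueError("expected proportions must be positive")
    exp = prop / prop.sum() * obs.sum()
    chi2, p = stats.chisquare(obs, exp)
    return float(chi2), float(p)
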