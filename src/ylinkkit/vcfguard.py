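"""Hard-filter cascade for cohort genotype calls, with a per-rule audit.

The cascade mirrors a conservative short-read genotyping filter for
population resequencing: strand support, site quality, per-genotype depth,
a max-depth rule against collapsed paralogs, indel proximity, cohort allele
balance, heterozygote allele-depth masking, and a missingness ceiling.
Rules are applied in a fixed order and each removed site is attributed to
the first rule that removes it, so the audit is deterministic.

Cohort-level constants (mean site depth, allele-balance percentile) are
computed once on the input cohort before any rule runs; they are recorded
in the audit and can be passed back in to make re-filtering idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import HET, HOM_ALT, HOM_REF, MISSING, CohortVariantSet

RULES = [
    "strand_support",      # (1) saf < min or sar < min
    "site_quality",        # (2) QUAL < 30
    "genotype_depth",      # (3) het dp<4 masked; hom dp<4 masked when QUAL<50; site dropped if unsupported
    "max_depth",           # (4) het sites: QUAL < 2*avg and max dp > avg + 3*sqrt(avg)
    "indel_proximity",     # (5) indels and SNPs within 3 bp of an indel
    "allele_balance",      # (6) non-fixed sites below the cohort AB percentile
    "het_ad_mask",         # (7) het genotypes with min(AD) < 3 masked (genotype-level)
    "missingness",         # (8) > 10% missing genotypes
]


@dataclass
class FilterConfig:
    min_strand_obs: int = 3
    min_qual: float = 30.0
    min_het_depth: int = 4
    hom_qual: float = 50.0
    hom_depth: int = 4
    indel_pad: int = 3
    ab_percentile: float = 10.0
    het_mask_min_reads: int = 3
    max_missing_frac: float = 0.10
    maxdepth_qual_mult: float = 2.0
    maxdepth_sd_mult: float = 3.0

    def __post_init__(self):
        numeric = [self.min_strand_obs, self.min_qual, self.min_het_depth, self.hom_qual,
                   self.hom_depth, self.indel_pad, self.het_mask_min_reads,
                   self.max_missing_frac, self.maxdepth_qual_mult, self.maxdepth_sd_mult]
        if any(v < 0 for v in numeric):
            raise ValueError("all thresholds must be non-negative")
        if not 0 < self.ab_percentile < 100:
            raise ValueError("ab_percentile must be in (0, 100)")


@dataclass
class FilterAudit:
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULES})
    masked_genotypes: dict[str, int] = field(default_factory=lambda: {"genotype_depth": 0, "het_ad_mask": 0})
    survivors: int = 0
    n_input: int = 0
    avg_depth: float = float("nan")
    ab_threshold: float = float("nan")

    def check(self) -> None:
        if self.survivors + sum(self.removed.values()) != self.n_input:
            raise AssertionError("audit does not account for every input site")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "masked_genotypes": dict(self.masked_genotypes),
            "survivors": self.survivors,
            "avg_depth": self.avg_depth,
            "ab_threshold": self.ab_threshold,
        }


def _site_allele_balance(cohort: CohortVariantSet) -> np.ndarray:
    """Mean het-genotype alt fraction per site; NaN where no het genotype has reads."""
    het = cohort.gt == HET
    tot = cohort.ad_ref + cohort.ad_alt
    ok = het & (tot > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(ok, cohort.ad_alt / np.maximum(tot, 1), np.nan)
    counts = ok.sum(axis=1)
    sums = np.nansum(np.where(ok, frac, 0.0), axis=1)
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _fixed_sites(cohort: CohortVariantSet) -> np.ndarray:
    """Sites where only one allele is present among non-missing genotypes."""
    called = cohort.gt != MISSING
    has_ref = ((cohort.gt == HOM_REF) | (cohort.gt == HET)) & called
    has_alt = ((cohort.gt == HOM_ALT) | (cohort.gt == HET)) & called
    return ~(has_ref.any(axis=1) & has_alt.any(axis=1))


def filter_cohort(
    cohort: CohortVariantSet,
    cfg: FilterConfig | None = None,
    avg_depth: float | None = None,
    ab_threshold: float | None = None,
) -> tuple[CohortVariantSet, FilterAudit]:
    """Apply the filter cascade; returns (filtered cohort, audit).

    ``avg_depth`` (cohort mean of site DP over all input sites) and
    ``ab_threshold`` (the allele-balance percentile cut) are computed from
    the input cohort when not supplied; pass the values recorded in a
    previous audit to re-filter idempotently.
    """
    cfg = cfg or FilterConfig()
    audit = FilterAudit(n_input=cohort.n_sites)
    if cohort.n_sites == 0:
        return cohort, audit

    gt = cohort.gt.copy()
    dp = cohort.dp
    S = cohort.n_sites

    # cohort constants, fixed before any rule runs; average depth is on the
    # per-genotype scale (the max-depth cap is compared to single-sample DP)
    if avg_depth is None:
        avg_depth = float(dp.mean())
    audit.avg_depth = avg_depth

    ab = _site_allele_balance(cohort)
    fixed = _fixed_sites(cohort)
    if ab_threshold is None:
        pool = ab[~fixed & np.isfinite(ab)]
        ab_threshold = float(np.percentile(pool, cfg.ab_percentile)) if pool.size else float("nan")
    audit.ab_threshold = ab_threshold

    alive = np.ones(S, dtype=bool)

    def drop(rule: str, mask: np.ndarray) -> None:
        hit = alive & mask
        audit.removed[rule] += int(hit.sum())
        alive[hit] = False

    # (1) strand support
    drop("strand_support", (cohort.saf < cfg.min_strand_obs) | (cohort.sar < cfg.min_strand_obs))

    # (2) site quality
    drop("site_quality", cohort.qual < cfg.min_qual)

    # (3) per-genotype depth support; site removed if no alt-carrying genotype remains
    het_low = (gt == HET) & (dp < cfg.min_het_depth)
    hom_low = ((gt == HOM_REF) | (gt == HOM_ALT)) & (dp < cfg.hom_depth)
    hom_low &= (cohort.qual < cfg.hom_qual)[:, None]
    to_mask = (het_low | hom_low) & alive[:, None]
    audit.masked_genotypes["genotype_depth"] += int(to_mask.sum())
    gt[to_mask] = MISSING
    supported = ((gt == HET) | (gt == HOM_ALT)).any(axis=1)
    drop("genotype_depth", ~supported)

    # (4) max-depth rule for sites with het genotypes
    has_het = (gt == HET).any(axis=1)
    cap = avg_depth + cfg.maxdepth_sd_mult * np.sqrt(avg_depth)
    drop(
        "max_depth",
        has_het
        & (cohort.qual < cfg.maxdepth_qual_mult * avg_depth)
        & (dp.max(axis=1) > cap),
    )

    # (5) indels, and SNPs within indel_pad bp of any input indel (same chromosome)
    near_indel = np.zeros(S, dtype=bool)
    indel_idx = np.flatnonzero(~cohort.is_snp)
    for i in indel_idx:
        same = (cohort.chrom == cohort.chrom[i]) & (np.abs(cohort.pos - cohort.pos[i]) <= cfg.indel_pad)
        near_indel |= same
    drop("indel_proximity", ~cohort.is_snp | near_indel)

    # (6) allele balance: non-fixed sites below the cohort percentile
    if np.isfinite(ab_threshold):
        drop("allele_balance", ~fixed & np.isfinite(ab) & (ab < ab_threshold))

    # (7) mask het genotypes with < 3 reads supporting either allele
    weak_het = (gt == HET) & (np.minimum(cohort.ad_ref, cohort.ad_alt) < cfg.het_mask_min_reads)
    weak_het &= alive[:, None]
    audit.masked_genotypes["het_ad_mask"] += int(weak_het.sum())
    gt[weak_het] = MISSING

    # (8) missingness ceiling (after masking)
    miss_frac = (gt == MISSING).sum(axis=1) / cohort.n_samples
    drop("missingness", miss_frac > cfg.max_missing_frac)

    audit.survivors = int(alive.sum())
    audit.check()

    out = cohort.subset_sites(alive)
    out.gt = gt[alive]
    if cohort.hap is not None:
        hap = cohort.hap[alive].copy()
        masked = out.gt == MISSING
        hap[:, 0::2][masked] = MISSING
        hap[:, 1::2][masked] = MISSING
        out.hap = hap
    return out, audit
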