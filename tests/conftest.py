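"""Shared fixtures: one chromosome-scale simulated cohort and one
sequence-scale cohort, built once per session (everything downstream is
deterministic given the seeds fixed here)."""

import numpy as np
import pytest

from ylinkkit import simpop
from ylinkkit.core import CohortVariantSet, SexLabels


@pytest.fixture(scope="session")
def sim_bundle():
    """Default-condition simulated cohort on the chromosome-scale layout."""
    pop = simpop.simulate_wf(simpop.WFConfig(seed=1))
    layout = simpop.default_layout()
    cohort, truth = simpop.overlay_layout(pop, layout, seed=2)
    return {
        "pop": pop,
        "layout": layout,
        "cohort": cohort,
        "truth": truth,
        "labels": simpop.sex_labels(pop),
        "populations": simpop.split_populations(pop),
    }


@pytest.fixture(scope="session")
def seq_bundle():
    """Small-layout cohort with per-individual sequences and a planted Y insertion.

    One Y lineage, so every planted insertion k-mer is carried by all males.
    """
    layout = simpop.small_layout()
    wf = simpop.WFConfig(
        pop_size=60,
        burn_in_generations=300,
        sample_males=8,
        sample_females=8,
        mu_per_locus={"A": 0.002, "X": 0.002, "Y": 0.002},
        n_loci={"A": 60, "X": 60, "Y": 60},
        n_y_lineages=1,
        seed=11,
    )
    pop = simpop.simulate_wf(wf)
    cohort, truth = simpop.overlay_layout(pop, layout, seed=12)
    reference, seqs, manifest = simpop.synth_sequences(
        cohort, pop, layout, truth["lineage_of"], y_insertion_length=200, seed=13
    )
    tables = simpop.kmer_tables_with_coverage(seqs, seed=14)
    return {
        "pop": pop,
        "layout": layout,
        "cohort": cohort,
        "truth": truth,
        "reference": reference,
        "sequences": seqs,
        "manifest": manifest,
        "tables": tables,
        "sex_of": dict(pop.individuals),
    }


def make_cohort(gt, qual=None, saf=None, sar=None, dp=None, ad_alt=None,
                chrom=None, pos=None, is_snp=None, hap=None):
    """Hand-built cohort from a genotype matrix; generous defaults pass every filter."""
    gt = np.asarray(gt, dtype=np.int8)
    S, n = gt.shape
    samples = [f"S{i:02d}" for i in range(n)]
    if dp is None:
        dp = np.full((S, n), 30, dtype=np.int32)
    dp = np.asarray(dp, dtype=np.int32)
    if ad_alt is None:
        ad_alt = np.where(gt == 1, dp // 2, np.where(gt == 2, dp, 0)).astype(np.int32)
    ad_alt = np.asarray(ad_alt, dtype=np.int32)
    if hap is None:
        hap = np.full((S, 2 * n), -1, dtype=np.int8)
        hap[:, 0::2] = np.where(gt == 2, 1, np.where(gt == 1, 0, np.where(gt == 0, 0, -1)))
        hap[:, 1::2] = np.where(gt == 2, 1, np.where(gt == 1, 1, np.where(gt == 0, 0, -1)))
    return CohortVariantSet(
        chrom=np.array(chrom if chrom is not None else ["chr1"] * S, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, S + 1) * 100, dtype=np.int64),
        ref=np.array(["A"] * S, dtype=object),
        alt=np.array(["G"] * S, dtype=object),
        qual=np.array(qual if qual is not None else [100.0] * S, dtype=float),
        is_snp=np.array(is_snp if is_snp is not None else [True] * S, dtype=bool),
        saf=np.array(saf if saf is not None else [10] * S, dtype=np.int64),
        sar=np.array(sar if sar is not None else [10] * S, dtype=np.int64),
        samples=samples,
        gt=gt,
        dp=dp,
        ad_ref=(dp - ad_alt).astype(np.int32),
        ad_alt=ad_alt,
        hap=np.asarray(hap, dtype=np.int8),
    )


def sexes_for(n_males, n_females):
    names = [f"S{i:02d}" for i in range(n_males + n_females)]
    return SexLabels({s: ("M" if i < n_males else "F") for i, s in enumerate(names)})
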