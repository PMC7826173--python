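"""End-to-end orchestration of the analysis stages.

A single :class:`RunConfig` drives either a fully simulated run (the
default: the Wright-Fisher simulator synthesizes every input) or a run on
user files (VCF + sex TSV, optional depth/molecule tables).  Stages execute
in dependency order — simulate -> variant filtering -> coverage scan ->
F_ST/diversity -> male-linked SNPs -> gene trees -> Y-mers -> barcode scan
— and the consolidated JSON summary carries the per-stage headline numbers
together with seeds and filter audits.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import bxscan, covwin, divstats, io, sexsnp, simpop, treescan, ymer
from .core import SexLabels
from .vcfguard import FilterConfig, filter_cohort


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str = "ylinkkit_run"
    seed: int = 0
    # simulated-mode parameters
    simulate: bool = True
    pop_size: int = 200
    sample_males: int = 20
    sample_females: int = 20
    n_y_lineages: int = 3
    # file-mode inputs
    vcf: str | None = None
    sex_tsv: str | None = None
    chrom_sizes: dict[str, int] | None = None
    # stage toggles
    stages: list[str] = field(
        default_factory=lambda: [
            "filter", "coverage", "fst", "sexsnp", "trees", "ymer", "bxscan",
        ]
    )
    # analysis thresholds (paper defaults)
    window_bp: int = 50_000
    snp_window: int = 100
    kmer_k: int = 21
    null_iterations: int = 10_000
    autosomal_baseline_windows: int = 1000
    presence_floor: int = 3
    min_mean_count: float = 5.0
    min_carriers: int = 6
    scaffold_min_ymers: int = 100

    def validate(self) -> None:
        if not self.simulate:
            for path in (self.vcf, self.sex_tsv):
                if path is None or not os.path.exists(path):
                    raise FileNotFoundError(f"input file missing: {path}")


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the summary dict."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    rng_seed = config.seed

    def stage(name):
        return name in config.stages

    try:
        if config.simulate:
            layout = simpop.default_layout()
            wf = simpop.WFConfig(
                pop_size=config.pop_size,
                sample_males=config.sample_males,
                sample_females=config.sample_females,
                n_y_lineages=config.n_y_lineages,
                seed=rng_seed,
            )
            pop = simpop.simulate_wf(wf)
            cohort, truth = simpop.overlay_layout(pop, layout, seed=rng_seed + 1)
            labels = simpop.sex_labels(pop)
            populations = simpop.split_populations(pop)
            chrom_sizes = layout.chrom_lengths
            summary["stages"]["simulate"] = {
                "n_sites": cohort.n_sites,
                "n_samples": cohort.n_samples,
                "n_male_limited_truth": len(truth["male_limited_positions"]),
                "theta_ratios": pop.theta_ratios(),
            }
        else:
            layout = None
            cohort = io.read_vcf(config.vcf)
            labels = io.read_sex_tsv(config.sex_tsv)
            populations = {s: "pop" for s in cohort.samples}
            chrom_sizes = config.chrom_sizes or {
                c: int(cohort.pos[cohort.chrom == c].max()) for c in set(cohort.chrom.tolist())
            }
            pop = truth = None
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate" if config.simulate else "load", e)

    grid = covwin.WindowGrid.tile(chrom_sizes, config.window_bp)

    if stage("filter"):
        try:
            cohort, audit = filter_cohort(cohort, FilterConfig())
            summary["stages"]["filter"] = audit.to_dict()
        except Exception as e:  # noqa: BLE001
            raise StageError("filter", e)

    if stage("coverage") and config.simulate:
        try:
            depth = simpop.synth_depth(layout, pop.individuals, seed=rng_seed + 2)
            table = covwin.coverage_from_windowed(depth, layout.grid())
            norm = covwin.normalize_coverage(table)
            ratio = covwin.mf_ratio(norm, labels)
            ratio.to_csv(os.path.join(config.out_dir, "mf_ratio.tsv"), sep="\t", index=False)
            degen = ratio[
                (ratio["chrom"] == layout.sex_chrom)
                & ratio.apply(
                    lambda r: any(
                        r["start"] < e and r["end"] > s
                        for s, e in layout.degenerate_subintervals
                    ),
                    axis=1,
                )
            ]
            summary["stages"]["coverage"] = {
                "mean_mf_ratio_degenerate": float(degen["ratio"].mean()),
                "mean_mf_ratio_elsewhere": float(
                    ratio.loc[~ratio.index.isin(degen.index), "ratio"].mean()
                ),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("coverage", e)

    if stage("fst"):
        try:
            fst = divstats.fst_windows(cohort, labels, grid)
            fst.to_csv(os.path.join(config.out_dir, "fst.tsv"), sep="\t", index=False)
            sexchrom = layout.sex_chrom if config.simulate else None
            auto = fst[fst["chrom"] != sexchrom]["fst"].dropna()
            ci = divstats.bootstrap_autosomal_ci(auto, seed=rng_seed + 3) if len(auto) else None
            summary["stages"]["fst"] = {
                "mean_autosomal": float(auto.mean()) if len(auto) else None,
                "ci95": [ci.lo, ci.hi] if ci else None,
                "n_windows": int(len(fst)),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("fst", e)

    if stage("sexsnp"):
        try:
            catalog = sexsnp.classify_tiers(cohort, labels)
            catalog.to_csv(os.path.join(config.out_dir, "sexsnp_catalog.tsv"), sep="\t", index=False)
            null = sexsnp.permutation_null(
                cohort, labels, chrom_sizes, tier="ge66",
                n_iter=config.null_iterations, seed=rng_seed + 4,
            )
            enr = None
            if config.simulate:
                chr12 = cohort.chrom == layout.sex_chrom
                enr = sexsnp.stratum_enrichment(
                    catalog,
                    (layout.sex_chrom, *layout.stratum1),
                    layout.chrom_lengths[layout.sex_chrom],
                    all_snp_positions=cohort.pos[chr12],
                )
            summary["stages"]["sexsnp"] = {
                "n_male_linked": int((catalog["tier"] != "none").sum()),
                "n_fully_linked": int((catalog["tier"] == "full").sum()),
                "flagged_chromosomes": null.flagged,
                "stratum_enrichment": {k: v for k, v in (enr or {}).items()},
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("sexsnp", e)

    if stage("trees"):
        try:
            sexchrom = layout.sex_chrom if config.simulate else sorted(set(cohort.chrom))[0]
            wins = treescan.snp_windows(cohort, labels, populations,
                                        chrom=sexchrom, window_size=config.snp_window)
            calls = []
            for aln in wins:
                d = treescan.distance_matrix(aln, model="JC69")
                tree = treescan.nj_tree(d, [l.name for l in aln.leaves], method="BIONJ")
                calls.append(treescan.call_xy_topology(tree, aln))
            n_xy = sum(c.any_xy for c in calls)
            shared = treescan.shared_y(calls)
            summary["stages"]["trees"] = {
                "n_windows": len(calls),
                "n_xy": n_xy,
                "n_shared": len(shared),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("trees", e)

    if stage("ymer") and config.simulate:
        try:
            sl = simpop.small_layout()
            wf_small = simpop.WFConfig(
                pop_size=60, burn_in_generations=300, sample_males=8, sample_females=8,
                mu_per_locus={"A": 0.002, "X": 0.002, "Y": 0.002},
                n_loci={"A": 60, "X": 60, "Y": 60},
                n_y_lineages=2, seed=rng_seed + 5,
            )
            pop_s = simpop.simulate_wf(wf_small)
            cohort_s, truth_s = simpop.overlay_layout(pop_s, sl, seed=rng_seed + 6)
            _, seqs, manifest = simpop.synth_sequences(
                cohort_s, pop_s, sl, truth_s["lineage_of"], seed=rng_seed + 7, k=config.kmer_k
            )
            tables = simpop.kmer_tables_with_coverage(seqs, k=config.kmer_k, seed=rng_seed + 8)
            sex_of = dict(pop_s.individuals)
            ymers = ymer.find_sex_specific(
                tables, sex_of, "male",
                presence_floor=config.presence_floor,
                min_carriers=min(config.min_carriers, wf_small.sample_males),
                min_mean=config.min_mean_count,
            )
            min_carriers = min(config.min_carriers, wf_small.sample_males)
            lineage_sizes: dict[str, int] = {}
            for lin in truth_s["lineage_of"].values():
                lineage_sizes[str(lin)] = lineage_sizes.get(str(lin), 0) + 1
            carriers: dict[str, int] = {}
            for lin, kms in manifest["planted_kmers_per_lineage"].items():
                for km in kms:
                    carriers[km] = carriers.get(km, 0) + lineage_sizes.get(lin, 0)
            recoverable = {km for km, c in carriers.items() if c >= min_carriers}
            found = set(ymers.as_strings())
            summary["stages"]["ymer"] = {
                "n_ymers": len(ymers),
                "n_planted": len(carriers),
                "n_recoverable": len(recoverable),
                "planted_recovered_frac": (
                    len(recoverable & found) / len(recoverable) if recoverable else None
                ),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("ymer", e)

    if stage("bxscan") and config.simulate:
        try:
            ml = simpop.molecule_layout()
            mols = simpop.synth_molecules(pop, ml, n_per_individual=800, seed=rng_seed + 9)
            mgrid = ml.grid()
            mats = [
                bxscan.link_matrix(mols, mgrid, individual=name)
                for name, _ in pop.individuals
            ]
            calls = bxscan.sex_differential_links(mats, labels)
            summary["stages"]["bxscan"] = {"n_calls": int(len(calls))}
        except Exception as e:  # noqa: BLE001
            raise StageError("bxscan", e)

    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
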