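"""Y-mer mining: male-specific canonical 21-mers with a female-specific control.

A Y-mer is a canonical 21-mer present (>= 3 observations, the error floor)
in males and absent from every female, with mean count above 5 across
males. Female-specific k-mers should not exist in an XY system, so their
count calibrates the false-positive rate of the thresholds.
"""

from ylinkkit import simpop, ymer

layout = simpop.small_layout()
wf = simpop.WFConfig(pop_size=60, burn_in_generations=300, sample_males=8,
                     sample_females=8, mu_per_locus={"A": 0.002, "X": 0.002, "Y": 0.002},
                     n_loci={"A": 60, "X": 60, "Y": 60}, n_y_lineages=1, seed=11)
pop = simpop.simulate_wf(wf)
cohort, truth = simpop.overlay_layout(pop, layout, seed=12)
reference, seqs, manifest = simpop.synth_sequences(
    cohort, pop, layout, truth["lineage_of"], y_insertion_length=200, seed=13
)
tables = simpop.kmer_tables_with_coverage(seqs, mean_coverage=30, seed=14)
sex_of = dict(pop.individuals)

chosen, curve = ymer.calibrate_fpr(tables, sex_of, carrier_thresholds=[1, 2, 4, 6, 8])
print("carrier threshold sweep (threshold, male-specific, female-specific, FPR):")
for row in curve:
    print(f"  {row[0]}: {row[1]:5d} male, {row[2]:4d} female, FPR = {row[3]:.3f}")
print(f"smallest threshold with FPR < 5%: {chosen}")

ymers = ymer.find_sex_specific(tables, sex_of, "male", min_carriers=6)
planted = {km for kms in manifest["planted_kmers_per_lineage"].values() for km in kms}
found = set(ymers.as_strings())
print(f"\nY-mers at >= 6 male carriers: {len(ymers)}")
print(f"planted insertion k-mers recovered: {len(planted & found)}/{len(planted)}")

scaffolds = {"male_y_hap": seqs[pop.males[0]][f"{pop.males[0]}_{layout.sex_chrom}_h2"],
             "male_x_hap": seqs[pop.males[0]][f"{pop.males[0]}_{layout.sex_chrom}_h1"]}
hits = ymer.map_to_scaffolds(ymers, scaffolds, min_ymers=100,
                             homolog_of={"male_y_hap": "male_x_hap"})
print(f"scaffold Y-mer hits: {hits.counts}, enriched: {hits.enriched}")
print("The Y haplotype scaffold carries the insertion plus Y-linked SNP "
      "k-mers; its X homolog carries almost none.")
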