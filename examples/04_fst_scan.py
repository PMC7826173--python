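"""Male-female Hudson F_ST in 50-kb windows with an autosomal bootstrap band.

Male-limited Y alleles raise allele-frequency differences between the
sexes, so windows in the sex-linked region stand out above the band formed
by bootstrapping autosomal window values.
"""

from ylinkkit import divstats, simpop
from ylinkkit.covwin import WindowGrid

layout = simpop.default_layout()
pop = simpop.simulate_wf(simpop.WFConfig(seed=4))
cohort, _ = simpop.overlay_layout(pop, layout, seed=5)
labels = simpop.sex_labels(pop)

grid = WindowGrid.tile(layout.chrom_lengths, 50_000)
fst = divstats.fst_windows(cohort, labels, grid)

auto = fst[fst["chrom"] != layout.sex_chrom]["fst"].dropna()
ci = divstats.bootstrap_autosomal_ci(auto, n_boot=1000, seed=6)
print(f"autosomal windows: {len(auto)}, mean F_ST = {auto.mean():.4f}, "
      f"95% bootstrap band of the mean = [{ci.lo:.4f}, {ci.hi:.4f}]")

sex = fst[fst["chrom"] == layout.sex_chrom].dropna()
s1 = layout.stratum1
in_s1 = sex[(sex["start"] >= s1[0]) & (sex["start"] < s1[1])]
print(f"sex chromosome stratum I: mean F_ST = {in_s1['fst'].mean():.3f} over "
      f"{len(in_s1)} windows — far above the autosomal band")
h, p = divstats.kruskal_wallis(in_s1["fst"], auto)
print(f"Kruskal-Wallis stratum I vs autosomes: H = {h:.1f}, p = {p:.2e}")
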