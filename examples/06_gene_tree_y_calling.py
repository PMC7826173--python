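"""Window gene trees, Y-monophyly calls, clade diversity and a haplotype network.

Phased haplotypes are cut into 100-SNP windows; a BIONJ tree is built per
window and a window supports an XY system when some side of the unrooted
tree contains only male haplotypes covering >2/3 of a population's males.
The Y side's Watterson theta is compared with its X complement and an
autosomal baseline, and the distinct Y sequences form an MST network.
"""

import numpy as np

from ylinkkit import simpop, treescan

layout = simpop.default_layout()
pop = simpop.simulate_wf(simpop.WFConfig(seed=8))
cohort, truth = simpop.overlay_layout(pop, layout, seed=9)
labels = simpop.sex_labels(pop)
populations = simpop.split_populations(pop)

wins = treescan.snp_windows(cohort, labels, populations, chrom=layout.sex_chrom)
calls = []
for aln in wins:
    d = treescan.distance_matrix(aln, model="JC69")
    tree = treescan.nj_tree(d, [l.name for l in aln.leaves], method="BIONJ")
    calls.append((aln, treescan.call_xy_topology(tree, aln)))

s1 = layout.stratum1
in_s1 = [(a, c) for a, c in calls if s1[0] <= a.start - 1 < s1[1]]
xy = [(a, c) for a, c in in_s1 if c.any_xy]
shared = [c for _, c in in_s1 if c.shared]
print(f"stratum I: {len(xy)}/{len(in_s1)} windows called XY, {len(shared)} with "
      "Y haplotypes shared between the two populations")

def n_distinct_y(aln, call):
    names = [l.name for l in aln.leaves]
    rows = [names.index(x) for x in call.y_leaves]
    return len(np.unique(aln.codes[rows], axis=0))

aln, call = max(xy, key=lambda t: n_distinct_y(*t))
ty, tx = treescan.clade_theta(aln, call.y_leaves)
auto_wins = treescan.snp_windows(cohort, labels, populations, chrom="chr1")
ta = treescan.autosomal_baseline_theta(auto_wins, labels, n_windows=200, seed=10)
print(f"most Y-diverse XY window {aln.chrom}:{aln.start}-{aln.end}: "
      f"theta_Y = {ty.theta_per_site:.2e}, theta_X = {tx.theta_per_site:.2e}, "
      f"autosomal baseline = {ta:.2e}")

names = [l.name for l in aln.leaves]
rows = [names.index(x) for x in sorted(call.y_leaves)]
pops = [aln.leaves[r].population for r in rows]
net = treescan.build_network(aln.codes[rows], pops)
print(f"Y haplotype network: {len(net.sequences)} distinct haplotypes, "
      f"MST edges {net.edges}")
for p in sorted(set(pops)):
    print(f"  mean mutational steps within {p}: {net.mean_steps_within(p)}")
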