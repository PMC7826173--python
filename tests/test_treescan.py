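"""Gene-tree machinery: distances, NJ/BIONJ, topology calls, networks.

Oracles: scikit-bio's neighbor joining for topology agreement, a numerical
maximum-likelihood optimizer over the F84 generator for the F84 distance,
edge-removal connected components for bipartitions, and exhaustive
spanning-tree enumeration for the MST network.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from ylinkkit import treescan
from ylinkkit.treescan import HaplotypeAlignment, Leaf


def make_aln(codes, sexes, pops=None, haps=None):
    codes = np.asarray(codes, dtype=np.int8)
    n = codes.shape[0]
    pops = pops or ["p1"] * n
    names = []
    leaves = []
    count = {}
    for i in range(n):
        ind = f"i{i // 2}" if haps is None else haps[i][0]
        h = (i % 2) + 1 if haps is None else haps[i][1]
        name = f"{ind}|{h}"
        leaves.append(Leaf(name, ind, h, sexes[i], pops[i]))
        names.append(name)
    return HaplotypeAlignment(
        chrom="c", start=1, end=codes.shape[1], positions=np.arange(1, codes.shape[1] + 1),
        leaves=leaves, codes=codes,
    )


class TestDistances:
    def test_identical_sequences_zero(self):
        codes = np.zeros((4, 50), dtype=np.int8)
        aln = make_aln(codes, ["M"] * 4)
        for model in ("p", "JC69", "F84"):
            d = treescan.distance_matrix(aln, model)
            np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_one_mismatch_in_hundred(self):
        codes = np.zeros((2, 100), dtype=np.int8)
        codes[1, 0] = 2  # A->G transition
        aln = make_aln(codes, ["M", "M"])
        p = treescan.distance_matrix(aln, "p")[0, 1]
        jc = treescan.distance_matrix(aln, "JC69")[0, 1]
        assert p == pytest.approx(0.01)
        assert jc == pytest.approx(-0.75 * np.log(1 - 4 * 0.01 / 3), rel=1e-9)  # 0.010067

    def test_jc_saturation_capped(self):
        codes = np.zeros((2, 4), dtype=np.int8)
        codes[1] = 1  # every site differs: p = 1 >= 3/4
        aln = make_aln(codes, ["M", "M"])
        assert treescan.distance_matrix(aln, "JC69")[0, 1] == treescan.SATURATION_CAP

    def test_pairwise_deletion(self):
        codes = np.zeros((2, 10), dtype=np.int8)
        codes[1, 0] = 1
        codes[0, 5:] = -1  # half the columns unusable
        aln = make_aln(codes, ["M", "M"])
        assert treescan.distance_matrix(aln, "p")[0, 1] == pytest.approx(1 / 5)

    def test_f84_equal_frequencies_matches_k80_closed_form(self):
        # with equal base frequencies F84 reduces to K80, whose two-sequence
        # ML distance is -0.5 ln(1-2P-Q) - 0.25 ln(1-2Q)
        P, Q = 0.06, 0.04
        d = treescan.f84_distance(np.array(P), np.array(Q), np.full(4, 0.25))
        k80 = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
        assert float(d) == pytest.approx(k80, rel=1e-9)

    def test_f84_against_ml_optimization_oracle(self):
        # maximize the F84 likelihood over (t, kappa) for a two-sequence
        # site-pattern table and compare with the closed-form inversion
        from scipy.linalg import expm
        from scipy.optimize import minimize

        freqs = np.full(4, 0.25)
        n_sites, n_ts, n_tv = 1000, 60, 40

        def generator(kappa):
            # F84 rates: transversion beta*pi_j; transition beta*pi_j*(1 + kappa/pi_class)
            piA, piC, piG, piT = freqs
            piR, piY = piA + piG, piC + piT
            Q = np.zeros((4, 4))
            purine = {0: True, 1: False, 2: True, 3: False}
            for i in range(4):
                for j in range(4):
                    if i == j:
                        continue
                    rate = freqs[j]
                    if purine[i] == purine[j]:
                        rate *= 1 + kappa / (piR if purine[i] else piY)
                    Q[i, j] = rate
                Q[i, i] = -Q[i].sum()
            scale = -np.dot(freqs, np.diag(Q))
            return Q / scale

        # site-pattern counts: same / transition (A<->G) / transversion (A<->C)
        def negloglik(params):
            t, kappa = params
            if t <= 0 or kappa < 0:
                return 1e9
            P = expm(generator(kappa) * t)
            return -(
                (n_sites - n_ts - n_tv) * np.log(P[0, 0])
                + n_ts * np.log(P[0, 2])
                + n_tv * np.log(P[0, 1])
            )

        res = minimize(negloglik, x0=[0.1, 1.0], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10})
        t_ml = res.x[0]
        closed = float(
            treescan.f84_distance(np.array(n_ts / n_sites), np.array(n_tv / n_sites), freqs)
        )
        assert closed == pytest.approx(t_ml, rel=1e-3)


def bipartitions_by_edge_removal(tree):
    """Independent oracle: cut each edge, take connected components."""
    out = set()
    leaves = set(tree.leaf_names)
    for u, v in list(tree.graph.edges()):
        g = tree.graph.copy()
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        out.add(frozenset(comp & leaves))
    return out


class TestNeighborJoining:
    def test_three_taxon_exact_branch_lengths(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = treescan.nj_tree(D, ["A", "B", "C"])
        hub = next(n for n in tree.graph.nodes if n not in ("A", "B", "C"))
        assert tree.branch_length("A", hub) == pytest.approx(1.0)
        assert tree.branch_length("B", hub) == pytest.approx(1.0)
        assert tree.branch_length("C", hub) == pytest.approx(3.0)

    def test_two_taxa_single_edge(self):
        tree = treescan.nj_tree(np.array([[0.0, 0.7], [0.7, 0.0]]), ["A", "B"])
        assert tree.branch_length("A", "B") == pytest.approx(0.7)

    @pytest.mark.parametrize("method", ["NJ", "BIONJ"])
    def test_additive_four_taxon_topology_recovered(self, method):
        # tree ((A:1,B:2):1,(C:3,D:4)); additive distances
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = treescan.nj_tree(D, ["A", "B", "C", "D"], method=method)
        splits = bipartitions_by_edge_removal(tree)
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits
        # and the wrong pairings are absent
        assert frozenset({"A", "C"}) not in splits
        assert frozenset({"A", "D"}) not in splits

    def test_matches_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(12)
        for _ in range(5):
            n = 8
            pts = rng.normal(size=(n, 4))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            names = [f"t{i}" for i in range(n)]
            mine = treescan.nj_tree(D, names, method="NJ")
            theirs = skbio_nj(DistanceMatrix(D, ids=names))
            their_splits = set()
            for node in theirs.non_tips(include_self=False):
                tips = frozenset(t.name for t in node.tips())
                their_splits.add(min(tips, frozenset(names) - tips, key=sorted))
            my_splits = {
                min(s, frozenset(names) - s, key=sorted)
                for s in bipartitions_by_edge_removal(mine)
                if 2 <= len(s) <= n - 2
            }
            their_splits = {s for s in their_splits if 2 <= len(s) <= n - 2}
            assert my_splits == their_splits

    def test_bipartitions_agree_with_edge_removal_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = rng.normal(size=(8, 3))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            names = [f"t{i}" for i in range(8)]
            tree = treescan.nj_tree(D, names, method="BIONJ")
            mine = set()
            for a, b in tree.bipartitions():
                mine.add(a)
                mine.add(b)
            assert mine == bipartitions_by_edge_removal(tree) | {
                frozenset(names) - s for s in bipartitions_by_edge_removal(tree)
            }

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            treescan.nj_tree(np.zeros((2, 2)), ["A", "B"], method="UPGMA")


class TestSnpWindows:
    def test_window_counts(self, sim_bundle):
        cohort = sim_bundle["cohort"]
        wins = treescan.snp_windows(
            cohort, sim_bundle["labels"], sim_bundle["populations"], chrom="chr1", window_size=100
        )
        n_chr1 = int((cohort.chrom == "chr1").sum())
        assert len(wins) == n_chr1 // 100
        assert all(w.codes.shape == (2 * cohort.n_samples, 100) for w in wins)

    def test_too_few_snps_no_window(self, sim_bundle):
        cohort = sim_bundle["cohort"].subset_sites(np.arange(99))
        wins = treescan.snp_windows(cohort, sim_bundle["labels"], sim_bundle["populations"],
                                    window_size=100)
        assert wins == []


class TestTopologyCalls:
    def build(self, n_males=6, n_females=6, y_snps=12, noise_snps=30, seed=0, two_pops=True):
        """Alignment with complete lineage sorting: male hap2 carries Y alleles."""
        rng = np.random.default_rng(seed)
        inds = [(f"M{i}", "M") for i in range(n_males)] + [(f"F{i}", "F") for i in range(n_females)]
        n_leaves = 2 * len(inds)
        codes = rng.integers(0, 2, (n_leaves, noise_snps)).astype(np.int8)
        y_cols = np.zeros((n_leaves, y_snps), dtype=np.int8)
        for k, (name, sex) in enumerate(inds):
            if sex == "M":
                y_cols[2 * k + 1, :] = 1  # hap2 of every male carries the Y allele
        codes = np.concatenate([y_cols, codes], axis=1)
        sexes = [s for _, s in inds for _ in (1, 2)]
        pops = None
        if two_pops:
            pops = []
            for k, (name, _) in enumerate(inds):
                pops += [f"p{k % 2 + 1}"] * 2
        haps = [(name, h) for name, _ in inds for h in (1, 2)]
        return make_aln(codes, sexes, pops=pops, haps=haps)

    def call(self, aln, method="BIONJ"):
        d = treescan.distance_matrix(aln, "p")
        tree = treescan.nj_tree(d, [l.name for l in aln.leaves], method)
        return treescan.call_xy_topology(tree, aln)

    def test_complete_lineage_sorting_called_xy(self):
        call = self.call(self.build())
        assert call.any_xy and call.all_xy
        assert call.shared  # both pseudo-populations contribute Y haplotypes
        assert all(c.fraction == 1.0 for c in call.per_population.values())
        assert all(name.endswith("|2") and name.startswith("M") for name in call.y_leaves)

    def test_female_in_clade_disqualifies(self):
        aln = self.build()
        # give one female hap the full Y allele complement
        f_idx = next(i for i, l in enumerate(aln.leaves) if l.sex == "F")
        aln.codes[f_idx, :12] = 1  # she joins the Y cluster and breaks male-exclusivity
        call = self.call(aln)
        assert not call.any_xy

    def test_calls_invariant_to_leaf_order(self):
        aln = self.build(seed=3)
        call1 = self.call(aln)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(aln.leaves))
        aln2 = HaplotypeAlignment(
            chrom=aln.chrom, start=aln.start, end=aln.end, positions=aln.positions,
            leaves=[aln.leaves[i] for i in perm], codes=aln.codes[perm],
        )
        call2 = self.call(aln2)
        assert call1.y_leaves == call2.y_leaves
        for pop in call1.per_population:
            assert call1.per_population[pop].is_xy == call2.per_population[pop].is_xy
            assert call1.per_population[pop].fraction == call2.per_population[pop].fraction

    def test_shared_requires_both_populations(self):
        # Y alleles only in population p1's males
        aln = self.build(two_pops=False)
        # assign pops: all males p1, all females p2... instead: both pops exist,
        # but only p1 males carry Y alleles
        for k, leaf in enumerate(aln.leaves):
            leaf.population = "p1" if leaf.sex == "M" else "p2"
        call = self.call(aln)
        assert call.per_population["p1"].is_xy
        assert not call.shared  # Y clade holds only p1 haplotypes

    def test_call_agrees_with_bruteforce_side_enumeration(self):
        """Re-derive the XY decision from the oracle bipartition set."""
        for seed in range(4):
            aln = self.build(seed=seed, y_snps=1, noise_snps=25, n_males=4, n_females=4)
            d = treescan.distance_matrix(aln, "p")
            tree = treescan.nj_tree(d, [l.name for l in aln.leaves], "BIONJ")
            call = treescan.call_xy_topology(tree, aln)
            all_names = frozenset(l.name for l in aln.leaves)
            sides = bipartitions_by_edge_removal(tree)
            sides |= {all_names - s for s in list(sides)}
            meta = {l.name: l for l in aln.leaves}
            pops = sorted({l.population for l in aln.leaves})
            expected = {p: False for p in pops}
            for side in sides:
                if not 2 <= len(side) < len(aln.leaves):
                    continue
                if any(meta[x].sex == "F" for x in side):
                    continue
                for p in pops:
                    males = {l.individual for l in aln.leaves if l.sex == "M" and l.population == p}
                    cnt = {}
                    for x in side:
                        if meta[x].population == p:
                            cnt[meta[x].individual] = cnt.get(meta[x].individual, 0) + 1
                    frac = sum(1 for v in cnt.values() if v == 1) / len(males)
                    if frac > 2 / 3:
                        expected[p] = True
            for p in pops:
                assert call.per_population[p].is_xy == expected[p]


class TestCladeTheta:
    def test_identical_y_sequences_zero_theta(self):
        codes = np.zeros((8, 100), dtype=np.int8)
        codes[4:, ::2] = 1  # X haplotypes vary... actually differ from Y block
        codes[5, 1] = 1
        aln = make_aln(codes, ["M"] * 4 + ["F"] * 4)
        y_leaves = frozenset(l.name for l in aln.leaves[:4])
        ty, tx = treescan.clade_theta(aln, y_leaves)
        assert ty.theta_per_site == 0.0
        assert tx.theta_per_site > 0.0

    def test_too_few_y_leaves(self):
        codes = np.zeros((4, 10), dtype=np.int8)
        aln = make_aln(codes, ["M"] * 4)
        with pytest.raises(ValueError):
            treescan.clade_theta(aln, frozenset([aln.leaves[0].name]))

    def test_autosomal_baseline(self, sim_bundle):
        wins = treescan.snp_windows(
            sim_bundle["cohort"], sim_bundle["labels"], sim_bundle["populations"], chrom="chr1"
        )
        theta = treescan.autosomal_baseline_theta(wins, sim_bundle["labels"], n_windows=50, seed=0)
        assert theta > 0


def exhaustive_mst_weight(nodes, dist):
    """Minimum spanning-tree weight by enumerating all spanning trees."""
    m = len(nodes)
    edges = [(i, j) for i in range(m) for j in range(i + 1, m)]
    best = None
    for combo in itertools.combinations(edges, m - 1):
        g = nx.Graph(combo)
        if g.number_of_nodes() == m and nx.is_connected(g):
            w = sum(dist[u][v] for u, v in combo)
            best = w if best is None else min(best, w)
    return best


class TestHaploNetwork:
    def test_single_difference_single_edge(self):
        seqs = np.array([[0, 0, 0], [0, 0, 1]])
        net = treescan.build_network(seqs, ["p1", "p2"])
        assert net.edges == [(0, 1, 1)]

    def test_identical_sequences_collapse(self):
        seqs = np.zeros((3, 5), dtype=int)
        net = treescan.build_network(seqs, ["p1", "p1", "p2"])
        assert len(net.sequences) == 1
        assert net.multiplicity == [3]
        assert net.pop_counts[0] == {"p1": 2, "p2": 1}

    def test_mst_weight_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(4):
            seqs = rng.integers(0, 2, (6, 12))
            seqs = np.unique(seqs, axis=0)
            if len(seqs) < 3:
                continue
            net = treescan.build_network(seqs, ["p1"] * len(seqs))
            dist = [
                [int((a != b).sum()) for b in np.array(net.sequences)]
                for a in np.array(net.sequences)
            ]
            assert sum(w for *_, w in net.edges) == exhaustive_mst_weight(net.sequences, dist)

    def test_mean_steps_within_population(self):
        seqs = np.array([[0, 0], [0, 1], [1, 1]])
        net = treescan.build_network(seqs, ["p1", "p1", "p2"])
        assert net.mean_steps_within("p1") == pytest.approx(1.0)
        assert net.mean_steps_within("p2") is None
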