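"""Window gene trees from phased haplotypes and Y-haplotype calling.

The genome is cut into non-overlapping windows of a fixed number of SNPs
(100 by default; SNP windows give uniform resolution where SNP density is
elevated).  Within each window every individual contributes two haplotype
sequences; a neighbor-joining (or BIONJ) tree is built from pairwise
distances, and a window supports an XY system when some side of an edge of
the unrooted tree contains only male haplotypes and covers more than 2/3 of
a population's males (one haplotype each) — that side is read as the Y
lineage.  Downstream utilities compute Watterson diversity for the Y clade,
its X complement and an autosomal baseline, and build minimum-spanning-tree
haplotype networks.

Monophyly is evaluated on bipartitions of the unrooted tree.  A male whose
two haplotypes both fall on the candidate Y side is not counted toward the
quota but does not disqualify the side; this avoids penalizing windows with
incomplete lineage sorting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import MISSING, CohortVariantSet, SexLabels

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
PURINES = {BASE_CODE["A"], BASE_CODE["G"]}
SATURATION_CAP = 5.0  # distance assigned when a correction formula saturates
DEFAULT_WINDOW_SNPS = 100
XY_THRESHOLD = 2.0 / 3.0


@dataclass
class Leaf:
    name: str
    individual: str
    hap_index: int  # 1 or 2
    sex: str
    population: str


@dataclass
class HaplotypeAlignment:
    """SNP-column alignment for one window (leaves x SNP columns)."""

    chrom: str
    start: int  # 1-based position of first SNP
    end: int  # 1-based position of last SNP
    positions: np.ndarray
    leaves: list[Leaf]
    codes: np.ndarray  # int8, 0..3 base codes, -1 missing

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def span_bp(self) -> int:
        return int(self.end - self.start + 1)


def snp_windows(
    cohort: CohortVariantSet,
    labels: SexLabels,
    populations: dict[str, str],
    chrom: str | None = None,
    window_size: int = DEFAULT_WINDOW_SNPS,
) -> list[HaplotypeAlignment]:
    """Cut phased SNPs into consecutive non-overlapping windows of ``window_size`` columns.

    The trailing remainder of fewer than ``window_size`` SNPs is dropped.
    Each individual contributes exactly two leaves.
    """
    if cohort.hap is None:
        raise ValueError("phased haplotypes are required")
    sexes = {s: ("M" if m else "F") for s, m in zip(cohort.samples, labels.masks(cohort.samples)[0])}
    leaves = []
    for j, s in enumerate(cohort.samples):
        for h in (1, 2):
            leaves.append(Leaf(f"{s}|{h}", s, h, sexes[s], populations.get(s, "pop")))

    mask = cohort.is_snp.copy()
    if chrom is not None:
        mask &= cohort.chrom == chrom
    idx = np.flatnonzero(mask)
    # sort by chromosome then position, keeping chromosomes contiguous
    order = np.lexsort((cohort.pos[idx], cohort.chrom[idx].astype(str)))
    idx = idx[order]

    # map hap alleles to base codes
    ref_codes = np.array([BASE_CODE.get(str(r), -1) for r in cohort.ref[idx]], dtype=np.int8)
    alt_codes = np.array([BASE_CODE.get(str(a), -1) for a in cohort.alt[idx]], dtype=np.int8)
    hap = cohort.hap[idx]  # sites x 2N
    codes = np.where(hap == 0, ref_codes[:, None], np.where(hap == 1, alt_codes[:, None], MISSING))

    out = []
    chroms = cohort.chrom[idx]
    pos = cohort.pos[idx]
    for c in dict.fromkeys(chroms.tolist()):
        cmask = np.flatnonzero(chroms == c)
        n_win = len(cmask) // window_size
        for w in range(n_win):
            cols = cmask[w * window_size : (w + 1) * window_size]
            out.append(
                HaplotypeAlignment(
                    chrom=str(c),
                    start=int(pos[cols[0]]),
                    end=int(pos[cols[-1]]),
                    positions=pos[cols].copy(),
                    leaves=list(leaves),
                    codes=codes[cols].T.astype(np.int8).copy(),
                )
            )
    return out


# ---------------------------------------------------------------------------
# distances


def _pairwise_counts(codes: np.ndarray):
    """Mismatch proportion and transition proportion per leaf pair (pairwise deletion)."""
    valid = codes != MISSING
    n = codes.shape[0]
    p = np.zeros((n, n))
    ts = np.zeros((n, n))
    denom = np.zeros((n, n))
    is_purine = np.isin(codes, list(PURINES))
    for i in range(n):
        both = valid[i] & valid
        diff = both & (codes[i] != codes)
        transition = diff & (is_purine[i] == is_purine)
        denom[i] = both.sum(axis=1)
        p[i] = diff.sum(axis=1)
        ts[i] = transition.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (
            np.where(denom > 0, p / np.maximum(denom, 1), 0.0),
            np.where(denom > 0, ts / np.maximum(denom, 1), 0.0),
        )


def _base_frequencies(codes: np.ndarray) -> np.ndarray:
    # one pseudocount per base keeps F84 defined on alignments missing a
    # purine or pyrimidine class entirely
    counts = np.array([(codes == b).sum() for b in range(4)], dtype=float) + 1.0
    return counts / counts.sum()


def f84_distance(p_transition: np.ndarray, p_transversion: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Closed-form F84 distance from transition/transversion proportions.

    With base frequencies pi and pyrimidine/purine sums piY, piR:
        A = piC*piT/piY + piA*piG/piR
        B = piC*piT + piA*piG
        C = piR*piY
        d = -2A ln(1 - P/(2A) - (A-B) Q /(2AC)) + 2(A - B - C) ln(1 - Q/(2C))
    Saturated arguments are capped at ``SATURATION_CAP``.
    """
    piA, piC, piG, piT = freqs
    piR, piY = piA + piG, piC + piT
    if piR == 0 or piY == 0:
        raise ValueError("degenerate base composition for F84")
    A = piC * piT / piY + piA * piG / piR
    B = piC * piT + piA * piG
    C = piR * piY
    P, Q = np.asarray(p_transition, float), np.asarray(p_transversion, float)
    arg1 = 1 - P / (2 * A) - (A - B) * Q / (2 * A * C)
    arg2 = 1 - Q / (2 * C)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -2 * A * np.log(arg1) + 2 * (A - B - C) * np.log(arg2)
    d = np.where((arg1 <= 0) | (arg2 <= 0) | ~np.isfinite(d), SATURATION_CAP, d)
    return np.maximum(d, 0.0)


def distance_matrix(aln: HaplotypeAlignment, model: str = "JC69") -> np.ndarray:
    """Pairwise distances between leaves under 'p', 'JC69' or 'F84'."""
    p, ts = _pairwise_counts(aln.codes)
    if model == "p":
        d = p
    elif model == "JC69":
        arg = 1 - 4.0 * p / 3.0
        with np.errstate(invalid="ignore", divide="ignore"):
            d = -0.75 * np.log(arg)
        d = np.where(arg <= 0, SATURATION_CAP, d)
    elif model == "F84":
        d = f84_distance(ts, p - ts, _base_frequencies(aln.codes))
    else:
        raise ValueError(f"unknown model {model!r}")
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class UnrootedTree:
    graph: nx.Graph
    leaf_names: list[str]

    def bipartitions(self):
        """Yield (leafset_side_a, leafset_side_b) for every internal edge.

        Trivial splits (single leaf vs rest) are included; callers filter.
        """
        all_leaves = frozenset(self.leaf_names)
        for u, v in self.graph.edges():
            side = self._leaves_beyond(u, v)
            yield side, all_leaves - side

    def _leaves_beyond(self, u, v) -> frozenset:
        """Leaves reachable from u when the edge (u, v) is cut."""
        seen = {v, u}
        stack = [u]
        leaves = set()
        leafset = set(self.leaf_names)
        while stack:
            node = stack.pop()
            if node in leafset:
                leaves.add(node)
            for nb in self.graph.neighbors(node):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if u in leafset:
            leaves.add(u)
        return frozenset(leaves)

    def branch_length(self, u, v) -> float:
        return self.graph.edges[u, v]["length"]

    def to_newick(self) -> str:
        internal = [n for n in self.graph.nodes if n not in set(self.leaf_names)]
        if not internal:  # two-taxon tree: a single edge
            a, b = self.leaf_names
            return f"({a}:{self.graph.edges[a, b]['length']:.6g},{b}:0);"
        start = internal[0]

        def rec(node, parent):
            children = [nb for nb in self.graph.neighbors(node) if nb != parent]
            if not children:
                return str(node)
            inner = ",".join(
                f"{rec(ch, node)}:{self.graph.edges[node, ch]['length']:.6g}" for ch in children
            )
            return f"({inner})"

        return rec(start, None) + ";"


def nj_tree(dist: np.ndarray, names: list[str], method: str = "NJ") -> UnrootedTree:
    """Neighbor joining or BIONJ on a distance matrix.

    Ties in the selection criterion are broken by the (sorted) label order
    of the joined pair, so the result is independent of input row order.
    """
    if method not in ("NJ", "BIONJ"):
        raise ValueError(f"unknown method {method!r}")
    n = len(names)
    if dist.shape != (n, n):
        raise ValueError("distance matrix does not match label count")
    if n < 2:
        raise ValueError("need at least two taxa")

    order = sorted(range(n), key=lambda i: names[i])
    active = [names[i] for i in order]
    D = dist[np.ix_(order, order)].astype(float).copy()
    V = D.copy()  # BIONJ variance matrix
    g = nx.Graph()
    for name in active:
        g.add_node(name)
    next_id = 0

    if n == 2:
        g.add_edge(active[0], active[1], length=float(D[0, 1]))
        return UnrootedTree(graph=g, leaf_names=list(names))

    while len(active) > 3:
        r = len(active)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        vi = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        vj = D[i, j] - vi
        new = f"_n{next_id}"
        next_id += 1
        g.add_edge(active[i], new, length=float(vi))
        g.add_edge(active[j], new, length=float(vj))

        keep = [k for k in range(r) if k not in (i, j)]
        if method == "NJ":
            d_new = 0.5 * (D[i, keep] + D[j, keep] - D[i, j])
            v_new = d_new  # unused for NJ
        else:
            if V[i, j] > 0:
                lam = 0.5 + (V[j, keep] - V[i, keep]).sum() / (2 * (r - 2) * V[i, j])
                lam = min(1.0, max(0.0, lam))
            else:
                lam = 0.5
            d_new = lam * (D[i, keep] - vi) + (1 - lam) * (D[j, keep] - vj)
            v_new = lam * V[i, keep] + (1 - lam) * V[j, keep] - lam * (1 - lam) * V[i, j]

        D = D[np.ix_(keep, keep)]
        V = V[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        V = np.pad(V, ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = d_new
        V[-1, :-1] = V[:-1, -1] = v_new
        active = [active[k] for k in keep] + [new]

    # join the last three nodes at a central vertex
    hub = f"_n{next_id}"
    (a, b, c) = active
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, length in ((a, la), (b, lb), (c, lc)):
        g.add_edge(node, hub, length=float(length))
    return UnrootedTree(graph=g, leaf_names=list(names))


# ---------------------------------------------------------------------------
# topology calls


@dataclass
class PopulationCall:
    is_xy: bool
    fraction: float
    y_leaves: frozenset


@dataclass
class TopologyCall:
    chrom: str
    start: int
    end: int
    per_population: dict[str, PopulationCall]
    shared: bool
    y_leaves: frozenset = field(default_factory=frozenset)

    @property
    def any_xy(self) -> bool:
        return any(c.is_xy for c in self.per_population.values())

    @property
    def all_xy(self) -> bool:
        return all(c.is_xy for c in self.per_population.values())


def _side_stats(side: frozenset, leaves: list[Leaf], threshold: float):
    """Per-population male fraction for a male-only side; None if any female leaf."""
    by_name = {l.name: l for l in leaves}
    members = [by_name[x] for x in side]
    if any(l.sex == "F" for l in members):
        return None
    pops = sorted({l.population for l in leaves})
    stats = {}
    for pop in pops:
        males = {l.individual for l in leaves if l.sex == "M" and l.population == pop}
        if not males:
            stats[pop] = 0.0
            continue
        hap_count: dict[str, int] = {}
        for l in members:
            if l.population == pop:
                hap_count[l.individual] = hap_count.get(l.individual, 0) + 1
        one_hap = sum(1 for v in hap_count.values() if v == 1)
        stats[pop] = one_hap / len(males)
    return stats


def call_xy_topology(
    tree: UnrootedTree,
    aln: HaplotypeAlignment,
    threshold: float = XY_THRESHOLD,
) -> TopologyCall:
    """Scan all bipartitions for a male-only side covering > threshold of males.

    A side qualifies for a population when it contains no female haplotypes
    (from any population) and more than ``threshold`` of that population's
    males contribute exactly one haplotype each.  The best side (largest
    summed fraction over populations) provides the reported Y-leaf set; the
    window is ``shared`` when some qualifying side holds haplotypes of both
    populations and meets the quota in at least one.
    """
    leaves = aln.leaves
    pops = sorted({l.population for l in leaves})
    best = {pop: PopulationCall(False, 0.0, frozenset()) for pop in pops}
    best_side: frozenset = frozenset()
    best_score = -1.0
    shared = False
    pop_of = {l.name: l.population for l in leaves}

    seen: set[frozenset] = set()
    for side_a, side_b in tree.bipartitions():
        for side in (side_a, side_b):
            if side in seen or len(side) < 2 or len(side) >= len(leaves):
                continue
            seen.add(side)
            stats = _side_stats(side, leaves, threshold)
            if stats is None:
                continue
            qualifying = [pop for pop, frac in stats.items() if frac > threshold]
            for pop, frac in stats.items():
                cur = best[pop]
                if (pop in qualifying, frac) > (cur.is_xy, cur.fraction):
                    best[pop] = PopulationCall(pop in qualifying, frac, side)
            if qualifying:
                side_pops = {pop_of[x] for x in side}
                if len(side_pops) >= 2:
                    shared = True
                score = sum(stats.values())
                if score > best_score:
                    best_score = score
                    best_side = side
    return TopologyCall(
        chrom=aln.chrom,
        start=aln.start,
        end=aln.end,
        per_population=best,
        shared=shared,
        y_leaves=best_side,
    )


def shared_y(calls: list[TopologyCall]) -> list[TopologyCall]:
    """Windows whose Y clade holds haplotypes of both populations, quota met in >= 1."""
    return [c for c in calls if c.shared]


# ---------------------------------------------------------------------------
# clade diversity and haplotype networks


def clade_theta(aln: HaplotypeAlignment, y_leaves: frozenset):
    """Watterson theta of the Y clade and of the complementary X haplotypes.

    The alignment holds only SNP columns; per-site values use the window's
    genomic span as L (intervening monomorphic sites are implicitly
    invariant).  Returns (theta_y, theta_x) as ThetaEstimates.
    """
    from .divstats import theta_from_alignment

    names = [l.name for l in aln.leaves]
    y_idx = [i for i, n in enumerate(names) if n in y_leaves]
    x_idx = [i for i, n in enumerate(names) if n not in y_leaves]
    if len(y_idx) < 2:
        raise ValueError("fewer than 2 Y haplotypes; diversity undefined")
    if len(x_idx) < 2:
        raise ValueError("fewer than 2 X haplotypes; diversity undefined")
    ty = theta_from_alignment(aln.codes[y_idx], L=aln.span_bp)
    tx = theta_from_alignment(aln.codes[x_idx], L=aln.span_bp)
    return ty, tx


def autosomal_baseline_theta(
    windows: list[HaplotypeAlignment],
    labels: SexLabels,
    n_windows: int = 1000,
    seed: int = 0,
):
    """Mean Watterson theta over randomly sampled autosomal windows.

    Takes one haplotype per male in each sampled window (random haplotype
    index per male per window) and averages the per-window per-site theta.
    Windows are sampled with replacement, so fewer than ``n_windows``
    distinct windows is fine.
    """
    from .divstats import theta_from_alignment

    if not windows:
        raise ValueError("no autosomal windows supplied")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(windows), size=n_windows)
    thetas = []
    for i in idx:
        aln = windows[i]
        males = sorted({l.individual for l in aln.leaves if l.sex == "M"})
        if len(males) < 2:
            continue
        rows = []
        names = [l.name for l in aln.leaves]
        for m in males:
            h = int(rng.integers(1, 3))
            rows.append(names.index(f"{m}|{h}"))
        thetas.append(theta_from_alignment(aln.codes[rows], L=aln.span_bp).theta_per_site)
    if not thetas:
        raise ValueError("no usable autosomal windows (need >= 2 males)")
    return float(np.mean(thetas))


@dataclass
class HaploNetwork:
    sequences: list[tuple]  # distinct haplotype sequences (as tuples of codes)
    multiplicity: list[int]
    pop_counts: list[dict[str, int]]
    edges: list[tuple[int, int, int]]  # MST edges (u, v, hamming)
    alternative_edges: list[tuple[int, int, int]]

    def mean_steps_within(self, pop: str) -> float | None:
        """Mean MST edge weight among edges joining nodes that include ``pop``."""
        weights = [
            w
            for u, v, w in self.edges
            if self.pop_counts[u].get(pop, 0) > 0 and self.pop_counts[v].get(pop, 0) > 0
        ]
        return float(np.mean(weights)) if weights else None


def build_network(sequences: np.ndarray, pop_labels: list[str]) -> HaploNetwork:
    """Minimum-spanning-tree haplotype network over distinct sequences.

    Identical rows collapse into one node with multiplicity and population
    composition; edges are Hamming distances and the network is an MST with
    deterministic tie-breaking (edges sorted by weight, then node index).
    Non-tree edges that tie the maximum-weight edge on the tree path
    between their endpoints are reported as alternative links.
    """
    sequences = np.asarray(sequences)
    if sequences.ndim != 2 or len(sequences) == 0:
        raise ValueError("need a non-empty 2-D sequence matrix")
    if len(pop_labels) != len(sequences):
        raise ValueError("one population label per sequence")

    uniq: dict[tuple, int] = {}
    mult: list[int] = []
    pops: list[dict[str, int]] = []
    for row, pop in zip(sequences, pop_labels):
        key = tuple(int(x) for x in row)
        if key not in uniq:
            uniq[key] = len(uniq)
            mult.append(0)
            pops.append({})
        k = uniq[key]
        mult[k] += 1
        pops[k][pop] = pops[k].get(pop, 0) + 1
    nodes = list(uniq)
    m = len(nodes)

    g = nx.Graph()
    g.add_nodes_from(range(m))
    pairs = sorted(
        ((int(sum(a != b for a, b in zip(nodes[u], nodes[v]))), u, v)
         for u, v in itertools.combinations(range(m), 2))
    )
    for w, u, v in pairs:
        g.add_edge(u, v, weight=w)
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    edges = sorted((min(u, v), max(u, v), int(mst.edges[u, v]["weight"])) for u, v in mst.edges)

    alt = []
    tree_edges = {(u, v) for u, v, _ in edges}
    for w, u, v in pairs:
        if (u, v) in tree_edges or m < 2:
            continue
        path = nx.shortest_path(mst, u, v)
        path_max = max(mst.edges[a, b]["weight"] for a, b in zip(path, path[1:]))
        if w == path_max:
            alt.append((u, v, w))
    return HaploNetwork(
        sequences=nodes, multiplicity=mult, pop_counts=pops, edges=edges, alternative_edges=alt
    )
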