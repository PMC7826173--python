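"""Forward Wright-Fisher simulator of a male-heterogametic (XY) population.

The simulator exists to realize the neutral copy-number scaling of
diversity — X carried 1.5x and Y 0.5x per breeding pair relative to
autosomes, so at mutation-drift equilibrium theta_X/theta_A = 3/4 and
theta_Y/theta_A = 1/4 — and to synthesize every input of the downstream
analyses (phased cohort variants, depth tables, per-individual sequences
with a planted Y-specific insertion, and linked-read molecules) with a
truth manifest for the planted features.

Model: discrete non-overlapping generations with fixed male/female counts;
each offspring draws a random mother and father; sons receive the father's
Y and one maternal X, daughters the father's X and one maternal X; at each
autosomal locus the offspring receives one allele from each parent.  Loci
assort independently (free recombination between loci) but are internally
non-recombining, so each locus carries its own genealogy and averaging over
loci tames the coalescent variance of the diversity ratios.  Mutation is
infinite-sites: Poisson(mu) new unique mutations per transmitted locus
copy.  Haplotype states are parent-pointer chains of mutation events.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HET, MISSING, CohortVariantSet, SexLabels
from .covwin import WindowGrid
from .divstats import ThetaEstimate, watterson_theta

COMPARTMENTS = ("A", "X", "Y")


# ---------------------------------------------------------------------------
# layout


@dataclass
class SimLayout:
    """Genome geometry: autosomes plus one sex chromosome with PAR and two strata."""

    chrom_lengths: dict[str, int]
    sex_chrom: str
    par: tuple[int, int]
    stratum2: tuple[int, int]
    stratum1: tuple[int, int]
    degenerate_subintervals: list[tuple[int, int]]
    window_width: int = 50_000

    def __post_init__(self):
        if self.sex_chrom not in self.chrom_lengths:
            raise ValueError("sex chromosome missing from chrom_lengths")
        L = self.chrom_lengths[self.sex_chrom]
        for name, (s, e) in [("par", self.par), ("stratum2", self.stratum2), ("stratum1", self.stratum1)]:
            if not (0 <= s < e <= L):
                raise ValueError(f"{name} interval out of range")
        ivs = sorted([self.par, self.stratum2, self.stratum1])
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("par/stratum intervals overlap")
        for s, e in self.degenerate_subintervals:
            if not (self.stratum1[0] <= s < e <= self.stratum1[1]):
                raise ValueError("degenerate subintervals must lie within stratum1")

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chrom_lengths if c != self.sex_chrom]

    def grid(self) -> WindowGrid:
        return WindowGrid.tile(self.chrom_lengths, self.window_width)

    def strata_bed(self) -> list[tuple[str, int, int, str]]:
        out = [
            (self.sex_chrom, *self.par, "PAR"),
            (self.sex_chrom, *self.stratum2, "stratumII"),
            (self.sex_chrom, *self.stratum1, "stratumI"),
        ]
        for s, e in self.degenerate_subintervals:
            out.append((self.sex_chrom, s, e, "degenerate"))
        return out


def default_layout() -> SimLayout:
    """Chromosome-scale layout mirroring the guppy geometry: a ~26-Mb sex
    chromosome whose distal end is the old stratum with two degenerate
    intervals, and three 20-Mb autosomes."""
    return SimLayout(
        chrom_lengths={"chr1": 20_000_000, "chr2": 20_000_000, "chr3": 20_000_000,
                       "chr12": 26_500_000},
        sex_chrom="chr12",
        par=(0, 10_000_000),
        stratum2=(10_000_000, 20_000_000),
        stratum1=(20_000_000, 26_500_000),
        degenerate_subintervals=[(21_000_000, 22_000_000), (25_000_000, 26_000_000)],
        window_width=50_000,
    )


def small_layout() -> SimLayout:
    """Sequence-scale layout (hundreds of kb) for k-mer and FASTA fixtures."""
    return SimLayout(
        chrom_lengths={"chr1": 150_000, "chr12": 300_000},
        sex_chrom="chr12",
        par=(0, 100_000),
        stratum2=(100_000, 200_000),
        stratum1=(200_000, 300_000),
        degenerate_subintervals=[(210_000, 230_000), (260_000, 280_000)],
        window_width=10_000,
    )


def molecule_layout() -> SimLayout:
    """Mb-scale layout for linked-read molecule fixtures (distant-window scan)."""
    return SimLayout(
        chrom_lengths={"chr1": 2_000_000, "chr12": 4_000_000},
        sex_chrom="chr12",
        par=(0, 1_000_000),
        stratum2=(1_000_000, 2_000_000),
        stratum1=(2_000_000, 4_000_000),
        degenerate_subintervals=[(2_200_000, 2_400_000), (3_600_000, 3_800_000)],
        window_width=100_000,
    )


# ---------------------------------------------------------------------------
# Wright-Fisher engine


@dataclass
class WFConfig:
    pop_size: int = 200
    sex_ratio: float = 0.5
    mu_per_locus: dict[str, float] = field(default_factory=lambda: {"A": 0.005, "X": 0.005, "Y": 0.005})
    n_loci: dict[str, int] = field(default_factory=lambda: {"A": 200, "X": 200, "Y": 200})
    burn_in_generations: int | None = None  # default 10 * pop_size
    sample_males: int = 20
    sample_females: int = 20
    n_y_lineages: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.sex_ratio < 1:
            raise ValueError("sex_ratio must be strictly between 0 and 1")
        for c in COMPARTMENTS:
            if self.mu_per_locus.get(c, 0) < 0 or self.n_loci.get(c, 0) < 0:
                raise ValueError("mutation rates and locus counts must be >= 0")
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("population must contain both sexes")
        if self.sample_males > self.n_males:
            raise ValueError(
                f"sample_males={self.sample_males} exceeds the {self.n_males} males in the population"
            )
        if self.sample_females > self.n_females:
            raise ValueError(
                f"sample_females={self.sample_females} exceeds the {self.n_females} females in the population"
            )

    @property
    def n_males(self) -> int:
        return int(round(self.pop_size * self.sex_ratio))

    @property
    def n_females(self) -> int:
        return self.pop_size - self.n_males

    @property
    def burn_in(self) -> int:
        return self.burn_in_generations if self.burn_in_generations is not None else 10 * self.pop_size


class _NodeStore:
    """Append-only forest of mutation events: node -> (parent node, mutation id).

    A haplotype at one locus is a chain of mutation events; -1 is the
    mutation-free founder state.  Each event carries exactly one new
    infinite-sites mutation.
    """

    __slots__ = ("parent", "mut")

    def __init__(self):
        self.parent: list[int] = []
        self.mut: list[int] = []

    def add(self, parent: int, mutation_id: int) -> int:
        self.parent.append(parent)
        self.mut.append(mutation_id)
        return len(self.parent) - 1

    def resolve(self, node: int) -> list[int]:
        out = []
        while node != -1:
            out.append(self.mut[node])
            node = self.parent[node]
        return out

    def resolve_union(self, nodes) -> frozenset:
        out: list[int] = []
        for node in nodes:
            out.extend(self.resolve(int(node)))
        return frozenset(out)


@dataclass
class SampledPopulation:
    """Sampled individuals with per-compartment haplotype mutation sets."""

    individuals: list[tuple[str, str]]  # (id, sex)
    autosomal: dict[str, tuple[frozenset, frozenset]]
    x: dict[str, tuple[frozenset, ...]]  # 2 for females, 1 for males
    y: dict[str, frozenset]  # males only
    config: WFConfig
    y_pedigree: list | None = None  # optional (fathers array, y_nodes) per generation

    @property
    def males(self) -> list[str]:
        return [i for i, s in self.individuals if s == "M"]

    @property
    def females(self) -> list[str]:
        return [i for i, s in self.individuals if s == "F"]

    def haplotypes(self, compartment: str) -> list[frozenset]:
        if compartment == "A":
            return [h for i, _ in self.individuals for h in self.autosomal[i]]
        if compartment == "X":
            return [h for i, _ in self.individuals for h in self.x[i]]
        if compartment == "Y":
            return [self.y[i] for i in self.males]
        raise ValueError(f"unknown compartment {compartment!r}")

    def segregating_mutations(self, compartment: str) -> set:
        """Mutations present in some but not all sampled haplotypes of the compartment."""
        haps = self.haplotypes(compartment)
        counts: dict[int, int] = {}
        for h in haps:
            for m in h:
                counts[m] = counts.get(m, 0) + 1
        n = len(haps)
        return {m for m, c in counts.items() if 0 < c < n}

    def theta(self, compartment: str) -> ThetaEstimate:
        """Watterson's theta per locus for the sampled haplotypes of a compartment."""
        haps = self.haplotypes(compartment)
        S = len(self.segregating_mutations(compartment))
        return watterson_theta(S, len(haps), self.config.n_loci[compartment], check_length=False)

    def theta_ratios(self) -> tuple[float, float]:
        """(theta_X/theta_A, theta_Y/theta_A), mutation-rate adjusted.

        Each compartment's theta is divided by its per-locus mutation rate
        first, so configs with unequal rates still estimate the pure
        copy-number ratios.
        """
        mu = self.config.mu_per_locus
        ta = self.theta("A").theta_per_site / mu["A"]
        tx = self.theta("X").theta_per_site / mu["X"]
        ty = self.theta("Y").theta_per_site / mu["Y"]
        if ta == 0:
            raise ValueError("no autosomal diversity; ratios undefined")
        return tx / ta, ty / ta


def _scatter_mutations(state: np.ndarray, rng: np.random.Generator, mu: float,
                       store: _NodeStore, counter: list[int]) -> None:
    """Add Poisson(mu)-per-cell new mutations to a (loci x copies) state matrix.

    Uses Poisson-process thinning: the total over cells is Poisson(mu * n),
    and each event lands in a uniformly chosen cell — exactly equivalent to
    iid Poisson(mu) per transmitted haplotype per locus.
    """
    if mu <= 0 or state.size == 0:
        return
    total = rng.poisson(mu * state.size)
    if total == 0:
        return
    cells = rng.integers(0, state.size, total)
    flat = state.reshape(-1)
    for cell in cells:
        flat[cell] = store.add(int(flat[cell]), counter[0])
        counter[0] += 1


def simulate_wf(config: WFConfig, record_y_pedigree: bool = False) -> SampledPopulation:
    """Run the forward simulation and return a uniform sample of individuals.

    State per compartment is a (loci x haplotype copies) matrix of node ids
    into an append-only mutation-event store; loci assort independently
    (free recombination between loci, none within a locus).  Deterministic
    given ``config.seed``.  With ``record_y_pedigree`` the per-generation Y
    transmission (father indices and Y state matrices) is retained for
    genealogy checks, together with the node store.
    """
    rng = np.random.default_rng(config.seed)
    n_m, n_f = config.n_males, config.n_females
    N = config.pop_size
    L = config.n_loci
    mu = config.mu_per_locus
    counter = [0]
    stores = {c: _NodeStore() for c in COMPARTMENTS}

    # founder states: every copy is the mutation-free chain (-1)
    A = np.full((L["A"], 2 * N), -1, dtype=np.int64)  # male i: cols 2i, 2i+1; female j: 2(n_m+j), +1
    X = np.full((L["X"], n_m + 2 * n_f), -1, dtype=np.int64)  # male i: col i; female j: n_m+2j, +1
    Y = np.full((L["Y"], n_m), -1, dtype=np.int64)
    pedigree = [] if record_y_pedigree else None

    for _ in range(config.burn_in):
        fathers = rng.integers(0, n_m, N)  # offspring 0..n_m-1 are sons
        mothers = rng.integers(0, n_f, N)

        # autosomes: one haplotype from each parent, chosen per locus
        pat_bit = rng.integers(0, 2, (L["A"], N))
        mat_bit = rng.integers(0, 2, (L["A"], N))
        pat_col = 2 * fathers[None, :] + pat_bit
        mat_col = 2 * (n_m + mothers)[None, :] + mat_bit
        A_new = np.empty_like(A)
        A_new[:, 0::2] = np.take_along_axis(A, pat_col, axis=1)
        A_new[:, 1::2] = np.take_along_axis(A, mat_col, axis=1)

        # X: sons get a maternal X; daughters get the paternal X plus a maternal X
        X_new = np.empty_like(X)
        son_bit = rng.integers(0, 2, (L["X"], n_m))
        X_new[:, :n_m] = np.take_along_axis(X, n_m + 2 * mothers[None, :n_m] + son_bit, axis=1)
        X_new[:, n_m::2] = X[:, fathers[n_m:]]
        dau_bit = rng.integers(0, 2, (L["X"], n_f))
        X_new[:, n_m + 1 :: 2] = np.take_along_axis(X, n_m + 2 * mothers[None, n_m:] + dau_bit, axis=1)

        # Y: sons copy the father's Y
        Y_new = Y[:, fathers[:n_m]]

        _scatter_mutations(A_new, rng, mu["A"], stores["A"], counter)
        _scatter_mutations(X_new, rng, mu["X"], stores["X"], counter)
        Y_new = Y_new.copy()
        _scatter_mutations(Y_new, rng, mu["Y"], stores["Y"], counter)

        if pedigree is not None:
            pedigree.append((fathers[:n_m].copy(), Y_new.copy()))
        A, X, Y = A_new, X_new, Y_new

    pick_m = np.sort(rng.choice(n_m, size=config.sample_males, replace=False))
    pick_f = np.sort(rng.choice(n_f, size=config.sample_females, replace=False))
    individuals, autosomal, x, y = [], {}, {}, {}
    for r, i in enumerate(pick_m):
        name = f"M{r:02d}"
        individuals.append((name, "M"))
        autosomal[name] = (
            stores["A"].resolve_union(A[:, 2 * i]),
            stores["A"].resolve_union(A[:, 2 * i + 1]),
        )
        x[name] = (stores["X"].resolve_union(X[:, i]),)
        y[name] = stores["Y"].resolve_union(Y[:, i])
    for r, j in enumerate(pick_f):
        name = f"F{r:02d}"
        individuals.append((name, "F"))
        autosomal[name] = (
            stores["A"].resolve_union(A[:, 2 * (n_m + j)]),
            stores["A"].resolve_union(A[:, 2 * (n_m + j) + 1]),
        )
        x[name] = (
            stores["X"].resolve_union(X[:, n_m + 2 * j]),
            stores["X"].resolve_union(X[:, n_m + 2 * j + 1]),
        )
    return SampledPopulation(
        individuals=individuals,
        autosomal=autosomal,
        x=x,
        y=y,
        config=config,
        y_pedigree=None if pedigree is None else {"history": pedigree, "store": stores["Y"]},
    )


# ---------------------------------------------------------------------------
# layout overlay: genealogical mutations -> cohort variants


def _sample_positions(
    rng: np.random.Generator,
    intervals: list[tuple[str, int, int]],
    k: int,
    taken: set[tuple[str, int]] | None = None,
) -> list[tuple[str, int]]:
    """k distinct (chrom, 0-based pos) sites drawn uniformly from interval union."""
    lens = np.array([e - s for _, s, e in intervals], dtype=np.int64)
    total = int(lens.sum())
    if k > total - (len(taken) if taken else 0):
        raise ValueError(f"cannot place {k} variants in {total} available positions")
    taken = set(taken or ())
    offsets = np.cumsum(np.concatenate([[0], lens]))
    out: list[tuple[str, int]] = []
    while len(out) < k:
        draw = rng.integers(0, total, size=2 * (k - len(out)) + 8)
        for d in draw:
            seg = int(np.searchsorted(offsets, d, side="right") - 1)
            chrom, s, _ = intervals[seg]
            site = (chrom, s + int(d) - int(offsets[seg]))
            if site not in taken:
                taken.add(site)
                out.append(site)
                if len(out) == k:
                    break
    return sorted(out)


def _cluster_y_lineages(pop: SampledPopulation, k: int) -> dict[str, int]:
    """Group sampled males into k Y-lineage classes by Y-haplotype similarity."""
    males = pop.males
    if k < 1 or k > len(males):
        raise ValueError("n_y_lineages must be between 1 and the number of sampled males")
    if k == 1:
        return {m: 0 for m in males}
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n = len(males)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pop.y[males[i]], pop.y[males[j]]
            union = len(a | b)
            D[i, j] = D[j, i] = 1.0 - (len(a & b) / union if union else 1.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    # identical haplotype sets can collapse clusters; split deterministically to reach k
    used = sorted(set(labels))
    nxt = 0
    while len(used) < k:
        counts = {u: int((labels == u).sum()) for u in used}
        big = max(counts, key=lambda u: (counts[u], -u))
        idx = np.flatnonzero(labels == big)[0]
        new_label = max(used) + 1
        labels[idx] = new_label
        used = sorted(set(labels))
        nxt += 1
    return {m: int(l) for m, l in zip(males, labels)}


_BASES = np.array(list("ACGT"))


def overlay_layout(
    pop: SampledPopulation,
    layout: SimLayout,
    seed: int = 0,
    stratum2_frac: float = 0.3,
    stratum1_mappable_frac: float = 0.7,
    marker_snps_per_lineage: int = 5,
    mean_depth: float = 30.0,
    clean_genotypes: bool = True,
) -> tuple[CohortVariantSet, dict]:
    """Place sampled mutations on the genome and emit phased cohort variants.

    Autosomal mutations go uniformly on the autosomes and the PAR (the PAR
    recombines freely, so it behaves autosomally).  X mutations go on the
    X-linked coordinates of stratum I+II.  Y mutations are mapped to
    stratum II with probability ``stratum2_frac`` (X and Y both align to
    the female reference there: divergence without coverage loss); the rest
    belong to stratum I, where only ``stratum1_mappable_frac`` of them stay
    mappable and appear as male-limited heterozygous SNPs — the remainder
    represents diverged Y sequence lost to the reference.  Each of the
    ``config.n_y_lineages`` Y classes additionally receives
    ``marker_snps_per_lineage`` lineage-marker SNPs in stratum I.

    Returns (cohort, truth) where truth records lineage assignments and the
    planted variant classes.
    """
    if not 0 <= stratum2_frac <= 1 or not 0 <= stratum1_mappable_frac <= 1:
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = [i for i, _ in pop.individuals]
    sex_of = dict(pop.individuals)
    n = len(samples)
    males = pop.males

    def present_mutations(compartment: str) -> list[int]:
        seen: set[int] = set()
        for h in pop.haplotypes(compartment):
            seen |= h
        return sorted(seen)

    a_muts = present_mutations("A")
    x_muts = present_mutations("X")
    y_muts = present_mutations("Y")

    # Y mutations: stratum II vs stratum I (mappable or dropped)
    u = rng.random(len(y_muts))
    y_in_s2 = [m for m, v in zip(y_muts, u) if v < stratum2_frac]
    rest = [m for m, v in zip(y_muts, u) if v >= stratum2_frac]
    u2 = rng.random(len(rest))
    y_in_s1 = [m for m, v in zip(rest, u2) if v < stratum1_mappable_frac]

    lineage_of = _cluster_y_lineages(pop, pop.config.n_y_lineages)
    n_markers = marker_snps_per_lineage * pop.config.n_y_lineages

    sx = layout.sex_chrom
    auto_intervals = [(c, 0, layout.chrom_lengths[c]) for c in layout.autosomes]
    auto_intervals.append((sx, *layout.par))

    # positions: autosomal+PAR pool, then the sex-chromosome strata pool shared by X and Y
    a_pos = _sample_positions(rng, auto_intervals, len(a_muts))
    strata = [(sx, *layout.stratum1), (sx, *layout.stratum2)]
    x_pos = _sample_positions(rng, strata, len(x_muts))
    taken = set(x_pos)
    y1_pos = _sample_positions(rng, [(sx, *layout.stratum1)], len(y_in_s1), taken)
    taken |= set(y1_pos)
    y2_pos = _sample_positions(rng, [(sx, *layout.stratum2)], len(y_in_s2), taken)
    taken |= set(y2_pos)
    mk_pos = _sample_positions(rng, [(sx, *layout.stratum1)], n_markers, taken)

    # assemble site table: (chrom, pos0, class, payload)
    sites: list[tuple[str, int, str, object]] = []
    for m, (chrom, p) in zip(a_muts, a_pos):
        sites.append((chrom, p, "A", m))
    for m, (_, p) in zip(x_muts, x_pos):
        sites.append((sx, p, "X", m))
    for m, (_, p) in zip(y_in_s1, y1_pos):
        sites.append((sx, p, "Y", m))
    for m, (_, p) in zip(y_in_s2, y2_pos):
        sites.append((sx, p, "Y", m))
    mi = 0
    for lineage in range(pop.config.n_y_lineages):
        for _ in range(marker_snps_per_lineage):
            sites.append((sx, mk_pos[mi][1], "marker", lineage))
            mi += 1
    sites.sort(key=lambda t: (t[0], t[1]))
    S = len(sites)

    hap = np.zeros((S, 2 * n), dtype=np.int8)
    col = {name: 2 * j for j, name in enumerate(samples)}
    for si, (chrom, p, klass, payload) in enumerate(sites):
        if klass == "A":
            for j, name in enumerate(samples):
                h1, h2 = pop.autosomal[name]
                hap[si, 2 * j] = payload in h1
                hap[si, 2 * j + 1] = payload in h2
        elif klass == "X":
            for j, name in enumerate(samples):
                if sex_of[name] == "F":
                    x1, x2 = pop.x[name]
                    hap[si, 2 * j] = payload in x1
                    hap[si, 2 * j + 1] = payload in x2
                else:
                    hap[si, 2 * j] = payload in pop.x[name][0]
        elif klass == "Y":
            for name in males:
                hap[si, col[name] + 1] = payload in pop.y[name]
        else:  # lineage marker
            for name in males:
                hap[si, col[name] + 1] = lineage_of[name] == payload
    gt = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)

    # alleles and synthetic support
    ref_idx = rng.integers(0, 4, S)
    alt_shift = rng.integers(1, 4, S)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]
    dp = rng.poisson(mean_depth, (S, n)).astype(np.int32)
    if clean_genotypes:
        dp = np.maximum(dp, 8)
    ad_alt = np.zeros((S, n), dtype=np.int32)
    het = gt == HET
    hom_alt = gt == 2
    ad_alt[hom_alt] = dp[hom_alt]
    draw = rng.binomial(dp[het], 0.5).astype(np.int32)
    if clean_genotypes:
        draw = np.clip(draw, 3, np.maximum(dp[het] - 3, 3))
    ad_alt[het] = draw
    ad_ref = dp - ad_alt
    qual = rng.uniform(100, 900, S)
    tot_alt = ad_alt.sum(axis=1)
    saf = np.where(tot_alt > 0, np.maximum(tot_alt // 2, 3), 0).astype(np.int64)
    sar = np.where(tot_alt > 0, np.maximum(tot_alt - tot_alt // 2, 3), 0).astype(np.int64)

    cohort = CohortVariantSet(
        chrom=np.array([c for c, *_ in sites], dtype=object),
        pos=np.array([p + 1 for _, p, *_ in sites], dtype=np.int64),  # VCF is 1-based
        ref=ref.astype(object),
        alt=alt.astype(object),
        qual=qual,
        is_snp=np.ones(S, dtype=bool),
        saf=saf,
        sar=sar,
        samples=samples,
        gt=gt,
        dp=dp,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        hap=hap,
    )

    # planted truth: sites whose alt allele lives on the Y (or is a lineage
    # marker) and is carried by at least one sampled male; chance male-limited
    # patterns on autosomes are discoverable but are not planted features
    male_cols = np.array([sex_of[s] == "M" for s in samples])
    klass_arr = np.array([k for _, _, k, _ in sites], dtype=object)
    planted = np.isin(klass_arr, ["Y", "marker"])
    male_limited = planted & (gt[:, male_cols] == HET).any(axis=1)
    fully_linked = male_limited & (gt[:, male_cols] == HET).all(axis=1)
    truth = {
        "lineage_of": lineage_of,
        "n_y_lineages": pop.config.n_y_lineages,
        "male_limited_positions": [
            (str(cohort.chrom[i]), int(cohort.pos[i])) for i in np.flatnonzero(male_limited)
        ],
        "fully_male_linked_positions": [
            (str(cohort.chrom[i]), int(cohort.pos[i])) for i in np.flatnonzero(fully_linked)
        ],
        "marker_positions": [(c, int(p) + 1) for c, p, klass, _ in sites if klass == "marker"],
        "n_y_dropped_unmappable": len(rest) - len(y_in_s1),
        "stratum2_frac": stratum2_frac,
        "stratum1_mappable_frac": stratum1_mappable_frac,
        "y_haplotype_column": "hap2 of males",
    }
    return cohort, truth


def sex_labels(pop: SampledPopulation) -> SexLabels:
    return SexLabels(dict(pop.individuals))


def split_populations(pop: SampledPopulation, names: tuple[str, str] = ("down", "up")) -> dict[str, str]:
    """Assign sampled individuals alternately to two population labels.

    The sample comes from one panmictic population, so this emulates a
    fully connected downstream/upstream pair — the limiting case in which
    Y haplotypes are shared between populations.
    """
    out = {}
    for sex in ("M", "F"):
        inds = [i for i, s in pop.individuals if s == sex]
        for r, i in enumerate(inds):
            out[i] = names[r % 2]
    return out


# ---------------------------------------------------------------------------
# depth synthesis


def synth_depth(
    layout: SimLayout,
    individuals: list[tuple[str, str]],
    mean_depth: dict[str, float] | None = None,
    degeneracy_factor: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-window median depths: Poisson around the sex mean, with male
    windows overlapping degenerate intervals scaled by ``degeneracy_factor``
    (default 0.75: one of the two male haplotypes contributes half coverage
    over the Y-divergent half of the interval).

    Returns an individual x window DataFrame aligned with ``layout.grid()``.
    """
    if degeneracy_factor < 0:
        raise ValueError("degeneracy_factor must be >= 0")
    mean_depth = mean_depth or {"M": 30.0, "F": 20.0}
    rng = np.random.default_rng(seed)
    grid = layout.grid()
    degen = np.zeros(len(grid), dtype=bool)
    for i, (c, s, e) in enumerate(grid.windows):
        if c == layout.sex_chrom:
            for ds, de in layout.degenerate_subintervals:
                if s < de and e > ds:
                    degen[i] = True
    rows = {}
    for name, sex in individuals:
        mu = np.full(len(grid), float(mean_depth[sex]))
        if sex == "M":
            mu[degen] *= degeneracy_factor
        rows[name] = rng.poisson(mu).astype(float)
    return pd.DataFrame(rows, index=grid.index()).T


# ---------------------------------------------------------------------------
# sequence synthesis


def synth_sequences(
    cohort: CohortVariantSet,
    pop: SampledPopulation,
    layout: SimLayout,
    lineage_of: dict[str, int],
    y_insertion_length: int = 200,
    lineage_variants: int = 2,
    seed: int = 0,
    k: int = 21,
) -> tuple[dict[str, str], dict[str, dict[str, str]], dict]:
    """Per-individual haplotype FASTA sequences with a planted Y-only insertion.

    Builds a random reference per chromosome whose base at every variant
    position equals the cohort REF allele, applies each individual's phased
    alleles to both haplotypes, and inserts a Y-only segment of
    ``y_insertion_length`` bp (with ``lineage_variants`` lineage-specific
    substitutions) into each male's Y haplotype inside stratum I.

    Returns (reference, sequences, manifest): ``sequences`` maps individual
    -> {record name -> sequence}; the manifest lists, per lineage, the
    canonical k-mers fully contained in the planted insertion
    (length - k + 1 of them) — junction k-mers spanning the insertion
    boundaries are also Y-only but are not counted in the manifest.
    """
    from .ymer import canonical

    if y_insertion_length < 0:
        raise ValueError("insertion length must be >= 0")
    if y_insertion_length > layout.stratum1[1] - layout.stratum1[0]:
        raise ValueError("insertion longer than stratum I")
    rng = np.random.default_rng(seed)

    reference: dict[str, str] = {}
    for chrom, L in layout.chrom_lengths.items():
        seq = rng.integers(0, 4, L)
        reference[chrom] = "".join(_BASES[seq])
    # force reference base = REF allele at variant positions
    ref_arrays = {c: np.array(list(s)) for c, s in reference.items()}
    for i in range(cohort.n_sites):
        ref_arrays[str(cohort.chrom[i])][int(cohort.pos[i]) - 1] = str(cohort.ref[i])
    reference = {c: "".join(a) for c, a in ref_arrays.items()}

    ref_kmers = {canonical(reference[c][i : i + k]) for c in reference
                 for i in range(0, len(reference[c]) - k + 1)} if y_insertion_length else set()

    # insertion: base segment plus lineage-specific substitutions, all k-mers novel
    insert_point = layout.degenerate_subintervals[0][0] + (
        layout.degenerate_subintervals[0][1] - layout.degenerate_subintervals[0][0]
    ) // 2
    lineage_inserts: dict[int, str] = {}
    planted: dict[int, list[str]] = {}
    if y_insertion_length >= 1:
        for _attempt in range(50):
            base = "".join(_BASES[rng.integers(0, 4, y_insertion_length)])
            ok = True
            lineage_inserts = {}
            for lineage in sorted(set(lineage_of.values())):
                s = list(base)
                if y_insertion_length >= k:
                    for _ in range(lineage_variants):
                        p = int(rng.integers(0, y_insertion_length))
                        s[p] = "ACGT"[(("ACGT".index(s[p])) + 1 + int(rng.integers(0, 3))) % 4]
                ins = "".join(s)
                kms = [canonical(ins[i : i + k]) for i in range(0, max(len(ins) - k + 1, 0))]
                if any(km in ref_kmers for km in kms):
                    ok = False
                    break
                lineage_inserts[lineage] = ins
            if ok:
                break
        else:
            raise RuntimeError("could not draw an insertion with novel k-mers")
        for lineage, ins in lineage_inserts.items():
            planted[lineage] = [canonical(ins[i : i + k]) for i in range(0, max(len(ins) - k + 1, 0))]

    by_chrom: dict[str, list[int]] = {}
    for i in range(cohort.n_sites):
        by_chrom.setdefault(str(cohort.chrom[i]), []).append(i)

    sequences: dict[str, dict[str, str]] = {}
    for j, (name, sex) in enumerate(pop.individuals):
        recs: dict[str, str] = {}
        for chrom in layout.chrom_lengths:
            base = ref_arrays[chrom]
            for h in (0, 1):
                arr = base.copy()
                for i in by_chrom.get(chrom, []):
                    if cohort.hap[i, 2 * j + h] == 1:
                        arr[int(cohort.pos[i]) - 1] = str(cohort.alt[i])
                seq = "".join(arr)
                if (
                    sex == "M"
                    and h == 1
                    and chrom == layout.sex_chrom
                    and y_insertion_length >= 1
                ):
                    ins = lineage_inserts[lineage_of[name]]
                    seq = seq[:insert_point] + ins + seq[insert_point:]
                recs[f"{name}_{chrom}_h{h + 1}"] = seq
        sequences[name] = recs

    manifest = {
        "insert_point_0based": insert_point,
        "y_insertion_length": y_insertion_length,
        "k": k,
        "planted_kmers_per_lineage": {str(l): kms for l, kms in planted.items()},
        "planted_count_per_lineage": {str(l): len(kms) for l, kms in planted.items()},
        "junction_kmers_counted": False,
    }
    return reference, sequences, manifest


def kmer_tables_with_coverage(
    sequences: dict[str, dict[str, str]],
    k: int = 21,
    mean_coverage: float = 30.0,
    error_kmers: int = 50,
    seed: int = 0,
):
    """Read-like k-mer count tables: per-copy counts scaled by Poisson coverage.

    Counting k-mers on assembled haplotypes gives per-copy multiplicities;
    sequencing reads observe each copy ~coverage times.  Each k-mer's count
    is drawn Poisson(copies * mean_coverage), and ``error_kmers`` random
    k-mers with counts 1-2 emulate sequencing-error k-mers below the
    presence floor.
    """
    from .ymer import KmerTable, count_kmers

    rng = np.random.default_rng(seed)
    tables = []
    for name, recs in sequences.items():
        t = count_kmers(recs, k=k, individual=name)
        counts = rng.poisson(t.counts * mean_coverage).astype(np.int64)
        kmers = t.kmers[counts > 0]
        counts = counts[counts > 0]
        if error_kmers:
            errs = rng.integers(0, 4 ** k, size=error_kmers, dtype=np.uint64)
            ecounts = rng.integers(1, 3, size=error_kmers).astype(np.int64)
            allk = np.concatenate([kmers, errs])
            allc = np.concatenate([counts, ecounts])
            order = np.argsort(allk, kind="stable")
            allk, allc = allk[order], allc[order]
            kmers, idx = np.unique(allk, return_index=True)
            counts = np.add.reduceat(allc, idx)
        tables.append(KmerTable(individual=name, k=k, kmers=kmers, counts=counts))
    return tables


# ---------------------------------------------------------------------------
# linked-read molecule synthesis


def synth_molecules(
    pop: SampledPopulation,
    layout: SimLayout,
    molecule_length: tuple[int, int] = (20_000, 60_000),
    n_per_individual: int = 2000,
    y_inversion: tuple[int, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniformly placed long molecules per haplotype, barcode-tagged.

    With ``y_inversion`` = (a, b) on the sex chromosome, molecules from the
    male Y haplotype that cross a breakpoint produce two reference-space
    footprints (the in-inversion part maps to mirrored coordinates), which
    is exactly the distant same-barcode signal an inversion leaves in
    linked reads.  Females and male X haplotypes never carry it.
    """
    lo, hi = molecule_length
    if not 0 < lo < hi:
        raise ValueError("molecule_length must be an increasing positive pair")
    if y_inversion is not None:
        a, b = y_inversion
        s1 = layout.stratum1
        if not (s1[0] <= a < b <= s1[1]):
            raise ValueError("y_inversion must lie within stratum I")
    rng = np.random.default_rng(seed)
    chroms = list(layout.chrom_lengths)
    lens = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()

    rows = []
    bc = 0
    for name, sex in pop.individuals:
        ci = rng.choice(len(chroms), size=n_per_individual, p=probs)
        hs = rng.integers(1, 3, size=n_per_individual)
        ls = rng.integers(lo, hi + 1, size=n_per_individual)
        for t in range(n_per_individual):
            chrom = chroms[ci[t]]
            L = layout.chrom_lengths[chrom]
            length = int(min(ls[t], L))
            start = int(rng.integers(0, max(L - length, 1)))
            end = start + length
            barcode = f"BX{bc:07d}"
            bc += 1
            h = int(hs[t])
            on_y = sex == "M" and h == 2 and chrom == layout.sex_chrom
            if on_y and y_inversion is not None:
                a, b = y_inversion
                if start < a < end <= b:  # crosses left breakpoint
                    rows.append((barcode, name, chrom, start, a, h))
                    rows.append((barcode, name, chrom, a + b - end, b, h))
                    continue
                if a <= start < b < end:  # crosses right breakpoint
                    rows.append((barcode, name, chrom, a, a + b - start, h))
                    rows.append((barcode, name, chrom, b, end, h))
                    continue
                if start < a and end > b:  # spans the whole inversion
                    rows.append((barcode, name, chrom, start, end, h))
                    continue
            rows.append((barcode, name, chrom, start, end, h))
    df = pd.DataFrame(rows, columns=["barcode", "individual", "chrom", "start", "end", "haplotype"])
    return df


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixtures(out_dir: str | os.PathLike, seed: int = 0,
                   config: WFConfig | None = None, layout: SimLayout | None = None) -> dict:
    """Simulate one cohort and write every downstream input format.

    Emits VCF, sex TSV, strata BED, per-window depth TSV, molecules TSV and
    a JSON truth manifest; returns the manifest (with file paths).  Uses the
    chromosome-scale layout; sequence fixtures live on the small layout and
    are produced by :func:`synth_sequences` directly.
    """
    from . import io as yio

    os.makedirs(out_dir, exist_ok=True)
    config = config or WFConfig(seed=seed)
    layout = layout or default_layout()
    pop = simulate_wf(config)
    cohort, truth = overlay_layout(pop, layout, seed=seed + 1)
    labels = sex_labels(pop)
    depth = synth_depth(layout, pop.individuals, seed=seed + 2)
    molecules = synth_molecules(pop, layout, n_per_individual=200, seed=seed + 3)

    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "sex": os.path.join(out_dir, "sex.tsv"),
        "strata": os.path.join(out_dir, "strata.bed"),
        "depth": os.path.join(out_dir, "depth.tsv"),
        "molecules": os.path.join(out_dir, "molecules.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    yio.write_vcf(cohort, paths["vcf"], contig_lengths=layout.chrom_lengths)
    yio.write_sex_tsv(labels, paths["sex"])
    yio.write_bed(layout.strata_bed(), paths["strata"])
    depth.to_csv(paths["depth"], sep="\t")
    yio.write_molecules_tsv(molecules, paths["molecules"])
    manifest = {"seed": seed, "paths": paths, "truth": truth,
                "chrom_lengths": layout.chrom_lengths}
    with open(paths["truth"], "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
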