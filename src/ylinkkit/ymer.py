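"""Canonical k-mer counting and sex-specific k-mer (Y-mer) discovery.

A canonical k-mer is the lexicographic minimum of a k-mer and its reverse
complement (equivalently the numeric minimum under the A<C<G<T 2-bit
encoding used here).  Y-mers are canonical 21-mers present — above a
per-individual error floor of 3 observations — in males and absent from
every female; the symmetric female-specific set serves as an empirical
false-positive control, since female-limited sequence should not exist in
a male-heterogametic species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_K = 21
PRESENCE_FLOOR = 3
MIN_MEAN_COUNT = 5.0
SCAFFOLD_MIN_YMERS = 100

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def encode_kmers(seq: str, k: int = DEFAULT_K) -> np.ndarray:
    """Canonical k-mers of a sequence as uint64 codes; k-mers touching non-ACGT are skipped."""
    if k < 1 or k > 31:
        raise ValueError("k must be in 1..31")
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    m = len(codes) - k + 1
    if m <= 0:
        return np.zeros(0, dtype=np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    c = codes.astype(np.uint64)
    for i in range(k):
        window = c[i : i + m]
        fwd += window << np.uint64(2 * (k - 1 - i))
        rev += (np.uint64(3) - window) << np.uint64(2 * i)
    invalid = (codes == 255).astype(np.int64)
    run = np.cumsum(np.concatenate([[0], invalid]))
    bad = (run[k:] - run[:-k]) > 0
    canon = np.minimum(fwd, rev)
    return canon[~bad]


def decode_kmer(code: int, k: int = DEFAULT_K) -> str:
    out = []
    for i in range(k):
        out.append("ACGT"[(code >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    comp = str.maketrans("ACGT", "TGCA")
    rc = kmer.upper().translate(comp)[::-1]
    return min(kmer.upper(), rc)


@dataclass
class KmerTable:
    """Sorted canonical k-mer codes with counts, for one individual."""

    individual: str
    k: int
    kmers: np.ndarray  # uint64, sorted ascending
    counts: np.ndarray  # int64, aligned with kmers

    def present(self, floor: int = 1) -> np.ndarray:
        return self.kmers[self.counts >= floor]

    def as_dict(self) -> dict[str, int]:
        return {decode_kmer(int(km), self.k): int(c) for km, c in zip(self.kmers, self.counts)}


def count_kmers(sequences: list[str] | dict[str, str], k: int = DEFAULT_K,
                individual: str = "sample") -> KmerTable:
    """Count canonical k-mers over all sequences of one individual."""
    if isinstance(sequences, dict):
        sequences = list(sequences.values())
    chunks = [encode_kmers(s, k) for s in sequences]
    allk = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.uint64)
    kmers, counts = np.unique(allk, return_counts=True)
    return KmerTable(individual=individual, k=k, kmers=kmers, counts=counts.astype(np.int64))


@dataclass
class SexSpecificKmerSet:
    direction: str  # "male" or "female"
    k: int
    kmers: np.ndarray  # uint64 codes
    n_carriers: np.ndarray
    mean_counts: np.ndarray
    presence_floor: int
    min_carriers: int
    min_mean: float

    def __len__(self) -> int:
        return len(self.kmers)

    def as_strings(self) -> list[str]:
        return [decode_kmer(int(km), self.k) for km in self.kmers]


def find_sex_specific(
    tables: list[KmerTable],
    sex_of: dict[str, str],
    direction: str = "male",
    presence_floor: int = PRESENCE_FLOOR,
    min_carriers: int = 1,
    min_mean: float = MIN_MEAN_COUNT,
) -> SexSpecificKmerSet:
    """k-mers present in >= ``min_carriers`` same-sex individuals and in no
    opposite-sex individual, with mean raw count across all same-sex
    individuals strictly above ``min_mean``.

    Presence means count >= ``presence_floor`` (counts below the floor are
    treated as sequencing-error absences, in both sexes).
    """
    if direction not in ("male", "female"):
        raise ValueError("direction must be 'male' or 'female'")
    want = "M" if direction == "male" else "F"
    same = [t for t in tables if sex_of[t.individual] == want]
    other = [t for t in tables if sex_of[t.individual] != want]
    if not same or not other:
        raise ValueError("need at least one individual of each sex")
    k = tables[0].k

    same_present = [t.present(presence_floor) for t in same]
    cand, carriers = np.unique(np.concatenate(same_present), return_counts=True)
    if cand.size:
        other_present = np.unique(
            np.concatenate([t.present(presence_floor) for t in other])
            if other
            else np.zeros(0, dtype=np.uint64)
        )
        keep = ~np.isin(cand, other_present)
        cand, carriers = cand[keep], carriers[keep]

    # mean raw count across all same-sex individuals (zeros for absentees)
    sums = np.zeros(cand.size, dtype=np.float64)
    for t in same:
        if t.kmers.size == 0:
            continue
        pos = np.searchsorted(t.kmers, cand)
        pos_ok = (pos < t.kmers.size) & (t.kmers[np.minimum(pos, t.kmers.size - 1)] == cand)
        sums[pos_ok] += t.counts[pos[pos_ok]]
    means = sums / len(same)

    keep = (carriers >= min_carriers) & (means > min_mean)
    return SexSpecificKmerSet(
        direction=direction,
        k=k,
        kmers=cand[keep],
        n_carriers=carriers[keep],
        mean_counts=means[keep],
        presence_floor=presence_floor,
        min_carriers=min_carriers,
        min_mean=min_mean,
    )


def calibrate_fpr(
    tables: list[KmerTable],
    sex_of: dict[str, str],
    carrier_thresholds: list[int] | None = None,
    presence_floor: int = PRESENCE_FLOOR,
    min_mean: float = MIN_MEAN_COUNT,
    max_fpr: float = 0.05,
):
    """Sweep the carrier threshold; FPR = female-specific / male-specific counts.

    Returns (chosen_min_carriers or None, curve) where curve is a list of
    (threshold, n_male_specific, n_female_specific, fpr); fpr is NaN when no
    male-specific k-mers survive the threshold.  The chosen threshold is the
    smallest with FPR < ``max_fpr``.
    """
    if not tables:
        raise ValueError("no k-mer tables supplied")
    n_males = sum(1 for t in tables if sex_of[t.individual] == "M")
    if carrier_thresholds is None:
        carrier_thresholds = list(range(1, n_males + 1))
    curve = []
    chosen = None
    for thr in carrier_thresholds:
        n_m = len(find_sex_specific(tables, sex_of, "male", presence_floor, thr, min_mean))
        n_f = len(find_sex_specific(tables, sex_of, "female", presence_floor, thr, min_mean))
        fpr = n_f / n_m if n_m > 0 else float("nan")
        curve.append((thr, n_m, n_f, fpr))
        if chosen is None and n_m > 0 and fpr < max_fpr:
            chosen = thr
    return chosen, curve


@dataclass
class ScaffoldHits:
    counts: dict[str, int]  # scaffold -> unique-match Y-mer count
    enriched: dict[str, bool]
    n_non_unique: int


def map_to_scaffolds(
    kmer_set: SexSpecificKmerSet,
    scaffolds: dict[str, str],
    min_ymers: int = SCAFFOLD_MIN_YMERS,
    homolog_of: dict[str, str] | None = None,
) -> ScaffoldHits:
    """Exact-match Y-mers against scaffolds (both orientations, via canonical codes).

    k-mers matching more than one scaffold are excluded from the unique
    counts.  A scaffold is enriched when its unique count reaches
    ``min_ymers`` and, if a homologous haplotype scaffold is named in
    ``homolog_of``, exceeds that homolog's count.
    """
    target = kmer_set.kmers
    hit_count = np.zeros(target.size, dtype=np.int64)
    per_scaffold_mask = {}
    for name, seq in scaffolds.items():
        present = np.unique(encode_kmers(seq, kmer_set.k))
        mask = np.isin(target, present)
        per_scaffold_mask[name] = mask
        hit_count += mask
    unique = hit_count == 1
    counts = {name: int((mask & unique).sum()) for name, mask in per_scaffold_mask.items()}
    enriched = {}
    for name, c in counts.items():
        ok = c >= min_ymers
        if homolog_of and name in homolog_of and homolog_of[name] in counts:
            ok = ok and c > counts[homolog_of[name]]
        enriched[name] = ok
    return ScaffoldHits(counts=counts, enriched=enriched, n_non_unique=int((hit_count > 1).sum()))
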