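"""Linked-read barcode co-occurrence scan for sex-specific rearrangements.

Long input molecules tagged by a droplet barcode span tens of kb; when a
haplotype carries an inversion relative to the reference, molecules crossing
a breakpoint align as split footprints, so the same barcode recurs in two
distant windows.  A Y-linked inversion therefore produces a distant
window-pair with shared barcodes in most males and no females.

The statistic here is a deliberate reconstruction, not a replication, of
the qualitative linked-read scan: per individual, count barcodes whose
molecules touch both windows of a pair separated by at least ``min_gap``;
call a pair sex-differential when it has support in at least
``min_male_frac`` of males and at most ``max_female_frac`` of females (or
the reverse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SexLabels
from .covwin import WindowGrid

DEFAULT_MIN_GAP = 1_000_000
DEFAULT_MIN_MALE_FRAC = 0.8
DEFAULT_MAX_FEMALE_FRAC = 0.1


@dataclass
class BarcodeLinkMatrix:
    individual: str
    grid: WindowGrid
    pair_counts: dict[tuple[int, int], int]  # (window i, window j), i < j, distant pairs only
    window_totals: np.ndarray  # barcodes touching each window

    def normalized(self) -> dict[tuple[int, int], float]:
        out = {}
        for (i, j), c in self.pair_counts.items():
            denom = min(self.window_totals[i], self.window_totals[j])
            out[(i, j)] = c / denom if denom > 0 else 0.0
        return out


def _window_span(grid: WindowGrid, chrom: str, start: int, end: int) -> list[int]:
    """Indices of grid windows overlapped by [start, end) on chrom."""
    hits = []
    for i, (c, s, e) in enumerate(grid.windows):
        if c == chrom and start < e and end > s:
            hits.append(i)
    return hits


def link_matrix(molecules: pd.DataFrame, grid: WindowGrid, min_gap: int = DEFAULT_MIN_GAP,
                individual: str | None = None) -> BarcodeLinkMatrix:
    """Distant-window shared-barcode counts for one individual.

    ``molecules`` columns: barcode, individual, chrom, start, end (0-based
    half-open).  For each barcode, all windows its molecules overlap are
    collected; every same-chromosome window pair whose start coordinates
    differ by >= ``min_gap`` increments the pair count.
    """
    if individual is not None:
        molecules = molecules[molecules["individual"] == individual]
    else:
        inds = molecules["individual"].unique()
        if len(inds) != 1:
            raise ValueError("pass individual= when the table holds several individuals")
        individual = str(inds[0])

    window_barcodes: dict[int, set] = {}
    barcode_windows: dict[str, set[int]] = {}
    for bc, chrom, start, end in molecules[["barcode", "chrom", "start", "end"]].itertuples(index=False):
        for w in _window_span(grid, str(chrom), int(start), int(end)):
            barcode_windows.setdefault(str(bc), set()).add(w)
            window_barcodes.setdefault(w, set()).add(str(bc))

    pair_counts: dict[tuple[int, int], int] = {}
    for bc, wins in barcode_windows.items():
        ws = sorted(wins)
        for a in range(len(ws)):
            ca, sa, _ = grid.windows[ws[a]]
            for b in range(a + 1, len(ws)):
                cb, sb, _ = grid.windows[ws[b]]
                if ca == cb and abs(sb - sa) >= min_gap:
                    key = (ws[a], ws[b])
                    pair_counts[key] = pair_counts.get(key, 0) + 1

    totals = np.zeros(len(grid), dtype=np.int64)
    for w, bcs in window_barcodes.items():
        totals[w] = len(bcs)
    return BarcodeLinkMatrix(individual=individual, grid=grid,
                             pair_counts=pair_counts, window_totals=totals)


def sex_differential_links(
    matrices: list[BarcodeLinkMatrix],
    labels: SexLabels,
    min_male_frac: float = DEFAULT_MIN_MALE_FRAC,
    max_female_frac: float = DEFAULT_MAX_FEMALE_FRAC,
    min_pair_count: int = 1,
) -> pd.DataFrame:
    """Distant window pairs supported in one sex and absent from the other.

    An individual supports a pair when its shared-barcode count reaches
    ``min_pair_count``.  A pair is called when the supporting fraction is
    >= ``min_male_frac`` in one sex and <= ``max_female_frac`` in the other
    (either direction).  Returns a tidy frame: chrom, winA_start, winB_start,
    n_males_support, n_females_support, n_males, n_females, direction.
    """
    inds = [m.individual for m in matrices]
    male, female = labels.masks(inds)
    n_m, n_f = int(male.sum()), int(female.sum())
    if n_m == 0 or n_f == 0:
        raise ValueError("need linked-read matrices for both sexes")
    grid = matrices[0].grid

    support: dict[tuple[int, int], np.ndarray] = {}
    for k, m in enumerate(matrices):
        for pair, c in m.pair_counts.items():
            if c >= min_pair_count:
                support.setdefault(pair, np.zeros(len(matrices), dtype=bool))[k] = True

    rows = []
    for (i, j), vec in sorted(support.items()):
        ms = int(vec[male].sum())
        fs = int(vec[female].sum())
        male_called = ms / n_m >= min_male_frac and fs / n_f <= max_female_frac
        female_called = fs / n_f >= min_male_frac and ms / n_m <= max_female_frac
        if male_called or female_called:
            chrom, sa, _ = grid.windows[i]
            _, sb, _ = grid.windows[j]
            rows.append((chrom, sa, sb, ms, fs, n_m, n_f, "male" if male_called else "female"))
    return pd.DataFrame(
        rows,
        columns=["chrom", "winA_start", "winB_start", "n_males_support",
                 "n_females_support", "n_males", "n_females", "direction"],
    )
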