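"""Windowed coverage and interval-density tracks.

The degeneration scan works on median per-site read depth in non-overlapping
windows (50 kb by default), normalized per individual by their genome-wide
median window depth; Y degeneration then shows up as a depressed
male:female ratio of window means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SexLabels

DEFAULT_WINDOW = 50_000


@dataclass
class WindowGrid:
    """Non-overlapping, sorted windows tiling each chromosome (0-based half-open)."""

    windows: list[tuple[str, int, int]]
    width: int = DEFAULT_WINDOW

    @classmethod
    def tile(cls, chrom_lengths: dict[str, int], width: int = DEFAULT_WINDOW) -> "WindowGrid":
        wins = []
        for chrom, length in chrom_lengths.items():
            for start in range(0, length, width):
                wins.append((chrom, start, min(start + width, length)))
        return cls(windows=wins, width=width)

    def __len__(self) -> int:
        return len(self.windows)

    def index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_tuples(self.windows, names=["chrom", "start", "end"])

    def locate(self, chrom: str, pos0: int) -> int | None:
        """Index of the window containing 0-based position ``pos0``, or None."""
        for i, (c, s, e) in enumerate(self.windows):
            if c == chrom and s <= pos0 < e:
                return i
        return None


@dataclass
class CoverageTable:
    """Individual x window depth matrix with per-individual normalizers.

    ``values`` holds median per-site depth per window (NaN for empty
    windows); after :func:`normalize_coverage`, values are dimensionless
    and ``normalizers`` records the genome-wide median window depth used.
    """

    values: pd.DataFrame  # rows: individuals, columns: grid MultiIndex
    grid: WindowGrid
    normalizers: pd.Series | None = None

    @property
    def normalized(self) -> bool:
        return self.normalizers is not None


def window_median_depth(depths: dict[str, pd.DataFrame], grid: WindowGrid) -> CoverageTable:
    """Median per-site depth in each window, per individual.

    ``depths`` maps individual -> DataFrame with columns (chrom, pos, depth),
    pos 1-based.  Positions absent from the table count as uncovered only if
    absent; the median is over reported sites (windows without any reported
    site are NaN).
    """
    idx = grid.index()
    rows = {}
    for ind, df in depths.items():
        vals = np.full(len(grid), np.nan)
        for i, (chrom, start, end) in enumerate(grid.windows):
            sel = df[(df["chrom"] == chrom) & (df["pos"] - 1 >= start) & (df["pos"] - 1 < end)]
            if len(sel):
                vals[i] = float(np.median(sel["depth"]))
        rows[ind] = vals
    return CoverageTable(values=pd.DataFrame(rows, index=idx).T, grid=grid)


def coverage_from_windowed(table: pd.DataFrame, grid: WindowGrid) -> CoverageTable:
    """Wrap an already-windowed individual x window depth table."""
    table = table.copy()
    table.columns = grid.index()
    return CoverageTable(values=table, grid=grid)


def normalize_coverage(table: CoverageTable) -> CoverageTable:
    """Divide each individual's windows by their genome-wide median window depth."""
    med = table.values.median(axis=1, skipna=True)
    if (med == 0).any() or med.isna().any():
        bad = med.index[(med == 0) | med.isna()].tolist()
        raise ValueError(f"zero or undefined median depth for individuals {bad}")
    return CoverageTable(values=table.values.div(med, axis=0), grid=table.grid, normalizers=med)


def mf_ratio(table: CoverageTable, labels: SexLabels, log2: bool = False) -> pd.DataFrame:
    """Per-window male:female ratio of mean normalized depth.

    Uses the ratio of sex means (robust to unequal sample sizes).  Returns a
    tidy frame chrom, start, end, ratio (log2-ratio when ``log2``).
    """
    inds = list(table.values.index)
    male, female = labels.masks(inds)
    if male.sum() == 0:
        raise ValueError("no males in coverage table")
    if female.sum() == 0:
        raise ValueError("no females in coverage table")
    m = table.values.iloc[np.flatnonzero(male)].mean(axis=0, skipna=True)
    f = table.values.iloc[np.flatnonzero(female)].mean(axis=0, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m / f
        if log2:
            ratio = np.log2(ratio)
    out = pd.DataFrame(list(table.values.columns), columns=["chrom", "start", "end"])
    out["ratio"] = np.asarray(ratio, dtype=float)
    return out


def merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent intervals per chromosome."""
    out: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def feature_density(intervals: list[tuple[str, int, int]], grid: WindowGrid) -> pd.DataFrame:
    """Covered bp per window for a set of (merged) intervals, e.g. TE annotations.

    Overlapping input intervals are merged first so each base counts once;
    intervals spanning window boundaries contribute the overlapping part to
    each window.  Returns chrom, start, end, covered_bp.
    """
    merged = merge_intervals(intervals) if intervals else []
    covered = np.zeros(len(grid), dtype=np.int64)
    for chrom, s, e in merged:
        for i, (wc, ws, we) in enumerate(grid.windows):
            if wc != chrom:
                continue
            ov = min(e, we) - max(s, ws)
            if ov > 0:
                covered[i] += ov
    out = pd.DataFrame(grid.windows, columns=["chrom", "start", "end"])
    out["covered_bp"] = covered
    return out
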