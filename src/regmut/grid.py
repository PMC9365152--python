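"""Genomic window grid and per-window epigenome track profiles.

The coordinate frame for the whole pipeline is a set of non-overlapping,
fixed-size genomic windows (1 Mbp by default, 100 kbp for fine-grained
analyses). Coverage tracks (ATAC-seq chromatin accessibility, RepliSeq
replication timing) are reduced to one mean signal value per window;
somatic mutation counts use the same frame.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Chromatin-accessibility / replication-timing predictor classes.
FEATURE_CLASSES = ("cancer_CA", "normal_CA", "cancer_cell_line_CA", "RT")

#: RepliSeq cell-cycle phases, ordered from early to late replication.
RT_PHASES = ("G1b", "S1", "S2", "S3", "S4", "G2")


@dataclass(frozen=True)
class WindowGrid:
    """Ordered, non-overlapping, fixed-size genomic windows.

    Attributes
    ----------
    chroms, starts, ends
        Parallel arrays defining each window, sorted by (chrom, start).
    window_size
        Nominal window length in bp; ``end - start == window_size`` for
        every window (trailing chromosome remainders are dropped).
    mappability
        Fraction of uniquely mappable bases per window, in [0, 1].
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    window_size: int
    mappability: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "chroms", np.asarray(self.chroms, dtype=object))
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=np.int64))
        object.__setattr__(self, "ends", np.asarray(self.ends, dtype=np.int64))
        if self.mappability is None:
            object.__setattr__(self, "mappability", np.ones(len(self.starts)))
        else:
            object.__setattr__(
                self, "mappability", np.asarray(self.mappability, dtype=float)
            )
        self._validate()

    def _validate(self) -> None:
        n = len(self.starts)
        if not (len(self.chroms) == len(self.ends) == len(self.mappability) == n):
            raise ValueError("grid arrays must have equal length")
        if np.any(self.ends - self.starts != self.window_size):
            raise ValueError("every window must span exactly window_size bp")
        if np.any((self.mappability < 0) | (self.mappability > 1)):
            raise ValueError("mappability must lie in [0, 1]")
        # sorted by (chrom, start) with non-overlap within chromosome
        for chrom in pd.unique(self.chroms):
            s = self.starts[self.chroms == chrom]
            if np.any(np.diff(s) < self.window_size):
                raise ValueError(f"overlapping or unsorted windows on {chrom}")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def labels(self) -> np.ndarray:
        """Window names formatted ``chrom:start-end``."""
        return np.array(
            [f"{c}:{s}-{e}" for c, s, e in zip(self.chroms, self.starts, self.ends)],
            dtype=object,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "mappability": self.mappability,
            }
        )

    def with_mappability(self, mappability: Sequence[float]) -> "WindowGrid":
        return replace(self, mappability=np.asarray(mappability, dtype=float))

    def subset(self, mask: np.ndarray) -> "WindowGrid":
        mask = np.asarray(mask, dtype=bool)
        return WindowGrid(
            self.chroms[mask],
            self.starts[mask],
            self.ends[mask],
            self.window_size,
            self.mappability[mask],
        )

    def window_index(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Map 0-based positions to window indices; -1 where not covered.

        Uses per-chromosome binary search over the sorted window starts,
        so it works on filtered (non-contiguous) grids too.
        """
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos0, dtype=np.int64)
        out = np.full(len(pos0), -1, dtype=np.int64)
        for c in pd.unique(chrom):
            sel = chrom == c
            cidx = np.flatnonzero(self.chroms == c)
            if len(cidx) == 0:
                continue
            starts = self.starts[cidx]
            j = np.searchsorted(starts, pos0[sel], side="right") - 1
            ok = (j >= 0) & (pos0[sel] < self.ends[cidx][np.clip(j, 0, None)])
            res = np.full(sel.sum(), -1, dtype=np.int64)
            res[ok] = cidx[j[ok]]
            out[sel] = res
        return out


@dataclass
class TrackProfile:
    """One epigenome feature reduced to per-window mean signal.

    ``feature_class`` distinguishes chromatin accessibility of primary
    cancers, normal tissues and cancer cell lines from replication-timing
    profiles; RT profiles additionally carry their cell-cycle phase.
    """

    track_id: str
    feature_class: str
    tissue: str
    values: np.ndarray
    rt_phase: str | None = None

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature_class {self.feature_class!r}")
        if (self.feature_class == "RT") != (self.rt_phase is not None):
            raise ValueError("rt_phase must be set iff feature_class is RT")
        if self.rt_phase is not None and self.rt_phase not in RT_PHASES:
            raise ValueError(f"unknown RT phase {self.rt_phase!r}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"track {self.track_id}: values must be finite")


def build_windows(chrom_sizes: Mapping[str, int], window_size: int) -> WindowGrid:
    """Tile each chromosome with consecutive fixed-size windows.

    Windows are ``[0, w), [w, 2w), ...``; a trailing remainder shorter
    than ``window_size`` is dropped so all windows have equal length.

    Parameters
    ----------
    chrom_sizes
        Mapping of chromosome name to length in bp.
    window_size
        Window length in bp (e.g. 1_000_000 or 100_000).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if len(chrom_sizes) == 0:
        raise ValueError("no chromosomes")
    chroms, starts = [], []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        n = int(length) // window_size
        chroms.extend([chrom] * n)
        starts.extend(range(0, n * window_size, window_size))
    starts_arr = np.asarray(starts, dtype=np.int64)
    return WindowGrid(
        np.asarray(chroms, dtype=object),
        starts_arr,
        starts_arr + window_size,
        window_size,
    )


def filter_windows(
    grid: WindowGrid,
    min_mappability: float = 0.8,
    exclude: Iterable[tuple[str, int]] = (),
) -> WindowGrid:
    """Drop low-mappability windows and explicitly excluded windows.

    A window is kept iff its mappability is strictly greater than
    ``min_mappability`` (windows at exactly the threshold are removed)
    and its (chrom, start) is not listed in ``exclude``. The exclude list
    is how immunoglobulin regions with intrinsically high somatic
    variation are removed for lymphoid cohorts.
    """
    keep = grid.mappability > min_mappability
    excl = set((str(c), int(s)) for c, s in exclude)
    if excl:
        matched = set()
        for i, (c, s) in enumerate(zip(grid.chroms, grid.starts)):
            if (str(c), int(s)) in excl:
                keep[i] = False
                matched.add((str(c), int(s)))
        for miss in excl - matched:
            logger.warning("exclude entry %s matches no window", miss)
    return grid.subset(keep)


def aggregate_track(coverage: pd.DataFrame, grid: WindowGrid) -> np.ndarray:
    """Length-weighted mean signal per window from bedGraph-style intervals.

    ``coverage`` must have columns (chrom, start, end, value) with 0-based
    half-open intervals. Bases not covered by any interval contribute
    signal 0, matching the sparse bedGraph convention; intervals running
    past the last window of a chromosome are clipped with a warning.
    Returns one value per grid window.
    """
    required = {"chrom", "start", "end", "value"}
    if not required.issubset(coverage.columns):
        raise ValueError(f"coverage needs columns {sorted(required)}")
    acc = np.zeros(len(grid), dtype=float)
    clipped = 0
    for chrom, sub in coverage.groupby("chrom", sort=False):
        cidx = np.flatnonzero(grid.chroms == chrom)
        if len(cidx) == 0:
            continue
        wstart = grid.starts[cidx]
        wend = grid.ends[cidx]
        istart = sub["start"].to_numpy(dtype=np.int64)
        iend = sub["end"].to_numpy(dtype=np.int64)
        vals = sub["value"].to_numpy(dtype=float)
        chrom_end = wend[-1]
        if np.any(iend > chrom_end):
            clipped += int((iend > chrom_end).sum())
            iend = np.minimum(iend, chrom_end)
        ok = iend > istart
        istart, iend, vals = istart[ok], iend[ok], vals[ok]
        # first and last window each interval touches
        first = np.searchsorted(wend, istart, side="right")
        last = np.searchsorted(wstart, iend, side="left") - 1
        for s, e, v, f, l in zip(istart, iend, vals, first, last):
            if l < f:
                continue
            for j in range(f, l + 1):
                ov = min(e, wend[j]) - max(s, wstart[j])
                if ov > 0:
                    acc[cidx[j]] += v * ov
    if clipped:
        logger.warning("clipped %d intervals extending past chromosome end", clipped)
    return acc / grid.window_size


def tracks_to_matrix(
    tracks: Sequence[TrackProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack tracks into a windows x tracks matrix plus a metadata table."""
    if not tracks:
        raise ValueError("no tracks")
    n = len(tracks[0].values)
    for t in tracks:
        if len(t.values) != n:
            raise ValueError(f"track {t.track_id} length mismatch")
    X = pd.DataFrame({t.track_id: t.values for t in tracks})
    meta = pd.DataFrame(
        {
            "track_id": [t.track_id for t in tracks],
            "feature_class": [t.feature_class for t in tracks],
            "tissue": [t.tissue for t in tracks],
            "rt_phase": [t.rt_phase if t.rt_phase is not None else "" for t in tracks],
        }
    )
    return X, meta
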