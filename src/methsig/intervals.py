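"""Genomic interval containers with vectorised point queries.

Coordinates are 0-based half-open ``[start, end)`` throughout, matching BED.
The hot operations of the pipeline are "is this probe inside any interval of
this set" and "how far is this probe from the nearest interval edge", asked
for tens of thousands of probes at once, so intervals are stored per
chromosome as sorted (and, for membership queries, merged) numpy arrays and
queried with ``searchsorted``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenomicInterval", "IntervalSet"]


@dataclass(frozen=True)
class GenomicInterval:
    """One genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if not self.start < self.end:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Intervals grouped by chromosome, sorted by start.

    Parameters
    ----------
    df
        DataFrame with columns ``chrom``, ``start``, ``end`` and optionally
        ``name``. Intervals may overlap; membership queries operate on the
        merged union, while :meth:`nearest_edge` uses the raw intervals.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"interval frame needs columns {sorted(required)}")
        df = df.copy()
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy 0 <= start < end")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self._raw: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            self._raw[str(chrom)] = (starts, ends)
            self._merged[str(chrom)] = _merge(starts, ends)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_intervals(cls, intervals: list[GenomicInterval]) -> "IntervalSet":
        return cls(
            pd.DataFrame(
                {
                    "chrom": [iv.chrom for iv in intervals],
                    "start": [iv.start for iv in intervals],
                    "end": [iv.end for iv in intervals],
                    "name": [iv.name for iv in intervals],
                }
            )
            if intervals
            else pd.DataFrame(columns=["chrom", "start", "end", "name"])
        )

    @classmethod
    def read_bed(cls, path) -> "IntervalSet":
        """Read a (headerless) BED3+ file."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name"})
        keep = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
        return cls(df[keep])

    def write_bed(self, path) -> None:
        cols = ["chrom", "start", "end"] + (["name"] if "name" in self.df.columns else [])
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)

    # -- queries ----------------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return list(self._raw)

    def __len__(self) -> int:
        return len(self.df)

    def is_empty(self, chrom: str | None = None) -> bool:
        if chrom is None:
            return len(self.df) == 0
        return chrom not in self._raw

    def contains(self, chrom: str, pos) -> np.ndarray:
        """Vectorised membership: is each position inside any interval?"""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if chrom not in self._merged:
            return np.zeros(pos.shape, dtype=bool)
        starts, ends = self._merged[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(pos.shape, dtype=bool)
        inside[ok] = pos[ok] < ends[idx[ok]]
        return inside

    def nearest_edge(self, chrom: str, pos) -> tuple[np.ndarray, np.ndarray]:
        """Distance to the nearest interval base and the side it lies on.

        Returns ``(distance, side)`` where distance is 0 for positions inside
        an interval, else the gap to the closest covered base; ``side`` is
        ``+1`` when the nearest interval lies at higher coordinates, ``-1``
        when at lower coordinates and ``0`` inside. Ties (equidistant flanking
        intervals) resolve to the lower-coordinate interval (side -1).
        """
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if chrom not in self._merged:
            raise KeyError(f"no intervals on chromosome {chrom!r}")
        starts, ends = self._merged[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        # distance to interval on the left (its last covered base is end-1)
        d_left = np.full(pos.shape, np.iinfo(np.int64).max, dtype=np.int64)
        has_left = idx >= 0
        d_left[has_left] = pos[has_left] - (ends[idx[has_left]] - 1)
        inside = has_left & (d_left <= 0)
        d_left[inside] = 0
        # distance to interval on the right
        nxt = idx + 1
        d_right = np.full(pos.shape, np.iinfo(np.int64).max, dtype=np.int64)
        has_right = nxt < len(starts)
        d_right[has_right] = starts[nxt[has_right]] - pos[has_right]
        dist = np.where(d_left <= d_right, d_left, d_right)
        side = np.where(d_left <= d_right, -1, 1).astype(np.int8)
        side[inside] = 0
        dist[inside] = 0
        return dist, side

    def overlap_fraction(self, chrom_arr, pos_arr) -> np.ndarray:
        """Boolean overlap for arrays of (chrom, pos) pairs across chromosomes."""
        chrom_arr = np.asarray(chrom_arr)
        pos_arr = np.asarray(pos_arr, dtype=np.int64)
        out = np.zeros(pos_arr.shape, dtype=bool)
        for chrom in np.unique(chrom_arr):
            mask = chrom_arr == chrom
            out[mask] = self.contains(str(chrom), pos_arr[mask])
        return out


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted, possibly overlapping intervals into disjoint ones."""
    if len(starts) == 0:
        return starts, ends
    ms, me = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms, dtype=np.int64), np.asarray(me, dtype=np.int64)
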