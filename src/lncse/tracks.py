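"""Binned signal tracks (bigWig-like coverage stored as plain TSV)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SignalTrack", "read_signal_track", "write_signal_track"]


@dataclass
class SignalTrack:
    """Contiguous fixed-width bins over a single chromosome.

    Bin ``i`` covers ``[i * binsize, (i + 1) * binsize)``; ``values[i]`` is the
    mean signal density over that bin.
    """

    chrom: str
    binsize: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.binsize <= 0:
            raise ValueError("binsize must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")

    @property
    def length(self) -> int:
        return self.binsize * len(self.values)

    def region_sum(self, start: int, end: int) -> float:
        """Integral of the signal density over [start, end), overlap-weighted.

        Raises if the region extends past the track (a coverage gap).
        """
        if start < 0 or end > self.length or start >= end:
            raise ValueError(
                f"region [{start}, {end}) not covered by track of length {self.length}"
            )
        b0, b1 = start // self.binsize, (end - 1) // self.binsize
        if b0 == b1:
            return float(self.values[b0] * (end - start))
        total = self.values[b0] * ((b0 + 1) * self.binsize - start)
        total += self.values[b1] * (end - b1 * self.binsize)
        if b1 > b0 + 1:
            total += self.values[b0 + 1 : b1].sum() * self.binsize
        return float(total)

    def slice_values(self, start: int, end: int) -> np.ndarray:
        """Per-bin values for the bins fully or partly inside [start, end)."""
        if start < 0 or end > self.length or start >= end:
            raise ValueError("slice outside track")
        return self.values[start // self.binsize : (end - 1) // self.binsize + 1]


def write_signal_track(track: SignalTrack, path: str | Path) -> None:
    """Three-column TSV: chrom, bin_start, value."""
    import pandas as pd

    starts = np.arange(len(track.values), dtype=np.int64) * track.binsize
    pd.DataFrame({"chrom": track.chrom, "start": starts, "value": track.values}).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.17g"
    )


def read_signal_track(path: str | Path) -> SignalTrack:
    chroms: list[str] = []
    starts: list[int] = []
    vals: list[float] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            c, s, v = line.rstrip("\n").split("\t")[:3]
            chroms.append(c)
            starts.append(int(s))
            vals.append(float(v))
    if not starts:
        raise ValueError(f"empty signal track: {path}")
    if len(set(chroms)) != 1:
        raise ValueError("signal track must cover a single chromosome")
    starts_arr = np.asarray(starts)
    diffs = np.diff(starts_arr)
    if len(diffs) and (diffs <= 0).any():
        raise ValueError("bins must be sorted and contiguous")
    binsize = int(diffs[0]) if len(diffs) else int(starts_arr[0]) or 1
    if len(diffs) and not (diffs == binsize).all():
        raise ValueError("bins must be contiguous with a fixed width")
    if starts_arr[0] != 0:
        raise ValueError("track must start at position 0")
    return SignalTrack(chroms[0], binsize, np.asarray(vals))
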