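"""Fixed-width genomic binning, moving averages, and local-maximum peak calling.

A :class:`BinnedTrack` holds one value array per chromosome with bin ``i``
covering ``[i*bin_size, (i+1)*bin_size)``. Tracks are the substrate for the
hotspot/peak analysis: raw per-bin variant counts are smoothed with a centered
truncated-window moving average, and peaks are strict local maxima of the
smoothed track that clear a fold threshold over the genomic average.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FormatError, GenomeAssembly


@dataclass
class BinnedTrack:
    """Per-chromosome binned values over an assembly."""

    assembly: GenomeAssembly
    bin_size: int
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for name, length in self.assembly.chromosomes:
            n = -(-length // self.bin_size)  # ceil division
            arr = np.asarray(self.values[name], dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name}: expected {n} bins, got {arr.shape}")
            self.values[name] = arr

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def bin_center(self, chrom: str, bin_index: int) -> int:
        """Midpoint of a bin, clipped to the chromosome for the terminal bin."""
        center = bin_index * self.bin_size + self.bin_size // 2
        return min(center, self.assembly.length_of(chrom) - 1)

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            self.assembly, self.bin_size, {c: v.copy() for c, v in self.values.items()}
        )

    def same_grid(self, other: "BinnedTrack") -> bool:
        return self.assembly == other.assembly and self.bin_size == other.bin_size


@dataclass(frozen=True)
class Peak:
    """A called local maximum on a smoothed track."""

    chrom: str
    bin_index: int
    center_pos: int
    height: float
    fold_over_mean: float


def bin_counts(
    positions: Mapping[str, Sequence[int] | np.ndarray],
    assembly: GenomeAssembly,
    bin_size: int,
) -> BinnedTrack:
    """Count positions into fixed-width bins: bin of ``p`` is ``p // bin_size``."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    values: dict[str, np.ndarray] = {}
    for name, length in assembly.chromosomes:
        n = -(-length // bin_size)
        pos = np.asarray(positions.get(name, []), dtype=np.int64)
        if pos.size and (pos.min() < 0 or pos.max() >= length):
            raise ValueError(f"position outside chromosome {name}")
        values[name] = np.bincount(pos // bin_size, minlength=n).astype(float)
    return BinnedTrack(assembly, bin_size, values)


def moving_average(track: BinnedTrack, span_bins: int) -> BinnedTrack:
    """Centered moving average with truncated windows at chromosome edges.

    ``span_bins`` must be odd so the window is symmetric; at the edges the
    window shrinks to the in-bounds bins and the mean divides by the truncated
    window size (no zero padding).
    """
    if span_bins < 1 or span_bins % 2 == 0:
        raise ValueError("span_bins must be a positive odd integer")
    half = span_bins // 2
    out: dict[str, np.ndarray] = {}
    for chrom, vals in track.values.items():
        n = len(vals)
        cs = np.concatenate([[0.0], np.cumsum(vals)])
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, n)
        out[chrom] = (cs[hi] - cs[lo]) / (hi - lo)
    return BinnedTrack(track.assembly, track.bin_size, out)


def _bin_midpoints(track: BinnedTrack, chrom: str) -> np.ndarray:
    n = track.n_bins(chrom)
    centers = np.arange(n, dtype=np.int64) * track.bin_size + track.bin_size // 2
    return np.minimum(centers, track.assembly.length_of(chrom) - 1)


def _mask_array(track: BinnedTrack, mask: Sequence[tuple[str, int, int]]) -> dict[str, np.ndarray]:
    """Boolean per-chromosome arrays: True where the bin midpoint is masked."""
    masked = {c: np.zeros(track.n_bins(c), dtype=bool) for c in track.values}
    for chrom, start, end in mask:
        if chrom not in track.values:
            continue
        mid = _bin_midpoints(track, chrom)
        masked[chrom] |= (mid >= start) & (mid < end)
    return masked


def genomic_average(
    track: BinnedTrack, mask: Sequence[tuple[str, int, int]] | None = None
) -> float:
    """Mean bin value across the whole assembly.

    Zero-count bins (centromeres, unmappable regions) are included unless a
    mask excludes them: with a mask, bins whose midpoint lies in any masked
    interval are dropped from the mean.
    """
    if mask is None:
        total = sum(v.sum() for v in track.values.values())
        n = sum(len(v) for v in track.values.values())
        return float(total / n)
    masked = _mask_array(track, mask)
    total = 0.0
    n = 0
    for chrom, vals in track.values.items():
        keep = ~masked[chrom]
        total += vals[keep].sum()
        n += int(keep.sum())
    if n == 0:
        raise ValueError("all bins masked")
    return float(total / n)


def find_peaks(smoothed: BinnedTrack, fold_threshold: float = 2.0) -> list[Peak]:
    """Local maxima of a smoothed track above ``fold_threshold ×`` genomic average.

    A peak is a bin (or the midpoint of a plateau run, ties broken leftward)
    strictly greater than both flanking values; chromosome-terminal bins need
    only exceed their single neighbour. A run spanning a whole chromosome is
    never a peak. Returned in genome order.
    """
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    mean = genomic_average(smoothed)
    peaks: list[Peak] = []
    for chrom in smoothed.assembly.names:
        vals = smoothed.values[chrom]
        n = len(vals)
        i = 0
        while i < n:
            j = i
            while j + 1 < n and vals[j + 1] == vals[i]:
                j += 1
            if not (i == 0 and j == n - 1):
                left_ok = i == 0 or vals[i - 1] < vals[i]
                right_ok = j == n - 1 or vals[j + 1] < vals[i]
                if left_ok and right_ok:
                    mid = (i + j) // 2
                    height = float(vals[mid])
                    if mean > 0 and height >= fold_threshold * mean:
                        peaks.append(
                            Peak(chrom, mid, smoothed.bin_center(chrom, mid), height, height / mean)
                        )
            i = j + 1
    return peaks


def high_loci(
    sv_track: BinnedTrack, snv_track: BinnedTrack, fold_threshold: float = 2.0
) -> list[tuple[str, int]]:
    """Bins where *both* tracks are >= fold_threshold × their own genomic average."""
    if not sv_track.same_grid(snv_track):
        raise ValueError("tracks must share assembly and bin_size")
    sv_mean = genomic_average(sv_track)
    snv_mean = genomic_average(snv_track)
    out: list[tuple[str, int]] = []
    for chrom in sv_track.assembly.names:
        hit = (sv_track.values[chrom] >= fold_threshold * sv_mean) & (
            snv_track.values[chrom] >= fold_threshold * snv_mean
        )
        out.extend((chrom, int(i)) for i in np.flatnonzero(hit))
    return out


def track_to_tsv(track: BinnedTrack, path: str | Path) -> None:
    """Export as TSV with columns chrom, bin_start, bin_end, value."""
    rows = []
    for chrom, length in track.assembly.chromosomes:
        vals = track.values[chrom]
        for i, v in enumerate(vals):
            start = i * track.bin_size
            rows.append((chrom, start, min(start + track.bin_size, length), v))
    pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "value"]).to_csv(
        path, sep="\t", index=False
    )


def track_from_tsv(path: str | Path, assembly: GenomeAssembly) -> BinnedTrack:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "bin_start", "bin_end", "value"} <= set(df.columns):
        raise FormatError(f"{path}: missing track columns")
    starts = df.loc[df["bin_start"] > 0, "bin_start"]
    if starts.empty:
        raise FormatError(f"{path}: cannot infer bin size from a single-bin track")
    bin_size = int(np.gcd.reduce(starts.to_numpy(dtype=np.int64)))
    values: dict[str, np.ndarray] = {}
    for chrom, length in assembly.chromosomes:
        sub = df[df["chrom"] == chrom].sort_values("bin_start")
        n = -(-length // bin_size)
        arr = np.zeros(n)
        arr[(sub["bin_start"] // bin_size).to_numpy()] = sub["value"].to_numpy()
        values[chrom] = arr
    return BinnedTrack(assembly, bin_size, values)
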