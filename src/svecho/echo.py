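"""Echoed SV/SNV induction: SNV profiles superimposed around SV peaks.

For every qualifying SV peak (a local maximum of the smoothed SV track above a
fold threshold over the genomic average), the smoothed SNV track is extracted
over a ±flank window centered on the peak bin and averaged across peaks,
offset by offset. An SNV elevation centered at offset 0 — an "echo" of the SV
peak — is quantified as the ratio of the central profile mean to the SNV
genomic average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinnedTrack, Peak, genomic_average


@dataclass
class EchoProfile:
    """Mean SNV signal by offset from superimposed SV peaks."""

    flank_bp: int
    bin_size: int
    offsets_bp: np.ndarray  # −flank..+flank in bin steps
    mean_snv_by_offset: np.ndarray  # NaN where no peak contributed
    n_contributing: np.ndarray  # peaks contributing per offset
    n_peaks: int
    snv_genomic_average: float

    @property
    def is_empty(self) -> bool:
        return self.n_peaks == 0


def echo_profile(
    sv_peaks: list[Peak],
    snv_smoothed: BinnedTrack,
    flank_bp: int = 15_000_000,
) -> EchoProfile:
    """Superimpose the smoothed SNV signal around SV peaks.

    Offsets that fall off the peak's chromosome are skipped: each offset's
    mean is taken over the peaks that actually cover it (no zero padding).
    An empty peak list yields an explicit empty profile, not an error.
    """
    bin_size = snv_smoothed.bin_size
    if flank_bp % bin_size != 0:
        raise ValueError("flank_bp must be a multiple of bin_size")
    k = flank_bp // bin_size
    offsets = np.arange(-k, k + 1)
    sums = np.zeros(2 * k + 1)
    counts = np.zeros(2 * k + 1, dtype=int)
    for peak in sv_peaks:
        vals = snv_smoothed.values[peak.chrom]
        idx = peak.bin_index + offsets
        ok = (idx >= 0) & (idx < len(vals))
        sums[ok] += vals[idx[ok]]
        counts[ok] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return EchoProfile(
        flank_bp=flank_bp,
        bin_size=bin_size,
        offsets_bp=offsets * bin_size,
        mean_snv_by_offset=means,
        n_contributing=counts,
        n_peaks=len(sv_peaks),
        snv_genomic_average=genomic_average(snv_smoothed),
    )


def echo_enrichment_score(profile: EchoProfile, center_halfwidth_bp: int = 1_000_000) -> float:
    """Central profile mean over the SNV genomic average; > 1 means elevation.

    The center is the offsets with |offset| <= center_halfwidth_bp (default
    1 Mb, the scale of breakpoint-proximal enrichment). Offsets without any
    contributing peak are ignored.
    """
    if profile.is_empty:
        raise ValueError("empty profile (no qualifying peaks)")
    if center_halfwidth_bp >= profile.flank_bp:
        raise ValueError("center_halfwidth_bp must be < flank_bp")
    if profile.snv_genomic_average <= 0:
        raise ValueError("zero SNV genomic average")
    central = np.abs(profile.offsets_bp) <= center_halfwidth_bp
    vals = profile.mean_snv_by_offset[central]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no in-bounds contributions at central offsets")
    return float(vals.mean() / profile.snv_genomic_average)


def combine_profiles(profiles: list[EchoProfile]) -> EchoProfile:
    """Pool echo profiles (e.g. one per tumor) into a cohort profile.

    Offset means are combined weighted by each profile's per-offset peak
    counts; the baseline is the n_peaks-weighted mean of the per-profile SNV
    genomic averages. All profiles must share flank and bin size.
    """
    profiles = [p for p in profiles if not p.is_empty]
    if not profiles:
        raise ValueError("no non-empty profiles to combine")
    first = profiles[0]
    if any(p.flank_bp != first.flank_bp or p.bin_size != first.bin_size for p in profiles):
        raise ValueError("profiles must share flank_bp and bin_size")
    sums = np.zeros_like(first.mean_snv_by_offset)
    counts = np.zeros_like(first.n_contributing)
    for p in profiles:
        contrib = np.where(p.n_contributing > 0, p.mean_snv_by_offset, 0.0)
        sums += contrib * p.n_contributing
        counts += p.n_contributing
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    total_peaks = sum(p.n_peaks for p in profiles)
    baseline = sum(p.snv_genomic_average * p.n_peaks for p in profiles) / total_peaks
    return EchoProfile(
        flank_bp=first.flank_bp,
        bin_size=first.bin_size,
        offsets_bp=first.offsets_bp.copy(),
        mean_snv_by_offset=means,
        n_contributing=counts,
        n_peaks=total_peaks,
        snv_genomic_average=float(baseline),
    )


def rotate_track(track: BinnedTrack, rng: np.random.Generator) -> BinnedTrack:
    """Circularly rotate each chromosome's bins by an independent random offset.

    Rotation preserves each chromosome's marginal bin-value distribution while
    destroying any alignment with fixed positions — the permutation null for
    the echo score.
    """
    values = {
        chrom: np.roll(vals, int(rng.integers(0, len(vals))))
        for chrom, vals in track.values.items()
    }
    return BinnedTrack(track.assembly, track.bin_size, values)


def profile_to_tsv(profile: EchoProfile, path) -> None:
    pd.DataFrame(
        {
            "offset_bp": profile.offsets_bp,
            "mean_snv": profile.mean_snv_by_offset,
            "n_contributing": profile.n_contributing,
        }
    ).to_csv(path, sep="\t", index=False)
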