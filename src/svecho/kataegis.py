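"""Rainfall statistics, kataegis calling, and SV-high/low distance comparison.

Rainfall data assign every SNV (after the first on each chromosome) its
distance to the preceding SNV; kataegis — localized hypermutation — appears as
runs of sub-kilobase distances. A kataegis cluster here is a maximal run of
>= ``min_count`` SNVs whose consecutive gaps are each <= ``max_gap`` (the
chain rule; a strict fixed-window variant is available). Inter-SNV distances
are compared between SV-high and SV-low genomic bins with Welch's t-test on
log10 distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinnedTrack, genomic_average
from .io import SnvSet
from .stats import TTestResult, welch_t_test

ZONE_LT_1KB = "lt_1kb"
ZONE_1KB_1MB = "kb_1_to_Mb_1"
ZONE_GE_1MB = "ge_1Mb"


@dataclass(frozen=True)
class RainfallPoint:
    """One SNV with its distance to the preceding SNV on the same chromosome."""

    chrom: str
    pos: int
    dist_to_prev: int | None  # None for the first SNV on a chromosome
    zone: str | None
    is_tie: bool = False  # duplicate position (distance 0)


@dataclass(frozen=True)
class KataegisCluster:
    """A called hypermutation cluster (maximal under the gap rule)."""

    chrom: str
    start_pos: int
    end_pos: int
    n_snvs: int
    max_gap: int


def _zone(dist: int) -> str:
    if dist < 1_000:
        return ZONE_LT_1KB
    if dist < 1_000_000:
        return ZONE_1KB_1MB
    return ZONE_GE_1MB


def inter_snv_distances(snvs: SnvSet) -> list[RainfallPoint]:
    """Rainfall points: per-chromosome distance to the preceding SNV.

    The first SNV of each chromosome carries no distance; duplicate positions
    yield distance 0 and are flagged as ties (zone still assigned).
    """
    points: list[RainfallPoint] = []
    for chrom in snvs.assembly.names:
        pos = snvs.positions(chrom)
        for i, p in enumerate(pos):
            if i == 0:
                points.append(RainfallPoint(chrom, int(p), None, None))
            else:
                d = int(p - pos[i - 1])
                points.append(RainfallPoint(chrom, int(p), d, _zone(d), is_tie=(d == 0)))
    return points


def call_kataegis(
    snvs: SnvSet,
    max_gap: int = 1_000,
    min_count: int = 3,
    *,
    rule: str = "chain",
) -> list[KataegisCluster]:
    """Call kataegis clusters.

    rule ``"chain"`` (default): maximal runs of consecutive SNVs with every
    adjacent gap <= max_gap; runs with >= min_count members are clusters (a
    cluster may span more than max_gap in total). rule ``"window"``: an SNV
    belongs to a cluster iff some window of width max_gap contains it together
    with >= min_count SNVs; overlapping qualifying windows merge.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if min_count < 2:
        raise ValueError("min_count must be >= 2")
    if rule not in ("chain", "window"):
        raise ValueError("rule must be 'chain' or 'window'")
    clusters: list[KataegisCluster] = []
    for chrom in snvs.assembly.names:
        pos = snvs.positions(chrom)
        if pos.size == 0:
            continue
        if rule == "chain":
            gaps = np.diff(pos)
            run_start = 0
            for i in range(1, len(pos) + 1):
                if i == len(pos) or gaps[i - 1] > max_gap:
                    if i - run_start >= min_count:
                        clusters.append(
                            KataegisCluster(
                                chrom, int(pos[run_start]), int(pos[i - 1]), i - run_start, max_gap
                            )
                        )
                    run_start = i
        else:
            member = np.zeros(len(pos), dtype=bool)
            # every window anchored at an SNV; [p, p + max_gap] inclusive
            j_hi = np.searchsorted(pos, pos + max_gap, side="right")
            for i in range(len(pos)):
                if j_hi[i] - i >= min_count:
                    member[i : j_hi[i]] = True
            i = 0
            while i < len(pos):
                if not member[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < len(pos) and member[j + 1] and pos[j + 1] - pos[j] <= max_gap:
                    j += 1
                if j - i + 1 >= min_count:
                    clusters.append(
                        KataegisCluster(chrom, int(pos[i]), int(pos[j]), j - i + 1, max_gap)
                    )
                i = j + 1
    return clusters


def classify_bins_by_sv(
    sv_smoothed: BinnedTrack, fold_threshold: float = 2.0
) -> dict[str, np.ndarray]:
    """Label each bin SV-high (True) where value >= fold × genomic average."""
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    mean = genomic_average(sv_smoothed)
    return {
        chrom: vals >= fold_threshold * mean for chrom, vals in sv_smoothed.values.items()
    }


def _in_cluster(point: RainfallPoint, clusters: list[KataegisCluster]) -> bool:
    return any(
        c.chrom == point.chrom and c.start_pos <= point.pos <= c.end_pos for c in clusters
    )


def compare_distances_by_region(
    points: list[RainfallPoint],
    sv_high: dict[str, np.ndarray],
    bin_size: int,
    *,
    exclude_kataegis: bool = False,
    clusters: list[KataegisCluster] | None = None,
    log_scale: bool = True,
) -> tuple[TTestResult, dict[str, dict[str, float]]]:
    """Welch t-test of inter-SNV distances in SV-high vs SV-low bins.

    Each rainfall point is assigned the label of the bin containing its own
    position. Distances are compared on the log10 scale by default (zero-
    distance ties are excluded there); ``exclude_kataegis`` drops points
    inside the supplied clusters first.

    Returns the test and per-group descriptive stats (n, mean on the tested
    scale, mean raw distance).
    """
    if exclude_kataegis and clusters is None:
        raise ValueError("exclude_kataegis requires the called clusters")
    groups: dict[str, list[float]] = {"sv_high": [], "sv_low": []}
    raw: dict[str, list[float]] = {"sv_high": [], "sv_low": []}
    for pt in points:
        if pt.dist_to_prev is None:
            continue
        if log_scale and pt.dist_to_prev == 0:
            continue
        if exclude_kataegis and _in_cluster(pt, clusters or []):
            continue
        labels = sv_high.get(pt.chrom)
        if labels is None:
            raise ValueError(f"no bin labels for chromosome {pt.chrom}")
        label = "sv_high" if labels[pt.pos // bin_size] else "sv_low"
        value = math.log10(pt.dist_to_prev) if log_scale else float(pt.dist_to_prev)
        groups[label].append(value)
        raw[label].append(float(pt.dist_to_prev))
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label} has fewer than 2 usable distances")
    test = welch_t_test(groups["sv_high"], groups["sv_low"])
    desc = {
        label: {
            "n": float(len(vals)),
            "mean": float(np.mean(vals)),
            "mean_raw_distance": float(np.mean(raw[label])),
        }
        for label, vals in groups.items()
    }
    return test, desc


def stratify_by_base_pair(snvs: SnvSet) -> dict[str, int]:
    """Count SNVs by the base pair of their reference allele: A:T vs G:C."""
    at = gc = 0
    for rec in snvs:
        if rec.ref_base in ("A", "T"):
            at += 1
        elif rec.ref_base in ("G", "C"):
            gc += 1
        else:  # unreachable via SnvSet validation; guards raw record lists
            raise ValueError(f"invalid ref base {rec.ref_base!r}")
    return {"AT": at, "GC": gc}


def rainfall_to_tsv(
    points: list[RainfallPoint],
    path,
    *,
    sv_high: dict[str, np.ndarray] | None = None,
    bin_size: int | None = None,
    clusters: list[KataegisCluster] | None = None,
) -> None:
    """Export rainfall points (with optional bin labels and kataegis flags)."""
    rows = []
    for pt in points:
        label = ""
        if sv_high is not None and bin_size is not None:
            label = "sv_high" if sv_high[pt.chrom][pt.pos // bin_size] else "sv_low"
        in_k = _in_cluster(pt, clusters) if clusters is not None else ""
        rows.append(
            (pt.chrom, pt.pos, "" if pt.dist_to_prev is None else pt.dist_to_prev,
             pt.zone or "", label, in_k, pt.is_tie)
        )
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "dist_to_prev", "zone", "bin_label", "in_kataegis", "is_tie"],
    ).to_csv(path, sep="\t", index=False)


def clusters_to_bed(clusters: list[KataegisCluster], path) -> None:
    """Write clusters as BED (half-open; end_pos + 1 to include the last SNV)."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.chrom}\t{c.start_pos}\t{c.end_pos + 1}\tkataegis_n{c.n_snvs}\n")
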