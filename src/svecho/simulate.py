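"""Synthetic tumor cohorts with known ground truth.

Each simulated tumor carries:

* SV events whose breakpoints concentrate in a small number of recurrent
  hotspots (a configurable fraction falls uniformly instead), mirroring the
  strongly clustered breakpoint landscapes the co-localization analysis is
  built for;
* background SNVs as a homogeneous Poisson process at ``snv_rate_per_bp``;
* breakpoint-proximal SNVs: within ``enrichment_range`` of any breakpoint the
  SNV rate is multiplied by ``enrichment_factor`` f. Implemented by
  superposition — an independent process at (f−1)·λ restricted to the merged
  windows — so the marginal rate is exact even where windows overlap. A
  linear distance taper is available instead of the step profile;
* optional kataegis bursts: with probability p per breakpoint, a run of
  ``kataegis_size`` SNVs with inter-SNV gaps uniform on [1, max_gap];
* an optional age-linked "clock-like" SNV component placed uniformly
  (count = alpha + beta·age + Gaussian noise), with matching SBS1/SBS5
  signature counts in the sample metadata.

Randomness derives from one master seed; sample ``i`` uses the stream seeded
by (seed, 1, i) and cohort-level draws (hotspot centers) by (seed, 0), so any
sample is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    GenomeAssembly,
    SampleMeta,
    SnvRecord,
    SnvSet,
    SvRecord,
    SvSet,
    write_snv_subset,
    write_svs,
)

_DEFAULT_CHROMS = (("chr1", 50_000_000), ("chr2", 50_000_000), ("chr3", 50_000_000))

#: GRCh38 primary chromosome lengths (autosomes + X, Y)
HUMAN_CHROM_LENGTHS = (
    ("chr1", 248_956_422), ("chr2", 242_193_529), ("chr3", 198_295_559),
    ("chr4", 190_214_555), ("chr5", 181_538_259), ("chr6", 170_805_979),
    ("chr7", 159_345_973), ("chr8", 145_138_636), ("chr9", 138_394_717),
    ("chr10", 133_797_422), ("chr11", 135_086_622), ("chr12", 133_275_309),
    ("chr13", 114_364_328), ("chr14", 107_043_718), ("chr15", 101_991_189),
    ("chr16", 90_338_345), ("chr17", 83_257_441), ("chr18", 80_373_285),
    ("chr19", 58_617_616), ("chr20", 64_444_167), ("chr21", 46_709_983),
    ("chr22", 50_818_468), ("chrX", 156_040_895), ("chrY", 57_227_415),
)


def desk_scale_assembly() -> GenomeAssembly:
    """Three 50 Mb chromosomes — the default test-scale genome."""
    return GenomeAssembly(_DEFAULT_CHROMS)


def human_scale_assembly() -> GenomeAssembly:
    return GenomeAssembly(HUMAN_CHROM_LENGTHS)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort. Defaults are the desk-scale study
    conditions; see the methods note for the rationale behind each value."""

    chrom_lengths: tuple[tuple[str, int], ...] = _DEFAULT_CHROMS
    n_samples: int = 20
    sv_rate: float = 20.0  # Poisson mean SV events per sample
    n_hotspots: int = 3
    hotspot_width: int = 250_000
    fraction_in_hotspots: float = 0.95
    sv_size_min: int = 10_000  # log-uniform size of non-hotspot intra-chrom SVs
    sv_size_max: int = 1_000_000
    snv_rate_per_bp: float = 1e-5  # background lambda
    enrichment_factor: float = 3.0  # f >= 1; multiplies lambda near breakpoints
    enrichment_range: int = 1_000_000  # d: half-width of the enriched window
    decay: str = "step"  # "step" or "linear" taper of the proximal rate
    kataegis_prob: float = 0.05  # per breakpoint
    kataegis_size: int = 6
    kataegis_max_gap: int = 1_000
    at_fraction: float = 0.4  # P(ref base is A or T)
    age_model: bool = False
    age_min: float = 40.0
    age_max: float = 80.0
    clock_alpha: float = 200.0
    clock_beta: float = 15.0  # clock-like SNVs per year of age
    clock_noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        for name, p in (("fraction_in_hotspots", self.fraction_in_hotspots),
                        ("kataegis_prob", self.kataegis_prob),
                        ("at_fraction", self.at_fraction)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.snv_rate_per_bp < 0 or self.sv_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.decay not in ("step", "linear"):
            raise ValueError("decay must be 'step' or 'linear'")
        min_len = min(l for _, l in self.chrom_lengths)
        if self.enrichment_range > min_len:
            raise ValueError("enrichment_range exceeds the shortest chromosome")
        if self.kataegis_size < 2 or self.kataegis_max_gap < 1:
            raise ValueError("invalid kataegis parameters")
        if not (0 < self.sv_size_min <= self.sv_size_max):
            raise ValueError("invalid SV size range")

    @property
    def assembly(self) -> GenomeAssembly:
        return GenomeAssembly(tuple(self.chrom_lengths))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class TruthRecord:
    """Ground truth for one simulated sample."""

    sample_id: str
    enrichment_factor: float
    enrichment_range: int
    age: float | None
    n_background: int
    n_proximal: int
    n_kataegis: int
    n_clock: int
    hotspots: list[tuple[str, int, int]]
    breakpoints: list[tuple[str, int]]
    planted_clusters: list[tuple[str, int, int, int]]  # chrom, start, end, n

    @property
    def n_total(self) -> int:
        return self.n_background + self.n_proximal + self.n_kataegis + self.n_clock

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_total"] = self.n_total
        return d


def kataegis_contamination_bound(config: SimConfig) -> float:
    """Expected background SNVs within reach of a planted cluster.

    A planted cluster stays exactly recoverable as long as no background SNV
    lands within ``max_gap`` of its span; this returns the expected number of
    such intruders per cluster (expected span + a max_gap margin on each side,
    times the background rate). Values below 1e-3 make exact recovery safe.
    """
    expected_span = (config.kataegis_size - 1) * (config.kataegis_max_gap + 1) / 2.0
    reach = expected_span + 2 * config.kataegis_max_gap
    return config.snv_rate_per_bp * reach


def hotspot_intervals(config: SimConfig) -> list[tuple[str, int, int]]:
    """Cohort-level hotspot intervals, deterministic in the master seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    assembly = config.assembly
    lengths = np.array([l for _, l in assembly.chromosomes], dtype=float)
    out = []
    for _ in range(config.n_hotspots):
        ci = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
        name, length = assembly.chromosomes[ci]
        start = int(rng.integers(0, length - config.hotspot_width))
        out.append((name, start, start + config.hotspot_width))
    return out


def _merged_windows(
    breakpoints: dict[str, list[int]], assembly: GenomeAssembly, range_bp: int
) -> dict[str, list[tuple[int, int]]]:
    windows: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in assembly.chromosomes:
        bps = sorted(breakpoints.get(chrom, []))
        merged: list[tuple[int, int]] = []
        for bp in bps:
            s, e = max(0, bp - range_bp), min(length, bp + range_bp + 1)
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        windows[chrom] = merged
    return windows


def _draw_genome_positions(
    rng: np.random.Generator, assembly: GenomeAssembly, n: int
) -> list[tuple[str, int]]:
    lengths = np.array([l for _, l in assembly.chromosomes], dtype=float)
    choice = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
    return [
        (assembly.chromosomes[ci][0], int(rng.integers(0, assembly.chromosomes[ci][1])))
        for ci in choice
    ]


def _draw_sv_events(
    rng: np.random.Generator, config: SimConfig, hotspots: list[tuple[str, int, int]]
) -> list[SvRecord]:
    assembly = config.assembly
    lengths = np.array([l for _, l in assembly.chromosomes], dtype=float)
    n_sv = int(rng.poisson(config.sv_rate))
    classes = ("duplication", "inversion", "deletion", "translocation")
    events: list[SvRecord] = []
    for _ in range(n_sv):
        cls = classes[int(rng.integers(0, 4))]
        in_hotspot = hotspots and rng.random() < config.fraction_in_hotspots
        if in_hotspot:
            hi = int(rng.integers(0, len(hotspots)))
            chrom, s, e = hotspots[hi]
            if cls == "translocation":
                others = [h for h in hotspots if h[0] != chrom]
                if others:
                    c2, s2, e2 = others[int(rng.integers(0, len(others)))]
                    events.append(SvRecord(chrom, int(rng.integers(s, e)), c2,
                                           int(rng.integers(s2, e2)), cls))
                    continue
                cls = "inversion"  # no second chromosome available
            p1, p2 = int(rng.integers(s, e)), int(rng.integers(s, e))
            events.append(SvRecord(chrom, p1, chrom, p2, cls))
        else:
            ci = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
            chrom, length = assembly.chromosomes[ci]
            p1 = int(rng.integers(0, length))
            if cls == "translocation" and len(assembly) > 1:
                other = [i for i in range(len(lengths)) if i != ci]
                w = lengths[other] / lengths[other].sum()
                cj = other[int(rng.choice(len(other), p=w))]
                c2, l2 = assembly.chromosomes[cj]
                events.append(SvRecord(chrom, p1, c2, int(rng.integers(0, l2)), cls))
            else:
                if cls == "translocation":
                    cls = "inversion"
                size = int(np.exp(rng.uniform(np.log(config.sv_size_min),
                                              np.log(config.sv_size_max))))
                p2 = p1 + size if rng.random() < 0.5 else p1 - size
                p2 = int(np.clip(p2, 0, length - 1))
                events.append(SvRecord(chrom, p1, chrom, p2, cls))
    return events


def _draw_window_positions(
    rng: np.random.Generator,
    windows: dict[str, list[tuple[int, int]]],
    n: int,
) -> list[tuple[str, int]]:
    flat = [(chrom, s, e) for chrom, ivs in windows.items() for s, e in ivs]
    if not flat or n == 0:
        return []
    lens = np.array([e - s for _, s, e in flat], dtype=float)
    choice = rng.choice(len(flat), size=n, p=lens / lens.sum())
    out = []
    for i in choice:
        chrom, s, e = flat[i]
        out.append((chrom, int(rng.integers(s, e))))
    return out


def _nearest_breakpoint_dist(pos: int, bps: np.ndarray) -> int:
    i = int(np.searchsorted(bps, pos))
    best = np.iinfo(np.int64).max
    if i > 0:
        best = min(best, pos - int(bps[i - 1]))
    if i < len(bps):
        best = min(best, int(bps[i]) - pos)
    return int(best)


def _assign_bases(rng: np.random.Generator, n: int, at_fraction: float) -> list[tuple[str, str]]:
    out = []
    for _ in range(n):
        if rng.random() < at_fraction:
            ref = "A" if rng.random() < 0.5 else "T"
        else:
            ref = "G" if rng.random() < 0.5 else "C"
        alts = [b for b in "ACGT" if b != ref]
        out.append((ref, alts[int(rng.integers(0, 3))]))
    return out


def simulate_sample(
    config: SimConfig, sample_index: int
) -> tuple[SnvSet, SvSet, TruthRecord, SampleMeta]:
    """Simulate one tumor: SNVs, SVs, ground truth, and metadata.

    Deterministic given (config.seed, sample_index).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, sample_index]))
    assembly = config.assembly
    sample_id = f"sample_{sample_index:03d}"
    hotspots = hotspot_intervals(config)

    events = _draw_sv_events(rng, config, hotspots)
    svs = SvSet(assembly, events)
    bp_by_chrom: dict[str, list[int]] = {}
    bp_list: list[tuple[str, int]] = []
    for ev in events:
        for chrom, pos in ((ev.chrom1, ev.pos1), (ev.chrom2, ev.pos2)):
            bp_by_chrom.setdefault(chrom, []).append(pos)
            bp_list.append((chrom, pos))

    L = assembly.total_length
    positions: list[tuple[str, int]] = []

    # background Poisson process
    n_bg = int(rng.poisson(config.snv_rate_per_bp * L))
    positions.extend(_draw_genome_positions(rng, assembly, n_bg))

    # proximal superposition at (f-1)*lambda inside merged windows
    windows = _merged_windows(bp_by_chrom, assembly, config.enrichment_range)
    w_len = sum(e - s for ivs in windows.values() for s, e in ivs)
    n_prox = 0
    if config.enrichment_factor > 1 and w_len > 0:
        n_cand = int(rng.poisson((config.enrichment_factor - 1) * config.snv_rate_per_bp * w_len))
        cands = _draw_window_positions(rng, windows, n_cand)
        if config.decay == "linear":
            kept = []
            bp_arrays = {c: np.array(sorted(v), dtype=np.int64) for c, v in bp_by_chrom.items()}
            for chrom, pos in cands:
                dist = _nearest_breakpoint_dist(pos, bp_arrays[chrom])
                if rng.random() < max(0.0, 1.0 - dist / config.enrichment_range):
                    kept.append((chrom, pos))
            cands = kept
        positions.extend(cands)
        n_prox = len(cands)

    # kataegis bursts anchored at breakpoints
    planted: list[tuple[str, int, int, int]] = []
    n_kat = 0
    for chrom, bp in bp_list:
        if rng.random() >= config.kataegis_prob:
            continue
        direction = 1 if rng.random() < 0.5 else -1
        length = assembly.length_of(chrom)
        burst = [bp]
        p = bp
        for _ in range(config.kataegis_size - 1):
            p += direction * int(rng.integers(1, config.kataegis_max_gap + 1))
            if 0 <= p < length:
                burst.append(p)
        if len(burst) >= 2:
            positions.extend((chrom, q) for q in burst)
            n_kat += len(burst)
            planted.append((chrom, min(burst), max(burst), len(burst)))

    # age-linked clock-like component
    age: float | None = None
    n_clock = 0
    if config.age_model:
        age = float(rng.uniform(config.age_min, config.age_max))
        n_clock = max(
            0,
            int(round(rng.normal(config.clock_alpha + config.clock_beta * age,
                                 config.clock_noise_sd))),
        )
        positions.extend(_draw_genome_positions(rng, assembly, n_clock))

    bases = _assign_bases(rng, len(positions), config.at_fraction)
    snvs = SnvSet(
        assembly,
        (SnvRecord(chrom, pos, ref, alt) for (chrom, pos), (ref, alt) in zip(positions, bases)),
    )

    truth = TruthRecord(
        sample_id=sample_id,
        enrichment_factor=config.enrichment_factor,
        enrichment_range=config.enrichment_range,
        age=age,
        n_background=n_bg,
        n_proximal=n_prox,
        n_kataegis=n_kat,
        n_clock=n_clock,
        hotspots=list(hotspots),
        breakpoints=bp_list,
        planted_clusters=planted,
    )
    signature_counts: dict[str, float] = {}
    if config.age_model:
        sbs1 = int(rng.binomial(n_clock, 0.55))
        signature_counts = {
            "SBS1": sbs1,
            "SBS5": n_clock - sbs1,
            "SBS3": n_prox,
            "SBS2": n_kat,
        }
    meta = SampleMeta(sample_id, age_at_diagnosis=age, signature_counts=signature_counts)
    return snvs, svs, truth, meta


def simulate_cohort(config: SimConfig, out_dir: str | Path) -> dict:
    """Simulate and write a cohort; returns (and writes) the manifest.

    Per sample: ``<id>.vcf`` and ``<id>.bedpe``; cohort-wide:
    ``metadata.tsv``, ``truth.json``, ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    truths: list[dict] = []
    meta_rows = ["sample_id\tage_at_diagnosis\tn_snv\tn_sv\tsignature_counts"]
    for i in range(config.n_samples):
        snvs, svs, truth, meta = simulate_sample(config, i)
        vcf = out / f"{truth.sample_id}.vcf"
        bedpe = out / f"{truth.sample_id}.bedpe"
        write_snv_subset(snvs, vcf)
        write_svs(svs, bedpe)
        files.extend([vcf.name, bedpe.name])
        truths.append(truth.to_dict())
        age_s = "" if meta.age_at_diagnosis is None else f"{meta.age_at_diagnosis:.2f}"
        sig_s = json.dumps(meta.signature_counts, sort_keys=True)
        meta_rows.append(f"{meta.sample_id}\t{age_s}\t{len(snvs)}\t{len(svs)}\t{sig_s}")

    (out / "metadata.tsv").write_text("\n".join(meta_rows) + "\n")
    cohort_truth = {
        "samples": truths,
        "totals": {
            "n_background": sum(t["n_background"] for t in truths),
            "n_proximal": sum(t["n_proximal"] for t in truths),
            "n_kataegis": sum(t["n_kataegis"] for t in truths),
            "n_clock": sum(t["n_clock"] for t in truths),
        },
    }
    (out / "truth.json").write_text(json.dumps(cohort_truth, indent=1, sort_keys=True))
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for name, length in config.chrom_lengths:
            fh.write(f"{name}\t{length}\n")
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_samples": config.n_samples,
        "files": sorted(files) + ["chrom_sizes.tsv", "metadata.tsv", "truth.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
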