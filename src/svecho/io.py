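"""Core variant data model and parsers for the standard text formats.

Conventions
-----------
All internal coordinates are 0-based; intervals are half-open ``[start, end)``.
On disk, VCF POS is 1-based inclusive and BEDPE/BED are 0-based half-open; the
readers and writers below convert at the boundary so no other module ever
handles a 1-based coordinate.

The containers (:class:`SnvSet`, :class:`SvSet`) keep their records sorted by
assembly chromosome order and position, and expose per-chromosome position
arrays for the downstream counting machinery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

SV_CLASSES = ("duplication", "inversion", "deletion", "translocation", "unknown")

#: case-insensitive aliases accepted in the BEDPE class column
_SV_CLASS_ALIASES = {
    "dup": "duplication",
    "duplication": "duplication",
    "td": "duplication",
    "inv": "inversion",
    "inversion": "inversion",
    "del": "deletion",
    "deletion": "deletion",
    "tra": "translocation",
    "trans": "translocation",
    "translocation": "translocation",
    "bnd": "translocation",
    "ctx": "translocation",
    "unknown": "unknown",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and lengths.

    The assembly defines chromosome sort order for every variant container
    and the total genome length used by the random-expectation formula.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("assembly needs at least one chromosome")
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in assembly")
        for name, length in self.chromosomes:
            if not isinstance(length, (int, np.integer)) or length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def total_length(self) -> int:
        return int(sum(l for _, l in self.chromosomes))

    def length_of(self, chrom: str) -> int:
        for n, l in self.chromosomes:
            if n == chrom:
                return int(l)
        raise KeyError(chrom)

    def index_of(self, chrom: str) -> int:
        for i, (n, _) in enumerate(self.chromosomes):
            if n == chrom:
                return i
        raise KeyError(chrom)

    def __contains__(self, chrom: object) -> bool:
        return any(n == chrom for n, _ in self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)


class SnvRecord(NamedTuple):
    """A single somatic single-nucleotide substitution (0-based position)."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str


class SvRecord(NamedTuple):
    """A structural variant: two breakpoints (0-based) and a class."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_class: str


@dataclass
class SampleMeta:
    """Per-sample metadata: age at diagnosis and optional signature counts."""

    sample_id: str
    age_at_diagnosis: float | None = None
    signature_counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.age_at_diagnosis is not None and self.age_at_diagnosis < 0:
            raise ValueError("age_at_diagnosis must be >= 0")
        for k, v in self.signature_counts.items():
            if v < 0:
                raise ValueError(f"negative signature count for {k}")


def _validate_snv(rec: SnvRecord, assembly: GenomeAssembly) -> None:
    if rec.ref_base not in VALID_BASES or rec.alt_base not in VALID_BASES:
        raise ValueError(f"invalid bases {rec.ref_base}>{rec.alt_base} at {rec.chrom}:{rec.pos}")
    if rec.ref_base == rec.alt_base:
        raise ValueError(f"ref == alt ({rec.ref_base}) at {rec.chrom}:{rec.pos}")
    if not 0 <= rec.pos < assembly.length_of(rec.chrom):
        raise ValueError(f"position {rec.pos} outside {rec.chrom}")


class SnvSet:
    """Sorted collection of SNVs on one assembly.

    Backed by a DataFrame with columns ``chrom, pos, ref, alt``, sorted by
    (assembly chromosome order, position, ref, alt). Duplicate positions are
    permitted; they surface as zero inter-SNV distances downstream.
    """

    def __init__(self, assembly: GenomeAssembly, records: Iterable[SnvRecord] = ()):
        self.assembly = assembly
        rows = []
        for r in records:
            rec = SnvRecord(*r)
            _validate_snv(rec, assembly)
            rows.append(rec)
        df = pd.DataFrame(rows, columns=["chrom", "pos", "ref_base", "alt_base"])
        if len(df):
            order = df["chrom"].map(assembly.index_of)
            df = (
                df.assign(_order=order)
                .sort_values(["_order", "pos", "ref_base", "alt_base"], kind="mergesort")
                .drop(columns="_order")
                .reset_index(drop=True)
            )
        self._df = df
        self._pos_cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[SnvRecord]:
        return (SnvRecord(*t) for t in self._df.itertuples(index=False, name=None))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnvSet):
            return NotImplemented
        return list(self) == list(other)

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted positions on one chromosome (int64 array; cached)."""
        if chrom not in self._pos_cache:
            sub = self._df.loc[self._df["chrom"] == chrom, "pos"]
            self._pos_cache[chrom] = sub.to_numpy(dtype=np.int64)
        return self._pos_cache[chrom]

    def subset(self, keep: Sequence[bool]) -> "SnvSet":
        mask = np.asarray(keep, dtype=bool)
        recs = [SnvRecord(*t) for t, k in zip(self._df.itertuples(index=False, name=None), mask) if k]
        return SnvSet(self.assembly, recs)


class SvSet:
    """Sorted collection of SVs (two breakpoints + class each)."""

    def __init__(self, assembly: GenomeAssembly, records: Iterable[SvRecord] = ()):
        self.assembly = assembly
        rows = []
        for r in records:
            rec = SvRecord(*r)
            if rec.sv_class not in SV_CLASSES:
                raise ValueError(f"unknown SV class {rec.sv_class!r}")
            for chrom, pos in ((rec.chrom1, rec.pos1), (rec.chrom2, rec.pos2)):
                if not 0 <= pos < assembly.length_of(chrom):
                    raise ValueError(f"breakpoint {pos} outside {chrom}")
            if rec.sv_class == "translocation" and rec.chrom1 == rec.chrom2:
                warnings.warn(
                    f"intra-chromosomal record labelled translocation at {rec.chrom1}:{rec.pos1}",
                    stacklevel=2,
                )
            rows.append(rec)
        df = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2", "sv_class"])
        if len(df):
            order = df["chrom1"].map(assembly.index_of)
            df = (
                df.assign(_order=order)
                .sort_values(["_order", "pos1", "pos2"], kind="mergesort")
                .drop(columns="_order")
                .reset_index(drop=True)
            )
        self._df = df
        self._bp_cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[SvRecord]:
        return (SvRecord(*t) for t in self._df.itertuples(index=False, name=None))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SvSet):
            return NotImplemented
        return sorted(self) == sorted(other)

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def n_breakpoints(self) -> int:
        return 2 * len(self._df)

    def breakpoints(self, chrom: str) -> np.ndarray:
        """Sorted breakpoint positions on one chromosome (both ends of every SV)."""
        if chrom not in self._bp_cache:
            p1 = self._df.loc[self._df["chrom1"] == chrom, "pos1"].to_numpy(dtype=np.int64)
            p2 = self._df.loc[self._df["chrom2"] == chrom, "pos2"].to_numpy(dtype=np.int64)
            self._bp_cache[chrom] = np.sort(np.concatenate([p1, p2]))
        return self._bp_cache[chrom]


# ---------------------------------------------------------------------------
# readers / writers


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    """Read a two-column ``name<TAB>length`` TSV into a :class:`GenomeAssembly`."""
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected name<TAB>length")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from exc
            if length < 1:
                raise FormatError(f"{path}:{lineno}: non-positive length {length}")
            chroms.append((name, length))
    if not chroms:
        raise FormatError(f"{path}: empty chrom-sizes file")
    try:
        return GenomeAssembly(tuple(chroms))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _normalize_chrom(chrom: str, assembly: GenomeAssembly, strip_chr: bool) -> str:
    if chrom in assembly:
        return chrom
    if strip_chr:
        alt = chrom[3:] if chrom.lower().startswith("chr") else "chr" + chrom
        if alt in assembly:
            return alt
    return chrom


def read_snvs(
    path: str | Path,
    assembly: GenomeAssembly,
    *,
    strip_chr: bool = False,
    on_unknown_chrom: str = "fail",
) -> SnvSet:
    """Read single-nucleotide substitutions from a VCF 4.x text file.

    Only rows whose REF and each ALT allele are single A/C/G/T bases are kept;
    multi-allelic rows are split into one record per ALT; everything else
    (indels, MNVs, symbolic alleles) is skipped and counted. The skip count is
    logged and stored on the returned set as ``skipped_non_snv``.

    Parameters
    ----------
    on_unknown_chrom:
        ``"fail"`` raises on a chromosome absent from the assembly;
        ``"skip"`` drops the row (counted in ``skipped_unknown_chrom``).
    """
    if on_unknown_chrom not in ("fail", "skip"):
        raise ValueError("on_unknown_chrom must be 'fail' or 'skip'")
    records: list[SnvRecord] = []
    skipped_non_snv = 0
    skipped_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: VCF row with fewer than 5 columns")
            chrom, pos_s, _id, ref, alts = parts[0], parts[1], parts[2], parts[3], parts[4]
            chrom = _normalize_chrom(chrom, assembly, strip_chr)
            if chrom not in assembly:
                if on_unknown_chrom == "skip":
                    skipped_unknown += 1
                    continue
                raise FormatError(f"{path}:{lineno}: chromosome {parts[0]!r} not in assembly")
            try:
                pos = int(pos_s) - 1  # VCF is 1-based
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer POS {pos_s!r}") from exc
            ref = ref.upper()
            for alt in alts.upper().split(","):
                if len(ref) == 1 and len(alt) == 1 and ref in VALID_BASES and alt in VALID_BASES and ref != alt:
                    if not 0 <= pos < assembly.length_of(chrom):
                        raise FormatError(f"{path}:{lineno}: POS outside {chrom}")
                    records.append(SnvRecord(chrom, pos, ref, alt))
                else:
                    skipped_non_snv += 1
    if skipped_non_snv:
        logger.info("%s: skipped %d non-SNV alleles", path, skipped_non_snv)
    snvs = SnvSet(assembly, records)
    snvs.skipped_non_snv = skipped_non_snv  # type: ignore[attr-defined]
    snvs.skipped_unknown_chrom = skipped_unknown  # type: ignore[attr-defined]
    return snvs


def write_snv_subset(snvs: SnvSet, path: str | Path) -> None:
    """Write an :class:`SnvSet` as a minimal VCF 4.2 file (1-based POS)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=svecho\n")
        for name, length in snvs.assembly.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in snvs:
            fh.write(f"{rec.chrom}\t{rec.pos + 1}\t.\t{rec.ref_base}\t{rec.alt_base}\t.\t.\t.\n")


def parse_sv_class(token: str | None) -> str:
    if token is None:
        return "unknown"
    return _SV_CLASS_ALIASES.get(token.strip().lower(), "unknown")


def read_svs(
    path: str | Path,
    assembly: GenomeAssembly,
    *,
    class_column: int = 6,
    strip_chr: bool = False,
    on_unknown_chrom: str = "fail",
) -> SvSet:
    """Read SVs from a BEDPE file (0-based half-open intervals on disk).

    The breakpoint of each end is the *start* of its interval. The SV class is
    parsed case-insensitively from ``class_column`` (0-based column index,
    default 6 = the BEDPE name column) when present, else ``unknown``.
    """
    records: list[SvRecord] = []
    skipped_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BEDPE row needs >= 6 columns")
            c1 = _normalize_chrom(parts[0], assembly, strip_chr)
            c2 = _normalize_chrom(parts[3], assembly, strip_chr)
            if c1 not in assembly or c2 not in assembly:
                if on_unknown_chrom == "skip":
                    skipped_unknown += 1
                    continue
                raise FormatError(f"{path}:{lineno}: chromosome not in assembly")
            try:
                p1, p2 = int(parts[1]), int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            cls = parse_sv_class(parts[class_column]) if len(parts) > class_column else "unknown"
            for chrom, pos in ((c1, p1), (c2, p2)):
                if not 0 <= pos < assembly.length_of(chrom):
                    raise FormatError(f"{path}:{lineno}: breakpoint {pos} outside {chrom}")
            records.append(SvRecord(c1, p1, c2, p2, cls))
    svs = SvSet(assembly, records)
    svs.skipped_unknown_chrom = skipped_unknown  # type: ignore[attr-defined]
    return svs


def write_svs(svs: SvSet, path: str | Path) -> None:
    """Write an :class:`SvSet` as 7-column BEDPE (point intervals of width 1)."""
    with open(path, "w") as fh:
        for rec in svs:
            fh.write(
                f"{rec.chrom1}\t{rec.pos1}\t{rec.pos1 + 1}\t"
                f"{rec.chrom2}\t{rec.pos2}\t{rec.pos2 + 1}\t{rec.sv_class}\n"
            )


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED file into (chrom, start, end) triples (0-based half-open)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED row needs >= 3 columns")
            start, end = int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            out.append((parts[0], start, end))
    return out


def read_regions_bed(path: str | Path) -> list[tuple[str, tuple[str, int, int]]]:
    """Read a 4-column BED (chrom, start, end, name) into (name, interval) pairs."""
    out: list[tuple[str, tuple[str, int, int]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: regions BED needs a name column")
            start, end = int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            out.append((parts[3], (parts[0], start, end)))
    return out
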