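import numpy as np
import pytest

from svecho.io import GenomeAssembly, SnvRecord, SnvSet, SvRecord, SvSet

BASES = "ACGT"


@pytest.fixture
def tiny_assembly() -> GenomeAssembly:
    return GenomeAssembly((("chr1", 10_000_000), ("chr2", 5_000_000)))


def make_snvs(assembly: GenomeAssembly, positions: dict[str, list[int]],
              ref: str = "A", alt: str = "T") -> SnvSet:
    recs = [SnvRecord(c, p, ref, alt) for c, ps in positions.items() for p in ps]
    return SnvSet(assembly, recs)


def make_svs(assembly: GenomeAssembly, breakpoints: list[tuple[str, int, str, int]],
             sv_class: str = "deletion") -> SvSet:
    recs = [SvRecord(c1, p1, c2, p2, sv_class) for c1, p1, c2, p2 in breakpoints]
    return SvSet(assembly, recs)


def random_snvs(rng: np.random.Generator, assembly: GenomeAssembly, n: int) -> SnvSet:
    recs = []
    for _ in range(n):
        ci = int(rng.integers(0, len(assembly)))
        chrom, length = assembly.chromosomes[ci]
        ref = BASES[int(rng.integers(0, 4))]
        alt = [b for b in BASES if b != ref][int(rng.integers(0, 3))]
        recs.append(SnvRecord(chrom, int(rng.integers(0, length)), ref, alt))
    return SnvSet(assembly, recs)
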