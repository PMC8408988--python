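"""Genome annotations used by the genomic-scar calculations.

A :class:`GenomeAnnotation` records, per chromosome, its length and the
centromere interval (1-based inclusive coordinates).  Scar counting needs
this to decide whether a segment reaches a telomere, crosses the
centromere, or spans a whole chromosome, and to split segments into arms.

Two built-in annotations are provided:

* :func:`toy_genome` — a deliberately small 3-chromosome genome (~200 Mb)
  used throughout the unit tests, where arithmetic can be checked by hand.
* :func:`simulation_genome` — a larger 12-chromosome genome (~2 Gb) used by
  the synthetic-cohort generator, big enough that a heavily scarred tumour
  can accumulate a genomic-scar score well above the clinical threshold.

Real genome builds are supported through :func:`read_genome_tsv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MB = 1_000_000


@dataclass(frozen=True)
class ChromosomeAnnotation:
    """Length and centromere interval of one chromosome (1-based, inclusive)."""

    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.cen_start <= self.cen_end <= self.length):
            raise ValueError(
                f"chromosome {self.name}: centromere [{self.cen_start}, {self.cen_end}] "
                f"must lie within [1, {self.length}]"
            )


@dataclass(frozen=True)
class GenomeAnnotation:
    """A set of chromosomes with centromere intervals."""

    chromosomes: dict[str, ChromosomeAnnotation] = field(default_factory=dict)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __getitem__(self, chrom: str) -> ChromosomeAnnotation:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise KeyError(
                f"no annotation for chromosome {chrom!r}; "
                f"known: {sorted(self.chromosomes)}"
            ) from None

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": c.name,
                    "length": c.length,
                    "cen_start": c.cen_start,
                    "cen_end": c.cen_end,
                }
                for c in self.chromosomes.values()
            ]
        )


def make_genome(rows: list[tuple[str, int, int, int]]) -> GenomeAnnotation:
    """Build an annotation from (name, length, cen_start, cen_end) tuples."""
    return GenomeAnnotation(
        {name: ChromosomeAnnotation(name, length, cs, ce) for name, length, cs, ce in rows}
    )


def toy_genome() -> GenomeAnnotation:
    """3-chromosome, 200-Mb genome for hand-checkable scar arithmetic."""
    return make_genome(
        [
            ("chr1", 100 * MB, 48 * MB, 52 * MB),
            ("chr2", 60 * MB, 28 * MB, 31 * MB),
            ("chr3", 40 * MB, 18 * MB, 20 * MB),
        ]
    )


def simulation_genome() -> GenomeAnnotation:
    """12-chromosome, ~2-Gb genome used by the synthetic-cohort generator.

    Sized so that a scarred genome can plausibly exceed the deficiency
    threshold of 42 lesions, which a 200-Mb toy genome cannot.
    """
    rows = []
    lengths = [240, 220, 200, 190, 180, 170, 160, 150, 140, 130, 120, 110]
    for i, length_mb in enumerate(lengths, start=1):
        length = length_mb * MB
        cen_start = int(length * 0.45)
        rows.append((f"chr{i}", length, cen_start, cen_start + 3 * MB - 1))
    return make_genome(rows)


def read_genome_tsv(path) -> GenomeAnnotation:
    """Read a genome annotation TSV with columns chrom, length, cen_start, cen_end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "length", "cen_start", "cen_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genome annotation TSV missing columns: {sorted(missing)}")
    return make_genome(
        [
            (r.chrom, int(r.length), int(r.cen_start), int(r.cen_end))
            for r in df.itertuples()
        ]
    )


def write_genome_tsv(genome: GenomeAnnotation, path) -> None:
    genome.to_frame().to_csv(path, sep="\t", index=False)
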