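"""Shared genomic containers and plain-text I/O.

Internal coordinate convention is 0-based half-open throughout; GFF3 (1-based
closed) is converted on read and write.  Fragments are fixed-length, strandless
for coverage purposes, carried as a pandas DataFrame wrapped in
:class:`FragmentSet`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class Gene:
    """A single-interval gene model (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Ordered, stranded gene models on named chromosomes.

    The coordinate frame for everything downstream: island annotation,
    metagene binning, chromosomal clustering.
    """

    genes: list[Gene]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for g in self.genes:
            L = self.chrom_lengths.get(g.chrom)
            if L is None:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > L:
                raise ValueError(f"{g.gene_id}: extends past end of {g.chrom}")
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.start))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_on(self, chrom: str) -> list[Gene]:
        """Genes on one chromosome, in coordinate order."""
        return [g for g in self.genes if g.chrom == chrom]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
            }
        )


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Write genes as GFF3 (1-based closed coordinates on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(annotation.chrom_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in annotation.genes:
            fh.write(
                f"{g.chrom}\tepimark\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3(path) -> GenomeAnnotation:
    """Read a gene-only GFF3 back into a GenomeAnnotation."""
    chrom_lengths: dict[str, int] = {}
    genes: list[Gene] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, chrom, _one, length = line.split()
                chrom_lengths[chrom] = int(length)
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            genes.append(
                Gene(
                    gene_id=attrs.get("ID", f"{fields[0]}:{fields[3]}"),
                    chrom=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    if not chrom_lengths:
        # fall back to the extent of the genes themselves
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.end)
    return GenomeAnnotation(genes=genes, chrom_lengths=chrom_lengths)


@dataclass
class FragmentSet:
    """Mapped, deduplicatable fragment intervals (0-based half-open).

    ``library_size`` is the retained fragment count and drives RPM scaling.
    """

    frame: pd.DataFrame  # columns chrom, start, end, strand

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "strand"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"FragmentSet frame missing columns {missing}")
        if len(self.frame) and not (self.frame["start"] < self.frame["end"]).all():
            raise ValueError("fragments must satisfy start < end")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def library_size(self) -> int:
        return len(self.frame)

    def validate_bounds(self, chrom_lengths: dict[str, int]) -> None:
        for chrom, sub in self.frame.groupby("chrom", observed=True):
            L = chrom_lengths.get(chrom)
            if L is None:
                raise ValueError(f"fragment on unknown chromosome {chrom}")
            if (sub["start"] < 0).any() or (sub["end"] > L).any():
                raise ValueError(f"fragment outside bounds of {chrom}")

    def sorted(self) -> "FragmentSet":
        return FragmentSet(
            self.frame.sort_values(
                ["chrom", "start", "end", "strand"], kind="mergesort"
            ).reset_index(drop=True)
        )


def write_bed(fragments: FragmentSet, path, name_prefix: str = "frag") -> None:
    """Write fragments as BED6 (0-based half-open, as BED requires)."""
    df = fragments.frame
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": [f"{name_prefix}{i}" for i in range(len(df))],
            "score": 0,
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> FragmentSet:
    df = pd.read_csv(
        path, sep="\t", header=None, names=BED6_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "name": str, "strand": str},
    )
    return FragmentSet(df[["chrom", "start", "end", "strand"]].copy())


class CoverageTrack:
    """Per-base fragment coverage with library size and RPM scaling."""

    def __init__(self, arrays: dict[str, np.ndarray], library_size: int,
                 rpm: bool = False):
        self.arrays = arrays
        self.library_size = int(library_size)
        self.rpm = bool(rpm)

    @property
    def rpm_factor(self) -> float:
        return 1e6 / self.library_size

    def chrom(self, name: str) -> np.ndarray:
        return self.arrays[name]

    @property
    def total_mass(self) -> float:
        return float(sum(a.sum() for a in self.arrays.values()))

    def region(self, chrom: str, start: int, end: int,
               pad_value: float = 0.0) -> np.ndarray:
        """Per-base values over [start, end), zero-padded outside the chromosome.

        Flanks of edge genes may reach past the sequence; the pad keeps every
        profile the same length.
        """
        arr = self.arrays[chrom]
        lo, hi = max(start, 0), min(end, len(arr))
        out = np.full(end - start, pad_value, dtype=float)
        if hi > lo:
            out[lo - start: hi - start] = arr[lo:hi]
        return out


def frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    """Order-insensitive equality of two fragment/interval frames."""
    key = [c for c in ("chrom", "start", "end", "strand") if c in a.columns]
    sa = a.sort_values(key, kind="mergesort").reset_index(drop=True)
    sb = b.sort_values(key, kind="mergesort").reset_index(drop=True)
    return sa.equals(sb)
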