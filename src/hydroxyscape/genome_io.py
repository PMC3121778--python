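"""Readers and writers for the coordinate universe of the pipeline.

All coordinates are 0-based, half-open (BED native). A sequencing tag is
represented by its 5'-most aligned coordinate plus strand; the nominal tag
length (38 bp for the libraries this pipeline was designed around) is kept
as metadata only — tags are counted as points, never extended to fragments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAssembly",
    "GenomicInterval",
    "IntervalSet",
    "TagCollection",
    "GeneModel",
    "MethylationCalls",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_aligned_tags",
    "write_aligned_tags",
    "write_bedgraph",
    "read_bedgraph",
    "read_methylation_table",
    "write_methylation_table",
    "read_gene_table",
    "union_length",
]

DEFAULT_TAG_LENGTH = 38

STRANDS = ("+", "-", ".")


class GenomeIOError(ValueError):
    """Malformed input file or coordinate outside the assembly."""


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and lengths: the coordinate universe.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs in file order.
    sex_chromosomes
        Subset of names whose expected-by-chance read share is halved in
        haploid-sex-chromosome corrections (see
        :func:`hydroxyscape.signal_binning.chromosome_density`).
    """

    chromosomes: tuple[tuple[str, int], ...]
    sex_chromosomes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise GenomeIOError("duplicate chromosome name in assembly")
        for n, length in self.chromosomes:
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise GenomeIOError(f"chromosome {n!r}: length must be a positive integer, got {length!r}")
        unknown_sex = set(self.sex_chromosomes) - set(names)
        if unknown_sex:
            raise GenomeIOError(f"sex chromosomes not in assembly: {sorted(unknown_sex)}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise GenomeIOError(f"unknown chromosome {name!r}") from None


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open stranded region ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise GenomeIOError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total base coverage of the union of intervals (overlaps collapsed)."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for spans in per_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


@dataclass(frozen=True)
class IntervalSet:
    """A labelled collection of intervals, e.g. peaks, CpG islands, enhancers."""

    label: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))

    @property
    def base_coverage(self) -> int:
        """Length of the union of member intervals in bp."""
        if not self.intervals:
            return 0
        return union_length(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def validate_against(self, assembly: GenomeAssembly) -> None:
        for iv in self.intervals:
            L = assembly.length_of(iv.chrom)
            if iv.end > L:
                raise GenomeIOError(
                    f"{self.label}: interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {L}"
                )


@dataclass
class TagCollection:
    """Aligned single-end tags as (chrom, 5' start, strand) triples.

    ``frame`` holds columns ``chrom`` (str), ``start`` (int64, the 5'-most
    aligned base), ``strand`` ('+'/'-').
    """

    frame: pd.DataFrame
    tag_length: int = DEFAULT_TAG_LENGTH
    deduplicated: bool = False

    REQUIRED = ("chrom", "start", "strand")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise GenomeIOError(f"tag frame missing columns {missing}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def total_tags(self) -> int:
        return len(self.frame)

    def deduplicate(self) -> "TagCollection":
        """Collapse tags sharing (chrom, 5' start, strand) to one. Idempotent."""
        dedup = self.frame.drop_duplicates(subset=["chrom", "start", "strand"], ignore_index=True)
        return TagCollection(dedup, tag_length=self.tag_length, deduplicated=True)

    def starts(self, chrom: str, sort: bool = True) -> np.ndarray:
        """5' start coordinates on one chromosome (sorted by default)."""
        v = self.frame.loc[self.frame["chrom"] == chrom, "start"].to_numpy(np.int64)
        return np.sort(v) if sort else v

    def counts_per_chrom(self) -> pd.Series:
        return self.frame["chrom"].value_counts()

    def subset(self, chroms: Iterable[str]) -> "TagCollection":
        keep = self.frame["chrom"].isin(set(chroms))
        return TagCollection(self.frame[keep], tag_length=self.tag_length, deduplicated=self.deduplicated)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS/TES anchors and an expression value (RPKM).

    For '+' strand genes the TSS is ``interval.start`` and the TES is
    ``interval.end``; '-' strand genes are the mirror image.
    """

    interval: GenomicInterval
    rpkm: float

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise GenomeIOError("gene model requires a stranded interval")
        if self.rpkm < 0:
            raise GenomeIOError("rpkm must be non-negative")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def name(self) -> str | None:
        return self.interval.name


@dataclass
class MethylationCalls:
    """Per-cytosine methylation calls with read support.

    ``frame`` columns: ``chrom``, ``pos`` (0-based), ``context``
    (CG/CHG/CHH), ``meth`` (methylated read count), ``total`` (coverage).
    """

    frame: pd.DataFrame

    REQUIRED = ("chrom", "pos", "context", "meth", "total")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise GenomeIOError(f"methylation frame missing columns {missing}")
        bad = self.frame["meth"] > self.frame["total"]
        if bool(bad.any()):
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = self.frame.iloc[i]
            raise GenomeIOError(
                f"methylated reads exceed coverage at {row['chrom']}:{row['pos']} ({row['meth']}>{row['total']})"
            )
        self.frame = self.frame.reset_index(drop=True)

    def in_context(self, context: str) -> "MethylationCalls":
        return MethylationCalls(self.frame[self.frame["context"] == context])


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path, sex_chromosomes: Iterable[str] = ()) -> GenomeAssembly:
    """Read a UCSC-style two-column chrom.sizes file, preserving order."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise GenomeIOError(f"{path}:{lineno}: expected 'name length', got {line.strip()!r}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise GenomeIOError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
            if length <= 0:
                raise GenomeIOError(f"{path}:{lineno}: non-positive length {length} for {name!r}")
            if name in seen:
                raise GenomeIOError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise GenomeIOError(f"{path}: empty chrom.sizes file")
    return GenomeAssembly(tuple(chroms), frozenset(sex_chromosomes))


def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in assembly.chromosomes:
            fh.write(f"{name}\t{length}\n")


def _parse_bed_line(line: str, lineno: int, path: str) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:  # tolerate space-delimited BED
        fields = line.split()
    if len(fields) < 3:
        raise GenomeIOError(f"{path}:{lineno}: fewer than 3 BED fields")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise GenomeIOError(f"{path}:{lineno}: non-integer coordinates") from None
    if start >= end:
        raise GenomeIOError(f"{path}:{lineno}: start {start} >= end {end}")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score: float | None = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError:
            raise GenomeIOError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from None
    strand = fields[5] if len(fields) > 5 else "."
    if strand not in STRANDS:
        raise GenomeIOError(f"{path}:{lineno}: invalid strand {strand!r}")
    return GenomicInterval(fields[0], start, end, strand, name, score)


def read_bed_intervals(
    path: str | Path, assembly: GenomeAssembly, label: str | None = None
) -> IntervalSet:
    """Read BED3/BED6 intervals, validated against the assembly."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(line, lineno, str(path))
            if iv.chrom not in assembly:
                raise GenomeIOError(f"{path}:{lineno}: unknown chromosome {iv.chrom!r}")
            if iv.end > assembly.length_of(iv.chrom):
                raise GenomeIOError(
                    f"{path}:{lineno}: end {iv.end} exceeds {iv.chrom} length {assembly.length_of(iv.chrom)}"
                )
            intervals.append(iv)
    return IntervalSet(label or Path(path).stem, tuple(intervals))


def write_bed_intervals(regions: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_aligned_tags(
    path: str | Path,
    assembly: GenomeAssembly,
    deduplicate: bool = True,
    tag_length: int = DEFAULT_TAG_LENGTH,
) -> TagCollection:
    """Read aligned tags from BED6; the 5' coordinate is the BED start for
    '+' tags and ``end - 1`` for '-' tags. Optionally collapse duplicates
    (identical chrom, 5' start, strand), mirroring the unique-non-duplicate
    alignment filter."""
    chroms: list[str] = []
    starts: list[int] = []
    strands: list[str] = []
    lengths = assembly.lengths
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(line, lineno, str(path))
            if iv.chrom not in lengths:
                raise GenomeIOError(f"{path}:{lineno}: unknown chromosome {iv.chrom!r}")
            if iv.end > lengths[iv.chrom]:
                raise GenomeIOError(f"{path}:{lineno}: tag out of bounds on {iv.chrom}")
            if iv.strand not in ("+", "-"):
                raise GenomeIOError(f"{path}:{lineno}: tags require explicit strand")
            five_p = iv.start if iv.strand == "+" else iv.end - 1
            chroms.append(iv.chrom)
            starts.append(five_p)
            strands.append(iv.strand)
    frame = pd.DataFrame(
        {"chrom": chroms, "start": np.asarray(starts, np.int64), "strand": strands}
    )
    tags = TagCollection(frame, tag_length=tag_length)
    return tags.deduplicate() if deduplicate else tags


def write_aligned_tags(tags: TagCollection, path: str | Path) -> None:
    """Write tags as single-base BED6 stubs marking the 5' coordinate.

    One base per tag keeps the file within chromosome bounds for tags near
    an end; :func:`read_aligned_tags` recovers the identical 5' coordinate
    for either strand.
    """
    with open(path, "w") as fh:
        for row in tags.frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.start + 1}\ttag\t0\t{row.strand}\n")


def write_bedgraph(track, path: str | Path, omit_zero: bool = True, decimals: int = 6) -> None:
    """Write a :class:`~hydroxyscape.signal_binning.BinnedTrack` as bedGraph.

    NaN bins (missing values, e.g. uncovered methylation bins) are always
    omitted; zero bins are omitted when ``omit_zero``.
    """
    bin_size = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.assembly.names:
            values = track.data[chrom]
            L = track.assembly.length_of(chrom)
            for i, v in enumerate(values):
                if np.isnan(v) or (omit_zero and v == 0):
                    continue
                start = i * bin_size
                end = min(start + bin_size, L)
                fh.write(f"{chrom}\t{start}\t{end}\t{round(float(v), decimals):.{decimals}f}\n")


def read_bedgraph(path: str | Path, assembly: GenomeAssembly, bin_size: int, units: str = "rpm"):
    """Read a bedGraph written by :func:`write_bedgraph` back into a track.

    Bins absent from the file are zero (the omit-zero convention).
    """
    from .signal_binning import BinnedTrack  # local import to avoid a cycle

    track = BinnedTrack.zeros(assembly, bin_size, units=units)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, _e, v = line.split()[:4]
            if chrom not in assembly:
                raise GenomeIOError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            idx = int(s) // bin_size
            track.data[chrom][idx] = float(v)
    return track


METHYLATION_COLUMNS = ["chrom", "pos", "context", "meth", "total"]


def read_methylation_table(path: str | Path) -> MethylationCalls:
    """Read a tab-delimited per-position methylation call table
    (chrom, pos, context, methylated reads, total reads)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=METHYLATION_COLUMNS,
        dtype={"chrom": str, "pos": np.int64, "context": str, "meth": np.int64, "total": np.int64},
    )
    return MethylationCalls(frame)


def write_methylation_table(calls: MethylationCalls, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(METHYLATION_COLUMNS) + "\n")
        calls.frame.to_csv(fh, sep="\t", header=False, index=False)


def read_gene_table(path: str | Path, assembly: GenomeAssembly) -> list[GeneModel]:
    """Read gene models from BED6 where the score column carries RPKM."""
    regions = read_bed_intervals(path, assembly, label="genes")
    genes = []
    for iv in regions:
        genes.append(GeneModel(iv, float(iv.score if iv.score is not None else 0.0)))
    return genes
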