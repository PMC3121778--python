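"""Genome-wide fixed-width binning and normalisation of tag counts.

Tags are counted by their 5' coordinate into bins of a fixed width (1 kb,
5 kb and 10 kb are the conventional choices; 10 kb is the reporting
default), normalised to reads per million (RPM) of the library, and
enriched-library values are background-corrected by subtracting the
identically processed unenriched-input track per bin. Negative values after
subtraction are preserved — no clipping rule is applied, which keeps the
subtraction invertible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GenomeAssembly, TagCollection

__all__ = [
    "BinnedTrack",
    "count_tags_in_bins",
    "normalize_rpm",
    "subtract_input",
    "chromosome_density",
    "DEFAULT_BIN_SIZE",
]

DEFAULT_BIN_SIZE = 10_000

UNITS = ("raw_counts", "rpm", "rpm_minus_input", "percent")


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width signal vectors over a genome assembly.

    The vector for a chromosome of length L has ``ceil(L / bin_size)``
    entries; the last bin may be short. NaN marks a missing value (used by
    methylation tracks for bins with no covered cytosine).
    """

    assembly: GenomeAssembly
    bin_size: int
    data: dict[str, np.ndarray]
    units: str = "raw_counts"
    total_tags_used: int = 0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}")
        for name in self.assembly.names:
            expected = self.n_bins(name)
            if name not in self.data:
                raise ValueError(f"track missing chromosome {name!r}")
            if len(self.data[name]) != expected:
                raise ValueError(
                    f"{name}: expected {expected} bins, got {len(self.data[name])}"
                )

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.assembly.length_of(chrom) / self.bin_size)

    @classmethod
    def zeros(cls, assembly: GenomeAssembly, bin_size: int, units: str = "raw_counts") -> "BinnedTrack":
        data = {
            name: np.zeros(math.ceil(length / bin_size))
            for name, length in assembly.chromosomes
        }
        return cls(assembly, bin_size, data, units=units)

    def values(self) -> np.ndarray:
        """All bin values concatenated in assembly order."""
        return np.concatenate([self.data[n] for n in self.assembly.names])

    def total(self) -> float:
        return float(np.nansum(self.values()))

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.assembly.chromosomes == other.assembly.chromosomes
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.assembly.names:
            v = self.data[chrom]
            starts = np.arange(len(v), dtype=np.int64) * self.bin_size
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "value": v}))
        return pd.concat(rows, ignore_index=True)


def count_tags_in_bins(
    tags: TagCollection, assembly: GenomeAssembly, bin_size: int = DEFAULT_BIN_SIZE
) -> BinnedTrack:
    """Count tags into fixed-width bins by 5' coordinate.

    A tag at position p lands in bin ``floor(p / bin_size)``. The sum over
    all bins equals the number of in-bounds tags.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    data: dict[str, np.ndarray] = {}
    used = 0
    for chrom, length in assembly.chromosomes:
        n_bins = math.ceil(length / bin_size)
        pos = tags.starts(chrom, sort=False)
        pos = pos[(pos >= 0) & (pos < length)]
        counts = np.bincount(pos // bin_size, minlength=n_bins).astype(float)
        used += int(pos.size)
        data[chrom] = counts
    return BinnedTrack(assembly, bin_size, data, units="raw_counts", total_tags_used=used)


def normalize_rpm(track: BinnedTrack, total_tags: int) -> BinnedTrack:
    """Normalise raw counts to reads per million: value / (total_tags / 1e6).

    ``total_tags`` is the library size (total non-duplicate reads), which
    may exceed the in-bounds count held by the track.
    """
    if total_tags <= 0:
        raise ValueError("total_tags must be positive")
    scale = 1e6 / total_tags
    data = {c: v * scale for c, v in track.data.items()}
    return BinnedTrack(
        track.assembly, track.bin_size, data, units="rpm", total_tags_used=track.total_tags_used
    )


def subtract_input(ip: BinnedTrack, input_track: BinnedTrack) -> BinnedTrack:
    """Per-bin enriched-minus-input signal. Negative values are retained."""
    if not ip.same_grid(input_track):
        raise ValueError("IP and input tracks are on different bin grids")
    data = {c: ip.data[c] - input_track.data[c] for c in ip.data}
    return BinnedTrack(
        ip.assembly, ip.bin_size, data, units="rpm_minus_input", total_tags_used=ip.total_tags_used
    )


def chromosome_density(
    tags: TagCollection,
    assembly: GenomeAssembly,
    halve: set[str] | frozenset[str] | None = None,
) -> pd.DataFrame:
    """Observed vs expected-by-chance per-chromosome read densities.

    observed_rpm = 1e6 * tags_on_chrom / total_tags;
    expected_rpm = 1e6 * L_chrom / L_genome, halved afterwards for
    chromosomes in ``halve`` (the haploid-sex-chromosome correction in a
    male diploid sample — conventionally {X, Y}, supplied by the caller).

    Returns a DataFrame indexed by chromosome with columns
    ``observed_rpm`` and ``expected_rpm``.
    """
    if tags.total_tags == 0:
        raise ValueError("empty tag collection")
    halve = set(halve or ())
    unknown = halve - set(assembly.names)
    if unknown:
        raise ValueError(f"halve names not in assembly: {sorted(unknown)}")
    counts = tags.counts_per_chrom()
    total = tags.total_tags
    L_G = assembly.total_length
    rows = {}
    for chrom, L_c in assembly.chromosomes:
        observed = 1e6 * counts.get(chrom, 0) / total
        expected = 1e6 * L_c / L_G
        if chrom in halve:
            expected /= 2.0
        rows[chrom] = (observed, expected)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["observed_rpm", "expected_rpm"]
    ).rename_axis("chrom")
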