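"""Sequence-composition statistics of genomic region sets.

Dinucleotide observed/expected (O/E) ratios follow the classical CpG-island
convention: over a region set, the observed frequency of a dinucleotide XY
(overlapping 2-mers, pooled across all regions) is divided by the product
of the pooled mononucleotide frequencies freq(X)*freq(Y). Ratios are
computed once per region set, not averaged per region. Ambiguous bases (N)
are excluded from both the mono- and dinucleotide counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeAssembly, GenomicInterval, IntervalSet

__all__ = [
    "DinucleotideOEReport",
    "GCReport",
    "dinucleotide_oe",
    "gc_profile",
    "sample_random_regions",
    "fetch_sequence",
]

NUCS = "ACGT"
DINUCS = tuple(x + y for x in NUCS for y in NUCS)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(NUCS):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch a subsequence from a pyfaidx.Fasta or a plain mapping of strings."""
    seq = genome[chrom][start:end]
    return str(seq if isinstance(seq, str) else getattr(seq, "seq", seq))


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class DinucleotideOEReport:
    """Pooled O/E ratios over a region set."""

    label: str
    observed: dict[str, int]          # dinucleotide -> pooled 2-mer count
    oe_ratio: dict[str, float]
    mono_counts: dict[str, int]
    n_windows: int                    # W: total valid overlapping 2-mers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed": pd.Series(self.observed),
                "oe_ratio": pd.Series(self.oe_ratio),
            }
        ).rename_axis("dinucleotide")


@dataclass(frozen=True)
class GCReport:
    label: str
    gc_fractions: tuple[float, ...]   # per interval, NaN where all-N
    n_undefined: int

    def cdf(self) -> pd.DataFrame:
        """Empirical CDF over defined intervals as (gc, cumulative_fraction)."""
        vals = np.sort([g for g in self.gc_fractions if not np.isnan(g)])
        if vals.size == 0:
            raise ValueError("no defined GC values")
        frac = np.arange(1, vals.size + 1) / vals.size
        return pd.DataFrame({"gc": vals, "cumulative_fraction": frac})

    def cdf_at(self, gc: float) -> float:
        vals = np.asarray([g for g in self.gc_fractions if not np.isnan(g)])
        return float(np.mean(vals <= gc))


def dinucleotide_oe(regions: IntervalSet, genome, both_strands: bool = False) -> DinucleotideOEReport:
    """Pooled dinucleotide O/E ratios over a region set.

    With ``both_strands`` each region contributes its reverse complement as
    well (given-strand counting is the default).
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    mono = np.zeros(4, dtype=np.int64)
    di = np.zeros((4, 4), dtype=np.int64)
    n_windows = 0
    for iv in regions:
        if len(iv) < 2:
            raise ValueError(f"region {iv.chrom}:{iv.start}-{iv.end} shorter than 2 bp")
        codes = _encode(fetch_sequence(genome, iv.chrom, iv.start, iv.end))
        variants = [codes]
        if both_strands:
            rc = codes[::-1].copy()
            valid = rc >= 0
            rc[valid] = 3 - rc[valid]  # A<->T, C<->G under the ACGT coding
            variants.append(rc)
        for c in variants:
            valid = c >= 0
            mono += np.bincount(c[valid], minlength=4)
            x, y = c[:-1], c[1:]
            ok = (x >= 0) & (y >= 0)
            if ok.any():
                np.add.at(di, (x[ok], y[ok]), 1)
                n_windows += int(ok.sum())
    if n_windows == 0:
        raise ValueError("no valid dinucleotide windows (all-N regions?)")
    total_mono = mono.sum()
    freq = mono / total_mono
    observed: dict[str, int] = {}
    oe: dict[str, float] = {}
    for i, x in enumerate(NUCS):
        for j, y in enumerate(NUCS):
            observed[x + y] = int(di[i, j])
            expected = freq[i] * freq[j]
            oe[x + y] = (di[i, j] / n_windows) / expected if expected > 0 else np.nan
    return DinucleotideOEReport(
        regions.label,
        observed,
        oe,
        {b: int(mono[i]) for i, b in enumerate(NUCS)},
        n_windows,
    )


def gc_profile(regions: IntervalSet, genome) -> GCReport:
    """Per-interval GC fraction (G+C over unambiguous bases) and its CDF."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    fractions: list[float] = []
    n_undef = 0
    for iv in regions:
        codes = _encode(fetch_sequence(genome, iv.chrom, iv.start, iv.end))
        valid = codes >= 0
        n_valid = int(valid.sum())
        if n_valid == 0:
            fractions.append(np.nan)
            n_undef += 1
            continue
        gc = int(np.isin(codes[valid], (1, 2)).sum())
        fractions.append(gc / n_valid)
    return GCReport(regions.label, tuple(fractions), n_undef)


def sample_random_regions(
    assembly: GenomeAssembly,
    n: int,
    lengths: int | Sequence[int] | IntervalSet,
    seed: int,
    label: str = "random_regions",
) -> IntervalSet:
    """Uniformly placed random regions, chromosome chosen proportional to length.

    ``lengths`` is a fixed bp length, an explicit sequence to resample from,
    or an IntervalSet whose member lengths are resampled — the
    length-matched null for composition comparisons.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(lengths, IntervalSet):
        pool = np.asarray([len(iv) for iv in lengths.intervals], np.int64)
        if pool.size == 0:
            raise ValueError("length source set is empty")
        lens = rng.choice(pool, size=n, replace=True)
    elif np.isscalar(lengths):
        lens = np.full(n, int(lengths), np.int64)
    else:
        pool = np.asarray(lengths, np.int64)
        lens = rng.choice(pool, size=n, replace=True)
    chrom_names = list(assembly.names)
    chrom_lens = np.asarray([assembly.length_of(c) for c in chrom_names], np.int64)
    if lens.max() > chrom_lens.max():
        raise ValueError("requested length exceeds every chromosome")
    p = chrom_lens / chrom_lens.sum()
    intervals: list[GenomicInterval] = []
    for length in lens:
        length = int(length)
        while True:
            ci = int(rng.choice(len(chrom_names), p=p))
            if chrom_lens[ci] >= length:
                break
        start = int(rng.integers(0, chrom_lens[ci] - length + 1))
        intervals.append(GenomicInterval(chrom_names[ci], start, start + length, "."))
    return IntervalSet(label, tuple(intervals))
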