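"""Positional profile matrices around genomic anchors.

Three layouts cover the profiling needs of an enrichment-sequencing study:

* **anchored** — fixed-width bins centred on a point anchor (TSS or TES),
  e.g. 100-bp bins over +/-5 kb for heatmaps, or 10-bp bins over +/-2.5 kb
  for stratum curves;
* **three-segment** — a fixed core region (4 kb in 100-bp bins) centred on
  a feature, plus equally binned flanks of the same width up- and
  downstream (120 columns total), used for chromatin-signature classes;
* **scaled** — each site and flanking windows of one site-length each are
  divided into a fixed number of proportional portions (40 per segment),
  so sites of different lengths align column-wise.

Values are tag counts normalised to reads per million of the library;
when an input library is supplied it is binned and normalised identically
and subtracted. Rows of '-' strand features are flipped once, at matrix
construction, so upstream is always on the left. Bins extending past a
chromosome end are missing (NaN), not zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeAssembly, GeneModel, GenomicInterval, IntervalSet, TagCollection

__all__ = [
    "ProfileMatrix",
    "ExpressionStrata",
    "SegmentLayout",
    "stratify_by_expression",
    "anchored_profile",
    "three_segment_profile",
    "scaled_site_profile",
    "profile_summary",
    "classify_bimodal",
]

STRATA = ("top25", "mid25_50", "mid50_75", "bottom25")


@dataclass
class ProfileMatrix:
    """Features-by-positional-bins matrix of normalised tag densities."""

    values: np.ndarray                # (n_rows, n_cols), NaN = missing
    row_ids: tuple[str, ...]
    anchor: str                       # "TSS", "TES", "center", "site"
    bin_size: int | None              # bp per column; None for scaled layouts
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.row_ids):
            raise ValueError("values shape inconsistent with row_ids")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids))


@dataclass(frozen=True)
class ExpressionStrata:
    """Gene index quartiles by descending expression (RPKM)."""

    top25: tuple[int, ...]
    mid25_50: tuple[int, ...]
    mid50_75: tuple[int, ...]
    bottom25: tuple[int, ...]

    def group(self, name: str) -> tuple[int, ...]:
        return getattr(self, name)

    def all_groups(self) -> dict[str, tuple[int, ...]]:
        return {s: getattr(self, s) for s in STRATA}


@dataclass(frozen=True)
class SegmentLayout:
    """Three-segment fixed layout: flank | core | flank, each equally binned."""

    core_width: int = 4000
    core_bin: int = 100
    flank_width: int = 4000
    flank_bin: int = 100

    def __post_init__(self) -> None:
        if self.core_width % self.core_bin or self.flank_width % self.flank_bin:
            raise ValueError("segment widths must be divisible by their bin sizes")

    @property
    def n_cols(self) -> int:
        return 2 * (self.flank_width // self.flank_bin) + self.core_width // self.core_bin


def stratify_by_expression(genes: Sequence[GeneModel]) -> ExpressionStrata:
    """Quartile gene groups by descending RPKM (stable sort; ties keep
    input order), split at floor(n/4), floor(n/2), floor(3n/4)."""
    n = len(genes)
    if n == 0:
        raise ValueError("empty gene list")
    order = np.argsort([-g.rpkm for g in genes], kind="stable")
    q1, q2, q3 = n // 4, n // 2, (3 * n) // 4
    return ExpressionStrata(
        tuple(int(i) for i in order[:q1]),
        tuple(int(i) for i in order[q1:q2]),
        tuple(int(i) for i in order[q2:q3]),
        tuple(int(i) for i in order[q3:]),
    )


def _counts_at_edges(pos_sorted: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(pos_sorted, edges, side="left")
    return (idx[1:] - idx[:-1]).astype(float)


def _profile_rows(
    tags: TagCollection,
    rows: Sequence[tuple[str, np.ndarray, str]],
    assembly: GenomeAssembly,
    mask_bounds: bool,
) -> np.ndarray:
    """Count tags per row given per-row bin-edge arrays (chrom, edges, strand)."""
    out = np.empty((len(rows), len(rows[0][1]) - 1 if rows else 0), float)
    cache: dict[str, np.ndarray] = {}
    for i, (chrom, edges, strand) in enumerate(rows):
        if chrom not in cache:
            cache[chrom] = tags.starts(chrom)
        counts = _counts_at_edges(cache[chrom], edges)
        if mask_bounds:
            L = assembly.length_of(chrom)
            oob = (edges[1:] <= 0) | (edges[:-1] >= L)
            counts[oob] = np.nan
        if strand == "-":
            counts = counts[::-1]
        out[i] = counts
    return out


def _normalize(matrix: np.ndarray, total_tags: int) -> np.ndarray:
    if total_tags <= 0:
        raise ValueError("library size must be positive")
    return matrix / (total_tags / 1e6)


def anchored_profile(
    tags: TagCollection,
    input_tags: TagCollection | None,
    genes: Sequence[GeneModel],
    assembly: GenomeAssembly,
    anchor: str = "TSS",
    flank: int = 5000,
    bin_size: int = 100,
) -> ProfileMatrix:
    """Per-gene tag densities in fixed bins centred on the TSS or TES.

    Column 0 is the most upstream bin regardless of gene strand.
    """
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be 'TSS' or 'TES'")
    if flank % bin_size:
        raise ValueError("flank must be divisible by bin_size")
    if not genes:
        raise ValueError("empty gene list")
    n_cols = 2 * flank // bin_size
    rows = []
    ids = []
    for k, g in enumerate(genes):
        a = g.tss if anchor == "TSS" else g.tes
        edges = a - flank + bin_size * np.arange(n_cols + 1, dtype=np.int64)
        rows.append((g.interval.chrom, edges, g.strand))
        ids.append(g.name or f"gene_{k}")
    mat = _profile_rows(tags, rows, assembly, mask_bounds=True)
    mat = _normalize(mat, tags.total_tags)
    if input_tags is not None:
        imat = _profile_rows(input_tags, rows, assembly, mask_bounds=True)
        mat = mat - _normalize(imat, input_tags.total_tags)
    return ProfileMatrix(
        mat,
        tuple(ids),
        anchor=anchor,
        bin_size=bin_size,
        metadata={"flank": flank, "layout": "anchored", "input_subtracted": input_tags is not None},
    )


def three_segment_profile(
    tags: TagCollection,
    input_tags: TagCollection | None,
    regions: IntervalSet,
    assembly: GenomeAssembly,
    layout: SegmentLayout = SegmentLayout(),
) -> ProfileMatrix:
    """Flank | core | flank binned profile centred on each region's midpoint."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    rows = []
    ids = []
    half_core = layout.core_width // 2
    for k, iv in enumerate(regions):
        c = iv.center
        up = c - half_core - layout.flank_width + layout.flank_bin * np.arange(
            layout.flank_width // layout.flank_bin, dtype=np.int64
        )
        core = c - half_core + layout.core_bin * np.arange(
            layout.core_width // layout.core_bin, dtype=np.int64
        )
        down = c + half_core + layout.flank_bin * np.arange(
            layout.flank_width // layout.flank_bin + 1, dtype=np.int64
        )
        edges = np.concatenate([up, core, down])
        rows.append((iv.chrom, edges, iv.strand))
        ids.append(iv.name or f"region_{k}")
    mat = _profile_rows(tags, rows, assembly, mask_bounds=True)
    mat = _normalize(mat, tags.total_tags)
    if input_tags is not None:
        imat = _profile_rows(input_tags, rows, assembly, mask_bounds=True)
        mat = mat - _normalize(imat, input_tags.total_tags)
    return ProfileMatrix(
        mat,
        tuple(ids),
        anchor="center",
        bin_size=layout.core_bin if layout.core_bin == layout.flank_bin else None,
        metadata={"layout": "three_segment", "segments": layout, "input_subtracted": input_tags is not None},
    )


def _scaled_edges(s0: int, length: int, portions: int) -> np.ndarray:
    """Edges assigning offset o to portion floor(portions*o/length)."""
    k = np.arange(portions + 1, dtype=np.int64)
    return s0 + np.ceil(k * length / portions).astype(np.int64)


def scaled_site_profile(
    tags: TagCollection,
    input_tags: TagCollection | None,
    sites: IntervalSet,
    assembly: GenomeAssembly,
    portions: int = 40,
) -> ProfileMatrix:
    """Length-scaled profiles: upstream window, site, downstream window,
    each split into ``portions`` proportional sub-intervals (3*portions
    columns). Flank windows have the same length as the site itself."""
    if portions < 1:
        raise ValueError("portions must be >= 1")
    if len(sites) == 0:
        raise ValueError("empty site set")
    rows = []
    ids = []
    for k, iv in enumerate(sites):
        L = len(iv)
        up = _scaled_edges(iv.start - L, L, portions)[:-1]
        within = _scaled_edges(iv.start, L, portions)[:-1]
        down = _scaled_edges(iv.end, L, portions)
        edges = np.concatenate([up, within, down])
        rows.append((iv.chrom, edges, iv.strand))
        ids.append(iv.name or f"site_{k}")
    mat = _profile_rows(tags, rows, assembly, mask_bounds=True)
    mat = _normalize(mat, tags.total_tags)
    if input_tags is not None:
        imat = _profile_rows(input_tags, rows, assembly, mask_bounds=True)
        mat = mat - _normalize(imat, input_tags.total_tags)
    return ProfileMatrix(
        mat,
        tuple(ids),
        anchor="site",
        bin_size=None,
        metadata={"layout": "scaled", "portions": portions, "input_subtracted": input_tags is not None},
    )


def profile_summary(matrix: ProfileMatrix, rows: Sequence[int] | None = None) -> np.ndarray:
    """Column-wise mean curve over a row subset, ignoring missing values."""
    sub = matrix.values if rows is None else matrix.values[list(rows)]
    if sub.shape[0] == 0:
        raise ValueError("empty row subset")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN columns
        return np.nanmean(sub, axis=0)


def classify_bimodal(
    matrix: ProfileMatrix,
    flank_offset_bp: int,
    center_cols: int = 5,
    flank_cols: int = 5,
    ratio: float = 0.5,
) -> np.ndarray:
    """Per-row bimodality call: True when the mean over the central
    ``center_cols`` columns is below ``ratio`` times the mean over columns
    at +/- ``flank_offset_bp`` from the anchor (``flank_cols`` columns per
    side). Characterises TSS-depleted profiles with flanking peaks, the
    signature of highly expressed promoters."""
    if matrix.bin_size is None:
        raise ValueError("classifier requires a fixed-bin layout")
    m = matrix.values
    c0 = m.shape[1] // 2
    off = flank_offset_bp // matrix.bin_size
    half_c = center_cols // 2
    half_f = flank_cols // 2
    center = m[:, c0 - half_c : c0 - half_c + center_cols]
    left = m[:, c0 - off - half_f : c0 - off - half_f + flank_cols]
    right = m[:, c0 + off - half_f : c0 + off - half_f + flank_cols]
    with np.errstate(invalid="ignore"):
        c_mean = np.nanmean(center, axis=1)
        f_mean = np.nanmean(np.concatenate([left, right], axis=1), axis=1)
    return c_mean < ratio * f_mean
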