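"""Cross-mark correlation of binned tracks and percent-methylation tracks.

Two input-corrected tracks on the same bin grid are compared by the square
of the Pearson correlation over their bins (the r-squared of the genome-wide
scatter). Percent methylation per bin is the coverage-weighted value
100 * sum(methylated reads) / sum(total reads) over the cytosine positions
falling in the bin — positions with deeper coverage contribute
proportionally more, which is the only weighting per-position count data
support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_io import GenomeAssembly, MethylationCalls
from .signal_binning import BinnedTrack, DEFAULT_BIN_SIZE

__all__ = ["CorrelationResult", "correlate_tracks", "percent_methylation_track"]

BIN_FILTERS = ("all", "both_nonzero")


@dataclass(frozen=True)
class CorrelationResult:
    label_a: str
    label_b: str
    r_squared: float
    n_bins_used: int
    bin_size: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.r_squared <= 1.0 + 1e-12


def correlate_tracks(
    a: BinnedTrack,
    b: BinnedTrack,
    bin_filter: str = "all",
    label_a: str = "a",
    label_b: str = "b",
) -> CorrelationResult:
    """Squared Pearson correlation between two tracks on an identical grid.

    ``bin_filter='all'`` keeps every bin defined in both tracks;
    ``'both_nonzero'`` additionally drops bins where either value is zero
    (an alternative for sparse tracks where empty bins dominate). NaN bins
    (missing values) are always dropped.
    """
    if bin_filter not in BIN_FILTERS:
        raise ValueError(f"bin_filter must be one of {BIN_FILTERS}")
    if not a.same_grid(b):
        raise ValueError("tracks are on different bin grids")
    x = a.values()
    y = b.values()
    keep = ~(np.isnan(x) | np.isnan(y))
    if bin_filter == "both_nonzero":
        keep &= (x != 0) & (y != 0)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"only {x.size} usable bins; need >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one track; correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return CorrelationResult(label_a, label_b, min(float(r) ** 2, 1.0), int(x.size), a.bin_size)


def percent_methylation_track(
    calls: MethylationCalls,
    assembly: GenomeAssembly,
    bin_size: int = DEFAULT_BIN_SIZE,
    context: str = "CG",
) -> BinnedTrack:
    """Coverage-weighted percent methylation per fixed-width bin.

    Bins containing no covered cytosine in the requested context are NaN
    (missing), not zero — absence of data is not absence of methylation.
    """
    if context not in ("CG", "CHG", "CHH"):
        raise ValueError(f"unknown context {context!r}")
    sub = calls.in_context(context).frame
    track = BinnedTrack.zeros(assembly, bin_size, units="percent")
    for chrom in assembly.names:
        n_bins = track.n_bins(chrom)
        rows = sub[sub["chrom"] == chrom]
        pos = rows["pos"].to_numpy(np.int64)
        if np.any((pos < 0) | (pos >= assembly.length_of(chrom))):
            raise ValueError(f"methylation position out of bounds on {chrom}")
        idx = pos // bin_size
        meth = np.bincount(idx, weights=rows["meth"].to_numpy(float), minlength=n_bins)
        total = np.bincount(idx, weights=rows["total"].to_numpy(float), minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * meth / total
        pct[total == 0] = np.nan
        track.data[chrom] = pct
    return track
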