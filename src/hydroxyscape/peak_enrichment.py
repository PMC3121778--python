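"""Local-lambda Poisson peak calling and peak/feature overlap statistics.

The caller is a deliberately simple sliding-window scan in the spirit of
MACS-style ChIP-seq peak callers: windows of a fixed bandwidth slide along
each chromosome; each window's expected count is the most conservative
(largest) of a genome-wide background rate and locally estimated rates over
a set of flanking ranges, all estimated from the unenriched input library
when one is supplied (from the enriched library itself otherwise) and
scaled to the enriched library's depth and the window width; significance
is the upper-tail Poisson probability P(X >= k; lambda_local). Significant
windows closer than one tag length are merged into peaks. There is no
fragment-shift model and no dynamic background switching — the defaults
(p <= 1e-8, 200-bp bandwidth, 200/1000-bp local ranges, 38-bp tags,
2.7 Gb effective genome) match the parameter set this pipeline was built
around.

Feature association reports, for each annotation set, the fraction of peaks
overlapping it by >= 1 bp against the fraction expected by chance from the
annotation's base coverage, and their ratio (fold change over expected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeAssembly, GenomicInterval, IntervalSet, TagCollection

__all__ = [
    "PeakCallParams",
    "Peak",
    "call_peaks",
    "peaks_to_interval_set",
    "feature_association",
    "set_overlap",
    "overlap_percentages",
    "poisson_upper_tail",
]


@dataclass(frozen=True)
class PeakCallParams:
    """Tuning parameters of the sliding-window Poisson scan.

    ``effective_genome_size`` caps the genome length used for the
    background rate (mappable fraction of a real genome); on an assembly
    smaller than it, the assembly length itself is used.
    """

    p_cutoff: float = 1e-8
    bandwidth: int = 200
    lambda_ranges: tuple[int, ...] = (200, 1000)
    tag_size: int = 38
    effective_genome_size: float = 2.7e9
    window_step: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.p_cutoff < 1.0):
            raise ValueError("p_cutoff must be in (0, 1)")
        if self.bandwidth < self.window_step:
            raise ValueError("bandwidth must be >= window_step")
        if self.window_step < 1 or self.tag_size < 1:
            raise ValueError("window_step and tag_size must be >= 1")
        if any(r < 1 for r in self.lambda_ranges):
            raise ValueError("lambda ranges must be positive")


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    p_value: float
    summit: int
    tag_count: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit outside peak interval")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def poisson_upper_tail(k, lam):
    """P(X >= k) for X ~ Poisson(lam); vectorised, k >= 0."""
    k = np.asarray(k)
    return stats.poisson.sf(k - 1, lam)


def _window_counts(pos: np.ndarray, centers: np.ndarray, half_width: float) -> np.ndarray:
    """Counts of sorted positions in [center - hw, center + hw) per center."""
    lo = np.searchsorted(pos, centers - half_width, side="left")
    hi = np.searchsorted(pos, centers + half_width, side="left")
    return hi - lo


def call_peaks(
    ip: TagCollection,
    input_tags: TagCollection | None,
    assembly: GenomeAssembly,
    params: PeakCallParams = PeakCallParams(),
) -> list[Peak]:
    """Scan the genome for windows of significant tag enrichment.

    Returns peaks sorted by (chromosome order, start). Each peak carries the
    smallest window p-value inside it, the center of its highest-count
    window as the summit, and the tag count of the full merged interval.
    """
    if ip.total_tags == 0:
        raise ValueError("empty IP tag collection")
    n_ip = ip.total_tags
    have_input = input_tags is not None and input_tags.total_tags > 0
    lam_source = input_tags if have_input else ip
    # without a control library, a local range no wider than the window would
    # make each window its own background (lambda = k); drop such ranges
    ranges = tuple(
        r for r in params.lambda_ranges if have_input or r > params.bandwidth
    )
    n_src = lam_source.total_tags
    depth_scale = n_ip / n_src
    genome_len = min(params.effective_genome_size, assembly.total_length)
    bw = params.bandwidth
    lam_bg = n_src * depth_scale * bw / genome_len

    peaks: list[Peak] = []
    for chrom, L in assembly.chromosomes:
        ip_pos = ip.starts(chrom)
        if ip_pos.size == 0:
            continue
        src_pos = lam_source.starts(chrom)
        starts = np.arange(0, max(L - bw, 0) + 1, params.window_step, dtype=np.int64)
        centers = starts + bw / 2.0
        k = _window_counts(ip_pos, centers, bw / 2.0)
        lam = np.full(starts.shape, lam_bg)
        for r in ranges:
            local = _window_counts(src_pos, centers, r / 2.0) * depth_scale * (bw / r)
            np.maximum(lam, local, out=lam)
        # p-values only where the count could conceivably be significant
        candidate = k > lam
        p = np.ones_like(lam)
        if candidate.any():
            p[candidate] = poisson_upper_tail(k[candidate], lam[candidate])
        sig = np.flatnonzero(p <= params.p_cutoff)
        if sig.size == 0:
            continue
        # merge significant windows whose gap is < tag_size
        win_s = starts[sig]
        win_e = np.minimum(win_s + bw, L)
        breaks = np.flatnonzero(win_s[1:] - win_e[:-1] >= params.tag_size)
        group_starts = np.r_[0, breaks + 1]
        group_ends = np.r_[breaks, sig.size - 1]
        for g0, g1 in zip(group_starts, group_ends):
            idx = sig[g0 : g1 + 1]
            region_start = int(win_s[g0])
            region_end = int(win_e[g1])
            best = idx[np.argmin(p[idx])]
            top = idx[np.argmax(k[idx])]
            summit = int(min(centers[top], region_end - 1))
            count = int(
                np.searchsorted(ip_pos, region_end) - np.searchsorted(ip_pos, region_start)
            )
            peaks.append(
                Peak(
                    GenomicInterval(chrom, region_start, region_end, "."),
                    p_value=float(p[best]),
                    summit=summit,
                    tag_count=count,
                )
            )
    return peaks


def peaks_to_interval_set(peaks: Sequence[Peak], label: str = "peaks") -> IntervalSet:
    intervals = []
    for i, pk in enumerate(peaks):
        score = float(-np.log10(pk.p_value)) if pk.p_value > 0 else 999.0
        intervals.append(
            GenomicInterval(pk.chrom, pk.start, pk.end, ".", name=f"peak_{i + 1}", score=score)
        )
    return IntervalSet(label, tuple(intervals))


# ---------------------------------------------------------------------------
# interval overlap machinery
# ---------------------------------------------------------------------------


def _merged_arrays(intervals: Iterable[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (start, end) arrays of the interval union."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, spans in per_chrom.items():
        spans.sort()
        merged_s, merged_e = [spans[0][0]], [spans[0][1]]
        for s, e in spans[1:]:
            if s > merged_e[-1]:
                merged_s.append(s)
                merged_e.append(e)
            else:
                merged_e[-1] = max(merged_e[-1], e)
        out[chrom] = (np.asarray(merged_s, np.int64), np.asarray(merged_e, np.int64))
    return out


def _overlaps_union(
    queries: Sequence[GenomicInterval],
    union: dict[str, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Boolean: does each query overlap >= 1 bp of the union intervals."""
    hits = np.zeros(len(queries), dtype=bool)
    for i, iv in enumerate(queries):
        if iv.chrom not in union:
            continue
        starts, ends = union[iv.chrom]
        # rightmost union interval starting left of the query end
        j = np.searchsorted(starts, iv.end, side="left")
        hits[i] = j > 0 and ends[j - 1] > iv.start
    return hits


def _as_intervals(obj) -> list[GenomicInterval]:
    out = []
    for item in obj:
        if isinstance(item, GenomicInterval):
            out.append(item)
        elif isinstance(item, Peak):
            out.append(item.interval)
        else:
            raise TypeError(f"cannot interpret {type(item).__name__} as an interval")
    return out


def feature_association(
    peaks,
    features: Sequence[IntervalSet],
    assembly: GenomeAssembly,
) -> pd.DataFrame:
    """Fold enrichment of peak/feature overlap over the genomic expectation.

    For each annotation set: ``observed_fraction`` is the fraction of peaks
    overlapping >= 1 bp of the set's interval union; ``expected_fraction``
    is the set's base coverage divided by the genome length (the chance a
    random position lies in the set); ``fold_change`` is their ratio. A peak
    may count toward several (non-exclusive) features. ``fraction_of_peaks``
    duplicates observed_fraction for report readability.
    """
    query = _as_intervals(peaks)
    if not query:
        raise ValueError("no peaks supplied")
    n = len(query)
    L_G = assembly.total_length
    rows = []
    for fs in features:
        cov = fs.base_coverage
        if cov <= 0:
            raise ValueError(f"feature set {fs.label!r} has zero base coverage")
        union = _merged_arrays(fs.intervals)
        n_hit = int(_overlaps_union(query, union).sum())
        observed = n_hit / n
        expected = cov / L_G
        rows.append(
            {
                "feature": fs.label,
                "n_peaks": n,
                "n_overlapping": n_hit,
                "observed_fraction": observed,
                "expected_fraction": expected,
                "fold_change": observed / expected,
                "fraction_of_peaks": observed,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def set_overlap(
    a: IntervalSet, b: IntervalSet, c: IntervalSet | None = None
) -> dict[str, float | int | str]:
    """Member-level >=1 bp overlap counts between interval sets (Venn-style).

    Counts members of each set overlapping any member of the other; with a
    third set, additionally counts members of ``a`` overlapping both ``b``
    and ``c``. Overlap is not symmetric in counts (one member of A may hit
    several of B), so both directions are reported.
    """
    union_a = _merged_arrays(a.intervals)
    union_b = _merged_arrays(b.intervals)
    a_ivs, b_ivs = list(a.intervals), list(b.intervals)
    a_in_b = int(_overlaps_union(a_ivs, union_b).sum()) if a_ivs and b_ivs else 0
    b_in_a = int(_overlaps_union(b_ivs, union_a).sum()) if a_ivs and b_ivs else 0
    report: dict[str, float | int | str] = {
        "label_a": a.label,
        "label_b": b.label,
        "n_a": len(a_ivs),
        "n_b": len(b_ivs),
        "a_overlapping_b": a_in_b,
        "b_overlapping_a": b_in_a,
        "pct_a_in_b": 100.0 * a_in_b / len(a_ivs) if a_ivs else 0.0,
        "pct_b_in_a": 100.0 * b_in_a / len(b_ivs) if b_ivs else 0.0,
    }
    if c is not None:
        union_c = _merged_arrays(c.intervals)
        triple = (
            int((_overlaps_union(a_ivs, union_b) & _overlaps_union(a_ivs, union_c)).sum())
            if a_ivs
            else 0
        )
        report["label_c"] = c.label
        report["n_c"] = len(c.intervals)
        report["a_overlapping_b_and_c"] = triple
    return report


def overlap_percentages(overlapping: int, total: int, decimals: int = 1) -> float:
    """Percentage 100*overlapping/total rounded half-up to ``decimals``.

    Half-up (not banker's) rounding reproduces conventionally printed
    percentages such as 58% or 34.4%.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= overlapping <= total):
        raise ValueError("need 0 <= overlapping <= total")
    pct = Decimal(100) * Decimal(overlapping) / Decimal(total)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))
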