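"""Synthetic genome, annotation and tag-library generator with planted truth.

Emulates every input the pipeline consumes, at a toy scale where every
expectation is analytic:

* a small multi-chromosome genome of i.i.d. sequence with CpG-depleted
  background (CG dinucleotides thinned after generation, mimicking the
  CpG suppression of vertebrate genomes) and CpG-island-like regions where
  GC content is raised and no thinning is applied, so island CG O/E exceeds
  background O/E by construction;
* non-overlapping gene models with lognormal expression (RPKM), each
  assigned a promoter class — P1 (bimodal: TSS-flanking intensity peaks
  with central depletion, the signature of highly expressed promoters),
  P2 (unimodal peak over the TSS) or unmarked;
* enhancer intervals with a planted fold enrichment, and gene-body folds
  that vary by expression stratum (intermediate strata above the top
  stratum, matching the non-monotone expression relationship the pipeline
  is designed to detect);
* IP and input tag libraries drawn by inverse-CDF sampling from a per-base
  piecewise-constant intensity — input homogeneous, IP proportional to the
  planted fold landscape — so every downstream estimator has a closed-form
  target;
* coverage-weighted methylation calls at CG positions, hypomethylated
  inside island-like regions.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    GenomeAssembly,
    GenomicInterval,
    GeneModel,
    IntervalSet,
    MethylationCalls,
    TagCollection,
)

__all__ = ["SimulationConfig", "SimulationTruth", "generate_truth", "simulate_tags", "simulate_mark_pair", "write_simulation"]

PROMOTER_CLASSES = ("P1", "P2", "unmarked")


@dataclass(frozen=True)
class SimulationConfig:
    """Planted study conditions for the generator.

    Defaults describe a two-chromosome 10 Mb toy genome carrying 200 genes
    and 100 enhancers, with libraries of a few hundred thousand tags —
    large enough that planted folds are recovered to a few percent, small
    enough that a full pipeline run takes seconds.
    """

    chrom_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    gc_content: float = 0.41
    cgi_gc_content: float = 0.60
    cpg_retention: float = 0.25       # background CG dinucleotides kept (CpG suppression)

    n_genes: int = 200
    gene_length: int = 20_000
    rpkm_log_mean: float = 1.0        # lognormal parameters of RPKM
    rpkm_log_sigma: float = 1.5
    promoter_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # P1, P2, unmarked

    n_enhancers: int = 100
    enhancer_length: int = 1_000
    enhancer_fold: float = 8.0

    # gene-body fold by expression stratum (intermediate > top)
    body_fold: Mapping[str, float] = field(
        default_factory=lambda: {"top25": 2.0, "mid25_50": 3.5, "mid50_75": 3.0, "bottom25": 1.5}
    )

    # promoter intensity shapes (bp offsets relative to the TSS)
    tss_peak_offset: int = 750
    tss_peak_halfwidth: int = 250
    tss_peak_fold: float = 6.0
    tss_depletion_halfwidth: int = 250
    tss_depletion_fold: float = 0.2
    p2_peak_halfwidth: int = 500
    p2_peak_fold: float = 4.0

    ip_tags: int = 400_000
    input_tags: int = 400_000
    tag_length: int = 38

    cgi_promoter_fraction: float = 0.5  # promoters carrying an island-like region
    cgi_halfwidth: int = 500
    meth_baseline_pct: float = 75.0
    meth_cgi_pct: float = 15.0
    meth_coverage: float = 20.0

    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.promoter_probs) - 1.0) > 1e-9:
            raise ValueError("promoter class probabilities must sum to 1")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if min(self.enhancer_fold, self.tss_peak_fold, self.p2_peak_fold) < 0:
            raise ValueError("folds must be non-negative")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))


@dataclass
class SimulationTruth:
    """Machine-readable record of everything planted."""

    config: SimulationConfig
    gene_classes: tuple[str, ...]       # per gene: P1/P2/unmarked
    gene_strata: tuple[str, ...]        # per gene: expression stratum
    gene_body_folds: tuple[float, ...]
    enhancer_fold: float

    def to_json(self, genes: Sequence[GeneModel], enhancers: IntervalSet, cgis: IntervalSet) -> str:
        cfg = asdict(self.config)
        cfg["body_fold"] = dict(self.config.body_fold)
        payload = {
            "config": cfg,
            "enhancer_fold": self.enhancer_fold,
            "genes": [
                {
                    "name": g.name,
                    "chrom": g.interval.chrom,
                    "start": g.interval.start,
                    "end": g.interval.end,
                    "strand": g.strand,
                    "rpkm": g.rpkm,
                    "class": c,
                    "stratum": s,
                    "body_fold": f,
                }
                for g, c, s, f in zip(genes, self.gene_classes, self.gene_strata, self.gene_body_folds)
            ],
            "enhancers": [[iv.chrom, iv.start, iv.end] for iv in enhancers],
            "cgi_like": [[iv.chrom, iv.start, iv.end] for iv in cgis],
        }
        return json.dumps(payload, indent=1)


def _simulate_sequence(rng: np.random.Generator, length: int, gc: float,
                       cgi_spans: list[tuple[int, int]], cgi_gc: float,
                       cpg_retention: float) -> np.ndarray:
    """Nucleotide codes (0..3 = ACGT) with CpG-suppressed background and
    unsuppressed, GC-rich island spans."""
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p_bg).astype(np.int8)
    in_cgi = np.zeros(length, dtype=bool)
    for s, e in cgi_spans:
        p_cgi = np.array([(1 - cgi_gc) / 2, cgi_gc / 2, cgi_gc / 2, (1 - cgi_gc) / 2])
        codes[s:e] = rng.choice(4, size=e - s, p=p_cgi)
        in_cgi[s:e] = True
    # CpG suppression outside islands: mutate the G of a CG pair to A or T
    cg = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2) & ~in_cgi[:-1])
    hit = cg[rng.random(cg.size) >= cpg_retention]
    codes[hit + 1] = np.where(rng.random(hit.size) < 0.5, 0, 3)
    return codes


def _codes_to_str(codes: np.ndarray) -> str:
    return codes.astype(np.uint8).choose(np.frombuffer(b"ACGT", np.uint8)).tobytes().decode()


def _place_non_overlapping(rng: np.random.Generator, chrom_lengths: Sequence[int],
                           n: int, length: int, margin: int,
                           occupied: dict[int, list[tuple[int, int]]] | None = None,
                           spacing: int = 0) -> list[tuple[int, int, int]]:
    """Place n intervals of fixed length, avoiding ``occupied`` spans and each
    other; returns (chrom index, start, end). Raises if the genome is too full."""
    occupied = occupied or {i: [] for i in range(len(chrom_lengths))}
    placed: list[tuple[int, int, int]] = []
    attempts = 0
    weights = np.asarray(chrom_lengths, float)
    weights /= weights.sum()
    while len(placed) < n:
        attempts += 1
        if attempts > 2000 * max(n, 1):
            raise ValueError("genome too small to place requested features")
        ci = int(rng.choice(len(chrom_lengths), p=weights))
        L = chrom_lengths[ci]
        if L < length + 2 * margin:
            continue
        s = int(rng.integers(margin, L - length - margin + 1))
        e = s + length
        clash = any(s - spacing < oe and os < e + spacing for os, oe in occupied[ci])
        if clash:
            continue
        occupied[ci].append((s, e))
        placed.append((ci, s, e))
    return placed


def generate_truth(config: SimulationConfig = SimulationConfig()):
    """Generate the full synthetic study: genome, annotations, methylation,
    and the truth record.

    Returns ``(assembly, sequences, genes, feature_sets, methylation, truth)``
    where ``sequences`` maps chromosome name to its string sequence and
    ``feature_sets`` holds 'enhancers', 'cgi_like', and per-class promoter
    window sets ('promoters_P1', 'promoters_P2').
    """
    from .feature_profiles import STRATA, stratify_by_expression

    rng = np.random.default_rng(config.seed)
    names = config.chrom_names
    assembly = GenomeAssembly(tuple(zip(names, config.chrom_lengths)))

    # --- genes ---------------------------------------------------------
    margin = 10_000  # keep profile windows fully on-chromosome
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(names))}
    gene_spans = _place_non_overlapping(
        rng, config.chrom_lengths, config.n_genes, config.gene_length, margin,
        occupied, spacing=2_000,
    )
    genes: list[GeneModel] = []
    for k, (ci, s, e) in enumerate(gene_spans):
        strand = "+" if rng.random() < 0.5 else "-"
        rpkm = float(rng.lognormal(config.rpkm_log_mean, config.rpkm_log_sigma))
        iv = GenomicInterval(names[ci], s, e, strand, name=f"gene_{k}")
        genes.append(GeneModel(iv, rpkm))
    classes = tuple(
        PROMOTER_CLASSES[i]
        for i in rng.choice(3, size=config.n_genes, p=list(config.promoter_probs))
    ) if config.n_genes else ()

    # expression strata and per-gene body folds
    strata_names = [""] * config.n_genes
    if config.n_genes:
        strata = stratify_by_expression(genes)
        for sname, idxs in strata.all_groups().items():
            for i in idxs:
                strata_names[i] = sname
    body_folds = tuple(config.body_fold[s] if s else 1.0 for s in strata_names)

    # --- enhancers -----------------------------------------------------
    enh_spans = _place_non_overlapping(
        rng, config.chrom_lengths, config.n_enhancers, config.enhancer_length,
        margin, occupied, spacing=2_000,
    )
    enhancers = IntervalSet(
        "enhancers",
        tuple(
            GenomicInterval(names[ci], s, e, ".", name=f"enh_{k}")
            for k, (ci, s, e) in enumerate(enh_spans)
        ),
    )

    # --- CpG-island-like regions at a fraction of promoters ------------
    cgi_ivs = []
    if config.n_genes:
        take = np.flatnonzero(rng.random(config.n_genes) < config.cgi_promoter_fraction)
        for i in take:
            tss = genes[i].tss
            cgi_ivs.append(
                GenomicInterval(
                    genes[i].interval.chrom,
                    max(tss - config.cgi_halfwidth, 0),
                    min(tss + config.cgi_halfwidth, assembly.length_of(genes[i].interval.chrom)),
                    ".",
                    name=f"cgi_{len(cgi_ivs)}",
                )
            )
    cgis = IntervalSet("cgi_like", tuple(cgi_ivs))

    # --- sequence ------------------------------------------------------
    sequences: dict[str, str] = {}
    cgi_by_chrom: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for iv in cgis:
        cgi_by_chrom[iv.chrom].append((iv.start, iv.end))
    for name, L in assembly.chromosomes:
        codes = _simulate_sequence(
            rng, L, config.gc_content, cgi_by_chrom[name],
            config.cgi_gc_content, config.cpg_retention,
        )
        sequences[name] = _codes_to_str(codes)

    # --- methylation calls at CG positions -----------------------------
    meth_frames = []
    for name in names:
        codes = _encode_seq(sequences[name])
        cg_pos = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))
        if cg_pos.size == 0:
            continue
        cov = rng.poisson(config.meth_coverage, size=cg_pos.size)
        keep = cov > 0
        cg_pos, cov = cg_pos[keep], cov[keep]
        p = np.full(cg_pos.size, config.meth_baseline_pct / 100.0)
        for s, e in cgi_by_chrom[name]:
            inside = (cg_pos >= s) & (cg_pos < e)
            p[inside] = config.meth_cgi_pct / 100.0
        meth = rng.binomial(cov, p)
        meth_frames.append(
            pd.DataFrame(
                {"chrom": name, "pos": cg_pos, "context": "CG", "meth": meth, "total": cov}
            )
        )
    methylation = MethylationCalls(
        pd.concat(meth_frames, ignore_index=True)
        if meth_frames
        else pd.DataFrame(columns=list(MethylationCalls.REQUIRED))
    )

    feature_sets = {
        "enhancers": enhancers,
        "cgi_like": cgis,
        "promoters_P1": _promoter_windows(genes, classes, "P1", assembly),
        "promoters_P2": _promoter_windows(genes, classes, "P2", assembly),
    }
    truth = SimulationTruth(config, classes, tuple(strata_names), body_folds, config.enhancer_fold)
    return assembly, sequences, genes, feature_sets, methylation, truth


def _encode_seq(seq: str) -> np.ndarray:
    lut = np.full(256, -1, np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), np.uint8)]


def _promoter_windows(genes, classes, cls, assembly, halfwidth: int = 2000) -> IntervalSet:
    ivs = []
    for g, c in zip(genes, classes):
        if c != cls:
            continue
        L = assembly.length_of(g.interval.chrom)
        ivs.append(
            GenomicInterval(
                g.interval.chrom,
                max(g.tss - halfwidth, 0),
                min(g.tss + halfwidth, L),
                g.strand,
                name=g.name,
            )
        )
    return IntervalSet(f"promoters_{cls}", tuple(ivs))


def build_intensity(truth: SimulationTruth, genes: Sequence[GeneModel],
                    enhancers: IntervalSet, assembly: GenomeAssembly) -> dict[str, np.ndarray]:
    """Per-base IP intensity fold landscape implied by the planted features.

    Contributions multiply where features overlap. Background fold is 1.
    """
    cfg = truth.config
    fold: dict[str, np.ndarray] = {
        name: np.ones(L, dtype=np.float32) for name, L in assembly.chromosomes
    }
    for iv in enhancers:
        fold[iv.chrom][iv.start : iv.end] *= truth.enhancer_fold
    for g, cls, body in zip(genes, truth.gene_classes, truth.gene_body_folds):
        arr = fold[g.interval.chrom]
        arr[g.interval.start : g.interval.end] *= body
        tss = g.tss
        if cls == "P1":
            for sign in (-1, +1):
                c = tss + sign * cfg.tss_peak_offset
                arr[max(c - cfg.tss_peak_halfwidth, 0) : c + cfg.tss_peak_halfwidth] *= cfg.tss_peak_fold
            arr[max(tss - cfg.tss_depletion_halfwidth, 0) : tss + cfg.tss_depletion_halfwidth] *= cfg.tss_depletion_fold
        elif cls == "P2":
            arr[max(tss - cfg.p2_peak_halfwidth, 0) : tss + cfg.p2_peak_halfwidth] *= cfg.p2_peak_fold
    return fold


def _sample_positions(rng: np.random.Generator, intensity: np.ndarray, n: int) -> np.ndarray:
    cdf = np.cumsum(intensity, dtype=np.float64)
    u = rng.random(n) * cdf[-1]
    return np.searchsorted(cdf, u, side="right")


def simulate_tags(truth: SimulationTruth, genes: Sequence[GeneModel],
                  enhancers: IntervalSet, assembly: GenomeAssembly,
                  seed: int | None = None) -> tuple[TagCollection, TagCollection]:
    """Draw IP and input tag libraries.

    Input tags are uniform over the genome (homogeneous background); IP tag
    positions are drawn proportional to the planted fold landscape. Strands
    are assigned uniformly. Returns ``(ip, input)``.
    """
    cfg = truth.config
    if cfg.ip_tags <= 0 or cfg.input_tags <= 0:
        raise ValueError("library sizes must be positive")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    fold = build_intensity(truth, genes, enhancers, assembly)
    names = assembly.names
    weights = np.array([fold[n].sum() for n in names], np.float64)
    n_per_chrom = rng.multinomial(cfg.ip_tags, weights / weights.sum())
    ip_rows = []
    for name, n in zip(names, n_per_chrom):
        pos = _sample_positions(rng, fold[name], int(n))
        ip_rows.append(pd.DataFrame({"chrom": name, "start": pos}))
    lens = np.array([assembly.length_of(n) for n in names], np.float64)
    n_in = rng.multinomial(cfg.input_tags, lens / lens.sum())
    in_rows = []
    for name, n in zip(names, n_in):
        pos = rng.integers(0, assembly.length_of(name), int(n))
        in_rows.append(pd.DataFrame({"chrom": name, "start": pos}))
    ip_frame = pd.concat(ip_rows, ignore_index=True)
    in_frame = pd.concat(in_rows, ignore_index=True)
    ip_frame["strand"] = np.where(rng.random(len(ip_frame)) < 0.5, "+", "-")
    in_frame["strand"] = np.where(rng.random(len(in_frame)) < 0.5, "+", "-")
    ip_frame["start"] = ip_frame["start"].astype(np.int64)
    in_frame["start"] = in_frame["start"].astype(np.int64)
    return (
        TagCollection(ip_frame, tag_length=cfg.tag_length),
        TagCollection(in_frame, tag_length=cfg.tag_length),
    )


def simulate_mark_pair(assembly: GenomeAssembly, shared_weight: float,
                       n_tags: int = 200_000, block: int = 10_000,
                       seed: int = 0) -> tuple[TagCollection, TagCollection]:
    """Two tag libraries sharing a planted block-level intensity component.

    Each mark's intensity is ``(1 - w) * own + w * shared`` where own/shared
    are independent lognormal block fields at ``block`` bp resolution; the
    measured between-track r-squared rises monotonically with ``w``. Used
    for correlation-recovery checks.
    """
    if not (0.0 <= shared_weight <= 1.0):
        raise ValueError("shared_weight must be in [0, 1]")
    rng = np.random.default_rng(seed)
    frames: list[list[pd.DataFrame]] = [[], []]
    shared_fields = {
        name: rng.lognormal(0.0, 0.8, size=-(-L // block)) for name, L in assembly.chromosomes
    }
    for mark in range(2):
        for name, L in assembly.chromosomes:
            own = rng.lognormal(0.0, 0.8, size=-(-L // block))
            blocks = (1 - shared_weight) * own + shared_weight * shared_fields[name]
            intensity = np.repeat(blocks, block)[:L].astype(np.float32)
            pos = _sample_positions(rng, intensity, n_tags // len(assembly.names))
            frames[mark].append(pd.DataFrame({"chrom": name, "start": pos.astype(np.int64)}))
    out = []
    for mark in range(2):
        f = pd.concat(frames[mark], ignore_index=True)
        f["strand"] = "+"
        out.append(TagCollection(f))
    return out[0], out[1]


def write_simulation(out_dir: str | Path, config: SimulationConfig = SimulationConfig()) -> dict[str, Path]:
    """Materialise a simulated study as the on-disk formats the readers consume
    (FASTA, chrom.sizes, BED6, methylation TSV, truth JSON, tag BED files)."""
    from .genome_io import (
        write_aligned_tags,
        write_bed_intervals,
        write_chrom_sizes,
        write_methylation_table,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assembly, sequences, genes, feats, meth, truth = generate_truth(config)
    ip, input_tags = simulate_tags(truth, genes, feats["enhancers"], assembly)

    paths = {}
    paths["chrom_sizes"] = out / "genome.chrom.sizes"
    write_chrom_sizes(assembly, paths["chrom_sizes"])
    paths["fasta"] = out / "genome.fa"
    with open(paths["fasta"], "w") as fh:
        for name in assembly.names:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genes"] = out / "genes.bed"
    with open(paths["genes"], "w") as fh:
        for g in genes:
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.name}\t{g.rpkm:.4f}\t{g.strand}\n"
            )
    for key in ("enhancers", "cgi_like", "promoters_P1", "promoters_P2"):
        paths[key] = out / f"{key}.bed"
        write_bed_intervals(feats[key], paths[key])
    paths["methylation"] = out / "methylation.tsv"
    write_methylation_table(meth, paths["methylation"])
    paths["ip_tags"] = out / "ip_tags.bed"
    write_aligned_tags(ip, paths["ip_tags"])
    paths["input_tags"] = out / "input_tags.bed"
    write_aligned_tags(input_tags, paths["input_tags"])
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(truth.to_json(genes, feats["enhancers"], feats["cgi_like"]))
    return paths
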