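"""End-to-end orchestration of the analysis from one declarative config.

A run either simulates a study (``simulation`` block) or loads files
(``inputs`` block), then executes: deduplication, genome-wide binning at
the configured bin sizes, RPM normalisation and input subtraction,
chromosome densities, track correlation (enriched mark vs percent
methylation), peak calling, peak/feature association, sequence composition
of peaks vs a length-matched random null, expression-stratified TSS/TES
profiles, three-segment promoter-class profiles, scaled site profiles over
the enhancer set, and member-level overlap reports. Every stage writes a
self-describing TSV under the output directory, and a manifest records the
config hash, seed and per-stage record counts so that a rerun with the
same config is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import feature_profiles as fp
from . import genome_io as gio
from . import peak_enrichment as pe
from . import sequence_composition as sc
from . import signal_binning as sb
from . import synthetic_data as sd
from . import track_correlation as tc

log = logging.getLogger("hydroxyscape")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Declarative run description.

    Exactly one of ``simulation`` (a SimulationConfig field mapping, may be
    empty for defaults) or ``inputs`` (paths: chrom_sizes, ip_tags,
    input_tags, genes, and optional feature BEDs / methylation table) must
    be provided.
    """

    out_dir: str
    seed: int = 0
    simulation: Mapping[str, Any] | None = None
    inputs: Mapping[str, str] | None = None
    bin_sizes: tuple[int, ...] = (1000, 5000, 10000)
    reporting_bin_size: int = 10_000
    halve_chromosomes: tuple[str, ...] = ()
    peak_params: Mapping[str, Any] = field(default_factory=dict)
    n_random_regions: int = 2000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("provide exactly one of 'simulation' or 'inputs'")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "bin_sizes" in raw:
        raw["bin_sizes"] = tuple(raw["bin_sizes"])
    if "halve_chromosomes" in raw:
        raw["halve_chromosomes"] = tuple(raw["halve_chromosomes"])
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _check_paths(inputs: Mapping[str, str]) -> None:
    for role, p in inputs.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"input {role!r}: missing file {p}")


def _load_study(config: PipelineConfig):
    if config.simulation is not None:
        sim_cfg = sd.SimulationConfig(**{"seed": config.seed, **dict(config.simulation)})
        assembly, sequences, genes, feats, meth, truth = sd.generate_truth(sim_cfg)
        ip, input_tags = sd.simulate_tags(truth, genes, feats["enhancers"], assembly)
        return assembly, sequences, genes, feats, meth, ip, input_tags
    inputs = dict(config.inputs or {})
    _check_paths(inputs)
    assembly = gio.read_chrom_sizes(inputs["chrom_sizes"])
    ip = gio.read_aligned_tags(inputs["ip_tags"], assembly, deduplicate=False)
    input_tags = gio.read_aligned_tags(inputs["input_tags"], assembly, deduplicate=False)
    genes = gio.read_gene_table(inputs["genes"], assembly) if "genes" in inputs else []
    feats = {}
    for role, p in inputs.items():
        if role.startswith("features."):
            feats[role.split(".", 1)[1]] = gio.read_bed_intervals(p, assembly)
    meth = gio.read_methylation_table(inputs["methylation"]) if "methylation" in inputs else None
    sequences = None
    if "fasta" in inputs:
        import pyfaidx

        sequences = pyfaidx.Fasta(inputs["fasta"])
    return assembly, sequences, genes, feats, meth, ip, input_tags


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns the manifest (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "defaults": {
            "bin_sizes": list(config.bin_sizes),
            "reporting_bin_size": config.reporting_bin_size,
            "peak_params": asdict(pe.PeakCallParams(**dict(config.peak_params))),
        },
        "stages": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    assembly, sequences, genes, feats, meth, ip_raw, input_raw = _load_study(config)
    record("load", chromosomes=len(assembly.names), genes=len(genes),
           feature_sets=len(feats), ip_tags=ip_raw.total_tags, input_tags=input_raw.total_tags)

    # dedup
    ip = ip_raw.deduplicate()
    input_tags = input_raw.deduplicate()
    record("deduplicate", ip_tags=ip.total_tags, input_tags=input_tags.total_tags)

    # binning / normalisation / subtraction at every configured size
    signal = None
    for bs in sorted(set(config.bin_sizes) | {config.reporting_bin_size}):
        ip_rpm = sb.normalize_rpm(sb.count_tags_in_bins(ip, assembly, bs), ip.total_tags)
        in_rpm = sb.normalize_rpm(sb.count_tags_in_bins(input_tags, assembly, bs), input_tags.total_tags)
        diff = sb.subtract_input(ip_rpm, in_rpm)
        gio.write_bedgraph(diff, out / f"signal_minus_input.{bs}bp.bedgraph")
        if bs == config.reporting_bin_size:
            signal = diff
    assert signal is not None
    record("binning", bin_sizes=len(set(config.bin_sizes) | {config.reporting_bin_size}))

    # chromosome densities
    dens = sb.chromosome_density(ip, assembly, halve=set(config.halve_chromosomes))
    dens_in = sb.chromosome_density(input_tags, assembly, halve=set(config.halve_chromosomes))
    dens.join(dens_in, lsuffix="_ip", rsuffix="_input").to_csv(
        out / "chromosome_density.tsv", sep="\t",
        index_label="# chrom (observed/expected reads-per-million)",
    )
    record("chromosome_density", chromosomes=len(dens))

    # methylation track + correlation with the enriched signal
    if meth is not None and len(meth.frame):
        meth_track = tc.percent_methylation_track(meth, assembly, config.reporting_bin_size, "CG")
        gio.write_bedgraph(meth_track, out / "percent_methylation.CG.bedgraph", omit_zero=False)
        corr = tc.correlate_tracks(signal, meth_track, label_a="signal_minus_input", label_b="pct_meth_CG")
        pd.DataFrame([corr.__dict__]).to_csv(out / "track_correlation.tsv", sep="\t", index=False)
        record("correlation", n_bins_used=corr.n_bins_used, r_squared=round(corr.r_squared, 4))

    # peak calling + feature association + overlap
    params = pe.PeakCallParams(**dict(config.peak_params))
    peaks = pe.call_peaks(ip, input_tags, assembly, params)
    peak_set = pe.peaks_to_interval_set(peaks)
    with open(out / "peaks.bed", "w") as fh:
        fh.write("# chrom\tstart\tend\tname\tneg_log10_p\tstrand\tp_value\tsummit\ttag_count\n")
        for iv, pk in zip(peak_set, peaks):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:.3f}\t.\t"
                f"{pk.p_value:.3e}\t{pk.summit}\t{pk.tag_count}\n"
            )
    record("call_peaks", peaks=len(peaks))

    if peaks and feats:
        assoc = pe.feature_association(peaks, list(feats.values()), assembly)
        assoc.to_csv(out / "feature_association.tsv", sep="\t",
                     index_label="# feature (fractions of peaks; fold = observed/expected)")
        record("feature_association", features=len(assoc))
        enh = feats.get("enhancers")
        if enh is not None:
            venn = pe.set_overlap(peak_set, enh)
            pd.DataFrame([venn]).to_csv(out / "overlap_report.tsv", sep="\t", index=False)
            record("set_overlap", **{k: v for k, v in venn.items() if isinstance(v, int)})

    # sequence composition: peaks vs length-matched random null
    if sequences is not None and peaks:
        rng_regions = sc.sample_random_regions(
            assembly, config.n_random_regions, peak_set, seed=config.seed + 17, label="random"
        )
        rows = []
        for regions in (peak_set, rng_regions):
            oe = sc.dinucleotide_oe(regions, sequences)
            f = oe.to_frame()
            f.insert(0, "region_set", regions.label)
            rows.append(f.reset_index())
        pd.concat(rows, ignore_index=True).to_csv(
            out / "dinucleotide_oe.tsv", sep="\t", index=False
        )
        gc_rows = []
        for regions in (peak_set, rng_regions):
            cdf = sc.gc_profile(regions, sequences).cdf()
            cdf.insert(0, "region_set", regions.label)
            gc_rows.append(cdf)
        pd.concat(gc_rows, ignore_index=True).to_csv(out / "gc_cdf.tsv", sep="\t", index=False)
        record("sequence_composition", peak_regions=len(peak_set), random_regions=len(rng_regions))

    # profiles
    if genes:
        strata = fp.stratify_by_expression(genes)
        curves = {}
        for anchor in ("TSS", "TES"):
            mat = fp.anchored_profile(ip, input_tags, genes, assembly, anchor=anchor)
            for name, idxs in strata.all_groups().items():
                curves[f"{anchor}_{name}"] = fp.profile_summary(mat, idxs)
        pd.DataFrame(curves).to_csv(
            out / "expression_stratified_profiles.tsv", sep="\t",
            index_label="# bin (100 bp, -5kb..+5kb; normalized RPM, input-subtracted)",
        )
        record("anchored_profiles", strata=len(strata.all_groups()), genes=len(genes))
    for key in ("promoters_P1", "promoters_P2"):
        if key in feats and len(feats[key]):
            mat = fp.three_segment_profile(ip, input_tags, feats[key], assembly)
            pd.DataFrame({key: fp.profile_summary(mat)}).to_csv(
                out / f"three_segment.{key}.tsv", sep="\t",
                index_label="# column (120 x 100 bp: 4kb flank | 4kb core | 4kb flank)",
            )
            record(f"three_segment_{key}", regions=len(feats[key]))
    if "enhancers" in feats and len(feats["enhancers"]):
        mat = fp.scaled_site_profile(ip, input_tags, feats["enhancers"], assembly)
        pd.DataFrame({"enhancers": fp.profile_summary(mat)}).to_csv(
            out / "scaled_site_profile.tsv", sep="\t",
            index_label="# portion (40 upstream | 40 within | 40 downstream)",
        )
        record("scaled_profile", sites=len(feats["enhancers"]))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
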