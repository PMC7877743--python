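"""End-to-end orchestration: simulate to disk, run the analysis stages.

``run_simulate`` writes a complete synthetic study (annotation BEDs,
mappability bedGraph, tabular alignment libraries, truth sidecar and a
run manifest).  ``run_pipeline`` consumes such a directory — or any
directory with the same layout built from real alignments — and executes
filter -> count -> normalise -> fold change -> classify -> ping-pong ->
group tests -> ChIP tracks, writing one TSV per product.  Deterministic
stages write byte-identical TSVs when re-run with the same inputs and
seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chip import chip_bin_signal, log2_fc_track
from .config import AnalysisConfig, save_config
from .dependency import (
    bin_fold_change,
    boxplot_summary,
    class_totals,
    classify_sources,
    compare_groups,
)
from .io import (
    read_alignments,
    read_bed_intervals,
    read_bedgraph,
    read_bins_bed,
    write_alignments,
    write_bedgraph,
    write_bins_bed,
)
from .model import Cluster, GenomeAnnotation, GenomicBin, Library
from .pingpong import length_histogram, overlap_profile, pingpong_zscore
from .quant import (
    cluster_abundance,
    count_bins,
    count_mirna_factor,
    filter_pirna_reads,
    pool_and_normalize,
)
from .simulate import (
    CHIP_CONDITIONS,
    SMALLRNA_CONDITIONS,
    make_truth,
    simulate_chip_library,
    simulate_smallrna_library,
    write_truth_json,
)

__all__ = ["RunManifest", "PipelineError", "run_simulate", "run_pipeline"]

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunManifest:
    """Record of a run: config digest, seed, input digests, outputs."""

    config_digest: str
    seed: int
    version: str = __version__
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, list[str]] = field(default_factory=dict)
    libraries: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_simulate(
    config: AnalysisConfig,
    seed: int,
    outdir: str | Path,
    n_dependent: int = 200,
    n_independent: int = 920,
    n_up: int = 80,
    effect_size_log2: float = 2.5,
    base_rate: float = 100.0,
    pingpong_fraction: float = 0.2,
    n_replicates: int = 3,
    with_chip: bool = True,
) -> RunManifest:
    """Write a synthetic study to ``outdir`` and return its manifest."""
    outdir = Path(outdir)
    if not outdir.parent.exists():
        raise FileNotFoundError(f"parent of output directory does not exist: {outdir.parent}")
    outdir.mkdir(exist_ok=True)
    truth = make_truth(
        config,
        n_dependent=n_dependent,
        n_independent=n_independent,
        n_up=n_up,
        effect_size_log2=effect_size_log2,
        seed=seed,
        base_rate=base_rate,
        pingpong_fraction=pingpong_fraction,
    )
    ann = truth.annotation
    manifest = RunManifest(config_digest=config.digest(), seed=seed)

    write_bins_bed(ann.bins, outdir / "bins.bed")
    with open(outdir / "clusters.bed", "w") as fh:
        for c in ann.clusters:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}|{c.cluster_type}\t0\t{c.strand}\n")
    with open(outdir / "mirna_loci.bed", "w") as fh:
        for chrom, start, end in ann.mirna_loci:
            fh.write(f"{chrom}\t{start}\t{end}\tmirna\t0\t+\n")
    write_bedgraph(ann.bins, [b.mappability for b in ann.bins], outdir / "mappability.bedgraph")
    write_truth_json(truth, outdir / "truth.json")
    save_config(config, outdir / "config.yaml")
    with open(outdir / "chrom_sizes.tsv", "w") as fh:
        for chrom, size in ann.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    for condition in SMALLRNA_CONDITIONS:
        for rep in range(1, n_replicates + 1):
            lib = simulate_smallrna_library(truth, condition, rep, seed=seed)
            path = outdir / f"smallRNA_{condition}_rep{rep}.tsv"
            write_alignments(lib.reads, path)
            manifest.libraries.append(
                {
                    "sample_id": lib.sample_id,
                    "condition": condition,
                    "replicate": rep,
                    "assay": "smallRNA",
                    "path": path.name,
                    "depth": lib.depth,
                }
            )
    if with_chip:
        for condition in CHIP_CONDITIONS:
            for assay in ("chip_IP", "chip_input"):
                for rep in range(1, n_replicates + 1):
                    lib = simulate_chip_library(truth, condition, assay, rep, seed=seed)
                    path = outdir / f"{assay}_{condition}_rep{rep}.tsv"
                    write_alignments(lib.reads, path)
                    manifest.libraries.append(
                        {
                            "sample_id": lib.sample_id,
                            "condition": condition,
                            "replicate": rep,
                            "assay": assay,
                            "path": path.name,
                            "depth": lib.depth,
                        }
                    )
    for name in ("bins.bed", "clusters.bed", "mirna_loci.bed", "mappability.bedgraph", "truth.json"):
        manifest.inputs[name] = _digest_file(outdir / name)
    manifest.save(outdir / "manifest.json")
    return manifest


def _load_annotation(simdir: Path) -> GenomeAnnotation:
    bins = read_bins_bed(simdir / "bins.bed")
    clusters = []
    for iv in read_bed_intervals(simdir / "clusters.bed", min_fields=6):
        cid, ctype = iv.name.split("|")
        clusters.append(Cluster(cid, iv.chrom, iv.start, iv.end, ctype, iv.strand or "+"))
    mirna = [(iv.chrom, iv.start, iv.end) for iv in read_bed_intervals(simdir / "mirna_loci.bed")]
    chrom_sizes: dict[str, int] = {}
    sizes_path = simdir / "chrom_sizes.tsv"
    if sizes_path.exists():
        for line in sizes_path.read_text().splitlines():
            chrom, size = line.split("\t")
            chrom_sizes[chrom] = int(size)
    else:
        for b in bins:
            chrom_sizes[b.chrom] = max(chrom_sizes.get(b.chrom, 0), b.end)
        for chrom, start, end in mirna:
            chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), end)
    return GenomeAnnotation(
        chrom_sizes=chrom_sizes, clusters=clusters, mirna_loci=mirna, bins=bins
    )


def _load_libraries(simdir: Path, manifest: RunManifest) -> list[Library]:
    libs = []
    for entry in manifest.libraries:
        path = simdir / entry["path"]
        if not path.exists():
            raise FileNotFoundError(f"declared library file missing: {path}")
        reads, _skipped = read_alignments(path)
        libs.append(
            Library(
                sample_id=entry["sample_id"],
                condition=entry["condition"],
                replicate=entry["replicate"],
                assay=entry["assay"],
                reads=reads,
                depth=entry["depth"],
            )
        )
    return libs


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: Optional[str] = None) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index_label is not None,
                 index_label=index_label)


def run_pipeline(
    config: AnalysisConfig,
    simdir: str | Path,
    outdir: str | Path,
    stages: Optional[Sequence[str]] = None,
    resume: bool = False,
) -> RunManifest:
    """Run the analysis stages over a simulated (or equivalently laid out) study.

    ``stages`` selects a subset of {"quant", "classify", "pingpong",
    "chip", "compare"}; prerequisites are computed as needed.  With
    ``resume`` a stage whose outputs already exist under a matching
    manifest is skipped.
    """
    simdir, outdir = Path(simdir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wanted = set(stages) if stages else {"quant", "classify", "pingpong", "chip", "compare"}
    unknown = wanted - {"quant", "classify", "pingpong", "chip", "compare"}
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    sim_manifest = RunManifest.load(simdir / "manifest.json")
    manifest = RunManifest(config_digest=config.digest(), seed=sim_manifest.seed)
    manifest.inputs = dict(sim_manifest.inputs)

    prior: Optional[RunManifest] = None
    manifest_path = outdir / "manifest.json"
    if resume and manifest_path.exists():
        prior = RunManifest.load(manifest_path)
        if prior.config_digest != manifest.config_digest or prior.inputs != manifest.inputs:
            prior = None

    def stage_done(name: str) -> bool:
        if prior is None or name not in prior.outputs:
            return False
        return all((outdir / f).exists() for f in prior.outputs[name])

    try:
        annotation = _load_annotation(simdir)
    except Exception as exc:
        raise PipelineError(f"stage 'load-annotation': {exc}") from exc
    try:
        libraries = _load_libraries(simdir, sim_manifest)
    except Exception as exc:
        raise PipelineError(f"stage 'load-libraries': {exc}") from exc

    smallrna = [l for l in libraries if l.assay == "smallRNA"]
    chip_libs = [l for l in libraries if l.assay.startswith("chip_")]
    bins = annotation.bins
    ids = [f"{b.chrom}:{b.start}-{b.end}" for b in bins]

    # ---- small-RNA quantification ------------------------------------
    signals: dict[str, object] = {}
    filtered: dict[str, list[Library]] = {}
    count_rows = {}
    if wanted & {"quant", "classify", "pingpong", "compare"}:
        try:
            conditions = sorted({l.condition for l in smallrna})
            for cond in conditions:
                reps = sorted(
                    [l for l in smallrna if l.condition == cond], key=lambda l: l.replicate
                )
                flt = []
                counts = []
                depths = []
                for lib in reps:
                    f, _stats = filter_pirna_reads(lib, config)
                    count_mirna_factor(lib, annotation)
                    f.mirna_count = lib.mirna_count
                    flt.append(f)
                    c = count_bins(f, bins, "both")
                    counts.append(c)
                    depths.append(lib.depth)
                    count_rows[lib.sample_id] = c
                filtered[cond] = flt
                signals[cond] = pool_and_normalize(counts, depths, bins, condition=cond)
        except Exception as exc:
            raise PipelineError(f"stage 'quant': {exc}") from exc

    if "quant" in wanted and not stage_done("quant"):
        try:
            counts_frame = pd.DataFrame(count_rows, index=ids)
            _write_tsv(counts_frame, outdir / "bin_counts.tsv", index_label="bin")
            outs = ["bin_counts.tsv"]
            for cond, sig in signals.items():
                frame = pd.DataFrame({"value": sig.values})
                excl = pd.DataFrame(
                    {"value": np.nan, "excluded": list(sig.excluded.values())},
                    index=list(sig.excluded.keys()),
                )
                frame["excluded"] = ""
                frame = pd.concat([frame, excl]).sort_index()
                _write_tsv(frame, outdir / f"signal_{cond}.tsv", index_label="bin")
                outs.append(f"signal_{cond}.tsv")
            # per-cluster miRNA-normalised abundance, pooled over replicates
            rows = []
            for cond, flt in filtered.items():
                for lib in flt:
                    ab = cluster_abundance(lib, annotation.clusters, "both")
                    for cid, v in ab.items():
                        rows.append(
                            {"cluster": cid, "condition": cond,
                             "replicate": lib.replicate, "abundance": v}
                        )
            _write_tsv(pd.DataFrame(rows), outdir / "cluster_abundance.tsv")
            outs.append("cluster_abundance.tsv")
            manifest.outputs["quant"] = outs
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'quant': {exc}") from exc
    elif "quant" in wanted:
        manifest.outputs["quant"] = prior.outputs["quant"]

    # ---- dependency classification -----------------------------------
    calls = None
    if wanted & {"classify", "compare", "chip"}:
        if {"WT", "mut1", "mut2"} <= set(signals):
            try:
                fc1, ex1 = bin_fold_change(signals["mut1"], signals["WT"])
                fc2, ex2 = bin_fold_change(signals["mut2"], signals["WT"])
                calls = classify_sources(
                    fc1, fc2, config.dependency_threshold, ex1, ex2
                )
            except Exception as exc:
                raise PipelineError(f"stage 'classify': {exc}") from exc
    if "classify" in wanted and calls is not None and not stage_done("classify"):
        try:
            _write_tsv(calls, outdir / "dependency_calls.tsv", index_label="bin")
            totals = class_totals(calls)
            _write_tsv(
                pd.DataFrame(sorted(totals.items()), columns=["call", "n"]),
                outdir / "class_totals.tsv",
            )
            manifest.outputs["classify"] = ["dependency_calls.tsv", "class_totals.tsv"]
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'classify': {exc}") from exc
    elif "classify" in wanted and calls is not None:
        manifest.outputs["classify"] = prior.outputs["classify"]

    # ---- ping-pong signature -----------------------------------------
    if "pingpong" in wanted and filtered and not stage_done("pingpong"):
        try:
            rows = []
            hist_rows = []
            for cond, flt in filtered.items():
                reads = pd.concat([l.reads for l in flt], ignore_index=True)
                factor = sum(l.mirna_count or 0 for l in flt)
                profile = overlap_profile(reads, config, mirna_factor=factor or None)
                profile = pingpong_zscore(profile, config)
                for k, v in profile.overlap_counts.items():
                    rows.append({"condition": cond, "overlap": k, "pairs": v})
                rows.append(
                    {
                        "condition": cond,
                        "overlap": "z%d" % config.pingpong_focus,
                        "pairs": np.nan if profile.zscore is None else profile.zscore,
                    }
                )
                hist = length_histogram(reads, mirna_factor=factor or 1)
                for r in hist.counts.itertuples(index=False):
                    hist_rows.append(
                        {"condition": cond, "length": r.length, "strand": r.strand, "value": r.value}
                    )
            _write_tsv(pd.DataFrame(rows), outdir / "pingpong_profile.tsv")
            _write_tsv(pd.DataFrame(hist_rows), outdir / "length_histogram.tsv")
            manifest.outputs["pingpong"] = ["pingpong_profile.tsv", "length_histogram.tsv"]
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'pingpong': {exc}") from exc
    elif "pingpong" in wanted and filtered:
        manifest.outputs["pingpong"] = prior.outputs["pingpong"] if prior else []

    # ---- group comparisons -------------------------------------------
    if "compare" in wanted and calls is not None and not stage_done("compare"):
        try:
            comp_rows = []
            dep_ids = calls.index[calls["call"] == "dependent"]
            ind_ids = calls.index[calls["call"] == "independent"]
            box_groups = {}
            for cond, sig in signals.items():
                dep_vals = sig.values.reindex(dep_ids).dropna()
                ind_vals = sig.values.reindex(ind_ids).dropna()
                box_groups[f"dependent_{cond}"] = dep_vals.to_numpy()
                box_groups[f"independent_{cond}"] = ind_vals.to_numpy()
                if len(dep_vals) and len(ind_vals):
                    cmp = compare_groups(
                        dep_vals, ind_vals, config,
                        group_a=f"dependent_{cond}", group_b=f"independent_{cond}",
                    )
                    comp_rows.append(cmp.__dict__)
            _write_tsv(pd.DataFrame(comp_rows), outdir / "comparisons.tsv")
            _write_tsv(boxplot_summary(box_groups), outdir / "boxplot_summary.tsv",
                       index_label="group")
            manifest.outputs["compare"] = ["comparisons.tsv", "boxplot_summary.tsv"]
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'compare': {exc}") from exc
    elif "compare" in wanted and calls is not None:
        manifest.outputs["compare"] = prior.outputs["compare"] if prior else []

    # ---- ChIP tracks --------------------------------------------------
    if "chip" in wanted:
        if not chip_libs:
            manifest.notes.append("no ChIP libraries declared; ChIP stages skipped")
        elif not stage_done("chip"):
            try:
                chip_signals = {}
                for cond in sorted({l.condition for l in chip_libs}):
                    for assay in ("chip_IP", "chip_input"):
                        group = [
                            l for l in chip_libs if l.condition == cond and l.assay == assay
                        ]
                        if group:
                            chip_signals[(cond, assay)] = chip_bin_signal(group, bins, config)
                conds = sorted({c for c, _ in chip_signals})
                outs = []
                for (cond, assay), sig in chip_signals.items():
                    frame = pd.DataFrame({"value": sig.values})
                    name = f"chip_signal_{assay}_{cond}.tsv"
                    _write_tsv(frame.sort_index(), outdir / name, index_label="bin")
                    outs.append(name)
                if len(conds) == 2:
                    ctrl, kd = ("control_KD", "enok_KD") if "enok_KD" in conds else (conds[0], conds[1])
                    track = log2_fc_track(
                        chip_signals[(kd, "chip_IP")],
                        chip_signals[(ctrl, "chip_IP")],
                        chip_signals[(kd, "chip_input")],
                        chip_signals[(ctrl, "chip_input")],
                        config,
                    )
                    _write_tsv(pd.DataFrame({"log2_fc": track}).sort_index(),
                               outdir / "chip_fc_track.tsv", index_label="bin")
                    by_id = {f"{b.chrom}:{b.start}-{b.end}": b for b in bins}
                    track_bins = [by_id[i] for i in track.index]
                    sorted_bins = sorted(track_bins, key=lambda b: (b.chrom, b.start))
                    vals = [track[f"{b.chrom}:{b.start}-{b.end}"] for b in sorted_bins]
                    write_bedgraph(sorted_bins, vals, outdir / "chip_fc_track.bedgraph")
                    outs += ["chip_fc_track.tsv", "chip_fc_track.bedgraph"]
                manifest.outputs["chip"] = outs
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage 'chip': {exc}") from exc
        else:
            manifest.outputs["chip"] = prior.outputs["chip"]

    manifest.save(manifest_path)
    return manifest
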