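"""End-to-end orchestration: simulate (or load) -> build reference ->
preprocess -> quantify -> differential expression -> profiling -> enrichment.

``run_all`` drives the whole analysis from a single config mapping (typically
a YAML file via the CLI) and writes every stage's tables under one output
directory, plus a run manifest with package/library versions, the effective
parameters and md5 checksums of the input files.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .diffexp import (
    SignificanceThresholds,
    build_default_contrasts,
    estimate_size_factors,
    filter_significant,
    run_contrast,
)
from .enrichment import load_gmt, load_target_map, pathway_enrichment, top_pathways
from .preprocess import (
    ContaminantReference,
    PreprocessParams,
    ReadClass,
    ReadRecord,
    classify_and_filter,
    read_fastq,
    write_class_counts,
)
from .profiling import (
    abundance_overlap,
    hierarchical_cluster,
    species_distribution,
    transform_and_pca,
)
from .quantify import (
    build_count_matrix,
    build_index,
    key_annotation_table,
    quantify_library,
    rollup_canonical,
    split_key,
)
from .reference import (
    EnumerationParams,
    enumerate_isomir_space,
    load_mirna_reference,
    variants_by_id,
    write_variant_fasta,
    write_variant_table,
)
from .simulate import (
    PlantedEffect,
    ReferenceBundle,
    SimulationDesign,
    simulate_experiment,
    simulate_reference,
    simulate_target_sets,
    write_reference_fastas,
    write_target_sets,
)


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def auto_planted_effects(
    bundle: ReferenceBundle,
    group: str,
    log2fc_by_time: Mapping[str, float],
    n_features: int,
) -> tuple[PlantedEffect, ...]:
    """Plant effects on the canonical variants of the first ``n_features``
    miRNAs, one effect per configured time point (emulating a time-dependent
    postprandial increase)."""
    canonical_ids = []
    for v in sorted(bundle.variants, key=lambda v: v.variant_id):
        if any(e5 == 0 and e3 == 0 and m == v.canonical_parent for m, e5, e3 in v.parents):
            canonical_ids.append(v.variant_id)
    chosen = canonical_ids[:n_features]
    return tuple(
        PlantedEffect(vid, group, t, float(lfc))
        for t, lfc in log2fc_by_time.items()
        for vid in chosen
    )


def _build_design(sim_cfg: Mapping[str, Any], seed: int, bundle: ReferenceBundle) -> SimulationDesign:
    kwargs: dict[str, Any] = {"seed": seed}
    for key in (
        "groups", "time_points", "replicates", "depth", "dispersion", "error_rate",
        "contaminant_fraction", "short_fraction", "no_adapter_fraction", "adapter",
        "read_length", "canonical_fraction", "mirna_abundance_sigma",
        "noncanonical_concentration",
    ):
        if key in sim_cfg:
            value = sim_cfg[key]
            kwargs[key] = tuple(value) if key in ("groups", "time_points") else value
    design = SimulationDesign(**kwargs)
    effects: list[PlantedEffect] = [
        PlantedEffect(**e) for e in sim_cfg.get("planted_effects", [])
    ]
    planted = sim_cfg.get("planted")
    if planted:
        effects.extend(
            auto_planted_effects(
                bundle,
                planted["group"],
                planted["log2fc_by_time"],
                int(planted.get("n_features", 8)),
            )
        )
    if effects:
        from dataclasses import replace

        design = replace(design, planted_effects=tuple(effects))
    return design


def run_all(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run the full pipeline per ``config``; returns a summary dict.

    The config either contains a ``simulate`` section (synthetic mode) or an
    ``inputs`` section pointing at mature/hairpin/contaminant FASTAs, a FASTQ
    directory and a sample sheet (real-data mode).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    checksums: dict[str, str] = {}

    enum_cfg = config.get("enumeration", {})
    enum_params = EnumerationParams(
        max_trim=int(enum_cfg.get("max_trim", 6)),
        max_add=int(enum_cfg.get("max_add", 3)),
        min_len=int(enum_cfg.get("min_len", 16)),
        addition_mode=enum_cfg.get("addition_mode", "templated"),
    )

    # ------------------------------------------------------------------ inputs
    if "simulate" in config:
        sim_cfg = config["simulate"]
        bundle = simulate_reference(
            n_mirnas=int(sim_cfg.get("n_mirnas", 20)),
            seed=seed,
            params=enum_params,
            n_contaminants_per_class=int(sim_cfg.get("contaminants_per_class", 3)),
        )
        design = _build_design(sim_cfg, seed, bundle)
        sim_dir = outdir / "sim"
        write_reference_fastas(bundle, sim_dir / "reference")
        experiment = simulate_experiment(bundle, design, outdir=sim_dir)
        sample_sheet = experiment.sample_sheet
        fastqs = {sid: experiment.paths[sid] for sid in experiment.paths}
        adapter = design.adapter
        target_map, pathways = simulate_target_sets(
            [m.mirna_id for m in bundle.reference.matures], seed=seed
        )
        write_target_sets(target_map, pathways, sim_dir / "annotation")
        reference = bundle.reference
        contaminants = bundle.contaminants
        variants = bundle.variants
    else:
        inputs = config["inputs"]
        reference = load_mirna_reference(
            inputs["mature_fasta"], inputs["hairpin_fasta"],
            inputs.get("link_table"),
        )
        contaminants = (
            ContaminantReference.from_single_fasta(inputs["contaminant_fasta"])
            if inputs.get("contaminant_fasta")
            else None
        )
        variants = enumerate_isomir_space(reference, enum_params)
        sample_sheet = pd.read_csv(inputs["sample_sheet"], sep="\t")
        fastq_dir = Path(inputs["fastq_dir"])
        fastqs = {}
        for sid in sample_sheet["sample_id"]:
            for suffix in (".fastq.gz", ".fastq", ".fq.gz", ".fq"):
                cand = fastq_dir / f"{sid}{suffix}"
                if cand.exists():
                    fastqs[sid] = cand
                    break
            else:
                raise FileNotFoundError(f"no FASTQ found for sample {sid!r}")
        adapter = config.get("preprocess", {}).get("adapter")
        if not adapter:
            raise ValueError("real-data mode requires preprocess.adapter in the config")
        target_map = (
            load_target_map(
                inputs["target_map"],
                evidence_filter=config.get("enrichment", {}).get("evidence"),
            )
            if inputs.get("target_map")
            else None
        )
        pathways = load_gmt(inputs["pathways"]) if inputs.get("pathways") else None
        for key in ("mature_fasta", "hairpin_fasta", "contaminant_fasta", "sample_sheet"):
            if inputs.get(key):
                checksums[key] = _md5(Path(inputs[key]))

    for sid, path in fastqs.items():
        checksums[f"fastq:{sid}"] = _md5(Path(path))

    # --------------------------------------------------------------- reference
    ref_dir = outdir / "reference"
    ref_dir.mkdir(exist_ok=True)
    write_variant_fasta(variants, ref_dir / "isomir_reference.fasta")
    write_variant_table(variants, ref_dir / "isomir_annotation.tsv")
    index = build_index(variants)
    vmap = variants_by_id(variants)

    # ---------------------------------------------------- preprocess + quantify
    pp_cfg = config.get("preprocess", {})
    pp_params = PreprocessParams(
        adapter=adapter,
        min_overlap=int(pp_cfg.get("min_overlap", 6)),
        max_adapter_mismatch=int(pp_cfg.get("max_adapter_mismatch", 1)),
        min_len=int(pp_cfg.get("min_len", 16)),
        contaminant_max_mismatch=int(pp_cfg.get("contaminant_max_mismatch", 1)),
    )
    per_sample_counts = {}
    class_counts = {}
    for sid in sample_sheet["sample_id"]:
        result = classify_and_filter(read_fastq(fastqs[sid]), contaminants, pp_params)
        quant = quantify_library(result.retained, index, keep_read_ids=True)
        counts = dict(result.class_counts)
        counts[ReadClass.MAPPED] = counts.pop(ReadClass.RETAINED) - quant.unmapped
        counts[ReadClass.UNMAPPED] = counts.get(ReadClass.UNMAPPED, 0) + quant.unmapped
        class_counts[sid] = counts
        per_sample_counts[sid] = quant.key_counts

    pre_dir = outdir / "preprocess"
    pre_dir.mkdir(exist_ok=True)
    write_class_counts(class_counts, pre_dir / "class_counts.tsv")

    counts_dir = outdir / "counts"
    counts_dir.mkdir(exist_ok=True)
    isomir_counts = build_count_matrix(per_sample_counts)
    isomir_counts.to_csv(counts_dir / "isomir_counts.tsv", sep="\t")
    key_annotation_table(isomir_counts.index, vmap).to_csv(
        counts_dir / "key_annotation.tsv", sep="\t"
    )
    canonical_counts = rollup_canonical(isomir_counts, vmap)
    canonical_counts.to_csv(counts_dir / "canonical_counts.tsv", sep="\t")

    # ------------------------------------------------------------------- stats
    stats_dir = outdir / "stats"
    stats_dir.mkdir(exist_ok=True)
    groups_by_sample = dict(zip(sample_sheet["sample_id"], sample_sheet["group"]))
    pct, group_means = species_distribution(class_counts, groups_by_sample)
    pct.to_csv(stats_dir / "species_distribution.tsv", sep="\t")
    if group_means is not None:
        group_means.to_csv(stats_dir / "species_distribution_group_means.tsv", sep="\t")

    # ---------------------------------------------------------------- diffexp
    thr_cfg = config.get("thresholds", {})
    thresholds = SignificanceThresholds(
        alpha=float(thr_cfg.get("alpha", 0.05)),
        min_abs_lfc=float(thr_cfg.get("min_abs_lfc", 1.0)),
        min_base_mean=float(thr_cfg.get("min_base_mean", 50.0)),
    )
    min_total = int(config.get("diffexp", {}).get("min_total_count", 10))
    de_dir = outdir / "diffexp"
    de_dir.mkdir(exist_ok=True)
    contrasts = build_default_contrasts(sample_sheet)
    manifest_rows = []
    de_results: dict[str, dict[str, pd.DataFrame]] = {"canonical": {}, "isomir": {}}
    for contrast in contrasts:
        for level, matrix in (("canonical", canonical_counts), ("isomir", isomir_counts)):
            cols = list(contrast.samples_a) + list(contrast.samples_b)
            sub = matrix[cols]
            sub = sub.loc[sub.sum(axis=1) >= min_total] if level == "isomir" else sub
            de = filter_significant(run_contrast(sub, contrast), thresholds)
            de.to_csv(de_dir / f"{level}__{contrast.name}.tsv", sep="\t")
            de_results[level][contrast.name] = de
            manifest_rows.append(
                {
                    "contrast": contrast.name,
                    "level": level,
                    "n_features_tested": int(de["pvalue"].notna().sum()),
                    "n_significant": int(de["significant"].sum()),
                    "n_up": int((de["direction"] == "up").sum()),
                    "n_down": int((de["direction"] == "down").sum()),
                }
            )
    pd.DataFrame(manifest_rows).to_csv(
        de_dir / "comparison_manifest.tsv", sep="\t", index=False
    )

    # --------------------------------------------------------------- profiling
    prof_cfg = config.get("profiling", {})
    top_k = int(prof_cfg.get("top_k", 500))
    n_top_abundant = int(prof_cfg.get("n_top_abundant", 100))
    groups = list(dict.fromkeys(sample_sheet["group"]))
    reference_group = prof_cfg.get("reference_group", groups[0])
    prof_dir = outdir / "profiling"
    prof_dir.mkdir(exist_ok=True)

    sf = estimate_size_factors(isomir_counts)
    pca = transform_and_pca(isomir_counts, sf, k=top_k)
    pca.coordinates.to_csv(prof_dir / "pca_coordinates.tsv", sep="\t")
    pd.Series(
        pca.explained_variance_percent,
        index=pca.coordinates.columns,
        name="explained_variance_percent",
    ).to_csv(prof_dir / "pca_explained_variance.tsv", sep="\t")
    clust = hierarchical_cluster(isomir_counts, sf)
    np.savetxt(prof_dir / "linkage.tsv", clust.linkage, delimiter="\t")
    (prof_dir / "leaf_order.txt").write_text("\n".join(clust.leaf_order) + "\n")

    ref_samples = [
        s for s, g in groups_by_sample.items() if g == reference_group
    ]
    other_groups = [g for g in groups if g != reference_group]
    up_sets = {}
    if other_groups:
        target_group = other_groups[0]
        times = list(dict.fromkeys(sample_sheet["time_point"]))
        for t in times[1:]:
            name = f"{target_group}_{t}_vs_{times[0]}"
            if name in de_results["isomir"]:
                de = de_results["isomir"][name]
                up_sets[t] = set(de.index[de["direction"] == "up"])
    overlaps = abundance_overlap(
        isomir_counts[ref_samples], sf[ref_samples], up_sets, n_top=n_top_abundant
    ) if up_sets else []
    if overlaps:
        pd.DataFrame(
            [
                {
                    "time_point": o.time_point,
                    "n_top": o.n_top,
                    "overlap_count": o.overlap_count,
                    "overlap_percent": o.overlap_percent,
                    "top_read_fraction_percent": o.top_read_fraction_percent,
                    "overlap_features": ";".join(o.overlap_features),
                }
                for o in overlaps
            ]
        ).to_csv(prof_dir / "abundance_overlap.tsv", sep="\t", index=False)

    # -------------------------------------------------------------- enrichment
    enr_summary = {}
    if target_map and pathways and other_groups:
        enr_dir = outdir / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        target_group = other_groups[0]
        times = list(dict.fromkeys(sample_sheet["time_point"]))
        for t in times[1:]:
            name = f"{target_group}_{t}_vs_{times[0]}"
            de = de_results["canonical"].get(name)
            if de is None:
                continue
            up_mirnas = list(de.index[de["direction"] == "up"])
            if not up_mirnas:
                continue
            enr = pathway_enrichment(up_mirnas, target_map, pathways)
            enr.to_csv(enr_dir / f"enrichment__{t}.tsv", sep="\t")
            top_pathways(enr, 20).to_csv(enr_dir / f"top20__{t}.tsv", sep="\t")
            enr_summary[t] = {
                "n_query_mirnas": len(up_mirnas),
                "top_pathway": enr.index[0],
                "top_pvalue": float(enr["pvalue"].iloc[0]),
            }

    # ---------------------------------------------------------------- manifest
    manifest = {
        "isomirseq_version": __version__,
        "python": sys.version.split()[0],
        "library_versions": {
            mod: __import__(mod).__version__
            for mod in ("numpy", "scipy", "pandas", "statsmodels", "Bio")
        },
        "seed": seed,
        "enumeration": asdict(enum_params),
        "preprocess": asdict(pp_params),
        "thresholds": asdict(thresholds),
        "n_variants": len(variants),
        "n_samples": int(len(sample_sheet)),
        "input_checksums": checksums,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return {
        "sample_sheet": sample_sheet,
        "class_counts": class_counts,
        "isomir_counts": isomir_counts,
        "canonical_counts": canonical_counts,
        "species_distribution": pct,
        "de_results": de_results,
        "overlaps": overlaps,
        "enrichment": enr_summary,
        "manifest": manifest,
    }
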