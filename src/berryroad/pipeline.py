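"""End-to-end orchestration of the phenotyping pipeline.

``run_all`` chains simulation (or loading), texture extraction, volatile
filtering, storage indices, multivariate clustering, genetic structure
and the selection roadmap, writing every table under one output
directory together with a manifest (seed, version, file hashes).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from . import genetics, multivariate, roadmap as roadmap_mod, storage, voc as voc_mod
from .mechanogram import cultivar_means, extract_texture_profile, profiles_frame, summarize_texture
from .synthetic import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)


def texture_stage(curves, gradient_mode: str = "raw") -> pd.DataFrame:
    """Extract per-fruit texture profiles from a list of curves."""
    profiles = [extract_texture_profile(c, gradient_mode=gradient_mode) for c in curves]
    return profiles_frame(profiles)


def voc_cultivar_means(reduced: voc_mod.PeakTable) -> dict[str, pd.DataFrame]:
    """Cultivar x m/z mean-concentration matrix per timepoint."""
    df = pd.concat([reduced.meta[["cultivar", "timepoint"]], reduced.conc], axis=1)
    out = {}
    for tp, grp in df.groupby("timepoint"):
        out[tp] = grp.drop(columns="timepoint").groupby("cultivar").mean()
    return out


def texture_cultivar_matrices(profiles: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cultivar x texture-trait mean matrix per timepoint."""
    means = cultivar_means(profiles)
    return {tp: means.xs(tp, level="timepoint")
            for tp in means.index.get_level_values("timepoint").unique()}


def run_all(
    config: CohortConfig | None = None,
    out_dir: str | Path = "results/run",
    seed: int | None = None,
    n_boot: int = 200,
    k_max_genetic: int = 20,
    n_starts: int = 200,
    keep_curves: bool = False,
) -> dict:
    """Simulate a cohort and run every downstream stage; returns a summary.

    All artifacts are written as TSV/JSON/Newick under ``out_dir`` and a
    run manifest records the seed, package version and file hashes.
    """
    t0 = time.time()
    if config is None:
        config = CohortConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth, curves, peaks, genotypes = simulate_cohort(config)
    truth.to_json(out / "truth.json")
    if keep_curves:  # raw curves are bulky; profiles are the durable artifact
        bio.write_curves(curves, out / "curves.tsv")
    bio.write_peak_table(peaks, out / "peaks_raw.tsv")
    genotypes.to_csv(out / "genotypes.tsv", sep="\t", index=False)

    # --- texture
    profiles = texture_stage(curves)
    profiles.to_csv(out / "texture_profiles.tsv", sep="\t", index=False)
    summary = summarize_texture(profiles, *config.timepoints)
    summary.to_csv(out / "texture_summary.tsv", sep="\t")
    tex = texture_cultivar_matrices(profiles)

    # --- volatiles
    reduced, report = voc_mod.reduce_peaks(peaks)
    bio.write_peak_table(reduced, out / "peaks_reduced.tsv")
    with open(out / "peak_filter_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    annotations = voc_mod.annotate(report.retained)
    annotations.to_csv(out / "peak_annotations.tsv", sep="\t", index=False)
    vocm = voc_cultivar_means(reduced)

    # --- storage indices
    h_tp, p_tp = config.timepoints
    si_tex = storage.si_matrix(tex[h_tp], tex[p_tp])
    si_voc = storage.si_matrix(vocm[h_tp], vocm[p_tp])
    bio.write_matrix(si_tex, out / "si_texture.tsv")
    bio.write_matrix(si_voc, out / "si_voc.tsv")
    storage.si_summary(si_tex).to_csv(out / "si_texture_summary.tsv", sep="\t")
    storage.si_summary(si_voc).to_csv(out / "si_voc_summary.tsv", sep="\t")

    # --- multivariate: PCA + Ward per view
    cluster_labels = {}
    for name, mat, log10 in (("texture_harvest", tex[h_tp], False),
                             ("texture_postharvest", tex[p_tp], False),
                             ("texture_si", si_tex, False),
                             ("voc_harvest", vocm[h_tp], True),
                             ("voc_postharvest", vocm[p_tp], True)):
        X = multivariate.prepare_matrix(mat, log10=log10)
        res = multivariate.pca(X, scale=False)
        res.scores.to_csv(out / f"pca_scores_{name}.tsv", sep="\t")
        cl = multivariate.ward_cluster(X, standardize=False)
        sel = multivariate.choose_k(cl)
        labels = cl.cut(sel.k)
        labels.rename("cluster").to_csv(out / f"clusters_{name}.tsv", sep="\t")
        with open(out / f"dendrogram_{name}.nwk", "w") as fh:
            fh.write(multivariate.linkage_to_newick(cl) + "\n")
        cluster_labels[name] = labels

    # --- genetics
    gts = genetics.genotypes_from_frame(genotypes)
    repeat_lengths = dict(config.genetic.loci)
    dist = genetics.bruvo_distance_matrix(gts, repeat_lengths)
    bio.write_matrix(dist, out / "bruvo_distances.tsv")
    tree = genetics.bootstrap_nj(gts, repeat_lengths, n_boot=n_boot, seed=config.seed)
    with open(out / "nj_tree.nwk", "w") as fh:
        fh.write(tree.as_string(schema="newick"))
    dapc_res = genetics.dapc(gts, k_max=k_max_genetic, n_starts=n_starts, seed=config.seed)
    pd.DataFrame({"cultivar": dapc_res.cultivars, "cluster": dapc_res.labels}).to_csv(
        out / "dapc_clusters.tsv", sep="\t", index=False)
    pd.DataFrame(dapc_res.posteriors, index=dapc_res.cultivars).to_csv(
        out / "dapc_posteriors.tsv", sep="\t")
    genetic_labels = pd.Series(dapc_res.labels, index=dapc_res.cultivars)

    # --- phenotype vs genotype association
    assoc = {}
    for name, labels in cluster_labels.items():
        shared = labels.index.intersection(genetic_labels.index)
        ari, p = multivariate.cluster_association(
            labels.loc[shared], genetic_labels.loc[shared], n_perm=999, seed=config.seed)
        assoc[name] = {"ari": ari, "p": p}
    with open(out / "phenotype_genotype_association.json", "w") as fh:
        json.dump(assoc, fh, indent=1)

    # --- roadmap
    rm = roadmap_mod.build_roadmap(
        pd.concat([tex[h_tp], vocm[h_tp]], axis=1),
        pd.concat([tex[p_tp], vocm[p_tp]], axis=1))
    rm.table.to_csv(out / "roadmap.tsv", sep="\t", index=False)

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    bio.write_manifest(out, config.seed, files, extra={
        "n_peaks_raw": len(peaks.mz),
        "n_peaks_retained": len(report.retained),
        "dapc_k": dapc_res.k,
        "runtime_s": round(time.time() - t0, 2),
    })
    return {
        "out_dir": str(out),
        "n_peaks_raw": len(peaks.mz),
        "n_peaks_retained": len(report.retained),
        "dapc_k": dapc_res.k,
        "association": assoc,
        "cluster_labels": cluster_labels,
        "runtime_s": time.time() - t0,
    }
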