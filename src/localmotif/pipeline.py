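"""End-to-end orchestration: scan -> clusters/k* -> S_local -> null -> regions -> ORI.

Every stage writes its artifact to the output directory, so intermediate
results (site tables, cluster model, k* report, profiles, regions, ORI
table) can be inspected or re-run individually.  All randomness flows from
the config seed; identical config and inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import motif_scan, null_model, parzen, regions as regions_mod, global_stats
from .config import RunConfig
from .motif_scan import MotifMatrix, SiteCollection
from .null_model import GCClusterModel
from .sequence_io import PromoterSet, gc_profile_matrix, read_promoters

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(
    config: RunConfig,
    genomic_fasta,
    input_fasta,
    motifs_path,
    motif_dialect: str = "jaspar_pfm",
    outdir="localmotif_out",
) -> dict:
    """Run the whole pipeline; returns a dict of result objects per stage."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        genomic = read_promoters(genomic_fasta, config.span_start, config.span_end)
        input_set = read_promoters(input_fasta, config.span_start, config.span_end)
        motifs = motif_scan.parse_motifs(
            motifs_path, motif_dialect,
            strong_fraction=config.strong_fraction,
            weak_fraction=config.weak_fraction,
        )
    except Exception as exc:
        raise StageError("load", exc) from exc
    log.info(
        "loaded %d genomic and %d input promoters, %d motifs",
        len(genomic), len(input_set), len(motifs),
    )

    results = run_on_sets(config, genomic, input_set, motifs, outdir=out)
    return results


def run_on_sets(
    config: RunConfig,
    genomic: PromoterSet,
    input_set: PromoterSet,
    motifs: list[MotifMatrix],
    outdir=None,
) -> dict:
    """Pipeline body on in-memory objects (used by run_all and the tests)."""
    out = Path(outdir) if outdir is not None else None

    # --- scan both sets once per motif; genomic site lists are reused by
    # every resampling stage.
    try:
        sites_genomic = {m.motif_id: motif_scan.scan(genomic, m) for m in motifs}
        sites_input = {m.motif_id: motif_scan.scan(input_set, m) for m in motifs}
    except Exception as exc:
        raise StageError("scan", exc) from exc
    if out is not None:
        motif_scan.write_sites(list(sites_input.values()), out / "input_sites.tsv")
        motif_scan.write_sites(list(sites_genomic.values()), out / "genomic_sites.tsv")

    # --- GC clustering and k* selection
    try:
        genomic_profiles = gc_profile_matrix(genomic)
        models: dict[int, GCClusterModel] = {}
        for k in range(config.k_min, config.k_max + 1):
            models[k] = null_model.fit_gc_clusters(
                genomic, k,
                restarts=config.kmeans_restarts,
                max_iter=config.kmeans_max_iter,
                seed=config.seed + k,
                profiles=genomic_profiles,
            )
        report = null_model.choose_k_star(
            genomic, models, input_set,
            reps=config.kstar_reps,
            seed=config.seed,
            genomic_profiles=genomic_profiles,
        )
        model = models[report.k_star]
    except Exception as exc:
        raise StageError("gc_clusters", exc) from exc
    log.info("chose k* = %d", report.k_star)
    if out is not None:
        report.to_json(out / "k_star.json")
        model.to_json(out / "gc_clusters.json")

    # --- local enrichment, null, regions per (motif, width)
    all_regions: dict[str, list] = {}
    profiles_out = []
    for m in motifs:
        per_width = []
        for rank, hw in enumerate(config.half_widths):
            kernel = parzen.KernelSpec(config.kernel_shape, hw)
            try:
                obs = parzen.local_enrichment(
                    sites_input[m.motif_id], kernel,
                    config.x_start, config.x_stop,
                )
                null = null_model.null_pvalues(
                    obs, genomic, sites_genomic[m.motif_id], model, input_set,
                    n_samples=config.n_samples_local,
                    seed=config.seed + 1000 * (rank + 1),
                )
                called = regions_mod.call_regions(
                    null, obs, sites_input[m.motif_id],
                    p_dep_thresholds=config.p_dep_thresholds,
                    p_ind_threshold=config.p_ind_threshold,
                )
                called = regions_mod.merge_same_width(
                    called, sites_input[m.motif_id]
                ) if called else []
            except Exception as exc:
                raise StageError(f"enrich[{m.motif_id},h/2={hw}]", exc) from exc
            per_width.extend(called)
            profiles_out.append(obs)
        all_regions[m.motif_id] = regions_mod.remove_cross_width_redundancy(
            per_width
        ) if per_width else []
    flat_regions = [r for rs in all_regions.values() for r in rs]
    if out is not None:
        regions_mod.write_regions(flat_regions, out / "regions.tsv")
        for prof in profiles_out:
            prof.write_tsv(
                out / f"profile_{prof.motif_id}_h{prof.kernel.half_width}.tsv"
            )

    # --- global over-representation
    ori_rows = []
    ori_results = {}
    for m in motifs:
        try:
            res = global_stats.ori(
                sites_input[m.motif_id], sites_genomic[m.motif_id],
                input_set.gene_ids, genomic.gene_ids,
            )
            res.p_ori = global_stats.p_ori(
                res, genomic, sites_genomic[m.motif_id], model, input_set,
                n_samples=config.n_samples_ori, seed=config.seed + 99,
            )
        except ValueError as exc:
            log.warning("ORI undefined for %s: %s", m.motif_id, exc)
            continue
        ori_results[m.motif_id] = res
        ori_rows.append(
            {
                "motif_id": m.motif_id,
                "density_S": res.density_s,
                "density_genomic": res.density_genomic,
                "proportion_S": res.proportion_s,
                "proportion_genomic": res.proportion_genomic,
                "ORI": res.ori,
                "P_ORI": res.p_ori,
            }
        )
    ori_table = pd.DataFrame(
        ori_rows,
        columns=[
            "motif_id", "density_S", "density_genomic", "proportion_S",
            "proportion_genomic", "ORI", "P_ORI",
        ],
    )
    if out is not None:
        ori_table.to_csv(out / "ori.tsv", sep="\t", index=False)

    return {
        "sites_input": sites_input,
        "sites_genomic": sites_genomic,
        "k_star_report": report,
        "gc_model": model,
        "profiles": profiles_out,
        "regions": all_regions,
        "ori": ori_results,
        "ori_table": ori_table,
    }
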