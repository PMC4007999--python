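"""End-to-end pipeline driver: QC -> dosage -> duplicates -> map ->
homology groups -> pairing, with every artifact written to disk."""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import __version__
from .homology import anchor_families, assemble_hgs, cluster_fraction, hg_summary, multilocus_rate
from .io import PipelineConfig, read_genotypes, write_loc, write_map
from .linkage import two_stage_build
from .matrix import MarkerMatrix
from .pairing import detect_repulsion, hg_difference_ratios, pairing_summary
from .scoring import collapse_duplicates, quality_filter, score_matrix

__all__ = ["run_pipeline"]

log = logging.getLogger("polylink")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig, matrix: MarkerMatrix | None = None) -> dict:
    """Run the full analysis and write the report bundle.

    ``matrix`` may be passed directly (e.g. from the simulator);
    otherwise ``config.genotypes``/``config.metadata`` are read.
    Returns a dict of the in-memory results.  Outputs under
    ``config.outdir``: dosage_report.tsv, map.tsv, map.loc,
    hg_report.tsv, anchors.tsv, repulsion.tsv, difference_ratios.tsv,
    pairing_summary.tsv and manifest.json.  Given the same inputs,
    config and seed the bundle is byte-identical across runs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if matrix is None:
        if not config.genotypes:
            raise ValueError("no genotype input: pass a matrix or set config.genotypes")
        matrix = _stage("read")(read_genotypes)(config.genotypes, config.metadata)
    log.info("input: %d markers x %d progeny", matrix.n_markers, matrix.n_progeny)

    if matrix.metadata is not None and "quality" in matrix.metadata:
        matrix, qlog = _stage("quality_filter")(quality_filter)(
            matrix, q_min=config.q_min, call_rate_min=config.call_rate_min
        )
        log.info(
            "quality_filter: removed %d (quality), %d (call rate); %d kept",
            qlog["quality"], qlog["call_rate"], matrix.n_markers,
        )

    dosage = _stage("classify_dosage")(score_matrix)(
        matrix, ploidy=config.ploidy, alpha=config.alpha
    )
    dosage.to_csv(outdir / "dosage_report.tsv", sep="\t")
    sd_ids = dosage.index[dosage["dosage_class"].isin(["SD", "SD_skewed"])]
    log.info(
        "classify_dosage: %d SD (%d skewed) of %d",
        len(sd_ids),
        int((dosage["dosage_class"] == "SD_skewed").sum()),
        len(dosage),
    )
    sd = matrix.subset(sd_ids)

    sd, removed = _stage("find_duplicates")(collapse_duplicates)(
        sd, min_overlap=config.duplicate_min_overlap
    )
    log.info("find_duplicates: collapsed %d duplicate markers", len(removed))

    gmap = _stage("two_stage_build")(two_stage_build)(
        sd,
        lod_min=config.lod_min,
        rf_max=config.rf_max,
        framework_min_scored=config.framework_min_scored,
        min_informative=config.min_informative,
    )
    system_of = (
        matrix.metadata["system"].to_dict()
        if matrix.metadata is not None and "system" in matrix.metadata
        else None
    )
    write_map(gmap, outdir / "map.tsv", system_of=system_of)
    write_loc(sd, outdir / "map.loc")
    log.info(
        "two_stage_build: %d LGs, %d markers mapped, %d unplaced, %.1f cM",
        len(gmap.groups), gmap.n_markers, len(gmap.unplaced), gmap.total_length,
    )

    hgs, unassigned, anchors = [], [g.name for g in gmap.groups], None
    if matrix.metadata is not None and "locus_family" in matrix.metadata:
        anchors = _stage("anchor_families")(anchor_families)(matrix.metadata, gmap.lg_of())
        hgs, unassigned = _stage("assemble_hgs")(assemble_hgs)(
            [g.name for g in gmap.groups], anchors, min_shared=config.min_shared_anchors
        )
        pd.DataFrame(
            [
                {"family": f, "lgs": ";".join(sorted(lgs))}
                for f, lgs in sorted(anchors.anchors.items())
            ]
        ).to_csv(outdir / "anchors.tsv", sep="\t", index=False)
    log.info("assemble_hgs: %d HGs, %d unassigned LGs", len(hgs), len(unassigned))

    results: dict = {"matrix": matrix, "dosage": dosage, "map": gmap, "hgs": hgs}
    if hgs:
        summary = _stage("hg_summary")(hg_summary)(hgs, gmap, unassigned)
        summary.to_csv(outdir / "hg_report.tsv", sep="\t")
        results["hg_summary"] = summary
        hg_of_lg = {lg: hg.id for hg in hgs for lg in hg.members}
        n_multi, n_fam, frac = multilocus_rate(anchors, hg_of_lg)
        log.info("multilocus anchors: %d of %d families (%.0f%%)", n_multi, n_fam, 100 * frac)
        results["multilocus_rate"] = (n_multi, n_fam, frac)
        if system_of:
            results["dart_cluster_fraction"] = cluster_fraction(
                gmap,
                window=config.cluster_window_cm,
                min_markers=config.cluster_min_markers,
                system_of=system_of,
                system="DArT",
            )

    links = _stage("detect_repulsion")(detect_repulsion)(
        sd,
        gmap,
        lod_min=config.repulsion_lod_min,
        min_support=config.repulsion_min_support,
        min_span_frac=config.repulsion_min_span_frac,
        min_informative=config.min_informative,
    )
    pd.DataFrame(
        [
            {
                "lg_a": l.lg_a,
                "lg_b": l.lg_b,
                "best_lod": round(l.best_lod, 2),
                "n_support": len(l.support),
                "span_frac_a": round(l.span_frac_a, 3),
                "span_frac_b": round(l.span_frac_b, 3),
                "accepted": l.accepted,
            }
            for l in links
        ],
        columns=["lg_a", "lg_b", "best_lod", "n_support", "span_frac_a", "span_frac_b", "accepted"],
    ).to_csv(outdir / "repulsion.tsv", sep="\t", index=False)
    results["repulsion"] = links
    log.info(
        "detect_repulsion: %d candidate LG pairs, %d accepted",
        len(links), sum(l.accepted for l in links),
    )

    if hgs and matrix.metadata is not None and "locus_family" in matrix.metadata:
        hg_members = {str(hg.id): hg.members for hg in hgs}
        fams = matrix.metadata["locus_family"].to_dict()
        ratios = _stage("difference_ratio")(hg_difference_ratios)(hg_members, gmap, fams)
        pd.DataFrame(
            [
                {
                    "hg": r.hg,
                    "reference_lg": r.reference_lg,
                    "compared_lg": r.compared_lg,
                    "k": r.k,
                    "sum_abs_diff_cm": round(r.sum_abs_diff, 1),
                    "sum_total_cm": round(r.sum_total, 1),
                    "difference_ratio": round(r.ratio, 1),
                }
                for r in ratios
            ],
            columns=[
                "hg", "reference_lg", "compared_lg", "k",
                "sum_abs_diff_cm", "sum_total_cm", "difference_ratio",
            ],
        ).to_csv(outdir / "difference_ratios.tsv", sep="\t", index=False)
        hg_of_lg = {lg: str(hg.id) for hg in hgs for lg in hg.members}
        table, r2 = _stage("pairing_summary")(pairing_summary)(
            links, ratios, hg_of_lg, hg_members
        )
        table.to_csv(outdir / "pairing_summary.tsv", sep="\t")
        results["difference_ratios"] = ratios
        results["pairing_summary"] = table
        results["pairing_r2"] = r2

    manifest = {
        "polylink_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "n_markers_in": int(matrix.n_markers),
        "n_markers_mapped": int(gmap.n_markers),
        "n_lgs": len(gmap.groups),
        "n_hgs": len(hgs),
        "total_length_cm": round(gmap.total_length, 1),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return results
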