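"""End-to-end driver: simulate -> identify -> score -> profile -> cluster.

Chains the pipeline stages over a collection of simulated proteins,
writing per-stage TSV tables (stamped with the config hash), a TreeView
dendrogram and a provenance log.  Identical config + seed re-runs produce
identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    clustering,
    confidence,
    ellipse,
    enrichment,
    features,
    profiles as profiles_mod,
    segmentation,
    shapes as shapes_mod,
    synthetic,
)
from .config import PipelineConfig

__all__ = ["run_pipeline", "identify_cells", "IdentifiedImage", "PipelineResult"]

log = logging.getLogger("budprofiler")


@dataclass
class IdentifiedImage:
    """All per-image identification products."""

    micrograph: segmentation.Micrograph
    truth: synthetic.GroundTruth | None
    seg: segmentation.SegmentationResult
    edge_map: segmentation.EdgeDistanceMap
    ellipses: list
    cells: list  # TypedCell
    protein: str = ""
    image_id: str = ""


def identify_cells(
    mic: segmentation.Micrograph,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    truth: synthetic.GroundTruth | None = None,
    protein: str = "",
    image_id: str = "",
) -> IdentifiedImage:
    """Run segmentation, ellipse fitting, shape assembly and typing."""
    cfg = cfg or PipelineConfig()
    seg = segmentation.segment_foreground(mic.rfp)
    edge_map = segmentation.edge_distance_map(seg)
    fg = edge_map.dist > 0
    background_mask = ~fg
    contours = ellipse.extract_contour_pixels(edge_map, cfg.contour_thickness)
    rng = np.random.default_rng(seed)
    all_cells: list[shapes_mod.TypedCell] = []
    all_ellipses: list[ellipse.EllipseParams] = []
    from scipy import ndimage as _ndi

    clump_labels, _ = _ndi.label(fg, structure=np.ones((3, 3), int))
    id_offset = 0
    for contour in contours:
        fits = ellipse.fit_ellipses_robust(
            contour,
            seed=rng,
            background_mask=background_mask,
            sigma=cfg.robust_sigma,
            mean_radius=cfg.mean_cell_radius,
            ratio_min=cfg.axis_ratio_min,
        )
        if not fits:
            continue
        clump_mask = clump_labels == contour.clump_id
        basins = shapes_mod.watershed_basins(mic.rfp, clump_mask)
        cell_shapes, _unassigned = shapes_mod.assemble_shapes(
            basins, fits, mic.rfp, clump_id=contour.clump_id,
            id_offset=id_offset,
        )
        id_offset += len(cell_shapes)
        typed = shapes_mod.assign_cell_types(cell_shapes, mic.shape)
        all_cells.extend(typed)
        all_ellipses.extend(fits)
    return IdentifiedImage(
        micrograph=mic, truth=truth, seg=seg, edge_map=edge_map,
        ellipses=all_ellipses, cells=all_cells, protein=protein,
        image_id=image_id,
    )


@dataclass
class PipelineResult:
    """Handles to every table the pipeline produced."""

    out_dir: Path
    cell_table: pd.DataFrame
    profile_table: pd.DataFrame
    dendrogram: clustering.Dendrogram | None
    enrichment_stats: dict
    config_hash: str
    counts: dict = field(default_factory=dict)


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute every stage on a simulated collection; see module docs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.hash()
    logging.basicConfig(level=logging.INFO)
    proteins = cfg.proteins or {
        "prot_uniform": {"kind": "uniform"},
        "prot_nuclear": {"kind": "nuclear-disc"},
        "prot_ring": {"kind": "peripheral-ring"},
    }

    # ---- stage 1: simulate ------------------------------------------------
    scenes: list[IdentifiedImage] = []
    raw: list[tuple[str, str, segmentation.Micrograph, synthetic.GroundTruth]] = []
    for ip, (pname, pattern) in enumerate(sorted(proteins.items())):
        for j in range(cfg.images_per_protein):
            scene_cfg = synthetic.SceneConfig(
                **{**cfg.scene, "gfp_pattern": dict(pattern),
                   "seed": cfg.seed + 997 * ip + j},
            )
            mic, truth = synthetic.simulate_micrograph(scene_cfg)
            raw.append((pname, f"{pname}_img{j}", mic, truth))
    log.info("simulated %d images for %d proteins", len(raw), len(proteins))

    # ---- stage 2: background correction ----------------------------------
    # per-pixel median once the stack is background-dominated; a global
    # scalar for very small stacks (the mean of a handful of images still
    # carries substantial cell signal)
    bg_method = "median" if len(raw) >= 5 else "scalar"
    bg_rfp = segmentation.compute_background_image(
        [m.rfp for _, _, m, _ in raw], method=bg_method
    )
    bg_gfp = segmentation.compute_background_image(
        [m.gfp for _, _, m, _ in raw], method=bg_method
    )
    corrected = [
        (
            pname, img_id,
            segmentation.Micrograph(
                rfp=segmentation.correct_image(m.rfp, bg_rfp),
                gfp=segmentation.correct_image(m.gfp, bg_gfp),
                source=m.source,
            ),
            truth,
        )
        for pname, img_id, m, truth in raw
    ]

    # ---- stage 3: per-image identification -------------------------------
    for k, (pname, img_id, mic, truth) in enumerate(corrected):
        scenes.append(
            identify_cells(
                mic, cfg, seed=cfg.seed + 13 * k, truth=truth,
                protein=pname, image_id=img_id,
            )
        )
        log.info("%s: %d cells identified", img_id, len(scenes[-1].cells))

    # ---- stage 4: confidence model ---------------------------------------
    records = []
    for scene in scenes:
        t_centers = scene.truth.centers() if scene.truth else np.zeros((0, 2))
        for cell in scene.cells:
            try:
                fit = confidence.moment_ellipse_fit(cell.shape.pixels)
            except confidence.ShapeTooSmallError:
                continue
            artifact = confidence.is_artifact(
                fit, cfg.min_cell_area, cfg.min_cell_axis
            )
            qv = None
            if not artifact:
                qv = confidence.quality_vector(
                    cell.shape.pixels, fit, scene.edge_map, scene.micrograph.rfp
                )
            is_true = False
            if len(t_centers) and not artifact:
                d = np.linalg.norm(t_centers - fit.centroid, axis=1)
                is_true = bool(d.min() <= cfg.match_radius)
            records.append(
                {
                    "scene": scene, "cell": cell, "fit": fit, "qv": qv,
                    "artifact": artifact, "is_true": is_true,
                }
            )
    labelled = [
        (r["qv"], float(r["fit"].n)) for r in records
        if r["is_true"] and r["qv"] is not None
    ]
    all_objs = [
        (r["qv"], float(r["fit"].n)) for r in records if r["qv"] is not None
    ]
    model = None
    if len(labelled) >= 20:
        model = confidence.fit_confidence_model(
            labelled, all_objs, n_bins=cfg.n_size_bins
        )
        model.rho = confidence.estimate_mixing(all_objs, model)
    for r in records:
        if r["qv"] is not None and model is not None:
            r["posterior"] = confidence.cell_posterior(
                r["qv"], float(r["fit"].n), model
            )
        else:
            r["posterior"] = 0.0 if r["artifact"] else 1.0
    if model is not None:
        (out / "confidence_model.json").write_text(model.to_json())

    # ---- stage 5: RFP size model + features ------------------------------
    size_data = [
        (float(r["fit"].n), r["qv"].mean_rfp)
        for r in records if r["qv"] is not None
    ]
    rfp_model = features.fit_rfp_size_model(
        size_data, min_cells=min(cfg.rfp_model_min_cells, max(4, len(size_data)))
    )
    cell_rows = []
    for r in records:
        if r["qv"] is None:
            continue
        scene, cell = r["scene"], r["cell"]
        try:
            iratio = features.intensity_ratio(
                cell.shape.pixels, scene.micrograph.gfp, scene.micrograph.rfp,
                rfp_model,
            )
        except (features.RupturedCellError, ValueError):
            iratio = np.nan
        dists = features.morphological_distances(
            cell.shape.pixels, scene.micrograph.gfp, scene.micrograph.rfp,
            scene.edge_map, neck_position=cell.neck_position,
        )
        row = {
            "protein": scene.protein, "image": scene.image_id,
            "cell_id": cell.shape.shape_id, "type": cell.cell_type,
            "partner": -1 if cell.partner_id is None else cell.partner_id,
            "area": cell.shape.area,
            "row": cell.shape.centroid[0], "col": cell.shape.centroid[1],
            "bud_area": np.nan if cell.bud_area is None else cell.bud_area,
            "cell_probability": r["posterior"],
            "intensity_ratio": iratio,
        }
        for name in features.DISTANCE_NAMES:
            row[name] = np.nan if dists.get(name) is None else dists[name]
        cell_rows.append(row)
    cell_table = pd.DataFrame(cell_rows)
    _write_table(cell_table, out / "cells.tsv", chash)

    # ---- stage 6: time profiles ------------------------------------------
    feature_cols = list(features.FEATURE_NAMES)
    pair_stages = []
    series_by_protein: dict[str, profiles_mod.StageSeries] = {}
    if not cell_table.empty:
        paired = cell_table[cell_table["type"] == "bud"]
        for pname in sorted(proteins):
            sub = paired[paired["protein"] == pname]
            rows = []
            for _, bud in sub.iterrows():
                mother = cell_table[
                    (cell_table["image"] == bud["image"])
                    & (cell_table["cell_id"] == bud["partner"])
                ]
                if mother.empty or bud["bud_area"] <= 0:
                    continue
                mother = mother.iloc[0]
                vals = np.concatenate(
                    [bud[feature_cols].to_numpy(dtype=float),
                     mother[feature_cols].to_numpy(dtype=float)]
                )
                rows.append(
                    (
                        profiles_mod.cell_stage(
                            bud["bud_area"], cfg.stage_exponent
                        ),
                        vals,
                        confidence.pair_probability(
                            float(mother["cell_probability"]),
                            float(bud["cell_probability"]),
                        ),
                    )
                )
            if len(rows) >= 2:
                st = np.array([r[0] for r in rows])
                series_by_protein[pname] = profiles_mod.StageSeries(
                    stage=st,
                    values=np.vstack([np.nan_to_num(r[1]) for r in rows]),
                    weights=np.array([r[2] for r in rows]),
                )
                pair_stages.append(st)
    profile_rows = {}
    if series_by_protein:
        pooled = np.concatenate(pair_stages)
        keypoints = profiles_mod.stage_keypoints(pooled, cfg.n_keypoints)
        for pname, series in series_by_protein.items():
            tp = profiles_mod.loess_profile(
                series, protein=pname, keypoints=keypoints,
                bandwidth=cfg.bandwidth,
            )
            profile_rows[pname] = tp
    colnames = profiles_mod.profile_column_names(cfg.n_keypoints)
    profile_table = pd.DataFrame(
        {
            pname: np.concatenate([tp.means, tp.variances, [tp.n_pairs]])
            for pname, tp in profile_rows.items()
        },
        index=[f"mean:{c}" for c in colnames]
        + [f"var:{c}" for c in colnames] + ["n_pairs"],
    ).T
    _write_table(
        profile_table.reset_index(names="protein"), out / "profiles.tsv", chash
    )

    # ---- stage 7: clustering ---------------------------------------------
    dend = None
    enrich_stats: dict = {}
    if len(profile_rows) >= 2:
        leaf_profiles = []
        for pname, tp in sorted(profile_rows.items()):
            mean, var = _impute_profile(tp.means, tp.variances)
            leaf_profiles.append(
                clustering.ClusterProfile(
                    n=1, mean=mean, var=var, members=(pname,)
                )
            )
        dend = clustering.agglomerate(leaf_profiles, metric=cfg.cluster_metric)
        clustering.write_treeview(
            dend, leaf_profiles, str(out / "clusters"), column_names=colnames
        )
        # ---- stage 8: enrichment on the true pattern labels --------------
        pattern_of = {
            pname: (proteins[pname].get("kind", "uniform")
                    if isinstance(proteins[pname], dict)
                    else proteins[pname].kind)
            for pname in profile_rows
        }
        family = {}
        for pname, kind in pattern_of.items():
            family.setdefault(kind, set()).add(pname)
        family = {
            t: frozenset(m) for t, m in family.items() if len(m) >= 2
        }
        if family:
            s_obs, z, p, _ = enrichment.permutation_null_S(
                dend, family, n_perm=cfg.enrichment_n_perm, seed=cfg.seed
            )
            enrich_stats = {"S": s_obs, "Z": z, "p": p}
            (out / "enrichment.json").write_text(json.dumps(enrich_stats))

    counts = {
        "images": len(scenes),
        "objects": len(records),
        "cells": int(sum(1 for r in records if not r["artifact"])),
        "mother_bud_pairs": int((cell_table["type"] == "bud").sum())
        if not cell_table.empty else 0,
        "lone_cells": int((cell_table["type"] == "lone").sum())
        if not cell_table.empty else 0,
    }
    (out / "run_manifest.json").write_text(
        json.dumps({"config_hash": chash, "config": cfg.to_dict(),
                    "counts": counts}, indent=2, default=str)
    )
    log.info("pipeline complete: %s", counts)
    return PipelineResult(
        out_dir=out, cell_table=cell_table, profile_table=profile_table,
        dendrogram=dend, enrichment_stats=enrich_stats, config_hash=chash,
        counts=counts,
    )


def _impute_profile(means: np.ndarray, variances: np.ndarray):
    """Fill unreliable (NaN) profile entries feature-block-wise.

    Missing keypoints take the feature's mean over reliable keypoints with
    a 10x inflated variance, so they carry little weight in merge scores.
    """
    means = means.copy()
    variances = variances.copy()
    n = len(means)
    block = 10  # keypoints per feature block
    for start in range(0, n, block):
        sl = slice(start, start + block)
        m, v = means[sl], variances[sl]
        ok = np.isfinite(m)
        fill_m = float(np.mean(m[ok])) if ok.any() else 0.0
        fill_v = float(np.mean(v[ok]) * 10.0) if ok.any() else 1.0
        m[~ok] = fill_m
        v[~np.isfinite(v)] = max(fill_v, clustering.VAR_FLOOR)
        means[sl], variances[sl] = m, v
    return means, np.maximum(variances, clustering.VAR_FLOOR)
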