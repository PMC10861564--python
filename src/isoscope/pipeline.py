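"""End-to-end post-processing: match -> NA-correct -> metrics -> cluster -> export.

``run_pipeline`` consumes a validated :class:`~isoscope.config.RunConfig`
pointing at a feature table, compound database and sample metadata, and
writes a deterministic output tree of delimited tables.  Rerunning with the
same inputs and seed reproduces the tables byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .chem import enumerate_isotopologues, parse_formula
from .clustering import build_trajectories, hierarchical_cluster, kmeans_cluster, pca_project
from .config import RunConfig
from .export import export_flux_tables, write_table
from .matching import (
    assemble_intensity_matrix,
    compound_identified,
    match_isotopologues,
    read_compound_db,
    read_feature_table,
    read_sample_metadata,
)
from .metrics import build_mid_series, replicate_summary
from .nacorrect import build_correction_matrix, correct_mid

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and return the output directory."""
    for attr in ("features_path", "compound_db_path", "metadata_path"):
        p = getattr(config, attr)
        if not p or not Path(p).exists():
            raise StageError("config", f"{attr} missing or not found: {p!r}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    seed = config.seed

    try:
        meta = read_sample_metadata(config.metadata_path)
        features = read_feature_table(config.features_path, meta)
        db = read_compound_db(config.compound_db_path)
    except (ValueError, OSError) as e:
        raise StageError("io", str(e)) from e

    tracers = config.tracer_specs()
    adducts = config.adduct_table()

    matched_rows = []
    metrics_frames = []
    mid_frames = []
    for _, comp in db.iterrows():
        try:
            grid = enumerate_isotopologues(
                parse_formula(comp["formula"]),
                tracers,
                adducts[comp["adduct"]],
                compound=comp["name"],
            )
        except (KeyError, ValueError) as e:
            raise StageError("chem", f"{comp['name']}: {e}") from e
        measurements = match_isotopologues(
            features,
            grid,
            float(comp["rt_seconds"]),
            mz_tol_ppm=config.mz_tol_ppm,
            rt_tol_s=config.rt_tol_s,
        )
        identified = compound_identified(measurements, meta)
        for m in measurements:
            matched_rows.append(
                dict(
                    compound=m.compound,
                    index="(" + ",".join(map(str, m.index)) + ")",
                    theoretical_mz=m.theoretical_mz,
                    matched_feature_id=m.matched_feature_id or "",
                    observed_mz=m.observed_mz,
                    ppm_error=m.ppm_error,
                    rt_error_s=m.rt_error_s,
                    identified=identified,
                )
            )
        if not identified:
            log.warning("compound %s not identified (no M0 match)", comp["name"])
            continue
        mat, sample_order = assemble_intensity_matrix(measurements, meta)
        correction = build_correction_matrix(
            grid,
            mode=config.correction_mode,
            instrument_resolution=config.instrument_resolution,
        )
        corrected = np.zeros((len(grid), mat.shape[1]))
        for i in range(mat.shape[1]):
            col = mat[:, i]
            if col.sum() == 0:
                continue
            if config.correction_mode == "nominal":
                from .chem import project_nominal

                y = project_nominal(grid, col)
            else:
                y = col
            x, _ = correct_mid(y, correction)
            corrected[:, i] = x
        pool = comp.get("pool_nmol")
        pool = float(pool) if pool is not None and not pd.isna(pool) else None
        series = build_mid_series(grid, mat, corrected, sample_order, meta, pool)
        metrics_frames.append(series.metrics_table())
        # long-format MID table, raw + corrected
        for kind, arr in (("raw", series.raw), ("corrected", series.corrected)):
            df = pd.DataFrame(arr, columns=sample_order)
            df.insert(0, "index", ["(" + ",".join(map(str, ix)) + ")" for ix in grid.indices])
            df.insert(0, "kind", kind)
            df.insert(0, "compound", comp["name"])
            mid_frames.append(df)
        flux = export_flux_tables(grid, corrected, sample_order)
        for name, table in flux.items():
            write_table(
                table.reset_index(names="isotopologue"),
                outdir / "flux" / f"{comp['name'].replace('/', '_')}_{name}.csv",
                seed=seed,
                config_hash=chash,
            )

    write_table(pd.DataFrame(matched_rows), outdir / "matched.csv", seed=seed, config_hash=chash)
    if mid_frames:
        write_table(pd.concat(mid_frames), outdir / "mids.csv", seed=seed, config_hash=chash)
    if not metrics_frames:
        raise StageError("metrics", "no compound was identified")
    metrics = pd.concat(metrics_frames, ignore_index=True)
    write_table(metrics, outdir / "metrics.csv", seed=seed, config_hash=chash)
    write_table(replicate_summary(metrics), outdir / "metrics_summary.csv", seed=seed, config_hash=chash)

    # clustering needs >= 2 compounds and >= 2 time points
    try:
        traj = build_trajectories(metrics, metric=config.cluster_metric)
    except ValueError:
        traj = None
    if traj is not None and len(traj.compounds) >= 2:
        k = min(config.cluster_k, len(traj.compounds))
        km = kmeans_cluster(traj, k=k, seed=seed)
        hc = hierarchical_cluster(traj, k=k)
        pca = pca_project(traj)
        assign = pd.DataFrame(
            dict(
                compound=traj.compounds,
                kmeans_cluster=km.labels.to_numpy(),
                hierarchical_cluster=hc.labels.to_numpy(),
            )
        )
        write_table(assign, outdir / "clusters.csv", seed=seed, config_hash=chash)
        write_table(
            km.centroids.reset_index(names="cluster"),
            outdir / "cluster_centroids.csv",
            seed=seed,
            config_hash=chash,
        )
        write_table(
            pca.scores.reset_index(names="compound"),
            outdir / "pca_scores.csv",
            seed=seed,
            config_hash=chash,
        )
        if config.make_plots:
            from .plots import plot_cluster_trajectories, plot_pca

            plot_cluster_trajectories(traj, km, outdir / "clusters.png")
            plot_pca(pca, km, outdir / "pca.png")
    return outdir
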