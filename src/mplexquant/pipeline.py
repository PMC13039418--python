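"""End-to-end pipeline orchestration.

``run_pipeline`` chains the stages — registration of all rounds to the
reference, nucleus detection and cell tessellation, background correction,
feature extraction, islet segmentation and statistics, and the
expression-landscape clustering — writing every stage's outputs to a
directory.  Given a fixed ``random_seed`` the run is reproducible
end-to-end (byte-identical tables).
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cellquant, islets, landscape, registration
from .config import PipelineConfig
from .errors import StageError
from .io import (
    MultiplexImage,
    write_cell_table,
    write_islet_table,
    write_label_map,
    write_multiplex_image,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def run_pipeline(
    config: PipelineConfig,
    rounds: list[MultiplexImage],
    outdir: str | Path,
) -> dict:
    """Run all stages on a list of imaging rounds (first = reference).

    Writes the aligned stack, label maps, the cell feature table (with
    cluster assignments and positivity calls appended), the islet table,
    cluster profiles/occurrences and a parameter log under ``outdir``.
    Returns a dict with the in-memory results and output paths.  Any stage
    failure aborts with a stage-named error.
    """
    if not rounds:
        raise StageError("input", "at least one imaging round is required")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"outdir": outdir}

    # --- registration ------------------------------------------------------
    reference = rounds[0]
    if len(rounds) > 1:
        aligned, transforms = registration.register_rounds(
            reference,
            rounds[1:],
            downsample=config.rigid_downsample,
            step_px=config.deform_grid_step_px,
        )
        for rnd, (rigid, grid) in zip(rounds[1:], transforms):
            registration.save_transform(
                outdir / f"transform_{rnd.round_id}.yaml", rigid, grid
            )
        logger.info("registered %d round(s) to %s", len(aligned), reference.round_id)
    else:
        aligned, transforms = [], []

    merged_channels = dict(reference.channels)
    for rnd in aligned:
        for name, chan in rnd.channels.items():
            if name == rnd.nuclei_channel and name in merged_channels:
                continue  # one nuclei channel is enough after alignment
            key = name if name not in merged_channels else f"{rnd.round_id}_{name}"
            merged_channels[key] = chan
    image = MultiplexImage(
        round_id="aligned",
        channels=merged_channels,
        pixel_size_um=reference.pixel_size_um,
        nuclei_channel=reference.nuclei_channel,
    )
    write_multiplex_image(image, outdir / "aligned.ome.tif")
    results["image"] = image
    results["transforms"] = transforms

    # --- segmentation ------------------------------------------------------
    try:
        bg_feasible = min(image.shape) >= config.background_downsize
        nuc_bg = (
            cellquant.estimate_background(
                image.nuclei,
                window_px=config.background_window_px,
                downsize=config.background_downsize,
            )
            if bg_feasible
            else None
        )
        nuclei = cellquant.detect_nuclei(image.nuclei, background=nuc_bg)
        cells = cellquant.expand_cells(nuclei, config.expansion_px)
    except Exception as exc:
        raise StageError("segmentation", str(exc)) from exc
    write_label_map(nuclei, outdir / "nuclei_labels.tif")
    write_label_map(cells, outdir / "cell_labels.tif")
    results["nucleus_labels"] = nuclei
    results["cell_labels"] = cells
    logger.info("detected %d nuclei", int(nuclei.max()))

    # --- background correction + features ---------------------------------
    try:
        corrected = {}
        for name, chan in image.channels.items():
            if bg_feasible:
                bg = cellquant.estimate_background(
                    chan,
                    window_px=config.background_window_px,
                    downsize=config.background_downsize,
                )
                corrected[name] = cellquant.subtract_background(chan, bg)
            else:
                corrected[name] = np.asarray(chan, dtype=np.float64)
        corrected_image = image.with_channels(corrected)
        table = cellquant.extract_features(nuclei, cells, corrected_image)
    except Exception as exc:
        raise StageError("features", str(exc)) from exc
    results["corrected_image"] = corrected_image

    # --- expression landscape ----------------------------------------------
    markers = [c for c in image.channel_names if c != image.nuclei_channel]
    try:
        rois = _feasible_rois(config, image.shape)
        matrix = landscape.build_expression_matrix(
            table, markers, config.marker_localization, rois=rois
        )
        results["rois"] = rois
        n_cells = len(matrix)
        if n_cells >= 2 and markers:
            k = min(config.kmeans_k, n_cells)
            model, assignments, profile, occurrence = landscape.cluster_cells(
                matrix,
                markers,
                var_frac=config.pca_var_frac,
                k=k,
                seed=config.random_seed,
                n_init=config.kmeans_n_init,
            )
            profile.to_csv(outdir / "cluster_profiles.csv")
            occurrence.to_frame().to_csv(outdir / "cluster_occurrence.csv")
            results["cluster_model"] = model
            cl = pd.Series(-1, index=table.index, name="cluster")
            id_to_cluster = dict(zip(matrix["cell_id"], assignments))
            cl[:] = [id_to_cluster.get(cid, -1) for cid in table["cell_id"]]
            table["cluster"] = cl.to_numpy()
        thresholds = {
            m: config.thresholds.get(m, "otsu") for m in markers
        }
        calls = landscape.call_positivity(
            landscape.build_expression_matrix(
                table, markers, config.marker_localization
            ),
            thresholds,
        )
        for m in markers:
            table[f"{m}_pos"] = calls.calls[m].to_numpy()
        table["subtype"] = calls.subtype.to_numpy()
        results["positivity"] = calls
    except Exception as exc:
        raise StageError("landscape", str(exc)) from exc

    write_cell_table(table, outdir / "cell_table.csv")
    results["cell_table"] = table

    # --- islets -------------------------------------------------------------
    ins, glu = "Insulin", "Glucagon"
    if ins in corrected and glu in corrected:
        try:
            thr = config.thresholds.get("islet_segmentation", "otsu")
            islet_labels = islets.segment_islets(
                corrected[ins],
                corrected[glu],
                thresholds=thr,
                min_area_um2=config.islet_min_area_um2,
                pixel_size_um=config.pixel_size_um,
                struct_radius_px=config.struct_radius_px,
            )
            islet_table = islets.islet_features(
                islet_labels, corrected_image, cells=table
            )
        except Exception as exc:
            raise StageError("islets", str(exc)) from exc
        write_label_map(islet_labels, outdir / "islet_labels.tif")
        write_islet_table(islet_table, outdir / "islet_table.csv")
        results["islet_labels"] = islet_labels
        results["islet_table"] = islet_table
        logger.info("segmented %d islets", int(islet_labels.max()))
    else:
        logger.info("no insulin/glucagon channels; islet stage skipped")

    with open(outdir / "parameters.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    return results


def _feasible_rois(config: PipelineConfig, shape) -> list | None:
    """ROIs as configured, shrunk to the image when the slide is smaller."""
    h, w = shape
    size = min(config.roi_size_px, h, w)
    max_fit = (h // size) * (w // size)
    n = min(config.n_rois, max_fit)
    if n < 1:
        return None
    return landscape.select_rois((h, w), n_rois=n, roi_size_px=size,
                                 seed=config.random_seed)
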