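"""End-to-end orchestration: correct -> segment -> gate -> detect ->
cluster -> decode -> geometry (-> Hi-C comparison).

Stages are pure functions over in-memory objects; :func:`run_pipeline`
adds file I/O (per-channel TIFFs in, CSV tables out) around them so a
run is fully reproducible from its config file and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatic import AberrationModel, apply_correction
from .decoding import (Allocation, cluster_homologs, decode_cluster)
from .detection import Dot, dog_detect, dots_to_dataframe
from .geometry import pairwise_distance_matrix
from .io import PipelineConfig, read_fov, write_fov, write_scene_truth
from .nuclei import NucleusMask, g1_gate, lamina_distances, segment_nuclei
from .scheme import ColorScheme, build_chr2_scheme
from .simulate import SceneTruth, VoxelStack, render_stack, simulate_structures

logger = logging.getLogger("mifish")

__all__ = ["PipelineResult", "analyze_dataset", "run_pipeline"]


@dataclass
class PipelineResult:
    """Aggregated outputs of one pipeline run."""

    dot_table: pd.DataFrame
    nucleus_table: pd.DataFrame
    allocation_table: pd.DataFrame
    allocations: list[Allocation]
    distance_matrix: pd.DataFrame
    lamina_by_probe: dict[str, list[float]]
    stage_counts: dict[str, int] = field(default_factory=dict)


def _detect_fov(
    stacks: dict[str, VoxelStack],
    scheme: ColorScheme,
    config: PipelineConfig,
    model: AberrationModel | None,
) -> tuple[list[NucleusMask], list[Dot]]:
    """Per-FOV stage: segment nuclei, detect + localize + correct dots,
    attribute dots to nuclei."""
    masks = segment_nuclei(stacks["dapi"]) if "dapi" in stacks else []
    dots: list[Dot] = []
    for channel in scheme.channels:
        if channel not in stacks:
            continue
        chan_dots = dog_detect(stacks[channel], channel,
                               dog_threshold=config.dog_threshold)
        if model is not None:
            chan_dots = apply_correction(chan_dots, model)
        dots.extend(chan_dots)
    for i, d in enumerate(dots):
        d.dot_id = i
        d.nucleus_id = -1
        for m in masks:
            if m.contains_dot(d):
                d.nucleus_id = m.nucleus_id
                break
    return masks, dots


def analyze_dataset(
    fovs: list[dict[str, VoxelStack]],
    scheme: ColorScheme,
    config: PipelineConfig | None = None,
    model: AberrationModel | None = None,
) -> PipelineResult:
    """Run the full analysis over loaded fields of view.

    Nuclei are gated to G1 across the whole dataset; each G1 nucleus
    with enough dots is split into two homolog clusters which are then
    decoded against the scheme.  Lamina distances are recorded for every
    assigned probe position.
    """
    config = config or PipelineConfig()
    counts: dict[str, int] = {}

    all_masks: list[tuple[int, NucleusMask]] = []
    all_dots: list[tuple[int, Dot]] = []
    for fov, stacks in enumerate(fovs):
        masks, dots = _detect_fov(stacks, scheme, config, model)
        all_masks.extend((fov, m) for m in masks)
        all_dots.extend((fov, d) for d in dots)
    counts["nuclei"] = len(all_masks)
    counts["dots_detected"] = len(all_dots)

    if config.assume_g1:
        for _, m in all_masks:
            m.cell_cycle_label = "G1"
    else:
        g1_gate([m for _, m in all_masks])
    counts["g1_nuclei"] = sum(
        1 for _, m in all_masks if m.cell_cycle_label == "G1"
    )

    allocations: list[Allocation] = []
    lamina_by_probe: dict[str, list[float]] = {
        p.probe_id: [] for p in scheme.probes
    }
    alloc_rows = []
    rng = np.random.default_rng(config.seed)
    next_cluster_id = 0
    for fov, mask in all_masks:
        if mask.cell_cycle_label != "G1":
            continue
        nuc_dots = [d for f, d in all_dots
                    if f == fov and d.nucleus_id == mask.nucleus_id]
        if len(nuc_dots) < 4:
            continue
        clusters = cluster_homologs(
            nuc_dots, radius_px=config.cluster_radius_px,
            seed=int(rng.integers(0, 2**31 - 1)), nucleus_id=mask.nucleus_id,
        )
        probe_dots: list[Dot] = []
        probe_dot_ids: list[str] = []
        for cluster in clusters:
            if len(cluster.dots) < 2:
                continue
            cluster.cluster_id = next_cluster_id
            next_cluster_id += 1
            alloc = decode_cluster(
                cluster, scheme,
                split_radius_um=config.split_radius_um,
                outlier_radius_um=config.outlier_radius_um,
            )
            allocations.append(alloc)
            for pid, a in alloc.assignments.items():
                row = {
                    "fov": fov, "nucleus_id": mask.nucleus_id,
                    "cluster_id": alloc.cluster_id, "probe_id": pid,
                    "status": a.status,
                    "coloc_distance_um": a.coloc_distance_um,
                    "n_dots": len(a.dots),
                }
                pos = alloc.probe_position_um(pid)
                if pos is not None:
                    row.update(x_um=pos[0], y_um=pos[1], z_um=pos[2])
                    probe_dots.append(Dot(
                        x=pos[0] * 1000 / 130.0, y=pos[1] * 1000 / 130.0,
                        z=pos[2] * 1000 / 200.0, channel="", probe_id=pid,
                    ))
                    probe_dot_ids.append(pid)
                alloc_rows.append(row)
        if probe_dots:
            dists = lamina_distances(probe_dots, mask,
                                     config.center_percentile)
            for pid, (_, _, norm) in zip(probe_dot_ids, dists):
                if np.isfinite(norm):
                    lamina_by_probe[pid].append(norm)

    counts["clusters_decoded"] = len(allocations)
    counts["probes_assigned"] = sum(a.n_assigned for a in allocations)

    nucleus_rows = [
        {
            "fov": fov, "nucleus_id": m.nucleus_id,
            "volume_um3": m.volume_um3,
            "integrated_intensity": m.integrated_dna_intensity,
            "cell_cycle_label": m.cell_cycle_label,
        }
        for fov, m in all_masks
    ]
    dot_frames = []
    for fov in range(len(fovs)):
        fov_dots = [d for f, d in all_dots if f == fov]
        if fov_dots:
            df = dots_to_dataframe(fov_dots)
            df.insert(0, "fov", fov)
            dot_frames.append(df)
    dot_table = (pd.concat(dot_frames, ignore_index=True)
                 if dot_frames else pd.DataFrame())

    distance_matrix = (
        pairwise_distance_matrix(allocations, scheme)
        if allocations else pd.DataFrame()
    )
    return PipelineResult(
        dot_table=dot_table,
        nucleus_table=pd.DataFrame(nucleus_rows),
        allocation_table=pd.DataFrame(alloc_rows),
        allocations=allocations,
        distance_matrix=distance_matrix,
        lamina_by_probe=lamina_by_probe,
        stage_counts=counts,
    )


def simulate_fovs(
    scheme: ColorScheme,
    config: PipelineConfig,
) -> tuple[list[dict[str, VoxelStack]], list[SceneTruth]]:
    """Simulate ``config.n_cells`` single-cell fields of view."""
    scenes = simulate_structures(
        scheme, config.n_cells, seed=config.seed,
        photons_dual=config.photons_dual,
    )
    rng = np.random.default_rng(config.seed + 1)
    fovs = []
    for scene in scenes:
        stacks = {
            ch: render_stack(scene, ch, noise=True,
                             seed=int(rng.integers(0, 2**31 - 1)))
            for ch in ["dapi"] + scheme.channels
        }
        fovs.append(stacks)
    return fovs, scenes


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-level entry point: read or simulate FOVs, analyze, write CSVs.

    Every intermediate table lands in ``config.output_dir``; the run log
    records counts per stage.  Any stage failure aborts with the stage
    name in the raised exception.
    """
    from pathlib import Path

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = build_chr2_scheme()
    model = (AberrationModel.load(config.aberration_model)
             if config.aberration_model else None)

    stage = "input"
    try:
        if config.simulate:
            fovs, scenes = simulate_fovs(scheme, config)
            for i, stacks in enumerate(fovs):
                write_fov(out / "images", i, stacks)
            write_scene_truth(out / "scene_truth.csv", scenes)
        else:
            if not config.input_dir:
                raise ValueError("input_dir required unless simulate=True")
            fovs = [read_fov(config.input_dir, i)
                    for i in range(config.n_fovs)]
        stage = "analysis"
        result = analyze_dataset(fovs, scheme, config, model)
        stage = "output"
        result.dot_table.to_csv(out / "dots.csv", index=False)
        result.nucleus_table.to_csv(out / "nuclei.csv", index=False)
        result.allocation_table.to_csv(out / "allocations.csv", index=False)
        if len(result.distance_matrix):
            result.distance_matrix.drop(columns=["samples_um"]).to_csv(
                out / "pairwise_distances.csv", index=False)
        logger.info("pipeline done: %s", result.stage_counts)
        (out / "run_log.txt").write_text(
            "\n".join(f"{k}: {v}" for k, v in result.stage_counts.items()) + "\n"
        )
        return result
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
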