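"""File dialects: per-channel TIFF stacks, truth CSVs, configuration.

Fields of view follow the deposited-dataset naming convention: one TIFF
per channel named ``<channel>_<fov:03d>.tif`` with channels dapi, a488,
tmr, a594, cy5, a700, ir800 (cy5 denotes AT647N).  Configuration is a
YAML file that round-trips losslessly through :class:`PipelineConfig`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .psf import VOXEL_NM
from .simulate import SceneTruth, VoxelStack

__all__ = [
    "PipelineConfig",
    "read_fov",
    "write_fov",
    "fov_filename",
    "write_scene_truth",
    "read_scene_truth",
]

CHANNEL_ORDER = ("dapi", "a488", "tmr", "a594", "cy5", "a700", "ir800")


def fov_filename(channel: str, fov_index: int) -> str:
    return f"{channel}_{fov_index:03d}.tif"


def write_fov(directory: str | Path, fov_index: int,
              stacks: dict[str, VoxelStack]) -> None:
    """Write per-channel TIFF stacks for one field of view."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for channel, stack in stacks.items():
        tifffile.imwrite(directory / fov_filename(channel, fov_index),
                         stack.data.astype(np.float32))


def read_fov(directory: str | Path, fov_index: int,
             channels=CHANNEL_ORDER) -> dict[str, VoxelStack]:
    """Load one field of view's per-channel stacks.

    Raises ``FileNotFoundError`` naming the first missing channel and
    ``ValueError`` on shape mismatches between channels.
    """
    directory = Path(directory)
    stacks: dict[str, VoxelStack] = {}
    shape = None
    for channel in channels:
        path = directory / fov_filename(channel, fov_index)
        if not path.exists():
            raise FileNotFoundError(
                f"missing channel {channel!r} for FOV {fov_index}: {path}"
            )
        data = tifffile.imread(path).astype(float)
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise ValueError(
                f"channel {channel!r} shape {data.shape} != {shape}"
            )
        stacks[channel] = VoxelStack(data, VOXEL_NM, channel)
    return stacks


def write_scene_truth(path: str | Path, scenes: list[SceneTruth]) -> None:
    """Serialize scene ground truth as a flat CSV (one row per emitter
    per dye)."""
    rows = []
    for fov, scene in enumerate(scenes):
        for d in scene.dots:
            for dye, photons in d.photons.items():
                rows.append({
                    "fov": fov, "probe_id": d.probe_id, "allele": d.allele,
                    "x_nm": d.x_nm, "y_nm": d.y_nm, "z_nm": d.z_nm,
                    "dye": dye, "photons": photons,
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scene_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class PipelineConfig:
    """All pipeline knobs with the method-standard defaults.

    Thresholds: co-localization 0.25 um (same dichroic cube) / 0.55 um
    (different cubes), split-dot suppression 0.50 um, cluster outlier
    5 um, homolog cluster radius 40 px, top-10 (or 2 for ir800)
    candidate dots per channel.
    """

    input_dir: str = ""
    output_dir: str = "mifish_out"
    n_fovs: int = 1
    simulate: bool = False
    n_cells: int = 20
    seed: int = 0
    voxel_size_nm: tuple[float, float, float] = VOXEL_NM
    dog_threshold: float = 3.0
    photons_dual: float = 2500.0
    same_cube_um: float = 0.25
    different_cube_um: float = 0.55
    split_radius_um: float = 0.50
    outlier_radius_um: float = 5.0
    cluster_radius_px: float = 40.0
    candidates_per_channel: int = 10
    candidates_ir800: int = 2
    center_percentile: float = 99.0
    #: treat every segmented nucleus as G1 (for datasets known to be
    #: pre-gated or simulated without G2 cells)
    assume_g1: bool = False
    contact_threshold_um: float = 1.0
    hic_matrix: str = ""
    hic_eigenvector: str = ""
    aberration_model: str = ""

    def save(self, path: str | Path) -> None:
        d = asdict(self)
        d["voxel_size_nm"] = list(self.voxel_size_nm)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["voxel_size_nm"] = tuple(d.get("voxel_size_nm", VOXEL_NM))
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("dog_threshold", "same_cube_um", "different_cube_um",
                     "split_radius_um", "outlier_radius_um",
                     "cluster_radius_px", "contact_threshold_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
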