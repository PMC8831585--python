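"""Ground-truthed synthetic miFISH imaging.

Three generators cover the inputs the analysis pipeline consumes:

* :func:`simulate_structures` — cell scenes: an ellipsoidal nucleus per
  cell with two homolog chromatin chains whose inter-locus steps follow a
  power-law of genomic distance, optionally biased toward the nuclear
  lamina for B-compartment loci.
* :func:`render_stack` — a per-channel 3D image of a scene: dots rendered
  as pixel-integrated 3D Gaussians with per-channel PSF widths, the DNA
  stain as filled nuclei, and the sensor noise model (Poisson on
  signal+background, then additive Gaussian read noise).
* :func:`render_bead_field` / :func:`simulate_patch` — calibration bead
  fields with injected chromatic aberrations, and single-dot patches for
  the localization-precision experiment.

All randomness flows through one ``numpy.random.Generator`` seeded per
call, so identical seeds give bit-identical scenes and images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .psf import AXIAL_NM, LATERAL_NM, VOXEL_NM, channel_psf_params
from .scheme import ColorScheme, DYE_NAMES

__all__ = [
    "VoxelStack",
    "Nucleus",
    "TrueDot",
    "SceneTruth",
    "AberrationField",
    "simulate_structures",
    "render_stack",
    "render_bead_field",
    "simulate_patch",
    "add_sensor_noise",
]

#: default scene raster: 40 planes x 128 x 128 px = 8.0 x 16.6 x 16.6 um
DEFAULT_SHAPE: tuple[int, int, int] = (40, 128, 128)

#: default nucleus semi-axes (x, y, z) nm — a flattened interphase
#: nucleus, ~12 um across laterally as typical for adherent RPE-1 cells
DEFAULT_SEMI_AXES_NM: tuple[float, float, float] = (6200.0, 5400.0, 3100.0)

#: chain step scale: per-axis sd in nm of the displacement between loci
#: separated by 1 Mb (scaled by gap_Mb**nu); 400 nm/Mb^0.5 puts the
#: median 3D distance of 3-Mb pairs near 1 um, the scale reported for
#: few-Mb separations in interphase chromatin.
DEFAULT_STEP_SCALE_NM: float = 400.0
DEFAULT_NU: float = 0.5

#: chromosome-territory confinement radius: each allele's chain is kept
#: within this distance of its territory center (interphase chromosome
#: territories are a few um across).
DEFAULT_TERRITORY_RADIUS_NM: float = 3000.0

#: photons collected per dye for a dual-color probe's dot; single-color
#: probes carry twice the oligos of one dye, hence 2x photons.
DEFAULT_PHOTONS_DUAL: float = 2500.0
DEFAULT_BACKGROUND: float = 100.0
DEFAULT_READ_NOISE: float = 5.0

_SQRT2 = np.sqrt(2.0)


@dataclass
class VoxelStack:
    """One channel's 3D image, indexed (z, y, x).

    Continuous coordinates place integer voxel index at the voxel center;
    physical coordinates are ``index * voxel_size_nm`` per axis.
    """

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float] = VOXEL_NM
    channel: str = ""

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class Nucleus:
    """Ellipsoidal nucleus: center and semi-axes in nm (x, y, z)."""

    center_nm: np.ndarray
    semi_axes_nm: np.ndarray
    cell_cycle: str = "G1"  # G1 | G2

    def rho(self, pos_nm: np.ndarray) -> float:
        """Normalized ellipsoidal radius (1.0 at the surface)."""
        rel = (np.asarray(pos_nm) - self.center_nm) / self.semi_axes_nm
        return float(np.sqrt(np.sum(rel**2, axis=-1)))

    def contains(self, pos_nm: np.ndarray, margin: float = 1.0) -> bool:
        return self.rho(pos_nm) <= margin


@dataclass
class TrueDot:
    """Ground-truth emitter: one locus (or bead) in one allele/field."""

    probe_id: str
    allele: int
    x_nm: float
    y_nm: float
    z_nm: float
    photons: dict[str, float]  # dye -> photons

    @property
    def pos_nm(self) -> np.ndarray:
        return np.array([self.x_nm, self.y_nm, self.z_nm])


@dataclass
class SceneTruth:
    """Full ground truth for one field: geometry, emitters, noise levels."""

    kind: str  # "nuclei" | "beads"
    shape: tuple[int, int, int]
    nuclei: list[Nucleus] = field(default_factory=list)
    dots: list[TrueDot] = field(default_factory=list)
    background_level: float = DEFAULT_BACKGROUND
    read_noise_sigma: float = DEFAULT_READ_NOISE

    def dots_in_channel(self, channel: str) -> list[TrueDot]:
        return [d for d in self.dots if channel in d.photons]

    @property
    def channels(self) -> list[str]:
        chans = {c for d in self.dots for c in d.photons}
        return [c for c in DYE_NAMES if c in chans]


# ---------------------------------------------------------------------------
# chromatin-chain scene generation


def _sample_point_in_ellipsoid(rng: np.random.Generator, nuc: Nucleus,
                               max_rho: float = 1.0) -> np.ndarray:
    while True:
        u = rng.uniform(-1.0, 1.0, 3)
        if np.sum(u**2) <= max_rho**2:
            return nuc.center_nm + u * nuc.semi_axes_nm


def _constrained_step(rng: np.random.Generator, pos: np.ndarray,
                      sd_nm: float, nuc: Nucleus,
                      territory_center: np.ndarray | None = None,
                      territory_radius_nm: float = np.inf,
                      max_rho: float = 0.95) -> np.ndarray:
    """Gaussian step kept inside the nucleus (and, if given, inside the
    chromosome territory) by rejection, with a deterministic fallback
    near the territory center for pathological step scales."""
    for _ in range(300):
        cand = pos + rng.normal(0.0, sd_nm, 3)
        if nuc.rho(cand) > max_rho:
            continue
        if territory_center is not None and np.linalg.norm(
                cand - territory_center) > territory_radius_nm:
            continue
        return cand
    anchor = territory_center if territory_center is not None else nuc.center_nm
    return anchor + rng.normal(0.0, min(sd_nm, territory_radius_nm / 3.0), 3)


def _push_to_lamina(pos: np.ndarray, nuc: Nucleus, bias: float,
                    max_rho: float = 0.95) -> np.ndarray:
    """Move a point radially outward by ``bias`` of its remaining
    distance to the nuclear surface (in ellipsoidal coordinates)."""
    rel = (pos - nuc.center_nm) / nuc.semi_axes_nm
    rho = float(np.sqrt(np.sum(rel**2)))
    if rho < 1e-9:
        return pos
    rho_new = rho + bias * (max_rho - rho)
    return nuc.center_nm + rel / rho * rho_new * nuc.semi_axes_nm


def simulate_structures(
    scheme: ColorScheme,
    n_cells: int,
    step_scale_nm: float = DEFAULT_STEP_SCALE_NM,
    nu: float = DEFAULT_NU,
    radial_bias: dict[str, float] | None = None,
    seed: int | None = None,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    semi_axes_nm: Sequence[float] = DEFAULT_SEMI_AXES_NM,
    g2_fraction: float = 0.3,
    photons_dual: float = DEFAULT_PHOTONS_DUAL,
    background: float = DEFAULT_BACKGROUND,
    read_noise_sigma: float = DEFAULT_READ_NOISE,
    min_allele_separation_nm: float = 7000.0,
    territory_radius_nm: float = DEFAULT_TERRITORY_RADIUS_NM,
) -> list[SceneTruth]:
    """Simulate ``n_cells`` single-nucleus scenes with two allele chains.

    Successive loci of an allele are displaced by isotropic Gaussian
    steps with per-axis sd ``step_scale_nm * gap_Mb**nu``, kept (by
    rejection) inside the nucleus and inside the allele's chromosome
    territory (a sphere of ``territory_radius_nm`` around the territory
    center).  ``radial_bias`` maps probe_id -> bias in [0, 1): those
    loci are pushed toward the lamina by that fraction of their
    remaining radial distance (used to emulate B-compartment lamina
    association).

    Dual-color probes emit ``photons_dual`` per dye at the *same* true
    position in both channels; single-color probes emit twice that in
    their one channel.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 < nu <= 1.0:
        raise ValueError("chain exponent nu must be in (0, 1]")
    if step_scale_nm < 0:
        raise ValueError("step_scale_nm must be non-negative")
    rng = np.random.default_rng(seed)
    radial_bias = radial_bias or {}

    field_nm = np.array([shape[2] * LATERAL_NM, shape[1] * LATERAL_NM,
                         shape[0] * AXIAL_NM])
    center = field_nm / 2.0
    semi = np.asarray(semi_axes_nm, float)

    probes = scheme.probes
    gaps_mb = [
        (probes[i + 1].midpoint - probes[i].midpoint) / 1e6
        for i in range(len(probes) - 1)
    ]

    scenes: list[SceneTruth] = []
    for _ in range(n_cells):
        cc = "G2" if rng.uniform() < g2_fraction else "G1"
        nuc = Nucleus(center.copy(), semi.copy(), cc)
        # two allele territories at guaranteed separation: antipodal
        # placement along a random direction with enough nuclear extent
        for _ in range(500):
            u = rng.normal(0.0, 1.0, 3)
            u /= np.linalg.norm(u)
            t_max = 0.65 / np.sqrt(np.sum((u / semi) ** 2))
            if 2.0 * t_max >= min_allele_separation_nm:
                break
        t0 = rng.uniform(min_allele_separation_nm / 2.0, t_max)
        t1 = rng.uniform(min_allele_separation_nm / 2.0, t_max)
        starts = [center + t0 * u, center - t1 * u]

        dots: list[TrueDot] = []
        for allele, terr_center in enumerate(starts):
            pos = terr_center + rng.normal(0.0, 400.0, 3)
            positions = [pos]
            for gap in gaps_mb:
                sd = step_scale_nm * gap**nu
                if sd > 0:
                    pos = _constrained_step(
                        rng, pos, sd, nuc, terr_center, territory_radius_nm)
                positions.append(pos)
            for probe, p in zip(probes, positions):
                bias = radial_bias.get(probe.probe_id, 0.0)
                if bias > 0:
                    p = _push_to_lamina(p, nuc, bias)
                if probe.is_dual:
                    photons = {d: photons_dual for d in probe.dyes}
                else:
                    photons = {next(iter(probe.dyes)): 2.0 * photons_dual}
                dots.append(
                    TrueDot(probe.probe_id, allele, p[0], p[1], p[2], photons)
                )
        scenes.append(
            SceneTruth("nuclei", tuple(shape), [nuc], dots,
                       background, read_noise_sigma)
        )
    return scenes


# ---------------------------------------------------------------------------
# rendering


def _render_gaussian_dot(data: np.ndarray, x_px: float, y_px: float,
                         z_px: float, photons: float, sigma_lat_px: float,
                         sigma_z_px: float) -> None:
    """Add a pixel-integrated 3D Gaussian (total = ``photons``) in place.

    Integration over each voxel uses erf differences per axis; the
    support window is clipped at +-5 sigma.
    """
    nz, ny, nx = data.shape
    wz = max(2, int(np.ceil(5 * sigma_z_px)))
    wl = max(2, int(np.ceil(5 * sigma_lat_px)))
    z0, z1 = max(0, int(z_px) - wz), min(nz, int(z_px) + wz + 1)
    y0, y1 = max(0, int(y_px) - wl), min(ny, int(y_px) + wl + 1)
    x0, x1 = max(0, int(x_px) - wl), min(nx, int(x_px) + wl + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return

    def axis_frac(idx: np.ndarray, mu: float, sig: float) -> np.ndarray:
        lo = (idx - 0.5 - mu) / (sig * _SQRT2)
        hi = (idx + 0.5 - mu) / (sig * _SQRT2)
        return 0.5 * (erf(hi) - erf(lo))

    fz = axis_frac(np.arange(z0, z1), z_px, sigma_z_px)
    fy = axis_frac(np.arange(y0, y1), y_px, sigma_lat_px)
    fx = axis_frac(np.arange(x0, x1), x_px, sigma_lat_px)
    data[z0:z1, y0:y1, x0:x1] += photons * (
        fz[:, None, None] * fy[None, :, None] * fx[None, None, :]
    )


def add_sensor_noise(signal: np.ndarray, background: float,
                     read_noise_sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Sensor model: Poisson(signal + background) then additive
    Gaussian read noise, clipped at zero."""
    img = rng.poisson(np.maximum(signal + background, 0.0)).astype(float)
    if read_noise_sigma > 0:
        img += rng.normal(0.0, read_noise_sigma, img.shape)
    return np.clip(img, 0.0, None)


def render_stack(
    scene: SceneTruth,
    channel: str,
    noise: bool = True,
    seed: int | None = None,
    dna_intensity: float = 150.0,
) -> VoxelStack:
    """Render one channel of a scene as a :class:`VoxelStack`.

    Dye channels render each true dot carrying that dye as a 3D Gaussian
    with the channel's predicted PSF widths.  The ``'dapi'`` channel
    renders filled nuclei (G2 nuclei at twice the intensity).  With
    ``noise=True`` the sensor model (Poisson + Gaussian sigma =
    ``scene.read_noise_sigma``) is applied on top of
    ``scene.background_level``.
    """
    nz, ny, nx = scene.shape
    data = np.zeros((nz, ny, nx), float)

    if channel == "dapi":
        zz, yy, xx = np.meshgrid(
            np.arange(nz) * AXIAL_NM, np.arange(ny) * LATERAL_NM,
            np.arange(nx) * LATERAL_NM, indexing="ij",
        )
        for nuc in scene.nuclei:
            cx, cy, cz = nuc.center_nm
            ax, ay, az = nuc.semi_axes_nm
            inside = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + (
                (zz - cz) / az
            ) ** 2 <= 1.0
            level = dna_intensity * (2.0 if nuc.cell_cycle == "G2" else 1.0)
            data[inside] += level
        data = ndimage.gaussian_filter(data, sigma=(0.8, 1.2, 1.2))
    else:
        dots = scene.dots_in_channel(channel)
        if channel not in DYE_NAMES:
            raise KeyError(f"unknown channel {channel!r}")
        psf = channel_psf_params(channel)
        for d in dots:
            _render_gaussian_dot(
                data,
                d.x_nm / LATERAL_NM,
                d.y_nm / LATERAL_NM,
                d.z_nm / AXIAL_NM,
                d.photons[channel],
                psf.expected_sigma_px,
                psf.expected_sigma_z_px,
            )

    if noise:
        rng = np.random.default_rng(seed)
        data = add_sensor_noise(data, scene.background_level,
                                scene.read_noise_sigma, rng)
    else:
        data = data + scene.background_level
    return VoxelStack(data, VOXEL_NM, channel)


# ---------------------------------------------------------------------------
# bead fields for aberration calibration


@dataclass
class AberrationField:
    """Per-channel chromatic displacement model in pixel units.

    Lateral displacement is a 2nd-order polynomial of the lateral
    position: dx = c . [1, x, y, x^2, xy, y^2] (likewise dy), plus a
    constant axial shift ``dz`` in focal-plane units.  The reference
    channel (cy5 / AT647N) has the identity field.
    """

    coeff_x: dict[str, np.ndarray] = field(default_factory=dict)
    coeff_y: dict[str, np.ndarray] = field(default_factory=dict)
    dz: dict[str, float] = field(default_factory=dict)
    reference_channel: str = "cy5"

    @staticmethod
    def design_row(x_px: float | np.ndarray, y_px: float | np.ndarray) -> np.ndarray:
        x = np.asarray(x_px, float)
        y = np.asarray(y_px, float)
        return np.stack(
            [np.ones_like(x), x, y, x**2, x * y, y**2], axis=-1
        )

    def displacement(self, channel: str, x_px, y_px):
        """(dx_px, dy_px, dz_axial_px) of ``channel`` at lateral (x, y)."""
        if channel == self.reference_channel or channel not in self.coeff_x:
            zeros = np.zeros_like(np.asarray(x_px, float))
            return zeros, np.zeros_like(zeros), np.zeros_like(zeros)
        row = self.design_row(x_px, y_px)
        dx = row @ self.coeff_x[channel]
        dy = row @ self.coeff_y[channel]
        dz = np.full_like(dx, self.dz.get(channel, 0.0))
        return dx, dy, dz


def render_bead_field(
    n_beads: int,
    aberration: AberrationField,
    channels: Iterable[str] = DYE_NAMES,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    photons: float = 20000.0,
    background: float = DEFAULT_BACKGROUND,
    read_noise_sigma: float = DEFAULT_READ_NOISE,
    noise: bool = True,
    seed: int | None = None,
):
    """Render a multi-channel TetraSpeck-like bead field.

    Beads are placed uniformly at random and are visible in every
    channel; in channel ``c`` each bead is rendered at its true position
    plus ``aberration.displacement(c, ...)``.  Returns ``(stacks, truth)``
    where ``stacks`` maps channel -> :class:`VoxelStack` and ``truth`` is
    a list of per-channel dicts with true and displaced positions (px).
    """
    import warnings

    if n_beads < 6:
        warnings.warn("fewer than 6 beads cannot constrain a 2nd-order fit",
                      stacklevel=2)
    channels = list(channels)
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    margin_l, margin_z = 6.0, 4.0
    xs = rng.uniform(margin_l, nx - 1 - margin_l, n_beads)
    ys = rng.uniform(margin_l, ny - 1 - margin_l, n_beads)
    zs = rng.uniform(margin_z, nz - 1 - margin_z, n_beads)

    stacks: dict[str, VoxelStack] = {}
    truth: list[dict] = []
    for c in channels:
        psf = channel_psf_params(c)
        data = np.zeros(shape, float)
        dx, dy, dz = aberration.displacement(c, xs, ys)
        for i in range(n_beads):
            _render_gaussian_dot(
                data, xs[i] + dx[i], ys[i] + dy[i], zs[i] + dz[i],
                photons, psf.expected_sigma_px, psf.expected_sigma_z_px,
            )
            truth.append({
                "channel": c, "bead_id": i,
                "x_px": xs[i], "y_px": ys[i], "z_px": zs[i],
                "x_obs_px": xs[i] + dx[i], "y_obs_px": ys[i] + dy[i],
                "z_obs_px": zs[i] + dz[i],
            })
        if noise:
            data = add_sensor_noise(data, background, read_noise_sigma, rng)
        else:
            data = data + background
        stacks[c] = VoxelStack(data, VOXEL_NM, c)
    return stacks, truth


# ---------------------------------------------------------------------------
# localization-precision patches


def simulate_patch(
    channel: str,
    photons: float,
    background: float = DEFAULT_BACKGROUND,
    n: int = 1000,
    patch_size: int = 15,
    read_noise_sigma: float = DEFAULT_READ_NOISE,
    seed: int | None = None,
) -> list[tuple[np.ndarray, tuple[float, float, float]]]:
    """Single-dot patches for the localization-precision experiment.

    Each patch is ``patch_size``^3 voxels with one Gaussian dot whose
    true sub-voxel position is uniform within the central voxel, the
    stated ``background`` level, Poisson noise and Gaussian read noise
    (sigma = ``read_noise_sigma``).  Returns ``n`` pairs of
    (patch, (x_px, y_px, z_px) truth).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    psf = channel_psf_params(channel)
    rng = np.random.default_rng(seed)
    c = patch_size // 2
    out = []
    for _ in range(n):
        x = c + rng.uniform(-0.5, 0.5)
        y = c + rng.uniform(-0.5, 0.5)
        z = c + rng.uniform(-0.5, 0.5)
        data = np.zeros((patch_size,) * 3, float)
        _render_gaussian_dot(data, x, y, z, photons,
                             psf.expected_sigma_px, psf.expected_sigma_z_px)
        data = add_sensor_noise(data, background, read_noise_sigma, rng)
        out.append((data, (x, y, z)))
    return out
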