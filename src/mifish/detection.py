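"""FISH dot detection and sub-voxel 3D localization.

Detection proceeds in the classical spot-calling order: band-pass the
stack with a difference-of-Gaussians (DoG) filter tuned to the channel's
diffraction-limited spot size, keep 6-connected local maxima above a DoG
threshold, then localize every candidate by two-stage maximum-likelihood
Gaussian fitting — a pixel-integrated 2D Gaussian in-plane for (x, y),
followed by a 1D Gaussian fit of the interpolated axial profile for z.
The noise is taken to be Gaussian, so the ML functional is a sum of
squares and is minimized by nonlinear least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import erf

from .psf import (AXIAL_NM, FWHM_PER_SIGMA, LATERAL_NM, PsfParams,
                  channel_psf_params)
from .simulate import VoxelStack

__all__ = [
    "Dot",
    "FitError",
    "channel_psf_params",
    "PsfParams",
    "local_maxima_6conn",
    "dog_detect",
    "fit_dot_3d",
    "localization_experiment",
    "pixel_center_localization_mae",
    "dots_to_dataframe",
    "DEFAULT_DOG_THRESHOLD",
]

#: Default DoG threshold (counts).  Calibrated on rendered synthetic
#: fields so that pure background (Poisson level 100 + read noise 5)
#: yields no candidates while dots of >= ~1500 photons are kept: the
#: DoG response of that background is ~0.45 counts rms, so 3.0 is a
#: ~7 sigma cut, while a 2500-photon dot responds at 12-30 counts.
DEFAULT_DOG_THRESHOLD: float = 3.0

#: sigma of the narrow DoG kernel relative to the expected spot sigma.
DOG_NARROW_FACTOR: float = 1.72
#: wide/narrow sigma ratio of the DoG pair (standard blob-detection ratio).
DOG_WIDE_RATIO: float = 1.6

_SQRT2 = math.sqrt(2.0)


class FitError(RuntimeError):
    """Raised when a dot fit fails to converge or the patch is degenerate."""


@dataclass
class Dot:
    """A localized FISH dot.

    Coordinates are continuous, in pixel units (``z`` in focal-plane
    units) and in nm; ``intensity`` is the fitted total photon count,
    ``sigma_px`` the fitted lateral Gaussian sigma.
    """

    x: float
    y: float
    z: float
    channel: str
    intensity: float = 0.0
    background: float = 0.0
    sigma_px: float = 0.0
    dog_value: float = 0.0
    nucleus_id: int = -1
    cluster_id: int = -1
    probe_id: str = ""
    dot_id: int = -1

    @property
    def fwhm_px(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_px

    @property
    def x_nm(self) -> float:
        return self.x * LATERAL_NM

    @property
    def y_nm(self) -> float:
        return self.y * LATERAL_NM

    @property
    def z_nm(self) -> float:
        return self.z * AXIAL_NM

    @property
    def pos_nm(self) -> np.ndarray:
        return np.array([self.x_nm, self.y_nm, self.z_nm])


def dots_to_dataframe(dots: list[Dot]) -> pd.DataFrame:
    """Flatten dots into the CSV table schema used by the pipeline."""
    return pd.DataFrame(
        [
            {
                "dot_id": d.dot_id, "channel": d.channel,
                "x_px": d.x, "y_px": d.y, "z_px": d.z,
                "x_nm": d.x_nm, "y_nm": d.y_nm, "z_nm": d.z_nm,
                "photons": d.intensity, "background": d.background,
                "sigma_px": d.sigma_px, "fwhm_px": d.fwhm_px,
                "dog_value": d.dog_value, "nucleus_id": d.nucleus_id,
                "cluster_id": d.cluster_id, "probe_id": d.probe_id,
            }
            for d in dots
        ]
    )


# ---------------------------------------------------------------------------
# candidate detection


def local_maxima_6conn(stack: VoxelStack | np.ndarray) -> list[tuple[int, int, int]]:
    """Voxels strictly brighter than all six face neighbors.

    Border voxels are compared against their existing neighbors only.
    A constant image has no strict maxima.
    """
    data = stack.data if isinstance(stack, VoxelStack) else np.asarray(stack)
    if min(data.shape) < 1:
        return []
    mask = np.ones(data.shape, bool)
    for axis in range(3):
        for sign in (1, -1):
            shifted = np.full_like(data, -np.inf)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if sign == 1:
                src[axis], dst[axis] = slice(1, None), slice(None, -1)
            else:
                src[axis], dst[axis] = slice(None, -1), slice(1, None)
            shifted[tuple(dst)] = data[tuple(src)]
            mask &= data > shifted
    return [tuple(idx) for idx in np.argwhere(mask)]


def dog_filter(data: np.ndarray, psf: PsfParams) -> np.ndarray:
    """Difference-of-Gaussians band-pass tuned to the channel's spot size."""
    s_lat = DOG_NARROW_FACTOR * psf.expected_sigma_px
    s_ax = DOG_NARROW_FACTOR * psf.expected_sigma_z_px
    narrow = ndimage.gaussian_filter(data, (s_ax, s_lat, s_lat))
    wide = ndimage.gaussian_filter(
        data, (DOG_WIDE_RATIO * s_ax, DOG_WIDE_RATIO * s_lat, DOG_WIDE_RATIO * s_lat)
    )
    return narrow - wide


def dog_detect(
    stack: VoxelStack,
    channel: str | None = None,
    dog_threshold: float = DEFAULT_DOG_THRESHOLD,
    fwhm_range: tuple[float, float] | None = None,
    fit: bool = True,
    max_candidates: int | None = None,
) -> list[Dot]:
    """Detect and localize dots in one channel's stack.

    The stack is DoG-filtered, 6-connected maxima of the filtered image
    with response >= ``dog_threshold`` become candidates, and each
    candidate is localized with :func:`fit_dot_3d`.  Fitted dots whose
    FWHM falls outside ``fwhm_range`` (default [0.5x, 2x] the channel's
    predicted FWHM) are discarded, as are non-converging fits.
    """
    if dog_threshold <= 0:
        raise ValueError("dog_threshold must be positive")
    channel = channel or stack.channel
    psf = channel_psf_params(channel)
    if fwhm_range is None:
        fwhm_range = (0.5 * psf.predicted_fwhm_px, 2.0 * psf.predicted_fwhm_px)

    dog = dog_filter(stack.data, psf)
    # maxima are found on a lightly smoothed copy of the image itself
    # (noise suppression at half the PSF sigma) rather than on the DoG
    # map: the broad DoG kernel would fuse dots a few pixels apart,
    # whereas image maxima keep them separable; the DoG response at each
    # maximum still provides the detection score.
    smooth = ndimage.gaussian_filter(
        stack.data, (0.5 * psf.expected_sigma_z_px,
                     0.5 * psf.expected_sigma_px, 0.5 * psf.expected_sigma_px)
    )
    candidates = [idx for idx in local_maxima_6conn(smooth)
                  if dog[idx] >= dog_threshold]
    candidates.sort(key=lambda idx: -dog[idx])
    # deduplicate residual noise-split maxima of one dot (keep highest DoG)
    kept: list[tuple[int, int, int]] = []
    min_sep = max(2.0, psf.expected_sigma_px)
    z_scale = AXIAL_NM / LATERAL_NM
    for idx in candidates:
        p = np.array([idx[2], idx[1], idx[0] * z_scale])
        if all(np.linalg.norm(p - np.array([k[2], k[1], k[0] * z_scale]))
               >= min_sep for k in kept):
            kept.append(idx)
    candidates = kept
    if max_candidates is not None:
        candidates = candidates[:max_candidates]

    dots: list[Dot] = []
    for idx in candidates:
        if not fit:
            dots.append(
                Dot(x=float(idx[2]), y=float(idx[1]), z=float(idx[0]),
                    channel=channel, intensity=float(stack.data[idx]),
                    dog_value=float(dog[idx]))
            )
            continue
        try:
            dot = fit_dot_3d(stack, idx, channel=channel)
        except FitError:
            continue
        if not fwhm_range[0] <= dot.fwhm_px <= fwhm_range[1]:
            continue
        dot.dog_value = float(dog[idx])
        dots.append(dot)
    for i, d in enumerate(dots):
        d.dot_id = i
    return dots


# ---------------------------------------------------------------------------
# two-stage Gaussian localization


def _axis_frac(idx: np.ndarray, mu: float, sig: float) -> np.ndarray:
    lo = (idx - 0.5 - mu) / (sig * _SQRT2)
    hi = (idx + 0.5 - mu) / (sig * _SQRT2)
    return 0.5 * (erf(hi) - erf(lo))


def fit_dot_3d(
    stack: VoxelStack,
    seed_voxel: tuple[int, int, int],
    patch_radius: int | None = None,
    channel: str | None = None,
) -> Dot:
    """Localize one dot by two-stage ML Gaussian fitting.

    Stage 1 fits a pixel-integrated 2D Gaussian (parameters x, y,
    photons, background, sigma) to the candidate's focal plane by
    nonlinear least squares (the Gaussian-noise ML estimate).  Stage 2
    interpolates the axial intensity profile at the fitted (x, y) and
    fits a 1D Gaussian for z.  Raises :class:`FitError` on
    non-convergence or a degenerate (constant) patch.
    """
    channel = channel or stack.channel
    try:
        psf = channel_psf_params(channel)
        sigma0, sigma_z = psf.expected_sigma_px, psf.expected_sigma_z_px
    except KeyError:
        sigma0, sigma_z = 1.2, 1.5
    if patch_radius is None:
        patch_radius = int(math.ceil(3.5 * sigma0))

    data = stack.data
    nz, ny, nx = data.shape
    z0, y0c, x0c = (int(v) for v in seed_voxel)
    if not (0 <= z0 < nz and 0 <= y0c < ny and 0 <= x0c < nx):
        raise FitError("seed voxel out of bounds")

    ylo, yhi = max(0, y0c - patch_radius), min(ny, y0c + patch_radius + 1)
    xlo, xhi = max(0, x0c - patch_radius), min(nx, x0c + patch_radius + 1)
    patch = data[z0, ylo:yhi, xlo:xhi].astype(float)
    if patch.size < 9 or np.ptp(patch) == 0:
        raise FitError("degenerate patch")

    yy = np.arange(ylo, yhi)
    xx = np.arange(xlo, xhi)
    bg0 = float(np.median(patch))
    # photons in this plane, from the peak height above background
    amp0 = max(float(data[z0, y0c, x0c]) - bg0, 1.0)
    n0 = amp0 * 2.0 * math.pi * sigma0**2

    def resid2d(p):
        x, y, n, b, s = p
        model = b + n * np.outer(_axis_frac(yy, y, s), _axis_frac(xx, x, s))
        return (model - patch).ravel()

    lb = [xlo - 0.5, ylo - 0.5, 0.0, 0.0, 0.25 * sigma0]
    ub = [xhi - 0.5, yhi - 0.5, np.inf, np.inf, 4.0 * sigma0]
    try:
        res = least_squares(
            resid2d, [float(x0c), float(y0c), n0, bg0, sigma0],
            bounds=(lb, ub), xtol=1e-10, ftol=1e-10, max_nfev=400,
        )
    except Exception as e:  # pragma: no cover - scipy internal failures
        raise FitError(str(e)) from None
    if not res.success and res.status <= 0:
        raise FitError("lateral fit did not converge")
    x_hat, y_hat, n_plane, bg_hat, sig_hat = res.x

    # stage 2: axial profile interpolated at (x_hat, y_hat)
    zwin = max(4, int(math.ceil(3.0 * sigma_z)))
    zlo, zhi = max(0, z0 - zwin), min(nz, z0 + zwin + 1)
    zz = np.arange(zlo, zhi)
    coords = np.stack([
        zz.astype(float),
        np.full(zz.shape, y_hat),
        np.full(zz.shape, x_hat),
    ])
    pz = ndimage.map_coordinates(data, coords, order=1, mode="nearest")
    if np.ptp(pz) == 0:
        raise FitError("flat axial profile")

    def resid1d(p):
        zc, a, b, s = p
        return a * np.exp(-0.5 * ((zz - zc) / s) ** 2) + b - pz

    a0 = max(float(pz.max() - pz.min()), 1.0)
    try:
        res_z = least_squares(
            resid1d, [float(z0), a0, float(pz.min()), sigma_z],
            bounds=([zlo - 0.5, 0.0, 0.0, 0.2], [zhi - 0.5, np.inf, np.inf, 5.0 * sigma_z]),
            xtol=1e-10, ftol=1e-10, max_nfev=200,
        )
    except Exception as e:  # pragma: no cover
        raise FitError(str(e)) from None
    if not res_z.success and res_z.status <= 0:
        raise FitError("axial fit did not converge")
    z_hat, _, _, sig_z_hat = res_z.x

    # total photons: undo the axial slicing of the fitted plane
    plane_frac = _axis_frac(np.array([z0]), z_hat, sig_z_hat)[0]
    photons = n_plane / max(plane_frac, 1e-3)

    return Dot(x=float(x_hat), y=float(y_hat), z=float(z_hat),
               channel=channel, intensity=float(photons),
               background=float(bg_hat), sigma_px=float(sig_hat))


# ---------------------------------------------------------------------------
# localization-precision experiment


def localization_experiment(
    channels=("a594", "cy5"),
    photon_levels=(2000.0, 8000.0, 32000.0),
    n: int = 1000,
    background: float = 100.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic localization precision: fit simulated single-dot patches.

    For every channel x photon level, ``n`` patches are generated with
    :func:`mifish.simulate.simulate_patch` (dot position uniform within
    the central voxel, Poisson + Gaussian sensor noise) and localized
    with :func:`fit_dot_3d`.  Returns a table of 3D RMSE (nm) per
    condition; failed fits are excluded and counted.
    """
    from .simulate import simulate_patch

    rng = np.random.default_rng(seed)
    rows = []
    for channel in channels:
        for photons in photon_levels:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            patches = simulate_patch(channel, photons, background, n=n,
                                     seed=sub_seed)
            sq_err, n_failed = [], 0
            for patch, (xt, yt, zt) in patches:
                c = patch.shape[0] // 2
                stack = VoxelStack(patch, channel=channel)
                try:
                    dot = fit_dot_3d(stack, (c, c, c), channel=channel)
                except FitError:
                    n_failed += 1
                    continue
                dx = (dot.x - xt) * LATERAL_NM
                dy = (dot.y - yt) * LATERAL_NM
                dz = (dot.z - zt) * AXIAL_NM
                sq_err.append(dx * dx + dy * dy + dz * dz)
            rows.append({
                "channel": channel, "photons": photons,
                "n_fit": len(sq_err), "n_failed": n_failed,
                "rmse_nm": float(np.sqrt(np.mean(sq_err))) if sq_err else np.nan,
            })
    return pd.DataFrame(rows)


def pixel_center_localization_mae(
    n_samples: int = 1_000_000,
    voxel_nm: tuple[float, float, float] = (LATERAL_NM, LATERAL_NM, AXIAL_NM),
    seed: int | None = None,
) -> float:
    """Mean absolute 3D error (nm) of pixel-center-only localization.

    Monte-Carlo estimate of the error incurred by snapping a uniformly
    distributed sub-voxel position to the voxel center — the baseline
    that sub-voxel Gaussian fitting improves on (~74 nm at
    130 x 130 x 200 nm voxels).
    """
    rng = np.random.default_rng(seed)
    err = rng.uniform(-0.5, 0.5, (n_samples, 3)) * np.asarray(voxel_nm)
    return float(np.mean(np.linalg.norm(err, axis=1)))
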