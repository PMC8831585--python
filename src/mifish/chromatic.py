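"""Chromatic-aberration measurement and correction from bead fields.

Multi-color imaging displaces the same physical point between channels
(wavelength-dependent refraction plus mechanical shifts when dichroic
cubes are swapped).  Following standard practice, the displacement of
each channel relative to the reference channel (cy5 / AT647N) is modeled
as a second-order polynomial of the lateral position plus a constant
axial shift, fitted on multi-spectral calibration beads.  Correction is
applied to dot *coordinates*; for point data this is equivalent to
resampling the images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .detection import Dot
from .psf import AXIAL_NM, LATERAL_NM
from .simulate import AberrationField

__all__ = [
    "AberrationModel",
    "match_beads",
    "fit_aberration",
    "apply_correction",
    "correction_mse",
    "REFERENCE_CHANNEL",
]

REFERENCE_CHANNEL = "cy5"

#: axial px -> lateral px conversion when forming 3D pixel distances
Z_ANISOTROPY = AXIAL_NM / LATERAL_NM


@dataclass
class AberrationModel:
    """Fitted per-channel displacement model.

    For each non-reference channel: 6 polynomial coefficients per
    lateral axis (basis 1, x, y, x^2, xy, y^2, pixel units) and a scalar
    axial shift dz (focal-plane units), plus fit bookkeeping.
    """

    reference_channel: str = REFERENCE_CHANNEL
    coeff_x: dict[str, np.ndarray] = field(default_factory=dict)
    coeff_y: dict[str, np.ndarray] = field(default_factory=dict)
    dz: dict[str, float] = field(default_factory=dict)
    n_beads_used: dict[str, int] = field(default_factory=dict)
    residual_mse_px: dict[str, float] = field(default_factory=dict)
    coeff_se_x: dict[str, np.ndarray] = field(default_factory=dict)
    coeff_se_y: dict[str, np.ndarray] = field(default_factory=dict)

    def predict(self, channel: str, x_px, y_px):
        """Predicted (dx, dy, dz) of ``channel`` relative to the reference."""
        if channel == self.reference_channel:
            zeros = np.zeros_like(np.asarray(x_px, float))
            return zeros, np.zeros_like(zeros), np.zeros_like(zeros)
        if channel not in self.coeff_x:
            raise KeyError(f"channel {channel!r} not in model")
        row = AberrationField.design_row(x_px, y_px)
        dx = row @ self.coeff_x[channel]
        dy = row @ self.coeff_y[channel]
        dz = np.full_like(np.asarray(dx, float), self.dz[channel])
        return dx, dy, dz

    # -- serialization (small JSON file, per the dataset convention of
    #    shipping displacement parameters + bead counts alongside images)
    def save(self, path: str | Path) -> None:
        payload = {
            "reference_channel": self.reference_channel,
            "channels": {
                c: {
                    "coeff_x": self.coeff_x[c].tolist(),
                    "coeff_y": self.coeff_y[c].tolist(),
                    "dz": self.dz[c],
                    "n_beads": self.n_beads_used.get(c, 0),
                    "residual_mse_px": self.residual_mse_px.get(c, float("nan")),
                }
                for c in self.coeff_x
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "AberrationModel":
        payload = json.loads(Path(path).read_text())
        model = cls(reference_channel=payload["reference_channel"])
        for c, d in payload["channels"].items():
            model.coeff_x[c] = np.asarray(d["coeff_x"], float)
            model.coeff_y[c] = np.asarray(d["coeff_y"], float)
            model.dz[c] = float(d["dz"])
            model.n_beads_used[c] = int(d.get("n_beads", 0))
            model.residual_mse_px[c] = float(d.get("residual_mse_px", "nan"))
        return model


def match_beads(
    ref_dots: list[Dot], other_dots: list[Dot], max_radius_px: float = 5.0
) -> list[tuple[Dot, Dot]]:
    """Mutual-nearest-neighbor bead pairing within ``max_radius_px``.

    Distances are 3D in lateral-pixel units (z scaled by the voxel
    anisotropy); each dot joins at most one pair.
    """
    if not ref_dots or not other_dots:
        raise ValueError("empty dot list")

    def coords(dots):
        return np.array([[d.x, d.y, d.z * Z_ANISOTROPY] for d in dots])

    a, b = coords(ref_dots), coords(other_dots)
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tree_b.query(a, k=1)
    d_ba, j_ba = tree_a.query(b, k=1)
    pairs = []
    for i, (dist, j) in enumerate(zip(d_ab, j_ab)):
        if dist <= max_radius_px and j_ba[j] == i:
            pairs.append((ref_dots[i], other_dots[j]))
    if not pairs:
        raise ValueError("no bead matches within max_radius_px")
    return pairs


def _displacements(pairs: list[tuple[Dot, Dot]]):
    """Observed (non-reference) positions and their displacement from
    the reference channel.  The polynomial is a function of the
    *observed* coordinates, so that subtracting the prediction from an
    observed dot is exactly the inverse mapping."""
    ref = np.array([[r.x, r.y, r.z] for r, _ in pairs])
    oth = np.array([[o.x, o.y, o.z] for _, o in pairs])
    return oth, oth - ref


def fit_aberration(pairs: list[tuple[Dot, Dot]], degree: int = 2) -> AberrationModel:
    """Least-squares fit of the displacement field for one channel pair.

    Fits each lateral axis independently against the 6-term 2nd-order
    polynomial basis evaluated at the observed (non-reference) positions,
    so applying the model to observed dots inverts the displacement
    exactly; dz is the mean axial displacement.  Coefficient standard errors come from the
    ordinary least-squares covariance.
    """
    if degree != 2:
        raise NotImplementedError("only the 2nd-order lateral model is supported")
    if len(pairs) < 6:
        raise ValueError("need >= 6 bead pairs for a 2nd-order fit")
    obs, delta = _displacements(pairs)
    channel = pairs[0][1].channel or "other"

    design = AberrationField.design_row(obs[:, 0], obs[:, 1])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design: beads are degenerate (collinear)")

    model = AberrationModel()
    n, p = design.shape
    gram_inv = np.linalg.inv(design.T @ design)
    resid_var = []
    for axis, store, store_se in (
        (0, model.coeff_x, model.coeff_se_x),
        (1, model.coeff_y, model.coeff_se_y),
    ):
        coef, res, *_ = np.linalg.lstsq(design, delta[:, axis], rcond=None)
        store[channel] = coef
        fitted = design @ coef
        rss = float(np.sum((delta[:, axis] - fitted) ** 2))
        resid_var.append(rss)
        sigma2 = rss / max(n - p, 1)
        store_se[channel] = np.sqrt(np.clip(sigma2 * np.diag(gram_inv), 0, None))
    model.dz[channel] = float(np.mean(delta[:, 2]))
    rss_z = float(np.sum((delta[:, 2] - model.dz[channel]) ** 2))
    model.n_beads_used[channel] = n
    # residual 3D MSE in lateral px (z in axial px, per the pixel-unit
    # convention of the calibration tables)
    model.residual_mse_px[channel] = (sum(resid_var) + rss_z) / n
    return model


def apply_correction(dots: list[Dot], model: AberrationModel) -> list[Dot]:
    """Return dots with model-predicted displacements subtracted.

    Reference-channel dots pass through unchanged.  Channels absent from
    the model raise ``KeyError``.
    """
    out = []
    for d in dots:
        if d.channel == model.reference_channel:
            out.append(d)
            continue
        dx, dy, dz = model.predict(d.channel, d.x, d.y)
        out.append(
            Dot(x=d.x - float(dx), y=d.y - float(dy), z=d.z - float(dz),
                channel=d.channel, intensity=d.intensity,
                background=d.background, sigma_px=d.sigma_px,
                dog_value=d.dog_value, nucleus_id=d.nucleus_id,
                cluster_id=d.cluster_id, probe_id=d.probe_id,
                dot_id=d.dot_id)
        )
    return out


def correction_mse(
    pairs: list[tuple[Dot, Dot]], model: AberrationModel
) -> tuple[float, float, float]:
    """(3D MSE before, 2D MSE after, 3D MSE after) in pixel units.

    Mean squared pair distance between reference and other-channel bead
    positions, before and after subtracting the fitted displacement
    field; z enters 3D distances in axial-pixel units.
    """
    obs, delta = _displacements(pairs)
    scale = np.array([1.0, 1.0, Z_ANISOTROPY])  # z in lateral-px equivalents
    mse3_before = float(np.mean(np.sum((delta * scale) ** 2, axis=1)))
    channel = pairs[0][1].channel or "other"
    dx, dy, dz = model.predict(channel, obs[:, 0], obs[:, 1])
    resid = (delta - np.stack([dx, dy, dz], axis=1)) * scale
    mse2_after = float(np.mean(np.sum(resid[:, :2] ** 2, axis=1)))
    mse3_after = float(np.mean(np.sum(resid**2, axis=1)))
    return mse3_before, mse2_after, mse3_after
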