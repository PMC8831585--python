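"""Chromatic-aberration model fitting and coordinate correction."""

import numpy as np
import pytest

from mifish.chromatic import (AberrationModel, apply_correction,
                              correction_mse, fit_aberration, match_beads)
from mifish.detection import Dot, dog_detect
from mifish.simulate import AberrationField, render_bead_field


def _dots(coords, channel="a594"):
    return [Dot(x=float(x), y=float(y), z=float(z), channel=channel,
                dot_id=i) for i, (x, y, z) in enumerate(coords)]


def _spread_positions(n, seed=0, extent=90.0):
    rng = np.random.default_rng(seed)
    return np.column_stack([
        rng.uniform(5, extent, n), rng.uniform(5, extent, n),
        rng.uniform(3, 30, n),
    ])


QUAD_FIELD = AberrationField(
    coeff_x={"a594": np.array([0.4, 2e-3, -1e-3, 1.5e-5, -8e-6, 6e-6])},
    coeff_y={"a594": np.array([-0.2, 1e-3, 2e-3, -9e-6, 5e-6, 1.2e-5])},
    dz={"a594": 0.6},
)


def _pairs_from_field(n=60, jitter_px=0.0, seed=0):
    # observed positions are drawn and the reference positions derived
    # by subtracting the field, matching the model's convention that
    # displacement is a polynomial of the observed coordinates
    obs = _spread_positions(n, seed)
    rng = np.random.default_rng(seed + 1)
    rows = AberrationField.design_row(obs[:, 0], obs[:, 1])
    dx = rows @ QUAD_FIELD.coeff_x["a594"]
    dy = rows @ QUAD_FIELD.coeff_y["a594"]
    ref = obs - np.column_stack([dx, dy, np.full(n, 0.6)])
    if jitter_px:
        ref = ref + rng.normal(0, jitter_px, ref.shape)
    return list(zip(_dots(ref, "cy5"), _dots(obs, "a594")))


class TestMatchBeads:
    def test_identical_lists_all_matched_at_zero(self):
        dots = _dots(_spread_positions(20), "cy5")
        pairs = match_beads(dots, _dots(_spread_positions(20), "a594"))
        assert len(pairs) == 20
        for r, o in pairs:
            assert r.x == o.x and r.y == o.y and r.z == o.z

    def test_displacement_beyond_radius_unmatched(self):
        ref = _dots([(10, 10, 5), (50, 50, 5)], "cy5")
        other = _dots([(10.2, 10.1, 5), (70, 70, 5)], "a594")
        pairs = match_beads(ref, other, max_radius_px=5.0)
        assert len(pairs) == 1

    def test_rendered_bead_field_fully_matched(self):
        stacks, _ = render_bead_field(
            40, AberrationField(), channels=("cy5", "a594"),
            shape=(24, 96, 96), seed=5)
        ref = dog_detect(stacks["cy5"], "cy5")
        other = dog_detect(stacks["a594"], "a594")
        pairs = match_beads(ref, other)
        assert len(pairs) == 40

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            match_beads([], _dots([(1, 1, 1)]))


class TestFitAberration:
    def test_zero_displacement_gives_zero_model(self):
        pos = _spread_positions(20)
        pairs = list(zip(_dots(pos, "cy5"), _dots(pos, "a594")))
        model = fit_aberration(pairs)
        assert np.allclose(model.coeff_x["a594"], 0.0, atol=1e-12)
        assert np.allclose(model.coeff_y["a594"], 0.0, atol=1e-12)
        assert model.dz["a594"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_interpolation_with_six_beads(self):
        pairs = _pairs_from_field(n=6, seed=3)
        model = fit_aberration(pairs)
        assert model.residual_mse_px["a594"] == pytest.approx(0.0, abs=1e-16)

    def test_quadratic_field_recovered_within_3se(self):
        pairs = _pairs_from_field(n=100, jitter_px=10.0 / 130.0, seed=4)
        model = fit_aberration(pairs)
        for coeff, se, truth in (
            (model.coeff_x["a594"], model.coeff_se_x["a594"],
             QUAD_FIELD.coeff_x["a594"]),
            (model.coeff_y["a594"], model.coeff_se_y["a594"],
             QUAD_FIELD.coeff_y["a594"]),
        ):
            assert np.all(np.abs(coeff - truth) <= 3 * se + 1e-12)
        assert model.dz["a594"] == pytest.approx(0.6, abs=0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_aberration(_pairs_from_field(n=5))

    def test_collinear_beads_rejected(self):
        pos = np.column_stack([np.arange(10.0), np.arange(10.0),
                               np.full(10, 5.0)])
        pairs = list(zip(_dots(pos, "cy5"), _dots(pos + 0.1, "a594")))
        with pytest.raises(ValueError, match="rank"):
            fit_aberration(pairs)


class TestApplyCorrection:
    def test_reference_channel_unchanged(self):
        model = fit_aberration(_pairs_from_field(n=30))
        dots = _dots(_spread_positions(5), "cy5")
        out = apply_correction(dots, model)
        assert [(d.x, d.y, d.z) for d in out] == \
            [(d.x, d.y, d.z) for d in dots]

    def test_inverse_consistency(self):
        # dots displaced by the model's own field come back to truth
        pairs = _pairs_from_field(n=50)
        model = fit_aberration(pairs)
        corrected = apply_correction([o for _, o in pairs], model)
        for (r, _), c in zip(pairs, corrected):
            assert c.x == pytest.approx(r.x, abs=1e-9)
            assert c.y == pytest.approx(r.y, abs=1e-9)
            assert c.z == pytest.approx(r.z, abs=1e-9)

    def test_unknown_channel_raises(self):
        model = fit_aberration(_pairs_from_field(n=30))
        with pytest.raises(KeyError):
            apply_correction(_dots([(1, 1, 1)], "tmr"), model)


class TestCorrectionMse:
    def test_identity_displacements_all_zero(self):
        pos = _spread_positions(15)
        pairs = list(zip(_dots(pos, "cy5"), _dots(pos, "a594")))
        model = fit_aberration(pairs)
        assert correction_mse(pairs, model) == (0.0, 0.0, 0.0)

    def test_quadratic_field_reduces_mse(self):
        pairs = _pairs_from_field(n=80, jitter_px=0.05, seed=6)
        model = fit_aberration(pairs)
        before, after2d, after3d = correction_mse(pairs, model)
        assert after3d < before
        assert after2d <= after3d

    def test_pure_noise_leaves_mse_roughly_unchanged(self):
        rng = np.random.default_rng(8)
        pos = _spread_positions(120, seed=8)
        moved = pos + rng.normal(0, 0.5, pos.shape)
        pairs = list(zip(_dots(pos, "cy5"), _dots(moved, "a594")))
        model = fit_aberration(pairs)
        before, _, after = correction_mse(pairs, model)
        assert after <= before  # least-squares optimality
        assert after > 0.8 * before  # nothing systematic to remove

    def test_axial_voxel_shift_equals_200nm(self):
        # a one-plane axial displacement is 200 nm of physical shift
        pos = _spread_positions(20, seed=9)
        moved = pos + np.array([0.0, 0.0, 1.0])
        pairs = list(zip(_dots(pos, "cy5"), _dots(moved, "a594")))
        model = fit_aberration(pairs)
        assert model.dz["a594"] * 200.0 == pytest.approx(200.0, abs=1e-9)


def test_model_serialization_roundtrip(tmp_path):
    model = fit_aberration(_pairs_from_field(n=30))
    path = tmp_path / "model.json"
    model.save(path)
    loaded = AberrationModel.load(path)
    assert np.allclose(loaded.coeff_x["a594"], model.coeff_x["a594"])
    assert loaded.dz["a594"] == model.dz["a594"]
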