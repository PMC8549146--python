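import numpy as np
import pytest
from scipy import ndimage as ndi

import prostacc as pa
from prostacc.core import DeformationField, ScalarVolume, sample_at_voxel_coords, voxel_index_grid
from prostacc.phantom import _invert_displacement


SPACING = (2.0, 2.0, 2.0)


# ------------------------------------------------------------- couch shift


def test_zero_shift_is_identity():
    rng = np.random.default_rng(0)
    vol = ScalarVolume(rng.normal(size=(10, 10, 10)).astype(np.float32), SPACING)
    out = pa.apply_couch_shift(vol, np.zeros(3))
    np.testing.assert_array_equal(out.data, vol.data)


def test_one_voxel_shift_matches_index_oracle():
    rng = np.random.default_rng(1)
    vol = ScalarVolume(rng.normal(size=(10, 10, 10)).astype(np.float32), SPACING)
    out = pa.apply_couch_shift(vol, np.array([2.0, 0.0, 0.0]))
    np.testing.assert_allclose(out.data[:-1], vol.data[1:], atol=1e-6)


def test_shift_round_trip_for_integer_voxel_shifts():
    rng = np.random.default_rng(2)
    vol = ScalarVolume(rng.normal(size=(12, 12, 12)).astype(np.float32), SPACING)
    shift = np.array([2.0, -4.0, 2.0])
    back = pa.apply_couch_shift(pa.apply_couch_shift(vol, shift), -shift)
    interior = np.s_[3:-3, 3:-3, 3:-3]
    span = vol.data.max() - vol.data.min()
    assert np.abs(back.data[interior] - vol.data[interior]).max() < 1e-6 * span


def test_couch_shift_matches_simpleitk_oracle():
    sitk = pytest.importorskip("SimpleITK")
    rng = np.random.default_rng(3)
    vol = ScalarVolume(rng.normal(size=(9, 10, 11)).astype(np.float32), SPACING)
    shift = np.array([1.3, -0.7, 2.1])
    ours = pa.apply_couch_shift(vol, shift, fill=0.0)

    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T))  # sitk is (z,y,x)
    img.SetSpacing(SPACING)
    tx = sitk.TranslationTransform(3, tuple(shift))
    res = sitk.Resample(img, img, tx, sitk.sitkLinear, 0.0)
    oracle = sitk.GetArrayFromImage(res).T
    # edge semantics differ between the libraries; compare in-domain voxels
    idx = np.indices(vol.shape).astype(float)
    valid = np.ones(vol.shape, dtype=bool)
    for ax in range(3):
        c = idx[ax] + shift[ax] / SPACING[ax]
        valid &= (c >= 0) & (c <= vol.shape[ax] - 1)
    assert valid.sum() > 200
    np.testing.assert_allclose(ours.data[valid], oracle[valid], atol=1e-4)


def test_non_finite_shift_rejected():
    vol = ScalarVolume(np.zeros((4, 4, 4)), SPACING)
    with pytest.raises(ValueError):
        pa.apply_couch_shift(vol, np.array([np.nan, 0, 0]))
    with pytest.raises(ValueError):
        pa.CouchShift(np.array([np.inf, 0, 0]))


# ----------------------------------------------------------------- demons


@pytest.fixture(scope="module")
def phantom_density(ct_ref_density):
    return ct_ref_density


def _boundary_band(density, body_mask, width_mm=6.0):
    g = sum(np.abs(np.gradient(density.data, axis=a)) for a in range(3))
    edge = g > 0.01
    band = ndi.distance_transform_edt(~edge, sampling=density.spacing) <= width_mm
    return band & body_mask


def _warp_by_known_field(density, disp, spacing):
    u = np.moveaxis(disp, -1, 0).astype(np.float32)
    w = _invert_displacement(u, np.asarray(spacing, dtype=np.float32), n_iter=8)
    coords = voxel_index_grid(density.shape) + w / np.asarray(spacing, dtype=np.float32)[:, None, None, None]
    return density.like(sample_at_voxel_coords(density.data, coords, fill=0.001))


@pytest.fixture(scope="module")
def known_field_case(anatomy, ct_ref_density):
    """Moving image = reference warped by a known ~2 mm smooth field."""
    shape = ct_ref_density.shape
    grids = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    gm = [g * s for g, s in zip(grids, SPACING)]
    c = anatomy.structures.centroid_mm("rectum")
    d2 = sum((gg - ci) ** 2 for gg, ci in zip(gm, c))
    win = np.exp(-d2 / (2 * 25.0**2))
    u = np.zeros((3,) + shape, dtype=np.float32)
    u[1] = (2.0 * win).astype(np.float32)
    u[0] = (0.6 * win).astype(np.float32)
    u *= anatomy.structures["body"][None]
    truth = DeformationField(np.moveaxis(u, 0, -1), SPACING)
    moving = _warp_by_known_field(ct_ref_density, truth.disp, SPACING)
    return truth, moving


def test_identity_registration_returns_near_zero_field(ct_ref_density):
    dvf = pa.deformable_register(ct_ref_density, ct_ref_density.copy())
    assert dvf.magnitude().max() < 0.1 * min(SPACING)


def test_known_field_recovered_within_one_mm_in_boundary_band(
    anatomy, ct_ref_density, known_field_case
):
    truth, moving = known_field_case
    dvf = pa.deformable_register(ct_ref_density, moving)
    band = _boundary_band(ct_ref_density, anatomy.structures["body"])
    q = pa.field_quality(dvf, truth, band)
    assert q["mean_error_mm"] < 1.0
    # and it must beat not registering at all
    zero = DeformationField(np.zeros_like(truth.disp), SPACING)
    assert q["mean_error_mm"] < pa.field_quality(zero, truth, band)["mean_error_mm"]


def test_similarity_improves_where_images_disagree(ct_ref_density, known_field_case):
    truth, moving = known_field_case
    params = pa.RegistrationParams(track_similarity=True)
    dvf = pa.deformable_register(ct_ref_density, moving, params)
    trace = dvf.meta["msd_mismatch_per_level"]
    assert len(trace) == params.levels + 1
    assert all(level <= trace[0] for level in trace[1:])
    assert dvf.meta["msd_mismatch_final"] < dvf.meta["msd_mismatch_initial"]


def test_field_zero_outside_body(ct_ref_density, known_field_case, anatomy):
    truth, moving = known_field_case
    dvf = pa.deformable_register(ct_ref_density, moving)
    outside = ~ndi.binary_dilation(anatomy.structures["body"], iterations=3)
    assert np.abs(dvf.disp[outside]).max() == 0.0


def test_inverse_consistency_smoke(ct_ref_density, known_field_case, anatomy):
    truth, moving = known_field_case
    fwd = pa.deformable_register(ct_ref_density, moving)
    bwd = pa.deformable_register(moving, ct_ref_density)
    band = _boundary_band(ct_ref_density, anatomy.structures["body"])
    residual = pa.compose_fields(bwd, fwd)  # should be ~identity
    res_mag = np.sqrt((residual.disp**2).sum(-1))
    single_err = pa.field_quality(fwd, truth, band)["mean_error_mm"]
    assert res_mag[band].mean() < 2.0 * max(single_err, 0.25)


def test_registration_is_deterministic(ct_ref_density, known_field_case):
    truth, moving = known_field_case
    a = pa.deformable_register(ct_ref_density, moving)
    b = pa.deformable_register(ct_ref_density, moving)
    np.testing.assert_array_equal(a.disp, b.disp)


def test_lattice_mismatch_rejected(ct_ref_density):
    other = ScalarVolume(np.zeros((4, 4, 4)), SPACING)
    with pytest.raises(ValueError):
        pa.deformable_register(ct_ref_density, other)


# ----------------------------------------------------------- field quality


def test_field_quality_trivial_cases():
    shape = (6, 6, 6)
    truth = DeformationField(np.zeros(shape + (3,)), SPACING)
    same = pa.field_quality(truth, truth, np.ones(shape, dtype=bool))
    assert same["mean_error_mm"] == 0.0 and same["min_jacobian"] == pytest.approx(1.0)

    const = np.zeros(shape + (3,))
    const[..., 1] = 3.0
    q = pa.field_quality(
        DeformationField(np.zeros(shape + (3,)), SPACING),
        DeformationField(const, SPACING),
        np.ones(shape, dtype=bool),
    )
    assert q["mean_error_mm"] == pytest.approx(3.0)
    with pytest.raises(ValueError):
        pa.field_quality(
            DeformationField(const, SPACING),
            DeformationField(const, SPACING),
            np.zeros(shape, dtype=bool),
        )
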