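import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi

import prostacc as pa
from prostacc.core import ScalarVolume, StructureSet
from prostacc.planning import MarginSpec, expand_margin, shape_dose_per_fraction


SPACING = (2.0, 2.0, 2.0)


def sphere_mask(shape, center_vox, radius_vox):
    idx = np.indices(shape).astype(float)
    d2 = sum((idx[a] - center_vox[a]) ** 2 for a in range(3))
    return d2 <= radius_vox**2


# ----------------------------------------------------------------- margins


def test_zero_margin_is_identity():
    mask = sphere_mask((24, 24, 24), (12, 12, 12), 5)
    out = expand_margin(mask, MarginSpec(0.0), SPACING)
    np.testing.assert_array_equal(out, mask)


def test_empty_mask_rejected():
    with pytest.raises(ValueError):
        expand_margin(np.zeros((4, 4, 4), dtype=bool), MarginSpec(5.0), SPACING)


def test_isotropic_expansion_matches_distance_transform_oracle():
    mask = sphere_mask((32, 32, 32), (16, 16, 16), 10)
    out = expand_margin(mask, MarginSpec(4.0), SPACING)
    # independent brute-force oracle: Euclidean distance to mask voxels
    pts = np.argwhere(mask) * 2.0
    grid = np.argwhere(np.ones_like(mask)) * 2.0
    # chunk to keep memory modest
    dmin = np.full(grid.shape[0], np.inf)
    for start in range(0, pts.shape[0], 512):
        chunk = pts[start : start + 512]
        d = np.sqrt(((grid[:, None, :] - chunk[None, :, :]) ** 2).sum(-1)).min(1)
        dmin = np.minimum(dmin, d)
    oracle = (dmin <= 4.0 + 1e-9).reshape(mask.shape)
    np.testing.assert_array_equal(out, oracle)


def test_dorsal_override_limits_posterior_growth():
    mask = np.zeros((40, 40, 40), dtype=bool)
    mask[15:25, 15:25, 15:25] = True
    out = expand_margin(mask, MarginSpec(10.0, dorsal_mm=7.0), SPACING)
    ys = np.where(out.any(axis=(0, 2)))[0]
    # anterior edge moves by 10 mm = 5 voxels, posterior by <= 7 mm
    assert ys.min() == 15 - 5
    assert 24 + 3 <= ys.max() <= 24 + 4  # 7 mm at 2 mm spacing, within one voxel
    xs = np.where(out.any(axis=(1, 2)))[0]
    assert xs.min() == 15 - 5 and xs.max() == 24 + 5


# ----------------------------------------------------------------- targets


def test_target_construction_invariants(anatomy, targets):
    st = anatomy.structures
    assert not (targets["PTV_Boost"] & st["rectum"]).any()
    assert not (targets["CTV_P-SV"] & ~targets["CTV_P+SV"]).any()
    assert not (targets["CTV_P+SV"] & ~targets["PTV"]).any()
    assert not (targets["PTV_Boost"] & ~targets["PTV"]).any()
    assert not (targets["PTV_DIL"] & ~st["prostate"]).any()


def test_targets_without_vesicles_degenerate_to_prostate(anatomy):
    st = anatomy.structures.copy()
    st.add("seminal_vesicles", np.zeros(st.shape, dtype=bool))
    targets = pa.build_target_volumes(st)
    np.testing.assert_array_equal(targets["CTV_P-SV"], st["prostate"])
    np.testing.assert_array_equal(targets["CTV_P+SV"], st["prostate"])


def test_missing_structures_rejected(anatomy):
    st = StructureSet({"prostate": anatomy.structures["prostate"]}, SPACING)
    with pytest.raises(ValueError):
        pa.build_target_volumes(st)


# ----------------------------------------------------------------- dose engine


@pytest.fixture(scope="module")
def plan():
    return pa.TreatmentPlan()


def test_fraction_dose_plateaus(ct_ref_density, targets, plan):
    # plateau levels hold away from the penumbra and the rectum-sparing notch
    dose = pa.compute_fraction_dose(ct_ref_density, targets, plan, ct_ref_density)
    boost = targets["PTV_Boost"]
    far_rectum = (
        ndi.distance_transform_edt(~targets["rectum"], sampling=SPACING)
        >= 5 * plan.sparing_sigma_mm
    )
    interior = (ndi.distance_transform_edt(boost, sampling=SPACING) > 4.0) & far_rectum
    assert interior.any()
    np.testing.assert_allclose(dose.data[interior], 2.31, atol=1e-4)

    dist_boost = ndi.distance_transform_edt(~boost, sampling=SPACING)
    far_ptv = targets["PTV"] & (dist_boost >= 5 * plan.penumbra_sigma_mm) & far_rectum
    assert far_ptv.any()
    np.testing.assert_allclose(dose.data[far_ptv], 1.82, atol=1e-3)


def test_rectum_sparing_pulls_wall_dose_to_low_level(ct_ref_density, targets, plan):
    dose = pa.compute_fraction_dose(ct_ref_density, targets, plan, ct_ref_density)
    rectum = targets["rectum"]
    wall = rectum & ndi.binary_dilation(targets["PTV_Boost"])
    assert wall.any()
    # at the boost/rectum interface the dose drops to ~the low dose level
    assert dose.data[wall].max() <= 2.31 * (1 - plan.rectum_sparing) + 0.15
    # and sparing only reduces dose relative to the unspared shape
    unspared = dataclasses.replace(plan, rectum_sparing=0.0)
    ref = pa.compute_fraction_dose(ct_ref_density, targets, unspared, ct_ref_density)
    assert (dose.data <= ref.data + 1e-6).all()


def test_attenuation_identity_when_density_matches(ct_ref_density, targets, plan):
    dose = pa.compute_fraction_dose(ct_ref_density, targets, plan, ct_ref_density)
    shape = shape_dose_per_fraction(targets, plan)
    np.testing.assert_array_equal(dose.data, shape)


def test_upstream_density_increase_reduces_downstream_dose(ct_ref_density, targets, plan):
    denser = ct_ref_density.copy()
    # add material upstream (anterior) of the target on the beam path
    denser.data[:, :20, :] += 0.5
    dose = pa.compute_fraction_dose(denser, targets, plan, ct_ref_density)
    ref = pa.compute_fraction_dose(ct_ref_density, targets, plan, ct_ref_density)
    boost = targets["PTV_Boost"]
    assert (dose.data[boost] < ref.data[boost]).all()


def test_attenuation_ignores_density_downstream_of_voxel(ct_ref_density, targets, plan):
    changed = ct_ref_density.copy()
    changed.data[:, -5:, :] += 1.0  # far posterior: downstream of everything
    dose = pa.compute_fraction_dose(changed, targets, plan, ct_ref_density)
    ref = shape_dose_per_fraction(targets, plan)
    np.testing.assert_allclose(dose.data[:, :-6, :], ref[:, :-6, :], atol=1e-6)


def test_planned_dose_bounds_and_plateau(ct_ref_density, targets, plan):
    planned = pa.compute_planned_dose(ct_ref_density, targets, plan)
    assert planned.data.min() >= 0
    assert planned.data.max() <= 33 * 2.31 + 1e-6
    boost_mean = pa.dose_metric(planned, targets["PTV_Boost"], "DMean")
    assert boost_mean == pytest.approx(76.23, rel=0.01)


def test_penumbra_width_does_not_change_deep_plateau(ct_ref_density, targets):
    narrow = pa.TreatmentPlan(rectum_sparing=0.0)
    wide = dataclasses.replace(narrow, penumbra_sigma_mm=6.0, sparing_sigma_mm=6.0)
    d1 = pa.compute_fraction_dose(ct_ref_density, targets, narrow, ct_ref_density)
    d2 = pa.compute_fraction_dose(ct_ref_density, targets, wide, ct_ref_density)
    deep = ndi.distance_transform_edt(targets["PTV_Boost"], sampling=SPACING) > 6.0
    np.testing.assert_allclose(d1.data[deep], d2.data[deep], atol=1e-6)


def test_dose_monotone_decay_outside_target_along_ray(ct_ref_density, targets):
    # pure shape function (no attenuation, no rectum notch)
    plan = pa.TreatmentPlan(attenuation_mu_per_mm=0.0, rectum_sparing=0.0)
    dose = pa.compute_fraction_dose(ct_ref_density, targets, plan, ct_ref_density)
    # walk posterior from the PTV's posterior edge at the boost center line
    boost_idx = np.argwhere(targets["PTV_Boost"])
    i, k = int(np.median(boost_idx[:, 0])), int(np.median(boost_idx[:, 2]))
    ys = np.where(targets["PTV"][i, :, k])[0]
    ray = dose.data[i, ys.max() :, k]
    assert (np.diff(ray) <= 1e-9).all()


def test_invalid_plans_rejected():
    with pytest.raises(ValueError):
        pa.TreatmentPlan(dose_low_gy=2.5)  # low >= boost
    with pytest.raises(ValueError):
        pa.TreatmentPlan(n_fractions=0)
    with pytest.raises(ValueError):
        pa.TreatmentPlan(penumbra_sigma_mm=0.0)
    with pytest.raises(ValueError):
        pa.TreatmentPlan(rectum_sparing=1.5)
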