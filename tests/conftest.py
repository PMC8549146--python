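import numpy as np
import pytest

import prostacc as pa
from prostacc.density import apply_density_override


def identity_phantom_config(**overrides) -> pa.PhantomConfig:
    """Config with every degradation switched off (motion/noise/shift-free)."""
    kwargs = dict(
        fill_scale_sd=0.0,
        prostate_drift_sd_mm=0.0,
        rectum_prostate_coupling=0.0,
        couch_shift_sd_mm=(0.0, 0.0, 0.0),
        cbct_noise_sd_hu=0.0,
        bias_amplitude_hu=0.0,
    )
    kwargs.update(overrides)
    return pa.PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def default_config():
    return pa.PhantomConfig()


@pytest.fixture(scope="session")
def anatomy(default_config):
    return pa.build_reference_anatomy(default_config)


@pytest.fixture(scope="session")
def targets(anatomy):
    return pa.build_target_volumes(anatomy.structures)


@pytest.fixture(scope="session")
def ct_ref_density(anatomy):
    return apply_density_override(anatomy.hu)


@pytest.fixture(scope="session")
def identity_sim():
    """One patient simulated under identity conditions (33 fractions)."""
    cohort = pa.generate_cohort(
        1, identity_phantom_config(), seed=5, anatomical_jitter=False
    )
    return cohort[0]


@pytest.fixture(scope="session")
def identity_run(identity_sim):
    """Planned dose and full accumulation for the identity patient."""
    plan = pa.TreatmentPlan()
    targets = pa.build_target_volumes(identity_sim.anatomy.structures)
    dref = apply_density_override(identity_sim.anatomy.hu)
    planned = pa.compute_planned_dose(dref, targets, plan)
    acc = pa.accumulate_course(
        identity_sim.anatomy, identity_sim.scenarios, plan, targets=targets
    )
    return {
        "sim": identity_sim,
        "plan": plan,
        "targets": targets,
        "planned": planned,
        "accumulated": acc,
    }


@pytest.fixture(scope="session")
def cohort_result():
    """Full 10-patient synthetic study (33-fraction courses, default motion)."""
    return pa.run_cohort(10, seed=0)
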