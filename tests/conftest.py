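import numpy as np
import pytest

from bvselect.cohort import (CohortSpec, ProtocolSpec, generate_cohort,
                             standard_protocol)
from bvselect.models import FluidProtocol, ModelParameters


@pytest.fixture
def original_params() -> ModelParameters:
    return ModelParameters("original", alpha_u=1.72, alpha_v=1.06,
                           Kp=0.08, Ki=0.003)


@pytest.fixture
def refined_params() -> ModelParameters:
    return ModelParameters("refined", alpha_u=0.20, alpha_v=0.60,
                           Kp=0.28, Ki=0.01, A_u=-0.16, A_v=-0.007)


@pytest.fixture
def fixed_protocol() -> FluidProtocol:
    """Standard 180-min protocol with a fixed (open-loop) infusion table."""
    spec = ProtocolSpec()
    time = np.round(np.arange(0.0, spec.duration + spec.dt / 2, spec.dt), 9)
    infusion = np.where((time >= 30) & (time < 180), 25.0, 0.0)
    return standard_protocol(40.0, spec, infusion_profile=infusion)


def random_params(variant: str, rng: np.random.Generator) -> ModelParameters:
    """A random valid parameter set, roughly spanning the cohort ranges."""
    return ModelParameters(
        variant,
        alpha_u=rng.uniform(-0.5, 3.0),
        alpha_v=rng.uniform(-0.5, 3.0),
        Kp=rng.uniform(0.02, 0.5),
        Ki=rng.uniform(0.001, 0.03),
        A_u=0.0 if variant == "original" else -rng.uniform(0.0, 0.4),
        A_v=0.0 if variant == "original" else -rng.uniform(0.0, 0.03),
    )


@pytest.fixture
def small_cohort():
    """Six noisy refined-model subjects (3 LR + 3 HEX), deterministic."""
    spec = CohortSpec(n_lr=3, n_hex=3, variant="refined", noise_sd=50.0, seed=101)
    subjects, manifest = generate_cohort(spec)
    return subjects, manifest


@pytest.fixture
def noisefree_subject():
    """One noise-free refined-model subject with known generating truth."""
    spec = CohortSpec(n_lr=1, n_hex=0, variant="refined", noise_sd=0.0, seed=5)
    subjects, _ = generate_cohort(spec)
    return subjects[0]
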