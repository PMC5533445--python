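import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helix_ensemble():
    """Rigid 12-residue ideal alpha helix, one model."""
    from bboxnmr.synthetic_data import EnsembleRecipe, gen_ensemble
    return gen_ensemble(EnsembleRecipe(topology="helix", length=12))


@pytest.fixture(scope="session")
def hairpin_ensemble():
    """Ideal antiparallel two-strand hairpin (7 residues per strand)."""
    from bboxnmr.synthetic_data import EnsembleRecipe, gen_ensemble
    return gen_ensemble(EnsembleRecipe(topology="hairpin", length=14))


@pytest.fixture(scope="session")
def jittered_helix_tail():
    """10-model helix+tail ensemble: rigid core, floppy 4-residue tail."""
    from bboxnmr.synthetic_data import EnsembleRecipe, gen_ensemble
    return gen_ensemble(EnsembleRecipe(topology="helix+tail", length=16,
                                       core_sigma=0.3, tail_sigma=3.0,
                                       n_models=10, seed=7))


def random_rotation(rng):
    """Uniform proper rotation matrix (for rigid-motion invariance tests)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
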