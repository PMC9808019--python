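import numpy as np
import pytest

from duomil import SynthConfig, generate_dataset
from duomil.stain import REFERENCE_PROFILE, od_to_rgb
from duomil.synth import _rotation_matrix


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-class synthetic cohort shared across module tests."""
    cfg = SynthConfig(n_normal=4, n_positive=4, n_cases=4, n_sources=2,
                      slide_size=1024, seed=42)
    return cfg, generate_dataset(cfg)


def render_from_concentrations(conc: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Beer–Lambert rendering used as a construction oracle in stain tests."""
    od = conc @ matrix.T
    return od_to_rgb(od)


def perturbed_stain_matrix(rng: np.random.Generator,
                           max_angle_deg: float = 15.0) -> np.ndarray:
    """Randomly rotate the reference stain basis by up to ``max_angle_deg``."""
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    rot = _rotation_matrix(rng.standard_normal(3), angle)
    m = np.clip(rot @ REFERENCE_PROFILE.stain_matrix, 0.0, None)
    return m / np.linalg.norm(m, axis=0, keepdims=True)


def angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))
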