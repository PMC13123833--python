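import numpy as np
import pytest

from knotsol.synthetic import SolenoidSpec, make_ideal_solenoid


def torus_curve(p: int, q: int, n: int = 120, big: float = 10.0,
                small: float = 4.0) -> np.ndarray:
    """Closed (p, q) torus curve; the (2, 3) case is the right-handed
    trefoil (Gauss writhe ~ +3.3)."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    radial = big + small * np.cos(q * th)
    return np.column_stack([
        radial * np.cos(p * th),
        radial * np.sin(p * th),
        small * np.sin(q * th),
    ])


@pytest.fixture(scope="session")
def regular_solenoid():
    return make_ideal_solenoid(SolenoidSpec(n_coils=4, residues_per_side=6, seed=1))


@pytest.fixture(scope="session")
def knotted_solenoid():
    return make_ideal_solenoid(
        SolenoidSpec(n_coils=4, residues_per_side=6, skip_and_backtrack=True, seed=1))


@pytest.fixture(scope="session")
def small_knotted_solenoid():
    """Reduced knotted solenoid used by the folding tests."""
    return make_ideal_solenoid(
        SolenoidSpec(n_coils=4, residues_per_side=4, skip_and_backtrack=True,
                     linker_length=15, cterm_thread_length=10, seed=1))
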