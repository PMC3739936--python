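import warnings

import numpy as np
import pytest

from helixgeom import (
    AnalyticHelixSpec,
    HelixTrace,
    fit_polynomial_curve,
    make_circular_helix,
    realistic_helix_spec,
)


def quiet_trace(label, residue_ids, points, b_factors=None):
    """Build a HelixTrace suppressing the consecutive-distance warning
    (analytic fixtures are free to leave the protein-like range)."""
    points = np.asarray(points, dtype=float)
    if b_factors is None:
        b_factors = np.full(len(points), 20.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return HelixTrace(label, list(residue_ids), points, np.asarray(b_factors, float))


@pytest.fixture
def helix_345():
    """Noiseless circular helix r=3, c=4 nm: kappa=0.12, tau=0.16 nm^-1."""
    spec = AnalyticHelixSpec(radius=3.0, pitch_rate=4.0, turns=3.5, points_per_turn=10)
    trace, kappa, tau = make_circular_helix(spec)
    return trace, kappa, tau


@pytest.fixture
def helix_345_curve(helix_345):
    trace, kappa, tau = helix_345
    curve = fit_polynomial_curve(trace, max_degree=trace.n_res - 2)
    return curve, trace, kappa, tau


@pytest.fixture
def realistic_pair(tmp_path):
    """Two alpha-helix-like traces 1.8 nm apart, as for a toy groove."""
    tr_a, _, _ = make_circular_helix(realistic_helix_spec(turns=35 / 3.6, seed=11))
    tr_b, _, _ = make_circular_helix(realistic_helix_spec(turns=35 / 3.6, seed=12))
    tr_b = quiet_trace("B", tr_b.residue_ids, tr_b.points + np.array([1.8, 0.0, 0.0]),
                       tr_b.b_factors)
    return tr_a, tr_b


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1))).as_matrix()
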