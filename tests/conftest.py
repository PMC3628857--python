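import numpy as np
import pytest

import idenet as I


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


@pytest.fixture(scope="session")
def truth_20():
    """20-bead heterogeneous truth network (no tail), moderate stiffness."""
    spec = I.FixtureSpec(n_core=20, n_tail=0, K_core_range=(50, 500), seed=3)
    struct, net = I.make_truth_system(spec)
    return struct, net


@pytest.fixture(scope="session")
def stiff_truth_20():
    """Stiff 20-bead truth network: fluctuations well below bond lengths,
    the regime where the linearised distance variance is accurate."""
    spec = I.FixtureSpec(n_core=20, n_tail=0, K_core_range=(3000, 12000), seed=3)
    struct, net = I.make_truth_system(spec)
    return struct, net


@pytest.fixture(scope="session")
def core_tail_system():
    """Core+tail truth system whose tail hugs the core in the reference
    conformation but fluctuates almost independently of it."""
    spec = I.FixtureSpec(n_core=20, n_tail=6, seed=5)
    struct, net = I.make_truth_system(spec)
    return struct, net


@pytest.fixture(scope="session")
def gaussian_ensemble_10x20(truth_20):
    """Small (10-frame) Gaussian ensemble on the 20-bead truth network."""
    _, net = truth_20
    model = I.HarmonicModel(net, 300.0)
    return I.sample_ensemble(model, 10, seed=42)


@pytest.fixture(scope="session")
def langevin_bond_variances(stiff_truth_20):
    """Overdamped-trajectory bond variances on the stiff truth network at
    50 K, with blocked standard errors (the expensive shared computation)."""
    _, net = stiff_truth_20
    model = I.HarmonicModel(net, 50.0)
    ens = I.langevin_dynamics(
        model, n_steps=1_200_000, dt=2e-6, friction=1.0, seed=11, stride=60
    )
    skip = ens.n_frames // 10
    d = np.linalg.norm(
        ens.frames[skip:, net.bond_j] - ens.frames[skip:, net.bond_i], axis=2
    )

    def block_se(nb):
        F = d.shape[0] - d.shape[0] % nb
        bv = d[:F].reshape(nb, -1, d.shape[1]).var(axis=1)
        return bv.std(axis=0, ddof=1) / np.sqrt(nb)

    return d.var(axis=0), np.maximum(block_se(10), block_se(20))


@pytest.fixture(scope="session")
def toy_shell():
    """42-bead spherical shell, radius 2 nm, uniform K = 300."""
    struct, net = I.make_toy_capsid(radius=2.0, n_beads=42, K=300.0, seed=1)
    return struct, net
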