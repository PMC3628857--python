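"""Harmonic evaluation and dynamics of elastic networks.

For a pure bead-spring network with energy ``E = sum_b K_b/2 (d_b - r0_b)^2``
the equilibrium fluctuations follow from the anisotropic-network Hessian H
(3N x 3N, one ``K e e^T`` super-element per bond, with e the unit bond vector
at the reference geometry): the coordinate covariance is ``C = kB T H^+``
with the pseudo-inverse taken over the 6 rigid-body zero modes, and the
linearised distance variance of a pair is ``Var(d_ij) ~= e^T (C_ii + C_jj -
C_ij - C_ji) e``.

Three routes to per-bond distance variances are provided, all satisfying the
same evaluator contract (callable: ElasticNetwork -> per-bond nm^2 array):

* :class:`AnalyticEvaluator` — the closed-form result above (fast, exact for
  harmonic systems to first order in fluctuation/r0);
* :class:`LangevinEvaluator` — overdamped (positions-only) Langevin dynamics,
  needed once anharmonic add-ons (walls, excluded volume) enter;
* :class:`EnsembleEvaluator` — measured variances of an externally produced
  ensemble, the hook for coupling the refinement loop to a real CG engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph as csgraph
from scipy.sparse import coo_matrix

from .networks import ElasticNetwork
from .structures import Ensemble

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.008314462

#: Relative eigenvalue tolerance separating rigid-body modes from real ones.
ZERO_MODE_RTOL = 1e-8


class EngineError(RuntimeError):
    pass


@dataclass
class HarmonicModel:
    """An elastic network at a temperature (K)."""

    network: ElasticNetwork
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise EngineError("temperature must be non-negative")

    @property
    def kBT(self) -> float:
        return KB * self.temperature


@dataclass
class FluctuationPrediction:
    coord_covariance: np.ndarray  # (3N, 3N) nm^2
    pair_distance_variance: np.ndarray  # per-bond nm^2
    per_bead_rmsf: np.ndarray  # (N,) nm


def _bond_geometry(net: ElasticNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Current bond lengths and unit vectors at the reference coordinates."""
    rij = net.topology.positions[net.bond_j] - net.topology.positions[net.bond_i]
    d = np.linalg.norm(rij, axis=1)
    if np.any(d < 1e-12):
        k = int(np.argmin(d))
        raise EngineError(
            f"bonded beads {net.bond_i[k]}-{net.bond_j[k]} coincide"
        )
    return d, rij / d[:, None]


def assemble_hessian(model: HarmonicModel | ElasticNetwork) -> np.ndarray:
    """Anisotropic-network Hessian at the reference geometry, (3N, 3N).

    Each bond contributes ``K e e^T`` on the (i,i) and (j,j) diagonal blocks
    and ``-K e e^T`` on the (i,j)/(j,i) blocks; row sums vanish (translation
    invariance).
    """
    net = model.network if isinstance(model, HarmonicModel) else model
    if net.n_beads < 2:
        raise EngineError("need at least 2 beads")
    n = net.n_beads
    _, e = _bond_geometry(net)
    H = np.zeros((3 * n, 3 * n))
    blocks = net.K[:, None, None] * np.einsum("bi,bj->bij", e, e)
    for b in range(net.n_bonds):
        i, j = net.bond_i[b], net.bond_j[b]
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[si, si] += blocks[b]
        H[sj, sj] += blocks[b]
        H[si, sj] -= blocks[b]
        H[sj, si] -= blocks[b]
    return H


def bond_hessian(net: ElasticNetwork, coords: np.ndarray) -> np.ndarray:
    """Exact second derivatives of the bond energy at arbitrary *coords*.

    Unlike :func:`assemble_hessian` (the reference-geometry ANM form, where
    every bond sits at its rest length) this keeps the transverse
    ``K (d - r0)/d (I - e e^T)`` term that appears once bonds are strained,
    e.g. in a deformed minimum under external load.
    """
    n = net.n_beads
    rij = coords[net.bond_j] - coords[net.bond_i]
    d = np.linalg.norm(rij, axis=1)
    if np.any(d < 1e-12):
        raise EngineError("coincident bonded beads")
    e = rij / d[:, None]
    eet = np.einsum("bi,bj->bij", e, e)
    trans = (net.K * (d - net.r0) / d)[:, None, None] * (np.eye(3)[None] - eet)
    blocks = net.K[:, None, None] * eet + trans
    H = np.zeros((3 * n, 3 * n))
    for b in range(net.n_bonds):
        i, j = net.bond_i[b], net.bond_j[b]
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[si, si] += blocks[b]
        H[sj, sj] += blocks[b]
        H[si, sj] -= blocks[b]
        H[sj, si] -= blocks[b]
    return H


def _connected_components(net: ElasticNetwork) -> tuple[int, np.ndarray]:
    n = net.n_beads
    data = np.ones(net.n_bonds)
    adj = coo_matrix((data, (net.bond_i, net.bond_j)), shape=(n, n))
    return csgraph.connected_components(adj, directed=False)[:2]


def rigid_mode_count(positions: np.ndarray) -> int:
    """Number of rigid-body zero modes: 6 in general, 5 for collinear
    geometries (rotation about the axis is trivial), 3 for a single point."""
    centered = positions - positions.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    rank = int(np.sum(s > 1e-9 * max(s[0], 1.0)))
    return {0: 3, 1: 5}.get(rank, 6)


def equilibrium_covariance(model: HarmonicModel) -> np.ndarray:
    """Coordinate covariance ``C = kB T H^+`` (nm^2).

    Requires the network to be mechanically rigid: exactly as many zero
    Hessian modes as rigid-body motions (6 for a 3D geometry).  More zero
    modes mean the network is floppy or disconnected, and no equilibrium
    covariance exists.
    """
    H = assemble_hessian(model)
    w, V = scipy.linalg.eigh(H)
    tol = ZERO_MODE_RTOL * max(w[-1], 1.0)
    n_zero = int(np.sum(np.abs(w) <= tol))
    n_rigid = rigid_mode_count(model.network.topology.positions)
    if n_zero != n_rigid:
        ncomp, labels = _connected_components(model.network)
        if ncomp > 1:
            smallest = int(np.argmin(np.bincount(labels)))
            members = np.flatnonzero(labels == smallest)
            raise EngineError(
                f"network is disconnected ({ncomp} components; e.g. beads "
                f"{members.tolist()[:8]} form a separate component)"
            )
        raise EngineError(
            f"expected {n_rigid} zero modes, found {n_zero}: network is "
            + ("floppy (internal mechanism)" if n_zero > n_rigid else "over-constrained?")
        )
    inv = np.zeros_like(w)
    nonzero = np.abs(w) > tol
    inv[nonzero] = 1.0 / w[nonzero]
    return model.kBT * (V * inv) @ V.T


def predicted_distance_variance(
    model: HarmonicModel,
    coord_covariance: np.ndarray | None = None,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Linearised distance variance per pair (default: per bond), nm^2.

    First order in fluctuation amplitude over separation:
    ``Var(d_ij) ~= e^T (C_ii + C_jj - C_ij - C_ji) e``.
    """
    C = coord_covariance if coord_covariance is not None else equilibrium_covariance(model)
    net = model.network
    if pairs is None:
        pi, pj = net.bond_i, net.bond_j
    else:
        pi = np.array([p[0] for p in pairs], int)
        pj = np.array([p[1] for p in pairs], int)
    rij = net.topology.positions[pj] - net.topology.positions[pi]
    e = rij / np.linalg.norm(rij, axis=1)[:, None]
    out = np.empty(len(pi))
    for b, (i, j) in enumerate(zip(pi, pj)):
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        block = C[si, si] + C[sj, sj] - C[si, sj] - C[sj, si]
        out[b] = e[b] @ block @ e[b]
    return out


def per_bead_rmsf(coord_covariance: np.ndarray) -> np.ndarray:
    """RMSF_i = sqrt(trace of the (i,i) 3x3 covariance block), nm."""
    n = coord_covariance.shape[0] // 3
    diag = np.diag(coord_covariance).reshape(n, 3)
    return np.sqrt(diag.sum(axis=1))


def predict_fluctuations(model: HarmonicModel) -> FluctuationPrediction:
    C = equilibrium_covariance(model)
    return FluctuationPrediction(
        coord_covariance=C,
        pair_distance_variance=predicted_distance_variance(model, C),
        per_bead_rmsf=per_bead_rmsf(C),
    )


def sample_ensemble(
    model: HarmonicModel,
    n_frames: int,
    seed: int,
    coord_covariance: np.ndarray | None = None,
) -> Ensemble:
    """Exact Gaussian sample from the harmonic equilibrium distribution.

    Mean = reference coordinates, covariance = ``kB T H^+`` (the 6 rigid-body
    modes carry zero weight, so samples stay superposed on the reference).
    """
    if n_frames < 2:
        raise EngineError("need at least 2 frames")
    C = coord_covariance if coord_covariance is not None else equilibrium_covariance(model)
    w, V = scipy.linalg.eigh(C)
    w = np.clip(w, 0.0, None)  # rounding can leave tiny negatives
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, C.shape[0]))
    disp = z @ (V * np.sqrt(w)).T
    frames = model.network.topology.positions[None] + disp.reshape(
        n_frames, -1, 3
    )
    return Ensemble(model.network.topology, frames)


# --------------------------------------------------------------------------- #
# overdamped Langevin dynamics
# --------------------------------------------------------------------------- #

class ExtraPotential(Protocol):
    """Anharmonic add-on for the Langevin engine (walls, excluded volume...)."""

    def energy(self, positions: np.ndarray) -> float: ...
    def forces(self, positions: np.ndarray) -> np.ndarray: ...


def bond_forces(net: ElasticNetwork, positions: np.ndarray) -> np.ndarray:
    """Forces of the harmonic bonds at *positions*, kJ mol^-1 nm^-1."""
    rij = positions[net.bond_j] - positions[net.bond_i]
    d = np.linalg.norm(rij, axis=1)
    d = np.maximum(d, 1e-12)
    fpair = (net.K * (d - net.r0) / d)[:, None] * rij  # on bead i, toward j
    F = np.zeros_like(positions)
    np.add.at(F, net.bond_i, fpair)
    np.add.at(F, net.bond_j, -fpair)
    return F


def bond_energy(net: ElasticNetwork, positions: np.ndarray) -> float:
    rij = positions[net.bond_j] - positions[net.bond_i]
    d = np.linalg.norm(rij, axis=1)
    return float(0.5 * np.sum(net.K * (d - net.r0) ** 2))


def langevin_dynamics(
    model: HarmonicModel,
    extra_potentials: Sequence[ExtraPotential] = (),
    n_steps: int = 10000,
    dt: float = 0.002,  # ps
    friction: float = 1.0,  # ps^-1
    seed: int = 0,
    stride: int = 10,
    initial_positions: np.ndarray | None = None,
    force_monitor: Callable[[int, np.ndarray], None] | None = None,
) -> Ensemble:
    """Overdamped (Brownian) dynamics of the network plus add-on potentials.

    Position-only update with unit mass in the Leimkuhler-Matthews form,
    ``x += F dt / friction + sqrt(2 kB T dt / friction) (xi_n + xi_{n+1})/2``
    (successive-noise averaging), which satisfies fluctuation-dissipation at
    the model temperature and samples configurations with O(dt^2) accuracy —
    plain Euler-Maruyama would inflate every mode variance by lambda*dt/(2*
    friction).  Stability for the stiffest part of the network requires
    ``lambda_max dt / friction < 2``; enforced through the Gershgorin bound
    ``lambda_max <= 2 max_i sum_b K_ib`` with a factor-2 margin.  Frames are
    recorded every *stride* steps.
    """
    net = model.network
    if n_steps < 1 or stride < 1:
        raise EngineError("n_steps and stride must be positive")
    if net.n_bonds:
        per_bead = np.zeros(net.n_beads)
        np.add.at(per_bead, net.bond_i, net.K)
        np.add.at(per_bead, net.bond_j, net.K)
        lam_bound = 2.0 * per_bead.max()
        if lam_bound * dt / friction > 1.0:
            raise EngineError(
                f"dt={dt} ps unstable for the stiffest bead (bonded stiffness "
                f"sum {per_bead.max():.3g}) at friction {friction}; need "
                f"dt <= {friction / lam_bound:.3g} ps"
            )
    rng = np.random.default_rng(seed)
    x = np.array(
        initial_positions if initial_positions is not None else net.topology.positions,
        dtype=float,
    )
    mobility = dt / friction
    noise_amp = np.sqrt(2.0 * model.kBT * dt / friction)
    xi_prev = rng.standard_normal(x.shape)
    frames = []
    for step in range(1, n_steps + 1):
        F = bond_forces(net, x)
        for pot in extra_potentials:
            F = F + pot.forces(x)
        xi = rng.standard_normal(x.shape)
        x = x + mobility * F + noise_amp * 0.5 * (xi_prev + xi)
        xi_prev = xi
        if np.any(np.abs(x) > 1e4):
            raise EngineError(
                f"trajectory diverged at step {step}; use a smaller dt"
            )
        if step % stride == 0:
            if force_monitor is not None:
                force_monitor(step, x)
            frames.append(x.copy())
    if not frames:
        frames.append(x.copy())
    return Ensemble(net.topology, np.array(frames))


# --------------------------------------------------------------------------- #
# fluctuation-evaluator contract
# --------------------------------------------------------------------------- #

class AnalyticEvaluator:
    """Per-bond distance variances from the Hessian pseudo-inverse."""

    def __init__(self, temperature: float = 300.0):
        self.temperature = temperature

    def __call__(self, net: ElasticNetwork) -> np.ndarray:
        model = HarmonicModel(net, self.temperature)
        return predicted_distance_variance(model)


class LangevinEvaluator:
    """Per-bond distance variances measured from an overdamped trajectory.

    With ``common_random_numbers=True`` the same seed is reused on every call
    (variance reduction across refinement iterations); default off.
    """

    def __init__(
        self,
        temperature: float = 300.0,
        n_steps: int = 200_000,
        dt: float = 5e-4,
        friction: float = 1.0,
        stride: int = 20,
        equilibration_fraction: float = 0.1,
        seed: int = 0,
        common_random_numbers: bool = False,
    ):
        self.temperature = temperature
        self.n_steps = n_steps
        self.dt = dt
        self.friction = friction
        self.stride = stride
        self.equilibration_fraction = equilibration_fraction
        self.seed = seed
        self.common_random_numbers = common_random_numbers
        self._calls = 0

    def __call__(self, net: ElasticNetwork) -> np.ndarray:
        seed = self.seed if self.common_random_numbers else self.seed + self._calls
        self._calls += 1
        model = HarmonicModel(net, self.temperature)
        ens = langevin_dynamics(
            model, n_steps=self.n_steps, dt=self.dt,
            friction=self.friction, seed=seed, stride=self.stride,
        )
        skip = int(self.equilibration_fraction * ens.n_frames)
        frames = ens.frames[skip:]
        rij = frames[:, net.bond_j] - frames[:, net.bond_i]
        d = np.linalg.norm(rij, axis=2)
        return d.var(axis=0)


class EnsembleEvaluator:
    """Per-bond distance variances observed in a fixed external ensemble.

    The adapter for plugging in a real CG-engine trajectory: refinement sees
    the variances this ensemble exhibits for the network's bond pairs.
    """

    def __init__(self, ensemble: Ensemble):
        self.ensemble = ensemble

    def __call__(self, net: ElasticNetwork) -> np.ndarray:
        rij = (
            self.ensemble.frames[:, net.bond_j]
            - self.ensemble.frames[:, net.bond_i]
        )
        d = np.linalg.norm(rij, axis=2)
        return d.var(axis=0)
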