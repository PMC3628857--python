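"""Two-wall indentation of bead-spring systems.

The protocol mimics plate-compression nanoindentation: two flat repulsive
walls normal to one axis squeeze the system, the wall separation L is reduced
stepwise (e.g. 29 nm -> 20 nm in 0.04 nm steps), the system relaxes under
overdamped Langevin dynamics for a fixed time at each separation while the
walls are held, and the force the beads exert on a wall is averaged per step.
Expanding the walls again from the compressed state gives the relaxation
branch; the area between the forward and backward force-separation curves is
the hysteresis (dissipated work).

Walls carry a 10-4 potential, U(h) = eps*[(2/5)(sigma/h)^10 - (sigma/h)^4],
truncated at its minimum h = sigma and shifted up by 3*eps/5, so it is purely
repulsive and exactly zero beyond one sigma.  Walls act on the protein beads
only; there is no solvent in this engine, so "semi-permeable" is a statement
about what the walls ignore, not a separate mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .engine import (
    EngineError,
    HarmonicModel,
    bond_energy,
    bond_forces,
    bond_hessian,
    langevin_dynamics,
)
from .networks import ElasticNetwork

_AXIS = {"x": 0, "y": 1, "z": 2}


class IndentationError(RuntimeError):
    pass


def wall_force(
    h: float | np.ndarray, epsilon: float = 1.0, sigma: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Energy and repulsive force of the truncated-shifted 10-4 wall.

    *h* is the bead-wall distance (nm, must be positive).  Returns
    ``(U, f)`` with ``f = -dU/dh`` directed away from the wall; both vanish
    for h >= sigma, and f(sigma) = 0 exactly (the cut sits at the minimum).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise IndentationError("bead at or behind a wall (h <= 0)")
    s4 = (sigma / h) ** 4
    s10 = (sigma / h) ** 10
    U = np.where(h < sigma, epsilon * (0.4 * s10 - s4) + 0.6 * epsilon, 0.0)
    f = np.where(h < sigma, 4.0 * epsilon * (s10 / h - s4 / h), 0.0)
    return U, f


def _softened_wall(
    h: np.ndarray, epsilon: float, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Wall energy/force with a linear continuation below h = sigma/4.

    The continuation keeps energies and forces defined for any h (including
    behind the wall), which minimiser line searches and unlucky noise kicks
    can probe transiently; the continued branch still repels strongly, so
    equilibrium states never live there and the physics is unchanged.
    """
    h = np.asarray(h, dtype=float)
    h_min = 0.25 * sigma
    hc = np.maximum(h, h_min)
    U, f = wall_force(hc, epsilon, sigma)
    below = h < h_min
    if np.any(below):
        U0, f0 = wall_force(np.array(h_min), epsilon, sigma)
        U = np.where(below, U0 + f0 * (h_min - h), U)
        f = np.where(below, f0, f)
    return U, f


def _wall_curvature(h: np.ndarray, epsilon: float, sigma: float) -> np.ndarray:
    """d2U/dh2 of the wall potential (zero beyond sigma)."""
    s4 = (sigma / h) ** 4
    s10 = (sigma / h) ** 10
    return np.where(h < sigma, epsilon * (44.0 * s10 - 20.0 * s4) / h**2, 0.0)


@dataclass
class WallPair:
    """Two parallel repulsive walls normal to *axis*, *separation* nm apart.

    The pair is centred at coordinate *center* along the axis; walls sit at
    center -/+ separation/2.
    """

    axis: str = "z"
    separation: float = 10.0
    center: float = 0.0
    epsilon: float = 1.0  # kJ mol^-1
    sigma: float = 0.5  # nm

    def __post_init__(self) -> None:
        if self.axis not in _AXIS:
            raise IndentationError(f"axis must be x, y or z, not {self.axis!r}")
        if self.separation <= 0 or self.epsilon <= 0 or self.sigma <= 0:
            raise IndentationError("separation, epsilon and sigma must be positive")

    @property
    def positions(self) -> tuple[float, float]:
        half = 0.5 * self.separation
        return self.center - half, self.center + half

    def _distances(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = coords[:, _AXIS[self.axis]]
        left, right = self.positions
        return z - left, right - z

    def energy(self, coords: np.ndarray) -> float:
        hl, hr = self._distances(coords)
        return float(
            _softened_wall(hl, self.epsilon, self.sigma)[0].sum()
            + _softened_wall(hr, self.epsilon, self.sigma)[0].sum()
        )

    def forces(self, coords: np.ndarray) -> np.ndarray:
        hl, hr = self._distances(coords)
        _, fl = _softened_wall(hl, self.epsilon, self.sigma)
        _, fr = _softened_wall(hr, self.epsilon, self.sigma)
        F = np.zeros_like(coords)
        F[:, _AXIS[self.axis]] = fl - fr  # left wall pushes +, right wall -
        return F

    def wall_load(self, coords: np.ndarray) -> tuple[float, float]:
        """Total force the beads exert on (left, right) wall, kJ mol^-1 nm^-1."""
        hl, hr = self._distances(coords)
        _, fl = _softened_wall(hl, self.epsilon, self.sigma)
        _, fr = _softened_wall(hr, self.epsilon, self.sigma)
        return float(fl.sum()), float(fr.sum())


@dataclass
class IndentationTrace:
    """Per-separation force statistics of one schedule direction."""

    L: np.ndarray  # nm
    mean_force: np.ndarray  # kJ mol^-1 nm^-1, load on the reported wall
    force_sd: np.ndarray
    frames_used: np.ndarray
    direction: str  # 'forward' (compression) or 'backward' (relaxation)

    def __post_init__(self) -> None:
        dL = np.diff(self.L)
        if self.direction == "forward" and np.any(dL >= 0):
            raise IndentationError("forward trace must have strictly decreasing L")
        if self.direction == "backward" and np.any(dL <= 0):
            raise IndentationError("backward trace must have strictly increasing L")
        if not np.all(np.isfinite(self.mean_force)):
            raise IndentationError("non-finite forces in trace")


def make_schedule(start: float, end: float, step: float) -> np.ndarray:
    """Inclusive arithmetic separation schedule from *start* to *end* (nm).

    *step* is the unsigned increment; (start - end) must be an integer
    multiple of it (to 1e-9).  The canonical compression run is
    29 -> 20 nm at 0.04 nm (226 separations).
    """
    if step <= 0:
        raise IndentationError("step must be positive")
    if start == end:
        raise IndentationError("start and end coincide")
    span = abs(start - end)
    n = span / step
    if abs(n - round(n)) > 1e-9 * max(1.0, n):
        raise IndentationError(
            f"span {span} nm is not an integer multiple of step {step} nm"
        )
    n = int(round(n))
    sched = start + np.sign(end - start) * step * np.arange(n + 1)
    sched[-1] = end
    return sched


def run_indentation(
    network: ElasticNetwork,
    schedule: np.ndarray,
    per_step_time: float = 100.0,  # ps of dynamics per separation
    dt: float = 5e-4,  # ps
    friction: float = 1.0,  # ps^-1
    temperature: float = 300.0,
    seed: int = 0,
    axis: str = "z",
    epsilon: float = 1.0,
    sigma: float = 0.5,
    center: float | None = None,
    extra_potentials: Sequence = (),
    stride: int = 20,
    report_wall: str = "right",
    initial_positions: np.ndarray | None = None,
    equilibration_fraction: float = 0.0,
) -> tuple[IndentationTrace, np.ndarray]:
    """Stepwise wall compression (or expansion) with per-step force averages.

    For every separation L in *schedule* the walls are held fixed while the
    system runs ``per_step_time`` of overdamped dynamics continuing from the
    previous step's final coordinates; the load the beads exert on
    ``report_wall`` is averaged over the step's recorded frames (mean and
    SD).  ``equilibration_fraction`` discards that leading fraction of each
    step's frames before averaging (0 = whole-step average, the default
    reporting convention; raise it for quasi-static estimates free of the
    post-move transient).  Returns the trace and the final coordinates (so a
    relaxation run can continue from the compressed state).
    """
    if not (0.0 <= equilibration_fraction < 1.0):
        raise IndentationError("equilibration_fraction must lie in [0, 1)")
    schedule = np.asarray(schedule, float)
    if schedule.ndim != 1 or schedule.size < 2:
        raise IndentationError("schedule needs at least 2 separations")
    direction = "forward" if schedule[1] < schedule[0] else "backward"
    if center is None:
        center = float(network.topology.positions[:, _AXIS[axis]].mean())
    n_steps = max(stride, int(round(per_step_time / dt)))
    x = np.array(
        initial_positions if initial_positions is not None else network.topology.positions,
        dtype=float,
    )
    model = HarmonicModel(network, temperature)
    which = 0 if report_wall == "left" else 1
    L_out, f_mean, f_sd, n_used = [], [], [], []
    for k, L in enumerate(schedule):
        wall = WallPair(axis=axis, separation=float(L), center=center,
                        epsilon=epsilon, sigma=sigma)
        try:
            ens = langevin_dynamics(
                model,
                extra_potentials=[wall, *extra_potentials],
                n_steps=n_steps,
                dt=dt,
                friction=friction,
                seed=seed + k,
                stride=stride,
                initial_positions=x,
            )
        except EngineError as exc:
            err = IndentationError(
                f"dynamics diverged at schedule step {k} (L={L} nm): {exc}"
            )
            if len(L_out) >= 2:
                err.partial_trace = IndentationTrace(
                    np.array(L_out), np.array(f_mean), np.array(f_sd),
                    np.array(n_used), direction,
                )
            raise err from exc
        x = ens.frames[-1]
        use = ens.frames[int(equilibration_fraction * ens.n_frames):]
        loads = np.array([wall.wall_load(f)[which] for f in use])
        L_out.append(L)
        f_mean.append(loads.mean())
        f_sd.append(loads.std())
        n_used.append(loads.size)
    trace = IndentationTrace(
        np.array(L_out), np.array(f_mean), np.array(f_sd),
        np.array(n_used), direction,
    )
    return trace, x


def running_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean over *window* samples (e.g. 10 or 50)."""
    if window < 1:
        raise IndentationError("window must be >= 1")
    kernel = np.ones(window) / window
    return np.convolve(np.asarray(values, float), kernel, mode="same")


def hysteresis_area(
    forward: IndentationTrace, backward: IndentationTrace
) -> float:
    """Trapezoidal area between compression and relaxation curves, kJ mol^-1.

    Positive when the compression branch carries more force than the
    relaxation branch (dissipated work); zero for reversible behaviour.
    """
    Lf = forward.L[::-1]  # ascending
    Ff = forward.mean_force[::-1]
    if backward.L.shape != Lf.shape or np.max(np.abs(backward.L - Lf)) > 1e-9:
        raise IndentationError("forward and backward traces cover different separations")
    return float(np.trapezoid(Ff - backward.mean_force, Lf))


# --------------------------------------------------------------------------- #
# quasi-static (zero-temperature) reference
# --------------------------------------------------------------------------- #

def minimize_under_walls(
    network: ElasticNetwork, wall: WallPair, x0: np.ndarray | None = None
) -> np.ndarray:
    """Energy-minimised coordinates of network + walls (L-BFGS, analytic grad)."""
    x0 = np.array(x0 if x0 is not None else network.topology.positions, float)

    def fun(flat: np.ndarray):
        x = flat.reshape(-1, 3)
        e = bond_energy(network, x) + wall.energy(x)
        g = -(bond_forces(network, x) + wall.forces(x))
        return e, g.ravel()

    res = scipy.optimize.minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                                  options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return res.x.reshape(-1, 3)


def constrained_stiffness(
    network: ElasticNetwork, wall: WallPair, coords: np.ndarray
) -> float:
    """Analytic quasi-static stiffness -dF/dL at an energy minimum.

    Linear response of the minimised system: the network Hessian is augmented
    with the wall curvature on the contact beads, the bead displacement per
    unit wall travel solves H_tot dx = -d(grad E)/dL, and the slope of the
    wall load follows by the chain rule.  Returned with the sign convention
    that a repulsive contact gives a positive stiffness (force grows as the
    walls close), kJ mol^-1 nm^-2.
    """
    a = _AXIS[wall.axis]
    hl, hr = wall._distances(coords)
    cl = _wall_curvature(hl, wall.epsilon, wall.sigma)
    cr = _wall_curvature(hr, wall.epsilon, wall.sigma)
    n = coords.shape[0]
    H = bond_hessian(network, coords)
    # wall curvature enters the (axis, axis) diagonal entries
    diag_idx = 3 * np.arange(n) + a
    H[diag_idx, diag_idx] += cl + cr
    # b = -d(grad E)/dL; each wall recedes by dL/2 with mirrored signs
    b = np.zeros(3 * n)
    b[diag_idx] = 0.5 * (cr - cl)
    dx, *_ = scipy.linalg.lstsq(H, b, lapack_driver="gelsd")
    dz = dx[diag_idx]
    # load on right wall: F_R = sum f(h_r); dF_R/dL = sum f'(h_r) (1/2 - dz)
    fprime_r = -cr  # f = -U'  =>  f' = -U''
    dF_dL = float(np.sum(fprime_r * (0.5 - dz)))
    return -dF_dL


def quasi_static_force_curve(
    network: ElasticNetwork,
    schedule: np.ndarray,
    axis: str = "z",
    epsilon: float = 1.0,
    sigma: float = 0.5,
    center: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-temperature force-separation curve by successive minimisation."""
    if center is None:
        center = float(network.topology.positions[:, _AXIS[axis]].mean())
    x = np.array(network.topology.positions, float)
    forces = np.empty(len(schedule))
    for k, L in enumerate(schedule):
        wall = WallPair(axis=axis, separation=float(L), center=center,
                        epsilon=epsilon, sigma=sigma)
        x = minimize_under_walls(network, wall, x)
        forces[k] = wall.wall_load(x)[1]
    return np.asarray(schedule, float), forces
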