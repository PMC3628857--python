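"""Synthetic ground-truth systems for testing and validation.

Real reference data for fluctuation matching are long atomistic trajectories;
everything in this module replaces them with small systems whose answers are
known by construction:

* a heterogeneous "truth" network — a compact, densely bonded core carrying a
  pendant, softly bonded tail.  The tail emulates the behaviour of a flexible
  terminal arm that happens to rest against the core in the reference
  conformation but explores a wide volume in the ensemble: exactly the kind
  of contact a single-snapshot cutoff criterion wrongly bonds;
* a quasi-uniform spherical bead shell (Fibonacci lattice) for wall
  indentation;
* a two-subunit "dimer" whose inter-unit orientation fluctuates about a
  hinge with a prescribed angular variance, for orientation-map analysis.

All generators are deterministic under their seed, and their outputs
round-trip through the structure and network writers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .engine import KB, assemble_hessian
from .networks import ElasticNetwork
from .structures import Ensemble, Structure


class FixtureError(RuntimeError):
    pass


@dataclass
class FixtureSpec:
    """Parameters of a ground-truth core+tail network."""

    n_core: int = 20
    n_tail: int = 0
    K_core_range: tuple[float, float] = (50.0, 500.0)  # kJ mol^-1 nm^-2
    K_tail_range: tuple[float, float] = (2.0, 10.0)
    geometry: str = "globule"  # globule | chain | shell
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core < 4:
            raise FixtureError("need at least 4 core beads")
        if self.n_tail < 0:
            raise FixtureError("n_tail must be >= 0")
        for lo, hi in (self.K_core_range, self.K_tail_range):
            if lo <= 0 or hi < lo:
                raise FixtureError("spring-constant ranges must be positive intervals")
        if self.geometry not in ("globule", "chain", "shell"):
            raise FixtureError(f"unknown geometry {self.geometry!r}")


def _count_zero_modes(net: ElasticNetwork) -> int:
    w = scipy.linalg.eigvalsh(assemble_hessian(net))
    tol = 1e-8 * max(w[-1], 1.0)
    return int(np.sum(np.abs(w) <= tol))


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), n))


def _core_positions(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_core
    if spec.geometry == "chain":
        # gentle helix, 0.38 nm rise between consecutive beads
        t = np.arange(n) * 0.9
        pts = np.stack([0.30 * np.cos(t), 0.30 * np.sin(t), 0.33 * np.arange(n)], axis=1)
        return pts + rng.normal(0, 0.01, (n, 3))
    if spec.geometry == "shell":
        return _fibonacci_sphere(n) * max(0.9, 0.25 * np.sqrt(n))
    # globule: min-separation rejection sampling inside a ball
    radius = max(0.9, 0.42 * n ** (1 / 3) + 0.35)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 200_000:
            raise FixtureError("could not pack core beads; spec too dense")
        p = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(p) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < 0.45:
            continue
        pts.append(p)
    return np.array(pts)


def _core_bonds(
    positions: np.ndarray, residues: np.ndarray, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    n = len(positions)
    i, j = np.triu_indices(n, k=1)
    d = np.linalg.norm(positions[i] - positions[j], axis=1)
    keep = (d < cutoff) & (np.abs(residues[j] - residues[i]) >= 2)
    return i[keep], j[keep]


def make_truth_system(spec: FixtureSpec) -> tuple[Structure, ElasticNetwork]:
    """Ground-truth heterogeneous network: rigid core, floppy pendant tail.

    Core bonds are placed between all residue-separated pairs within a
    neighbour cutoff with log-uniform spring constants in ``K_core_range``.
    Each tail bead sits just outside a core bead it hugs in the reference
    conformation and is softly tied (log-uniform ``K_tail_range``) to its
    three nearest sequence-eligible predecessors, so the assembled system is
    connected and mechanically rigid (exactly 6 zero modes) while the tail's
    fluctuations dwarf the core's.
    """
    rng = np.random.default_rng(spec.seed)
    core_pos = _core_positions(spec, rng)
    n_core, n_tail = spec.n_core, spec.n_tail
    residues = np.arange(1, n_core + n_tail + 1)
    chain = np.full(n_core + n_tail, "A", dtype=object)

    # tail path: hug the surface next to randomly chosen distinct core beads
    tail_pos = np.empty((n_tail, 3))
    if n_tail:
        anchors = rng.choice(n_core, size=n_tail, replace=n_tail > n_core)
        for k, a in enumerate(anchors):
            outward = core_pos[a] - core_pos.mean(axis=0)
            norm = np.linalg.norm(outward)
            outward = outward / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
            tail_pos[k] = core_pos[a] + 0.55 * outward + rng.normal(0, 0.03, 3)
    positions = np.vstack([core_pos, tail_pos]) if n_tail else core_pos
    struct = Structure(residues, chain, positions)

    for cutoff in (1.2, 1.35, 1.5, 1.8):
        bi, bj = _core_bonds(core_pos, residues[:n_core], cutoff)
        bonds = [(int(a), int(b)) for a, b in zip(bi, bj)]
        K = list(_log_uniform(rng, *spec.K_core_range, len(bonds)))
        # tail: 3 nearest sequence-eligible predecessors each
        for k in range(n_tail):
            bead = n_core + k
            cand = np.arange(bead)
            cand = cand[np.abs(residues[cand] - residues[bead]) >= 2]
            d = np.linalg.norm(positions[cand] - positions[bead], axis=1)
            for c in cand[np.argsort(d)][:3]:
                bonds.append((int(c), bead))
                K.append(float(_log_uniform(rng, *spec.K_tail_range, 1)[0]))
        bi_all = np.array([b[0] for b in bonds])
        bj_all = np.array([b[1] for b in bonds])
        r0 = np.linalg.norm(positions[bi_all] - positions[bj_all], axis=1)
        net = ElasticNetwork(
            struct, bi_all, bj_all, r0, np.array(K),
            provenance="synthetic-truth",
            meta={"fixture": "truth", "seed": spec.seed, "n_core": n_core,
                  "n_tail": n_tail, "geometry": spec.geometry, "cutoff": cutoff},
        )
        if _count_zero_modes(net) == 6:
            return struct, net
    raise FixtureError("generated network is floppy even at the densest cutoff")


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def make_toy_capsid(
    radius: float,
    n_beads: int,
    K: float | tuple[float, float] = 500.0,
    seed: int = 0,
    cutoff: float | None = None,
) -> tuple[Structure, ElasticNetwork]:
    """Quasi-uniform spherical bead shell with neighbour bonds.

    Beads sit on a Fibonacci lattice of the given radius (nm); bonds connect
    all sequence-eligible pairs within *cutoff* (default: twice the mean
    lattice spacing).  *K* may be a uniform constant or a (lo, hi) range for
    log-uniform heterogeneous constants.
    """
    if n_beads < 12:
        raise FixtureError("need at least 12 beads for a shell")
    rng = np.random.default_rng(seed)
    pos = _fibonacci_sphere(n_beads) * radius
    spacing = radius * np.sqrt(4.0 * np.pi / n_beads)
    cut = cutoff if cutoff is not None else 2.0 * spacing
    residues = np.arange(1, n_beads + 1)
    struct = Structure(residues, np.full(n_beads, "A", object), pos)
    bi, bj = _core_bonds(pos, residues, cut)
    if bi.size == 0:
        raise FixtureError(f"cutoff {cut:.3g} nm places no bonds")
    r0 = np.linalg.norm(pos[bi] - pos[bj], axis=1)
    if np.isscalar(K):
        Karr = np.full(bi.size, float(K))
    else:
        Karr = _log_uniform(rng, K[0], K[1], bi.size)
    net = ElasticNetwork(
        struct, bi, bj, r0, Karr,
        provenance="synthetic-shell",
        meta={"fixture": "toy-capsid", "seed": seed, "radius": radius,
              "n_beads": n_beads, "cutoff": cut},
    )
    if _count_zero_modes(net) != 6:
        raise FixtureError(
            f"shell with cutoff {cut:.3g} nm is not rigid; increase cutoff"
        )
    return struct, net


def _subunit_template(rng: np.random.Generator, n_beads: int = 150) -> np.ndarray:
    """Random globular subunit whose guide clusters span orthogonal axes."""
    from .rom import DEFAULT_CLUSTERS

    pos = rng.uniform(-1.0, 1.0, (n_beads, 3))
    pos *= 1.4 / np.maximum(np.linalg.norm(pos, axis=1), 1.0)[:, None]
    targets = {"X": np.array([1.5, 0, 0]), "Y": np.array([0, 1.5, 0]),
               "Z": np.array([0, 0, 1.5])}
    for label, residues in DEFAULT_CLUSTERS.items():
        for r in residues:
            pos[r - 1] = targets[label] + rng.normal(0, 0.05, 3)
    return pos - pos.mean(axis=0)


def make_dimer_fixture(
    hinge_stiffness: float,
    seed: int = 0,
    n_frames: int = 200,
    angles: np.ndarray | None = None,
    rotation_axis: np.ndarray | None = None,
    temperature: float = 300.0,
    positional_jitter: float = 0.0,
) -> Ensemble:
    """Two rigid subunits whose relative orientation wobbles about a hinge.

    Subunit 2 is a translated copy of subunit 1 (chains A and B, residues
    1-150 each, valid guide clusters for orientation analysis).  Per frame it
    is rotated rigidly about its own centre of mass by an angle drawn from
    N(0, kB*T / hinge_stiffness) — *hinge_stiffness* is an angular spring in
    kJ mol^-1 rad^-2 — about a fixed axis perpendicular to the internal
    Z-axis, so the Z-axis misalignment angle equals the drawn angle exactly.
    Pass *angles* (rad) to prescribe the rotation series instead.
    Frame 0 of the returned ensemble is the unrotated reference.
    """
    if hinge_stiffness <= 0:
        raise FixtureError("hinge_stiffness must be positive")
    rng = np.random.default_rng(seed)
    unit = _subunit_template(rng)
    n = unit.shape[0]
    offset = np.array([3.4, 0.0, 0.0])
    residues = np.concatenate([np.arange(1, n + 1)] * 2)
    chains = np.array(["A"] * n + ["B"] * n, object)
    reference = np.vstack([unit, unit + offset])
    topo = Structure(residues, chains, reference)

    if angles is None:
        sigma = np.sqrt(KB * temperature / hinge_stiffness)
        theta = rng.normal(0.0, sigma, n_frames)
        theta[0] = 0.0
    else:
        theta = np.asarray(angles, float)
        n_frames = theta.size
    u = np.asarray(
        rotation_axis if rotation_axis is not None else [1.0, 0.0, 0.0], float
    )
    u = u / np.linalg.norm(u)
    Kx = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    frames = np.empty((n_frames, 2 * n, 3))
    com2 = unit.mean(axis=0) + offset
    for t in range(n_frames):
        R = np.eye(3) + np.sin(theta[t]) * Kx + (1 - np.cos(theta[t])) * (Kx @ Kx)
        frames[t, :n] = unit
        frames[t, n:] = (unit + offset - com2) @ R.T + com2
        if positional_jitter > 0:
            frames[t] += rng.normal(0, positional_jitter, (2 * n, 3))
    return Ensemble(topo, frames)
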