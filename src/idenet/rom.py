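"""Relative orientation maps (ROMs) of protein dimers.

A ROM characterises how one subunit of a dimer is oriented relative to the
other over an ensemble.  Each subunit carries an internal reference frame:
origin at its centre of mass, and axes X, Y, Z pointing from the origin to
the centres of mass of fixed residue clusters (guide clusters chosen to be
approximately orthogonal).  Cluster-based axes are used instead of gyration-
tensor eigenvectors because near-degenerate gyration eigenvalues let those
eigenvectors swap identity between frames.

For a chosen axis M (X, Y or Z), every frame is processed as:

1. the whole dimer is rigidly fitted to a reference on subunit 1's core,
   removing global translation/rotation;
2. the internal axes M1 (subunit 1) and M2 (subunit 2) are computed;
3. the axis pair is rotated rigidly so M1 points along the global alignment
   direction (+z by default);
4. the projection p of M2 onto the plane normal to that direction, scaled by
   M2's guide length, is recorded.

|p| = L * sin(theta), with theta the M1-M2 angle: parallel axes project to
the origin, perpendicular ones onto the circle of radius L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structures import (
    Ensemble,
    Selection,
    Structure,
    StructureError,
    superpose_coords,
)

#: Guide clusters (1-based residue indices within a subunit).
METHODS_CLUSTERS: dict[str, list[int]] = {
    "X": [69, 70, 71, 92, 122, 123, 124],
    "Y": [19, 20, 21, 136],
    "Z": [55, 56, 57, 137, 138, 139],
}

#: Alternative preset: the guide clusters as annotated on the structure
#: overview figure (X identical, Y and Z differ from the methods lists).
FIGURE_CLUSTERS: dict[str, list[int]] = {
    "X": [69, 70, 71, 92, 122, 123, 124],
    "Y": [20, 21, 134, 135],
    "Z": [56, 57, 58, 99, 100],
}

DEFAULT_CLUSTERS = METHODS_CLUSTERS


class RomError(ValueError):
    pass


@dataclass
class InternalFrame:
    """Cluster-guided internal axes of one subunit."""

    origin: np.ndarray  # (3,) nm
    axes: np.ndarray  # (3, 3) unit rows in X, Y, Z order
    axis_lengths: np.ndarray  # (3,) nm, guide lengths before normalisation

    def axis(self, label: str) -> np.ndarray:
        return self.axes["XYZ".index(label)]

    def axis_length(self, label: str) -> float:
        return float(self.axis_lengths["XYZ".index(label)])


@dataclass
class RomResult:
    axis_label: str
    points: np.ndarray  # (F, 2) nm: L * sin(theta) decomposed in-plane
    theta: np.ndarray  # (F,) rad, M1-M2 angle
    com_distance: np.ndarray  # (F,) nm, D between subunit centres of mass
    circle_radius: float  # nm, longest guide length seen

    def density(self, n_bins: int = 60) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return density_map(self.points, n_bins, radius=self.circle_radius)

    def summary(self) -> tuple[float, float, float, float]:
        return rom_summary(self.points)


def _cluster_indices(struct: Structure, residues: list[int]) -> np.ndarray:
    idx = []
    for r in residues:
        hits = np.flatnonzero(struct.residue_index == r)
        if hits.size == 0:
            raise RomError(f"guide residue {r} missing from subunit")
        idx.extend(hits.tolist())
    return np.array(idx, int)


def internal_frame(
    struct: Structure, cluster_spec: dict[str, list[int]] | None = None
) -> InternalFrame:
    """Internal axes of one subunit from guide residue clusters.

    Axes are unit vectors from the subunit centre of mass to each cluster's
    centre of mass; their guide lengths (before normalisation) are kept for
    scaling projections.  Warns (does not fail) if the axes deviate from
    orthogonality by more than 25 degrees.
    """
    spec = cluster_spec or DEFAULT_CLUSTERS
    origin = struct.center_of_mass()
    axes = np.empty((3, 3))
    lengths = np.empty(3)
    for k, label in enumerate("XYZ"):
        guide = struct.positions[_cluster_indices(struct, spec[label])].mean(axis=0) - origin
        lengths[k] = np.linalg.norm(guide)
        if lengths[k] < 1e-9:
            raise RomError(f"{label}-axis guide cluster coincides with the origin")
        axes[k] = guide / lengths[k]
    angles = np.degrees(
        [
            np.arccos(np.clip(abs(axes[a] @ axes[b]), 0, 1))
            for a, b in ((0, 1), (0, 2), (1, 2))
        ]
    )
    if np.any(angles < 90.0 - 25.0):
        warnings.warn(
            f"internal axes far from orthogonal (pair angles {angles.round(1)} deg)",
            RuntimeWarning,
            stacklevel=2,
        )
    return InternalFrame(origin=origin, axes=axes, axis_lengths=lengths)


def _rotation_to(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation matrix taking unit vector u onto unit vector v.

    Rotates about u x v by their included angle; for antiparallel vectors
    (degenerate cross product) it rotates by pi about an arbitrary axis
    perpendicular to u — the documented tie-break.
    """
    c = float(np.clip(u @ v, -1.0, 1.0))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        perp = np.eye(3)[np.argmin(np.abs(u))]
        axis = perp - (perp @ u) * u
        axis /= np.linalg.norm(axis)
        s, c = 0.0, -1.0
    else:
        axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


_GLOBAL_DIR = {"x": np.array([1.0, 0, 0]), "z": np.array([0, 0, 1.0])}
_PLANE_AXES = {"z": (0, 1), "x": (1, 2)}  # in-plane coordinate components


def rom_projection(
    dimer_ens: Ensemble,
    axis_label: str,
    reference: Structure,
    cap1_sel: Selection,
    cap2_sel: Selection,
    cluster_spec: dict[str, list[int]] | None = None,
    fit_sel: Selection | None = None,
    align_to: str = "z",
) -> RomResult:
    """Project subunit 2's internal axis in the subunit-1-aligned frame.

    ``fit_sel`` (default: ``cap1_sel``) is the rigid-core selection used to
    superpose each frame on *reference*; the same reference must be used for
    every ensemble being compared.  ``align_to`` chooses the global direction
    M1 is rotated onto ('z' default, 'x' available for visualisation).
    """
    if axis_label not in "XYZ" or len(axis_label) != 1:
        raise RomError(f"axis_label must be 'X', 'Y' or 'Z', got {axis_label!r}")
    if align_to not in _GLOBAL_DIR:
        raise RomError("align_to must be 'z' or 'x'")
    target = _GLOBAL_DIR[align_to]
    ia, ib = _PLANE_AXES[align_to]
    fit_idx = (fit_sel or cap1_sel).resolve(reference)
    idx1 = cap1_sel.resolve(reference)
    idx2 = cap2_sel.resolve(reference)
    points = np.empty((dimer_ens.n_frames, 2))
    theta = np.empty(dimer_ens.n_frames)
    dist = np.empty(dimer_ens.n_frames)
    radius = 0.0
    for t in range(dimer_ens.n_frames):
        fitted, _ = superpose_coords(
            dimer_ens.frames[t], reference.positions, fit_idx
        )
        frame = dimer_ens.topology.with_positions(fitted)
        f1 = internal_frame(frame.subset(idx1), cluster_spec)
        f2 = internal_frame(frame.subset(idx2), cluster_spec)
        m1, m2 = f1.axis(axis_label), f2.axis(axis_label)
        length2 = f2.axis_length(axis_label)
        R = _rotation_to(m1, target)
        m2r = R @ m2
        points[t] = length2 * m2r[[ia, ib]]
        # atan2 form is well conditioned at theta ~ 0 and ~ pi
        theta[t] = np.arctan2(np.linalg.norm(np.cross(m1, m2)), m1 @ m2)
        dist[t] = np.linalg.norm(f2.origin - f1.origin)
        radius = max(radius, float(f1.axis_lengths.max()), float(f2.axis_lengths.max()))
    return RomResult(
        axis_label=axis_label,
        points=points,
        theta=theta,
        com_distance=dist,
        circle_radius=radius,
    )


def density_map(
    points: np.ndarray, n_bins: int, radius: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised 2D occupancy histogram over [-r, r]^2.

    Returns (density, x_edges, y_edges); the density sums to 1 (probability
    mass per bin, not per area).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] != 2:
        raise RomError("points must be a non-empty (F, 2) array")
    r = float(radius) if radius is not None else float(np.abs(pts).max() or 1.0)
    # nudge so on-boundary points (|p| == r) are counted
    r *= 1.0 + 1e-9
    H, xe, ye = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=n_bins, range=[[-r, r], [-r, r]]
    )
    return H / pts.shape[0], xe, ye


def rom_summary(points: np.ndarray) -> tuple[float, float, float, float]:
    """Componentwise (mean_x, mean_y, sd_x, sd_y) of the projected cloud."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise RomError("need at least 2 points for summary statistics")
    mean = pts.mean(axis=0)
    sd = pts.std(axis=0)
    return float(mean[0]), float(mean[1]), float(sd[0]), float(sd[1])


def write_rom_csv(result: RomResult, path) -> None:
    """Per-frame CSV: t, p_x, p_y, theta (rad), D (nm)."""
    with open(path, "w") as fh:
        fh.write("t,p_x_nm,p_y_nm,theta_rad,D_nm\n")
        for t in range(result.points.shape[0]):
            fh.write(
                f"{t},{result.points[t, 0]:.9g},{result.points[t, 1]:.9g},"
                f"{result.theta[t]:.9g},{result.com_distance[t]:.9g}\n"
            )
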