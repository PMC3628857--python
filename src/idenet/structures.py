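"""Bead-resolution structures, ensembles, selections and rigid-body analysis.

The package works on coarse-grained protein models in which each residue is
represented by a single bead (the C-alpha position).  A :class:`Structure`
holds one labelled conformation, an :class:`Ensemble` a stack of conformations
sharing that topology (a trajectory, or any other sample set to average over).
All coordinates are stored in nanometres; PDB files (Angstrom) are converted
on read.

Superposition is least-squares rigid-body fitting (Kabsch); reflections are
rejected so chirality is always preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation


class StructureError(ValueError):
    """Raised for malformed structure/ensemble inputs."""


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

@dataclass
class Structure:
    """One bead-resolution conformation.

    Parameters
    ----------
    residue_index : (N,) int array, 1-based residue numbers, strictly
        increasing within each chain.
    chain_id : (N,) array of short strings.
    positions : (N, 3) float array, nm.

    Bead ids are implicit: bead ``k`` is row ``k`` (dense from 0).
    """

    residue_index: np.ndarray
    chain_id: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        n = self.residue_index.shape[0]
        if self.chain_id.shape != (n,) or self.positions.shape != (n, 3):
            raise StructureError(
                f"inconsistent field shapes: {n} residues, "
                f"{self.chain_id.shape} chains, {self.positions.shape} positions"
            )
        if n and not np.all(np.isfinite(self.positions)):
            raise StructureError("non-finite coordinates")
        for chain in self.chains:
            res = self.residue_index[self.chain_id == chain]
            if np.any(np.diff(res) <= 0):
                raise StructureError(
                    f"residue indices not strictly increasing in chain {chain!r}"
                )

    @property
    def n_beads(self) -> int:
        return len(self.residue_index)

    @property
    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(c, None)
        return list(seen)

    def with_positions(self, positions: np.ndarray) -> "Structure":
        """Same labelling, new coordinates."""
        return Structure(self.residue_index, self.chain_id, np.asarray(positions, float))

    def subset(self, beads: Sequence[int]) -> "Structure":
        """Structure restricted to the given bead indices (order preserved)."""
        idx = np.asarray(beads, dtype=int)
        return Structure(self.residue_index[idx], self.chain_id[idx], self.positions[idx])

    def center_of_mass(self) -> np.ndarray:
        """Unweighted bead centroid, nm."""
        return self.positions.mean(axis=0)


@dataclass
class Ensemble:
    """Ordered set of conformations with identical topology.

    ``frames`` has shape (n_frames, n_beads, 3) in nm; ``topology`` supplies
    the bead labelling (its own coordinates are the reference conformation).
    """

    topology: Structure
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.topology.n_beads, 3):
            raise StructureError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.topology.n_beads}-bead topology"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.topology.n_beads

    def frame(self, t: int) -> Structure:
        return self.topology.with_positions(self.frames[t])


@dataclass
class Selection:
    """Subset of beads, by explicit index list or by residue range.

    ``residue_range`` is an inclusive 1-based ``(lo, hi)`` applied per chain;
    ``chains`` optionally restricts which chains the range applies to.
    Exactly one of ``beads`` / ``residue_range`` must be given.
    """

    beads: Sequence[int] | None = None
    residue_range: tuple[int, int] | None = None
    chains: Sequence[str] | None = None

    def resolve(self, struct: Structure) -> np.ndarray:
        """Bead indices of this selection on *struct* (ascending)."""
        if (self.beads is None) == (self.residue_range is None):
            raise StructureError("give exactly one of beads / residue_range")
        if self.beads is not None:
            idx = np.asarray(self.beads, dtype=int)
            if idx.size == 0:
                raise StructureError("empty selection")
            if idx.min() < 0 or idx.max() >= struct.n_beads:
                raise StructureError("selection references beads outside structure")
            return np.unique(idx)
        lo, hi = self.residue_range
        mask = (struct.residue_index >= lo) & (struct.residue_index <= hi)
        if self.chains is not None:
            mask &= np.isin(struct.chain_id.astype(str), list(self.chains))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise StructureError(
                f"selection residues {lo}-{hi} (chains={self.chains}) matches no beads"
            )
        return idx


def all_beads(struct: Structure) -> Selection:
    return Selection(beads=np.arange(struct.n_beads))


# --------------------------------------------------------------------------- #
# readers / writers
# --------------------------------------------------------------------------- #

_A_TO_NM = 0.1


def _structure_from_biopdb_model(model) -> Structure:
    res_idx, chains, xyz = [], [], []
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.get_name().strip() == "CA":
                    res_idx.append(residue.get_id()[1])
                    chains.append(chain.get_id())
                    xyz.append(atom.get_coord() * _A_TO_NM)
    if not xyz:
        raise StructureError("no CA atoms found in PDB model")
    return Structure(np.array(res_idx), np.array(chains, object), np.array(xyz))


def _parse_pdb_models(path: Path):
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure("s", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureError(f"malformed PDB file {path}: {exc}") from exc
    models = list(bio)
    if not models:
        raise StructureError(f"no models in PDB file {path}")
    return models


def _read_table(path: Path, n_cols: int) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != n_cols:
                raise StructureError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            rows.append(parts)
    if not rows:
        raise StructureError(f"{path}: no data rows")
    return np.array(rows, dtype=object)


def _table_structure(rows: np.ndarray, path) -> Structure:
    # columns: bead residue chain x y z
    order = np.argsort(rows[:, 0].astype(int))
    rows = rows[order]
    bead = rows[:, 0].astype(int)
    if not np.array_equal(bead, np.arange(len(bead))):
        raise StructureError(f"{path}: bead ids must be dense from 0")
    return Structure(
        rows[:, 1].astype(int),
        rows[:, 2],
        rows[:, 3:6].astype(float),
    )


def read_structure(path: str | Path, dialect: str = "pdb") -> Structure:
    """Read one conformation.

    ``dialect='pdb'``: CA atoms of the first MODEL; Angstrom -> nm.
    ``dialect='table'``: whitespace rows ``bead residue chain x y z`` (nm),
    ``#`` comments allowed.
    """
    path = Path(path)
    if dialect == "pdb":
        return _structure_from_biopdb_model(_parse_pdb_models(path)[0])
    if dialect == "table":
        return _table_structure(_read_table(path, 6), path)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_ensemble(path: str | Path, dialect: str = "pdb") -> Ensemble:
    """Read a multi-conformation file.

    ``dialect='pdb'``: one frame per MODEL record.
    ``dialect='table'``: whitespace rows ``frame bead residue chain x y z``.
    Every frame must match the first frame's topology.
    """
    path = Path(path)
    if dialect == "pdb":
        structs = [_structure_from_biopdb_model(m) for m in _parse_pdb_models(path)]
        topo = structs[0]
        frames = np.empty((len(structs), topo.n_beads, 3))
        for t, s in enumerate(structs):
            if s.n_beads != topo.n_beads:
                raise StructureError(
                    f"frame {t} has {s.n_beads} beads, expected {topo.n_beads}"
                )
            frames[t] = s.positions
        return Ensemble(topo, frames)
    if dialect == "table":
        rows = _read_table(path, 7)
        frame_ids = rows[:, 0].astype(int)
        order = np.unique(frame_ids)
        per_frame = [rows[frame_ids == f, 1:] for f in order]
        topo = _table_structure(per_frame[0], path)
        frames = np.empty((len(per_frame), topo.n_beads, 3))
        for t, block in enumerate(per_frame):
            if block.shape[0] != topo.n_beads:
                raise StructureError(
                    f"frame {order[t]} has {block.shape[0]} beads, "
                    f"expected {topo.n_beads}"
                )
            frames[t] = _table_structure(block, path).positions
        return Ensemble(topo, frames)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_structure(struct: Structure, path: str | Path, dialect: str = "pdb") -> None:
    if dialect == "table":
        with open(path, "w") as fh:
            fh.write("# bead residue chain x_nm y_nm z_nm\n")
            for k in range(struct.n_beads):
                x, y, z = struct.positions[k]
                fh.write(
                    f"{k} {struct.residue_index[k]} {struct.chain_id[k]} "
                    f"{x:.17g} {y:.17g} {z:.17g}\n"
                )
        return
    write_ensemble(Ensemble(struct, struct.positions[None]), path, dialect)


def write_ensemble(ens: Ensemble, path: str | Path, dialect: str = "pdb") -> None:
    """Write an ensemble as a multi-model CA-only PDB or a plain table."""
    path = Path(path)
    topo = ens.topology
    if dialect == "pdb":
        with open(path, "w") as fh:
            for t in range(ens.n_frames):
                fh.write(f"MODEL     {t + 1:4d}\n")
                for k in range(topo.n_beads):
                    x, y, z = ens.frames[t, k] / _A_TO_NM  # nm -> A
                    fh.write(
                        f"ATOM  {k + 1:5d}  CA  ALA {str(topo.chain_id[k])[:1]:1s}"
                        f"{topo.residue_index[k]:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")
    elif dialect == "table":
        with open(path, "w") as fh:
            fh.write("# frame bead residue chain x_nm y_nm z_nm\n")
            for t in range(ens.n_frames):
                for k in range(topo.n_beads):
                    x, y, z = ens.frames[t, k]
                    fh.write(
                        f"{t} {k} {topo.residue_index[k]} {topo.chain_id[k]} "
                        f"{x:.17g} {y:.17g} {z:.17g}\n"
                    )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# --------------------------------------------------------------------------- #
# superposition and deviation measures
# --------------------------------------------------------------------------- #

def _check_fit_points(ref: np.ndarray) -> None:
    if ref.shape[0] < 3:
        raise StructureError("need at least 3 beads to superpose")
    centered = ref - ref.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise StructureError("selected beads are collinear; fit is degenerate")


def superpose_coords(
    mobile: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray
) -> tuple[np.ndarray, float]:
    """Rigid-body least-squares fit of coordinate arrays.

    Rotation+translation are fitted on ``fit_idx`` only (proper rotation,
    det = +1) and applied to every bead.  Returns the transformed coordinates
    and the fitted-bead RMSD in nm.
    """
    ref = reference[fit_idx]
    mob = mobile[fit_idx]
    _check_fit_points(ref)
    ref_c, mob_c = ref.mean(axis=0), mob.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    moved = rot.apply(mobile - mob_c) + ref_c
    dev = moved[fit_idx] - ref
    return moved, float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))


def superpose(
    mobile: Structure, reference: Structure, sel: Selection
) -> tuple[Structure, float]:
    """Kabsch superposition of *mobile* onto *reference* over *sel*.

    The transform is fitted on the selected beads and applied to all beads.
    Returns the moved structure and the selected-bead RMSD (nm).
    """
    idx = sel.resolve(reference)
    sel.resolve(mobile)  # must also resolve on mobile
    moved, rmsd = superpose_coords(mobile.positions, reference.positions, idx)
    return mobile.with_positions(moved), rmsd


def coords_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no-fit) RMSD between congruent coordinate arrays, nm."""
    dev = a - b
    return float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))


def rmsd_series(
    ens: Ensemble,
    reference: Structure,
    fit_sel: Selection,
    measure_sel: Selection | None = None,
) -> np.ndarray:
    """Per-frame RMSD over *measure_sel* after fitting each frame on *fit_sel*.

    With ``measure_sel=fit_sel`` this is the usual fitted RMSD time series;
    fitting on one region and measuring on another quantifies relative motion
    (e.g. fit on one monomer core, measure over the whole dimer core).
    """
    fit_idx = fit_sel.resolve(reference)
    measure_idx = (measure_sel or fit_sel).resolve(reference)
    out = np.empty(ens.n_frames)
    for t in range(ens.n_frames):
        moved, _ = superpose_coords(ens.frames[t], reference.positions, fit_idx)
        out[t] = coords_rmsd(moved[measure_idx], reference.positions[measure_idx])
    return out


def fitted_frames(
    ens: Ensemble, reference: Structure, fit_sel: Selection
) -> np.ndarray:
    """All frames rigidly fitted to *reference* on *fit_sel*; (F, N, 3) nm."""
    fit_idx = fit_sel.resolve(reference)
    out = np.empty_like(ens.frames)
    for t in range(ens.n_frames):
        out[t], _ = superpose_coords(ens.frames[t], reference.positions, fit_idx)
    return out


def rmsf(ens: Ensemble, reference: Structure, fit_sel: Selection) -> np.ndarray:
    """Per-bead root-mean-square fluctuation about the ensemble mean, nm.

    Frames are first fitted to *reference* on *fit_sel* to remove overall
    translation and rotation; fluctuations are then measured about the mean
    of the fitted frames.
    """
    if ens.n_frames < 2:
        raise StructureError("RMSF undefined for fewer than 2 frames")
    frames = fitted_frames(ens, reference, fit_sel)
    dev = frames - frames.mean(axis=0)
    return np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))


def histogram(values: Sequence[float], bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Density histogram with fixed bin width.

    Bins are left-closed right-open, anchored so the minimum value sits on a
    bin edge; the global maximum falls in the last bin (on-edge maxima are not
    opened into a new empty bin).  Densities are normalised so that
    ``sum(density) * bin_width == 1``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = v.min(), v.max()
    n_bins = int(math.floor((hi - lo) / bin_width + 1e-12)) + 1
    idx = np.minimum(
        np.floor((v - lo) / bin_width + 1e-12).astype(int), n_bins - 1
    )
    counts = np.bincount(idx, minlength=n_bins)
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width
    density = counts / (v.size * bin_width)
    return centers, density
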