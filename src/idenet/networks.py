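"""Elastic network construction: cutoff networks and fluctuation-gated ones.

Two constructions are provided.  ``build_elnedyn`` is the classic anisotropic
cutoff network: every same-chain bead pair at least ``min_seq_sep`` residues
apart along the backbone and closer than ``R_c`` in the input conformation is
bonded with one uniform spring constant (standard choice R_c = 0.9 nm,
K = 500 kJ mol^-1 nm^-2).

``select_iden_bonds`` refines that criterion using ensemble statistics: the
gate distance is the ensemble-average distance rather than a single-snapshot
one, and the pair must in addition either be strongly correlated (c_ij above
a threshold) OR have a small distance variance.  Pairs that are close merely
by accident — a flexible tail resting against the core in one conformation —
fail both branches and stay unbonded, so the network does not freeze motion
the reference ensemble actually shows.

``assign_initial_constants`` then seeds heterogeneous spring constants: the
stiffest (lowest-variance) bond gets K0 and every other bond is scaled down
inversely proportional to its distance variance, K_ij = K0 * Var_min /
Var(d_ij).  Rest lengths are ensemble-mean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pairstats import PairStatistics
from .structures import Structure

#: Cutoff-network defaults (nm, kJ mol^-1 nm^-2).
DEFAULT_CUTOFF = 0.9
DEFAULT_K = 500.0
DEFAULT_MIN_SEQ_SEP = 2

#: Suggested fluctuation-gate values.  These are this package's defaults;
#: they are deliberately *not* baked into IdenCriteria — both thresholds must
#: be given explicitly so that no analysis silently depends on them.
SUGGESTED_CORR_MIN = 0.5
SUGGESTED_VAR_MAX = 0.01  # nm^2


class NetworkError(ValueError):
    pass


@dataclass
class ElasticNetwork:
    """Bead topology plus harmonic bonds.

    Bonds are stored as parallel arrays ``i < j`` (bead indices), rest length
    ``r0`` (nm) and spring constant ``K`` (kJ mol^-1 nm^-2).  Bonds never
    cross chains and always span at least 2 residues along the backbone:
    networks support a single protein unit internally, never tie units
    together.
    """

    topology: Structure
    bond_i: np.ndarray
    bond_j: np.ndarray
    r0: np.ndarray
    K: np.ndarray
    provenance: str = "unspecified"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bond_i = np.asarray(self.bond_i, dtype=int)
        self.bond_j = np.asarray(self.bond_j, dtype=int)
        self.r0 = np.asarray(self.r0, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        nb = self.n_bonds
        if not (self.bond_j.shape == self.r0.shape == self.K.shape == (nb,)):
            raise NetworkError("bond arrays have inconsistent lengths")
        if nb == 0:
            return
        if np.any(self.bond_i >= self.bond_j):
            raise NetworkError("bonds must have i < j")
        if self.bond_i.min() < 0 or self.bond_j.max() >= self.topology.n_beads:
            raise NetworkError("bond references bead outside topology")
        pairs = set(zip(self.bond_i.tolist(), self.bond_j.tolist()))
        if len(pairs) != nb:
            raise NetworkError("duplicate bond pair")
        if np.any(self.r0 <= 0) or np.any(self.K <= 0):
            raise NetworkError("rest lengths and spring constants must be positive")
        ch = self.topology.chain_id
        if np.any(ch[self.bond_i] != ch[self.bond_j]):
            raise NetworkError("inter-chain bonds are not allowed")
        sep = np.abs(
            self.topology.residue_index[self.bond_j]
            - self.topology.residue_index[self.bond_i]
        )
        if np.any(sep < 2):
            raise NetworkError("bonds must span at least 2 residues along the chain")

    @property
    def n_bonds(self) -> int:
        return self.bond_i.shape[0]

    @property
    def n_beads(self) -> int:
        return self.topology.n_beads

    def bond_pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.bond_i.tolist(), self.bond_j.tolist()))

    def with_constants(self, K: np.ndarray, provenance: str | None = None) -> "ElasticNetwork":
        """Same topology and bonds, new spring constants."""
        return ElasticNetwork(
            self.topology, self.bond_i, self.bond_j, self.r0,
            np.asarray(K, float).copy(),
            provenance if provenance is not None else self.provenance,
            dict(self.meta),
        )


@dataclass
class IdenCriteria:
    """Bond-selection thresholds for the fluctuation-gated network.

    ``corr_min`` and ``var_max`` have no defaults on purpose: the gate values
    are study choices, and every analysis must state them.
    ``SUGGESTED_CORR_MIN``/``SUGGESTED_VAR_MAX`` give this package's suggested
    starting point.
    """

    corr_min: float
    var_max: float  # nm^2
    cutoff: float = DEFAULT_CUTOFF  # nm, gate on the ensemble-MEAN distance
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP
    K0: float = DEFAULT_K  # kJ mol^-1 nm^-2

    def __post_init__(self) -> None:
        if not (0.0 <= self.corr_min <= 1.0):
            raise NetworkError("corr_min must lie in [0, 1]")
        if self.var_max <= 0 or self.cutoff <= 0 or self.K0 <= 0:
            raise NetworkError("var_max, cutoff and K0 must be positive")
        if self.min_seq_sep < 1:
            raise NetworkError("min_seq_sep must be >= 1")


def _eligible_pairs(topo: Structure, min_seq_sep: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs on the same chain with sequence separation >= sep."""
    n = topo.n_beads
    i, j = np.triu_indices(n, k=1)
    same = topo.chain_id[i] == topo.chain_id[j]
    sep = np.abs(topo.residue_index[j] - topo.residue_index[i]) >= min_seq_sep
    keep = same & sep
    return i[keep], j[keep]


def build_elnedyn(
    struct: Structure,
    cutoff: float = DEFAULT_CUTOFF,
    K: float = DEFAULT_K,
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
) -> ElasticNetwork:
    """Uniform cutoff network on a single conformation.

    Bond (i, j) iff same chain, |res_j - res_i| >= min_seq_sep, and the
    distance in *struct* is below *cutoff*; rest length = that distance.
    """
    if struct.n_beads == 0:
        raise NetworkError("empty structure")
    i, j = _eligible_pairs(struct, min_seq_sep)
    d = np.linalg.norm(struct.positions[i] - struct.positions[j], axis=1)
    keep = d < cutoff
    return ElasticNetwork(
        struct, i[keep], j[keep], d[keep],
        np.full(int(keep.sum()), float(K)),
        provenance="elnedyn",
        meta={"R_c": cutoff, "K0": float(K), "min_seq_sep": min_seq_sep},
    )


def select_iden_bonds(
    stats: PairStatistics, topo: Structure, crit: IdenCriteria
) -> list[tuple[int, int]]:
    """Fluctuation-gated bond selection.

    (i, j) is bonded iff: same chain; sequence separation >= min_seq_sep;
    ensemble-mean distance < cutoff; and (correlation >= corr_min OR distance
    variance <= var_max).  An undefined correlation (frozen bead, NaN) simply
    fails the correlation branch; the variance branch can still bond the pair.
    """
    if stats.n_beads != topo.n_beads:
        raise NetworkError(
            f"statistics cover {stats.n_beads} beads, topology has {topo.n_beads}"
        )
    i, j = _eligible_pairs(topo, crit.min_seq_sep)
    close = stats.mean_distance[i, j] < crit.cutoff
    with np.errstate(invalid="ignore"):
        correlated = stats.correlation[i, j] >= crit.corr_min  # NaN -> False
    quiet = stats.distance_variance[i, j] <= crit.var_max
    keep = close & (correlated | quiet)
    return list(zip(i[keep].tolist(), j[keep].tolist()))


def assign_initial_constants(
    bonds: Sequence[tuple[int, int]],
    stats: PairStatistics,
    topo: Structure,
    K0: float = DEFAULT_K,
    crit: IdenCriteria | None = None,
) -> ElasticNetwork:
    """Heterogeneous initial spring constants from distance variances.

    K_ij = K0 * Var_min / Var(d_ij) with Var_min the smallest variance among
    the placed bonds, so the stiffest bond gets exactly K0 and every bond
    satisfies K_ij * Var(d_ij) = K0 * Var_min.  Bonds with exactly zero
    variance also get K0.  Rest lengths are the ensemble-mean distances.
    """
    if len(bonds) == 0:
        raise NetworkError("no bonds to assign constants to")
    i = np.array([b[0] for b in bonds], dtype=int)
    j = np.array([b[1] for b in bonds], dtype=int)
    var = stats.distance_variance[i, j]
    r0 = stats.mean_distance[i, j]
    positive = var > 0
    if positive.any():
        var_min = var[positive].min()
        K = np.where(positive, K0 * var_min / np.where(positive, var, 1.0), K0)
    else:
        K = np.full(len(bonds), float(K0))
    meta = {"K0": float(K0)}
    if crit is not None:
        meta.update(
            R_c=crit.cutoff, corr_min=crit.corr_min,
            var_max=crit.var_max, min_seq_sep=crit.min_seq_sep,
        )
    return ElasticNetwork(topo, i, j, r0, K, provenance="iden-initial", meta=meta)


def build_iden(
    stats: PairStatistics, topo: Structure, crit: IdenCriteria
) -> ElasticNetwork:
    """Convenience: select bonds, then assign initial constants."""
    bonds = select_iden_bonds(stats, topo, crit)
    return assign_initial_constants(bonds, stats, topo, K0=crit.K0, crit=crit)


# --------------------------------------------------------------------------- #
# serialization
# --------------------------------------------------------------------------- #

def write_network(net: ElasticNetwork, path: str | Path) -> None:
    """Lossless plain-text network file (topology + bonds)."""
    topo = net.topology
    with open(path, "w") as fh:
        fh.write(f"# idenet network provenance={net.provenance}\n")
        for k, v in net.meta.items():
            fh.write(f"# meta {k}={v!r}\n")
        fh.write(f"# beads {topo.n_beads} : id residue chain x_nm y_nm z_nm\n")
        for k in range(topo.n_beads):
            x, y, z = topo.positions[k]
            fh.write(
                f"bead {k} {topo.residue_index[k]} {topo.chain_id[k]} "
                f"{x:.17g} {y:.17g} {z:.17g}\n"
            )
        fh.write(f"# bonds {net.n_bonds} : i j r0_nm K_kJ_mol_nm2\n")
        for i, j, r0, K in zip(net.bond_i, net.bond_j, net.r0, net.K):
            fh.write(f"bond {i} {j} {r0:.17g} {K:.17g}\n")


def read_network(path: str | Path) -> ElasticNetwork:
    provenance = "unspecified"
    meta: dict = {}
    beads, bonds = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "provenance=" in line:
                    provenance = line.split("provenance=")[1].split()[0]
                elif line.startswith("# meta "):
                    k, v = line[len("# meta "):].split("=", 1)
                    import ast
                    meta[k] = ast.literal_eval(v)
                continue
            parts = line.split()
            if parts[0] == "bead":
                beads.append(parts[1:])
            elif parts[0] == "bond":
                bonds.append(parts[1:])
            else:
                raise NetworkError(f"{path}:{lineno}: unrecognised record {parts[0]!r}")
    if not beads:
        raise NetworkError(f"{path}: no beads")
    beads.sort(key=lambda p: int(p[0]))
    topo = Structure(
        np.array([int(b[1]) for b in beads]),
        np.array([b[2] for b in beads], object),
        np.array([[float(b[3]), float(b[4]), float(b[5])] for b in beads]),
    )
    pairs = [(int(b[0]), int(b[1])) for b in bonds]
    if len(set(pairs)) != len(pairs):
        raise NetworkError(f"{path}: duplicate bond pair")
    return ElasticNetwork(
        topo,
        np.array([p[0] for p in pairs], int),
        np.array([p[1] for p in pairs], int),
        np.array([float(b[2]) for b in bonds]),
        np.array([float(b[3]) for b in bonds]),
        provenance,
        meta,
    )


def write_topology_include(net: ElasticNetwork, path: str | Path) -> None:
    """Bonded-term include file for importing the network into a CG engine.

    One ``i j funct r0 K`` line per bond, 1-based indices, funct = 1
    (harmonic), suitable for pasting into a topology [bonds] section.
    """
    with open(path, "w") as fh:
        fh.write(f"; elastic network bonds provenance={net.provenance}\n")
        for i, j, r0, K in zip(net.bond_i, net.bond_j, net.r0, net.K):
            fh.write(f"{i + 1} {j + 1} 1 {r0:.6f} {K:.6f}\n")
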