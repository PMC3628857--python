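"""Per-pair fluctuation statistics of bead ensembles.

These are the quantities that drive heterogeneous-network construction:

* the scalar covariance of a bead pair,
  ``cov_ij = <(r_i - <r_i>) . (r_j - <r_j>)>`` (nm^2), computed after rigidly
  fitting every frame to a reference to remove overall translation/rotation;
* its normalised form, the correlation coefficient
  ``c_ij = cov_ij / sqrt(cov_ii cov_jj)`` — the "per-atom normalised
  covariance" of the crystallographic literature, bounded in [-1, 1];
* the mean inter-bead distance ``dmean_ij = <|r_i - r_j|>`` (nm) and its
  variance ``dvar_ij`` (nm^2), which need no fitting because distances are
  rigid-motion invariant.

The fitting step that makes covariances well defined also suppresses genuine
correlation between rigid-core beads, which is why distance fluctuations are
kept as an independent, fit-free statistic: bonding decisions combine both.

Averages use population normalisation (1/F) and two-pass (mean, then
deviation) accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures import Ensemble, Selection, Structure, all_beads, fitted_frames


class StatisticsError(ValueError):
    pass


@dataclass
class PairStatistics:
    """Symmetric per-pair statistics matrices for an N-bead topology.

    ``correlation`` is NaN where a bead has zero positional variance (frozen
    bead): the correlation is undefined there, and such pairs simply fail any
    correlation-based criterion rather than raising.
    """

    mean_distance: np.ndarray  # (N, N) nm
    distance_variance: np.ndarray  # (N, N) nm^2
    covariance: np.ndarray  # (N, N) nm^2
    correlation: np.ndarray  # (N, N) dimensionless, NaN where undefined
    n_frames: int

    def __post_init__(self) -> None:
        n = self.mean_distance.shape[0]
        for name in ("mean_distance", "distance_variance", "covariance", "correlation"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (n, n):
                raise StatisticsError(f"{name} is not {n}x{n}")
            if not np.allclose(m, m.T, equal_nan=True):
                raise StatisticsError(f"{name} is not symmetric")
            setattr(self, name, m)
        if np.any(self.distance_variance < -1e-12):
            raise StatisticsError("negative distance variance")

    @property
    def n_beads(self) -> int:
        return self.mean_distance.shape[0]


def pair_covariance(
    ens: Ensemble, reference: Structure, fit_sel: Selection | None = None
) -> np.ndarray:
    """Scalar covariance matrix cov_ij (nm^2), frames fitted to *reference*.

    Fitting defaults to all beads; pass a core-region selection to fit on the
    rigid part only.
    """
    if ens.n_frames < 2:
        raise StatisticsError("need at least 2 frames for covariances")
    frames = fitted_frames(ens, reference, fit_sel or all_beads(reference))
    dev = frames - frames.mean(axis=0)
    return np.einsum("tik,tjk->ij", dev, dev) / ens.n_frames


def correlation_coefficients(cov: np.ndarray) -> np.ndarray:
    """Normalise a covariance matrix to correlation coefficients.

    Rows/columns of zero-variance beads come out NaN (undefined, flagged).
    """
    cov = np.asarray(cov, dtype=float)
    diag = np.diag(cov)
    if np.any(diag < -1e-12 * max(np.abs(diag).max(), 1.0)):
        raise StatisticsError("covariance has negative diagonal entries")
    diag = np.clip(diag, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.sqrt(np.outer(diag, diag))
    corr[~np.isfinite(corr)] = np.nan
    # Cauchy-Schwarz can be violated by rounding only; clip to the bound.
    return np.clip(corr, -1.0, 1.0)


def _pair_distances(frames: np.ndarray) -> np.ndarray:
    diff = frames[:, :, None, :] - frames[:, None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=3))


def distance_stats(ens: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    """Mean pair distance (nm) and its variance (nm^2), no fitting.

    Distances are invariant under per-frame rigid motion, so unlike the
    covariance no superposition is applied (or needed).
    """
    if ens.n_frames < 2:
        raise StatisticsError("need at least 2 frames for distance statistics")
    d = _pair_distances(ens.frames)
    dmean = d.mean(axis=0)
    dev = d - dmean
    return dmean, (dev * dev).mean(axis=0)


def compute_pair_statistics(
    ens: Ensemble, reference: Structure | None = None, fit_sel: Selection | None = None
) -> PairStatistics:
    """All pair statistics of an ensemble in one object."""
    reference = reference or ens.topology
    cov = pair_covariance(ens, reference, fit_sel)
    dmean, dvar = distance_stats(ens)
    return PairStatistics(
        mean_distance=dmean,
        distance_variance=dvar,
        covariance=cov,
        correlation=correlation_coefficients(cov),
        n_frames=ens.n_frames,
    )


def average_over_units(
    stats_list: Sequence[PairStatistics],
    unit_maps: Sequence[np.ndarray] | None = None,
) -> PairStatistics:
    """Average statistics over equivalent units (e.g. the chains of a dimer).

    ``unit_maps[u][k]`` gives, for universal bead ``k``, the bead index in
    unit ``u``.  Averaging acts on the statistics matrices, never on
    coordinates, so no unphysical average structure is ever built.  Yields one
    universal statistics set whose frame count is the sum over units.
    """
    if not stats_list:
        raise StatisticsError("no statistics to average")
    if unit_maps is None:
        unit_maps = [np.arange(s.n_beads) for s in stats_list]
    if len(unit_maps) != len(stats_list):
        raise StatisticsError("one unit map per statistics set required")
    n = len(unit_maps[0])
    acc = {k: np.zeros((n, n)) for k in
           ("mean_distance", "distance_variance", "covariance", "correlation")}
    for stats, amap in zip(stats_list, unit_maps):
        amap = np.asarray(amap, dtype=int)
        if amap.shape != (n,):
            raise StatisticsError("unit maps have inconsistent lengths")
        if amap.min() < 0 or amap.max() >= stats.n_beads:
            raise StatisticsError("unit map references beads outside its unit")
        ix = np.ix_(amap, amap)
        for k in acc:
            acc[k] += getattr(stats, k)[ix]
    m = len(stats_list)
    return PairStatistics(
        mean_distance=acc["mean_distance"] / m,
        distance_variance=acc["distance_variance"] / m,
        covariance=acc["covariance"] / m,
        correlation=np.clip(acc["correlation"] / m, -1.0, 1.0),
        n_frames=sum(s.n_frames for s in stats_list),
    )


# --------------------------------------------------------------------------- #
# serialization
# --------------------------------------------------------------------------- #

def write_stats(stats: PairStatistics, path: str | Path) -> None:
    """Write the upper triangle (incl. diagonal) as a plain table.

    Columns: ``i j dmean_nm dvar_nm2 cov_nm2 corr``; exact round-trip.
    """
    n = stats.n_beads
    with open(path, "w") as fh:
        fh.write(f"# idenet pair statistics n_beads={n} n_frames={stats.n_frames}\n")
        fh.write("# i j dmean_nm dvar_nm2 cov_nm2 corr\n")
        for i in range(n):
            for j in range(i, n):
                fh.write(
                    f"{i} {j} {stats.mean_distance[i, j]:.17g} "
                    f"{stats.distance_variance[i, j]:.17g} "
                    f"{stats.covariance[i, j]:.17g} "
                    f"{stats.correlation[i, j]:.17g}\n"
                )


def read_stats(path: str | Path) -> PairStatistics:
    n = n_frames = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for tok in line.split():
                    if tok.startswith("n_beads="):
                        n = int(tok.split("=")[1])
                    elif tok.startswith("n_frames="):
                        n_frames = int(tok.split("=")[1])
                continue
            if line:
                rows.append(line.split())
    if n is None or n_frames is None:
        raise StatisticsError(f"{path}: missing n_beads/n_frames header")
    mats = [np.zeros((n, n)) for _ in range(4)]
    for parts in rows:
        i, j = int(parts[0]), int(parts[1])
        for m, val in zip(mats, parts[2:6]):
            m[i, j] = m[j, i] = float(val)
    return PairStatistics(*mats, n_frames=n_frames)
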